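# Methods

## Model and conventions

All binding constants are **apparent (conditional) macroscopic** stepwise
dissociation constants at pH 7.4, stored and manipulated as −log₁₀ molar
values ("pkd"). Proton competition is folded into the conditional constants;
no proton sub-equilibria, ternary species, statistical factors or activity
corrections are added. Step i of a model is the association of the i-th
Zn(II) onto Zn_{i−1}-protein, counted **tightest first** (pkd_steps
non-increasing). Experimental tables often index dissociation from the holo
form instead, so their "K_d1" (first zinc lost, i.e. the weakest site) is
this package's step n; `step_from_release_index` /
`release_index_from_step` make that conversion explicit rather than leaving
an off-by-one trap.

Cumulative Adair constants are running sums of pkd values in log₁₀ space;
a 9-site protein has β₉ ≈ 10⁹⁰, so species weights are always formed as
log₁₀ β_i + i·log₁₀ z with max-subtraction before exponentiation. Species
fractions therefore sum to 1 to < 1e−9 over the full working range
z ∈ [1e−20, 1e−1] M.

Grouped tabulated entries (e.g. four tight sites sharing one printed
constant) expand to repeated identical step constants, one per site; this is
the convention under which the bundled models reproduce the published
speciation maxima. For the bacterial proteins the bundled model is two tight
sites at the metal-buffer average constant, one intermediate site at the
moderate estimate, and the weakest site at the fluorescent-probe competition
value. PflQ2MT has no metal-buffer value of its own (its CD competition
changes were within experimental error), so its tight pair carries 14.5, the
mean of the SmtA (14.68) and TvMT (14.3) values, marked "estimated" in the
fixture; nothing downstream depends on it quantitatively.

## Mass-balance solver

`solve_free_zinc` solves Zn_tot = z + Σ bound(z) for free zinc. Bound terms:
protein → P_tot · mean occupancy; 1:1 chelator or probe → L_tot·z/(z+K_d);
2:1 probe → z·P_free²/K_d12 with its own ligand balance
P_tot = P_free + 2[ZnL₂], solved in the quadratic root form
P_free = 2P_tot/(1+√(1+8zP_tot/K_d12)) that stays stable as z→0. The
residual is strictly decreasing in z, so the root in log₁₀ z ∈ [−20, −1] is
unique; it is located with Brent's method (xtol 1e−14), which brackets like
plain bisection but converges in fewer residual evaluations, and the
solution is accepted only if total zinc is reconstructed to a relative
1e−8. Zn_tot = 0 short-circuits to an all-apo sentinel (free Zn 0, pZn
undefined as +inf) instead of raising, so ratio grids that start at zero
work. An independent dense-grid sign-scan solver lives in the test suite
and agrees with the package solver to < 1e−6 log units on randomized
mixed systems.

Useful exact identities used throughout: d log f_i / d log z = i − n̄(z), so
the interior maximum of the Zn_i fraction sits exactly where the mean
occupancy equals i (`peak_pzn` solves n̄(z) = i by bracketing rather than
differentiating a grid); and when adjacent steps are well separated the peak
converges to the midpoint of the neighbouring step constants. The
`buffering_window` endpoints solve n̄ = c·n and n̄ = (1−c)·n, reducing to the
10–90% logistic width for a single site.

One caveat on "identical sites": equal **macroscopic** step constants do not
describe independent identical sites (the partition function is not
binomial). `independent_sites_model` builds the macro steps that do —
pkd_i = pkd_micro + log₁₀((n−i+1)/i) — and only for that construction does
occupancy/n equal z/(z+K_d) exactly; the property suite asserts this
identity and the estimator/forward consistency checks use it.

## Estimators

**Average per-site constant.** From a transfer endpoint of t mol eq (of x)
to the 2:1 probe: free zinc from K_d12·[ZnL₂]/([L]_free)², then
K_d^av = z·t/(x−t), the per-site empty/filled form. Validated against the
published table of ten MTs: nine reproduce to ≤ 0.05 log units from the
printed transfers; OsMTI-1B (printed 10.78, computed 10.48) does not
reproduce under any variant examined and is carried as a documented outlier,
not force-fitted. The whole-molecule cooperative form misses by ~0.6 log
units and is not used. The reported standard error propagates ±0.005 mol eq
(half a printed last digit) through the formula.

**Equal-constant stepwise model** (1–3 weakest sites, tighter sites assumed
full): with a = K/z and the species that has lost k zincs weighted a^k,
solve Σk·a^k/Σa^k = t for a by bracketing; K = a·z. n=1 reduces exactly to
K_d1 = z·t/(1−t). The published two-/three-step averages mostly but not
exactly reproduce under this model (e.g. 10.45 computed vs 10.52 printed
for one protein); the model is implemented as stated and the residual
discrepancies are accepted rather than tuned away.

**Weak-site isotherm fits.** t(z) = Σ_k K_k/(K_k+z) over 1–2 weak sites
(least squares in −log₁₀ K via lmfit), or the cooperative all-or-nothing
variant t(z) = n·K^n/(K^n+z^n) for proteins whose last n zincs leave in one
transition. Site 1 is reported as the weakest. Fits against data generated
from a full stepwise model (rather than the fit's own independent-site
form) carry a model-mismatch bias that grows with how closely the moderate
sites crowd the weak ones — up to ~0.5 log units for the worst bundled case
— which is why end-to-end recovery tolerances are wider than the ±0.05
achieved when generator and fit share the functional form.

**Tight/moderate refinement.** Each declared affinity group is represented
by one shared constant; a coordinate-descent sweep over a 0.05-log-unit grid
on [9, 16] (matching the one-decimal precision of grouped published
constants) minimizes Σ(pZn_model − pZn_obs)² of the full competition
equilibrium, ties broken toward the tighter constant, followed by a
0.01-step local polish. With no probe present the objective carries no
information and the call returns a `no-competition` error flag immediately.
A refined group constant more than 4 decades above the probe's pkd is
flagged `underestimated-range`: 4 decades corresponds to a ~1e−4 relative
fluorescence resolution in the calibration equation, beyond which the probe
cannot distinguish tighter constants — this reproduces the exclusion of
bacterial tight sites from probe-based refinement while leaving the
picomolar animal/plant tight sites (≤ 11.7 vs threshold 12.26) unflagged.

**Hill fits.** Shared logistic-in-log form
y = y_lo + (y_hi−y_lo)/(1+10^{n(m−x)}) with the Hill coefficient free by
default (fixable by flag; whether the original analyses fixed it is not
stated, and leaving it free is the weaker assumption). The pH variant
returns pKa′ with a monotonicity warning when the data back-step by more
than 3σ of the fit scatter. The metal-buffer variant iterates: fit → from
the fitted plateaus compute each point's fractional transfer and
protein-bound zinc → correct the buffered free zinc for pool depletion,
z′ = K_chel(ZnL − transferred)/(L_free + transferred) → refit, until the
midpoint moves < 0.01 log units; transfer exceeding the ZnL pool is an
input error. At 20 µM protein against 0.5 mM buffers the correction matters
(the low-saturation points lose a third of their pool) and zero-noise
recovery is within ±0.05 log units.

**Kinetics.** A(t) = A₀ + A_amp(1−e^{−kt}) with the offset fitted, since
baseline absorbances of the source traces are unspecified; initialization
from the observed half-rise time; flat traces return a flagged
non-convergence instead of a rate. Endpoint detection fits a continuous
piecewise-linear model with 1–2 free knots (hinge basis, grid-initialized,
Nelder-Mead refined, knots constrained to the interior, ties toward smaller
x); a knot that does not improve on a single line is flagged
unidentifiable. The chelator-rate relation is ordinary least squares of
log₁₀ k_obsd (base 10 to match conventional axes) on chelator −logK_d.

## Synthetic data

Simulators generate from ground truth through the same equilibrium
formalism the estimators invert; Gaussian noise is applied in signal space
with σ expressed as a fraction of each trace's dynamic range, and a fixed
seed reproduces the dataset bit-for-bit. pZn values attached to simulated
datasets come from the package solver deliberately, so recovery tests
isolate estimator error from solver error (solver correctness is tested
separately against the independent grid-scan oracle). The CD forward model
takes ellipticity proportional to the fractional saturation of the model it
is given; callers pass the tight-site submodel, reflecting that the CD
change tracks formation of the zinc-finger fold.

What the simulators do **not** emulate: instrument drift, photobleaching,
inner-filter effects, heteroscedastic noise, or slow transfer kinetics.
The last point matters for the bacterial proteins: their published probe
transfers were equilibrated for an hour and remain far below what the
bundled equilibrium models predict (e.g. SmtA: 0.05 mol eq measured vs
0.45 simulated), because the probe-competition constant for the weakest
bacterial site (13.36) and the fluorescent-probe value the fixture carries
(11.2) are not mutually consistent. The simulators answer "what would
equilibrium give for these constants", not "what did the instrument read";
passing recovery tests therefore validates the estimator machinery, not the
internal consistency of any particular constant set.

Known inconsistency, flagged not forced: from the bundled constants the
Zn₄ species of SmtA dominates near pZn 10 (the weakest site, pkd 11.2, is
~94% occupied there); a published statement placing Zn₂ there is consistent
only with a transposition. The SmtA Zn₃ maximum computes to pZn 12.05 and
the XlMT Zn₅ maximum to 9.72 (published as 12.1 and 9.6 respectively);
Zn₆ of XlMT computes to 8.54, matching the published 8.5. The moderate
SmtA constant is taken as the printed 12.9 rather than the unrounded
weak/tight mean 12.94.

## Pipeline and problem sizes

The demo pipeline simulates, per protein: one probe-competition endpoint
(1 µM protein, 200 µM 2:1 probe), a 25-point transfer isotherm
(0.05–5 µM 1:1 probe, 0.5 µM protein), a 23-point pH titration (pH 2.5–8,
Hill n = 2), 21 metal-buffer CD points (three chelators × seven
saturations, 20 µM protein, 0.5 mM ligand; bacterial proteins with a buffer
value only), and a 60-point kinetic trace (k = 0.01 s⁻¹) — sizes chosen to
match the corresponding bench experiments while keeping the full ten-protein
demo under a few seconds. Transfers above three equivalents are outside the
stepwise estimator's scope and are skipped with a flag (one bundled protein,
whose nine sites release ~3.7 eq at equilibrium). Monte-Carlo calibration
uses 200 replicates at 2% noise. Identical config and seed give
byte-identical JSON outputs.

## Limitations

* No explicit proton or ternary equilibria, no Cd(II) or Cu(I) models, no
  ionic-strength/activity corrections: everything is conditional at pH 7.4.
* Macroscopic constants only; microscopic site identities are not resolved.
* The equal-constant stepwise transfer model and the independent-site weak
  fits are summaries; when real site constants are closely spaced the
  grouped estimates interpolate between them (bias documented above).
* Equilibrium only: slow-exchange systems (bacterial MTs vs the 2:1 probe)
  are simulated at their thermodynamic endpoint, which published endpoint
  readings need not have reached.
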