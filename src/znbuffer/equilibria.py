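"""Multi-component Zn(II) binding equilibria at fixed pH.

The central object is a :class:`SteppedBindingModel`: a protein described by
its ordered *macroscopic* stepwise apparent dissociation constants (stored as
-log10 molar values at pH 7.4, tightest step first).  From the stepwise
constants the cumulative (Adair) association constants follow, and with free
Zn(II) as the independent variable every Zn_i-protein molar fraction is a
closed-form expression.  When total rather than free zinc is known, a scalar
mass balance over all components (protein, 1:1 chelators, 1:1 and 2:1
chromophoric/fluorescent probes) is solved for free Zn(II) by root bracketing
on the log10 concentration axis.

All cumulative-constant arithmetic is carried out in log10 space: a 9-site
protein has beta_9 ~ 1e90, far beyond double range.

Conventions
-----------
* Concentrations are molar; constants are -log10 molar ("pkd") apparent
  (conditional) values at pH 7.4.  No proton competition or statistical
  factors are added on top of the tabulated constants.
* Step i of a model is the association of the i-th Zn(II) onto the
  Zn_{i-1}-protein, counted tightest-first.  Experimental work often indexes
  dissociation from the holo form instead (the "first" constant lost is the
  weakest site); :func:`step_from_release_index` converts explicitly.
* pZn = -log10 of the free Zn(II) molar concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SteppedBindingModel",
    "OneToOneChelator",
    "TwoToOneProbe",
    "OneToOneProbe",
    "EquilibriumSystem",
    "EquilibriumState",
    "SpeciationProfile",
    "ConvergenceError",
    "cumulative_log_betas",
    "species_fractions_at_free_zn",
    "mean_occupancy",
    "solve_free_zinc",
    "speciation_vs_pzn",
    "speciation_vs_ratio",
    "peak_pzn",
    "buffering_window",
    "independent_sites_model",
    "step_from_release_index",
    "release_index_from_step",
]

#: search bracket for free Zn(II), log10 molar
LOG_FREE_ZN_MIN = -20.0
LOG_FREE_ZN_MAX = -1.0


class ConvergenceError(RuntimeError):
    """Mass-balance root finding failed; carries diagnostic context."""


@dataclass(frozen=True)
class SteppedBindingModel:
    """Ordered stepwise apparent Zn(II) dissociation constants of a protein.

    Parameters
    ----------
    name
        Text label, e.g. ``"XlMT"``.
    pkd_steps
        -log10 stepwise apparent dissociation constants (molar, pH 7.4),
        tightest first (non-increasing).  Length defines the maximum Zn load.
    site_groups
        Optional affinity grouping, mapping a label (``"tight"``,
        ``"moderate"``, ``"weak"``) to 1-based step indices.  Used by the
        tight/moderate refinement and by CD forward models.
    notes
        Free-text provenance remarks carried through from config files.
    """

    name: str
    pkd_steps: tuple[float, ...]
    site_groups: Optional[Mapping[str, tuple[int, ...]]] = None
    notes: str = ""

    def __post_init__(self) -> None:
        steps = tuple(float(p) for p in self.pkd_steps)
        if len(steps) < 1:
            raise ValueError(f"{self.name}: model needs at least one site")
        if not all(math.isfinite(p) and p > 0 for p in steps):
            raise ValueError(f"{self.name}: pkd_steps must be finite and > 0, got {steps}")
        if any(a < b - 1e-9 for a, b in zip(steps, steps[1:])):
            raise ValueError(
                f"{self.name}: pkd_steps must be non-increasing (tightest first), got {steps}"
            )
        object.__setattr__(self, "pkd_steps", steps)
        if self.site_groups is not None:
            for label, idx in self.site_groups.items():
                bad = [i for i in idx if not (1 <= i <= len(steps))]
                if bad:
                    raise ValueError(f"{self.name}: group {label!r} has out-of-range steps {bad}")

    @property
    def n_sites(self) -> int:
        return len(self.pkd_steps)

    def cumulative_log_betas(self) -> np.ndarray:
        return cumulative_log_betas(self)

    def group_steps(self, label: str) -> tuple[int, ...]:
        if not self.site_groups or label not in self.site_groups:
            raise KeyError(f"{self.name}: no site group {label!r}")
        return tuple(self.site_groups[label])

    def subset(self, label: str) -> "SteppedBindingModel":
        """Sub-model containing only the steps of one affinity group."""
        idx = self.group_steps(label)
        steps = tuple(sorted((self.pkd_steps[i - 1] for i in idx), reverse=True))
        return SteppedBindingModel(name=f"{self.name}:{label}", pkd_steps=steps)

    def with_steps(self, pkd_steps: Sequence[float]) -> "SteppedBindingModel":
        steps = tuple(sorted((float(p) for p in pkd_steps), reverse=True))
        return SteppedBindingModel(
            name=self.name, pkd_steps=steps, site_groups=self.site_groups, notes=self.notes
        )


@dataclass(frozen=True)
class OneToOneChelator:
    """1:1 chelator (e.g. ATP, NTA, EDTA, TPEN) with apparent pkd at pH 7.4."""

    name: str
    pkd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pkd):
            raise ValueError(f"{self.name}: pkd must be finite")

    @property
    def kd(self) -> float:
        return 10.0 ** (-self.pkd)


@dataclass(frozen=True)
class TwoToOneProbe:
    """Chromogenic 2:1 (ligand:metal) probe such as PAR.

    ``kd12`` is the overall dissociation constant of the Zn(ligand)2 complex
    in M^2; ``epsilon_492`` the molar absorptivity of the complex.
    """

    name: str
    kd12: float
    epsilon_492: float
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kd12 > 0):
            raise ValueError(f"{self.name}: kd12 must be > 0")
        if not (self.epsilon_492 > 0):
            raise ValueError(f"{self.name}: epsilon_492 must be > 0")


@dataclass(frozen=True)
class OneToOneProbe:
    """Fluorescent 1:1 probe such as ZnAF-2F (signal increases on binding)."""

    name: str
    pkd: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.pkd):
            raise ValueError(f"{self.name}: pkd must be finite")

    @property
    def kd(self) -> float:
        return 10.0 ** (-self.pkd)


@dataclass(frozen=True)
class EquilibriumSystem:
    """Totals of Zn(II) plus any mixture of binding components.

    ``protein``, ``probe_2to1`` and ``probe_1to1`` are (object, total-molar)
    pairs; ``chelators`` a sequence of such pairs.
    """

    zn_total: float
    protein: Optional[tuple[SteppedBindingModel, float]] = None
    chelators: tuple[tuple[OneToOneChelator, float], ...] = ()
    probe_2to1: Optional[tuple[TwoToOneProbe, float]] = None
    probe_1to1: Optional[tuple[OneToOneProbe, float]] = None

    def __post_init__(self) -> None:
        totals = [self.zn_total]
        for pair in (self.protein, self.probe_2to1, self.probe_1to1, *self.chelators):
            if pair is not None:
                totals.append(pair[1])
        if any(t < 0 for t in totals):
            raise ValueError("all totals must be >= 0")


@dataclass(frozen=True)
class EquilibriumState:
    """Solution of one mass balance: free Zn and every species concentration."""

    free_zn: float
    species: Mapping[str, float]
    residual: float
    all_apo: bool = False

    @property
    def pzn(self) -> float:
        return -math.log10(self.free_zn) if self.free_zn > 0 else math.inf


@dataclass(frozen=True)
class SpeciationProfile:
    """Molar fractions of Zn_0..Zn_x protein species over a grid.

    ``fractions`` has one row per grid point and ``n_sites + 1`` columns.
    """

    axis_kind: str  # "pzn" | "ratio"
    axis: np.ndarray
    fractions: np.ndarray
    free_zn: np.ndarray
    model_name: str = ""

    def __post_init__(self) -> None:
        if self.axis_kind not in ("pzn", "ratio"):
            raise ValueError(f"axis_kind must be 'pzn' or 'ratio', got {self.axis_kind!r}")

    @property
    def n_sites(self) -> int:
        return self.fractions.shape[1] - 1

    def to_frame(self):
        """Tidy DataFrame (axis, species, fraction, free_zn_M)."""
        import pandas as pd

        rows = []
        for j in range(self.fractions.shape[1]):
            rows.append(
                pd.DataFrame(
                    {
                        self.axis_kind: self.axis,
                        "species": j,
                        "fraction": self.fractions[:, j],
                        "free_zn_M": self.free_zn,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# closed-form species arithmetic


def cumulative_log_betas(model: SteppedBindingModel) -> np.ndarray:
    """log10 cumulative (Adair) association constants beta_1..beta_n.

    beta_i = prod_{j<=i} 1/Kd_j, so log10 beta_i is simply the running sum of
    the stepwise pkd values.
    """
    return np.cumsum(np.asarray(model.pkd_steps, dtype=float))


def _log_species_weights(model: SteppedBindingModel, log_z: np.ndarray) -> np.ndarray:
    """log10 relative weights of Zn_0..Zn_n at log10 free Zn values.

    Shape (len(log_z), n_sites + 1); column 0 (apo) is identically zero
    before normalization.
    """
    log_z = np.atleast_1d(np.asarray(log_z, dtype=float))
    logb = np.concatenate([[0.0], cumulative_log_betas(model)])
    i = np.arange(model.n_sites + 1)
    return logb[None, :] + i[None, :] * log_z[:, None]


def _fractions_from_log_z(model: SteppedBindingModel, log_z: np.ndarray) -> np.ndarray:
    s = _log_species_weights(model, log_z)
    s -= s.max(axis=1, keepdims=True)  # max-subtraction for stability
    w = 10.0 ** s
    return w / w.sum(axis=1, keepdims=True)


def species_fractions_at_free_zn(model: SteppedBindingModel, free_zn: float) -> np.ndarray:
    """Molar fractions of Zn_0..Zn_n protein species at a given free Zn(II).

    fraction_i is proportional to beta_i * [Zn]^i, evaluated in log space.
    """
    if not (free_zn > 0):
        raise ValueError(f"free_zn must be > 0, got {free_zn}")
    return _fractions_from_log_z(model, np.array([math.log10(free_zn)]))[0]


def mean_occupancy(model: SteppedBindingModel, free_zn: float) -> float:
    """Average number of Zn(II) bound per protein molecule; in [0, n_sites]."""
    f = species_fractions_at_free_zn(model, free_zn)
    return float(np.arange(model.n_sites + 1) @ f)


def _mean_occupancy_log(model: SteppedBindingModel, log_z: float) -> float:
    f = _fractions_from_log_z(model, np.array([log_z]))[0]
    return float(np.arange(model.n_sites + 1) @ f)


# ---------------------------------------------------------------------------
# mass balance


def _free_2to1_ligand(z: float, p_total: float, kd12: float) -> float:
    """Free ligand of a 2:1 probe from its own mass balance.

    Solves c*P^2 + P - P_tot = 0 with c = 2 z / kd12, using the root form
    that stays stable as z -> 0.
    """
    if p_total == 0.0:
        return 0.0
    c = 2.0 * z / kd12
    return 2.0 * p_total / (1.0 + math.sqrt(1.0 + 4.0 * c * p_total))


def _bound_zinc(system: EquilibriumSystem, z: float) -> float:
    bound = 0.0
    if system.protein is not None:
        model, p_tot = system.protein
        if p_tot > 0:
            bound += p_tot * _mean_occupancy_log(model, math.log10(z))
    for chel, l_tot in system.chelators:
        if l_tot > 0:
            bound += l_tot * z / (z + chel.kd)
    if system.probe_1to1 is not None:
        probe, l_tot = system.probe_1to1
        if l_tot > 0:
            bound += l_tot * z / (z + probe.kd)
    if system.probe_2to1 is not None:
        probe, p_tot = system.probe_2to1
        if p_tot > 0:
            p_free = _free_2to1_ligand(z, p_tot, probe.kd12)
            bound += z * p_free * p_free / probe.kd12
    return bound


def _species_at(system: EquilibriumSystem, z: float) -> dict[str, float]:
    species: dict[str, float] = {"Zn_free": z}
    if system.protein is not None:
        model, p_tot = system.protein
        if z > 0:
            frac = species_fractions_at_free_zn(model, z)
        else:
            frac = np.zeros(model.n_sites + 1)
            frac[0] = 1.0
        for i, f in enumerate(frac):
            species[f"{model.name}:Zn{i}"] = p_tot * f
    for chel, l_tot in system.chelators:
        znl = l_tot * z / (z + chel.kd) if z > 0 else 0.0
        species[f"{chel.name}:Zn"] = znl
        species[f"{chel.name}:free"] = l_tot - znl
    if system.probe_1to1 is not None:
        probe, l_tot = system.probe_1to1
        znl = l_tot * z / (z + probe.kd) if z > 0 else 0.0
        species[f"{probe.name}:Zn"] = znl
        species[f"{probe.name}:free"] = l_tot - znl
    if system.probe_2to1 is not None:
        probe, p_tot = system.probe_2to1
        if z > 0 and p_tot > 0:
            p_free = _free_2to1_ligand(z, p_tot, probe.kd12)
            znp2 = z * p_free * p_free / probe.kd12
        else:
            p_free, znp2 = p_tot, 0.0
        species[f"{probe.name}:ZnL2"] = znp2
        species[f"{probe.name}:free"] = p_free
    return species


def solve_free_zinc(
    system: EquilibriumSystem,
    rel_tol: float = 1e-8,
) -> EquilibriumState:
    """Solve the scalar Zn(II) mass balance for free Zn and all species.

    The residual ``zn_total - z - bound(z)`` is strictly decreasing in z, so
    a sign change inside the bracket [1e-20, 1e-1] M identifies the root
    uniquely; it is located by Brent's method on log10 z.

    ``zn_total = 0`` short-circuits to an all-apo state with free Zn 0.
    """
    if system.zn_total == 0.0:
        return EquilibriumState(
            free_zn=0.0, species=_species_at(system, 0.0), residual=0.0, all_apo=True
        )

    def residual(log_z: float) -> float:
        z = 10.0 ** log_z
        return system.zn_total - z - _bound_zinc(system, z)

    lo, hi = LOG_FREE_ZN_MIN, LOG_FREE_ZN_MAX
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo < 0 or r_hi > 0:
        raise ConvergenceError(
            f"no sign change in [{lo}, {hi}]: residual({lo})={r_lo:.3e}, "
            f"residual({hi})={r_hi:.3e}, zn_total={system.zn_total:.3e}"
        )
    log_z = brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=300)
    z = 10.0 ** log_z
    rec = z + _bound_zinc(system, z)
    rel = abs(system.zn_total - rec) / max(system.zn_total, 1e-30)
    if rel > rel_tol:
        raise ConvergenceError(
            f"mass balance residual {rel:.3e} exceeds {rel_tol:.1e} at z={z:.3e}"
        )
    return EquilibriumState(free_zn=z, species=_species_at(system, z), residual=rel)


# ---------------------------------------------------------------------------
# speciation profiles


def _check_grid(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError(f"{name} grid is empty")
    d = np.diff(grid)
    if grid.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError(f"{name} grid must be strictly monotone")
    return grid


def speciation_vs_pzn(model: SteppedBindingModel, pzn_grid: Sequence[float]) -> SpeciationProfile:
    """Species distribution with free Zn(II) as the independent variable.

    Closed-form per-point evaluation; no mass-balance solve is needed because
    pZn fixes the free concentration directly.
    """
    grid = _check_grid(np.asarray(pzn_grid), "pzn")
    log_z = -grid
    fractions = _fractions_from_log_z(model, log_z)
    return SpeciationProfile(
        axis_kind="pzn",
        axis=grid,
        fractions=fractions,
        free_zn=10.0 ** log_z,
        model_name=model.name,
    )


def speciation_vs_ratio(
    model: SteppedBindingModel,
    protein_total: float,
    ratio_grid: Sequence[float],
    extra_components: Optional[EquilibriumSystem] = None,
) -> SpeciationProfile:
    """Species distribution along a Zn(II)/apo-protein molar-ratio titration.

    Each grid point sets zn_total = ratio * protein_total and solves the full
    mass balance (any extra chelators/probes of ``extra_components`` compete).
    """
    if not (protein_total > 0):
        raise ValueError("protein_total must be > 0")
    grid = _check_grid(np.asarray(ratio_grid), "ratio")
    extra = extra_components
    fractions = np.zeros((grid.size, model.n_sites + 1))
    free = np.zeros(grid.size)
    for k, r in enumerate(grid):
        system = EquilibriumSystem(
            zn_total=r * protein_total,
            protein=(model, protein_total),
            chelators=extra.chelators if extra else (),
            probe_2to1=extra.probe_2to1 if extra else None,
            probe_1to1=extra.probe_1to1 if extra else None,
        )
        try:
            state = solve_free_zinc(system)
        except ConvergenceError as err:
            raise ConvergenceError(f"ratio grid point {r}: {err}") from err
        free[k] = state.free_zn
        if state.all_apo:
            fractions[k, 0] = 1.0
        else:
            fractions[k] = species_fractions_at_free_zn(model, state.free_zn)
    return SpeciationProfile(
        axis_kind="ratio", axis=grid, fractions=fractions, free_zn=free, model_name=model.name
    )


def peak_pzn(model: SteppedBindingModel, species_index: int) -> float:
    """pZn at which the Zn_i species reaches its maximal molar fraction.

    The log-fraction derivative with respect to log z is (i - occupancy), so
    the interior maximum sits exactly where the mean occupancy equals i.
    Terminal species have no interior maximum: index 0 returns +inf (apo
    dominates as Zn vanishes) and index n_sites returns -inf.
    """
    if not (0 <= species_index <= model.n_sites):
        raise ValueError(f"species_index must be in [0, {model.n_sites}]")
    if species_index == 0:
        return math.inf
    if species_index == model.n_sites:
        return -math.inf
    return _pzn_at_occupancy(model, float(species_index))


def _pzn_at_occupancy(model: SteppedBindingModel, target: float) -> float:
    lo, hi = -30.0, 5.0
    f = lambda log_z: _mean_occupancy_log(model, log_z) - target
    return -brentq(f, lo, hi, xtol=1e-12, maxiter=300)


def buffering_window(model: SteppedBindingModel, coverage: float = 0.9) -> tuple[float, float]:
    """pZn interval over which the protein absorbs/releases most of its zinc.

    Returns (pzn_low, pzn_high) where mean occupancy equals
    ``coverage * n_sites`` at pzn_low (zinc-rich end) and
    ``(1 - coverage) * n_sites`` at pzn_high (zinc-poor end).
    """
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    n = model.n_sites
    return (
        _pzn_at_occupancy(model, coverage * n),
        _pzn_at_occupancy(model, (1.0 - coverage) * n),
    )


# ---------------------------------------------------------------------------
# helpers


def independent_sites_model(name: str, n_sites: int, pkd_micro: float) -> SteppedBindingModel:
    """Macroscopic model equivalent to ``n_sites`` identical independent sites.

    Equal microscopic constants imply macroscopic steps carrying statistical
    factors: pkd_i = pkd_micro + log10((n - i + 1) / i).  For this model the
    binding polynomial is (1 + z/Kd)^n, so occupancy/n == z/(z+Kd) exactly.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    steps = [pkd_micro + math.log10((n_sites - i + 1) / i) for i in range(1, n_sites + 1)]
    return SteppedBindingModel(name=name, pkd_steps=tuple(steps))


def step_from_release_index(model: SteppedBindingModel, release_index: int) -> int:
    """Convert a dissociation-order index (1 = first Zn lost from the holo
    form, i.e. the weakest site) to this package's association-order step."""
    if not (1 <= release_index <= model.n_sites):
        raise ValueError(f"release_index must be in [1, {model.n_sites}]")
    return model.n_sites - release_index + 1


def release_index_from_step(model: SteppedBindingModel, step: int) -> int:
    """Inverse of :func:`step_from_release_index` (the mapping is involutive)."""
    if not (1 <= step <= model.n_sites):
        raise ValueError(f"step must be in [1, {model.n_sites}]")
    return model.n_sites - step + 1
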