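"""Affinity estimators: competition formulas, curve fits, refinement."""

import math

import numpy as np
import pytest

from znbuffer.equilibria import (
    EquilibriumSystem,
    OneToOneChelator,
    SteppedBindingModel,
    independent_sites_model,
    solve_free_zinc,
)
from znbuffer.estimators import (
    average_persite_kd,
    fit_hill_buffer,
    fit_hill_ph,
    fit_weak_sites_znaf,
    refine_tight_moderate,
    stepwise_kd_from_transfer,
)
from znbuffer.probes import TransferObservation, free_zinc_from_par
from znbuffer.synthetic import simulate_buffer_cd, simulate_par_transfer


def obs(t, x):
    return TransferObservation(
        transferred_eq=t, protein_total=1e-6, competitor_total=200e-6, n_sites=x
    )


class TestAveragePersiteKd:
    @pytest.mark.parametrize(
        "t, x, expected",
        [
            (0.98, 6, 11.47),  # BcrMT1B
            (1.27, 7, 11.29),  # XlMT
            (1.22, 7, 11.33),  # SpMTA
            (2.66, 9, 10.69),  # LlMT
            (0.93, 6, 11.52),  # Ec-1
            (1.02, 3, 11.03),  # MacMT3
            (0.08, 3, 13.40),  # PflQ2MT
        ],
    )
    def test_reference_transfer_values(self, par, t, x, expected):
        res = average_persite_kd(obs(t, x), par)
        assert res["-log_kd_av"] == pytest.approx(expected, abs=0.05)

    def test_half_transfer_returns_free_zinc(self, par):
        res = average_persite_kd(obs(3.0, 6), par)
        z = free_zinc_from_par(3.0e-6, 200e-6, par)
        assert 10 ** -res["-log_kd_av"] == pytest.approx(z, rel=1e-12)

    def test_boundary_transfer_flagged(self, par):
        res = average_persite_kd(obs(0.01, 6), par)
        assert "near-boundary" in res.flags

    def test_forward_simulation_round_trip(self, par):
        # identical independent weak sites: the estimator must return the
        # generating per-site constant from its own forward-simulated transfer
        model = independent_sites_model("ind", 4, 10.5)
        sim = simulate_par_transfer(model, 1e-6, 200e-6, par)
        res = average_persite_kd(sim, par)
        assert res["-log_kd_av"] == pytest.approx(10.5, abs=0.01)


class TestStepwiseKd:
    @pytest.mark.parametrize(
        "t, x, n, lo, hi",
        [
            (0.93, 6, 1, 9.65, 9.67),  # Ec-1
            (0.05, 4, 1, 13.33, 13.36),  # SmtA
        ],
    )
    def test_reference_single_step_values(self, par, t, x, n, lo, hi):
        res = stepwise_kd_from_transfer(obs(t, x), par, n)
        assert lo <= res["-log_kd1"] <= hi

    def test_single_step_closed_form(self, par):
        t = 0.37
        res = stepwise_kd_from_transfer(obs(t, 5), par, 1)
        z = free_zinc_from_par(t * 1e-6, 200e-6, par)
        assert 10 ** -res["-log_kd1"] == pytest.approx(z * t / (1 - t), rel=1e-12)

    def test_half_transfer_single_step_equals_free_zinc(self, par):
        res = stepwise_kd_from_transfer(obs(0.5, 6), par, 1)
        assert 10 ** -res["-log_kd1"] == pytest.approx(res.parameters["free_zn_M"], rel=1e-9)

    def test_multi_step_consistent_with_partition(self, par):
        res = stepwise_kd_from_transfer(obs(1.27, 7), par, 2)
        a = 10 ** -res["-log_kd12_av"] / res.parameters["free_zn_M"]
        assert (a + 2 * a * a) / (1 + a + a * a) == pytest.approx(1.27, abs=1e-9)

    def test_transfer_exceeding_steps_rejected(self, par):
        with pytest.raises(ValueError):
            stepwise_kd_from_transfer(obs(1.5, 6), par, 1)


def _weak_site_isotherm(pkds, pzn_grid):
    z = 10.0 ** (-np.asarray(pzn_grid))
    t = sum(10.0**-p / (10.0**-p + z) for p in pkds)
    return list(zip(pzn_grid, t))


class TestWeakSiteFits:
    def test_two_site_recovery(self):
        iso = _weak_site_isotherm([7.74, 9.37], np.arange(6.0, 11.5, 0.25))
        res = fit_weak_sites_znaf(iso, n_weak=2)
        assert res.parameters["pkd_site_1"] == pytest.approx(7.74, abs=0.05)
        assert res.parameters["pkd_site_2"] == pytest.approx(9.37, abs=0.05)

    def test_single_site_exact_residual(self):
        iso = _weak_site_isotherm([8.5], np.arange(6.5, 10.5, 0.25))
        res = fit_weak_sites_znaf(iso, n_weak=1)
        assert res.residual_norm < 1e-10
        assert res.parameters["pkd_site_1"] == pytest.approx(8.5, abs=1e-6)

    def test_cooperative_release_recovery(self):
        # three sites released together in one transition
        pzn = np.arange(5.0, 9.0, 0.2)
        z = 10.0**-pzn
        kd = 10.0**-6.75
        t = 3 * kd**3 / (kd**3 + z**3)
        res = fit_weak_sites_znaf(list(zip(pzn, t)), cooperative=3)
        assert res.parameters["pkd"] == pytest.approx(6.75, abs=0.05)

    def test_no_transition_flagged(self):
        flat = [(p, 0.001) for p in np.arange(6.0, 8.0, 0.25)]
        res = fit_weak_sites_znaf(flat, n_weak=1)
        assert not res.converged
        assert "no-transition" in res.flags


def _competition_curve(model, probe, probe_total, protein_total, ratios):
    curve = []
    for r in ratios:
        state = solve_free_zinc(
            EquilibriumSystem(
                zn_total=r * protein_total,
                protein=(model, protein_total),
                probe_1to1=(probe, probe_total),
            )
        )
        curve.append((r, state.pzn))
    return curve


class TestRefineTightModerate:
    def test_recovers_xlmt_constants(self, registry, znaf):
        truth = registry.proteins["XlMT"]
        curve = _competition_curve(truth, znaf, 3e-6, 0.5e-6, np.arange(0.5, 8.0, 0.75))
        # start the template away from the truth
        start = truth.with_steps([10.0, 10.0, 10.0, 10.0, 9.0, 9.0, 7.74])
        res = refine_tight_moderate(curve, start, znaf, 3e-6, 0.5e-6)
        assert res.converged and not res.flags
        assert res.parameters["pkd_tight"] == pytest.approx(11.2, abs=0.1)
        # the two moderate steps are represented by one shared constant
        assert res.parameters["pkd_moderate"] == pytest.approx(9.7, abs=0.35)

    def test_probe_removed_is_uninformative(self, registry, znaf):
        truth = registry.proteins["XlMT"]
        curve = _competition_curve(truth, znaf, 3e-6, 0.5e-6, np.arange(1.0, 7.0, 1.0))
        res = refine_tight_moderate(curve, truth, znaf, 0.0, 0.5e-6)
        assert not res.converged
        assert "no-competition" in res.flags

    def test_bacterial_tight_sites_flagged_out_of_range(self, registry, znaf):
        truth = registry.proteins["SmtA"]
        curve = _competition_curve(truth, znaf, 3e-6, 0.5e-6, np.arange(0.5, 5.5, 0.5))
        res = refine_tight_moderate(curve, truth, znaf, 3e-6, 0.5e-6)
        assert any(f.startswith("underestimated-range") for f in res.flags)


class TestHillPh:
    def test_exact_recovery_noiseless(self):
        ph = np.arange(2.5, 8.01, 0.25)
        a = 0.1 + (0.9 - 0.1) / (1 + 10 ** (2.0 * (4.73 - ph)))
        res = fit_hill_ph(list(zip(ph, a)))
        assert res.parameters["pka_prime"] == pytest.approx(4.73, abs=1e-6)
        assert res.parameters["n"] == pytest.approx(2.0, abs=1e-6)

    def test_midpoint_amplitude(self):
        ph = np.arange(2.0, 8.01, 0.5)
        a = 1 / (1 + 10 ** (1.0 * (5.0 - ph)))
        res = fit_hill_ph(list(zip(ph, a)))
        mid = res.parameters["y_lo"] + 0.5 * (
            res.parameters["y_hi"] - res.parameters["y_lo"]
        )
        a_at_pka = 1 / (1 + 10 ** (1.0 * (5.0 - res.parameters["pka_prime"])))
        assert a_at_pka == pytest.approx(mid, abs=1e-9)

    def test_no_transition_flagged(self):
        ph = np.arange(2.5, 8.01, 0.5)
        res = fit_hill_ph(list(zip(ph, np.full_like(ph, 0.4))))
        assert not res.converged


class TestHillBuffer:
    @staticmethod
    def _buffers(registry):
        fracs = (0.05, 0.1, 0.2, 0.35, 0.5, 0.65, 0.85)
        return [
            (registry.chelators[c], 0.5e-3, f)
            for c in ("HEDTA", "EDTA", "TPEN")
            for f in fracs
        ]

    def test_negligible_depletion_equals_plain_fit(self, registry):
        buffers = self._buffers(registry)
        model = SteppedBindingModel("tiny", (14.0, 14.0))
        frame = simulate_buffer_cd(model, buffers, protein_total=1e-9)
        points = list(zip(frame["pzn_initial"], frame["ellipticity"]))
        res = fit_hill_buffer(points, buffers, protein_total=1e-9, n_transfer=2)
        assert res.parameters["-log_kd_av"] == pytest.approx(14.0, abs=0.02)

    @pytest.mark.parametrize("truth", [14.68, 14.3])
    def test_recovery_with_depletion_correction(self, registry, truth):
        buffers = self._buffers(registry)
        model = SteppedBindingModel("truth", (truth, truth))
        frame = simulate_buffer_cd(model, buffers, protein_total=20e-6)
        points = list(zip(frame["pzn_initial"], frame["ellipticity"]))
        res = fit_hill_buffer(points, buffers, protein_total=20e-6, n_transfer=2)
        assert res.parameters["-log_kd_av"] == pytest.approx(truth, abs=0.05)

    def test_pool_exhaustion_rejected(self, registry):
        # a 1 uM ligand pool cannot supply 40 uM of protein sites
        chel = registry.chelators["EDTA"]
        buffers = [(chel, 1e-6, f) for f in (0.05, 0.1, 0.2, 0.4, 0.6, 0.8)]
        pzn = np.array(
            [-(math.log10(chel.kd) + math.log10(f / (1 - f))) for _, _, f in buffers]
        )
        theta = -30.0 * (pzn.max() - pzn) / (pzn.max() - pzn.min())
        with pytest.raises(ValueError, match="pool"):
            fit_hill_buffer(list(zip(pzn, theta)), buffers, protein_total=20e-6, n_transfer=2)
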