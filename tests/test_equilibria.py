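"""Stepwise binding models, species fractions and the mass-balance solver."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import grid_scan_free_zinc
from znbuffer.equilibria import (
    ConvergenceError,
    EquilibriumSystem,
    OneToOneChelator,
    SteppedBindingModel,
    buffering_window,
    cumulative_log_betas,
    independent_sites_model,
    mean_occupancy,
    peak_pzn,
    release_index_from_step,
    solve_free_zinc,
    speciation_vs_pzn,
    speciation_vs_ratio,
    species_fractions_at_free_zn,
    step_from_release_index,
)

EDTA = OneToOneChelator("EDTA", -math.log10(2.3e-14))


class TestSteppedBindingModel:
    def test_rejects_increasing_steps(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SteppedBindingModel("bad", (9.0, 11.0))

    def test_rejects_nonpositive_steps(self):
        with pytest.raises(ValueError):
            SteppedBindingModel("bad", (9.0, -1.0))

    @pytest.mark.parametrize(
        "steps, expected",
        [
            ((11.2,), [11.2]),
            ((11.2, 10.1), [11.2, 21.3]),
            ((11.2, 11.2, 11.2, 11.2, 10.1, 9.37, 7.74), None),  # last entry checked below
        ],
    )
    def test_cumulative_log_betas(self, steps, expected):
        got = cumulative_log_betas(SteppedBindingModel("m", steps))
        if expected is not None:
            assert got == pytest.approx(expected)
        else:
            assert got[-1] == pytest.approx(72.01)


class TestSpeciesFractions:
    def test_half_saturation_single_site(self):
        m = SteppedBindingModel("one", (9.0,))
        assert species_fractions_at_free_zn(m, 1e-9) == pytest.approx([0.5, 0.5])

    def test_apo_limit(self):
        m = SteppedBindingModel("m", (12.0, 10.0, 8.0))
        f = species_fractions_at_free_zn(m, 1e-19)
        assert f[0] == pytest.approx(1.0, abs=1e-6)

    def test_nonpositive_free_zn_rejected(self):
        m = SteppedBindingModel("one", (9.0,))
        with pytest.raises(ValueError):
            species_fractions_at_free_zn(m, 0.0)

    def test_xlmt_zn6_modal_at_pzn_8p5(self, registry):
        f = species_fractions_at_free_zn(registry.proteins["XlMT"], 10**-8.5)
        assert int(np.argmax(f)) == 6

    @given(
        st.lists(st.floats(5.0, 16.0), min_size=1, max_size=9),
        st.floats(-20.0, -1.0),
    )
    def test_normalization_property(self, pkds, log_z):
        m = SteppedBindingModel("h", tuple(sorted(pkds, reverse=True)))
        f = species_fractions_at_free_zn(m, 10.0**log_z)
        assert abs(f.sum() - 1.0) < 1e-9
        assert np.all((f >= 0) & (f <= 1))


class TestMeanOccupancy:
    def test_half_saturation(self):
        m = SteppedBindingModel("one", (9.0,))
        assert mean_occupancy(m, 1e-9) == pytest.approx(0.5)

    def test_saturation_limit(self):
        m = SteppedBindingModel("m", (10.0, 9.0))
        assert mean_occupancy(m, 1e-2) == pytest.approx(2.0, abs=1e-5)

    def test_xlmt_occupancy_near_six_at_pzn_8p5(self, registry):
        assert mean_occupancy(registry.proteins["XlMT"], 10**-8.5) == pytest.approx(6.0, abs=0.05)

    @given(st.floats(-16.0, -3.0), st.floats(0.05, 3.0))
    def test_strictly_increasing(self, log_z, dz):
        m = SteppedBindingModel("m", (12.0, 10.5, 8.0))
        assert mean_occupancy(m, 10.0 ** (log_z + dz)) > mean_occupancy(m, 10.0**log_z)

    def test_identical_independent_sites_reduce_to_langmuir(self):
        m = independent_sites_model("ind", 4, 9.0)
        for z in (1e-11, 1e-9, 3e-9, 1e-7):
            assert mean_occupancy(m, z) / 4 == pytest.approx(z / (z + 1e-9), rel=1e-12)


class TestSolveFreeZinc:
    def test_half_saturated_chelator_gives_kd(self):
        state = solve_free_zinc(
            EquilibriumSystem(zn_total=0.25e-3, chelators=((EDTA, 0.5e-3),))
        )
        assert state.free_zn == pytest.approx(2.3e-14, rel=1e-6)

    def test_85_percent_saturated_edta(self):
        state = solve_free_zinc(
            EquilibriumSystem(zn_total=0.425e-3, chelators=((EDTA, 0.5e-3),))
        )
        assert state.free_zn == pytest.approx(2.3e-14 * 0.425 / 0.075, rel=1e-6)

    def test_zero_total_zinc_sentinel(self, registry):
        state = solve_free_zinc(
            EquilibriumSystem(zn_total=0.0, protein=(registry.proteins["XlMT"], 1e-6))
        )
        assert state.all_apo and state.free_zn == 0.0
        assert state.species["XlMT:Zn0"] == pytest.approx(1e-6)

    def test_conservation(self, registry, znaf):
        model = registry.proteins["XlMT"]
        system = EquilibriumSystem(
            zn_total=2e-6, protein=(model, 0.5e-6), probe_1to1=(znaf, 3e-6)
        )
        state = solve_free_zinc(system)
        total = state.free_zn + state.species["ZnAF-2F:Zn"] + sum(
            i * state.species[f"XlMT:Zn{i}"] for i in range(model.n_sites + 1)
        )
        assert total == pytest.approx(2e-6, rel=1e-8)

    def test_matches_grid_scan_oracle_mixed_system(self, registry, znaf):
        system = EquilibriumSystem(
            zn_total=2e-6,
            protein=(registry.proteins["XlMT"], 0.5e-6),
            probe_1to1=(znaf, 3e-6),
        )
        state = solve_free_zinc(system)
        assert math.log10(state.free_zn) == pytest.approx(
            grid_scan_free_zinc(system), abs=1e-6
        )

    def test_free_zinc_increases_with_total(self):
        m = SteppedBindingModel("m", (12.0, 10.0))
        frees = [
            solve_free_zinc(
                EquilibriumSystem(zn_total=z, protein=(m, 1e-6))
            ).free_zn
            for z in (0.5e-6, 1.0e-6, 1.5e-6, 2.5e-6)
        ]
        assert np.all(np.diff(frees) > 0)

    @given(
        st.lists(st.floats(5.0, 16.0), min_size=1, max_size=6),
        st.floats(-7.0, -3.0),
        st.floats(-7.0, -3.0),
    )
    def test_oracle_equivalence_randomized(self, pkds, log_ptot, log_zn):
        model = SteppedBindingModel("h", tuple(sorted(pkds, reverse=True)))
        system = EquilibriumSystem(
            zn_total=10.0**log_zn, protein=(model, 10.0**log_ptot)
        )
        state = solve_free_zinc(system)
        assert math.log10(state.free_zn) == pytest.approx(
            grid_scan_free_zinc(system), abs=1e-6
        )


class TestSpeciationProfiles:
    def test_single_site_logistic_in_pzn(self):
        m = SteppedBindingModel("one", (9.0,))
        prof = speciation_vs_pzn(m, [8.0, 9.0, 10.0])
        assert prof.fractions[:, 1] == pytest.approx([10 / 11, 0.5, 1 / 11], abs=1e-3)

    def test_rows_sum_to_one(self, registry):
        prof = speciation_vs_pzn(registry.proteins["LlMT"], np.arange(4, 18, 0.25))
        assert np.allclose(prof.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            speciation_vs_pzn(SteppedBindingModel("one", (9.0,)), [])

    def test_smta_zn3_fraction_peaks_near_12(self, registry):
        grid = np.arange(8.0, 17.0, 0.01)
        prof = speciation_vs_pzn(registry.proteins["SmtA"], grid)
        assert grid[np.argmax(prof.fractions[:, 3])] == pytest.approx(12.05, abs=0.1)

    def test_ratio_zero_is_all_apo(self, registry):
        prof = speciation_vs_ratio(registry.proteins["MacMT3"], 1e-6, [0.0, 1.0])
        assert prof.fractions[0, 0] == pytest.approx(1.0)

    def test_excess_zinc_saturates_single_site(self):
        m = SteppedBindingModel("one", (12.0,))
        prof = speciation_vs_ratio(m, 1e-6, [2.0])
        assert prof.fractions[0, 1] == pytest.approx(1.0, abs=1e-4)
        assert prof.free_zn[0] == pytest.approx(1e-6, rel=1e-3)

    def test_xlmt_zn4_modal_at_ratio_4(self, registry):
        prof = speciation_vs_ratio(registry.proteins["XlMT"], 1e-6, [4.0])
        assert int(np.argmax(prof.fractions[0])) == 4

    def test_tidy_export_round_trips(self, registry, tmp_path):
        import pandas as pd

        prof = speciation_vs_pzn(registry.proteins["SmtA"], np.arange(9.0, 16.0, 0.5))
        path = tmp_path / "prof.csv"
        prof.to_frame().to_csv(path, index=False)
        back = pd.read_csv(path)
        assert set(back.columns) == {"pzn", "species", "fraction", "free_zn_M"}
        pivot = back.pivot(index="pzn", columns="species", values="fraction")
        assert np.allclose(pivot.to_numpy(), prof.fractions, atol=1e-12)


class TestPeakPzn:
    def test_separated_steps_midpoint(self):
        m = SteppedBindingModel("sep", (12.0, 8.0))
        assert peak_pzn(m, 1) == pytest.approx(10.0, abs=1e-6)

    def test_terminal_species_sentinels(self):
        m = SteppedBindingModel("m", (12.0, 8.0))
        assert peak_pzn(m, 0) == math.inf
        assert peak_pzn(m, 2) == -math.inf

    def test_out_of_range_index(self):
        with pytest.raises(ValueError):
            peak_pzn(SteppedBindingModel("one", (9.0,)), 5)

    def test_xlmt_zn6_peak(self, registry):
        assert peak_pzn(registry.proteins["XlMT"], 6) == pytest.approx(8.5, abs=0.1)

    def test_smta_zn3_peak(self, registry):
        assert peak_pzn(registry.proteins["SmtA"], 3) == pytest.approx(12.1, abs=0.1)

    @given(st.floats(8.0, 13.0), st.floats(3.0, 6.0))
    def test_converges_to_midpoint_when_steps_far_apart(self, pk_hi, gap):
        m = SteppedBindingModel("sep", (pk_hi, pk_hi - gap))
        assert peak_pzn(m, 1) == pytest.approx(pk_hi - gap / 2, abs=0.01)


class TestBufferingWindow:
    def test_single_site_logistic_width(self):
        m = SteppedBindingModel("one", (9.0,))
        low, high = buffering_window(m, coverage=0.9)
        assert low == pytest.approx(9 - math.log10(9), abs=1e-6)
        assert high == pytest.approx(9 + math.log10(9), abs=1e-6)

    def test_endpoints_monotone_in_coverage(self, registry):
        m = registry.proteins["SmtA"]
        l1, h1 = buffering_window(m, 0.8)
        l2, h2 = buffering_window(m, 0.95)
        assert l2 < l1 and h2 > h1

    def test_smta_window_within_buffering_range(self, registry):
        low, high = buffering_window(registry.proteins["SmtA"], 0.95)
        assert 9.0 <= low < high <= 15.5


class TestReleaseIndexMapping:
    @pytest.mark.parametrize("n, release, step", [(4, 1, 4), (7, 3, 5), (1, 1, 1)])
    def test_bijection(self, n, release, step):
        m = SteppedBindingModel("m", tuple(range(n + 4, 4, -1)))
        assert step_from_release_index(m, release) == step
        assert release_index_from_step(m, step) == release
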