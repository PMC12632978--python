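import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

import novoscreen as nv
from novoscreen.synthetic_screen import CONTROL_LABEL, MechanismTruth


class TestTernarySignal:
    def test_zero_dose_gives_zero(self):
        assert nv.ternary_signal(0.0, 10, 10, 1000, 1000) == 0.0

    @pytest.mark.parametrize("dose", [0.1, 10.0, 250.0, 5000.0])
    def test_zero_density_silences_all_doses(self, dose):
        assert nv.ternary_signal(dose, 10, 10, 1000, 0.0) == 0.0
        assert nv.ternary_signal(dose, 10, 10, 0.0, 1000) == 0.0

    def test_peak_at_geometric_mean_of_affinities(self):
        # dT/d(dose) = 0 at dose = sqrt(kd1*kd2); grid argmax must agree
        kd1, kd2 = 10.0, 10.0
        doses = np.geomspace(1e-3, 1e5, 4001)
        s = nv.ternary_signal(doses, kd1, kd2, 1000, 1000)
        peak = doses[np.argmax(s)]
        assert peak == pytest.approx(np.sqrt(kd1 * kd2), rel=0.01)
        beyond = s[doses >= peak]
        assert np.all(np.diff(beyond) <= 1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(
        kd1=st.floats(1, 200), kd2=st.floats(1, 200),
        r1=st.floats(10, 5000), r2=st.floats(10, 5000),
    )
    def test_single_peaked_and_symmetric(self, kd1, kd2, r1, r2):
        doses = np.geomspace(1e-3, 1e5, 600)
        s = nv.ternary_signal(doses, kd1, kd2, r1, r2)
        swapped = nv.ternary_signal(doses, kd2, kd1, r2, r1)
        assert np.allclose(s, swapped)
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(s)))) > 0)
        assert sign_changes <= 2  # rises once, falls once

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            nv.ternary_signal(-1.0, 10, 10, 100, 100)
        with pytest.raises(ValueError):
            nv.ternary_signal(1.0, -10, 10, 100, 100)


class TestClusteringSignal:
    def test_zero_dose_gives_zero(self):
        assert nv.clustering_signal(0.0, 50, 1000) == 0.0

    def test_no_plateau_doubling_top_dose_increases(self):
        doses = np.geomspace(0.1, 1e4, 50)
        s = nv.clustering_signal(doses, 50, 1000, slope=2.0)
        assert np.all(np.diff(s) > 0)
        assert nv.clustering_signal(2e4, 50, 1000, slope=2.0) > s[-1]

    def test_single_receptor_mechanism(self):
        # only the aggregated receptor's density matters
        assert nv.clustering_signal(100, 50, 800) == nv.clustering_signal(100, 50, 800)
        assert nv.clustering_signal(100, 50, 0.0) == 0.0


class TestStatProfile:
    def test_private_receptor_dominates(self, constructs_by_id, registry):
        prof = nv.stat_profile(constructs_by_id["b_IL4Ra__2xGGS__b_IFNAR1"], registry, 0.0)
        assert prof["pSTAT6"] == max(prof.values()) == 1.0

    def test_leak_adds_pstat5_to_flexible_constructs(self, constructs_by_id, registry):
        prof = nv.stat_profile(constructs_by_id["b_IL21Ra__2xGGS__b_IFNAR1"], registry, 0.3)
        assert prof["pSTAT3"] == 1.0
        assert prof["pSTAT5"] >= 0.3

    def test_zero_vector_pair_stays_zero_even_with_leak(self, constructs_by_id, registry):
        prof = nv.stat_profile(constructs_by_id["b_OX40__2xGGS__b_TNFR1"], registry, 0.3)
        assert set(prof.values()) == {0.0}

    def test_common_common_pair_signals_via_fallback(self, constructs_by_id, registry):
        prof = nv.stat_profile(constructs_by_id["b_betac__2xGGS__b_gammac"], registry, 0.0)
        assert prof["pSTAT5"] == 1.0


class TestKnockout:
    def test_sets_density_to_zero_and_silences_signal(self, pbmc):
        cell = pbmc[0]
        ko = nv.apply_knockout(cell, "gammac")
        assert ko.receptor_density["gammac"] == 0.0
        assert nv.ternary_signal(250, 10, 10, ko.receptor_density["gammac"], 1000) == 0.0

    def test_idempotent(self, pbmc):
        once = nv.apply_knockout(pbmc[0], "IL7Ra")
        twice = nv.apply_knockout(once, "IL7Ra")
        assert once.receptor_density == twice.receptor_density

    def test_unknown_receptor_rejected(self, pbmc):
        with pytest.raises(ValueError, match="not in density map"):
            nv.apply_knockout(pbmc[0], "nonexistent")


@pytest.fixture(scope="module")
def tiny_truth(library, registry):
    sel = library[:20]
    return sel, {
        c.construct_id: MechanismTruth("inactive", 0.0) for c in sel
    }


class TestGenerateScreen:
    def test_same_seed_identical_tables(self, tiny_truth, pbmc, donors):
        sel, truth = tiny_truth
        plan = nv.ScreenPlan(seed=11)
        t1 = nv.generate_screen(sel, truth, pbmc[:2], donors, plan)
        t2 = nv.generate_screen(sel, truth, pbmc[:2], donors, plan)
        assert t1.equals(t2)

    def test_different_seeds_differ(self, tiny_truth, pbmc, donors):
        sel, truth = tiny_truth
        t1 = nv.generate_screen(sel, truth, pbmc[:1], donors, nv.ScreenPlan(seed=1))
        t2 = nv.generate_screen(sel, truth, pbmc[:1], donors, nv.ScreenPlan(seed=2))
        assert not t1["mfi"].equals(t2["mfi"])

    def test_missing_truth_rejected(self, library, pbmc, donors):
        with pytest.raises(ValueError, match="ground truth missing"):
            nv.generate_screen(library[:3], {}, pbmc[:1], donors, nv.ScreenPlan())

    def test_controls_have_zero_dose_and_three_replicates(self, tiny_truth, pbmc, donors):
        sel, truth = tiny_truth
        tbl = nv.generate_screen(sel, truth, pbmc[:1], donors, nv.ScreenPlan(seed=4))
        ctrl = tbl[tbl["condition"] == "unstimulated_control"]
        assert (ctrl["dose_nM"] == 0).all()
        assert (ctrl["construct_id"] == CONTROL_LABEL).all()
        reps = ctrl.groupby(["donor_id", "cell_type", "pathway"])["replicate"].count()
        assert (reps == 3).all()
        assert (tbl["mfi"] > 0).all()

    def test_all_inactive_screen_indistinguishable_from_controls(self, library, donors, pbmc):
        # Monte-Carlo: with no planted signal, stimulated MFI and unstimulated
        # control MFI come from the same distribution (two-sample KS, n = 500)
        sel = library[:500]
        truth = {c.construct_id: MechanismTruth("inactive", 0.0) for c in sel}
        plan = nv.ScreenPlan(seed=3, n_control_reps=500, include_single_binder_controls=False)
        tbl = nv.generate_screen(sel, truth, pbmc[:1], donors[:1], plan)
        sub = tbl[tbl["pathway"] == "pSTAT5"]
        stim = sub.loc[sub["condition"] == "stimulated", "mfi"]
        ctrl = sub.loc[sub["condition"] == "unstimulated_control", "mfi"]
        assert len(stim) == len(ctrl) == 500
        assert ks_2samp(stim, ctrl).pvalue > 0.01


class TestDoseSeriesGeneration:
    def test_requires_four_doses_including_zero(self, constructs_by_id, registry, pbmc):
        c = constructs_by_id["b_IL7Ra__2xGGS__b_gammac"]
        truth = {c.construct_id: MechanismTruth("inactive", 0.0)}
        with pytest.raises(ValueError):
            nv.generate_dose_series(c, truth, [0, 1, 10], pbmc[0])
        with pytest.raises(ValueError):
            nv.generate_dose_series(c, truth, [1, 10, 100, 1000], pbmc[0])

    def test_zero_dose_response_near_baseline_and_inactive_flat(
        self, constructs_by_id, registry, pbmc
    ):
        c = constructs_by_id["b_IL7Ra__2xGGS__b_gammac"]
        truth = {c.construct_id: MechanismTruth("inactive", 0.0)}
        series = nv.generate_dose_series(
            c, truth, [0, 1, 10, 100, 1000], pbmc[0], pathway="pSTAT5", seed=2
        )
        base = pbmc[0].baseline_mfi["pSTAT5"]
        assert all(abs(r / base - 1) < 0.5 for r in series.responses)
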