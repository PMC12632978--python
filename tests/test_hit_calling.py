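import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import novoscreen as nv
from novoscreen.hit_calling import ControlStats, control_stats_table


def _frame(values, condition="stimulated", donor="d1", cell="T", pathway="pSTAT5"):
    return pd.DataFrame(
        {
            "construct_id": [f"c{i}" for i in range(len(values))],
            "donor_id": donor,
            "cell_type": cell,
            "pathway": pathway,
            "dose_nM": 250.0,
            "replicate": 1,
            "condition": condition,
            "mfi": values,
        }
    )


class TestNormalize01:
    def test_min_max_rescaling(self):
        out = nv.normalize_01(_frame([100.0, 150.0, 200.0]))
        assert out["normalized_score"].tolist() == [0.0, 0.5, 1.0]

    def test_constant_stratum_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = nv.normalize_01(_frame([5.0, 5.0, 5.0]))
        assert out["normalized_score"].tolist() == [0.0, 0.0, 0.0]

    @settings(max_examples=25, derandomize=True)
    @given(
        a=st.floats(0.1, 100), b=st.floats(-50, 50),
        values=st.lists(st.floats(1, 1e4), min_size=3, max_size=8, unique=True),
    )
    def test_affine_invariance(self, a, b, values):
        raw = nv.normalize_01(_frame(values))["normalized_score"]
        scaled = nv.normalize_01(_frame([a * v + b for v in values]))["normalized_score"]
        assert np.allclose(raw, scaled, atol=1e-9)


class TestCallSignal:
    def test_boundary(self):
        stats = ControlStats(mean=0.1, sem=0.01, n=3)
        assert nv.call_signal(0.1 + 6.01 * 0.01, stats, k=6)
        assert not nv.call_signal(0.1 + 5.99 * 0.01, stats, k=6)
        assert not nv.call_signal(0.1, stats, k=6)

    def test_sem_undefined_below_two_controls(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ControlStats(mean=0.1, sem=0.01, n=1)

    def test_null_false_positive_rate_matches_t2_closed_form(self):
        # (x - mean)/(s*sqrt(1+1/n)) ~ t_{n-1}; at k=6, n=3 the threshold is
        # t = 6/sqrt(4) = 3, so the per-test FPR is P(t_2 > 3) ~ 0.0477
        exact = nv.null_false_positive_rate_exact(n_controls=3, k=6.0)
        assert exact == pytest.approx(0.04773, abs=2e-4)
        mc = nv.null_false_positive_rate(n_controls=3, k=6.0, n_sims=200_000, seed=0)
        assert mc == pytest.approx(exact, abs=0.003)

    @pytest.mark.parametrize("scale", [1.0, 17.3, 1e4])
    def test_statistic_is_scale_invariant(self, scale):
        rng = np.random.default_rng(5)
        controls = rng.normal(10, 2, size=(2000, 3))
        x = rng.normal(10, 2, size=2000)
        def rate(fac):
            sem = (controls * fac).std(axis=1, ddof=1) / np.sqrt(3)
            return np.mean(x * fac > (controls * fac).mean(axis=1) + 6 * sem)
        assert rate(scale) == rate(1.0)


class TestAdaptiveCutoff:
    def test_strong_positive_keeps_base_cutoff(self):
        assert nv.adaptive_cutoff([0.8, 0.9], control_mean=0.05) == 6.0

    def test_weak_positive_escalates(self):
        assert nv.adaptive_cutoff([0.1], control_mean=0.05, gamma=1.5) == 9.0

    def test_no_positive_controls_warns_and_keeps_base(self):
        with pytest.warns(UserWarning, match="no positive controls"):
            assert nv.adaptive_cutoff([], control_mean=0.0) == 6.0

    def test_monotone_in_effect(self):
        ks = [nv.adaptive_cutoff([e], control_mean=0.0) for e in np.linspace(1, 0, 21)]
        assert all(k2 >= k1 for k1, k2 in zip(ks, ks[1:]))


class TestReproducibility:
    @pytest.mark.parametrize(
        "calls,expected",
        [([True, True, False], True), ([True, False, False], False),
         ([False, False, False], False), ([True, True, True], True)],
    )
    def test_two_of_three_gate(self, calls, expected):
        assert nv.reproducibility(calls, min_donors=2) is expected


def _mini_screen():
    """3 donors x 1 cell x 1 pathway: controls near 100, one strong construct."""
    rng = np.random.default_rng(0)
    rows = []
    for donor in ["d1", "d2", "d3"]:
        for rep in range(1, 4):
            rows.append((nv.synthetic_screen.CONTROL_LABEL, donor, rep,
                         "unstimulated_control", rng.normal(100, 5)))
        rows.append(("hit", donor, 1, "stimulated", 400.0))
        rows.append(("dud", donor, 1, "stimulated", rng.normal(100, 5)))
        rows.append(("b_x", donor, 1, "single_binder_control", rng.normal(100, 5)))
    df = pd.DataFrame(rows, columns=["construct_id", "donor_id", "replicate", "condition", "mfi"])
    df["cell_type"], df["pathway"], df["dose_nM"] = "T", "pSTAT5", 250.0
    return df


class TestCallHits:
    def test_hit_and_dud_resolved(self):
        hits = nv.call_hits(_mini_screen())
        row = hits.set_index(["construct_id", "condition"])
        hit = row.loc[("hit", "stimulated")]
        assert hit["reproducible"] and hit["n_donors_positive"] == 3
        assert hit["donor_calls"] == "T;T;T"
        assert not row.loc[("dud", "stimulated")]["reproducible"]

    def test_missing_controls_rejected(self):
        df = _mini_screen()
        df = df[df["condition"] != "unstimulated_control"]
        with pytest.raises(ValueError):
            nv.call_hits(df)


class TestActivationRates:
    def _manifest(self):
        return pd.DataFrame(
            {"construct_id": ["hit", "dud"], "receptor_a": ["gammac", "gp130"],
             "receptor_b": ["IL7Ra", "gp130"]}
        )

    def test_all_and_none(self):
        hits = nv.call_hits(_mini_screen())
        rates = nv.activation_rate_by_receptor(hits, self._manifest(), min_combos=1)
        assert rates == {"gammac": 1.0, "IL7Ra": 1.0, "gp130": 0.0}

    def test_single_binder_rows_never_counted(self):
        hits = nv.call_hits(_mini_screen())
        rates = nv.activation_rate_by_receptor(hits, self._manifest(), min_combos=1)
        assert "b_x" not in rates  # not a manifest construct
        assert set(rates) == {"gammac", "IL7Ra", "gp130"}

    def test_receptor_without_constructs_absent(self):
        hits = nv.call_hits(_mini_screen())
        rates = nv.activation_rate_by_receptor(hits, self._manifest(), min_combos=1)
        assert "betac" not in rates


def test_planted_activation_rate_recovered_within_five_points(registry, library, pbmc):
    """Plant 42% of the shared gamma-chain constructs as dual-receptor actives;
    the recovered per-receptor activation rate lands within ±5 points."""
    from novoscreen.library_builder import to_manifest
    from novoscreen.synthetic_screen import DEFAULT_KD_NM, MechanismTruth

    gc = [c for c in library if "gammac" in c.receptor_pair]
    eligible = [
        c for c in gc
        if any(
            ct.receptor_density.get(c.receptor_pair[0], 0) >= 300
            and ct.receptor_density.get(c.receptor_pair[1], 0) >= 300
            for ct in pbmc
        )
    ]
    n_active = round(0.42 * len(gc))
    rng = np.random.default_rng(42)
    active = set(rng.choice([c.construct_id for c in eligible], size=n_active, replace=False))
    truth = {}
    for c in library:
        if c.construct_id in active:
            truth[c.construct_id] = MechanismTruth(
                "ternary", float(rng.uniform(3, 6)), nv.stat_profile(c, registry, 0.15),
                registry.binders[c.n_term_binder].kd_nM or DEFAULT_KD_NM,
                registry.binders[c.c_term_binder].kd_nM or DEFAULT_KD_NM,
            )
        else:
            truth[c.construct_id] = MechanismTruth("inactive", 0.0)
    donors = nv.make_donors(3, registry.receptors, seed=1)
    plan = nv.ScreenPlan(seed=1, positive_controls=nv.natural_positive_controls(registry))
    screen = nv.generate_screen(library, truth, pbmc, donors, plan)
    rates = nv.activation_rate_by_receptor(nv.call_hits(screen), to_manifest(library))
    assert rates["gammac"] == pytest.approx(n_active / len(gc), abs=0.05)
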