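"""Signaling-call statistic and donor-reproducibility gating.

Raw per-well MFI values are first rescaled 0-1 within each donor × cell type
× pSTAT stratum (min-max over every condition in the stratum, controls
included, so controls land near zero). A condition in a stratum is *called
signaling* when its normalized score exceeds the unstimulated-control mean by
at least ``k`` standard errors (default ``k = 6`` with three control
replicates). A construct × pathway × cell-type combination is a
*reproducible hit* when it is called in at least ``min_donors`` of the
donors (default 2 of 3).

Under a Gaussian null with ``n`` controls the 6×SEM rule has a closed-form
per-test false-positive rate: the statistic ``(x - x̄)/(s·√(1 + 1/n))``
follows a Student t with ``n - 1`` degrees of freedom, so the threshold
``k·SEM`` corresponds to ``t = k/√(n+1)`` — for n = 3, k = 6 that is
``P(t₂ > 3) ≈ 0.0477``. The statistic is location/scale invariant, so the
0-1 normalization does not alter it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

STRATUM = ["donor_id", "cell_type", "pathway"]
UNIT = ["construct_id", "cell_type", "pathway", "condition"]
SEM_FLOOR = 1e-6  # fraction of the (unit) normalized stratum range


@dataclass(frozen=True)
class ControlStats:
    """Unstimulated-control summary for one donor × cell type × pathway stratum."""

    mean: float
    sem: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("control SEM is undefined with fewer than 2 replicates")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


def normalize_01(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized_score`` column: per-stratum min-max rescaling to [0,1].

    Constant strata (max == min) map to all-zero scores with a warning.
    """
    out = table.copy()
    grouped = out.groupby(STRATUM)["mfi"]
    lo = grouped.transform("min")
    hi = grouped.transform("max")
    span = hi - lo
    degenerate = span <= 0
    if degenerate.any():
        n_strata = out.loc[degenerate, STRATUM].drop_duplicates().shape[0]
        warnings.warn(
            f"{n_strata} stratum/strata with constant MFI normalized to all zeros",
            stacklevel=2,
        )
    out["normalized_score"] = np.where(degenerate, 0.0, (out["mfi"] - lo) / span.where(span > 0))
    return out


def control_stats_table(normalized: pd.DataFrame, sem_floor: float = SEM_FLOOR) -> pd.DataFrame:
    """Per-stratum mean/SEM/n of the unstimulated controls (normalized scale).

    SEM uses the n-1 sample standard deviation and is floored at ``sem_floor``
    (a fraction of the unit normalized range) to avoid degenerate all-hit
    strata when controls happen to coincide.
    """
    ctrl = normalized[normalized["condition"] == "unstimulated_control"]
    if ctrl.empty:
        raise ValueError("no unstimulated_control rows in table")
    agg = ctrl.groupby(STRATUM)["normalized_score"].agg(["mean", "std", "count"]).reset_index()
    if (agg["count"] < 2).any():
        raise ValueError("every stratum needs at least 2 unstimulated controls")
    agg["sem"] = np.maximum(agg["std"] / np.sqrt(agg["count"]), sem_floor)
    return agg.rename(columns={"count": "n"})[STRATUM + ["mean", "sem", "n"]]


def call_signal(score, control_stats: ControlStats, k: float = 6.0):
    """True iff ``score > mean + k·sem`` of the stratum's unstimulated controls."""
    result = np.asarray(score) > control_stats.mean + k * control_stats.sem
    return result if result.ndim else bool(result)


def adaptive_cutoff(
    positive_control_scores,
    control_mean: float = 0.0,
    k_base: float = 6.0,
    theta: float = 0.2,
    gamma: float = 1.5,
) -> float:
    """Escalate the SEM multiplier for strata with weak positive-control responses.

    When the natural-cytokine positive controls barely respond (normalized
    effect below ``theta``), noise would be misread as signal at the base
    cutoff, so ``k`` is raised to ``k_base·gamma``. Returns ``k_base`` (with a
    warning) when no positive controls are available.
    """
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    scores = np.asarray(positive_control_scores, dtype=float)
    if scores.size == 0:
        warnings.warn("no positive controls for stratum; using base cutoff", stacklevel=2)
        return k_base
    effect = float(scores.max() - control_mean)
    return k_base if effect >= theta else k_base * gamma


def reproducibility(calls, min_donors: int = 2) -> bool:
    """True iff the per-donor boolean calls are positive in >= ``min_donors`` donors."""
    return int(np.sum(np.asarray(calls, dtype=bool))) >= min_donors


def call_hits(
    table: pd.DataFrame,
    k: float = 6.0,
    min_donors: int = 2,
    sem_floor: float = SEM_FLOOR,
    theta: float = 0.2,
    gamma: float = 1.5,
) -> pd.DataFrame:
    """Full hit-calling pass over a long-format screen table.

    Returns one row per construct × cell type × pathway × condition with the
    per-donor calls (sorted donor order), the number of positive donors, the
    reproducibility verdict, and the mean normalized score across donors.
    Unstimulated controls define the null and are not themselves called.

    When the table carries natural-cytokine ``positive_control`` rows, the
    SEM multiplier is escalated per stratum via :func:`adaptive_cutoff`
    (``k·gamma`` wherever the strongest positive control's normalized effect
    falls below ``theta``), so noise in weakly-responding strata is not
    misread as signal.
    """
    normalized = normalize_01(table)
    ctrl = control_stats_table(normalized, sem_floor=sem_floor)
    tests = normalized[normalized["condition"] != "unstimulated_control"].merge(
        ctrl, on=STRATUM, how="left", validate="many_to_one"
    )
    if tests[["mean", "sem"]].isna().any().any():
        raise ValueError("some strata have test rows but no unstimulated controls")
    pos = normalized[normalized["condition"] == "positive_control"]
    if not pos.empty:
        best_pos = pos.groupby(STRATUM)["normalized_score"].max().rename("best_positive")
        tests = tests.merge(best_pos, on=STRATUM, how="left")
        weak = (tests["best_positive"].fillna(-np.inf) - tests["mean"]) < theta
        tests["k_used"] = np.where(weak, k * gamma, k)
    else:
        tests["k_used"] = k
    tests["called"] = tests["normalized_score"] > tests["mean"] + tests["k_used"] * tests["sem"]
    tests = tests.sort_values(UNIT + ["donor_id"], kind="mergesort")
    hits = (
        tests.groupby(UNIT, sort=True)
        .agg(
            donor_calls=("called", lambda s: ";".join("T" if v else "F" for v in s)),
            n_donors_positive=("called", "sum"),
            n_donors=("called", "size"),
            mean_score=("normalized_score", "mean"),
        )
        .reset_index()
    )
    hits["reproducible"] = hits["n_donors_positive"] >= min_donors
    return hits


def hit_constructs(hit_table: pd.DataFrame, min_combos: int = 2) -> pd.Series:
    """Boolean per construct: reproducible in at least ``min_combos`` combinations.

    Each construct is tested in every pathway × cell-type combination (30 by
    default), so a single reproducible combination is within the procedure's
    own false-positive expectation; requiring two keeps construct-level calls
    specific. Only ``stimulated`` rows are considered.
    """
    stim = hit_table[hit_table["condition"] == "stimulated"]
    return stim.groupby("construct_id")["reproducible"].sum() >= min_combos


def activation_rate_by_receptor(
    hit_table: pd.DataFrame, manifest: pd.DataFrame, min_combos: int = 2
) -> dict[str, float]:
    """Fraction of each receptor's constructs that are reproducible hits.

    A construct counts as a hit when :func:`hit_constructs` says so.
    Single-binder control rows are excluded: only construct ids present in
    the manifest contribute. Receptors with zero constructs are absent from
    the map.
    """
    required = {"construct_id", "receptor_a", "receptor_b"}
    if not required <= set(manifest.columns):
        raise ValueError(f"manifest must carry columns {sorted(required)}")
    construct_hit = hit_constructs(hit_table, min_combos=min_combos)
    rates: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for rec in manifest.itertuples(index=False):
        hit = bool(construct_hit.get(rec.construct_id, False))
        for receptor in {rec.receptor_a, rec.receptor_b}:
            n_hit, n_all = counts.get(receptor, (0, 0))
            counts[receptor] = (n_hit + hit, n_all + 1)
    for receptor, (n_hit, n_all) in counts.items():
        rates[receptor] = n_hit / n_all
    return rates


def null_false_positive_rate(
    n_controls: int = 3,
    k: float = 6.0,
    n_sims: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo per-test false-positive rate of the k×SEM rule under a Gaussian null.

    Draws ``n_controls`` controls and one test value from the same normal
    distribution and applies the exact call rule. Converges to
    ``P(t_{n-1} > k/√(n+1))``.
    """
    rng = np.random.default_rng(seed)
    controls = rng.standard_normal((n_sims, n_controls))
    x = rng.standard_normal(n_sims)
    sem = controls.std(axis=1, ddof=1) / np.sqrt(n_controls)
    return float(np.mean(x > controls.mean(axis=1) + k * sem))


def null_false_positive_rate_exact(n_controls: int = 3, k: float = 6.0) -> float:
    """Closed form of the rule's per-test false-positive rate under a Gaussian null."""
    return float(sps.t.sf(k / np.sqrt(n_controls + 1), df=n_controls - 1))
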