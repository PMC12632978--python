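"""Synthetic multi-donor phospho-flow screen generator with planted ground truth.

The generator emulates the statistical structure of a pooled agonist screen
read out by phospho-flow: per construct × donor × cell type × pSTAT pathway
fluorescence intensities, three unstimulated control replicates per stratum,
single-binder controls, donor-to-donor receptor-density variability, and
well-level multiplicative lognormal noise.

Mechanisms
----------
Signal-generating constructs follow one of two planted mechanisms:

* ``ternary`` — dual-receptor bridging. The bridged-complex abundance is
  approximated by ``T = α · (r1/ρ)(r2/ρ) · d / ((kd1+d)(kd2+d))`` where
  ``d`` is dose (nM), ``kd`` the binder affinities, ``r`` surface receptor
  densities and ``ρ`` a reference density. ``T`` is single-peaked in dose
  with its maximum at ``√(kd1·kd2)`` (the high-dose "hook": excess ligand
  occupies the two receptors on separate molecules). The observed signal is
  a saturating transform ``emax · T/(T + K_half)``, zero whenever either
  receptor is absent.
* ``clustering`` — self-association of one binding domain aggregates a single
  receptor; modelled as ``slope · (r/ρ) · occupancy(d; kd) · log1p(d/kd)``,
  which keeps growing with dose (non-saturating) and involves one receptor
  only.

``inactive`` constructs and single-binder controls contribute zero signal.
The pSTAT distribution of a construct's signal comes from
:func:`stat_profile`: the canonical pathway weights of the pair's private
receptor(s) (falling back to both receptors for common/common or
cross-family pairs), max-normalized, plus an optional pSTAT5 leak for
flexible fusions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .dose_response import DoseSeries
from .library_builder import FusionConstruct
from .registry import PATHWAYS, Registry

DENSITY_REF = 1000.0  # reference surface density (copies/cell)
K_HALF = 1e-4  # half-saturation of the bridging->signal transform (dimensionless)
DEFAULT_KD_NM = 50.0  # stand-in affinity for binders without a printed KD

CONTROL_LABEL = "UNSTIM_CTRL"
SCREEN_COLUMNS = [
    "construct_id",
    "donor_id",
    "cell_type",
    "pathway",
    "dose_nM",
    "replicate",
    "condition",
    "mfi",
]


@dataclass(frozen=True)
class CellType:
    """A cell population: receptor surface densities and per-pathway baselines."""

    name: str
    receptor_density: dict[str, float]
    baseline_mfi: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.receptor_density.values()):
            raise ValueError(f"{self.name}: receptor densities must be >= 0")
        if any(v <= 0 for v in self.baseline_mfi.values()):
            raise ValueError(f"{self.name}: baseline MFI must be positive")


@dataclass(frozen=True)
class DonorProfile:
    donor_id: str
    density_multiplier: dict[str, float]
    noise_cv: float = 0.15

    def __post_init__(self):
        if any(m <= 0 for m in self.density_multiplier.values()):
            raise ValueError("donor density multipliers must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")


@dataclass(frozen=True)
class MechanismTruth:
    """Planted ground truth for one construct."""

    mechanism: str  # ternary | clustering | inactive
    efficacy: float  # fold-over-baseline signal on the dominant pathway
    stat_profile: dict[str, float] = field(default_factory=dict)
    kd1_nM: float = DEFAULT_KD_NM
    kd2_nM: float = DEFAULT_KD_NM
    cluster_receptor: str | None = None  # receptor aggregated under "clustering"

    def __post_init__(self):
        if self.mechanism not in {"ternary", "clustering", "inactive"}:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "inactive" and self.efficacy != 0:
            raise ValueError("inactive constructs must have efficacy 0")
        if self.efficacy < 0:
            raise ValueError("efficacy must be >= 0")
        if any(not 0 <= w <= 1 for w in self.stat_profile.values()):
            raise ValueError("stat_profile weights must lie in [0,1]")


@dataclass(frozen=True)
class PositiveControl:
    """A natural-cytokine stimulation condition used to gauge stratum sensitivity."""

    label: str
    receptor_a: str
    receptor_b: str
    stat_profile: dict[str, float]
    kd1_nM: float = 1.0
    kd2_nM: float = 1.0
    efficacy: float = 4.0


@dataclass(frozen=True)
class ScreenPlan:
    """Single-point screen conditions (defaults mirror a 250 nM, 15-min stimulation)."""

    dose_nM: float = 250.0
    n_control_reps: int = 3
    seed: int = 0
    avidity_alpha: float = 1.0
    k_half: float = K_HALF
    include_single_binder_controls: bool = True
    positive_controls: tuple[PositiveControl, ...] = ()


def _validate_nonnegative(**kwargs) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) < 0):
            raise ValueError(f"{name} must be non-negative")


def ternary_signal(
    dose_nM,
    kd1_nM,
    kd2_nM,
    r1_density,
    r2_density,
    avidity_alpha: float = 1.0,
    emax: float = 1.0,
    k_half: float = K_HALF,
    density_ref: float = DENSITY_REF,
):
    """Saturating dual-receptor bridging signal (vectorized over any argument).

    Returns ``emax * T/(T + k_half)`` with the bridging term
    ``T = α (r1/ρ)(r2/ρ) d / ((kd1+d)(kd2+d))``. Zero at zero dose and
    whenever either receptor density is zero; symmetric under swapping
    (kd1, r1) with (kd2, r2); single-peaked in dose with the maximum at
    ``√(kd1 kd2)``.
    """
    _validate_nonnegative(
        dose_nM=dose_nM, r1_density=r1_density, r2_density=r2_density,
        avidity_alpha=avidity_alpha, emax=emax,
    )
    if np.any(np.asarray(kd1_nM) <= 0) or np.any(np.asarray(kd2_nM) <= 0):
        raise ValueError("kd values must be positive")
    d = np.asarray(dose_nM, dtype=float)
    t = (
        avidity_alpha
        * (np.asarray(r1_density, dtype=float) / density_ref)
        * (np.asarray(r2_density, dtype=float) / density_ref)
        * d
        / ((kd1_nM + d) * (kd2_nM + d))
    )
    out = emax * t / (t + k_half)
    return out if out.ndim else float(out)


def clustering_signal(
    dose_nM,
    kd_nM,
    density,
    slope: float = 1.0,
    density_ref: float = DENSITY_REF,
):
    """Non-saturating single-receptor aggregation signal.

    ``slope · (r/ρ) · occupancy · log1p(d/kd)``: strictly increasing in dose
    on any bounded range, independent of the partner receptor.
    """
    _validate_nonnegative(dose_nM=dose_nM, density=density, slope=slope)
    if np.any(np.asarray(kd_nM) <= 0):
        raise ValueError("kd must be positive")
    d = np.asarray(dose_nM, dtype=float)
    occ = d / (d + kd_nM)
    out = slope * (np.asarray(density, dtype=float) / density_ref) * occ * np.log1p(d / kd_nM)
    return out if out.ndim else float(out)


def stat_profile(
    construct: FusionConstruct, registry: Registry, leak_lambda: float = 0.0
) -> dict[str, float]:
    """pSTAT weight vector of a construct, max-normalized to the dominant pathway.

    Private receptor(s) dictate the signature; pairs without a private
    contribution (common/common and cross-family fusions) inherit the summed
    weights of both receptors. Flexible (non-rigid) constructs gain a pSTAT5
    leak ``leak_lambda``, reflecting the permissiveness of relaxed dimer
    geometry — applied only when the pair can signal at all.
    """
    if not 0 <= leak_lambda <= 1:
        raise ValueError("leak_lambda must lie in [0,1]")
    receptors = [registry.receptors[name] for name in construct.receptor_pair]
    if len(set(construct.receptor_pair)) == 1:
        receptors = receptors[:1]
    return pair_stat_profile(receptors, leak_lambda=0.0 if construct.linker.rigid else leak_lambda)


def pair_stat_profile(receptors, leak_lambda: float = 0.0) -> dict[str, float]:
    """Max-normalized pSTAT weights of a receptor pair (see :func:`stat_profile`)."""
    privates = [r for r in receptors if r.chain_class == "private"]
    contributors = privates if any(sum(r.canonical_stats.values()) > 0 for r in privates) else receptors
    summed = np.zeros(len(PATHWAYS))
    for rec in contributors:
        summed += np.asarray(rec.stats_vector())
    peak = summed.max()
    if peak == 0:
        return {pw: 0.0 for pw in PATHWAYS}
    weights = summed / peak
    if leak_lambda > 0:
        weights[PATHWAYS.index("pSTAT5")] += leak_lambda
    weights = np.clip(weights, 0.0, 1.0)
    return dict(zip(PATHWAYS, weights.tolist()))


def apply_knockout(cell_type: CellType, receptor: str) -> CellType:
    """The same cell population with one receptor's surface density set to zero."""
    if receptor not in cell_type.receptor_density:
        raise ValueError(f"receptor {receptor!r} not in density map of {cell_type.name}")
    densities = dict(cell_type.receptor_density)
    densities[receptor] = 0.0
    return replace(cell_type, receptor_density=densities)


def default_panel():
    """Packaged cell panel and generator defaults: (cell_types, donor_cfg, screen_cfg)."""
    ref = importlib.resources.files("novoscreen.data").joinpath("panel.yaml")
    cfg = yaml.safe_load(ref.read_text())
    cells = [
        CellType(
            name=name,
            receptor_density={str(k): float(v) for k, v in spec["receptor_density"].items()},
            baseline_mfi={str(k): float(v) for k, v in spec["baseline_mfi"].items()},
        )
        for name, spec in cfg["cell_types"].items()
    ]
    screen_cfg = dict(cfg["screen"])
    screen_cfg["natural_cytokines"] = {
        str(k): tuple(v) for k, v in cfg.get("natural_cytokines", {}).items()
    }
    return cells, dict(cfg["donors"]), screen_cfg


def natural_positive_controls(
    registry: Registry, natural_cytokines: dict[str, tuple[str, str]] | None = None
) -> tuple[PositiveControl, ...]:
    """Positive-control conditions from the packaged natural-cytokine panel.

    Natural cytokines are modelled as high-affinity (1 nM) rigid-geometry
    ternary agonists of their receptor pairs; their pSTAT profile follows the
    same private-receptor rule as designed constructs, without the leak.
    """
    if natural_cytokines is None:
        _, _, screen_cfg = default_panel()
        natural_cytokines = screen_cfg["natural_cytokines"]
    controls = []
    for label, (ra, rb) in sorted(natural_cytokines.items()):
        if ra not in registry.receptors or rb not in registry.receptors:
            continue  # sub-registries may lack some natural receptors
        receptors = [registry.receptors[name] for name in dict.fromkeys((ra, rb))]
        controls.append(
            PositiveControl(
                label=label,
                receptor_a=ra,
                receptor_b=rb,
                stat_profile=pair_stat_profile(receptors),
            )
        )
    return tuple(controls)


def pbmc_panel() -> list[CellType]:
    """The six packaged PBMC populations (cell-line contexts excluded)."""
    cells, _, _ = default_panel()
    return [c for c in cells if c.name != "U937_like"]


def make_donors(
    n: int,
    receptors,
    seed: int = 0,
    noise_cv: float = 0.15,
    density_sigma: float = 0.30,
) -> list[DonorProfile]:
    """Sample donor profiles: lognormal per-receptor density multipliers."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7001]))
    receptors = sorted(receptors)
    donors = []
    for i in range(n):
        mult = np.exp(rng.normal(0.0, density_sigma, size=len(receptors)))
        donors.append(
            DonorProfile(
                donor_id=f"donor{i + 1}",
                density_multiplier=dict(zip(receptors, mult.tolist())),
                noise_cv=noise_cv,
            )
        )
    return donors


DEFAULT_RECEPTOR_PROPENSITY = {
    "gammac": 0.42,
    "betac": 0.20,
    "gp130": 0.20,
    "IL7Ra": 0.20,
    "IL10Ra": 0.20,
    "IL21Ra": 0.20,
    "TrkA": 0.20,
    "IFNAR1": 0.20,
}


def plant_truth(
    constructs: list[FusionConstruct],
    registry: Registry,
    cell_types: list[CellType],
    seed: int = 0,
    receptor_propensity: dict[str, float] | None = None,
    base_propensity: float = 0.02,
    clustering_fraction: float = 0.2,
    efficacy_range: tuple[float, float] = (3.0, 6.0),
    min_coexpression_density: float = 300.0,
    stat5_leak: float = 0.15,
) -> dict[str, MechanismTruth]:
    """Assign a planted mechanism to every construct.

    A construct can be active only if its receptor pair is co-expressed at
    ``min_coexpression_density`` copies/cell in at least one panel cell type
    (a screen cannot report on receptors the assayed cells lack). Among
    eligible constructs, activity is Bernoulli with a per-receptor propensity
    (the maximum over the pair); shared subunits carry the highest
    propensities. Active constructs are mostly dual-receptor (``ternary``),
    with ``clustering_fraction`` of them driven by single-domain
    self-association instead. Efficacies are uniform over ``efficacy_range``.
    """
    if receptor_propensity is None:
        receptor_propensity = DEFAULT_RECEPTOR_PROPENSITY
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7002]))
    truth: dict[str, MechanismTruth] = {}
    for c in constructs:
        ra, rb = c.receptor_pair
        coexpressed = any(
            ct.receptor_density.get(ra, 0.0) >= min_coexpression_density
            and ct.receptor_density.get(rb, 0.0) >= min_coexpression_density
            for ct in cell_types
        )
        prop = max(
            receptor_propensity.get(ra, base_propensity),
            receptor_propensity.get(rb, base_propensity),
        )
        # single draw per construct keeps the truth stable under panel edits
        active = coexpressed and rng.random() < prop
        profile = stat_profile(c, registry, leak_lambda=stat5_leak)
        kd1 = registry.binders[c.n_term_binder].kd_nM or DEFAULT_KD_NM
        kd2 = registry.binders[c.c_term_binder].kd_nM or DEFAULT_KD_NM
        if not active or max(profile.values(), default=0.0) == 0.0:
            truth[c.construct_id] = MechanismTruth(mechanism="inactive", efficacy=0.0)
            continue
        efficacy = float(rng.uniform(*efficacy_range))
        if rng.random() < clustering_fraction:
            idx = int(rng.integers(2))
            truth[c.construct_id] = MechanismTruth(
                mechanism="clustering",
                efficacy=efficacy,
                stat_profile=profile,
                kd1_nM=kd1,
                kd2_nM=kd2,
                cluster_receptor=c.receptor_pair[idx],
            )
        else:
            truth[c.construct_id] = MechanismTruth(
                mechanism="ternary",
                efficacy=efficacy,
                stat_profile=profile,
                kd1_nM=kd1,
                kd2_nM=kd2,
            )
    return truth


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def _construct_signal(
    constructs: list[FusionConstruct],
    truth: dict[str, MechanismTruth],
    densities: dict[str, float],
    dose_nM: float,
    avidity_alpha: float,
    k_half: float,
) -> np.ndarray:
    """Mechanism signal of each construct in a given receptor-density context."""
    out = np.zeros(len(constructs))
    for i, c in enumerate(constructs):
        t = truth[c.construct_id]
        if t.mechanism == "ternary":
            out[i] = ternary_signal(
                dose_nM,
                t.kd1_nM,
                t.kd2_nM,
                densities.get(c.receptor_pair[0], 0.0),
                densities.get(c.receptor_pair[1], 0.0),
                avidity_alpha=avidity_alpha,
                emax=t.efficacy,
                k_half=k_half,
            )
        elif t.mechanism == "clustering":
            kd = t.kd1_nM if t.cluster_receptor == c.receptor_pair[0] else t.kd2_nM
            out[i] = clustering_signal(
                dose_nM,
                kd,
                densities.get(t.cluster_receptor, 0.0),
                slope=t.efficacy,
            )
    return out


def generate_screen(
    constructs: list[FusionConstruct],
    truth: dict[str, MechanismTruth],
    cell_types: list[CellType],
    donors: list[DonorProfile],
    plan: ScreenPlan | None = None,
) -> pd.DataFrame:
    """Simulate one single-dose screen; fully reproducible given ``plan.seed``.

    For every donor × cell type × pathway stratum the table holds
    ``plan.n_control_reps`` unstimulated controls at baseline, one stimulated
    record per construct with
    ``mfi = baseline · (1 + signal · stat_weight) · noise``, and (optionally)
    one zero-signal record per binder as a single-binder control.
    """
    plan = plan or ScreenPlan()
    missing = [c.construct_id for c in constructs if c.construct_id not in truth]
    if missing:
        raise ValueError(f"ground truth missing for constructs: {missing[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([plan.seed, 7003]))
    n_path = len(PATHWAYS)
    profile_matrix = np.array(
        [
            [truth[c.construct_id].stat_profile.get(pw, 0.0) for pw in PATHWAYS]
            for c in constructs
        ]
    )
    binder_ids = sorted(
        {c.n_term_binder for c in constructs} | {c.c_term_binder for c in constructs}
    )
    blocks = []
    for donor in donors:
        for cell in cell_types:
            densities = {
                r: d * donor.density_multiplier.get(r, 1.0)
                for r, d in cell.receptor_density.items()
            }
            baseline = np.array([cell.baseline_mfi[pw] for pw in PATHWAYS])
            # unstimulated controls
            ctrl = baseline[None, :] * _lognormal_factors(
                rng, donor.noise_cv, (plan.n_control_reps, n_path)
            )
            blocks.append(
                pd.DataFrame(
                    {
                        "construct_id": CONTROL_LABEL,
                        "donor_id": donor.donor_id,
                        "cell_type": cell.name,
                        "pathway": np.tile(PATHWAYS, plan.n_control_reps),
                        "dose_nM": 0.0,
                        "replicate": np.repeat(
                            np.arange(1, plan.n_control_reps + 1), n_path
                        ),
                        "condition": "unstimulated_control",
                        "mfi": ctrl.ravel(),
                    }
                )
            )
            # stimulated constructs
            if constructs:
                signal = _construct_signal(
                    constructs, truth, densities, plan.dose_nM, plan.avidity_alpha, plan.k_half
                )
                mfi = (
                    baseline[None, :]
                    * (1.0 + signal[:, None] * profile_matrix)
                    * _lognormal_factors(rng, donor.noise_cv, (len(constructs), n_path))
                )
                blocks.append(
                    pd.DataFrame(
                        {
                            "construct_id": np.repeat(
                                [c.construct_id for c in constructs], n_path
                            ),
                            "donor_id": donor.donor_id,
                            "cell_type": cell.name,
                            "pathway": np.tile(PATHWAYS, len(constructs)),
                            "dose_nM": plan.dose_nM,
                            "replicate": 1,
                            "condition": "stimulated",
                            "mfi": mfi.ravel(),
                        }
                    )
                )
            # natural-cytokine positive controls gauge stratum sensitivity
            if plan.positive_controls:
                pos_profiles = np.array(
                    [[pc.stat_profile.get(pw, 0.0) for pw in PATHWAYS] for pc in plan.positive_controls]
                )
                pos_signal = np.array(
                    [
                        ternary_signal(
                            plan.dose_nM,
                            pc.kd1_nM,
                            pc.kd2_nM,
                            densities.get(pc.receptor_a, 0.0),
                            densities.get(pc.receptor_b, 0.0),
                            avidity_alpha=plan.avidity_alpha,
                            emax=pc.efficacy,
                            k_half=plan.k_half,
                        )
                        for pc in plan.positive_controls
                    ]
                )
                pos_mfi = (
                    baseline[None, :]
                    * (1.0 + pos_signal[:, None] * pos_profiles)
                    * _lognormal_factors(rng, donor.noise_cv, (len(plan.positive_controls), n_path))
                )
                blocks.append(
                    pd.DataFrame(
                        {
                            "construct_id": np.repeat(
                                [f"NAT_{pc.label}" for pc in plan.positive_controls], n_path
                            ),
                            "donor_id": donor.donor_id,
                            "cell_type": cell.name,
                            "pathway": np.tile(PATHWAYS, len(plan.positive_controls)),
                            "dose_nM": plan.dose_nM,
                            "replicate": 1,
                            "condition": "positive_control",
                            "mfi": pos_mfi.ravel(),
                        }
                    )
                )
            # single-binder controls: dual engagement is required, so signal is 0
            if plan.include_single_binder_controls and binder_ids:
                sb = baseline[None, :] * _lognormal_factors(
                    rng, donor.noise_cv, (len(binder_ids), n_path)
                )
                blocks.append(
                    pd.DataFrame(
                        {
                            "construct_id": np.repeat(binder_ids, n_path),
                            "donor_id": donor.donor_id,
                            "cell_type": cell.name,
                            "pathway": np.tile(PATHWAYS, len(binder_ids)),
                            "dose_nM": plan.dose_nM,
                            "replicate": 1,
                            "condition": "single_binder_control",
                            "mfi": sb.ravel(),
                        }
                    )
                )
    table = pd.concat(blocks, ignore_index=True)[SCREEN_COLUMNS]
    return table


def generate_knockout_screen(
    construct: FusionConstruct,
    truth: dict[str, MechanismTruth],
    cell_type: CellType,
    receptor: str,
    donors: list[DonorProfile],
    plan: ScreenPlan | None = None,
) -> pd.DataFrame:
    """Screen table for one construct in a single-receptor-knockout background."""
    ko_cell = apply_knockout(cell_type, receptor)
    table = generate_screen([construct], truth, [ko_cell], donors, plan)
    table.loc[table["condition"] == "stimulated", "condition"] = f"knockout:{receptor}"
    return table


def generate_dose_series(
    construct: FusionConstruct,
    truth: dict[str, MechanismTruth],
    doses,
    cell_type: CellType,
    pathway: str | None = None,
    seed: int = 0,
    noise_cv: float = 0.15,
    n_replicates: int = 3,
    avidity_alpha: float = 1.0,
    k_half: float = K_HALF,
) -> DoseSeries:
    """Noisy responses of one construct along a dose titration.

    Each reported response is the mean of ``n_replicates`` wells, as dose
    titrations are typically plated; reads out the construct's dominant
    pathway unless ``pathway`` is given. Requires at least four doses
    including zero.
    """
    doses = [float(d) for d in doses]
    if len(doses) < 4:
        raise ValueError("a dose series needs at least 4 doses")
    if 0.0 not in doses:
        raise ValueError("a dose series must include dose 0")
    t = truth[construct.construct_id]
    if pathway is None:
        pathway = max(PATHWAYS, key=lambda pw: t.stat_profile.get(pw, 0.0))
    weight = t.stat_profile.get(pathway, 0.0)
    baseline = cell_type.baseline_mfi[pathway]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7004]))
    sorted_doses = sorted(doses)
    responses = []
    for d in sorted_doses:
        s = _construct_signal(
            [construct], truth, dict(cell_type.receptor_density), d, avidity_alpha, k_half
        )[0]
        wells = baseline * (1.0 + s * weight) * _lognormal_factors(rng, noise_cv, n_replicates)
        responses.append(float(np.mean(wells)))
    return DoseSeries(
        construct_id=construct.construct_id,
        doses=sorted_doses,
        responses=responses,
        pathway=pathway,
        cell_type=cell_type.name,
    )
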