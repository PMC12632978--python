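"""Receptor-dependence testing by single-receptor knockout.

A dual-receptor agonist must lose its signaling call when either targeted
receptor subunit is removed. For each construct that signals in the wild-type
background, the screen is regenerated in each single-knockout background and
re-called with the same statistic (``k`` × SEM against knockout-condition
unstimulated controls). A receptor is *required* when no reproducible call
survives its knockout; a construct is *dual-dependent* when both receptors
are required. Clustering-mechanism constructs, which aggregate a single
receptor, lose signaling only when that receptor is knocked out.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .hit_calling import call_hits
from .library_builder import FusionConstruct
from .synthetic_screen import (
    CellType,
    DonorProfile,
    MechanismTruth,
    ScreenPlan,
    generate_knockout_screen,
    generate_screen,
)


class KOPreconditionError(RuntimeError):
    """Raised when the wild-type background shows no reproducible signaling.

    Knockout dependence is only interpretable where the construct signals to
    begin with; backgrounds are chosen by confirming wild-type activity first.
    """


@dataclass(frozen=True)
class DependenceVerdict:
    construct_id: str
    receptor_a: str
    receptor_b: str
    receptor_a_required: bool
    receptor_b_required: bool

    @property
    def dual_dependent(self) -> bool:
        return self.receptor_a_required and self.receptor_b_required


def _any_reproducible(table: pd.DataFrame, k: float, min_donors: int) -> bool:
    hits = call_hits(table, k=k, min_donors=min_donors)
    tested = hits[
        (hits["condition"] == "stimulated") | hits["condition"].str.startswith("knockout:")
    ]
    return bool(tested["reproducible"].any())


def knockout_test(
    construct: FusionConstruct,
    truth: dict[str, MechanismTruth],
    cell_type: CellType,
    donors: list[DonorProfile],
    plan: ScreenPlan | None = None,
    k: float = 6.0,
    min_donors: int = 2,
) -> DependenceVerdict:
    """Dependence verdict for one construct in one cell context.

    Raises :class:`KOPreconditionError` if the wild-type screen yields no
    reproducible signaling call for the construct.
    """
    plan = plan or ScreenPlan()
    wt = generate_screen([construct], truth, [cell_type], donors, plan)
    if not _any_reproducible(wt, k, min_donors):
        raise KOPreconditionError(
            f"{construct.construct_id} does not signal in wild-type {cell_type.name}; "
            "knockout dependence is undefined without a positive baseline"
        )
    required = {}
    for receptor in dict.fromkeys(construct.receptor_pair):
        ko = generate_knockout_screen(construct, truth, cell_type, receptor, donors, plan)
        required[receptor] = not _any_reproducible(ko, k, min_donors)
    ra, rb = construct.receptor_pair
    return DependenceVerdict(
        construct_id=construct.construct_id,
        receptor_a=ra,
        receptor_b=rb,
        receptor_a_required=required[ra],
        receptor_b_required=required[rb],
    )


def batch_ko(
    constructs: list[FusionConstruct],
    truth: dict[str, MechanismTruth],
    cell_type: CellType,
    donors: list[DonorProfile],
    plan: ScreenPlan | None = None,
    k: float = 6.0,
    min_donors: int = 2,
) -> tuple[list[DependenceVerdict], int]:
    """Knockout-test a panel of constructs; returns verdicts and the dual-dependent count."""
    verdicts = [
        knockout_test(c, truth, cell_type, donors, plan, k=k, min_donors=min_donors)
        for c in constructs
    ]
    return verdicts, sum(v.dual_dependent for v in verdicts)


def verdicts_frame(verdicts: list[DependenceVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": v.construct_id,
                "receptor_a": v.receptor_a,
                "a_required": v.receptor_a_required,
                "receptor_b": v.receptor_b,
                "b_required": v.receptor_b_required,
                "dual_dependent": v.dual_dependent,
            }
            for v in verdicts
        ],
        columns=[
            "construct_id",
            "receptor_a",
            "a_required",
            "receptor_b",
            "b_required",
            "dual_dependent",
        ],
    )
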