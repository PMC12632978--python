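"""All-by-all enumeration of binder-fusion agonist constructs.

Each construct joins two binding domains with a flexible glycine-serine
linker (or a rigid scaffold, represented as metadata only). With ``n``
binders and ``ordered_all`` enumeration there are exactly ``n**2`` constructs
per linker: both orientations of every heterotypic pair plus ``n`` homotypic
fusions. The number of distinct unordered receptor pairings is
``n*(n+1)/2`` when every binder targets a different receptor — 561 for the
33-binder fixture, of which over 500 are non-natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .registry import Registry

MANIFEST_COLUMNS = [
    "construct_id",
    "n_term_binder",
    "c_term_binder",
    "linker_unit",
    "linker_repeats",
    "rigid",
    "receptor_a",
    "receptor_b",
]


@dataclass(frozen=True)
class LinkerSpec:
    """A flexible ``unit × repeats`` linker, or a rigid-fusion marker.

    Rigid constructs carry no linker sequence here: rigid scaffold geometry
    is designed elsewhere and only the label is tracked.
    """

    unit: str = "GGS"
    repeats: int = 2
    rigid: bool = False

    def __post_init__(self):
        if self.repeats < 0:
            raise ValueError("linker repeats must be >= 0")
        if not self.rigid and not self.unit:
            raise ValueError("flexible linker needs a non-empty unit motif")

    @property
    def name(self) -> str:
        return "rigid" if self.rigid else f"{self.repeats}x{self.unit}"

    @property
    def sequence(self) -> str:
        return "" if self.rigid else self.unit * self.repeats


@dataclass(frozen=True)
class FusionConstruct:
    """An ordered pair of binders joined by a linker; the unit of screening."""

    construct_id: str
    n_term_binder: str
    c_term_binder: str
    linker: LinkerSpec
    receptor_pair: tuple[str, str]  # sorted, derived from the registry
    orientation_index: int  # 1 for canonical order, 2 for the swap

    @property
    def is_homotypic(self) -> bool:
        return self.n_term_binder == self.c_term_binder


def _make_construct(registry: Registry, a: str, b: str, linker: LinkerSpec) -> FusionConstruct:
    pair = tuple(sorted((registry.binders[a].target, registry.binders[b].target)))
    return FusionConstruct(
        construct_id=f"{a}__{linker.name}__{b}",
        n_term_binder=a,
        c_term_binder=b,
        linker=linker,
        receptor_pair=pair,
        orientation_index=1 if a <= b else 2,
    )


def enumerate_library(
    registry: Registry,
    linkers: list[LinkerSpec] | None = None,
    orientations: str = "ordered_all",
) -> list[FusionConstruct]:
    """Enumerate fusion constructs from every binder pair in the registry.

    ``ordered_all`` yields all n² ordered pairs per linker (homotypic fusions
    once, heterotypic pairs in both orientations); ``unordered`` yields one
    construct per unordered pair (n(n+1)/2). Output is deterministically
    sorted by (n-terminal binder, c-terminal binder, linker name).
    """
    if len(registry) == 0:
        raise ValueError("cannot enumerate a library from an empty registry")
    linkers = linkers if linkers is not None else [LinkerSpec()]
    if not linkers:
        raise ValueError("at least one linker spec is required")
    if orientations not in {"ordered_all", "unordered"}:
        raise ValueError(f"unknown orientations mode {orientations!r}")

    ids = list(registry.binders)
    constructs = []
    for a in ids:
        for b in ids:
            if orientations == "unordered" and a > b:
                continue
            for linker in linkers:
                constructs.append(_make_construct(registry, a, b, linker))
    constructs.sort(key=lambda c: (c.n_term_binder, c.c_term_binder, c.linker.name))
    return constructs


def count_unique_pairings(constructs: list[FusionConstruct]) -> int:
    """Distinct unordered receptor pairs covered (homotypic pairs count once)."""
    if not constructs:
        raise ValueError("no constructs given")
    return len({c.receptor_pair for c in constructs})


def assemble_sequence(construct: FusionConstruct, registry: Registry) -> str:
    """N-terminal binder + linker repeats + C-terminal binder, as one chain."""
    missing = [
        bid
        for bid in (construct.n_term_binder, construct.c_term_binder)
        if registry.binders[bid].sequence is None
    ]
    if missing:
        raise ValueError(f"binders without sequences: {', '.join(dict.fromkeys(missing))}")
    return (
        registry.binders[construct.n_term_binder].sequence
        + construct.linker.sequence
        + registry.binders[construct.c_term_binder].sequence
    )


def to_manifest(constructs: list[FusionConstruct]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": c.construct_id,
                "n_term_binder": c.n_term_binder,
                "c_term_binder": c.c_term_binder,
                "linker_unit": "" if c.linker.rigid else c.linker.unit,
                "linker_repeats": 0 if c.linker.rigid else c.linker.repeats,
                "rigid": c.linker.rigid,
                "receptor_a": c.receptor_pair[0],
                "receptor_b": c.receptor_pair[1],
            }
            for c in constructs
        ],
        columns=MANIFEST_COLUMNS,
    )


def write_library(
    constructs: list[FusionConstruct],
    registry: Registry,
    fasta_path,
    manifest_path,
    header_comment: str | None = None,
) -> None:
    """Write construct sequences (FASTA, headers = construct ids) and a manifest TSV."""
    records = [
        SeqRecord(Seq(assemble_sequence(c, registry)), id=c.construct_id, description="")
        for c in constructs
    ]
    with open(fasta_path, "w") as fh:
        seqio_write(records, fh, "fasta")
    manifest = to_manifest(constructs)
    with open(manifest_path, "w", newline="\n") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        manifest.to_csv(fh, sep="\t", index=False)


def read_manifest(path, registry: Registry | None = None) -> list[FusionConstruct]:
    """Reconstruct the construct list from a manifest TSV (round-trip of write_library)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    constructs = []
    for rec in df.itertuples(index=False):
        linker = LinkerSpec(
            unit=rec.linker_unit or "GGS",
            repeats=int(rec.linker_repeats),
            rigid=rec.rigid.lower() == "true",
        )
        constructs.append(
            FusionConstruct(
                construct_id=rec.construct_id,
                n_term_binder=rec.n_term_binder,
                c_term_binder=rec.c_term_binder,
                linker=linker,
                receptor_pair=tuple(sorted((rec.receptor_a, rec.receptor_b))),
                orientation_index=1 if rec.n_term_binder <= rec.c_term_binder else 2,
            )
        )
    return constructs
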