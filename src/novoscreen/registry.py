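"""Catalogue of receptor-binding domains and their target receptors.

A registry is the entry point of the pipeline: each row of a registry TSV
declares one binding domain (a small designed protein or a previously
published binder), the receptor chain it engages, and receptor-level
metadata (family, chain class). Receptor pSTAT pathway identities
(``canonical_stats``) are a separate, editable configuration because they
describe receptors, not binders.

The packaged fixture (``data/binders.tsv``) holds 33 domains covering 33
distinct receptors: nine newly designed binders (Rosetta, RFdiffusion, or
agonist redesign) plus 24 previously developed ones. Affinities for the nine
new binders are synthetic placeholders drawn once from the 1-200 nM range;
affinities for prior-work binders are not published as numbers and are left
absent (``NA``).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

PATHWAYS = ("pSTAT1", "pSTAT3", "pSTAT4", "pSTAT5", "pSTAT6")
FAMILIES = frozenset(
    {"cytokine_common", "cytokine_private", "tnf_family", "checkpoint", "growth_factor"}
)
CHAIN_CLASSES = frozenset({"common", "private", "non_cytokine"})
ORIGINS = ("rosetta", "rfdiffusion", "redesigned_agonist", "prior_work")

REGISTRY_COLUMNS = [
    "binder_id",
    "target_receptor",
    "receptor_family",
    "chain_class",
    "length_aa",
    "kd_nM",
    "origin",
    "blocks_native_site",
]


class RegistryError(ValueError):
    """Structured load/validation error, naming the offending row when known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class ReceptorRef:
    """One receptor chain: identity, family, and canonical pSTAT weights."""

    name: str
    family: str
    chain_class: str
    canonical_stats: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise RegistryError(f"unknown receptor_family {self.family!r} for {self.name}")
        if self.chain_class not in CHAIN_CLASSES:
            raise RegistryError(f"unknown chain_class {self.chain_class!r} for {self.name}")
        total = 0.0
        for pw, w in self.canonical_stats.items():
            if pw not in PATHWAYS:
                raise RegistryError(f"unknown pathway {pw!r} in canonical_stats of {self.name}")
            if not 0.0 <= w <= 1.0:
                raise RegistryError(f"canonical_stats weight {w} out of [0,1] for {self.name}")
            total += w
        if total > 1.0 + 1e-9:
            raise RegistryError(f"canonical_stats of {self.name} sum to {total} > 1")

    def stats_vector(self) -> list[float]:
        return [self.canonical_stats.get(pw, 0.0) for pw in PATHWAYS]


@dataclass
class BinderDomain:
    """One receptor-binding module; the unit from which fusions are built."""

    id: str
    target: str
    length_aa: int
    origin: str
    kd_nM: float | None = None
    blocks_native_site: bool = False
    sequence: str | None = None

    def __post_init__(self):
        if self.length_aa <= 0:
            raise RegistryError(f"binder {self.id}: length_aa must be positive")
        if self.kd_nM is not None and not self.kd_nM > 0:
            raise RegistryError(f"binder {self.id}: kd_nM must be positive when present")
        if self.origin not in ORIGINS:
            raise RegistryError(f"binder {self.id}: unknown origin {self.origin!r}")


class Registry:
    """Validated collection of :class:`ReceptorRef` and :class:`BinderDomain`.

    Binder ids are unique; every binder's target resolves to a registered
    receptor. Iteration order over binders is insertion order.
    """

    def __init__(self):
        self.receptors: dict[str, ReceptorRef] = {}
        self.binders: dict[str, BinderDomain] = {}

    def add_receptor(self, rec: ReceptorRef, row: int | None = None) -> None:
        existing = self.receptors.get(rec.name)
        if existing is None:
            self.receptors[rec.name] = rec
        elif (existing.family, existing.chain_class) != (rec.family, rec.chain_class):
            raise RegistryError(
                f"conflicting metadata for receptor {rec.name!r}: "
                f"{(existing.family, existing.chain_class)} vs {(rec.family, rec.chain_class)}",
                row,
            )

    def add_binder(self, binder: BinderDomain, row: int | None = None) -> None:
        if binder.id in self.binders:
            raise RegistryError(f"duplicate binder id {binder.id!r}", row)
        if binder.target not in self.receptors:
            raise RegistryError(
                f"binder {binder.id!r}: target {binder.target!r} is not a registered receptor",
                row,
            )
        self.binders[binder.id] = binder

    def __len__(self) -> int:
        return len(self.binders)

    def __iter__(self):
        return iter(self.binders.values())

    def receptor_of(self, binder_id: str) -> ReceptorRef:
        return self.receptors[self.binders[binder_id].target]

    def subset(self, binder_ids) -> "Registry":
        """New registry restricted to ``binder_ids`` (receptors carried over)."""
        sub = Registry()
        for bid in binder_ids:
            b = self.binders[bid]
            sub.add_receptor(self.receptors[b.target])
            sub.add_binder(replace(b))
        return sub

    def with_synthetic_sequences(self, seed: int = 0) -> "Registry":
        """Attach deterministic placeholder amino-acid sequences of the declared lengths.

        Real binder sequences are out of scope; these synthetic sequences
        exist so that library FASTA output and length arithmetic are testable.
        """
        import zlib

        import numpy as np

        alphabet = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")
        out = Registry()
        out.receptors = dict(self.receptors)
        for b in self:
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, zlib.crc32(b.id.encode())])
            )
            seq = b"".join(rng.choice(alphabet, size=b.length_aa)).decode()
            out.binders[b.id] = replace(b, sequence=seq)
        return out


def _parse_bool(value: str, row: int) -> bool:
    v = str(value).strip().lower()
    if v in {"true", "1", "yes"}:
        return True
    if v in {"false", "0", "no"}:
        return False
    raise RegistryError(f"cannot parse boolean {value!r}", row)


def default_canonical_stats() -> dict[str, dict[str, float]]:
    """Packaged receptor -> pSTAT weight configuration."""
    ref = importlib.resources.files("novoscreen.data").joinpath("receptors.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return {str(k): dict(v or {}) for k, v in cfg["canonical_stats"].items()}


def load_registry(path, canonical_stats: dict | None = None) -> Registry:
    """Load and validate a registry TSV (see module docstring for the dialect).

    ``canonical_stats`` maps receptor name -> pathway weight dict; receptors
    not listed default to a zero vector. When omitted, the packaged
    configuration is used.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    except FileNotFoundError:
        raise RegistryError(f"registry file not found: {path}")
    if list(df.columns) != REGISTRY_COLUMNS:
        raise RegistryError(
            f"bad registry header: expected {REGISTRY_COLUMNS}, got {list(df.columns)}"
        )
    if canonical_stats is None:
        canonical_stats = default_canonical_stats()

    reg = Registry()
    for i, rec in enumerate(df.itertuples(index=False), start=1):
        receptor = ReceptorRef(
            name=rec.target_receptor,
            family=rec.receptor_family,
            chain_class=rec.chain_class,
            canonical_stats=canonical_stats.get(rec.target_receptor, {}),
        )
        reg.add_receptor(receptor, row=i)
        try:
            length = int(rec.length_aa)
            kd = None if rec.kd_nM == "NA" else float(rec.kd_nM)
        except ValueError as exc:
            raise RegistryError(str(exc), row=i)
        # re-raise invariant violations with the row number attached
        try:
            binder = BinderDomain(
                id=rec.binder_id,
                target=rec.target_receptor,
                length_aa=length,
                kd_nM=kd,
                origin=rec.origin,
                blocks_native_site=_parse_bool(rec.blocks_native_site, i),
            )
            reg.add_binder(binder, row=i)
        except RegistryError as exc:
            if exc.row is None:
                raise RegistryError(str(exc), row=i) from None
            raise
    return reg


def write_registry(registry: Registry, path) -> None:
    """Write the canonical TSV form: rows sorted by binder id, %g-formatted KDs.

    ``write_registry(load_registry(f), f2)`` followed by a reload reproduces
    ``f2`` byte-identically.
    """
    lines = ["\t".join(REGISTRY_COLUMNS)]
    for b in sorted(registry, key=lambda b: b.id):
        rec = registry.receptors[b.target]
        kd = "NA" if b.kd_nM is None else ("%g" % b.kd_nM)
        lines.append(
            "\t".join(
                [
                    b.id,
                    b.target,
                    rec.family,
                    rec.chain_class,
                    str(b.length_aa),
                    kd,
                    b.origin,
                    "true" if b.blocks_native_site else "false",
                ]
            )
        )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def count_by_origin(registry: Registry) -> dict[str, int]:
    """Partition of the binder set by design origin (all origins present, zero-filled)."""
    counts = {origin: 0 for origin in ORIGINS}
    for b in registry:
        counts[b.origin] += 1
    return counts


def packaged_registry() -> Registry:
    """The 33-binder fixture shipped with the package."""
    ref = importlib.resources.files("novoscreen.data").joinpath("binders.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_registry(path)
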