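"""sgRNA library representation, assembly, validation and TSV serialization.

A *library* is an ordered collection of guides; each guide carries a 20-nt
spacer sequence that doubles as the screen's heritable barcode, a target gene,
and a role (candidate, negative control, or positive control). Downstream
count matrices and score tables use the library's canonical guide order
(gene alphabetical, then guide index) as their column order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SPACER_LEN = 20
SPACER_ALPHABET = frozenset("ACGT")
ROLES = ("candidate", "negative_control", "positive_control")

#: Output blood compartments a gene effect may be restricted to.
LINEAGES = ("HSPC", "Gr1", "T", "B", "GCB", "B1a", "NK", "CD11b")


class LibraryError(ValueError):
    """Invalid library content (duplicate spacers, bad alphabet, ...)."""


class LibraryFormatError(LibraryError):
    """Malformed library file (missing columns, bad spacer format, ...)."""


@dataclass(frozen=True)
class SgRNA:
    """One guide: id, target gene, 20-nt spacer, and control role.

    Construction itself does not validate, so malformed entries can be held
    and *reported* by :func:`validate_library`; strict entry points
    (:func:`assemble_library`) raise via :func:`check_sgrna`.
    """

    guide_id: str
    gene: str
    spacer: str
    role: str = "candidate"


def check_sgrna(guide: SgRNA) -> None:
    """Raise :class:`LibraryFormatError` on a malformed guide entry."""
    if len(guide.spacer) != SPACER_LEN:
        raise LibraryFormatError(
            f"guide {guide.guide_id!r}: spacer must be {SPACER_LEN} nt, "
            f"got {len(guide.spacer)} ({guide.spacer!r})"
        )
    if not SPACER_ALPHABET.issuperset(guide.spacer):
        bad = sorted(set(guide.spacer) - SPACER_ALPHABET)
        raise LibraryFormatError(
            f"guide {guide.guide_id!r}: spacer contains non-ACGT characters {bad}"
        )
    if guide.role not in ROLES:
        raise LibraryFormatError(
            f"guide {guide.guide_id!r}: role {guide.role!r} not in {ROLES}"
        )


@dataclass(frozen=True)
class Library:
    """Ordered guide collection with a fixed per-gene multiplicity.

    ``entries`` are kept in canonical order (gene alphabetical, then guide
    index) by :func:`assemble_library`; libraries built by hand keep the
    order given.
    """

    entries: tuple[SgRNA, ...]
    guides_per_gene: int = 3
    name: str = ""
    ragged: bool = False

    @property
    def guide_ids(self) -> list[str]:
        return [g.guide_id for g in self.entries]

    @property
    def spacers(self) -> list[str]:
        return [g.spacer for g in self.entries]

    @property
    def genes(self) -> list[str]:
        """Distinct genes in first-appearance order."""
        seen: dict[str, None] = {}
        for g in self.entries:
            seen.setdefault(g.gene, None)
        return list(seen)

    @property
    def roles(self) -> dict[str, str]:
        return {g.gene: g.role for g in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def gene_of(self, guide_id: str) -> str:
        for g in self.entries:
            if g.guide_id == guide_id:
                return g.gene
        raise KeyError(guide_id)

    def guides_for(self, gene: str) -> list[SgRNA]:
        return [g for g in self.entries if g.gene == gene]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "guide_id": [g.guide_id for g in self.entries],
                "gene": [g.gene for g in self.entries],
                "spacer": [g.spacer for g in self.entries],
                "role": [g.role for g in self.entries],
            }
        )


@dataclass(frozen=True)
class GeneRole:
    """A gene's control role and the lineages where its loss is expected to matter."""

    role: str = "candidate"
    expected_lineage_effects: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise LibraryError(f"unknown role {self.role!r}")
        unknown = set(self.expected_lineage_effects) - set(LINEAGES)
        if unknown:
            raise LibraryError(f"unknown lineage labels {sorted(unknown)}")
        if self.role == "negative_control" and self.expected_lineage_effects:
            raise LibraryError("negative-control genes must have no expected lineage effects")


class GeneRoleMap(dict):
    """Mapping gene symbol -> :class:`GeneRole`."""

    @classmethod
    def from_specs(cls, specs: Mapping[str, tuple[str, Iterable[str]]]) -> "GeneRoleMap":
        return cls(
            {
                gene: GeneRole(role, frozenset(lineages))
                for gene, (role, lineages) in specs.items()
            }
        )


def assemble_library(
    gene_specs: Sequence[tuple[str, str, Sequence[str]]],
    guides_per_gene: int = 3,
    name: str = "",
    allow_ragged: bool = False,
) -> Library:
    """Build a canonical library from ``(gene, role, spacers)`` specs.

    Genes are ordered alphabetically and guides named ``<gene>_sg<i>`` in the
    order the spacers were supplied; genes providing more than
    ``guides_per_gene`` spacers contribute the first ``guides_per_gene``.
    Supplying fewer is an error unless ``allow_ragged`` is set.
    """
    if guides_per_gene < 1:
        raise LibraryError("guides_per_gene must be positive")
    seen_genes: set[str] = set()
    for gene, _, _ in gene_specs:
        if gene in seen_genes:
            raise LibraryError(f"gene {gene!r} listed more than once")
        seen_genes.add(gene)

    entries: list[SgRNA] = []
    for gene, role, spacers in sorted(gene_specs, key=lambda s: s[0]):
        if len(spacers) < guides_per_gene and not allow_ragged:
            raise LibraryError(
                f"gene {gene!r} supplies {len(spacers)} spacers; "
                f"{guides_per_gene} required (use allow_ragged to permit)"
            )
        take = spacers if allow_ragged else spacers[:guides_per_gene]
        for i, spacer in enumerate(take, start=1):
            guide = SgRNA(f"{gene}_sg{i}", gene, str(spacer).upper(), role)
            check_sgrna(guide)
            entries.append(guide)

    by_spacer: dict[str, str] = {}
    for g in entries:
        if g.spacer in by_spacer:
            raise LibraryError(
                f"duplicate spacer {g.spacer} shared by guides "
                f"{by_spacer[g.spacer]!r} and {g.guide_id!r}"
            )
        by_spacer[g.spacer] = g.guide_id

    return Library(
        tuple(entries),
        guides_per_gene=guides_per_gene,
        name=name,
        ragged=allow_ragged,
    )


@dataclass(frozen=True)
class Check:
    name: str
    ok: bool
    detail: str = ""


@dataclass(frozen=True)
class ValidationReport:
    checks: tuple[Check, ...]

    @property
    def ok(self) -> bool:
        return all(c.ok for c in self.checks)

    def __getitem__(self, name: str) -> Check:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)

    def failures(self) -> list[Check]:
        return [c for c in self.checks if not c.ok]


def validate_library(lib: Library) -> ValidationReport:
    """Report-only structural validation of a library."""
    checks: list[Check] = []

    bad_len = [g.guide_id for g in lib.entries if len(g.spacer) != SPACER_LEN]
    checks.append(Check("spacer_length", not bad_len, ", ".join(bad_len)))

    bad_alpha = [
        g.guide_id for g in lib.entries if not SPACER_ALPHABET.issuperset(g.spacer)
    ]
    checks.append(Check("spacer_alphabet", not bad_alpha, ", ".join(bad_alpha)))

    ids = lib.guide_ids
    dup_ids = sorted({i for i in ids if ids.count(i) > 1})
    checks.append(Check("guide_id_unique", not dup_ids, ", ".join(dup_ids)))

    sp = lib.spacers
    dup_sp = sorted({s for s in sp if sp.count(s) > 1})
    checks.append(Check("spacer_unique", not dup_sp, ", ".join(dup_sp)))

    if lib.ragged:
        checks.append(Check("per_gene_multiplicity", True, "ragged library; not checked"))
    else:
        uneven = [
            f"{gene} ({len(lib.guides_for(gene))})"
            for gene in lib.genes
            if len(lib.guides_for(gene)) != lib.guides_per_gene
        ]
        checks.append(Check("per_gene_multiplicity", not uneven, ", ".join(uneven)))

    has_neg = any(g.role == "negative_control" for g in lib.entries)
    checks.append(
        Check(
            "no_negative_control",
            has_neg,
            "" if has_neg else "library has no negative-control gene",
        )
    )
    return ValidationReport(tuple(checks))


_COLUMNS = ("guide_id", "gene", "spacer", "role")


def write_library_tsv(lib: Library, path: str | Path) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_library_tsv(path: str | Path, name: str | None = None) -> Library:
    """Read a library from TSV; column order is header-driven, blank lines skipped."""
    df = pd.read_csv(path, sep="\t", dtype=str, skip_blank_lines=True, comment="#")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise LibraryFormatError(f"{path}: missing column(s) {missing}")
    n_blank = int(df.isna().all(axis=1).sum())
    if n_blank:
        logger.info("%s: skipped %d blank line(s)", path, n_blank)
        df = df.dropna(how="all")
    entries = tuple(
        SgRNA(r.guide_id, r.gene, r.spacer, r.role) for r in df.itertuples(index=False)
    )
    counts = {g: sum(1 for e in entries if e.gene == g) for g in {e.gene for e in entries}}
    mult = max(counts.values()) if counts else 3
    ragged = len(set(counts.values())) > 1
    return Library(
        entries,
        guides_per_gene=mult,
        name=name if name is not None else Path(path).stem,
        ragged=ragged,
    )
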