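"""Gene-set construction and overlap significance.

Implements the meta-analysis primitives: a percentile cutoff that turns a
transcription factor's per-gene binding scores into its direct-target set
(top decile by default, nearest-rank with inclusive ties), the one-sided
hypergeometric (Fisher exact) upper-tail test for the significance of an
overlap between two gene sets in an explicit universe, and exact Venn
region counts for two or three sets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from scipy import stats


class OverlapError(ValueError):
    """Invalid set input (empty scores, inconsistent sizes)."""


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols, optionally bound to a universe size."""

    name: str
    members: frozenset[str]
    universe_size: int | None = None

    def __post_init__(self) -> None:
        if self.universe_size is not None and len(self.members) > self.universe_size:
            raise OverlapError(
                f"set {self.name!r} has {len(self.members)} members but "
                f"universe of only {self.universe_size}"
            )

    def __len__(self) -> int:
        return len(self.members)

    @classmethod
    def from_iterable(cls, name: str, genes, universe_size: int | None = None) -> "GeneSet":
        return cls(name, frozenset(str(g) for g in genes), universe_size)


@dataclass(frozen=True)
class OverlapResult:
    """Summary of one two-set overlap test."""

    set_a: str
    set_b: str
    size_a: int
    size_b: int
    intersection: int
    universe: int
    p_value: float
    fold_enrichment: float
    jaccard: float

    def to_dict(self) -> dict:
        return {
            "set_a": self.set_a,
            "set_b": self.set_b,
            "size_a": self.size_a,
            "size_b": self.size_b,
            "intersection": self.intersection,
            "universe": self.universe,
            "p_value": self.p_value,
            "fold_enrichment": self.fold_enrichment,
            "jaccard": self.jaccard,
        }

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kw)


def percentile_target_set(
    binding_scores: Mapping[str, float],
    q: float = 0.90,
    name: str = "targets",
) -> GeneSet:
    """Genes at or above the empirical q-quantile of their binding scores.

    Nearest-rank cutoff: the threshold is the ``ceil((1-q)*n)``-th largest
    score, and every gene tied with it is included, so set membership is
    stable under score permutations. With all scores equal the whole input
    is returned.
    """
    if not binding_scores:
        raise OverlapError("empty score map")
    if not 0.0 < q < 1.0:
        raise OverlapError("q must lie strictly between 0 and 1")
    items = list(binding_scores.items())
    for gene, s in items:
        if not math.isfinite(s):
            raise OverlapError(f"non-finite score for {gene!r}")
    n = len(items)
    k = max(1, math.ceil((1.0 - q) * n))
    cutoff = sorted((s for _, s in items), reverse=True)[k - 1]
    return GeneSet.from_iterable(name, (g for g, s in items if s >= cutoff))


def overlap_test(a: GeneSet, b: GeneSet, universe_size: int) -> OverlapResult:
    """Hypergeometric upper-tail significance of the overlap of two sets.

    p = P(X >= |A n B|) for X ~ Hypergeometric(N, |B|, |A|): the chance that
    a uniform draw of |A| genes from the N-gene universe hits at least the
    observed number of B members.
    """
    n_a, n_b = len(a), len(b)
    if n_a > universe_size or n_b > universe_size:
        raise OverlapError("set larger than the declared universe")
    k = len(a.members & b.members)
    if k > min(n_a, n_b):  # unreachable for real sets; guards hand-built inputs
        raise OverlapError("overlap exceeds the smaller set")
    p = float(stats.hypergeom.sf(k - 1, universe_size, n_b, n_a))
    p = min(p, 1.0)
    expected_rate = n_b / universe_size
    fold = (k / n_a) / expected_rate if n_a and expected_rate else float("nan")
    union = len(a.members | b.members)
    jaccard = k / union if union else 0.0
    return OverlapResult(
        set_a=a.name,
        set_b=b.name,
        size_a=n_a,
        size_b=n_b,
        intersection=k,
        universe=universe_size,
        p_value=p,
        fold_enrichment=fold,
        jaccard=jaccard,
    )


def multiway_venn(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Exact Venn region counts for 2 or 3 gene sets.

    Region keys are membership signatures over the input names, e.g. for
    sets A, B, C: ``"A"`` (A only), ``"A&B"``, ``"A&B&C"``. Counts over all
    regions sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise OverlapError("multiway_venn supports exactly 2 or 3 sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise OverlapError("set names must be distinct")
    regions: dict[str, int] = {}
    universe = frozenset().union(*(s.members for s in sets))
    for mask in range(1, 2 ** len(sets)):
        inside = [s for i, s in enumerate(sets) if mask >> i & 1]
        outside = [s for i, s in enumerate(sets) if not mask >> i & 1]
        region = frozenset.intersection(*(s.members for s in inside))
        for s in outside:
            region = region - s.members
        key = "&".join(s.name for s in inside)
        regions[key] = len(region)
    assert sum(regions.values()) == len(universe)
    return regions
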