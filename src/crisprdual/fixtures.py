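"""Packaged screen fixtures: gene panels, synthetic spacers, planted fitness.

The published guide sequences are not publicly deposited, so the packaged
libraries combine the screens' gene panels with synthetic 20-nt spacers
generated deterministically at pairwise Hamming distance >= 3 (which makes
single-mismatch barcode assignment unambiguous). Everything here is
synthetic except the gene symbols and role annotations.
"""

from __future__ import annotations

import numpy as np

from .library import GeneRoleMap, Library, assemble_library
from .simulate import FitnessModel

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed entropy for fixture spacers; fixtures must be bit-stable across runs.
_FIXTURE_SEED = 20240723


def synthetic_spacers(
    n: int, seed: int = _FIXTURE_SEED, min_pairwise_hamming: int = 3
) -> list[str]:
    """Generate ``n`` synthetic 20-nt spacers with a minimum pairwise distance.

    Greedy rejection sampling from uniform random 20-mers; deterministic for
    a fixed seed. Distance >= 3 guarantees that a spacer one substitution away
    from a library spacer is never within one substitution of another.
    """
    rng = np.random.default_rng(seed)
    chosen = np.empty((0, 20), dtype=np.uint8)
    out: list[str] = []
    while len(out) < n:
        cand = rng.choice(_BASES, size=20)
        if chosen.size and int((chosen != cand).sum(axis=1).min()) < min_pairwise_hamming:
            continue
        chosen = np.vstack([chosen, cand])
        out.append(cand.tobytes().decode())
    return out


# 15-gene transplantation screen panel: lineage-specific positive controls,
# two neutral controls, and the candidate genes carried over or added.
_INVIVO_PANEL: dict[str, tuple[str, tuple[str, ...]]] = {
    "Gfi1": ("positive_control", ("HSPC", "Gr1")),
    "Uhrf1": ("positive_control", ("HSPC", "Gr1")),
    "Ebf1": ("positive_control", ("B", "GCB", "B1a")),
    "Pax5": ("positive_control", ("B", "GCB", "B1a")),
    "Btk": ("positive_control", ("B", "GCB", "B1a")),
    "Bcl6": ("positive_control", ("GCB",)),
    "Cd3e": ("positive_control", ("T",)),
    "Notch1": ("positive_control", ("T",)),
    "Csf3r": ("positive_control", ("Gr1",)),
    "Gfi1b": ("negative_control", ()),
    "Rosa26": ("negative_control", ()),
    "Tfdp1": ("candidate", ("HSPC", "Gr1", "T", "B", "GCB", "B1a")),
    "Zfp114": ("candidate", ()),
    "Mllt3": ("candidate", ()),
    "Dach1": ("candidate", ()),
}

# 33-gene in vitro expansion screen panel: zinc-finger and TFDP family
# candidates plus controls. Four genes are the planted depletion truth
# (the two positive controls and the two candidates found depleted).
_INVITRO_CANDIDATES = (
    "Tfdp1",
    "Tfdp2",
    "Zfp114",
    "Zfp36",
    "Zfp90",
    "Zfp148",
    "Zfp217",
    "Zfp281",
    "Zfp335",
    "Zfp362",
    "Zfp383",
    "Zfp420",
    "Zfp445",
    "Zfp462",
    "Zfp467",
    "Zfp512",
    "Zfp521",
    "Zfp558",
    "Zfp574",
    "Zfp592",
    "Zfp607",
    "Zfp622",
    "Zfp646",
    "Zfp652",
    "Zfp687",
    "Zfp706",
    "Zfp740",
    "Zfp768",
    "Zfp800",
    "Zfp846",
)
INVITRO_DEPLETION_GENES = ("Lmo2", "Uhrf1", "Tfdp1", "Zfp114")

# 8-member E2F-family follow-up screen panel.
_E2F_PANEL = ("E2f1", "E2f2", "E2f3", "E2f4", "E2f5", "E2f6", "E2f7", "E2f8")
E2F_DEPLETION_GENES = ("Tfdp1", "E2f4")


def invivo_role_map() -> GeneRoleMap:
    return GeneRoleMap.from_specs(_INVIVO_PANEL)


def invivo_library() -> Library:
    """45-guide, 15-gene transplantation-screen library (3 guides/gene)."""
    genes = sorted(_INVIVO_PANEL)
    spacers = synthetic_spacers(3 * len(genes))
    specs = [
        (g, _INVIVO_PANEL[g][0], spacers[3 * i : 3 * i + 3]) for i, g in enumerate(genes)
    ]
    return assemble_library(specs, guides_per_gene=3, name="invivo15")


def invitro_library() -> Library:
    """99-guide, 33-gene in vitro expansion-screen library."""
    genes = sorted(("Rosa26", "Lmo2", "Uhrf1") + _INVITRO_CANDIDATES)
    spacers = synthetic_spacers(3 * len(genes), seed=_FIXTURE_SEED + 1)
    roles = {"Rosa26": "negative_control", "Lmo2": "positive_control", "Uhrf1": "positive_control"}
    specs = [
        (g, roles.get(g, "candidate"), spacers[3 * i : 3 * i + 3])
        for i, g in enumerate(genes)
    ]
    return assemble_library(specs, guides_per_gene=3, name="invitro33")


def e2f_library() -> Library:
    """27-guide E2F-family follow-up library (8 E2F genes + Rosa26 control)."""
    genes = sorted(_E2F_PANEL + ("Rosa26",))
    spacers = synthetic_spacers(3 * len(genes), seed=_FIXTURE_SEED + 2)
    specs = [
        (g, "negative_control" if g == "Rosa26" else "candidate", spacers[3 * i : 3 * i + 3])
        for i, g in enumerate(genes)
    ]
    return assemble_library(specs, guides_per_gene=3, name="e2f")


def invitro_fitness(w_depleted: float = 0.5, editing_efficiency: float = 0.9) -> FitnessModel:
    """Planted truth for the in vitro screen: four strongly depleted genes.

    ``w_depleted=0.5`` halves the per-division growth of edited cells
    (expected offspring 2w = 1, i.e. no net expansion).
    """
    return FitnessModel(
        fitness={(g, "HSPC"): w_depleted for g in INVITRO_DEPLETION_GENES},
        editing={g: editing_efficiency for g in INVITRO_DEPLETION_GENES},
        default_editing=editing_efficiency,
        negative_controls=("Rosa26",),
    )


def invivo_fitness(w_depleted: float = 0.5, editing_efficiency: float = 0.9) -> FitnessModel:
    """Planted truth for the transplantation screen from the role map."""
    fitness = {}
    for gene, (_, lineages) in _INVIVO_PANEL.items():
        for lin in lineages:
            fitness[(gene, lin)] = w_depleted
    return FitnessModel(
        fitness=fitness,
        default_editing=editing_efficiency,
        negative_controls=("Gfi1b", "Rosa26"),
    )


def e2f_fitness(w_depleted: float = 0.5, editing_efficiency: float = 0.9) -> FitnessModel:
    return FitnessModel(
        fitness={(g, "HSPC"): w_depleted for g in E2F_DEPLETION_GENES},
        default_editing=editing_efficiency,
        negative_controls=("Rosa26",),
    )
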