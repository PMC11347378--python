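"""Generative model of the dual-fluorescence CRISPR depletion screen.

The simulated experiment mirrors the screen's stage structure:

1. Cas9-GFP and wild-type HSPCs are mixed (1:1 in vitro, 3:2 in vivo) and
   transduced per well with a single guide (mCherry marks transduction).
2. Edited cells (probability ``e`` per transduced Cas9+ cell) grow with
   per-division relative fitness ``w``: expected offspring per division is
   ``2w`` (``w=1`` neutral, ``w=0.5`` no net growth, ``w=0`` extinction).
3. In vivo, wells are pooled and a fixed-size graft is drawn without
   replacement (multivariate hypergeometric bottleneck), expanded per output
   lineage, and sorted into GFP+ / GFP- fractions.
4. Sorted cells are sequenced with Dirichlet-multinomial PCR overdispersion,
   optionally emitted as FASTQ for end-to-end barcode-counting tests.

Growth noise is Poisson around the branching-process expectation; every
partition (graft draw, sorting) conserves cell counts exactly.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountMatrix, ReadLayout
from .library import LINEAGES, Library, SgRNA

logger = logging.getLogger(__name__)


class SimulationError(ValueError):
    """Invalid simulation parameters or impossible sampling request."""


def stage_rng(seed: int, *stage: object) -> np.random.Generator:
    """Derive an independent, reproducible generator for a named stage.

    One root seed drives the whole simulation; each stage hashes its name
    into the seed sequence so stages are individually reproducible and
    insensitive to the order in which other stages consume randomness.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [
        zlib.crc32(str(k).encode()) for k in stage
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class FitnessModel:
    """Planted truth: per-gene editing efficiency and per-gene-and-lineage fitness.

    ``fitness`` maps ``(gene, lineage) -> w``; unlisted pairs are neutral
    (``w = 1``). ``editing`` maps ``gene -> e``; unlisted genes use
    ``default_editing``. Negative-control genes are forced neutral.
    """

    fitness: Mapping[tuple[str, str], float] = field(default_factory=dict)
    editing: Mapping[str, float] = field(default_factory=dict)
    default_editing: float = 0.9
    negative_controls: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for (gene, lineage), w in self.fitness.items():
            if w < 0:
                raise SimulationError(f"fitness w must be >= 0; got {w} for {gene}/{lineage}")
            if gene in self.negative_controls and w != 1.0:
                raise SimulationError(f"negative control {gene!r} must stay neutral (w=1)")
        for gene, e in self.editing.items():
            if not 0.0 <= e <= 1.0:
                raise SimulationError(f"editing efficiency must lie in [0,1]; got {e} for {gene}")
        if not 0.0 <= self.default_editing <= 1.0:
            raise SimulationError("default_editing must lie in [0,1]")

    def w(self, gene: str, lineage: str = "HSPC") -> float:
        if gene in self.negative_controls:
            return 1.0
        return float(self.fitness.get((gene, lineage), 1.0))

    def e(self, gene: str) -> float:
        return float(self.editing.get(gene, self.default_editing))

    def truth_frame(self, lib: Library, lineages: Iterable[str] = ("HSPC",)) -> pd.DataFrame:
        """Tabulate planted (gene, lineage, w, e) for recovery tests."""
        rows = [
            {"gene": g, "lineage": lin, "w": self.w(g, lin), "e": self.e(g)}
            for g in lib.genes
            for lin in lineages
        ]
        return pd.DataFrame(rows)

    @classmethod
    def neutral(cls) -> "FitnessModel":
        return cls()


@dataclass(frozen=True)
class LineageSpec:
    """Per-lineage reconstitution: expansion factor and FACS sort depth."""

    expansion: float = 1000.0
    sort_depth: int = 20000

    def __post_init__(self) -> None:
        if self.expansion <= 0:
            raise SimulationError("expansion must be positive")
        if self.sort_depth < 1:
            raise SimulationError("sort_depth must be >= 1")

    @property
    def divisions(self) -> float:
        """Effective division count implied by the expansion factor."""
        return float(np.log2(self.expansion))


@dataclass(frozen=True)
class ScreenDesign:
    """Experimental design constants for one screen arm."""

    mix_ratio: tuple[float, float] = (1.0, 1.0)
    transduction_rate: float = 0.3
    cells_per_well: int = 20000
    graft_size: int = 50000
    divisions_by_readout: Mapping[int, int] = field(
        default_factory=lambda: {2: 1, 7: 5}
    )
    lineages: Mapping[str, LineageSpec] = field(
        default_factory=lambda: {"HSPC": LineageSpec()}
    )
    facs_events: int = 10000
    input_concentration: float = 150.0

    def __post_init__(self) -> None:
        if min(self.mix_ratio) <= 0:
            raise SimulationError("mix_ratio parts must be positive")
        if not 0.0 < self.transduction_rate < 1.0:
            raise SimulationError("transduction_rate must lie in (0,1)")
        if self.cells_per_well < 1 or self.graft_size < 1 or self.facs_events < 1:
            raise SimulationError("cell/event counts must be positive")
        tps = sorted(self.divisions_by_readout)
        divs = [self.divisions_by_readout[t] for t in tps]
        if any(b < a for a, b in zip(divs, divs[1:])):
            raise SimulationError("divisions must be non-decreasing in time")
        unknown = set(self.lineages) - set(LINEAGES)
        if unknown:
            raise SimulationError(f"unknown lineage labels {sorted(unknown)}")
        if self.input_concentration <= 0:
            raise SimulationError("input_concentration must be positive")

    @property
    def cas9_fraction(self) -> float:
        """Fraction of the input mix that is Cas9+ (GFP+)."""
        return self.mix_ratio[0] / (self.mix_ratio[0] + self.mix_ratio[1])

    @property
    def gfp_ratio(self) -> float:
        """Designed GFP+/GFP- cell ratio (1.0 at 1:1, 1.5 at 3:2)."""
        return self.mix_ratio[0] / self.mix_ratio[1]

    @property
    def graft_split(self) -> tuple[int, int]:
        """Graft split between Cas9+ and Cas9- cells at the design mix."""
        pos = round(self.graft_size * self.cas9_fraction)
        return pos, self.graft_size - pos

    @classmethod
    def in_vitro(cls, **kw) -> "ScreenDesign":
        """1:1 Cas9+:Cas9- mix, arrayed wells read at day 2 and day 7."""
        kw.setdefault("mix_ratio", (1.0, 1.0))
        kw.setdefault("transduction_rate", 0.3)
        return cls(**kw)

    @classmethod
    def in_vivo(cls, **kw) -> "ScreenDesign":
        """3:2 mix, transduction kept <0.3, six sorted output lineages."""
        kw.setdefault("mix_ratio", (3.0, 2.0))
        kw.setdefault("transduction_rate", 0.25)
        kw.setdefault(
            "lineages",
            {lin: LineageSpec() for lin in ("HSPC", "Gr1", "T", "B", "GCB", "B1a")},
        )
        return cls(**kw)


@dataclass(frozen=True)
class FlowCounts:
    """Four-gate FACS event counts for one well at one timepoint."""

    mchpos_gfppos: int
    mchpos_gfpneg: int
    mchneg_gfppos: int
    mchneg_gfpneg: int

    def __post_init__(self) -> None:
        if min(self.as_tuple()) < 0:
            raise SimulationError("event counts must be >= 0")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (
            self.mchpos_gfppos,
            self.mchpos_gfpneg,
            self.mchneg_gfppos,
            self.mchneg_gfpneg,
        )

    @property
    def total(self) -> int:
        return sum(self.as_tuple())


def simulate_input_frequencies(
    lib: Library, concentration: float = 150.0, seed: int = 0
) -> pd.Series:
    """Draw per-guide input-library frequencies from a symmetric Dirichlet.

    ``concentration`` is the per-guide Dirichlet parameter; large values give
    an even library (the default 150 keeps a 45-guide library within a few
    percent of uniform). Concentrations >= 1e6 short-circuit to the exact
    uniform limit.
    """
    if len(lib) == 0:
        raise SimulationError("cannot draw input frequencies for an empty library")
    if concentration <= 0:
        raise SimulationError("concentration must be positive")
    n = len(lib)
    if n == 1:
        freqs = np.array([1.0])
    elif concentration >= 1e6:
        freqs = np.full(n, 1.0 / n)
    else:
        freqs = stage_rng(seed, "input").dirichlet(np.full(n, concentration))
    return pd.Series(freqs, index=lib.guide_ids, name="input_frequency")


def simulate_well(
    design: ScreenDesign,
    fitness: FitnessModel,
    guide: SgRNA | str,
    timepoints: Sequence[int] | None = None,
    seed: int = 0,
    lineage: str = "HSPC",
    transduction_rate: float | None = None,
) -> dict[int, FlowCounts]:
    """Simulate one arrayed well (one guide) and its FACS readouts.

    The well's four subpopulations (mCherry x GFP, with transduced Cas9+
    cells split edited/unedited at the gene's editing efficiency) grow for
    the timepoint's division count — factor ``2**D`` for neutral cells and
    ``(2w)**D`` for edited cells — with Poisson noise, then ``facs_events``
    events are sampled multinomially.
    """
    gene = guide.gene if isinstance(guide, SgRNA) else str(guide)
    tau = design.transduction_rate if transduction_rate is None else float(transduction_rate)
    if not 0.0 < tau < 1.0:
        raise SimulationError("transduction rate must lie in (0,1)")
    if timepoints is None:
        timepoints = sorted(design.divisions_by_readout)
    phi = design.cas9_fraction
    e = fitness.e(gene)
    w = fitness.w(gene, lineage)
    n0 = design.cells_per_well
    # subpopulations: [mCh+GFP+ edited, mCh+GFP+ unedited, mCh+GFP-, mCh-GFP+, mCh-GFP-]
    base = n0 * np.array(
        [tau * phi * e, tau * phi * (1 - e), tau * (1 - phi), (1 - tau) * phi, (1 - tau) * (1 - phi)]
    )
    out: dict[int, FlowCounts] = {}
    for tp in timepoints:
        if tp not in design.divisions_by_readout:
            raise SimulationError(f"no division count configured for timepoint {tp}")
        d = design.divisions_by_readout[tp]
        rng = stage_rng(seed, "well", gene, tp)
        growth = np.array([(2.0 * w) ** d, 2.0**d, 2.0**d, 2.0**d, 2.0**d])
        sizes = rng.poisson(base * growth)
        total = sizes.sum()
        if total == 0:
            raise SimulationError("well population collapsed to zero cells")
        ev = rng.multinomial(design.facs_events, sizes / total)
        out[tp] = FlowCounts(int(ev[0] + ev[1]), int(ev[2]), int(ev[3]), int(ev[4]))
    return out


def simulate_invitro_screen(
    lib: Library,
    fitness: FitnessModel,
    design: ScreenDesign | None = None,
    n_replicates: int = 2,
    seed: int = 0,
    tau_range: tuple[float, float] = (0.2, 0.6),
) -> pd.DataFrame:
    """Simulate the arrayed in vitro screen: one well per guide per replicate.

    Per-well transduction efficiency is drawn uniformly from ``tau_range``
    (wells vary between 20% and 60% in practice); the internal-control score
    is insensitive to it. Returns a tidy frame of four-gate event counts.
    """
    design = design or ScreenDesign.in_vitro()
    rows = []
    for rep in range(1, n_replicates + 1):
        tau_rng = stage_rng(seed, "tau", rep)
        for g in lib.entries:
            tau = tau_rng.uniform(*tau_range)
            wells = simulate_well(
                design,
                fitness,
                g.gene,
                seed=stage_rng(seed, "invitro", rep, g.guide_id).integers(2**31),
                transduction_rate=tau,
            )
            for tp, fc in wells.items():
                rows.append(
                    {
                        "replicate": rep,
                        "guide_id": g.guide_id,
                        "gene": g.gene,
                        "timepoint": tp,
                        "transduction_rate": tau,
                        "n_mchpos_gfppos": fc.mchpos_gfppos,
                        "n_mchpos_gfpneg": fc.mchpos_gfpneg,
                        "n_mchneg_gfppos": fc.mchneg_gfppos,
                        "n_mchneg_gfpneg": fc.mchneg_gfpneg,
                    }
                )
    return pd.DataFrame(rows)


# --- in vivo screen -------------------------------------------------------

# pool/graft category axes: (guide, [cas9+edited, cas9+unedited, cas9-])
_N_CAT = 3
_EDITED, _UNEDITED, _CAS9NEG = 0, 1, 2


@dataclass(frozen=True)
class PopulationState:
    """Integer cell counts per (guide, cas9/edited category) for one compartment."""

    counts: np.ndarray  # shape (n_guides, 3), dtype int64
    guide_ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.guide_ids), _N_CAT):
            raise SimulationError("PopulationState counts shape mismatch")
        if (self.counts < 0).any():
            raise SimulationError("cell counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def gfp_pos(self) -> np.ndarray:
        """Per-guide Cas9+ (GFP+) cell counts."""
        return self.counts[:, _EDITED] + self.counts[:, _UNEDITED]

    @property
    def gfp_neg(self) -> np.ndarray:
        return self.counts[:, _CAS9NEG]

    @property
    def gfp_ratio(self) -> float:
        return float(self.gfp_pos.sum() / self.gfp_neg.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts,
            index=pd.Index(self.guide_ids, name="guide_id"),
            columns=["cas9pos_edited", "cas9pos_unedited", "cas9neg"],
        )


@dataclass(frozen=True)
class InVivoScreen:
    """All stage outputs of one simulated transplantation screen."""

    lib: Library
    design: ScreenDesign
    fitness: FitnessModel
    input_freqs: pd.Series
    pool: PopulationState
    grafts: tuple[PopulationState, ...]
    lineage_populations: dict[str, PopulationState]
    sorted_counts: pd.DataFrame  # samples x guides (cells)
    sample_meta: pd.DataFrame  # lineage, gfp_gate per sample

    @property
    def gfp_ratios(self) -> dict[str, float]:
        """Observed GFP+/GFP- cell ratio per output lineage (pre-sort)."""
        return {lin: pop.gfp_ratio for lin, pop in self.lineage_populations.items()}

    def truth_frame(self) -> pd.DataFrame:
        return self.fitness.truth_frame(self.lib, self.design.lineages)

    def to_count_matrix(
        self, depth: int = 500000, pcr_rho: float = 1e-4, seed: int = 0
    ) -> CountMatrix:
        return simulate_sequencing(
            self.sorted_counts, depth=depth, pcr_rho=pcr_rho, seed=seed, meta=self.sample_meta
        )


def simulate_invivo_screen(
    design: ScreenDesign,
    fitness: FitnessModel,
    lib: Library,
    n_mice: int = 3,
    seed: int = 0,
    input_freqs: pd.Series | None = None,
) -> InVivoScreen:
    """Run the pooled transplantation screen stage by stage.

    Stages: (1) transduced cells from all wells are pooled with per-guide
    input frequencies; (2) each mouse's graft is drawn without replacement
    from the remaining pool (multivariate hypergeometric bottleneck);
    (3) each lineage expands by its expansion factor, edited cells growing
    with ``(2w)**log2(E)``, with Poisson noise; (4) each lineage is sorted
    into GFP+ and GFP- fractions at the lineage's sort depth, again without
    replacement. Cell counts are conserved at every partition.
    """
    if n_mice < 1:
        raise SimulationError("n_mice must be >= 1")
    guide_ids = tuple(lib.guide_ids)
    genes = [g.gene for g in lib.entries]
    n = len(lib)
    if input_freqs is None:
        input_freqs = simulate_input_frequencies(lib, design.input_concentration, seed)
    f = np.asarray(input_freqs.reindex(guide_ids), dtype=float)
    if np.isnan(f).any():
        raise SimulationError("input_freqs must cover every guide in the library")

    phi = design.cas9_fraction
    e = np.array([fitness.e(g) for g in genes])
    # pool of transduced (mCherry+) cells across all wells
    pool_total = int(round(design.cells_per_well * design.transduction_rate)) * n
    probs = np.stack([f * phi * e, f * phi * (1 - e), f * (1 - phi)], axis=1)
    rng_pool = stage_rng(seed, "pool")
    pool_counts = rng_pool.multinomial(pool_total, probs.ravel() / probs.sum()).reshape(n, _N_CAT)
    pool = PopulationState(pool_counts, guide_ids, "pool")

    if design.graft_size * n_mice > pool.total:
        raise SimulationError(
            f"graft of {design.graft_size} x {n_mice} mice exceeds pool of {pool.total} cells"
        )
    remaining = pool_counts.copy().ravel()
    grafts = []
    for m in range(n_mice):
        rng_graft = stage_rng(seed, "graft", m)
        take = rng_graft.multivariate_hypergeometric(
            remaining, design.graft_size, method="marginals"
        )
        remaining = remaining - take
        grafts.append(PopulationState(take.reshape(n, _N_CAT), guide_ids, f"graft_mouse{m + 1}"))

    lineage_pops: dict[str, PopulationState] = {}
    sorted_rows: dict[str, np.ndarray] = {}
    meta_rows = []
    for lin, spec in design.lineages.items():
        d = spec.divisions
        w = np.array([fitness.w(g, lin) for g in genes])
        factor = np.stack(
            [(2.0 * w) ** d, np.full(n, spec.expansion), np.full(n, spec.expansion)], axis=1
        )
        total = np.zeros((n, _N_CAT), dtype=np.int64)
        for m, graft in enumerate(grafts):
            rng_exp = stage_rng(seed, "expand", lin, m)
            total += rng_exp.poisson(graft.counts * factor)
        pop = PopulationState(total, guide_ids, lin)
        lineage_pops[lin] = pop
        for gate, counts in (("pos", pop.gfp_pos), ("neg", pop.gfp_neg)):
            depth = min(spec.sort_depth, int(counts.sum()))
            rng_sort = stage_rng(seed, "sort", lin, gate)
            taken = rng_sort.multivariate_hypergeometric(counts, depth, method="marginals")
            sample_id = f"{lin}_GFP{gate}"
            sorted_rows[sample_id] = taken
            meta_rows.append({"sample": sample_id, "lineage": lin, "gfp_gate": gate})

    sorted_counts = pd.DataFrame.from_dict(sorted_rows, orient="index", columns=list(guide_ids))
    sorted_counts.index.name = "sample"
    sample_meta = pd.DataFrame(meta_rows).set_index("sample")
    return InVivoScreen(
        lib=lib,
        design=design,
        fitness=fitness,
        input_freqs=input_freqs,
        pool=pool,
        grafts=tuple(grafts),
        lineage_populations=lineage_pops,
        sorted_counts=sorted_counts,
        sample_meta=sample_meta,
    )


def simulate_sequencing(
    sorted_counts: pd.DataFrame,
    depth: int = 500000,
    pcr_rho: float = 0.0,
    seed: int = 0,
    meta: pd.DataFrame | None = None,
) -> CountMatrix:
    """Sequence sorted cell counts into barcode read counts.

    Reads per sample are Dirichlet-multinomial: mean proportional to the
    sorted cell frequencies, per-sample concentration ``1/pcr_rho``
    (``pcr_rho=0`` degenerates to a pure multinomial, i.e. no PCR
    overdispersion).
    """
    if depth < 1:
        raise SimulationError("depth must be >= 1")
    if pcr_rho < 0:
        raise SimulationError("pcr_rho must be >= 0")
    rows = {}
    for i, (sample, row) in enumerate(sorted_counts.iterrows()):
        cells = np.asarray(row, dtype=float)
        tot = cells.sum()
        rng = stage_rng(seed, "seq", sample)
        if tot == 0:
            logger.warning("sample %s has no sorted cells; emitting all-zero counts", sample)
            rows[sample] = np.zeros(len(cells), dtype=np.int64)
            continue
        p = cells / tot
        if pcr_rho > 0:
            pos = p > 0
            jittered = np.zeros_like(p)
            jittered[pos] = rng.dirichlet(p[pos] / pcr_rho)
            p = jittered
        rows[sample] = rng.multinomial(depth, p)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=sorted_counts.columns)
    counts.index.name = "sample"
    if meta is None:
        meta = pd.DataFrame(index=counts.index)
    meta = meta.copy()
    meta["total_reads"] = depth
    return CountMatrix(counts.astype(np.int64), meta)


# --- FASTQ emission -------------------------------------------------------

_BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_CODE[_b] = _i
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def write_fastq(
    counts: pd.Series | Mapping[str, int],
    lib: Library,
    path: str | Path,
    layout: ReadLayout | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Path:
    """Emit amplicon reads for one sorted sample as a FASTQ file.

    Each read is ``anchor5 + spacer + anchor3`` padded with 'A' to the layout
    read length, with independent per-base substitution errors at
    ``error_rate`` and constant Phred quality Q37.
    """
    layout = layout or ReadLayout()
    if not 0.0 <= error_rate < 1.0:
        raise SimulationError("error_rate must lie in [0,1)")
    counts = pd.Series(counts)
    spacer_by_id = {g.guide_id: g.spacer for g in lib.entries}
    unknown = [gid for gid in counts.index if gid not in spacer_by_id]
    if unknown:
        raise SimulationError(f"counts reference guides not in library: {unknown[:3]}")
    rng = stage_rng(seed, "fastq", Path(path).name)
    qual = chr(37 + 33) * layout.read_length
    path = Path(path)
    with open(path, "w") as fh:
        read_no = 0
        for gid in lib.guide_ids:
            k = int(counts.get(gid, 0))
            if k < 0:
                raise SimulationError(f"negative read count for {gid}")
            if k == 0:
                continue
            template = layout.anchor5 + spacer_by_id[gid] + layout.anchor3
            template = (template + "A" * layout.read_length)[: layout.read_length]
            codes = _BASE_TO_CODE[np.frombuffer(template.encode(), dtype=np.uint8)]
            reads = np.tile(codes, (k, 1))
            if error_rate > 0:
                hit = rng.random(reads.shape) < error_rate
                shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
                reads = np.where(hit, (reads + shift) % 4, reads)
            seqs = _CODE_TO_BASE[reads]
            for j in range(k):
                read_no += 1
                fh.write(f"@read{read_no}\n{seqs[j].tobytes().decode()}\n+\n{qual}\n")
    return path


def simulate_celltrace(
    design: ScreenDesign,
    fitness: FitnessModel,
    gene: str,
    days: Sequence[float] = (2, 4),
    seed: int = 0,
    n_cells: int = 5000,
    divisions_per_day: float = 1.25,
    editing_delay_divisions: float = 1.5,
    max_division: int = 8,
) -> pd.DataFrame:
    """Division-tracking-dye histograms for transduced and untransduced cells.

    Founder cells are dye-labeled at day 0; a neutral cell divides at
    ``divisions_per_day`` (default tuned so unperturbed cells reach division
    5 by day 4). Edited cells complete an editing-delay number of free
    divisions (1 or 2, split around ``editing_delay_divisions``) before the
    knockout's per-division continuation probability ``max(2w - 1, 0)``
    applies; a cell that fails to continue is arrested at its current
    division. Histograms report the fraction of *final* cells at each dye
    peak (a founder arrested after k divisions contributes ``2**k`` cells),
    separately for mCherry+ (transduced, edited with probability ``e``) and
    mCherry- cells; the mCherry- histogram never depends on the gene.

    Returns a tidy frame with columns day, division, mch_pos, mch_neg.
    """
    if n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    e = fitness.e(gene)
    w = fitness.w(gene, "HSPC")
    q = max(0.0, 2.0 * w - 1.0)
    lo = int(np.floor(editing_delay_divisions))
    frac_hi = editing_delay_divisions - lo
    out = []
    for day in days:
        if day < 0:
            raise SimulationError("days must be >= 0")
        # schedule rng is keyed without the gene so the untransduced (mCherry-)
        # histogram is bit-identical across genes at the same seed
        rng_sched = stage_rng(seed, "celltrace", "schedule", day)
        rng = stage_rng(seed, "celltrace", gene, day)
        n_epochs_f = divisions_per_day * day
        n_lo = int(np.floor(n_epochs_f))
        # per-cell scheduled divisions: floor or ceil of the fractional epoch count
        sched = n_lo + (rng_sched.random(n_cells) < (n_epochs_f - n_lo))
        sched = np.minimum(sched, max_division)

        def _histogram(divs: np.ndarray) -> np.ndarray:
            weights = 2.0**divs
            h = np.bincount(divs.astype(int), weights=weights, minlength=max_division + 1)
            return h / h.sum()

        # mCherry- (and unedited mCherry+) cells divide on schedule
        neutral_divs = sched.astype(float)
        # edited cells: free divisions until editing takes effect, then
        # geometric continuation with probability q, capped by the schedule
        edited_mask = rng.random(n_cells) < e
        delay = lo + (rng.random(n_cells) < frac_hi)
        if q >= 1.0:
            cont = np.full(n_cells, max_division)
        elif q <= 0.0:
            cont = np.zeros(n_cells, dtype=int)
        else:
            cont = rng.geometric(1.0 - q) - 1
        edited_divs = np.minimum(sched, delay + cont)
        mchpos_divs = np.where(edited_mask, edited_divs, sched)
        out.append(
            pd.DataFrame(
                {
                    "day": day,
                    "division": np.arange(max_division + 1),
                    "mch_pos": _histogram(mchpos_divs),
                    "mch_neg": _histogram(neutral_divs),
                }
            )
        )
    return pd.concat(out, ignore_index=True)
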