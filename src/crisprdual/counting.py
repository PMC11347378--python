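"""Barcode quantification: amplicon reads -> per-sample sgRNA count matrix.

Each sequencing read carries the 20-nt spacer between two fixed vector
anchors. Extraction locates the 5' anchor (allowing a bounded number of
substitutions within a small offset window) and takes the following 20-mer;
assignment matches it against the library exactly, then rescues single-
mismatch reads when the nearest library spacer is unique. Ambiguous and
unmatched reads are tallied but excluded from the matrix.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import Library

AMBIGUOUS = "__ambiguous__"


class CountingError(ValueError):
    """Invalid counting input (bad FASTQ, missing metadata, zero library)."""


@dataclass(frozen=True)
class ReadLayout:
    """Amplicon read structure around the spacer barcode.

    Defaults follow the common U6-promoter lentiviral design: the spacer sits
    between the end of the U6 cassette and the start of the guide scaffold.
    Real amplicon designs differ; set anchors per experiment.
    """

    anchor5: str = "TTGTGGAAAGGACGAAACACCG"
    anchor3: str = "GTTTTAGAGCTAGAAATAGCAA"
    spacer_len: int = 20
    max_anchor_mismatch: int = 1
    anchor_search_window: int = 5
    read_length: int = 75

    def __post_init__(self) -> None:
        if not self.anchor5 or not self.anchor3:
            raise CountingError("anchors must be non-empty")
        if self.spacer_len != 20:
            raise CountingError("spacer_len is fixed at 20")
        if self.max_anchor_mismatch < 0 or self.anchor_search_window < 0:
            raise CountingError("mismatch allowance and search window must be >= 0")
        if self.read_length < len(self.anchor5) + self.spacer_len:
            raise CountingError(
                "read_length shorter than anchor5 + spacer; no spacer can be read"
            )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def extract_spacer(read: str, layout: ReadLayout) -> str | None:
    """Return the 20-mer following the 5' anchor, or None if not locatable."""
    read = read.upper()
    la = len(layout.anchor5)
    for off in range(layout.anchor_search_window + 1):
        end = off + la + layout.spacer_len
        if end > len(read):
            break
        if _hamming(read[off : off + la], layout.anchor5) <= layout.max_anchor_mismatch:
            return read[off + la : end]
    return None


class SpacerIndex:
    """Exact + bounded-Hamming lookup of library spacers."""

    def __init__(self, lib: Library):
        if len(lib) == 0:
            raise CountingError("cannot index an empty library")
        self.guide_ids = list(lib.guide_ids)
        self._exact = {g.spacer: g.guide_id for g in lib.entries}
        self._mat = np.frombuffer(
            "".join(lib.spacers).encode(), dtype=np.uint8
        ).reshape(len(lib), -1)

    def assign(self, spacer: str, max_mismatch: int = 1) -> str | None:
        """Return guide_id, :data:`AMBIGUOUS`, or None (unassigned)."""
        hit = self._exact.get(spacer)
        if hit is not None:
            return hit
        if max_mismatch == 0 or len(spacer) != self._mat.shape[1]:
            return None
        q = np.frombuffer(spacer.encode(), dtype=np.uint8)
        dists = (self._mat != q).sum(axis=1)
        dmin = int(dists.min())
        if dmin > max_mismatch:
            return None
        nearest = np.flatnonzero(dists == dmin)
        if len(nearest) > 1:
            return AMBIGUOUS
        return self.guide_ids[int(nearest[0])]


def assign_spacer(spacer: str, lib: Library, max_mismatch: int = 1) -> str | None:
    """One-shot spacer assignment (builds a throwaway index; loop with SpacerIndex)."""
    return SpacerIndex(lib).assign(spacer, max_mismatch)


@dataclass
class CountMatrix:
    """Integer read counts per sample x guide, with per-sample metadata.

    ``counts`` rows are samples, columns the library's canonical guide
    order; ``meta`` is indexed like ``counts`` and carries experiment,
    lineage, gfp_gate, replicate and total_reads where known.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise CountingError("counts must be >= 0")
        if self.meta.empty:
            self.meta = pd.DataFrame(index=self.counts.index)
        if not self.meta.index.equals(self.counts.index):
            self.meta = self.meta.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.columns)

    def select(self, **conditions) -> "CountMatrix":
        """Subset samples by metadata equality, e.g. ``select(lineage="T")``."""
        mask = pd.Series(True, index=self.meta.index)
        for key, value in conditions.items():
            mask &= self.meta[key] == value
        return CountMatrix(self.counts.loc[mask], self.meta.loc[mask])

    def write_tsv(self, path: str | Path, provenance: Mapping[str, object] | None = None) -> None:
        meta_cols = list(self.meta.columns)
        with open(path, "w") as fh:
            for key, value in (provenance or {}).items():
                fh.write(f"# {key}={value}\n")
            fh.write(f"# meta_columns={','.join(meta_cols)}\n")
            table = pd.concat([self.meta, self.counts], axis=1)
            table.index.name = "sample"
            table.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "CountMatrix":
        meta_cols: list[str] = []
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                if line.startswith("# meta_columns="):
                    raw = line.split("=", 1)[1].strip()
                    meta_cols = [c for c in raw.split(",") if c]
                pos = fh.tell()
            table = pd.read_csv(fh, sep="\t", index_col="sample")
        meta = table[meta_cols]
        counts = table.drop(columns=meta_cols).astype(np.int64)
        return cls(counts, meta)


def _open_maybe_gzip(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def count_fastq(
    samples: Sequence[tuple[str | Path, Mapping[str, object]]] | pd.DataFrame,
    lib: Library,
    layout: ReadLayout | None = None,
    max_mismatch: int = 1,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count spacer barcodes in FASTQ files into a CountMatrix.

    ``samples`` is either a sample sheet DataFrame (index = sample id,
    columns including ``file`` plus metadata) or a list of
    ``(fastq_path, metadata_dict)`` pairs where metadata may carry a
    ``sample`` id. Returns the count matrix and per-sample mapping stats
    (reads_total, anchor_found, assigned_exact, assigned_mm1, ambiguous,
    unassigned; the last four partition anchor_found).
    """
    layout = layout or ReadLayout()
    index = SpacerIndex(lib)
    if isinstance(samples, pd.DataFrame):
        if "file" not in samples.columns:
            raise CountingError("sample sheet must have a 'file' column")
        items = [
            (row["file"], {k: v for k, v in row.items() if k != "file"}, sample)
            for sample, row in samples.iterrows()
        ]
    else:
        items = [
            (path, dict(meta), str(dict(meta).pop("sample", Path(path).stem)))
            for path, meta in samples
        ]

    count_rows: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict] = {}
    stat_rows = []
    col_pos = {gid: i for i, gid in enumerate(lib.guide_ids)}
    for path, meta, sample in items:
        row = np.zeros(len(lib), dtype=np.int64)
        stats = dict.fromkeys(
            ("reads_total", "anchor_found", "assigned_exact", "assigned_mm1",
             "ambiguous", "unassigned"),
            0,
        )
        with _open_maybe_gzip(path) as fh:
            it = FastqGeneralIterator(fh)
            record_no = 0
            while True:
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise CountingError(
                        f"{path}: malformed FASTQ record near record {record_no + 1}: {exc}"
                    ) from exc
                record_no += 1
                stats["reads_total"] += 1
                spacer = extract_spacer(seq, layout)
                if spacer is None:
                    continue
                stats["anchor_found"] += 1
                hit = index.assign(spacer, max_mismatch)
                if hit is None:
                    stats["unassigned"] += 1
                elif hit == AMBIGUOUS:
                    stats["ambiguous"] += 1
                else:
                    exact = spacer == lib.entries[col_pos[hit]].spacer
                    stats["assigned_exact" if exact else "assigned_mm1"] += 1
                    row[col_pos[hit]] += 1
        count_rows[sample] = row
        meta_rows[sample] = {**meta, "total_reads": stats["reads_total"]}
        stat_rows.append({"sample": sample, **stats})

    counts = pd.DataFrame.from_dict(count_rows, orient="index", columns=lib.guide_ids)
    counts.index.name = "sample"
    meta = pd.DataFrame.from_dict(meta_rows, orient="index").reindex(counts.index)
    stats_df = pd.DataFrame(stat_rows).set_index("sample")
    return CountMatrix(counts, meta), stats_df


def normalize_cpm(
    cm: CountMatrix | pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Per-library depth normalization to counts per million.

    Entry = (count + a) / sum_guides(count + a) * 1e6 with pseudocount ``a``
    added before normalization, so every downstream log ratio is finite.
    """
    counts = cm.counts if isinstance(cm, CountMatrix) else cm
    if pseudocount < 0:
        raise CountingError("pseudocount must be >= 0")
    padded = counts.astype(float) + pseudocount
    totals = padded.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise CountingError(
            f"sample(s) {bad} have zero total counts and zero pseudocount; "
            "check sequencing QC before normalizing"
        )
    return padded.div(totals, axis=0) * 1e6
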