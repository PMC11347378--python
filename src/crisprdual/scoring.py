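"""Depletion statistics, gene aggregation, hit calling and screen QC.

Two scores, both in log2 units and both internally controlled by the
co-cultured / co-transplanted wild-type (Cas9-, GFP-) cells:

* survival/proliferation score (flow readout, arrayed wells): the GFP+
  fraction within transduced (mCherry+) cells relative to the GFP+ fraction
  within untransduced (mCherry-) cells, log2. Zero means the knockout arm
  kept pace with the wild-type arm; negative means depletion of edited cells.
* abundance score (sequencing readout, pooled screen): log2 fold change of a
  guide's depth-normalized read counts in sorted GFP+ versus GFP- cells of a
  lineage.

A gene is a depletion hit in a context when its guide-mean score falls below
the -1 log2 threshold in every replicate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountMatrix, normalize_cpm
from .library import Library
from .simulate import FlowCounts, ScreenDesign


class ScoringError(ValueError):
    """Invalid scoring input (empty gates, mismatched guide order, ...)."""


def surpro_score(
    fc: FlowCounts,
    pseudocount: float = 0.5,
    mode: str = "fraction_ratio",
) -> float:
    """Survival/proliferation score of one well from four-gate FACS counts.

    ``fraction_ratio`` (default): S = log2(f+ / f-) where f+ and f- are the
    pseudocounted GFP+ fractions within the mCherry+ and mCherry- gates.
    This form is invariant to the well's transduction efficiency, which
    varies 20-60% between wells. ``raw_ratio`` is the literal
    mCherry+GFP+ / mCherry-GFP+ event-count ratio; it inherits that
    per-well variation and is provided for comparison only.
    """
    a = pseudocount
    if fc.mchpos_gfppos + fc.mchpos_gfpneg == 0 or fc.mchneg_gfppos + fc.mchneg_gfpneg == 0:
        raise ScoringError(
            "a mCherry gate recorded no events; increase FACS sampling depth"
        )
    if mode == "fraction_ratio":
        f_pos = (fc.mchpos_gfppos + a) / (fc.mchpos_gfppos + fc.mchpos_gfpneg + 2 * a)
        f_neg = (fc.mchneg_gfppos + a) / (fc.mchneg_gfppos + fc.mchneg_gfpneg + 2 * a)
        return float(np.log2(f_pos / f_neg))
    if mode == "raw_ratio":
        return float(np.log2((fc.mchpos_gfppos + a) / (fc.mchneg_gfppos + a)))
    raise ScoringError(f"unknown surpro mode {mode!r}")


def surpro_table(
    flow: pd.DataFrame,
    pseudocount: float = 0.5,
    mode: str = "fraction_ratio",
    anchor_day2: bool = False,
) -> pd.DataFrame:
    """Per-guide score table from tidy four-gate flow data.

    ``flow`` is the frame produced by ``simulate_invitro_screen`` (or read
    from a flow TSV): columns replicate, guide_id, gene, timepoint and the
    four ``n_*`` gate counts. With ``anchor_day2`` the earliest timepoint's
    score is subtracted within each guide x replicate, removing any
    pre-growth composition offset.
    """
    rows = []
    for r in flow.itertuples(index=False):
        fc = FlowCounts(
            r.n_mchpos_gfppos, r.n_mchpos_gfpneg, r.n_mchneg_gfppos, r.n_mchneg_gfpneg
        )
        rows.append(
            {
                "guide_id": r.guide_id,
                "gene": r.gene,
                "context": f"day{r.timepoint}",
                "timepoint": r.timepoint,
                "replicate": r.replicate,
                "score": surpro_score(fc, pseudocount, mode),
            }
        )
    table = pd.DataFrame(rows)
    if anchor_day2:
        t0 = table["timepoint"].min()
        base = (
            table[table["timepoint"] == t0]
            .set_index(["guide_id", "replicate"])["score"]
        )
        keys = list(zip(table["guide_id"], table["replicate"]))
        table["score"] = table["score"].to_numpy() - base.loc[keys].to_numpy()
    return table.drop(columns="timepoint")


def abundance_score(cpm_gfp_pos: pd.Series, cpm_gfp_neg: pd.Series) -> pd.Series:
    """Per-guide log2 fold change of CPM in sorted GFP+ versus GFP- cells."""
    if not cpm_gfp_pos.index.equals(cpm_gfp_neg.index):
        raise ScoringError("GFP+ and GFP- CPM vectors have mismatched guide order")
    return pd.Series(
        np.log2(cpm_gfp_pos.to_numpy() / cpm_gfp_neg.to_numpy()),
        index=cpm_gfp_pos.index,
        name="score",
    )


def abundance_table(
    cm: CountMatrix,
    lib: Library,
    pseudocount: float = 0.5,
    replicate_col: str | None = None,
) -> pd.DataFrame:
    """Per-guide abundance scores for every lineage (and replicate) in a CountMatrix.

    Samples are paired GFP+/GFP- within each lineage (and replicate when
    ``replicate_col`` is given or present in the metadata).
    """
    meta = cm.meta
    if "lineage" not in meta.columns or "gfp_gate" not in meta.columns:
        raise ScoringError("CountMatrix metadata must carry 'lineage' and 'gfp_gate'")
    if replicate_col is None and "replicate" in meta.columns:
        replicate_col = "replicate"
    cpm = normalize_cpm(cm, pseudocount)
    gene_of = {g.guide_id: g.gene for g in lib.entries}
    group_cols = ["lineage"] + ([replicate_col] if replicate_col else [])
    rows = []
    for keys, sub in meta.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        pos = sub.index[sub["gfp_gate"] == "pos"]
        neg = sub.index[sub["gfp_gate"] == "neg"]
        if len(pos) != 1 or len(neg) != 1:
            raise ScoringError(
                f"group {dict(zip(group_cols, keys))} must have exactly one "
                f"GFP+ and one GFP- sample"
            )
        scores = abundance_score(cpm.loc[pos[0]], cpm.loc[neg[0]])
        for gid, s in scores.items():
            rows.append(
                {
                    "guide_id": gid,
                    "gene": gene_of.get(gid, gid),
                    "context": keys[0],
                    "replicate": keys[1] if replicate_col else 1,
                    "score": s,
                }
            )
    return pd.DataFrame(rows)


def gene_score(score_table: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Aggregate per-guide scores to genes within context x replicate."""
    if method not in ("mean", "median"):
        raise ScoringError(f"unknown aggregation method {method!r}")
    agg = (
        score_table.groupby(["gene", "context", "replicate"], sort=True)["score"]
        .agg(method)
        .reset_index()
    )
    return agg


def call_hits(
    gene_scores: pd.DataFrame,
    threshold: float = -1.0,
    require_all_replicates: bool = True,
    direction: str = "depleted",
) -> pd.DataFrame:
    """Flag genes whose aggregated score crosses the depletion threshold.

    Default rule: depleted hit in a context iff the gene score is below the
    threshold in *every* replicate; the replicate-mean rule is the optional
    mode. ``direction="enriched"`` flips the comparison (score > -threshold).
    """
    if direction not in ("depleted", "enriched"):
        raise ScoringError(f"unknown direction {direction!r}")
    if gene_scores.empty:
        raise ScoringError("gene_scores is empty; need at least one replicate")

    def _below(s: pd.Series) -> pd.Series:
        return s < threshold if direction == "depleted" else s > -threshold

    rows = []
    for (gene, context), sub in gene_scores.groupby(["gene", "context"], sort=True):
        crossed = _below(sub["score"])
        hit = bool(crossed.all()) if require_all_replicates else bool(
            _below(pd.Series([sub["score"].mean()])).iloc[0]
        )
        rows.append(
            {
                "gene": gene,
                "context": context,
                "score": float(sub["score"].mean()),
                "threshold": threshold,
                "hit": hit,
                "direction": direction,
            }
        )
    return pd.DataFrame(rows)


def replicate_correlation(
    scores_a: pd.Series | Mapping[str, float],
    scores_b: pd.Series | Mapping[str, float],
) -> tuple[float, int]:
    """Pearson correlation of two replicate score vectors over matched keys."""
    a = pd.Series(scores_a)
    b = pd.Series(scores_b)
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ScoringError(f"need >= 3 matched keys for a correlation; got {len(common)}")
    r = stats.pearsonr(a.loc[common], b.loc[common]).statistic
    return float(r), int(len(common))


def _rounded_pct(x: float) -> int:
    # compare at the evenness band's printed precision (whole percent)
    return int(np.floor(100.0 * x + 0.5))


@dataclass
class QCReport:
    """Screen-level quality checks; report-only, nothing raises."""

    input_min: float
    input_max: float
    evenness_bounds: tuple[float, float]
    evenness_pass: bool
    evenness_offenders: list[str] = field(default_factory=list)
    recovered_fraction: dict[str, float] = field(default_factory=dict)
    all_guides_recovered: bool = True
    gfp_ratios: dict[str, float] = field(default_factory=dict)
    gfp_ratio_design: float | None = None
    gfp_ratio_pass: bool | None = None
    mcherry_fraction: float | None = None
    mcherry_fraction_design: float | None = None
    mcherry_pass: bool | None = None
    replicate_r: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "input_min": self.input_min,
            "input_max": self.input_max,
            "evenness_bounds": list(self.evenness_bounds),
            "evenness_pass": self.evenness_pass,
            "evenness_offenders": self.evenness_offenders,
            "recovered_fraction": self.recovered_fraction,
            "all_guides_recovered": self.all_guides_recovered,
            "gfp_ratios": self.gfp_ratios,
            "gfp_ratio_design": self.gfp_ratio_design,
            "gfp_ratio_pass": self.gfp_ratio_pass,
            "mcherry_fraction": self.mcherry_fraction,
            "mcherry_fraction_design": self.mcherry_fraction_design,
            "mcherry_pass": self.mcherry_pass,
            "replicate_r": self.replicate_r,
        }

    def to_json(self, **kw) -> str:
        kw.setdefault("indent", 2)
        kw.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kw)


def qc_screen(
    input_freqs: pd.Series,
    cm: CountMatrix | None,
    design: ScreenDesign,
    evenness_bounds: tuple[float, float] = (0.02, 0.09),
    gfp_ratios: Mapping[str, float] | None = None,
    mcherry_fraction: float | None = None,
    ratio_tol: float = 0.25,
    score_table: pd.DataFrame | None = None,
) -> QCReport:
    """Quality-check a screen run against its design.

    Checks: input-library evenness against the expected band (compared at
    the band's printed whole-percent precision), per-sample fraction of
    guides recovered (count > 0), GFP+/GFP- lineage ratios against the
    design mix and the mCherry+ fraction against the design transduction
    rate (each within ``ratio_tol`` relative tolerance, when supplied), and
    per-context replicate Pearson correlations when a score table is given.
    """
    f = pd.Series(input_freqs)
    lo, hi = evenness_bounds
    lo_pct, hi_pct = _rounded_pct(lo), _rounded_pct(hi)
    offenders = [
        str(gid)
        for gid, x in f.items()
        if not lo_pct <= _rounded_pct(float(x)) <= hi_pct
    ]
    report = QCReport(
        input_min=float(f.min()),
        input_max=float(f.max()),
        evenness_bounds=(lo, hi),
        evenness_pass=not offenders,
        evenness_offenders=offenders,
    )
    if cm is not None:
        rec = (cm.counts > 0).mean(axis=1)
        report.recovered_fraction = {str(s): float(x) for s, x in rec.items()}
        report.all_guides_recovered = bool((rec == 1.0).all())
    if gfp_ratios is not None:
        report.gfp_ratios = {str(k): float(v) for k, v in gfp_ratios.items()}
        report.gfp_ratio_design = design.gfp_ratio
        report.gfp_ratio_pass = all(
            abs(v - design.gfp_ratio) <= ratio_tol * design.gfp_ratio
            for v in report.gfp_ratios.values()
        )
    if mcherry_fraction is not None:
        report.mcherry_fraction = float(mcherry_fraction)
        report.mcherry_fraction_design = design.transduction_rate
        report.mcherry_pass = (
            abs(mcherry_fraction - design.transduction_rate)
            <= ratio_tol * design.transduction_rate
        )
    if score_table is not None:
        for context, sub in score_table.groupby("context"):
            reps = sorted(sub["replicate"].unique())
            if len(reps) < 2:
                continue
            a = sub[sub["replicate"] == reps[0]].set_index("guide_id")["score"]
            b = sub[sub["replicate"] == reps[1]].set_index("guide_id")["score"]
            r, _ = replicate_correlation(a, b)
            report.replicate_r[str(context)] = r
    return report
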