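"""Score arithmetic, aggregation, hit calling, correlation and QC."""

import numpy as np
import pandas as pd
import pytest

from crisprdual import (
    CountMatrix,
    FitnessModel,
    FlowCounts,
    ScoringError,
    abundance_score,
    abundance_table,
    call_hits,
    gene_score,
    qc_screen,
    replicate_correlation,
    simulate_input_frequencies,
    simulate_invitro_screen,
    simulate_invivo_screen,
    surpro_score,
    surpro_table,
)
from crisprdual.fixtures import INVITRO_DEPLETION_GENES, invitro_fitness


class TestSurproScore:
    def test_equal_fractions_score_zero(self):
        assert surpro_score(FlowCounts(300, 700, 600, 1400), pseudocount=0) == 0.0

    def test_hand_arithmetic(self):
        s = surpro_score(FlowCounts(100, 900, 500, 500), pseudocount=0)
        assert s == pytest.approx(np.log2(0.1 / 0.5), abs=1e-12)

    def test_pseudocount_keeps_empty_gate_finite(self):
        s = surpro_score(FlowCounts(0, 1000, 500, 500), pseudocount=0.5)
        assert s == pytest.approx(np.log2(0.5 / 500.5), abs=1e-9)
        assert np.isfinite(s)

    def test_fully_empty_gate_errors(self):
        with pytest.raises(ScoringError, match="FACS"):
            surpro_score(FlowCounts(0, 0, 500, 500))

    def test_transduction_invariance_of_fraction_ratio(self):
        # scaling the mCherry+ gate (transduction efficiency) leaves the
        # within-gate fractions, hence the score, unchanged
        base = surpro_score(FlowCounts(100, 400, 500, 500), pseudocount=0)
        for scale in (2, 3, 6):
            scaled = surpro_score(
                FlowCounts(100 * scale, 400 * scale, 500, 500), pseudocount=0
            )
            assert scaled == pytest.approx(base, abs=1e-12)

    def test_raw_ratio_mode_depends_on_transduction(self):
        a = surpro_score(FlowCounts(100, 400, 500, 500), mode="raw_ratio")
        b = surpro_score(FlowCounts(300, 1200, 500, 500), mode="raw_ratio")
        assert a != pytest.approx(b)

    def test_antisymmetric_under_control_role_swap(self):
        # exchanging which gate is treated as knockout vs internal control
        # (mCherry+ <-> mCherry-) negates the score exactly
        fc = FlowCounts(120, 880, 450, 550)
        swapped = FlowCounts(450, 550, 120, 880)
        assert surpro_score(swapped) == pytest.approx(-surpro_score(fc), abs=1e-12)


class TestAbundanceScore:
    def _cpm(self, vals, idx):
        return pd.Series(vals, index=idx, dtype=float)

    def test_identical_vectors_zero(self):
        idx = ["g1", "g2"]
        s = abundance_score(self._cpm([100, 200], idx), self._cpm([100, 200], idx))
        assert (s == 0).all()

    def test_hand_arithmetic(self):
        s = abundance_score(self._cpm([200], ["g"]), self._cpm([800], ["g"]))
        assert s.iloc[0] == pytest.approx(-2.0)

    def test_zero_count_guide_finite_via_cpm_pseudocount(self):
        # raw 0 vs 1000 counts at depth 1e6 over 45 guides, alpha=0.5
        from crisprdual import normalize_cpm

        counts = pd.DataFrame(
            {"g0": [0, 1000], **{f"g{i}": [22000, 22000] for i in range(1, 46)}},
            index=["pos", "neg"],
        )
        cpm = normalize_cpm(counts, pseudocount=0.5)
        s = abundance_score(cpm.loc["pos"], cpm.loc["neg"])
        # plug-in oracle computed directly from the CPM formula
        pos_tot = 0 + 0.5 + 45 * (22000 + 0.5)
        neg_tot = 1000 + 0.5 + 45 * (22000 + 0.5)
        oracle = np.log2((0.5 / pos_tot) / (1000.5 / neg_tot))
        assert s["g0"] == pytest.approx(oracle, abs=1e-12)
        assert np.isfinite(s["g0"]) and s["g0"] < -9

    def test_mismatched_order_errors(self):
        with pytest.raises(ScoringError):
            abundance_score(
                self._cpm([1, 2], ["g1", "g2"]), self._cpm([1, 2], ["g2", "g1"])
            )

    def test_antisymmetric_under_gate_swap(self):
        idx = ["g1", "g2", "g3"]
        a = self._cpm([100, 400, 250], idx)
        b = self._cpm([400, 100, 250], idx)
        assert np.allclose(abundance_score(a, b), -abundance_score(b, a))


class TestGeneAggregation:
    def _table(self, scores, gene="G"):
        return pd.DataFrame(
            {
                "guide_id": [f"{gene}_sg{i}" for i in range(len(scores))],
                "gene": gene,
                "context": "day7",
                "replicate": 1,
                "score": scores,
            }
        )

    def test_mean_of_three_guides(self):
        out = gene_score(self._table([-2.0, -1.5, -1.0]))
        assert out.loc[0, "score"] == pytest.approx(-1.5)

    def test_single_guide_identity(self):
        out = gene_score(self._table([-0.7]))
        assert out.loc[0, "score"] == pytest.approx(-0.7)

    def test_median_option(self):
        out = gene_score(self._table([-3.0, -1.0, 0.0]), method="median")
        assert out.loc[0, "score"] == pytest.approx(-1.0)


class TestCallHits:
    def _genes(self, rep_scores, gene="G", context="day7"):
        return pd.DataFrame(
            {
                "gene": gene,
                "context": context,
                "replicate": range(1, len(rep_scores) + 1),
                "score": rep_scores,
            }
        )

    def test_hit_when_below_in_all_replicates(self):
        hits = call_hits(self._genes([-2.1, -1.8]))
        assert hits.loc[0, "hit"]

    def test_not_hit_when_one_replicate_above(self):
        hits = call_hits(self._genes([-1.2, -0.4]))
        assert not hits.loc[0, "hit"]

    def test_replicate_mean_mode(self):
        hits = call_hits(self._genes([-1.2, -0.9]), require_all_replicates=False)
        assert hits.loc[0, "hit"]  # mean -1.05 < -1

    def test_monotone_in_threshold(self):
        genes = pd.concat(
            [self._genes([-0.5, -0.6], "A"), self._genes([-1.5, -1.4], "B"),
             self._genes([-2.5, -2.6], "C")],
            ignore_index=True,
        )
        hitsets = []
        for thr in (-0.25, -1.0, -2.0, -3.0):
            h = call_hits(genes, threshold=thr)
            hitsets.append(set(h[h.hit].gene))
        for larger, smaller in zip(hitsets, hitsets[1:]):
            assert smaller <= larger

    def test_enrichment_direction(self):
        hits = call_hits(self._genes([1.6, 2.0]), direction="enriched")
        assert hits.loc[0, "hit"]


class TestReplicateCorrelation:
    def test_identity_and_negation(self):
        v = pd.Series([-2.0, 0.1, 1.3, -0.4], index=list("abcd"))
        assert replicate_correlation(v, v)[0] == pytest.approx(1.0)
        assert replicate_correlation(v, -v)[0] == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(8)
        idx = [f"g{i}" for i in range(40)]
        a = pd.Series(rng.normal(size=40), index=idx)
        b = pd.Series(0.6 * a.to_numpy() + rng.normal(size=40), index=idx)
        r, n = replicate_correlation(a, b)
        x, y = a.to_numpy(), b.to_numpy()
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert n == 40
        assert abs(r - oracle) < 1e-12

    def test_too_few_keys_errors(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ScoringError):
            replicate_correlation(a, a)


class TestScreenRecovery:
    def test_planted_depletion_genes_recovered_exactly(self, invitro_lib, invitro_design):
        # end-to-end parameter recovery against the simulator truth
        flow = simulate_invitro_screen(
            invitro_lib, invitro_fitness(), invitro_design, n_replicates=2, seed=42
        )
        table = surpro_table(flow)
        day7 = table[table.context == "day7"]
        hits = call_hits(gene_score(day7))
        called = set(hits[hits.hit].gene)
        assert called == set(INVITRO_DEPLETION_GENES)

    def test_neutral_screen_gene_scores_center_on_zero(self, invitro_lib, invitro_design):
        flow = simulate_invitro_screen(
            invitro_lib, FitnessModel.neutral(), invitro_design, n_replicates=1, seed=7
        )
        genes = gene_score(surpro_table(flow))
        day7 = genes[genes.context == "day7"]["score"]
        se = day7.std(ddof=1) / np.sqrt(len(day7))
        assert abs(day7.mean()) < 3 * se + 0.01
        assert (day7 < -1).mean() < 0.01

    def test_replicates_correlate_when_signal_present(self, invitro_lib, invitro_design):
        flow = simulate_invitro_screen(
            invitro_lib, invitro_fitness(), invitro_design, n_replicates=2, seed=3
        )
        genes = gene_score(surpro_table(flow))
        day7 = genes[genes.context == "day7"]
        a = day7[day7.replicate == 1].set_index("gene")["score"]
        b = day7[day7.replicate == 2].set_index("gene")["score"]
        r, n = replicate_correlation(a, b)
        assert n == 33 and r > 0.9


class TestQc:
    def test_uniform_input_passes_evenness(self, invivo_lib, invivo_design):
        f = pd.Series(1 / 45, index=invivo_lib.guide_ids)
        report = qc_screen(f, None, invivo_design)
        assert report.evenness_pass
        assert report.input_min == report.input_max == pytest.approx(1 / 45)

    def test_dominant_guide_fails_and_is_named(self, invivo_lib, invivo_design):
        f = pd.Series(0.5 / 44, index=invivo_lib.guide_ids)
        f.iloc[0] = 0.5
        report = qc_screen(f, None, invivo_design)
        assert not report.evenness_pass
        assert invivo_lib.guide_ids[0] in report.evenness_offenders

    def test_neutral_invivo_run_recovers_all_guides(self, invivo_lib, invivo_design):
        scr = simulate_invivo_screen(
            invivo_design, FitnessModel.neutral(), invivo_lib, seed=5
        )
        cm = scr.to_count_matrix(seed=5)
        report = qc_screen(
            scr.input_freqs, cm, invivo_design, gfp_ratios=scr.gfp_ratios
        )
        assert report.all_guides_recovered
        assert all(v == 1.0 for v in report.recovered_fraction.values())
        assert report.gfp_ratio_pass

    def test_abundance_table_pairs_gates_per_lineage(self, invivo_lib, invivo_design):
        scr = simulate_invivo_screen(
            invivo_design, FitnessModel.neutral(), invivo_lib, seed=9
        )
        cm = scr.to_count_matrix(seed=9)
        table = abundance_table(cm, invivo_lib)
        assert set(table.context) == set(invivo_design.lineages)
        genes = gene_score(table)
        se = genes["score"].std(ddof=1) / np.sqrt(len(genes))
        assert abs(genes["score"].mean()) < 3 * se + 0.01
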