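"""Generator properties: determinism, packing, planted enrichment, coupling."""

import numpy as np
import pytest

from epiconcord.annotation import DEFAULT_RULES, classify_islands, target_region
from epiconcord.expression import DifferentialExpressionModel, delta_delta_ct
from epiconcord.islands import Island
from epiconcord.simulate import (
    GroundTruth,
    SyntheticConfig,
    generate_genome,
    simulate_all,
    simulate_expression,
    simulate_mark_fragments,
    simulate_qpcr,
)

from conftest import intervals_to_bases


def small_config(**overrides):
    base = dict(
        chrom_length_bp=300_000,
        n_genes=20,
        n_planted_per_mark_direction=3,
        n_de_genes=10,
        seed=7,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestGenome:
    def test_empty_annotation_for_zero_genes(self):
        cfg = small_config(n_genes=0, n_de_genes=0, n_planted_per_mark_direction=0)
        assert len(generate_genome(cfg)) == 0

    def test_same_seed_identical(self):
        cfg = small_config()
        assert generate_genome(cfg) == generate_genome(small_config())

    def test_fifty_genes_pairwise_disjoint_by_exhaustive_check(self):
        cfg = SyntheticConfig(
            chrom_length_bp=1_000_000, n_genes=50,
            gene_length_range_bp=(2_000, 10_000), seed=3,
        )
        genes = list(generate_genome(cfg))
        assert len(genes) == 50
        for i in range(50):
            for j in range(i + 1, 50):
                a, b = genes[i], genes[j]
                assert a.chrom != b.chrom or a.end <= b.start or b.end <= a.start

    def test_infeasible_packing_is_explicit_error(self):
        with pytest.raises(ValueError, match="infeasible packing"):
            generate_genome(
                SyntheticConfig(chrom_length_bp=50_000, n_genes=20,
                                gene_length_range_bp=(4_000, 5_000), seed=0)
            )


class TestMarkFragments:
    def test_null_fold_makes_conditions_exchangeable(self):
        cfg = small_config(enrichment_fold=1.0)
        ann = generate_genome(cfg)
        ctrl, trt, truth = simulate_mark_fragments(ann, cfg, "H3K9ac")
        # no extra fragments are planted anywhere: mean count difference in
        # the recorded regions is driven by background noise only
        diffs = [
            trt.count_in(p.chrom, p.start, p.end) - ctrl.count_in(p.chrom, p.start, p.end)
            for p in truth.planted_islands
        ]
        lam = cfg.background_fragment_rate * cfg.planted_region_bp
        se = np.sqrt(2 * lam / len(diffs))
        assert abs(np.mean(diffs)) < 4 * se

    def test_enrichment_fold_recovered_over_seeds(self):
        """Mean treated/control count ratio in the planted region matches the
        configured fold within 3 SE of the Poisson closed form."""
        fold, rate, width = 5.0, 0.005, 2_000
        t_counts, c_counts = [], []
        for seed in range(200):
            cfg = SyntheticConfig(
                chrom_length_bp=100_000, n_genes=5, n_planted_per_mark_direction=1,
                enrichment_fold=fold, background_fragment_rate=rate,
                n_de_genes=2, seed=seed,
            )
            ann = generate_genome(cfg)
            ctrl, trt, truth = simulate_mark_fragments(ann, cfg, "H3K9me1")
            p = next(q for q in truth.planted_islands if q.direction == "increased")
            t_counts.append(trt.count_in(p.chrom, p.start, p.end))
            c_counts.append(ctrl.count_in(p.chrom, p.start, p.end))
        lam = rate * width
        mean_t, mean_c = np.mean(t_counts), np.mean(c_counts)
        se_t = np.sqrt(fold * lam / 200)
        assert abs(mean_c - lam) < 3 * np.sqrt(lam / 200)
        assert abs(mean_t - fold * lam) < 3 * se_t

    @pytest.mark.parametrize("mark", ["H3K9ac", "H3K9me1", "H3K9me3"])
    def test_planted_regions_satisfy_their_positional_class(self, mark):
        """Cross-module oracle: the annotation stage assigns every planted
        island to its gene under the mark's rule."""
        cfg = small_config()
        ann = generate_genome(cfg)
        _, _, truth = simulate_mark_fragments(ann, cfg, mark)
        islands = [
            Island(p.chrom, p.start, p.end, p.mark, p.direction, 1.0, 1, 1, 0.0)
            for p in truth.planted_islands
        ]
        sets = classify_islands(islands, ann)
        for p in truth.planted_islands:
            assert p.gene_id in sets.genes(p.mark, p.direction)

    def test_determinism(self):
        cfg = small_config()
        ann = generate_genome(cfg)
        a = simulate_mark_fragments(ann, cfg, "H3K9me3")
        b = simulate_mark_fragments(ann, cfg, "H3K9me3")
        assert a[0].records() == b[0].records()
        assert a[1].records() == b[1].records()
        assert a[2].planted_islands == b[2].planted_islands

    def test_empty_annotation_with_planting_is_error(self):
        cfg = small_config(n_genes=0, n_de_genes=0)
        with pytest.raises(ValueError, match="empty annotation"):
            simulate_mark_fragments(generate_genome(cfg), cfg, "H3K9ac")


class TestExpression:
    def _dataset(self, **overrides):
        cfg = small_config(**overrides)
        ann = generate_genome(cfg)
        truth = GroundTruth()
        _, _, slice_ = simulate_mark_fragments(ann, cfg, "H3K9ac")
        truth = truth.merge(slice_)
        matrix = simulate_expression(ann, cfg, truth)
        return cfg, ann, truth, matrix

    def test_same_seed_identical_matrix(self):
        _, _, _, m1 = self._dataset()
        _, _, _, m2 = self._dataset()
        assert m1.values.equals(m2.values)

    def test_planted_de_recovered_by_filter(self):
        cfg, _, truth, matrix = self._dataset()
        res = DifferentialExpressionModel(matrix).fit()
        up_t, down_t = truth.de_genes("up"), truth.de_genes("down")
        assert len(up_t & res.up_genes) / max(len(up_t), 1) >= 0.99
        assert down_t <= res.down_genes

    def test_null_effect_calibrated(self):
        """de_log2fc=0: the p-gate fires at ~alpha on every probe (all null)."""
        hits = total = 0
        for seed in range(30):
            cfg, _, truth, matrix = self._dataset(de_log2fc=0.0, seed=100 + seed)
            table = DifferentialExpressionModel(matrix).fit(alpha=0.05, fc_min=1.0).table
            hits += (table["p_value"] < 0.05).sum()
            total += len(table)
        se = np.sqrt(0.05 * 0.95 / total)
        assert hits / total <= 0.05 + 3 * se

    def test_concordant_genes_are_planted_both_sides(self):
        cfg, _, truth, _ = self._dataset()
        assert truth.concordant_genes  # non-empty under defaults
        for gene, mark, direction in truth.concordant_genes:
            assert gene in truth.mark_genes(mark, direction)
            want = "up" if direction == "increased" else "down"
            assert gene in truth.de_genes(want)

    def test_too_many_de_genes_is_error(self):
        with pytest.raises(ValueError, match="n_de_genes"):
            self._dataset(n_de_genes=21)


class TestQpcr:
    def test_noise_free_closed_form_fold(self):
        """Planted log2fc +2 with slope 1 and zero noise -> fold exactly 4."""
        cfg = small_config(qpcr_noise_sd=0.0)
        truth = GroundTruth(planted_de=[("gX", "up", 2.0)], baseline_log2={"gX": 8.0})
        table = simulate_qpcr(truth, cfg)
        out = delta_delta_ct(table)
        assert out.iloc[0]["fold_change"] == pytest.approx(4.0)
        assert out.iloc[0]["delta_delta_ct"] == pytest.approx(-2.0)

    def test_null_gene_fold_near_one(self):
        cfg = small_config(qpcr_noise_sd=0.0)
        truth = GroundTruth(planted_de=[("gX", "up", 0.0)], baseline_log2={"gX": 8.0})
        out = delta_delta_ct(simulate_qpcr(truth, cfg))
        assert out.iloc[0]["fold_change"] == pytest.approx(1.0)

    def test_array_vs_qpcr_correlation_on_panel(self):
        """20-gene panel with mixed effect sizes, Ct noise 0.1: r >= 0.9."""
        from epiconcord.expression import validation_correlation
        import pandas as pd

        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(20)]
            log2fcs = rng.uniform(-3, 3, 20)
            truth = GroundTruth(
                planted_de=[(g, "up" if f >= 0 else "down", float(f))
                            for g, f in zip(genes, log2fcs)],
                baseline_log2={g: 8.0 for g in genes},
            )
            cfg = small_config(qpcr_noise_sd=0.1, seed=seed)
            folds = delta_delta_ct(simulate_qpcr(truth, cfg))
            de = pd.DataFrame({"gene_id": genes, "log2fc": log2fcs})
            out = validation_correlation(de, dict(zip(folds["gene"], folds["fold_change"])))
            rs.append(out["pearson_r"])
        assert np.mean(rs) >= 0.9

    def test_empty_truth_is_error(self):
        with pytest.raises(ValueError, match="no differential genes"):
            simulate_qpcr(GroundTruth(), small_config())


def test_simulate_all_bundles_consistent_truth():
    cfg = small_config()
    data = simulate_all(cfg)
    marks = {p.mark for p in data.truth.planted_islands}
    assert marks == {"H3K9ac", "H3K9me1", "H3K9me3"}
    assert set(data.tracks) == marks
    de_ids = {g for g, _, _ in data.truth.planted_de}
    assert de_ids <= {g.gene_id for g in data.annotation}
    # qPCR panel covers the planted DE genes
    assert set(data.qpcr.target_genes) == de_ids


def test_config_validation():
    with pytest.raises(ValueError, match="concordant_fraction"):
        SyntheticConfig(concordant_fraction=1.5)
    with pytest.raises(ValueError, match="gene_length_range"):
        SyntheticConfig(chrom_length_bp=5_000, gene_length_range_bp=(2_000, 10_000))
    with pytest.raises(ValueError, match="n_replicates"):
        SyntheticConfig(n_replicates=1)
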