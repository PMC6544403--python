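"""DE filter arithmetic, ANOVA behaviour, ddCt quantification, validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epiconcord.expression import (
    DifferentialExpressionModel,
    ExpressionMatrix,
    QpcrTable,
    delta_delta_ct,
    filter_de,
    signed_fold_change,
    validation_correlation,
)
from epiconcord.expression import test_differential as anova_table  # noqa: renamed to dodge collection


def _matrix(control_rows, treated_rows, probe_gene=None):
    """Build a 2x3+3 ExpressionMatrix from per-probe value lists."""
    n = len(control_rows)
    probes = [f"p{i}" for i in range(n)]
    cols = ["control_1", "control_2", "control_3", "treated_1", "treated_2", "treated_3"]
    values = pd.DataFrame(
        [list(c) + list(t) for c, t in zip(control_rows, treated_rows)],
        index=probes, columns=cols,
    )
    groups = {c: c.rsplit("_", 1)[0] for c in cols}
    pg = probe_gene or {p: p.replace("p", "gene") for p in probes}
    return ExpressionMatrix(values, pg, groups)


class TestAnova:
    def test_identical_groups_no_change(self):
        m = _matrix([[1, 2, 3]], [[1, 2, 3]])
        res = DifferentialExpressionModel(m).fit()
        row = res.table.iloc[0]
        assert row["log2fc"] == 0
        assert not row["passes_filter"]

    def test_closed_form_fold_change(self):
        eps = [0, 1e-9, -1e-9]
        m = _matrix([[1 + e for e in eps]], [[3 + e for e in eps]])
        row = DifferentialExpressionModel(m).fit().table.iloc[0]
        assert row["log2fc"] == pytest.approx(2.0)
        assert row["fold_change_signed"] == pytest.approx(4.0)
        assert row["direction"] == "up"

    def test_degenerate_variance_conventions(self):
        m = _matrix([[1, 1, 1], [1, 1, 1]], [[1, 1, 1], [2, 2, 2]])
        table = anova_table(m)
        assert table.iloc[0]["p_value"] == 1.0  # no variance, no difference
        assert table.iloc[1]["p_value"] == 0.0  # no variance, real difference

    def test_matches_exhaustive_permutation(self, rng):
        """Parametric F p-values track the exhaustive 20-relabeling
        permutation p at n=3+3 on random null data."""
        n_probes = 300
        data = rng.normal(8, 1, size=(n_probes, 6))
        m = _matrix(data[:, :3], data[:, 3:])
        p_param = DifferentialExpressionModel(m).fit().table["p_value"].to_numpy()

        def f_stat(vals, idx):
            a = vals[list(idx)]
            b = np.delete(vals, list(idx))
            num = (a.mean() - b.mean()) ** 2
            den = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / 4
            return np.inf if den == 0 else num / den

        p_perm = np.empty(n_probes)
        combos = list(itertools.combinations(range(6), 3))
        for i in range(n_probes):
            obs = f_stat(data[i], (0, 1, 2))
            stats_all = [f_stat(data[i], c) for c in combos]
            p_perm[i] = np.mean([s >= obs - 1e-12 for s in stats_all])
        from scipy.stats import spearmanr

        assert spearmanr(p_param, p_perm).statistic > 0.9
        assert np.mean(np.abs(p_param - p_perm)) < 0.12

    def test_label_swap_negates_everything(self, rng):
        data = rng.normal(8, 1, size=(50, 6))
        m = _matrix(data[:, :3], data[:, 3:])
        fwd = DifferentialExpressionModel(m, "control", "treated").fit(0.3, 1.1)
        rev = DifferentialExpressionModel(m, "treated", "control").fit(0.3, 1.1)
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"])
        assert fwd.up_genes == rev.down_genes
        assert fwd.down_genes == rev.up_genes


class TestFilter:
    def test_fold_threshold_inclusive_at_1_5(self):
        results = pd.DataFrame(
            {
                "probe_id": ["a", "b"],
                "gene_id": ["ga", "gb"],
                "log2fc": [np.log2(1.5), np.log2(1.49)],
                "p_value": [0.04, 0.04],
            }
        )
        up, down, summary = filter_de(results, alpha=0.05, fc_min=1.5)
        assert up["probe_id"].tolist() == ["a"]  # exactly 1.5 passes
        assert len(down) == 0
        assert summary["probes_up"] == 1

    def test_up_down_disjoint_and_gene_counts(self, rng):
        n = 400
        results = pd.DataFrame(
            {
                "probe_id": [f"p{i}" for i in range(n)],
                "gene_id": [f"g{i // 2}" for i in range(n)],  # 2 probes per gene
                "log2fc": rng.normal(0, 1.2, n),
                "p_value": rng.random(n),
            }
        )
        up, down, summary = filter_de(results)
        assert set(up["probe_id"]).isdisjoint(down["probe_id"])
        assert summary["genes_up"] <= summary["probes_up"]
        assert summary["genes_down"] <= summary["probes_down"]

    def test_power_and_type_one_error(self, rng):
        """30 planted up-probes (log2fc=2, sd=0.25, n=3) among 970 nulls."""
        planted = 30
        nulls = 970
        base = rng.uniform(6, 12, planted + nulls)
        data = base[:, None] + rng.normal(0, 0.25, (planted + nulls, 6))
        data[:planted, 3:] += 2.0
        m = _matrix(data[:, :3], data[:, 3:])
        res = DifferentialExpressionModel(m).fit()
        table = res.table
        recovered = table.iloc[:planted]["passes_filter"].mean()
        assert recovered >= 0.99
        # null pass rate of the p-gate alone, FC gate disabled
        null_p = table.iloc[planted:]["p_value"].to_numpy()
        rate = (null_p < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / nulls)
        assert rate <= 0.05 + 3 * se


def test_signed_fold_change_convention():
    assert signed_fold_change(1.0) == pytest.approx(2.0)
    assert signed_fold_change(-1.0) == pytest.approx(-2.0)
    assert signed_fold_change(0.0) == pytest.approx(1.0)


def _qpcr_frame(gene_ct: dict, n_rep=3):
    rows = []
    for (gene, condition), ct in gene_ct.items():
        for rep in range(1, n_rep + 1):
            c = ct[rep - 1] if isinstance(ct, (list, tuple)) else ct
            rows.append({"gene": gene, "condition": condition, "replicate": rep, "ct": c})
    return pd.DataFrame(rows)


class TestDeltaDeltaCt:
    def _table(self, target_ctrl, target_trt):
        frame = _qpcr_frame(
            {
                ("tgt", "control"): target_ctrl,
                ("tgt", "treated"): target_trt,
                ("actb", "control"): 16.0,
                ("actb", "treated"): 16.0,
                ("r18s", "control"): 10.0,
                ("r18s", "treated"): 10.0,
            }
        )
        return QpcrTable(frame, ["actb", "r18s"])

    def test_no_change_gives_unit_fold(self):
        out = delta_delta_ct(self._table(25.0, 25.0))
        assert out.iloc[0]["delta_delta_ct"] == pytest.approx(0.0)
        assert out.iloc[0]["fold_change"] == pytest.approx(1.0)

    def test_minus_one_ddct_gives_fold_two(self):
        out = delta_delta_ct(self._table(25.0, 24.0))
        assert out.iloc[0]["delta_delta_ct"] == pytest.approx(-1.0)
        assert out.iloc[0]["fold_change"] == pytest.approx(2.0)

    def test_replicate_constant_shift_invariance(self, rng):
        """Adding a constant to every Ct of one replicate cancels out."""
        frame = _qpcr_frame(
            {
                ("tgt", "control"): [25.0, 25.3, 24.8],
                ("tgt", "treated"): [23.0, 23.4, 22.9],
                ("actb", "control"): [16.0, 16.1, 15.9],
                ("actb", "treated"): [16.2, 15.8, 16.0],
                ("r18s", "control"): [10.0, 10.2, 9.9],
                ("r18s", "treated"): [10.1, 9.8, 10.0],
            }
        )
        base = delta_delta_ct(QpcrTable(frame.copy(), ["actb", "r18s"]))
        shifted = frame.copy()
        bump = (shifted["condition"] == "treated") & (shifted["replicate"] == 2)
        shifted.loc[bump, "ct"] += 3.7
        out = delta_delta_ct(QpcrTable(shifted, ["actb", "r18s"]))
        assert out.iloc[0]["delta_delta_ct"] == pytest.approx(
            base.iloc[0]["delta_delta_ct"]
        )

    def test_missing_condition_named(self):
        frame = _qpcr_frame(
            {
                ("tgt", "control"): 25.0,
                ("actb", "control"): 16.0,
                ("actb", "treated"): 16.0,
                ("r18s", "control"): 10.0,
                ("r18s", "treated"): 10.0,
            }
        )
        with pytest.raises(ValueError, match="tgt"):
            delta_delta_ct(QpcrTable(frame, ["actb", "r18s"]))

    def test_nonpositive_ct_rejected(self):
        frame = _qpcr_frame({("tgt", "control"): -1.0, ("actb", "control"): 16.0})
        with pytest.raises(ValueError, match="positive"):
            QpcrTable(frame, ["actb"])


class TestValidationCorrelation:
    def test_identity_gives_perfect_correlation(self):
        de = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "log2fc": [0.5, 1.0, -0.7, 2.0]}
        )
        folds = {g: 2.0 ** fc for g, fc in zip(de["gene_id"], de["log2fc"])}
        out = validation_correlation(de, folds)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["n"] == 4

    def test_anticorrelated_toy(self):
        de = pd.DataFrame({"gene_id": ["a", "b", "c"], "log2fc": [1.0, 2.0, 3.0]})
        folds = {"a": 2.0**-1, "b": 2.0**-2, "c": 2.0**-3}
        out = validation_correlation(de, folds)
        assert out["pearson_r"] == pytest.approx(-1.0)

    def test_too_few_shared_genes(self):
        de = pd.DataFrame({"gene_id": ["a", "b"], "log2fc": [1.0, 2.0]})
        with pytest.raises(ValueError, match="3 shared"):
            validation_correlation(de, {"a": 2.0, "b": 4.0})


def test_matrix_validation():
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0]],
        index=["p0"],
        columns=["control_1", "control_2", "treated_1", "treated_2"],
    )
    groups = {c: c.rsplit("_", 1)[0] for c in values.columns}
    ExpressionMatrix(values, {"p0": "g0"}, groups)  # valid
    with pytest.raises(ValueError, match="missing values"):
        bad = values.copy()
        bad.iloc[0, 0] = np.nan
        ExpressionMatrix(bad, {"p0": "g0"}, groups)
    with pytest.raises(ValueError, match="two groups"):
        ExpressionMatrix(values, {"p0": "g0"}, {c: "x" for c in values.columns})
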