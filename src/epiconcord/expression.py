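"""Differential expression filter and qPCR relative quantification.

The expression side works on an already-normalised log2 intensity matrix
(probes x samples, two groups).  Per probe a one-way ANOVA across the two
groups is computed — with two groups the F statistic is the square of the
pooled-variance t statistic — and probes pass the filter when the
*unadjusted* p-value is below ``alpha`` and the absolute fold change is at
least ``fc_min`` (inclusive at the boundary).

The qPCR side implements relative quantification with two endogenous
controls: per replicate, dCt = Ct_target - mean(Ct of the two controls);
ddCt = mean dCt(treated) - mean dCt(control); fold change = 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "QpcrTable",
    "DifferentialExpressionModel",
    "DEResults",
    "test_differential",
    "filter_de",
    "delta_delta_ct",
    "validation_correlation",
    "signed_fold_change",
]

#: relative slack applied at the inclusive |log2fc| >= log2(fc_min) boundary,
#: so an effect constructed to sit exactly on the threshold is not lost to
#: floating-point rounding of the group means.
_FC_EPS = 1e-12


def signed_fold_change(log2fc: np.ndarray | float) -> np.ndarray | float:
    """Signed linear fold change: +2^log2fc for up, -2^(-log2fc) for down.

    The magnitude is always >= 1; a log2fc of 0 maps to +1.
    """
    l = np.asarray(log2fc, dtype=float)
    out = np.where(l >= 0, np.power(2.0, l), -np.power(2.0, -l))
    return float(out) if np.isscalar(log2fc) else out


class ExpressionMatrix:
    """Probes x samples log2 intensities with a probe->gene map and groups."""

    def __init__(
        self,
        values: pd.DataFrame,
        probe_gene: Mapping[str, str],
        groups: Mapping[str, str],
    ):
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe_ids: {dupes}")
        if values.isna().any().any():
            raise ValueError("missing values must be resolved upstream")
        missing = [s for s in values.columns if s not in groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        labels = pd.Series({s: groups[s] for s in values.columns})
        sizes = labels.value_counts()
        if len(sizes) != 2 or (sizes < 2).any():
            raise ValueError("need exactly two groups with >= 2 samples each")
        unmapped = [p for p in values.index if p not in probe_gene]
        if unmapped:
            raise ValueError(f"probes without gene mapping: {unmapped[:5]}")
        self.values = values.astype(float)
        self.probe_gene = dict(probe_gene)
        self.groups = dict(labels)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    def samples(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]

    @property
    def group_labels(self) -> list[str]:
        return sorted(set(self.groups.values()))


def _anova_two_group(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorised one-way ANOVA p-values for two groups (rows = probes).

    Degenerate rows follow the documented conventions: zero within-group
    variance with a zero between-group difference gives p=1; zero
    within-group variance with a nonzero difference gives p=0.
    """
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    ssw = ((a - m1[:, None]) ** 2).sum(axis=1) + ((b - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    diff = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        sp2 = ssw / df
        f_stat = diff**2 / (sp2 * (1 / n1 + 1 / n2))
        p = stats.f.sf(f_stat, 1, df)
    degenerate = ssw == 0
    p = np.where(degenerate & (diff == 0), 1.0, p)
    p = np.where(degenerate & (diff != 0), 0.0, p)
    return p


class DifferentialExpressionModel:
    """Two-group differential expression on a log2 matrix.

    ``fit`` computes per-probe ANOVA p-values, log2 fold changes and the
    signed-fold filter verdicts; thresholds live on ``fit`` so one model can
    be re-filtered cheaply.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        control_label: str = "control",
        treated_label: str = "treated",
    ):
        for lbl in (control_label, treated_label):
            if lbl not in matrix.group_labels:
                raise ValueError(f"group {lbl!r} absent from matrix (has {matrix.group_labels})")
        self.matrix = matrix
        self.control_label = control_label
        self.treated_label = treated_label

    def fit(self, alpha: float = 0.05, fc_min: float = 1.5) -> "DEResults":
        if fc_min < 1:
            raise ValueError("fc_min must be >= 1")
        m = self.matrix
        a = m.values[m.samples(self.control_label)].to_numpy()
        b = m.values[m.samples(self.treated_label)].to_numpy()
        p = _anova_two_group(a, b)
        log2fc = b.mean(axis=1) - a.mean(axis=1)
        passes = (p < alpha) & (np.abs(log2fc) >= np.log2(fc_min) - _FC_EPS)
        table = pd.DataFrame(
            {
                "probe_id": m.probe_ids,
                "gene_id": [m.probe_gene[pid] for pid in m.probe_ids],
                "mean_log2_control": a.mean(axis=1),
                "mean_log2_treated": b.mean(axis=1),
                "log2fc": log2fc,
                "fold_change_signed": signed_fold_change(log2fc),
                "p_value": p,
                "passes_filter": passes,
            }
        )
        table["direction"] = np.where(
            ~passes, "none", np.where(log2fc > 0, "up", "down")
        )
        # a zero log2fc cannot pass the fold gate (fc_min >= 1), so 'up'/'down'
        # always carries a definite sign
        return DEResults(model=self, table=table, alpha=alpha, fc_min=fc_min)


@dataclass
class DEResults:
    """Per-probe differential expression results plus filtered gene sets."""

    model: DifferentialExpressionModel
    table: pd.DataFrame
    alpha: float
    fc_min: float

    def _probes(self, direction: str) -> pd.DataFrame:
        return self.table[self.table["direction"] == direction]

    @property
    def up_probes(self) -> list[str]:
        return self._probes("up")["probe_id"].tolist()

    @property
    def down_probes(self) -> list[str]:
        return self._probes("down")["probe_id"].tolist()

    @property
    def up_genes(self) -> set[str]:
        return set(self._probes("up")["gene_id"])

    @property
    def down_genes(self) -> set[str]:
        return set(self._probes("down")["gene_id"])

    def gene_log2fc(self) -> pd.Series:
        """Gene-level log2 fold change: mean over the gene's probes."""
        return self.table.groupby("gene_id")["log2fc"].mean()

    def summary(self) -> str:
        n_pass = int(self.table["passes_filter"].sum())
        lines = [
            "Differential expression filter",
            f"  probes tested: {len(self.table)}  "
            f"(alpha={self.alpha}, |FC|>={self.fc_min})",
            f"  passing probes: {n_pass} "
            f"({len(self.up_probes)} up, {len(self.down_probes)} down)",
            f"  passing genes: {len(self.up_genes | self.down_genes)} "
            f"({len(self.up_genes)} up, {len(self.down_genes)} down)",
        ]
        return "\n".join(lines)


def test_differential(
    matrix: ExpressionMatrix,
    control_label: str = "control",
    treated_label: str = "treated",
) -> pd.DataFrame:
    """Per-probe ANOVA and fold changes without applying any filter."""
    res = DifferentialExpressionModel(matrix, control_label, treated_label).fit()
    return res.table.drop(columns=["passes_filter", "direction"])


def filter_de(
    results: pd.DataFrame, alpha: float = 0.05, fc_min: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Partition DE results into up/down tables; summary at probe and gene level."""
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    passes = (results["p_value"] < alpha) & (
        np.abs(results["log2fc"]) >= np.log2(fc_min) - _FC_EPS
    )
    up = results[passes & (results["log2fc"] > 0)]
    down = results[passes & (results["log2fc"] < 0)]
    summary = {
        "probes_up": len(up),
        "probes_down": len(down),
        "genes_up": up["gene_id"].nunique(),
        "genes_down": down["gene_id"].nunique(),
    }
    return up, down, summary


class QpcrTable:
    """Tidy Ct table: one row per (gene, condition, replicate).

    ``control_genes`` names the endogenous-control rows (e.g. a beta-actin-
    like and an 18S-like gene); their Ct values must be present for every
    (condition, replicate) so that per-replicate normalisation is defined.
    """

    REQUIRED = ("gene", "condition", "replicate", "ct")

    def __init__(self, data: pd.DataFrame, control_genes: Sequence[str]):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns: {missing}")
        if (data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if len(control_genes) < 1:
            raise ValueError("at least one endogenous control gene required")
        absent = [g for g in control_genes if g not in set(data["gene"])]
        if absent:
            raise ValueError(f"endogenous controls absent from table: {absent}")
        self.data = data.reset_index(drop=True)
        self.control_genes = list(control_genes)

    @property
    def target_genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - set(self.control_genes))

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.data["condition"]))


def delta_delta_ct(table: QpcrTable, control_condition: str = "control") -> pd.DataFrame:
    """Relative quantification against the endogenous controls.

    Per replicate, dCt = Ct_gene - mean(Ct of the control genes for that
    condition and replicate).  ddCt = mean dCt(treated) - mean dCt(control
    condition), and fold = 2^(-ddCt).  Adding a constant to every Ct of a
    replicate leaves dCt — hence ddCt — unchanged.
    """
    data = table.data
    if control_condition not in table.conditions:
        raise ValueError(f"condition {control_condition!r} not present")
    ctrl_ct = (
        data[data["gene"].isin(table.control_genes)]
        .groupby(["condition", "replicate"])["ct"]
        .mean()
    )
    rows = []
    for gene in table.target_genes:
        sub = data[data["gene"] == gene]
        present = set(sub["condition"])
        if not set(table.conditions) <= present:
            missing = sorted(set(table.conditions) - present)
            raise ValueError(f"gene {gene!r} missing in condition(s): {missing}")
        dct = sub.set_index(["condition", "replicate"])["ct"] - ctrl_ct
        if dct.isna().any():
            bad = dct[dct.isna()].index.tolist()
            raise ValueError(f"gene {gene!r}: no endogenous-control Ct for {bad}")
        by_cond = dct.groupby(level="condition").mean()
        treated_conds = [c for c in table.conditions if c != control_condition]
        for cond in treated_conds:
            ddct = by_cond[cond] - by_cond[control_condition]
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "delta_ct_control": by_cond[control_condition],
                    "delta_ct_treated": by_cond[cond],
                    "delta_delta_ct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                }
            )
    return pd.DataFrame(rows).sort_values(["gene", "condition"]).reset_index(drop=True)


def validation_correlation(
    de_table: pd.DataFrame, qpcr_folds: Mapping[str, float]
) -> dict[str, float]:
    """Correlate array log2 fold changes with log2 qPCR fold changes.

    ``de_table`` needs ``gene_id`` and ``log2fc`` columns (probe-level rows
    are averaged per gene); ``qpcr_folds`` maps gene -> linear fold change.
    Returns Pearson r, Spearman rho and the number of genes compared.
    """
    array_fc = de_table.groupby("gene_id")["log2fc"].mean()
    shared = sorted(set(array_fc.index) & set(qpcr_folds))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    x = array_fc[shared].to_numpy()
    y = np.log2([qpcr_folds[g] for g in shared])
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return {
        "n": len(shared),
        "pearson_r": float(pearson.statistic),
        "pearson_p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
    }
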