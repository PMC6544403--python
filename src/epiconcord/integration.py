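"""Multi-mark overlap, concordance with expression, and over-representation.

``venn3`` partitions three gene sets into the seven exclusive regions of a
three-set Venn diagram.  ``integrate_with_expression`` intersects each
(mark, island direction) gene set with the up- and down-regulated gene sets
into concordance classes — e.g. genes with increased H3K9ac that are also
up-regulated, the classic activation signature.  ``ora`` is a generic
hypergeometric over-representation test against GMT-style collections with
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import MarkGeneSets, audit_direction_conflicts

__all__ = ["venn3", "integrate_with_expression", "ora", "IntegrationReport"]

#: region keys: membership flags for (A, B, C), '1' = inside
VENN_REGIONS = ("100", "010", "001", "110", "101", "011", "111")


def venn3(a: set, b: set, c: set) -> dict[str, set]:
    """Exact partition of A|B|C into the 7 exclusive Venn regions.

    Keys are membership strings over (A, B, C): '110' is (A & B) - C, etc.
    Region sizes always sum to |A | B | C|.
    """
    return {
        "100": a - b - c,
        "010": b - a - c,
        "001": c - a - b,
        "110": (a & b) - c,
        "101": (a & c) - b,
        "011": (b & c) - a,
        "111": a & b & c,
    }


@dataclass
class IntegrationReport:
    """Venn counts over marks plus mark x expression concordance classes."""

    marks: list[str]
    venn_increased: dict[str, list[str]]
    venn_decreased: dict[str, list[str]]
    #: (mark, island direction, DE direction) -> sorted gene list
    concordance: dict[tuple[str, str, str], list[str]]
    #: per mark: genes in both increased and decreased sets that are also DE
    direction_conflicts_in_de: dict[str, list[str]]
    counts: dict[str, int] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def concordant(self, mark: str, island_direction: str, de_direction: str) -> list[str]:
        return self.concordance.get((mark, island_direction, de_direction), [])

    def to_dict(self) -> dict:
        return {
            "marks": self.marks,
            "venn_increased": {k: sorted(v) for k, v in self.venn_increased.items()},
            "venn_decreased": {k: sorted(v) for k, v in self.venn_decreased.items()},
            "concordance": {
                f"{m}|{idir}|{ddir}": genes for (m, idir, ddir), genes in sorted(self.concordance.items())
            },
            "direction_conflicts_in_de": self.direction_conflicts_in_de,
            "counts": self.counts,
            "parameters": self.parameters,
        }

    def summary(self) -> str:
        lines = [f"Integration over marks: {', '.join(self.marks)}"]
        for (m, idir, ddir), genes in sorted(self.concordance.items()):
            lines.append(f"  {m} {idir} islands & {ddir}-regulated genes: {len(genes)}")
        conflicts = {m: v for m, v in self.direction_conflicts_in_de.items() if v}
        lines.append(
            "  genes in both directions of one mark and DE: "
            + (", ".join(f"{m}:{len(v)}" for m, v in conflicts.items()) if conflicts else "none")
        )
        return "\n".join(lines)


def integrate_with_expression(
    mark_sets: MarkGeneSets,
    de_up: set[str],
    de_down: set[str],
    parameters: Mapping | None = None,
) -> IntegrationReport:
    """Cross every (mark, island direction) gene set with the DE gene sets.

    ``de_up`` and ``de_down`` must be disjoint.  Also reports, per mark, any
    gene carried by both increased and decreased islands that intersects the
    DE genes — the sanity check expected to come back empty when candidates
    are built as one merged per-mark universe.
    """
    clash = de_up & de_down
    if clash:
        raise ValueError(f"de_up and de_down overlap: {sorted(clash)[:5]}")
    marks = sorted(mark_sets.marks)
    venns = {}
    for direction in ("increased", "decreased"):
        sets3 = [mark_sets.genes(m, direction) for m in marks[:3]]
        while len(sets3) < 3:
            sets3.append(set())
        venns[direction] = {k: sorted(v) for k, v in venn3(*sets3).items()}
    de_sets = {"up": de_up, "down": de_down}
    concordance = {
        (m, idir, ddir): sorted(mark_sets.genes(m, idir) & de_genes)
        for m in marks
        for idir in ("increased", "decreased")
        for ddir, de_genes in de_sets.items()
    }
    all_de = de_up | de_down
    conflicts = {
        m: sorted(set(genes) & all_de)
        for m, genes in audit_direction_conflicts(mark_sets).items()
    }
    counts = {f"{m}|{idir}|{ddir}": len(g) for (m, idir, ddir), g in concordance.items()}
    counts["de_up"] = len(de_up)
    counts["de_down"] = len(de_down)
    return IntegrationReport(
        marks=marks,
        venn_increased=venns["increased"],
        venn_decreased=venns["decreased"],
        concordance=concordance,
        direction_conflicts_in_de=conflicts,
        counts=counts,
        parameters=dict(parameters or {}),
    )


def ora(
    query: set[str],
    universe: set[str],
    collections: Mapping[str, tuple[str, set[str]]],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term set.

    Each term set is intersected with ``universe`` before testing; the
    upper-tail p-value is P(X >= k) for k = |query & term| when drawing
    |query| genes from a universe containing |term| successes.  An overlap
    of zero gives p = 1.  Benjamini-Hochberg q-values are computed across
    all tested terms; rows are sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    m_univ, n_query = len(universe), len(query)
    rows = []
    for term_id, (term_name, members) in collections.items():
        in_univ = members & universe
        k = len(query & in_univ)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(in_univ), n_query))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "overlap_count": k,
                "set_size": len(in_univ),
                "universe_size": m_univ,
                "query_size": n_query,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table = table.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table
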