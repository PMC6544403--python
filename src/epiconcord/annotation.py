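"""Positional classification of differential islands against gene models.

Each histone mark carries its own positional rule describing where on a gene
an enrichment island must fall to be attributed to that gene:

* H3K9ac  — within +/-1000 bp of the TSS but *not* inside the gene body
  (the promoter flank, with the body subtracted from the window);
* H3K9me1 — anywhere inside the gene body;
* H3K9me3 — inside a -2000/+200 bp window around the TSS *or* inside the
  gene body (the union of the two; an intersection reading would leave an
  almost empty region and is rejected).

Coordinates are 0-based half-open throughout.  The TSS of a '+' gene is
``start``; for a '-' gene it is ``end - 1`` (the last covered base), so the
promoter window of a minus-strand gene extends to the *right* of the span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "GeneAnnotation",
    "PositionalRule",
    "MarkGeneSets",
    "DEFAULT_RULES",
    "POSITIONAL_CLASS",
    "canonical_mark",
    "target_region",
    "classify_islands",
    "audit_direction_conflicts",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene: transcript span and strand, 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Transcription start site: first covered base in 5'->3' orientation."""
        return self.start if self.strand == "+" else self.end - 1


class GeneAnnotation:
    """An ordered collection of non-conflicting gene models."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: list[GeneModel] = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_ids: {', '.join(dupes)}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    @property
    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes}

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneAnnotation) and self.genes == other.genes


@dataclass(frozen=True)
class PositionalRule:
    """Mark-specific admissible region relative to a gene.

    ``promoter_upstream_bp``/``promoter_downstream_bp`` define a strand-aware
    window around the TSS (``None`` disables the promoter component);
    ``include_gene_body`` unions the transcript span into the region while
    ``exclude_gene_body`` subtracts it from the promoter window.
    """

    mark: str
    promoter_upstream_bp: int | None = None
    promoter_downstream_bp: int | None = None
    include_gene_body: bool = False
    exclude_gene_body: bool = False
    min_overlap_bp: int = 1

    def __post_init__(self) -> None:
        if self.include_gene_body and self.exclude_gene_body:
            raise ValueError("include_gene_body and exclude_gene_body are mutually exclusive")
        if self.min_overlap_bp < 1:
            raise ValueError("min_overlap_bp must be >= 1")
        if (self.promoter_upstream_bp is None) != (self.promoter_downstream_bp is None):
            raise ValueError("promoter upstream/downstream must be set together")
        if self.promoter_upstream_bp is None and not (
            self.include_gene_body or self.exclude_gene_body
        ):
            raise ValueError("rule defines no region at all")


POSITIONAL_CLASS: dict[str, str] = {
    "H3K9ac": "tss_flank_excluding_body",
    "H3K9me1": "gene_body",
    "H3K9me3": "tss_window_or_body",
}

DEFAULT_RULES: dict[str, PositionalRule] = {
    "H3K9ac": PositionalRule(
        mark="H3K9ac",
        promoter_upstream_bp=1000,
        promoter_downstream_bp=1000,
        exclude_gene_body=True,
    ),
    "H3K9me1": PositionalRule(mark="H3K9me1", include_gene_body=True),
    "H3K9me3": PositionalRule(
        mark="H3K9me3",
        promoter_upstream_bp=2000,
        promoter_downstream_bp=200,
        include_gene_body=True,
    ),
}

_MARK_ALIASES = {"h3k9ac": "H3K9ac", "h3k9me": "H3K9me1", "h3k9me1": "H3K9me1", "h3k9me3": "H3K9me3"}


def canonical_mark(mark: str) -> str:
    """Normalise a mark token ('H3K9me' is accepted as monomethylation)."""
    try:
        return _MARK_ALIASES[mark.lower()]
    except KeyError:
        raise ValueError(f"unknown mark token: {mark!r}") from None


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Canonicalise to sorted, disjoint, non-empty intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _subtract(intervals: list[tuple[int, int]], hole: tuple[int, int]) -> list[tuple[int, int]]:
    hs, he = hole
    out: list[tuple[int, int]] = []
    for s, e in intervals:
        if e <= hs or s >= he:
            out.append((s, e))
            continue
        if s < hs:
            out.append((s, hs))
        if e > he:
            out.append((he, e))
    return out


def target_region(gene: GeneModel, rule: PositionalRule) -> list[tuple[int, int]]:
    """Admissible genomic region for ``rule`` around ``gene``.

    Returns sorted disjoint 0-based half-open intervals, clipped at 0.
    The promoter window covers ``upstream`` bases 5' of the TSS through
    ``downstream`` bases 3' of it, TSS base included.
    """
    parts: list[tuple[int, int]] = []
    if rule.promoter_upstream_bp is not None:
        up, down = rule.promoter_upstream_bp, rule.promoter_downstream_bp
        if gene.strand == "+":
            win = (gene.tss - up, gene.tss + down + 1)
        else:  # upstream is to the right of a minus-strand TSS
            win = (gene.tss - down, gene.tss + up + 1)
        parts.append(win)
    if rule.include_gene_body:
        parts.append((gene.start, gene.end))
    region = _merge(parts)
    if rule.exclude_gene_body:
        region = _subtract(region, (gene.start, gene.end))
    return _merge([(max(0, s), e) for s, e in region])


@dataclass
class MarkGeneSets:
    """Per (mark, direction) gene sets with island-level provenance."""

    sets: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    #: gene_id -> list of (chrom, start, end, mark, direction) contributing islands
    provenance: dict[str, list[tuple[str, int, int, str, str]]] = field(default_factory=dict)

    def genes(self, mark: str, direction: str) -> set[str]:
        return self.sets.get((canonical_mark(mark), direction), set())

    def add(self, mark: str, direction: str, gene_id: str, island: tuple[str, int, int]) -> None:
        self.sets.setdefault((mark, direction), set()).add(gene_id)
        self.provenance.setdefault(gene_id, []).append((*island, mark, direction))

    @property
    def marks(self) -> set[str]:
        return {m for m, _ in self.sets}


def _region_trees(
    annotation: GeneAnnotation, rule: PositionalRule
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        for s, e in target_region(gene, rule):
            trees.setdefault(gene.chrom, IntervalTree()).addi(s, e, gene.gene_id)
    return trees


def classify_islands(
    islands: Sequence,
    annotation: GeneAnnotation,
    rules: Mapping[str, PositionalRule] | None = None,
) -> MarkGeneSets:
    """Assign islands to genes under each mark's positional rule.

    An island is assigned to a gene iff its overlap with the gene's target
    region totals at least ``rule.min_overlap_bp``; one island may hit several
    genes and every hit is recorded.  Islands on chromosomes absent from the
    annotation are left unassigned with a warning.
    """
    rules = dict(DEFAULT_RULES) if rules is None else dict(rules)
    out = MarkGeneSets()
    known_chroms = annotation.chroms
    tree_cache: dict[str, dict[str, IntervalTree]] = {}
    for isl in islands:
        mark = canonical_mark(isl.mark)
        if mark not in rules:
            raise ValueError(f"no positional rule for mark {mark}")
        if isl.chrom not in known_chroms:
            warnings.warn(
                f"island {isl.chrom}:{isl.start}-{isl.end} on chromosome absent from "
                "annotation; left unassigned",
                stacklevel=2,
            )
            continue
        if mark not in tree_cache:
            tree_cache[mark] = _region_trees(annotation, rules[mark])
        tree = tree_cache[mark].get(isl.chrom)
        if tree is None:
            continue
        overlap_by_gene: dict[str, int] = {}
        for hit in tree.overlap(isl.start, isl.end):
            bp = min(isl.end, hit.end) - max(isl.start, hit.begin)
            overlap_by_gene[hit.data] = overlap_by_gene.get(hit.data, 0) + bp
        for gene_id, bp in overlap_by_gene.items():
            if bp >= rules[mark].min_overlap_bp:
                out.add(mark, isl.direction, gene_id, (isl.chrom, isl.start, isl.end))
    return out


def audit_direction_conflicts(sets: MarkGeneSets) -> dict[str, list[str]]:
    """Per mark, genes appearing in both the increased and the decreased set.

    With candidates built as one merged per-mark universe these lists are
    empty by construction unless *distinct* opposite-direction islands hit
    the same gene; the report enumerates any such gene explicitly.
    """
    report: dict[str, list[str]] = {}
    for mark in sorted(sets.marks):
        both = sets.genes(mark, "increased") & sets.genes(mark, "decreased")
        report[mark] = sorted(both)
    return report
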