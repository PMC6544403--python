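"""Synthetic genomes, fragment tracks, expression and qPCR with planted truth.

Every downstream stage of the pipeline is testable against this module: it
emits toy chromosomes with non-overlapping genes, two-condition ChIP
fragment tracks with planted treated-vs-control enrichment differences at
genes of known positional class, triplicate log2 expression with planted
fold changes, and Ct tables linearly coupled to the planted expression —
all with an explicit :class:`GroundTruth` ledger for parameter-recovery
tests.

Design choices: fragments are intervals, not reads (no sequence content is
generated — nothing downstream needs bases); the background is a homogeneous
Poisson process, the simplest null under which the island caller's
background model is well specified; concordance between planted marks and
planted differential expression is an explicit gene list, not an emergent
property, so recovery is assertable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np

from .annotation import (
    DEFAULT_RULES,
    POSITIONAL_CLASS,
    GeneAnnotation,
    GeneModel,
    canonical_mark,
    target_region,
)
from .expression import ExpressionMatrix, QpcrTable
from .islands import FragmentTrack

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PlantedIsland",
    "SyntheticDataset",
    "MARKS",
    "generate_genome",
    "simulate_mark_fragments",
    "simulate_expression",
    "simulate_qpcr",
    "simulate_all",
]

MARKS = ("H3K9ac", "H3K9me1", "H3K9me3")

# substream tags so each stage draws from an independent, reproducible stream
_TAG_GENOME = 0
_TAG_MARK = {"H3K9ac": 11, "H3K9me1": 12, "H3K9me3": 13}
_TAG_EXPRESSION = 2
_TAG_QPCR = 3

#: endogenous-control genes emitted by the qPCR simulator, with their
#: condition-invariant expected Ct values
ENDOGENOUS_CONTROLS = {"ACTB_ctrl": 16.0, "RNA18S_ctrl": 10.0}


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic experiment.

    Defaults are desk-scale: one 2-Mb chromosome carrying 100 genes of
    2-10 kb, ChIP fragments of 200-500 bp at 0.005 fragments/bp background,
    5-fold planted enrichment, biological triplicates with log2 noise sd
    0.25 and planted |log2FC| = 2.
    """

    n_chroms: int = 1
    chrom_length_bp: int = 2_000_000
    n_genes: int = 100
    gene_length_range_bp: tuple[int, int] = (2_000, 10_000)
    n_planted_per_mark_direction: int = 10
    enrichment_fold: float = 5.0
    background_fragment_rate: float = 0.005
    fragment_length_range_bp: tuple[int, int] = (200, 500)
    planted_region_bp: int = 2_000
    n_de_genes: int = 40
    de_log2fc: float = 2.0
    expr_noise_sd: float = 0.25
    n_replicates: int = 3
    multi_probe_fraction: float = 0.2
    concordant_fraction: float = 0.75
    qpcr_slope: float = 1.0
    qpcr_intercept: float = 30.0
    qpcr_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_chroms", "chrom_length_bp", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n_genes", "n_planted_per_mark_direction", "n_de_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lmin, lmax = self.gene_length_range_bp
        if not (0 < lmin <= lmax):
            raise ValueError("gene_length_range_bp must satisfy 0 < min <= max")
        if lmax > self.chrom_length_bp:
            raise ValueError("gene_length_range_bp does not fit inside the chromosome")
        fmin, fmax = self.fragment_length_range_bp
        if not (0 < fmin <= fmax <= self.chrom_length_bp):
            raise ValueError("invalid fragment_length_range_bp")
        if not 0.0 <= self.concordant_fraction <= 1.0:
            raise ValueError("concordant_fraction must be in [0, 1]")
        if not 0.0 <= self.multi_probe_fraction <= 1.0:
            raise ValueError("multi_probe_fraction must be in [0, 1]")
        if self.enrichment_fold <= 0:
            raise ValueError("enrichment_fold must be > 0")
        if self.background_fragment_rate <= 0:
            raise ValueError("background_fragment_rate must be > 0")
        if self.expr_noise_sd <= 0 or self.qpcr_noise_sd < 0:
            raise ValueError("noise sds must be positive (qPCR noise may be 0)")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)}

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class PlantedIsland:
    chrom: str
    start: int
    end: int
    mark: str
    direction: str
    positional_class: str
    gene_id: str


@dataclass
class GroundTruth:
    """Ledger of everything planted, for parameter-recovery assertions."""

    planted_islands: list[PlantedIsland] = field(default_factory=list)
    #: (gene_id, direction 'up'|'down', log2fc)
    planted_de: list[tuple[str, str, float]] = field(default_factory=list)
    #: (gene_id, mark, island direction) pairs planted to be concordant
    concordant_genes: list[tuple[str, str, str]] = field(default_factory=list)
    #: per-gene baseline log2 expression, shared by expression and qPCR sims
    baseline_log2: dict[str, float] = field(default_factory=dict)

    def mark_genes(self, mark: str, direction: str) -> set[str]:
        mark = canonical_mark(mark)
        return {
            p.gene_id
            for p in self.planted_islands
            if p.mark == mark and p.direction == direction
        }

    def de_genes(self, direction: str) -> set[str]:
        return {g for g, d, _ in self.planted_de if d == direction}

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            planted_islands=self.planted_islands + other.planted_islands,
            planted_de=self.planted_de + other.planted_de,
            concordant_genes=self.concordant_genes + other.concordant_genes,
            baseline_log2={**self.baseline_log2, **other.baseline_log2},
        )

    def to_dict(self) -> dict:
        return {
            "planted_islands": [asdict(p) for p in self.planted_islands],
            "planted_de": [list(t) for t in self.planted_de],
            "concordant_genes": [list(t) for t in self.concordant_genes],
            "baseline_log2": self.baseline_log2,
        }


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, tag])


def generate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> GeneAnnotation:
    """Place non-overlapping genes uniformly with random strand.

    Genes are split as evenly as possible across chromosomes.  Within a
    chromosome, lengths are drawn uniformly from ``gene_length_range_bp``
    and starts are laid out by drawing the inter-gene free space uniformly,
    which guarantees pairwise disjointness.  Infeasible packing (total gene
    length exceeding the chromosome) is an explicit error.
    """
    rng = _rng(config, _TAG_GENOME) if rng is None else rng
    lmin, lmax = config.gene_length_range_bp
    genes: list[GeneModel] = []
    per_chrom = np.full(config.n_chroms, config.n_genes // config.n_chroms)
    per_chrom[: config.n_genes % config.n_chroms] += 1
    gid = 0
    for i, k in enumerate(per_chrom):
        chrom = f"chr{i + 1}"
        if k == 0:
            continue
        lengths = rng.integers(lmin, lmax + 1, size=int(k))
        free = config.chrom_length_bp - int(lengths.sum())
        if free < 0:
            raise ValueError(
                f"infeasible packing on {chrom}: {k} genes totalling {lengths.sum()} bp "
                f"exceed chromosome length {config.chrom_length_bp}"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=int(k)))
        starts = cuts + np.concatenate([[0], np.cumsum(lengths[:-1])])
        strands = rng.choice(np.array(["+", "-"]), size=int(k))
        for s, l, st in zip(starts, lengths, strands):
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:04d}",
                    chrom=chrom,
                    start=int(s),
                    end=int(s + l),
                    strand=str(st),
                )
            )
            gid += 1
    return GeneAnnotation(genes)


def _planting_interval(
    gene: GeneModel, mark: str, chrom_size: int, config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Pick a planted region anchored on the gene's target region.

    The widest admissible interval is the anchor; the planted region has
    width ``planted_region_bp`` and always covers (or sits inside) the
    anchor, so classification under the mark's rule is guaranteed while the
    region may — as real broad domains do — spill beyond the admissible
    window.  Returns None when the gene has no usable anchor inside the
    chromosome (e.g. a gene at the chromosome edge), in which case the
    caller resamples another gene.
    """
    intervals = [
        (s, min(e, chrom_size))
        for s, e in target_region(gene, DEFAULT_RULES[mark])
        if s < min(e, chrom_size)
    ]
    fmin, _ = config.fragment_length_range_bp
    intervals = [iv for iv in intervals if iv[1] - iv[0] >= fmin]
    if not intervals:
        return None
    widths = [e - s for s, e in intervals]
    s, e = intervals[int(np.argmax(widths))]
    width = config.planted_region_bp
    if e - s >= width:
        offset = int(rng.integers(0, (e - s) - width + 1))
        return s + offset, s + offset + width
    # anchor narrower than the planted width: extend symmetrically, clipped
    centre = (s + e) // 2
    start = max(0, min(centre - width // 2, chrom_size - width))
    return start, min(start + width, chrom_size)


def _fragments_from_midpoints(
    mids: np.ndarray, chrom: str, chrom_size: int, config: SyntheticConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, int]]:
    fmin, fmax = config.fragment_length_range_bp
    lengths = rng.integers(fmin, fmax + 1, size=mids.size)
    starts = mids - lengths // 2
    starts = np.clip(starts, 0, np.maximum(chrom_size - lengths, 0))
    return [(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]


def simulate_mark_fragments(
    annotation: GeneAnnotation,
    config: SyntheticConfig,
    mark: str,
    rng: np.random.Generator | None = None,
) -> tuple[FragmentTrack, FragmentTrack, GroundTruth]:
    """Two-condition fragment tracks with planted differential regions.

    Background fragments follow a homogeneous Poisson process at
    ``background_fragment_rate`` per bp in both conditions.  For each of
    ``n_planted_per_mark_direction`` genes per direction, a region
    satisfying the mark's positional class receives extra fragments in one
    condition so that its rate there equals ``enrichment_fold`` times the
    background — in the treated track for 'increased' islands and in the
    control track for 'decreased' ones.  Genes for which the class is
    geometrically impossible (chromosome edges) are skipped and another is
    drawn; running out of feasible genes is an explicit error.
    """
    mark = canonical_mark(mark)
    rng = _rng(config, _TAG_MARK[mark]) if rng is None else rng
    chrom_sizes = config.chrom_sizes()
    n_plant = config.n_planted_per_mark_direction
    if n_plant > 0 and len(annotation) == 0:
        raise ValueError("cannot plant islands into an empty annotation")

    truth = GroundTruth()
    planted: list[tuple[tuple[int, int], str, str]] = []  # (region, chrom, direction)
    if n_plant > 0:
        order = rng.permutation(len(annotation))
        chosen: list[tuple[GeneModel, tuple[int, int]]] = []
        for idx in order:
            gene = annotation.genes[int(idx)]
            iv = _planting_interval(gene, mark, chrom_sizes[gene.chrom], config, rng)
            if iv is not None:
                chosen.append((gene, iv))
            if len(chosen) == 2 * n_plant:
                break
        if len(chosen) < 2 * n_plant:
            raise ValueError(
                f"could not place {2 * n_plant} {mark} regions: only {len(chosen)} "
                "genes admit the positional class"
            )
        for j, (gene, (s, e)) in enumerate(chosen):
            direction = "increased" if j < n_plant else "decreased"
            truth.planted_islands.append(
                PlantedIsland(
                    chrom=gene.chrom,
                    start=s,
                    end=e,
                    mark=mark,
                    direction=direction,
                    positional_class=POSITIONAL_CLASS[mark],
                    gene_id=gene.gene_id,
                )
            )
            planted.append(((s, e), gene.chrom, direction))

    rate = config.background_fragment_rate
    tracks: dict[str, list[tuple[str, int, int]]] = {"control": [], "treated": []}
    for condition in ("control", "treated"):
        frags = tracks[condition]
        for chrom, size in chrom_sizes.items():
            n_bg = int(rng.poisson(rate * size))
            mids = rng.integers(0, size, size=n_bg)
            frags.extend(_fragments_from_midpoints(mids, chrom, size, config, rng))
        boosted = "treated" if condition == "treated" else "control"
        for (s, e), chrom, direction in planted:
            wants = (direction == "increased" and condition == "treated") or (
                direction == "decreased" and condition == "control"
            )
            if not wants:
                continue
            extra = int(rng.poisson((config.enrichment_fold - 1.0) * rate * (e - s)))
            mids = rng.integers(s, e, size=extra)
            frags.extend(
                _fragments_from_midpoints(mids, chrom, chrom_sizes[chrom], config, rng)
            )
    return FragmentTrack(tracks["control"]), FragmentTrack(tracks["treated"]), truth


def simulate_expression(
    annotation: GeneAnnotation,
    config: SyntheticConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """Triplicate log2 expression with planted fold changes.

    A ``concordant_fraction`` of each mark's planted genes is made
    differentially expressed in the matching direction (increased -> up,
    decreased -> down); the differential set is then filled with unplanted
    genes (direction up, mirroring the treatment's predominantly activating
    effect) until ``n_de_genes`` genes carry a shift of ``de_log2fc`` on the
    log2 scale.  ``multi_probe_fraction`` of genes get a second probe, so
    gene-level counts can be strictly smaller than probe-level counts.
    The planted DE list and the concordant gene list are recorded onto
    ``truth`` in place.
    """
    rng = _rng(config, _TAG_EXPRESSION) if rng is None else rng
    if config.n_de_genes > len(annotation):
        raise ValueError(
            f"n_de_genes={config.n_de_genes} exceeds number of genes ({len(annotation)})"
        )
    gene_ids = [g.gene_id for g in annotation.genes]

    de_direction: dict[str, str] = {}
    marks = sorted({p.mark for p in truth.planted_islands})
    for mark in marks:
        for mark_dir, dedir in (("increased", "up"), ("decreased", "down")):
            genes = sorted(truth.mark_genes(mark, mark_dir))
            k = int(round(config.concordant_fraction * len(genes)))
            picked = 0
            for g in genes:
                if picked == k:
                    break
                if de_direction.get(g, dedir) != dedir:
                    continue  # already DE the other way via another mark
                if g not in de_direction:
                    picked += 1
                de_direction[g] = dedir
                truth.concordant_genes.append((g, mark, mark_dir))
    planted_any_mark = {p.gene_id for p in truth.planted_islands}
    fillers = [g for g in gene_ids if g not in de_direction and g not in planted_any_mark]
    n_fill = max(0, config.n_de_genes - len(de_direction))
    if n_fill > len(fillers):
        raise ValueError("not enough unplanted genes to fill the differential set")
    for g in list(rng.choice(fillers, size=n_fill, replace=False)) if n_fill else []:
        de_direction[str(g)] = "up"
    for g in sorted(de_direction):
        sign = 1.0 if de_direction[g] == "up" else -1.0
        truth.planted_de.append((g, de_direction[g], sign * abs(config.de_log2fc)))

    probes: list[tuple[str, str]] = []
    for g in gene_ids:
        probes.append((f"{g}.p1", g))
        if rng.random() < config.multi_probe_fraction:
            probes.append((f"{g}.p2", g))
    baselines = rng.uniform(6.0, 12.0, size=len(probes))
    for (pid, g), b in zip(probes, baselines):
        truth.baseline_log2.setdefault(g, float(b))

    n_rep = config.n_replicates
    samples = [f"control_{i + 1}" for i in range(n_rep)] + [
        f"treated_{i + 1}" for i in range(n_rep)
    ]
    values = baselines[:, None] + rng.normal(0.0, config.expr_noise_sd, (len(probes), 2 * n_rep))
    shift = {g: (1.0 if d == "up" else -1.0) * abs(config.de_log2fc) for g, d in de_direction.items()}
    for i, (pid, g) in enumerate(probes):
        if g in shift:
            values[i, n_rep:] += shift[g]

    import pandas as pd

    frame = pd.DataFrame(values, index=[p for p, _ in probes], columns=samples)
    groups = {s: ("control" if s.startswith("control") else "treated") for s in samples}
    return ExpressionMatrix(frame, dict(probes), groups)


def simulate_qpcr(
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> QpcrTable:
    """Ct tables linearly coupled to the planted log2 expression.

    Ct = intercept - slope * log2(expression) + Gaussian noise, so a planted
    log2FC of +x yields a ddCt of -slope*x and a fold change of 2^(slope*x)
    in the noise-free limit.  Two endogenous-control genes are emitted with
    condition-invariant expected Ct.
    """
    rng = _rng(config, _TAG_QPCR) if rng is None else rng
    if not truth.planted_de:
        raise ValueError("ground truth contains no differential genes to assay")
    import pandas as pd

    rows = []
    n_rep = config.n_replicates
    for gene, _direction, log2fc in truth.planted_de:
        base = truth.baseline_log2.get(gene)
        if base is None:
            base = float(rng.uniform(6.0, 12.0))
            truth.baseline_log2[gene] = base
        for condition in ("control", "treated"):
            expr = base + (log2fc if condition == "treated" else 0.0)
            for rep in range(1, n_rep + 1):
                ct = config.qpcr_intercept - config.qpcr_slope * expr
                if config.qpcr_noise_sd > 0:
                    ct += rng.normal(0.0, config.qpcr_noise_sd)
                rows.append({"gene": gene, "condition": condition, "replicate": rep, "ct": ct})
    for ctrl_gene, ctrl_ct in ENDOGENOUS_CONTROLS.items():
        for condition in ("control", "treated"):
            for rep in range(1, n_rep + 1):
                ct = ctrl_ct
                if config.qpcr_noise_sd > 0:
                    ct += rng.normal(0.0, config.qpcr_noise_sd)
                rows.append(
                    {"gene": ctrl_gene, "condition": condition, "replicate": rep, "ct": ct}
                )
    return QpcrTable(pd.DataFrame(rows), control_genes=list(ENDOGENOUS_CONTROLS))


@dataclass
class SyntheticDataset:
    """Everything one synthetic experiment produces, plus its truth ledger."""

    config: SyntheticConfig
    annotation: GeneAnnotation
    tracks: dict[str, tuple[FragmentTrack, FragmentTrack]]  # mark -> (control, treated)
    truth: GroundTruth
    expression: ExpressionMatrix
    qpcr: QpcrTable

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return self.config.chrom_sizes()


def simulate_all(config: SyntheticConfig, marks: tuple[str, ...] = MARKS) -> SyntheticDataset:
    """Run the full generator: genome, per-mark tracks, expression, qPCR."""
    annotation = generate_genome(config)
    truth = GroundTruth()
    tracks: dict[str, tuple[FragmentTrack, FragmentTrack]] = {}
    for mark in marks:
        control, treated, slice_ = simulate_mark_fragments(annotation, config, mark)
        tracks[canonical_mark(mark)] = (control, treated)
        truth = truth.merge(slice_)
    expression = simulate_expression(annotation, config, truth)
    qpcr = simulate_qpcr(truth, config)
    return SyntheticDataset(
        config=config,
        annotation=annotation,
        tracks=tracks,
        truth=truth,
        expression=expression,
        qpcr=qpcr,
    )
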