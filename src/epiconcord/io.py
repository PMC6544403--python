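"""Readers and writers for the pipeline's plain-text interchange formats.

Conventions: BED-style 0-based half-open coordinates everywhere; readers
reject malformed input with the offending line number rather than repairing
it; writers are deterministic (stable ordering) and stamp each file with a
comment header naming the producing stage and a hash of its parameters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneAnnotation, GeneModel, MarkGeneSets, canonical_mark
from .expression import ExpressionMatrix, QpcrTable
from .integration import IntegrationReport
from .islands import FragmentTrack, Island

__all__ = [
    "read_bed_fragments",
    "read_bed_islands",
    "read_chrom_sizes",
    "read_gene_table",
    "read_expression",
    "read_group_map",
    "read_qpcr",
    "read_gmt",
    "write_bed_fragments",
    "write_islands",
    "write_gene_table",
    "write_expression",
    "write_qpcr",
    "read_gene_sets",
    "write_gene_sets",
    "write_integration_report",
    "param_hash",
    "stage_header",
]


def param_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping, for provenance headers."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.md5(blob).hexdigest()[:12]


def stage_header(stage: str, params: Mapping | None = None) -> str:
    return f"# epiconcord stage={stage} params={param_hash(params or {})}\n"


def _data_lines(path: str | Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_coords(fields: Sequence[str], lineno: int, path) -> tuple[str, int, int]:
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: non-numeric coordinates {fields[1]!r}, {fields[2]!r}"
        ) from None
    if start >= end:
        raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
    if start < 0:
        raise ValueError(f"{path}:{lineno}: negative start {start}")
    return chrom, start, end


def read_bed_fragments(path: str | Path) -> FragmentTrack:
    """BED3 -> fragment track; malformed lines are reported with line numbers."""
    frags = []
    for lineno, line in _data_lines(path):
        frags.append(_parse_coords(line.split("\t"), lineno, path))
    return FragmentTrack(frags)


def read_bed_islands(path: str | Path) -> list[Island]:
    """BED6+3 (name=mark:direction, score, strand, counts, q) -> islands."""
    islands = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        chrom, start, end = _parse_coords(fields, lineno, path)
        if len(fields) < 9:
            raise ValueError(f"{path}:{lineno}: island records need 9 fields, got {len(fields)}")
        name = fields[3]
        if ":" not in name:
            raise ValueError(f"{path}:{lineno}: island name must be mark:direction, got {name!r}")
        mark_tok, direction = name.split(":", 1)
        try:
            mark = canonical_mark(mark_tok)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unknown mark token {mark_tok!r}") from None
        if direction not in ("increased", "decreased"):
            raise ValueError(f"{path}:{lineno}: bad direction {direction!r}")
        try:
            islands.append(
                Island(
                    chrom=chrom,
                    start=start,
                    end=end,
                    mark=mark,
                    direction=direction,
                    score=float(fields[4]),
                    treated_count=int(fields[6]),
                    control_count=int(fields[7]),
                    q_value=float(fields[8]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return islands


def write_bed_fragments(path: str | Path, track: FragmentTrack, stage: str = "simulate",
                        params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(stage_header(stage, params))
        for chrom, start, end in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_islands(path: str | Path, islands: Iterable[Island], stage: str = "call-islands",
                  params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(stage_header(stage, params))
        for i in sorted(islands, key=lambda x: (x.chrom, x.start, x.end, x.direction)):
            fh.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{i.mark}:{i.direction}\t{i.score:.4f}\t.\t"
                f"{i.treated_count}\t{i.control_count}\t{i.q_value:.6g}\n"
            )


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
        chrom = fields[0]
        try:
            size = int(fields[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric size {fields[1]!r}") from None
        if chrom in sizes:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        sizes[chrom] = size
    return sizes


_GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def read_gene_table(path: str | Path) -> GeneAnnotation:
    """Minimal gene table TSV: gene_id, chrom, start, end, strand (0-based)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene_id(s): {dupes}")
    genes = [
        GeneModel(r.gene_id, r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]
    return GeneAnnotation(genes)


def write_gene_table(path: str | Path, annotation: GeneAnnotation,
                     stage: str = "simulate", params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(stage_header(stage, params))
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in annotation:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV sample -> group label."""
    groups: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>group'")
        if fields[0] in groups:
            raise ValueError(f"{path}:{lineno}: duplicate sample {fields[0]!r}")
        groups[fields[0]] = fields[1]
    return groups


def read_expression(path: str | Path, groups: Mapping[str, str] | None = None) -> ExpressionMatrix:
    """Expression TSV: probe_id, gene_id, then sample columns of log2 values.

    When ``groups`` is omitted, sample names must start with their group
    label followed by '_' (as the simulator writes them).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "gene_id": str})
    for col in ("probe_id", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if df["probe_id"].duplicated().any():
        dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"{path}: duplicate probe_id(s): {dupes}")
    sample_cols = [c for c in df.columns if c not in ("probe_id", "gene_id")]
    if groups is None:
        groups = {s: s.rsplit("_", 1)[0] for s in sample_cols}
    values = df.set_index("probe_id")[sample_cols]
    probe_gene = dict(zip(df["probe_id"], df["gene_id"]))
    return ExpressionMatrix(values, probe_gene, dict(groups))


def write_expression(path: str | Path, matrix: ExpressionMatrix,
                     stage: str = "simulate", params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(stage_header(stage, params))
        samples = list(matrix.values.columns)
        fh.write("\t".join(["probe_id", "gene_id"] + samples) + "\n")
        for pid in matrix.probe_ids:
            row = matrix.values.loc[pid]
            vals = "\t".join(f"{row[s]:.6f}" for s in samples)
            fh.write(f"{pid}\t{matrix.probe_gene[pid]}\t{vals}\n")


def read_qpcr(path: str | Path) -> QpcrTable:
    """qPCR TSV: gene, condition, replicate, ct, is_control (0/1)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene": str, "condition": str})
    for col in ("gene", "condition", "replicate", "ct", "is_control"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    controls = sorted(df.loc[df["is_control"] == 1, "gene"].unique())
    if not controls:
        raise ValueError(f"{path}: no endogenous-control rows flagged (is_control=1)")
    return QpcrTable(df.drop(columns=["is_control"]), control_genes=controls)


def write_qpcr(path: str | Path, table: QpcrTable,
               stage: str = "simulate", params: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(stage_header(stage, params))
        fh.write("gene\tcondition\treplicate\tct\tis_control\n")
        data = table.data.sort_values(["gene", "condition", "replicate"], kind="stable")
        for r in data.itertuples():
            flag = 1 if r.gene in table.control_genes else 0
            fh.write(f"{r.gene}\t{r.condition}\t{r.replicate}\t{r.ct:.6f}\t{flag}\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, set[str]]]:
    """GMT: term_id <TAB> description <TAB> member genes...

    A two-field line (a term with no members) is retained as an empty set,
    with a warning.
    """
    collections: dict[str, tuple[str, set[str]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: GMT lines need at least term and description")
        term, desc = fields[0], fields[1]
        if term in collections:
            raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
        members = {f for f in fields[2:] if f}
        if not members:
            warnings.warn(f"{path}:{lineno}: term {term!r} has no members", stacklevel=2)
        collections[term] = (desc, members)
    return collections


def write_gene_sets(path: str | Path, sets: MarkGeneSets,
                    stage: str = "annotate", params: Mapping | None = None) -> None:
    """Per-(mark, direction) gene lists with contributing-island provenance."""
    with open(path, "w") as fh:
        fh.write(stage_header(stage, params))
        fh.write("mark\tdirection\tgene_id\tislands\n")
        for (mark, direction), genes in sorted(sets.sets.items()):
            for g in sorted(genes):
                prov = ";".join(
                    f"{c}:{s}-{e}"
                    for c, s, e, m, d in sorted(sets.provenance.get(g, []))
                    if m == mark and d == direction
                )
                fh.write(f"{mark}\t{direction}\t{g}\t{prov}\n")


def read_gene_sets(path: str | Path) -> MarkGeneSets:
    """Inverse of :func:`write_gene_sets` (provenance coordinates included)."""
    sets = MarkGeneSets()
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    for col in ("mark", "direction", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    for r in df.itertuples():
        mark = canonical_mark(r.mark)
        prov = getattr(r, "islands", "")
        if prov:
            for token in prov.split(";"):
                chrom, span = token.rsplit(":", 1)
                s, e = span.split("-")
                sets.add(mark, r.direction, r.gene_id, (chrom, int(s), int(e)))
        else:
            sets.sets.setdefault((mark, r.direction), set()).add(r.gene_id)
    return sets


def write_integration_report(path: str | Path, report: IntegrationReport,
                             stage: str = "integrate", params: Mapping | None = None) -> None:
    payload = {
        "producer": {"stage": stage, "params_hash": param_hash(params or {})},
        "report": report.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
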