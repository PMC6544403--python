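"""End-to-end orchestration: simulate -> islands -> annotate -> DE -> integrate.

The pipeline mirrors the analysis narrative of an HDAC-inhibitor study:
differential islands are called per histone mark, classified positionally
against the gene models, intersected with the differential expression gene
sets into concordance classes, and optionally tested for gene-set
over-representation.  Every stage logs its parameters and record counts to
stderr; outputs are deterministic given an identical configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as eio
from .annotation import DEFAULT_RULES, PositionalRule, classify_islands, audit_direction_conflicts
from .expression import (
    DifferentialExpressionModel,
    delta_delta_ct,
    validation_correlation,
)
from .integration import integrate_with_expression, ora
from .islands import DifferentialIslandModel
from .simulate import MARKS, SyntheticConfig, simulate_all

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("epiconcord")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Run configuration: synthetic generation plus per-stage parameters."""

    outdir: str = "epiconcord_run"
    seed: int = 0
    simulate: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    marks: tuple[str, ...] = MARKS
    # island caller
    window_size_bp: int = 200
    gap_windows: int = 3
    window_p: float = 0.01
    fdr: float = 0.01
    # DE filter
    alpha: float = 0.05
    fc_min: float = 1.5
    # positional rules (mark -> rule); defaults are the per-mark criteria
    rules: dict = field(default_factory=lambda: dict(DEFAULT_RULES))
    # optional external inputs (used when simulate=False)
    annotation_path: str | None = None
    chrom_sizes_path: str | None = None
    track_paths: dict = field(default_factory=dict)  # mark -> {control, treated}
    expression_path: str | None = None
    qpcr_path: str | None = None
    gmt_path: str | None = None
    write_fragments: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SyntheticConfig(**raw.pop("synthetic", {}))
        rules_raw = raw.pop("rules", None)
        cfg = cls(synthetic=synth, **raw)
        if rules_raw:
            rules = dict(DEFAULT_RULES)
            for mark, spec in rules_raw.items():
                rules[mark] = PositionalRule(mark=mark, **spec)
            cfg.rules = rules
        return cfg

    def validate(self) -> None:
        """Fail fast, before any compute."""
        if not self.simulate:
            required = {
                "annotation_path": self.annotation_path,
                "chrom_sizes_path": self.chrom_sizes_path,
            }
            for name, p in required.items():
                if p is None:
                    raise PipelineError(f"validation: {name} required when simulate=false")
                if not Path(p).exists():
                    raise PipelineError(f"validation: {name}={p} does not exist")
            if self.expression_path is None:
                raise PipelineError(
                    "validation: expression_path required for integration when simulate=false"
                )
            for mark in self.marks:
                paths = self.track_paths.get(mark)
                if not paths:
                    raise PipelineError(f"validation: no track paths for mark {mark}")
                for key in ("control", "treated"):
                    if key not in paths or not Path(paths[key]).exists():
                        raise PipelineError(
                            f"validation: missing {key} track for mark {mark}"
                        )
        for p in (self.expression_path, self.qpcr_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"validation: input path {p} does not exist")
        if not 0 < self.alpha < 1 or self.fc_min < 1:
            raise PipelineError("validation: alpha must be in (0,1) and fc_min >= 1")

    def params_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("outdir")  # output location is not an analysis parameter
        d["synthetic"] = self.synthetic.to_dict()
        d["rules"] = {
            m: dataclasses.asdict(r) for m, r in sorted(self.rules.items())
        }
        return d


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the machine-readable run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.params_dict()
    manifest: dict = {"parameters_hash": eio.param_hash(params), "stages": {}}

    # -- inputs ------------------------------------------------------------
    if config.simulate:
        synth = dataclasses.replace(config.synthetic, seed=config.seed)
        logger.info("[simulate] seed=%d genome=%d bp x %d, %d genes",
                    synth.seed, synth.chrom_length_bp, synth.n_chroms, synth.n_genes)
        data = _stage("simulate")(simulate_all)(synth, marks=config.marks)
        annotation, chrom_sizes = data.annotation, data.chrom_sizes
        tracks = data.tracks
        expression, qpcr, truth = data.expression, data.qpcr, data.truth
        eio.write_gene_table(outdir / "annotation.tsv", annotation, "simulate", params)
        eio.write_expression(outdir / "expression.tsv", expression, "simulate", params)
        eio.write_qpcr(outdir / "qpcr.tsv", qpcr, "simulate", params)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
        if config.write_fragments:
            for mark, (ctrl, trt) in tracks.items():
                eio.write_bed_fragments(outdir / f"fragments_{mark}_control.bed", ctrl,
                                        "simulate", params)
                eio.write_bed_fragments(outdir / f"fragments_{mark}_treated.bed", trt,
                                        "simulate", params)
        manifest["stages"]["simulate"] = {
            "genes": len(annotation),
            "planted_islands": len(truth.planted_islands),
            "planted_de": len(truth.planted_de),
        }
    else:
        annotation = _stage("read-inputs")(eio.read_gene_table)(config.annotation_path)
        chrom_sizes = eio.read_chrom_sizes(config.chrom_sizes_path)
        tracks = {
            mark: (
                eio.read_bed_fragments(config.track_paths[mark]["control"]),
                eio.read_bed_fragments(config.track_paths[mark]["treated"]),
            )
            for mark in config.marks
        }
        expression = eio.read_expression(config.expression_path)
        qpcr = eio.read_qpcr(config.qpcr_path) if config.qpcr_path else None
        manifest["stages"]["read-inputs"] = {"genes": len(annotation)}

    # -- differential islands per mark ------------------------------------
    all_islands = []
    for mark in config.marks:
        control, treated = tracks[mark]
        model = DifferentialIslandModel(
            treated, control, chrom_sizes, mark=mark,
            window_size_bp=config.window_size_bp, gap_windows=config.gap_windows,
            window_p=config.window_p, fdr=config.fdr,
        )
        res = _stage(f"call-islands[{mark}]")(model.fit)()
        logger.info("[call-islands] %s: %d candidates, %d significant",
                    mark, len(res.candidates), len(res.islands))
        eio.write_islands(outdir / f"islands_{mark}.bed", res.islands, "call-islands", params)
        all_islands.extend(res.islands)
        manifest["stages"][f"call-islands[{mark}]"] = {
            "candidates": len(res.candidates),
            "islands": len(res.islands),
        }

    # -- positional annotation ---------------------------------------------
    sets = _stage("annotate")(classify_islands)(all_islands, annotation, config.rules)
    conflicts = audit_direction_conflicts(sets)
    logger.info("[annotate] gene sets: %s",
                {f"{m}:{d}": len(g) for (m, d), g in sorted(sets.sets.items())})
    eio.write_gene_sets(outdir / "gene_sets.tsv", sets, "annotate", params)
    manifest["stages"]["annotate"] = {
        "assigned_genes": len(sets.provenance),
        "direction_conflicts": {m: len(v) for m, v in conflicts.items()},
    }

    # -- differential expression -------------------------------------------
    de_model = DifferentialExpressionModel(expression)
    de_res = _stage("de")(de_model.fit)(alpha=config.alpha, fc_min=config.fc_min)
    logger.info("[de] %s", de_res.summary().replace("\n", " | "))
    de_table = de_res.table.sort_values("probe_id", kind="stable")
    with open(outdir / "de_table.tsv", "w") as fh:
        fh.write(eio.stage_header("de", params))
        de_table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    manifest["stages"]["de"] = {
        "probes": len(de_table),
        "up_probes": len(de_res.up_probes),
        "down_probes": len(de_res.down_probes),
    }

    # -- qPCR validation ----------------------------------------------------
    if qpcr is not None:
        folds = _stage("qpcr")(delta_delta_ct)(qpcr, "control")
        with open(outdir / "qpcr_folds.tsv", "w") as fh:
            fh.write(eio.stage_header("qpcr", params))
            folds.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fold_map = dict(zip(folds["gene"], folds["fold_change"]))
        try:
            corr = validation_correlation(de_res.table, fold_map)
        except ValueError as exc:
            corr = {"error": str(exc)}
        with open(outdir / "validation.json", "w") as fh:
            json.dump(corr, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["stages"]["qpcr"] = {"genes": len(folds), "correlation": corr}
        logger.info("[qpcr] %d genes, validation %s", len(folds), corr)

    # -- integration ---------------------------------------------------------
    report = _stage("integrate")(integrate_with_expression)(
        sets, de_res.up_genes, de_res.down_genes, parameters=params
    )
    eio.write_integration_report(outdir / "integration.json", report, "integrate", params)
    logger.info("[integrate] %s", report.summary().replace("\n", " | "))
    manifest["stages"]["integrate"] = dict(report.counts)

    # -- over-representation -------------------------------------------------
    if config.gmt_path:
        collections = eio.read_gmt(config.gmt_path)
        universe = {g.gene_id for g in annotation}
        query = (de_res.up_genes | de_res.down_genes) & universe
        ora_table = _stage("ora")(ora)(query, universe, collections)
        with open(outdir / "ora.tsv", "w") as fh:
            fh.write(eio.stage_header("ora", params))
            ora_table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        manifest["stages"]["ora"] = {"terms": len(ora_table), "query": len(query)}
        logger.info("[ora] %d terms tested on %d query genes", len(ora_table), len(query))

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
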