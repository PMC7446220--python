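"""End-to-end orchestration: preprocess -> DE -> GO -> deconvolution -> qPCR validation.

A single config (YAML/JSON mapping) drives the run. Exactly one of the
``inputs`` (paths to real data) or ``synthetic`` (generation block)
sections must be present. All tabular outputs are TSV; the run summary
is deterministic JSON (sorted keys, no timestamps) so repeated runs with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .deconvolution import (
    associate_with_response,
    compare_longitudinal,
    derive_signature,
    score_samples,
)
from .diffexpr import differential_expression, select_de_genes
from .enrichment import enrich, results_to_frame
from .io import (
    ExpressionMatrix,
    GeneSignature,
    GOAnnotation,
    QpcrTable,
    SampleSheet,
    Scale,
    read_expression_tsv,
    read_gmt,
    read_go_annotation,
    read_qpcr_table,
    read_sample_sheet,
    write_expression_tsv,
    write_gmt,
    write_go_annotation,
    write_qpcr_table,
    write_sample_sheet,
)
from .preprocess import batch_adjust, log2_transform, quantile_normalize
from .qpcr import ddct_fold_change, pearson_correlation
from .synthetic import (
    PlantedTerm,
    generate_cohort,
    generate_go_annotation,
    generate_qpcr,
    generate_reference_profiles,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_CONTRASTS = ("baseline", "week20", "longitudinal-responders")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class PipelineConfig:
    """Validated pipeline configuration.

    Fields: ``seed`` (int), ``output_dir`` (path), thresholds
    (``p_nominal``, ``fc_threshold``, ``alpha``), ``contrasts`` (subset of
    baseline / week20 / longitudinal-responders), and exactly one of
    ``inputs`` (matrix, samples, signatures, annotation, optional qpcr)
    or ``synthetic`` (passed to the generators).
    """

    def __init__(self, raw: Mapping[str, Any]):
        self.raw = dict(raw)
        has_inputs = "inputs" in raw
        has_synth = "synthetic" in raw
        if has_inputs == has_synth:
            raise ValueError("config must contain exactly one of 'inputs' or 'synthetic'")
        self.synthetic = dict(raw.get("synthetic") or {})
        self.inputs = dict(raw.get("inputs") or {})
        self.seed = int(raw.get("seed", 0))
        self.output_dir = Path(raw.get("output_dir", "pipeline_out"))
        thresholds = dict(raw.get("thresholds") or {})
        self.p_nominal = float(thresholds.get("p_nominal", 0.05))
        self.fc_threshold = float(thresholds.get("fc_threshold", 1.2))
        self.alpha = float(thresholds.get("alpha", 0.05))
        if not (0 < self.p_nominal <= 1 and 0 < self.alpha <= 1 and self.fc_threshold >= 1):
            raise ValueError("thresholds out of range")
        self.contrasts = tuple(raw.get("contrasts", _CONTRASTS))
        unknown = [c for c in self.contrasts if c not in _CONTRASTS]
        if unknown:
            raise ValueError(f"unknown contrasts: {unknown}")

    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(name, str(exc)) from exc
            logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("generate")
def _generate_inputs(cfg: PipelineConfig):
    s = cfg.synthetic
    ref = generate_reference_profiles(
        n_genes=int(s.get("n_genes", 2000)),
        cell_types=tuple(s.get("cell_types", ("TPH", "FIB_CD34", "FIB_THY1", "FIB_DN"))),
        n_markers_per_type=int(s.get("n_markers_per_type", 50)),
        marker_effect=float(s.get("marker_effect", 2.0)),
        seed=cfg.seed,
    )
    matrix, sheet, truth = generate_cohort(
        ref,
        n_responders=int(s.get("n_responders", 8)),
        n_nonresponders=int(s.get("n_nonresponders", 3)),
        tph_fraction_resp=float(s.get("tph_fraction_resp", 0.05)),
        tph_fraction_nonresp=float(s.get("tph_fraction_nonresp", 0.15)),
        noise_sd=float(s.get("noise_sd", 0.3)),
        n_de_genes=int(s.get("n_de_genes", 20)),
        de_effect=float(s.get("de_effect", 1.0)),
        batches=s.get("batches"),
        seed=cfg.seed,
    )
    signatures = [
        derive_signature(
            ref.to_frame(),
            target_type=t,
            n_top=int(s.get("signature_n_top", 100)),
            min_fc=float(s.get("signature_min_fc", 1.5)),
        )
        for t in ref.cell_types
    ]
    go_cfg = dict(s.get("go") or {})
    planted = [
        PlantedTerm(
            name="planted responder term",
            de_genes=truth.de_genes_up_resp,
            size=int(go_cfg.get("planted_size", 10)),
            overlap_fraction=float(go_cfg.get("planted_overlap", 0.8)),
        ),
        PlantedTerm(
            name="planted non-responder term",
            de_genes=truth.de_genes_up_nonresp,
            size=int(go_cfg.get("planted_size", 10)),
            overlap_fraction=float(go_cfg.get("planted_overlap", 0.8)),
        ),
    ]
    annotation, planted_ids = generate_go_annotation(
        matrix.genes,
        n_terms=int(go_cfg.get("n_terms", 50)),
        term_size_range=tuple(go_cfg.get("term_size_range", (5, 40))),
        planted=planted,
        seed=cfg.seed,
    )
    qpcr_cfg = dict(s.get("qpcr") or {})
    endogenous = matrix.genes[0]
    targets = sorted(truth.de_genes_up_resp)[: int(qpcr_cfg.get("n_targets", 4))]
    qpcr = generate_qpcr(
        matrix,
        target_genes=targets,
        endogenous_gene=endogenous,
        noise_sd=float(qpcr_cfg.get("noise_sd", 0.0)),
        seed=cfg.seed,
    )
    return matrix, sheet, signatures, annotation, qpcr, truth, planted_ids


@_stage("load")
def _load_inputs(cfg: PipelineConfig):
    inp = cfg.inputs
    matrix = read_expression_tsv(inp["matrix"], scale=inp.get("matrix_scale", "log2"))
    sheet = read_sample_sheet(inp["samples"])
    signatures = read_gmt(inp["signatures"])
    annotation = read_go_annotation(inp["annotation"])
    qpcr = None
    if "qpcr" in inp:
        qpcr = read_qpcr_table(inp["qpcr"], endogenous_gene=inp["qpcr_endogenous"])
    return matrix, sheet, signatures, annotation, qpcr, None, ()


@_stage("preprocess")
def _preprocess(matrix: ExpressionMatrix, sheet: SampleSheet) -> ExpressionMatrix:
    if matrix.scale == Scale.raw:
        matrix = log2_transform(matrix)
    if matrix.scale == Scale.log2:
        matrix = quantile_normalize(matrix)
    batches = sheet.batches()
    labels = {batches[s] for s in matrix.samples}
    if len(labels) >= 2:
        matrix = batch_adjust(matrix, batches)
    return matrix


@_stage("differential_expression")
def _run_de(matrix: ExpressionMatrix, sheet: SampleSheet, cfg: PipelineConfig):
    results = {}
    for contrast in cfg.contrasts:
        if contrast == "baseline":
            a = sheet.samples_where(timepoint="week0", responder=True)
            b = sheet.samples_where(timepoint="week0", responder=False)
            res = differential_expression(matrix, a, b, contrast=contrast)
        elif contrast == "week20":
            a = sheet.samples_where(timepoint="week20", responder=True)
            b = sheet.samples_where(timepoint="week20", responder=False)
            res = differential_expression(matrix, a, b, contrast=contrast)
        else:  # longitudinal-responders, paired within patient
            patients = [
                p
                for p in sheet.paired_patients()
                if sheet.record(sheet.sample_of(p, "week0")).responder_flag
            ]
            a = [sheet.sample_of(p, "week0") for p in patients]
            b = [sheet.sample_of(p, "week20") for p in patients]
            res = differential_expression(matrix, a, b, paired=True, contrast=contrast)
        results[contrast] = res
    return results


_GROUP_LABELS = {
    "baseline": ("Response", "Non-response"),
    "week20": ("Response", "Non-response"),
    "longitudinal-responders": ("Downregulated", "Upregulated"),
}


@_stage("pathway_enrichment")
def _run_enrichment(de_results, annotation: GOAnnotation, matrix: ExpressionMatrix, cfg: PipelineConfig):
    annotated = set().union(*(genes for _, genes in annotation.terms.values()))
    universe = [g for g in matrix.genes if g in annotated]
    out = {}
    for contrast, res in de_results.items():
        up_a, up_b = select_de_genes(res, cfg.p_nominal, cfg.fc_threshold)
        label_a, label_b = _GROUP_LABELS[contrast]
        rows = []
        for genes, label in ((up_a, label_a), (up_b, label_b)):
            in_universe = [g for g in genes if g in annotated]
            rows.extend(enrich(in_universe, annotation, universe, group_label=label))
        out[contrast] = {"selected": {label_a: up_a, label_b: up_b}, "results": rows}
    return out


@_stage("deconvolution")
def _run_deconvolution(matrix, sheet, signatures, cfg: PipelineConfig):
    scores = score_samples(matrix, signatures)
    associations = {}
    for timepoint in ("week0", "week20"):
        try:
            associations[timepoint] = associate_with_response(scores, sheet, timepoint=timepoint)
        except ValueError as exc:
            logger.warning("association at %s skipped: %s", timepoint, exc)
    lead = scores.signatures[0]
    longitudinal = compare_longitudinal(scores, sheet, lead)
    return scores, associations, longitudinal


@_stage("qpcr_validation")
def _run_qpcr(qpcr: QpcrTable, matrix: ExpressionMatrix):
    """Correlate -ddCt log2 fold changes with array relative expression.

    The array counterpart of a ddCt fold change is target-minus-endogenous
    log2 expression, taken from the matrix the qPCR was measured against.
    """
    target_genes = sorted(
        {g for _, g, _ in qpcr.rows if g != qpcr.endogenous_gene and g in matrix.genes}
    )
    calibrator = list(qpcr.sample_ids)  # mean delta-Ct of all samples as reference
    endo_idx = matrix.gene_index(qpcr.endogenous_gene) if qpcr.endogenous_gene in matrix.genes else None
    report = {}
    for gene in target_genes:
        res = ddct_fold_change(qpcr, gene, calibrator)
        samples = [s for s in res.samples if s in matrix.samples]
        log_fold = {s: float(np.log2(f)) for s, f in zip(res.samples, res.fold_change)}
        x = [log_fold[s] for s in samples]
        gi = matrix.gene_index(gene)
        y = []
        for s in samples:
            sj = matrix.sample_index(s)
            val = float(matrix.values[gi, sj])
            if endo_idx is not None:
                val -= float(matrix.values[endo_idx, sj])
            y.append(val)
        r, r2, p = pearson_correlation(x, y)
        report[gene] = {"r": r, "r_squared": r2, "p_value": p, "n": len(samples)}
    return report


def run_pipeline(config: Mapping[str, Any] | PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis and write all outputs under ``output_dir``.

    Returns the summary dict (also written as ``summary.json``).
    """
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig(config)
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic:
        matrix, sheet, signatures, annotation, qpcr, truth, planted_ids = _generate_inputs(cfg)
        write_expression_tsv(matrix, outdir / "expression_input.tsv")
        write_sample_sheet(sheet, outdir / "samples.tsv")
        write_gmt(signatures, outdir / "signatures.gmt")
        write_go_annotation(annotation, outdir / "go_annotation.tsv")
        if qpcr is not None:
            write_qpcr_table(qpcr, outdir / "qpcr.tsv")
    else:
        matrix, sheet, signatures, annotation, qpcr, truth, planted_ids = _load_inputs(cfg)

    processed = _preprocess(matrix, sheet)
    write_expression_tsv(processed, outdir / "expression_processed.tsv")

    de_results = _run_de(processed, sheet, cfg)
    for contrast, res in de_results.items():
        res.to_frame().to_csv(outdir / f"de_{contrast}.tsv", sep="\t", index=False)

    enr = _run_enrichment(de_results, annotation, processed, cfg)
    for contrast, block in enr.items():
        results_to_frame(block["results"]).to_csv(
            outdir / f"enrichment_{contrast}.tsv", sep="\t", index=False
        )

    scores, associations, longitudinal = _run_deconvolution(processed, sheet, signatures, cfg)
    scores.to_frame().to_csv(outdir / "enrichment_scores.tsv", sep="\t", index_label="sample_id")
    assoc_rows = []
    for timepoint, results in associations.items():
        for r in results:
            assoc_rows.append(
                {
                    "signature": r.signature,
                    "contrast": r.contrast,
                    "mean_responders": r.mean_responders,
                    "mean_nonresponders": r.mean_nonresponders,
                    "t_statistic": r.t_statistic,
                    "p_value": r.p_value,
                    "direction": r.direction,
                }
            )
    pd.DataFrame(assoc_rows).to_csv(outdir / "associations.tsv", sep="\t", index=False)

    qpcr_report = _run_qpcr(qpcr, matrix) if qpcr is not None else {}

    gene_set = set(matrix.genes)
    overlap_diag = {
        sig.name: {"n_genes": len(sig), "n_on_matrix": len(sig.gene_ids & gene_set)}
        for sig in signatures
    }
    summary: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "thresholds": {
            "p_nominal": cfg.p_nominal,
            "fc_threshold": cfg.fc_threshold,
            "alpha": cfg.alpha,
        },
        "libraries": _library_versions(),
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "signature_overlap": overlap_diag,
        "differential_expression": {
            contrast: {
                "n_selected_a": len(enr[contrast]["selected"][_GROUP_LABELS[contrast][0]]),
                "n_selected_b": len(enr[contrast]["selected"][_GROUP_LABELS[contrast][1]]),
                "n_bonferroni_significant": int(
                    (de_results[contrast].p_bonferroni < cfg.alpha).sum()
                ),
            }
            for contrast in de_results
        },
        "pathway_enrichment": {
            contrast: {
                "n_terms_tested": len({r.term_id for r in block["results"]}),
                "n_significant": sum(1 for r in block["results"] if r.p_adjusted < cfg.alpha),
                "top_terms": [r.term_id for r in block["results"][:5]],
            }
            for contrast, block in enr.items()
        },
        "deconvolution": {
            "associations": {
                timepoint: {
                    r.signature: {"p_value": r.p_value, "direction": r.direction}
                    for r in results
                }
                for timepoint, results in associations.items()
            },
            "longitudinal": {
                "signature": scores.signatures[0],
                "paired": [
                    {
                        "group": r.group,
                        "n_pairs": r.n_pairs,
                        "mean_change": r.mean_change,
                        "p_value": r.p_value,
                    }
                    for r in longitudinal["paired"]
                ],
            },
        },
        "qpcr_validation": qpcr_report,
    }
    if truth is not None:
        summary["synthetic_truth"] = {
            "planted_go_terms": list(planted_ids),
            "n_de_up_resp": len(truth.de_genes_up_resp),
            "n_de_up_nonresp": len(truth.de_genes_up_nonresp),
        }

    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _library_versions() -> dict[str, str]:
    import numpy
    import pandas
    import scipy

    return {
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scipy": scipy.__version__,
        "python": ".".join(map(str, sys.version_info[:3])),
    }
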