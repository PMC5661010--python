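"""End-to-end orchestration: QC → bucketing → PQN → DAPC (both designs) →
contributions → correlations → summaries → enrichment.

A single :class:`PipelineConfig` drives the run; every intermediate artifact
is written to the output directory as delimited or structured text, and the
final :class:`run_pipeline` report is deterministic given the config (all
randomness flows from the configured seed; timestamps appear only in the
log, never in the report, so re-runs are byte-identical).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .correlation import (
    bucket_correlations,
    group_intensity_summary,
    metabolite_consistency,
    write_consistency_report,
    write_group_summaries,
)
from .dapc import (
    dapc_fit,
    reclassification_accuracy,
    save_model,
    top_contributors,
    xval_select_npca,
)
from .data_model import (
    BucketTable,
    derive_group_labels,
    read_bucket_table,
    read_metadata,
    read_pathway_library,
    write_bucket_table,
)
from .enrichment import msea, rank_pathway_table, write_enrichment_table
from .preprocess import pqn_normalize, write_dilution_factors
from .spectral_qc import QCThresholds, bucket_spectra, qc_filter, read_spectrum, write_qc_report

logger = logging.getLogger(__name__)

DESIGNS = ("conformation", "combined")
DEFAULT_XVAL_GRID = (5, 10, 15, 20, 25, 30, 40)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, serializable to/from YAML."""

    metadata: str
    bucket_table: str | None = None
    spectra: list[str] = field(default_factory=list)
    bucket_definitions: str | None = None   # bucket-table file whose header defines buckets
    pathway_library: str | None = None
    output_dir: str = "pipeline_out"
    qc_enabled: bool = True
    qc_max_linewidth_hz: float = 1.5
    qc_max_baseline_ratio: float = 0.01
    qc_center_tolerance_ppm: float = 0.005
    pqn_reference_mode: str = "median_all"
    pqn_integral_prestep: bool = True
    xval_grid: tuple[int, ...] = DEFAULT_XVAL_GRID
    xval_reps: int = 30
    xval_train_fraction: float = 0.9
    seed: int = 0
    n_ld: int | None = None
    top_fractions: tuple[float, ...] = (0.10, 0.25)
    r_min: float = 0.7
    enrichment_min_overlap: int = 1
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("xval_grid", "top_fractions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dict(self.__dict__)
        d["xval_grid"] = list(self.xval_grid)
        d["top_fractions"] = list(self.top_fractions)
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _load_table(config: PipelineConfig, outdir: Path) -> tuple[BucketTable, dict[str, Any]]:
    info: dict[str, Any] = {}
    if config.spectra:
        with _stage("qc"):
            spectra = [read_spectrum(p) for p in config.spectra]
            info["n_spectra_in"] = len(spectra)
            if config.qc_enabled:
                thresholds = QCThresholds(
                    max_linewidth_hz=config.qc_max_linewidth_hz,
                    max_baseline_ratio=config.qc_max_baseline_ratio,
                    center_tolerance_ppm=config.qc_center_tolerance_ppm,
                )
                results = qc_filter(spectra, thresholds)
                write_qc_report(results, outdir / "qc_report.tsv")
                passed = {r.sample_id for r in results if r.passed}
                spectra = [s for s in spectra if s.sample_id in passed]
                info["n_spectra_passed_qc"] = len(spectra)
                if not spectra:
                    raise ValueError("no spectra passed QC")
        with _stage("bucketing"):
            if not config.bucket_definitions:
                raise ValueError("spectra input requires bucket_definitions")
            defs = read_bucket_table(config.bucket_definitions)
            table = bucket_spectra(spectra, defs.buckets)
    else:
        with _stage("load_table"):
            if not config.bucket_table:
                raise ValueError("config needs either bucket_table or spectra")
            table = read_bucket_table(config.bucket_table)
            info["n_spectra_in"] = table.n_samples
    return table, info


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis for both discriminant designs.

    Returns the run report (also written to ``report.json``); all artifacts
    land in ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict[str, Any] = {
        "software_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
    }

    table, info = _load_table(config, outdir)
    report.update(info)

    with _stage("metadata"):
        metadata = read_metadata(config.metadata)
        known = {m.sample_id for m in metadata}
        keep = [s for s in table.samples if s in known]
        if not keep:
            raise ValueError("no overlap between table samples and metadata")
        if len(keep) < table.n_samples:
            logger.warning("dropping %d samples without metadata",
                           table.n_samples - len(keep))
        table = table.subset_samples(keep)
        metadata = [m for m in metadata if m.sample_id in set(keep)]
        report["n_samples"] = table.n_samples
        report["n_buckets_total"] = table.n_buckets
        report["n_buckets_annotated"] = sum(1 for b in table.buckets if b.annotation)

    with _stage("pqn"):
        norm = pqn_normalize(table, reference_mode=config.pqn_reference_mode,
                             integral_prestep=config.pqn_integral_prestep)
        write_dilution_factors(norm, outdir / "dilution_factors.tsv")
        write_bucket_table(norm.table, outdir / "normalized_table.tsv")
        ntable = norm.table

    annotation_map = ntable.annotation_map()
    bucket_to_met = {b.bucket_id: b.annotation for b in ntable.buckets if b.annotation}
    met_to_compound = {
        b.annotation: b.metabolite_id
        for b in ntable.buckets
        if b.annotation and b.metabolite_id
    }

    design_results: dict[str, dict[str, Any]] = {}
    top_sets: dict[str, set[str]] = {}
    for design in DESIGNS:
        with _stage(f"dapc_{design}"):
            labels = derive_group_labels(metadata, design)
            groups = sorted(set(labels.values()))
            report.setdefault("samples_per_group", {})[design] = {
                g: sum(1 for s in ntable.samples if labels[s] == g) for g in groups
            }
            max_npca = min(ntable.n_samples - 1, ntable.n_buckets)
            grid = [g for g in config.xval_grid if 1 <= g <= max_npca - 1]
            if not grid:
                grid = [min(3, max_npca)]
            xval = xval_select_npca(
                ntable, labels, grid,
                train_fraction=config.xval_train_fraction,
                n_reps=config.xval_reps,
                seed=config.seed,
            )
            model = dapc_fit(ntable, labels, n_pca=xval.chosen_n_pca, n_ld=config.n_ld)
            overall, per_group = reclassification_accuracy(model, ntable, labels)
            save_model(model, outdir / f"dapc_{design}_model.json")

            tops: dict[str, list] = {}
            for frac in config.top_fractions:
                ranked = top_contributors(
                    model.var_contrib_total, model.bucket_ids, frac, bucket_to_met
                )
                tops[f"{frac:g}"] = ranked
            _write_contributions(model, bucket_to_met, outdir / f"contributions_{design}.tsv")

            top10 = tops.get("0.1") or next(iter(tops.values()))
            top_sets[design] = {met for _, _, met in top10 if met}
            design_results[design] = {
                "n_groups": len(groups),
                "chosen_n_pca": xval.chosen_n_pca,
                "xval_grid": [int(g) for g in xval.grid],
                "xval_mean_accuracy": [round(float(a), 6) for a in xval.mean_accuracy],
                "n_ld": model.n_ld,
                "reclassification_accuracy": round(overall, 6),
                "per_group_accuracy": {g: round(a, 6) for g, a in per_group.items()},
                "top_buckets": {
                    frac: [
                        {"bucket_id": b, "contribution": round(c, 8), "metabolite": m}
                        for b, c, m in ranked
                    ]
                    for frac, ranked in tops.items()
                },
                "top10_metabolites": sorted(top_sets[design]),
            }
            if config.plots:
                from .plots import plot_scores, plot_contributions

                plot_scores(model, ntable, labels,
                            outdir / f"dapc_{design}_scores.png")
                plot_contributions(model, bucket_to_met,
                                   outdir / f"dapc_{design}_contrib.png")
    report["dapc"] = design_results

    with _stage("correlation"):
        corr = bucket_correlations(ntable)
        corr.to_csv(outdir / "bucket_correlations.tsv", sep="\t")
        consistency = metabolite_consistency(corr, annotation_map, r_min=config.r_min)
        write_consistency_report(consistency, outdir / "metabolite_consistency.tsv")
        report["consistency"] = {
            "n_confirmed": sum(1 for c in consistency if c.status == "confirmed"),
            "n_low_correlation": sum(1 for c in consistency if c.status == "low_correlation"),
            "n_single_bucket": sum(1 for c in consistency if c.status == "single_bucket"),
        }

    with _stage("group_summaries"):
        labels_conf = derive_group_labels(metadata, "conformation")
        summary_buckets = sorted(
            {b for design in DESIGNS
             for b in (rec["bucket_id"]
                       for rec in design_results[design]["top_buckets"].get("0.1", []))}
        )
        if summary_buckets:
            summaries = group_intensity_summary(ntable, labels_conf, summary_buckets)
            write_group_summaries(summaries, outdir / "group_summaries.tsv")
            report["n_summary_buckets"] = len(summary_buckets)

    with _stage("enrichment"):
        low_corr = {c.metabolite for c in consistency if c.status == "low_correlation"}
        shared = (top_sets["conformation"] & top_sets["combined"]) - low_corr
        report["enrichment_input_metabolites"] = sorted(shared)
        if config.pathway_library and shared:
            library = read_pathway_library(config.pathway_library)
            compound_ids = sorted(
                met_to_compound[m] for m in shared if m in met_to_compound
            )
            if compound_ids:
                records = msea(compound_ids, library,
                               min_overlap=config.enrichment_min_overlap)
                write_enrichment_table(records, outdir / "enrichment.tsv")
                if records:
                    ranked = rank_pathway_table(records, library)
                    ranked.to_csv(outdir / "pathway_ranking.tsv", sep="\t", index=False)
                report["enrichment"] = {
                    "n_pathways_tested": len(records),
                    "n_significant_q05": sum(1 for r in records if r.q_bh <= 0.05),
                    "top_pathways": [
                        {"pathway_id": r.pathway_id, "overlap": r.overlap,
                         "p_ease": round(r.p_ease, 8), "q_bh": round(r.q_bh, 8)}
                        for r in records[:5]
                    ],
                }

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return report


def _write_contributions(model, bucket_to_met, path: Path) -> None:
    import pandas as pd

    from .data_model import parse_bucket_id

    rows = []
    order = np.argsort(model.var_contrib_total)[::-1]
    for rank, i in enumerate(order, start=1):
        bid = model.bucket_ids[i]
        try:
            left, right = parse_bucket_id(bid)
            ppm = f"{left}..{right}"
        except ValueError:
            ppm = ""
        rows.append(
            {
                "bucket_id": bid,
                "ppm_range": ppm,
                "metabolite": bucket_to_met.get(bid, ""),
                "contribution": model.var_contrib_total[i],
                "rank": rank,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
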