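"""End-to-end orchestration: normalize -> cutoff -> QC scan -> sex bias -> compensation.

Sample exclusions mirror the study's bookkeeping: replicate-less samples and
lines whose annotated deficiency shows no dosage effect (``df_absent`` in
the QC scan) are dropped before the sex-bias and compensation stages, and
every exclusion is recorded in the output manifest.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import dosage, noise, normalization, sexbias


@dataclass
class PipelineConfig:
    counts: str
    design: str
    annotation: str
    df_intervals: str
    outdir: str
    feature_classes: str | None = None  # TSV feature_id -> class; else classes inferred
    spikein_reference: str | None = None
    count_cutoff_override: float | None = None
    cv_percentile: float = 5.0
    loess_span: float = 0.75
    bootstrap_n: int = 1000
    seed: int = 0
    alpha: float = 0.05
    qc_log2_threshold: float = dosage.DEFAULT_QC_LOG2_THRESHOLD
    sexbias_group_a: dict = field(default_factory=lambda: {"genotype": "w1118", "karyotype": "XX", "tra2": False})
    sexbias_group_b: dict = field(default_factory=lambda: {"genotype": "w1118", "karyotype": "XY", "tra2": False})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _infer_classes(annotation: pd.DataFrame) -> pd.Series:
    return annotation["feature_class"]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest dict (also written to the outdir)."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {"seed": config.seed, "stages": [], "exclusions": {}}

    counts = dio.read_counts(config.counts)
    design = dio.read_design(config.design)
    annotation = dio.read_annotation(config.annotation)
    df_intervals = dio.read_df_intervals(config.df_intervals)
    if config.feature_classes:
        fc = pd.read_csv(config.feature_classes, sep="\t").set_index("feature_id")["feature_class"]
    else:
        fc = _infer_classes(annotation)
    fc = fc.reindex(counts.index).fillna("gene")
    n_in = len(design)

    def stage(name):
        timings[name] = time.time()
        manifest["stages"].append(name)

    try:
        stage("normalize")
        size_factors = normalization.compute_size_factors(counts, feature_classes=fc)
        expr = normalization.normalize(counts, size_factors)
        size_factors.rename_axis("sample_id").to_csv(outdir / "size_factors.tsv", sep="\t")
        timings["normalize"] = time.time() - timings["normalize"]

        stage("noise_cutoff")
        cut = noise.derive_cutoff(
            expr, design, fc, percentile=config.cv_percentile, span=config.loess_span
        )
        cutoff = (
            config.count_cutoff_override
            if config.count_cutoff_override is not None
            else cut.count_cutoff
        )
        cut.fitted_curve.to_csv(outdir / "spikein_cv_curve.tsv", sep="\t", index=False)
        corr = noise.replicate_correlation(expr, design)
        corr.to_csv(outdir / "replicate_correlations.tsv", sep="\t", index=False)
        with open(outdir / "cutoff_report.txt", "w") as fh:
            fh.write(
                f"intergenic CV threshold (percentile {config.cv_percentile}): "
                f"{cut.cv_threshold_percent:.2f}%\n"
                f"derived count cutoff: {cut.count_cutoff:.3f} normalized counts\n"
                f"count cutoff applied: {cutoff:.3f}"
                f"{' (manual override)' if config.count_cutoff_override is not None else ''}\n"
                f"fraction of genes above cutoff: {cut.fraction_genes_above_cutoff:.3f}\n"
                f"fraction of genes with CV below threshold: "
                f"{cut.fraction_genes_below_cv_threshold:.3f}\n"
                f"median replicate correlation: {corr['r'].median():.4f}\n"
            )
        timings["noise_cutoff"] = time.time() - timings["noise_cutoff"]

        stage("qc_scan")
        qc = dosage.df_validation_scan(
            expr, design, annotation, df_intervals,
            count_cutoff=cutoff, log2_threshold=config.qc_log2_threshold,
        )
        qc.to_csv(outdir / "df_qc_scan.tsv", sep="\t", index=False)
        absent = qc.loc[qc["verdict"] == "df_absent", "df_id"].tolist()
        no_rep = dio.single_replicate_samples(design)
        excluded_absent = design.loc[design["df_id"].isin(absent), "sample_id"].tolist()
        manifest["exclusions"] = {
            "df_absent_lines": absent,
            "df_absent_samples": excluded_absent,
            "no_replicate_samples": no_rep,
        }
        drop = set(excluded_absent) | set(no_rep)
        design_kept = design[~design["sample_id"].isin(drop)].reset_index(drop=True)
        kept_dfs = df_intervals[~df_intervals["df_id"].isin(absent)]
        timings["qc_scan"] = time.time() - timings["qc_scan"]

        stage("sex_bias_de")
        try:
            de = sexbias.sex_bias_table(
                counts, design_kept, size_factors,
                group_a=config.sexbias_group_a, group_b=config.sexbias_group_b,
                count_cutoff=cutoff, alpha=config.alpha, label_a="A", label_b="B",
            )
            de.rename_axis("feature_id").to_csv(outdir / "sex_bias_de.tsv", sep="\t")
            n_a, n_b = sexbias.classify_sex_bias(de, alpha=config.alpha)
            manifest["sex_bias"] = {"a_biased": n_a, "b_biased": n_b}
        except ValueError as exc:
            manifest["sex_bias"] = {"skipped": str(exc)}
        timings["sex_bias_de"] = time.time() - timings["sex_bias_de"]

        stage("dosage_response")
        table = dosage.compensation_table(
            expr, design_kept, annotation, kept_dfs,
            count_cutoff=cutoff, n_boot=config.bootstrap_n, seed=config.seed,
        )
        table.to_csv(outdir / "compensation_table.tsv", sep="\t", index=False)
        summaries = dosage.arm_summaries(table)
        summaries.to_csv(outdir / "arm_boxstats.tsv", sep="\t", index=False)
        hemi = table[(table["kind"] == "hemizygous") & table["passes_cutoff"]]
        comparison = None
        if {"X", "3L"} <= set(hemi["arm"]):
            comparison = dosage.compare_arms(
                hemi.loc[hemi["arm"] == "X", "compensation"],
                hemi.loc[hemi["arm"] == "3L", "compensation"],
            )
        per_df = dosage.per_df_median_compensation(table)
        try:
            rho, rho_p = dosage.df_extent_correlation(per_df, kept_dfs)
        except ValueError:
            rho, rho_p = float("nan"), float("nan")
        manifest["dosage"] = {
            "median_compensation": dosage.cohort_median_compensation(table),
            "arm_comparison": asdict(comparison) if comparison else None,
            "extent_correlation": {"rho": rho, "p": rho_p},
        }
        timings["dosage_response"] = time.time() - timings["dosage_response"]
    except Exception as exc:
        stage_name = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed in stage {stage_name!r}: {exc}") from exc

    n_excluded = len(drop)
    manifest.update(
        {
            "cutoff": {
                "cv_threshold_percent": cut.cv_threshold_percent,
                "count_cutoff_derived": cut.count_cutoff,
                "count_cutoff_applied": cutoff,
                "fraction_genes_above_cutoff": cut.fraction_genes_above_cutoff,
                "fraction_genes_below_cv_threshold": cut.fraction_genes_below_cv_threshold,
            },
            "samples_in": n_in,
            "samples_excluded": n_excluded,
            "samples_analyzed": n_in - n_excluded,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "runtime_s": round(time.time() - t0, 3),
        }
    )
    assert manifest["samples_in"] - manifest["samples_excluded"] == manifest["samples_analyzed"]
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
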