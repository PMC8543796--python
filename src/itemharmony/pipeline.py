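"""End-to-end orchestration of the harmonization checklist.

Stages run in a fixed, recorded order:

1. read and validate the crosswalk against the raw study tables;
2. raw-code QC: sentinel missing-code detection and the cross-study
   min/max cross-tabulation on raw codes;
3. deterministic recoding into harmonized 0-based scores (summary-score
   items excluded up front);
4. exclusion of conditional (gated) items;
5. no-variability and sparse-cell handling, then truncation of any
   remaining ordinal items to binary for the model stage;
6. directionality check (report-only: reversal requires an explicit
   crosswalk edit, because an anti-correlated item can be substantively,
   not artifactually, reversed);
7. per-study 2PL fit with fit statistics and residual flags;
8. reports and a run manifest.

No stage consumes the outputs of a later stage, input files are never
mutated, and two runs with equal manifests produce byte-identical
reports.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import QCFlag, StudyDataset, flags_to_frame, read_study_data
from .crosswalk import Crosswalk, read_crosswalk, validate_crosswalk
from .irt import IRTConfig, fit_2pl, fit_statistics, residual_report
from .errors import DegenerateItemError, EstimationError
from .qc import (
    QCThresholds,
    crosstab_ranges,
    detect_missing_codes,
    detect_no_variability,
    detect_reverse_candidates,
    exclude_conditional,
)
from .standardize import AuditLog, apply_recode, collapse_sparse, dichotomize

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RunManifest",
    "run_pipeline",
    "run_pipeline_objects",
    "summarize_flags",
    "select_random_visit",
]

STAGE_ORDER = [
    "read_validate",
    "raw_qc",
    "standardize",
    "conditional_exclusion",
    "variability_sparse",
    "directionality",
    "irt_fit",
    "report",
]


@dataclass
class PipelineConfig:
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    irt: IRTConfig = field(default_factory=IRTConfig)
    residual_thresholds: tuple = (0.3, 3.0)
    min_items_for_fit: int = 3
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.to_dict(),
            "irt": {
                "n_quad": self.irt.n_quad,
                "tol": self.irt.tol,
                "max_iter": self.irt.max_iter,
                "a_max": self.irt.a_max,
            },
            "residual_thresholds": list(self.residual_thresholds),
            "min_items_for_fit": self.min_items_for_fit,
            "seed": self.seed,
        }

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load thresholds and estimation settings from a YAML config file.

        All keys are optional; omitted ones keep their defaults.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        th = raw.get("thresholds", {})
        ir = raw.get("irt", {})
        return cls(
            thresholds=QCThresholds(
                reverse_r=th.get("reverse_r", -0.2),
                min_overlap=th.get("min_overlap", 20),
                min_cell=th.get("min_cell", 5),
            ),
            irt=IRTConfig(
                n_quad=ir.get("n_quad", 41),
                tol=ir.get("tol", 1e-6),
                max_iter=ir.get("max_iter", 500),
                a_max=ir.get("a_max", 5.0),
            ),
            residual_thresholds=tuple(raw.get("residual_thresholds", (0.3, 3.0))),
            min_items_for_fit=raw.get("min_items_for_fit", 3),
            seed=raw.get("seed", 0),
        )


@dataclass
class RunManifest:
    config: dict
    input_digests: dict
    stage_order: list
    seed: int
    flag_counts: dict
    output_paths: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "input_digests": self.input_digests,
                "stage_order": self.stage_order,
                "seed": self.seed,
                "flag_counts": self.flag_counts,
                "output_paths": self.output_paths,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class PipelineResult:
    flags: list
    audit: AuditLog
    range_table: pd.DataFrame
    datasets: list  # final harmonized, model-ready StudyDatasets
    fits: dict  # study_id -> IRTFitResult (fit + residuals attached)
    skipped_studies: dict  # study_id -> reason
    stage_flag_counts: dict


def run_pipeline_objects(
    cw: Crosswalk, raw_datasets: list, config: PipelineConfig | None = None
) -> PipelineResult:
    """Run all stages on in-memory objects; the file CLI wraps this."""
    config = config or PipelineConfig()
    th = config.thresholds
    flags: list = []
    audit = AuditLog()
    stage_counts: dict = {}

    def _stage(name, new_flags):
        stage_counts[name] = stage_counts.get(name, 0) + len(new_flags)
        flags.extend(new_flags)

    # 1. read/validate
    _stage("read_validate", validate_crosswalk(cw, raw_datasets))
    by_study = {ds.study_id: ds for ds in raw_datasets}

    # 2. raw-code QC: sentinels and cross-study raw ranges
    raw_flags = []
    for m in cw.mappings:
        ds = by_study[m.study_id]
        if m.source_variable not in ds.items:
            continue
        f = detect_missing_codes(ds.items[m.source_variable], m.construct_id, m.study_id)
        if f is not None:
            raw_flags.append(f)
    range_table, range_flags = crosstab_ranges(raw_datasets, cw)
    _stage("raw_qc", raw_flags + range_flags)

    # 3. recode/standardize
    harmonized = []
    std_flags = []
    for study_id in sorted(by_study):
        ds = by_study[study_id]
        items = {}
        for m in sorted(cw.for_study(study_id), key=lambda m: m.construct_id):
            if m.source_variable not in ds.items:
                continue
            if m.is_summary_score:
                std_flags.append(
                    QCFlag("summary_score", m.construct_id, study_id, {"excluded": True})
                )
                continue
            items[m.construct_id] = apply_recode(ds.items[m.source_variable], m.recode)
            audit.record(
                study_id, m.construct_id, "apply_recode", recode=m.recode.to_text()
            )
        harmonized.append(StudyDataset(study_id, list(ds.respondent_ids), items))
    _stage("standardize", std_flags)

    # 4. conditional exclusion
    cond_flags = []
    filtered = []
    for ds in harmonized:
        ds2, fl = exclude_conditional(ds, cw)
        for f in fl:
            audit.record(ds.study_id, f.construct_id, "exclude_conditional", gate=f.evidence["gate"])
        cond_flags.extend(fl)
        filtered.append(ds2)
    _stage("conditional_exclusion", cond_flags)

    # 5. no-variability, sparse cells, truncation to binary
    var_flags = []
    model_ready = []
    for ds in filtered:
        items = {}
        for name in sorted(ds.items):
            v = ds.items[name]
            f = detect_no_variability(v, name, ds.study_id)
            if f is not None:
                var_flags.append(f)
                audit.record(ds.study_id, name, "exclude_no_variability")
                continue
            v, f = collapse_sparse(v, th.min_cell, name, ds.study_id)
            if f is not None:
                var_flags.append(f)
                audit.record(ds.study_id, name, "collapse_sparse", min_cell=th.min_cell)
            obs = v[~np.isnan(v)]
            if obs.size and obs.max() > 1:
                v = dichotomize(v)
                audit.record(ds.study_id, name, "dichotomize")
            f = detect_no_variability(v, name, ds.study_id)
            if f is not None:
                var_flags.append(f)
                audit.record(ds.study_id, name, "exclude_no_variability_after_truncation")
                continue
            items[name] = v
        model_ready.append(ds.copy_with(items))
    _stage("variability_sparse", var_flags)

    # 6. directionality (report-only)
    rev_flags = []
    for ds in model_ready:
        rev_flags.extend(
            detect_reverse_candidates(ds, threshold=th.reverse_r, min_overlap=th.min_overlap)
        )
    _stage("directionality", rev_flags)

    # 7. per-study 2PL fit
    fits = {}
    skipped = {}
    for ds in model_ready:
        names = sorted(ds.items)
        if len(names) < config.min_items_for_fit:
            skipped[ds.study_id] = f"only {len(names)} items after QC"
            continue
        X = np.column_stack([ds.items[n] for n in names])
        try:
            fit = fit_2pl(X, item_names=names, study_id=ds.study_id, config=config.irt)
            fit.fit = fit_statistics(fit, X)
            fit.residuals = residual_report(fit, X, thresholds=config.residual_thresholds)
            fits[ds.study_id] = fit
        except (DegenerateItemError, EstimationError) as exc:
            skipped[ds.study_id] = str(exc)
    stage_counts["irt_fit"] = sum(
        len(f.residuals.flagged_pairs) for f in fits.values() if f.residuals
    )

    return PipelineResult(
        flags=flags,
        audit=audit,
        range_table=range_table,
        datasets=model_ready,
        fits=fits,
        skipped_studies=skipped,
        stage_flag_counts=stage_counts,
    )


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _fit_report_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for study_id in sorted(result.fits):
        fit = result.fits[study_id]
        fs = fit.fit
        rows.append(
            {
                "study_id": study_id,
                "n": fit.n_respondents,
                "n_items": len(fit.params.item_names),
                "converged": fit.converged,
                "loglik": round(fit.loglik, 6),
                "rmsea": round(fs.rmsea, 6) if np.isfinite(fs.rmsea) else "",
                "cfi": round(fs.cfi, 6) if np.isfinite(fs.cfi) else "",
                "srmr": round(fs.srmr, 6) if np.isfinite(fs.srmr) else "",
                "rmsea_label": fs.labels["rmsea"],
                "cfi_label": fs.labels["cfi"],
                "srmr_label": fs.labels["srmr"],
                "n_flagged_pairs": len(fit.residuals.flagged_pairs),
            }
        )
    return pd.DataFrame(rows)


def _params_report_frame(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for study_id in sorted(result.fits):
        p = result.fits[study_id].params
        for i, name in enumerate(p.item_names):
            rows.append(
                {
                    "study_id": study_id,
                    "item": name,
                    "a": round(float(p.a[i]), 6),
                    "b": round(float(p.b[i]), 6),
                    "se_a": round(float(p.se_a[i]), 6),
                    "se_b": round(float(p.se_b[i]), 6),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    crosswalk_path,
    data_paths: dict,
    outdir,
    config: PipelineConfig | None = None,
    delimiter: str = "\t",
) -> RunManifest:
    """File-level entry point: read inputs, run all stages, write reports.

    ``data_paths`` maps study_id to its raw table path. Outputs (QC
    report, audit log, fit and parameter reports, manifest) go to
    ``outdir``; inputs are never modified.
    """
    config = config or PipelineConfig()
    os.makedirs(outdir, exist_ok=True)
    cw = read_crosswalk(crosswalk_path, delimiter=delimiter)
    datasets = [
        read_study_data(path, study_id, delimiter=delimiter)
        for study_id, path in sorted(data_paths.items())
    ]
    result = run_pipeline_objects(cw, datasets, config)

    paths = {
        "qc_report": os.path.join(outdir, "qc_report.tsv"),
        "audit_log": os.path.join(outdir, "audit.jsonl"),
        "range_table": os.path.join(outdir, "range_table.tsv"),
        "fit_report": os.path.join(outdir, "fit_report.tsv"),
        "params_report": os.path.join(outdir, "params_report.tsv"),
        "flag_digest": os.path.join(outdir, "flag_digest.tsv"),
        "manifest": os.path.join(outdir, "manifest.json"),
    }
    flags_to_frame(result.flags).to_csv(paths["qc_report"], sep="\t", index=False)
    result.audit.write(paths["audit_log"])
    result.range_table.to_csv(paths["range_table"], sep="\t", index=False, float_format="%.10g")
    _fit_report_frame(result).to_csv(paths["fit_report"], sep="\t", index=False)
    _params_report_frame(result).to_csv(paths["params_report"], sep="\t", index=False)
    summarize_flags(result.flags).to_csv(paths["flag_digest"], sep="\t", index=False)

    flag_counts = dict(sorted(result.stage_flag_counts.items()))
    manifest = RunManifest(
        config=config.to_dict(),
        input_digests={
            "crosswalk": _digest(crosswalk_path),
            **{s: _digest(p) for s, p in sorted(data_paths.items())},
        },
        stage_order=list(STAGE_ORDER),
        seed=config.seed,
        flag_counts=flag_counts,
        output_paths={k: os.path.basename(v) for k, v in paths.items()},
    )
    with open(paths["manifest"], "w") as fh:
        fh.write(manifest.to_json() + "\n")
    return manifest


def summarize_flags(flags) -> pd.DataFrame:
    """Digest: per (study, kind), the count and the affected items."""
    df = flags_to_frame(flags)
    if df.empty:
        return pd.DataFrame(columns=["study_id", "kind", "count", "constructs"])
    out = (
        df.groupby(["study_id", "kind"], sort=True)["construct_id"]
        .agg(["count", lambda s: ",".join(sorted(set(s)))])
        .reset_index()
    )
    out.columns = ["study_id", "kind", "count", "constructs"]
    return out


def select_random_visit(frame: pd.DataFrame, id_column: str, seed: int) -> pd.DataFrame:
    """Reduce a longitudinal table to one seeded random row per respondent.

    Convenience pre-processing for sources with repeated visits; the seed
    belongs in the run manifest so the selection is reproducible.
    """
    rng = np.random.default_rng(seed)
    parts = []
    for _, grp in frame.groupby(id_column, sort=True):
        parts.append(grp.iloc[rng.integers(0, len(grp))])
    return pd.DataFrame(parts).reset_index(drop=True)
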