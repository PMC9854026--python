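"""End-to-end validation pipeline: read a cohort, complete-case filter,
score, and emit the association report, calibration table, ROC points, a
JSON summary and a run manifest — deterministically, so repeated runs on the
same inputs are byte-identical apart from the manifest timestamp.

Numeric output precision is fixed: test statistics and percentages are
printed at 2 decimals (the registry-table convention), probabilities and
curve coordinates at 4.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .association import cohort_association_report
from .cohort import Cohort, ConfigurationError, complete_case_filter, read_cohort
from .grobman import score_cohort
from .validation import (
    auc_with_ci,
    calibration_table,
    hosmer_lemeshow,
    predicted_summary,
    prevalence,
    roc_curve,
)

__all__ = ["RunManifest", "run_full_validation", "compare_reports", "score_to_csv"]

log = logging.getLogger("vbacval")

STAT_DECIMALS = 2
PROB_DECIMALS = 4


def _version() -> str:
    from . import __version__

    return __version__


def _config_hash(options: dict) -> str:
    """Stable hash of the run options (key order independent)."""
    payload = json.dumps(options, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run: inputs, options and emitted files."""

    inputs: list[str]
    model: str
    config_hash: str
    seed: int | None
    version: str
    timestamp: str
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json_file(cls, path) -> "RunManifest":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


def _round(value, decimals):
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else round(value, decimals)


def score_to_csv(cohort: Cohort, model: str, out_path) -> pd.DataFrame:
    """Score a cohort and write it with linear_predictor / probability_percent
    columns appended."""
    results = score_cohort(cohort, model)
    frame = cohort.to_dataframe()
    frame["linear_predictor"] = [round(r.linear_predictor, PROB_DECIMALS) for r in results]
    frame["probability_percent"] = [
        round(r.probability_percent, PROB_DECIMALS) for r in results
    ]
    frame.to_csv(out_path, index=False)
    return frame


def run_full_validation(
    cohort_path,
    model: str,
    out_dir,
    column_map=None,
    ci_method: str = "wilson",
    hl_binning: str = "fixed_deciles",
    hl_df_policy: str = "development",
    auc_method: str = "delong",
    seed: int | None = None,
    quiet: bool = False,
) -> RunManifest:
    """Run the whole external-validation analysis on one cohort file.

    Emits into ``out_dir``: ``association.tsv``, ``calibration.tsv``,
    ``roc.tsv``, ``summary.json`` and ``manifest.json``.  Returns the
    manifest.  Any stage failure propagates with the stage name attached.
    """
    if quiet:
        log.setLevel(logging.ERROR)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    options = {
        "model": model,
        "ci_method": ci_method,
        "hl_binning": hl_binning,
        "hl_df_policy": hl_df_policy,
        "auc_method": auc_method,
        "column_map": dict(column_map or {}),
    }
    manifest = RunManifest(
        inputs=[str(cohort_path)],
        model=model,
        config_hash=_config_hash(options),
        seed=seed,
        version=_version(),
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )

    def stage(name, fn, *args, **kwargs):
        try:
            log.info("stage %s", name)
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"stage {name!r}: {exc}") from exc

    raw = stage("read_cohort", read_cohort, cohort_path, model, column_map)
    cohort, dropped = stage("complete_case_filter", complete_case_filter, raw)
    if len(cohort) == 0:
        raise ConfigurationError(
            f"no complete cases for the {model} model in {cohort_path} — "
            "wrong model variant or unmapped columns?"
        )
    scores = stage("score_cohort", score_cohort, cohort, model)
    outcomes = cohort.outcomes()

    report = stage("association_report", cohort_association_report, cohort)
    assoc_path = out_dir / "association.tsv"
    report_out = report.copy()
    report_out["p_value"] = report_out["p_value"].map(
        lambda v: "" if pd.isna(v) else format(v, f".{PROB_DECIMALS}f")
    )
    report_out.to_csv(assoc_path, sep="\t", index=False)

    table = stage("calibration_table", calibration_table, scores, outcomes, ci_method)
    cal_path = out_dir / "calibration.tsv"
    cal_out = table.rows.copy()
    for col in ("observed_probability", "ci_low", "ci_high", "mean_predicted"):
        cal_out[col] = cal_out[col].map(
            lambda v: "NA" if pd.isna(v) else format(v, f".{STAT_DECIMALS}f")
        )
    cal_out.to_csv(cal_path, sep="\t", index=False)

    hl = stage("hosmer_lemeshow", hosmer_lemeshow, scores, outcomes, hl_binning, hl_df_policy)
    roc = stage("roc_curve", roc_curve, scores, outcomes)
    roc = stage("auc_ci", auc_with_ci, roc, auc_method)
    roc_path = out_dir / "roc.tsv"
    pd.DataFrame(
        {
            "one_minus_specificity": np.round(roc.points[:, 0], PROB_DECIMALS),
            "sensitivity": np.round(roc.points[:, 1], PROB_DECIMALS),
        }
    ).to_csv(roc_path, sep="\t", index=False)

    prev = stage("prevalence", prevalence, cohort)
    mean_pct, sd_pct = stage("predicted_summary", predicted_summary, scores)

    summary = {
        "model": model,
        "n_read": len(raw),
        "n_complete_cases": len(cohort),
        "n_dropped_incomplete": dropped,
        "prevalence_percent": _round(prev.percent, STAT_DECIMALS),
        "prevalence_fraction": [prev.numerator, prev.denominator],
        "mean_predicted_percent": _round(mean_pct, STAT_DECIMALS),
        "sd_predicted_percent": _round(sd_pct, STAT_DECIMALS),
        "auc": _round(roc.auc, PROB_DECIMALS),
        "auc_ci": [_round(roc.ci_low, PROB_DECIMALS), _round(roc.ci_high, PROB_DECIMALS)],
        "auc_ci_method": roc.method,
        "hl_statistic": _round(hl.statistic, PROB_DECIMALS),
        "hl_df": hl.df,
        "hl_p": _round(hl.p_value, PROB_DECIMALS),
        "hl_binning": hl.binning,
        "ci_method": ci_method,
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    manifest.outputs = sorted(
        p.name for p in (assoc_path, cal_path, roc_path, summary_path)
    ) + ["manifest.json"]
    (out_dir / "manifest.json").write_text(manifest.to_json() + "\n")
    log.info("run complete: %s", out_dir)
    return manifest


def compare_reports(run_a, run_b, tolerance: float = 0.0) -> dict:
    """Field-wise numeric diff of two pipeline output directories.

    Compares ``summary.json`` and every shared TSV cell-by-cell; numeric
    fields differing by more than ``tolerance`` (and any non-numeric
    mismatch) are reported.  Returns an empty dict when the runs agree.
    The manifest timestamp and input paths are not compared.
    """
    run_a, run_b = Path(run_a), Path(run_b)
    diff: dict[str, list] = {}

    man_a = RunManifest.from_json_file(run_a / "manifest.json")
    man_b = RunManifest.from_json_file(run_b / "manifest.json")
    if sorted(man_a.outputs) != sorted(man_b.outputs):
        raise ConfigurationError(
            f"manifests list different outputs: {man_a.outputs} vs {man_b.outputs}"
        )
    if man_a.model != man_b.model:
        raise ConfigurationError("manifests describe different models")

    def numeric(x):
        try:
            return float(x)
        except (TypeError, ValueError):
            return None

    def compare_values(key, va, vb, bucket):
        na, nb = numeric(va), numeric(vb)
        if na is not None and nb is not None:
            if math.isnan(na) and math.isnan(nb):
                return
            if abs(na - nb) > tolerance:
                bucket.append({"field": key, "a": va, "b": vb})
        elif va != vb:
            bucket.append({"field": key, "a": va, "b": vb})

    with open(run_a / "summary.json") as fh:
        sum_a = json.load(fh)
    with open(run_b / "summary.json") as fh:
        sum_b = json.load(fh)
    bucket: list = []
    for key in sorted(set(sum_a) | set(sum_b)):
        va, vb = sum_a.get(key), sum_b.get(key)
        if isinstance(va, list) and isinstance(vb, list) and len(va) == len(vb):
            for i, (xa, xb) in enumerate(zip(va, vb)):
                compare_values(f"{key}[{i}]", xa, xb, bucket)
        else:
            compare_values(key, va, vb, bucket)
    if bucket:
        diff["summary.json"] = bucket

    for name in sorted(set(man_a.outputs) - {"manifest.json", "summary.json"}):
        ta = pd.read_csv(run_a / name, sep="\t", dtype=str, keep_default_na=False)
        tb = pd.read_csv(run_b / name, sep="\t", dtype=str, keep_default_na=False)
        bucket = []
        if ta.shape != tb.shape or list(ta.columns) != list(tb.columns):
            raise ConfigurationError(f"{name}: table schemas differ")
        for col in ta.columns:
            for i, (va, vb) in enumerate(zip(ta[col], tb[col])):
                compare_values(f"{col}@row{i}", va, vb, bucket)
        if bucket:
            diff[name] = bucket
    return diff
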