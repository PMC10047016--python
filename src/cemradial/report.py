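"""End-to-end pipeline orchestration and report artifacts.

``run_pipeline`` wires the stages together — simulate (or load), ingest,
radial features, penalized-LDA cross-validation, and clinical models —
and writes the study-style report bundle: a cohort summary table, a
classification-metric table per task and feature set with paired t-test
comparisons, an odds-ratio table, an AUC comparison table, mean radial
profiles, and figures.  A line-delimited JSON log records seeds,
exclusion counts and penalty selections.  Identical configurations
produce byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .classify import (
    CvResult,
    paired_accuracy_ttest,
    permuted_baseline_cv,
    repeated_cv,
)
from .clinical import (
    ImagingScores,
    covariate_table,
    compare_auc,
    fit_logistic,
    predictive_model,
    roc_from_scores,
)
from .config import RunConfig
from .errors import CemRadialError, DataError
from .ingest import Case, exclusion_filter, read_cohort
from .radial import build_feature_matrix, case_histograms, class_average_profile

_STAGES = ("simulate", "ingest", "features", "classify", "models", "report")


def format_percent(count: int, total: int) -> str:
    """One-decimal percentage, rounded half-up (e.g. 64/159 -> '40.3%')."""
    if total <= 0:
        raise DataError("total must be positive")
    pct = Decimal(100 * count) / Decimal(total)
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)}%"


def summarize_cohort(manifest: pd.DataFrame) -> pd.DataFrame:
    """Demographic / imaging / pathology summary of a cohort manifest.

    One row per item with columns (section, item, value): counts with
    one-decimal percentages for each categorical field, median and IQR
    for age.
    """
    n = len(manifest)
    if n == 0:
        raise DataError("empty manifest")
    rows = []
    age = manifest["age"].astype(float)
    q1, med, q3 = np.percentile(age, [25, 50, 75])
    rows.append(
        {
            "section": "demographics",
            "item": "Age (median (IQR))",
            "value": f"{med:.1f} ({q1:.1f}, {q3:.1f})",
        }
    )
    sections = [
        ("demographics", "race"),
        ("demographics", "history"),
        ("demographics", "menopause"),
        ("imaging", "density_category"),
        ("imaging", "bpe"),
        ("imaging", "finding_category"),
        ("pathology", "class"),
    ]
    for section, col in sections:
        if col not in manifest.columns:
            continue
        counts = manifest[col].value_counts()
        for level, count in counts.items():
            rows.append(
                {
                    "section": section,
                    "item": f"{col}={level}",
                    "value": f"{format_percent(int(count), n)} ({int(count)}/{n})",
                }
            )
    if "invasive_flag" in manifest.columns:
        mal = manifest[manifest["class"] == "malignant"]
        if len(mal):
            inv = int(
                sum(str(v).strip().lower() in ("true", "1") for v in mal["invasive_flag"])
            )
            rows.append(
                {
                    "section": "pathology",
                    "item": "invasive (of malignant)",
                    "value": f"{format_percent(inv, len(mal))} ({inv}/{len(mal)})",
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """Paths and in-memory results of a pipeline run."""

    out_dir: Path
    cohort_summary: pd.DataFrame
    metric_table: pd.DataFrame
    comparison_table: pd.DataFrame
    or_table: pd.DataFrame
    auc_table: pd.DataFrame
    cv_results: dict[tuple[str, str], CvResult]


class _JsonLog:
    def __init__(self, path: Path):
        self._path = path
        self._records: list[dict] = []

    def log(self, stage: str, **fields) -> None:
        self._records.append({"stage": stage, **fields})

    def flush(self) -> None:
        with open(self._path, "w") as fh:
            for rec in self._records:
                fh.write(json.dumps(rec, sort_keys=True, default=str) + "\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(
    config: RunConfig,
    out_dir: Path | str,
    manifest_path: Path | str | None = None,
) -> ReportBundle:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Without ``manifest_path`` a synthetic cohort is generated from
    ``config.cohort`` and written under ``out_dir/cohort``; with it, an
    existing cohort in the manifest layout is loaded instead.  Any stage
    failure raises a stage-named :class:`CemRadialError`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _JsonLog(out / "run_log.jsonl")
    stage = "simulate"
    try:
        if manifest_path is None:
            cohort = synthetic.generate_cohort(config.cohort)
            manifest_path = synthetic.write_cohort(cohort, out / "cohort")
            log.log(stage, seed=config.cohort.seed, n_findings=config.cohort.n_findings)
        stage = "ingest"
        cases = read_cohort(manifest_path)
        manifest = pd.read_csv(manifest_path)
        log.log(stage, n_cases=len(cases))

        stage = "report"
        cohort_summary = summarize_cohort(manifest)
        _write_csv(cohort_summary, out / "cohort_summary.csv")

        stage = "features"
        profiles: dict[str, pd.DataFrame] = {}

        stage = "classify"
        metric_rows = []
        comparison_rows = []
        cv_results: dict[tuple[str, str], CvResult] = {}
        task_data: dict[str, tuple[list[Case], np.ndarray]] = {}
        for task in config.tasks:
            kept, labels, excl = exclusion_filter(
                cases, task, include_atypia_as_benign=config.include_atypia_as_benign
            )
            task_data[task] = (kept, labels)
            log.log(
                "classify",
                task=task,
                n_retained=excl.n_retained,
                dropped=excl.dropped,
            )
            features = {
                fs: build_feature_matrix(kept, labels, fs, config.n_bands)
                for fs in config.feature_sets
            }
            # mean radial profiles per class (density channel view)
            hists = [case_histograms(c, config.n_bands)["density"] for c in kept]
            neg_mean, pos_mean = class_average_profile(hists, labels)
            profiles[task] = pd.DataFrame(
                {
                    "band": np.arange(config.n_bands),
                    "negative_mean": neg_mean,
                    "positive_mean": pos_mean,
                }
            )
            _write_csv(profiles[task], out / f"radial_profiles_{task}.csv")

            for fs in config.feature_sets:
                fm = features[fs]
                res = repeated_cv(
                    fm.X,
                    fm.y,
                    k=config.cv_folds,
                    reps=config.cv_reps,
                    seed=config.seed,
                    feature_set=fs,
                    task=task,
                )
                cv_results[(task, fs)] = res
                log.log(
                    "classify",
                    task=task,
                    feature_set=fs,
                    penalties=sorted(set(res.chosen_penalties)),
                )
            baseline = permuted_baseline_cv(
                features[config.feature_sets[0]].X,
                labels,
                k=config.cv_folds,
                reps=config.cv_reps,
                seed=config.seed,
                feature_set=config.feature_sets[0],
                task=task,
            )
            cv_results[(task, "permuted_baseline")] = baseline
            for fs in (*config.feature_sets, "permuted_baseline"):
                res = cv_results[(task, fs)]
                metric_rows.append(
                    {
                        "task": task,
                        "feature_set": fs,
                        "accuracy_pct": 100 * res.accuracy,
                        **{k: v for k, v in res.summary.items() if k != "accuracy"},
                    }
                )
            pairs = [
                (a, b)
                for i, a in enumerate(config.feature_sets)
                for b in config.feature_sets[i + 1 :]
            ] + [(fs, "permuted_baseline") for fs in config.feature_sets]
            for a, b in pairs:
                tt = paired_accuracy_ttest(
                    cv_results[(task, a)].per_fold_accuracy,
                    cv_results[(task, b)].per_fold_accuracy,
                )
                comparison_rows.append(
                    {
                        "task": task,
                        "arm_a": a,
                        "arm_b": b,
                        "mean_diff": tt.mean_difference,
                        "t": tt.statistic,
                        "p": tt.p_value,
                        "degenerate": tt.degenerate,
                    }
                )
        metric_table = pd.DataFrame(metric_rows)
        comparison_table = pd.DataFrame(comparison_rows)
        _write_csv(metric_table, out / "classification_metrics.csv")
        _write_csv(comparison_table, out / "accuracy_comparisons.csv")

        stage = "models"
        primary = "malignant_vs_benign"
        or_table = pd.DataFrame()
        auc_table = pd.DataFrame()
        if primary in task_data:
            kept, labels = task_data[primary]
            cov = covariate_table(kept)
            uni = fit_logistic(labels, cov, mode="univariable")
            multi = fit_logistic(labels, cov, mode="multivariable")
            uni_t = uni.table.assign(model="univariable")
            multi_t = multi.table.assign(model="multivariable")
            or_table = pd.concat([uni_t, multi_t], ignore_index=True)
            _write_csv(or_table, out / "odds_ratios.csv")
            log.log("models", univariable_converged=uni.converged,
                    multivariable_converged=multi.converged)

            auc_rows = []
            roc_store = {}
            clin_only = predictive_model(
                labels, covariates=cov, cv_folds=config.cv_folds, seed=config.seed
            )
            for fs in config.feature_sets:
                res = cv_results[(primary, fs)]
                scores = ImagingScores(
                    values=res.mean_oof_score, out_of_fold=True, source=fs
                )
                roc_imaging = roc_from_scores(
                    scores.values, labels, provenance=f"{fs} cross-validated score"
                )
                combined = predictive_model(
                    labels,
                    covariates=cov,
                    imaging_scores=scores,
                    cv_folds=config.cv_folds,
                    seed=config.seed,
                )
                cmp_res = compare_auc(combined.roc_cv, roc_imaging, seed=config.seed)
                auc_rows.append(
                    {
                        "feature_set": fs,
                        "auc_without_clinical": roc_imaging.auc,
                        "auc_with_clinical": combined.roc_cv.auc,
                        "auc_with_clinical_apparent": combined.roc_apparent.auc,
                        "p_with_vs_without": cmp_res.p_value,
                    }
                )
                roc_store[fs] = (roc_imaging, combined.roc_cv)
            auc_rows.append(
                {
                    "feature_set": "clinical_only",
                    "auc_without_clinical": float("nan"),
                    "auc_with_clinical": clin_only.roc_cv.auc,
                    "auc_with_clinical_apparent": clin_only.roc_apparent.auc,
                    "p_with_vs_without": float("nan"),
                }
            )
            auc_table = pd.DataFrame(auc_rows)
            _write_csv(auc_table, out / "auc_comparison.csv")

            if config.make_figures:
                _make_figures(out, profiles, metric_table, roc_store)
        log.log("report", status="complete")
        log.flush()
    except CemRadialError as exc:
        log.log(stage, status="failed", error=str(exc))
        log.flush()
        raise CemRadialError(f"stage '{stage}' failed: {exc}") from exc
    return ReportBundle(
        out_dir=out,
        cohort_summary=cohort_summary,
        metric_table=metric_table,
        comparison_table=comparison_table,
        or_table=or_table,
        auc_table=auc_table,
        cv_results=cv_results,
    )


def _make_figures(out: Path, profiles, metric_table, roc_store) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    for task, df in profiles.items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(df["band"], df["negative_mean"], label="negative class")
        ax.plot(df["band"], df["positive_mean"], label="positive class")
        ax.set_xlabel("radial band index")
        ax.set_ylabel("normalized band mass")
        ax.set_title(f"Mean radial profiles: {task}")
        ax.legend()
        fig.tight_layout()
        fig.savefig(figdir / f"radial_profiles_{task}.png", dpi=120)
        plt.close(fig)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for task, sub in metric_table.groupby("task"):
        ax.bar(
            [f"{task[:12]}\n{fs}" for fs in sub["feature_set"]],
            sub["accuracy_pct"],
        )
    ax.set_ylabel("CV accuracy (%)")
    ax.tick_params(axis="x", labelsize=6)
    fig.tight_layout()
    fig.savefig(figdir / "accuracy_summary.png", dpi=120)
    plt.close(fig)
    if roc_store:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
        for fs, (roc_img, roc_comb) in roc_store.items():
            axes[0].plot(roc_img.fpr, roc_img.tpr, label=f"{fs} ({roc_img.auc:.2f})")
            axes[1].plot(
                roc_comb.fpr, roc_comb.tpr, label=f"{fs} ({roc_comb.auc:.2f})"
            )
        for ax, title in zip(axes, ("imaging only", "imaging + clinical")):
            ax.plot([0, 1], [0, 1], "k:", lw=0.8)
            ax.set_title(title)
            ax.set_xlabel("false positive rate")
            ax.legend(fontsize=7)
        axes[0].set_ylabel("true positive rate")
        fig.tight_layout()
        fig.savefig(figdir / "roc_curves.png", dpi=120)
        plt.close(fig)
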