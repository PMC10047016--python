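"""Logistic odds-ratio models, ROC/AUC machinery, and AUC comparison.

Covers the clinical-statistics half of the pipeline: univariable and
multivariable logistic regressions of malignancy on clinical covariates
(age, race, personal history of breast cancer, menopausal status, breast
density, background parenchymal enhancement), predictive models that add
the cross-validated imaging discriminant score, AUC by the Mann-Whitney
identity, and the DeLong test for comparing correlated ROC curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import DataError
from .ingest import Case

#: Covariates entering the odds-ratio regressions (dichotomized coding).
REGRESSION_COVARIATES = ("age", "race_other", "history", "post_menopausal", "dense", "bpe_marked")

#: Covariates entering the combined predictive models (no BPE).
PREDICTIVE_COVARIATES = ("age", "race_other", "history", "post_menopausal", "dense")


def covariate_table(cases: Sequence[Case]) -> pd.DataFrame:
    """Dichotomized covariate design table for a list of cases.

    Race is coded White (0) vs. all other races (1), breast density
    non-dense (0) vs. dense (1), BPE minimal/moderate (0) vs. marked (1),
    menopause pre (0) vs. post (1).
    """
    return pd.DataFrame(
        {
            "age": [c.age for c in cases],
            "race_other": [int(c.race_other) for c in cases],
            "history": [int(c.history) for c in cases],
            "post_menopausal": [int(c.post_menopausal) for c in cases],
            "dense": [int(c.dense) for c in cases],
            "bpe_marked": [int(c.bpe_marked) for c in cases],
        },
        index=[c.case_id for c in cases],
    )


@dataclass
class LogisticFit:
    """Coefficients, odds ratios and Wald CIs of a logistic model.

    ``table`` has one row per term with columns: term, coef, se, or_,
    ci_low, ci_high, p.  Reference categories carry no row.
    """

    table: pd.DataFrame
    mode: str
    converged: bool
    separation_flagged: bool = False

    def odds_ratio(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "or_"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


def _ridge_logit_params(y: np.ndarray, X: pd.DataFrame) -> pd.Series:
    """Weakly ridge-penalized logistic coefficients (separation fallback)."""
    from sklearn.linear_model import LogisticRegression

    cols = [c for c in X.columns if c != "const"]
    lr = LogisticRegression(C=1e3, max_iter=2000)
    lr.fit(X[cols].to_numpy(), y)
    params = pd.Series(0.0, index=X.columns)
    params["const"] = float(lr.intercept_[0])
    params[cols] = lr.coef_[0]
    return params


def _fit_one_logit(
    y: np.ndarray, design: pd.DataFrame
) -> tuple[pd.DataFrame, bool, bool]:
    X = sm.add_constant(design.astype(float), has_constant="add")
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
            params, bse = fit.params, fit.bse
            if not np.all(np.isfinite(bse)) or np.any(bse > 1e3):
                separation = True
        except Exception:
            separation = True
            converged = False
            params = bse = None
    if separation and params is None:
        # penalized fallback keeps coefficients finite; Wald CIs are not
        # meaningful under separation and are reported as NaN
        params = _ridge_logit_params(y, X)
        bse = pd.Series(np.nan, index=params.index)
    rows = []
    for term in design.columns:
        coef = float(params[term])
        se = float(bse[term])
        rows.append(
            {
                "term": term,
                "coef": coef,
                "se": se,
                "or_": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.96 * se)),
                "ci_high": float(np.exp(coef + 1.96 * se)),
                "p": float(2 * stats.norm.sf(abs(coef / se))) if se > 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows), converged, separation


def fit_logistic(
    outcome: np.ndarray,
    covariates: pd.DataFrame,
    mode: str = "multivariable",
) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald odds-ratio CIs.

    ``mode="univariable"`` fits each covariate in a separate model and
    stacks the resulting single-term rows; ``mode="multivariable"`` fits
    them jointly.  Perfect separation is flagged and handled with a small
    ridge penalty (CIs then reported as NaN).
    """
    y = np.asarray(outcome, dtype=int)
    if set(np.unique(y)) != {0, 1}:
        raise DataError("outcome must contain both classes")
    if len(y) != len(covariates):
        raise DataError("outcome and covariate table must align")
    if mode not in ("univariable", "multivariable"):
        raise DataError(f"unknown mode {mode!r}")
    if mode == "univariable":
        tables = []
        converged = True
        separation = False
        for col in covariates.columns:
            t, conv, sep = _fit_one_logit(y, covariates[[col]])
            tables.append(t)
            converged &= conv
            separation |= sep
        table = pd.concat(tables, ignore_index=True)
    else:
        table, converged, separation = _fit_one_logit(y, covariates)
    return LogisticFit(
        table=table, mode=mode, converged=converged, separation_flagged=separation
    )


def auc(scores: np.ndarray, truth: np.ndarray) -> float:
    """AUC by the Mann-Whitney identity: P(random positive outscores a
    random negative), ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("both classes must be present to compute AUC")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: len(pos)].sum()
    return float((r_pos - len(pos) * (len(pos) + 1) / 2.0) / (len(pos) * len(neg)))


@dataclass
class RocCurve:
    """A receiver operating characteristic curve with provenance."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    scores: np.ndarray
    truth: np.ndarray
    provenance: str = ""


def roc_from_scores(
    scores: np.ndarray, truth: np.ndarray, provenance: str = ""
) -> RocCurve:
    """Build a ROC curve; the stored AUC is the Mann-Whitney value, which
    equals the trapezoidal integral of the curve."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores)
    return RocCurve(
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        auc=auc(scores, truth),
        scores=scores,
        truth=truth,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# DeLong test for correlated ROC curves
# ---------------------------------------------------------------------------

def _delong_components(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values (structural components) of one classifier."""
    pos = scores[truth == 1]
    neg = scores[truth == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-positive placements
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative placements
    return v10, v01, float(v10.mean())


@dataclass
class AucComparison:
    """Result of comparing two AUCs."""

    auc_a: float
    auc_b: float
    statistic: float
    p_value: float
    method: str


def compare_auc(
    roc_a: RocCurve,
    roc_b: RocCurve,
    paired: bool = True,
    n_boot: int = 2000,
    seed: int = 0,
) -> AucComparison:
    """DeLong test for the difference between two AUCs.

    Paired mode (default) requires both curves to be computed on the same
    cases, i.e. identical truth vectors, and uses the covariance of the
    placement values; a seeded bootstrap over cases (``n_boot``
    resamples) is used as fallback when the DeLong variance estimate
    degenerates.  Identical score vectors give statistic 0 and p = 1.
    """
    ta = np.asarray(roc_a.truth, dtype=int)
    tb = np.asarray(roc_b.truth, dtype=int)
    if paired:
        if len(ta) != len(tb) or not np.array_equal(ta, tb):
            raise DataError("paired comparison requires identical case sets")
    diff = roc_a.auc - roc_b.auc
    v10_a, v01_a, _ = _delong_components(roc_a.scores, ta)
    v10_b, v01_b, _ = _delong_components(roc_b.scores, tb)
    m, n = len(v10_a), len(v01_a)
    var_a = v10_a.var(ddof=1) / m + v01_a.var(ddof=1) / n
    var_b = v10_b.var(ddof=1) / m + v01_b.var(ddof=1) / n
    if paired:
        cov = (
            np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
            + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
        )
        var = var_a + var_b - 2 * cov
    else:
        var = var_a + var_b
    if diff == 0:
        return AucComparison(roc_a.auc, roc_b.auc, 0.0, 1.0, "delong")
    if var <= 0 or not np.isfinite(var):
        return _bootstrap_compare(roc_a, roc_b, n_boot=n_boot, seed=seed)
    z = diff / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return AucComparison(roc_a.auc, roc_b.auc, float(z), p, "delong")


def _bootstrap_compare(
    roc_a: RocCurve, roc_b: RocCurve, n_boot: int, seed: int
) -> AucComparison:
    """Seeded paired bootstrap of the AUC difference (fallback)."""
    rng = np.random.default_rng(seed)
    truth = roc_a.truth
    n = len(truth)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t = truth[idx]
        if len(np.unique(t)) < 2:
            continue
        diffs.append(auc(roc_a.scores[idx], t) - auc(roc_b.scores[idx], t))
    diffs = np.asarray(diffs)
    observed = roc_a.auc - roc_b.auc
    se = diffs.std(ddof=1)
    if se == 0:
        return AucComparison(roc_a.auc, roc_b.auc, 0.0, 1.0, "bootstrap")
    z = observed / se
    p = float(2 * stats.norm.sf(abs(z)))
    return AucComparison(roc_a.auc, roc_b.auc, float(z), p, "bootstrap")


# ---------------------------------------------------------------------------
# Combined imaging + clinical predictive models
# ---------------------------------------------------------------------------

@dataclass
class ImagingScores:
    """Per-case continuous imaging scores with provenance.

    ``out_of_fold`` must be True for scores entering a predictive model:
    each case's score must come from cross-validation folds that did not
    train on it.
    """

    values: np.ndarray
    out_of_fold: bool
    source: str = ""


@dataclass
class PredictiveModel:
    """A fitted predictive model with apparent and cross-validated ROC."""

    fit: LogisticFit
    roc_cv: RocCurve
    roc_apparent: RocCurve
    terms: tuple[str, ...]


def _cv_probabilities(
    y: np.ndarray, design: pd.DataFrame, k: int, seed: int
) -> np.ndarray:
    """Out-of-fold predicted probabilities of a logistic model."""
    probs = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    Xf = design.astype(float)
    for train, test in skf.split(Xf, y):
        Xtr = sm.add_constant(Xf.iloc[train], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y[train], Xtr).fit(disp=0, maxiter=200)
                params = fit.params
                if not np.all(np.isfinite(params)):
                    raise ValueError("non-finite coefficients")
            except Exception:
                params = _ridge_logit_params(y[train], Xtr)
        Xt = sm.add_constant(Xf.iloc[test], has_constant="add")
        eta = Xt.to_numpy() @ params.to_numpy()
        probs[test] = 1.0 / (1.0 + np.exp(-eta))
    return probs


def predictive_model(
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    imaging_scores: ImagingScores | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> PredictiveModel:
    """Fit a predictive logistic model and compute its ROC curves.

    Any combination of clinical covariates (age, race, history,
    menopause, breast density) and a continuous cross-validated imaging
    score is accepted; at least one must be given.  In-fold imaging
    scores are rejected to prevent optimistic AUCs.  The headline ROC is
    computed from out-of-fold predicted probabilities of the model
    itself; the apparent (in-sample) ROC is reported alongside.
    """
    y = np.asarray(outcome, dtype=int)
    parts = []
    if imaging_scores is not None:
        if not imaging_scores.out_of_fold:
            raise DataError(
                "imaging scores must be out-of-fold cross-validated scores; "
                "in-fold scores would inflate the AUC"
            )
        if len(imaging_scores.values) != len(y):
            raise DataError("imaging scores and outcome must align")
        parts.append(
            pd.DataFrame({"imaging_score": np.asarray(imaging_scores.values, float)})
        )
    if covariates is not None:
        cols = [c for c in PREDICTIVE_COVARIATES if c in covariates.columns]
        parts.append(covariates[cols].reset_index(drop=True))
    if not parts:
        raise DataError("need imaging scores, covariates, or both")
    design = pd.concat(parts, axis=1)
    fit = fit_logistic(y, design, mode="multivariable")
    X = sm.add_constant(design.astype(float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = full.params
            if not np.all(np.isfinite(params)):
                raise ValueError("non-finite coefficients")
        except Exception:
            params = _ridge_logit_params(y, X)
    eta_app = X.to_numpy() @ params.to_numpy()
    probs_app = 1.0 / (1.0 + np.exp(-eta_app))
    probs_cv = _cv_probabilities(y, design, cv_folds, seed)
    return PredictiveModel(
        fit=fit,
        roc_cv=roc_from_scores(probs_cv, y, provenance="cross-validated"),
        roc_apparent=roc_from_scores(probs_app, y, provenance="apparent"),
        terms=tuple(design.columns),
    )
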