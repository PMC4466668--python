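"""Evaluation battery: ROC/AUC with significance and CI, Welch t-test,
Spearman rank correlation, and logistic regression with odds ratios.

AUC is the Mann-Whitney statistic (concordant + half-tied pairs over
n_pos * n_neg); its significance against AUC = 0.5 uses exact enumeration
of the U distribution for small tie-free problems (n_pos * n_neg <= 400)
and the tie-corrected normal approximation otherwise; the confidence
interval uses the DeLong rank-variance estimator. Logistic models are
maximum-likelihood fits (IRLS via statsmodels) with Wald intervals on the
odds-ratio scale. All p-values are two-sided.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ROCResult",
    "TestResult",
    "LogisticModel",
    "roc_auc",
    "welch_t_test",
    "spearman",
    "fit_logistic",
    "standardize_score_for_regression",
]


@dataclass
class ROCResult:
    auc: float
    p_value: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    orientation: str = "higher score => positive class"
    p_method: str = "exact"

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValidationError("AUC outside [0, 1]")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValidationError("both classes must be present")


@dataclass
class TestResult:
    statistic: float
    p_value: float
    estimate: float
    n: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError("p-value outside [0, 1]")


@dataclass
class LogisticModel:
    terms: list[str]
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    ci95: np.ndarray  # (n_terms, 2) on the OR scale
    p_values: np.ndarray
    converged: bool
    n: int
    separation: bool = False


def _delong_variance(pos: np.ndarray, neg: np.ndarray, auc: float) -> float:
    """DeLong rank-variance of the AUC via placement values."""
    # placement of each positive among negatives, and vice versa
    v10 = np.array([(np.sum(x > neg) + 0.5 * np.sum(x == neg)) / len(neg) for x in pos])
    v01 = np.array([(np.sum(pos > y) + 0.5 * np.sum(pos == y)) / len(pos) for y in neg])
    s10 = v10.var(ddof=1) if len(pos) > 1 else 0.0
    s01 = v01.var(ddof=1) if len(neg) > 1 else 0.0
    return s10 / len(pos) + s01 / len(neg)


def roc_auc(scores, labels, *, positive: int = 1, exact_limit: int = 400) -> ROCResult:
    """AUC with two-sided significance against 0.5 and a DeLong 95% CI.

    ``labels`` are binary; the class equal to ``positive`` is the positive
    class (under the pipeline's orientation contract: resistant /
    non-responder / mutant scores higher). AUC is computed by midrank
    pair-counting; p comes from exact Mann-Whitney enumeration when
    n_pos * n_neg <= ``exact_limit`` and scores are tie-free, else from the
    tie-corrected normal approximation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must align")
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError("one class is absent")

    ranks = sps.rankdata(scores)  # midranks
    u = float(ranks[labels == positive].sum() - len(pos) * (len(pos) + 1) / 2)
    auc = u / (len(pos) * len(neg))

    has_ties = len(np.unique(scores)) < len(scores)
    if len(pos) * len(neg) <= exact_limit and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(pos, neg, alternative="two-sided", method=method)
    p = float(res.pvalue)

    var = _delong_variance(pos, neg, auc)
    half = 1.959963984540054 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return ROCResult(auc, p, ci, len(pos), len(neg), p_method=method)


def welch_t_test(a, b) -> TestResult:
    """Welch two-sample t with Satterthwaite df, two-sided.

    Degenerate inputs (zero variance in both groups) are handled
    explicitly: equal means give t = 0, p = 1; unequal means give an
    infinite statistic with p = 0, flagged degenerate.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs at least 2 observations")
    est = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return TestResult(0.0, 1.0, est, len(a) + len(b), degenerate=True)
        return TestResult(np.inf if est > 0 else -np.inf, 0.0, est, len(a) + len(b), degenerate=True)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(t), float(p), est, len(a) + len(b))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (midranks for ties), two-sided p via the
    t-approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("samples must have equal length")
    if len(x) < 4:
        raise ValidationError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for a constant sample")
    rho, p = sps.spearmanr(x, y)
    return TestResult(float(rho), float(p), float(rho), len(x))


def standardize_score_for_regression(scores) -> np.ndarray:
    """Center and scale scores to unit standard deviation (ddof=1), so
    logistic odds ratios are reported per SD of the score."""
    scores = np.asarray(scores, dtype=float)
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValidationError("cannot standardize constant scores")
    return (scores - scores.mean()) / sd


def _check_design(x: pd.DataFrame) -> None:
    for col in x.columns:
        if x[col].nunique() <= 1:
            raise ValidationError(f"constant covariate {col!r}")
    mat = np.column_stack([np.ones(len(x)), x.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # identify an offending pair by pairwise correlation
        corr = np.corrcoef(x.to_numpy(dtype=float), rowvar=False)
        worst = None
        if corr.ndim == 2:
            iu = np.triu_indices(corr.shape[0], k=1)
            if len(iu[0]):
                k = int(np.nanargmax(np.abs(corr[iu])))
                worst = (x.columns[iu[0][k]], x.columns[iu[1][k]])
        raise ValidationError(f"singular design matrix; collinear terms: {worst}")


def fit_logistic(outcome, covariates: pd.DataFrame) -> LogisticModel:
    """Maximum-likelihood logistic regression with Wald odds-ratio CIs.

    Perfect separation is flagged (``separation=True``, ``converged=False``)
    rather than reported as silently huge coefficients; a singular design
    raises, naming the collinear terms.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(outcome, dtype=float)
    x = covariates.copy()
    if len(y) != len(x):
        raise ValidationError("outcome and covariates must align")
    if len(y) <= x.shape[1] + 1:
        raise ValidationError("too few observations for the number of terms")
    _check_design(x)

    design = sm.add_constant(x.astype(float), has_constant="add")
    terms = list(design.columns)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200, method="newton", tol=1e-10)
        params = fit.params.to_numpy()
        bse = fit.bse.to_numpy()
        pvals = fit.pvalues.to_numpy()
        converged = bool(fit.mle_retvals.get("converged", True))
        separation = bool(np.any(np.abs(params) > 15))
        if separation:
            converged = False
    except (PerfectSeparationError, np.linalg.LinAlgError):
        k = design.shape[1]
        params = np.full(k, np.nan)
        bse = np.full(k, np.nan)
        pvals = np.full(k, np.nan)
        converged, separation = False, True

    z = 1.959963984540054
    lo = np.exp(params - z * bse)
    hi = np.exp(params + z * bse)
    return LogisticModel(
        terms=terms,
        coefficients=params,
        odds_ratios=np.exp(params),
        ci95=np.column_stack([lo, hi]),
        p_values=pvals,
        converged=converged,
        n=len(y),
        separation=separation,
    )
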