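"""Nearest-shrunken-centroids (PAM) classification with cross-validated
threshold selection.

Per gene g and class k, the standardised centroid difference is

    d_gk = (xbar_gk - xbar_g) / (m_k * (s_g + s0)),   m_k = sqrt(1/n_k - 1/n)

where s_g is the pooled within-class standard deviation and s0 a fudge
constant (median of s_g). Soft-thresholding d'_gk = sign(d_gk) *
max(|d_gk| - delta, 0) shrinks class centroids toward the overall
centroid, x'_gk = xbar_g + m_k (s_g + s0) d'_gk; genes whose differences
shrink to zero in every class drop out of the classifier, yielding a
sparse signature. Classification minimises the penalised distance

    delta_k(x) = sum_g (x_g - x'_gk)^2 / (s_g + s0)^2  -  2 log pi_k.

Threshold selection runs stratified k-fold cross-validation over a delta
grid and, by default, applies the one-standard-error rule: the LARGEST
delta whose CV error is within one SE of the minimum, i.e. the sparsest
competitive model. Plain minimum-error selection is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "ShrunkenCentroidModel",
    "CrossValResult",
    "fit_shrunken_centroids",
    "pam_discriminant",
    "pam_predict",
    "pam_signature_scores",
    "cross_validate_pam",
    "default_delta_grid",
]


@dataclass
class ShrunkenCentroidModel:
    classes: list
    gene_ids: list[str]
    overall_centroid: np.ndarray  # (g,)
    class_centroids_shrunken: np.ndarray  # (k, g)
    pooled_sd: np.ndarray  # (g,)
    s0: float
    delta: float
    priors: np.ndarray  # (k,)
    d_unshrunken: np.ndarray  # (k, g) standardised differences before thresholding
    dprime: np.ndarray  # (k, g) after soft-thresholding at `delta`
    m_k: np.ndarray  # (k,)

    @property
    def selected_genes(self) -> list[str]:
        mask = np.any(self.dprime != 0.0, axis=0)
        return [g for g, m in zip(self.gene_ids, mask) if m]

    def at_delta(self, delta: float) -> "ShrunkenCentroidModel":
        """Re-threshold this fit at a new delta (no moment refitting)."""
        if delta < 0:
            raise ValidationError("delta must be non-negative")
        dprime = np.sign(self.d_unshrunken) * np.maximum(np.abs(self.d_unshrunken) - delta, 0.0)
        mk_s = self.m_k[:, None] * (self.pooled_sd + self.s0)[None, :]
        shrunken = self.overall_centroid[None, :] + mk_s * dprime
        return ShrunkenCentroidModel(
            classes=self.classes,
            gene_ids=self.gene_ids,
            overall_centroid=self.overall_centroid,
            class_centroids_shrunken=shrunken,
            pooled_sd=self.pooled_sd,
            s0=self.s0,
            delta=float(delta),
            priors=self.priors,
            d_unshrunken=self.d_unshrunken,
            dprime=dprime,
            m_k=self.m_k,
        )


@dataclass
class CrossValResult:
    delta_grid: np.ndarray
    cv_error: np.ndarray
    cv_se: np.ndarray
    chosen_delta: float
    fold_assignments: np.ndarray
    model: ShrunkenCentroidModel
    n_selected: np.ndarray  # genes surviving at each delta (full-data fit)


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, ExpressionMatrix):
        return X.values, list(X.gene_ids)
    arr = np.asarray(X, dtype=float)
    return arr, [f"g{i}" for i in range(arr.shape[0])]


def fit_shrunken_centroids(X, y, delta: float = 0.0, *, priors: str = "empirical") -> ShrunkenCentroidModel:
    """Fit the shrunken-centroid model at threshold ``delta``.

    ``X`` is genes x samples (ExpressionMatrix or array); ``y`` one label
    per sample, each class with at least 2 samples. ``priors`` is
    ``"empirical"`` (class frequencies) or ``"uniform"``.
    """
    values, gene_ids = _as_matrix(X)
    y = np.asarray(y)
    if delta < 0:
        raise ValidationError("delta must be non-negative")
    if values.shape[1] != len(y):
        raise ValidationError("label vector must align with samples")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes")
    n = len(y)

    n_k = np.array([int(np.sum(y == c)) for c in classes])
    if np.any(n_k < 2):
        bad = [c for c, nk in zip(classes, n_k) if nk < 2]
        raise ValidationError(f"classes with fewer than 2 samples: {bad}")

    overall = values.mean(axis=1)
    centroids = np.stack([values[:, y == c].mean(axis=1) for c in classes])  # (k, g)

    # pooled within-class variance with n - K degrees of freedom
    ss = np.zeros(values.shape[0])
    for i, c in enumerate(classes):
        resid = values[:, y == c] - centroids[i][:, None]
        ss += (resid**2).sum(axis=1)
    pooled_sd = np.sqrt(ss / (n - len(classes)))
    s0 = float(np.median(pooled_sd))
    denom_sd = pooled_sd + s0
    if np.any(denom_sd == 0):
        raise ValidationError("degenerate data: s_g + s0 = 0 for some gene")

    m_k = np.sqrt(1.0 / n_k - 1.0 / n)  # (k,)
    d = (centroids - overall[None, :]) / (m_k[:, None] * denom_sd[None, :])

    if priors == "empirical":
        pri = n_k / n
    elif priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValidationError("priors must be 'empirical' or 'uniform'")

    base = ShrunkenCentroidModel(
        classes=classes,
        gene_ids=gene_ids,
        overall_centroid=overall,
        class_centroids_shrunken=centroids,  # provisional; replaced by at_delta
        pooled_sd=pooled_sd,
        s0=s0,
        delta=0.0,
        priors=pri,
        d_unshrunken=d,
        dprime=d,
        m_k=m_k,
    )
    return base.at_delta(delta)


def _class_scores(model: ShrunkenCentroidModel, values: np.ndarray) -> np.ndarray:
    """Penalised distances, shape (k, n_samples)."""
    denom = (model.pooled_sd + model.s0) ** 2
    diffs = (values[None, :, :] - model.class_centroids_shrunken[:, :, None]) ** 2 / denom[None, :, None]
    return diffs.sum(axis=1) - 2.0 * np.log(model.priors)[:, None]


def _align(model: ShrunkenCentroidModel, X) -> np.ndarray:
    values, gene_ids = _as_matrix(X)
    if gene_ids != model.gene_ids:
        idx = {g: i for i, g in enumerate(gene_ids)}
        if not all(g in idx for g in model.gene_ids):
            raise ValidationError("matrix does not cover model genes")
        values = values[[idx[g] for g in model.gene_ids]]
    return values


def pam_discriminant(model: ShrunkenCentroidModel, x, *, positive_class=None) -> dict:
    """Class scores and prediction for one per-gene profile.

    ``x`` may be a dict keyed by gene id or an array aligned with the
    model's genes; genes missing from a dict profile are imputed at the
    overall centroid (count reported). Returns all class scores, the
    argmin prediction (ties broken by class label order and flagged) and,
    for two-class models, a scalar ``signature_score`` = delta(negative) -
    delta(positive), oriented so higher means more positive-class-like
    (the mutant class, under the pipeline's labels).
    """
    if isinstance(x, dict):
        n_missing = sum(1 for g in model.gene_ids if g not in x)
        if n_missing:
            log.info("%d model genes missing from profile; imputed at overall centroid", n_missing)
        vec = np.array(
            [x.get(g, model.overall_centroid[i]) for i, g in enumerate(model.gene_ids)], dtype=float
        )
    else:
        vec = np.asarray(x, dtype=float)
        if vec.shape != model.overall_centroid.shape:
            raise ValidationError("profile length must match model genes")

    scores = _class_scores(model, vec[:, None])[:, 0]
    best = float(np.min(scores))
    winners = [c for c, s in zip(model.classes, scores) if np.isclose(s, best, rtol=0.0, atol=1e-12)]
    tie = len(winners) > 1
    if tie:
        log.warning("discriminant tie among classes %s; broken by label order", winners)

    out = {"scores": dict(zip(model.classes, scores.tolist())), "predicted": winners[0], "tie": tie}
    if len(model.classes) == 2:
        pos = positive_class if positive_class is not None else model.classes[-1]
        if pos not in model.classes:
            raise ValidationError(f"positive_class {pos!r} not among model classes")
        neg = next(c for c in model.classes if c != pos)
        out["signature_score"] = float(out["scores"][neg] - out["scores"][pos])
        out["positive_class"] = pos
    return out


def pam_predict(model: ShrunkenCentroidModel, X) -> np.ndarray:
    """Argmin-prediction for a genes x samples matrix (ties: label order)."""
    scores = _class_scores(model, _align(model, X))
    return np.array(model.classes)[np.argmin(scores, axis=0)]


def pam_signature_scores(model: ShrunkenCentroidModel, X, *, positive_class=None) -> np.ndarray:
    """Two-class per-sample signature score: delta(neg) - delta(pos);
    higher = more positive-class-like."""
    if len(model.classes) != 2:
        raise ValidationError("signature scores require a two-class model")
    pos = positive_class if positive_class is not None else model.classes[-1]
    if pos not in model.classes:
        raise ValidationError(f"positive_class {pos!r} not among model classes")
    scores = _class_scores(model, _align(model, X))
    i_pos = model.classes.index(pos)
    i_neg = 1 - i_pos
    return scores[i_neg] - scores[i_pos]


def default_delta_grid(X, y, n_points: int = 30) -> np.ndarray:
    """Evenly spaced thresholds from 0 to the largest |d_gk| of the
    unshrunken full-data fit (beyond which every gene vanishes)."""
    base = fit_shrunken_centroids(X, y, delta=0.0)
    return np.linspace(0.0, float(np.max(np.abs(base.d_unshrunken))), n_points)


def cross_validate_pam(
    X,
    y,
    n_folds: int = 10,
    delta_grid=None,
    *,
    seed: int = 0,
    selection: str = "one_se",
    priors: str = "empirical",
) -> CrossValResult:
    """Select the shrinkage threshold by stratified k-fold CV and refit.

    ``selection='one_se'`` (default) picks the largest delta whose CV
    misclassification is within one standard error of the minimum — the
    sparsest competitive model; ``'min'`` picks the minimum error (ties
    toward larger delta). Folds come from a seeded stratified splitter and
    are returned for reproducibility. The final model is refit on all data
    at the chosen delta.
    """
    from sklearn.model_selection import StratifiedKFold

    values, gene_ids = _as_matrix(X)
    y = np.asarray(y)
    n = len(y)
    if n < n_folds:
        raise ValidationError("need at least as many samples as folds")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < n_folds):
        raise ValidationError(
            f"class sizes {counts.tolist()} are too small for {n_folds}-fold stratified CV; "
            "use fewer folds"
        )
    if selection not in ("one_se", "min"):
        raise ValidationError("selection must be 'one_se' or 'min'")

    if delta_grid is None:
        delta_grid = default_delta_grid(values, y)
    delta_grid = np.asarray(delta_grid, dtype=float)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    fold_errors = np.zeros((n_folds, len(delta_grid)))
    fold_sizes = np.zeros(n_folds)
    for f, (train, test) in enumerate(skf.split(values.T, y)):
        folds[test] = f
        fold_sizes[f] = len(test)
        if len(np.unique(y[train])) < len(classes):
            raise ValidationError("a training fold lost a class; use fewer folds")
        base = fit_shrunken_centroids(values[:, train], y[train], delta=0.0, priors=priors)
        for j, d in enumerate(delta_grid):
            pred = pam_predict(base.at_delta(d), values[:, test])
            fold_errors[f, j] = float(np.mean(pred != y[test]))

    cv_error = (fold_sizes / n) @ fold_errors
    cv_se = fold_errors.std(axis=0, ddof=1) / np.sqrt(n_folds)

    full = fit_shrunken_centroids(values, y, delta=0.0, priors=priors)
    full.gene_ids = gene_ids
    n_selected = np.array(
        [int(np.any(np.abs(full.d_unshrunken) > d, axis=0).sum()) for d in delta_grid]
    )

    # a 0-gene model is prior-only and degenerate; never select it
    viable = np.flatnonzero(n_selected >= 1)
    j_min = int(viable[np.argmin(cv_error[viable])])
    if selection == "min":
        minima = viable[np.isclose(cv_error[viable], cv_error[j_min])]
        chosen = float(delta_grid[minima[-1]])
    else:
        cutoff = cv_error[j_min] + cv_se[j_min]
        ok = viable[cv_error[viable] <= cutoff + 1e-12]
        chosen = float(delta_grid[ok[-1]])
    return CrossValResult(delta_grid, cv_error, cv_se, chosen, folds, full.at_delta(chosen), n_selected)
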