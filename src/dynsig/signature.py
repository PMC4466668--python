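"""Per-tumor module-change scoring and the pre-treatment Response Signature.

A tumor's module change score is the mean log2 fold change over the
module's genes; its sign classifies the tumor as up- or down-regulating
the module after treatment. The Response Signature (RS) is derived from
the pre-treatment profiles of the most extreme tumors at either end of
that ranking: the ``n_genes`` genes with the largest |two-sample
statistic| between the top-``k_extreme`` (up) and bottom-``k_extreme``
(down) groups, each weighted by the sign of its statistic (+1 = higher
pre-treatment expression in module-up-regulating tumors).

Scoring contract: ``score_samples`` returns a per-sample mean of
direction-weighted gene z-scores, oriented so that a HIGHER score predicts
module DOWN-regulation and hence resistance to treatment. The +1 weights
(up-group-high genes) are therefore negated internally; the orientation is
recorded on the returned series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import ExpressionMatrix, GeneSignature, PairedCohort, ValidationError
from .module_discovery import FoldChangeMatrix, WeightedModule
from .stats_eval import TestResult, spearman

log = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "ModuleChangeProfile",
    "module_change_score",
    "correlate_level_vs_change",
    "derive_response_signature",
    "score_samples",
]

SCORE_ORIENTATION = "higher score => predicted module down-regulation => predicted resistance"


@dataclass
class ModuleChangeProfile:
    """Per-tumor mean module fold change and its direction class."""

    tumor_ids: list[str]
    change_score: np.ndarray
    direction_class: list[str]

    def __post_init__(self) -> None:
        self.change_score = np.asarray(self.change_score, dtype=float)
        if self.change_score.shape != (len(self.tumor_ids),):
            raise ValidationError("change_score must align with tumor_ids")
        if not np.all(np.isfinite(self.change_score)):
            raise ValidationError("non-finite change scores")
        if any(c not in ("up", "down", "zero") for c in self.direction_class):
            raise ValidationError("direction_class entries must be up/down/zero")


def module_change_score(module: WeightedModule, fcm: FoldChangeMatrix) -> ModuleChangeProfile:
    """Mean log2 FC over module genes, per tumor; class = sign of the mean.

    Module genes absent from the fold-change matrix are reported and
    skipped; it is an error for none to be present.
    """
    idx = {g: i for i, g in enumerate(fcm.gene_ids)}
    present = [g for g in module.genes if g in idx]
    missing = [g for g in module.genes if g not in idx]
    if missing:
        log.info("%d module genes absent from fold-change matrix; skipped", len(missing))
    if not present:
        raise ValidationError("no module gene present in the fold-change matrix")
    scores = fcm.values[[idx[g] for g in present]].mean(axis=0)
    classes = ["up" if s > 0 else ("down" if s < 0 else "zero") for s in scores]
    return ModuleChangeProfile(list(fcm.tumor_ids), scores, classes)


def correlate_level_vs_change(
    module: WeightedModule, cohort: PairedCohort, profile: ModuleChangeProfile
) -> TestResult:
    """Spearman correlation between per-tumor mean pre-treatment module
    expression and the module change score (two-sided p).

    Used to check that how much a tumor expresses the module at baseline
    does not determine which way treatment moves it.
    """
    if profile.tumor_ids != cohort.tumor_ids:
        raise ValidationError("profile and cohort tumor ids differ")
    if cohort.n_tumors < 4:
        raise ValidationError("need at least 4 tumors for a usable p-value")
    idx = {g: i for i, g in enumerate(cohort.gene_ids)}
    rows = [idx[g] for g in module.genes if g in idx]
    if not rows:
        raise ValidationError("no module gene present in the cohort")
    pre_level = cohort.pre.values[rows].mean(axis=0)
    return spearman(pre_level, profile.change_score)


def _welch_statistics(up: np.ndarray, down: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistics (up minus down); zero where both groups
    are constant with equal means."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t, _ = sps.ttest_ind(up, down, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    t[~np.isfinite(t)] = np.where(
        np.isclose(up.mean(axis=1), down.mean(axis=1)), 0.0, np.inf
    )[~np.isfinite(t)]
    return t


def derive_response_signature(
    cohort: PairedCohort,
    profile: ModuleChangeProfile,
    k_extreme: int = 6,
    n_genes: int = 10,
    statistic: str = "welch_t",
) -> GeneSignature:
    """Derive the RS from the pre-treatment profiles of extreme tumors.

    Tumors are ranked by change score; the ``k_extreme`` highest form the
    up-group and the ``k_extreme`` lowest the down-group. Each gene gets a
    two-sample statistic (Welch t by default; plain mean difference via
    ``statistic='mean_diff'``) on pre-treatment expression, up minus down;
    the ``n_genes`` genes of largest |statistic| are returned with weight
    sign(statistic). Ties at the cutoff resolve by gene identifier, so the
    result is independent of tumor and gene input order.
    """
    n = cohort.n_tumors
    if 2 * k_extreme > n:
        raise ValidationError(f"2*k_extreme = {2 * k_extreme} exceeds cohort size {n}")
    if n_genes > cohort.pre.n_genes:
        raise ValidationError("n_genes exceeds the number of genes in the cohort")
    if statistic not in ("welch_t", "mean_diff"):
        raise ValidationError("statistic must be 'welch_t' or 'mean_diff'")
    if profile.tumor_ids != cohort.tumor_ids:
        raise ValidationError("profile and cohort tumor ids differ")

    # stable ranking: ties in change score resolve by tumor id
    order = sorted(range(n), key=lambda i: (-profile.change_score[i], cohort.tumor_ids[i]))
    up_idx = [order[i] for i in range(k_extreme)]
    down_idx = [order[n - 1 - i] for i in range(k_extreme)]

    pre = cohort.pre.values
    up, down = pre[:, up_idx], pre[:, down_idx]
    if statistic == "welch_t":
        stat = _welch_statistics(up, down)
    else:
        stat = up.mean(axis=1) - down.mean(axis=1)

    genes = np.array(cohort.gene_ids)
    # largest |stat| first; ties by identifier
    pick = sorted(range(len(genes)), key=lambda i: (-abs(stat[i]), genes[i]))[:n_genes]
    weights = [1 if stat[i] >= 0 else -1 for i in pick]
    return GeneSignature("RS", [genes[i] for i in pick], weights)


def score_samples(sig: GeneSignature, matrix: ExpressionMatrix) -> pd.Series:
    """Mean direction-weighted z-score per sample, oriented so higher =
    predicted resistance.

    Genes are z-scored across the cohort's samples (ddof=1), making the
    score invariant to per-gene affine rescaling of the input; constant
    genes contribute 0 and are flagged. Signature genes absent from the
    matrix reduce coverage (reported); at least one must be present.
    """
    idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    present = [(g, w) for g, w in zip(sig.genes, sig.weights) if g in idx]
    if not present:
        raise ValidationError("no signature gene present in the matrix")
    coverage = len(present) / len(sig.genes)
    if coverage < 1.0:
        log.info("signature coverage %.0f%% (%d/%d genes)", 100 * coverage, len(present), len(sig.genes))

    rows = matrix.values[[idx[g] for g, _ in present]]
    mu = rows.mean(axis=1, keepdims=True)
    sd = rows.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        log.warning("%d signature genes constant across samples; contribute 0", int(constant.sum()))
    sd[sd == 0] = 1.0
    z = (rows - mu) / sd
    z[constant] = 0.0

    # +1 weights mark genes high in module-UP tumors (predicted responders);
    # negate so that higher score predicts down-regulation / resistance.
    w = -np.array([w for _, w in present], dtype=float)
    scores = (w[:, None] * z).mean(axis=0)
    out = pd.Series(scores, index=matrix.sample_ids, name=sig.name)
    out.attrs["orientation"] = SCORE_ORIENTATION
    out.attrs["coverage"] = coverage
    return out
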