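"""End-to-end orchestration with seeded reproducibility and a hashed
artifact manifest.

``run_discovery_pipeline`` executes fold-change computation, responsive
gene selection, network weighting, module detection and filtering, module
change profiling, Response Signature derivation, pre-treatment scoring,
and evaluation, writing every intermediate artifact plus a manifest
(parameter echo, seed, per-stage counts, sha256 of each artifact).
``run_p53_pipeline`` trains the shrunken-centroid classifier with
cross-validated threshold selection on a labelled training split, scores
the held-out samples, and evaluates by t-test and ROC.

Artifacts are written with fixed float formatting and sorted JSON keys,
so identical inputs and seed reproduce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import module_discovery as md
from . import signature as sig
from . import stats_eval as se
from .core_io import (
    ExpressionMatrix,
    GeneSignature,
    InteractionNetwork,
    PairedCohort,
    ValidationError,
    write_expression_matrix,
    write_gene_signature,
)
from .pam_classifier import cross_validate_pam, pam_signature_scores

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_discovery_pipeline", "run_p53_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Parameters of one pipeline run; mirrors the per-module parameter types."""

    out_dir: str = "run"
    seed: int = 0
    discovery: md.DiscoveryParams = field(default_factory=md.DiscoveryParams)
    k_extreme: int = 6
    n_signature_genes: int = 10
    rs_statistic: str = "welch_t"
    pam_folds: int = 10
    pam_selection: str = "one_se"
    pam_priors: str = "empirical"
    n_train: int | None = None  # p53 pipeline training-split size

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        disc = md.DiscoveryParams(**raw.pop("discovery", {}))
        return cls(discovery=disc, **raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_tsv(frame: pd.DataFrame, path: Path, index_label: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        frame.to_csv(fh, sep="\t", index_label=index_label, float_format="%.10g", lineterminator="\n")


def _roc_to_dict(r: se.ROCResult) -> dict:
    return {
        "auc": r.auc,
        "p_value": r.p_value,
        "ci95": list(r.ci95),
        "n_pos": r.n_pos,
        "n_neg": r.n_neg,
        "p_method": r.p_method,
        "orientation": r.orientation,
    }


def _test_to_dict(t: se.TestResult) -> dict:
    return {"statistic": t.statistic, "p_value": t.p_value, "estimate": t.estimate, "n": t.n}


def _logistic_to_dict(m: se.LogisticModel) -> dict:
    return {
        "terms": m.terms,
        "coefficients": [None if np.isnan(v) else float(v) for v in m.coefficients],
        "odds_ratios": [None if np.isnan(v) else float(v) for v in m.odds_ratios],
        "ci95": [[None if np.isnan(v) else float(v) for v in row] for row in m.ci95],
        "p_values": [None if np.isnan(v) else float(v) for v in m.p_values],
        "converged": m.converged,
        "separation": m.separation,
        "n": m.n,
    }


def run_discovery_pipeline(
    cohort: PairedCohort,
    network: InteractionNetwork,
    config: RunConfig,
) -> dict:
    """Run the full discovery chain on a paired cohort; returns the manifest.

    The Response Signature is derived from the largest filtered module and
    scored on the cohort's own pre-treatment matrix; evaluation covers the
    Spearman level-vs-change check, the ROC of the RS against module
    direction (and against response when labels exist), the score t-test
    between classes, and — when covariates exist — uni/multivariate
    logistic regression of non-response on the standardized RS score.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"pipeline": "discovery", "seed": config.seed, "config": config.echo(), "stages": {}}
    artifacts: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            t = time.time()
            result = fn()
            log.info("stage %s done in %.2fs", name, time.time() - t)
            return result
        except Exception as exc:  # halt with the stage name, artifacts preserved
            raise StageError(name, exc) from exc

    params = config.discovery

    fcm = stage("fold_changes", lambda: md.compute_log_fold_changes(cohort))
    p = out / "fold_changes.tsv"
    _write_tsv(fcm.to_frame(), p, "gene_id")
    artifacts["fold_changes"] = p
    manifest["stages"]["fold_changes"] = {"n_genes": len(fcm.gene_ids), "n_tumors": len(fcm.tumor_ids)}

    responsive = stage("responsive_genes", lambda: md.select_responsive_genes(fcm, params))
    p = out / "responsive_genes.txt"
    p.write_text("\n".join(responsive) + "\n", encoding="utf-8")
    artifacts["responsive_genes"] = p
    manifest["stages"]["responsive_genes"] = {"n_selected": len(responsive)}

    graph = stage("weight_network", lambda: md.weight_network(network, cohort, responsive, params))
    expr = md.pooled_expression(cohort, params.correlation_samples)
    modules = stage("detect_modules", lambda: md.detect_modules(graph, params, expression=expr))
    kept = stage("filter_modules", lambda: md.filter_modules(modules, params))
    p = out / "modules.json"
    _write_json(
        {
            "missing_from_network": graph.graph.get("missing_genes", []),
            "modules": [
                {"genes": m.genes, "mean_correlation": m.mean_correlation, "edge_count": m.edge_count}
                for m in kept
            ],
            "n_detected": len(modules),
        },
        p,
    )
    artifacts["modules"] = p
    manifest["stages"]["modules"] = {"n_detected": len(modules), "n_filtered": len(kept)}
    if not kept:
        raise StageError("filter_modules", ValidationError("no module survived filtering"))
    top = kept[0]

    profile = stage("module_change_profile", lambda: sig.module_change_score(top, fcm))
    p = out / "module_change_profile.tsv"
    _write_tsv(
        pd.DataFrame(
            {"change_score": profile.change_score, "direction_class": profile.direction_class},
            index=profile.tumor_ids,
        ),
        p,
        "tumor_id",
    )
    artifacts["module_change_profile"] = p
    n_up = sum(c == "up" for c in profile.direction_class)
    manifest["stages"]["module_change_profile"] = {
        "n_up": n_up,
        "n_down": sum(c == "down" for c in profile.direction_class),
    }

    rs = stage(
        "derive_rs",
        lambda: sig.derive_response_signature(
            cohort, profile, k_extreme=config.k_extreme,
            n_genes=config.n_signature_genes, statistic=config.rs_statistic,
        ),
    )
    p = out / "rs.gmt"
    write_gene_signature(rs, p)
    artifacts["rs"] = p
    manifest["stages"]["derive_rs"] = {"n_genes": len(rs.genes)}

    scores = stage("score", lambda: sig.score_samples(rs, cohort.pre))
    p = out / "rs_scores.tsv"
    _write_tsv(scores.to_frame("rs_score"), p, "tumor_id")
    artifacts["rs_scores"] = p

    evaluation: dict = {"score_orientation": sig.SCORE_ORIENTATION}
    level_change = stage("evaluate", lambda: sig.correlate_level_vs_change(top, cohort, profile))
    evaluation["spearman_level_vs_change"] = _test_to_dict(level_change)

    # higher score predicts module down-regulation: positive class = down
    down_label = np.array([1 if c != "up" else 0 for c in profile.direction_class])
    if down_label.min() != down_label.max():
        evaluation["roc_vs_direction"] = _roc_to_dict(se.roc_auc(scores.to_numpy(), down_label))
    if cohort.response is not None and 0 < cohort.response.sum() < cohort.n_tumors:
        nonresp = 1 - cohort.response
        evaluation["roc_vs_nonresponse"] = _roc_to_dict(se.roc_auc(scores.to_numpy(), nonresp))
        evaluation["t_test_scores_by_response"] = _test_to_dict(
            se.welch_t_test(scores.to_numpy()[nonresp == 1], scores.to_numpy()[nonresp == 0])
        )
        std = se.standardize_score_for_regression(scores.to_numpy())
        uni = se.fit_logistic(nonresp, pd.DataFrame({"rs_per_sd": std}, index=cohort.tumor_ids))
        evaluation["logistic_univariate"] = _logistic_to_dict(uni)
        if cohort.covariates is not None:
            cov = cohort.covariates.copy()
            cov.insert(0, "rs_per_sd", std)
            try:
                evaluation["logistic_multivariate"] = _logistic_to_dict(se.fit_logistic(nonresp, cov))
            except ValidationError as exc:
                evaluation["logistic_multivariate"] = {"error": str(exc)}
    p = out / "evaluation.json"
    _write_json(evaluation, p)
    artifacts["evaluation"] = p

    manifest["artifacts"] = {k: {"path": v.name, "sha256": _sha256(v)} for k, v in sorted(artifacts.items())}
    _write_json(manifest, out / "manifest.json")
    log.info("discovery pipeline finished in %.2fs", time.time() - t0)
    return manifest


def run_p53_pipeline(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    config: RunConfig,
    *,
    train_ids: list[str] | None = None,
) -> dict:
    """Train the shrunken-centroid classifier on a training split, score the
    held-out samples, and evaluate; returns the manifest.

    ``train_ids`` fixes the training samples explicitly; otherwise the
    first ``config.n_train`` samples of a seeded stratified shuffle are
    used (default: roughly 1/7 of the cohort, at least ``pam_folds`` per
    class).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(labels)
    manifest: dict = {"pipeline": "p53", "seed": config.seed, "config": config.echo(), "stages": {}}
    artifacts: dict[str, Path] = {}

    ids = matrix.sample_ids
    if train_ids is None:
        n_train = config.n_train or max(2 * config.pam_folds, round(len(ids) / 7))
        rng = np.random.default_rng(config.seed)
        # stratified draw keeping class proportions in the training split
        train_idx: list[int] = []
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            k = max(config.pam_folds, int(round(n_train * len(members) / len(ids))))
            train_idx.extend(rng.choice(members, size=min(k, len(members) - 2), replace=False))
        train_idx = sorted(train_idx)
    else:
        pos = {s: i for i, s in enumerate(ids)}
        train_idx = sorted(pos[s] for s in train_ids)
    test_idx = [i for i in range(len(ids)) if i not in set(train_idx)]
    if not test_idx:
        raise ValidationError("training split leaves no validation samples")

    X_train = matrix.values[:, train_idx]
    y_train = labels[train_idx]
    try:
        cv = cross_validate_pam(
            ExpressionMatrix(matrix.gene_ids, [ids[i] for i in train_idx], X_train),
            y_train,
            n_folds=config.pam_folds,
            seed=config.seed,
            selection=config.pam_selection,
            priors=config.pam_priors,
        )
    except Exception as exc:
        raise StageError("pam_train", exc) from exc

    model = cv.model
    p = out / "pam_model.json"
    _write_json(
        {
            "classes": [str(c) for c in model.classes],
            "delta": model.delta,
            "s0": model.s0,
            "priors": model.priors.tolist(),
            "selected_genes": model.selected_genes,
            "cv": {
                "delta_grid": cv.delta_grid.tolist(),
                "cv_error": cv.cv_error.tolist(),
                "cv_se": cv.cv_se.tolist(),
                "chosen_delta": cv.chosen_delta,
                "fold_assignments": cv.fold_assignments.tolist(),
            },
        },
        p,
    )
    artifacts["pam_model"] = p
    manifest["stages"]["pam_train"] = {
        "n_train": len(train_idx),
        "n_selected_genes": len(model.selected_genes),
        "chosen_delta": cv.chosen_delta,
    }

    X_test = matrix.values[:, test_idx]
    y_test = labels[test_idx]
    pos_class = model.classes[-1]  # label 1 = mutant under the pipeline convention
    try:
        test_m = ExpressionMatrix(matrix.gene_ids, [ids[i] for i in test_idx], X_test)
        train_m = ExpressionMatrix(matrix.gene_ids, [ids[i] for i in train_idx], X_train)
        test_scores = pam_signature_scores(model, test_m, positive_class=pos_class)
        train_scores = pam_signature_scores(model, train_m, positive_class=pos_class)
    except Exception as exc:
        raise StageError("pam_score", exc) from exc
    p = out / "p53_scores.tsv"
    _write_tsv(
        pd.DataFrame(
            {
                "score": np.concatenate([train_scores, test_scores]),
                "split": ["train"] * len(train_idx) + ["validation"] * len(test_idx),
                "label": np.concatenate([y_train, y_test]),
            },
            index=[ids[i] for i in train_idx] + [ids[i] for i in test_idx],
        ),
        p,
        "sample_id",
    )
    artifacts["p53_scores"] = p

    evaluation: dict = {"positive_class": str(pos_class)}
    evaluation["t_test_train"] = _test_to_dict(
        se.welch_t_test(train_scores[y_train == pos_class], train_scores[y_train != pos_class])
    )
    if len(np.unique(y_test)) == 2:
        evaluation["t_test_validation"] = _test_to_dict(
            se.welch_t_test(test_scores[y_test == pos_class], test_scores[y_test != pos_class])
        )
        evaluation["roc_validation"] = _roc_to_dict(
            se.roc_auc(test_scores, (y_test == pos_class).astype(int))
        )
    p = out / "p53_evaluation.json"
    _write_json(evaluation, p)
    artifacts["p53_evaluation"] = p

    manifest["artifacts"] = {k: {"path": v.name, "sha256": _sha256(v)} for k, v in sorted(artifacts.items())}
    _write_json(manifest, out / "manifest.json")
    return manifest
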