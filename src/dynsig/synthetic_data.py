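"""Synthetic paired pre/post-treatment cohorts, interaction networks, and
p53-status cohorts with the statistical structure the downstream analysis
assumes.

The generator emulates a neoadjuvant study design: a minority subset of
tumors coordinately up-regulates a planted co-expression module after
treatment while the remainder down-regulates it; the clinical response
label is anti-associated with module down-regulation; a disjoint set of
genes differs at baseline between the two direction classes, so a
pre-treatment response signature is learnable; and an independent cohort
carries a binary "p53 status" label driven by a sparse set of informative
probes.

Pairwise correlation among module genes is induced by a single shared
latent factor per tumor: ``x_g = sqrt(rho) * f + sqrt(1 - rho) * eps_g``
with unit-variance ``f`` and ``eps_g``, which gives expected pairwise
correlation exactly ``rho``.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from ``SimulationConfig.seed``, so outputs are bit-reproducible across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, InteractionNetwork, PairedCohort, ValidationError

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_network",
    "generate_paired_cohort",
    "generate_p53_cohort",
]


class ConfigError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohorts.

    Defaults mirror the emulated design: a 26-tumor paired cohort with one
    planted 40-gene module, ~8/26 of tumors up-regulating it after
    treatment, target within-module correlation 0.7, mean |log2 FC| 1.5 on
    module genes, residual log2 noise 0.5, and a response label that
    disagrees with the tumor's direction class with probability 0.1.
    The p53 cohort plants 18 informative probes shifted by 1.0 between
    classes, with ~30% of samples in the mutant class.
    """

    n_tumors: int = 26
    n_genes: int = 2000
    module_size: int = 40
    frac_up: float = 8 / 26
    within_module_corr: float = 0.7
    module_effect: float = 1.5
    noise_sd: float = 0.5
    response_flip_prob: float = 0.1
    n_rs_informative: int = 10
    rs_effect: float = 3.0
    n_informative_p53: int = 18
    p53_effect: float = 1.0
    p53_mut_frac: float = 0.3
    covariate_assoc: float = 1.0
    module_density: float = 0.3
    background_mean_degree: float = 3.0
    seed: int = 0
    rng_algorithm: str = field(default="PCG64", init=False)  # recorded for provenance

    def __post_init__(self) -> None:
        if not 0.0 < self.frac_up < 1.0:
            raise ConfigError("frac_up must lie strictly between 0 and 1")
        if self.module_size < 2:
            raise ConfigError("module_size must be at least 2")
        if self.module_size > self.n_genes:
            raise ConfigError("module_size cannot exceed n_genes")
        if not 0.0 <= self.within_module_corr < 1.0:
            raise ConfigError("within_module_corr must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0.0 <= self.response_flip_prob < 0.5:
            raise ConfigError("response_flip_prob must lie in [0, 0.5)")
        if self.n_informative_p53 > self.n_genes:
            raise ConfigError("n_informative_p53 cannot exceed n_genes")
        if self.module_size + self.n_rs_informative > self.n_genes:
            raise ConfigError("module and RS-informative gene sets exceed the gene universe")
        if not 0.0 < self.p53_mut_frac < 1.0:
            raise ConfigError("p53_mut_frac must lie strictly between 0 and 1")
        if self.n_tumors < 2:
            raise ConfigError("n_tumors must be at least 2")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    @property
    def module_genes(self) -> list[str]:
        return self.gene_ids[: self.module_size]

    @property
    def rs_informative_genes(self) -> list[str]:
        return self.gene_ids[self.module_size : self.module_size + self.n_rs_informative]

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort, for recovery tests."""

    module_genes: list[str]
    direction_class: list[str] | None = None  # per-tumor "up"/"down"
    response: np.ndarray | None = None
    rs_informative_genes: list[str] | None = None
    p53_informative_probes: list[str] | None = None
    p53_labels: np.ndarray | None = None


def _rng(config: SimulationConfig, salt: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([config.seed, salt]))


def generate_network(config: SimulationConfig) -> InteractionNetwork:
    """Build an interaction network containing the planted module as a dense
    connected subgraph inside a sparse Erdos-Renyi background.

    Module genes are wired as a ring plus second-neighbour chords (every
    module gene touches >= 4 module genes, one connected component) and,
    on top, independent within-module edges at probability
    ``module_density``, making the module a dense subgraph. The background
    draws each remaining pair independently with probability
    ``background_mean_degree / (n_genes - 1)``.
    """
    rng = _rng(config, 1)
    genes = config.gene_ids
    m = config.module_size
    edges: set[tuple[str, str]] = set()
    for i in range(m):
        for step in (1, 2):
            j = (i + step) % m
            if i != j:
                a, b = genes[i], genes[j]
                edges.add((a, b) if a < b else (b, a))
    for i in range(m - 1):
        for j in range(i + 1, m):
            if rng.random() < config.module_density:
                a, b = genes[i], genes[j]
                edges.add((a, b) if a < b else (b, a))

    p = config.background_mean_degree / max(config.n_genes - 1, 1)
    n = config.n_genes
    # Sample background edges by drawing the per-row binomial counts; this is
    # O(expected edges) rather than O(n^2).
    for i in range(n - 1):
        k = rng.binomial(n - 1 - i, p)
        if k == 0:
            continue
        js = rng.choice(np.arange(i + 1, n), size=k, replace=False)
        for j in js:
            a, b = genes[i], genes[int(j)]
            edges.add((a, b) if a < b else (b, a))
    return InteractionNetwork(genes, sorted(edges))


def _covariates(rng: np.random.Generator, response: np.ndarray, assoc: float) -> pd.DataFrame:
    """Clinical covariates with a configurable association to response.

    At ``assoc = 1`` ER positivity is depleted and high grade enriched among
    responders (the directions reported for neoadjuvant breast cohorts);
    ``assoc = 0`` makes every covariate independent of response. Age and
    node status are always independent.
    """
    n = len(response)
    age = np.round(rng.normal(55.0, 10.0, size=n), 1)
    p_er = 0.6 + assoc * np.where(response == 1, -0.25, 0.15)
    er = (rng.random(n) < np.clip(p_er, 0.05, 0.95)).astype(int)
    p_high_grade = 0.4 + assoc * np.where(response == 1, 0.3, -0.15)
    high = rng.random(n) < np.clip(p_high_grade, 0.05, 0.95)
    grade = np.where(high, 3, rng.integers(1, 3, size=n))
    node = (rng.random(n) < 0.45).astype(int)
    return pd.DataFrame(
        {"age": age, "grade": grade.astype(int), "er_status": er, "node_status": node}
    )


def generate_paired_cohort(config: SimulationConfig) -> tuple[PairedCohort, SyntheticTruth]:
    """Simulate one matched pre/post cohort plus its ground truth.

    Pre-treatment module genes follow the shared-latent-factor model at the
    configured correlation; post = pre + s_t * module_effect on module genes
    (s_t = +1 for up-class tumors, -1 for down-class) plus N(0, noise_sd)
    noise everywhere. RS-informative genes are shifted by ``rs_effect/2``
    toward the tumor's class sign in both pre and post, so they carry
    baseline (not fold-change) information. Response = 1 for up-class
    tumors, flipped with ``response_flip_prob``.
    """
    rng = _rng(config, 2)
    n, g = config.n_tumors, config.n_genes
    genes = config.gene_ids
    tumor_ids = [f"T{i:03d}" for i in range(n)]

    n_up = int(round(config.frac_up * n))
    n_up = min(max(n_up, 1), n - 1)
    cls = np.array([1] * n_up + [-1] * (n - n_up))
    rng.shuffle(cls)

    baseline = rng.normal(8.0, 1.2, size=g)
    pre = baseline[:, None] + rng.normal(0.0, 1.0, size=(g, n))

    m = config.module_size
    rho = config.within_module_corr
    factor = rng.normal(0.0, 1.0, size=n)
    eps = rng.normal(0.0, 1.0, size=(m, n))
    pre[:m] = baseline[:m, None] + np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * eps

    rs_lo = m
    rs_hi = m + config.n_rs_informative
    pre[rs_lo:rs_hi] += 0.5 * config.rs_effect * cls[None, :]

    post = pre + rng.normal(0.0, config.noise_sd, size=(g, n))
    post[:m] += config.module_effect * cls[None, :]

    response = (cls == 1).astype(int)
    flips = rng.random(n) < config.response_flip_prob
    response = np.where(flips, 1 - response, response)

    covariates = _covariates(rng, response, config.covariate_assoc)
    covariates.index = tumor_ids

    cohort = PairedCohort(
        pre=ExpressionMatrix(genes, tumor_ids, pre),
        post=ExpressionMatrix(genes, tumor_ids, post),
        tumor_ids=tumor_ids,
        response=response,
        covariates=covariates,
    )
    truth = SyntheticTruth(
        module_genes=config.module_genes,
        direction_class=["up" if c == 1 else "down" for c in cls],
        response=response,
        rs_informative_genes=config.rs_informative_genes,
    )
    return cohort, truth


def generate_p53_cohort(
    config: SimulationConfig, n_samples: int
) -> tuple[ExpressionMatrix, np.ndarray, SyntheticTruth]:
    """Simulate a single-timepoint cohort with a binary p53-status label.

    Exactly ``n_informative_p53`` probes are shifted by ``p53_effect``
    (mutant class higher) on a unit-variance Gaussian background; all other
    probes are null. Class sizes follow ``p53_mut_frac`` up to rounding.
    """
    if n_samples < 4:
        raise ConfigError("p53 cohort needs at least 4 samples")
    rng = _rng(config, 3)
    g = config.n_genes
    genes = config.gene_ids
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]

    n_mut = int(round(config.p53_mut_frac * n_samples))
    n_mut = min(max(n_mut, 2), n_samples - 2)
    labels = np.array([1] * n_mut + [0] * (n_samples - n_mut))
    rng.shuffle(labels)

    baseline = rng.normal(8.0, 1.2, size=g)
    values = baseline[:, None] + rng.normal(0.0, 1.0, size=(g, n_samples))
    k = config.n_informative_p53
    values[:k] += config.p53_effect * labels[None, :]

    matrix = ExpressionMatrix(genes, sample_ids, values)
    truth = SyntheticTruth(
        module_genes=config.module_genes,
        p53_informative_probes=genes[:k],
        p53_labels=labels,
    )
    return matrix, labels, truth
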