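"""Discovery of treatment-responsive gene modules.

The stage chain: per-tumor log2 fold changes from a matched pre/post
cohort; selection of responsive genes whose mean |log2 FC| clears a
threshold (1.0, i.e. 2-fold, by default); the induced subgraph of an
interaction network on those genes, with each edge weighted by the
expression correlation of its endpoints; greedy weighted-modularity
clustering of that graph; and a size/coherence filter keeping modules of
at least ``min_module_size`` genes whose mean pairwise correlation
strictly exceeds ``min_avg_corr``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import InteractionNetwork, PairedCohort, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "FoldChangeMatrix",
    "WeightedModule",
    "DiscoveryParams",
    "compute_log_fold_changes",
    "select_responsive_genes",
    "weight_network",
    "detect_modules",
    "filter_modules",
    "pooled_expression",
]


@dataclass
class FoldChangeMatrix:
    """Per-gene, per-tumor log2(post) - log2(pre)."""

    gene_ids: list[str]
    tumor_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tumor_ids)):
            raise ValidationError("fold-change matrix shape does not match identifier lists")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite fold changes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.tumor_ids)


@dataclass
class WeightedModule:
    """A gene set with its mean pairwise expression correlation and the
    number of interaction-network edges among its members."""

    genes: list[str]
    mean_correlation: float
    edge_count: int

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in module")
        if not -1.0 <= self.mean_correlation <= 1.0 and not np.isnan(self.mean_correlation):
            raise ValidationError("mean_correlation outside [-1, 1]")

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class DiscoveryParams:
    """Tuning knobs of the discovery stage.

    ``fc_threshold`` is on the log2 scale (1.0 = 2-fold) and the selection
    is inclusive at the boundary; ``min_avg_corr`` is strict ("exceeds").
    ``fc_summary`` chooses how per-gene fold changes are summarised across
    tumors: mean of |FC| (default) or mean of signed FC. ``resolution``
    is the modularity resolution of the greedy partitioner: values below 1
    favour coarser partitions, which keeps a dense coherent module in one
    piece instead of splitting it along random edge-density fluctuations;
    disconnected structures still separate at any positive resolution.
    """

    fc_threshold: float = 1.0
    min_module_size: int = 10
    min_avg_corr: float = 0.5
    correlation_method: str = "pearson"
    correlation_samples: str = "pre_and_post"
    edge_weight_floor: float = 0.0
    fc_summary: str = "abs_mean"
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.fc_threshold < 0:
            raise ValidationError("fc_threshold must be non-negative")
        if self.min_module_size < 2:
            raise ValidationError("min_module_size must be at least 2")
        if not -1.0 < self.min_avg_corr < 1.0:
            raise ValidationError("min_avg_corr must lie in (-1, 1)")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ValidationError("correlation_method must be 'pearson' or 'spearman'")
        if self.correlation_samples not in ("pre", "post", "pre_and_post"):
            raise ValidationError("correlation_samples must be pre, post or pre_and_post")
        if self.fc_summary not in ("abs_mean", "signed_mean"):
            raise ValidationError("fc_summary must be 'abs_mean' or 'signed_mean'")
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")


def compute_log_fold_changes(cohort: PairedCohort) -> FoldChangeMatrix:
    """Element-wise post - pre on the log2 scale."""
    if cohort.pre.gene_ids != cohort.post.gene_ids:
        raise ValidationError("pre and post gene lists differ")
    return FoldChangeMatrix(
        gene_ids=list(cohort.gene_ids),
        tumor_ids=list(cohort.tumor_ids),
        values=cohort.post.values - cohort.pre.values,
    )


def select_responsive_genes(fcm: FoldChangeMatrix, params: DiscoveryParams) -> list[str]:
    """Genes whose summarised fold change clears ``fc_threshold`` (inclusive).

    Default summary is the mean over tumors of |log2 FC|, so a gene moving
    +1 in half the tumors and -1 in the rest is retained even though its
    signed mean is zero. Returns genes in their input order.
    """
    if fcm.values.size == 0:
        raise ValidationError("empty fold-change matrix")
    if params.fc_summary == "abs_mean":
        summary = np.abs(fcm.values).mean(axis=1)
    else:
        summary = np.abs(fcm.values.mean(axis=1))
    keep = summary >= params.fc_threshold
    return [g for g, k in zip(fcm.gene_ids, keep) if k]


def pooled_expression(cohort: PairedCohort, which: str = "pre_and_post") -> pd.DataFrame:
    """Genes x samples frame over the requested sample set of a cohort."""
    if which == "pre":
        return cohort.pre.to_frame()
    if which == "post":
        return cohort.post.to_frame()
    pre = cohort.pre.to_frame().add_suffix("_pre")
    post = cohort.post.to_frame().add_suffix("_post")
    return pd.concat([pre, post], axis=1)


def _correlation_rows(frame: pd.DataFrame, method: str) -> np.ndarray:
    """Row values ready for dot-product correlation (rank-transformed for
    Spearman), standardised to zero mean / unit norm."""
    vals = frame.to_numpy(dtype=float)
    if method == "spearman":
        vals = stats.rankdata(vals, axis=1)
    vals = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(vals, axis=1, keepdims=True)
    norms[norms == 0] = np.nan  # constant rows: correlation undefined
    return vals / norms


def weight_network(
    network: InteractionNetwork,
    cohort: PairedCohort,
    genes: list[str],
    params: DiscoveryParams,
) -> nx.Graph:
    """Induced subgraph on the responsive genes, edges weighted by the
    expression correlation of their endpoints.

    Edges whose weight falls below ``edge_weight_floor`` (default 0, which
    also drops anti-correlated pairs) are removed. Responsive genes absent
    from the network are recorded in ``graph.graph['missing_genes']`` and
    logged, never silently dropped.
    """
    gene_set = set(genes)
    node_set = set(network.nodes)
    present = sorted(gene_set & node_set)
    missing = sorted(gene_set - node_set)
    if missing:
        log.info("%d responsive genes absent from the interaction network", len(missing))

    graph = nx.Graph(missing_genes=missing, correlation_method=params.correlation_method)
    graph.add_nodes_from(present)
    if len(present) < 2:
        log.warning("fewer than 2 responsive genes present in the network; empty graph")
        return graph

    frame = pooled_expression(cohort, params.correlation_samples)
    expr_genes = set(frame.index)
    rows = _correlation_rows(frame.loc[[g for g in present if g in expr_genes]], params.correlation_method)
    row_of = {g: i for i, g in enumerate(g for g in present if g in expr_genes)}

    for a, b in network.edges:
        if a in gene_set and b in gene_set and a in row_of and b in row_of:
            w = float(rows[row_of[a]] @ rows[row_of[b]])
            if np.isfinite(w) and w >= params.edge_weight_floor:
                graph.add_edge(a, b, weight=w)
    return graph


def _mean_pairwise_correlation(members: list[str], expression: pd.DataFrame, method: str) -> float:
    """Mean correlation over ALL unordered member pairs (not just network
    edges), computed on the given genes x samples frame."""
    members = [g for g in members if g in expression.index]
    if len(members) < 2:
        return float("nan")
    rows = _correlation_rows(expression.loc[members], method)
    corr = rows @ rows.T
    iu = np.triu_indices(len(members), k=1)
    vals = corr[iu]
    return float(np.nanmean(vals))


def detect_modules(
    graph: nx.Graph,
    params: DiscoveryParams,
    expression: pd.DataFrame | None = None,
) -> list[WeightedModule]:
    """Partition the weighted graph into modules by greedy modularity
    maximisation (CNM), deterministically.

    Nodes are relabelled in sorted order before clustering so tie-breaking
    is reproducible. Isolated nodes become singleton modules (they are
    removed later by ``filter_modules``). Each module is annotated with its
    mean pairwise correlation — over all member pairs when ``expression``
    is given, else the mean retained edge weight — and its edge count.
    Modules are sorted by size descending, then by first gene id.
    """
    if graph.number_of_nodes() == 0:
        return []
    isolates = sorted(nx.isolates(graph))
    core = graph.subgraph(n for n in graph.nodes if n not in set(isolates))

    communities: list[list[str]] = []
    if core.number_of_edges() > 0:
        order = sorted(core.nodes)
        relabel = {n: i for i, n in enumerate(order)}
        h = nx.Graph()
        h.add_nodes_from(range(len(order)))
        for a, b, d in core.edges(data=True):
            h.add_edge(relabel[a], relabel[b], weight=d.get("weight", 1.0))
        for comm in nx.community.greedy_modularity_communities(
            h, weight="weight", resolution=params.resolution
        ):
            communities.append(sorted(order[i] for i in comm))
    else:
        communities.extend([n] for n in sorted(core.nodes))
    communities.extend([n] for n in isolates)

    modules = []
    for members in communities:
        sub = graph.subgraph(members)
        if expression is not None:
            mc = _mean_pairwise_correlation(members, expression, params.correlation_method)
        else:
            weights = [d.get("weight", 1.0) for _, _, d in sub.edges(data=True)]
            mc = float(np.mean(weights)) if weights else float("nan")
        modules.append(WeightedModule(sorted(members), mc, sub.number_of_edges()))
    modules.sort(key=lambda m: (-m.size, m.genes[0]))
    return modules


def filter_modules(modules: list[WeightedModule], params: DiscoveryParams) -> list[WeightedModule]:
    """Keep modules with at least ``min_module_size`` genes whose mean
    correlation strictly exceeds ``min_avg_corr``."""
    return [
        m
        for m in modules
        if m.size >= params.min_module_size
        and np.isfinite(m.mean_correlation)
        and m.mean_correlation > params.min_avg_corr
    ]
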