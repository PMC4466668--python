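"""Validated domain containers and readers/writers for the text formats the pipeline touches.

Formats handled: plain TSV expression (genes in rows, header of sample ids),
GCT 1.2, SIF and two-column TSV edge lists, and a GMT-like gene-signature
file (one record per direction class). All I/O is UTF-8 and tab-delimited.

Expression values are assumed to be log2-scale intensities; ``log2_transform``
applies ``log2(x + 1)`` for linear-scale input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "PairedCohort",
    "InteractionNetwork",
    "GeneSignature",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_edge_list",
    "write_edge_list",
    "read_gene_signature",
    "write_gene_signature",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A genes x samples matrix of log2-scale expression values.

    Invariants: identifiers are unique, dimensions match the identifier
    lists, and every value is finite (missing-value policy is applied at
    read time, before construction).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) == 0 or len(self.sample_ids) == 0:
            raise ValidationError("empty expression matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite expression values after missing-value policy")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in idx]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}...")
        rows = [idx[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])


@dataclass
class PairedCohort:
    """Matched pre/post-treatment expression for N tumors.

    ``pre`` and ``post`` share identical gene lists and their sample ids
    equal ``tumor_ids`` in order, so column t of each matrix is the same
    tumor before and after treatment. ``response`` is an optional binary
    label per tumor (1 = responder); ``covariates`` an optional per-tumor
    clinical table (age, grade, er_status, node_status).
    """

    pre: ExpressionMatrix
    post: ExpressionMatrix
    tumor_ids: list[str]
    response: np.ndarray | None = None
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.pre.gene_ids != self.post.gene_ids:
            raise ValidationError("pre and post matrices must share identical gene lists")
        self.tumor_ids = [str(t) for t in self.tumor_ids]
        if len(self.tumor_ids) < 2:
            raise ValidationError("a paired cohort needs at least 2 tumors")
        if self.pre.sample_ids != self.tumor_ids or self.post.sample_ids != self.tumor_ids:
            raise ValidationError("pre/post sample ids must match tumor_ids one-to-one, in order")
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=int)
            if self.response.shape != (len(self.tumor_ids),):
                raise ValidationError("response labels must align with tumor_ids")
            if not np.isin(self.response, [0, 1]).all():
                raise ValidationError("response labels must be binary")
        if self.covariates is not None and len(self.covariates) != len(self.tumor_ids):
            raise ValidationError("covariate table must align with tumor_ids")

    @property
    def n_tumors(self) -> int:
        return len(self.tumor_ids)

    @property
    def gene_ids(self) -> list[str]:
        return self.pre.gene_ids


@dataclass
class InteractionNetwork:
    """An undirected gene-gene interaction network (no self-loops, deduplicated)."""

    nodes: list[str]
    edges: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.nodes = [str(n) for n in self.nodes]
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        canon = set()
        for a, b in self.edges:
            a, b = str(a), str(b)
            if a == b:
                raise ValidationError(f"self-loop on {a!r}")
            if a not in node_set or b not in node_set:
                raise ValidationError(f"edge endpoint not in node list: ({a!r}, {b!r})")
            canon.add((a, b) if a < b else (b, a))
        self.edges = sorted(canon)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


@dataclass
class GeneSignature:
    """An ordered gene list with per-gene direction weights in {+1, -1}.

    By convention a weight of +1 marks a gene expressed higher, before
    treatment, in tumors that up-regulate the module after treatment.
    """

    name: str
    genes: list[str]
    weights: list[int]

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.weights = [int(w) for w in self.weights]
        if len(self.genes) < 1:
            raise ValidationError("signature must contain at least one gene")
        if len(self.weights) != len(self.genes):
            raise ValidationError("weights length must match gene list")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in signature")
        if any(w not in (1, -1) for w in self.weights):
            raise ValidationError("direction weights must be +1 or -1")

    @property
    def up_genes(self) -> list[str]:
        return [g for g, w in zip(self.genes, self.weights) if w == 1]

    @property
    def down_genes(self) -> list[str]:
        return [g for g, w in zip(self.genes, self.weights) if w == -1]


# ---------------------------------------------------------------------------
# expression I/O
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated identifier, the row with the highest mean.

    Ties resolved deterministically: among equal means the first row in
    identifier-then-position order wins.
    """
    if frame.index.is_unique:
        return frame
    means = frame.mean(axis=1, skipna=True).to_numpy()
    order = np.lexsort((np.arange(len(frame)), -means))  # highest mean first, stable
    ranked = frame.iloc[order]
    kept = ranked[~ranked.index.duplicated(keep="first")]
    n_dropped = len(frame) - len(kept)
    log.info("collapsed %d duplicate gene rows (highest-mean policy)", n_dropped)
    # restore first-appearance order of the surviving identifiers
    first_pos = {}
    for pos, gid in enumerate(frame.index):
        first_pos.setdefault(gid, pos)
    return kept.loc[sorted(kept.index, key=lambda g: first_pos[g])]


def _apply_missing_policy(frame: pd.DataFrame, max_missing_frac: float = 0.5) -> pd.DataFrame:
    """Drop genes with more than ``max_missing_frac`` missing; impute per-gene mean."""
    n_samples = frame.shape[1]
    missing = frame.isna().sum(axis=1)
    drop = missing / n_samples > max_missing_frac
    if drop.any():
        log.info("dropping %d genes with >%d%% missing values", int(drop.sum()), int(max_missing_frac * 100))
        frame = frame.loc[~drop]
    n_imputed = int(frame.isna().to_numpy().sum())
    if n_imputed:
        log.info("imputing %d missing values with per-gene means", n_imputed)
        row_means = frame.mean(axis=1, skipna=True)
        frame = frame.apply(lambda col: col.fillna(row_means), axis=0)
    return frame


def _read_tsv_expression(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if not header:
        raise FormatError(f"{path}: empty file")
    sample_ids = header.split("\t")[1:]
    if len(sample_ids) != len(set(sample_ids)):
        raise ValidationError(f"{path}: duplicate sample ids in header")
    frame = pd.read_csv(path, sep="\t", index_col=0, header=0)
    frame.columns = sample_ids
    frame.index = frame.index.map(str)
    return frame


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: line 1 must be the GCT version tag '#1.2'")
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GCT file")
    dims = lines[1].split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: line 2 must be '<n_genes>\\t<n_samples>'") from exc
    header = lines[2].split("\t")
    if len(header) < 2 or header[0] != "Name" or header[1] != "Description":
        raise FormatError(f"{path}: line 3 must start with 'Name\\tDescription'")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise FormatError(
            f"{path}: dimension line declares {n_samples} samples but header has {len(sample_ids)}"
        )
    if len(sample_ids) != len(set(sample_ids)):
        raise ValidationError(f"{path}: duplicate sample ids")
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != n_genes:
        raise FormatError(
            f"{path}: dimension line declares {n_genes} data rows but found {len(data_lines)}"
        )
    genes, rows = [], []
    for i, ln in enumerate(data_lines, start=4):
        parts = ln.split("\t")
        if len(parts) != 2 + n_samples:
            raise FormatError(f"{path}: line {i} has {len(parts)} columns, expected {2 + n_samples}")
        genes.append(parts[0])
        rows.append([np.nan if p in ("", "NA", "nan") else float(p) for p in parts[2:]])
    return pd.DataFrame(rows, index=genes, columns=sample_ids)


def read_expression_matrix(
    path: str | Path,
    format: str = "tsv",
    *,
    log2_transform: bool = False,
    max_missing_frac: float = 0.5,
) -> ExpressionMatrix:
    """Read an expression matrix from a TSV or GCT 1.2 file.

    Duplicate gene rows are collapsed (highest-mean row wins); cells missing
    in at most ``max_missing_frac`` of samples are imputed with the per-gene
    mean, genes beyond that are dropped; both events are logged.
    """
    path = Path(path)
    if format == "tsv":
        frame = _read_tsv_expression(path)
    elif format == "gct":
        frame = _read_gct(path)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    frame = frame.apply(pd.to_numeric, errors="coerce")
    frame = _collapse_duplicate_genes(frame)
    frame = _apply_missing_policy(frame, max_missing_frac)
    if frame.empty:
        raise ValidationError(f"{path}: no genes remain after missing-value policy")
    if log2_transform:
        frame = np.log2(frame + 1.0)
    return ExpressionMatrix.from_frame(frame)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    frame = matrix.to_frame()
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            frame.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.10g", lineterminator="\n")
    elif format == "gct":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
            for g, row in zip(matrix.gene_ids, matrix.values):
                fh.write(g + "\tna\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# network I/O
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path, format: str = "sif") -> InteractionNetwork:
    """Read an undirected interaction network from SIF or two-column TSV.

    SIF lines are ``source<ws>relation<ws>target [target ...]``; the relation
    column is ignored. Self-loops are dropped with a logged count; duplicate
    and reversed edges collapse to one undirected edge.
    """
    path = Path(path)
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if format == "sif":
                parts = line.split()
                if len(parts) < 3:
                    raise FormatError(f"{path}: line {lineno}: SIF needs source, relation, target")
                src, targets = parts[0], parts[2:]
            elif format == "tsv2col":
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(f"{path}: line {lineno}: expected 2 tab-separated columns")
                src, targets = parts[0], [parts[1]]
            else:
                raise ValueError(f"unknown edge-list format {format!r}")
            nodes.add(src)
            for tgt in targets:
                nodes.add(tgt)
                if tgt == src:
                    n_self += 1
                    continue
                edges.add((src, tgt) if src < tgt else (tgt, src))
    if n_self:
        log.info("dropped %d self-loops", n_self)
    return InteractionNetwork(sorted(nodes), sorted(edges))


def write_edge_list(network: InteractionNetwork, path: str | Path, format: str = "tsv2col") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in network.edges:
            if format == "sif":
                fh.write(f"{a}\tpp\t{b}\n")
            elif format == "tsv2col":
                fh.write(f"{a}\t{b}\n")
            else:
                raise ValueError(f"unknown edge-list format {format!r}")


# ---------------------------------------------------------------------------
# signature I/O (GMT-like: one record per direction class)
# ---------------------------------------------------------------------------

_DIRECTION_TOKENS = {"up": 1, "down": -1}


def read_gene_signature(path: str | Path) -> GeneSignature:
    """Read a signature from a GMT-like file.

    Each line: ``name<TAB>direction<TAB>gene1<TAB>gene2...`` where direction
    is ``up`` or ``down``. Gene order within and across lines is preserved.
    """
    path = Path(path)
    name = None
    genes: list[str] = []
    weights: list[int] = []
    seen: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected name, direction, genes")
            rec_name, token = parts[0], parts[1]
            if token not in _DIRECTION_TOKENS:
                raise FormatError(f"{path}: line {lineno}: unknown direction token {token!r}")
            name = name or rec_name
            w = _DIRECTION_TOKENS[token]
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    raise ValidationError(f"{path}: gene {g!r} appears with more than one direction")
                seen[g] = w
                genes.append(g)
                weights.append(w)
    if name is None or not genes:
        raise ValidationError(f"{path}: signature contains no genes")
    return GeneSignature(name, genes, weights)


def write_gene_signature(sig: GeneSignature, path: str | Path) -> None:
    """Write a signature as GMT-like records.

    Consecutive genes sharing a direction are emitted as one record, so the
    overall gene order (which encodes the ranking) survives a round-trip.
    """
    path = Path(path)
    runs: list[tuple[int, list[str]]] = []
    for g, w in zip(sig.genes, sig.weights):
        if runs and runs[-1][0] == w:
            runs[-1][1].append(g)
        else:
            runs.append((w, [g]))
    token = {1: "up", -1: "down"}
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for w, members in runs:
            fh.write(sig.name + "\t" + token[w] + "\t" + "\t".join(members) + "\n")
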