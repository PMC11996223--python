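"""Global network construction, pruning, and edge filtering.

The global adjacency is the average over subsamples of the absolute outer
product of the concatenated canonical weight vector with itself, restricted
to features that received a nonzero weight in at least one subsample.  The
phenotype view (dimension 1) contributes its weight sign to the solution
but is not itself a network node.

Pruning ranks nodes by weighted PageRank and scans candidate subnetwork
sizes, scoring each candidate by the best absolute Pearson correlation
between a topology-aware principal-component summary (NetSHy-style: PCA of
the node data concatenated with the node data times the graph Laplacian)
and the phenotype; the smallest candidate within tolerance of the best
correlation is selected.  A final edge filter removes edges between weakly
correlated nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .subsampling import CanonicalWeightMatrices

__all__ = [
    "NetworkModule",
    "PruneResult",
    "build_adjacency",
    "pagerank_scores",
    "netshy_summarize",
    "prune",
    "filter_edges",
    "to_networkx",
    "node_table",
    "write_edge_list",
]


@dataclass
class NetworkModule:
    """Symmetric nonnegative adjacency over selected features."""

    adjacency: np.ndarray
    node_ids: list[str]
    node_views: list[int]
    node_feature_index: list[tuple[int, int]]  # (view, column within view)
    edge_signs: np.ndarray | None = None  # from Pearson correlation, after filtering
    edge_correlations: np.ndarray | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(a < 0):
            raise ValueError("adjacency must be nonnegative")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def subgraph(self, order: np.ndarray) -> "NetworkModule":
        order = np.asarray(order, int)
        return NetworkModule(
            self.adjacency[np.ix_(order, order)],
            [self.node_ids[i] for i in order],
            [self.node_views[i] for i in order],
            [self.node_feature_index[i] for i in order],
        )


@dataclass
class PruneResult:
    selected: np.ndarray           # indices into the global module
    module: NetworkModule
    trace: list[tuple[int, float]]  # (candidate size, best |corr| with phenotype)
    chosen_size: int
    summary_scores: np.ndarray
    pagerank: np.ndarray = field(default=None)  # type: ignore[assignment]


def build_adjacency(
    weights: CanonicalWeightMatrices,
    view_names: list[str] | None = None,
    feature_ids: list[list[str]] | None = None,
) -> NetworkModule:
    """Average over subsamples of |w w^T| for the concatenated weights.

    Views of dimension 1 (the phenotype) are excluded from the node set.
    """
    views = [j for j, m in enumerate(weights.matrices) if m.shape[0] > 1]
    if not views:
        raise ValueError("no omics views with more than one feature")
    if view_names is None:
        view_names = [f"view{j}" for j in range(len(weights.matrices))]
    stacked = np.vstack([np.abs(weights.matrices[j]) for j in views])
    active = stacked.any(axis=1)
    if not active.any():
        raise ValueError("all canonical weights are zero; empty network")
    w = stacked[active]
    adjacency = (w @ w.T) / w.shape[1]
    np.fill_diagonal(adjacency, 0.0)

    node_ids, node_views, node_feature_index = [], [], []
    offset = 0
    for j in views:
        d = weights.matrices[j].shape[0]
        keep = np.flatnonzero(active[offset:offset + d])
        for c in keep:
            fid = feature_ids[j][c] if feature_ids is not None else f"f{c}"
            node_ids.append(f"{view_names[j]}:{fid}")
            node_views.append(j)
            node_feature_index.append((j, int(c)))
        offset += d
    return NetworkModule(adjacency, node_ids, node_views, node_feature_index)


def pagerank_scores(module: NetworkModule, damping: float = 0.85,
                    tol: float = 1e-14, max_iter: int = 10_000) -> np.ndarray:
    """Weighted-PageRank stationary distribution (power iteration)."""
    a = module.adjacency
    n = a.shape[0]
    if n == 0:
        raise ValueError("empty network")
    deg = a.sum(axis=1)
    dangling = deg == 0
    p = np.full(n, 1.0 / n)
    trans = np.zeros_like(a)
    nz = ~dangling
    trans[nz] = a[nz] / deg[nz, None]
    for _ in range(max_iter):
        new = damping * (trans.T @ p + p[dangling].sum() / n) + (1 - damping) / n
        if np.abs(new - p).sum() < tol:
            p = new
            break
        p = new
    return p / p.sum()


def netshy_summarize(node_data: np.ndarray, adjacency: np.ndarray,
                     n_pcs: int = 3) -> np.ndarray:
    """Topology-aware principal-component scores (samples x n_pcs).

    PCA of the column-concatenation of the node data X and the
    topology-weighted channel X L, with L the combinatorial graph Laplacian
    of the adjacency.  Columns are ordered by variance explained and
    sign-canonicalized (largest-magnitude score entry positive).
    """
    x = np.asarray(node_data, float)
    a = np.asarray(adjacency, float)
    if x.shape[1] != a.shape[0]:
        raise ValueError("node data and adjacency are not aligned")
    if n_pcs > x.shape[1]:
        raise ValueError("n_pcs exceeds node count")
    lap = np.diag(a.sum(axis=1)) - a
    m = np.hstack([x, x @ lap])
    m = m - m.mean(axis=0)
    u, s, _ = np.linalg.svd(m, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    for c in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, c])))
        if scores[i, c] < 0:
            scores[:, c] *= -1
    return scores


def _max_abs_corr(scores: np.ndarray, phenotype: np.ndarray) -> float:
    y = phenotype - phenotype.mean()
    ys = np.linalg.norm(y)
    best = 0.0
    for c in range(scores.shape[1]):
        v = scores[:, c] - scores[:, c].mean()
        vn = np.linalg.norm(v)
        if vn > 0 and ys > 0:
            best = max(best, abs(float(v @ y) / (vn * ys)))
    return best


def prune(
    module: NetworkModule,
    node_data: np.ndarray,
    phenotype: np.ndarray,
    min_size: int = 30,
    max_size: int = 300,
    n_pcs: int = 3,
    step: int = 10,
    tolerance: float = 0.05,
) -> PruneResult:
    """PageRank + summarization pruning of the global network.

    Nodes are ranked by PageRank (ties broken by node id); candidate
    prefixes from ``min_size`` to ``min(max_size, n)`` in steps of ``step``
    are scored by the best |Pearson correlation| between the first
    ``n_pcs`` summary scores and the phenotype; the smallest candidate
    within ``tolerance`` (fraction) of the best score is selected.
    """
    phenotype = np.asarray(phenotype, float).ravel()
    if node_data.shape[0] != phenotype.size:
        raise ValueError("phenotype length does not match sample count")
    n = module.n_nodes
    pr = pagerank_scores(module)
    order = sorted(range(n), key=lambda i: (-pr[i], module.node_ids[i]))
    order = np.asarray(order, int)

    top = min(max_size, n)
    if n <= min_size:
        sizes = [n]
    else:
        sizes = list(range(min_size, top + 1, step))
        if sizes[-1] != top:
            sizes.append(top)

    trace: list[tuple[int, float]] = []
    for size in sizes:
        sel = order[:size]
        scores = netshy_summarize(node_data[:, sel],
                                  module.adjacency[np.ix_(sel, sel)],
                                  n_pcs=min(n_pcs, size))
        trace.append((size, _max_abs_corr(scores, phenotype)))
    best = max(c for _, c in trace)
    chosen_size = next(size for size, c in trace if c >= (1 - tolerance) * best)
    selected = order[:chosen_size]
    summary = netshy_summarize(node_data[:, selected],
                               module.adjacency[np.ix_(selected, selected)],
                               n_pcs=min(n_pcs, chosen_size))
    return PruneResult(selected, module.subgraph(selected), trace, chosen_size,
                       summary, pagerank=pr)


def filter_edges(module: NetworkModule, node_data: np.ndarray,
                 threshold: float = 0.2) -> NetworkModule:
    """Remove edges whose endpoint features have |Pearson corr| < threshold.

    Surviving edges are annotated with the correlation and its sign
    (positive / negative co-variation of the underlying data).
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    x = np.asarray(node_data, float)
    if x.shape[1] != module.n_nodes:
        raise ValueError("node data and network are not aligned")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr))
    keep = np.abs(corr) >= threshold
    adjacency = np.where(keep, module.adjacency, 0.0)
    np.fill_diagonal(adjacency, 0.0)
    signs = np.sign(corr) * (adjacency > 0)
    out = NetworkModule(adjacency, list(module.node_ids), list(module.node_views),
                        list(module.node_feature_index))
    out.edge_signs = signs
    out.edge_correlations = np.where(adjacency > 0, corr, 0.0)
    return out


# --------------------------------------------------------------------------
# Exports
# --------------------------------------------------------------------------

def to_networkx(module: NetworkModule) -> nx.Graph:
    g = nx.Graph()
    for i, nid in enumerate(module.node_ids):
        g.add_node(nid, view=int(module.node_views[i]))
    a = module.adjacency
    ii, jj = np.nonzero(np.triu(a, 1))
    for i, j in zip(ii, jj):
        attrs = {"weight": float(a[i, j])}
        if module.edge_correlations is not None:
            attrs["correlation"] = float(module.edge_correlations[i, j])
            attrs["sign"] = "positive" if module.edge_signs[i, j] > 0 else "negative"
        g.add_edge(module.node_ids[i], module.node_ids[j], **attrs)
    return g


def write_edge_list(module: NetworkModule, path) -> pd.DataFrame:
    a = module.adjacency
    ii, jj = np.nonzero(np.triu(a, 1))
    rows = []
    for i, j in zip(ii, jj):
        corr = (float(module.edge_correlations[i, j])
                if module.edge_correlations is not None else np.nan)
        sign = ("" if np.isnan(corr)
                else ("positive" if corr > 0 else "negative"))
        rows.append((module.node_ids[i], module.node_ids[j],
                     float(a[i, j]), corr, sign))
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight",
                                     "correlation", "sign"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def node_table(module: NetworkModule, node_data: np.ndarray,
               phenotype: np.ndarray, view_names: list[str] | None = None,
               pagerank: np.ndarray | None = None) -> pd.DataFrame:
    """Per-node summary: PageRank, phenotype correlation, BH-adjusted p."""
    if pagerank is None:
        pagerank = pagerank_scores(module)
    y = np.asarray(phenotype, float).ravel()
    corrs, pvals = [], []
    for c in range(module.n_nodes):
        col = node_data[:, c]
        if np.std(col) == 0 or np.std(y) == 0:
            corrs.append(0.0)
            pvals.append(1.0)
        else:
            r, p = stats.pearsonr(col, y)
            corrs.append(float(r))
            pvals.append(float(p))
    fdr = stats.false_discovery_control(pvals, method="bh")
    names = (view_names if view_names is not None
             else [f"view{v}" for v in range(max(module.node_views) + 1)])
    return pd.DataFrame({
        "id": module.node_ids,
        "view": [names[v] for v in module.node_views],
        "pagerank": pagerank,
        "phenotype_correlation": corrs,
        "fdr": fdr,
    })
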