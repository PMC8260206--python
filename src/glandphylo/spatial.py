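"""Spatial clonal cartography on the ductal graph.

Distances are measured along the ducts (root-to-node path length in
micrometres), not through tissue, because clones spread by lining
ducts.  The module provides classical metric MDS for flattening the 3D
gland into figures, ordinary least-squares gradient regressions
(burden vs distance, telomere vs burden/distance), clone territories
with their ductal contiguity, the multiclonal-microdissection
fraction, and the spatial scope of adult clones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import pdist, squareform

from .ductal import DuctalGraph

CC_PRESENCE_THRESHOLD = 0.10


# ---------------------------------------------------------------------------
# ductal distances
# ---------------------------------------------------------------------------


def path_distance(graph: DuctalGraph, node: str) -> float:
    """Sum of edge lengths on the unique root-to-node duct path (um)."""
    if node not in graph:
        raise KeyError(f"node {node!r} not in ductal graph")
    dist = 0.0
    while (parent := graph.parent(node)) is not None:
        dist += graph.edge_length(parent, node)
        node = parent
    return dist


def all_path_distances(graph: DuctalGraph) -> dict[str, float]:
    out = {graph.root: 0.0}
    stack = [graph.root]
    while stack:
        n = stack.pop()
        for c in graph.children(n):
            out[c] = out[n] + graph.edge_length(n, c)
            stack.append(c)
    return out


def _pairwise_duct_distance(graph: DuctalGraph, nodes: list[str]) -> np.ndarray:
    g = graph.undirected()
    n = len(nodes)
    D = np.zeros((n, n))
    for i, u in enumerate(nodes):
        lengths = nx.single_source_dijkstra_path_length(g, u, weight="length")
        for j, v in enumerate(nodes):
            D[i, j] = lengths[v]
    return D


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------


def mds_2d(points_or_distances: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) metric MDS to two dimensions.

    Accepts either an (n, d) coordinate array or an (n, n) symmetric
    zero-diagonal distance matrix.  The Gram matrix is obtained by
    double centring -D^2/2; the embedding is the top-2 eigenvectors
    scaled by the square roots of their eigenvalues.  For
    reproducibility each output axis is oriented so that its
    largest-magnitude loading is positive.

    Returns ``(embedding, eigenvalues)`` with eigenvalues sorted
    descending.
    """
    X = np.asarray(points_or_distances, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2D array")
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a 2D embedding")
    if X.shape[0] == X.shape[1] and np.allclose(X, X.T) and np.allclose(np.diag(X), 0):
        D = X
    else:
        D = squareform(pdist(X))
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    neg_mass = float(np.abs(eigval[eigval < 0]).sum())
    pos_mass = float(eigval[eigval > 0].sum())
    if pos_mass > 0 and neg_mass > 0.5 * pos_mass:
        warnings.warn(
            "more than half the eigenvalue mass is negative: input distances "
            "are far from Euclidean",
            stacklevel=2,
        )
    emb = eigvec[:, :2] * np.sqrt(np.clip(eigval[:2], 0, None))
    for k in range(2):
        col = emb[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            emb[:, k] = -col
    return emb, eigval


# ---------------------------------------------------------------------------
# gradient regressions
# ---------------------------------------------------------------------------


@dataclass
class GradientFit:
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    r_squared: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_ci95": list(self.slope_ci),
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
        }


def gradient_regression(
    y_values, x_values, exclude_y_above: float | None = None
) -> GradientFit:
    """OLS of y on x with intercept.

    Used for burden ~ ductal distance (mutations/um), telomere ~
    distance (bp/um) and telomere ~ burden (bp/mutation).
    ``exclude_y_above`` supports the sensitivity re-fit that drops
    outlying samples (e.g. burdens above 2,000 mutations); it is not
    applied by default.
    """
    y = np.asarray(y_values, dtype=float)
    x = np.asarray(x_values, dtype=float)
    mask = ~(np.isnan(y) | np.isnan(x))
    if exclude_y_above is not None:
        mask &= y <= exclude_y_above
    y, x = y[mask], x[mask]
    if y.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()
    return GradientFit(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=int(y.size),
    )


def multiclonality_vs_distance(
    multiclonal: np.ndarray, distances: np.ndarray
) -> dict:
    """Logistic regression of multiclonal status on ductal distance.

    The choice of a logistic model for "does multiclonality correlate
    with distance" is this package's own; it returns the slope (per um,
    log-odds) and its p-value.
    """
    y = np.asarray(multiclonal, dtype=float)
    X = sm.add_constant(np.asarray(distances, dtype=float))
    if len(np.unique(y)) < 2:
        return {"slope": 0.0, "p_value": 1.0, "note": "no variation in outcome"}
    fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return {"slope": float(fit.params[1]), "p_value": float(fit.pvalues[1])}


# ---------------------------------------------------------------------------
# clone territories
# ---------------------------------------------------------------------------


@dataclass
class CloneTerritory:
    cluster_id: str
    positive_samples: list[str]
    components: list[set[str]]
    span_um: float

    @property
    def n_samples(self) -> int:
        return len(self.positive_samples)

    @property
    def n_components(self) -> int:
        return len(self.components)


def clone_territory(
    graph: DuctalGraph,
    cc_row: pd.Series,
    sample_nodes: pd.Series,
    threshold: float = CC_PRESENCE_THRESHOLD,
    cluster_id: str | None = None,
) -> CloneTerritory:
    """Positive samples of a clone and their contiguity in the ducts.

    Two positive samples belong to the same component iff the duct path
    between them passes through no node hosting a negative sample
    (unsampled nodes do not interrupt territories).  The span is the
    maximum pairwise duct-path distance between positive samples.
    """
    cc_row = cc_row.astype(float)
    positive = sorted(cc_row.index[cc_row >= threshold])
    cid = cluster_id if cluster_id is not None else str(cc_row.name)
    if not positive:
        return CloneTerritory(cid, [], [], 0.0)
    pos_nodes = {s: str(sample_nodes[s]) for s in positive}
    neg_nodes = {
        str(sample_nodes[s]) for s in cc_row.index if s not in set(positive)
    } - set(pos_nodes.values())
    g = graph.undirected()
    g.remove_nodes_from(neg_nodes)
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        for node in comp:
            comp_of[node] = ci
    groups: dict[int, set[str]] = {}
    for s, node in pos_nodes.items():
        groups.setdefault(comp_of[node], set()).add(s)
    components = [groups[k] for k in sorted(groups)]
    nodes = sorted(set(pos_nodes.values()))
    D = _pairwise_duct_distance(graph, nodes)
    span = float(D.max()) if len(nodes) > 1 else 0.0
    return CloneTerritory(cid, positive, components, span)


@dataclass
class MulticlonalResult:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> int:
        return int(round(100.0 * self.fraction))


def multiclonal_fraction(
    embryonic_cc: pd.DataFrame, threshold: float = CC_PRESENCE_THRESHOLD
) -> MulticlonalResult:
    """Fraction of microdissections with > ``threshold`` contribution
    from more than one embryonic clone."""
    if embryonic_cc.shape[1] == 0:
        raise ValueError("no samples")
    n_embryonic = (embryonic_cc.to_numpy(dtype=float) > threshold).sum(axis=0)
    return MulticlonalResult(
        numerator=int((n_embryonic >= 2).sum()), denominator=int(embryonic_cc.shape[1])
    )


def adult_clone_span(
    epochs: dict[str, str],
    territories: dict[str, CloneTerritory],
    max_adult_samples: int = 5,
) -> pd.DataFrame:
    """Spatial scope of adult clones.

    Adult clones are expected to stay within ``max_adult_samples``
    anatomically proximate microdissections; clones exceeding that are
    flagged as candidate driver expansions.
    """
    rows = []
    for cid, epoch in sorted(epochs.items()):
        if epoch != "adult" or cid not in territories:
            continue
        t = territories[cid]
        rows.append(
            {
                "cluster_id": cid,
                "n_samples": t.n_samples,
                "n_components": t.n_components,
                "span_um": t.span_um,
                "flagged_expansion": t.n_samples > max_adult_samples,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_samples", "n_components", "span_um", "flagged_expansion"],
    )
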