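"""Dirichlet-process clustering of mutations by their VAF vectors.

Mutations acquired on the same ancestral lineage branch share a cell of
origin and therefore show concordant VAFs across every microdissection.
The model is a DP mixture in which each cluster ``k`` carries an
independent latent VAF ``theta_{k,s}`` per sample with a Beta prior,
and a mutation's alt count in sample ``s`` is Binomial(depth, theta).
Inference is collapsed Gibbs sampling over the partition (the Betas are
integrated out), with a Chinese-restaurant-process prior at
concentration ``alpha``.

Single-site Gibbs merges redundant clusters readily but nucleates new
ones slowly, so the chain starts from a deliberately over-fragmented
k-means partition of the VAF vectors and anneals down.  The reported
hard assignment is the maximum-a-posteriori sweep; posterior
co-clustering frequencies over a subset of mutations are kept as a
diagnostic.

Under diploidy a cluster's per-sample median VAF ``m`` converts to the
cellular contribution ``cc = min(2 m, 1)``: the fraction of the
microdissection's cells descending from the cluster's ancestral cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2
from scipy.special import betaln, gammaln


@dataclass
class ClusterConfig:
    """Sampler settings.

    The Beta(1, 5) base measure favours low VAFs, matching the
    polyclonal regime where most clusters contribute a minority of a
    sample's cells.  Clusters below ``min_cluster_size`` mutations are
    dropped before tree building.  ``init`` is either ``"kmeans"``
    (over-fragmented k-means start, recommended) or ``"crp"``
    (sequential predictive assignment).  If more than
    ``max_gibbs_mutations`` mutations are supplied, the Gibbs scan runs
    on a random subset and the remainder is assigned to the MAP
    clusters by posterior likelihood.
    """

    alpha: float = 1.0
    max_iterations: int = 60
    burn_in: int = 30
    seed: int = 0
    min_cluster_size: int = 10
    beta_a: float = 1.0
    beta_b: float = 5.0
    init: str = "kmeans"
    kmeans_k: int | None = None  # default: n/150, clipped to [15, 120]
    max_gibbs_mutations: int = 40000
    thin: int = 3
    cocluster_max: int = 1500

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("concentration alpha must be positive")
        if not 0 <= self.burn_in < self.max_iterations:
            raise ValueError("burn_in must be below max_iterations")
        if self.init not in ("kmeans", "crp"):
            raise ValueError("init must be 'kmeans' or 'crp'")


@dataclass
class ClusterResult:
    assignments: pd.Series  # mutation_id -> cluster_id
    clusters: pd.DataFrame  # cluster_id, n_mutations
    median_vaf: pd.DataFrame  # cluster x sample
    cc: pd.DataFrame  # cluster x sample, min(2 m, 1)
    cocluster: pd.DataFrame | None  # posterior co-clustering (diagnostic subset)
    converged: bool
    trace_n_clusters: list[int] = field(default_factory=list)
    map_score: float = float("nan")

    def filtered(self, min_cluster_size: int | None = None) -> "ClusterResult":
        """Drop clusters below the size threshold (default 10
        mutations, the tree-building requirement)."""
        keep = list(filter_clusters(self.clusters, min_cluster_size or 10)["cluster_id"])
        assignments = self.assignments[self.assignments.isin(keep)]
        return ClusterResult(
            assignments=assignments,
            clusters=self.clusters[self.clusters["cluster_id"].isin(keep)].reset_index(
                drop=True
            ),
            median_vaf=self.median_vaf.loc[keep],
            cc=self.cc.loc[keep],
            cocluster=self.cocluster,
            converged=self.converged,
            trace_n_clusters=self.trace_n_clusters,
            map_score=self.map_score,
        )


def cellular_contribution(median_vaf: float):
    """cc = min(2 m, 1): a median VAF of 0.5 means every cell in the
    microdissection descends from the cluster's ancestral cell."""
    m = np.asarray(median_vaf, dtype=float)
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("median VAF must lie in [0, 1]")
    cc = np.minimum(2.0 * m, 1.0)
    return float(cc) if np.ndim(median_vaf) == 0 else cc


def filter_clusters(clusters: pd.DataFrame, min_cluster_size: int = 10) -> pd.DataFrame:
    """Keep clusters with at least ``min_cluster_size`` mutations."""
    return clusters[clusters["n_mutations"] >= min_cluster_size].reset_index(drop=True)


def artifact_screen(
    assignments: pd.Series,
    mutation_flags: pd.Series,
    min_flagged_fraction: float = 0.5,
) -> list[str]:
    """Report clusters whose members are systematically flagged.

    ``mutation_flags`` marks mutations with poor quality surrogates
    (e.g. low mapping quality).  This replaces a manual per-cluster
    artifact inspection with a reporting hook; nothing is removed.
    """
    flagged = []
    for cid, members in assignments.groupby(assignments):
        frac = float(mutation_flags.reindex(members.index).fillna(False).mean())
        if frac >= min_flagged_fraction:
            flagged.append(str(cid))
    return sorted(flagged)


# ---------------------------------------------------------------------------
# collapsed Gibbs sampler
# ---------------------------------------------------------------------------


class _BetalnTable:
    """betaln(a0 + x, b0 + y) via a gammaln lookup when a0, b0 are
    integral (the default Beta(1, 5)); falls back to scipy otherwise."""

    def __init__(self, a0: float, b0: float, max_count: int):
        self.a0, self.b0 = a0, b0
        self.fast = float(a0).is_integer() and float(b0).is_integer()
        if self.fast:
            self.ia, self.ib = int(a0), int(b0)
            self.gl = gammaln(np.arange(max_count + self.ia + self.ib + 2, dtype=float))

    def __call__(self, x, y):
        if self.fast:
            x = np.asarray(x) + self.ia
            y = np.asarray(y) + self.ib
            return self.gl[x] + self.gl[y] - self.gl[x + y]
        return betaln(self.a0 + x, self.b0 + y)


class _GibbsState:
    """Sufficient statistics of the current partition."""

    def __init__(self, n_samples: int, table: _BetalnTable, capacity: int = 64):
        self.S = n_samples
        self.table = table
        self.K = 0
        self.N = np.zeros(capacity, dtype=np.int64)
        self.A = np.zeros((capacity, n_samples), dtype=np.int64)
        self.R = np.zeros((capacity, n_samples), dtype=np.int64)  # depth - alt
        # cached betaln(a0 + A, b0 + R) per cluster
        self.base = np.zeros((capacity, n_samples), dtype=float)

    def _grow(self) -> None:
        cap = self.N.shape[0] * 2
        self.N = np.resize(self.N, cap)
        for name in ("A", "R", "base"):
            arr = getattr(self, name)
            new = np.zeros((cap, self.S), dtype=arr.dtype)
            new[: arr.shape[0]] = arr
            setattr(self, name, new)

    def _refresh(self, k: int) -> None:
        self.base[k] = self.table(self.A[k], self.R[k])

    def add(self, k: int, a: np.ndarray, r: np.ndarray) -> None:
        self.N[k] += 1
        self.A[k] += a
        self.R[k] += r
        self._refresh(k)

    def new_cluster(self, a: np.ndarray, r: np.ndarray) -> int:
        if self.K == self.N.shape[0]:
            self._grow()
        k = self.K
        self.K += 1
        self.N[k] = 0
        self.A[k] = 0
        self.R[k] = 0
        self.add(k, a, r)
        return k

    def remove(self, k: int, a: np.ndarray, r: np.ndarray) -> int | None:
        """Remove one observation; returns the index of the cluster
        relocated into slot ``k`` (swap-delete), if any."""
        self.N[k] -= 1
        self.A[k] -= a
        self.R[k] -= r
        if self.N[k] == 0:
            last = self.K - 1
            moved = None
            if k != last:
                self.N[k] = self.N[last]
                self.A[k] = self.A[last]
                self.R[k] = self.R[last]
                self.base[k] = self.base[last]
                moved = last
            self.K -= 1
            return moved
        self._refresh(k)
        return None

    def score(self, alpha: float) -> float:
        """Joint log posterior of the partition up to constants."""
        K = self.K
        crp = K * np.log(alpha) + gammaln(self.N[:K]).sum()
        lik = self.base[:K].sum() - K * self.S * betaln(self.table.a0, self.table.b0)
        return float(crp + lik)


def _init_labels(A: np.ndarray, D: np.ndarray, config: ClusterConfig, rng) -> np.ndarray:
    n = A.shape[0]
    if config.init == "crp" or n < 30:
        return np.full(n, -1, dtype=np.int64)
    vaf = A / np.maximum(D, 1)
    k = config.kmeans_k or int(np.clip(n // 150, 15, 120))
    k = min(k, n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, labels = kmeans2(vaf, k, minit="++", seed=rng)
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return labels.astype(np.int64)


def _gibbs(
    A: np.ndarray,
    D: np.ndarray,
    config: ClusterConfig,
    rng: np.random.Generator,
    cocluster_idx: np.ndarray,
):
    n, S = A.shape
    R = D - A
    alpha = config.alpha
    table = _BetalnTable(
        config.beta_a, config.beta_b, int(D.sum(axis=0).max()) + int(D.max()) + 2
    )
    state = _GibbsState(S, table)
    ref = betaln(config.beta_a, config.beta_b)
    log_alpha = np.log(alpha)
    # per-mutation marginal under an empty cluster, precomputed
    self_marg = (table(A, R) - ref).sum(axis=1)

    def assign(i):
        a, r = A[i], R[i]
        K = state.K
        num = table(state.A[:K] + a, state.R[:K] + r)
        logw = np.empty(K + 1)
        np.log(state.N[:K], out=logw[:K])
        logw[:K] += (num - state.base[:K]).sum(axis=1)
        logw[K] = log_alpha + self_marg[i]
        # inverse-CDF sampling from the normalised weights
        logw -= logw.max()
        w = np.exp(logw)
        cdf = np.cumsum(w)
        k = int(np.searchsorted(cdf, rng.random() * cdf[-1]))
        if k >= state.K:
            k = state.new_cluster(a, r)
        else:
            state.add(k, a, r)
        z[i] = k

    z = _init_labels(A, D, config, rng)
    if z[0] < 0:  # sequential CRP initialisation in canonical order
        for i in range(n):
            assign(i)
    else:
        for k in range(int(z.max()) + 1):
            members = np.flatnonzero(z == k)
            kk = state.new_cluster(A[members[0]], R[members[0]])
            for i in members[1:]:
                state.N[kk] += 1
                state.A[kk] += A[i]
                state.R[kk] += R[i]
            state._refresh(kk)
            z[members] = kk

    def merge_gain(j: int, ks: np.ndarray) -> np.ndarray:
        """Collapsed log posterior gain of merging cluster j into each of ks."""
        joint = table(state.A[j] + state.A[ks], state.R[j] + state.R[ks])
        lik = (joint - state.base[j] - state.base[ks]).sum(axis=1) + S * ref
        crp = (
            gammaln(state.N[j] + state.N[ks])
            - gammaln(state.N[j])
            - gammaln(state.N[ks])
            - log_alpha
        )
        return lik + crp

    def merge_pass(max_merges: int = 20) -> None:
        """Greedy merges of redundant clusters; single-site updates
        drain clusters one mutation at a time and stall in split local
        modes, so whole-cluster merges are proposed explicitly."""
        for _ in range(max_merges):
            K = state.K
            if K < 2:
                return
            best = (0.0, None, None)
            for j in range(K - 1):
                ks = np.arange(j + 1, K)
                gains = merge_gain(j, ks)
                kbest = int(np.argmax(gains))
                if gains[kbest] > best[0]:
                    best = (float(gains[kbest]), j, int(ks[kbest]))
            if best[1] is None:
                return
            _, j, k = best
            z[z == k] = j
            state.N[j] += state.N[k]
            state.A[j] += state.A[k]
            state.R[j] += state.R[k]
            state._refresh(j)
            last = state.K - 1
            if k != last:
                state.N[k] = state.N[last]
                state.A[k] = state.A[last]
                state.R[k] = state.R[last]
                state.base[k] = state.base[last]
                z[z == last] = k
            state.K -= 1

    def split_pass(min_size: int = 8) -> None:
        """Propose bisecting each cluster (2-means on member VAFs) and
        accept splits that raise the collapsed posterior.  Single-site
        updates cannot nucleate a small cluster out of a large one when
        the first move alone loses probability, so splits are proposed
        wholesale."""
        from scipy.cluster.vq import kmeans2 as _km2

        for k in range(state.K):
            members = np.flatnonzero(z == k)
            if members.size < min_size:
                continue
            vaf = A[members] / np.maximum(D[members], 1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, sub = _km2(vaf, 2, minit="++", seed=rng)
            left = members[sub == 0]
            right = members[sub == 1]
            if left.size == 0 or right.size == 0:
                continue
            A1, R1 = A[left].sum(axis=0), R[left].sum(axis=0)
            A2, R2 = A[right].sum(axis=0), R[right].sum(axis=0)
            gain = (
                (table(A1, R1) + table(A2, R2) - state.base[k]).sum()
                - S * ref
                + gammaln(left.size)
                + gammaln(right.size)
                - gammaln(state.N[k])
                + log_alpha
            )
            if gain > 0:
                new = state.new_cluster(A[right[0]], R[right[0]])
                for i in right[1:]:
                    state.N[new] += 1
                    state.A[new] += A[i]
                    state.R[new] += R[i]
                state._refresh(new)
                z[right] = new
                state.N[k] -= right.size
                state.A[k] -= A2
                state.R[k] -= R2
                state._refresh(k)

    best_score = -np.inf
    best_z = z.copy()
    trace = []
    cocount = None
    n_cosamples = 0
    for it in range(config.max_iterations):
        for i in range(n):
            moved = state.remove(z[i], A[i], R[i])
            if moved is not None:
                z[z == moved] = z[i]
            z[i] = -1
            assign(i)
        split_pass()
        merge_pass()
        trace.append(int(state.K))
        score = state.score(alpha)
        if score > best_score:  # ties keep the earliest iteration
            best_score = score
            best_z = z.copy()
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            zc = z[cocluster_idx]
            eq = zc[:, None] == zc[None, :]
            if cocount is None:
                cocount = eq.astype(np.int32)
            else:
                cocount += eq
            n_cosamples += 1

    tail_len = min(10, max(len(trace) // 4, 2))
    tail = trace[-tail_len:]
    converged = (max(tail) - min(tail)) <= 2
    cofreq = cocount / n_cosamples if n_cosamples else None
    return best_z, best_score, trace, converged, cofreq


def _classify(
    A: np.ndarray, D: np.ndarray, Ak: np.ndarray, Dk: np.ndarray, Nk: np.ndarray,
    a0: float, b0: float,
) -> np.ndarray:
    """Assign mutations to fixed clusters by posterior-mean likelihood."""
    theta = (a0 + Ak) / (a0 + b0 + Dk)  # (K, S)
    ll = A @ np.log(theta).T + (D - A) @ np.log1p(-theta).T
    ll += np.log(Nk)[None, :]
    return np.argmax(ll, axis=1)


def cluster_mutations(vaf_matrix, config: ClusterConfig | None = None) -> ClusterResult:
    """Cluster mutations by their VAF vectors across samples.

    Deterministic for a fixed ``config.seed``; the scan runs in
    canonical (sorted mutation id) order, so permuting the input rows
    does not change the result.
    """
    if config is None:
        config = ClusterConfig()
    config.validate()
    vm = vaf_matrix.sort()
    A_all = vm.alt.to_numpy()
    D_all = vm.depth.to_numpy()
    if vm.n_mutations == 0:
        raise ValueError("empty mutation table")
    if not (D_all > 0).any():
        raise ValueError("all depths are zero; nothing to cluster")
    mutations = np.array(vm.mutations)
    samples = list(vm.samples)
    rng = np.random.default_rng(config.seed)

    n = len(mutations)
    if n > config.max_gibbs_mutations:
        subset = np.sort(rng.choice(n, size=config.max_gibbs_mutations, replace=False))
    else:
        subset = np.arange(n)
    rest = np.setdiff1d(np.arange(n), subset)
    cocluster_idx = np.sort(
        rng.choice(
            subset.size, size=min(config.cocluster_max, subset.size), replace=False
        )
    )

    z_sub, map_score, trace, converged, cofreq = _gibbs(
        A_all[subset], D_all[subset], config, rng, cocluster_idx
    )
    if not converged:
        warnings.warn("cluster-count trace still drifting; increase max_iterations",
                      stacklevel=2)

    K = int(z_sub.max()) + 1
    Ak = np.zeros((K, vm.n_samples), dtype=np.int64)
    Dk = np.zeros((K, vm.n_samples), dtype=np.int64)
    Nk = np.zeros(K, dtype=np.int64)
    np.add.at(Ak, z_sub, A_all[subset])
    np.add.at(Dk, z_sub, D_all[subset])
    np.add.at(Nk, z_sub, 1)

    z_all = np.empty(n, dtype=np.int64)
    z_all[subset] = z_sub
    if rest.size:
        z_all[rest] = _classify(
            A_all[rest], D_all[rest], Ak, Dk, Nk, config.beta_a, config.beta_b
        )

    # relabel by size, largest first
    sizes = np.bincount(z_all, minlength=K)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(K, dtype=np.int64)
    relabel[order] = np.arange(K)
    z_all = relabel[z_all]
    width = len(str(max(K - 1, 1)))
    names = np.array([f"c{j:0{width}d}" for j in range(K)])

    assignments = pd.Series(names[z_all], index=mutations, name="cluster_id")
    cluster_ids = [names[j] for j in range(K) if (z_all == j).any()]

    vaf = vm.vaf().to_numpy()
    med = np.full((len(cluster_ids), vm.n_samples), np.nan)
    n_mut = []
    for row, cid in enumerate(cluster_ids):
        mask = assignments.to_numpy() == cid
        n_mut.append(int(mask.sum()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med[row] = np.nanmedian(vaf[mask], axis=0)
    med = np.nan_to_num(med, nan=0.0)
    median_vaf = pd.DataFrame(med, index=cluster_ids, columns=samples)
    cc = median_vaf.apply(lambda col: np.minimum(2.0 * col, 1.0))

    cocluster = None
    if cofreq is not None:
        sub_ids = mutations[subset][cocluster_idx]
        cocluster = pd.DataFrame(cofreq, index=sub_ids, columns=sub_ids)

    clusters = pd.DataFrame({"cluster_id": cluster_ids, "n_mutations": n_mut})
    return ClusterResult(
        assignments=assignments,
        clusters=clusters,
        median_vaf=median_vaf,
        cc=cc,
        cocluster=cocluster,
        converged=converged,
        trace_n_clusters=trace,
        map_score=map_score,
    )
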