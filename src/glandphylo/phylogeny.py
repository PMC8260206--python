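"""Pigeonhole ordering of mutation clusters into a rooted clone tree.

Cellular contributions of disjoint clones cannot sum above 100% in any
microdissection, so overlapping contributions force nesting.  Three
rules, strongest first, generate nesting evidence between cluster
pairs:

* ``certain_95`` — both clusters exceed 95% cellular contribution in
  the same microdissection; they must be nested.
* ``strong_75`` — the clusters show the same relative contribution
  pattern across microdissections (cosine similarity of their cc
  vectors) and jointly reach at least 75% somewhere.
* ``pigeonhole_sum`` — their contributions sum above 100% (plus a
  noise tolerance) in some microdissection, so they cannot be
  disjoint.

In every rule the cluster with the greater contribution in the
witnessing sample is the ancestor.  Each cluster then attaches to its
most recent proven ancestor; branch lengths are cluster mutation
counts, so root-to-node path lengths are molecular times convertible
to developmental epochs (embryonic < 20 mutations, pubertal 300-500,
adult > 500).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

RULES = ("certain_95", "strong_75", "pigeonhole_sum")
EPOCH_BOUNDARIES = (20.0, 300.0, 500.0)
CC_PRESENCE_THRESHOLD = 0.10


class CyclicEvidenceError(ValueError):
    def __init__(self, cycle):
        self.cycle = cycle
        super().__init__(f"cyclic nesting evidence: {cycle}")


@dataclass(frozen=True)
class NestingEvidence:
    ancestor: str
    descendant: str
    rule: str
    witness_samples: tuple[str, ...]


@dataclass(frozen=True)
class NestingConflict:
    cluster_a: str
    cluster_b: str
    rule: str
    detail: str


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def infer_nesting(
    cc: pd.DataFrame,
    tolerance: float = 0.1,
    certain_threshold: float = 0.95,
    strong_threshold: float = 0.75,
    cosine_min: float = 0.95,
) -> tuple[list[NestingEvidence], list[NestingConflict]]:
    """Derive nesting evidence from a cluster x sample cc matrix.

    For each pair the strongest applicable rule is emitted.  If
    different witnessing samples imply opposite directions the pair is
    reported as a conflict instead of evidence.
    """
    clusters = list(cc.index)
    samples = list(cc.columns)
    M = cc.to_numpy(dtype=float)
    evidence: list[NestingEvidence] = []
    conflicts: list[NestingConflict] = []
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            a, b = M[i], M[j]
            rule = None
            witnesses: np.ndarray | None = None
            both_high = (a > certain_threshold) & (b > certain_threshold)
            if both_high.any():
                rule, witnesses = "certain_95", np.flatnonzero(both_high)
            elif (
                _cosine(a, b) >= cosine_min
                and ((joint := a + b) >= strong_threshold).any()
            ):
                rule, witnesses = "strong_75", np.flatnonzero(joint >= strong_threshold)
            elif ((over := a + b) > 1.0 + tolerance).any():
                rule, witnesses = "pigeonhole_sum", np.flatnonzero(over > 1.0 + tolerance)
            if rule is None:
                continue
            # a direction is only admissible if the descendant never
            # exceeds the ancestor (within tolerance) in any sample
            ok_i_anc = bool((b <= a + tolerance).all())
            ok_j_anc = bool((a <= b + tolerance).all())
            if not ok_i_anc and not ok_j_anc:
                # joint cc near or above 2x the pigeonhole bound cannot
                # come from disjoint clones whatever the noise, so
                # nesting is certain even though monotonicity broke
                forced = rule == "certain_95" or float((a + b).max()) >= 1.4
                if forced:
                    # direct by total contribution
                    evidence.append(
                        NestingEvidence(
                            ancestor=clusters[i] if a.sum() >= b.sum() else clusters[j],
                            descendant=clusters[j] if a.sum() >= b.sum() else clusters[i],
                            rule=rule,
                            witness_samples=tuple(samples[s] for s in witnesses),
                        )
                    )
                    continue
                conflicts.append(
                    NestingConflict(
                        clusters[i],
                        clusters[j],
                        rule,
                        "no direction satisfies cc monotonicity",
                    )
                )
                continue
            if ok_i_anc != ok_j_anc:
                i_is_anc = ok_i_anc
            else:
                diffs = a[witnesses] - b[witnesses]
                if (diffs > 0).any() and (diffs < 0).any():
                    conflicts.append(
                        NestingConflict(
                            clusters[i],
                            clusters[j],
                            rule,
                            "witnessing samples disagree on direction",
                        )
                    )
                    continue
                if (diffs != 0).any():
                    i_is_anc = diffs[diffs != 0][0] > 0
                else:  # exact ties in every witness: larger total contribution
                    i_is_anc = a.sum() >= b.sum()
            anc, dec = (clusters[i], clusters[j]) if i_is_anc else (clusters[j], clusters[i])
            evidence.append(
                NestingEvidence(
                    ancestor=anc,
                    descendant=dec,
                    rule=rule,
                    witness_samples=tuple(samples[s] for s in witnesses),
                )
            )
    return evidence, conflicts


# ---------------------------------------------------------------------------
# clone tree
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    parent: str | None
    children: list[str] = field(default_factory=list)
    branch_length: float = 0.0
    epoch: str | None = None


class CloneTree:
    """Rooted tree of clusters; branch lengths in mutations.

    A synthetic root (id ``"root"``) with zero branch length anchors
    clusters that have no proven ancestor.
    """

    ROOT = "root"

    def __init__(self):
        self.nodes: dict[str, _Node] = {self.ROOT: _Node(parent=None)}
        self.ambiguous: dict[str, list[str]] = {}
        self.cc_violations: list[tuple[str, str, str]] = []

    # -- construction -------------------------------------------------

    def add(self, node_id: str, parent: str, branch_length: float) -> None:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node {node_id}")
        if parent not in self.nodes:
            raise ValueError(f"unknown parent {parent}")
        self.nodes[node_id] = _Node(parent=parent, branch_length=float(branch_length))
        self.nodes[parent].children.append(node_id)

    @classmethod
    def from_parents(
        cls, parents: dict[str, str], branch_lengths: dict[str, float]
    ) -> "CloneTree":
        tree = cls()
        remaining = dict(parents)
        while remaining:
            progressed = [c for c, p in remaining.items() if p in tree.nodes]
            if not progressed:
                raise ValueError(f"orphaned nodes: {sorted(remaining)}")
            for c in sorted(progressed):
                tree.add(c, remaining.pop(c), branch_lengths.get(c, 0.0))
        return tree

    # -- queries ------------------------------------------------------

    @property
    def clusters(self) -> list[str]:
        return [n for n in self.nodes if n != self.ROOT]

    def parent(self, node: str) -> str | None:
        return self.nodes[node].parent

    def children(self, node: str) -> list[str]:
        return list(self.nodes[node].children)

    def branch_length(self, node: str) -> float:
        return self.nodes[node].branch_length

    def molecular_time(self, node: str) -> float:
        """Cumulative mutation count from the root to ``node``."""
        t = 0.0
        while node is not None:
            t += self.nodes[node].branch_length
            node = self.nodes[node].parent
        return t

    def subtree(self, node: str) -> set[str]:
        out = {node}
        stack = list(self.nodes[node].children)
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(self.nodes[n].children)
        return out

    def clades(self) -> set[frozenset]:
        """Label sets of all non-root subtrees (the tree's clades)."""
        return {frozenset(self.subtree(n)) for n in self.clusters}

    def restrict(self, keep: set[str]) -> "CloneTree":
        """Splice out clusters not in ``keep``, summing branch lengths
        through removed nodes."""
        out = CloneTree()

        def walk(node: str, anchor: str, carried: float) -> None:
            for child in self.nodes[node].children:
                bl = self.nodes[child].branch_length + carried
                if child in keep:
                    out.add(child, anchor, bl)
                    walk(child, child, 0.0)
                else:
                    walk(child, anchor, bl)

        walk(self.ROOT, self.ROOT, 0.0)
        return out

    # -- newick -------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: str) -> str:
            n = self.nodes[node]
            kids = (
                "(" + ",".join(fmt(c) for c in sorted(n.children)) + ")"
                if n.children
                else ""
            )
            return f"{kids}{node}:{n.branch_length:.10g}"

        return fmt(self.ROOT) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "CloneTree":
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False
        )
        tree = cls()

        def label(nd) -> str:
            return nd.taxon.label if nd.taxon is not None else nd.label

        def walk(nd, parent_id: str) -> None:
            for child in nd.child_nodes():
                cid = label(child)
                tree.add(cid, parent_id, child.edge.length or 0.0)
                walk(child, cid)

        root = dtree.seed_node
        if label(root) not in (cls.ROOT, None):
            # rooted at a real cluster: hang it under the synthetic root
            rid = label(root)
            tree.add(rid, cls.ROOT, root.edge.length or 0.0)
            walk(root, rid)
        else:
            walk(root, cls.ROOT)
        return tree


def build_tree(
    cc: pd.DataFrame,
    n_mutations: pd.Series,
    evidence: list[NestingEvidence],
    tolerance: float = 0.1,
) -> CloneTree:
    """Assemble the clone tree from nesting evidence.

    Each cluster's parent is its most recent proven ancestor: among the
    ancestors implied by the (transitively closed) evidence, the one
    minimising the total cc slack ``sum_s max(cc_anc - cc_child, 0)``.
    Clusters with no ancestor attach to the synthetic root.  Ambiguous
    attachments (ancestor sets that are not totally ordered) are
    recorded on the tree; cyclic evidence raises
    :class:`CyclicEvidenceError`.
    """
    clusters = list(cc.index)
    dag = nx.DiGraph()
    dag.add_nodes_from(clusters)
    dag.add_edges_from((e.ancestor, e.descendant) for e in evidence)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = [u for u, _ in nx.find_cycle(dag)]
        raise CyclicEvidenceError(cycle)
    closure = nx.transitive_closure_dag(dag)

    parents: dict[str, str] = {}
    ambiguous: dict[str, list[str]] = {}
    for c in clusters:
        ancestors = sorted(closure.predecessors(c))
        if not ancestors:
            parents[c] = CloneTree.ROOT
            continue
        child_cc = cc.loc[c].to_numpy()

        def slack(anc: str) -> float:
            diff = cc.loc[anc].to_numpy() - child_cc
            return float(np.clip(diff, 0, None).sum())

        # most recent ancestor: the candidate that is itself nested
        # below the largest number of the other candidates; cc slack
        # breaks the remaining ties
        def depth(anc: str) -> int:
            return sum(closure.has_edge(other, anc) for other in ancestors)

        best = min(
            ancestors, key=lambda a: (-depth(a), slack(a), cc.loc[a].sum(), a)
        )
        parents[c] = best
        # total order check: every ancestor pair must itself be nested
        for a in ancestors:
            for b in ancestors:
                if a < b and not (closure.has_edge(a, b) or closure.has_edge(b, a)):
                    ambiguous.setdefault(c, []).append(f"{a}|{b}")
    tree = CloneTree.from_parents(
        parents, {c: float(n_mutations.get(c, 0)) for c in clusters}
    )
    tree.ambiguous = ambiguous
    # report (not repair) cc monotonicity violations along edges
    for c in clusters:
        p = tree.parent(c)
        if p == CloneTree.ROOT:
            continue
        over = cc.loc[c] > cc.loc[p] + tolerance
        for s in cc.columns[over]:
            tree.cc_violations.append((p, c, s))
    return tree


def molecular_time(tree: CloneTree, node: str) -> float:
    return tree.molecular_time(node)


def classify_epoch(
    molecular_time: float, boundaries: tuple[float, float, float] = EPOCH_BOUNDARIES
) -> str:
    """Map molecular time (mutations) to a developmental epoch.

    ``< 20`` embryonic, ``[20, 300)`` childhood (an epoch in which
    essentially no coalescences are observed), ``[300, 500]`` pubertal,
    ``> 500`` adult.
    """
    if molecular_time < 0:
        raise ValueError("molecular time cannot be negative")
    embryonic, pubertal_lo, pubertal_hi = boundaries
    if molecular_time < embryonic:
        return "embryonic"
    if molecular_time < pubertal_lo:
        return "childhood"
    if molecular_time <= pubertal_hi:
        return "pubertal"
    return "adult"


def classify_tree_epochs(
    tree: CloneTree, boundaries: tuple[float, float, float] = EPOCH_BOUNDARIES
) -> dict[str, str]:
    epochs = {}
    for c in tree.clusters:
        epoch = classify_epoch(tree.molecular_time(c), boundaries)
        tree.nodes[c].epoch = epoch
        epochs[c] = epoch
    return epochs


def supporting_samples(
    cc_row: pd.Series, threshold: float = CC_PRESENCE_THRESHOLD
) -> int:
    """Number of microdissections to which the cluster contributes at
    least ``threshold`` of cells (boundary inclusive)."""
    return int((cc_row >= threshold).sum())


def adult_coalescences(tree: CloneTree) -> list[str]:
    """Internal nodes with >= 2 cluster children whose molecular time
    falls in adulthood (coalescences during adult tissue maintenance)."""
    if any(tree.nodes[c].epoch is None for c in tree.clusters):
        classify_tree_epochs(tree)
    return sorted(
        c
        for c in tree.clusters
        if len(tree.children(c)) >= 2 and tree.nodes[c].epoch == "adult"
    )


def rf_distance(tree_a: CloneTree, tree_b: CloneTree) -> int:
    """Robinson-Foulds distance between two labelled clone trees: the
    symmetric difference of their clade label-sets."""
    return len(tree_a.clades() ^ tree_b.clades())
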