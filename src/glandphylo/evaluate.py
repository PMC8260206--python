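"""Comparing recovered structure against simulation ground truth.

The simulator knows which lineage branch every mutation sits on and
what each clone contributes to every microdissection; these helpers
score a clustering/tree reconstruction against that truth, restricted
to the clones a read-count experiment can plausibly recover (enough
stem mutations to pass the cluster-size filter and a sizeable cellular
contribution somewhere).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phylogeny import build_tree, infer_nesting, rf_distance
from .simulate import SimulationTruth


def majority_mapping(assignments: pd.Series, truth: SimulationTruth) -> pd.Series:
    """Map each inferred cluster to the true clone contributing the
    majority of its (stem) members."""
    stems = truth.mutations[truth.mutations["kind"] == "stem"]
    clone_of = stems.set_index("mutation_id")["clone_id"]
    df = pd.DataFrame({"cluster": assignments})
    df["clone"] = clone_of.reindex(df.index)
    df = df.dropna()
    mapping = {}
    for cid, grp in df.groupby("cluster", observed=True):
        mapping[cid] = grp["clone"].mode().iloc[0]
    return pd.Series(mapping, name="clone_id")


def clustering_ari(
    assignments: pd.Series,
    truth: SimulationTruth,
    min_cc: float = 0.2,
    min_mutations: int = 10,
) -> float:
    """Adjusted Rand index on the stem mutations of detectable clones."""
    from sklearn.metrics import adjusted_rand_score

    detectable = set(truth.detectable_clones(min_cc, min_mutations))
    meta = truth.mutations.set_index("mutation_id")
    ids = [
        m
        for m in assignments.index
        if m in meta.index
        and meta.loc[m, "kind"] == "stem"
        and meta.loc[m, "clone_id"] in detectable
    ]
    if not ids:
        return float("nan")
    return float(
        adjusted_rand_score(meta.loc[ids, "clone_id"], assignments.loc[ids])
    )


def tree_recovery_rf(
    cluster_result,
    truth: SimulationTruth,
    tolerance: float = 0.1,
    min_cc: float = 0.2,
    min_mutations: int = 10,
) -> dict:
    """Robinson-Foulds distance between the inferred clone tree and the
    truth tree, both restricted to detectable clones.

    Inferred clusters are identified with true clones by majority vote
    over their stem members; the inferred tree is built from the
    cluster cc matrix with the pigeonhole rules, relabelled by matched
    clone, and compared clade-by-clade with the truth tree restricted
    to the same clone set.  A detectable clone with no matching cluster
    counts as a missed clade.
    """
    cc = cluster_result.cc
    n_mut = cluster_result.clusters.set_index("cluster_id")["n_mutations"]
    evidence, _conflicts = infer_nesting(cc, tolerance=tolerance)
    inferred = build_tree(cc, n_mut, evidence, tolerance=tolerance)

    mapping = majority_mapping(cluster_result.assignments, truth)
    detectable = set(truth.detectable_clones(min_cc, min_mutations))
    matched = {
        cid: clone for cid, clone in mapping.items() if clone in detectable
    }
    # a clone claimed by several clusters keeps the largest cluster
    by_clone: dict[str, str] = {}
    sizes = cluster_result.clusters.set_index("cluster_id")["n_mutations"]
    for cid, clone in matched.items():
        if clone not in by_clone or sizes[cid] > sizes[by_clone[clone]]:
            by_clone[clone] = cid
    keep = set(by_clone.values())

    restricted = inferred.restrict(keep)
    relabel = {cid: clone for clone, cid in by_clone.items()}
    renamed_parents = {}
    lengths = {}
    for cid in restricted.clusters:
        parent = restricted.parent(cid)
        renamed_parents[relabel[cid]] = (
            parent if parent == restricted.ROOT else relabel[parent]
        )
        lengths[relabel[cid]] = restricted.branch_length(cid)
    from .phylogeny import CloneTree

    inferred_renamed = CloneTree.from_parents(renamed_parents, lengths)
    true_tree = truth.true_tree(clones=sorted(detectable))
    rf = rf_distance(inferred_renamed, true_tree)
    return {
        "rf": rf,
        "n_detectable": len(detectable),
        "n_matched": len(by_clone),
        "missed_clones": sorted(detectable - set(by_clone)),
        "inferred_tree": inferred_renamed,
        "true_tree": true_tree,
    }
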