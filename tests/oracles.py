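"""Independent brute-force oracles used by the tree tests.

These re-derive pigeonhole consequences from first principles (explicit
enumeration of parent maps, direct rule application) so that the
optimised implementations can be checked against them.
"""

import itertools

import numpy as np
import pandas as pd

TOL = 0.1


def oracle_evidence(cc: pd.DataFrame):
    """Re-derive the nesting evidence set with direct, unoptimised logic."""
    out = set()
    names = list(cc.index)
    for a, b in itertools.combinations(names, 2):
        va, vb = cc.loc[a].to_numpy(), cc.loc[b].to_numpy()
        rule = None
        wit = None
        high = (va > 0.95) & (vb > 0.95)
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        cos = 0.0 if na == 0 or nb == 0 else va @ vb / (na * nb)
        if high.any():
            rule, wit = "certain_95", high
        elif cos >= 0.95 and (va + vb >= 0.75).any():
            rule, wit = "strong_75", va + vb >= 0.75
        elif (va + vb > 1 + TOL).any():
            rule, wit = "pigeonhole_sum", va + vb > 1 + TOL
        if rule is None:
            continue
        ok_ab = (vb <= va + TOL).all()
        ok_ba = (va <= vb + TOL).all()
        if not ok_ab and not ok_ba:
            if rule == "certain_95" or (va + vb).max() >= 1.4:
                # nesting certain despite broken monotonicity: totals
                anc, dec = (a, b) if va.sum() >= vb.sum() else (b, a)
                out.add((anc, dec, rule))
            continue  # otherwise no monotonicity-consistent direction
        if ok_ab != ok_ba:
            anc, dec = (a, b) if ok_ab else (b, a)
        else:
            diffs = (va - vb)[wit]
            if (diffs > 0).any() and (diffs < 0).any():
                continue  # conflicting direction: no usable evidence
            if (diffs != 0).any():
                anc, dec = (a, b) if diffs[diffs != 0][0] > 0 else (b, a)
            else:
                anc, dec = (a, b) if va.sum() >= vb.sum() else (b, a)
        out.add((anc, dec, rule))
    return out


def all_parent_trees(names):
    """Every rooted forest over the labelled clusters (parent maps)."""
    choices = [[p for p in names + ["root"] if p != c] for c in names]
    for combo in itertools.product(*choices):
        parents = dict(zip(names, combo))
        ok = True
        for c in names:
            seen = set()
            cur = c
            while cur != "root":
                if cur in seen:
                    ok = False
                    break
                seen.add(cur)
                cur = parents[cur]
            if not ok:
                break
        if ok:
            yield parents


def pigeonhole_consistent(parents, cc: pd.DataFrame, tol=TOL) -> bool:
    """A parent map is admissible iff nested pairs respect cc
    monotonicity and disjoint pairs never jointly exceed a sample."""
    names = list(cc.index)

    def ancestors(c):
        out = set()
        cur = parents[c]
        while cur != "root":
            out.add(cur)
            cur = parents[cur]
        return out

    for a, b in itertools.combinations(names, 2):
        va, vb = cc.loc[a].to_numpy(), cc.loc[b].to_numpy()
        if a in ancestors(b):
            if (vb > va + tol).any():
                return False
        elif b in ancestors(a):
            if (va > vb + tol).any():
                return False
        else:
            if (va + vb > 1 + tol).any():
                return False
    return True
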