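"""Generative model of a branching prostatic gland and its clones.

The simulator reproduces the statistical structure of deeply
microdissected normal prostate epithelium:

* a rooted ductal tree from the urethral outlet through branchpoints to
  terminal acini, with log-normal segment lengths and 3D coordinates;
* 5-10 embryonic founder cells whose descendants tile the ducts as a
  contiguous patchwork, with a tunable fraction of nodes receiving a
  minor (>10%) second founder so that ~27% of microdissections are
  multiclonal;
* founder lineages splitting from the zygote within the first ~20
  mutations of molecular time; pubertal subclones founded at 300-500
  mutations that own one or a few adjacent side branches; an adult
  dominant lineage per duct node claiming 30-60% of local cells (so
  median VAFs land in the 0.15-0.3 range) with a subclonal tail of
  late, low-frequency mutations;
* a linear molecular clock (~16.4 mutations/year/clone above a ~133
  mutation intercept), a proximal-to-distal burden gradient
  (0.06 mutations/um) realised on the terminal branch of each node's
  dominant lineage, and telomere attrition of -0.32 bp per mutation;
* read counts per mutation x microdissection: depth ~ Poisson(~30x),
  alt ~ Binomial(depth, cc/2) under diploidy, with detection requiring
  at least four variant reads in at least one sample.

Every quantity the recovery modules estimate is also recorded as
ground truth (clone tree, per-sample cellular contributions, burdens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ductal import DuctalGraph
from .phylogeny import CloneTree, classify_epoch
from .matrix import VafMatrix


class InvalidConfigError(ValueError):
    pass


class InvalidGenealogyError(ValueError):
    pass


ZYGOTE = "zygote"


@dataclass
class SimulationConfig:
    """Generative parameters of the synthetic gland.

    Defaults encode the study conditions: a 59-year-old donor, 25-35x
    depth, 200-500 cells per microdissection, a 16.4 mutations/year
    clock with 133-mutation intercept, founder splits inside the first
    20 mutations, pubertal coalescences at 300-500 mutations, a 0.06
    mutations/um distal burden gradient and -0.32 bp/mutation telomere
    attrition.
    """

    seed: int = 0
    n_terminal_acini: int = 14
    n_embryonic_founders: int | None = None  # drawn uniformly from 5-10 when None
    donor_age: float = 59.0
    donor_id: str = "SIM0"
    clock_rate: float = 16.4  # mutations / year / clone
    clock_intercept: float = 133.0  # mutations at age 0
    embryonic_window_mutations: float = 20.0
    founder_split_window: tuple[float, float] = (16.0, 19.5)
    pubertal_molecular_range: tuple[float, float] = (300.0, 500.0)
    pubertal_age_range: tuple[float, float] = (10.0, 17.0)
    pubertal_per_founder: int = 2
    pubertal_share: tuple[float, float] = (0.90, 0.98)
    adult_share: tuple[float, float] = (0.52, 0.60)
    adult_time_fraction: tuple[float, float] = (0.70, 0.90)
    minor_adult_per_node: int = 2
    minor_adult_share: tuple[float, float] = (0.12, 0.19)
    distance_burden_gradient: float = 0.06  # mutations / um
    burden_dispersion_sd: float = 100.0  # extra per-sample burden scatter
    telomere_slope: float = -0.32  # bp / mutation
    telomere_baseline: float = 5000.0  # bp
    telomere_noise_sd: float = 70.0
    depth_mean: float = 30.0
    depth_sample_sd: float = 2.5
    cells_per_dissection: tuple[int, int] = (200, 500)
    min_alt_reads: int = 4
    n_microdissections: int = 48
    driver_expansion_flag: bool = False
    driver_share: tuple[float, float] = (0.75, 0.90)
    driver_adult_share: tuple[float, float] = (0.50, 0.70)
    driver_time_range: tuple[float, float] = (550.0, 700.0)
    driver_min_acini: int = 4
    driver_min_nodes: int = 13
    mixed_node_fraction: float = 0.27
    mixed_minor_fraction: tuple[float, float] = (0.105, 0.15)
    max_blocks: int = 3
    segment_length_mu: float = math.log(150.0)  # log um
    segment_length_sigma: float = 0.4
    tail_vaf_beta: tuple[float, float] = (1.0, 5.0)

    def validate(self) -> None:
        if self.n_terminal_acini < 1:
            raise InvalidConfigError("n_terminal_acini must be >= 1")
        if self.n_embryonic_founders is not None and self.n_embryonic_founders < 1:
            raise InvalidConfigError("founder count must be >= 1")
        if self.donor_age < 0:
            raise InvalidConfigError("donor_age must be >= 0")
        for name in ("clock_rate", "clock_intercept", "distance_burden_gradient"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.telomere_slope > 0:
            raise InvalidConfigError("telomere_slope must be <= 0 (attrition)")
        if self.depth_mean < 1:
            raise InvalidConfigError("depth_mean must be >= 1")
        if self.n_microdissections < 1:
            raise InvalidConfigError("n_microdissections must be >= 1")
        if not 0 <= self.mixed_node_fraction < 1:
            raise InvalidConfigError("mixed_node_fraction must be in [0, 1)")

    @property
    def total_molecular_time(self) -> float:
        """Expected present-day burden of a proximal clone."""
        return self.clock_intercept + self.clock_rate * self.donor_age


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# ductal topology
# ---------------------------------------------------------------------------


def generate_ductal_tree(config: SimulationConfig, seed=None) -> DuctalGraph:
    """Grow a rooted ductal tree with the requested number of acini.

    A short trunk leaves the urethral origin; the remaining leaves are
    produced by recursive binary splitting with uniformly random leaf
    partitions, which yields a main duct with secondary/tertiary side
    branches.  Segment lengths are log-normal; positions follow a
    persistent random walk in 3D.  Deterministic for a fixed seed.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed)
    nodes: list[dict] = []
    edges: list[dict] = []
    counter = 0

    def add_node(kind: str, parent: dict | None, direction: np.ndarray) -> dict:
        nonlocal counter
        length = float(rng.lognormal(config.segment_length_mu, config.segment_length_sigma))
        if parent is None:
            rec = {"id": f"N{counter:03d}", "kind": kind,
                   "position": (0.0, 0.0, 0.0), "dir": direction}
        else:
            pos = np.asarray(parent["position"]) + direction * length
            rec = {"id": f"N{counter:03d}", "kind": kind,
                   "position": tuple(pos), "dir": direction}
            edges.append({"parent": parent["id"], "child": rec["id"], "length": length})
        counter += 1
        nodes.append(rec)
        return rec

    def bend(direction: np.ndarray, wobble: float = 0.5) -> np.ndarray:
        d = direction + wobble * rng.standard_normal(3)
        return d / np.linalg.norm(d)

    root = add_node("urethral_origin", None, np.array([1.0, 0.0, 0.0]))

    def grow(parent: dict, n_leaves: int) -> None:
        if n_leaves == 1:
            cur = parent
            for _ in range(int(rng.integers(0, 2))):
                cur = add_node("duct", cur, bend(cur["dir"]))
            add_node("acinus", cur, bend(cur["dir"]))
            return
        bp = add_node("branchpoint", parent, bend(parent["dir"]))
        n1 = int(rng.integers(1, n_leaves))
        grow(bp, n1)
        grow(bp, n_leaves - n1)

    trunk = add_node("duct", root, root["dir"])
    trunk = add_node("duct", trunk, bend(trunk["dir"]))
    grow(trunk, config.n_terminal_acini)
    for rec in nodes:
        rec.pop("dir")
    return DuctalGraph.from_records(nodes, edges)


# ---------------------------------------------------------------------------
# embryonic founder patchwork
# ---------------------------------------------------------------------------


@dataclass
class FounderAssignment:
    """Per-node founder cell fractions; dominant founder first."""

    shares: dict[str, list[tuple[str, float]]]  # node -> [(founder, fraction)]
    founders: list[str]

    def dominant(self, node: str) -> str:
        return self.shares[node][0][0]

    def territory(self, founder: str) -> set[str]:
        return {n for n, fr in self.shares.items() if any(f == founder for f, _ in fr)}

    def dominant_territory(self, founder: str) -> set[str]:
        return {n for n in self.shares if self.dominant(n) == founder}

    def fraction(self, founder: str, node: str) -> float:
        return dict(self.shares[node]).get(founder, 0.0)


def seed_embryonic_founders(
    graph: DuctalGraph,
    n_founders: int,
    seed=None,
    mixed_node_fraction: float = 0.27,
    mixed_minor_fraction: tuple[float, float] = (0.105, 0.15),
    reserved: tuple[set[str], int] | None = None,
) -> FounderAssignment:
    """Tile the ductal tree with founder territories.

    Founders colonise the graph by competitive boundary spreading from
    random seed nodes, producing contiguous blocks.  A
    ``mixed_node_fraction`` of nodes additionally receives a minor
    contribution (10-16% of cells) from a neighbouring founder, which
    is what makes microdissections multiclonal.  ``reserved`` pins one
    founder to a node set no other founder may enter (used for driver
    runs).
    """
    rng = _rng(seed)
    all_nodes = list(graph.nodes)
    if n_founders < 1:
        raise InvalidConfigError("n_founders must be >= 1")
    if n_founders > len(all_nodes):
        raise InvalidConfigError("more founders than ductal nodes")
    founders = [f"F{i}" for i in range(n_founders)]
    owner: dict[str, str] = {}
    g = graph.undirected()

    reserved_nodes: set[str] = set()
    if reserved is not None:
        reserved_nodes, f_idx = reserved
        for n in reserved_nodes:
            owner[n] = founders[f_idx]
    free = [n for n in all_nodes if n not in owner]
    k_free = n_founders - (1 if reserved else 0)
    # farthest-point seeding: each rudimentary duct starts well away
    # from the others, so territories come out multi-segment
    import networkx as nx

    hop = dict(nx.all_pairs_shortest_path_length(g))
    seeds: list[str] = []
    if free and k_free > 0:
        seeds.append(str(rng.choice(free)))
        while len(seeds) < min(k_free, len(free)):
            dist_to_seeds = {
                n: min(hop[n][s] for s in seeds) for n in free if n not in seeds
            }
            far = max(dist_to_seeds.values())
            candidates = sorted(n for n, d in dist_to_seeds.items() if d == far)
            seeds.append(candidates[int(rng.integers(len(candidates)))])
    free_founders = [f for i, f in enumerate(founders)
                     if not (reserved and i == reserved[1])]
    for f, s in zip(free_founders, seeds):
        owner[s] = f
    # competitive boundary spreading
    while len(owner) < len(all_nodes):
        frontier = [
            n for n in all_nodes
            if n not in owner and any(nb in owner for nb in g.neighbors(n))
        ]
        if not frontier:  # disconnected safety net (cannot happen on a tree)
            n = next(n for n in all_nodes if n not in owner)
            owner[n] = founders[int(rng.integers(n_founders))]
            continue
        for n in rng.permutation(frontier):
            assigned_nbrs = [owner[nb] for nb in g.neighbors(n) if nb in owner]
            if not assigned_nbrs:
                continue
            choice = assigned_nbrs[int(rng.integers(len(assigned_nbrs)))]
            if n in reserved_nodes:
                continue
            owner[n] = choice

    # repair pass: a founder must span several duct segments (it built
    # a rudimentary duct, not a single segment); starve-outs annex
    # boundary nodes from richer neighbours while both stay contiguous
    min_nodes = min(3, max(1, len(all_nodes) // max(n_founders, 1)))
    territories: dict[str, set[str]] = {f: set() for f in founders}
    for n, f in owner.items():
        territories[f].add(n)

    def _connected_without(f: str, node: str) -> bool:
        remaining = territories[f] - {node}
        if not remaining:
            return False
        sub = g.subgraph(remaining)
        return nx.is_connected(sub)

    for f in founders:
        guard = 0
        while len(territories[f]) < min_nodes and guard < 50:
            guard += 1
            frontier = sorted(
                n
                for t in territories[f]
                for n in g.neighbors(t)
                if owner[n] != f
                and n not in reserved_nodes
                and len(territories[owner[n]]) > min_nodes
                and _connected_without(owner[n], n)
            )
            if not frontier:
                break
            grab = frontier[int(rng.integers(len(frontier)))]
            territories[owner[grab]].discard(grab)
            owner[grab] = f
            territories[f].add(grab)

    shares = {n: [(owner[n], 1.0)] for n in all_nodes}
    # minor second founder on a fraction of (non-reserved) nodes
    eligible = [n for n in all_nodes if n not in reserved_nodes]
    n_mixed = int(round(mixed_node_fraction * len(all_nodes)))
    boundary = [
        n for n in eligible
        if any(owner[nb] != owner[n] and nb not in reserved_nodes
               for nb in g.neighbors(n))
    ]
    interior = [n for n in eligible if n not in boundary]
    pool = list(rng.permutation(boundary)) + list(rng.permutation(interior))
    for n in pool[:n_mixed]:
        others = {owner[nb] for nb in g.neighbors(n)
                  if owner[nb] != owner[n] and nb not in reserved_nodes}
        if not others:
            others = set(founders) - {owner[n]}
        if not others:
            continue
        minor = sorted(others)[int(rng.integers(len(others)))]
        u = float(rng.uniform(*mixed_minor_fraction))
        shares[n] = [(owner[n], 1.0 - u), (minor, u)]
    return FounderAssignment(shares=shares, founders=founders)


# ---------------------------------------------------------------------------
# clonal genealogy
# ---------------------------------------------------------------------------


@dataclass
class Clone:
    clone_id: str
    parent: str | None
    founding_time: float  # molecular time (mutations)
    epoch: str
    territory: set[str] = field(default_factory=set)


@dataclass
class CloneGenealogy:
    """Clone tree plus per-node cell fractions.

    ``cell_fraction[clone][node]`` is the fraction of the node's cells
    descending from the clone's founding cell; it is monotone
    non-increasing from ancestors to descendants by construction.
    ``adult_of[node]`` names the node's dominant adult lineage.
    """

    clones: dict[str, Clone]
    cell_fraction: dict[str, dict[str, float]]
    adult_of: dict[str, str]
    driver_clone: str | None = None

    def children(self, clone_id: str) -> list[str]:
        return sorted(c.clone_id for c in self.clones.values() if c.parent == clone_id)

    def validate(self) -> None:
        for c in self.clones.values():
            if c.parent is not None:
                p = self.clones[c.parent]
                if not c.founding_time > p.founding_time and c.clone_id != ZYGOTE:
                    raise InvalidGenealogyError(
                        f"{c.clone_id} founded no later than its parent"
                    )
                for node, frac in self.cell_fraction.get(c.clone_id, {}).items():
                    pf = self.cell_fraction.get(c.parent, {}).get(node, 0.0)
                    if c.parent == ZYGOTE:
                        pf = 1.0
                    if frac > pf + 1e-9:
                        raise InvalidGenealogyError(
                            f"cell fraction of {c.clone_id} exceeds parent at {node}"
                        )


def _driver_subtree(graph: DuctalGraph, config: SimulationConfig, rng) -> set[str]:
    candidates = []
    for n in graph.nodes:
        if n == graph.root:
            continue
        sub = graph.subtree_nodes(n)
        n_acini = sum(1 for m in sub if graph.kind(m) == "acinus")
        if n_acini >= config.driver_min_acini and len(sub) >= config.driver_min_nodes:
            candidates.append((len(sub), n))
    if not candidates:
        raise InvalidConfigError(
            "no subtree large enough for a driver expansion; increase n_terminal_acini"
        )
    smallest = min(s for s, _ in candidates)
    pick = sorted(n for s, n in candidates if s == smallest)
    return graph.subtree_nodes(pick[int(rng.integers(len(pick)))])


def simulate_genealogy(
    graph: DuctalGraph,
    founders: FounderAssignment,
    config: SimulationConfig,
    seed=None,
    driver_territory: set[str] | None = None,
) -> CloneGenealogy:
    """Build the clone genealogy over the founder patchwork.

    Founder lineages split from the zygote inside the embryonic window;
    each founder seeds pubertal subclones (300-500 mutations) owning
    adjacent side-branch subtrees; every duct node then carries one
    dominant adult lineage.  With ``driver_expansion_flag`` one adult
    clone (the driver) additionally spans a whole subtree with at least
    ``driver_min_acini`` terminal branches.
    """
    rng = _rng(config.seed + 1 if seed is None else seed)
    m_total = config.total_molecular_time
    clones: dict[str, Clone] = {
        ZYGOTE: Clone(ZYGOTE, None, 0.0, "embryonic", set(graph.nodes))
    }
    frac: dict[str, dict[str, float]] = {ZYGOTE: {n: 1.0 for n in graph.nodes}}

    lo, hi = config.founder_split_window
    if hi >= config.embryonic_window_mutations:
        hi = config.embryonic_window_mutations - 1e-6
    for f in founders.founders:
        t = float(rng.uniform(lo, hi))
        terr = founders.territory(f)
        clones[f] = Clone(f, ZYGOTE, t, "embryonic", terr)
        frac[f] = {n: founders.fraction(f, n) for n in terr}

    driver_nodes = driver_territory or set()
    driver_id = None
    if config.driver_expansion_flag:
        if not driver_nodes:
            raise InvalidConfigError("driver run requires a reserved territory")
        owner_f = founders.dominant(next(iter(driver_nodes)))
        t_drv = float(rng.uniform(*config.driver_time_range))
        driver_id = "A_drv"
        s_d = float(rng.uniform(*config.driver_share))
        clones[driver_id] = Clone(driver_id, owner_f, t_drv, "adult", set(driver_nodes))
        frac[driver_id] = {
            n: s_d * founders.fraction(owner_f, n) for n in driver_nodes
        }

    # pubertal subclones own side-branch subtrees inside founder territory
    pub_counter = 0
    covered: set[str] = set(driver_nodes)
    pubertal_of: dict[str, str] = {}
    for f in founders.founders:
        # pubertal side branches grow from founder-pure nodes; embryonically
        # mixed nodes keep their rudimentary-duct (founder-direct) lineage
        dom = {
            n
            for n in founders.dominant_territory(f)
            if founders.fraction(f, n) == 1.0
        } - driver_nodes
        for _ in range(config.pubertal_per_founder):
            anchors = [
                n for n in sorted(dom - covered)
                if len((graph.subtree_nodes(n) & dom) - covered) >= 2
            ]
            if not anchors:
                break
            anchor = anchors[int(rng.integers(len(anchors)))]
            terr = (graph.subtree_nodes(anchor) & dom) - covered
            t = float(rng.uniform(*config.pubertal_molecular_range))
            pid = f"P{pub_counter}"
            pub_counter += 1
            clones[pid] = Clone(pid, f, t, "pubertal", terr)
            frac[pid] = {
                n: float(rng.uniform(*config.pubertal_share))
                * founders.fraction(f, n)
                for n in sorted(terr)  # draw order must not depend on set hashing
            }
            covered |= terr
            pubertal_of.update({n: pid for n in terr})

    # adult lineages per duct node: one dominant clone claiming the
    # largest share of cells, plus minor sibling lineages making up the
    # rest of the node's polyclonal mixture
    adult_of: dict[str, str] = {}
    lo_f, hi_f = config.adult_time_fraction
    for i, node in enumerate(sorted(set(graph.nodes) - {graph.root})):
        if node in driver_nodes:
            parent = driver_id
            q = float(rng.uniform(*config.driver_adult_share))
        else:
            parent = pubertal_of.get(node, founders.dominant(node))
            q = float(rng.uniform(*config.adult_share))
        q_minor = rng.uniform(
            *config.minor_adult_share, size=config.minor_adult_per_node
        )
        # sibling shares of the parent's cells cannot exceed the whole
        budget = 0.95 - q
        if q_minor.size and q_minor.sum() > budget:
            q_minor *= budget / q_minor.sum()

        def adult_time() -> float:
            if node in driver_nodes:
                t0 = clones[driver_id].founding_time
                return float(rng.uniform(t0 + 80.0, max(0.95 * m_total, t0 + 120.0)))
            return max(
                clones[parent].founding_time + 60.0,
                float(rng.uniform(lo_f, hi_f)) * m_total,
            )

        aid = f"A{i:03d}"
        t = adult_time()
        clones[aid] = Clone(aid, parent, t, classify_epoch(t), {node})
        frac[aid] = {node: q * frac[parent][node]}
        adult_of[node] = aid
        for j, qm in enumerate(q_minor):
            mid = f"A{i:03d}m{j}"
            tm = adult_time()
            clones[mid] = Clone(mid, parent, tm, classify_epoch(tm), {node})
            frac[mid] = {node: float(qm) * frac[parent][node]}

    gen = CloneGenealogy(
        clones=clones, cell_fraction=frac, adult_of=adult_of, driver_clone=driver_id
    )
    gen.validate()
    return gen


# ---------------------------------------------------------------------------
# mutation accumulation
# ---------------------------------------------------------------------------


def sample_branch_mutation_counts(
    rate_per_year: float,
    duration_years,
    seed=None,
    gradient_multiplier: float = 1.0,
    size: int | None = None,
):
    """Poisson mutation counts on branches of given duration (years).

    The effective rate is ``rate_per_year * gradient_multiplier``; a
    multiplier above 1 models the faster-dividing distal epithelium.
    """
    rng = _rng(seed)
    duration = np.asarray(duration_years, dtype=float)
    if np.any(duration < 0):
        raise InvalidGenealogyError("negative branch duration")
    lam = rate_per_year * gradient_multiplier * duration
    out = rng.poisson(lam, size=size if size is not None else lam.shape or None)
    return out


def accumulate_mutations(
    genealogy: CloneGenealogy,
    graph: DuctalGraph,
    config: SimulationConfig,
    seed=None,
) -> pd.DataFrame:
    """Realise mutation counts on every genealogy branch.

    Stem mutations on the branch into clone ``c`` number
    Poisson(t_c - t_parent) in molecular time.  Each node's dominant
    adult lineage additionally carries a subclonal tail reaching the
    node's expected present-day burden: clock intercept + rate x age +
    gradient x ductal distance (+ Gaussian dispersion), with tail
    mutations at low cell fractions (Beta-distributed multiples of the
    adult clone's cc).

    Returns a table (mutation_id, clone_id, kind, vaf_scale).
    """
    from .spatial import all_path_distances

    rng = _rng(config.seed + 2 if seed is None else seed)
    distances = all_path_distances(graph)
    rows: list[tuple[str, str, str, float]] = []
    counter = 0

    def emit(clone_id: str, n: int, kind: str, scales=None) -> None:
        nonlocal counter
        for j in range(n):
            scale = 1.0 if scales is None else float(scales[j])
            rows.append((f"mut{counter:06d}", clone_id, kind, scale))
            counter += 1

    for cid in sorted(genealogy.clones):
        clone = genealogy.clones[cid]
        if clone.parent is None:
            continue
        dt = clone.founding_time - genealogy.clones[clone.parent].founding_time
        if dt < 0:
            raise InvalidGenealogyError(f"negative duration into {cid}")
        emit(cid, int(rng.poisson(dt)), "stem")

    a, b = config.tail_vaf_beta
    for node in sorted(genealogy.adult_of):
        aid = genealogy.adult_of[node]
        t_a = genealogy.clones[aid].founding_time
        target = (
            config.total_molecular_time
            + config.distance_burden_gradient * distances[node]
            + float(rng.normal(0.0, config.burden_dispersion_sd))
        )
        n_tail = int(rng.poisson(max(target - t_a, 0.0)))
        emit(aid, n_tail, "tail", rng.beta(a, b, size=n_tail))

    return pd.DataFrame(rows, columns=["mutation_id", "clone_id", "kind", "vaf_scale"])


def simulate_telomeres(true_burden: pd.Series, config: SimulationConfig, seed=None) -> pd.Series:
    """Telomere length per sample: baseline + slope x burden + noise."""
    rng = _rng(config.seed + 3 if seed is None else seed)
    noise = rng.normal(0.0, config.telomere_noise_sd, size=len(true_burden))
    return pd.Series(
        config.telomere_baseline + config.telomere_slope * true_burden.to_numpy() + noise,
        index=true_burden.index,
        name="telomere_bp",
    )


# ---------------------------------------------------------------------------
# observation layer
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Everything the recovery pipeline is asked to reconstruct."""

    config: SimulationConfig
    clone_table: pd.DataFrame  # clone_id, parent, founding_time, epoch
    cc: pd.DataFrame  # clone x sample cellular contribution
    mutations: pd.DataFrame  # mutation_id, clone_id, kind, vaf_scale, detected
    true_burden: pd.Series  # per sample
    stem_counts: pd.Series  # realised stem mutations per clone

    def true_tree(self, clones: list[str] | None = None) -> CloneTree:
        parents = {}
        lengths = {}
        for rec in self.clone_table.itertuples():
            if rec.clone_id == ZYGOTE:
                continue
            parent = CloneTree.ROOT if rec.parent == ZYGOTE else rec.parent
            parents[rec.clone_id] = parent
            lengths[rec.clone_id] = float(self.stem_counts.get(rec.clone_id, 0))
        tree = CloneTree.from_parents(parents, lengths)
        if clones is not None:
            tree = tree.restrict(set(clones))
        return tree

    def detectable_clones(self, min_cc: float = 0.2, min_mutations: int = 10) -> list[str]:
        """Clones a read-count clustering can hope to recover: enough
        stem mutations and a sizeable contribution somewhere."""
        out = []
        for cid in self.cc.index:
            if cid == ZYGOTE:
                continue
            if (
                self.stem_counts.get(cid, 0) >= min_mutations
                and self.cc.loc[cid].max() >= min_cc
            ):
                out.append(cid)
        return sorted(out)

    def embryonic_cc(self) -> pd.DataFrame:
        tab = self.clone_table
        emb = tab[(tab["epoch"] == "embryonic") & (tab["clone_id"] != ZYGOTE)][
            "clone_id"
        ]
        return self.cc.loc[[c for c in emb if c in self.cc.index]]


@dataclass
class GlandSimulation:
    config: SimulationConfig
    graph: DuctalGraph
    founders: FounderAssignment
    genealogy: CloneGenealogy
    truth: SimulationTruth
    vaf_matrix: VafMatrix
    samples: pd.DataFrame


def sample_microdissections(
    graph: DuctalGraph,
    genealogy: CloneGenealogy,
    mutations: pd.DataFrame,
    config: SimulationConfig,
    seed=None,
) -> tuple[VafMatrix, pd.DataFrame, SimulationTruth]:
    """Draw read counts for microdissections at sampled duct nodes.

    Each microdissection captures 200-500 contiguous cells at one node;
    per mutation the depth is Poisson around the sample's mean coverage
    and the alt count Binomial(depth, cc/2) under diploidy.  A mutation
    enters the observable table only if it reaches ``min_alt_reads``
    variant reads in at least one sample (the caller's filter); the
    truth table keeps the censored remainder flagged.
    """
    from .spatial import all_path_distances

    rng = _rng(config.seed + 4 if seed is None else seed)
    nodes = sorted(set(graph.nodes) - {graph.root})
    n_samp = min(config.n_microdissections, len(nodes))
    sampled_nodes = sorted(rng.choice(nodes, size=n_samp, replace=False))
    sample_ids = [f"S{i:03d}" for i in range(n_samp)]
    node_of = dict(zip(sample_ids, sampled_nodes))

    # per-clone cc over the sampled nodes
    clone_ids = sorted(genealogy.clones)
    cc = pd.DataFrame(0.0, index=clone_ids, columns=sample_ids)
    for cid in clone_ids:
        fr = genealogy.cell_fraction.get(cid, {})
        for s, node in node_of.items():
            cc.loc[cid, s] = fr.get(node, 0.0)

    resident = ~(cc.loc[mutations["clone_id"]].to_numpy() == 0).all(axis=1)
    obs = mutations[resident].reset_index(drop=True)

    vaf = 0.5 * cc.loc[obs["clone_id"]].to_numpy() * obs["vaf_scale"].to_numpy()[:, None]
    depth_means = np.clip(
        rng.normal(config.depth_mean, config.depth_sample_sd, size=n_samp), 5.0, None
    )
    depth = rng.poisson(np.broadcast_to(depth_means, vaf.shape))
    alt = rng.binomial(depth, np.clip(vaf, 0.0, 1.0))
    detected_rows = (alt >= config.min_alt_reads).any(axis=1)

    vm = VafMatrix.from_arrays(
        alt[detected_rows],
        depth[detected_rows],
        mutations=obs["mutation_id"][detected_rows],
        samples=sample_ids,
    )

    mutations = mutations.copy()
    detected_ids = set(obs["mutation_id"][detected_rows])
    mutations["detected"] = mutations["mutation_id"].isin(detected_ids)

    # ground-truth burden: the dominant adult lineage's realised mutations
    stem_counts = mutations[mutations["kind"] == "stem"].groupby("clone_id").size()
    tail_counts = mutations[mutations["kind"] == "tail"].groupby("clone_id").size()
    burden = {}
    for s, node in node_of.items():
        aid = genealogy.adult_of[node]
        total = int(tail_counts.get(aid, 0))
        cid = aid
        while cid is not None and cid != ZYGOTE:
            total += int(stem_counts.get(cid, 0))
            cid = genealogy.clones[cid].parent
        burden[s] = total
    true_burden = pd.Series(burden, name="true_burden")

    telomeres = simulate_telomeres(true_burden, config, seed=rng.integers(2**31))
    distances = all_path_distances(graph)
    positions = {s: graph.position(node_of[s]) for s in sample_ids}
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": config.donor_id,
            "age_years": config.donor_age,
            "x_um": [positions[s][0] for s in sample_ids],
            "y_um": [positions[s][1] for s in sample_ids],
            "z_um": [positions[s][2] for s in sample_ids],
            "duct_node": [node_of[s] for s in sample_ids],
            "path_distance_um": [distances[node_of[s]] for s in sample_ids],
            "telomere_bp": telomeres.to_numpy(),
            "depth_mean": depth_means,
            "n_cells": rng.integers(
                config.cells_per_dissection[0],
                config.cells_per_dissection[1] + 1,
                size=n_samp,
            ),
        }
    )

    clone_table = pd.DataFrame(
        {
            "clone_id": clone_ids,
            "parent": [genealogy.clones[c].parent for c in clone_ids],
            "founding_time": [genealogy.clones[c].founding_time for c in clone_ids],
            "epoch": [genealogy.clones[c].epoch for c in clone_ids],
        }
    )
    truth = SimulationTruth(
        config=config,
        clone_table=clone_table,
        cc=cc,
        mutations=mutations,
        true_burden=true_burden,
        stem_counts=stem_counts,
    )
    return vm, samples, truth


def simulate_gland(config: SimulationConfig | None = None) -> GlandSimulation:
    """End-to-end gland simulation from a single seed."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    graph = generate_ductal_tree(config, seed=rng.integers(2**31))
    n_founders = (
        config.n_embryonic_founders
        if config.n_embryonic_founders is not None
        else int(rng.integers(5, 11))
    )
    driver_nodes: set[str] | None = None
    reserved = None
    if config.driver_expansion_flag:
        driver_nodes = _driver_subtree(graph, config, rng)
        reserved = (driver_nodes, 0)
    founders = seed_embryonic_founders(
        graph,
        n_founders,
        seed=rng.integers(2**31),
        mixed_node_fraction=config.mixed_node_fraction,
        mixed_minor_fraction=config.mixed_minor_fraction,
        reserved=reserved,
    )
    genealogy = simulate_genealogy(
        graph, founders, config, seed=rng.integers(2**31),
        driver_territory=driver_nodes,
    )
    mutations = accumulate_mutations(genealogy, graph, config, seed=rng.integers(2**31))
    vm, samples, truth = sample_microdissections(
        graph, genealogy, mutations, config, seed=rng.integers(2**31)
    )
    return GlandSimulation(
        config=config,
        graph=graph,
        founders=founders,
        genealogy=genealogy,
        truth=truth,
        vaf_matrix=vm,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# multi-donor clock cohort
# ---------------------------------------------------------------------------

#: donor ages spanning the cohort's 22-78 year range
DEFAULT_COHORT_AGES = (22.0, 31.0, 38.0, 45.0, 52.0, 59.0, 66.0, 78.0)


def simulate_clock_cohort(
    seed=None,
    ages: tuple[float, ...] = DEFAULT_COHORT_AGES,
    samples_per_donor: int = 20,
    slope: float = 16.4,
    intercept: float = 133.0,
    donor_sd: float = 150.0,
    within_donor_sd: float = 550.0,
) -> pd.DataFrame:
    """Corrected burdens for a multi-donor cohort under the linear clock.

    b_c = intercept + slope x age + donor intercept (sd ``donor_sd``) +
    within-donor scatter (sd ``within_donor_sd``).  Burdens are Gaussian
    around the clock line and deliberately not truncated at zero, so the
    mixed model that analyses them is correctly specified.
    """
    rng = _rng(seed)
    rows = []
    for d, age in enumerate(ages):
        donor_eff = rng.normal(0.0, donor_sd)
        b = (
            intercept
            + slope * age
            + donor_eff
            + rng.normal(0.0, within_donor_sd, size=samples_per_donor)
        )
        for v in b:
            rows.append((f"D{d}", age, float(v)))
    return pd.DataFrame(rows, columns=["donor", "age", "b_c"])
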