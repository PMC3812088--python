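"""Single-locus structured-coalescent genealogies, as explicit trees.

This is the readable reference implementation of the simulator: it builds a
full :class:`Genealogy` (node times, parents, per-branch descent vectors) and
supports infinite-sites mutation dropping and the ascertainment-subtree
extraction used for SNP-chip models. The batch kernels in
:mod:`sfscl._kernels` implement the same process without materialising trees;
the test-suite checks the two against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .demography import Demography, validate_demography

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "total_tree_length",
    "drop_mutations",
    "ascertain_subtree",
]

DEFAULT_TIME_CAP = 1e10


@dataclass
class Genealogy:
    """A binary coalescent tree over the sampled lineages.

    Nodes 0..n-1 are the leaves (time 0), nodes n..2n-2 internal; ``parent``
    is -1 for the root. ``descent[b, k]`` counts sampled leaves of deme k
    below node b; every non-root node is a branch of length
    ``time[parent[b]] - time[b]``.
    """

    num_demes: int
    leaf_deme: np.ndarray  # (n,) deme of each leaf
    parent: np.ndarray  # (2n-1,)
    time: np.ndarray  # (2n-1,)

    def __post_init__(self) -> None:
        n = self.num_leaves
        self.descent = np.zeros((2 * n - 1, self.num_demes), dtype=np.int64)
        self.descent[np.arange(n), self.leaf_deme] = 1
        # children precede parents in index order (merge order)
        for b in range(2 * n - 2):
            self.descent[self.parent[b]] += self.descent[b]

    @property
    def num_leaves(self) -> int:
        return len(self.leaf_deme)

    @property
    def root(self) -> int:
        return 2 * self.num_leaves - 2

    def branch_lengths(self) -> np.ndarray:
        """Length of each non-root branch (indexed by child node)."""
        nr = np.arange(2 * self.num_leaves - 2)
        return self.time[self.parent[nr]] - self.time[nr]

    @property
    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def newick(self) -> str:
        """Debug dump with branch lengths in generations."""
        children: dict[int, list[int]] = {}
        for b in range(self.root):
            children.setdefault(int(self.parent[b]), []).append(b)

        def fmt(node: int) -> str:
            if node < self.num_leaves:
                return f"l{node}"
            return "(" + ",".join(
                f"{fmt(c)}:{self.time[node] - self.time[c]:.6g}"
                for c in children[node]
            ) + ")"

        return fmt(self.root) + ";"


def _coal_waiting_time(c: int, n_now: float, growth: float, rng) -> float:
    """Exact first-coalescence time for c lineages in a deme of current
    (backward-time) size ``n_now`` growing at forward rate ``growth``."""
    rate0 = c * (c - 1) / (4.0 * n_now)  # C(c,2)/(2N)
    e = rng.exponential()
    if growth == 0.0:
        return e / rate0
    arg = 1.0 + growth * e / rate0
    return math.log(arg) / growth if arg > 0 else math.inf


def simulate_genealogy(
    d: Demography,
    rng: np.random.Generator,
    time_cap: float = DEFAULT_TIME_CAP,
) -> Genealogy:
    """Simulate one genealogy under the exact continuous-time structured
    coalescent: pairwise coalescence at rate 1/(2N_k(t)) within deme k,
    per-lineage migration k->j at the active matrix's rate, historical events
    applied in time order (ties in declaration order).
    """
    issues = validate_demography(d)
    if issues:
        raise ValueError("invalid demography: " + "; ".join(issues))
    v = d.num_pops
    n = d.total_samples
    leaf_deme = np.repeat(np.arange(v), d.sample_sizes)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)

    active = list(range(n))  # node ids of active lineages
    lin_deme = leaf_deme.copy().tolist()
    size_now = np.asarray(d.sizes, dtype=float).copy()
    growth_now = np.asarray(d.growth_rates, dtype=float).copy()
    anchor = np.zeros(v)
    migs = [m.copy() for m in d.migration_matrices]
    for m in migs:
        np.fill_diagonal(m, 0.0)
    rowsum = [m.sum(axis=1) for m in migs]

    t = 0.0
    mig_id = 0
    ev_i = 0
    next_node = n
    events = list(d.events)

    while len(active) > 1:
        t_ev = events[ev_i].time if ev_i < len(events) else math.inf
        cnt = np.bincount([lin_deme[i] for i in range(len(active))], minlength=v)

        best_dt, best_type, best_deme = math.inf, -1, -1
        for k in range(v):
            if cnt[k] >= 2:
                n_now = size_now[k] * math.exp(-growth_now[k] * (t - anchor[k]))
                dt = _coal_waiting_time(int(cnt[k]), n_now, growth_now[k], rng)
                if dt < best_dt:
                    best_dt, best_type, best_deme = dt, 0, k
        mtot = float(np.dot(cnt, rowsum[mig_id]))
        if mtot > 0:
            dtm = rng.exponential() / mtot
            if dtm < best_dt:
                best_dt, best_type = dtm, 1

        if math.isinf(best_dt) and math.isinf(t_ev):
            raise RuntimeError(
                f"no coalescence or migration possible at t={t:g} "
                f"(occupied demes {sorted(set(lin_deme))}); model not closable"
            )

        if t + best_dt >= t_ev:
            t = t_ev
            size_now *= np.exp(-growth_now * (t - anchor))
            anchor[:] = t
            e = events[ev_i]
            if e.proportion > 0 and e.source != e.sink:
                for i in range(len(active)):
                    if lin_deme[i] == e.source and (
                        e.proportion >= 1.0 or rng.random() < e.proportion
                    ):
                        lin_deme[i] = e.sink
            if e.new_size is not None:
                size_now[e.sink] = e.new_size
            if e.new_growth is not None:
                growth_now[e.sink] = e.new_growth
            if e.migration_matrix is not None:
                mig_id = e.migration_matrix
            ev_i += 1
            continue

        t += best_dt
        if t > time_cap:
            raise RuntimeError(
                f"simulation exceeded time cap {time_cap:g} generations "
                f"at epoch starting after event {ev_i - 1}"
            )

        if best_type == 0:
            members = [i for i in range(len(active)) if lin_deme[i] == best_deme]
            r, s = rng.choice(len(members), size=2, replace=False)
            i1, i2 = members[int(r)], members[int(s)]
            node_time[next_node] = t
            parent[active[i1]] = next_node
            parent[active[i2]] = next_node
            active[i1] = next_node
            # keep lin_deme[i1] = best_deme for the merged lineage
            for arr in (active, lin_deme):
                arr.pop(i2)
            next_node += 1
        else:
            w = cnt * rowsum[mig_id]
            k = int(rng.choice(v, p=w / w.sum()))
            members = [i for i in range(len(active)) if lin_deme[i] == k]
            i1 = members[int(rng.integers(len(members)))]
            p = migs[mig_id][k] / rowsum[mig_id][k]
            lin_deme[i1] = int(rng.choice(v, p=p))

    return Genealogy(
        num_demes=v, leaf_deme=leaf_deme, parent=parent, time=node_time
    )


def total_tree_length(g: Genealogy) -> float:
    """Sum of all branch lengths T, in generations."""
    return g.total_length


def drop_mutations(
    g: Genealogy, mu: float, L: float, rng: np.random.Generator
) -> np.ndarray:
    """Drop infinite-sites mutations on the genealogy.

    The number of mutations is Poisson(mu * L * T) and each lands on a branch
    with probability proportional to its length. Returns an (m, v) array of
    descent vectors, one row per mutation (its joint frequency class).
    """
    if mu < 0 or L < 1:
        raise ValueError("need mu >= 0 and L >= 1")
    lens = g.branch_lengths()
    T = lens.sum()
    m = rng.poisson(mu * L * T)
    if m == 0:
        return np.zeros((0, g.num_demes), dtype=np.int64)
    branches = rng.choice(len(lens), size=m, p=lens / T)
    return g.descent[branches]


@dataclass
class AscertainedSubtree:
    """Branches of the subtree joining two ascertainment lineages to their
    MRCA, each with its full-sample descent vector and length."""

    nodes: np.ndarray  # child-node ids of the subtree branches
    lengths: np.ndarray
    descent: np.ndarray  # (m, v) full-sample descent vectors
    pair: tuple[int, int]

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


def ascertain_subtree(
    g: Genealogy, asc_deme: int, rng: np.random.Generator
) -> AscertainedSubtree:
    """Pick two random lineages in the ascertained deme and extract the
    subtree relating them to their MRCA.

    A mutation is heterozygous between the two chosen copies exactly when it
    falls on a branch subtending one of them but not the other, i.e. on the
    union of the two leaf-to-MRCA paths.
    """
    leaves = np.nonzero(g.leaf_deme == asc_deme)[0]
    if len(leaves) < 2:
        raise ValueError(
            f"ascertained deme {asc_deme} has {len(leaves)} sampled lineages; need >= 2"
        )
    a, b = leaves[rng.choice(len(leaves), size=2, replace=False)]
    # walk both paths to the root, cut at the shared MRCA
    path_a: list[int] = []
    node = int(a)
    while node != g.root:
        path_a.append(node)
        node = int(g.parent[node])
    anc_a = {int(g.parent[x]) for x in path_a} | {int(a)}
    path_b: list[int] = []
    node = int(b)
    while node not in anc_a:
        path_b.append(node)
        node = int(g.parent[node])
    mrca = node
    keep_a = []
    for x in path_a:
        keep_a.append(x)
        if int(g.parent[x]) == mrca:
            break
    nodes = np.asarray(keep_a + path_b, dtype=np.int64)
    lengths = g.time[g.parent[nodes]] - g.time[nodes]
    return AscertainedSubtree(
        nodes=nodes, lengths=lengths, descent=g.descent[nodes], pair=(int(a), int(b))
    )
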