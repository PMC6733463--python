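"""Energy-landscape enumeration, local minima and barrier analysis.

States live on the N-dimensional hypercube: two states are neighbors when
they differ in exactly one bit (Hamming distance 1).  A local minimum is a
state with strictly lower energy than all N neighbors.  The connection
threshold E_th of a pair of minima is the bottleneck (minimax) energy: the
minimum over all one-flip paths of the maximum energy along the path, and
the pair energy barrier is E_B = E_th - max(E_i, E_j).

Thresholds are computed with an energy-ascending filtration: states are
inserted in increasing energy order, each joined (union-find) to its
already-inserted neighbors, and two minima connect exactly at the energy
of the state whose insertion merges their components.  This is equivalent
to the iterative shortest-path/removal procedure, which is retained as a
test oracle (:func:`pair_threshold_oracle`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from elanet.errors import ValidationError
from elanet.mem import SystemModel, state_energies

__all__ = [
    "LandscapeResult",
    "BarrierTable",
    "DisconnectivityTree",
    "enumerate_energies",
    "find_local_minima",
    "complement_state",
    "complement_code",
    "connection_thresholds",
    "pair_threshold",
    "pair_threshold_oracle",
    "barrier_matrix",
    "build_disconnectivity_tree",
    "tree_threshold",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class LandscapeResult:
    """All state energies plus the local and global minima.

    ``local_minima`` is sorted by ascending energy (ties by code);
    ``global_minimum`` is its first element.
    """

    energies: np.ndarray
    local_minima: list[int]
    global_minimum: int

    @property
    def n_regions(self) -> int:
        return int(round(np.log2(self.energies.size)))

    def minima_energies(self) -> np.ndarray:
        return self.energies[np.asarray(self.local_minima, dtype=np.int64)]


@dataclass
class BarrierTable:
    """Pairwise connection thresholds and barriers between local minima.

    ``thresholds[a, b]`` is E_th of minima pair (a, b) (diagonal holds each
    minimum's own energy); ``barriers`` the symmetric pair barrier
    E_th - max(E_a, E_b); ``directed`` the source-referenced barrier
    E_th - E_a in row a, which sets the a -> b transition rate.
    Rows/columns follow the order of ``minima``.
    """

    minima: list[int]
    thresholds: np.ndarray
    barriers: np.ndarray
    directed: np.ndarray


@dataclass
class DisconnectivityTree:
    """Single-linkage merge structure of minima under rising energy.

    ``merges`` lists (cluster_a, cluster_b, e_th, new_cluster_size) in
    scipy linkage convention: leaves are 0..m-1 in the order of ``minima``
    and merge k creates cluster id m + k.  ``leaf_energies`` carries the
    minima energies for dendrogram annotation.
    """

    minima: list[int]
    merges: list[tuple[int, int, float, int]]
    leaf_energies: np.ndarray


# ---------------------------------------------------------------------------
# Enumeration and minima
# ---------------------------------------------------------------------------

def enumerate_energies(model: SystemModel) -> np.ndarray:
    """Energy of every state, indexed by state code (length 2**N)."""
    return state_energies(model)


def _neighbor_energy_matrix(energies: np.ndarray, n: int) -> np.ndarray:
    """(2**N, N) matrix: column i holds the energy of the bit-i flip."""
    codes = np.arange(energies.size, dtype=np.int64)
    cols = [energies[codes ^ (1 << i)] for i in range(n)]
    return np.stack(cols, axis=1)


def find_local_minima(model: SystemModel, energies: np.ndarray | None = None) -> LandscapeResult:
    """Locate all states strictly below every Hamming-1 neighbor.

    Minima are returned in ascending-energy order (ties broken by smaller
    code, with a warning, since downstream barrier tie-breaks then depend
    on code order).
    """
    if energies is None:
        energies = enumerate_energies(model)
    n = model.n_regions
    nbr = _neighbor_energy_matrix(energies, n)
    is_min = (energies[:, None] < nbr).all(axis=1)
    minima = np.flatnonzero(is_min)
    if np.any(energies[:, None] == nbr):
        warnings.warn(
            "exact energy ties between neighbor states; minima and barrier "
            "tie-breaking depend on code order",
            stacklevel=2,
        )
    order = np.lexsort((minima, energies[minima]))
    minima = [int(c) for c in minima[order]]
    if not minima:
        # cannot happen for finite energies: the global energy minimum is
        # always a local minimum, absent exact ties
        raise ValidationError("no local minimum found (degenerate ties?)")
    return LandscapeResult(
        energies=energies, local_minima=minima, global_minimum=minima[0]
    )


def complement_state(state) -> np.ndarray:
    """Flip every bit of a state vector."""
    arr = np.asarray(state)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("state entries must be 0 or 1")
    return (1 - arr).astype(np.int8)


def complement_code(code: int, n: int) -> int:
    """Integer code of the bitwise complement in an N-channel system."""
    if not 0 <= code < 2**n:
        raise ValidationError(f"code {code} out of range for N={n}")
    return int(code) ^ ((1 << n) - 1)


# ---------------------------------------------------------------------------
# Connection thresholds (bottleneck energies)
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, size: int) -> None:
        self.parent = np.arange(size, dtype=np.int64)

    def find(self, x: int) -> int:
        p = self.parent
        root = x
        while p[root] != root:
            root = p[root]
        while p[x] != root:
            p[x], x = root, p[x]
        return int(root)

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def connection_thresholds(
    energies: np.ndarray,
    minima: list[int],
    n: int,
    excluded: set[int] | frozenset[int] = frozenset(),
):
    """Bottleneck threshold E_th for every minima pair by filtration.

    States (minus ``excluded``) are inserted in ascending energy (ties by
    code); inserting a state unions it with inserted neighbors.  The pair
    threshold is the energy of the state whose insertion first joins the
    two minima's components.  Returns (threshold matrix, merge events);
    pairs kept apart by exclusions get +inf.  Merge events are
    (set_of_minima_a, set_of_minima_b, e_th) in insertion order, suitable
    for dendrogram construction.
    """
    m = len(minima)
    size = energies.size
    thresholds = np.full((m, m), np.inf)
    e_min = energies[np.asarray(minima, dtype=np.int64)]
    for a in range(m):
        thresholds[a, a] = e_min[a]
    if m < 2 and not excluded:
        return thresholds, []

    idx_of = {code: k for k, code in enumerate(minima)}
    uf = _UnionFind(size)
    inserted = np.zeros(size, dtype=bool)
    groups: dict[int, set[int]] = {}  # root -> set of minima indices
    merges: list[tuple[set[int], set[int], float]] = []

    order = np.lexsort((np.arange(size), energies))
    pending = m * (m - 1) // 2
    for code in order:
        code = int(code)
        if code in excluded:
            continue
        inserted[code] = True
        my_group = {idx_of[code]} if code in idx_of else set()
        root = uf.find(code)
        if my_group:
            groups[root] = groups.get(root, set()) | my_group
        for i in range(n):
            nb = code ^ (1 << i)
            if not inserted[nb]:
                continue
            ra, rb = uf.find(code), uf.find(nb)
            if ra == rb:
                continue
            ga = groups.pop(ra, set())
            gb = groups.pop(rb, set())
            if ga and gb:
                e_th = float(energies[code])
                merges.append((set(ga), set(gb), e_th))
                for x in ga:
                    for y in gb:
                        thresholds[x, y] = thresholds[y, x] = e_th
                pending -= len(ga) * len(gb)
            uf.union(ra, rb)
            merged = ga | gb
            if merged:
                groups[uf.find(code)] = merged
        if pending == 0:
            break
    return thresholds, merges


def pair_threshold(
    model: SystemModel,
    lm_i: int,
    lm_j: int,
    energies: np.ndarray | None = None,
    minima: list[int] | None = None,
) -> float:
    """Bottleneck connection threshold E_th of one minima pair."""
    if energies is None:
        energies = enumerate_energies(model)
    if minima is None:
        minima = find_local_minima(model, energies).local_minima
    for code in (lm_i, lm_j):
        if code not in minima:
            raise ValidationError(f"state {code} is not a local minimum")
    if lm_i == lm_j:
        raise ValidationError("the two minima must differ")
    th, _ = connection_thresholds(energies, [lm_i, lm_j], model.n_regions)
    return float(th[0, 1])


def pair_threshold_oracle(
    model: SystemModel,
    lm_i: int,
    lm_j: int,
    energies: np.ndarray | None = None,
) -> float:
    """Reference E_th via iterative shortest-path extraction and removal.

    Repeatedly finds a fewest-step path between the minima on the surviving
    state graph, takes its maximum energy as the running threshold, deletes
    all states strictly above that threshold (or, when none exist, the
    non-endpoint states attaining it, to guarantee progress), and stops
    when the minima disconnect; the last connected path's maximum is E_th.
    Test-only reference for :func:`pair_threshold`; O(2**N) per round.
    """
    import networkx as nx

    if energies is None:
        energies = enumerate_energies(model)
    n = model.n_regions
    g = nx.Graph()
    g.add_nodes_from(range(energies.size))
    for code in range(energies.size):
        for i in range(n):
            nb = code ^ (1 << i)
            if nb > code:
                g.add_edge(code, nb)

    last_th: float | None = None
    while True:
        try:
            path = nx.shortest_path(g, lm_i, lm_j)
        except nx.NetworkXNoPath:
            assert last_th is not None
            return last_th
        th = float(max(energies[v] for v in path))
        last_th = th
        doomed = [v for v in g.nodes if energies[v] > th]
        if not doomed:
            doomed = [
                v for v in g.nodes
                if energies[v] == th and v not in (lm_i, lm_j)
            ]
        if not doomed:
            return th
        g.remove_nodes_from(doomed)


# ---------------------------------------------------------------------------
# Barriers and disconnectivity tree
# ---------------------------------------------------------------------------

def barrier_matrix(model: SystemModel, landscape: LandscapeResult) -> BarrierTable:
    """Thresholds, pair barriers and directed barriers for all minima pairs."""
    minima = landscape.local_minima
    m = len(minima)
    if m < 2:
        warnings.warn("single-minimum landscape: empty barrier table", stacklevel=2)
        e = landscape.minima_energies()
        z = np.zeros((m, m))
        return BarrierTable(
            minima=list(minima),
            thresholds=np.diag(e) if m else z,
            barriers=z,
            directed=z,
        )
    th, _ = connection_thresholds(landscape.energies, minima, model.n_regions)
    e = landscape.minima_energies()
    pairmax = np.maximum.outer(e, e)
    barriers = th - pairmax
    directed = th - e[:, None]
    np.fill_diagonal(barriers, 0.0)
    np.fill_diagonal(directed, 0.0)
    return BarrierTable(
        minima=list(minima), thresholds=th, barriers=barriers, directed=directed
    )


def build_disconnectivity_tree(
    barriers: BarrierTable, landscape: LandscapeResult
) -> DisconnectivityTree:
    """Single-linkage merge tree of minima at their connection thresholds."""
    minima = barriers.minima
    m = len(minima)
    if m < 2:
        raise ValidationError("disconnectivity tree needs at least 2 minima")
    # sort pairs by threshold ascending; union-find assembles the dendrogram
    pairs = [
        (float(barriers.thresholds[a, b]), a, b)
        for a in range(m) for b in range(a + 1, m)
    ]
    pairs.sort()
    cluster_of = list(range(m))  # leaf/cluster id per minimum index
    sizes = {k: 1 for k in range(m)}
    uf = _UnionFind(m)
    merges: list[tuple[int, int, float, int]] = []
    next_id = m
    for e_th, a, b in pairs:
        ra, rb = uf.find(a), uf.find(b)
        if ra == rb:
            continue
        ca, cb = cluster_of[ra], cluster_of[rb]
        new_size = sizes[ca] + sizes[cb]
        merges.append((min(ca, cb), max(ca, cb), e_th, new_size))
        uf.union(ra, rb)
        root = uf.find(ra)
        cluster_of[root] = next_id
        sizes[next_id] = new_size
        next_id += 1
    return DisconnectivityTree(
        minima=list(minima),
        merges=merges,
        leaf_energies=landscape.energies[np.asarray(minima, dtype=np.int64)],
    )


def tree_threshold(tree: DisconnectivityTree, a: int, b: int) -> float:
    """Tree-implied connection threshold between minima indices a and b."""
    m = len(tree.minima)
    members: dict[int, set[int]] = {k: {k} for k in range(m)}
    for k, (ca, cb, e_th, _) in enumerate(tree.merges):
        ma, mb = members.pop(ca), members.pop(cb)
        if (a in ma and b in mb) or (a in mb and b in ma):
            return e_th
        members[m + k] = ma | mb
    raise ValidationError(f"minima indices {a}, {b} never merge in the tree")
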