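"""Minimax transition pathways and state-transition networks.

For every pair of local minima the optimal (minimax) pathway is the
one-flip-per-step route whose maximum energy equals the pair's bottleneck
threshold E_th; the state attaining that maximum is the rate-determining
transition state (TS), and the pathway's transition rate is exp(-E_B) with
E_B = E_th - E(source), the barrier seen from the higher-energy endpoint.

Three networks summarize the pathway ensemble:

- STN-FS: every state on any pathway is a node; consecutive pathway states
  are directed edges (higher-energy minimum toward lower), each stamped
  with its pathway's rate.
- STN-GM: the STN-FS restricted to the pathways terminating at the global
  minimum.
- STN-LM: local minima and rate-determining transition states only, with
  source -> TS (inward) and TS -> target (outward) edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from elanet.errors import ValidationError
from elanet.landscape import (
    LandscapeResult,
    connection_thresholds,
    enumerate_energies,
    find_local_minima,
)
from elanet.mem import SystemModel

logger = logging.getLogger(__name__)

ROLE_LOCAL_MINIMUM = "local_minimum"
ROLE_TRANSITION_STATE = "transition_state"
ROLE_TRANSIENT = "transient"


@dataclass
class TransitionPath:
    """A minimax pathway between two local minima.

    ``source_lm`` is the higher-energy endpoint; ``states`` runs from
    source to target, one bit flip per step; ``ts_code`` is the
    rate-determining transition state (first state attaining the path
    maximum ``e_th``); ``e_b = e_th - E(source)``; ``intermediates`` are
    interior states that are themselves local minima, in path order.
    """

    source_lm: int
    target_lm: int
    states: list[int]
    e_th: float
    e_b: float
    ts_code: int
    intermediates: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.states) - 1  # number of steps


@dataclass
class RerouteRecord:
    """Outcome of re-deriving one pair's pathway after a state removal."""

    source_lm: int
    target_lm: int
    path: TransitionPath | None
    disconnected: bool


@dataclass
class TransitionNetwork:
    """A state-transition network over codes with role-labeled nodes.

    ``graph`` is a directed simple graph; node attributes: ``role``,
    ``energy``; edge attributes: ``rate``, ``e_b``, ``pathways`` (ids of
    contributing pathways) and ``multiplicity``.
    """

    variant: str
    graph: nx.DiGraph
    paths: list[TransitionPath]
    n_regions: int = 0

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def transition_rate(e_b: float) -> float:
    """Transition rate exp(-E_B) of a pathway with barrier E_B >= 0."""
    if e_b < 0:
        raise ValidationError(f"energy barrier must be >= 0, got {e_b}")
    return float(np.exp(-e_b))


def minima_pairs(minima: list[int]) -> list[tuple[int, int]]:
    """All unordered pairs of local minima, in minima-list order."""
    return [
        (minima[a], minima[b])
        for a in range(len(minima))
        for b in range(a + 1, len(minima))
    ]


# ---------------------------------------------------------------------------
# Path extraction
# ---------------------------------------------------------------------------

def _orient(energies: np.ndarray, lm_i: int, lm_j: int) -> tuple[int, int]:
    """Source = higher-energy minimum; exact ties orient toward the smaller
    code (the first-ranked minimum), so tied pairs still flow toward the
    global minimum."""
    ei, ej = energies[lm_i], energies[lm_j]
    if ei > ej:
        return lm_i, lm_j
    if ej > ei:
        return lm_j, lm_i
    logger.info("equal-energy minima pair (%d, %d): orienting by code", lm_i, lm_j)
    return (lm_j, lm_i) if lm_i < lm_j else (lm_i, lm_j)


def _shortest_lex_path(
    energies: np.ndarray,
    n: int,
    source: int,
    target: int,
    e_th: float,
    excluded: frozenset[int],
) -> list[int] | None:
    """Fewest-step path from source to target within the E <= E_th subspace,
    ties broken by the lexicographically smallest code sequence."""
    size = energies.size
    allowed = energies <= e_th
    for code in excluded:
        allowed[code] = False
    if not (allowed[source] and allowed[target]):
        return None
    dist = np.full(size, -1, dtype=np.int32)
    dist[target] = 0
    frontier = [target]
    while frontier and dist[source] < 0:
        nxt = []
        for code in frontier:
            d = dist[code] + 1
            for i in range(n):
                nb = code ^ (1 << i)
                if allowed[nb] and dist[nb] < 0:
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt
    if dist[source] < 0:
        return None
    # walk downhill in BFS distance, smallest code first => lexicographically
    # smallest among all fewest-step sequences
    path = [source]
    code = source
    while code != target:
        d = dist[code]
        best = None
        for i in range(n):
            nb = code ^ (1 << i)
            if allowed[nb] and dist[nb] == d - 1 and (best is None or nb < best):
                best = nb
        path.append(best)
        code = best
    return path


def _path_from_threshold(
    energies: np.ndarray,
    n: int,
    source: int,
    target: int,
    e_th: float,
    minima: list[int],
    excluded: frozenset[int],
) -> TransitionPath | None:
    states = _shortest_lex_path(energies, n, source, target, e_th, excluded)
    if states is None:
        return None
    path_e = energies[np.asarray(states, dtype=np.int64)]
    ts_pos = int(np.flatnonzero(path_e == path_e.max())[0])  # first = nearest source
    minima_set = set(minima)
    intermediates = [c for c in states[1:-1] if c in minima_set]
    e_b = float(e_th - energies[source])
    return TransitionPath(
        source_lm=source,
        target_lm=target,
        states=[int(c) for c in states],
        e_th=float(e_th),
        e_b=e_b,
        ts_code=int(states[ts_pos]),
        intermediates=intermediates,
    )


def minimax_path(
    model: SystemModel,
    lm_i: int,
    lm_j: int,
    landscape: LandscapeResult | None = None,
    excluded: frozenset[int] = frozenset(),
) -> TransitionPath:
    """The minimax pathway of one minima pair.

    Among all one-flip paths achieving the pair's bottleneck threshold the
    fewest-step path is returned, remaining ties broken by the
    lexicographically smallest code sequence, so extraction is
    deterministic.
    """
    if landscape is None:
        landscape = find_local_minima(model)
    minima = landscape.local_minima
    for code in (lm_i, lm_j):
        if code not in minima:
            raise ValidationError(f"state {code} is not a local minimum")
    if lm_i == lm_j:
        raise ValidationError("the two minima must differ")
    energies = landscape.energies
    source, target = _orient(energies, lm_i, lm_j)
    th, _ = connection_thresholds(
        energies, [source, target], model.n_regions, excluded=excluded
    )
    e_th = float(th[0, 1])
    if not np.isfinite(e_th):
        raise ValidationError(
            f"minima {lm_i} and {lm_j} are disconnected by the exclusions"
        )
    path = _path_from_threshold(
        energies, model.n_regions, source, target, e_th, minima, excluded
    )
    assert path is not None
    return path


def all_pair_paths(
    model: SystemModel,
    landscape: LandscapeResult | None = None,
    excluded: frozenset[int] = frozenset(),
) -> list[TransitionPath]:
    """Minimax pathways for all C(m, 2) minima pairs (connected ones)."""
    if landscape is None:
        landscape = find_local_minima(model)
    minima = landscape.local_minima
    energies = landscape.energies
    n = model.n_regions
    th, _ = connection_thresholds(energies, minima, n, excluded=excluded)
    paths = []
    for a in range(len(minima)):
        for b in range(a + 1, len(minima)):
            e_th = float(th[a, b])
            if not np.isfinite(e_th):
                continue
            source, target = _orient(energies, minima[a], minima[b])
            path = _path_from_threshold(
                energies, n, source, target, e_th, minima, excluded
            )
            if path is not None:
                paths.append(path)
    return paths


def locate_intermediates(
    path: TransitionPath, landscape: LandscapeResult
) -> list[int]:
    """Interior pathway states that are local minima, in path order."""
    minima = set(landscape.local_minima)
    return [c for c in path.states[1:-1] if c in minima]


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def _node_roles(
    paths: list[TransitionPath], minima: set[int]
) -> dict[int, str]:
    roles: dict[int, str] = {}
    for path in paths:
        for code in path.states:
            roles.setdefault(code, ROLE_TRANSIENT)
    for path in paths:
        if path.ts_code not in minima:
            roles[path.ts_code] = ROLE_TRANSITION_STATE
    for code in list(roles):
        if code in minima:
            roles[code] = ROLE_LOCAL_MINIMUM
    return roles


def _stamp_edge(
    g: nx.DiGraph, u: int, v: int, rate: float, e_b: float, pathway: int
) -> None:
    """Add or update a directed edge; parallel pathway contributions keep
    the maximum rate and count multiplicity."""
    if g.has_edge(u, v):
        data = g[u][v]
        data["multiplicity"] += 1
        data["pathways"].append(pathway)
        if rate > data["rate"]:
            data["rate"] = rate
            data["e_b"] = e_b
    else:
        g.add_edge(u, v, rate=rate, e_b=e_b, multiplicity=1, pathways=[pathway])


def _network_from_paths(
    variant: str,
    paths: list[TransitionPath],
    landscape: LandscapeResult,
) -> TransitionNetwork:
    minima = set(landscape.local_minima)
    g = nx.DiGraph()
    roles = _node_roles(paths, minima)
    for code, role in roles.items():
        g.add_node(code, role=role, energy=float(landscape.energies[code]))
    for pid, path in enumerate(paths):
        rate = transition_rate(path.e_b)
        for u, v in zip(path.states[:-1], path.states[1:]):
            _stamp_edge(g, u, v, rate, path.e_b, pid)
    return TransitionNetwork(
        variant=variant, graph=g, paths=list(paths),
        n_regions=landscape.n_regions,
    )


def build_stn_fs(
    model: SystemModel,
    landscape: LandscapeResult | None = None,
    paths: list[TransitionPath] | None = None,
) -> TransitionNetwork:
    """Full-state transition network over all pathway states."""
    if landscape is None:
        landscape = find_local_minima(model)
    if len(landscape.local_minima) < 2:
        raise ValidationError("STN construction needs at least 2 local minima")
    if paths is None:
        paths = all_pair_paths(model, landscape)
    return _network_from_paths("FS", paths, landscape)


def build_stn_gm(
    stn_fs: TransitionNetwork, landscape: LandscapeResult
) -> TransitionNetwork:
    """Restriction of the STN-FS to pathways ending at the global minimum."""
    gm = landscape.global_minimum
    gm_paths = [p for p in stn_fs.paths if p.target_lm == gm]
    return _network_from_paths("GM", gm_paths, landscape)


def build_stn_lm(
    paths: list[TransitionPath], landscape: LandscapeResult
) -> TransitionNetwork:
    """Reduced network over local minima and rate-determining TSs.

    Each pathway contributes an inward edge source -> TS and an outward
    edge TS -> target.  When the TS coincides with a pathway endpoint (the
    two minima are Hamming-1 adjacent) a direct minimum-to-minimum edge is
    recorded instead and the special case logged.
    """
    minima = set(landscape.local_minima)
    g = nx.DiGraph()
    for code in landscape.local_minima:
        g.add_node(
            code, role=ROLE_LOCAL_MINIMUM, energy=float(landscape.energies[code])
        )
    for path in paths:
        ts = path.ts_code
        if ts not in minima and ts not in g:
            g.add_node(
                ts,
                role=ROLE_TRANSITION_STATE,
                energy=float(landscape.energies[ts]),
            )
    for pid, path in enumerate(paths):
        rate = transition_rate(path.e_b)
        ts = path.ts_code
        if ts in (path.source_lm, path.target_lm):
            logger.info(
                "adjacent minima pair (%d, %d): direct LM->LM edge",
                path.source_lm, path.target_lm,
            )
            _stamp_edge(g, path.source_lm, path.target_lm, rate, path.e_b, pid)
        else:
            _stamp_edge(g, path.source_lm, ts, rate, path.e_b, pid)
            _stamp_edge(g, ts, path.target_lm, rate, path.e_b, pid)
    return TransitionNetwork(
        variant="LM", graph=g, paths=list(paths),
        n_regions=landscape.n_regions,
    )


def remove_state_and_reroute(
    model: SystemModel,
    landscape: LandscapeResult,
    removed: int,
    excluded: frozenset[int] = frozenset(),
) -> list[RerouteRecord]:
    """Re-derive every pair's pathway with one state code deleted.

    ``excluded`` carries previously removed codes so multi-removal can be
    composed by the caller.  Pairs left with no surviving path are flagged
    disconnected.
    """
    minima = landscape.local_minima
    if removed in minima:
        raise ValidationError("cannot remove a local minimum under analysis")
    energies = landscape.energies
    n = model.n_regions
    excl = frozenset(excluded) | {int(removed)}
    th, _ = connection_thresholds(energies, minima, n, excluded=excl)
    records = []
    for a in range(len(minima)):
        for b in range(a + 1, len(minima)):
            source, target = _orient(energies, minima[a], minima[b])
            e_th = float(th[a, b])
            if not np.isfinite(e_th):
                records.append(
                    RerouteRecord(
                        source_lm=source, target_lm=target,
                        path=None, disconnected=True,
                    )
                )
                continue
            path = _path_from_threshold(
                energies, n, source, target, e_th, minima, excl
            )
            records.append(
                RerouteRecord(
                    source_lm=source, target_lm=target,
                    path=path, disconnected=path is None,
                )
            )
    return records
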