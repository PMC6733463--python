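"""Graph-theoretic and statistical analysis of transition networks.

Covers node-degree profiles and hub flagging, pathway length decomposition
(full / to-TS / from-TS / effective), UPGMA clustering of local minima by
their barrier or rate profiles, Pearson correlation summaries, intra- vs
inter-group transition tabulation, and perturbation sweeps that rescale
all couplings by a factor alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from elanet.errors import ValidationError
from elanet.landscape import BarrierTable, LandscapeResult, find_local_minima
from elanet.mem import SystemModel
from elanet.transitions import (
    TransitionNetwork,
    TransitionPath,
    all_pair_paths,
    build_stn_fs,
    transition_rate,
)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """UPGMA grouping of local minima.

    ``linkage`` is a scipy linkage matrix over the minima (leaf order =
    ``minima``); ``group_labels`` maps each minimum code to its group id
    at the requested cut (two groups by default).
    """

    minima: list[int]
    linkage: np.ndarray
    group_labels: dict[int, int]
    mode: str


@dataclass
class CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value."""

    r: float
    p: float
    n: int


@dataclass
class PerturbationSweep:
    """Landscape and network summaries across a grid of coupling scales.

    ``stn_summaries[k]`` is None when the alpha-scaled landscape has fewer
    than two minima; otherwise a dict with node/edge counts, maximum
    collapsed degree and the effective-path-length histogram.
    """

    alphas: np.ndarray
    minima_counts: np.ndarray
    stn_summaries: list[dict | None]


class PathLengths(NamedTuple):
    full: int
    to_ts: int
    from_ts: int
    effective: int


# ---------------------------------------------------------------------------
# Elementary measures
# ---------------------------------------------------------------------------

def hamming_distance(a, b) -> int:
    """Number of differing bits between two equal-length state vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValidationError("states must have equal length")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValidationError("state entries must be 0 or 1")
    return int(np.sum(a != b))


def hamming_codes(a: int, b: int) -> int:
    """Hamming distance between two states given as integer codes."""
    return int(a ^ b).bit_count()


def path_lengths(path: TransitionPath) -> PathLengths:
    """Decompose a pathway's length.

    ``full`` is the number of one-flip steps, ``to_ts``/``from_ts`` the
    steps from source to the rate-determining TS and onward to the target,
    and ``effective`` the detour excess: full minus the endpoint Hamming
    distance (always even and non-negative by parity of bit flips).
    """
    full = len(path)
    ts_idx = path.states.index(path.ts_code)
    eff = full - hamming_codes(path.source_lm, path.target_lm)
    return PathLengths(full=full, to_ts=ts_idx, from_ts=full - ts_idx, effective=eff)


def node_degree_profile(network: TransitionNetwork) -> pd.DataFrame:
    """Degree of every node on the collapsed undirected simple graph.

    Returns a frame (code, role, degree, hub) sorted by descending degree;
    a node is flagged hub when its degree exceeds mean + 2 SD of the
    network's degree distribution (reported, not asserted).
    """
    und = network.graph.to_undirected()
    rows = [
        (code, network.graph.nodes[code]["role"], deg)
        for code, deg in und.degree()
    ]
    df = pd.DataFrame(rows, columns=["code", "role", "degree"])
    mu, sd = df["degree"].mean(), df["degree"].std(ddof=0)
    df["hub"] = df["degree"] > mu + 2 * sd
    return df.sort_values(
        ["degree", "code"], ascending=[False, True], ignore_index=True
    )


# ---------------------------------------------------------------------------
# Clustering and correlation
# ---------------------------------------------------------------------------

def cluster_local_minima(
    barriers: BarrierTable,
    mode: str = "barrier",
    n_groups: int = 2,
    feature_vectors: bool = True,
) -> ClusterResult:
    """UPGMA (average-linkage) clustering of local minima.

    Each minimum is represented by its row of pairwise values — energy
    barriers in ``barrier`` mode, transition rates exp(-E_B) in ``rate``
    mode (self-entry 0 in both) — and UPGMA runs on Euclidean distances
    between those feature vectors.  With ``feature_vectors=False`` the
    pairwise values are used directly as the dissimilarity (1 - rate in
    rate mode, so that faster transitions mean closer minima).
    """
    if mode not in ("barrier", "rate"):
        raise ValidationError("mode must be 'barrier' or 'rate'")
    m = len(barriers.minima)
    if m < 2:
        raise ValidationError("clustering needs at least 2 minima")
    if mode == "barrier":
        mat = barriers.barriers.copy()
    else:
        mat = np.exp(-barriers.barriers)
        np.fill_diagonal(mat, 0.0)
    if feature_vectors:
        z = linkage(pdist(mat, metric="euclidean"), method="average")
    else:
        dissim = mat if mode == "barrier" else 1.0 - mat
        np.fill_diagonal(dissim, 0.0)
        z = linkage(squareform(dissim, checks=False), method="average")
    labels = fcluster(z, t=n_groups, criterion="maxclust")
    group_labels = {
        code: int(lab) for code, lab in zip(barriers.minima, labels)
    }
    return ClusterResult(
        minima=list(barriers.minima), linkage=z, group_labels=group_labels, mode=mode
    )


def correlate_pearson(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p-value (t-distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=x.size)


def analyze_group_transitions(
    paths: list[TransitionPath],
    clusters: ClusterResult,
    landscape: LandscapeResult,
    both_directions: bool = True,
) -> pd.DataFrame:
    """Per-pair transition records tagged intra- or inter-group.

    One row per ordered minima pair (2 * C(m, 2) rows when
    ``both_directions``): source/target groups, endpoint Hamming distance,
    threshold, source-referenced barrier and rate, and the full / to-TS /
    from-TS / effective length decomposition.  The reverse direction reuses
    the same pathway with the barrier re-referenced to its own source.
    """
    energies = landscape.energies
    rows = []
    for path in paths:
        pl = path_lengths(path)
        ham = hamming_codes(path.source_lm, path.target_lm)
        directions = [
            (path.source_lm, path.target_lm, path.e_b, pl.to_ts, pl.from_ts)
        ]
        if both_directions:
            e_b_rev = path.e_th - float(energies[path.target_lm])
            directions.append(
                (path.target_lm, path.source_lm, e_b_rev, pl.from_ts, pl.to_ts)
            )
        for src, tgt, e_b, to_ts, from_ts in directions:
            g_src = clusters.group_labels[src]
            g_tgt = clusters.group_labels[tgt]
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "source_group": g_src,
                    "target_group": g_tgt,
                    "kind": "intra" if g_src == g_tgt else "inter",
                    "hamming": ham,
                    "e_th": path.e_th,
                    "e_b": e_b,
                    "rate": transition_rate(e_b),
                    "full": pl.full,
                    "to_ts": to_ts,
                    "from_ts": from_ts,
                    "effective": pl.effective,
                    "ts_code": path.ts_code,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------

def scale_interactions(model: SystemModel, alpha: float) -> SystemModel:
    """Rescale all couplings: J <- alpha * J, fields unchanged."""
    if alpha < 0:
        raise ValidationError("alpha must be >= 0")
    return SystemModel(
        n_regions=model.n_regions,
        h=model.h.copy(),
        j=alpha * model.j,
        region_labels=list(model.region_labels) if model.region_labels else None,
    )


def permute_parameters(model: SystemModel, mode: str, seed: int = 0) -> SystemModel:
    """Randomized-parameter control systems.

    ``permute_h`` shuffles the fields, ``permute_j`` shuffles the
    upper-triangle couplings (re-symmetrized), ``random_values`` redraws
    both from their empirical value multisets with replacement.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = model.n_regions
    iu = np.triu_indices(n, k=1)
    h = model.h.copy()
    jvals = model.j[iu].copy()
    if mode == "permute_h":
        h = rng.permutation(h)
    elif mode == "permute_j":
        jvals = rng.permutation(jvals)
    elif mode == "random_values":
        h = rng.choice(model.h, size=n, replace=True)
        jvals = rng.choice(model.j[iu], size=jvals.size, replace=True)
    else:
        raise ValidationError(
            "mode must be 'permute_h', 'permute_j' or 'random_values'"
        )
    j = np.zeros((n, n))
    j[iu] = jvals
    j = j + j.T
    return SystemModel(n_regions=n, h=h, j=j)


def default_alpha_grid() -> np.ndarray:
    """The standard coupling-scale grid 0.0, 0.1, ..., 5.0."""
    return np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)


def sweep_alpha(
    model: SystemModel, alphas: np.ndarray | None = None
) -> PerturbationSweep:
    """Landscape and STN-FS summaries for each coupling scale alpha.

    For every alpha the couplings are rescaled, the landscape re-derived
    and the minima counted; when at least two minima survive the STN-FS is
    rebuilt and summarized (node/edge counts, maximum collapsed degree,
    histogram of effective path lengths).
    """
    if alphas is None:
        alphas = default_alpha_grid()
    alphas = np.asarray(alphas, dtype=float)
    if np.any(alphas < 0):
        raise ValidationError("all alphas must be >= 0")
    counts = np.zeros(alphas.size, dtype=int)
    summaries: list[dict | None] = []
    for k, alpha in enumerate(alphas):
        scaled = scale_interactions(model, float(alpha))
        scape = find_local_minima(scaled)
        counts[k] = len(scape.local_minima)
        if counts[k] < 2:
            summaries.append(None)
            continue
        paths = all_pair_paths(scaled, scape)
        stn = build_stn_fs(scaled, scape, paths=paths)
        degs = node_degree_profile(stn)["degree"]
        eff = [path_lengths(p).effective for p in paths]
        summaries.append(
            {
                "alpha": float(alpha),
                "n_nodes": stn.n_nodes,
                "n_edges": stn.n_edges,
                "max_degree": int(degs.max()),
                "effective_lengths": np.bincount(eff).tolist(),
            }
        )
    return PerturbationSweep(
        alphas=alphas, minima_counts=counts, stn_summaries=summaries
    )
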