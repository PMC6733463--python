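"""Readers and writers for models, time series, networks and trees.

Formats: TSV (default, CSV accepted on read) for time series and tables,
JSON for model parameters, configs and provenance, GraphML or TSV edge
lists for transition networks, and Newick-like nested strings for
disconnectivity trees and UPGMA dendrograms.

Integer state codes use channel 0 as the least-significant bit; rendered
bitstrings put channel 0 leftmost.  Both are written wherever states
appear, to avoid ambiguity.
"""

from __future__ import annotations

import json
import platform
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from elanet.errors import ValidationError
from elanet.landscape import DisconnectivityTree, LandscapeResult
from elanet.mem import StateTimeSeries, SystemModel, decode_state
from elanet.transitions import TransitionNetwork


@dataclass
class RunConfig:
    """Configuration of one pipeline run (all knobs in one record)."""

    input_path: str | None = None
    out_dir: str = "elanet_out"
    threshold: float = 0.0
    a_g: float = 0.1
    tol: float = 1e-5
    max_iter: int = 500_000
    variants: list[str] = dc_field(default_factory=lambda: ["FS", "GM", "LM"])
    cluster_mode: str = "barrier"
    alpha_grid: list[float] | None = None
    remove_states: list[int] = dc_field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def bitstring(code: int, n: int) -> str:
    """Render a state code with channel 0 leftmost."""
    return "".join(str(b) for b in decode_state(code, n))


# ---------------------------------------------------------------------------
# Time series
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_timeseries(path) -> pd.DataFrame:
    """Read a T x N table (TSV or CSV, header row of channel labels)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if df.shape[0] < 1 or df.shape[1] < 1:
        raise ValidationError(f"{path}: empty time-series table")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        raise ValidationError(f"{path}: non-numeric column(s) {list(bad)}")
    if df.isna().any().any():
        row, col = next(
            (r, c) for c in df.columns for r in df.index[df[c].isna()]
        )
        raise ValidationError(f"{path}: missing value at row {row}, column {col!r}")
    return df


def write_timeseries(series, path, labels: list[str] | None = None) -> None:
    """Write a binary series or continuous table as TSV/CSV with header."""
    path = Path(path)
    if isinstance(series, StateTimeSeries):
        data = series.states
    else:
        data = np.asarray(series)
    if labels is None:
        labels = [f"R{i}" for i in range(data.shape[1])]
    df = pd.DataFrame(data, columns=labels)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


def as_state_series(df: pd.DataFrame) -> StateTimeSeries:
    """Interpret a table as binary states (errors if not 0/1-valued)."""
    return StateTimeSeries(states=df.to_numpy())


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def write_model(model: SystemModel, path) -> None:
    payload = {
        "n_regions": model.n_regions,
        "region_labels": model.region_labels,
        "h": model.h.tolist(),
        "j": model.j.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path) -> SystemModel:
    payload = json.loads(Path(path).read_text())
    for key in ("n_regions", "h", "j"):
        if key not in payload:
            raise ValidationError(f"{path}: missing required key {key!r}")
    j = np.asarray(payload["j"], dtype=float)
    if j.ndim != 2 or j.shape[0] != j.shape[1]:
        raise ValidationError(f"{path}: j must be a square matrix")
    if not np.array_equal(j, j.T):
        raise ValidationError(f"{path}: j must be symmetric")
    if np.any(np.diag(j) != 0):
        raise ValidationError(f"{path}: j must have a zero diagonal")
    return SystemModel(
        n_regions=int(payload["n_regions"]),
        h=np.asarray(payload["h"], dtype=float),
        j=j,
        region_labels=payload.get("region_labels"),
    )


# ---------------------------------------------------------------------------
# Landscape tables
# ---------------------------------------------------------------------------

def minima_table(landscape: LandscapeResult) -> pd.DataFrame:
    """Local minima as a frame: label LM1.. in ascending-energy order."""
    n = landscape.n_regions
    rows = [
        {
            "label": f"LM{k + 1}",
            "code": code,
            "bitstring": bitstring(code, n),
            "energy": float(landscape.energies[code]),
            "is_global_minimum": code == landscape.global_minimum,
        }
        for k, code in enumerate(landscape.local_minima)
    ]
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

def write_network(network: TransitionNetwork, path, format: str = "graphml") -> None:
    """Export a transition network deterministically (nodes sorted by code).

    GraphML carries node attributes (code, bitstring, role, energy) and
    edge attributes (rate, e_b, pathway ids, multiplicity); the TSV edge
    list has columns from_code, to_code, rate, e_b, pathway.
    """
    path = Path(path)
    n = network.n_regions
    if format == "graphml":
        g = nx.DiGraph()
        for code in sorted(network.graph.nodes):
            attrs = network.graph.nodes[code]
            g.add_node(
                code,
                code=int(code),
                bitstring=bitstring(code, n),
                role=attrs["role"],
                energy=float(attrs["energy"]),
            )
        for u, v in sorted(network.graph.edges):
            data = network.graph[u][v]
            g.add_edge(
                u, v,
                rate=float(data["rate"]),
                e_b=float(data["e_b"]),
                pathways=",".join(map(str, data["pathways"])),
                multiplicity=int(data["multiplicity"]),
            )
        nx.write_graphml(g, path)
    elif format == "edgelist_tsv":
        rows = [
            {
                "from_code": u,
                "to_code": v,
                "rate": float(d["rate"]),
                "e_b": float(d["e_b"]),
                "pathway": ",".join(map(str, d["pathways"])),
            }
            for u, v, d in sorted(network.graph.edges(data=True))
        ]
        write_table(pd.DataFrame(rows), path)
    else:
        raise ValidationError("format must be 'graphml' or 'edgelist_tsv'")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def tree_to_newick(
    merges: list[tuple[int, int, float, int]] | np.ndarray,
    leaf_names: list[str],
    leaf_heights: np.ndarray | None = None,
) -> str:
    """Nested-parenthesis rendering of a merge list (scipy convention).

    Branch lengths are the height differences between a cluster and its
    parent merge.  ``leaf_heights`` places the leaves (e.g. at their own
    energies for a disconnectivity tree); default 0 suits an ordinary
    dendrogram.
    """
    m = len(leaf_names)
    if leaf_heights is None:
        leaf_heights = np.zeros(m)
    reps: dict[int, tuple[str, float]] = {
        k: (leaf_names[k], float(leaf_heights[k])) for k in range(m)
    }
    rep = ""
    for k, row in enumerate(merges):
        a, b, height = int(row[0]), int(row[1]), float(row[2])
        (sa, ha), (sb, hb) = reps.pop(a), reps.pop(b)
        rep = f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g})"
        reps[m + k] = (rep, height)
    if len(reps) != 1:
        # forest (disconnected pairs): join remaining subtrees at the root
        parts = [s for s, _ in reps.values()]
        rep = "(" + ",".join(parts) + ")"
    return rep + ";"


def write_disconnectivity_newick(tree: DisconnectivityTree, path) -> None:
    names = [f"LM{k + 1}" for k in range(len(tree.minima))]
    Path(path).write_text(
        tree_to_newick(tree.merges, names, leaf_heights=tree.leaf_energies)
        + "\n"
    )


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

def write_provenance(path, config: dict, seed: int, started: float) -> None:
    """Sidecar JSON recording config, seed, versions and wall time."""
    import elanet

    payload = {
        "config": config,
        "seed": seed,
        "elapsed_s": round(time.time() - started, 3),
        "versions": {
            "elanet": elanet.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "networkx": nx.__version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1))
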