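"""Directed movement networks between receiver stations.

Successive detections of a shark at two distinct stations form one
directed movement (edge weight = number of such transitions); runs of
detections at the same station collapse. Subset networks (sex,
maturity, season, diel) filter detections first and pair within the
subset, so a movement inherits the subset of its arrival detection.
Node degree counts distinct in- plus out-neighbours, the "traffic"
through a station. Group overlap is tested with a Mantel permutation
test on the off-diagonal entries of two weighted adjacency matrices,
and group mobility with a Mann-Whitney test on node-degree vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .config import StudyConfig
from .errors import ConfigurationError, DataIntegrityError
from . import stats as _stats


def assign_period(dets: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Attach ``season`` and ``diel`` columns from local timestamps.

    Season follows the calendar month; the diel day window is inclusive
    at both printed bounds (06:30:00 is day, 18:30:00 is night by
    default).
    """
    out = dets.copy()
    months = out["timestamp"].dt.month
    out["season"] = np.where(
        months.isin(list(config.summer_months)), "summer", "winter"
    )
    # inclusive minute-resolution bounds: 18:29:59 is still "day" when
    # the window is printed as 06:30-18:29
    minute = out["timestamp"].dt.hour * 60 + out["timestamp"].dt.minute
    lo = config.day_start.hour * 60 + config.day_start.minute
    hi = config.day_end.hour * 60 + config.day_end.minute
    out["diel"] = np.where((minute >= lo) & (minute <= hi), "day", "night")
    return out


@dataclass
class MovementNetwork:
    """Directed weighted station-transition network for a data subset."""

    nodes: tuple
    adjacency: np.ndarray  # integer counts, zero diagonal
    label: str = ""

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise ConfigurationError("adjacency shape must match node count")
        if np.diag(self.adjacency).any():
            raise ConfigurationError("self-loops are not allowed")

    @property
    def n_movements(self) -> int:
        return int(self.adjacency.sum())

    def edges(self) -> pd.DataFrame:
        src, dst = np.nonzero(self.adjacency)
        return pd.DataFrame(
            {
                "from": [self.nodes[i] for i in src],
                "to": [self.nodes[j] for j in dst],
                "weight": self.adjacency[src, dst].astype(int),
            }
        )

    def summary(self) -> dict:
        deg = node_degrees(self)
        active = deg[deg > 0]
        weights = self.adjacency[self.adjacency > 0]
        return {
            "label": self.label,
            "n_nodes": len(self.nodes),
            "n_active_nodes": int((deg > 0).sum()),
            "n_edges": int((self.adjacency > 0).sum()),
            "n_movements": self.n_movements,
            "degree_range": [int(active.min()), int(active.max())] if len(active) else None,
            "weight_range": [int(weights.min()), int(weights.max())] if len(weights) else None,
        }


def build_network(
    dets: pd.DataFrame,
    stations: Sequence[str],
    subset: Optional[Callable[[pd.DataFrame], pd.Series] | pd.Series] = None,
    label: str = "",
    pair_before_filter: bool = False,
    max_gap: Optional[pd.Timedelta] = None,
) -> MovementNetwork:
    """Build the directed transition network for a detection subset.

    ``subset`` is a boolean mask (or a callable producing one) selecting
    the detections of interest. By default detections are filtered
    before pairing; with ``pair_before_filter`` transitions are formed
    on the full sequence and then kept when their arrival detection is
    in the subset. ``max_gap``, if given, discards transitions whose
    consecutive detections are further apart in time.
    """
    nodes = tuple(stations)
    index = {s: i for i, s in enumerate(nodes)}
    unknown = set(dets["station_id"].unique()) - set(nodes)
    if unknown:
        raise DataIntegrityError(f"detections at unknown stations {sorted(unknown)}")

    mask = None
    if subset is not None:
        mask = subset(dets) if callable(subset) else subset
    work = dets if (mask is None or pair_before_filter) else dets[mask]

    adj = np.zeros((len(nodes), len(nodes)), dtype=int)
    for _, grp in work.groupby("tag_id", sort=True):
        grp = grp.sort_values("timestamp", kind="mergesort")
        st = grp["station_id"].to_numpy()
        if len(st) < 2:
            continue
        move = st[1:] != st[:-1]
        if max_gap is not None:
            ts = grp["timestamp"].to_numpy()
            move &= (ts[1:] - ts[:-1]) <= np.timedelta64(max_gap)
        if pair_before_filter and mask is not None:
            arrival_in = mask.loc[grp.index].to_numpy()[1:]
            move &= arrival_in
        for a, b in zip(st[:-1][move], st[1:][move]):
            adj[index[a], index[b]] += 1
    return MovementNetwork(nodes=nodes, adjacency=adj, label=label)


def node_degrees(net: MovementNetwork) -> pd.Series:
    """Distinct in- plus out-neighbour count per station."""
    indeg = (net.adjacency > 0).sum(axis=0)
    outdeg = (net.adjacency > 0).sum(axis=1)
    return pd.Series(indeg + outdeg, index=list(net.nodes), name="degree")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int
    tail: str


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
    tail: str = "upper",
) -> MantelResult:
    """Mantel permutation test between two square matrices.

    The statistic is the Pearson correlation of the off-diagonal
    entries (matrices may be directed and asymmetric). The null
    distribution permutes the rows and columns of ``m2`` simultaneously;
    p = (1 + #{permuted r at least as extreme}) / (1 + n_perm).
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ConfigurationError("mantel_test requires two square matrices of equal size")
    if n_perm < 99:
        raise ConfigurationError("n_perm must be at least 99")
    if tail not in ("upper", "lower", "two-sided"):
        raise ConfigurationError(f"unknown tail {tail!r}")
    n = m1.shape[0]
    off = ~np.eye(n, dtype=bool)
    x, y = m1[off], m2[off]
    if x.std() == 0 or y.std() == 0:
        raise ConfigurationError("mantel_test undefined for a zero-variance matrix")
    r_obs = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = m2[np.ix_(perm, perm)][off]
        r = np.corrcoef(x, yp)[0, 1]
        if tail == "upper":
            hits += r >= r_obs
        elif tail == "lower":
            hits += r <= r_obs
        else:
            hits += abs(r) >= abs(r_obs)
    p = (1 + hits) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=float(p), n_permutations=n_perm, seed=seed, tail=tail)


def compare_mobility(
    net_a: MovementNetwork,
    net_b: MovementNetwork,
    include_all_stations: bool = False,
) -> _stats.TestResult:
    """Mann-Whitney comparison of node-degree vectors of two networks.

    By default only stations with a positive degree in at least one
    network enter the comparison; otherwise the shared zeros of unused
    stations dominate the ranks. Set ``include_all_stations`` to keep
    every node.
    """
    if net_a.nodes != net_b.nodes:
        raise ConfigurationError("networks must share the same station universe")
    da, db = node_degrees(net_a), node_degrees(net_b)
    if not include_all_stations:
        keep = (da > 0) | (db > 0)
        da, db = da[keep], db[keep]
    if len(da) == 0:
        raise ConfigurationError("no station has any movement in either network")
    return _stats.mann_whitney_u(da.to_numpy(), db.to_numpy())


def export_network(
    net: MovementNetwork,
    out_prefix: str | Path,
    stations: Optional[pd.DataFrame] = None,
) -> tuple[Path, Path]:
    """Write an edge-list CSV and a GraphML file.

    GraphML nodes carry the island (when a station table is given) and
    the node degree as attributes. Returns the two paths written.
    """
    out_prefix = Path(out_prefix)
    edge_path = out_prefix.with_suffix(".edges.csv")
    graphml_path = out_prefix.with_suffix(".graphml")
    net.edges().to_csv(edge_path, index=False)

    g = nx.DiGraph()
    deg = node_degrees(net)
    islands = (
        stations.set_index("station_id")["island"] if stations is not None else None
    )
    for s in net.nodes:
        attrs = {"degree": int(deg[s])}
        if islands is not None and s in islands.index:
            attrs["island"] = str(islands[s])
        g.add_node(s, **attrs)
    for _, row in net.edges().iterrows():
        g.add_edge(row["from"], row["to"], weight=int(row["weight"]))
    nx.write_graphml(g, graphml_path)
    return edge_path, graphml_path


def read_network_graphml(path: str | Path, label: str = "") -> MovementNetwork:
    """Round-trip loader for :func:`export_network` GraphML output."""
    g = nx.read_graphml(path)
    nodes = tuple(sorted(g.nodes))
    index = {s: i for i, s in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), dtype=int)
    for a, b, data in g.edges(data=True):
        adj[index[a], index[b]] = int(data.get("weight", 1))
    return MovementNetwork(nodes=nodes, adjacency=adj, label=label)
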