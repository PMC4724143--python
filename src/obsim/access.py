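"""Drive-time computation over the road network and three-band access
classification.

Edge travel time is ``length_km / speed_kmh * 60`` minutes; shortest paths
are exact (Dijkstra on a sparse node-node matrix).  Grid cells and hospitals
snap to the Euclidean-nearest network node with no off-network penalty, ties
broken by ascending node id.  A cell's access class against a retained
facility set is ``LE30`` (<= 30 min, boundary inclusive), ``GT30_LE60``
(30 < t <= 60) or ``GT60`` (> 60 min or unreachable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree

from .errors import DataError

if TYPE_CHECKING:  # pragma: no cover
    from .scenarios import RetainedSet
    from .synthgeo import Geography

__all__ = [
    "RoadNetwork",
    "AccessMatrix",
    "AccessClass",
    "snap",
    "travel_time_matrix",
    "classify_access",
    "write_access_classes",
    "LE30", "GT30_LE60", "GT60",
    "THRESHOLD_NEAR_MIN", "THRESHOLD_FAR_MIN",
]

LE30 = "LE30"
GT30_LE60 = "GT30_LE60"
GT60 = "GT60"

THRESHOLD_NEAR_MIN = 30.0
THRESHOLD_FAR_MIN = 60.0

SPEED_MIN_KMH = 10.0
SPEED_MAX_KMH = 80.0


class RoadNetwork:
    """Undirected road graph with per-edge speeds.

    ``nodes``: DataFrame ``id, x_km, y_km``; ``edges``: DataFrame
    ``node_u, node_v, length_km, speed_kmh``.  Nodes are kept sorted by id,
    which makes positional order and id order coincide (the snap tie rule
    relies on this).
    """

    def __init__(self, nodes: pd.DataFrame, edges: pd.DataFrame):
        nodes = nodes.sort_values("id", kind="stable").reset_index(drop=True)
        edges = edges.reset_index(drop=True)
        if nodes["id"].duplicated().any():
            raise DataError("duplicate node ids")
        if (edges["node_u"] == edges["node_v"]).any():
            raise DataError("self-loop edge in road network")
        if (edges["length_km"] <= 0).any():
            raise DataError("edge length_km must be > 0")
        bad_speed = ~edges["speed_kmh"].between(SPEED_MIN_KMH, SPEED_MAX_KMH)
        if bad_speed.any():
            raise DataError(
                f"edge speed outside [{SPEED_MIN_KMH}, {SPEED_MAX_KMH}] km/h")
        self.nodes = nodes
        self.edges = edges
        self._index = pd.Series(np.arange(len(nodes)), index=nodes["id"])
        ui = self._index.loc[edges["node_u"]].to_numpy()
        vi = self._index.loc[edges["node_v"]].to_numpy()
        minutes = (edges["length_km"] / edges["speed_kmh"] * 60.0).to_numpy()
        # parallel edges collapse to the fastest one
        frame = pd.DataFrame({"u": np.minimum(ui, vi),
                              "v": np.maximum(ui, vi),
                              "m": minutes})
        frame = frame.groupby(["u", "v"], as_index=False)["m"].min()
        n = len(nodes)
        self._graph = coo_matrix(
            (frame["m"].to_numpy(dtype=float),
             (frame["u"].to_numpy(dtype=np.int64),
              frame["v"].to_numpy(dtype=np.int64))),
            shape=(n, n)).tocsr()
        self._tree = cKDTree(nodes[["x_km", "y_km"]].to_numpy(dtype=float)
                             .reshape(-1, 2))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_minutes(self) -> np.ndarray:
        return (self.edges["length_km"] / self.edges["speed_kmh"] * 60.0).to_numpy()

    # -- snapping -----------------------------------------------------------
    def snap_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Node ids of the Euclidean-nearest node per point; exact ties go to
        the smallest node id."""
        if self.n_nodes == 0:
            raise DataError("cannot snap to an empty network")
        pts = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
        k = min(2, self.n_nodes)
        dist, pos = self._tree.query(pts, k=k)
        if k == 1:
            nearest = np.atleast_1d(pos)
        else:
            nearest = pos[:, 0].copy()
            tol = 1e-9
            tied = dist[:, 1] - dist[:, 0] <= tol * (1.0 + dist[:, 0])
            for i in np.flatnonzero(tied):
                ball = self._tree.query_ball_point(
                    pts[i], dist[i, 0] + tol * (1.0 + dist[i, 0]))
                nearest[i] = min(ball)  # positional == id order
        return self.nodes["id"].to_numpy()[nearest]

    def node_positions(self, node_ids: Sequence) -> np.ndarray:
        return self._index.loc[list(node_ids)].to_numpy()

    # -- shortest paths -----------------------------------------------------
    def minutes_from_nodes(self, node_ids: Sequence) -> np.ndarray:
        """Shortest-path minutes from each source node to every node;
        shape (len(node_ids), n_nodes), ``inf`` where unreachable."""
        if len(node_ids) == 0:
            return np.empty((0, self.n_nodes))
        idx = self.node_positions(node_ids)
        return dijkstra(self._graph, directed=False, indices=idx)

    def connected_fraction(self, node_ids: Sequence) -> float:
        """Fraction of the given nodes lying in the largest component."""
        _, labels = connected_components(self._graph, directed=False)
        sub = labels[self.node_positions(node_ids)]
        if len(sub) == 0:
            return 1.0
        counts = np.bincount(sub)
        return counts.max() / len(sub)


def snap(x: float, y: float, network: RoadNetwork):
    """Nearest network node id for a single planar point."""
    return network.snap_many(np.array([x]), np.array([y]))[0]


@dataclass
class AccessMatrix:
    """Exact cell x hospital drive-time matrix (minutes; ``inf`` means no
    path) plus the snap assignments it was computed from."""

    minutes: np.ndarray
    cell_ids: np.ndarray
    hospital_ids: np.ndarray
    cell_nodes: np.ndarray
    hospital_nodes: np.ndarray

    def __post_init__(self):
        self._hosp_col = {h: j for j, h in enumerate(self.hospital_ids)}

    def columns_for(self, hospital_ids: Iterable) -> np.ndarray:
        try:
            return np.array([self._hosp_col[h] for h in hospital_ids], dtype=int)
        except KeyError as exc:
            raise DataError(f"unknown hospital id {exc.args[0]!r}") from exc

    def min_minutes(self, hospital_ids: Iterable) -> np.ndarray:
        """Per-cell time to the nearest of the given hospitals (``inf`` when
        the set is empty or nothing is reachable)."""
        cols = self.columns_for(hospital_ids)
        if len(cols) == 0:
            return np.full(len(self.cell_ids), np.inf)
        return self.minutes[:, cols].min(axis=1)


def travel_time_matrix(geo: "Geography") -> AccessMatrix:
    """Drive-time matrix between every grid cell and every hospital.

    One Dijkstra sweep per distinct hospital node; exact shortest-path
    minutes, no off-network penalty on either snap leg.
    """
    net = geo.network
    cell_nodes = net.snap_many(geo.cells["x_km"].to_numpy(),
                               geo.cells["y_km"].to_numpy())
    if len(geo.hospitals):
        hosp_nodes = net.snap_many(geo.hospitals["x_km"].to_numpy(),
                                   geo.hospitals["y_km"].to_numpy())
    else:
        hosp_nodes = np.array([], dtype=cell_nodes.dtype)

    unique_nodes, inverse = np.unique(hosp_nodes, return_inverse=True)
    node_minutes = net.minutes_from_nodes(unique_nodes)  # (uniq, n_nodes)
    cell_pos = net.node_positions(cell_nodes)
    if len(unique_nodes):
        minutes = node_minutes[:, cell_pos][inverse].T  # (cells, hospitals)
    else:
        minutes = np.empty((len(geo.cells), 0))
    return AccessMatrix(
        minutes=minutes,
        cell_ids=geo.cells["id"].to_numpy(),
        hospital_ids=geo.hospitals["id"].to_numpy(),
        cell_nodes=cell_nodes,
        hospital_nodes=hosp_nodes,
    )


@dataclass
class AccessClass:
    """Per-cell access band given a retained facility set."""

    cell_ids: np.ndarray
    min_minutes: np.ndarray
    labels: np.ndarray  # one of LE30 / GT30_LE60 / GT60 per cell

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids,
                             "min_minutes": self.min_minutes,
                             "class": self.labels})


def classify_access(matrix: AccessMatrix,
                    retained: "RetainedSet | Iterable",
                    near_min: float = THRESHOLD_NEAR_MIN,
                    far_min: float = THRESHOLD_FAR_MIN) -> AccessClass:
    """Classify every cell against the retained hospitals.

    Both band boundaries are inclusive on the near side: t == 30.0 is LE30,
    t == 60.0 is GT30_LE60.  Unreachable cells and an empty retained set
    yield GT60.
    """
    ids = getattr(retained, "hospital_ids", retained)
    t = matrix.min_minutes(list(ids))
    labels = np.where(t <= near_min, LE30,
                      np.where(t <= far_min, GT30_LE60, GT60)).astype(object)
    return AccessClass(cell_ids=matrix.cell_ids, min_minutes=t, labels=labels)


def write_access_classes(access: AccessClass, path: str | Path) -> Path:
    """Tabular analogue of the access maps: cell_id, min_minutes, class."""
    path = Path(path)
    access.to_frame().to_csv(path, index=False)
    return path
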