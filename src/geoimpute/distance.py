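"""Shortest road-network travel distance to the nearest facility.

Origins (zone or block centroids) and facilities are snapped to their
single nearest network node by a straight-line leg; the reported distance
is snap leg + shortest path + snap leg, minimised over facilities.  An
origin that coincides exactly with a facility location has distance zero.
A euclidean fallback (straight-line distance, flagged ``method=euclidean``)
is opt-in for disconnected inputs or network-free runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial import cKDTree

from .errors import EmptyInputError, NoDestinationError, UnreachableError
from .geography import StudyArea

_FACILITY_PREFIX = "__facility__"


def _node_arrays(network: nx.Graph):
    nodes = list(network.nodes)
    xy = np.array([[network.nodes[n]["x"], network.nodes[n]["y"]] for n in nodes])
    return nodes, xy


def _snap(points: np.ndarray, node_xy: np.ndarray):
    """Nearest network node index and straight-line leg length per point."""
    tree = cKDTree(node_xy)
    legs, idx = tree.query(np.atleast_2d(points))
    return idx, legs


def shortest_network_distance(
    origin: tuple[float, float],
    facilities: pd.DataFrame,
    network: nx.Graph | None,
    euclidean_fallback: bool = False,
) -> tuple[float, str]:
    """Distance (m) from one origin to its nearest facility.

    Returns ``(distance_m, method)`` with method in {network, euclidean}.
    Ties between equidistant facilities resolve to the smallest facility_id
    (the min is over distance only, so ties are value-identical).
    """
    if facilities is None or len(facilities) == 0:
        raise NoDestinationError("no facility supplied")
    fac = facilities.sort_values("facility_id")
    fxy = fac[["x", "y"]].to_numpy(dtype=float)
    origin = np.asarray(origin, dtype=float)
    straight = np.hypot(*(fxy - origin).T)
    if straight.min() == 0.0:
        return 0.0, "network" if network is not None else "euclidean"
    if network is None:
        if not euclidean_fallback:
            raise UnreachableError("no network supplied and euclidean fallback disabled")
        return float(straight.min()), "euclidean"

    nodes, node_xy = _node_arrays(network)
    (o_idx,), (o_leg,) = _snap(origin[None, :], node_xy)
    f_idx, f_legs = _snap(fxy, node_xy)
    lengths = nx.single_source_dijkstra_path_length(network, nodes[o_idx], weight="length_m")
    best = np.inf
    for k in range(len(fac)):
        node = nodes[f_idx[k]]
        if node in lengths:
            best = min(best, o_leg + lengths[node] + f_legs[k])
    if np.isinf(best):
        if euclidean_fallback:
            return float(straight.min()), "euclidean"
        raise UnreachableError("origin disconnected from all facilities")
    return float(best), "network"


def _multi_source_facility_distances(network: nx.Graph, facilities: pd.DataFrame) -> dict:
    """Distance from every network node to its nearest facility.

    Facilities are attached as pseudo-nodes via their snap legs so one
    multi-source Dijkstra covers all destinations.
    """
    nodes, node_xy = _node_arrays(network)
    f_idx, f_legs = _snap(facilities[["x", "y"]].to_numpy(dtype=float), node_xy)
    aug = network.copy()
    sources = []
    for k, fid in enumerate(facilities["facility_id"]):
        pseudo = f"{_FACILITY_PREFIX}{fid}"
        aug.add_edge(pseudo, nodes[f_idx[k]], length_m=float(f_legs[k]))
        sources.append(pseudo)
    return nx.multi_source_dijkstra_path_length(aug, sources, weight="length_m")


def nearest_facility_distances(
    study_area: StudyArea,
    level: str,
    euclidean_fallback: bool = False,
) -> pd.DataFrame:
    """Distance to the nearest facility for every zone or block.

    Zones measure from their population-weighted centroids, blocks from
    their geometric centroids.  Output columns: unit_id, level,
    distance_m, method.
    """
    if level not in ("zone", "block"):
        raise ValueError(f"level must be 'zone' or 'block', got {level!r}")
    if len(study_area.facilities) == 0:
        raise NoDestinationError("study area has no facilities")
    units = study_area.zones if level == "zone" else study_area.blocks
    id_col = "zone_id" if level == "zone" else "block_id"
    pts = units[["x", "y"]].to_numpy(dtype=float)

    fac = study_area.facilities.sort_values("facility_id")
    fxy = fac[["x", "y"]].to_numpy(dtype=float)
    straight_min = cKDTree(fxy).query(pts)[0]

    if study_area.network is None:
        if not euclidean_fallback:
            raise UnreachableError("no network supplied and euclidean fallback disabled")
        return pd.DataFrame({
            "unit_id": units[id_col], "level": level,
            "distance_m": straight_min, "method": "euclidean",
        })

    node_dist = _multi_source_facility_distances(study_area.network, fac)
    nodes, node_xy = _node_arrays(study_area.network)
    snap_idx, snap_legs = _snap(pts, node_xy)

    dist = np.empty(len(units))
    method = np.full(len(units), "network", dtype=object)
    for i in range(len(units)):
        if straight_min[i] == 0.0:
            dist[i] = 0.0
            continue
        node = nodes[snap_idx[i]]
        d = node_dist.get(node)
        if d is None:
            if not euclidean_fallback:
                raise UnreachableError(
                    f"{level} {units[id_col].iloc[i]!r} unreachable from all facilities"
                )
            dist[i], method[i] = straight_min[i], "euclidean"
        else:
            dist[i] = snap_legs[i] + d
    return pd.DataFrame({
        "unit_id": units[id_col].to_numpy(), "level": level,
        "distance_m": dist, "method": method,
    })


def distance_summary(results: pd.DataFrame | np.ndarray) -> dict:
    """Min / max / mean / median of distances, reported in kilometers.

    Median of an even-count sample is the midpoint of the two central
    order statistics.
    """
    if isinstance(results, pd.DataFrame):
        values = results["distance_m"].to_numpy(dtype=float)
    else:
        values = np.asarray(results, dtype=float)
    if values.size == 0:
        raise EmptyInputError("no distance results to summarise")
    km = values / 1000.0
    return {
        "min": float(km.min()),
        "max": float(km.max()),
        "mean": float(km.mean()),
        "median": float(np.median(km)),
    }
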