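"""CSV / GeoJSON readers and writers for the pipeline's table dialects.

All tables are plain CSV.  Coordinates must be planar (projected CRS) in
meters.  Optional polygon layers are GeoJSON read with shapely; blocks may
alternatively carry precomputed centroids (the x/y columns), which is the
primary path.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import shape

from .errors import IntegrityError, SchemaError
from .geography import POP_COLUMNS, StudyArea, geometric_centroid

BLOCK_COLUMNS = ("block_id", "zone_id", "x", "y") + POP_COLUMNS
CASE_COLUMNS = ("case_id", "zone_id", "age", "race", "sex", "stage", "year")
FACILITY_COLUMNS = ("facility_id", "x", "y")


def _require_columns(df: pd.DataFrame, required, name: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing required columns {missing}")


def read_blocks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, BLOCK_COLUMNS, "blocks.csv")
    pops = df[list(POP_COLUMNS)]
    bad = pops.lt(0).any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()[:5]  # 1-based incl. header
        raise SchemaError(f"blocks.csv: negative population counts at rows {rows}")
    if df["block_id"].duplicated().any():
        dup = df.loc[df["block_id"].duplicated(), "block_id"].iloc[0]
        raise SchemaError(f"blocks.csv: duplicate block_id {dup!r}")
    return df


def read_cases(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stage": object})
    _require_columns(df, CASE_COLUMNS, "cases.csv")
    return df


def read_facilities(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FACILITY_COLUMNS, "facilities.csv")
    if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
        raise SchemaError("facilities.csv: non-finite coordinates")
    return df


def read_network(edges_path, nodes_path) -> nx.Graph:
    edges = pd.read_csv(edges_path)
    nodes = pd.read_csv(nodes_path)
    _require_columns(edges, ("node_a", "node_b", "length_m"), "network.csv")
    _require_columns(nodes, ("node_id", "x", "y"), "nodes.csv")
    if (edges["length_m"] <= 0).any():
        raise SchemaError("network.csv: non-positive edge length")
    g = nx.Graph()
    for _, row in nodes.iterrows():
        g.add_node(row["node_id"], x=float(row["x"]), y=float(row["y"]))
    known = set(g.nodes)
    for i, row in edges.iterrows():
        if row["node_a"] not in known or row["node_b"] not in known:
            raise IntegrityError(f"network.csv row {i + 2}: edge references unknown node")
        g.add_edge(row["node_a"], row["node_b"], length_m=float(row["length_m"]))
    return g


def read_polygon_centroids(geojson_path, id_property: str) -> dict:
    """Geometric centroids of a GeoJSON polygon layer, keyed by feature id."""
    with open(geojson_path) as fh:
        collection = json.load(fh)
    out = {}
    for feat in collection.get("features", []):
        geom = shape(feat["geometry"])
        out[feat["properties"][id_property]] = geometric_centroid(geom)
    return out


def read_tables(paths: dict) -> tuple[StudyArea, pd.DataFrame]:
    """Load and cross-validate a study area plus its case table.

    ``paths`` keys: blocks, cases, facilities, and optionally network
    (edge list) + nodes, and blocks_geojson (polygons supplying centroids
    when x/y are absent).
    """
    blocks = read_blocks(paths["blocks"])
    cases = read_cases(paths["cases"])
    facilities = read_facilities(paths["facilities"])
    network = None
    if paths.get("network") and paths.get("nodes"):
        network = read_network(paths["network"], paths["nodes"])

    zones = set(blocks["zone_id"])
    dangling = cases.loc[~cases["zone_id"].isin(zones), "zone_id"]
    if len(dangling):
        raise IntegrityError(
            f"cases.csv: zone_id {dangling.iloc[0]!r} not present in blocks table"
        )
    area = StudyArea(blocks=blocks, facilities=facilities, network=network)
    return area, cases


def write_assignments(matrix, out_csv, out_meta=None):
    matrix.to_long().to_csv(out_csv, index=False)
    if out_meta:
        meta = {"master_seed": matrix.master_seed, **matrix.metadata}
        Path(out_meta).write_text(json.dumps(meta, indent=2, default=str))


def read_fit(path):
    """Rebuild a :class:`geoimpute.glmm.FitResult` from its CSV layout."""
    from .glmm import FitResult

    df = pd.read_csv(path).set_index("variable")
    terms = tuple(df.index)
    return FitResult(
        params=df["coefficient"].to_dict(),
        se=df["std_error"].to_dict(),
        p_values=df["p_value"].to_dict(),
        conf_int={t: (df.loc[t, "ci_low"], df.loc[t, "ci_high"]) for t in terms},
        tau2=float(df["tau2"].iloc[0]),
        loglik=float(df["loglik"].iloc[0]),
        converged=bool(df["converged"].iloc[0]),
        terms=terms,
    )


def write_fit(fit, path):
    """Fit output CSV in the coefficient-table layout plus fit metadata."""
    df = fit.to_frame()
    df["tau2"] = fit.tau2
    df["loglik"] = fit.loglik
    df["converged"] = fit.converged
    df.to_csv(path, index=False)


def write_study(study, out_dir) -> dict:
    """Emit a synthetic study in the exact CSV dialects consumed upstream."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.csv" for k in
             ("blocks", "cases", "facilities", "network", "nodes", "truth")}
    study.study_area.blocks.to_csv(paths["blocks"], index=False)
    study.cases.to_csv(paths["cases"], index=False)
    study.study_area.facilities.to_csv(paths["facilities"], index=False)
    g = study.study_area.network
    pd.DataFrame(
        [{"node_a": a, "node_b": b, "length_m": d["length_m"]}
         for a, b, d in g.edges(data=True)]
    ).to_csv(paths["network"], index=False)
    pd.DataFrame(
        [{"node_id": n, "x": d["x"], "y": d["y"]} for n, d in g.nodes(data=True)]
    ).to_csv(paths["nodes"], index=False)
    study.truth.to_csv(paths["truth"], index=False)
    return {k: str(v) for k, v in paths.items()}
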