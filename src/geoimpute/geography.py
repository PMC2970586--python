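"""Study-area data model: blocks, zones, demographic subgroups, case filtering.

The finest spatial unit is the census block, carrying six female population
counts (two race categories x three age bands).  Blocks nest in zones (zip
codes).  All coordinates are planar, in meters (a projected CRS); no
geographic-coordinate math is done anywhere in the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import DegenerateGeometryError, InvalidCategoryError, InvalidStageError

logger = logging.getLogger(__name__)

AGE_BANDS = ("lt50", "50to69", "ge70")
RACES = ("nonblack", "black")

#: Canonical order of the six demographic subgroups.
SUBGROUPS: tuple["SubgroupKey", ...]

#: blocks.csv population column for each subgroup, in canonical order.
POP_COLUMNS = (
    "pop_nb_lt50",
    "pop_nb_50to69",
    "pop_nb_ge70",
    "pop_b_lt50",
    "pop_b_50to69",
    "pop_b_ge70",
)

#: Default labels (lower-cased) mapped to the "black" race category.
DEFAULT_BLACK_LABELS = frozenset({"black", "b", "african american", "african-american"})

#: Sentinels accepted as "stage unknown" in case tables.
UNKNOWN_STAGE_SENTINELS = {None, "", "u", "unknown", "nan"}


class SubgroupKey(NamedTuple):
    """One of the six age-race demographic subgroups."""

    race: str
    age_band: str

    @property
    def pop_column(self) -> str:
        prefix = "pop_b" if self.race == "black" else "pop_nb"
        return f"{prefix}_{self.age_band}"


SUBGROUPS = tuple(SubgroupKey(race, band) for race in RACES for band in AGE_BANDS)


def classify_stage(stage_code) -> str:
    """Classify a summary-stage code as ``early``, ``late`` or ``unstaged``.

    Stages 0-1 are early; 2-7 are late; the unknown sentinel (None, empty
    string, "U", or NaN) is unstaged.  Any other value raises
    :class:`InvalidStageError`.
    """
    if stage_code is None:
        return "unstaged"
    if isinstance(stage_code, float) and np.isnan(stage_code):
        return "unstaged"
    if isinstance(stage_code, str):
        token = stage_code.strip().lower()
        if token in UNKNOWN_STAGE_SENTINELS:
            return "unstaged"
        try:
            stage_code = int(token)
        except ValueError:
            raise InvalidStageError(f"unrecognised stage code {stage_code!r}")
    if isinstance(stage_code, (int, np.integer)) or (
        isinstance(stage_code, float) and stage_code.is_integer()
    ):
        code = int(stage_code)
        if 0 <= code <= 1:
            return "early"
        if 2 <= code <= 7:
            return "late"
    raise InvalidStageError(f"stage code {stage_code!r} outside 0-7 / unknown")


def age_band_of(age_years: int) -> str:
    """Age band: [0, 50) -> lt50, [50, 70) -> 50to69, [70, inf) -> ge70.

    Age 70 belongs to the oldest band, consistent with the regression's
    reference category (age >= 70).
    """
    if age_years < 0:
        raise InvalidCategoryError(f"negative age {age_years}")
    if age_years < 50:
        return "lt50"
    if age_years < 70:
        return "50to69"
    return "ge70"


def race_category(race, black_labels: frozenset = DEFAULT_BLACK_LABELS) -> str:
    """Map a free-text race value to {black, nonblack}.

    Any value not matching a configured black label (case-insensitive) is
    nonblack; missing values raise.
    """
    if race is None or (isinstance(race, float) and np.isnan(race)):
        raise InvalidCategoryError("missing race value")
    token = str(race).strip().lower()
    if not token:
        raise InvalidCategoryError("empty race value")
    return "black" if token in black_labels else "nonblack"


def subgroup_of(age_years: int, race, black_labels: frozenset = DEFAULT_BLACK_LABELS) -> SubgroupKey:
    """Return the age-race subgroup of a case."""
    return SubgroupKey(race_category(race, black_labels), age_band_of(age_years))


def filter_cases(
    cases: pd.DataFrame,
    years: tuple[int, int] = (1998, 2002),
    black_labels: frozenset = DEFAULT_BLACK_LABELS,
) -> tuple[pd.DataFrame, dict]:
    """Select staged female cases in the year window; tally exclusions.

    Parameters
    ----------
    cases
        Table with columns case_id, zone_id, age, race, sex, stage, year.
        ``age`` may alternatively be a pre-binned band in ``age_band``.
    years
        Inclusive diagnosis-year window.

    Returns
    -------
    staged : DataFrame
        One row per kept case with ``late`` (bool), ``race_cat`` and
        ``age_band`` columns added.
    tally : dict
        Counts of exclusions: total input, non-female, out-of-window,
        unstaged, and the staged count kept.
    """
    tally = {
        "input": len(cases),
        "not_female": 0,
        "outside_years": 0,
        "unstaged": 0,
        "staged": 0,
    }
    if cases.empty:
        empty = cases.copy()
        for col in ("late", "race_cat", "age_band"):
            empty[col] = pd.Series(dtype=object)
        return empty, tally

    df = cases.copy()
    is_female = df["sex"].astype(str).str.strip().str.lower().isin({"f", "female", "2"})
    tally["not_female"] = int((~is_female).sum())
    df = df[is_female]

    in_window = df["year"].astype(int).between(years[0], years[1])
    tally["outside_years"] = int((~in_window).sum())
    df = df[in_window]

    stage_class = df["stage"].map(classify_stage)
    tally["unstaged"] = int((stage_class == "unstaged").sum())
    df = df[stage_class != "unstaged"].copy()
    df["late"] = stage_class[stage_class != "unstaged"] == "late"

    if "age_band" in df.columns and df["age_band"].notna().all():
        df["age_band"] = df["age_band"].astype(str)
    else:
        df["age_band"] = df["age"].astype(int).map(age_band_of)
    df["race_cat"] = df["race"].map(lambda r: race_category(r, black_labels))
    tally["staged"] = len(df)
    return df.reset_index(drop=True), tally


def geometric_centroid(polygon) -> tuple[float, float]:
    """Area centroid of a simple polygon (signed-area formula).

    Accepts a shapely Polygon or a vertex sequence.  A point-like input
    (single coordinate pair) is returned unchanged.
    """
    if isinstance(polygon, (tuple, list)) and len(polygon) == 2 and np.isscalar(polygon[0]):
        return (float(polygon[0]), float(polygon[1]))
    if not isinstance(polygon, Polygon):
        polygon = Polygon(polygon)
    if polygon.area == 0 or not polygon.is_valid:
        raise DegenerateGeometryError("zero-area or invalid polygon")
    c = polygon.centroid
    return (c.x, c.y)


def population_weighted_centroid(
    block_points: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Coordinate-wise weighted mean of block centroids.

    ``weights`` are total female populations per block.  A zone whose total
    population is zero falls back to the unweighted mean, with a warning.
    """
    pts = np.asarray(block_points, dtype=float)
    w = np.asarray(weights, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise DegenerateGeometryError("zone has no member blocks")
    total = w.sum()
    if total <= 0:
        logger.warning("zone has zero total population; using unweighted centroid")
        w = np.ones(len(pts))
        total = float(len(pts))
    x, y = (pts * w[:, None]).sum(axis=0) / total
    return (float(x), float(y))


@dataclass
class StudyArea:
    """In-memory study area: blocks, derived zones, facilities, road network.

    ``blocks`` must carry block_id, zone_id, x, y and the six population
    columns; ``zones`` is derived (population-weighted centroids) unless
    supplied.  The road network is an undirected networkx graph whose nodes
    carry planar ``x``/``y`` attributes and whose edges carry ``length_m``.
    """

    blocks: pd.DataFrame
    facilities: pd.DataFrame
    network: nx.Graph | None = None
    zones: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        missing = [c for c in ("block_id", "zone_id", "x", "y") + POP_COLUMNS
                   if c not in self.blocks.columns]
        if missing:
            raise ValueError(f"blocks table missing columns: {missing}")
        if (self.blocks[list(POP_COLUMNS)] < 0).any().any():
            raise ValueError("negative population count in blocks table")
        if self.zones is None:
            self.zones = derive_zones(self.blocks)

    @property
    def block_total_pop(self) -> pd.Series:
        return self.blocks[list(POP_COLUMNS)].sum(axis=1)


def derive_zones(blocks: pd.DataFrame) -> pd.DataFrame:
    """Zone table (zone_id, x, y) with population-weighted centroids."""
    rows = []
    for zone_id, grp in blocks.groupby("zone_id", sort=True):
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        w = grp[list(POP_COLUMNS)].sum(axis=1).to_numpy(dtype=float)
        x, y = population_weighted_centroid(pts, w)
        rows.append({"zone_id": zone_id, "x": x, "y": y,
                     "block_ids": list(grp["block_id"])})
    return pd.DataFrame(rows)


def subgroup_counts(staged: pd.DataFrame) -> pd.Series:
    """Staged-case counts per subgroup (canonical order), conserving totals."""
    keys = [SubgroupKey(r, a) for r, a in zip(staged["race_cat"], staged["age_band"])]
    counts = pd.Series(keys).value_counts()
    return pd.Series({sg: int(counts.get(sg, 0)) for sg in SUBGROUPS})
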