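"""Synthetic study areas and case data with known ground truth.

Registry case data below the zone (zip code) level is confidential, so the
whole pipeline is exercised on generated geographies that reproduce the
statistical structure the analysis assumes: a square grid of blocks nested
in rectangular zones, a monocentric density gradient, a two-component
segregation mechanism concentrating the black population into a contiguous
cluster of blocks, zone-varying age structure, dispersed or clustered
facilities on a grid road network, and cases drawn from a known
block-level logistic risk model (age, race and distance effects plus a
block-level random intercept).

Two presets bracket the geographic regimes of interest: ``kane_like``
(uniform density, dispersed facilities, moderate segregation) and
``peoria_like`` (strong monocentric gradient, clustered facilities, high
segregation) — the settings under which aggregation error is expected to
be mild vs severe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .geography import AGE_BANDS, POP_COLUMNS, StudyArea, derive_zones
from .distance import nearest_facility_distances
from scipy.special import expit


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions.

    The grid has ``blocks_x * blocks_y`` blocks grouped into rectangular
    zones of ``zone_nx * zone_ny`` blocks.  ``density_gradient`` = 0 gives
    uniform block totals; > 0 gives monocentric exponential decay.
    ``segregation`` in [0, 1] is the fraction of the black population
    allocated to a contiguous central cluster of ``concentration_fraction``
    of blocks (0 = proportional mixing everywhere).  True model
    coefficients are on the logit scale; distance enters per meter.
    """

    blocks_x: int = 12
    blocks_y: int = 12
    zone_nx: int = 3
    zone_ny: int = 3
    spacing_m: float = 2000.0
    mean_block_pop: float = 120.0
    density_gradient: float = 0.0
    black_share: float = 0.06
    segregation: float = 0.5
    concentration_fraction: float = 0.2
    elderly_share_range: tuple = (0.30, 0.36)
    lt50_ratio: float = 0.375          # lt50 share of the non-elderly remainder
    n_facilities: int = 8
    facility_mode: str = "dispersed"
    coefficients: dict = field(default_factory=lambda: {
        "intercept": -0.75,
        "age_lt50": 0.536,
        "age_50to70": 0.326,
        "black": 0.396,
        "distance_m": 5.27e-6,
    })
    tau2: float = 0.1
    expected_cases: int = 1102
    unstaged_fraction: float = 0.059
    years: tuple = (1998, 2002)
    seed: int = 0

    def validate(self):
        if self.blocks_x < 1 or self.blocks_y < 1:
            raise ConfigError("grid dimensions must be >= 1")
        if self.blocks_x % self.zone_nx or self.blocks_y % self.zone_ny:
            raise ConfigError("zone shape must tile the block grid exactly")
        if not 0.0 <= self.segregation <= 1.0:
            raise ConfigError("segregation must lie in [0, 1]")
        if self.n_facilities > self.blocks_x * self.blocks_y:
            raise ConfigError("more facilities than blocks")
        if self.expected_cases <= 0:
            raise ConfigError("expected case count must be positive")
        if self.facility_mode not in ("dispersed", "clustered"):
            raise ConfigError(f"unknown facility mode {self.facility_mode!r}")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to weights, exact sum."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = w / w.sum() * total
    base = np.floor(quota).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def generate_geography(config: SyntheticConfig, rng: np.random.Generator | None = None) -> StudyArea:
    """Grid blocks, zones, facilities and road network with block totals.

    Subgroup counts are provisionally all-nonblack with the base age split;
    :func:`generate_population` replaces them with the full demographic
    structure.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed))
    nx_, ny_ = config.blocks_x, config.blocks_y
    ii, jj = np.meshgrid(np.arange(nx_), np.arange(ny_), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    x = (ii + 0.5) * config.spacing_m
    y = (jj + 0.5) * config.spacing_m
    cx, cy = nx_ * config.spacing_m / 2, ny_ * config.spacing_m / 2
    r = np.hypot(x - cx, y - cy)
    w = np.exp(-config.density_gradient * r / max(r.max(), 1.0))
    totals = _largest_remainder(w, int(round(config.mean_block_pop * nx_ * ny_)))

    blocks = pd.DataFrame({
        "block_id": [f"B{k:04d}" for k in range(nx_ * ny_)],
        "zone_id": [f"Z{zi:02d}{zj:02d}" for zi, zj in
                    zip(ii // config.zone_nx, jj // config.zone_ny)],
        "x": x, "y": y,
    })
    base_age = _base_age_shares(config, 0.5 * sum(config.elderly_share_range))
    for col, share in zip(("pop_nb_lt50", "pop_nb_50to69", "pop_nb_ge70"), base_age):
        blocks[col] = np.round(totals * share).astype(int)
    blocks["pop_nb_ge70"] += totals - blocks[
        ["pop_nb_lt50", "pop_nb_50to69", "pop_nb_ge70"]].sum(axis=1)
    for col in ("pop_b_lt50", "pop_b_50to69", "pop_b_ge70"):
        blocks[col] = 0

    facilities = _place_facilities(config, blocks, totals, rng)
    network = _grid_network(config, blocks)
    return StudyArea(blocks=blocks, facilities=facilities, network=network)


def _base_age_shares(config: SyntheticConfig, elderly: float) -> tuple:
    rest = 1.0 - elderly
    return (config.lt50_ratio * rest, (1 - config.lt50_ratio) * rest, elderly)


def _place_facilities(config, blocks, totals, rng) -> pd.DataFrame:
    if config.facility_mode == "clustered":
        zone_pop = pd.Series(totals).groupby(blocks["zone_id"]).sum()
        dense_zone = zone_pop.idxmax()
        candidates = np.flatnonzero((blocks["zone_id"] == dense_zone).to_numpy())
    else:
        candidates = np.flatnonzero(totals >= np.median(totals))
    if len(candidates) < config.n_facilities:
        candidates = np.arange(len(blocks))
    chosen = rng.choice(candidates, size=config.n_facilities, replace=False)
    chosen = np.sort(chosen)
    return pd.DataFrame({
        "facility_id": [f"F{k:02d}" for k in range(config.n_facilities)],
        "x": blocks["x"].to_numpy()[chosen],
        "y": blocks["y"].to_numpy()[chosen],
    })


def _grid_network(config, blocks) -> nx.Graph:
    """4-neighbour lattice over block centroids; edge length = spacing."""
    g = nx.Graph()
    nx_, ny_ = config.blocks_x, config.blocks_y
    for k, (bx, by) in enumerate(zip(blocks["x"], blocks["y"])):
        g.add_node(k, x=float(bx), y=float(by))
    for i in range(nx_):
        for j in range(ny_):
            k = i * ny_ + j
            if i + 1 < nx_:
                g.add_edge(k, (i + 1) * ny_ + j, length_m=config.spacing_m)
            if j + 1 < ny_:
                g.add_edge(k, i * ny_ + j + 1, length_m=config.spacing_m)
    return g


def generate_population(
    config: SyntheticConfig, study_area: StudyArea, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Six subgroup counts per block (conserving block totals).

    Black population: a ``segregation`` fraction goes to the contiguous
    ``concentration_fraction`` of blocks nearest the grid centre (weighted
    by block total), the rest is spread proportionally to total population.
    Age bands: the zone elderly share interpolates over zone distance from
    the centre across ``elderly_share_range``; counts are multinomial
    draws within each block and race.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    blocks = study_area.blocks.copy()
    totals = study_area.block_total_pop.to_numpy(dtype=int)
    n_blocks = len(blocks)

    cx = blocks["x"].mean()
    cy = blocks["y"].mean()
    r = np.hypot(blocks["x"] - cx, blocks["y"] - cy).to_numpy()

    # two-component mixture allocation of the black population
    n_conc = max(1, int(round(config.concentration_fraction * n_blocks)))
    conc = np.zeros(n_blocks, dtype=bool)
    conc[np.argsort(r, kind="stable")[:n_conc]] = True
    w_conc = np.where(conc, totals, 0).astype(float)
    w_all = totals.astype(float)
    s = config.segregation
    p_black = s * w_conc / max(w_conc.sum(), 1) + (1 - s) * w_all / max(w_all.sum(), 1)
    black_total = int(round(config.black_share * totals.sum()))
    black = rng.multinomial(black_total, p_black / p_black.sum())
    # cap at block totals, redistributing overflow to remaining capacity
    while (black > totals).any():
        excess = int((black - totals).clip(min=0).sum())
        black = np.minimum(black, totals)
        cap = (totals - black).astype(float)
        if cap.sum() <= 0:
            break
        black += rng.multinomial(excess, cap / cap.sum())
    nonblack = totals - black

    zone_r = pd.Series(r).groupby(blocks["zone_id"]).mean()
    lo, hi = config.elderly_share_range
    span = max(zone_r.max() - zone_r.min(), 1e-12)
    zone_elderly = lo + (hi - lo) * (zone_r - zone_r.min()) / span

    counts = np.zeros((n_blocks, 6), dtype=int)
    for b in range(n_blocks):
        shares = np.array(_base_age_shares(config, zone_elderly[blocks["zone_id"].iloc[b]]))
        counts[b, 0:3] = rng.multinomial(int(nonblack[b]), shares)
        counts[b, 3:6] = rng.multinomial(int(black[b]), shares)
    for c, col in enumerate(POP_COLUMNS):
        blocks[col] = counts[:, c]
    return blocks


def generate_cases(
    study_area: StudyArea,
    config: SyntheticConfig,
    block_distances: pd.Series | dict,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample cases and their outcomes from the true block-level risk model.

    Cases are distinct persons drawn without replacement across all
    block x subgroup cells proportional to population (multivariate
    hypergeometric), so no cell can yield more cases than residents.  The
    late-stage indicator follows the configured logistic model with the
    case's true block distance, subgroup dummies and a block-level random
    intercept N(0, tau2).  Released cases are labelled only with their
    zone; the truth table keeps the block, distance and late indicator.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    blocks = study_area.blocks.reset_index(drop=True)
    dist_map = dict(block_distances) if not isinstance(block_distances, dict) else block_distances

    cell_pops = blocks[list(POP_COLUMNS)].to_numpy(dtype=np.int64).ravel()
    if cell_pops.sum() <= 0:
        raise ConfigError("zero eligible population")
    n = min(config.expected_cases, int(cell_pops.sum()))
    cell_cases = rng.multivariate_hypergeometric(cell_pops, n, method="marginals")

    band_lo = {"lt50": 30, "50to69": 50, "ge70": 70}
    band_hi = {"lt50": 50, "50to69": 70, "ge70": 90}
    races = ["nonblack"] * 3 + ["black"] * 3
    bands = list(AGE_BANDS) * 2

    coef = config.coefficients
    u_block = rng.normal(0.0, np.sqrt(config.tau2), size=len(blocks))

    rows, truth_rows = [], []
    k = 0
    for cell, m in enumerate(cell_cases):
        if m == 0:
            continue
        b, sg = divmod(cell, 6)
        race, band = races[sg], bands[sg]
        d = float(dist_map[blocks["block_id"].iloc[b]])
        eta = (coef["intercept"]
               + coef["age_lt50"] * (band == "lt50")
               + coef["age_50to70"] * (band == "50to69")
               + coef["black"] * (race == "black")
               + coef["distance_m"] * d
               + u_block[b])
        late = rng.random(m) < expit(eta)
        ages = rng.integers(band_lo[band], band_hi[band], size=m)
        years = rng.integers(config.years[0], config.years[1] + 1, size=m)
        unstaged = rng.random(m) < config.unstaged_fraction
        stage_known = np.where(late, rng.integers(2, 8, size=m), rng.integers(0, 2, size=m))
        for t in range(m):
            case_id = f"C{k:05d}"
            rows.append({
                "case_id": case_id,
                "zone_id": blocks["zone_id"].iloc[b],
                "age": int(ages[t]),
                "race": race,
                "sex": "F",
                "stage": "U" if unstaged[t] else int(stage_known[t]),
                "year": int(years[t]),
            })
            truth_rows.append({
                "case_id": case_id,
                "true_block_id": blocks["block_id"].iloc[b],
                "true_distance_m": d,
                "race_cat": race,
                "age_band": band,
                "late": bool(late[t]),
            })
            k += 1
    cases = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    order = rng.permutation(len(cases))
    return (cases.iloc[order].reset_index(drop=True),
            truth.iloc[order].reset_index(drop=True))


@dataclass
class SyntheticStudy:
    """A complete generated study: area, released cases, retained truth."""

    config: SyntheticConfig
    study_area: StudyArea
    cases: pd.DataFrame
    truth: pd.DataFrame
    block_distances: pd.DataFrame
    zone_distances: pd.DataFrame


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Run the full generator: geography -> population -> distances -> cases."""
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    area = generate_geography(config, np.random.default_rng(ss[0]))
    blocks = generate_population(config, area, np.random.default_rng(ss[1]))
    area = StudyArea(blocks=blocks, facilities=area.facilities, network=area.network)
    block_dist = nearest_facility_distances(area, "block")
    zone_dist = nearest_facility_distances(area, "zone")
    dist_map = dict(zip(block_dist["unit_id"], block_dist["distance_m"]))
    cases, truth = generate_cases(area, config, dist_map, np.random.default_rng(ss[2]))
    return SyntheticStudy(config, area, cases, truth, block_dist, zone_dist)


def scenario_presets(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Deterministic kane_like / peoria_like generator configurations.

    ``kane_like``: uniform density, 8 dispersed facilities, moderate
    segregation, case scale and late-stage rate matching a ~1100-case
    county with ~39% late share.  ``peoria_like``: strong monocentric
    gradient, 3 facilities clustered in the densest zone, high
    segregation, ~800 cases with ~32% late share and an older, more
    black population.
    """
    kane = SyntheticConfig(seed=seed)
    peoria = replace(
        kane,
        density_gradient=3.0,
        black_share=0.10,
        segregation=0.9,
        elderly_share_range=(0.34, 0.46),
        lt50_ratio=0.323,
        n_facilities=3,
        facility_mode="clustered",
        coefficients={
            "intercept": -1.34,
            "age_lt50": 0.673,
            "age_50to70": 0.445,
            "black": 1.082,
            "distance_m": 1.419e-5,
        },
        expected_cases=804,
        unstaged_fraction=0.047,
        seed=seed,
    )
    return {"kane_like": kane, "peoria_like": peoria}
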