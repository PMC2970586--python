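"""Monte Carlo geo-imputation: zone -> block assignment without replacement.

Each case is assigned to a block within its own zone with probability
proportional to the block's population in the case's age-race subgroup.
Within one replicate, cases are processed sequentially in input order and
the receiving block's subgroup count is decremented by one after each
assignment (a person cannot be a case twice), so a block can never receive
more cases than its initial subgroup population; exhausted blocks drop out
of the candidate set.  Shares are rebuilt from the decremented counts
before every draw — true sampling without replacement, whose occupancy law
is multivariate hypergeometric.

Reproducibility: randomness flows from a single master seed through
``numpy.random.SeedSequence.spawn``, one independent child stream per
replicate, so the full assignment matrix is bit-identical for a given
(master_seed, R).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    CapacityExhaustedError,
    EmptySupportError,
    InvalidDrawError,
)
from .geography import POP_COLUMNS, SubgroupKey

logger = logging.getLogger(__name__)


@dataclass
class CumulativeShares:
    """Normalized cumulative population shares of one (zone, subgroup).

    ``intervals`` maps each block (in the zone's canonical block order) to a
    half-open interval [lo, hi) of [0, 1); widths are proportional to the
    block's current subgroup population and blocks with zero population
    carry empty intervals.
    """

    zone_id: object
    subgroup: SubgroupKey | None
    block_ids: list
    bounds: np.ndarray  # len(block_ids) + 1, bounds[0] == 0, bounds[-1] == 1

    @property
    def intervals(self) -> list[tuple[object, float, float]]:
        return [
            (b, float(self.bounds[i]), float(self.bounds[i + 1]))
            for i, b in enumerate(self.block_ids)
        ]


def cumulative_shares(block_ids, current_pops, zone_id=None, subgroup=None) -> CumulativeShares:
    """Build normalized cumulative shares from current subgroup populations."""
    pops = np.asarray(current_pops, dtype=float)
    if (pops < 0).any():
        raise ValueError("negative population count")
    total = pops.sum()
    if total <= 0:
        raise EmptySupportError(
            f"zone {zone_id!r} subgroup {subgroup!r} has zero population"
        )
    bounds = np.concatenate([[0.0], np.cumsum(pops) / total])
    bounds[-1] = 1.0  # exact, despite float rounding
    return CumulativeShares(zone_id, subgroup, list(block_ids), bounds)


def draw_assignment(shares: CumulativeShares, u: float):
    """Block whose half-open interval [lo, hi) contains the uniform draw."""
    if not (0.0 <= u < 1.0):
        raise InvalidDrawError(f"draw {u} outside [0, 1)")
    # side='right' skips empty (zero-width) intervals and lands on the
    # first block whose cumulative bound exceeds u.
    idx = int(np.searchsorted(shares.bounds[1:], u, side="right"))
    return shares.block_ids[idx]


class _Group:
    """Working state of one (zone, subgroup): candidate blocks and counts."""

    __slots__ = ("zone_id", "subgroup", "block_codes", "init_pops", "case_rows", "fallback")

    def __init__(self, zone_id, subgroup, block_codes, init_pops, fallback=False):
        self.zone_id = zone_id
        self.subgroup = subgroup
        self.block_codes = block_codes      # indices into the blocks table
        self.init_pops = init_pops          # float copy source
        self.case_rows: list[int] = []
        self.fallback = fallback            # zone-total weights, no decrement


@dataclass
class AssignmentMatrix:
    """n-cases x R-replicates table of imputed block assignments."""

    case_ids: np.ndarray
    block_index: np.ndarray          # block_id per block code
    codes: np.ndarray                # (n, R) int array of block codes
    master_seed: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return self.codes.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.codes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def column(self, r: int) -> np.ndarray:
        """Block ids assigned to every case in replicate ``r``."""
        return self.block_index[self.codes[:, r]]

    def to_long(self) -> pd.DataFrame:
        """Long-form table: case_id, replicate, block_id."""
        n, R = self.codes.shape
        return pd.DataFrame({
            "case_id": np.repeat(self.case_ids, R),
            "replicate": np.tile(np.arange(R), n),
            "block_id": self.block_index[self.codes.ravel()],
        })


def _build_groups(staged: pd.DataFrame, blocks: pd.DataFrame, on_empty: str):
    """Index cases and blocks into per-(zone, subgroup) working groups."""
    zone_rows = {z: grp.index.to_numpy() for z, grp in blocks.groupby("zone_id", sort=True)}
    total_pop = blocks[list(POP_COLUMNS)].sum(axis=1).to_numpy(dtype=float)

    groups: dict[tuple, _Group] = {}
    case_group = np.empty(len(staged), dtype=object)
    fallback_events = []
    for row, (zone_id, race, band) in enumerate(
        zip(staged["zone_id"], staged["race_cat"], staged["age_band"])
    ):
        if zone_id not in zone_rows:
            raise KeyError(f"case zone {zone_id!r} not present in blocks table")
        sg = SubgroupKey(race, band)
        key = (zone_id, sg)
        g = groups.get(key)
        if g is None:
            rows = zone_rows[zone_id]
            pops = blocks.loc[rows, sg.pop_column].to_numpy(dtype=float)
            if pops.sum() <= 0:
                if on_empty == "error":
                    raise EmptySupportError(
                        f"zone {zone_id!r} subgroup {sg} has zero population"
                    )
                logger.warning(
                    "zone %r subgroup %s empty; falling back to zone total population",
                    zone_id, sg,
                )
                fallback_events.append({"zone_id": zone_id, "subgroup": "_".join(sg)})
                g = _Group(zone_id, sg, rows, total_pop[rows].copy(), fallback=True)
            else:
                g = _Group(zone_id, sg, rows, pops)
            groups[key] = g
        g.case_rows.append(row)
        case_group[row] = g
    return groups, case_group, fallback_events


def _check_capacity(groups: dict):
    for (zone_id, sg), g in groups.items():
        if not g.fallback and len(g.case_rows) > g.init_pops.sum():
            raise CapacityExhaustedError(
                f"zone {zone_id!r} subgroup {sg}: {len(g.case_rows)} cases exceed "
                f"subgroup population {int(g.init_pops.sum())}"
            )


def run_replicate(
    staged: pd.DataFrame,
    blocks: pd.DataFrame,
    rng: np.random.Generator,
    with_replacement: bool = False,
    on_empty: str = "fallback",
    _prebuilt=None,
) -> np.ndarray:
    """One complete disaggregation: an array of block row codes per case.

    Cases are processed sequentially in input order; after every assignment
    the receiving block's subgroup count is decremented and shares rebuilt
    (unless ``with_replacement``).
    """
    if _prebuilt is None:
        groups, case_group, _ = _build_groups(staged, blocks, on_empty)
        _check_capacity(groups)
    else:
        groups, case_group = _prebuilt

    working = {id(g): g.init_pops.copy() for g in groups.values()}
    totals = {id(g): float(g.init_pops.sum()) for g in groups.values()}
    u = rng.random(len(case_group))
    out = np.empty(len(case_group), dtype=np.int64)
    for i in range(len(case_group)):
        g = case_group[i]
        pops = working[id(g)]
        T = totals[id(g)]
        if T <= 0:
            raise CapacityExhaustedError(
                f"zone {g.zone_id!r} subgroup {g.subgroup} exhausted"
            )
        cum = np.cumsum(pops)
        idx = int(np.searchsorted(cum, u[i] * T, side="right"))
        out[i] = g.block_codes[idx]
        if not (with_replacement or g.fallback):
            pops[idx] -= 1.0
            totals[id(g)] = T - 1.0
    return out


def disaggregate(
    staged: pd.DataFrame,
    blocks: pd.DataFrame,
    R: int,
    master_seed: int,
    with_replacement: bool = False,
    on_empty: str = "fallback",
) -> AssignmentMatrix:
    """Produce the n x R assignment matrix over R independent replicates.

    Parameters
    ----------
    staged
        Staged cases (from :func:`geoimpute.filter_cases`) with zone_id,
        race_cat and age_band columns; row order is the processing order.
    blocks
        Block table with the six subgroup population columns.
    R
        Number of Monte Carlo replicates (columns).
    master_seed
        Single source of randomness; replicate r uses the r-th spawned
        child stream.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    blocks = blocks.reset_index(drop=True)
    staged = staged.reset_index(drop=True)
    groups, case_group, fallback_events = _build_groups(staged, blocks, on_empty)
    if not with_replacement:
        _check_capacity(groups)

    codes = np.empty((len(staged), R), dtype=np.int64)
    children = np.random.SeedSequence(master_seed).spawn(R)
    for r in range(R):
        rng = np.random.default_rng(children[r])
        try:
            codes[:, r] = run_replicate(
                staged, blocks, rng,
                with_replacement=with_replacement,
                on_empty=on_empty,
                _prebuilt=(groups, case_group),
            )
        except CapacityExhaustedError as exc:  # pragma: no cover - prechecked
            raise CapacityExhaustedError(f"replicate {r}: {exc}") from exc

    return AssignmentMatrix(
        case_ids=staged["case_id"].to_numpy(),
        block_index=blocks["block_id"].to_numpy(),
        codes=codes,
        master_seed=master_seed,
        metadata={
            "R": R,
            "with_replacement": with_replacement,
            "fallback_events": fallback_events,
        },
    )
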