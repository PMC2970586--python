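"""Zone-level vs block-level comparison of model coefficients.

Orchestrates one random-intercept fit per Monte Carlo replicate at the
block level, summarises the replicate coefficient distributions (mean,
min, max, histogram), and contrasts them with the single zone-level fit:
is each zone coefficient inside the closed [min, max] envelope of the
block-level replicates, does its sign agree with the replicate mean, and
how do the two levels' predicted risks for a reference person differ at
chosen distances?
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import AnalysisQualityError, EmptyInputError, NonConvergenceError, SchemaError
from .disaggregate import AssignmentMatrix
from .glmm import TERMS, FitResult, ModelSpec, build_design, fit_random_intercept_logit, predict_risk

logger = logging.getLogger(__name__)


@dataclass
class CoefficientDistribution:
    """Replicate distribution of one coefficient at the block level."""

    variable: str
    values: np.ndarray
    mean: float
    min: float
    max: float
    bin_edges: np.ndarray
    counts: np.ndarray


@dataclass
class ComparisonReport:
    """Zone-level coefficients vs the replicate block-level distributions."""

    variables: dict            # term -> per-variable comparison dict
    n_replicates: int
    n_nonconverged: int
    distance_one_sided_p: float
    distance_significant_010: bool
    predicted_risk: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "n_replicates": self.n_replicates,
            "n_nonconverged": self.n_nonconverged,
            "distance_one_sided_p": self.distance_one_sided_p,
            "distance_significant_010": self.distance_significant_010,
            "predicted_risk": self.predicted_risk,
        }


def fit_all_replicates(
    matrix: AssignmentMatrix,
    block_distances: pd.Series | dict,
    staged: pd.DataFrame,
    spec: ModelSpec | None = None,
    max_nonconverged_frac: float = 0.10,
) -> tuple[list[FitResult], int]:
    """One block-level fit per replicate column of the assignment matrix.

    Non-converged replicates are recorded and excluded; more than
    ``max_nonconverged_frac`` failures raises
    :class:`AnalysisQualityError`.

    Returns (converged fits, number non-converged).
    """
    if matrix.n_cases == 0 or matrix.n_replicates == 0:
        raise EmptyInputError("empty assignment matrix")
    spec = spec or ModelSpec()
    dist_map = dict(block_distances) if not isinstance(block_distances, dict) else block_distances

    fits: list[FitResult] = []
    failures = 0
    start = None
    for r in range(matrix.n_replicates):
        units = matrix.column(r)
        try:
            design = build_design(staged, units, dist_map)
            fit = fit_random_intercept_logit(design, spec, start=start)
            fits.append(fit)
            # replicate designs differ only in grouping/distance; warm-start
            start = {**fit.params, "tau2": fit.tau2}
        except (NonConvergenceError, ValueError) as exc:
            failures += 1
            logger.warning("replicate %d fit failed: %s", r, exc)
    if failures > max_nonconverged_frac * matrix.n_replicates:
        raise AnalysisQualityError(
            f"{failures}/{matrix.n_replicates} replicate fits failed"
        )
    return fits, failures


def _fd_bins(values: np.ndarray) -> int:
    """Freedman-Diaconis bin count with a 20-bin fallback for flat IQR."""
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    span = values.max() - values.min()
    if iqr <= 0 or span <= 0:
        return 20
    width = 2 * iqr / len(values) ** (1 / 3)
    return max(1, int(np.ceil(span / width)))


def summarize_coefficients(fits: list[FitResult]) -> dict[str, CoefficientDistribution]:
    """Per-variable replicate mean/min/max and histogram data."""
    if not fits:
        raise EmptyInputError("no converged replicate fits to summarise")
    out = {}
    for term in TERMS:
        vals = np.array([f.params[term] for f in fits])
        if np.ptp(vals) == 0:
            edges = np.array([vals[0] - 0.5, vals[0] + 0.5])
            counts = np.array([len(vals)])
        else:
            counts, edges = np.histogram(vals, bins=_fd_bins(vals))
        out[term] = CoefficientDistribution(
            variable=term, values=vals,
            mean=float(vals.mean()), min=float(vals.min()), max=float(vals.max()),
            bin_edges=edges, counts=counts,
        )
    return out


def distributions_from_values(values: pd.DataFrame) -> dict[str, CoefficientDistribution]:
    """Build coefficient distributions from a long table (variable, replicate,
    value), e.g. one written by an earlier pipeline stage."""
    out = {}
    for term, grp in values.groupby("variable"):
        vals = grp.sort_values("replicate")["value"].to_numpy(dtype=float)
        if np.ptp(vals) == 0:
            edges = np.array([vals[0] - 0.5, vals[0] + 0.5])
            counts = np.array([len(vals)])
        else:
            counts, edges = np.histogram(vals, bins=_fd_bins(vals))
        out[term] = CoefficientDistribution(
            variable=term, values=vals,
            mean=float(vals.mean()), min=float(vals.min()), max=float(vals.max()),
            bin_edges=edges, counts=counts,
        )
    return out


def compare_levels(
    zone_fit: FitResult,
    distributions: dict[str, CoefficientDistribution],
    risk_distances_m: tuple = (0.0, 20000.0),
    n_nonconverged: int = 0,
) -> ComparisonReport:
    """Classify each zone coefficient against the block replicate envelope.

    ``inside_range`` uses the closed interval [min, max]; ``sign_change``
    compares the zone coefficient's sign with the replicate mean's.
    Predicted late-stage risks for the reference person (non-black, age
    >= 70) are reported at each requested distance under (a) the zone
    model and (b) the mean block coefficients.
    """
    missing = [t for t in zone_fit.terms if t not in distributions]
    if missing:
        raise SchemaError(f"distributions missing variables: {missing}")

    variables = {}
    for term in zone_fit.terms:
        z = zone_fit.params[term]
        d = distributions[term]
        variables[term] = {
            "zone_coefficient": z,
            "zone_se": zone_fit.se[term],
            "zone_p_value": zone_fit.p_values[term],
            "zone_ci": list(zone_fit.conf_int[term]),
            "block_mean": d.mean,
            "block_min": d.min,
            "block_max": d.max,
            "inside_range": bool(d.min <= z <= d.max),
            "sign_change": bool(np.sign(z) != np.sign(d.mean)),
        }

    mean_params = {t: distributions[t].mean for t in zone_fit.terms}
    risks = []
    for dist_m in risk_distances_m:
        risks.append({
            "distance_m": float(dist_m),
            "zone_model": predict_risk(zone_fit.params, distance_m=dist_m),
            "block_mean_model": predict_risk(mean_params, distance_m=dist_m),
        })

    p1 = zone_fit.one_sided_p("distance_m")
    n_rep = len(next(iter(distributions.values())).values)
    return ComparisonReport(
        variables=variables,
        n_replicates=n_rep,
        n_nonconverged=n_nonconverged,
        distance_one_sided_p=p1,
        distance_significant_010=bool(p1 < 0.10),
        predicted_risk=risks,
    )


def export_histograms(
    distributions: dict[str, CoefficientDistribution],
    zone_fit: FitResult | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-variable plot-data tables: bin edges, counts, zone overlay value."""
    tables = {}
    for term, d in distributions.items():
        df = pd.DataFrame({
            "bin_left": d.bin_edges[:-1],
            "bin_right": d.bin_edges[1:],
            "count": d.counts,
        })
        df["zone_coefficient"] = zone_fit.params[term] if zone_fit else np.nan
        tables[term] = df
    return tables


def comparison_table(
    zone_fit: FitResult, distributions: dict[str, CoefficientDistribution]
) -> pd.DataFrame:
    """Side-by-side coefficient table in the block/zone column layout."""
    rows = []
    for term in zone_fit.terms:
        d = distributions[term]
        rows.append({
            "variable": term,
            "block_mean_coefficient": d.mean,
            "block_min": d.min,
            "block_max": d.max,
            "zone_coefficient": zone_fit.params[term],
            "zone_std_error": zone_fit.se[term],
            "zone_p_value": zone_fit.p_values[term],
            "zone_ci_low": zone_fit.conf_int[term][0],
            "zone_ci_high": zone_fit.conf_int[term][1],
        })
    return pd.DataFrame(rows)
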