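import numpy as np
import pandas as pd
import pytest

from geoimpute import (
    compare_levels,
    disaggregate,
    export_histograms,
    fit_all_replicates,
    summarize_coefficients,
)
from geoimpute.compare import comparison_table
from geoimpute.errors import EmptyInputError, SchemaError
from geoimpute.glmm import TERMS, FitResult


def make_fit(params, se=None, tau2=0.05):
    se = se or {t: 0.1 for t in TERMS}
    return FitResult(
        params=dict(params), se=dict(se),
        p_values={t: 0.5 for t in TERMS},
        conf_int={t: (params[t] - 0.2, params[t] + 0.2) for t in TERMS},
        tau2=tau2, loglik=-100.0, converged=True,
        n_obs=100, n_units=10,
    )


def replicate_fits(values_per_term):
    n = len(next(iter(values_per_term.values())))
    return [make_fit({t: values_per_term[t][r] for t in TERMS}) for r in range(n)]


# published zone-level coefficients and block-level replicate envelopes for
# the two counties: benign (inside-range) vs adverse (outside, sign flip)
KANE_DISTANCE = {"zone": 2.620e-6, "block": (-4.155e-5, 5.394e-5, 5.270e-6)}
PEORIA_DISTANCE = {"zone": -3.51e-4, "block": (5.950e-6, 2.250e-5, 1.419e-5)}


def distributions_with_distance(lo, hi, mean):
    vals = {t: np.full(5, 0.3) for t in TERMS}
    vals["distance_m"] = np.array([lo, hi, mean, mean, mean])
    return summarize_coefficients(replicate_fits(vals))


class TestSummarize:
    def test_constant_values(self):
        d = summarize_coefficients(replicate_fits({t: [2.0, 2.0, 2.0] for t in TERMS}))
        assert d["black"].min == d["black"].mean == d["black"].max == 2.0
        assert d["black"].counts.sum() == 3 and len(d["black"].counts) == 1

    def test_order_statistics(self):
        d = summarize_coefficients(replicate_fits({t: [1.0, 2.0, 3.0] for t in TERMS}))
        assert (d["intercept"].min, d["intercept"].mean, d["intercept"].max) == (1, 2, 3)

    def test_empty(self):
        with pytest.raises(EmptyInputError):
            summarize_coefficients([])

    def test_min_le_mean_le_max(self):
        rng = np.random.default_rng(0)
        vals = {t: rng.normal(size=40) for t in TERMS}
        for d in summarize_coefficients(replicate_fits(vals)).values():
            assert d.min <= d.mean <= d.max
            assert d.counts.sum() == 40


class TestCompareLevels:
    def test_benign_distance_inside_range(self):
        lo, hi, mean = KANE_DISTANCE["block"]
        zone = make_fit({**{t: 0.3 for t in TERMS}, "distance_m": KANE_DISTANCE["zone"]})
        report = compare_levels(zone, distributions_with_distance(lo, hi, mean))
        v = report.variables["distance_m"]
        assert v["inside_range"] and not v["sign_change"]

    def test_adverse_distance_outside_with_sign_change(self):
        lo, hi, mean = PEORIA_DISTANCE["block"]
        zone = make_fit({**{t: 0.3 for t in TERMS}, "distance_m": PEORIA_DISTANCE["zone"]},
                        se={**{t: 0.1 for t in TERMS}, "distance_m": 2.08e-4})
        report = compare_levels(zone, distributions_with_distance(lo, hi, mean))
        v = report.variables["distance_m"]
        assert not v["inside_range"] and v["sign_change"]
        # one-sided test at alpha = 0.1: |z| = 3.51/2.08 -> significant
        assert report.distance_significant_010

    def test_boundary_value_counts_as_inside(self):
        lo, hi, mean = 1.0e-6, 3.0e-6, 2.0e-6
        zone = make_fit({**{t: 0.3 for t in TERMS}, "distance_m": lo})
        report = compare_levels(zone, distributions_with_distance(lo, hi, mean))
        assert report.variables["distance_m"]["inside_range"]

    def test_predicted_risk_pairs(self):
        zone = make_fit({"intercept": np.log(1 / 3), "age_lt50": 0.0,
                         "age_50to70": 0.0, "black": 0.0, "distance_m": 0.0})
        dists = distributions_with_distance(0.0, 0.0, 0.0)
        report = compare_levels(zone, dists, risk_distances_m=(0.0, 20000.0))
        assert report.predicted_risk[0]["zone_model"] == pytest.approx(0.25)
        assert {r["distance_m"] for r in report.predicted_risk} == {0.0, 20000.0}

    def test_variable_mismatch(self):
        zone = make_fit({t: 0.3 for t in TERMS})
        dists = distributions_with_distance(0, 1, 0.5)
        del dists["black"]
        with pytest.raises(SchemaError):
            compare_levels(zone, dists)


class TestHistograms:
    def test_counts_sum_and_overlay(self):
        rng = np.random.default_rng(1)
        vals = {t: rng.normal(size=1000) for t in TERMS}
        dists = summarize_coefficients(replicate_fits(vals))
        zone = make_fit({t: 0.0 for t in TERMS})
        tables = export_histograms(dists, zone)
        for t, tab in tables.items():
            assert tab["count"].sum() == 1000
            assert (tab["zone_coefficient"] == 0.0).all()
            assert len(tab) >= 1

    def test_degenerate_single_bin(self):
        dists = summarize_coefficients(replicate_fits({t: [1.5] * 4 for t in TERMS}))
        tables = export_histograms(dists)
        assert len(tables["black"]) == 1


class TestFitAllReplicates:
    def test_identical_columns_identical_fits(self, kane_study, kane_staged):
        m = disaggregate(kane_staged, kane_study.study_area.blocks, R=1, master_seed=2)
        m.codes = np.repeat(m.codes, 3, axis=1)  # 3 identical replicates
        block_map = dict(zip(kane_study.block_distances["unit_id"],
                             kane_study.block_distances["distance_m"]))
        fits, n_fail = fit_all_replicates(m, block_map, kane_staged)
        assert n_fail == 0 and len(fits) == 3
        # warm starts traverse slightly different optimizer paths; agreement
        # is to numerical tolerance of the flat optimum
        for t in TERMS:
            assert fits[1].params[t] == pytest.approx(fits[0].params[t], abs=5e-4)
            assert fits[2].params[t] == pytest.approx(fits[0].params[t], abs=5e-4)

    def test_empty_matrix(self, kane_staged):
        from geoimpute.disaggregate import AssignmentMatrix
        empty = AssignmentMatrix(
            case_ids=np.array([]), block_index=np.array([]),
            codes=np.empty((0, 0), dtype=int), master_seed=0)
        with pytest.raises(EmptyInputError):
            fit_all_replicates(empty, {}, kane_staged)

    def test_comparison_table_layout(self):
        dists = distributions_with_distance(0, 1, 0.5)
        zone = make_fit({t: 0.3 for t in TERMS})
        tab = comparison_table(zone, dists)
        assert list(tab.columns) == [
            "variable", "block_mean_coefficient", "block_min", "block_max",
            "zone_coefficient", "zone_std_error", "zone_p_value",
            "zone_ci_low", "zone_ci_high",
        ]
        assert len(tab) == 5
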