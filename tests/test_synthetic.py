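import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats
from scipy.special import logit

from geoimpute import distance_summary, generate_study, scenario_presets
from geoimpute.errors import ConfigError
from geoimpute.geography import POP_COLUMNS
from geoimpute.synthetic import SyntheticConfig, generate_geography, generate_population

from dataclasses import replace


class TestGeography:
    def test_uniform_gradient_gives_even_totals(self):
        study = generate_study(SyntheticConfig(density_gradient=0.0, seed=0))
        totals = study.study_area.block_total_pop.to_numpy()
        assert totals.std() / totals.mean() < 0.1

    def test_gradient_concentrates_population_centrally(self):
        study = generate_study(SyntheticConfig(density_gradient=3.0, seed=0))
        blocks = study.study_area.blocks
        totals = study.study_area.block_total_pop.to_numpy()
        r = np.hypot(blocks["x"] - blocks["x"].mean(), blocks["y"] - blocks["y"].mean())
        inner = totals[r <= np.median(r)].sum()
        assert inner > 0.75 * totals.sum()

    def test_clustered_facilities_in_one_zone(self):
        cfg = SyntheticConfig(density_gradient=3.0, facility_mode="clustered",
                              n_facilities=3, seed=0)
        area = generate_geography(cfg)
        fac = area.facilities.merge(area.blocks, on=["x", "y"])
        assert fac["zone_id"].nunique() == 1

    def test_determinism(self):
        a = generate_study(SyntheticConfig(seed=5))
        b = generate_study(SyntheticConfig(seed=5))
        pd.testing.assert_frame_equal(a.study_area.blocks, b.study_area.blocks)
        pd.testing.assert_frame_equal(a.cases, b.cases)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    @pytest.mark.parametrize("bad", [
        dict(n_facilities=1000),
        dict(zone_nx=5),               # does not tile 12 blocks
        dict(segregation=1.5),
        dict(expected_cases=0),
        dict(facility_mode="ring"),
    ])
    def test_config_validation(self, bad):
        with pytest.raises(ConfigError):
            SyntheticConfig(**bad).validate()


class TestPopulation:
    def test_counts_conserve_block_totals(self):
        cfg = SyntheticConfig(seed=2)
        area = generate_geography(cfg)
        totals = area.block_total_pop.to_numpy().copy()
        blocks = generate_population(cfg, area)
        assert (blocks[list(POP_COLUMNS)].sum(axis=1).to_numpy() == totals).all()

    def test_no_segregation_gives_proportional_shares(self):
        cfg = SyntheticConfig(segregation=0.0, black_share=0.2,
                              mean_block_pop=400, seed=3)
        area = generate_geography(cfg)
        blocks = generate_population(cfg, area)
        black = blocks[["pop_b_lt50", "pop_b_50to69", "pop_b_ge70"]].sum(axis=1)
        total = blocks[list(POP_COLUMNS)].sum(axis=1)
        expected = total / total.sum() * black.sum()
        p = stats.chisquare(black, f_exp=expected).pvalue
        assert p > 0.01

    def test_full_segregation_concentrates_black_population(self):
        cfg = SyntheticConfig(segregation=1.0, concentration_fraction=0.2, seed=4)
        area = generate_geography(cfg)
        blocks = generate_population(cfg, area)
        black = blocks[["pop_b_lt50", "pop_b_50to69", "pop_b_ge70"]].sum(axis=1)
        r = np.hypot(blocks["x"] - blocks["x"].mean(), blocks["y"] - blocks["y"].mean())
        n_conc = int(round(0.2 * len(blocks)))
        conc = np.zeros(len(blocks), dtype=bool)
        conc[np.argsort(r.to_numpy(), kind="stable")[:n_conc]] = True
        assert black[conc].sum() >= 0.95 * black.sum()


class TestCases:
    def test_null_model_late_rate(self):
        """All effects zero, intercept logit(0.32): late share ~ 0.32."""
        cfg = SyntheticConfig(
            coefficients={"intercept": float(logit(0.32)), "age_lt50": 0.0,
                          "age_50to70": 0.0, "black": 0.0, "distance_m": 0.0},
            tau2=0.0, expected_cases=2000, unstaged_fraction=0.0, seed=6,
            mean_block_pop=300,
        )
        study = generate_study(cfg)
        rate = study.truth["late"].mean()
        assert abs(rate - 0.32) <= 3 * np.sqrt(0.32 * 0.68 / 2000)

    def test_zero_distance_effect_gives_flat_slope(self):
        cfg = SyntheticConfig(
            coefficients={"intercept": -0.5, "age_lt50": 0.0, "age_50to70": 0.0,
                          "black": 0.0, "distance_m": 0.0},
            tau2=0.0, expected_cases=2000, unstaged_fraction=0.0, seed=7,
            mean_block_pop=300,
        )
        study = generate_study(cfg)
        X = sm.add_constant(study.truth["true_distance_m"])
        fit = sm.Logit(study.truth["late"].astype(int), X).fit(disp=0)
        assert abs(fit.params["true_distance_m"]) <= 2 * fit.bse["true_distance_m"]

    def test_true_block_lies_in_labelled_zone(self, kane_study):
        blocks = kane_study.study_area.blocks
        zone_of = dict(zip(blocks["block_id"], blocks["zone_id"]))
        merged = kane_study.cases.merge(kane_study.truth, on="case_id")
        assert (merged["true_block_id"].map(zone_of) == merged["zone_id"]).all()

    def test_case_scale_and_unstaged_fraction(self, kane_study):
        assert len(kane_study.cases) == 1102
        unstaged = (kane_study.cases["stage"] == "U").mean()
        assert 0.02 < unstaged < 0.10


class TestPresets:
    def test_presets_deterministic(self):
        p1 = scenario_presets(seed=9)
        p2 = scenario_presets(seed=9)
        assert p1["kane_like"] == p2["kane_like"]
        assert p1["peoria_like"] == p2["peoria_like"]

    def test_zone_block_distance_discrepancy_ordering(self, kane_study, peoria_study):
        """The bifurcated geography shows the larger zone-vs-block gap."""
        def gap(study):
            b = distance_summary(study.block_distances)
            z = distance_summary(study.zone_distances)
            return abs(b["mean"] - z["mean"]) + abs(b["median"] - z["median"])
        assert gap(kane_study) < gap(peoria_study)

    def test_presets_satisfy_invariants(self, peoria_study):
        blocks = peoria_study.study_area.blocks
        assert (blocks[list(POP_COLUMNS)] >= 0).all().all()
        assert blocks["block_id"].is_unique
        assert peoria_study.study_area.zones["zone_id"].is_unique
        assert len(peoria_study.cases) == 804
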