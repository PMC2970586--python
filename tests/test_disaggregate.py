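import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geoimpute import cumulative_shares, disaggregate, draw_assignment, run_replicate
from geoimpute.errors import CapacityExhaustedError, EmptySupportError, InvalidDrawError
from tests.conftest import make_cases


def single_zone_blocks(pops, subgroup_col="pop_nb_lt50"):
    n = len(pops)
    df = pd.DataFrame({
        "block_id": [f"b{i}" for i in range(n)],
        "zone_id": ["z1"] * n,
        "x": np.arange(n, dtype=float), "y": np.zeros(n),
        "pop_nb_lt50": 0, "pop_nb_50to69": 0, "pop_nb_ge70": 0,
        "pop_b_lt50": 0, "pop_b_50to69": 0, "pop_b_ge70": 0,
    })
    df[subgroup_col] = pops
    return df


def staged_cases(n, zone="z1", age_band="lt50", race="nonblack"):
    df = make_cases([zone] * n)
    df["late"] = True
    df["age_band"] = age_band
    df["race_cat"] = race
    return df


class TestCumulativeShares:
    def test_proportions(self):
        cs = cumulative_shares(["a", "b", "c"], [30, 50, 20])
        assert cs.intervals == [("a", 0.0, 0.3), ("b", 0.3, 0.8), ("c", 0.8, 1.0)]

    def test_single_block(self):
        cs = cumulative_shares(["a"], [7])
        assert cs.intervals == [("a", 0.0, 1.0)]

    def test_zero_population_block_has_empty_interval(self):
        cs = cumulative_shares(["a", "b"], [0, 5])
        assert cs.intervals == [("a", 0.0, 0.0), ("b", 0.0, 1.0)]

    def test_final_bound_exactly_one(self):
        cs = cumulative_shares(list("abcdefg"), [1, 3, 7, 11, 13, 17, 19])
        assert cs.bounds[-1] == 1.0 and cs.bounds[0] == 0.0

    def test_empty_support(self):
        with pytest.raises(EmptySupportError):
            cumulative_shares(["a", "b"], [0, 0])


class TestDrawAssignment:
    @pytest.mark.parametrize("u,expected", [
        (0.85, "c"),   # third interval [0.8, 1.0)
        (0.3, "b"),    # half-open boundary: 0.3 belongs to [0.3, 0.8)
        (0.0, "a"),
    ])
    def test_interval_membership(self, u, expected):
        cs = cumulative_shares(["a", "b", "c"], [30, 50, 20])
        assert draw_assignment(cs, u) == expected

    def test_zero_width_interval_never_drawn(self):
        cs = cumulative_shares(["a", "b"], [0, 5])
        assert draw_assignment(cs, 0.0) == "b"

    @pytest.mark.parametrize("u", [1.0, -0.01, 1.5])
    def test_invalid_draw(self, u):
        cs = cumulative_shares(["a"], [1])
        with pytest.raises(InvalidDrawError):
            draw_assignment(cs, u)


class TestRunReplicate:
    def test_forced_assignment_without_replacement(self):
        """Two cases, two blocks with one resident each: one case per block."""
        blocks = single_zone_blocks([1, 1])
        cases = staged_cases(2)
        for seed in range(20):
            codes = run_replicate(cases, blocks, np.random.default_rng(seed))
            assert sorted(codes.tolist()) == [0, 1]

    def test_capacity_exhausted(self):
        blocks = single_zone_blocks([1, 1])
        cases = staged_cases(3)
        with pytest.raises(CapacityExhaustedError):
            disaggregate(cases, blocks, R=1, master_seed=0)

    def test_with_replacement_override(self):
        blocks = single_zone_blocks([1, 1])
        cases = staged_cases(3)
        m = disaggregate(cases, blocks, R=4, master_seed=0, with_replacement=True)
        assert m.shape == (3, 4)
        assert m.metadata["with_replacement"]

    def test_empty_support_fallback_uses_zone_totals(self, caplog):
        # no black residents anywhere: fallback spreads by total population
        blocks = single_zone_blocks([10, 30])
        cases = staged_cases(1, race="black")
        m = disaggregate(cases, blocks, R=500, master_seed=3)
        assert m.metadata["fallback_events"] == [
            {"zone_id": "z1", "subgroup": "black_lt50"}]
        frac_b1 = (m.codes == 1).mean()
        assert frac_b1 == pytest.approx(0.75, abs=3 * np.sqrt(0.75 * 0.25 / 500))

    def test_empty_support_error_mode(self):
        blocks = single_zone_blocks([10, 30])
        cases = staged_cases(1, race="black")
        with pytest.raises(EmptySupportError):
            disaggregate(cases, blocks, R=1, master_seed=0, on_empty="error")


class TestDisaggregate:
    def test_determinism(self):
        blocks = single_zone_blocks([5, 3, 2])
        cases = staged_cases(4)
        m1 = disaggregate(cases, blocks, R=7, master_seed=42)
        m2 = disaggregate(cases, blocks, R=7, master_seed=42)
        assert np.array_equal(m1.codes, m2.codes)
        m3 = disaggregate(cases, blocks, R=7, master_seed=43)
        assert not np.array_equal(m1.codes, m3.codes)

    def test_assignments_stay_in_case_zone(self, kane_study, kane_staged):
        m = disaggregate(kane_staged, kane_study.study_area.blocks, R=3, master_seed=5)
        block_zone = dict(zip(kane_study.study_area.blocks["block_id"],
                              kane_study.study_area.blocks["zone_id"]))
        for r in range(3):
            zones = np.array([block_zone[b] for b in m.column(r)])
            assert (zones == kane_staged["zone_id"].to_numpy()).all()

    def test_capacity_invariant_by_direct_count(self, kane_study, kane_staged):
        """Per replicate and (block, subgroup): assigned <= initial population."""
        blocks = kane_study.study_area.blocks.reset_index(drop=True)
        m = disaggregate(kane_staged, blocks, R=3, master_seed=5)
        sub = kane_staged["race_cat"] + "_" + kane_staged["age_band"]
        for r in range(3):
            df = pd.DataFrame({"code": m.codes[:, r], "sub": sub})
            for (code, sg), count in df.value_counts().items():
                col = ("pop_b_" if sg.startswith("black") else "pop_nb_") + sg.split("_")[1]
                assert count <= blocks.loc[code, col]

    def test_long_form_round_trip(self):
        blocks = single_zone_blocks([5, 3])
        cases = staged_cases(2)
        m = disaggregate(cases, blocks, R=2, master_seed=0)
        long = m.to_long()
        assert list(long.columns) == ["case_id", "replicate", "block_id"]
        assert len(long) == 4
        assert set(long["block_id"]).issubset({"b0", "b1"})


class TestAssignmentLaw:
    def test_first_case_marginal_matches_population_shares(self):
        """First-draw frequencies follow initial proportions (chi-square)."""
        pops = [30, 50, 20]
        blocks = single_zone_blocks(pops)
        cases = staged_cases(1)
        m = disaggregate(cases, blocks, R=4000, master_seed=11)
        observed = np.bincount(m.codes[0], minlength=3)
        p = stats.chisquare(observed, f_exp=4000 * np.array(pops) / 100).pvalue
        assert p > 0.01

    def test_two_case_occupancy_matches_enumeration(self):
        """pops [2,1], two cases: P(both in block 1) = 1/3 exactly.

        Sequential no-replacement: 2/3 * 1/2 = 1/3; the multivariate
        hypergeometric gives the same.
        """
        blocks = single_zone_blocks([2, 1])
        cases = staged_cases(2)
        R = 6000
        m = disaggregate(cases, blocks, R=R, master_seed=13)
        both_b0 = ((m.codes == 0).sum(axis=0) == 2).mean()
        se = np.sqrt((1 / 3) * (2 / 3) / R)
        assert abs(both_b0 - 1 / 3) <= 3 * se

    def test_joint_occupancy_matches_hypergeometric_oracle(self):
        """3 blocks, 3 cases: occupancy counts ~ MVHG within 3 MC SEs."""
        pops = np.array([3, 2, 1])
        blocks = single_zone_blocks(pops)
        cases = staged_cases(3)
        R = 4000
        m = disaggregate(cases, blocks, R=R, master_seed=17)
        occ = np.stack([np.bincount(m.codes[:, r], minlength=3) for r in range(R)])
        patterns, counts = np.unique(occ, axis=0, return_counts=True)
        mvh = stats.multivariate_hypergeom(pops, 3)
        for pat, count in zip(patterns, counts):
            p = mvh.pmf(pat)
            se = np.sqrt(p * (1 - p) / R)
            assert abs(count / R - p) <= 3 * se + 1e-12

    def test_order_invariance_of_occupancy_law(self):
        """Permuting case order leaves the occupancy distribution unchanged."""
        pops = np.array([2, 2])
        blocks = single_zone_blocks(pops)
        R = 4000
        mvh = stats.multivariate_hypergeom(pops, 2)
        for order_seed in (0, 1):
            cases = staged_cases(2)
            if order_seed:
                cases = cases.iloc[::-1].reset_index(drop=True)
            m = disaggregate(cases, blocks, R=R, master_seed=19)
            n_b0 = (m.codes == 0).sum(axis=0)
            for k in (0, 1, 2):
                p = mvh.pmf([k, 2 - k])
                se = np.sqrt(p * (1 - p) / R)
                assert abs((n_b0 == k).mean() - p) <= 3 * se
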