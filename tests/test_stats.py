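"""Effect sizes, t-tests, Bland--Altman and case-control matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lamt2.stats import (
    MatchCriteria,
    bland_altman,
    cohens_d_ci_unpaired,
    match_pairs,
    paired_compare,
    pearson_r,
    unpaired_compare,
)


class TestPairedCompare:
    def test_closed_form_diffs(self):
        x = np.array([2.0, 4.0, 6.0])
        y = np.array([1.0, 2.0, 3.0])   # diffs 1, 2, 3
        cmp = paired_compare(x, y)
        assert cmp.mean_diff == pytest.approx(2.0)
        assert cmp.cohens_d == pytest.approx(2.0)   # 2 / sd({1,2,3}) = 2/1

    def test_identical_series(self, rng):
        x = rng.normal(40, 3, 20)
        cmp = paired_compare(x, x)
        assert cmp.mean_diff == 0.0
        assert cmp.cohens_d == 0.0
        assert cmp.p_value == 1.0

    def test_p_matches_reference_t_distribution(self, rng):
        x = rng.normal(48, 4, 39)
        y = rng.normal(47, 4, 39)
        cmp = paired_compare(x, y)
        ref = sps.ttest_rel(x, y)
        assert cmp.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2])


class TestUnpairedCompare:
    def test_mftc_superficial_effect_size(self):
        cmp = unpaired_compare((48.9, 3.6, 39), (47.3, 3.2, 982))
        assert cmp.cohens_d == pytest.approx(0.49, abs=0.02)

    def test_lftc_deep_change_effect_size(self):
        cmp = unpaired_compare((0.8, 2.1, 39), (0.1, 1.8, 777))
        assert cmp.cohens_d == pytest.approx(0.39, abs=0.02)

    def test_equal_means_zero_d(self):
        for n in (10, 500):
            cmp = unpaired_compare((40.0, 2.0, n), (40.0, 3.0, n))
            assert cmp.cohens_d == 0.0

    def test_degenerate_sd(self):
        with pytest.raises(ValueError):
            unpaired_compare((40, 0.0, 10), (41, 2.0, 10))

    def test_d_location_and_scale_invariance(self, rng):
        a = (45.0, 3.0, 30)
        b = (43.0, 2.5, 50)
        base = unpaired_compare(a, b).cohens_d
        shift = unpaired_compare((a[0] + 7, a[1], a[2]), (b[0] + 7, b[1], b[2])).cohens_d
        scale = unpaired_compare((a[0] * 3, a[1] * 3, a[2]), (b[0] * 3, b[1] * 3, b[2])).cohens_d
        assert shift == pytest.approx(base, abs=1e-12)
        assert scale == pytest.approx(base, abs=1e-12)

    def test_welch_flag(self):
        pooled = unpaired_compare((48, 3.0, 20), (46, 6.0, 100))
        welch = unpaired_compare((48, 3.0, 20), (46, 6.0, 100), welch=True)
        assert pooled.cohens_d == welch.cohens_d     # D uses pooled SD either way
        assert pooled.p_value != welch.p_value


class TestCohensDCI:
    def test_published_interval_reproduced(self):
        """Normal-approximation CI around D=0.54 with n=39 vs 982."""
        lo, hi = cohens_d_ci_unpaired(0.54, 39, 982)
        assert round(lo, 2) == 0.22
        assert round(hi, 2) == 0.86


class TestPearson:
    def test_trivial(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -2 * x) == pytest.approx(-1.0)

    def test_covariance_formula_oracle(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        cx, cy = x - x.mean(), y - y.mean()
        expected = (cx * cy).sum() / np.sqrt((cx**2).sum() * (cy**2).sum())
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


class TestBlandAltman:
    def test_identical_series(self, rng):
        x = rng.normal(40, 2, 15)
        bias, sd, lo, hi, table = bland_altman(x, x)
        assert (bias, sd, lo, hi) == (0.0, 0.0, 0.0, 0.0)
        assert len(table) == 15

    def test_closed_form_limits(self):
        # differences with mean -1.2 and sd 0.9 (bias magnitude of the
        # all-echo deep-layer FTJ accuracy row)
        d = np.array([-1.2 - 0.9, -1.2, -1.2 + 0.9])
        y = np.zeros(3)
        bias, sd, lo, hi, _ = bland_altman(d, y)
        assert bias == pytest.approx(-1.2)
        assert sd == pytest.approx(0.9)
        assert lo == pytest.approx(-2.964)
        assert hi == pytest.approx(0.564)

    def test_direct_formula_oracle(self, rng):
        x = rng.normal(40, 3, 30)
        y = rng.normal(41, 3, 30)
        bias, sd, lo, hi, table = bland_altman(x, y)
        d = x - y
        assert bias == pytest.approx(d.mean(), abs=1e-12)
        assert sd == pytest.approx(d.std(ddof=1), abs=1e-12)
        assert lo == pytest.approx(bias - 1.96 * sd, abs=1e-12)
        np.testing.assert_allclose(table["mean"], (x + y) / 2)


def _cohort(rng, n, ids):
    return pd.DataFrame({
        "id": ids,
        "sex": rng.integers(0, 2, n),
        "painfreq": rng.integers(0, 3, n),
        "age": rng.uniform(45, 75, n),
        "bmi": rng.uniform(20, 35, n),
    })


class TestMatchPairs:
    def test_identical_tables_self_match(self, rng):
        cases = _cohort(rng, 12, [f"c{i}" for i in range(12)])
        controls = cases.copy()
        res = match_pairs(cases, controls, seed=0)
        assert len(res.pairs) == 12
        assert not res.unmatched_cases
        assert (res.pairs["age_diff"] == 0).all()
        assert (res.pairs["bmi_diff"] == 0).all()

    def test_case_outside_caliper_unmatched(self):
        cases = pd.DataFrame({"id": ["a"], "sex": [1], "painfreq": [0],
                              "age": [80.0], "bmi": [25.0]})
        controls = pd.DataFrame({"id": ["k"], "sex": [1], "painfreq": [0],
                                 "age": [60.0], "bmi": [25.0]})
        res = match_pairs(cases, controls)
        assert res.unmatched_cases == ["a"]
        assert res.pairs.empty

    def test_caliper_and_exact_compliance(self, rng):
        cases = _cohort(rng, 15, [f"c{i}" for i in range(15)])
        controls = _cohort(rng, 60, [f"k{i}" for i in range(60)])
        res = match_pairs(cases, controls, seed=3)
        assert (res.pairs["age_diff"] <= 5.0).all()
        assert (res.pairs["bmi_diff"] <= 5.0).all()
        merged = (res.pairs
                  .merge(cases, left_on="case_id", right_on="id")
                  .merge(controls, left_on="control_id", right_on="id",
                         suffixes=("_case", "_ctrl")))
        assert (merged["sex_case"] == merged["sex_ctrl"]).all()
        assert (merged["painfreq_case"] == merged["painfreq_ctrl"]).all()
        assert res.pairs["control_id"].is_unique

    def test_greedy_matches_optimal_count_on_small_cohort(self):
        """On a 10x20 cohort the greedy pairing achieves the maximum-cardinality
        matching size (computed with an exhaustive bipartite-matching oracle)."""
        import networkx as nx

        rng = np.random.default_rng(42)
        cases = _cohort(rng, 10, [f"c{i}" for i in range(10)])
        controls = _cohort(rng, 20, [f"k{i}" for i in range(20)])
        res = match_pairs(cases, controls, seed=0)

        crit = MatchCriteria()
        g = nx.Graph()
        g.add_nodes_from(cases["id"], bipartite=0)
        for _, case in cases.iterrows():
            for _, ctrl in controls.iterrows():
                if (case["sex"] == ctrl["sex"]
                        and case["painfreq"] == ctrl["painfreq"]
                        and abs(case["age"] - ctrl["age"]) <= crit.age_caliper
                        and abs(case["bmi"] - ctrl["bmi"]) <= crit.bmi_caliper):
                    g.add_edge(case["id"], ctrl["id"])
        optimal = nx.algorithms.matching.max_weight_matching(g, maxcardinality=True)
        assert len(res.pairs) == len(optimal)

    def test_missing_column_raises(self):
        with pytest.raises(ValueError):
            match_pairs(pd.DataFrame({"id": [1]}), pd.DataFrame({"id": [2]}))
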