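import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recurmap.cohort_stats import (
    MANN_WHITNEY,
    T_TEST,
    benjamini_hochberg,
    choose_test,
    compare_categorical,
    compare_region,
    subgroup_compare,
    survival_summary,
)

from oracles import mann_whitney_exact_p, pearson_chi2


def frame(values_a, values_b, region="outside_ctv", group_a="proton", group_b="photon"):
    return pd.DataFrame(
        {
            "case_id": [f"c{i}" for i in range(len(values_a) + len(values_b))],
            "group": [group_a] * len(values_a) + [group_b] * len(values_b),
            region: list(values_a) + list(values_b),
        }
    )


class TestChooseTest:
    def test_skewed_samples_route_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        rejected = 0
        for _ in range(20):
            a = rng.lognormal(0, 1.5, size=50)
            b = rng.lognormal(0, 1.5, size=50)
            if choose_test(a, b) == MANN_WHITNEY:
                rejected += 1
        assert rejected == 20

    def test_near_uniform_sequences_route_to_t_test(self):
        a = np.arange(1.0, 21.0)
        b = np.arange(5.0, 25.0) + 0.5
        assert choose_test(a, b) == T_TEST

    def test_constant_sample_routes_to_mann_whitney(self):
        assert choose_test([3.0, 3.0, 3.0, 3.0], [1.0, 2.0, 4.0, 8.0]) == MANN_WHITNEY

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            choose_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCompareRegion:
    def test_identical_multisets_give_p_near_one(self):
        vals = [1.0, 4.0, 9.0, 16.0, 25.0, 36.0]
        res = compare_region(frame(vals, vals), "outside_ctv")
        assert res.p_value > 0.9
        assert res.group_a_median == res.group_b_median

    def test_fully_separated_triplets_exact_p(self):
        res = compare_region(frame([1, 2, 3], [10, 11, 12]), "outside_ctv",
                             method=MANN_WHITNEY)
        assert res.test_used == MANN_WHITNEY
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(mann_whitney_exact_p([1, 2, 3], [10, 11, 12]))

    def test_relabeling_swaps_medians_keeps_p(self):
        rng = np.random.default_rng(5)
        a = rng.lognormal(6, 1, size=12)
        b = rng.lognormal(4, 1, size=9)
        res = compare_region(frame(a, b), "outside_ctv")
        # swap the group labels on the same values
        swapped = compare_region(frame(a, b, group_a="photon", group_b="proton"),
                                 "outside_ctv")
        # ordering is fixed proton-first, so medians swap with the labels
        assert res.group_a_median == pytest.approx(swapped.group_b_median)
        assert res.group_b_median == pytest.approx(swapped.group_a_median)
        assert res.p_value == pytest.approx(swapped.p_value)

    def test_unknown_region_rejected(self):
        with pytest.raises(KeyError):
            compare_region(frame([1, 2, 3], [4, 5, 6]), "no_such_region")

    def test_iqr_brackets_median(self):
        rng = np.random.default_rng(8)
        res = compare_region(
            frame(rng.lognormal(5, 1, 15), rng.lognormal(5, 1, 15)), "outside_ctv"
        )
        q1, q3 = res.group_a_iqr
        assert q1 <= res.group_a_median <= q3


class TestMannWhitneyProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_exact_p_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 9, size=2)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1.0) * 1.37)
        a, b = pooled[:n1], pooled[n1:]
        res = compare_region(frame(a, b), "outside_ctv", method=MANN_WHITNEY)
        assert res.p_value == pytest.approx(mann_whitney_exact_p(a, b), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(2, 1, size=20)
        b = rng.lognormal(3, 1, size=25)
        p1 = compare_region(frame(a, b), "outside_ctv").p_value
        p2 = compare_region(frame(np.log(a), np.log(b)), "outside_ctv").p_value
        p3 = compare_region(frame(a**3, b**3), "outside_ctv").p_value
        assert p1 == pytest.approx(p2) == pytest.approx(p3)

    def test_exact_vs_asymptotic_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = rng.normal(size=8)
            b = rng.normal(rng.uniform(0, 1.5), size=8)
            p_exact = stats.mannwhitneyu(a, b, alternative="two-sided",
                                         method="exact").pvalue
            p_asym = stats.mannwhitneyu(a, b, alternative="two-sided",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_asym) <= 0.05


class TestCategorical:
    def _records(self, table, variable="mgmt"):
        rows = []
        levels = ["methylated", "unmethylated", "other_a", "other_b"]
        for gi, group in enumerate(["proton", "photon"]):
            for li, n in enumerate(table[gi]):
                rows += [{"group": group, variable: levels[li]}] * n
        return pd.DataFrame(rows)

    def test_proportional_table_statistic_zero(self):
        res = compare_categorical(self._records([[10, 10], [20, 20]]), "mgmt")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_diagonal_table_hand_computed(self):
        res = compare_categorical(self._records([[10, 0], [0, 10]]), "mgmt")
        assert res.statistic == pytest.approx(20.0)
        assert res.dof == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_closed_form(self, seed):
        rng = np.random.default_rng(500 + seed)
        k = int(rng.integers(2, 5))
        table = rng.integers(1, 30, size=(2, k))
        res = compare_categorical(self._records(table.tolist()), "mgmt")
        assert res.statistic == pytest.approx(pearson_chi2(table))
        assert res.dof == k - 1

    def test_zero_margin_rejected(self):
        frame_ = pd.DataFrame(
            {"group": ["proton"] * 4 + ["photon"] * 4,
             "mgmt": ["methylated"] * 8}
        )
        with pytest.raises(ValueError):
            compare_categorical(frame_, "mgmt")

    def test_unknown_level_dropped_by_default(self):
        rows = self._records([[10, 10], [20, 20]])
        rows = pd.concat([rows, pd.DataFrame(
            [{"group": "proton", "mgmt": "unknown"}] * 5)], ignore_index=True)
        res = compare_categorical(rows, "mgmt")
        assert res.table.sum() == 60


class TestSubgroup:
    def _cohort(self, rng, effect_in_stratum=1.0):
        rows = []
        for i in range(40):
            group = "proton" if i < 20 else "photon"
            stratum = "methylated" if i % 2 == 0 else "unmethylated"
            mult = effect_in_stratum if (group == "proton" and stratum == "methylated") else 1.0
            rows.append({
                "case_id": f"c{i}", "group": group, "mgmt": stratum,
                "outside_ctv": float(rng.lognormal(np.log(200 * mult), 0.6)),
            })
        return pd.DataFrame(rows)

    def test_all_covering_stratum_equals_compare_region(self, rng):
        cohort = self._cohort(rng)
        cohort["all"] = "yes"
        direct = compare_region(cohort, "outside_ctv")
        via = subgroup_compare(cohort, "outside_ctv", "all", "yes")
        assert via.p_value == pytest.approx(direct.p_value)
        assert via.stratum_level == "yes"

    def test_empty_stratum_cell_rejected(self, rng):
        cohort = self._cohort(rng)
        cohort.loc[cohort["group"] == "photon", "mgmt"] = "unmethylated"
        with pytest.raises(ValueError, match="photon"):
            subgroup_compare(cohort, "outside_ctv", "mgmt", "methylated")

    def test_effect_confined_to_stratum_detected_there(self):
        rng = np.random.default_rng(77)
        hits_in, hits_out = 0, 0
        for _ in range(50):
            cohort = self._cohort(rng, effect_in_stratum=10.0)
            p_in = subgroup_compare(cohort, "outside_ctv", "mgmt", "methylated").p_value
            p_out = subgroup_compare(cohort, "outside_ctv", "mgmt", "unmethylated").p_value
            hits_in += p_in < 0.05
            hits_out += p_out < 0.05
        assert hits_in >= 45  # power >= 0.9 at this effect size
        assert hits_out <= 10  # near-nominal false positives in the complement


class TestSurvival:
    def _records(self, n, events, group, rng, median=9.0):
        pfs = rng.exponential(median / np.log(2), size=n)
        progressed = np.zeros(n, bool)
        progressed[:events] = True
        return pd.DataFrame({
            "case_id": [f"{group}{i}" for i in range(n)],
            "group": group, "progressed": progressed, "pfs_months": pfs,
        })

    def test_progression_proportions_from_event_counts(self, rng):
        records = pd.concat([
            self._records(94, 79, "proton", rng),
            self._records(50, 40, "photon", rng),
        ])
        summaries, logrank_p = survival_summary(records)
        by_group = {s.group: s for s in summaries}
        assert by_group["proton"].progression_proportion_pct == 84.0
        assert by_group["photon"].progression_proportion_pct == 80.0
        assert 0.0 <= logrank_p <= 1.0

    def test_point_mass_km_median(self):
        records = pd.DataFrame({
            "case_id": list("abcdef"),
            "group": ["proton"] * 3 + ["photon"] * 3,
            "progressed": [True] * 6,
            "pfs_months": [7.5] * 6,
        })
        summaries, _ = survival_summary(records)
        assert all(s.median_pfs_months == pytest.approx(7.5) for s in summaries)

    def test_no_events_rejected(self):
        records = pd.DataFrame({
            "case_id": list("abcd"),
            "group": ["proton", "proton", "photon", "photon"],
            "progressed": [False] * 4,
            "pfs_months": [5.0, 6.0, 7.0, 8.0],
        })
        with pytest.raises(ValueError, match="events"):
            survival_summary(records)


def test_benjamini_hochberg_known_example():
    adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    assert adjusted == pytest.approx([0.04, 0.04, 0.04, 0.04])
    assert np.all(np.diff(benjamini_hochberg([0.001, 0.5, 0.9])) >= 0)
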