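"""Tests for the nonparametric validation pipeline.

The Kruskal–Wallis and Dunn implementations are checked against a
brute-force rank oracle (explicit sort-and-average mid-ranks, direct
summation of the defining formulas) and, for Kruskal–Wallis, against
scipy's independent implementation.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from neutroscore import (
    describe_groups,
    dunn_posthoc,
    kruskal_wallis,
    shapiro_wilk,
    simulate_cohort,
    validate_cohort,
)

# ---------------------------------------------------------------- oracle ----


def oracle_midranks(pooled):
    """Mid-ranks by explicit sorting and position averaging."""
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1  # average of 1-based positions i+1 .. j+1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_tie_sum(pooled):
    return sum(c**3 - c for c in pd.Series(pooled).value_counts())


def oracle_kruskal(groups):
    pooled = [x for g in groups for x in g]
    ranks = oracle_midranks(pooled)
    N = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    correction = 1 - oracle_tie_sum(pooled) / (N**3 - N)
    return h / correction if correction > 0 else 0.0


def oracle_dunn_z(groups):
    pooled = [x for g in groups for x in g]
    ranks = oracle_midranks(pooled)
    N = len(pooled)
    means, start = [], 0
    for g in groups:
        means.append(sum(ranks[start : start + len(g)]) / len(g))
        start += len(g)
    var = N * (N + 1) / 12 - oracle_tie_sum(pooled) / (12 * (N - 1))
    out = {}
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(var * (1 / len(groups[i]) + 1 / len(groups[j])))
        out[(i, j)] = 0.0 if se == 0 else (means[i] - means[j]) / se
    return out


# ----------------------------------------------------------------- tests ----


class TestDescriptives:
    def test_basic_statistics(self):
        df = pd.DataFrame({"S": [0.2, 0.4, 0.6], "group": "a"})
        row = describe_groups(df).iloc[0]
        assert (row["mean"], row["median"], row["min"], row["max"]) == pytest.approx(
            (0.4, 0.4, 0.2, 0.6)
        )
        assert row["n"] == 3

    def test_single_row_group(self):
        df = pd.DataFrame({"S": [0.5], "group": "solo"})
        row = describe_groups(df).iloc[0]
        assert row["sd"] == 0.0
        assert row["min"] == row["median"] == row["max"] == 0.5

    def test_order_invariants(self, cohort):
        table = describe_groups(cohort)
        assert (table["min"] <= table["median"]).all()
        assert (table["median"] <= table["max"]).all()
        assert (table["sd"] >= 0).all()

    def test_missing_group_column(self):
        with pytest.raises(ValueError):
            describe_groups(pd.DataFrame({"S": [1.0]}))


class TestShapiroWilk:
    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            shapiro_wilk([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            shapiro_wilk([0.1, 0.2])

    def test_high_w_under_normality(self):
        rng = np.random.default_rng(0)
        count = sum(shapiro_wilk(rng.normal(size=20))[0] > 0.9 for _ in range(100))
        assert count >= 90

    def test_saturated_sample_flagged(self):
        # heavy ties at a floor (the novice saturation pattern) break normality
        values = np.array([1 / 3] * 15 + [0.35, 0.36, 0.34, 0.37, 0.355])
        w, p = shapiro_wilk(values)
        assert p < 0.05


class TestKruskalWallis:
    def test_hand_value_no_ties(self):
        h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert h == pytest.approx(32 / 7, abs=1e-12)
        assert 0 < p < 1

    def test_identical_groups_interleave(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(oracle_kruskal([[1, 2, 3], [1, 2, 3]]), abs=1e-12)
        assert p > 0.5

    def test_all_values_identical(self):
        h, p = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert h == 0.0 and p == 1.0

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1], []])

    def test_matches_oracle_and_scipy_on_random_instances(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [
                list(np.round(rng.normal(0, 1, int(rng.integers(2, 6))), 1))
                for _ in range(k)
            ]
            h, p = kruskal_wallis(groups)
            assert h == pytest.approx(oracle_kruskal(groups), abs=1e-9)
            try:
                h_sp, p_sp = scipy.stats.kruskal(*groups)
            except ValueError:
                continue  # scipy refuses all-identical pooled data
            assert h == pytest.approx(h_sp, abs=1e-9)
            assert p == pytest.approx(p_sp, abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(i, 1, 8) for i in range(3)]
        h0, _ = kruskal_wallis(groups)
        for fn in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
            h1, _ = kruskal_wallis([fn(np.asarray(g)) for g in groups])
            assert h1 == pytest.approx(h0, abs=1e-9)


class TestDunn:
    def test_identical_groups(self):
        res = dunn_posthoc([[1, 2, 3], [1, 2, 3]])
        assert res["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res["p_adjusted"].iloc[0] == 1.0

    def test_complete_separation_hand_value(self):
        # mean ranks 1.5 vs 3.5, variance N(N+1)/12 = 5/3:
        # |z| = 2 / sqrt(5/3 * (1/2 + 1/2)), frozen from the rank oracle
        res = dunn_posthoc([[1, 2], [5, 6]])
        expected = oracle_dunn_z([[1, 2], [5, 6]])[(0, 1)]
        assert abs(expected) == pytest.approx(2 / math.sqrt(5 / 3), abs=1e-12)
        assert res["z"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [
                list(np.round(rng.normal(0, 1, int(rng.integers(2, 6))), 1))
                for _ in range(k)
            ]
            res = dunn_posthoc(groups)
            expected = oracle_dunn_z(groups)
            for row, ((i, j), z) in zip(res.itertuples(), expected.items()):
                assert row.z == pytest.approx(z, abs=1e-9)
                assert row.p_raw == pytest.approx(
                    2 * scipy.stats.norm.sf(abs(z)), abs=1e-9
                )

    def test_bonferroni_dominates_raw(self, cohort):
        res = dunn_posthoc(
            {g: v["S"].to_numpy() for g, v in cohort.data.groupby("group")}
        )
        assert (res["p_adjusted"] >= res["p_raw"] - 1e-15).all()
        assert set(res.loc[res["p_adjusted"] < 0.05].index) <= set(
            res.loc[res["p_raw"] < 0.05].index
        )

    def test_labels_preserved(self, cohort):
        res = dunn_posthoc(
            {g: v["S"].to_numpy() for g, v in cohort.data.groupby("group")}
        )
        assert set(res["group_1"]) | set(res["group_2"]) == {
            "expert",
            "indeterminate",
            "novice",
        }


class TestValidateCohort:
    def test_full_report_structure(self, cohort):
        report = validate_cohort(cohort)
        assert len(report.descriptives) == 3
        assert len(report.normality) == 3
        assert len(report.posthoc) == 3
        assert 0 < report.omnibus_p < 1
        summary = report.summary()
        assert summary["kruskal_wallis"]["H"] == report.omnibus_h

    def test_normality_gate_fires_on_novice_saturation(self, cohort):
        report = validate_cohort(cohort)
        novice = report.normality.set_index("group").loc["novice"]
        assert not novice["normal"]
        assert report.normality_violated

    def test_pipeline_gate_replication(self):
        # the omnibus and expert pairwise rejections are essentially certain
        # under the default study conditions
        omnibus = expert_novice = 0
        for seed in range(100):
            report = validate_cohort(simulate_cohort(seed=seed))
            omnibus += report.omnibus_p < 0.05
            ph = report.posthoc.set_index(["group_1", "group_2"])
            expert_novice += ph.loc[("expert", "novice"), "p_adjusted"] < 0.05
        assert omnibus >= 99
        assert expert_novice >= 99

    def test_requires_two_groups(self):
        df = pd.DataFrame({"S": np.linspace(0, 1, 10), "group": "only"})
        with pytest.raises(ValueError):
            validate_cohort(df)
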