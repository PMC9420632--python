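"""Nonparametric tests, Bonferroni thresholds, fold changes, screening."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from metabomark import (
    ThresholdPolicy,
    bonferroni_threshold,
    fold_change,
    mann_whitney,
    median_test,
    univariate_screen,
)
from metabomark.chemometrics import VipScores
from metabomark import SimulationConfig, simulate_feature_table, run_preprocess
from metabomark import fit_oplsda, compute_vip, log_pareto
from conftest import make_table


def _exact_mw_p(a, b):
    """Brute-force exact two-sided p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    count = 0
    total = 0
    all_ranks = np.arange(1, n + 1)
    for idx in combinations(range(n), n1):
        u = all_ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        stat, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert stat == 0.0
        assert p == pytest.approx(0.1)  # 2 of 20 rank assignments as extreme

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(size=4)
            b = rng.normal(1.0, 1.0, size=5)
            _, p = mann_whitney(a, b)
            assert p == pytest.approx(_exact_mw_p(a, b), abs=1e-12)

    def test_identical_samples_p_one(self):
        a = np.arange(10.0)
        _, p = mann_whitney(a, a.copy())
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_large_shift_highly_significant(self, rng):
        a = rng.normal(10, 1, size=30)
        b = rng.normal(0, 1, size=30)
        _, p = mann_whitney(a, b)
        assert p < 1e-6

    @given(
        shift=st.floats(-3, 3),
        scale=st.floats(0.1, 10),
    )
    def test_invariant_to_monotone_transforms(self, shift, scale):
        rng = np.random.default_rng(5)
        a = rng.normal(size=12)
        b = rng.normal(0.8, 1, size=15)
        _, p0 = mann_whitney(a, b)
        _, p1 = mann_whitney(np.exp(scale * a + shift), np.exp(scale * b + shift))
        assert p1 == pytest.approx(p0, rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestMedianTest:
    def test_shifted_group_detected(self, rng):
        groups = [rng.normal(size=20), rng.normal(size=20), rng.normal(5, 1, size=20)]
        stat, p = median_test(groups)
        assert p < 0.001

    def test_two_groups_routed_away(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            median_test([[1.0, 2.0], [3.0, 4.0]])

    def test_degenerate_identical_data_rejected(self):
        with pytest.raises(ValueError):
            median_test([[1.0, 1.0], [1.0, 1.0], [1.0, 1.0]])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,family,expected",
        [(0.05, 28, 0.05 / 28), (0.05, 1, 0.05), (0.05, 80, 0.000625)],
    )
    def test_threshold_arithmetic(self, alpha, family, expected):
        assert bonferroni_threshold(alpha, family) == pytest.approx(expected)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_policy_consistency(self):
        pol = ThresholdPolicy(alpha=0.05, family_size=28)
        assert pol.corrected_threshold == bonferroni_threshold(0.05, 28)

    def test_corrected_selection_is_subset_of_uncorrected(self, rng):
        ps = rng.random(50) * 0.1
        corrected = set(np.flatnonzero(ps < 0.05 / 50))
        uncorrected = set(np.flatnonzero(ps < 0.05))
        assert corrected <= uncorrected


class TestFoldChange:
    def test_identical_groups_unity(self):
        assert fold_change([2.0, 4.0], [4.0, 2.0]) == 1.0

    def test_configured_ratio_recovered(self, rng):
        base = rng.lognormal(8, 0.1, size=500)
        assert fold_change(base * 8.12, base) == pytest.approx(8.12, rel=1e-12)

    def test_reciprocal_identity_for_means(self, rng):
        a = rng.lognormal(8, 1, size=20)
        b = rng.lognormal(7, 1, size=30)
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0, rel=1e-12)

    def test_raw_scale_unaffected_by_scaling_pipeline(self, rng):
        # FC uses raw intensities: applying log/Pareto elsewhere changes nothing
        vals = rng.lognormal(8, 0.5, size=(30, 5))
        vals[:10, 0] *= 4.0
        t = make_table(vals, ["a"] * 10 + ["b"] * 20)
        fc_before = fold_change(vals[:10, 0], vals[10:, 0])
        log_pareto(t)  # transforms a copy of the data for modelling only
        fc_after = fold_change(
            t.intensities.iloc[:10, 0], t.intensities.iloc[10:, 0]
        )
        assert fc_after == pytest.approx(fc_before, rel=1e-12)

    def test_median_summary_option(self):
        assert fold_change([1, 2, 9], [1, 2, 3], summary="median") == 1.0


class TestUnivariateScreen:
    def test_spiked_features_recovered(self):
        cfg = SimulationConfig(
            group_sizes={"PMC": 16, "HPG": 48}, n_features=80,
            log_mean_range=(8, 14),
            spike_plan=[(0, "PMC", 5.0), (1, "PMC", 7.0), (2, "PMC", 9.0)],
            seed=21,
        )
        table = simulate_feature_table(cfg)
        imputed, scaled, _ = run_preprocess(table)
        m = fit_oplsda(scaled, table.groups.to_numpy(), n_orthogonal=1)
        vip = compute_vip(m)
        recs = univariate_screen(imputed, vip, case_label="PMC")
        spiked = {"F0001", "F0002", "F0003"}
        hits = {r.feature_id for r in recs if r.passes_vip and r.passes_p}
        assert spiked <= hits
        by_id = {r.feature_id: r for r in recs}
        assert all(by_id[f].fold_change > 3 for f in spiked)

    def test_family_wise_error_control_on_null_data(self, rng):
        # Bonferroni across 60 null features keeps false positives rare
        p = 60
        vip = VipScores(pd.Series(1.5, index=[f"F{j}" for j in range(p)]),
                        "predictive_only")
        policy = ThresholdPolicy(alpha=0.05, family_size=p)
        ok = 0
        for _ in range(200):
            vals = rng.lognormal(8, 0.5, size=(30, p))
            t = make_table(vals, ["a"] * 10 + ["b"] * 20)
            recs = univariate_screen(t, vip, policy=policy)
            ok += sum(r.passes_p for r in recs) <= 1
        assert ok >= 190  # <= 1 false positive in >= 95% of simulations

    def test_all_vip_below_one_flags_nothing(self, rng):
        vals = rng.lognormal(8, 0.5, size=(12, 4))
        t = make_table(vals, ["a"] * 6 + ["b"] * 6)
        vip = VipScores(pd.Series(0.5, index=t.feature_ids), "predictive_only")
        recs = univariate_screen(t, vip)
        assert not any(r.passes_vip for r in recs)

    def test_multigroup_routes_to_median_test(self, rng):
        vals = rng.lognormal(8, 0.5, size=(30, 3))
        t = make_table(vals, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        vip = VipScores(pd.Series(1.5, index=t.feature_ids), "all_components")
        recs = univariate_screen(t, vip)
        assert all(r.test_name == "median_test" for r in recs)
        assert all(np.isnan(r.fold_change) for r in recs)

    def test_more_than_four_groups_rejected(self, rng):
        vals = rng.lognormal(8, 0.5, size=(10, 2))
        t = make_table(vals, ["a", "a", "b", "b", "c", "c", "d", "d", "e", "e"])
        vip = VipScores(pd.Series(1.5, index=t.feature_ids), "all_components")
        with pytest.raises(ValueError, match="4 groups"):
            univariate_screen(t, vip)
        assert len(univariate_screen(t, vip, allow_many_groups=True)) == 2
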