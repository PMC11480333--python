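"""Differential calling, BH adjustment, profile standardization, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phosdyn import (
    AnalysisThresholds,
    StudyDesign,
    bh_adjust,
    calibration_pipeline,
    call_regulated,
    differential_proteins_dia,
    differential_sites,
    direction_summary,
    residue_distribution,
    rounded_percent,
    standardize_profiles,
    summarize_multiplicity,
    two_group_test,
)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent step-up oracle: sort, scale by m/i, enforce monotonicity, cap."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


class TestTwoGroupTest:
    def test_identical_nonconstant_groups(self):
        res = two_group_test([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_student_closed_form(self):
        """Pooled-variance t for (1,2,3) vs (2,3,4): t=-1.2247, df=4."""
        res = two_group_test([1, 2, 3], [2, 3, 4], variant="student")
        t_expected = -1.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))  # pooled var = 1
        assert res.statistic == pytest.approx(t_expected, abs=1e-4)
        assert res.statistic == pytest.approx(-1.2247, abs=1e-4)
        p_expected = 2 * stats.t.cdf(t_expected, df=4)
        assert res.pvalue == pytest.approx(p_expected, rel=1e-12)
        assert res.pvalue == pytest.approx(0.2879, abs=1e-4)

    def test_welch_equals_student_for_equal_variances_and_sizes(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.5, 3.5, 4.5, 5.5]
        s = two_group_test(x, y, "student")
        w = two_group_test(x, y, "welch")
        assert w.pvalue == pytest.approx(s.pvalue, rel=1e-12)

    def test_insufficient_values_untestable(self):
        res = two_group_test([1.0], [1, 2, 3])
        assert res.pvalue is None and res.reason == "untestable"

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1, 2], [3, 4], variant="bayes")


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.03], [0.03]),
            ([0.5, 1.0], [1.0, 1.0]),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_nulls_skipped_and_returned_null(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], brute_force_bh(np.array([0.01, 0.02])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.integers(min_value=1, max_value=200), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, n, seed):
        p = np.random.default_rng(seed).random(n)
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    @settings(max_examples=60, deadline=None)
    def test_adjusted_at_least_raw_and_capped(self, p):
        out = bh_adjust(np.asarray(p))
        assert (out >= np.asarray(p) - 1e-15).all() and (out <= 1.0).all()


class TestDifferentialSites:
    def test_zero_noise_two_fold_site_is_significant_up(self):
        design = StudyDesign.balanced(("GV", "MII"), 5)
        values = pd.DataFrame(
            [[1.0] * 5 + [2.0] * 5, [1.0] * 5 + [1.2] * 5],
            index=["up2x", "up1.2x"],
            columns=design.samples_all,
        )
        # tiny jitter so variance is nonzero but effect dominates
        rng = np.random.default_rng(0)
        values = values * np.exp(rng.normal(0, 1e-6, values.shape))
        calls = differential_sites(values, design, [("MII", "GV")])
        up2 = calls.set_index("site_id").loc["up2x"]
        assert up2["significant"] and up2["direction"] == "up"
        assert up2["log2fc"] == pytest.approx(1.0, abs=1e-4)
        # 1.2x fails the FC > 1.5 gate regardless of p
        up12 = calls.set_index("site_id").loc["up1.2x"]
        assert not up12["significant"] and up12["direction"] == "none"

    def test_within_stage_label_permutation_invariance(self, default_study, calibrated):
        calls_a = differential_sites(calibrated, default_study.design, [("MII", "GV")])
        permuted = calibrated.values.rename(
            columns={"GV_1": "GV_3", "GV_3": "GV_1", "MII_2": "MII_5", "MII_5": "MII_2"}
        )
        calls_b = differential_sites(permuted, default_study.design, [("MII", "GV")])
        pd.testing.assert_frame_equal(calls_a, calls_b)

    def test_unknown_stage_rejected(self, default_study, calibrated):
        with pytest.raises(ValueError, match="unknown stage"):
            differential_sites(calibrated, default_study.design, [("MI", "GV")])

    def test_significance_invariant_holds(self, calls):
        thr = AnalysisThresholds()
        sig = calls["significant"]
        expected = (
            calls["p_adj"].notna()
            & (calls["p_adj"] < thr.padj_max)
            & (calls["log2fc"].abs() > np.log2(thr.fc_min_phospho))
        )
        assert (sig == expected).all()
        up = calls.loc[sig & (calls["log2fc"] > 0), "direction"]
        assert (up == "up").all()

    def test_untestable_site_gets_null_p(self, default_study):
        values = default_study.site_intensity.iloc[:5].copy()
        values.loc[values.index[0], default_study.design.samples("GV")[1:]] = np.nan
        calls = differential_sites(values, default_study.design, [("MII", "GV")])
        row = calls.set_index("site_id").iloc[0]
        assert np.isnan(row["p_raw"]) and not row["significant"]


class TestCallRegulated:
    def test_union_rule(self):
        calls = pd.DataFrame(
            {
                "site_id": ["a", "a", "a", "b", "b", "b"],
                "comparison": ["c1", "c2", "c3"] * 2,
                "significant": [False, True, False, False, False, False],
            }
        )
        flags = call_regulated(calls)
        assert bool(flags["a"]) and not bool(flags["b"])

    def test_recovers_planted_fraction(self, default_study, calls):
        recovered = call_regulated(calls).mean()
        planted = default_study.truth.site_truth["regulated"].mean()
        assert abs(recovered - planted) <= 0.05


@pytest.fixture(scope="module")
def two_group():
    design = StudyDesign.balanced(("WT", "MUT"), 5)
    rng = np.random.default_rng(1)
    base = pd.DataFrame(
        [[1.0] * 5 + [1.3] * 5, [1.0] * 5 + [1.1] * 5, [1.0] * 10],
        index=["fc1.3", "fc1.1", "flat"],
        columns=design.samples_all,
    ) * np.exp(rng.normal(0, 1e-6, (3, 10)))
    return design, base


class TestDiaProteins:
    def test_gates(self, two_group):
        design, base = two_group
        calls = differential_proteins_dia(base, design, ("MUT", "WT")).set_index("protein_id")
        assert calls.loc["fc1.3", "significant"]
        assert not calls.loc["fc1.1", "significant"]  # fails FC > 1.2 gate
        assert not calls.loc["flat", "significant"]


class TestStandardizeProfiles:
    def test_population_sd_standardization(self):
        z, dropped = standardize_profiles(pd.DataFrame({"GV": [1.0], "GVBD": [2.0], "MII": [3.0]}, index=["r"]))
        np.testing.assert_allclose(z.loc["r"].to_numpy(), [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert dropped == []

    def test_constant_rows_dropped_with_diagnostics(self):
        df = pd.DataFrame({"GV": [1.0, 2.0], "MII": [1.0, 4.0]}, index=["const", "ok"])
        z, dropped = standardize_profiles(df)
        assert dropped == ["const"] and list(z.index) == ["ok"]

    def test_affine_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=["GV", "GVBD", "MII"])
        z1, _ = standardize_profiles(df)
        z2, _ = standardize_profiles(df * 3.7 + 11.0)
        pd.testing.assert_frame_equal(z1, z2, rtol=1e-10)


class TestSummaries:
    def test_multiplicity_counts(self):
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(10)],
                "protein_id": ["A"] + ["B"] * 2 + ["C"] * 7,
                "residue": ["S"] * 10,
            }
        )
        out = summarize_multiplicity(sites)
        assert out["n_proteins"] == 3
        assert out["pct_multisite"] == 67  # 2/3
        assert out["pct_gt6"] == 33  # 1/3

    def test_residue_distribution(self):
        sites = pd.DataFrame({"residue": ["S", "S", "T", "Y"]})
        assert residue_distribution(sites) == {"S": 0.5, "T": 0.25, "Y": 0.25}
        only_s = pd.DataFrame({"residue": ["S", "S"]})
        assert residue_distribution(only_s) == {"S": 1.0, "T": 0.0, "Y": 0.0}

    def test_direction_summary(self):
        calls = pd.DataFrame(
            {
                "site_id": range(5),
                "comparison": "MII_vs_GV",
                "significant": [True, True, True, False, False],
                "direction": ["up", "up", "down", "none", "none"],
            }
        )
        out = direction_summary(calls)
        assert out["n_significant"] == 3 and out["n_up"] == 2 and out["pct_up"] == 67
        none_sig = calls.assign(significant=False, direction="none")
        assert direction_summary(none_sig)["pct_up"] is None

    @pytest.mark.parametrize(
        "n, d, expected",
        [(26, 29, 90), (1, 2, 50), (2268, 6700, 34), (1508, 2604, 58), (250, 2604, 10), (168, 197, 85)],
    )
    def test_rounded_percent(self, n, d, expected):
        assert rounded_percent(n, d) == expected

    def test_rounded_percent_requires_positive_denominator(self):
        with pytest.raises(ValueError):
            rounded_percent(1, 0)
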