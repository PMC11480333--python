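"""Kinome module: Fisher oracle, enzyme accounting, enrichment, activity."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phosdyn import (
    KinaseSubstrateNetwork,
    annotate_enzymes,
    call_regulated,
    fisher_exact_2x2,
    infer_activity,
    kinase_enrichment,
    simulate_ks_network,
    stage_means,
)


def exact_fisher_two_sided(a, b, c, d):
    """Independent oracle: exact-integer hypergeometric enumeration."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0
    denom = comb(n, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)
        for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    }
    p_obs = probs[a]
    total = sum(p for p in probs.values() if p <= p_obs)
    return float(total)


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            (((1, 0), (0, 1)), 1.0),
            (((5, 0), (0, 5)), 2 / 252),  # two extreme tables of C(10,5)=252
        ],
    )
    def test_enumerated_examples(self, table, expected):
        _, p = fisher_exact_2x2(table)
        assert p == pytest.approx(expected, rel=1e-12)

    def test_transpose_symmetry(self, rng):
        for _ in range(25):
            t = rng.integers(0, 12, size=(2, 2))
            assert fisher_exact_2x2(t)[1] == pytest.approx(fisher_exact_2x2(t.T)[1], rel=1e-10)

    def test_zero_margin_is_degenerate(self):
        assert fisher_exact_2x2(((0, 0), (3, 4)))[1] == 1.0

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(50):
            t = rng.integers(0, 25, size=(2, 2))
            ours = fisher_exact_2x2(t)[1]
            ref = stats.fisher_exact(t, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_matches_exact_enumeration_sample(self, rng):
        for _ in range(50):
            t = rng.integers(0, 15, size=4)
            ours = fisher_exact_2x2(t.reshape(2, 2))[1]
            oracle = exact_fisher_two_sided(*map(int, t))
            assert ours == pytest.approx(oracle, rel=1e-9, abs=1e-12)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(((1, 2, 3), (4, 5, 6)))
        with pytest.raises(ValueError):
            fisher_exact_2x2(((-1, 2), (3, 4)))


class TestAnnotateEnzymes:
    def _fixture(self):
        sites = pd.DataFrame(
            {
                "site_id": ["K1_S5", "K1_S9", "P1_T3"],
                "protein_id": ["K1", "K1", "P1"],
            }
        )
        return sites

    def test_nesting_and_counts(self):
        sites = self._fixture()
        table, counts = annotate_enzymes(
            proteome_ids={"K1", "K2", "P1"},
            sites=sites,
            regulated_site_ids={"K1_S5"},
            kinase_list=["K1", "K2", "K3"],
            phosphatase_list=["P1", "P2"],
        )
        t = table.set_index("enzyme_id")
        assert t.loc["K1"].tolist() == ["kinase", True, True, True]
        assert t.loc["K2"].tolist() == ["kinase", True, False, False]
        assert t.loc["K3"].tolist() == ["kinase", False, False, False]
        assert counts["kinase"] == {
            "n_total": 3, "n_detected": 2, "n_phosphorylated": 1, "n_regulated": 1,
        }
        assert counts["phosphatase"]["n_detected"] == 1

    def test_regulated_subset_of_phosphorylated_subset_of_detected(self, default_study, calls):
        regulated = call_regulated(calls)
        proteins = list(default_study.protein_intensity.index)
        table, counts = annotate_enzymes(
            proteins,
            default_study.sites_frame,
            regulated[regulated].index,
            kinase_list=proteins[:40],
            phosphatase_list=proteins[40:60],
        )
        assert (~table["regulated"] | table["phosphorylated"]).all()
        assert (~table["phosphorylated"] | table["detected"]).all()
        for kind in ("kinase", "phosphatase"):
            c = counts[kind]
            assert c["n_regulated"] <= c["n_phosphorylated"] <= c["n_detected"] <= c["n_total"]


@pytest.fixture(scope="module")
def planted_network(default_study):
    return simulate_ks_network(default_study.truth, seed=17)


class TestKinaseEnrichment:
    def test_up_kinases_rank_top(self, default_study, calibrated, calls, planted_network):
        network, ktruth = planted_network
        one = calls[calls["comparison"] == "MII_vs_GV"]
        result = kinase_enrichment(one, network, calibrated.values.index)
        up_archetypes = {"A3", "A4", "A5"}  # templates peaking at MII
        planted_up = set(ktruth.loc[ktruth["archetype"].isin(up_archetypes), "kinase_id"])
        top = set(result["kinase_id"].head(len(planted_up)))
        # rank-based: planted up-kinases dominate the smallest p values
        assert len(top & planted_up) >= len(planted_up) - 1

    def test_margins_reconcile(self, calls, calibrated, planted_network):
        network, _ = planted_network
        one = calls[calls["comparison"] == "MII_vs_GV"]
        result = kinase_enrichment(one, network, calibrated.values.index)
        universe = set(calibrated.values.index)
        n_up = len(
            set(one.loc[one["significant"] & (one["direction"] == "up"), "site_id"]) & universe
        )
        assert (result["sub_up"] + result["nonsub_up"] == n_up).all()
        assert (result["sub_up"] + result["sub_rest"] == result["n_substrates"]).all()

    def test_kinase_without_substrates_excluded(self, calls, calibrated):
        network = KinaseSubstrateNetwork(
            kinases=frozenset({"K_lonely"}),
            edges=pd.DataFrame({"kinase_id": ["K_lonely"], "site_id": ["not_in_universe"], "score": [1.0]}),
        )
        one = calls[calls["comparison"] == "MII_vs_GV"]
        result = kinase_enrichment(one, network, calibrated.values.index)
        assert result.empty

    def test_null_kinase_rarely_significant(self, rng):
        """Substrates drawn at the background up-rate: raw p < 0.05 in <= ~5% of draws."""
        universe = [f"s{i}" for i in range(500)]
        up = set(universe[:150])  # 30% up-rate
        calls = pd.DataFrame(
            {
                "site_id": universe,
                "comparison": "MII_vs_GV",
                "significant": [s in up for s in universe],
                "direction": ["up" if s in up else "none" for s in universe],
            }
        )
        n_sig = 0
        runs = 200
        for _ in range(runs):
            substrates = rng.choice(universe, size=20, replace=False)
            network = KinaseSubstrateNetwork(
                kinases=frozenset({"K"}),
                edges=pd.DataFrame({"kinase_id": "K", "site_id": substrates, "score": 1.0}),
            )
            p = kinase_enrichment(calls, network, universe)["p"].iloc[0]
            n_sig += p < 0.05
        # Fisher is conservative under the null; allow 3 binomial SD above 5%
        assert n_sig / runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / runs)


class TestInferActivity:
    def test_planted_archetype_trends_recovered(self, default_study, calibrated, planted_network):
        network, ktruth = planted_network
        profiles = stage_means(calibrated.values, default_study.design)
        activity = infer_activity(network, profiles)
        expected = {"A1": "decreasing", "A2": "transient", "A3": "increasing",
                    "A4": "increasing", "A5": "increasing"}
        merged = activity.merge(ktruth[["kinase_id", "archetype"]], on="kinase_id")
        hits = (merged["trend"] == merged["archetype"].map(expected)).mean()
        assert hits >= 0.95

    def test_monotone_substrates_give_monotone_trend(self):
        profiles = pd.DataFrame(
            {"GV": [1.0, 2.0, 1.5], "GVBD": [2.0, 3.0, 2.5], "MII": [3.0, 4.0, 3.5]},
            index=["a", "b", "c"],
        )
        network = KinaseSubstrateNetwork(
            kinases=frozenset({"K"}),
            edges=pd.DataFrame({"kinase_id": "K", "site_id": ["a", "b", "c"], "score": 1.0}),
        )
        out = infer_activity(network, profiles)
        assert out.iloc[0]["trend"] == "increasing"

    def test_symmetric_split_is_flat(self):
        profiles = pd.DataFrame(
            {"GV": [1.0, 3.0, 1.0, 3.0], "GVBD": [2.0, 2.0, 2.0, 2.0], "MII": [3.0, 1.0, 3.0, 1.0]},
            index=list("abcd"),
        )
        network = KinaseSubstrateNetwork(
            kinases=frozenset({"K"}),
            edges=pd.DataFrame({"kinase_id": "K", "site_id": list("abcd"), "score": 1.0}),
        )
        out = infer_activity(network, profiles)
        assert out.iloc[0]["trend"] == "flat"

    def test_too_few_substrates_gives_null_profile(self):
        profiles = pd.DataFrame({"GV": [1.0], "GVBD": [2.0], "MII": [3.0]}, index=["a"])
        network = KinaseSubstrateNetwork(
            kinases=frozenset({"K"}),
            edges=pd.DataFrame({"kinase_id": ["K"], "site_id": ["a"], "score": [1.0]}),
        )
        out = infer_activity(network, profiles, min_substrates=3)
        assert out.iloc[0]["trend"] is None and np.isnan(out.iloc[0]["z_GV"])

    def test_scale_invariance(self, rng):
        profiles = pd.DataFrame(
            rng.lognormal(size=(6, 3)), columns=["GV", "GVBD", "MII"],
            index=[f"s{i}" for i in range(6)],
        )
        network = KinaseSubstrateNetwork(
            kinases=frozenset({"K"}),
            edges=pd.DataFrame({"kinase_id": "K", "site_id": profiles.index, "score": 1.0}),
        )
        a = infer_activity(network, profiles)
        scaled = profiles.mul(rng.uniform(0.1, 10.0, size=6), axis=0)
        b = infer_activity(network, scaled)
        pd.testing.assert_frame_equal(a, b, rtol=1e-10)

    def test_duplicate_edges_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            KinaseSubstrateNetwork(
                kinases=frozenset({"K"}),
                edges=pd.DataFrame({"kinase_id": ["K", "K"], "site_id": ["a", "a"], "score": [1, 1]}),
            )
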