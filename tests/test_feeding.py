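"""Feeding assays: growth rates, rank tests, normalization, success groups."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from noctua import (
    candidate_success_groups,
    growth_rates,
    kruskal_dunn,
    normalize_to_control,
)
from noctua.feeding import PairwiseTestResult


def _records(rows):
    return pd.DataFrame(rows, columns=["species", "diet", "weight_mg", "dev_days"])


class TestGrowthRates:
    def test_rate_arithmetic_and_sample_sd(self):
        rec = _records(
            [
                ("T_ni", "control", 3.0, 10),  # rate 0.3
                ("T_ni", "Z_mays", 2.0, 10),   # 0.2
                ("T_ni", "Z_mays", 4.0, 10),   # 0.4
            ]
        )
        out = growth_rates(rec).set_index(["species", "diet"])
        assert out.loc[("T_ni", "control"), "mean_rate"] == pytest.approx(0.3)
        zm = out.loc[("T_ni", "Z_mays")]
        assert zm["mean_rate"] == pytest.approx(0.3)
        assert zm["sd_rate"] == pytest.approx(0.14142135, abs=1e-6)
        assert zm["n"] == 2

    def test_single_larva_flagged_with_zero_sd(self):
        out = growth_rates(_records([("T_ni", "control", 3.0, 10)]))
        assert out.loc[0, "sd_rate"] == 0.0
        assert bool(out.loc[0, "single_larva"])

    def test_nonpositive_dev_days_rejected(self):
        with pytest.raises(ValueError):
            growth_rates(_records([("T_ni", "control", 3.0, 0)]))


def _kw_h_oracle(values, labels):
    """Straight-line tie-corrected Kruskal-Wallis H, independent of the library."""
    n = len(values)
    ranks = rankdata(values)
    h = 0.0
    for g in set(labels):
        r = [ranks[i] for i in range(n) if labels[i] == g]
        h += sum(r) ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    corr = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / corr


class TestKruskalDunn:
    def test_exact_p_equals_full_permutation_enumeration(self):
        """3-vs-3 toy data: the exact KW p must match brute-force enumeration of
        all 20 equal-size label assignments."""
        rec = pd.DataFrame(
            {"grp": ["a"] * 3 + ["b"] * 3, "rate": [1, 2, 3, 4, 5, 6]}
        )
        res = kruskal_dunn(rec, grouping="grp", method="exact")
        values = [1, 2, 3, 4, 5, 6]
        h_obs = _kw_h_oracle(values, ["a"] * 3 + ["b"] * 3)
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            labels = ["a" if i in combo else "b" for i in range(6)]
            total += 1
            if _kw_h_oracle(values, labels) >= h_obs - 1e-12:
                hits += 1
        assert total == 20
        assert res.kw_p == pytest.approx(hits / total)
        assert res.kw_p == pytest.approx(0.1)

    def test_bonferroni_arithmetic_and_symmetry(self):
        rng = np.random.default_rng(0)
        rec = pd.DataFrame(
            {
                "grp": np.repeat(["a", "b", "c"], 15),
                "rate": rng.normal(size=45),
            }
        )
        res = kruskal_dunn(rec, grouping="grp")
        assert len(res.pairs) == 3
        for r in res.pairs.itertuples(index=False):
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * 3))
        # z antisymmetric in pair order by construction; p depends on |z| only
        lookup = res.p_adj_lookup()
        assert lookup[frozenset(("a", "b"))] == lookup[frozenset(("b", "a"))]

    def test_all_tied_values_not_an_error(self):
        rec = pd.DataFrame({"grp": ["a"] * 4 + ["b"] * 4, "rate": [1.0] * 8})
        res = kruskal_dunn(rec, grouping="grp")
        assert np.isfinite(res.pairs["p_adj"]).all()

    def test_fewer_than_two_groups_rejected(self):
        rec = pd.DataFrame({"grp": ["a"] * 4, "rate": [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            kruskal_dunn(rec, grouping="grp")

    def test_null_type_one_error_rate(self):
        """Two groups from the same distribution: omnibus rejection near 5%."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            rec = pd.DataFrame(
                {
                    "grp": np.repeat(["a", "b"], 200),
                    "rate": rng.normal(size=400),
                }
            )
            if kruskal_dunn(rec, grouping="grp").kw_p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sim <= 0.07


class TestNormalizeToControl:
    def _summaries(self, plant_mean, control_mean):
        return pd.DataFrame(
            [
                {"species": "T_ni", "diet": "Z_mays", "n": 5,
                 "mean_rate": plant_mean, "sd_rate": 0.1},
                {"species": "T_ni", "diet": "control", "n": 5,
                 "mean_rate": control_mean, "sd_rate": 0.1},
            ]
        )

    @pytest.mark.parametrize(
        "plant,control,expected", [(0.25, 0.5, -50.0), (0.4, 0.4, 0.0), (0.6, 0.4, 50.0)]
    )
    def test_percent_deviation(self, plant, control, expected):
        out = normalize_to_control(self._summaries(plant, control))
        got = out.loc[out.diet == "Z_mays", "normalized_pct"].iloc[0]
        assert got == pytest.approx(expected)

    def test_missing_control_names_species(self):
        df = self._summaries(0.25, 0.5)
        df = df[df.diet != "control"]
        with pytest.raises(ValueError, match="T_ni"):
            normalize_to_control(df)

    def test_scale_invariance(self):
        a = normalize_to_control(self._summaries(0.25, 0.5))
        b = normalize_to_control(self._summaries(0.25 * 7, 0.5 * 7))
        pd.testing.assert_series_equal(a["normalized_pct"], b["normalized_pct"])


def _norm_summaries(order):
    """Normalized summaries on one plant with the given descending ranking."""
    rows = []
    for rank, sp in enumerate(order):
        rows.append(
            {"species": sp, "diet": "Z_mays", "n": 50, "mean_rate": 0.5,
             "sd_rate": 0.1, "normalized_pct": -10.0 * rank}
        )
    return pd.DataFrame(rows)


def _pairwise(species, significant_pairs):
    """PairwiseTestResult where listed pairs are significant (p_adj .01), rest .5."""
    rows = []
    for a, b in itertools.combinations(sorted(species), 2):
        sig = frozenset((a, b)) in {frozenset(p) for p in significant_pairs}
        rows.append({"a": a, "b": b, "z": 0.0, "p_raw": 0.01 if sig else 0.5,
                     "p_adj": 0.01 if sig else 0.5})
    return PairwiseTestResult(grouping="species", kw_h=0.0, kw_p=0.0,
                              pairs=pd.DataFrame(rows))


SP5 = ["s1", "s2", "s3", "s4", "s5"]


class TestCandidateSuccessGroups:
    def test_top_two_tied_rest_lower_gives_single_pair(self):
        sig = [(a, b) for a, b in itertools.combinations(SP5, 2)
               if not {a, b} <= {"s1", "s2"}]
        res = candidate_success_groups(_norm_summaries(SP5), _pairwise(SP5, sig), "Z_mays")
        assert res.groups == [frozenset({"s1", "s2"})]

    def test_all_nonsignificant_gives_full_group(self):
        res = candidate_success_groups(_norm_summaries(SP5), _pairwise(SP5, []), "Z_mays")
        assert res.groups == [frozenset(SP5)]

    def test_maize_style_ranking_gives_three_groups(self):
        """Two tied top species, two further species each tied with the lower of
        the pair: exactly {top2}, {top2+a}, {top2+b}."""
        sig = set()
        for a, b in itertools.combinations(SP5, 2):
            sig.add((a, b))
        nonsig = [("s1", "s2"), ("s2", "s3"), ("s2", "s4")]
        sig -= {tuple(sorted(p)) for p in nonsig}
        res = candidate_success_groups(
            _norm_summaries(SP5), _pairwise(SP5, list(sig)), "Z_mays"
        )
        assert res.groups == [
            frozenset({"s1", "s2"}),
            frozenset({"s1", "s2", "s3"}),
            frozenset({"s1", "s2", "s4"}),
        ]

    def test_row_order_invariance(self):
        sig = [(a, b) for a, b in itertools.combinations(SP5, 2)
               if not {a, b} <= {"s1", "s2"}]
        base = candidate_success_groups(
            _norm_summaries(SP5), _pairwise(SP5, sig), "Z_mays"
        )
        shuffled = _norm_summaries(SP5).sample(frac=1.0, random_state=3)
        other = candidate_success_groups(shuffled, _pairwise(SP5, sig), "Z_mays")
        assert base.groups == other.groups

    def test_user_groups_bypass_rule(self):
        res = candidate_success_groups(
            _norm_summaries(SP5), _pairwise(SP5, []), "Z_mays",
            user_groups=[{"s3", "s4"}],
        )
        assert res.provenance == "user"
        assert res.groups == [frozenset({"s3", "s4"})]
        with pytest.raises(ValueError):
            candidate_success_groups(
                _norm_summaries(SP5), _pairwise(SP5, []), "Z_mays",
                user_groups=[{"s3"}],
            )
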