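from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from coculture.core import ValidationError
from coculture.stats import (
    chisq_mc,
    class_count_table,
    default_category_partition,
    pairwise_permanova,
    permanova,
    spearman_trend,
    species_rank_enrichment,
    subseed,
)


class TestSubseed:
    def test_stable_and_distinct(self):
        assert subseed(1, "a") == subseed(1, "a")
        assert subseed(1, "a") != subseed(1, "b")
        assert subseed(1, "a") != subseed(2, "a")
        assert 0 <= subseed(123, "x") < 2**31


class TestCategoryPartition:
    def test_covers_the_16_source_panel_once_each(self):
        part = default_category_partition()
        assert len(part) == 16
        assert set(part.values()) == {
            "sugars", "sugar alcohols", "carboxylate ions", "amino acids",
            "nucleic acids",
        }


class TestChisqMC:
    def test_identical_rows_give_zero_statistic(self):
        table = pd.DataFrame([[10, 5, 5], [10, 5, 5]])
        stat, p = chisq_mc(table, iters=200, seed=0)
        assert stat == 0.0 and p == 1.0

    def test_perfect_separation_hits_resolution_floor(self):
        table = pd.DataFrame([[20, 0], [0, 20]])
        iters = 20_000
        stat, p = chisq_mc(table, iters=iters, seed=0)
        assert stat == pytest.approx(40.0)
        assert p == pytest.approx(1 / (1 + iters))
        # agreement with the exact (Fisher) tail: both essentially zero
        assert sps.fisher_exact(table.to_numpy())[1] < p

    def test_mc_p_close_to_asymptotic_on_large_table(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.multinomial(300, np.full(6, 1 / 6), size=6))
        iters = 20_000
        stat, p = chisq_mc(table, iters=iters, seed=1)
        chi2, p_asym, _, _ = sps.chi2_contingency(table, correction=False)
        mc_se = np.sqrt(p_asym * (1 - p_asym) / iters)
        assert stat == pytest.approx(chi2, rel=1e-9)
        assert abs(p - p_asym) <= 3 * mc_se + 1 / iters

    def test_zero_margin_dropped_with_warning(self):
        table = pd.DataFrame([[5, 5, 0], [5, 5, 0], [0, 0, 0]])
        with pytest.warns(UserWarning):
            stat, _ = chisq_mc(table, iters=100, seed=0)
        assert stat == 0.0

    def test_count_table_shapes(self):
        classes = pd.DataFrame(
            {"species_i": ["A", "A"], "species_j": ["B", "C"],
             "env": ["e1", "e1"],
             "interaction_class": ["competition", "mutualism"]}
        )
        assert class_count_table(classes, by="pair").shape == (2, 2)
        assert class_count_table(classes, by="env").shape == (1, 2)
        with pytest.raises(ValidationError):
            class_count_table(classes, by="species")


def permanova_enumeration_oracle(points, groups):
    """Exact permutation p for the two-group case by full enumeration of
    label assignments, with pseudo-F recomputed from scratch each time."""

    def pseudo_f(pts, grp):
        pts = np.asarray(pts, dtype=float)
        grand = pts.mean(axis=0)
        ss_total = ((pts - grand) ** 2).sum()
        ss_within = 0.0
        for g in np.unique(grp):
            sub = pts[grp == g]
            ss_within += ((sub - sub.mean(axis=0)) ** 2).sum()
        a = len(np.unique(grp))
        n = len(pts)
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    groups = np.asarray(groups)
    labels = np.unique(groups)
    k = int((groups == labels[0]).sum())
    f_obs = pseudo_f(points, groups)
    ge = total = 0
    for idx in combinations(range(len(groups)), k):
        g = np.full(len(groups), labels[1], dtype=groups.dtype)
        g[list(idx)] = labels[0]
        ge += pseudo_f(points, g) >= f_obs - 1e-12
        total += 1
    return f_obs, ge / total


class TestPermanova:
    def test_identical_groups_give_high_p(self):
        pts = np.array([[0.0, 1.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        _, p = permanova(pts, np.array(["a", "a", "b", "b"]))
        assert p == 1.0

    def test_exhaustive_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(6, 4))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        f, p = permanova(pts, groups)
        f_oracle, p_oracle = permanova_enumeration_oracle(pts, groups)
        assert f == pytest.approx(f_oracle, rel=1e-9)
        assert p == pytest.approx(p_oracle)
        assert p * comb(6, 3) == pytest.approx(round(p * comb(6, 3)))

    def test_cross_check_against_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova

        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 3))
        pts[5:] += 1.5
        groups = np.array(["a"] * 5 + ["b"] * 5)
        f, _ = permanova(pts, groups, perms=200, seed=0)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = sk_permanova(DistanceMatrix(d), grouping=list(groups), permutations=99)
        assert f == pytest.approx(float(res["test statistic"]), rel=1e-9)

    def test_planted_shift_detected_after_bh(self):
        # categories of 5 environments each; category "c" shifted by 4 sd
        rng = np.random.default_rng(2)
        theta = pd.DataFrame(
            rng.normal(0, 1, size=(15, 5)),
            index=[f"s{k}" for k in range(15)],
        )
        theta.iloc[10:] += 4.0
        partition = {f"s{k}": ("a" if k < 5 else "b" if k < 10 else "c") for k in range(15)}
        out = pairwise_permanova(theta, partition, perms=2000, seed=5)
        out = out.set_index(["category_1", "category_2"])
        assert out.loc[("a", "c"), "significant"]
        assert out.loc[("b", "c"), "significant"]
        assert not out.loc[("a", "b"), "significant"]

    def test_small_category_skipped_with_warning(self):
        theta = pd.DataFrame(np.eye(3), index=["s0", "s1", "s2"])
        partition = {"s0": "a", "s1": "a", "s2": "b"}
        with pytest.warns(UserWarning):
            out = pairwise_permanova(theta, partition, perms=10, seed=0)
        assert len(out) == 0


class TestSpeciesRankEnrichment:
    def test_all_theta_equal_gives_p_one(self):
        pairs = pd.DataFrame(
            {"species_i": ["A", "A", "B"], "species_j": ["B", "C", "C"],
             "theta": [5.0, 5.0, 5.0]}
        )
        out = species_rank_enrichment(pairs)
        assert (out["p"] == 1.0).all()

    def test_exact_enumeration_of_top_ranked_species(self):
        # 4 species, 6 pairs; species A's three pairs hold the top 3 theta:
        # one-sided tail 1/C(6,3) = 1/20, two-sided p = 0.1
        pairs = pd.DataFrame(
            {
                "species_i": ["A", "A", "A", "B", "B", "C"],
                "species_j": ["B", "C", "D", "C", "D", "D"],
                "theta": [10.0, 9.0, 8.0, 1.0, 2.0, 3.0],
            }
        )
        out = species_rank_enrichment(pairs).set_index("species")
        assert out.loc["A", "mean_rank"] == pytest.approx(5.0)
        assert out.loc["A", "p"] == pytest.approx(2 / 20)

    def test_null_rarely_significant(self):
        rng = np.random.default_rng(0)
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            species = [f"S{k}" for k in range(6)]
            rows = [
                {"species_i": a, "species_j": b, "theta": rng.normal()}
                for a, b in combinations(species, 2)
            ]
            out = species_rank_enrichment(pd.DataFrame(rows), perms=500, seed=seed)
            hits += int(out["significant"].any())
        assert hits <= 3  # ~FDR-level false positives over 20 null datasets


class TestSpearmanTrend:
    def test_strictly_decreasing_is_minus_one(self):
        x = np.arange(10.0)
        rho, _ = spearman_trend(x, -(x**3))
        assert rho == pytest.approx(-1.0)

    def test_constant_input_undefined(self):
        rho, p = spearman_trend(np.ones(5), np.arange(5.0))
        assert np.isnan(rho) and np.isnan(p)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.integers(1, 17, size=100).astype(float)
        y = -x + rng.normal(0, 4, size=100)
        rho, _ = spearman_trend(x, y)
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(float(oracle), rel=1e-12)
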