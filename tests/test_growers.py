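from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from coculture.core import DETECTION_FLOOR, Environment, ValidationError
from coculture.growers import (
    ANY_NON_GROWER,
    BOTH_GROWERS,
    GROWER,
    NON_GROWER,
    class_enrichment,
    grower_fraction_by_carbon_number,
    growth_calls,
    stratify_interactions,
    ward_growers,
    ward_two_cluster_split,
)

LOG_FLOOR = np.log10(DETECTION_FLOOR)


def exhaustive_min_sse_bipartition(x: np.ndarray) -> frozenset:
    """Brute force over ALL bipartitions (not only contiguous ones): the
    membership of the higher-mean cluster minimising total within-cluster
    sum of squares under Ward's criterion."""
    n = len(x)
    best, best_mask = np.inf, None
    for bits in range(1, 2**n - 1):
        mask = np.array([(bits >> k) & 1 for k in range(n)], dtype=bool)
        a, b = x[mask], x[~mask]
        sse = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        if sse < best - 1e-12:
            best, best_mask = sse, mask
    upper = best_mask if x[best_mask].mean() > x[~best_mask].mean() else ~best_mask
    return frozenset(np.flatnonzero(upper))


class TestWardSplit:
    def test_separated_clusters(self):
        x = np.array([5.66, 5.70, 8.9, 9.0])
        labels = ward_growers(x, DETECTION_FLOOR)
        assert labels.tolist() == [NON_GROWER, NON_GROWER, GROWER, GROWER]

    def test_all_at_floor_skips_clustering(self):
        x = np.full(6, LOG_FLOOR)
        assert (ward_growers(x, DETECTION_FLOOR) == NON_GROWER).all()

    def test_narrow_gap_collapses_to_one_label(self):
        # two "clusters" 0.3 apart, well above the floor: all growers
        x = np.array([8.0, 8.05, 8.3, 8.35])
        assert (ward_growers(x, DETECTION_FLOOR) == GROWER).all()
        # and all near the floor: all non-growers
        y = LOG_FLOOR + np.array([0.0, 0.05, 0.3, 0.35])
        assert (ward_growers(y, DETECTION_FLOOR) == NON_GROWER).all()

    def test_matches_exhaustive_bipartition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            x = rng.uniform(LOG_FLOOR, 9.5, size=n)
            upper = ward_two_cluster_split(x)
            assert frozenset(np.flatnonzero(upper)) == exhaustive_min_sse_bipartition(x)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            ward_two_cluster_split(np.array([1.0]))


class TestGrowthCalls:
    def test_grower_labels_threshold_consistent_per_species(self, sim_pipeline):
        calls = sim_pipeline.growth_calls
        for _, grp in calls.groupby("species"):
            lo = grp.loc[grp["label"] == GROWER, "mean_log10"]
            hi = grp.loc[grp["label"] == NON_GROWER, "mean_log10"]
            if len(lo) and len(hi):
                assert lo.min() >= hi.max()

    def test_fraction_by_carbon_number(self):
        envs = {
            "a": Environment("a", {"a"}),
            "none": Environment("none", frozenset()),
        }
        calls = pd.DataFrame(
            {"species": ["X", "Y", "X", "Y"], "env": ["a", "a", "none", "none"],
             "mean_log10": [8, 8, LOG_FLOOR, LOG_FLOOR],
             "label": [GROWER, GROWER, NON_GROWER, NON_GROWER]}
        )
        out = grower_fraction_by_carbon_number(calls, envs).set_index("n_sources")
        assert out.loc[1, "grower_fraction"] == 1.0
        assert out.loc[0, "grower_fraction"] == 0.0


def _toy_classes_and_calls():
    envs = {"e1": Environment("e1", {"s1"}), "e2": Environment("e2", {"s2"})}
    classes = pd.DataFrame(
        {
            "species_i": ["A", "A", "B", "A"],
            "species_j": ["B", "C", "C", "B"],
            "env": ["e1", "e1", "e1", "e2"],
            "interaction_class": ["competition", "commensalism", "neutralism", "competition"],
        }
    )
    calls = pd.DataFrame(
        [
            ("A", "e1", GROWER), ("B", "e1", GROWER), ("C", "e1", NON_GROWER),
            ("A", "e2", GROWER), ("B", "e2", NON_GROWER),
        ],
        columns=["species", "env", "label"],
    )
    return classes, calls, envs


class TestStratification:
    def test_counts_match_hand_tally(self):
        classes, calls, envs = _toy_classes_and_calls()
        table = stratify_interactions(classes, calls, envs)
        idx = table.set_index(["stratum", "n_sources", "interaction_class"])["count"]
        assert idx.loc[(BOTH_GROWERS, 1, "competition")] == 1
        assert idx.loc[(ANY_NON_GROWER, 1, "commensalism")] == 1
        assert idx.loc[(ANY_NON_GROWER, 1, "neutralism")] == 1
        assert idx.loc[(ANY_NON_GROWER, 1, "competition")] == 1
        assert table["count"].sum() == len(classes)

    def test_strata_conserve_the_class_table(self, sim_pipeline):
        strata = sim_pipeline.strata
        total_by_class = strata.groupby("interaction_class")["count"].sum()
        full = sim_pipeline.interactions["interaction_class"].value_counts()
        assert total_by_class.sort_index().tolist() == full.sort_index().tolist()

    def test_missing_call_is_an_error(self):
        classes, calls, envs = _toy_classes_and_calls()
        with pytest.raises(ValidationError):
            stratify_interactions(classes, calls.iloc[:1], envs)


class TestClassEnrichment:
    def test_hand_hypergeometric_tail(self):
        # stratum of 10 records all competition; pooled table half competition
        strata = pd.DataFrame(
            {
                "stratum": [BOTH_GROWERS, ANY_NON_GROWER, ANY_NON_GROWER],
                "n_sources": [1, 1, 1],
                "interaction_class": ["competition", "competition", "neutralism"],
                "count": [10, 0, 10],
            }
        )
        out = class_enrichment(strata, bins=(1,))
        row = out.set_index(["stratum", "interaction_class"]).loc[
            (BOTH_GROWERS, "competition")
        ]
        assert row["p"] == pytest.approx(float(hypergeom.sf(9, 20, 10, 10)))
        assert row["p"] == pytest.approx(1 / 184756)

    def test_identical_composition_never_significant(self):
        strata = pd.DataFrame(
            {
                "stratum": [BOTH_GROWERS] * 2 + [ANY_NON_GROWER] * 2,
                "n_sources": [1] * 4,
                "interaction_class": ["competition", "neutralism"] * 2,
                "count": [5, 5, 5, 5],
            }
        )
        out = class_enrichment(strata, bins=(1,))
        assert not out["significant"].any()

    def test_absent_class_gets_p_one(self):
        strata = pd.DataFrame(
            {
                "stratum": [BOTH_GROWERS, ANY_NON_GROWER],
                "n_sources": [1, 1],
                "interaction_class": ["neutralism", "competition"],
                "count": [5, 5],
            }
        )
        out = class_enrichment(strata, bins=(1,))
        row = out.set_index(["stratum", "interaction_class"]).loc[
            (BOTH_GROWERS, "competition")
        ]
        assert row["observed"] == 0 and row["p"] == 1.0

    def test_empty_bins_rejected(self):
        strata = pd.DataFrame(
            {"stratum": [BOTH_GROWERS], "n_sources": [8],
             "interaction_class": ["competition"], "count": [3]}
        )
        with pytest.raises(ValidationError):
            class_enrichment(strata, bins=(1, 2, 4))
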