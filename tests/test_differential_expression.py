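"""Stage-wise DE calling, Venn regions, and K-means archetype recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from lncdissect.annotation_io import ExpressionMatrix
from lncdissect.differential_expression import (
    archetype_label,
    call_de_sets,
    differential_test,
    kmeans_cluster,
    run_comparisons,
    venn_intersections,
)
from lncdissect.exceptions import ValidationError
from lncdissect.synthetic_data import (
    design_frame,
    simulate_archetype_profiles,
    simulate_de_matrix,
    simulate_null_matrix,
)

from _oracles import bh_stepup, venn_enumeration

STAGES = ("A0", "A1", "A3", "A5")


def _matrix_from_stage_means(means: dict[str, list[float]]) -> ExpressionMatrix:
    design = design_frame()
    ids = list(means)
    values = pd.DataFrame(
        {s: [means[i][STAGES.index(stage)] for i in ids]
         for s, stage in zip(design["sample"], design["stage"])},
        index=ids,
    )
    return ExpressionMatrix(values, design)


class TestDifferentialTest:
    def test_identical_stages_are_never_called(self):
        em = simulate_null_matrix(50, noise_sd=0.2, seed=4)
        # A-vs-A: the same stage on both sides of the comparison
        table = differential_test(em, ("A0", "A0"))
        assert (table["log2fc"] == 0).all()
        assert (table["call"] == "ns").all()

    def test_noise_free_fold_change_arithmetic(self):
        em = _matrix_from_stage_means({"f": [10.0, 40.0, 10.0, 10.0]})
        table = differential_test(em, ("A1", "A0"))
        assert table.loc["f", "log2fc"] == pytest.approx(np.log2(41 / 11))
        assert table.loc["f", "p"] == 0.0
        assert table.loc["f", "call"] == "up"

    def test_call_respects_both_thresholds(self):
        em = _matrix_from_stage_means({
            "big": [10.0, 80.0, 10.0, 10.0],     # |lfc| > 1, p ~ 0 -> up
            "small": [10.0, 15.0, 10.0, 10.0],   # |lfc| < 1 -> ns even at p ~ 0
        })
        table = differential_test(em, ("A1", "A0"))
        assert table.loc["big", "call"] == "up"
        assert table.loc["small", "call"] == "ns"

    def test_down_direction(self):
        em = _matrix_from_stage_means({"f": [40.0, 5.0, 40.0, 40.0]})
        table = differential_test(em, ("A1", "A0"))
        assert table.loc["f", "call"] == "down"
        assert table.loc["f", "log2fc"] < 0

    def test_type_one_error_calibrated_on_planted_null(self):
        em = simulate_null_matrix(200, noise_sd=0.2, seed=7)
        table = differential_test(em, ("A1", "A0"))
        hits = int((table["p"] < 0.05).sum())
        lo = stats.binom.ppf(0.005, 200, 0.05)
        hi = stats.binom.ppf(0.995, 200, 0.05)
        assert lo <= hits <= hi

    def test_bh_adjustment_matches_stepup_oracle(self):
        em = simulate_de_matrix(150, 50, log2fc=1.5, noise_sd=0.3, seed=9)[0]
        table = differential_test(em, ("A5", "A0"))
        assert np.allclose(table["p_adjust"], bh_stepup(table["p"]))

    def test_requires_two_replicates(self):
        design = design_frame().iloc[[0, 3, 4, 5]]  # one A0 replicate only
        values = pd.DataFrame(np.ones((3, 4)), index=list("abc"),
                              columns=design["sample"])
        em = ExpressionMatrix(values, design)
        with pytest.raises(ValidationError):
            differential_test(em, ("A1", "A0"))

    def test_planted_direction_mix_recovered(self):
        em, up, down = simulate_de_matrix(100, 60, log2fc=2.0, noise_sd=0.1,
                                          seed=21, up_fraction=0.5)
        sets = call_de_sets({"A5vA0": differential_test(em, ("A5", "A0"))})["A5vA0"]
        assert len(sets["up"] & up) >= 0.9 * len(up)
        assert len(sets["down"] & down) >= 0.9 * len(down)
        assert not sets["up"] & down and not sets["down"] & up


class TestDeSets:
    def test_threshold_edge_cases(self):
        em = _matrix_from_stage_means({"f": [10.0, 80.0, 10.0, 10.0]})
        table = differential_test(em, ("A1", "A0"))
        assert "f" in call_de_sets({"c": table})["c"]["up"]
        strict = differential_test(em, ("A1", "A0"), alpha=0.0)
        assert call_de_sets({"c": strict})["c"] == {"up": set(), "down": set()}


class TestVenn:
    def test_common_region_of_spec_example(self):
        sets = {"s1": {"a", "b", "c"}, "s2": {"b", "c", "d"},
                "s3": {"c", "d", "e"}, "s4": {"c", "f"}}
        counts = venn_intersections(sets)
        assert counts[("s1", "s2", "s3", "s4")] == 1
        assert sum(counts.values()) == len({"a", "b", "c", "d", "e", "f"})

    def test_identical_sets_all_in_full_intersection(self):
        sets = {f"s{i}": set(range(7)) for i in range(4)}
        counts = venn_intersections(sets)
        assert counts[tuple(sets)] == 7
        assert sum(counts.values()) == 7

    def test_matches_membership_enumeration_oracle(self):
        rng = np.random.default_rng(13)
        sets = {f"s{i}": set(map(int, rng.integers(0, 60, size=rng.integers(5, 40))))
                for i in range(4)}
        assert venn_intersections(sets) == venn_enumeration(sets)

    def test_set_count_bounds(self):
        with pytest.raises(ValidationError):
            venn_intersections({"a": {1}})


class TestKmeans:
    def test_separable_archetypes_partition_perfectly(self):
        profiles, labels = simulate_archetype_profiles(25, noise_sd=0.0, seed=1)
        assignment = kmeans_cluster(profiles, k=4, seed=0)
        assert adjusted_rand_score(labels, assignment.labels) == 1.0

    def test_k_equals_one_puts_everything_together(self):
        profiles, _ = simulate_archetype_profiles(5, noise_sd=0.1, seed=2)
        assignment = kmeans_cluster(profiles, k=1, seed=0)
        assert set(assignment.labels) == {0}

    def test_noisy_recovery_meets_ari_bound(self):
        profiles, labels = simulate_archetype_profiles(50, noise_sd=0.3, seed=3)
        assignment = kmeans_cluster(profiles, k=4, seed=0, n_init=10)
        assert adjusted_rand_score(labels, assignment.labels) >= 0.9

    def test_sizes_sum_to_feature_count(self):
        profiles, _ = simulate_archetype_profiles(20, noise_sd=0.2, seed=5)
        assignment = kmeans_cluster(profiles, k=4, seed=0)
        assert sum(assignment.sizes.values()) == len(profiles)

    def test_partition_stable_under_feature_permutation(self):
        profiles, _ = simulate_archetype_profiles(30, noise_sd=0.2, seed=6)
        a = kmeans_cluster(profiles, k=4, seed=0)
        rng = np.random.default_rng(0)
        shuffled = profiles.iloc[rng.permutation(len(profiles))]
        b = kmeans_cluster(shuffled, k=4, seed=0)
        joined = pd.concat([a.labels.rename("a"), b.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_k_larger_than_features_rejected(self):
        profiles, _ = simulate_archetype_profiles(1, noise_sd=0.0, seed=0)
        with pytest.raises(ValidationError):
            kmeans_cluster(profiles.iloc[:3], k=4, seed=0)


class TestArchetypeLabel:
    def test_definitional_mapping(self):
        centroids = pd.DataFrame(
            [[3, 2, 1, 0], [0, 3, 1, 0], [0, 1, 2, 3], [0, 0, 2, 3]],
            columns=list(STAGES))
        labels = archetype_label(centroids)
        assert labels[0] == "K1"
        assert labels[1] == "K4"
        assert labels[2] == "K3"   # steady rise = earlier
        assert labels[3] == "K2"   # late rise
        assert sorted(labels.values()) == ["K1", "K2", "K3", "K4"]

    def test_flat_centroids_warn_but_stay_deterministic(self):
        centroids = pd.DataFrame(np.zeros((4, 4)), columns=list(STAGES))
        with pytest.warns(UserWarning):
            labels = archetype_label(centroids)
        assert sorted(labels.values()) == ["K1", "K2", "K3", "K4"]

    def test_planted_archetypes_get_their_names_back(self):
        profiles, truth_labels = simulate_archetype_profiles(40, noise_sd=0.2, seed=8)
        assignment = kmeans_cluster(profiles, k=4, seed=0)
        named = assignment.archetype_labels()
        agreement = (named == truth_labels).mean()
        assert agreement >= 0.95

    def test_wrong_centroid_count_rejected(self):
        with pytest.raises(ValidationError):
            archetype_label(pd.DataFrame(np.zeros((3, 4)), columns=list(STAGES)))


class TestPipelineComparisons:
    def test_planted_de_recovery_with_bounded_fdr(self, dataset):
        truth = dataset.truth
        tables = run_comparisons(dataset.expression)
        sets = call_de_sets(tables)
        called_any = set()
        for s in sets.values():
            called_any |= s["up"] | s["down"]
        planted = set(truth.table.index[truth.table["archetype"] != "none"])
        recovered = len(planted & called_any) / len(planted)
        assert recovered >= 0.95
        # false discoveries: called features with flat planted profiles
        flat = {
            i for i in truth.table.index
            if truth.table.loc[i, "archetype"] == "none"
            and truth.table.loc[i, "trans_partner"] == ""
        }
        false_calls = called_any & flat
        assert len(false_calls) <= 0.1 * max(len(called_any), 1)
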