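import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from metabocomp import (
    BucketTable,
    consolidate,
    cophenetic_coefficient,
    cosine_distance_matrix,
    hierarchical_cluster,
    prominent_features,
    select_features,
    transform,
)
from metabocomp.errors import ValidationError


def table_of(rows, samples=None, features=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    features = features or [f"{100.0 + j:.4f}@1.00" for j in range(rows.shape[1])]
    return BucketTable(pd.DataFrame(rows, index=samples, columns=features))


def brute_force_cophenetic(merge_table, condensed, n):
    """Independent oracle: explicit merge-height lookup + Pearson formula."""
    members = {i: [i] for i in range(n)}
    heights = {}
    for k, (a, b, h, _size) in enumerate(merge_table):
        left, right = members[int(a)], members[int(b)]
        for x in left:
            for y in right:
                heights[(min(x, y), max(x, y))] = h
        members[n + k] = left + right
    coph = []
    for i in range(n):
        for j in range(i + 1, n):
            coph.append(heights[(i, j)])
    x, y = np.asarray(condensed), np.asarray(coph)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


class TestCosineDistance:
    def test_self_distance_zero(self):
        d = cosine_distance_matrix(table_of([[1, 2, 3], [1, 2, 3]]))
        assert d.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        d = cosine_distance_matrix(table_of([[1, 0], [0, 1]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_forty_five_degrees(self):
        d = cosine_distance_matrix(table_of([[1, 1], [1, 0]]))
        assert d.iloc[0, 1] == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)

    def test_scale_invariance_and_bounds(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 10, size=(4, 12))
        d1 = cosine_distance_matrix(table_of(base))
        scaled = base * np.array([[1.0], [7.5], [0.01], [100.0]])
        d2 = cosine_distance_matrix(table_of(scaled))
        assert np.allclose(d1.values, d2.values, atol=1e-10)
        assert (d1.values >= 0).all() and (d1.values <= 1 + 1e-12).all()
        assert np.allclose(d1.values, d1.values.T)

    def test_all_zero_row_is_named(self):
        with pytest.raises(ValidationError, match="dead"):
            cosine_distance_matrix(table_of([[0, 0], [1, 2]], samples=["dead", "ok"]))


@settings(derandomize=True, max_examples=50)
@given(
    arrays(np.float64, (3, 5), elements=st.floats(0.01, 1e4)),
    st.floats(0.001, 1e3),
)
def test_cosine_distance_scale_invariant_property(values, scale):
    d1 = cosine_distance_matrix(table_of(values))
    scaled = values.copy()
    scaled[0] *= scale
    d2 = cosine_distance_matrix(table_of(scaled))
    assert np.allclose(d1.values, d2.values, atol=1e-8)
    assert (d1.values >= -1e-12).all() and (d1.values <= 1 + 1e-12).all()


class TestHierarchicalCluster:
    def test_two_samples_one_merge(self):
        dist = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
        result = hierarchical_cluster(dist)
        assert result.merge_table.shape == (1, 4)
        assert result.merge_table[0, 2] == pytest.approx(0.4)

    def test_hand_upgma_three_samples(self):
        labels = ["A", "B", "C"]
        dist = pd.DataFrame(
            [[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]],
            index=labels, columns=labels,
        )
        result = hierarchical_cluster(dist)
        assert result.merge_table[0, 2] == pytest.approx(0.1)
        assert result.merge_table[1, 2] == pytest.approx(0.8)
        assert set(result.merge_table[0, :2]) == {0.0, 1.0}

    def test_newick_branch_lengths_are_half_merge_heights(self):
        dist = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
        newick = hierarchical_cluster(dist).newick
        assert newick == "(a:0.2,b:0.2);"

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.array([[0.0, 0.5], [0.4, 0.0]]))

    def test_groups_form_pure_subtrees(self, chemogeo_features, chemogeo_dataset):
        _, truth = chemogeo_dataset
        table = transform(consolidate(chemogeo_features, 0.01, 0.2), "tic")
        result = hierarchical_cluster(cosine_distance_matrix(table))
        assert groups_are_pure_subtrees(result, truth.groups)


def groups_are_pure_subtrees(result, groups):
    """Every group's members must merge together before any outsider joins."""
    n = len(result.leaf_labels)
    members = {i: {i} for i in range(n)}
    label_groups = [groups[s] for s in result.leaf_labels]
    want = {g: {i for i, lg in enumerate(label_groups) if lg == g}
            for g in set(label_groups)}
    seen_pure = set()
    for k, (a, b, _h, _s) in enumerate(result.merge_table):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        for g, idx in want.items():
            if merged == idx:
                seen_pure.add(g)
    return seen_pure == set(want)


class TestCopheneticCoefficient:
    def test_ultrametric_distances_fit_perfectly(self):
        labels = ["A", "B", "C"]
        dist = pd.DataFrame(
            [[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]],
            index=labels, columns=labels,
        )
        result = hierarchical_cluster(dist)
        assert cophenetic_coefficient(result, dist) == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        table = table_of(rng.uniform(0.1, 10, size=(6, 10)))
        dist = cosine_distance_matrix(table)
        result = hierarchical_cluster(dist)
        from scipy.spatial.distance import squareform
        condensed = squareform(dist.values, checks=False)
        oracle = brute_force_cophenetic(result.merge_table, condensed, 6)
        assert cophenetic_coefficient(result, dist) == pytest.approx(oracle, abs=1e-10)

    def test_undefined_for_two_samples(self):
        dist = pd.DataFrame([[0, 0.4], [0.4, 0]], index=["a", "b"], columns=["a", "b"])
        result = hierarchical_cluster(dist)
        with pytest.raises(ValidationError):
            cophenetic_coefficient(result, dist)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.1, 10, size=(7, 9))
        t1 = table_of(values)
        perm = rng.permutation(7)
        t2 = table_of(values[perm], samples=[f"s{i}" for i in perm])
        c1 = hierarchical_cluster(cosine_distance_matrix(t1)).cophenetic_coefficient
        c2 = hierarchical_cluster(cosine_distance_matrix(t2)).cophenetic_coefficient
        assert c1 == pytest.approx(c2, abs=1e-12)


class TestSelectFeatures:
    def planted_table(self):
        # 10 vs 10: large enough that a rank test's smallest attainable
        # p-value survives BH correction over ~50 features
        rng = np.random.default_rng(23)
        n1, n2, n_null = 10, 10, 50
        null = rng.lognormal(3, 0.5, size=(n1 + n2, n_null))
        planted = np.concatenate([100 + rng.normal(0, 1, n1), np.zeros(n2)])
        values = np.column_stack([planted, null])
        samples = [f"g1_{i}" for i in range(n1)] + [f"g2_{i}" for i in range(n2)]
        features = ["457.7850@12.40"] + [f"{200 + j:.4f}@5.00" for j in range(n_null)]
        groups = {s: ("saipan" if s.startswith("g1") else "guam") for s in samples}
        return table_of(values, samples=samples, features=features), groups

    def test_planted_driver_ranks_first(self):
        table, groups = self.planted_table()
        ranking = select_features(table, groups)
        assert ranking.frame.iloc[0]["feature_key"] == "457.7850@12.40"
        assert ranking.frame.iloc[0]["q_value"] < 0.05
        assert ranking.frame.iloc[0]["direction"] == "saipan"

    def test_exact_null_gives_zero_statistics(self):
        values = np.tile([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]], (1, 4))
        samples = [f"s{i}" for i in range(6)]
        groups = {s: ("a" if i < 3 else "b") for i, s in enumerate(samples)}
        ranking = select_features(table_of(values, samples=samples), groups)
        assert (ranking.frame["statistic"] == 0).all()
        assert (ranking.frame["q_value"] >= 0.05).all()

    def test_single_group_rejected(self):
        table, groups = self.planted_table()
        with pytest.raises(ValidationError):
            select_features(table, {s: "only" for s in table.sample_ids})

    def test_undersized_group_rejected(self):
        table, groups = self.planted_table()
        groups = dict(groups)
        groups[table.sample_ids[0]] = "loner"
        with pytest.raises(ValidationError):
            select_features(table, groups)


class TestProminentFeatures:
    def test_dominant_column_ranks_first(self):
        table = table_of([[1, 1000, 2], [3, 900, 1]])
        top = prominent_features(table, n=1)
        assert top.iloc[0]["feature_key"] == table.feature_keys[1]
        assert top.iloc[0]["summed_value"] == pytest.approx(1900.0)

    def test_requesting_all_returns_all_ordered(self):
        table = table_of([[5, 1, 3]])
        out = prominent_features(table, n=3)
        assert out["summed_value"].tolist() == [5.0, 3.0, 1.0]

    def test_oversized_n_is_clamped(self):
        table = table_of([[5, 1]])
        assert len(prominent_features(table, n=10)) == 2

    def test_region_specific_feature_tops_its_group(self):
        values = [[10, 5000], [12, 4500], [11, 0], [9, 0]]
        samples = ["sai_1", "sai_2", "gua_1", "gua_2"]
        features = ["200.0000@1.00", "457.7850@12.40"]
        groups = {"sai_1": "saipan", "sai_2": "saipan",
                  "gua_1": "guam", "gua_2": "guam"}
        table = table_of(values, samples=samples, features=features)
        out = prominent_features(table, n=1, per_group=groups)
        saipan_top = out[out["group"] == "saipan"].iloc[0]
        guam_top = out[out["group"] == "guam"].iloc[0]
        assert saipan_top["feature_key"] == "457.7850@12.40"
        assert saipan_top["gua_1"] == 0.0
        assert guam_top["feature_key"] == "200.0000@1.00"
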