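"""Cohort statistics against combinatorial and textbook oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from prmkit import (
    ConfusionMatrix,
    bh_adjust,
    brcc,
    brcc_critical,
    hierarchical_cluster,
    logit_transform,
    mann_whitney_u,
    mcc,
    method_comparison,
    pca,
    rank_test,
    roc,
)


class TestLogit:
    def test_half_maps_to_zero(self):
        assert logit_transform(0.5) == 0.0

    @given(st.floats(min_value=0.01, max_value=0.99))
    @settings(max_examples=30, derandomize=True)
    def test_antisymmetry(self, p):
        assert logit_transform(p) == pytest.approx(-logit_transform(1.0 - p))

    def test_boundaries_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            lo = logit_transform(0.0)
        assert lo == pytest.approx(math.log(1e-6 / (1 - 1e-6)))
        with pytest.raises(ValueError):
            logit_transform(1.5)


def bh_oracle(pvals):
    """Textbook step-up definition, written independently."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        val = min(prev, pvals[i] * m / rank_from_end)
        adjusted[i] = val
        prev = val
    return adjusted


class TestBhAdjust:
    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_and_single_values_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.7]) == pytest.approx([0.7])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    @settings(max_examples=50, derandomize=True)
    def test_matches_stepup_oracle_and_idempotent(self, pvals):
        adjusted = bh_adjust(pvals)
        assert adjusted == pytest.approx(bh_oracle(pvals), abs=1e-12)
        assert bh_adjust(adjusted) == pytest.approx(
            bh_oracle(adjusted), abs=1e-12
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def mcc_phi(cm):
    """Independent MCC via the phi-coefficient identity on the 2x2 table."""
    n = cm.tp + cm.tn + cm.fp + cm.fn
    x = np.array([1] * (cm.tp + cm.fp) + [0] * (cm.fn + cm.tn))  # predicted
    y = np.array(
        [1] * cm.tp + [0] * cm.fp + [1] * cm.fn + [0] * cm.tn
    )  # actual
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


class TestMcc:
    def test_derived_example(self):
        assert mcc(ConfusionMatrix(tp=2, tn=5, fp=1, fn=0)) == pytest.approx(
            0.7454, abs=1e-4
        )

    def test_perfect_and_degenerate(self):
        assert mcc(ConfusionMatrix(tp=4, tn=4, fp=0, fn=0)) == 1.0
        assert mcc(ConfusionMatrix(tp=0, tn=3, fp=0, fn=2)) == 0.0

    @given(st.tuples(*[st.integers(min_value=0, max_value=20)] * 4))
    @settings(max_examples=100, derandomize=True)
    def test_matches_phi_coefficient_identity(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
        assert mcc(cm) == pytest.approx(mcc_phi(cm), abs=1e-12)


class TestMannWhitney:
    def test_separation_extremes(self):
        assert mann_whitney_u([3, 4, 5], [1, 2]) == 0.0
        assert mann_whitney_u([1, 2], [3, 4, 5]) == 6.0

    def test_tie_counts_half(self):
        assert mann_whitney_u([1.0], [1.0]) == 0.5

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=8),
        st.lists(st.integers(0, 50), min_size=1, max_size=8),
    )
    @settings(max_examples=50, derandomize=True)
    def test_complements_scipy_u1(self, g1, g2):
        u2 = mann_whitney_u(g1, g2)
        u1 = sps.mannwhitneyu(g1, g2, alternative="two-sided").statistic
        assert u1 + u2 == pytest.approx(len(g1) * len(g2))


def brcc_critical_oracle(n1, n2, alpha):
    """Exhaustive oracle over explicit rank arrangements."""
    n = n1 + n2
    us = []
    for group2 in itertools.combinations(range(1, n + 1), n2):
        g1 = [r for r in range(1, n + 1) if r not in group2]
        u = sum(1 for a in g1 for b in group2 if b > a)
        us.append(u)
    us = np.array(us)
    best = None
    for u in range(n1 * n2 + 1):
        if np.mean(us <= u) <= alpha:
            best = u
    if best is None:
        raise ValueError("none significant")
    return 1 - 2 * best / (n1 * n2)


class TestBrcc:
    def test_extremes(self):
        assert brcc(0, 4, 3) == 1.0
        assert brcc(6, 4, 3) == 0.0
        assert brcc(12, 4, 3) == -1.0

    def test_published_small_cohort_critical_value(self):
        # groups of 8 and 2: the largest U with exact one-sided tail
        # probability <= 0.05 is U=1 (2 of 45 arrangements)
        r = brcc_critical(8, 2, 0.05)
        assert r == pytest.approx(0.875)
        assert round(r, 2) == 0.88

    @pytest.mark.parametrize(
        "n1,n2", [(2, 2), (3, 2), (4, 2), (5, 3), (6, 2), (8, 2), (6, 6), (8, 4)]
    )
    def test_matches_exhaustive_oracle(self, n1, n2):
        for alpha in (0.05, 0.1):
            try:
                expected = brcc_critical_oracle(n1, n2, alpha)
            except ValueError:
                with pytest.raises(ValueError):
                    brcc_critical(n1, n2, alpha)
            else:
                assert brcc_critical(n1, n2, alpha) == pytest.approx(expected)

    def test_rank_test_bundles_effect_size(self):
        rt = rank_test([1, 2, 3, 4, 5, 6, 7, 8], [9, 10])
        assert rt.u == 16.0  # group2 entirely above group1
        assert rt.r == -1.0
        assert rt.critical_r == pytest.approx(0.875)


class TestRoc:
    def test_perfect_separation(self):
        result = roc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert result.auc == 1.0
        assert result.youden_j == pytest.approx(1.0)

    def test_derived_example_with_one_inversion(self):
        result = roc([10, 9, 9.5, 8, 7, 6, 5, 4], [1, 1, 0, 0, 0, 0, 0, 0])
        assert result.auc == pytest.approx(11 / 12)
        assert result.sensitivity == pytest.approx(1.0)
        assert result.specificity == pytest.approx(5 / 6)
        assert result.youden_j == pytest.approx(5 / 6)

    def test_optimal_point_lies_on_curve(self):
        result = roc([10, 9, 9.5, 8, 7, 6, 5, 4], [1, 1, 0, 0, 0, 0, 0, 0])
        assert (result.best_threshold, result.sensitivity, result.specificity) in (
            result.points
        )

    @given(
        st.lists(st.integers(0, 30), min_size=1, max_size=10),
        st.lists(st.integers(0, 30), min_size=1, max_size=10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_auc_equals_mann_whitney_identity(self, neg, pos):
        scores = neg + pos
        labels = [0] * len(neg) + [1] * len(pos)
        result = roc(scores, labels)
        u = mann_whitney_u(pos, neg)  # pairs with a negative above a positive
        assert result.auc == pytest.approx(1.0 - u / (len(pos) * len(neg)))

    def test_lower_scores_can_call_positives(self):
        result = roc([1, 2, 8, 9], [1, 1, 0, 0], positive_direction="less")
        assert result.auc == 1.0

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1])


def average_linkage_oracle(data):
    """Brute-force agglomeration: merge the closest pair of clusters under
    mean pairwise correlation distance until one cluster remains."""
    d = 1 - np.corrcoef(data)
    clusters = [[i] for i in range(data.shape[0])]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([[d[a, b] for b in clusters[j]] for a in clusters[i]])
                if best is None or dist < best[0] - 1e-12:
                    best = (dist, i, j)
        dist, i, j = best
        merges.append((frozenset(clusters[i] + clusters[j]), dist))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return merges


class TestClustering:
    def test_duplicate_profiles_merge_first_at_zero_distance(self):
        data = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 1.0, 2.0]])
        # rows 0 and 1 are perfectly correlated -> distance 0
        result = hierarchical_cluster(data, n_clusters=2)
        assert result.flat[0] == result.flat[1] != result.flat[2]
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_profiles_at_distance_two(self):
        data = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        result = hierarchical_cluster(data)
        assert result.linkage[0, 2] == pytest.approx(2.0)

    def test_merge_tree_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            data = rng.normal(size=(5, 4))
            result = hierarchical_cluster(data)
            oracle = average_linkage_oracle(data)
            n = data.shape[0]
            members = {i: frozenset([i]) for i in range(n)}
            for k, row in enumerate(result.linkage):
                a, b, dist, _ = row
                merged = members[int(a)] | members[int(b)]
                members[n + k] = merged
                assert merged == oracle[k][0]
                assert dist == pytest.approx(oracle[k][1], abs=1e-9)

    def test_zero_variance_profile_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            hierarchical_cluster(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))


class TestPca:
    def test_collinear_data_loads_on_single_component(self):
        data = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
        result = pca(data, scale=False)
        assert result.percent_variance[0] == pytest.approx(100.0)

    def test_percent_variance_sums_to_hundred(self):
        rng = np.random.default_rng(3)
        result = pca(rng.normal(size=(8, 5)))
        assert result.percent_variance.sum() == pytest.approx(100.0)

    def test_explained_variance_invariant_under_rotation(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(10, 3)) @ np.diag([3.0, 1.0, 0.3])
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        a = pca(data, scale=False).percent_variance
        b = pca(data @ q, scale=False).percent_variance
        assert a == pytest.approx(b, abs=1e-8)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(5)
        data = rng.normal(size=(6, 4))
        r1, r2 = pca(data), pca(data.copy())
        assert np.allclose(r1.scores, r2.scores)
        for row in r1.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_constant_column_with_scaling_rejected(self):
        data = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="constant"):
            pca(data, scale=True)
        assert pca(data, scale=False).percent_variance[0] == pytest.approx(100.0)


def _method_frame(values):
    rows = []
    for (band, cell), reps in values.items():
        for i, v in enumerate(reps):
            rows.append({"band": band, "cell": cell, "replicate": i, "percent": v})
    return pd.DataFrame(rows)


class TestMethodComparison:
    BASE = {
        ("high", "lineA"): [60.0, 61.0, 59.0],
        ("low", "lineA"): [10.0, 10.5, 9.5],
        ("high", "lineB"): [55.0, 56.0, 54.0],
        ("low", "lineB"): [12.0, 12.5, 11.5],
    }

    def test_identical_methods_all_not_significant(self):
        out = method_comparison(_method_frame(self.BASE), _method_frame(self.BASE))
        assert list(out["label"]) == ["n.s."] * 4

    def test_large_offset_in_one_contrast_detected(self):
        shifted = {k: list(v) for k, v in self.BASE.items()}
        shifted[("low", "lineA")] = [35.0, 35.5, 34.5]  # synthetic discrepancy
        out = method_comparison(_method_frame(self.BASE), _method_frame(shifted))
        out = out.set_index(["band", "cell"])
        assert out.loc[("low", "lineA"), "label"] == "***"
        others = out.drop(index=("low", "lineA"))
        assert (others["label"] == "n.s.").all()

    def test_underreplicated_contrast_rejected(self):
        broken = {k: list(v) for k, v in self.BASE.items()}
        broken[("high", "lineB")] = [55.0]
        with pytest.raises(ValueError, match="2 replicates"):
            method_comparison(_method_frame(broken), _method_frame(broken))

    def test_mismatched_designs_rejected(self):
        other = {k: v for k, v in self.BASE.items() if k[0] == "high"}
        with pytest.raises(ValueError, match="factor"):
            method_comparison(_method_frame(self.BASE), _method_frame(other))
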