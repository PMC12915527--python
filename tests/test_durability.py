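"""Persistence calls, washout deltas with Wilcoxon, trajectory clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from durens import differential, durability, normalize
from durens.durability import (
    call_persistence,
    cluster_trajectories,
    persistence_fraction,
    washout_delta_stats,
    wilcoxon_signed_rank,
)
from durens.io_formats import CountMatrix, SampleDesign


def results_frame(rows):
    return pd.DataFrame(rows).set_index("feature_id")


def brute_wilcoxon(d):
    """Independent oracle: full enumeration of sign assignments on midranks."""
    d = [x for x in d if x != 0]
    r = rankdata(np.abs(d))
    w_obs = sum(ri for ri, di in zip(r, d) if di > 0)
    ws = [
        sum(ri for ri, s in zip(r, signs) if s)
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    ws = np.asarray(ws)
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(cdf, sf))


class TestPersistence:
    def test_zero_l2fc_with_small_fdr_is_persistent(self):
        res = {"media": results_frame([{"feature_id": "a", "l2fc": 0.0, "fdr": 0.001}])}
        calls = call_persistence(["a"], res)
        assert calls["persistent"].tolist() == [True]

    def test_failing_fdr_is_not_persistent(self):
        res = {"media": results_frame([{"feature_id": "a", "l2fc": 1.5, "fdr": 0.02}])}
        calls = call_persistence(["a"], res)
        assert calls["persistent"].tolist() == [False]

    def test_missing_induced_feature_errors(self):
        res = {"media": results_frame([{"feature_id": "a", "l2fc": 0.0, "fdr": 0.5}])}
        with pytest.raises(KeyError, match="b"):
            call_persistence(["a", "b"], res)

    def test_fraction_arithmetic(self):
        rows = [
            {"feature_id": f"f{i}", "l2fc": 1.0, "fdr": 0.001 if i < 13 else 0.5}
            for i in range(16)
        ]
        calls = call_persistence([r["feature_id"] for r in rows], {"media": results_frame(rows)})
        assert persistence_fraction(calls, "media") == pytest.approx(0.8125)

    def test_fraction_bounds_and_order_invariance(self):
        rows = [
            {"feature_id": f"f{i}", "l2fc": 1.0, "fdr": 0.001 if i % 2 else 0.9}
            for i in range(10)
        ]
        ids = [r["feature_id"] for r in rows]
        f1 = persistence_fraction(call_persistence(ids, {"m": results_frame(rows)}), "m")
        f2 = persistence_fraction(
            call_persistence(ids[::-1], {"m": results_frame(rows)}), "m"
        )
        assert f1 == f2 and 0.0 <= f1 <= 1.0

    def test_planted_persistent_and_decaying_recovered(self, durability_peaks):
        ds = durability_peaks
        design = ds.peak_design
        args = dict(shrinkage_weight=0.7)
        uns = design.samples_for("UNSTIM")
        disp = differential.estimate_dispersion(
            ds.peak_counts, uns, design.samples_for("IFNG_8H"), **args
        )
        res8 = differential.nb_exact_test(
            ds.peak_counts, uns, design.samples_for("IFNG_8H"), disp
        )
        induced = differential.call_induced(res8)
        washout = {}
        for treatment, cond in (("media", "WASH_MEDIA"), ("rux", "WASH_RUX")):
            d = differential.estimate_dispersion(
                ds.peak_counts, uns, design.samples_for(cond), **args
            )
            washout[treatment] = differential.nb_exact_test(
                ds.peak_counts, uns, design.samples_for(cond), d
            )
        calls = call_persistence(induced, washout)
        assert 0.45 <= persistence_fraction(calls, "media") <= 0.55
        assert persistence_fraction(calls, "rux") <= 0.1
        truth = ds.truth.peak_class
        media = calls[calls["washout_treatment"] == "media"].set_index("feature_id")
        planted = [f for f in induced if truth[f] == "persistent"]
        assert media.loc[planted, "persistent"].mean() >= 0.9


class TestWilcoxon:
    def test_all_positive_deltas_exact(self):
        _, p = wilcoxon_signed_rank([1, 1, 1, 1, 1])
        assert p == pytest.approx(2 / 2**5)

    def test_symmetric_deltas_give_p_one(self):
        _, p = wilcoxon_signed_rank([-2, -1, 0, 1, 2])
        assert p == pytest.approx(1.0)

    def test_too_few_nonzero_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0, 1.0])

    @pytest.mark.parametrize("n", [3, 5, 8, 12])
    @pytest.mark.parametrize("tied", [False, True])
    def test_matches_brute_force_enumeration(self, n, tied):
        rng = np.random.default_rng(n + 100 * tied)
        for _ in range(5):
            if tied:
                d = rng.integers(-3, 4, n).astype(float)
                if np.count_nonzero(d) < 2:
                    continue
            else:
                d = rng.normal(size=n)
            _, p = wilcoxon_signed_rank(d)
            assert p == pytest.approx(brute_wilcoxon(d), rel=1e-9)


def tiny_cpm(frame, conditions):
    samples = list(frame.columns)
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": samples,
                "condition": conditions,
                "washout_treatment": ["none"] * len(samples),
                "timepoint_h": [0.0] * len(samples),
                "replicate": [
                    1 + conditions[:i].count(conditions[i]) for i in range(len(samples))
                ],
            }
        )
    )
    return normalize.CpmMatrix(frame, design)


class TestWashoutDelta:
    def test_identical_conditions_undefined_p(self):
        frame = pd.DataFrame({"s0": [4.0, 8.0], "s1": [4.0, 8.0]}, index=["a", "b"])
        m = tiny_cpm(frame, ["pre", "post"])
        with pytest.raises(ValueError):
            washout_delta_stats(m, ["a", "b"], "pre", "post")

    def test_uniform_doubling(self):
        frame = pd.DataFrame(
            {"s0": [4.0, 8.0, 16.0, 32.0, 64.0], "s1": [8.0, 16.0, 32.0, 64.0, 128.0]},
            index=list("abcde"),
        )
        m = tiny_cpm(frame, ["pre", "post"])
        stats = washout_delta_stats(m, list("abcde"), "pre", "post")
        assert stats.mean_l2fc == pytest.approx(1.0)
        assert stats.pvalue == pytest.approx(2 / 2**5)


class TestClustering:
    def test_two_archetypes_recovered_exactly(self):
        rng = np.random.default_rng(0)
        n = 40
        up = np.array([10.0, 1000.0, 1000.0])
        down = np.array([10.0, 1000.0, 10.0])
        rows = np.vstack([up * rng.uniform(0.9, 1.1, (n // 2, 3)),
                          down * rng.uniform(0.9, 1.1, (n // 2, 3))])
        frame = pd.DataFrame(rows, columns=["c0", "c1", "c2"],
                             index=[f"f{i}" for i in range(n)])
        m = tiny_cpm(frame, ["A", "B", "C"])
        cl = cluster_trajectories(m, frame.index, ["A", "B", "C"], k=2, seed=0,
                                  order_condition="C")
        labels = cl.assignments
        assert set(labels.iloc[: n // 2]) == {0}  # persists at the endpoint
        assert set(labels.iloc[n // 2:]) == {1}

    def test_k1_centroid_is_mean_profile(self):
        frame = pd.DataFrame(
            {"s0": [1.0, 2.0, 8.0], "s1": [2.0, 8.0, 16.0]}, index=list("abc")
        )
        m = tiny_cpm(frame, ["A", "B"])
        cl = cluster_trajectories(m, list("abc"), ["A", "B"], k=1, seed=3)
        assert (cl.assignments == 0).all()
        # every row z-scores to the same two-point profile
        np.testing.assert_allclose(cl.centroids.to_numpy(), [[-1.0, 1.0]])

    def test_same_seed_reproduces_assignments(self, trajectory_peaks):
        ds = trajectory_peaks
        cpm = normalize.apply_pseudocount(normalize.cpm(ds.peak_counts))
        truth = ds.truth.peak_class
        ids = truth.index[truth != "null"][:300]
        conds = ["UNSTIM", "IFNG_8H", "WASH_MEDIA"]
        a = cluster_trajectories(cpm, ids, conds, k=3, seed=7, order_condition="WASH_MEDIA")
        b = cluster_trajectories(cpm, ids, conds, k=3, seed=7, order_condition="WASH_MEDIA")
        assert a.assignments.equals(b.assignments)

    def test_zero_variance_features_excluded(self):
        frame = pd.DataFrame({"s0": [5.0, 1.0], "s1": [5.0, 9.0]}, index=["flat", "var"])
        m = tiny_cpm(frame, ["A", "B"])
        cl = cluster_trajectories(m, ["flat", "var"], ["A", "B"], k=1, seed=0)
        assert cl.excluded == ["flat"]
        assert list(cl.assignments.index) == ["var"]

    def test_k_larger_than_features_rejected(self):
        frame = pd.DataFrame({"s0": [1.0, 2.0], "s1": [2.0, 1.0]}, index=["a", "b"])
        m = tiny_cpm(frame, ["A", "B"])
        with pytest.raises(ValueError):
            cluster_trajectories(m, ["a", "b"], ["A", "B"], k=5, seed=0)

    def test_three_washout_patterns_recovered(self, trajectory_peaks):
        ds = trajectory_peaks
        cpm = normalize.apply_pseudocount(normalize.cpm(ds.peak_counts))
        truth = ds.truth.peak_class
        ids = truth.index[truth.isin(["persistent", "decaying", "increasing"])]
        cl = cluster_trajectories(
            cpm, ids, ["UNSTIM", "IFNG_8H", "WASH_MEDIA"], k=3, seed=0,
            order_condition="WASH_MEDIA",
        )
        tab = pd.crosstab(cl.assignments, truth[cl.assignments.index])
        # deterministic relabeling: cluster 0 has the highest washout centroid
        assert tab.loc[0].idxmax() == "increasing"
        assert tab.loc[1].idxmax() == "persistent"
        assert tab.loc[2].idxmax() == "decaying"
        purity = tab.max(axis=1) / tab.sum(axis=1)
        assert (purity >= 0.8).all()
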