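"""The NB exact test: closed-form oracles, edgeR cross-check, calibration."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from durens import differential
from durens.differential import (
    DispersionEstimate,
    bh_fdr,
    call_induced,
    estimate_dispersion,
    nb_exact_test,
)
from durens.io_formats import CountMatrix, SampleDesign


def make_matrix(values, groups=("A", "A", "B", "B")):
    values = np.asarray(values)
    samples = [f"s{i}" for i in range(values.shape[1])]
    design = SampleDesign(
        pd.DataFrame(
            {
                "sample_id": samples,
                "condition": list(groups),
                "washout_treatment": ["none"] * len(samples),
                "timepoint_h": [0.0] * len(samples),
                "replicate": [
                    1 + list(groups)[:i].count(groups[i]) for i in range(len(samples))
                ],
            }
        )
    )
    cm = CountMatrix(
        pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])], columns=samples),
        design,
    )
    ref = [s for s, g in zip(samples, groups) if g == "A"]
    trt = [s for s, g in zip(samples, groups) if g == "B"]
    return cm, ref, trt


def fixed_dispersion(cm, phi):
    return DispersionEstimate(phi, pd.Series(phi, index=cm.counts.index), 1.0)


def binom_two_sided(y_obs, total, p):
    """Independent minimum-likelihood binomial oracle via math.comb."""
    pmf = [math.comb(total, y) * p**y * (1 - p) ** (total - y) for y in range(total + 1)]
    obs = pmf[y_obs]
    return min(1.0, sum(q for q in pmf if q <= obs * (1 + 1e-9)))


class TestDispersion:
    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(20, 200, 20)
        cm, ref, trt = make_matrix(rng.poisson(mu[:, None], (20, 6)), ["A"] * 3 + ["B"] * 3)
        d = estimate_dispersion(cm, ref, trt)
        assert d.common <= 0.05

    def test_nb_dispersion_recovered_within_band(self):
        rng = np.random.default_rng(1)
        mu = rng.uniform(20, 200, 200)
        lam = rng.gamma(1 / 0.4, 0.4 * mu[:, None], (200, 6))
        cm, ref, trt = make_matrix(rng.poisson(lam), ["A"] * 3 + ["B"] * 3)
        d = estimate_dispersion(cm, ref, trt)
        assert 0.2 <= d.common <= 0.6

    def test_single_replicate_falls_back_to_common(self):
        cm, ref, trt = make_matrix([[3, 9], [8, 2]], ["A", "B"])
        d = estimate_dispersion(cm, ref, trt)
        assert d.common == 0.0
        assert (d.blended == d.common).all()

    def test_blend_is_convex_combination(self):
        rng = np.random.default_rng(2)
        cm, ref, trt = make_matrix(rng.integers(5, 50, (30, 4)))
        d = estimate_dispersion(cm, ref, trt, shrinkage_weight=0.7)
        expected = (0.7 * d.common + 0.3 * d.per_feature).clip(lower=0)
        pd.testing.assert_series_equal(d.blended, expected)


class TestExactTest:
    def test_identical_counts_give_p_one_and_zero_l2fc(self):
        cm, ref, trt = make_matrix([[10, 10, 10, 10], [3, 3, 3, 3]])
        res = nb_exact_test(cm, ref, trt, fixed_dispersion(cm, 0.1))
        assert res["pvalue"].tolist() == [1.0, 1.0]
        assert res["l2fc"].tolist() == pytest.approx([0.0, 0.0])

    def test_extreme_split_matches_closed_form(self):
        # (0,0) vs (50,50) at dispersion 0: conditional binomial(100, 1/2),
        # and only the two endpoint outcomes are as unlikely as observed
        cm, ref, trt = make_matrix([[0, 0, 50, 50], [100, 100, 100, 100]])
        res = nb_exact_test(cm, ref, trt, fixed_dispersion(cm, 0.0))
        assert res["pvalue"].iloc[0] == pytest.approx(2 * 0.5**100, rel=1e-9)

    @pytest.mark.parametrize("case", range(6))
    def test_matches_independent_binomial_enumeration(self, case):
        rng = np.random.default_rng(case)
        y = rng.integers(0, 40, (3, 4))
        # equalize library sizes with a filler row so no depth scaling occurs
        tot = y.sum(axis=0)
        filler = tot.max() + 50 - tot
        cm, ref, trt = make_matrix(np.vstack([y, filler]))
        res = nb_exact_test(cm, ref, trt, fixed_dispersion(cm, 0.0))
        for i in range(3):
            y_ref = int(y[i, :2].sum())
            total = int(y[i].sum())
            expected = binom_two_sided(y_ref, total, 0.5)
            assert res["pvalue"].iloc[i] == pytest.approx(expected, rel=1e-9)

    def test_group_swap_negates_l2fc_and_keeps_p(self):
        rng = np.random.default_rng(7)
        cm, ref, trt = make_matrix(rng.integers(0, 60, (20, 4)))
        d = fixed_dispersion(cm, 0.15)
        fwd = nb_exact_test(cm, ref, trt, d)
        rev = nb_exact_test(cm, trt, ref, d)
        np.testing.assert_allclose(fwd["pvalue"], rev["pvalue"], rtol=1e-9)
        np.testing.assert_allclose(fwd["l2fc"], -rev["l2fc"], rtol=1e-9)

    def test_cpm_and_l2fc_invariant_under_depth_scaling(self):
        # multiplying every sample's counts by a constant leaves CPM, and
        # hence every fold change, exactly unchanged
        base = np.array([[10, 12, 30, 33], [50, 55, 20, 18], [5, 6, 5, 7]])
        tot = base.sum(axis=0)
        y1 = np.vstack([base, 200 - tot])
        y2 = y1 * 5
        cm1, ref, trt = make_matrix(y1)
        cm2, _, _ = make_matrix(y2)
        d1 = fixed_dispersion(cm1, 0.1)
        r1 = nb_exact_test(cm1, ref, trt, d1)
        r2 = nb_exact_test(cm2, ref, trt, d1)
        np.testing.assert_allclose(r1["l2fc"], r2["l2fc"], rtol=1e-12)
        np.testing.assert_allclose(r1["mean_cpm_ref"], r2["mean_cpm_ref"], rtol=1e-12)
        np.testing.assert_allclose(r1["mean_cpm_trt"], r2["mean_cpm_trt"], rtol=1e-12)

    def test_null_simulation_calibrated(self, null_peaks):
        ds = null_peaks
        design = ds.peak_design
        disp = estimate_dispersion(
            ds.peak_counts, design.samples_for("UNSTIM"), design.samples_for("IFNG_8H")
        )
        res = nb_exact_test(
            ds.peak_counts,
            design.samples_for("UNSTIM"),
            design.samples_for("IFNG_8H"),
            disp,
        )
        frac = float((res["pvalue"] < 0.05).mean())
        assert 0.01 <= frac <= 0.08

    def test_matches_edger_exact_test(self, tmp_path):
        """Cross-check against edgeR's conditional exact test (smallp rule)."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        rng = np.random.default_rng(42)
        mu = rng.uniform(20, 300, 40)
        lam = rng.gamma(1 / 0.2, 0.2 * mu[:, None], (40, 4))
        y = rng.poisson(lam)
        tot = y.sum(axis=0)
        y2 = np.vstack([y, tot.max() + 1000 - tot])  # equalize depths
        counts_path = tmp_path / "counts.tsv"
        np.savetxt(counts_path, y2, fmt="%d", delimiter="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"y <- as.matrix(read.table('{counts_path}'))\n"
            "d <- DGEList(counts=y, group=factor(c(1,1,2,2)))\n"
            "et <- exactTest(d, dispersion=0.2, rejection.region='smallp')\n"
            f"write.table(et$table$PValue, '{tmp_path}/p.txt', row.names=FALSE, col.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        edger_p = np.loadtxt(tmp_path / "p.txt")
        cm, ref, trt = make_matrix(y2)
        res = nb_exact_test(cm, ref, trt, fixed_dispersion(cm, 0.2))
        np.testing.assert_allclose(res["pvalue"].to_numpy(), edger_p, rtol=1e-4)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_all_ones_stay_one(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_monotone_in_sorted_order_and_bounded(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestCallInduced:
    def test_boundary_l2fc_excluded(self):
        res = pd.DataFrame({"l2fc": [2.0], "fdr": [0.001]}, index=["a"])
        assert len(call_induced(res)) == 0

    def test_clear_hit_included(self):
        res = pd.DataFrame({"l2fc": [3.0], "fdr": [0.005]}, index=["a"])
        assert list(call_induced(res)) == ["a"]

    def test_planted_induction_recovered(self, recovery_peaks):
        ds = recovery_peaks
        design = ds.peak_design
        disp = estimate_dispersion(
            ds.peak_counts, design.samples_for("UNSTIM"), design.samples_for("IFNG_8H")
        )
        res = nb_exact_test(
            ds.peak_counts,
            design.samples_for("UNSTIM"),
            design.samples_for("IFNG_8H"),
            disp,
        )
        called = set(call_induced(res))
        truth = ds.truth.peak_class
        planted = set(truth.index[truth == "persistent"])
        assert len(called & planted) / len(planted) >= 0.9
        assert len(called - planted) <= 5
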