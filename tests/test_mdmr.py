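import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fetalcwas import mdmr
from fetalcwas.exceptions import DesignError, InputError
from fetalcwas.mdmr import (
    cwas_scan,
    design_matrix,
    gower_center,
    manhattan_distances,
    mdmr_fit,
    screen_covariates,
)


def ols_f_r2(x, y):
    """Classical univariate regression F and R2 (closed form)."""
    res = stats.linregress(x, y)
    r2 = res.rvalue**2
    n = len(x)
    return r2 / (1 - r2) * (n - 2), r2


class TestManhattan:
    def test_worked_example(self):
        profiles = np.array([[0.1, 0.2], [0.3, -0.1]])
        d = manhattan_distances(profiles)
        assert d[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_identical_subjects(self):
        d = manhattan_distances(np.ones((3, 5)))
        np.testing.assert_array_equal(d, 0)

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        d = manhattan_distances(rng.normal(size=(6, 10)))
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_array_equal(np.diag(d), 0)

    def test_missing_values_rejected(self):
        p = np.ones((3, 2))
        p[1, 0] = np.nan
        with pytest.raises(InputError):
            manhattan_distances(p)


class TestGower:
    def test_zero_distances(self):
        np.testing.assert_array_equal(gower_center(np.zeros((4, 4))), 0)

    def test_trace_is_total_sum_of_squares(self):
        # points {0, 1, 2} on a line: sum (x - mean)^2 = 2
        x = np.array([0.0, 1.0, 2.0])
        d = np.abs(x[:, None] - x[None, :])
        assert np.trace(gower_center(d)) == pytest.approx(2.0, abs=1e-12)

    def test_rows_and_columns_sum_to_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(7, 3))
        d = manhattan_distances(pts)
        g = gower_center(d)
        np.testing.assert_allclose(g.sum(axis=0), 0, atol=1e-10)
        np.testing.assert_allclose(g.sum(axis=1), 0, atol=1e-10)


class TestMdmrFit:
    def test_matches_classical_regression(self):
        # Euclidean distance on a univariate response: pseudo-F/R2 must
        # equal the classical OLS F/R2
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 30
            x = rng.normal(size=n)
            y = 0.4 * x + rng.normal(size=n)
            d = np.abs(y[:, None] - y[None, :])
            design = pd.DataFrame({"intercept": np.ones(n), "x": x})
            res = mdmr_fit(d, design, factors=[], permutations=5, seed=0)
            f_ref, r2_ref = ols_f_r2(x, y)
            assert res[0].pseudo_f == pytest.approx(f_ref, abs=1e-8)
            assert res[0].pseudo_r2 == pytest.approx(r2_ref, abs=1e-8)

    def test_strong_effect_attains_minimum_p(self):
        rng = np.random.default_rng(3)
        n, b = 30, 99
        x = rng.normal(size=n)
        y = 5.0 * x + 0.01 * rng.normal(size=n)
        d = np.abs(y[:, None] - y[None, :])
        design = pd.DataFrame({"intercept": np.ones(n), "x": x})
        res = mdmr_fit(d, design, permutations=b, seed=1)
        assert res[0].p_perm == pytest.approx(1 / (b + 1))

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        n = 20
        feats = rng.normal(size=(n, 8))
        x = rng.normal(size=n)
        d = manhattan_distances(feats)
        design = pd.DataFrame({"intercept": np.ones(n), "x": x})
        f0 = mdmr_fit(d, design, factors=[], permutations=2, seed=0)[0].pseudo_f
        perm = rng.permutation(n)
        design_p = design.iloc[perm].reset_index(drop=True)
        f1 = mdmr_fit(
            d[np.ix_(perm, perm)], design_p, factors=[], permutations=2, seed=0
        )[0].pseudo_f
        assert f1 == pytest.approx(f0, abs=1e-10)

    def test_scale_invariance_of_pseudo_f(self):
        rng = np.random.default_rng(5)
        n = 15
        d = manhattan_distances(rng.normal(size=(n, 4)))
        design = pd.DataFrame({"intercept": np.ones(n), "x": rng.normal(size=n)})
        f1 = mdmr_fit(d, design, factors=[], permutations=2, seed=0)[0].pseudo_f
        f2 = mdmr_fit(7.3 * d, design, factors=[], permutations=2, seed=0)[0].pseudo_f
        assert f2 == pytest.approx(f1, abs=1e-10)

    def test_freedman_lane_conditions_on_nuisance(self):
        # factor p-value stays calibrated when a strong nuisance drives
        # the distances
        rng = np.random.default_rng(6)
        n = 40
        nuisance = rng.normal(size=n)
        factor = rng.normal(size=n)
        rejected = 0
        reps = 100
        for i in range(reps):
            rng_i = np.random.default_rng(100 + i)
            nuisance = rng_i.normal(size=n)
            factor = rng_i.normal(size=n)
            y = 3.0 * nuisance + rng_i.normal(size=n)
            d = np.abs(y[:, None] - y[None, :])
            design = pd.DataFrame(
                {"intercept": np.ones(n), "nuis": nuisance, "f": factor}
            )
            res = mdmr_fit(d, design, factors=["f"], permutations=99, seed=i)
            rejected += res[1].p_perm < 0.05
        assert rejected / reps < 0.12

    def test_null_pvalues_uniform(self):
        # Kolmogorov-Smirnov on null omnibus p-values
        pvals = []
        for i in range(300):
            rng = np.random.default_rng(500 + i)
            n = 20
            d = manhattan_distances(rng.normal(size=(n, 5)))
            design = pd.DataFrame(
                {"intercept": np.ones(n), "x": rng.normal(size=n)}
            )
            pvals.append(
                mdmr_fit(d, design, factors=[], permutations=99, seed=i)[0].p_perm
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_monotone_power_in_effect_size(self):
        mean_f = []
        for slope in (0.0, 0.3, 0.6):
            fs = []
            for i in range(50):
                rng = np.random.default_rng(900 + i)
                n = 30
                x = rng.normal(size=n)
                feats = rng.normal(size=(n, 6)) + slope * x[:, None]
                d = manhattan_distances(feats)
                design = pd.DataFrame({"intercept": np.ones(n), "x": x})
                fs.append(
                    mdmr_fit(d, design, factors=[], permutations=2, seed=i)[0].pseudo_f
                )
            mean_f.append(np.mean(fs))
        assert mean_f[0] < mean_f[1] < mean_f[2]

    def test_design_errors(self):
        n = 10
        d = manhattan_distances(np.random.default_rng(7).normal(size=(n, 3)))
        dup = pd.DataFrame(
            {"intercept": np.ones(n), "a": np.arange(n), "b": np.arange(n)}
        )
        with pytest.raises(DesignError):
            mdmr_fit(d, dup, permutations=2, seed=0)
        no_int = pd.DataFrame({"a": np.arange(n)})
        with pytest.raises(DesignError):
            mdmr_fit(d, no_int, permutations=2, seed=0)
        ok = pd.DataFrame({"intercept": np.ones(n), "a": np.arange(n)})
        with pytest.raises(InputError):
            mdmr_fit(d, ok, permutations=0, seed=0)
        with pytest.raises(DesignError):
            mdmr_fit(d, ok, factors=["zzz"], permutations=2, seed=0)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_against_vegan_adonis2(self, tmp_path):
        """Independent oracle: vegan's distance-based permutational ANOVA."""
        rng = np.random.default_rng(42)
        n = 25
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        feats = rng.normal(size=(n, 6)) + 0.4 * x1[:, None]
        d = manhattan_distances(feats)
        design = pd.DataFrame({"intercept": np.ones(n), "x1": x1, "x2": x2})
        res = mdmr_fit(d, design, factors=[], permutations=5, seed=0)
        np.savetxt(tmp_path / "d.csv", d, delimiter=",")
        pd.DataFrame({"x1": x1, "x2": x2}).to_csv(tmp_path / "x.csv", index=False)
        r_code = (
            'suppressMessages(library(vegan));'
            f'd <- as.dist(as.matrix(read.csv("{tmp_path}/d.csv", header=FALSE)));'
            f'x <- read.csv("{tmp_path}/x.csv");'
            'res <- adonis2(d ~ x1 + x2, data=x, permutations=9, by=NULL);'
            'cat(res$F[1], res$R2[1])'
        )
        out = subprocess.run(
            ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
        )
        f_ref, r2_ref = map(float, out.stdout.split())
        assert res[0].pseudo_f == pytest.approx(f_ref, rel=1e-5)
        assert res[0].pseudo_r2 == pytest.approx(r2_ref, rel=1e-5)


class TestCwasScan:
    def test_per_roi_row_count(self, small_null_cohort, small_labels):
        from tests_helpers import build_edge_matrix as edge_matrix_for

        em, _ = edge_matrix_for(small_null_cohort, small_labels)
        x = design_matrix(small_null_cohort.covariates, ["stai"])
        table = cwas_scan(
            em, x, mode="per_roi", factors=[], permutations=1, seed=0,
            roi_labels=small_labels,
        )
        omni = table[table["factor"] == "omnibus"]
        assert len(omni) == 30
        assert set(omni["unit"]) == set(small_labels)

    def test_planted_roi_ranks_high(self):
        from fetalcwas import connectome, synthetic

        labels = synthetic.roi_labels(30)
        hits = 0
        reps = 20
        for rep in range(reps):
            k = 7
            partners = [j for j in range(30) if j != k][:12]
            eff = synthetic.EffectSpec(
                "stai", tuple((k, j) for j in partners), slope_per_unit=0.02
            )
            spec = synthetic.CohortSpec(
                n_subjects=59, n_rois=30, n_modules=5, n_volumes=110,
                motion_spike_prob=0.0, effect_specs=(eff,), seed=3000 + rep,
            )
            cohort = synthetic.generate_cohort(spec)
            em = np.stack(
                [
                    connectome.vectorize_edges(
                        connectome.build_connectome(s.timeseries, labels)
                    ).values
                    for s in cohort.scans
                ]
            )
            x = design_matrix(cohort.covariates, ["stai"])
            table = cwas_scan(
                em, x, mode="per_roi", factors=[], permutations=1,
                seed=rep, roi_labels=labels,
            )
            omni = table[table["factor"] == "omnibus"].reset_index(drop=True)
            hits += omni["pseudo_F"].rank(ascending=False)[k] <= 3  # top decile
        assert hits / reps > 0.8

    def test_whole_connectome_single_row(self, small_null_cohort, small_labels):
        from tests_helpers import build_edge_matrix as edge_matrix_for

        em, _ = edge_matrix_for(small_null_cohort, small_labels)
        x = design_matrix(small_null_cohort.covariates, ["ssai", "stai"])
        table = cwas_scan(em, x, permutations=19, seed=0)
        assert list(table["factor"]) == ["omnibus", "ssai", "stai"]
        assert (table["unit"] == "whole_connectome").all()

    def test_single_subject_rejected(self):
        x = pd.DataFrame({"intercept": [1.0], "a": [0.5]})
        with pytest.raises(InputError):
            cwas_scan(np.ones((1, 3)), x, permutations=2, seed=0)


def test_screen_covariates_keeps_real_predictor():
    rng = np.random.default_rng(11)
    n = 40
    real = rng.normal(size=n)
    noise = rng.normal(size=n)
    feats = rng.normal(size=(n, 10)) + 1.0 * real[:, None]
    d = manhattan_distances(feats)
    cov = pd.DataFrame({"real": real, "noise": noise})
    kept = screen_covariates(d, cov, ["real", "noise"], permutations=199, seed=0)
    assert "real" in kept
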