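"""Threshold-liability Gibbs sampler: design building, truncated draws,
posterior summaries, and exactness against an independent quadrature oracle."""
import numpy as np
import pandas as pd
import pytest
from scipy.linalg import block_diag
from scipy.special import logsumexp
from scipy.stats import norm

from bchfkit.genotypes import GRM
from bchfkit.gblup import fit_gblup
from bchfkit.recovery import recovery_dataset
from bchfkit.threshold import (
    PosteriorSamples,
    ThresholdModelSpec,
    build_design,
    run_gibbs,
    sample_liabilities,
    summarize_posterior,
)


class TestSpec:
    def test_invalid_chain_settings(self):
        with pytest.raises(ValueError):
            ThresholdModelSpec(n_iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            ThresholdModelSpec(thinning=0)
        with pytest.raises(ValueError):
            ThresholdModelSpec(binary_trait=None, continuous_trait=None)


class TestBuildDesign:
    @staticmethod
    def pheno(**cols):
        base = {"id": [f"a{i}" for i in range(len(next(iter(cols.values()))))]}
        base.update(cols)
        return pd.DataFrame(base)

    def test_two_level_factor_gives_one_dummy(self):
        df = self.pheno(bchf=[0.0, 1.0, 0.0, 1.0], sex=["m", "f", "m", "f"])
        X, y_bin, _, rows = build_design(df, ThresholdModelSpec(fixed_effects=("sex",)))
        assert X.shape == (4, 2)  # intercept + 1 dummy
        assert np.array_equal(X[:, 0], np.ones(4))

    def test_score_three_animals_excluded_from_binary(self):
        df = self.pheno(bchf=[0.0, np.nan, 1.0], sex=["m", "m", "f"])
        X, y_bin, _, rows = build_design(df, ThresholdModelSpec(fixed_effects=()))
        assert rows.tolist() == [0, 2]
        # category coding: control=1, case=2
        assert y_bin.tolist() == [1.0, 2.0]

    def test_no_factors_gives_intercept_only(self):
        df = self.pheno(bchf=[0.0, 1.0, 1.0])
        X, _, _, _ = build_design(df, ThresholdModelSpec(fixed_effects=()))
        assert X.shape == (3, 1)

    def test_single_level_factor_dropped_with_warning(self):
        df = self.pheno(bchf=[0.0, 1.0, 0.0], ranch=["r1", "r1", "r1"])
        with pytest.warns(UserWarning, match="single level"):
            X, _, _, _ = build_design(df, ThresholdModelSpec(fixed_effects=("ranch",)))
        assert X.shape == (3, 1)


class TestLiabilitySampling:
    def test_truncation_contract_far_mean(self, rng):
        # control whose conditional mean sits far above the threshold
        draws = sample_liabilities(np.full(1000, 5.0), 1.0, np.zeros(1000, bool), rng)
        assert (draws < 0).all()

    def test_half_normal_mean(self, rng):
        draws = sample_liabilities(np.zeros(100_000), 1.0, np.ones(100_000, bool), rng)
        assert draws.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.01)

    def test_extreme_tail_is_finite_and_on_side(self, rng):
        draws = sample_liabilities(np.full(100, -40.0), 1.0, np.ones(100, bool), rng)
        assert np.isfinite(draws).all() and (draws > 0).all()

    def test_zero_residual_variance_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_liabilities(np.zeros(5), 0.0, np.ones(5, bool), rng)


class TestSummaries:
    def test_constant_samples_collapse(self):
        frame = pd.DataFrame({"h2_binary": np.full(200, 0.3)})
        out = summarize_posterior(frame)
        assert out.loc["h2_binary", "mean"] == pytest.approx(out.loc["h2_binary", "q2.5"], rel=1e-12)
        assert out.loc["h2_binary", "mean"] == pytest.approx(out.loc["h2_binary", "q97.5"], rel=1e-12)

    def test_ratio_of_means_reproduces_reported_heritability(self):
        assert 0.554 / (0.554 + 1.003) == pytest.approx(0.356, abs=5e-4)

    def test_normal_samples_match_theoretical_quantiles(self, rng):
        x = rng.normal(2.0, 0.5, 40_000)
        out = summarize_posterior(pd.DataFrame({"v": x}))
        assert out.loc["v", "q2.5"] == pytest.approx(2.0 - 1.959964 * 0.5, abs=0.02)
        assert out.loc["v", "q97.5"] == pytest.approx(2.0 + 1.959964 * 0.5, abs=0.02)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(pd.DataFrame({"v": np.ones(50)}))


# ---------------------------------------------------------------------------
# independent oracle: exact flat-prior posterior for equicorrelated families
# ---------------------------------------------------------------------------

def _log_marginal_by_casecount(fam_size, sg, r, b0, nq=61):
    x, w = np.polynomial.hermite_e.hermegauss(nq)
    logw = np.log(w) - 0.5 * np.log(2 * np.pi)
    tau = np.sqrt(r * sg)
    s = np.sqrt((1.0 - r) * sg + 1.0)
    z = (b0 + tau * x) / s
    lp, ln = norm.logcdf(z), norm.logcdf(-z)
    k = np.arange(fam_size + 1)[:, None]
    return logsumexp(k * lp[None, :] + (fam_size - k) * ln[None, :] + logw[None, :], axis=1)


def exact_posterior_mean_h2(case, fam_of, r, h2_grid, b0_grid):
    """Posterior mean of h2 by quadrature. The likelihood depends only on
    scale-free parameters, so the flat-(sigma_g, sigma_e, b0) posterior
    factorises into an improper scale walk times a proper h2 marginal with a
    flat prior on h2; that marginal is integrated here on the sigma_e = 1
    slice (sigma_g = h2 / (1 - h2))."""
    fam_size = np.bincount(fam_of).max()
    k_per_fam = np.array([int(case[fam_of == f].sum()) for f in np.unique(fam_of)])
    mult = np.bincount(k_per_fam, minlength=fam_size + 1)
    logpost = np.array(
        [
            [
                float(mult @ _log_marginal_by_casecount(fam_size, h2 / (1.0 - h2), r, b0))
                for b0 in b0_grid
            ]
            for h2 in h2_grid
        ]
    )
    post = np.exp(logpost - logpost.max()).sum(axis=1)
    post /= np.trapezoid(post, h2_grid)
    return float(np.trapezoid(post * h2_grid, h2_grid))


class TestGibbsExactness:
    def test_matches_quadrature_posterior_on_family_blocks(self):
        """The sampler's posterior mean h2 agrees with exact numerical
        integration of the same flat-prior posterior (family-block GRM)."""
        rng = np.random.default_rng(7)
        n_fam, fam, r, sg_true = 120, 5, 0.5, 0.554
        n = n_fam * fam
        fam_of = np.repeat(np.arange(n_fam), fam)
        liab = (
            rng.normal(0, np.sqrt(r * sg_true), n_fam)[fam_of]
            + rng.normal(0, np.sqrt((1 - r) * sg_true), n)
            + rng.standard_normal(n)
        )
        thr = np.quantile(liab, 0.8)
        case = liab > thr
        exact = exact_posterior_mean_h2(
            case, fam_of, r, np.linspace(0.005, 0.985, 70), np.linspace(-thr - 1, -thr + 1, 15)
        )
        blk = np.full((fam, fam), r)
        np.fill_diagonal(blk, 1.0)
        ids = np.array([f"A{i:05d}" for i in range(n)])
        pheno = pd.DataFrame({"id": ids, "bchf": case.astype(float)})
        grm = GRM(ids=ids, matrix=block_diag(*[blk] * n_fam), scale=1.0)
        spec = ThresholdModelSpec(fixed_effects=(), n_iterations=8000, burn_in=2000, seed=3)
        samples = run_gibbs(pheno, grm, spec)
        gibbs = float(samples.samples["h2_binary"].mean())
        assert gibbs == pytest.approx(exact, abs=0.08)

    def test_null_heritability_posterior_near_zero(self):
        pheno, grm, _ = recovery_dataset(5, n_individuals=1500, n_loci=3000, sigma2_g=0.0)
        spec = ThresholdModelSpec(fixed_effects=("sex",), n_iterations=4000, burn_in=1000, seed=1)
        samples = run_gibbs(pheno, grm, spec)
        assert samples.samples["h2_binary"].mean() < 0.1

    def test_posterior_sample_invariants_and_truncation(self):
        pheno, grm, _ = recovery_dataset(6, bivariate=True, n_individuals=400, n_loci=1500, n_sires=20)
        spec = ThresholdModelSpec(
            fixed_effects=("sex",), continuous_trait="continuous",
            n_iterations=1500, burn_in=500, seed=2,
        )
        samples = run_gibbs(pheno, grm, spec)  # truncation asserted at every stored sweep
        s = samples.samples
        assert ((s["h2_binary"] >= 0) & (s["h2_binary"] <= 1)).all()
        assert ((s["r_g"] >= -1) & (s["r_g"] <= 1)).all()
        assert ((s["r_e"] >= -1) & (s["r_e"] <= 1)).all()

    def test_case_control_label_swap_flips_genetic_covariance(self):
        pheno, grm, _ = recovery_dataset(
            9, bivariate=True, r_g=0.6, n_individuals=400, n_loci=1500, n_sires=20,
            case_fraction=0.3,
        )
        spec = ThresholdModelSpec(
            fixed_effects=(), continuous_trait="continuous",
            n_iterations=3000, burn_in=1000, seed=4,
        )
        fwd = run_gibbs(pheno, grm, spec).samples["cov_g"].mean()
        swapped = pheno.copy()
        swapped["bchf"] = 1.0 - swapped["bchf"]
        rev = run_gibbs(swapped, grm, spec).samples["cov_g"].mean()
        assert fwd > 0 and rev < 0

    def test_continuous_mode_agrees_with_reml(self):
        """With no truncation the model is a standard Bayesian animal model;
        its posterior-mean heritability tracks REML on the same data."""
        pheno, grm, truth = recovery_dataset(
            12, bivariate=True, n_individuals=800, n_loci=3000, n_sires=40
        )
        y = pheno["continuous"].to_numpy()
        reml = fit_gblup(y, grm).heritability
        spec = ThresholdModelSpec(
            binary_trait=None, continuous_trait="continuous", fixed_effects=("sex",),
            n_iterations=6000, burn_in=1500, seed=3,
        )
        post = run_gibbs(pheno, grm, spec).samples["h2_continuous"].mean()
        assert post == pytest.approx(reml, abs=0.05)

    def test_seed_determinism(self):
        pheno, grm, _ = recovery_dataset(3, n_individuals=200, n_loci=800, n_sires=10, case_fraction=0.3)
        spec = ThresholdModelSpec(fixed_effects=(), n_iterations=400, burn_in=100, seed=9)
        a = run_gibbs(pheno, grm, spec).samples
        b = run_gibbs(pheno, grm, spec).samples
        pd.testing.assert_frame_equal(a, b)

    def test_credible_interval_calibration(self):
        """Across independent datasets the 95% interval for h2 covers the
        generating value in at least 15 of 20 runs."""
        covered = 0
        for rep in range(20):
            pheno, grm, _ = recovery_dataset(
                100 + rep, n_individuals=600, n_loci=2000, n_sires=30
            )
            spec = ThresholdModelSpec(
                fixed_effects=("sex",), n_iterations=3000, burn_in=750, seed=rep
            )
            samples = run_gibbs(pheno, grm, spec)
            lo, hi = samples.credible_interval("h2_binary")
            covered += lo <= 0.356 <= hi
        assert covered >= 15
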