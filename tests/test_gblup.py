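"""GBLUP REML, EPDs and the cross-validation protocol."""
import numpy as np
import pytest

from bchfkit.gblup import fit_gblup, forward_validate, kfold_cv, reml_loglik
from bchfkit.genotypes import compute_grm, maf_filter, recode_genotypes
from bchfkit.recovery import recovery_dataset
from bchfkit.simulate import SimulationConfig, simulate_population


@pytest.fixture(scope="module")
def binary_family_data():
    """Heritable case/control data on a half-sib cohort (n=600)."""
    pheno, grm, truth = recovery_dataset(21, n_individuals=600, n_loci=2000, n_sires=30)
    y = pheno["bchf"].to_numpy(dtype=float)
    return y, grm, truth


class TestFit:
    def test_recovers_signal_from_heritable_data(self, binary_family_data):
        y, grm, truth = binary_family_data
        fit = fit_gblup(y, grm)
        bv = truth.true_breeding_values["liability"].to_numpy()
        r = np.corrcoef(fit.epd["epd"], bv)[0, 1]
        assert r > 0.3
        assert fit.sigma2_g > 0

    def test_accuracy_increases_with_sample_size(self):
        rs = {200: [], 900: []}
        for n in rs:
            for rep in range(3):
                pheno, grm, truth = recovery_dataset(
                    31 + rep, n_individuals=n, n_loci=2000, n_sires=max(10, n // 20)
                )
                fit = fit_gblup(pheno["bchf"].to_numpy(dtype=float), grm)
                bv = truth.true_breeding_values["liability"].to_numpy()
                rs[n].append(np.corrcoef(fit.epd["epd"], bv)[0, 1])
        assert np.mean(rs[900]) > np.mean(rs[200])

    def test_shuffled_response_kills_signal(self, binary_family_data, rng):
        y, grm, truth = binary_family_data
        fit = fit_gblup(rng.permutation(y), grm)
        bv = truth.true_breeding_values["liability"].to_numpy()
        assert fit.heritability < 0.1
        assert abs(np.corrcoef(fit.epd["epd"], bv)[0, 1]) < 0.15

    def test_gblup_equals_snp_blup_ridge(self):
        """GRM-based EPDs equal W times ridge-regression marker effects at
        the matched variance ratio (the GBLUP/SNP-BLUP identity)."""
        gm, _, truth = simulate_population(
            SimulationConfig(n_individuals=50, n_loci=220, seed=5,
                             genetic_covariance=0.5, residual_covariance=0.5)
        )
        rec = recode_genotypes(maf_filter(gm, 0.05))
        grm = compute_grm(rec)
        rng = np.random.default_rng(0)
        y = truth.true_breeding_values["liability"].to_numpy() + rng.normal(0, 0.7, 50)
        fit = fit_gblup(y, grm)
        W = rec.codes.astype(float) - rec.codes.mean(axis=0)
        lam = grm.scale * fit.sigma2_e / fit.sigma2_g
        alpha = np.linalg.solve(W.T @ W + lam * np.eye(W.shape[1]), W.T @ (y - fit.beta[0]))
        assert np.abs(W @ alpha - fit.epd["epd"].to_numpy()).max() < 1e-6

    def test_epd_invariant_to_response_shift(self, binary_family_data):
        y, grm, _ = binary_family_data
        a = fit_gblup(y, grm).epd["epd"].to_numpy()
        b = fit_gblup(y + 7.5, grm).epd["epd"].to_numpy()
        assert np.allclose(a, b, atol=1e-8)

    def test_training_epds_center_near_zero(self, binary_family_data):
        y, grm, _ = binary_family_data
        fit = fit_gblup(y, grm)
        assert abs(fit.epd.loc[fit.epd["in_training"], "epd"].mean()) < 0.02

    def test_reml_matches_brute_force_grid(self):
        """Spectral REML equals a dense-matrix profile-likelihood grid search
        (independent slogdet/solve implementation) to 3 significant figures."""
        pheno, grm, _ = recovery_dataset(8, n_individuals=200, n_loci=1200, n_sires=10)
        y = pheno["bchf"].to_numpy(dtype=float)
        fit = fit_gblup(y, grm)
        G = grm.matrix
        n = len(y)
        X = np.ones((n, 1))

        def dense_reml(h):
            V = h * G + (1.0 - h) * np.eye(n)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            rss = float(r @ Vi @ r)
            return -0.5 * (
                np.linalg.slogdet(V)[1]
                + (n - 1) * np.log(rss)
                + np.linalg.slogdet(XtViX)[1]
            )

        coarse = np.linspace(1e-4, 1 - 1e-4, 201)
        h0 = coarse[np.argmax([dense_reml(h) for h in coarse])]
        fine = np.linspace(max(h0 - 0.01, 1e-5), min(h0 + 0.01, 1 - 1e-5), 401)
        h_grid = fine[np.argmax([dense_reml(h) for h in fine])]
        ratio_fit = fit.sigma2_g / fit.sigma2_e
        ratio_grid = h_grid / (1.0 - h_grid)
        assert ratio_fit == pytest.approx(ratio_grid, rel=2e-3)

    def test_masked_animals_predicted(self, binary_family_data):
        y, grm, _ = binary_family_data
        y_masked = y.copy()
        y_masked[:50] = np.nan
        fit = fit_gblup(y_masked, grm)
        assert not fit.epd["in_training"].iloc[:50].any()
        assert np.isfinite(fit.epd["epd"]).all()


class TestForward:
    def test_disjoint_sets_required(self, binary_family_data):
        y, grm, _ = binary_family_data
        with pytest.raises(ValueError, match="disjoint"):
            forward_validate(y, grm, grm.ids[:100], grm.ids[50:150])

    def test_single_class_test_response_errors(self, binary_family_data):
        y, grm, _ = binary_family_data
        controls = np.flatnonzero(y == 0.0)
        test_ids = grm.ids[controls[:40]]
        train_ids = np.setdiff1d(grm.ids, test_ids)
        with pytest.raises(ValueError, match="zero-variance"):
            forward_validate(y, grm, train_ids, test_ids)

    def test_year_structured_prediction_is_positive(self):
        corrs = []
        for rep in range(3):
            pheno, grm, _ = recovery_dataset(60 + rep, n_individuals=700, n_loci=2000, n_sires=35)
            y = pheno["bchf"].to_numpy(dtype=float)
            # later-season test split: last 150 animals
            rep_corr = forward_validate(y, grm, grm.ids[:550], grm.ids[550:]).mean_correlation
            corrs.append(rep_corr)
        assert np.mean(corrs) > 0


class TestKfold:
    def test_leave_one_out_boundary(self):
        pheno, grm, _ = recovery_dataset(14, n_individuals=24, n_loci=400, n_sires=4, case_fraction=0.35)
        y = pheno["bchf"].to_numpy(dtype=float)
        report = kfold_cv(y, grm, k=24, seed=0)
        assert len(report.correlations) == 24

    def test_seed_determinism(self, binary_family_data):
        y, grm, _ = binary_family_data
        a = kfold_cv(y, grm, k=5, seed=3)
        b = kfold_cv(y, grm, k=5, seed=3)
        assert a.correlations == b.correlations
        assert a.mean_correlation == b.mean_correlation

    def test_single_class_fold_recorded_missing(self):
        pheno, grm, _ = recovery_dataset(15, n_individuals=60, n_loci=500, n_sires=6, case_fraction=0.35)
        y = np.zeros(60)
        y[:2] = 1.0  # nearly all controls: some folds lack cases
        with pytest.warns(UserWarning, match="single-class"):
            report = kfold_cv(y, grm, k=5, seed=1)
        assert any(c is None for c in report.correlations)

    def test_mean_correlation_matches_truth_parameter_oracle(self):
        """Mean k-fold test correlation agrees with a Monte Carlo oracle that
        predicts with the *generating* variance components via direct
        mixed-model algebra (no REML), within +-0.15."""
        ours, oracle = [], []
        for rep in range(8):
            pheno, grm, truth = recovery_dataset(70 + rep, n_individuals=500, n_loci=1500, n_sires=25)
            y = pheno["bchf"].to_numpy(dtype=float)
            ours.append(kfold_cv(y, grm, k=5, seed=rep).mean_correlation)
            # oracle: BLUP with true variance ratio on the observed scale
            p = y.mean()
            h2_obs = 0.554 * norm_pdf_sq_over_pq(p)
            lam = (1 - h2_obs) / max(h2_obs, 1e-6)
            rng = np.random.default_rng(rep)
            folds = rng.permutation(len(y)) % 5
            cs = []
            for f in range(5):
                te = folds == f
                tr = ~te
                G = grm.matrix
                V = G[np.ix_(tr, tr)] + lam * np.eye(int(tr.sum()))
                pred = G[np.ix_(te, tr)] @ np.linalg.solve(V, y[tr] - y[tr].mean())
                cs.append(np.corrcoef(pred, y[te])[0, 1])
            oracle.append(np.mean(cs))
        assert np.mean(ours) > 0
        assert np.mean(ours) == pytest.approx(np.mean(oracle), abs=0.15)

    def test_mean_correlation_monotone_in_heritability(self):
        """Predictive accuracy rises with simulated liability heritability."""
        means = []
        for h2 in (0.0, 0.15, 0.356, 0.6):
            sg = h2 / (1 - h2) if h2 < 1 else 1.0  # residual fixed at 1
            cs = []
            for rep in range(3):
                pheno, grm, _ = recovery_dataset(
                    40 + rep, n_individuals=500, n_loci=1500, n_sires=25, sigma2_g=max(sg, 1e-9)
                )
                y = pheno["bchf"].to_numpy(dtype=float)
                cs.append(kfold_cv(y, grm, k=5, seed=rep).mean_correlation)
            means.append(np.mean(cs))
        assert means[0] < means[2] and means[1] <= means[2] + 0.03 and means[2] <= means[3] + 0.03
        assert means[3] > means[0]


def norm_pdf_sq_over_pq(p):
    """phi(z_p)^2 / (p (1-p)): observed-scale conversion factor for a
    binary trait at incidence p under the liability model."""
    from scipy.stats import norm

    z = norm.ppf(1 - p)
    return norm.pdf(z) ** 2 / (p * (1 - p))
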