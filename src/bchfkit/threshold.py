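"""Bayesian threshold-liability animal model with genomic relationships.

The model is the classic bivariate threshold-linear animal model: a latent
liability I underlies the binary BCHF status (control = 1, case = 2 in the
category coding), with

    [y_trait, I_bchf]' ~ N(X b + Z u, I (x) R),   u ~ N(0, G0 (x) G)

where G is the genomic relationship matrix, G0 the 2x2 genetic covariance and
R the 2x2 residual covariance. The threshold is fixed at t1 = 0; the second
threshold of the two-category display is +inf and not a free parameter.

Binary records carry no information about the absolute liability scale, so
the scale is treated as a gauge freedom rather than a parameter:

* univariate binary model -- total liability variance is pinned to 1
  (s2_g = h2, s2_e = 1 - h2) with a flat prior on h2, and each sweep draws
  (h2, u) as one block: h2 by inverse CDF of its breeding-value-marginalised
  conditional over the GRM eigen-spectrum, then u from its full
  conditional (a partially collapsed Gibbs step);
* bivariate threshold-linear model -- the full genetic and residual
  covariances are sampled from inverse-Wishart full conditionals under the
  flat-prior limit, and the binary block is renormalised each sweep so its
  total variance is 1. The likelihood is exactly invariant under that
  renormalisation; h2, r_g and r_e are scale-free ratios.

Liabilities are drawn from truncated-normal full conditionals (data
augmentation), fixed effects from their normal conditionals, and breeding
values as one block in the eigenbasis of G, where the conditional precision
is diagonal (2x2 per eigencomponent), so a full sweep costs a few dense
mat-vecs. The continuous-only mode is a standard Bayesian animal model with
scaled-inverse-chi-square variance conditionals.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from .genotypes import GRM
from .utils import rng_from, sample_one_sided_truncnorm

__all__ = [
    "ThresholdModelSpec",
    "PosteriorSamples",
    "build_design",
    "sample_liabilities",
    "run_gibbs",
    "summarize_posterior",
]

RIDGE = 1e-6


@dataclasses.dataclass
class ThresholdModelSpec:
    """Chain and model settings. Defaults follow the analysis protocol:
    50,000 iterations, 10,000 burn-in, every post-burn-in sample stored."""

    binary_trait: str | None = "bchf"
    continuous_trait: str | None = None
    fixed_effects: Sequence[str] = ("ranch", "harvest_date", "sex")
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.binary_trait is None and self.continuous_trait is None:
            raise ValueError("at least one response trait is required")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclasses.dataclass
class PosteriorSamples:
    """Stored post-burn-in draws of (co)variances and derived summaries."""

    samples: pd.DataFrame
    spec: ThresholdModelSpec
    posterior_mean_u: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.samples)

    def credible_interval(self, param: str, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        x = self.samples[param].to_numpy()
        return float(np.quantile(x, a)), float(np.quantile(x, 1.0 - a))


def build_design(phenotypes: pd.DataFrame, spec: ThresholdModelSpec):
    """Design matrices and responses for the sampler.

    Returns ``(X, y_binary, y_continuous, row_index)``. Rows are animals with
    a usable response: binary analyses keep animals whose status is 0/1
    (heart-score-3 animals are excluded by construction of the status
    column); a missing continuous record is allowed in the bivariate model
    (it is augmented during sampling). X is full rank: intercept plus
    reference-level-dropped dummies; single-level factors are dropped with a
    warning.
    """
    df = phenotypes.reset_index(drop=True)
    if spec.binary_trait is not None:
        b = df[spec.binary_trait].to_numpy(dtype=np.float64)
        rows = np.flatnonzero(np.isin(b, (0.0, 1.0)))
    else:
        c = df[spec.continuous_trait].to_numpy(dtype=np.float64)
        rows = np.flatnonzero(~np.isnan(c))
    sub = df.iloc[rows]
    cols = [np.ones(len(sub))]
    for f in spec.fixed_effects:
        levels = pd.unique(sub[f])
        if len(levels) < 2:
            warnings.warn(f"fixed effect {f!r} has a single level and was dropped", stacklevel=2)
            continue
        dummies = pd.get_dummies(sub[f].astype(str), drop_first=True, dtype=np.float64)
        cols.append(dummies.to_numpy())
    X = np.column_stack(cols)
    y_bin = None
    if spec.binary_trait is not None:
        # category coding: control = 1, case = 2
        y_bin = sub[spec.binary_trait].to_numpy(dtype=np.float64) + 1.0
    y_cont = None
    if spec.continuous_trait is not None:
        y_cont = sub[spec.continuous_trait].to_numpy(dtype=np.float64)
    return X, y_bin, y_cont, rows


def sample_liabilities(
    mean: np.ndarray,
    sd: float | np.ndarray,
    case: np.ndarray,
    rng: np.random.Generator,
    threshold: float = 0.0,
) -> np.ndarray:
    """Draw latent liabilities from their truncated-normal full conditionals:
    cases above the threshold, controls below it."""
    return sample_one_sided_truncnorm(mean, sd, threshold, np.asarray(case, dtype=bool), rng)


def _eigen_grm(grm: GRM, ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = grm.align(ids)
    d, U = np.linalg.eigh(sub.matrix)
    if d.min() < RIDGE:
        warnings.warn("GRM is singular to tolerance; adding 1e-6 ridge", stacklevel=3)
    d = np.maximum(d + RIDGE, RIDGE)
    return d, U


def _sample_beta(XtX_chol_inv, X, target, resid_var, rng):
    """beta | rest  ~  N((X'X)^-1 X' target, resid_var (X'X)^-1)."""
    bhat = XtX_chol_inv @ (XtX_chol_inv.T @ (X.T @ target))
    z = rng.standard_normal(X.shape[1])
    return bhat + np.sqrt(resid_var) * (XtX_chol_inv @ z)


def run_gibbs(phenotypes: pd.DataFrame, grm: GRM, spec: ThresholdModelSpec) -> PosteriorSamples:
    """Run the Gibbs sampler and return stored posterior samples.

    Modes: binary-only (univariate liability model), continuous-only (a
    standard Bayesian animal model, no truncation), or bivariate
    threshold-linear.
    """
    X, y_bin, y_cont, rows = build_design(phenotypes, spec)
    ids = phenotypes.reset_index(drop=True).loc[rows, "id"].to_numpy() if "id" in phenotypes.columns else np.asarray(rows)
    n, p = X.shape
    if n < p + 5:
        raise ValueError("too few records for the fixed-effect design")
    d, U = _eigen_grm(grm, ids)
    rng = rng_from(spec.seed, "gibbs")

    XtX = X.T @ X
    XtX_chol_inv = np.linalg.inv(np.linalg.cholesky(XtX)).T  # upper-tri: (X'X)^-1 = A A'

    bivariate = spec.binary_trait is not None and spec.continuous_trait is not None
    binary_only = spec.binary_trait is not None and spec.continuous_trait is None
    if spec.binary_trait is not None:
        case = y_bin == 2.0
        if case.all() or not case.any():
            raise ValueError("binary response needs both cases and controls")
    if spec.continuous_trait is not None:
        miss = np.isnan(y_cont)
        if bivariate:
            y2 = np.where(miss, 0.0, y_cont)
        else:
            if miss.any():
                raise ValueError("continuous-only mode requires complete records")
            y2 = y_cont.copy()

    n_store = (spec.n_iterations - spec.burn_in) // spec.thinning
    records: list[dict] = []
    u_accum = None

    if binary_only:
        # The liability scale is not identified by binary data, so it is
        # gauge-fixed: total variance 1, s2_g = h2, s2_e = 1 - h2, flat prior
        # on h2 in (0, 1). Each sweep draws (h2, u) as one block via a
        # partially collapsed step: h2 comes from its conditional given
        # (liabilities, fixed effects) with breeding values integrated out --
        # a 1-D density over the GRM eigen-spectrum sampled by inverse CDF on
        # a grid -- and u is then redrawn from its full conditional. This
        # avoids both the scale-ridge random walk of unconstrained variance
        # sampling and the near-absorbing slow mixing of (u, variance)
        # single-site updates.
        b1 = np.zeros(p)
        u1 = np.zeros(n)
        h2 = 0.25
        liab = np.where(case, 0.5, -0.5)
        h2_grid = (np.arange(1, 257) - 0.5) / 256.0
        # collapsed conditional: l - X b ~ N(0, h2 (G - I) + I); the grid of
        # eigen-variances is sweep-independent, so precompute its log-dets
        w = np.outer(h2_grid, d - 1.0) + 1.0  # (grid, n) variances
        logdet_w = np.log(w).sum(axis=1)
        winv_t = (1.0 / w).T  # (n, grid)
        for it in range(spec.n_iterations):
            se2 = 1.0 - h2
            mu = X @ b1 + u1
            liab = sample_one_sided_truncnorm(mu, np.sqrt(se2), 0.0, case, rng)
            b1 = _sample_beta(XtX_chol_inv, X, liab - u1, se2, rng)
            rt = U.T @ (liab - X @ b1)
            logp = -0.5 * (logdet_w + (rt * rt) @ winv_t)
            dens = np.exp(logp - logp.max())
            cdf = np.cumsum(dens)
            h2 = float(np.interp(rng.uniform(0.0, cdf[-1]), cdf, h2_grid))
            se2 = 1.0 - h2
            var_i = 1.0 / (1.0 / se2 + 1.0 / (h2 * d))
            ut = var_i * rt / se2 + np.sqrt(var_i) * rng.standard_normal(n)
            u1 = U @ ut
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
                _assert_truncation(liab, case)
                records.append({"var_g_binary": h2, "var_e_binary": 1.0 - h2, "h2_binary": h2})
                u_accum = u1.copy() if u_accum is None else u_accum + u1
    elif not bivariate:  # continuous-only animal model
        b2 = np.zeros(p)
        u2 = np.zeros(n)
        vy = float(np.var(y2))
        sg2, se2 = 0.5 * vy, 0.5 * vy
        for it in range(spec.n_iterations):
            b2 = _sample_beta(XtX_chol_inv, X, y2 - u2, se2, rng)
            rt = U.T @ (y2 - X @ b2)
            var_i = 1.0 / (1.0 / se2 + 1.0 / (sg2 * d))
            ut = var_i * rt / se2 + np.sqrt(var_i) * rng.standard_normal(n)
            u2 = U @ ut
            S = float(np.sum(ut * ut / d))
            sg2 = S / rng.chisquare(n - 2)
            res = y2 - X @ b2 - u2
            se2 = float(res @ res) / rng.chisquare(n - 2)
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
                records.append(
                    {
                        "var_g_continuous": sg2,
                        "var_e_continuous": se2,
                        "h2_continuous": sg2 / (sg2 + se2),
                    }
                )
                u_accum = u2.copy() if u_accum is None else u_accum + u2
    else:
        records = _run_bivariate(X, case, y2, miss, d, U, XtX_chol_inv, spec, rng)

    if not records:
        raise RuntimeError("no samples stored; check chain settings")
    frame = pd.DataFrame.from_records(records)
    if not np.isfinite(frame.to_numpy()).all():
        raise RuntimeError("divergent chain: non-finite state encountered")
    pm_u = None
    if u_accum is not None:
        pm_u = pd.DataFrame({"id": ids, "epd": u_accum / len(records)})
    return PosteriorSamples(samples=frame, spec=spec, posterior_mean_u=pm_u)


def _assert_truncation(liab: np.ndarray, case: np.ndarray) -> None:
    # hard invariant: stored liabilities sit strictly on their side of t1=0
    if not (liab[case] > 0.0).all() or not (liab[~case] < 0.0).all():
        raise AssertionError("liability truncation violated")


def _run_bivariate(X, case, y2, miss, d, U, XtX_chol_inv, spec, rng) -> list[dict]:
    """Bivariate threshold-linear sweep with the full 2x2 residual covariance
    sampled from its inverse-Wishart full conditional (threshold fixed at 0;
    all reported quantities are scale-invariant ratios)."""
    n, p = X.shape
    b1, b2 = np.zeros(p), np.zeros(p)
    u = np.zeros((n, 2))
    vy = max(float(np.var(y2[~miss])) if (~miss).any() else 1.0, 1e-3)
    G0 = np.diag([0.5, 0.5 * vy])
    R0 = np.diag([1.0, vy])
    liab = np.where(case, 0.5, -0.5)
    y2a = y2.copy()
    records: list[dict] = []
    for it in range(spec.n_iterations):
        r11, r12, r22 = R0[0, 0], R0[0, 1], R0[1, 1]
        # 1. liabilities: conditional on the continuous-trait residual
        e2 = y2a - X @ b2 - u[:, 1]
        m = X @ b1 + u[:, 0] + (r12 / r22) * e2
        s = np.sqrt(max(r11 - r12 * r12 / r22, 1e-10))
        liab = sample_one_sided_truncnorm(m, s, 0.0, case, rng)
        # 2. augment missing continuous records from e2 | e1
        e1 = liab - X @ b1 - u[:, 0]
        if miss.any():
            nm = int(miss.sum())
            cv = np.sqrt(max(r22 - r12 * r12 / r11, 1e-10))
            y2a[miss] = (
                X[miss] @ b2 + u[miss, 1] + (r12 / r11) * e1[miss] + cv * rng.standard_normal(nm)
            )
        # 3. fixed effects, trait-wise conditionals under correlated residuals
        cv1 = max(r11 - r12 * r12 / r22, 1e-10)
        t1 = liab - u[:, 0] - (r12 / r22) * (y2a - X @ b2 - u[:, 1])
        b1 = _sample_beta(XtX_chol_inv, X, t1, cv1, rng)
        cv2 = max(r22 - r12 * r12 / r11, 1e-10)
        t2 = y2a - u[:, 1] - (r12 / r11) * (liab - X @ b1 - u[:, 0])
        b2 = _sample_beta(XtX_chol_inv, X, t2, cv2, rng)
        # 4. breeding values, blocked in the GRM eigenbasis
        R0i = np.linalg.inv(R0)
        G0i = np.linalg.inv(G0)
        resid = np.column_stack([liab - X @ b1, y2a - X @ b2])
        Rt = U.T @ resid  # (n, 2)
        # per-eigencomponent 2x2 precision P_i = R0^-1 + G0^-1 / d_i
        a = R0i[0, 0] + G0i[0, 0] / d
        b_ = R0i[0, 1] + G0i[0, 1] / d
        c = R0i[1, 1] + G0i[1, 1] / d
        det = a * c - b_ * b_
        c11, c12, c22 = c / det, -b_ / det, a / det
        rhs1 = R0i[0, 0] * Rt[:, 0] + R0i[0, 1] * Rt[:, 1]
        rhs2 = R0i[1, 0] * Rt[:, 0] + R0i[1, 1] * Rt[:, 1]
        m1 = c11 * rhs1 + c12 * rhs2
        m2 = c12 * rhs1 + c22 * rhs2
        l11 = np.sqrt(c11)
        l21 = c12 / l11
        l22 = np.sqrt(np.maximum(c22 - l21 * l21, 1e-12))
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        ut1 = m1 + l11 * z1
        ut2 = m2 + l21 * z1 + l22 * z2
        u[:, 0] = U @ ut1
        u[:, 1] = U @ ut2
        # 5. genetic covariance: inverse-Wishart full conditional (flat-prior limit)
        S = np.empty((2, 2))
        S[0, 0] = np.sum(ut1 * ut1 / d)
        S[0, 1] = S[1, 0] = np.sum(ut1 * ut2 / d)
        S[1, 1] = np.sum(ut2 * ut2 / d)
        G0 = invwishart.rvs(df=n - 3, scale=S, random_state=rng)
        # 6. full residual covariance from its inverse-Wishart conditional
        E = np.column_stack([liab - X @ b1 - u[:, 0], y2a - X @ b2 - u[:, 1]])
        R0 = invwishart.rvs(df=n - 3, scale=E.T @ E, random_state=rng)
        # 7. gauge renormalisation: binary data leave the liability scale
        # free, so pin total binary variance to 1 each sweep. The likelihood
        # is exactly invariant along this direction; all ratios (h2, r_g,
        # r_e) are untouched and the otherwise-unbounded scale random walk
        # cannot accumulate.
        c = 1.0 / np.sqrt(G0[0, 0] + R0[0, 0])
        liab *= c
        u[:, 0] *= c
        b1 *= c
        G0[0, 0] *= c * c
        G0[0, 1] = G0[1, 0] = G0[0, 1] * c
        R0[0, 0] *= c * c
        R0[0, 1] = R0[1, 0] = R0[0, 1] * c
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
            _assert_truncation(liab, case)
            records.append(
                {
                    "var_g_binary": G0[0, 0],
                    "var_g_continuous": G0[1, 1],
                    "cov_g": G0[0, 1],
                    "var_e_binary": R0[0, 0],
                    "var_e_continuous": R0[1, 1],
                    "cov_e": R0[0, 1],
                    "h2_binary": G0[0, 0] / (G0[0, 0] + R0[0, 0]),
                    "h2_continuous": G0[1, 1] / (G0[1, 1] + R0[1, 1]),
                    "r_g": G0[0, 1] / np.sqrt(G0[0, 0] * G0[1, 1]),
                    "r_e": R0[0, 1] / np.sqrt(R0[0, 0] * R0[1, 1]),
                }
            )
    return records


def summarize_posterior(samples: PosteriorSamples | pd.DataFrame) -> pd.DataFrame:
    """Posterior mean and empirical 2.5/97.5 percentiles per parameter."""
    frame = samples.samples if isinstance(samples, PosteriorSamples) else samples
    if len(frame) < 100:
        raise ValueError("need at least 100 stored samples to summarise")
    out = pd.DataFrame(
        {
            "mean": frame.mean(),
            "q2.5": frame.quantile(0.025),
            "q97.5": frame.quantile(0.975),
        }
    )
    out.index.name = "parameter"
    return out
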