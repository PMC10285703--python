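"""GBLUP on the observed 0/1 case/control scale: REML variance components,
EPD prediction, and forward / k-fold cross-validation.

The model is y = X b + g + e with g ~ N(0, s2_g G) for a genomic
relationship matrix G. REML works in the eigenbasis of G: for a candidate
heritability h the covariance is diagonal with weights h*d_i + (1-h), the
total variance profiles out analytically, and a bounded 1-D optimisation of
the restricted likelihood finds h. EPDs are the BLUPs of g; animals with a
masked phenotype are predicted through the GRM cross-block, which is how the
cross-validation schemes mask test splits.

The binary response is deliberately modelled on the observed scale with a
linear model (matching the published protocol); the threshold module is the
liability-correct alternative.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotypes import GRM
from .utils import rng_from

__all__ = [
    "GblupFit",
    "CvReport",
    "reml_loglik",
    "fit_gblup",
    "forward_validate",
    "kfold_cv",
]


@dataclasses.dataclass
class GblupFit:
    """REML variance components and EPDs (GBLUP random-effect solutions)."""

    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    epd: pd.DataFrame  # columns: id, epd, in_training
    loglik: float

    @property
    def heritability(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


@dataclasses.dataclass
class CvReport:
    scheme: str
    correlations: list
    split_sizes: list
    seed: int | None

    def __post_init__(self) -> None:
        finite = [c for c in self.correlations if c is not None and np.isfinite(c)]
        if any(abs(c) > 1 + 1e-12 for c in finite):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def mean_correlation(self) -> float:
        finite = [c for c in self.correlations if c is not None and np.isfinite(c)]
        if not finite:
            raise ValueError("no fold produced a defined correlation")
        return float(np.mean(finite))


def reml_loglik(h: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> float:
    """Restricted log-likelihood at heritability ``h`` (total variance
    profiled out), in the GRM eigenbasis: weights w = h d + (1 - h)."""
    n, p = Xr.shape
    w = h * d + (1.0 - h)
    wi = 1.0 / w
    XtWX = (Xr * wi[:, None]).T @ Xr
    XtWy = (Xr * wi[:, None]).T @ yr
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r @ (wi * r))
    _, ld_xwx = np.linalg.slogdet(XtWX)
    return -0.5 * (np.sum(np.log(w)) + (n - p) * np.log(rss) + ld_xwx)


def _reml_fit(d: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    res = minimize_scalar(
        lambda h: -reml_loglik(h, d, yr, Xr),
        bounds=(1e-6, 1.0 - 1e-6),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:  # pragma: no cover - bounded Brent rarely fails
        raise RuntimeError(f"REML optimisation did not converge: {res.message}")
    h = float(res.x)
    n, p = Xr.shape
    w = h * d + (1.0 - h)
    wi = 1.0 / w
    XtWX = (Xr * wi[:, None]).T @ Xr
    beta = np.linalg.solve(XtWX, (Xr * wi[:, None]).T @ yr)
    r = yr - Xr @ beta
    s2_total = float(r @ (wi * r)) / (n - p)
    return h, s2_total, beta, -res.fun


def fit_gblup(
    response: np.ndarray,
    grm: GRM,
    fixed_effects: np.ndarray | None = None,
    ids: Sequence | None = None,
) -> GblupFit:
    """Fit GBLUP; NaN responses are treated as masked and predicted.

    ``fixed_effects`` is an optional design matrix (an intercept column is
    always prepended); the default model is intercept-only.
    """
    y = np.asarray(response, dtype=np.float64)
    if ids is None:
        ids = grm.ids
    ids = np.asarray(ids)
    if len(y) != len(ids) or len(y) != grm.n:
        raise ValueError("response length must match the GRM")
    obs = ~np.isnan(y)
    n_obs = int(obs.sum())
    if n_obs < 10:
        raise ValueError("too few phenotyped animals")
    X = np.ones((len(y), 1))
    if fixed_effects is not None:
        fe = np.atleast_2d(np.asarray(fixed_effects, dtype=np.float64))
        if fe.shape[0] != len(y):
            raise ValueError("fixed-effect rows must match the response")
        X = np.column_stack([X, fe])

    G = grm.matrix
    G_obs = G[np.ix_(obs, obs)]
    d, U = np.linalg.eigh(G_obs)
    if d.min() < -1e-8:
        warnings.warn("GRM not PSD to tolerance; adding ridge", stacklevel=2)
    d = np.maximum(d, 0.0) + 1e-8
    yr = U.T @ y[obs]
    Xr = U.T @ X[obs]
    h, s2_total, beta, ll = _reml_fit(d, yr, Xr)
    s2g, s2e = h * s2_total, (1.0 - h) * s2_total

    # BLUP of g for everyone: u_hat = s2g * G[:, obs] V^-1 (y - X beta)
    w = s2g * d + s2e
    vinv_r = U @ ((yr - Xr @ beta) / w)
    u_hat = s2g * (G[:, obs] @ vinv_r)
    epd = pd.DataFrame({"id": ids, "epd": u_hat, "in_training": obs})
    return GblupFit(sigma2_g=float(s2g), sigma2_e=float(s2e), beta=beta, epd=epd, loglik=float(ll))


def _test_correlation(fit: GblupFit, y: np.ndarray, test_mask: np.ndarray) -> float:
    yt = y[test_mask]
    pt = fit.epd.loc[test_mask, "epd"].to_numpy()
    if np.nanstd(yt) == 0:
        raise ValueError("zero-variance test response: correlation undefined")
    return float(np.corrcoef(pt, yt)[0, 1])


def forward_validate(
    response: np.ndarray,
    grm: GRM,
    train_ids: Sequence,
    test_ids: Sequence,
    fixed_effects: np.ndarray | None = None,
) -> CvReport:
    """Season-forward validation: fit with test phenotypes removed, report
    the Pearson correlation of test EPDs with the 0/1 status."""
    train_ids = np.asarray(train_ids)
    test_ids = np.asarray(test_ids)
    if np.intersect1d(train_ids, test_ids).size:
        raise ValueError("train and test id sets must be disjoint")
    id_pos = {v: i for i, v in enumerate(grm.ids)}
    tr = np.array([id_pos[i] for i in train_ids])
    te = np.array([id_pos[i] for i in test_ids])
    y = np.asarray(response, dtype=np.float64)
    keep = np.concatenate([tr, te])
    sub = grm.align(grm.ids[keep])
    y_sub = y[keep]
    mask = np.zeros(len(keep), dtype=bool)
    mask[len(tr) :] = True
    y_masked = y_sub.copy()
    y_masked[mask] = np.nan
    fe = None if fixed_effects is None else np.asarray(fixed_effects)[keep]
    fit = fit_gblup(y_masked, sub, fixed_effects=fe, ids=sub.ids)
    corr = _test_correlation(fit, y_sub, mask)
    return CvReport(scheme="forward", correlations=[corr], split_sizes=[[len(tr), len(te)]], seed=None)


def kfold_cv(
    response: np.ndarray,
    grm: GRM,
    k: int = 5,
    seed: int = 0,
    stratify: bool = False,
    fixed_effects: np.ndarray | None = None,
) -> CvReport:
    """k-fold cross-validation with per-fold phenotype masking.

    Folds partition the ids once with the given seed (optionally stratified
    by class). A fold whose test response has a single class is recorded as
    missing and excluded from the mean, with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(response, dtype=np.float64)
    n = len(y)
    if n != grm.n:
        raise ValueError("response length must match the GRM")
    rng = rng_from(seed, "kfold")
    if stratify:
        folds = np.empty(n, dtype=np.int64)
        for cls in np.unique(y):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            folds[idx] = np.arange(idx.size) % k
    else:
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=np.int64)
        folds[perm] = np.arange(n) % k
    corrs: list = []
    sizes: list = []
    for f in range(k):
        mask = folds == f
        y_masked = y.copy()
        y_masked[mask] = np.nan
        fit = fit_gblup(y_masked, grm, fixed_effects=fixed_effects)
        sizes.append([int((~mask).sum()), int(mask.sum())])
        try:
            corrs.append(_test_correlation(fit, y, mask))
        except ValueError:
            warnings.warn(f"fold {f} has a single-class test response; correlation recorded as missing", stacklevel=2)
            corrs.append(None)
    return CvReport(scheme="k-fold", correlations=corrs, split_sizes=sizes, seed=seed)
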