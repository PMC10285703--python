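"""Supervised admixture (breed percentage) estimation and breed-risk models.

Each individual's breed fractions Q are estimated against a fixed reference
panel of per-breed allele frequencies F by maximising the binomial
log-likelihood

    L(Q) = sum_j [ g_j log(p_j) + (2 - g_j) log(1 - p_j) ],   p_j = sum_k Q_k F_kj

over the simplex. With F fixed the problem is convex per individual and the
classic admixture EM (block relaxation) converges monotonically; all
individuals are updated in parallel with dense matrix products.

Breed risk is a per-breed univariate binary logistic regression of BCHF
case/control status on that breed's fraction.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "BreedReferencePanel",
    "AncestryFractions",
    "BreedRiskModel",
    "estimate_ancestry",
    "breed_risk_logistic",
]

FREQ_CLAMP = (0.001, 0.999)


@dataclasses.dataclass
class BreedReferencePanel:
    """Per-breed alternative-allele frequencies on a shared locus panel."""

    breeds: list[str]
    freqs: np.ndarray  # (n_breeds, n_loci)
    panel: pd.DataFrame  # chrom/pos/ref/alt locus metadata

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape[0] != len(self.breeds):
            raise ValueError("frequency matrix rows must match breed labels")
        if len(self.panel) != self.freqs.shape[1]:
            raise ValueError("frequency matrix columns must match locus panel")

    @property
    def n_breeds(self) -> int:
        return len(self.breeds)

    @property
    def n_loci(self) -> int:
        return self.freqs.shape[1]

    def clamped(self) -> np.ndarray:
        return np.clip(self.freqs, *FREQ_CLAMP)

    def to_frame(self) -> pd.DataFrame:
        out = self.panel.copy()
        for k, b in enumerate(self.breeds):
            out[b] = self.freqs[k]
        return out


@dataclasses.dataclass
class AncestryFractions:
    """Per-animal breed proportions Q (rows sum to one)."""

    fractions: pd.DataFrame  # index: animal ids, columns: breeds
    log_likelihood: np.ndarray
    n_iterations: int
    converged: bool
    identifiable: bool

    def __post_init__(self) -> None:
        q = self.fractions.to_numpy()
        if (q < -1e-8).any():
            raise ValueError("breed fractions must be non-negative")
        if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("breed fractions must sum to one per animal")


def _loglik(G: np.ndarray, P: np.ndarray) -> np.ndarray:
    return (G * np.log(P) + (2.0 - G) * np.log1p(-P)).sum(axis=1)


def estimate_ancestry(
    genotypes,
    panel: BreedReferencePanel,
    tol: float = 1e-7,
    max_iter: int = 2000,
) -> AncestryFractions:
    """Supervised admixture Q for every individual.

    ``genotypes`` is a :class:`bchfkit.genotypes.GenotypeMatrix` in raw
    0/1/2 coding (or a bare 0/1/2 array) on the panel's loci. EM iterates
    until the relative log-likelihood change drops below ``tol``; the
    likelihood is asserted non-decreasing at every step.
    """
    if hasattr(genotypes, "codes"):
        if genotypes.coding != "alt_count":
            raise ValueError("ancestry estimation needs raw 0/1/2 alt-allele counts")
        ids = genotypes.ids
        G = np.asarray(genotypes.codes, dtype=np.float64)
    else:
        G = np.asarray(genotypes, dtype=np.float64)
        ids = np.array([f"A{i:06d}" for i in range(G.shape[0])])
    if np.isnan(G).any():
        raise ValueError("missing genotypes not supported; impute or drop loci first")
    F = panel.clamped()
    K, m = F.shape
    if G.shape[1] != m:
        raise ValueError("genotypes and reference panel have different locus counts")
    n = G.shape[0]
    if K == 1:
        q = pd.DataFrame(np.ones((n, 1)), index=ids, columns=panel.breeds)
        ll = _loglik(G, np.broadcast_to(F[0], G.shape))
        return AncestryFractions(q, ll, 0, True, True)

    Q = np.full((n, K), 1.0 / K)
    ll_uniform = _loglik(G, Q @ F)
    ll_old = ll_uniform
    converged = False
    iters = 0
    for iters in range(1, max_iter + 1):
        P = Q @ F
        np.clip(P, FREQ_CLAMP[0] / 2, 1 - FREQ_CLAMP[0] / 2, out=P)
        # expected ancestry-of-allele counts, collapsed over loci
        Q_new = Q * ((G / P) @ F.T + ((2.0 - G) / (1.0 - P)) @ (1.0 - F.T))
        Q_new /= 2.0 * m
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        ll_new = _loglik(G, Q_new @ F)
        if np.any(ll_new < ll_old - 1e-6 * np.abs(ll_old) - 1e-6):
            raise AssertionError("EM log-likelihood decreased; numerical failure")
        rel = np.max(np.abs(ll_new - ll_old) / (np.abs(ll_old) + 1.0))
        Q, ll_old = Q_new, ll_new
        if rel < tol:
            converged = True
            break
    if not converged:
        warnings.warn("supervised admixture EM hit the iteration cap; returning best iterate", stacklevel=2)
    if not np.isfinite(ll_old).all():
        raise RuntimeError("non-finite admixture likelihood (unclamped frequencies?)")
    # flat-likelihood (non-identifiability) check: an indistinguishable panel
    # leaves the per-locus likelihood at its uniform-Q value
    gain = float(np.mean(ll_old - ll_uniform)) / m
    identifiable = gain > 1e-4
    if not identifiable:
        warnings.warn(
            "breed fractions are weakly identified (flat likelihood); "
            "reference breeds may be insufficiently diverged",
            stacklevel=2,
        )
    frame = pd.DataFrame(Q, index=ids, columns=panel.breeds)
    return AncestryFractions(frame, ll_old, iters, converged, identifiable)


@dataclasses.dataclass
class BreedRiskModel:
    breed: str
    intercept: float
    slope: float
    separation: bool

    def predict(self, q) -> np.ndarray:
        """Fitted BCHF risk at breed fraction q in [0, 1]."""
        q = np.asarray(q, dtype=np.float64)
        return 1.0 / (1.0 + np.exp(-(self.intercept + self.slope * q)))

    @property
    def risk_at_one(self) -> float:
        return float(self.predict(1.0))


def breed_risk_logistic(case_status, fractions, breed: str) -> BreedRiskModel:
    """Binary logistic regression of case status (0/1) on one breed's fraction.

    Heart-score-3 animals must already be excluded (status is strictly 0/1).
    Complete separation falls back to a lightly ridge-penalised fit and is
    flagged on the returned model.
    """
    if isinstance(fractions, AncestryFractions):
        q = fractions.fractions[breed].to_numpy(dtype=np.float64)
    elif isinstance(fractions, pd.DataFrame):
        q = fractions[breed].to_numpy(dtype=np.float64)
    else:
        q = np.asarray(fractions, dtype=np.float64)
    y = np.asarray(case_status, dtype=np.float64)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("case status must be coded 0/1 with score-3 animals excluded")
    if y.shape != q.shape:
        raise ValueError("case status and fractions differ in length")
    X = sm.add_constant(q, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            params = np.asarray(res.params, dtype=np.float64)
            # a coefficient this large on a [0,1] covariate means separation
            if not np.isfinite(params).all() or np.abs(params).max() > 15:
                raise np.linalg.LinAlgError
        except Exception:
            separation = True
            params = _ridge_logistic(y, X)
    return BreedRiskModel(breed=breed, intercept=float(params[0]), slope=float(params[1]), separation=separation)


def _ridge_logistic(y: np.ndarray, X: np.ndarray, alpha: float = 1e-3, n_iter: int = 100) -> np.ndarray:
    """IRLS with a small L2 penalty; stabilises separated data."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        A = (X * w[:, None]).T @ X + alpha * np.eye(X.shape[1])
        beta_new = np.linalg.solve(A, (X * w[:, None]).T @ z)
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    return beta
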