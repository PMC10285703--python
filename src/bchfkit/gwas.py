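"""Per-SNP linear mixed-model association on the binary BCHF phenotype.

Variance components are estimated once under the null model (the
EMMAX/P3D approximation) and reused for every SNP: data are rotated into the
GRM eigenbasis, whitened with the null weights, covariates are projected
out, and each SNP's effect, standard error and Wald p-value come from the
resulting generalised least squares. Population structure is handled by
fitting leading principal components of the GRM as covariates; the genomic
inflation factor lambda_GC (median chi-square ratio) is reported but no
genomic-control correction is applied.

An exact mode re-estimates the variance components per SNP and is intended
for small panels only.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import _reml_fit
from .genotypes import GRM, GenotypeMatrix

__all__ = ["GwasResult", "grm_pcs", "lmm_gwas", "manhattan"]


@dataclasses.dataclass
class GwasResult:
    table: pd.DataFrame  # chrom, pos, beta, se, p
    lambda_gc: float
    sigma2_g: float
    sigma2_e: float
    n_tested: int

    @property
    def bonferroni_threshold(self) -> float:
        return 0.05 / max(self.n_tested, 1)


def grm_pcs(grm: GRM, n_components: int) -> np.ndarray:
    """Leading principal-component scores of the GRM, scaled by the square
    root of the eigenvalue (projection coordinates)."""
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    d, U = np.linalg.eigh(grm.matrix)
    order = np.argsort(d)[::-1]
    d, U = d[order], U[:, order]
    pos = d > 1e-10
    if n_components > int(pos.sum()):
        import warnings

        warnings.warn("requested components exceed GRM rank; truncating", stacklevel=2)
        n_components = int(pos.sum())
    return U[:, :n_components] * np.sqrt(d[:n_components])


def lmm_gwas(
    response: np.ndarray,
    genotypes: GenotypeMatrix,
    grm: GRM,
    covariates: np.ndarray | None = None,
    n_pcs: int = 0,
    exact: bool = False,
) -> GwasResult:
    """LMM association scan of every locus against a 0/1 response.

    ``covariates`` (optional) are additional fixed effects; an intercept is
    always included; ``n_pcs`` GRM principal components may be appended.
    Monomorphic SNPs get a missing p-value.
    """
    y = np.asarray(response, dtype=np.float64)
    n = len(y)
    if n != grm.n or n != genotypes.n_individuals:
        raise ValueError("response, genotypes and GRM sizes must agree")
    if np.isnan(y).any():
        raise ValueError("missing responses are not allowed in the scan")
    X = np.ones((n, 1))
    if covariates is not None:
        X = np.column_stack([X, np.atleast_2d(np.asarray(covariates, dtype=np.float64))])
    if n_pcs > 0:
        X = np.column_stack([X, grm_pcs(grm, n_pcs)])

    d, U = np.linalg.eigh(grm.matrix)
    d = np.maximum(d, 0.0) + 1e-8
    yr = U.T @ y
    Xr = U.T @ X
    h, s2_total, _, _ = _reml_fit(d, yr, Xr)
    s2g, s2e = h * s2_total, (1.0 - h) * s2_total

    W = genotypes.codes.astype(np.float64)
    if genotypes.coding == "alt_count":
        W = W - 1.0  # scan is invariant to the constant shift
    mono = np.nanstd(W, axis=0) == 0.0
    if np.isnan(W).any():
        # mean-impute for the scan; QC should have handled this already
        col_mean = np.nanmean(W, axis=0)
        idx = np.where(np.isnan(W))
        W[idx] = col_mean[idx[1]]

    sw = 1.0 / np.sqrt(h * d + (1.0 - h))  # whitening weights (unit total variance)
    ys = sw * yr
    Xs = Xr * sw[:, None]
    Ws = (U.T @ W) * sw[:, None]
    # project covariates out of everything
    Q, _ = np.linalg.qr(Xs)
    y_res = ys - Q @ (Q.T @ ys)
    W_res = Ws - Q @ (Q.T @ Ws)
    p_cov = X.shape[1]
    dof = n - p_cov - 1

    if exact:
        beta = np.empty(W.shape[1])
        se = np.empty(W.shape[1])
        for j in range(W.shape[1]):
            Xj = np.column_stack([Xr, U.T @ W[:, j]])
            hj, s2j, bj, _ = _reml_fit(d, yr, Xj)
            wj = 1.0 / (hj * d + (1.0 - hj))
            XtWX = (Xj * wj[:, None]).T @ Xj
            cov = s2j * np.linalg.inv(XtWX)
            beta[j] = bj[-1]
            se[j] = np.sqrt(cov[-1, -1])
        tstat = beta / se
    else:
        xtx = np.einsum("ij,ij->j", W_res, W_res)
        xty = W_res.T @ y_res
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = xty / xtx
            yty = float(y_res @ y_res)
            rss = np.maximum(yty - beta * xty, 0.0)
            s2 = rss / dof
            se = np.sqrt(s2 / xtx)
            tstat = beta / se
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    p[mono] = np.nan
    beta[mono] = np.nan
    se[mono] = np.nan

    ok = ~np.isnan(p)
    chi2 = stats.chi2.isf(np.clip(p[ok], 1e-300, 1.0), 1)
    lambda_gc = float(np.median(chi2) / stats.chi2.ppf(0.5, 1))
    table = pd.DataFrame(
        {
            "chrom": genotypes.panel["chrom"].to_numpy(),
            "pos": genotypes.panel["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
        }
    )
    return GwasResult(table=table, lambda_gc=lambda_gc, sigma2_g=float(s2g), sigma2_e=float(s2e), n_tested=int(ok.sum()))


def manhattan(result: GwasResult, path: str) -> None:
    """Write a Manhattan plot of -log10 p by genome position."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = result.table.dropna(subset=["p"]).copy()
    tab["logp"] = -np.log10(np.clip(tab["p"], 1e-300, 1.0))
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, sub) in enumerate(tab.groupby("chrom", sort=False)):
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["logp"], s=4, color="C0" if i % 2 == 0 else "C1", rasterized=True)
        ticks.append(offset + sub["pos"].mean())
        labels.append(str(chrom))
        offset += sub["pos"].max()
    ax.axhline(-np.log10(result.bonferroni_threshold), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
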