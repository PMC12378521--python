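"""Mixed-linear-model association scan.

The model is ``y = Xb + Zu + e`` with ``u ~ N(0, G sigma_g2)`` for the
VanRaden genomic relationship matrix ``G`` and ``e ~ N(0, I sigma_e2)``.
Variance components are estimated once on the null (no-SNP) model by REML
through a single eigendecomposition of ``G`` and a one-dimensional Brent
search over the variance ratio; each marker is then tested by generalized
least squares with that covariance held fixed — the standard two-stage
approximation that trades exact per-marker refits for a scan that is fast
enough to re-run inside every cross-validation fold.  Only the ascending
p-value ranking is consumed downstream, so no multiple-testing correction
is applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .containers import GenotypeMatrix, KinshipMatrix, PhenotypeSet, VarianceComponents

__all__ = ["GwasResult", "vanraden_g", "fit_null_mlm", "scan"]

_RIDGE = 1e-8


@dataclass
class GwasResult:
    """Per-SNP association results, one row per tested marker.

    ``table`` columns: chrom, pos, id, beta, se, wald, p, monomorphic.
    Monomorphic markers are flagged and assigned ``beta=0, p=1`` rather than
    dropped, so the p-value ranking stays total over the panel.
    """

    table: pd.DataFrame

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "GwasResult":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str}))


def vanraden_g(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix ``G = WW' / (2 * sum p_j(1-p_j))``.

    ``W`` is the genotype matrix centered by twice the allele frequency.
    Under Hardy-Weinberg sampling the diagonal averages ~1.  Errors if every
    marker is monomorphic (zero denominator).
    """
    x = genotypes.values.astype(float)
    p = x.mean(axis=0) / 2.0
    w = x - 2.0 * p
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    g = (w @ w.T) / denom
    return KinshipMatrix(values=g, denominator=denom, sample_ids=list(genotypes.sample_ids))


def _reml_neg_loglik(
    log_lam: float, s: np.ndarray, yt: np.ndarray, xt: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Negative REML log-likelihood profiled over sigma_e2 at ratio
    ``lam = sigma_g2 / sigma_e2``; returns (nll, sigma_e2, beta)."""
    lam = np.exp(log_lam)
    d = lam * s + 1.0
    n, q = xt.shape
    xtd = xt / d[:, None]
    xtx = xt.T @ xtd
    xty = xtd.T @ yt
    beta = np.linalg.solve(xtx, xty)
    resid = yt - xt @ beta
    rss = float(np.sum(resid * resid / d))
    sigma_e2 = rss / (n - q)
    _, logdet_xtx = np.linalg.slogdet(xtx)
    _, logdet_xx = np.linalg.slogdet(xt.T @ xt)
    nll = 0.5 * (
        (n - q) * np.log(2.0 * np.pi * sigma_e2)
        + (n - q)
        + np.sum(np.log(d))
        + logdet_xtx
        - logdet_xx
    )
    return nll, sigma_e2, beta


class _NullFit:
    """Eigendecomposition and REML optimum reused by the per-SNP scan."""

    __slots__ = ("u", "s", "vc", "log_lam", "beta")

    def __init__(self, u, s, vc, log_lam, beta):
        self.u, self.s, self.vc, self.log_lam, self.beta = u, s, vc, log_lam, beta


def fit_null_mlm(
    phenotypes: PhenotypeSet | np.ndarray,
    kinship: KinshipMatrix,
    covariates: np.ndarray | None = None,
    *,
    return_details: bool = False,
) -> VarianceComponents | tuple[VarianceComponents, "_NullFit"]:
    """REML variance components of the null mixed model.

    An intercept is always included; ``covariates`` adds fixed-effect
    columns (must be full rank together with the intercept).  The variance
    ratio ``sigma_g2/sigma_e2`` is optimized on a log scale over [-10, 10]
    by Brent search (tolerance 1e-8), after one eigendecomposition of
    ``G`` (ridged by 1e-8 if slightly indefinite).
    """
    y = phenotypes.y if isinstance(phenotypes, PhenotypeSet) else np.asarray(phenotypes, float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 individuals for REML")
    if kinship.n != n:
        raise ValueError("kinship dimension does not match phenotypes")

    g = 0.5 * (kinship.values + kinship.values.T)
    s, u = np.linalg.eigh(g)
    if s[0] < -1e-6 * max(1.0, abs(s[-1])):
        raise ValueError(
            "kinship matrix is not positive semidefinite beyond ridge tolerance; "
            "add a ridge of eps*I to G"
        )
    s = np.clip(s, 0.0, None)

    x = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        x = np.column_stack([x, cov])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariates (with intercept) are rank deficient")

    yt = u.T @ y
    xt = u.T @ x

    res = minimize_scalar(
        lambda t: _reml_neg_loglik(t, s, yt, xt)[0],
        bounds=(-10.0, 10.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    # guard the boundaries: bounded Brent can stall short of an endpoint
    candidates = [res.x, -10.0, 10.0]
    nlls = [_reml_neg_loglik(t, s, yt, xt)[0] for t in candidates]
    best = int(np.argmin(nlls))
    log_lam = candidates[best]
    nll, sigma_e2, beta = _reml_neg_loglik(log_lam, s, yt, xt)
    lam = np.exp(log_lam)
    vc = VarianceComponents(
        sigma_g2=float(lam * sigma_e2), sigma_e2=float(sigma_e2), loglik=float(-nll)
    )
    if return_details:
        return vc, _NullFit(u, s, vc, log_lam, beta)
    return vc


def scan(
    phenotypes: PhenotypeSet | np.ndarray,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix | None = None,
    covariates: np.ndarray | None = None,
) -> GwasResult:
    """Single-SNP mixed-model association scan.

    Variance components come from the null model and are held fixed for
    every marker; each SNP's effect is the generalized-least-squares
    estimate in the whitened model, its Wald statistic is referred to
    chi-square with 1 df.  The per-marker residual variance is re-estimated
    from the marker-included regression, so at identity kinship the scan
    reduces exactly to the ordinary-least-squares large-sample z-test.
    """
    y = phenotypes.y if isinstance(phenotypes, PhenotypeSet) else np.asarray(phenotypes, float)
    if kinship is None:
        kinship = vanraden_g(genotypes)
    _, null = fit_null_mlm(y, kinship, covariates, return_details=True)

    d = np.exp(null.log_lam) * null.s + 1.0
    w = 1.0 / np.sqrt(d)
    yt = (null.u.T @ y) * w

    n = y.size
    x0 = np.ones((n, 1))
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        x0 = np.column_stack([x0, cov])
    x0t = (null.u.T @ x0) * w[:, None]
    q = x0t.shape[1]

    # project covariates out of whitened y and whitened SNPs
    q0, _ = np.linalg.qr(x0t)
    y_r = yt - q0 @ (q0.T @ yt)

    xt = (null.u.T @ genotypes.values.astype(float)) * w[:, None]
    xt -= q0 @ (q0.T @ xt)

    xtx = np.einsum("ij,ij->j", xt, xt)
    xty = xt.T @ y_r
    mono = xtx <= _RIDGE * n
    safe = np.where(mono, 1.0, xtx)
    beta = xty / safe
    rss = float(y_r @ y_r) - beta * xty  # per-SNP residual sum of squares
    dof = n - q - 1
    sigma2 = np.clip(rss, 0.0, None) / dof
    se = np.sqrt(np.where(sigma2 > 0, sigma2, np.inf) / safe)
    wald = (beta / se) ** 2
    p = stats.chi2.sf(wald, df=1)

    beta[mono] = 0.0
    se[mono] = np.inf
    wald[mono] = 0.0
    p[mono] = 1.0

    keys = genotypes.keys()
    table = pd.DataFrame(
        {
            "chrom": [k.chromosome for k in keys],
            "pos": [k.position for k in keys],
            "id": [k.id for k in keys],
            "beta": beta,
            "se": se,
            "wald": wald,
            "p": np.clip(p, np.finfo(float).tiny, 1.0),
            "monomorphic": mono,
        }
    )
    return GwasResult(table)
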