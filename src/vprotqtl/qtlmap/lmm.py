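"""Linear mixed model association scan (MLMA-style).

The null model y = X beta + u + eps with cov(u) = sigma_g^2 * K is fitted
once per (trait, GRM) by REML through a single eigendecomposition of K and a
1-d search over the heritability ratio; per-SNP effects are then estimated
by generalized least squares with the variance components held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from vprotqtl.genotypes import GenotypeSet
from vprotqtl.qtlmap.grm import GRM


@dataclass
class LMMNull:
    """Fitted null model with the spectral cache for fast per-SNP GLS."""

    sigma_g2: float
    sigma_e2: float
    h: float                      # sigma_g2 / (sigma_g2 + sigma_e2)
    reml_loglik: float
    eigvals: np.ndarray = field(repr=False)
    eigvecs: np.ndarray = field(repr=False)
    y_rot: np.ndarray = field(repr=False)
    x_rot: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)      # 1 / (h*lam + (1-h))
    q_basis: np.ndarray = field(repr=False)      # orthonormal basis of W^1/2 X
    y_resid: np.ndarray = field(repr=False)      # W^1/2 y residualized on X
    n: int = 0
    rank_x: int = 0

    @property
    def df_resid(self) -> int:
        """Degrees of freedom for the per-SNP t-test: n - rank(X) - 1."""
        return self.n - self.rank_x - 1


def _reml_neg_loglik(h: float, lam: np.ndarray, y_rot: np.ndarray, x_rot: np.ndarray) -> float:
    d = h * lam + (1.0 - h)
    if (d <= 0).any():
        return np.inf
    w = 1.0 / d
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    try:
        beta = np.linalg.solve(xtwx, x_rot.T @ (w * y_rot))
    except np.linalg.LinAlgError:
        return np.inf
    r = y_rot - x_rot @ beta
    n, p = x_rot.shape
    rss = float(np.sum(w * r * r))
    if rss <= 0:
        return -np.inf
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return np.inf
    return 0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(d)) + logdet_xtwx)


def fit_lmm_null(y: np.ndarray, x: np.ndarray, grm: GRM | None) -> LMMNull:
    """REML variance components via eigendecomposition of the GRM.

    ``x`` must include the intercept column and have full column rank.
    ``grm=None`` means an identity relationship matrix (plain OLS scan).
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = len(y)
    if x.shape[0] != n:
        raise ValueError("y and X row counts differ")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("covariate matrix X is rank deficient")

    if grm is None:
        lam = np.ones(n)
        u = np.eye(n)
    else:
        k = grm.matrix
        lam, u = np.linalg.eigh(k)
        if lam.min() < -1e-8 * max(1.0, lam.max()):
            raise ValueError(f"GRM not PSD: min eigenvalue {lam.min():g}")
        lam = np.clip(lam, 0.0, None)

    y_rot = u.T @ y
    x_rot = u.T @ x

    if np.allclose(lam, lam[0]):
        # identity-like GRM: h is not identified; downstream statistics are
        # invariant to it, so pick the boundary
        h_opt = 0.0
        nll = _reml_neg_loglik(h_opt, lam, y_rot, x_rot)
    else:
        res = optimize.minimize_scalar(
            _reml_neg_loglik,
            args=(lam, y_rot, x_rot),
            bounds=(1e-8, 1.0 - 1e-8),
            method="bounded",
            options={"xatol": 1e-10},
        )
        h_opt, nll = float(res.x), float(res.fun)

    d = h_opt * lam + (1.0 - h_opt)
    w = 1.0 / d
    xtwx = x_rot.T @ (w[:, None] * x_rot)
    beta = np.linalg.solve(xtwx, x_rot.T @ (w * y_rot))
    r = y_rot - x_rot @ beta
    sigma2 = float(np.sum(w * r * r) / (n - x.shape[1]))

    sw = np.sqrt(w)
    x_tilde = sw[:, None] * x_rot
    y_tilde = sw * y_rot
    q, _ = np.linalg.qr(x_tilde)
    y_resid = y_tilde - q @ (q.T @ y_tilde)

    return LMMNull(
        sigma_g2=h_opt * sigma2,
        sigma_e2=(1.0 - h_opt) * sigma2,
        h=h_opt,
        reml_loglik=-nll,
        eigvals=lam,
        eigvecs=u,
        y_rot=y_rot,
        x_rot=x_rot,
        weights=w,
        q_basis=q,
        y_resid=y_resid,
        n=n,
        rank_x=rank,
    )


def residualize_snps(null: LMMNull, snps: np.ndarray) -> np.ndarray:
    """Rotate, weight and project SNP dosages off the covariate space."""
    g_rot = null.eigvecs.T @ np.asarray(snps, dtype=float)
    g_tilde = np.sqrt(null.weights)[:, None] * g_rot
    return g_tilde - null.q_basis @ (null.q_basis.T @ g_tilde)


def lmm_scan(
    null: LMMNull,
    snps: np.ndarray,
    snp_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP GLS effect estimates with variance components fixed at the null.

    ``snps`` is an n x m dosage matrix. Returns a frame with gamma_hat, se,
    t and two-sided p from a t distribution on n - rank(X) - 1 df. SNPs
    collinear with the covariates are flagged with NaN statistics.
    """
    snps = np.atleast_2d(np.asarray(snps, dtype=float))
    if snps.ndim == 1:
        snps = snps[:, None]
    m = snps.shape[1]
    g_res = residualize_snps(null, snps)
    gtg = np.einsum("ij,ij->j", g_res, g_res)
    gty = g_res.T @ null.y_resid
    df = null.df_resid
    rss_null = float(null.y_resid @ null.y_resid)

    ok = gtg > 1e-10 * null.n
    gamma = np.full(m, np.nan)
    se = np.full(m, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma[ok] = gty[ok] / gtg[ok]
        rss = np.maximum(rss_null - gamma[ok] ** 2 * gtg[ok], 0.0)
        se[ok] = np.sqrt(rss / df / gtg[ok])
    t = gamma / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return pd.DataFrame(
        {
            "snp": snp_ids if snp_ids is not None else [f"snp{j}" for j in range(m)],
            "gamma_hat": gamma,
            "se": se,
            "t": t,
            "p": p,
            "collinear": ~ok,
        }
    )


def scan_genotypes(
    y: np.ndarray,
    x: np.ndarray,
    genotypes: GenotypeSet,
    grm: GRM | None = None,
    variant_mask: np.ndarray | None = None,
    trait: str = "trait",
    scan: str = "trans",
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Convenience wrapper: fit the null once and scan a genotype set."""
    null = fit_lmm_null(y, x, grm)
    if variant_mask is None:
        sub = genotypes
    else:
        sub = genotypes.subset_variants(variant_mask)
    out = lmm_scan(null, sub.dosages, snp_ids=sub.variants["id"].tolist())
    out.insert(0, "trait", trait)
    out["chrom"] = sub.variants["chrom"].to_numpy()
    out["pos"] = sub.variants["pos"].to_numpy()
    out["maf"] = sub.maf()
    out["scan"] = scan
    out["cohort"] = cohort
    return out
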