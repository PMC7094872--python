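"""cis windows, permutation-based window adjustment, and BH FDR."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from vprotqtl.genotypes import GenotypeSet
from vprotqtl.qtlmap.lmm import LMMNull, residualize_snps

CIS_HALF_WIDTH = 500_000


def cis_window(
    gene: pd.Series | dict, genotypes: GenotypeSet, half_width: int = CIS_HALF_WIDTH
) -> np.ndarray:
    """Boolean mask of variants within a closed 1Mb window on the gene's TSS."""
    chrom = str(gene["chrom"])
    tss = int(gene["tss"])
    chrom_col = genotypes.variants["chrom"].astype(str).to_numpy()
    pos = genotypes.variants["pos"].to_numpy()
    return (chrom_col == chrom) & (np.abs(pos - tss) <= half_width)


def cis_empirical_p(
    null: LMMNull,
    snps: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, dict]:
    """Window-level adjusted p for the best cis hit.

    Permutes the (weighted, rotated) residual vector, re-residualizes on the
    covariates, records the minimum nominal p across the window per
    permutation, fits a Beta distribution to the null minima by ML, and
    returns BetaCDF(observed min p). Falls back to the empirical rank p if
    the null sample is degenerate.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    snps = np.atleast_2d(np.asarray(snps, dtype=float))
    g_res = residualize_snps(null, snps)
    norms = np.linalg.norm(g_res, axis=0)
    ok = norms > 1e-12
    g_unit = g_res[:, ok] / norms[ok]
    df = null.df_resid

    def min_p(y_vec: np.ndarray) -> float:
        y_unit = y_vec / np.linalg.norm(y_vec)
        c = g_unit.T @ y_unit
        c = np.clip(c, -1 + 1e-15, 1 - 1e-15)
        t = c * np.sqrt(df / (1.0 - c * c))
        return float(2.0 * stats.t.sf(np.abs(t), df=df).min())

    p_obs = min_p(null.y_resid)
    rng = np.random.default_rng(seed)
    q = null.q_basis
    null_min = np.empty(n_perm)
    for b in range(n_perm):
        yp = rng.permutation(null.y_resid)
        yp = yp - q @ (q.T @ yp)  # restore orthogonality to the covariates
        null_min[b] = min_p(yp)

    if np.ptp(null_min) < 1e-12:
        warnings.warn("degenerate permutation null; using empirical rank p", stacklevel=2)
        adj = (np.sum(null_min <= p_obs) + 1.0) / (n_perm + 1.0)
        return float(adj), {"method": "empirical", "n_perm": n_perm, "p_nominal": p_obs}
    k1, k2, _, _ = stats.beta.fit(null_min, floc=0.0, fscale=1.0)
    adj = float(stats.beta.cdf(p_obs, k1, k2))
    return adj, {
        "method": "beta",
        "k1": float(k1),
        "k2": float(k2),
        "n_perm": n_perm,
        "p_nominal": p_obs,
    }


def fdr_bh(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up. Returns (q-values, discovery flags at q)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / (np.arange(m) + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, qvals <= q
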