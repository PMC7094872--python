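"""Two-sample G -> exposure -> outcome causal chain simulator."""

from __future__ import annotations

import numpy as np
import pandas as pd


def _marginal_ols(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple regression of y on g (with intercept), vectorized."""
    from scipy import stats

    n = len(y)
    gc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    beta = gc.T @ yc / sxx
    resid_ss = (yc**2).sum() - beta**2 * sxx
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return beta, se, p


def simulate_mr_chain(
    n: int,
    beta_gx: float | np.ndarray,
    beta_causal: float,
    confounding: float = 0.0,
    pleiotropy: float | np.ndarray = 0.0,
    seed: int = 0,
    n_snps: int = 1,
    maf: float = 0.3,
    pleiotropy_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a G -> E -> V chain and two-sample summary statistics.

    ``n`` individuals per sample (2n total). Exposure
    E = G @ beta_gx + confounding*U + noise and outcome
    V = beta_causal*E + confounding*U + G @ alpha + noise, where alpha is the
    per-SNP pleiotropic effect (``pleiotropy`` plus, if ``pleiotropy_sd`` > 0,
    a balanced Normal(0, pleiotropy_sd) draw). Summary statistics are per-SNP
    OLS estimates from two non-overlapping halves, so exposure and outcome
    estimation errors are independent.

    Returns (exposure_stats, outcome_stats, individual_data).
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    bgx = np.broadcast_to(np.asarray(beta_gx, dtype=float), (n_snps,)).copy()
    alpha = np.broadcast_to(np.asarray(pleiotropy, dtype=float), (n_snps,)).copy()
    if pleiotropy_sd > 0:
        alpha = alpha + rng.normal(0.0, pleiotropy_sd, n_snps)

    total = 2 * n
    g = rng.binomial(2, maf, size=(total, n_snps)).astype(float)
    u = rng.normal(size=total)
    exposure = g @ bgx + confounding * u + rng.normal(size=total)
    outcome = beta_causal * exposure + confounding * u + g @ alpha + rng.normal(size=total)

    snp_ids = [f"mrsnp{j + 1}" for j in range(n_snps)]
    meta = {
        "snp": snp_ids,
        "chrom": "1",
        "pos": [10_000 * (j + 1) for j in range(n_snps)],
        "effect_allele": "A",
        "other_allele": "G",
    }
    bx, sex, px = _marginal_ols(g[:n], exposure[:n])
    by, sey, py = _marginal_ols(g[n:], outcome[n:])
    exposure_stats = pd.DataFrame({**meta, "beta": bx, "se": sex, "p": px})
    outcome_stats = pd.DataFrame({**meta, "beta": by, "se": sey, "p": py})
    data = pd.DataFrame(
        {"sample": ["A"] * n + ["B"] * n, "exposure": exposure, "outcome": outcome, "u": u}
    )
    for j, sid in enumerate(snp_ids):
        data[sid] = g[:, j]
    return exposure_stats, outcome_stats, data
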