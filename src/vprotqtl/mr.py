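"""Two-sample Mendelian randomization from summary statistics.

Instrument selection around a lead variant, allele harmonization, the Wald
ratio with delta-method SE, a maximum-likelihood estimator that accounts for
error in both exposure and outcome effects, MR-Egger regression with a free
intercept, Cochran's Q heterogeneity, and an FDR-controlled screen across
(exposure, outcome) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from vprotqtl.qtlmap.cis import fdr_bh

MR_WINDOW = 200_000
MR_P_MAX = 1e-5
PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass
class InstrumentSet:
    """Harmonized per-SNP exposure/outcome effect estimates for one pair."""

    exposure: str
    outcome: str
    cell_type: str
    table: pd.DataFrame = field(repr=False)  # snp, b_x, se_x, b_y, se_y

    def __post_init__(self) -> None:
        required = {"snp", "b_x", "se_x", "b_y", "se_y"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"instrument table missing columns: {sorted(missing)}")
        if (self.table[["se_x", "se_y"]] <= 0).any().any():
            raise ValueError("standard errors must be > 0")

    @property
    def n_instruments(self) -> int:
        return len(self.table)


@dataclass
class MRResult:
    method: str
    beta_causal: float
    se: float
    p: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None


# ----- instrument selection & harmonization ------------------------------


def select_instruments(
    varsnp_pos: int,
    varsnp_chrom: str,
    eqtl_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    cell_type_map: dict[str, set[str]] | None = None,
    outcome_cell_type: str | None = None,
    window: int = MR_WINDOW,
    p_max: float = MR_P_MAX,
) -> pd.DataFrame:
    """Candidate instruments: eQTL rows within a ``window`` (centered on the
    lead variant, so +/- window/2), eQTL p <= p_max, cell type matched, and
    present in the outcome statistics."""
    half = window // 2
    stats_df = eqtl_stats.loc[
        (eqtl_stats["chrom"].astype(str) == str(varsnp_chrom))
        & (np.abs(eqtl_stats["pos"] - varsnp_pos) <= half)
        & (eqtl_stats["p"] <= p_max)
    ]
    if cell_type_map is not None and outcome_cell_type is not None and "cell_type" in stats_df:
        allowed = cell_type_map.get(outcome_cell_type, set())
        stats_df = stats_df.loc[stats_df["cell_type"].isin(allowed)]
    overlap = stats_df.loc[stats_df["snp"].isin(set(outcome_stats["snp"]))]
    return overlap.reset_index(drop=True)


def harmonize(exposure_row: pd.Series, outcome_row: pd.Series):
    """Align one SNP's outcome effect to the exposure's effect allele.

    Returns (b_x, se_x, b_y, se_y) or a string rejection reason. Palindromic
    (A/T, C/G) SNPs are rejected; incompatible allele pairs are rejected.
    """
    ea_x, oa_x = str(exposure_row["effect_allele"]), str(exposure_row["other_allele"])
    ea_y, oa_y = str(outcome_row["effect_allele"]), str(outcome_row["other_allele"])
    if frozenset({ea_x, oa_x}) in PALINDROMIC:
        return "palindromic SNP (strand ambiguous)"
    if (ea_x, oa_x) == (ea_y, oa_y):
        flip = 1.0
    elif (ea_x, oa_x) == (oa_y, ea_y):
        flip = -1.0
    else:
        return f"incompatible alleles {ea_x}/{oa_x} vs {ea_y}/{oa_y}"
    return (
        float(exposure_row["beta"]),
        float(exposure_row["se"]),
        flip * float(outcome_row["beta"]),
        float(outcome_row["se"]),
    )


def build_instrument_set(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    exposure: str = "exposure",
    outcome: str = "outcome",
    cell_type: str = "",
) -> tuple[InstrumentSet, list[dict]]:
    """Harmonize overlapping SNPs into an InstrumentSet; returns rejections too."""
    out_by_snp = outcome_stats.set_index("snp")
    rows, rejections = [], []
    for _, exp_row in exposure_stats.iterrows():
        snp = exp_row["snp"]
        if snp not in out_by_snp.index:
            rejections.append({"snp": snp, "reason": "absent from outcome stats"})
            continue
        res = harmonize(exp_row, out_by_snp.loc[snp])
        if isinstance(res, str):
            rejections.append({"snp": snp, "reason": res})
            continue
        b_x, se_x, b_y, se_y = res
        rows.append({"snp": snp, "b_x": b_x, "se_x": se_x, "b_y": b_y, "se_y": se_y})
    table = pd.DataFrame(rows, columns=["snp", "b_x", "se_x", "b_y", "se_y"])
    return InstrumentSet(exposure, outcome, cell_type, table), rejections


# ----- estimators --------------------------------------------------------


def mr_ratio(b_x: float, se_x: float, b_y: float, se_y: float) -> MRResult:
    """Wald ratio estimate with first-order delta-method standard error."""
    if b_x == 0:
        raise ValueError("weak/null instrument: exposure effect is 0")
    beta = b_y / b_x
    se = np.sqrt(se_y**2 / b_x**2 + b_y**2 * se_x**2 / b_x**4)
    z = beta / se
    return MRResult(
        method="ratio",
        beta_causal=float(beta),
        se=float(se),
        p=float(2 * stats.norm.sf(abs(z))),
        n_instruments=1,
    )


def _ml_profile_nll(beta: float, bx, sex, by, sey) -> float:
    """Profile negative log-likelihood: per-SNP true effects maximized out."""
    wx = 1.0 / sex**2
    wy = 1.0 / sey**2
    xi = (wx * bx + beta * wy * by) / (wx + beta**2 * wy)
    return float(
        0.5 * np.sum(wx * (bx - xi) ** 2 + wy * (by - beta * xi) ** 2)
    )


def mr_ml(instruments: InstrumentSet) -> MRResult:
    """Maximum-likelihood causal estimate over b_x,j ~ N(xi_j, se_x,j^2),
    b_y,j ~ N(beta * xi_j, se_y,j^2); SE from the curvature of the profile
    log-likelihood. Reduces to the Wald ratio for a single instrument."""
    if instruments.n_instruments < 1:
        raise ValueError("need >= 1 instrument")
    t = instruments.table
    bx, sex = t["b_x"].to_numpy(), t["se_x"].to_numpy()
    by, sey = t["b_y"].to_numpy(), t["se_y"].to_numpy()
    ratios = by / np.where(bx == 0, np.nan, bx)
    start = float(np.nanmedian(ratios)) if np.isfinite(ratios).any() else 0.0
    delta = max(1.0, abs(start))
    try:
        res = optimize.minimize_scalar(
            _ml_profile_nll,
            bracket=(start - delta, start + delta),
            args=(bx, sex, by, sey),
            method="brent",
            options={"xtol": 1e-12},
        )
    except ValueError:
        res = optimize.minimize_scalar(
            _ml_profile_nll,
            bounds=(start - 100 * delta, start + 100 * delta),
            args=(bx, sex, by, sey),
            method="bounded",
            options={"xatol": 1e-12},
        )
    if not np.isfinite(res.fun):
        raise RuntimeError("MR-ML optimizer failed to converge")
    beta = float(res.x)
    eps = 1e-5 * max(1.0, abs(beta))
    f0 = _ml_profile_nll(beta, bx, sex, by, sey)
    fp = _ml_profile_nll(beta + eps, bx, sex, by, sey)
    fm = _ml_profile_nll(beta - eps, bx, sex, by, sey)
    info = (fp - 2 * f0 + fm) / eps**2
    if info <= 0:
        raise RuntimeError("MR-ML: non-positive observed information")
    se = float(1.0 / np.sqrt(info))
    z = beta / se
    return MRResult(
        method="ml",
        beta_causal=beta,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        n_instruments=instruments.n_instruments,
    )


def mr_ivw(instruments: InstrumentSet) -> MRResult:
    """Inverse-variance-weighted combination of per-SNP Wald ratios
    (first-order weights, fixed effect)."""
    t = instruments.table
    bx, by, sey = t["b_x"].to_numpy(), t["b_y"].to_numpy(), t["se_y"].to_numpy()
    w = bx**2 / sey**2
    r = by / bx
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    return MRResult(
        method="ivw",
        beta_causal=beta,
        se=se,
        p=float(2 * stats.norm.sf(abs(z))),
        n_instruments=instruments.n_instruments,
    )


def mr_egger(instruments: InstrumentSet) -> MRResult:
    """MR-Egger: WLS of b_y on b_x with a free intercept, weights 1/se_y^2,
    after orienting all exposure effects non-negative. The intercept tests
    directional pleiotropy. Requires >= 3 instruments."""
    if instruments.n_instruments < 3:
        raise ValueError("Egger underdetermined: need >= 3 instruments")
    t = instruments.table
    sign = np.where(t["b_x"].to_numpy() < 0, -1.0, 1.0)
    bx = sign * t["b_x"].to_numpy()
    by = sign * t["b_y"].to_numpy()
    w = 1.0 / t["se_y"].to_numpy() ** 2
    design = np.column_stack([np.ones_like(bx), bx])
    wd = design * w[:, None]
    xtwx = design.T @ wd
    coef = np.linalg.solve(xtwx, wd.T @ by)
    resid = by - design @ coef
    j = len(bx)
    scale = max(1.0, float(np.sum(w * resid**2) / (j - 2))) if j > 2 else 1.0
    cov = np.linalg.inv(xtwx) * scale
    intercept, slope = coef
    se_int, se_slope = np.sqrt(np.diag(cov))
    df = j - 2
    return MRResult(
        method="egger",
        beta_causal=float(slope),
        se=float(se_slope),
        p=float(2 * stats.t.sf(abs(slope / se_slope), df=df)),
        n_instruments=j,
        egger_intercept=float(intercept),
        egger_intercept_se=float(se_int),
        egger_intercept_p=float(2 * stats.t.sf(abs(intercept / se_int), df=df)),
    )


def cochran_q(instruments: InstrumentSet) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP Wald ratios with first-order delta weights."""
    if instruments.n_instruments < 2:
        raise ValueError("Q undefined for fewer than 2 instruments")
    t = instruments.table
    bx, sex = t["b_x"].to_numpy(), t["se_x"].to_numpy()
    by, sey = t["b_y"].to_numpy(), t["se_y"].to_numpy()
    r = by / bx
    var_r = sey**2 / bx**2 + by**2 * sex**2 / bx**4
    w = 1.0 / var_r
    beta_ivw = np.sum(w * r) / np.sum(w)
    q = float(np.sum(w * (r - beta_ivw) ** 2))
    df = instruments.n_instruments - 1
    return q, df, float(stats.chi2.sf(q, df))


def mr_screen(
    pairs: list[InstrumentSet], fdr: float = 0.10, multi_method: str = "ml"
) -> pd.DataFrame:
    """Screen (exposure, outcome) pairs with BH-FDR across pairs.

    The primary causal estimate and p come from the ML estimator (= Wald
    ratio for a single instrument); Egger slope/intercept and Cochran's Q
    are reported in addition when >= 3 instruments are available. Pairs with
    empty instrument sets are excluded from the FDR denominator.
    """
    rows = []
    for ins in pairs:
        if ins.n_instruments == 0:
            continue
        primary = mr_ml(ins) if multi_method == "ml" else mr_ivw(ins)
        row = {
            "exposure": ins.exposure,
            "outcome": ins.outcome,
            "cell_type": ins.cell_type,
            "method": primary.method,
            "n_snps": ins.n_instruments,
            "beta": primary.beta_causal,
            "se": primary.se,
            "p": primary.p,
            "egger_intercept": np.nan,
            "egger_intercept_se": np.nan,
            "Q": np.nan,
            "Q_df": np.nan,
            "Q_p": np.nan,
        }
        if ins.n_instruments >= 3:
            egger = mr_egger(ins)
            row["egger_intercept"] = egger.egger_intercept
            row["egger_intercept_se"] = egger.egger_intercept_se
        if ins.n_instruments >= 2:
            q, q_df, q_p = cochran_q(ins)
            row.update({"Q": q, "Q_df": q_df, "Q_p": q_p})
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    qvals, discoveries = fdr_bh(np.clip(out["p"].to_numpy(), 1e-300, 1.0), q=fdr)
    out["q_fdr"] = qvals
    out["pass_fdr"] = discoveries
    explained = out.groupby("outcome")["pass_fdr"].transform("any")
    out["explained"] = explained
    return out
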