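"""Mean-adjusted expression variability (eta_res).

For each trait (cell type, protein) the mean-CV2 relationship across
individuals is modelled by a local polynomial regression on the
log10(mean) / log10(CV2) plane; eta_res is the standardized residual from
that fit, so each trait column has mean 0 and unit variance by construction
and is expressed in residual standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SPAN = 0.75
DEFAULT_DEGREE = 2
DEFAULT_ROBUST_ITERS = 3


def _loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    x_out: np.ndarray,
    span: float,
    degree: int,
    robust_iters: int,
) -> np.ndarray:
    """Locally-weighted polynomial regression with tricube weights and
    bisquare robustness iterations (classic loess)."""
    n = len(x)
    k = max(degree + 1, int(np.ceil(span * n)))
    k = min(k, n)
    robust = np.ones(n)
    fitted_at_obs = np.empty(n)
    for iteration in range(robust_iters + 1):
        for i, xi in enumerate(x):
            d = np.abs(x - xi)
            h = np.partition(d, k - 1)[k - 1]
            if h <= 0:
                h = max(d.max(), 1.0) * 1e-12
            w = np.clip(1.0 - (d / h) ** 3, 0.0, 1.0) ** 3 * robust
            fitted_at_obs[i] = _wpolyval(x, y, w, xi, degree)
        if iteration < robust_iters:
            resid = y - fitted_at_obs
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            robust = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, 1.0) ** 2
    out = np.empty(len(x_out))
    for i, xi in enumerate(x_out):
        d = np.abs(x - xi)
        h = np.partition(d, k - 1)[k - 1]
        if h <= 0:
            h = max(d.max(), 1.0) * 1e-12
        w = np.clip(1.0 - (d / h) ** 3, 0.0, 1.0) ** 3 * robust
        out[i] = _wpolyval(x, y, w, xi, degree)
    return out


def _wpolyval(x, y, w, x0, degree) -> float:
    """Weighted polynomial fit evaluated at x0 (centered basis for stability)."""
    mask = w > 0
    deg = min(degree, int(mask.sum()) - 1)
    if deg < 0:
        return float(np.average(y, weights=np.maximum(w, 1e-300)))
    xm = x[mask] - x0
    basis = np.vander(xm, deg + 1, increasing=True)
    sw = np.sqrt(w[mask])
    coef, *_ = np.linalg.lstsq(basis * sw[:, None], y[mask] * sw, rcond=None)
    return float(coef[0])


@dataclass
class MeanCV2Fit:
    """Fitted mean-CV2 curve for one trait on the log10-log10 scale."""

    trait: tuple[str, str]
    grid_x: np.ndarray = field(repr=False)
    grid_y: np.ndarray = field(repr=False)
    span: float = DEFAULT_SPAN
    degree: int = DEFAULT_DEGREE
    n_individuals: int = 0

    def predict(self, log_mean: np.ndarray) -> np.ndarray:
        """Predicted log10(CV2); constant (nearest-value) extrapolation."""
        log_mean = np.asarray(log_mean, dtype=float)
        if (log_mean < self.grid_x[0]).any() or (log_mean > self.grid_x[-1]).any():
            warnings.warn(
                "log10(mean) outside fitted range; using nearest fitted value",
                stacklevel=2,
            )
        return np.interp(log_mean, self.grid_x, self.grid_y)


def fit_mean_cv2(
    summaries: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
    grid_size: int = 200,
) -> MeanCV2Fit:
    """Fit the cross-individual mean-CV2 trend for one trait.

    ``summaries`` holds one trait: columns individual, cell_type, protein,
    mean, cv2 with a single (cell_type, protein) value. Fitting is on
    log10(cv2) ~ log10(mean). Must be called separately per cohort.
    """
    traits = summaries[["cell_type", "protein"]].drop_duplicates()
    if len(traits) != 1:
        raise ValueError("fit_mean_cv2 expects summaries for exactly one trait")
    n = len(summaries)
    if n < max(10, degree + 2):
        raise ValueError(f"need >= {max(10, degree + 2)} individuals, got {n}")
    mean = summaries["mean"].to_numpy(dtype=float)
    cv2 = summaries["cv2"].to_numpy(dtype=float).copy()
    if (mean <= 0).any():
        raise ValueError("means must be > 0 for the log-log fit")
    if (cv2 < 0).any():
        raise ValueError("cv2 must be >= 0")
    if (cv2 == 0).any():
        positive = cv2[cv2 > 0]
        if positive.size == 0:
            raise ValueError("all cv2 values are zero; cannot fit on log scale")
        offset = positive.min() * 1e-3
        warnings.warn(f"zero cv2 values offset by {offset:g} for log fit", stacklevel=2)
        cv2[cv2 == 0] = offset

    x = np.log10(mean)
    y = np.log10(cv2)
    grid_x = np.linspace(x.min(), x.max(), grid_size)
    # include observed x in the evaluation grid for faithful residuals
    grid_x = np.unique(np.concatenate([grid_x, x]))
    grid_y = _loess_fit(x, y, grid_x, span=span, degree=degree, robust_iters=robust_iters)
    return MeanCV2Fit(
        trait=(traits.iloc[0]["cell_type"], traits.iloc[0]["protein"]),
        grid_x=grid_x,
        grid_y=grid_y,
        span=span,
        degree=degree,
        n_individuals=n,
    )


def eta_res(summaries: pd.DataFrame, fit: MeanCV2Fit) -> pd.Series:
    """Standardized residual of log10(CV2) from the fitted mean-CV2 curve.

    The returned series (indexed by individual) has mean 0 and unit sample
    variance (n-1 denominator).
    """
    x = np.log10(summaries["mean"].to_numpy(dtype=float))
    y = np.log10(summaries["cv2"].to_numpy(dtype=float))
    resid = y - fit.predict(x)
    sd = resid.std(ddof=1)
    scale = max(1.0, float(np.abs(y).max()))
    if not np.isfinite(sd) or sd <= 1e-12 * scale:
        raise ValueError("degenerate trait: all residuals identical")
    values = (resid - resid.mean()) / sd
    return pd.Series(values, index=summaries["individual"].to_numpy(), name="eta_res")


def eta_res_matrix(
    summaries: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    degree: int = DEFAULT_DEGREE,
    robust_iters: int = DEFAULT_ROBUST_ITERS,
) -> pd.DataFrame:
    """Individuals x traits eta_res matrix from a full TraitSummary table.

    Trait columns are labelled ``cell_type:protein``. Missing combinations
    are NaN.
    """
    cols = {}
    for (ct, prot), grp in summaries.groupby(["cell_type", "protein"], sort=True):
        fit = fit_mean_cv2(grp, span=span, degree=degree, robust_iters=robust_iters)
        cols[f"{ct}:{prot}"] = eta_res(grp, fit)
    return pd.DataFrame(cols)


def mean_matrix(summaries: pd.DataFrame) -> pd.DataFrame:
    """Individuals x traits matrix of mean expression values."""
    wide = summaries.pivot_table(
        index="individual", columns=["cell_type", "protein"], values="mean"
    )
    wide.columns = [f"{ct}:{prot}" for ct, prot in wide.columns]
    return wide
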