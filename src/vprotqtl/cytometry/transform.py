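"""Biexponential scale transform (inverse of a generalized sinh map)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class BiexpParams:
    """Parameters of the forward map y(x) = a*exp(b*x) - c*exp(-d*x) + f.

    Defaults (a=c=0.5, b=d=1, f=0) make the inverse transform exactly asinh.
    ``w`` is accepted for interface compatibility with common cytometry
    parametrizations but does not enter the map.
    """

    a: float = 0.5
    b: float = 1.0
    c: float = 0.5
    d: float = 1.0
    f: float = 0.0
    w: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.d > 0 and self.c >= 0):
            raise ValueError(
                "biexponential forward map requires a>0, b>0, c>=0, d>0 "
                f"(got a={self.a}, b={self.b}, c={self.c}, d={self.d})"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a * np.exp(self.b * x) - self.c * np.exp(-self.d * x) + self.f


def biexp_transform(values, params: BiexpParams | None = None) -> np.ndarray:
    """Invert the biexponential forward map for each value.

    Solves y(x) = v by safeguarded bisection to a residual tolerance of
    1e-9 * max(1, |v|); the forward map is strictly increasing for any valid
    parameter set, so the root is unique.
    """
    params = params or BiexpParams()
    v = np.atleast_1d(np.asarray(values, dtype=float))
    # asinh-flavoured initial bracket around the exact solution for the
    # symmetric case; expand until the root is enclosed
    lo = np.full(v.shape, -1.0)
    hi = np.full(v.shape, 1.0)
    for _ in range(200):
        need = params.forward(lo) > v
        if not need.any():
            break
        lo[need] *= 2.0
    for _ in range(200):
        need = params.forward(hi) < v
        if not need.any():
            break
        hi[need] *= 2.0
    for _ in range(120):
        mid = 0.5 * (lo + hi)
        below = params.forward(mid) < v
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    x = 0.5 * (lo + hi)
    resid = np.abs(params.forward(x) - v)
    tol = 1e-9 * np.maximum(1.0, np.abs(v))
    if (resid > tol).any():  # pragma: no cover - bisection is robust
        raise RuntimeError("biexponential inversion did not reach tolerance")
    return x if np.ndim(values) else float(x[0])
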