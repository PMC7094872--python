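"""Landmark alignment of a channel across samples (density-peak warping)."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from vprotqtl.cytometry.events import EventTable

log = logging.getLogger(__name__)


@dataclass
class WarpConfig:
    """Landmark-warp settings: number of principal landmarks, spline-section
    count (recorded; the warp itself is piecewise linear), and the bandwidth
    factor applied to the Silverman rule."""

    peakNr: int = 2
    nbreaks: int = 11
    bwFac: float = 2.0
    grid_size: int = 512

    def __post_init__(self) -> None:
        if self.peakNr < 1:
            raise ValueError("peakNr must be >= 1")
        if self.bwFac <= 0:
            raise ValueError("bwFac must be > 0")


def _silverman_bw(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    if scale <= 0:
        scale = max(abs(x).max(), 1.0) * 1e-3
    return 0.9 * scale * n ** (-0.2)


def find_landmarks(x: np.ndarray, config: WarpConfig) -> tuple[np.ndarray, np.ndarray]:
    """Locations and heights of up to peakNr density modes (sorted by location)."""
    bw = config.bwFac * _silverman_bw(x)
    grid = np.linspace(x.min() - 3 * bw, x.max() + 3 * bw, config.grid_size)
    kde = stats.gaussian_kde(x, bw_method=bw / np.std(x, ddof=1))
    dens = kde(grid)
    peaks, props = signal.find_peaks(dens, height=0.0)
    if peaks.size == 0:
        peaks = np.array([int(np.argmax(dens))])
        props = {"peak_heights": np.array([dens.max()])}
    heights = props["peak_heights"]
    top = np.argsort(heights)[::-1][: config.peakNr]
    order = np.argsort(grid[peaks[top]])
    return grid[peaks[top]][order], heights[top][order]


def _monotone_warp(landmarks: np.ndarray, targets: np.ndarray):
    """Strictly increasing piecewise-linear map landmark_i -> target_i,
    extended by identity-plus-offset beyond the extreme landmarks."""
    lm, tg = np.asarray(landmarks, float), np.asarray(targets, float)
    keep = np.ones(len(lm), dtype=bool)
    for i in range(1, len(lm)):  # drop pairs that would break monotonicity
        if keep[: i].any():
            prev = np.flatnonzero(keep[:i])[-1]
            if lm[i] <= lm[prev] or tg[i] <= tg[prev]:
                keep[i] = False
    lm, tg = lm[keep], tg[keep]

    def warp(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.interp(x, lm, tg)
        out = np.where(x < lm[0], x + (tg[0] - lm[0]), out)
        out = np.where(x > lm[-1], x + (tg[-1] - lm[-1]), out)
        return out

    return warp


def landmark_normalize(
    samples: list[EventTable], channel: str, config: WarpConfig | None = None
) -> list[EventTable]:
    """Warp one channel of every sample so density landmarks align.

    Per sample the top-``peakNr`` KDE modes are matched by rank to the
    cross-sample median landmark positions; a monotone piecewise-linear warp
    maps each sample's landmarks onto the medians. Ranks within each sample
    are preserved exactly.
    """
    config = config or WarpConfig()
    if len(samples) < 2:
        raise ValueError("landmark normalization requires >= 2 samples")
    for s in samples:
        if channel not in s.data.columns:
            raise ValueError(f"channel {channel!r} missing from sample {s.individual}")

    per_sample = [find_landmarks(s.data[channel].to_numpy(), config) for s in samples]
    n_found = [len(lm) for lm, _ in per_sample]
    k = min(min(n_found), config.peakNr)
    if k < config.peakNr:
        warnings.warn(
            f"only {k} density peaks found in some samples (requested {config.peakNr}); "
            "matching by rank",
            stacklevel=2,
        )
    # keep each sample's k highest peaks, ordered by location
    trimmed = []
    for lm, h in per_sample:
        top = np.sort(np.argsort(h)[::-1][:k])
        trimmed.append(lm[top])
    targets = np.median(np.vstack(trimmed), axis=0)

    out = []
    for s, lm in zip(samples, trimmed):
        warp = _monotone_warp(lm, targets)
        data = s.data.copy()
        data[channel] = warp(data[channel].to_numpy())
        out.append(s.with_data(data))
    return out
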