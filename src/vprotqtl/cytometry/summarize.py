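"""Event QC, volume normalization and per-trait summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MIN_EVENTS = 1000
MIN_CELLS = 100


@dataclass
class Rejection:
    """Tagged QC rejection (not an exception)."""

    reason: str
    individual: str | None = None
    cell_type: str | None = None
    protein: str | None = None


@dataclass
class TraitSummary:
    individual: str
    cell_type: str
    protein: str
    n_cells: int
    mean: float
    cv2: float


def filter_low_event_samples(events, min_events: int = MIN_EVENTS):
    """Reject samples with fewer than ``min_events`` total recorded events."""
    if events.n_events < min_events:
        return Rejection(
            reason=f"sample has {events.n_events} events < {min_events}",
            individual=events.individual,
        )
    return events


def cell_volume(fsc_a) -> np.ndarray:
    """Cell volume proxy: log10 of the cubed forward-scatter area."""
    fsc_a = np.asarray(fsc_a, dtype=float)
    if (fsc_a <= 0).any():
        raise ValueError("FSC-A must be > 0 to compute cell volume")
    return 3.0 * np.log10(fsc_a)


def volume_normalize(
    fluor, volumes, mode: str = "divide"
) -> tuple[np.ndarray, int]:
    """log10-transform fluorescence and normalize to cell volume.

    ``mode='divide'`` returns log10(F)/volume per event (default);
    ``mode='residual'`` returns residuals of log10(F) regressed on volume
    (plus the intercept-free mean, keeping the scale interpretable).
    Events with non-positive fluorescence cannot be logged; they are dropped
    and counted. Returns (normalized values, n_dropped).
    """
    fluor = np.asarray(fluor, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if (volumes <= 0).any():
        raise ValueError("volumes must be > 0")
    ok = fluor > 0
    n_dropped = int((~ok).sum())
    logf = np.log10(fluor[ok])
    vol = volumes[ok]
    if mode == "divide":
        return logf / vol, n_dropped
    if mode == "residual":
        slope, intercept = np.polyfit(vol, logf, 1)
        return logf - slope * vol - intercept + logf.mean(), n_dropped
    raise ValueError(f"unknown normalization mode {mode!r}")


def summarize_trait(
    values,
    individual: str,
    cell_type: str,
    protein: str,
    min_cells: int = MIN_CELLS,
):
    """Summarize normalized expression values into (n, mean, CV2).

    CV2 is the unbiased sample variance divided by the squared mean.
    Populations with fewer than ``min_cells`` cells, or with mean 0 (CV2
    undefined), are rejected.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < min_cells:
        return Rejection(
            reason=f"{n} cells < {min_cells}",
            individual=individual,
            cell_type=cell_type,
            protein=protein,
        )
    mean = float(values.mean())
    if mean == 0.0:
        return Rejection(
            reason="mean expression is 0; CV2 undefined",
            individual=individual,
            cell_type=cell_type,
            protein=protein,
        )
    var = float(values.var(ddof=1))
    return TraitSummary(
        individual=individual,
        cell_type=cell_type,
        protein=protein,
        n_cells=n,
        mean=mean,
        cv2=var / mean**2,
    )


def summaries_to_frame(summaries: list[TraitSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        columns=["individual", "cell_type", "protein", "n_cells", "mean", "cv2"],
        data=[
            {
                "individual": s.individual,
                "cell_type": s.cell_type,
                "protein": s.protein,
                "n_cells": s.n_cells,
                "mean": s.mean,
                "cv2": s.cv2,
            }
            for s in summaries
        ]
    )
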