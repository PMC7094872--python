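"""Rectangular gating and pulse-geometry doublet removal."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from vprotqtl.cytometry.events import EventTable

DEFAULT_DOUBLET_BAND = (0.8, 1.3)


@dataclass
class RectGate:
    """Axis-aligned rectangle on two channels; events inside pass."""

    label: str
    channel_x: str
    x_low: float
    x_high: float
    channel_y: str | None = None
    y_low: float = -np.inf
    y_high: float = np.inf
    parent: str | None = None  # None = root (all events)

    def __post_init__(self) -> None:
        if self.x_low > self.x_high or self.y_low > self.y_high:
            raise ValueError(f"gate {self.label!r}: bounds must be ordered")

    def contains(self, table: EventTable) -> np.ndarray:
        if self.channel_x not in table.data.columns:
            raise ValueError(f"gate {self.label!r}: channel {self.channel_x!r} missing")
        x = table.data[self.channel_x].to_numpy()
        mask = (x >= self.x_low) & (x <= self.x_high)
        if self.channel_y is not None:
            if self.channel_y not in table.data.columns:
                raise ValueError(f"gate {self.label!r}: channel {self.channel_y!r} missing")
            y = table.data[self.channel_y].to_numpy()
            mask &= (y >= self.y_low) & (y <= self.y_high)
        return mask


@dataclass
class GateTree:
    """Ordered rectangular gates; populations nest along parent links."""

    gates: list[RectGate] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [g.label for g in self.gates]
        if len(set(labels)) != len(labels):
            raise ValueError("gate labels must be unique")
        known = {None}
        for g in self.gates:
            if g.parent not in known:
                raise ValueError(f"gate {g.label!r} references unknown parent {g.parent!r}")
            known.add(g.label)


def gate_population(events: EventTable, gates: GateTree) -> dict[str, EventTable]:
    """Assign events to populations by sequential rectangular containment."""
    masks: dict[str | None, np.ndarray] = {None: np.ones(events.n_events, dtype=bool)}
    out: dict[str, EventTable] = {}
    for gate in gates.gates:
        mask = masks[gate.parent] & gate.contains(events)
        masks[gate.label] = mask
        out[gate.label] = events.with_data(events.data.loc[mask].reset_index(drop=True))
    return out


def remove_doublets(
    events: EventTable, ratio_band: tuple[float, float] = DEFAULT_DOUBLET_BAND
) -> tuple[EventTable, dict]:
    """Keep events whose FSC-A/FSC-H ratio lies inside ``ratio_band``.

    Events with FSC-H <= 0 are dropped and counted separately. Returns the
    filtered table and a report with removal counts.
    """
    for ch in ("FSC-A", "FSC-H"):
        if ch not in events.data.columns:
            raise ValueError(f"doublet removal requires channel {ch!r}")
    lo, hi = ratio_band
    fsc_a = events.data["FSC-A"].to_numpy(dtype=float)
    fsc_h = events.data["FSC-H"].to_numpy(dtype=float)
    valid = fsc_h > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, fsc_a / np.where(valid, fsc_h, 1.0), np.inf)
    keep = valid & (ratio >= lo) & (ratio <= hi)
    report = {
        "n_input": int(events.n_events),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "n_nonpositive_height": int((~valid).sum()),
        "removed_fraction": float((~keep).mean()) if events.n_events else 0.0,
        "ratio_band": [float(lo), float(hi)],
    }
    kept = events.with_data(events.data.loc[keep].reset_index(drop=True))
    return kept, report
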