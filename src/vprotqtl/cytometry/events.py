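"""Per-individual single-cell event tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "SSC-A")


@dataclass
class EventTable:
    """One individual's events on one antibody panel; rows = cells."""

    individual: str
    panel: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            raise ValueError("channel names must be unique")

    @property
    def n_events(self) -> int:
        return len(self.data)

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def fluorescence_channels(self) -> list[str]:
        return [c for c in self.data.columns if c not in SCATTER_CHANNELS]

    def with_data(self, data: pd.DataFrame) -> "EventTable":
        return EventTable(self.individual, self.panel, data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, individual: str | None = None, panel: str = "panel1") -> "EventTable":
        path = Path(path)
        if individual is None:
            individual = path.stem.split(".")[0]
        return cls(individual=individual, panel=panel, data=pd.read_csv(path))


def try_read_fcs(path, individual: str | None = None, panel: str = "panel1") -> EventTable:
    """Optional FCS 3.1 ingestion via fcsparser; bit-exactness not promised."""
    try:
        import fcsparser
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("FCS ingestion requires the optional fcsparser package") from exc
    _, data = fcsparser.parse(str(path))
    if individual is None:
        individual = Path(path).stem
    return EventTable(individual=individual, panel=panel, data=pd.DataFrame(data))
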