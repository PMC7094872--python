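"""Fixed-order event-processing pipeline for one antibody panel.

Stage order (logged in the QC report): sample event-count filter ->
biexponential transform (non-scatter channels) -> landmark normalization ->
gating -> doublet removal -> volume normalization -> trait summarization.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from vprotqtl.cytometry.events import EventTable, SCATTER_CHANNELS
from vprotqtl.cytometry.gating import DEFAULT_DOUBLET_BAND, GateTree, gate_population, remove_doublets
from vprotqtl.cytometry.summarize import (
    MIN_CELLS,
    MIN_EVENTS,
    Rejection,
    cell_volume,
    filter_low_event_samples,
    summaries_to_frame,
    summarize_trait,
    volume_normalize,
)
from vprotqtl.cytometry.transform import BiexpParams, biexp_transform
from vprotqtl.cytometry.warp import WarpConfig, landmark_normalize

log = logging.getLogger(__name__)

PIPELINE_ORDER = [
    "filter_low_event_samples",
    "biexp_transform",
    "landmark_normalize",
    "gate_population",
    "remove_doublets",
    "volume_normalize",
    "summarize_trait",
]


def process_panel(
    samples: list[EventTable],
    gates: GateTree | None = None,
    biexp_params: BiexpParams | None = None,
    warp_config: WarpConfig | None = None,
    doublet_band: tuple[float, float] = DEFAULT_DOUBLET_BAND,
    min_events: int = MIN_EVENTS,
    min_cells: int = MIN_CELLS,
    normalize_mode: str = "divide",
    apply_biexp: bool = False,
    apply_warp: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Run the panel pipeline and return (trait summaries, QC report).

    The biexponential transform and landmark warping are opt-in: the
    canonical simulated input is already on a homogeneous scale, and the
    warp requires >= 2 retained samples.
    """
    qc: dict = {
        "pipeline_order": PIPELINE_ORDER,
        "n_input_samples": len(samples),
        "rejected_samples": [],
        "rejected_traits": [],
        "doublet_removal": {},
        "n_nonpositive_fluorescence": 0,
        "thresholds": {"min_events": min_events, "min_cells": min_cells},
    }

    retained: list[EventTable] = []
    for s in samples:
        out = filter_low_event_samples(s, min_events=min_events)
        if isinstance(out, Rejection):
            qc["rejected_samples"].append({"individual": out.individual, "reason": out.reason})
            log.info("rejected sample %s: %s", out.individual, out.reason)
        else:
            retained.append(out)
    qc["n_retained_samples"] = len(retained)

    if apply_biexp and retained:
        params = biexp_params or BiexpParams()
        transformed = []
        for s in retained:
            data = s.data.copy()
            for ch in s.fluorescence_channels:
                data[ch] = biexp_transform(data[ch].to_numpy(), params)
            transformed.append(s.with_data(data))
        retained = transformed

    if apply_warp and len(retained) >= 2:
        channels = retained[0].fluorescence_channels
        for ch in channels:
            retained = landmark_normalize(retained, ch, warp_config)

    summaries = []
    for s in retained:
        if gates is not None and gates.gates:
            populations = gate_population(s, gates)
        else:
            populations = {"all": s}
        for cell_type, pop in populations.items():
            singlets, doublet_report = remove_doublets(pop, doublet_band)
            qc["doublet_removal"][f"{s.individual}:{cell_type}"] = doublet_report
            if singlets.n_events == 0:
                continue
            volumes = cell_volume(singlets.data["FSC-A"].to_numpy())
            for protein in singlets.fluorescence_channels:
                values, n_dropped = volume_normalize(
                    singlets.data[protein].to_numpy(), volumes, mode=normalize_mode
                )
                qc["n_nonpositive_fluorescence"] += n_dropped
                out = summarize_trait(
                    values, s.individual, cell_type, protein, min_cells=min_cells
                )
                if isinstance(out, Rejection):
                    qc["rejected_traits"].append(
                        {
                            "individual": out.individual,
                            "cell_type": out.cell_type,
                            "protein": out.protein,
                            "reason": out.reason,
                        }
                    )
                else:
                    summaries.append(out)

    frame = summaries_to_frame(summaries)
    qc["n_trait_summaries"] = len(frame)
    return frame, qc
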