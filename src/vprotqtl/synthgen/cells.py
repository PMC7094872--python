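"""Single-cell event simulation: fluorescence, scatter geometry, doublets."""

from __future__ import annotations

import numpy as np
import pandas as pd

from vprotqtl.cytometry.events import EventTable
from vprotqtl.synthgen.config import LatentIndividualParams, SimConfig


def simulate_cells(
    params: LatentIndividualParams,
    config: SimConfig,
    cell_type: str | None = None,
    panel: str = "panel1",
) -> EventTable:
    """Simulate an event table for one individual.

    Singlets: FSC-A lognormal around the individual's mean scatter,
    FSC-H = FSC-A * (1 + small jitter), and per protein raw fluorescence F
    with log10(F) ~ Normal(mu + kappa * volume, sigma) where
    volume = 3*log10(FSC-A). A fraction ``doublet_rate`` of output events are
    merged pairs of singlets: areas and fluorescence add, FSC-H is the max of
    the two heights (so FSC-A/FSC-H ~ 2).
    """
    if config.n_cells_per_individual < 1:
        raise ValueError("n_cells_per_individual must be >= 1")
    cell_type = cell_type or config.cell_types[0]
    for protein in config.proteins:
        if not params.sigma[(cell_type, protein)] > 0:
            raise ValueError("sigma must be positive")

    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 11, hash(params.individual) & 0x7FFFFFFF])
    )
    n_out = config.n_cells_per_individual
    n_doub = int(round(config.doublet_rate * n_out))
    n_sing = n_out - n_doub + 2 * n_doub  # doublets consume two singlets

    fsc_a = params.mean_fsc * np.exp(rng.normal(0.0, config.fsc_sd, n_sing))
    fsc_h = fsc_a * (1.0 + rng.normal(0.0, config.fsc_height_jitter, n_sing))
    ssc_a = 0.6 * params.mean_fsc * np.exp(rng.normal(0.0, config.fsc_sd, n_sing))
    volume = 3.0 * np.log10(fsc_a)

    fluor = {}
    for protein in config.proteins:
        mu = params.mu[(cell_type, protein)]
        sigma = params.sigma[(cell_type, protein)]
        log10_f = rng.normal(mu + config.volume_coupling * volume, sigma, n_sing)
        fluor[protein] = np.power(10.0, log10_f)

    keep = n_out - n_doub
    cols = {
        "FSC-A": fsc_a[:keep],
        "FSC-H": fsc_h[:keep],
        "SSC-A": ssc_a[:keep],
    }
    for protein in config.proteins:
        cols[protein] = fluor[protein][:keep]
    if n_doub:
        i1 = np.arange(keep, keep + n_doub)
        i2 = np.arange(keep + n_doub, n_sing)
        cols["FSC-A"] = np.concatenate([cols["FSC-A"], fsc_a[i1] + fsc_a[i2]])
        cols["FSC-H"] = np.concatenate([cols["FSC-H"], np.maximum(fsc_h[i1], fsc_h[i2])])
        cols["SSC-A"] = np.concatenate([cols["SSC-A"], ssc_a[i1] + ssc_a[i2]])
        for protein in config.proteins:
            cols[protein] = np.concatenate(
                [cols[protein], fluor[protein][i1] + fluor[protein][i2]]
            )
    order = rng.permutation(n_out)
    data = pd.DataFrame({k: v[order] for k, v in cols.items()})
    return EventTable(individual=params.individual, panel=panel, data=data)
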