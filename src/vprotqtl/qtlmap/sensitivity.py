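"""Down-sampling sensitivity of QTL recovery."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from vprotqtl.genotypes import GenotypeSet
from vprotqtl.qtlmap.clump import ld_clump
from vprotqtl.qtlmap.grm import compute_grm
from vprotqtl.qtlmap.lmm import scan_genotypes

MIN_SUBSET = 30


def downsample_sensitivity(
    y: np.ndarray,
    x: np.ndarray,
    genotypes: GenotypeSet,
    fractions=tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    seed: int = 0,
    p_threshold: float = 5e-8,
    use_grm: bool = False,
    clump_p: float = 1e-4,
) -> pd.DataFrame:
    """Recovery of full-sample QTLs when individuals are down-sampled.

    The full-sample scan is clumped into QTLs; per fraction a random subset
    of individuals is re-scanned, and a QTL counts as recovered if any of
    its clump members reaches ``p_threshold``. Fractions yielding fewer than
    30 individuals are skipped with a warning.
    """
    y = np.asarray(y, dtype=float)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = len(y)
    grm = compute_grm(genotypes) if use_grm else None
    full = scan_genotypes(y, x, genotypes, grm=grm)
    full_sig = full.loc[full["p"] <= p_threshold]
    qtls = ld_clump(full_sig.assign(trait="trait"), genotypes, p_index=p_threshold)
    if not qtls:
        raise ValueError("no full-sample QTLs at the reporting threshold")
    qtl_members = [{c.index_snp, *c.members} for c in qtls]

    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        n_sub = int(round(frac * n))
        if n_sub < MIN_SUBSET:
            warnings.warn(f"fraction {frac} gives {n_sub} < {MIN_SUBSET} individuals; skipped")
            continue
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub_geno = GenotypeSet(
            variants=genotypes.variants.copy(),
            dosages=genotypes.dosages[idx],
            individuals=[genotypes.individuals[i] for i in idx],
        )
        sub_grm = compute_grm(sub_geno) if use_grm else None
        sub = scan_genotypes(y[idx], x[idx], sub_geno, grm=sub_grm)
        hits = set(sub.loc[sub["p"] <= p_threshold, "snp"])
        recovered = sum(1 for members in qtl_members if members & hits)
        rows.append(
            {
                "fraction": float(frac),
                "n_individuals": n_sub,
                "n_qtls_full": len(qtls),
                "n_recovered": recovered,
                "recovery": recovered / len(qtls),
            }
        )
    return pd.DataFrame(rows)
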