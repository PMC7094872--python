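"""Genetic relationship matrices (standardized-genotype / GCTA form)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from vprotqtl.genotypes import GenotypeSet


@dataclass
class GRM:
    matrix: np.ndarray = field(repr=False)
    n_variants: int = 0
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")


def compute_grm(genotypes: GenotypeSet, variant_subset=None) -> GRM:
    """GRM = (1/m) * Z Z' with z_ik = (g_ik - 2 p_k) / sqrt(2 p_k (1 - p_k)).

    ``p_k`` is the counted-allele frequency. Variants fixed in the subset
    (p in {0, 1}) are skipped with a warning. Missing dosages are
    mean-imputed (z = 0).
    """
    gs = genotypes if variant_subset is None else genotypes.subset_variants(variant_subset)
    if gs.n_variants == 0:
        raise ValueError("empty variant subset")
    p = gs.allele_frequency()
    usable = (p > 0) & (p < 1)
    if not usable.all():
        warnings.warn(
            f"skipping {int((~usable).sum())} monomorphic variants in GRM", stacklevel=2
        )
    if not usable.any():
        raise ValueError("no polymorphic variants for GRM")
    dos = gs.dosages[:, usable]
    p = p[usable]
    z = (dos - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.nan_to_num(z)
    m = z.shape[1]
    return GRM(matrix=z @ z.T / m, n_variants=m, individuals=list(gs.individuals))


def loco_grms(genotypes: GenotypeSet) -> dict[str, GRM]:
    """Leave-one-chromosome-out GRMs: for each chromosome, a GRM from all
    variants NOT on it. Requires >= 2 chromosomes."""
    chroms = list(dict.fromkeys(genotypes.variants["chrom"]))
    if len(chroms) < 2:
        raise ValueError("leave-one-chromosome-out requires >= 2 chromosomes")
    out = {}
    chrom_col = genotypes.variants["chrom"].to_numpy()
    for c in chroms:
        mask = chrom_col != c
        if not mask.any():
            raise ValueError(f"complement of chromosome {c} is empty")
        out[c] = compute_grm(genotypes, mask)
    return out
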