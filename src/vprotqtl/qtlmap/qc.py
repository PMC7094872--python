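"""Variant-level quality control: MAF and Hardy-Weinberg filters."""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from vprotqtl.genotypes import GenotypeSet

log = logging.getLogger(__name__)

MAF_MIN = 0.01
HWE_P_MAX = 1e-50


def hwe_chi2(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Expected counts use the estimated allele frequency
    p = (2*n_AA + n_Ab) / (2n). Monomorphic input is undefined.
    """
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotype observations")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        raise ValueError("monomorphic variant: HWE test undefined")
    expected = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(genotypes: GenotypeSet) -> np.ndarray:
    """HWE p per variant from hard-called dosages; NaN where monomorphic."""
    hard = np.rint(genotypes.dosages).clip(0, 2)
    out = np.empty(genotypes.n_variants)
    for j in range(genotypes.n_variants):
        col = hard[:, j]
        col = col[np.isfinite(col)]
        counts = [(col == g).sum() for g in (2, 1, 0)]
        try:
            _, out[j] = hwe_chi2(*counts)
        except ValueError:
            out[j] = np.nan
    return out


def qc_variants(
    genotypes: GenotypeSet,
    maf_min: float = MAF_MIN,
    hwe_p_max: float = HWE_P_MAX,
) -> tuple[GenotypeSet, dict]:
    """Drop variants with MAF < 1% or HWE p <= 1e-50.

    Both boundaries follow the stated rules strictly: MAF exactly at the
    threshold is retained; HWE p exactly at the threshold is excluded.
    Returns the filtered set and a removal report.
    """
    maf = genotypes.maf()
    hwe_p = hwe_pvalues(genotypes)
    fail_maf = maf < maf_min
    with np.errstate(invalid="ignore"):
        fail_hwe = np.where(np.isnan(hwe_p), False, hwe_p <= hwe_p_max)
    keep = ~(fail_maf | fail_hwe)
    report = {
        "n_input": int(genotypes.n_variants),
        "n_removed_maf": int(fail_maf.sum()),
        "n_removed_hwe": int(fail_hwe.sum()),
        "n_removed": int((~keep).sum()),
        "n_kept": int(keep.sum()),
        "maf_min": maf_min,
        "hwe_p_max": hwe_p_max,
    }
    log.info("variant QC: %s", report)
    return genotypes.subset_variants(keep), report
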