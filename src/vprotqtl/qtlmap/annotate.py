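"""varSNP annotation relative to gene models and TSS-proximity enrichment."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

FLANK = 5_000
TSS_THRESHOLD = 100_000

GENE_MODEL_COLUMNS = ["gene_id", "chrom", "start", "end", "tss", "strand"]


def _category_for_snp(pos: int, genes: pd.DataFrame) -> str:
    """Priority: transcribed > upstream > downstream > intergenic."""
    in_body = (genes["start"] <= pos) & (pos <= genes["end"])
    if in_body.any():
        return "transcribed"
    plus = genes["strand"] == "+"
    upstream = (
        (plus & (pos >= genes["start"] - FLANK) & (pos < genes["start"]))
        | (~plus & (pos > genes["end"]) & (pos <= genes["end"] + FLANK))
    )
    if upstream.any():
        return "upstream"
    downstream = (
        (plus & (pos > genes["end"]) & (pos <= genes["end"] + FLANK))
        | (~plus & (pos >= genes["start"] - FLANK) & (pos < genes["start"]))
    )
    if downstream.any():
        return "downstream"
    return "intergenic"


def nearest_tss_distance(snps: pd.DataFrame, gene_models: pd.DataFrame) -> np.ndarray:
    """Signed strand-aware distance to the nearest TSS per SNP.

    Positive = downstream of the TSS in the transcription direction. Ties in
    absolute distance go to the TSS at the lower coordinate. NaN when the
    SNP's chromosome has no gene.
    """
    out = np.full(len(snps), np.nan)
    by_chrom = {str(c): g.sort_values("tss") for c, g in gene_models.groupby("chrom")}
    for i, (_, snp) in enumerate(snps.iterrows()):
        genes = by_chrom.get(str(snp["chrom"]))
        if genes is None:
            continue
        delta = snp["pos"] - genes["tss"].to_numpy()
        order = np.lexsort((genes["tss"].to_numpy(), np.abs(delta)))
        best = order[0]
        signed = delta[best] if genes.iloc[best]["strand"] == "+" else -delta[best]
        out[i] = signed
    return out


def annotate_varsnps(varsnps: pd.DataFrame, gene_models: pd.DataFrame) -> pd.DataFrame:
    """Annotate SNPs (columns snp, chrom, pos) against a gene model table.

    Adds ``category`` (transcribed / upstream / downstream / intergenic,
    5kb flanks, strand aware) and ``dist_tss`` (signed distance to the
    nearest TSS; NaN with a warning when no gene shares the chromosome).
    """
    missing = set(GENE_MODEL_COLUMNS) - set(gene_models.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    out = varsnps.copy()
    by_chrom = {str(c): g for c, g in gene_models.groupby("chrom")}
    categories = []
    for _, snp in out.iterrows():
        genes = by_chrom.get(str(snp["chrom"]))
        if genes is None:
            warnings.warn(
                f"chromosome {snp['chrom']} absent from gene table", stacklevel=2
            )
            categories.append("intergenic")
        else:
            categories.append(_category_for_snp(int(snp["pos"]), genes))
    out["category"] = categories
    out["dist_tss"] = nearest_tss_distance(out, gene_models)
    return out


def tss_enrichment(
    varsnps: pd.DataFrame,
    all_snps: pd.DataFrame,
    gene_models: pd.DataFrame,
    threshold: int = TSS_THRESHOLD,
    n_controls_per_case: int = 1,
    seed: int = 0,
    maf_bin_width: float = 0.05,
) -> tuple[float, float, pd.DataFrame]:
    """Enrichment of varSNPs within ``threshold`` bp of the nearest TSS
    versus MAF-matched control SNPs.

    Controls are sampled MAF-bin-matched (bins of ``maf_bin_width``) without
    replacement from ``all_snps`` minus the cases; a bin short of controls is
    widened by a factor of 2 with a warning. Returns (odds ratio from the
    2x2 cross-product, Fisher exact p, the 2x2 table).
    """
    rng = np.random.default_rng(seed)
    case_ids = set(varsnps["snp"])
    pool = all_snps.loc[~all_snps["snp"].isin(case_ids)].reset_index(drop=True)
    controls_idx: list[int] = []
    taken = np.zeros(len(pool), dtype=bool)
    pool_maf = pool["maf"].to_numpy()
    for _, case in varsnps.iterrows():
        width = maf_bin_width
        chosen = None
        while width <= 0.5 + 1e-9:
            bin_lo = np.floor(case["maf"] / width) * width
            in_bin = (~taken) & (pool_maf >= bin_lo) & (pool_maf < bin_lo + width)
            avail = np.flatnonzero(in_bin)
            if len(avail) >= n_controls_per_case:
                chosen = rng.choice(avail, size=n_controls_per_case, replace=False)
                break
            warnings.warn(
                f"insufficient MAF-matched controls in bin width {width}; widening",
                stacklevel=2,
            )
            width *= 2
        if chosen is None:
            raise ValueError("control pool exhausted for MAF matching")
        taken[chosen] = True
        controls_idx.extend(chosen.tolist())
    controls = pool.iloc[controls_idx]

    case_dist = np.abs(nearest_tss_distance(varsnps, gene_models))
    ctrl_dist = np.abs(nearest_tss_distance(controls, gene_models))
    a = int(np.nansum(case_dist <= threshold))
    b = len(varsnps) - a
    c = int(np.nansum(ctrl_dist <= threshold))
    d = len(controls) - c
    table = pd.DataFrame(
        {"within": [a, c], "beyond": [b, d]}, index=["varsnp", "control"]
    )
    if b * c == 0:
        odds_ratio = np.inf if a * d > 0 else np.nan
    else:
        odds_ratio = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]])
    return float(odds_ratio), float(p), table
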