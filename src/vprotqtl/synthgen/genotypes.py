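"""LD-structured genotype simulation for twin cohorts.

Haplotypes follow a first-order copying model within LD blocks: the allele at
each variant copies the previous variant's allele with probability ``ld_rho``
and is otherwise drawn fresh from that variant's allele frequency. Blocks are
independent; MZ co-twins share both haplotypes; DZ co-twins are built from
four parental haplotypes with per-block transmission so LD is preserved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from vprotqtl.genotypes import GenotypeSet
from vprotqtl.pedigree import PedigreeTable
from vprotqtl.synthgen.config import SimConfig


def simulate_twin_cohort(config: SimConfig) -> PedigreeTable:
    """Pedigree with ``n_individuals`` unrelated plus MZ/DZ twin pairs."""
    if config.n_mz_pairs + config.n_dz_pairs + config.n_individuals < 1:
        raise ValueError("cohort is empty")
    rows = []
    for i in range(config.n_individuals):
        rows.append((f"U{i + 1:05d}", f"FU{i + 1:05d}", "unrelated"))
    for i in range(config.n_mz_pairs):
        fam = f"FM{i + 1:05d}"
        rows.append((f"M{i + 1:05d}a", fam, "MZ"))
        rows.append((f"M{i + 1:05d}b", fam, "MZ"))
    for i in range(config.n_dz_pairs):
        fam = f"FD{i + 1:05d}"
        rows.append((f"D{i + 1:05d}a", fam, "DZ"))
        rows.append((f"D{i + 1:05d}b", fam, "DZ"))
    return PedigreeTable(pd.DataFrame(rows, columns=["individual", "family", "zygosity"]))


def _variant_table(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Variant metadata plus the block index of each variant."""
    chrom_of = np.concatenate(
        [
            np.full(len(part), c + 1)
            for c, part in enumerate(np.array_split(np.arange(config.n_snps), config.n_chromosomes))
        ]
    )
    pos = np.empty(config.n_snps, dtype=int)
    block = np.empty(config.n_snps, dtype=int)
    next_block = 0
    for c in range(1, config.n_chromosomes + 1):
        idx = np.flatnonzero(chrom_of == c)
        pos[idx] = (np.arange(len(idx)) + 1) * config.variant_spacing
        nb = -(-len(idx) // config.ld_block_size)
        block[idx] = next_block + np.repeat(np.arange(nb), config.ld_block_size)[: len(idx)]
        next_block += nb
    variants = pd.DataFrame(
        {
            "id": [f"snp{k + 1}" for k in range(config.n_snps)],
            "chrom": chrom_of.astype(str),
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    return variants, block


def _copy_haplotypes(
    rng: np.random.Generator, n_hap: int, freqs: np.ndarray, block: np.ndarray, rho: float
) -> np.ndarray:
    """n_hap x m haplotype matrix under the within-block copying model."""
    m = len(freqs)
    hap = np.empty((n_hap, m), dtype=np.int8)
    for j in range(m):
        fresh = (rng.random(n_hap) < freqs[j]).astype(np.int8)
        if j > 0 and block[j] == block[j - 1] and rho > 0:
            copy = rng.random(n_hap) < rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        else:
            hap[:, j] = fresh
    return hap


def simulate_genotypes(config: SimConfig, pedigree: PedigreeTable | None = None) -> GenotypeSet:
    """Simulate biallelic dosages for a cohort.

    Without a pedigree, individuals are unrelated founders. With one, MZ
    pairs are genotype-identical and DZ pairs segregate from shared parental
    haplotypes (per-block transmission, expected allele sharing 1/2).
    """
    rng = np.random.default_rng(config.seed)
    variants, block = _variant_table(config)
    freqs = rng.uniform(*config.maf_range, size=config.n_snps)
    n_blocks = block.max() + 1

    if pedigree is None:
        pedigree = PedigreeTable(
            pd.DataFrame(
                {
                    "individual": [f"U{i + 1:05d}" for i in range(config.n_individuals)],
                    "family": [f"FU{i + 1:05d}" for i in range(config.n_individuals)],
                    "zygosity": "unrelated",
                }
            )
        )

    unrelated = pedigree.unrelated()
    mz_pairs = pedigree.pairs("MZ")
    dz_pairs = pedigree.pairs("DZ")

    # founder haplotypes: 2 per unrelated, 2 per MZ pair, 4 per DZ family
    n_hap = 2 * len(unrelated) + 2 * len(mz_pairs) + 4 * len(dz_pairs)
    hap = _copy_haplotypes(rng, n_hap, freqs, block, config.ld_rho)

    dosages: dict[str, np.ndarray] = {}
    cursor = 0
    for ind in unrelated:
        dosages[ind] = hap[cursor] + hap[cursor + 1]
        cursor += 2
    for a, b, _ in mz_pairs:
        g = hap[cursor] + hap[cursor + 1]
        dosages[a] = g
        dosages[b] = g.copy()
        cursor += 2
    block_expand = block  # variant -> block id
    for a, b, _ in dz_pairs:
        parental = hap[cursor : cursor + 4]  # m1, m2, f1, f2
        cursor += 4
        for child in (a, b):
            pick_m = rng.integers(0, 2, size=n_blocks)[block_expand]
            pick_f = rng.integers(0, 2, size=n_blocks)[block_expand]
            h1 = np.where(pick_m == 0, parental[0], parental[1])
            h2 = np.where(pick_f == 0, parental[2], parental[3])
            dosages[child] = h1 + h2

    individuals = pedigree.individuals
    mat = np.vstack([dosages[i] for i in individuals]).astype(float)
    return GenotypeSet(variants=variants, dosages=mat, individuals=individuals)
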