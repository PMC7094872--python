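"""Greedy LD clumping of association signals around index variants."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vprotqtl.genotypes import GenotypeSet

CLUMP_DISTANCE = 250_000
CLUMP_R2 = 0.5


@dataclass
class Clump:
    trait: str
    index_snp: str
    index_p: float
    chrom: str
    pos: int
    members: list[str] = field(default_factory=list)

    @property
    def n_members(self) -> int:
        return len(self.members)


def dosage_r2(genotypes: GenotypeSet, j1: int, j2: int) -> float:
    """Squared Pearson correlation of two dosage columns (mean-imputed)."""
    a = genotypes.dosages[:, j1].copy()
    b = genotypes.dosages[:, j2].copy()
    a[np.isnan(a)] = np.nanmean(a)
    b[np.isnan(b)] = np.nanmean(b)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def ld_clump(
    assoc: pd.DataFrame,
    genotypes: GenotypeSet,
    p_index: float = 1e-4,
    r2: float = CLUMP_R2,
    dist: int = CLUMP_DISTANCE,
    trait: str | None = None,
) -> list[Clump]:
    """Greedy clumping: take the best unassigned passing variant as index and
    absorb unassigned passing variants within ``dist`` bp and r^2 > ``r2``.

    Ties in p are broken by (chromosome, position, id). Returns clumps whose
    members partition the passing variants.
    """
    passing = assoc.loc[assoc["p"].notna() & (assoc["p"] <= p_index)].copy()
    if passing.empty:
        return []
    trait = trait if trait is not None else str(passing["trait"].iloc[0]) if "trait" in passing else ""
    passing["_chrom"] = passing["chrom"].astype(str)
    passing = passing.sort_values(
        ["p", "_chrom", "pos", "snp"], kind="mergesort"
    ).reset_index(drop=True)
    var_index = {vid: genotypes.variant_index(vid) for vid in passing["snp"]}

    assigned = np.zeros(len(passing), dtype=bool)
    clumps: list[Clump] = []
    for i in range(len(passing)):
        if assigned[i]:
            continue
        row = passing.iloc[i]
        assigned[i] = True
        members = []
        candidates = np.flatnonzero(
            ~assigned
            & (passing["_chrom"].to_numpy() == row["_chrom"])
            & (np.abs(passing["pos"].to_numpy() - row["pos"]) <= dist)
        )
        for j in candidates:
            if dosage_r2(genotypes, var_index[row["snp"]], var_index[passing.iloc[j]["snp"]]) > r2:
                assigned[j] = True
                members.append(passing.iloc[j]["snp"])
        clumps.append(
            Clump(
                trait=trait,
                index_snp=row["snp"],
                index_p=float(row["p"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                members=members,
            )
        )
    return clumps


def clumps_to_frame(clumps: list[Clump]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "trait": c.trait,
                "index_snp": c.index_snp,
                "index_p": c.index_p,
                "chrom": c.chrom,
                "pos": c.pos,
                "n_members": c.n_members,
                "members": ";".join(c.members),
            }
            for c in clumps
        ]
    )
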