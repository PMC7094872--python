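"""Genotype container and plain-text genotype I/O (dosage TSV, VCF)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeSet:
    """Biallelic variants with an individuals x variants dosage matrix.

    ``variants`` has columns id, chrom, pos (1-based), ref, alt; ``dosages``
    holds additive minor-allele counts (0/1/2 or expected dosage).
    """

    variants: pd.DataFrame = field(repr=False)
    dosages: np.ndarray = field(repr=False)
    individuals: list[str] = field(repr=False)

    def __post_init__(self) -> None:
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        if (self.variants["pos"] < 0).any():
            raise ValueError("positions must be non-negative")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def allele_frequency(self) -> np.ndarray:
        """Per-variant frequency of the counted (alt/minor) allele."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, mask_or_index) -> "GenotypeSet":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeSet(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            individuals=list(self.individuals),
        )

    def subset_individuals(self, ids) -> "GenotypeSet":
        lookup = {ind: i for i, ind in enumerate(self.individuals)}
        rows = [lookup[i] for i in ids]
        return GenotypeSet(
            variants=self.variants.copy(),
            dosages=self.dosages[rows, :],
            individuals=list(ids),
        )

    def variant_index(self, variant_id: str) -> int:
        hits = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if hits.size == 0:
            raise KeyError(f"variant {variant_id!r} not found")
        return int(hits[0])

    # ----- plain-text I/O -------------------------------------------------

    def to_dosage_tsv(self, path) -> None:
        """Rows = variants (with metadata columns), columns = individuals."""
        df = self.variants[VARIANT_COLUMNS].copy()
        dos = pd.DataFrame(self.dosages.T, columns=self.individuals)
        pd.concat([df, dos], axis=1).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dosage_tsv(cls, path) -> "GenotypeSet":
        df = pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str})
        individuals = [c for c in df.columns if c not in VARIANT_COLUMNS]
        return cls(
            variants=df[VARIANT_COLUMNS].copy(),
            dosages=df[individuals].to_numpy(dtype=float).T,
            individuals=individuals,
        )

    def to_vcf(self, path) -> None:
        """Write a minimal VCF v4.2 with GT genotypes (hard calls)."""
        hard = np.rint(self.dosages).clip(0, 2).astype(int)
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for chrom in pd.unique(self.variants["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(i) for i in self.individuals)
                + "\n"
            )
            for j, row in self.variants.iterrows():
                gts = "\t".join(gt_codes[g] for g in hard[:, j])
                fh.write(
                    f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t"
                    f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeSet":
        """Read GT dosages from a VCF via cyvcf2 (optional dependency)."""
        try:
            from cyvcf2 import VCF
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading VCF requires cyvcf2") from exc
        vcf = VCF(str(path))
        individuals = list(vcf.samples)
        records, columns = [], []
        for var in vcf:
            records.append(
                {
                    "id": var.ID or f"{var.CHROM}:{var.POS}",
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": var.ALT[0] if var.ALT else ".",
                }
            )
            gts = np.asarray(var.gt_types, dtype=float)  # 0,1,3 = hom-ref/het/hom-alt; 2 = unknown
            dos = np.where(gts == 3, 2.0, gts)
            dos[gts == 2] = np.nan
            columns.append(dos)
        return cls(
            variants=pd.DataFrame.from_records(records),
            dosages=np.column_stack(columns) if columns else np.empty((len(individuals), 0)),
            individuals=individuals,
        )
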