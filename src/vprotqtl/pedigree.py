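"""Twin pedigree / zygosity table."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

ZYGOSITIES = ("MZ", "DZ", "unrelated")


@dataclass
class PedigreeTable:
    """Individual -> (family, zygosity) mapping.

    Zygosity is one of ``MZ``, ``DZ`` or ``unrelated``; every MZ/DZ family
    must contain exactly two members (a twin pair).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"individual", "family", "zygosity"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        bad = set(self.table["zygosity"]) - set(ZYGOSITIES)
        if bad:
            raise ValueError(f"unknown zygosity labels: {sorted(bad)}")
        if self.table["individual"].duplicated().any():
            raise ValueError("duplicate individual ids in pedigree")
        twins = self.table[self.table["zygosity"].isin(("MZ", "DZ"))]
        sizes = twins.groupby("family").size()
        if (sizes != 2).any():
            bad_fams = sizes.index[sizes != 2].tolist()
            raise ValueError(f"MZ/DZ families must have exactly 2 members: {bad_fams}")

    @property
    def individuals(self) -> list[str]:
        return self.table["individual"].tolist()

    def pairs(self, zygosity: str | None = None) -> list[tuple[str, str, str]]:
        """Twin pairs as (id1, id2, zygosity), optionally filtered."""
        twins = self.table[self.table["zygosity"].isin(("MZ", "DZ"))]
        if zygosity is not None:
            twins = twins[twins["zygosity"] == zygosity]
        out = []
        for fam, grp in twins.groupby("family", sort=True):
            a, b = grp["individual"].tolist()
            out.append((a, b, grp["zygosity"].iloc[0]))
        return out

    def unrelated(self) -> list[str]:
        return self.table.loc[
            self.table["zygosity"] == "unrelated", "individual"
        ].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "PedigreeTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"individual": str, "family": str}))
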