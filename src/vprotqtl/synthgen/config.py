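"""Simulation configuration and latent-parameter containers."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field


@dataclass
class SimConfig:
    """Full parametrization of the synthetic cohort.

    ``ace_fractions`` are the (a2, c2, e2) variance fractions of the latent
    trait scores before SNP effects are added; ``qtl_effects`` is a list of
    ``(variant_index, beta_mean, beta_variability)`` tuples applied to every
    simulated trait.
    """

    seed: int = 0
    n_individuals: int = 100           # unrelated individuals
    n_mz_pairs: int = 0
    n_dz_pairs: int = 0
    n_snps: int = 100
    n_chromosomes: int = 2
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    ld_block_size: int = 1
    ace_fractions: tuple[float, float, float] = (0.0, 0.0, 1.0)
    qtl_effects: list[tuple[int, float, float]] = field(default_factory=list)
    trait_qtl_effects: dict[str, list[tuple[int, float, float]]] | None = None
    n_cells_per_individual: int = 1000
    doublet_rate: float = 0.0
    confounder_snp: int | None = None
    confounder_effect: float = 0.0
    # plumbing beyond the core knobs -------------------------------------
    proteins: tuple[str, ...] = ("prot1",)
    cell_types: tuple[str, ...] = ("lymphocytes",)
    variant_spacing: int = 10_000      # bp between adjacent variants
    mu_baseline: float = 1.0           # log10-fluorescence location offset
    mu_scale: float = 0.2              # SD of the mu-scale latent score
    sigma_baseline: float = 0.15       # log10-fluorescence dispersion
    sigma_scale: float = 0.3           # log-sigma units per latent score SD
    volume_coupling: float = 0.05      # kappa: log10F slope on cell volume
    fsc_location: float = 5e4          # typical FSC-A (arbitrary units)
    fsc_sd: float = 0.08               # per-cell log FSC-A SD
    fsc_individual_sd: float = 0.04    # between-individual log FSC-A SD
    fsc_height_jitter: float = 0.02    # singlet FSC-H multiplicative noise

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if abs(sum(self.ace_fractions) - 1.0) > 1e-12:
            raise ValueError(f"ace_fractions must sum to 1, got {self.ace_fractions}")
        if any(f < 0 for f in self.ace_fractions):
            raise ValueError("ace_fractions must be non-negative")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if not (0.0 <= self.doublet_rate < 1.0):
            raise ValueError("doublet_rate must be in [0, 1)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        for k, *_ in self.qtl_effects:
            if not (0 <= k < self.n_snps):
                raise ValueError(f"qtl_effects references absent variant index {k}")
        if self.trait_qtl_effects is not None:
            for protein, effects in self.trait_qtl_effects.items():
                if protein not in self.proteins:
                    raise ValueError(f"trait_qtl_effects references unknown protein {protein!r}")
                for k, *_ in effects:
                    if not (0 <= k < self.n_snps):
                        raise ValueError(f"trait_qtl_effects references absent variant index {k}")
        if self.confounder_snp is not None and not (0 <= self.confounder_snp < self.n_snps):
            raise ValueError("confounder_snp out of range")

    @property
    def traits(self) -> list[tuple[str, str]]:
        return [(ct, pr) for ct in self.cell_types for pr in self.proteins]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=list)


@dataclass
class LatentIndividualParams:
    """Ground-truth generative parameters for one individual.

    ``mu``/``sigma`` map (cell_type, protein) to the log10-scale location and
    dispersion of that individual's single-cell fluorescence; ``mu_score`` and
    ``sigma_score`` are the standardized latent trait values (SNP + A + C + E)
    used for parameter-recovery tests.
    """

    individual: str
    mu: dict[tuple[str, str], float]
    sigma: dict[tuple[str, str], float]
    mu_score: dict[tuple[str, str], float]
    sigma_score: dict[tuple[str, str], float]
    mean_fsc: float
    age: float
    confounder_genotype: float

    def __post_init__(self) -> None:
        for key, s in self.sigma.items():
            if not s > 0:
                raise ValueError(f"sigma must be > 0 for {key}, got {s}")


@dataclass
class TraitTruth:
    """Generative ground truth shared across individuals for one trait."""

    cell_type: str
    protein: str
    ace_fractions: tuple[float, float, float]
    qtl_effects: list[tuple[int, float, float]]
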