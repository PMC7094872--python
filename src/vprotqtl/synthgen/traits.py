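"""Latent per-individual trait parameters with A/C/E structure + SNP effects."""

from __future__ import annotations

import numpy as np

from vprotqtl.genotypes import GenotypeSet
from vprotqtl.pedigree import PedigreeTable
from vprotqtl.synthgen.config import LatentIndividualParams, SimConfig


def _ace_scores(
    rng: np.random.Generator, pedigree: PedigreeTable, fractions: tuple[float, float, float]
) -> dict[str, float]:
    """One standardized A+C+E score per individual.

    A is identical within MZ pairs, correlated 1/2 within DZ pairs; C is
    shared within twin pairs; E is independent. Marginal variance is
    a2 + c2 + e2 = 1.
    """
    a, c, e = (np.sqrt(f) for f in fractions)
    scores: dict[str, float] = {}
    for ind in pedigree.unrelated():
        scores[ind] = a * rng.normal() + c * rng.normal() + e * rng.normal()
    for i1, i2, zyg in pedigree.pairs():
        c_shared = rng.normal()
        if zyg == "MZ":
            a_shared = rng.normal()
            a_vals = (a_shared, a_shared)
        else:
            a_shared = rng.normal()
            a_vals = tuple(
                np.sqrt(0.5) * a_shared + np.sqrt(0.5) * rng.normal() for _ in range(2)
            )
        for ind, a_i in zip((i1, i2), a_vals):
            scores[ind] = a * a_i + c * c_shared + e * rng.normal()
    return scores


def simulate_latent_traits(
    genotypes: GenotypeSet, pedigree: PedigreeTable, config: SimConfig
) -> list[LatentIndividualParams]:
    """Draw per-individual (mu, sigma) parameters for every trait.

    For each (cell type, protein) the variability-scale score is
    sum_k gamma_k * (g_k - mean(g_k)) + A + C + E with variance fractions
    ``config.ace_fractions`` before SNP effects; the mean-scale score is
    generated analogously with its own effect sizes. The confounder SNP (a
    reagent-interaction stand-in) shifts mu of the first protein only.
    """
    missing = set(pedigree.individuals) - set(genotypes.individuals)
    if missing:
        raise ValueError(f"pedigree individuals absent from genotypes: {sorted(missing)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    lookup = {ind: i for i, ind in enumerate(genotypes.individuals)}
    rows = [lookup[i] for i in pedigree.individuals]
    dos = genotypes.dosages[rows, :]
    centered = dos - dos.mean(axis=0)

    ages = rng.uniform(20.0, 70.0, size=len(rows))
    conf_geno = (
        dos[:, config.confounder_snp]
        if config.confounder_snp is not None
        else np.zeros(len(rows))
    )
    mean_fsc = config.fsc_location * np.exp(
        rng.normal(0.0, config.fsc_individual_sd, size=len(rows))
    )

    mu: list[dict] = [dict() for _ in rows]
    sigma: list[dict] = [dict() for _ in rows]
    mu_score: list[dict] = [dict() for _ in rows]
    sigma_score: list[dict] = [dict() for _ in rows]
    first_protein = config.proteins[0]

    for trait in config.traits:
        cell_type, protein = trait
        s_ace = _ace_scores(rng, pedigree, config.ace_fractions)
        m_ace = _ace_scores(rng, pedigree, config.ace_fractions)
        s = np.array([s_ace[i] for i in pedigree.individuals])
        m = np.array([m_ace[i] for i in pedigree.individuals])
        effects = (
            config.trait_qtl_effects.get(protein, [])
            if config.trait_qtl_effects is not None
            else config.qtl_effects
        )
        for k, beta_mean, beta_var in effects:
            s = s + beta_var * centered[:, k]
            m = m + beta_mean * centered[:, k]
        mu_trait = config.mu_baseline + config.mu_scale * m
        if protein == first_protein and config.confounder_snp is not None:
            mu_trait = mu_trait + config.confounder_effect * conf_geno
        sigma_trait = config.sigma_baseline * np.exp(config.sigma_scale * s)
        for i in range(len(rows)):
            mu[i][trait] = float(mu_trait[i])
            sigma[i][trait] = float(sigma_trait[i])
            mu_score[i][trait] = float(m[i])
            sigma_score[i][trait] = float(s[i])

    return [
        LatentIndividualParams(
            individual=ind,
            mu=mu[i],
            sigma=sigma[i],
            mu_score=mu_score[i],
            sigma_score=sigma_score[i],
            mean_fsc=float(mean_fsc[i]),
            age=float(ages[i]),
            confounder_genotype=float(conf_geno[i]),
        )
        for i, ind in enumerate(pedigree.individuals)
    ]


def trait_scores(
    params: list[LatentIndividualParams], trait: tuple[str, str], kind: str = "sigma"
) -> np.ndarray:
    """Latent score vector across individuals for one trait."""
    attr = {"sigma": "sigma_score", "mu": "mu_score"}[kind]
    return np.array([getattr(p, attr)[trait] for p in params])
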