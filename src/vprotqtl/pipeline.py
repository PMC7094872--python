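"""End-to-end pipeline orchestration with manifests and per-stage seeds."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

import vprotqtl
from vprotqtl.cytometry import EventTable, GateTree, process_panel
from vprotqtl.genotypes import GenotypeSet
from vprotqtl.mr import build_instrument_set, mr_screen, select_instruments
from vprotqtl.pedigree import PedigreeTable
from vprotqtl.qtlmap import (
    cis_empirical_p,
    cis_window,
    clumps_to_frame,
    fdr_bh,
    fit_lmm_null,
    ld_clump,
    loco_grms,
    qc_variants,
    scan_genotypes,
)
from vprotqtl.synthgen import (
    SimConfig,
    simulate_cells,
    simulate_genotypes,
    simulate_latent_traits,
    simulate_twin_cohort,
)
from vprotqtl.twinvc import ace_table
from vprotqtl.variability import eta_res_matrix, mean_matrix

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "min_events": 1000,
    "min_cells": 100,
    "maf_min": 0.01,
    "hwe_p_max": 1e-50,
    "cis_half_width": 500_000,
    "clump_p_trans": 1e-4,
    "cis_fdr": 0.05,
    "clump_dist": 250_000,
    "clump_r2": 0.5,
    "mr_window": 200_000,
    "mr_p_max": 1e-5,
    "mr_fdr": 0.10,
    "genome_wide_p": 5e-8,
    "doublet_band": [0.8, 1.3],
}


def demo_config(seed: int = 7) -> dict:
    """Small bundled configuration that exercises every stage."""
    return {
        "seed": seed,
        "stages": ["simulate", "cytometry", "variability", "twinvc", "qtlmap", "mr"],
        "thresholds": dict(DEFAULT_THRESHOLDS),
        "simulate": {
            "seed": seed,
            "n_individuals": 60,
            "n_mz_pairs": 35,
            "n_dz_pairs": 35,
            "n_snps": 120,
            "n_chromosomes": 3,
            "ld_block_size": 4,
            "ld_rho": 0.8,
            "maf_range": (0.1, 0.5),
            "ace_fractions": (0.4, 0.1, 0.5),
            # variant 10 (chr1): cis mean effect on protA driving a trans
            # variability effect on protB - the MR causal chain
            "trait_qtl_effects": {
                "protA": [(10, 0.8, 0.0)],
                "protB": [(10, 0.0, 0.8)],
            },
            "n_cells_per_individual": 1200,
            "doublet_rate": 0.05,
            "proteins": ("protA", "protB"),
            "variant_spacing": 20_000,
        },
        # gene for protA sits at the causal variant (cis eGene); protB's gene
        # lives on another chromosome so variant 10 is trans to it
        "gene_anchors": {"protA": 10, "protB": 100},
        "twinvc": {"n_boot": 0, "n_perm": 0},
        "cis_n_perm": 200,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def _validate(config: dict, run_dir: Path) -> None:
    stages = config.get("stages", [])
    if "twinvc" in stages and "simulate" not in stages and not config.get("pedigree"):
        raise PipelineError("twinvc stage enabled but no pedigree input configured")
    if "qtlmap" in stages and "simulate" not in stages and not config.get("genotypes"):
        raise PipelineError("qtlmap stage enabled but no genotype input configured")


def run_pipeline(config: dict, run_dir) -> Path:
    """Execute the configured stages, writing outputs and manifests.

    Stage order: simulate -> cytometry -> variability -> twinvc -> qtlmap ->
    mr. Each stage writes its outputs plus a manifest (config, seed, input
    hashes, package version) under ``run_dir``.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _validate(config, run_dir)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    stages = config.get("stages", [])
    completed = []
    manifest = {
        "version": vprotqtl.__version__,
        "config": json.loads(json.dumps(config, default=list)),
        "stages": {},
    }

    state: dict = {}
    try:
        for stage in stages:
            t0 = time.time()
            outputs = _STAGE_FUNCS[stage](config, thresholds, run_dir, state)
            manifest["stages"][stage] = {
                "outputs": {k: _sha256(Path(v)) for k, v in outputs.items()},
                "seconds": round(time.time() - t0, 3),
            }
            completed.append(stage)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["completed_stages"] = completed
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["completed_stages"] = completed
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return run_dir


# ----- stages ------------------------------------------------------------


def _stage_simulate(config, thresholds, run_dir: Path, state) -> dict:
    sim = SimConfig(**{**config["simulate"]})
    out = run_dir / "simulated"
    events_dir = out / "events"
    events_dir.mkdir(parents=True, exist_ok=True)
    pedigree = simulate_twin_cohort(sim)
    genotypes = simulate_genotypes(sim, pedigree)
    params = simulate_latent_traits(genotypes, pedigree, sim)
    outputs = {}
    pedigree.to_tsv(out / "pedigree.tsv")
    genotypes.to_dosage_tsv(out / "genotypes.tsv")
    outputs["pedigree"] = out / "pedigree.tsv"
    outputs["genotypes"] = out / "genotypes.tsv"
    for p in params:
        table = simulate_cells(p, sim)
        table.to_csv(events_dir / f"{p.individual}.csv")
    covars = pd.DataFrame(
        {
            "individual": [p.individual for p in params],
            "age": [p.age for p in params],
            "confounder_genotype": [p.confounder_genotype for p in params],
        }
    )
    covars.to_csv(out / "covariates.tsv", sep="\t", index=False)
    outputs["covariates"] = out / "covariates.tsv"
    # gene models: one gene per protein, anchored at a configured variant
    anchors = config.get("gene_anchors", {})
    default_anchors = np.linspace(0, sim.n_snps - 1, len(sim.proteins)).astype(int)
    gene_rows = []
    for i, pr in enumerate(sim.proteins):
        var = genotypes.variants.iloc[int(anchors.get(pr, default_anchors[i]))]
        gene_rows.append(
            {
                "gene_id": f"gene_{pr}",
                "chrom": str(var["chrom"]),
                "start": int(var["pos"]),
                "end": int(var["pos"]) + 2_000,
                "tss": int(var["pos"]),
                "strand": "+",
            }
        )
    genes = pd.DataFrame(gene_rows)
    genes.to_csv(out / "gene_models.tsv", sep="\t", index=False)
    outputs["gene_models"] = out / "gene_models.tsv"
    truth = {
        "ace_fractions": list(sim.ace_fractions),
        "qtl_effects": [list(q) for q in sim.qtl_effects],
        "seed": sim.seed,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    outputs["truth"] = out / "truth.json"
    state.update(
        sim_config=sim, pedigree=pedigree, genotypes=genotypes, params=params,
        covariates=covars, gene_models=genes, events_dir=events_dir,
    )
    return {k: str(v) for k, v in outputs.items()}


def _stage_cytometry(config, thresholds, run_dir: Path, state) -> dict:
    events_dir = Path(config.get("events_dir") or state["events_dir"])
    samples = [EventTable.from_csv(p) for p in sorted(events_dir.glob("*.csv"))]
    gates = state.get("gates") or GateTree([])
    summaries, qc = process_panel(
        samples,
        gates=gates,
        doublet_band=tuple(thresholds["doublet_band"]),
        min_events=thresholds["min_events"],
        min_cells=thresholds["min_cells"],
    )
    out = run_dir / "cytometry"
    out.mkdir(exist_ok=True)
    summaries.to_csv(out / "trait_summaries.tsv", sep="\t", index=False)
    (out / "qc_report.json").write_text(json.dumps(qc, indent=2, default=str))
    state["summaries"] = summaries
    return {
        "trait_summaries": str(out / "trait_summaries.tsv"),
        "qc_report": str(out / "qc_report.json"),
    }


def _stage_variability(config, thresholds, run_dir: Path, state) -> dict:
    summaries = state.get("summaries")
    if summaries is None:
        summaries = pd.read_csv(config["trait_summaries"], sep="\t")
    eta = eta_res_matrix(summaries)
    means = mean_matrix(summaries)
    out = run_dir / "variability"
    out.mkdir(exist_ok=True)
    eta.to_csv(out / "eta_res.tsv", sep="\t", index_label="individual")
    means.to_csv(out / "means.tsv", sep="\t", index_label="individual")
    state["eta"] = eta
    state["means"] = means
    return {"eta_res": str(out / "eta_res.tsv"), "means": str(out / "means.tsv")}


def _stage_twinvc(config, thresholds, run_dir: Path, state) -> dict:
    pedigree = state.get("pedigree") or PedigreeTable.from_tsv(config["pedigree"])
    opts = config.get("twinvc", {})
    table = ace_table(
        state["eta"],
        pedigree,
        n_boot=opts.get("n_boot", 0),
        n_perm=opts.get("n_perm", 0),
        seed=config.get("seed", 0),
    )
    out = run_dir / "twinvc"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "ace_estimates.tsv", sep="\t", index=False)
    return {"ace_estimates": str(out / "ace_estimates.tsv")}


def _scan_covariates(state, individuals) -> np.ndarray:
    covars = state["covariates"].set_index("individual").loc[list(individuals)]
    cols = [np.ones(len(individuals))]
    for name in ("age", "confounder_genotype"):
        col = covars[name].to_numpy(dtype=float)
        if np.ptp(col) > 0:  # skip constant covariates (e.g. no confounder SNP)
            cols.append(col)
    return np.column_stack(cols)


def _stage_qtlmap(config, thresholds, run_dir: Path, state) -> dict:
    genotypes: GenotypeSet = state["genotypes"]
    genotypes, qc_report = qc_variants(
        genotypes, maf_min=thresholds["maf_min"], hwe_p_max=thresholds["hwe_p_max"]
    )
    grms = loco_grms(genotypes)
    gene_models = state["gene_models"].set_index("gene_id")
    eta, means = state["eta"], state["means"]
    out = run_dir / "qtlmap"
    out.mkdir(exist_ok=True)

    trans_records, cis_records, clump_frames = [], [], []
    chrom_col = genotypes.variants["chrom"].astype(str).to_numpy()
    for trait in eta.columns:
        protein = trait.split(":")[-1]
        gene = gene_models.loc[f"gene_{protein}"]
        y = eta[trait].dropna()
        geno_t = genotypes.subset_individuals(list(y.index))
        x = _scan_covariates(state, y.index)
        # trans: scan each chromosome with its LOCO GRM, excluding the gene's
        pieces = []
        for chrom, grm in grms.items():
            if str(chrom) == str(gene["chrom"]):
                continue
            rows = [genotypes.individuals.index(i) for i in y.index]
            grm_sub = type(grm)(
                matrix=grm.matrix[np.ix_(rows, rows)],
                n_variants=grm.n_variants,
                individuals=list(y.index),
            )
            mask = chrom_col == str(chrom)
            pieces.append(
                scan_genotypes(
                    y.to_numpy(), x, geno_t, grm=grm_sub, variant_mask=mask,
                    trait=trait, scan="trans",
                )
            )
        if pieces:
            trans = pd.concat(pieces, ignore_index=True)
            trans_records.append(trans)
            clumps = ld_clump(
                trans, geno_t, p_index=thresholds["clump_p_trans"],
                r2=thresholds["clump_r2"], dist=thresholds["clump_dist"], trait=trait,
            )
            if clumps:
                clump_frames.append(clumps_to_frame(clumps))

    # cis scans on mean traits
    cis_rows = []
    for trait in means.columns:
        protein = trait.split(":")[-1]
        gene = gene_models.loc[f"gene_{protein}"]
        y = means[trait].dropna()
        geno_t = genotypes.subset_individuals(list(y.index))
        x = _scan_covariates(state, y.index)
        mask = cis_window(
            {"chrom": gene["chrom"], "tss": gene["tss"]},
            genotypes,
            half_width=thresholds["cis_half_width"],
        )
        if not mask.any():
            continue
        grm = grms[str(gene["chrom"])]
        rows = [genotypes.individuals.index(i) for i in y.index]
        grm_sub = type(grm)(
            matrix=grm.matrix[np.ix_(rows, rows)],
            n_variants=grm.n_variants,
            individuals=list(y.index),
        )
        scan = scan_genotypes(
            y.to_numpy(), x, geno_t, grm=grm_sub, variant_mask=mask,
            trait=trait, scan="cis",
        )
        cis_records.append(scan)
        null = fit_lmm_null(y.to_numpy(), x, grm_sub)
        adj_p, meta = cis_empirical_p(
            null,
            geno_t.subset_variants(mask).dosages,
            n_perm=config.get("cis_n_perm", 200),
            seed=config.get("seed", 0),
        )
        cis_rows.append({"trait": trait, "p_adjusted": adj_p, **meta})

    outputs = {}
    if trans_records:
        trans_all = pd.concat(trans_records, ignore_index=True)
        trans_all.to_csv(out / "trans_assoc.tsv", sep="\t", index=False)
        outputs["trans_assoc"] = str(out / "trans_assoc.tsv")
        state["trans_assoc"] = trans_all
    if cis_records:
        cis_all = pd.concat(cis_records, ignore_index=True)
        cis_all.to_csv(out / "cis_assoc.tsv", sep="\t", index=False)
        outputs["cis_assoc"] = str(out / "cis_assoc.tsv")
        state["cis_assoc"] = cis_all
    if cis_rows:
        cis_traits = pd.DataFrame(cis_rows)
        qv, flags = fdr_bh(
            np.clip(cis_traits["p_adjusted"].to_numpy(), 1e-300, 1.0),
            q=thresholds["cis_fdr"],
        )
        cis_traits["q_fdr"] = qv
        cis_traits["pass_fdr"] = flags
        cis_traits.to_csv(out / "cis_trait_level.tsv", sep="\t", index=False)
        outputs["cis_trait_level"] = str(out / "cis_trait_level.tsv")
    if clump_frames:
        clumps_all = pd.concat(clump_frames, ignore_index=True)
    else:
        clumps_all = pd.DataFrame(
            columns=["trait", "index_snp", "index_p", "chrom", "pos", "n_members", "members"]
        )
    clumps_all.to_csv(out / "clumps.tsv", sep="\t", index=False)
    outputs["clumps"] = str(out / "clumps.tsv")
    state["clumps"] = clumps_all
    (out / "variant_qc.json").write_text(json.dumps(qc_report, indent=2))
    outputs["variant_qc"] = str(out / "variant_qc.json")
    state["qc_genotypes"] = genotypes
    return outputs


def _stage_mr(config, thresholds, run_dir: Path, state) -> dict:
    """Exposure = cis mean-expression stats per eGene; outcome = trans
    variability stats; one MR test per (varSNP clump, eGene) pair."""
    out = run_dir / "mr"
    out.mkdir(exist_ok=True)
    clumps = state.get("clumps")
    cis_assoc = state.get("cis_assoc")
    results_path = out / "mr_results.tsv"
    if clumps is None or clumps.empty or cis_assoc is None or cis_assoc.empty:
        pd.DataFrame().to_csv(results_path, sep="\t", index=False)
        return {"mr_results": str(results_path)}

    def to_stats(df):
        stats_df = df.rename(columns={"gamma_hat": "beta"})[
            ["snp", "chrom", "pos", "beta", "se", "p", "trait"]
        ].copy()
        stats_df["effect_allele"] = "G"
        stats_df["other_allele"] = "A"
        return stats_df

    trans_stats = to_stats(state["trans_assoc"])
    pairs = []
    for _, clump in clumps.iterrows():
        outcome_stats = trans_stats[trans_stats["trait"] == clump["trait"]]
        for exp_trait, grp in to_stats(cis_assoc).groupby("trait"):
            sel = select_instruments(
                int(clump["pos"]),
                str(clump["chrom"]),
                grp,
                outcome_stats,
                window=thresholds["mr_window"],
                p_max=thresholds["mr_p_max"],
            )
            if sel.empty:
                continue
            outcome_sel = outcome_stats.set_index("snp").loc[sel["snp"]].reset_index()
            ins, _ = build_instrument_set(
                sel, outcome_sel, exposure=str(exp_trait), outcome=str(clump["trait"])
            )
            if ins.n_instruments:
                pairs.append(ins)
    results = mr_screen(pairs, fdr=thresholds["mr_fdr"])
    results.to_csv(results_path, sep="\t", index=False)
    return {"mr_results": str(results_path)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "cytometry": _stage_cytometry,
    "variability": _stage_variability,
    "twinvc": _stage_twinvc,
    "qtlmap": _stage_qtlmap,
    "mr": _stage_mr,
}
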