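"""Tests for genotype QC, GRMs, the LMM scan, clumping and annotation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vprotqtl.genotypes import GenotypeSet
from vprotqtl.qtlmap import (
    cis_empirical_p,
    cis_window,
    compute_grm,
    dosage_r2,
    downsample_sensitivity,
    fdr_bh,
    fit_lmm_null,
    hwe_chi2,
    ld_clump,
    lmm_scan,
    loco_grms,
    qc_variants,
    scan_genotypes,
)
from vprotqtl.qtlmap.annotate import annotate_varsnps, nearest_tss_distance, tss_enrichment
from vprotqtl.synthgen import SimConfig, simulate_genotypes


def make_genotypes(dosages, chrom=None, pos=None, ids=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeSet(
        variants=pd.DataFrame(
            {
                "id": ids or [f"s{j}" for j in range(m)],
                "chrom": chrom or ["1"] * m,
                "pos": pos or [(j + 1) * 1000 for j in range(m)],
                "ref": "A",
                "alt": "G",
            }
        ),
        dosages=dosages,
        individuals=[f"i{k}" for k in range(n)],
    )


class TestHWE:
    def test_exact_proportions(self):
        chi2, p = hwe_chi2(25, 50, 25)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # p_hat = (60+30)/200 = 0.45; expected (20.25, 49.5, 30.25)
        expected = np.array([100 * 0.45**2, 2 * 100 * 0.45 * 0.55, 100 * 0.55**2])
        observed = np.array([30.0, 30.0, 40.0])
        oracle = float(((observed - expected) ** 2 / expected).sum())
        chi2, _ = hwe_chi2(30, 30, 40)
        assert chi2 == pytest.approx(oracle)
        assert chi2 == pytest.approx(15.52, abs=0.01)

    def test_no_hets(self):
        chi2, _ = hwe_chi2(50, 0, 50)
        assert chi2 == pytest.approx(100.0)

    def test_monomorphic_undefined(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_chi2(100, 0, 0)


class TestQCVariants:
    def test_maf_thresholds(self):
        n = 100
        dos = np.zeros((n, 3))
        dos[0, 0] = 1.0          # freq 1/200 = 0.005 -> excluded
        dos[:2, 1] = 1.0         # freq 2/200 = 0.01  -> retained (strict <)
        dos[: n // 2, 2] = 1.0   # freq 0.25          -> retained
        geno = make_genotypes(dos)
        kept, report = qc_variants(geno)
        assert list(kept.variants["id"]) == ["s1", "s2"]
        assert report["n_removed_maf"] == 1

    def test_hwe_boundary_excluded(self):
        # a variant violating HWE: boundary p <= threshold is excluded
        dos = np.array([[2.0] * 30 + [0.0] * 30 + [1.0] * 0]).reshape(-1, 1)
        geno = make_genotypes(dos)
        _, p = hwe_chi2(30, 0, 30)
        kept, report = qc_variants(geno, hwe_p_max=p)
        assert report["n_removed_hwe"] == 1
        assert kept.n_variants == 0

    def test_hwe_just_above_boundary_retained(self):
        dos = np.array([[2.0] * 30 + [0.0] * 30]).reshape(-1, 1)
        geno = make_genotypes(dos)
        _, p = hwe_chi2(30, 0, 30)
        kept, _ = qc_variants(geno, hwe_p_max=p * 0.999)
        assert kept.n_variants == 1


class TestGRM:
    def test_single_variant_diagonal(self):
        geno = make_genotypes(np.array([[0.0], [1.0], [2.0]]))
        grm = compute_grm(geno)
        # p = 0.5: z = (g-1)/sqrt(0.5) -> diag {2, 0, 2}
        np.testing.assert_allclose(np.diag(grm.matrix), [2.0, 0.0, 2.0])

    def test_identical_rows_look_like_self(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, (10, 2000)).astype(float)
        g[1] = g[0]  # MZ-like pair
        grm = compute_grm(make_genotypes(g))
        assert grm.matrix[0, 1] == pytest.approx(grm.matrix[0, 0])

    def test_unrelated_off_diagonal_small(self):
        # in-sample frequencies give mean off-diagonal ~ -1/(n-1), so a
        # moderately large cohort is needed for the +/-0.02 bound
        rng = np.random.default_rng(1)
        n = 200
        g = rng.binomial(2, 0.3, (n, 5000)).astype(float)
        grm = compute_grm(make_genotypes(g))
        off = grm.matrix[np.triu_indices(n, k=1)]
        assert abs(off.mean()) < 0.02

    def test_mean_diagonal_near_one(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, (50, 2000)).astype(float)
        grm = compute_grm(make_genotypes(g))
        assert abs(np.diag(grm.matrix).mean() - 1.0) < 0.1

    def test_monomorphic_skipped(self):
        g = np.column_stack([np.zeros(10), np.random.default_rng(3).binomial(2, 0.4, 10)])
        with pytest.warns(UserWarning, match="monomorphic"):
            grm = compute_grm(make_genotypes(g.astype(float)))
        assert grm.n_variants == 1


class TestLOCO:
    def _geno(self, seed=4, n=30, m=40, n_chrom=4):
        cfg = SimConfig(seed=seed, n_individuals=n, n_snps=m, n_chromosomes=n_chrom,
                        maf_range=(0.2, 0.5))
        return simulate_genotypes(cfg)

    def test_complement_uses_other_chromosomes(self):
        geno = self._geno(n_chrom=2)
        grms = loco_grms(geno)
        chr2_mask = (geno.variants["chrom"] == "2").to_numpy()
        direct = compute_grm(geno, chr2_mask)
        np.testing.assert_allclose(grms["1"].matrix, direct.matrix, atol=1e-12)

    def test_weighted_additivity_identity(self):
        # m_total * GRM_all = m_c * GRM_c + m_not_c * GRM_not_c entrywise
        geno = self._geno()
        grm_all = compute_grm(geno)
        grms = loco_grms(geno)
        for c in ("1", "2", "3", "4"):
            mask = (geno.variants["chrom"] == c).to_numpy()
            grm_c = compute_grm(geno, mask)
            lhs = grm_all.n_variants * grm_all.matrix
            rhs = grm_c.n_variants * grm_c.matrix + grms[c].n_variants * grms[c].matrix
            np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_single_chromosome_errors(self):
        geno = self._geno(n_chrom=1)
        with pytest.raises(ValueError, match="chromosomes"):
            loco_grms(geno)


class TestLMM:
    def test_identity_grm_equals_ols(self, rng):
        n, m = 150, 30
        g = rng.binomial(2, 0.3, (n, m)).astype(float)
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        null = fit_lmm_null(y, x, None)
        out = lmm_scan(null, g)
        for j in range(m):
            design = np.column_stack([x, g[:, j]])
            beta, rss, *_ = np.linalg.lstsq(design, y, rcond=None)
            df = n - design.shape[1]
            sigma2 = rss[0] / df
            se = np.sqrt(sigma2 * np.linalg.inv(design.T @ design)[-1, -1])
            t = beta[-1] / se
            p = 2 * stats.t.sf(abs(t), df=df)
            assert out["gamma_hat"][j] == pytest.approx(beta[-1], abs=1e-8)
            assert out["se"][j] == pytest.approx(se, abs=1e-8)
            assert out["p"][j] == pytest.approx(p, abs=1e-8)

    def test_identity_grm_total_variance(self, rng):
        n = 200
        x = np.ones((n, 1))
        y = rng.normal(size=n)
        null = fit_lmm_null(y, x, None)
        resid_var = y.var(ddof=1)
        assert null.sigma_g2 + null.sigma_e2 == pytest.approx(resid_var, abs=1e-6)

    def test_exact_fit_zero_variance(self):
        n = 50
        x = np.column_stack([np.ones(n), np.arange(n, dtype=float)])
        y = x @ np.array([1.0, 0.5])
        null = fit_lmm_null(y, x, None)
        assert null.sigma_g2 + null.sigma_e2 == pytest.approx(0.0, abs=1e-12)

    def test_variance_component_recovery(self):
        # twin-structured GRM with known variance split
        from conftest import make_pedigree
        from vprotqtl.twinvc import relatedness_matrices
        from vprotqtl.qtlmap.grm import GRM

        rng = np.random.default_rng(5)
        ped = make_pedigree(250, 250)
        k = relatedness_matrices(ped).genetic
        n = k.shape[0]
        lam, u = np.linalg.eigh(k)
        y = u @ (np.sqrt(np.clip(lam, 0, None) * 0.5) * rng.normal(size=n))
        y = y + rng.normal(0, np.sqrt(0.5), n)
        null = fit_lmm_null(y, np.ones((n, 1)), GRM(matrix=k, n_variants=1))
        assert abs(null.sigma_g2 - 0.5) < 0.1
        assert abs(null.sigma_e2 - 0.5) < 0.1

    def test_effect_recovery_within_2se(self, rng):
        n = 800
        hits = 0
        for rep in range(30):
            g = rng.binomial(2, 0.3, (n, 1)).astype(float)
            y = 0.5 * (g[:, 0] - g[:, 0].mean()) + rng.normal(size=n)
            null = fit_lmm_null(y, np.ones((n, 1)), None)
            out = lmm_scan(null, g)
            hits += abs(out["gamma_hat"][0] - 0.5) < 2 * out["se"][0]
        assert hits >= 27

    def test_collinear_snp_flagged(self, rng):
        n = 100
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        null = fit_lmm_null(rng.normal(size=n), x, None)
        out = lmm_scan(null, x[:, 1:2].copy())
        assert bool(out["collinear"][0])
        assert np.isnan(out["p"][0])

    def test_rank_deficient_x_rejected(self, rng):
        n = 50
        x = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            fit_lmm_null(rng.normal(size=n), x, None)

    def test_non_psd_grm_rejected(self, rng):
        from vprotqtl.qtlmap.grm import GRM

        n = 20
        mat = -np.eye(n)
        with pytest.raises(ValueError, match="PSD"):
            fit_lmm_null(rng.normal(size=n), np.ones((n, 1)), GRM(matrix=mat, n_variants=1))


class TestCisWindow:
    def _geno(self):
        return make_genotypes(
            np.random.default_rng(0).binomial(2, 0.3, (10, 5)).astype(float),
            chrom=["1", "1", "1", "1", "2"],
            pos=[9_499_999, 9_500_000, 10_000_000, 10_500_000, 10_000_000],
        )

    def test_window_geometry(self):
        mask = cis_window({"chrom": "1", "tss": 10_000_000}, self._geno())
        # closed interval [9.5e6, 10.5e6]; 9,499,999 is outside
        np.testing.assert_array_equal(mask, [False, True, True, True, False])

    def test_other_chromosome_excluded(self):
        mask = cis_window({"chrom": "2", "tss": 10_000_000}, self._geno())
        np.testing.assert_array_equal(mask, [False, False, False, False, True])


class TestCisEmpiricalP:
    def test_single_snp_window_adjusted_near_nominal(self, rng):
        n = 200
        g = rng.binomial(2, 0.3, (n, 1)).astype(float)
        y = rng.normal(size=n)
        null = fit_lmm_null(y, np.ones((n, 1)), None)
        nominal = lmm_scan(null, g)["p"][0]
        adj, meta = cis_empirical_p(null, g, n_perm=300, seed=0)
        assert abs(adj - nominal) < 0.1

    def test_n_perm_minimum(self, rng):
        n = 50
        null = fit_lmm_null(rng.normal(size=n), np.ones((n, 1)), None)
        with pytest.raises(ValueError, match="n_perm"):
            cis_empirical_p(null, rng.binomial(2, 0.3, (n, 2)).astype(float), n_perm=10)


class TestFdrBH:
    def test_hand_example(self):
        q, _ = fdr_bh([0.01, 0.02, 0.04])
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])

    def test_single_p(self):
        q, _ = fdr_bh([0.73])
        assert q[0] == pytest.approx(0.73)

    def test_all_ones_no_discoveries(self):
        q, flags = fdr_bh([1.0, 1.0, 1.0], q=0.99)
        assert not flags.any()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.0, 0.5])


def brute_force_clump(assoc, r2_matrix, p_index, dist):
    """Independent reference: greedy clumping from explicit r2 entries."""
    passing = assoc[assoc["p"] <= p_index].copy()
    passing = passing.sort_values(["p", "chrom", "pos", "snp"], kind="mergesort")
    taken = set()
    clumps = []
    for _, row in passing.iterrows():
        if row["snp"] in taken:
            continue
        taken.add(row["snp"])
        members = []
        for _, other in passing.iterrows():
            if other["snp"] in taken:
                continue
            if other["chrom"] != row["chrom"] or abs(other["pos"] - row["pos"]) > dist:
                continue
            if r2_matrix.loc[row["snp"], other["snp"]] > 0.5:
                taken.add(other["snp"])
                members.append(other["snp"])
        clumps.append((row["snp"], tuple(sorted(members))))
    return clumps


class TestLdClump:
    def test_hand_oracle(self):
        rng = np.random.default_rng(6)
        n = 400
        a = rng.binomial(2, 0.4, n).astype(float)
        flip = rng.random(n) < 0.05
        b = np.where(flip, rng.binomial(2, 0.4, n), a).astype(float)  # high r2 with A
        c = rng.binomial(2, 0.4, n).astype(float)                     # independent
        geno = make_genotypes(
            np.column_stack([a, b, c]), pos=[100_000, 110_000, 150_000],
            ids=["A", "B", "C"],
        )
        assert dosage_r2(geno, 0, 1) > 0.5
        assert dosage_r2(geno, 0, 2) < 0.5
        assoc = pd.DataFrame(
            {"trait": "t", "snp": ["A", "B", "C"], "chrom": "1",
             "pos": [100_000, 110_000, 150_000], "p": [1e-6, 1e-5, 2e-5]}
        )
        clumps = ld_clump(assoc, geno, p_index=1e-4)
        assert [(c.index_snp, tuple(c.members)) for c in clumps] == [("A", ("B",)), ("C", ())]

    def test_no_ld_every_snp_own_clump(self):
        rng = np.random.default_rng(7)
        geno = make_genotypes(rng.binomial(2, 0.3, (500, 5)).astype(float))
        assoc = pd.DataFrame(
            {"trait": "t", "snp": [f"s{j}" for j in range(5)], "chrom": "1",
             "pos": [(j + 1) * 1000 for j in range(5)],
             "p": [1e-6, 2e-6, 3e-6, 4e-6, 5e-6]}
        )
        clumps = ld_clump(assoc, geno, p_index=1e-4)
        assert len(clumps) == 5
        assert all(c.n_members == 0 for c in clumps)

    def test_empty_when_nothing_passes(self):
        geno = make_genotypes(np.random.default_rng(8).binomial(2, 0.3, (50, 3)).astype(float))
        assoc = pd.DataFrame(
            {"trait": "t", "snp": ["s0", "s1", "s2"], "chrom": "1",
             "pos": [1000, 2000, 3000], "p": [0.5, 0.6, 0.7]}
        )
        assert ld_clump(assoc, geno, p_index=1e-4) == []

    def test_partition_property(self):
        cfg = SimConfig(seed=9, n_individuals=200, n_snps=50, n_chromosomes=2,
                        ld_block_size=5, ld_rho=0.9, maf_range=(0.2, 0.5))
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(10)
        assoc = pd.DataFrame(
            {"trait": "t", "snp": geno.variants["id"], "chrom": geno.variants["chrom"],
             "pos": geno.variants["pos"], "p": rng.uniform(1e-8, 1e-3, 50)}
        )
        clumps = ld_clump(assoc, geno, p_index=1e-4)
        assigned = [c.index_snp for c in clumps] + [m for c in clumps for m in c.members]
        passing = assoc.loc[assoc["p"] <= 1e-4, "snp"]
        assert sorted(assigned) == sorted(passing)

    def test_matches_brute_force_on_random_instances(self):
        for seed in range(10):
            cfg = SimConfig(seed=100 + seed, n_individuals=120, n_snps=60,
                            n_chromosomes=2, ld_block_size=6, ld_rho=0.85,
                            maf_range=(0.1, 0.5), variant_spacing=60_000)
            geno = simulate_genotypes(cfg)
            rng = np.random.default_rng(seed)
            assoc = pd.DataFrame(
                {"trait": "t", "snp": geno.variants["id"],
                 "chrom": geno.variants["chrom"].astype(str),
                 "pos": geno.variants["pos"],
                 "p": rng.uniform(1e-10, 2e-4, 60)}
            )
            d = geno.dosages
            z = (d - d.mean(axis=0)) / np.maximum(d.std(axis=0), 1e-12)
            r2 = pd.DataFrame((z.T @ z / len(d)) ** 2,
                              index=geno.variants["id"], columns=geno.variants["id"])
            expected = brute_force_clump(assoc, r2, 1e-4, 250_000)
            got = [
                (c.index_snp, tuple(sorted(c.members)))
                for c in ld_clump(assoc, geno, p_index=1e-4)
            ]
            assert got == expected, f"seed {seed}"


GENES = pd.DataFrame(
    {
        "gene_id": ["gplus", "gminus"],
        "chrom": ["1", "1"],
        "start": [100_000, 300_000],
        "end": [120_000, 320_000],
        "tss": [100_000, 320_000],
        "strand": ["+", "-"],
    }
)


class TestAnnotate:
    def _snps(self, positions, chrom="1"):
        return pd.DataFrame(
            {"snp": [f"v{i}" for i in range(len(positions))],
             "chrom": chrom, "pos": positions}
        )

    def test_gene_body_transcribed(self):
        out = annotate_varsnps(self._snps([110_000]), GENES)
        assert out["category"][0] == "transcribed"

    def test_strand_aware_flanks(self):
        # 3kb 5' of the + strand TSS -> upstream
        out = annotate_varsnps(self._snps([97_000]), GENES)
        assert out["category"][0] == "upstream"
        # 3kb past the + strand gene end -> downstream
        out = annotate_varsnps(self._snps([123_000]), GENES)
        assert out["category"][0] == "downstream"
        # 3kb beyond the - strand gene's TSS side (end) -> upstream
        out = annotate_varsnps(self._snps([323_000]), GENES)
        assert out["category"][0] == "upstream"
        # 3kb before the - strand gene start -> downstream
        out = annotate_varsnps(self._snps([297_000]), GENES)
        assert out["category"][0] == "downstream"

    def test_intergenic_and_missing_chrom(self):
        out = annotate_varsnps(self._snps([200_000]), GENES)
        assert out["category"][0] == "intergenic"
        with pytest.warns(UserWarning, match="absent"):
            out = annotate_varsnps(self._snps([100], chrom="9"), GENES)
        assert out["category"][0] == "intergenic"
        assert np.isnan(out["dist_tss"][0])

    def test_nearest_tss_tie_goes_to_lower_coordinate(self):
        # equidistant between TSS 100,000 (+) and 320,000 (-): midpoint 210,000
        d = nearest_tss_distance(self._snps([210_000]), GENES)
        assert d[0] == 110_000  # + strand gene at the lower coordinate wins


class TestTssEnrichment:
    def test_cross_product_odds_ratio(self):
        rng = np.random.default_rng(11)
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["1"], "start": [1_000_000],
             "end": [1_010_000], "tss": [1_000_000], "strand": ["+"]}
        )
        # 30/100 cases within 100kb of the TSS, 20/100 controls
        case_pos = np.concatenate([
            np.linspace(950_000, 1_050_000, 30),
            np.linspace(2_000_000, 3_000_000, 70),
        ]).astype(int)
        ctrl_pos = np.concatenate([
            np.linspace(950_000, 1_050_000, 20),
            np.linspace(2_000_000, 3_000_000, 80),
        ]).astype(int)
        cases = pd.DataFrame({"snp": [f"c{i}" for i in range(100)], "chrom": "1",
                              "pos": case_pos, "maf": 0.26})
        pool = pd.DataFrame({"snp": [f"p{i}" for i in range(100)], "chrom": "1",
                             "pos": ctrl_pos, "maf": 0.27})
        all_snps = pd.concat([cases, pool], ignore_index=True)
        odds, p, table = tss_enrichment(cases, all_snps, genes, seed=0)
        assert odds == pytest.approx((30 * 80) / (70 * 20))
        assert 0 < p <= 1

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(12)
        genes = pd.DataFrame(
            {"gene_id": ["g"], "chrom": ["1"], "start": [500_000],
             "end": [510_000], "tss": [500_000], "strand": ["+"]}
        )
        cases = pd.DataFrame({"snp": [f"c{i}" for i in range(20)], "chrom": "1",
                              "pos": rng.integers(0, 2_000_000, 20), "maf": rng.uniform(0.05, 0.5, 20)})
        pool = pd.DataFrame({"snp": [f"p{i}" for i in range(200)], "chrom": "1",
                             "pos": rng.integers(0, 2_000_000, 200),
                             "maf": rng.uniform(0.05, 0.5, 200)})
        all_snps = pd.concat([cases, pool], ignore_index=True)
        r1 = tss_enrichment(cases, all_snps, genes, seed=5)
        r2 = tss_enrichment(cases, all_snps, genes, seed=5)
        assert r1[0] == r2[0] and r1[1] == r2[1]


class TestDownsample:
    def test_full_fraction_recovers_everything(self):
        cfg = SimConfig(seed=13, n_individuals=400, n_snps=30, n_chromosomes=2,
                        maf_range=(0.3, 0.4))
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(14)
        g = geno.dosages[:, 4]
        y = 0.8 * (g - g.mean()) + rng.normal(0, 1.0, 400)
        out = downsample_sensitivity(
            y, np.ones((400, 1)), geno, fractions=(0.05, 0.5, 1.0), seed=0
        )
        full = out.loc[out["fraction"] == 1.0, "recovery"].iloc[0]
        assert full == 1.0
        assert (out.loc[out["fraction"] == 0.5, "recovery"] <= full).all()
        # fraction 0.05 -> 20 < 30 individuals, skipped with warning
        assert 0.05 not in set(out["fraction"])
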