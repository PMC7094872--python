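"""ACE variance decomposition in twin cohorts.

Maximum-likelihood fit of the covariance sigma_A^2*K + sigma_C^2*S +
sigma_E^2*I, parametrized by path coefficients (a, c, e) so the variance
components are non-negative by construction. K carries 1 for MZ co-twins and
1/2 for DZ co-twins; S carries 1 within twin pairs. Because families are
pairs or singletons, the likelihood factorizes into closed-form 2x2 blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from vprotqtl.pedigree import PedigreeTable


@dataclass
class ExpectedRelatednessMatrices:
    """Zygosity-expected genetic (K) and shared-environment (S) matrices."""

    individuals: list[str]
    genetic: np.ndarray = field(repr=False)
    shared_env: np.ndarray = field(repr=False)


def relatedness_matrices(pedigree: PedigreeTable) -> ExpectedRelatednessMatrices:
    inds = pedigree.individuals
    idx = {ind: i for i, ind in enumerate(inds)}
    n = len(inds)
    genetic = np.eye(n)
    shared = np.eye(n)
    for a, b, zyg in pedigree.pairs():
        i, j = idx[a], idx[b]
        genetic[i, j] = genetic[j, i] = 1.0 if zyg == "MZ" else 0.5
        shared[i, j] = shared[j, i] = 1.0
    return ExpectedRelatednessMatrices(inds, genetic, shared)


@dataclass
class ACEEstimate:
    sigma_a2: float
    sigma_c2: float
    sigma_e2: float
    a2: float
    c2: float
    e2: float
    loglik: float
    n_pairs_mz: int
    n_pairs_dz: int
    n_unrelated: int
    se: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)

    @property
    def fractions(self) -> tuple[float, float, float]:
        return (self.a2, self.c2, self.e2)


def _collect(y: pd.Series, pedigree: PedigreeTable):
    """Split centered trait values into MZ/DZ pair arrays and singletons."""
    y = y.dropna()
    have = set(y.index)
    mz, dz, singles = [], [], []
    for a, b, zyg in pedigree.pairs():
        if a in have and b in have:
            (mz if zyg == "MZ" else dz).append((y[a], y[b]))
        else:
            singles.extend(y[i] for i in (a, b) if i in have)
    singles.extend(y[i] for i in pedigree.unrelated() if i in have)
    return (
        np.asarray(mz, dtype=float).reshape(-1, 2),
        np.asarray(dz, dtype=float).reshape(-1, 2),
        np.asarray(singles, dtype=float),
    )


def _nll(params: np.ndarray, mz: np.ndarray, dz: np.ndarray, singles: np.ndarray) -> float:
    a, c, e = params
    a2, c2, e2 = a * a, c * c, e * e
    v = a2 + c2 + e2
    if v <= 0:
        return np.inf
    total = 0.0
    for pairs, k in ((mz, a2 + c2), (dz, 0.5 * a2 + c2)):
        if len(pairs) == 0:
            continue
        det = v * v - k * k
        if det <= 0:
            return np.inf
        q = (v * (pairs[:, 0] ** 2 + pairs[:, 1] ** 2) - 2 * k * pairs[:, 0] * pairs[:, 1]) / det
        total += 0.5 * np.sum(np.log(det) + q) + len(pairs) * np.log(2 * np.pi)
    if len(singles):
        total += 0.5 * np.sum(np.log(v) + singles**2 / v) + 0.5 * len(singles) * np.log(
            2 * np.pi
        )
    return float(total)


def _empirical_pair_corr(pairs: np.ndarray) -> float:
    if len(pairs) < 3:
        return 0.0
    doubled = np.vstack([pairs, pairs[:, ::-1]])  # symmetrize
    return float(np.corrcoef(doubled[:, 0], doubled[:, 1])[0, 1])


def residualize(y: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """OLS residuals of y on covariates (plus intercept), index-aligned."""
    x = covariates.loc[y.index].to_numpy(dtype=float)
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y.to_numpy(dtype=float), rcond=None)
    return pd.Series(y.to_numpy() - design @ coef, index=y.index, name=y.name)


def ace_fit(
    y: pd.Series,
    pedigree: PedigreeTable,
    covariates: pd.DataFrame | None = None,
    min_pairs: int = 20,
    n_restarts: int = 5,
) -> ACEEstimate:
    """Maximum-likelihood ACE fit of one trait.

    ``y`` is indexed by individual id; it is centered internally (and
    optionally residualized on covariates first). Raises if the cohort has
    no MZ or no DZ pairs (A and C not separately identifiable).
    """
    if covariates is not None:
        y = residualize(y, covariates)
    y = y - y.mean()
    mz, dz, singles = _collect(y, pedigree)
    if len(mz) == 0 or len(dz) == 0:
        raise ValueError("A and C not separately identifiable: need both MZ and DZ pairs")
    if len(mz) + len(dz) < min_pairs:
        raise ValueError(f"need >= {min_pairs} complete twin pairs, got {len(mz) + len(dz)}")

    var_y = float(np.var(np.concatenate([mz.ravel(), dz.ravel(), singles]), ddof=1))
    if var_y <= 0:
        raise ValueError("trait has zero variance")

    r_mz = _empirical_pair_corr(mz)
    r_dz = _empirical_pair_corr(dz)
    a2_0 = np.clip(2 * (r_mz - r_dz), 0.02, 0.95)
    c2_0 = np.clip(2 * r_dz - r_mz, 0.02, 0.95)
    e2_0 = max(1.0 - a2_0 - c2_0, 0.02)
    starts = [np.sqrt(np.array([a2_0, c2_0, e2_0]) * var_y)]
    rng = np.random.default_rng(12345)
    for _ in range(n_restarts - 1):
        f = rng.dirichlet([1.0, 1.0, 1.0])
        starts.append(np.sqrt(f * var_y))

    best = None
    for x0 in starts:
        res = optimize.minimize(
            _nll,
            x0,
            args=(mz, dz, singles),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("ACE optimizer failed to converge")
    # baseline sanity: the optimum must beat the pure-E model
    baseline = _nll(np.array([0.0, 0.0, np.sqrt(var_y)]), mz, dz, singles)
    if best.fun > baseline + 1e-6:
        raise RuntimeError(
            f"ACE optimizer non-convergence: nll {best.fun:.6f} worse than "
            f"pure-E baseline {baseline:.6f}"
        )
    a2, c2, e2 = np.asarray(best.x) ** 2
    total = a2 + c2 + e2
    return ACEEstimate(
        sigma_a2=float(a2),
        sigma_c2=float(c2),
        sigma_e2=float(e2),
        a2=float(a2 / total),
        c2=float(c2 / total),
        e2=float(e2 / total),
        loglik=float(-best.fun),
        n_pairs_mz=len(mz),
        n_pairs_dz=len(dz),
        n_unrelated=len(singles),
    )


def falconer_fractions(y: pd.Series, pedigree: PedigreeTable) -> tuple[float, float, float]:
    """Closed-form Falconer estimates: a2 = 2(r_MZ - r_DZ), c2 = 2r_DZ - r_MZ."""
    yc = y - y.mean()
    mz, dz, _ = _collect(yc, pedigree)
    r_mz = _empirical_pair_corr(mz)
    r_dz = _empirical_pair_corr(dz)
    a2 = 2 * (r_mz - r_dz)
    c2 = 2 * r_dz - r_mz
    return (a2, c2, 1.0 - a2 - c2)


def ace_bootstrap(
    y: pd.Series,
    pedigree: PedigreeTable,
    n_boot: int = 100,
    pair_fraction: float = 0.75,
    seed: int = 0,
    min_pairs: int = 20,
) -> dict[str, float]:
    """Bootstrap SEs: refit on random 75% subsets of twin pairs.

    Pairs are resampled without replacement (co-twins never split);
    unrelated singletons are always retained. Failed replicates are dropped
    with a warning; more than 20% failures is an error.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50")
    rng = np.random.default_rng(seed)
    pair_families = sorted(
        set(pedigree.table.loc[pedigree.table["zygosity"] != "unrelated", "family"])
    )
    n_take = max(1, int(round(pair_fraction * len(pair_families))))
    estimates = []
    n_fail = 0
    for _ in range(n_boot):
        take = set(rng.choice(pair_families, size=n_take, replace=False))
        mask = (pedigree.table["zygosity"] == "unrelated") | pedigree.table["family"].isin(take)
        sub = PedigreeTable(pedigree.table.loc[mask].reset_index(drop=True))
        try:
            est = ace_fit(
                y[y.index.isin(sub.individuals)], sub, min_pairs=min(min_pairs, n_take)
            )
            estimates.append(est.fractions)
        except (ValueError, RuntimeError) as exc:
            n_fail += 1
            warnings.warn(f"bootstrap replicate failed: {exc}", stacklevel=2)
    if n_fail > 0.2 * n_boot:
        raise RuntimeError(f"{n_fail}/{n_boot} bootstrap replicates failed")
    arr = np.asarray(estimates)
    return {
        "a2": float(arr[:, 0].std(ddof=1)),
        "c2": float(arr[:, 1].std(ddof=1)),
        "e2": float(arr[:, 2].std(ddof=1)),
    }


def permutation_pvalue(test: float, null: np.ndarray, convention: str = "paper") -> float:
    """Permutation p for one component.

    ``paper`` follows the printed formula p = 1 - (#{test > null} + 1) /
    (n_perm + 1) exactly; ``standard`` is (#{null >= test} + 1) / (n_perm + 1).
    """
    n_perm = len(null)
    if convention == "paper":
        return 1.0 - (float(np.sum(test > null)) + 1.0) / (n_perm + 1.0)
    if convention == "standard":
        return (float(np.sum(null >= test)) + 1.0) / (n_perm + 1.0)
    raise ValueError(f"unknown convention {convention!r}")


def ace_permutation_p(
    y: pd.Series,
    pedigree: PedigreeTable,
    n_perm: int = 100,
    seed: int = 0,
    convention: str = "paper",
    min_pairs: int = 20,
) -> dict[str, float]:
    """Zygosity-label permutation p-values for the variance fractions.

    Zygosity labels are permuted between twin families (pair structure
    kept), the model refit per permutation, and the p-value computed per
    component from the null distribution of fraction estimates.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    test = ace_fit(y, pedigree, min_pairs=min_pairs)
    rng = np.random.default_rng(seed)
    twins = pedigree.table["zygosity"] != "unrelated"
    fam_labels = (
        pedigree.table.loc[twins]
        .drop_duplicates("family")
        .set_index("family")["zygosity"]
    )
    families = fam_labels.index.to_numpy()
    labels = fam_labels.to_numpy()
    null = {"a2": [], "c2": [], "e2": []}
    for _ in range(n_perm):
        perm = dict(zip(families, rng.permutation(labels)))
        table = pedigree.table.copy()
        table.loc[twins, "zygosity"] = table.loc[twins, "family"].map(perm)
        permuted = PedigreeTable(table)
        est = ace_fit(y, permuted, min_pairs=min_pairs)
        for key, val in zip(("a2", "c2", "e2"), est.fractions):
            null[key].append(val)
    return {
        key: permutation_pvalue(test_val, np.asarray(null[key]), convention)
        for key, test_val in zip(("a2", "c2", "e2"), test.fractions)
    }


def ace_table(
    matrix: pd.DataFrame,
    pedigree: PedigreeTable,
    n_boot: int = 0,
    n_perm: int = 0,
    seed: int = 0,
    min_pairs: int = 20,
) -> pd.DataFrame:
    """Per-trait ACE summary over the columns of a trait matrix."""
    rows = []
    for trait in matrix.columns:
        y = matrix[trait].dropna()
        est = ace_fit(y, pedigree, min_pairs=min_pairs)
        row = {
            "trait": trait,
            "sigma_a2": est.sigma_a2,
            "sigma_c2": est.sigma_c2,
            "sigma_e2": est.sigma_e2,
            "a2": est.a2,
            "c2": est.c2,
            "e2": est.e2,
            "loglik": est.loglik,
        }
        if n_boot:
            se = ace_bootstrap(y, pedigree, n_boot=n_boot, seed=seed, min_pairs=min_pairs)
            row.update({f"se_{k}": v for k, v in se.items()})
        if n_perm:
            p = ace_permutation_p(y, pedigree, n_perm=n_perm, seed=seed, min_pairs=min_pairs)
            row.update({f"p_{k}": v for k, v in p.items()})
        rows.append(row)
    return pd.DataFrame(rows)
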