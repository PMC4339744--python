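"""Simulation of pedigree genotype/phenotype datasets.

The generative model: two test loci on a shared haplotype (no
recombination) with founder haplotypes drawn from the 4-category law implied
by the marginal minor-allele frequencies and Lewontin's D'; Mendelian
transmission through a fixed family template; additive polygenic effects
(founders MVN(0, Sigma_B), offspring = parental average + MVN(0, 0.5 Sigma_B));
independent Gaussian errors; optional dichotomization by a liability
threshold chosen to preserve the target prevalence; and optional two-
subpopulation structure with Balding-Nichols allele frequencies, a 0.2
between-population phenotype mean shift, and a dense null-marker panel for
estimating the genomic relationship matrix.

Replicate studies (type-I error calibration and power) run the full
pipeline — simulate, fit the null mixed models, adjust phenotypes, test —
once per replicate, reusing the cached family-block eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from mfqls.core import variant_test
from mfqls.exceptions import DataError
from mfqls.genotype_model import GenotypeMatrix
from mfqls.linalg import BlockPhiOps, as_phi_ops
from mfqls.null_model import CovariateMatrix, PhenotypeMatrix
from mfqls.pedigree_kinship import (
    Pedigree,
    canonical_pedigree,
    grm_from_genotypes,
    kinship_from_pedigree,
)

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "haplotype_freqs",
    "simulate_family_genotypes",
    "simulate_polygenic",
    "assemble_quantitative",
    "dichotomize_liability",
    "balding_nichols_freqs",
    "simulate_dataset",
    "simulate_structured_dataset",
    "calibration_study",
    "power_study",
    "default_sigma_b",
    "default_sigma2_e",
    "default_prevalence",
]


# --------------------------------------------------------------------------
# parameter defaults
# --------------------------------------------------------------------------

def default_sigma_b(q: int, rho: float) -> np.ndarray:
    """Polygenic covariance used in the replicate studies."""
    if q == 2:
        r = rho * np.sqrt(2.0)
        return np.array([[1.0, r], [r, 2.0]])
    if q == 5:
        s = np.sqrt(2.0) * rho
        return np.array(
            [
                [1.0, rho, s, s, s],
                [rho, 1.0, s, s, s],
                [s, s, 2.0, 2 * rho, 2 * rho],
                [s, s, 2 * rho, 2.0, 2 * rho],
                [s, s, 2 * rho, 2 * rho, 2.0],
            ]
        )
    raise DataError(f"no default polygenic covariance for Q={q}; supply sigma_b")


def default_sigma2_e(q: int) -> np.ndarray:
    if q in (2, 5):
        return np.arange(1.0, q + 1.0)
    raise DataError(f"no default residual variances for Q={q}; supply sigma2_e")


def default_prevalence(q: int) -> np.ndarray:
    if q == 2:
        return np.array([0.1, 0.2])
    if q == 5:
        return np.array([0.1, 0.1, 0.2, 0.2, 0.3])
    raise DataError(f"no default prevalence for Q={q}; supply prevalence")


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset (see module docstring)."""

    n_families: int = 100
    q: int = 2
    dprime: float = 0.0
    rho: float = 0.2
    maf_low: float = 0.1
    maf_high: float = 0.4
    p_a: float | None = None          # fixed test-locus MAFs; else U(low, high)
    p_b: float | None = None
    beta: np.ndarray | None = None    # M x Q effects; None = null
    alpha: np.ndarray | None = None   # phenotype means; None = zeros
    sigma_b: np.ndarray | None = None
    sigma2_e: np.ndarray | None = None
    dichotomous: bool = False
    prevalence: np.ndarray | None = None
    fst: float | None = None
    mean_shift: float = 0.2
    family_level_ancestry: bool = False
    n_null_markers: int = 10_000

    def resolved(self) -> "SimulationConfig":
        cfg = replace(self)
        if cfg.sigma_b is None:
            cfg.sigma_b = default_sigma_b(cfg.q, cfg.rho)
        cfg.sigma_b = np.asarray(cfg.sigma_b, dtype=float)
        if cfg.sigma2_e is None:
            cfg.sigma2_e = default_sigma2_e(cfg.q)
        cfg.sigma2_e = np.asarray(cfg.sigma2_e, dtype=float)
        if cfg.alpha is None:
            cfg.alpha = np.zeros(cfg.q)
        cfg.alpha = np.asarray(cfg.alpha, dtype=float)
        if cfg.beta is None:
            cfg.beta = np.zeros((2, cfg.q))
        cfg.beta = np.atleast_2d(np.asarray(cfg.beta, dtype=float))
        if cfg.dichotomous and cfg.prevalence is None:
            cfg.prevalence = default_prevalence(cfg.q)
        if cfg.prevalence is not None:
            cfg.prevalence = np.asarray(cfg.prevalence, dtype=float)
        if cfg.fst is not None and not (0.0 < cfg.fst < 1.0):
            raise DataError("Fst must lie strictly in (0, 1)")
        return cfg


@dataclass
class SimulatedDataset:
    """One simulated replicate with its latent components kept for checks."""

    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeMatrix
    covariates: CovariateMatrix
    null_panel: np.ndarray | None = None
    liabilities: np.ndarray | None = field(default=None, repr=False)
    polygenic: np.ndarray | None = field(default=None, repr=False)
    errors: np.ndarray | None = field(default=None, repr=False)
    ancestry: np.ndarray | None = None

    def write(self, prefix: str) -> None:
        """Write PLINK .bed/.bim/.fam plus phenotype and covariate TSVs."""
        from mfqls import cli_io

        cli_io.write_plink(prefix, self.pedigree, self.genotypes)
        ids = self.pedigree.ids
        pheno = pd.DataFrame(
            self.phenotypes.values, columns=self.phenotypes.names
        )
        pheno.insert(0, "IID", [i for _, i in ids])
        pheno.insert(0, "FID", [f for f, _ in ids])
        pheno.to_csv(f"{prefix}.pheno.tsv", sep="\t", index=False, na_rep="NA")
        cov = pd.DataFrame(
            self.covariates.values[:, 1:],
            columns=[f"C{j + 1}" for j in range(self.covariates.c - 1)],
        )
        cov.insert(0, "IID", [i for _, i in ids])
        cov.insert(0, "FID", [f for f, _ in ids])
        cov.to_csv(f"{prefix}.covar.tsv", sep="\t", index=False, na_rep="NA")


# --------------------------------------------------------------------------
# elementary generators
# --------------------------------------------------------------------------

def haplotype_freqs(p_a: float, p_b: float, dprime: float) -> np.ndarray:
    """Haplotype frequencies (AB, Ab, aB, ab) from marginal MAFs and D'.

    The raw disequilibrium is ``d = D' * min(p_a (1 - p_b), (1 - p_a) p_b)``
    (Lewontin scaling for d >= 0).
    """
    if not (0.0 < p_a < 1.0 and 0.0 < p_b < 1.0):
        raise DataError("allele frequencies must lie in (0, 1)")
    if not (0.0 <= dprime <= 1.0):
        raise DataError("D' must lie in [0, 1]")
    d = dprime * min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    freqs = np.array(
        [
            p_a * p_b + d,
            p_a * (1.0 - p_b) - d,
            (1.0 - p_a) * p_b - d,
            (1.0 - p_a) * (1.0 - p_b) + d,
        ]
    )
    if (freqs < -1e-12).any():
        raise DataError("haplotype frequencies fell outside [0, 1]")
    return np.clip(freqs, 0.0, 1.0)


# haplotype index -> (carries A, carries B)
_HAP_A = np.array([1, 1, 0, 0])
_HAP_B = np.array([1, 0, 1, 0])


def _topo_template(template: Pedigree) -> tuple[list[int], np.ndarray]:
    order = template._topological_order()
    parents = template.parent_indices()
    return order, parents


def simulate_family_genotypes(
    template: Pedigree,
    haps: np.ndarray,
    rng: np.random.Generator,
    n_families: int = 1,
    founder_haps: np.ndarray | None = None,
) -> np.ndarray:
    """Two-locus genotypes for ``n_families`` copies of ``template``.

    Founders receive two haplotypes i.i.d. from ``haps`` (4 categories, HWE
    at the haplotype level) unless ``founder_haps`` — shape
    (n_families, k, 2, 4) of per-founder category laws — is given; children
    inherit one uniformly chosen haplotype from each parent with no
    recombination. Returns allele counts of shape (n_families, k, 2).
    """
    order, parents = _topo_template(template)
    k = template.n
    hap = np.zeros((n_families, k, 2), dtype=np.int64)
    fam_idx = np.arange(n_families)
    for member in order:
        fa, mo = parents[member]
        if fa < 0:
            if founder_haps is None:
                hap[:, member, :] = rng.choice(4, size=(n_families, 2), p=haps)
            else:
                cum = np.cumsum(founder_haps[:, member, :, :], axis=-1)
                u = rng.random((n_families, 2, 1))
                hap[:, member, :] = (u > cum[..., :-1]).sum(axis=-1)
        else:
            pick_f = rng.integers(2, size=n_families)
            pick_m = rng.integers(2, size=n_families)
            hap[:, member, 0] = hap[fam_idx, fa, pick_f]
            hap[:, member, 1] = hap[fam_idx, mo, pick_m]
    counts = np.stack(
        [_HAP_A[hap].sum(axis=2), _HAP_B[hap].sum(axis=2)], axis=2
    )
    return counts


def simulate_polygenic(
    template: Pedigree,
    sigma_b: np.ndarray,
    rng: np.random.Generator,
    n_families: int = 1,
) -> np.ndarray:
    """Additive polygenic effects, shape (n_families, k, Q).

    Founders are i.i.d. MVN(0, Sigma_B); each offspring is the average of
    its parents' effects plus an independent MVN(0, 0.5 Sigma_B) term.
    """
    sigma_b = np.atleast_2d(np.asarray(sigma_b, dtype=float))
    q = sigma_b.shape[0]
    order, parents = _topo_template(template)
    k = template.n
    if np.allclose(sigma_b, 0.0):
        return np.zeros((n_families, k, q))
    # PSD square root (Sigma_B may be singular)
    evals, evecs = np.linalg.eigh(sigma_b)
    if evals[0] < -1e-10:
        raise DataError("Sigma_B must be positive semidefinite")
    L = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    noise = rng.standard_normal((n_families, k, q)) @ L.T
    B = np.zeros((n_families, k, q))
    for member in order:
        fa, mo = parents[member]
        if fa < 0:
            B[:, member] = noise[:, member]
        else:
            B[:, member] = 0.5 * (B[:, fa] + B[:, mo]) \
                + np.sqrt(0.5) * noise[:, member]
    return B


def assemble_quantitative(
    genotypes: np.ndarray,
    beta: np.ndarray,
    alpha: np.ndarray,
    polygenic: np.ndarray,
    sigma2_e: np.ndarray,
    rng: np.random.Generator,
    mean_offset: np.ndarray | None = None,
) -> np.ndarray:
    """Phenotypes y = alpha + X beta + b + e, shape (N, Q).

    ``genotypes`` (N, M), ``polygenic`` (N, Q); errors are independent
    N(0, sigma2_e[q]). ``mean_offset`` (N,) adds a per-individual shift to
    every phenotype (population-structure mean difference).
    """
    X = np.asarray(genotypes, dtype=float)
    b = np.asarray(polygenic, dtype=float)
    n, q = b.shape
    e = rng.standard_normal((n, q)) * np.sqrt(np.asarray(sigma2_e, dtype=float))
    y = alpha + X @ beta + b + e
    if mean_offset is not None:
        y = y + np.asarray(mean_offset, dtype=float)[:, None]
    return y


def liability_thresholds(
    prevalence: np.ndarray, alpha: np.ndarray, sigma_b: np.ndarray,
    sigma2_e: np.ndarray
) -> np.ndarray:
    """Upper-K quantiles of the theoretical null marginal liability law
    N(alpha_q, Sigma_B[qq] + sigma2_E[q])."""
    sd = np.sqrt(np.diag(sigma_b) + sigma2_e)
    return norm.isf(np.asarray(prevalence, dtype=float), loc=alpha, scale=sd)


def dichotomize_liability(
    liabilities: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Affection status: 1 where liability exceeds the phenotype threshold."""
    return (liabilities > thresholds).astype(float)


def balding_nichols_freqs(
    p_ancestral: float, fst: float, rng: np.random.Generator, size: int = 2
) -> np.ndarray:
    """Subpopulation allele frequencies: i.i.d. draws from
    Beta(p (1-F)/F, (1-p) (1-F)/F)."""
    if not (0.0 < fst < 1.0):
        raise DataError("Fst must lie strictly in (0, 1)")
    if not (0.0 < p_ancestral < 1.0):
        raise DataError("ancestral frequency must lie in (0, 1)")
    scale = (1.0 - fst) / fst
    return rng.beta(p_ancestral * scale, (1.0 - p_ancestral) * scale, size=size)


# --------------------------------------------------------------------------
# whole-dataset generators
# --------------------------------------------------------------------------

def _draw_test_mafs(cfg: SimulationConfig, rng) -> tuple[float, float]:
    p_a = cfg.p_a if cfg.p_a is not None else rng.uniform(cfg.maf_low, cfg.maf_high)
    p_b = cfg.p_b if cfg.p_b is not None else rng.uniform(cfg.maf_low, cfg.maf_high)
    return float(p_a), float(p_b)


def _marker_frame(m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "snp": [f"snp{j + 1}" for j in range(m)],
            "cm": [0.0] * m,
            "pos": [1000 * (j + 1) for j in range(m)],
            "a1": ["A"] * m,
            "a2": ["G"] * m,
        }
    )


def _finish_dataset(
    cfg, template, n_fam, counts, rng, mean_offset=None, null_panel=None,
    ancestry=None, pedigree=None,
) -> SimulatedDataset:
    k = template.n
    n = n_fam * k
    X = counts.reshape(n, 2).astype(float)
    B = simulate_polygenic(template, cfg.sigma_b, rng, n_fam).reshape(n, cfg.q)
    e = rng.standard_normal((n, cfg.q)) * np.sqrt(cfg.sigma2_e)
    liab = cfg.alpha + X @ cfg.beta + B + e
    if mean_offset is not None:
        liab = liab + mean_offset[:, None]
    if cfg.dichotomous:
        thr = liability_thresholds(
            cfg.prevalence, cfg.alpha, cfg.sigma_b, cfg.sigma2_e
        )
        values = dichotomize_liability(liab, thr)
        kinds = ["dichotomous"] * cfg.q
    else:
        values = liab
        kinds = ["quantitative"] * cfg.q
    if pedigree is None:
        pedigree = _tile(template, n_fam)
    phen = PhenotypeMatrix(values, kinds=kinds, prevalence=cfg.prevalence)
    return SimulatedDataset(
        pedigree=pedigree,
        genotypes=GenotypeMatrix(X, markers=_marker_frame(2)),
        phenotypes=phen,
        covariates=CovariateMatrix.intercept_only(n),
        null_panel=null_panel,
        liabilities=liab,
        polygenic=B,
        errors=e,
        ancestry=ancestry,
    )


def _tile(template: Pedigree, n_fam: int) -> Pedigree:
    rows = []
    for f in range(1, n_fam + 1):
        t = template.table.copy()
        t["fid"] = f"F{f}"
        rows.append(t)
    return Pedigree(pd.concat(rows, ignore_index=True))


def simulate_dataset(
    cfg: SimulationConfig, rng: np.random.Generator,
    template: Pedigree | None = None,
    pedigree: Pedigree | None = None,
) -> SimulatedDataset:
    """Dataset without population substructure.

    ``pedigree``, if given, must be the ``n_families``-fold tiling of
    ``template``; passing it avoids rebuilding it per replicate.
    """
    cfg = cfg.resolved()
    template = template or canonical_pedigree(1)
    p_a, p_b = _draw_test_mafs(cfg, rng)
    haps = haplotype_freqs(p_a, p_b, cfg.dprime)
    counts = simulate_family_genotypes(template, haps, rng, cfg.n_families)
    return _finish_dataset(cfg, template, cfg.n_families, counts, rng,
                           pedigree=pedigree)


def _structured_founder_haps(
    cfg, template, labels, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Per-founder two-locus haplotype laws under Balding-Nichols."""
    n_fam, k = labels.shape
    qa = rng.uniform(cfg.maf_low, cfg.maf_high)
    qb = rng.uniform(cfg.maf_low, cfg.maf_high)
    pa_pops = balding_nichols_freqs(qa, cfg.fst, rng)
    pb_pops = balding_nichols_freqs(qb, cfg.fst, rng)
    pop_haps = np.stack(
        [haplotype_freqs(pa_pops[s], pb_pops[s], cfg.dprime) for s in (0, 1)]
    )  # (2, 4)
    laws = pop_haps[labels]  # (n_fam, k, 4)
    founder_laws = np.repeat(laws[:, :, None, :], 2, axis=2)
    return founder_laws, np.stack([pa_pops, pb_pops])


def _null_panel(
    cfg, template, labels, ancestry_child_order, rng
) -> np.ndarray:
    """Dense panel of unlinked null markers, shape (N, n_markers).

    Ancestral frequencies are U(maf_low, maf_high); markers are kept only if
    both subpopulation MAFs exceed 0.1 (common-variant filter), redrawing
    until the panel is full. Founder genotypes are binomial in their
    subpopulation; children receive one allele from each parent with
    probability count/2 (unlinked loci).
    """
    n_fam, k = labels.shape
    target = cfg.n_null_markers
    pa = np.empty((2, 0))
    while pa.shape[1] < target:
        anc = rng.uniform(cfg.maf_low, cfg.maf_high, size=2 * target)
        scale = (1.0 - cfg.fst) / cfg.fst
        pops = rng.beta(
            anc * scale, (1.0 - anc) * scale, size=(2, len(anc))
        )
        maf = np.minimum(pops, 1.0 - pops)
        keep = (maf > 0.1).all(axis=0)
        pa = np.concatenate([pa, pops[:, keep]], axis=1)
    pa = pa[:, :target]  # (2, M) subpop frequencies
    order, parents = _topo_template(template)
    geno = np.zeros((n_fam, k, target), dtype=np.int8)
    for member in order:
        fa, mo = parents[member]
        if fa < 0:
            p_member = pa[labels[:, member]]  # (n_fam, M)
            geno[:, member] = rng.binomial(2, p_member).astype(np.int8)
        else:
            tf = rng.random((n_fam, target)) < geno[:, fa] / 2.0
            tm = rng.random((n_fam, target)) < geno[:, mo] / 2.0
            geno[:, member] = tf.astype(np.int8) + tm.astype(np.int8)
    return geno.reshape(n_fam * k, target)


def simulate_structured_dataset(
    cfg: SimulationConfig, rng: np.random.Generator,
    template: Pedigree | None = None,
    with_null_panel: bool = True,
    pedigree: Pedigree | None = None,
) -> SimulatedDataset:
    """Dataset with two Balding-Nichols subpopulations.

    Founders join subpopulation 2 with probability 0.5 (per family when
    ``family_level_ancestry`` is set); each non-founder's ancestry proportion
    is the mean of its parents', and the phenotype mean shift is
    ``mean_shift * ancestry``.
    """
    cfg = cfg.resolved()
    if cfg.fst is None:
        raise DataError("structured simulation requires Fst")
    template = template or canonical_pedigree(1)
    n_fam, k = cfg.n_families, template.n
    order, parents = _topo_template(template)
    founder = template.founder_mask
    labels = np.zeros((n_fam, k), dtype=np.int64)
    if cfg.family_level_ancestry:
        fam_label = rng.integers(2, size=n_fam)
        labels[:, founder] = fam_label[:, None]
    else:
        labels[:, founder] = rng.integers(2, size=(n_fam, int(founder.sum())))
    ancestry = np.zeros((n_fam, k))
    for member in order:
        fa, mo = parents[member]
        if fa < 0:
            ancestry[:, member] = labels[:, member]
        else:
            ancestry[:, member] = 0.5 * (ancestry[:, fa] + ancestry[:, mo])
    founder_laws, _ = _structured_founder_haps(cfg, template, labels, rng)
    counts = simulate_family_genotypes(
        template, None, rng, n_fam, founder_haps=founder_laws
    )
    panel = None
    if with_null_panel:
        panel = _null_panel(cfg, template, labels, ancestry, rng)
    mean_offset = cfg.mean_shift * ancestry.reshape(n_fam * k)
    return _finish_dataset(
        cfg, template, n_fam, counts, rng,
        mean_offset=mean_offset, null_panel=panel,
        ancestry=ancestry.reshape(n_fam * k), pedigree=pedigree,
    )


# --------------------------------------------------------------------------
# replicate studies
# --------------------------------------------------------------------------

@dataclass
class StudyResult:
    """P-values and empirical rejection rates of a replicate study."""

    p_values: pd.DataFrame  # one column per method
    alphas: tuple[float, ...]

    @property
    def n_replicates(self) -> int:
        return len(self.p_values)

    def rejection_rates(self) -> pd.DataFrame:
        rows = {}
        for method in self.p_values.columns:
            p = self.p_values[method].to_numpy()
            rows[method] = {a: float(np.mean(p < a)) for a in self.alphas}
        return pd.DataFrame(rows).T

    def summary_frame(self) -> pd.DataFrame:
        rates = self.rejection_rates()
        rates.index.name = "METHOD"
        return rates.reset_index().melt(
            id_vars="METHOD", var_name="ALPHA", value_name="REJECTION_RATE"
        )


def _study(
    cfg: SimulationConfig,
    n_replicates: int,
    seed: int,
    methods: tuple[str, ...],
    alphas: tuple[float, ...],
    use_grm: bool,
) -> StudyResult:
    cfg = cfg.resolved()
    rng = np.random.default_rng(seed)
    template = canonical_pedigree(1)
    full_ped = canonical_pedigree(cfg.n_families)
    block = kinship_from_pedigree(template).values
    block_ops = BlockPhiOps(block, cfg.n_families)
    structured = cfg.fst is not None
    records = {m: np.empty(n_replicates) for m in methods}
    for r in range(n_replicates):
        if structured:
            ds = simulate_structured_dataset(
                cfg, rng, template=template, pedigree=full_ped
            )
        else:
            ds = simulate_dataset(cfg, rng, template=template, pedigree=full_ped)
        if use_grm:
            if ds.null_panel is None:
                raise DataError("GRM substitution requires a null panel")
            grm = grm_from_genotypes(ds.null_panel, ids=ds.pedigree.ids)
            ops = as_phi_ops(grm.ensure_positive_definite(ridge=1e-6))
        else:
            ops = block_ops
        fits = None
        if any(m in ("MFQLS", "MMASTOR") for m in methods):
            from mfqls.null_model import fit_null_models

            fits = fit_null_models(ds.phenotypes, ds.covariates, ops)
        for method in methods:
            res = variant_test(
                method,
                ds.phenotypes,
                ds.covariates,
                ops,
                ds.genotypes,
                fits=fits,
                prevalence=cfg.prevalence,
            )
            records[method][r] = res.p_value
    pvals = pd.DataFrame(records)
    return StudyResult(pvals, tuple(alphas))


def calibration_study(
    cfg: SimulationConfig,
    n_replicates: int,
    seed: int = 0,
    methods: tuple[str, ...] = ("MFQLS",),
    alphas: tuple[float, ...] = (0.005, 0.01, 0.05),
    use_grm: bool = False,
) -> StudyResult:
    """Null replicate study: empirical type-I error at the given levels."""
    cfg = cfg.resolved()
    if not np.allclose(cfg.beta, 0.0):
        raise DataError("calibration study requires beta = 0")
    return _study(cfg, n_replicates, seed, methods, alphas, use_grm)


def power_study(
    cfg: SimulationConfig,
    n_replicates: int,
    seed: int = 0,
    methods: tuple[str, ...] = ("MFQLS",),
    alphas: tuple[float, ...] = (0.005,),
    use_grm: bool = False,
) -> StudyResult:
    """Alternative-hypothesis replicate study (requires nonzero beta)."""
    cfg = cfg.resolved()
    if np.allclose(cfg.beta, 0.0):
        raise DataError("power study requires a nonzero beta")
    return _study(cfg, n_replicates, seed, methods, alphas, use_grm)
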