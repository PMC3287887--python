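"""GAW17-like study generator with known truth.

Emulates the structure of the GAW17 mini-exome: a fixed genotype matrix with
a strong rare-variant skew (~13% of SNPs common), per-gene SNP blocks,
Age/Sex/Smoke covariates, and phenotype replicates that redraw only the
environmental noise over a fixed genetic + covariate signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import special

from ebcoalesce.pipeline import GenotypeStudy, Truth

__all__ = [
    "CausalGeneSpec",
    "SimConfig",
    "gaw17_mini",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_study",
]

_N_CHROM = 22
_SNP_SPACING = 1_000
_GENE_SPACING = 50_000


@dataclass(frozen=True)
class CausalGeneSpec:
    """One causal gene: how many of its SNPs are causal and the effect-size
    parameter fed to the effect rule.  ``gene_id=None`` lets the simulator
    assign the largest still-unused gene that can host ``n_causal`` SNPs."""

    n_causal: int
    effect: float
    gene_id: str | None = None


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_individuals: int = 300
    n_genes: int = 150
    snps_per_gene_mean: float = 7.6  # l_k = 1 + Poisson(mean - 1)
    snps_per_gene_max: int = 40
    fraction_common: float = 0.128
    rare_maf: tuple[float, float] = (0.005, 0.05)
    common_maf: tuple[float, float] = (0.05, 0.4)
    ld_rho: float = 0.0
    n_replicates: int = 2
    causal: tuple[CausalGeneSpec, ...] = ()
    effect_rule: str = "constant"  # "constant" | "log_maf"
    age_beta: float = 0.0
    sex_beta: float = 0.0
    smoke_beta: float = 0.0
    h2: float = 0.0

    def validate(self) -> None:
        checks = {
            "n_individuals": self.n_individuals >= 3,
            "n_genes": self.n_genes >= 1,
            "snps_per_gene_mean": self.snps_per_gene_mean >= 1.0,
            "snps_per_gene_max": self.snps_per_gene_max >= 1,
            "fraction_common": 0.0 <= self.fraction_common <= 1.0,
            "rare_maf": 0.0 < self.rare_maf[0] <= self.rare_maf[1] <= 0.5,
            "common_maf": 0.0 < self.common_maf[0] <= self.common_maf[1] <= 0.5,
            "ld_rho": 0.0 <= self.ld_rho < 1.0,
            "n_replicates": self.n_replicates >= 2,
            "h2": 0.0 <= self.h2 < 1.0,
            "effect_rule": self.effect_rule in ("constant", "log_maf"),
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid SimConfig field(s): {bad}")
        for spec in self.causal:
            if spec.n_causal < 1:
                raise ValueError(f"causal spec {spec} must have n_causal >= 1")


def gaw17_mini(seed: int = 0) -> SimConfig:
    """Bundled miniature preset: 300 individuals, 150 genes (~1,150 SNPs),
    three causal genes with 11/10/2 causal SNPs of descending effect, Age and
    Smoke effects, h2 ~ 0.4, 20 replicates."""
    return SimConfig(
        seed=seed,
        n_individuals=300,
        n_genes=150,
        snps_per_gene_mean=7.6,
        fraction_common=0.128,
        ld_rho=0.15,
        n_replicates=20,
        causal=(
            CausalGeneSpec(n_causal=11, effect=1.0),
            CausalGeneSpec(n_causal=10, effect=0.7),
            CausalGeneSpec(n_causal=2, effect=0.8),
        ),
        age_beta=0.06,
        sex_beta=0.0,
        smoke_beta=1.4,
        h2=0.4,
    )


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stream,)))


def simulate_genotypes(cfg: SimConfig) -> GenotypeStudy:
    """Draw the fixed genotype matrix, SNP/gene map and covariates.

    Per gene, the block size is ``1 + Poisson(mean - 1)`` capped at the
    configured maximum; each SNP's population MAF comes from a rare/common
    two-part mixture; genotypes are two Bernoulli(MAF) allele draws,
    optionally correlated within a gene through a shared latent Gaussian
    (``ld_rho``) thresholded at the MAF quantile.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_individuals

    sizes = 1 + rng.poisson(cfg.snps_per_gene_mean - 1.0, size=cfg.n_genes)
    sizes = np.minimum(sizes, cfg.snps_per_gene_max)

    blocks, maf_true_all = [], []
    for l_k in sizes:
        common = rng.random(l_k) < cfg.fraction_common
        maf = np.where(
            common,
            rng.uniform(cfg.common_maf[0], cfg.common_maf[1], l_k),
            rng.uniform(cfg.rare_maf[0], cfg.rare_maf[1], l_k),
        )
        maf_true_all.append(maf)
        thresh = special.ndtri(maf)
        counts = np.zeros((n, l_k))
        for _ in range(2):  # two haplotype draws
            shared = rng.standard_normal(n)[:, None]
            eps = rng.standard_normal((n, l_k))
            latent = np.sqrt(cfg.ld_rho) * shared + np.sqrt(1.0 - cfg.ld_rho) * eps
            counts += (latent < thresh).astype(float)
        blocks.append(counts)

    genotypes = np.concatenate(blocks, axis=1)
    maf_true = np.concatenate(maf_true_all)

    # SNP metadata: genes laid out contiguously over 22 chromosome chunks
    genes_per_chrom = int(np.ceil(cfg.n_genes / _N_CHROM))
    rows = []
    snp_idx = 0
    pos_by_chrom: dict[str, int] = {}
    for g, l_k in enumerate(sizes):
        gid = f"GENE{g:04d}"
        chrom = str(1 + g // genes_per_chrom)
        pos = pos_by_chrom.get(chrom, 0) + _GENE_SPACING
        for _ in range(l_k):
            pos += _SNP_SPACING
            rows.append(
                {
                    "snp_id": f"SNP{snp_idx:06d}",
                    "chrom": chrom,
                    "pos": pos,
                    "gene_id": gid,
                    "maf_true": maf_true[snp_idx],
                }
            )
            snp_idx += 1
        pos_by_chrom[chrom] = pos
    snp_table = pd.DataFrame(rows)
    p_hat = genotypes.mean(axis=0) / 2.0
    snp_table["maf"] = np.minimum(p_hat, 1.0 - p_hat)

    covariates = pd.DataFrame(
        {
            "Age": np.clip(np.round(rng.normal(49.0, 12.0, n)), 18, 90),
            "Sex": rng.binomial(1, 0.5, n).astype(float),
            "Smoke": rng.binomial(1, 0.3, n).astype(float),
        }
    )
    return GenotypeStudy(
        genotypes=genotypes,
        snp_table=snp_table,
        covariates=covariates,
        phenotypes=np.empty((n, 0)),
        truth=None,
    )


def _assign_causal_genes(study: GenotypeStudy, cfg: SimConfig) -> list[tuple[CausalGeneSpec, str]]:
    sizes = {g: len(study.gene_columns(g)) for g in study.gene_ids()}
    by_size = sorted(sizes, key=lambda g: (-sizes[g], g))
    used: set[str] = set()
    assignment = []
    for spec in cfg.causal:
        if spec.gene_id is not None:
            gid = spec.gene_id
            if gid not in sizes:
                raise ValueError(f"causal spec references unknown gene {gid!r}")
            if sizes[gid] < spec.n_causal:
                raise ValueError(
                    f"gene {gid} has {sizes[gid]} SNPs, fewer than requested {spec.n_causal}"
                )
            if gid in used:
                raise ValueError(f"gene {gid} assigned to two causal specs")
        else:
            gid = next(
                (g for g in by_size if g not in used and sizes[g] >= spec.n_causal), None
            )
            if gid is None:
                raise ValueError(f"no unused gene with >= {spec.n_causal} SNPs available")
        used.add(gid)
        assignment.append((spec, gid))
    return assignment


def simulate_phenotypes(study: GenotypeStudy, cfg: SimConfig) -> tuple[np.ndarray, Truth]:
    """Draw the replicate phenotype matrix and the matching truth tables.

    The genetic value and covariate contribution are fixed across
    replicates; each replicate redraws only the residual noise, whose
    variance is set so that ``Var(genetic) / Var(total)`` equals ``h2`` in
    the plug-in sense.  With ``h2 = 0`` the genetic part is dropped entirely
    and unit residual noise is used.
    """
    cfg.validate()
    if study.n_individuals < 1 or study.n_snps < 1:
        raise ValueError("study has no genotypes")
    rng = _rng(cfg, 1)
    n = study.n_individuals

    assignment = _assign_causal_genes(study, cfg)
    snp_effects: dict[str, float] = {}
    causal_genes: set[str] = set()
    g_value = np.zeros(n)
    for spec, gid in assignment:
        causal_genes.add(gid)
        cols = study.gene_columns(gid)
        chosen = rng.choice(len(cols), size=spec.n_causal, replace=False)
        for c in sorted(chosen):
            j = cols[c]
            sid = study.snp_table["snp_id"].iloc[j]
            maf = float(study.snp_table["maf_true"].iloc[j]) if "maf_true" in study.snp_table else float(
                study.snp_table["maf"].iloc[j]
            )
            if cfg.effect_rule == "constant":
                beta = spec.effect
            else:  # heavier effects for rarer variants
                beta = spec.effect * abs(np.log10(max(maf, 1e-6)))
            snp_effects[sid] = beta
            g_value += beta * study.genotypes[:, j]

    cov = study.covariates
    c_value = (
        cfg.age_beta * cov["Age"].to_numpy()
        + cfg.sex_beta * cov["Sex"].to_numpy()
        + cfg.smoke_beta * cov["Smoke"].to_numpy()
    )
    covariate_effects = {
        name: b
        for name, b in (("Age", cfg.age_beta), ("Sex", cfg.sex_beta), ("Smoke", cfg.smoke_beta))
        if b != 0.0
    }

    var_g = float(np.var(g_value))
    var_c = float(np.var(c_value))
    if cfg.h2 == 0.0 or not snp_effects:
        if cfg.h2 > 0.0:
            raise ValueError("h2 > 0 requires at least one causal SNP")
        g_value = np.zeros(n)
        sigma_e = 1.0
        causal_genes = set()
        snp_effects = {}
    else:
        if var_g <= 0.0:
            raise ValueError("causal genotypes carry no variance; cannot calibrate h2")
        sigma2_e = var_g * (1.0 - cfg.h2) / cfg.h2 - var_c
        if sigma2_e <= 0.0:
            raise ValueError(
                "covariate variance too large for the requested h2 "
                f"(needs residual variance {sigma2_e:.4g})"
            )
        sigma_e = float(np.sqrt(sigma2_e))

    phenotypes = np.empty((n, cfg.n_replicates))
    for r in range(cfg.n_replicates):
        phenotypes[:, r] = g_value + c_value + rng.normal(0.0, sigma_e, n)

    truth = Truth(
        causal_genes=frozenset(causal_genes),
        causal_snps=frozenset(snp_effects),
        snp_effects=snp_effects,
        covariate_effects=covariate_effects,
    )
    return phenotypes, truth


def simulate_study(cfg: SimConfig) -> GenotypeStudy:
    """Convenience wrapper: genotypes + phenotypes + truth in one call,
    byte-reproducible from ``cfg.seed``."""
    study = simulate_genotypes(cfg)
    phenotypes, truth = simulate_phenotypes(study, cfg)
    study.phenotypes = phenotypes
    study.truth = truth
    return study
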