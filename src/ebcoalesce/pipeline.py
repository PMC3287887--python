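"""End-to-end study driver: train-replicate coalescing, per-replicate
variable selection with covariates, gene-to-SNP back-mapping, and
aggregation into selection-frequency tables and error-rate summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ebcoalesce import ebvs as _ebvs
from ebcoalesce import pocre as _pocre

__all__ = [
    "Truth",
    "GenotypeStudy",
    "PipelineConfig",
    "SelectionResult",
    "ReplicateSummary",
    "run_replicate",
    "run_study",
    "confusion_rates",
    "frequency_table",
    "snp_frequency_table",
]

logger = logging.getLogger(__name__)

_COVARIATE = "covariate"
_GENE = "gene_marker"


@dataclass(frozen=True)
class Truth:
    """Ground truth of a simulated study."""

    causal_genes: frozenset
    causal_snps: frozenset
    snp_effects: dict = field(default_factory=dict)
    covariate_effects: dict = field(default_factory=dict)


@dataclass
class GenotypeStudy:
    """A GAW17-style study: one fixed genotype matrix, SNP metadata with a
    gene map, environmental covariates, and R phenotype replicates over the
    same individuals."""

    genotypes: np.ndarray
    snp_table: pd.DataFrame
    covariates: pd.DataFrame
    phenotypes: np.ndarray
    truth: Truth | None = None
    individual_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.phenotypes.ndim == 1:
            self.phenotypes = self.phenotypes[:, None]
        n, m = self.genotypes.shape
        required = {"snp_id", "chrom", "pos", "gene_id"}
        missing = required - set(self.snp_table.columns)
        if missing:
            raise ValueError(f"snp_table missing columns: {sorted(missing)}")
        if len(self.snp_table) != m:
            raise ValueError("snp_table rows must match genotype columns")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows must match individuals")
        if self.phenotypes.shape[0] not in (0, n):
            raise ValueError("phenotype rows must match individuals")
        if not np.all(np.isin(self.genotypes, (0.0, 1.0, 2.0))):
            raise ValueError("genotype entries must be minor-allele counts 0/1/2")
        if self.individual_ids is None:
            self.individual_ids = tuple(f"ind{i:05d}" for i in range(n))
        gid = self.snp_table["gene_id"].fillna("")
        self._gene_cols = {}
        for j, g in enumerate(gid):
            if g == "":
                continue
            self._gene_cols.setdefault(g, []).append(j)
        n_unmapped = int((gid == "").sum())
        if n_unmapped:
            logger.info("%d SNP(s) not mapped to any gene; excluded from coalescing", n_unmapped)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.phenotypes.shape[1]

    def gene_ids(self) -> list[str]:
        return list(self._gene_cols)

    def gene_columns(self, gene_id: str) -> list[int]:
        return self._gene_cols[gene_id]

    def observed_maf(self) -> np.ndarray:
        p = self.genotypes.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def fraction_common(self, cutoff: float = 0.05) -> float:
        return float(np.mean(self.observed_maf() >= cutoff))


@dataclass
class PipelineConfig:
    training_replicate: int = 0
    allow_same_replicate: bool = False
    min_frequency: int = 5
    convention: str = "discovery"
    n_jobs: int = 1
    ebvs: _ebvs.EbvsConfig = field(default_factory=_ebvs.EbvsConfig)
    pocre: _pocre.PocreConfig = field(default_factory=_pocre.PocreConfig)


@dataclass
class SelectionResult:
    """Per-replicate outcome: selected genes/covariates, back-mapped SNPs,
    OLS effect sizes and fit diagnostics."""

    replicate_id: int
    selected_genes: list[str]
    selected_covariates: list[str]
    selected_snps: list[str]
    coefficients: pd.DataFrame
    diagnostics: dict


@dataclass
class ReplicateSummary:
    """Study-level aggregation across evaluated replicates."""

    results: list[SelectionResult]
    predictor_table: pd.DataFrame
    snp_table: pd.DataFrame
    rates: pd.DataFrame | None
    rate_summary: pd.DataFrame | None
    n_evaluated: int
    min_frequency: int


def _marker_design(study: GenotypeStudy, pocre_models: dict) -> tuple[np.ndarray, list[str], list[str]]:
    cols, names, kinds = [], [], []
    for name in study.covariates.columns:
        cols.append(study.covariates[name].to_numpy(dtype=float))
        names.append(str(name))
        kinds.append(_COVARIATE)
    for gid in study.gene_ids():
        model = pocre_models.get(gid)
        if model is None or model.is_empty:
            continue
        idx = study.gene_columns(gid)
        snp_ids = tuple(study.snp_table["snp_id"].iloc[idx])
        marker = _pocre.gene_marker(model, study.genotypes[:, idx], snp_ids=snp_ids)
        if float(np.linalg.norm(marker)) <= 1e-10:
            logger.info("gene %s: degenerate marker skipped", gid)
            continue
        cols.append(marker)
        names.append(gid)
        kinds.append(_GENE)
    if not cols:
        raise ValueError("no usable predictors: no covariates and no nonempty gene models")
    return np.column_stack(cols), names, kinds


def run_replicate(
    study: GenotypeStudy,
    replicate_id: int,
    pocre_models: dict,
    config: PipelineConfig | None = None,
) -> SelectionResult:
    """Fit the sparse selection model on one evaluation replicate using the
    gene markers coalesced on the training replicate."""
    if config is None:
        config = PipelineConfig()
    if not (0 <= replicate_id < study.n_replicates):
        raise ValueError(f"replicate {replicate_id} out of range")
    if replicate_id == config.training_replicate and not config.allow_same_replicate:
        raise ValueError(
            f"replicate {replicate_id} was used for training; evaluating it would "
            "overfit (pass allow_same_replicate to override)"
        )

    raw, names, kinds = _marker_design(study, pocre_models)
    design = _ebvs.prepare_design(raw, kinds, names)
    y = study.phenotypes[:, replicate_id]
    fit = _ebvs.ebvs_fit(design, y, config.ebvs)

    selected_genes, selected_covariates = [], []
    for j in fit.selected:
        if kinds[j] == _COVARIATE:
            selected_covariates.append(names[j])
        else:
            selected_genes.append(names[j])
    selected_snps = []
    for gid in selected_genes:
        selected_snps.extend(pocre_models[gid].support())

    coef = _ebvs.refit_unpenalized(design, y, fit.selected)
    diagnostics = {
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "w": fit.prior.w,
        "a": fit.prior.a,
        "sigma": fit.sigma,
        "n_predictors": design.p,
    }
    return SelectionResult(
        replicate_id=replicate_id,
        selected_genes=selected_genes,
        selected_covariates=selected_covariates,
        selected_snps=selected_snps,
        coefficients=coef,
        diagnostics=diagnostics,
    )


def confusion_rates(selected, truth, universe_size: int, convention: str = "discovery"):
    """False-positive and false-negative rates for a selected id set.

    ``discovery``: FPR is the false-discovery proportion
    ``|selected - truth| / max(|selected|, 1)`` and FNR is missed causals over
    the whole universe.  ``classical``: FPR over true negatives, FNR over
    causals.
    """
    selected = set(selected)
    truth = set(truth)
    if universe_size < len(truth):
        raise ValueError("universe smaller than the truth set")
    fp = len(selected - truth)
    fn = len(truth - selected)
    if convention == "discovery":
        fpr = fp / max(len(selected), 1)
        fnr = fn / universe_size
    elif convention == "classical":
        negatives = universe_size - len(truth)
        fpr = fp / negatives if negatives else 0.0
        fnr = fn / len(truth) if truth else 0.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(fpr), float(fnr)


def frequency_table(results, min_frequency: int = 5) -> pd.DataFrame:
    """Predictors selected in at least ``min_frequency`` replicates, with the
    mean and SD of their OLS estimates over the replicates where selected.

    SD over a single replicate is reported as 0.  Sorted by frequency
    descending, then predictor name.
    """
    if not results:
        raise ValueError("need at least one replicate result")
    acc: dict[tuple[str, str], list[float]] = {}
    for res in results:
        for row in res.coefficients.itertuples(index=False):
            if row.kind == "intercept":
                continue
            acc.setdefault((row.predictor, row.kind), []).append(float(row.estimate))
    rows = []
    for (pred, kind), vals in acc.items():
        freq = len(vals)
        if freq < min_frequency:
            continue
        arr = np.asarray(vals)
        rows.append(
            {
                "predictor": pred,
                "kind": kind,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if freq > 1 else 0.0,
                "frequency": freq,
            }
        )
    table = pd.DataFrame(rows, columns=["predictor", "kind", "mean", "sd", "frequency"])
    if len(table):
        table = table.sort_values(
            ["frequency", "predictor"], ascending=[False, True]
        ).reset_index(drop=True)
    return table


def snp_frequency_table(results, study: GenotypeStudy, min_frequency: int = 1) -> pd.DataFrame:
    """SNP selection frequencies with chromosome/position for
    frequency-by-position reporting."""
    counts: dict[str, int] = {}
    for res in results:
        for sid in res.selected_snps:
            counts[sid] = counts.get(sid, 0) + 1
    meta = study.snp_table.set_index("snp_id")
    causal = study.truth.causal_snps if study.truth is not None else frozenset()
    rows = []
    for sid, freq in counts.items():
        if freq < min_frequency:
            continue
        rows.append(
            {
                "snp_id": sid,
                "chrom": str(meta.at[sid, "chrom"]),
                "pos": int(meta.at[sid, "pos"]),
                "gene_id": meta.at[sid, "gene_id"],
                "frequency": freq,
                "is_causal": sid in causal,
            }
        )
    table = pd.DataFrame(
        rows, columns=["snp_id", "chrom", "pos", "gene_id", "frequency", "is_causal"]
    )
    if len(table):
        table = table.sort_values(["chrom", "pos"]).reset_index(drop=True)
    return table


def _rate_frames(results, study: GenotypeStudy):
    truth = study.truth
    if truth is None:
        return None, None
    gene_universe = study.gene_ids()
    snp_universe = study.snp_table.loc[study.snp_table["gene_id"].fillna("") != "", "snp_id"]
    rows = []
    for res in results:
        for convention in ("discovery", "classical"):
            g_fpr, g_fnr = confusion_rates(
                res.selected_genes, truth.causal_genes, len(gene_universe), convention
            )
            s_fpr, s_fnr = confusion_rates(
                res.selected_snps, truth.causal_snps, len(snp_universe), convention
            )
            rows.append(
                {
                    "replicate": res.replicate_id,
                    "convention": convention,
                    "gene_fpr": g_fpr,
                    "gene_fnr": g_fnr,
                    "snp_fpr": s_fpr,
                    "snp_fnr": s_fnr,
                }
            )
    rates = pd.DataFrame(rows)
    summary_rows = []
    for convention, sub in rates.groupby("convention", sort=True):
        for level in ("gene", "snp"):
            for kind in ("fpr", "fnr"):
                col = sub[f"{level}_{kind}"]
                summary_rows.append(
                    {
                        "convention": convention,
                        "level": level,
                        "rate": kind,
                        "mean": float(col.mean()),
                        "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
                    }
                )
    return rates, pd.DataFrame(summary_rows)


def run_study(study: GenotypeStudy, config: PipelineConfig | None = None) -> ReplicateSummary:
    """Train gene markers on the configured training replicate, run the
    selection model on every other replicate, and aggregate."""
    if config is None:
        config = PipelineConfig()
    r = study.n_replicates
    if r < 2 and not config.allow_same_replicate:
        raise ValueError("need at least 2 replicates (or allow_same_replicate)")
    if not (0 <= config.training_replicate < r):
        raise ValueError(f"training replicate {config.training_replicate} out of range")

    y_train = study.phenotypes[:, config.training_replicate]
    models = _pocre.coalesce_all(study, y_train - y_train.mean(), config.pocre, config.n_jobs)
    n_nonempty = sum(not m.is_empty for m in models.values())
    logger.info("coalescing kept %d of %d genes with nonempty models", n_nonempty, len(models))

    eval_reps = [i for i in range(r) if i != config.training_replicate]
    if not eval_reps:
        eval_reps = [config.training_replicate]
    results = [run_replicate(study, i, models, config) for i in eval_reps]

    predictor_table = frequency_table(results, config.min_frequency)
    snp_table = snp_frequency_table(results, study)
    rates, rate_summary = _rate_frames(results, study)
    return ReplicateSummary(
        results=results,
        predictor_table=predictor_table,
        snp_table=snp_table,
        rates=rates,
        rate_summary=rate_summary,
        n_evaluated=len(results),
        min_frequency=config.min_frequency,
    )
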