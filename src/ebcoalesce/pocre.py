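"""Penalized orthogonal-components regression per gene block.

For one gene's SNP submatrix, components with sparse unit-norm loadings are
built sequentially: marginal correlations of the working matrix with the
working response are scaled to unit noise (robust MAD scale), thresholded by
the empirical Bayes posterior-median rule, normalized into a loading, and the
fitted component is deflated from both the response and the working matrix.
Because deflation is linear, every component is also a linear map of the
original centered SNP columns, so the whole model collapses into a single
SNP-space coefficient vector that turns the gene into one marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ebcoalesce import eb_threshold as ebt

__all__ = [
    "GeneBlock",
    "PocreComponent",
    "PocreConfig",
    "PocreModel",
    "pocre_fit",
    "gene_marker",
    "coalesce_all",
]

logger = logging.getLogger(__name__)

_CENTER_TOL = 1e-8


@dataclass(frozen=True)
class GeneBlock:
    """One gene's SNPs: identifiers plus the n x l_k minor-allele-count
    submatrix (raw 0/1/2 counts; centered copies are derived on access)."""

    gene_id: str
    snp_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        if counts.ndim != 2:
            raise ValueError(f"gene {self.gene_id}: counts must be 2-D")
        if counts.shape[1] != len(self.snp_ids):
            raise ValueError(f"gene {self.gene_id}: snp_ids/counts mismatch")
        if counts.shape[1] < 1:
            raise ValueError(f"gene {self.gene_id}: needs at least one SNP")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError(f"gene {self.gene_id}: duplicate SNP ids")
        if not np.all(np.isin(counts, (0.0, 1.0, 2.0))):
            raise ValueError(f"gene {self.gene_id}: counts must be 0/1/2")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def centered(self) -> np.ndarray:
        return self.counts - self.counts.mean(axis=0)


@dataclass(frozen=True)
class PocreComponent:
    """A single component: sparse unit-norm loading on the working matrix,
    its score vector, the response regression coefficient, and the loading
    pulled back to original SNP space."""

    loading: np.ndarray
    component_scores: np.ndarray
    regression_coef: float
    span_loading: np.ndarray


@dataclass
class PocreConfig:
    a: float = 0.5  # Laplace scale fixed inside the coalescing step
    max_components: int = 5
    rel_tol: float = 1e-8
    w_method: str = "mml"  # "mml" | "pattern"
    scale_method: str = "norm"  # "norm": per-column exact null scale; "mad": global robust scale
    w_min: float = ebt.W_FLOOR
    w_max: float = ebt.W_CEIL
    strict: bool = False
    adjust_covariates: bool = False  # pre-adjust y for covariates before coalescing


@dataclass(frozen=True)
class PocreModel:
    """Fitted per-gene model; ``snp_coefficients`` is the single SNP-space
    vector combining all components and deflations.

    ``n_components`` is stored separately because serialized models carry the
    coefficient vector and component count but not the component internals.
    """

    gene_id: str
    snp_ids: tuple[str, ...]
    components: tuple[PocreComponent, ...]
    snp_coefficients: np.ndarray
    n_components: int = -1

    def __post_init__(self) -> None:
        if self.n_components < 0:
            object.__setattr__(self, "n_components", len(self.components))

    @property
    def is_empty(self) -> bool:
        return self.n_components == 0

    def support(self) -> list[str]:
        """SNP ids carrying a nonzero coefficient."""
        return [s for s, b in zip(self.snp_ids, self.snp_coefficients) if b != 0.0]


def _mml_weight(z: np.ndarray, a: float, w_min: float, w_max: float) -> float:
    """Marginal maximum likelihood estimate of the mixture weight from the
    vector of unit-scale observations (Johnstone–Silverman style)."""
    logphi = -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)
    logg = ebt.log_laplace_marginal(z, a)

    def nll(w: float) -> float:
        return -float(
            np.sum(np.logaddexp(np.log1p(-w) + logphi, np.log(w) + logg))
        )

    res = optimize.minimize_scalar(
        nll, bounds=(w_min, w_max), method="bounded", options={"xatol": 1e-6}
    )
    candidates = [(nll(w_min), w_min), (nll(w_max), w_max), (res.fun, float(res.x))]
    return min(candidates)[1]


def _pattern_weight(z: np.ndarray, a: float, w_min: float, w_max: float) -> float:
    """One conditional-mode pass: threshold at a neutral weight, then set the
    weight from the surviving pattern."""
    l = z.size
    gamma0 = ebt.posterior_median_array(z, ebt.MixturePrior(w=0.5, a=a))
    k = int(np.count_nonzero(gamma0))
    return float(min(max(k / l, max(1.0 / l, w_min)), w_max))


def pocre_fit(block: GeneBlock, y: np.ndarray, config: PocreConfig | None = None) -> PocreModel:
    """Sequentially extract sparse orthogonal components from one gene block.

    ``y`` must be centered (the intercept is removed by centering both sides).
    Stops when the thresholded loading is all-zero, when the component no
    longer reduces the residual sum of squares by ``rel_tol`` relatively, or
    at ``min(n - 1, l_k, max_components)`` components.
    """
    if config is None:
        config = PocreConfig()
    y = np.asarray(y, dtype=float)
    n, l_k = block.counts.shape
    if y.shape != (n,):
        raise ValueError(f"gene {block.gene_id}: y must have length {n}")
    scale_y = float(np.abs(y).max())
    if abs(float(y.mean())) > _CENTER_TOL * max(1.0, scale_y):
        raise ValueError(f"gene {block.gene_id}: y must be centered")

    e = block.centered()
    a_map = np.eye(l_k)  # current working matrix E = Xc @ a_map
    r = y.copy()
    components: list[PocreComponent] = []
    b_k = np.zeros(l_k)
    max_m = min(n - 1, l_k, config.max_components)

    while len(components) < max_m:
        s = e.T @ r
        if config.scale_method == "norm":
            # exact null scale per column: sd(x_i' r) = ||x_i|| sd(r) under H0
            norms = np.linalg.norm(e, axis=0) * float(np.std(r))
            if not np.any(norms > 0.0):
                break
            z = np.divide(s, norms, out=np.zeros_like(s), where=norms > 0.0)
        elif config.scale_method == "mad":
            mad = float(stats.median_abs_deviation(s, scale="normal"))
            scale = mad if mad > 0.0 else float(np.std(s))
            if scale <= 0.0:
                break
            z = s / scale
        else:
            raise ValueError(f"unknown scale_method {config.scale_method!r}")

        if config.w_method == "mml":
            w = _mml_weight(z, config.a, config.w_min, config.w_max)
        elif config.w_method == "pattern":
            w = _pattern_weight(z, config.a, config.w_min, config.w_max)
        else:
            raise ValueError(f"unknown w_method {config.w_method!r}")
        gamma = ebt.posterior_median_array(z, ebt.MixturePrior(w=w, a=config.a))
        if not np.any(gamma):
            break

        loading = gamma / np.linalg.norm(gamma)
        scores = e @ loading
        zz = float(scores @ scores)
        if zz <= 1e-24:
            break
        coef = float(scores @ r) / zz
        rss = float(r @ r)
        if rss <= 0.0 or (coef * coef * zz) / rss < config.rel_tol:
            break

        span_loading = a_map @ loading
        components.append(
            PocreComponent(
                loading=loading,
                component_scores=scores,
                regression_coef=coef,
                span_loading=span_loading,
            )
        )
        b_k += coef * span_loading
        r = r - coef * scores
        # deflate: E <- E - Z (Z'Z)^-1 Z'E, carried on the linear map
        proj = (scores @ e) / zz  # row vector Z'E / Z'Z
        e = e - np.outer(scores, proj)
        a_map = a_map - np.outer(span_loading, proj)

    return PocreModel(
        gene_id=block.gene_id,
        snp_ids=block.snp_ids,
        components=tuple(components),
        snp_coefficients=b_k,
    )


def gene_marker(model: PocreModel, x_new: np.ndarray, snp_ids=None) -> np.ndarray:
    """Apply a fitted gene model to (possibly new) count data for the same
    SNPs, returning the n-vector gene marker ``centered(X) @ b_k``."""
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim != 2 or x_new.shape[1] != len(model.snp_ids):
        raise ValueError(
            f"gene {model.gene_id}: expected {len(model.snp_ids)} SNP columns, "
            f"got shape {x_new.shape}"
        )
    if snp_ids is not None:
        snp_ids = tuple(snp_ids)
        if snp_ids != model.snp_ids:
            missing = sorted(set(model.snp_ids) - set(snp_ids))
            extra = sorted(set(snp_ids) - set(model.snp_ids))
            raise ValueError(
                f"gene {model.gene_id}: SNP mismatch (missing={missing}, extra={extra})"
            )
    if model.is_empty:
        return np.zeros(x_new.shape[0])
    xc = x_new - x_new.mean(axis=0)
    return xc @ model.snp_coefficients


def coalesce_all(study, y_train: np.ndarray, config: PocreConfig | None = None, n_jobs: int = 1):
    """Fit one POCRE model per gene of a study (order-independent; genes are
    processed independently).

    Returns a dict ``gene_id -> PocreModel`` covering every mapped gene,
    including empty models.  In non-strict mode a per-gene failure is logged
    with the gene id and replaced by an empty model; in strict mode it is
    re-raised with the gene id attached.
    """
    if config is None:
        config = PocreConfig()
    y_train = np.asarray(y_train, dtype=float)

    gene_ids = study.gene_ids()
    blocks = []
    for gid in gene_ids:
        cols = study.gene_columns(gid)
        snp_ids = tuple(study.snp_table["snp_id"].iloc[cols])
        blocks.append(GeneBlock(gene_id=gid, snp_ids=snp_ids, counts=study.genotypes[:, cols]))

    def _fit(block: GeneBlock) -> PocreModel:
        try:
            return pocre_fit(block, y_train, config)
        except Exception as exc:
            if config.strict:
                raise RuntimeError(f"gene {block.gene_id}: {exc}") from exc
            logger.warning("gene %s: coalescing failed (%s); using empty model", block.gene_id, exc)
            return PocreModel(
                gene_id=block.gene_id,
                snp_ids=block.snp_ids,
                components=(),
                snp_coefficients=np.zeros(block.n_snps),
            )

    if n_jobs != 1:
        from joblib import Parallel, delayed

        models = Parallel(n_jobs=n_jobs)(delayed(_fit)(b) for b in blocks)
    else:
        models = [_fit(b) for b in blocks]
    return {m.gene_id: m for m in models}
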