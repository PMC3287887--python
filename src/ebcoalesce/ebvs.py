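"""Empirical Bayes variable selection for large-p, small-n linear models.

The response is centered and each predictor column is centered and scaled to
unit Euclidean norm, so a coordinate-wise partial correlation is on the
unit-noise scale after dividing by the residual scale.  Each sweep applies
the posterior-median thresholding rule to every coordinate, then the mixture
weight, Laplace scale and noise scale are refreshed from their full
conditional modes; sweeps repeat until the coefficients stop moving.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from ebcoalesce import eb_threshold as ebt

__all__ = [
    "DesignMatrix",
    "EbvsConfig",
    "EbvsFit",
    "prepare_design",
    "ebvs_fit",
    "refit_unpenalized",
]

logger = logging.getLogger(__name__)

_SIGMA_FLOOR_FACTOR = 1e-8
_COLLINEARITY_WARN = 0.999


@dataclass(frozen=True)
class DesignMatrix:
    """Standardized design with the applied transforms recorded.

    ``values`` holds the columns actually regressed on; ``centers`` and
    ``scales`` map back to the original predictor scale via
    ``original = values * scales + centers``.
    """

    values: np.ndarray
    column_names: tuple[str, ...]
    column_kind: tuple[str, ...]
    centers: np.ndarray
    scales: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def original(self) -> np.ndarray:
        """Columns on the original (pre-standardization) scale."""
        return self.values * self.scales + self.centers


def prepare_design(
    raw: np.ndarray,
    column_kind=None,
    column_names=None,
    *,
    center: bool = True,
) -> DesignMatrix:
    """Center each column and scale it to unit Euclidean norm.

    Constant columns cannot be standardized and are rejected with an error
    naming the offending column.  ``center=False`` skips centering (used for
    designs that are already standardized, e.g. orthonormal test designs).
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"design must be 2-D, got shape {x.shape}")
    n, p = x.shape
    if n < 3:
        raise ValueError(f"need at least 3 rows, got {n}")
    if p < 1:
        raise ValueError("need at least 1 column")
    if not np.all(np.isfinite(x)):
        raise ValueError("design contains non-finite entries")

    if column_names is None:
        column_names = tuple(f"x{j}" for j in range(p))
    else:
        column_names = tuple(column_names)
    if column_kind is None:
        column_kind = ("gene_marker",) * p
    elif isinstance(column_kind, str):
        column_kind = (column_kind,) * p
    else:
        column_kind = tuple(column_kind)
    if len(column_names) != p or len(column_kind) != p:
        raise ValueError("column_names/column_kind length mismatch with design")

    centers = x.mean(axis=0) if center else np.zeros(p)
    xc = x - centers
    norms = np.linalg.norm(xc, axis=0)
    bad = np.where(norms <= 1e-12 * max(1.0, float(np.abs(x).max())))[0]
    if bad.size:
        raise ValueError(
            f"constant column(s) cannot be standardized: {[column_names[j] for j in bad]}"
        )
    values = xc / norms
    return DesignMatrix(
        values=values,
        column_names=column_names,
        column_kind=column_kind,
        centers=centers,
        scales=norms,
    )


@dataclass
class EbvsConfig:
    """Knobs for :func:`ebvs_fit`; defaults follow the sparse-start
    thresholding literature."""

    tol: float = 1e-6
    max_iter: int = 500
    a_init: float = 0.5
    w_init: float | None = None
    a_min: float = ebt.A_MIN_DEFAULT
    a_max: float = ebt.A_MAX_DEFAULT
    w_alpha: float = 1.0  # Beta hyperprior on w; (1, 1) is flat
    w_beta: float = 1.0
    a_shape: float = 1.0  # Gamma hyperprior on a; (1, 0) is flat
    a_rate: float = 0.0
    update_w: bool = True
    update_a: bool = True
    update_sigma: bool = True
    sigma_init: float | None = None
    unpenalized_kinds: tuple[str, ...] = ()


@dataclass
class EbvsFit:
    """Sparse fit: coefficients on both scales, final prior state, noise
    scale, and a per-sweep trace of ``(w, a, sigma, n_nonzero, max_delta)``."""

    beta: np.ndarray
    beta_std: np.ndarray
    prior: ebt.MixturePrior
    sigma: float
    selected: np.ndarray
    n_iter: int
    converged: bool
    trace: pd.DataFrame
    y_mean: float
    sigma_floored: bool = False

    def selected_names(self, design: DesignMatrix) -> list[str]:
        return [design.column_names[j] for j in self.selected]


def ebvs_fit(design: DesignMatrix, y: np.ndarray, config: EbvsConfig | None = None) -> EbvsFit:
    """Iterative conditional-mode fit of the sparse linear model.

    The loop: center ``y``; start from ``beta = 0``, ``sigma = sd(y)``,
    ``w = min(1/p, 0.5)``, ``a = a_init``; then repeat (cyclic coordinate
    sweep of posterior medians) -> (w mode) -> (a mode) -> (sigma from RSS)
    until the largest coefficient move in a sweep drops below
    ``tol * sd(y)`` or ``max_iter`` is hit.  Deterministic for fixed inputs.
    """
    if config is None:
        config = EbvsConfig()
    if not isinstance(design, DesignMatrix):
        raise TypeError("design must be a DesignMatrix (see prepare_design)")
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != design.n:
        raise ValueError(f"y must be a vector of length {design.n}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite entries")

    x = design.values
    n, p = x.shape
    y_mean = float(y.mean())
    yc = y - y_mean
    sdy = float(yc.std())
    if sdy <= 0.0:
        raise ValueError("response is constant")

    _warn_collinear(x, design.column_names)

    penalized = np.array([k not in config.unpenalized_kinds for k in design.column_kind])
    w_min = max(1.0 / p, ebt.W_FLOOR)
    w_max = ebt.W_CEIL
    w = config.w_init if config.w_init is not None else min(max(1.0 / p, ebt.W_FLOOR), 0.5)
    a = config.a_init
    sigma = config.sigma_init if config.sigma_init is not None else sdy
    sigma_floor = _SIGMA_FLOOR_FACTOR * sdy
    sigma_floored = False

    beta = np.zeros(p)
    r = yc.copy()
    trace_rows = []
    converged = False
    n_iter = 0

    for it in range(1, config.max_iter + 1):
        n_iter = it
        prior = ebt.MixturePrior(w=w, a=a)
        max_delta = 0.0
        for j in range(p):
            xj = x[:, j]
            z = (float(xj @ r) + beta[j]) / sigma
            if penalized[j]:
                b_new = sigma * ebt.posterior_median(z, prior).estimate
            else:
                b_new = sigma * z  # plain OLS coordinate for exempt columns
            delta = b_new - beta[j]
            if delta != 0.0:
                r -= xj * delta
                beta[j] = b_new
                max_delta = max(max_delta, abs(delta))

        pen_beta = beta[penalized]
        if config.update_w and pen_beta.size:
            w = ebt.conditional_mode_w(
                pen_beta,
                alpha=config.w_alpha,
                beta_shape=config.w_beta,
                w_min=w_min,
                w_max=w_max,
            )
        if config.update_a and pen_beta.size:
            a = ebt.conditional_mode_a(
                pen_beta,
                sigma,
                a_current=a,
                shape=config.a_shape,
                rate=config.a_rate,
                a_min=config.a_min,
                a_max=config.a_max,
            )
        rss = float(r @ r)
        if config.update_sigma:
            sigma = float(np.sqrt(rss / n))
            if sigma < sigma_floor:
                sigma = sigma_floor
                sigma_floored = True
                logger.warning("residual scale floored at %.3e", sigma_floor)

        trace_rows.append(
            {
                "iteration": it,
                "w": w,
                "a": a,
                "sigma": sigma,
                "n_nonzero": int(np.count_nonzero(beta)),
                "max_delta": max_delta,
                "rss": rss,
            }
        )
        if max_delta <= config.tol * sdy:
            converged = True
            break

    selected = np.flatnonzero(beta)
    return EbvsFit(
        beta=beta / design.scales,
        beta_std=beta.copy(),
        prior=ebt.MixturePrior(w=w, a=a),
        sigma=sigma,
        selected=selected,
        n_iter=n_iter,
        converged=converged,
        trace=pd.DataFrame(trace_rows),
        y_mean=y_mean,
        sigma_floored=sigma_floored,
    )


def _warn_collinear(x: np.ndarray, names) -> None:
    # pairwise check only on small p; exact duplicates still resolved by sweep order
    p = x.shape[1]
    if p > 400:
        return
    corr = x.T @ x  # columns are unit-norm and centered
    np.fill_diagonal(corr, 0.0)
    ii, jj = np.where(np.abs(np.triu(corr)) > _COLLINEARITY_WARN)
    for i, j in zip(ii, jj):
        warnings.warn(
            f"near-collinear predictors {names[i]!r} and {names[j]!r} "
            f"(|correlation| > {_COLLINEARITY_WARN}); sweep order resolves ties",
            stacklevel=3,
        )


def refit_unpenalized(design: DesignMatrix, y: np.ndarray, selected) -> pd.DataFrame:
    """Ordinary least squares on the selected columns only.

    Coefficients are reported on the original predictor scale (an intercept
    row is included).  Rank-deficient selections are repaired by dropping
    dependent columns with a warning.
    """
    selected = np.asarray(list(selected), dtype=int)
    y = np.asarray(y, dtype=float)
    if selected.size >= design.n:
        raise ValueError(f"cannot refit {selected.size} predictors with {design.n} rows")
    rows = [{"predictor": "(intercept)", "kind": "intercept", "estimate": float(y.mean())}]
    if selected.size == 0:
        return pd.DataFrame(rows)

    orig = design.original()[:, selected]
    names = [design.column_names[j] for j in selected]
    kinds = [design.column_kind[j] for j in selected]

    xmat = np.column_stack([np.ones(design.n), orig])
    q, rmat, piv = linalg.qr(xmat, mode="economic", pivoting=True)
    diag = np.abs(np.diag(rmat))
    rank_tol = diag[0] * max(xmat.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > rank_tol))
    keep_piv = set(piv[:rank])
    dropped = [i - 1 for i in range(xmat.shape[1]) if i not in keep_piv and i > 0]
    if dropped:
        warnings.warn(
            f"dropping linearly dependent selected column(s): {[names[i] for i in dropped]}",
            stacklevel=2,
        )
    keep = [i for i in range(len(names)) if i not in dropped]
    xmat = np.column_stack([np.ones(design.n), orig[:, keep]])
    coef, *_ = np.linalg.lstsq(xmat, y, rcond=None)
    rows[0]["estimate"] = float(coef[0])
    for c, i in zip(coef[1:], keep):
        rows.append({"predictor": names[i], "kind": kinds[i], "estimate": float(c)})
    return pd.DataFrame(rows)
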