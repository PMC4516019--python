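"""Parametric empirical-Bayes batch adjustment (ComBat-style), from first principles.

The model for gene g in sample j of batch i, after normalization and log
transform, is

    Y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig eps_ijg,

with biological covariates X (species, tissue), additive per-batch
per-gene location effects gamma and multiplicative scale effects delta.
The adjustment proceeds in three steps:

1. *standardize* — per gene, least-squares fit of the full model (batch
   indicators constrained to a batch-size-weighted zero sum), pooled
   variance sigma_g^2 (divide by n), and standardized residual-plus-batch
   data Z;
2. *eb_adjust* — per-batch per-gene location/scale estimates shrunk
   toward batch-level priors (normal prior for location, inverse-gamma
   for scale, hyperparameters by method of moments across genes), via the
   coupled fixed-point iteration;
3. de-standardize with the shrunken effects removed:
   Y*_ijg = sigma_g / delta*_ig (Z_ijg - gamma*_ig) + alpha_g + X_j beta_g.

A fully confounded design (a covariate level determined by batch, e.g.
species when every batch is single-species) makes the design matrix
rank-deficient.  The fit *refuses* such designs with a diagnostic naming
the absorbed factor, rather than silently dropping it: when batch and
biology are perfectly collinear no adjustment can separate them.  The
study this pipeline emulates is only *nearly* confounded — one batch
contains both species — which is precisely why the model is estimable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DesignSpec",
    "RankDeficientDesignError",
    "BatchModel",
    "build_design",
    "standardize",
    "eb_adjust",
    "combat",
]


class RankDeficientDesignError(ValueError):
    """The batch + covariate design matrix is not of full column rank."""


@dataclass
class DesignSpec:
    """Batch assignment plus categorical biological covariates.

    ``batch_of`` maps sample id -> batch label; ``covariates`` maps factor
    name -> (sample id -> level).
    """

    batch_of: Mapping[str, object]
    covariates: Mapping[str, Mapping[str, str]] = field(default_factory=dict)


@dataclass
class DesignMatrices:
    samples: list[str]
    batches: list[object]  # batch levels, in first-appearance order
    X_batch: np.ndarray  # n x B indicator matrix
    X_cov: np.ndarray  # n x p dummy matrix (reference levels dropped)
    cov_columns: list[str]
    rank: int

    @property
    def X(self) -> np.ndarray:
        return np.hstack([self.X_batch, self.X_cov])

    @property
    def batch_sizes(self) -> np.ndarray:
        return self.X_batch.sum(axis=0)


def build_design(design: DesignSpec, samples: Sequence[str]) -> DesignMatrices:
    """Build the [batch indicators | covariate dummies] design matrix.

    Batch indicators span all B batches (no intercept); each covariate is
    dummy-coded with its first-appearing level as reference.  Raises
    :class:`RankDeficientDesignError` if the combined matrix is
    rank-deficient, naming the covariate column(s) absorbed by batch.
    """
    samples = list(samples)
    missing = [s for s in samples if s not in design.batch_of]
    if missing:
        raise ValueError(f"samples without batch assignment: {missing}")
    batches: list[object] = []
    for s in samples:
        b = design.batch_of[s]
        if b not in batches:
            batches.append(b)
    X_batch = np.zeros((len(samples), len(batches)))
    for j, s in enumerate(samples):
        X_batch[j, batches.index(design.batch_of[s])] = 1.0
    cov_cols: list[np.ndarray] = []
    cov_names: list[str] = []
    for name, levels_of in design.covariates.items():
        levels: list[str] = []
        for s in samples:
            lev = levels_of[s]
            if lev not in levels:
                levels.append(lev)
        for lev in levels[1:]:  # first level is the reference
            cov_cols.append(
                np.array([1.0 if levels_of[s] == lev else 0.0 for s in samples])
            )
            cov_names.append(f"{name}={lev}")
    X_cov = (
        np.column_stack(cov_cols) if cov_cols else np.zeros((len(samples), 0))
    )
    X = np.hstack([X_batch, X_cov])
    rank = int(np.linalg.matrix_rank(X))
    if rank < X.shape[1]:
        # diagnose which covariate columns lie in the span of the batch block
        absorbed = []
        Qb, _ = np.linalg.qr(X_batch)
        for k, col in enumerate(cov_cols):
            resid = col - Qb @ (Qb.T @ col)
            if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(col)):
                absorbed.append(cov_names[k])
        detail = (
            f"covariate column(s) {absorbed} are fully determined by batch"
            if absorbed
            else "covariate columns are collinear"
        )
        raise RankDeficientDesignError(
            f"design matrix rank {rank} < {X.shape[1]} columns: {detail}. "
            "Batch and biology are completely confounded; no adjustment can "
            "separate them."
        )
    return DesignMatrices(
        samples=samples,
        batches=batches,
        X_batch=X_batch,
        X_cov=X_cov,
        cov_columns=cov_names,
        rank=rank,
    )


@dataclass
class Standardized:
    Z: pd.DataFrame  # genes x samples, standardized
    alpha: pd.Series  # per-gene grand mean
    beta: pd.DataFrame  # genes x covariate columns
    sigma: pd.Series  # per-gene pooled SD (divide-by-n convention)
    design: DesignMatrices
    invariant_genes: list[str]


def standardize(m: ExpressionMatrix, design: DesignMatrices) -> Standardized:
    """Per-gene model fit and standardization.

    The full model [batch | covariates] is fit by least squares; the
    grand mean alpha_g is the batch-size-weighted average of the batch
    coefficients, so batch effects carry a weighted zero-sum constraint.
    sigma_g^2 is the mean squared residual (divide by n).  Genes with
    sigma_g = 0 are flagged and excluded (they pass through the
    correction unchanged).
    """
    if list(m.values.columns) != design.samples:
        raise ValueError("matrix columns do not match design sample order")
    n, p = design.X.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than design columns ({p})")
    Y = m.values.to_numpy(dtype=float)  # genes x samples
    X = design.X
    B = design.X_batch.shape[1]
    # one solve for all genes: coef is p x genes
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    gamma_hat_fit = coef[:B, :]  # batch coefficients
    beta = coef[B:, :]  # covariate coefficients
    w = design.batch_sizes / n
    alpha = w @ gamma_hat_fit  # per-gene grand mean
    stand_mean = alpha[None, :] + design.X_cov @ beta  # samples x genes
    resid = Y.T - X @ coef
    sigma2 = (resid**2).mean(axis=0)  # divide by n
    sigma = np.sqrt(sigma2)
    # a constant row has zero sample variance exactly; the lstsq residual
    # may carry float dust, so test the data, then guard the divisor too
    invariant = (Y.var(axis=1) == 0) | (sigma == 0)
    safe_sigma = np.where(invariant, 1.0, sigma)
    Z = (Y.T - stand_mean) / safe_sigma[None, :]
    genes = list(m.values.index)
    inv_genes = [g for g, flag in zip(genes, invariant) if flag]
    if inv_genes:
        logger.warning("%d invariant genes excluded from EB adjustment", len(inv_genes))
    return Standardized(
        Z=pd.DataFrame(Z.T, index=m.values.index, columns=m.values.columns),
        alpha=pd.Series(alpha, index=m.values.index),
        beta=pd.DataFrame(beta.T, index=m.values.index, columns=design.cov_columns),
        sigma=pd.Series(sigma, index=m.values.index),
        design=design,
        invariant_genes=inv_genes,
    )


@dataclass
class BatchModel:
    batches: list[object]
    gamma_hat: pd.DataFrame  # batches x genes, raw per-batch means of Z
    delta2_hat: pd.DataFrame  # batches x genes, raw per-batch variances
    gamma_star: pd.DataFrame
    delta2_star: pd.DataFrame
    gamma_bar: pd.Series  # per-batch location-prior mean
    t2: pd.Series  # per-batch location-prior variance
    a_prior: pd.Series  # per-batch inverse-gamma shape
    b_prior: pd.Series  # per-batch inverse-gamma scale
    iterations: dict
    residual_trace: dict[object, list[float]] = field(default_factory=dict)


def _moments_inverse_gamma(d2: np.ndarray) -> tuple[float, float]:
    """Shape/scale of an inverse-gamma matched to empirical mean/variance."""
    m = d2.mean()
    s2 = d2.var(ddof=1)
    if s2 <= 0:
        # degenerate spread across genes: prior collapses onto the mean
        a = 1e12
        return a, float(m * (a - 1))
    a = (2 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return float(a), float(b)


def eb_adjust(
    Z: pd.DataFrame,
    batch_of: Mapping[str, object],
    parametric: bool = True,
    tol: float = 1e-4,
    max_iter: int = 500,
    prior_override: Mapping[object, tuple[float, float]] | None = None,
) -> tuple[BatchModel, pd.DataFrame]:
    """Empirical-Bayes shrinkage of per-batch location/scale and adjustment.

    Returns the fitted :class:`BatchModel` and the corrected standardized
    grid ``(Z - gamma*) / delta*``.  ``prior_override`` maps a batch to a
    fixed ``(gamma_bar, t2)`` pair, bypassing the moment estimates (used
    to study shrinkage limits, e.g. t2 -> inf recovers plain per-batch
    centering).
    """
    if not parametric:
        raise NotImplementedError("only the parametric variant is implemented")
    samples = list(Z.columns)
    batches: list[object] = []
    for s in samples:
        b = batch_of[s]
        if b not in batches:
            batches.append(b)
    Zv = Z.to_numpy(dtype=float)  # genes x samples
    corrected = Zv.copy()
    gamma_hat_rows, delta2_rows, gstar_rows, dstar_rows = [], [], [], []
    gbar, t2s, a_pri, b_pri = {}, {}, {}, {}
    iters, traces = {}, {}
    for b in batches:
        idx = [j for j, s in enumerate(samples) if batch_of[s] == b]
        n_i = len(idx)
        if n_i < 2:
            raise ValueError(f"batch {b!r} has {n_i} sample(s); scale not estimable")
        Zb = Zv[:, idx]
        g_hat = Zb.mean(axis=1)
        # divide-by-n convention, consistent with the pooled variance: a
        # single-batch adjustment is then an exact identity
        d2_hat = Zb.var(axis=1, ddof=0)
        if prior_override and b in prior_override:
            g_bar, t2 = prior_override[b]
        else:
            g_bar = float(g_hat.mean())
            t2 = float(g_hat.var(ddof=1))
        a, bb = _moments_inverse_gamma(d2_hat)
        g_star = g_hat.copy()
        d2_star = d2_hat.copy()
        sum_sq0 = ((Zb - g_star[:, None]) ** 2).sum(axis=1)
        trace: list[float] = []
        converged = False
        for it in range(1, max_iter + 1):
            g_new = (n_i * t2 * g_hat + d2_star * g_bar) / (n_i * t2 + d2_star)
            sum_sq = ((Zb - g_new[:, None]) ** 2).sum(axis=1)
            d2_new = (bb + 0.5 * sum_sq) / (n_i / 2 + a - 1)
            change = max(
                float(np.max(np.abs(g_new - g_star))),
                float(np.max(np.abs(d2_new - d2_star))),
            )
            g_star, d2_star = g_new, d2_new
            trace.append(change)
            if change < tol:
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"EB fixed point for batch {b!r} did not converge in {max_iter} "
                f"iterations (last change {trace[-1]:.3g})"
            )
        corrected[:, idx] = (Zb - g_star[:, None]) / np.sqrt(d2_star)[:, None]
        gamma_hat_rows.append(g_hat)
        delta2_rows.append(d2_hat)
        gstar_rows.append(g_star)
        dstar_rows.append(d2_star)
        gbar[b], t2s[b], a_pri[b], b_pri[b] = g_bar, t2, a, bb
        iters[b] = it
        traces[b] = trace
    genes = Z.index
    model = BatchModel(
        batches=batches,
        gamma_hat=pd.DataFrame(gamma_hat_rows, index=batches, columns=genes),
        delta2_hat=pd.DataFrame(delta2_rows, index=batches, columns=genes),
        gamma_star=pd.DataFrame(gstar_rows, index=batches, columns=genes),
        delta2_star=pd.DataFrame(dstar_rows, index=batches, columns=genes),
        gamma_bar=pd.Series(gbar),
        t2=pd.Series(t2s),
        a_prior=pd.Series(a_pri),
        b_prior=pd.Series(b_pri),
        iterations=iters,
        residual_trace=traces,
    )
    return model, pd.DataFrame(corrected, index=Z.index, columns=Z.columns)


def combat(
    m: ExpressionMatrix,
    design: DesignSpec,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[ExpressionMatrix, BatchModel]:
    """Full batch adjustment: standardize, EB-shrink, de-standardize.

    Invariant genes (zero pooled variance) pass through bit-identical.
    """
    matrices = build_design(design, list(m.values.columns))
    std = standardize(m, matrices)
    Zin = std.Z.drop(index=std.invariant_genes)
    model, Zcorr = eb_adjust(
        Zin, design.batch_of, tol=tol, max_iter=max_iter
    )
    keep = ~std.Z.index.isin(std.invariant_genes)
    stand_mean = (
        std.alpha.to_numpy()[keep][None, :]
        + matrices.X_cov @ std.beta.to_numpy().T[:, keep]
    )  # samples x kept genes
    Ystar = (Zcorr.to_numpy().T * std.sigma.to_numpy()[keep][None, :] + stand_mean).T
    values = m.values.copy().astype(float)
    values.loc[keep] = Ystar
    corrected = m.evolve(
        values,
        m.value_kind,
        {
            "step": "combat",
            "n_batches": len(matrices.batches),
            "covariates": matrices.cov_columns,
            "iterations": {str(k): v for k, v in model.iterations.items()},
        },
    )
    return corrected, model
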