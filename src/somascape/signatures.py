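"""Sparse nonnegative decomposition of mutation spectra onto a signature catalogue.

Each sample's 96-bin spectrum ``m`` is modelled as a nonnegative combination of
catalogue signatures: minimize over ``w >= 0``

    || S w - m ||_2^2  +  lambda * || w ||_1        (no intercept)

where ``S`` is the 96 x K column-stochastic signature matrix.  The penalty
weight is chosen per sample by 10-fold cross-validation over the 96 context
bins with the one-standard-error rule: the largest (sparsest) lambda whose CV
mean-square error stays within one standard error of the minimum.  Signatures
contributing less than a floor fraction (default 5%) of the fitted total are
discarded and the remainder renormalized.

The solver is cyclic coordinate descent with nonnegativity clipping, which is
exact for this separable penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .spectrum import CONTEXT_LABELS

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignatureCatalogue:
    """A 96 x K matrix of per-context mutation probabilities, one column per signature."""

    matrix: np.ndarray          # shape (96, K), columns sum to 1
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape != (96, len(self.names)):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match "
                             f"{len(self.names)} signature names")
        if (self.matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("catalogue columns must sum to 1 within 1e-6")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureCatalogue":
        """Build from a labels x signatures table, canonicalizing row order."""
        labels = set(df.index)
        missing = [l for l in CONTEXT_LABELS if l not in labels]
        if missing:
            raise ValueError(f"catalogue is missing context row(s): {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        df = df.loc[list(CONTEXT_LABELS)]
        matrix = df.to_numpy(dtype=float)
        if (matrix < 0).any():
            raise ValueError("catalogue contains negative entries")
        matrix = matrix / matrix.sum(axis=0, keepdims=True)
        return cls(matrix=matrix, names=tuple(str(c) for c in df.columns))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.copy(), index=list(CONTEXT_LABELS),
                            columns=list(self.names))


@dataclass(frozen=True)
class ExposureFit:
    """Fitted signature weights for one sample, on the mutation-count scale."""

    sample_id: str
    weights: pd.Series                 # K non-negative reals
    lambda_selected: float
    cv_curve: pd.DataFrame | None      # columns: lambda, mse_mean, mse_se

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def proportions(self) -> pd.Series:
        total = self.total
        if total <= 0:
            return self.weights.astype(float)
        return self.weights / total

    @property
    def retained(self) -> tuple[str, ...]:
        return tuple(self.weights.index[self.weights > 0])


def lasso_objective(S: np.ndarray, m: np.ndarray, w: np.ndarray, lam: float) -> float:
    """Penalized objective ||S w - m||^2 + lambda ||w||_1 (w assumed >= 0)."""
    r = S @ w - m
    return float(r @ r + lam * np.abs(w).sum())


def fit_exposures(
    m: np.ndarray,
    S: SignatureCatalogue | np.ndarray,
    lam: float,
    w0: np.ndarray | None = None,
    tol: float = 1e-9,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Solve the nonnegative L1-penalized least-squares problem for one spectrum.

    Cyclic coordinate descent: each coordinate has the closed-form update
    ``w_j = max(0, (S_j . r_j - lambda/2) / ||S_j||^2)`` where ``r_j`` is the
    partial residual.  Converges when the largest coordinate change in a sweep
    drops below ``tol``.
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    A = S.matrix if isinstance(S, SignatureCatalogue) else np.asarray(S, dtype=float)
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("spectrum entries must be non-negative")
    G = A.T @ A                    # K x K Gram matrix
    c = A.T @ m
    K = A.shape[1]
    w = np.zeros(K) if w0 is None else np.asarray(w0, dtype=float).copy()
    g = G @ w                      # maintained = G w
    diag = np.diag(G)
    half_lam = lam / 2.0
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in range(K):
            if diag[j] <= 0:
                continue
            new = (c[j] - g[j] + diag[j] * w[j] - half_lam) / diag[j]
            if new < 0.0:
                new = 0.0
            delta = new - w[j]
            if delta != 0.0:
                g += G[:, j] * delta
                w[j] = new
                if abs(delta) > max_delta:
                    max_delta = abs(delta)
        if max_delta < tol:
            break
    return w


def lambda_grid(S: SignatureCatalogue | np.ndarray, m: np.ndarray,
                n_lambdas: int = 50, ratio: float = 1e-4) -> np.ndarray:
    """Decreasing log-spaced grid from lambda_max (all-zero fit) downward.

    At ``w = 0`` the subgradient condition gives lambda_max = 2 max_j S_j . m.
    """
    A = S.matrix if isinstance(S, SignatureCatalogue) else np.asarray(S, dtype=float)
    m = np.asarray(m, dtype=float)
    lam_max = 2.0 * float(np.max(A.T @ m))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def select_lambda(
    m: np.ndarray,
    S: SignatureCatalogue,
    n_folds: int = 10,
    rng_seed: int = 0,
    n_lambdas: int = 50,
    sample_id: str = "",
) -> ExposureFit:
    """Pick the penalty by CV over context bins with the one-SE rule, then refit.

    The 96 bins are shuffled into ``n_folds`` folds; for each candidate lambda
    the model is fitted on the training bins and scored on the held-out bins.
    The selected lambda is the LARGEST grid value whose CV MSE does not exceed
    the minimum CV MSE plus the standard error at the minimizing lambda
    (maximum sparsity within one SE).  The final weights are refit on all bins.
    """
    m = np.asarray(m, dtype=float)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > m.size:
        raise ValueError(f"cannot make {n_folds} folds out of {m.size} bins")
    names = list(S.names)
    if m.sum() == 0:
        log.warning("%s: all-zero spectrum; returning zero exposures", sample_id or "<sample>")
        grid = lambda_grid(S, np.ones_like(m), n_lambdas)
        return ExposureFit(sample_id, pd.Series(np.zeros(len(names)), index=names),
                           float(grid[0]), None)

    grid = lambda_grid(S, m, n_lambdas)
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(m.size)
    folds = np.array_split(order, n_folds)

    A = S.matrix
    sq_err = np.zeros((n_folds, len(grid)))
    for f, test_idx in enumerate(folds):
        train = np.ones(m.size, dtype=bool)
        train[test_idx] = False
        A_tr, m_tr = A[train], m[train]
        A_te, m_te = A[test_idx], m[test_idx]
        w = None
        for g, lam in enumerate(grid):
            w = fit_exposures(m_tr, A_tr, lam, w0=w)
            resid = A_te @ w - m_te
            sq_err[f, g] = float(np.mean(resid ** 2))
    mse_mean = sq_err.mean(axis=0)
    mse_se = sq_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(mse_mean))
    threshold = mse_mean[best] + mse_se[best]
    eligible = np.nonzero(mse_mean <= threshold)[0]
    selected = int(eligible[0])  # grid is decreasing, so first eligible = largest lambda
    lam_sel = float(grid[selected])

    w_full = fit_exposures(m, A, lam_sel)
    curve = pd.DataFrame({"lambda": grid, "mse_mean": mse_mean, "mse_se": mse_se})
    return ExposureFit(sample_id, pd.Series(w_full, index=names), lam_sel, curve)


def filter_exposures(fit: ExposureFit, floor: float = 0.05) -> ExposureFit:
    """Drop signatures contributing less than ``floor`` of the fitted total.

    The surviving weights are kept on the count scale; proportions renormalize
    over the retained set.  If nothing survives the floor, the single largest
    signature is retained with a warning.
    """
    if fit.total <= 0:
        raise ValueError("cannot filter a fit with zero total exposure")
    props = fit.proportions
    keep = props >= floor
    if not keep.any():
        log.warning("%s: no signature reaches the %.0f%% floor; keeping the largest",
                    fit.sample_id, 100 * floor)
        keep = props == props.max()
    weights = fit.weights.where(keep, 0.0)
    return replace(fit, weights=weights)


def cohort_signature_summary(fits: Sequence[ExposureFit], floor: float = 0.05) -> pd.DataFrame:
    """Pooled per-signature contribution across samples.

    Sums the (count-scale) weights over samples and normalizes.  The headline
    column suppresses signatures pooling below the floor; the full pooled
    proportion is always reported.
    """
    if not fits:
        raise ValueError("need at least one fit")
    pooled = sum((f.weights for f in fits), start=fits[0].weights * 0.0)
    total = float(pooled.sum())
    prop = pooled / total if total > 0 else pooled
    df = pd.DataFrame({
        "pooled_weight": pooled,
        "pooled_proportion": prop,
        "headline_proportion": prop.where(prop >= floor),
    })
    df.index.name = "signature"
    return df.sort_values("pooled_proportion", ascending=False)
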