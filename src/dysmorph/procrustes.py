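"""Classical Procrustes machinery: closed-form (weighted) least-squares fits,
negative log-likelihoods, generalized Procrustes analysis, and PDM building.

The weighted fit is the workhorse of every robust estimator in the package:
the EM M-step, the IRLS M-estimators and the LMedS refinement all reduce to
a weighted least-sum-of-squares superimposition, solved in closed form via
the weighted cross-covariance SVD (Kabsch/Umeyama construction with a
reflection guard).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    PDM,
    BreakdownError,
    Configuration,
    DegenerateGeometryError,
    ResidualField,
    TransformParams,
    gauss_prefactor,
    validate_pair,
)
from .transforms import apply_rigid

__all__ = [
    "lss_fit",
    "weighted_lss_fit",
    "nll",
    "generalized_procrustes",
    "GPAResult",
    "build_pdm",
    "pdm_project",
]


def _weighted_kabsch(
    X: np.ndarray, Y: np.ndarray, w: np.ndarray, allow_scale: bool
) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form argmin_{R,t,s} sum_j w_j || s R x_j + t - y_j ||^2."""
    wsum = w.sum()
    if wsum <= 0:
        raise BreakdownError("all landmark weights are zero")
    xbar = (w[:, None] * X).sum(axis=0) / wsum
    ybar = (w[:, None] * Y).sum(axis=0) / wsum
    Xc = X - xbar
    Yc = Y - ybar
    H = (w[:, None] * Yc).T @ Xc  # d x d cross-covariance, maps source -> target
    U, S, Vt = np.linalg.svd(H)
    d = X.shape[1]
    sign = np.sign(np.linalg.det(U @ Vt))
    if sign == 0:
        sign = 1.0
    D = np.ones(d)
    D[-1] = sign
    R = U @ np.diag(D) @ Vt
    # geometry check on the effective (weighted) source: a similarity in dim d
    # needs rank >= d-1 of the centered source point set
    sv = np.linalg.svd(np.sqrt(w)[:, None] * Xc, compute_uv=False)
    if len(sv) < d or (d >= 2 and sv[d - 2] <= 1e-9 * max(sv[0], 1e-30)):
        raise DegenerateGeometryError(
            "effective landmarks are rank-deficient (collinear/coincident); "
            "cannot determine the rotation"
        )
    if allow_scale:
        denom = float((w * (Xc**2).sum(axis=1)).sum())
        if denom <= 0:
            raise DegenerateGeometryError("zero spread; scale undefined")
        s = float((S * D).sum() / denom)
        if s <= 0:
            raise DegenerateGeometryError("nonpositive optimal scale")
    else:
        s = 1.0
    t = ybar - s * R @ xbar
    return R, t, s


def lss_fit(
    source: Configuration, target: Configuration, allow_scale: bool = False
) -> TransformParams:
    """Least-sum-of-squares superimposition of ``source`` onto ``target``.

    Minimizes sum_j ||T(l'_j, theta) - l_j||^2 over rotation, translation and
    (optionally) scale.  The returned rotation is always proper (det = +1).
    """
    validate_pair(source, target)
    if source.n_landmarks < source.dim:
        raise DegenerateGeometryError(
            f"need at least dim={source.dim} landmarks, got {source.n_landmarks}"
        )
    w = np.ones(source.n_landmarks)
    R, t, s = _weighted_kabsch(source.coords, target.coords, w, allow_scale)
    return TransformParams(R, t, s)


def weighted_lss_fit(
    source: Configuration,
    target: Configuration,
    weights,
    allow_scale: bool = False,
) -> TransformParams:
    """Weighted LSS superimposition, minimizing sum_j w_j ||d_j||^2.

    With the inlier beliefs as weights this is exactly the transformation
    update of the EM M-step: outliers (w -> 0) stop contributing to the fit.
    """
    validate_pair(source, target)
    w = np.asarray(weights, dtype=float)
    if w.shape != (source.n_landmarks,):
        raise ValueError("one weight per landmark required")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    R, t, s = _weighted_kabsch(source.coords, target.coords, w, allow_scale)
    return TransformParams(R, t, s)


def nll(residuals: ResidualField, sigma=None) -> float:
    """Negative log-likelihood of the residual field under the AWGN model.

    The variant is selected by the form of ``sigma``: ``None`` gives the pure
    sum of squared residual magnitudes (the LSS objective); a scalar gives
    the homoscedastic single-sigma form sum_j |d_j|^2/(2 sigma^2) +
    log(sqrt(2 pi) sigma); an array of per-landmark sigmas the heteroscedastic
    diagonal form.  Constant terms are omitted throughout, and the Gaussian
    normalization is the magnitude-scale prefactor 1/(sqrt(2 pi) sigma) used
    everywhere in this package.
    """
    r2 = (residuals.vectors**2).sum(axis=1)
    if sigma is None:
        return float(r2.sum())
    sig = np.asarray(sigma, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")
    if sig.ndim == 0:
        sig = np.full(r2.shape, float(sig))
    elif sig.shape != r2.shape:
        raise ValueError("per-landmark sigma must match the number of landmarks")
    return float(np.sum(r2 / (2.0 * sig**2) - np.log(gauss_prefactor(1.0) / sig)))


@dataclass(frozen=True)
class GPAResult:
    consensus: Configuration
    aligned: tuple[Configuration, ...]
    converged: bool
    n_iter: int


def generalized_procrustes(
    configs,
    allow_scale: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes analysis: align all configurations to an
    evolving consensus (the estimated geometric mean form).

    Iterates (align everything to the consensus; recompute the consensus as
    the coordinate-wise mean) until the consensus RMS change drops below
    ``tol`` mm.  The consensus is centered at the origin; with scaling
    enabled it is additionally rescaled to unit centroid size each iteration
    to pin the size gauge.  Non-convergence sets ``converged=False`` rather
    than raising.
    """
    configs = list(configs)
    if len(configs) < 2:
        raise ValueError("generalized Procrustes needs at least two configurations")
    for c in configs[1:]:
        validate_pair(configs[0], c)
    # initial consensus: mean of the centered inputs — permutation-invariant,
    # so the final frame does not depend on the input order
    mean0 = np.mean([c.centered().coords for c in configs], axis=0)
    consensus = Configuration(mean0, configs[0].labels)
    if allow_scale:
        consensus = consensus.with_coords(
            consensus.coords / consensus.centroid_size()
        )
    aligned = list(configs)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = [
            apply_rigid(c, lss_fit(c, consensus, allow_scale)) for c in configs
        ]
        mean = np.mean([c.coords for c in aligned], axis=0)
        new = Configuration(mean - mean.mean(axis=0), consensus.labels)
        if allow_scale:
            new = new.with_coords(new.coords / new.centroid_size())
        change = math.sqrt(
            ((new.coords - consensus.coords) ** 2).mean()
        )
        consensus = new
        if change < tol:
            converged = True
            break
    return GPAResult(consensus, tuple(aligned), converged, it)


def build_pdm(aligned, variance_fraction: float = 0.98) -> PDM:
    """Principal component analysis of aligned configurations into a PDM.

    Keeps the smallest number of top-ranked components whose cumulative
    variance reaches ``variance_fraction`` of the total; the remainder is
    treated as biologically insignificant (noise/artifact) variance.
    """
    if not 0.0 < variance_fraction <= 1.0:
        raise ValueError(f"variance_fraction must be in (0, 1], got {variance_fraction}")
    aligned = list(aligned)
    if len(aligned) < 2:
        raise ValueError("need at least two configurations to build a PDM")
    for c in aligned[1:]:
        validate_pair(aligned[0], c)
    X = np.stack([c.vec() for c in aligned])
    mean = X.mean(axis=0)
    Xc = X - mean
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2 / (len(aligned) - 1)
    keep = var > max(var[0], 1e-30) * 1e-14  # numerical rank
    var, Vt, S = var[keep], Vt[keep], S[keep]
    cum = np.cumsum(var) / var.sum()
    D = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    D = min(D, len(var))
    consensus = Configuration(
        mean.reshape(aligned[0].coords.shape), aligned[0].labels
    )
    return PDM(consensus, Vt[:D], np.sqrt(var[:D]), variance_fraction)


def pdm_project(pdm: PDM, config: Configuration) -> np.ndarray:
    """Orthonormal-mode least squares: c_k = U_k . vec(config - consensus).

    The configuration must already live in the PDM consensus frame.
    """
    validate_pair(pdm.consensus, config)
    return pdm.modes @ (config.vec() - pdm.consensus.vec())
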