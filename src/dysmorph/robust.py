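"""Reference robust superimposition baselines.

These estimators are the classical answers to the Pinocchio effect that the
EM mixture estimator is compared against: redescending M-estimators solved
by iteratively reweighted least squares, least-median-of-squares with
minimal-subset sampling, and the historical resistant fit built from
repeated medians.  They are robust against outliers but model them only
implicitly — none yields a posterior outlier probability per landmark.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    Configuration,
    DegenerateGeometryError,
    TransformParams,
    validate_pair,
)
from .procrustes import lss_fit, weighted_lss_fit
from .transforms import apply_rigid

__all__ = ["mestimator_fit", "lmeds_fit", "repeated_median_fit", "LOSSES"]


def _rho_quadratic(r, s):
    return r**2


def _w_quadratic(r, s):
    return np.ones_like(r)


def _rho_lorentzian(r, s):
    return np.log1p(0.5 * (r / s) ** 2)


def _w_lorentzian(r, s):
    # proportional to rho'(r)/r, the IRLS weight of the Lorentzian loss
    return 1.0 / (1.0 + 0.5 * (r / s) ** 2)


def _rho_truncated_quadratic(r, s):
    return np.minimum(r**2, s**2)


def _w_truncated_quadratic(r, s):
    # hard 0/1 weights: the discontinuity the smooth mixture estimator avoids
    return (r <= s).astype(float)


LOSSES = {
    "quadratic": (_rho_quadratic, _w_quadratic),
    "lorentzian": (_rho_lorentzian, _w_lorentzian),
    "truncated_quadratic": (_rho_truncated_quadratic, _w_truncated_quadratic),
}


def mestimator_fit(
    source: Configuration,
    target: Configuration,
    loss: str = "lorentzian",
    scale_param: float = 1.0,
    allow_scale: bool = False,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> TransformParams:
    """M-estimator superimposition argmin_theta sum_j rho(|d_j|) via IRLS.

    Each iteration refits with weights w_j = rho'(|d_j|)/|d_j| evaluated at
    the current residuals; the quadratic loss has constant weights and
    reproduces the LSS fit exactly.  ``scale_param`` is the loss width in mm.
    Non-convergence emits a warning and returns the last iterate.
    """
    if loss not in LOSSES:
        raise ValueError(f"unknown loss {loss!r}; choose from {sorted(LOSSES)}")
    if scale_param <= 0:
        raise ValueError("scale_param must be positive")
    _, wfun = LOSSES[loss]
    params = lss_fit(source, target, allow_scale)
    for _ in range(max_iter):
        r = np.linalg.norm(
            apply_rigid(source, params).coords - target.coords, axis=1
        )
        w = wfun(r, scale_param)
        new = weighted_lss_fit(source, target, w, allow_scale)
        delta = max(
            np.abs(new.rotation - params.rotation).max(),
            np.abs(new.translation - params.translation).max(),
            abs(new.scale - params.scale),
        )
        params = new
        if delta < tol:
            return params
    warnings.warn(f"IRLS did not converge within {max_iter} iterations")
    return params


def lmeds_fit(
    source: Configuration,
    target: Configuration,
    n_subsets: int = 500,
    seed: int = 0,
    allow_scale: bool = False,
) -> TransformParams:
    """Least-median-of-squares superimposition by minimal-subset search.

    Draws random minimal subsets (dim landmarks), fits each exactly, scores
    candidates by the median squared residual over all landmarks, and
    refines the best candidate by a weighted LSS fit on its inliers (within
    2.5 robust standard deviations, with the usual small-sample correction).
    """
    validate_pair(source, target)
    K, d = source.coords.shape
    if K < d + 1:
        raise DegenerateGeometryError(
            f"LMedS needs at least dim+1={d + 1} landmarks, got {K}"
        )
    rng = np.random.default_rng(seed)
    best_med = np.inf
    best = None
    for _ in range(n_subsets):
        idx = rng.choice(K, size=d, replace=False)
        sub_s = Configuration(source.coords[idx], [source.labels[i] for i in idx])
        sub_t = Configuration(target.coords[idx], [target.labels[i] for i in idx])
        try:
            cand = lss_fit(sub_s, sub_t, allow_scale)
        except DegenerateGeometryError:
            continue
        r2 = (
            (apply_rigid(source, cand).coords - target.coords) ** 2
        ).sum(axis=1)
        med = float(np.median(r2))
        if med < best_med:
            best_med, best = med, cand
    if best is None:
        raise DegenerateGeometryError("no non-degenerate minimal subset found")
    s0 = 1.4826 * (1.0 + 5.0 / max(K - d, 1)) * np.sqrt(best_med)
    r2 = ((apply_rigid(source, best).coords - target.coords) ** 2).sum(axis=1)
    inliers = (r2 <= (2.5 * s0) ** 2).astype(float)
    if inliers.sum() >= d:
        try:
            best = weighted_lss_fit(source, target, inliers, allow_scale)
        except DegenerateGeometryError:
            pass
    return best


def _repeated_median(theta: np.ndarray) -> float:
    """Repeated median over a K x K antisymmetric matrix of pairwise values."""
    K = theta.shape[0]
    mask = ~np.eye(K, dtype=bool)
    inner = np.array([np.median(theta[i][mask[i]]) for i in range(K)])
    return float(np.median(inner))


def _pairwise_angles(P: np.ndarray, Q: np.ndarray, min_edge: float = 1e-9):
    """Angles rotating projected edge vectors of P onto those of Q, per pair."""
    dP = P[:, None, :] - P[None, :, :]
    dQ = Q[:, None, :] - Q[None, :, :]
    dot = (dP * dQ).sum(-1)
    cross = dP[..., 0] * dQ[..., 1] - dP[..., 1] * dQ[..., 0]
    ok = (np.linalg.norm(dP, axis=-1) > min_edge) & (
        np.linalg.norm(dQ, axis=-1) > min_edge
    )
    ang = np.arctan2(cross, dot)
    ang[~ok] = 0.0
    return ang


_PLANES = ((0, 1, 2), (1, 2, 0), (2, 0, 1))  # (in-plane axes, rotation axis)


def _embed(i: int, j: int, c: float, s: float) -> np.ndarray:
    R = np.eye(3)
    R[i, i] = c
    R[j, j] = c
    R[i, j] = -s
    R[j, i] = s
    return R


def repeated_median_fit(
    source: Configuration, target: Configuration, max_sweeps: int = 30
) -> TransformParams:
    """Resistant rigid fit by repeated medians of pairwise estimates.

    2D: the rotation angle is the repeated median of pairwise edge-direction
    differences; the translation the axis-wise median of the per-landmark
    offsets.  3D: the rotation is accumulated by axis-wise sweeps, each
    taking the repeated median of in-plane pairwise angles in one coordinate
    plane, iterated until the per-sweep corrections vanish.  This is a
    reference baseline: its breakdown is excellent but its cost grows
    quadratically in K and its convergence theory is murky — the EM
    estimator is the supported path.
    """
    validate_pair(source, target)
    K, d = source.coords.shape
    if K < 3:
        raise DegenerateGeometryError("repeated-median fit needs at least 3 landmarks")
    X, Y = source.coords, target.coords
    if d == 2:
        theta = _repeated_median(_pairwise_angles(X, Y))
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s], [s, c]])
    else:
        R = np.eye(3)
        for _ in range(max_sweeps):
            P = X @ R.T
            worst = 0.0
            for i, j, axis in _PLANES:
                ang = _repeated_median(
                    _pairwise_angles(P[:, (i, j)], Y[:, (i, j)])
                )
                G = _embed(i, j, np.cos(ang), np.sin(ang))
                R = G @ R
                P = X @ R.T
                worst = max(worst, abs(ang))
            if worst < 1e-12:
                break
    t = np.median(Y - X @ R.T, axis=0)
    return TransformParams(R, t, 1.0)
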