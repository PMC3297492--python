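"""Transformation models: rigid/similarity maps, PDM-extended maps, mirroring.

The rigid (or similarity) model x -> s*R*x + t removes the confounders of
position, orientation and optionally size.  The PDM-extended model first
synthesizes a configuration inside the population's variation,
C' = consensus + sum_k U_k c_k, and then applies the rigid part; its Gibbs
prior penalizes implausible mode loadings through the Mahalanobis norm
0.5 * sum_k c_k^2 / alpha_k^2.
"""

from __future__ import annotations

import numpy as np

from .core import (
    PDM,
    BilateralMap,
    Configuration,
    InvalidTransformError,
    NoReflectionError,
    TransformParams,
)

__all__ = [
    "apply_rigid",
    "apply_pdm",
    "regularization_penalty",
    "mirror",
    "extract_symmetry_plane",
    "euler_from_rotation",
    "rotation_from_euler",
]


def apply_rigid(config: Configuration, params: TransformParams) -> Configuration:
    """Apply x -> s*R*x + t row-wise; labels are preserved."""
    if params.pdm_coeffs is not None:
        raise InvalidTransformError(
            "params carry PDM coefficients; use apply_pdm with the PDM norm"
        )
    if params.dim != config.dim:
        raise InvalidTransformError(
            f"transform dim {params.dim} does not match configuration dim {config.dim}"
        )
    coords = params.scale * config.coords @ params.rotation.T + params.translation
    return config.with_coords(coords)


def apply_pdm(pdm: PDM, params: TransformParams) -> Configuration:
    """Generate consensus + sum_k U_k c_k, then apply the rigid/similarity part.

    This is the norm-equivalent generator: at fitted parameters it produces
    the harmonious counterpart of an assessed configuration, expressed in the
    assessed configuration's coordinate frame.
    """
    c = params.pdm_coeffs
    if c is None:
        c = np.zeros(pdm.n_modes)
    c = np.asarray(c, dtype=float)
    if c.shape != (pdm.n_modes,):
        raise ValueError(
            f"expected {pdm.n_modes} PDM coefficients, got shape {c.shape}"
        )
    shape = pdm.consensus.coords.shape
    coords = pdm.consensus.coords + (pdm.modes.T @ c).reshape(shape)
    rigid = TransformParams(params.rotation, params.translation, params.scale)
    return apply_rigid(Configuration(coords, pdm.labels), rigid)


def regularization_penalty(params: TransformParams, pdm: PDM | None = None) -> float:
    """Gibbs-prior penalty 0.5 * sum_k c_k^2 / alpha_k^2 on PDM loadings.

    For purely rigid parameter sets (no PDM coefficients) no transformation is
    favored over another and the penalty is identically zero.
    """
    c = params.pdm_coeffs
    if c is None or pdm is None:
        return 0.0
    sd = pdm.mode_sd
    if np.any(sd == 0):
        raise ValueError("degenerate PDM mode with zero standard deviation")
    c = np.asarray(c, dtype=float)
    if c.shape != sd.shape:
        raise ValueError("coefficient / mode count mismatch")
    return float(0.5 * np.sum(c**2 / sd**2))


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


def mirror(
    config: Configuration,
    bmap: BilateralMap,
    plane_normal=(1.0, 0.0, 0.0),
) -> Configuration:
    """Reflect across the plane through the centroid and swap paired labels.

    Landmark j of the output is the anatomical mirror-homologue of landmark j
    of the input, so the output is directly comparable (label-homologous) to
    the input.  For a perfectly bilaterally symmetric configuration the
    mirror equals the original.
    """
    n = _unit(np.asarray(plane_normal, dtype=float)[: config.dim])
    if not bmap.covers(config.labels):
        missing = next(l for l in config.labels if not _covered(bmap, l))
        raise KeyError(f"label {missing!r} not covered by bilateral map")
    c0 = config.centroid
    reflected = config.coords - 2.0 * np.outer((config.coords - c0) @ n, n)
    perm = bmap.permutation(config.labels)
    return config.with_coords(reflected[perm])


def _covered(bmap: BilateralMap, label: str) -> bool:
    try:
        bmap.partner(label)
        return True
    except KeyError:
        return False


def extract_symmetry_plane(
    mirror_normal,
    fitted: TransformParams,
    plane_point,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Recover the midsagittal plane from a fitted mirror superimposition.

    The initial reflection (across the plane through ``plane_point`` with
    normal ``mirror_normal``) composed with the fitted rigid map is one
    improper orthogonal map G(x) = A x + g.  Its -1 eigenvector is the plane
    normal of the subject's true symmetry plane; the fixed points of G,
    obtained as the least-squares solution of (I - A) x = g, lie on that
    plane.  The initial mirror plane need not be anatomically meaningful —
    the robust fit corrects it, which is the whole point of extracting the
    plane from the fitted transform.
    """
    n0 = _unit(mirror_normal)
    d = n0.shape[0]
    p0 = np.asarray(plane_point, dtype=float)
    H = np.eye(d) - 2.0 * np.outer(n0, n0)
    m = 2.0 * (p0 @ n0) * n0
    A = fitted.scale * fitted.rotation @ H
    g = fitted.scale * fitted.rotation @ m + fitted.translation
    w, V = np.linalg.eig(A)
    i = int(np.argmin(np.abs(w + 1.0)))
    if abs(w[i] + 1.0) > tol:
        raise NoReflectionError(
            f"composed map has no eigenvalue near -1 (closest {w[i]:.6g}); "
            "it is not a reflection"
        )
    normal = np.real(V[:, i])
    normal = _unit(normal)
    if normal @ n0 < 0:
        normal = -normal
    point, *_ = np.linalg.lstsq(np.eye(d) - A, g, rcond=None)
    return point, normal


def rotation_from_euler(angles) -> np.ndarray:
    """Intrinsic Z-Y-X Euler angles (radians) to a 3D rotation matrix.

    Euler angles exist only at the I/O boundary; all fitting works with
    matrices directly.
    """
    az, ay, ax = [float(a) for a in angles]
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    Ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
    Rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


def euler_from_rotation(R: np.ndarray) -> np.ndarray:
    """Rotation matrix to intrinsic Z-Y-X Euler angles (radians)."""
    R = np.asarray(R, dtype=float)
    ay = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if abs(R[2, 0]) < 1.0 - 1e-12:
        az = np.arctan2(R[1, 0], R[0, 0])
        ax = np.arctan2(R[2, 1], R[2, 2])
    else:  # gimbal lock: fold the indeterminate angle into az
        az = np.arctan2(-R[0, 1], R[1, 1])
        ax = 0.0
    return np.array([az, ay, ax])
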