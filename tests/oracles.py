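"""Independent brute-force oracles used by the test suite.

The grid oracle evaluates superimposition objectives by exhaustive search
over rotation angle and translation on small 2D instances, never touching
the closed-form fitting code it is used to check.
"""

import numpy as np

ANGLE_RES = 1e-3
TRANS_RES = 1e-3


def rot2d(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def grid_fit_2d(source, target, rho, weights=None):
    """Exhaustive angle x translation search minimizing sum_j w_j rho(|d_j|).

    Two-stage grid: a full-circle coarse sweep (0.01 rad, 0.1 mm translation
    window around the rotated-centroid offset), then a fine sweep at
    ANGLE_RES / TRANS_RES around the coarse optimum.  Returns (objective,
    angle, translation).
    """
    X, Y = source.coords, target.coords
    w = np.ones(len(X)) if weights is None else np.asarray(weights, float)

    def objective(theta, tgrid):
        base = X @ rot2d(theta).T
        diff = base[None, :, :] + tgrid[:, None, :] - Y[None, :, :]
        rmag = np.sqrt((diff**2).sum(-1))
        return (w[None, :] * rho(rmag)).sum(-1)

    best = (np.inf, 0.0, np.zeros(2))
    for theta in np.arange(-np.pi, np.pi, 0.01):
        tc = Y.mean(0) - (X @ rot2d(theta).T).mean(0)
        g = np.arange(-2.0, 2.0001, 0.1)
        tgrid = np.stack(np.meshgrid(g + tc[0], g + tc[1]), -1).reshape(-1, 2)
        vals = objective(theta, tgrid)
        i = int(vals.argmin())
        if vals[i] < best[0]:
            best = (vals[i], theta, tgrid[i])
    _, th0, t0 = best
    for theta in np.arange(th0 - 0.02, th0 + 0.02, ANGLE_RES):
        g = np.arange(-0.15, 0.1501, TRANS_RES)
        tgrid = np.stack(np.meshgrid(g + t0[0], g + t0[1]), -1).reshape(-1, 2)
        vals = objective(theta, tgrid)
        i = int(vals.argmin())
        if vals[i] < best[0]:
            best = (vals[i], theta, tgrid[i])
    return best


def quotient_principal_angles(template, pdm, true_modes):
    """Principal angles between mode subspaces modulo the similarity group.

    The estimated modes are first rotated from the PDM consensus frame into
    the template frame (the GPA consensus inherits the arbitrary pose of its
    initialization).  Procrustes-aligned variation is then defined only in
    the shape quotient: alignment can add tangent-space (translation /
    rotation / scale) components to estimated modes, so both sets are
    projected off the similarity tangent space at the template before
    comparison.
    """
    from scipy.linalg import subspace_angles

    from dysmorph import lss_fit
    from dysmorph.synthetic import _similarity_tangent_basis

    K, d = template.coords.shape
    frame = lss_fit(pdm.consensus, template.centered())
    est = (pdm.modes.reshape(-1, K, d) @ frame.rotation.T).reshape(pdm.n_modes, -1)
    T = _similarity_tangent_basis(template.centered())

    def project(M):
        M = M - (M @ T.T) @ T
        return M / np.linalg.norm(M, axis=1, keepdims=True)

    return subspace_angles(project(est).T, project(np.atleast_2d(true_modes)).T)


def angle_of(params) -> float:
    return float(np.arctan2(params.rotation[1, 0], params.rotation[0, 0]))


def wrapped_angle_diff(a: float, b: float) -> float:
    return abs(float(np.angle(np.exp(1j * (a - b)))))
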