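"""Synthetic face-like landmark data: templates, cohorts, noise, deformations.

Everything here is a pure function of its seed (NumPy's PCG64 generator), so
all simulations are bitwise reproducible.  The template emulates a spatially
dense quasi-landmark representation of a face: a half-ellipsoid surface with
named anatomical regions, exact bilateral left/right pairing and a midline.
The proportions are deliberately cartoonish — in particular the protruding
nose-tip region carries 12% of the landmarks, which makes the classic
"Pinocchio" experiment (a 30 mm forward nose displacement) well posed both
for robust flagging at kappa = 2 and for the unweighted limit at large
kappa.
"""

from __future__ import annotations

import numpy as np

from .core import BilateralMap, Configuration, TransformParams
from .transforms import apply_rigid

__all__ = [
    "make_template",
    "inject_deformation",
    "add_awgn",
    "make_modes",
    "sample_population",
    "random_rigid",
    "pinocchio_pair",
]

# (name, lateral?, fraction, x-range (right half), y-range) in mm
_REGIONS = (
    ("forehead", False, 0.18, (0.0, 40.0), (30.0, 70.0)),
    ("eye", True, 0.06, (15.0, 33.0), (11.0, 21.0)),
    ("cheek", True, 0.10, (22.0, 48.0), (-28.0, 2.0)),
    ("jaw", True, 0.07, (14.0, 38.0), (-58.0, -34.0)),
    ("midface", True, 0.02, (8.0, 20.0), (-10.0, 8.0)),
    ("nose", False, 0.06, (0.0, 9.0), (0.0, 16.0)),
    ("nose_tip", False, 0.12, (0.0, 8.0), (-12.0, -2.0)),
    ("mouth", False, 0.08, (0.0, 20.0), (-32.0, -20.0)),
    ("chin", False, 0.06, (0.0, 13.0), (-66.0, -44.0)),
)


def _surface_z(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Facial depth: half-ellipsoid base plus nose bridge and tip protrusions."""
    z = 55.0 * np.sqrt(np.clip(1.0 - (x / 65.0) ** 2 - (y / 85.0) ** 2, 0.0, 1.0))
    bridge = 8.0 * np.clip(1.0 - np.abs(x) / 9.0, 0, None) * np.clip(
        1.0 - np.abs(y - 8.0) / 8.0, 0, None
    )
    tip = 14.0 * np.clip(1.0 - (x / 8.0) ** 2, 0, None) * np.clip(
        1.0 - ((y + 7.0) / 5.0) ** 2, 0, None
    )
    return z + bridge + tip


def make_template(
    n_landmarks: int = 1000, seed: int = 0
) -> tuple[Configuration, BilateralMap, dict[str, list[str]]]:
    """Sample a bilaterally symmetric face-like landmark template.

    Returns the configuration (exactly mirror-symmetric about the x = 0
    plane through its centroid), the bilateral correspondence map, and a
    dict mapping region names to the labels they contain (a partition of all
    landmarks).  Lateral regions come in ``_R``/``_L`` twins; central
    regions contain paired off-midline points plus exact-midline points.
    """
    if n_landmarks < 20:
        raise ValueError("template needs at least 20 landmarks")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for name, lateral, frac, *_ in _REGIONS:
        counts[name] = max(1 if lateral else 2, round(frac * n_landmarks))
    total = sum(
        2 * counts[name] if lateral else counts[name]
        for name, lateral, *_ in _REGIONS
    )
    counts["forehead"] += n_landmarks - total  # absorb rounding drift

    labels: list[str] = []
    coords: list[np.ndarray] = []
    pairs: list[tuple[str, str]] = []
    midline: list[str] = []
    regions: dict[str, list[str]] = {}

    def emit(x, y, label):
        labels.append(label)
        coords.append(np.array([x, y, 0.0]))

    for name, lateral, frac, (x0, x1), (y0, y1) in _REGIONS:
        n = counts[name]
        if lateral:
            regions[f"{name}_R"] = []
            regions[f"{name}_L"] = []
            for i in range(n):
                x = rng.uniform(max(x0, 0.5), x1)
                y = rng.uniform(y0, y1)
                right, left = f"{name}_R_{i:03d}", f"{name}_L_{i:03d}"
                emit(x, y, right)
                emit(-x, y, left)
                pairs.append((left, right))
                regions[f"{name}_R"].append(right)
                regions[f"{name}_L"].append(left)
        else:
            regions[name] = []
            n_mid = max(1, round(0.1 * n))
            if (n - n_mid) % 2:
                n_mid += 1
            n_half = (n - n_mid) // 2
            for i in range(n_half):
                x = rng.uniform(max(x1 * 0.05, 0.4), x1)
                y = rng.uniform(y0, y1)
                right, left = f"{name}_{i:03d}R", f"{name}_{i:03d}L"
                emit(x, y, right)
                emit(-x, y, left)
                pairs.append((left, right))
                regions[name] += [right, left]
            for i in range(n_mid):
                y = rng.uniform(y0, y1)
                lab = f"{name}_{i:03d}M"
                emit(0.0, y, lab)
                midline.append(lab)
                regions[name].append(lab)

    pts = np.stack(coords)
    pts[:, 2] = _surface_z(pts[:, 0], pts[:, 1])
    config = Configuration(pts, labels)
    return config, BilateralMap(tuple(pairs), tuple(midline)), regions


def inject_deformation(
    config: Configuration,
    region,
    direction="outward",
    magnitude_mm: float = 0.0,
) -> Configuration:
    """Displace exactly the named landmarks by ``magnitude_mm`` along a direction.

    ``direction`` is a unit vector applied to every landmark of the region,
    or the string ``"outward"`` for the per-landmark radial direction from
    the configuration centroid.  All other landmarks are untouched.
    """
    region = list(region)
    if not region:
        raise ValueError("deformation region is empty")
    idx = np.array([config.index_of(l) for l in region])
    coords = config.coords.copy()
    if isinstance(direction, str):
        if direction != "outward":
            raise ValueError(f"unknown direction {direction!r}")
        d = coords[idx] - config.centroid
        norms = np.linalg.norm(d, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        d = d / norms
    else:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
    coords[idx] = coords[idx] + magnitude_mm * d
    return config.with_coords(coords)


def add_awgn(config: Configuration, sigma: float, seed: int = 0) -> Configuration:
    """Add i.i.d. zero-mean isotropic Gaussian offsets (SD sigma per coordinate)."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return config
    rng = np.random.default_rng(seed)
    return config.with_coords(config.coords + rng.normal(0.0, sigma, config.coords.shape))


def _similarity_tangent_basis(template: Configuration) -> np.ndarray:
    """Orthonormal basis of infinitesimal similarity motions at the template.

    Spans translations, infinitesimal rotations and uniform scaling of the
    centered template — the directions a Procrustes alignment removes.
    """
    K, d = template.coords.shape
    X = template.coords - template.centroid
    basis = []
    for a in range(d):  # translations
        t = np.zeros((K, d))
        t[:, a] = 1.0
        basis.append(t.ravel())
    if d == 2:
        gens = [np.array([[0.0, -1.0], [1.0, 0.0]])]
    else:
        gens = [
            np.array([[0, -1, 0], [1, 0, 0], [0, 0, 0]], dtype=float),
            np.array([[0, 0, 1], [0, 0, 0], [-1, 0, 0]], dtype=float),
            np.array([[0, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
        ]
    for G in gens:  # rotations
        basis.append((X @ G.T).ravel())
    basis.append(X.ravel())  # scaling
    Q, _ = np.linalg.qr(np.stack(basis).T)
    return Q.T


def make_modes(
    template: Configuration, n_modes: int, seed: int = 0, smoothness_mm: float = 30.0
) -> np.ndarray:
    """Smooth orthonormal deformation fields for synthesizing populations.

    Each mode is a sum of Gaussian-bump vector fields over the template
    surface, projected off the similarity-group tangent space (so the modes
    carry pure shape variation that a Procrustes alignment cannot absorb)
    and orthonormalized across modes (rows of the returned
    n_modes x (K*dim) matrix).  They play the role of the principal modes of
    a population's shape variation.
    """
    rng = np.random.default_rng(seed)
    K, d = template.coords.shape
    T = _similarity_tangent_basis(template)
    fields = np.empty((n_modes, K * d))
    for m in range(n_modes):
        field = np.zeros((K, d))
        for _ in range(6):
            center = template.coords[rng.integers(K)]
            direction = rng.normal(size=d)
            direction /= np.linalg.norm(direction)
            r2 = ((template.coords - center) ** 2).sum(axis=1)
            field += np.outer(np.exp(-r2 / (2.0 * smoothness_mm**2)), direction)
        v = field.ravel()
        fields[m] = v - T.T @ (T @ v)
    # Gram-Schmidt across modes
    Q, _ = np.linalg.qr(fields.T)
    return Q.T[:n_modes]


def sample_population(
    template: Configuration,
    modes,
    mode_sd,
    n: int,
    noise_sigma: float = 0.0,
    seed: int = 0,
    max_angle: float = 0.0,
    max_translation: float = 0.0,
    scale_range=(1.0, 1.0),
) -> list[Configuration]:
    """Draw a cohort: template + sum_k c_k * mode_k + AWGN, optional random pose.

    Mode loadings are drawn c_k ~ Normal(0, mode_sd_k^2).  With
    ``max_angle``/``max_translation``/``scale_range`` set, each individual
    additionally receives a random similarity transform, as raw scans would.
    """
    if n < 2:
        raise ValueError("a population needs at least two individuals")
    modes = np.atleast_2d(np.asarray(modes, dtype=float).reshape(len(mode_sd), -1))
    mode_sd = np.asarray(mode_sd, dtype=float)
    shape = template.coords.shape
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(n)
    out = []
    for i in range(n):
        rng = np.random.default_rng(seeds[i])
        c = rng.normal(0.0, mode_sd)
        coords = template.coords + (modes.T @ c).reshape(shape)
        if noise_sigma > 0:
            coords = coords + rng.normal(0.0, noise_sigma, shape)
        config = Configuration(coords, template.labels)
        if max_angle > 0 or max_translation > 0 or tuple(scale_range) != (1.0, 1.0):
            params = random_rigid(
                seed=rng.integers(2**31),
                max_angle=max_angle,
                max_translation=max_translation,
                scale_range=scale_range,
                dim=template.dim,
            )
            config = apply_rigid(config, params)
        out.append(config)
    return out


def random_rigid(
    seed: int = 0,
    max_angle: float = np.pi,
    max_translation: float = 0.0,
    scale_range=(1.0, 1.0),
    dim: int = 3,
) -> TransformParams:
    """Seeded random similarity transform within the given bounds."""
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-max_angle, max_angle)
    if dim == 2:
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
    else:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        Kx = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(angle) * Kx + (1 - np.cos(angle)) * (Kx @ Kx)
    t = rng.uniform(-max_translation, max_translation, size=dim)
    s = rng.uniform(*scale_range)
    return TransformParams(R, t, float(s))


def pinocchio_pair(
    n_landmarks: int = 1000,
    seed: int = 0,
    magnitude_mm: float = 30.0,
    max_angle: float = 0.5,
    max_translation: float = 20.0,
    noise_sigma: float = 0.0,
):
    """The canonical toy experiment: honest face, lying face, ground truth.

    The nose tip grows forward (+z) by ``magnitude_mm`` (30 mm by default),
    and the deformed face additionally receives a random rigid transform.
    Returns (honest, lying, bilateral map, region labels, truth transform).
    """
    honest, bmap, regions = make_template(n_landmarks, seed)
    lying = inject_deformation(
        honest, regions["nose_tip"], direction=(0.0, 0.0, 1.0), magnitude_mm=magnitude_mm
    )
    if noise_sigma > 0:
        lying = add_awgn(lying, noise_sigma, seed=seed + 1)
    truth = random_rigid(
        seed=seed + 2, max_angle=max_angle, max_translation=max_translation
    )
    lying = apply_rigid(lying, truth)
    return honest, lying, bmap, regions, truth
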