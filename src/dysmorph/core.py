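"""Domain types for dysmorphometric analysis.

A biological form is an ordered configuration of labelled landmarks (mm).
Comparisons between forms are only meaningful between configurations whose
label sequences agree exactly: the j-th landmark of each configuration is
assumed to be the same anatomical point (positional homology by label).
Permuted label lists are refused rather than silently re-sorted, because a
permutation almost always indicates a data handling error upstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Configuration",
    "ResidualField",
    "TransformParams",
    "PDM",
    "InlierModel",
    "SuperimpositionResult",
    "Dysmorphogram",
    "BilateralMap",
    "validate_pair",
    "gauss_prefactor",
    "CorrespondenceError",
    "InvalidTransformError",
    "DegenerateGeometryError",
    "BreakdownError",
    "NoReflectionError",
    "LandmarkParseError",
]


class CorrespondenceError(ValueError):
    """Two configurations do not share landmark homology (labels/dim/K)."""


class InvalidTransformError(ValueError):
    """A transformation parameterization violates its constraints."""


class DegenerateGeometryError(ValueError):
    """Landmark geometry too degenerate (rank-deficient) to fit a transform."""


class BreakdownError(RuntimeError):
    """Effective inlier mass fell below the breakdown guard of an estimator."""


class NoReflectionError(RuntimeError):
    """A composed map expected to contain a reflection has none."""


class LandmarkParseError(ValueError):
    """A landmark file could not be parsed."""


def gauss_prefactor(sigma: float) -> float:
    """Normalization prefactor 1/(sqrt(2*pi)*sigma) of the inlier density.

    The inlier density is defined on the residual magnitude with this
    prefactor, and the same prefactor enters the outlier level lambda.  The
    self-consistency makes the inlier belief depend only on the Mahalanobis
    ratio ``|d|/sigma`` and on kappa, so the choice of normalization constant
    cancels out of the flagging decision.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return 1.0 / (math.sqrt(2.0 * math.pi) * sigma)


@dataclass(frozen=True)
class Configuration:
    """One biological form: an ordered K x dim matrix of labelled landmarks (mm)."""

    coords: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise ValueError(f"coords must be K x 2 or K x 3, got shape {coords.shape}")
        if coords.shape[0] < 1:
            raise ValueError("a configuration needs at least one landmark")
        if not np.all(np.isfinite(coords)):
            raise ValueError("all landmark coordinates must be finite")
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != coords.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {coords.shape[0]} landmarks"
            )
        if len(set(labels)) != len(labels):
            seen = set()
            dup = next(l for l in labels if l in seen or seen.add(l))
            raise ValueError(f"duplicate landmark label {dup!r}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", labels)

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def centered(self) -> "Configuration":
        return self.with_coords(self.coords - self.centroid)

    def centroid_size(self) -> float:
        """Euclidean norm of the centered configuration (the usual size gauge)."""
        c = self.coords - self.centroid
        return float(np.sqrt((c**2).sum()))

    def vec(self) -> np.ndarray:
        """Row-major flattening to a length K*dim vector."""
        return self.coords.ravel()

    def with_coords(self, coords: np.ndarray) -> "Configuration":
        return Configuration(coords=np.asarray(coords, dtype=float), labels=self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown landmark label {label!r}") from None


@dataclass(frozen=True)
class ResidualField:
    """Per-landmark residual displacement vectors d_j after superimposition."""

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.ndim != 2:
            raise ValueError("residual vectors must be K x dim")
        object.__setattr__(self, "vectors", v)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


@dataclass(frozen=True)
class TransformParams:
    """Similarity transform x -> s*R*x + t, optionally extended with PDM loadings."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0
    pdm_coeffs: Optional[np.ndarray] = None

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        d = t.shape[0]
        if R.shape != (d, d):
            raise InvalidTransformError(
                f"rotation {R.shape} incompatible with translation dim {d}"
            )
        if not np.allclose(R @ R.T, np.eye(d), atol=1e-8):
            raise InvalidTransformError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise InvalidTransformError("rotation matrix is a reflection (det=-1)")
        if self.scale <= 0:
            raise InvalidTransformError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if self.pdm_coeffs is not None:
            object.__setattr__(
                self, "pdm_coeffs", np.asarray(self.pdm_coeffs, dtype=float)
            )

    @property
    def dim(self) -> int:
        return self.translation.shape[0]

    @classmethod
    def identity(cls, dim: int = 3, pdm_coeffs=None) -> "TransformParams":
        return cls(np.eye(dim), np.zeros(dim), 1.0, pdm_coeffs=pdm_coeffs)


@dataclass(frozen=True)
class PDM:
    """Point distribution model: consensus + orthonormal modes of variation.

    ``modes`` is a D x (K*dim) matrix of orthonormal row vectors, ``mode_sd``
    the per-mode standard deviations (square roots of the PCA eigenvalues).
    New configurations in the population are generated as
    consensus + sum_k modes[k] * c_k.
    """

    consensus: Configuration
    modes: np.ndarray
    mode_sd: np.ndarray
    variance_fraction: float = 0.98

    def __post_init__(self):
        U = np.atleast_2d(np.asarray(self.modes, dtype=float))
        sd = np.atleast_1d(np.asarray(self.mode_sd, dtype=float))
        p = self.consensus.n_landmarks * self.consensus.dim
        if U.shape[1] != p:
            raise ValueError(f"modes have length {U.shape[1]}, expected {p}")
        if U.shape[0] != sd.shape[0]:
            raise ValueError("one standard deviation per mode required")
        if np.any(sd <= 0):
            raise ValueError("mode standard deviations must be positive")
        if np.any(np.diff(sd) > 1e-12):
            raise ValueError("mode standard deviations must be nonincreasing")
        if not np.allclose(U @ U.T, np.eye(U.shape[0]), atol=1e-8):
            raise ValueError("modes must be mutually orthonormal")
        object.__setattr__(self, "modes", U)
        object.__setattr__(self, "mode_sd", sd)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def labels(self) -> tuple[str, ...]:
        return self.consensus.labels

    @property
    def dim(self) -> int:
        return self.consensus.dim


@dataclass(frozen=True)
class InlierModel:
    """AWGN inlier distribution plus the uniform outlier level.

    sigma is the scale of the residual magnitude (mm); kappa the Mahalanobis
    threshold beyond which a displacement is deemed atypical.  lam is derived
    from (sigma, kappa) with the same Gaussian prefactor as the inlier
    density, so that the inlier belief is exactly 0.5 at |d| = kappa*sigma.
    """

    sigma: float
    kappa: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")

    @property
    def lam(self) -> float:
        return gauss_prefactor(self.sigma) * math.exp(-0.5 * self.kappa**2)


@dataclass(frozen=True)
class SuperimpositionResult:
    """Output of the extended Procrustes EM superimposition."""

    params: TransformParams
    sigma_hat: float
    beliefs: np.ndarray
    residuals: ResidualField
    objective_trace: tuple[float, ...]
    converged: bool
    n_iter: int
    labels: tuple[str, ...]

    def __post_init__(self):
        b = np.asarray(self.beliefs, dtype=float)
        if np.any(b < -1e-12) or np.any(b > 1 + 1e-12):
            raise ValueError("beliefs must lie in [0, 1]")
        object.__setattr__(self, "beliefs", np.clip(b, 0.0, 1.0))
        object.__setattr__(self, "objective_trace", tuple(self.objective_trace))

    @property
    def dim(self) -> int:
        return self.residuals.vectors.shape[1]

    @property
    def sigma_per_coord(self) -> float:
        """Per-coordinate AWGN standard deviation, sigma_hat / sqrt(dim).

        sigma_hat lives on the residual-magnitude scale; under isotropic
        per-coordinate noise sigma_c the expected squared magnitude is
        dim * sigma_c**2.
        """
        return self.sigma_hat / math.sqrt(self.dim)

    @property
    def flagged(self) -> np.ndarray:
        """Convenience binary view: landmarks whose outlier belief exceeds 0.5."""
        return self.beliefs < 0.5


@dataclass(frozen=True)
class Dysmorphogram:
    """Per-landmark abnormality map: outlier score 1-b_j plus residual size."""

    scores: np.ndarray
    magnitudes: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        m = np.asarray(self.magnitudes, dtype=float)
        labels = tuple(str(l) for l in self.labels)
        if not (s.shape == m.shape == (len(labels),)):
            raise ValueError("scores, magnitudes and labels must have equal length")
        if np.any(s < -1e-12) or np.any(s > 1 + 1e-12):
            raise ValueError("scores must lie in [0, 1]")
        if np.any(m < 0):
            raise ValueError("residual magnitudes must be nonnegative")
        object.__setattr__(self, "scores", np.clip(s, 0.0, 1.0))
        object.__setattr__(self, "magnitudes", m)
        object.__setattr__(self, "labels", labels)

    @property
    def flagged(self) -> np.ndarray:
        return self.scores > 0.5

    def flagged_labels(self) -> tuple[str, ...]:
        return tuple(l for l, f in zip(self.labels, self.flagged) if f)


@dataclass(frozen=True)
class BilateralMap:
    """Left/right landmark pairing plus self-paired midline landmarks."""

    pairs: tuple[tuple[str, str], ...]
    midline: tuple[str, ...] = ()

    def __post_init__(self):
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        midline = tuple(str(m) for m in self.midline)
        seen: set[str] = set()
        for lab in [x for p in pairs for x in p] + list(midline):
            if lab in seen:
                raise ValueError(f"label {lab!r} appears more than once in bilateral map")
            seen.add(lab)
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "midline", midline)

    def partner(self, label: str) -> str:
        for a, b in self.pairs:
            if label == a:
                return b
            if label == b:
                return a
        if label in self.midline:
            return label
        raise KeyError(f"label {label!r} not covered by bilateral map")

    def covers(self, labels: Sequence[str]) -> bool:
        covered = {x for p in self.pairs for x in p} | set(self.midline)
        return all(l in covered for l in labels)

    def permutation(self, labels: Sequence[str]) -> np.ndarray:
        """Index array p with p[j] = index of the mirror homologue of landmark j."""
        index = {l: i for i, l in enumerate(labels)}
        perm = np.empty(len(labels), dtype=int)
        for j, lab in enumerate(labels):
            mate = self.partner(lab)
            if mate not in index:
                raise KeyError(
                    f"mirror homologue {mate!r} of {lab!r} missing from configuration"
                )
            perm[j] = index[mate]
        return perm


def validate_pair(a: Configuration, b: Configuration) -> None:
    """Check that two configurations are landmark-homologous.

    Raises :class:`CorrespondenceError` naming the first offending label when
    the configurations differ in dimension, landmark count, or label order.
    """
    if a.dim != b.dim:
        raise CorrespondenceError(f"dimension mismatch: {a.dim} vs {b.dim}")
    if a.n_landmarks != b.n_landmarks:
        raise CorrespondenceError(
            f"landmark count mismatch: {a.n_landmarks} vs {b.n_landmarks}"
        )
    if a.labels != b.labels:
        for j, (la, lb) in enumerate(zip(a.labels, b.labels)):
            if la != lb:
                raise CorrespondenceError(
                    f"label mismatch at position {j}: {la!r} vs {lb!r}"
                    " (landmark order defines homology; refusing to re-sort)"
                )
        raise CorrespondenceError("label sequences differ")
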