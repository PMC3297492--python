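"""The three dysmorphometric assessment protocols.

Each protocol is a thin orchestration over the EM superimposition engine and
emits a dysmorphogram: the per-landmark outlier score 1 - b_j in [0, 1]
together with the residual magnitudes in mm.  Scores are kept soft — the
0.5 threshold exists only as a convenience view — and no multiple-testing
correction is applied across landmarks: kappa encodes the per-landmark
significance level directly.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    PDM,
    BilateralMap,
    Configuration,
    Dysmorphogram,
    SuperimpositionResult,
    validate_pair,
)
from .extp_em import extp_fit
from .transforms import apply_pdm, extract_symmetry_plane, mirror

__all__ = ["assess_change", "assess_asymmetry", "assess_discordancy"]


def _dysmorphogram(result: SuperimpositionResult) -> Dysmorphogram:
    return Dysmorphogram(
        scores=1.0 - result.beliefs,
        magnitudes=result.residuals.magnitudes,
        labels=result.labels,
    )


def assess_change(
    pre: Configuration,
    post: Configuration,
    kappa: float = 2.0,
    allow_scale: bool = False,
    **fit_kwargs,
) -> tuple[Dysmorphogram, SuperimpositionResult]:
    """Abrupt-change assessment: where did the form change between states?

    The earlier state is the norm; the later state is robustly superimposed
    onto it so that unchanged regions align and changed regions surface as
    outliers.  Scale is off by default: both states are the same subject and
    absolute millimetres are meaningful.
    """
    validate_pair(pre, post)
    result = extp_fit(post, pre, kappa=kappa, allow_scale=allow_scale, **fit_kwargs)
    return _dysmorphogram(result), result


def assess_asymmetry(
    config: Configuration,
    bmap: BilateralMap,
    kappa: float = 2.0,
    plane_normal=(1.0, 0.0, 0.0),
    **fit_kwargs,
) -> tuple[Dysmorphogram, tuple[np.ndarray, np.ndarray], SuperimpositionResult]:
    """Asymmetry assessment: which regions break bilateral symmetry?

    The configuration itself is the norm; its mirror (reflected and
    relabelled to restore homology) is robustly superimposed onto it.
    Asymmetric regions disagree with their mirror image and are flagged;
    scores are reported per original landmark so the map paints directly
    onto the subject.  As a by-product the subject's midsagittal plane is
    extracted from the fitted improper map — the initial ``plane_normal``
    need not be anatomically correct, the robust fit straightens it out.

    Returns (dysmorphogram, (plane_point, plane_normal), fit result).
    """
    mirrored = mirror(config, bmap, plane_normal)
    result = extp_fit(mirrored, config, kappa=kappa, allow_scale=False, **fit_kwargs)
    plane = extract_symmetry_plane(
        np.asarray(plane_normal, dtype=float)[: config.dim],
        result.params,
        plane_point=config.centroid,
    )
    return _dysmorphogram(result), plane, result


def assess_discordancy(
    config: Configuration,
    pdm: PDM,
    kappa: float = 2.0,
    allow_scale: bool = False,
    coeff_bound: float = 3.0,
    **fit_kwargs,
) -> tuple[Dysmorphogram, Configuration, SuperimpositionResult]:
    """Discordancy assessment: where does a form leave its population's range?

    The population PDM is the norm.  Its modes become part of the
    transformation model, so typical within-population variation is
    compensated exactly like pose: the fitted PDM instance is the
    norm-equivalent — the harmonious counterpart of the assessed
    configuration — and landmarks that still disagree with it beyond the
    estimated noise level are flagged as discordant.

    Returns (dysmorphogram, norm_equivalent, fit result).  A warning is
    emitted when any fitted mode loading exceeds ``coeff_bound`` standard
    deviations (the norm-equivalent left the plausible range).
    """
    result = extp_fit(
        config, pdm, kappa=kappa, allow_scale=allow_scale, **fit_kwargs
    )
    c = result.params.pdm_coeffs
    z = np.abs(c) / pdm.mode_sd
    if np.any(z > coeff_bound):
        k = int(np.argmax(z))
        warnings.warn(
            f"PDM loading {k} at {z[k]:.2f} standard deviations exceeds the "
            f"plausibility bound {coeff_bound}; norm-equivalent may be extrapolating"
        )
    norm_equivalent = apply_pdm(pdm, result.params)
    return _dysmorphogram(result), norm_equivalent, result
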