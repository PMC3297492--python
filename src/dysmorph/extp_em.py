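"""Extended Procrustes ML-estimation: joint superimposition and outlier
flagging by Expectation-Maximization.

The residual field is modelled as a two-component mixture.  A latent
indicator per landmark selects between an AWGN inlier process, whose density
on the residual magnitude is Pr_i(d) = 1/(sqrt(2 pi) sigma) *
exp(-|d|^2 / (2 sigma^2)), and a uniform outlier process of level delta.
Collapsing the Bernoulli prior and delta into a single level lambda, and
re-parameterizing lambda = 1/(sqrt(2 pi) sigma) * exp(-kappa^2 / 2) ties the
outlier decision to a Mahalanobis threshold: the posterior inlier belief

    b_j = Pr_i(d_j) / (Pr_i(d_j) + lambda) = expit((kappa^2 - |d_j|^2/sigma^2)/2)

crosses 0.5 exactly at |d_j| = kappa * sigma, for every sigma.  kappa thus
encodes a per-landmark significance level while sigma adapts to the data.

The E-step evaluates the beliefs; the M-step maximizes the expected complete
log-likelihood, which for the transformation is a belief-weighted LSS fit
and for sigma the belief-weighted second moment of the residual magnitudes.
Because lambda is refreshed from the updated sigma each E-step, the surrogate
objective is monotone only up to that refresh; convergence is declared on
relative objective change.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import expit

from .core import (
    PDM,
    BreakdownError,
    Configuration,
    InlierModel,
    ResidualField,
    SuperimpositionResult,
    TransformParams,
    gauss_prefactor,
    validate_pair,
)
from .procrustes import lss_fit, weighted_lss_fit
from .transforms import apply_pdm, apply_rigid

__all__ = [
    "lambda_from_kappa",
    "inlier_belief",
    "e_step",
    "q_objective",
    "m_step",
    "extp_fit",
]

SIGMA_FLOOR = 1e-6  # mm; prevents degenerate collapse on noiseless data


def lambda_from_kappa(sigma: float, kappa: float) -> float:
    """Uniform outlier level lambda = 1/(sqrt(2 pi) sigma) * exp(-kappa^2/2).

    Shares the Gaussian prefactor of the inlier density, so the belief
    boundary sits at Mahalanobis distance kappa regardless of sigma.
    """
    if sigma <= 0 or kappa <= 0:
        raise ValueError("sigma and kappa must be positive")
    return gauss_prefactor(sigma) * math.exp(-0.5 * kappa**2)


def inlier_belief(res_norm, model: InlierModel):
    """Posterior probability that a residual of the given magnitude is an inlier.

    Strictly decreasing in the residual magnitude; equals 0.5 exactly at
    kappa * sigma.
    """
    r = np.asarray(res_norm, dtype=float)
    md2 = (r / model.sigma) ** 2
    b = expit(0.5 * (model.kappa**2 - md2))
    return float(b) if np.isscalar(res_norm) else b


def e_step(residuals: ResidualField, model: InlierModel) -> np.ndarray:
    """Element-wise inlier beliefs over the residual magnitudes."""
    return inlier_belief(residuals.magnitudes, model)


def q_objective(
    residuals: ResidualField, beliefs, model: InlierModel
) -> float:
    """Negative Q-function sum_j rho(d_j) of the augmented superimposition.

    rho(d_j) = b_j |d_j|^2 / (2 sigma^2) + b_j log(sqrt(2 pi) sigma)
               - (1 - b_j) log(lambda).
    With all beliefs one this is the classical single-sigma Procrustes NLL;
    a fully outlying landmark contributes only the constant -log(lambda).
    """
    b = np.asarray(beliefs, dtype=float)
    r2 = (residuals.vectors**2).sum(axis=1)
    log_norm = -math.log(gauss_prefactor(model.sigma))
    log_lam = math.log(model.lam)
    return float(np.sum(b * r2 / (2.0 * model.sigma**2) + b * log_norm - (1.0 - b) * log_lam))


def _pdm_coefficient_update(
    pdm: PDM,
    observed: Configuration,
    rigid: TransformParams,
    beliefs: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Solve the belief-weighted, Gibbs-regularized linear system for c.

    Minimizes sum_j b_j |s R (cons_j + sum_k U_kj c_k) + t - obs_j|^2/(2 s^2igma)
    + 0.5 sum_k c_k^2 / alpha_k^2, which is quadratic in c.
    """
    K, d = observed.coords.shape
    B = pdm.modes.reshape(pdm.n_modes, K, d)
    RB = rigid.scale * np.einsum("dkj,ij->dki", B, rigid.rotation)
    r0 = (
        rigid.scale * pdm.consensus.coords @ rigid.rotation.T
        + rigid.translation
        - observed.coords
    )
    wRB = RB * beliefs[None, :, None]
    G = np.einsum("dki,eki->de", wRB, RB)
    g = np.einsum("dki,ki->d", wRB, r0)
    s2 = sigma**2
    A = G / s2 + np.diag(1.0 / pdm.mode_sd**2)
    return np.linalg.solve(A, -g / s2)


def m_step(
    norm,
    observed: Configuration,
    beliefs,
    allow_scale: bool = False,
    prev: TransformParams | None = None,
    sigma: float | None = None,
    dim_factor: float = 1.0,
    breakdown: float = 0.25,
    pdm_inner: int = 3,
) -> tuple[TransformParams, float]:
    """Maximize the Q-function over transformation parameters and sigma.

    Single-configuration norm: a belief-weighted LSS fit of the observed
    configuration onto the norm, then sigma^2 = sum b|d|^2 / (dim_factor *
    sum b).  PDM norm: a short alternation between the weighted rigid update
    of the current model instance and the regularized linear solve for the
    mode loadings.

    Raises :class:`BreakdownError` when the mean belief falls below the
    ``breakdown`` guard — too few effective inliers remain for a meaningful
    superimposition.
    """
    b = np.asarray(beliefs, dtype=float)
    mass = float(b.mean())
    if mass < breakdown:
        raise BreakdownError(
            f"effective inlier mass {mass:.3f} below breakdown guard {breakdown}"
        )
    if isinstance(norm, PDM):
        if sigma is None:
            raise ValueError("PDM M-step needs the current sigma estimate")
        c = (
            prev.pdm_coeffs
            if prev is not None and prev.pdm_coeffs is not None
            else np.zeros(norm.n_modes)
        )
        rigid = None
        for _ in range(max(1, pdm_inner)):
            inst = apply_pdm(norm, TransformParams.identity(norm.dim, pdm_coeffs=c))
            rigid = weighted_lss_fit(inst, observed, b, allow_scale)
            c = _pdm_coefficient_update(norm, observed, rigid, b, sigma)
        params = TransformParams(
            rigid.rotation, rigid.translation, rigid.scale, pdm_coeffs=c
        )
        res = apply_pdm(norm, params).coords - observed.coords
    else:
        params = weighted_lss_fit(observed, norm, b, allow_scale)
        res = apply_rigid(observed, params).coords - norm.coords
    r2 = (res**2).sum(axis=1)
    sigma_hat = math.sqrt(float((b * r2).sum() / (dim_factor * b.sum())))
    return params, max(sigma_hat, SIGMA_FLOOR)


def _residuals(
    norm, observed: Configuration, params: TransformParams
) -> ResidualField:
    if isinstance(norm, PDM):
        vec = apply_pdm(norm, params).coords - observed.coords
    else:
        vec = apply_rigid(observed, params).coords - norm.coords
    return ResidualField(vec)


def extp_fit(
    observed: Configuration,
    norm,
    kappa: float = 2.0,
    allow_scale: bool = False,
    tol: float = 1e-9,
    max_iter: int = 200,
    dim_factor: float = 1.0,
    breakdown: float = 0.25,
    pdm_inner: int = 3,
) -> SuperimpositionResult:
    """Superimpose ``observed`` onto a norm while flagging outliers, by EM.

    ``norm`` is either a single reference :class:`Configuration` (the
    observed configuration is transformed onto it) or a :class:`PDM`
    population norm (the PDM instance is deformed and transformed onto the
    observed configuration; the fitted instance is the norm-equivalent).

    Initialization is the unweighted LSS fit (PDM loadings start at zero),
    all beliefs one, and sigma from the classical residual moment.  Each
    iteration refreshes lambda from the current sigma, takes one E-step and
    one M-step, and records the negative Q objective; the loop stops when the
    relative objective change drops below ``tol``.

    ``dim_factor`` rescales the sigma update (1 keeps sigma on the
    residual-magnitude scale, the package default; ``dim`` would put it on
    the per-coordinate scale).  Use :attr:`SuperimpositionResult.sigma_per_coord`
    for the per-coordinate noise estimate.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if isinstance(norm, PDM):
        validate_pair(norm.consensus, observed)
        rigid0 = lss_fit(norm.consensus, observed, allow_scale)
        params = TransformParams(
            rigid0.rotation,
            rigid0.translation,
            rigid0.scale,
            pdm_coeffs=np.zeros(norm.n_modes),
        )
    else:
        validate_pair(observed, norm)
        params = lss_fit(observed, norm, allow_scale)
    res = _residuals(norm, observed, params)
    K = observed.n_landmarks
    sigma = max(
        math.sqrt(float((res.magnitudes**2).sum() / (dim_factor * K))), SIGMA_FLOOR
    )
    trace: list[float] = []
    prev_obj = None
    converged = False
    beliefs = np.ones(K)
    for _ in range(max_iter):
        model = InlierModel(sigma, kappa)
        beliefs = e_step(res, model)
        params, sigma = m_step(
            norm,
            observed,
            beliefs,
            allow_scale=allow_scale,
            prev=params,
            sigma=sigma,
            dim_factor=dim_factor,
            breakdown=breakdown,
            pdm_inner=pdm_inner,
        )
        res = _residuals(norm, observed, params)
        obj = q_objective(res, beliefs, InlierModel(sigma, kappa))
        trace.append(obj)
        if prev_obj is not None and abs(obj - prev_obj) <= tol * (1.0 + abs(prev_obj)):
            converged = True
            break
        prev_obj = obj
    beliefs = e_step(res, InlierModel(sigma, kappa))
    return SuperimpositionResult(
        params=params,
        sigma_hat=sigma,
        beliefs=beliefs,
        residuals=res,
        objective_trace=tuple(trace),
        converged=converged,
        n_iter=len(trace),
        labels=observed.labels,
    )
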