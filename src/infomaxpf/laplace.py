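"""MAP estimation and Laplace (Gaussian) posterior approximation.

The posterior mode is found by a trust-region Newton method with the
analytic gradient and Hessian.  The box constraint on the lapse parameters
u ∈ [log 0.001, 0] is handled by optimizing an unconstrained scaled-logistic
reparameterization ξ with u = lo + (hi − lo)·σ(ξ), so the optimizer never
leaves the prior support and u stays strictly interior.  For the lapse-free
model the objective is concave and the optimum is global.

The Gaussian approximation is N(θ̂, C) with C = −H⁻¹ the inverse Hessian of
the log posterior at the mode.  For information-gain computations only the
weight block is used: the *partial* covariance C_ww = −(∂²logP/∂w²)⁻¹.
Both are repaired to the nearest symmetric PSD matrix (eigenvalue clipping)
when numerical asymmetry or indefiniteness creeps in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .model import (
    Dataset,
    ModelParams,
    ParamLayout,
    PriorSpec,
    log_posterior,
    log_posterior_grad_hess,
)

__all__ = [
    "GaussianPosterior",
    "MAPConvergenceError",
    "map_estimate",
    "laplace_posterior",
    "nearest_psd",
]

_XI_CLIP = 30.0  # keeps u strictly inside the box in floating point


class MAPConvergenceError(RuntimeError):
    """Raised when the MAP optimizer fails to converge; carries the best
    iterate found so far in ``best_params``."""

    def __init__(self, message: str, best_params: ModelParams):
        super().__init__(message)
        self.best_params = best_params


def nearest_psd(mat: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Frobenius-nearest symmetric PSD matrix (eigenvalue clipping at 0).

    Symmetrizes the input, then zeroes any negative eigenvalues.  A matrix
    that is already PSD (min eigenvalue ≥ −tol) is returned symmetrized but
    otherwise unchanged.
    """
    mat = np.asarray(mat, dtype=float)
    sym = 0.5 * (mat + mat.T)
    eigval, eigvec = np.linalg.eigh(sym)
    if eigval.min() >= -tol:
        return sym
    return (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T


def _u_to_xi(u: np.ndarray, prior: PriorSpec) -> np.ndarray:
    lo, hi = prior.lapse_lower, prior.lapse_upper
    frac = np.clip((u - lo) / (hi - lo), 1e-12, 1 - 1e-12)
    return np.clip(logit(frac), -_XI_CLIP, _XI_CLIP)


def _xi_to_u(xi: np.ndarray, prior: PriorSpec) -> np.ndarray:
    lo, hi = prior.lapse_lower, prior.lapse_upper
    return lo + (hi - lo) * expit(np.clip(xi, -_XI_CLIP, _XI_CLIP))


def map_estimate(
    data: Dataset,
    prior: PriorSpec,
    layout: ParamLayout,
    init: ModelParams | None = None,
    gtol: float = 1e-8,
    max_iter: int = 500,
) -> ModelParams:
    """Maximum a posteriori estimate of θ given the accumulated data.

    ``init`` warm-starts the optimizer (typically the previous trial's
    estimate in a closed-loop experiment); by default the prior mode (zero
    weights, lapse parameters at an interior default) is used.
    """
    if init is None:
        init = layout.default_params()
    nw, nu = layout.n_weights, layout.n_lapse
    z0 = layout.pack(init).copy()
    if nu:
        z0[nw:] = _u_to_xi(z0[nw:], prior)

    def split(z):
        vec = z.copy()
        if nu:
            vec[nw:] = _xi_to_u(z[nw:], prior)
        return layout.unpack(vec)

    def neg_lp(z):
        return -log_posterior(split(z), data, prior)

    def neg_grad_hess(z):
        params = split(z)
        g, h = log_posterior_grad_hess(params, data, prior)
        if nu:
            lo, hi = prior.lapse_lower, prior.lapse_upper
            sig = expit(np.clip(z[nw:], -_XI_CLIP, _XI_CLIP))
            du = (hi - lo) * sig * (1 - sig)
            d2u = du * (1 - 2 * sig)
            jac = np.ones_like(z)
            jac[nw:] = du
            h = h * jac[:, None] * jac[None, :]
            h[nw:, nw:] += np.diag(g[nw:] * d2u)
            g = g * jac
        return -g, -h

    res = minimize(
        neg_lp,
        z0,
        method="trust-exact",
        jac=lambda z: neg_grad_hess(z)[0],
        hess=lambda z: neg_grad_hess(z)[1],
        options={"gtol": gtol, "maxiter": max_iter},
    )
    z = res.x
    gnorm = float(np.linalg.norm(neg_grad_hess(z)[0]))
    # polish with damped Newton steps if the trust-region stop left the
    # gradient above target (rare near-flat directions)
    polish = 0
    while gnorm > 1e-6 and polish < 25:
        g, h = neg_grad_hess(z)
        try:
            step = np.linalg.solve(h + 1e-10 * np.eye(h.shape[0]), g)
        except np.linalg.LinAlgError:
            break
        f0 = neg_lp(z)
        scale = 1.0
        while scale > 1e-6 and neg_lp(z - scale * step) > f0:
            scale *= 0.5
        if scale <= 1e-6:
            break
        z = z - scale * step
        gnorm = float(np.linalg.norm(neg_grad_hess(z)[0]))
        polish += 1
    best = split(z)
    if gnorm > 1e-4:
        raise MAPConvergenceError(
            f"MAP optimization did not converge after {max_iter} iterations "
            f"(gradient norm {gnorm:.2e})",
            best_params=best,
        )
    return best


@dataclass(frozen=True)
class GaussianPosterior:
    """Laplace approximation N(θ̂, C) with the weight-block partial
    covariance C_ww kept separately for infomax computations."""

    mode: ModelParams
    cov: np.ndarray
    cov_ww: np.ndarray
    log_det_cov: float

    @property
    def layout(self) -> ParamLayout:
        return self.mode.layout

    def entropy_weights(self) -> float:
        """½ log|C_ww| — posterior entropy of the weights, additive
        constant dropped."""
        sign, logdet = np.linalg.slogdet(self.cov_ww)
        return 0.5 * logdet


def laplace_posterior(
    data: Dataset,
    prior: PriorSpec,
    mode: ModelParams,
    grad_tol: float = 1e-4,
) -> GaussianPosterior:
    """Gaussian posterior approximation at a stationary point ``mode``.

    C = −H⁻¹ with H the log-posterior Hessian at the mode; C_ww inverts the
    weight block of H only (partial covariance).  Both are repaired to the
    nearest PSD matrix when needed.
    """
    layout = mode.layout
    grad, hess = log_posterior_grad_hess(mode, data, prior)
    nw = layout.n_weights
    wnorm = float(np.linalg.norm(grad[:nw]))
    if wnorm > grad_tol:
        warnings.warn(
            f"laplace_posterior called at a point with weight-gradient norm "
            f"{wnorm:.2e} > {grad_tol:g}; the mode may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    neg_h = -hess
    hww = neg_h[:nw, :nw]
    try:
        cov_ww = np.linalg.inv(hww)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular weight-block Hessian; consider a stronger (smaller "
            "weight_sd) prior"
        ) from exc
    cov_ww = nearest_psd(cov_ww)
    if layout.n_lapse:
        try:
            cov = np.linalg.inv(neg_h)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular log-posterior Hessian (flat lapse direction?); "
                "consider a stronger prior or more data"
            ) from exc
        cov = nearest_psd(cov)
    else:
        cov = cov_ww
    sign, logdet = np.linalg.slogdet(cov)
    return GaussianPosterior(
        mode=mode, cov=cov, cov_ww=cov_ww, log_det_cov=float(logdet)
    )
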