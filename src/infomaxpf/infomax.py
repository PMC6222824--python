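"""Expected-information-gain computation and stimulus selection.

Two engines score every candidate stimulus by the conditional mutual
information between the upcoming response and the model parameters:

* the **Laplace engine** works with the Gaussian posterior over the weights
  (partial information I(w; y|x), using the weight-block covariance C_ww).
  The one-step posterior-covariance update for a hypothetical trial is a
  rank-(k−1) correction in the space of the linear predictors v = Jw, so
  the expected log-determinant reduces to a (k−1)-dimensional integral over
  v, evaluated by tensorized Gauss–Hermite quadrature;

* the **MCMC engine** evaluates the response-entropy form of the mutual
  information directly from posterior samples via the potential matrix
  L_jm = p(y_j = 1 | x, θ_m):

      I = −(1/M) Σ_{j,m} L_jm log( L_jm / ((1/M) Σ_m' L_jm') ).

A brute-force oracle integrates the mutual information on a dense parameter
grid (≤ 3 free parameters) and serves as ground truth for both engines on
small problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .laplace import GaussianPosterior
from .mcmc import SampleSet
from .model import ParamLayout

__all__ = [
    "UtilityTable",
    "potential_matrix",
    "mi_mcmc",
    "mi_laplace",
    "covariance_update",
    "mi_oracle",
    "select_stimulus",
    "laplace_utilities",
    "mcmc_utilities",
]


@dataclass(frozen=True)
class UtilityTable:
    """Per-candidate expected information gain (nats) and its argmax."""

    utilities: np.ndarray
    argmax: int
    engine: str  # laplace | mcmc | oracle

    def __post_init__(self):
        u = np.asarray(self.utilities, dtype=float)
        object.__setattr__(self, "utilities", u)


# ---------------------------------------------------------------------------
# sample-based engine
# ---------------------------------------------------------------------------

def sample_choice_probs(
    layout: ParamLayout, samples: np.ndarray, features: np.ndarray
) -> np.ndarray:
    """Choice probabilities p(y|x, θ_m) for every sample and stimulus.

    Parameters
    ----------
    samples : (M, n_free) array of free parameter vectors.
    features : (n, m) feature matrix.

    Returns
    -------
    (M, n, k) array of probabilities.
    """
    samples = np.atleast_2d(samples)
    n_samp = samples.shape[0]
    k, m = layout.n_categories, layout.n_features
    w_free = samples[:, : layout.n_weights].reshape(n_samp, k - 1, m)
    v_free = np.einsum("nf,Mjf->Mnj", features, w_free)
    v = np.zeros((n_samp, features.shape[0], k))
    v[:, :, layout.free_categories] = v_free
    v -= v.max(axis=2, keepdims=True)
    q = np.exp(v)
    q /= q.sum(axis=2, keepdims=True)
    if layout.n_lapse == 0:
        return q
    u = samples[:, layout.n_weights:]
    if layout.lapse_mode == "uniform":
        u = np.repeat(u, k, axis=1)
    e = np.exp(u)  # (M, k)
    s = 1.0 + e.sum(axis=1)  # (M,)
    return (q + e[:, None, :]) / s[:, None, None]


def potential_matrix(samples: SampleSet, features_row: np.ndarray) -> np.ndarray:
    """Potential matrix L (k × M) with L_jm = p(y_j = 1 | x, θ_m)."""
    probs = sample_choice_probs(
        samples.layout, samples.samples, np.atleast_2d(features_row)
    )  # (M, 1, k)
    return probs[:, 0, :].T


def _mi_from_probs(probs: np.ndarray) -> np.ndarray:
    """MI for probability stacks of shape (..., M, k), in nats."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(probs > 0, probs * np.log(probs), 0.0)
    cond_entropy = -plogp.sum(axis=-1).mean(axis=-1)
    marg = probs.mean(axis=-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        mlogm = np.where(marg > 0, marg * np.log(marg), 0.0)
    marg_entropy = -mlogm.sum(axis=-1)
    return marg_entropy - cond_entropy


def mi_mcmc(samples: SampleSet, features_row: np.ndarray) -> float:
    """Mutual information I(θ; y|x) in nats from posterior samples."""
    if samples.n_samples == 0:
        raise ValueError("empty sample set")
    probs = sample_choice_probs(
        samples.layout, samples.samples, np.atleast_2d(features_row)
    )[:, 0, :]  # (M, k)
    return float(_mi_from_probs(probs))


def mcmc_utilities(samples: SampleSet, features: np.ndarray) -> UtilityTable:
    """Sample-based expected information gain for every candidate stimulus."""
    probs = sample_choice_probs(samples.layout, samples.samples, features)
    util = _mi_from_probs(np.moveaxis(probs, 0, 1))  # (n,)
    return UtilityTable(
        utilities=util, argmax=int(np.argmax(util)), engine="mcmc"
    )


# ---------------------------------------------------------------------------
# Laplace engine
# ---------------------------------------------------------------------------

def _gh_nodes(order: int, dim: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensorized probabilists' Gauss–Hermite nodes/weights for N(0, I_dim)."""
    if order < 1:
        raise ValueError("quadrature order must be >= 1")
    x, w = hermegauss(order)
    w = w / np.sqrt(2 * np.pi)
    grids = np.meshgrid(*([x] * dim), indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=-1)
    wgrids = np.meshgrid(*([w] * dim), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=-1), axis=-1)
    return nodes, weights


def _predictor_moments(
    posterior: GaussianPosterior, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the free linear predictors v = Jw for each
    candidate, under the weight-block Gaussian posterior."""
    layout = posterior.layout
    k, m = layout.n_categories, layout.n_features
    w_hat = posterior.mode.weights[layout.free_categories]  # (k-1, m)
    mu = features @ w_hat.T  # (n, k-1)
    cb = posterior.cov_ww.reshape(k - 1, m, k - 1, m)
    sigma = np.einsum("nf,jflg,ng->njl", features, cb, features)  # (n, k-1, k-1)
    return mu, sigma


def _softmax_with_ref(v_free: np.ndarray, layout: ParamLayout) -> np.ndarray:
    """Softmax over all k categories given free-category predictors."""
    shape = v_free.shape[:-1]
    k = layout.n_categories
    v = np.zeros(shape + (k,))
    v[..., layout.free_categories] = v_free
    v -= v.max(axis=-1, keepdims=True)
    q = np.exp(v)
    q /= q.sum(axis=-1, keepdims=True)
    return q


def _predictor_curvature(
    q: np.ndarray, layout: ParamLayout, mode_params
) -> np.ndarray:
    """Likelihood information matrix Λ(v) in predictor space.

    Lapse-free model: the observed information −∂²log p(y|v)/∂v² is
    independent of y and equals diag(q̃) − q̃ q̃ᵀ over the free categories.
    With lapses, the expected (Fisher) information of the mixture
    p = (1−λ)q + λc is used, with λ, c fixed at the posterior mode:
    Λ = (1−λ)² Σ_y (q_y²/p_y) (δ_y − q̃)(δ_y − q̃)ᵀ.
    """
    free = layout.free_categories
    q_free = q[..., free]
    if mode_params.u is None:
        return (
            np.einsum("...j,jl->...jl", q_free, np.eye(len(free)))
            - q_free[..., :, None] * q_free[..., None, :]
        )
    from .model import lapse_summary

    lam, c = lapse_summary(mode_params.u_full())
    p = (1 - lam) * q + lam * c[..., :]
    k = layout.n_categories
    eye_free = np.eye(k)[:, free]  # (k, k-1): δ_y restricted to free categories
    diff = eye_free.reshape((1,) * (q.ndim - 1) + eye_free.shape) - q_free[
        ..., None, :
    ]
    wgt = (1 - lam) ** 2 * q ** 2 / p  # (..., k)
    return np.einsum("...y,...yj,...yl->...jl", wgt, diff, diff)


def mi_laplace(
    posterior: GaussianPosterior,
    features_row: np.ndarray,
    quadrature_order: int = 7,
) -> float:
    """Expected information gain (nats) about the weights for one stimulus."""
    table = laplace_utilities(
        posterior, np.atleast_2d(features_row), quadrature_order
    )
    return float(table.utilities[0])


def laplace_utilities(
    posterior: GaussianPosterior,
    features: np.ndarray,
    quadrature_order: int = 7,
) -> UtilityTable:
    """Laplace-engine expected information gain for every candidate.

    For each candidate the utility is ½ E_v[ log|I + Λ(v) Σ_v| ] where
    Σ_v = J C_ww Jᵀ is the posterior covariance of the linear predictors
    and Λ(v) the likelihood information; this equals
    ½(log|C_ww| − E log|C̃_ww|), the expected entropy reduction of the
    weight posterior, so its argmax solves the expected-log-determinant
    minimization.  The expectation over v is a Gauss–Hermite quadrature.
    """
    layout = posterior.layout
    dim = layout.n_categories - 1
    mu, sigma = _predictor_moments(posterior, features)  # (n,d), (n,d,d)
    nodes, weights = _gh_nodes(quadrature_order, dim)  # (Q,d), (Q,)
    jitter = 1e-12 * np.eye(dim)
    try:
        chol = np.linalg.cholesky(sigma + jitter)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(sigma + 1e-9 * np.eye(dim))
    v = mu[:, None, :] + np.einsum("Qd,ned->nQe", nodes, chol)  # (n,Q,d)
    q = _softmax_with_ref(v, layout)  # (n,Q,k)
    lam_mat = _predictor_curvature(q, layout, posterior.mode)  # (n,Q,d,d)
    mat = np.eye(dim) + lam_mat @ sigma[:, None, :, :]
    sign, logdet = np.linalg.slogdet(mat)
    util = 0.5 * (weights[None, :] * logdet).sum(axis=1)
    return UtilityTable(
        utilities=util, argmax=int(np.argmax(util)), engine="laplace"
    )


def covariance_update(
    posterior: GaussianPosterior,
    features_row: np.ndarray,
    y: np.ndarray | int | None = None,
) -> np.ndarray:
    """One-step weight-covariance update C̃ for a hypothetical trial at x.

    C̃⁻¹ = C⁻¹ + Jᵀ Λ J with J the map from weights to the k−1 free linear
    predictors (J[j] = φ on block j) and Λ the likelihood curvature in
    predictor space at the current mode.  Evaluated without inverting C via
    the Woodbury identity; the correction is PSD, so C̃ ⪯ C.

    For the lapse-free model Λ does not depend on the hypothetical response
    ``y``; with lapses the observed information of the given response is
    used (``y`` may be a one-hot vector or a category index; None averages
    over responses via the Fisher information).
    """
    layout = posterior.layout
    phi = np.asarray(features_row, dtype=float).ravel()
    k, m = layout.n_categories, layout.n_features
    dim = k - 1
    v_free = (posterior.mode.weights[layout.free_categories] @ phi)[None, :]
    q = _softmax_with_ref(v_free, layout)[0]  # (k,)
    if posterior.mode.u is None or y is None:
        lam_mat = _predictor_curvature(q[None, :], layout, posterior.mode)[0]
    else:
        lam_mat = _observed_curvature(q, layout, posterior.mode, y)
    c = posterior.cov_ww
    cb = c.reshape(dim, m, dim, m)
    cjt = np.einsum("jflg,g->jfl", cb, phi).reshape(dim * m, dim)  # C Jᵀ
    sigma_v = np.einsum("f,jflg,g->jl", phi, cb, phi)  # J C Jᵀ, (d, d)
    b = np.eye(dim) + lam_mat @ sigma_v
    correction = cjt @ np.linalg.solve(b, lam_mat @ cjt.T)
    return c - correction


def _observed_curvature(q, layout, mode_params, y) -> np.ndarray:
    """−∂² log p(y|v)/∂v² at the mode for a specific hypothetical response,
    for the lapse-mixture likelihood (restricted to free categories)."""
    from .model import lapse_summary

    k = layout.n_categories
    free = layout.free_categories
    if np.ndim(y) > 0:
        y = int(np.argmax(y))
    u = mode_params.u_full()
    e = np.exp(u)
    q_y = q[y]
    t_y = q_y + e[y]
    delta = np.eye(k)[y]
    d = q_y * (delta - q)  # (k,)
    dd = (
        d[:, None] * delta[None, :]
        - d[:, None] * q[None, :]
        - (q_y * q[None, :]) * (np.eye(k) - q[:, None])
    )
    h_vv = dd / t_y - np.outer(d, d) / t_y ** 2
    return -h_vv[np.ix_(free, free)]


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def mi_oracle(log_density, response_probs, grid_axes) -> float:
    """Brute-force mutual information on a dense parameter grid.

    Parameters
    ----------
    log_density : callable
        Unnormalized log posterior density, called with an (n_pts, d) array
        of parameter points; returns (n_pts,) log densities.
    response_probs : callable
        Response distribution p(y|x, θ) at the stimulus of interest, called
        with the same (n_pts, d) array; returns (n_pts, k).
    grid_axes : sequence of 1-D arrays
        Per-parameter integration grids; at most 3 dimensions.
    """
    grid_axes = [np.asarray(a, dtype=float) for a in grid_axes]
    if len(grid_axes) > 3:
        raise ValueError("mi_oracle supports at most 3 free parameters")
    mesh = np.meshgrid(*grid_axes, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    logd = np.asarray(log_density(pts), dtype=float)
    logd = logd - logd.max()
    w = np.exp(logd)
    w /= w.sum()
    probs = np.asarray(response_probs(pts), dtype=float)  # (n_pts, k)
    marg = w @ probs  # (k,)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(probs > 0, np.log(probs) - np.log(marg)[None, :], 0.0)
    return float((w[:, None] * probs * ratio).sum())


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def select_stimulus(
    utilities: UtilityTable | np.ndarray,
    rng: np.random.Generator | int | None = None,
    tie_tol: float = 1e-12,
) -> int:
    """Index of the maximal utility; exact ties broken uniformly at random."""
    util = (
        utilities.utilities
        if isinstance(utilities, UtilityTable)
        else np.asarray(utilities, dtype=float)
    )
    if util.size == 0:
        raise ValueError("empty utility table")
    top = util.max()
    ties = np.nonzero(util >= top - tie_tol)[0]
    if ties.size == 1:
        return int(ties[0])
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    return int(rng.choice(ties))
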