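"""Multinomial-logistic psychometric observer model with a lapse mixture.

The observer sees a stimulus x, embedded as a feature vector φ(x), and picks
one of k response categories (omission trials, if present, are simply an
extra category).  On a non-lapse trial the choice follows a multinomial
logistic (MNL) model with per-category weight vectors w_i,

    q_i = exp(w_i·φ) / Σ_j exp(w_j·φ),

with one weight vector (the reference category) fixed to zero for
identifiability.  With probability λ the observer lapses and responds from a
stimulus-independent distribution c.  The per-category lapse probabilities
are parameterized through auxiliary parameters u_i,

    λ c_i = exp(u_i) / (1 + Σ_j exp(u_j)),

so that p_i = (1 − λ) q_i + λ c_i.  Writing e_i = exp(u_i) and
S = 1 + Σ_j e_j, the mixture collapses to the convenient form

    p_i = (q_i + e_i) / S,

which is what the analytic gradient and Hessian below are derived from.

The prior is an independent zero-mean Gaussian N(0, σ²I) over the free
weights and a flat (box) prior over each u_i on [log 0.001, 0]; the upper
bound caps each per-option lapse probability at 1/(k+1), the lower bound
reflects that lapse rates below ~1/N are not resolvable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "PriorSpec",
    "ParamLayout",
    "ModelParams",
    "ChoiceDistribution",
    "Dataset",
    "choice_probabilities",
    "lapse_summary",
    "log_likelihood",
    "log_posterior",
    "log_posterior_grad_hess",
    "uniform_lapse_u",
]

LAPSE_LOWER = math.log(0.001)
LAPSE_UPPER = 0.0


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior over weights, box prior over lapse parameters."""

    weight_sd: float = 3.0
    lapse_lower: float = LAPSE_LOWER
    lapse_upper: float = LAPSE_UPPER

    def __post_init__(self):
        if self.weight_sd <= 0:
            raise ValueError("weight_sd must be positive")
        if not self.lapse_lower < self.lapse_upper <= 0.0:
            raise ValueError("need lapse_lower < lapse_upper <= 0")


@dataclass(frozen=True)
class ParamLayout:
    """Packing of the free parameters into a flat vector.

    Order: free weight rows (all categories except the reference, each of
    length ``n_features``, C-order), then the free lapse parameters
    (``n_categories`` entries in 'full' mode, one in 'uniform' mode, none
    when lapse is disabled).
    """

    n_categories: int
    n_features: int
    lapse_mode: str = "none"  # none | uniform | full
    ref_category: int = -1

    def __post_init__(self):
        if self.lapse_mode not in ("none", "uniform", "full"):
            raise ValueError(f"unknown lapse_mode {self.lapse_mode!r}")
        if self.n_categories < 2:
            raise ValueError("need at least 2 response categories")
        ref = self.ref_category % self.n_categories
        object.__setattr__(self, "ref_category", ref)

    @property
    def free_categories(self) -> np.ndarray:
        return np.array(
            [i for i in range(self.n_categories) if i != self.ref_category]
        )

    @property
    def n_weights(self) -> int:
        return (self.n_categories - 1) * self.n_features

    @property
    def n_lapse(self) -> int:
        return {"none": 0, "uniform": 1, "full": self.n_categories}[self.lapse_mode]

    @property
    def n_free(self) -> int:
        return self.n_weights + self.n_lapse

    def pack(self, params: "ModelParams") -> np.ndarray:
        w = params.weights[self.free_categories].ravel()
        if self.n_lapse == 0:
            return w
        return np.concatenate([w, np.atleast_1d(params.u)])

    def unpack(self, vec: np.ndarray) -> "ModelParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.n_free,):
            raise ValueError(
                f"expected free vector of length {self.n_free}, got {vec.shape}"
            )
        weights = np.zeros((self.n_categories, self.n_features))
        weights[self.free_categories] = vec[: self.n_weights].reshape(
            self.n_categories - 1, self.n_features
        )
        u = vec[self.n_weights:].copy() if self.n_lapse else None
        return ModelParams(
            weights=weights, u=u, lapse_mode=self.lapse_mode,
            ref_category=self.ref_category,
        )

    def default_params(self, interior_u: float = math.log(0.01)) -> "ModelParams":
        """Zero weights; lapse parameters at an interior default of the box."""
        u = None if self.n_lapse == 0 else np.full(self.n_lapse, interior_u)
        return ModelParams(
            weights=np.zeros((self.n_categories, self.n_features)),
            u=u, lapse_mode=self.lapse_mode, ref_category=self.ref_category,
        )


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector θ = [w; u] of the observer model.

    ``weights`` has shape (k, m) with the reference row identically zero;
    ``u`` is None (lapse disabled, λ = 0 exactly), a length-1 array (uniform
    lapse, c_i = 1/k) or a length-k array (full per-option lapse).
    """

    weights: np.ndarray
    u: np.ndarray | None = None
    lapse_mode: str = "none"
    ref_category: int = -1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("weights must be a (k, m) array")
        object.__setattr__(self, "weights", w)
        k = w.shape[0]
        ref = self.ref_category % k
        object.__setattr__(self, "ref_category", ref)
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite weight values")
        if np.any(w[ref] != 0.0):
            raise ValueError("reference-category weights must be zero")
        if self.lapse_mode == "none":
            if self.u is not None:
                raise ValueError("u must be None when lapse is disabled")
        else:
            u = np.atleast_1d(np.asarray(self.u, dtype=float))
            expected = 1 if self.lapse_mode == "uniform" else k
            if u.shape != (expected,):
                raise ValueError(
                    f"u must have length {expected} in {self.lapse_mode!r} mode"
                )
            if not np.all(np.isfinite(u)):
                raise ValueError("non-finite lapse parameters")
            object.__setattr__(self, "u", u)

    @property
    def n_categories(self) -> int:
        return self.weights.shape[0]

    @property
    def n_features(self) -> int:
        return self.weights.shape[1]

    @property
    def layout(self) -> ParamLayout:
        return ParamLayout(
            n_categories=self.n_categories, n_features=self.n_features,
            lapse_mode=self.lapse_mode, ref_category=self.ref_category,
        )

    def u_full(self) -> np.ndarray | None:
        """Per-category lapse parameters, broadcasting the uniform mode."""
        if self.lapse_mode == "none":
            return None
        if self.lapse_mode == "uniform":
            return np.full(self.n_categories, self.u[0])
        return self.u

    def with_weights(self, weights: np.ndarray) -> "ModelParams":
        return replace(self, weights=np.asarray(weights, dtype=float))


@dataclass(frozen=True)
class ChoiceDistribution:
    """Choice probabilities p = (1−λ)q + λc and their mixture pieces."""

    probs: np.ndarray
    lapse_free_probs: np.ndarray
    total_lapse: float
    lapse_conditional: np.ndarray
    log_probs: np.ndarray = field(repr=False, default=None)


@dataclass(frozen=True)
class Dataset:
    """Accumulated trial data: feature matrix and 0-based response indices."""

    phi: np.ndarray  # (t, m)
    y: np.ndarray  # (t,) int, in [0, k)

    def __post_init__(self):
        phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        y = np.atleast_1d(np.asarray(self.y, dtype=int))
        if phi.shape[0] != y.shape[0]:
            raise ValueError("phi and y must have matching first dimension")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "y", y)

    @property
    def n_trials(self) -> int:
        return self.y.shape[0]

    def one_hot(self, k: int) -> np.ndarray:
        out = np.zeros((self.n_trials, k))
        out[np.arange(self.n_trials), self.y] = 1.0
        return out

    def append(self, phi_row: np.ndarray, y: int) -> "Dataset":
        return Dataset(
            phi=np.vstack([self.phi, np.atleast_2d(phi_row)]),
            y=np.append(self.y, int(y)),
        )

    @staticmethod
    def empty(n_features: int) -> "Dataset":
        return Dataset(
            phi=np.empty((0, n_features)), y=np.empty((0,), dtype=int)
        )


def uniform_lapse_u(total_lapse: float, k: int) -> float:
    """Invert λ(u) for the uniform-lapse model: u with c_i = 1/k at given λ."""
    if not 0 < total_lapse < k / (k + 1):
        raise ValueError(f"total_lapse must lie in (0, {k/(k+1):.3f})")
    return math.log(total_lapse / (k * (1.0 - total_lapse)))


def _logits(params: ModelParams, phi: np.ndarray) -> np.ndarray:
    """Linear predictors w_i·φ for all categories, (n, k)."""
    phi = np.atleast_2d(np.asarray(phi, dtype=float))
    if phi.shape[1] != params.n_features:
        raise ValueError(
            f"feature dimension mismatch: got {phi.shape[1]}, "
            f"model has {params.n_features}"
        )
    if not np.all(np.isfinite(phi)):
        raise ValueError("non-finite feature values")
    return phi @ params.weights.T


def _log_probs(params: ModelParams, phi: np.ndarray) -> np.ndarray:
    """Log choice probabilities, (n, k), stable under large |w·φ|."""
    v = _logits(params, phi)
    log_q = v - logsumexp(v, axis=1, keepdims=True)
    u = params.u_full()
    if u is None:
        return log_q
    # p_i = (q_i + e_i) / S with e = exp(u), S = 1 + sum(e)
    log_s = np.log1p(np.exp(u).sum())
    return np.logaddexp(log_q, u[None, :]) - log_s


def lapse_summary(u, k: int | None = None) -> tuple[float, np.ndarray]:
    """Total lapse probability λ and lapse-conditional distribution c.

    ``u`` may be a length-k vector (full mode) or a scalar with ``k`` given
    (uniform mode).  λ = Σ_i e_i / (1 + Σ_j e_j), c_i = e_i / Σ_j e_j.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite lapse parameters")
    if u.shape[0] == 1 and k is not None:
        u = np.full(k, u[0])
    e = np.exp(u)
    se = e.sum()
    lam = se / (1.0 + se)
    c = e / se if se > 0 else np.full(u.shape[0], 1.0 / u.shape[0])
    return float(lam), c


def choice_probabilities(params: ModelParams, phi: np.ndarray) -> ChoiceDistribution:
    """Choice probabilities p, lapse-free q, total lapse λ and conditional c.

    ``phi`` may be a single feature vector (m,) or a batch (n, m); outputs
    follow the input shape.
    """
    single = np.asarray(phi).ndim == 1
    log_p = _log_probs(params, phi)
    p = np.exp(log_p)
    v = _logits(params, phi)
    v = v - v.max(axis=1, keepdims=True)
    q = np.exp(v)
    q /= q.sum(axis=1, keepdims=True)
    u = params.u_full()
    if u is None:
        lam, c = 0.0, np.full(params.n_categories, 1.0 / params.n_categories)
    else:
        lam, c = lapse_summary(u)
    if single:
        p, q, log_p = p[0], q[0], log_p[0]
    return ChoiceDistribution(
        probs=p, lapse_free_probs=q, total_lapse=lam,
        lapse_conditional=c, log_probs=log_p,
    )


def log_likelihood(params: ModelParams, data: Dataset) -> float:
    """Σ_s y_s · log p(x_s, θ).  Returns −inf (not an exception) if some
    observed response has probability exactly zero."""
    if data.n_trials == 0:
        raise ValueError("log_likelihood requires at least one trial")
    log_p = _log_probs(params, data.phi)
    return float(log_p[np.arange(data.n_trials), data.y].sum())


def _log_prior(params: ModelParams, prior: PriorSpec) -> float:
    layout = params.layout
    w = params.weights[layout.free_categories].ravel()
    n_w = w.size
    sd = prior.weight_sd
    lp = -0.5 * n_w * math.log(2 * math.pi * sd * sd) - 0.5 * (w @ w) / (sd * sd)
    if params.u is not None:
        u = np.atleast_1d(params.u)
        if np.any(u < prior.lapse_lower) or np.any(u > prior.lapse_upper):
            return -math.inf
    return lp


def log_posterior(params: ModelParams, data: Dataset, prior: PriorSpec) -> float:
    """Unnormalized log posterior: log prior + log likelihood.

    The flat prior over u contributes 0 inside its box and −inf outside
    (−inf signals rejection to samplers/optimizers, never an exception).
    """
    lp = _log_prior(params, prior)
    if not np.isfinite(lp):
        return -math.inf
    if data.n_trials:
        lp += log_likelihood(params, data)
    return lp


def _per_trial_derivs(params: ModelParams, data: Dataset):
    """Per-trial gradient and Hessian of log p(y|x, θ) in the space of the
    k−1 free linear predictors v and the k per-category lapse parameters u.

    With e = exp(u), S = 1 + Σe, t_i = q_i + e_i and y the observed index:

        ∂ℓ/∂v_l  = q_y (δ_yl − q_l) / t_y
        ∂ℓ/∂u_r  = δ_yr e_r / t_y − e_r / S

    Second derivatives follow by differentiating once more; the lapse-free
    limit (e = 0) recovers the classical MNL curvature −(diag(q) − qqᵀ).
    """
    k = params.n_categories
    t = data.n_trials
    v = _logits(params, data.phi)
    v = v - v.max(axis=1, keepdims=True)
    q = np.exp(v)
    q /= q.sum(axis=1, keepdims=True)  # (t, k)
    u = params.u_full()
    if u is None:
        e = np.zeros(k)
        s = 1.0
    else:
        e = np.exp(u)
        s = 1.0 + e.sum()
    yi = data.y
    rows = np.arange(t)
    q_y = q[rows, yi]  # (t,)
    t_y = q_y + e[yi]  # (t,)
    delta_y = np.zeros((t, k))
    delta_y[rows, yi] = 1.0

    d = q_y[:, None] * (delta_y - q)  # D_l = ∂t_y/∂v_l, (t, k)

    g_v = d / t_y[:, None]  # (t, k) — later restricted to free categories
    g_u = delta_y * (e / t_y[:, None]) - (e / s)[None, :]  # (t, k)

    # H_vv[s,j,l] = (∂D_l/∂v_j)/t_y − D_l D_j / t_y²
    # ∂D_l/∂v_j = D_j δ_yl − D_j q_l − q_y q_l (δ_lj − q_j)
    eye = np.eye(k)
    dd = (
        d[:, :, None] * delta_y[:, None, :]
        - d[:, :, None] * q[:, None, :]
        - (q_y[:, None, None] * q[:, None, :])
        * (eye[None, :, :] - q[:, :, None])
    )  # (t, j, l)
    h_vv = dd / t_y[:, None, None] - (
        d[:, :, None] * d[:, None, :]
    ) / (t_y ** 2)[:, None, None]

    # H_uv[s,r,l] = −D_l e_r δ_yr / t_y²
    h_uv = -(
        (delta_y * e[None, :])[:, :, None] * d[:, None, :]
    ) / (t_y ** 2)[:, None, None]

    # H_uu[s,r,t] = δ_yr δ_rt e_r/t_y − δ_yr δ_yt e_r e_t/t_y²
    #              − δ_rt e_r/S + e_r e_t/S²
    ee = e[:, None] * e[None, :]
    h_uu = (
        np.einsum("sr,rt->srt", delta_y * (e / t_y[:, None]), eye)
        - (delta_y * e[None, :])[:, :, None]
        * (delta_y * e[None, :])[:, None, :]
        / (t_y ** 2)[:, None, None]
        + (-np.diag(e) / s + ee / (s * s))[None, :, :]
    )
    return q, g_v, g_u, h_vv, h_uv, h_uu


def log_posterior_grad_hess(
    params: ModelParams, data: Dataset, prior: PriorSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient and Hessian of the log posterior w.r.t. the free
    parameter vector (see :class:`ParamLayout` for the packing).

    Requires u strictly inside the prior box (the flat prior is not
    differentiable at the boundary).  For the lapse-free model the Hessian
    is negative semidefinite everywhere (log-concave likelihood).
    """
    layout = params.layout
    free = layout.free_categories
    m = layout.n_features
    n_free = layout.n_free
    grad = np.zeros(n_free)
    hess = np.zeros((n_free, n_free))

    # Gaussian prior on free weights
    sd2 = prior.weight_sd ** 2
    w = params.weights[free].ravel()
    grad[: layout.n_weights] = -w / sd2
    hess[: layout.n_weights, : layout.n_weights] = -np.eye(layout.n_weights) / sd2

    if params.u is not None:
        u = np.atleast_1d(params.u)
        if np.any(u <= prior.lapse_lower) or np.any(u >= prior.lapse_upper):
            raise ValueError(
                "lapse parameters must be strictly inside the prior box "
                "for gradient/Hessian evaluation"
            )

    if data.n_trials:
        _, g_v, g_u, h_vv, h_uv, h_uu = _per_trial_derivs(params, data)
        phi = data.phi
        gv = g_v[:, free]  # (t, k-1)
        grad[: layout.n_weights] += (gv.T @ phi).ravel()
        hw = np.einsum("sjl,sa,sb->jalb", h_vv[:, free][:, :, free], phi, phi)
        hess[: layout.n_weights, : layout.n_weights] += hw.reshape(
            layout.n_weights, layout.n_weights
        )
        if layout.n_lapse:
            if layout.lapse_mode == "uniform":
                gu = g_u.sum(axis=1, keepdims=True)  # (t, 1)
                huv = h_uv.sum(axis=1, keepdims=True)  # (t, 1, k)
                huu = h_uu.sum(axis=(1, 2)).reshape(-1, 1, 1)  # (t, 1, 1)
            else:
                gu, huv, huu = g_u, h_uv, h_uu
            nw = layout.n_weights
            grad[nw:] += gu.sum(axis=0)
            cross = np.einsum("srl,sa->rla", huv[:, :, free], phi).reshape(
                layout.n_lapse, nw
            )
            hess[nw:, :nw] += cross
            hess[:nw, nw:] += cross.T
            hess[nw:, nw:] += huu.sum(axis=0)
    return grad, hess
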