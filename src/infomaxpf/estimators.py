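"""Scikit-learn–style estimators for the psychometric observer model.

These wrap the package's Bayesian machinery in the familiar
fit/predict_proba surface so that fitted psychometric models compose with
sklearn pipelines and model selection.  ``X`` rows are (normalized)
stimulus vectors; a constant feature is prepended internally, so each
response category gets one bias plus d sensitivity weights.

``LaplacePsychometricModel`` fits by MAP with a Gaussian (Laplace)
posterior; ``MCMCPsychometricModel`` samples the posterior with the
random-walk Metropolis–Hastings chain and predicts with the
posterior-predictive average.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .infomax import (
    laplace_utilities,
    mcmc_utilities,
    sample_choice_probs,
)
from .laplace import laplace_posterior, map_estimate
from .mcmc import default_proposal, sample_posterior
from .model import Dataset, ParamLayout, PriorSpec, choice_probabilities

__all__ = ["LaplacePsychometricModel", "MCMCPsychometricModel"]


class _BasePsychometricModel(BaseEstimator, ClassifierMixin):
    def __init__(self, lapse_mode="none", weight_sd=3.0, ref_category=-1):
        self.lapse_mode = lapse_mode
        self.weight_sd = weight_sd
        self.ref_category = ref_category

    def _validate_and_prepare(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.shape[0] < 2:
            raise ValueError("need at least 2 response categories in y")
        self.n_features_in_ = X.shape[1]
        self.layout_ = ParamLayout(
            n_categories=self.classes_.shape[0],
            n_features=X.shape[1] + 1,
            lapse_mode=self.lapse_mode,
            ref_category=self.ref_category,
        )
        self.prior_ = PriorSpec(weight_sd=self.weight_sd)
        phi = np.hstack([np.ones((X.shape[0], 1)), X])
        return Dataset(phi=phi, y=y_idx)

    def _features(self, X):
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; expected {self.n_features_in_}"
            )
        return np.hstack([np.ones((X.shape[0], 1)), X])

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class LaplacePsychometricModel(_BasePsychometricModel):
    """MAP fit with a Laplace (Gaussian) posterior approximation.

    Parameters
    ----------
    lapse_mode : {"none", "uniform", "full"}
        Lapse-mixture structure of the fitted model.
    weight_sd : float
        Standard deviation σ of the independent Gaussian prior N(0, σ²I)
        over the free weights.
    ref_category : int
        Which response category's weight vector is fixed to zero.

    Attributes
    ----------
    map_params_ : ModelParams
        The posterior mode.
    posterior_ : GaussianPosterior
        Mode, full covariance and the weight-block partial covariance.
    """

    def fit(self, X, y):
        data = self._validate_and_prepare(X, y)
        self.map_params_ = map_estimate(data, self.prior_, self.layout_)
        self.posterior_ = laplace_posterior(data, self.prior_, self.map_params_)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "posterior_")
        return choice_probabilities(self.map_params_, self._features(X)).probs

    def expected_information_gain(self, X, quadrature_order: int = 7):
        """Per-stimulus expected information gain about the weights (nats)."""
        check_is_fitted(self, "posterior_")
        return laplace_utilities(
            self.posterior_, self._features(X), quadrature_order
        ).utilities


class MCMCPsychometricModel(_BasePsychometricModel):
    """Posterior sampling with random-walk Metropolis–Hastings.

    Parameters
    ----------
    n_samples : int
        Post-burn-in chain length M (default 1,000).
    burn_in : int or None
        Discarded fresh draws; defaults to ``n_samples // 2``.
    random_state : int
        Chain seed; fits are deterministic given the seed.

    Attributes
    ----------
    samples_ : SampleSet
        Posterior samples of the free parameter vector.
    """

    def __init__(
        self,
        lapse_mode="none",
        weight_sd=3.0,
        ref_category=-1,
        n_samples=1000,
        burn_in=None,
        random_state=0,
    ):
        super().__init__(
            lapse_mode=lapse_mode, weight_sd=weight_sd, ref_category=ref_category
        )
        self.n_samples = n_samples
        self.burn_in = burn_in
        self.random_state = random_state

    def fit(self, X, y):
        data = self._validate_and_prepare(X, y)
        self.samples_ = sample_posterior(
            data,
            self.prior_,
            self.layout_,
            proposal_cov=default_proposal(self.layout_.n_free),
            n_samples=self.n_samples,
            burn_in=self.burn_in,
            seed=self.random_state,
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "samples_")
        return sample_choice_probs(
            self.layout_, self.samples_.samples, self._features(X)
        ).mean(axis=0)

    def expected_information_gain(self, X):
        """Per-stimulus mutual information I(θ; y|x) from the samples."""
        check_is_fitted(self, "samples_")
        return mcmc_utilities(self.samples_, self._features(X)).utilities
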