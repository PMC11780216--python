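"""Scikit-learn-style Bayesian regression estimators.

Two estimators carry the package's statistical core:

* :class:`LognormalMixedRegression` — a Bayesian lognormal regression with an
  optional grouping-factor random intercept, fit by blocked Gibbs sampling.
  Used directly for the reef-metric response models and as the positive part
  of the hurdle model.
* :class:`HurdleLognormalRegression` — a two-part (hurdle) model for
  zero-inflated positive responses: a Bernoulli-logit model of the
  probability that the response is zero, and a lognormal mixed model for the
  strictly positive responses.

Both follow the scikit-learn contract: hyperparameters are set in
``__init__`` and introspectable via ``get_params``/``set_params``; ``fit``
validates inputs and stores results in trailing-underscore attributes;
``random_state`` controls all randomness.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin

from . import diagnostics
from ._gibbs import sample_lognormal_mixed, sample_logistic
from .exceptions import ParameterError, SamplerDiagnosticsError

__all__ = ["LognormalMixedRegression", "HurdleLognormalRegression"]


def _check_Xy(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise ValueError("X must be a finite 2-D array")
    if y is not None:
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y length must match X")
        if not np.all(np.isfinite(y)):
            raise ValueError("y must be finite")
    return X, y


def _encode_groups(groups, n):
    if groups is None:
        return None, 0, None
    groups = np.asarray(groups)
    if groups.shape != (n,):
        raise ValueError("groups length must match X")
    labels, idx = np.unique(groups, return_inverse=True)
    return idx, labels.size, labels


class LognormalMixedRegression(BaseEstimator, RegressorMixin):
    """Bayesian lognormal regression with a grouping-factor random intercept.

    The model for a strictly positive response ``y`` is::

        log y = X @ beta (+ intercept) + u[group] + eps
        u ~ Normal(0, tau),  eps ~ Normal(0, sigma)

    with independent ``Normal(0, prior_sd_beta)`` priors on coefficients and
    half-Student-t(``sd_prior_df``, ``sd_prior_scale``) priors on ``sigma``
    and ``tau``.  Sampling is by fully conjugate blocked Gibbs (Huang–Wand
    parameter expansion for the half-t scales).

    Parameters
    ----------
    fit_intercept : bool
        Prepend an intercept column.  Disable when X already encodes
        per-group intercepts (e.g. species dummies).
    prior_sd_beta : float or sequence
        Prior sd of each coefficient (after any intercept is prepended).
    chains, iterations, warmup : int
        MCMC schedule; post-warmup draws are retained from every chain.
    random_state : int or None
        Root seed for all chains.

    Attributes
    ----------
    coef_draws_ : ndarray, shape (chains, draws, p)
    sigma_draws_, tau_draws_ : ndarray, shape (chains, draws)
    u_draws_ : ndarray, shape (chains, draws, n_groups)
    group_labels_ : ndarray or None
    rhat_ : dict of parameter name -> split-R̂
    coef_ : ndarray — posterior-mean coefficients (RegressorMixin surface)
    """

    def __init__(
        self,
        fit_intercept=True,
        prior_sd_beta=2.5,
        sd_prior_df=3.0,
        sd_prior_scale=2.5,
        chains=4,
        iterations=3000,
        warmup=1000,
        random_state=None,
        rhat_warn=1.01,
    ):
        self.fit_intercept = fit_intercept
        self.prior_sd_beta = prior_sd_beta
        self.sd_prior_df = sd_prior_df
        self.sd_prior_scale = sd_prior_scale
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.random_state = random_state
        self.rhat_warn = rhat_warn

    def _validate_schedule(self):
        if self.chains < 2:
            raise ParameterError("chains must be >= 2 for convergence diagnostics")
        if self.iterations <= self.warmup:
            raise ParameterError("iterations must exceed warmup")

    def fit(self, X, y, groups=None):
        self._validate_schedule()
        X, y = _check_Xy(X, y)
        if np.any(y <= 0):
            raise ValueError("lognormal response requires y > 0")
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(y)), X])
        n, p = X.shape
        sds = np.broadcast_to(np.atleast_1d(np.asarray(self.prior_sd_beta, float)), (p,))
        gidx, n_groups, labels = _encode_groups(groups, n)

        out = sample_lognormal_mixed(
            np.log(y),
            X,
            gidx,
            n_groups,
            prior_sd_beta=sds,
            sd_prior_df=self.sd_prior_df,
            sd_prior_scale=self.sd_prior_scale,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=self.random_state,
        )
        self.n_features_in_ = X.shape[1] - (1 if self.fit_intercept else 0)
        self.coef_draws_ = out["beta"]
        self.sigma_draws_ = out["sigma"]
        self.tau_draws_ = out["tau"]
        self.u_draws_ = out["u"]
        self.group_labels_ = labels
        self.group_index_ = gidx
        self.coef_ = out["beta"].mean(axis=(0, 1))
        self.rhat_ = self._compute_rhat()
        bad = {k: v for k, v in self.rhat_.items() if np.isfinite(v) and v > self.rhat_warn}
        if bad:
            warnings.warn(f"split-Rhat above {self.rhat_warn}: {bad}", stacklevel=2)
        return self

    def _compute_rhat(self):
        named = {"sigma": self.sigma_draws_}
        if self.group_labels_ is not None:
            named["tau"] = self.tau_draws_
        for j in range(self.coef_draws_.shape[2]):
            named[f"beta[{j}]"] = self.coef_draws_[:, :, j]
        return {k: diagnostics.split_rhat(v) for k, v in named.items()}

    # -- prediction -------------------------------------------------------

    def _mu_draws(self, X):
        """Linear predictor per draw, flattened over chains: (S, n)."""
        X, _ = _check_Xy(X)
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        S = self.coef_draws_.shape[0] * self.coef_draws_.shape[1]
        beta = self.coef_draws_.reshape(S, -1)
        if X.shape[1] != beta.shape[1]:
            raise ValueError("X has wrong number of features")
        return beta @ X.T

    def predict_draws(self, X, kind="mean", group_effect="integrate"):
        """Posterior draws of the predicted response for new groups.

        ``kind="mean"`` returns the lognormal mean ``exp(mu + 0.5 sigma²
        [+ 0.5 tau²])``; ``kind="median"`` returns ``exp(mu)``.
        ``group_effect="integrate"`` marginalizes the random intercept of an
        unobserved group into the mean (adds ``tau²/2``; only under
        ``kind="mean"``); ``"zero"`` conditions on ``u = 0``.
        """
        if kind not in ("mean", "median"):
            raise ValueError("kind must be 'mean' or 'median'")
        if group_effect not in ("integrate", "zero"):
            raise ValueError("group_effect must be 'integrate' or 'zero'")
        mu = self._mu_draws(X)
        if kind == "median":
            return np.exp(mu)
        sig2 = (self.sigma_draws_.reshape(-1) ** 2)[:, None]
        extra = 0.0
        if group_effect == "integrate" and self.group_labels_ is not None:
            extra = (self.tau_draws_.reshape(-1) ** 2)[:, None]
        return np.exp(mu + 0.5 * (sig2 + extra))

    def predict(self, X, kind="mean", group_effect="integrate"):
        """Posterior-mean prediction of the response."""
        return self.predict_draws(X, kind=kind, group_effect=group_effect).mean(axis=0)

    def log_likelihood_draws(self, X, y, groups=None):
        """Pointwise lognormal log-likelihood per draw: (S, n).

        Conditional on the fitted group intercepts when ``groups`` labels
        match training groups (unseen labels get u = 0).
        """
        X, y = _check_Xy(X, y)
        mu = self._mu_draws(X)
        if groups is not None and self.group_labels_ is not None:
            lookup = {lab: i for i, lab in enumerate(self.group_labels_)}
            u = self.u_draws_.reshape(mu.shape[0], -1)
            for j, lab in enumerate(np.asarray(groups)):
                if lab in lookup:
                    mu[:, j] += u[:, lookup[lab]]
        sig = self.sigma_draws_.reshape(-1)[:, None]
        ly = np.log(y)[None, :]
        return norm.logpdf(ly, loc=mu, scale=sig) - ly


class HurdleLognormalRegression(BaseEstimator):
    """Bayesian hurdle-lognormal regression for zero-inflated positive counts.

    Part 1 (hurdle): ``P(y == 0) = expit(W @ gamma)`` where ``W`` is an
    intercept plus the columns of ``X`` selected by ``hurdle_features``.
    Part 2 (positive): ``log y | y > 0`` follows
    :class:`LognormalMixedRegression` on all columns of ``X`` (no global
    intercept by default — pass explicit intercept/dummy columns, e.g. one
    per species).  The two parts have disjoint parameters and are sampled
    independently.

    Parameters
    ----------
    hurdle_features : sequence of int
        Column indices of ``X`` entering the zero model.
    prior_sd_beta, hurdle_prior_sd_intercept, hurdle_prior_sd_beta : float
        Normal prior scales (positive-part coefficients, hurdle intercept,
        hurdle coefficients).
    min_mh_acceptance : float
        Lower bound on the hurdle sampler's Metropolis acceptance rate;
        below it a :class:`SamplerDiagnosticsError` is raised with a report.
    """

    def __init__(
        self,
        hurdle_features=(0,),
        fit_intercept=False,
        prior_sd_beta=2.5,
        hurdle_prior_sd_intercept=1.5,
        hurdle_prior_sd_beta=2.5,
        sd_prior_df=3.0,
        sd_prior_scale=2.5,
        chains=4,
        iterations=3000,
        warmup=1000,
        random_state=None,
        rhat_warn=1.01,
        min_mh_acceptance=0.05,
    ):
        self.hurdle_features = hurdle_features
        self.fit_intercept = fit_intercept
        self.prior_sd_beta = prior_sd_beta
        self.hurdle_prior_sd_intercept = hurdle_prior_sd_intercept
        self.hurdle_prior_sd_beta = hurdle_prior_sd_beta
        self.sd_prior_df = sd_prior_df
        self.sd_prior_scale = sd_prior_scale
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.random_state = random_state
        self.rhat_warn = rhat_warn
        self.min_mh_acceptance = min_mh_acceptance

    def fit(self, X, y, groups=None):
        X, y = _check_Xy(X, y)
        if np.any(y < 0):
            raise ValueError("counts must be >= 0")
        n = X.shape[0]
        z = (y == 0).astype(float)

        hf = list(self.hurdle_features)
        W = np.column_stack([np.ones(n), X[:, hf]]) if hf else np.ones((n, 1))
        w_sds = np.concatenate(
            [[self.hurdle_prior_sd_intercept], np.full(len(hf), self.hurdle_prior_sd_beta)]
        )
        seed = self.random_state
        gamma, accept = sample_logistic(
            z,
            W,
            prior_sd=w_sds,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            seed=seed,
        )
        if accept.min() < self.min_mh_acceptance:
            raise SamplerDiagnosticsError(
                "hurdle sampler acceptance rate below configured minimum",
                report={
                    "acceptance_rates": accept.tolist(),
                    "min_required": self.min_mh_acceptance,
                },
            )
        self.hurdle_coef_draws_ = gamma
        self.mh_acceptance_ = accept

        pos = y > 0
        self.positive_ = LognormalMixedRegression(
            fit_intercept=self.fit_intercept,
            prior_sd_beta=self.prior_sd_beta,
            sd_prior_df=self.sd_prior_df,
            sd_prior_scale=self.sd_prior_scale,
            chains=self.chains,
            iterations=self.iterations,
            warmup=self.warmup,
            random_state=None if seed is None else seed + 104729,
            rhat_warn=np.inf,  # collected and warned jointly below
        ).fit(X[pos], y[pos], None if groups is None else np.asarray(groups)[pos])

        self.n_features_in_ = X.shape[1]
        self.rhat_ = dict(self.positive_.rhat_)
        for j in range(gamma.shape[2]):
            self.rhat_[f"hurdle_gamma[{j}]"] = diagnostics.split_rhat(gamma[:, :, j])
        bad = {k: round(float(v), 4) for k, v in self.rhat_.items()
               if np.isfinite(v) and v > self.rhat_warn}
        if bad:
            warnings.warn(f"split-Rhat above {self.rhat_warn}: {bad}", stacklevel=2)
        return self

    # -- prediction and likelihood ---------------------------------------

    def predict_zero_prob_draws(self, X):
        """Draws of P(y = 0) for each row: (S, n)."""
        X, _ = _check_Xy(X)
        hf = list(self.hurdle_features)
        W = np.column_stack([np.ones(X.shape[0]), X[:, hf]]) if hf else np.ones((X.shape[0], 1))
        S = self.hurdle_coef_draws_.shape[0] * self.hurdle_coef_draws_.shape[1]
        gamma = self.hurdle_coef_draws_.reshape(S, -1)
        return expit(gamma @ W.T)

    def log_likelihood_draws(self, X, y, groups=None):
        """Pointwise hurdle log-likelihood per draw: (S, n).

        Zeros contribute ``log P(zero)``; positives contribute
        ``log(1 - P(zero))`` plus the lognormal density (conditional on the
        fitted island intercepts).
        """
        X, y = _check_Xy(X, y)
        p0 = self.predict_zero_prob_draws(X)
        S = p0.shape[0]
        ll = np.where(y[None, :] == 0, np.log(p0), np.log1p(-p0))
        pos = y > 0
        if pos.any():
            ll_pos = self.positive_.log_likelihood_draws(
                X[pos], y[pos], None if groups is None else np.asarray(groups)[pos]
            )
            if ll_pos.shape[0] != S:
                raise ValueError("hurdle and positive parts have different draw counts")
            ll[:, pos] += ll_pos
        return ll

    def sample_posterior_predictive(self, X, groups=None, random_state=0):
        """Replicated count datasets, one per posterior draw: (S, n).

        New draws of the island intercept are taken for unseen groups;
        training groups reuse their fitted intercepts.  Positive draws are
        rounded to integers as in the generating process.
        """
        X, _ = _check_Xy(X)
        rng = np.random.default_rng(random_state)
        p0 = self.predict_zero_prob_draws(X)
        S, n = p0.shape
        mu = self.positive_._mu_draws(X)
        if groups is not None and self.positive_.group_labels_ is not None:
            lookup = {lab: i for i, lab in enumerate(self.positive_.group_labels_)}
            u = self.positive_.u_draws_.reshape(S, -1)
            tau = self.positive_.tau_draws_.reshape(S)
            for j, lab in enumerate(np.asarray(groups)):
                if lab in lookup:
                    mu[:, j] += u[:, lookup[lab]]
                else:
                    mu[:, j] += rng.normal(0.0, tau)
        sig = self.positive_.sigma_draws_.reshape(S)[:, None]
        pos_counts = np.round(np.exp(rng.normal(mu, np.broadcast_to(sig, mu.shape))))
        zero = rng.uniform(size=(S, n)) < p0
        return np.where(zero, 0.0, pos_counts)
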