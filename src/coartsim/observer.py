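"""Bayesian observer: intention recognition by probabilistic motor simulation.

The observer entertains one hypothesis per candidate sequential action
(e.g. reach-and-pour vs reach-and-move), each backed by the same motor
repertoire as the performer. Per hypothesis it runs a Gaussian
(Kalman-style) filter over the hand state: the inverse model proposes the
control u_t = mu_h(t) - mu_h(t - dt) (the hypothesis's mean kinematic
increment, coarticulated when the hypothesis coarticulates), the forward
model propagates the belief, and the observation model corrects it with the
noisy percept z_t. The per-frame predictive log-likelihoods accumulate (in
log space, renormalized every step) into the discrete model posterior
p(i_t | z_1:t); the first hypothesis whose posterior strictly exceeds the
decision threshold is the recognized intention and that instant is the
recognition (crossing) time.

With process_noise = 0 and state_var_inflation = 0 the filters have zero
gain and the model posterior reduces exactly to the accumulated Gaussian
likelihood-ratio posterior, which is the closed-form oracle used in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .coarticulation import CoarticulationSpec, GaussianParams
from .config import ConfigurationError, INTENT_TO_DISTAL
from .performer import ObservationSequence, SequenceDefinition, sequence_moments
from .primitives import PrimitiveLibrary

__all__ = [
    "Hypothesis", "PosteriorTrace", "RecognitionResult",
    "DegenerateLikelihoodError", "predict_step", "update_step", "recognize",
    "first_crossing", "IntentionObserver", "default_hypotheses",
]


class DegenerateLikelihoodError(ValueError):
    """Zero observation noise with an observation off the predicted mean."""


@dataclass
class Hypothesis:
    """A candidate sequential action with its prior probability p(i | c_0)."""

    id: str
    sequence: SequenceDefinition
    prior: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.prior <= 1.0:
            raise ValueError(f"prior must be in [0,1], got {self.prior}")


@dataclass
class PosteriorTrace:
    """p(i_t | z_1:t) over time, plus per-hypothesis predictive log-likelihoods."""

    times: np.ndarray
    posterior: np.ndarray          # (T, H), rows sum to 1
    log_likelihoods: np.ndarray    # (T, H) per-frame predictive log-likelihoods
    hypothesis_ids: list[str]

    def column(self, hyp_id: str) -> np.ndarray:
        return self.posterior[:, self.hypothesis_ids.index(hyp_id)]


@dataclass
class RecognitionResult:
    """First threshold crossing: which hypothesis won, and when."""

    winner: str | None
    crossing_time_ms: float | None
    threshold: float


def predict_step(belief: GaussianParams, hyp: Hypothesis, t: float,
                 lib: PrimitiveLibrary, process_noise: float,
                 state_var_inflation: float = 1.0) -> GaussianParams:
    """Inverse/forward model prediction for one hypothesis at time t.

    The control is the hypothesis's mean increment over the last step; the
    predicted variance adds process noise and (scaled) hypothesis execution
    variance.
    """
    if not 0.0 <= t <= lib.timeline.sequence_end_ms:
        raise ValueError(f"t={t:g} ms beyond the timeline")
    dt = lib.dt_ms
    times = np.array([max(t - dt, 0.0), t])
    means, variances = sequence_moments(hyp.sequence, lib, times)
    u = means[1] - means[0]
    var = belief.var + process_noise**2 + state_var_inflation * variances[1]
    return GaussianParams(belief.mean + u, var)


def update_step(pred: GaussianParams, z_t: np.ndarray,
                sigma_obs: float) -> tuple[GaussianParams, float]:
    """Conjugate Gaussian correction; returns the predictive log-likelihood of z_t."""
    z = np.asarray(z_t, float)
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be >= 0")
    r = sigma_obs**2
    if sigma_obs == 0.0:
        if not np.allclose(z, pred.mean, atol=1e-12):
            raise DegenerateLikelihoodError(
                "sigma_obs=0 requires observations equal to the predicted mean")
        return GaussianParams(z, np.zeros_like(pred.var)), 0.0
    s = pred.var + r
    loglik = float(np.sum(-0.5 * (np.log(2.0 * np.pi * s) + (z - pred.mean) ** 2 / s)))
    gain = pred.var / s
    post_mean = pred.mean + gain * (z - pred.mean)
    post_var = pred.var * r / s
    return GaussianParams(post_mean, post_var), loglik


def recognize(obs: ObservationSequence, hyps: Sequence[Hypothesis],
              lib: PrimitiveLibrary, threshold: float = 0.95,
              process_noise: float = 0.02,
              state_var_inflation: float = 1.0,
              ) -> tuple[PosteriorTrace, RecognitionResult]:
    """Run the multi-hypothesis filter over an observation sequence."""
    hyps = list(hyps)
    if len(hyps) < 2:
        raise ValueError("need at least 2 hypotheses")
    if len(obs) == 0:
        raise ValueError("empty observation sequence")
    if not 0.5 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0.5, 1), got {threshold}")
    priors = np.array([h.prior for h in hyps], float)
    if not np.isclose(priors.sum(), 1.0, atol=1e-6):
        raise ValueError(f"hypothesis priors must sum to 1, got {priors.sum():g}")
    priors = priors / priors.sum()

    times = obs.times
    n_t, n_h = times.size, len(hyps)
    # Hypothesis mean/variance profiles on the observation grid.
    moments = [sequence_moments(h.sequence, lib, times) for h in hyps]

    beliefs = [GaussianParams(m[0].copy(), state_var_inflation * v[0])
               for m, v in moments]
    log_post = np.log(priors)
    posterior = np.empty((n_t, n_h))
    loglik_mat = np.empty((n_t, n_h))

    for k in range(n_t):
        lls = np.empty(n_h)
        for h in range(n_h):
            means, variances = moments[h]
            if k == 0:
                pred = beliefs[h]
            else:
                u = means[k] - means[k - 1]
                var = (beliefs[h].var + process_noise**2
                       + state_var_inflation * variances[k])
                pred = GaussianParams(beliefs[h].mean + u, var)
            beliefs[h], lls[h] = update_step(pred, obs.values[k], obs.sigma_obs)
        log_post = log_post + lls
        log_post = log_post - logsumexp(log_post)
        posterior[k] = np.exp(log_post)
        loglik_mat[k] = lls

    trace = PosteriorTrace(times, posterior, loglik_mat, [h.id for h in hyps])
    winner, crossing = None, None
    cross = posterior > threshold
    if cross.any():
        k, h = np.argwhere(cross)[0]
        winner, crossing = hyps[h].id, float(times[k])
    return trace, RecognitionResult(winner, crossing, threshold)


def first_crossing(trace: PosteriorTrace, hyp_id: str,
                   threshold: float) -> float | None:
    """First time a given hypothesis's posterior strictly exceeds threshold."""
    col = trace.column(hyp_id)
    idx = np.nonzero(col > threshold)[0]
    return float(trace.times[idx[0]]) if idx.size else None


def default_hypotheses(lib: PrimitiveLibrary, mode: str = "plain",
                       spec: CoarticulationSpec | None = None,
                       proximal: str = "reach_to_grasp",
                       priors: Sequence[float] | None = None) -> list[Hypothesis]:
    """Pour/move hypothesis pair sharing the performer's repertoire and mode."""
    intents = list(INTENT_TO_DISTAL)
    priors = [1.0 / len(intents)] * len(intents) if priors is None else list(priors)
    out = []
    for intent, prior in zip(intents, priors):
        distal = INTENT_TO_DISTAL[intent]
        hyp_spec = spec
        if mode != "plain" and spec is not None:
            hyp_spec = CoarticulationSpec(
                primary=spec.primary, future=(distal,), weights=dict(spec.weights),
                window_ms=spec.window_ms, dof_channels=spec.dof_channels,
                max_tries=spec.max_tries)
        seq = SequenceDefinition(intent=intent, proximal=proximal, distal=distal,
                                 mode=mode, spec=hyp_spec)
        out.append(Hypothesis(id=intent, sequence=seq, prior=prior))
    return out


class IntentionObserver(BaseEstimator):
    """Scikit-learn style front end to the multi-hypothesis filter.

    Parameters
    ----------
    library : PrimitiveLibrary
        Shared motor repertoire (also the performer's).
    mode : {"plain", "coarticulated"}
        Whether the hypotheses assume coarticulated execution.
    coarticulation : CoarticulationSpec, optional
        Required when mode != "plain".
    threshold : float
        Decision threshold on the model posterior, in (0.5, 1).
    process_noise, state_var_inflation : float
        Forward-model noise parameters (radians; dimensionless scale).
    """

    def __init__(self, library: PrimitiveLibrary | None = None, mode: str = "plain",
                 coarticulation: CoarticulationSpec | None = None,
                 threshold: float = 0.95, process_noise: float = 0.02,
                 state_var_inflation: float = 1.0):
        self.library = library
        self.mode = mode
        self.coarticulation = coarticulation
        self.threshold = threshold
        self.process_noise = process_noise
        self.state_var_inflation = state_var_inflation

    def fit(self, X: Sequence[Hypothesis] | None = None, y=None):
        """Freeze the hypothesis set (default: pour/move with uniform priors)."""
        if self.library is None:
            raise ConfigurationError("IntentionObserver requires a library")
        if X is None:
            self.hypotheses_ = default_hypotheses(
                self.library, mode=self.mode, spec=self.coarticulation)
        else:
            self.hypotheses_ = list(X)
        self.hypothesis_ids_ = [h.id for h in self.hypotheses_]
        return self

    def recognize(self, obs: ObservationSequence
                  ) -> tuple[PosteriorTrace, RecognitionResult]:
        if not hasattr(self, "hypotheses_"):
            raise RuntimeError("IntentionObserver is not fitted")
        return recognize(obs, self.hypotheses_, self.library,
                         threshold=self.threshold,
                         process_noise=self.process_noise,
                         state_var_inflation=self.state_var_inflation)

    def predict_proba(self, obs: ObservationSequence) -> np.ndarray:
        """Posterior p(i_t | z_1:t) over time, shape (T, n_hypotheses)."""
        trace, _ = self.recognize(obs)
        return trace.posterior

    def predict(self, obs: ObservationSequence) -> str | None:
        """Recognized intention (first threshold crosser), or None if undecided."""
        _, result = self.recognize(obs)
        return result.winner
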