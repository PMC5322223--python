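"""Coarticulation and signaling distributions and their rejection samplers.

Coarticulation (assimilation) blends the primitive currently being executed
(index ``i``) with the primitive(s) to be executed next (``j``): samples are
drawn from the primary density and accepted only if they are also good
exemplars of the future primitives, yielding (up to normalization)

    p_coa(x | m_i; w)  ∝  w_i · p(x|m_i) · ∏_{j≠i} w_j · p(x|m_j)

Signaling (dissimilation) is the converse: samples of the primary primitive
are kept preferentially where the future primitives are *unlikely*,

    p_sig(x | m_i; w)  ∝  p(x|m_i) · ∏_{j≠i} (1 − w_j · p(x|m_j)/p_j^max).

The rejection rule draws a candidate from the primary density and, for each
future primitive j, an independent u_j ~ Uniform(0, 1); the candidate is
accepted iff u_j < w_j · p(x|m_j)/p_j^max for every j (coarticulation) or
u_j < 1 − w_j · p(x|m_j)/p_j^max (signaling). For Gaussian channels the
per-channel density supremum p^max is analytic (the density at the mean),
so the acceptance ratio reduces to exp(−(x−μ_j)²/(2σ_j²)).

Only the channels in the spec's ``dof_channels`` mask participate in the
cross-primitive acceptance (the grasping scenario coarticulates index and
thumb, not wrist); since covariances are diagonal, acceptance is resolved
independently per masked channel, which leaves the accepted joint
distribution unchanged while keeping sampling efficient.

A weight w_j = 0 removes the j-th factor entirely (continuous identity
limit) rather than annihilating the density. Note that for w_j in (0, 1]
the *normalized* coarticulated density is invariant in w_j — the linear
weight uniformly thins acceptance without reshaping the accepted law.

``product_gaussian_oracle`` gives the closed-form normalized product of
diagonal Gaussians (precision-weighted) used as the independent test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import ConfigurationError
from .primitives import PrimitiveLibrary

__all__ = [
    "GaussianParams",
    "CoarticulationSpec",
    "RejectionExhaustedError",
    "product_gaussian_oracle",
    "coarticulated_density",
    "sample_coarticulated",
    "sample_signaling",
    "coarticulation_moments",
]


class RejectionExhaustedError(RuntimeError):
    """No sample accepted within max_tries — the primitives barely overlap."""

    def __init__(self, t_ms: float, channels: Sequence[int], max_tries: int):
        self.t_ms = t_ms
        self.channels = list(channels)
        super().__init__(
            f"rejection sampling exhausted {max_tries} tries at t={t_ms:g} ms "
            f"on channels {list(channels)}"
        )


@dataclass
class GaussianParams:
    """Diagonal Gaussian: per-channel mean and variance vectors."""

    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, float))
        self.var = np.atleast_1d(np.asarray(self.var, float))
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and var must have the same shape")
        if np.any(self.var < 0):
            raise ValueError("variances must be non-negative")


@dataclass
class CoarticulationSpec:
    """Which primitive leads, which are blended in, where, and on what channels."""

    primary: str
    future: tuple[str, ...]
    weights: Mapping[str, float]
    window_ms: tuple[float, float]
    dof_channels: np.ndarray
    max_tries: int = 10000
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.future = tuple(self.future)
        self.dof_channels = np.asarray(self.dof_channels, int)
        t0, t1 = self.window_ms
        if not t0 < t1:
            raise ConfigurationError(f"window must satisfy t0 < t1, got {self.window_ms}")
        if self.dof_channels.size == 0:
            raise ConfigurationError("dof_channels must be non-empty")
        for name in (self.primary, *self.future):
            w = float(self.weights.get(name, 1.0))
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError(f"weight for {name!r} must be in [0,1], got {w}")
        if float(self.weights.get(self.primary, 1.0)) <= 0.0:
            raise ConfigurationError("primary primitive weight must be positive")
        if self.max_tries < 1:
            raise ConfigurationError("max_tries must be >= 1")

    def weight(self, name: str) -> float:
        return float(self.weights.get(name, 1.0))

    def active_future(self) -> list[str]:
        """Future primitives whose factor participates (w > 0 convention)."""
        return [j for j in self.future if self.weight(j) > 0.0]

    def in_window(self, t: float) -> bool:
        return self.window_ms[0] <= t < self.window_ms[1]


def product_gaussian_oracle(components: Sequence[GaussianParams]) -> GaussianParams:
    """Normalized product of diagonal Gaussians (closed form, test oracle).

    Precision adds; the mean is the precision-weighted average of means.
    """
    comps = list(components)
    if not comps:
        raise ValueError("need at least one Gaussian component")
    if any(np.any(c.var <= 0) for c in comps):
        raise ValueError("all component variances must be > 0")
    prec = sum(1.0 / c.var for c in comps)
    var = 1.0 / prec
    mean = var * sum(c.mean / c.var for c in comps)
    return GaussianParams(mean=mean, var=var)


def _check_domain(t: float, lib: PrimitiveLibrary) -> None:
    if not 0.0 <= t <= lib.timeline.sequence_end_ms:
        raise ValueError(
            f"t={t:g} ms outside the sequence support "
            f"[0, {lib.timeline.sequence_end_ms:g}]")


def _log_normal_pdf(x, mean, var):
    return -0.5 * (np.log(2.0 * np.pi * var) + (x - mean) ** 2 / var)


def coarticulated_density(x: np.ndarray, t: float, lib: PrimitiveLibrary,
                          spec: CoarticulationSpec) -> float:
    """Unnormalized coarticulated density at x (all channels of the primary;
    cross-primitive factors on the masked channels only)."""
    _check_domain(t, lib)
    x = np.asarray(x, float)
    mi, vi = lib.channel_moments(spec.primary, t)
    logd = np.log(spec.weight(spec.primary)) + np.sum(_log_normal_pdf(x, mi, vi))
    mask = spec.dof_channels
    for j in spec.active_future():
        mj, vj = lib.channel_moments(j, t)
        logd += np.log(spec.weight(j))
        logd += np.sum(_log_normal_pdf(x[mask], mj[mask], vj[mask]))
    return float(np.exp(logd))


def _rejection_sample(t: float, lib: PrimitiveLibrary, spec: CoarticulationSpec,
                      rng: np.random.Generator, max_tries: int | None,
                      signaling: bool) -> np.ndarray:
    _check_domain(t, lib)
    tries_budget = spec.max_tries if max_tries is None else int(max_tries)
    if tries_budget < 1:
        raise ValueError("max_tries must be >= 1")

    mi, vi = lib.channel_moments(spec.primary, t)
    sdi = np.sqrt(vi)
    x = mi + sdi * rng.standard_normal(mi.shape)

    futures = spec.active_future()
    if not futures:
        return x

    fut_moments = [lib.channel_moments(j, t) for j in futures]
    fut_w = [spec.weight(j) for j in futures]

    remaining = spec.dof_channels.copy()
    for _ in range(tries_budget):
        cand = mi[remaining] + sdi[remaining] * rng.standard_normal(remaining.shape)
        ok = np.ones(remaining.shape, bool)
        for (mj, vj), wj in zip(fut_moments, fut_w):
            # Gaussian channel: p(x|m_j)/p_j^max = exp(-(x-mu)^2 / (2 var))
            ratio = wj * np.exp(-0.5 * (cand - mj[remaining]) ** 2 / vj[remaining])
            u = rng.uniform(size=remaining.shape)
            ok &= u < (1.0 - ratio if signaling else ratio)
        x[remaining[ok]] = cand[ok]
        remaining = remaining[~ok]
        if remaining.size == 0:
            return x
    raise RejectionExhaustedError(t, remaining, tries_budget)


def sample_coarticulated(t: float, lib: PrimitiveLibrary, spec: CoarticulationSpec,
                         rng: np.random.Generator,
                         max_tries: int | None = None) -> np.ndarray:
    """One sample from the coarticulated distribution at sequence time t."""
    return _rejection_sample(t, lib, spec, rng, max_tries, signaling=False)


def sample_signaling(t: float, lib: PrimitiveLibrary, spec: CoarticulationSpec,
                     rng: np.random.Generator,
                     max_tries: int | None = None) -> np.ndarray:
    """One sample from the signaling (dissimilation) distribution at time t."""
    return _rejection_sample(t, lib, spec, rng, max_tries, signaling=True)


def coarticulation_moments(t: float, lib: PrimitiveLibrary,
                           spec: CoarticulationSpec) -> GaussianParams:
    """Closed-form moments of the normalized coarticulated Gaussian at time t.

    Masked channels carry the precision-weighted product of the primary and
    all active future primitives; unmasked channels carry the primary alone.
    (The linear weights cancel under normalization and do not appear.)
    """
    _check_domain(t, lib)
    mi, vi = lib.channel_moments(spec.primary, t)
    mean, var = mi.copy(), vi.copy()
    futures = spec.active_future()
    if futures:
        mask = spec.dof_channels
        comps = [GaussianParams(mi[mask], vi[mask])]
        comps += [GaussianParams(*(a[mask] for a in lib.channel_moments(j, t)))
                  for j in futures]
        prod = product_gaussian_oracle(comps)
        mean[mask], var[mask] = prod.mean, prod.var
    return GaussianParams(mean, var)
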