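"""Performer agent: compose sequential actions and emit noisy observations.

A sequential action (reach-and-pour, reach-and-move) assigns the reach
primitive to t ≤ reach_end and the distal primitive to t > reach_end. In
``coarticulated`` mode the masked channels (index + thumb by default) are
drawn, inside the coarticulation window, from the rejection sampler that
blends the reach with the upcoming grasp primitive; ``signaling`` mode uses
the dissimilation sampler instead. Kinematic frames are sampled
independently per time step from the generating distribution, and the
observer's percepts add i.i.d. Gaussian observation noise per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coarticulation import (CoarticulationSpec, GaussianParams,
                             coarticulation_moments, sample_coarticulated,
                             sample_signaling)
from .config import ConfigurationError, INTENT_TO_DISTAL
from .primitives import PrimitiveLibrary, Trajectory

__all__ = ["SequenceDefinition", "ObservationSequence", "compose_sequence",
           "observe", "sequence_moments"]

MODES = ("plain", "coarticulated", "signaling")


@dataclass
class SequenceDefinition:
    """A two-step sequential action: proximal primitive then distal primitive."""

    intent: str
    proximal: str
    distal: str
    mode: str = "plain"
    spec: CoarticulationSpec | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ConfigurationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode != "plain" and self.spec is None:
            raise ConfigurationError(f"mode {self.mode!r} requires a CoarticulationSpec")
        expected = INTENT_TO_DISTAL.get(self.intent)
        if expected is not None and self.distal in INTENT_TO_DISTAL.values() \
                and self.distal != expected:
            raise ConfigurationError(
                f"intent {self.intent!r} inconsistent with distal {self.distal!r}")

    def validate_against(self, lib: PrimitiveLibrary) -> None:
        for name in (self.proximal, self.distal):
            if name not in lib.primitives:
                raise ConfigurationError(f"primitive {name!r} not in library")


@dataclass
class ObservationSequence:
    """Noisy percepts z_t of a trajectory, with the noise level that made them."""

    times: np.ndarray
    values: np.ndarray
    sigma_obs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.values.shape[0] != self.times.size:
            raise ValueError("observation length must match times")
        if self.sigma_obs < 0:
            raise ValueError(f"sigma_obs must be >= 0, got {self.sigma_obs}")

    def __len__(self) -> int:
        return self.times.size


def _frame_moments(seq: SequenceDefinition, lib: PrimitiveLibrary,
                   t: float) -> GaussianParams:
    """Generating distribution of one frame (closed form; used by the observer)."""
    reach_end = lib.timeline.reach_end_ms
    if t > reach_end:
        mean, var = lib.channel_moments(seq.distal, t)
        return GaussianParams(mean, var)
    if seq.mode == "coarticulated" and seq.spec is not None and seq.spec.in_window(t):
        return coarticulation_moments(t, lib, seq.spec)
    mean, var = lib.channel_moments(seq.proximal, t)
    return GaussianParams(mean, var)


def sequence_moments(seq: SequenceDefinition, lib: PrimitiveLibrary,
                     times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame generating mean and variance arrays (T, J) for a sequence.

    For signaling mode the masked in-window channels are non-Gaussian; the
    primary primitive's moments are returned there (the observer models
    signaling trials no better than plain ones, which is the intended
    asymmetry of dissimilation).
    """
    seq.validate_against(lib)
    means, variances = [], []
    for t in times:
        gp = _frame_moments(seq, lib, float(t))
        means.append(gp.mean)
        variances.append(gp.var)
    return np.stack(means), np.stack(variances)


def compose_sequence(seq: SequenceDefinition, lib: PrimitiveLibrary,
                     rng: np.random.Generator) -> Trajectory:
    """Sample one full kinematic trajectory of a sequential action."""
    seq.validate_against(lib)
    times = lib.times()
    reach_end = lib.timeline.reach_end_ms
    frames = np.empty((times.size, lib.n_channels))
    for k, t in enumerate(times):
        t = float(t)
        in_window = (seq.mode != "plain" and seq.spec is not None
                     and seq.spec.in_window(t) and t <= reach_end)
        if in_window:
            sampler = (sample_coarticulated if seq.mode == "coarticulated"
                       else sample_signaling)
            frames[k] = sampler(t, lib, seq.spec, rng)
        else:
            name = seq.proximal if t <= reach_end else seq.distal
            mean, var = lib.channel_moments(name, t)
            frames[k] = mean + np.sqrt(var) * rng.standard_normal(mean.shape)
    return Trajectory(times, frames,
                      meta={"intent": seq.intent, "mode": seq.mode,
                            "proximal": seq.proximal, "distal": seq.distal})


def observe(traj: Trajectory, sigma_obs: float,
            rng: np.random.Generator) -> ObservationSequence:
    """Add i.i.d. Gaussian observation noise per channel: z_t = x_t + eps."""
    if sigma_obs < 0:
        raise ValueError(f"sigma_obs must be >= 0, got {sigma_obs}")
    noise = sigma_obs * rng.standard_normal(traj.values.shape) if sigma_obs > 0 \
        else np.zeros_like(traj.values)
    return ObservationSequence(traj.times, traj.values + noise, sigma_obs,
                               meta=dict(traj.meta))
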