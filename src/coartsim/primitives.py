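"""Motor primitives as time-indexed Gaussian distributions over joint angles.

A motor primitive (reach-to-grasp, grasp-to-pour, grasp-to-move) is modelled
as an independent Gaussian per channel at every instant: a mean trajectory
``mean_fn(t)`` and a diagonal variance ``var_fn(t)``, both over local time
``t`` in ``[0, duration_ms]``. The synthetic library emulates dataglove
recordings of a human hand: 16 flexion channels (radians) grouped into
index, thumb, wrist and other fingers, on a 0-1500 ms timeline with the
reach occupying the first 1000 ms.

Mean profiles are minimum-jerk interpolations between configured start and
end postures; the reach additionally opens the index/thumb channels
mid-movement (a Gaussian "aperture bump"), producing the classic maximum
grip aperture during the reach. Variance profiles are smooth and strictly
positive.

``GaussianTrajectoryRegressor`` recovers such a primitive from trials by
kernel-smoothed per-time-bin Gaussian regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .config import ConfigurationError, default_config

__all__ = [
    "Timeline",
    "MotorPrimitive",
    "Trajectory",
    "PrimitiveLibrary",
    "make_primitive_library",
    "simulate_trials",
    "GaussianTrajectoryRegressor",
    "fit_primitive",
    "make_toy_2d",
]


@dataclass(frozen=True)
class Timeline:
    """Sequence timeline: reach phase is [0, reach_end]; distal phase follows."""

    reach_end_ms: float
    sequence_end_ms: float

    def __post_init__(self):
        if not 0 < self.reach_end_ms < self.sequence_end_ms:
            raise ConfigurationError(
                f"need 0 < reach_end_ms < sequence_end_ms, got "
                f"{self.reach_end_ms}, {self.sequence_end_ms}"
            )


@dataclass
class MotorPrimitive:
    """Time-indexed diagonal-Gaussian distribution over joint-angle controls."""

    name: str
    role: str  # {"proximal", "distal"}
    duration_ms: float
    mean_fn: Callable[[float], np.ndarray]
    var_fn: Callable[[float], np.ndarray]

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ConfigurationError(f"duration_ms must be > 0, got {self.duration_ms}")
        if self.role not in ("proximal", "distal"):
            raise ConfigurationError(f"unknown role {self.role!r}")

    def moments(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Mean and per-channel variance at local time t, clamped to the support.

        Clamping below 0 yields the onset distribution — this is how a distal
        primitive is queried inside the coarticulation window, before its
        nominal start.
        """
        t = float(np.clip(t, 0.0, self.duration_ms))
        return np.asarray(self.mean_fn(t), float), np.asarray(self.var_fn(t), float)


@dataclass
class Trajectory:
    """Realized kinematics on a uniform time grid (T frames x J channels)."""

    times: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[0] != self.times.size:
            raise ValueError("values must be (len(times), J)")
        dt = np.diff(self.times)
        if self.times.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory contains non-finite angles")

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def dt_ms(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0


@dataclass
class PrimitiveLibrary:
    """A keyed set of primitives sharing channel layout and timeline."""

    primitives: dict[str, MotorPrimitive]
    channel_map: dict[str, list[int]]
    dt_ms: float
    timeline: Timeline
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ConfigurationError(f"dt_ms must be > 0, got {self.dt_ms}")

    @property
    def n_channels(self) -> int:
        return int(max(max(v) for v in self.channel_map.values() if v) + 1)

    def times(self) -> np.ndarray:
        """Uniform sequence-time grid covering [0, sequence_end]."""
        n = int(round(self.timeline.sequence_end_ms / self.dt_ms))
        return np.arange(n + 1) * self.dt_ms

    def start_time(self, name: str) -> float:
        """Sequence-time onset of a primitive (0 for proximal, reach end for distal)."""
        prim = self.primitives[name]
        return 0.0 if prim.role == "proximal" else self.timeline.reach_end_ms

    def channel_moments(self, name: str, t: float) -> tuple[np.ndarray, np.ndarray]:
        """Primitive moments at *sequence* time t (clamped to the support)."""
        return self.primitives[name].moments(t - self.start_time(name))

    def group_channels(self, groups: Sequence[str]) -> np.ndarray:
        chans: list[int] = []
        for g in groups:
            chans.extend(self.channel_map.get(g, []))
        return np.asarray(sorted(set(chans)), int)


def _minimum_jerk(tau: np.ndarray | float) -> np.ndarray | float:
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau * tau)


def _expand_posture(posture: Mapping[str, float], channel_map: Mapping[str, list[int]],
                    n_channels: int) -> np.ndarray:
    vec = np.zeros(n_channels)
    for group, chans in channel_map.items():
        if group not in posture:
            raise ConfigurationError(f"posture missing group {group!r}")
        vec[list(chans)] = float(posture[group])
    return vec


def _make_mean_fn(start: np.ndarray, end: np.ndarray, duration: float,
                  bump: np.ndarray | None, bump_center: float,
                  bump_width: float) -> Callable[[float], np.ndarray]:
    def mean_fn(t: float) -> np.ndarray:
        m = start + (end - start) * _minimum_jerk(t / duration)
        if bump is not None:
            m = m - bump * np.exp(-(((t - bump_center) / bump_width) ** 2))
        return m

    return mean_fn


def _make_var_fn(profile: Mapping[str, Any], duration: float,
                 n_channels: int) -> Callable[[float], np.ndarray]:
    kind = profile.get("kind", "sine")
    ones = np.ones(n_channels)
    if kind == "sine":
        base, peak = float(profile["base_sd"]), float(profile["peak_sd"])

        def var_fn(t: float) -> np.ndarray:
            sd = base + (peak - base) * np.sin(np.pi * np.clip(t / duration, 0, 1))
            return ones * sd * sd

    elif kind == "linear":
        s0, s1 = float(profile["start_sd"]), float(profile["end_sd"])

        def var_fn(t: float) -> np.ndarray:
            sd = s0 + (s1 - s0) * np.clip(t / duration, 0, 1)
            return ones * sd * sd

    else:
        raise ConfigurationError(f"unknown variance profile kind {kind!r}")
    return var_fn


def make_primitive_library(config: Mapping[str, Any] | None = None,
                           seed: int = 0) -> PrimitiveLibrary:
    """Build the synthetic three-primitive library from a configuration.

    The construction is deterministic given the configuration; ``seed`` is
    recorded in the library metadata and seeds any optional stochastic
    elements (none in the default configuration).
    """
    cfg = default_config() if config is None else config
    n_channels = int(cfg["channels"])
    dt_ms = float(cfg["dt_ms"])
    if dt_ms <= 0:
        raise ConfigurationError(f"dt_ms must be positive, got {dt_ms}")
    if n_channels < 3:
        raise ConfigurationError(f"need at least 3 channels, got {n_channels}")
    channel_map = {g: list(v) for g, v in cfg["channel_map"].items()}
    timeline = Timeline(float(cfg["timeline"]["reach_end_ms"]),
                        float(cfg["timeline"]["sequence_end_ms"]))

    prims: dict[str, MotorPrimitive] = {}
    for name, pc in cfg["primitives"].items():
        role = pc.get("role", "distal")
        duration = (timeline.reach_end_ms if role == "proximal"
                    else timeline.sequence_end_ms - timeline.reach_end_ms)
        start = _expand_posture(pc["start_posture"], channel_map, n_channels)
        end = _expand_posture(pc["end_posture"], channel_map, n_channels)
        bump_cfg = pc.get("aperture_bump")
        bump = center = width = None
        if bump_cfg is not None:
            bump = np.zeros(n_channels)
            for g in bump_cfg.get("groups", ["index", "thumb"]):
                bump[channel_map[g]] = float(bump_cfg["amplitude"])
            center = float(bump_cfg["center_ms"])
            width = float(bump_cfg["width_ms"])
        prims[name] = MotorPrimitive(
            name=name, role=role, duration_ms=duration,
            mean_fn=_make_mean_fn(start, end, duration, bump,
                                  center or 0.0, width or 1.0),
            var_fn=_make_var_fn(pc["variance_profile"], duration, n_channels),
        )

    distal = [p for p in prims.values() if p.role == "distal"]
    if len(distal) >= 2:
        mask = np.asarray(channel_map["index"] + channel_map["thumb"], int)
        a, b = distal[0], distal[1]
        sep_end = float(np.min(np.abs(
            a.mean_fn(a.duration_ms)[mask] - b.mean_fn(b.duration_ms)[mask])))
        sep_onset = float(np.min(np.abs(a.mean_fn(0.0)[mask] - b.mean_fn(0.0)[mask])))
        if sep_end <= 0 or sep_onset <= 0:
            raise ConfigurationError(
                "distal primitives must be separated on index/thumb channels "
                f"(onset sep {sep_onset:.3g}, endpoint sep {sep_end:.3g})")

    return PrimitiveLibrary(primitives=prims, channel_map=channel_map, dt_ms=dt_ms,
                            timeline=timeline, meta={"seed": int(seed)})


def simulate_trials(primitive: MotorPrimitive, n_trials: int, seed: int,
                    dt_ms: float = 10.0) -> list[Trajectory]:
    """Draw independent trials: each frame ~ Normal(mean_fn(t), var_fn(t)) per channel."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    times = np.arange(int(round(primitive.duration_ms / dt_ms)) + 1) * dt_ms
    means = np.stack([primitive.moments(t)[0] for t in times])
    sds = np.sqrt(np.stack([primitive.moments(t)[1] for t in times]))
    noise = rng.standard_normal((n_trials, *means.shape))
    return [
        Trajectory(times, means + sds * noise[k],
                   meta={"primitive": primitive.name, "seed": int(seed), "trial": k})
        for k in range(n_trials)
    ]


class GaussianTrajectoryRegressor(BaseEstimator):
    """Kernel-smoothed per-time-bin Gaussian trajectory regression.

    Estimates a time-indexed Gaussian (mean and diagonal variance per time
    bin) from repeated trials of a movement, smoothing along time with a
    Gaussian kernel of bandwidth ``smoothing_ms`` (0 = no smoothing).
    Variances are floored at ``var_floor`` so the recovered primitive always
    defines a proper density.

    Attributes (after ``fit``)
    --------------------------
    times_ : (T,) time grid of the trials
    mean_ : (T, J) smoothed per-bin sample means
    var_ : (T, J) smoothed, floored per-bin sample variances
    n_trials_ : number of trials used
    """

    def __init__(self, smoothing_ms: float = 30.0, var_floor: float = 1e-6):
        self.smoothing_ms = smoothing_ms
        self.var_floor = var_floor

    def fit(self, X: Sequence[Trajectory] | np.ndarray, y=None):
        if isinstance(X, np.ndarray):
            stack = np.asarray(X, float)
            if stack.ndim != 3:
                raise ValueError("array input must be (n_trials, T, J)")
            times = np.arange(stack.shape[1], dtype=float)
        else:
            trials = list(X)
            if not trials:
                raise ValueError("need at least one trial")
            shapes = {tr.values.shape for tr in trials}
            if len(shapes) != 1:
                raise ValueError(f"trials have mismatched shapes: {shapes}")
            times = trials[0].times
            stack = np.stack([tr.values for tr in trials])
        if self.var_floor <= 0:
            raise ValueError("var_floor must be > 0")

        mean = stack.mean(axis=0)
        var = stack.var(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
        if self.smoothing_ms > 0:
            d = times[:, None] - times[None, :]
            w = np.exp(-0.5 * (d / self.smoothing_ms) ** 2)
            w /= w.sum(axis=1, keepdims=True)
            mean = w @ mean
            var = w @ var
        self.times_ = times
        self.mean_ = mean
        self.var_ = np.maximum(var, self.var_floor)
        self.n_trials_ = stack.shape[0]
        return self

    def predict(self, t: np.ndarray) -> np.ndarray:
        """Interpolated mean trajectory at times t."""
        t = np.atleast_1d(np.asarray(t, float))
        return np.stack([
            np.interp(t, self.times_, self.mean_[:, j])
            for j in range(self.mean_.shape[1])
        ], axis=1)

    def to_primitive(self, name: str = "fitted", role: str = "proximal") -> MotorPrimitive:
        times, mean, var = self.times_, self.mean_, self.var_

        def mean_fn(t: float) -> np.ndarray:
            return np.array([np.interp(t, times, mean[:, j])
                             for j in range(mean.shape[1])])

        def var_fn(t: float) -> np.ndarray:
            return np.array([np.interp(t, times, var[:, j])
                             for j in range(var.shape[1])])

        return MotorPrimitive(name=name, role=role,
                              duration_ms=float(times[-1]) or 1.0,
                              mean_fn=mean_fn, var_fn=var_fn)


def fit_primitive(trials: Sequence[Trajectory], smoothing_ms: float = 30.0,
                  var_floor: float = 1e-6, name: str = "fitted",
                  role: str = "proximal") -> MotorPrimitive:
    """Functional wrapper over :class:`GaussianTrajectoryRegressor`."""
    reg = GaussianTrajectoryRegressor(smoothing_ms=smoothing_ms,
                                      var_floor=var_floor).fit(trials)
    return reg.to_primitive(name=name, role=role)


def make_toy_2d(seed: int = 0) -> PrimitiveLibrary:
    """Two-channel (x, y position) demo library.

    One proximal primitive moves to the centre-right over 1000 ms; two distal
    primitives continue to the top-right or bottom-right over the final
    500 ms, mirror-symmetric about the proximal endpoint's y.
    """
    def const_var(sd):
        v = np.full(2, sd * sd)
        return lambda t: v

    def mj_mean(p0, p1, dur):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        return lambda t: p0 + (p1 - p0) * _minimum_jerk(t / dur)

    prims = {
        "advance": MotorPrimitive("advance", "proximal", 1000.0,
                                  mj_mean([0, 0], [1, 0], 1000.0), const_var(0.05)),
        "up": MotorPrimitive("up", "distal", 500.0,
                             mj_mean([1, 0], [1.5, 0.5], 500.0), const_var(0.05)),
        "down": MotorPrimitive("down", "distal", 500.0,
                               mj_mean([1, 0], [1.5, -0.5], 500.0), const_var(0.05)),
    }
    channel_map = {"index": [0], "thumb": [1], "wrist": [], "other": []}
    return PrimitiveLibrary(primitives=prims, channel_map=channel_map, dt_ms=10.0,
                            timeline=Timeline(1000.0, 1500.0),
                            meta={"seed": int(seed), "toy": True})
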