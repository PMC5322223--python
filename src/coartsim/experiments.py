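"""Batch experiments: grip-aperture markers and recognition curves.

Reproduces the study's two analyses on synthetic data:

* Kinematic markers — per-trial Maximum Grip Aperture (MGA) and its time
  (tMGA) over the reach phase, compared across conditions (coarticulated
  with pour, coarticulated with move, not coarticulated) with seeded
  permutation tests.
* Recognition curves — per-condition mean +/- SD of the observer's
  posterior for the to-be-recognized intention over time, and the
  distribution of first threshold-crossing (recognition) times, over a
  2 (intent) x 2 (mode) grid of seeded runs.

Everything is a deterministic function of (config, seed); ``verify_results``
recomputes a saved results directory from its recorded config and seed and
checks the artifacts byte-for-byte.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .coarticulation import CoarticulationSpec
from .config import ConfigurationError, INTENT_TO_DISTAL, default_config
from .observer import default_hypotheses, first_crossing, recognize
from .performer import SequenceDefinition, compose_sequence, observe
from .primitives import PrimitiveLibrary, Trajectory, make_primitive_library

__all__ = [
    "grip_aperture", "aperture_series", "grip_metrics", "mga_analysis",
    "recognition_experiment", "ExperimentSummary", "verify_results",
    "coarticulation_spec_from_config", "make_sequence", "VerificationError",
]


class VerificationError(RuntimeError):
    """A stored results directory does not match its recomputation."""


# ---------------------------------------------------------------------------
# Config plumbing


def coarticulation_spec_from_config(cfg: Mapping[str, Any],
                                    lib: PrimitiveLibrary,
                                    distal: str) -> CoarticulationSpec:
    cc = cfg["coarticulation"]
    return CoarticulationSpec(
        primary="reach_to_grasp",
        future=(distal,),
        weights=dict(cc["weights"]),
        window_ms=tuple(float(v) for v in cc["window_ms"]),
        dof_channels=lib.group_channels(cc.get("dof_groups", ["index", "thumb"])),
        max_tries=int(cc.get("max_tries", 10000)),
    )


def make_sequence(intent: str, mode: str, cfg: Mapping[str, Any],
                  lib: PrimitiveLibrary) -> SequenceDefinition:
    distal = INTENT_TO_DISTAL[intent]
    spec = None if mode == "plain" else coarticulation_spec_from_config(cfg, lib, distal)
    return SequenceDefinition(intent=intent, proximal="reach_to_grasp",
                              distal=distal, mode=mode, spec=spec)


# ---------------------------------------------------------------------------
# Grip aperture


def aperture_series(values: np.ndarray, channel_map: Mapping[str, Sequence[int]],
                    theta_max: float = np.pi / 2) -> np.ndarray:
    """Grip aperture over time: mean index + thumb extension.

    Channels hold flexion angles; extension of a digit channel is
    (theta_max - angle), so the functional is linear, zero at full flexion,
    and monotone decreasing in every index/thumb flexion channel.
    """
    chans = list(channel_map.get("index", [])) + list(channel_map.get("thumb", []))
    if not chans:
        raise ConfigurationError("channel map must define index and thumb groups")
    values = np.atleast_2d(np.asarray(values, float))
    return theta_max - values[:, chans].mean(axis=1)


def grip_aperture(angles: np.ndarray, channel_map: Mapping[str, Sequence[int]],
                  theta_max: float = np.pi / 2) -> float:
    """Aperture of a single kinematic frame."""
    return float(aperture_series(np.atleast_2d(angles), channel_map, theta_max)[0])


def grip_metrics(traj: Trajectory, channel_map: Mapping[str, Sequence[int]],
                 reach_end_ms: float,
                 theta_max: float = np.pi / 2) -> tuple[float, float]:
    """(MGA, tMGA) over the reach phase (t < reach_end); earliest-tie rule."""
    mask = traj.times < reach_end_ms
    ap = aperture_series(traj.values[mask], channel_map, theta_max)
    k = int(np.argmax(ap))  # argmax returns the first maximizer
    return float(ap[k]), float(traj.times[mask][k])


def _permutation_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int,
                        rng: np.random.Generator) -> float:
    """Two-sided permutation p-value for a difference in group means."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    obs = abs(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n_a = a.size
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:n_a].mean() - perm[n_a:].mean()) >= obs:
            count += 1
    return (count + 1) / (n_perm + 1)


def mga_analysis(groups: Mapping[str, Sequence[Trajectory]],
                 channel_map: Mapping[str, Sequence[int]],
                 reach_end_ms: float, theta_max: float = np.pi / 2,
                 n_permutations: int = 10000,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial MGA/tMGA table and pairwise permutation contrasts.

    Returns
    -------
    trials : DataFrame with columns (condition, trial, mga, t_mga_ms)
    contrasts : DataFrame with columns (group_a, group_b, p_mga, p_tmga)
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 condition groups")
    rows = []
    for label, trajs in groups.items():
        if not trajs:
            raise ValueError(f"group {label!r} is empty")
        for k, tr in enumerate(trajs):
            mga, tmga = grip_metrics(tr, channel_map, reach_end_ms, theta_max)
            rows.append({"condition": label, "trial": k, "mga": mga,
                         "t_mga_ms": tmga})
    trials = pd.DataFrame(rows)

    rng = np.random.default_rng(seed)
    contrasts = []
    for ga, gb in combinations(groups, 2):
        sub_a = trials[trials.condition == ga]
        sub_b = trials[trials.condition == gb]
        contrasts.append({
            "group_a": ga, "group_b": gb,
            "p_mga": _permutation_pvalue(sub_a.mga.to_numpy(),
                                         sub_b.mga.to_numpy(), n_permutations, rng),
            "p_tmga": _permutation_pvalue(sub_a.t_mga_ms.to_numpy(),
                                          sub_b.t_mga_ms.to_numpy(),
                                          n_permutations, rng),
        })
    return trials, pd.DataFrame(contrasts)


# ---------------------------------------------------------------------------
# Recognition experiment


@dataclass
class ExperimentSummary:
    """All artifacts of one seeded batch run of the 2x2 recognition grid."""

    config: dict
    seed: int
    n_runs: int
    times: np.ndarray
    posterior_curves: dict[str, pd.DataFrame]   # cell -> (t_ms, mean, sd)
    crossing_times: pd.DataFrame                # (cell, run, crossing_ms)
    median_crossing: dict[str, float]
    mga_trials: pd.DataFrame
    mga_contrasts: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cell, df in self.posterior_curves.items():
            df.to_csv(outdir / f"posterior_mean_{cell}.csv", index=False)
        self.crossing_times.to_csv(outdir / "crossing_times.csv", index=False)
        self.mga_trials.to_csv(outdir / "mga_table.csv", index=False)
        self.mga_contrasts.to_csv(outdir / "mga_contrasts.csv", index=False)
        summary = {
            "seed": self.seed,
            "n_runs": self.n_runs,
            "median_crossing_ms": self.median_crossing,
            "cells": sorted(self.posterior_curves),
            "config": self.config,
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                        sort_keys=True))


def _cell_name(intent: str, mode: str) -> str:
    return f"{intent}_{mode}"


def recognition_experiment(config: Mapping[str, Any] | None = None,
                           n_runs: int | None = None,
                           seed: int = 0) -> ExperimentSummary:
    """Run the full 2 (intent) x 2 (mode) grid of performer+observer runs."""
    cfg = default_config() if config is None else dict(config)
    exp_cfg = cfg["experiment"]
    intents = list(exp_cfg.get("intents", ["pour", "move"]))
    modes = list(exp_cfg.get("modes", ["plain", "coarticulated"]))
    if not intents or not modes:
        raise ConfigurationError("experiment grid must define intents and modes")
    for intent in intents:
        if intent not in INTENT_TO_DISTAL:
            raise ConfigurationError(f"unknown intent {intent!r}")
    n_runs = int(exp_cfg.get("n_runs", 50)) if n_runs is None else int(n_runs)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    lib = make_primitive_library(cfg, seed=7)
    sigma_obs = float(cfg["observation"]["sigma_obs"])
    obs_cfg = cfg["observer"]
    threshold = float(obs_cfg["threshold"])
    times = lib.times()

    cells = [(intent, mode) for intent in intents for mode in modes]
    master = np.random.SeedSequence(seed)
    cell_seeds = master.spawn(len(cells))

    posterior_curves: dict[str, pd.DataFrame] = {}
    crossing_rows = []
    mga_groups: dict[str, list[Trajectory]] = {}

    for (intent, mode), cell_ss in zip(cells, cell_seeds):
        cell = _cell_name(intent, mode)
        seq = make_sequence(intent, mode, cfg, lib)
        hyp_mode = mode if mode in ("plain", "coarticulated") else "plain"
        hyps = default_hypotheses(lib, mode=hyp_mode, spec=seq.spec)
        curves = np.empty((n_runs, times.size))
        for run, run_ss in enumerate(cell_ss.spawn(n_runs)):
            rng = np.random.default_rng(run_ss)
            traj = compose_sequence(seq, lib, rng)
            obs = observe(traj, sigma_obs, rng)
            trace, _ = recognize(
                obs, hyps, lib, threshold=threshold,
                process_noise=float(obs_cfg["process_noise"]),
                state_var_inflation=float(obs_cfg["state_var_inflation"]))
            curves[run] = trace.column(intent)
            crossing = first_crossing(trace, intent, threshold)
            crossing_rows.append({"cell": cell, "intent": intent, "mode": mode,
                                  "run": run,
                                  "crossing_ms": np.nan if crossing is None
                                  else crossing})
            group = ("plain" if mode == "plain"
                     else f"{mode}_{intent}")
            mga_groups.setdefault(group, []).append(traj)
        posterior_curves[cell] = pd.DataFrame({
            "t_ms": times,
            "mean": curves.mean(axis=0),
            "sd": curves.std(axis=0, ddof=1) if n_runs > 1
            else np.zeros(times.size),
        })

    crossing_times = pd.DataFrame(crossing_rows)
    median_crossing = {
        cell: float(np.nanmedian(
            crossing_times.loc[crossing_times.cell == cell, "crossing_ms"]))
        for cell in sorted(posterior_curves)
    }

    mga_cfg = cfg.get("mga", {})
    mga_trials, mga_contrasts = mga_analysis(
        mga_groups, lib.channel_map, lib.timeline.reach_end_ms,
        theta_max=float(mga_cfg.get("theta_max", np.pi / 2)),
        n_permutations=int(mga_cfg.get("n_permutations", 10000)),
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    )

    return ExperimentSummary(
        config=json.loads(json.dumps(cfg)), seed=int(seed), n_runs=n_runs,
        times=times, posterior_curves=posterior_curves,
        crossing_times=crossing_times, median_crossing=median_crossing,
        mga_trials=mga_trials, mga_contrasts=mga_contrasts,
    )


def verify_results(results_dir: str | Path) -> bool:
    """Recompute a saved results directory from its (config, seed) and diff.

    Raises :class:`VerificationError` on any byte-level mismatch.
    """
    results_dir = Path(results_dir)
    summary = json.loads((results_dir / "summary.json").read_text())
    recomputed = recognition_experiment(config=summary["config"],
                                        n_runs=summary["n_runs"],
                                        seed=summary["seed"])
    with tempfile.TemporaryDirectory() as tmp:
        recomputed.save(tmp)
        mismatches = []
        for path in sorted(Path(tmp).iterdir()):
            stored = results_dir / path.name
            if not stored.exists():
                mismatches.append(f"missing file {path.name}")
            elif stored.read_bytes() != path.read_bytes():
                mismatches.append(f"content differs: {path.name}")
        if mismatches:
            raise VerificationError("; ".join(mismatches))
    return True
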