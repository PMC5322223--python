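"""Default configuration and YAML loading.

The package carries its study conditions in a single nested configuration
dictionary: the hand model (16 joint-angle channels grouped into index,
thumb, wrist and other fingers), the 0-1500 ms timeline with the reach
phase ending at 1000 ms, the three motor primitives with their start/end
postures (radians of flexion; 0 = fully extended), the coarticulation
window and channel mask, and the observer's noise parameters.

``default_config()`` returns a deep copy of the built-in defaults;
``load_config(path)`` merges a user YAML file over them, so partial
configs are valid.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration value violates a documented constraint."""


#: Flexion angle (radians) treated as a fully flexed digit by the grip
#: aperture functional; pi/2 is a conventional full-curl bound.
THETA_MAX = 1.5707963267948966

DEFAULT_CONFIG: dict[str, Any] = {
    "channels": 16,
    "dt_ms": 10.0,
    "channel_map": {
        "index": [0, 1, 2, 3],
        "thumb": [4, 5, 6, 7],
        "wrist": [8, 9],
        "other": [10, 11, 12, 13, 14, 15],
    },
    "timeline": {"reach_end_ms": 1000.0, "sequence_end_ms": 1500.0},
    "primitives": {
        # Reach-to-grasp: hand starts in a relaxed semi-flexed posture,
        # opens mid-reach (the grip-aperture bump on index+thumb) and
        # closes onto a neutral grasp posture at contact.
        "reach_to_grasp": {
            "role": "proximal",
            "start_posture": {"index": 0.95, "thumb": 0.95, "wrist": 0.10, "other": 0.95},
            "end_posture": {"index": 0.75, "thumb": 0.75, "wrist": 0.20, "other": 0.80},
            "aperture_bump": {
                "amplitude": 0.20,
                "center_ms": 750.0,
                "width_ms": 100.0,
                "groups": ["index", "thumb"],
            },
            "variance_profile": {"kind": "sine", "base_sd": 0.05, "peak_sd": 0.08},
        },
        # Grasp-to-pour: power grasp — digits wrapped wide around the
        # bottle body, i.e. comparatively extended index/thumb.
        "grasp_to_pour": {
            "role": "distal",
            "start_posture": {"index": 0.55, "thumb": 0.55, "wrist": 0.20, "other": 0.70},
            "end_posture": {"index": 0.50, "thumb": 0.50, "wrist": 0.30, "other": 0.65},
            "variance_profile": {"kind": "linear", "start_sd": 0.12, "end_sd": 0.04},
        },
        # Grasp-to-move: precision grip — fingertip opposition, more
        # flexed index/thumb. Wrist/other channels mirror grasp_to_pour.
        "grasp_to_move": {
            "role": "distal",
            "start_posture": {"index": 0.95, "thumb": 0.95, "wrist": 0.20, "other": 0.70},
            "end_posture": {"index": 1.00, "thumb": 1.00, "wrist": 0.30, "other": 0.65},
            "variance_profile": {"kind": "linear", "start_sd": 0.12, "end_sd": 0.04},
        },
    },
    "coarticulation": {
        "window_ms": [500.0, 1000.0],
        # One weight per future primitive; the proximal primitive's weight
        # is the proposal and must be positive.
        "weights": {"reach_to_grasp": 1.0, "grasp_to_pour": 1.0, "grasp_to_move": 1.0},
        "dof_groups": ["index", "thumb"],
        "max_tries": 10000,
    },
    "observation": {"sigma_obs": 0.05},
    "observer": {
        "threshold": 0.95,
        "process_noise": 0.02,
        "state_var_inflation": 1.0,
    },
    "experiment": {
        "n_runs": 50,
        "intents": ["pour", "move"],
        "modes": ["plain", "coarticulated"],
    },
    "mga": {"theta_max": THETA_MAX, "n_permutations": 10000},
    "fit": {"smoothing_ms": 30.0, "var_floor": 1e-6},
}

#: Mapping from distal intention label to the distal primitive realizing it.
INTENT_TO_DISTAL = {"pour": "grasp_to_pour", "move": "grasp_to_move"}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(DEFAULT_CONFIG)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config, merged recursively over the package defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ConfigurationError(f"config file {path!r} must contain a mapping")
    return _deep_merge(cfg, user)


def dump_default_config(path: str | Path) -> None:
    """Write the built-in defaults as YAML (used to ship configs/default.yaml)."""
    with open(path, "w") as fh:
        yaml.safe_dump(DEFAULT_CONFIG, fh, sort_keys=False)
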