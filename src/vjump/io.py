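"""Configuration files, track CSV interchange, and example networks.

Model configs are YAML: a list of state blocks (name, velocity, rate), a
transition matrix or edge list, the observation scheme (dt, sigma,
n_increments), a seed, and a ``rate_multiplier`` that scales every switching
rate (the x1 / x5 / x10 device used to stress the approximations). Tracks
are CSV with columns ``track_id, frame, t, y`` plus the simulator's
ground-truth columns ``x, state, w`` when available.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import VelocityJumpModel, validate_model
from .simulate import ObservationScheme, Track

__all__ = [
    "load_model_config",
    "save_model_config",
    "write_tracks",
    "read_tracks",
    "example_network",
    "config_to_model",
]

_FLOAT_FMT = "%.17g"


class ConfigError(ValueError):
    """A model configuration file is malformed."""


def _transition_matrix(cfg: dict, names: list[str]) -> np.ndarray:
    n = len(names)
    trans = cfg.get("transitions")
    if trans is None:
        raise ConfigError("missing 'transitions' section")
    if isinstance(trans[0], dict):  # edge list
        P = np.zeros((n, n))
        idx = {nm: i for i, nm in enumerate(names)}
        for edge in trans:
            try:
                P[idx[edge["from"]], idx[edge["to"]]] = float(edge["prob"])
            except KeyError as exc:
                raise ConfigError(f"bad edge entry {edge!r}: {exc}") from exc
        bad = np.flatnonzero(np.abs(P.sum(axis=1) - 1.0) > 1e-9)
        if bad.size:
            raise ConfigError(
                f"edge probabilities out of state '{names[bad[0]]}' sum to "
                f"{P.sum(axis=1)[bad[0]]!r}, expected 1"
            )
        return P
    return np.asarray(trans, dtype=float)


def config_to_model(cfg: dict) -> tuple[VelocityJumpModel, ObservationScheme, int]:
    """Build (validated model, scheme, seed) from a parsed config dict."""
    try:
        states = cfg["states"]
        names = [s["name"] for s in states]
        vel = np.array([float(s["velocity"]) for s in states])
        rates = np.array([float(s["rate"]) for s in states])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"bad 'states' section: {exc}") from exc
    mult = float(cfg.get("rate_multiplier", 1.0))
    if mult <= 0:
        raise ConfigError(f"rate_multiplier must be positive, got {mult}")
    P = _transition_matrix(cfg, names)
    model = validate_model(VelocityJumpModel(vel, rates * mult, P, state_names=names))
    scheme = ObservationScheme(
        dt=float(cfg.get("dt", 1.0)),
        sigma=float(cfg.get("sigma", 0.0)),
        n_increments=int(cfg.get("n_increments", 1)),
    )
    return model, scheme, int(cfg.get("seed", 0))


def load_model_config(path) -> tuple[VelocityJumpModel, ObservationScheme, int]:
    """Parse and validate a YAML model config file."""
    text = Path(path).read_text()
    try:
        cfg = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return config_to_model(cfg)


def save_model_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def write_tracks(tracks: list[Track], path) -> None:
    """Serialize tracks to CSV, floats at 17 significant digits.

    Rows are (track_id, frame, t, y) plus ground-truth columns x, state and
    per-interval switch count w (empty on frame 0) when the tracks carry
    them; N increments give N + 1 rows per track.
    """
    frames = []
    for i, tr in enumerate(tracks):
        nf = tr.times.size
        df = pd.DataFrame(
            {
                "track_id": i,
                "frame": np.arange(nf),
                "t": tr.times,
                "y": tr.noisy_positions,
            }
        )
        if tr.exact_positions is not None:
            df["x"] = tr.exact_positions
        if tr.states_at_frames is not None:
            df["state"] = tr.states_at_frames
        if tr.switch_counts is not None:
            df["w"] = np.concatenate(([np.nan], tr.switch_counts))
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tracks(path) -> list[Track]:
    """Read tracks from CSV; round-trips `write_tracks` to full precision."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"track_id", "frame", "t", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required column(s): {sorted(missing)}")
    tracks = []
    for _, g in df.groupby("track_id", sort=True):
        frames = g["frame"].to_numpy()
        if frames.size != np.unique(frames).size:
            raise ValueError("duplicated frame index within a track")
        if np.any(np.diff(frames) <= 0):
            raise ValueError("non-monotone frames within a track")
        tracks.append(
            Track(
                times=g["t"].to_numpy(float),
                exact_positions=g["x"].to_numpy(float) if "x" in g else None,
                noisy_positions=g["y"].to_numpy(float),
                states_at_frames=g["state"].to_numpy(int) if "state" in g else None,
                switch_counts=g["w"].to_numpy(float)[1:].astype(int) if "w" in g else None,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# example networks
# ---------------------------------------------------------------------------

# Numeric defaults are package-documented placeholders (not taken from any
# external source): forward/backward speeds of 1 length-unit per time-unit,
# baseline switching so that lambda*dt = 0.2 for the moving states, a slow
# stationary state SL and a faster one SS, dt = 1, sigma = 0.05.
_NETWORKS = {
    "two_state": {
        "states": [
            {"name": "F", "velocity": 1.0, "rate": 0.2},
            {"name": "B", "velocity": -1.0, "rate": 0.2},
        ],
        "transitions": [[0.0, 1.0], [1.0, 0.0]],
    },
    "three_state": {
        "states": [
            {"name": "F", "velocity": 1.0, "rate": 0.2},
            {"name": "B", "velocity": -1.0, "rate": 0.2},
            {"name": "SL", "velocity": 0.0, "rate": 0.05},
        ],
        "transitions": [
            [0.0, 0.5, 0.5],
            [0.5, 0.0, 0.5],
            [0.5, 0.5, 0.0],
        ],
    },
    # F and B are not directly connected: direction changes pass through a
    # stationary state, and SL always hands over to SS (hypoexponential
    # total pause).
    "four_state": {
        "states": [
            {"name": "F", "velocity": 1.0, "rate": 0.2},
            {"name": "B", "velocity": -1.0, "rate": 0.2},
            {"name": "SL", "velocity": 0.0, "rate": 0.05},
            {"name": "SS", "velocity": 0.0, "rate": 0.5},
        ],
        "transitions": [
            [0.0, 0.0, 0.5, 0.5],
            [0.0, 0.0, 0.5, 0.5],
            [0.0, 0.0, 0.0, 1.0],
            [0.5, 0.5, 0.0, 0.0],
        ],
    },
    # cyclic structure with pause states that mostly return to the previous
    # direction of motion
    "six_state": {
        "states": [
            {"name": "F", "velocity": 1.0, "rate": 0.2},
            {"name": "B", "velocity": -1.0, "rate": 0.2},
            {"name": "SL", "velocity": 0.0, "rate": 0.05},
            {"name": "SS", "velocity": 0.0, "rate": 0.5},
            {"name": "PF", "velocity": 0.0, "rate": 0.5},
            {"name": "PB", "velocity": 0.0, "rate": 0.5},
        ],
        "transitions": [
            [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],  # F -> PF
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],  # B -> PB
            [0.0, 0.0, 0.0, 1.0, 0.0, 0.0],  # SL -> SS
            [0.5, 0.5, 0.0, 0.0, 0.0, 0.0],  # SS -> F or B
            [0.8, 0.0, 0.2, 0.0, 0.0, 0.0],  # PF -> F (mostly) or SL
            [0.0, 0.8, 0.2, 0.0, 0.0, 0.0],  # PB -> B (mostly) or SL
        ],
    },
}


def example_network(name: str, **overrides) -> dict:
    """Config dict for a named example network topology.

    Names: ``two_state``, ``three_state``, ``four_state``, ``six_state``.
    Numeric values are package defaults (stamped
    ``provenance: package-default``); keyword overrides are merged in
    (e.g. ``rate_multiplier=10``, ``sigma=0.1``).
    """
    if name not in _NETWORKS:
        raise KeyError(f"unknown network {name!r}; choose from {sorted(_NETWORKS)}")
    cfg = {
        "network": name,
        **{k: [dict(d) for d in v] if k == "states" else [list(r) for r in v] for k, v in _NETWORKS[name].items()},
        "dt": 1.0,
        "sigma": 0.05,
        "n_increments": 500,
        "seed": 0,
        "rate_multiplier": 1.0,
        "provenance": "package-default",
    }
    cfg.update(overrides)
    return cfg
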