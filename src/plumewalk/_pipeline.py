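"""Converters between labeled behavior and likelihood-ready containers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._filters import causal_exp_filter, exposure_exp_filter
from .stopwalk_models import BoutData
from .turn_model import TurnLikelihoodData


def wrapped_diff(theta: np.ndarray) -> np.ndarray:
    """Per-step orientation change mapped to (-180, 180]; first step 0."""
    d = np.diff(np.asarray(theta, dtype=float), prepend=theta[0])
    return (d + 180.0) % 360.0 - 180.0


def behavior_to_turn_data(behavior, filter_tau: float = 2.0) -> TurnLikelihoodData:
    """Likelihood inputs from one ground-truth behavior trajectory.

    The orientation entering each step's direction classification is the
    pre-step orientation; per-step angle changes are branch-cut-safe
    wrapped differences.
    """
    theta = np.asarray(behavior.theta, dtype=float)
    dt = behavior.time_step
    theta_pre = np.concatenate(([theta[0]], theta[:-1]))
    dtheta = wrapped_diff(theta)
    n = theta.size
    turn_mask = np.zeros(n, dtype=bool)
    steps = np.round(np.asarray(behavior.turn_times) / dt).astype(int)
    turn_mask[steps[steps < n]] = True
    w = behavior.encounters.w
    d = behavior.encounters.d
    W_freq = causal_exp_filter(w, filter_tau, dt, normalize=True)
    W_dur = exposure_exp_filter(d, filter_tau, dt)
    return TurnLikelihoodData(dtheta=dtheta, theta=theta_pre, W_freq=W_freq,
                              W_dur=W_dur, turn_mask=turn_mask,
                              walking_mask=np.asarray(behavior.walking, dtype=bool),
                              time_step=dt)


def behaviors_to_bout_data(behaviors) -> BoutData:
    dt = behaviors[0].time_step
    trajectories = [dict(w=b.encounters.w, d=b.encounters.d,
                         walking=np.asarray(b.walking, dtype=bool))
                    for b in behaviors]
    return BoutData(trajectories=trajectories, time_step=dt)


def _read_behavior_table(path) -> list[dict]:
    df = pd.read_csv(path, sep="\t")
    need = {"trajectory_id", "t", "walking", "theta_deg", "w", "d"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"behavior table missing columns {sorted(missing)}")
    out = []
    for _, g in df.groupby("trajectory_id", sort=True):
        t = g.t.to_numpy()
        out.append(dict(time_step=float(np.median(np.diff(t))),
                        walking=g.walking.to_numpy().astype(bool),
                        theta=g.theta_deg.to_numpy(),
                        w=g.w.to_numpy().astype(np.uint8),
                        d=g.d.to_numpy().astype(np.uint8)))
    return out


def behavior_table_to_turn_data(path, filter_tau: float = 2.0,
                                turn_threshold: float = 5.0
                                ) -> list[TurnLikelihoodData]:
    """Turn-likelihood inputs from a labeled behavior table.

    Without explicit turn labels in the table, steps whose wrapped
    orientation change exceeds ``turn_threshold`` degrees are treated as
    saccade steps (the generating model's jitter is far below this).
    """
    out = []
    for tr in _read_behavior_table(path):
        dt = tr["time_step"]
        theta = tr["theta"]
        dtheta = wrapped_diff(theta)
        theta_pre = np.concatenate(([theta[0]], theta[:-1]))
        out.append(TurnLikelihoodData(
            dtheta=dtheta, theta=theta_pre,
            W_freq=causal_exp_filter(tr["w"], filter_tau, dt, normalize=True),
            W_dur=exposure_exp_filter(tr["d"], filter_tau, dt),
            turn_mask=np.abs(dtheta) > turn_threshold,
            walking_mask=tr["walking"], time_step=dt))
    return out


def behavior_table_to_bout_data(path) -> BoutData:
    trajs = _read_behavior_table(path)
    return BoutData(trajectories=[dict(w=t["w"], d=t["d"], walking=t["walking"])
                                  for t in trajs],
                    time_step=trajs[0]["time_step"])
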