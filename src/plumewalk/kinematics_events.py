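"""Trajectory smoothing, kinematic derivatives, and behavioral segmentation.

Position and orientation traces are smoothed with a Savitzky-Golay filter
(4th-order polynomial, 9-sample window by default); speed comes from the
analytic derivative of the smoothed positions.  Angular velocity is never
computed by differentiating the wrapped angle: the orientation is first
mapped to unit-circle components (cos, sin), each component is smoothed and
differentiated, and omega is recovered from the quotient whose denominator
is larger in magnitude (omega = -dthx/thy when |thy| >= |thx|, else
dthy/thx), which is free of branch-cut artifacts at 0/360.

Behavioral events use symmetric persistence thresholding: stops where the
speed stays below 2 mm/s for at least 300 ms, turns (saccades) where the
angular speed stays above 200 deg/s for at least 20 ms; walks tile the
remainder.  The signed turn angle is measured over a centered window
(200 ms default) around the turn midpoint.

Orientation convention: theta = 0 faces upwind (the -x direction); the
reflected upwind deviation is theta+ = min(theta, 360 - theta) in [0, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from ._filters import min_samples_for, persistent_intervals
from .turn_model import reflect_upwind

__all__ = [
    "SmoothingConfig",
    "KinematicsTrace",
    "EventDetectionConfig",
    "EventSeries",
    "smooth_and_differentiate",
    "detect_events",
    "turn_discreteness_analysis",
    "empirical_transition_rates",
]


@dataclass
class SmoothingConfig:
    polynomial_order: int = 4
    window_length: int = 9

    def __post_init__(self):
        if self.window_length % 2 == 0:
            raise ValueError("window_length must be odd")
        if self.window_length <= self.polynomial_order:
            raise ValueError("window_length must exceed polynomial_order")


@dataclass
class KinematicsTrace:
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray        # deg in [0, 360), 0 = upwind
    theta_plus: np.ndarray   # deg in [0, 180]
    v: np.ndarray            # mm/s
    omega: np.ndarray        # deg/s
    valid_mask: np.ndarray
    time_step: float


@dataclass
class EventDetectionConfig:
    stop_speed_threshold: float = 2.0    # mm/s
    stop_min_duration: float = 0.300     # s
    turn_omega_threshold: float = 200.0  # deg/s
    turn_min_duration: float = 0.020     # s
    dtheta_window: float = 0.200         # s, centered window for turn angle
    dtheta_mode: str = "window"          # "window" or "onset_to_offset"

    def __post_init__(self):
        for name in ("stop_speed_threshold", "stop_min_duration",
                     "turn_omega_threshold", "turn_min_duration",
                     "dtheta_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dtheta_mode not in ("window", "onset_to_offset"):
            raise ValueError("dtheta_mode must be 'window' or 'onset_to_offset'")


@dataclass
class Turn:
    onset: float
    offset: float
    midpoint: float
    dtheta: float            # signed deg
    direction: str           # "upwind" or "downwind"


@dataclass
class EventSeries:
    turns: list
    stops: list              # (onset_s, offset_s)
    walks: list
    state: np.ndarray        # per-step label: 1 = walk, 0 = stop
    time_step: float


def smooth_and_differentiate(trajectory, cfg: SmoothingConfig | None = None
                             ) -> KinematicsTrace:
    """Smooth a raw (t, x, y, theta_deg) trajectory and derive v and omega.

    Orientation derivatives go through the unit-circle components; the
    numerically stable quotient is chosen per sample by comparing |thx| and
    |thy|.  Samples within half a window of the trace ends are flagged
    invalid.
    """
    cfg = cfg or SmoothingConfig()
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 4:
        raise ValueError("trajectory must have columns (t, x, y, theta_deg)")
    t, x, y, theta = traj.T
    m = cfg.window_length
    if t.size < m:
        raise ValueError(f"need at least {m} samples")
    dts = np.diff(t)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=dt * 1e-6):
        raise ValueError("non-uniform sampling")
    k = cfg.polynomial_order
    xs = savgol_filter(x, m, k)
    ys = savgol_filter(y, m, k)
    vx = savgol_filter(x, m, k, deriv=1, delta=dt)
    vy = savgol_filter(y, m, k, deriv=1, delta=dt)
    v = np.hypot(vx, vy)
    th = np.deg2rad(theta)
    thx, thy = np.cos(th), np.sin(th)
    thx_s = savgol_filter(thx, m, k)
    thy_s = savgol_filter(thy, m, k)
    dthx = savgol_filter(thx, m, k, deriv=1, delta=dt)
    dthy = savgol_filter(thy, m, k, deriv=1, delta=dt)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = np.where(np.abs(thy_s) >= np.abs(thx_s),
                         -dthx / thy_s, dthy / thx_s)
    omega = np.rad2deg(omega)
    theta_s = np.mod(np.rad2deg(np.arctan2(thy_s, thx_s)), 360.0)
    valid = np.ones(t.size, dtype=bool)
    half = (m - 1) // 2
    valid[:half] = valid[-half:] = False
    return KinematicsTrace(t=t, x=xs, y=ys, theta=theta_s,
                           theta_plus=reflect_upwind(theta_s), v=v,
                           omega=omega, valid_mask=valid, time_step=dt)


def _unwrapped_theta(trace: KinematicsTrace) -> np.ndarray:
    return np.rad2deg(np.unwrap(np.deg2rad(trace.theta)))


def _turn_from_interval(trace: KinematicsTrace, a: int, b: int,
                        cfg: EventDetectionConfig) -> Turn:
    dt = trace.time_step
    unw = _unwrapped_theta(trace)
    mid = (a + b - 1) // 2
    if cfg.dtheta_mode == "window":
        half = max(int(round(cfg.dtheta_window / 2 / dt)), 1)
        i0 = max(mid - half, 0)
        i1 = min(mid + half, unw.size - 1)
    else:
        i0, i1 = a, min(b, unw.size - 1)
    dtheta = unw[i1] - unw[i0]
    tp0 = reflect_upwind(np.mod(unw[i0], 360.0))
    tp1 = reflect_upwind(np.mod(unw[i1], 360.0))
    direction = "upwind" if tp1 < tp0 else "downwind"
    return Turn(onset=a * dt, offset=b * dt, midpoint=mid * dt,
                dtheta=float(dtheta), direction=direction)


def detect_events(trace: KinematicsTrace, cfg: EventDetectionConfig | None = None
                  ) -> EventSeries:
    """Segment a trace into stops, walks, and turns with persistence rules."""
    cfg = cfg or EventDetectionConfig()
    dt = trace.time_step
    stop_min = min_samples_for(cfg.stop_min_duration, dt)
    turn_min = min_samples_for(cfg.turn_min_duration, dt)
    below = (trace.v < cfg.stop_speed_threshold) & trace.valid_mask
    stop_idx = persistent_intervals(below, stop_min)
    n = trace.v.size
    state = np.ones(n, dtype=np.uint8)
    for a, b in stop_idx:
        state[a:b] = 0
    state[~trace.valid_mask] = 1  # invalid edges default to walk label
    stops = [(a * dt, b * dt) for a, b in stop_idx]
    # walks: complement of stops over the valid span
    walks = []
    vidx = np.flatnonzero(trace.valid_mask)
    if vidx.size:
        lo, hi = int(vidx[0]), int(vidx[-1]) + 1
        cur = lo
        for a, b in stop_idx:
            if a > cur:
                walks.append((cur * dt, a * dt))
            cur = max(cur, b)
        if cur < hi:
            walks.append((cur * dt, hi * dt))
    fast = (np.abs(trace.omega) > cfg.turn_omega_threshold) & trace.valid_mask
    turn_idx = persistent_intervals(fast, turn_min)
    turns = []
    for a, b in turn_idx:
        if any(sa <= a * dt and b * dt <= sb for sa, sb in stops):
            continue  # inside a stop: not a walking saccade
        if any(sa < b * dt and a * dt < sb for sa, sb in stops):
            continue  # straddles a stop boundary
        turn = _turn_from_interval(trace, a, b, cfg)
        if turn.dtheta == 0.0:
            continue
        turns.append(turn)
    return EventSeries(turns=turns, stops=stops, walks=walks, state=state,
                       time_step=dt)


def turn_discreteness_analysis(trace: KinematicsTrace,
                               omega_thresholds=(150.0, 200.0, 250.0, 300.0),
                               windows=(0.05, 0.1, 0.15, 0.2, 0.3, 0.4),
                               min_turns: int = 50,
                               cfg: EventDetectionConfig | None = None) -> dict:
    """Positive mode of the turn-angle distribution vs window length.

    For each angular-speed threshold, turns are detected and the signed
    angle change is measured over centered windows of increasing length;
    if turning is saccadic the positive mode plateaus once the window
    exceeds the true saccade duration, whereas continuous turning grows
    without leveling off.  Returns {threshold: (windows, modes)}; empty
    when fewer than ``min_turns`` turns are detected.
    """
    cfg = cfg or EventDetectionConfig()
    out = {}
    unw = _unwrapped_theta(trace)
    dt = trace.time_step
    for thr in omega_thresholds:
        c = EventDetectionConfig(stop_speed_threshold=cfg.stop_speed_threshold,
                                 stop_min_duration=cfg.stop_min_duration,
                                 turn_omega_threshold=thr,
                                 turn_min_duration=cfg.turn_min_duration)
        fast = (np.abs(trace.omega) > thr) & trace.valid_mask
        turn_idx = persistent_intervals(fast,
                                        min_samples_for(c.turn_min_duration, dt))
        if len(turn_idx) < min_turns:
            out[thr] = (np.asarray(windows), np.full(len(windows), np.nan))
            continue
        mids = np.array([(a + b - 1) // 2 for a, b in turn_idx])
        modes = []
        for w in windows:
            half = max(int(round(w / 2 / dt)), 1)
            i0 = np.clip(mids - half, 0, unw.size - 1)
            i1 = np.clip(mids + half, 0, unw.size - 1)
            dth = unw[i1] - unw[i0]
            pos = np.abs(dth)
            hist, edges = np.histogram(pos, bins=np.arange(0, 181, 2.0))
            modes.append(0.5 * (edges[hist.argmax()] + edges[hist.argmax() + 1]))
        out[thr] = (np.asarray(windows), np.asarray(modes))
    return out


def empirical_transition_rates(events: EventSeries):
    """Piecewise-constant empirical hazard series from bout durations.

    Within every walk-then-stop snippet the walk-to-stop hazard is the
    reciprocal walk duration, held constant over the snippet and updated at
    each bout onset; symmetrically for stop-to-walk.  Returns (t, lam_ws,
    lam_sw) arrays with nan where a rate is undefined; empty arrays when no
    complete bout pair exists.
    """
    dt = events.time_step
    bouts = sorted([(a, b, "walk") for a, b in events.walks] +
                   [(a, b, "stop") for a, b in events.stops])
    pairs_ws = [(w, s) for w, s in zip(bouts[:-1], bouts[1:])
                if w[2] == "walk" and s[2] == "stop"]
    pairs_sw = [(s, w) for s, w in zip(bouts[:-1], bouts[1:])
                if s[2] == "stop" and w[2] == "walk"]
    if not pairs_ws and not pairs_sw:
        return np.array([]), np.array([]), np.array([])
    n = events.state.size
    t = np.arange(n) * dt
    lam_ws = np.full(n, np.nan)
    lam_sw = np.full(n, np.nan)
    for (wa, wb, _), (sa, sb, _) in pairs_ws:
        i0, i1 = int(round(wa / dt)), int(round(sb / dt))
        lam_ws[i0:i1] = 1.0 / (wb - wa)
    for (sa, sb, _), (wa, wb, _) in pairs_sw:
        i0, i1 = int(round(sa / dt)), int(round(wb / dt))
        lam_sw[i0:i1] = 1.0 / (sb - sa)
    return t, lam_ws, lam_sw
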