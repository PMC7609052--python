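"""Agent-based plume navigation with the fitted stochastic decision models.

Each agent is a point walker with four behavioral states (walk, stop, left
saccade, right saccade -- saccades are instantaneous) driven by three
stochastic components estimated from walking flies: Poisson saccades whose
direction is upwind-biased through the sigmoid p_T(W_freq), a walk-to-stop
hazard, and a stop-to-walk hazard, both modulated by the agent's own
encounter history.  Agents sense the plume through an elliptical virtual
antenna ahead of the body, threshold the signal at the sensory threshold,
and register at most one encounter per refractory period (100 ms).

Ablations replace one component's rate with its ensemble-average constant
from a reference (full-model) run; performance is measured by fractional
changes in source arrivals and arrival times against a control ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .signal_encounters import (AntennaGeometry, BackgroundModel,
                                EncounterDetectionConfig, SignalTrace,
                                detect_encounters)
from .stopwalk_models import RateModelSpec, fitted_stop_spec, fitted_walk_spec, \
    rate_from_features
from .turn_model import TurnModelParams, full_turn_rate, upwind_turn_probability

__all__ = [
    "AgentParams",
    "ArenaConfig",
    "SimulationResult",
    "run_agents",
    "ablate",
    "performance_metrics",
    "occupancy_pdf",
]


@dataclass
class AgentParams:
    """Constants and fitted model components of one virtual navigator."""

    walk_speed: float = 10.1                  # mm/s
    turn_params: TurnModelParams = field(default_factory=TurnModelParams)
    stop_spec: RateModelSpec = field(default_factory=fitted_stop_spec)
    walk_spec: RateModelSpec = field(default_factory=fitted_walk_spec)
    antenna: AntennaGeometry = field(default_factory=AntennaGeometry)
    encounter_refractory: float = 0.100       # s
    time_step: float = 1.0 / 90.0
    k_sigma: float = 2.5
    fixed_upwind_probability: float | None = None  # turn ablation

    def __post_init__(self):
        if self.walk_speed < 0:
            raise ValueError("walk_speed must be non-negative")
        if self.encounter_refractory < 0:
            raise ValueError("encounter_refractory must be non-negative")


@dataclass
class ArenaConfig:
    extent: tuple = (300.0, 180.0)       # mm; source at (0, 0)
    source_box_length: float = 20.0      # mm downwind of the source
    source_box_width: float = 20.0       # mm, centered on the source
    start_margin: float = 5.0            # mm from the downwind wall

    def __post_init__(self):
        if (self.source_box_length > self.extent[0]
                or self.source_box_width > self.extent[1]):
            raise ValueError("source box must fit inside the arena")


@dataclass
class SimulationResult:
    n_agents: int
    n_steps: int
    time_step: float
    arrived: np.ndarray                # bool per agent
    arrival_times: np.ndarray          # s (nan if not arrived)
    walk_durations: np.ndarray         # completed walk bouts, pooled (s)
    stop_durations: np.ndarray
    n_up_turns: int
    n_down_turns: int
    n_onsets: int
    onset_W_freq: np.ndarray           # W_freq sampled at each onset
    positions: np.ndarray | None       # (agents, steps, 2) float32
    theta: np.ndarray | None
    walking: np.ndarray | None         # (agents, steps) bool
    signals: np.ndarray | None         # (agents, steps) float32
    params: AgentParams = None
    arena: ArenaConfig = None

    @property
    def arrival_fraction(self) -> float:
        return float(self.arrived.mean())

    @property
    def upwind_turn_fraction(self) -> float:
        tot = self.n_up_turns + self.n_down_turns
        return self.n_up_turns / tot if tot else np.nan

    def encounter_series(self, bg: BackgroundModel,
                         cfg: EncounterDetectionConfig | None = None):
        """Post-hoc encounter detection on the recorded agent signals."""
        if self.signals is None:
            raise ValueError("run with record_signals=True")
        cfg = cfg or EncounterDetectionConfig()
        out = []
        for s in self.signals:
            trace = SignalTrace(values=np.asarray(s, dtype=float),
                                time_step=self.time_step)
            out.append(detect_encounters(trace, bg, cfg))
        return out


def _theta_from_heading(hx, hy):
    """Wind-relative angle of a heading vector (theta=0 faces -x)."""
    return np.mod(np.rad2deg(np.arctan2(hy, -hx)), 360.0)


def _resample_inward(rng, x, y, extent):
    """Headings pointing away from the nearest violated wall."""
    lx, ly = extent
    nx_ = np.where(x < 0, 1.0, np.where(x > lx, -1.0, 0.0))
    ny_ = np.where(y < -ly / 2, 1.0, np.where(y > ly / 2, -1.0, 0.0))
    norm = np.hypot(nx_, ny_)
    nx_, ny_ = nx_ / norm, ny_ / norm
    psi = rng.uniform(-np.pi / 2 * 0.9, np.pi / 2 * 0.9, size=x.size)
    hx = nx_ * np.cos(psi) - ny_ * np.sin(psi)
    hy = nx_ * np.sin(psi) + ny_ * np.cos(psi)
    return _theta_from_heading(hx, hy)


def run_agents(plume, params: AgentParams | None = None,
               arena: ArenaConfig | None = None, n_agents: int = 10000,
               n_steps: int = 11690, seed=None,
               background: BackgroundModel | None = None,
               record_trajectories: bool = False,
               record_signals: bool = False,
               antenna_quadrature: tuple = (1, 4)) -> SimulationResult:
    """Simulate an agent ensemble inside a plume.

    ``plume`` is a PlumeField (sampled analytically through the antenna
    quadrature points) and is looped in time when shorter than the run.
    Agents start at random positions along the downwind wall with uniform
    random headings.  Walls are reflective in effect: an agent stepping out
    has its position clamped and its heading resampled away from the wall.
    Arrival is the first entry into the source box; arrived agents keep
    navigating.  Reproducible from ``seed``.
    """
    params = params or AgentParams()
    arena = arena or ArenaConfig()
    cfg = getattr(plume, "config", None)
    if cfg is not None and tuple(cfg.arena_size) != tuple(arena.extent):
        raise ValueError("plume and arena geometry mismatch")
    if background is None:
        if cfg is None:
            raise ValueError("provide a BackgroundModel for movie input")
        background = BackgroundModel(mean=cfg.background_mean,
                                     sd=cfg.background_noise_sd)
    thr = background.threshold(params.k_sigma)
    dt = params.time_step
    if cfg is not None and abs(dt - 1.0 / cfg.frame_rate) > 1e-12:
        raise ValueError("agent time step must match the plume frame rate")
    rng = np.random.default_rng(seed)
    lx, ly = arena.extent
    tp = params.turn_params
    tau = tp.filter_tau
    decay = np.exp(-dt / tau)
    s_decay = np.exp(-dt / params.stop_spec.params.get("tau", 1.0))
    w_decay = np.exp(-dt / params.walk_spec.params.get("tau", 1.0))
    offsets = params.antenna.sample_offsets(*antenna_quadrature)

    # agent state
    x = np.full(n_agents, lx - arena.start_margin)
    y = rng.uniform(-ly / 2, ly / 2, size=n_agents)
    theta = rng.uniform(0.0, 360.0, size=n_agents)
    walking = np.ones(n_agents, dtype=bool)
    W_freq = np.zeros(n_agents)
    W_dur = np.zeros(n_agents)
    F_stop = np.zeros(n_agents)   # raw filtered onsets at the stop-model tau
    F_walk = np.zeros(n_agents)
    dT = np.full(n_agents, np.inf)
    since_onset = np.full(n_agents, np.inf)
    arrived = np.zeros(n_agents, dtype=bool)
    arrival_times = np.full(n_agents, np.nan)
    bout_start = np.zeros(n_agents)
    walk_durs, stop_durs = [], []
    n_up = n_down = 0
    onset_W = []
    pos_rec = (np.empty((n_agents, n_steps, 2), dtype=np.float32)
               if record_trajectories else None)
    th_rec = (np.empty((n_agents, n_steps), dtype=np.float32)
              if record_trajectories else None)
    walk_rec = (np.empty((n_agents, n_steps), dtype=bool)
                if record_trajectories else None)
    sig_rec = (np.empty((n_agents, n_steps), dtype=np.float32)
               if record_signals else None)
    n_frames = getattr(plume, "n_frames", None)

    for step in range(n_steps):
        frame = step % n_frames if n_frames else 0
        # --- sense
        th_r = np.deg2rad(theta)
        hx, hy = -np.cos(th_r), np.sin(th_r)
        px, py = -hy, hx  # perpendicular to the heading
        pts = np.empty((n_agents * offsets.shape[0], 2))
        for j, (u, v) in enumerate(offsets):
            pts[j::offsets.shape[0], 0] = x + u * hx + v * px
            pts[j::offsets.shape[0], 1] = y + u * hy + v * py
        vals = plume.intensity_at(frame, pts).reshape(n_agents, offsets.shape[0])
        signal = vals.mean(axis=1) + rng.normal(background.mean, background.sd,
                                                size=n_agents)
        if sig_rec is not None:
            sig_rec[:, step] = signal
        d_now = signal > thr
        # --- encounter registration (threshold + refractory)
        onset = d_now & (since_onset >= params.encounter_refractory)
        since_onset += dt
        dT += dt
        W_freq *= decay
        F_stop *= s_decay
        F_walk *= w_decay
        W_dur = W_dur * decay + d_now * dt
        if onset.any():
            W_freq[onset] += 1.0 / tau
            F_stop[onset] += 1.0
            F_walk[onset] += 1.0
            dT[onset] = 0.0
            since_onset[onset] = 0.0
            onset_W.append(W_freq[onset].copy())
        # --- transition hazards
        lam_ws = rate_from_features(params.stop_spec, dT=dT, F=F_stop, d=d_now)
        lam_sw = rate_from_features(params.walk_spec, dT=dT, F=F_walk, d=d_now)
        u01 = rng.random(n_agents)
        to_stop = walking & (u01 < lam_ws * dt)
        to_walk = ~walking & (u01 < lam_sw * dt)
        now = (step + 1) * dt  # bout boundaries at the end of the step
        for idx in np.flatnonzero(to_stop):
            walk_durs.append(now - bout_start[idx])
            bout_start[idx] = now
        for idx in np.flatnonzero(to_walk):
            stop_durs.append(now - bout_start[idx])
            bout_start[idx] = now
        walking = walking & ~to_stop | to_walk
        # --- saccades (walking agents only)
        lam_F = np.broadcast_to(full_turn_rate(tp, W_freq, W_dur),
                                (n_agents,))
        turn = walking & (rng.random(n_agents) < lam_F * dt)
        if turn.any():
            nt = int(turn.sum())
            mags = np.abs(rng.normal(tp.turn_mean, tp.turn_sd, size=nt))
            if params.fixed_upwind_probability is not None:
                p_up = np.full(nt, params.fixed_upwind_probability)
            else:
                p_up = upwind_turn_probability(tp.filter_tau * W_freq[turn],
                                               tp.alpha)
            up = rng.random(nt) < p_up
            tt = np.mod(theta[turn], 360.0)
            sgn = np.where(tt < 180.0, -1.0, 1.0)
            tie = np.isin(tt, (0.0, 180.0))
            if tie.any():
                sgn[tie] = rng.integers(0, 2, size=int(tie.sum())) * 2 - 1
            dth = np.where(up, sgn, -sgn) * mags
            theta[turn] = np.mod(theta[turn] + dth, 360.0)
            n_up += int((np.sign(dth) == sgn).sum())
            n_down += nt - int((np.sign(dth) == sgn).sum())
        jit = walking & ~turn
        theta[jit] = np.mod(theta[jit] + rng.normal(
            0.0, tp.straight_jitter_sd, size=int(jit.sum())), 360.0)
        # --- locomotion
        th_r = np.deg2rad(theta)
        x = x + walking * params.walk_speed * dt * (-np.cos(th_r))
        y = y + walking * params.walk_speed * dt * np.sin(th_r)
        out = (x < 0) | (x > lx) | (y < -ly / 2) | (y > ly / 2)
        if out.any():
            theta[out] = _resample_inward(rng, x[out], y[out], arena.extent)
            x = np.clip(x, 0.0, lx)
            y = np.clip(y, -ly / 2, ly / 2)
        hit = (~arrived & (x <= arena.source_box_length)
               & (np.abs(y) <= arena.source_box_width / 2))
        if hit.any():
            arrived[hit] = True
            arrival_times[hit] = now
        if pos_rec is not None:
            pos_rec[:, step, 0] = x
            pos_rec[:, step, 1] = y
            th_rec[:, step] = theta
            walk_rec[:, step] = walking
    return SimulationResult(
        n_agents=n_agents, n_steps=n_steps, time_step=dt, arrived=arrived,
        arrival_times=arrival_times,
        walk_durations=np.asarray(walk_durs), stop_durations=np.asarray(stop_durs),
        n_up_turns=n_up, n_down_turns=n_down,
        n_onsets=int(sum(a.size for a in onset_W)),
        onset_W_freq=(np.concatenate(onset_W) if onset_W else np.array([])),
        positions=pos_rec, theta=th_rec, walking=walk_rec, signals=sig_rec,
        params=params, arena=arena)


def ablate(params: AgentParams, component: str,
           reference: SimulationResult) -> AgentParams:
    """Replace one navigational component with its ensemble-average rate.

    ``stop``: the walk-to-stop hazard becomes the constant reciprocal of
    the exponential-fit timescale of the reference walk durations (the
    exponential MLE timescale is the sample mean).  ``walk``: analogous
    from the reference stop durations.  ``turn``: the upwind-turn
    probability is fixed at the reference's overall upwind-turn fraction.
    """
    if component == "stop":
        if reference.walk_durations.size == 0:
            raise ValueError("reference lacks completed walk bouts")
        lam = 1.0 / float(reference.walk_durations.mean())
        spec = RateModelSpec("last_encounter", "walk_to_stop",
                             dict(lam0=lam, dlam=0.0, tau=1.0))
        return replace(params, stop_spec=spec)
    if component == "walk":
        if reference.stop_durations.size == 0:
            raise ValueError("reference lacks completed stop bouts")
        lam = 1.0 / float(reference.stop_durations.mean())
        spec = RateModelSpec("last_encounter", "stop_to_walk",
                             dict(lam0=lam, dlam=0.0, tau=1.0))
        return replace(params, walk_spec=spec)
    if component == "turn":
        frac = reference.upwind_turn_fraction
        if not np.isfinite(frac):
            raise ValueError("reference lacks turns")
        return replace(params, fixed_upwind_probability=float(frac))
    raise ValueError("component must be one of 'turn', 'stop', 'walk'")


def performance_metrics(result: SimulationResult, control: SimulationResult,
                        n_boot: int = 30, seed=None) -> dict:
    """Fractional arrival and arrival-time changes versus a control.

    arrival_change = 100 (N_i - N_C) / N_C where N are arrival counts;
    time_change = 100 (T_C - T_i) / T_C where T are mean arrival times of
    arrived agents.  Standard errors from bootstrapping the agents
    ``n_boot`` times with replacement.  Undefined metrics (no control
    arrivals) are reported as nan.
    """
    if result.arena != control.arena:
        raise ValueError("results must share the same arena")
    rng = np.random.default_rng(seed)

    def metrics(r_arr, r_t, c_arr, c_t):
        n_i, n_c = r_arr.sum(), c_arr.sum()
        da = 100.0 * (n_i - n_c) / n_c if n_c else np.nan
        ti = np.nanmean(r_t) if n_i else np.nan
        tc = np.nanmean(c_t) if n_c else np.nan
        dtm = 100.0 * (tc - ti) / tc if n_c and n_i and tc else np.nan
        return da, dtm

    da, dtm = metrics(result.arrived, result.arrival_times,
                      control.arrived, control.arrival_times)
    boots = np.empty((n_boot, 2))
    for b in range(n_boot):
        ri = rng.integers(0, result.n_agents, size=result.n_agents)
        ci = rng.integers(0, control.n_agents, size=control.n_agents)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            boots[b] = metrics(result.arrived[ri], result.arrival_times[ri],
                               control.arrived[ci], control.arrival_times[ci])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(boots, axis=0, ddof=1)
    if not control.arrived.any():
        warnings.warn("control has no arrivals; metrics undefined")
    return dict(arrival_change_pct=da, arrival_change_se=float(se[0]),
                time_change_pct=dtm, time_change_se=float(se[1]),
                n_arrived=int(result.arrived.sum()),
                n_control=int(control.arrived.sum()))


def occupancy_pdf(result: SimulationResult, bin_mm: float = 1.0,
                  exclude_front_mm: float = 20.0,
                  min_duration: float = 5.0, min_mean_speed: float = 2.0,
                  min_displacement: float = 50.0) -> dict:
    """Normalized 2D occupancy histogram with x/y marginals.

    Trajectories shorter than ``min_duration``, with mean speed below
    ``min_mean_speed``, or maximum displacement from start below
    ``min_displacement`` are excluded.  Unvisited bins are nan in the pdf
    (distinct from visited zero-probability bins -- which cannot occur in a
    count histogram, but the distinction is preserved for masking).
    Marginals exclude the front ``exclude_front_mm`` of the arena (the
    region nearest the source).
    """
    if result.positions is None:
        raise ValueError("run with record_trajectories=True")
    lx, ly = result.arena.extent
    dt = result.time_step
    counts = np.zeros((int(np.ceil(ly / bin_mm)), int(np.ceil(lx / bin_mm))))
    kept = 0
    for a in range(result.n_agents):
        p = result.positions[a].astype(float)
        dur = p.shape[0] * dt
        path = np.hypot(*np.diff(p, axis=0).T).sum()
        disp = np.hypot(p[:, 0] - p[0, 0], p[:, 1] - p[0, 1]).max()
        if dur < min_duration or path / dur < min_mean_speed or disp < min_displacement:
            continue
        kept += 1
        ix = np.clip((p[:, 0] / bin_mm).astype(int), 0, counts.shape[1] - 1)
        iy = np.clip(((p[:, 1] + ly / 2) / bin_mm).astype(int), 0,
                     counts.shape[0] - 1)
        np.add.at(counts, (iy, ix), 1)
    if kept == 0:
        warnings.warn("all trajectories filtered out; empty occupancy")
        return dict(pdf=None, x_marginal=None, y_marginal=None, n_kept=0)
    pdf = counts / counts.sum()
    pdf_masked = np.where(counts > 0, pdf, np.nan)
    skip = int(np.ceil(exclude_front_mm / bin_mm))
    sub = pdf[:, skip:]
    x_marg = sub.sum(axis=0)
    y_marg = sub.sum(axis=1)
    return dict(pdf=pdf_masked, x_marginal=x_marg, y_marginal=y_marg,
                n_kept=kept, bin_mm=bin_mm)
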