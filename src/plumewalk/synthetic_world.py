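"""Synthetic plumes, encounter trains, and ground-truth-labeled behavior.

The plume generator emulates the walking-arena apparatus: a steady
downwind flow (150 mm/s) perturbed by lateral jets that alternate sides at
a Poisson rate (100 ms correlation time), producing a meandering, highly
intermittent plume.  The mechanism is deliberately simple: discrete odor
packets are emitted at the source at a Poisson rate, advected downwind at
the mean flow speed, displaced laterally by a shared two-state telegraph
cross-wind velocity, and rendered as Gaussian blobs whose radius grows
linearly with age (peak intensity decays with the radius squared,
conserving packet mass in 2D).  This is the simplest generator that
reproduces a conical intermittency map and broad, clumpy encounter/blank
statistics; it makes no attempt at turbulence-resolving fluid dynamics.

Coordinates: the origin sits at the odor source on the upwind wall, x
increases downwind, y is centered on the source.  All positions are in mm
and continuous; rasterization to pixels happens only when rendering movies.
Orientation angles are wind-relative: theta = 0 faces upwind (-x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_encounters import EncounterSeries
from .stopwalk_models import RateModelSpec, simulate_transitions
from .turn_model import TurnModelParams, simulate_turn_model

__all__ = [
    "PlumeConfig",
    "PlumeMovie",
    "PlumeField",
    "EncounterTrainConfig",
    "GroundTruthBehavior",
    "generate_plume_field",
    "generate_plume_movie",
    "generate_encounter_train",
    "generate_clumped_train",
    "simulate_ground_truth_behavior",
]


@dataclass
class PlumeConfig:
    """Apparatus and calibration parameters of the synthetic plume.

    Flow, switching, and geometry values mirror the walking-arena
    apparatus; ``packet_emission_rate``, ``packet_growth_rate``,
    ``packet_initial_radius``, ``packet_peak_intensity`` and
    ``lateral_gain`` are free calibration knobs of the packet generator,
    tuned once so that full-model agents perceive encounters of ~200 ms
    mean duration at ~4 Hz mean encounter frequency.
    """

    mean_flow_speed: float = 150.0      # mm/s downwind advection
    jet_switch_rate: float = 10.0       # 1/s telegraph switching (100 ms)
    jet_speed: float = 1500.0           # mm/s lateral jet speed
    lateral_gain: float = 0.065         # fraction of jet speed imparted laterally
    packet_emission_rate: float = 13.0  # packets / s
    packet_growth_rate: float = 2.8     # mm/s radius growth
    packet_initial_radius: float = 2.5  # mm
    packet_peak_intensity: float = 150.0
    source_position: tuple = (0.0, 0.0)
    arena_size: tuple = (300.0, 180.0)  # mm (downwind, crosswind)
    frame_rate: float = 90.0            # Hz
    pixel_size: float = 0.154           # mm (camera resolution)
    background_mean: float = 3.0        # intensity units (shot-noise floor)
    background_noise_sd: float = 1.5    # intensity units
    seed: int = 0

    def __post_init__(self):
        for name in ("mean_flow_speed", "jet_switch_rate", "jet_speed",
                     "frame_rate", "pixel_size", "packet_growth_rate",
                     "packet_initial_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.packet_emission_rate < 0:
            raise ValueError("packet_emission_rate must be non-negative")
        if self.arena_size[0] <= 0 or self.arena_size[1] <= 0:
            raise ValueError("arena dimensions must be positive")


@dataclass
class PlumeMovie:
    """Rasterized intensity stack (frame, y, x) on the 0-255 camera scale."""

    frames: np.ndarray
    frame_rate: float
    pixel_size: float
    source_position: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (frame, y, x) stack")

    @property
    def arena_size(self) -> tuple:
        ny, nx = self.frames.shape[1:]
        return (nx * self.pixel_size, ny * self.pixel_size)

    @property
    def duration(self) -> float:
        return self.frames.shape[0] / self.frame_rate

    @property
    def time_step(self) -> float:
        return 1.0 / self.frame_rate


class PlumeField:
    """Analytic (packet-list) representation of the plume.

    Holds the emitted packet states and evaluates the noiseless intensity
    at arbitrary points and frames, without rasterizing.  A burn-in period
    of one full packet transit precedes frame 0 so the plume is developed
    from the first frame.
    """

    def __init__(self, config: PlumeConfig, duration: float, rng=None):
        self.config = config
        dt = 1.0 / config.frame_rate
        n_frames = int(round(duration / dt))
        if abs(n_frames * dt - duration) > 1e-9 or n_frames <= 0:
            raise ValueError("duration must be a positive multiple of the "
                             "frame interval")
        self.n_frames = n_frames
        rng = np.random.default_rng(config.seed if rng is None else rng)
        u = config.mean_flow_speed
        self.max_age = (config.arena_size[0] +
                        4 * (config.packet_initial_radius +
                             config.packet_growth_rate * 3.0)) / u
        self.n_burn = int(np.ceil(self.max_age / dt))
        n_total = n_frames + self.n_burn
        # shared telegraph cross-wind velocity
        v_lat = config.jet_speed * config.lateral_gain
        sign = np.empty(n_total)
        s = rng.choice([-1.0, 1.0])
        flips = rng.random(n_total) < config.jet_switch_rate * dt
        for i in range(n_total):
            if flips[i]:
                s = -s
            sign[i] = s
        self._Y = np.concatenate(([0.0], np.cumsum(sign * v_lat * dt)))
        # Poisson packet emission (at most one per frame step)
        emit = rng.random(n_total) < config.packet_emission_rate * dt
        self._emit_frames = np.flatnonzero(emit)
        self._dt = dt

    def packet_states(self, frame: int):
        """(x, y, radius, amplitude) arrays of packets alive at a frame."""
        cfg = self.config
        fi = frame + self.n_burn
        age_max_frames = int(self.max_age / self._dt)
        lo = np.searchsorted(self._emit_frames, fi - age_max_frames)
        hi = np.searchsorted(self._emit_frames, fi, side="right")
        fe = self._emit_frames[lo:hi]
        age = (fi - fe) * self._dt
        x = cfg.source_position[0] + cfg.mean_flow_speed * age
        y = cfg.source_position[1] + (self._Y[fi] - self._Y[fe])
        r = cfg.packet_initial_radius + cfg.packet_growth_rate * age
        amp = cfg.packet_peak_intensity * (cfg.packet_initial_radius / r) ** 2
        keep = x <= cfg.arena_size[0] + 3 * r
        return x[keep], y[keep], r[keep], amp[keep]

    def intensity_at(self, frame: int, points: np.ndarray) -> np.ndarray:
        """Noiseless odor intensity at (n, 2) points for one frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, r, amp = self.packet_states(frame)
        if x.size == 0:
            return np.zeros(pts.shape[0])
        dx = pts[:, 0, None] - x[None, :]
        dy = pts[:, 1, None] - y[None, :]
        g = amp[None, :] * np.exp(-(dx * dx + dy * dy) / (2.0 * r[None, :] ** 2))
        return g.sum(axis=1)

    def render_movie(self, pixel_size: float | None = None, rng=None) -> PlumeMovie:
        """Rasterize to a PlumeMovie with background shot noise added.

        Each packet is painted only within 3 radii of its center.  Rendering
        at the full camera resolution over a long duration is memory-heavy;
        pass a coarser ``pixel_size`` for analysis-scale movies.
        """
        cfg = self.config
        ps = pixel_size or cfg.pixel_size
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, 0xB0B]))\
            if rng is None else np.random.default_rng(rng)
        lx, ly = cfg.arena_size
        nx, ny = int(round(lx / ps)), int(round(ly / ps))
        frames = np.empty((self.n_frames, ny, nx), dtype=np.uint8)
        px = (np.arange(nx) + 0.5) * ps
        py = (np.arange(ny) + 0.5) * ps - ly / 2
        for f in range(self.n_frames):
            img = rng.normal(cfg.background_mean, cfg.background_noise_sd,
                             size=(ny, nx))
            x, y, r, amp = self.packet_states(f)
            for xi, yi, ri, ai in zip(x, y, r, amp):
                ix0 = max(int((xi - 3 * ri) / ps), 0)
                ix1 = min(int((xi + 3 * ri) / ps) + 1, nx)
                iy0 = max(int((yi + ly / 2 - 3 * ri) / ps), 0)
                iy1 = min(int((yi + ly / 2 + 3 * ri) / ps) + 1, ny)
                if ix0 >= ix1 or iy0 >= iy1:
                    continue
                dx = px[ix0:ix1] - xi
                dy = py[iy0:iy1] - yi
                img[iy0:iy1, ix0:ix1] += ai * np.exp(
                    -(dx[None, :] ** 2 + dy[:, None] ** 2) / (2 * ri ** 2))
            frames[f] = np.clip(img, 0, 255).astype(np.uint8)
        return PlumeMovie(frames=frames, frame_rate=cfg.frame_rate,
                          pixel_size=ps, source_position=cfg.source_position)


def generate_plume_field(config: PlumeConfig, duration: float) -> PlumeField:
    """Simulate the packet plume without rasterizing (for agent sampling)."""
    return PlumeField(config, duration)


def generate_plume_movie(config: PlumeConfig, duration: float,
                         pixel_size: float | None = None) -> PlumeMovie:
    """Simulate and rasterize a plume movie; reproducible from config.seed."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return PlumeField(config, duration).render_movie(pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# encounter trains


@dataclass
class EncounterTrainConfig:
    """Driver for synthetic encounter trains with known statistics.

    ``duration_sampler`` is (name, params) with names: "constant"
    (``value``), "exponential" (``mean``), "pareto" (``alpha``, ``minimum``)
    -- all durations in seconds.
    """

    onset_rate: float = 4.0
    duration_sampler: tuple = ("constant", {"value": 0.2})
    total_time: float = 60.0
    time_step: float = 1.0 / 90.0
    seed: int = 0

    def __post_init__(self):
        if self.onset_rate < 0:
            raise ValueError("onset_rate must be non-negative")
        if self.onset_rate > 0 and self.total_time < 1.0 / self.onset_rate:
            raise ValueError("total_time shorter than one expected interval")


def _sample_durations(sampler: tuple, n: int, rng) -> np.ndarray:
    name, p = sampler
    if name == "constant":
        return np.full(n, float(p["value"]))
    if name == "exponential":
        return rng.exponential(p["mean"], size=n)
    if name == "pareto":
        return p["minimum"] * (1.0 + rng.pareto(p["alpha"], size=n))
    raise ValueError(f"unknown duration sampler {name!r}")


def generate_encounter_train(config: EncounterTrainConfig) -> EncounterSeries:
    """Poisson onsets with sampled durations; overlaps merged.

    At most one onset per time step; an onset sampled while a previous
    encounter is still active extends that encounter instead of starting a
    new one (one onset, the first).
    """
    rng = np.random.default_rng(config.seed)
    dt = config.time_step
    n = int(round(config.total_time / dt))
    onsets = np.flatnonzero(rng.random(n) < config.onset_rate * dt)
    durs = _sample_durations(config.duration_sampler, onsets.size, rng)
    if np.any(durs <= 0):
        raise ValueError("sampled durations must be positive")
    intervals = []
    for o, du in zip(onsets, durs):
        end = min(o + max(int(round(du / dt)), 1), n)
        if intervals and o < intervals[-1][1]:
            intervals[-1][1] = max(intervals[-1][1], end)
        else:
            intervals.append([o, end])
    return EncounterSeries.from_intervals([tuple(iv) for iv in intervals], n, dt)


def generate_clumped_train(total_time: float, time_step: float = 1.0 / 90.0,
                           event_rate: float = 1.2, clump_size: int = 8,
                           clump_prob: float = 0.5, intra_interval: float = 0.1,
                           duration: float = 0.05, seed=None) -> EncounterSeries:
    """Encounter train mixing isolated onsets with fixed-size clumps.

    Events arrive at a Poisson rate; each is either a single onset or a
    clump of ``clump_size`` onsets spaced ``intra_interval`` apart.  This
    design dissociates reset-type rate responses (identical after a single
    onset and after a clump) from accumulation-type responses (scaling with
    the number of recent onsets), and is the recommended stimulus ensemble
    for model-recovery and model-comparison experiments.
    """
    rng = np.random.default_rng(seed)
    n = int(round(total_time / time_step))
    idx, last = [], 0
    t = rng.exponential(1.0 / event_rate)
    while t < total_time - 2.0:
        size = clump_size if rng.random() < clump_prob else 1
        for k in range(size):
            a = int((t + k * intra_interval) / time_step)
            b = min(a + max(int(round(duration / time_step)), 1), n)
            if a >= last and b > a:
                idx.append((a, b))
                last = b
        t += max(rng.exponential(1.0 / event_rate),
                 size * intra_interval + 0.4)
    return EncounterSeries.from_intervals(idx, n, time_step)


# ---------------------------------------------------------------------------
# ground-truth behavior


@dataclass
class GroundTruthBehavior:
    """A labeled synthetic trajectory with its generating parameters."""

    walking: np.ndarray          # bool per step
    turn_times: np.ndarray       # s
    turn_angles: np.ndarray      # signed deg
    theta: np.ndarray            # deg, wind-relative
    encounters: EncounterSeries
    turn_params: TurnModelParams
    stop_spec: RateModelSpec
    walk_spec: RateModelSpec
    time_step: float

    def walk_bouts(self):
        return _bout_list(self.walking, True, self.time_step)

    def stop_bouts(self):
        return _bout_list(self.walking, False, self.time_step)


def _bout_list(walking: np.ndarray, value: bool, dt: float):
    """(start_s, stop_s, censored) bouts of the given state."""
    w = np.asarray(walking, dtype=bool)
    change = np.flatnonzero(np.diff(w.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [w.size]))
    out = []
    for a, b in zip(starts, stops):
        if w[a] == value:
            out.append((a * dt, b * dt, b == w.size))
    return out


def simulate_ground_truth_behavior(turn_params: TurnModelParams,
                                   stop_spec: RateModelSpec,
                                   walk_spec: RateModelSpec,
                                   encounters, n_trajectories: int,
                                   seed=None, time_step: float | None = None
                                   ) -> list[GroundTruthBehavior]:
    """Simulate labeled walk/stop + turning behavior on encounter trains.

    ``encounters`` is one EncounterSeries (shared by all trajectories) or a
    sequence of length ``n_trajectories``.  Walk/stop transitions follow
    the two rate specs; the saccade model runs during walk bouts only
    (orientation frozen during stops).  Reproducible from ``seed``.
    """
    if stop_spec.direction != "walk_to_stop":
        raise ValueError("stop_spec must be walk_to_stop")
    if walk_spec.direction != "stop_to_walk":
        raise ValueError("walk_spec must be stop_to_walk")
    if isinstance(encounters, EncounterSeries):
        trains = [encounters] * n_trajectories
    else:
        trains = list(encounters)
        if len(trains) != n_trajectories:
            raise ValueError("need one encounter train per trajectory")
    if time_step is not None and abs(trains[0].time_step - time_step) > 1e-12:
        raise ValueError("encounter train time step does not match requested dt")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_trajectories)
    out = []
    for train, child in zip(trains, children):
        rng = np.random.default_rng(child)
        dt = train.time_step
        walking = simulate_transitions(stop_spec, walk_spec, train.w, train.d,
                                       dt, rng=rng)
        trace = simulate_turn_model(turn_params, train,
                                    seed=rng.integers(2 ** 31),
                                    walking_mask=walking)
        out.append(GroundTruthBehavior(
            walking=walking, turn_times=trace.turn_times,
            turn_angles=trace.turn_angles, theta=trace.theta,
            encounters=train, turn_params=turn_params,
            stop_spec=stop_spec, walk_spec=walk_spec, time_step=dt))
    return out
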