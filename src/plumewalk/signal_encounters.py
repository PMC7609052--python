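"""Signal extraction, encounter detection, and plume-level statistics.

A "signal" is the intensity perceived by an observer (a tracked fly or a
simulated agent) through a small virtual antenna patch.  An "encounter" is a
contiguous interval during which that signal exceeds a sensory threshold set
at ``k`` standard deviations above the camera background, subject to a
minimum-duration persistence rule that suppresses detections produced by
shot noise.  From the binary encounter train three causal exponentially
filtered signals are derived: the encounter frequency W_freq (Hz), the
encounter exposure W_dur (s), and the filtered raw signal W_conc (intensity
units), all with the same timescale tau (default 2 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from ._filters import (causal_exp_filter, exposure_exp_filter,
                       min_samples_for, persistent_intervals)

__all__ = [
    "SignalTrace",
    "BackgroundModel",
    "EncounterDetectionConfig",
    "EncounterSeries",
    "FilteredSignals",
    "AntennaGeometry",
    "extract_virtual_antenna_signal",
    "fit_background",
    "detect_encounters",
    "compute_filtered_signals",
    "intermittency_map",
    "duration_distributions",
    "directional_encounter_probability",
]


@dataclass
class SignalTrace:
    """Per-frame antenna intensity s(t) on the 0-255 camera scale."""

    values: np.ndarray
    time_step: float
    valid_mask: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.size != self.values.size:
            raise ValueError("valid_mask length mismatch")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        bad = ~np.isfinite(self.values) & self.valid_mask
        if bad.any():
            raise ValueError("non-finite signal values on valid steps")


@dataclass
class BackgroundModel:
    """Gaussian model of the odor-free (shot-noise) signal distribution."""

    mean: float
    sd: float

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError("background sd must be positive")

    def threshold(self, k_sigma: float) -> float:
        return self.mean + k_sigma * self.sd


@dataclass
class EncounterDetectionConfig:
    k_sigma: float = 2.5
    min_encounter_duration: float = 0.050  # s

    def __post_init__(self):
        if self.min_encounter_duration <= 0:
            raise ValueError("min_encounter_duration must be positive")


@dataclass
class EncounterSeries:
    """Binary onset train w(t), binary exposure d(t), and interval list.

    w(t) carries a single unit impulse at the first above-threshold step of
    each encounter; d(t) is 1 exactly inside encounter intervals.  Intervals
    are half-open [onset, offset) in seconds, non-overlapping and ordered.
    """

    w: np.ndarray
    d: np.ndarray
    intervals: list
    time_step: float
    threshold_used: float = np.nan

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=np.uint8)
        self.d = np.asarray(self.d, dtype=np.uint8)
        if self.w.size != self.d.size:
            raise ValueError("w and d must have equal length")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @classmethod
    def from_intervals(cls, intervals_idx, n_steps: int, time_step: float,
                       threshold: float = np.nan) -> "EncounterSeries":
        """Build from half-open *index* intervals [start, stop)."""
        w = np.zeros(n_steps, dtype=np.uint8)
        d = np.zeros(n_steps, dtype=np.uint8)
        secs = []
        prev_stop = 0
        for a, b in intervals_idx:
            if not (0 <= a < b <= n_steps) or a < prev_stop:
                raise ValueError("intervals must be ordered, non-overlapping, in range")
            prev_stop = b
            w[a] = 1
            d[a:b] = 1
            secs.append((a * time_step, b * time_step))
        return cls(w=w, d=d, intervals=secs, time_step=time_step,
                   threshold_used=threshold)

    @property
    def n_encounters(self) -> int:
        return int(self.w.sum())

    @property
    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals])

    @property
    def onset_times(self) -> np.ndarray:
        return np.flatnonzero(self.w) * self.time_step


@dataclass
class FilteredSignals:
    """The three exponentially filtered perceptual signals."""

    W_freq: np.ndarray  # Hz
    W_dur: np.ndarray   # s
    W_conc: np.ndarray  # intensity units
    tau: float = 2.0
    time_step: float = 1.0 / 90.0


@dataclass
class AntennaGeometry:
    """Elliptical virtual-antenna patch ahead of the observer's head.

    The patch center sits ``center_offset`` mm ahead along the heading; the
    semi-major axis (``semi_major``) is oriented perpendicular to the
    heading, emulating the paired antennae spanning the head width.
    """

    center_offset: float = 2.16  # mm ahead of the body center
    semi_major: float = 0.77     # mm, perpendicular to heading
    semi_minor: float = 0.23     # mm, along heading

    def sample_offsets(self, n_radial: int = 2, n_angular: int = 8) -> np.ndarray:
        """Deterministic quadrature offsets (in the body frame, x = heading)
        used to approximate the patch-mean intensity: the ellipse center plus
        rings of points at fractional radii."""
        pts = [(self.center_offset, 0.0)]
        for i in range(1, n_radial + 1):
            f = i / (n_radial + 0.5)
            for j in range(n_angular):
                ang = 2 * np.pi * (j + 0.5 * (i % 2)) / n_angular
                pts.append((self.center_offset + f * self.semi_minor * np.cos(ang),
                            f * self.semi_major * np.sin(ang)))
        return np.asarray(pts)


def heading_vector(theta_deg):
    """Unit heading for the wind-relative angle convention.

    theta = 0 faces upwind (the -x direction, toward the source); theta
    increases toward +y; theta = 180 faces downwind (+x).
    """
    th = np.deg2rad(theta_deg)
    return -np.cos(th), np.sin(th)


def _patch_pixel_mask(movie, x: float, y: float, theta_deg: float,
                      geom: AntennaGeometry):
    """Pixel indices of the antenna ellipse for a pose, or None if the patch
    leaves the arena."""
    hx, hy = heading_vector(theta_deg)
    cx = x + geom.center_offset * hx
    cy = y + geom.center_offset * hy
    ny, nx = movie.frames.shape[1:]
    ps = movie.pixel_size
    half_extent = geom.semi_major + ps
    ix0 = int(np.floor((cx - half_extent) / ps))
    ix1 = int(np.ceil((cx + half_extent) / ps)) + 1
    ly = movie.arena_size[1]
    iy0 = int(np.floor((cy - half_extent + ly / 2) / ps))
    iy1 = int(np.ceil((cy + half_extent + ly / 2) / ps)) + 1
    if ix0 < 0 or iy0 < 0 or ix1 > nx or iy1 > ny:
        return None
    ix = np.arange(ix0, ix1)
    iy = np.arange(iy0, iy1)
    px = (ix + 0.5) * ps
    py = (iy + 0.5) * ps - ly / 2
    dx = px[None, :] - cx
    dy = py[:, None] - cy
    # body frame: u along heading (semi-minor), v perpendicular (semi-major)
    u = dx * hx + dy * hy
    v = -dx * hy + dy * hx
    inside = (u / geom.semi_minor) ** 2 + (v / geom.semi_major) ** 2 <= 1.0
    if not inside.any():
        # patch smaller than one pixel at this resolution: use nearest pixel
        jx = min(max(int(cx / ps), 0), nx - 1)
        jy = min(max(int((cy + ly / 2) / ps), 0), ny - 1)
        return np.array([jy]), np.array([jx])
    yy, xx = np.nonzero(inside)
    return iy[yy], ix[xx]


def extract_virtual_antenna_signal(movie, trajectory, geom: AntennaGeometry | None = None
                                   ) -> SignalTrace:
    """Mean intensity over the antenna patch for each trajectory frame.

    ``trajectory`` is an array-like of shape (n, 3) with columns (x_mm, y_mm,
    theta_deg) aligned with the movie frames, or (n, 4) with a leading time
    column (which must match the movie frame times).  Frames where the patch
    exits the arena are flagged invalid.
    """
    geom = geom or AntennaGeometry()
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 2 or traj.shape[1] not in (3, 4):
        raise ValueError("trajectory must have columns (x, y, theta) or (t, x, y, theta)")
    if traj.shape[1] == 4:
        t = traj[:, 0]
        dt = 1.0 / movie.frame_rate
        if not np.allclose(np.diff(t), dt, atol=dt * 1e-3):
            raise ValueError("trajectory timestamps do not align with movie frames")
        traj = traj[:, 1:]
    n = min(traj.shape[0], movie.frames.shape[0])
    values = np.zeros(n)
    valid = np.zeros(n, dtype=bool)
    for i in range(n):
        m = _patch_pixel_mask(movie, traj[i, 0], traj[i, 1], traj[i, 2], geom)
        if m is None:
            continue
        values[i] = float(movie.frames[i][m].mean())
        valid[i] = True
    if not valid.any():
        warnings.warn("trajectory outside arena for all frames; empty trace")
    return SignalTrace(values=values, time_step=1.0 / movie.frame_rate,
                       valid_mask=valid)


def fit_background(traces) -> BackgroundModel:
    """Gaussian fit to the dominant (background) mode of pooled signal values.

    Robust to a minority of above-background (odor-containing) samples: the
    mode of the histogram is located first and the Gaussian is fit only to
    samples below mode + 3 * (a robust initial scale), then refined once.
    """
    if isinstance(traces, SignalTrace):
        traces = [traces]
    pooled = np.concatenate([t.values[t.valid_mask] for t in traces])
    if pooled.size < 100:
        raise ValueError("need at least 100 valid samples to fit the background")
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate constant signal: background sd would be 0")
    med = np.median(pooled)
    mad = stats.median_abs_deviation(pooled, scale="normal")
    if mad == 0:
        mad = pooled.std() or 1.0
    sub = pooled[pooled <= med + 3 * mad]
    mean, sd = float(sub.mean()), float(sub.std())
    for _ in range(3):  # refine the mode restriction
        sub = pooled[pooled <= mean + 3 * sd]
        mean, sd = float(sub.mean()), float(sub.std())
    if sd <= 0:
        raise ValueError("degenerate signal: fitted background sd is 0")
    return BackgroundModel(mean=mean, sd=sd)


def detect_encounters(trace: SignalTrace, bg: BackgroundModel,
                      cfg: EncounterDetectionConfig | None = None) -> EncounterSeries:
    """Threshold the signal at mean + k*sd with symmetric persistence.

    Both the onset and the offset require the signal to stay on its side of
    the threshold for at least ``min_encounter_duration``; shorter excursions
    in either direction are ignored.  Invalid steps break intervals.
    """
    cfg = cfg or EncounterDetectionConfig()
    dt = trace.time_step
    if cfg.min_encounter_duration < dt:
        raise ValueError("min_encounter_duration is shorter than one time step")
    min_samples = min_samples_for(cfg.min_encounter_duration, dt)
    thr = bg.threshold(cfg.k_sigma)
    above = (trace.values > thr) & trace.valid_mask
    intervals = []
    # persistence applied independently within each contiguous valid segment
    vm = trace.valid_mask
    seg_starts = np.flatnonzero(vm & ~np.roll(vm, 1)) if vm.any() else []
    if vm.size and vm[0]:
        seg_starts = np.concatenate(([0], seg_starts[seg_starts != 0])) if len(seg_starts) else np.array([0])
    for a in np.atleast_1d(seg_starts):
        b = a
        while b < vm.size and vm[b]:
            b += 1
        for i, j in persistent_intervals(above[a:b], min_samples):
            intervals.append((a + i, a + j))
    return EncounterSeries.from_intervals(intervals, trace.values.size, dt,
                                          threshold=thr)


def compute_filtered_signals(enc: EncounterSeries, trace: SignalTrace | None = None,
                             tau: float = 2.0) -> FilteredSignals:
    """The three causal exponentially filtered signals.

    W_freq is normalized by 1/tau so that a steady onset rate r (Hz) maps to
    W_freq -> r; W_dur and W_conc are Riemann-sum convolutions (a constant
    d(t) = 1 gives W_dur -> tau).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    dt = enc.time_step
    if trace is not None and abs(trace.time_step - dt) > 1e-12:
        raise ValueError("trace and encounter series have inconsistent time steps")
    W_freq = causal_exp_filter(enc.w, tau, dt, normalize=True)
    W_dur = exposure_exp_filter(enc.d, tau, dt)
    if trace is not None:
        W_conc = exposure_exp_filter(np.where(trace.valid_mask, trace.values, 0.0),
                                     tau, dt)
    else:
        W_conc = np.zeros_like(W_dur)
    return FilteredSignals(W_freq=W_freq, W_dur=W_dur, W_conc=W_conc, tau=tau,
                           time_step=dt)


def intermittency_map(movie, bg: BackgroundModel,
                      cfg: EncounterDetectionConfig | None = None,
                      median_filter_mm: float = 2.3) -> np.ndarray:
    """Per-pixel fraction of frames above the sensory threshold.

    Frames are spatially median-filtered (square window, default 2.3 mm)
    before thresholding; a window of one pixel or less disables filtering.
    """
    cfg = cfg or EncounterDetectionConfig()
    if movie.frames.shape[0] / movie.frame_rate <= 10:
        raise ValueError("movie must be longer than 10 s for a stable map")
    thr = bg.threshold(cfg.k_sigma)
    k = int(round(median_filter_mm / movie.pixel_size))
    counts = np.zeros(movie.frames.shape[1:], dtype=np.int64)
    for frame in movie.frames:
        f = frame if k <= 1 else ndimage.median_filter(frame, size=k)
        counts += f > thr
    return counts / movie.frames.shape[0]


def _pixel_signal(movie, x: float, y: float) -> np.ndarray:
    ps = movie.pixel_size
    ly = movie.arena_size[1]
    ix = int(x / ps)
    iy = int((y + ly / 2) / ps)
    ny, nx = movie.frames.shape[1:]
    if not (0 <= ix < nx and 0 <= iy < ny):
        raise ValueError(f"point ({x}, {y}) outside arena")
    return movie.frames[:, iy, ix].astype(float)


def fit_powerlaw_tail(durations: np.ndarray, n_decades: float = 1.5,
                      min_count: int = 50, upper_quantile: float = 0.995):
    """Least-squares power-law fit to the tail of a duration distribution.

    Durations are log-binned and the density exponent is fit over a window
    of ``n_decades`` decades ending at the ``upper_quantile`` duration (the
    quantile anchor keeps the window off the noise-dominated extreme order
    statistics of heavy-tailed samples).  Returns (exponent, curvature):
    curvature is the quadratic coefficient of a second-order fit in log-log
    space, a diagnostic that flags non-power-law (e.g. exponential) tails,
    whose log-log density is strongly concave.  The exponent is reported
    for the probability *density* (a survival-tail index a gives density
    exponent -(a+1)).
    """
    durations = np.asarray(durations, dtype=float)
    durations = durations[durations > 0]
    if durations.size < min_count:
        return np.nan, np.nan
    lo, hi = durations.min(), float(np.quantile(durations, upper_quantile))
    if hi / lo < 10 ** 0.5:
        return np.nan, np.nan
    edges = np.logspace(np.log10(lo), np.log10(hi), 25)
    counts, edges = np.histogram(durations, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / (widths * durations.size)
    keep = (dens > 0) & (centers >= hi / 10 ** n_decades)
    if keep.sum() < 4:
        return np.nan, np.nan
    lx, ly_ = np.log10(centers[keep]), np.log10(dens[keep])
    slope = np.polyfit(lx, ly_, 1)[0]
    curv = np.polyfit(lx, ly_, 2)[0]
    return float(slope), float(curv)


def duration_distributions(movie, points, bg: BackgroundModel,
                           cfg: EncounterDetectionConfig | None = None,
                           tail_decades: float = 1.5) -> list[dict]:
    """Per-point encounter/blank duration samples and power-law tail fits.

    For each (x, y) point, the single-pixel signal is thresholded (with the
    configured persistence) and the encounter and blank duration lists are
    returned together with log-log tail exponents of their densities.  With
    fewer than 50 encounters the exponent is reported as nan (undefined).
    """
    cfg = cfg or EncounterDetectionConfig()
    out = []
    dt = 1.0 / movie.frame_rate
    for (x, y) in points:
        sig = _pixel_signal(movie, x, y)
        trace = SignalTrace(values=sig, time_step=dt)
        enc = detect_encounters(trace, bg, cfg)
        durs = enc.durations
        blanks = np.array([b[0] - a[1] for a, b in zip(enc.intervals[:-1],
                                                       enc.intervals[1:])])
        exp_e, curv_e = fit_powerlaw_tail(durs, tail_decades)
        exp_b, curv_b = fit_powerlaw_tail(blanks, tail_decades)
        out.append(dict(point=(x, y), encounter_durations=durs,
                        blank_durations=blanks,
                        encounter_tail_exponent=exp_e,
                        encounter_tail_curvature=curv_e,
                        blank_tail_exponent=exp_b,
                        blank_tail_curvature=curv_b))
    return out


def directional_encounter_probability(movie, origin, bg: BackgroundModel,
                                      cfg: EncounterDetectionConfig | None = None,
                                      speed: float = 10.0, horizon: float = 1.0,
                                      n_headings: int = 16,
                                      frame_stride: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Probability of an odor encounter within ``horizon`` seconds of walking
    straight from ``origin`` at ``speed``, as a function of heading.

    For each start frame (subsampled by ``frame_stride``) and heading, the
    walk samples the single-pixel signal along its path through subsequent
    frames; a heading scores a hit if the signal exceeds the threshold at any
    step.  Returns (headings_deg, probability).
    """
    cfg = cfg or EncounterDetectionConfig()
    thr = bg.threshold(cfg.k_sigma)
    ox, oy = origin
    lx, ly = movie.arena_size
    if not (0 <= ox <= lx and -ly / 2 <= oy <= ly / 2):
        raise ValueError("origin outside arena")
    dt = 1.0 / movie.frame_rate
    n_sub = int(round(horizon / dt))
    headings = np.arange(n_headings) * (360.0 / n_headings)
    nt = movie.frames.shape[0]
    starts = np.arange(0, nt - n_sub, frame_stride)
    ps = movie.pixel_size
    ny, nx = movie.frames.shape[1:]
    probs = np.zeros(n_headings)
    for hi, h in enumerate(headings):
        hx, hy = heading_vector(h)
        xs = ox + speed * dt * np.arange(n_sub) * hx
        ys = oy + speed * dt * np.arange(n_sub) * hy
        ix = np.clip((xs / ps).astype(int), 0, nx - 1)
        iy = np.clip(((ys + ly / 2) / ps).astype(int), 0, ny - 1)
        steps = np.arange(n_sub)
        hits = 0
        for s in starts:
            path = movie.frames[s + steps, iy, ix]
            if (path > thr).any():
                hits += 1
        probs[hi] = hits / starts.size
    return headings, probs
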