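"""Shared low-level numerics: causal exponential filters and persistence
thresholding.

These primitives are used by several modules (encounter detection, event
segmentation, rate models) and are kept free of domain types so they can be
tested against closed forms in isolation.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as _sig


def causal_exp_filter(x: np.ndarray, tau: float, dt: float, *,
                      normalize: bool = False) -> np.ndarray:
    """Causal exponential filter y[i] = decay * y[i-1] + x[i] * gain.

    With ``normalize=False`` this is the plain discrete convolution of ``x``
    with the kernel exp(-t/tau) sampled at ``dt`` (gain = 1); a unit impulse
    produces a decaying exponential starting at 1.  With ``normalize=True``
    the gain is 1/tau, so a steady train of unit impulses arriving at rate r
    (in 1/s) converges to r -- the convention used for the encounter
    frequency signal, whose units are then Hz.

    Filter state before the first sample is zero (nothing before recording).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(x, dtype=float)
    decay = np.exp(-dt / tau)
    gain = 1.0 / tau if normalize else 1.0
    # y[i] = decay*y[i-1] + gain*x[i]  ==  IIR filter b=[gain], a=[1, -decay]
    return _sig.lfilter([gain], [1.0, -decay], x)


def exposure_exp_filter(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Riemann-sum exponential filter: integral of exp(-(t-t')/tau) x(t') dt'.

    For x == 1 the output converges to dt / (1 - exp(-dt/tau)) ~= tau as
    dt -> 0; used for the exposure (duration) and concentration signals,
    whose units are s and intensity respectively.
    """
    return causal_exp_filter(x, tau, dt) * dt


def time_since_last_onset(w: np.ndarray, dt: float) -> np.ndarray:
    """Per-step time since the most recent onset in the binary train ``w``.

    The step carrying an onset has elapsed time 0.  Steps before the first
    onset are +inf (no encounter has happened yet).
    """
    w = np.asarray(w)
    n = w.size
    idx = np.where(w > 0)[0]
    out = np.full(n, np.inf)
    if idx.size == 0:
        return out
    # index of most recent onset at or before each step
    last = np.full(n, -1, dtype=np.int64)
    last[idx] = idx
    last = np.maximum.accumulate(last)
    seen = last >= 0
    steps = np.arange(n)
    out[seen] = (steps[seen] - last[seen]) * dt
    return out


def min_samples_for(duration: float, dt: float) -> int:
    """Samples needed to cover ``duration``: an event shorter than the
    minimum duration must be rejected, so partial coverage rounds up."""
    return max(int(np.ceil(duration / dt - 1e-9)), 1)


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Contiguous runs of a boolean vector as (start, stop_exclusive, value)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [mask.size]))
    return [(int(a), int(b), bool(mask[a])) for a, b in zip(starts, stops)]


def persistent_intervals(above: np.ndarray, min_samples: int) -> list[tuple[int, int]]:
    """Intervals where ``above`` is True, with persistence on both edges.

    An event onset requires the quantity to stay above threshold for at least
    ``min_samples`` consecutive samples, and an event offset requires it to
    stay below for at least as long; shorter excursions in either direction
    are ignored.  Concretely: below-threshold gaps shorter than the minimum
    are first merged into the surrounding above-runs, then any remaining
    above-run shorter than the minimum is discarded.  Gaps at the start or
    end of the record are never merged (there is no surrounding event).

    Returns half-open index intervals [start, stop).
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    runs = _runs(above)
    merged: list[list[int]] = []  # above-runs, merging across short gaps
    for i, (a, b, val) in enumerate(runs):
        if not val:
            continue
        if merged and i >= 2:
            ga, gb, _ = runs[i - 1]  # the gap just before this run
            if (gb - ga) < min_samples and merged[-1][1] == ga:
                merged[-1][1] = b
                continue
        merged.append([a, b])
    return [(a, b) for a, b in merged if (b - a) >= min_samples]
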