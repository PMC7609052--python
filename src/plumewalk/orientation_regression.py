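"""Post-encounter orientation analyses and the trilinear regression.

These analyses quantify how the reflected upwind orientation theta+ of
walking observers depends on the recent encounter history: the orientation
change within a fixed window after an encounter (relative to matched
random times), the decay of the frequency-orientation relation with delay
since the last encounter, orientation conditioned on one filtered signal
while the other is held fixed, and a simultaneous ordinary-least-squares
regression of theta+ on the standardized filtered signals W_freq, W_dur,
and W_conc, with a moment-matrix condition-number diagnostic for
multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .turn_model import reflect_upwind

__all__ = [
    "RegressionDataset",
    "build_regression_dataset",
    "post_encounter_orientation_change",
    "orientation_vs_frequency_at_delay",
    "conditioned_orientation_curves",
    "trilinear_regression",
]

REGRESSORS = ("W_freq", "W_dur", "W_conc")


@dataclass
class RegressionDataset:
    """Per-walking-timestep table with standardized regressors."""

    frame: pd.DataFrame   # columns: trajectory, theta_plus, W_freq, W_dur, W_conc
    means: dict
    sds: dict

    def __post_init__(self):
        needed = {"trajectory", "theta_plus", *REGRESSORS}
        if not needed.issubset(self.frame.columns):
            raise ValueError(f"dataset must have columns {sorted(needed)}")


def build_regression_dataset(trajectories) -> RegressionDataset:
    """Pool walking steps and standardize the regressors.

    ``trajectories`` is a sequence of dicts with keys ``theta`` (deg),
    ``W_freq``, ``W_dur``, ``W_conc``, and ``walking`` (bool mask).
    Regressors are standardized to zero mean / unit variance over the
    pooled included steps.
    """
    rows = []
    for i, tr in enumerate(trajectories):
        m = np.asarray(tr["walking"], dtype=bool)
        rows.append(pd.DataFrame(dict(
            trajectory=i,
            theta_plus=reflect_upwind(np.asarray(tr["theta"])[m]),
            W_freq=np.asarray(tr["W_freq"])[m],
            W_dur=np.asarray(tr["W_dur"])[m],
            W_conc=np.asarray(tr.get("W_conc", np.zeros(len(tr["W_freq"]))))[m])))
    frame = pd.concat(rows, ignore_index=True)
    means, sds = {}, {}
    for c in REGRESSORS:
        mu, sd = frame[c].mean(), frame[c].std(ddof=0)
        if sd == 0:
            raise ValueError(f"regressor {c} has zero variance")
        frame[c] = (frame[c] - mu) / sd
        means[c], sds[c] = float(mu), float(sd)
    return RegressionDataset(frame=frame, means=means, sds=sds)


def post_encounter_orientation_change(trajectories, window: float = 2.0,
                                      partitions=((0, 0), (1, 3), (4, np.inf)),
                                      bins=None, seed=None,
                                      min_encounters: int = 100) -> dict:
    """Mean orientation change ``window`` s after an encounter onset, versus
    orientation at onset, partitioned by the number of onsets following
    within the window, with a matched random-time baseline subtracted.

    ``trajectories``: dicts with ``theta`` (deg), ``onset_steps`` (indices),
    ``walking`` (bool mask), ``time_step``.  Negative values mean a turn
    toward upwind.  Returns {partition: (bin_centers, mean, se, n)}.
    """
    if bins is None:
        bins = np.linspace(0.0, 180.0, 7)
    rng = np.random.default_rng(seed)
    rows = []        # (theta0, dtheta_plus, n_following)
    base_rows = []   # random-time baseline
    total_onsets = 0
    for tr in trajectories:
        theta_plus = reflect_upwind(np.asarray(tr["theta"], dtype=float))
        dt = tr["time_step"]
        lag = int(round(window / dt))
        onsets = np.asarray(tr["onset_steps"], dtype=int)
        total_onsets += onsets.size
        walking = np.asarray(tr["walking"], dtype=bool)
        n = theta_plus.size
        for o in onsets:
            if o + lag >= n or not walking[o]:
                continue
            n_follow = int(((onsets > o) & (onsets <= o + lag)).sum())
            rows.append((theta_plus[o], theta_plus[o + lag] - theta_plus[o],
                         n_follow))
        cand = np.flatnonzero(walking[:max(n - lag, 0)])
        if cand.size:
            pick = rng.choice(cand, size=min(onsets.size, cand.size),
                              replace=False)
            for o in pick:
                base_rows.append((theta_plus[o],
                                  theta_plus[o + lag] - theta_plus[o]))
    if total_onsets < min_encounters:
        raise ValueError(f"need at least {min_encounters} encounters")
    rows = np.array(rows) if rows else np.empty((0, 3))
    base = np.array(base_rows) if base_rows else np.empty((0, 2))
    centers = 0.5 * (bins[:-1] + bins[1:])
    base_curve = np.zeros(centers.size)
    for b in range(centers.size):
        sel = (base[:, 0] >= bins[b]) & (base[:, 0] < bins[b + 1])
        if sel.any():
            base_curve[b] = base[sel, 1].mean()
    out = {}
    for lo, hi in partitions:
        part = rows[(rows[:, 2] >= lo) & (rows[:, 2] <= hi)]
        if part.size == 0:
            continue  # empty partition omitted
        mean = np.full(centers.size, np.nan)
        se = np.full(centers.size, np.nan)
        cnt = np.zeros(centers.size, dtype=int)
        for b in range(centers.size):
            sel = (part[:, 0] >= bins[b]) & (part[:, 0] < bins[b + 1])
            if sel.sum() >= 2:
                vals = part[sel, 1] - base_curve[b]
                mean[b] = vals.mean()
                se[b] = vals.std(ddof=1) / np.sqrt(sel.sum())
                cnt[b] = int(sel.sum())
        out[(lo, hi)] = (centers, mean, se, cnt)
    return out


def orientation_vs_frequency_at_delay(trajectories, delays=(0.0, 1.0, 2.0, 5.0),
                                      delay_tol: float = 0.25) -> pd.DataFrame:
    """Regression slope of theta+ on W_freq at the last encounter, as a
    function of delay since that encounter.

    For each delay d, the included steps are walking steps whose most
    recent onset occurred d (within +/- delay_tol) seconds ago; theta+ at
    the step is regressed on W_freq evaluated at that onset.  Standard
    errors are trajectory-clustered: per-timestep samples are strongly
    autocorrelated within a trajectory, and plain OLS errors would be
    wildly anti-conservative.  Returns a table (delay, slope, se, t, p, n).
    """
    rows = []
    for d in delays:
        xs, ys, gs = [], [], []
        for gi, tr in enumerate(trajectories):
            theta_plus = reflect_upwind(np.asarray(tr["theta"], dtype=float))
            W = np.asarray(tr["W_freq"], dtype=float)
            dt = tr["time_step"]
            onsets = np.asarray(tr["onset_steps"], dtype=int)
            walking = np.asarray(tr["walking"], dtype=bool)
            if onsets.size == 0:
                continue
            n = theta_plus.size
            lag = int(round(d / dt))
            tol = max(int(round(delay_tol / dt)), 1)
            for o, nxt in zip(onsets, np.append(onsets[1:], n)):
                i0 = o + max(lag - tol, 0)
                i1 = min(o + lag + tol + 1, nxt, n)
                for i in range(i0, i1):
                    if walking[i]:
                        xs.append(W[o])
                        ys.append(theta_plus[i])
                        gs.append(gi)
        groups = np.asarray(gs)
        if len(xs) < 10 or np.unique(groups).size < 5 \
                or np.std(xs) == 0:
            rows.append(dict(delay=d, slope=np.nan, se=np.nan, t=np.nan,
                             p=np.nan, n=len(xs)))
            continue
        X = sm.add_constant(np.asarray(xs))
        fit = sm.OLS(np.asarray(ys), X).fit(cov_type="cluster",
                                            cov_kwds=dict(groups=groups))
        rows.append(dict(delay=d, slope=fit.params[1], se=fit.bse[1],
                         t=fit.tvalues[1], p=fit.pvalues[1], n=len(xs)))
    return pd.DataFrame(rows)


def conditioned_orientation_curves(dataset: RegressionDataset, hold: str,
                                   held_bins=None, free_bins=None,
                                   min_occupancy: int = 200) -> dict:
    """theta+ versus the free filtered signal within bins of the held one.

    ``hold`` is "W_dur" or "W_freq"; the free variable is the other.
    Sparse held-bins (below ``min_occupancy`` steps) are omitted.  Returns
    {held_bin_center: dict(centers, mean, se, slope)} on the standardized
    regressor scale.
    """
    if hold not in ("W_dur", "W_freq"):
        raise ValueError("hold must be 'W_dur' or 'W_freq'")
    free = "W_freq" if hold == "W_dur" else "W_dur"
    df = dataset.frame
    if held_bins is None:
        held_bins = np.quantile(df[hold], np.linspace(0, 1, 5))
        held_bins[-1] += 1e-9
    if free_bins is None:
        free_bins = np.quantile(df[free], np.linspace(0, 1, 7))
        free_bins[-1] += 1e-9
    out = {}
    for b in range(len(held_bins) - 1):
        sel = (df[hold] >= held_bins[b]) & (df[hold] < held_bins[b + 1])
        sub = df[sel]
        if len(sub) < min_occupancy:
            continue
        centers, means, ses = [], [], []
        for f in range(len(free_bins) - 1):
            s2 = sub[(sub[free] >= free_bins[f]) & (sub[free] < free_bins[f + 1])]
            if len(s2) < 5:
                continue
            centers.append(float(s2[free].mean()))
            means.append(float(s2.theta_plus.mean()))
            ses.append(float(s2.theta_plus.std(ddof=1) / np.sqrt(len(s2))))
        slope = np.nan
        if len(centers) >= 2:
            slope = float(np.polyfit(centers, means, 1)[0])
        out[0.5 * (held_bins[b] + held_bins[b + 1])] = dict(
            centers=np.array(centers), mean=np.array(means),
            se=np.array(ses), slope=slope)
    return out


def trilinear_regression(dataset: RegressionDataset,
                         block_bootstrap: bool = False, n_boot: int = 200,
                         seed=None, cond_flag: float = 10.0) -> dict:
    """OLS of theta+ on the three standardized filtered signals.

    Reports coefficients, plain two-tailed t-tests, and the condition
    number of the regressor moment matrix X'X (flagged when above
    ``cond_flag``).  Optionally adds trajectory-level block-bootstrap
    standard errors, which are robust to the within-trajectory
    autocorrelation of per-timestep samples.
    """
    df = dataset.frame
    X = df[list(REGRESSORS)].to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient regressor matrix (perfectly "
                         "collinear signals)")
    cond = float(np.linalg.cond(X.T @ X / len(df)))
    y = df.theta_plus.to_numpy()
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    terms = ("const",) + REGRESSORS
    table = pd.DataFrame(dict(term=terms, coef=fit.params, se=fit.bse,
                              t=fit.tvalues, p=fit.pvalues))
    result = dict(table=table, condition_number=cond,
                  multicollinear=cond > cond_flag, fit=fit)
    if block_bootstrap:
        rng = np.random.default_rng(seed)
        ids = df.trajectory.unique()
        coefs = []
        for _ in range(n_boot):
            pick = rng.choice(ids, size=ids.size, replace=True)
            sub = pd.concat([df[df.trajectory == i] for i in pick])
            Xb = sm.add_constant(sub[list(REGRESSORS)].to_numpy())
            coefs.append(sm.OLS(sub.theta_plus.to_numpy(), Xb).fit().params)
        result["bootstrap_se"] = np.std(np.array(coefs), axis=0, ddof=1)
    return result
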