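"""Stochastic saccade model: Poisson turn times, discrete +/-30 deg turn
magnitudes, and a sigmoidal upwind bias driven by encounter frequency.

The model: while walking, turns occur as a Poisson process with rate
lambda_F = 1/tau_T (optionally modulated linearly by the filtered encounter
frequency and exposure).  When a turn fires, its magnitude is drawn from
|N(turn_mean, turn_sd^2)| and its direction is upwind with probability

    p_T = 1 / (1 + exp(-alpha * S(t))),

so turns are unbiased (p = 0.5) without recent encounters and increasingly
upwind as the encounter frequency rises.  The sigmoid drive S(t) is the
*raw* causal exponential sum of encounter-onset impulses (the literal
convolution of the onset train with exp(-t/tau)); at a steady onset rate r
it converges to tau * r, i.e. S = tau * W_freq where W_freq is the
Hz-normalized frequency signal.  The gain alpha is expressed per unit of
that sum.  Between turns the orientation
performs small white jitter.  The per-timestep likelihood mixes
upwind-turn, downwind-turn, and straight-step terms, and parameters are
estimated by quasi-Newton maximization over bootstrapped trajectory subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._filters import causal_exp_filter, exposure_exp_filter

__all__ = [
    "TurnModelParams",
    "TurnLikelihoodData",
    "TurnFitResult",
    "upwind_turn_probability",
    "sigmoid_drive",
    "full_turn_rate",
    "turn_log_likelihood",
    "fit_turn_model",
    "simulate_turn_model",
    "simulate_turn_ensemble",
    "orientation_vs_frequency_curve",
    "reflect_upwind",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class TurnModelParams:
    """Parameters of the stochastic saccade model.

    ``tau_freq`` and ``tau_dur`` (s) add optional linear modulation of the
    turn rate by W_freq and W_dur; ``None`` disables a term.  ``alpha`` is
    the sigmoid gain in 1/Hz.  ``straight_jitter_sd`` is the orientation
    jitter per time step during straight walking, in degrees.
    """

    alpha: float = 0.242
    tau_T: float = 0.75
    tau_freq: float | None = None
    tau_dur: float | None = None
    turn_mean: float = 30.0
    turn_sd: float = 10.0
    straight_jitter_sd: float = 0.22
    filter_tau: float = 2.0

    def __post_init__(self):
        if self.tau_T <= 0:
            raise ValueError("tau_T must be positive")
        if self.turn_sd <= 0 or self.straight_jitter_sd <= 0:
            raise ValueError("angle-noise scales must be positive")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")


@dataclass
class TurnLikelihoodData:
    """Per-timestep observables of one walking trajectory.

    ``dtheta`` holds the orientation change assigned to each step (for a
    detected turn, the windowed turn angle at its midpoint step); ``theta``
    the orientation in [0, 360) with 0 facing upwind; ``turn_mask`` marks
    the midpoint step of each detected turn; ``walking_mask`` selects steps
    entering the likelihood.
    """

    dtheta: np.ndarray
    theta: np.ndarray
    W_freq: np.ndarray
    W_dur: np.ndarray
    turn_mask: np.ndarray
    walking_mask: np.ndarray
    time_step: float

    def __post_init__(self):
        n = len(self.dtheta)
        for name in ("theta", "W_freq", "W_dur", "turn_mask", "walking_mask"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        self.turn_mask = np.asarray(self.turn_mask, dtype=bool)
        self.walking_mask = np.asarray(self.walking_mask, dtype=bool)


def upwind_turn_probability(drive, alpha: float):
    """Sigmoidal probability that a turn is directed upwind.

    ``drive`` is the filtered-onset signal the gain multiplies; the model
    uses the raw exponential onset sum S = tau * W_freq (see module notes).
    """
    return 1.0 / (1.0 + np.exp(-alpha * np.asarray(drive, dtype=float)))


def sigmoid_drive(params: TurnModelParams, W_freq):
    """Raw filtered-onset sum S(t) = filter_tau * W_freq(t)."""
    return params.filter_tau * np.asarray(W_freq, dtype=float)


def full_turn_rate(params: TurnModelParams, W_freq, W_dur):
    """Turn rate lambda_F = 1/tau_T + W_freq/tau_freq + W_dur/tau_dur (1/s)."""
    lam = 1.0 / params.tau_T + np.zeros_like(np.asarray(W_freq, dtype=float))
    if params.tau_freq is not None:
        lam = lam + np.asarray(W_freq, dtype=float) / params.tau_freq
    if params.tau_dur is not None:
        lam = lam + np.asarray(W_dur, dtype=float) / params.tau_dur
    if np.any(lam <= 0):
        raise ValueError("parameters yield a non-positive turn rate")
    return lam


def _upwind_sign(theta):
    """Sign of the orientation change that reduces the upwind deviation.

    -1 for theta in (0, 180) (turning toward 0 decreases theta), +1 for
    theta in (180, 360); 0 at the reflection boundaries 0 and 180 where the
    direction is ambiguous.
    """
    theta = np.mod(np.asarray(theta, dtype=float), 360.0)
    s = np.where(theta < 180.0, -1.0, 1.0)
    return np.where(np.isin(theta, (0.0, 180.0)), 0.0, s)


def reflect_upwind(theta):
    """Reflected upwind deviation theta+ = min(theta, 360 - theta) in [0, 180]."""
    theta = np.mod(np.asarray(theta, dtype=float), 360.0)
    return np.minimum(theta, 360.0 - theta)


def _log_normal_pdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def turn_log_likelihood(params: TurnModelParams, data: TurnLikelihoodData) -> float:
    """Log-likelihood of the saccade model for one trajectory.

    Straight walking steps contribute exp(-dt*lambda_F) times a zero-mean
    jitter Gaussian; turn steps contribute dt*lambda_F*exp(-dt*lambda_F)
    times the direction probability (p_T or 1-p_T) times a Gaussian of the
    turn angle around +/-turn_mean (sign set by the orientation half-plane).
    At the reflection boundaries (theta exactly 0 or 180) the direction is
    ambiguous and the two direction terms are mixed with weight 1/2.
    """
    walk = data.walking_mask
    if not walk.any():
        return 0.0
    dt = data.time_step
    lam = np.broadcast_to(
        full_turn_rate(params, np.asarray(data.W_freq, dtype=float)[walk],
                       np.asarray(data.W_dur, dtype=float)[walk]),
        (int(walk.sum()),))
    turn = data.turn_mask[walk]
    dth = np.asarray(data.dtheta, dtype=float)[walk]
    theta = np.asarray(data.theta, dtype=float)[walk]

    logp = np.empty(walk.sum())
    # straight steps: survival x jitter density
    logp[~turn] = -dt * lam[~turn] + _log_normal_pdf(dth[~turn], 0.0,
                                                     params.straight_jitter_sd)
    if turn.any():
        W = np.asarray(data.W_freq, dtype=float)[walk][turn]
        pT = upwind_turn_probability(sigmoid_drive(params, W), params.alpha)
        sgn = _upwind_sign(theta[turn])
        mu_up = sgn * params.turn_mean  # upwind-turn mean angle change
        dturn = dth[turn]
        log_up = _log_normal_pdf(dturn, mu_up, params.turn_sd)
        log_down = _log_normal_pdf(dturn, -mu_up, params.turn_sd)
        event = np.log(dt * lam[turn]) - dt * lam[turn]
        is_up = np.sign(dturn) == np.sign(mu_up)
        amb = sgn == 0.0
        with np.errstate(divide="ignore"):  # saturated sigmoid -> -inf, caught below
            contrib = np.where(is_up, log_up + np.log(pT),
                               log_down + np.log1p(-pT))
        if amb.any():
            both = np.logaddexp(_log_normal_pdf(dturn, params.turn_mean,
                                                params.turn_sd),
                                _log_normal_pdf(dturn, -params.turn_mean,
                                                params.turn_sd))
            contrib = np.where(amb, both + np.log(0.5), contrib)
        logp[turn] = event + contrib
    total = float(logp.sum())
    if not np.isfinite(total):
        bad = int(np.flatnonzero(~np.isfinite(logp))[0])
        raise FloatingPointError(
            f"non-finite turn log-likelihood at walking step {bad}")
    return total


# ---------------------------------------------------------------------------
# fitting


def _sufficient_stats(traj: TurnLikelihoodData, filter_tau: float = 2.0):
    """Reduced statistics for the homogeneous-rate (no modulation) model.

    With lambda_F constant, the log-likelihood depends on the data only
    through the number of walking steps, the number of turns, and the
    sigmoid drive and upwind/downwind label of each turn.
    """
    walk = traj.walking_mask
    turn = traj.turn_mask & walk
    W = filter_tau * np.asarray(traj.W_freq, dtype=float)[turn]
    sgn = _upwind_sign(np.asarray(traj.theta, dtype=float)[turn])
    dth = np.asarray(traj.dtheta, dtype=float)[turn]
    is_up = np.sign(dth) == np.sign(sgn)
    amb = sgn == 0.0
    return dict(n_walk=int(walk.sum()), n_turn=int(turn.sum()),
                W_up=W[is_up & ~amb], W_down=W[~is_up & ~amb],
                n_amb=int(amb.sum()))


def _stats_loglik(alpha: float, inv_tau_T: float, stats: dict, dt: float) -> float:
    """Parameter-dependent part of the log-likelihood from sufficient stats."""
    if inv_tau_T <= 0:
        return -np.inf
    n_walk = stats["n_walk"]
    n_turn = stats["n_turn"]
    ll = -dt * inv_tau_T * n_walk + n_turn * np.log(dt * inv_tau_T)
    up, down = stats["W_up"], stats["W_down"]
    # log sigmoid(a W) and log sigmoid(-a W), numerically stable
    if up.size:
        ll -= np.logaddexp(0.0, -alpha * up).sum()
    if down.size:
        ll -= np.logaddexp(0.0, alpha * down).sum()
    return float(ll)


@dataclass
class TurnFitResult:
    table: pd.DataFrame           # one row per subset
    medians: dict                 # per-parameter median over converged subsets
    n_failed: int

    def summary(self) -> dict:
        return dict(self.medians, n_subsets=len(self.table),
                    n_failed=self.n_failed)


def fit_turn_model(data: list[TurnLikelihoodData], n_subsets: int = 500,
                   subset_fraction: float = 0.2, bounds: dict | None = None,
                   seed: int | None = None, fit_modulation: bool = False,
                   x0: dict | None = None, filter_tau: float = 2.0
                   ) -> TurnFitResult:
    """Maximum-likelihood estimation over bootstrapped trajectory subsets.

    Each subset draws ``subset_fraction`` of the trajectories without
    replacement and maximizes the log-likelihood with L-BFGS-B (numerical
    gradients) over (alpha, log(1/tau_T)) -- plus the two inverse modulation
    timescales when ``fit_modulation`` -- reporting the per-subset estimates
    and their medians.  The base timescale is optimized on a log scale of
    its inverse to avoid bound singularities.  Default box bounds span two
    orders of magnitude around the initializer for the rate parameter.
    """
    if len(data) < 10:
        raise ValueError("need at least 10 trajectories to fit subsets")
    rng = np.random.default_rng(seed)
    dt = data[0].time_step
    if any(abs(d.time_step - dt) > 1e-12 for d in data):
        raise ValueError("trajectories have inconsistent time steps")
    x0 = x0 or {}
    a0 = x0.get("alpha", 0.1)
    total_turns = sum(int((d.turn_mask & d.walking_mask).sum()) for d in data)
    total_steps = sum(int(d.walking_mask.sum()) for d in data)
    k0 = x0.get("inv_tau_T", max(total_turns, 1) / max(total_steps * dt, dt))
    bounds = bounds or {}
    b_alpha = bounds.get("alpha", (-10.0, 10.0))
    b_logk = bounds.get("log_inv_tau_T",
                        (np.log(k0) - np.log(10.0), np.log(k0) + np.log(10.0)))

    stats = None if fit_modulation else [_sufficient_stats(d, filter_tau)
                                         for d in data]
    n_pick = max(1, int(round(subset_fraction * len(data))))

    def merge_stats(idx):
        return dict(
            n_walk=sum(stats[i]["n_walk"] for i in idx),
            n_turn=sum(stats[i]["n_turn"] for i in idx),
            W_up=np.concatenate([stats[i]["W_up"] for i in idx]),
            W_down=np.concatenate([stats[i]["W_down"] for i in idx]),
            n_amb=sum(stats[i]["n_amb"] for i in idx))

    rows = []
    for s in range(n_subsets):
        idx = rng.choice(len(data), size=n_pick, replace=False)
        if fit_modulation:
            subset = [data[i] for i in idx]

            def nll(x):
                p = TurnModelParams(alpha=x[0], tau_T=1.0 / np.exp(x[1]),
                                    tau_freq=1.0 / x[2] if x[2] != 0 else None,
                                    tau_dur=1.0 / x[3] if x[3] != 0 else None,
                                    filter_tau=filter_tau)
                try:
                    return -sum(turn_log_likelihood(p, d) for d in subset)
                except (ValueError, FloatingPointError):
                    return 1e12

            xinit = [a0, np.log(k0), 1e-3, 1e-3]
            bnds = [b_alpha, b_logk, (-5.0, 5.0), (-5.0, 5.0)]
        else:
            st = merge_stats(idx)

            def nll(x):
                return -_stats_loglik(x[0], np.exp(x[1]), st, dt)

            xinit = [a0, np.log(k0)]
            bnds = [b_alpha, b_logk]
        res = optimize.minimize(nll, xinit, method="L-BFGS-B", bounds=bnds)
        row = dict(subset=s, alpha=res.x[0], tau_T=1.0 / np.exp(res.x[1]),
                   converged=bool(res.success), logL=-float(res.fun))
        if fit_modulation:
            row["inv_tau_freq"] = res.x[2]
            row["inv_tau_dur"] = res.x[3]
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table.converged]
    n_failed = int((~table.converged).sum())
    use = ok if len(ok) else table
    medians = {c: float(use[c].median())
               for c in table.columns if c not in ("subset", "converged", "logL")}
    return TurnFitResult(table=table, medians=medians, n_failed=n_failed)


# ---------------------------------------------------------------------------
# simulation


@dataclass
class OrientationTrace:
    theta: np.ndarray           # deg in [0, 360), wind-relative
    turn_steps: np.ndarray      # step indices of turns
    turn_angles: np.ndarray     # signed deg
    W_freq: np.ndarray
    W_dur: np.ndarray
    time_step: float

    @property
    def turn_times(self) -> np.ndarray:
        return self.turn_steps * self.time_step

    @property
    def theta_plus(self) -> np.ndarray:
        return reflect_upwind(self.theta)


def _signals_from_train(train, params: TurnModelParams):
    dt = train.time_step
    W_freq = causal_exp_filter(train.w, params.filter_tau, dt, normalize=True)
    W_dur = exposure_exp_filter(train.d, params.filter_tau, dt)
    return W_freq, W_dur


def simulate_turn_ensemble(params: TurnModelParams, train, n_trajectories: int,
                           seed=None, initial_theta=None, walking_mask=None
                           ) -> list[OrientationTrace]:
    """Simulate several orientation traces driven by one encounter train.

    All trajectories share the train (and hence W_freq/W_dur) but use
    independent randomness.  ``walking_mask`` freezes the orientation on
    non-walking steps (no turns, no jitter).  Vectorized across
    trajectories; reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    dt = train.time_step
    W_freq, W_dur = _signals_from_train(train, params)
    lam = np.broadcast_to(full_turn_rate(params, W_freq, W_dur), W_freq.shape)
    n = W_freq.size
    m = n_trajectories
    if initial_theta is None:
        theta0 = rng.uniform(0.0, 360.0, size=m)
    else:
        theta0 = np.full(m, float(initial_theta))
    if walking_mask is None:
        walking_mask = np.ones(n, dtype=bool)
    p_turn = np.clip(lam * dt, 0.0, 1.0)
    turn_draw = rng.random((m, n)) < p_turn[None, :]
    turn_draw &= walking_mask[None, :]
    mags = np.abs(rng.normal(params.turn_mean, params.turn_sd, size=(m, n)))
    up_draw = rng.random((m, n)) < upwind_turn_probability(
        sigmoid_drive(params, W_freq), params.alpha)[None, :]
    tie = rng.integers(0, 2, size=(m, n)) * 2 - 1
    jitter = rng.normal(0.0, params.straight_jitter_sd, size=(m, n))
    jitter *= walking_mask[None, :]

    theta = np.empty((m, n))
    cur = theta0.copy()
    for i in range(n):
        ti = turn_draw[:, i]
        if ti.any():
            sgn = _upwind_sign(cur[ti])
            sgn = np.where(sgn == 0.0, tie[ti, i], sgn)
            dth = np.where(up_draw[ti, i], sgn, -sgn) * mags[ti, i]
            cur[ti] = cur[ti] + dth
        cur = np.mod(cur + np.where(ti, 0.0, jitter[:, i]), 360.0)
        theta[:, i] = cur
    out = []
    for k in range(m):
        steps = np.flatnonzero(turn_draw[k])
        out.append(OrientationTrace(theta=theta[k], turn_steps=steps,
                                    turn_angles=np.zeros(steps.size),
                                    W_freq=W_freq, W_dur=W_dur, time_step=dt))
    return out


def simulate_turn_model(params: TurnModelParams, train, initial_theta=None,
                        duration: float | None = None, seed=None,
                        walking_mask=None) -> OrientationTrace:
    """Simulate a single orientation trace of the saccade model.

    Turn times are Poisson at lambda_F; each turn draws |dtheta| from
    N(turn_mean, turn_sd^2) and is directed upwind with probability
    p_T(W_freq); straight steps add white jitter.  At the reflection
    boundaries (theta = 0 or 180) the upwind direction is drawn uniformly.
    """
    rng = np.random.default_rng(seed)
    dt = train.time_step
    if duration is not None:
        n_req = int(round(duration / dt))
        if n_req > train.w.size:
            raise ValueError("encounter train shorter than requested duration")
    else:
        n_req = train.w.size
    W_freq, W_dur = _signals_from_train(train, params)
    W_freq, W_dur = W_freq[:n_req], W_dur[:n_req]
    lam = np.broadcast_to(full_turn_rate(params, W_freq, W_dur), W_freq.shape)
    if walking_mask is None:
        walking_mask = np.ones(n_req, dtype=bool)
    theta = np.empty(n_req)
    cur = rng.uniform(0, 360) if initial_theta is None else float(initial_theta)
    turn_steps, turn_angles = [], []
    p_turn = np.clip(lam * dt, 0.0, 1.0)
    u_turn = rng.random(n_req)
    for i in range(n_req):
        if walking_mask[i] and u_turn[i] < p_turn[i]:
            mag = abs(rng.normal(params.turn_mean, params.turn_sd))
            sgn = _upwind_sign(cur)
            if sgn == 0.0:
                sgn = rng.integers(0, 2) * 2 - 1
            up = rng.random() < upwind_turn_probability(
                params.filter_tau * W_freq[i], params.alpha)
            dth = (sgn if up else -sgn) * mag
            cur = np.mod(cur + dth, 360.0)
            turn_steps.append(i)
            turn_angles.append(dth)
        elif walking_mask[i]:
            cur = np.mod(cur + rng.normal(0.0, params.straight_jitter_sd), 360.0)
        theta[i] = cur
    return OrientationTrace(theta=theta, turn_steps=np.array(turn_steps, dtype=int),
                            turn_angles=np.array(turn_angles),
                            W_freq=W_freq, W_dur=W_dur, time_step=dt)


@dataclass
class OrientationFrequencyCurve:
    bin_centers: np.ndarray
    mean_theta_plus: np.ndarray
    se_theta_plus: np.ndarray
    counts: np.ndarray
    slope: float
    intercept: float
    slope_se: float


def orientation_vs_frequency_curve(theta_plus, W_freq, bins=None,
                                   walking_mask=None,
                                   freq_range: tuple = (0.0, 3.5)
                                   ) -> OrientationFrequencyCurve:
    """Binned mean reflected orientation versus encounter frequency, with an
    ordinary least-squares line fitted over ``freq_range``."""
    theta_plus = np.asarray(theta_plus, dtype=float).ravel()
    W = np.asarray(W_freq, dtype=float).ravel()
    if walking_mask is not None:
        m = np.asarray(walking_mask, dtype=bool).ravel()
        theta_plus, W = theta_plus[m], W[m]
    if bins is None:
        bins = np.arange(0.0, max(freq_range[1], W.max()) + 0.25, 0.25)
    which = np.digitize(W, bins) - 1
    centers, means, ses, counts = [], [], [], []
    for b in range(len(bins) - 1):
        sel = which == b
        if sel.sum() < 2:
            continue
        centers.append(0.5 * (bins[b] + bins[b + 1]))
        means.append(theta_plus[sel].mean())
        ses.append(theta_plus[sel].std(ddof=1) / np.sqrt(sel.sum()))
        counts.append(int(sel.sum()))
    centers = np.array(centers)
    means = np.array(means)
    in_range = (centers >= freq_range[0]) & (centers <= freq_range[1])
    if in_range.sum() < 2:
        raise ValueError("need at least two occupied bins in the fit range")
    A = np.vstack([centers[in_range], np.ones(in_range.sum())]).T
    coef, res_, *_ = np.linalg.lstsq(A, means[in_range], rcond=None)
    yhat = A @ coef
    dof = max(in_range.sum() - 2, 1)
    s2 = ((means[in_range] - yhat) ** 2).sum() / dof
    sxx = ((centers[in_range] - centers[in_range].mean()) ** 2).sum()
    slope_se = float(np.sqrt(s2 / sxx)) if sxx > 0 else np.nan
    return OrientationFrequencyCurve(bin_centers=centers,
                                     mean_theta_plus=means,
                                     se_theta_plus=np.array(ses),
                                     counts=np.array(counts),
                                     slope=float(coef[0]),
                                     intercept=float(coef[1]),
                                     slope_se=slope_se)
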