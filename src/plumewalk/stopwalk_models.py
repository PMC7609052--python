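"""Inhomogeneous-Poisson models of walk<->stop transitions.

Three competing rate families describe how the hazard of stopping (while
walking) or of resuming a walk (while stopped) depends on the recent history
of odor encounters:

* ``last_encounter`` -- the rate resets to a fixed value at every encounter
  onset and relaxes exponentially back to baseline:
  lambda(t) = lam0 + dlam * exp(-DT(t)/tau), DT = time since last onset.
* ``accumulated_evidence`` -- the rate depends on the causal exponentially
  filtered sum of onsets F(t).  For stopping:
  lambda(t) = lam0 + lam1 / (1 + lam2 * F(t)); for walking:
  lambda(t) = lam0 + dlam * F(t).
* ``encounter_duration`` -- two constant rates, one inside encounters and
  one during blanks: lambda(t) = lam_enc * d(t) + lam_blank * (1 - d(t)).

Bout likelihoods follow the per-step Poisson approximation: every step in
the source state contributes a survival factor exp(-dt*lambda), and every
observed transition contributes dt*lambda*exp(-dt*lambda) at its onset
step; censored bouts (trajectory ends) contribute survival only.  Fitting
is quasi-Newton MLE on log-transformed positive parameters over
bootstrapped trajectory subsets, and model comparison uses held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from ._filters import causal_exp_filter, time_since_last_onset

__all__ = [
    "RateModelSpec",
    "BoutData",
    "RateFitResult",
    "fitted_stop_spec",
    "fitted_walk_spec",
    "rate_trace",
    "rate_from_features",
    "bout_log_likelihood",
    "fit_rate_model",
    "simulate_transitions",
    "classify_onsets",
    "generate_model_statistics",
    "compare_models",
]

FAMILIES = ("last_encounter", "accumulated_evidence", "encounter_duration")
DIRECTIONS = ("walk_to_stop", "stop_to_walk")


@dataclass
class RateModelSpec:
    """One parameterized transition-rate function.

    ``params`` keys by family: last_encounter (lam0, dlam, tau);
    accumulated_evidence walk_to_stop (lam0, lam1, lam2, tau);
    accumulated_evidence stop_to_walk (lam0, dlam, tau);
    encounter_duration (lam_enc, lam_blank).  Rates in 1/s, tau in s.
    """

    family: str
    direction: str
    params: dict

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        req = self.param_names(self.family, self.direction)
        missing = [k for k in req if k not in self.params]
        if missing:
            raise ValueError(f"missing parameters {missing} for {self.family}")
        if "tau" in req and self.params["tau"] <= 0:
            raise ValueError("tau must be positive")

    @staticmethod
    def param_names(family: str, direction: str) -> tuple:
        if family == "last_encounter":
            return ("lam0", "dlam", "tau")
        if family == "accumulated_evidence":
            return (("lam0", "lam1", "lam2", "tau") if direction == "walk_to_stop"
                    else ("lam0", "dlam", "tau"))
        return ("lam_enc", "lam_blank")

    @property
    def n_params(self) -> int:
        return len(self.param_names(self.family, self.direction))


def fitted_stop_spec() -> RateModelSpec:
    """Median fitted last-encounter stopping model of the walking-fly
    dataset: baseline 0.78 1/s, dropping to 0.17 1/s at each encounter
    onset and relaxing back with timescale 0.25 s."""
    return RateModelSpec("last_encounter", "walk_to_stop",
                         dict(lam0=0.78, dlam=-0.61, tau=0.25))


def fitted_walk_spec() -> RateModelSpec:
    """Median fitted accumulated-evidence walk-initiation model: baseline
    0.29 1/s, incremented by 0.41 1/s at each onset with filter timescale
    0.52 s."""
    return RateModelSpec("accumulated_evidence", "stop_to_walk",
                         dict(lam0=0.29, dlam=0.41, tau=0.52))


def rate_from_features(spec: RateModelSpec, dT=None, F=None, d=None):
    """Rate from precomputed features: dT = time since last onset (s),
    F = raw exponentially filtered onset train, d = binary exposure."""
    p = spec.params
    if spec.family == "last_encounter":
        lam = p["lam0"] + p["dlam"] * np.exp(-np.asarray(dT) / p["tau"])
    elif spec.family == "accumulated_evidence":
        F = np.asarray(F, dtype=float)
        if spec.direction == "walk_to_stop":
            lam = p["lam0"] + p["lam1"] / (1.0 + p["lam2"] * F)
        else:
            lam = p["lam0"] + p["dlam"] * F
    else:
        d = np.asarray(d, dtype=float)
        lam = p["lam_enc"] * d + p["lam_blank"] * (1.0 - d)
    return lam


def rate_trace(spec: RateModelSpec, w, d, dt: float):
    """Evaluate the rate function lambda(t) along aligned binary series."""
    w = np.asarray(w, dtype=float)
    d = np.asarray(d, dtype=float)
    if w.shape != d.shape:
        raise ValueError("w and d must be aligned")
    if spec.family == "last_encounter":
        lam = rate_from_features(spec, dT=time_since_last_onset(w, dt))
    elif spec.family == "accumulated_evidence":
        lam = rate_from_features(spec, F=causal_exp_filter(w, spec.params["tau"], dt))
    else:
        lam = rate_from_features(spec, d=d)
    if np.any(lam <= 0):
        raise ValueError("parameter set yields a non-positive rate")
    return lam


@dataclass
class BoutData:
    """Encounter-aligned behavior of a set of trajectories.

    Each trajectory is a dict with keys ``w`` and ``d`` (binary per-step
    series) and ``walking`` (boolean per step).  The last bout of every
    trajectory is censored (no transition observed at the end).  ``bouts()``
    iterates the per-bout view (type, slices of w/d, terminal flag).
    """

    trajectories: list
    time_step: float

    def __post_init__(self):
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")
        for tr in self.trajectories:
            n = len(tr["walking"])
            if len(tr["w"]) != n or len(tr["d"]) != n:
                raise ValueError("w, d, walking must be aligned")

    def bouts(self):
        for tr in self.trajectories:
            walking = np.asarray(tr["walking"], dtype=bool)
            if walking.size == 0:
                continue
            change = np.flatnonzero(np.diff(walking.astype(np.int8))) + 1
            starts = np.concatenate(([0], change))
            stops = np.concatenate((change, [walking.size]))
            for k, (a, b) in enumerate(zip(starts, stops)):
                yield dict(kind="walk" if walking[a] else "stop",
                           w=tr["w"][a:b], d=tr["d"][a:b],
                           start=a, stop=b,
                           terminal=(b < walking.size))

    def n_transitions(self, direction: str) -> int:
        want = "walk" if direction == "walk_to_stop" else "stop"
        return sum(1 for b in self.bouts() if b["kind"] == want and b["terminal"])


def _traj_loglik(spec: RateModelSpec, tr: dict, dt: float) -> float:
    walking = np.asarray(tr["walking"], dtype=bool)
    lam = rate_trace(spec, tr["w"], tr["d"], dt)
    if spec.direction == "walk_to_stop":
        in_state = walking
        trans = np.flatnonzero(walking[:-1] & ~walking[1:]) + 1
    else:
        in_state = ~walking
        trans = np.flatnonzero(~walking[:-1] & walking[1:]) + 1
    ll = -dt * lam[in_state].sum()
    if trans.size:
        lam_t = lam[trans]
        ll += np.sum(np.log(dt * lam_t)) - dt * lam_t.sum()
    return float(ll)


def bout_log_likelihood(spec: RateModelSpec, data: BoutData) -> float:
    """Sum of per-step survival terms and per-transition event terms.

    Every step spent in the source state contributes -dt*lambda(t); each
    observed transition adds log(dt*lambda) - dt*lambda at its onset step.
    Bouts censored by the trajectory end contribute survival terms only.
    """
    total = 0.0
    for tr in data.trajectories:
        ll = _traj_loglik(spec, tr, data.time_step)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite bout log-likelihood "
                                     f"(trajectory of length {len(tr['walking'])})")
        total += ll
    return total


# ---------------------------------------------------------------------------
# fitting


def _pack(family: str, direction: str, params: dict) -> np.ndarray:
    """Parameters -> unconstrained optimizer coordinates (logs of positive
    quantities; the last-encounter onset rate lam0+dlam is optimized as a
    positive quantity so dlam may take either sign)."""
    p = params
    if family == "last_encounter":
        return np.log([p["lam0"], p["lam0"] + p["dlam"], 1.0 / p["tau"]])
    if family == "accumulated_evidence":
        if direction == "walk_to_stop":
            return np.log([p["lam0"], p["lam1"], p["lam2"], 1.0 / p["tau"]])
        return np.log([p["lam0"], p["dlam"], 1.0 / p["tau"]])
    return np.log([p["lam_enc"], p["lam_blank"]])


def _unpack(family: str, direction: str, x: np.ndarray) -> dict:
    e = np.exp(x)
    if family == "last_encounter":
        return dict(lam0=e[0], dlam=e[1] - e[0], tau=1.0 / e[2])
    if family == "accumulated_evidence":
        if direction == "walk_to_stop":
            return dict(lam0=e[0], lam1=e[1], lam2=e[2], tau=1.0 / e[3])
        return dict(lam0=e[0], dlam=e[1], tau=1.0 / e[2])
    return dict(lam_enc=e[0], lam_blank=e[1])


@dataclass
class RateFitResult:
    family: str
    direction: str
    table: pd.DataFrame
    medians: dict
    n_failed: int
    bound_hugging_fraction: float

    def median_spec(self) -> RateModelSpec:
        names = RateModelSpec.param_names(self.family, self.direction)
        return RateModelSpec(self.family, self.direction,
                             {k: self.medians[k] for k in names})


def _initial_params(family, direction, data: BoutData) -> dict:
    dt = data.time_step
    n_steps = sum(int(np.asarray(tr["walking"], dtype=bool).sum()
                      if direction == "walk_to_stop"
                      else (~np.asarray(tr["walking"], dtype=bool)).sum())
                  for tr in data.trajectories)
    n_trans = data.n_transitions(direction)
    lam_bar = max(n_trans, 1) / max(n_steps * dt, dt)
    if family == "last_encounter":
        return dict(lam0=lam_bar, dlam=lam_bar * (-0.5 if direction == "walk_to_stop"
                                                  else 0.5), tau=0.5)
    if family == "accumulated_evidence":
        if direction == "walk_to_stop":
            return dict(lam0=lam_bar * 0.5, lam1=lam_bar * 0.5, lam2=1.0, tau=0.5)
        return dict(lam0=lam_bar, dlam=lam_bar * 0.5, tau=0.5)
    return dict(lam_enc=lam_bar, lam_blank=lam_bar)


def fit_rate_model(family: str, direction: str, data: BoutData,
                   n_subsets: int = 500, subset_fraction: float = 0.2,
                   bounds_decades: float = 2.0, seed=None,
                   x0: dict | None = None, min_transitions: int = 20
                   ) -> RateFitResult:
    """Per-subset maximum-likelihood estimation of one rate family.

    Each subset draws ``subset_fraction`` of the trajectories and maximizes
    the bout likelihood with L-BFGS-B (numerical gradients) in the
    log-parameter space; box bounds span ``bounds_decades`` orders of
    magnitude centered on the initializer.  Estimates landing within 5% of
    a bound (in log space) are flagged as bound-hugging (non-robust).
    """
    if data.n_transitions(direction) < min_transitions:
        raise ValueError(f"need at least {min_transitions} observed transitions")
    rng = np.random.default_rng(seed)
    dt = data.time_step
    p0 = x0 or _initial_params(family, direction, data)
    xinit = _pack(family, direction, p0)
    half = 0.5 * bounds_decades * np.log(10.0)
    bnds = [(xi - half, xi + half) for xi in xinit]
    n_traj = len(data.trajectories)
    n_pick = max(1, int(round(subset_fraction * n_traj)))
    names = RateModelSpec.param_names(family, direction)

    rows, hug = [], 0
    for s in range(n_subsets):
        idx = rng.choice(n_traj, size=n_pick, replace=False)
        subset = [data.trajectories[i] for i in idx]

        def nll(x):
            params = _unpack(family, direction, x)
            spec = RateModelSpec(family, direction, params)
            try:
                return -sum(_traj_loglik(spec, tr, dt) for tr in subset)
            except (ValueError, FloatingPointError):
                return 1e12

        res = optimize.minimize(nll, xinit, method="L-BFGS-B", bounds=bnds)
        params = _unpack(family, direction, res.x)
        width = 2 * half
        hugging = bool(np.any((res.x - np.array([b[0] for b in bnds]) < 0.05 * width)
                              | (np.array([b[1] for b in bnds]) - res.x < 0.05 * width)))
        hug += hugging
        rows.append(dict(subset=s, **{k: params[k] for k in names},
                         converged=bool(res.success), bound_hugging=hugging,
                         logL=-float(res.fun)))
    table = pd.DataFrame(rows)
    ok = table[table.converged]
    n_failed = int((~table.converged).sum())
    if len(ok) == 0:
        raise RuntimeError("all subsets failed to converge; "
                           f"last optimizer status: {res.message}")
    medians = {k: float(ok[k].median()) for k in names}
    return RateFitResult(family=family, direction=direction, table=table,
                         medians=medians, n_failed=n_failed,
                         bound_hugging_fraction=float(table.bound_hugging.mean()))


# ---------------------------------------------------------------------------
# simulation and model statistics


def simulate_transitions(stop_spec: RateModelSpec, walk_spec: RateModelSpec,
                         w, d, dt: float, rng=None, initial_walking: bool = True,
                         max_rate_dt: float = 0.2) -> np.ndarray:
    """Two-state walk/stop chain driven by an encounter train.

    Per step, the active hazard (stop_spec while walking, walk_spec while
    stopped) fires with probability dt*lambda(t).  Returns the boolean
    walking sequence.  The per-step Poisson approximation requires
    dt*lambda << 1; violations beyond ``max_rate_dt`` raise.
    """
    if stop_spec.direction != "walk_to_stop":
        raise ValueError("stop_spec must have direction walk_to_stop")
    if walk_spec.direction != "stop_to_walk":
        raise ValueError("walk_spec must have direction stop_to_walk")
    rng = np.random.default_rng(rng)
    lam_ws = rate_trace(stop_spec, w, d, dt)
    lam_sw = rate_trace(walk_spec, w, d, dt)
    lam_ws = np.broadcast_to(lam_ws, np.shape(w)).astype(float)
    lam_sw = np.broadcast_to(lam_sw, np.shape(w)).astype(float)
    worst = max(lam_ws.max(), lam_sw.max()) * dt
    if worst > max_rate_dt:
        raise ValueError(f"dt*lambda reaches {worst:.3f}; the per-step Poisson "
                         "approximation requires dt*lambda << 1")
    n = len(lam_ws)
    u = rng.random(n)
    walking = np.empty(n, dtype=bool)
    state = initial_walking
    for i in range(n):
        p = lam_ws[i] * dt if state else lam_sw[i] * dt
        if u[i] < p:
            state = not state
        walking[i] = state
    return walking


def classify_onsets(onset_times: np.ndarray, isolation_window: float = 1.0,
                    clump_window: float = 1.0, clump_min: int = 3) -> dict:
    """Label encounter onsets as isolated / clump members.

    An onset is *isolated* when no other onset falls within
    +/-``isolation_window``; it belongs to a *clump* when at least
    ``clump_min`` onsets (itself included) fall within a window of
    ``clump_window`` seconds around it.
    """
    t = np.asarray(onset_times, dtype=float)
    isolated = np.zeros(t.size, dtype=bool)
    clump = np.zeros(t.size, dtype=bool)
    for i, ti in enumerate(t):
        isolated[i] = (np.abs(t - ti) <= isolation_window).sum() == 1
        clump[i] = (np.abs(t - ti) <= clump_window).sum() >= clump_min
    return dict(isolated=isolated, clump=clump)


def _time_to_event(event_steps: np.ndarray, query_steps: np.ndarray,
                   dt: float, active: np.ndarray) -> np.ndarray:
    """Time from each query step to the next event step, restricted to
    queries on ``active`` steps; censored queries (no later event) dropped."""
    out = []
    for q in query_steps:
        if not active[q]:
            continue
        later = event_steps[event_steps > q]
        if later.size:
            out.append((later[0] - q) * dt)
    return np.array(out)


def _survival(samples: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if samples.size == 0:
        return np.full(grid.size, np.nan)
    return (samples[None, :] > grid[:, None]).mean(axis=1)


def generate_model_statistics(stop_spec: RateModelSpec, walk_spec: RateModelSpec,
                              trains, seed=None, grid=None,
                              min_condition_events: int = 25,
                              n_repeats: int = 1) -> dict:
    """Time-to-stop / time-to-walk statistics of a simulated model.

    For each encounter train, a walk/stop sequence is simulated with the
    given rate pair; time-to-transition samples are collected from (i) every
    encounter onset, (ii) isolated onsets, (iii) clump-member onsets, and
    (iv) matched random times (the baseline), separately for walking and
    stopped states.  Also returns cumulative encounter counts and mean
    encounter frequency versus bout duration.  Results are survival curves
    on ``grid`` (s).
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.linspace(0.0, 6.0, 61)
    samples = {("stop", k): [] for k in ("all", "isolated", "clump", "random")}
    samples.update({("walk", k): [] for k in ("all", "isolated", "clump", "random")})
    bout_rows = []
    for train in trains * max(int(n_repeats), 1):
        dt = train.time_step
        walking = simulate_transitions(stop_spec, walk_spec, train.w, train.d,
                                       dt, rng=rng)
        onset_steps = np.flatnonzero(train.w)
        labels = classify_onsets(onset_steps * dt)
        stop_steps = np.flatnonzero(walking[:-1] & ~walking[1:]) + 1
        walk_steps = np.flatnonzero(~walking[:-1] & walking[1:]) + 1
        for state, ev in (("stop", stop_steps), ("walk", walk_steps)):
            active = walking if state == "stop" else ~walking
            samples[(state, "all")].append(
                _time_to_event(ev, onset_steps, dt, active))
            samples[(state, "isolated")].append(
                _time_to_event(ev, onset_steps[labels["isolated"]], dt, active))
            samples[(state, "clump")].append(
                _time_to_event(ev, onset_steps[labels["clump"]], dt, active))
            act_idx = np.flatnonzero(active)
            if act_idx.size:
                rnd = rng.choice(act_idx, size=min(onset_steps.size + 1,
                                                   act_idx.size), replace=False)
                samples[(state, "random")].append(
                    _time_to_event(ev, np.sort(rnd), dt, active))
        # per-bout encounter bookkeeping (walk bouts)
        change = np.flatnonzero(np.diff(walking.astype(np.int8))) + 1
        starts = np.concatenate(([0], change))
        stops_ = np.concatenate((change, [walking.size]))
        for a, b in zip(starts, stops_):
            if not walking[a] or b >= walking.size:
                continue
            n_enc = int(train.w[a:b].sum())
            dur = (b - a) * dt
            bout_rows.append(dict(duration=dur, n_encounters=n_enc,
                                  freq=n_enc / dur))
    out = dict(grid=grid, curves={}, n={}, bouts=pd.DataFrame(bout_rows))
    for key, lists in samples.items():
        pooled = np.concatenate(lists) if lists else np.array([])
        out["n"][key] = pooled.size
        if key[1] in ("isolated", "clump") and pooled.size < min_condition_events:
            warnings.warn(f"too few {key[1]} events for the {key[0]} curve; omitted")
            out["curves"][key] = np.full(grid.size, np.nan)
        else:
            out["curves"][key] = _survival(pooled, grid)
    return out


def _empirical_statistics(data: BoutData, grid: np.ndarray,
                          min_condition_events: int = 25) -> dict:
    """Conditioned survival curves computed from labeled (observed) data."""
    rng = np.random.default_rng(0)
    curves = {}
    conds = ("all", "isolated", "clump", "random")
    samples = {(s, k): [] for s in ("stop", "walk") for k in conds}
    dt = data.time_step
    for tr in data.trajectories:
        walking = np.asarray(tr["walking"], dtype=bool)
        onset_steps = np.flatnonzero(tr["w"])
        labels = classify_onsets(onset_steps * dt)
        stop_steps = np.flatnonzero(walking[:-1] & ~walking[1:]) + 1
        walk_steps = np.flatnonzero(~walking[:-1] & walking[1:]) + 1
        for state, ev in (("stop", stop_steps), ("walk", walk_steps)):
            active = walking if state == "stop" else ~walking
            samples[(state, "all")].append(_time_to_event(ev, onset_steps, dt, active))
            samples[(state, "isolated")].append(
                _time_to_event(ev, onset_steps[labels["isolated"]], dt, active))
            samples[(state, "clump")].append(
                _time_to_event(ev, onset_steps[labels["clump"]], dt, active))
            act_idx = np.flatnonzero(active)
            if act_idx.size:
                rnd = rng.choice(act_idx, size=min(onset_steps.size + 1,
                                                   act_idx.size), replace=False)
                samples[(state, "random")].append(
                    _time_to_event(ev, np.sort(rnd), dt, active))
    for key, lists in samples.items():
        pooled = np.concatenate(lists) if lists else np.array([])
        if key[1] in ("isolated", "clump") and pooled.size < min_condition_events:
            curves[key] = np.full(grid.size, np.nan)
        else:
            curves[key] = _survival(pooled, grid)
    return curves


def compare_models(fitted: dict, held_out: BoutData, direction: str,
                   seed=None, grid=None, compute_discrepancy: bool = True
                   ) -> dict:
    """Cross-validated comparison of fitted rate models of one direction.

    ``fitted`` maps family name -> RateModelSpec (all with ``direction``).
    For each model: the held-out bout log-likelihood (the cross-validation
    score), AIC and BIC on the held-out data, and -- unless disabled -- a
    prediction discrepancy: the summed squared deviation between
    model-simulated and empirical held-out conditioned survival curves
    (post-encounter all/isolated/clump and random-time, for the relevant
    state).  Selection is by largest held-out log-likelihood, the
    predictive score that generalizes the visual curve comparison; exact
    ties are reported, not broken silently.
    """
    if grid is None:
        grid = np.linspace(0.0, 6.0, 61)
    for fam, spec in fitted.items():
        if spec.direction != direction:
            raise ValueError(f"model {fam} has direction {spec.direction}, "
                             f"expected {direction}")
    state = "stop" if direction == "walk_to_stop" else "walk"
    emp = _empirical_statistics(held_out, grid) if compute_discrepancy else None
    # trains of the held-out trajectories drive the model simulations
    from .signal_encounters import EncounterSeries
    trains = []
    for tr in held_out.trajectories if compute_discrepancy else []:
        w = np.asarray(tr["w"])
        d = np.asarray(tr["d"])
        idx = []
        onsets = np.flatnonzero(w)
        for o in onsets:
            e = o + 1
            while e < d.size and d[e] and not w[e]:
                e += 1
            idx.append((o, e))
        trains.append(EncounterSeries.from_intervals(idx, w.size, held_out.time_step))
    rng = np.random.default_rng(seed)
    rows = {}
    n_obs = sum(int(np.asarray(tr["walking"], dtype=bool).sum()
                    if direction == "walk_to_stop"
                    else (~np.asarray(tr["walking"], dtype=bool)).sum())
                for tr in held_out.trajectories)
    for fam, spec in fitted.items():
        ll = bout_log_likelihood(spec, held_out)
        k = spec.n_params
        disc = np.nan
        if compute_discrepancy:
            pair = ((spec, _default_other(spec, held_out))
                    if direction == "walk_to_stop"
                    else (_default_other(spec, held_out), spec))
            stats = generate_model_statistics(pair[0], pair[1], trains,
                                              seed=rng.integers(2 ** 31),
                                              grid=grid, n_repeats=3)
            disc = 0.0
            for cond in ("all", "isolated", "clump", "random"):
                a = stats["curves"][(state, cond)]
                b = emp[(state, cond)]
                m = np.isfinite(a) & np.isfinite(b)
                disc += float(((a[m] - b[m]) ** 2).sum())
        rows[fam] = dict(held_out_logL=ll, AIC=2 * k - 2 * ll,
                         BIC=k * np.log(max(n_obs, 1)) - 2 * ll,
                         discrepancy=disc)
    table = pd.DataFrame(rows).T
    best = table.held_out_logL.max()
    winners = list(table.index[table.held_out_logL == best])
    return dict(table=table, selected=winners[0], tie=len(winners) > 1,
                winners=winners)


def _default_other(spec: RateModelSpec, data: BoutData) -> RateModelSpec:
    """Constant-rate companion model for the opposite direction, matched to
    the empirical mean transition rate of the held-out data (used only to
    complete the two-state simulation when comparing one direction)."""
    other_dir = ("stop_to_walk" if spec.direction == "walk_to_stop"
                 else "walk_to_stop")
    dt = data.time_step
    n_steps = sum(int((~np.asarray(tr["walking"], dtype=bool)).sum()
                      if other_dir == "stop_to_walk"
                      else np.asarray(tr["walking"], dtype=bool).sum())
                  for tr in data.trajectories)
    n_trans = data.n_transitions(other_dir)
    lam = max(n_trans, 1) / max(n_steps * dt, dt)
    return RateModelSpec("last_encounter", other_dir,
                         dict(lam0=lam, dlam=0.0, tau=1.0))
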