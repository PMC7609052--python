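# plumewalk

Stochastic-decision analysis of walking insects navigating intermittent
odor plumes.

In a turbulent plume, odor arrives as brief, unpredictable *encounters* —
intervals during which the signal at the antennae exceeds a sensory
threshold — separated by blanks whose durations span orders of magnitude.
`plumewalk` implements, fits, and simulates a family of models in which
navigation emerges from three stochastic behavioral decisions modulated by
the *timing* of recent encounters:

* **Saccadic turning.** Turns fire as a Poisson process (timescale
  τ_T = 0.75 s) with discrete magnitudes |Δθ| ~ |N(30°, 10°²)|; each turn
  is directed upwind with probability p_T = (1 + e^(−αS))⁻¹, where S is the
  exponentially filtered encounter-onset train (τ = 2 s) and α the sigmoid
  gain.
* **Stopping.** While walking, the stop hazard follows an inhomogeneous
  Poisson rate λ_w→s(t) = λ₀ + Δλ·e^(−ΔT(t)/τ_s) that resets at every
  encounter onset (ΔT = time since the last onset) — the *last encounter*
  model — with competing *accumulated evidence* and *encounter duration*
  families fit and compared by cross-validation.
* **Walk initiation.** While stopped, the walk hazard follows the
  accumulated-evidence rate λ_s→w(t) = λ₀ + Δλ·F(t), with F the filtered
  onset train, against the same two competitors.

Around the models, the package provides the full pipeline: a synthetic
plume generator calibrated to realistic perceived-encounter statistics,
virtual-antenna signal extraction and encounter detection (2.5 σ threshold,
50 ms persistence), trajectory smoothing and stop/walk/saccade
segmentation, maximum-likelihood fitting over bootstrapped trajectory
subsets, post-encounter orientation analyses with a standardized trilinear
regression, and a 10,000-agent navigation simulator with component
ablations. Everything runs on synthetic data generated in-package; no
external downloads are required.

## Worked example

Simulate labeled behavior from the fitted models and re-estimate the
stopping-model parameters:

```python
import numpy as np
from plumewalk.synthetic_world import (EncounterTrainConfig,
                                       generate_encounter_train,
                                       simulate_ground_truth_behavior)
from plumewalk.stopwalk_models import (fitted_stop_spec, fitted_walk_spec,
                                       fit_rate_model)
from plumewalk.turn_model import TurnModelParams
from plumewalk._pipeline import behaviors_to_bout_data

trains = [generate_encounter_train(EncounterTrainConfig(
    onset_rate=4.0, duration_sampler=("constant", {"value": 0.05}),
    total_time=90.0, seed=21000 + i)) for i in range(500)]
behaviors = simulate_ground_truth_behavior(
    TurnModelParams(), fitted_stop_spec(), fitted_walk_spec(),
    trains, 500, seed=101)
bouts = behaviors_to_bout_data(behaviors)
fit = fit_rate_model("last_encounter", "walk_to_stop", bouts,
                     n_subsets=20, subset_fraction=0.2, seed=102)
print({k: round(v, 3) for k, v in fit.medians.items()})
```

prints

```
{'lam0': 0.789, 'dlam': -0.63, 'tau': 0.259}
```

— the subset-median maximum-likelihood estimates recover the generating
parameters (baseline stop rate 0.78 s⁻¹, onset drop −0.61 s⁻¹, recovery
timescale 0.25 s): at each encounter the stopping hazard falls to
λ₀ + Δλ ≈ 0.17 s⁻¹, about a five-fold suppression, and relaxes back within
a quarter second.

A command-line interface wraps the pipeline stages
(`plumewalk synth-plume`, `synth-behavior`, `detect`, `segment`,
`fit-turn`, `fit-stopwalk`, `compare`, `simulate`, `report`); every
subcommand takes `--config` (YAML), `--seed`, and `--out`, and writes a
run manifest alongside its outputs.

## Layout

| module | contents |
| --- | --- |
| `synthetic_world` | packet-based plume generator, encounter trains, ground-truth behavior |
| `signal_encounters` | virtual antenna, background fit, encounter detection, filtered signals, plume statistics |
| `kinematics_events` | Savitzky–Golay smoothing, branch-cut-free angular velocity, stop/walk/saccade segmentation |
| `turn_model` | sigmoidal-bias saccade model: likelihood, subset MLE, simulation |
| `stopwalk_models` | six transition-rate models, bout likelihoods, MLE, model statistics, cross-validated comparison |
| `orientation_regression` | post-encounter orientation analyses, trilinear regression |
| `agent_sim` | agent-based navigator, ablations, performance metrics, occupancy |
| `config`, `io`, `cli` | YAML configs, deterministic seeding, HDF5/TSV I/O, command line |

See `docs/methods.md` for the models, conventions, numerical choices, and
limitations.
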