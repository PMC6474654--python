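# scrval

Simulation-based validation of spatial capture-recapture (SCR) density
estimation under **spatially unstructured sampling** — the situation faced
by, e.g., mountain-lion surveys that search for sign with scent-detection
dogs rather than operating fixed detectors.  Detections are referenced to a
post-hoc grid of trapping cells with a per-cell, per-occasion search-effort
covariate, and the question the package answers is: *given a level of
search effort, and given optional extra data from harvested animals and a
few GPS collars, how biased and how precise are the resulting density
estimates?*

The package provides, as importable modules and a small CLI:

* a **generative simulator** — a spatially autocorrelated habitat field on
  a 100 x 100 km landscape of 2,500 cells; activity centers from the
  inhomogeneous Poisson intensity `mu = exp(-4 + 0.5 * Habitat) * 4 km^2`
  conditioned on N = 200 (or 400) animals; Dirichlet-allocated search
  effort over 100 trapping cells; and cloglog-hazard encounter, harvest and
  telemetry processes sharing sex-specific scale parameters
  (`log sigma_male = -0.65`, `log sigma_female = -0.85`, distances in 5-km
  units);
* an **integrated maximum-likelihood SCR estimator** on the discrete
  landscape state space,

  `cloglog(p_ijt) = beta0 + beta_eff * log(effort_jt) - d(x_j, s_i) / (2 sigma_sex^2)`,

  marginalizing activity centers over cells with intensity
  `lambda_k = exp(a0 + a1 * Habitat_k)`, optionally folding in harvest
  records as effort-"borrowed" pseudo-detections with post-harvest
  censoring, and telemetry as an independent multinomial likelihood;
* a **study harness** that crosses six effort/correlation scenarios with
  four data-integration models (M1 encounters only, M2 +harvest, M3/M4
  +2/+4 collars per sex), fits every model to each replicate dataset, and
  reports mean, SD, percentiles, CV = SD/mean and relative bias
  RB = (mean - truth)/truth of the density estimates.

See `docs/methods.md` for the model, its assumptions, and numerical
choices.

## Worked example

Simulate one low-effort dataset (scenario 1: 2,000 km of search per
occasion, uncorrelated with density), fit the encounter+harvest model, and
inspect the density estimate:

```python
from scrval import (MODELS, ScenarioSpec, simulate_dataset,
                    build_state_space, merge_harvest_as_detections, fit_scr)

data = simulate_dataset(ScenarioSpec.from_id(1), master_seed=7, rep_index=0)
print(data.summary_encounter)   # encounter-only dataset summary
print(data.summary_merged)      # after folding in harvest records

capture = merge_harvest_as_detections(data.encounters, data.harvest, data.effort)
statespace = build_state_space(data.landscape, data.traps)
fit = fit_scr(capture, statespace)
print(f"density {fit.density_per_100km2:.2f} per 100 km^2 "
      f"(truth 2.00), converged={fit.converged}")
```

which prints

```
DatasetSummary(n=27, recap=1.2962962962962963, spatial_recap=1.2222222222222223)
DatasetSummary(n=50, recap=1.32, spatial_recap=1.24)
density 2.59 per 100 km^2 (truth 2.00), converged=True
```

Only 27 of 200 animals were detected by search (about 1.3 detections
each), 50 after adding harvest records; one sparse replicate like this
typically overestimates density — quantifying that bias *across* replicates
is the point of the harness:

```python
from scrval import run_study, summarize_study

results = run_study([ScenarioSpec.from_id(1)], [MODELS["M1"], MODELS["M2"]],
                    n_reps=50, master_seed=42, coarsen=2)
print(summarize_study(results, truth_density=2.0)
      [["model", "mean", "cv", "rb", "n_converged"]])
```

The same pipeline is scriptable from a shell: `scrval simulate`,
`scrval fit` and `scrval study` read/write documented CSV/JSON artifacts
(`landscape.csv`, `effort.csv`, `captures.csv` in long one-row-per-detection
format, `telemetry.csv`, `fit.json`); see `scrval --help`.

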