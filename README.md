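# luvburst

Analysis toolkit for a single-vesicle membrane-permeabilization assay, for
researchers screening membrane-disrupting agents (ionophores, antimicrobial
peptides, amyloid oligomers) against model lipid membranes.

Dye-loaded large unilamellar vesicles (LUVs) flow through a confocal probe
at ~1000 vesicles per minute. Each vesicle encapsulates on average ~7.5
turn-on Ca²⁺ indicator molecules; when a permeabilizing agent admits
external Ca²⁺, the indicator brightens ~40-fold and the vesicle's transit
registers as a photon burst. The package implements the full analysis
chain and a stochastic simulator of the raw data:

- **stoichiometry** — vesicle geometry ↔ concentrations ↔ molecules per
  vesicle (the assay's sensitivity arithmetic);
- **synthetic** — simulated photon-count traces with per-vesicle ground
  truth: Poisson arrivals, Poisson(7.5) dye occupancy, two-state
  brightness, Gaussian transits, shot noise, size-exclusion dye leakage,
  and control scenarios (blank / Ca²⁺-only / fully permeabilized /
  detergent-lysed);
- **burst** — threshold event counting on binned traces (default: bins of
  100 µs, events strictly above 50 counts/bin over a 5-min window) and the
  normalized response `f_norm = (f_sample − f_min)/(f_max − f_min)`,
  anchored per batch at the Ca²⁺-only blank (0) and the fully
  permeabilized reference (1);
- **dose_response** — replicate summaries, Hill-equation fitting
  `f(d) = bottom + (top − bottom)·dⁿ/(EC50ⁿ + dⁿ)` with deterministic
  grid-seeded least squares, EC50 standard errors, and a 3σ detection
  limit;
- **imaging** — SAVE-style single-aggregate counting on TIRF images:
  synthetic diffraction-limited puncta plus robust detection
  (median/MAD background, k·σ threshold, connected components), reporting
  surface density per µm²;
- **io** / **cli** — text trace format, YAML run configs, and a
  `luvburst` command with `stoich`, `simulate`, `count`, `fit`,
  `save-count`, and `run` subcommands.

## Worked example

Simulate a complete dose–response experiment — a ladder of eight ionomycin
doses plus the three controls, three replicate records each — then count
bursts, normalize, and fit the Hill model:

```python
import numpy as np
import luvburst as lb

cfg = lb.RunConfig(
    seed=1,
    sim=lb.SimConfig(duration_s=60.0),          # 60 s records, 100 us bins
    analysis=lb.AnalysisConfig(window_s=60.0),  # threshold 50 counts/bin
    doses=tuple(np.geomspace(0.001, 0.3, 8).round(6)),  # mol% vs lipid
    ec50_molpct=0.010, hill_n=1.0,              # generating ground truth
    replicates=3,
)
report = lb.run_pipeline(cfg)
fit = report["fit"]
print(f"EC50 = {fit['ec50_molpct']:.4f} ± {fit['ec50_se_molpct']:.4f} mol%, "
      f"n = {fit['hill_n']:.2f}, converged = {fit['converged']}")
```

prints

```
EC50 = 0.0094 ± 0.0003 mol%, n = 1.05, converged = True
```

The fitted EC50 (0.0094 mol%) recovers the generating value (0.010 mol%)
to within the Monte-Carlo error of ~1000-transit records; the Hill slope
comes back near the generating 1.0. Each dose's normalized response sits
between 0 (the batch's Ca²⁺-only blank) and 1 (its fully permeabilized
reference) by construction of the anchoring.

The sensitivity arithmetic behind the assay:

```sh
$ luvburst stoich --dose-molpct 0.0027
```

reports, for the standard prep (5 µM lipid, 5 µM dye, 200 nm vesicles),
~7.7 dyes per vesicle, ~15 pM of vesicles, and — at a 0.0027 mol% dose —
135 pM of agent, ~9 molecules per vesicle, and 13.5 fmol in a 100 µL
sample.

See `docs/methods.md` for the generative model, parameter defaults, and
numerical choices.

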