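# Methods

## The assay in brief

Large unilamellar vesicles (LUVs, ~200 nm POPC) are loaded with a handful
of turn-on Ca²⁺ indicator molecules and flowed through a diffraction-limited
confocal probe at roughly a thousand vesicles per minute. In the presence
of external Ca²⁺, a membrane-permeabilizing agent lets the cation in; the
indicator brightens, and the vesicle's transit produces a photon burst far
above background. Counting bursts over a fixed observation window, and
normalizing a sample's count against the same batch's blank and fully
permeabilized reference, yields a dimensionless activity readout whose dose
dependence follows the Hill equation. A companion TIRF modality counts
individual dye-bound protein aggregates as diffraction-limited puncta and
reports their surface density.

`luvburst` implements the complete analysis chain plus a stochastic
simulator of the raw observables, so every stage can be validated against
known ground truth without experimental records.

## Stoichiometry

Pure arithmetic, SI units internally (lengths nm, volumes L,
concentrations M):

- encapsulated volume: `V = (π/6) d³` for diameter `d`;
- mean encapsulated dyes: `λ = c_dye · V · N_A` (occupancy is Poisson(λ)
  because vesicles close around a dilute solution);
- lipids per vesicle: outer plus inner leaflet areas over the area per
  lipid (0.72 nm² for fluid POPC), inner radius reduced by the 5 nm
  bilayer;
- vesicle concentration: lipid concentration over lipids per vesicle;
- doses in mol% relative to lipid convert to molarity as
  `(mol%/100) · c_lipid`.

Two diameters are deliberately distinct: the nominal 200 nm extrusion pore
for the lipid count (and hence vesicle concentration) and the smaller
measured mean (default 170 nm; sizing typically reports 160–180 nm) for
the encapsulated volume. Under the standard prep (5 µM lipid, 5 µM dye)
this yields ~15 pM vesicles carrying ~7.5 dyes each, and a 0.0027 mol%
dose corresponds to ~135 pM of agent — between 8 and 9 molecules per
vesicle and under 15 fmol in a 100 µL sample.

The lysis dilution factor (encapsulated dye concentration over the bulk
concentration after complete lysis, `c_dye / (c_ves · λ)`) evaluates to
~4×10⁴ under these defaults. Published descriptions of comparable preps
quote an order-of-magnitude 10⁵; the compositional formula is what the
main-text numbers support, and the ~2.4× gap is left standing rather than
tuned away.

No polydispersity, lamellarity, or encapsulation-efficiency corrections
are applied; the arithmetic is the idealized single-population model.

## Simulator

One acquisition is generated as:

1. transit times: homogeneous Poisson process at `arrival_rate`
   (default 16.7 s⁻¹ ≈ 1000/min) over `duration` (default 300 s);
2. per vesicle: `n_dyes ~ Poisson(mean_dyes = 7.5)`,
   `permeabilized ~ Bernoulli(p)`, and a dye-retention draw (below);
3. instantaneous signal rate: each transit adds a temporal Gaussian
   `peak · exp(−(t−t₀)²/2σ²)` with `σ = transit_sigma` (default 50 µs) and
   `peak = n_dyes ×` the bright (2×10⁵ photons/s, Ca²⁺-bound) or dark
   (5×10³ photons/s, Ca²⁺-free) per-dye rate. Overlapping transits add —
   no exclusion, since pM occupancies make coincidences rare and
   additivity is physically right;
4. per 100 µs bin: counts `~ Poisson((background + signal at bin
   centre) · bin_width)`.

Parameter choices and their reasoning:

- **bin width 100 µs** is the only reading consistent with a 50 counts/bin
  threshold equalling 50×10⁴ photons/s; the transit σ of 50 µs makes a
  burst span one or two bins, matching binning at the expected probe
  residence time;
- **background 3.3×10³ photons/s** puts the blank mean at ~0.33 counts/bin,
  i.e. the 50-count threshold sits ~150× above the blank intensity;
- **turn-on ratio 40×** (bright/dark) is a configurable stand-in for the
  indicator's Ca²⁺ enhancement; no published per-molecule number is
  assumed. Dark vesicles at 7.5 dyes peak near 4 counts/bin — occasionally
  visible, never above threshold;
- **arrival rate** is free: the flow velocity behind the observed
  detection rate is not derivable from first principles here, so the
  default simply reproduces the ~1000/min regime.

Draw order is fixed (arrival count, times, occupancies, permeabilization,
leak, shot noise), so a seed determines the trace and truth list
bit-exactly.

**Dye leakage.** A `LeakModel` compares the dye's hydrodynamic diameter
with the pore diameter: a dye larger than the pore is always retained
(size exclusion — the mechanism by which a 10 kDa dextran conjugate,
Stokes diameter ~46 Å, survives 5–11 Å barrel-stave pores); a dye that
fits escapes with probability `leak_probability_if_fits`, a free knob
because transient pores (10–60 Å class) need not flush the lumen. Leakage
is only resolved for permeabilized vesicles — an intact membrane has no
pore to leak through. A leaked vesicle contributes zero signal.

**Scenarios.** `blank` (no Ca²⁺: all dark), `calcium_only` (Ca²⁺ without
agent: a 2% defective/leaky fraction lights up), `permeabilized`
(reference, p = 1), and `triton` (lysis: no transits; the released dye,
diluted ~4×10⁴-fold, raises the continuous background by its mean
occupancy of a 1 fL probe volume times the bright rate — about 1 count/bin,
far below threshold, so lysed samples are eventless by construction of the
physics, not by fiat). Dosed samples use
`p(d) = baseline + (1−baseline)·Hill(d)` with baseline = the 2% defective
fraction, so the dose response rides on the same baseline the blank anchor
subtracts.

Not modelled: 3-D probe/flow physics, photobleaching (fast flow makes
exposure brief), indicator photophysics beyond the two brightness states,
diffusional broadening of transits.

## Burst counting and normalization

Bins with counts **strictly greater** than the threshold (default 50) are
suprathreshold; the default `per_excursion` definition merges each maximal
contiguous run into one event (one transit = one burst), with `per_bin`
available since either reading of "bursts exceeding a threshold" is
defensible. Counts are taken over the first analysis window (default
300 s); shorter traces are rejected rather than extrapolated because the
readout is window-extensive. `rebin` sums integer groups of bins exactly
for records acquired at finer binning.

The activity statistic is `f_norm = (f_sample − f_min)/(f_max − f_min)`
with `f_min` the Ca²⁺-only blank and `f_max` the fully permeabilized
reference *of the same batch* — event counts vary between vesicle batches,
so anchors are mandatory per batch and never defaulted. Values below 0
(agents that suppress events, e.g. by dye leakage) and above 1 are
preserved.

A caveat found by property testing: per-excursion counts are **not**
monotone in the threshold (raising it can split one burst into two); only
the per-bin count is. The per-excursion count is instead bounded above by
the per-bin count on every trace.

## Dose–response fitting

Per dose, replicates are summarized by the sample mean and n−1 standard
deviation (single replicates are flagged degenerate). The Hill model

    f(d) = bottom + (top − bottom) · dⁿ / (EC50ⁿ + dⁿ)

is fitted by least squares on the per-dose means. `bottom` is fixed at 0
by default (the response is blank-anchored by construction) and can be
freed for negative-response assays; weighting is off by default with
1/sd² optional. Internally the model is the logistic in log-dose with
parameters (log EC50, log n, top[, bottom]); initialization scans a
deterministic 25×7 grid over (log EC50, n) spanning a decade beyond the
dose range, solving the linear parameters exactly at each node, and the
best node seeds a Levenberg–Marquardt polish at tight (1e-15) tolerances.
Fits are therefore reproducible and recover noiseless curves to ≤1e-6
relative error. Zero doses cannot sit on a log axis and are excluded from
the fit. The EC50 standard error comes from the residual-scaled Gauss–
Newton covariance via the delta method on log EC50; non-convergence and
singular covariances set `converged = False`, never silently.

The 3σ detection limit is the smallest tested dose whose mean response
exceeds three times the blank's replicate standard deviation (computed, in
the pipeline, from the no-Ca²⁺ blank's normalized responses, since the
Ca²⁺-only anchor is identically zero within each replicate).

## Aggregate counting (TIRF)

Synthetic fields place `n` isotropic 2-D Gaussian puncta (PSF σ default
1.2 px) of given peak amplitude at uniform-random subpixel positions on a
constant background, then apply per-pixel Poisson noise. Crowding beyond a
mean nearest-neighbour distance of 2σ raises a warning — counting is
ill-posed there, not silently wrong.

Detection: Gaussian smoothing (σ 1 px) → robust background as
median ± 1.4826·MAD (the median is insensitive to the spots themselves,
which would bias a mean/sd estimate) → threshold at background + k·sd
(k = 5, the conservative single-molecule convention) → 8-connected
components → minimum area 4 px → intensity-weighted centroids. Density is
spots per image area in µm². A spread-free image returns an empty result
flagged `degenerate-background`. At SNR 20 and 0.01 spots/µm² (the early
aggregate density scale), recall is ≥95% with ≤5% false positives against
generator truth; these figures are validated in the test suite, and say
nothing about crowded, dim, or structured-background real images.

## Pipeline and problem sizes

`run_pipeline` simulates the scenario ladder (blank, Ca²⁺-only,
doses, reference) with every record drawn from an independent child of one
master seed (`numpy` `SeedSequence` spawning), counts, normalizes within
each replicate, fits, and emits a JSON report echoing the full
configuration. Identical config + seed gives a byte-identical report.

Validation uses 60 s records (one fifth of the standard 5-min window) for
the end-to-end dose ladder and 10 s records for scenario contrasts: at
~17 transits/s these already give hundreds to a thousand transits per
record, which sets the Monte-Carlo error on recovered parameters at a few
percent while keeping a full ladder under a few seconds. The end-to-end
EC50 recovery tolerance (25%) reflects that sampling error, not the
fitter's accuracy (≤1e-6 on noiseless data).

## What passing tests do and do not show

The simulator realizes exactly the statistical assumptions the analysis
makes (Poisson arrivals, Poisson occupancy, two-state brightness, Gaussian
transits, Poisson shot noise). Recovery tests therefore validate the
implementation chain, not the assay's robustness to real-world deviations:
detector afterpulsing/dead time, flow instability, vesicle polydispersity
and multilamellarity, indicator photophysics, or structured TIRF
backgrounds are all outside the generative model and untested by
construction.
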