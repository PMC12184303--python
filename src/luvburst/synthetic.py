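"""Stochastic simulator of the flow-confocal vesicle assay.

Generates binned photon-count traces with the statistical structure the
assay assumes, plus per-vesicle ground truth, so every downstream stage is
testable without experimental records.

Generative model
----------------
Vesicle transits through the confocal probe form a homogeneous Poisson
process at ``arrival_rate``.  Each vesicle carries ``n ~ Poisson(mean_dyes)``
indicator molecules (vesicles assemble in a dye solution, so occupancy is
Poissonian) and is permeabilized with probability
``permeabilized_fraction``.  Indicator brightness is two-state: a dim
Ca2+-free level and a bright Ca2+-bound level (turn-on dyes such as Fluo-8
are ~40x brighter when complexed).  A transit contributes a temporal
Gaussian of width ``transit_sigma`` (plug flow through a Gaussian probe
profile) with peak rate ``n_dyes * brightness``; overlapping transits add.
Per-bin photon counts are Poisson draws of (background + signal at the bin
centre) x bin width — shot-noise-limited detection.

Pores narrower than the dye let nothing out; pores wide enough for the dye
to pass may flush it before detection (``LeakModel``), zeroing that
vesicle's signal.  This reproduces the dye-size/pore-size logic by which a
dextran-conjugated indicator (Stokes diameter ~46 A) stays inside 5-11 A
alamethicin pores while a free dye escapes.

Sub-draw order is fixed (arrival count, arrival times, dye occupancies,
permeabilization flags, leak draws, then per-bin shot noise), so a given
seed yields a bit-identical trace and truth list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .burst import PhotonTrace
from .stoichiometry import AVOGADRO, VesiclePrep, lysis_dilution_factor

__all__ = [
    "SimConfig",
    "LeakModel",
    "TransitTruth",
    "simulate_trace",
    "permeabilized_fraction_from_dose",
    "resolve_leak",
    "make_scenario",
    "dose_config",
    "SCENARIOS",
    "DEFAULT_BASELINE_LEAKY_FRACTION",
    "DEFAULT_PROBE_VOLUME_L",
]

#: Fraction of defective, partially leaky liposomes that light up with
#: Ca2+ alone (no permeabilizing agent).
DEFAULT_BASELINE_LEAKY_FRACTION = 0.02

#: Effective confocal probe volume, litres (femtolitre-scale focus).
DEFAULT_PROBE_VOLUME_L = 1e-15

SCENARIOS = ("blank", "calcium_only", "permeabilized", "triton")


@dataclass(frozen=True)
class LeakModel:
    """Size-exclusion dye leakage through membrane pores.

    If the dye's hydrodynamic diameter exceeds the pore diameter the dye is
    always retained.  Otherwise it escapes (before the vesicle reaches the
    probe) with probability ``leak_probability_if_fits`` — pores may be
    transient, so fitting through does not guarantee escape.
    """

    dye_diameter_A: float
    pore_diameter_A: float
    leak_probability_if_fits: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dye_diameter_A > 0 and self.pore_diameter_A > 0):
            raise ValueError("diameters must be positive")
        if not 0.0 <= self.leak_probability_if_fits <= 1.0:
            raise ValueError("leak probability must be in [0, 1]")


@dataclass(frozen=True)
class TransitTruth:
    """Ground truth for one simulated vesicle transit."""

    arrival_time_s: float
    n_dyes: int
    permeabilized: bool
    dye_retained: bool
    peak_rate: float  # photons/s at the transit centre


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated acquisition.

    Defaults reproduce the standard assay conditions: 5-min records in
    100 us bins, ~1000 vesicle transits per minute (16.7/s), a 50 us
    Gaussian transit so a burst spans one or two bins, background set so
    the blank trace averages ~1/150 of the 50-count threshold per bin
    (~3.3e3 photons/s), 7.5 dyes per vesicle, and a 40x turn-on ratio
    between the Ca2+-bound and Ca2+-free indicator states.
    """

    duration_s: float = 300.0
    bin_width_s: float = 1e-4
    background_rate: float = 3.3e3  # photons/s
    arrival_rate: float = 1000.0 / 60.0  # transits/s
    transit_sigma_s: float = 5e-5
    brightness_dark: float = 5e3  # photons/s per dye, Ca2+-free
    brightness_bright: float = 2e5  # photons/s per dye, Ca2+-bound
    mean_dyes: float = 7.5
    permeabilized_fraction: float = 0.0
    leak: LeakModel | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.duration_s > 0 and self.bin_width_s > 0 and self.transit_sigma_s > 0):
            raise ValueError("duration, bin_width and transit_sigma must be positive")
        if self.bin_width_s >= self.duration_s:
            raise ValueError("bin_width must be smaller than duration")
        if min(self.background_rate, self.arrival_rate, self.mean_dyes) < 0:
            raise ValueError("rates and mean_dyes must be non-negative")
        if not self.brightness_bright > self.brightness_dark >= 0:
            raise ValueError("require brightness_bright > brightness_dark >= 0")
        if not 0.0 <= self.permeabilized_fraction <= 1.0:
            raise ValueError("permeabilized_fraction must be in [0, 1]")


def permeabilized_fraction_from_dose(
    dose_molpct: float, ec50_molpct: float, hill_n: float
) -> float:
    """Hill-form per-vesicle permeabilization probability.

    d^n / (EC50^n + d^n): 0 at zero dose, 1/2 at the EC50, saturating at 1.
    The population dose-response curve inherits this form because each
    vesicle responds independently.
    """
    if dose_molpct < 0:
        raise ValueError("dose must be non-negative")
    if not ec50_molpct > 0 or not hill_n > 0:
        raise ValueError("ec50 and hill_n must be positive")
    if dose_molpct == 0.0:
        return 0.0
    # work with the ratio to stay stable for extreme doses
    r = (dose_molpct / ec50_molpct) ** hill_n
    return r / (1.0 + r)


def resolve_leak(model: LeakModel, rng: np.random.Generator) -> bool:
    """Whether the dye stays inside a permeabilized vesicle.

    Returns True (retained) when the dye is larger than the pore; otherwise
    retained with probability 1 - leak_probability_if_fits.
    """
    if model.dye_diameter_A > model.pore_diameter_A:
        return True
    return bool(rng.random() >= model.leak_probability_if_fits)


def simulate_trace(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PhotonTrace, list[TransitTruth]]:
    """Simulate one binned photon-count record plus per-vesicle truth.

    Returns the trace and a list of :class:`TransitTruth`, one per vesicle
    that entered the probe during the record (sorted by arrival time).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n_bins = round(config.duration_s / config.bin_width_s)
    t_centres = (np.arange(n_bins) + 0.5) * config.bin_width_s

    n_transits = rng.poisson(config.arrival_rate * config.duration_s)
    arrivals = np.sort(rng.uniform(0.0, config.duration_s, size=n_transits))
    n_dyes = rng.poisson(config.mean_dyes, size=n_transits)
    permeabilized = rng.random(n_transits) < config.permeabilized_fraction

    if config.leak is None:
        retained = np.ones(n_transits, dtype=bool)
    else:
        m = config.leak
        if m.dye_diameter_A > m.pore_diameter_A:
            retained = np.ones(n_transits, dtype=bool)
        else:
            draws = rng.random(n_transits)
            # leakage needs an open pore: only permeabilized vesicles leak
            retained = ~(permeabilized & (draws < m.leak_probability_if_fits))

    per_dye = np.where(permeabilized, config.brightness_bright, config.brightness_dark)
    peak_rates = np.where(retained, n_dyes * per_dye, 0.0)

    signal = np.zeros(n_bins)
    half_width = 6.0 * config.transit_sigma_s
    inv_2s2 = 1.0 / (2.0 * config.transit_sigma_s**2)
    for t0, peak in zip(arrivals, peak_rates):
        if peak == 0.0:
            continue
        lo = max(0, int((t0 - half_width) / config.bin_width_s))
        hi = min(n_bins, int((t0 + half_width) / config.bin_width_s) + 1)
        dt = t_centres[lo:hi] - t0
        signal[lo:hi] += peak * np.exp(-dt * dt * inv_2s2)

    lam = (config.background_rate + signal) * config.bin_width_s
    counts = rng.poisson(lam)

    trace = PhotonTrace(
        counts=counts, bin_width_s=config.bin_width_s, duration_s=config.duration_s
    )
    truth = [
        TransitTruth(
            arrival_time_s=float(arrivals[i]),
            n_dyes=int(n_dyes[i]),
            permeabilized=bool(permeabilized[i]),
            dye_retained=bool(retained[i]),
            peak_rate=float(peak_rates[i]),
        )
        for i in range(n_transits)
    ]
    return trace, truth


def make_scenario(
    name: Literal["blank", "calcium_only", "permeabilized", "triton"],
    base: SimConfig,
    prep: VesiclePrep | None = None,
    probe_volume_L: float = DEFAULT_PROBE_VOLUME_L,
    baseline_leaky_fraction: float = DEFAULT_BASELINE_LEAKY_FRACTION,
) -> SimConfig:
    """Derive a control-scenario configuration from a base config.

    blank
        Vesicles without Ca2+: every indicator stays dim
        (permeabilized_fraction 0).
    calcium_only
        Vesicles + Ca2+, no agent: a small fraction of defective,
        partially leaky liposomes lights up (default 2%).
    permeabilized
        The fully permeabilized reference (1 mol% ionomycin):
        permeabilized_fraction 1.
    triton
        Detergent lysis: no intact vesicles transit (arrival_rate 0) and
        the released dye — diluted by the lysis dilution factor of ``prep``
        (default standard prep) — raises the continuous background by the
        mean number of free Ca2+-bound dyes in the probe volume times their
        brightness.  The dilution is so large (~4e4-fold) that this adds
        only ~1 count/bin, far below any burst threshold.
    """
    if name == "blank":
        return replace(base, permeabilized_fraction=0.0)
    if name == "calcium_only":
        return replace(base, permeabilized_fraction=baseline_leaky_fraction)
    if name == "permeabilized":
        return replace(base, permeabilized_fraction=1.0)
    if name == "triton":
        if prep is None:
            prep = VesiclePrep()
        released_conc_M = prep.dye_loading_conc_M / lysis_dilution_factor(prep)
        mean_dyes_in_probe = released_conc_M * AVOGADRO * probe_volume_L
        extra_rate = mean_dyes_in_probe * base.brightness_bright
        return replace(
            base,
            arrival_rate=0.0,
            background_rate=base.background_rate + extra_rate,
        )
    raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")


def dose_config(
    base: SimConfig,
    dose_molpct: float,
    ec50_molpct: float,
    hill_n: float,
    baseline_leaky_fraction: float = DEFAULT_BASELINE_LEAKY_FRACTION,
) -> SimConfig:
    """Configuration for a sample dosed with a permeabilizing agent.

    The per-vesicle permeabilization probability composes the
    defective-liposome baseline (present in every sample, including the
    Ca2+-only blank) with the dose-dependent Hill term:

        p(d) = baseline + (1 - baseline) * Hill(d)

    so the blank-anchored normalized response recovers the Hill curve.
    """
    hill = permeabilized_fraction_from_dose(dose_molpct, ec50_molpct, hill_n)
    p = baseline_leaky_fraction + (1.0 - baseline_leaky_fraction) * hill
    return replace(base, permeabilized_fraction=min(p, 1.0))
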