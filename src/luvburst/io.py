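"""Trace file format, run configuration, and pipeline orchestration.

Traces are stored as plain columnar text with a two-line metadata header
(bin width and duration), so records survive version control and diffing.
A single YAML configuration file drives the full pipeline: simulate (or
load) a scenario ladder, count bursts, normalize against the batch's own
blank and fully-permeabilized reference, and fit the Hill model.

Normalization anchors are mandatory per batch: the blank (f_min) and the
fully permeabilized reference (f_max) must both be present, because event
counts vary between vesicle batches and cross-batch pooling is invalid.
A missing anchor is an error, never a silent default.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .burst import AnalysisConfig, PhotonTrace, count_events, normalized_response
from .dose_response import detection_limit, fit_hill, summarize_doses
from .stoichiometry import VesicleGeometry, VesiclePrep, lysis_dilution_factor
from .synthetic import SimConfig, dose_config, make_scenario, simulate_trace

__all__ = [
    "read_trace",
    "write_trace",
    "RunConfig",
    "run_pipeline",
    "stoichiometry_report",
]

logger = logging.getLogger("luvburst")

_TRACE_MAGIC = "# luvburst photon trace v1"


def write_trace(trace: PhotonTrace, path: str | Path) -> None:
    """Write a trace as headered columnar text (bin_index, counts)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_TRACE_MAGIC}\n")
        fh.write(f"# bin_width_s = {trace.bin_width_s!r}\n")
        fh.write(f"# duration_s = {trace.duration_s!r}\n")
        fh.write("bin_index\tcounts\n")
        for i, c in enumerate(trace.counts):
            fh.write(f"{i}\t{c}\n")


def read_trace(path: str | Path) -> PhotonTrace:
    """Read a trace written by :func:`write_trace`.

    Parse failures carry the offending line number.  Round trips are exact
    on counts and metadata.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty trace file")

    meta: dict[str, float] = {}
    counts: list[int] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                try:
                    meta[key.strip()] = float(val)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad metadata value {val.strip()!r}"
                    ) from exc
            continue
        if line.startswith("bin_index"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 'bin_index<TAB>counts', got {line!r}"
            )
        try:
            c = int(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer count {parts[1]!r}") from exc
        if c < 0:
            raise ValueError(f"{path}:{lineno}: negative count {c}")
        counts.append(c)

    for key in ("bin_width_s", "duration_s"):
        if key not in meta:
            raise ValueError(f"{path}: missing required metadata '{key}'")
    if not counts:
        raise ValueError(f"{path}: no count records found")
    return PhotonTrace(
        counts=np.asarray(counts, dtype=np.int64),
        bin_width_s=meta["bin_width_s"],
        duration_s=meta["duration_s"],
    )


@dataclass(frozen=True)
class RunConfig:
    """One reproducible end-to-end run.

    ``doses`` (mol% relative to lipid) are simulated at the generating
    ``ec50_molpct`` / ``hill_n`` with ``replicates`` independent records
    per sample, alongside the blank, Ca2+-only and fully permeabilized
    scenario controls.  Every random draw descends deterministically from
    ``seed``.
    """

    seed: int = 0
    prep: VesiclePrep = field(default_factory=VesiclePrep)
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    doses: tuple[float, ...] = ()
    ec50_molpct: float = 0.010
    hill_n: float = 1.0
    replicates: int = 3
    fix_bottom: float | None = 0.0
    weighted_fit: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        prep_raw = dict(raw.get("prep", {}))
        geometry = VesicleGeometry(
            diameter_nm=float(prep_raw.pop("diameter_nm", 200.0)),
            bilayer_thickness_nm=float(prep_raw.pop("bilayer_nm", 5.0)),
            area_per_lipid_nm2=float(prep_raw.pop("area_per_lipid_nm2", 0.72)),
        )
        prep = VesiclePrep(
            lipid_conc_M=float(prep_raw.pop("lipid_conc_M", 5e-6)),
            dye_loading_conc_M=float(prep_raw.pop("dye_conc_M", 5e-6)),
            geometry=geometry,
            sample_volume_uL=float(prep_raw.pop("sample_volume_uL", 100.0)),
            **prep_raw,
        )
        sim = SimConfig(**raw.get("sim", {}))
        analysis = AnalysisConfig(**raw.get("analysis", {}))
        return cls(
            seed=int(raw.get("seed", 0)),
            prep=prep,
            sim=sim,
            analysis=analysis,
            doses=tuple(float(d) for d in raw.get("doses", ())),
            ec50_molpct=float(raw.get("ec50_molpct", 0.010)),
            hill_n=float(raw.get("hill_n", 1.0)),
            replicates=int(raw.get("replicates", 3)),
            fix_bottom=raw.get("fix_bottom", 0.0),
            weighted_fit=bool(raw.get("weighted_fit", False)),
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "prep": {
                "lipid_conc_M": self.prep.lipid_conc_M,
                "dye_conc_M": self.prep.dye_loading_conc_M,
                "diameter_nm": self.prep.geometry.diameter_nm,
                "bilayer_nm": self.prep.geometry.bilayer_thickness_nm,
                "area_per_lipid_nm2": self.prep.geometry.area_per_lipid_nm2,
                "sample_volume_uL": self.prep.sample_volume_uL,
            },
            "sim": dataclasses.asdict(self.sim),
            "analysis": dataclasses.asdict(self.analysis),
            "doses": list(self.doses),
            "ec50_molpct": self.ec50_molpct,
            "hill_n": self.hill_n,
            "replicates": self.replicates,
            "fix_bottom": self.fix_bottom,
            "weighted_fit": self.weighted_fit,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def stoichiometry_report(prep: VesiclePrep, dose_molpct: float | None = None) -> dict:
    """Derived stoichiometric quantities for a vesicle prep."""
    rep = {
        "mean_vesicle_volume_L": prep.mean_vesicle_volume_L,
        "mean_dyes_per_vesicle": prep.mean_dyes,
        "vesicle_conc_pM": prep.vesicle_conc_M * 1e12,
        "lysis_dilution_factor": lysis_dilution_factor(prep),
    }
    if dose_molpct is not None:
        rep["dose_molpct"] = dose_molpct
        rep["dose_pM"] = prep.dose_molar(dose_molpct) * 1e12
        rep["agent_molecules_per_vesicle"] = prep.agent_molecules_per_vesicle(
            dose_molpct
        )
        rep["amount_in_sample_fmol"] = (
            prep.dose_molar(dose_molpct) * prep.sample_volume_uL * 1e-6 * 1e15
        )
    return rep


def _count(trace: PhotonTrace, analysis: AnalysisConfig) -> int:
    return count_events(trace, analysis).n_events


def run_pipeline(config: RunConfig) -> dict:
    """Simulate the scenario ladder, count, normalize, and fit.

    Per replicate, simulates the blank, Ca2+-only (f_min anchor), each
    dose, and the fully permeabilized reference (f_max anchor), each from
    an independent child seed of ``config.seed``.  Returns a
    JSON-serializable report echoing the full configuration, per-sample
    event counts, normalized responses, the Hill fit (when >= 3 positive
    doses are present) and the 3-sigma detection limit.
    """
    analysis = config.analysis
    sample_names = ["blank", "calcium_only", "permeabilized"] + [
        f"dose:{d:g}" for d in config.doses
    ]
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.replicates * len(sample_names))
    seed_iter = iter(children)

    logger.info(
        "pipeline: seed=%d replicates=%d threshold=%g window=%gs doses=%s",
        config.seed,
        config.replicates,
        analysis.threshold,
        analysis.window_s,
        list(config.doses),
    )

    samples: list[dict] = []
    per_dose: dict[float, list[float]] = {d: [] for d in config.doses}
    for rep in range(config.replicates):
        counts: dict[str, int] = {}
        for name in sample_names:
            rng = np.random.default_rng(next(seed_iter))
            if name.startswith("dose:"):
                dose = float(name.split(":", 1)[1])
                cfg = dose_config(
                    config.sim, dose, config.ec50_molpct, config.hill_n
                )
            else:
                cfg = make_scenario(name, config.sim, prep=config.prep)
            trace, _ = simulate_trace(cfg, rng=rng)
            counts[name] = _count(trace, analysis)
            logger.debug("rep %d sample %s: %d events", rep, name, counts[name])

        f_min = counts["calcium_only"]
        f_max = counts["permeabilized"]
        for name in sample_names:
            entry = {
                "replicate": rep,
                "sample": name,
                "n_events": counts[name],
            }
            if f_max != f_min:
                entry["f_normalized"] = normalized_response(
                    counts[name], f_min, f_max
                ).value
                if name.startswith("dose:"):
                    per_dose[float(name.split(":", 1)[1])].append(
                        entry["f_normalized"]
                    )
            samples.append(entry)

    report: dict[str, Any] = {
        "config": config.to_dict(),
        "stoichiometry": stoichiometry_report(config.prep),
        "samples": samples,
    }

    positive = [d for d in config.doses if d > 0]
    if per_dose:
        points = summarize_doses([(d, r) for d, r in per_dose.items() if r])
        # replicate spread of the no-Ca2+ blank's normalized response
        # (the Ca2+-only anchor is identically 0 within each replicate)
        blank_norm = [
            s["f_normalized"]
            for s in samples
            if s["sample"] == "blank" and "f_normalized" in s
        ]
        blank_sd = float(np.std(blank_norm, ddof=1)) if len(blank_norm) > 1 else 0.0
        report["dose_summary"] = [dataclasses.asdict(p) for p in points]
        report["detection_limit_molpct"] = detection_limit(points, blank_sd)
        if len(set(positive)) >= 3:
            fit = fit_hill(
                points, fix_bottom=config.fix_bottom, weighted=config.weighted_fit
            )
            report["fit"] = dataclasses.asdict(fit)
    return report
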