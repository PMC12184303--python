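"""Vesicle stoichiometry for dye-loaded LUV permeabilization assays.

Deterministic arithmetic linking vesicle geometry, lipid/dye/agent
concentrations, and per-vesicle molecule counts.  These numbers frame the
sensitivity of the single-vesicle assay: how many indicator dyes a vesicle
encapsulates, how many vesicles a given lipid concentration corresponds to,
and how many permeabilizing molecules per vesicle a dose in mol% (relative
to lipid) implies.

All quantities use SI internally (metres are avoided entirely: lengths are
nanometres, volumes litres, amounts moles, concentrations molar).  The
conversion constants live here and nowhere else, so unit handling cannot
diverge between modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

AVOGADRO = 6.02214076e23  # mol^-1 (exact, 2019 SI)
NM3_TO_L = 1e-24  # 1 nm^3 = 1e-24 L

__all__ = [
    "AVOGADRO",
    "VesicleGeometry",
    "VesiclePrep",
    "Dose",
    "sphere_volume",
    "mean_dyes_per_vesicle",
    "lipids_per_vesicle",
    "vesicle_concentration",
    "molpercent_to_molar",
    "molecules_per_vesicle",
    "amount_in_sample",
    "lysis_dilution_factor",
]


@dataclass(frozen=True)
class VesicleGeometry:
    """Geometry of a single unilamellar vesicle.

    Parameters
    ----------
    diameter_nm
        Outer vesicle diameter in nm.  Extrusion through 200 nm pores gives
        a nominal 200 nm; light-scattering sizing typically reports a
        slightly smaller mean (160-180 nm).
    bilayer_thickness_nm
        Membrane thickness in nm; ~5 nm for a POPC bilayer.
    area_per_lipid_nm2
        Headgroup area per lipid in nm^2; 0.72 nm^2 is the accepted POPC
        fluid-phase value.
    """

    diameter_nm: float
    bilayer_thickness_nm: float = 5.0
    area_per_lipid_nm2: float = 0.72

    def __post_init__(self) -> None:
        if not self.diameter_nm > 2 * self.bilayer_thickness_nm > 0:
            raise ValueError(
                "require diameter > 2 * bilayer_thickness > 0, got "
                f"diameter={self.diameter_nm} nm, "
                f"thickness={self.bilayer_thickness_nm} nm"
            )
        if not self.area_per_lipid_nm2 > 0:
            raise ValueError("area_per_lipid must be positive")


def sphere_volume(diameter_nm: float) -> float:
    """Volume of a sphere of the given diameter, in litres.

    A 168 nm vesicle holds ~2.5e-18 L (2.5 attolitres).
    """
    if not diameter_nm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_nm}")
    return (math.pi / 6.0) * diameter_nm**3 * NM3_TO_L


def mean_dyes_per_vesicle(dye_conc_M: float, volume_L: float) -> float:
    """Expected number of dye molecules encapsulated per vesicle.

    Vesicles assembled in a dye solution trap, on average,
    ``dye_conc * volume * N_A`` molecules; at 5 uM dye and 2.5 aL this is
    ~7.5 molecules.  The realized occupancy per vesicle is Poisson with
    this mean (the simulator draws it accordingly).
    """
    if dye_conc_M < 0 or volume_L < 0:
        raise ValueError("concentration and volume must be non-negative")
    return dye_conc_M * volume_L * AVOGADRO


def lipids_per_vesicle(geometry: VesicleGeometry) -> float:
    """Number of lipids forming one vesicle.

    Sum of outer and inner leaflet areas divided by the area per lipid,
    with the inner leaflet radius reduced by the bilayer thickness.
    """
    r_out = geometry.diameter_nm / 2.0
    r_in = r_out - geometry.bilayer_thickness_nm
    total_area = 4.0 * math.pi * (r_out**2 + r_in**2)
    return total_area / geometry.area_per_lipid_nm2


def vesicle_concentration(lipid_conc_M: float, lipids_per_ves: float) -> float:
    """Molar concentration of vesicles implied by a lipid concentration.

    5 uM lipid at ~3.3e5 lipids per 200 nm vesicle gives ~15-16 pM of
    vesicles.
    """
    if lipids_per_ves < 1:
        raise ValueError("lipids_per_vesicle must be >= 1")
    if lipid_conc_M < 0:
        raise ValueError("lipid concentration must be non-negative")
    return lipid_conc_M / lipids_per_ves


def molpercent_to_molar(mol_percent: float, lipid_conc_M: float) -> float:
    """Convert a dose in mol% (relative to lipid) to molarity."""
    if mol_percent < 0 or lipid_conc_M < 0:
        raise ValueError("dose and lipid concentration must be non-negative")
    return (mol_percent / 100.0) * lipid_conc_M


def molecules_per_vesicle(agent_conc_M: float, vesicle_conc_M: float) -> float:
    """Average number of agent molecules available per vesicle."""
    if not vesicle_conc_M > 0:
        raise ValueError("vesicle concentration must be positive")
    if agent_conc_M < 0:
        raise ValueError("agent concentration must be non-negative")
    return agent_conc_M / vesicle_conc_M


def amount_in_sample(conc_M: float, volume_L: float) -> float:
    """Amount of substance (mol) in a sample of given volume."""
    if conc_M < 0 or volume_L < 0:
        raise ValueError("concentration and volume must be non-negative")
    return conc_M * volume_L


@dataclass(frozen=True)
class VesiclePrep:
    """A batch of dye-loaded LUVs.

    ``vesicle_conc_M`` and ``mean_dyes`` are derived from the other fields
    unless supplied explicitly (e.g. when an independently measured vesicle
    concentration is available).

    The default geometry follows the two-diameter convention: the nominal
    200 nm extrusion pore size for the lipid count (hence vesicle
    concentration), and the measured mean diameter (170 nm; sizing reports
    160-180 nm) for the encapsulated volume.  With 5 uM lipid and 5 uM dye
    these defaults give ~15 pM vesicles each holding ~7.5 dyes.
    """

    lipid_conc_M: float = 5e-6
    dye_loading_conc_M: float = 5e-6
    geometry: VesicleGeometry = field(
        default_factory=lambda: VesicleGeometry(diameter_nm=200.0)
    )
    volume_diameter_nm: float = 170.0
    mean_vesicle_volume_L: float | None = None
    vesicle_conc_M: float | None = None
    sample_volume_uL: float = 100.0

    def __post_init__(self) -> None:
        if self.lipid_conc_M < 0 or self.dye_loading_conc_M < 0:
            raise ValueError("concentrations must be non-negative")
        if self.mean_vesicle_volume_L is None:
            object.__setattr__(
                self,
                "mean_vesicle_volume_L",
                sphere_volume(self.volume_diameter_nm),
            )
        if not self.mean_vesicle_volume_L > 0:
            raise ValueError("mean vesicle volume must be positive")
        if self.vesicle_conc_M is None:
            object.__setattr__(
                self,
                "vesicle_conc_M",
                vesicle_concentration(
                    self.lipid_conc_M, lipids_per_vesicle(self.geometry)
                ),
            )
        if self.vesicle_conc_M < 0:
            raise ValueError("vesicle concentration must be non-negative")

    @property
    def mean_dyes(self) -> float:
        """Expected encapsulated dye molecules per vesicle."""
        return mean_dyes_per_vesicle(
            self.dye_loading_conc_M, self.mean_vesicle_volume_L
        )

    def dose_molar(self, mol_percent: float) -> float:
        return molpercent_to_molar(mol_percent, self.lipid_conc_M)

    def agent_molecules_per_vesicle(self, mol_percent: float) -> float:
        return molecules_per_vesicle(
            self.dose_molar(mol_percent), self.vesicle_conc_M
        )


@dataclass(frozen=True)
class Dose:
    """An agent dose expressed relative to the lipid concentration."""

    mol_percent: float
    lipid_conc_M: float

    def __post_init__(self) -> None:
        if self.mol_percent < 0 or self.lipid_conc_M < 0:
            raise ValueError("dose and lipid concentration must be non-negative")

    @property
    def molar(self) -> float:
        return molpercent_to_molar(self.mol_percent, self.lipid_conc_M)


def lysis_dilution_factor(prep: VesiclePrep) -> float:
    """Fold-dilution of encapsulated dye on complete vesicle lysis.

    On detergent lysis the dye loading concentration (inside the vesicles)
    is released into the bulk, where the total dye concentration is
    ``vesicle_conc * mean_dyes``.  The ratio is the dilution factor; for
    the default prep (5 uM dye inside, ~15 pM vesicles x ~7.5 dyes) it is
    of order 4e4, which renders the released dye invisible above any
    burst threshold.
    """
    denom = prep.vesicle_conc_M * prep.mean_dyes
    if not denom > 0:
        raise ValueError(
            "lysis dilution undefined for zero vesicle concentration or "
            "zero dye occupancy"
        )
    if not prep.dye_loading_conc_M > 0:
        raise ValueError("dye loading concentration must be positive")
    return prep.dye_loading_conc_M / denom
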