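"""Physical constants and per-map discretization settings.

The qBOLD / vessel-architecture formulas share a small set of physical
constants (gyromagnetic ratio, susceptibility difference of deoxy- vs
oxyhemoglobin, microvascular hematocrit, ...).  Defaults are the values
conventionally used at 3 T; all are overridable through
:class:`PhysioConstants`.

Each quantitative biomarker map carries a physiological value range and a
fixed bin width used for gray-level discretization before texture analysis;
:data:`MAP_SPECS` holds the canonical table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: The five tumor entity classes, in canonical order.
ENTITY_LABELS = ("GBM", "AG", "MNG", "PCNSL", "META")


@dataclass(frozen=True)
class PhysioConstants:
    """Physical constants entering the vessel-architecture and qBOLD models.

    Attributes
    ----------
    gamma : float
        Nuclear gyromagnetic ratio of the proton, rad/s/T.
    delta_chi : float
        Susceptibility difference between fully deoxygenated and fully
        oxygenated hemoglobin (SI, dimensionless).
    hct : float
        Microvascular hematocrit fraction; systemic 0.42 scaled by 0.85
        for small vessels.
    b0 : float
        Static field strength, Tesla.
    ca : float
        Arterial blood oxygen content (printed unit "mmol/mL"; the label
        is configurable, the number is used as-is).
    p50 : float
        Hemoglobin half-saturation oxygen tension, mmHg.
    hill : float
        Hill coefficient of oxygen binding to hemoglobin.
    oxy_conductivity : float
        Tissue oxygen conductivity L, mmol/Hg per minute.
    beta : float
        Numerical constant of the vessel-architecture closed forms.
    mean_vessel_radius : float
        Mean vessel lumen radius, µm.
    """

    gamma: float = 2.67502e8
    delta_chi: float = 0.264e-6
    hct: float = 0.42 * 0.85
    b0: float = 3.0
    ca: float = 8.68
    ca_unit: str = "mmol/mL"
    p50: float = 27.0
    hill: float = 2.7
    oxy_conductivity: float = 4.4
    beta: float = 1.6781
    mean_vessel_radius: float = 3.0

    @property
    def susceptibility_factor(self) -> float:
        """(4/3)·π·γ·Δχ·Hct·B0 — the qBOLD denominator per unit CBV, s⁻¹."""
        return (4.0 / 3.0) * math.pi * self.gamma * self.delta_chi * self.hct * self.b0


@dataclass(frozen=True)
class MapSpec:
    """Value range, unit and discretization bin width for one biomarker map."""

    name: str
    vmin: float
    vmax: float
    unit: str
    bin_width: float

    @property
    def n_bins(self) -> int:
        return math.ceil((self.vmax - self.vmin) / self.bin_width)


#: Physiological ranges, units and discretization bin widths per map.
#: Bin counts follow from ceil(range / width): ADC 60, CBV 67, µCBV 60,
#: MVD 67, VSI 63, MTI 67, OEF 67, CMRO2 67, PO2 67.
MAP_SPECS: dict[str, MapSpec] = {
    "ADC": MapSpec("ADC", 0.0, 3.0, "mm^2/s", 0.05),
    "CBV": MapSpec("CBV", 0.0, 100.0, "%", 1.5),
    "uCBV": MapSpec("uCBV", 0.0, 30.0, "%", 0.5),
    "MVD": MapSpec("MVD", 0.0, 2000.0, "mm^-2", 30.0),
    "VSI": MapSpec("VSI", 0.0, 500.0, "um", 8.0),
    "MTI": MapSpec("MTI", -1000.0, 1000.0, "s^-2/5", 30.0),
    "OEF": MapSpec("OEF", 0.0, 100.0, "%", 1.5),
    "CMRO2": MapSpec("CMRO2", 0.0, 1000.0, "umol/100g*min", 15.0),
    "PO2": MapSpec("PO2", 0.0, 200.0, "mmHg", 3.0),
}

#: Bin width used for z-normalized anatomical images (CE-T1w, FLAIR),
#: expected range [-3, 3] -> about 60 bins.
ANATOMICAL_BIN_WIDTH = 0.1
ANATOMICAL_RANGE = (-3.0, 3.0)

#: Image lists per data-set combination.  "advMRI" includes the anatomical
#: images plus ADC and CBV; combination sets are additive.
PHY_MAPS = ("uCBV", "MVD", "VSI", "MTI", "OEF", "CMRO2", "PO2")
DATASET_IMAGES: dict[str, tuple[str, ...]] = {
    "cMRI": ("CET1w", "FLAIR"),
    "advMRI": ("CET1w", "FLAIR", "ADC", "CBV"),
    "phyMRI": PHY_MAPS,
    "cMRI+phyMRI": ("CET1w", "FLAIR") + PHY_MAPS,
    "advMRI+phyMRI": ("CET1w", "FLAIR", "ADC", "CBV") + PHY_MAPS,
}

VOI_CHOICES = ("tumor", "edema", "both")
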