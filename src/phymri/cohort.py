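"""Synthetic multi-modal MRI cohort generator.

Emulates a five-class contrast-enhancing brain-tumor study: for each case an
ellipsoidal tumor core with a surrounding edema shell is placed in a uniform
"brain" background, class-specific physiological ground-truth maps are drawn
from per-entity distributions, and the raw acquisitions are produced by the
forward signal models that the mapping stage inverts:

* gradient-echo and spin-echo dynamic susceptibility series driven by a
  gamma-variate arterial input function convolved with an exponential
  residue function (so time-integrals are proportional to blood volume and
  the deconvolution recovers flow);
* a configurable GE-vs-SE bolus time lag that opens a hysteresis loop in the
  ΔR2,GE vs (ΔR2,SE)^(3/2) plane with a per-case rotational direction;
* mono-exponential multi-echo decays for transverse relaxation mapping;
* a two-point diffusion-weighted pair;
* anatomical CE-T1w / FLAIR volumes with class-specific intensity texture.

All stochastic draws are controlled by explicit integer seeds; the same seed
reproduces the identical case bit-for-bit.  Geometry is deliberately
simple (ellipsoids, homogeneous background): the goal is testability of the
downstream mapping, radiomics and classification stages, not anatomical
realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .constants import ENTITY_LABELS, MAP_SPECS, PhysioConstants

__all__ = [
    "AcquisitionConfig",
    "EntityProfile",
    "SyntheticCase",
    "default_profiles",
    "generate_phantom",
    "simulate_dsc_series",
    "simulate_multi_echo",
    "simulate_dwi",
    "simulate_case",
    "perturb_mask",
    "generate_cohort",
    "gamma_variate",
]

#: mL/100 g/min per (blood-volume fraction / s); unit tissue density assumed.
CBF_SCALE = 6000.0


def gamma_variate(t, K, alpha, beta, t0):
    """First-pass bolus model K·(t−t0)^α·exp(−(t−t0)/β), zero before t0."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    with np.errstate(invalid="ignore"):
        out = K * dt**alpha * np.exp(-dt / beta)
    return np.where(t > t0, out, 0.0)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry, timing and noise settings for the simulator."""

    shape: tuple = (48, 48, 20)
    spacing: tuple = (1.0, 1.0, 3.0)  # mm
    n_dynamics: int = 60
    tr: float = 1.5  # s, dynamic repetition interval
    te_ge: float = 0.030  # s
    te_se: float = 0.080  # s
    echo_times_ge: tuple = (0.005, 0.010, 0.015, 0.020, 0.025, 0.030, 0.035, 0.040)
    echo_times_se: tuple = (0.015, 0.030, 0.045, 0.060, 0.075, 0.090, 0.105, 0.120)
    b_values: tuple = (0.0, 1000.0)  # s/mm^2
    b0_field: float = 3.0  # Tesla
    noise_sigma: float = 0.5  # Rician sigma, signal units (baseline 100)
    baseline_signal: float = 100.0
    # arterial input function: gamma-variate defaults
    aif_alpha: float = 3.0
    aif_beta: float = 1.5  # s
    bolus_arrival_dynamics: int = 10  # t0, in dynamics
    aif_peak: float = 300.0  # s^-1, peak ΔR2 of the AIF
    #: GE-vs-SE bolus lag in dynamics; its sign is set per case and controls
    #: the hysteresis-loop rotation.
    vhl_lag_dynamics: int = 1
    baseline_window: int = 8  # dynamics used for S0 estimation
    #: per-axis lesion radius jitter (0 → exact spheres)
    lesion_anisotropy: float = 0.15

    def __post_init__(self):
        if self.n_dynamics < 20:
            raise ValueError("n_dynamics must be >= 20")
        for train in (self.echo_times_ge, self.echo_times_se):
            if len(train) < 2:
                raise ValueError("multi-echo trains need >= 2 echoes")
            if np.any(np.diff(train) <= 0):
                raise ValueError("echo times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_dynamics) * self.tr

    @property
    def bolus_t0(self) -> float:
        return self.bolus_arrival_dynamics * self.tr


@dataclass(frozen=True)
class EntityProfile:
    """Per-entity physiology: (mean, sd) pairs in the units of the map table.

    The literature reports no single quantitative per-entity physiology
    table; these distributions are package choices placed inside the
    physiological value ranges (see docs/methods.md).
    """

    label: str
    cbv: tuple  # %
    ucbv: tuple  # %
    cbf: tuple  # mL/100 g/min
    adc: tuple  # 1e-3 mm^2/s (map values 0..3)
    oef: tuple  # %
    r2: tuple  # s^-1 baseline spin-spin rate
    mvd: tuple  # mm^-2 (stored ground truth)
    vsi: tuple  # um (stored ground truth)
    clockwise_prob: float  # P(hysteresis loop clockwise) -> MTI > 0
    cet1w: tuple  # arbitrary units, tumor core
    flair_tumor: tuple
    flair_edema: tuple
    adc_edema: tuple  # elevated diffusivity in vasogenic edema
    tumor_radius_mm: tuple
    edema_thickness_mm: tuple

    def __post_init__(self):
        if self.label not in ENTITY_LABELS:
            raise ValueError(f"unknown entity label {self.label!r}")
        ranged = {
            "cbv": "CBV", "ucbv": "uCBV", "adc": "ADC",
            "oef": "OEF", "mvd": "MVD", "vsi": "VSI",
        }
        for attr, spec_name in ranged.items():
            mean, sd = getattr(self, attr)
            if sd <= 0:
                raise ValueError(f"{attr}: dispersion must be > 0")
            spec = MAP_SPECS[spec_name]
            if not (spec.vmin <= mean <= spec.vmax):
                raise ValueError(f"{attr} mean {mean} outside [{spec.vmin}, {spec.vmax}]")
        if not 0.0 <= self.clockwise_prob <= 1.0:
            raise ValueError("clockwise_prob must be in [0, 1]")


# Background ("normal brain") physiology, same units as the profiles.
_BACKGROUND = {
    "CBV": 4.0, "uCBV": 2.0, "CBF": 45.0, "ADC": 0.80, "OEF": 33.0,
    "R2": 13.0, "CET1w": 50.0, "FLAIR": 50.0,
}


def default_profiles(separation: float = 1.0) -> dict[str, EntityProfile]:
    """Five entity profiles with distinct physiology.

    ``separation`` scales the between-class contrast of the means relative
    to the background (1.0 = default, well separated; smaller values move
    every class toward background physiology).
    """

    def m(background, mean):
        return background + separation * (mean - background)

    def p(label, cbv, ucbv, cbf, adc, oef, r2, mvd, vsi, cw, t1, flt, fle,
          adce, rad, shell):
        return EntityProfile(
            label=label,
            cbv=(m(_BACKGROUND["CBV"], cbv), 0.12 * cbv),
            ucbv=(m(_BACKGROUND["uCBV"], ucbv), 0.12 * ucbv),
            cbf=(m(_BACKGROUND["CBF"], cbf), 0.10 * cbf),
            adc=(m(_BACKGROUND["ADC"], adc), 0.08 * adc),
            oef=(m(_BACKGROUND["OEF"], oef), 0.08 * oef),
            r2=(m(_BACKGROUND["R2"], r2), 0.8),
            mvd=(mvd, 0.15 * mvd),
            vsi=(vsi, 0.15 * vsi),
            clockwise_prob=cw,
            cet1w=(m(_BACKGROUND["CET1w"], t1), 6.0),
            flair_tumor=(m(_BACKGROUND["FLAIR"], flt), 6.0),
            flair_edema=(m(_BACKGROUND["FLAIR"], fle), 6.0),
            adc_edema=(m(_BACKGROUND["ADC"], adce), 0.10),
            tumor_radius_mm=(rad, 0.08 * rad),
            edema_thickness_mm=(shell, 0.6),
        )

    return {
        #       label    cbv ucbv cbf  adc   oef  r2  mvd  vsi  cw   t1  flt  fle adce  rad shell
        "GBM": p("GBM", 12.0, 6.0, 55, 1.00, 35.0, 18, 350, 30, 0.9, 90, 75, 100, 1.5, 10.0, 6.0),
        "AG": p("AG", 7.0, 3.5, 45, 1.20, 32.0, 16, 220, 20, 0.7, 72, 85, 95, 1.4, 9.0, 5.0),
        "MNG": p("MNG", 18.0, 8.0, 70, 0.90, 25.0, 14, 500, 45, 0.5, 110, 70, 85, 1.3, 9.0, 3.0),
        "PCNSL": p("PCNSL", 5.0, 2.5, 35, 0.65, 33.0, 17, 160, 15, 0.3, 95, 90, 95, 1.2, 8.0, 4.5),
        "META": p("META", 10.0, 5.0, 50, 1.35, 28.0, 15, 300, 35, 0.6, 100, 65, 105, 1.7, 8.5, 6.0),
    }


@dataclass
class SyntheticCase:
    """One simulated patient: raw series, masks, ground truth, label."""

    entity_label: str
    spacing: tuple
    tumor_mask: np.ndarray
    edema_mask: np.ndarray
    truth: dict  # name -> 3D array (map units) or scalar
    series: dict = field(default_factory=dict)  # name -> ndarray
    aif_ge: np.ndarray | None = None
    aif_se: np.ndarray | None = None
    seed: int = 0

    @property
    def brain_mask(self) -> np.ndarray:
        return self.truth["brain_mask"]


def _smooth_field(rng, shape, mean, sd, sigma_vox=1.5):
    """Spatially coherent Gaussian random field with the requested moments."""
    noise = rng.standard_normal(shape)
    noise = ndimage.gaussian_filter(noise, sigma_vox)
    s = noise.std()
    if s > 0:
        noise /= s
    return mean + sd * noise


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm):
    grids = np.meshgrid(
        *[np.arange(n) * sp for n, sp in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center_mm, radii_mm))
    return d2 <= 1.0


def generate_phantom(profile: EntityProfile, config: AcquisitionConfig,
                     seed: int) -> SyntheticCase:
    """Place an ellipsoidal tumor + edema shell and draw ground-truth maps.

    Raw series are not simulated here; see :func:`simulate_case`.
    Raises ``ValueError`` if the lesion does not fit in the field of view.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = config.shape, config.spacing
    extent = np.array(shape) * np.array(spacing)

    radius = max(2.0, rng.normal(*profile.tumor_radius_mm))
    shell = max(0.0, rng.normal(*profile.edema_thickness_mm))
    if 2 * (radius + shell) >= extent.min():
        raise ValueError(
            f"lesion diameter {2 * (radius + shell):.1f} mm exceeds field of view "
            f"{extent.min():.1f} mm"
        )
    # mild per-axis anisotropy and center jitter
    a = config.lesion_anisotropy
    axis_ratio = rng.uniform(1.0 - a, 1.0 + a, size=3)
    radii = radius * axis_ratio
    max_jitter = (extent / 2.0) - (radii + shell) - np.array(spacing)
    max_jitter = np.clip(max_jitter, 0.0, extent * 0.1)
    center = extent / 2.0 + rng.uniform(-1, 1, size=3) * max_jitter

    tumor = _ellipsoid_mask(shape, spacing, center, radii)
    outer = _ellipsoid_mask(shape, spacing, center, radii + shell)
    edema = outer & ~tumor  # edema excludes the enhancing core
    if not tumor.any():
        raise ValueError("tumor mask is empty")
    brain = np.ones(shape, dtype=bool)

    def draw(mean_sd, background, spec_name=None):
        mean, sd = mean_sd
        fld = np.full(shape, float(background))
        tumor_field = _smooth_field(rng, shape, mean, sd)
        fld[tumor] = tumor_field[tumor]
        if spec_name is not None:
            spec = MAP_SPECS[spec_name]
            fld = np.clip(fld, spec.vmin, spec.vmax)
        return fld

    truth = {
        "CBV": draw(profile.cbv, _BACKGROUND["CBV"], "CBV"),
        "uCBV": draw(profile.ucbv, _BACKGROUND["uCBV"], "uCBV"),
        "CBF": draw(profile.cbf, _BACKGROUND["CBF"]),
        "ADC": draw(profile.adc, _BACKGROUND["ADC"], "ADC"),
        "OEF": draw(profile.oef, _BACKGROUND["OEF"], "OEF"),
        "R2": draw(profile.r2, _BACKGROUND["R2"]),
        "MVD": draw(profile.mvd, 120.0, "MVD"),
        "VSI": draw(profile.vsi, 10.0, "VSI"),
        "CET1w": draw(profile.cet1w, _BACKGROUND["CET1w"]),
        "brain_mask": brain,
    }
    # FLAIR: tumor and edema have separate intensity distributions
    flair = np.full(shape, _BACKGROUND["FLAIR"])
    ft = _smooth_field(rng, shape, *profile.flair_tumor)
    fe = _smooth_field(rng, shape, *profile.flair_edema)
    flair[tumor] = ft[tumor]
    flair[edema] = fe[edema]
    truth["FLAIR"] = flair
    # edema elevates diffusivity
    adc_e = _smooth_field(rng, shape, *profile.adc_edema)
    truth["ADC"][edema] = np.clip(adc_e[edema], MAP_SPECS["ADC"].vmin,
                                  MAP_SPECS["ADC"].vmax)
    # hysteresis-loop rotation: one sign per case
    clockwise = bool(rng.random() < profile.clockwise_prob)
    truth["mti_clockwise"] = clockwise
    # R2* from the qBOLD relation, microvascular blood volume as the
    # susceptibility-carrying compartment
    const = PhysioConstants(b0=config.b0_field)
    truth["R2star"] = truth["R2"] + (
        (truth["OEF"] / 100.0) * const.susceptibility_factor * (truth["uCBV"] / 100.0)
    )

    return SyntheticCase(
        entity_label=profile.label,
        spacing=spacing,
        tumor_mask=tumor,
        edema_mask=edema,
        truth=truth,
        seed=seed,
    )


def _rician(rng, signal, sigma):
    if sigma <= 0:
        return signal
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(re**2 + im**2)


def _aif_curve(config: AcquisitionConfig, lag_dynamics: int = 0) -> np.ndarray:
    t = config.times
    t0 = (config.bolus_arrival_dynamics + lag_dynamics) * config.tr
    raw = gamma_variate(t, 1.0, config.aif_alpha, config.aif_beta, t0)
    peak = raw.max()
    return raw * (config.aif_peak / peak) if peak > 0 else raw


def simulate_dsc_series(case: SyntheticCase, config: AcquisitionConfig,
                        echo_type: str, rng=None) -> np.ndarray:
    """Forward-model one dynamic susceptibility series, (x, y, z, t).

    The voxel relaxation-rate curve is CBF·(AIF ⊛ exp(−t/MTT))·dt with
    MTT = CBV/CBF, so its time-integral equals the blood-volume fraction
    times the AIF integral and deconvolution recovers the flow.  The SE
    series uses the microvascular blood volume and a bolus lag whose sign
    follows the case's hysteresis-loop rotation.
    """
    if echo_type not in ("GE", "SE"):
        raise ValueError(f"echo_type must be 'GE' or 'SE', got {echo_type!r}")
    if rng is None:
        rng = np.random.default_rng(case.seed + (1 if echo_type == "GE" else 2))
    # Empirically (see tests), delaying the SE bolus relative to GE traces the
    # ΔR2,GE vs (ΔR2,SE)^(3/2) loop clockwise.
    clockwise = case.truth["mti_clockwise"]
    if echo_type == "GE":
        cbv_frac = case.truth["CBV"] / 100.0
        te, lag = config.te_ge, 0
        aif = _aif_curve(config, 0)
        case.aif_ge = aif
    else:
        cbv_frac = case.truth["uCBV"] / 100.0
        lag = config.vhl_lag_dynamics if clockwise else -config.vhl_lag_dynamics
        te = config.te_se
        aif = _aif_curve(config, lag)
        case.aif_se = aif

    t = config.times
    cbf_frac = case.truth["CBF"] / CBF_SCALE  # fraction / s
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(cbf_frac > 0, cbv_frac / np.maximum(cbf_frac, 1e-12), 1.0)
    # discretize residue on the dynamic grid per voxel via broadcasting:
    # conv is linear in CBV so compute the normalized convolution for a grid
    # of MTT values and interpolate (keeps the forward model exact enough
    # while avoiding a per-voxel convolution loop).
    mtt_grid = np.linspace(max(0.5, mtt.min()), mtt.max() + 1e-6, 64)
    kernels = np.exp(-np.outer(1.0 / mtt_grid, t))  # (64, T)
    convs = np.array([
        np.convolve(aif, k)[: len(t)] * config.tr for k in kernels
    ])  # (64, T), response per unit CBF
    # interpolate per voxel
    idx = np.interp(mtt.ravel(), mtt_grid, np.arange(len(mtt_grid)))
    lo = np.clip(idx.astype(int), 0, len(mtt_grid) - 2)
    w = (idx - lo)[:, None]
    resp = convs[lo] * (1 - w) + convs[lo + 1] * w  # (V, T)
    delta_r2 = cbf_frac.ravel()[:, None] * resp  # (V, T)
    s0 = config.baseline_signal
    signal = s0 * np.exp(-te * delta_r2)
    signal = _rician(rng, signal, config.noise_sigma)
    return signal.reshape(case.tumor_mask.shape + (len(t),))


def simulate_multi_echo(case: SyntheticCase, config: AcquisitionConfig,
                        echo_type: str, rng=None) -> np.ndarray:
    """Mono-exponential multi-echo decay S(TE) = S0·exp(−R·TE), (x,y,z,echo)."""
    if echo_type not in ("GE", "SE"):
        raise ValueError(f"echo_type must be 'GE' or 'SE', got {echo_type!r}")
    if rng is None:
        rng = np.random.default_rng(case.seed + (3 if echo_type == "GE" else 4))
    rate = case.truth["R2star"] if echo_type == "GE" else case.truth["R2"]
    tes = np.asarray(config.echo_times_ge if echo_type == "GE"
                     else config.echo_times_se)
    signal = config.baseline_signal * np.exp(-rate[..., None] * tes)
    return _rician(rng, signal, config.noise_sigma)


def simulate_dwi(case: SyntheticCase, config: AcquisitionConfig,
                 rng=None) -> tuple[np.ndarray, np.ndarray]:
    """Two-point diffusion pair (S_b0, S_b1000); S = S0·exp(−b·ADC)."""
    if rng is None:
        rng = np.random.default_rng(case.seed + 5)
    adc_mm2s = case.truth["ADC"] * 1e-3  # map stored in 1e-3 mm^2/s
    b = config.b_values[1]
    s0 = np.full(case.tumor_mask.shape, config.baseline_signal)
    sb = s0 * np.exp(-b * adc_mm2s)
    return _rician(rng, s0, config.noise_sigma), _rician(rng, sb, config.noise_sigma)


def _anatomical(case, config, name, rng):
    vol = case.truth[name].copy()
    if config.noise_sigma > 0:
        vol = _rician(rng, vol, config.noise_sigma)
    return vol


def simulate_case(profile: EntityProfile, config: AcquisitionConfig,
                  seed: int) -> SyntheticCase:
    """Generate geometry, ground truth, and every raw series for one case."""
    case = generate_phantom(profile, config, seed)
    case.series["DSC_GE"] = simulate_dsc_series(case, config, "GE")
    case.series["DSC_SE"] = simulate_dsc_series(case, config, "SE")
    case.series["ME_GE"] = simulate_multi_echo(case, config, "GE")
    case.series["ME_SE"] = simulate_multi_echo(case, config, "SE")
    rng = np.random.default_rng(seed + 6)
    case.series["DWI_b0"], case.series["DWI_b1000"] = simulate_dwi(case, config, rng)
    case.series["CET1w"] = _anatomical(case, config, "CET1w",
                                       np.random.default_rng(seed + 7))
    case.series["FLAIR"] = _anatomical(case, config, "FLAIR",
                                       np.random.default_rng(seed + 8))
    return case


def perturb_mask(mask: np.ndarray, seed: int, magnitude_mm: float = 1.0,
                 spacing=(1.0, 1.0, 1.0), dice_floor: float = 0.80) -> np.ndarray:
    """Emulate a second reader's segmentation by jittering the boundary.

    A smooth random field is added to the signed Euclidean distance of the
    boundary and the zero level set re-thresholded; the jitter amplitude is
    reduced until the Dice overlap with the original stays above
    ``dice_floor``.  ``magnitude_mm == 0`` returns the mask unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot perturb an empty mask")
    if magnitude_mm == 0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    sampling = tuple(spacing)
    dist = ndimage.distance_transform_edt(mask, sampling=sampling) - \
        ndimage.distance_transform_edt(~mask, sampling=sampling)
    noise = ndimage.gaussian_filter(rng.standard_normal(mask.shape), 2.0)
    noise /= max(noise.std(), 1e-12)
    amplitude = float(magnitude_mm)
    for _ in range(8):
        perturbed = (dist + amplitude * noise) > 0
        inter = np.logical_and(mask, perturbed).sum()
        denom = mask.sum() + perturbed.sum()
        dice = 2.0 * inter / denom if denom else 0.0
        if perturbed.any() and dice >= dice_floor:
            return perturbed
        amplitude *= 0.6
    if not perturbed.any():
        raise ValueError("perturbation emptied the mask")
    return perturbed


def cohort_case_plan(n_per_class: dict[str, int],
                     seed: int) -> list[tuple[str, int]]:
    """Deterministic (label, case_seed) plan for a cohort."""
    for label in n_per_class:
        if label not in ENTITY_LABELS:
            raise ValueError(f"unknown entity label {label!r}")
    ss = np.random.SeedSequence(seed)
    total = sum(n_per_class.values())
    case_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(total)]
    plan = []
    i = 0
    for label in ENTITY_LABELS:
        for _ in range(n_per_class.get(label, 0)):
            plan.append((label, case_seeds[i]))
            i += 1
    return plan


def generate_cohort(profiles: dict[str, EntityProfile],
                    n_per_class: dict[str, int],
                    config: AcquisitionConfig, seed: int) -> list[SyntheticCase]:
    """Simulate a cohort with the requested per-class counts.

    Per-case seeds are derived deterministically from the master seed, so
    the cohort is a pure function of (profiles, n_per_class, config, seed).
    For large cohorts prefer iterating :func:`cohort_case_plan` and
    simulating one case at a time (raw series are memory-hungry).
    """
    for label in n_per_class:
        if label not in profiles:
            raise ValueError(f"unknown entity label {label!r}")
    return [simulate_case(profiles[label], config, case_seed)
            for label, case_seed in cohort_case_plan(n_per_class, seed)]
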