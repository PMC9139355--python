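"""Quantitative biomarker maps from raw MRI series.

Implements the full mapping chain of the physiological-MRI protocol:

* **ADC** from a two-point diffusion-weighted pair, ADC = −ln(S/S0)/b.
* **ΔR2(t)** concentration-proxy curves from dynamic susceptibility series,
  ΔR2(t) = −ln(S(t)/S̄_baseline)/TE.
* **Gamma-variate first-pass fitting** K·(t−t0)^α·e^(−(t−t0)/β) as a
  simplified leakage control: only the fitted first-pass curve enters the
  vessel-architecture statistics.
* **CBV / CBF** by AIF-normalized integration and regularized block-circulant
  SVD deconvolution; the same operation applied to the spin-echo series with
  its own AIF yields the microvascular blood volume µCBV.
* **Vascular hysteresis loop (VHL)**: the parametric curve of ΔR2,GE versus
  (ΔR2,SE)^(3/2) over the first pass.  Its signed area is the microvessel
  type indicator **MTI** (+ for clockwise traversal, − for counter-clockwise).
* **MVD / VSI** closed forms combining Qmax = max ΔR2,GE / (max ΔR2,SE)^(3/2)
  with CBV and ADC.
* **R2* / R2** by per-voxel log-linear multi-echo fits, and the qBOLD chain
  **OEF**, **CMRO2** = Ca·CBF·OEF and tissue oxygen tension **PO2**.

Degenerate voxels (non-positive signals, zero blood volume, out-of-range
values) are marked invalid in the map's validity mask rather than raising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cohort import gamma_variate
from .constants import MAP_SPECS, MapSpec, PhysioConstants

__all__ = [
    "BiomarkerMap", "DynamicSeries", "MultiEchoSeries", "VHLCurve", "GammaFit",
    "compute_adc", "compute_delta_r2_curve", "fit_gamma_variate",
    "fit_gamma_variate_loglinear", "compute_cbv_cbf", "first_pass_window",
    "build_vhl", "compute_mti", "shoelace_area", "compute_qmax",
    "mvd_closed_form", "vsi_closed_form", "compute_mvd", "compute_vsi",
    "fit_relaxation_rate", "oef_closed_form", "compute_oef", "compute_cmro2",
    "po2_closed_form", "compute_po2", "apply_physiological_threshold",
    "compute_case_maps",
]

#: Relative floor applied to non-positive dynamic signals before the log.
SIGNAL_FLOOR = 1e-6


@dataclass
class BiomarkerMap:
    """A quantitative 3D map with units, physiological range and validity."""

    values: np.ndarray
    name: str
    unit: str
    value_range: tuple
    valid: np.ndarray

    @classmethod
    def from_spec(cls, values, spec: MapSpec, valid=None):
        if valid is None:
            valid = np.isfinite(values)
        return cls(np.asarray(values, dtype=float), spec.name, spec.unit,
                   (spec.vmin, spec.vmax), np.asarray(valid, dtype=bool))


@dataclass
class DynamicSeries:
    """4D dynamic signal (x, y, z, t) with timing and echo metadata."""

    data: np.ndarray
    times: np.ndarray
    echo_time: float
    echo_type: str
    baseline: slice = field(default_factory=lambda: slice(0, 8))

    def __post_init__(self):
        if self.data.shape[-1] < 20:
            raise ValueError("dynamic series needs >= 20 time points")
        if self.echo_time <= 0:
            raise ValueError("echo time must be positive")
        if self.echo_type not in ("GE", "SE"):
            raise ValueError(f"echo_type must be GE or SE, got {self.echo_type!r}")


@dataclass
class MultiEchoSeries:
    """Echo-indexed volumes (x, y, z, echo) with strictly increasing TEs."""

    data: np.ndarray
    echo_times: np.ndarray
    echo_type: str

    def __post_init__(self):
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if len(self.echo_times) < 2:
            raise ValueError("need >= 2 echoes")
        if np.any(np.diff(self.echo_times) <= 0):
            raise ValueError("echo times must be strictly increasing")


@dataclass
class VHLCurve:
    """Ordered vascular-hysteresis-loop points: x=(ΔR2,SE)^(3/2), y=ΔR2,GE."""

    x: np.ndarray
    y: np.ndarray
    time_indices: np.ndarray

    def __post_init__(self):
        if len(self.x) < 3:
            raise ValueError("a loop needs at least 3 points")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("non-finite loop coordinates")


def compute_adc(s0_volume, sb_volume, b: float) -> BiomarkerMap:
    """ADC = −ln(S_b/S_0)/b, reported in 1e-3 mm²/s for b in s/mm².

    Non-positive signals mark the voxel invalid instead of raising.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    s0 = np.asarray(s0_volume, dtype=float)
    sb = np.asarray(sb_volume, dtype=float)
    valid = (s0 > 0) & (sb > 0)
    adc = np.zeros_like(s0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc[valid] = -np.log(sb[valid] / s0[valid]) / b
    return BiomarkerMap.from_spec(adc * 1e3, MAP_SPECS["ADC"], valid)


def compute_delta_r2_curve(series: DynamicSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel ΔR2(t) = −ln(S(t)/S̄_baseline)/TE.

    Returns ``(delta_r2, valid)``; signals at or below zero are clipped to
    ``SIGNAL_FLOOR`` times the baseline, voxels with non-positive baseline
    are invalid.
    """
    s = np.asarray(series.data, dtype=float)
    baseline = s[..., series.baseline].mean(axis=-1)
    valid = baseline > 0
    floor = SIGNAL_FLOOR * np.where(valid, baseline, 1.0)
    ratio = np.maximum(s, floor[..., None]) / np.where(valid, baseline, 1.0)[..., None]
    with np.errstate(divide="ignore"):
        dr2 = -np.log(ratio) / series.echo_time
    dr2[~valid] = 0.0
    return dr2, valid


@dataclass
class GammaFit:
    """Result of a first-pass gamma-variate fit."""

    K: float
    alpha: float
    beta: float
    t0: float
    fitted: np.ndarray  # same length as the input curve, zero outside window
    residual: float
    success: bool


def first_pass_window(curve: np.ndarray, times: np.ndarray,
                      baseline_n: int = 8, recovery: float = 0.6) -> slice:
    """First-pass window: bolus arrival (baseline + 3σ crossing) to the
    sample where the curve has recovered to ``recovery`` × peak after it."""
    base = curve[:baseline_n]
    thresh = base.mean() + 3.0 * max(base.std(), 1e-9)
    above = np.nonzero(curve > thresh)[0]
    if len(above) == 0:
        raise ValueError("no bolus detected above baseline noise")
    start = int(above[0])
    peak = start + int(np.argmax(curve[start:]))
    level = recovery * curve[peak]
    after = np.nonzero(curve[peak:] <= level)[0]
    end = peak + (int(after[0]) if len(after) else len(curve) - peak - 1)
    return slice(max(start - 1, 0), min(end + 1, len(curve)))


def fit_gamma_variate(curve: np.ndarray, times: np.ndarray,
                      baseline_n: int = 8) -> GammaFit:
    """Nonlinear least-squares gamma-variate fit over the first-pass window.

    Degenerate curves (no detectable peak, divergent fit) return a result
    flagged ``success=False`` rather than raising.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    try:
        win = first_pass_window(curve, times, baseline_n)
    except ValueError:
        return GammaFit(0, 0, 0, 0, np.zeros_like(curve), np.inf, False)
    t_w, c_w = times[win], curve[win]
    peak_i = int(np.argmax(c_w))
    p0 = [c_w[peak_i], 3.0, 1.5, max(t_w[0] - 1.0, 0.0)]
    # amplitude p0: K such that model peak matches; peak of (t-t0)^a e^(-dt/b)
    dt_pk = max(t_w[peak_i] - p0[3], 1e-3)
    p0[0] = c_w[peak_i] / (dt_pk**3.0 * np.exp(-dt_pk / 1.5))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                gamma_variate, t_w, c_w, p0=p0,
                bounds=([0, 0.2, 0.05, 0.0], [np.inf, 20, 60, times[-1]]),
                maxfev=5000,
            )
    except (RuntimeError, ValueError):
        return GammaFit(0, 0, 0, 0, np.zeros_like(curve), np.inf, False)
    fitted = np.zeros_like(curve)
    fitted[win] = gamma_variate(t_w, *popt)
    residual = float(np.sqrt(np.mean((fitted[win] - c_w) ** 2)))
    return GammaFit(*popt, fitted=fitted, residual=residual, success=True)


def fit_gamma_variate_loglinear(curves: np.ndarray, times: np.ndarray,
                                t0: float) -> np.ndarray:
    """Vectorized gamma-variate fit with fixed arrival time t0.

    For t > t0 the model is log-linear, ln c = ln K + α ln(t−t0) − (t−t0)/β,
    so a single least-squares solve fits every curve at once.  ``curves`` is
    (n_voxels, T); returns the fitted curves (zero at or before t0).
    Intended for whole-cohort pipelines; :func:`fit_gamma_variate` is the
    reference single-curve operation.
    """
    times = np.asarray(times, dtype=float)
    post = times > t0
    dt = times[post] - t0
    design = np.column_stack([np.ones_like(dt), np.log(dt), -dt])
    c = np.maximum(curves[:, post], 1e-9)
    w = np.sqrt(np.maximum(curves[:, post], 0.0))  # weight the bolus, not noise
    lhs = design[None, :, :] * w[:, :, None]
    rhs = np.log(c) * w
    coef = _batch_lstsq(lhs, rhs)
    log_k, alpha, inv_beta = coef.T
    fitted = np.zeros_like(curves)
    fitted[:, post] = np.exp(
        log_k[:, None] + alpha[:, None] * np.log(dt)[None, :]
        - inv_beta[:, None] * dt[None, :]
    )
    fitted[~np.isfinite(fitted)] = 0.0
    return fitted


def _batch_lstsq(lhs: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve (n, T, k) x = (n, T) in the least-squares sense via normal eqs."""
    ata = np.einsum("ntk,ntl->nkl", lhs, lhs)
    atb = np.einsum("ntk,nt->nk", lhs, rhs)
    ata += 1e-12 * np.eye(lhs.shape[2])[None]
    return np.linalg.solve(ata, atb[..., None])[..., 0]


def compute_cbv_cbf(tissue_curves: np.ndarray, aif: np.ndarray,
                    times: np.ndarray, kappa: float = 1.0,
                    svd_threshold: float = 0.1,
                    cbf_scale: float = 6000.0) -> tuple[np.ndarray, np.ndarray]:
    """Blood volume (%) and flow from ΔR2 curves and an arterial input.

    CBV = κ·∫ΔR2,tissue dt / ∫ΔR2,AIF dt × 100 %.  CBF is the maximum of the
    residue function obtained by block-circulant SVD deconvolution with
    singular values below ``svd_threshold``·σ_max discarded, scaled by
    ``cbf_scale`` (fraction/s → mL/100 g/min for unit tissue density).

    ``tissue_curves`` is (..., T); raises if the AIF integral is not positive.
    """
    aif = np.asarray(aif, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = float(times[1] - times[0])
    aif_int = np.trapezoid(aif, times)
    if aif_int <= 0:
        raise ValueError("AIF integral must be positive")
    tis = np.asarray(tissue_curves, dtype=float)
    cbv = kappa * np.trapezoid(tis, times, axis=-1) / aif_int * 100.0

    # block-circulant deconvolution (zero-padded to 2T)
    T = len(times)
    L = 2 * T
    col = np.zeros(L)
    col[:T] = aif
    A = np.empty((L, L))
    for j in range(L):
        A[:, j] = np.roll(col, j)
    A *= dt
    U, s, Vt = np.linalg.svd(A)
    s_inv = np.where(s > svd_threshold * s.max(), 1.0 / s, 0.0)
    flat = tis.reshape(-1, T)
    padded = np.zeros((flat.shape[0], L))
    padded[:, :T] = flat
    residue = ((padded @ U) * s_inv) @ Vt  # (V, L); rows k = A⁺ @ c_tis
    cbf = residue[:, :T].max(axis=1).reshape(tis.shape[:-1]) * cbf_scale
    return cbv, cbf


def auto_select_aif(dr2_curves: np.ndarray, times: np.ndarray,
                    n_select: int = 10) -> np.ndarray:
    """Heuristic arterial-input selection from a set of ΔR2 curves.

    Candidate voxels are ranked by early bolus arrival, high peak and low
    first moment (arterial curves are early, tall and narrow); the AIF is
    the mean of the ``n_select`` best-ranked curves.  ``dr2_curves`` is
    (n_voxels, T).  Synthetic cases carry the true AIF, so this heuristic
    is only needed for externally acquired data.
    """
    curves = np.asarray(dr2_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] == 0:
        raise ValueError("need a (n_voxels, T) stack of curves")
    peaks = curves.max(axis=1)
    ok = peaks > 0
    if not ok.any():
        raise ValueError("no curve with a positive peak")
    pos = np.clip(curves, 0.0, None)
    area = pos.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        first_moment = np.where(area > 0, (pos * times).sum(axis=1) / area,
                                np.inf)
    # arrival: first sample above half peak
    half = peaks[:, None] / 2.0
    arrival = np.argmax(curves >= half, axis=1).astype(float)
    arrival[~ok] = np.inf

    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        r[order] = np.arange(len(v))
        return r

    score = ranks(arrival) + ranks(-peaks) + ranks(first_moment)
    score[~ok] = np.inf
    best = np.argsort(score, kind="stable")[:min(n_select, int(ok.sum()))]
    return curves[best].mean(axis=0)


def build_vhl(dr2_ge: np.ndarray, dr2_se: np.ndarray, window: slice) -> VHLCurve:
    """Vascular hysteresis loop over the first-pass window.

    Negative ΔR2,SE samples are clamped to zero before the 3/2 power.  The
    loop is closed by joining the last point back to the first.
    """
    idx = np.arange(len(dr2_ge))[window]
    if len(idx) < 3:
        raise ValueError("first-pass window must contain >= 3 samples")
    x = np.clip(np.asarray(dr2_se, dtype=float)[window], 0.0, None) ** 1.5
    y = np.asarray(dr2_ge, dtype=float)[window]
    return VHLCurve(x=x, y=y, time_indices=idx)


def shoelace_area(x: np.ndarray, y: np.ndarray) -> float:
    """Signed polygon area; positive for counter-clockwise traversal."""
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * y2 - x2 * y))


def compute_mti(vhl: VHLCurve) -> float:
    """Microvessel type indicator: |loop area| signed by rotation.

    Clockwise traversal → positive MTI (arteriole-dominated vasculature),
    counter-clockwise → negative.  Degenerate loops return 0.
    """
    # shoelace sign is + for counter-clockwise, so MTI = −signed area
    return -shoelace_area(vhl.x, vhl.y)


def compute_qmax(dr2_ge: np.ndarray, dr2_se: np.ndarray,
                 literal_ge_denominator: bool = False) -> float:
    """Qmax = max[ΔR2,GE] / (max[ΔR2,SE])^(3/2).

    ``literal_ge_denominator`` reproduces the GE/GE variant found in some
    printed renderings of the formula.  Returns NaN for a non-positive
    denominator (degenerate voxel).
    """
    num = float(np.max(dr2_ge))
    den_base = float(np.max(dr2_ge if literal_ge_denominator else dr2_se))
    if den_base <= 0:
        return float("nan")
    return num / den_base**1.5


def mvd_closed_form(qmax, cbv, adc, rbar, beta):
    """MVD = Qmax^β · (CBV / (24·π²·ADC·R̄⁴))^(1/3), raw-unit grouping."""
    return qmax**beta * (cbv / (24.0 * np.pi**2 * adc * rbar**4)) ** (1.0 / 3.0)


def vsi_closed_form(qmax, cbv, adc, beta):
    """VSI = (CBV·ADC·β / (32·π·Qmax³))^(1/2), raw-unit grouping."""
    return np.sqrt(cbv * adc * beta / (32.0 * np.pi * qmax**3))


def compute_mvd(qmax, cbv_percent, adc_map, constants: PhysioConstants = PhysioConstants()) -> BiomarkerMap:
    """Microvessel density map, mm⁻².

    Units entering the closed form: CBV as a volume fraction, ADC in mm²/s
    (map values are 1e-3 mm²/s), mean vessel radius in mm.  Non-positive ADC
    or NaN Qmax mark voxels invalid; Qmax = 0 gives MVD = 0.
    """
    qmax = np.asarray(qmax, dtype=float)
    cbv_frac = np.asarray(cbv_percent, dtype=float) / 100.0
    adc = np.asarray(adc_map, dtype=float) * 1e-3
    rbar_mm = constants.mean_vessel_radius * 1e-3
    valid = (adc > 0) & np.isfinite(qmax) & (cbv_frac >= 0) & (qmax >= 0)
    mvd = np.zeros_like(qmax)
    with np.errstate(invalid="ignore", divide="ignore"):
        mvd[valid] = mvd_closed_form(qmax[valid], cbv_frac[valid], adc[valid],
                                     rbar_mm, constants.beta)
    return BiomarkerMap.from_spec(mvd, MAP_SPECS["MVD"], valid)


def compute_vsi(qmax, cbv_percent, adc_map, constants: PhysioConstants = PhysioConstants()) -> BiomarkerMap:
    """Vessel size index map, µm (closed form evaluated in mm, scaled)."""
    qmax = np.asarray(qmax, dtype=float)
    cbv_frac = np.asarray(cbv_percent, dtype=float) / 100.0
    adc = np.asarray(adc_map, dtype=float) * 1e-3
    valid = np.isfinite(qmax) & (qmax > 0) & (cbv_frac >= 0) & (adc >= 0)
    vsi = np.zeros_like(qmax)
    with np.errstate(invalid="ignore", divide="ignore"):
        vsi[valid] = vsi_closed_form(qmax[valid], cbv_frac[valid], adc[valid],
                                     constants.beta) * 1e3
    return BiomarkerMap.from_spec(vsi, MAP_SPECS["VSI"], valid)


def fit_relaxation_rate(series: MultiEchoSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel log-linear fit of S(TE) = S0·e^(−R·TE); returns (R, valid)."""
    s = np.asarray(series.data, dtype=float)
    valid = np.all(s > 0, axis=-1)
    tes = series.echo_times
    design = np.column_stack([np.ones_like(tes), -tes])
    pinv = np.linalg.pinv(design)  # (2, E)
    logs = np.log(np.where(s > 0, s, 1.0))
    coef = logs @ pinv.T  # (..., 2)
    rate = coef[..., 1]
    rate[~valid] = 0.0
    return rate, valid


def oef_closed_form(r2star, r2, cbv_fraction, constants: PhysioConstants) -> np.ndarray:
    """OEF = (R2* − R2) / ((4/3)·π·γ·Δχ·Hct·B0·CBV), as a fraction."""
    return (np.asarray(r2star, float) - np.asarray(r2, float)) / (
        constants.susceptibility_factor * np.asarray(cbv_fraction, float)
    )


def compute_oef(r2star, r2, cbv_fraction,
                constants: PhysioConstants = PhysioConstants()) -> BiomarkerMap:
    """Oxygen extraction fraction map, stored in % (Table range [0, 100]).

    ``cbv_fraction`` is the blood volume as a dimensionless fraction; zero
    blood volume marks the voxel invalid.
    """
    cbv = np.asarray(cbv_fraction, dtype=float)
    valid = cbv > 0
    oef = np.zeros(np.broadcast_shapes(np.shape(r2star), cbv.shape))
    with np.errstate(divide="ignore", invalid="ignore"):
        full = oef_closed_form(r2star, r2, np.where(valid, cbv, 1.0), constants)
    oef = np.where(valid, full, 0.0) * 100.0
    return BiomarkerMap.from_spec(oef, MAP_SPECS["OEF"], valid)


def compute_cmro2(r2star, r2, cbv_fraction, cbf,
                  constants: PhysioConstants = PhysioConstants()) -> BiomarkerMap:
    """CMRO2 = Ca·CBF·OEF, µmol/100 g·min for CBF in mL/100 g/min."""
    oef = compute_oef(r2star, r2, cbv_fraction, constants)
    cmro2 = constants.ca * np.asarray(cbf, dtype=float) * (oef.values / 100.0)
    return BiomarkerMap.from_spec(cmro2, MAP_SPECS["CMRO2"], oef.valid)


def po2_closed_form(oef_fraction, cmro2, constants: PhysioConstants) -> np.ndarray:
    """PO2 = P50·(2/OEF − 1)^(1/h) − CMRO2/L, mmHg."""
    oef = np.asarray(oef_fraction, dtype=float)
    return (constants.p50 * (2.0 / oef - 1.0) ** (1.0 / constants.hill)
            - np.asarray(cmro2, float) / constants.oxy_conductivity)


def compute_po2(oef_map: BiomarkerMap, cmro2_map: BiomarkerMap,
                constants: PhysioConstants = PhysioConstants()) -> BiomarkerMap:
    """Tissue oxygen tension map, mmHg; requires 0 < OEF ≤ 1."""
    oef_frac = oef_map.values / 100.0
    valid = oef_map.valid & cmro2_map.valid & (oef_frac > 0) & (oef_frac <= 1.0)
    po2 = np.zeros_like(oef_frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        full = po2_closed_form(np.where(valid, oef_frac, 1.0),
                               cmro2_map.values, constants)
    po2 = np.where(valid, full, 0.0)
    return BiomarkerMap.from_spec(po2, MAP_SPECS["PO2"], valid)


def apply_physiological_threshold(bm: BiomarkerMap) -> BiomarkerMap:
    """Mark voxels outside the map's declared physiological range invalid."""
    lo, hi = bm.value_range
    in_range = (bm.values >= lo) & (bm.values <= hi)
    return BiomarkerMap(bm.values, bm.name, bm.unit, bm.value_range,
                        bm.valid & in_range)


# ---------------------------------------------------------------------------
# case-level orchestration


def compute_case_maps(case, config, constants: PhysioConstants | None = None,
                      gamma_fit: bool = True, threshold: bool = True,
                      roi: np.ndarray | None = None) -> dict:
    """Run the full mapping chain on one simulated (or loaded) case.

    Returns a dict name → :class:`BiomarkerMap` with ADC, CBV, CBF, uCBV,
    MTI, Qmax, MVD, VSI, R2star, R2, OEF, CMRO2 and PO2.  Vectorized over
    voxels; with ``gamma_fit`` the per-voxel ΔR2 first passes are replaced
    by a log-linear gamma-variate fit before the hysteresis statistics.
    ``roi`` restricts the per-voxel dynamic-series work (perfusion,
    hysteresis, qBOLD) to a region; voxels outside are marked invalid.
    """
    if constants is None:
        constants = PhysioConstants(b0=config.b0_field)
    shape = case.tumor_mask.shape
    if roi is None:
        roi = np.ones(shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    flat_roi = roi.ravel()

    def scatter(flat_vals, fill=0.0):
        full = np.full(flat_roi.shape, fill, dtype=float)
        full[flat_roi] = flat_vals
        return full.reshape(shape)

    out: dict[str, BiomarkerMap] = {}

    out["ADC"] = compute_adc(case.series["DWI_b0"], case.series["DWI_b1000"],
                             config.b_values[1])

    times = config.times
    base = slice(0, config.baseline_window)
    ge = DynamicSeries(case.series["DSC_GE"], times, config.te_ge, "GE", base)
    se = DynamicSeries(case.series["DSC_SE"], times, config.te_se, "SE", base)
    dr2_ge, valid_ge = compute_delta_r2_curve(ge)
    dr2_se, valid_se = compute_delta_r2_curve(se)
    valid_ge &= roi
    valid_se &= roi

    flat_ge = dr2_ge.reshape(-1, len(times))[flat_roi]
    flat_se = dr2_se.reshape(-1, len(times))[flat_roi]
    if gamma_fit:
        t0 = config.bolus_t0
        flat_ge = fit_gamma_variate_loglinear(flat_ge, times, t0)
        flat_se = fit_gamma_variate_loglinear(
            flat_se, times, t0 - abs(config.vhl_lag_dynamics) * config.tr)

    aif_ge = case.aif_ge
    aif_se = case.aif_se if case.aif_se is not None else case.aif_ge
    cbv, cbf = compute_cbv_cbf(flat_ge, aif_ge, times)
    ucbv, _ = compute_cbv_cbf(flat_se, aif_se, times)
    out["CBV"] = BiomarkerMap.from_spec(scatter(cbv), MAP_SPECS["CBV"],
                                        valid_ge)
    out["CBF"] = BiomarkerMap(scatter(cbf), "CBF", "mL/100g/min",
                              (0.0, np.inf), valid_ge)
    out["uCBV"] = BiomarkerMap.from_spec(scatter(ucbv), MAP_SPECS["uCBV"],
                                         valid_se)

    # hysteresis statistics over the AIF-derived first-pass window,
    # vectorized shoelace over all ROI voxels
    aif_win = first_pass_window(aif_ge, times, config.baseline_window)
    xs = np.clip(flat_se[:, aif_win], 0.0, None) ** 1.5
    ys = flat_ge[:, aif_win]
    x2 = np.roll(xs, -1, axis=1)
    y2 = np.roll(ys, -1, axis=1)
    signed = 0.5 * np.sum(xs * y2 - x2 * ys, axis=1)
    mti = scatter(-signed)
    out["MTI"] = BiomarkerMap.from_spec(mti, MAP_SPECS["MTI"],
                                        valid_ge & valid_se)

    den = np.max(flat_se[:, aif_win], axis=1)
    num = np.max(flat_ge[:, aif_win], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        qmax = scatter(np.where(den > 0, num / den**1.5, np.nan),
                       fill=np.nan)
    out["Qmax"] = BiomarkerMap(qmax, "Qmax", "1", (0.0, np.inf),
                               np.isfinite(qmax))

    out["MVD"] = compute_mvd(qmax, out["CBV"].values, out["ADC"].values,
                             constants)
    out["VSI"] = compute_vsi(qmax, out["CBV"].values, out["ADC"].values,
                             constants)

    me_ge = MultiEchoSeries(case.series["ME_GE"], config.echo_times_ge, "GE")
    me_se = MultiEchoSeries(case.series["ME_SE"], config.echo_times_se, "SE")
    r2star, v1 = fit_relaxation_rate(me_ge)
    r2, v2 = fit_relaxation_rate(me_se)
    out["R2star"] = BiomarkerMap(r2star, "R2star", "s^-1", (0.0, np.inf), v1)
    out["R2"] = BiomarkerMap(r2, "R2", "s^-1", (0.0, np.inf), v2)

    ucbv_frac = np.clip(out["uCBV"].values, 0.0, None) / 100.0
    # negative noise-induced R2*−R2 differences are clipped at zero
    r2star_eff = np.maximum(r2star, r2)
    out["OEF"] = compute_oef(r2star_eff, r2, ucbv_frac, constants)
    out["OEF"].valid &= v1 & v2
    out["CMRO2"] = compute_cmro2(r2star_eff, r2, ucbv_frac,
                                 out["CBF"].values, constants)
    out["CMRO2"].valid &= v1 & v2 & valid_ge
    out["PO2"] = compute_po2(out["OEF"], out["CMRO2"], constants)

    if threshold:
        for name, bm in out.items():
            if name in MAP_SPECS:
                out[name] = apply_physiological_threshold(bm)
    return out
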