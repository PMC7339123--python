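"""Synthetic assay generators with known ground truth.

The studies this package analyses combine five instrument outputs:
single-channel current traces, DSC melting endotherms, calcein-leakage
fluorescence time courses, carrier-conductance adsorption series and
styryl-dye excitation-ratio series.  None of the raw instrument data
are redistributable, so every analysis stage here is exercised against
these generators, which produce each data type from explicit
ground-truth parameters with the noise and filtering structure the
analyses assume:

* gating is simulated in continuous time (exact exponential sojourns in
  a two-state Markov scheme) and then sampled, avoiding discretization
  bias; white Gaussian instrument noise is added at the digitizer rate
  *before* a causal 4-pole Bessel-type low-pass filter, as in a
  patch-clamp acquisition chain;
* melting endotherms are sums of two-state van't Hoff components plus a
  polynomial baseline;
* leakage kinetics are mono-exponential in the normalized RF scale;
* adsorption follows the Langmuir isotherm, emitted both as potential
  shifts and as the equivalent Boltzmann conductance ratios so the
  conductance-to-potential stage can be tested end to end.

Every generator is deterministic for a fixed model + seed.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy.signal import bessel, sosfilt

from .constants import thermal_voltage_mV
from .dsc import Thermogram, vant_hoff_excess_cp, vant_hoff_fwhm
from .electrostatics import AdsorptionSeries, RatioSeries
from .errors import ConfigurationError
from .leakage import LeakageSeries
from .models import AdsorptionModel, DipoleCalibration, GatingModel, LeakageModel, MeltingComponent
from .single_channel import CurrentTrace, EventList


def derive_seed(global_seed: int, *labels) -> int:
    """Stable per-stage seed derived from a global seed and labels.

    Hashes the labels (compound name, stage name, replicate index, ...)
    with CRC-32 and folds in the global seed; result is < 2**31 so it
    is safe for any RNG constructor.
    """
    h = zlib.crc32(repr(labels).encode())
    return int((global_seed * 0x9E3779B1 + h) % (2**31 - 1))


# --------------------------------------------------------------------------
# channel gating
# --------------------------------------------------------------------------

def gen_gating_sojourns(model: GatingModel, rng: np.random.Generator | None = None):
    """Exact continuous-time sojourn sequence over the trace duration.

    Returns (states, dwells): boolean open flags and exponential dwell
    durations (s), alternating, with the last sojourn truncated at
    ``model.duration``.  The initial state is drawn from the stationary
    distribution.
    """
    rng = np.random.default_rng(model.seed) if rng is None else rng
    states, dwells = [], []
    open_now = bool(rng.random() < model.open_fraction)
    t = 0.0
    while t < model.duration:
        rate = model.close_rate if open_now else model.open_rate
        dt = rng.exponential(1.0 / rate)
        dt = min(dt, model.duration - t)
        states.append(open_now)
        dwells.append(dt)
        t += dt
        open_now = not open_now
    return np.asarray(states, dtype=bool), np.asarray(dwells, dtype=float)


def sojourns_to_events(model: GatingModel, states, dwells) -> EventList:
    """Package true (pre-noise, pre-filter) sojourns as an EventList."""
    states = np.asarray(states, dtype=bool)
    dwells = np.asarray(dwells, dtype=float)
    starts = np.concatenate([[0.0], np.cumsum(dwells[:-1])])
    amps = np.where(states, model.unit_current, 0.0)
    return EventList(
        states=states,
        starts=starts,
        dwells=dwells,
        amplitudes=amps,
        baseline=model.baseline_current,
        dead_time=0.0,
        voltage=model.voltage,
    )


def gen_true_events(model: GatingModel) -> EventList:
    """Ground-truth event list (no noise, no dead time) for a gating model."""
    return sojourns_to_events(model, *gen_gating_sojourns(model))


def gen_channel_trace(model: GatingModel, return_events: bool = False):
    """Simulate a sampled, noisy, low-pass-filtered current trace.

    The two-state level sequence is sampled at ``model.sampling_rate``;
    Gaussian noise of sd ``model.noise_sd`` (pA) is added per sample and
    the sum passed through a causal 4-pole Bessel-type digital filter at
    ``model.filter_cutoff`` (None disables filtering).  With
    ``return_events`` the true sojourn EventList is returned alongside.
    """
    rng = np.random.default_rng(model.seed)
    states, dwells = gen_gating_sojourns(model, rng)
    n = int(round(model.duration * model.sampling_rate))
    t = np.arange(n) / model.sampling_rate
    ends = np.cumsum(dwells)
    idx = np.minimum(np.searchsorted(ends, t, side="right"), states.size - 1)
    level = model.baseline_current + model.unit_current * states[idx]
    current = level if model.noise_sd == 0 else level + rng.normal(0.0, model.noise_sd, n)
    if model.filter_cutoff:
        sos = bessel(4, model.filter_cutoff, btype="low", fs=model.sampling_rate, output="sos")
        current = sosfilt(sos, current)
    trace = CurrentTrace(
        current=current,
        sampling_rate=model.sampling_rate,
        voltage=model.voltage,
        filter_cutoff=model.filter_cutoff,
    )
    if return_events:
        return trace, sojourns_to_events(model, states, dwells)
    return trace


def gen_macroscopic_trace(
    mean_current: float,
    duration: float,
    sampling_rate: float = 5000.0,
    noise_sd: float = 0.0,
    voltage: float = 50.0,
    seed: int | None = None,
) -> CurrentTrace:
    """Steady-state macroscopic (many-channel) current with Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    current = np.full(n, float(mean_current))
    if noise_sd:
        current = current + rng.normal(0.0, noise_sd, n)
    return CurrentTrace(current=current, sampling_rate=sampling_rate, voltage=voltage, filter_cutoff=None)


# --------------------------------------------------------------------------
# DSC
# --------------------------------------------------------------------------

def gen_thermogram(
    components: list[MeltingComponent],
    grid,
    baseline_coeffs=(),
    noise_sd: float = 0.0,
    seed: int | None = None,
    label: str = "",
) -> Thermogram:
    """Sum of van't Hoff endotherm components + baseline + noise.

    ``grid`` is the Celsius temperature grid (strictly increasing) and
    must span each component's t_m by at least three full widths;
    components outside the grid raise a configuration error naming
    them.  ``baseline_coeffs`` are numpy polyval coefficients (highest
    power first) evaluated on the Celsius grid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or not np.all(np.diff(grid) > 0):
        raise ConfigurationError("grid: must be a strictly increasing 1-D array")
    uncovered = [
        c for c in components
        if c.t_m - 3 * vant_hoff_fwhm(c.t_m, c.vant_hoff_enthalpy) < grid[0]
        or c.t_m + 3 * vant_hoff_fwhm(c.t_m, c.vant_hoff_enthalpy) > grid[-1]
    ]
    if uncovered:
        names = ", ".join(f"t_m={c.t_m:g} C" for c in uncovered)
        raise ConfigurationError(f"grid: does not cover components: {names}")
    cp = np.zeros_like(grid)
    for c in components:
        cp += vant_hoff_excess_cp(grid, c.t_m, c.vant_hoff_enthalpy, c.calorimetric_enthalpy)
    if len(baseline_coeffs):
        cp = cp + np.polyval(baseline_coeffs, grid)
    if noise_sd:
        cp = cp + np.random.default_rng(seed).normal(0.0, noise_sd, grid.size)
    return Thermogram(grid, cp, label=label)


# --------------------------------------------------------------------------
# leakage
# --------------------------------------------------------------------------

def gen_leakage_series(model: LeakageModel) -> LeakageSeries:
    """Fluorescence time course whose noiseless RF(t) is
    rf_max * (1 - exp(-t/rise_time)).

    The RF curve is inverted through the dilution-corrected
    normalization to raw intensities; Gaussian noise (a.u.) is added to
    the intensity channel, as an instrument would.
    """
    t = np.asarray(model.times, dtype=float)
    rf = model.rf_max * (1.0 - np.exp(-t / model.rise_time))
    denom = model.i_max / model.dilution_factor - model.i0
    intensity = model.i0 + rf / 100.0 * denom
    if model.noise_sd:
        intensity = intensity + np.random.default_rng(model.seed).normal(0.0, model.noise_sd, t.size)
    return LeakageSeries(
        times=t, intensity=intensity, i0=model.i0, i_max=model.i_max, dilution_factor=model.dilution_factor
    )


# --------------------------------------------------------------------------
# adsorption & dye ratios
# --------------------------------------------------------------------------

def gen_adsorption_series(model: AdsorptionModel, with_conductance: bool = False):
    """Langmuir potential shifts, optionally with Boltzmann conductance ratios.

    Emits dphi(C) = dphi_max*C/(C+K) + noise (mV).  With
    ``with_conductance`` also returns G_m/G_m0 = exp(dphi / (kT/e))
    computed from the *noisy* shifts, so converting the ratios back
    through the Boltzmann stage reproduces the emitted shifts to
    machine precision.
    """
    c = np.asarray(model.concentrations, dtype=float)
    dphi = model.dphi_max * c / (c + model.k_desorption)
    if model.noise_sd:
        dphi = dphi + np.random.default_rng(model.seed).normal(0.0, model.noise_sd, c.size)
    series = AdsorptionSeries(concentrations=c, dphi=dphi)
    if with_conductance:
        g_ratio = np.exp(dphi / thermal_voltage_mV(model.temperature))
        return series, g_ratio
    return series


def gen_ratio_series(
    model: AdsorptionModel, calibration: DipoleCalibration, seed: int | None = None
) -> RatioSeries:
    """Styryl-dye excitation-ratio series for a Langmuir dipole shift.

    R(C) = r_ref + slope * dphi_d(C) + noise, with dphi_d following the
    Langmuir form; the ratio noise is |slope| * model.noise_sd so that
    the shift recovered through the calibration carries the model's
    stated mV-scale noise.
    """
    if calibration.slope == 0:
        raise ConfigurationError("slope: calibration slope must be nonzero")
    c = np.asarray(model.concentrations, dtype=float)
    dphi = model.dphi_max * c / (c + model.k_desorption)
    ratios = calibration.r_ref + calibration.slope * dphi
    if model.noise_sd:
        rng = np.random.default_rng(model.seed if seed is None else seed)
        ratios = ratios + rng.normal(0.0, abs(calibration.slope) * model.noise_sd, c.size)
    return RatioSeries(concentrations=c, ratios=ratios)
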