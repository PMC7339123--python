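"""Ground-truth parameter sets for the synthetic assay generators.

Each dataclass bundles the parameters of one instrument-free data
generator: two-state channel gating, van't Hoff melting endotherms,
exponential calcein-leakage kinetics, Langmuir adsorption of a
potential-modifying compound, and the ratiometric readout of a
voltage-sensitive styryl dye.  Validation happens at construction and
raises :class:`~bilayerlab.errors.ConfigurationError` naming the
offending field, so downstream generators can assume invariants hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigurationError


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {message}")


@dataclass
class GatingModel:
    """Two-state (closed <-> open) Markov gating of a single channel.

    ``open_rate`` is the rate of opening transitions from the closed
    state (1/s) so the mean closed dwell is ``1/open_rate``; likewise
    ``close_rate`` governs the open state.  ``unit_current`` is the
    single-channel current step i (pA) at the holding ``voltage`` (mV).
    Acquisition mimics a patch-clamp chain: Gaussian instrument noise is
    added at the digitizer rate and then low-pass filtered at
    ``filter_cutoff`` (Hz).
    """

    open_rate: float
    close_rate: float
    unit_current: float
    voltage: float
    duration: float
    baseline_current: float = 0.0
    noise_sd: float = 0.0
    sampling_rate: float = 5000.0
    filter_cutoff: float | None = 200.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _require(self.open_rate > 0, "open_rate", "must be > 0")
        _require(self.close_rate > 0, "close_rate", "must be > 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.sampling_rate > 0, "sampling_rate", "must be > 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        if self.filter_cutoff is not None:
            _require(
                self.sampling_rate > 2 * self.filter_cutoff,
                "sampling_rate",
                "must exceed twice filter_cutoff (Nyquist)",
            )

    @property
    def open_fraction(self) -> float:
        """Long-run probability of the open state, k_open/(k_open+k_close)."""
        return self.open_rate / (self.open_rate + self.close_rate)


@dataclass
class MeltingComponent:
    """One two-state van't Hoff melting transition.

    ``t_m`` is the peak temperature in Celsius.  ``vant_hoff_enthalpy``
    (J/mol) sets the peak sharpness; ``calorimetric_enthalpy`` (J/mol)
    is the peak area.  ``weight`` is the component's fraction of the
    total calorimetric enthalpy when used inside a mixture.
    """

    t_m: float
    vant_hoff_enthalpy: float
    calorimetric_enthalpy: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        _require(self.vant_hoff_enthalpy > 0, "vant_hoff_enthalpy", "must be > 0")
        _require(self.calorimetric_enthalpy > 0, "calorimetric_enthalpy", "must be > 0")
        _require(0 < self.weight <= 1, "weight", "must lie in (0, 1]")


@dataclass
class LeakageModel:
    """Mono-exponential calcein de-quenching kinetics.

    Noiseless truth: RF(t) = rf_max * (1 - exp(-t/rise_time)) with RF in
    percent, converted to raw fluorescence through the dilution-corrected
    normalization used for detergent-lysed samples.
    """

    rf_max: float
    rise_time: float
    i0: float = 100.0
    i_max: float = 900.0
    dilution_factor: float = 0.9
    times: Sequence[float] = field(default_factory=lambda: np.arange(0.0, 80.5, 0.5))
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _require(0 <= self.rf_max <= 100, "rf_max", "must lie in [0, 100]")
        _require(self.rise_time > 0, "rise_time", "must be > 0")
        _require(self.i0 >= 0, "i0", "must be >= 0")
        _require(self.i_max > self.i0, "i_max", "must exceed i0")
        _require(self.dilution_factor > 0, "dilution_factor", "must be > 0")
        t = np.asarray(self.times, dtype=float)
        _require(t.ndim == 1 and t.size >= 2, "times", "need a 1-D grid of >= 2 points")
        _require(bool(np.all(np.diff(t) >= 0)), "times", "must be nondecreasing")


@dataclass
class AdsorptionModel:
    """Langmuir adsorption of a modifier shifting the boundary potential.

    Noiseless truth: dphi(C) = dphi_max * C / (C + K) with ``dphi_max``
    in mV (the saturation shift, reported as a positive reduction) and
    ``k_desorption`` = K in uM.
    """

    dphi_max: float
    k_desorption: float
    concentrations: Sequence[float] = field(
        default_factory=lambda: np.array([5.0, 10.0, 20.0, 40.0, 80.0, 160.0, 320.0, 640.0, 1000.0])
    )
    temperature: float = 298.15
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _require(self.k_desorption > 0, "k_desorption", "must be > 0")
        _require(self.temperature > 0, "temperature", "must be > 0 (kelvin)")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        c = np.asarray(self.concentrations, dtype=float)
        _require(c.ndim == 1 and c.size >= 1, "concentrations", "need >= 1 value")
        _require(bool(np.all(c >= 0)), "concentrations", "must be >= 0")
        _require(bool(np.all(np.diff(c) > 0)), "concentrations", "must be strictly increasing")


@dataclass
class DipoleCalibration:
    """Linear map between the styryl-dye excitation ratio R and phi_d.

    ``r_ref`` is the control (no modifier) 420/520 nm excitation ratio;
    ``slope`` is dR per mV of dipole-potential change.  The numeric
    calibration is instrument- and protocol-specific, so it is carried
    as configuration rather than hard-coded.
    """

    r_ref: float = 1.0
    slope: float = -0.005

    def __post_init__(self) -> None:
        _require(self.slope != 0, "slope", "must be nonzero")
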