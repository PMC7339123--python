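"""Calcein-release quantification for vesicle permeabilization assays.

Calcein self-quenches at the millimolar concentrations entrapped in
vesicles; marker efflux de-quenches it, so the fluorescence time course
I(t) reports membrane permeabilization.  The relative fluorescence is
normalized to complete detergent lysis,

    RF(t) = 100 * (I(t) - I0) / (Imax / 0.9 - I0)   [%],

where I0 is the pre-addition intensity, Imax the post-Triton intensity
and the 0.9 factor corrects for sample dilution by the detergent.

The plateau RF_max is extracted either from the tail of the record
("endpoint": mean of the final 10% of points) or by fitting a
mono-exponential rise RF(t) = RF_max*(1 - exp(-t/tau)) ("exponential
fit", the default, which falls back to the endpoint when the fit does
not converge).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError


@dataclass
class LeakageSeries:
    """Fluorescence time course with its normalization anchors."""

    times: np.ndarray
    intensity: np.ndarray
    i0: float
    i_max: float
    dilution_factor: float = 0.9

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise DomainError("times and intensity must have equal length")
        if np.any(np.diff(self.times) < 0):
            raise DomainError("times must be nondecreasing")
        if self.i_max / self.dilution_factor <= self.i0:
            raise DomainError("i_max/dilution_factor must exceed i0")


@dataclass
class LeakageResult:
    rf_max: float
    rf_max_err: float
    method: str
    tau: float | None = None
    warning: str | None = None


def compute_rf(series: LeakageSeries) -> np.ndarray:
    """Relative calcein fluorescence RF(t) in percent.

    Noise can make individual values slightly negative; they are kept
    as-is here (clipping would bias plateau fits) and only the reported
    RF_max is floored at zero.
    """
    denom = series.i_max / series.dilution_factor - series.i0
    if denom <= 0:
        raise DomainError("RF denominator must be positive")
    return 100.0 * (series.intensity - series.i0) / denom


class ExponentialRelease(RegressorMixin, BaseEstimator):
    """Mono-exponential leakage-plateau estimator.

    fit(t, rf) fits RF(t) = RF_max*(1 - exp(-t/tau)); fitted attributes
    ``rf_max_``, ``rf_max_err_``, ``tau_``.  When the optimizer fails
    (flat or pathological curves) it falls back to the endpoint mean
    and records a warning in ``warning_``.
    """

    def __init__(self, endpoint_fraction: float = 0.1):
        self.endpoint_fraction = endpoint_fraction

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).reshape(-1)
        rf = np.asarray(y, dtype=float).reshape(-1)
        if t.size < 10:
            raise DomainError("need >= 10 time points")
        self.warning_ = None
        if np.ptp(rf) == 0:
            # flat record: the plateau is the constant itself
            self.rf_max_, self.rf_max_err_, self.tau_ = float(rf[0]), 0.0, None
            self.method_ = "exponential_fit"
            return self
        try:
            p0 = [max(rf[-1], 1e-3), max(t[-1] / 5.0, 1e-6)]
            popt, pcov = curve_fit(
                lambda tt, a, tau: a * (1.0 - np.exp(-tt / tau)),
                t, rf, p0=p0, bounds=([0, 1e-9], [np.inf, np.inf]), maxfev=5000,
            )
            self.rf_max_, self.tau_ = float(popt[0]), float(popt[1])
            self.rf_max_err_ = float(np.sqrt(max(pcov[0, 0], 0.0)))
            self.method_ = "exponential_fit"
            if not np.isfinite(self.rf_max_err_):
                self.rf_max_err_ = 0.0
        except (RuntimeError, ValueError) as exc:
            tail = rf[int(np.floor(t.size * (1 - self.endpoint_fraction))):]
            self.rf_max_ = float(np.mean(tail))
            self.rf_max_err_ = float(np.std(tail, ddof=1) / np.sqrt(tail.size)) if tail.size > 1 else 0.0
            self.tau_ = None
            self.method_ = "endpoint"
            self.warning_ = f"exponential fit failed ({exc}); endpoint fallback"
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        if self.tau_ is None:
            return np.full_like(t, self.rf_max_)
        return self.rf_max_ * (1.0 - np.exp(-t / self.tau_))


def estimate_rf_max(
    times, rf_curve, method: str = "exponential_fit", endpoint_fraction: float = 0.1
) -> LeakageResult:
    """Extract the leakage plateau RF_max (%) from an RF(t) curve.

    method "endpoint": mean +/- standard error of the final
    ``endpoint_fraction`` of points.  method "exponential_fit": plateau
    of a mono-exponential rise via :class:`ExponentialRelease` (falls
    back to endpoint with a warning on non-convergence).  The reported
    plateau is floored at 0.
    """
    t = np.asarray(times, dtype=float).reshape(-1)
    rf = np.asarray(rf_curve, dtype=float).reshape(-1)
    if t.size < 10:
        raise DomainError("need >= 10 time points")
    if method == "endpoint":
        tail = rf[int(np.floor(t.size * (1 - endpoint_fraction))):]
        err = float(np.std(tail, ddof=1) / np.sqrt(tail.size)) if tail.size > 1 else 0.0
        return LeakageResult(rf_max=max(float(np.mean(tail)), 0.0), rf_max_err=err, method="endpoint")
    if method != "exponential_fit":
        raise ValueError(f"unknown method {method!r}")
    est = ExponentialRelease(endpoint_fraction=endpoint_fraction).fit(t, rf)
    return LeakageResult(
        rf_max=max(est.rf_max_, 0.0),
        rf_max_err=est.rf_max_err_,
        method=est.method_,
        tau=est.tau_,
        warning=est.warning_,
    )
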