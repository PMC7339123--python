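"""Membrane boundary- and dipole-potential analysis.

The boundary potential phi_b of a planar bilayer is probed through the
steady-state conductance G_m induced by a lipophilic cation carrier
(K+-nonactin): the carrier concentration at the membrane core follows a
Boltzmann distribution in the interfacial potential, so

    delta_phi = (kT/e) * ln(G_m / G_m0)

converts a conductance ratio into a potential change in mV.  The sign
convention used throughout: an *increase* of the cation-carrier
conductance means the interfacial potential barrier for cations fell,
i.e. a boundary-potential *reduction*; the value returned here is that
reduction as a positive number (the quantity plotted and tabulated as
-delta_phi_b).

Adsorption of a modifier at aqueous concentration C saturates according
to a Langmuir isotherm,

    delta_phi(C) = delta_phi_max * C / (C + K),

with K (uM) the desorption constant measuring lipid affinity.  The
isotherm is fitted either by nonlinear least squares (default) or by
the classical double-reciprocal linearization in which
delta_phi_max/delta_phi(C) is linear in 1/C with slope K and unit
intercept.

The dipole-potential component phi_d is probed ratiometrically with a
voltage-sensitive styryl dye (di-8-ANEPPS); the 420/520 nm excitation
ratio R maps linearly onto phi_d through an instrument calibration
carried as configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import ROOM_TEMPERATURE_K, thermal_voltage_mV
from .errors import ConfigurationError, DomainError
from .models import DipoleCalibration


@dataclass
class ConductanceMeasurement:
    """Paired carrier-mediated conductances with and without modifier."""

    g_m: float
    g_m0: float
    voltage: float = 50.0
    temperature: float = ROOM_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.g_m <= 0 or self.g_m0 <= 0:
            raise DomainError("conductances must be positive")
        if self.temperature <= 0:
            raise DomainError("temperature must be positive (kelvin)")


def boltzmann_delta_phi(
    g_m, g_m0=None, temperature: float = ROOM_TEMPERATURE_K
):
    """Boundary-potential change (mV) from a conductance ratio.

    Accepts either a :class:`ConductanceMeasurement` or explicit
    ``g_m``/``g_m0`` values (scalars or arrays).  Returns
    (kT/e) * ln(g_m/g_m0) in mV; positive output is the reported
    boundary-potential reduction (see module docstring for the sign
    convention).
    """
    if isinstance(g_m, ConductanceMeasurement):
        m = g_m
        g_m, g_m0, temperature = m.g_m, m.g_m0, m.temperature
    g_m = np.asarray(g_m, dtype=float)
    g_m0 = np.asarray(g_m0, dtype=float)
    if np.any(g_m <= 0) or np.any(g_m0 <= 0):
        raise DomainError("conductances must be positive")
    out = thermal_voltage_mV(temperature) * np.log(g_m / g_m0)
    return float(out) if out.ndim == 0 else out


@dataclass
class AdsorptionSeries:
    """Per-compound concentration series of potential shifts (mV)."""

    concentrations: np.ndarray
    dphi: np.ndarray
    compound: str = ""
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.dphi = np.asarray(self.dphi, dtype=float)
        if self.concentrations.shape != self.dphi.shape:
            raise DomainError("concentrations and dphi must have equal length")
        if not np.all(np.diff(self.concentrations) > 0):
            raise DomainError("concentrations must be strictly increasing")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.dphi.shape:
                raise DomainError("sd must match dphi length")


@dataclass
class LangmuirFit:
    """Langmuir isotherm fit result (mV / uM scale)."""

    dphi_max: float | None = None
    k_desorption: float | None = None
    dphi_max_err: float | None = None
    k_err: float | None = None
    method: str = "nonlinear"
    intercept_diagnostic: float | None = None
    rss: float | None = None
    n: int = 0
    ok: bool = True
    reason: str | None = None

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return self.dphi_max * c / (c + self.k_desorption)


class LangmuirIsotherm(RegressorMixin, BaseEstimator):
    """Langmuir adsorption isotherm estimator.

    Parameters
    ----------
    method : {"nonlinear", "linearized"}
        "nonlinear" fits delta_phi(C) = dphi_max*C/(C+K) by (optionally
        1/sd^2-weighted) least squares.  "linearized" is the
        double-reciprocal regression in which dphi_max/delta_phi(C) is
        linear in 1/C with slope K; the regression intercept times the
        recovered dphi_max is reported as a diagnostic expected to be 1.

    Fitted attributes: ``dphi_max_``, ``k_``, ``dphi_max_err_``,
    ``k_err_``, ``result_`` (a :class:`LangmuirFit`).  Degenerate input
    (no curvature, flat response) sets ``result_.ok = False`` with a
    reason code instead of returning a silent number.
    """

    def __init__(self, method: str = "nonlinear"):
        self.method = method

    # -- internal fitters ------------------------------------------------
    @staticmethod
    def _fit_nonlinear(c, y, w):
        k0 = max(np.interp(0.5 * y.max(), np.sort(y), np.sort(c)), c[c > 0].min())
        p0 = np.array([y.max() * 1.2 if y.max() > 0 else y.min() * 1.2, k0])

        def resid(p):
            return (p[0] * c / (c + p[1]) - y) * np.sqrt(w)

        sol = least_squares(resid, p0, bounds=([-np.inf, 1e-12], [np.inf, np.inf]))
        rss = float(np.sum(resid(sol.x) ** 2))
        dof = max(c.size - 2, 1)
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * rss / dof
            errs = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            errs = np.array([np.nan, np.nan])
        return sol.x[0], sol.x[1], errs[0], errs[1], rss, None

    @staticmethod
    def _fit_linearized(c, y, w):
        if np.any(c <= 0) or np.any(y == 0):
            keep = (c > 0) & (y != 0)
            c, y, w = c[keep], y[keep], w[keep]
        if c.size < 3:
            raise DomainError("need >= 3 usable points for linearization")
        x_inv, y_inv = 1.0 / c, 1.0 / y
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x_inv), x_inv])
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y_inv, rcond=None)
        a, b = beta  # y_inv = a + b * x_inv
        if a == 0:
            raise DomainError("degenerate double-reciprocal intercept")
        dphi_max, k = 1.0 / a, b / a
        resid = X @ beta - y_inv
        rss = float(np.sum(w * resid**2))
        dof = max(c.size - 2, 1)
        s2 = rss / dof
        cov = np.linalg.inv(X.T @ W @ X) * s2
        # delta-method propagation through (1/a, b/a)
        da, db = np.sqrt(max(cov[0, 0], 0)), np.sqrt(max(cov[1, 1], 0))
        cab = cov[0, 1]
        dphi_err = da / a**2
        k_var = (db / a) ** 2 + (b * da / a**2) ** 2 - 2 * b * cab / a**3
        k_err = np.sqrt(max(k_var, 0.0))
        intercept = dphi_max * a  # identically 1 when the algebra is consistent
        return dphi_max, k, dphi_err, k_err, rss, float(intercept)

    # -- sklearn surface -------------------------------------------------
    def fit(self, X, y=None, sample_weight=None):
        """Fit the isotherm.

        X may be an :class:`AdsorptionSeries`, or an array of
        concentrations (n,) / (n, 1) with y the potential shifts (mV).
        ``sample_weight`` defaults to 1/sd^2 when the series carries
        per-point standard deviations.
        """
        if isinstance(X, AdsorptionSeries):
            c, yv = X.concentrations, X.dphi
            if sample_weight is None and X.sd is not None and np.all(X.sd > 0):
                # floor small replicate sds so a lucky near-zero spread
                # cannot dominate the weighted fit
                sd_eff = np.maximum(X.sd, np.median(X.sd) / 3.0)
                sample_weight = 1.0 / sd_eff**2
        else:
            c = np.asarray(X, dtype=float).reshape(-1)
            yv = np.asarray(y, dtype=float).reshape(-1)
        w = np.ones_like(c) if sample_weight is None else np.asarray(sample_weight, float)

        self.result_ = LangmuirFit(method=self.method, n=int(c.size))
        usable = c > 0
        if usable.sum() < 3:
            self._fail("too_few_points")
            return self
        if np.ptp(yv) == 0:
            self._fail("flat_response")
            return self
        # curvature check: a straight line through the origin explains a
        # saturating isotherm poorly only if the data actually bend
        lin_pred = yv[usable][-1] / c[usable][-1] * c[usable]
        if np.allclose(yv[usable], lin_pred, rtol=1e-10, atol=1e-12):
            self._fail("no_curvature")
            return self
        try:
            fitter = self._fit_nonlinear if self.method == "nonlinear" else self._fit_linearized
            dphi_max, k, dphi_err, k_err, rss, intercept = fitter(c[usable], yv[usable], w[usable])
        except (DomainError, np.linalg.LinAlgError) as exc:
            self._fail(f"fit_failed:{exc}")
            return self
        if not np.isfinite(dphi_max) or not np.isfinite(k) or k <= 0:
            self._fail("nonphysical_parameters")
            return self
        self.dphi_max_, self.k_ = float(dphi_max), float(k)
        self.dphi_max_err_, self.k_err_ = float(dphi_err), float(k_err)
        self.result_ = LangmuirFit(
            dphi_max=self.dphi_max_,
            k_desorption=self.k_,
            dphi_max_err=self.dphi_max_err_,
            k_err=self.k_err_,
            method=self.method,
            intercept_diagnostic=intercept,
            rss=rss,
            n=int(c.size),
        )
        return self

    def _fail(self, reason: str) -> None:
        self.result_.ok = False
        self.result_.reason = reason
        self.dphi_max_ = self.k_ = self.dphi_max_err_ = self.k_err_ = None

    def predict(self, X):
        c = np.asarray(X, dtype=float).reshape(-1)
        if self.k_ is None:
            raise DomainError("estimator not successfully fitted")
        return self.dphi_max_ * c / (c + self.k_)


def fit_langmuir(series: AdsorptionSeries, method: str = "nonlinear") -> LangmuirFit:
    """Functional wrapper over :class:`LangmuirIsotherm`."""
    return LangmuirIsotherm(method=method).fit(series).result_


@dataclass
class RatioSeries:
    """di-8-ANEPPS 420/520 nm excitation ratios per concentration."""

    concentrations: np.ndarray
    ratios: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.concentrations.shape != self.ratios.shape:
            raise DomainError("concentrations and ratios must have equal length")


def ratio_to_dipole_shift(series: RatioSeries, cal: DipoleCalibration) -> AdsorptionSeries:
    """Convert excitation ratios to dipole-potential reductions (mV).

    delta_phi_d(C) = (R(C) - r_ref) / slope.  With the default
    negative calibration slope a ratio decrease maps to a positive
    reported reduction.  Returns an :class:`AdsorptionSeries` ready for
    Langmuir fitting.
    """
    if cal.slope == 0:
        raise ConfigurationError("slope: calibration slope must be nonzero")
    shifts = (series.ratios - cal.r_ref) / cal.slope
    return AdsorptionSeries(series.concentrations, shifts)


@dataclass
class CompoundElectrostaticsRecord:
    """Assembled per-compound electrostatics summary.

    ``k_na`` marks the desorption constant as not-applicable when the
    fitted saturation shift is below the detectability floor (weak
    modifiers whose isotherm cannot be resolved).  phi_d fields are
    None — not zero — when no dye series was measured.
    """

    compound: str
    dphi_b_max: float | None
    dphi_b_max_err: float | None
    k_desorption: float | None
    k_err: float | None
    k_na: bool
    dphi_d_max: float | None = None
    dphi_d_max_err: float | None = None
    notes: list[str] = field(default_factory=list)


def summarize_compound(
    compound: str,
    phi_b_fit: LangmuirFit,
    phi_d_fit: LangmuirFit | None = None,
    detectability_floor: float = 10.0,
    observed_max: float | None = None,
) -> CompoundElectrostaticsRecord:
    """Assemble the per-compound record of boundary/dipole potential fits.

    The desorption constant is flagged not-applicable when the fitted
    saturation shift — or, when given, the largest *measured* shift —
    is below ``detectability_floor`` (mV): below that floor the
    isotherm's curvature is not measurable, so a fitted K would be
    noise.  The observed-maximum criterion also catches the
    near-linear weak-responder regime where the unconstrained
    asymptote diverges along the dphi_max/K ridge; in that case the
    observed maximum is reported in place of the meaningless
    asymptote.
    """
    notes: list[str] = []
    if not phi_b_fit.ok:
        notes.append(f"phi_b fit failed: {phi_b_fit.reason}")
        return CompoundElectrostaticsRecord(
            compound, None, None, None, None, True, notes=notes
        )
    na = phi_b_fit.dphi_max is None or abs(phi_b_fit.dphi_max) < detectability_floor
    if observed_max is not None and abs(observed_max) < detectability_floor:
        na = True
    dphi_b_max = phi_b_fit.dphi_max
    dphi_b_max_err = phi_b_fit.dphi_max_err
    if na and observed_max is not None and (dphi_b_max is None or abs(dphi_b_max) > 2 * detectability_floor):
        notes.append("saturation not reached; observed maximum shift reported")
        dphi_b_max, dphi_b_max_err = observed_max, None
    rec = CompoundElectrostaticsRecord(
        compound=compound,
        dphi_b_max=dphi_b_max,
        dphi_b_max_err=dphi_b_max_err,
        k_desorption=None if na else phi_b_fit.k_desorption,
        k_err=None if na else phi_b_fit.k_err,
        k_na=na,
    )
    if phi_d_fit is not None and phi_d_fit.ok:
        rec.dphi_d_max = phi_d_fit.dphi_max
        rec.dphi_d_max_err = phi_d_fit.dphi_max_err
    elif phi_d_fit is not None:
        notes.append(f"phi_d fit failed: {phi_d_fit.reason}")
    rec.notes = notes
    return rec
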