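"""Differential scanning calorimetry of lipid phase transitions.

A heating scan of a phospholipid vesicle suspension shows the gel ->
ripple pretransition (peak at T_p) and the ripple -> fluid main
transition (peak at T_m).  This module extracts the peak temperatures,
the full width at half maximum of the main endotherm (T_1/2, an inverse
proxy for melting cooperativity), the calorimetric enthalpy (peak
area), and a multi-component decomposition of the main peak into
two-state van't Hoff transitions; shifts of these features relative to
a control scan quantify the effect of a membrane-intercalating
modifier.

The two-state excess heat capacity used both for synthesis and for
deconvolution is

    Cp(T) = dH_cal * (dH_vH / (R T^2)) * Theta (1 - Theta),
    Theta = Keq / (1 + Keq),   ln Keq = -(dH_vH / R)(1/T - 1/T_m),

whose area is exactly dH_cal and whose full width at half maximum is
FWHM = 3.5255 R T_m^2 / dH_vH (T in kelvin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .constants import GAS_CONSTANT_R, celsius_to_kelvin
from .errors import DomainError
from .models import MeltingComponent

#: 2*ln(3+2*sqrt(2)): FWHM of the two-state peak in units of R*T_m^2/dH_vH
VANT_HOFF_FWHM_FACTOR = 3.5255


def vant_hoff_excess_cp(temp_C, t_m_C, vant_hoff_enthalpy, calorimetric_enthalpy):
    """Two-state van't Hoff excess heat capacity on a Celsius grid.

    Parameters are the peak temperature (Celsius), the van't Hoff
    enthalpy controlling sharpness (J/mol) and the calorimetric
    enthalpy equal to the peak area (J/mol, per Celsius grid units).
    """
    T = celsius_to_kelvin(np.asarray(temp_C, dtype=float))
    Tm = celsius_to_kelvin(t_m_C)
    ln_keq = -(vant_hoff_enthalpy / GAS_CONSTANT_R) * (1.0 / T - 1.0 / Tm)
    # theta*(1-theta) = 1/(2+2*cosh(ln_keq)), numerically safe for large |ln_keq|
    theta_one_minus = 1.0 / (2.0 + 2.0 * np.cosh(np.clip(ln_keq, -700, 700)))
    return calorimetric_enthalpy * vant_hoff_enthalpy / (GAS_CONSTANT_R * T**2) * theta_one_minus


def vant_hoff_fwhm(t_m_C: float, vant_hoff_enthalpy: float) -> float:
    """Closed-form full width at half maximum of a two-state endotherm, in C."""
    Tm = celsius_to_kelvin(t_m_C)
    return VANT_HOFF_FWHM_FACTOR * GAS_CONSTANT_R * Tm**2 / vant_hoff_enthalpy


def enthalpy_for_fwhm(t_m_C: float, fwhm_C: float) -> float:
    """van't Hoff enthalpy (J/mol) giving a requested peak width, in C."""
    Tm = celsius_to_kelvin(t_m_C)
    return VANT_HOFF_FWHM_FACTOR * GAS_CONSTANT_R * Tm**2 / fwhm_C


@dataclass
class Thermogram:
    """Temperature-indexed excess heat capacity scan."""

    temperature: np.ndarray
    cp_excess: np.ndarray
    scan_rate: float = 0.2
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.cp_excess = np.asarray(self.cp_excess, dtype=float)
        if self.temperature.shape != self.cp_excess.shape or self.temperature.ndim != 1:
            raise DomainError("temperature and cp_excess must be equal-length 1-D arrays")
        if not np.all(np.diff(self.temperature) > 0):
            raise DomainError("temperature grid must be strictly increasing")

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.temperature)))


@dataclass
class ThermogramFeatures:
    """Features of one scan: peak temperatures, width, area, components."""

    t_m: float | None = None
    t_p: float | None = None
    t_half: float | None = None
    enthalpy: float | None = None
    pretransition_abolished: bool = True
    components: list[MeltingComponent] = field(default_factory=list)
    ok: bool = True
    reason: str | None = None


@dataclass
class MeltingShifts:
    """Treated-vs-control feature shifts, with the reporting conventions
    that a main-transition downshift and a peak broadening are positive."""

    minus_delta_t_m: float
    delta_t_half: float
    delta_t_p: float | None
    pretransition_abolished: bool


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-grid peak location by a 3-point parabola through (i-1, i, i+1)."""
    if i == 0 or i == len(x) - 1:
        return float(x[i]), float(y[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0 or abs(denom) < 1e-300:
        return float(x1), float(y1)
    h = (x2 - x0) / 2.0
    delta = 0.5 * (y0 - y2) / denom * h
    yv = y1 - 0.25 * (y0 - y2) * delta / h
    return float(x1 + delta), float(yv)


def _vertex_ls(x: np.ndarray, y: np.ndarray, ipk: int, cap_fraction: float = 0.9) -> tuple[float, float]:
    """Sub-grid peak location from a least-squares parabola over the
    contiguous peak cap (points above ``cap_fraction`` of the apex).

    Averaging over the cap makes the vertex robust to per-point noise
    on broad peaks; narrow peaks degrade gracefully to the classic
    3-point parabolic interpolation.
    """
    cap = cap_fraction * y[ipk]
    lo = ipk
    while lo > 0 and y[lo - 1] >= cap:
        lo -= 1
    hi = ipk
    while hi < y.size - 1 and y[hi + 1] >= cap:
        hi += 1
    if hi - lo + 1 < 5:
        return _parabolic_vertex(x, y, ipk)
    xs, ys = x[lo : hi + 1], y[lo : hi + 1]
    a, b, c = np.polyfit(xs - x[ipk], ys, 2)
    if a >= 0:
        return _parabolic_vertex(x, y, ipk)
    xv = -b / (2 * a)
    return float(x[ipk] + xv), float(c - b**2 / (4 * a))


def _robust_baseline(x: np.ndarray, y: np.ndarray, order: int, z: float = 2.5, n_iter: int = 10):
    """Iteratively-masked polynomial baseline (endotherm peaks sit above
    the baseline, so points significantly above the running fit are
    excluded and the fit repeated until the flank mask stabilizes).

    Returns (coeffs, flank_mask, robust_noise_sd).
    """
    scale = float(np.max(np.abs(y))) if y.size else 0.0
    mask = np.ones(y.size, dtype=bool)
    coeffs = np.zeros(order + 1)
    sd = 0.0
    for _ in range(n_iter):
        coeffs = np.polyfit(x[mask], y[mask], order)
        resid = y - np.polyval(coeffs, x)
        sd = float(1.4826 * np.median(np.abs(resid[mask] - np.median(resid[mask]))))
        new = resid <= z * sd + 1e-12 * max(scale, 1.0)
        if new.sum() < max(order + 2, y.size // 10):
            raise DomainError("peaks occupy the entire scan; cannot anchor a baseline")
        if np.array_equal(new, mask):
            break
        mask = new
    return coeffs, mask, sd


def preprocess(raw: Thermogram, baseline_order: int = 1) -> Thermogram:
    """Fit a polynomial baseline on the off-peak flanks and subtract it.

    Raises :class:`DomainError` when peaks occupy essentially the whole
    scan and no flank remains to anchor the baseline.
    """
    if raw.temperature.size < 50:
        raise DomainError("preprocess requires >= 50 grid points")
    x = raw.temperature
    coeffs, mask, sd = _robust_baseline(x, raw.cp_excess, baseline_order)
    corrected = raw.cp_excess - np.polyval(coeffs, x)
    peak = float(np.max(corrected)) if corrected.size else 0.0
    # two signatures of a peak occupying the whole scan (no true flank):
    # the shoulder-anchored "baseline" carves negative lobes comparable
    # to the peak, or masking excluded nothing although the residual is
    # smooth structure rather than point noise
    if peak > 10 * sd and float(np.min(corrected)) < -0.2 * peak:
        raise DomainError("peaks occupy the entire scan; cannot anchor a baseline")
    if mask.mean() > 0.95 and corrected.std() > 0:
        r = corrected - corrected.mean()
        lag1 = float(np.dot(r[:-1], r[1:]) / np.dot(r, r))
        if lag1 > 0.9:
            raise DomainError("peaks occupy the entire scan; cannot anchor a baseline")
    return Thermogram(x.copy(), corrected, scan_rate=raw.scan_rate, label=raw.label)


def _flank_noise(t: Thermogram) -> float:
    """Robust (MAD-based) noise estimate from the off-peak flanks."""
    try:
        _, _, sd = _robust_baseline(t.temperature, t.cp_excess, 1)
    except DomainError:
        y = t.cp_excess
        sd = float(1.4826 * np.median(np.abs(y - np.median(y))))
    return sd


def _flank_crossing(x: np.ndarray, y: np.ndarray, ipk: int, height: float, step: int) -> float | None:
    """Temperature at which the flank (walking from the peak in
    ``step`` direction) crosses half height.

    The crossing is solved on a local quadratic fitted to the flank
    points between 20% and 80% of the peak height, which averages
    per-point noise on broad peaks; narrow flanks (<5 points) fall
    back to linear interpolation between the bracketing samples.
    """
    half = height / 2.0
    j = ipk
    while 0 <= j + step < y.size and y[j] > half:
        j += step
    if y[j] > half:
        return None
    # contiguous flank window around the crossing
    lo = hi = j
    while lo - 1 >= 0 and 0.2 * height <= y[lo - 1] <= 0.8 * height:
        lo -= 1
    while hi + 1 < y.size and 0.2 * height <= y[hi + 1] <= 0.8 * height:
        hi += 1
    if hi - lo + 1 >= 5:
        xs, ys = x[lo : hi + 1], y[lo : hi + 1]
        x0 = x[j]
        a, b, c = np.polyfit(xs - x0, ys, 2)
        roots = np.roots([a, b, c - half]) if a != 0 else np.array([(half - c) / b])
        roots = roots[np.isreal(roots)].real + x0
        in_win = roots[(roots >= xs[0] - (xs[1] - xs[0])) & (roots <= xs[-1] + (xs[1] - xs[0]))]
        if in_win.size:
            return float(in_win[np.argmin(np.abs(in_win - x[j]))])
    # linear interpolation fallback between the bracketing samples
    j_in = j - step
    if y[j] == y[j_in]:
        return float(x[j])
    f = (y[j_in] - half) / (y[j_in] - y[j])
    return float(x[j_in] + f * (x[j] - x[j_in]))


def _half_height_width(x: np.ndarray, y: np.ndarray, ipk: int, height: float) -> float | None:
    """FWHM around the peak at index ipk."""
    left = _flank_crossing(x, y, ipk, height, -1)
    right = _flank_crossing(x, y, ipk, height, +1)
    if left is None or right is None:
        return None
    return float(right - left)


def extract_features(
    t: Thermogram,
    pretransition_margin: float = 1.0,
    prominence_noise_factor: float = 3.0,
    min_pretransition_height_rel: float = 0.01,
    deconvolve_components: int = 0,
) -> ThermogramFeatures:
    """Extract T_m, T_p, T_1/2 and the main-transition enthalpy.

    The main transition is the global maximum (sub-grid location by
    parabolic interpolation); T_1/2 is its full width at half maximum.
    The pretransition is the most prominent secondary peak at least
    ``pretransition_margin`` C below T_m whose prominence exceeds
    ``prominence_noise_factor`` times the robust flank-noise estimate
    and whose height reaches ``min_pretransition_height_rel`` of the
    main peak (a detectability floor: isolated noise bumps can clear a
    3-sigma prominence by chance, a real gel->ripple endotherm is a
    few percent of the main peak); if none qualifies the pretransition
    is reported as abolished.  Enthalpy is the trapezoidal integral
    over the contiguous main-transition window.  Optionally runs
    :func:`deconvolve` and attaches the components.
    """
    x, y = t.temperature, t.cp_excess
    scale = float(np.max(y)) if y.size else 0.0
    noise = _flank_noise(t)
    if scale <= 0 or scale < prominence_noise_factor * noise:
        return ThermogramFeatures(ok=False, reason="no_peak")

    ipk = int(np.argmax(y))
    t_m, peak_height = _vertex_ls(x, y, ipk)
    t_half = _half_height_width(x, y, ipk, peak_height)
    if t_half is None:
        return ThermogramFeatures(ok=False, reason="peak_truncated_by_grid")

    # main-transition window: contiguous region around the peak above a
    # floor set by noise and a small fraction of the peak height
    floor = max(0.005 * peak_height, prominence_noise_factor * noise)
    lo = ipk
    while lo > 0 and y[lo - 1] > floor:
        lo -= 1
    hi = ipk
    while hi < y.size - 1 and y[hi + 1] > floor:
        hi += 1
    enthalpy = float(np.trapezoid(np.clip(y[lo : hi + 1], 0, None), x[lo : hi + 1]))

    # pretransition: most prominent secondary peak well below T_m
    t_p = None
    noise_floor = max(noise, 1e-9 * peak_height)
    region = x < (t_m - pretransition_margin)
    region[lo:] = False  # exclude the main-transition window itself
    if np.any(region):
        sub = np.where(region)[0]
        speaks, props = find_peaks(
            y[sub],
            prominence=prominence_noise_factor * noise_floor,
            height=min_pretransition_height_rel * peak_height,
        )
        if speaks.size:
            best = speaks[int(np.argmax(props["prominences"]))]
            t_p, _ = _vertex_ls(x, y, sub[best])

    feats = ThermogramFeatures(
        t_m=t_m,
        t_p=t_p,
        t_half=float(t_half),
        enthalpy=enthalpy,
        pretransition_abolished=t_p is None,
    )
    if deconvolve_components:
        feats.components = deconvolve(t, max_components=deconvolve_components)
    return feats


def _component_curve(x, params, model):
    if model == "vant_hoff":
        tm, dhvh, dhcal = params
        return vant_hoff_excess_cp(x, tm, dhvh, dhcal)
    tm, width, area = params  # gaussian alternative
    sd = max(width, 1e-9) / 2.3548200450309493
    return area / (sd * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((x - tm) / sd) ** 2)


def _deconvolve_impl(
    t: Thermogram,
    max_components: int = 3,
    model: str = "vant_hoff",
    noise_floor_rel: float = 1e-3,
) -> list[MeltingComponent]:
    x, y = t.temperature, t.cp_excess
    peak = float(np.max(y))
    if peak <= 0:
        return []
    total_area = float(np.trapezoid(np.clip(y, 0, None), x))
    sigma2 = max(_flank_noise(t) ** 2, (noise_floor_rel * peak) ** 2)
    # initial width guess from the main peak's FWHM
    ipk = int(np.argmax(y))
    w0 = _half_height_width(x, y, ipk, y[ipk]) or max(5 * t.grid_step, 0.2)
    center = x[ipk]

    best: tuple[float, list[MeltingComponent]] | None = None
    n_obs = x.size
    for n_comp in range(1, max_components + 1):
        # spread initial peak positions across the envelope
        offsets = np.linspace(-0.6 * w0 * (n_comp - 1), 0.6 * w0 * (n_comp - 1), n_comp)
        p0, lower, upper = [], [], []
        for off in offsets:
            tm0 = float(np.clip(center + off, x[0], x[-1]))
            if model == "vant_hoff":
                p0 += [tm0, enthalpy_for_fwhm(tm0, w0), total_area / n_comp]
                lower += [x[0], enthalpy_for_fwhm(center, 20 * (x[-1] - x[0])), 1e-12]
                upper += [x[-1], enthalpy_for_fwhm(center, max(2 * t.grid_step, w0 / 50)), 10 * total_area + 1e-9]
            else:
                p0 += [tm0, w0, total_area / n_comp]
                lower += [x[0], 2 * t.grid_step, 1e-12]
                upper += [x[-1], x[-1] - x[0], 10 * total_area + 1e-9]

        def residual(p, n=n_comp):
            yhat = np.zeros_like(x)
            for j in range(n):
                yhat = yhat + _component_curve(x, p[3 * j : 3 * j + 3], model)
            return yhat - y

        try:
            sol = least_squares(residual, p0, bounds=(lower, upper), max_nfev=4000)
        except Exception:
            continue
        if not sol.success and not np.isfinite(sol.cost):
            continue
        rss = float(2 * sol.cost)
        k = 3 * n_comp
        if n_obs - k - 1 <= 0:
            continue
        aicc = rss / sigma2 + 2 * k + 2 * k * (k + 1) / (n_obs - k - 1)
        comps = []
        for j in range(n_comp):
            tm, a, b = sol.x[3 * j : 3 * j + 3]
            if model == "vant_hoff":
                dhvh, dhcal = a, b
            else:
                dhvh, dhcal = enthalpy_for_fwhm(tm, a), b
            comps.append((tm, dhvh, dhcal))
        comps.sort(key=lambda c: c[0])
        total = sum(c[2] for c in comps)
        out = [
            MeltingComponent(t_m=c[0], vant_hoff_enthalpy=c[1], calorimetric_enthalpy=c[2], weight=c[2] / total)
            for c in comps
            if c[2] > 1e-9 * total
        ]
        if best is None or aicc < best[0]:
            best = (aicc, out)
    return best[1] if best else []


class VantHoffDeconvolver(BaseEstimator):
    """Estimator decomposing an endotherm into two-state transitions.

    Fits sums of 1..``max_components`` van't Hoff (or, with
    ``model='gaussian'``, Gaussian) peaks to a preprocessed thermogram
    and selects the component count by corrected AIC.  The residual
    variance entering the criterion is floored at ``noise_floor_rel``
    of the peak height; this acts as the instrument resolution, so
    transitions closer together than that floor can discriminate
    collapse into a single fitted component.

    Attributes
    ----------
    components_ : list of MeltingComponent, sorted by t_m, weights
        proportional to calorimetric enthalpy; empty if nothing
        converged.
    n_components_ : selected component count.
    """

    def __init__(self, max_components: int = 3, model: str = "vant_hoff", noise_floor_rel: float = 1e-3):
        self.max_components = max_components
        self.model = model
        self.noise_floor_rel = noise_floor_rel

    def fit(self, X, y=None):
        """Fit on a Thermogram, or on (temperature, cp_excess) given as
        X (n, 1) or (n,) with y the heat capacities."""
        if isinstance(X, Thermogram):
            t = X
        else:
            temp = np.asarray(X, dtype=float).reshape(-1)
            t = Thermogram(temp, np.asarray(y, dtype=float))
        self.components_ = _deconvolve_impl(
            t, max_components=self.max_components, model=self.model, noise_floor_rel=self.noise_floor_rel
        )
        self.n_components_ = len(self.components_)
        return self

    def predict(self, X):
        """Reconstruct the fitted excess-heat-capacity curve on a grid."""
        temp = np.asarray(X, dtype=float).reshape(-1)
        out = np.zeros_like(temp)
        for c in self.components_:
            out += vant_hoff_excess_cp(temp, c.t_m, c.vant_hoff_enthalpy, c.calorimetric_enthalpy)
        return out


def deconvolve(
    t: Thermogram,
    max_components: int = 3,
    model: str = "vant_hoff",
    noise_floor_rel: float = 1e-3,
) -> list[MeltingComponent]:
    """Functional wrapper over :class:`VantHoffDeconvolver`."""
    return VantHoffDeconvolver(max_components, model, noise_floor_rel).fit(t).components_


def shifts_vs_control(control: ThermogramFeatures, treated: ThermogramFeatures) -> MeltingShifts:
    """Feature shifts of a treated scan relative to the control.

    ``minus_delta_t_m`` = T_m(control) - T_m(treated) (positive when the
    modifier melts the bilayer earlier); ``delta_t_half`` =
    T_1/2(treated) - T_1/2(control) (positive for broadening);
    ``delta_t_p`` likewise downshift-positive, and None with the
    abolition flag set when the treated pretransition has vanished.
    """
    if not (control.ok and treated.ok) or control.t_m is None or treated.t_m is None:
        raise DomainError("both control and treated features must be present")
    abolished = treated.pretransition_abolished and not control.pretransition_abolished
    delta_t_p = None
    if control.t_p is not None and treated.t_p is not None:
        delta_t_p = control.t_p - treated.t_p
    return MeltingShifts(
        minus_delta_t_m=control.t_m - treated.t_m,
        delta_t_half=(treated.t_half or 0.0) - (control.t_half or 0.0),
        delta_t_p=delta_t_p,
        pretransition_abolished=abolished,
    )
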