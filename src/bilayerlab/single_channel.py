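"""Single-channel electrophysiology: idealization and gating statistics.

A current record from a bilayer holding a single two-state channel is
*idealized* into an alternating sequence of open/closed events by the
half-amplitude threshold convention: the baseline is the dominant mode
of the all-points amplitude histogram, the open level the second mode,
and transitions are placed at crossings of their midpoint.  Events
shorter than the dead time imposed by low-pass filtering (rise time
T_r ~ 0.3321/f_c for a 4-pole Bessel-type filter; dead time defaults to
2 T_r) cannot be resolved and are merged into their neighbours.

From the event list the module estimates

* single-channel conductance G_SC = |i| / |V| from the per-event
  amplitude histogram fitted by a normal density (chi-square
  goodness-of-fit on pooled bins),
* the open-state dwell time tau by the left-truncated exponential
  maximum-likelihood estimate E[X | X > d] = tau + d, i.e.
  tau_hat = mean(dwell) - dead_time, with a histogram chi-square test
  for exponentiality,
* conductance-voltage (G-V) curves and their shape comparison after
  amplitude normalization,
* the ratio I_inf/I_inf0 of steady-state macroscopic currents before
  and after modifier addition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import ROOM_TEMPERATURE_K
from .errors import DomainError

#: rise time of a 4-pole Bessel-type low-pass filter, seconds * Hz
BESSEL_RISE_TIME_FACTOR = 0.3321


@dataclass
class CurrentTrace:
    """Uniformly sampled transmembrane current record."""

    current: np.ndarray
    sampling_rate: float
    voltage: float
    filter_cutoff: float | None = 200.0
    temperature: float = ROOM_TEMPERATURE_K
    label: str = ""

    def __post_init__(self) -> None:
        self.current = np.asarray(self.current, dtype=float)
        if self.current.ndim != 1 or self.current.size == 0:
            raise DomainError("current must be a nonempty 1-D array")
        if self.sampling_rate <= 0:
            raise DomainError("sampling_rate must be positive")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.current.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.current.size / self.sampling_rate

    def dead_time(self) -> float:
        """Default resolvable-event floor: twice the filter rise time."""
        if not self.filter_cutoff:
            return 0.0
        return 2.0 * BESSEL_RISE_TIME_FACTOR / self.filter_cutoff


@dataclass
class EventList:
    """Alternating idealized open/closed events.

    ``states`` is boolean (True = open); starts/dwells in seconds,
    amplitudes in pA relative to baseline.  By construction the dwells
    partition the analysed trace: they sum to its duration.
    """

    states: np.ndarray
    starts: np.ndarray
    dwells: np.ndarray
    amplitudes: np.ndarray
    baseline: float
    dead_time: float
    voltage: float | None = None
    ok: bool = True
    reason: str | None = None

    def __len__(self) -> int:
        return int(self.states.size)

    def dwells_of(self, state: str = "open") -> np.ndarray:
        mask = self.states if state == "open" else ~self.states
        return self.dwells[mask]

    def amplitudes_of(self, state: str = "open") -> np.ndarray:
        mask = self.states if state == "open" else ~self.states
        return self.amplitudes[mask]

    @staticmethod
    def empty(reason: str, baseline: float = 0.0, dead_time: float = 0.0) -> "EventList":
        z = np.array([])
        return EventList(z.astype(bool), z, z, z, baseline, dead_time, ok=False, reason=reason)


def _histogram_modes(x: np.ndarray, min_fraction: float = 0.02):
    """Locate amplitude-histogram modes: (positions, counts), descending count.

    The all-points histogram is lightly smoothed (3-bin moving average)
    and padded with empty bins so modes at the extremes are still
    detected; modes smaller than ``min_fraction`` of the dominant one
    are ignored.
    """
    from scipy.signal import find_peaks

    n_bins = max(int(np.sqrt(x.size)), 20)
    counts, edges = np.histogram(x, bins=min(n_bins, 400))
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, props = find_peaks(padded, prominence=max(min_fraction * smooth.max(), 1.0), distance=3)
    peaks = peaks - 1
    order = np.argsort(smooth[peaks])[::-1]
    return centers[peaks][order], smooth[peaks][order]


class ChannelIdealizer(TransformerMixin, BaseEstimator):
    """Half-amplitude threshold idealizer for two-level traces.

    ``fit`` locates the baseline (dominant all-points-histogram mode)
    and the open level (the mode farthest-separated significant peak);
    ``transform`` segments the trace at the half-amplitude threshold
    and merges events shorter than the dead time into their
    neighbours.  Fitted attributes: ``baseline_``, ``open_level_``,
    ``threshold_``.

    Parameters
    ----------
    dead_time : seconds; None uses twice the trace's filter rise time.
    min_mode_fraction : secondary histogram modes below this fraction
        of the dominant mode are treated as noise.
    """

    def __init__(self, dead_time: float | None = None, min_mode_fraction: float = 0.02):
        self.dead_time = dead_time
        self.min_mode_fraction = min_mode_fraction

    def fit(self, X: CurrentTrace, y=None):
        modes, counts = _histogram_modes(X.current, self.min_mode_fraction)
        self.n_modes_ = len(modes)
        base = float(modes[0]) if len(modes) else float(np.median(X.current))
        if len(modes) >= 2:
            # open level candidate: the significant mode farthest from baseline
            others = modes[1:]
            open_c = float(others[np.argmax(np.abs(others - base))])
            # refine both levels as medians of their sample clusters and
            # require the separation to clear the baseline noise width
            mid = 0.5 * (base + open_c)
            lower = X.current < mid if open_c > base else X.current > mid
            base_samples = X.current[lower]
            open_samples = X.current[~lower]
            sigma_b = 1.4826 * np.median(np.abs(base_samples - np.median(base_samples)))
            if abs(open_c - base) > 4 * sigma_b and open_samples.size:
                self.baseline_ = float(np.median(base_samples))
                self.open_level_ = float(np.median(open_samples))
                self.threshold_ = 0.5 * (self.baseline_ + self.open_level_)
                return self
        self.baseline_ = base
        self.open_level_ = None
        self.threshold_ = None
        return self

    def transform(self, X: CurrentTrace) -> EventList:
        dead = X.dead_time() if self.dead_time is None else self.dead_time
        if self.open_level_ is None:
            return EventList.empty("unimodal_amplitude_histogram", self.baseline_, dead)
        fs = X.sampling_rate
        above = X.current > self.threshold_ if self.open_level_ > self.baseline_ else X.current < self.threshold_
        # run-length encode
        change = np.flatnonzero(np.diff(above.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [above.size]])
        lengths = np.diff(bounds)
        states = above[bounds[:-1]]
        # merge events below the dead time into their neighbours,
        # shortest first (standard missed-event convention)
        lengths = lengths.astype(np.int64).tolist()
        states = states.tolist()
        min_len = int(np.ceil(dead * fs))
        while len(lengths) > 1:
            i = int(np.argmin(lengths))
            if lengths[i] >= min_len:
                break
            if i == 0:
                lengths[1] += lengths[0]
                del lengths[0], states[0]
            elif i == len(lengths) - 1:
                lengths[-2] += lengths[-1]
                del lengths[-1], states[-1]
            else:
                lengths[i - 1] += lengths[i] + lengths[i + 1]
                del lengths[i : i + 2], states[i : i + 2]
        if len(lengths) == 1:
            return EventList.empty("no_resolvable_transitions", self.baseline_, dead)
        lengths = np.asarray(lengths)
        states = np.asarray(states, dtype=bool)
        starts = np.concatenate([[0], np.cumsum(lengths[:-1])])
        # per-event amplitude: mean over the event interior (trimming
        # filter-settling samples at the edges when the event is long enough)
        trim = 0
        if X.filter_cutoff:
            trim = int(round(fs * BESSEL_RISE_TIME_FACTOR / X.filter_cutoff))
        amps = np.empty(lengths.size)
        for j, (s, L) in enumerate(zip(starts, lengths)):
            a, b = s, s + L
            if L > 4 * trim:
                a, b = s + trim, s + L - trim
            amps[j] = np.mean(X.current[a:b]) - self.baseline_
        return EventList(
            states=states,
            starts=starts / fs,
            dwells=lengths / fs,
            amplitudes=amps,
            baseline=self.baseline_,
            dead_time=dead,
            voltage=X.voltage,
        )


def idealize(trace: CurrentTrace, dead_time: float | None = None) -> EventList:
    """Functional wrapper over :class:`ChannelIdealizer`."""
    ideal = ChannelIdealizer(dead_time=dead_time)
    return ideal.fit(trace).transform(trace)


@dataclass
class Chi2Result:
    statistic: float
    p_value: float
    dof: int


@dataclass
class ChannelStats:
    g_sc: float | None = None
    g_sc_sd: float | None = None
    tau: float | None = None
    tau_err: float | None = None
    n_amplitude_events: int = 0
    n_dwell_events: int = 0
    chi2_amplitude: Chi2Result | None = None
    chi2_dwell: Chi2Result | None = None
    accepted: bool = False
    ok: bool = True
    reason: str | None = None


def _pooled_chi2(observed: np.ndarray, expected: np.ndarray, n_fitted: int) -> Chi2Result:
    """Chi-square GOF with adjacent bins pooled to expected counts >= 5."""
    obs_p, exp_p = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= 5:
            obs_p.append(o_acc)
            exp_p.append(e_acc)
            o_acc = e_acc = 0.0
    if exp_p and e_acc > 0:
        obs_p[-1] += o_acc
        exp_p[-1] += e_acc
    obs_p, exp_p = np.asarray(obs_p), np.asarray(exp_p)
    if obs_p.size < n_fitted + 2:
        return Chi2Result(np.inf, 0.0, 0)
    stat = float(np.sum((obs_p - exp_p) ** 2 / exp_p))
    dof = int(obs_p.size - 1 - n_fitted)
    return Chi2Result(stat, float(sps.chi2.sf(stat, dof)), dof)


def conductance_stats(
    events: EventList, voltage: float | None = None, min_events: int = 1000
):
    """Single-channel conductance (pS) from open-event amplitudes.

    Per-event conductances |i|/|V| are binned (Freedman-Diaconis), the
    histogram peak fitted by a normal density; its mean and sd are the
    reported G_SC +/- sd.  Returns (g_sc, g_sc_sd, Chi2Result) packed
    in a :class:`ChannelStats`; an insufficient-data result carries a
    reason code instead.
    """
    V = events.voltage if voltage is None else voltage
    if V in (None, 0):
        raise DomainError("a nonzero voltage is required for conductance")
    amps = events.amplitudes_of("open")
    st = ChannelStats(n_amplitude_events=int(amps.size))
    if amps.size < min_events:
        st.ok = False
        st.reason = f"insufficient amplitude events ({amps.size} < {min_events})"
        return st
    g = np.abs(amps / V) * 1000.0  # pA/mV -> pS
    mu, sd = float(np.mean(g)), float(np.std(g, ddof=1))
    st.g_sc, st.g_sc_sd = mu, sd
    if sd == 0:
        st.chi2_amplitude = Chi2Result(0.0, 1.0, 0)
        st.accepted = True
        return st
    edges = np.histogram_bin_edges(g, bins="fd")
    obs, edges = np.histogram(g, bins=edges)
    cdf = sps.norm.cdf(edges, mu, sd)
    exp = np.diff(cdf) * g.size
    st.chi2_amplitude = _pooled_chi2(obs, exp, n_fitted=2)
    st.accepted = st.chi2_amplitude.p_value >= 0.05
    return st


def dwell_stats(
    events: EventList,
    state: str = "open",
    min_events: int = 1500,
    log_bins: bool = False,
):
    """Mean dwell time tau (s) of the chosen state.

    Point estimate: left-truncated-exponential maximum likelihood,
    tau_hat = mean(dwell) - dead_time (the naive mean is biased upward
    by exactly the dead time).  ``tau_err`` = tau_hat/sqrt(n).  The
    histogram chi-square against the truncated exponential serves
    acceptance only; ``log_bins`` switches to logarithmic dwell
    binning.
    """
    d = events.dwells_of(state)
    st = ChannelStats(n_dwell_events=int(d.size))
    if d.size < min_events:
        st.ok = False
        st.reason = f"insufficient dwell events ({d.size} < {min_events})"
        return st
    dead = events.dead_time
    tau = float(np.mean(d) - dead)
    if tau <= 0:
        st.ok = False
        st.reason = "mean dwell does not exceed dead time"
        return st
    st.tau = tau
    st.tau_err = tau / np.sqrt(d.size)
    if np.ptp(d) == 0:
        st.chi2_dwell = Chi2Result(np.inf, 0.0, 0)
        st.accepted = False
        return st
    if log_bins:
        lo = max(d.min(), dead if dead > 0 else d.min())
        edges = np.geomspace(max(lo, 1e-9), d.max() * (1 + 1e-9), 25)
    else:
        edges = np.histogram_bin_edges(d, bins="fd")
    obs, edges = np.histogram(d, bins=edges)
    # truncated exponential: P(X in bin | X > dead), renormalized to the
    # binned range so expected counts sum to n
    sf = np.exp(-np.clip(edges - dead, 0, None) / tau)
    exp = -np.diff(sf) / (sf[0] - sf[-1]) * d.size
    st.chi2_dwell = _pooled_chi2(obs, exp, n_fitted=1)
    st.accepted = st.chi2_dwell.p_value >= 0.05
    return st


def gv_curve(stats_by_voltage) -> "pd.DataFrame":
    """Ordered conductance-voltage table.

    ``stats_by_voltage``: iterable of (voltage_mV, g_sc_pS, g_sc_sd_pS)
    or (voltage, ChannelStats).  Requires >= 3 voltages spanning both
    signs.
    """
    import pandas as pd

    rows = []
    for item in stats_by_voltage:
        v, rest = item[0], item[1:]
        if len(rest) == 1 and isinstance(rest[0], ChannelStats):
            rows.append((v, rest[0].g_sc, rest[0].g_sc_sd))
        else:
            g, sd = rest if len(rest) == 2 else (rest[0], np.nan)
            rows.append((v, g, sd))
    df = pd.DataFrame(rows, columns=["voltage_mV", "g_sc_pS", "g_sc_sd_pS"]).sort_values(
        "voltage_mV", ignore_index=True
    )
    if df.shape[0] < 3 or df.voltage_mV.min() >= 0 or df.voltage_mV.max() <= 0:
        raise DomainError("G(V) needs >= 3 voltages spanning both signs")
    return df


def gv_shape_deviation(curve_a, curve_b) -> float:
    """Maximum relative deviation between two G(V) curves after
    amplitude normalization (least-squares scaling of b onto a).

    Zero for curves differing by a pure scale factor; used to check
    that a modifier changed channel amplitude without changing the
    G-V shape.
    """
    a = np.asarray(curve_a["g_sc_pS"], dtype=float)
    b = np.asarray(curve_b["g_sc_pS"], dtype=float)
    if a.shape != b.shape:
        raise DomainError("curves must share the same voltage grid")
    scale = float(np.dot(a, b) / np.dot(b, b))
    return float(np.max(np.abs(a - scale * b)) / np.max(np.abs(a)))


@dataclass
class MacroscopicResult:
    i_inf: float
    i_inf0: float
    ratio: float
    ratio_err: float


def macroscopic_ratio(
    before: CurrentTrace, after: CurrentTrace, window: tuple[float, float]
) -> MacroscopicResult:
    """Ratio of steady-state macroscopic currents after/before modifier.

    Both traces are averaged over the same time ``window`` (seconds);
    the ratio error is propagated from the window-mean standard
    errors.  Raises :class:`DomainError` when the window falls outside
    either trace.
    """
    t0, t1 = window
    if t0 >= t1:
        raise DomainError("window must satisfy t0 < t1")
    out = []
    for tr in (before, after):
        if t0 < 0 or t1 > tr.duration + 1e-12:
            raise DomainError(f"window [{t0}, {t1}] s outside trace of {tr.duration} s")
        i0 = int(round(t0 * tr.sampling_rate))
        i1 = int(round(t1 * tr.sampling_rate))
        seg = tr.current[i0:max(i1, i0 + 1)]
        out.append((float(np.mean(seg)), float(np.std(seg, ddof=1) / np.sqrt(seg.size)) if seg.size > 1 else 0.0))
    (i_inf0, se0), (i_inf, se1) = out
    if i_inf0 == 0:
        raise DomainError("before-trace steady-state current is zero")
    ratio = i_inf / i_inf0
    ratio_err = abs(ratio) * np.sqrt((se1 / i_inf) ** 2 + (se0 / i_inf0) ** 2) if i_inf != 0 else se1 / abs(i_inf0)
    return MacroscopicResult(i_inf=i_inf, i_inf0=i_inf0, ratio=ratio, ratio_err=float(ratio_err))
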