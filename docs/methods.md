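# Methods

This note records the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical decisions a maintainer would otherwise
have to reverse-engineer.

## Boundary potential and the Boltzmann stage

A neutral cation carrier (nonactin/K⁺) partitions into the membrane
according to the potential drop between bulk water and the hydrophobic
core, so the steady-state bilayer conductance reports interfacial
potential changes: Δφ = (kT/e)·ln(G_m/G_m⁰), with k and e taken from
scipy's CODATA constants and T defaulting to 298.15 K (room
temperature). At 25 °C an e-fold conductance ratio corresponds to
25.69 mV.

**Sign convention.** The pipeline reports *reductions* of the boundary
and dipole potentials as positive numbers (−Δφ_b, −Δφ_d), matching how
such data are tabulated and plotted: an increased cation-carrier
conductance is interpreted as a lowered interfacial barrier for
cations, i.e. a boundary-potential reduction. `boltzmann_delta_phi`
returns exactly (kT/e)·ln(G_m/G_m⁰); the convention is stated once in
the module docstring rather than scattered through the code.

## Langmuir adsorption fitting

Model: Δφ(C) = Δφ(∞)·C/(C+K), K in μM. Two methods:

* **nonlinear** (default): least squares on the isotherm directly,
  weighted by 1/sd² when per-point replicate standard deviations are
  available (small sds are floored at one third of the median sd so a
  lucky near-zero replicate spread cannot dominate). Parameter errors
  come from the Jacobian covariance scaled by the residual variance.
  Note that `run_study` leaves replicate-sd weighting *off* by
  default: with ~5 replicates the per-point sds carry only 4 degrees
  of freedom, and weighting by such noisy variance estimates
  measurably degrades K recovery. Enable it
  (`weight_by_replicate_sd`) for data with many replicates.
* **linearized** (validation mode): Δφ(∞)/Δφ(C) is linear in 1/C with
  slope K and unit intercept. Since Δφ(∞) is itself unknown, the
  regression is performed on the equivalent double-reciprocal form
  (1/Δφ on 1/C; K = slope/intercept, Δφ(∞) = 1/intercept); the
  intercept on the Δφ(∞)/Δφ scale is reported as a diagnostic that
  equals 1 when the algebra is consistent. Errors by the delta method.

Degenerate series (fewer than 3 nonzero concentrations, flat response,
no curvature) produce a result object with `ok=False` and a reason
code — never a silent number.

**Detectability floor.** Weak responders pose an identifiability
problem: when the response is essentially linear in C, the likelihood
is flat along the Δφ(∞)/K ridge and the unconstrained asymptote can
diverge to physically absurd values (thousands of mV with K far above
the measured range). `summarize_compound` therefore flags the
desorption constant "na" when either the fitted asymptote or the
largest *measured* shift is below a configurable floor (default
10 mV), and in the diverged case reports the observed maximum in place
of the asymptote. This mirrors the experimental practice of only
fitting isotherms for compounds with a distinguishable (>10 mV)
response.

## Dipole potential from dye ratios

The di-8-ANEPPS 420/520 nm excitation ratio R is mapped to φ_d shifts
linearly: Δφ_d = (R − R_ref)/slope. The numeric calibration (R_ref,
slope) is instrument- and protocol-specific and published separately
from the studies that use it, so it is *configuration*, not code; the
package default (R_ref = 1.0, slope = −0.005 /mV) is a placeholder of
realistic magnitude used by the simulator and must be replaced by a
measured calibration for real data. Downstream, Δφ_d(C) series go
through the identical Langmuir machinery to give −Δφ_d(max).

## DSC melting analysis

**Two-state van't Hoff model.** Excess heat capacity of one
transition: C_p(T) = ΔH_cal·(ΔH_vH/(RT²))·Θ(1−Θ) with
ln K_eq = −(ΔH_vH/R)(1/T − 1/T_m) and Θ = K_eq/(1+K_eq). Its area is
exactly ΔH_cal and its full width at half maximum is
FWHM = 2·ln(3+2√2)·R·T_m²/ΔH_vH ≈ 3.5255·R·T_m²/ΔH_vH (T in kelvin) —
both identities are exercised by tests. Temperatures are Celsius at
every interface and kelvin internally (offset 273.15).

**"Half-width" = FWHM.** The half-width T_1/2 is interpreted as the
full width at the half height of the main peak, everywhere. (The term
is occasionally used for the half-width at half height; one
interpretation is chosen and used consistently.)

**Baseline.** Polynomial baseline (default order 1) fitted by
iterative robust masking: fit on all points, exclude points more than
2.5 robust sigmas above the fit, repeat until stable. Two failure
signatures are checked — negative lobes comparable to the peak after
subtraction, and a no-exclusion fit whose residual is smooth structure
(lag-1 autocorrelation > 0.9) rather than noise — both of which mean a
peak occupies the whole scan and no flank exists to anchor a baseline.

**Features.** The main transition is the global maximum; its sub-grid
location comes from a least-squares parabola over the contiguous peak
cap (points above 90% of the apex), which averages per-point noise on
broad peaks and degrades gracefully to 3-point parabolic interpolation
on narrow ones. T_1/2 is found by linear interpolation of the
half-height crossings; enthalpy is the trapezoidal integral over the
contiguous region above a small floor. The pretransition is the most
prominent secondary peak at least 1 °C below T_m whose prominence
exceeds 3× the robust flank noise *and* whose height reaches 1% of the
main peak; absent such a peak the pretransition is reported abolished
(flagged, never coerced to a zero shift). The height floor exists
because across hundreds of candidate grid points isolated noise bumps
clear a 3-sigma prominence by chance, whereas a real gel→ripple
endotherm is several percent of the main peak.

**Deconvolution.** Sums of 1..max_components van't Hoff curves (or
Gaussians, as a sensitivity alternative) are fitted by bounded least
squares from systematically spread initial peak positions; the count
is selected by corrected AIC with the residual variance floored at
0.1% of the peak height. The floor acts as the instrument resolution:
on noiseless synthetic data a 2-component truth with 0.05 °C
separation is deliberately reported as one component (the data cannot
discriminate), while 2 °C separations are resolved cleanly.

**Shifts.** −ΔT_m = T_m(control) − T_m(treated) (positive when the
modifier melts the bilayer earlier), ΔT_1/2 = treated − control
(positive for broadening), ΔT_p downshift-positive and absent (not
zero) when the treated pretransition is abolished.

## Calcein leakage

RF(t) = 100·(I−I₀)/(I_max/0.9−I₀); the 0.9 accounts for dilution by
the detergent used for the 100% (full-lysis) reference. RF_max is
extracted by a mono-exponential plateau fit RF_max·(1−exp(−t/τ))
(default) or the mean of the final 10% of points ("endpoint"); the fit
falls back to the endpoint with a warning when it does not converge.
The default is the fit because with slow kinetics (τ ~ 30 min against
an 80 min record) the endpoint underestimates the plateau — a
Monte-Carlo comparison in the tests shows the fit's median error is
smaller. Noise-induced negative RF values are retained in the curve
(clipping would bias the fit); only the reported RF_max is floored at
zero.

## Single-channel analysis

**Idealization.** Half-amplitude threshold convention: the baseline is
the dominant mode of the all-points amplitude histogram, the open
level the farthest significant secondary mode, and transitions are
placed at crossings of their midpoint. Both levels are refined as
medians of their sample clusters (exact on noiseless data), and the
mode pair is accepted only if separated by more than 4 baseline noise
sigmas — otherwise the trace is reported unimodal with no events.
Events shorter than the dead time are merged into their neighbours,
shortest first; the dead time defaults to twice the filter rise time
T_r ≈ 0.3321/f_c (≈3.3 ms at 200 Hz). Because the baseline is defined
as the *dominant* mode, the convention assumes the channel is closed
more than half the time; traces from mostly-open channels would have
their states inverted and should be analysed with an explicit level
assignment. Per-event amplitudes are means over the event interior,
trimming one rise time at each edge when the event is long enough.

**Conductance.** G_SC = |i|/|V| per event (pA/mV → nS; reported in
pS), amplitude histogram with Freedman–Diaconis bins fitted by a
normal density; the χ² test pools adjacent bins to expected counts ≥5
and uses k−1−2 degrees of freedom.

**Dwell times.** For exponentially distributed dwells left-truncated
at the dead time d, E[X | X > d] = τ + d; the MLE is therefore
τ̂ = mean(dwell) − d, with standard error τ̂/√n. The histogram χ²
against the truncated exponential (optionally log-binned) serves
acceptance only — the MLE, not a histogram fit, is the point estimate,
because binned least squares is both less efficient and binning-
dependent. Measured calibration: the χ² rejects ~5.6% of
well-specified simulations at p<0.05. Dead-time *merging* (as opposed
to pure truncation) concatenates events across missed gaps and biases
τ̂ upward by roughly the fraction of opposite-state dwells shorter
than d; with d ≲ τ_other/30 this bias is a few percent.

**G(V) and macroscopic ratios.** G(V) tables require ≥3 voltages of
both signs; curve-shape comparison scales one curve onto the other by
least squares and reports the maximum relative deviation (zero for a
pure amplitude change — the "shape unchanged" check). I∞/I∞⁰ is the
ratio of windowed steady-state means with errors propagated from the
window-mean standard errors.

## Correlation screen

Pearson r with Fisher-transform CI: z = atanh(r),
z ± Φ⁻¹(1−α/2)/√(n−3), back-transformed; α defaults to 0.1 (the
"confidence level 0.1" convention = 90% coverage), with the plain
normal quantile and no small-sample t-adjustment, as in the classical
Fisher procedure. A pair is significant when the CI excludes zero.
Missing entries are pairwise-deleted, so n varies per cell; cells with
fewer than 4 overlapping compounds are marked not computable. Spearman
rank correlation (midranks for ties) confirms monotone association for
every cell except dipole-moment-vs-potential pairs, where a
parallel-plate-capacitor argument predicts a *linear* relation and a
rank statistic adds nothing. No multiple-testing correction is applied
(the screen is exploratory and reports CIs, not decisions).

Measured calibration (tests and acceptance script): 90% CI coverage
90±1% at n ∈ {7, 22}; type-I rate ≈ α under independence and under
permutation of the effect column.

## Synthetic-data generators

The generators emulate the *statistical structure* the analyses
assume, with known ground truth:

* **Gating**: exact exponential sojourns in a two-state Markov scheme
  simulated in continuous time, then sampled at 5 kHz — no
  discretization bias. `open_rate` is the closed→open transition rate
  (mean closed dwell 1/open_rate); `close_rate` governs the open
  state. White Gaussian noise (pA) is added at the digitizer rate
  *before* a causal 4-pole Bessel-type low-pass filter at 200 Hz,
  mimicking a patch-clamp acquisition chain.
* **Thermograms**: sums of van't Hoff components + polynomial baseline
  + white noise; the grid must span every component by ±3 FWHM.
* **Leakage**: mono-exponential RF kinetics inverted through the
  dilution-corrected normalization to raw intensities; noise on the
  intensity channel. (Only plateau values are typically published;
  the rise time is a free fixture parameter.)
* **Adsorption**: Langmuir shifts plus the equivalent Boltzmann
  conductance ratios computed from the *noisy* shifts, so the
  conversion stage round-trips to machine precision.
* **Dye ratios**: R(C) = R_ref + slope·Δφ_d(C) with noise of
  |slope|·noise_sd so the recovered shifts carry the stated mV-scale
  noise.

Not emulated: multi-state or voltage-dependent gating, correlated
(1/f) noise, membrane drift, heating/cooling hysteresis, vesicle
size distributions, photobleaching. Passing tests therefore
demonstrate correctness of the estimators under the stated models, not
robustness to every instrument artifact.

**Noise defaults** (instrument amplitudes are rarely published; these
were chosen once as realistic and are fixture conventions, documented
rather than inferred): adsorption 2 mV per point with 5 replicate
bilayers averaged per concentration (protocols average 3–11
membranes); DSC 0.1% of the control main-peak height (microcalorimeter
scans are smooth at 0.2 °C/min); leakage 1% of the lysis dynamic
range; channel noise 0.5 pA before filtering (SNR ≈ 30 after the
200 Hz filter for a 4.5 pA channel); macroscopic current noise 5%.

## Study orchestration

`run_study` derives every stage seed from the single study seed via a
CRC-based label hash (`derive_seed(seed, compound, stage, ...)`), so
any number in the report is reproducible from config + seed with no
shared global RNG state. Stage failures are recorded per compound and
the run continues. The reference 3-compound configuration pairs a
strong modifier (saturation 118 mV, K 32 μM, −ΔT_m 4.8 °C, RF_max
57%), a moderate one (51 mV, 79 μM, 2.9 °C, 31%) and an inert one
(4 mV, no DSC/leakage effect); channel truth uses 20–50 pS
conductances with open dwells of 100–300 ms and closed dwells about
twice as long, in 600 s traces — long enough that τ̂ carries ~3%
sampling error against the 10% recovery tolerance, and closed-dominant
so the all-points histogram convention holds. Dwell times around 1 ms,
though physiologically possible for strongly inhibited channels, fall
below the 200 Hz-filter dead time (~3.3 ms) and cannot be idealized by
any half-amplitude detector; they are excluded from generator truth.

`recovery_summary` audits each run against tolerances of 10%
(−Δφ_b(max)), 15% (K), 0.1 °C (−ΔT_m and ΔT_1/2), 3 points (RF_max),
5% (G_SC), 10% (τ) and 10% (I∞/I∞⁰); for compounds whose true shift is
below the detectability floor the electrostatics check is the na
classification itself. Measured: ≥90% of 50 seeded runs pass all
checks (typically 96%).

## Problem sizes

Defaults were sized for complete statistical coverage at desk scale:
DSC grids of ~1400 points at 0.02 °C; 9-concentration isotherms with 5
replicates; 600 s channel traces at 5 kHz (≈1500–4000 events);
1000–2000 events for conductance/dwell estimation; 2000-replicate
calibration Monte Carlos; 50-seed end-to-end audits. The full test
suite runs in ~2 minutes and the acceptance script in ~2 minutes on
one CPU.

## Known limitations

* Single two-state channel per trace; no superposition of multiple
  channels, burst analysis, or hidden-Markov idealization.
* The idealizer's dominant-mode baseline assumes closed-dominant
  records (see above).
* The Langmuir model is first-order adsorption; cooperative or
  multi-site binding will show as lack of fit, not as a warning.
* Deconvolution component counts depend on the assumed component
  family (van't Hoff vs Gaussian) near the resolution limit;
  equivalence with any particular commercial package's counts is not
  claimed.
* The dye calibration default is a placeholder; absolute −Δφ_d values
  from real data require a measured calibration.
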