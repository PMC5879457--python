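# Methods

## The model

`fotmech` analyses respiratory input impedance measured by the forced
oscillation technique (FOT): a ventilator superimposes small flow
oscillations at a discrete set of frequencies, and the complex ratio of
airway-opening pressure to flow, Z(f) = P(f)/V̇(f), characterises the
mechanical state of the lung. The real part of Z is the resistance
spectrum R_L(f); the imaginary part carries the elastic reactance, from
which the elastance spectrum is recovered as E_L(f) = −2πf · Im Z(f)
(sign convention: elastic reactance negative, Z = R_L − i·E_L/2πf).

Both spectra are summarised by a heterogeneous lung-function
parameterisation:

    R_L(f) = (a + b·f) / (c + f)
    E_L(f) = E0 + ΔE · (1 − e^{−β·f})

with f in Hz throughout (so β is in 1/Hz). Five physiology summaries are
reported from the fits: the inherent tissue stiffness E0 (cmH2O/mL), the
low-frequency resistance a/c = R_L(0) (cmH2O·s/mL), the high-frequency
resistance asymptote b, the magnitude of change in elastance ΔE, and the
rate of change of elastance β. Low-frequency behaviour (a/c, E0, β)
reflects the parenchyma; the high-frequency limit b reflects the conducting
airways. The model contains no inertance term; real data at frequencies
where gas inertia matters (tens of Hz in mice) would need one, and the
synthetic generator deliberately stays inside the model class.

## Synthetic studies

No raw animal data accompany this problem, so the package ships a
first-class generator that emulates the study design end to end:

* **Design.** Factorial roster treatment × dose × day × PEEP × animal.
  Defaults mirror the in-vivo layout: treatments HBSS (vehicle control),
  carbon black, silver nanoparticles, silver nitrate; doses 0.05 and
  0.5 μg particle/g body weight; days 1, 3, 7 post-instillation; PEEP 0,
  1, 3, 6 cmH2O; 4–6 animals per group (default 5).
* **Ground truth.** Each animal draws MechParams =
  base × group shift × lognormal noise. The lognormal has geometric mean
  exactly 1 and log-sd √log(1+cv²); cv defaults to 0.15, chosen as a
  typical between-animal spread for murine mechanics while keeping all
  parameters positive. The base point (a=2, b=0.2, c=5, E0=20, ΔE=10,
  β=0.5 in the units above) is a plausible mouse-scale configuration, not
  a physiological claim.
* **Effect template.** Group-level multiplicative shifts encode the
  qualitative treatment time-course: acute (day-1) AgNP stiffening
  (E0 ×1.3 high dose, ×1.25 low), no CB mechanics effect at any time,
  day-7 AgNP decrease of E0 and a/c (×0.7 each), CB neutrophilia at days
  1–3, day-3 AgNP lymphocyte influx with a 60-fold IL10 burst, day-7
  residual CCL2 elevation (6-fold AgNP, 1.8-fold CB). The control row of
  the template is pinned to 1 by a type invariant.
* **Waveforms.** Flow is a multi-sine over 13 mutually prime multiples of
  0.5 Hz spanning 0.5–20.5 Hz (so every tone completes whole cycles over
  any multiple of the 2 s fundamental period and the sinusoid regressors
  are orthogonal), 8 s at 256 Hz by default. Pressure is PEEP plus each
  tone scaled by |Z(f)| and shifted by arg Z(f), plus Gaussian sensor
  noise (default sd 0.05 cmH2O). The true perturbation recipe of
  commercial ventilators is proprietary; amplitudes (1 mL/s per tone) and
  random phases are declared defaults, not reconstructions.
* **qPCR.** One pooled sample per group and gene (no within-group
  replicates, matching the pooling protocol): CT_target =
  base_CT − log2(true fold) + noise against a flat reference gene.
  Amplification efficiency is fixed at 2 (classic ΔΔCT); the reference
  gene is an explicit schema column.
* **BAL differentials.** Multinomial draws of ~200 scored cells per
  animal over macrophage/neutrophil/lymphocyte/eosinophil.

What the generator does *not* emulate: gas compression, equipment
(tubing) impedance, nonlinear airway mechanics, PEEP-dependence of the
mechanics, within-animal correlation of repeated PEEP measurements, and
qPCR efficiency deviations. Passing tests therefore demonstrate that the
estimation and statistics machinery is correct *within the model class*,
not that the model class describes any particular lung.

## Impedance estimation

Because the perturbation is a known tone set, Z is estimated per
frequency by least-squares regression of each signal on [cos, sin, 1]
over an integer number of fundamental cycles (leading 1 s discarded as
transient). On integer-cycle records this is algebraically identical to
reading the FFT bin; the FFT path is kept as an independent oracle in the
tests, with agreement required at 1e−9 relative. Tones whose flow
coefficient magnitude falls below a floor (default 1e−6 mL/s) are flagged
invalid rather than divided out.

Quality control is a segment-averaged magnitude-squared coherence between
pressure and flow (≥4 segments, 50% overlap). Segments are whole
fundamental periods with rectangular windows whenever they fit, which
makes the estimate leakage-free at the tone frequencies (a noiseless
record scores exactly 1); otherwise a Hann-windowed power-of-two segment
length is used. Frequencies below the coherence threshold (default 0.9)
are dropped before fitting.

## Fitting

R and E are fitted separately (the two equations share no parameters) by
bounded nonlinear least squares (scipy trust-region reflective, analytic
Jacobians, unweighted — no weighting scheme is part of the protocol).
Initialisation is data-driven: b₀ = R_L(f_max), (a/c)₀ = R_L(f_min),
c₀ = median frequency, a₀ = (a/c)₀·c₀; E0₀ = E_L(f_min),
ΔE₀ = E_L(f_max) − E0₀, β₀ = 1/f_median. Five log-perturbed restarts
(fixed internal seed, so identical spectra always give identical fits)
guard against local minima; lowest rss wins, ties broken by smaller
parameter norm. Tolerances 1e−12 (ftol/xtol/gtol), max 500 evaluations
per start.

Degenerate geometries are reported, not hidden: a constant resistance
spectrum (a = b·c) identifies only the ratio a/c = b, a flat elastance
spectrum leaves β meaningless (|ΔE| < 1e−6·E0 triggers a warning), and β
far above 1/f_min pushes the exponential below the first measured
frequency so only the plateau E0+ΔE is identified. These all surface as
`condition_warnings` via a Jacobian curvature test ((s_min/s_max)² <
1e−8). Recovery benchmarks keep a/c away from b for the same reason — on
the ridge the individual parameters are mathematically undefined.

## Bootstrap intervals

Per-spectrum uncertainty uses a residual bootstrap: leverage-studentised
recentred residuals (r_i/√(1−h_ii), the standard correction for the
downward bias of fitted residuals) are resampled onto the fitted curve
and each replicate refitted from the parent estimate. Interval endpoints
use expanded percentile levels: the nominal z quantile is replaced by
t_{n−p}·√(n/(n−p)) and the percentile levels set to its normal tail
areas, compensating for the noise of the residual-variance estimate at
n−p ≈ 10 degrees of freedom. With plain 2.5/97.5 percentiles the nominal
95% interval for a/c covers the truth in only ≈89% of replicates at
spectrum sizes of 13; with the studentised/expanded construction the
coverage audit (analysis/05) lands near 95%. Refit failures are tolerated
up to 20% of replicates, then the bootstrap aborts.

## Group statistics

* **Two-way ANOVA** (dose × particle, or treatment × PEEP), fixed effects
  with interaction. Balanced designs use closed-form cell-means sums of
  squares (exactly conserving SS_total); unbalanced designs (n = 4–6)
  use Type II SS, appropriate when no interaction is emphasised a priori.
  The all-observations-equal case is reported as a no-variance result
  (NaN F) rather than a division by zero.
* **Protected t-tests** implement Fisher's protected LSD: pairwise
  two-sample t-tests on the pooled residual mean square and residual df,
  counted significant only when the omnibus F for that factor is
  significant. The gate, not a multiplicity adjustment, is the protection.
* **Holm-Sidak**: step-down adjustment 1−(1−p_(i))^(m−i+1) with enforced
  monotonicity, clamped at 1, decisions by step-down comparison to α.
* **compare_parameters** runs, per reported parameter, the
  treatment × PEEP ANOVA plus Holm-Sidak-adjusted pairwise treatment
  t-tests at a fixed PEEP (default 3 cmH2O, where spectra are customarily
  compared). The pairwise tests pool the within-cell variance at that
  PEEP (df = t(n−1)) rather than the full-model residual MS: each
  animal's parameters are shared across PEEP levels, so the full-model
  residual df would overstate the information in the variance estimate
  and inflate the family-wise error. Analyses run per day by default.

Statistical calibration (analysis/04 and the acceptance script) is run on
parameter-level simulated studies (`simulate_fit_table`: lognormal
between-animal variation plus 2% lognormal per-measurement noise standing
in for estimation error). Hundreds of studies are needed there, and the
waveform → impedance → fit chain — audited separately at numerical
precision — would add cost but no information to the question being
asked of the statistics. Observed calibration: pooled family-wise
rejection ≈ 4% under the null; day-7 AgNP detection ≈ 100% for E0 and
≈ 92% for a/c (a/c is noisier because the ratio compounds the spread of
a and c). Acute day-1 stiffening (×1.3, n = 5, cv = 0.15) is only
moderately powered, and any individual simulated study may legitimately
miss some of the true effects; the calibration drivers, not single runs,
are the statement about the procedure.

## BAL quantifications

ΔΔCT fold expression (fold = 2^−ΔΔCT normalised to the control group,
efficiency 2), differential proportions with group means/SDs,
SP-D/SP-B densitometry ratios normalised to the control mean, and the
capillary-surfactometer percent-open metric (100 × open time / 120 s).
Pooled qPCR samples carry no replicates, so no inference is attached to
fold changes.

## Problem sizes

Default demo study: 3 treatments × 1 dose × 3 days × 5 animals × 4 PEEPs
= 180 records of 8 s at 256 Hz. Calibration: 200 simulated studies per
condition. Bootstrap audit: 500 replicates × 300 bootstrap draws.
Recovery grid: 3 × 3 over (a/c, E0).
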