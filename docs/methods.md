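# Methods

## Signal model

A trapped ion shuttling through the ELIT detector tube induces a
rectangular charge waveform: plateau `gain * z` for the fraction of each
oscillation period spent inside the tube (the duty cycle *d*), zero outside.
Its Fourier series has DC level `gain*z*d` and harmonic amplitudes

    A_n = gain * z * 2|sin(n π d)| / (n π),   n = 1, 2, ...

The simulator synthesizes this waveform band-limited — a truncated Fourier
series (default 16 harmonics, always below Nyquist) — rather than as a
hard-thresholded pulse train.  Sampling hard edges at a rate commensurate
with the oscillation frequency would alias harmonics near `fs` back onto the
fitted ones (an effect a real anti-aliased preamplifier chain does not
produce), biasing amplitudes by ~1%.  White Gaussian noise of RMS
`noise_rms` is added per sample.  For an ion losing mass at rate *r* the
instantaneous frequency follows `f(t) = sqrt(C z / (m0 − r t))` via the
calibration law, and the phase is integrated numerically.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| sample rate | 1 MHz | standard digitizer rate for kHz-band ELIT signals |
| trap event | 500 ms | full single-ion event; tests may shorten to 100–200 ms |
| segment / hop | 25 ms / 5 ms | frequency resolution 40 Hz with 5× overlap |
| calibration C | 2.9879e12 Th·Hz² | places a 4.93 MDa, 165 e ion at 10.000 kHz, all species in 5–25 kHz |
| duty cycle | 0.45 | harmonics 2–4 nonvanishing so all four can be fitted |
| gain | 1 amplitude unit / e | free scale |
| noise_rms | 300 | gives per-segment charge SD ≈ 4 e and full-trap per-ion SD ≈ 1 e — typical CDMS single-ion precision |

On the noise calibration: 25 ms segments at a 5 ms hop overlap fivefold, so
a 500 ms trap contains ~20 statistically independent segments, not 96.  The
noise default is therefore set by the full-trap target (per-ion charge SD
≈ 1 e, measured 0.9–1.1 e across the charge range of interest), and the
resulting single-segment SD is ≈ 4 e.

## Frequency and amplitude estimation

Each trace is cut into rectangular (unapodized) STFT segments, left-aligned,
discarding the final partial window: `floor((trap−segment)/step)+1`
segments.  Per segment:

1. **Candidate fundamental** — the strongest peak of the trace-averaged
   spectrum (above 5× the median spectral amplitude) whose 2nd–4th harmonic
   region also shows energy in the single strongest segment (>2.5× that
   row's noise floor).  Harmonic corroboration is the classic guard against
   calling a harmonic the fundamental; remaining ties break toward the lower
   frequency.  Corroboration uses a single segment rather than the average
   because in-trap frequency drift smears harmonics of the averaged spectrum
   across bins while leaving them sharp within one 25 ms window.
2. **Grid-free refinement** — for a rectangular window the complex-bin
   interpolator `δ = −Re[(X[k+1]−X[k−1])/(2X[k]−X[k+1]−X[k−1])]` recovers
   the fractional bin offset of a sinusoid exactly in the noiseless limit.
   It is applied at the fundamental and at each harmonic; the per-segment
   fundamental is then the weighted least-squares solution of
   `f_n ≈ n f0` with weights `(n A_n)²` (inverse frequency variances).
   This frequency-domain least squares is the stationary point of fitting
   `Σ A_n cos(2π n f0 t + φ_n)` to the segment with free per-harmonic
   phases (rectangular windows destroy phase coherence at segment edges, so
   phases are never locked across harmonics or segments).
3. **Amplitudes** — peak-bin magnitudes divided by the Dirichlet-kernel
   attenuation `sin(πδ)/(N sin(πδ/N))`, then Rician-debiased by subtracting
   the first-order noise term `2σ_noise²` in quadrature (weak harmonics
   otherwise read ~0.2 amplitude units high; the per-row noise scale is the
   Rayleigh median of the spectrum).  Segment mean removal eliminates DC
   leakage exactly.

Per ion: medians (not means) of `f0` and the four harmonic amplitudes over
converged segments, robust to single-segment misfits; charge by weighted
least squares of the median amplitudes against the waveform pattern;
`m/z = C/f0²`; `mass = (m/z)·z`.  An ion with no converged segment is
dropped with a log record; <80% segment convergence flags UNSTABLE; traces
shorter than one segment flag SHORT_TRAP.

**Mass-change detection.**  The reported drift is the OLS slope of segment
`f0` versus time.  Because overlapping windows correlate the segment noise
(the naive OLS slope SE would be ~√5 too small), significance is tested on
a stride-decimated subset (every 5th converged fit, effectively independent):
flag MASS_CHANGE when `|slope| > 3·SE + 0.1 Hz/s` (the absolute floor guards
the numerically-noiseless case).  At default noise this flags a constant-
frequency ion in well under 1% of events, while an ion losing ~319 kDa/s of
water at 5.1 MDa (the evaporation rate measured for bare aqueous nanodrops
of that size) drifts ~150 Hz over the trap and is flagged essentially
always — so an unflagged ensemble is a substantive "no detectable mass
loss" null result.

Measured end-to-end precision at defaults (500 ms traps): per-ion charge SD
0.9–1.1 e, relative m/z jitter ~1.5e-5, mass SD ~0.6%, charge bias within
±0.2 e.  `emulate_measurements` applies exactly these calibrated errors to
ground-truth ions without waveform synthesis; it is used for the large
(n = 5,000–20,000) population-level analyses where the waveform path adds
only runtime, while the waveform path itself is validated on hundreds of
full traces.

## Capsid mass accounting

Masses are exactly additive:
`multiplicity·(Σ vp_counts·vp_masses + cargo) + adducts + n_ligand·ligand`.
VP masses default to the rounded literature values (83.5 / 68.6 / 62.0 kDa);
with the 1:1:10 stoichiometry resolved to (5, 5, 50) by largest-remainder
rounding (ties toward VP3 — the only scheme mapping every permutation of
1:1:10 onto the canonical counts) and a 1.05 MDa CMV-GFP cargo this gives
4.9105 MDa for the full capsid and 3.8605 MDa for the bare shell.  The
VP3-only VLP registry entry computes to 4.560 MDa from these inputs; the
commonly quoted 4.54 MDa for that particle evidently used unrounded subunit
masses, and the discrepancy is documented rather than absorbed into the
inputs.  Nonvolatile-salt adduction is a single lump-sum offset because only
aggregate mass shifts (+0.38/+0.42 MDa in PBS) are observable.

## Rayleigh limit

`diameter_from_charge`, `charge_from_diameter` and `rayleigh_charge_for_mass`
implement the Rayleigh limit of a spherical aqueous droplet with
ε₀ = 8.8542e-12 F/m, γ = 0.0720 N/m, ρ = 1000 kg/m³.  γ is chosen because it
reproduces the 165 e ↔ 24.0 nm and 170 e ↔ 24.5 nm anchor pairs; charges are
real-valued throughout and rounded only for presentation.  The "Rayleigh
line" overlaid on 2D mass/charge histograms is `z_R(m)` at unit density.

## Scenario presets

Presets encode the observed phenomenology as mixtures of components; where
component weights and widths are not reported they are package defaults
(σ 3–5 e, equal or stated weights) and remain free parameters:

- `aa_neutral` — one species at 4.93 MDa (calculated mass plus residual
  adducts), charge 165 e (σ 4, w 0.85) with a 150 e shoulder (σ 5, w 0.15);
- `pbs_neutral` / `vlp_pbs` / `pbs_ph4_37c` — salt-adducted masses
  (+0.38/+0.42 MDa) with 7 / 5 / 6 equal-weight conformer peaks at the
  respective fitted centroids;
- `aa_ph4_37c` — intact capsids (w 0.55) plus a 1–12 MDa fragment continuum
  charged at 82–100% of the Rayleigh limit (w 0.30), capsid dimers at twice
  the intact mass charged at 98–106% of the limit (w 0.08), and protein
  aggregates 0.3–1.2 MDa above the intact mass (w 0.07);
- `freeze_thaw` — 16% degraded (13:3 fragment continuum : aggregates),
  <2% empty capsids, remainder intact;
- `nuclease` — 0–20 bound 34 kDa enzymes (discrete uniform), charge
  `160 − (40/15)·n ± 3` e (the linear binding trend from ~160 e unbound to
  ~120 e at 15 bound), plus a 3% off-trend cluster at (5.0 MDa, 100 e).

Ground-truth labels for continuum components are assigned by the same
mass/charge region rules the classifier uses (a continuum ion above the
intact mass *is* an aggregate-region ion).  Classifier-vs-truth agreement
scores therefore measure recovery under measurement noise and gate-boundary
effects, not an independent re-derivation of the taxonomy — they validate
the measurement chain, not the biology.  The generator emulates: ensemble
heterogeneity, conformer charge structure, Rayleigh-band fragment charging,
adduction as a mean shift, and in-trap mass loss.  It does not emulate:
discrete charge-state ladders (conformer distributions are continuous),
multi-ion trap events, ion-energy/trajectory physics, ESI droplet
chemistry, or non-Gaussian noise — so passing tests demonstrate correctness
of the analysis chain under the stated noise model, not instrument fidelity.

## Mixture decomposition

Charge (and mass) histograms are decomposed by non-linear least squares of
`Σ area_j·N(x; c_j, σ_j)` against the binned counts (the field's standard
reporting route; not per-ion maximum likelihood), with analytic Jacobian,
non-negative areas, and σ bounded to [bin_width/2, span/2] to prevent
collapse (with 1 e bins the floor is 0.5 e).  Initial centroids come from
local maxima of the 3-bin-smoothed counts (user-suppliable; quantile
fill-in when fewer maxima than components).  Unweighted residuals by
default, Poisson weighting (`1/sqrt(y+1)`) by flag.  `k="auto"` fits k=1..8
and minimizes BIC; because per-bin count variances are strongly
count-dependent, selection always runs on Poisson-weighted fits, where the
weighted RSS is the χ² statistic and `BIC = χ² + 3k·ln(n_bins)`; the
smallest k within ΔBIC ≤ 2 of the minimum wins (parsimony rule) and the
chosen k is refitted with the user's weighting.  Components are reported in
descending-centroid order.  Non-convergence returns best-so-far parameters
with the flag down.  `centroid()` is the k=1 special case, falling back to
the count-weighted mean (flagged) when the fit fails or R² < 0.8.

## Population gates

Classification precedence DIMER > INTACT_FULL > EMPTY > AGGREGATE >
FRAGMENT, with defaults: intact window ±5% of the expected full mass, empty
window ±2%, dimer window ±4% of twice the full mass, FRAGMENT requiring
mass < 0.93× full *and* charge within 0.80–1.02 of `z_R(m)`, AGGREGATE any
non-dimer mass >250 kDa above full.  The 0.93 ceiling excludes the intact
tail (intact mass SD ≈ 1.5% at default noise); the gates themselves are
package conventions — the underlying experiments classify visually from 2D
histograms — and are fully exposed in the run config.  Bound-ligand counts
round the mass increment over the unbound capsid to the nearest integer
(negative → 0); the binding slope is OLS of charge on the estimated count.
Estimating the count from measured mass attenuates the OLS slope slightly
(regression dilution, ~4% at default precision); the reported slope is the
estimator's honest output, not corrected.

## Problem sizes

Full-scale checks: 200 × 500 ms traces for STFT recovery, n = 20,000 for
the 7-component mixture, n = 5,000–10,000 (measurement emulator) for the
population analyses.  Unit tests run reduced sizes chosen to keep the suite
under a minute — 100–200 ms traps, 30–60 ions, 30–40 seeds for selection/
goodness-of-fit properties — with tolerances widened in proportion to the
reduced statistics.

## Known limitations

- The calibration law and constant C are package conventions (real
  instruments calibrate empirically); all mass results are conditional on it.
- Harmonic amplitudes are estimated from peak bins, so cross-harmonic
  spectral leakage (~0.1% of the fundamental) survives; it cancels in
  ensemble means but contributes to per-ion scatter.
- The drift test assumes a linear frequency ramp over the trap; strongly
  non-linear mass loss would be flagged but its rate misestimated.
- Gaussian mixture fits with heavily overlapping components (Δc < 2σ) are
  not identifiable from binned counts; `k="auto"` will merge them.
- Classification near gate boundaries is decided by the measured point;
  no probabilistic soft assignment is attempted.
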