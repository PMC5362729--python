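# Methods

This note documents the models implemented in `lspsmap`, the synthetic
data they are validated against, the numerical choices made where the
procedure left room, and what the passing test suite does and does not
establish about real recordings.

## The generative circuit model

`synthdata.simulate_circuit` scatters interneuron somata as a 2-D spatial
Poisson process over a rectangular field centered on the recorded
(target) pyramidal cell, in slice coordinates (µm; +x along the layer,
+y depth from the pia — the orientation is a bookkeeping convention and
does not enter any statistic). Each soma at distance *d* from the target
is connected with probability

    p(d) = connect_prob0 · exp(−d / connect_lambda)

and, if connected, contributes a fixed evoked-IPSC peak amplitude drawn
from |N(strength_mean, strength_sd)|. Somata within `close_in_radius` of
the target have their strength multiplied by `close_in_gain`; a gain
above 1 models selectively strengthened perisomatic (basket-type)
inhibition, the phenotype the two-cohort experiment is designed to
detect.

A light flash at a grid site fires every connected interneuron whose
soma lies within `activation_radius` of the spot. Each activated cell
emits one presynaptic spike (optionally a short burst), producing an
inward IPSC — a peak-normalized difference of exponentials,
exp(−t/τ_decay) − exp(−t/τ_rise) — at flash + latency, with latency
drawn per event from N(latency_mean, latency_sd). Spontaneous IPSCs
arrive as a homogeneous Poisson process over the whole trace with
amplitudes from the same distribution (no close-in gain), and white
Gaussian noise is added last. Traces run from −100 ms to +300 ms around
the flash at 10 kHz. Every generator is a pure function of
(config, seed); ground-truth event times and amplitudes are recorded
per trace, which is what makes detector precision/recall measurable.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `interneuron_density` | 6000 / mm² | effective areal density of photoexcitable GABAergic somata: ~1.7×10⁴ VGAT⁺ neurons/mm³ integrated across a 350-µm slice, treating the full slice depth as excitable by single-photon stimulation |
| `connect_prob0`, `connect_lambda` | 0.9, 110 µm | dense local inhibitory innervation near the soma; the 110-µm decay length matches the ~100–120 µm space constant over which mapped inhibitory input falls off |
| `activation_radius` | 50 µm | with a ~50 µm (1/e²) spot, interneurons fire when the flash lands on or immediately adjacent to the soma — in mapping experiments spikes are evoked from one or two grid sites at 50-µm spacing |
| `strength_mean`, `strength_sd` | 60 ± 15 pA | unitary evoked IPSC peaks at high-chloride driving force |
| `tau_rise`, `tau_decay` | 1, 15 ms | the stereotypical fast-rise/slow-decay IPSC shape |
| `latency_mean`, `latency_sd` | 17 ± 2 ms | evoked IPSC onsets cluster 10–25 ms after the flash (interneuron spike latency plus synaptic delay). The mean is placed so that even compound events — whose onset is the *minimum* of many per-cell latencies — stay inside the 10–40 ms post-stimulus analysis window |
| `spont_rate` | 8 Hz | typical spontaneous IPSC rates in cortical pyramidal cells with high-Cl internals; spontaneous activity is also what gives the across-spot baseline-charge SD (the Z-score normalizer) a realistic, event-dominated value |
| `noise_sd` | 2 pA | recording noise floor after 10 kHz downsampling |

These defaults produce maps that are dense near the soma (tens of
convergent inhibitory inputs to one pyramidal cell), with input falling
off over ~100–200 µm and occasional spontaneous events far away. They
were fixed at design time, before the acceptance suite was written, from
a power analysis of the prescribed two-cohort comparison (close-in gain
1.5 vs 1.0, 12 vs 9 cells, 3 map repetitions): with sparser circuits the
Poisson variability of the handful of presynaptic cells under the soma
site dominates the between-cell variance and no analysis, however
correct, could resolve a 1.5× strengthening in cohorts of this size.

What the simulator deliberately omits: conductance-based membrane
dynamics, ChR2 photocurrent kinetics, light scattering and depth
attenuation, short-term plasticity, and correlated network activity.
Passing tests therefore establish that the *analysis* is correct and
calibrated under the stated statistical structure — not that real tissue
satisfies that structure.

## Event detection

Traces are low-pass filtered with a 4-pole Butterworth at 1 kHz applied
forward–backward (zero phase) and detrended by subtracting a running
median with a 1-s window (computed on a decimated copy and linearly
interpolated back; at these time scales the approximation is
indistinguishable from the exact running median).

**Exponential deconvolution.** The sign-flipped trace is divided in the
frequency domain by the spectrum of the unit IPSC kernel, with Wiener
regularization: D = F⁻¹[X·conj(K) / (|K|² + ε²)], ε = 1% of the kernel's
spectral peak. Each IPSC becomes a quasi-delta at its onset, so events
superimposed on the decay of earlier ones are resolved. Detection
threshold: `threshold_k` (default 4) × robust SD (1.4826·MAD) of the
deconvolved trace; on noiseless traces, where the MAD of a sparse delta
series vanishes, the plain SD is used instead. Supra-threshold samples
are grouped with a 3-ms merge window; the deconvolved peak of each group
is the event onset (the deconvolution maps a kernel starting at t₀ onto
a delta at t₀, so the peak — not the threshold crossing, which sits on
the regularized delta's shoulder — is the onset estimator).

**Template matching.** A sliding optimal-scaling fit of a 10·τ_decay
template with free scale and offset; the detection criterion is
scale / SE-of-fit with default threshold θ = 3. One event is taken per
contiguous supra-threshold region of the criterion (gaps shorter than
the refractory period merged), at the region's criterion maximum —
plain local-maximum selection produces spurious secondary detections on
the broad criterion hump around each event. A floor on the fit SE keeps
the criterion finite where a noiseless template fit is exact. Because
the fitted window spans the full template, events need clear space:
within ~150 ms of a neighboring event the fit SE is inflated and
sensitivity drops. At spontaneous-like densities (2 Hz, SNR 10) both
detectors exceed 0.9 precision and recall; the deconvolution detector is
the default in the map pipeline.

Events are measured on the original trace: peak = max |baseline-
subtracted current| over 30 ms from onset (local baseline: mean of the
2 ms preceding the onset), charge = ∫|I| dt over the same window
(1 pA·s = 1 pC).

## Map statistics

Charge transfer is integrated over three 30-ms windows relative to the
flash at 0 ms — baseline (−40, −10), pre-stimulus control (−70, −40),
post-stimulus (10, 40) — after subtracting each trace's holding current
(mean of (−100, −70) ms). The Z scores standardize each spot's post (or
pre-control) charge by the mean and SD (ddof = 1) of the baseline
charge across all spots of the same repetition. Charges entering the Z
statistic are **signed** (inward events negative): under a silent
circuit the signed charge integral is Gaussian and |Z| > 2.575 fires at
its nominal 1%, which the acceptance suite verifies over 20 simulated
maps of ~470 sites; with magnitude charges the null would be folded
Gaussian and the false-positive rate nearly doubles. Evoked inhibitory
input drives Z strongly *negative*; cohort comparisons are therefore run
on the response magnitude (−Z).

First-event amplitude and charge are taken from the earliest detected
event with onset inside the 10–40 ms window, computed only at spots
classified evoked; pre-flash events never contribute. The broader
charge measure integrates (0, 150) ms post-flash. Response probability
per site is the fraction of repetitions classified evoked (a 0/1 map
for single repetitions). Within a cell, measures are averaged across
repetitions (first-event fields over the repetitions where defined);
across cells, maps are accumulated soma-centered onto a square grid
(default 50 µm bins, nearest-bin assignment, empty bins flagged missing
rather than zero) or collapsed into radial profiles with half-open
50-µm annuli ([50, 100) receives a site at exactly 50 µm), mean ± SEM
across cells per bin, SEM undefined below two cells.

## Intrinsic excitability

Spikes are upward dV/dt crossings (20 V/s) whose waveform exceeds 0 mV
within 5 ms, with a 2-ms refractory. FI points are spike count divided
by step duration over 0.5–1 s steps. The FI model is fitted by SLSQP
with all parameters bounded at 0 and convergence tolerance 1e-8; because
the SSE surface is multimodal in the breakpoint, the optimizer starts
from a deterministic grid of candidate breakpoints (the observed
currents up to 60% of the range) with data-informed initial values for
the other parameters, and the best solution is kept. The fit is
deterministic, and on noiseless data inverts the generator to better
than 0.1% per parameter across random parameter sets. F0 is fitted, not
pinned at zero, although interneuron and pyramidal reference sets both
have F0 ≈ 0.

Input resistance is the IV slope between rest and 20 mV below rest
(mV/pA × 1000 = MΩ). The membrane time constant is a single-exponential
fit to the first 100 ms of hyperpolarizing responses settling 3–20 mV
below rest, averaged over qualifying steps. The adaptation ratio is the
mean of the last two interspike intervals (the intervals among the final
three spikes) over the first interval, defined only for trains of ≥ 4
spikes below 50 Hz; 1 means no adaptation. AP half-width is measured at
the voltage midway between the dV/dt-threshold point and the peak, with
sub-sample interpolation of both crossings.

Discharge classification is rule-based, in priority order: first spike
later than 50% of the step → delayed-onset; ISI coefficient of variation
> 1 with a silent gap (an ISI over 5× the median) → stuttering;
adaptation ratio ≥ 1.3 → adapting; otherwise fast-spiking. These rules
are an adaptation of published interneuron classification schemes, not a
reimplementation of any particular one.

## Inferential statistics

Welch's t with Welch–Satterthwaite df is computed in closed form (sample
SDs use ddof = 1 throughout; equal SDs at n = 13 per group give df = 24.0
exactly, SDs 6.1 and 12.7 give 17.26). Two-sample permutation tests are
exhaustive when the number of label arrangements is ≤ 20,000, otherwise
seeded Monte Carlo with the add-one correction. Two-way ANOVA uses a
full-factorial least-squares model (statsmodels) with Type II sums of
squares by default for unbalanced data (Type III with sum-to-zero
contrasts is available); on balanced designs it reproduces the classical
sums-of-squares decomposition to 1e-8. Per-distance-bin post-tests use
Welch comparisons at a Šidák-adjusted level, 1 − (1 − α)^(1/m), with m
the number of testable bins.

## The two-cohort contrast experiment

`experiments.genotype_contrast_experiment` simulates a high-gain cohort
(close_in_gain 1.5 within 50 µm, 12 cells) against a control cohort
(gain 1.0, 9 cells), three map repetitions per cell, runs the full
pipeline per cell, and compares the cohorts bin-by-bin on first-event
amplitude and response-magnitude Z. Grids are soma-aligned: a jittered
grid mixes ring sites — whose activation discs are only half inside the
gained zone — into the innermost 50-µm bin and dilutes the contrast.
The experiment uses a 600 × 600 µm field (~150 sites per map), a
scaled-down problem size chosen so that twenty full experiment
replicates run in minutes; the Z-calibration check runs at the full
0.85 × 1.2 mm map size (~470 sites). The expected readout is a
significant cohort difference confined to the innermost bin, mirroring a
selectively strengthened perisomatic input.

## Calibration utilities

Nernst potentials use total concentrations as mixed and ignore activity
coefficients: with 72 CsCl + 3 QX-314·Cl in the pipette against
125 NaCl + 2.5 KCl + 2 CaCl₂ in the bath at 295 K, E_Cl = −14.3 mV. The
laser spot is sized by fitting I₀·exp(−2(x − x₀)²/w²) to a measured
intensity profile (diameter = 2w at 1/e²), with a unimodality check
calibrated to the profile's own noise. Irradiance is exposed under
several explicit conventions — uniform disc P/(πr²), Gaussian peak
2P/(πw²), and the enclosed-power average over a disc of 95% of the 1/e²
area — because "average intensity over the spot" is not uniquely defined
for a Gaussian beam; no single convention is privileged.

## Known limitations

- The simulator's 2-D geometry conflates slice depth with areal density;
  the density default absorbs the unknown effective excitable depth.
- First-event amplitude of a compound IPSC is the peak of the
  superposition, which under-counts slow-latency components by a few
  percent and depends on the latency spread.
- The template-matching detector loses sensitivity for events closer
  than the template length; the deconvolution detector should be
  preferred at high event rates.
- Degenerate inputs are rejected loudly (zero baseline-charge variance,
  all-zero FI rates, infeasible stimulus orderings) rather than patched.
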