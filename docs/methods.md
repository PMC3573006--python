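# Methods

`swostim` models how weak transcranial electrical stimulation interacts with
the slow-wave oscillation (SWO, 0.5–1 Hz) of non-REM sleep and with the
homeostatic decline of its power across a night.  The package has three
layers: a spiking lattice model that generates UP/DOWN slow-wave dynamics, a
field-coupling and plasticity layer that applies stimulation and synaptic
downscaling, and an EEG-style analysis layer (band power, spatial coherence,
robust decay fits, shuffle statistics, entrainment) applied identically to
simulated local field potentials and to synthetic multi-channel sleep EEG.

## Network model

900 Izhikevich neurons (80% regular-spiking excitatory `a,b,c,d =
0.02, 0.2, −65, 8`; 20% fast-spiking inhibitory `0.1, 0.2, −65, 2`) occupy a
30×30 lattice with periodic boundaries.  Every neuron receives one synapse
from each excitatory neuron in its 5×5 neighborhood and from each inhibitory
neuron in its 3×3 neighborhood; no self-connections.  Izhikevich constants
and per-edge conductance increments are jittered with a 5% coefficient of
variation (weights redrawn until positive).

Synapses are conductance-based with first-order kinetics: AMPA (τ = 5 ms),
NMDA (150 ms, with the sigmoidal magnesium-block factor
`B(v) = ((v+80)/60)² / (1+((v+80)/60)²)`), GABA_A (6 ms, E = −70 mV) and
GABA_B (150 ms, E = −90 mV); excitatory reversal 0 mV.  A presynaptic spike
increments the fast conductance by the edge weight and the slow conductance
by a configurable fraction of it (both default to the full weight).

### UP/DOWN generation

Each neuron carries a slow excitability bias `e = e_ss − k_e·r`, added to the
voltage equation's drive, where `r` is a leaky estimate of the neuron's own
firing rate (time constant 0.9 s; each spike adds 1/τ_r so `r` reads in Hz)
and `k_e = 6`.  Sustained firing depresses excitability and terminates the
UP state; during the quiescent DOWN state `r` decays and excitability
recovers until a noise fluctuation seeds the next avalanche.  A small
per-step white-noise current (σ = 1.0 in Izhikevich current units ≈ 1.25 mV
of equivalent polarization) supplies those fluctuations and the
cycle-to-cycle irregularity.

### Calibration of the stated world

The population steady-state biases (`e_ss`), coupling strengths and noise
amplitude are not published; they were fixed once by a calibration sweep
against three joint targets measured on unstimulated runs: spectral peak of
the LFP inside 0.5–1 Hz (and as close to the 0.75 Hz stimulation frequency
as the other constraints allow), mean excitatory firing rate in detected UP
states ≈ 5 Hz, and an autocorrelation coherence time of ~3 cycles.  The
shipped defaults are `e_ss_exc = 2.9`, `e_ss_inh = 2.0`,
`w_exc_mean = 0.032`, `w_inh_mean = 0.2`, `noise_std = 1.0`, giving a median
spectral peak near 0.75 Hz, UP-state rates near 5.3 Hz and coherence times
near 3 cycles across realizations.

Inhibitory strength turned out to be the knob that controls cycle-to-cycle
irregularity: with weak inhibition the DOWN→UP restart is the minimum over
hundreds of near-independent threshold crossings, which concentrates its
timing and makes the rhythm far more regular than sleep EEG (coherence
times of 5–15 cycles).  At `w_inh_mean = 0.2` avalanches are partially
quenched, restarts become fluctuation-dominated, and the coherence time
drops to ~3 cycles while the spectral peak moves up to ~0.75 Hz.  Raising
`w_exc_mean` lengthens coherence and raises power, as expected for a
synaptically sustained rhythm.

The model LFP is the mean synaptic current across neurons, zero-phase
low-pass filtered at 2.5 Hz (4th-order Butterworth, `sosfiltfilt`).  Four
11×11 subregion LFPs, centered in the lattice quadrants, play the role of
separate EEG electrodes for spatial-coherence analysis.  UP/DOWN states are
detected by hysteresis on the 50-ms-smoothed population rate: UP onset above
30% of the rate's 90th percentile, offset below 10%.

### Integration

Forward Euler, dt = 0.5 ms, with the voltage advanced in two 0.25 ms
half-steps and conductances decayed exactly.  The voltage entering the
recovery-variable update is clamped at the +30 mV spike value, and a −120 mV
floor guards against Euler undershoot; both only matter in pathological
parameter regimes.  Synaptic deliveries are applied at the end of each step
(one-step latency), keeping avalanches causal.  Spiking is chaotic, so
trajectories are reproducible only for identical seed and build; all
randomness flows from explicit seeds.

## Field coupling

Uniform fields polarize pyramidal somata by λ = 0.2 mV per V/m; inhibitory
somata, being symmetric, are unaffected.  The model injects an equivalent
current `I = E·λ/z` into each excitatory neuron, where the input gain `z`
(mV per current unit) is measured by probing the resting neuron with a small
constant current.  The subthreshold response is linear to better than 2%
over ±2 V/m (slightly compressive on the hyperpolarizing side, from the
quadratic voltage equation).

Stimulation waveforms: `sham` (zero), `dc`, and the 0.75 Hz `onoff`
trapezoid (ON half-period with linear ramps occupying 10% of the ON half
each; the ramp fraction is a guess documented here — only "trapezoid" is
known).  Spatial profiles assign one signed field value per lattice column.
The anatomical current-flow model is out of scope; its published output
statistics are reproduced by `make_field_profile`: sort the radial-field
samples near an electrode, drop `floor(0.0312·n)` samples from each tail,
take 30 evenly spaced ranks, rescale so mean |E| = 0.93 V/m.
`synth_field_samples` generates mixed-polarity surrogate samples (signed
folded-normal lobes) standing in for the unpublished per-electrode
distributions.

## Homeostatic plasticity

Each neuron carries a multiplicative factor `w_hom` on its excitatory input
currents, driven by the normalized error between a target rate `r0` and the
neuron's instantaneous rate (inverse of its latest inter-spike interval,
held for at most 5 s of silence, then read as zero):

    τ_h · dw_hom/dt = (r0 − r_inst) / r0,   w_hom ≥ 0.

An absolute-error variant `(r0 − r_inst)` is available behind a switch.

The printed `r0` and `τ_h` are unavailable.  In this implementation the
1/ISI statistic is strongly bimodal — neurons either fire single spikes per
slow-wave cycle (≈0.7 Hz) or millisecond doublets inside avalanche fronts
(≈100+ Hz held rates) — so a target tied to the population *mean* sits above
most neurons and would strengthen the majority.  The default target is
derived per network by `calibrate_target_rate`: 0.8× the population *median*
of the per-neuron time-weighted 1/ISI rate from a plasticity-free baseline
(typically ≈0.6 Hz, just below the single-spike mode).  With that target
almost every neuron sits above target and the mean factor declines
monotonically through a compressed night, with power and coherence
declining alongside; once the high-rate tail has been fully scaled down the
loop equilibrates and the decline flattens — the "night" is the declining
phase.  `τ_h` defaults to 3600 s, sized so that this phase spans a
desk-scale compressed night (minutes) rather than completing in seconds.

A consequence of the bimodal 1/ISI statistic worth stating plainly: the
downscaling pressure is dominated by the doublet tail, and weak entrainment
(which regularizes avalanches) can reduce doublet incidence even while the
mean firing rate rises.  The acute rate increase under 0.31 V/m ON/OFF
stimulation (~+1.4%) therefore translates into a much smaller and noisier
acceleration of the mean `w_hom` decline than the clean separation the
original large-n simulations show; see the acceptance notes.

## Compressed nights

Real nights are hours; the package compresses time by a factor (default 60:
one simulated minute per night-equivalent hour) and reports decay slopes per
night-equivalent hour.  A night run is pre-stimulation baseline, five
stimulation blocks separated by gaps (the human protocol's 5×5-minute shape,
durations config-scaled), and a post-stimulation epoch.  Sham and stimulated
nights share seeds, networks and the calibrated target rate, so conditions
are paired with common random numbers.  Post-stimulation SWO power and
spatial coherence of the four subregion LFPs are fitted for their decay in
dB per night-equivalent hour.

## Analysis

* **Band power**: per non-overlapping 40-s window, plain (rectangular)
  periodogram power summed over the bins inside the band (SWO 0.5–1 Hz,
  SWA 0.5–4 Hz); dB = 10·log₁₀.  Zero-power windows are masked, not −∞.
* **Spatial coherence**: per window and channel pair, Welch
  magnitude-squared coherence (8-s segments, 50% overlap) averaged over band
  bins, debiased by the standard small-sample correction (L·C − 1)/(L − 1)
  for L segments, clipped to [0, 1]; per channel, the mean over its pairs.
  Power-normalized by construction, hence invariant to channel rescaling.
* **Decay rate**: robust line fit (IRLS, Tukey bisquare, c = 4.685) of the
  dB series against time in hours; an exact line short-circuits to OLS.
* **Paired shuffle test**: two-sided permutation test of the mean paired
  difference under within-pair label swaps; exhaustive enumeration when
  2ⁿ ≤ n_perm, otherwise sampled with the add-one correction.
* **FDR**: Benjamini–Hochberg step-up (via statsmodels).
* **Entrainment**: network phase from the analytic signal of the band-passed
  LFP, sampled at stimulus ON onsets; PLV is the mean resultant length;
  Rayleigh p from the standard approximation.
* **Coherence time**: the normalized autocorrelation of the (drift-removed)
  signal shows peaks at multiples of the oscillation period; an exponential
  fit to the peak heights, truncated where they sink toward the long-lag
  pedestal (estimated from the autocorrelation tail at 10–20 cycles) or stop
  decaying, gives a decay constant reported in cycles.  On synthetic
  phase-diffusing oscillators the estimator is unbiased within ~10% at 2–6
  cycles.

## Synthetic sleep EEG

Channels mix a shared band-limited (0.5–1 Hz) noise source with per-channel
independent ones; the total band power follows the programmed exponential
decay (dB/hour) and the shared power fraction ρ(t) is scheduled so squared
coherence ρ² decays at the programmed coherence rate.  A multiplicative
envelope emulates non-REM/REM cycling as a cosine in log-power peaking at
sleep onset (6 dB peak-to-trough, period 84 min — inside the physiological
70–110 min range and chosen so a 7-h recording spans whole cycles).  The
cosine phase and integer cycle count make the envelope orthogonal to the
linear time trend, so it cannot bias the fitted decay slope; with a 90-min
period or a sine phase the aliasing shifts the slope by ~0.1–0.17 dB/h,
which is a property of any linear fit over partial cycles.  Broadband
sensor noise sits 20 dB below the initial signal.  What a green
recovery test establishes: the analysis pipeline recovers programmed decay
slopes from signals with realistic band structure, envelope modulation and
noise floors.  What it does not: artifact robustness, sleep-stage
segmentation, or any physiological claim — the generator is a measurement
fixture, not a model of EEG genesis.

## Numerical and degenerate-input choices

* dB of zero power → masked (NaN) and dropped from fits.
* Robust fits require ≥10 finite windows (≥5 in compressed nights).
* `detect_updown` returns an empty list when the rate never crosses
  threshold; UP-rate summaries then return 0.
* Weight jitter redraws non-positive samples (exact truncation at 0 would
  put an atom at zero conductance).
* The spike buffer is sized by `max_mean_rate` (default 40 Hz/neuron); a
  saturated network raises rather than silently truncating.
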