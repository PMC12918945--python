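# Methods

`mnreflex` simulates H-reflex experiments in a pool of spinal motor
neurons (MNs) and estimates single-unit reflex amplitudes from the two
standard peristimulus statistics — the peristimulus time histogram
(PSTH) and the peristimulus frequencygram (PSF) — via their cumulative
sums. This note documents the model, the estimation procedures, the
calibration choices, and what the synthetic benchmarks do and do not
establish.

## Motor neuron model

Each MN is a two-compartment conductance-based model in the pulse-gating
family: an excitable soma coupled electrotonically to a passive
dendrite. The soma carries a fast Na+ current (gates m, h), a fast
delayed-rectifier K+ current (gate n) and a slow K+
afterhyperpolarization (AHP) current (gate q):

    C_s dVs/dt = I(t) − g_Na m³h (Vs−E_Na) − (g_Kf n⁴ + g_Ks q²)(Vs−E_K)
                 − g_ls (Vs−E_l) − g_c (Vs−Vd)
    C_d dVd/dt = −g_ld (Vd−E_l) − g_c (Vd−Vs)

Instead of voltage-dependent rate functions, each gate relaxes with one
of two constant rates selected by a rectangular pulse of fixed duration
(0.6 ms) triggered when the soma voltage crosses a gate threshold
(−62 mV) from below; this is the classic pulse-based reduction of spike
generation. Because the rates are piecewise constant the gate updates
are exact exponential relaxations; the voltage updates use exponential
Euler with a fixed step of dt = 0.05 ms (20 steps per millisecond of
EPSC rise time). Spikes are reported at upward crossings of 0 mV with a
1 ms lockout. Modulatory currents (PICs) and within-interval threshold
accommodation are deliberately absent.

All constants are listed in `mnreflex.params.NeuronConstants` (units:
mV, ms, nA, µS, nF). The AHP pair (α_q = 4 ms⁻¹, β_q = 0.03 ms⁻¹,
g_Ks = 2 µS at unit size) sets the minimum sustained rate near 7 Hz and
a current–frequency (f–I) relation that rises steeply just above
recruitment and more shallowly at mid-range.

## Pool construction and the size principle

The pool (N = 200 by default) is parametrised by a target *rheobase*
profile that is exponential in the neuron index; input resistance is
therefore exactly exponential and strictly decreasing with index (the
size principle: index 1 = smallest MN = highest resistance = lowest
threshold). Each neuron is derived from a single reference neuron by
two scale factors:

* the **size factor** σ_i multiplies the passive conductances (soma and
  dendrite leak, coupling) and the AHP conductance, so rheobase is
  proportional to σ_i;
* the **capacitance factor** multiplies the compartment capacitances
  and the spike conductances (Na+, fast K+), and follows
  σ_i^γ with γ = 0 by default, i.e. a shared effective soma.

The decoupling is deliberate. MN size differences are carried mostly by
the dendritic membrane; the somatic capacitance charged by a
millisecond-scale synaptic current varies much less across the pool.
With uniform scaling (γ = 1) a fixed stimulus current produces EPSPs
spanning an order of magnitude across the pool, and the reflex
amplitude distribution is dominated by that gradient; with the shared
soma (γ = 0) the EPSP varies only ~3× (≈9 mV in the smallest, ≈3 mV in
the largest neurons) and the discharge statistics, not the raw EPSP
gradient, shape the amplitude distribution. γ is exposed as
`SizeDistribution.capacitance_exponent`.

The exponential profile is anchored at two calibration points,
rho(89) = 4.64 nA and rho(197) = 19.5 nA, chosen so that under the
default noisy drive about 44.5% of the pool sustains ≥ 7 Hz firing at
the lowest drive (4 nA) and about 98.5% at the highest (16 nA). The
7 Hz criterion equals the pool's minimum sustained discharge rate:
*recruited* here means tonically firing, while sporadic sub-threshold
discharges (≥ 0.5 Hz) are reported separately as `firing`. The anchors
sit above the nominal drives because band-limited noise recruits
neurons whose rheobase exceeds the mean input.

Biased pool compositions for the population analysis multiply the
exponential's exponent by a scale factor while pinning the smallest
neuron: scales < 1 flatten the profile (proportionally more small,
high-resistance MNs), scales > 1 steepen it (more large MNs).

## Synaptic input

Every neuron receives the linear sum of three effective synaptic
currents at the soma:

* **Common drive**: a constant mean (4–16 nA in seven equally spaced
  activation levels standing in for contraction intensity) plus
  zero-mean Gaussian noise band-passed to 15–35 Hz (4th-order
  Butterworth, zero-phase), with SD fixed at 20% of the mean after
  filtering. Shared by the whole pool within a level, redrawn across
  levels.
* **Independent noise** per neuron: zero-mean Gaussian noise low-passed
  below 100 Hz (2nd-order Butterworth, zero-phase), scaled to carry 20%
  of the total noise *variance* (so its SD is half the common SD; an
  SD-share interpretation is available as a config switch).
* **Stimulus train**: an EPSC `6 nA · (t/1 ms) · exp(1 − t/1 ms)`,
  truncated at 40 ms, delivered 200 times with Gaussian inter-stimulus
  intervals of 1000 ± 100 ms truncated below at 200 ms (so consecutive
  EPSCs can never overlap).

Noise is synthesised on a 1 ms grid — the signals are band-limited well
below that grid's 500 Hz Nyquist, and designing a 15 Hz Butterworth at
the 20 kHz integration rate would be numerically fragile — and linearly
interpolated to the 0.05 ms integration grid inside the integrator.
Every random stream is derived from (global seed, level, stream id,
neuron index) via `numpy.random.SeedSequence`, so studies are exactly
reproducible and any single neuron's input can be reconstructed.

With this configuration the included units' interspike-interval
coefficient of variation (CoV_ISI) spans roughly 7–26%, overlapping the
physiological 10–30% band, and background discharge rates span ~7–40 Hz
across the seven levels.

## Discharge statistics and inclusion

Background discharge rate is the spike count in the union of 500 ms
pre-stimulus windows divided by the total window time. CoV_ISI uses
only intervals that do not overlap the 100 ms post-stimulus exclusion
zone, so evoked discharges do not contaminate the noise index.
Simulated units are included when DR ≥ 7 Hz and CoV_ISI ≤ 30%;
externally recorded units use a 5 Hz floor (decomposition-quality
screening is upstream of this package).

## Reflex-amplitude estimation

PSTH and PSF are built on 1 ms bins over a peristimulus window of
300 ms pre / 150 ms post for simulated data (200/100 ms for recorded
data). The PSTH accumulates spike counts; the PSF accumulates each
discharge's instantaneous rate (1000/ISI to the preceding discharge).

The cusum baselines differ by construction of the two statistics. The
PSTH cusum subtracts the mean pre-stimulus count per bin. The PSF cusum
subtracts the mean pre-stimulus discharge *frequency* from every
discharge's instantaneous frequency (bin j contributes
`sum_rates(j) − n_spikes(j) · f̄_pre`), following the established
frequencygram-cusum practice; a per-bin baseline would make the PSF
amplitude measure `p · r_evoked` instead of the evoked rate *change*
`p · (r_evoked − r_background)` and inflates amplitudes several-fold.
Both cusums return exactly to zero at the last pre-stimulus bin.

Detection on the cusum proceeds as follows. The *error box* is the
maximum absolute pre-stimulus cusum deflection from zero. The *slope
threshold* is the maximum absolute pre-stimulus forward difference. The
response onset is the first post-stimulus bin whose forward difference
strictly exceeds the slope threshold — constrained to ≤ 15 ms after the
stimulus in simulated mode, where no conduction delay exists — and the
response end is the last bin of the contiguous supra-threshold run. The
amplitude is the cusum rise from onset to the *first turning point*: the
earliest subsequent bin whose cusum is not exceeded within the following
3 ms (the reflex rise-time scale; this patience keeps single-bin noise
dips from truncating the response — PSTH results are insensitive to it,
PSF amplitudes at high drive depend on it). Amplitudes are normalized by
the stimulus count, giving the extra count (PSTH) or extra rate (PSF)
evoked per stimulation. A response is *significant* when the cusum value
at its turning point strictly exceeds the error box; only excitatory
(positive) responses are tested, and exceedances away from the detected
response do not count — a free post-stimulus random walk crosses the
pre-stimulus maximum by chance alone with substantial probability at
high background rates, which would swamp the evoked-response count.
Ties and plateaus resolve to the earliest bin throughout.

## Population statistics

Amplitudes are standardized (z-score with population SD) before linear
regression on background DR; slope p-values are two-sided t-tests
(ordinary least squares). Pearson correlations with DR and with
recruitment threshold are one-tailed in the expected direction and
rated on the conventional |ρ| scale (poor < 0.3, fair < 0.5, moderate
< 0.8, strong ≥ 0.8). Per-level amplitude dispersion is the
coefficient of variation (population SD / mean) over significant units.
Pool compositions are compared by the empirical cumulative
distributions of significant amplitudes under identical stimulus and
noise streams, summarized by a signed mean ECDF gap whose sign
identifies stochastic dominance. Units with non-significant responses
are excluded from regressions, ECDFs and dispersion summaries.

## Surrogate ground truth

The estimators are validated independently of the biophysics by
surrogate spike trains: Gaussian-ISI renewal processes with prescribed
DR and CoV_ISI (ISIs truncated at 10% of the mean) into which a reflex
is injected either as an extra discharge at a fixed latency with known
probability per stimulus, or as a phase reset advancing the next
natural discharge. The central oracle identity is that the PSTH
normalized amplitude equals the injected-discharge probability within
binomial sampling error and one bin's discretization.

## Problem sizes and numerics

The integrator processes the whole pool in one compiled pass
(~10⁶ neuron-steps per millisecond of simulated time); a full
activation level (200 MNs, 200 stimuli, ≈200 s simulated) takes on the
order of a minute on one core, and the test suite runs the full
seven-level study once and reuses it across population-level checks.
Divergent membrane state (non-finite voltage) aborts integration with
an error naming the neuron. Calibration experiments behind the frozen
constants (spike-conductance ratios, AHP strength, capacitance,
recruitment anchors) were run once during development and are not part
of the test suite.

## What the synthetic benchmarks show — and what they do not

The generator reproduces the study conditions it declares: recruitment
fractions at the extreme drives, discharge-rate and CoV_ISI ranges,
stimulus statistics, and ground-truth reflex injections. Passing tests
therefore establish that the estimation pipeline measures what it
claims to measure under those conditions. They do not establish
fidelity to any particular biological dataset: real decomposed EMG
spike trains carry decomposition errors, non-stationary drive, fatigue
and doublets, none of which the renewal surrogate or the stationary
pool emulate. The model family reproduces the qualitative dependence of
reflex-amplitude estimates on discharge statistics and MN size; exact
per-level counts depend on unpublished details of the original model's
size distribution and are expected to differ in the mid-range.

## Known limitations

* Excitatory stimuli only; inhibitory reflex analysis is out of scope.
* No muscle model: activation levels are unitless drive levels, not
  %MVC.
* The pulse-gating reduction has no spike-threshold accommodation
  within the interspike interval, so stimuli arriving late in the
  interval may be slightly too effective.
* CoV_ISI sits in the lower half of the physiological band; the
  band-passed common noise produces coherent rate modulation rather
  than fully independent interval jitter, which is visible as a larger
  pre-stimulus error box for the PSTH than a renewal process would
  give.
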