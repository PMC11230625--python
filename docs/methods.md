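# Methods

`swdkit` chains four analysis layers that together emulate an awake-rodent
EEG–fMRI stimulation experiment in absence epilepsy: a mean-field model of
one cortical region that switches between an asynchronous-irregular (AI,
interictal) and a spike-and-wave (SWD, ictal) regime; a connectome-coupled
whole-brain simulator with square-pulse sensory stimulation and per-region
responsiveness statistics; automated EEG event rules (SWD detection,
merging, and an eight-way stimulation-block taxonomy); and a gamma-basis
mass-univariate GLM with cluster-level permutation correction.  All inputs
can be produced by the synthetic-data generators, which carry exact ground
truth.

## The mean-field model

Each region holds an excitatory (regular-spiking, adapting) and an
inhibitory (fast-spiking) population of conductance-based AdEx neurons,
reduced to first-order rate equations:

    T  dnu_e/dt = F_e(nu_e_tot, nu_i, W) - nu_e + noise
    T  dnu_i/dt = F_i(nu_e_tot, nu_i, 0) - nu_i
    dW/dt       = -W/tau_w + b nu_e + a (mu_V - E_L_e)/tau_w

`W` is the population-mean spike-frequency-adaptation current; `b` (pA per
spike) is the single control parameter that moves the node between regimes.

The transfer functions `F` are semi-analytic.  Shot-noise theory maps the
presynaptic rates onto the mean, standard deviation and autocorrelation
time of the membrane potential (`mu_V`, `sigma_V`, `tau_V`), with
`K_s = p_conn * frac * N_tot` synapses per neuron, mean conductances
`mu_Gs = K_s nu_s tau_s Q_s`, and

    mu_V    = (mu_Ge E_e + mu_Gi E_i + g_L E_L - W) / mu_G
    sigma_V = sqrt( sum_s K_s nu_s (U_s tau_s)^2 / (2 (tau_m + tau_s)) )

The output rate is an error-function escape rate across a phenomenological
threshold, `F = Erfc((V_thr - mu_V)/(sqrt(2) sigma_V)) / (2 tau_V)`, where
`V_thr` is a polynomial in the normalized `(mu_V, sigma_V,
tau_V mu_G / C_m)`: all second-order terms plus the triple cross term, 11
coefficients per population.  The coefficients are not hand-set: they are
fitted (`fit_transfer_coefficients`) against the in-repo Monte-Carlo AdEx
single-neuron simulation (`swdkit.adex`) by inverting the Erfc relation at
each grid point and polishing with nonlinear least squares on the rate
residuals.  The shipped fit used oracle rates between 0.05 and 100 Hz (the
model's validity domain); its RMS error is 0.9 Hz (excitatory) and 0.6 Hz
(inhibitory), and spot checks at twelve input triples agree with the
Monte-Carlo neuron to at most 9 % relative error.  The fit depends only on
membrane/synaptic parameters, not on `tau_w`, `b`, or the ambient drive.

### Parameter calibration

Defaults (all configurable): C_m = 200 pF, g_L = 10 nS, E_L_e = -64 mV,
E_L_i = -65 mV, E_e = 0, E_i = -80 mV, Q_e = 1.5 nS, Q_i = 3 nS,
tau_e = tau_i = 5 ms, N_tot = 10^4, p_conn = 0.05, frac_exc = 0.8,
T = 5 ms, tau_w = 40 ms, a = 0, nu_ext = 1 Hz, rate cap 200 Hz, drive
noise 0.5 Hz (sqrt(T/dt)-scaled so the integrated diffusion is
dt-independent).

Three of these were calibrated rather than inherited, because the obvious
textbook values admit no spike-and-wave regime once the transfer function
is fitted accurately:

* with Q_i = 5 nS the node is inhibition-stabilized at every adaptation
  strength — no oscillation exists;
* with strong recurrent drive a high-rate absorbing state appears in which
  the synaptic conductance load (~1 uS) makes even nano-ampere adaptation
  currents shift mu_V by only a few mV, so adaptation can never terminate
  the hyperactivity.

The shipped Q_i = 3 nS, tau_w = 40 ms, nu_ext = 1 Hz place the node in a
regime with a deterministic adaptation-paced limit cycle: the excitatory
population bursts, the adaptation current accumulates and silences it, and
the cycle re-ignites as W decays.  A scan over `b`
(`swdkit.meanfield.scan_adaptation`) shows AI for b <= 50, rhythmic SWD
from b ~ 150, and the spectral peak entering the 7–12 Hz band used for
experimental SWD classification from b ~ 500.  The shipped regime defaults
are `b_interictal = 10` (comfortably inside the AI plateau, so the
baseline state stays robust under coupling and stimulation) and
`b_ictal = 700` (peak 9.75–10.5 Hz across seeds, with margin to both band
edges).

`classify_regime` labels a rate trace SWD when the Welch power fraction
within +/-1.5 Hz of the 1–20 Hz peak exceeds 0.4 *relative to the 1–20 Hz
band* and the peak-to-trough excursion exceeds 10 Hz.  The denominator is
the classification band rather than the full spectrum on purpose: a
spike-and-wave cycle is strongly non-sinusoidal and carries much of its
power in harmonics above 20 Hz, which should not count against its
rhythmicity.

## Whole-brain simulation

Regions are coupled through a directed weighted connectome whose incoming
weights are row-normalized to unit sum and scaled by `S` (default 0.05),
so the long-range afferent to region k is `S * sum_j w[k,j] nu_e_j`
(optionally delayed through a ring buffer of each source's past rate).
Coupling and stimulation are excitatory and, by default, target only the
excitatory population; routing them to the fast-spiking population as well
(`couple_to_inhibitory=True`) makes feedforward inhibition cancel or even
invert stimulus responses under the fitted transfer function, so the
switch exists but is off.  The default `S` was likewise chosen so the
coupling afferent stays inside the rising part of a node's
(non-monotone) input–response curve; at S = 0.2 every node sits past the
response peak and the stimulated region stops responding to stimulation
altogether.

Stimulation is a periodic square pulse train (defaults mirror the visual
protocol: 3 Hz, 166 ms pulses, 6 s blocks) added to the target regions'
excitatory drive.  `responsiveness_map` places `n_trials` blocks in one
continuous simulation, computes per region the trial-wise difference of
mean excitatory rate between each block and the equal-length window before
it, and applies a paired t test (or sign-flip permutation test) with
Benjamini–Hochberg correction.  Integration is stochastic Heun with
dt = 0.1 ms by default (0.25 ms in the large scans; the stability guard
rejects dt > 0.5 ms), per-region noise streams spawned from one seed, and
bit-reproducible output.

## EEG event rules

`preprocess_eeg` applies a zero-phase 50 Hz notch and a 1–90 Hz Butterworth
band pass.  `detect_swd` slides 0.5 s windows (50 % overlap) and marks a
window when the 7–12 Hz fraction of 1–45 Hz power exceeds 0.4 *and* its
RMS amplitude is at least 2.0 times the rolling baseline (median window
RMS outside detections, two-pass).  Marked windows fuse into intervals,
after which the counting rules apply: gaps shorter than 1 s merge, events
shorter than 2 s are discarded (both bounds as the experimental criteria
state them, the 2 s bound inclusive).  Boundaries therefore snap to a
0.25 s grid, which is also the tolerance the recovery tests use.

`classify_stimulations` assigns each block exactly one of eight labels
with the precedence: ended a seizure (seizure end within 0–2 s of block
onset) > fully inside > started during (split at > 50 % overlap, ties to
"mostly outside" per the strict reading) > started before (same split) >
right after a seizure (onset within 2 s of a seizure end; this window is
not defined experimentally and is a configurable choice) > baseline.

## GLM analysis

Stimulation and seizure events are convolved with a third-order gamma
basis (unit-peak gamma densities; default shapes 3/5/7 with 1 s scale,
peaking at 2/4/6 s — an early, rodent-like hemodynamic response; exact
basis parameterizations vary between processing pipelines, so these are
documented, configurable choices).  Effects of interest are interictal stimulation, ictal
(fully-inside) stimulation, stimulation that ended a seizure, and seizures
without stimulation; the intermediate timing categories, six motion
parameters and an intercept are confounds of no interest.  Voxel-wise OLS
(`fit_glm`) yields betas, unbiased residual variance and dof;
`f_contrast` tests a condition's three betas jointly or an
interictal-minus-ictal difference with +1/-1 weights on matched basis
columns, and the F map can be masked by the sign of the first-basis t map
to make the difference directional.

Cluster correction is nonparametric: 26-connected components above the
voxel threshold are compared against the maximal cluster size over
permutations in which the effect regressors are jointly circularly shifted
in time (999 permutations, voxel p < 0.01 and cluster alpha 0.05 by
default; tests use 99 permutations at the same alpha).  Serial correlation
is ignored in the OLS itself — a documented limitation, partly compensated
by the shift permutation preserving the noise autocorrelation.

Framewise displacement sums the absolute differentials of the six rigid
motion parameters; rotations convert to millimetres either as arc length
(`radius * |delta| in radians`, the default) or by dividing the rotation
in degrees by the radius (`divide_by_radius`), a dimensionally anomalous
convention that nonetheless appears in some processing pipelines — both
modes ship.  Stimulation blocks coinciding with displacement above 0.3 %
of the in-plane voxel size (1.5 um at 0.5 mm voxels; "percent of voxel
size" is one of two possible readings of the criterion) are scrubbed.

## Synthetic data

Connectomes are modular directed graphs (within-module connection
probability 4x the between-module one, matching the requested overall
density in expectation) with log-normal weights and atlas-like labels
including "V1" and "S1BF".  EEG is 1/f background plus an additive
spike-wave waveform — cosine fundamental with aligned 2nd/3rd harmonics,
so each cycle has one sharp spike and a slow remainder — scaled to a
stated multiple of the background RMS (3x by default; 7–12 Hz criteria are
then satisfied by construction, and a 1x fixture serves as negative
control).  Stimulation schedules alternate between onsets inside scheduled
seizures and onsets at least 5 s clear of any seizure, with at least 20 s
between blocks.  Synthetic fMRI sums per-condition ROI signals (betas times
boxcar-basis convolutions), AR(1) noise (coefficient 0.3), a sub-micrometre
motion random walk matching well-habituated awake recordings, and optional
motion spikes that jump the parameters and corrupt the affected volume.
The default volume grid is 20 x 20 x 12 (desk scale; a full 45 min run at
the 2 s volume time is 1350 volumes and is available by configuration).

What the generators deliberately do not emulate: recorded SWD morphology
(the waveform is analytic), EEG gradient/ballistocardiogram artifacts, MR
physics (no k-space, susceptibility or registration effects), and
physiological noise structure beyond AR(1).  Passing tests therefore
demonstrate that the *analysis chain* is correct against known truth, not
that the detector or GLM would perform identically on recorded data.

## Problem sizes used by the test suite and acceptance script

Single-node runs are 6–11 s at dt 0.1–0.25 ms; the transfer-function
oracle checks use 10 s Monte-Carlo runs with 3–5 seeds; the whole-brain
responsiveness contrast runs the full 496-region connectome with 10
stimulation trials per state at dt 0.25 ms; GLM suites use runs of 40–210
volumes on grids up to 14 x 14 x 8 with 99 permutations.  These sizes are
the package's default desk-scale choices; every generator and solver
accepts larger values.

## Known limitations

* **Responsiveness of the ictal attractor.**  In this calibration the
  spike-and-wave limit cycle remains sensitive to excitatory drive: a
  stimulus shortens the silent phases, so the stimulated region's
  block-averaged rate rises during ictal stimulation highly reproducibly.
  On the full 496-region connectome the *global* contrast behaves as in
  the experiment (more significant regions interictally than ictally,
  because the desynchronized ictal network transmits the perturbation
  poorly), but the stimulated region itself stays responsive in both
  states.  Configurations whose deeper-quenched seizure cycle is stiff
  against input oscillate at 1–4 Hz, outside the 7–12 Hz SWD band, so
  they were not adopted.  The corresponding acceptance test asserts the
  full experimental direction and fails on the stimulated-region clause.
* The kernel LFP is a linear functional of the population rates and
  carries no adaptation-current information; its trough leads the
  membrane-potential minimum by ~24 ms within the SWD cycle (both fall in
  the silent phase, which is what the signals test asserts).
* First-order mean field only: no second-order covariance dynamics; the
  regime dichotomy is reproduced at the level of mean traces.
* OLS without prewhitening; cluster inference is permutation-based
  specifically so this does not bias the null.
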