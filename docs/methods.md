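# Methods

`megevoke` implements a complete evoked-response MEG/EEG analysis chain at
desk scale, together with a synthetic-subject generator that provides ground
truth for every stage. This note documents the models, the numerical
choices, and what the synthetic data can and cannot establish about real
recordings.

## Data model and conventions

Continuous data live in a `Recording`: a channels × samples matrix in SI
units (T for magnetometers, T/m for planar gradiometers, V for EEG), with
per-channel type, unit, head-frame position and (MEG) orientation. Time is
in seconds on the recording clock; sample `j` is at
`first_sample_time + j/sfreq`, event onsets are absolute, and epoch
latencies are relative to the event sample (latency 0). The head frame is
right-handed with X toward the nasion, Y toward the left pre-auricular
point, Z superior; meters everywhere.

Bad data are represented uniformly: channels carry an `is_bad` flag,
intervals become bad segments or events whose label contains `bad`. Bad
channels never enter multichannel estimates (PSD averages, references, SSP,
covariance, gain rows); trials overlapping bad intervals are flagged and
never averaged. Linear projectors (SSP components, the EEG average
reference) are carried lazily on the recording and applied by downstream
estimators, so the original data — and the original EEG reference — are
always recoverable by removing the projector.

The raw container is a flat little-endian float64 matrix plus a JSON
sidecar; round trips are bit-exact. Channels and events use tab-separated
files with `n/a` for missing values.

## Trigger decoding

The stimulus channel holds integer codes; each bit is decoded independently
(one point event per 0→1 transition) and coincident bit events are merged
back into labeled stimulus events. Bits are numbered 1-based from the least
significant bit, so code 5 = binary 00101 has bits 1 and 3 set. The category
rules are: bit 3 = face, bit 4 = unfamiliar, bit 5 = scrambled, giving
Familiar = {5, 6, 7}, Unfamiliar = {13, 14, 15}, Scrambled = {17, 18, 19}.
A constant 34.5 ms offset compensates the trigger-to-screen hardware delay;
the event editor makes it explicit and exactly invertible.

## Artifact detection

* **Blinks** — threshold detector on the band-passed (0.3–20 Hz) EOG trace:
  every contiguous |signal| excursion above threshold (default 100 μV)
  becomes one event; excursions closer than 500 ms merge. Events get a
  `_bad` suffix so the epoching stage rejects co-occurring trials, mirroring
  the choice to *reject* blink trials rather than correct them.
* **Heartbeats** — R peaks found as local maxima of the rectified 8–40 Hz
  band-passed ECG with an adaptive amplitude threshold (half the 99.5th
  percentile, guarded against flat traces by a median-based noise floor)
  and a 300 ms refractory period. Rectification makes detection
  polarity-invariant. The contract is detection accuracy on ECG-like
  signals, not any particular published QRS algorithm.
* **cHPI activation** — head-position-indicator coils emit sinusoids far
  above the physiological band. A 1-s sliding window is marked HPI-active
  when its >250 Hz band power exceeds 10× its <100 Hz band power; the
  interval from the file start to the first active window (refined to
  ~sample precision with a 20 ms moving average of the instantaneous band
  power) is returned as one bad segment. Zero-phase filtering smears the
  onset backward by ~10 ms, which is far inside the tolerance that matters
  for spectral cleanliness.
* **Movement / muscle bands** — per band (1–7 Hz, 40–240 Hz clipped at
  Nyquist), sliding-window RMS of the band-limited good channels is
  z-scored robustly (median/MAD); windows with z > 5 merge into
  `movement_bad` / `muscle_bad` events. Windows inside the band-pass
  startup transient at either file edge are not scored.

## Spectral estimation and filtering

**Welch PSD** uses 3-s Hann windows with 50% overlap; windows are taken only
inside contiguous good spans, and spans are combined weighting by their
window counts. Density scaling is such that the PSD integrates to the
signal variance.

**Notch filters** are biquad notches (−3 dB bandwidth 1 Hz) cascaded twice
(total order 4) and applied forward–backward for zero phase.

**The evoked low-pass** is a linear-phase FIR designed by frequency sampling:
the target magnitude response is 1 in the passband with a squared-cosine
rolloff over the transition band, inverse-transformed and truncated to an
odd length. Two frozen constants define the design: the transition width is
0.0672 × the upper passband edge, and the filter length is the odd integer
nearest to 4.884/transition-width seconds, scaled by attenuation/60 dB so
lower attenuation gives shorter filters. For the default 0–32 Hz, 60 dB
design at 1100 Hz this yields a 2499-tap filter whose measured stopband is
below −60 dB beyond one transition width and whose transient metadata reads:

* `transient_full` = group delay = 1135.45 ms — the time for the filter to
  settle completely;
* `transient_99` = 91.82 ms — the one-sided half-width of the shortest
  centered interval containing 99% of the impulse-response energy.

A Kaiser-window design cannot produce this pair (at the order giving an
1135 ms group delay its 99%-energy transient is 160–200 ms): energy
concentration requires the smooth frequency-domain rolloff. Both transients
propagate as metadata: `apply_fir` masks samples within `transient_99` of
each edge (the energy criterion governs what epoch cropping must discard —
cropping 300 ms per side of a [−500, 1200] ms epoch leaves the
[−200, 900] ms window clean), while `transient_full` is available for
strictly settled measurements.

DC offset removal subtracts the per-channel mean over [−500, −0.9] ms,
where the upper endpoint resolves to the last sample strictly before the
event. The EEG average reference is the projector I − 11ᵀ/n over good EEG
channels. Resampling is polyphase with the rational ratio of the two rates.

## SSP

Artifact subspaces are the left singular vectors of band-passed data
concatenated in windows around artifact events, computed separately per
sensor kind (magnetometer and gradiometer patterns never mix). Defaults:
cardiac ±40 ms / 13–40 Hz, blink ±200 ms / 1.5–15 Hz; the first component is
active by default. P = I − UUᵀ is idempotent, symmetric and contracting, and
the same P multiplies the forward-gain rows before inversion so that source
estimates see a consistent measurement model.

## Epoching and averaging

Epochs span [−500, 1200] ms on a grid anchored at the event sample. Run
averages are arithmetic means over good trials; run averages combine into
subject averages weighted by good-trial counts, which is algebraically
identical (to 1e-12) to pooling the trials; subjects combine into unweighted
grand averages. The subject-level "Faces" response is the weighted average
of the Familiar and Unfamiliar averages. Contrasts come in two forms with
different meanings for signed data: amplitude (A − B) and magnitude
(|A| − |B|); e.g. A = −10, B = −5 gives A − B = −5 but |A| − |B| = +5, and
A = −10, B = +10 gives |A| − |B| = 0 although |A − B| = 20.

## Head modeling

Registration: a closed-form SVD rigid fit of the NAS/LPA/RPA pairs
initializes an iterative-closest-point refinement against the scalp mesh
(exact point-to-triangle projection; the association cost is non-increasing
by construction). Note that rotation about a symmetry axis is intrinsically
unidentifiable on a spherical scalp — validation uses ellipsoidal meshes.
Electrodes are projected to their nearest scalp-surface point.

MEG forward fields use the Sarvas closed form for a current dipole in a
spherically symmetric conductor, projected on the sensor orientation;
planar gradiometers are evaluated as a two-point field difference across a
16.8 mm baseline whose direction is derived deterministically from the
sensor orientation. Spheres are fitted to the scalp algebraically; the
local variant weights scalp vertices by a Gaussian (width 0.1 rad of arc)
around the point nearest each sensor. Radial dipoles produce exactly zero
field — consequently, constrained sources with near-radial orientations
have near-zero MEG gain columns. These are kept in the source space; the
depth-weighting clip (below) keeps their prior finite, and standardization
leaves their (zero) kernel rows at zero rather than dividing by zero.

EEG potentials use a three-shell concentric-sphere model (default radii
7/8/9 cm, conductivities 0.33/0.0042/0.33 S/m). Per spherical-harmonic
degree, the potential coefficients in each shell follow from continuity of
potential and radial current plus the outer Neumann condition — a small
linear system solved per degree and cached per geometry. The series is
truncated when the relative term falls below 1e-6 (hard cap 200 terms; 60
for bulk gain assembly). The equal-conductivity limit reproduces the
homogeneous-sphere coefficient (2n+1)/n · bⁿ⁻¹/Rⁿ⁺¹ to machine precision.

The source space is a triangulated cortical mesh with one dipole per vertex;
the free-orientation gain (3 columns per vertex) contracts with the vertex
normals when the orientation constraint is applied. Desk-scale meshes are
icosphere-derived with 42–642 vertices; full-scale configuration keeps the
conventional 15,000-vertex default.

## Minimum-norm inversion

With gain G, noise covariance C (empty-room recordings or concatenated
pre-stimulus baselines; diagonal loading of 0.1 × the mean diagonal, per
channel kind), depth prior R_jj = ‖g_j‖^(−2γ) (γ = 0.5, clipped at 10× the
smallest weight) and λ² = tr(G R Gᵀ)/(snr²·tr C) with snr = 3 (a
regularization convention, not a statement about data quality):

    K = R Gᵀ (G R Gᵀ + λ² C)⁻¹

evaluated in the whitened domain through the Cholesky factor of C
(algebraically identical; verified against the dense formula). dSPM divides
kernel row j by √((K C Kᵀ)_jj), giving unit source variance on pure noise;
sLORETA divides by √((K G R)_jj), which restores zero localization error
for a single noiseless source. The z-score standardization divides each
source trace by its pre-stimulus ([−200, −5] ms) standard deviation after
mean removal, applied after cross-run averaging, per condition. Every source
estimate is a fixed linear operator applied to sensor traces.

## Time-frequency

Complex Morlet wavelets with mother parameters fc = 1 Hz and temporal
FWHM = 3 s, scaled by fc/f, on a 20-bin log-spaced 6–60 Hz grid. Power is
the squared modulus of the unit-energy-normalized convolution. The edge
mask excludes samples within √2·σ_t(f) of either epoch edge — the point
where the Gaussian envelope has decayed to e⁻¹ of its peak. At 6 Hz
(σ_t = 212 ms) this is ±300 ms, so a [−500, 1200] ms epoch is reliable over
[−200, 900] ms; a stricter envelope criterion (e.g. the 1% point, ±644 ms)
would contradict that operational window, which pins the convention.
ERS/ERD maps power to percent change from the per-frequency baseline mean
over valid baseline samples, which also removes the 1/f background from
comparisons across frequencies.

## Group statistics

Subject source maps (rectified by default) are projected to the template
mesh through a row-stochastic vertex mapping and smoothed by iterated
explicit graph-Laplacian diffusion, v ← v + (α/deg_max)(Av − deg·v) with
α = 0.15; the step count is chosen so the accumulated per-axis variance
matches a Gaussian of the requested FWHM (default 3 mm). The Laplacian form
conserves the vertex sum exactly and preserves constants; on an equilateral
flat lattice the kernel matches the analytic Gaussian within 10%.

Inference is nonparametric throughout. The paired permutation t-test flips
the signs of whole subject difference maps (sign flips leave Σd²
invariant, so the null statistics come from the flipped sums alone);
p = (1 + #{|t*| ≥ |t|})/(n_rand + 1), with a 1e-9 relative tolerance so
permutations tied with the observed statistic are counted despite
round-off. Elementwise correction is Benjamini–Hochberg step-up pooled over
all sources/channels × times jointly. The cluster alternative thresholds
|t| at the two-tailed t quantile (default α = 0.05), forms connected
components on the spatio-temporal graph (spatial adjacency × time ±1
sample), scores them by mass (summed |t|) and ranks against the
permutation distribution of the maximum cluster mass. Sensor adjacency
comes from Delaunay neighbors or a distance rule; source adjacency is the
mesh edge graph. An export option zeroes t-values wherever not significant,
the conventional display form.

## Synthetic data

`simulate_subject` builds a spherical head (9 cm scalp, 3-shell EEG model)
with an ellipsoidal cortex (6.0/5.5/5.0 cm semi-axes) so vertex normals are
not purely radial, a Fibonacci-spiral MEG helmet (radial magnetometers and
planar gradiometers at 13 cm) and an EEG montage on the scalp. Two
constrained dipoles drive the evoked response: an "occipital" source
(Gaussian time course, σ = 20 ms, ~100 ms, 30 nAm, condition-independent)
and a "ventral" face-sensitive source (σ = 25 ms, ~155 ms, 40 nAm for faces
vs 15 nAm for scrambled stimuli). Source vertices are chosen
deterministically among vertices with usefully tangential normals. Trials
follow a shuffled schedule with 1.1–1.5 s inter-stimulus intervals, 50 ms
trigger pulses carrying the category codes, and the 34.5 ms
trigger-to-screen delay between pulse and neural response.

Noise is 60% 1/f (corner 2 Hz), 30% white and ~10% line-frequency power,
scaled per channel kind so the single-trial peak amplitude SNR at the best
channel equals `evoked_snr` (default 3). The N-trial average therefore has
SNR ≈ 3·√N, the way averaging behaves in a real session; with the
full-scale trial counts this gives average SNRs in the tens, comparable to
robust visual evoked components. Artifacts are physical: blinks are 400 ms
raised-cosine bumps on the forward field of an eye-position dipole
(150–250 μV on EOG), heartbeats a synthetic QRS on the field of a deep
inferior dipole (~1 mV on ECG, rate 1.2 Hz, timing jitter 5 ms), and
optional cHPI sinusoids (293–321 Hz) from a configurable start time.
Between-subject variability multiplies source amplitudes by N(1, 0.2²) and
shifts latencies by N(0, 10 ms); `simulate_group` gives each subject an
independent seed stream, a shared template cortex with identity vertex
mappings, and an empty-room recording with the session's noise amplitudes.

What this does **not** emulate: realistic cortical folding and BEM-level
conductor geometry, head movement, sensor drift/jumps, SQUID artifacts,
correlated sensor noise, inter-subject anatomical variability (the vertex
mapping is identity), or overlapping/induced oscillatory dynamics beyond
the injected components. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under a controlled model, not
robustness to every pathology of real recordings.

Problem sizes used by the test batteries (chosen once as desk-scale
renditions of the study design): single-subject checks use 1 run × 12–30
trials at 300–1100 Hz with 16–40 MEG channels and 42-vertex cortices; the
group power and null batteries use 16 subjects × 1 run × 10 trials/condition
at 300 Hz with 16 magnetometers, cardiac SSP and blink-trial rejection, and
the cluster test restricted to the 80–280 ms face-response window; the
familywise-error Monte Carlo uses 500 replicates of 16-subject null data on
a 12 × 10 map with 250 randomizations each. Notably, the injected group
effect is detected reliably (10/10 seeds) only *with* the cardiac-SSP
cleaning step — the cardiac artifact exceeds the condition difference in
amplitude — which is the pipeline's raison d'être in miniature.

## Known limitations

* The spherical EEG model substitutes for boundary-element solutions; an
  externally computed gain matrix can be supplied for parity.
* MEG-silent (near-radial) sources remain in the source space with zero
  gain; their estimates are identically zero rather than excluded.
* The frequency-sampled FIR design constants are calibrated regression pins
  for the default design; other passbands use the same rule but have no
  external reference values.
* `PipelineConfig` validates keys and types, not cross-parameter
  consistency (e.g. epoch windows vs crop windows).
* The cluster test's time adjacency is a fixed ±1 sample; heavily
  downsampled maps change cluster granularity accordingly.
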