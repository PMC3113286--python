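# Methods

This note documents the models implemented in ephyskit, their assumptions,
the defaults that matter, and the numerical choices behind them. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Containers and conventions

Sample indices are 0-based; the time of sample *k* in a continuous record
is *k/fs* seconds; epoch and baseline windows are half-open *[t₀, t₁)* and
hold `round((t₁ − t₀)·fs)` samples. Units are opaque strings and are never
converted (an SCD transform rewrites `uV` to `uV/m^2`, nothing else).
Every reader validates its container's invariants (event samples inside the
recording, strictly increasing positive frequencies, PLF/PLV in [0, 1],
p-values in (0, 1]) and refuses to construct an invalid object; writers
re-validate, so a mutated record cannot be serialized in an inconsistent
state. The binary layout (magic `EPHYSKT1`, JSON header, raw little-endian
arrays) stores arrays with their in-memory dtype, making write∘read the
identity at the bit level, NaN payloads included. It is this package's own
format; no compatibility with any historical layout is attempted.

Event files are whitespace-delimited text (`sample code [reject]`, `#`
comments, missing reject column = kept), montage files are
`label azimuth elevation` in degrees (azimuth from +x/nose towards +y,
elevation from the horizontal plane; Cz = elevation 90) or `label x y z`
normalized to the unit sphere, and parameter files are `key = value` lines.
Unknown parameter keys are an error by design: silent typos in batch files
are worse than a failed run.

## Synthetic data: what it emulates, what it does not

The generator renders an event train (per code: trial count, inter-trial
interval, uniform jitter) into channels × samples data with additive
Gaussian noise, white or 1/f-amplitude ("pink", spectrally shaped, DC
removed, variance-normalized), plus stereotyped components time-locked to
events:

- `evoked_wave` — Gaussian-windowed cosine (±3σ envelope spanning the
  stated duration) with a fixed phase on every trial: survives averaging.
- `induced_burst` — the same burst with an independent uniform phase per
  trial: cancels in the average, survives averaged single-trial power.
- `coupled_pair` — an induced burst on two channels with a fixed phase
  lag. The pair's phase is always random per trial: with a stimulus-fixed
  phase, trial-shuffled surrogates would be exactly as synchronous as the
  data and the coupling null would be degenerate, so a fixed-phase pair is
  not a meaningful synchrony testbed.
- `artifact_step` — a DC step for rejection tests; `dc_topography` — a
  constant offset on selected channels.

Determinism: one integer seed; noise, event jitter, and each component draw
from separate substreams (`default_rng([seed, stream_id])`), so adding a
component never perturbs another's realization.

Not emulated: volume conduction / realistic forward models, correlated
sensor noise, non-stationary background rhythms, realistic artifact
morphologies (blinks, muscle), or amplitude-phase coupling. Tests passing
on this generator therefore demonstrate algorithmic correctness against
known ground truth, not robustness to the full messiness of recorded data.

## Preprocessing

Artifact rejection never alters the signal; it returns an event list with
updated reject flags. A trial is rejected when any thresholded channel
*exceeds* its limit (|x| > θ, strict, so a tie at exactly ±θ is kept — a
limit that "should not be exceeded" reads as >). The range criterion slides
a `round(win_len·fs)`-sample window one sample at a time and compares
max − min against the per-channel limit; sliding (rather than tiled)
windows are the stricter reading and the one implemented. Epochs crossing
a recording edge are rejected outright with a logged reason, not truncated.
Raising any threshold can only shrink the rejected set (monotonicity,
property-tested).

Butterworth filters (orders default 4) use scipy's SOS forms. Zero-phase
mode runs forward and backward (squared magnitude, −6.02 dB at the cutoff;
no phase shift), causal mode is a single pass (−3.01 dB). Edges are
handled by odd-reflection padding (zero-phase: scipy's default pad length;
causal: 6× the order). User-supplied FIR taps are applied causally with
left-edge reflection. Bad channels are rebuilt by the spherical-spline
interpolator fitted on the good channels; because fit and evaluation are
both linear, a whole recording is one matrix product.

## Averaging and measures

Epochs keep each trial's event sample, so baselines can be re-anchored to
another event: the reference is the nearest *preceding* kept event of the
reference code (the natural rule for a pre-stimulus baseline applied to
response-locked epochs); trials without a usable reference are dropped with
a warning. Grand averages weight equally by default or by trial count;
subtraction requires exact axis match — no implicit resampling, ever.
Peak/trough/mean measures break ties towards the earliest sample and may
sit on window edges; measurement rows append to a delimited text table for
external statistics.

## Spherical splines and scalp current density

The interpolant is *u(E) = c₀ + Σ cᵢ g_m(cos γ(E, Eᵢ))* with
*g_m(x) = (1/4π) Σ_{n≥1} (2n+1)/(n(n+1))^m Pₙ(x)*, coefficients solving
the bordered system `(G + λI)c + 1c₀ = v`, `Σcᵢ = 0`. Defaults: order
m = 4; series truncated at 50 terms or when a term's coefficient falls
below 1e-10 (for m = 4 the coefficients decay like n⁻⁷, so 50 terms is
converged well past single precision); λ = 0 for interpolation (exact at
the electrodes), λ = 1e-5 for SCD, where a little smoothing stabilizes the
second-derivative estimate. All overridable.

Because the Laplace–Beltrami operator maps Pₙ(cos γ) to −n(n+1)Pₙ(cos γ),
the surface Laplacian of the spline is the same series with exponent
m − 1. The SCD reported is the **negative** surface Laplacian scaled by
1/r² (head radius default 0.09 m), so a degree-n spherical-harmonic
potential gives SCD = +n(n+1)/r² × potential and a positive SCD marks a
current source (outward current). SCD is reference-free exactly: adding a
constant moves only c₀.

The eigenvalue oracle (SCD of Yₙ vs n(n+1)/r²·Yₙ) is checked on a
64-channel *full-sphere* Fibonacci montage. This is deliberate: the
eigenrelation is global, and a spline fitted only on an electrode cap
cannot constrain the harmonic beyond the cap, which inflates the apparent
SCD error at higher degrees regardless of implementation quality. The
montage generator's default remains cap-like (a Fibonacci lattice cut at
z > −0.25) for realistic EEG simulations. 2-D maps use the
azimuthal-equidistant ("radial", radius = polar angle) or orthographic
projection, masked beyond the outermost electrode's projected radius;
depth-electrode arrays reduce to contact × time matrices with no spherical
machinery.

## Time-frequency analysis

Morlet wavelets with m cycles (default 7, per-frequency allowed) have
σ_t = m/(2πf); kernels are sampled to ±5σ_t and normalized to unit energy
so power is comparable across frequencies. Convolution is FFT-based after
reflection padding; samples within 2σ_t of an epoch edge are flagged (in
the record's metadata) as unreliable rather than deleted. The Gabor option
is the same machinery with a fixed Gaussian window SD (default 0.05 s) —
a one-sample-hop short-time Fourier analysis.

Averaged power, evoked power (transform of the average), induced power
(average power after per-trial subtraction of the evoked waveform — the
subtraction happens *before* the transform), and PLF are as defined in the
README. PLF uses unit phasors, so it is invariant to per-trial amplitude
rescaling; for identical trials it equals 1 to machine precision, and for
uniform random phases E[PLF²] = 1/N. Baseline modes for TF maps: subtract,
ratio, dB (10·log₁₀), z-score (baseline SD across samples). Band extraction
averages the bins inside [f_lo, f_hi] and returns an event-locked record,
closing the loop back into averaging and statistics.

## Phase synchrony and surrogates

PLV is computed from the same wavelet phases on a channel pair. The
surrogate null permutes the trial pairing of one channel: each channel's
marginal phase statistics (including stimulus locking) are preserved and
only the cross-channel association is destroyed — the correct null for
stimulus-independent coupling. p = (1 + #{PLV* ≥ PLV})/(1 + n_perm),
deterministic given the seed. Field spread is a documentation-level caveat:
nearby sensors see the same sources, so high PLV at small angular
separations is not evidence of interareal coupling; `plv` can warn when a
pair sits closer than a configurable angular distance.

## Statistics

All tests run independently per domain point; observations are axis 0.
Ties use midranks throughout; tests are two-sided by default.

- **Wilcoxon signed-rank**: zero differences dropped per point; exact null
  for n ≤ 25 when the remaining |differences| are tie-free (ties make the
  tabulated exact null invalid), otherwise the normal approximation with
  tie and continuity correction.
- **Paired t**: classical; zero-variance nonzero-mean points get the
  smallest representable p and a degenerate flag.
- **Kruskal–Wallis**: tie-corrected H, χ²(k−1) reference.
- **Quade**: within-block midranks r_ij, block ranges ranked into Q_i,
  S_ij = Q_i(r_ij − (k+1)/2), F = (b−1)B/(A−B) on F(k−1, (b−1)(k−1)).
  A = 0 (all treatments identical everywhere) gives p = 1; A = B (perfect
  concordance, F undefined) falls back to a seeded within-block permutation
  p-value.
- **Randomization tests**: sign-flip for paired designs, label shuffling
  for two independent samples. When the full rearrangement group has at
  most 2¹⁶ members it is enumerated exhaustively and p is the observed
  statistic's rank in the group (the identity is a member, so p ≥ 1/N);
  Monte-Carlo sampling otherwise, with the add-one rule
  p = (1 + #{|T*| ≥ |T|})/(1 + n_perm). Tie comparison uses a relative
  1e-12 tolerance so re-summed copies of the observed statistic count as
  ties. The maximum-statistic correction compares each point's |T| to the
  permutation distribution of max|T*| over all points (strong familywise
  control; corrected rejections are a subset of uncorrected ones).
- **Additive-model interaction** (e.g. audio-visual): the observed
  statistic is D = mean(AV) − mean(A) − mean(V). The null must not let
  condition main effects masquerade as interactions, so surrogates are
  built from the additive model itself: unisensory trials are paired at
  random into synthetic sums Aᵢ + Vⱼ (which share the compound mean under
  additivity) and labels are shuffled between the compound pool and the
  sum pool. Naive reassignment of trials among the three raw pools was
  considered and rejected: its surrogate D* is offset by the grand mean,
  which destroys power and miscalibrates the test.
- **Corrections**: Bonferroni (strict p < α/M), Benjamini–Hochberg step-up
  over all points of a map as one family (per-channel families by flag),
  maximum statistic (above), and the minimum-duration criterion: a time
  point is significant only within a run of ≥ L consecutive samples with
  p < α (strict), per channel and frequency. L is always user-supplied; no
  lookup table is bundled.

Statistic and p-value maps are repackaged into event-locked or TF
containers (`pvalues_to_evoked` / `pvalues_to_tf`), so statistical output
is viewable and storable like any other result.

## Test-suite problem sizes

Calibration checks use 500 replicate null simulations at reduced sizes
chosen so the discrete attainable level sits near the nominal 0.05:
Wilcoxon with 12 pairs (exact), Kruskal–Wallis with 3 groups of 8, Quade
with 12 blocks × 3 treatments, sign-flip with 12 pairs (exhaustive 4096
flips; maxstat over 8 points), PLV surrogates with 20 trials and 199
permutations. The evoked/induced dissociation testbed uses 200 trials at
256 Hz with amplitude-5 components in amplitude-1 white noise. These sizes
keep the full suite fast while leaving the statistical checks
well-powered.

## Known limitations

- EDF import requires a single sampling rate across signals and returns
  values in each channel's native header unit; annotations import only
  through an explicit description→code map (unmapped ones are dropped with
  a warning). No other vendor formats are read.
- The exact Wilcoxon path declines tied data (falls back to the corrected
  normal approximation).
- Spline/SCD accuracy degrades towards the edge of an electrode cap, as
  with any extrapolating interpolant on partial coverage.
- Ocular-artifact decomposition (ICA) is out of scope; externally computed
  component time courses can be imported as ASCII and handled like any
  multichannel record.
- No cluster-mass permutation statistics; the duration criterion is the
  implemented relative. No cross-frequency coupling or coherence measures.
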