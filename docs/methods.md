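# Methods

## Signal model and detection rule

The target events are micro-scale hypoxic–ischemic spike transients:
brief (< 20 ms) oscillatory events with dominant frequency in the
80–120 Hz gamma band and peak amplitude at or above the 14 μV annotation
floor, riding on the strongly suppressed ECoG background of the ~6 h
latent phase after an asphyxial insult. A conventional EEG spike may last
up to 70 ms; the gamma transients of interest are far shorter.

Detection combines two per-sample conditions:

- a fixed raw-amplitude threshold λ₁ = 14 μV applied to the zero-meaned
  trace in physical units (never to a rescaled trace), and
- a moving threshold λ₂ ∈ (0, 1) applied to the band signal — the inverse
  FFT of the spectrum with every bin outside [80, 120] Hz zeroed — after
  normalization to unit peak absolute value.

A sample is labeled iff both hold. The rule is framed as a type-1 fuzzy
if–then with step memberships and a min t-norm, which reduces exactly to
the boolean conjunction; product t-norm and linear membership ramps
(`transition_uv`, `transition_band`) are available for experimentation but
are not the published behavior. Both thresholds are inclusive (≥).

Band isolation is a plain spectral mask: no taper, no windowing, DC and
Nyquist always zeroed, bins kept when k·fs/N ∈ [f_low, f_high]. Masking
ringing is tolerated; it is absorbed by λ₂. The whole record is
transformed at once (a 6 h, 1024 Hz trace is a ~22 M-point FFT, well
within memory); records are immutable and the pipeline is deterministic.
If the band signal's peak is at the numerical noise floor of the transform
(≤ 1e-9 of the raw peak), the record is treated as holding no in-band
energy and the detector returns no events rather than normalizing noise.

Point labels become events by merging consecutive labeled samples and runs
separated by less than `merge_gap_ms` = 10 ms — a spike is < 20 ms, so
sub-10 ms fragmentation (e.g. the carrier crossing zero) belongs to one
physiological event. The event center is the raw-amplitude peak (the
quantity experts annotate), not the band-signal peak. Merged groups longer
than `max_event_ms` = 70 ms are split at their largest internal gap, or,
if gapless, truncated around the peak; the truncation length is floored in
samples so a reported duration never exceeds the cap.

## Preprocessing

`zero_mean` precedes everything (the FFT mask's DC-zeroing makes the
detector invariant to constant offsets regardless). The optional FIR stage
is a 100th-order linear-phase Hamming design over normalized frequencies
0.05–0.13 (25.6–66.56 Hz at 1024 Hz). It is applied as a single forward
convolution in `same` mode, which removes the integer group delay of the
even-order symmetric filter without squaring the response (as
forward–backward filtering would), so the stated single-pass attenuation
(≥ 20 dB at the 46 Hz band center, ≤ 1 dB at 100 Hz) applies and event
timing — the currency of evaluation — is untouched. The stage defaults to
**band-stop**: its 25.6–66.56 Hz range covers the mains region and lies
below the 80–120 Hz target band, so rejecting it is the only internally
consistent reading; band-pass is selectable. The stage is disabled by
default and all performance statements are defined with it off.

## Wavelet band justification

`center_frequency` samples the mother wavelet at dyadic precision
(level 8, ≥ 2¹⁰ points) and takes the dominant peak of its magnitude
spectrum; for the biorthogonal rbio2.8 pair the decomposition wavelet is
used, matching the convention of the standard center-frequency estimator,
and gives f_c ≈ 0.58837 cycles/sample. The pseudo-frequency
f_p = f_c/(a·Δt) then maps integer scales to Hz; a·f_p is constant by
construction. The tabulated "wavelength" column is fs/f_p — numerically
the wavelet period in **samples** at fs (at 1024 Hz one sample is
0.977 ms, so the numbers are close to, but not equal to, milliseconds;
some tabulations label the column "ms").

`band_from_scales` rounds the extreme pseudo-frequencies outward to the
nearest 10 Hz; scales 5–7 give (80, 130), conventionally clamped to the
published 120 Hz upper edge, which is also where the spike energy sits.

The energy spectrum E_w(f) = (f_c·C_φ)⁻¹ ∫|T(f,b)|² db is computed over a
fine log-spaced fractional-scale sweep (64 scales spanning the requested
integer range) so the spectrum is a curve rather than three points. The
CWT kernel is the wavelet function resampled onto the signal grid at
dilation *a* with **1/a (amplitude-preserving) normalization**: with the
usual 1/√a energy normalization the integrated energy of a matched
oscillation grows ∝ a, which biases the spectrum peak a full scale low
(a 100 Hz tone would peak at ≈ 93 Hz); with 1/a the tone peaks at its
pseudo-frequency (102.1 Hz on the scale grid). C_φ is the numerically
evaluated admissibility integral ∫|Ψ(ω)|²/ω dω; it scales E_w uniformly
and is exposed in the result, but every check in this package uses peak
locations or ratios, never absolute energies.

## Evaluation

Matching is event-level: a detection and an annotation pair if their
centers lie within ±`tolerance_ms` (default 20 ms — one maximal spike
duration, far tighter than inter-spike spacing at observed rates); each
annotation takes at most one detection. The default greedy policy pairs
smallest |Δt| first (ties toward the earlier detection); the `optimal`
policy maximizes pair count via linear-sum assignment. The two provably
agree on conflict-free instances, which property tests check against an
exhaustive enumeration oracle for up to six events a side.

Overall performance is the unweighted mean of sensitivity and selectivity;
this convention is confirmed by the shipped cohort records, whose raw
TP/FP/FN sums reproduce the reported per-subject maxima to ±0.01
percentage points (±0.02 for subject e, a printed-rounding artifact: the
derived value 97.966 rounds to 97.97 against a printed 97.96). Degenerate
denominators (no annotations, or no detections) are reported as 100% with
an explicit flag rather than an error, because all-correct subjects are
conventionally scored 100%. The cohort summary reports mean and *sample*
(n−1) standard deviation unrounded — the seven reported maxima give
98.91 ± 1.06, which rounds to the reported 98.9 ± 1.0 only at one decimal;
the package reports the unrounded values and leaves rounding to the
caller. True positives are binned over the latent phase in half-open
30-min epochs (0–360 min post-insult); out-of-range events go to a
flagged overflow bucket.

## Synthetic scenes

The generator stands in for recordings that are not publicly deposited.
Its defaults define the reference study scene used throughout the tests:

| parameter | default | rationale |
| --- | --- | --- |
| fs, duration | 1024 Hz, 10 min | the native acquisition rate; long enough for ~50 events at realistic rates, short enough for seconds-scale tests |
| background | power-law PSD ∝ f⁻³, 5 μV RMS | see below |
| spikes | 50 × 25 μV, carrier U(80, 120) Hz, duration U(6, 18) ms | 25 μV on 5 μV RMS is a broadband SNR of 20·log₁₀(5) ≈ 14 dB; durations stay under the 20 ms ceiling |
| distractors | 10 sharp (70–120 ms, 20–45 Hz), 5 slow (250–500 ms, 1–3 Hz) | exercise the band condition: large-amplitude events with no gamma energy |
| placement | ≥ 100 ms center separation, uniform (or per-30-min rate profile) | keeps ground-truth events resolvable at the ±20 ms matching tolerance |

Transients are Gabor atoms: a Gaussian envelope whose full width at 5% of
peak equals the nominal duration, times a cosine carrier, rescaled to the
exact peak amplitude. The atom realizes the only two properties the
detector assumes — raw amplitude and in-band energy. Note that a 6–12 ms
atom is spectrally broad (σ_f ≳ 50 Hz): its periodogram peak can sit well
off the carrier (a bare 10 ms, 100 Hz atom peaks at 93.1 Hz), so
spectral-consistency checks use the 12 ms midpoint of the duration range,
where carrier, periodogram peak and wavelet-spectrum peak agree to a few
Hz.

**Background color.** Presets are `white` (flat PSD), `pink` (1/f),
`ecog` (1/f³, the default) and `mixture` (pink + white at equal power),
all high-passed at 1.6 Hz, with an arbitrary exponent available via
`background_exponent`. The default is deliberately much steeper than pink:
intracranial background falls off with PSD exponents of roughly 2–4 above
~75 Hz, and the suppressed post-insult latent-phase background even more
so. The choice matters quantitatively: a *pink* background at 5 μV RMS
carries ≈ 1.3 μV RMS inside 80–120 Hz — the same order as the λ₂ = 0.10
decision level — and floods the detector with on-the-order-of-10³ false
events per 10 min, whereas real suppressed ECoG supports near-zero false
detections at λ₂ = 0.10 over hours. With the f⁻³ default the gamma-band
background RMS is ≈ 0.1 μV and the detector round trip (sensitivity and
selectivity ≥ 95% at λ₁ = 14 μV, λ₂ = 0.10 on the seed-fixed reference
scene) holds, with typically 0–3 false events per 10-min scene across
seeds (an occasional scene dips a point below 95% selectivity at this
operating point; raising λ₂ one grid step removes the false events). The pink preset remains available (and its
periodogram slope is property-tested at −1 ± 0.3 over 1–100 Hz); scenes
built on it represent a far harsher noise environment than the recordings
the method targets.

All randomness flows from one integer seed through a single
`numpy.random.Generator`; identical seeds give bit-identical scenes.
Event placement is rejection sampling with a bounded number of tries, so
an infeasible packing (too many events for the separation constraint)
raises rather than loops.

**What passing on synthetic scenes does and does not show.** The
generator reproduces the amplitude/frequency/duration envelope of the
target events, gross background spectral shape, distractor morphologies
and latent-phase rate profiles. It does not reproduce non-Gaussian or
non-stationary background structure, electrode artifacts, seizure trains,
or the waveform diversity of real spikes; performance on these scenes
bounds the method's behavior under its stated assumptions and is not a
claim about real recordings.

## Numerical choices and degenerate inputs

- Sample indices are 0-based; annotation centers are stored as nearest
  integer samples; seconds↔samples conversions invert up to half-sample
  rounding.
- CSV is comma-separated with `#`-prefixed `key=value` header lines; the
  time column, if present, must be uniform to 1e-6 s. EDF is read-only
  (detections are events, not signals).
- Ties in the λ₂ sweep's best threshold go to the smallest λ₂; ties in
  greedy matching to the earlier detection.
- `normalize`/`unit_normalize` reject all-zero inputs; per-epoch
  normalization rejects epochs with an all-zero band signal.
- Amplitude thresholds are always applied in μV to the unscaled trace;
  max-abs normalization returns the scale so units can be restored.

## Known limitations

- Whether true-positive accounting in the original evaluation was
  per-point or per-event is not documented; the event-level matcher with
  a ±20 ms tolerance is this package's explicit formalization, and the
  tolerance is exposed in `MatchConfig`.
- The FIR stage's "if needed" application criterion is undocumented;
  the package leaves it off by default.
- Per-record band normalization is the default; per-epoch normalization
  (`epoch_s`) changes λ₂'s meaning across quiet/active epochs and is
  provided but unvalidated against any published operating point.
- The CWT pathway is provided for band justification (energy spectra),
  not as a production detector backend.
- Multi-channel montages, artifact rejection and streaming acquisition
  are out of scope.
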