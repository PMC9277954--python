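# Methods

## The approach

`usvkit` compares ultrasonic vocal activity between groups of animals
without segmenting or classifying discrete calls.  Instead of asking "where
does each call start and end, and what type is it?", the pipeline asks
"what short spectral events occur, how often, and with what spectrum?":

1. **Fragmentation.** Every recording is resampled to a common analysis
   rate (250 kHz) and tiled into contiguous, non-overlapping 6-ms
   fragments.
2. **Detection.** The whole clip is high-pass filtered at 15 kHz
   (zero-phase 4th-order Butterworth), and every fragment whose RMS power
   exceeds a threshold becomes an *ultrasonic fragment* (USF).  The
   threshold is the pipeline's single user-facing knob.
3. **Featurization.** Each USF's 15–100 kHz spectrum is summarized by 16
   mel-frequency cepstral coefficients (MFCCs).
4. **Embedding and clustering.** MFCCs pooled over all clips of an
   experiment are embedded in 3-D by Barnes-Hut t-SNE (perplexity 500) and
   clustered by DBSCAN (eps 1.5, minPts 50) or by user-defined convex
   regions.  Clusters judged non-vocal can be flagged as noise and are
   excluded from every downstream analysis.
5. **Analysis.** Per-cluster mean power spectral densities (PSDs),
   count-scaled group spectral profiles, per-session counts with
   categorical summaries, vicinity/repeatability curves and validation
   metrics against ground-truth annotations.

The underlying assumption is that a 6-ms fragment is short relative to any
call of interest, so calls appear as *runs* of similar fragments; group
differences in call usage then surface as differences in cluster occupancy
and in cluster spectra, with no model of call structure required.  The
price is the loss of call-level structure and sequence information, which
this package deliberately does not attempt to recover.

## Detection details

**Filter-then-fragment.** The high-pass filter is applied to the whole
clip before tiling, not per fragment: filtering 1,500-sample chunks would
put edge transients into every fragment.  Zero-phase (forward–backward)
filtering keeps fragment timestamps unshifted and doubles the nominal
stop-band attenuation (≈77 dB at 5 kHz for the default order).

**Power statistic.** "Power" is the RMS amplitude of the filtered
fragment in full-scale units.  RMS is monotone in fragment energy, so any
threshold on it yields nested detection sets: detections at a higher
threshold are always a subset of detections at a lower one, which is the
property the monotonicity analyses rely on.

**Noise-relative thresholds.** An absolute RMS threshold is tied to the
recording gain.  The default mode therefore resolves the threshold per
clip as `k × median(fragment power)`: the median fragment of a recording
is silent background, so it estimates the noise floor robustly even in
call-rich sessions.  The multiplier ladder `(1.2, 1.5, 2.2, 2.7, 3.5)`
spans permissive to conservative settings; the permissive end starts just
above 1 because `k = 1` would sit exactly at the noise median and admit
half of all silent fragments by construction.  Absolute mode is retained
for gain-calibrated setups.

## Features

The MFCC pipeline is: Hann window over the whole 1,500-sample fragment →
magnitude spectrum (zero-padded to 2,048 points) → 32 triangular filters
equally spaced on the mel scale between 15 and 100 kHz → log energies with
a floor of 1e-10 full scale → orthonormal DCT-II → first 16 coefficients.

Choices worth noting:

- **One frame per fragment.** A 6-ms fragment is a single analysis frame;
  no sub-frame averaging, no delta coefficients, no cepstral mean
  normalization.
- **Coefficient 0 is kept.** c0 carries overall log-amplitude, so the
  embedding separates fragments by amplitude as well as spectral shape.
  Scaling a fragment's amplitude provably moves only c0 (a constant offset
  of the log filterbank energies lies in the DCT's 0th basis vector) — a
  property the test suite asserts.
- **32 filters for 16 coefficients** gives standard 2× headroom between
  filterbank resolution and cepstral order over this one-band setup.
- The log floor makes all-zero fragments produce finite (constant)
  feature vectors rather than −∞.

## Embedding and clustering

t-SNE is run with the Barnes-Hut approximation (θ = 0.5), three output
dimensions and a fixed seed; the pipeline is bit-reproducible for a fixed
seed.  When fewer than `3 × perplexity + 1` points are pooled, perplexity
is reduced to `floor((N−1)/3)` with a warning — small corpora would
otherwise be rejected outright.

DBSCAN runs on the 3-D t-SNE coordinates, not on the raw 16-D features.
t-SNE distances are not metric-faithful, but clustering the embedding is
what keeps manual region definitions and the automatic clustering mutually
consistent — both operate on the same space the analyst sees.  Outliers
keep label 0; clusters are renumbered 1..K by descending size.  Border
points of DBSCAN are order-dependent by construction; tests therefore
constrain core-point labels only.

Manual regions are ordered convex polytopes (vertex lists); the first
region containing a point wins.  Noise flagging is always an explicit
user decision; `suggest_noise_clusters` offers an advisory heuristic —
a cluster is suggested as noise when its peak PSD bin holds less than 5%
of its total band power, i.e. when no carrier-like concentration exists.

## Spectral analyses

All spectral estimates use 512-sample Hann windows with 50% overlap at
250 kHz (488.28-Hz bins).  A fragment's PSD is the Welch average of its
~4 overlapping windows; a cluster's PSD is the mean over member
fragments, so the count-weighted mean of cluster PSDs equals the grand
mean exactly (asserted to 1e-9 relative tolerance).  A group's spectral
profile is `Σ_c count_c × meanPSD_c` over non-noise clusters — clusters
contribute in proportion to their occupancy.  Peak frequencies are global
argmaxima with ties broken toward lower frequency; normalization to unit
peak is applied only for display, never for computation.

## Temporal analyses

**Vicinity curves.** For a focal cluster, the curve gives the probability
(mean indicator over focal fragments) that a fragment of another cluster
starts in each 6-ms lag bin within ±0.5 s.  83 bins of 6 ms per side
cover ±498 ms (0.5 s is not an integer multiple of the bin width).  For
same-cluster curves the focal fragment is excluded from its own lag-0
bin; otherwise the center bin would be identically 1 and carry no
information.  "At least one occurrence in the bin" is used rather than
expected counts, so probabilities stay in [0, 1].

**Repeatability half-width.** The same-cluster curve has a central peak
whose width tracks call duration: a call spanning n fragments contributes
same-cluster neighbors at lags up to ±(n−1) bins with linearly decaying
frequency, so the full width at half maximum of the peak approximates the
call duration.  The implementation treats the bin at lag k·6 ms as the
interval ((k−1)·6, k·6] ms and interpolates linearly between interval
centers; the peak is the larger of the two innermost bins.  A curve equal
to 1 at ±6 ms only therefore has half-width exactly 12 ms.

**Session summaries** count non-noise fragments per cluster per session.
Totals are categorized *low*/*high* strictly around 600 (the boundary
value falls in *low*); per-cluster counts are binned with strict
thresholds at 10 and 50.  Pearson correlations (r, r², two-sided p) are
computed with `scipy.stats.pearsonr`; inputs shorter than 3 or constant
are rejected.

## Validation metrics

Fragment intervals are half-open, `[start, start + 6 ms)`.  A call is
detected when ≥ 1 fragment interval intersects it; duration coverage is
|union of fragment intervals ∩ union of call intervals| / |union of call
intervals|; a fragment is a false positive when it intersects no call.
Overlap is purely temporal — annotation frequency bands are carried for
synthesis and future use but do not enter the metric.  Scoring is per
clip and pooled.

## The synthetic generator

The generator emulates the rodent repertoire the pipeline is meant to
separate:

- **aversive-like** calls: flat, 20–30 kHz, 150–800 ms (the natural upper
  range extends to 3 s; the default cap keeps desk-scale sessions from
  being dominated by a single call);
- **appetitive-like** calls: 40–80 kHz, 10–150 ms, drawn as flat tones,
  linear sweeps (5–15 kHz span) or trills (sinusoidal FM, ±5 kHz depth,
  30–80 Hz rate);
- **strain presets** `mouse_low` / `mouse_high`: short calls with carrier
  frequencies drawn from N(40 kHz, 2 kHz) / N(60 kHz, 2 kHz), a spread
  wide enough to be realistic and narrow enough that a 100-call corpus
  has a well-defined group spectral peak.

Calls are phase-continuous sinusoids with 2-ms raised-cosine ramps,
scheduled at non-overlapping random onsets (≥ 50 ms apart).  The noise
bed is white Gaussian broadband noise plus Poisson-scheduled (0.5/s)
20-ms impulsive bursts band-limited to 2–8 kHz at 5× the broadband RMS —
a stand-in for cage knocks that the 15-kHz high-pass must remove.  Call
amplitudes are set from a target SNR measured against broadband noise
power inside the 15–100 kHz band (default 20 dB, jittered ±2 dB per
call).  Annotation bands are the emitted frequency extent widened by the
Fourier limit (±0.5/duration).

Every session derives from one explicit seed; corpora spawn per-session
seeds from a root seed via `numpy.random.SeedSequence`.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: reverberation and echoes, microphone
directionality and distance-dependent attenuation, amplitude modulation
within calls, harmonic stacks, overlapping simultaneous callers, and
non-stationary background (fans, movement broadband).  Detection and
spectral-recovery figures on this corpus are best-case values for clean,
well-gained recordings; the structural properties (threshold
monotonicity, PSD identities, oracle equivalences) are data-independent.

## Problem sizes and numerical choices

Synthetic studies run at desk scale: the validation corpus is 6 × 60-s
sessions (a few thousand fragments), strain corpora are 100 calls
(~1,000 fragments each), and the frequency–duration study uses 2 × 60-s
sessions of four coupled call types.  At these sizes the perplexity
auto-reduction is active, and DBSCAN at (1.5, 50) yields one cluster per
well-separated call family.  Degenerate inputs are handled explicitly:
clips shorter than one fragment yield an empty fragment list with a
warning; fewer than 10 pooled fragments skip embedding and clustering;
all-zero fragments produce finite features and all-zero PSDs; empty
clusters, all-zero curves and constant correlation inputs raise errors
naming the offending quantity.

## Known limitations

- Absolute threshold values are not comparable across gains; only the
  noise-relative mode is portable.
- Fragment-level detection gives call *sampling*, not call boundaries:
  duration coverage of long calls with internal silent gaps is
  structurally below 100%.
- DBSCAN on t-SNE coordinates inherits the embedding's scale, which
  varies with corpus size; for very large pooled corpora the fixed
  (eps, minPts) may need revisiting.
- The repeatability half-width is a duration proxy only when calls of a
  cluster repeat with inter-call gaps longer than the call itself.
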