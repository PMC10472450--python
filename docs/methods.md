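# Methods

This note documents the models, parameter choices and numerical
decisions behind `bcgkit`, and what its synthetic validation does and
does not demonstrate.

## Signal model and pre-processing

The BCG channel is modelled as a train of W-shaped cardiomechanical
complexes (H, I, J, K, L and the smaller M, N deflections) superposed on
residual respiration (~0.2–0.5 Hz), broadband sensor noise and
occasional large motion artifacts. Pre-processing applies a linear-phase
FIR bandpass (default 1–20 Hz) designed by the Hamming-window method
with transition width 0.5× the lower edge, giving >53 dB attenuation at
half the low cutoff and <1 dB passband ripple; the group delay is
compensated exactly (odd tap count, centred convolution) so annotations
live on the raw time axis. Records are processed in 10 s segments with
2 s pads on each side; beats whose J falls in a pad belong to the
neighbouring core, which removes boundary duplicates.

The ECG (used only as the evaluation reference, never inside the
detector) gets a 50 Hz IIR notch (Q = 30, zero-phase), a 1–40 Hz FIR
bandpass, and baseline removal by a cubic spline through per-second
medians — a robust "segmented fit" that leaves R spikes in place. R
peaks are local maxima above half the median of the eight largest
maxima, at least 0.3 s apart. On noise-free synthetic ECG this recovers
every R within one sample, which is all the reference role requires.

A sample-level amplitude screen marks motion-artifact spans: samples
exceeding 5× the record's normal-scaled median absolute deviation,
grouped into runs (gaps under 0.3 s closed), kept when longer than 0.5 s
and dilated by 0.25 s. Heartbeat lobes exceed the threshold only for
tens of milliseconds and are never flagged. Detected beats inside masked
spans are discarded; reference (ECG) beats there still count in coverage
denominators, mirroring how motion-corrupted data depress coverage in
real recordings.

## STFT band-energy locator

S(t) sums the magnitudes of the STFT coefficients over the J-wave band
(4.5–7 Hz) with a Hann window centred on every sample (hop = 1).
Magnitude (not power) summation keeps S(t) linear in signal amplitude,
which the 3× prominence rule below relies on. The transform length is
the next power of two ≥ 4·fs (1024 at 250 Hz) so the band holds ~11
interpolated bins even at the shortest window; the implementation
evaluates only the in-band DFT bins as a windowed matrix product, which
is numerically identical to the FFT values at those bins (verified to
1e-8 in the tests).

The window length w<sub>t</sub> controls a resolution/robustness
trade-off: short windows track the J wave closely but leave spurious
S(t) lobes; long windows smooth the curve at the cost of temporal
correspondence. The adaptive rule starts at 0.3 s — a floor justified by
the maximum plausible resting heart rate (~200 bpm ⇒ 0.3 s beat
interval) — and grows in 0.1 s steps until **every** retained candidate
peak exceeds 3× every other local maximum within ±w<sub>t</sub>/2
(candidates without competitors pass vacuously), capping at 1.0 s. The
universal quantifier is deliberate: requiring only one dominating peak
would terminate at 0.3 s on almost any noisy record and defeat the
rule's purpose. The existential reading remains available via
`prominence_quantifier="any"`.

Candidate beats are S(t) maxima at least 0.3 s apart, resolved greedily
from the highest amplitude. With the generator's full HIJKLMN
morphology, trailing L/M/N lobes contribute small satellite S(t) peaks
(~8 % of the main lobes); these survive the candidate stage by design
and are eliminated later by fusion and the beat-gap floor.

## EMD / EEMD

EMD is implemented by classical sifting: cubic-spline envelopes through
the maxima and minima, iterated until the Cauchy SD criterion falls
below 0.2 **and** the candidate satisfies the IMF property (extrema and
zero-crossing counts differing by ≤ 1), capped at 50 iterations; modes
are extracted until the residue is monotone or has fewer than three
extrema. Envelopes use natural cubic splines through the extrema with
two extrema mirrored beyond each record end, which (together with the
2 s segment pads) contains the edge effect. The decomposition is exactly
additive by construction, asserted to 1e-9 in the tests.

EEMD decomposes an ensemble of copies perturbed with white noise of SD
N<sub>std</sub>×(signal SD) and averages modes index-wise. Defaults are
N<sub>std</sub> = 3 % — inside the conventional 1–5 % range, enough to
regularize the extremum distribution without biasing mode shapes — and
N<sub>E</sub> = 100. The residual ensemble noise is the mean of the
added noises, so its RMS concentrates at N<sub>std</sub>·SD/√N<sub>E</sub>
(0.3 % of signal SD at the defaults); the tests allow a 1.15× margin for
the chi-distribution fluctuation of a finite-length RMS. Both the
canonical √-relation and the linear ratio N<sub>std</sub>/N<sub>E</sub>
are reported in the decomposition config, and a warning is raised when
the residual level exceeds the conventional 0.01. With
N<sub>std</sub> = 0 the function reduces bit-exactly to plain EMD.

The cardiac IMF is chosen by the largest fraction of periodogram power
inside the J band (ties to the lower, higher-frequency index), with the
dominant frequency required to fall in the admissible 1–12 Hz cardiac
band when possible. This selector is a package decision validated only
against the simulator; no principled universal rule exists.

## Fusion rules

For each S(t) candidate the nearest IMF peaks strictly left and right
are examined against a ±40 ms region (a quarter of the ~160 ms average
IJK width):

* exactly one peak in the region → it is the J wave;
* both in the region → the nearer wins (rare by construction; ties go
  left, a deterministic choice on the I-wave side);
* neither in the region → the candidate has drifted toward a dominant H
  or L lobe. The drift direction is persistent over short time spans, so
  the median sign of the last 9 signed offsets (chosen J − candidate)
  decides left vs right; a counting variant is available via
  `trend_rule="count"`. If the trend-consistent peak is more than twice
  as far as the other, the nearer peak is taken instead — a deviation
  that large contradicts the normal-morphology assumption.

With no history yet (record start) the trend degrades to
nearest-candidate. Duplicate choices by adjacent candidates collapse to
one beat, and a chosen J closer than 0.3 s to its predecessor is
dropped, which also disposes of the satellite-lobe candidates.

I is the first local minimum left of J (K right) that lies below −0.5×
the IMF peak threshold and is separated from J by a zero crossing,
searched within 0.3 s; beats missing I or K keep their J for rate
estimation but are excluded from morphology (`valid=False`). Positions
are then refined to the matching extremum of the raw filtered signal
within ±12 ms. (A literal ±3 ms window would be sub-sample at 250 Hz;
±12 ms = ±3 samples is the package's reading, exposed as `refine_ms`.)
Finally, J-J intervals outside [0.6, 1.67]× an 11-beat running median —
±40 % of the local rate, wide enough to pass true HRV — mark their
terminal beat for linear interpolation and invalidation. Interpolated
beats are excluded from HRV by default (configurable).

## HRV conventions

SDNN uses the population denominator n; MSSD is the RMS of the n−1
successive differences; pNN50 is reported as a proportion (the count is
also exposed) because published per-subject values of ~0.06 are
dimensionally proportions. Spectral indices come from a Welch
periodogram (256-sample Hann segments, 50 % overlap) of the tachogram
cubic-interpolated to 4 Hz and mean-detrended: LF = 0.04–0.15 Hz,
HF = 0.15–0.4 Hz, TP = 0.0033–0.4 Hz. Interval series built from beat
indices drop intervals outside [0.3, 3) s — gaps across masked artifact
spans — as is standard when cleaning a tachogram of ectopy.

## Evaluation machinery

The reference detector is ECG-gated ensemble averaging: epochs
[R, R + 0.6 s) of the filtered BCG are arithmetically averaged, the
template J is the average's global maximum and I/K its flanking minima,
and per-beat waves are epoch extrema within ±25 ms of the template
offsets. (The literature sometimes calls this "geometric averaging";
since BCG epochs are signed, a literal geometric mean is undefined and
plain ensemble averaging is used.) Heart-rate agreement pairs each R
with the unique unused J in (R, R + 0.4 s] and compares instantaneous
rates 60/RR vs 60/JJ for consecutive matched beats; coverage is the
percentage of reference beats matched. MAE/MAE%/RMSE, Bland-Altman bias
with 1.96-SD limits and a paired t-test summarise each comparison.

## Synthetic generator: scope and honesty

Beat waves are Gaussian lobes with per-wave latency/amplitude/width
(defaults: I at −80 ms and K at +80 ms around J, giving the typical
~160 ms I-K width; H/L at ∓150 ms). Gaussians are used instead of
recorded templates because their extrema are known analytically, which
makes the ground truth exact: true I/J/K are the extrema of the clean
beat train before respiration/noise are added. Inter-beat intervals are
60/HR plus a sinusoidal RSA component (default 0.3 Hz, 20 ms depth) and
white jitter scaled so the sample SDNN matches the 40 ms target, clipped
at the 0.3 s floor. The ECG is a stylized R-spike train at a fixed
250 ms R→J latency (within the 203–290 ms range reported for supine
adults); only R timing matters for evaluation. Defaults: white noise SD
5 % of the J amplitude, 0.5 motion bursts/min of 1 s at 6× J (band-
limited 1–12 Hz, Hann-tapered), chosen as representative of a quiet
supine bed recording; no SNR was published for the original recordings,
so these noise levels are a package decision and are documented as
synthetic.

What passing the synthetic suite shows: the implementation honours its
stated contracts (additivity, determinism, rule fixtures) and the
pipeline recovers beats under the simulated difficulty (in-band noise,
H/L dominance, artifacts, RSA). What it does not show: performance on
real sensors, whose beat morphology varies within and across subjects,
whose noise is structured, and whose artifacts are not band-limited
bursts. The published per-subject benchmark tables bundled with the
package anchor expectations on real data; only their summary arithmetic
is recomputed here.

## Problem sizes

The test and acceptance workloads use 30–60 s records at 250 Hz
(10–11 records end-to-end, N<sub>E</sub> = 100), 512–1000-sample EEMD
contract fixtures over 20 seeds, and the full 12-subject benchmark
tables — sizes at which every stage's behaviour is already exercised at
its defaults.

## Known limitations

* EEMD can still mix modes on hard-mode segments (L ≥ J); when the
  cardiac IMF carries L-dominated peaks the fusion rule has no correct
  peak to choose, and localized beat losses follow (observed on one
  hard-mode segment as an ~87 % hit rate for that record). Mode merging
  is left configurable off.
* L, M and N waves are not annotated; the ensemble-averaged modes
  nearly erase them, so only the IJK-complex is claimed.
* Streaming/real-time operation and multi-channel fusion are out of
  scope.
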