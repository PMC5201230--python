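# Methods

This note records the measurement model, the parameter choices that matter,
what the synthetic test-bed does and does not emulate, and the places where
the design was genuinely open.

## Signal model and coordinate conventions

All times are milliseconds from the start of the record or beat, with
0-based sample indexing and half-open windows `[start, end)`; amplitudes are
microvolts. Median beats are defined at exactly 1 ms resolution with the QRS
trigger (R apex) at `alignment_ms` = 300 ms. A median beat has no literal
"next QRS", so wherever the algorithm needs one (search-window end, offset
cost) it is projected as `alignment_ms + median_rr_ms`.

## Preprocessing

* **Baseline removal.** One isoelectric knot per beat at trigger - 80 ms (a
  PR-segment proxy), amplitude = median over a 20 ms window; a cubic spline
  through the knots is subtracted lead-wise. Outside the knot span the
  spline is continued *linearly* — cubic extrapolation at record edges can
  diverge by hundreds of microvolts, and a linear tail keeps the edge beats
  usable. Residual wander after subtraction is a few microvolts within the
  knot span for 0.3 Hz wander at physiological trigger rates; the first and
  last inter-knot intervals are less accurate, which is one reason the
  median beat matters.
* **QRS triggers.** A deliberately simple substitute detector (the package
  accepts external annotations, which bypass it entirely): across-lead RMS
  of the 5-25 Hz zero-phase band-passed signal, squared derivative, peaks
  above 30% of the running 2 s maximum, 200 ms refractory, detections within
  100 ms of the record edges discarded (filter transients), each detection
  refined to the RMS apex within +/-50 ms so triggers land on the R apex.
  It is adequate for clean 10 s resting segments; it makes no claim on
  arrhythmia, poor signal quality or exercise recordings.
* **Median beat.** Window `[trigger - 300 ms, trigger + post)` with
  `post = min(0.9 RR, max(700, 0.65 RR))` ms; the lower bound guarantees
  room for the T-wave search window (40% of RR) plus the tangent tail at any
  RR, the 0.9 RR cap keeps windows inside one cycle at short RR. Sample-wise
  median across aligned beats (at least 3), then cubic-spline upsampling to
  1 kHz. The median needs no beat-quality scoring at the noise levels it is
  meant for; a single corrupted beat is absorbed by construction.

## Vector magnitude lead

X, Y, Z are fixed linear combinations of the 8 independent leads
(I, II, V1-V6). The bundled 3x8 coefficient file is the Kors regression
matrix, chosen because its published values are unambiguous and widely
reproduced; any other matrix (e.g. a Guldenring variant) can be supplied as
a plain-text 3x8 table via `vm_lead.load_transform_matrix` or the
`transform` argument — the delineator is agnostic to the particular
reconstruction. Because the transform is linear and the median is taken
before it, transforming before or after median construction differs only
through the non-linearity of the final norm; the package transforms the
median beat.

## Delineation

All stages measure on the **zero-phase low-pass filtered** beat (4th-order
Butterworth, 25 Hz) and its central-difference derivative. Filtering only
the derivative while reading amplitudes off the raw signal would make the
apex location (an argmax on a flat-topped wave) the noisiest quantity in the
pipeline; measuring everything on one filtered signal keeps T-peak jitter
near 1 ms at realistic median-beat noise. Zero-phase filtering preserves
fiducial timing; 25 Hz passes T-wave content (a few Hz) essentially
untouched.

Parameters with their defaults and reasons:

| parameter | default | role |
|---|---|---|
| window start | J-point + 25 ms | clears the J-point transition |
| window end | alignment + 0.40 RR | rate-adaptive T-peak bound; the trigger is the only rate-linked landmark in a median beat |
| min candidate width | 10 ms | rejects noise ripples in the derivative |
| minVoltage | 100 uV | amplitude floor for any detection |
| merge threshold | valley >= 0.90 x lower apex | two humps with a shallow valley are one peak |
| remove threshold | gap > 0.50 x largest apex | a dwarfed second peak is not a notch |
| convert threshold | limb angle < 5 deg | a peak with one flat side behaves as a slur |
| cost weights w1, w2 | 0.5 / 0.5 | equal weighting is the minimal assumption |
| tie-break | earliest candidate | determinism |

The cleanup thresholds and cost weights are exposed in
`DelineationConfig`; the values above are defaults chosen for qualitative
behavior (merging genuine near-equal humps, not deleting real notches), not
fitted constants.

Candidate labeling uses the continuity argument directly: a candidate runs
from a derivative local maximum to the following local minimum, so a peak is
present exactly when the derivative is positive at the rise and negative at
the fall. Slur limb slopes are least-squares line fits between the bounding
derivative extremum and the apex; when that span is degenerate (a trailing
slur's apex coincides with its rise, because amplitude is monotone across
it) the limb slope falls back to the smoothed derivative over a 5 ms window.
Angles take the inverse tangent of slopes in uV/ms — they are
unit-convention dependent, so the ms/uV convention is fixed package-wide.
The candidate-pair "junction" is the intersection of the peak's falling and
the slur's rising limb lines, the line-geometry analogue of the valley
between them. The "rotation" feature composes an inverse tangent with a
value already in degrees; the published feature table defines it that way
and it is kept literally, since only its ordering matters to a tree split.

**T-peak choice.** With several surviving peaks the highest one is selected
(the algorithm statement); an alternative reading ("first discernible
peak") exists in the literature and differs only for near-equal notches.
The selected-versus-secondary distinction is reported (`notched`,
`secondary_peak_ms`) so downstream users can audit those beats.

**Energy signal.** The cumulative rule increments by `|d|` when the
derivative rises sample-to-sample and decrements by `|d|` otherwise; the
normalization `(max - E)/(max - min)` orients the signal so a convex
decaying tail starts at 1 and ends at 0, and a flattening shelf produces an
interior local minimum — the offset-candidate generator. This is one
consistent reading of a qualitatively described construction; its role is
only to offer earlier offset candidates when the tail flattens before the
tangent projection, and on clean tails it leaves the tangent offset
untouched.

**Relevance tree.** The three features retained after pruning are the slur
two-slope angle, the peak-falling/slur-rising angle, and the amplitude ratio
peak / slur-bisector-origin (the feature table marks this ratio variant as
the selected one; prose summaries call it the "slur/peak amplitude ratio").
The original training ECGs are not available, so the bundled tree is trained
(CART, depth 4, balanced class weights, fixed seed) on a synthetic corpus of
500 labeled examples: pronounced terminal shoulders (the slurred morphology,
label *relevant*) versus tiny narrow trailing bumps at 8-18% of the peak
amplitude (label *irrelevant*). Balanced weights encode that missing a
genuine terminal shoulder costs ~10-15 ms of T-end error while keeping a
spurious slur is nearly free. The corpus is deliberately clean and the two
populations are separable; held-out accuracy is above 0.95. The tree is
serialized as JSON data, overridable per call, and traversed without any
model library at run time (`<=` goes left at a threshold tie).

## Synthetic test-bed

T-waves are sums of Gaussian bumps, the QRS three narrow Gaussians; beats
are placed on the X lead and spread across the 8 independent leads by the
pseudo-inverse of the bundled transform, so the reconstructed vm equals the
template exactly and the analytic truth carries through the full pipeline.
Ground truth comes from a dense 0.05 ms grid over the noiseless T
components: T-peak is the argmax (local maxima >= 100 uV decide notching),
T-end is the tangent at the steepest descent past the terminal component's
center. For an isolated terminal Gaussian this equals `center + 2 width` in
closed form; the generated parameter ranges keep the closed form within
0.5 ms of the dense-grid value, which pins down the shoulder geometry of
the slurred class (wide shoulders, about 2.5 main-widths out, 50-58% of the
main amplitude — far enough to carry the terminal decay, close enough that
the derivative never crosses zero and the shoulder stays a slur rather than
a secondary peak).

Reference conditions: RR 950-1100 ms; normal T 250-500 uV with width
25-38 ms; flat T 105-150 uV, width 35-50 ms; notched humps 60-85 ms apart
with width 18-24 ms and amplitude ratios kept away from 1 so the primary
hump is unambiguous; white noise 5 uV and 0.3 Hz / 150 uV baseline wander on
records; a drug effect is a 12 ms delay of all T components plus 6 ms
widening of the terminal one. What the generator does **not** emulate:
physiological T-wave asymmetry beyond Gaussian mixtures, beat-to-beat RR
and morphology variability within a record, muscle/electrode artifacts,
U-waves, and arrhythmia. Passing tests therefore demonstrate correctness of
the measurement chain and its noise behavior at clinical noise scales — not
clinical-grade validation on real ECGs. In particular the intra-time-point
replicate SDs on synthetic studies (fractions of a millisecond) are far
below values on real trials (a few milliseconds), because replicates differ
only by additive noise, not by physiological state.

## Numerical choices and degenerate inputs

* Derivative extrema are strict (`<` / `>`), making candidate enumeration
  identical to a plain brute-force scan; ties on a flat plateau produce no
  extremum, which is irrelevant off a measure-zero set.
* The tangent uses the discrete steepest sample; at 1 kHz this bounds the
  offset error well inside the 2 ms test tolerance.
* Unmeasurable beats (empty window, no candidate above the floors, no
  surviving peak, no descending limb) return a flagged `FiducialSet` with a
  machine-readable reason code instead of raising; caller contract
  violations raise typed exceptions.
* Everything downstream of fixed inputs is deterministic: no randomness
  outside the synthetic generator, ties broken earliest, serialization
  byte-stable.

## Known limitations

The search window's 40%-of-RR end is anchored at the trigger; at extreme
tachycardia the window degenerates and the beat is flagged rather than
measured. The substitute QRS detector and the pluggable rate corrections
(Fridericia for QT; power-law with exponent 0.58 for J-T<sub>peak</sub>)
are conventional choices, not contributions of this package. Exposure-
response modeling and human-review workflows are out of scope.
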