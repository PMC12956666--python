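# Methods

This note records the models, conventions and design choices behind
`eegmdh`, in the order the pipeline runs.

## Signal model and feature conventions

A trial is a time × channels matrix of preprocessed (normalized,
7–31 Hz bandpassed) EEG.  The loader accepts any epoch length ≥ 2 samples
and any channel count ≥ 1; the defaults mirror the reference setting of
16 channels at 125 Hz.  Epoch duration is not pinned by the reference
protocol; the generator defaults to 4 s (500 samples), which sets the
spectral resolution fs/N = 0.25 Hz.

Spectral features use the plain unnormalized one-sided DFT on a rectangular
window over the full epoch — no Welch averaging, detrending or zero padding
— because the band-power definition is a plain sum of |X(f)|² over bins.
Consequences worth knowing:

- **Inclusive band limits.** A bin exactly on a shared boundary (4 Hz
  between delta and theta, say) is counted in *both* bands.  This matches
  the summation limits as defined; with a 0.25 Hz grid the affected bins are
  exactly the integer boundaries.
- **DC exclusion for the dominant frequency.** The argmax runs over
  positive-frequency bins only; otherwise any nonzero mean would win.  Ties
  break toward the lower frequency, making the statistic deterministic.  A
  channel with no positive-frequency power (a constant signal) raises an
  error naming the channel rather than returning an arbitrary number.
- **Amplitude-statistic asymmetry.** Mean and standard deviation operate on
  |x[n]| (population normalization, divide by N), while the median operates
  on the signed samples — the formulas are implemented as defined, and the
  asymmetry is deliberate, not a bug.
- On 7–31 Hz bandpassed data the delta band (0.5–4 Hz) and most of gamma
  (30–50 Hz) are near zero.  They are still computed — the 10-feature layout
  is part of the contract — and the standardizer passes constant columns
  through untouched.  A two-band sensorimotor variant (μ 7.5–12.5 Hz,
  β 16–31 Hz) is selectable via the band configuration.

## The GMDH network

Quadratic two-input neurons are fitted by ordinary least squares on the
design [1, x₁, x₂, x₁², x₂², x₁x₂].  The public single-neuron fit uses the
minimum-norm solution, so degenerate designs (constant or duplicated
columns) are well defined.  Layer construction solves the 6×6 normal
equations for all candidate pairs in one batched pass (chunked at 2048
pairs); any pair whose system is singular falls back to the per-pair
minimum-norm solve.  With 160 inputs, layer 1 fits all C(160,2) = 12,720
candidates in well under a second, so the optional seeded
`max_candidate_pairs` subsample is a convenience for very wide inputs, not a
requirement.

Selection uses the classical GMDH regularity criterion: MSE on an internal
validation split.  The split is a seeded shuffle of the training rows at
fraction 0.25 (the reference procedure invokes a validation set without
specifying fraction or criterion; these are this package's choices).
Candidates are ranked by ascending criterion with lexicographic (input_a,
input_b) tie-breaking; a layer keeps min(width, n_candidates) units, so on
tiny inputs the realized width can fall below the nominal schedule (logged,
and reflected in `realized_widths()`).

Two further structural choices keep the arithmetic accounting exact:

- **Previous-layer-only wiring.** Layer *l* consumes only layer *l−1*
  outputs (no passthrough of raw features), so the per-sample cost is
  exactly 8 multiplications and 5 additions per retained neuron.
- **Selected, not refitted, output.** The single output is the best neuron
  of the last layer.  Adding a fresh combining neuron would change the
  parameter count; selection keeps 6 × Σ widths exact — 996 for the full
  decremental schedule.

**Multiclass encoding.** A single output neuron cannot represent 8 classes
without an encoding.  The default is ordinal regression on the numeric class
code 1..8 with round-and-clamp decoding — the only reading consistent with a
single output and the reference parameter count.  This induces an ordering
on the classes; for the synthetic study the class signatures are constructed
so dominant frequency increases with class code, making the ordinal target
natural.  Users who reject the induced structure can select
`encoding_mode="one_vs_rest"` (K parallel networks, argmax decoding, K× the
parameters).

Features are z-scored using training rows only before layer 1.  Polynomial
terms are scale-sensitive; standardization keeps the least-squares systems
well conditioned.  Depth is fixed by the schedule (default 8 layers); there
is no early stopping at the criterion minimum, matching the fixed-depth
design under study.

## Evaluation protocol

The 70/30 split is stratified by default (an unstratified flag exists for
the strict "randomly selected" reading); 480 balanced trials give 336/144.
Cross-validation is stratified 5-fold with every sample tested exactly once;
standardization and the internal GMDH split are re-fitted inside each
training fold, so no test information leaks.  Zero-denominator precision or
recall is defined as 0.  Reported percentages are rounded only at the
reporting layer.

The depth ablation truncates the base schedule for depth ≤ 8 and extends it
by repeating the final width (5) beyond — the extension widths are this
package's choice, as no reference values exist past the reference depth.
The feature ablation masks columns of the electrode-major layout: frequency
= band powers + dominant frequency (6 per electrode, 96 columns), time =
mean/std/median/ptp (4 per electrode, 64 columns).

## Synthetic data: what it does and does not show

The generator encodes class structure spectrally: each of the 8 classes has
a distinct dominant sinusoid (evenly spaced over 8–30 Hz) plus weaker
band-limited components whose alpha/beta gains trade off across classes.
Subjects differ by one amplitude scalar (s.d. 0.10), channels by random
phase, and white Gaussian noise (s.d. 2.5 against a unit-amplitude dominant
component) is added before an exact frequency-domain 7–31 Hz mask.  The
noise level was calibrated once so the default pipeline lands near but below
ceiling (≈93–97 % held-out accuracy across seeds) — a regime where the
ablations show variation rather than saturating.

Deliberately absent: 1/f background, event-related
desynchronization/synchronization dynamics, volume conduction, artifacts,
and per-subject frequency shifts.  The subject effect being amplitude-only
makes the subject-dependent protocol's assumption (same-subject
characteristics in train and test) explicit.  Passing tests on this data
therefore demonstrate that the pipeline recovers class-conditional spectral
structure of the kind the features target — not that real-EEG accuracies
are reproduced.  In particular, the time-domain-only ablation is near chance
here because amplitude statistics carry almost no class signal in the
simulator, which overstates the frequency-vs-time gap relative to real
recordings.

## Numerical and reproducibility choices

- All randomness flows from explicit seeds; one top-level pipeline seed fans
  out to stage seeds by fixed offsets.  Identical config + seed reproduces
  every artifact byte-for-byte (model JSON, report JSON, feature CSV).
- Feature tables are written with `repr`-precision floats and read with
  round-trip parsing, so write→read is bit-exact.
- Ordinal decoding uses banker's-rounding `rint` then clamps to [1, K].
- Problem sizes in the shipped tests and the acceptance script are the study
  defaults (480 trials, 160 features, full candidate enumeration); the whole
  acceptance run completes in seconds, so nothing is scaled down.

## Known limitations

- The ordinal encoding is sensitive to class numbering on data whose
  structure does not align with the code order; one-vs-rest costs K× the
  parameters and loses the exact complexity accounting.
- No leave-one-subject-out protocol (out of scope for the subject-dependent
  design), no real-data readers beyond the documented CSV/manifest
  convention, and no artifact handling.
- Band powers double-count bins on shared inclusive boundaries; users who
  need a strict partition should configure half-open-equivalent band edges
  (e.g. offset by less than one bin width).
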