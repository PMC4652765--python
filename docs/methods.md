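# Methods

## Motif model

A GQ motif is four G-tracts of at least `min_g_tract_length` (default 3)
consecutive guanines separated by three loops of `min_loop_length`..
`max_loop_length` (default 1..7) arbitrary nucleotides. `N` is never
counted as guanine but may appear in loops; input is uppercased on read.
Coordinates are 0-based half-open on the forward strand (BED convention);
minus-strand motifs are found by scanning the reverse complement and mapped
back, with tract/loop attributes reported in the motif's own 5'→3' order.

G-runs longer than the tract minimum admit several decompositions (a
leading `GGGG` can keep all four guanines in the tract or donate one to the
adjacent loop). Under the `all_maximal` overlap policy the scanner
enumerates **every** valid 4-tract/3-loop decomposition — the same set an
exhaustive brute-force enumerator produces, which is how the scanner is
cross-checked in the tests. `greedy_nonoverlapping` instead reports the
first motif in (start, end, tract-length) order and resumes scanning past
its end, giving a compact non-overlapping call set. No thermodynamic or
sliding-window scoring is attempted; the scanner is purely structural.

## Conformation rules and calibration

Conformation calls use ordered first-match-wins rule tables per context:

- **ss**: any 1-nt loop → parallel/high; otherwise all loops ≤ 3 →
  antiparallel/intermediate; otherwise unfolded/none.
- **ds**: all loops ≤ 2 → parallel/high; exactly one 1-nt loop with the
  others ≤ 5 → parallel/intermediate; otherwise unfolded/none. A ds table
  that contains an antiparallel row is rejected at load time, encoding the
  observation that the antiparallel fold exists only in ssDNA.

The ss boundary between antiparallel and unfolded (max loop 3) reflects the
longest-loop antiparallel exemplars in the calibration set; it is a
config value in the YAML rule table, not a hard-coded constant. The exact
cluster membership of profiles such as 2-3-3/4-3-3/5-3-3 is not sharply
determined by the calibration data; the default ≤3 rule covers them and can
be edited per table.

Predicted dsDNA folded percentages come from a calibration map keyed by
sorted loop triplet: (1,1,2) → 92 (the CMYC promoter profile, written
1-2-1 in sequence order), (1,3,3) → 86, (1,4,4) → 66, (1,5,5) → 58,
(3,3,3) → 0. Lookups are exact on keys; triplets matching the ds unfolded
rule return 0; anything else takes the nearest key by L1 distance on sorted
triplets, ties broken toward the smaller total loop length and then
lexicographically. Nearest-key interpolation is a deliberate, transparent
stand-in for a fitted loop-length response curve: with five calibration
points a parametric fit would suggest more precision than the data support.

## Ligand-fluorescence classification

NMM reports parallel GQs (emission read at 610 nm, secondary band at
670 nm recorded but unused for classification; excitation 393 nm); Crystal
Violet reports antiparallel GQs (640 nm; excitation 540 nm). Peak readout
averages the piecewise-linear spectrum over a ±2 nm window (exact integral
of the interpolant, so off-grid window edges are handled analytically);
instrument bandwidth is otherwise not modeled. Optional background
subtraction against a non-GQ control interpolates the control onto the
sample grid and floors at zero; it is off by default since the normalized
readouts are ratio quantities.

Per-channel intensities are expressed as percent of a designated reference
sample (reference = 100% on each channel). Classification is supervised
nearest-centroid: per-class mean points fitted from labeled calibration
data, assignment by distance in the (NMM%, CV%) plane, ties broken
parallel > antiparallel > unfolded. Unsupervised k-means is deliberately
not used — the calibration points carry labels, and centroid/label matching
would otherwise be ambiguous. By default distances are computed in
per-channel z-units (channel standard deviations of the calibration set),
so the wider-ranging channel does not dominate; plain Euclidean is
available. Centroids always come from calibration data and are never
hard-coded.

The CD classifier is rule-based on local extrema after 3-point
moving-average smoothing: a positive local maximum within 260 ± 5 nm plus a
local minimum within 240 ± 5 nm → parallel; otherwise a global positive
maximum within 290 ± 5 nm → antiparallel; anything else — including the
broad ~275 nm band a duplex contributes — is *indeterminate*. No
basis-spectrum decomposition is attempted: CD cannot resolve a GQ embedded
in duplex DNA, so refusing to classify is the correct behaviour there.

## smFRET simulator

Each molecule draws a class: donor-only with probability
`donor_only_fraction`; of the remainder, dynamic with probability
`dynamic_fraction`; the rest static folded with probability
`folded_fraction`, else static duplex. Key parameters (defaults):

| parameter | default | meaning |
|---|---|---|
| `frame_interval` | 0.1 s | camera exposure per frame |
| `n_frames` | 600 | 1-minute recordings |
| `e_folded`, `e_duplex` | 0.8, 0.3 | apparent FRET of the two states |
| `total_intensity_mean/sd` | 500 ± 50 | per-molecule emission, counts/frame |
| `channel_noise_sd` | 30 | additive Gaussian noise per channel |
| `donor_only_fraction` | 0.2 | molecules without an active acceptor |
| `donor/acceptor_bleach_mean_s` | 60 s | exponential bleach lifetimes (0 disables) |
| `red_pulse_frames` | 5 | direct-acceptor-excitation marker frames |
| `molecules_per_field` | 400–500 | field-of-view occupancy |

Per frame, donor = I·(1−E) and acceptor = I·E plus background and noise,
with I constant per molecule and Normal across molecules — inter-molecule
intensity variation broadens the histogram realistically without modeling
excitation-field inhomogeneity. Noise is additive Gaussian, not
Poisson/EMCCD; donor leakage and the detection-efficiency γ are fixed at 0
and 1 (no corrections are applied anywhere, so apparent E is
self-consistent end to end). After acceptor bleach the acceptor falls to
background and the donor recovers to I; after donor bleach both channels
fall to background; intensities are floored at 0. The red-pulse record is
≈I whenever the acceptor is present and survives past the pulse.

Dynamic molecules follow a two-state continuous-time Markov chain
(`k_unfold`: folded→duplex, `k_fold`: duplex→folded) discretized with the
exact per-frame transition probabilities from the closed-form 2×2 rate
matrix exponential, initial state from the stationary distribution. Note
that frame-resolved dwell times are geometric, with mean `dt/p_switch` ≈
`(1/k)·(1 + k·dt/2 + …)`; the dwell-statistics tests therefore run at
`k·dt = 0.02`, where this discretization bias is under 1%, and check the
exponential signature as mean ≈ 1/k and sd ≈ mean.

`construct_config(name)` packages fixture configs for the five dsDNA
constructs with `folded_fraction` set to the measured folded percentages
(CMYC 0.92, 1-3-3 0.86, 1-4-4 0.66, 1-5-5 0.58, (TTA)3 0.0).
1-4-4 and 1-5-5 carry `dynamic_fraction = 0.04` — the middle of the
observed 3–5% range — with total rate 1 /s split so the dynamic
subpopulation's stationary folded occupancy equals the construct's folded
fraction; the dynamic molecules then leave the histogram area unbiased.
Donor-only prevalence (0.2) and bleach lifetimes (60 s) are fixture
choices; no measured values exist for them.

All randomness flows from one seed through named, CRC-keyed substreams
(fields vs traces vs spectra), so datasets are bit-reproducible and adding
a stage never perturbs another stage's draws.

What the generator does **not** emulate: raw movies and spot detection
(the pipeline starts at per-molecule traces), Poisson photon statistics,
spectral cross-talk, molecular-crowding chemistry (folded fraction is a
direct generative parameter, not a PEG response). Passing tests therefore
demonstrate correct recovery of the assumed generative structure, not
robustness to instrument artifacts absent from that structure.

## FRET pipeline

- **Efficiency**: `E_t = (I_A−b_A) / ((I_D−b_D)+(I_A−b_A))`; frames with
  denominator ≤ 10 counts are invalid; E is clamped to [−0.1, 1.1].
- **Dual-label selection**: mean red-pulse acceptor >
  `background + 5·noise_sd`. With default noise this separates
  acceptor-bearing molecules from donor-only molecules perfectly (signal
  ≈ 500 vs ≈ 0 against a threshold of 150). For real traces without a
  red-pulse record a fallback (mean acceptor over the first second) exists
  but must be enabled explicitly.
- **Bleach truncation**: the valid window ends at the first frame where
  total intensity stays below `background + 3·noise_sd` for ≥3 consecutive
  frames.
- **Histogram**: the first 10 valid frames per molecule, 60 bins over
  [−0.1, 1.1]. Both values are configurable; 10 frames × ~4000 kept
  molecules gives smooth, fittable histograms while keeping early-bleach
  contamination below a percent.
- **Folded fraction**: least-squares fit (Levenberg–Marquardt via lmfit) of
  two area-parameterized Gaussians to the density-normalized histogram.
  Initialization: means 0.3/0.8, sds 0.08, areas split by mass on either
  side of E = 0.55. Constraints: mean_low ∈ [0, 0.55), mean_high ∈
  (0.55, 1.05], sds ∈ [0.02, 0.25], areas ≥ 0. A single-Gaussian refit is
  preferred when it lowers the small-sample-corrected information score
  (AICc on the least-squares likelihood) — this makes the one-peak cases
  (all-folded, all-duplex) deterministic instead of fitting a spurious
  second component — and then the folded percentage is 100 or 0 by the side
  of 0.55 the single mean falls on. Otherwise
  `folded_percent = 100·area_high/(area_high+area_low)`. Optimizer failure
  raises with diagnostics; there is no silent fallback.
- **Dynamics**: the valid-window E series is 3-frame median filtered;
  crossings are counted with hysteresis (a transition commits only when the
  signal exits the [0.45, 0.65] band on the side opposite the last
  committed state); a trace is dynamic at ≥2 crossings. Traces shorter than
  20 valid frames are excluded from the dynamics denominator and counted
  separately. The criterion and thresholds are package choices (exemplar
  traces, not a printed rule, define "dynamic"); all are config values.
  Dwells shorter than the median kernel are unresolvable by construction.
- No HMM state inference or dwell-time kinetic fitting: rates are simulator
  inputs, not pipeline outputs.

## Problem sizes and tolerances

Recovery checks run at 5000 molecules per dataset — matching the >5000
molecules a 10–20-field experiment aggregates — where the binomial sampling
error of a folded fraction is ≈0.7 percentage points and recovered values
sit within ±2 points of generative truth; fitted state means recover within
±0.02. Histogram moments, donor-only counts and dynamic-trace percentages
are tested against 3-standard-deviation binomial bands. Scanner
equivalence is exhaustive against brute force on 100 random 200-nt
sequences; conformation-rule invariants are exhaustive over the 7³ loop
grid.

## Known limitations

- The dsDNA calibration map interpolates by nearest profile; predictions
  for profiles far from the five calibrated triplets are coarse.
- Additive-Gaussian noise understates the intensity dependence of real
  shot noise; fitted Gaussian widths are not interpretable as photon
  statistics.
- Apparent FRET only: no γ/leakage corrections, so absolute E values are
  instrument-convention quantities, not distances.
- The ss rule boundaries encode a specific calibration panel; sequence
  composition of loops (e.g. TTA vs AAA) is recorded on motifs but unused
  by the default rules.
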