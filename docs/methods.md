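# Methods

This note documents the models, numerical choices and limitations behind
`mferg_emd`, at the level a user would need to judge what the package's
results do and do not show.

## Signal model and geometry

A recording is 61 sector traces of 84 samples at 1017 Hz, in nV.  Sample
indices are 0-based; sample *m* occurs at *m*/1017 s, so the trace spans
about 82.6 ms.  Only single-eye, first-order-kernel traces are modelled;
the eye label is metadata.

The shipped cluster layout is the standard 61-hexagon array: rings of
1/6/12/18/24 sectors by hexagonal distance from the centre, numbered
ring-by-ring counter-clockwise from the positive horizontal axis.
Quadrants split the 60 peripheral sectors by the vertical and horizontal
meridians into four groups of 15; hexagon centres that fall exactly on a
meridian are assigned by rank order around the circle.  Published
descriptions of this analysis do not pin down the sector-number-to-
position map, so the layout is exported/imported as a plain CSV
(`sector,ring,quadrant`) and can be replaced without code changes.  Any
replacement must keep SUM = all 61 sectors, rings a partition, and
quadrants pairwise disjoint.

## Empirical mode decomposition

The decomposition is classical univariate sifting, capped at 4 IMFs:

* **Envelopes**: natural cubic splines through the local maxima (upper)
  and minima (lower).  Extrema are strict sign changes of the first
  difference; a plateau counts once at its midpoint.
* **Boundaries**: two extrema are mirrored past each end of the trace
  before spline fitting.  Mirroring is the conservative standard fix for
  spline edge effects on short traces.
* **Stop rule**: sifting of one mode stops when Huang's SD criterion
  Σ(h_prev − h)² / Σ h_prev² < 0.2 is met *and* the candidate satisfies
  the IMF oscillation property (interior extrema and zero-crossing
  counts differ by ≤ 1), or after 100 iterations.  The SD threshold 0.2
  is the strict end of the conventional 0.2–0.3 range; the oscillation
  requirement is added because the SD criterion alone frequently stops
  on candidates that are not yet modes (on random 84-sample signals,
  roughly a third violated the count property without it).
* **Degenerate inputs**: a trace with fewer than two maxima or two
  minima yields no further IMFs; remaining IMF slots are zero-filled so
  the four partial reconstructions x^(k) = Σ_{j≥k} IMF_j + residue are
  always defined.  A constant trace is returned as pure residue.

Completeness (components sum back to the input within 1e-8 relative) is
enforced by construction and tested on random signals.

The "energy fraction" diagnostic is Σ_k ‖IMF_k‖² / ‖x‖², IMFs only,
residue excluded.  IMFs are not exactly orthogonal, so this can exceed 1
when cross-terms are negative — which they systematically are on
noise-dominated traces.  On the default synthetic cohorts the control
average is ≈ 1.3; on cleaner, oscillation-dominated signals it
approaches the share of energy the modes genuinely carry.  Values above
100% should be read as "the first four modes plus leakage", not as a
bug.

## Normative template

The template for sector S is the sample-wise arithmetic mean of the
control recordings' sector-S traces, stored and compared in raw nV — no
normalisation or detrending.  Controls are always evaluated (both for
filter selection and for the correlation feature) against the
leave-one-out template excluding their own recording; patients against
the full template.  Applying the leave-one-out rule to both uses is the
only self-consistent way to avoid self-correlation bias.  The exact
identity N·T_full = (N−1)·T_loo(j) + rec_j holds sample-wise and is
tested at 1e-10.

One consequence worth knowing: with only 6 controls the leave-one-out
templates average 5 recordings and are therefore slightly noisier than
the full template, so under the null hypothesis the correlation features
of controls sit marginally below those of patients and the null AUC of
the PCC features centres a little below 0.5 (≈ 0.42 at the default noise
level).  This is inherent to the evaluation design at this cohort size,
not an implementation artifact.

## Adaptive filter conventions

The filter computes one EMD per sector and picks the partial
reconstruction with the highest Pearson correlation against the
template.  Three edge conventions are fixed here because the selection
rule itself does not fix them:

* correlations equal within 1e-12 break to the smaller k (retain more
  signal);
* an undefined correlation (zero-variance reconstruction, e.g. a
  constant residue) is treated as negative for the non-analyzable (NaS)
  rule;
* a correlation of exactly 0 is not negative; such a sector is kept.

NaS is declared exactly when all four correlations are negative or
undefined.  Cluster averages exclude NaS sectors; a cluster whose
members are all NaS is propagated as undefined rather than invented.

## Features

* **PCC features**: Pearson correlation between the subject's cluster
  average and the template's cluster average (templates average all
  member sectors — the NaS concept does not apply to them), computed on
  raw traces (PCC_RAW) and on filtered traces (PCC_EMD).
* **A_N1**: computed per cluster on the *raw* cluster-averaged trace as
  |baseline − minimum in the 9–32 ms window|, with the baseline the mean
  of all samples strictly before 9 ms.  A pre-trough baseline is the
  common ERG convention and makes the feature invariant to constant
  offsets.  Computing per cluster-average (rather than per sector, then
  averaging amplitudes) was a genuine design choice; the cluster-average
  reading matches how the correlation features are defined.

## Group statistics

Per cluster × feature, both groups are Shapiro–Wilk tested at α = 0.05;
if both pass, Welch's two-sample t-test, otherwise the Mann–Whitney U
test with normal approximation, tie correction and continuity
correction.  A paired test is not applicable to independent groups of
unequal size, so the independent-samples test is used wherever a
"dependent t-test" might be expected in this literature.  The asymptotic
Mann–Whitney p agrees with exact enumeration within 0.02 for tie-free
samples at the study's group sizes (slightly worse, ~0.03, under heavy
ties).  No multiple-testing correction is applied; p-values are raw.

AUC is the rank-based (Mann–Whitney) statistic with ties counted 0.5 and
a direction fixed a priori per feature — controls high for the PCC
features, patients high for A_N1 — recorded in the output and never
flipped per sample.  Cells with fewer than 3 defined values in either
group are emitted flagged unavailable and excluded from the per-feature
mean AUC.

## Synthetic cohort generator

The generator exists so the full chain is testable without clinical
data.  Each sector trace is

    gain_ring · s_subj · [ −A_N1 g(t; μ_N1+δ_1, σ_N1) + A_P1 g(t; μ_P1+δ_2, σ_P1)
                           − A_N2 g(t; μ_N2+δ_3, σ_N2) ] + common(t) + ε(t)

with g a unit-peak Gaussian.  Defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| μ_N1, μ_P1, μ_N2 | 15 / 30 / 45 ms | component latencies |
| A_N1, A_P1, A_N2 | 160 / 240 / 60 nV | base amplitudes |
| σ_N1, σ_P1, σ_N2 | 3.5 / 2.5 / 6 ms | component widths |
| ring gain | 1.92 / 1.30 / 1.12 / 1.00 / 0.98 | eccentricity gradient (centre largest) |
| inter_subject_cv | 0.20 | CV of the log-normal subject amplitude factor s_subj |
| subject_latency_sd_ms | 0.25 | healthy per-subject timing variability (per component) |
| noise_sd_nV | 45 | independent per-sector white noise ε |
| common_noise_sd_nV | 34 | white noise shared by all 61 sectors of a recording |
| n_controls / n_patients | 6 / 15 | study-sized cohort |

The **common-mode noise** term reflects that all 61 sector responses are
extracted from a single electrode's continuous signal, so much of the
contamination (EEG, ECG, eye movement) is shared across sectors and does
*not* shrink with cluster averaging — while per-sector EMD filtering
does remove its high-frequency bulk.  This term is what makes
filter-then-average genuinely different from plain averaging; with
purely independent noise the two are nearly equivalent at cluster level.

The **patient perturbation** (defaults: latency jitter SD 3 ms,
amplitude scale 1.2, extra per-sector noise SD 90 nV ≈ 2× the control
per-sector level; deterministic latency shift 0) jitters each component
latency with the sum of a per-subject and a per-sector draw of equal
variance (intra-subject correlation 0.5): the shared half makes patients
heterogeneous, the sector-level half broadens the cluster-averaged
waveform into a shape deficit that filtering cannot mask.  The patient
effect sizes and noise levels were calibrated once, by grid search, to
place the synthetic cohorts in the regime where the filtered-correlation
feature discriminates at mean AUC ≈ 0.9 and the feature ordering
PCC_EMD ≥ PCC_RAW ≥ A_N1 is reproducible across seeds; they are
synthetic effect sizes, not physiologic measurements.

What the generator does **not** emulate: m-sequence stimulation and
kernel cross-contamination, blink/fixation artifacts, the 10–200 Hz
analog recording bandwidth (noise is white), age structure, and any
spatially localised (sector-specific) pathology.  Passing tests on
synthetic cohorts therefore show that the pipeline implements the method
correctly and that the method behaves as expected under this generative
model — not that the clinical effect sizes are reproduced.

## Problem sizes used in tests

The test suite runs the full pipeline on study-sized cohorts
(21 subjects × 61 sectors): 25 seeded cohorts for the discrimination-
ordering check, 8 for null calibration, and 1000 direct null draws for
the type-I error of the gated test (observed ≈ 0.04, slightly
conservative because Welch's test at n = 6/15 and the normality gate
both err on the safe side).  A single 6-vs-15 AUC has standard deviation
≈ 0.14 under the null, so null-calibration bands are applied to
across-seed averages, and ordering checks are counted over seeds rather
than asserted per seed.

## Known limitations

* Sifting parameters (SD threshold, boundary rule, spline end
  conditions) are not standardised anywhere; the filter's k-usage
  distribution is sensitive to them, so k-usage tables should be
  compared only qualitatively across implementations.
* The energy-fraction diagnostic exceeds 1 on noise-dominated traces
  (IMF non-orthogonality), see above.
* With 6 controls the leave-one-out template asymmetry biases null PCC
  AUCs slightly below 0.5.
* The EMD-over-raw advantage depends on the noise being partly
  common-mode and the patient deficit being low-frequency; cohorts with
  purely independent sector noise, or with large healthy inter-subject
  waveform variability, can erase or even invert it.  The generator's
  `common_noise_sd_nV` and `subject_latency_sd_ms` knobs let users probe
  exactly this sensitivity.
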