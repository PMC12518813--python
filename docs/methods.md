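# Methods notes

## Analysis model

The unit of analysis is an *IOI sequence*: the n−1 intervals between the n
consecutive element onsets of one analysis run. Onsets are taken as given
from annotation (TextGrid interval starts, seconds from file start);
element segmentation and labelling are annotation semantics and are not
re-derived here. Three parameters are computed per sequence — IOI beat
(1/mean interval), small-sample-adjusted CV, and nPVI — all in double
precision, with rounding only at CSV output (6 decimals).

The CV adjustment is the standard unbiasing factor (1 + 1/(4m)) applied to
the sample CV (sd with denominator m−1). The factor is isolated in
`small_sample_cv_correction` and `compute_cv_adj(..., adjust=False)`
returns the raw CV, so an alternative correction can be swapped in if
bit-compatibility with other toolchains is needed. A perfectly constant
sequence short-circuits to exactly 0 for both CV and nPVI (no float
residue).

## Subsetting scheme

A tutee element is *shared* iff its label occurs anywhere in the tutor's
reference sequence (set semantics). The tutor's reference sequence is the
most frequent label sequence across its motifs (songs are crystallised, so
they normally all agree; first observed wins ties).

The at-most-one shared run per motif is anchored at the tutee motif's
first element. Two matching relations are available (`match_mode`):

- `subsequence` (default): each successive tutee element consumes the
  leftmost feasible tutor position at or after the previous one. This
  tolerates the tutee skipping tutor elements while preserving order.
- `substring`: the run must be a contiguous excerpt of the tutor sequence.

The run is ALL_SHARED when every tutor element was matched, PART_SHARED
otherwise, and it stops at the last tutor-matched element — elements the
tutee appended after a complete copy are excluded by definition (they are
not shared). Shared runs that start later than element 0 are not
classified (a warning is logged when a qualifying one exists); they still
count as shared for the NOT_SHARED mask. NOT_SHARED units are all maximal
runs of consecutive non-shared elements.

Minimum length: an analysis unit needs `min_intervals` IOIs (default 3,
i.e. four elements). The stricter 3-interval default guarantees nPVI has
at least two adjacent-pair terms; setting `min_intervals=2` selects the
3-element reading. Motifs shorter than the minimum contribute no unit of
that kind and are counted in the log, never silently dropped.

## Group statistics

Welch's unequal-variance t-test over all unordered subset pairs, two-sided,
with Bonferroni correction within each parameter (family = number of
pairs, 10 for five groups; `family="global"` multiplies by the number of
parameters as a stricter option). Effect sizes are pooled-sd Cohen's d,
sign = mean(a) − mean(b) with groups ordered TUTOR < EVERYTHING <
ALL_SHARED < PART_SHARED < NOT_SHARED. The observation unit is the
analysis sequence (pooled across birds); `aggregate_per_bird` provides a
per-bird-mean view for sensitivity analysis, deliberately avoiding
mixed-effects machinery. Identical constant samples are reported as
t = 0, p = 1 rather than NaN.

The nest-level coupling statistic is the Pearson correlation, across
nests, of the tutor's mean IOI beat (over its whole-motif units) against
the mean over that nest's tutee units of a chosen subset (default
*everything*).

## Surrogate (null) simulation

Sequences are assembled by sampling IOIs i.i.d. with replacement from an
empirical pool, lengths discrete-uniform over 4–22 elements (a 3–20
reading is selectable). Sampled intervals are exact pool values. Because
intervals are exchangeable across lengths, the mean IOI and the nPVI are
length-independent *exactly* in expectation. Two estimators are not:
the beat 1/mean(d) carries a Jensen bias ≈ beat·CV²/m, and the adjusted
CV retains a residual small-sample bias under non-normal pools — both of
order 1/m, both shrinking with sequence length. With a realistic pool
(CV ≈ 0.57) the induced beat-vs-length correlation is about −0.1 at
lengths 4–22; the qualitative "no correlation" conclusion therefore holds
approximately, not exactly, and the tests assert it accordingly (exact
2-SE slope checks for mean IOI and nPVI, |r| < 0.1 at the full simulation
size for all three parameters).

## Synthetic nest generator

The generator emulates the study's structure: 17 nests, 1–4 tutees each
(probabilities 0.25/0.45/0.20/0.10 over 1..4 — median 2, mean 2.15, so a
default run yields ≈37 tutees), 10 crystallised motifs per bird, 6–14
elements per motif, per-bird beat ~ Normal(17.1, 3.7²) Hz truncated to
[8.6, 26.4], intervals confined to [0.009, 0.29] s.

Timing model per bird: elements are grouped into 1–3-element syllables.
Intra-syllable gaps default to a species-typical constant (0.04 s) while
the inter-syllable gap is solved per bird so the mean interval equals
1/beat — this is what keeps the pooled interval histogram bimodal with a
sharp first mode even though birds differ threefold in tempo, and it lets
the per-sequence CV vary with tempo (slow birds are more variable, fast
birds less, matching a wide empirical CV range around a mean of ~0.57).
An alternative proportional model (`intra_ioi_s=None`,
`ioi_ratio_inter_intra`) makes both components scale with tempo; there a
total-CV target below what the components alone produce is rejected as
infeasible.

Each interval receives independent multiplicative log-normal jitter with
unit mean. The jitter magnitude is solved from `ioi_jitter_cv`, the target
*total* within-motif CV, after subtracting the base pattern's contribution
(`c² = (mean(b)²(1+t²) − mean(b²)) / mean(b²s²)`); intra-syllable gaps get
a reduced share (`intra_jitter_scale=0.35`, they are more stereotyped),
and a motor-noise floor (`min_ioi_jitter_cv=0.08`, capped by the target)
keeps no interval exact. Log-normal noise keeps durations positive;
intervals are finally clipped to the support.

Tutee songs derive from the tutor: the tutee beat is the tutor beat
divided by `tutee_slowdown_factor` (default 1.05 — tutees sing slightly
slower) with small log-normal noise (`tutee_beat_noise_cv`, default
0.015), so nest-level beat correlation is an emergent, controllable
property. Copy strategies: `full_copy` (same labels, tutor timing pattern
rescaled), `partial_copy` (a ≥4-element tutor prefix plus 4–6 novel
elements), `improvise` (a 0–3-element prefix — below the analysis minimum
— plus 5–9 novel elements). Intervals inside novel runs get their jitter
multiplied (`novel_jitter_multiplier=2`), making improvised material
locally more variable, which propagates to higher nPVI in NOT_SHARED
units.

What the generator does *not* emulate: acoustic structure, developmental
stages, within-bird sequence variants (crystallisation is absolute here),
annotation noise (onset measurement error), or non-stationary tempo drift
within a bout. Tests passing on this generator therefore validate the
pipeline's arithmetic and classification logic under controlled
conditions, not the biological conclusions on real recordings.

## Problem sizes and numerical choices

Test simulations are sized to run comfortably on one CPU: the type-I-error
check uses 5000 replicates of a five-group null family (binomial SE
≈ 0.003); the surrogate control uses 1000 sequences (null r SE ≈ 0.032,
so |r| < 0.1 is a ≈3-SE bound); parameter recovery uses the full 17-nest
corpus at within-motif jitter CV 0.1, where the per-bird beat-estimate SE
is ≈1% against a 2% tolerance and a 5% slowdown margin. The recovery
corpus uses the high-fidelity configuration (full copying, beat noise CV
0.005, unimodal base) because the identity-line check is a statement
about faithful copying, not about mixed strategies.

Ties and degenerate inputs: empty-labelled TextGrid intervals are not
elements; a single-element motif has zero IOIs and is skipped with a log
entry wherever two intervals are required; a constant IOI pool triggers a
degenerate-pool warning and NaN length correlations rather than invented
values; TextGrid times are written with 6 decimals, making write→read a
1e-6-second round trip.
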