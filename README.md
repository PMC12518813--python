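# motifrhythm

Isochrony-oriented rhythm analysis of annotated zebra finch song motifs.

Adult male zebra finches sing a crystallised *motif*: a fixed sequence of
elements whose onset times define inter-onset intervals (IOIs). Young males
(tutees) learn their song from an adult tutor — usually their father — and
may copy the tutor's element sequence completely, in part, or improvise new
material. `motifrhythm` quantifies how faithfully the *temporal* side of
song is copied: given element-onset annotations for a set of nests (one
tutor plus its tutees), it computes rhythm statistics per analysis
sequence, classifies each tutee motif against its tutor, compares rhythm
parameters across sharing categories, and checks length artefacts with an
i.i.d. surrogate simulation. A synthetic nest generator makes the whole
pipeline testable without recordings.

## Rhythm parameters

For a sequence of m intervals d₁…d_m (seconds):

- **IOI beat** `= 1 / mean(d)` [Hz] — the rate of the best-fitting
  metronome under the mean-interval model.
- **CV_adj** `= (1 + 1/(4m)) · sd(d)/mean(d)` — coefficient of variation
  with the standard small-sample unbiasing factor (sample sd, denominator
  m−1). Global, scale-free variability; 0 iff the sequence is isochronous.
- **nPVI** `= 100/(m−1) · Σₖ |dₖ − dₖ₊₁| / ((dₖ + dₖ₊₁)/2)` — normalized
  pairwise variability index; local variability over adjacent interval
  pairs, 0 for perfect isochrony, < 200 always.

Tutee motifs are decomposed into analysis subsets: the whole motif
(*everything*), one beginning-anchored run that follows the tutor's element
order (*all-shared* if the tutor's complete sequence was copied,
*part-shared* otherwise), and maximal runs of elements absent from the
tutor's motif (*not-shared*). A unit enters the analysis only with at least
3 IOIs (4 elements; configurable). Group differences use Welch's t-test
with Bonferroni correction and pooled-sd Cohen's d; tutor–tutee coupling is
the Pearson correlation of per-nest mean IOI beats.

## Worked example

Generate a synthetic study (17 nests, study-shaped defaults) and run the
full pipeline:

```bash
motifrhythm simulate --out demo --seed 7
motifrhythm run --config pipeline.yaml   # or, in Python:
```

```python
from motifrhythm.synthetic_data import GeneratorConfig, write_corpus
from motifrhythm.pipeline import PipelineConfig, run_pipeline

write_corpus(GeneratorConfig(seed=7), "demo")
summary = run_pipeline(PipelineConfig(out_dir="demo/report",
                                      motifs_csv="demo/motifs.csv", seed=7))
```

With seed 7 this prints/returns (abridged):

```
n_motifs: 490            # 17 tutors + 32 tutees x 10 motifs
unit_counts: tutor 170, everything 320, all_shared 140,
             part_shared 90, not_shared 180
nest_beat_correlation: r = 0.905 (p = 5.8e-07)
nullsim_length_correlations: ioi_beat_hz -0.11, cv_adj 0.12, npvi 0.015
```

Reading: tutee tempos track their tutor's tempo tightly (per-nest beat
correlation r ≈ 0.9) while sitting slightly below the identity line — the
generator's 5% tutee slowdown recovered by the pipeline. The surrogate
(`nullsim`) correlations near zero show that the length dependence seen in
real subsets is a property of the data, not of the metrics. The report
directory additionally contains `units.csv`, `metrics.csv`,
`comparisons.csv` (Welch/Bonferroni/Cohen's d), `correlations.csv` and
diagnostic plots.

## Layout

- `motifrhythm.io_annotations` — TextGrid/CSV reading and writing.
- `motifrhythm.sequence_matching` — shared/not-shared subset extraction.
- `motifrhythm.rhythm_metrics` — IOI beat, CV_adj, nPVI, histograms.
- `motifrhythm.group_stats` — Welch comparisons, correlations.
- `motifrhythm.null_simulation` — i.i.d. surrogate control.
- `motifrhythm.synthetic_data` — synthetic nest generator with ground truth.
- `motifrhythm.pipeline` / `motifrhythm.cli` — orchestration and the
  `motifrhythm` console script.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
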