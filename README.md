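# rhythmboot

Replicate-resampling consensus detection of rhythmically expressed genes in
time-course expression data.

## The problem

Circadian time-course experiments in animals and plants sample a *different
individual* at every timepoint (sampling is destructive), so a "replicate
time course" is really a chimera of organisms, and between-individual
variance masquerades as temporal signal. Rhythmicity detectors run on a
single replicate — or on the replicate average — therefore call many
non-oscillating transcripts rhythmic. False positives are expensive: each
one may trigger follow-up experiments.

rhythmboot implements a resampling remedy for anyone analysing such data
(chronobiologists, transcriptomics analysts) and a simulation benchmark to
quantify it. From an *R*-replicate dataset it builds many single-replicate
datasets by picking, independently at each (gene, timepoint), one of the
*R* measured values uniformly at random; runs a detector on each; and
keeps genes called rhythmic in at least *k* of the *N* resampled datasets
(the *consensus*). Because a spurious rhythm rarely survives many random
recombinations of the replicates while a genuine one does, false positives
collapse with growing *k* while true positives persist.

## What is inside

* **Detectors** (sklearn-style estimators over a `genes x timepoints`
  matrix, uniform sampling in hours):
  * `ArserDetector` — linear detrend; autoregressive spectral estimation
    (Yule-Walker, Burg, conditional least squares at orders up to n/3) of
    candidate periods in [20, 28] h; harmonic regression
    `y ~ mu + beta*t + A cos(2*pi*(t - phi)/tau)` with AIC selection and
    local period refinement; F-test p-values and Benjamini–Hochberg
    q-values; rhythmic iff q <= 0.05.
  * `HaystackDetector` — best Pearson correlation against a library of
    phase-shifted 24 h templates (cosine, sine, box-like, spike, rigid,
    asymmetric); rhythmic iff r >= 0.8, fold change >= 2 and p <= 0.05.
  * `FftNllsDetector` — Fourier-initialised nonlinear least-squares cosine
    fit with the period constrained to [20, 28] h; rhythmic iff the
    relative amplitude error (95 % CI half-width / amplitude) < 0.5.
* **Resampling & consensus**: `ResamplingConsensus`, `resample_dataset`,
  `average_dataset`, `consensus_counts`, `consensus_set`.
* **Synthetic benchmarks** with ground truth: entrained cosines
  (`simulate_ld`: per-gene period U(22, 28) h, amplitude SNR*2 = 4, unit
  noise), free-running populations (`simulate_ll`: per-individual period
  N(25, 3) h), limit-cycle oscillator waveforms (`simulate_ode`), plus
  white-noise nulls; `assemble_initial_datasets` mimics destructive
  sampling by giving every (timepoint, replicate) slot its own simulated
  individual.
* **Evaluation**: TP/FP-versus-consensus curves (`run_benchmark`),
  replicate-count sensitivity (`replicate_sensitivity`), venn-region
  overlap counts (`overlap_counts`).
* **CLI**: `rhythmboot simulate | detect | resample | benchmark | overlap`,
  each writing a JSON run manifest; `--seed` determines every stochastic
  stage.

## Worked example

```python
import numpy as np
from rhythmboot import (SimulationConfig, simulate_ld, assemble_initial_datasets,
                        ArserDetector, ResamplingConsensus, average_dataset,
                        confusion_from_mask)

# entrained-population benchmark, 500 rhythmic + 500 noise genes
cfg = SimulationConfig(n_rhythmic=500, n_null=500, n_individuals=36)
rng = np.random.default_rng(1)
individuals = simulate_ld(cfg, rng)
dataset, truth = assemble_initial_datasets(individuals, 3, rng,
                                           timepoints=cfg.times)

# single replicates and the replicate average
for r in range(3):
    calls = ArserDetector().fit(dataset.replicate(r), times=cfg.times).rhythmic_
    c = confusion_from_mask(calls, truth)
    print(f"replicate {r + 1}:      TP={c.tp:3d}  FP={c.fp:3d}")
avg = ArserDetector().fit(average_dataset(dataset), times=cfg.times).rhythmic_
c = confusion_from_mask(avg, truth)
print(f"averaged:         TP={c.tp:3d}  FP={c.fp:3d}")

# consensus over 36 resampled datasets
rc = ResamplingConsensus(ArserDetector(), n_resamples=36,
                         random_state=1).fit(dataset)
for k in (7, 15, 25):
    c = confusion_from_mask(rc.consensus_mask(k), truth)
    print(f"resampled k={k:2d}/36: TP={c.tp:3d}  FP={c.fp:3d}")
```

Output:

```
replicate 1:      TP=498  FP= 27
replicate 2:      TP=500  FP= 22
replicate 3:      TP=500  FP= 32
averaged:         TP=500  FP= 34
resampled k= 7/36: TP=500  FP= 26
resampled k=15/36: TP=500  FP=  0
resampled k=25/36: TP=500  FP=  0
```

Each single replicate (and the average) carries 22–34 false positives out
of 500 noise genes; requiring a consensus of 15 of 36 resampled datasets
removes *all* of them without losing a single true positive. The same
experiment at the full 8400+8400-gene design leaves single-digit false
positives at k = 15.

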