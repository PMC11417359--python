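# pachydyn

Transcription-kinetics analysis of a stalled meiotic trajectory:
simulate paired spliced/unspliced single-cell data for a wild-type and a
knockout-like sample, fit per-gene two-state kinetics to recover latent
cell time and driver genes, classify per-gene trend anomalies between
samples with a Mann–Kendall / slope-ratio rule, and intersect anomalous
drivers with promoter-bound targets defined by peak annotation and a
degenerate GAA-motif grammar.

The package is for computational biologists who want the full inference
chain behind "loss of this transcription factor stalls pachynema
progression" as tested, reusable code: every stage runs on synthetic
data generated from known ground truth, so calibration (false-anomaly
rate) and power (planted-anomaly recovery) are measurable.

## The model

Per gene, nascent (u) and mature (s) mRNA follow the two-state kinetics

    du/dt = α(t) − βu        ds/dt = βu − γs

with α switching between `α_on` and 0 at a switch time.  *Repression*
genes start at the ON fixed point (α/β, α/γ) and switch off; *induction*
genes start silent and switch on; *steady* genes never switch.  Fitting
fixes β = 1 (data identify rates only up to a time rescaling) and
profiles per-cell latent times inside the objective.  Driver genes are
fits with likelihood > 0; velocities v = βMu − γMs direct a cell-cell
Markov chain whose stationary distribution locates the terminal
(arrest) state.  For each driver, unspliced counts ordered by inferred
time are Mann–Kendall-tested in both samples: a real wild-type trend
(P < 0.01) that reverses sign in the knockout or flattens by a slope
ratio > 4 is an anomaly, typed by the wild-type direction.

## Worked example

Fitting one noiseless repression gene (`examples/02_fit_kinetics.py`):

```
true gamma/beta  : 0.500
fitted gamma/beta: 0.500
fit likelihood   : 1.0000
latent-vs-true time Spearman: 0.976
```

The degradation/splicing ratio is recovered exactly and the per-cell
latent times reproduce the true ordering (the Spearman is below 1 only
because pre-switch cells are legitimately tied).  The end-to-end run
(`examples/05_full_pipeline.py`, 60 genes, 200 cells/sample) prints:

```
drivers: 60
DGTs (promoter-bound drivers): 16
terminal cluster: P-like  scores: {'P-like': 0.00901, 'eP': 0.00011, 'mP': 0.00298}

             label  count  percent
repression_anomaly      9     56.2
 induction_anomaly      1      6.2
         unchanged      6     37.5
             total     16    100.0
```

Stationary mass concentrates on the knockout-specific arrest cluster
(P-like), and the promoter-bound drivers split into repression
anomalies (the planted lesion), induction anomalies (genes stalled by
the arrest) and unchanged genes.

Each script under `examples/` demonstrates one capability: dataset
simulation, kinetic fitting, trend classification, motif/peak
annotation, and the full pipeline.  A thin CLI wraps the same stages
(`pachydyn simulate|qc|fit|annotate|overlap|run-all`), each subcommand
reading and writing only standard on-disk formats (MatrixMarket + TSV,
FASTA, BED, GFF-lite, YAML).

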