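# Methods

## The model

Each gene's transcription is a two-state (telegraph-like) process with
deterministic rate equations for unspliced (nascent) and spliced
(mature) mRNA:

    du/dt = alpha(t) - beta * u
    ds/dt = beta * u - gamma * s

with transcription rate `alpha(t)` piecewise constant (ON at `alpha_on`
or OFF at 0, changing at the switch time `t_switch`), splicing rate
`beta` and degradation rate `gamma`.  Within a phase of constant alpha
the solution is closed-form; the implementation requires `beta != gamma`
(the closed form has a `(gamma - beta)` denominator) and composes phases
continuously.  Three gene classes define the trajectory: *repression*
genes start at the ON fixed point `(alpha/beta, alpha/gamma)` and switch
off at `t_switch`; *induction* genes start silent and switch on;
*steady* genes hold the ON fixed point throughout.

`(u, s)` data identify the rates only up to a common rescaling of time,
so fitting fixes `beta = 1` as the gauge; fitted `gamma` is the
identifiable ratio gamma/beta and latent times are in units of 1/beta.

## Synthetic study conditions

The generator emulates a two-sample (wild-type vs knockout-like)
single-cell experiment over one differentiation stage:

* latent cell times uniform on [0, 1] (a beta distribution is available
  for density imbalance across substages);
* default panel 200 genes: 80 repression, 60 induction, 60 steady;
  `alpha_on` log-uniform on [5, 50] counts/unit time, gamma/beta
  log-uniform on [0.1, 2];
* repression switch times uniform on [0.25, 0.45]; induction on
  [0.15, 0.45], so mid-stage identity comes from genes that have
  already risen — this is what makes the arrest state transcriptionally
  distinct, as the phenotype it emulates requires;
* cluster labels cut the time axis at 1/3 and 2/3 (eP / mP / lP);
* counts are Poisson (optionally negative-binomial or disabled) around
  capture-efficiency-scaled expectations; a deterministic mode
  (noise off, rounding off) reproduces the closed form exactly and
  backs the oracle tests;
* QC covariates (genes detected, mitochondrial fraction) are drawn
  independently of the kinetics, with a 2% planted failure rate, solely
  to exercise the QC stage.

**Knockout semantics.**  The perturbation has two components.  Genes
flagged `ko_frozen` (by default the repression class) carry the lesion
in *every* KO cell: their switch-off never happens, so nascent
transcription stays high across the stage.  Independently, KO cells
drawn past the arrest time (default 0.5) stop progressing: all other
genes are evaluated at `min(t, arrest)`.  Arrested cells therefore
accumulate at a fixed, continuously reachable point of the trajectory
and are labelled with the distinct arrest cluster (`P-like`).  An
earlier design froze genes per cell past the arrest only; that
teleports arrested repression genes back to their plateau and makes the
arrest state geometrically indistinguishable from early pachytene —
with no attractor, terminal-state inference reduced to a coin flip.

The generator does not model doublets, ambient RNA, batch effects or
read-level artifacts, and its gene panel is small (hundreds, not
thousands).  Passing tests therefore demonstrate the pipeline's
correctness and calibration under clean two-state dynamics, not
robustness to those real-data pathologies.

## Kinetic fitting

Smoothing first: counts are library-size normalized per cell, a kNN
graph (default 30 neighbors) is built on Euclidean distance in the top
30 principal components of the **log1p**-transformed normalized spliced
matrix, and smoothed `Ms`/`Mu` are neighborhood means (self included),
kept on the linear scale the model expects.  The log transform is a
deliberate choice: count noise scales with the mean, and on linear
values the distances are dominated by high-expression genes' noise
(measured smoothed-vs-expected correlation ~0.25 vs 0.7–0.9 with the
log).

Per-gene fitting minimizes the weighted squared distance of each cell's
`(Mu, Ms)` to the parametric cycle (ON from the origin until `t_switch`,
then OFF), with dimensions weighted by reciprocal data spread.  The
search runs in two stages:

1. **Joint search.**  Nelder–Mead over `(log alpha, log gamma,
   log t_switch)` with per-cell latent times profiled out — re-assigned
   at every objective evaluation by a dense grid over both phases
   (quadratically stretched, dense where the curve moves fast) plus
   golden-section refinement per cell.  Profiling the times inside the
   objective matters: alternating schemes have a biased fixed point in
   which a slightly-off amplitude is self-consistent with compensating
   times and rates.  Starting points: the plateau ratio `u/s` at the ON
   fixed point estimated two ways (ratio of 95th percentiles — exact
   for noiseless plateau-plus-decay data; ratio of means — unbiased
   under count noise on flat genes) and a coarse scan over
   `(gamma, amplitude)` candidates; the two most promising basins are
   both polished and the better result kept.
2. **Alternating polish.**  Refresh time assignments (kept per cell only
   when they improve), then update `(gamma, t_switch)` at fixed times
   with `alpha` profiled by least squares (accepted only when the SSE
   drops).  The polish objective is non-increasing by construction and
   its trace is asserted in tests.

`fit_likelihood` is the geometric-mean Gaussian density of the
residuals under the gene's own data spread, rescaled by the
zero-residual density: `exp(-mean((ru/su)^2 + (rs/ss)^2)/2)`, in (0, 1]
for any valid fit and 0 for degenerate genes (all-zero, constant, or
fewer than 20 cells with signal).  With the maximum-likelihood residual
scale the same ratio is a constant `e^{-1/2}` regardless of fit quality,
which is why the data spread, not the residual spread, sets the scale;
the MLE residual scale is still reported.  Driver genes are the valid
fits with `fit_likelihood > 0` (threshold configurable), each labelled
`repression` or `induction` by the sign of its smoothed-unspliced trend
along the consensus inferred time (a single gene's latent time can be
orientation-ambiguous when one phase is nearly flat).

The per-cell **inferred time** is the median of per-gene latent times
over genes above a fit-likelihood quantile cutoff (default: the median),
each gene's times rescaled to [0, 1] first because the beta gauge makes
raw latent times gene-specific in scale.

## Velocity, transition chain, terminal states

Velocity is `v = beta*Mu - gamma*Ms` per fitted gene.  The pipeline
restricts the field to the top 30% of fits by likelihood: a flat gene's
fitted gamma is ill-determined and its velocity is noise.  Transition
probabilities live on the kNN edges with weight
`exp(cos(v_i, s_j - s_i) / kernel_scale)` (scale 0.1) plus a **neutral
self-edge** of weight `exp(0) = 1`, rows normalized.  The self-edge
implements the terminal-state semantics: a cell with a well-aligned
neighbor passes essentially all its mass forward, while a cell whose
velocity points where no neighbor lies — the end of the trajectory —
keeps a large share and becomes quasi-absorbing.  Without it every row
is forced to transition with probability 1 and "low probability of
transitioning to other nodes" has no referent.  Terminal probabilities
are the stationary distribution (power iteration on the transpose,
tolerance 1e-10) and the per-cluster score is the mean over member
cells.  The cluster-graph abstraction reports observed/expected
inter-cluster kNN edge counts (symmetric, zero diagonal) with edge
directions from net transition flux.

## Trend-anomaly classification

For each driver gene, per-cell **raw unspliced counts** are ordered by
each sample's inferred time and tested with the Mann–Kendall statistic
(`S` from all pairwise difference signs; tie-corrected variance;
continuity-corrected normal approximation, `z = 0` when `S = 0`;
two-sided p).  Slopes are OLS on ordinal position rescaled to [0, 1].
A gene is anomalous when the wild-type trend is real (`p < 0.01`; gate
configurable to `ko` or `both`) and the knockout either reverses the
sign of `S` or flattens the slope by more than 4x
(`|slope_WT| / max(|slope_KO|, eps)`, `eps = 1e-6` of the WT range);
the anomaly type follows the wild-type direction.  Untestable series
(below 8 points) are `unchanged` with an audit flag.

Raw rather than smoothed counts are tested for two measured reasons:
kNN-smoothed series are autocorrelated, which makes Mann–Kendall
p-values on flat genes wildly anti-conservative (drift on steady genes
reached p ~ 1e-25; 11.4% of identically-simulated genes were called
anomalous), and library-size normalization imprints composition trends
on flat genes when a large fraction of the panel is dynamic.  With raw
(independent-error) counts the null anomaly rate is 0.2% and the
planted-anomaly recovery 97.5–100% under the study conditions.
"Trend change" defaults to sign reversal of `S`; a
loss-of-significance mode is available behind a flag.  No
multiple-testing correction is applied across genes.

## Binding, motifs, targets

Peaks are assigned a genomic category by their midpoint with precedence
proximal promoter (TSS-500..TSS+500, transcription-strand oriented) >
promoter (upstream extension to -2000, configurable) > exon > intron >
intergenic; intergenic peaks take the nearest TSS.  Midpoint assignment
keeps the categories mutually exclusive so fractions are well defined.
Sequences are scanned on both strands for IUPAC-degenerate patterns
(heptamer `HRGAAYV`, octamer `GAMSCKYC`); `N` never matches;
reverse-strand hits are reported at forward coordinates.  Heat-shock
elements are maximal tandem arrays of ≥3 pentamer units at period 5
whose middle triplet alternates `GAA`/`TTC`; a degenerate mode admits a
budgeted number of single-mismatch units.  Promoter-bound genes
intersected with driver genes give the driver gene targets (DGTs),
whose trend calls are summarized as counts and percentages per label.

## Expression-level stages

Cells survive QC iff 200 < genes detected < 8500 and mitochondrial
fraction < 20% (boundaries filtered, per the stated rule).
Normalization is `ln(1 + 1e4 * count / cell_total)`.  Highly-variable
genes rank by variance/mean dispersion of the normalized values with
deterministic gene-id tie-breaks.  Pseudobulk cluster correlation is
Spearman over the top-3000-SD gene panel (panel computed on the
wild-type profiles); on the synthetic panel this metric is weakly
discriminative — cluster rank order is pinned by per-gene amplitude, so
all cluster pairs correlate near 1 — a limitation of the small clean
panel, not of the implementation, and the reason tests assert its
contracts (bounds, symmetry, monotone-transform invariance) rather than
cluster rankings.  Differential expression is a two-sided Wilcoxon
rank-sum on normalized values with log2 fold change of means
(pseudocount 1) and the |log2FC| > 1, P < 0.01 calling rule; the
hurdle-model test the thresholds originate from is deliberately out of
scope.

## Determinism and problem sizes

Every stochastic stage consumes a sub-seed derived from the master seed
via `SeedSequence`, and reruns produce byte-identical outputs (asserted
in tests).  The test and acceptance workloads use the study sizes the
analyses are stated at — 50 noiseless genes x 300 cells for parameter
recovery, 500 genes x 200 cells/sample for the null calibration, 200
genes x 500 cells/sample for the knockout study — which keep a full run
of everything in a few minutes on one core.
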