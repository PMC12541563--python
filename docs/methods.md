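# Methods

This note documents the models and procedures implemented in `metaprog`,
the defaults and why they were chosen, and what the synthetic cohort does
and does not establish about real data.

## Pipeline model

### Normalization

NMF requires a non-negative input, so each sample is normalized to
`log1p(CP10K)` (counts per 10,000, log-transformed) over all genes detected
in at least `min_cells = 3` cells. No highly-variable-gene selection is
applied by default and no centering/scaling is performed (either would
break non-negativity); library sizes are computed within each sample,
matching the per-sample factorization design. CP10K is exactly invariant
to a common scaling of all counts; it is only asymptotically invariant to
per-cell depth, which is the usual limitation of proportional
normalization.

### Per-sample NMF

`X ≈ WH` with `W ≥ 0` (genes × k), `H ≥ 0` (k × cells), minimizing the
Frobenius error by Lee–Seung multiplicative updates. Design choices:

- **Initialization**: seeded uniform random entries scaled by
  `sqrt(mean(X)/k)`, so the initial product matches `X` in magnitude.
- **Stopping**: relative objective decrease below `tol = 1e-4` over one
  iteration, or `max_iter = 500`. At the desk scales used here the updates
  typically converge in 100–300 iterations.
- **Numerics**: denominators are floored at `1e-10`, so no division by zero
  and no NaN/Inf can arise; the objective is computed through the Gram-trick
  identity `‖X−WH‖² = ‖X‖² − 2⟨WᵀX,H⟩ + ⟨WᵀW,HHᵀ⟩` with negative
  round-off clamped at zero. Multiplicative updates guarantee a monotone
  non-increasing trace; tests allow `1e-9` relative slack for round-off.
- **Identifiability**: NMF is invariant to diagonal rescaling of `(W, H)`,
  so factors are reported with unit-L2 `W` columns (scale folded into `H`)
  and sorted by decreasing `‖w_j‖·‖h_j‖`. Ties in loadings at program
  extraction break lexicographically by gene id, making "top-50 genes per
  factor" fully deterministic.
- **Restarts**: single seeded run by default; `restarts = r` takes the best
  of `r` consecutive seeds. Multiplicative updates find local optima, so a
  single documented seed keeps provenance simple and results reproducible.

The factorization rank defaults to `k = 15` per sample, the cohort default
to 9 samples, so 135 programs enter the cross-sample stage.

### Module scoring

The per-cell enrichment score of a gene set follows the binned-control
convention (as in Seurat's `AddModuleScore`): rank genes by mean expression
across the sample's cells (ties by gene id), cut into `n_bins = 24`
equal-frequency bins, draw `n_ctrl = 100` control genes per member from the
member's bin (seeded, without replacement, member excluded; the whole bin
is used when it is smaller than `n_ctrl`), and report

`score_c = mean_{g ∈ set} x_gc − mean_{g ∈ controls} x_gc`

over the pooled multiset of controls. The score is exactly zero when all
gene profiles are identical and is unchanged by adding a constant to a
cell's column (given fixed binning), so it measures set-specific deviation,
not cell depth.

Scores are computed **per sample** (each sample's own bin structure and
gene universe) and concatenated over pooled cells; genes missing from a
sample's universe are dropped with the effective set size logged. Control
draws are seeded per (sample, program) through a hash of the identifiers,
so scoring is deterministic and independent of program order. A merged
all-cohort binning was considered and rejected as the default because bins
would then mix sample-specific depth profiles; the per-sample route keeps
each sample's expression strata intact.

### Meta-programs

Programs are correlated (Pearson, over all pooled cells; constant columns
get correlation 0 with everything, logged) and clustered agglomeratively on
the distance `d = 1 − r`, cutting all merges above height `1.3`.

- **Linkage**: `complete` by default (`average`, `single`, `ward` are
  accepted in the configuration). This choice is forced by geometry: on
  `d = 1 − r` (range 0–2) a cut at 1.3 can separate two clusters only if
  their linkage distance exceeds 1.3, i.e. only where scores are
  *anti-correlated*. Per-sample factorization at a rank above the true
  state count always produces residual factors whose scores correlate with
  nothing (`r ≈ 0`, `d ≈ 1`). Under average linkage such factors act as
  bridges: they attach to a tight cluster at `d ≈ 1` and drag the average
  inter-cluster distance below 1.3, collapsing everything into one cluster
  (observed on the synthetic cohort: one cluster, zero MPs). Complete
  linkage merges two clusters only if *every* cross pair is closer than the
  cut, so a single anti-correlated pair keeps genuine states apart while
  residual factors are still absorbed. Ward over-fragments tight blocks at
  this cut height (observed: 11 clusters).
- **MP filters**: a cluster becomes a meta-program when it has
  `min_programs = 3` members from `min_samples = 2` distinct samples
  (recurrence across the cohort) and mean pairwise member correlation
  `min_coherence = 0.3`. The coherence filter operationalizes the defining
  property of a meta-program — member programs whose per-cell scores are
  mutually correlated — and discards any loose cluster of mutually
  uncorrelated residual factors that happens to satisfy the size filters.
  All three are configuration fields; `min_coherence = 0` disables the
  coherence test.
- **Consensus genes**: the `n_consensus = 50` genes occurring most
  frequently among member programs' top-50 lists; ties break by better
  (lower) mean within-program rank, then lexicographically. The consensus
  is always a subset of the member union, with length
  `min(n_consensus, |union|)`.
- **Assignment**: a cell's MP score is the mean of the MP's member-program
  score columns; the label is the argmax, ties to the lower MP number.

### Recovery metrics

Planted shared programs are matched one-to-one to recovered MPs by
maximizing total Jaccard similarity (Hungarian assignment on gene sets).
Reported: per-match Jaccard, recovered-MP count, mean Jaccard over planted
programs (unmatched planted programs count 0), and — when per-cell labels
are supplied — the fraction of planted-active cells (dominant planted
program by activity) labeled with the matched MP.

## Synthetic cohort generator

For cell `c` of a sample and gene `g`:

```
rate_gc  = baseline_g · (1 + Σ_p activity_cp · weight_gp)
p_gc     = rate_gc / Σ_g rate_gc
count_gc ~ Poisson(libsize_c · p_gc)
```

with `baseline_g` log-normal (cohort-level: gene baselines are conserved
across patients), `libsize_c` log-normal per cell, `weight_gp =
program_weight` on a program's member genes, and `activity_cp` gamma for a
seeded `active_fraction` subset of in-scope cells. Program gene blocks are
pairwise disjoint by construction, carved from one permutation of the gene
universe, so Jaccard-based recovery is unambiguous. Per-cell rates are
renormalized after adding program effects, which keeps the expected cell
total equal to the drawn library size and decouples depth from program
load. All randomness flows from one seed through a single generator stream
in a documented order (see the module docstring), so cohorts are
bit-reproducible.

**Exclusive states.** Shared programs model discrete transcriptional
states: within a sample their active-cell subsets are sampled mutually
exclusively (each a uniformly random `active_fraction` subset, pairwise
disjoint) whenever `n_shared_programs · active_fraction ≤ 1`; otherwise,
and for all private programs, gates are independent Bernoulli. This is the
load-bearing realism choice: real cell states (cycling vs. stem-like vs.
stress) are largely mutually exclusive, which makes their enrichment scores
anti-correlated — for `S` equally likely exclusive states, score
correlation between two states approaches `−1/(S−1)` (= −1/3 for four
states, distance ≈ 1.33). Without exclusivity (independent gates), planted
program scores are uncorrelated and *no* linkage can separate them with a
1.3 cut on `1 − r`; a pipeline validated only on independent programs would
be untestable at that operating point. The `exclusive_states=False` switch
restores fully independent gates for sensitivity analyses.

### Default parameters

| parameter | default | rationale |
|---|---|---|
| `n_samples` | 9 | cohort size of the emulated study design |
| `cells_per_sample` | 400 | desk scale; enough cells for stable per-cell moments and correlations |
| `n_genes` | 2000 | desk scale; 650 planted + 1350 background genes |
| `n_shared_programs` | 4 | shared states to recover |
| `n_private_programs_per_sample` | 1 | patient-specific module per sample |
| `genes_per_program` | 50 | matches the top-50 program size used downstream |
| `program_weight` | 8 | with mean activity 2, an active program claims ≈ 25–35 % of a cell's library — the load of strong real modules (ribosomal, cell-cycle) |
| `active_fraction` | 0.25 | 4 × 0.25 tiles each sample into four exclusive states |
| `activity_shape`, `activity_scale` | 8, 0.25 | gamma mean 2, CV ≈ 0.35: cells differ in state intensity without blurring state membership |
| `baseline_log_mean/sd` | 0, 0.5 | moderate spread of baseline expression; keeps planted elevations above the top housekeeping values in log space |
| `libsize_log_mean/sd` | 8.5, 0.35 | ≈ 4,900 median counts per cell, typical snRNA-seq depth |
| `seed` | 1 | documented default stream |

Stage seeds default to: generator 1, NMF `42 + sample_index`, scoring 7.

## What the synthetic cohort does and does not show

The generator reproduces the features that make meta-program discovery
well- or ill-posed: shared vs. private programs, sparse graded activity,
per-gene baselines, depth variation, Poisson noise, and the
anti-correlation structure of exclusive states. It deliberately omits
doublets, ambient RNA, batch effects, overlapping program gene sets, and
continuous (trajectory-like) state gradients. Passing recovery tests
therefore demonstrates that the pipeline's stages compose correctly and
that its operating point (cut 1.3, complete linkage, the MP filters) can
detect planted recurrent states under realistic noise — not that the same
configuration is optimal for any particular real data set, where program
overlap, weaker effect sizes and technical structure will lower
correlations and Jaccard recovery.

## Degenerate inputs and edge behavior

- Zero-total cells are dropped with a warning at normalization; filtering
  away every gene raises a degenerate-input error.
- Gene sets entirely absent from a sample's universe raise a scoring error;
  partially absent sets are scored on the intersection and logged.
- Constant score columns get correlation 0 (logged), keeping the
  correlation matrix well defined.
- An empty meta-program list is a warning from cluster filtering but a
  contract error for cell assignment.
- Factor count `k` must not exceed either matrix dimension; `n_top` must
  not exceed the gene universe.

## Problem sizes

Defaults are sized for a laptop-class single CPU: the full default cohort
(9 × 2000 × 400) runs end-to-end in ≈ 7 s in memory and ≈ 11 s through the
on-disk pipeline; the five-seed recovery study completes in under a minute.
Larger cohorts scale linearly in cells and genes per NMF iteration.

## Known limitations

- The Frobenius objective with multiplicative updates finds local optima;
  different seeds give different (usually equivalent-quality)
  factorizations. Use `restarts` when a best-of-r factorization is wanted.
- KL-divergence NMF, automatic rank selection, AUC-style scoring, and
  pathway annotation of MP gene sets are out of scope; MP `annotation` is a
  free-text field for the analyst.
- Pooled-cell Pearson correlation weights samples by their cell counts;
  cohorts with very unbalanced sample sizes may want per-sample correlation
  aggregation, which is not implemented.
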