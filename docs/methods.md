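# Methods

## Differential binding from spectral counts

A BioID experiment yields a protein × sample matrix of peptide-spectrum-match
(PSM) counts for a bait fusion and a control fusion, with a handful of
replicates each.  bioidnet models these counts as negative binomial,
Var(Y) = μ + φμ², with one dispersion φ shared by every protein — the only
stable choice at 2–3 replicates per condition, where per-protein dispersions
are essentially unidentifiable.

Processing order matters and is fixed: missing cells are set to PSM 0
(undetected peptide, not missing-at-random), each sample is scaled by
(grand mean of sample totals)/(its own total) so column totals equalize while
the count scale is preserved for the NB model, and the detection filter
(raw PSM > `min_psm` in at least `min_reps` bait replicates) is evaluated on
**raw** counts in **bait** samples only — the rule expresses repeated
detection of the labeled protein, not control carryover.

φ is estimated by maximizing the pooled Cox–Reid adjusted profile likelihood:
for fixed φ the NB mean MLE of each protein × condition group is its sample
mean, and the adjustment term −½ log I(μ̂) per group (I the Fisher
information of the group's log-mean) removes the downward bias that plain
profiling incurs by spending one degree of freedom per group.  Without the
adjustment the estimate is biased low by roughly (n−p)/n (≈ 0.19 at true
φ = 0.3 with 3 + 3 samples), which makes the downstream test anticonservative
(measured type-I 0.128 at nominal 0.05); with it, null simulations at 3 + 3
give φ̂ ≈ 0.30 at truth 0.3, type-I error 0.042–0.066 over 12 seeds, and
Kolmogorov–Smirnov distance to uniform ≤ 0.042.  The NB log-likelihood is
evaluated in its gamma-function form, which is continuous in y, so
sum-normalized real-valued counts need no rounding; φ → 0 reduces to the
continuous Poisson log-likelihood.

The per-protein test holds φ at the common estimate, so both the full model
(separate bait/control means) and the null (one mean) have closed-form MLEs
(group sample means); Λ = 2(ℓ_full − ℓ_null) is referred to χ² with 1 df.
All-zero proteins receive Λ = 0, p = 1, log-fold-change 0, keeping the
ranking total.  Log₂ fold-changes use a 0.5 pseudo-count per condition mean
(bounded when controls are all zero), p-values are Benjamini–Hochberg
adjusted over the tested (filtered) proteins, and candidates require
adjp < α **and** fold-change > `fc_min`, both strict.

Defaults: α = 0.05, `fc_min` = 3, `min_psm` = 2, `min_reps` = 2 — the
published operating point for this type of screen.

Set-overlap statistics (e.g. candidates vs an external interaction database)
use the 2 × 2 in/out table: odds ratio with Haldane's 0.5 correction only
when a zero cell occurs (flagged in the output), chi-squared test without
continuity correction.

## Network construction and Markov clustering

Edges come from a STRING-dialect list (protein1, protein2, combined score in
(0, 1]).  The score cutoff is strict (> 0.4 by default, the "intermediate
confidence" convention); self-edges are dropped, reciprocal duplicates merged
keeping the maximum score (conservative and deterministic), and degree-0
nodes pruned before analysis.

MCL treats the weighted adjacency itself as flow capacity (scores are not
binarized).  Self-loops with weight equal to each node's maximum incident
edge weight damp the period-2 oscillation of bipartite-ish structures; the
matrix is column-normalized and then alternately squared (expansion) and
raised elementwise to the inflation power with entries < 1e-5 pruned and
columns renormalized, until successive iterates differ by < 1e-8 (idempotent
flow) or 200 iterations, whichever first — non-convergence is flagged, not
fatal.  Clusters are the attractor systems of the converged matrix; a node
reached by several systems joins the one holding more of its column mass,
ties to the smaller preliminary id.  Cluster ids are renumbered by decreasing
size, ties by smallest member symbol, so outputs are reproducible across
runs and node orderings (verified by an isomorphism test).  Inflation
defaults to 2.0, the canonical MCL granularity; it is exposed in the config
and the regression tests pin its behavior (ARI ≥ 0.9 on 4 × 15
planted-partition graphs with p_in 0.6 / p_out 0.02).

Topology metrics (degree, average shortest path, closeness) are computed on
the unweighted skeleton, per connected component: average shortest path is
the mean hop distance to reachable nodes and closeness is
(reachable nodes)/(sum of distances to them), matching the hop-based
definitions of standard network-analysis tools.

## Specificity filtering

A bait/control interaction survey (many transcription-factor baits vs many
unrelated control baits) labels proteins `specific` or `nonspecific`;
proteins absent from the survey are `unobserved` — the potential new
interactors.  Clusters whose fraction of nonspecific members exceeds
`max_nonspecific_frac` (default 0.5, a majority rule; the choice is exposed
in the config) are dropped and the survivors renumbered.  This removes the
hubs of sticky background proteins (heat-shock, cytoskeleton) that every
pulldown recovers.

## Heat diffusion and ranking

Seed genes (phenotype-associated) carry initial heat 1.  Heat evolves under
dh/dt = −L h with the weighted combinatorial Laplacian L = D − W — weighted,
for consistency with the MCL flow matrix — and is read out at t = 0.25
(dimensionless diffusion time; small t keeps heat local to the seeds, large t
approaches the per-component uniform distribution).  The kernel exp(−Lt)
conserves total heat exactly, which the tests exploit (conservation to 1e-8,
long-time limit to 1e-6, linearity in seeds to 1e-9).  Computation is by
symmetric eigendecomposition up to 5000 nodes and by sparse
matrix-exponential action above; t = 0 returns the seed vector exactly.  A
normalized-Laplacian variant sits behind a flag (off by default) for users
who want degree-corrected propagation.  Seeds absent from the network are
dropped with a warning rather than added as isolated nodes — an isolated
seed cannot propagate and would distort the conservation checks.  Ranking is
by descending heat with lexicographic tie-break; the ranked table is
restricted to called candidates (top `top_k` = 30 by default) and annotated
with cluster id and specificity class.

Category over-representation of a gene set uses a resampling null:
size-matched uniform draws without replacement from the universe, with the
add-one estimator p = (1 + #{null ≥ observed})/(n_resamples + 1), which never
returns 0 and agrees with the exact hypergeometric tail within Monte-Carlo
error (verified on small universes).

## Synthetic data: what it emulates, and what it does not

`simulate_psm` draws counts NB(μ = baseline · libsize · fold^[planted ∧ bait],
φ), then zeroes each cell independently with probability `zero_rate`.
Defaults: 500 proteins, 60 planted interactors at fold 8, φ = 0.3,
baseline mean 20 PSM, 3 + 3 replicates, lognormal library-size factors with
σ = 0.2 (≈ 20% loading spread, the scale sum normalization is meant to
remove), dropout 0.02.  The dropout rate is deliberately small: the
mechanism is abundance-independent per-cell dropout, and in real MS data
missingness concentrates in low-abundance peptides — a uniform rate much
above a few percent would routinely delete high-abundance bait observations,
which no instrument does.

`simulate_network` builds a weighted planted-partition graph (blocks = known
modules; within-block edge probability p_in = 0.6, between p_out = 0.02;
weights uniform on [0.41, 1] so construction at the 0.4 cutoff never shrinks
the planted blocks), places three seed genes in a designated block and labels
another block nonspecific.  The default 4 × 15 layout reuses the first 60
planted protein symbols so the PSM and network stages compose into one
coherent end-to-end fixture.

What the generator does **not** emulate: peptide-to-protein mapping and
shared peptides, abundance-dependent missingness, correlated contamination
across samples, the heavy-tailed abundance distribution of real proteomes
(baseline mean is constant), or scale-free network topology.  Passing tests
therefore certify the statistical machinery under its stated model, not
instrument-level realism.

One measured property of the composed defaults deserves note.  Sum
normalization is compositional: 60 proteins truly enriched at fold 8 add
≈ 84% to bait totals at 500 proteins, so the realized post-normalization fold
is ≈ 8/(1 + 7·60/n_proteins) ≈ 4.4, and with a correctly calibrated test at
3 + 3 replicates and φ = 0.3 the pipeline recovers roughly 20–50% of planted
interactors at the default bundle (70–85% when the planted fraction is
diluted to 2000+ proteins), always with observed false discovery well under
10%.  Recovery near 90% at these settings is achievable only by an
anticonservative test — the uncorrected-profile-likelihood variant reached
it, and simultaneously failed null calibration.  bioidnet prefers the
calibrated test; sensitivity at fixed fold rises with replicates or with a
lower planted signal mass, not with looser inference.

## Numerical choices

- Dispersion optimizer: bounded scalar minimization of the negative adjusted
  profile likelihood on φ ∈ [0, 50], xatol 1e-8; estimates < 1e-6 with no
  likelihood gain over φ = 0 snap to the Poisson boundary.
- LRT statistics are clamped at 0 (profiling noise can produce −1e-12).
- MCL pruning threshold 1e-5, convergence 1e-8 on the max-norm of successive
  iterates; columns that prune to zero renormalize to themselves (guarded).
- Eigendecomposition heat values are clipped at 0 (eigensolver noise at the
  boundary of the nonnegative cone).
- All output tables use fixed column order and %.6g float formatting, so
  identical configs produce byte-identical files.

## Limitations

- One common dispersion is a modeling choice, not a fact about proteomes;
  with ≥ 5 replicates per arm, per-protein or trended dispersions would be
  preferable.
- The detection filter ignores control counts by design; a protein abundant
  in both arms passes the filter and is left to the fold-change threshold.
- MCL is dense-matrix (O(n³) per iteration): comfortable to a few thousand
  nodes, not for proteome-scale graphs.
- The resampling null treats genes as exchangeable within the universe; it
  does not condition on degree or abundance.
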