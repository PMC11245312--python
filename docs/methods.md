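# Methods

## Model and estimation

Each bulk sample is modelled as a multinomial draw over genes whose
probability vector is a convex mixture of cell-state reference profiles:
`x ~ Multinomial(n, A θ)` with `A` (gene × state) column-stochastic and `θ`
on the simplex. This is the topic-model view of deconvolution; the "cell
state" layer lets one cell type contribute several expression programs, and
type-level fractions are obtained afterwards by summing state fractions
within each type.

Estimation iterates the conditional mean of the latent per-read state
assignments instead of sampling them. Writing the per-gene responsibility
`r_{g,s} = A_{g,s} θ_s / Σ_{s'} A_{g,s'} θ_{s'}`, one update is
`θ'_s ∝ Σ_g x_g r_{g,s}`. This is exactly the EM update for the multinomial
mixture, so the data log-likelihood `Σ_g x_g log(Σ_s A_{g,s} θ_s)` is
non-decreasing along the trajectory and a fixed point is a stationary point
of the likelihood (the MLE on identifiable instances). A Gibbs sampler for
the same model targets the posterior whose mean coincides with this fixed
point up to O(1/n) terms; the derandomised update computes that limit
directly, one vectorised pass over all genes per iteration, with no
Monte-Carlo noise and no chains to store.

An optional symmetric Dirichlet concentration α over states turns the
update into MAP estimation (expected state counts shifted by α − 1 and
clipped at zero). The default is α = 1 — the flat prior, plain maximum
likelihood — which is also what the Gibbs oracle uses, so the two targets
match in the equivalence tests.

### Numerical choices

- Initialisation is uniform over states. On identifiable instances the
  fixed point does not depend on the start; uniform is the symmetric
  choice and makes runs reproducible without a seed.
- Stopping: max-absolute change in θ below `tol` (default 1e-6) or
  `max_iter` (default 100) iterations, per sample, whichever comes first.
  Samples are independent; the vectorised sweep freezes each sample's θ the
  moment it converges, so batching cannot change any sample's answer.
- A sample with zero total signal cannot be deconvolved: it is flagged
  (`converged = False`), gets the uniform vector, and the run continues.
- A gene with positive bulk signal but zero mixture density would make the
  responsibility undefined. The reference builder prevents this by adding a
  pseudocount (default 1e-8 per gene) before normalisation, so no state
  assigns exactly zero probability to a retained gene; if a degenerate
  denominator still arises (hand-built references), the model raises
  rather than silently renormalising.
- Bulk input must be on a linear scale. A heuristic warns when the matrix
  maximum is below 50, which almost always means log-transformed input.
- Genes are matched between bulk and reference as exact strings; the
  intersection is taken in reference order and reference columns are
  re-normalised over the retained genes.

## Reference construction

`ref_prepare` pools raw counts of all cells sharing a state label and
normalises each pooled column — the maximum-likelihood profile estimate
under the multinomial model. Genes with zero counts in every state are
dropped (keeping them would only dilute the normalisation; they carry no
signal). State ids are namespaced as `type.state` so they remain globally
unique; a state label observed under two different type labels is an error.

When the source data has no state annotation, `derive_cell_states`
partitions each type's cells by k-means into `min(states_per_type, n_cells)`
clusters on library-size-normalised, log1p-transformed profiles.
Depth-normalisation is applied because library size is a technical nuisance
that would otherwise dominate the clustering. This is deliberately a plain,
deterministic stand-in for full subclustering workflows (graph clustering,
marker curation); granularity tuning is the user's responsibility and the
evaluation pipeline exists to compare the candidates.

## Cell-type-specific expression and the reference update

The fit stores only θ and the gene × sample denominator
`d = A θᵀ` ("the 2D scaling matrix"). Any type's slice of the 3D array is
reconstructed as `Z_{g,n,k} = X_{g,n} · (Σ_{s∈k} A_{g,s} θ_{n,s}) / d_{g,n}`,
with `Z = 0` wherever `X = 0`. Because responsibilities sum to one over
types, `Σ_k Z_{g,n,k} = X_{g,n}` holds exactly; this conservation, and the
bit-level equality of compressed vs direct reconstruction, are tested. The
array axis order is gene × sample × type.

The optional second round re-estimates a type-level reference from Z —
`pooled` (sum over samples per type, add the same 1e-8 pseudocount,
normalise) or `per_sample_malignant`, where a named malignant type keeps
one profile per sample (tumour expression is patient-specific) while
environment types stay pooled — and re-deconvolves at type resolution. On
exact-fit data the update is a fixed point: it returns the original
profiles and the second round reproduces the first-round fractions. The
update is off by default; empirically it does not reliably improve
accuracy, and the evaluation pipeline can quantify its effect per dataset.

## The Gibbs oracle

`statemix.testing.gibbs` implements the randomised counterpart: alternately
sample per-gene assignment counts `z_g ~ Multinomial(x_g, r_g)` — collapsed
per gene, which is distributionally identical to read-level sampling — and
`θ ~ Dirichlet(α + Σ_g z_g)`. The post-burn-in mean estimates the posterior
mean; its Monte-Carlo standard error is computed by batch means (25
batches), which stays honest under the chain's autocorrelation where a
naive iid standard error would be several-fold too small.

The agreement battery draws random instances with ≤ 5 genes, ≤ 3 states and
total counts of 100k–200k, and asserts element-wise agreement of the fixed
point with the sampled mean within 3 MCSE. Two deliberate restrictions
define the comparison regime:

- **Conditioning.** Instances whose reference matrix has smallest singular
  value below 0.15 are rejected. With nearly collinear state columns the
  fractions are weakly identifiable: the posterior is a long skewed ridge
  whose mean sits measurably away from the MLE, and the chain mixes slowly
  along it. That gap is a property of weak identifiability, not of
  derandomisation, and no point estimator is stable there.
- **Interior truth.** True fractions are redrawn until every coordinate is
  ≥ 0.05. At a simplex vertex the MLE can land on the boundary while any
  posterior mean is necessarily interior, again separating the two
  summaries for reasons unrelated to the algorithm.
- **Count scale.** The fixed point is the MLE; the posterior mean carries a
  finite-count offset of order 1/n while the Monte-Carlo band shrinks only
  like 1/√n_keep. At ~10k counts that offset (~1e-3) is already resolvable
  by a 20k-draw chain, so the battery runs at ~100k counts where the two
  estimators agree to ~3e-4, below Monte-Carlo precision. Chain defaults:
  2000 burn-in, 20 000 kept draws.

## Synthetic data

`simulate_dataset` generates: per-type base profiles
~ Dirichlet(profile_separation per gene; default 0.1 — sparse, distinct,
gene-expression-like), per-state profiles ~ Dirichlet(state_concentration ·
base; default total 5000, i.e. states deviate from their type's base by a
~40–50% relative sd on typical genes), cells ~ Multinomial(cell_depth,
Dirichlet(noise · state profile)) with noise = 1000 giving per-cell,
per-gene variability of roughly the same magnitude as the mean — moderate
single-cell noise. Cells are split 50/50 per state into disjoint reference
and simulation halves; pseudobulk columns are multinomial draws from the
mixture of the *simulation* half's pooled state profiles at Dirichlet-drawn
type fractions split equally among each type's states. Two off-model
stressors are available: `shift_reference` multiplies the reference half's
counts by per-gene log-normal factors (platform bias between reference and
bulk), and `overdispersion` adds gamma-weight extra-multinomial variance to
the bulk draws.

Default sizes (1000 genes, 8 types × 2 states, 200 cells/state, 100
samples × 100k reads) are the benchmark's study conditions and also what
`scripts/acceptance.py` runs, with `shift_reference = 0.2`.

What the generator does **not** emulate: real platform-specific count
distributions (UMI saturation, dropout structure), batch effects within the
single-cell data, correlated gene modules, rare cell types at realistic
abundance skews, or mismatched cell-type ontologies between reference and
tissue. Passing the held-out benchmark shows the estimator recovers
mixtures when the model family and label structure are right and the
reference is mildly perturbed — not that any particular real reference
generalises to any particular cohort; that is what the evaluation pipeline
is for, per dataset.

## Evaluation

`evaluate_fractions` scores type-level fractions: per type, Pearson r and
RMSE across samples, plus the mean over types. Types with zero variance in
the truth (or the estimate) have no defined correlation; they are excluded
from the mean with a warning rather than given an arbitrary value. Types
are matched by id, and types present on only one side are reported, never
dropped silently. `compare_references` ranks candidate references by mean
per-type r with a stable tie-break in input order. `nnls_baseline`
(non-negative least squares of bulk proportions on type-pooled profiles)
is a deliberately simple regression baseline for the harness, not a
recommended estimator.

## Known limitations

- The per-sample EM converges linearly; near-collinear references converge
  slowly and may hit the iteration cap before the tolerance (flagged in
  `converged` / `n_iter_used`). The estimates at the cap are still the best
  likelihood ascent so far, but users should inspect the flags.
- No posterior uncertainty is reported — derandomisation replaces the
  sampler with its mean, which is the method's point; use the oracle
  sampler (desk scale only) if a posterior spread is needed.
- The reference update's per-sample malignant mode assumes the malignant
  type is present in every sample; a sample with zero malignant mass is an
  error rather than a silent fallback.
- Gene identifiers are matched as exact strings; symbol/Ensembl
  harmonisation is upstream scope.
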