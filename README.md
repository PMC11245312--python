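# statemix

Reference-based cell-type deconvolution of bulk RNA-seq, using a
deterministic fixed-point algorithm in place of Gibbs sampling.

Bulk tissue expression is a mixture of signals from heterogeneous cell
populations — in tumours, malignant cells plus the immune and stromal
microenvironment. `statemix` estimates, for every bulk sample, the fraction
of reads contributed by each **cell state** (a fine-grained expression
program) and each **cell type** (states summed within a type), given a
reference built from single-cell RNA-seq of similar tissue. It can also
apportion every gene's bulk signal among cell types (the "Z" array), and it
ships a pseudobulk simulator plus an evaluation pipeline for scoring and
comparing candidate references.

## Model

The model is a per-sample multinomial mixture, i.e. a topic model: reads are
words, samples are documents, cell states are topics, genes the vocabulary.
With reference profile A (gene × state, columns on the simplex) and unknown
state fractions θ, a bulk column x follows

    x ~ Multinomial(n, A θ).

Rather than Gibbs-sampling the latent per-read state assignments, each
iteration computes their conditional **mean** in one vectorised step:

    θ′_s ∝ Σ_g x_g · A_{g,s} θ_s / (Σ_{s′} A_{g,s′} θ_{s′})

This is EM for the multinomial mixture: the log-likelihood
Σ_g x_g log(Σ_s A_{g,s} θ_s) is non-decreasing and the fixed point is the
MLE, which the sampled posterior mean approaches in the large-count regime
(a collapsed Gibbs sampler is included under `statemix.testing` and the test
suite verifies the agreement instance by instance).

Cell-type-specific expression is never stored as a 3D array. The fit keeps
only θ and the gene × sample mixture denominator d_{g,n} = Σ_s A_{g,s} θ_{n,s};
any type's slice is rebuilt on demand as

    Z_{g,n,k} = X_{g,n} · (Σ_{s∈k} A_{g,s} θ_{n,s}) / d_{g,n},

which conserves the observed signal exactly: Σ_k Z_{g,n,k} = X_{g,n}.

## Worked example

```python
import pandas as pd
from statemix import fixture_small, ref_prepare, run_deconv, evaluate_fractions

ds = fixture_small(seed=0)                    # 50 genes, 3 types × 2 states
ref = ref_prepare(ds.sc_reference_half)       # reference from held-out cells
res = run_deconv(ds.pseudobulk, ref)          # fixed-point deconvolution
print(res.summary())
```

```
Deconvolution results
=====================
samples: 20   genes: 50   states: 6   types: 3
converged: 0/20   iterations: median 100, max 100

mean cell-type fractions across samples:
  T2                         0.4223
  T3                         0.3029
  T1                         0.2748
```

(`converged: 0/20` means no sample crossed the tight 1e-6 stopping
threshold within the default 100 iterations — the estimates at the cap are
already accurate, as the scores below show.)

```python
truth = pd.DataFrame(ds.true_type_fractions,
                     index=ds.pseudobulk.sample_ids, columns=ds.type_ids)
report = evaluate_fractions(res.type_fractions(), truth)
print(report.to_frame().round(4))
```

```
    pearson    rmse
T1   0.9995  0.0081
T2   0.9995  0.0067
T3   0.9990  0.0087
```

Per type, the Pearson r compares estimated vs true fractions across the 20
pseudobulk samples; RMSE is on the fraction scale. `res.reconstruct_expression("T1")`
returns the 50 × 20 expression slice attributed to type T1, and
`res.expression_array()` the full gene × sample × type stack, which sums
over types back to the input bulk matrix.

A command-line interface mirrors the library:

```
statemix simulate --config sim.json --out sim/
statemix build-ref --sc sim/sc_reference.mtx --labels sim/sc_reference.labels.tsv \
    --genes sim/sc_reference.genes.txt --barcodes sim/sc_reference.barcodes.txt --out ref.tsv
statemix deconvolve --bulk sim/pseudobulk.tsv --ref ref.tsv --out out/
statemix evaluate --est out/fractions_type.tsv --truth sim/truth_type.tsv --out report.json
```

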