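# otdeconv

Cell-type deconvolution of bulk RNA-seq with an entropic Wasserstein loss
and single-cell references.

Bulk RNA-seq measures the average expression of a mixed cell population.
`otdeconv` estimates the cell-type composition of each bulk sample from an
annotated single-cell reference, for researchers who have bulk cohorts
(e.g. pancreatic islets, kidney) and matching or public scRNA-seq atlases.
Unlike square-loss deconvolution (NNLS and its descendants), the loss here
is an optimal-transport distance in gene space, so it can exploit
gene–gene relationships — two histograms that differ only between tightly
co-expressed genes are close, not orthogonal.

## Model

Each cell type *t* has a reference expression histogram *C·ₜ* ∈ Σₙ (the
n-gene simplex), built by averaging the raw counts of that type's cells and
renormalizing; a normalized bulk sample *y* ∈ Σₙ is modeled as *y ≈ C p*
with unknown proportions *p* ∈ Σₖ.  The estimate solves

```
min_{p ∈ Σ_k}  W_γ(y, C p)_M  +  ρ ⟨p, log p⟩
```

where `W_γ(·,·)_M = min_{T ∈ U(p,q)} ⟨M, T⟩ − γ h(T)` is the
entropic-regularized Wasserstein distance (Sinkhorn distance) under a
gene × gene ground cost *M*, `h` is the plan entropy, and the ρ-term is a
smooth barrier keeping proportions strictly positive (defaults
γ = ρ = 0.001 on costs rescaled to max 1; see `docs/methods.md` for the
sign convention of the entropy term).

Supported ground costs, all computed from the reference cells: Euclidean,
cosine, Pearson-correlation distance, and **dissTOM** — the
topological-overlap dissimilarity of the soft-thresholded co-expression
network, `a_ij = |cor(x_i, x_j)|^β`,

```
d_ij = 1 − (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij).
```

When references from several individuals are available, each is deconvolved
separately and the results are merged by simplex-constrained least squares
on the reconstructed bulks, `min ‖Y − Σ_r w_r Ĉ⁽ʳ⁾P̂⁽ʳ⁾‖²` with
`Σ w_r = 1, w_r ≥ 0` — the weight of a reference reflects how similar its
individual's expression is to the bulk individual, which mitigates
batch/individual effects.

## Worked example

Simulate three donors with donor-level batch effects, build pseudo-bulk
mixtures from donor 0's held-out cells, and deconvolve with the ensemble:

```python
import numpy as np
from otdeconv import (
    DeconvConfig, SyntheticScenario, ensemble_deconvolve,
    generate_pseudobulk, generate_synthetic_truth, pearson_correlation,
    rmse, split_cells,
)
from otdeconv.ground_cost import ground_cost_from_reference
from otdeconv.io_qc import normalize_columns_to_simplex
from otdeconv.reference import build_signatures

scenario = SyntheticScenario(n_genes=100, n_types=4, n_individuals=3,
                             cells_per_type=60, individual_effect_sd=0.3, seed=0)
data = generate_synthetic_truth(scenario)

ref_ids, test_ids = split_cells(data.annotations, seed=0)
sc_ref = data.sc.subset_columns(ref_ids)
ann_ref = data.annotations[data.annotations["cell_id"].isin(ref_ids)]
donor = data.individuals[0]
held_out = [c for c in test_ids
            if data.annotations.set_index("cell_id").loc[c, "individual"] == donor]
pseudo = generate_pseudobulk(data.sc.subset_columns(held_out), data.annotations,
                             n_replicates=5, fraction=0.6, seed=0,
                             source_individual=donor)

yset = normalize_columns_to_simplex(pseudo.mixtures, epsilon=1e-9)
refs = build_signatures(sc_ref, ann_ref, by_individual=True)
costs = [ground_cost_from_reference(
             sc_ref.subset_columns(list(
                 ann_ref.loc[ann_ref["individual"] == r.individual, "cell_id"])),
             metric="dissTOM")
         for r in refs]
result = ensemble_deconvolve(yset, refs, costs, DeconvConfig(),
                             sample_ids=list(pseudo.mixtures.column_ids))

for ind, w in zip(result.individuals, result.weights):
    print(f"weight[{ind}] = {w:.3f}")
print(f"RMSE    = {rmse(pseudo.truth, result.combined_P):.4f}")
print(f"Pearson = {pearson_correlation(pseudo.truth, result.combined_P):.4f}")
```

Output:

```
weight[indiv_0] = 0.989
weight[indiv_1] = 0.011
weight[indiv_2] = 0.000
RMSE    = 0.0015
Pearson = 0.9988
```

The pseudo-bulks come from donor 0's cells, so the ensemble assigns that
donor's reference almost all of the weight; the recovered proportions match
the recorded sampling truth to about 0.1% per entry.

For real data the same pipeline is available from the shell:

```
otdeconv deconvolve --bulk bulk.tsv --reference sc.tsv --annotation ann.tsv \
    --metric dissTOM --ensemble --outdir run1
otdeconv benchmark --n-individuals 3 --replicates 20 --outdir bench1
otdeconv simulate --n-bulk 10 --outdir sim1
```

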