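# selfrep

Prediction of synthetic-lethal (SL) gene interactions by **graph-regularized
self-representative matrix factorization**. The known interaction matrix `X`
(symmetric, binary, zero diagonal) is approximated by `UᵀXU`, where each
column of the representation matrix `U` lies on the probability simplex:
`U[l, i]` is the weight of gene *l* in representing gene *i*. The objective

```
J(U) = ||X - UᵀXU||²_F + λ ||U||²_F + β Tr(UᵀLU)
```

adds an ℓ2 penalty (weight `λ`) and a graph penalty (weight `β`) built from
the Laplacian `L = D − S` of a gene functional-similarity matrix `S ∈ [0,1]ⁿˣⁿ`,
so functionally similar genes receive similar representations. The solver is
a relaxed majorization–minimization scheme: the gradient is split into
non-negative parts and each entry of `U` is rescaled multiplicatively, with
per-column scalars absorbing the simplex constraint. Iteration stops when the
relative objective change drops below `1e-4`. Prediction scores are
`X̂ = UᵀXU`; unknown pairs (`X_ij = 0`) are ranked by descending score.

## Package layout

| module | contents |
| --- | --- |
| `selfrep.data` | `GeneIndex`, `InteractionMatrix`, `SimilarityGraph`, `Hyperparameters`, builders/validation |
| `selfrep.model` | objective, gradient split, column scalars, multiplicative update, `fit`, `predict` |
| `selfrep.evaluation` | fold construction, fold masking, rank-based AUC (ties = ½), `cross_validate` |
| `selfrep.selection` | `grid_search` over (λ, β), one-dimensional `sensitivity_sweep` |
| `selfrep.simulate` | seeded synthetic networks with planted partner-group structure and a correlated similarity matrix |
| `selfrep.ranking` | descending ranking of unknown pairs, deterministic tie-breaking |
| `selfrep.workflow` / `selfrep.cli` | end-to-end fit → predict workflow with manifest; command-line interface |

## Command line

All inputs/outputs are TSV. Pair lists are headered (`gene_a`, `gene_b`);
similarity matrices are either square (gene ids in the first row/column) or
long form (`gene_a`, `gene_b`, `similarity`), auto-detected. A flat YAML
config can supply any option; explicit flags override it.

```bash
# generate a synthetic benchmark (pairs.tsv, similarity.tsv, truth.tsv)
selfrep simulate --out-dir data/ --n-genes 150 --n-groups 6 --seed 0

# fit on all known pairs, rank unknown pairs (ranking.tsv, trace.tsv, U.tsv, manifest.json)
selfrep fit --pairs data/pairs.tsv --similarity data/similarity.tsv \
            --out-dir run/ --lambda 0.0078125 --beta 0.03125 --top-k 100

# score pairs with a saved model
selfrep predict --pairs data/pairs.tsv --model run/U.tsv --out ranked.tsv --top-k 10

# 5-fold cross-validation (per-fold AUC + summary)
selfrep cv --pairs data/pairs.tsv --similarity data/similarity.tsv --out cv.tsv

# hyperparameter grid search / sensitivity sweep
selfrep gridsearch --pairs data/pairs.tsv --similarity data/similarity.tsv \
                   --out grid.tsv --lambda-grid 0.0078125 --beta-grid 0.0,0.03125
selfrep sweep --pairs data/pairs.tsv --similarity data/similarity.tsv \
              --out sweep.tsv --fix lambda --fix-value 0.0078125 --grid 0.0,0.03125,8.0
```

Default hyperparameters are λ = 2⁻⁷, β = 2⁻⁵; the default grid is
{2⁻⁸, 2⁻⁷, …, 2⁵}. Setting β = 0 gives the plain self-representation model
(no graph term), useful as an ablation.

With real data, point `--pairs` at an SL pair list (e.g. exported from an SL
interaction database) and `--similarity` at a precomputed gene functional
similarity matrix; computing such a similarity matrix from raw ontology
annotations is out of scope here. Genes present in the pair list but absent
from the similarity file get zero similarity rows (neutral graph penalty).

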