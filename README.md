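# ilrmr — weighted low-rank recovery of miRNA–disease associations

Experimentally verified miRNA–disease associations form a sparse
bipartite network: a binary matrix `X` (rows = miRNAs, columns =
diseases) in which a 1 is a curated association and a 0 simply means
*unknown*. Because diseases share pathways and miRNAs act in
functional groups, the true association matrix is approximately
low-rank, and unknown pairs can be prioritised by how well they fit
that latent structure. This package implements such a prioritisation
for computational biologists who have an association edge list plus
precomputed miRNA functional and disease semantic similarity matrices
(all plain TSV), and want ranked candidate associations together with
the standard evaluation protocols.

## The model

The network is decomposed into a low-rank score matrix `R` and a
sparse error `E`:

```
min  ‖R‖* + λ ‖Ω ∘ (X − R)‖₁     s.t.  X = R + E
```

with `‖·‖*` the nuclear norm, `∘` the Hadamard product and `λ`
defaulting to `1/√max(m,n)`. The elementwise penalty weight `Ω` is
derived from a confidence matrix `W` that integrates miRNA functional
similarity, miRBase family membership, disease semantic similarity and
the cosine similarity of association profiles:

```
Sim_mir = Sim_fun · (1 + Sim_cos) · (1 + FAM)
Sim_dd  = Sim_phe · (1 + Sim_cos)
W(i,j)  = ( ⟨Sim_mir[i,:], X[:,j]⟩/‖X[:,j]‖ + ⟨X[i,:], Sim_dd[:,j]⟩/‖X[i,:]‖ ) / 2
Ω(i,j)  = (1 + W(i,j))^(2·X(i,j) − 1)
```

so observed associations backed by high confidence are expensive to
explain away as error, while high-confidence zeros are cheap to
overwrite with a completed score. The program is solved by an exact
augmented-Lagrange-multiplier scheme (singular value thresholding for
`R`, weighted soft thresholding for `E`); entries of `R` are the
association scores. See `docs/methods.md` for assumptions, parameter
defaults and numerical details.

## Worked example

`examples/02_cross_validation.py` generates a planted 20×12 network
(rank 2, 37 known associations) and runs leave-one-out cross
validation with and without the confidence weighting:

```
network: 20 miRNAs x 12 diseases, 37 known associations
LOOCV AUC  with confidence weights: 0.8169  (AUPR 0.0695)
LOOCV AUC  plain robust PCA:        0.5511  (AUPR 0.0065)
```

Each known association is hidden in turn and must be ranked above
every unknown pair by a recovery run on the remaining network; AUC
1.0 would mean perfect separation and 0.5 chance. On this small, noisy
instance the similarity-derived weighting lifts the ranking from near
chance to clearly informative. The other scripts in `examples/` cover
candidate prediction, mask-ratio robustness, isolated-disease
prediction and the raw low-rank + sparse separation primitive, each
printing a short explanation with its numbers.

## Command line

The same workflows are available as subcommands operating on TSV files:

```
ilrmr simulate  --out-dir net --seed 1            # synthetic network to TSV
ilrmr predict   --assoc net/associations.tsv --sim-mir net/sim_mirna_functional.tsv \
                --sim-dd net/sim_disease_semantic.tsv --family net/families.tsv \
                --out predictions.tsv --top-k 50
ilrmr loocv     ... --out loocv.json
ilrmr mask-eval ... --ratio 0.3 --repeats 20 --seed 7 --out mask.json
```

Every run writes a JSON summary containing its full configuration and
seed, and identical invocations are byte-reproducible.

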