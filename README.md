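# pottsalign

Optimal pairwise alignment of protein **Potts models**, for remote-homology
analysis that uses direct residue–residue couplings, not just positional
composition.

Profile HMM tools compare proteins position by position; they are blind to
covariation between residues that are distant in sequence but coupled in
structure. `pottsalign` instead represents each protein by a Potts model —
the pairwise Markov random field that direct coupling analysis (DCA) infers
from an MSA of the protein's close homologs — and compares two proteins by
**aligning the models themselves**, so that similarity of coupling matrices
contributes alongside similarity of positional fields.

## The model and the alignment objective

A Potts model over sequences of length *L* on a *q*-letter alphabet assigns

P(x) ∝ exp( Σᵢ vᵢ(xᵢ) + Σ_{i<j} w_ij(xᵢ, xⱼ) )

with field vectors vᵢ ∈ ℝ^q and coupling matrices w_ij ∈ ℝ^{q×q}, fixed in
the zero-sum gauge. Models are inferred by regularized pseudo-likelihood
maximization with the field prior R(v,w) = λ_v‖v−v*‖² + λ_w‖w‖², where
softmax(v*ᵢ) equals the empirical column frequencies — so couplings are
added only where the data demand them. Before comparison, parameters are
smoothed for comparability: field softmax distributions are mixed with the
uniform distribution (weight τ_v) and coupling blocks are passed through a
base-β_w softmax, smoothed (τ_w) and mapped back, damping the spurious
anti-correlations that finite samples produce.

An alignment of models A and B is a strictly increasing set of matched
position pairs maximizing

s(A,B) = Σ s_v(vᵢᴬ, v_kᴮ)·x_ik + α_w Σ s_w(w_ijᴬ, w_klᴮ)·y_ikjl − gap costs

where s_v is the scalar product of background-corrected fields
⟨vᵢᴬ−v₀, v_kᴮ−v₀⟩ minus a per-pair offset γ, s_w is the Frobenius inner
product of coupling blocks, and gaps are affine. Because the coupling term
makes the problem non-local (it is related to contact-map overlap and is
expected NP-hard), the maximization is cast as an integer linear program
over node variables x_ik and edge variables y_ikjl and solved by
branch-and-bound (HiGHS) with a certificate: the returned alignment
satisfies 2(UB−LB)/(s(A,A)+s(B,B)) ≤ ε.

Computed alignments are scored against a reference by precision, recall and
F1 over matched residue pairs.

## Worked example

```python
import numpy as np
import pottsalign as pa

# two "homologous" models: copies of a common base, each with one extra
# background column inserted, ground-truth correspondence recorded
base = pa.random_potts_model(10, 20, field_scale=2.0, n_coupled_pairs=3,
                             coupling_scale=1.0, seed=0)
pair = pa.plant_homologous_pair(base, perturbation_scale=0.0,
                                n_insertions_A=1, n_insertions_B=1, seed=0)

# smooth parameters, then align with the trained defaults
# (gap open 13, α_w = 6, β_w = 8.0, γ = 1.0, τ_v = τ_w = 0.4, ε = 0.02)
A = pa.rescale_model(pair.model_A, pa.RescaleConfig())
B = pa.rescale_model(pair.model_B, pa.RescaleConfig())
res = pa.solve_alignment(A, B, pa.AlignConfig(), v0=np.zeros(20))
rep = pa.precision_recall_f1(set(res.alignment.pairs), set(pair.truth))
print(res.status, res.alignment.n_aligned, round(res.relative_gap, 6))
print(rep.precision, rep.recall, rep.f1)
```

prints

```
optimal 10 0.0
1.0 1.0 1.0
```

The solver proved the alignment optimal (relative gap 0 ≤ ε), matched all
10 true column pairs while skipping both inserted columns, and the
alignment reproduces the planted correspondence exactly (precision =
recall = F1 = 1).

The same pipeline is available from the shell:

```sh
pottsalign infer msa_A.fasta -o A.potts
pottsalign rescale A.potts -o A.rs.potts
pottsalign align A.rs.potts B.rs.potts -o aln.tsv
pottsalign eval computed.fasta reference.fasta --json
```

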