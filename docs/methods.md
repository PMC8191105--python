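# Methods

## Scope

`pottsalign` implements a complete desk-scale pipeline for Potts-model
("DCA-based") protein comparison: MSA preprocessing, pseudo-likelihood
inference of a Potts model, parameter rescaling for comparability, optimal
model-to-model alignment by integer linear programming with an ε-optimality
certificate, and precision/recall/F1 evaluation against reference
alignments. Homolog retrieval (building the input MSA of close homologs) is
out of scope; users supply MSAs in FASTA or A3M.

## Preprocessing

An input MSA is reduced before inference:

1. **Redundancy filter** at 80% identity, where identity is
   matches / min(ungapped lengths) with gap–gap columns ignored. The scan
   is greedy top-to-bottom (a row is kept iff its identity to every
   already-kept row is ≤ the threshold; the query row is always kept),
   which makes the filter deterministic. This emulates the HHfilter step
   commonly used in DCA pipelines; HHfilter's internal diff-based identity
   may differ in edge cases, so retained sets are comparable but not
   guaranteed identical to HHfilter's.
2. **Depth cap**: first 1000 rows.
3. **Column trim**: columns with strictly more than 50% gaps are removed;
   a `TrimRecord` keeps the map back to original column indices. After
   inference the trimmed columns are re-inserted with background fields
   v₀(a) = log f₀(a) − mean_b log f₀(b) and zero couplings, so downstream
   coordinates refer to the original sequence numbering.

The background frequency table f₀ is the Robinson & Robinson (1991) set
used across the PSI-BLAST/HH-suite lineage, renormalized to sum to 1.
No sequence weighting is applied before counting (none is part of this
pipeline's definition); this is a known difference from some DCA codebases.

Gaps are handled with a q = 20 alphabet: a gap contributes to no
amino-acid state in the frequency tables, contributes no conditional term
to the pseudo-likelihood, and never acts as a conditioning neighbour. A
q = 21 mode (gap as a state) exists in the frequency code but is off by
default. Gapped sequences cannot be energy-scored.

## Inference

The fit maximizes the regularized log-pseudo-likelihood

Σₙ Σᵢ log P(xᵢⁿ | x₋ᵢⁿ; v, w) − λ_v‖v − v*‖² − λ_w‖w‖²,

where each conditional is a softmax over q states of
vᵢ(a) + Σ_{j≠i} w_ij(a, xⱼⁿ), and v* is the zero-sum field vector whose
softmax reproduces the empirical column frequencies (after adding a
pseudocount ε = 1e-6 and renormalizing, to avoid log 0). Centering the
field prior at v* rather than 0 pushes explanatory weight onto fields and
admits couplings only where the data demand them, which is what makes
independently inferred models comparable.

Defaults: λ_v = 10, λ_w = 0.2·(L−1) (coupling regularization scaled with
the number of neighbours per position, standard DCA practice), both
exposed. Any strictly positive pair preserves the method's structure.
Optimization is L-BFGS on the stacked (v, upper-triangular w) vector with
analytic gradients, deterministically initialized at v = v*, w = 0 — no
random seed is involved in inference. Non-convergence within
`max_iterations` sets a flag in the model's provenance rather than raising.

The result is returned in the **zero-sum gauge**
(Σₐ vᵢ(a) = 0, Σₐ w_ij(a,b) = Σ_b w_ij(a,b) = 0), obtained by
double-centering every coupling block and compensating the fields; the
compensation used is vᵢ(a) ← vᵢ(a) + Cᵢ − Σ_{j≠i} K_ij(a) for blocks
shifted by w_ij(a,b) ← w_ij(a,b) + K_ij(a) + K_ji(b), which is verified in
the tests to leave every conditional distribution invariant (to 1e-9) for
fully observed sequences. Invariance does not extend to conditionals with
gapped neighbours, since their compensating terms are dropped by the gap
convention — a property the tests pin down explicitly.

## Rescaling

Two transforms make independently inferred models more comparable under
inner-product scores:

* **Fields**: the per-site softmax distribution pᵢ is replaced by
  (1−τ_v)·pᵢ + τ_v/q and mapped back to zero-sum fields. Identity at
  τ_v = 0; zero map at τ_v = 1.
* **Couplings**: each q×q block is read as a distribution over its q²
  entries through a softmax with base β_w > 1 (skewing weight towards
  large positive entries, since finite samples support positive
  correlations much better than anti-correlations), smoothed with τ_w, and
  mapped back via log/β_w minus the grand log-mean.

The coupling map centers over all q² entries jointly — exactly what the
formula prescribes — so rescaled models intentionally leave the strict
per-row/column zero-sum gauge. All softmaxes use max-subtraction; the
mixture log uses `logaddexp`; round-trip identities hold to 1e-10.
Rescaling is applied to the inferred (trimmed) model before background
columns are re-inserted, so re-inserted columns stay exactly v₀ / 0.

## Alignment

Score tables for a model pair hold s_v(i,k) = ⟨vᵢᴬ−v₀, v_kᴮ−v₀⟩ − γ (the
per-pair offset γ is folded in at build time, which is mathematically the
same as penalizing each aligned pair) and s_w(i,j,k,l) = ⟨w_ijᴬ, w_klᴮ⟩_F
for i<j, k<l. A `w_norm_threshold` knob can drop coupling terms with small
block norms for tractability; the default 0 keeps every pair, as the
reference formulation does.

The ILP has binary node variables x_ik, edge variables y_ikjl, and
consecutive-match arc variables z for the affine gap flow:

* antichain constraints per row/column tie the edges sharing a tail (or
  head) node to that node's variable;
* edges whose weighted score α_w·s_w is non-positive additionally get
  y ≥ x_tail + x_head − 1, so negative couplings cannot be silently
  deactivated (positive edges are pulled up by the objective and capped by
  the antichain constraints);
* Σ_{l≤k} x_il + Σ_{j<i} x_jk ≤ 1 keeps the selected nodes on an
  increasing path;
* a unit source→sink flow over the selected nodes charges
  gap_open·([j>i+1]+[l>k+1]) + gap_extend·((j−i−1)+(l−k−1)) on the arc
  between consecutive matches; with the trained gap_extend = 0 this is
  gap_open per gap segment. End gaps are free by default (reference
  alignments are structure-trimmed domains; a flag restores penalized
  ends). The empty alignment is always feasible via the source→sink arc.

The solver is HiGHS branch-and-bound (scipy's `milp`). The ε criterion
2(UB−LB)/(s(A,A)+s(B,B)) ≤ ε — with s(M,M) the identity-alignment score of
M under the same γ, α_w and threshold — is honoured in two phases: a first
solve with the solver's relative gap set to ε, accepted only if the
criterion verifies against the reported dual bound, otherwise a second
solve to proven optimality within the remaining time budget. Defaults:
ε = 0.02, time limit 21600 s. Reported pairs are strictly increasing;
re-scoring them from the tables reproduces the incumbent to 1e-6
(asserted in tests).

Trained default hyperparameters: gap open 13, gap extend 0, α_w = 6,
β_w = 8.0, γ = 1.0, τ_v = τ_w = 0.4.

Two independent oracles verify the solver: exhaustive enumeration of all
increasing pair sets (guarded to L ≤ 8; ties broken by fewest pairs, then
lexicographically) and, for the independent-site case α_w = 0, an exact
dynamic program over match predecessors that charges term-for-term the
same arc gap model (O((L_A·L_B)²) — an oracle, not a production aligner).
The printed edge-activation constraint family references an index
convention for its guard scores that is not defined anywhere; the
implementation applies the constraint's stated purpose (force activation
of non-positive edges when both endpoints are matched), which the
enumeration oracle confirms on ~10⁵ random instances across the test and
acceptance runs.

## Evaluation

Precision = correct/computed, recall = correct/reference, F1 = harmonic
mean, over exactly identical residue-index pairs (no ±k tolerance),
1-based, in original pre-trim numbering. F1 = 0 when P + R = 0.

## Synthetic fixtures: what they emulate, and what not

The generator produces (i) random zero-sum-gauge models with a chosen
number of dense coupled pairs, (ii) MSAs sampled from a model's Boltzmann
distribution — exactly, by enumerating all q^L states (guard q^L ≤ 1e6),
or by single-site Gibbs sampling (burn-in 100·L sweeps, thinning L sweeps,
settings recorded in provenance) — and (iii) planted homologous pairs:
two noisy copies of a base model with background-like columns inserted and
the true column correspondence recorded. Every function is pure given its
arguments and one integer seed.

Study conditions chosen for the planted-pair experiments, fixed once:
base length L = 10, q = 20, field scale 2.0 (column softmax odds of order
e^±4, i.e. well-conserved columns, matching the deep close-homolog MSAs
the method presumes), 3 coupled pairs of unit scale, one insertion per
side. Insertion slots are drawn from disjoint sets for A and B, pairwise
≥ 4 columns apart and ≥ 3 columns from the termini. The spacing rules are
not a convenience: with gap open 13 and τ_v = 0.4 smoothing, a planted
indel flanked by too few conserved columns (or facing an indel of the
other model across a short stretch) admits alternative alignments that
trade the gap cost against a handful of field matches, and *no* aligner
could be expected to prefer the planted correspondence there — the truth
would simply not be identifiable from the models.

The coupling-disambiguation construction plants two field-identical copies
of a block in model A and one copy in B, with a strong diagonal coupling
tying an anchor column to the second copy (and to B's copy). Fields alone
favour the first copy (no internal gap); the coupling term pays the gap
and recovers the truth, so coupled alignment beats independent-site
alignment — a desk-scale analogue of coupling-driven alignment of remote
homologs.

What the fixtures do **not** emulate: phylogenetic correlation among
sampled sequences (rows are i.i.d. draws; real homolog sets are
tree-correlated and effectively shallower), realistic gap patterns
(insertions are clean background columns, not ragged indel distributions),
alphabet composition bias, and model lengths beyond desk scale (the paper
pipeline runs to L = 200; the exhaustive/enumeration oracles cap the
verified regime at L ≤ 10 or so). Passing tests therefore demonstrate
correctness of the machinery and the qualitative value of couplings under
controlled conditions, not benchmark-level alignment quality on real
remote homologs.

## Numerical choices and degenerate inputs

* Gauge checks at 1e-8; conditional-invariance checks at 1e-9; smoothing
  round-trips at 1e-10; score re-evaluation at 1e-6.
* Problem sizes in the default test and acceptance runs: ~10⁵ enumerated
  alignments across 100 ILP-vs-brute-force instances (L ≤ 5), 50
  independent-site instances (L ≤ 8), 20 inference-recovery fits
  (L = 5, q = 4, N = 2000 exactly enumerated samples), and ~50 full
  pipeline solves at L ≤ 12 grids — chosen as the largest sizes the
  exhaustive oracles can certify.
* Empty MSAs, ragged rows, out-of-alphabet symbols, all-columns-trimmed
  MSAs, zero frequencies without pseudocount, non-positive β_w, τ outside
  [0, 1], mismatched alphabets and oversized enumeration requests all
  raise informative errors rather than propagating NaNs.
* Ties among equal-score alignments are solver-dependent in the ILP; the
  enumeration oracle defines the canonical tie rule (fewest pairs, then
  lexicographic) and score equality — not pair-list equality — is the
  contract checked against it.

## Known limitations

* Inference materializes the full (N, L, q) one-hot tensor and the dense
  (L, L, q, q) coupling gradient; fine for desk scale, not for L ≫ 100.
* The MILP grows as O(L_A²·L_B²) variables; real-scale pairs (L ~ 200)
  would need the coupling-sparsification threshold and a stronger solver
  configuration.
* Pseudo-likelihood precludes count-level pseudocounts; the rescaling
  transforms exist precisely to compensate, and would be unnecessary under
  an inference scheme that smooths counts directly.
* Gap handling is minimal by design (q = 20, gaps uninformative); models
  built from very gappy MSAs lose the trimmed columns' information
  entirely.
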