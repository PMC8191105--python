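"""Synthetic Potts models, sampled MSAs and planted homologous pairs.

Desk-scale stand-ins for the real pipeline's inputs: random gauge-fixed
models, sequences drawn from their Boltzmann distribution (exactly, by
enumerating all q^L states, or approximately by Gibbs sampling), and pairs
of "homologous" models obtained by perturbing a common base model and
inserting background columns, with the ground-truth column correspondence
recorded.  Everything is a pure function of its arguments and one integer
seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .alphabet import AMINO_ACIDS
from .model import PottsModel, symmetrize_couplings


def _alphabet_for(q: int) -> str:
    """Reduced amino-acid alphabet (first q canonical letters), so sampled
    MSAs remain readable by the protein-facing pipeline."""
    if q > len(AMINO_ACIDS):
        raise ValueError(f"q must be ≤ {len(AMINO_ACIDS)}")
    return AMINO_ACIDS[:q]


def _double_center(block: np.ndarray) -> np.ndarray:
    return (block - block.mean(axis=0, keepdims=True)
            - block.mean(axis=1, keepdims=True) + block.mean())


def random_potts_model(L: int, q: int = 20, field_scale: float = 1.0,
                       n_coupled_pairs: int = 0, coupling_scale: float = 1.0,
                       seed: int = 0) -> PottsModel:
    """Random zero-sum-gauge model with a chosen number of coupled pairs.

    Fields are i.i.d. normal (sd ``field_scale``) then centered; exactly
    ``n_coupled_pairs`` randomly chosen position pairs receive dense
    double-centered normal coupling blocks (sd ``coupling_scale``); all
    other couplings are zero.
    """
    if L < 1 or q < 2:
        raise ValueError("need L ≥ 1 and q ≥ 2")
    max_pairs = L * (L - 1) // 2
    if not (0 <= n_coupled_pairs <= max_pairs):
        raise ValueError(f"n_coupled_pairs must lie in [0, {max_pairs}]")
    rng = np.random.default_rng(seed)
    v = rng.normal(scale=field_scale, size=(L, q))
    v -= v.mean(axis=1, keepdims=True)
    w = np.zeros((L, L, q, q))
    all_pairs = list(itertools.combinations(range(L), 2))
    chosen = rng.choice(len(all_pairs), size=n_coupled_pairs, replace=False)
    for idx in chosen:
        i, j = all_pairs[idx]
        block = _double_center(rng.normal(scale=coupling_scale, size=(q, q)))
        w[i, j] = block
        w[j, i] = block.T
    if coupling_scale == 0:
        w[:] = 0.0
    return PottsModel(v=v, w=w, alphabet=_alphabet_for(q),
                      provenance={"generator": "random_potts_model",
                                  "seed": int(seed)})


def _energies_all_states(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """All q^L states and their (negative log-probability) energies."""
    L, q = model.L, model.q
    states = np.array(list(itertools.product(range(q), repeat=L)), dtype=int)
    e = model.v[np.arange(L), states].sum(axis=1)
    iu, ju = np.triu_indices(L, k=1)
    for i, j in zip(iu, ju):
        e += model.w[i, j][states[:, i], states[:, j]]
    return states, -e          # H = -(Σv + Σw)


def boltzmann_distribution(model: PottsModel) -> tuple[np.ndarray, np.ndarray]:
    """Exact state list and probabilities (q^L ≤ 1e6 guard)."""
    if model.q ** model.L > 1_000_000:
        raise ValueError("exact enumeration limited to q^L ≤ 1e6")
    states, H = _energies_all_states(model)
    logp = -H - (-H).max()
    p = np.exp(logp)
    return states, p / p.sum()


def sample_sequences(model: PottsModel, n: int, seed: int = 0,
                     method: str = "exact_enumeration",
                     burn_in_sweeps: int | None = None,
                     thinning_sweeps: int | None = None):
    """Draw ``n`` sequences from the model's Boltzmann distribution.

    ``exact_enumeration`` samples i.i.d. from the enumerated distribution
    (guard q^L ≤ 1e6).  ``gibbs`` runs a single-site Gibbs chain with
    100·L burn-in sweeps and thinning of L sweeps by default.
    """
    from .msa import MSA   # local import to avoid a cycle at import time

    rng = np.random.default_rng(seed)
    L, q = model.L, model.q
    if method == "exact_enumeration":
        states, p = boltzmann_distribution(model)
        draws = states[rng.choice(len(states), size=n, p=p)]
        prov = {"sampling": "exact_enumeration", "seed": int(seed)}
    elif method == "gibbs":
        burn = 100 * L if burn_in_sweeps is None else burn_in_sweeps
        thin = L if thinning_sweeps is None else thinning_sweeps
        x = rng.integers(0, q, size=L)
        draws = np.empty((n, L), dtype=int)

        def sweep():
            for i in range(L):
                # w[i,i] is zero, so including j=i in the sum is harmless
                logits = model.v[i] + model.w[i, np.arange(L), :, x].sum(axis=0)
                p_i = np.exp(logits - logits.max())
                p_i /= p_i.sum()
                x[i] = rng.choice(q, p=p_i)

        for _ in range(burn):
            sweep()
        for t in range(n):
            for _ in range(thin):
                sweep()
            draws[t] = x
        prov = {"sampling": "gibbs", "burn_in_sweeps": burn,
                "thinning_sweeps": thin, "seed": int(seed)}
    else:
        raise ValueError(f"unknown sampling method {method!r}")

    seqs = ["".join(model.alphabet[a] for a in row) for row in draws]
    return MSA(sequences=seqs, ids=[f"s{t}" for t in range(n)],
               alphabet=model.alphabet, provenance=prov)


@dataclass
class PlantedPair:
    """Two perturbed copies of a base model with the true correspondence."""

    model_A: PottsModel
    model_B: PottsModel
    truth: list[tuple[int, int]]
    recipe: dict

    def __post_init__(self) -> None:
        for (i, k), (j, l) in zip(self.truth, self.truth[1:]):
            if not (i < j and k < l):
                raise ValueError("truth correspondence must be strictly increasing")
        if self.truth:
            i_max = max(i for i, _ in self.truth)
            k_max = max(k for _, k in self.truth)
            if i_max >= self.model_A.L or k_max >= self.model_B.L:
                raise ValueError("truth indices out of model range")


def _insert_background_columns(model: PottsModel, positions_after: np.ndarray,
                               rng: np.random.Generator,
                               field_noise: float = 0.05
                               ) -> tuple[PottsModel, np.ndarray]:
    """Insert near-background columns; return new model and old→new index map."""
    L, q = model.L, model.q
    L_new = L + len(positions_after)
    inserted_slots: list[int] = []
    mapping = np.zeros(L, dtype=int)
    insert_counts = np.bincount(positions_after, minlength=L + 1)
    pos = 0
    for slot in range(L + 1):
        for _ in range(insert_counts[slot]):
            inserted_slots.append(pos)
            pos += 1
        if slot < L:
            mapping[slot] = pos
            pos += 1
    v = np.zeros((L_new, q))
    w = np.zeros((L_new, L_new, q, q))
    v[mapping] = model.v
    w[np.ix_(mapping, mapping)] = model.w
    for s in inserted_slots:
        noise = rng.normal(scale=field_noise, size=q)
        v[s] = noise - noise.mean()
    out = PottsModel(v=v, w=w, alphabet=model.alphabet,
                     provenance=dict(model.provenance))
    return out, mapping


def plant_homologous_pair(base: PottsModel, perturbation_scale: float = 0.0,
                          n_insertions_A: int = 0, n_insertions_B: int = 0,
                          seed: int = 0, min_slot_separation: int = 4,
                          min_end_distance: int = 3) -> PlantedPair:
    """Derive a homologous model pair from ``base`` with known truth.

    A and B are copies of the base with i.i.d. normal parameter noise of
    scale ``perturbation_scale`` (re-centered to stay near the zero-sum
    gauge), then insertions of background-like columns.  Insertion slots
    are drawn without replacement from disjoint sets for A and B, pairwise
    at least ``min_slot_separation`` base columns apart and at least
    ``min_end_distance`` columns from either terminus.  These spacing rules
    make the recorded ``truth`` structurally identifiable: an indel flanked
    by too few conserved columns (or facing an indel of the other model
    across a short stretch) admits alternative alignments that trade the
    affine gap cost against a handful of field matches, and no aligner
    could be expected to prefer the planted correspondence there.
    """
    rng = np.random.default_rng(seed)
    n_total = n_insertions_A + n_insertions_B
    slot_range = np.arange(min_end_distance, base.L - min_end_distance + 1)

    def greedy(order):
        chosen: list[int] = []
        for s in order:
            if len(chosen) == n_total:
                break
            if all(abs(int(s) - c) >= min_slot_separation for c in chosen):
                chosen.append(int(s))
        return chosen

    if n_total and len(greedy(slot_range)) < n_total:
        raise ValueError(
            f"cannot place {n_total} insertions with separation "
            f"{min_slot_separation} in a length-{base.L} base model")
    chosen = []
    for _ in range(200):
        chosen = greedy(rng.permutation(slot_range))
        if len(chosen) == n_total:
            break
    else:
        chosen = greedy(slot_range)
        rng.shuffle(chosen)
    slot_sets = (np.array(chosen[:n_insertions_A], dtype=int),
                 np.array(chosen[n_insertions_A:], dtype=int))
    models = []
    maps = []
    for n_ins, slot_set in zip((n_insertions_A, n_insertions_B), slot_sets):
        v = base.v + rng.normal(scale=perturbation_scale, size=base.v.shape)
        v -= v.mean(axis=1, keepdims=True)
        w = base.w.copy()
        if perturbation_scale > 0:
            iu, ju = np.triu_indices(base.L, k=1)
            for i, j in zip(iu, ju):
                if np.any(base.w[i, j]):
                    block = base.w[i, j] + rng.normal(
                        scale=perturbation_scale, size=(base.q, base.q))
                    block = (block - block.mean(axis=0, keepdims=True)
                             - block.mean(axis=1, keepdims=True) + block.mean())
                    w[i, j] = block
                    w[j, i] = block.T
        m = PottsModel(v=v, w=symmetrize_couplings(w), alphabet=base.alphabet)
        m, mapping = _insert_background_columns(m, slot_set, rng)
        models.append(m)
        maps.append(mapping)
    truth = [(int(maps[0][c]), int(maps[1][c])) for c in range(base.L)]
    return PlantedPair(
        model_A=models[0], model_B=models[1], truth=truth,
        recipe={"perturbation_scale": perturbation_scale,
                "n_insertions_A": n_insertions_A,
                "n_insertions_B": n_insertions_B, "seed": int(seed)})


def ambiguous_coupling_pair(block_len: int = 3, q: int = 20,
                            field_scale: float = 1.0,
                            coupling_strength: float = 3.0,
                            seed: int = 0) -> PlantedPair:
    """A pair solvable only through couplings.

    Model A carries an anchor column followed by two field-identical copies
    of a ``block_len`` block; model B carries the anchor and a single copy.
    A strong diagonal coupling ties the anchor to the *second* copy in A and
    to the copy in B, so the true correspondence maps B's block onto A's
    second copy.  On fields alone the two copies are indistinguishable and
    the first copy wins (it needs no internal gap), so independent-site
    alignment is driven to the wrong copy while the coupling term pays for
    the gap and recovers the truth.
    """
    rng = np.random.default_rng(seed)
    alphabet = _alphabet_for(q)
    block = rng.normal(scale=field_scale, size=(block_len, q))
    block -= block.mean(axis=1, keepdims=True)
    anchor = rng.normal(scale=field_scale, size=q)
    anchor -= anchor.mean()

    L_A = 1 + 2 * block_len
    L_B = 1 + block_len
    vA = np.vstack([anchor, block, block])
    vB = np.vstack([anchor, block])
    coupling = _double_center(coupling_strength * np.eye(q))
    wA = np.zeros((L_A, L_A, q, q))
    wB = np.zeros((L_B, L_B, q, q))
    second_copy_start = 1 + block_len
    wA[0, second_copy_start] = coupling
    wA[second_copy_start, 0] = coupling.T
    wB[0, 1] = coupling
    wB[1, 0] = coupling.T
    A = PottsModel(v=vA, w=wA, alphabet=alphabet)
    B = PottsModel(v=vB, w=wB, alphabet=alphabet)
    truth = [(0, 0)] + [(second_copy_start + t, 1 + t) for t in range(block_len)]
    return PlantedPair(model_A=A, model_B=B, truth=truth,
                       recipe={"construction": "ambiguous_coupling_pair",
                               "block_len": block_len, "q": q,
                               "coupling_strength": coupling_strength,
                               "seed": int(seed)})
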