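"""Potts model container, gauge transforms and serialization.

A Potts model assigns a probability ∝ exp(Σ_i v_i(x_i) + Σ_{i<j} w_ij(x_i,x_j))
to every length-L sequence over a q-letter alphabet.  The parameters are only
identified up to a gauge freedom; this module fixes the zero-sum gauge
(Σ_a v_i(a) = 0, Σ_a w_ij(a,b) = Σ_b w_ij(a,b) = 0) by double-centering each
coupling block and compensating the fields so the distribution is unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, encode_sequences

GAUGE_TOL = 1e-8


@dataclass
class PottsModel:
    """Fields v (L×q) and couplings w (L×L×q×q) with w[i,j] = w[j,i].T, w[i,i]=0."""

    v: np.ndarray
    w: np.ndarray
    alphabet: str = AMINO_ACIDS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        L, q = self.v.shape
        if self.w.shape != (L, L, q, q):
            raise ValueError(f"w shape {self.w.shape} incompatible with v {self.v.shape}")
        if len(self.alphabet) != q:
            raise ValueError("alphabet size does not match q")

    @property
    def L(self) -> int:
        return self.v.shape[0]

    @property
    def q(self) -> int:
        return self.v.shape[1]

    def check_symmetry(self, tol: float = 0.0) -> bool:
        return bool(np.allclose(self.w, np.transpose(self.w, (1, 0, 3, 2)), atol=tol)
                    and np.allclose(np.einsum("iiab->iab", self.w), 0.0, atol=tol))

    def is_zero_sum_gauge(self, tol: float = GAUGE_TOL) -> bool:
        return bool(np.abs(self.v.sum(axis=1)).max() <= tol
                    and np.abs(self.w.sum(axis=2)).max() <= tol
                    and np.abs(self.w.sum(axis=3)).max() <= tol)

    def copy(self) -> "PottsModel":
        return PottsModel(v=self.v.copy(), w=self.w.copy(),
                          alphabet=self.alphabet, provenance=dict(self.provenance))


def symmetrize_couplings(w: np.ndarray) -> np.ndarray:
    """Enforce w[i,j] = w[j,i].T exactly and zero the diagonal blocks."""
    w = 0.5 * (w + np.transpose(w, (1, 0, 3, 2)))
    idx = np.arange(w.shape[0])
    w[idx, idx] = 0.0
    return w


def gauge_transform(model: PottsModel, K: np.ndarray, C: np.ndarray) -> PottsModel:
    """Apply the gauge freedom of the Potts parametrization.

    For every pair i<j the coupling block changes as
    ``w_ij(a,b) += K[i,j,a] + K[j,i,b]`` and each field compensates as
    ``v_i(a) += C[i] − Σ_{j≠i} K[i,j,a]``, which leaves every conditional
    P(x_i | x_−i) — and hence the model distribution — unchanged for fully
    observed sequences.  (With gapped neighbours the dropped conditioning
    terms break the cancellation, so invariance is not claimed there.)
    """
    L, q = model.L, model.q
    K = np.asarray(K, dtype=float)
    if K.shape != (L, L, q):
        raise ValueError("K must have shape (L, L, q)")
    C = np.asarray(C, dtype=float).reshape(L)
    w = model.w.copy()
    # w[i,j,a,b] += K[i,j,a] + K[j,i,b] for i != j (consistent with symmetry)
    w += K[:, :, :, None] + np.transpose(K, (1, 0, 2))[:, :, None, :]
    idx = np.arange(L)
    w[idx, idx] = model.w[idx, idx]
    v = model.v + C[:, None]
    mask = ~np.eye(L, dtype=bool)
    v = v - (K * mask[:, :, None]).sum(axis=1)
    return PottsModel(v=v, w=w, alphabet=model.alphabet,
                      provenance=dict(model.provenance))


def apply_zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Return the zero-sum-gauge representative of ``model``.

    Each coupling block is double-centered (row means, column means and the
    grand mean removed); the removed row/column means are pushed into the
    fields, and each field vector is then mean-centered.  Conditional
    distributions are invariant under the whole operation.
    """
    w = symmetrize_couplings(model.w.copy())
    row = w.mean(axis=3)                      # (L, L, q): mean over b
    grand = w.mean(axis=(2, 3))               # (L, L)
    K = -row + 0.5 * grand[:, :, None]
    shifted = gauge_transform(PottsModel(v=model.v, w=w, alphabet=model.alphabet,
                                         provenance=dict(model.provenance)),
                              K, np.zeros(model.L))
    v = shifted.v - shifted.v.mean(axis=1, keepdims=True)
    w = symmetrize_couplings(shifted.w)
    return PottsModel(v=v, w=w, alphabet=model.alphabet,
                      provenance=dict(model.provenance))


def conditional_distributions(model: PottsModel, sequences: np.ndarray) -> np.ndarray:
    """P(x_i = a | x_−i) for each sequence and position, shape (N, L, q).

    ``sequences`` is integer-encoded (gaps −1); gapped positions neither
    receive a conditional nor act as conditioning neighbours.
    """
    X = np.asarray(sequences)
    if X.ndim == 1:
        X = X[None, :]
    N, L = X.shape
    q = model.q
    onehot = np.zeros((N, L, q))
    valid = X >= 0
    onehot[np.nonzero(valid)[0], np.nonzero(valid)[1], X[valid]] = 1.0
    logits = model.v[None, :, :] + np.einsum("ijab,njb->nia", model.w, onehot)
    logits -= logits.max(axis=2, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=2, keepdims=True)


def sequence_energy(model: PottsModel, sequence: str) -> float:
    """Potts energy −(Σ_i v_i(x_i) + Σ_{i<j} w_ij(x_i, x_j)) of an ungapped sequence."""
    if len(sequence) != model.L:
        raise ValueError(f"sequence length {len(sequence)} != model length {model.L}")
    x = encode_sequences([sequence], model.alphabet)[0]
    if (x < 0).any():
        bad = sorted({c for c in sequence if c not in model.alphabet})
        raise ValueError(f"sequence contains symbols outside the model alphabet: {bad}")
    field_term = model.v[np.arange(model.L), x].sum()
    iu, ju = np.triu_indices(model.L, k=1)
    pair_term = model.w[iu, ju, x[iu], x[ju]].sum()
    return float(-(field_term + pair_term))


def save_model(model: PottsModel, path) -> None:
    """Serialize to a single JSON document (bit-exact float round-trip)."""
    iu, ju = np.triu_indices(model.L, k=1)
    doc = {
        "format": "pottsalign-model-v1",
        "L": model.L, "q": model.q, "alphabet": model.alphabet,
        "provenance": model.provenance,
        "v": model.v.tolist(),
        "w_upper": model.w[iu, ju].tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> PottsModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "pottsalign-model-v1":
        raise ValueError(f"{path} is not a pottsalign model file")
    L, q = doc["L"], doc["q"]
    v = np.array(doc["v"], dtype=float)
    w = np.zeros((L, L, q, q))
    iu, ju = np.triu_indices(L, k=1)
    blocks = np.array(doc["w_upper"], dtype=float).reshape(len(iu), q, q)
    w[iu, ju] = blocks
    w[ju, iu] = np.transpose(blocks, (0, 2, 1))
    return PottsModel(v=v, w=w, alphabet=doc["alphabet"],
                      provenance=doc.get("provenance", {}))
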