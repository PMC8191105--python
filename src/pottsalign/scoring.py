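"""Similarity scores between two Potts models.

The alignment objective combines a positional term — the scalar product of
background-corrected field vectors, ⟨v_i^A − v0, v_k^B − v0⟩, a log-odds
analogue — and a coupling term, the Frobenius inner product
⟨w_ij^A, w_kl^B⟩, weighted by α_w.  A fixed offset γ is subtracted from
every positional score at table-build time; this is mathematically the
per-aligned-pair penalty that stops the aligner from greedily matching
everything, folded into s_v so the ILP objective keeps its plain form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import PottsModel


@dataclass
class AlignConfig:
    """Alignment hyperparameters.

    Defaults are the trained values: gap open 13, gap extend 0, coupling
    weight α_w = 6, offset γ = 1.0, precision ε = 0.02.  ``w_norm_threshold``
    optionally drops coupling score terms whose block norms are both below
    the cutoff (a tractability knob; 0 keeps every pair, as the reference
    formulation does).  ``free_end_gaps`` leaves terminal gaps unpenalized.
    """

    alpha_w: float = 6.0
    gap_open: float = 13.0
    gap_extend: float = 0.0
    offset_gamma: float = 1.0
    epsilon: float = 0.02
    w_norm_threshold: float = 0.0
    time_limit_seconds: int = 21600
    free_end_gaps: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_w", "gap_open", "gap_extend", "offset_gamma",
                     "w_norm_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if not (0.0 < self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in (0, 1]")


@dataclass
class ScoreTables:
    """Precomputed similarity tables for one model pair.

    ``sv[i, k]`` already includes the −γ offset.  ``sw`` maps
    (i, j, k, l) with i<j, k<l to the raw Frobenius inner product (the α_w
    weight is applied by the objective, not stored).  ``self_score_A/B`` are
    the identity-alignment scores s(A,A), s(B,B) used as the ε-criterion
    normalizer.
    """

    sv: np.ndarray
    sw: dict[tuple[int, int, int, int], float]
    self_score_A: float
    self_score_B: float
    offset_gamma: float = 0.0
    alpha_w: float = 6.0
    meta: dict = field(default_factory=dict)

    @property
    def L_A(self) -> int:
        return self.sv.shape[0]

    @property
    def L_B(self) -> int:
        return self.sv.shape[1]


def field_similarity(vA_i: np.ndarray, vB_k: np.ndarray, v0: np.ndarray) -> float:
    """⟨vA_i − v0, vB_k − v0⟩."""
    vA_i, vB_k, v0 = (np.asarray(x, dtype=float) for x in (vA_i, vB_k, v0))
    if not (vA_i.shape == vB_k.shape == v0.shape):
        raise ValueError("field vectors and v0 must share one length q")
    return float((vA_i - v0) @ (vB_k - v0))


def coupling_similarity(wA_ij: np.ndarray, wB_kl: np.ndarray) -> float:
    """Frobenius inner product Σ_ab wA_ij(a,b)·wB_kl(a,b)."""
    wA_ij = np.asarray(wA_ij, dtype=float)
    wB_kl = np.asarray(wB_kl, dtype=float)
    if wA_ij.shape != wB_kl.shape:
        raise ValueError("coupling blocks must share the same shape")
    return float((wA_ij * wB_kl).sum())


def _self_score(model: PottsModel, v0: np.ndarray, config: AlignConfig,
                norms: np.ndarray) -> float:
    """Identity-alignment score s(M, M) with the same γ, α_w and threshold."""
    dv = model.v - v0[None, :]
    sv_diag = (dv * dv).sum(axis=1) - config.offset_gamma
    iu, ju = np.triu_indices(model.L, k=1)
    keep = norms[iu, ju] > config.w_norm_threshold if config.w_norm_threshold > 0 \
        else np.ones(len(iu), dtype=bool)
    sw_diag = (norms[iu, ju][keep] ** 2).sum()
    return float(sv_diag.sum() + config.alpha_w * sw_diag)


def build_score_tables(A: PottsModel, B: PottsModel, v0: np.ndarray,
                       config: AlignConfig | None = None) -> ScoreTables:
    """All s_v(i, k) and retained s_w(i, j, k, l) for a model pair.

    Coupling entries are stored for i<j, k<l and only where both block
    Frobenius norms exceed ``w_norm_threshold`` (default 0 keeps every pair
    with a nonzero product).
    """
    config = config or AlignConfig()
    if A.q != B.q or A.alphabet != B.alphabet:
        raise ValueError("models must share alphabet (and its order)")
    v0 = np.asarray(v0, dtype=float)
    dA = A.v - v0[None, :]
    dB = B.v - v0[None, :]
    sv = dA @ dB.T - config.offset_gamma

    normsA = np.linalg.norm(A.w, axis=(2, 3))
    normsB = np.linalg.norm(B.w, axis=(2, 3))
    thr = config.w_norm_threshold
    iuA, juA = np.triu_indices(A.L, k=1)
    iuB, juB = np.triu_indices(B.L, k=1)
    pairsA = [(i, j) for i, j in zip(iuA, juA)
              if normsA[i, j] > thr or (thr == 0 and normsA[i, j] > 0)]
    pairsB = [(k, l) for k, l in zip(iuB, juB)
              if normsB[k, l] > thr or (thr == 0 and normsB[k, l] > 0)]
    sw: dict[tuple[int, int, int, int], float] = {}
    for i, j in pairsA:
        blockA = A.w[i, j]
        for k, l in pairsB:
            s = float((blockA * B.w[k, l]).sum())
            if s != 0.0:
                sw[(int(i), int(j), int(k), int(l))] = s

    return ScoreTables(
        sv=sv, sw=sw,
        self_score_A=_self_score(A, v0, config, normsA),
        self_score_B=_self_score(B, v0, config, normsB),
        offset_gamma=config.offset_gamma, alpha_w=config.alpha_w,
        meta={"w_norm_threshold": thr})


def write_score_tables_tsv(tables: ScoreTables, sv_path, sw_path) -> None:
    """Diagnostic dump: (i, k, sv) and (i, j, k, l, sw), 1-based."""
    with open(sv_path, "w") as fh:
        fh.write("i\tk\tsv\n")
        for i in range(tables.L_A):
            for k in range(tables.L_B):
                fh.write(f"{i + 1}\t{k + 1}\t{tables.sv[i, k]:.10g}\n")
    with open(sw_path, "w") as fh:
        fh.write("i\tj\tk\tl\tsw\n")
        for (i, j, k, l), s in sorted(tables.sw.items()):
            fh.write(f"{i + 1}\t{j + 1}\t{k + 1}\t{l + 1}\t{s:.10g}\n")
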