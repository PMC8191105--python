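"""Parameter rescaling for model comparability.

Inference methods tuned for contact prediction produce parameters whose
small-sample noise is hostile to inner-product similarity scores: fields are
log-frequencies, so rare symbols get large negative values whose sign flips
dominate a scalar product, and coupling matrices are full of spurious
anti-correlations that sufficient data would have erased.

Two transforms compensate:

* fields — the per-site softmax distribution is additively smoothed towards
  the uniform distribution with weight τ_v and mapped back to zero-sum
  fields (log minus mean-log);
* couplings — each q×q block is pushed through a softmax with base β_w > 1
  (skewing mass towards the largest, typically positive, entries), smoothed
  towards uniform with weight τ_w, and mapped back through log / β_w with
  the grand mean over all q² entries removed.

Both maps are identities at τ = 0, β_w = 1 (up to grand-centering) and send
everything to zero at τ = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax, softmax

from .model import PottsModel


@dataclass
class RescaleConfig:
    """Smoothing weights τ_v, τ_w ∈ [0, 1] and coupling softmax base β_w > 0."""

    tau_v: float = 0.4
    tau_w: float = 0.4
    beta_w: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_v <= 1.0 and 0.0 <= self.tau_w <= 1.0):
            raise ValueError("tau_v and tau_w must lie in [0, 1]")
        if self.beta_w <= 0:
            raise ValueError("beta_w must be > 0")


def smooth_fields(v: np.ndarray, tau_v: float) -> np.ndarray:
    """Additively smooth each field vector's softmax distribution.

    Returns ṽ with softmax(ṽ_i) = (1−τ_v)·softmax(v_i) + τ_v/q and each row
    zero-sum.  τ_v = 0 is the identity on zero-sum rows; τ_v = 1 maps every
    row to zeros (uniform distribution).
    """
    if not (0.0 <= tau_v <= 1.0):
        raise ValueError("tau_v must lie in [0, 1]")
    v = np.atleast_2d(np.asarray(v, dtype=float))
    q = v.shape[1]
    if tau_v == 0.0:
        return v - v.mean(axis=1, keepdims=True)
    p = softmax(v, axis=1)
    p_smooth = (1.0 - tau_v) * p + tau_v / q
    logp = np.log(p_smooth)
    return logp - logp.mean(axis=1, keepdims=True)


def smooth_couplings(w_ij: np.ndarray, tau_w: float, beta_w: float) -> np.ndarray:
    """Temperature-skewed smoothing of one q×q coupling block.

    The block is read as a distribution over its q² entries through a
    softmax with base β_w, mixed with the uniform distribution with weight
    τ_w, and mapped back via log/β_w minus the grand log-mean.  The output
    therefore sums to zero over all q² entries (a single grand centering,
    deliberately weaker than the per-row/column zero-sum gauge) and
    preserves the entrywise order of the input.
    """
    if not (0.0 <= tau_w <= 1.0):
        raise ValueError("tau_w must lie in [0, 1]")
    if beta_w <= 0:
        raise ValueError("beta_w must be > 0")
    w_ij = np.asarray(w_ij, dtype=float)
    q2 = w_ij.size
    logp = log_softmax(beta_w * w_ij.ravel())
    if tau_w == 0.0:
        logmix = logp
    elif tau_w == 1.0:
        return np.zeros_like(w_ij)
    else:
        # log((1-τ)·p + τ/q²) via logaddexp for stability at tiny p
        logmix = np.logaddexp(np.log1p(-tau_w) + logp,
                              np.log(tau_w) - np.log(q2))
    out = (logmix - logmix.mean()) / beta_w
    return out.reshape(w_ij.shape)


def rescale_model(model: PottsModel, config: RescaleConfig | None = None
                  ) -> PottsModel:
    """Apply field and coupling smoothing to a whole model.

    Each unordered coupling pair is smoothed once and mirrored, so the
    symmetry w[i,j] = w[j,i].T is preserved exactly.
    """
    config = config or RescaleConfig()
    v = smooth_fields(model.v, config.tau_v)
    w = np.zeros_like(model.w)
    iu, ju = np.triu_indices(model.L, k=1)
    for i, j in zip(iu, ju):
        block = smooth_couplings(model.w[i, j], config.tau_w, config.beta_w)
        w[i, j] = block
        w[j, i] = block.T
    return PottsModel(v=v, w=w, alphabet=model.alphabet,
                      provenance={**model.provenance,
                                  "rescaled": {"tau_v": config.tau_v,
                                               "tau_w": config.tau_w,
                                               "beta_w": config.beta_w}})
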