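"""Potts model inference by regularized pseudo-likelihood maximization.

The full likelihood of a Potts model is intractable (it requires the
partition function Z over q^L sequences), so the fit maximizes the
pseudo-likelihood — the product over positions of the conditional
probability of each observed symbol given the rest of its sequence — which
is a consistent estimator in the large-sample limit and only needs per-site
softmax normalizations.

The regularizer is R(v, w) = λ_v‖v − v*‖² + λ_w‖w‖², where v* is the field
vector whose per-site softmax reproduces the empirical single-site
frequencies exactly.  Centering the field prior on v* (rather than on 0)
means an MSA with no residue covariation is explained entirely by the
fields, and couplings are added only where the data demand them — which is
what makes independently inferred models comparable.

Gap handling: with the q=20 alphabet a gapped position contributes no
conditional term and never appears as a conditioning neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import PottsModel, apply_zero_sum_gauge
from .msa import MSA, FrequencyTables, TrimRecord, compute_frequencies


@dataclass
class InferenceConfig:
    """Settings for the pseudo-likelihood fit.

    lambda_v, lambda_w
        Weights of the field prior ‖v−v*‖² and the coupling ridge ‖w‖².
        ``lambda_w=None`` uses 0.2·(L−1), scaling the coupling penalty with
        the number of neighbours each position has (common DCA practice).
    pseudocount_epsilon
        Added to single-site frequencies before inverting the softmax for
        v*, so zero counts do not produce −inf fields.
    """

    lambda_v: float = 10.0
    lambda_w: float | None = None
    max_iterations: int = 500
    gradient_tolerance: float = 1e-6
    pseudocount_epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_v < 0 or (self.lambda_w is not None and self.lambda_w < 0):
            raise ValueError("regularization weights must be ≥ 0")

    def effective_lambda_w(self, L: int) -> float:
        return 0.2 * max(L - 1, 1) if self.lambda_w is None else self.lambda_w


def field_prior_vstar(freqs: FrequencyTables,
                      pseudocount_epsilon: float = 1e-6) -> np.ndarray:
    """Zero-sum fields v* with softmax(v*_i) equal to the regularized f_i.

    Each frequency row is shifted by ``pseudocount_epsilon`` and renormalized
    (over amino-acid states only; gap mass is discarded), then the softmax
    is inverted as log f − mean log f.
    """
    f = np.asarray(freqs.f_single, dtype=float) + pseudocount_epsilon
    if (f <= 0).any():
        raise ValueError("zero frequency encountered with pseudocount_epsilon = 0")
    f = f / f.sum(axis=1, keepdims=True)
    logf = np.log(f)
    return logf - logf.mean(axis=1, keepdims=True)


def background_field_v0(f_background: np.ndarray) -> np.ndarray:
    """Background fields v0(a) = log f0(a) − mean_b log f0(b) (zero-sum)."""
    f0 = np.asarray(f_background, dtype=float)
    if (f0 <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    if not np.isclose(f0.sum(), 1.0):
        raise ValueError("background frequencies must sum to 1")
    logf = np.log(f0)
    return logf - logf.mean()


def _neg_log_pseudolikelihood(theta, X_onehot, x_idx, valid, vstar,
                              lam_v, lam_w, L, q, iu, ju):
    """Objective and gradient for the stacked parameter vector (v, w_upper)."""
    n_pairs = len(iu)
    v = theta[:L * q].reshape(L, q)
    w_ut = theta[L * q:].reshape(n_pairs, q, q)
    W = np.zeros((L, L, q, q))
    W[iu, ju] = w_ut
    W[ju, iu] = np.transpose(w_ut, (0, 2, 1))

    logits = v[None, :, :] + np.einsum("ijab,njb->nia", W, X_onehot)
    lse = logsumexp(logits, axis=2)
    obs = np.where(valid, np.take_along_axis(
        logits, np.maximum(x_idx, 0)[:, :, None], axis=2)[:, :, 0], 0.0)
    nll = float(((lse - obs) * valid).sum())

    P = np.exp(logits - lse[:, :, None])
    G = (P - X_onehot) * valid[:, :, None]          # (N, L, q)
    grad_v = G.sum(axis=0) + 2.0 * lam_v * (v - vstar)
    D = np.einsum("nia,njb->ijab", G, X_onehot)
    grad_w = D[iu, ju] + np.transpose(D[ju, iu], (0, 2, 1)) + 2.0 * lam_w * w_ut

    nll += lam_v * float(((v - vstar) ** 2).sum()) + lam_w * float((w_ut ** 2).sum())
    return nll, np.concatenate([grad_v.ravel(), grad_w.ravel()])


def fit_pseudolikelihood(msa: MSA, config: InferenceConfig | None = None
                         ) -> PottsModel:
    """Fit a Potts model to an MSA.

    Deterministic: the optimizer (L-BFGS) starts from v = v*, w = 0.  The
    result is returned in the zero-sum gauge; convergence status and the
    regularization actually used are recorded in ``provenance``.
    """
    config = config or InferenceConfig()
    X = msa.to_array()
    N, L = X.shape
    q = len(msa.alphabet)
    valid = X >= 0
    X_onehot = np.zeros((N, L, q))
    X_onehot[np.nonzero(valid)[0], np.nonzero(valid)[1], X[valid]] = 1.0

    freqs = compute_frequencies(msa, include_pairs=False)
    vstar = field_prior_vstar(freqs, config.pseudocount_epsilon)
    lam_w = config.effective_lambda_w(L)

    iu, ju = np.triu_indices(L, k=1)
    theta0 = np.concatenate([vstar.ravel(), np.zeros(len(iu) * q * q)])
    res = minimize(
        _neg_log_pseudolikelihood, theta0, jac=True, method="L-BFGS-B",
        args=(X_onehot, X, valid, vstar, config.lambda_v, lam_w, L, q, iu, ju),
        options={"maxiter": config.max_iterations,
                 "gtol": config.gradient_tolerance, "ftol": 1e-12})

    v = res.x[:L * q].reshape(L, q)
    w = np.zeros((L, L, q, q))
    blocks = res.x[L * q:].reshape(len(iu), q, q)
    w[iu, ju] = blocks
    w[ju, iu] = np.transpose(blocks, (0, 2, 1))
    model = PottsModel(v=v, w=w, alphabet=msa.alphabet, provenance={
        "method": "pseudo-likelihood",
        "lambda_v": config.lambda_v, "lambda_w": lam_w,
        "pseudocount_epsilon": config.pseudocount_epsilon,
        "n_sequences": N, "converged": bool(res.success),
        "n_iterations": int(res.nit), "optimizer_message": str(res.message),
    })
    return apply_zero_sum_gauge(model)


def reinsert_trimmed_columns(model: PottsModel, trim: TrimRecord,
                             v0: np.ndarray) -> PottsModel:
    """Re-insert trimmed (gappy) columns with background fields and zero couplings.

    Positions listed in ``trim.kept_columns`` carry the inferred parameters;
    every other original position gets v_i = v0 and w_ij = 0 for all j, so a
    trimmed column is maximally uninformative rather than absent.
    """
    if model.L != len(trim.kept_columns):
        raise ValueError(f"model length {model.L} != {len(trim.kept_columns)} kept columns")
    v0 = np.asarray(v0, dtype=float)
    if v0.shape != (model.q,):
        raise ValueError("v0 has the wrong length")
    L_full = trim.original_length
    v = np.tile(v0, (L_full, 1))
    w = np.zeros((L_full, L_full, model.q, model.q))
    kept = np.asarray(trim.kept_columns)
    v[kept] = model.v
    w[np.ix_(kept, kept)] = model.w
    return PottsModel(v=v, w=w, alphabet=model.alphabet,
                      provenance={**model.provenance,
                                  "reinserted_columns": sorted(set(range(L_full)) - set(kept.tolist()))})
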