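"""Pseudo-likelihood inference: priors, fitting, column re-insertion."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from pottsalign import (MSA, InferenceConfig, TrimRecord, background_field_v0,
                        compute_frequencies, field_prior_vstar,
                        fit_pseudolikelihood, random_potts_model,
                        reinsert_trimmed_columns, sample_sequences)
from pottsalign.msa import FrequencyTables


def tables_from(f_single):
    f = np.atleast_2d(np.asarray(f_single, dtype=float))
    return FrequencyTables(f_single=f, f_pair=None,
                           f_background=np.full(f.shape[1], 1.0 / f.shape[1]))


class TestFieldPriorVstar:
    def test_uniform_frequencies_give_zero_fields(self):
        v = field_prior_vstar(tables_from([[0.25] * 4]))
        assert np.allclose(v, 0.0, atol=1e-5)

    def test_two_state_closed_form(self):
        # softmax inverse of (0.8, 0.2) under zero-sum: ±½·log 4
        v = field_prior_vstar(tables_from([[0.8, 0.2]]), pseudocount_epsilon=0)
        assert v[0] == pytest.approx([0.5 * np.log(4), -0.5 * np.log(4)])

    def test_round_trip_softmax(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(6), size=4)
        eps = 1e-6
        v = field_prior_vstar(tables_from(f), pseudocount_epsilon=eps)
        f_reg = (f + eps) / (f + eps).sum(axis=1, keepdims=True)
        assert np.allclose(softmax(v, axis=1), f_reg, atol=1e-12)
        assert np.allclose(v.sum(axis=1), 0.0, atol=1e-10)

    def test_zero_frequency_without_pseudocount_is_an_error(self):
        with pytest.raises(ValueError):
            field_prior_vstar(tables_from([[1.0, 0.0]]), pseudocount_epsilon=0)


class TestBackgroundField:
    def test_uniform_background_is_zero(self):
        assert np.allclose(background_field_v0(np.full(5, 0.2)), 0.0)

    def test_two_state_closed_form_and_zero_sum(self):
        v0 = background_field_v0(np.array([0.8, 0.2]))
        assert v0 == pytest.approx([0.5 * np.log(4), -0.5 * np.log(4)])
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.ones(20))
        assert background_field_v0(f).sum() == pytest.approx(0.0, abs=1e-12)

    def test_rejects_degenerate_input(self):
        with pytest.raises(ValueError):
            background_field_v0(np.array([1.0, 0.0]))
        with pytest.raises(ValueError):
            background_field_v0(np.array([0.5, 0.2]))


class TestFitPseudolikelihood:
    def test_single_column_matches_numeric_oracle(self):
        # L=1: objective is Σ_n (lse(v) − v[x_n]) + λ_v‖v − v*‖², solvable
        # directly by a generic optimizer over the q-vector.
        msa = MSA(sequences=list("AAAC"), ids=list("1234"), alphabet="AC")
        cfg = InferenceConfig(lambda_v=2.0, lambda_w=1.0)
        model = fit_pseudolikelihood(msa, cfg)
        counts = np.array([3.0, 1.0])
        vstar = field_prior_vstar(compute_frequencies(msa, include_pairs=False),
                                  cfg.pseudocount_epsilon)[0]

        def obj(v):
            return (4 * logsumexp(v) - counts @ v
                    + cfg.lambda_v * ((v - vstar) ** 2).sum())

        ref = minimize(obj, np.zeros(2), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12}).x
        ref = ref - ref.mean()   # compare in the zero-sum gauge
        assert model.v[0] == pytest.approx(ref, abs=1e-5)

    def test_covarying_columns_get_the_strongest_coupling(self):
        rng = np.random.default_rng(2)
        # columns 0-1 perfectly covary (AB or BA); column 2 independent
        rows = []
        for _ in range(400):
            pair = "AB" if rng.random() < 0.5 else "BA"
            rows.append(pair + rng.choice(list("AB")))
        msa = MSA(sequences=rows, ids=[str(i) for i in range(400)],
                  alphabet="AB")
        m = fit_pseudolikelihood(msa)
        norms = np.linalg.norm(m.w, axis=(2, 3))
        assert norms[0, 1] > norms[0, 2] and norms[0, 1] > norms[1, 2]

    def test_couplings_vanish_as_lambda_w_grows(self):
        base = random_potts_model(4, 3, field_scale=1.0, n_coupled_pairs=2,
                                  coupling_scale=1.0, seed=3)
        msa = sample_sequences(base, 300, seed=3)
        norms = []
        for lam in (0.5, 5.0, 50.0, 500.0):
            m = fit_pseudolikelihood(msa, InferenceConfig(lambda_w=lam))
            norms.append(np.linalg.norm(m.w))
        assert all(a > b for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.05 * norms[0]

    def test_result_is_gauge_fixed_with_provenance(self):
        msa = MSA(sequences=["AC", "AA", "CA", "CC"], ids=list("abcd"),
                  alphabet="AC")
        m = fit_pseudolikelihood(msa)
        assert m.is_zero_sum_gauge()
        assert m.provenance["method"] == "pseudo-likelihood"
        assert "converged" in m.provenance

    def test_gapped_msa_fits_without_error(self):
        msa = MSA(sequences=["AC-", "A-C", "-CC", "ACC"], ids=list("abcd"),
                  alphabet="AC")
        m = fit_pseudolikelihood(msa)
        assert np.isfinite(m.v).all() and np.isfinite(m.w).all()


class TestReinsertTrimmedColumns:
    def test_no_trimming_is_identity(self):
        m = random_potts_model(4, 3, seed=5)
        trim = TrimRecord(kept_columns=[0, 1, 2, 3], original_length=4)
        out = reinsert_trimmed_columns(m, trim, np.zeros(3))
        assert np.allclose(out.v, m.v) and np.allclose(out.w, m.w)

    def test_background_column_placed_at_original_index(self):
        m = random_potts_model(4, 3, n_coupled_pairs=2, seed=6)
        v0 = background_field_v0(np.array([0.5, 0.3, 0.2]))
        trim = TrimRecord(kept_columns=[0, 1, 3, 4], original_length=5)
        out = reinsert_trimmed_columns(m, trim, v0)
        assert out.L == 5
        assert np.allclose(out.v[2], v0)
        assert np.allclose(out.w[2], 0.0) and np.allclose(out.w[:, 2], 0.0)
        assert np.allclose(out.v[[0, 1, 3, 4]], m.v)
        assert np.allclose(out.w[np.ix_([0, 1, 3, 4], [0, 1, 3, 4])], m.w)

    def test_length_mismatch_rejected(self):
        m = random_potts_model(4, 3, seed=7)
        with pytest.raises(ValueError):
            reinsert_trimmed_columns(m, TrimRecord([0, 1], 5), np.zeros(3))
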