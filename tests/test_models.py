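"""Representation models: VAE training, PCA baseline, selection, decoding."""

import numpy as np
import pytest

from mregle import models, synthgen, waveforms
from mregle.models import (
    VAEConfig, _DenseVAE, decode, encode, encode_concat, fit_pca, max_offdiag_corr,
    overall_mse, pca_embed, perturb_and_interpolate, reconstruction_compare, select_model,
    train_vae,
)
from conftest import make_fused


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        cfg = VAEConfig(latent_dim=2, hidden=(5,), activation="tanh", beta=0.5,
                        stochastic=False, epochs=1, seed=0)
        net = _DenseVAE(7, cfg, rng)
        x = rng.standard_normal((4, 7))
        _, grads = net.grads(x, rng)
        params = net.params()
        eps = 1e-6
        for p, g in zip(params, grads):
            idx = tuple(0 for _ in p.shape)
            p[idx] += eps
            net.set_params(params)
            up, _ = net.grads(x, rng)
            p[idx] -= 2 * eps
            net.set_params(params)
            dn, _ = net.grads(x, rng)
            p[idx] += eps
            net.set_params(params)
            assert (up - dn) / (2 * eps) == pytest.approx(g[idx], abs=1e-7)

    def test_beta_zero_objective_equals_plain_autoencoder(self, rng):
        # with beta = 0 and sampling disabled the training objective is the
        # reconstruction term alone (the CAE baseline)
        cfg = VAEConfig(latent_dim=3, hidden=(8,), beta=0.0, stochastic=False, seed=1)
        net = _DenseVAE(10, cfg, rng)
        x = rng.standard_normal((6, 10))
        total, recon, kl = net.loss(x)
        assert total == recon and kl >= 0


class TestTrainVae:
    def test_linear_subspace_data_reconstructed(self, linear_waveform_data):
        ft, fv, X = linear_waveform_data
        cfg = VAEConfig(latent_dim=4, hidden=(32,), activation="identity",
                        beta=0.0, stochastic=False, epochs=150, seed=1)
        cand = train_vae(ft, fv, cfg)
        assert cand.val_recon_loss < 1e-3 * X.var()

    def test_same_seed_same_result(self, linear_waveform_data):
        ft, fv, _ = linear_waveform_data
        cfg = VAEConfig(latent_dim=3, hidden=(16,), epochs=10, seed=7)
        a = train_vae(ft, fv, cfg)
        b = train_vae(ft, fv, cfg)
        assert a.val_recon_loss == b.val_recon_loss
        assert all(np.array_equal(p, q) for p, q in zip(a.net.params(), b.net.params()))

    def test_latent_span_matches_pca_subspace(self, linear_waveform_data):
        # beta -> 0 on linear data: posterior-mean span vs PCA score span
        ft, fv, _ = linear_waveform_data
        cfg = VAEConfig(latent_dim=4, hidden=(32,), activation="identity",
                        beta=0.0, stochastic=False, epochs=150, seed=2)
        cand = train_vae(ft, fv, cfg)
        emb = encode(cand, fv)
        pca = fit_pca(fv, 4)
        scores = (fv.matrix - pca.mean_) @ pca.components_.T
        Qa, _ = np.linalg.qr(emb.values - emb.values.mean(axis=0))
        Qb, _ = np.linalg.qr(scores)
        angle = np.arccos(np.clip(np.linalg.svd(Qa.T @ Qb, compute_uv=False).min(), -1, 1))
        assert angle < 0.1

    def test_overlapping_train_val_rejected(self, linear_waveform_data):
        ft, _, _ = linear_waveform_data
        with pytest.raises(ValueError, match="disjoint"):
            train_vae(ft, ft, VAEConfig(latent_dim=2, epochs=1))

    def test_latent_dim_must_be_below_input_length(self, linear_waveform_data):
        ft, fv, _ = linear_waveform_data
        with pytest.raises(ValueError, match="latent_dim"):
            train_vae(ft, fv, VAEConfig(latent_dim=120, epochs=1))


class TestEncodeDecode:
    def test_encode_is_deterministic(self, linear_waveform_data):
        ft, fv, _ = linear_waveform_data
        cand = train_vae(ft, fv, VAEConfig(latent_dim=2, hidden=(16,), epochs=5, seed=3))
        a, b = encode(cand, fv), encode(cand, fv)
        assert np.array_equal(a.values, b.values)

    def test_pca_decode_is_rank_d_projection(self, rng):
        X = rng.standard_normal((50, 20))
        fused = make_fused(X)
        pca = fit_pca(fused, 5)
        recon = decode(pca, encode(pca, fused))
        Xc = X - X.mean(axis=0)
        proj = X.mean(axis=0) + Xc @ pca.components_.T @ pca.components_
        assert np.allclose(recon, proj, atol=1e-12)

    def test_u_style_concat_width(self, rng):
        # 12 per-lead encoders of width 8 concatenate to 96 dims
        blocks, cands = {}, {}
        for lead in waveforms.ECG_LEADS:
            X = rng.standard_normal((40, 30))
            blocks[lead] = make_fused(X, name=lead)
            cands[lead] = fit_pca(blocks[lead], 8)
        emb = encode_concat(cands, blocks, waveforms.ECG_LEADS)
        assert emb.d == 96


class TestPcaEmbed:
    def test_full_rank_reconstruction_exact(self, rng):
        X = rng.standard_normal((30, 10))
        fused = make_fused(X)
        pca = fit_pca(fused, 10)
        recon = decode(pca, encode(pca, fused))
        assert np.allclose(recon, X, atol=1e-10)

    def test_variance_explained_non_increasing(self, rng):
        X = rng.standard_normal((100, 15)) * np.linspace(3, 0.1, 15)
        _, ratio = pca_embed(make_fused(X), 10)
        assert np.all(np.diff(ratio) <= 1e-12)

    def test_rank8_lead_data_explained_by_8_pcs(self, rng):
        B = rng.standard_normal((600, 8))
        X = rng.standard_normal((500, 8)) @ B.T + 1e-3 * rng.standard_normal((500, 600))
        _, ratio = pca_embed(make_fused(X), 8)
        assert ratio.sum() >= 0.99

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca(make_fused(rng.standard_normal((5, 10))), 8)

    def test_sign_convention_stable(self, rng):
        X = rng.standard_normal((60, 12))
        pca = fit_pca(make_fused(X), 4)
        for comp in pca.components_:
            assert comp[np.abs(comp).argmax()] > 0


class _FakeCand:
    def __init__(self, corr, loss):
        self.max_abs_corr, self.val_recon_loss = corr, loss


class TestSelectModel:
    def test_threshold_excludes_correlated_candidate(self):
        good, bad = _FakeCand(0.05, 2.0), _FakeCand(0.2, 1.0)
        assert select_model([good, bad]) is good

    def test_fallback_when_none_pass(self):
        cands = [_FakeCand(0.3, 1.0), _FakeCand(0.4, 0.5)]
        with pytest.warns(UserWarning, match="falling back"):
            assert select_model(cands) is cands[0]

    def test_single_candidate_returned(self):
        only = _FakeCand(0.01, 9.9)
        assert select_model([only]) is only


class TestReconstructionCompare:
    def test_length_weighted_average(self):
        # ECG MSE 0.02 over 600 points + PPG MSE 0.09 over 100 points -> 0.03
        per = {"ECG_leadI": 0.02, "PPG": 0.09}
        lengths = {"ECG_leadI": 600, "PPG": 100}
        assert overall_mse(per, lengths, "concatenate") == pytest.approx(0.03)
        assert overall_mse(per, lengths, "channel_stack") == pytest.approx(0.055)

    def test_identical_reconstructions_ratio_one(self, rng):
        X = rng.standard_normal((40, 20))
        m_fused = make_fused(X)
        pca = fit_pca(m_fused, 20)  # lossless
        rep = reconstruction_compare(pca, {"blk": pca}, m_fused, {"blk": m_fused})
        assert rep["ratio"] == pytest.approx(1.0)
        assert rep["reduction_pct"] == pytest.approx(0.0)

    def test_multimodal_beats_unimodal_on_shared_factors(self):
        # scaled-down analog of the reconstruction-dominance result, PCA route
        model = synthgen.LatentFactorModel.reconstruction_benchmark()
        samples, _, _ = synthgen.simulate_multimodal_waveforms(1200, model=model, seed=21)
        waveforms.assign_splits(samples)
        order = ("ECG_leadI", "PPG")
        factors = waveforms.compute_scale_factors(samples, order)
        train = [s for s in samples if s.split == "train"]
        val = [s for s in samples if s.split == "val"]
        m_spec = waveforms.FusionSpec("concatenate", order, factors)
        u_specs = {m: waveforms.FusionSpec("concatenate", (m,), {m: factors[m]})
                   for m in order}
        ft, fv = waveforms.fuse(train, m_spec), waveforms.fuse(val, m_spec)
        uft = {m: waveforms.fuse(train, u_specs[m]) for m in order}
        ufv = {m: waveforms.fuse(val, u_specs[m]) for m in order}
        for d in (1, 2, 4, 8):
            rep = reconstruction_compare(
                fit_pca(ft, 2 * d), {m: fit_pca(uft[m], d) for m in order}, fv, ufv)
            assert rep["m_overall"] < rep["u_overall"]

    def test_unequal_total_dims_warns(self, rng):
        X = rng.standard_normal((40, 20))
        fused = make_fused(X)
        with pytest.warns(UserWarning, match="latent dims differ"):
            reconstruction_compare(fit_pca(fused, 3), {"blk": fit_pca(fused, 5)},
                                   fused, {"blk": fused})


class TestPerturbAndInterpolate:
    def test_endpoints_and_step_count(self, rng):
        pca = fit_pca(make_fused(rng.standard_normal((30, 10))), 4)
        e0, e1 = rng.standard_normal(4), rng.standard_normal(4)
        out = perturb_and_interpolate(pca, e0, dim=2, e_end=e1, steps=20)
        assert out.shape[0] == 20
        assert np.allclose(out[0], decode(pca, e0)[0], atol=1e-12)
        end = e0.copy()
        end[2] = e1[2]
        assert np.allclose(out[-1], decode(pca, end)[0], atol=1e-12)

    def test_zero_perturbation_matches_baseline(self, rng):
        pca = fit_pca(make_fused(rng.standard_normal((30, 10))), 4)
        out = perturb_and_interpolate(pca, np.zeros(4), dim=0, steps=21,
                                      range_sd=(-2.0, 2.0))
        # middle step of an odd grid over [-2, 2] is the unperturbed origin
        assert np.allclose(out[10], decode(pca, np.zeros(4))[0], atol=1e-12)

    def test_too_few_steps_rejected(self, rng):
        pca = fit_pca(make_fused(rng.standard_normal((30, 10))), 2)
        with pytest.raises(ValueError):
            perturb_and_interpolate(pca, np.zeros(2), dim=0, steps=1)


def test_checkpoint_roundtrip(linear_waveform_data, tmp_path):
    ft, fv, _ = linear_waveform_data
    cand = train_vae(ft, fv, VAEConfig(latent_dim=3, hidden=(16,), epochs=5, seed=4))
    path = str(tmp_path / "model.npz")
    models.save_candidate(cand, path)
    back = models.load_candidate(path)
    emb_a, emb_b = encode(cand, fv), encode(back, fv)
    assert np.array_equal(emb_a.values, emb_b.values)
    assert back.config == cand.config
    assert back.val_recon_loss == cand.val_recon_loss


def test_max_offdiag_corr_handles_constant_columns(rng):
    X = np.column_stack([rng.standard_normal(50), np.ones(50), rng.standard_normal(50)])
    assert 0.0 <= max_offdiag_corr(X) <= 1.0
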