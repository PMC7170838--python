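"""VAE architecture, closed-form KL, training determinism, traversal."""

import warnings

import numpy as np
import pytest
from scipy import integrate

import orawave as ow
from orawave import vae as V
from orawave.errors import ConfigError, DegenerateFitError


@pytest.fixture(scope="module")
def trained():
    """A model trained on single-replicate noisy traces."""
    cfg = ow.SimConfig(n_eyes=200, n_replicates=1, noise_sd=10.0, seed=21)
    bundle = ow.simulate_cohort(cfg)
    traces = np.vstack([r.trace for r in bundle.records])
    model = V.init_vae(V.VAEArch(), seed=1)
    V.train_vae(model, traces, epochs=400, batch_size=32, seed=2)
    return model, traces, bundle


class TestArchitecture:
    def test_parameter_count_matches_layer_arithmetic(self):
        model = V.init_vae(V.VAEArch(), seed=0)
        # hand count: 400->40->20->(2+2) encoder, 2->20->40->400 decoder
        expected = ((400 * 40 + 40) + (40 * 20 + 20)
                    + 2 * (20 * 2 + 2)
                    + (2 * 20 + 20) + (20 * 40 + 40) + (40 * 400 + 400))
        assert model.n_parameters == expected

    def test_same_seed_same_initial_weights(self):
        a = V.init_vae(V.VAEArch(), seed=9)
        b = V.init_vae(V.VAEArch(), seed=9)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_zero_latent_dim_rejected(self):
        with pytest.raises(ConfigError):
            V.VAEArch(latent_dim=0)

    def test_forward_maps_400_to_400(self):
        model = V.init_vae(V.VAEArch(), seed=0)
        out = V.forward(model, np.zeros(400))
        assert out.shape == (1, 400)


class TestKL:
    def test_zero_code_gives_zero(self):
        assert V.kl_standard_normal((np.zeros(2), np.zeros(2))) == 0.0

    def test_unit_mean_closed_form(self):
        assert V.kl_standard_normal((np.array([1.0, 0.0]), np.zeros(2))) \
            == pytest.approx(0.5)

    def test_matches_numerical_quadrature(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            mu = rng.normal(size=2)
            lv = rng.normal(scale=0.7, size=2)
            closed = V.kl_standard_normal((mu, lv))
            num = 0.0
            for m, l in zip(mu, lv):
                s = np.exp(0.5 * l)
                def integrand(x, m=m, s=s):
                    q = np.exp(-(x - m) ** 2 / (2 * s * s)) / (s * np.sqrt(2 * np.pi))
                    return q * ((-(x - m) ** 2 / (2 * s * s) - np.log(s))
                                + x ** 2 / 2)
                val, _ = integrate.quad(integrand, m - 12 * s - abs(m),
                                        m + 12 * s + abs(m), limit=200)
                num += val
            assert closed == pytest.approx(num, abs=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            V.kl_standard_normal((np.array([np.nan, 0.0]), np.zeros(2)))


class TestLoss:
    def test_total_is_recon_plus_beta_kl(self):
        model = V.init_vae(V.VAEArch(), seed=0)
        x = np.random.default_rng(0).normal(scale=0.3, size=(4, 400))
        r1, k1, t1 = V.elbo_loss(x, model, beta=1.0)
        r2, k2, t2 = V.elbo_loss(x, model, beta=2.0)
        assert r1 >= 0 and k1 >= 0
        assert t1 == pytest.approx(r1 + k1)
        assert r2 == pytest.approx(r1) and k2 == pytest.approx(k1)
        assert t2 - r2 == pytest.approx(2.0 * (t1 - r1))  # beta scales KL part

    def test_kl_term_is_batch_mean_of_closed_form(self):
        model = V.init_vae(V.VAEArch(), seed=0)
        x = np.random.default_rng(1).normal(scale=0.3, size=(5, 400))
        _, kl, _ = V.elbo_loss(x, model)
        codes = V.encode_traces(model, x)
        # encode_traces normalises by norm_const (None -> 1), same as elbo here
        assert kl == pytest.approx(np.mean([V.kl_standard_normal(c)
                                            for c in codes]))

    def test_unnormalised_input_warns(self):
        model = V.init_vae(V.VAEArch(), seed=0)
        with pytest.warns(UserWarning, match="unnormalised"):
            V.elbo_loss(np.full((2, 400), 100.0), model)


class TestTraining:
    def test_loss_decreases(self, trained):
        model, _, _ = trained
        assert model.history[-1]["total"] < model.history[0]["total"]

    def test_zero_epochs_is_noop(self):
        model = V.init_vae(V.VAEArch(), seed=4)
        before = {k: v.copy() for k, v in model.params.items()}
        V.train_vae(model, np.random.default_rng(0).normal(size=(20, 400)),
                    epochs=0)
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])
        assert not model.trained

    def test_seeded_training_is_bit_reproducible(self):
        rng = np.random.default_rng(5)
        traces = 100 + 50 * rng.normal(size=(30, 400))
        runs = []
        for _ in range(2):
            m = V.init_vae(V.VAEArch(), seed=6)
            V.train_vae(m, traces, epochs=5, batch_size=8, seed=7)
            runs.append(m)
        for k in runs[0].params:
            np.testing.assert_array_equal(runs[0].params[k], runs[1].params[k])

    def test_reconstruction_of_constant_zero_trace_is_finite(self, trained):
        model, _, _ = trained
        out = V.reconstruct(model, np.zeros(400))
        assert out.shape == (400,) and np.all(np.isfinite(out))

    def test_untrained_model_warns_on_reconstruct(self):
        model = V.init_vae(V.VAEArch(), seed=0)
        with pytest.warns(UserWarning, match="untrained"):
            V.reconstruct(model, np.zeros(400))

    def test_reconstruction_is_approximately_idempotent(self, trained):
        """The first pass projects a noisy trace onto the learned manifold;
        a second pass moves it far less (the encoder is calibrated to noisy
        inputs, so the residual drift is small but not zero)."""
        model, traces, _ = trained
        ratios = []
        for x in traces[:20]:
            r1 = V.reconstruct(model, x)
            r2 = V.reconstruct(model, r1)
            ratios.append(np.linalg.norm(r2 - r1) / np.linalg.norm(r1 - x))
        assert max(ratios) < 0.5
        assert np.mean(ratios) < 0.3


class TestPraaAxisAndTraversal:
    def test_exact_linear_relation_recovered(self):
        praa = np.array([100.0, 120.0, 140.0, 160.0])
        codes = [V.LatentCode(np.array([p / 10.0, 0.0]), np.zeros(2))
                 for p in praa]
        axis = V.fit_praa_axis(codes, praa)
        np.testing.assert_allclose(axis.direction, [1.0, 0.0], atol=1e-9)
        assert axis.slope == pytest.approx(10.0)
        assert axis.intercept == pytest.approx(0.0, abs=1e-9)

    def test_permuted_labels_flatten_the_axis(self):
        """Breaking the latent-PRAA link by permutation collapses the fitted
        slope to a small fraction of the exact-relation slope."""
        rng = np.random.default_rng(11)
        praa = np.linspace(100, 170, 2000)
        codes = [V.LatentCode(np.array([p / 10.0, rng.normal()]), np.zeros(2))
                 for p in praa]
        true_slope = V.fit_praa_axis(codes, praa).slope
        assert true_slope == pytest.approx(10.0, rel=1e-9)
        permuted = [V.fit_praa_axis(codes, rng.permutation(praa)).slope
                    for _ in range(20)]
        assert max(permuted) < true_slope / 5.0
        assert np.mean(permuted) < true_slope / 10.0

    def test_two_eyes_rejected(self):
        codes = [V.LatentCode(np.zeros(2), np.zeros(2))] * 2
        with pytest.raises(ValueError):
            V.fit_praa_axis(codes, [1.0, 2.0])

    def test_identical_latents_degenerate(self):
        codes = [V.LatentCode(np.ones(2), np.zeros(2))] * 5
        with pytest.raises(DegenerateFitError):
            V.fit_praa_axis(codes, [1, 2, 3, 4, 5])

    @pytest.fixture()
    def axis(self, trained):
        model, traces, bundle = trained
        codes = V.encode_traces(model, traces)
        praa = [c.PRAA for c in bundle.covariates]
        return V.fit_praa_axis(codes, praa)

    def test_middle_frame_decodes_latent_center(self, trained, axis):
        model, _, _ = trained
        frames = V.traverse(model, axis, span=2.0, n_frames=11)
        assert len(frames) == 11
        mid = frames[5]
        norm = model.norm_const
        expected = V._decode(model.params,
                             model.latent_center[None, :])[0][0] * norm
        np.testing.assert_allclose(mid, expected, atol=1e-9)

    def test_zero_span_is_constant(self, trained, axis):
        model, _, _ = trained
        frames = V.traverse(model, axis, span=0.0, n_frames=5)
        for f in frames[1:]:
            np.testing.assert_array_equal(f, frames[0])

    def test_reversed_direction_reverses_frames(self, trained, axis):
        model, _, _ = trained
        rev = V.PraaAxis(direction=-axis.direction, slope=axis.slope,
                         intercept=axis.intercept)
        fwd = V.traverse(model, axis, span=1.5, n_frames=7)
        bwd = V.traverse(model, rev, span=1.5, n_frames=7)
        for a, b in zip(fwd, bwd[::-1]):
            np.testing.assert_allclose(a, b, atol=1e-9)

    def test_traversal_is_smooth(self, trained, axis):
        model, _, _ = trained
        frames = V.traverse(model, axis, span=2.0, n_frames=21)
        total = np.linalg.norm(frames[-1] - frames[0])
        steps = [np.linalg.norm(b - a) for a, b in zip(frames, frames[1:])]
        assert all(s < total for s in steps)

    def test_too_few_frames_rejected(self, trained, axis):
        model, _, _ = trained
        with pytest.raises(ValueError):
            V.traverse(model, axis, span=1.0, n_frames=1)


class TestAnimationExport:
    def test_gif_and_csv_round_trip(self, trained, tmp_path):
        model, _, _ = trained
        axis = V.PraaAxis(direction=np.array([1.0, 0.0]), slope=5.0,
                          intercept=130.0)
        frames = V.traverse(model, axis, span=1.0, n_frames=11)
        gif = tmp_path / "trav.gif"
        V.export_animation(frames, gif)
        import imageio.v2 as imageio
        assert gif.exists()
        assert len(imageio.mimread(gif)) == 11
        back = np.loadtxt(str(gif) + ".frames.csv", delimiter=",")
        np.testing.assert_allclose(back, np.vstack(frames), atol=1e-6)

    def test_minimal_two_frame_animation(self, trained, tmp_path):
        model, _, _ = trained
        frames = [np.zeros(400), np.ones(400)]
        gif = tmp_path / "two.gif"
        V.export_animation(frames, gif)
        import imageio.v2 as imageio
        assert len(imageio.mimread(gif)) == 2

    def test_single_frame_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            V.export_animation([np.zeros(400)], tmp_path / "x.gif")


class TestCheckpoint:
    def test_save_load_round_trip(self, trained, tmp_path):
        model, traces, _ = trained
        path = tmp_path / "model.npz"
        V.save_model(model, path)
        back = V.load_model(path)
        np.testing.assert_allclose(V.reconstruct(back, traces[0]),
                                   V.reconstruct(model, traces[0]), atol=1e-12)
        assert back.norm_const == model.norm_const
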