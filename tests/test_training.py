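"""Closed-form loss values, gradient penalty, and optimization behaviour."""

import numpy as np
import pytest

from cyclebp import model as M
from cyclebp import training as T
from cyclebp.autodiff import Tensor
from cyclebp.preprocessing import PairedSample


class TestLSGANLosses:
    @pytest.mark.parametrize(
        "real,fake,expected",
        [
            ([1.0, 1.0], [0.0, 0.0], 0.0),
            ([0.5, 0.5], [0.5, 0.5], 0.25),
            ([1.0], [1.0], 0.5),
        ],
    )
    def test_discriminator_values(self, real, fake, expected):
        assert T.lsgan_discriminator_loss(real, fake).item() == pytest.approx(
            expected, abs=1e-6
        )

    @pytest.mark.parametrize(
        "fake,expected", [([1.0, 1.0], 0.0), ([0.0], 0.5), ([0.5], 0.125)]
    )
    def test_generator_values(self, fake, expected):
        assert T.lsgan_generator_loss(fake).item() == pytest.approx(expected, abs=1e-6)

    def test_minimum_at_perfect_discrimination(self):
        grid = np.linspace(0.01, 0.99, 25)
        best = min(
            (T.lsgan_discriminator_loss([r], [f]).item(), r, f)
            for r in grid
            for f in grid
        )
        assert best[1] == grid[-1] and best[2] == grid[0]

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            T.lsgan_generator_loss([])


class TestWGANLosses:
    def test_indistinguishable_critic_is_zero(self):
        assert T.wgan_gp_discriminator_loss([2.0, 2.0], [2.0, 2.0], 0.0, 10.0).item() == 0.0

    def test_hand_computed_value(self):
        # mean fake 1, mean real 3, gp 0.1 at lambda 10 -> 1 - 3 + 1 = -1
        val = T.wgan_gp_discriminator_loss([3.0], [1.0], 0.1, 10.0).item()
        assert val == pytest.approx(-1.0, abs=1e-6)

    def test_penalty_scaling(self):
        base = T.wgan_gp_discriminator_loss([0.0], [0.0], 0.0, 10.0).item()
        with_gp = T.wgan_gp_discriminator_loss([0.0], [0.0], 0.35, 10.0).item()
        assert with_gp - base == pytest.approx(3.5, abs=1e-6)

    @pytest.mark.parametrize("fake,expected", [([0.0, 0.0], 0.0), ([5.0], -5.0)])
    def test_generator_values(self, fake, expected):
        assert T.wgan_generator_loss(fake).item() == pytest.approx(expected, abs=1e-6)

    def test_generator_loss_monotone_in_scores(self):
        lo = T.wgan_generator_loss([1.0, 2.0]).item()
        hi = T.wgan_generator_loss([2.0, 3.0]).item()
        assert hi < lo


class TestCycleLoss:
    def test_perfect_reconstruction(self, rng):
        x = rng.standard_normal((2, 2, 10))
        y = rng.standard_normal((2, 2, 10))
        assert T.cycle_consistency_loss(x, x, y, y).item() == 0.0

    def test_constant_offset(self, rng):
        x = rng.standard_normal((3, 2, 16))
        y = rng.standard_normal((3, 2, 16))
        val = T.cycle_consistency_loss(x, x + 0.1, y, y).item()
        assert val == pytest.approx(0.1, abs=1e-6)

    def test_symmetric_between_domains(self, rng):
        x, xr = rng.standard_normal((2, 8)), rng.standard_normal((2, 8))
        y, yr = rng.standard_normal((2, 8)), rng.standard_normal((2, 8))
        a = T.cycle_consistency_loss(x, xr, y, yr).item()
        b = T.cycle_consistency_loss(y, yr, x, xr).item()
        assert a == pytest.approx(b, abs=1e-12)

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            T.cycle_consistency_loss(np.zeros((2, 3)), np.zeros((2, 4)),
                                     np.zeros((2, 3)), np.zeros((2, 3)))


class _LinearCritic:
    """D(v) = <a, flatten(v)>; gradient is a everywhere."""

    def __init__(self, a):
        self.a = a

    def __call__(self, v):
        flat = v.reshape((v.shape[0], -1))
        from cyclebp import autodiff as ad

        return ad.matmul(flat, Tensor(self.a)).reshape((v.shape[0],))


class TestGradientPenalty:
    def test_unit_norm_linear_critic_gives_zero(self, rng):
        a = rng.standard_normal((2 * 64, 1))
        a /= np.linalg.norm(a)
        real = rng.uniform(-1, 1, (5, 2, 64))
        fake = rng.uniform(-1, 1, (5, 2, 64))
        gp = T.gradient_penalty(_LinearCritic(a), real, fake, rng)
        assert gp.item() == pytest.approx(0.0, abs=1e-10)

    def test_double_slope_critic_gives_one(self, rng):
        # D(v) = 2 v on scalar inputs: |grad| = 2 -> penalty (2-1)^2 = 1
        a = np.array([[2.0]])
        real = rng.uniform(-1, 1, (8, 1))
        fake = rng.uniform(-1, 1, (8, 1))
        gp = T.gradient_penalty(_LinearCritic(a), real, fake, rng)
        assert gp.item() == pytest.approx(1.0, abs=1e-6)

    def test_parameter_gradient_matches_finite_differences(self, rng):
        disc = M.Discriminator(M.DiscriminatorSpec.for_loss("wgan_gp", 6), 127, rng)
        for p in disc.parameters():
            p.data = p.data + rng.normal(0, 0.3, p.data.shape)
        real = rng.uniform(-1, 1, (3, 2, 127))
        fake = rng.uniform(-1, 1, (3, 2, 127))

        def gp():
            return T.gradient_penalty(disc, real, fake, np.random.default_rng(42))

        disc.zero_grad()
        gp().backward()
        p = disc.convs[1].weight
        idx = (4, 2)
        eps = 1e-5
        orig = p.data[idx]
        p.data[idx] = orig + eps
        lp = gp().item()
        p.data[idx] = orig - eps
        lm = gp().item()
        p.data[idx] = orig
        fd = (lp - lm) / (2 * eps)
        assert abs(p.grad[idx] - fd) / max(1e-9, abs(fd)) < 1e-4

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            T.gradient_penalty(_LinearCritic(np.ones((4, 1))),
                               np.zeros((2, 4)), np.zeros((3, 4)), rng)


def _toy_samples(n, t, rng):
    """Smooth paired windows linked by a fixed invertible map."""
    samples = []
    for i in range(n):
        phase = rng.uniform(0, 2 * np.pi)
        base = np.sin(np.linspace(0, 4 * np.pi, t) + phase)
        x = np.stack([0.8 * base, 0.5 * base])
        y = np.stack([-0.8 * base, 0.6 * base])
        samples.append(PairedSample(subject_id=f"t{i}", x=x, y=y, pulse_len_target=t))
    return samples


class TestTrainingStep:
    def test_lsgan_uses_one_discriminator_update(self, monkeypatch, rng):
        cfg = T.TrainConfig(loss_kind="lsgan", d_iters=25, epochs=1, batch_size=4)
        assert cfg.d_iters == 1  # forced by the least-squares game
        models = M.build_models(M.GeneratorSpec(4), M.DiscriminatorSpec.for_loss("lsgan", 6), 127, 0)
        trainer = T.Trainer(models, cfg)
        calls = []
        orig = T.Trainer._update_discriminator

        def counting(self, *a, **k):
            calls.append(1)
            return orig(self, *a, **k)

        monkeypatch.setattr(T.Trainer, "_update_discriminator", counting)
        trainer.training_step(rng.uniform(-1, 1, (4, 2, 127)), rng.uniform(-1, 1, (4, 2, 127)))
        assert len(calls) == 2  # one per discriminator

    def test_wgan_runs_d_iters_critic_updates(self, monkeypatch, rng):
        cfg = T.TrainConfig(loss_kind="wgan_gp", d_iters=5, epochs=1, batch_size=4)
        models = M.build_models(M.GeneratorSpec(4), M.DiscriminatorSpec.for_loss("wgan_gp", 6), 127, 0)
        trainer = T.Trainer(models, cfg)
        calls = []
        orig = T.Trainer._update_discriminator

        def counting(self, *a, **k):
            calls.append(1)
            return orig(self, *a, **k)

        monkeypatch.setattr(T.Trainer, "_update_discriminator", counting)
        trainer.training_step(rng.uniform(-1, 1, (4, 2, 127)), rng.uniform(-1, 1, (4, 2, 127)))
        assert len(calls) == 10  # 5 iterations x 2 discriminators

    def test_identical_seeds_give_identical_reports(self, rng):
        bx = rng.uniform(-1, 1, (4, 2, 127))
        by = rng.uniform(-1, 1, (4, 2, 127))
        reports = []
        for _ in range(2):
            models = M.build_models(M.GeneratorSpec(4), M.DiscriminatorSpec.for_loss("lsgan", 6), 127, 11)
            trainer = T.Trainer(models, T.TrainConfig(loss_kind="lsgan", epochs=1, batch_size=4, seed=11))
            reports.append([trainer.training_step(bx, by) for _ in range(2)])
        assert reports[0] == reports[1]


class TestFit:
    def test_epoch_and_batch_arithmetic(self, rng):
        samples = _toy_samples(10, 127, rng)
        models, log = T.fit(
            samples,
            T.TrainConfig(loss_kind="lsgan", epochs=2, batch_size=96, seed=0),
            window_len=127,
            g_spec=M.GeneratorSpec(4),
            d_spec=M.DiscriminatorSpec.for_loss("lsgan", 6),
        )
        assert len(log) == 2

    def test_cycle_loss_decreases_during_training(self, rng):
        samples = _toy_samples(8, 127, rng)
        cfg = T.TrainConfig(loss_kind="lsgan", epochs=50, batch_size=96,
                            learning_rate=1e-3, seed=0)
        _, log = T.fit(samples, cfg, 127, g_spec=M.GeneratorSpec(8),
                       d_spec=M.DiscriminatorSpec.for_loss("lsgan", 6))
        first = log[0].cycle_x + log[0].cycle_y
        last = log[-1].cycle_x + log[-1].cycle_y
        assert last < first

    def test_empty_training_set_rejected(self):
        models = M.build_models(M.GeneratorSpec(4), M.DiscriminatorSpec.for_loss("lsgan", 6), 127, 0)
        with pytest.raises(ValueError):
            T.Trainer(models, T.TrainConfig(epochs=1)).fit([])


class TestGrid:
    def test_combination_counts(self):
        combos = T.grid_combinations()
        ls = [c for c in combos if c["loss_kind"] == "lsgan"]
        wg = [c for c in combos if c["loss_kind"] == "wgan_gp"]
        assert (len(ls), len(wg), len(combos)) == (12, 36, 48)

    def test_single_combo_grid(self, rng, prepared):
        samples, norm, window, _ = prepared
        base = T.TrainConfig(loss_kind="lsgan", epochs=1, batch_size=8, seed=0)
        combo = {"loss_kind": "lsgan", "g_gru": 4, "d_l1": 6, "lambda_cyc": 5.0, "d_iters": 1}
        table = T.grid_search(
            base, samples[:4], samples[4:], window.window_len_target, norm,
            combos=[combo],
        )
        assert len(table) == 1
        assert table.loc[0, "g_gru"] == 4
        assert np.isfinite(table.loc[0, "val_pressure_rmse"])
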