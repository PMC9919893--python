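"""Adversarial objectives and the alternating CycleGAN optimization.

Two adversarial loss families are supported:

* **LSGAN** — least-squares objective (Pearson χ² divergence).  Discriminator:
  ``½·E[(D(y)−1)²] + ½·E[D(ỹ)²]``; generator: ``½·E[(D(ỹ)−1)²]``.
  One discriminator update per generator update.
* **WGAN-GP** — Wasserstein critic with gradient penalty.  Critic:
  ``E[D(ỹ)] − E[D(y)] + λ_GP·E[(‖∇_ŷ D(ŷ)‖₂ − 1)²]`` at interpolates
  ``ŷ = δ·y + (1−δ)·ỹ``, ``δ ~ U[0,1]`` per sample, ``λ_GP = 10``;
  generator: ``−E[D(ỹ)]``.  Several critic updates per generator update.

Both are combined with the cycle-consistency term
``E‖Gyx(Gxy(x)) − x‖₁ + E‖Gxy(Gyx(y)) − y‖₁`` scaled by ``λ_cyc``.
Optimization uses Adam (lr 1e-4, batch 96 at full scale, 1750 epochs in the
reference configuration; all three are configurable for desk-scale runs).
"""

from __future__ import annotations

import itertools
from dataclasses import asdict, dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from . import nn
from .model import (
    CycleGANModels,
    DiscriminatorSpec,
    GeneratorSpec,
    build_models,
)
from .preprocessing import PairedSample

LAMBDA_GP = 10.0


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


@dataclass
class TrainConfig:
    loss_kind: str = "lsgan"  # lsgan | wgan_gp
    lambda_cyc: float = 5.0  # grid: 5 / 15 / 25
    lambda_gp: float = LAMBDA_GP
    d_iters: int = 1  # wgan_gp grid: 5 / 15 / 25; lsgan: always 1
    learning_rate: float = 1e-4
    batch_size: int = 96
    epochs: int = 1750
    adam_betas: Tuple[float, float] = (0.5, 0.999)
    seed: int = 0
    checkpoint_interval: int = 0  # epochs between checkpoints; 0 = end only

    def __post_init__(self):
        if self.loss_kind not in ("lsgan", "wgan_gp"):
            raise ValueError("loss_kind must be 'lsgan' or 'wgan_gp'")
        if self.loss_kind == "lsgan":
            self.d_iters = 1  # the least-squares game always uses one update
        if self.d_iters < 1:
            raise ValueError("d_iters must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class LossReport:
    epoch: int
    d_x: float
    d_y: float
    adv_x: float
    adv_y: float
    cycle_x: float
    cycle_y: float
    gp_x: float
    gp_y: float
    g_total: float

    def as_dict(self):
        return asdict(self)


# ---------------------------------------------------------------------------
# closed-form loss primitives (scalar Tensors; accept arrays or Tensors)
# ---------------------------------------------------------------------------


def _scores(x) -> Tensor:
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
    if t.size == 0:
        raise ValueError("empty score set")
    return t


def lsgan_discriminator_loss(scores_real, scores_fake) -> Tensor:
    """½·mean((D(real) − 1)²) + ½·mean(D(fake)²)."""
    r, f = _scores(scores_real), _scores(scores_fake)
    return 0.5 * ((r - 1.0) ** 2).mean() + 0.5 * (f**2).mean()


def lsgan_generator_loss(scores_fake) -> Tensor:
    """½·mean((D(fake) − 1)²)."""
    f = _scores(scores_fake)
    return 0.5 * ((f - 1.0) ** 2).mean()


def wgan_gp_discriminator_loss(scores_real, scores_fake, gp, lambda_gp: float) -> Tensor:
    """mean(D(fake)) − mean(D(real)) + λ_GP·gp."""
    r, f = _scores(scores_real), _scores(scores_fake)
    gp_t = gp if isinstance(gp, Tensor) else Tensor(float(gp))
    return f.mean() - r.mean() + lambda_gp * gp_t


def wgan_generator_loss(scores_fake) -> Tensor:
    """−mean(D(fake))."""
    return -_scores(scores_fake).mean()


def cycle_consistency_loss(x, x_rec, y, y_rec) -> Tensor:
    """Per-element mean absolute reconstruction error, summed over domains."""
    terms = []
    for a, b in ((x, x_rec), (y, y_rec)):
        ta = a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))
        tb = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=np.float64))
        if ta.shape != tb.shape:
            raise ValueError(f"shape mismatch {ta.shape} vs {tb.shape}")
        terms.append(ad.abs_(tb - ta).mean())
    return terms[0] + terms[1]


def gradient_penalty(
    discriminator,
    real: np.ndarray,
    fake: np.ndarray,
    rng: np.random.Generator,
) -> Tensor:
    """Two-sided penalty (‖∇_ŷ D(ŷ)‖₂ − 1)² at per-sample interpolates.

    The interpolation weight δ is drawn uniformly per sample.  The returned
    scalar stays on the tape: differentiating it again reaches the
    discriminator parameters (double backward through the conv stack).
    """
    real = np.asarray(real, dtype=np.float64)
    fake = np.asarray(fake, dtype=np.float64)
    if real.shape != fake.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {fake.shape}")
    b = real.shape[0]
    delta = rng.uniform(size=(b,) + (1,) * (real.ndim - 1))
    interp = Tensor(delta * real + (1.0 - delta) * fake, requires_grad=True)
    score = discriminator(interp)
    (g,) = ad.grad_of(score.sum(), [interp], create_graph=True)
    axes = tuple(range(1, real.ndim))
    sq = (g * g).sum(axis=axes)
    norm = ad.sqrt(sq + 1e-12)
    return ((norm - 1.0) ** 2).mean()


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


class Trainer:
    """Alternating optimization of the four networks."""

    def __init__(self, models: CycleGANModels, config: TrainConfig):
        self.models = models
        self.config = config
        self.rng = np.random.Generator(np.random.PCG64(config.seed))
        g_params = models.gxy.parameters() + models.gyx.parameters()
        self.opt_g = nn.Adam(g_params, lr=config.learning_rate, betas=config.adam_betas)
        self.opt_dx = nn.Adam(
            models.dx.parameters(), lr=config.learning_rate, betas=config.adam_betas
        )
        self.opt_dy = nn.Adam(
            models.dy.parameters(), lr=config.learning_rate, betas=config.adam_betas
        )

    # -- one optimization step --------------------------------------------
    def training_step(self, batch_x: np.ndarray, batch_y: np.ndarray, epoch: int = 0) -> LossReport:
        cfg = self.config
        m = self.models
        if batch_x.shape[0] != batch_y.shape[0]:
            raise ValueError("batch sizes differ between domains")

        # forward the generators once, on tape; the discriminator updates use
        # the same fake values detached from the graph
        x_t, y_t = Tensor(batch_x), Tensor(batch_y)
        fake_y = m.gxy(x_t)
        fake_x = m.gyx(y_t)

        d_x_val = d_y_val = gp_x_val = gp_y_val = 0.0
        for _ in range(cfg.d_iters):
            d_y_val, gp_y_val = self._update_discriminator(
                m.dy, self.opt_dy, batch_y, fake_y.data
            )
            d_x_val, gp_x_val = self._update_discriminator(
                m.dx, self.opt_dx, batch_x, fake_x.data
            )

        # generator update: adversarial + cycle, through live generators
        rec_x = m.gyx(fake_y)
        rec_y = m.gxy(fake_x)
        if cfg.loss_kind == "lsgan":
            adv_y = lsgan_generator_loss(m.dy(fake_y))
            adv_x = lsgan_generator_loss(m.dx(fake_x))
        else:
            adv_y = wgan_generator_loss(m.dy(fake_y))
            adv_x = wgan_generator_loss(m.dx(fake_x))
        cyc_x = ad.abs_(rec_x - x_t).mean()
        cyc_y = ad.abs_(rec_y - y_t).mean()
        g_total = adv_x + adv_y + cfg.lambda_cyc * (cyc_x + cyc_y)
        if not np.isfinite(g_total.item()):
            raise DivergenceError(f"non-finite generator loss at epoch {epoch}")
        self.opt_g.zero_grad()
        g_total.backward()
        self.opt_g.step()

        return LossReport(
            epoch=epoch,
            d_x=d_x_val,
            d_y=d_y_val,
            adv_x=adv_x.item(),
            adv_y=adv_y.item(),
            cycle_x=cyc_x.item(),
            cycle_y=cyc_y.item(),
            gp_x=gp_x_val,
            gp_y=gp_y_val,
            g_total=g_total.item(),
        )

    def _update_discriminator(self, disc, opt, real, fake_data):
        cfg = self.config
        real_scores = disc(Tensor(real))
        fake_scores = disc(Tensor(fake_data))  # detached fakes
        gp_val = 0.0
        if cfg.loss_kind == "lsgan":
            loss = lsgan_discriminator_loss(real_scores, fake_scores)
        else:
            gp = gradient_penalty(disc, real, fake_data, self.rng)
            gp_val = gp.item()
            loss = wgan_gp_discriminator_loss(
                real_scores, fake_scores, gp, cfg.lambda_gp
            )
        if not np.isfinite(loss.item()):
            raise DivergenceError("non-finite discriminator loss")
        opt.zero_grad()
        loss.backward()
        opt.step()
        return loss.item(), gp_val

    # -- epochs ------------------------------------------------------------
    def fit(
        self,
        samples: Sequence[PairedSample],
        checkpoint_fn=None,
        progress: bool = False,
    ) -> List[LossReport]:
        """Run ``config.epochs`` epochs; returns one averaged report per epoch."""
        if len(samples) == 0:
            raise ValueError("empty training set")
        cfg = self.config
        xs = np.stack([s.x for s in samples])
        ys = np.stack([s.y for s in samples])
        n = len(samples)
        log: List[LossReport] = []
        for epoch in range(cfg.epochs):
            order = self.rng.permutation(n)
            reports = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                reports.append(self.training_step(xs[idx], ys[idx], epoch=epoch))
            mean = {
                k: float(np.mean([getattr(r, k) for r in reports]))
                for k in vars(reports[0])
                if k != "epoch"
            }
            log.append(LossReport(epoch=epoch, **mean))
            if progress and (epoch % max(1, cfg.epochs // 20) == 0):
                print(
                    f"epoch {epoch:5d}  cycle={log[-1].cycle_x + log[-1].cycle_y:.4f}"
                    f"  g_total={log[-1].g_total:.4f}"
                )
            if (
                checkpoint_fn is not None
                and cfg.checkpoint_interval
                and (epoch + 1) % cfg.checkpoint_interval == 0
            ):
                checkpoint_fn(self.models, epoch)
        if checkpoint_fn is not None:
            checkpoint_fn(self.models, cfg.epochs - 1)
        return log


def fit(
    samples: Sequence[PairedSample],
    config: TrainConfig,
    window_len: int,
    g_spec: Optional[GeneratorSpec] = None,
    d_spec: Optional[DiscriminatorSpec] = None,
    checkpoint_fn=None,
    progress: bool = False,
) -> Tuple[CycleGANModels, List[LossReport]]:
    """Build models and train them on preprocessed paired samples."""
    g_spec = g_spec or GeneratorSpec()
    d_spec = d_spec or DiscriminatorSpec.for_loss(config.loss_kind, 8)
    models = build_models(g_spec, d_spec, window_len, seed=config.seed)
    trainer = Trainer(models, config)
    log = trainer.fit(samples, checkpoint_fn=checkpoint_fn, progress=progress)
    return models, log


def loss_log_frame(log: Iterable[LossReport]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in log])


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------

GRID_G_GRU = (64, 128)
GRID_D_L1 = (6, 8)
GRID_LAMBDA_CYC = (5.0, 15.0, 25.0)
GRID_D_ITERS = (5, 15, 25)


def grid_combinations(
    loss_kinds: Sequence[str] = ("lsgan", "wgan_gp"),
    g_gru: Sequence[int] = GRID_G_GRU,
    d_l1: Sequence[int] = GRID_D_L1,
    lambda_cyc: Sequence[float] = GRID_LAMBDA_CYC,
    d_iters: Sequence[int] = GRID_D_ITERS,
) -> List[dict]:
    """Enumerate the hyperparameter grid; d_iters varies only for WGAN-GP."""
    combos = []
    for kind in loss_kinds:
        iters = d_iters if kind == "wgan_gp" else (1,)
        for g, d, lam, it in itertools.product(g_gru, d_l1, lambda_cyc, iters):
            combos.append(
                {"loss_kind": kind, "g_gru": g, "d_l1": d, "lambda_cyc": lam, "d_iters": it}
            )
    return combos


def grid_search(
    base_config: TrainConfig,
    train_samples: Sequence[PairedSample],
    val_samples: Sequence[PairedSample],
    window_len: int,
    norm_spec,
    combos: Optional[Sequence[dict]] = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Train each grid combination and rank by validation pressure RMSE."""
    from .evaluation import rmse_against_truth

    combos = list(combos) if combos is not None else grid_combinations()
    if not combos:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for combo in combos:
        cfg = TrainConfig(
            loss_kind=combo["loss_kind"],
            lambda_cyc=combo["lambda_cyc"],
            d_iters=combo["d_iters"],
            learning_rate=base_config.learning_rate,
            batch_size=base_config.batch_size,
            epochs=base_config.epochs,
            adam_betas=base_config.adam_betas,
            seed=base_config.seed,
        )
        models, _ = fit(
            train_samples,
            cfg,
            window_len,
            g_spec=GeneratorSpec(gru_features=combo["g_gru"]),
            d_spec=DiscriminatorSpec.for_loss(combo["loss_kind"], combo["d_l1"]),
            progress=progress,
        )
        rmse_p, rmse_a = rmse_against_truth(models.gxy, val_samples, norm_spec)
        rows.append(
            {
                **combo,
                "val_pressure_rmse": rmse_p,
                "val_area_rmse": rmse_a,
            }
        )
    frame = pd.DataFrame(rows).sort_values("val_pressure_rmse").reset_index(drop=True)
    return frame
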