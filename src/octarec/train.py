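"""Two-staged training schedule and the subsequent adversarial stage.

Each training iteration (one mini-batch) performs three updates:

1. the SR module alone, against the (HR, LQ) intermediate target;
2. the QE module alone, consuming the SR output with gradients
   detached so the stages stay isolated;
3. the concatenated end-to-end network, against (HR, HQ), at a lower
   learning rate (``learning_rate * finetune_lr_factor``).

Weights use He-normal initialization, Adam optimization with an L2
penalty, and early stopping on the validation combined loss.  The
adversarial stage alternates discriminator and generator updates per
batch around a pre-trained generator; its early stopping monitors the
generator's non-adversarial validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor, no_grad, working_dtype
from .angio import split_dataset
from .losses import LossConfig, combined_loss, discriminator_loss, \
    generator_adv_loss
from .nets import Discriminator, Generator, NetConfig
from .nn import Adam

__all__ = ["TrainConfig", "train_two_stage", "train_adversarial"]

# an epoch only counts as an improvement when the validation loss drops
# by more than this, so float-level noise does not reset patience
_MIN_DELTA = 1e-4


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    finetune_lr_factor: float = 0.1
    batch_size: int = 8
    max_epochs: int = 100
    patience: int = 10
    l2_weight: float = 1e-5
    seed: int = 0
    adversarial: bool = False
    dtype: str = "float32"  # single precision roughly halves CPU time

    def __post_init__(self):
        if not (0.0 < self.finetune_lr_factor < 1.0):
            raise ValueError("finetune_lr_factor must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


def _stack(pairs, attr: str) -> np.ndarray:
    return np.stack([getattr(p, attr).pixels for p in pairs])


def _split_pairs(pairs, val_pairs, seed):
    if val_pairs is not None:
        return list(pairs), list(val_pairs)
    tr, va = split_dataset(len(pairs), (9, 1), seed)
    return [pairs[i] for i in tr], [pairs[i] for i in va]


def _validation_loss(G: Generator, val_pairs, loss_cfg) -> float:
    lr = _stack(val_pairs, "lr_lq")
    hr = _stack(val_pairs, "hr_hq")
    with no_grad():
        rec = G(Tensor(lr).reshape(lr.shape[0], 1, *lr.shape[1:]))
        return combined_loss(hr, rec, loss_cfg).item()


def _snapshot(module):
    return [a.copy() for a in module.state_arrays()]


def train_two_stage(pairs, net_cfg: NetConfig, loss_cfg: LossConfig,
                    train_cfg: TrainConfig, val_pairs=None):
    """Train the two-stage generator; returns (generator, history).

    ``pairs`` supplies training records; validation records come from
    ``val_pairs`` or, when omitted, a seeded 9:1 split of ``pairs``.
    ``history`` maps 'train_sr' / 'train_qe' / 'train_e2e' / 'val' to
    per-epoch mean losses.  Fixed seed gives a reproducible history.
    """
    with working_dtype(train_cfg.dtype):
        return _train_two_stage(pairs, net_cfg, loss_cfg, train_cfg,
                                val_pairs)


def _train_two_stage(pairs, net_cfg, loss_cfg, train_cfg, val_pairs):
    if not pairs:
        raise ValueError("no training pairs")
    train_pairs, vpairs = _split_pairs(pairs, val_pairs, train_cfg.seed)
    if not train_pairs or not vpairs:
        raise ValueError("empty train or validation split")
    ratios = {p.ratio for p in train_pairs + vpairs}
    if ratios != {net_cfg.upsample_ratio}:
        raise ValueError(f"pair ratio(s) {sorted(ratios)} do not match the "
                         f"network ratio {net_cfg.upsample_ratio}")

    G = Generator(net_cfg, seed=train_cfg.seed)
    lr0 = train_cfg.learning_rate
    opt_sr = Adam(G.sr.parameters(), lr=lr0, l2=train_cfg.l2_weight)
    opt_qe = Adam(G.qe.parameters(), lr=lr0, l2=train_cfg.l2_weight)
    opt_e2e = Adam(G.parameters(), lr=lr0 * train_cfg.finetune_lr_factor,
                   l2=train_cfg.l2_weight)
    rng = np.random.default_rng([train_cfg.seed, 0xA1])

    x_lr = _stack(train_pairs, "lr_lq")
    y_hrlq = _stack(train_pairs, "hr_lq")
    y_hrhq = _stack(train_pairs, "hr_hq")

    history = {"train_sr": [], "train_qe": [], "train_e2e": [], "val": []}
    best_val, best_state, since_best = np.inf, None, 0
    n = len(train_pairs)
    for _epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n)
        ep = {"train_sr": [], "train_qe": [], "train_e2e": []}
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            xb = Tensor(x_lr[idx][:, None])
            hrlq, hrhq = y_hrlq[idx], y_hrhq[idx]

            loss = combined_loss(hrlq, G.sr(xb), loss_cfg)
            opt_sr.zero_grad(); loss.backward(); opt_sr.step()
            ep["train_sr"].append(loss.item())

            with no_grad():
                sr_out = G.sr(xb).data
            loss = combined_loss(hrhq, G.qe(Tensor(sr_out)), loss_cfg)
            opt_qe.zero_grad(); loss.backward(); opt_qe.step()
            ep["train_qe"].append(loss.item())

            loss = combined_loss(hrhq, G(xb), loss_cfg)
            opt_e2e.zero_grad(); loss.backward(); opt_e2e.step()
            ep["train_e2e"].append(loss.item())

        for key, vals in ep.items():
            history[key].append(float(np.mean(vals)))
        val = _validation_loss(G, vpairs, loss_cfg)
        history["val"].append(val)
        if val < best_val - _MIN_DELTA:
            best_val, best_state, since_best = val, _snapshot(G), 0
        else:
            since_best += 1
            if since_best >= train_cfg.patience:
                break
    if best_state is not None:
        G.load_state_arrays(best_state)
    return G, history


def train_adversarial(G: Generator, pairs, loss_cfg: LossConfig,
                      train_cfg: TrainConfig, val_pairs=None,
                      discriminator: Discriminator = None):
    """Adversarial refinement of a pre-trained generator.

    Alternates, per batch, a discriminator update on
    -[log D(HR,HQ) + log(1 - D(G(LR,LQ)))] and a generator update on the
    combined loss plus ``w_adv * (-log D(G(LR,LQ)))``.  Returns
    (generator, discriminator, history) with per-epoch 'd_loss',
    'g_loss' and non-adversarial 'val' curves.
    """
    with working_dtype(train_cfg.dtype):
        return _train_adversarial(G, pairs, loss_cfg, train_cfg, val_pairs,
                                  discriminator)


def _train_adversarial(G, pairs, loss_cfg, train_cfg, val_pairs,
                       discriminator):
    if not pairs:
        raise ValueError("no training pairs")
    train_pairs, vpairs = _split_pairs(pairs, val_pairs, train_cfg.seed)
    if not train_pairs or not vpairs:
        raise ValueError("empty train or validation split")
    D = discriminator if discriminator is not None else \
        Discriminator(base_channels=32, seed=train_cfg.seed)
    opt_g = Adam(G.parameters(), lr=train_cfg.learning_rate,
                 l2=train_cfg.l2_weight)
    opt_d = Adam(D.parameters(), lr=train_cfg.learning_rate,
                 l2=train_cfg.l2_weight)
    rng = np.random.default_rng([train_cfg.seed, 0xD1])

    x_lr = _stack(train_pairs, "lr_lq")
    y_hrhq = _stack(train_pairs, "hr_hq")
    history = {"d_loss": [], "g_loss": [], "val": []}
    best_val, best_state, since_best = np.inf, None, 0
    n = len(train_pairs)
    for _epoch in range(train_cfg.max_epochs):
        order = rng.permutation(n)
        ep_d, ep_g = [], []
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            xb = Tensor(x_lr[idx][:, None])
            hrhq = y_hrhq[idx]

            with no_grad():
                fake = G(xb).data
            D.train()
            d_loss = discriminator_loss(D(hrhq), D(fake))
            opt_d.zero_grad(); d_loss.backward(); opt_d.step()
            ep_d.append(d_loss.item())

            D.eval()
            rec = G(xb)
            g_loss = generator_adv_loss(hrhq, rec, D(rec), loss_cfg)
            opt_g.zero_grad(); g_loss.backward(); opt_g.step()
            ep_g.append(g_loss.item())

        history["d_loss"].append(float(np.mean(ep_d)))
        history["g_loss"].append(float(np.mean(ep_g)))
        val = _validation_loss(G, vpairs, loss_cfg)
        history["val"].append(val)
        if val < best_val - _MIN_DELTA:
            best_val = val
            best_state = (_snapshot(G), _snapshot(D))
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_cfg.patience:
                break
    if best_state is not None:
        G.load_state_arrays(best_state[0])
        D.load_state_arrays(best_state[1])
    return G, D, history
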