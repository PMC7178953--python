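"""Training: adaptive-Gaussian initialization, polynomial learning-rate
decay, soft-Dice objective with deep supervision, and the RMSProp loop.

The per-term objective is one minus the soft Dice coefficient
2*sum(p*q) / (sum(p^2) + sum(q^2) + eps), and the total loss adds the three
supervision heads weighted w = (1/16, 1/8, 1/4), coarsest head first — the
weighting is lowest at the lowest-resolution supervising level.  The
learning rate follows l_n = l_0 * (1 - n/N_e)^alpha with l_0 = 5e-4 and
alpha = 1.5, updated once per epoch; mini-batches hold four images.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import DTYPE, RMSProp, init_std  # re-export: init_std lives with the layers
from .network import D2FCDN

__all__ = ["TrainConfig", "LossTerms", "init_std", "lr_at_epoch", "dice_value",
           "soft_dice", "total_loss", "train"]

DICE_EPS = 1e-6


@dataclass
class TrainConfig:
    batch_size: int = 4
    l_0: float = 5e-4
    N_e: int = 50  # 50 for single-image datasets, 20 for the series dataset
    alpha: float = 1.5
    supervision_weights: tuple = (1 / 16, 1 / 8, 1 / 4)  # coarse -> fine
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-8

    def __post_init__(self):
        if self.N_e < 1:
            raise ValueError("N_e must be >= 1")
        if self.l_0 <= 0:
            raise ValueError("initial learning rate must be positive")
        if not all(0 <= w < 1 for w in self.supervision_weights):
            raise ValueError("supervision weights must lie in [0, 1)")


@dataclass
class LossTerms:
    """Dice coefficients of the main output and the supervision heads."""

    main: float
    supervised: tuple

    def __post_init__(self):
        for v in (self.main, *self.supervised):
            if not 0.0 <= float(v) <= 1.0 + 1e-9:
                raise ValueError(f"Dice value {v} outside [0, 1]")


def lr_at_epoch(n: int, cfg: TrainConfig) -> float:
    """Polynomial decay l_0 * (1 - n/N_e)^alpha, n = 0 .. N_e."""
    if not 0 <= n <= cfg.N_e:
        raise ValueError(f"epoch {n} outside [0, {cfg.N_e}]")
    return cfg.l_0 * (1.0 - n / cfg.N_e) ** cfg.alpha


def dice_value(p: np.ndarray, q: np.ndarray, eps: float = DICE_EPS) -> float:
    """Soft Dice coefficient 2*sum(p*q) / (sum(p^2) + sum(q^2) + eps).

    p is a probability map, q the binary ground truth (object 1,
    background 0); the smoothing eps defines the empty-empty case as 0.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    return float(2.0 * (p * q).sum() / ((p * p).sum() + (q * q).sum() + eps))


def soft_dice(p: Tensor, q: np.ndarray, eps: float = DICE_EPS) -> Tensor:
    """Differentiable soft Dice coefficient (autograd version)."""
    qt = Tensor(np.asarray(q, dtype=p.dtype))
    if p.shape != qt.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {qt.shape}")
    num = 2.0 * (p * qt).sum()
    den = (p * p).sum() + (qt * qt).sum() + eps
    return num / den


def total_loss(terms: LossTerms, cfg: TrainConfig) -> float:
    """(1 - dice_main) + sum_i w_i * (1 - dice_supervised_i)."""
    w = cfg.supervision_weights
    if len(terms.supervised) != len(w):
        raise ValueError(
            f"expected {len(w)} supervised terms, got {len(terms.supervised)}")
    return (1.0 - terms.main) + sum(
        wi * (1.0 - di) for wi, di in zip(w, terms.supervised))


def _loss_tensor(main_prob: Tensor, head_probs, truth: np.ndarray,
                 cfg: TrainConfig):
    """Autograd total loss; returns (loss tensor, main dice float)."""
    w = cfg.supervision_weights
    if len(head_probs) != len(w):
        raise ValueError(
            f"expected {len(w)} supervised terms, got {len(head_probs)}")
    d_main = soft_dice(main_prob, truth)
    loss = 1.0 - d_main
    for wi, hp in zip(w, head_probs):
        loss = loss + wi * (1.0 - soft_dice(hp, truth))
    return loss, d_main.item()


def train(net: D2FCDN, data, cfg: TrainConfig = None, seed: int = 0,
          augment=None, log_path=None):
    """Train a D2FC-DN with RMSProp on the deeply supervised Dice loss.

    Parameters
    ----------
    net : D2FCDN
    data : sequence of (image, mask) pairs; images (H, W) in [0, 255] or
        [0, 1], masks binary, both matching the network input shape.
    cfg : TrainConfig
    seed : int — controls shuffling and online augmentation; the run is
        deterministic given (net weights, data, cfg, seed).
    augment : optional callable (img, mask, rng) -> (img, mask) applied to
        every sample each epoch (online augmentation).
    log_path : optional CSV path receiving (epoch, lr, total_loss, main_dice).

    Returns the per-epoch log as a list of dicts; net is trained in place.
    """
    cfg = cfg if cfg is not None else TrainConfig()
    if len(data) == 0:
        raise ValueError("empty training dataset")
    images, masks = [], []
    for img, mask in data:
        img = np.asarray(img, dtype=DTYPE)
        if img.max() > 1.5:
            img = img / 255.0
        if img.shape != tuple(net.spec.input_hw):
            raise ValueError(
                f"image shape {img.shape} does not match network input "
                f"{tuple(net.spec.input_hw)}")
        images.append(img)
        masks.append(np.asarray(mask, dtype=DTYPE))

    rng = np.random.default_rng(seed)
    opt = RMSProp(net.parameters(), lr=cfg.l_0, decay=cfg.rmsprop_decay,
                  eps=cfg.rmsprop_eps)
    net.train()
    log = []
    for epoch in range(cfg.N_e):
        opt.lr = lr_at_epoch(epoch, cfg)
        order = rng.permutation(len(images))
        epoch_loss, epoch_dice, n_batches = 0.0, 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = [], []
            for i in idx:
                img, mask = images[i], masks[i]
                if augment is not None:
                    img, mask = augment(img, mask, rng)
                xb.append(img)
                yb.append(np.asarray(mask, dtype=DTYPE))
            x = Tensor(np.stack(xb)[:, None])
            y = np.stack(yb)[:, None]
            net.zero_grad()
            main_prob, head_probs = net(x)
            loss, d_main = _loss_tensor(main_prob, head_probs, y, cfg)
            lval = loss.item()
            if not np.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite loss {lval} at epoch {epoch}, batch {n_batches}")
            loss.backward()
            opt.step()
            epoch_loss += lval
            epoch_dice += d_main
            n_batches += 1
        log.append({"epoch": epoch, "lr": opt.lr,
                    "total_loss": epoch_loss / n_batches,
                    "main_dice": epoch_dice / n_batches})
    net.eval()
    if log_path is not None:
        with open(log_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["epoch", "lr", "total_loss",
                                                    "main_dice"])
            writer.writeheader()
            writer.writerows(log)
    return log
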