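"""Convolutional variational autoencoder over one-hot protein alignments.

The encoder is three blocks of (3x3 same-padding convolution, batch
normalization, ELU, 2x max pooling along the length dimension); the flattened
feature map feeds two affine heads producing the latent Gaussian parameters
(mu, log-variance). The decoder mirrors this with nearest-neighbor 2x
upsampling along length and ends in a convolution to a single channel whose
softmax over the alphabet dimension yields per-position categorical
distributions. Training maximizes the evidence lower bound (ELBO):
reconstruction cross-entropy plus a KL term to the standard-normal prior,
annealed linearly from beta=0 to beta=1 over the epochs to avoid posterior
collapse. Batches are drawn with replacement, weighted by similarity to the
wildtype.

The alignment width is padded to the next multiple of 8 with gap-letter
columns (three 2x poolings require divisibility); the decoder output is
cropped back before the loss, so padding never enters the objective.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._layers import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    ELU,
    Layer,
    MaxPoolLen,
    Param,
    UpsampleLen,
)
from .alphabet import ALPHABET
from .encoding import weighted_batches

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LatentEncoding",
    "LossComponents",
    "SequenceVAE",
    "build_model",
    "elbo_loss",
    "gaussian_kl",
    "kl_anneal",
    "reparameterized_sample",
    "train",
    "load_model",
]

_PROB_EPS = 1e-8


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration (alignment width 322,
    alphabet 21, filters 128/96/64 mirrored, latent dimension 64). For quick
    CPU experiments shrink ``encoder_filters``/``decoder_filters`` and
    ``latent_dim``; the shapes adapt automatically.
    """

    L: int
    alphabet: str = ALPHABET
    latent_dim: int = 64
    encoder_filters: tuple[int, int, int] = (128, 96, 64)
    decoder_filters: tuple[int, int, int] = (64, 96, 128)
    batch_norm: bool = True
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if len(self.encoder_filters) != 3 or len(self.decoder_filters) != 3:
            raise ValueError("exactly three encoder and three decoder blocks")
        if self.padded_length < 8:
            raise ValueError(
                f"alignment width {self.L} too small for three 2x poolings"
            )

    @property
    def A(self) -> int:
        return len(self.alphabet)

    @property
    def padded_length(self) -> int:
        return int(math.ceil(self.L / 8) * 8)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    anneal: bool = True
    patience: int | None = None  # optional early stop on beta=1 test loss

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class LatentEncoding:
    """Gaussian posterior parameters; arrays are (..., latent_dim)."""

    mu: np.ndarray
    log_var: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu).all() and np.isfinite(self.log_var).all()):
            raise ValueError("latent encoding contains non-finite entries")

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(0.5 * self.log_var)


@dataclass(frozen=True)
class LossComponents:
    reconstruction: float
    kl: float
    beta: float

    @property
    def total(self) -> float:
        return self.reconstruction + self.beta * self.kl


def kl_anneal(epoch: int, total_epochs: int) -> float:
    """Linear KL annealing weight: 0 at the first epoch, 1 at the last."""
    if total_epochs < 2:
        return 1.0
    if not 0 <= epoch < total_epochs:
        raise ValueError("epoch must satisfy 0 <= epoch < total_epochs")
    return epoch / (total_epochs - 1)


def gaussian_kl(mu: np.ndarray, log_var: np.ndarray) -> np.ndarray:
    """Closed-form KL(N(mu, diag exp(log_var)) || N(0, I)) per sequence."""
    return 0.5 * np.sum(np.exp(log_var) + mu ** 2 - 1.0 - log_var, axis=-1)


def elbo_loss(
    probs: np.ndarray,
    x: np.ndarray,
    enc: LatentEncoding,
    beta: float,
) -> LossComponents:
    """Loss components from decoder probabilities and a one-hot batch.

    ``reconstruction`` is the batch-mean of the per-sequence cross-entropy
    (sum over positions, nats); ``kl`` is the batch-mean closed-form Gaussian
    KL. Probabilities are clamped at 1e-8 before the log.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    if probs.shape != x.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs x {x.shape}")
    logp = np.log(np.clip(probs, _PROB_EPS, None))
    recon = float(-(x * logp).sum(axis=(-2, -1)).mean())
    kl = float(gaussian_kl(enc.mu, enc.log_var).mean())
    return LossComponents(reconstruction=recon, kl=kl, beta=float(beta))


def reparameterized_sample(
    enc: LatentEncoding, seed: int | np.random.Generator
) -> np.ndarray:
    """z = mu + exp(log_var / 2) * eps with eps ~ N(0, I)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(enc.mu.shape)
    return enc.mu + np.exp(0.5 * enc.log_var) * eps


def _make_block_enc(c_in, c_out, rng, dtype, bn) -> list[Layer]:
    block: list[Layer] = [Conv2D(c_in, c_out, rng, dtype=dtype)]
    if bn:
        block.append(BatchNorm(c_out, dtype=dtype))
    block += [ELU(), MaxPoolLen()]
    return block


def _make_block_dec(c_in, c_out, rng, dtype, bn) -> list[Layer]:
    block: list[Layer] = [Conv2D(c_in, c_out, rng, dtype=dtype)]
    if bn:
        block.append(BatchNorm(c_out, dtype=dtype))
    block += [ELU(), UpsampleLen()]
    return block


class SequenceVAE:
    """The assembled encoder/decoder with training and checkpoint support."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        self.cfg = cfg
        dtype = np.dtype(cfg.dtype).type
        self._dtype = dtype
        rng = np.random.default_rng(seed)
        Lp, A = cfg.padded_length, cfg.A
        ef, df = cfg.encoder_filters, cfg.decoder_filters
        bn = cfg.batch_norm

        self.encoder: list[Layer] = []
        c_in = 1
        for c_out in ef:
            self.encoder += _make_block_enc(c_in, c_out, rng, dtype, bn)
            c_in = c_out
        self._enc_out_shape = (Lp // 8, A, ef[-1])
        flat = (Lp // 8) * A * ef[-1]
        self.fc_mu = Dense(flat, cfg.latent_dim, rng, dtype=dtype)
        self.fc_log_var = Dense(flat, cfg.latent_dim, rng, dtype=dtype)

        self._dec_in_shape = (Lp // 8, A, df[0])
        self.fc_dec = Dense(cfg.latent_dim, (Lp // 8) * A * df[0], rng, dtype=dtype)
        self.decoder: list[Layer] = []
        c_in = df[0]
        for c_out in df:
            self.decoder += _make_block_dec(c_in, c_out, rng, dtype, bn)
            c_in = c_out
        self.conv_out = Conv2D(df[-1], 1, rng, dtype=dtype)

    # ---- parameter plumbing -------------------------------------------------

    def _all_layers(self) -> list[tuple[str, Layer]]:
        named = []
        for i, layer in enumerate(self.encoder):
            named.append((f"enc{i}", layer))
        named += [("fc_mu", self.fc_mu), ("fc_log_var", self.fc_log_var),
                  ("fc_dec", self.fc_dec)]
        for i, layer in enumerate(self.decoder):
            named.append((f"dec{i}", layer))
        named.append(("conv_out", self.conv_out))
        return named

    def parameters(self) -> list[Param]:
        return [p for _, layer in self._all_layers() for p in layer.params()]

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self._all_layers():
            for j, p in enumerate(layer.params()):
                state[f"{name}.p{j}"] = p.val
            for key, buf in layer.buffers().items():
                state[f"{name}.{key}"] = buf
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._all_layers():
            for j, p in enumerate(layer.params()):
                p.val[...] = state[f"{name}.p{j}"]
            bufs = {
                key: np.array(state[f"{name}.{key}"])
                for key in layer.buffers()
            }
            layer.set_buffers(bufs)

    # ---- forward pieces -----------------------------------------------------

    def _pad_input(self, x: np.ndarray) -> np.ndarray:
        """(B, L, A) one-hot -> (B, Lp, A, 1) with gap-letter padding."""
        B = x.shape[0]
        Lp, A = self.cfg.padded_length, self.cfg.A
        if x.shape[1] != self.cfg.L or x.shape[2] != A:
            raise ValueError(
                f"batch shape {x.shape[1:]} does not match model "
                f"(L={self.cfg.L}, A={A})"
            )
        out = np.zeros((B, Lp, A, 1), dtype=self._dtype)
        out[:, : self.cfg.L, :, 0] = x
        out[:, self.cfg.L:, A - 1, 0] = 1.0  # gap letter in padded columns
        return out

    def encode(self, x: np.ndarray, train: bool = False) -> LatentEncoding:
        """One-hot batch (B, L, A) -> posterior parameters (B, latent_dim)."""
        h = self._pad_input(np.asarray(x, dtype=self._dtype))
        for layer in self.encoder:
            h = layer.forward(h, train)
        flat = h.reshape(h.shape[0], -1)
        if train:
            self._enc_flat_shape = h.shape
        mu = self.fc_mu.forward(flat, train)
        log_var = self.fc_log_var.forward(flat, train)
        return LatentEncoding(mu=mu, log_var=log_var)

    def decode_logits(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        """Latent batch (B, d) -> cropped logits (B, L, A)."""
        z = np.asarray(z, dtype=self._dtype)
        if z.ndim == 1:
            z = z[None, :]
        if z.shape[1] != self.cfg.latent_dim:
            raise ValueError(
                f"latent dimension {z.shape[1]} != {self.cfg.latent_dim}"
            )
        g = self.fc_dec.forward(z, train)
        g = g.reshape(z.shape[0], *self._dec_in_shape)
        for layer in self.decoder:
            g = layer.forward(g, train)
        logits = self.conv_out.forward(g, train)[..., 0]
        return logits[:, : self.cfg.L, :]

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        """Latent batch -> per-position categorical probabilities (B, L, A)."""
        return _softmax(self.decode_logits(z, train))

    # ---- training step ------------------------------------------------------

    def train_step(
        self, x: np.ndarray, beta: float, rng: np.random.Generator
    ) -> LossComponents:
        """One forward/backward pass; gradients accumulate into the params."""
        x = np.asarray(x, dtype=self._dtype)
        B = x.shape[0]
        enc = self.encode(x, train=True)
        mu, lv = enc.mu, enc.log_var
        eps = rng.standard_normal(mu.shape).astype(self._dtype)
        z = mu + np.exp(0.5 * lv) * eps
        logits = self.decode_logits(z, train=True)
        probs = _softmax(logits)

        logp = logits - _logsumexp(logits)
        recon = float(-(x * logp).sum(axis=(1, 2)).mean())
        kl = float(gaussian_kl(mu, lv).mean())
        loss = LossComponents(reconstruction=recon, kl=kl, beta=float(beta))

        # backward: d total / d logits for softmax cross-entropy
        dlogits = (probs - x) / B
        Lp, A = self.cfg.padded_length, self.cfg.A
        dfull = np.zeros((B, Lp, A, 1), dtype=self._dtype)
        dfull[:, : self.cfg.L, :, 0] = dlogits
        dg = self.conv_out.backward(dfull)
        for layer in reversed(self.decoder):
            dg = layer.backward(dg)
        dz = self.fc_dec.backward(dg.reshape(B, -1))
        dmu = dz + beta * mu / B
        dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + beta * 0.5 * (np.exp(lv) - 1.0) / B
        dflat = self.fc_mu.backward(dmu) + self.fc_log_var.backward(dlv)
        dh = dflat.reshape(self._enc_flat_shape)
        for layer in reversed(self.encoder):
            dh = layer.backward(dh)
        return loss

    def evaluate(self, x: np.ndarray, beta: float = 1.0,
                 batch_size: int = 256) -> LossComponents:
        """Deterministic loss at the posterior mean (z = mu), eval mode."""
        recon_sum = 0.0
        kl_sum = 0.0
        n = x.shape[0]
        for start in range(0, n, batch_size):
            xb = np.asarray(x[start:start + batch_size], dtype=self._dtype)
            enc = self.encode(xb, train=False)
            probs = self.decode(enc.mu, train=False)
            logp = np.log(np.clip(probs, _PROB_EPS, None))
            recon_sum += float(-(xb * logp).sum(axis=(1, 2)).sum())
            kl_sum += float(gaussian_kl(enc.mu, enc.log_var).sum())
        return LossComponents(recon_sum / n, kl_sum / n, float(beta))

    # ---- checkpointing ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        meta = json.dumps(dataclasses.asdict(self.cfg))
        np.savez(path, __config__=np.array(meta), **self.state_dict())

    def __repr__(self) -> str:  # pragma: no cover
        c = self.cfg
        return (
            f"SequenceVAE(L={c.L}, A={c.A}, latent={c.latent_dim}, "
            f"enc={c.encoder_filters}, dec={c.decoder_filters})"
        )


def build_model(cfg: ModelConfig, seed: int = 0) -> SequenceVAE:
    """Seed-reproducible Kaiming-normal initialized model."""
    return SequenceVAE(cfg, seed=seed)


def load_model(path: str | Path) -> SequenceVAE:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__config__"]))
        meta["encoder_filters"] = tuple(meta["encoder_filters"])
        meta["decoder_filters"] = tuple(meta["decoder_filters"])
        cfg = ModelConfig(**meta)
        model = SequenceVAE(cfg, seed=0)
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model


def _softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=-1, keepdims=True)


def _logsumexp(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    return m + np.log(np.exp(logits - m).sum(axis=-1, keepdims=True))


def train(
    model: SequenceVAE,
    data: np.ndarray,
    train_idx: Sequence[int],
    test_idx: Sequence[int],
    weights: np.ndarray,
    tcfg: TrainConfig,
) -> tuple[SequenceVAE, pd.DataFrame]:
    """Train in place; returns the model and a per-epoch history table.

    ``data`` is the full (N, L, A) one-hot stack; ``train_idx``/``test_idx``
    index into it and ``weights`` aligns with ``train_idx``. Batches are drawn
    with replacement, weighted; the KL weight beta rises linearly from 0 to 1
    across epochs (or stays at 1 if annealing is disabled). Test loss is
    recorded both at the annealed beta and at beta = 1.
    """
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError("train and test splits must be non-empty")
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != train_idx.shape[0]:
        raise ValueError("weights must align with train_idx")

    steps = max(1, math.ceil(train_idx.size / tcfg.batch_size))
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)
    eps_rng = np.random.default_rng(tcfg.seed + 1)
    batch_stream = weighted_batches(
        train_idx, weights, tcfg.batch_size, seed=tcfg.seed + 2
    )

    history: list[dict] = []
    best_test = np.inf
    stale = 0
    for epoch in range(tcfg.epochs):
        beta = kl_anneal(epoch, tcfg.epochs) if tcfg.anneal else 1.0
        recon_acc = kl_acc = 0.0
        for _ in range(steps):
            batch = train_idx[next(batch_stream)]
            opt.zero_grad()
            loss = model.train_step(data[batch], beta, eps_rng)
            if not (np.isfinite(loss.reconstruction) and np.isfinite(loss.kl)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} "
                    f"(recon={loss.reconstruction}, kl={loss.kl})"
                )
            opt.step()
            recon_acc += loss.reconstruction
            kl_acc += loss.kl
        test_loss = model.evaluate(data[test_idx])
        row = {
            "epoch": epoch,
            "beta": beta,
            "train_reconstruction": recon_acc / steps,
            "train_kl": kl_acc / steps,
            "train_total": recon_acc / steps + beta * kl_acc / steps,
            "test_reconstruction": test_loss.reconstruction,
            "test_kl": test_loss.kl,
            "test_total_annealed": test_loss.reconstruction + beta * test_loss.kl,
            "test_total": test_loss.total,  # beta = 1
        }
        history.append(row)
        if tcfg.patience is not None:
            if row["test_total"] < best_test - 1e-6:
                best_test = row["test_total"]
                stale = 0
            else:
                stale += 1
                if stale > tcfg.patience:
                    break
    return model, pd.DataFrame(history)
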