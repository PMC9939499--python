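"""Sliced-Wasserstein autoencoder for 3D ultrasound patches.

The encoder ``q(z|X)`` maps a normalised 24x24x24 patch to a latent vector
``z`` of configurable dimension ``k``; the decoder ``p(X_hat|z)`` maps it
back. Training minimises

    loss = alpha * MSE(X, X_hat) + beta * SW(p_z, p_gamma)

where ``SW`` is the sliced-Wasserstein distance between the empirical latent
batch distribution ``p_z`` and a ball-shaped prior ``p_gamma`` (uniform on a
k-ball), estimated by projecting both samples onto random 1D directions and
matching order statistics. Compared with a KL-regularised VAE this keeps the
encoder deterministic and the regulariser a simple sort-based statistic.

Encoder layout: four 3x3x3 convolutions with two interleaved 2x average
poolings (24^3 -> 12^3 -> 6^3) followed by three fully connected layers down
to ``k``. The decoder mirrors it: two fully connected layers up to a 6^3
feature block, then two 2x upsamplings interleaved with four convolutions
back to one channel. Channel widths are configurable; the defaults are sized
for single-CPU training.

Three training regimes are supported: subject-individual models, generalized
models trained on the pooled patches of all *other* subjects, and generalized
models fine-tuned on a small subject-specific patch set where only the fully
connected layers are updated.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from . import _nn
from .patches import PATCH_SIZE, Patch

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "AutoencoderModel",
    "sample_ball_prior",
    "sliced_wasserstein",
    "loss",
    "train",
    "finetune",
    "build_regime_models",
]

LATENT_SIZES = (8, 16, 32, 64, 128, 256, 512)
REGIMES = ("individual", "generalized", "generalized_finetuned")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Channel widths of the convolutional trunk and the dense head.

    ``half_resolution=True`` moves the first pooling in front of the first
    convolution and the last upsampling behind the last convolution, so no
    convolution runs at the full 24^3 grid. That trades away voxel-scale
    reconstruction detail for a roughly four-fold faster training step; it
    is meant for capacity/trend studies where the absolute reconstruction
    ceiling is not the object of interest.
    """

    conv_channels: tuple[int, int, int, int] = (4, 8, 8, 16)
    fc_hidden: tuple[int, int] = (256, 128)
    half_resolution: bool = False

    @property
    def bottleneck_spatial(self) -> int:
        return PATCH_SIZE // 4  # two 2x poolings

    @property
    def flat_features(self) -> int:
        return self.conv_channels[-1] * self.bottleneck_spatial**3


@dataclass
class TrainingConfig:
    """Optimisation settings; defaults follow common SWAE practice.

    ``alpha``/``beta`` weight reconstruction against the latent-prior match;
    ``prior_radius`` is the radius of the uniform-ball target distribution;
    ``n_projections`` controls the variance of the SW estimate (it halves per
    doubling). Early stopping monitors the total loss on an internal
    ``val_split`` fraction and restores the best weights.
    """

    alpha: float = 1.0
    beta: float = 1.0
    n_projections: int = 50
    prior_radius: float = 1.0
    batch_size: int = 32
    val_split: float = 0.05
    patience: int = 10
    max_epochs: int = 50
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0 or (self.alpha == 0 and self.beta == 0):
            raise ValueError("alpha, beta must be >= 0 and not both zero")
        if not 0 < self.val_split < 1:
            raise ValueError("val_split must be in (0, 1)")
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.batch_size < 1 or self.max_epochs < 0 or self.patience < 0:
            raise ValueError("batch_size >= 1, max_epochs >= 0, patience >= 0 required")


def sample_ball_prior(n: int, k: int, radius: float, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample inside the k-ball: Gaussian direction times U^(1/k) radius."""
    g = rng.standard_normal((n, k))
    g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-12)
    r = radius * rng.random(n) ** (1.0 / k)
    return (g * r[:, None]).astype(np.float32)


def _sw_core(z: np.ndarray, prior: np.ndarray, n_projections: int,
             rng: np.random.Generator, with_grad: bool) -> tuple[float, np.ndarray | None]:
    m, k = z.shape
    theta = rng.standard_normal((n_projections, k))
    theta /= np.maximum(np.linalg.norm(theta, axis=1, keepdims=True), 1e-12)
    theta = theta.astype(z.dtype)
    u = z @ theta.T          # (m, L)
    v = prior @ theta.T
    order_u = np.argsort(u, axis=0, kind="stable")
    su = np.take_along_axis(u, order_u, axis=0)
    sv = np.sort(v, axis=0)
    diff = su - sv
    sw = float(np.mean(diff**2))
    if not with_grad:
        return sw, None
    g_sorted = (2.0 / diff.size) * diff
    du = np.empty_like(u)
    np.put_along_axis(du, order_u, g_sorted, axis=0)
    return sw, du @ theta


def sliced_wasserstein(batch_z: np.ndarray, prior_samples: np.ndarray,
                       n_projections: int = 50, seed: int = 0) -> float:
    """Squared sliced 2-Wasserstein distance between two equal-size samples.

    Averages, over ``n_projections`` random unit directions, the squared 1D
    2-Wasserstein distance between the projected samples (sorted matching of
    order statistics). Zero exactly when the two sets coincide.
    """
    z = np.atleast_2d(np.asarray(batch_z, dtype=np.float64))
    p = np.atleast_2d(np.asarray(prior_samples, dtype=np.float64))
    if z.shape != p.shape:
        raise ValueError(f"sample sets must match in size and dimension: {z.shape} vs {p.shape}")
    sw, _ = _sw_core(z, p, n_projections, np.random.default_rng(seed), with_grad=False)
    return sw


class AutoencoderModel:
    """Encoder/decoder pair with latent size ``k`` and training provenance."""

    def __init__(self, k: int, arch: ArchitectureConfig | None = None,
                 seed: int = 0, regime: str = "untrained"):
        if k < 1:
            raise ValueError("latent size k must be >= 1")
        self.k = int(k)
        self.arch = arch or ArchitectureConfig()
        self.regime = regime
        self.training_meta: dict = {}
        # Intensity standardisation fitted on the training patches: the
        # network sees (x - mean) / scale. Normalised ultrasound patches have
        # local std orders of magnitude below their DC level; without this the
        # optimiser spends its budget on the (NCC-invisible) mean intensity
        # and the MSE term is dwarfed by the sliced-Wasserstein term.
        self.input_mean: float = 0.0
        self.input_scale: float = 1.0
        rng = np.random.default_rng(seed)
        c1, c2, c3, c4 = self.arch.conv_channels
        h1, h2 = self.arch.fc_hidden
        flat = self.arch.flat_features
        s = self.arch.bottleneck_spatial
        L = _nn
        if self.arch.half_resolution:
            self.encoder = L.Sequential([
                L.AvgPool3d(),
                L.Conv3d(1, c1, rng), L.LeakyReLU(),
                L.Conv3d(c1, c2, rng), L.LeakyReLU(),
                L.AvgPool3d(),
                L.Conv3d(c2, c3, rng), L.LeakyReLU(),
                L.Conv3d(c3, c4, rng), L.LeakyReLU(),
                L.Flatten(),
                L.Dense(flat, h1, rng), L.LeakyReLU(),
                L.Dense(h1, h2, rng), L.LeakyReLU(),
                L.Dense(h2, self.k, rng, activation_gain=1.0),
            ])
            self.decoder = L.Sequential([
                L.Dense(self.k, h2, rng), L.LeakyReLU(),
                L.Dense(h2, flat, rng), L.LeakyReLU(),
                L.Reshape((s, s, s, c4)),
                L.Conv3d(c4, c3, rng), L.LeakyReLU(),
                L.Conv3d(c3, c2, rng), L.LeakyReLU(),
                L.Upsample3d(),
                L.Conv3d(c2, c1, rng), L.LeakyReLU(),
                L.Conv3d(c1, 1, rng, activation_gain=1.0),
                L.Upsample3d(),
            ])
        else:
            self.encoder = L.Sequential([
                L.Conv3d(1, c1, rng), L.LeakyReLU(),
                L.AvgPool3d(),
                L.Conv3d(c1, c2, rng), L.LeakyReLU(),
                L.Conv3d(c2, c3, rng), L.LeakyReLU(),
                L.AvgPool3d(),
                L.Conv3d(c3, c4, rng), L.LeakyReLU(),
                L.Flatten(),
                L.Dense(flat, h1, rng), L.LeakyReLU(),
                L.Dense(h1, h2, rng), L.LeakyReLU(),
                L.Dense(h2, self.k, rng, activation_gain=1.0),
            ])
            # Upsamplings sit late in the decoder so only the output
            # convolution runs at full 24^3 resolution — the dominant CPU cost.
            self.decoder = L.Sequential([
                L.Dense(self.k, h2, rng), L.LeakyReLU(),
                L.Dense(h2, flat, rng), L.LeakyReLU(),
                L.Reshape((s, s, s, c4)),
                L.Conv3d(c4, c3, rng), L.LeakyReLU(),
                L.Upsample3d(),
                L.Conv3d(c3, c2, rng), L.LeakyReLU(),
                L.Conv3d(c2, c1, rng), L.LeakyReLU(),
                L.Upsample3d(),
                L.Conv3d(c1, 1, rng, activation_gain=1.0),
            ])

    # -- inference ---------------------------------------------------------
    @staticmethod
    def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x, dtype=np.float32)
        single = x.ndim == 3
        if single:
            x = x[None]
        if x.ndim != 4 or x.shape[1:] != (PATCH_SIZE,) * 3:
            raise ValueError(f"expected (n, 24, 24, 24) or (24, 24, 24), got {x.shape}")
        return x[..., None], single

    #: inference chunk size — bounds the convolution scratch buffers, whose
    #: size scales linearly with the batch dimension
    CHUNK = 32

    def encode(self, patch) -> np.ndarray:
        """Map one patch (24^3) or a batch (n, 24^3) to latent vector(s)."""
        data = patch.data if isinstance(patch, Patch) else patch
        xb, single = self._as_batch(data)
        xb = (xb - self.input_mean) / self.input_scale
        z = np.concatenate([self.encoder.forward(xb[i:i + self.CHUNK])
                            for i in range(0, len(xb), self.CHUNK)])
        return z[0] if single else z

    def decode(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=np.float32)
        single = z.ndim == 1
        if single:
            z = z[None]
        if z.shape[1] != self.k:
            raise ValueError(f"latent dimension {z.shape[1]} does not match model k={self.k}")
        x = np.concatenate([self.decoder.forward(z[i:i + self.CHUNK])[..., 0]
                            for i in range(0, len(z), self.CHUNK)])
        x = x * self.input_scale + self.input_mean
        return x[0] if single else x

    def reconstruct(self, patch) -> np.ndarray:
        return self.decode(self.encode(patch))

    # -- bookkeeping -------------------------------------------------------
    def conv_layers(self) -> list[_nn.Conv3d]:
        return [l for net in (self.encoder, self.decoder)
                for l in net.layers if isinstance(l, _nn.Conv3d)]

    def fc_layers(self) -> list[_nn.Dense]:
        return [l for net in (self.encoder, self.decoder)
                for l in net.layers if isinstance(l, _nn.Dense)]

    def freeze_convolutions(self) -> None:
        for l in self.conv_layers():
            l.trainable = False

    def copy(self) -> "AutoencoderModel":
        return copy.deepcopy(self)

    @property
    def is_trained(self) -> bool:
        return bool(self.training_meta)

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: one .npz of weights + JSON manifest (the compatibility contract)."""
        enc, dec = self.encoder.state(), self.decoder.state()
        arrays = {f"enc_{i}": a for i, a in enumerate(enc)}
        arrays.update({f"dec_{i}": a for i, a in enumerate(dec)})
        np.savez(path, **arrays)
        manifest = {
            "k": self.k,
            "regime": self.regime,
            "arch": asdict(self.arch),
            "training_meta": self.training_meta,
            "input_mean": self.input_mean,
            "input_scale": self.input_scale,
            "n_encoder_arrays": len(enc),
            "n_decoder_arrays": len(dec),
        }
        with open(_manifest_path(path), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, path) -> "AutoencoderModel":
        with open(_manifest_path(path)) as fh:
            man = json.load(fh)
        arch = ArchitectureConfig(
            conv_channels=tuple(man["arch"]["conv_channels"]),
            fc_hidden=tuple(man["arch"]["fc_hidden"]),
            half_resolution=bool(man["arch"].get("half_resolution", False)),
        )
        model = cls(k=man["k"], arch=arch, regime=man["regime"])
        model.training_meta = man["training_meta"]
        model.input_mean = float(man.get("input_mean", 0.0))
        model.input_scale = float(man.get("input_scale", 1.0))
        with np.load(path) as arc:
            model.encoder.load_state([arc[f"enc_{i}"] for i in range(man["n_encoder_arrays"])])
            model.decoder.load_state([arc[f"dec_{i}"] for i in range(man["n_decoder_arrays"])])
        return model


def _manifest_path(path) -> str:
    p = str(path)
    return (p[:-4] if p.endswith(".npz") else p) + ".json"


def _stack(patches: list[Patch]) -> np.ndarray:
    return np.stack([p.data for p in patches])[..., None].astype(np.float32)


def loss(model: AutoencoderModel, batch: list[Patch], config: TrainingConfig,
         seed: int = 0) -> tuple[float, float, float]:
    """Evaluate the training objective on a batch: (total, mse, sw)."""
    if len(batch) == 0:
        raise ValueError("empty batch")
    rng = np.random.default_rng(seed)
    data = np.stack([p.data for p in batch])
    z = model.encode(data)
    xhat = model.decode(z)
    # MSE on the model's standardised working scale, mirroring training.
    mse = float(np.mean(((xhat - data) / model.input_scale) ** 2))
    if config.beta > 0:
        prior = sample_ball_prior(len(batch), model.k, config.prior_radius, rng)
        sw, _ = _sw_core(z, prior, config.n_projections, rng, with_grad=False)
    else:
        sw = 0.0
    return config.alpha * mse + config.beta * sw, mse, sw


def _train_step(model: AutoencoderModel, xb: np.ndarray, config: TrainingConfig,
                opt: _nn.Adam, rng: np.random.Generator) -> tuple[float, float]:
    z = model.encoder.forward(xb)
    xhat = model.decoder.forward(z)
    diff = xhat - xb
    mse = float(np.mean(diff**2))
    dxhat = (config.alpha * 2.0 / diff.size) * diff
    dz = model.decoder.backward(dxhat)
    if config.beta > 0:
        prior = sample_ball_prior(len(xb), model.k, config.prior_radius, rng)
        sw, dz_sw = _sw_core(z, prior, config.n_projections, rng, with_grad=True)
        dz = dz + config.beta * dz_sw.astype(np.float32)
    else:
        sw = 0.0
    model.encoder.backward(dz)
    grads = (model.encoder.grads(trainable_only=True)
             + model.decoder.grads(trainable_only=True))
    opt.step(grads)
    return mse, sw


def _eval_loss(model: AutoencoderModel, xv: np.ndarray, config: TrainingConfig,
               prior: np.ndarray | None, proj_seed: int) -> float:
    zs, sq = [], 0.0
    for i in range(0, len(xv), model.CHUNK):
        zc = model.encoder.forward(xv[i:i + model.CHUNK])
        xc = model.decoder.forward(zc)
        sq += float(((xc - xv[i:i + model.CHUNK]) ** 2).sum())
        zs.append(zc)
    z = np.concatenate(zs)
    mse = sq / xv.size
    sw = 0.0
    if config.beta > 0 and prior is not None:
        sw, _ = _sw_core(z, prior, config.n_projections,
                         np.random.default_rng(proj_seed), with_grad=False)
    return config.alpha * mse + config.beta * sw


def _fit(model: AutoencoderModel, x: np.ndarray, config: TrainingConfig,
         fit_scaler: bool = True) -> AutoencoderModel:
    """Shared optimisation loop for train() and finetune()."""
    config.validate()
    n = len(x)
    rng = np.random.default_rng(config.seed)
    if fit_scaler:
        model.input_mean = float(x.mean())
        model.input_scale = float(max(x.std(), 1e-6))
    x = (x - model.input_mean) / model.input_scale
    if n >= 2:
        n_val = min(max(1, int(round(n * config.val_split))), n - 1)
    else:
        n_val = 0
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xv = x[val_idx] if n_val else x
    xt = x[train_idx]

    # Fixed validation prior and projections so epochs are comparable.
    eval_prior = (sample_ball_prior(len(xv), model.k, config.prior_radius, rng)
                  if config.beta > 0 else None)
    eval_proj_seed = int(rng.integers(2**31))

    params = (model.encoder.params(trainable_only=True)
              + model.decoder.params(trainable_only=True))
    opt = _nn.Adam(params, lr=config.learning_rate)

    best_val = _eval_loss(model, xv, config, eval_prior, eval_proj_seed)
    best_state = model.encoder.state() + model.decoder.state()
    best_epoch = 0
    since_best = 0
    epochs_run = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(xt))
        for lo in range(0, len(xt), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            _train_step(model, xt[idx], config, opt, rng)
        epochs_run = epoch
        val = _eval_loss(model, xv, config, eval_prior, eval_proj_seed)
        if val < best_val - 1e-12:
            best_val, best_epoch, since_best = val, epoch, 0
            best_state = model.encoder.state() + model.decoder.state()
        else:
            since_best += 1
            if since_best > config.patience:
                break
    n_enc = len(model.encoder.params())
    model.encoder.load_state(best_state[:n_enc])
    model.decoder.load_state(best_state[n_enc:])
    model.training_meta = {
        "seed": config.seed,
        "epochs_run": epochs_run,
        "best_epoch": best_epoch,
        "best_val_loss": best_val,
        "n_patches": n,
    }
    return model


def train(patches: list[Patch], k: int, config: TrainingConfig,
          arch: ArchitectureConfig | None = None) -> AutoencoderModel:
    """Train a fresh autoencoder with Adam, early stopping and best-weight restore."""
    if len(patches) < 2:
        raise ValueError("training needs at least 2 patches")
    model = AutoencoderModel(k=k, arch=arch, seed=config.seed, regime="individual")
    return _fit(model, _stack(patches), config)


def finetune(model: AutoencoderModel, patches: list[Patch],
             config: TrainingConfig, max_patches: int = 5000) -> AutoencoderModel:
    """Adapt a trained model to a new subject by updating only the FC layers.

    Convolutional weights are frozen (bit-identical before and after); at most
    ``max_patches`` randomly selected patches are used. The input model is not
    modified; a copy is returned.
    """
    if not model.is_trained:
        raise ValueError("finetune requires a trained model")
    if len(patches) < 2:
        raise ValueError("finetune needs at least 2 patches")
    out = model.copy()
    if config.max_epochs == 0:
        return out
    rng = np.random.default_rng(config.seed)
    if len(patches) > max_patches:
        keep = rng.choice(len(patches), size=max_patches, replace=False)
        patches = [patches[i] for i in keep]
    out.freeze_convolutions()
    # The frozen convolutional features assume the base model's intensity
    # standardisation, so it is kept rather than refitted.
    out = _fit(out, _stack(patches), config, fit_scaler=False)
    out.regime = "generalized_finetuned"
    return out


def build_regime_models(subjects: list[list[Patch]], k: int, config: TrainingConfig,
                        arch: ArchitectureConfig | None = None,
                        finetune_config: TrainingConfig | None = None,
                        finetune_max_patches: int = 5000) -> dict[str, list[AutoencoderModel]]:
    """Train the three model families over a leave-one-subject-out design.

    For each subject ``i``: an individual model on its own patches, a
    generalized model on the pooled patches of every *other* subject, and a
    fine-tuned copy of the generalized model adapted on (at most
    ``finetune_max_patches``) of subject ``i``'s patches.
    """
    if len(subjects) < 2:
        raise ValueError("the generalized regime needs at least 2 subjects")
    ft_cfg = finetune_config or config
    out: dict[str, list[AutoencoderModel]] = {r: [] for r in REGIMES}
    for i, own in enumerate(subjects):
        cfg_i = replace(config, seed=config.seed + 101 * i)
        indiv = train(own, k, cfg_i, arch)
        indiv.regime = "individual"
        pooled = [p for j, s in enumerate(subjects) if j != i for p in s]
        gen = train(pooled, k, replace(cfg_i, seed=cfg_i.seed + 1), arch)
        gen.regime = "generalized"
        gen_ft = finetune(gen, own, replace(ft_cfg, seed=cfg_i.seed + 2),
                          max_patches=finetune_max_patches)
        out["individual"].append(indiv)
        out["generalized"].append(gen)
        out["generalized_finetuned"].append(gen_ft)
    return out
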