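"""Adversarial autoencoder with progressive growing.

The model is a standard AAE — encoder q(z|x), decoder p(x|z) and a
latent discriminator that pushes the aggregated posterior q(z) toward
the prior p(z) = N(0, I_k) — with three stabilisers:

* progressive growing: training starts at a low resolution (7x7 by
  default) and doubles it stage by stage, adding one conv block to the
  encoder and decoder per stage and widening the discriminator's dense
  layers (500 -> 3000 neurons across the full schedule), transferring
  the shared weights at each growth step;
* denoising: reconstruction inputs are corrupted with Gaussian pixel
  noise (sigma = 0.1), and the same noise level is injected into the
  discriminator's latent inputs;
* mini-batch discrimination (B kernels, C dimensions) on the
  discriminator's penultimate features to resist mode collapse.

Each training epoch alternates a Reconstruction phase (pixel MSE on
corrupted inputs) and a Regularization phase (discriminator update on
prior samples vs. encoded codes, then an encoder fooling step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .synthetic import LabeledImageSet

__all__ = [
    "AAEConfig", "AdversarialAutoencoder", "encode", "decode",
    "discriminate", "corrupt", "minibatch_similarity", "train_progressive",
    "reconstruction_rmse",
]


@dataclass
class AAEConfig:
    """Hyperparameters of the progressive AAE.

    Defaults follow the full-scale setup (k=256 latent features, six
    stages 7->224, discriminator width 500->3000, sigma=0.1, B=16, C=5);
    desk-scale runs pass smaller values.
    """

    latent_dim: int = 256
    stage_resolutions: tuple[int, ...] = (7, 14, 28, 56, 112, 224)
    disc_widths: tuple[int, ...] | None = None   # default: linspace 500->3000
    noise_sigma: float = 0.1
    mb_kernels: int = 16     # B; 0 disables mini-batch discrimination
    mb_dims: int = 5         # C
    epochs_per_stage: int | tuple[int, ...] = 8
    batch_size: int = 32
    lr_recon: float = 1e-3
    lr_adv: float = 2e-4
    lr_moment: float = 2e-3   # moment-matching step; 0 disables
    base_channels: int = 32

    def resolved_disc_widths(self) -> tuple[int, ...]:
        if self.disc_widths is not None:
            return tuple(self.disc_widths)
        n = len(self.stage_resolutions)
        if n == 1:
            return (500,)
        return tuple(int(round(w)) for w in np.linspace(500, 3000, n))

    def resolved_epochs(self) -> tuple[int, ...]:
        if isinstance(self.epochs_per_stage, int):
            return (self.epochs_per_stage,) * len(self.stage_resolutions)
        return tuple(self.epochs_per_stage)

    def validate(self) -> None:
        res = self.stage_resolutions
        if not res:
            raise ValueError("stage_resolutions must be nonempty")
        for a, b in zip(res, res[1:]):
            if b != 2 * a:
                raise ValueError(
                    f"stage resolutions must strictly double: {a} -> {b}")
        if len(self.resolved_disc_widths()) != len(res):
            raise ValueError("disc_widths length must match stages")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.mb_kernels < 0 or self.mb_dims < 1:
            raise ValueError("mb_kernels must be >= 0 and mb_dims >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if len(self.resolved_epochs()) != len(res):
            raise ValueError("epochs_per_stage length must match stages")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "AAEConfig":
        d = json.loads(s)
        for key in ("stage_resolutions", "disc_widths", "epochs_per_stage"):
            if isinstance(d.get(key), list):
                d[key] = tuple(d[key])
        return cls(**d)


def corrupt(x: np.ndarray, sigma: float,
            seed: int | np.random.Generator) -> np.ndarray:
    """Additive Gaussian pixel noise, clipped back into [0, 1]."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return np.array(x, copy=True)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return np.clip(x + rng.normal(0.0, sigma, size=np.shape(x)), 0.0, 1.0)


def minibatch_similarity(F: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Mini-batch similarity features o(x_i)_b = sum_j exp(-||M_ib - M_jb||_1).

    F is the (m, f) feature batch; T maps features to a (B, C) space,
    M_i = F_i . T.  Returns the (m, B) block that gets concatenated to F.
    """
    F = np.asarray(F, dtype=float)
    T = np.asarray(T, dtype=float)
    if T.ndim != 3 or F.ndim != 2 or F.shape[1] != T.shape[0]:
        raise ValueError(
            f"T must be (feature_dim, B, C) matching F: {F.shape} vs {T.shape}")
    f, B, C = T.shape
    M = (F @ T.reshape(f, B * C)).reshape(-1, B, C)
    D = np.abs(M[:, None] - M[None, :]).sum(axis=-1)   # (m, m, B)
    return np.exp(-D).sum(axis=1)


def _channels(base: int, n_levels: int) -> list[int]:
    # widest at the lowest resolution, halving as resolution doubles
    return [max(base // (2 ** i), 4) for i in range(n_levels)]


class AdversarialAutoencoder(BaseEstimator, TransformerMixin):
    """Progressive-growing adversarial autoencoder (sklearn estimator).

    ``fit(X)`` runs the full stage schedule on images X of shape
    (n, H, W, 3) in [0, 1]; ``transform`` encodes to latent vectors and
    ``inverse_transform`` decodes back to images.

    Fitted attributes: ``encoder_``, ``decoder_``, ``discriminator_``,
    ``current_stage_``, ``current_resolution_``, ``training_log_``.
    """

    def __init__(self, latent_dim: int = 256,
                 stage_resolutions: tuple[int, ...] = (7, 14, 28, 56, 112, 224),
                 disc_widths: tuple[int, ...] | None = None,
                 noise_sigma: float = 0.1, mb_kernels: int = 16,
                 mb_dims: int = 5,
                 epochs_per_stage: int | tuple[int, ...] = 8,
                 batch_size: int = 32, lr_recon: float = 1e-3,
                 lr_adv: float = 2e-4, lr_moment: float = 2e-3,
                 base_channels: int = 32,
                 random_state: int = 0):
        self.latent_dim = latent_dim
        self.stage_resolutions = stage_resolutions
        self.disc_widths = disc_widths
        self.noise_sigma = noise_sigma
        self.mb_kernels = mb_kernels
        self.mb_dims = mb_dims
        self.epochs_per_stage = epochs_per_stage
        self.batch_size = batch_size
        self.lr_recon = lr_recon
        self.lr_adv = lr_adv
        self.lr_moment = lr_moment
        self.base_channels = base_channels
        self.random_state = random_state

    # -- construction -----------------------------------------------------

    def _config(self) -> AAEConfig:
        return AAEConfig(
            latent_dim=self.latent_dim,
            stage_resolutions=tuple(self.stage_resolutions),
            disc_widths=(None if self.disc_widths is None
                         else tuple(self.disc_widths)),
            noise_sigma=self.noise_sigma, mb_kernels=self.mb_kernels,
            mb_dims=self.mb_dims, epochs_per_stage=self.epochs_per_stage,
            batch_size=self.batch_size, lr_recon=self.lr_recon,
            lr_adv=self.lr_adv, lr_moment=self.lr_moment,
            base_channels=self.base_channels)

    def _init_stage0(self, rng: np.random.Generator) -> None:
        cfg = self._config()
        cfg.validate()
        k = cfg.latent_dim
        r0 = cfg.stage_resolutions[0]
        ch = _channels(cfg.base_channels, len(cfg.stage_resolutions))
        c0 = ch[0]
        self._ch = ch
        self._r0 = r0
        enc = [nn.Conv2d(3, c0, rng), nn.ReLU(),               # fromRGB
               nn.Conv2d(c0, c0, rng), nn.BatchNorm2d(c0), nn.ReLU(),
               nn.Flatten(), nn.Dense(r0 * r0 * c0, k, rng)]
        dec = [nn.Dense(k, r0 * r0 * c0, rng), nn.Reshape((c0, r0, r0)),
               nn.Conv2d(c0, c0, rng), nn.BatchNorm2d(c0), nn.ReLU(),
               nn.Conv2d(c0, 3, rng), nn.Sigmoid()]            # toRGB
        self.encoder_ = nn.Sequential(enc)
        self.decoder_ = nn.Sequential(dec)
        self._build_discriminator(cfg.resolved_disc_widths()[0], rng)
        self.current_stage_ = 0
        self.current_resolution_ = r0
        self.training_log_: list[dict] = []

    def _build_discriminator(self, width: int,
                             rng: np.random.Generator) -> None:
        cfg = self._config()
        self._disc_width = width
        self.discriminator_ = nn.Sequential([
            nn.Dense(cfg.latent_dim, width, rng), nn.LeakyReLU(),
            nn.Dense(width, width, rng), nn.LeakyReLU(),
            nn.MinibatchDiscrimination(width, cfg.mb_kernels, cfg.mb_dims,
                                       rng),
            nn.Dense(width + cfg.mb_kernels, 1, rng),
        ])

    def grow(self, rng: np.random.Generator) -> None:
        """Advance one stage: add conv blocks, widen the discriminator.

        Trunk (shared-architecture) weights are transferred unchanged;
        the widened discriminator preserves its function at the moment
        of growth (new units' contributions start at zero).
        """
        s = self.current_stage_ + 1
        cfg = self._config()
        if s >= len(cfg.stage_resolutions):
            raise ValueError("schedule exhausted")
        ch = self._ch
        # encoder: new fromRGB + downsampling block in front of the trunk
        trunk = self.encoder_.layers[2:]
        new = [nn.Conv2d(3, ch[s], rng), nn.ReLU(),
               nn.Conv2d(ch[s], ch[s - 1], rng), nn.BatchNorm2d(ch[s - 1]),
               nn.ReLU(), nn.MaxPool2()]
        self.encoder_ = nn.Sequential(new + trunk)
        # decoder: upsampling block + new toRGB behind the trunk
        trunk = self.decoder_.layers[:-2]
        new = [nn.Upsample2(), nn.Conv2d(ch[s - 1], ch[s], rng),
               nn.BatchNorm2d(ch[s]), nn.ReLU(),
               nn.Conv2d(ch[s], 3, rng), nn.Sigmoid()]
        self.decoder_ = nn.Sequential(trunk + new)
        self._widen_discriminator(cfg.resolved_disc_widths()[s], rng)
        self.current_stage_ = s
        self.current_resolution_ = cfg.stage_resolutions[s]

    def _widen_discriminator(self, new_w: int,
                             rng: np.random.Generator) -> None:
        old = self.discriminator_.layers
        old_w = self._disc_width
        cfg = self._config()
        self._build_discriminator(new_w, rng)
        newl = self.discriminator_.layers
        # layer 0: keep incoming weights of retained units
        newl[0].params["W"][:, :old_w] = old[0].params["W"]
        newl[0].params["b"][:old_w] = old[0].params["b"]
        # layer 2: top-left block copied; outgoing weights of new first-
        # layer units zeroed so the pre-growth function is preserved
        newl[2].params["W"][:old_w, :old_w] = old[2].params["W"]
        newl[2].params["W"][old_w:, :old_w] = 0.0
        newl[2].params["b"][:old_w] = old[2].params["b"]
        # mini-batch tensor: retained feature rows copied, new rows zero
        if cfg.mb_kernels > 0:
            newl[4].params["T"][:old_w] = old[4].params["T"]
            newl[4].params["T"][old_w:] = 0.0
        # output layer: retained rows copied, rows of new units zeroed
        B = cfg.mb_kernels
        newl[5].params["W"][:old_w] = old[5].params["W"][:old_w]
        newl[5].params["W"][old_w:new_w] = 0.0
        if B:
            newl[5].params["W"][new_w:] = old[5].params["W"][old_w:]
        newl[5].params["b"][:] = old[5].params["b"]

    # -- inference --------------------------------------------------------

    def encode(self, x: np.ndarray) -> np.ndarray:
        """Latent code(s) for one image (H,W,3) or a batch (n,H,W,3)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 3
        if single:
            x = x[None]
        res = self.current_resolution_
        if x.shape[1] != res or x.shape[2] != res or x.shape[3] != 3:
            raise ValueError(
                f"expected {res}x{res}x3 input, got {x.shape[1:]}")
        z = self.encoder_.forward(x.transpose(0, 3, 1, 2), train=False)
        return z[0] if single else z

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Image(s) for one latent vector (k,) or a batch (n, k)."""
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        if single:
            z = z[None]
        if z.shape[1] != self.latent_dim:
            raise ValueError(
                f"expected latent dim {self.latent_dim}, got {z.shape[1]}")
        x = self.decoder_.forward(z, train=False).transpose(0, 2, 3, 1)
        x = np.clip(x, 0.0, 1.0)
        return x[0] if single else x

    def discriminate(self, Z: np.ndarray) -> np.ndarray:
        """Realism scores in [0, 1] for a nonempty batch of latents."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[0] == 0:
            raise ValueError("empty batch")
        logits = self.discriminator_.forward(Z, train=False)
        return 1.0 / (1.0 + np.exp(-np.clip(logits[:, 0], -60, 60)))

    def sample_prior(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.latent_dim))

    # sklearn surface
    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.encode(np.asarray(X))

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        return self.decode(np.asarray(Z))

    # -- training ---------------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "AdversarialAutoencoder":
        cfg = self._config()
        cfg.validate()
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must be (n, H, W, 3)")
        if X.shape[1] < max(cfg.stage_resolutions):
            raise ValueError("data resolution below final stage resolution")
        rng = np.random.default_rng(self.random_state)
        self._init_stage0(rng)
        epochs = cfg.resolved_epochs()
        for s, res in enumerate(cfg.stage_resolutions):
            if s > 0:
                self.grow(rng)
            Xs = _downsample(X, res).transpose(0, 3, 1, 2)
            self._train_stage(Xs, s, epochs[s], rng)
        return self

    def _train_stage(self, Xs: np.ndarray, stage: int, epochs: int,
                     rng: np.random.Generator) -> None:
        cfg = self._config()
        n = len(Xs)
        k = cfg.latent_dim
        sigma = cfg.noise_sigma
        enc, dec, disc = self.encoder_, self.decoder_, self.discriminator_
        opt_ae = nn.Adam([enc, dec], lr=cfg.lr_recon)
        opt_d = nn.Adam([disc], lr=cfg.lr_adv)
        opt_g = nn.Adam([enc], lr=cfg.lr_adv)
        opt_mm = (nn.Adam([enc], lr=cfg.lr_moment)
                  if cfg.lr_moment > 0 else None)
        for epoch in range(epochs):
            order = rng.permutation(n)
            rloss = dloss = gloss = 0.0
            nb = 0
            for start in range(0, n, cfg.batch_size):
                xb = Xs[order[start:start + cfg.batch_size]]
                m = len(xb)
                # --- Reconstruction phase (denoising MSE) ---
                xc = np.clip(xb + rng.normal(0, sigma, xb.shape), 0, 1) \
                    if sigma > 0 else xb
                z = enc.forward(xc, train=True)
                xr = dec.forward(z, train=True)
                diff = xr - xb
                rloss += float(np.mean(diff ** 2))
                enc.zero_grad(); dec.zero_grad()
                gz = dec.backward(2.0 * diff / diff.size)
                enc.backward(gz)
                opt_ae.step()
                # --- Regularization phase: discriminator update ---
                z_fake = enc.forward(xb, train=True)
                z_real = rng.standard_normal((m, k))
                zr = z_real + rng.normal(0, sigma, z_real.shape)
                zf = z_fake + rng.normal(0, sigma, z_fake.shape)
                # far negatives: scaled prior draws teach the
                # discriminator to reject out-of-distribution codes, so
                # the downstream validation filter is meaningful there
                nf = max(1, m // 8)
                far = (rng.standard_normal((nf, k))
                       * rng.uniform(3.0, 10.0, (nf, 1)))
                zf = np.vstack([zf, far])
                disc.zero_grad()
                lr_ = disc.forward(zr, train=True)
                dloss += nn.bce_with_logits(lr_, 1.0)
                disc.backward(nn.bce_with_logits_grad(lr_, 1.0))
                lf_ = disc.forward(zf, train=True)
                dloss += nn.bce_with_logits(lf_, 0.0)
                disc.backward(nn.bce_with_logits_grad(lf_, 0.0))
                opt_d.step()
                # --- Regularization phase: encoder fooling step ---
                z2 = enc.forward(xb, train=True)
                z2n = z2 + rng.normal(0, sigma, z2.shape)
                disc.zero_grad(); enc.zero_grad()
                lg = disc.forward(z2n, train=True)
                gloss += nn.bce_with_logits(lg, 1.0)
                gz = disc.backward(nn.bce_with_logits_grad(lg, 1.0))
                enc.backward(gz)
                opt_g.step()
                # --- Regularization phase: moment matching q(z) -> p(z) ---
                if opt_mm is not None:
                    z3 = enc.forward(xb, train=True)
                    mu = z3.mean(axis=0)
                    sd = z3.std(axis=0) + 1e-8
                    gmm = (2.0 * mu / m)[None, :] \
                        + 2.0 * (sd - 1.0) * (z3 - mu) / (m * sd)
                    enc.zero_grad()
                    enc.backward(gmm)
                    opt_mm.step()
                nb += 1
            # end-of-epoch moment pass on a large sample: batch-level
            # moments are noisy (O(1/sqrt(batch)) per coordinate), so a
            # few large-batch steps tighten the match of q(z) to p(z)
            if opt_mm is not None:
                big = Xs[rng.choice(n, size=min(n, 256), replace=False)]
                for _ in range(4):
                    zb = enc.forward(big, train=True)
                    mu = zb.mean(axis=0)
                    sd = zb.std(axis=0) + 1e-8
                    gmm = (2.0 * mu / len(big))[None, :] \
                        + 2.0 * (sd - 1.0) * (zb - mu) / (len(big) * sd)
                    enc.zero_grad()
                    enc.backward(gmm)
                    opt_mm.step()
            self.training_log_.append({
                "stage": stage, "epoch": epoch,
                "recon_loss": rloss / nb, "disc_loss": dloss / nb,
                "gen_loss": gloss / nb})

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: weights + config JSON."""
        arrays: dict[str, np.ndarray] = {}
        for net_name in ("encoder_", "decoder_", "discriminator_"):
            net = getattr(self, net_name)
            for i, layer in enumerate(net.layers):
                for pname, arr in layer.params.items():
                    arrays[f"{net_name}.{i}.{pname}"] = arr
                if isinstance(layer, nn.BatchNorm2d):
                    arrays[f"{net_name}.{i}.running_mean"] = layer.running_mean
                    arrays[f"{net_name}.{i}.running_var"] = layer.running_var
        meta = json.dumps({
            "config": asdict(self._config()),
            "random_state": self.random_state,
            "current_stage": self.current_stage_,
        })
        np.savez_compressed(path, _meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AdversarialAutoencoder":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["_meta"]))
            cfg = AAEConfig.from_json(json.dumps(meta["config"]))
            model = cls(random_state=meta["random_state"],
                        **{k: v for k, v in asdict(cfg).items()})
            rng = np.random.default_rng(0)
            model._init_stage0(rng)
            for _ in range(meta["current_stage"]):
                model.grow(rng)
            for net_name in ("encoder_", "decoder_", "discriminator_"):
                net = getattr(model, net_name)
                for i, layer in enumerate(net.layers):
                    for pname in layer.params:
                        layer.params[pname][...] = f[f"{net_name}.{i}.{pname}"]
                    if isinstance(layer, nn.BatchNorm2d):
                        layer.running_mean = f[f"{net_name}.{i}.running_mean"]
                        layer.running_var = f[f"{net_name}.{i}.running_var"]
        return model


def _downsample(X: np.ndarray, res: int) -> np.ndarray:
    """Area-average images (n, H, W, 3) down to (n, res, res, 3)."""
    h = X.shape[1]
    if h == res:
        return X
    if h % res == 0:
        f = h // res
        return X.reshape(len(X), res, f, res, f, 3).mean(axis=(2, 4))
    from scipy.ndimage import zoom
    s = res / h
    return np.clip(zoom(X, (1, s, s, 1), order=1), 0.0, 1.0)


# -- thin functional wrappers over the estimator --------------------------

def encode(model: AdversarialAutoencoder, x: np.ndarray) -> np.ndarray:
    return model.encode(x)


def decode(model: AdversarialAutoencoder, z: np.ndarray) -> np.ndarray:
    return model.decode(z)


def discriminate(model: AdversarialAutoencoder, Z: np.ndarray) -> np.ndarray:
    return model.discriminate(Z)


def train_progressive(data: LabeledImageSet, config: AAEConfig,
                      seed: int) -> AdversarialAutoencoder:
    """Run the full progressive schedule on a labelled image set."""
    config.validate()
    model = AdversarialAutoencoder(random_state=seed, **asdict(config))
    return model.fit(data.images)


def reconstruction_rmse(model: AdversarialAutoencoder,
                        data: LabeledImageSet
                        ) -> tuple[float, dict[int, float]]:
    """Overall and per-class pixel RMSE of x vs decode(encode(x))."""
    if len(data) == 0:
        raise ValueError("empty data")
    recon = model.decode(model.encode(data.images))
    se = (recon - data.images) ** 2
    overall = float(np.sqrt(se.mean()))
    per_class = {int(c): float(np.sqrt(se[data.labels == c].mean()))
                 for c in np.unique(data.labels)}
    return overall, per_class
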