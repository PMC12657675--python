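"""DCGAN minority-class balancing with least-squares adversarial loss.

The generator maps a 100-d latent vector through a dense projection to a
(size/4, size/4, 128) feature map, two stride-2 transposed-convolution
upsampling blocks (128 -> 64 -> 64 filters) with leaky-rectifier
activations, and a final 1-channel convolution with tanh output, so sampled
images live in [-1, 1]. The discriminator is two stride-2 convolution
blocks followed by a dense head emitting one raw real-valued score — the
least-squares (LSGAN) objective acts on raw scores, no terminal squashing:

    d_loss = 1/2 E[(D(x) - 1)^2] + 1/2 E[D(G(z))^2]
    g_loss = 1/2 E[(D(G(z)) - 1)^2]

Quality control is logged, not gated, by default: mean SSIM of each
synthetic image against its nearest real image and against the real class
mean, plus the pixel-intensity histogram overlap between the real and
synthetic pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.metrics import structural_similarity

from . import _nn
from .synthetic_mri import ImageDataset


class InvalidConfigError(ValueError):
    pass


class ConventionError(ValueError):
    """Images are in the wrong intensity convention for the GAN."""


class InvalidInputError(ValueError):
    pass


@dataclass(frozen=True)
class GanConfig:
    latent_dim: int = 100
    image_size: int = 128
    learning_rate: float = 0.0002
    batch_size: int = 32
    epochs: int = 10
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.latent_dim < 1:
            raise InvalidConfigError("latent_dim must be >= 1")
        if self.image_size % 4 != 0:
            raise InvalidConfigError(
                "image_size must be a multiple of 4 (two 2x upsampling stages)"
            )


@dataclass
class GanBundle:
    """Generator/discriminator networks plus the per-epoch loss log."""

    config: GanConfig
    generator: _nn.Sequential
    discriminator: _nn.Sequential
    d_losses: list[float] = field(default_factory=list)
    g_losses: list[float] = field(default_factory=list)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n images in [-1, 1], shape (n, size, size)."""
        z = rng.normal(size=(n, self.config.latent_dim)).astype(_nn.DTYPE)
        out = self.generator.forward(z, train=False)
        return out[:, 0]


def build_generator(config: GanConfig, rng: np.random.Generator) -> _nn.Sequential:
    """Latent vector -> (image_size, image_size, 1) tanh image."""
    s4 = config.image_size // 4
    a = config.leaky_slope
    return _nn.Sequential(
        [
            _nn.Dense(config.latent_dim, s4 * s4 * 128, rng),
            _nn.LeakyReLU(a),
            _nn.Reshape((128, s4, s4)),
            _nn.ConvTranspose2D(128, 64, 4, rng, stride=2, pad=1),
            _nn.BatchNorm2D(64),
            _nn.LeakyReLU(a),
            _nn.ConvTranspose2D(64, 64, 4, rng, stride=2, pad=1),
            _nn.BatchNorm2D(64),
            _nn.LeakyReLU(a),
            _nn.Conv2D(64, 1, 3, rng),
            _nn.Tanh(),
        ]
    )


def build_discriminator(config: GanConfig, rng: np.random.Generator) -> _nn.Sequential:
    """(image_size, image_size, 1) -> one raw score per image."""
    s4 = config.image_size // 4
    a = config.leaky_slope
    return _nn.Sequential(
        [
            _nn.Conv2D(1, 32, 3, rng, stride=2, pad=1),
            _nn.LeakyReLU(a),
            _nn.Conv2D(32, 64, 3, rng, stride=2, pad=1),
            _nn.LeakyReLU(a),
            _nn.Flatten(),
            _nn.Dense(s4 * s4 * 64, 1, rng),
        ]
    )


def lsgan_losses(
    real_scores: np.ndarray, fake_scores: np.ndarray
) -> tuple[float, float]:
    """Least-squares adversarial losses from raw discriminator scores."""
    real_scores = np.asarray(real_scores, dtype=np.float64).ravel()
    fake_scores = np.asarray(fake_scores, dtype=np.float64).ravel()
    if real_scores.size == 0 or fake_scores.size == 0:
        raise InvalidInputError("score arrays must be nonempty")
    d_loss = 0.5 * np.mean((real_scores - 1.0) ** 2) + 0.5 * np.mean(fake_scores**2)
    g_loss = 0.5 * np.mean((fake_scores - 1.0) ** 2)
    return float(d_loss), float(g_loss)


def train_gan(
    real_images: np.ndarray, config: GanConfig, seed: int
) -> GanBundle:
    """Adversarially train generator/discriminator on one class's images.

    ``real_images``: (N, size, size) in the [-1, 1] convention (the caller
    rescales; passing [0, 1] images raises :class:`ConventionError`).
    Alternating Adam updates (beta1=0.5) per minibatch; the loss log gains
    one (mean d_loss, mean g_loss) entry per epoch.
    """
    real_images = np.asarray(real_images, dtype=np.float64)
    if real_images.ndim != 3 or real_images.shape[1] != config.image_size:
        raise InvalidConfigError(
            f"expected (N, {config.image_size}, {config.image_size}) images"
        )
    if real_images.min() >= 0.0:
        raise ConventionError(
            "images appear to be in the [0, 1] convention; rescale with x -> 2x - 1"
        )
    if len(real_images) < config.batch_size:
        raise InvalidInputError(
            f"need at least batch_size={config.batch_size} images, got {len(real_images)}"
        )

    rng = np.random.default_rng(seed)
    gen = build_generator(config, rng)
    disc = build_discriminator(config, rng)
    bundle = GanBundle(config, gen, disc)
    g_opt = _nn.Adam(gen.params, gen.grads, lr=config.learning_rate, beta1=0.5)
    d_opt = _nn.Adam(disc.params, disc.grads, lr=config.learning_rate, beta1=0.5)

    n = len(real_images)
    bs = config.batch_size
    real_images = real_images.astype(_nn.DTYPE)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        d_ep, g_ep = [], []
        for start in range(0, n - bs + 1, bs):
            real = real_images[order[start : start + bs]][:, None]
            z = rng.normal(size=(bs, config.latent_dim)).astype(_nn.DTYPE)
            fake = gen.forward(z, train=True)

            # --- discriminator step ---
            rs = disc.forward(real, train=True).ravel()
            grad_r = (rs - 1.0)[:, None] / bs  # d/ds of 1/2 mean((s-1)^2)
            disc.backward(grad_r.reshape(-1, 1).astype(_nn.DTYPE))
            gr = [g.copy() for g in disc.grads]
            fs = disc.forward(fake, train=True).ravel()
            grad_f = fs[:, None] / bs
            disc.backward(grad_f.reshape(-1, 1).astype(_nn.DTYPE))
            for g, extra in zip(disc.grads, gr):
                g += extra
            d_opt.step()
            d_loss, _ = lsgan_losses(rs, fs)
            d_ep.append(d_loss)

            # --- generator step (reuses the cached generator activations:
            # the generator was not updated during the discriminator step) ---
            fs2 = disc.forward(fake, train=True).ravel()
            grad_g = (fs2 - 1.0)[:, None] / bs
            dimg = disc.backward(grad_g.reshape(-1, 1).astype(_nn.DTYPE))
            gen.backward(dimg)
            g_opt.step()
            g_ep.append(lsgan_losses(rs, fs2)[1])
        bundle.d_losses.append(float(np.mean(d_ep)))
        bundle.g_losses.append(float(np.mean(g_ep)))
    return bundle


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Structural similarity with a Gaussian 11x11 window, K1=0.01, K2=0.03."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def ssim_stats(
    real_images: np.ndarray, synth_images: np.ndarray, data_range: float = 2.0
) -> dict:
    """Mean SSIM of each synthetic image vs its nearest real image and vs the
    real class mean image (both logged; the reference for a single headline
    number is the nearest-real mean)."""
    real = np.asarray(real_images, dtype=np.float64)
    synth = np.asarray(synth_images, dtype=np.float64)
    mean_img = real.mean(axis=0)
    nearest, vs_mean = [], []
    for img in synth:
        d = np.abs(real - img).sum(axis=(1, 2))
        nearest.append(ssim(img, real[int(np.argmin(d))], data_range))
        vs_mean.append(ssim(img, mean_img, data_range))
    return {
        "mean_ssim_nearest_real": float(np.mean(nearest)),
        "mean_ssim_vs_class_mean": float(np.mean(vs_mean)),
    }


def balance_class(
    dataset: ImageDataset,
    class_id: int,
    n_synthetic: int,
    bundle: GanBundle,
    seed: int,
    min_ssim: float | None = None,
) -> ImageDataset:
    """Append ``n_synthetic`` GAN samples with label ``class_id``.

    Samples come out of the generator in [-1, 1] and are rescaled to the
    dataset's convention; provenance is "synthetic"; originals untouched.
    With ``min_ssim`` set, samples below that SSIM against their nearest
    real class image are resampled (up to 20 rounds, then kept as-is).
    """
    if n_synthetic < 0:
        raise InvalidInputError("n_synthetic must be >= 0")
    if n_synthetic == 0:
        return dataset
    rng = np.random.default_rng(seed)
    samples = bundle.sample(n_synthetic, rng)
    if min_ssim is not None:
        real = dataset.images[dataset.labels == class_id]
        real_sym = real * 2.0 - 1.0 if dataset.convention == "unit" else real
        for _ in range(20):
            bad = [
                i
                for i, img in enumerate(samples)
                if ssim_stats(real_sym, img[None])["mean_ssim_nearest_real"] < min_ssim
            ]
            if not bad:
                break
            samples[bad] = bundle.sample(len(bad), rng)
    if dataset.convention == "unit":
        samples = (samples + 1.0) / 2.0
    extra = ImageDataset(
        samples,
        np.full(n_synthetic, class_id, dtype=np.int64),
        ["synthetic"] * n_synthetic,
        list(dataset.class_names),
        dataset.convention,
    )
    return dataset.concat(extra)


def intensity_overlap(
    real_images: np.ndarray,
    synth_images: np.ndarray,
    n_bins: int = 100,
    value_range: tuple[float, float] = (-1.0, 1.0),
) -> float:
    """Histogram-overlap coefficient sum(min(p, q)) of the two pixel pools."""
    real = np.asarray(real_images, dtype=np.float64).ravel()
    synth = np.asarray(synth_images, dtype=np.float64).ravel()
    if real.size == 0 or synth.size == 0:
        raise InvalidInputError("image pools must be nonempty")
    p, _ = np.histogram(real, bins=n_bins, range=value_range)
    q, _ = np.histogram(synth, bins=n_bins, range=value_range)
    p = p / p.sum()
    q = q / q.sum()
    return float(np.minimum(p, q).sum())


__all__ = [
    "GanConfig",
    "GanBundle",
    "InvalidConfigError",
    "ConventionError",
    "InvalidInputError",
    "build_generator",
    "build_discriminator",
    "lsgan_losses",
    "train_gan",
    "ssim",
    "ssim_stats",
    "balance_class",
    "intensity_overlap",
]
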