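"""Class-structured synthetic lesion-like images and a toy black box.

Images are a skin-tone background with one elliptical lesion whose hue,
border irregularity and internal texture carry the class signal, so a
weak classifier succeeds and the class-defining features are visible in
explanations.  Everything is deterministic under an explicit seed.
"""

from __future__ import annotations

import colorsys
import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "LesionParams", "LabeledImageSet", "generate_image", "lesion_mask",
    "class_params", "generate_dataset", "boundary_roughness",
    "ToyPixelClassifier", "BlackBoxAdapter", "train_toy_blackbox",
    "save_npz", "load_npz", "save_png_dir",
]

_N_FOURIER = 4  # radial boundary harmonics


@dataclass(frozen=True)
class LesionParams:
    """Parameters of one synthetic lesion image.

    center/radii are fractions of the image side; radii must lie in
    (0, 0.5].  ``border_noise_amp`` scales a smooth random radial
    perturbation of the ellipse boundary; ``texture_freq`` is the count
    of sinusoidal texture cycles across the lesion.
    """

    class_id: int = 0
    center: tuple[float, float] = (0.5, 0.5)
    radii: tuple[float, float] = (0.3, 0.22)
    hue: float = 0.0
    border_noise_amp: float = 0.0
    texture_freq: float = 0.0
    background_tone: float = 0.75

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if not all(0 < r <= 0.5 for r in self.radii):
            raise ValueError("radii must lie in (0, 0.5]")
        for v in (*self.center, self.hue, self.background_tone):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.border_noise_amp < 0 or self.texture_freq < 0:
            raise ValueError("border_noise_amp and texture_freq must be >= 0")


@dataclass
class LabeledImageSet:
    """Bundle of square RGB images in [0,1] with integer labels."""

    images: np.ndarray          # (n, res, res, 3) float
    labels: np.ndarray          # (n,) int
    class_names: list[str] = field(default_factory=list)
    resolution: int = 0
    # generator provenance (None when loaded from plain files)
    lesion_params: list["LesionParams"] | None = None
    image_seeds: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.resolution == 0 and len(self.images):
            self.resolution = self.images.shape[1]
        if len(self.images):
            if self.images.shape[1] != self.images.shape[2]:
                raise ValueError("images must be square")
            if self.images.min() < 0 or self.images.max() > 1:
                raise ValueError("pixels must lie in [0, 1]")

    def __len__(self):
        return len(self.images)


def _boundary_coeffs(params: LesionParams, seed: int) -> np.ndarray:
    """Random Fourier coefficients of the radial boundary perturbation."""
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, 1.0, size=(2, _N_FOURIER))


def _radial_perturbation(theta: np.ndarray, coeffs: np.ndarray,
                         amp: float) -> np.ndarray:
    if amp == 0:
        return np.zeros_like(theta)
    out = np.zeros_like(theta)
    for m in range(_N_FOURIER):
        out += (coeffs[0, m] * np.cos((m + 2) * theta)
                + coeffs[1, m] * np.sin((m + 2) * theta))
    return amp * out / np.sqrt(_N_FOURIER)


def lesion_mask(params: LesionParams, resolution: int,
                seed: int) -> np.ndarray:
    """Analytic boolean lesion mask (shared by the renderer and tests).

    A pixel (i, j) is inside the lesion when its normalised elliptical
    radius is below 1 + the Fourier boundary perturbation at its angle.
    """
    if resolution < 7:
        raise ValueError("resolution must be >= 7")
    cr = params.center[0] * resolution
    cc = params.center[1] * resolution
    rr = (np.arange(resolution) + 0.5 - cr) / (params.radii[0] * resolution)
    cc_ = (np.arange(resolution) + 0.5 - cc) / (params.radii[1] * resolution)
    u, v = np.meshgrid(rr, cc_, indexing="ij")
    rho = np.sqrt(u * u + v * v)
    theta = np.arctan2(v, u)
    coeffs = _boundary_coeffs(params, seed)
    pert = _radial_perturbation(theta, coeffs, params.border_noise_amp)
    return rho <= 1.0 + pert


def generate_image(params: LesionParams, resolution: int,
                   seed: int) -> np.ndarray:
    """Render one lesion image, (res, res, 3) float in [0,1]."""
    if resolution < 7:
        raise ValueError("resolution must be >= 7")
    rng = np.random.default_rng(seed)

    # skin-tone background: warm tint scaled by background_tone
    tone = params.background_tone
    bg = np.array([tone, tone * 0.82, tone * 0.70])
    img = np.broadcast_to(bg, (resolution, resolution, 3)).copy()

    mask = lesion_mask(params, resolution, seed)
    lesion_rgb = np.array(colorsys.hsv_to_rgb(params.hue, 0.75, 0.55))

    if params.texture_freq > 0:
        ii = np.arange(resolution) / resolution
        tex_phase = rng.uniform(0, 2 * np.pi)
        tex = 0.5 + 0.5 * np.sin(
            2 * np.pi * params.texture_freq * ii[:, None]
            + 2 * np.pi * params.texture_freq * 0.6 * ii[None, :]
            + tex_phase)
        shade = 0.75 + 0.5 * tex
    else:
        shade = np.ones((resolution, resolution))

    lesion = lesion_rgb[None, None, :] * shade[:, :, None]
    img[mask] = lesion[mask]

    img += rng.normal(0.0, 0.015, size=img.shape)  # sensor-like grain
    return np.clip(img, 0.0, 1.0)


def boundary_roughness(mask: np.ndarray) -> float:
    """Perimeter-to-area roughness proxy: boundary pixels / sqrt(area)."""
    area = int(mask.sum())
    if area == 0:
        return 0.0
    interior = mask.copy()
    interior[1:] &= mask[:-1]
    interior[:-1] &= mask[1:]
    interior[:, 1:] &= mask[:, :-1]
    interior[:, :-1] &= mask[:, 1:]
    return float((mask & ~interior).sum()) / np.sqrt(area)


# class template: hue / border irregularity / texture cycles per class.
# classes are linearly separated in (hue, border_noise_amp, texture_freq).
_CLASS_HUE = (0.0, 0.33, 0.66)
_CLASS_BORDER = (0.0, 0.1, 0.25)
_CLASS_TEXTURE = (0.0, 4.0, 8.0)


def class_params(class_id: int, rng: np.random.Generator) -> LesionParams:
    """Draw one parameter set from the class-conditional distribution."""
    i = class_id % 3
    extra = class_id // 3  # classes beyond 3 shift hue by 0.11 per wrap
    hue = (_CLASS_HUE[i] + 0.11 * extra + rng.uniform(-0.05, 0.05)) % 1.0
    return LesionParams(
        class_id=class_id,
        center=(rng.uniform(0.4, 0.6), rng.uniform(0.4, 0.6)),
        radii=(rng.uniform(0.22, 0.34), rng.uniform(0.18, 0.28)),
        hue=hue,
        border_noise_amp=_CLASS_BORDER[i] * rng.uniform(0.8, 1.2),
        texture_freq=_CLASS_TEXTURE[i] * rng.uniform(0.9, 1.1),
        background_tone=rng.uniform(0.65, 0.85),
    )


def generate_dataset(n_per_class: int, n_classes: int, resolution: int,
                     seed: int) -> LabeledImageSet:
    """Generate ``n_per_class * n_classes`` labelled lesion images."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    images, labels, plist, seeds = [], [], [], []
    for cls in range(n_classes):
        for _ in range(n_per_class):
            params = class_params(cls, rng)
            img_seed = int(rng.integers(0, 2**31 - 1))
            images.append(generate_image(params, resolution, img_seed))
            labels.append(cls)
            plist.append(params)
            seeds.append(img_seed)
    names = [f"class_{c}" for c in range(n_classes)]
    return LabeledImageSet(np.stack(images), np.array(labels), names,
                           resolution, lesion_params=plist,
                           image_seeds=np.array(seeds))


class BlackBoxAdapter:
    """Contract for any classifier plugged into the explainer.

    ``predict(images)`` takes a batch (n, H, W, 3) in [0,1] and returns
    ``(labels, probs)`` with probs rows non-negative summing to one and
    label == argmax(probs) (ties to the lowest class id).
    """

    def predict(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError


class ToyPixelClassifier(BaseEstimator, ClassifierMixin, BlackBoxAdapter):
    """Multinomial logistic regression on raw flattened pixels.

    A deliberately weak but reliable black box for desk-scale runs;
    the lesion classes are separable enough that it reaches >=0.9
    held-out accuracy.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 300,
                 random_state: int = 0):
        self.C = C
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ToyPixelClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("need at least two classes to fit")
        self.input_shape_ = X.shape[1:]
        self.model_ = LogisticRegression(
            C=self.C, max_iter=self.max_iter, random_state=self.random_state)
        self.model_.fit(X.reshape(len(X), -1), y)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        return self.model_.predict_proba(X.reshape(len(X), -1))

    def predict(self, X: np.ndarray):
        probs = self.predict_proba(X)
        labels = self.classes_[np.argmax(probs, axis=1)]
        return labels, probs

    def score(self, X, y, sample_weight=None):
        labels, _ = self.predict(X)
        return float(np.average(labels == np.asarray(y),
                                weights=sample_weight))


class ToyConvClassifier(BaseEstimator, ClassifierMixin, BlackBoxAdapter):
    """Small CNN black box (2 conv blocks) on the numpy core.

    Slower than the logistic adapter; provided for experiments where a
    non-linear black box matters.
    """

    def __init__(self, n_channels: int = 8, epochs: int = 20,
                 batch_size: int = 32, lr: float = 1e-3,
                 random_state: int = 0):
        self.n_channels = n_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.random_state = random_state

    def fit(self, X, y):
        from . import nn
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least two classes to fit")
        self.classes_ = classes
        res = X.shape[1]
        rng = np.random.default_rng(self.random_state)
        c = self.n_channels
        flat = (res // 4) ** 2 * 2 * c
        self.net_ = nn.Sequential([
            nn.Conv2d(3, c, rng), nn.ReLU(), nn.MaxPool2(),
            nn.Conv2d(c, 2 * c, rng), nn.ReLU(), nn.MaxPool2(),
            nn.Flatten(), nn.Dense(flat, len(classes), rng),
        ])
        opt = nn.Adam([self.net_], lr=self.lr)
        Xn = X.transpose(0, 3, 1, 2)
        yi = np.searchsorted(classes, y)
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.net_.forward(Xn[idx], train=True)
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                grad = p.copy()
                grad[np.arange(len(idx)), yi[idx]] -= 1.0
                grad /= len(idx)
                self.net_.zero_grad()
                self.net_.backward(grad)
                opt.step()
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = np.asarray(X, dtype=float).transpose(0, 3, 1, 2)
        logits = self.net_.forward(X, train=False)
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)], probs


def train_toy_blackbox(data: LabeledImageSet, seed: int,
                       kind: str = "logistic") -> BlackBoxAdapter:
    """Fit the toy black box on a labelled image set.

    Requires >= 20 images per class; ``kind`` selects 'logistic'
    (default, fast and deterministic) or 'cnn'.
    """
    counts = np.bincount(data.labels)
    if len(counts[counts > 0]) < 2:
        raise ValueError("need at least two classes")
    if counts[counts > 0].min() < 20:
        raise ValueError("need at least 20 images per class")
    if kind == "logistic":
        clf = ToyPixelClassifier(random_state=seed)
    elif kind == "cnn":
        clf = ToyConvClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown black-box kind: {kind!r}")
    return clf.fit(data.images, data.labels)


def save_npz(data: LabeledImageSet, path: str | Path) -> None:
    np.savez_compressed(
        path, images=data.images, labels=data.labels,
        class_names=np.array(data.class_names),
        resolution=np.array(data.resolution))


def load_npz(path: str | Path) -> LabeledImageSet:
    with np.load(path, allow_pickle=False) as f:
        return LabeledImageSet(
            f["images"], f["labels"],
            [str(s) for s in f["class_names"]], int(f["resolution"]))


def save_png_dir(data: LabeledImageSet, directory: str | Path) -> None:
    """Write one PNG per image plus a filename,label CSV manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (img, lab) in enumerate(zip(data.images, data.labels)):
            name = f"img_{i:05d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(
                directory / name)
            writer.writerow([name, int(lab)])
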