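"""Deletion and insertion faithfulness curves for saliency maps.

Deletion removes pixels in order of decreasing saliency magnitude and
tracks the black box's probability for the image's original class; a
faithful map makes the probability collapse early (low AUC).  Insertion
starts from a baseline image and re-inserts pixels in the same order; a
faithful map restores the probability early (high AUC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CurveResult", "deletion_curve", "insertion_curve",
    "random_saliency_baseline",
]


@dataclass
class CurveResult:
    fractions: np.ndarray    # strictly increasing grid from 0 to 1
    scores: np.ndarray       # class probability at each fraction
    auc: float               # trapezoidal area over the fraction axis

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.fractions) <= 0):
            raise ValueError("fractions must be strictly increasing")


def _pixel_order(s: np.ndarray) -> np.ndarray:
    """Flat pixel indices by descending |s|; ties keep row-major order."""
    flat = np.abs(np.asarray(s, dtype=float)).ravel()
    return np.argsort(-flat, kind="stable")


def _baseline_image(x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "mean":
        return np.broadcast_to(x.mean(axis=(0, 1)), x.shape).copy()
    if mode == "zeros":
        return np.zeros_like(x)
    raise ValueError(f"unknown baseline mode {mode!r}")


def _curve(bb, x: np.ndarray, s: np.ndarray, step_frac: float,
           baseline: str, insert: bool) -> CurveResult:
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.isnan(s).any():
        raise ValueError("saliency map contains NaNs")
    if s.shape != x.shape[:2]:
        raise ValueError(f"saliency shape {s.shape} != spatial {x.shape[:2]}")
    if not 0 < step_frac <= 1:
        raise ValueError("step_frac must lie in (0, 1]")

    order = _pixel_order(s)
    n_px = s.size
    n_steps = max(1, round(1.0 / step_frac))
    fractions = np.arange(n_steps + 1) / n_steps
    fill = _baseline_image(x, baseline)
    y0 = int(bb.predict(x[None])[0][0])
    cls = int(np.flatnonzero(_classes(bb) == y0)[0]) if _classes(bb) is not None else y0

    batch = []
    for f in fractions:
        m = int(round(f * n_px))
        mask = np.zeros(n_px, dtype=bool)
        mask[order[:m]] = True
        mask2d = mask.reshape(s.shape)
        if insert:
            img = fill.copy()
            img[mask2d] = x[mask2d]
        else:
            img = x.copy()
            img[mask2d] = fill[mask2d]
        batch.append(img)
    _, probs = bb.predict(np.stack(batch))
    scores = probs[:, cls]
    auc = float(np.trapezoid(scores, fractions))
    return CurveResult(fractions, scores, auc)


def _classes(bb):
    return getattr(bb, "classes_", None)


def deletion_curve(bb, x: np.ndarray, s: np.ndarray,
                   step_frac: float = 0.01,
                   baseline: str = "mean") -> CurveResult:
    """Remove step_frac of the pixels per step, most salient first; the
    removed pixels take the baseline fill (per-image mean colour by
    default, or zeros)."""
    return _curve(bb, x, s, step_frac, baseline, insert=False)


def insertion_curve(bb, x: np.ndarray, s: np.ndarray,
                    step_frac: float = 0.01,
                    baseline: str = "mean") -> CurveResult:
    """Start from the baseline image and re-insert pixels most salient
    first; the fraction-1 endpoint is the untouched image."""
    return _curve(bb, x, s, step_frac, baseline, insert=True)


def random_saliency_baseline(shape: tuple[int, int],
                             seed: int) -> np.ndarray:
    """Uniform-random saliency map — the uninformed comparison point."""
    return np.random.default_rng(seed).random(shape)
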