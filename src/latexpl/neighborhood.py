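"""Latent neighborhood generation around an encoded instance.

Two genetic runs evolve latent populations near the code z of the image
being explained — one rewarding candidates the black box labels like
the original (H=), one rewarding different labels (H!=).  Survivors are
pooled, filtered by the discriminator (the validation half of the
discriminator+decoder step), decoded and labelled by the black box.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Neighborhood", "GASettings", "DegenerateLocalityError",
    "latent_scale", "generate_neighborhood", "realism_scores",
    "validate_latents",
    "decode_and_label",
]


class DegenerateLocalityError(RuntimeError):
    """No differently-labelled neighbour could be found near z."""


@dataclass
class GASettings:
    """Genetic-search knobs (population size is the neighborhood size N)."""

    generations: int = 20
    tournament: int = 3
    crossover_p: float = 0.5
    mutation_p: float = 0.2
    mutation_scale: float = 0.2     # in units of the latent scale rho


@dataclass
class Neighborhood:
    """Validated, decoded, black-box-labelled latent neighborhood."""

    z_ref: np.ndarray               # (k,)
    latents: np.ndarray             # (N, k)
    decoded: np.ndarray             # (N, res, res, 3)
    labels: np.ndarray              # (N,) black-box classes
    same_mask: np.ndarray           # (N,) True where label == label of x
    label_ref: int = 0

    def __post_init__(self):
        n = len(self.latents)
        if not (len(self.decoded) == len(self.labels)
                == len(self.same_mask) == n):
            raise ValueError("neighborhood arrays must align")

    @property
    def same(self) -> np.ndarray:
        return self.latents[self.same_mask]

    @property
    def different(self) -> np.ndarray:
        return self.latents[~self.same_mask]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    def save(self, path: str | Path) -> None:
        np.savez_compressed(path, z_ref=self.z_ref, latents=self.latents,
                            decoded=self.decoded, labels=self.labels,
                            same_mask=self.same_mask,
                            label_ref=np.array(self.label_ref))

    @classmethod
    def load(cls, path: str | Path) -> "Neighborhood":
        with np.load(path, allow_pickle=False) as f:
            return cls(f["z_ref"], f["latents"], f["decoded"], f["labels"],
                       f["same_mask"], int(f["label_ref"]))


def latent_scale(k: int, rng: np.random.Generator,
                 n_samples: int = 100) -> float:
    """rho: median pairwise distance among prior samples — the natural
    length unit of the latent space."""
    Z = rng.standard_normal((n_samples, k))
    d2 = ((Z[:, None] - Z[None, :]) ** 2).sum(-1)
    iu = np.triu_indices(n_samples, k=1)
    return float(np.median(np.sqrt(d2[iu])))


_CONTEXT_SEED = 987654321   # fixed reference batch for stable scoring
_CONTEXT_SIZE = 31


def realism_scores(model, Z: np.ndarray) -> np.ndarray:
    """Discriminator score of each row, judged in a fixed prior context.

    With mini-batch discrimination enabled, raw batch scores depend on
    the composition of the batch being scored (a batch of near-duplicate
    candidates looks mode-collapsed regardless of how realistic each
    code is).  Scoring one candidate at a time alongside a fixed batch
    of prior reference samples removes that dependence: the score
    reflects the candidate itself, deterministically.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    k = Z.shape[1]
    ref = np.random.default_rng(_CONTEXT_SEED).standard_normal(
        (_CONTEXT_SIZE, k))
    return np.array([
        float(model.discriminate(np.vstack([ref, row[None]]))[-1])
        for row in Z])


def validate_latents(model, Z: np.ndarray, tau: float) -> np.ndarray:
    """Keep rows whose context-stable discriminator score is >= tau
    (the validation half of the discriminator+decoder step)."""
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if len(Z) == 0:
        return Z
    keep = realism_scores(model, Z) >= tau
    if not keep.any():
        warnings.warn("discriminator rejected every candidate latent",
                      RuntimeWarning, stacklevel=2)
    return Z[keep]


def decode_and_label(model, bb, Z: np.ndarray):
    """Decode a validated batch and classify it with the black box."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    images = model.decode(Z)
    labels, probs = bb.predict(images)
    return images, labels, probs


def _bb_labels(model, bb, Z: np.ndarray) -> np.ndarray:
    labels, _ = bb.predict(model.decode(Z))
    return labels


def _ga_run(z: np.ndarray, label_fn, y_ref: int, want_same: bool,
            pop_size: int, rho: float, ga: GASettings,
            rng: np.random.Generator) -> np.ndarray:
    """One genetic run; returns the final population (pop_size, k)."""
    k = len(z)
    sigma = ga.mutation_scale * rho
    pop = z[None, :] + rng.normal(0, sigma, (pop_size, k))

    def fitness(P: np.ndarray) -> np.ndarray:
        labels = label_fn(P)
        match = (labels == y_ref) if want_same else (labels != y_ref)
        dist = np.linalg.norm(P - z[None, :], axis=1)
        is_z = np.all(P == z[None, :], axis=1)
        return match.astype(float) + np.exp(-dist / rho) - is_z.astype(float)

    fit = fitness(pop)
    for _ in range(ga.generations):
        # tournament selection of parents
        idx = rng.integers(0, pop_size, (2 * pop_size, ga.tournament))
        winners = idx[np.arange(2 * pop_size),
                      np.argmax(fit[idx], axis=1)]
        pa, pb = pop[winners[:pop_size]], pop[winners[pop_size:]]
        # uniform crossover + Gaussian mutation
        swap = rng.random((pop_size, k)) < ga.crossover_p
        children = np.where(swap, pb, pa)
        mut = rng.random((pop_size, k)) < ga.mutation_p
        children = children + mut * rng.normal(0, sigma, (pop_size, k))
        cfit = fitness(children)
        # elitist replacement: child replaces parent slot when fitter
        better = cfit > fit
        pop = np.where(better[:, None], children, pop)
        fit = np.where(better, cfit, fit)
    return pop


def generate_neighborhood(z: np.ndarray, bb, model, N: int, seed: int,
                          tau: float = 0.05,
                          ga: GASettings | None = None,
                          label_ref: int | None = None) -> Neighborhood:
    """Build the neighborhood H around z (|H| <= N, balanced H=/H!=).

    Runs the same-label and different-label genetic searches, validates
    the pooled survivors with the discriminator, decodes and labels
    them, and balances the two partitions as far as the pool allows.
    Falls back to ascending-radius rejection sampling when the search
    finds no differently-labelled instance; raises
    :class:`DegenerateLocalityError` if that also fails.

    ``label_ref`` is the black-box label the H= partition must match;
    it defaults to the label of decode(z).  Callers explaining a real
    image pass b(x) so the partition anchors on the original image even
    when reconstruction crosses the decision boundary.
    """
    if N < 20:
        raise ValueError("N must be >= 20")
    ga = ga or GASettings()
    rng = np.random.default_rng(seed)
    z = np.asarray(z, dtype=float)
    k = len(z)
    rho = latent_scale(k, rng)
    y_ref = (int(bb.predict(model.decode(z)[None])[0][0])
             if label_ref is None else int(label_ref))
    label_fn = lambda P: _bb_labels(model, bb, P)

    pop_same = _ga_run(z, label_fn, y_ref, True, N, rho, ga, rng)
    pop_diff = _ga_run(z, label_fn, y_ref, False, N, rho, ga, rng)
    pool = np.vstack([pop_same, pop_diff])
    valid = validate_latents(model, pool, tau)
    if len(valid) == 0:
        valid = pool  # degraded mode: warned upstream, keep searching

    images, labels, probs = decode_and_label(model, bb, valid)
    same = labels == y_ref

    if not (~same).any():
        extra = _radius_fallback(z, model, bb, y_ref, rho, tau, rng)
        if extra is None:
            raise DegenerateLocalityError(
                f"no neighbour with label != {y_ref} found near z")
        valid = np.vstack([valid, extra])
        images, labels, probs = decode_and_label(model, bb, valid)
        same = labels == y_ref
    if not same.any():
        # different-only neighborhoods are equally degenerate
        raise DegenerateLocalityError(
            f"no neighbour with label == {y_ref} found near z")

    keep = _balance(same, N, rng)
    return Neighborhood(z, valid[keep], images[keep], labels[keep],
                        same[keep], label_ref=y_ref)


def _balance(same: np.ndarray, N: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a balanced-as-possible subset of size <= N."""
    idx_s = np.flatnonzero(same)
    idx_d = np.flatnonzero(~same)
    half = N // 2
    n_s = min(len(idx_s), max(half, N - len(idx_d)))
    n_d = min(len(idx_d), N - n_s)
    pick = np.concatenate([
        rng.choice(idx_s, size=n_s, replace=False),
        rng.choice(idx_d, size=n_d, replace=False)])
    return np.sort(pick)


def _radius_fallback(z, model, bb, y_ref, rho, tau, rng,
                     n_per_radius: int = 200):
    for radius in (1.0, 2.0, 4.0, 8.0):
        cand = z[None, :] + rng.normal(0, radius * rho,
                                       (n_per_radius, len(z)))
        cand = validate_latents(model, cand, tau)
        if len(cand) == 0:
            continue
        labels = _bb_labels(model, bb, cand)
        hit = cand[labels != y_ref]
        if len(hit):
            return hit[:max(1, n_per_radius // 10)]
    return None
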