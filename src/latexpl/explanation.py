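"""Exemplar / counter-exemplar synthesis and the explanation triple.

The explanation of an image x is <exemplars, counter-exemplars,
saliency>: synthetic images the black box labels like x (generated from
latents satisfying the factual rule r), images it labels differently
(latents satisfying a counterfactual rule), and a signed per-pixel map
s[i] = median over exemplars of (x[i] - exemplar[i]).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
import numpy as np

from .neighborhood import (GASettings, generate_neighborhood, latent_scale,
                           validate_latents)
from .surrogate import (DecisionRule, fit_surrogate, rules_for_class,
                        surrogate_fidelity)

__all__ = [
    "Explanation", "ExplainConfig", "generate_exemplars",
    "generate_counter_exemplars", "select_counter_exemplar",
    "compute_saliency", "explain",
]


@dataclass
class ExplainConfig:
    """End-to-end explanation settings (neighborhood, rules, exemplars)."""

    n_neighborhood: int = 100       # N latent instances around z
    tau: float = 0.05               # validation threshold (see methods)
    n_exemplars: int = 4            # images shown with x's label
    n_counter_exemplars: int = 2    # images shown with other labels
    sample_scale: float = 0.3       # exemplar jitter, units of rho
    budget_factor: int = 50         # sampling budget = factor * n wanted
    ga: GASettings = field(default_factory=GASettings)
    surrogate_max_depth: int = 8
    surrogate_min_samples_leaf: int = 3


@dataclass
class Explanation:
    """The triple <exemplars, counter-exemplars, saliency> plus rules."""

    rule: DecisionRule
    counter_rules: list[DecisionRule]
    exemplars: np.ndarray            # (n_ex, H, W, 3)
    counter_exemplars: np.ndarray    # (n_ce, H, W, 3)
    saliency: np.ndarray             # (H, W) signed
    neighborhood_counts: dict[int, int]
    label: int
    fidelity: float

    def to_dict(self) -> dict:
        return {
            "label": int(self.label),
            "rule": self.rule.to_dict(),
            "counter_rules": [r.to_dict() for r in self.counter_rules],
            "neighborhood_counts": {str(k): int(v) for k, v in
                                    self.neighborhood_counts.items()},
            "fidelity": float(self.fidelity),
            "saliency": np.asarray(self.saliency).tolist(),
            "exemplars": np.asarray(self.exemplars).tolist(),
            "counter_exemplars": np.asarray(self.counter_exemplars).tolist(),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "Explanation":
        return cls(
            rule=DecisionRule.from_dict(d["rule"]),
            counter_rules=[DecisionRule.from_dict(r)
                           for r in d["counter_rules"]],
            exemplars=np.asarray(d["exemplars"], dtype=float),
            counter_exemplars=np.asarray(d["counter_exemplars"], dtype=float),
            saliency=np.asarray(d["saliency"], dtype=float),
            neighborhood_counts={int(k): int(v) for k, v in
                                 d["neighborhood_counts"].items()},
            label=int(d["label"]),
            fidelity=float(d["fidelity"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "Explanation":
        return cls.from_dict(json.loads(s))


def _sample_rule_latents(rule: DecisionRule, z: np.ndarray, n: int,
                         scale: float, rng: np.random.Generator) -> np.ndarray:
    """z + Gaussian jitter with rule-violating coordinates resampled
    (up to a per-coordinate retry cap) rather than clamped, to avoid
    piling samples onto the rule boundary."""
    k = len(z)
    out = z[None, :] + rng.normal(0, scale, (n, k))
    by_feature: dict[int, list] = {}
    for p in rule.premises:
        by_feature.setdefault(p.feature_index, []).append(p)
    for f, prems in by_feature.items():
        lo = max((p.threshold for p in prems if p.op == ">"), default=-np.inf)
        hi = min((p.threshold for p in prems if p.op == "<="), default=np.inf)
        col = out[:, f]
        for _ in range(40):
            bad = (col <= lo) | (col > hi)
            if not bad.any():
                break
            col[bad] = z[f] + rng.normal(0, scale, bad.sum())
        # final fallback: uniform inside the (possibly half-open) box
        bad = (col <= lo) | (col > hi)
        if bad.any():
            lo_f = lo if np.isfinite(lo) else min(z[f], hi) - 3 * scale
            hi_f = hi if np.isfinite(hi) else max(z[f], lo) + 3 * scale
            col[bad] = rng.uniform(lo_f + 1e-9, hi_f, bad.sum())
        out[:, f] = col
    return out


def _collect(model, bb, rule: DecisionRule, z: np.ndarray, n_want: int,
             scale: float, tau: float, budget: int,
             rng: np.random.Generator, anchor: np.ndarray | None = None):
    """Draw latents satisfying `rule`, validate, decode, keep those the
    black box assigns rule.outcome; returns (latents, images, probs).

    Samples that satisfy the rule's premises can still decode to images
    of another class (the surrogate is only locally faithful).  When a
    validated batch yields no correctly-labelled survivor, the jitter
    scale escalates so samples move deeper into the rule's region, away
    from z's side of the boundary.  Validation failures do *not*
    escalate: wider jitter only makes candidates less realistic."""
    centre = z if anchor is None else np.asarray(anchor, dtype=float)
    got_z, got_img, got_p = [], [], []
    remaining = budget
    batch = max(2 * n_want, 16)
    mult = 1.0
    while remaining > 0 and sum(len(g) for g in got_img) < n_want:
        m = min(batch, remaining)
        remaining -= m
        cand = _sample_rule_latents(rule, centre, m, scale * mult, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cand = validate_latents(model, cand, tau)
        if len(cand) == 0:
            continue
        images = model.decode(cand)
        labels, probs = bb.predict(images)
        keep = labels == rule.outcome
        if keep.any():
            got_z.append(cand[keep])
            got_img.append(images[keep])
            got_p.append(probs[keep])
        else:
            mult = min(mult * 1.6, 8.0)
    if not got_img:
        return (np.empty((0, len(z))), np.empty((0,)), np.empty((0,)))
    Z = np.vstack(got_z)[:n_want]
    return Z, np.vstack(got_img)[:n_want], np.vstack(got_p)[:n_want]


def generate_exemplars(model, bb, r: DecisionRule, z: np.ndarray,
                       n_ex: int, seed: int, tau: float = 0.05,
                       sample_scale: float = 0.3,
                       budget_factor: int = 50) -> np.ndarray:
    """Synthesize up to n_ex exemplar images satisfying the factual rule.

    Emits a RuntimeWarning (partial result) when the sampling budget is
    exhausted before n_ex survivors are found.
    """
    if n_ex < 1:
        raise ValueError("n_ex must be >= 1")
    rng = np.random.default_rng(seed)
    rho = latent_scale(len(z), rng)
    _, images, _ = _collect(model, bb, r, z, n_ex, sample_scale * rho,
                            tau, budget_factor * n_ex, rng)
    if len(images) < n_ex:
        warnings.warn(
            f"exemplar budget exhausted: {len(images)}/{n_ex} found",
            RuntimeWarning, stacklevel=2)
    return images


def generate_counter_exemplars(model, bb, counter_rules, z: np.ndarray,
                               n_ce: int, seed: int, tau: float = 0.05,
                               sample_scale: float = 0.3,
                               budget_factor: int = 50,
                               anchors: list | None = None):
    """Counter-exemplars per counterfactual rule, consumed in Phi order.

    Returns (latents, images, probs); images' black-box labels equal
    their generating rule's outcome, hence differ from x's label.

    ``anchors`` optionally supplies, per rule, a latent to centre the
    sampling on (e.g. the closest differently-labelled neighborhood
    member satisfying that rule); by default sampling centres on z.
    """
    if not counter_rules:
        raise ValueError("counter_rules must be nonempty")
    rng = np.random.default_rng(seed)
    rho = latent_scale(len(z), rng)
    Zs, imgs, ps = [], [], []
    need = n_ce
    for ri, rule in enumerate(counter_rules):
        if need <= 0:
            break
        anchor = anchors[ri] if anchors is not None else None
        Zr, im, pr = _collect(model, bb, rule, z, need, sample_scale * rho,
                              tau, budget_factor * need, rng,
                              anchor=anchor)
        if len(im):
            Zs.append(Zr); imgs.append(im); ps.append(pr)
            need -= len(im)
    if not imgs:
        warnings.warn("no counter-exemplar found within budget",
                      RuntimeWarning, stacklevel=2)
        return (np.empty((0, len(z))), np.empty((0,)), np.empty((0,)))
    return np.vstack(Zs), np.vstack(imgs), np.vstack(ps)


def select_counter_exemplar(latents: np.ndarray, images: np.ndarray,
                            probs: np.ndarray, z: np.ndarray,
                            y_x: int) -> np.ndarray:
    """Displayed counter-exemplar: minimal latent distance to z, ties
    broken by maximal alternate-class probability."""
    if len(images) == 0:
        raise ValueError("no candidates")
    dist = np.linalg.norm(np.asarray(latents) - np.asarray(z)[None, :],
                          axis=1)
    p = np.asarray(probs).copy()
    if p.ndim == 2 and 0 <= y_x < p.shape[1]:
        p[:, y_x] = -np.inf
    alt = p.max(axis=1) if p.ndim == 2 else p
    order = sorted(range(len(images)), key=lambda i: (dist[i], -alt[i]))
    return images[order[0]]


def compute_saliency(x: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    """Signed saliency: per-pixel median over exemplars of (x - exemplar),
    averaged across colour channels to a single (H, W) map."""
    x = np.asarray(x, dtype=float)
    exemplars = np.asarray(exemplars, dtype=float)
    if exemplars.ndim == x.ndim:
        exemplars = exemplars[None]
    if len(exemplars) == 0:
        raise ValueError("need at least one exemplar")
    if exemplars.shape[1:] != x.shape:
        raise ValueError(
            f"exemplar shape {exemplars.shape[1:]} != image shape {x.shape}")
    diffs = x[None] - exemplars                  # (n_ex, H, W, C) or (n_ex, H, W)
    med = np.median(diffs, axis=0)
    if med.ndim == 3:
        med = med.mean(axis=-1)
    return med


def explain(x: np.ndarray, bb, model, config: ExplainConfig | None = None,
            seed: int = 0) -> Explanation:
    """Full pipeline: encode -> neighborhood -> surrogate -> rules ->
    exemplars / counter-exemplars -> saliency."""
    config = config or ExplainConfig()
    z = model.encode(x)
    y_x = int(bb.predict(x[None])[0][0])

    nbr = generate_neighborhood(z, bb, model, config.n_neighborhood,
                                seed, tau=config.tau, ga=config.ga,
                                label_ref=y_x)
    tree = fit_surrogate(nbr, seed,
                         max_depth=config.surrogate_max_depth,
                         min_samples_leaf=config.surrogate_min_samples_leaf)
    fidelity = surrogate_fidelity(tree, nbr)
    r = tree.rule_for(z)
    if r.outcome != y_x:
        # reconstruction crossed the decision boundary: z's own leaf
        # disagrees with b(x).  Anchor the factual rule on the nearest
        # leaf region the surrogate labels y_x instead.
        same_rules = rules_for_class(tree, z, y_x)
        if same_rules:
            r = same_rules[0]
        else:
            warnings.warn(
                "surrogate has no leaf matching the black-box label of x; "
                "factual rule follows the latent code's leaf",
                RuntimeWarning, stacklevel=2)
    phi = tree.counterfactuals_for(z, r)

    exemplars = generate_exemplars(
        model, bb, r, z, config.n_exemplars, seed + 1, tau=config.tau,
        sample_scale=config.sample_scale,
        budget_factor=config.budget_factor)
    if phi:
        # anchor each counter-rule's sampler at the closest H!= member
        # that satisfies it and carries the rule's class — a latent
        # known to decode to the right side of the black-box boundary
        diff_lat = nbr.latents[~nbr.same_mask]
        diff_lab = nbr.labels[~nbr.same_mask]
        anchors = []
        for rule in phi:
            cand = [h for h, lab in zip(diff_lat, diff_lab)
                    if lab == rule.outcome and rule.satisfied_by(h)]
            if cand:
                dists = [np.linalg.norm(h - z) for h in cand]
                anchors.append(cand[int(np.argmin(dists))])
            else:
                anchors.append(None)
        ce_lat, ce_img, ce_p = generate_counter_exemplars(
            model, bb, phi, z, config.n_counter_exemplars, seed + 2,
            tau=config.tau, sample_scale=config.sample_scale,
            budget_factor=config.budget_factor, anchors=anchors)
    else:
        ce_lat = np.empty((0, len(z)))
        ce_img = np.empty((0,) + x.shape)
        ce_p = np.empty((0,))
    if len(ce_img):
        best = select_counter_exemplar(ce_lat, ce_img, ce_p, z, y_x)
        rest = [im for im in ce_img
                if not np.array_equal(im, best)][:len(ce_img) - 1]
        ce_img = np.stack([best] + rest) if rest else best[None]

    if len(exemplars) == 0:
        raise RuntimeError("no exemplar found; cannot build saliency")
    saliency = compute_saliency(x, exemplars)

    return Explanation(
        rule=r, counter_rules=phi, exemplars=exemplars,
        counter_exemplars=ce_img, saliency=saliency,
        neighborhood_counts=nbr.class_counts(), label=y_x,
        fidelity=fidelity)
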