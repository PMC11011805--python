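# latexpl — latent exemplar explanations for image classifiers

`latexpl` explains individual predictions of any black-box image
classifier by *showing*, not just highlighting: for an image x it
synthesises **exemplars** (realistic images the classifier labels the
same way), **counter-exemplars** (minimally different images it labels
differently) and a signed per-pixel **saliency map**. It is aimed at
researchers and practitioners evaluating classifiers on biomedical
images — the synthetic study system emulates dermoscopic skin-lesion
images — but any classifier exposing a probability vector can be
plugged in.

## Method

A progressively grown **adversarial autoencoder** (encoder
q(z|x): Rⁿ→Rᵏ, decoder p(x|z), latent discriminator pushing the
aggregated posterior q(z) toward the prior p(z)=N(0, I_k)) learns a
generative latent space over the image domain. Training grows from 7×7
to the target resolution, doubling per stage, with denoising
corruption (σ=0.1), discriminator-input noise and mini-batch
discrimination (B=16 kernels × C=5 dimensions) against mode collapse.

To explain x with black box b:

1. **encode** x to z;
2. **neighborhood** — two genetic searches evolve N latent instances
   around z (fitness: correct/incorrect label + exp(−‖h−z‖/ρ));
   survivors are validated by the discriminator, decoded and labelled
   by b, giving partitions H= (b(h̃)=b(x)) and H≠;
3. **surrogate** — a decision tree fitted to (latents, labels) yields
   the factual rule r (z's path, per-feature bounds merged) and
   counterfactual rules Φ (other-class leaves, fewest violated
   premises first);
4. **synthesis** — latents satisfying r (resp. Φ) are sampled,
   validated, decoded, and kept if b agrees with the rule's outcome;
5. **saliency** — s[i] = median over exemplars h̃e of (x[i] − h̃e[i]).

Saliency maps are scored by **deletion/insertion** curves (remove or
re-insert pixels in order of |s|, track b's class probability; lower
deletion AUC and higher insertion AUC = more faithful), and the latent
space is probed by **MDS** projection plus Random-Forest pairwise class
separability. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

```python
import numpy as np
from latexpl import (AdversarialAutoencoder, ExplainConfig, explain,
                     generate_dataset, train_toy_blackbox)

data = generate_dataset(n_per_class=200, n_classes=3, resolution=28, seed=11)
bb = train_toy_blackbox(data, seed=11)                  # logistic black box
model = AdversarialAutoencoder(
    latent_dim=32, stage_resolutions=(7, 14, 28), disc_widths=(64, 96, 128),
    epochs_per_stage=(8, 6, 6), mb_kernels=8, mb_dims=4, random_state=7,
).fit(data.images)                                       # ~5 min on 1 CPU

x = generate_dataset(50, 3, 28, seed=99).images[0]       # held-out image
exp = explain(x, bb, model,
              ExplainConfig(n_neighborhood=60, n_exemplars=3,
                            n_counter_exemplars=1), seed=300)
print("label:", exp.label)
print("rule:", exp.rule)
print("counter-rule:", exp.counter_rules[0])
print("neighborhood:", exp.neighborhood_counts,
      "fidelity: %.2f" % exp.fidelity)
```

Output from this exact run:

```
label: 0
rule: {28<=0.25} -> {class: 0}
counter-rule: {7<=2.00, 28>0.25} -> {class: 2}
neighborhood: {0: 30, 2: 30} fidelity: 0.98
```

Read: the classifier calls this lesion class 0; locally, the surrogate
says the decision rests on latent coordinate 28 staying at or below
0.25, and pushing it above 0.25 (with coordinate 7 at most 2.00) is the
smallest latent change that flips the decision to class 2. Of the 60
validated neighbourhood images, 30 kept the label and 30 did not, and
the surrogate reproduces the black box on 98% of them.
`exp.exemplars` holds 3 synthetic images the classifier also labels 0,
`exp.counter_exemplars` a class-2 image minimally distant in latent
space, and `exp.saliency` the 28×28 signed median-difference map.

The same pipeline is scriptable from the shell:

```bash
latexpl synth --n-per-class 200 --n-classes 3 --resolution 28 --seed 11 \
        --out data.npz --blackbox-out bb.joblib
latexpl train-aae --data data.npz --stages 7,14,28 --latent-dim 32 \
        --seed 7 --out model.npz
latexpl explain --model model.npz --blackbox bb.joblib --image img.npy \
        --seed 4 --out-dir exp/
latexpl eval-saliency --blackbox bb.joblib --image img.npy \
        --saliency exp/saliency.npy --out-prefix exp/curves
latexpl latent-map --model model.npz --data data.npz --dims 2 \
        --out coords.csv --plot map.png
```

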