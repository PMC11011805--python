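# Methods

`latexpl` explains individual predictions of a black-box image
classifier by example: it learns a generative latent space over the
image domain, explores how the classifier behaves in a neighborhood of
the image being explained, distils that behaviour into a decision-tree
rule, and renders the rule as synthetic *exemplars* (images the
classifier labels the same way), *counter-exemplars* (images it labels
differently) and a signed per-pixel saliency map. This note documents
the model, the knobs that matter, and the choices made where the design
was genuinely open.

## The generative backbone

The backbone is an adversarial autoencoder (AAE): an encoder
q(z|x): R^n -> R^k, a decoder p(x|z): R^k -> R^n, and a latent
discriminator trained to tell prior samples z ~ p(z) from encoded
codes. The prior is the standard normal N(0, I_k) — the usual AAE
choice. Training alternates two phases per batch:

* **Reconstruction** — minimise mean squared pixel error of
  decode(encode(x̃)) against the clean x, where x̃ is x corrupted with
  Gaussian pixel noise (σ = 0.1, clipped back to [0, 1]). The denoising
  corruption regularises the code and measurably improves
  reconstruction of held-out images.
* **Regularization** — (i) update the discriminator on prior samples
  (label 1) vs. encoded codes (label 0), with N(0, σ²) noise added to
  its inputs; (ii) update the encoder to fool the discriminator;
  (iii) update the encoder to match the batch code moments to the
  prior's (mean → 0, std → 1 per coordinate).

Step (iii) is a deliberate addition. With Adam on both sides, the
adversarial fooling step corrects one discriminative direction at a
time and cannot anchor dozens of drifting code coordinates within a
small epoch budget: in ablations at desk scale, per-coordinate code
means drifted to |mean| ≈ 8–20 while the discriminator kept winning.
Explicit first/second-moment matching is a distribution-matching
stabiliser in the same family as the feature-matching and mini-batch
tricks common in generative adversarial training; it handles the two
coarsest moments and leaves higher-order structure to the
discriminator. Set `lr_moment=0` to disable it and recover the plain
two-step loop.

Three further stabilisers:

* **Progressive growing.** Training starts at 7×7 pixels and doubles
  the resolution stage by stage (default schedule 7→14→28→56→112→224).
  Each growth step adds one convolutional block (conv3×3 → batch-norm →
  ReLU → max-pool in the encoder; upsample → conv → batch-norm → ReLU
  in the decoder) in front of / behind the shared trunk, whose weights
  transfer unchanged. Per-stage input/output adapter convolutions
  (image→features, features→image) are stage-specific and rebuilt at
  each growth. The latent dimension is constant across stages, so the
  discriminator always sees inputs of the same size; instead of
  deepening, its two dense layers widen stage by stage (500 → 3000
  units across the full schedule, linearly interpolated). Widening
  copies the old weights into the top-left block of the new matrices.
  New units receive small random *incoming* weights and zero *outgoing*
  weights: the discriminator's function at the instant of growth is
  preserved exactly, while the new units remain trainable (pure zero
  initialisation would leave them permanently dead, since zero outgoing
  weights gate their incoming gradient to zero and vice versa).
* **Mini-batch discrimination.** Before the discriminator's output
  layer, each sample's penultimate features F_i are projected through a
  learned tensor T (feature_dim × B × C) to M_i, and the batch-context
  features o(x_i)_b = Σ_j exp(−‖M_{i,b} − M_{j,b}‖₁) are concatenated
  to F_i. Overly uniform batches (a mode-collapse signature) become
  easy to reject. Defaults B = 16 kernels of C = 5 dimensions; B = 0
  disables the layer for ablation.
* **Input noise on the discriminator** (σ = 0.1, same scale as the
  denoising corruption), which smooths its decision boundary.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `latent_dim` (k) | 256 | code length; 64–512 is the sensible range at 224×224, 32 suffices at 28×28 |
| `stage_resolutions` | (7, 14, 28, 56, 112, 224) | strictly doubling; a 1-stage list degenerates to a plain denoising AAE |
| `disc_widths` | 500 → 3000 (linear) | discriminator dense-layer width per stage |
| `noise_sigma` (σ) | 0.1 | pixel-corruption *and* discriminator-input noise, in pixel units |
| `mb_kernels` / `mb_dims` (B / C) | 16 / 5 | mini-batch discrimination capacity |
| `lr_recon` / `lr_adv` / `lr_moment` | 1e-3 / 2e-4 / 2e-3 | Adam rates of the three phases |
| `epochs_per_stage`, `batch_size` | 8, 32 | per-stage budget |

Optimiser (Adam), learning rates, epochs and channel widths are not
prescribed by the method; the defaults above were chosen once at desk
scale and are all exposed in `AAEConfig`.

The network core is a small, self-contained numpy implementation
(`latexpl.nn`) — conv/dense/batch-norm layers with explicit backward
passes, each validated against central finite differences in the test
suite — so the package runs anywhere scientific Python runs.

## Neighborhood generation

To explain x, its code z = encode(x) is surrounded with N latent
instances (default N = 100, matching the scale of typical neighborhood
count read-outs) that mimic the classifier's local behaviour. Two
genetic runs evolve populations of size N for 20 generations: one
rewards candidates the black box labels like x, the other candidates it
labels differently. The fitness is

    fitness(h) = 1{b(decode(h)) = / ≠ b(x)} + exp(−‖h − z‖₂ / ρ) − 1{h = z}

with ρ the median pairwise distance of 100 prior samples — a scale-free
unit of latent length. Selection is tournament-of-3; variation is
uniform crossover (p = 0.5) and per-gene Gaussian mutation
(p = 0.2, scale 0.2ρ); a child replaces its parent slot only when
fitter. The pooled survivors pass the *validation* step — kept only if
their realism score is ≥ τ — then are decoded and labelled by the black
box, and the two partitions (H=, H≠) are balanced as far as the pool
allows.

Two validation details matter in practice. First, with mini-batch
discrimination the discriminator's output depends on the composition of
the batch being scored: a batch of near-duplicate candidates (exactly
what exemplar sampling produces) is rejected wholesale as
mode-collapse-like even when each code is individually realistic.
Validation therefore scores each candidate in a *fixed context* — one
candidate alongside 31 fixed prior reference samples, matching the
training batch size — which makes the score a property of the candidate
alone, deterministically (`realism_scores`). Second, the threshold τ
must be calibrated to the model rather than fixed at the 0.5 midpoint:
at desk scale the discriminator wins its game (context scores: prior
samples ≈ 0.98 median, encoded codes ≈ 0.16, ×3-scaled codes ≈ 0.045,
uniform junk ≈ 0.001), so τ = 0.5 would reject precisely the
encoded-region codes that decode to realistic images. The pipeline
default τ = 0.05 sits an order of magnitude above the junk median and
below the encoded lower quartile: it rejects ~90% of junk while keeping
~75% of realistic codes. τ remains exposed everywhere because the score
distribution shifts with training length and data.

If the search finds no differently-labelled instance, ascending-radius
rejection sampling (1ρ, 2ρ, 4ρ, 8ρ) is tried before a
`DegenerateLocalityError` is raised; a degenerate locality is reported,
never silently ignored.

## Surrogate tree and rules

A CART tree (Gini, max depth 8, min 3 samples per leaf, fixed seed) is
fitted to (latents, black-box labels), unweighted. The factual rule r
is z's root-to-leaf path with per-feature bounds merged to the tightest
lower (>) and upper (≤) thresholds — one or two conditions per feature,
as in the usual textual rendering of latent rules. Counterfactual rules
Φ are the path rules of every leaf predicting a different class, sorted
by how few premises z violates, with ties broken by the Euclidean
distance from z to the rule's satisfying box (clamped projection), then
by leaf index — a total, deterministic order. Surrogate fidelity is the
fraction of neighborhood instances on which the tree reproduces the
black-box label.

One boundary case needs care: the reconstruction decode(encode(x)) can
cross the classifier's decision boundary, so the leaf containing z may
predict a different class than b(x). The explanation always anchors on
b(x): the neighborhood partition H= is defined against b(x), and if z's
own leaf disagrees, the factual rule is taken from the nearest leaf
region the surrogate labels b(x) (nearest in the same
violations-then-boundary-distance order used for counterfactuals).
Exemplars therefore always carry the label the black box actually
assigned to the image being explained.

## Exemplars, counter-exemplars, saliency

Exemplar latents are drawn as z + N(0, (0.3ρ)²) with coordinates that
violate r *resampled* rather than clamped (clamping piles samples onto
the rule boundary and produces near-duplicate images), validated by the
discriminator, decoded, and kept only if the black box assigns
r's outcome; the budget is 50 draws per requested exemplar, and a
partial result warns rather than fails. Counter-exemplars work the same
way per counterfactual rule, consuming Φ in its fewest-violations
order, with two refinements. The sampler anchors on the closest H≠
neighborhood member that satisfies the counter-rule and carries its
class — a latent already known to decode to the far side of the
black-box boundary — because jitter around z itself rarely crosses the
true boundary when the surrogate's leaf describes it with fewer
coordinates than the classifier actually uses. And when a validated
batch yields only wrong-label survivors, the jitter scale escalates
(×1.6 per failed batch, capped at ×8) so samples move deeper into the
rule's region; validation failures do not escalate, since wider jitter
only makes candidates less realistic. The single *displayed* counter-exemplar minimises latent
distance to z first and maximises the alternate-class probability as
the tie-break (the two stated criteria, combined lexicographically).

The saliency map is s[i] = median over exemplars of (x[i] − h̃e[i]),
computed per colour channel and averaged across channels into one
signed 2D map: positive values mark pixels the exemplars agree should
be darker than they are in x (features pushing toward the label),
negative the reverse. Defaults show 4 exemplars and 2 counter-exemplars.

## Faithfulness metrics

Deletion/insertion curves use |s| (the map is signed) in descending
order, ties broken by row-major pixel index. Deletion replaces pixels
with a baseline fill — per-image mean colour by default, zeros as the
alternative, recorded in the output metadata — in steps of
`step_frac` (default 1%) of the pixels, tracking the black box's
probability for x's original class; insertion starts from the baseline
image and re-inserts pixels in the same order. AUC is the trapezoid
over the fraction axis normalised to [0, 1]. Lower deletion AUC and
higher insertion AUC indicate a more faithful map; the package ships a
seeded uniform-random map as the uninformed comparison point.

## Latent-space analysis

Encoded datasets are projected to 2D/3D by metric MDS — SMACOF started
from the classical (Torgerson) scaling solution; for 3D a second start
pads the converged 2D solution with a zero column, so reported stress
cannot increase with dimension. Stress is reported in normalised
(Kruskal-style) form. Inputs beyond 2000 points are seeded-subsampled
(SMACOF is O(n²) per iteration). Pairwise class separability is the
5-fold stratified cross-validated accuracy of a Random Forest (500
trees) on the two classes' embedded coordinates; cross-validation is a
protocol choice made here for stability, since single-split accuracies
are noisy at desk scale.

## Synthetic study system

The generator emulates class-structured dermoscopic-like images: one
elliptical lesion on a warm skin-tone background, with class identity
carried by hue (0.0 / 0.33 / 0.66 ± 0.05 jitter), border irregularity
(radial Fourier perturbation, amplitude 0 / 0.1 / 0.25) and internal
sinusoidal texture (0 / 4 / 8 cycles); centre, radii and background
tone vary uniformly within class. A depth-3 decision tree on four
summary features (mean R/G/B, boundary roughness) separates the classes
at ≥ 95% — the intended "weak classifier succeeds" regime — and the
class-defining features are visible, so explanations have something to
find. What the generator does *not* emulate: hair, rulers, specular
artifacts, varied skin tones, class imbalance, label noise, or any
photorealistic texture. Passing tests therefore demonstrate the
machinery is correct and well-calibrated on clean class-structured
images, not that explanation quality transfers to clinical dermoscopy.

The toy black box is multinomial logistic regression on raw pixels
(deterministic, ≥ 0.9 held-out accuracy at 200 images per class); a
small CNN on the same numpy core is available where a non-linear black
box matters. Any classifier can be plugged in through the adapter
contract: `predict(batch) -> (labels, probs)` with rows of `probs`
summing to one and `label = argmax` (ties to the lowest class id).

## Desk-scale study conditions

The test suite and the acceptance script train on 600 images
(3 classes × 200) at 28×28 with k = 32, stages (7, 14, 28),
discriminator widths (64, 96, 128), epochs (8, 6, 6), B = 8 / C = 4 —
about five minutes on one CPU — and evaluate on a fresh 150-image draw
from a disjoint seed. Under these conditions held-out reconstruction
RMSE lands near 0.10, within the 0.08–0.24 envelope reported for
full-scale training on real dermoscopy; encoded codes match the prior
moments loosely (per-coordinate |mean| < 0.5, std in [0.3, 2]); and
prior draws decode to visibly distinct images (mode-collapse guard).

## Numerical notes and limitations

* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; no global state. Fixed-seed reruns of the
  whole explanation pipeline are bitwise identical.
* Encoding/decoding at inference uses batch-norm running statistics and
  no noise, hence is deterministic.
* Degenerate inputs are errors, not silent fallbacks: single-label
  neighborhoods (`cannot fit surrogate`), empty candidate sets, invalid
  stage schedules, τ outside [0, 1].
* The discriminator's scores are not calibrated probabilities; the
  validation threshold τ is calibrated against the measured score
  distributions (default 0.05 at desk scale) and exposed because the
  distributions shift with training length and data.
* Saliency channel-averaging loses colour-opponent detail; per-channel
  maps can be recovered from the exemplars if needed.
* Rule thresholds refer to latent coordinates, which have no fixed
  semantic meaning across retrainings; rules are comparable only within
  one trained model.
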