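# Methods

`lsproj` implements privacy-preserving data obfuscation by latent space
projection: an autoencoder whose latent space Z = Z_s ⊕ Z_ns is split into
a sensitive subspace (the first `d_s` coordinates) and a released,
nonsensitive subspace, trained so that a privacy discriminator cannot
recover the sensitive attribute s from Z_ns.  Obfuscated data are decoder
reconstructions with Z_s neutralised.  This note records the model, the
training procedure and the design decisions that were genuinely open,
together with what the synthetic experiments do and do not show.

## Model

**Encoder (images).**  Four convolution blocks with 32, 64, 128 and 256
filters — each a 4×4 stride-2 convolution, batch normalisation and leaky
ReLU (slope 0.2) — followed by one fully connected layer into the latent
vector: five weight layers in total.  Stride-2 convolution was chosen over
pooling so the decoder mirrors the encoder exactly.  Input images live in
[0, 1] at the interface and are mapped to [−1, 1] internally to match the
decoder's tanh output; the mapping is part of the model contract.  Image
sides must be divisible by 2⁴ (one halving per block).

**Decoder (images).**  A dense layer into a spatial seed tensor, then four
transposed convolutions (256, 128, 64, 32 filters, 4×4, stride 2) with
batch norm and ReLU, the final one squashed through tanh.  The transposed
convolution is implemented as the exact adjoint of the encoder convolution
(verified by an inner-product identity in the tests).

**Tabular networks.**  Three fully connected layers each way (256, 128
hidden widths), linear decoder output.  Latent size defaults: 128 for
images, 64 for tabular data; `d_s` defaults to `latent_dim / 8`.

**Privacy discriminator.**  A fully connected adversary with hidden widths
512, 256, 128, batch norm, ReLU and dropout 0.3, sigmoid head for binary
attributes and softmax otherwise.  By default it reads Z_ns — the
representation that is actually released; attacking the full Z is a config
option (`discriminator_input="z"`).

All networks run on an in-package numpy backend (`lsproj.nn`) with
hand-written backward passes, an Adam optimiser and float32 parameters;
every source of randomness is an explicit `numpy.random.Generator`, so a
fixed seed reproduces training bit-for-bit.  Backprop is verified against
central-difference gradients in the test suite.

## Training procedure

Each minibatch alternates a discriminator update (cross-entropy on
(Z_ns, s), encoder frozen) with an autoencoder update (discriminator
frozen).  The autoencoder gradient combines:

* **Reconstruction** — mean squared error in the data domain.
* **Routing** — `lambda_s` × cross-entropy of a linear auxiliary head
  predicting s from Z_s.  This pulls sensitive information *into* the
  sensitive subspace so that neutralising Z_s at obfuscation time removes
  it from reconstructions.
* **Privacy pressure on Z_ns**, scaled by `gamma × privacy_pressure`:
  a *confusion* term — the gradient of CE(P(Z_ns), uniform) — plus
  class-conditional batch-mean matching of Z_ns.

Three details of this recipe are load-bearing; all three were established
empirically on the synthetic image task and the package treats them as
defaults rather than options to rediscover:

1. **Non-saturating adversarial gradient.**  The textbook min–max form
   (encoder maximises CE(P(Z_ns), s)) has gradient p − s at the logits,
   which vanishes exactly when the discriminator is confidently *correct* —
   when leakage is worst.  Trained that way, a freshly fitted post-hoc
   attacker recovers the sensitive attribute with accuracy ≈ 1.0 at every
   privacy weight tried.  The confusion objective (push P toward maximal
   uncertainty) is strongest in precisely that regime.  The mean-matching
   term complements it by directly aligning the first moments of the two
   sensitive groups, which the pointwise adversarial gradient is slow to do.
2. **Adversary consolidation.**  A discriminator that only tracks the
   encoder with one SGD step per batch is never close to a best response,
   and the game cycles: the encoder hides information from the *current*
   adversary without removing it.  At each epoch start the discriminator is
   re-fitted for `disc_refit_steps` (default 300) minibatch steps on freshly
   encoded latents of the whole training set.
3. **Learning-rate cooling.**  Both optimisers decay their learning rate by
   `lr_decay` (default 0.90) per epoch.  Without it the adversarial game
   oscillates and the attack accuracy at the end of training depends
   sharply on when training stops.

`privacy_pressure` (default 25) is the fixed gain converting the
user-facing privacy weight `gamma` into gradient units; it was set so that
`gamma` values of order one trade utility against privacy over a useful
range: `gamma=0` is a plain autoencoder (and, with `lambda_s=0`, reduces
*bit-exactly* to reconstruction-only training — a test pins this),
`gamma≈0.2` purges mildly, `gamma≥2` drives a post-hoc attacker to near
chance on the synthetic image task.  Optimiser: Adam, lr 1e-3,
β = (0.9, 0.999); batch 64; 50 epochs by default; autoencoder gradients
are clipped to a global L2 norm of 5.

**Obfuscation modes.**  `zero` writes zeros into Z_s; `mean` writes the
training-set mean of Z_s; `resample` draws from a stored reservoir of
training Z_s vectors (seeded).  Mean and reservoir are fitted after
training (`fit_latent_statistics`).

## Privacy evaluation

The attribute-inference attack trains a *fresh* discriminator (same
architecture family, independent seed) on a disjoint half of the released
codes and reports held-out accuracy `a` against the majority-class chance
rate `c`, summarised as the protection score
`100·(1 − max(0, (a − c)/(1 − c)))` — 100 at chance-level attack, 0 at a
perfect attack.  This definition is this package's own (the quantity is
usually reported without a formula); it is monotone in `a` and clamped to
[0, 100].  The model-inversion attack trains a dense inverse network from
released codes to images on a public split and scores the fraction of
private-split reconstructions whose SSIM exceeds a threshold (default 0.8).

An honest caveat from the experiments: a post-hoc attacker retrained to
convergence detects far smaller residuals than the training-time adversary,
and its accuracy grows with the attack-training set.  Reported protection
is therefore specific to the attack protocol (architecture, split, budget)
and should not be read as an information-theoretic guarantee.

## Synthetic data

**Images** emulate small grayscale tissue-like micrographs: the utility
class is morphological (radius of a soft-edged central blob, 0.14 vs 0.26
of the image side), the sensitive attribute is textural (horizontal vs
vertical background stripes, 4 cycles per side, small phase jitter), with
independent centre jitter and N(0, 0.05²) pixel noise.  (y, s) are drawn
from a 2×2 contingency table solved from the two marginal rates and a
target phi correlation; infeasible combinations are rejected with the
feasible interval.  The stripe amplitude (default 0.05) is calibrated
against the generator's two design oracles: raw-pixel linear probes must
recover both factors at ≥ 0.90 held-out accuracy, while the texture stays
cheap enough to drop from reconstructions that an adversarially trained
encoder can purge it — a contrast so strong that no encoder could afford
to discard it would make every separation experiment fail trivially.

**Transactions** emulate heavily imbalanced fraud tables: standardized
Gaussian-mixture features, a positive label from a logistic model whose
intercept is calibrated by root finding so the marginal prevalence matches
the configured rate (default 0.172%), and a sensitive attribute from a
second logistic model over an overlapping feature subset.

What these generators do *not* emulate: photorealistic histopathology,
spatially correlated noise, multi-scale texture, temporal transaction
structure, or covariate shift.  Passing tests show the mechanism separates
*geometrically independent, low-dimensional* factors; they do not show it
would purge, say, scanner signatures from real micrographs.

## Baselines

* **Mondrian k-anonymity** — greedy recursive median splits on the
  widest-range quasi-identifier (stable tie-break, lower median left),
  stopping when a split would leave a side below k; leaf values are
  replaced by interval midpoints.  The ≥ k class-size postcondition is
  machine-checked exhaustively in the tests.
* **k-Same** — greedy nearest-neighbour grouping in pixel space into
  exactly ⌊n/k⌋ groups (leftovers join their nearest centroid), each image
  replaced by its group mean.
* **Gaussian mechanism** — input perturbation with
  σ = Δ·sqrt(2·ln(1.25/δ))/ε after clipping to the sensitivity bound;
  images are re-clipped to [0, 1].

## Numerical choices and edge cases

* PSNR of identical inputs returns an `inf` sentinel, not an exception.
* SSIM uses the standard constants (11×11 Gaussian window, σ=1.5,
  K1=0.01, K2=0.03) via scikit-image; the test oracle is an independent
  direct Gaussian-filter computation.
* F1 with no positive predictions and no true positives is reported as 0
  with a `f1_degenerate` flag.
* Splits use the floor rule (train size = ⌊n·fraction⌋).
* Checkpoints are a single JSON document (spec + base64 arrays) whose
  bytes are write→read→write stable; datasets round-trip as PNG + CSV
  manifest (images, 8-bit quantisation on first save) or full-precision
  CSV (tabular).
* Batches with fewer than 2 samples are skipped (batch norm needs ≥ 2);
  single-class batches skip the matching term.

## Problem sizes used by the test suite and acceptance script

The reference purge experiment uses 2000 32×32 images, 20 epochs; the
privacy-weight sweep uses 600 16×16 images, 10 epochs, 3 seeds per weight;
the Monte-Carlo noise check uses 10⁶ draws.  These sizes were chosen to
make the full suite reproducible on a single CPU core in minutes while
keeping every statistical margin comfortable.

## Known limitations

* Protection is empirical, not certified; no formal differential-privacy
  accounting is attempted (out of scope by design).
* The adversarial equilibrium degrades texture reconstruction at high
  gamma — by construction: information the attacker cannot find is also
  unavailable to the decoder unless routed through Z_s.
* Tabular obfuscation quality is judged by downstream metrics only; no
  fidelity analogue of PSNR/SSIM is defined for feature vectors.
* The text modality (transformer encoder/decoder) is not implemented.
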