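# Methods

This note documents the models, the numerical choices, what the synthetic
generators emulate, and the limits of what passing tests demonstrate.

## Structure metrics

**TM-score.** For aligned Cα pairs with distances `d_i` under a rigid
superposition, `TM = (1/L_ref) Σ 1/(1 + (d_i/d0)²)` with
`d0 = 1.24·(L_ref − 15)^{1/3} − 1.8` Å.  Normalization is by the reference
length (a deliberate choice; target-, query- and average-length
normalizations exist in the wild, and the difference vanishes for the
equal-length pairs produced by the distillation pipeline).  `d0` is clamped
below at 0.5 Å: the cube-root formula is non-positive for `L_ref ≤ 21` and
the clamp keeps toy-sized inputs well defined.

The score is the maximum over a deterministic family of superpositions:
Kabsch fits seeded from the full correspondence and from its two halves,
each refined by repeatedly keeping the pairs within a distance cutoff
(8, then 6, then 4 Å, at most 20 iterations each) and re-fitting, until the
inlier set stabilizes.  This bounded search is reproducible bit for bit; on
small, moderately perturbed pairs it attains the same optimum as an
exhaustive search over all contiguous-fragment seeds plus random rigid
restarts (verified in the acceptance checks).  For strongly divergent
structures the true TM optimum may involve inlier subsets this family never
visits, a standard property of all practical TM implementations.

**LDDT.** Superposition-free.  A reference pair (i, j), i ≠ j, is included
when its reference Cα distance is below the 15 Å inclusion radius; it is
preserved at tolerance t when the model reproduces the distance within t.
The per-residue score is the preserved fraction of that residue's included
pairs, averaged over the four standard tolerances {0.5, 1, 2, 4} Å; the
global score is the mean over residues (so it equals the per-residue mean
by construction).  Residues with no included pair are excluded from the
global mean and logged.  Cα-only is the default, matching backbone-level
distillation labels; an all-atom mode uses `atom_records` when present.
Strict inequalities are used on both the inclusion radius and the
tolerances; this convention matters only on sets of measure zero but is
fixed and documented so independent implementations can agree exactly.

**Residue correspondence** is positional.  Distillation pairs share a
sequence, so no alignment search is needed or provided.

**Core/surface classes.** A residue with ≥ 24 other Cα atoms within 10 Å is
core, ≤ 16 is surface, anything between is intermediate.

## Score discretization

Scores live in the open interval (0, 1) and are discretized into 50
equal-width bins (half-open, final bin closed; exact endpoint values nudged
inward by one machine epsilon).  The inverse map returns bin centers, so
the round-trip error is at most half a bin width (0.01).  pLDDT values on
the 0–100 reporting scale are converted at the IO boundary
(`plddt_to_unit` / `plddt_from_unit`).

## Dataset curation

The curation ops mirror how confidence-scored training sets are built from
a structure database: (1) similarity filtering against held-out evaluation
splits at a 40 % threshold — the cheap default is a 3-mer containment proxy
(fraction of the query's 3-mers present in a holdout sequence), which is
exact for identical sequences; an exact global-identity mode
(Needleman–Wunsch, match 1 / mismatch 0 / gap 0, normalized by query
length) is provided for short sequences; (2) random contiguous cropping to
a maximum length of 500, with per-residue scores cropped in register;
(3) sequence-perturbation augmentation (segment permutation or replacement
covering a chosen fraction of the length) which deliberately returns
*unscored* records — augmented sequences acquire scores only from an
external scorer, never fabricated; (4) balance filtering that keeps all
low-score records and a fixed fraction of high-score ones; and
(5) inverse-bin-frequency sampling weights so that minibatch exposure is
uniform over occupied score bins.

## The distillation model

The reference architecture is a small encoder trainable on one CPU in
seconds to minutes: learned 24-dimensional token embeddings over the
20 amino acids plus X; per-position features concatenating the embedding
with windowed means at half-widths 2 and 5; a tanh MLP (64 hidden units)
per position producing 50-bin logits (the pLDDT-style track); and the same
feature vector mean-pooled over positions feeding a second MLP for the
sequence-level 50-bin logits (the pTM-style scalar head, the counterpart of
a first-token readout).  About 16k parameters.  Forward and backward passes
are explicit numpy; the backward pass returns the gradient with respect to
the *input probability matrix*, which is what lets the SC regularizer reach
a generator.  Any model exposing the same forward contract can be plugged
in; the architecture here is sized for desk-scale experiments, not for
competing with large pretrained protein language models.

Training discretizes each target score into its bin label and minimizes
focal loss `−(1 − p_t)^γ log p_t` with γ = 2 by default (γ = 0 recovers
cross-entropy exactly; the true-class probability is clamped at 1e-12
before the log).  Minibatches are drawn with the inverse-frequency weights;
validation uses plain cross-entropy each epoch, and the parameters from the
best validation epoch are restored.  Optimization is Adam (lr 3e-3, β =
0.9/0.999); every random draw descends from the config seed, so runs are
bit-reproducible.  The scalar readout of a 50-bin logit vector is the
softmax-weighted mean of bin centers — smooth in the logits, shift
invariant, bounded strictly inside (0, 1); argmax-bin-center is available
for reporting.

## The SC regularizer

`L = L_CE + α·L_SC` with `L_SC = Σᵢ (1 − SC(ŝᵢ))` and α = 1 as the standard
setting.  The distill model is always frozen during downstream training.
Three scoring modes are provided, because how gradients should cross a
discrete generated sequence is genuinely open: **soft** (default) feeds the
generator's per-position probability rows as probability-weighted
embeddings, making SC smooth in the generator's distributions; **hard**
embeds discrete tokens (no generator gradient); **straight_through** scores
the argmax sequence forward but propagates the soft gradient backward.
Per-residue (pLDDT-style) scores are reduced to one scalar per sequence by
the unweighted mean before entering the objective.

## Synthetic generators: what they emulate, and what they do not

**Backbones.** Ideal α-helix geometry (1.5 Å rise, ~3.6 residues/turn,
2.3 Å radius), extended chains (3.5 Å spacing with a small zigzag to avoid
collinearity), and self-avoiding random coils (3.8 Å steps, 3.4 Å clash
threshold, direction persistence).  These reproduce Cα-chain geometry well
enough to exercise superposition, TM, LDDT and neighbor-density code; they
are not physically realistic proteins (no secondary-structure statistics,
no side chains, no compact hydrophobic cores, hence few genuinely "core"
residues at coil scale).

**Score oracles.** A per-residue score is a logistic of the mean
coefficient of the residues in a ±4 window; the sequence score is the mean
of the track (the same way mean-pLDDT summarizes a per-residue track).
`make_oracle(seed)` draws random coefficients for property tests.  The
canonical fixed oracle (`hydropathy_oracle`) uses the Kyte–Doolittle
hydropathy scale normalized to [−1, 1] with gain 5 — a fixed, interpretable
"windowed hydrophobic fraction" signal.  Real folding-confidence scores
depend on long-range structure; this oracle is local by construction, so
recovering it demonstrates that the distillation pipeline works, not that
local composition predicts real foldability.

**The toy design task.** Each residue is bucketed by neighbor density
(counts within 10 Å at thresholds 6/10) × local geometry (the i−2…i+2 span
under 9 Å is "bent"), giving six classes; a fixed planted rule maps each
class to one preferred amino acid, corrupted independently at the noise
rate (default 0.2).  The features exposed to the designer are rotation- and
translation-invariant (neighbor counts at 6/8/10 Å, local span and
neighbor distances, relative chain position), so the task cannot be solved
by coordinate memorization.  Two properties are deliberate: the rule
residues are all polar/charged (N, D, G, E, S, K — surface/loop-like
preferences), so the hydropathy oracle's preference is genuinely distinct
from the task's ground truth.  If the two aligned, "consistency guidance"
would be indistinguishable from extra reconstruction signal and the
regularization experiment would measure nothing.  A contiguous mask span
per record supports the infilling variant.

## Designer training protocol

The toy designer is a per-position MLP (8 features → 48 hidden → 20
classes, ~1.4k parameters) trained with per-position mean cross-entropy.
Training runs in two phases under one seed and minibatch schedule: a
reconstruction phase (15 epochs, CE only) and a consistency fine-tuning
phase (1 epoch by default) in which the SC term is active, each phase with
a freshly initialized Adam optimizer.  Applying SC as a brief fine-tune of
the converged designer keeps the regularizer a perturbative nudge.  This is
a real finding at toy scale, documented as a limitation: if the SC term is
instead trained jointly from scratch at α = 1 against a position-mean CE,
the frozen distill model's coherent input gradient eventually dominates the
converged CE equilibrium and the designer collapses toward pure
high-confidence sequences (recovery drops by ~15 points).  Large inverse
folding models with rich structural encoders and large datasets anchor the
CE term far more strongly; the tiny designer does not.  With α = 0 the SC
gradient contribution is exactly zero, so the two-phase trajectory is
bit-for-bit identical to unregularized training — the regularizer can be
audited by switching it off.

## Problem sizes used in the shipped experiments

Distillation parameter recovery trains on 2,000 oracle-scored random
sequences of length 30–80 (three seeds; held-out Pearson for the scalar
head, held-out MAE for the per-residue track).  The regularization
experiment uses one distill model (1,500 sequences, 12 epochs), five
designer seeds, 500 training backbones at noise 0.2, and evaluates 16
sampled decodes on 40 fresh backbones per seed.  These sizes were chosen so
the full suite runs in minutes on one CPU while leaving each effect
comfortably measurable.

## Known limitations

- The TM superposition search is bounded and can undershoot the true
  optimum for strongly divergent pairs (see above).
- The oracle is local; nothing here validates sequence→confidence
  prediction on real proteins.
- The designer is deliberately tiny; its absolute recovery numbers are
  specific to the planted task and say nothing about real inverse folding
  benchmarks.
- Similarity filtering's 3-mer proxy over-estimates similarity for
  low-complexity sequences (many shared trivial 3-mers); use the identity
  mode when that matters.
- Per-residue training masks nothing beyond sequence length; there is no
  padding machinery because batches are processed per sequence.
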