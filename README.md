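# scdistill

Structure-consistency scoring and distillation for protein sequence design.

## The problem

Inverse protein folding — designing an amino-acid sequence that folds into a
given 3D backbone — is usually trained with a sequence reconstruction loss
alone, which rewards recovering the one deposited sequence and under-rewards
the many *other* sequences that would fold equally well.  Forward folding
models could grade candidate sequences during training, but they are far too
slow to sit inside an optimization loop, and their structure outputs are not
practically differentiable.

`scdistill` implements the alternative: distill a folding model's
*confidence* metrics — the global pTM score and the per-residue pLDDT track —
into a small, fast sequence→score model, then use that frozen model as a
differentiable **structure-consistency (SC)** regularizer.  The design
objective becomes

```
L = L_CE + α · L_SC,        L_SC = Σᵢ (1 − SC(ŝᵢ)),    α = 1 by default,
```

where `SC(ŝ) ∈ (0,1)` is the distilled model's confidence score for a
generated sequence `ŝ`.  Because the SC model is differentiable down to its
input token probabilities, the regularizer passes gradients into the
generator, nudging it toward sequences that look structurally plausible —
which raises design *diversity* while maintaining *recovery*.

The toolkit is written to be exercised end to end at desk scale: every stage
has a synthetic counterpart (toy Cα backbones, perturbed structure pairs,
a fixed sequence→score oracle, a planted structure→sequence design task) so
the whole pipeline runs on a laptop CPU in minutes with no downloads.

## What is in the box

| module | contents |
|---|---|
| `scdistill.structure` | PDB read/write (Cα chains), Kabsch superposition |
| `scdistill.metrics` | TM-score (d0 = 1.24·(L−15)^⅓ − 1.8, iterative superposition refinement), LDDT (15 Å inclusion radius, tolerances {0.5, 1, 2, 4} Å), core/surface neighbor-density classes |
| `scdistill.binning` | 50-bin discretization of scores in (0,1) and its inverse |
| `scdistill.data` | scored-sequence records (JSONL/CSV/FASTA), 40 % similarity filtering, random cropping to length 500, perturbation augmentation, score balancing, inverse-frequency sampling weights |
| `scdistill.model` / `scdistill.train` | small sequence encoder with scalar (pTM-style) and per-residue (pLDDT-style) heads over the 50-bin vocabulary; focal-loss training with weighted sampling |
| `scdistill.regularizer` | the SC loss, soft / hard / straight-through scoring of generated sequences, analytic input gradients |
| `scdistill.evaluate` | recovery, diversity, perplexity, per-class (core/surface) breakdowns |
| `scdistill.synthetic` | backbone generators, graded perturbation, score oracles, the toy design task |
| `scdistill.designer` | a toy structure-conditioned designer trained with optional SC regularization |
| `scdistill.cli` | `scdistill score / curate / distill-train / distill-predict / train-designer / evaluate / fixtures` |

## Worked example

Train a distillation model on oracle-scored sequences and use it to
regularize the toy designer:

```python
import numpy as np
import scdistill as sd
from scdistill.synthetic import hydropathy_oracle

# 1. oracle-scored training data (random sequences, fixed planted signal)
oracle = hydropathy_oracle()
rng = np.random.default_rng(100)
records = sd.generate_synthetic_scored(1500, oracle, length_range=(30, 80), rng=rng)

# 2. distill the oracle into the small scalar-confidence model
model, report = sd.train_distill(
    records, sd.DistillConfig(target_kind="scalar", epochs=12, seed=0))
print(f"best val CE {min(report.val_losses):.3f}")          # 1.628

seq = records[0].sequence
print(f"oracle {oracle.score(seq):.3f}  predicted {sd.predict_ptm(model, seq):.3f}")
# oracle 0.228  predicted 0.233

# 3. train the toy designer with and without SC regularization
task = sd.make_design_task(500, noise=0.2, rng=np.random.default_rng(1000))
plain, _ = sd.train_designer(task, sd.DesignerConfig(alpha=0.0, seed=0))
reg, _   = sd.train_designer(task, sd.DesignerConfig(alpha=1.0, seed=0),
                             distill_model=model)

# 4. compare 16-sample decodes on fresh backbones
ev = sd.make_design_task(40, noise=0.2, rng=np.random.default_rng(5000))
for name, designer in [("alpha=0", plain), ("alpha=1", reg)]:
    er = np.random.default_rng(77)
    rec, div = [], []
    for i in range(len(ev)):
        samples = designer.sample(ev.features[i], 16, er)
        rec.append(np.mean([sd.recovery(s, ev.sequences[i]) for s in samples]))
        div.append(sd.diversity(samples))
    print(f"{name}: recovery {np.mean(rec):.1f}  diversity {np.mean(div):.1f}")
# alpha=0: recovery 55.6  diversity 46.9
# alpha=1: recovery 54.7  diversity 48.2
```

Recovery is the percentage of positions matching the ground-truth sequence;
diversity is 100 minus the mean pairwise recovery among the 16 samples.  The
SC-regularized designer trades a small amount of recovery for a clear
diversity gain — the behavior the regularizer exists to produce.

Scoring structures from the shell:

```bash
scdistill fixtures --out fixtures --seed 7        # toy PDBs + scored JSONL
scdistill score --model fixtures/backbone_0_helix.pdb \
                --reference fixtures/backbone_0_helix.pdb
# tm=1.0000 lddt=1.0000
```

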