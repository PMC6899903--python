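# contactnet

Residue–residue contact prediction from multiple sequence alignments with
a dilated, fully convolutional residual network — a desk-scale,
fully tested implementation of the MetaPSICOV/DeepCov-lineage
contact-prediction stack, including its feature construction, training
protocol, data augmentations, and CASP-style evaluation.

## Who this is for

Structural bioinformaticians who want a transparent, hackable reference
implementation of covariation-based contact prediction: every stage — MSA
encoding, sequence weighting, the 441-channel covariance tensor, mutual
information with APC, the 501-channel input assembly, the dilated ResNet,
masked-loss training with augmentation, and top-L/k assessment — is a
small, tested NumPy module rather than a framework black box.

## The model

For a protein of length *L* with an MSA, the predictor scores every
residue pair (i, j) with the probability that Cβᵢ–Cβⱼ ≤ 8 Å:

* **Features (501 × L × L).** Per-residue features (21-state profile,
  3-state secondary structure, solvent accessibility, column entropy)
  striped horizontally and vertically; pairwise maps (mutual information
  *I(i,j)* in nats, its average-product-corrected form
  *I − mean_i·mean_j / mean_all*, a contact-potential map, optional
  PSICOV/CCMpred/FreeContact couplings); the 441 raw covariances
  *f_ij(a,b) − f_i(a)f_j(b)* over the gap-inclusive alphabet; and
  sequence-separation and all-ones bounds channels.
* **Network.** A convolutional Maxout layer reduces 501 → 64 channels;
  18 residual blocks of two 5 × 5 convolutions with dilation rates
  alternating through 1, 2, 4, …, 64 grow the receptive field past 1000
  residues; a 1 × 1 sigmoid head emits the score map, symmetrized as
  *(s(i,j) + s(j,i))/2* and averaged over a 5-model ensemble.
* **Training.** Masked binary cross-entropy (|i−j| ≥ 5), Adam at 0.001,
  Xavier-uniform init, batches of 8 with per-example gradient
  accumulation (no padding across lengths), three on-the-fly
  augmentations (loop-residue deletion, deep/shallow alignment-tensor
  interpolation *x′ = m·x₁ + (1−m)·x₂*, 180° flips), and early stopping
  on validation Matthews correlation.

Because real structure databases are out of scope at desk scale, the
package ships a first-class synthetic generator: helix-bundle toy
structures and Gibbs-sampled sequence families whose column covariation
is elevated exactly at contact positions (see `docs/methods.md`).

## Worked example

Generate a synthetic family, inspect alignment depth, and measure how
much contact signal the alignment statistics alone carry:

```python
import numpy as np
from contactnet import make_family, pair_matrices
from contactnet.pipeline import family_to_example
from contactnet.evaluation import topk_precision

rng = np.random.default_rng(4)
fam = make_family(L=60, n_deep=200, n_shallow=20, rng=rng, coupling_strength=2.0)
ex = family_to_example(fam)
print("channels:", ex.x.C, " alignment depth:", fam.msa_deep.N)

pm = pair_matrices(fam.msa_deep)
print("top-L/5 long-range precision of APC-corrected MI alone: "
      f"{topk_precision(pm.mi_apc, ex.y, 5, 'long'):.1f}%")
```

```
channels: 501  alignment depth: 200
top-L/5 long-range precision of APC-corrected MI alone: 100.0%
```

The assembled tensor has the full 501 channels, and at coupling strength
2 with 200 sequences the APC-corrected mutual information already ranks
the 12 (= ⌊60/5⌋) strongest long-range predictions perfectly — the
covariation signal the network is trained to exploit, here visible before
any learning.  The same objects feed training
(`contactnet.training.train`) and ensembling
(`contactnet.network.ensemble_predict`).

The same workflow from the shell:

```console
$ contactnet synth --out demo --n-families 1 --length 60 --n-deep 200 --n-shallow 20 --seed 4
$ contactnet meff demo/family000/deep.aln --format psicov
200
$ contactnet table
{"mean_precision": 66.18, "n_rows": 43}
$ contactnet table --meff-max 50
{"mean_precision": 57.88, "n_rows": 16}
```

`meff` is the effective sequence count (greedy 62%-identity clustering);
`table` aggregates the packaged CASP13 FM/FM-TBM domain benchmark: a mean
top-L/5 long-range precision of 66.18% over all 43 domains, and 57.88%
over the 16 domains whose alignments have Meff ≤ 50.  Other subcommands:
`train`, `predict` (writes CASP RR + flat score matrix), `evaluate`.

## Layout

| Module | Contents |
| --- | --- |
| `msa_io` | FASTA / A3M / PSICOV-flat readers, integer encoding, one-hot |
| `meff` | pairwise identity, greedy 62% clustering, Meff |
| `pair_features` | sequence weights, f₁/f₂, 441-channel covariance, MI/APC/entropy |
| `features` | striping, separation/bounds channels, 501-channel assembly, ss2 reader |
| `augment` | loop sampling, feature interpolation, 180° flips, batch assembly |
| `nn`, `network` | NumPy conv/Maxout/instance-norm engine; the ResNet, symmetrize, ensemble, checkpoints |
| `training` | masked BCE, MCC, Adam loop with gradient accumulation and early stopping |
| `evaluation` | top-L/k precision, benchmark-table aggregation, RR I/O, domain splicing |
| `synthetic` | toy structures, coupled MSAs, deep/shallow family pairs |
| `cli` | `contactnet` command-line entry points |
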