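# Methods

## Problem and model

`contactnet` predicts residue–residue contacts (Cβ–Cβ ≤ 8 Å, Cα for
glycine) for a protein of length L from a multiple sequence alignment
(MSA).  The predictor is a deep, fully convolutional residual network in
the MetaPSICOV/DeepCov lineage: it consumes a 501-channel L × L input
tensor and emits an L × L map of contact probabilities, so it handles any
sequence length with one set of weights.

### Input features (501 channels)

Alignment- and residue-level statistics (58 channels):

* **Striped per-residue features.** Each per-residue feature vector v is
  converted into two L × L maps, one constant along rows (`out[i,j] =
  v[i]`) and one along columns (`out[i,j] = v[j]`).  Striped groups: the
  21-state sequence profile (42 channels), 3-state secondary structure
  H/E/C (6), relative solvent accessibility (2), and profile column
  entropy (2).
* **Pairwise maps (6 channels).** Plug-in mutual information (nats), its
  average-product-corrected form (APC: subtract `mean_i · mean_j /
  mean_all` over off-diagonal entries), a mean contact-potential map, and
  three externally computed coupling maps (PSICOV / CCMpred / FreeContact
  style flat matrices).  External maps are inputs, not computations; when
  absent they are zero-filled with a warning and flagged in the tensor
  metadata.

Raw covariances (441 channels): for every residue-type pair (a, b) over
the 21-state alphabet (20 amino acids + gap),

    cov[(a,b), i, j] = f_ij(a,b) − f_i(a) f_j(b),

where f are sequence-weighted column frequencies.  Sequences are weighted
by inverse 62%-identity neighbourhood size before counting (the DeepCov
convention); unweighted counting is available behind a flag.

Geometry channels (2): a sequence-separation channel
`min(|i−j|, 100)/100` (the saturation constant is a configurable package
choice — the encoding keeps inputs bounded) and an all-ones *bounds*
channel that lets the first convolution distinguish genuine zeros in the
data from zeros introduced by padding.

The 58-channel layout above is a reconstruction: published descriptions
of this feature lineage fix the group inventory and the total (58) but
not an exact ordering, and our inventory is one channel over when a
separate joint-entropy map is included.  We therefore carry MI, APC-MI
and the two striped column-entropy channels and leave the joint-entropy
map out of the default manifest (it remains available from
`pair_features.mutual_information`).  The entire layout lives in one
manifest (`features.channel_manifest`) so consumers never hard-code
positions.

The contact-potential table shipped with the package is a **synthetic
stand-in**: the negated outer product of normalized Kyte–Doolittle
hydropathies.  It is not a published knowledge-based potential; it merely
behaves like one (symmetric, hydrophobic-pair favouring) so the channel
is populated with a structure-relevant signal.

### Architecture

* Convolutional **Maxout** input layer reducing 501 → width (default 64)
  channels with 2 pieces, followed by instance normalization.  The input
  layer uses a 1 × 1 kernel by default: its role is channel
  mixing/dimensionality reduction, while spatial context is supplied by
  the residual stack (kernel size configurable).
* 18 **residual blocks**, each two 5 × 5 convolutions with ReLU and an
  identity skip connection (`out = ReLU(conv2(ReLU(conv1(x))) + x)`).
  Both convolutions share the block's dilation rate.  The default
  schedule alternates regular and dilated blocks with increasing rates —
  (1, 2, 1, 4, 1, 8, 1, 16, 1, 32, 1, 64) — followed by six regular
  blocks.  The receptive field is 1 + Σ 2·4·d = 1105 residues, covering
  any realistic protein.
* Output head: 1 × 1 convolution to one channel, instance normalization,
  sigmoid.  Predictions are symmetrized by averaging scores at (i, j) and
  (j, i); final predictions average an ensemble of independently seeded
  models.
* No normalization inside residual blocks; the first block's skip is an
  identity (the input is already at working width).

Weights are Xavier-initialized from the uniform distribution.  The
default configuration has 3,753,155 parameters.

## Training

* **Loss**: binary cross-entropy over upper-triangle residue pairs with
  sequence separation ≥ 5; probabilities clamped to [1e-7, 1−1e-7].
  During training the logit map is symmetrized (`z_sym = (z + zᵀ)/2`)
  before the sigmoid so both triangles receive gradient and the training
  objective matches the symmetrized inference rule; at inference,
  probabilities are averaged over (i,j)/(j,i).
* **Optimization**: Adam at lr 0.001 (other hyperparameters at library
  defaults).  Batches of 8 examples; each example is forwarded
  individually and its gradient accumulated, then one optimizer step per
  batch — examples of different lengths never need padding.  The batch
  loss is the mean of per-example mean losses, so long proteins do not
  dominate.
* **Validation / early stopping**: Matthews correlation coefficient at a
  0.5 threshold over the same separation mask, computed per protein and
  averaged.  Training stops after `patience` (default 10) consecutive
  epochs without improvement and returns the best-MCC weights (latest
  among exact ties).
* **Augmentations**, applied on the fly per batch:
  1. *Loop sampling* — each loop residue (no helix/strand assignment) is
     deleted with probability 0.3 (rows/columns removed from every
     channel and the contact map; the separation channel is rebuilt for
     the new length); applied with probability 0.5 and only when ≤ 40% of
     residues are loop.  Deletion (not masking) is implemented — the
     separation recomposition only makes sense under resizing.  Stripes
     are excised rather than rebuilt; the two are equivalent and this is
     asserted by test.
  2. *Feature interpolation* — `x′ = m·x₁ + (1−m)·x₂` with one uniform
     scalar m per example, mixing the tensors built from a deep and a
     shallow alignment of the same protein; the target map is never
     interpolated.  Applied whenever a paired tensor exists (probability
     configurable).
  3. *180° flipping* — both spatial axes of inputs and targets reversed
     (chain-direction reversal); one coin per batch with probability 0.5,
     appending flipped copies to the batch.

## Effective sequence count (Meff)

Meff is the number of clusters from CD-HIT-style greedy clustering at 62%
identity: rows sorted by descending non-gap length (ties by input order),
each row joins the first representative it matches at ≥ 62% identity,
where identity = identical non-gap matches / shorter non-gap length.
The word-size prefilter of CD-HIT is treated as an optimization, not part
of the statistic's definition, and is not implemented; equivalence with
the plain greedy scan is what the tests assert.  Whether to de-gap rows
first only affects the identity denominator and is configurable through
the identity function.

## Evaluation

Top-L/k precision (k ∈ {1, 2, 5, 10}): percentage of true contacts among
the floor(L/k) highest-scoring eligible pairs (minimum 1; deterministic
tie-break by descending score then ascending (i, j)).  Ranges follow the
CASP convention: long |i−j| ≥ 24, medium 12–23.  Score maps travel in
CASP RR format (`i j 0 8 p`, 1-based) or flat whitespace matrices.
Domain splicing copies the scores predicted for a putative domain
(a ≥ 30-residue template-free region) back into the full-length map over
the segment's square block.  A packaged benchmark table of 43 CASP13
FM/FM-TBM domains supports filtered aggregation (mean precision, row
counts).

## Synthetic data

The generator supplies desk-scale stand-ins for structure-derived
training data:

* **Toy structures**: alternating helix (10–16 residues) and loop (3–6)
  segments; helices are ideal (1.5 Å rise, 100°/residue, side-chain
  radius 2.9 Å) and packed antiparallel around a bundle circle with
  10.5 Å between neighbouring axes; loops are bowed arcs.  Structures are
  rejected and resampled until self-avoiding (≥ 3.5 Å for |i−j| ≥ 3) with
  at least one long-range contact.
* **Coupled MSAs**: sequences Gibbs-sampled (4 sweeps) from a Potts-like
  model with per-column Gaussian fields and, at every contact with
  |i−j| ≥ 5, a compatibility bonus of `coupling_strength` whenever
  (a, b) satisfies b = perm(a) for that contact's random one-to-one
  compatibility permutation.  Couplings are restricted to |i−j| ≥ 5 so
  the learnable signal lives inside the loss mask.  Gaps are injected at
  rate 0.05 in loop columns (never in the query row).
* **Families**: a deep MSA plus a shallow random row-subsample (query
  retained), the stand-in for alignment pairs of differing quality used
  by feature interpolation.  Per-residue features come from the
  generator's ground truth: profile = empirical column frequencies, ss3 =
  smoothed one-hot true labels (0.9/0.05/0.05), solvent accessibility = a
  distance-from-centroid burial proxy.

What the fixtures do *not* emulate: realistic amino-acid composition,
phylogenetic correlation between sequences, alignment errors, indels
outside loops, or real protein energetics.  Passing the synthetic
benchmark shows the pipeline can extract covariation signal end to end;
it says nothing quantitative about precision on real proteins.

## Numerical choices and degenerate inputs

* MI/entropy sums run over cells with f₂ > 0 only; a positive joint cell
  forces positive marginals, so no flooring is needed.  MI is clipped at
  0 against −1e-16-scale rounding.  All information quantities are in
  nats.
* The identity denominator for all-gap rows is 0; their pairwise identity
  is defined as 0.
* Loop sampling never deletes the last residue (at least one survives);
  proteins shorter than the separation mask raise rather than return an
  empty loss.
* MCC returns 0 when any confusion-matrix margin is 0.
* The network runs in float32 by default (configurable; the
  gradient-equivalence tests use float64).
* Checkpoints embed the model config and the feature channel map and
  refuse to load against mismatched channel maps.

## Scaled-down benchmark

The training-recovery test uses 30 training and 10 held-out families
(L = 60, 300-sequence alignments, coupling strength 2), a reduced model
(width 16, 4 blocks, dilations 1, 2, 4, 1), 12 epochs, and 3 training
seeds; the held-out families also serve as the early-stopping validation
set (a third split would cut into the stated 30 training families).
These problem sizes are the package's desk-scale choice; the same code
paths scale to full-size models unchanged.

## Known limitations

* The NumPy engine is CPU-only and single-example; it is written for
  clarity and desk-scale experiments, not production training throughput.
* The 58-channel manifest is a reconstruction (see above), and the
  contact-potential table is synthetic.
* Greedy clustering is order-canonicalized but not guaranteed to
  byte-match CD-HIT on adversarial inputs.
* External coupling maps are consumed, never computed.
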