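# Methods

## Model

`pocketformer` encodes binding pockets and small molecules as typed 3D
atom graphs and learns their interaction with a dual-track graph
transformer.

**Inputs.** An atom is a vocabulary code (element symbol only: C, N, O,
S, P, F; hydrogens are dropped on input) plus Cartesian coordinates in
Angstrom. Molecules carry chemical bonds (single/double/triple/
aromatic); pockets carry none, but retain per-atom residue labels for
the residue-level inclusion and filter rules. Four reserved vocabulary
codes exist for virtual tokens, one per (CLS/ENCODE x pocket/molecule).
A virtual token sits at the unweighted centroid of the real atoms and
has no bond records; its "connection to all atoms" exists only through
the fully connected pair representation.

**Two feature tracks.** Atom features `a_i` start from the type
embedding. Pair features `q_ij` (one scalar channel per attention head,
H channels total) start from a Gaussian RBF expansion of squared
inter-atomic distances

    K_g(x_i, x_j) = exp(-gamma_g * ||x_i - x_j||^2),

with a fixed log-spaced bank of G = 16 gammas in [0.01, 10] A^-2,
linearly projected G -> H, plus a learned bond-type embedding (the
no-bond embedding is the zero vector). Because `q^0` depends only on
distances and bond types, it is an SE(3)-invariant positional encoding.

**Blocks.** Each of L layers runs pair-biased multi-head attention —
per head h, `logits_ij = (Q_i . K_j)/sqrt(d/H) + q_ij[h]`, masked
softmax, value aggregation — followed by residual + layer norm, a ReLU
feed-forward block with residual + layer norm, and atom-to-pair
communication: the block's scaled pre-softmax, pre-mask query-key
logits are added back into the pair track,
`q^{l+1}_ij[h] = q^l_ij[h] + (Q_i^h . K_j^h)/sqrt(d/H)`. One scaling
convention (per-head dimension) is used in both places.

**Heads.**

* *Contrastive projections*: linear maps `g_P`, `g_M` (d -> k = 128),
  L2-normalized, dot product similarity in [-1, 1], temperature
  parameterized as `tau = exp(theta)` with `tau_0 = 0.07`.
* *Matching classifier*: a linear map on the ENCODE-token embedding of
  a joint pass, two logits (matched / unmatched).
* *Coordinate head* (SE(3)-equivariant):
  `c_ij = ReLU((q^L_ij - q^0_ij) U) W` (scalar per ordered pair, hidden
  width 64, no biases so an unchanged pair track proposes zero
  movement), then `x_i <- x_i + (1/n) sum_j (x_i - x_j) c_ij` with j
  over all real atoms in context (pocket + molecule) and n that count.
  Only real molecule atoms move.
* *Distance head*: an MLP on symmetrized pair features with a softplus
  positivity map; diagonal forced to zero.

Joint passes concatenate pocket and molecule atoms into one fully
connected set (no bond features across entities) and run through the
molecular encoder; separate passes use each entity's own encoder with a
CLS token.

**Docking score.** The score of a pose is the *negative mean
displacement* the coordinate head proposes for the ligand at that pose.
A docking-trained model proposes large corrections far from the binding
mode and almost none at it, so "little proposed movement" ranks poses;
this also makes the score a pure function of the trained docking
objective rather than a separate untrained head.

## Objectives

For a batch of N matched pairs:

* **Contrastive** `L_pmc`: symmetric InfoNCE over the N x N projected
  CLS similarity matrix divided by tau; mean of pocket-to-molecule and
  molecule-to-pocket cross-entropies against the diagonal.
* **Matching** `L_pmm`: binary cross-entropy of the ENCODE classifier
  over all N positives plus 2N hard negatives — for each pocket one
  non-matching molecule drawn with probability proportional to the
  softmax of its off-diagonal similarity (an argmax variant exists),
  and symmetrically one pocket per molecule. All molecules in matching
  passes are recentered at the pocket centroid, so the classifier
  measures *compatibility*, not pose quality; this is what lets the
  matching score transfer to target fishing, where a candidate pocket's
  bound pose is unknown.
* **Docking** `L_intra + L_inter`: the ligand enters the joint pass at
  its *stored* input pose (for fine-tuning, a fixed decoy start); the
  coordinate head's output is penalized by a Huber loss (delta = 1 A)
  on all unordered intra-molecular distance errors and by the mean
  squared coordinate deviation (A^2) from the true pose.

The total is the unit-weight sum. Expectations over the pair
distribution are mini-batch means.

## Optimization

AdamW with decoupled weight decay 0.05 (normalization gains, biases and
the temperature exempt); learning rate ramps linearly from 0 over the
warm-up, then cosine-anneals to the minimum. The reference schedule is
a 1000-step warm-up with peak 1e-4 and minimum 5e-6. Parameters whose
gradient is absent in a step (objective masking) are left completely
untouched. Everything runs in float32 on one thread with fixed
summation order, so training trajectories, generator outputs and
checkpoints are bit-reproducible; checkpoints use a deterministic
container (JSON header + raw array bytes) whose digest is stable across
repeated saves.

## Synthetic lock-and-key data

The generator emulates the matched-pair structure the objectives
assume. Pocket atoms sit on a partial spherical shell (7 A) around a
cavity (4 A); the ligand is a self-avoiding chain (1.5 A steps, >= 1.2 A
non-adjacent separation) grown inside the cavity. Each ligand atom's
element is a fixed permutation ("complement") of its nearest pocket
atom's element, assigned before 0.1 A Gaussian jitter; mismatched pairs
swap ligands between pockets; decoy poses are rigid perturbations of
the true pose dialed to a target RMSD by bisection (within 10%).
Defaults: 48 pocket atoms in pseudo-residues of 4, 12 ligand atoms,
6-element vocabulary. A hand-coded nearest-neighbour complementarity
score separates matched from mismatched pairs essentially perfectly,
bounding from above what the learned model can detect.

What this data does *not* emulate: chemical valence, torsional
flexibility, real residue geometry, protonation, water, conformational
ensembles, or the redundancy structure of real benchmark sets. Passing
the toy protocols therefore demonstrates that the architecture and
objectives can extract a planted geometric/chemical complementarity
signal at desk scale — not benchmark-level performance on real
complexes.

## Desk-scale protocols and their problem sizes

All reference experiments use the desk backbone (L = 2, H = 4, d = 64,
G = 16, FFN 128) and run on one CPU core in minutes.

* **Retrieval**: 64 matched pairs, contrastive objective only, 500
  steps, batch 16, peak LR 1e-3; evaluated as top-1 retrieval over the
  full 64 x 64 similarity matrix.
* **Docking overfit**: 8 complexes, two training rows each (native pose
  and a fixed 2 A decoy start), docking objective only, 300 *full-batch*
  steps at an essentially constant LR of 1e-2 (warm-up 10, weight decay
  0, Adam beta2 = 0.99). Full-batch optimization is used because
  mini-batch noise dominates on a 16-row set and slows convergence
  roughly twenty-fold; beta2 = 0.99 lets the second moment adapt within
  the short run; annealing the LR early prolongs the
  zero-displacement plateau some initializations start in. Pose quality
  is measured with a single coordinate-head
  application on the 2 A starts — exactly the map the loss supervises;
  deeper recycling drifts slightly at intermediate poses it was never
  trained on.
* **Docking power**: the same protocol on 16 complexes, then each
  native pose is ranked against 20 rigid decoys at 2-10 A RMSD by
  docking score; success = a pose under 2 A among the top-k.
* **Matching/fishing**: 32 pairs, contrastive + matching, 400 steps,
  batch 16, peak LR 3e-3; each ligand then ranks its own pocket among 8
  candidates by matching probability.
* **Screening**: per-pocket libraries of 6 fresh complementary actives
  and 6 swapped-in decoys, scored by projected-CLS similarity; AUROC,
  BEDROC (alpha = 80.5) and EF (hit-rate-ratio convention, top
  ceil(f*N)) averaged over pockets.

## Numerical choices and edge cases

* Pair channels equal the head count; this is the only dimensionality
  consistent with the bias entering each per-head softmax and each head
  writing one logit back.
* Softmax uses max-subtraction; padding columns get a -1e9 additive
  mask, which underflows to exactly zero weight, making encoder outputs
  independent of padding content.
* Intra-molecular distances use sqrt(. + 1e-12); the Huber branch
  switch is value-based and continuous at |a| = delta.
* An intra loss on fewer than two atoms is defined as zero with a
  warning; empty coordinate-head context is an error.
* Ranking ties break deterministically by item id; duplicate inputs
  produce tied scores.
* Alternate locations in PDB keep the highest-occupancy conformer;
  waters and HETATM records are excluded; pocket inclusion is
  residue-level (no partial residues).

## Known limitations

* The separate-encoder screening route summarizes each entity
  independently, so it cannot express joint geometric correspondence;
  on synthetic libraries its AUROC (~0.7) sits well below the joint
  nearest-neighbour oracle (1.0). This is an information ceiling of the
  CLIP-style route at this scale, not an optimization failure.
* Recycling is available but the coordinate map is only trained
  single-shot; it is not a contraction, so many recycles can drift.
* RMSD is plain atom-order RMSD (synthetic ligands are asymmetric
  chains); no symmetry correction.
* The distance head is architecturally complete and tested for
  symmetry/invariance but is not supervised by the default objectives.
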