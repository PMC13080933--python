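# pocketformer

A multi-task SE(3) graph transformer for protein–ligand interaction:
one backbone, three task modes — **virtual screening**, **target
fishing**, and **docking / pose ranking** — trained jointly with
contrastive alignment, pocket-grounded matching, and geometric docking
objectives. Everything runs at desk scale on a built-in synthetic
lock-and-key complex generator; no downloads, no GPU.

## Who this is for

Researchers who want a small, fully inspectable reference
implementation of the "dual-track" family of structure-aware
protein–ligand models: atom features and pairwise features updated
jointly, with geometry entering as an invariant attention bias and
leaving through an equivariant coordinate head. The package is also a
testbed for the three classical scoring-function roles (screen, fish,
dock) under one set of weights.

## The model in brief

Pockets and molecules are typed 3D atom graphs. Pair features are
initialized from Gaussian RBF-encoded squared distances plus bond-type
embeddings,

$$q^0_{ij} = W\,\big[e^{-\gamma_g \lVert x_i - x_j\rVert^2}\big]_{g=1..G} + \mathrm{BondEmb}(b_{ij}),$$

and act as a per-head additive bias inside self-attention, while each
layer writes its scaled query–key logits back into the pair track.
Virtual CLS/ENCODE atoms at the entity centroid summarize each graph.
Training combines

$$\mathcal{L} = \mathcal{L}_{pmc} + \mathcal{L}_{pmm} + \mathcal{L}_{intra} + \mathcal{L}_{inter},$$

an InfoNCE contrastive loss over projected CLS embeddings (learnable
temperature), a matched/unmatched classifier on the ENCODE token with
hard-negative mining, a Huber loss on intra-molecular distances, and an
MSE loss on ligand coordinates produced by the SE(3)-equivariant update

$$\hat{x}_i = x_i + \tfrac{1}{n}\textstyle\sum_j (x_i - x_j)\,c_{ij},\qquad c_{ij} = \mathrm{ReLU}\big((q^L_{ij} - q^0_{ij})\,U\big)\,W .$$

Poses are scored by how *little* movement the trained coordinate head
proposes. Details, defaults and design rationale: `docs/methods.md`.

## Worked example

```python
import numpy as np
from pocketformer import protocols

# train the docking objective on 8 synthetic complexes (fixed 2 A decoy
# starts), then re-dock the starts and rank native vs 20 decoys
run = protocols.toy_docking_run(seed=1)
print(f"mean pose RMSD  : {run.mean_rmsd:.2f} A")
print(f"loss reduction  : {run.loss_ratio:.0f}x")

power = protocols.docking_power_run(run.model, run.pairs, seed=101)
print(f"top-1 docking power: {power[1]:.0f}%")
```

Output from this exact snippet:

```
mean pose RMSD  : 0.28 A
loss reduction  : 12x
top-1 docking power: 100%
```

The model has memorized eight binding modes: it moves each ligand from
its 2 Å decoy start to within ~0.3 Å of the true pose,
and because it proposes essentially no movement at the native pose, the
native ranks first against every decoy set.

Command-line equivalents (`pocketformer generate-data / train / screen /
fish / dock / evaluate`) operate on SDF/PDB/JSON-lines files; see
`pocketformer --help`.

## Layout

```
src/pocketformer/
  graphs.py      atom graphs, virtual tokens, batching, pocket filter
  fileio.py      SDF / PDB / JSON-lines fixtures
  nn.py          numpy autodiff + AdamW
  backbone.py    RBF pair track, pair-biased attention, heads
  model.py       two encoders + projection / matching / coordinate heads
  objectives.py  contrastive, matching (hard negatives), docking losses
  synthetic.py   lock-and-key generator, decoys, datasets
  metrics.py     AUROC, BEDROC, EF, RMSD, top-k success
  tasks.py       screen_library, fish_targets, dock, rank_poses
  protocols.py   desk-scale reference experiments
  train.py       trainer, LR schedule, checkpoints
  cli.py         command-line interface
```
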