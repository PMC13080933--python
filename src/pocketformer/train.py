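"""Training: the three-objective step, LR schedule, checkpointing.

One training step on a batch of matched complexes performs

1. separate pocket / molecule CLS encodes -> contrastive loss and the
   in-batch similarity matrix,
2. hard-negative mining on that matrix, then a joint pocket-grounded
   pass over all positives plus both mined negative directions (3N rows)
   -> matching loss,
3. a joint pass on the positives with the ligand at its *stored* input
   pose (for docking fine-tuning this is a fixed decoy start; see
   ``synthetic.make_docking_set``), the coordinate head, and the intra
   (Huber on distances) + inter (coordinate MSE) docking losses against
   the recorded true pose.

The optimizer is AdamW with decoupled weight decay (normalization gains,
biases and the contrastive temperature exempt); the learning rate ramps
linearly from zero over the warm-up then follows cosine annealing to the
configured minimum.  Runs are bit-reproducible for a fixed seed on one
thread, and checkpoints round-trip training state exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import FrozenSet, List, Optional, Sequence

import numpy as np

from . import nn, objectives
from .backbone import BackboneConfig
from .graphs import ComplexPair
from .model import MODEL_VERSION, InteractionModel
from .nn import AdamW
from .objectives import DockingLossConfig, LossReport

ALL_OBJECTIVES = frozenset({"contrastive", "matching", "docking"})
CHECKPOINT_MAGIC = b"PKTF"


@dataclass
class OptimizerConfig:
    weight_decay: float = 0.05
    peak_lr: float = 1e-4
    min_lr: float = 5e-6
    warmup_steps: int = 1000
    total_steps: int = 10000
    batch_size: int = 8
    betas: tuple = (0.9, 0.999)

    def __post_init__(self):
        self.betas = tuple(self.betas)
        if not (self.peak_lr > self.min_lr > 0):
            raise ValueError("need peak_lr > min_lr > 0")
        if not (0 <= self.warmup_steps < self.total_steps):
            raise ValueError("need warmup_steps < total_steps")


@dataclass
class TrainConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    loss: DockingLossConfig = field(default_factory=DockingLossConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    proj_dim: int = 128
    seed: int = 0
    objective_mask: FrozenSet[str] = ALL_OBJECTIVES
    mining_strategy: str = "sample"

    def __post_init__(self):
        self.objective_mask = frozenset(self.objective_mask)
        bad = self.objective_mask - ALL_OBJECTIVES
        if bad:
            raise ValueError(f"unknown objectives {sorted(bad)}")
        if not self.objective_mask:
            raise ValueError("objective_mask must not be empty")

    def to_dict(self) -> dict:
        return {
            "backbone": self.backbone.to_dict(),
            "loss": {"delta": self.loss.delta},
            "optimizer": vars(self.optimizer).copy(),
            "proj_dim": self.proj_dim,
            "seed": self.seed,
            "objective_mask": sorted(self.objective_mask),
            "mining_strategy": self.mining_strategy,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(backbone=BackboneConfig.from_dict(d["backbone"]),
                   loss=DockingLossConfig(**d["loss"]),
                   optimizer=OptimizerConfig(**d["optimizer"]),
                   proj_dim=d["proj_dim"], seed=d["seed"],
                   objective_mask=frozenset(d["objective_mask"]),
                   mining_strategy=d.get("mining_strategy", "sample"))


def lr_schedule(step: int, cfg: OptimizerConfig) -> float:
    """Linear warm-up from 0 to peak, then cosine annealing to the minimum."""
    if step < 0 or step > cfg.total_steps:
        raise ValueError(f"step {step} outside [0, {cfg.total_steps}]")
    if step <= cfg.warmup_steps:
        if cfg.warmup_steps == 0:
            return cfg.peak_lr
        return cfg.peak_lr * step / cfg.warmup_steps
    frac = (step - cfg.warmup_steps) / (cfg.total_steps - cfg.warmup_steps)
    return cfg.min_lr + 0.5 * (cfg.peak_lr - cfg.min_lr) * (1 + np.cos(np.pi * frac))


class Trainer:
    """Stateful training loop over matched complexes."""

    def __init__(self, model: InteractionModel, cfg: TrainConfig,
                 log_path: Optional[Path] = None):
        self.model = model
        self.cfg = cfg
        self.opt = AdamW(model.parameters(),
                         weight_decay=cfg.optimizer.weight_decay,
                         betas=cfg.optimizer.betas,
                         no_decay=model.no_decay_predicate())
        self.rng = np.random.default_rng(cfg.seed)
        self.step_count = 0
        self.log_path = Path(log_path) if log_path else None
        self.history: List[LossReport] = []

    # ------------------------------------------------------------------
    def train_step(self, batch: Sequence[ComplexPair]) -> LossReport:
        cfg = self.cfg
        mask = cfg.objective_mask
        model = self.model
        model.zero_grad()
        N = len(batch)
        terms = {}

        sims_data = None
        if "contrastive" in mask or "matching" in mask:
            enc_p = model.encode_pockets([p.pocket for p in batch])
            enc_m = model.encode_molecules([p.molecule for p in batch])
            l_pmc, sims = objectives.contrastive_loss(
                enc_p.cls_embedding, enc_m.cls_embedding, model.proj)
            sims_data = sims.data
            if "contrastive" in mask:
                terms["l_pmc"] = l_pmc

        if "matching" in mask and N > 1:
            negatives = objectives.mine_hard_negatives(
                sims_data, self.rng, cfg.mining_strategy)
            # canonical placement: every molecule recentered at the pocket
            # centroid, so matching scores measure compatibility rather
            # than pose quality and transfer to target fishing, where the
            # bound pose of a candidate pocket is unknown
            joint_pairs, coords, labels = [], [], []

            def place(pocket, mol):
                site = pocket.strip_virtual().coords.mean(axis=0)
                lig = mol.strip_virtual()
                return lig, lig.coords - lig.coords.mean(axis=0) + site

            for pair in batch:  # positives
                lig, cc = place(pair.pocket, pair.molecule)
                joint_pairs.append((pair.pocket, lig))
                coords.append(cc)
                labels.append(1)
            for i, j in negatives:  # mined mismatches
                lig, cc = place(batch[i].pocket, batch[j].molecule)
                joint_pairs.append((batch[i].pocket, lig))
                coords.append(cc)
                labels.append(0)
            enc_j = model.encode_joint(joint_pairs, encode_token=True,
                                       molecule_coords=coords)
            logits = model.match_logits(enc_j)
            terms["l_pmm"] = objectives.matching_loss(logits, np.array(labels))

        if "docking" in mask:
            # input pose = the pair's stored molecule coordinates (e.g. a
            # decoy start), target = the recorded true pose
            truths, starts = [], []
            for pair in batch:
                truth = (pair.true_ligand_coords
                         if pair.true_ligand_coords is not None
                         else pair.molecule.real_coords)
                truths.append(truth)
                starts.append(pair.molecule.real_coords)
            enc_d = model.encode_joint([(p.pocket, p.molecule) for p in batch],
                                       molecule_coords=starts)
            pred = model.predict_coords(enc_d)
            intra_terms, inter_terms = [], []
            seg = enc_d.batch.segments
            real = enc_d.batch.real_mask
            for b, truth in enumerate(truths):
                idx = np.nonzero(real[b] & (seg[b] == 1))[0]
                lo, hi = int(idx[0]), int(idx[-1]) + 1
                pc = pred[b, lo:hi]
                intra_terms.append(objectives.intra_loss(pc, truth, cfg.loss))
                inter_terms.append(objectives.inter_loss(pc, truth))
            terms["l_intra"] = sum(intra_terms[1:], intra_terms[0]) / float(N)
            terms["l_inter"] = sum(inter_terms[1:], inter_terms[0]) / float(N)

        if not terms:
            raise ValueError("no objective produced a loss on this batch")
        total = None
        for t in terms.values():
            total = t if total is None else total + t
        nn.backward(total)
        self.step_count += 1
        lr = lr_schedule(min(self.step_count, cfg.optimizer.total_steps),
                         cfg.optimizer)
        self.opt.step(lr)
        report = objectives.total_loss(**{k: float(v.data)
                                          for k, v in terms.items()})
        self.history.append(report)
        if self.log_path:
            with open(self.log_path, "a") as fh:
                rec = {"step": self.step_count, "lr": lr, **report.to_dict()}
                fh.write(json.dumps(rec) + "\n")
        return report

    # ------------------------------------------------------------------
    def train(self, pairs: Sequence[ComplexPair], steps: int) -> List[LossReport]:
        pairs = list(pairs)
        bs = min(self.cfg.optimizer.batch_size, len(pairs))
        reports = []
        for _ in range(steps):
            idx = self.rng.choice(len(pairs), size=bs, replace=False)
            reports.append(self.train_step([pairs[i] for i in idx]))
        return reports

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        save_checkpoint(path, self.model, train_cfg=self.cfg,
                        opt_state=self.opt.state_dict(),
                        rng_state=self.rng.bit_generator.state,
                        step=self.step_count)

    @classmethod
    def resume(cls, path, log_path: Optional[Path] = None) -> "Trainer":
        ckpt = load_checkpoint(path)
        if ckpt["train_config"] is None:
            raise ValueError("checkpoint lacks training state")
        cfg = TrainConfig.from_dict(ckpt["train_config"])
        model = model_from_checkpoint(ckpt)
        trainer = cls(model, cfg, log_path=log_path)
        trainer.opt.load_state_dict(ckpt["opt_state"])
        trainer.rng.bit_generator.state = ckpt["rng_state"]
        trainer.step_count = ckpt["step"]
        return trainer


# ---------------------------------------------------------------------------
# checkpoints: deterministic container (JSON header + raw array bytes)
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: InteractionModel,
                    train_cfg: Optional[TrainConfig] = None,
                    opt_state: Optional[dict] = None,
                    rng_state: Optional[dict] = None, step: int = 0) -> None:
    params = model.parameters()
    arrays: List[np.ndarray] = []
    index = []
    offset = 0

    def put(name, arr):
        nonlocal offset
        shape = list(arr.shape)  # before ascontiguousarray (it 1-d-ifies 0-d)
        arr = np.ascontiguousarray(arr)
        index.append({"name": name, "dtype": str(arr.dtype),
                      "shape": shape, "offset": offset})
        arrays.append(arr)
        offset += arr.nbytes

    for name, p in params.items():
        put(f"param/{name}", p.data)
    if opt_state is not None:
        for name in params:
            put(f"adam_m/{name}", opt_state["m"][name])
            put(f"adam_v/{name}", opt_state["v"][name])
    header = {
        "version": MODEL_VERSION,
        "backbone": model.cfg.to_dict(),
        "proj_dim": model.proj_dim,
        "model_seed": model.seed,
        "train_config": train_cfg.to_dict() if train_cfg else None,
        "adam_t": opt_state["t"] if opt_state else None,
        "rng_state": _jsonable_rng(rng_state),
        "step": step,
        "arrays": index,
    }
    blob = json.dumps(header, sort_keys=True).encode()
    with open(path, "wb") as fh:
        fh.write(CHECKPOINT_MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        for arr in arrays:
            fh.write(arr.tobytes())


def _jsonable_rng(state):
    if state is None:
        return None
    out = json.loads(json.dumps(state, default=int))
    return out


def load_checkpoint(path) -> dict:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != CHECKPOINT_MAGIC:
            raise ValueError(f"{path}: not a checkpoint file")
        n = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(n).decode())
        if header["version"] != MODEL_VERSION:
            raise ValueError(
                f"checkpoint version {header['version']!r} does not match "
                f"supported version {MODEL_VERSION!r}")
        payload = fh.read()
    tensors = {}
    for ent in header["arrays"]:
        dt = np.dtype(ent["dtype"])
        size = int(np.prod(ent["shape"])) if ent["shape"] else 1
        start = ent["offset"]
        arr = np.frombuffer(payload, dtype=dt, count=size, offset=start
                            ).reshape(ent["shape"]).copy()
        tensors[ent["name"]] = arr
    params = {k[len("param/"):]: v for k, v in tensors.items()
              if k.startswith("param/")}
    opt_state = None
    if header["adam_t"] is not None:
        opt_state = {
            "t": header["adam_t"],
            "m": {k[len("adam_m/"):]: v for k, v in tensors.items()
                  if k.startswith("adam_m/")},
            "v": {k[len("adam_v/"):]: v for k, v in tensors.items()
                  if k.startswith("adam_v/")},
        }
    rng_state = header["rng_state"]
    if rng_state is not None:
        rng_state["state"]["state"] = int(rng_state["state"]["state"])
        rng_state["state"]["inc"] = int(rng_state["state"]["inc"])
    return {
        "version": header["version"],
        "backbone": BackboneConfig.from_dict(header["backbone"]),
        "proj_dim": header["proj_dim"],
        "model_seed": header["model_seed"],
        "train_config": header["train_config"],
        "params": params,
        "opt_state": opt_state,
        "rng_state": rng_state,
        "step": header["step"],
    }


def model_from_checkpoint(ckpt: dict,
                          expect_cfg: Optional[BackboneConfig] = None
                          ) -> InteractionModel:
    cfg = ckpt["backbone"]
    if expect_cfg is not None and expect_cfg.to_dict() != cfg.to_dict():
        raise ValueError("checkpoint BackboneConfig does not match the "
                         "requested configuration; refusing to load")
    model = InteractionModel(cfg, proj_dim=ckpt["proj_dim"],
                             seed=ckpt["model_seed"])
    params = model.parameters()
    missing = set(params) ^ set(ckpt["params"])
    if missing:
        raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]}")
    for name, p in params.items():
        arr = ckpt["params"][name]
        if arr.shape != p.data.shape:
            raise ValueError(f"shape mismatch for {name}")
        p.data = arr.astype(p.data.dtype)
    return model
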