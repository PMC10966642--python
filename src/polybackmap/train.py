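"""Dataset assembly, splitting and mini-batch training.

One sample is one chain of one frame.  Training uses mini-batch gradient
descent (batch size 64) with Adam at an initial learning rate of 1e-3,
multiplied by 1/8 whenever the validation loss stagnates, with a floor of
1e-6; data are split 80/10/10 into train/validation/test by frame.  The
best-validation parameter set is retained.
"""

from __future__ import annotations

import copy
import csv
from dataclasses import dataclass, field

import numpy as np

from .loss import LossTerms, LossWeights, PhysicsLoss
from .nn import Adam, UNet
from .represent import (DEFAULT_CG_SCALE, DEFAULT_VECTOR_SCALE, build_scheme,
                        encode_chain, next_pow2)

__all__ = ["TrainConfig", "EncodedDataset", "split_dataset", "train",
           "evaluate", "save_history"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    initial_lr: float = 1e-3
    lr_floor: float = 1e-6
    lr_factor: float = 1.0 / 8.0
    plateau_patience: int = 20
    min_delta: float = 1e-5      # relative improvement that resets the plateau
    max_epochs: int = 1000
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    split_fractions: tuple = (0.8, 0.1, 0.1)

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not self.lr_floor < self.initial_lr:
            raise ValueError("lr_floor must be below initial_lr")


@dataclass
class EncodedDataset:
    """Encoded chain samples sharing one chain layout."""

    inputs: np.ndarray       # (N, S, k+3)
    targets: np.ndarray      # (N, S, 3)
    mask: np.ndarray         # (S,)
    loss: PhysicsLoss
    k: int

    def __len__(self):
        return len(self.inputs)

    @classmethod
    def from_ensemble(cls, ensemble, frames=None, S: int | None = None,
                      vector_scale: float = DEFAULT_VECTOR_SCALE,
                      cg_scale: float = DEFAULT_CG_SCALE):
        """Encode every chain of the selected frames into one array pair."""
        top = ensemble.topology
        if frames is None:
            frames = range(ensemble.n_frames)
        n_mono = {c.n_monomers for c in top.chains}
        if len(n_mono) != 1:
            raise ValueError("dataset chains must have equal length")
        chain0 = top.chains[0]
        scheme = build_scheme(chain0)
        if S is None:
            S = next_pow2(chain0.n_atoms)
        m_off = top.chain_monomer_offsets
        a_off = top.chain_atom_offsets
        k = ensemble.cg.k
        inputs, targets, mask = [], [], None
        for f in frames:
            coords = ensemble.coords[f]
            Qf = ensemble.cg_coords[f]
            for ci, chain in enumerate(top.chains):
                sample = encode_chain(
                    coords[a_off[ci]:a_off[ci + 1]], chain,
                    Qf[m_off[ci]:m_off[ci + 1]],
                    ensemble.cg.c[m_off[ci]:m_off[ci + 1]],
                    k, scheme=scheme, vector_scale=vector_scale,
                    cg_scale=cg_scale, S=S)
                inputs.append(sample.input)
                targets.append(sample.target)
                mask = sample.mask
        lossfn = PhysicsLoss(chain0, scheme, vector_scale, cg_scale)
        return cls(inputs=np.stack(inputs), targets=np.stack(targets),
                   mask=mask, loss=lossfn, k=k)


def split_dataset(n_frames: int, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Disjoint, exhaustive train/validation/test frame partition."""
    if n_frames < 3:
        raise ValueError("need at least 3 frames to split")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    perm = np.random.default_rng(seed).permutation(n_frames)
    n_train = int(n_frames * fractions[0])
    n_val = max(int(n_frames * fractions[1]), 1)
    train_idx = np.sort(perm[:n_train])
    val_idx = np.sort(perm[n_train:n_train + n_val])
    test_idx = np.sort(perm[n_train + n_val:])
    return train_idx, val_idx, test_idx


def _mean_terms(terms_list) -> LossTerms:
    arr = np.array([[t.bv, t.bl, t.ba, t.da, t.v0] for t in terms_list])
    return LossTerms(*arr.mean(axis=0))


def evaluate(model: UNet, dataset: EncodedDataset,
             weights: LossWeights | None = None,
             batch_size: int = 64) -> dict:
    """Mean loss terms over a split, dropout off."""
    weights = weights or LossWeights()
    terms_list = []
    for i in range(0, len(dataset), batch_size):
        x = dataset.inputs[i:i + batch_size]
        y = dataset.targets[i:i + batch_size]
        pred = model.forward(x, training=False)
        terms_list.append(dataset.loss.terms(pred, y, inputs=x))
    mean = _mean_terms(terms_list)
    out = mean.as_dict()
    out["total"] = mean.total(weights)
    return out


def train(model: UNet, train_set: EncodedDataset, val_set: EncodedDataset,
          config: TrainConfig):
    """Train with the plateau learning-rate schedule; returns (model, history).

    The returned model carries the best-validation parameters.  Raises on
    divergence (non-finite loss).
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=config.initial_lr)
    history = []
    best_val = np.inf
    best_state = None
    stale = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_set))
        train_terms = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i:i + config.batch_size]
            x = train_set.inputs[idx]
            y = train_set.targets[idx]
            pred = model.forward(x, training=True)
            terms, total, gpred = train_set.loss.value_and_grad(
                pred, y, config.weights, inputs=x)
            if not np.isfinite(total):
                raise RuntimeError(f"training diverged at epoch {epoch}: loss={total}")
            opt.zero_grad()
            model.backward(gpred)
            opt.step()
            train_terms.append(terms)
        tr = _mean_terms(train_terms)
        va = evaluate(model, val_set, config.weights, config.batch_size)
        record = {"epoch": epoch, "lr": opt.lr,
                  "train_total": tr.total(config.weights), "val_total": va["total"]}
        record.update({f"train_{k}": v for k, v in tr.as_dict().items()})
        record.update({f"val_{k}": v for k, v in va.items() if k != "total"})
        history.append(record)

        if va["total"] < best_val * (1.0 - config.min_delta):
            best_val = va["total"]
            best_state = [a.copy() for a in model.state_arrays()]
            stale = 0
        else:
            stale += 1
            if stale >= config.plateau_patience:
                if opt.lr <= config.lr_floor:
                    break
                opt.lr = max(opt.lr * config.lr_factor, config.lr_floor)
                stale = 0
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, history


def save_history(history, path) -> None:
    """Write the per-epoch loss-term records as CSV."""
    if not history:
        raise ValueError("empty history")
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)
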