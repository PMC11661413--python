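"""Subject-wise splitting, class balancing and the optimization loop.

The evaluation protocol is two-fold subject-wise cross-validation: the
subjects carrying AF or PAC/PVC are divided into two folds with equal
AF-subject and PAC/PVC-subject counts, each fold is internally split
80/10/10 by subject into train/validation/subject-dependent test, each
fold's model is tested on the *entire other fold* plus a held-out pool
of NSR-only subjects.  Every test prediction therefore comes from a
model that never saw that subject.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BiGRUClassifier, ModelSpec, build_model
from .records import Rhythm

__all__ = ["TrainConfig", "FoldPlan", "ArrayDataset", "make_fold_plan",
           "upsample_minority", "AdamOptimizer", "train_loop",
           "cross_fold_protocol"]


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the reference protocol (batch 32, up to 200 epochs,
    early stop after 40 epochs without validation-loss improvement,
    Adam with step size 1e-3 and moment decays 0.9/0.999).  The gradient
    norm clip guards the long-sequence BPTT against rare exploding
    gradients and can be disabled with ``grad_clip=None``.
    """

    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 40
    lr: float = 1e-3
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    grad_clip: float | None = 5.0
    lr_warmup_epochs: int = 0
    lr_cosine_floor: float | None = None  # e.g. 0.1 -> decay to 10% of lr
    rng_seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Step size for a 1-based epoch under warmup + optional cosine decay."""
        if self.lr_warmup_epochs > 0 and epoch <= self.lr_warmup_epochs:
            return self.lr * epoch / self.lr_warmup_epochs
        if self.lr_cosine_floor is None:
            return self.lr
        span = max(self.max_epochs - self.lr_warmup_epochs, 1)
        frac = (epoch - self.lr_warmup_epochs) / span
        floor = self.lr * self.lr_cosine_floor
        return floor + 0.5 * (self.lr - floor) * (1 + np.cos(np.pi * min(frac, 1.0)))

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (self.patience < self.max_epochs):
            raise ValueError("patience must be smaller than max_epochs")


@dataclass
class ArrayDataset:
    """Preprocessed segments ready for the model: x (n, L, d) in [0, 1]."""

    x: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    segment_ids: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subjects = np.asarray(self.subjects)
        self.segment_ids = np.asarray(self.segment_ids)

    def __len__(self) -> int:
        return int(self.y.size)

    def subset(self, idx: np.ndarray) -> "ArrayDataset":
        return ArrayDataset(self.x[idx], self.y[idx],
                            self.subjects[idx], self.segment_ids[idx])

    def for_subjects(self, subjects) -> "ArrayDataset":
        mask = np.isin(self.subjects, list(subjects))
        return self.subset(np.flatnonzero(mask))


@dataclass(frozen=True)
class FoldPlan:
    """Subject-level assignment for the two-fold protocol."""

    fold1_train: tuple[str, ...]
    fold1_val: tuple[str, ...]
    fold1_test: tuple[str, ...]
    fold2_train: tuple[str, ...]
    fold2_val: tuple[str, ...]
    fold2_test: tuple[str, ...]
    nsr_only_test: tuple[str, ...]

    @property
    def fold1_subjects(self) -> tuple[str, ...]:
        return self.fold1_train + self.fold1_val + self.fold1_test

    @property
    def fold2_subjects(self) -> tuple[str, ...]:
        return self.fold2_train + self.fold2_val + self.fold2_test

    def validate(self) -> None:
        pools = [self.fold1_train, self.fold1_val, self.fold1_test,
                 self.fold2_train, self.fold2_val, self.fold2_test,
                 self.nsr_only_test]
        flat = [s for pool in pools for s in pool]
        if len(flat) != len(set(flat)):
            raise ValueError("fold plan pools are not pairwise disjoint")


def make_fold_plan(manifest: pd.DataFrame, rng: np.random.Generator) -> FoldPlan:
    """Split subjects into two balanced folds plus an NSR-only test pool.

    AF subjects (any AF segment) and PAC/PVC subjects (any PAC/PVC
    segment, no AF) are each divided as evenly as possible (+-1) between
    the folds; subjects with neither rhythm form the NSR-only pool.
    Within each fold, subjects are partitioned 80/10/10 into
    train/validation/subject-dependent test with at least one subject in
    each part, interleaving AF and PAC/PVC subjects for stratification.
    Deterministic under the generator's state.
    """
    by_subject = manifest.groupby("subject_id")["rhythm_label"].agg(set)
    af_subjects = sorted(s for s, labels in by_subject.items() if "AF" in labels)
    pac_subjects = sorted(s for s, labels in by_subject.items()
                          if "PACPVC" in labels and "AF" not in labels)
    nsr_only = sorted(s for s in by_subject.index
                      if s not in af_subjects and s not in pac_subjects)
    if not af_subjects or not pac_subjects:
        warnings.warn("degenerate fold plan: a rhythm class has no subjects",
                      stacklevel=2)

    def split_half(subjects: list[str]) -> tuple[list[str], list[str]]:
        order = list(rng.permutation(subjects))
        return order[0::2], order[1::2]

    af1, af2 = split_half(af_subjects)
    pac1, pac2 = split_half(pac_subjects)

    def interleave(a: list[str], b: list[str]) -> list[str]:
        combined: list[str] = []
        for pair in zip(a, b):
            combined.extend(pair)
        longer = a if len(a) > len(b) else b
        combined.extend(longer[min(len(a), len(b)):])
        return combined

    def partition(af_part: list[str], pac_part: list[str]):
        # stratified: the validation pool gets one subject of each
        # arrhythmia type, so the model-selection loss sees all classes
        af, pac = list(af_part), list(pac_part)
        if af and pac and len(af) + len(pac) >= 5:
            val = (af.pop(0), pac.pop(0))
            test = (af.pop(0),) if len(af) >= len(pac) else (pac.pop(0),)
            return tuple(interleave(af, pac)), val, test
        combined = interleave(af, pac)
        n = len(combined)
        if n < 3:
            return tuple(combined), (), ()
        n_val = max(1, int(round(0.1 * n)))
        n_test = max(1, int(round(0.1 * n)))
        val = tuple(combined[:n_val])
        test = tuple(combined[n_val:n_val + n_test])
        train = tuple(combined[n_val + n_test:])
        return train, val, test

    t1, v1, s1 = partition(af1, pac1)
    t2, v2, s2 = partition(af2, pac2)
    plan = FoldPlan(fold1_train=t1, fold1_val=v1, fold1_test=s1,
                    fold2_train=t2, fold2_val=v2, fold2_test=s2,
                    nsr_only_test=tuple(nsr_only))
    plan.validate()
    return plan


def upsample_minority(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices that balance every class to the NSR segment count.

    Minority classes are duplicated by uniform resampling with
    replacement.  Intended for training and validation sets only — never
    apply it to test data.  Raises if a class is absent.
    """
    y = np.asarray(y, dtype=np.int64)
    target = int(np.sum(y == Rhythm.NSR))
    out: list[np.ndarray] = []
    for cls in (Rhythm.NSR, Rhythm.AF, Rhythm.PACPVC):
        idx = np.flatnonzero(y == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls.name} is absent; cannot balance")
        if idx.size == target:
            out.append(idx)
        elif idx.size < target:
            extra = rng.choice(idx, size=target - idx.size, replace=True)
            out.append(np.concatenate([idx, extra]))
        else:  # degenerate: a class larger than NSR is subsampled to match
            out.append(rng.choice(idx, size=target, replace=False))
    merged = np.concatenate(out)
    return merged[rng.permutation(merged.size)]


class AdamOptimizer:
    """Adam with optional global gradient-norm clipping."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_clip: float | None = None):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.grad_clip = grad_clip
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.grad_clip is not None:
            norm = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum())
                                     for g in grads.values())))
            if norm > self.grad_clip:
                scale = np.float32(self.grad_clip / (norm + 1e-12))
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * (g * g)
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def train_loop(model: BiGRUClassifier,
               train_x: np.ndarray, train_y: np.ndarray,
               val_x: np.ndarray, val_y: np.ndarray,
               cfg: TrainConfig) -> tuple[pd.DataFrame, int]:
    """Mini-batch Adam with early stopping on validation loss.

    Runs at most ``cfg.max_epochs`` epochs and stops when the validation
    loss has not strictly improved for ``cfg.patience`` consecutive
    epochs.  On return the model holds the weights of the epoch with the
    minimum validation loss; the history lists per-epoch train and
    validation losses (1-based epoch numbers).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    opt = AdamOptimizer(model.params, lr=cfg.lr, betas=cfg.betas,
                        eps=cfg.eps, grad_clip=cfg.grad_clip)
    n = train_y.size
    best_loss = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_improvement = 0
    rows = []
    for epoch in range(1, cfg.max_epochs + 1):
        opt.lr = cfg.lr_at(epoch)
        perm = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = perm[lo:lo + cfg.batch_size]
            loss, grads = model.loss_and_grads(train_x[idx], train_y[idx], rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"batch starting at {lo}")
            opt.step(grads)
            losses.append(loss)
        # batch statistics: the running BN averages trail the weights when
        # an epoch is only a few optimizer steps, which would make the
        # selection signal noise at small scale
        val_loss = model.eval_loss(val_x, val_y, use_batch_stats=True)
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_loss": val_loss})
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            since_improvement = 0
        else:
            since_improvement += 1
            if since_improvement >= cfg.patience:
                break
    model.load_state_dict(best_state)
    if hasattr(model, "recalibrate_bn"):
        # short schedules leave the running BN statistics trailing the
        # selected weights; re-estimate them exactly before returning
        model.recalibrate_bn(train_x)
    return pd.DataFrame(rows), best_epoch


def _train_fold(dataset: ArrayDataset, train_subj, val_subj,
                model_spec: ModelSpec, cfg: TrainConfig,
                seed_offset: int) -> tuple[BiGRUClassifier, pd.DataFrame, int]:
    rng = np.random.default_rng(cfg.rng_seed + seed_offset)
    train = dataset.for_subjects(train_subj)
    val = dataset.for_subjects(val_subj)
    if len(val) == 0:
        warnings.warn("empty validation pool; validating on training data",
                      stacklevel=2)
        val = train

    def balanced_or_all(y: np.ndarray) -> np.ndarray:
        try:
            return upsample_minority(y, rng)
        except ValueError as exc:  # tiny pools may miss a class entirely
            warnings.warn(f"skipping upsampling: {exc}", stacklevel=2)
            return np.arange(y.size)

    tr_idx = balanced_or_all(train.y)
    va_idx = balanced_or_all(val.y)
    model = build_model(model_spec, seed=cfg.rng_seed + seed_offset)
    fold_cfg = dataclasses.replace(cfg, rng_seed=cfg.rng_seed + seed_offset)
    history, best_epoch = train_loop(model, train.x[tr_idx], train.y[tr_idx],
                                     val.x[va_idx], val.y[va_idx], fold_cfg)
    return model, history, best_epoch


def cross_fold_protocol(plan: FoldPlan, dataset: ArrayDataset,
                        model_spec: ModelSpec, cfg: TrainConfig
                        ) -> dict:
    """Run the full two-fold protocol and collect merged test predictions.

    Fold 1's model is evaluated on all fold-2 segments and vice versa;
    both models are evaluated on the NSR-only pool.  Returns a dict with
    the two models, their histories, and a prediction table with one row
    per (model, test segment) tagged by source pool.
    """
    models, histories, rows = {}, {}, []
    for fold, (train_s, val_s) in enumerate(
            [(plan.fold1_train, plan.fold1_val),
             (plan.fold2_train, plan.fold2_val)], start=1):
        model, history, best_epoch = _train_fold(
            dataset, train_s, val_s, model_spec, cfg, seed_offset=fold)
        models[fold] = model
        histories[fold] = history

    pools = {1: ("fold2", plan.fold2_subjects), 2: ("fold1", plan.fold1_subjects)}
    for fold, model in models.items():
        pool_name, subjects = pools[fold]
        for pool, subj in ((pool_name, subjects),
                           ("nsr_only", plan.nsr_only_test)):
            if not subj:
                continue
            part = dataset.for_subjects(subj)
            probs = model.predict_proba(part.x)
            for i in range(len(part)):
                rows.append({"segment_id": str(part.segment_ids[i]),
                             "subject_id": str(part.subjects[i]),
                             "true_label": int(part.y[i]),
                             "p_nsr": probs[i, 0], "p_af": probs[i, 1],
                             "p_pacpvc": probs[i, 2],
                             "model_fold": fold, "pool": pool})
    predictions = pd.DataFrame(rows)
    return {"models": models, "histories": histories, "predictions": predictions}
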