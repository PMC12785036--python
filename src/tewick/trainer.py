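"""Training: weighted cross-entropy, AdamW, checkpoints, epoch metrics.

The public surface follows the model/results idiom: a
:class:`TEClassifier` is built from dataset splits plus configuration,
``fit()`` runs the training loop and returns a
:class:`TrainingResults` carrying the trained encoder, the per-epoch
metric history and evaluation helpers.

Class imbalance is countered by inverse-frequency class weights,
w_c = N / (C * n_c), rescaled to mean 1 so that the learning rate is
invariant to the weight scale.  Training sequences are augmented
on the fly and re-tokenized every epoch; chunked sequences contribute
one training example per chunk, each carrying the source label.
Validation (every epoch) and the final test evaluation use unaugmented
sequences with per-sequence median aggregation over chunks.

Every epoch's randomness (shuffling, augmentation, dropout) comes from
a generator derived from ``(seed, epoch)``, so resuming from the
checkpoint of epoch e reproduces the trajectory of an uninterrupted
run exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import autograd as ag
from .augment import AugmentationConfig, augment_pipeline
from .autograd import Tensor
from .classifier import aggregate_chunks
from .encoder import (ModelConfig, SparseAttentionEncoder, load_checkpoint,
                      save_checkpoint, softmax)
from .metrics import ConfusionMatrix, MetricsReport
from .registry import ClassRegistry, DEFAULT_REGISTRY
from .sequence_db import DatasetSplits, LabeledSequence, read_labeled_fasta, split_dataset
from .tokenizer import TokenizerError, Vocabulary, build_vocabulary, pad_batch, tokenize

logger = logging.getLogger(__name__)


class TrainError(ValueError):
    pass


@dataclass
class TrainConfig:
    """Optimization settings.

    ``learning_rate`` feeds AdamW with a linear warmup over the first
    ``warmup_fraction`` of steps, then stays constant.  Gradient
    accumulation multiplies the effective batch size without growing
    the per-step memory footprint.
    """

    num_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    warmup_fraction: float = 0.05
    gradient_accumulation_steps: int = 1
    checkpoint_dir: str | None = None
    seed: int = 0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self) -> None:
        if self.num_epochs < 1:
            raise TrainError("num_epochs must be >= 1")
        if self.batch_size < 1:
            raise TrainError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise TrainError("learning_rate must be positive")
        if self.gradient_accumulation_steps < 1:
            raise TrainError("gradient_accumulation_steps must be >= 1")


def compute_class_weights(class_counts: Sequence[int]) -> np.ndarray:
    """Inverse-frequency weights w_c = N/(C*n_c), rescaled to mean 1."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 1).any():
        raise TrainError("every class needs at least one training example")
    raw = counts.sum() / (len(counts) * counts)
    return raw / raw.mean()


def weighted_cross_entropy(logits: np.ndarray, true_class: int,
                           weights: np.ndarray) -> float:
    """Per-example loss -w_y * log p_y with p from a max-shifted softmax."""
    p = softmax(np.asarray(logits, dtype=np.float64))
    return float(-weights[true_class] * np.log(p[true_class]))


class AdamW:
    """AdamW with decoupled weight decay; decay skips biases and norms."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 weight_decay: float = 0.01, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.step_count = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    @staticmethod
    def _decays(name: str) -> bool:
        return not (name.endswith(".b") or name.endswith(".g")
                    or ".ln" in name or name.startswith("b")
                    or name.split(".")[-1].startswith("b"))

    def step(self, lr_scale: float = 1.0) -> None:
        self.step_count += 1
        lr = self.lr * lr_scale
        bc1 = 1 - self.b1 ** self.step_count
        bc2 = 1 - self.b2 ** self.step_count
        for name, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / bc1
            vhat = self.v[name] / bc2
            update = mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and self._decays(name):
                update = update + self.weight_decay * p.data
            p.data = p.data - lr * update

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {f"m:{k}": v for k, v in self.m.items()}
        out.update({f"v:{k}": v for k, v in self.v.items()})
        out["step_count"] = np.asarray(self.step_count)
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        self.step_count = int(arrays["step_count"])
        for k in self.m:
            self.m[k] = arrays[f"m:{k}"]
            self.v[k] = arrays[f"v:{k}"]


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    validation: MetricsReport
    seconds: float

    def to_dict(self) -> dict:
        return {"epoch": self.epoch, "train_loss": self.train_loss,
                "seconds": self.seconds,
                "validation": self.validation.to_dict()}


class TEClassifier:
    """Superfamily classifier model bound to dataset splits.

    Parameters
    ----------
    splits
        Stratified train/validation/test partitions of labeled
        sequences.
    registry
        Class registry; fixes the class index order of the model head.
    model_config, train_config
        Architecture and optimization settings; both default to the
        package defaults.

    Examples
    --------
    >>> model = TEClassifier(splits, registry=registry,
    ...                      model_config=ModelConfig(num_classes=4),
    ...                      train_config=TrainConfig(num_epochs=5))
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(self, splits: DatasetSplits,
                 registry: ClassRegistry = DEFAULT_REGISTRY,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        if not splits.train:
            raise TrainError("training split is empty")
        self.splits = splits
        self.registry = registry
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()
        if self.model_config.num_classes != len(registry):
            raise TrainError(
                f"model has {self.model_config.num_classes} outputs but the "
                f"registry defines {len(registry)} classes")
        self.vocab: Vocabulary = build_vocabulary(self.model_config.kmer_size)
        counts = splits.class_counts("train")
        missing = [c for c in registry.class_names if counts.get(c, 0) == 0]
        if missing:
            raise TrainError(f"classes with no training examples: {missing}")
        self.class_weights = compute_class_weights(
            [counts[c] for c in registry.class_names])

    @classmethod
    def from_fasta(cls, path: str | Path,
                   registry: ClassRegistry = DEFAULT_REGISTRY,
                   label_separator: str = "#",
                   fractions=(0.75, 0.15, 0.10), seed: int = 0,
                   model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None) -> "TEClassifier":
        """Build the model straight from a labeled FASTA file."""
        records = read_labeled_fasta(path, label_separator, registry)
        splits = split_dataset(records, fractions, seed)
        return cls(splits, registry, model_config, train_config)

    # -- internals ---------------------------------------------------------

    def _epoch_rng(self, epoch: int, stream: int) -> np.random.Generator:
        return np.random.default_rng(
            [self.train_config.seed % (2 ** 31), epoch, stream])

    def _tokenize_examples(self, seqs: Sequence[LabeledSequence],
                           augment_rng: np.random.Generator | None):
        """(chunks, labels) for a list of sequences; one example per chunk."""
        chunks, labels = [], []
        aug_cfg = self.train_config.augmentation
        for rec in seqs:
            seq = rec.sequence
            if augment_rng is not None:
                seq = augment_pipeline(seq, aug_cfg, augment_rng)
            try:
                seq_chunks = tokenize(seq, self.vocab,
                                      self.model_config.max_embeddings)
            except TokenizerError:
                logger.warning("skipping %r: shorter than k after edits",
                               rec.id)
                continue
            label_idx = self.registry.index(rec.label)
            for ch in seq_chunks:
                chunks.append(ch)
                labels.append(label_idx)
        return chunks, np.asarray(labels, dtype=np.int64)

    def _forward_probs(self, encoder: SparseAttentionEncoder,
                       chunks, batch_size: int) -> np.ndarray:
        """Deterministic per-chunk class probabilities, batched."""
        probs = np.empty((len(chunks), self.model_config.num_classes))
        order = np.argsort([c.n_tokens for c in chunks], kind="stable")
        for lo in range(0, len(order), batch_size):
            sel = order[lo:lo + batch_size]
            ids, mask = pad_batch([chunks[i] for i in sel], self.vocab.pad_id)
            logits, _ = encoder.forward(ids, mask, training=False)
            probs[sel] = softmax(logits.data)
        return probs

    def _eval_chunks(self, seqs: Sequence[LabeledSequence]):
        """Tokenized (chunks, owners, true_idx); cached, as evaluation
        sequences are never augmented and re-tokenize identically."""
        key = id(seqs)
        cached = getattr(self, "_eval_cache", {}).get(key)
        if cached is not None:
            return cached
        chunks, owners, true_idx = [], [], []
        for s_i, rec in enumerate(seqs):
            true_idx.append(self.registry.index(rec.label))
            for ch in tokenize(rec.sequence, self.vocab,
                               self.model_config.max_embeddings):
                chunks.append(ch)
                owners.append(s_i)
        if not hasattr(self, "_eval_cache"):
            self._eval_cache = {}
        self._eval_cache[key] = (chunks, owners, true_idx)
        return chunks, owners, true_idx

    def _evaluate(self, encoder: SparseAttentionEncoder,
                  seqs: Sequence[LabeledSequence],
                  batch_size: int) -> MetricsReport:
        """Per-sequence evaluation with chunk-median aggregation."""
        chunks, owners, true_idx = self._eval_chunks(seqs)
        probs = self._forward_probs(encoder, chunks, batch_size)
        owners = np.asarray(owners)
        pred_idx = np.empty(len(seqs), dtype=np.int64)
        for s_i in range(len(seqs)):
            agg = aggregate_chunks(probs[owners == s_i])
            pred_idx[s_i] = int(np.argmax(agg))
        cm = ConfusionMatrix.from_pairs(true_idx, pred_idx,
                                        self.registry.class_names)
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # zero-support classes mid-training
            return MetricsReport.from_confusion(cm)

    # -- fitting -----------------------------------------------------------

    def fit(self, resume_from: str | Path | None = None,
            verbose: bool = False) -> "TrainingResults":
        """Run (or resume) the training loop.

        Each epoch: augment on the fly, tokenize, take batched AdamW
        steps (optionally accumulated), evaluate on the validation
        split and, if a checkpoint directory is configured, write an
        epoch checkpoint with the optimizer state.  The checkpoint with
        the best validation weighted F1 is tagged ``best``.
        """
        cfg = self.train_config
        encoder = SparseAttentionEncoder(self.model_config)
        optimizer = AdamW(encoder.params, cfg.learning_rate, cfg.weight_decay)
        history: list[EpochRecord] = []
        start_epoch = 0

        if resume_from is not None:
            encoder, extra, meta = load_checkpoint(resume_from)
            if meta.get("model_config") != self.model_config.to_dict():
                raise TrainError("checkpoint model config does not match")
            if meta.get("train_fingerprint") != self._train_fingerprint():
                raise TrainError("checkpoint training config does not match")
            optimizer = AdamW(encoder.params, cfg.learning_rate,
                              cfg.weight_decay)
            optimizer.load_state_arrays(extra)
            start_epoch = int(meta["epoch"]) + 1
            history = [self._record_from_dict(d) for d in meta["history"]]

        n_train = len(self.splits.train)
        steps_per_epoch = max(1, -(-n_train // cfg.batch_size))
        total_steps = max(1, cfg.num_epochs * steps_per_epoch
                          // cfg.gradient_accumulation_steps)
        warmup_steps = max(1, int(cfg.warmup_fraction * total_steps))

        ckpt_dir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
        if ckpt_dir:
            ckpt_dir.mkdir(parents=True, exist_ok=True)

        for epoch in range(start_epoch, cfg.num_epochs):
            t0 = time.time()
            shuffle_rng = self._epoch_rng(epoch, 0)
            augment_rng = self._epoch_rng(epoch, 1)
            dropout_rng = self._epoch_rng(epoch, 2)

            order = shuffle_rng.permutation(n_train)
            epoch_seqs = [self.splits.train[i] for i in order]
            chunks, labels = self._tokenize_examples(epoch_seqs, augment_rng)

            losses = []
            accum = 0
            for lo in range(0, len(chunks), cfg.batch_size):
                batch = chunks[lo:lo + cfg.batch_size]
                ids, mask = pad_batch(batch, self.vocab.pad_id)
                logits, _ = encoder.forward(ids, mask, training=True,
                                            rng=dropout_rng)
                loss = ag.weighted_cross_entropy_logits(
                    logits, labels[lo:lo + cfg.batch_size],
                    self.class_weights)
                (loss / cfg.gradient_accumulation_steps).backward()
                losses.append(float(loss.data))
                accum += 1
                if accum == cfg.gradient_accumulation_steps:
                    lr_scale = min(1.0, (optimizer.step_count + 1)
                                   / warmup_steps)
                    optimizer.step(lr_scale)
                    encoder.zero_grad()
                    accum = 0
            if accum:  # flush a trailing partial accumulation window
                optimizer.step(min(1.0, (optimizer.step_count + 1)
                                   / warmup_steps))
                encoder.zero_grad()

            report = self._evaluate(encoder, self.splits.validation,
                                    cfg.batch_size)
            rec = EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)),
                              validation=report, seconds=time.time() - t0)
            history.append(rec)
            if verbose:
                logger.info("epoch %d: loss %.4f, val weighted F1 %.3f "
                            "(%.1fs)", epoch, rec.train_loss,
                            report.weighted_f1, rec.seconds)
            if ckpt_dir:
                self._save_epoch(ckpt_dir, encoder, optimizer, epoch, history)

        results = TrainingResults(model=self, encoder=encoder,
                                  history=history,
                                  checkpoint_dir=ckpt_dir)
        if ckpt_dir:
            save_checkpoint(ckpt_dir / "best.npz",
                            results.best_encoder(), extra_meta={
                                "model_config": self.model_config.to_dict(),
                                "class_names": list(self.registry.class_names),
                                "orders": dict(self.registry.orders),
                                "epoch": results.best_epoch,
                            })
            (ckpt_dir / "training_log.json").write_text(json.dumps(
                [r.to_dict() for r in history], indent=1))
        return results

    def _train_fingerprint(self) -> dict:
        c = self.train_config
        return {"num_epochs": c.num_epochs, "batch_size": c.batch_size,
                "learning_rate": c.learning_rate, "seed": c.seed,
                "gradient_accumulation_steps": c.gradient_accumulation_steps,
                "n_train": len(self.splits.train)}

    def _save_epoch(self, ckpt_dir: Path, encoder, optimizer, epoch: int,
                    history: list[EpochRecord]) -> None:
        save_checkpoint(
            ckpt_dir / f"epoch_{epoch:04d}.npz", encoder,
            extra_arrays=optimizer.state_arrays(),
            extra_meta={"model_config": self.model_config.to_dict(),
                        "train_fingerprint": self._train_fingerprint(),
                        "class_names": list(self.registry.class_names),
                        "orders": dict(self.registry.orders),
                        "epoch": epoch,
                        "history": [r.to_dict() for r in history]})

    @staticmethod
    def _record_from_dict(d: dict) -> EpochRecord:
        v = d["validation"]
        names = tuple(v["per_class"])
        pc = v["per_class"]
        report = MetricsReport(
            class_names=names,
            precision=np.array([pc[n]["precision"] for n in names]),
            recall=np.array([pc[n]["recall"] for n in names]),
            f1=np.array([pc[n]["f1"] for n in names]),
            support=np.array([pc[n]["support"] for n in names]),
            accuracy=v["accuracy"], macro_precision=v["macro_precision"],
            macro_recall=v["macro_recall"], macro_f1=v["macro_f1"],
            weighted_precision=v["weighted_precision"],
            weighted_recall=v["weighted_recall"],
            weighted_f1=v["weighted_f1"])
        return EpochRecord(epoch=d["epoch"], train_loss=d["train_loss"],
                           validation=report, seconds=d["seconds"])


@dataclass
class TrainingResults:
    """Outcome of :meth:`TEClassifier.fit`.

    Carries the final-epoch encoder, the per-epoch history and the
    checkpoint directory (when configured).  ``summary()`` renders the
    trajectory; ``evaluate()`` scores a partition with the final (or
    best) weights.
    """

    model: TEClassifier
    encoder: SparseAttentionEncoder
    history: list[EpochRecord]
    checkpoint_dir: Path | None = None

    @property
    def best_epoch(self) -> int:
        """Epoch with the highest validation weighted F1."""
        return max(self.history,
                   key=lambda r: (r.validation.weighted_f1, -r.epoch)).epoch

    def best_encoder(self) -> SparseAttentionEncoder:
        """Encoder of the best epoch (from checkpoints when available).

        Falls back to the final-epoch weights when the best epoch's
        checkpoint is not on disk (e.g. it predates a resume into a
        fresh checkpoint directory).
        """
        if self.checkpoint_dir is None or self.best_epoch == self.history[-1].epoch:
            return self.encoder
        path = self.checkpoint_dir / f"epoch_{self.best_epoch:04d}.npz"
        if not path.exists():
            logger.warning("checkpoint for best epoch %d not found; using "
                           "final weights", self.best_epoch)
            return self.encoder
        encoder, _, _ = load_checkpoint(path)
        return encoder

    def evaluate(self, part: str = "test", use_best: bool = False) -> MetricsReport:
        seqs = self.model.splits.parts[part]
        encoder = self.best_encoder() if use_best else self.encoder
        return self.model._evaluate(encoder, seqs,
                                    self.model.train_config.batch_size)

    def summary(self) -> str:
        lines = ["Training summary",
                 "================",
                 f"classes:      {len(self.model.registry)}",
                 f"train/val/test: {len(self.model.splits.train)}/"
                 f"{len(self.model.splits.validation)}/"
                 f"{len(self.model.splits.test)}",
                 f"epochs:       {len(self.history)} "
                 f"(best: {self.best_epoch}, by validation weighted F1)",
                 "",
                 "epoch  train_loss  val_acc  val_macro_f1  val_weighted_f1"]
        for r in self.history:
            v = r.validation
            lines.append(f"{r.epoch:5d}  {r.train_loss:10.4f}  "
                         f"{v.accuracy:7.3f}  {v.macro_f1:12.3f}  "
                         f"{v.weighted_f1:15.3f}")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Write a standalone inference checkpoint of the final weights."""
        save_checkpoint(path, self.encoder, extra_meta={
            "model_config": self.model.model_config.to_dict(),
            "class_names": list(self.model.registry.class_names),
            "orders": dict(self.model.registry.orders),
            "epoch": self.history[-1].epoch if self.history else -1})
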