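"""Inference: tokenize, forward per chunk, median-aggregate, threshold, TSV.

A sequence longer than the embedding budget is processed in chunks and
its class probabilities are the element-wise median over chunk outputs
(renormalized, since medians need not sum to one).  A sequence is
reported as classified only when its top probability reaches the
confidence threshold (default 0.7; 0.9 is the strict preset);
below-threshold records keep their full probability vector so the
caller can re-filter without re-running the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encoder import SparseAttentionEncoder, load_checkpoint, softmax
from .registry import ClassRegistry
from .sequence_db import LabeledSequence, read_fasta
from .tokenizer import TokenizerError, Vocabulary, build_vocabulary, pad_batch, tokenize

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.7
STRICT_THRESHOLD = 0.9

VERDICT_CLASSIFIED = "classified"
VERDICT_UNCLASSIFIED = "unclassified"
VERDICT_TOO_SHORT = "too_short"


@dataclass(frozen=True)
class ClassificationRecord:
    """Per-sequence prediction with its full probability vector."""

    id: str
    probabilities: np.ndarray | None
    superfamily: str | None
    order: str | None
    max_probability: float | None
    verdict: str


def aggregate_chunks(per_chunk_probabilities: np.ndarray) -> np.ndarray:
    """Element-wise median over chunk probability vectors, renormalized.

    With one chunk this is the identity; with two it is the midpoint.
    Invariant to the order of the chunks.
    """
    probs = np.asarray(per_chunk_probabilities, dtype=np.float64)
    if probs.ndim != 2 or probs.shape[0] == 0:
        raise ValueError("need a (n_chunks, n_classes) array with >= 1 chunk")
    med = np.median(probs, axis=0)
    total = med.sum()
    if total <= 0:  # degenerate; fall back to uniform
        return np.full(probs.shape[1], 1.0 / probs.shape[1])
    return med / total


def predict_records(encoder: SparseAttentionEncoder, vocab: Vocabulary,
                    registry: ClassRegistry,
                    sequences: Sequence[LabeledSequence],
                    threshold: float = DEFAULT_THRESHOLD,
                    batch_size: int = 16) -> list[ClassificationRecord]:
    """Classify sequences; one record per input, input order preserved.

    Argmax ties break to the first class in registry order.  Sequences
    shorter than k are flagged ``too_short`` rather than dropped.
    """
    chunk_list, owners = [], []
    too_short: set[int] = set()
    for s_i, rec in enumerate(sequences):
        try:
            for ch in tokenize(rec.sequence, vocab,
                               encoder.config.max_embeddings):
                chunk_list.append(ch)
                owners.append(s_i)
        except TokenizerError:
            too_short.add(s_i)
            logger.warning("sequence %r shorter than k=%d; flagged",
                           rec.id, vocab.k)

    n_classes = len(registry)
    probs = np.empty((len(chunk_list), n_classes))
    order = np.argsort([c.n_tokens for c in chunk_list], kind="stable")
    for lo in range(0, len(order), batch_size):
        sel = order[lo:lo + batch_size]
        ids, mask = pad_batch([chunk_list[i] for i in sel], vocab.pad_id)
        logits, _ = encoder.forward(ids, mask, training=False)
        probs[sel] = softmax(logits.data)
    owners_arr = np.asarray(owners)

    records = []
    for s_i, rec in enumerate(sequences):
        if s_i in too_short:
            records.append(ClassificationRecord(
                id=rec.id, probabilities=None, superfamily=None, order=None,
                max_probability=None, verdict=VERDICT_TOO_SHORT))
            continue
        agg = aggregate_chunks(probs[owners_arr == s_i])
        best = int(np.argmax(agg))  # first maximum = registry-order tie-break
        name = registry.class_names[best]
        records.append(ClassificationRecord(
            id=rec.id, probabilities=agg, superfamily=name,
            order=registry.order_of(name), max_probability=float(agg[best]),
            verdict=(VERDICT_CLASSIFIED if agg[best] >= threshold
                     else VERDICT_UNCLASSIFIED)))
    return records


def records_to_frame(records: Sequence[ClassificationRecord],
                     registry: ClassRegistry) -> pd.DataFrame:
    """TSV-shaped table: id, order, superfamily, max prob, verdict, then
    one probability column per class in registry order."""
    rows = []
    for r in records:
        row = {"id": r.id,
               "predicted_order": r.order or "",
               "predicted_superfamily": r.superfamily or "",
               "max_probability": ("" if r.max_probability is None
                                   else f"{r.max_probability:.6f}"),
               "verdict": r.verdict}
        for i, name in enumerate(registry.class_names):
            row[f"p_{name}"] = ("" if r.probabilities is None
                                else f"{r.probabilities[i]:.6f}")
        rows.append(row)
    return pd.DataFrame(rows)


def registry_from_checkpoint_meta(meta: dict) -> ClassRegistry:
    return ClassRegistry.from_names(meta["class_names"],
                                    meta.get("orders", {}))


def classify_fasta(fasta_path: str | Path, checkpoint_path: str | Path,
                   threshold: float = DEFAULT_THRESHOLD,
                   output_tsv: str | Path | None = None,
                   batch_size: int = 16) -> list[ClassificationRecord]:
    """End-to-end inference: FASTA in, records (and optionally TSV) out."""
    encoder, _, meta = load_checkpoint(checkpoint_path)
    registry = registry_from_checkpoint_meta(meta)
    vocab = build_vocabulary(encoder.config.kmer_size)
    sequences = read_fasta(fasta_path)
    records = predict_records(encoder, vocab, registry, sequences,
                              threshold, batch_size)
    if output_tsv is not None:
        records_to_frame(records, registry).to_csv(output_tsv, sep="\t",
                                                   index=False)
    n_cls = sum(r.verdict == VERDICT_CLASSIFIED for r in records)
    logger.info("classified %d/%d sequences at threshold %.2f",
                n_cls, len(records), threshold)
    return records
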