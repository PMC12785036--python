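"""On-the-fly, biologically motivated DNA sequence augmentation.

Ten string-level edits emulate the mutation processes that diversify
real TE copies: point substitutions (SNP), ambiguous bases (Masking),
insertions, deletions, segment duplications (Repeat), strand artefacts
(Reverse, Complement, ReverseComplement) and poly-A tail gain/loss.
During training each kind is applied stochastically; at inference no
augmentation is applied.

The three strand kinds are, by default, a mutually exclusive draw: a
sequence is reversed, complemented, or reverse-complemented, never a
composition of those.  Setting ``strand_exclusive=False`` instead
applies each strand kind independently with its own probability, in the
fixed kind order, so Reverse followed by Complement composes to the
reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

#: Fixed application order of the augmentation kinds.
KINDS = ("SNP", "Masking", "Insertion", "Deletion", "Repeat",
         "Reverse", "Complement", "ReverseComplement",
         "AddTail", "RemoveTail")

_STRAND_KINDS = ("Reverse", "Complement", "ReverseComplement")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"


@dataclass
class AugmentationConfig:
    """Per-kind application probabilities and magnitude parameters.

    Magnitudes default to length-relative draws: SNP/Masking counts are
    uniform in [1, max(1, len/100)]; insertion/deletion/repeat segment
    lengths uniform in [1, max(1, len/20)]; poly-A tails uniform in
    [5, 30] nt.  Fixed integers may be supplied instead.
    """

    snp_prob: float = 0.05
    masking_prob: float = 0.05
    insertion_prob: float = 0.05
    deletion_prob: float = 0.05
    repeat_prob: float = 0.05
    reverse_prob: float = 0.25
    complement_prob: float = 0.25
    reverse_complement_prob: float = 0.25
    add_tail_prob: float = 0.05
    remove_tail_prob: float = 0.05
    strand_exclusive: bool = True

    snp_count: int | None = None        # None -> uniform in [1, len/100]
    mask_count: int | None = None
    max_insert_len: int | None = None   # None -> len/20
    max_delete_len: int | None = None
    max_repeat_len: int | None = None
    tail_len_range: tuple[int, int] = (5, 30)
    min_tail: int = 5                   # shortest A-run that counts as a tail

    def __post_init__(self) -> None:
        for kind in KINDS:
            p = self.probability(kind)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{kind} probability {p} outside [0, 1]")
        lo, hi = self.tail_len_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad tail_len_range {self.tail_len_range}")
        for name in ("snp_count", "mask_count", "max_insert_len",
                     "max_delete_len", "max_repeat_len"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.strand_exclusive:
            total = sum(self.probability(k) for k in _STRAND_KINDS)
            if total > 1.0 + 1e-9:
                raise ValueError(
                    "strand probabilities sum to >1 under strand_exclusive")

    def probability(self, kind: str) -> float:
        key = {"SNP": "snp_prob", "Masking": "masking_prob",
               "Insertion": "insertion_prob", "Deletion": "deletion_prob",
               "Repeat": "repeat_prob", "Reverse": "reverse_prob",
               "Complement": "complement_prob",
               "ReverseComplement": "reverse_complement_prob",
               "AddTail": "add_tail_prob", "RemoveTail": "remove_tail_prob"}[kind]
        return getattr(self, key)

    @classmethod
    def disabled(cls) -> "AugmentationConfig":
        """All probabilities zero (identity pipeline; inference setting)."""
        return cls(snp_prob=0, masking_prob=0, insertion_prob=0,
                   deletion_prob=0, repeat_prob=0, reverse_prob=0,
                   complement_prob=0, reverse_complement_prob=0,
                   add_tail_prob=0, remove_tail_prob=0)


def _count(rng: np.random.Generator, fixed: int | None, seq_len: int,
           divisor: int) -> int:
    if fixed is not None:
        return fixed
    return int(rng.integers(1, max(1, seq_len // divisor) + 1))


def _snp(seq: str, rng: np.random.Generator, cfg: AugmentationConfig) -> str:
    n = min(_count(rng, cfg.snp_count, len(seq), 100), len(seq))
    positions = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for pos in positions:
        old = chars[pos]
        new = old
        while new == old:  # never replace a base with itself
            new = _BASES[rng.integers(4)]
        chars[pos] = new
    return "".join(chars)


def _masking(seq: str, rng: np.random.Generator, cfg: AugmentationConfig) -> str:
    n = min(_count(rng, cfg.mask_count, len(seq), 100), len(seq))
    positions = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for pos in positions:
        chars[pos] = "N"
    return "".join(chars)


def _insertion(seq: str, rng: np.random.Generator, cfg: AugmentationConfig) -> str:
    max_len = cfg.max_insert_len or max(1, len(seq) // 20)
    length = int(rng.integers(1, max_len + 1))
    pos = int(rng.integers(0, len(seq) + 1))
    insert = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
    return seq[:pos] + insert + seq[pos:]


def _deletion(seq: str, rng: np.random.Generator, cfg: AugmentationConfig) -> str:
    max_len = cfg.max_delete_len or max(1, len(seq) // 20)
    length = int(rng.integers(1, max_len + 1))
    if length >= len(seq):
        logger.warning("deletion of %d nt would empty a %d nt sequence; "
                       "skipped", length, len(seq))
        return seq
    pos = int(rng.integers(0, len(seq) - length + 1))
    return seq[:pos] + seq[pos + length:]


def _repeat(seq: str, rng: np.random.Generator, cfg: AugmentationConfig) -> str:
    max_len = cfg.max_repeat_len or max(1, len(seq) // 20)
    length = min(int(rng.integers(1, max_len + 1)), len(seq))
    pos = int(rng.integers(0, len(seq) - length + 1))
    segment = seq[pos:pos + length]
    return seq[:pos + length] + segment + seq[pos + length:]


def reverse(seq: str) -> str:
    return seq[::-1]


def complement(seq: str) -> str:
    """Watson-Crick complement, position-wise; N complements to N."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """The opposite strand, 5'->3'."""
    return seq.translate(_COMPLEMENT)[::-1]


def _add_tail(seq: str, rng: np.random.Generator, cfg: AugmentationConfig) -> str:
    lo, hi = cfg.tail_len_range
    return seq + "A" * int(rng.integers(lo, hi + 1))


def remove_tail(seq: str, min_tail: int = 5) -> str:
    """Strip a trailing poly-A run of at least ``min_tail`` nt, if present."""
    n = len(seq)
    i = n
    while i > 0 and seq[i - 1] == "A":
        i -= 1
    run = n - i
    if run < min_tail or i == 0:  # no tail, or removal would empty the sequence
        return seq
    return seq[:i]


def apply_augmentation(seq: str, kind: str, rng: np.random.Generator,
                       config: AugmentationConfig | None = None) -> str:
    """Apply one augmentation kind to ``seq`` and return the edited string."""
    cfg = config or AugmentationConfig()
    if not seq:
        raise ValueError("cannot augment an empty sequence")
    table: dict[str, Callable[[], str]] = {
        "SNP": lambda: _snp(seq, rng, cfg),
        "Masking": lambda: _masking(seq, rng, cfg),
        "Insertion": lambda: _insertion(seq, rng, cfg),
        "Deletion": lambda: _deletion(seq, rng, cfg),
        "Repeat": lambda: _repeat(seq, rng, cfg),
        "Reverse": lambda: reverse(seq),
        "Complement": lambda: complement(seq),
        "ReverseComplement": lambda: reverse_complement(seq),
        "AddTail": lambda: _add_tail(seq, rng, cfg),
        "RemoveTail": lambda: remove_tail(seq, cfg.min_tail),
    }
    if kind not in table:
        raise ValueError(f"unknown augmentation kind {kind!r}")
    return table[kind]()


def augment_pipeline(seq: str, config: AugmentationConfig,
                     rng: np.random.Generator) -> str:
    """Stochastically compose the augmentation kinds in their fixed order.

    Each kind fires with its configured probability; under
    ``strand_exclusive`` the three strand kinds are replaced by a single
    categorical draw.  Identical ``(seq, config, rng state)`` give
    identical output; the output is never empty.
    """
    out = seq
    for kind in KINDS:
        if config.strand_exclusive and kind in _STRAND_KINDS:
            if kind != "Reverse":
                continue  # handled once, at the strand slot
            u = rng.random()
            edge = 0.0
            for strand_kind in _STRAND_KINDS:
                edge += config.probability(strand_kind)
                if u < edge:
                    out = apply_augmentation(out, strand_kind, rng, config)
                    break
            continue
        if rng.random() < config.probability(kind):
            out = apply_augmentation(out, kind, rng, config)
    return out
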