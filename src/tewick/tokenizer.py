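"""k-mer vocabulary and dilated sliding-window tokenization.

Sequences over {A,C,G,T,N} are cut into overlapping k-mers (default
k=5, giving a 5^5 = 3125-token vocabulary) starting every ``step``
nucleotides.  The step dilates dynamically with sequence length,

    step = clamp(ceil(len(seq) / max_embeddings), 2, k - 1),

so short inputs keep the default two-nucleotide stride (maximal
overlap) while long inputs trade overlap for coverage; the cap at
k - 1 guarantees consecutive k-mers always share at least one
nucleotide.  Token streams longer than the model's embedding budget are
split into consecutive non-overlapping chunks, each prefixed with a CLS
token that anchors classification and global attention.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np

ALPHABET = "ACGTN"

PAD_TOKEN = "[PAD]"
CLS_TOKEN = "[CLS]"
UNK_TOKEN = "[UNK]"
SPECIAL_TOKENS = (PAD_TOKEN, CLS_TOKEN, UNK_TOKEN)


class TokenizerError(ValueError):
    pass


@dataclass(frozen=True)
class Vocabulary:
    """Dense k-mer -> id mapping over {A,C,G,T,N} plus special tokens.

    Ids 0 .. 5^k - 1 enumerate the k-mers in lexicographic order of the
    alphabet; PAD, CLS and UNK follow.  The mapping is a pure function
    of ``k`` and therefore stable across runs.
    """

    k: int
    kmer_to_id: dict[str, int]

    @property
    def n_kmers(self) -> int:
        return len(ALPHABET) ** self.k

    @property
    def size(self) -> int:
        return self.n_kmers + len(SPECIAL_TOKENS)

    @property
    def pad_id(self) -> int:
        return self.n_kmers

    @property
    def cls_id(self) -> int:
        return self.n_kmers + 1

    @property
    def unk_id(self) -> int:
        return self.n_kmers + 2

    def id_of(self, kmer: str) -> int:
        return self.kmer_to_id.get(kmer, self.unk_id)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as a two-column (token, id) TSV for reproducibility."""
        with open(path, "w") as fh:
            fh.write("token\tid\n")
            for kmer, idx in self.kmer_to_id.items():
                fh.write(f"{kmer}\t{idx}\n")
            for offset, tok in enumerate(SPECIAL_TOKENS):
                fh.write(f"{tok}\t{self.n_kmers + offset}\n")


def build_vocabulary(k: int) -> Vocabulary:
    """Enumerate all 5^k k-mers over {A,C,G,T,N} in lexicographic order."""
    if not 1 <= k <= 8:
        raise TokenizerError(f"kmer size {k} outside the supported range 1..8")
    mapping = {"".join(chars): i
               for i, chars in enumerate(product(ALPHABET, repeat=k))}
    return Vocabulary(k=k, kmer_to_id=mapping)


def compute_step(seq_len: int, k: int, max_embeddings: int) -> int:
    """Dynamic sliding-window step: clamp(ceil(len/max_embeddings), 2, k-1)."""
    if k <= 2:
        raise TokenizerError(
            f"kmer size {k} leaves no valid step window (need k >= 3)")
    if seq_len < k:
        raise TokenizerError(f"sequence length {seq_len} shorter than k={k}")
    if max_embeddings < 1:
        raise TokenizerError("max_embeddings must be >= 1")
    raw = -(-seq_len // max_embeddings)  # ceil division
    return int(min(max(raw, 2), k - 1))


@dataclass(frozen=True)
class TokenChunk:
    """One model-ready window of token ids.

    ``token_ids`` starts with CLS followed by k-mer ids (no padding;
    batching pads).  ``starts[i]`` is the 0-based nucleotide coordinate
    of k-mer token i in the source sequence; each token covers
    ``[starts[i], starts[i] + k)``.
    """

    token_ids: np.ndarray       # int64, CLS + k-mer ids
    step: int
    starts: np.ndarray          # int64, one per k-mer token
    k: int
    source_length: int

    @property
    def n_tokens(self) -> int:
        """Total tokens including CLS."""
        return len(self.token_ids)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.k


# vectorized k-mer id computation: base-5 positional encoding
_CHAR_CODE = np.full(128, -1, dtype=np.int64)
for _i, _c in enumerate(ALPHABET):
    _CHAR_CODE[ord(_c)] = _i


def encode_kmer_ids(seq: str, k: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (kmer ids, window starts) for the dilated sliding window."""
    codes = _CHAR_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise TokenizerError("sequence contains characters outside {A,C,G,T,N}")
    n = len(seq)
    starts = np.arange(0, n - k + 1, step, dtype=np.int64)
    powers = len(ALPHABET) ** np.arange(k - 1, -1, -1, dtype=np.int64)
    windows = codes[starts[:, None] + np.arange(k)]
    return windows @ powers, starts


def tokenize(seq: str, vocab: Vocabulary,
             max_embeddings: int = 2048,
             step: int | None = None) -> list[TokenChunk]:
    """Tokenize a sanitized sequence into one or more CLS-prefixed chunks.

    Windows start at 0, step, 2*step, ... while ``start + k <= len(seq)``
    (token count = floor((len-k)/step) + 1).  If the stream exceeds the
    embedding budget (one position is reserved for CLS per chunk), it is
    split into consecutive non-overlapping chunks of at most
    ``max_embeddings - 1`` k-mer tokens.
    """
    k = vocab.k
    if len(seq) < k:
        raise TokenizerError(
            f"sequence shorter than k ({len(seq)} < {k})")
    if step is None:
        step = compute_step(len(seq), k, max_embeddings)
    ids, starts = encode_kmer_ids(seq, k, step)
    per_chunk = max_embeddings - 1
    chunks = []
    for lo in range(0, len(ids), per_chunk):
        hi = lo + per_chunk
        chunk_ids = np.concatenate(
            ([vocab.cls_id], ids[lo:hi])).astype(np.int64)
        chunks.append(TokenChunk(token_ids=chunk_ids, step=step,
                                 starts=starts[lo:hi], k=k,
                                 source_length=len(seq)))
    return chunks


def pad_batch(chunks: list[TokenChunk], pad_id: int,
              length: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Stack chunks into (ids, valid_mask) arrays padded to a common length."""
    n = len(chunks)
    target = length or max(c.n_tokens for c in chunks)
    ids = np.full((n, target), pad_id, dtype=np.int64)
    mask = np.zeros((n, target), dtype=bool)
    for i, c in enumerate(chunks):
        ids[i, :c.n_tokens] = c.token_ids
        mask[i, :c.n_tokens] = True
    return ids, mask
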