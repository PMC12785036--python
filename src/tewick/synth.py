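"""Synthetic labeled TE families for desk-scale testing and benchmarks.

Each family is defined by a consensus drawn from a family-specific base
composition with planted signature motifs (internal, terminal repeats,
inverted terminal repeats, or a poly-A suffix); copies are the
consensus perturbed by per-site substitutions and short indel events.
The default four-family preset imitates the coarse structure of the
Wicker orders at toy scale: an LTR-like family with terminal repeats, a
long poly-A-tailed LINE-like family, a short poly-A-tailed SINE-like
family and a short family with inverted terminal repeats (TIR-like).

This emulates what matters to the classifier -- compositional bias,
length structure, diagnostic motifs, copy divergence -- and nothing
else; there is no phylogeny, no ORFs, no genome context.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .registry import ClassRegistry
from .sequence_db import (DatasetSplits, LabeledSequence, DEFAULT_FRACTIONS,
                          split_dataset, write_fasta)

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class FamilySpecError(ValueError):
    pass


@dataclass(frozen=True)
class Motif:
    """A fixed signature string and where it is planted in the consensus.

    placement: ``internal`` (one copy at a random interior position),
    ``terminal_repeat`` (verbatim at both ends, LTR-like),
    ``inverted_terminal_repeat`` (5' verbatim, 3' reverse complement,
    TIR-like) or ``polya`` (appended A-run of the motif's length).
    """

    sequence: str
    placement: str = "internal"

    def __post_init__(self) -> None:
        if self.placement not in ("internal", "terminal_repeat",
                                  "inverted_terminal_repeat", "polya"):
            raise FamilySpecError(f"unknown placement {self.placement!r}")
        if self.placement != "polya" and (
                not self.sequence or set(self.sequence) - set("ACGT")):
            raise FamilySpecError(f"motif must be non-empty over ACGT: "
                                  f"{self.sequence!r}")


@dataclass(frozen=True)
class FamilySpec:
    """Generative description of one synthetic TE family."""

    name: str
    n_copies: int = 200
    length_range: tuple[int, int] = (300, 1500)
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motifs: tuple[Motif, ...] = ()
    substitution_rate: float = 0.05
    indel_rate: float = 0.002

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise FamilySpecError(f"bad length range {self.length_range}")
        if not 0 <= self.substitution_rate < 0.5:
            raise FamilySpecError("substitution rate must be in [0, 0.5)")
        if not 0 <= self.indel_rate < 0.5:
            raise FamilySpecError("indel rate must be in [0, 0.5)")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise FamilySpecError("base probabilities must sum to 1")
        for m in self.motifs:
            if m.placement != "polya" and len(m.sequence) > lo:
                raise FamilySpecError(
                    f"motif {m.sequence!r} longer than the minimum length {lo}")


def _draw_consensus(spec: FamilySpec, rng: np.random.Generator) -> str:
    length = int(rng.integers(spec.length_range[0],
                              spec.length_range[1] + 1))
    seq = list(rng.choice(_BASES, size=length, p=spec.base_probs))
    suffix = ""
    for m in spec.motifs:
        if m.placement == "internal":
            pos = int(rng.integers(0, length - len(m.sequence) + 1))
            seq[pos:pos + len(m.sequence)] = list(m.sequence)
        elif m.placement == "terminal_repeat":
            seq[:len(m.sequence)] = list(m.sequence)
            seq[-len(m.sequence):] = list(m.sequence)
        elif m.placement == "inverted_terminal_repeat":
            seq[:len(m.sequence)] = list(m.sequence)
            rc = [_COMP[b] for b in reversed(m.sequence)]
            seq[-len(rc):] = rc
        elif m.placement == "polya":
            suffix = "A" * len(m.sequence)
    return "".join(seq) + suffix


def _mutate_copy(consensus: str, spec: FamilySpec,
                 rng: np.random.Generator) -> str:
    chars = np.array(list(consensus))
    n = len(chars)
    # substitutions: each chosen site is redrawn to a different base
    hits = np.flatnonzero(rng.random(n) < spec.substitution_rate)
    for pos in hits:
        options = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = options[rng.integers(3)]
    seq = "".join(chars)
    # indels: Bernoulli(indel_rate) event initiations, single segments 1-10 nt
    n_events = int(rng.binomial(n, spec.indel_rate))
    for _ in range(n_events):
        length = int(rng.integers(1, 11))
        if rng.random() < 0.5 and len(seq) > length:  # deletion
            pos = int(rng.integers(0, len(seq) - length + 1))
            seq = seq[:pos] + seq[pos + length:]
        else:  # insertion
            pos = int(rng.integers(0, len(seq) + 1))
            ins = "".join(rng.choice(_BASES, size=length))
            seq = seq[:pos] + ins + seq[pos:]
    return seq


def _stable_hash(text: str) -> int:
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2 ** 31 - 1)
    return h


def _content_hash(spec: FamilySpec) -> int:
    """Hash of the generative fields only (name excluded).

    Two specs identical except for their name therefore draw the same
    consensus -- which makes a pair of identically parameterized
    families a genuine negative control for separability.
    """
    payload = repr((spec.length_range, spec.base_probs,
                    tuple((m.sequence, m.placement) for m in spec.motifs),
                    spec.substitution_rate, spec.indel_rate))
    return _stable_hash(payload)


def generate_family(spec: FamilySpec, seed: int = 0) -> list[LabeledSequence]:
    """Draw the family consensus, then ``n_copies`` perturbed copies.

    Deterministic given ``(spec, seed)``.  The consensus stream is
    seeded by the spec's generative content, the copy-noise stream by
    its name, so re-seeding changes both while a renamed-but-identical
    spec keeps the consensus and redraws only the copy noise.
    """
    cons_rng = np.random.default_rng(
        [seed % (2 ** 31), _content_hash(spec), 0])
    copy_rng = np.random.default_rng(
        [seed % (2 ** 31), _stable_hash(spec.name), 1])
    consensus = _draw_consensus(spec, cons_rng)
    return [
        LabeledSequence(id=f"{spec.name}_{i:04d}",
                        sequence=_mutate_copy(consensus, spec, copy_rng),
                        label=spec.name)
        for i in range(spec.n_copies)
    ]


def family_consensus(spec: FamilySpec, seed: int = 0) -> str:
    """The (noise-free) consensus a given (spec, seed) pair generates."""
    cons_rng = np.random.default_rng(
        [seed % (2 ** 31), _content_hash(spec), 0])
    return _draw_consensus(spec, cons_rng)


# -- presets -----------------------------------------------------------------


def four_family_preset(n_copies: int = 200,
                       substitution_rate: float = 0.05,
                       indel_rate: float = 0.002) -> list[FamilySpec]:
    """Four well-separated families spanning the main TE orders.

    Distinct base compositions, length ranges and 12-15 nt signature
    motifs; the SINE-like and LINE-like families carry poly-A tails,
    the LTR-like family terminal repeats, the TIR-like family inverted
    terminal repeats.  Lengths stay within 300-1500 nt.
    """
    return [
        FamilySpec(
            name="LTRlike", n_copies=n_copies, length_range=(600, 1500),
            base_probs=(0.20, 0.30, 0.30, 0.20),
            motifs=(Motif("TGTTGGGCCCAACA", "terminal_repeat"),
                    Motif("GGCCATCAGGCC", "internal")),
            substitution_rate=substitution_rate, indel_rate=indel_rate),
        FamilySpec(
            name="LINElike", n_copies=n_copies, length_range=(800, 1500),
            base_probs=(0.35, 0.15, 0.15, 0.35),
            motifs=(Motif("ATTAGGATTAGG", "internal"),
                    Motif("A" * 15, "polya")),
            substitution_rate=substitution_rate, indel_rate=indel_rate),
        FamilySpec(
            name="SINElike", n_copies=n_copies, length_range=(300, 500),
            base_probs=(0.25, 0.25, 0.25, 0.25),
            motifs=(Motif("CCGTACTCCGTA", "internal"),
                    Motif("A" * 12, "polya")),
            substitution_rate=substitution_rate, indel_rate=indel_rate),
        FamilySpec(
            name="TIRlike", n_copies=n_copies, length_range=(300, 700),
            base_probs=(0.30, 0.25, 0.20, 0.25),
            motifs=(Motif("CAGTGCGTGCACTG", "inverted_terminal_repeat"),
                    Motif("TTCGACGTTCGA", "internal")),
            substitution_rate=substitution_rate, indel_rate=indel_rate),
    ]


def negative_control_pair(n_copies: int = 200,
                          substitution_rate: float = 0.05) -> list[FamilySpec]:
    """Two families identical in every respect except the label.

    Because the consensus stream is seeded by generative content, both
    draw the SAME consensus and differ only in copy noise, so no
    classifier can separate them beyond chance -- the floor against
    which real separability is judged.
    """
    base = FamilySpec(name="ControlA", n_copies=n_copies,
                      length_range=(500, 1000),
                      motifs=(Motif("GATTACAGATTA", "internal"),),
                      substitution_rate=substitution_rate)
    return [base,
            FamilySpec(name="ControlB", n_copies=n_copies,
                       length_range=(500, 1000),
                       motifs=(Motif("GATTACAGATTA", "internal"),),
                       substitution_rate=substitution_rate)]




def registry_for(specs: Sequence[FamilySpec]) -> ClassRegistry:
    """A registry whose classes are the family names, in given order."""
    return ClassRegistry.from_names([s.name for s in specs])


def generate_benchmark(family_specs: Sequence[FamilySpec],
                       split_fractions=DEFAULT_FRACTIONS,
                       seed: int = 0,
                       out_dir: str | Path | None = None
                       ) -> tuple[list[LabeledSequence], DatasetSplits]:
    """Generate all families, split them, optionally write FASTA+manifest.

    Writes ``families.fasta`` (``#``-labeled headers), ``manifest.tsv``
    and a JSON record of the specs when ``out_dir`` is given.
    """
    names = [s.name for s in family_specs]
    if len(set(names)) != len(names):
        raise FamilySpecError("duplicate family names")
    if len(names) < 2:
        raise FamilySpecError("need at least two families")
    records: list[LabeledSequence] = []
    for spec in family_specs:
        records.extend(generate_family(spec, seed))
    splits = split_dataset(records, split_fractions, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out / "families.fasta")
        splits.write_manifest(out / "manifest.tsv")
        spec_record = [{**asdict(s)} for s in family_specs]
        (out / "specs.json").write_text(json.dumps(
            {"seed": seed, "fractions": list(split_fractions),
             "families": spec_record}, indent=1))
    return records, splits
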