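"""Synthetic family generator: determinism, noise statistics, separability."""

import edlib
import numpy as np
import pytest

from tewick.sequence_db import read_labeled_fasta
from tewick.synth import (FamilySpec, FamilySpecError, Motif,
                          family_consensus, four_family_preset,
                          generate_benchmark, generate_family,
                          negative_control_pair, registry_for)


def spec(name="Fam", **kw):
    base = dict(n_copies=20, length_range=(400, 600),
                substitution_rate=0.05, indel_rate=0.0)
    base.update(kw)
    return FamilySpec(name=name, **base)


class TestGenerateFamily:
    def test_zero_noise_copies_equal_consensus(self):
        s = spec(substitution_rate=0.0, indel_rate=0.0)
        copies = generate_family(s, seed=3)
        consensus = family_consensus(s, seed=3)
        assert all(c.sequence == consensus for c in copies)
        assert all(c.label == "Fam" for c in copies)

    def test_seeding_contract(self):
        s = spec()
        a = generate_family(s, seed=1)
        b = generate_family(s, seed=1)
        c = generate_family(s, seed=2)
        assert a == b
        assert a != c
        assert family_consensus(s, 1) != family_consensus(s, 2)

    def test_renamed_identical_spec_shares_consensus(self):
        a = spec(name="X")
        b = spec(name="Y")
        assert family_consensus(a, 5) == family_consensus(b, 5)

    def test_substitution_rate_yields_binomial_hamming_distance(self):
        n_len, rate, n_copies = 1000, 0.05, 60
        s = spec(n_copies=n_copies, length_range=(n_len, n_len),
                 substitution_rate=rate)
        consensus = family_consensus(s, seed=4)
        copies = generate_family(s, seed=4)
        dists = [sum(a != b for a, b in zip(consensus, c.sequence))
                 for c in copies]
        mean_expected = n_len * rate
        se = np.sqrt(n_len * rate * (1 - rate) / n_copies)
        assert abs(np.mean(dists) - mean_expected) < 3 * se

    def test_motif_planting(self):
        s = spec(motifs=(Motif("GATTACAGATTACA", "terminal_repeat"),),
                 substitution_rate=0.0)
        consensus = family_consensus(s, seed=0)
        assert consensus.startswith("GATTACAGATTACA")
        assert consensus.endswith("GATTACAGATTACA")
        s_itr = spec(motifs=(Motif("AACCGGTT", "inverted_terminal_repeat"),),
                     substitution_rate=0.0)
        cons = family_consensus(s_itr, seed=0)
        assert cons.startswith("AACCGGTT") and cons.endswith("AACCGGTT"[::-1]
                                                             .translate(str.maketrans("ACGT", "TGCA")))
        s_pa = spec(motifs=(Motif("A" * 12, "polya"),), substitution_rate=0.0)
        assert family_consensus(s_pa, seed=0).endswith("A" * 12)

    def test_motif_longer_than_min_length_rejected(self):
        with pytest.raises(FamilySpecError):
            spec(length_range=(10, 20), motifs=(Motif("A" * 30, "internal"),))

    def test_rates_validated(self):
        with pytest.raises(FamilySpecError):
            spec(substitution_rate=0.6)
        with pytest.raises(FamilySpecError):
            spec(indel_rate=-0.1)


class TestGenerateBenchmark:
    def test_counts_and_manifest(self, tmp_path, four_family_small):
        records, splits, _ = four_family_small
        assert len(records) == 160  # 4 x 40
        for name in ("LTRlike", "LINElike", "SINElike", "TIRlike"):
            assert splits.class_counts("train")[name] == 30
            assert splits.class_counts("validation")[name] == 6
            assert splits.class_counts("test")[name] == 4

    def test_manifest_counts_for_200_copies(self):
        specs = four_family_preset(n_copies=200)
        _, splits = generate_benchmark(specs, seed=0)
        for name in splits.class_counts("train"):
            assert splits.class_counts("train")[name] == 150
            assert splits.class_counts("validation")[name] == 30
            assert splits.class_counts("test")[name] == 20

    def test_fasta_roundtrip_via_sequence_db(self, tmp_path):
        specs = four_family_preset(n_copies=5)
        records, _ = generate_benchmark(specs, seed=2, out_dir=tmp_path)
        assert (tmp_path / "specs.json").exists()
        reread = read_labeled_fasta(tmp_path / "families.fasta",
                                    registry=registry_for(specs))
        assert reread == records

    def test_duplicate_names_rejected(self):
        with pytest.raises(FamilySpecError):
            generate_benchmark([spec("A"), spec("A")])

    def test_preset_interfamily_identity_below_60_percent(self):
        # global pairwise alignment identity on a sample of cross-family pairs
        specs = four_family_preset(n_copies=6)
        families = {s.name: generate_family(s, seed=9) for s in specs}
        rng = np.random.default_rng(0)
        idents = []
        names = list(families)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                for _ in range(4):
                    a = families[names[i]][rng.integers(6)].sequence
                    b = families[names[j]][rng.integers(6)].sequence
                    d = edlib.align(a, b, task="distance")["editDistance"]
                    idents.append(1.0 - d / max(len(a), len(b)))
        assert np.mean(idents) < 0.60

    def test_negative_control_families_are_near_identical(self):
        specs = negative_control_pair(n_copies=4)
        fam_a = generate_family(specs[0], seed=1)
        fam_b = generate_family(specs[1], seed=1)
        # same consensus, independent noise: identity far above cross-family
        d = edlib.align(fam_a[0].sequence, fam_b[0].sequence,
                        task="distance")["editDistance"]
        ident = 1.0 - d / max(len(fam_a[0].sequence), len(fam_b[0].sequence))
        assert ident > 0.85

    def test_separability_decreases_with_substitution_rate(self):
        # k-mer-composition nearest-centroid accuracy, same seeds throughout
        from tewick.tokenizer import build_vocabulary, encode_kmer_ids

        def kmer_profile(seq):
            ids, _ = encode_kmer_ids(seq, 3, 1)
            prof = np.bincount(ids, minlength=125).astype(float)
            return prof / prof.sum()

        def centroid_accuracy(sub_rate):
            specs = four_family_preset(n_copies=12,
                                       substitution_rate=sub_rate)
            fams = {s.name: [kmer_profile(r.sequence)
                             for r in generate_family(s, seed=13)]
                    for s in specs}
            cents = {n: np.mean(v[:6], axis=0) for n, v in fams.items()}
            correct = total = 0
            for n, profs in fams.items():
                for p in profs[6:]:
                    pred = min(cents, key=lambda c: np.linalg.norm(p - cents[c]))
                    correct += pred == n
                    total += 1
            return correct / total

        accs = [centroid_accuracy(r) for r in (0.02, 0.20, 0.45)]
        assert accs[0] >= accs[1] >= accs[2] or accs[0] > accs[2]
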