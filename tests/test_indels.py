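import numpy as np
import pytest

from mutspect import (
    CATEGORY_16,
    GenomeSequence,
    ID83_LABELS,
    IndelCall,
    VariantRecord,
    VariantSet,
    build_indel_spectrum,
    classify_indel,
    microhomology_length,
    normalize_indel,
    repeat_units,
)
from mutspect.indels import CHANNEL_TO_CATEGORY, IndelSpectrum

from oracles import (
    brute_indel_channel,
    brute_left_align_deletion,
    brute_left_align_insertion,
    brute_microhomology,
    brute_repeat_units,
)


def var(chrom, pos, ref, alt):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=50, depth=20,
        samples=frozenset(["s1"]),
    )


def repeat_rich_genome(rng, length=400):
    """Random sequence interspersed with short tandem repeats."""
    parts, n = [], 0
    while n < length:
        if rng.random() < 0.3:
            unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
            copies = int(rng.integers(2, 6))
            parts.append(unit * copies)
            n += len(unit) * copies
        else:
            parts.append(str(rng.choice(list("ACGT"))))
            n += 1
    return GenomeSequence({"chr1": "".join(parts)})


class TestNormalizeIndel:
    def test_homopolymer_deletion_left_shifts(self):
        #            123456789
        g = GenomeSequence({"chr1": "GGCAAATTT"})
        call = normalize_indel(var("chr1", 5, "AA", "A"), g)
        assert call.kind == "deletion" and call.sequence == "A"
        assert call.pos == 3  # anchor moves to the C before the A run
        assert call.left_aligned

    def test_insertion_keeps_anchor_when_no_repeat(self):
        g = GenomeSequence({"chr1": "GGCAT"})
        call = normalize_indel(var("chr1", 3, "C", "CTG"), g)
        assert call.kind == "insertion"
        assert (call.pos, call.sequence) == (3, "TG")

    def test_reference_mismatch_raises(self):
        g = GenomeSequence({"chr1": "GGCAT"})
        with pytest.raises(Exception, match="mismatch"):
            normalize_indel(var("chr1", 3, "CT", "C"), g)

    def test_matches_exhaustive_shift_oracle(self, rng):
        for _ in range(60):
            g = repeat_rich_genome(rng)
            seq = g.chromosomes["chr1"]
            for _ in range(20):
                k = int(rng.integers(1, 5))
                if rng.random() < 0.5:  # deletion
                    a = int(rng.integers(1, len(seq) - k))
                    v = var("chr1", a, seq[a - 1 : a + k], seq[a - 1])
                    call = normalize_indel(v, g)
                    start0, deleted = brute_left_align_deletion(seq, a, k)
                    assert call.pos == start0  # anchor is base before segment
                    assert call.sequence == deleted
                else:  # insertion, half the time copying the next k bases
                    a = int(rng.integers(1, len(seq) - k))
                    ins = (
                        seq[a : a + k]
                        if rng.random() < 0.5
                        else "".join(rng.choice(list("ACGT"), size=k))
                    )
                    v = var("chr1", a, seq[a - 1], seq[a - 1] + ins)
                    call = normalize_indel(v, g)
                    anchor0, ins_norm = brute_left_align_insertion(seq, a - 1, ins)
                    assert call.pos == anchor0 + 1
                    assert call.sequence == ins_norm


class TestRepeatUnits:
    def test_homopolymer_run_length_counts_deleted_base(self):
        #                       123456789
        g = GenomeSequence({"chr1": "GCAAAATGC"})
        call = normalize_indel(var("chr1", 3, "AA", "A"), g)
        assert repeat_units(call, g) == 4

    def test_tandem_dinucleotide_copies(self):
        #                       0123456789
        g = GenomeSequence({"chr1": "CTGTGTGACC"})
        call = normalize_indel(var("chr1", 1, "CTG", "C"), g)
        assert call.sequence == "TG"
        assert repeat_units(call, g) == 3

    def test_insertion_with_no_adjacent_copy_has_zero_units(self):
        g = GenomeSequence({"chr1": "GGCAT"})
        call = IndelCall("chr1", 3, "insertion", "TG", left_aligned=True)
        assert repeat_units(call, g) == 0

    def test_matches_scanning_oracle(self, rng):
        for _ in range(60):
            g = repeat_rich_genome(rng)
            seq = g.chromosomes["chr1"]
            for _ in range(20):
                k = int(rng.integers(1, 5))
                a = int(rng.integers(1, len(seq) - k))
                if rng.random() < 0.5:
                    v = var("chr1", a, seq[a - 1 : a + k], seq[a - 1])
                else:
                    ins = (
                        seq[a : a + k]
                        if rng.random() < 0.5
                        else "".join(rng.choice(list("ACGT"), size=k))
                    )
                    v = var("chr1", a, seq[a - 1], seq[a - 1] + ins)
                call = normalize_indel(v, g)
                assert repeat_units(call, g) == brute_repeat_units(
                    seq, call.pos - 1, call.kind, call.sequence
                )


class TestMicrohomology:
    def test_prefix_homology_with_3prime_flank(self):
        # deleted TAGC; 3' flank begins TAG -> MH 3
        #                       12345678901234
        g = GenomeSequence({"chr1": "GGTAGCTAGGACCA"})
        call = IndelCall("chr1", 2, "deletion", "TAGC", left_aligned=True)
        assert g.slice("chr1", 3, 6) == "TAGC"
        assert microhomology_length(call, g) == 3

    def test_no_shared_sequence_gives_zero(self):
        g = GenomeSequence({"chr1": "GGTACCGGAA"})
        call = IndelCall("chr1", 2, "deletion", "TACC", left_aligned=True)
        assert microhomology_length(call, g) == 0

    def test_rejects_insertions_and_repeat_context(self):
        g = GenomeSequence({"chr1": "GGTAGCTAGG"})
        with pytest.raises(ValueError):
            microhomology_length(
                IndelCall("chr1", 2, "insertion", "TAGC"), g
            )
        g2 = GenomeSequence({"chr1": "GGTATATACC"})
        call = IndelCall("chr1", 2, "deletion", "TA", left_aligned=True)
        with pytest.raises(ValueError, match="repeat"):
            microhomology_length(call, g2)

    def test_matches_two_sided_scan_oracle(self, rng):
        checked = 0
        while checked < 400:
            g = repeat_rich_genome(rng, length=120)
            seq = g.chromosomes["chr1"]
            k = int(rng.integers(2, 7))
            a = int(rng.integers(1, len(seq) - 2 * k))
            v = var("chr1", a, seq[a - 1 : a + k], seq[a - 1])
            call = normalize_indel(v, g)
            kk = len(call.sequence)
            if repeat_units(call, g) != 1:
                continue
            expected = brute_microhomology(seq, call.pos - 1, call.sequence)
            assert microhomology_length(call, g) == min(expected, kk - 1)
            checked += 1


class TestClassifyIndel:
    def test_isolated_single_base_deletion(self):
        #            123456
        g = GenomeSequence({"chr1": "GACTGA"})
        call = normalize_indel(var("chr1", 3, "CT", "C"), g)
        assert ID83_LABELS[classify_indel(call, g)] == "1:Del:T:1"

    def test_purine_single_base_events_strand_collapse(self):
        g = GenomeSequence({"chr1": "TCGTT"})
        call = normalize_indel(var("chr1", 2, "CG", "C"), g)
        assert ID83_LABELS[classify_indel(call, g)] == "1:Del:C:1"

    def test_long_deletion_with_microhomology(self):
        # 6 bp deletion whose 3' flank shares a 2 bp prefix -> 5+ MH bin
        core = "TACGCA"
        g = GenomeSequence({"chr1": "GG" + core + "TATTTTTT"})
        call = IndelCall("chr1", 2, "deletion", core, left_aligned=True)
        lab = ID83_LABELS[classify_indel(call, g)]
        assert lab == "5+:Del:M:2"

    def test_repeat_takes_precedence_over_microhomology(self):
        # TG deleted from a (TG)x3 tract is a repeat deletion, never MH
        g = GenomeSequence({"chr1": "CATGTGTGCC"})
        call = normalize_indel(var("chr1", 2, "ATG", "A"), g)
        assert ID83_LABELS[classify_indel(call, g)] == "2:Del:R:3"

    def test_representation_invariance_across_vcf_shifts(self):
        # the same TG deletion written at three VCF anchors
        g = GenomeSequence({"chr1": "CATGTGTGCC"})
        reps = [
            var("chr1", 2, "ATG", "A"),
            var("chr1", 4, "GTG", "G"),
            var("chr1", 6, "GTG", "G"),
        ]
        labels = {
            ID83_LABELS[classify_indel(normalize_indel(v, g), g)] for v in reps
        }
        assert labels == {"2:Del:R:3"}

    def test_matches_independent_priority_rule(self, rng):
        checked = 0
        while checked < 2000:
            g = repeat_rich_genome(rng)
            seq = g.chromosomes["chr1"]
            for _ in range(25):
                k = int(rng.integers(1, 7))
                a = int(rng.integers(1, len(seq) - 2 * k - 1))
                if rng.random() < 0.5:
                    v = var("chr1", a, seq[a - 1 : a + k], seq[a - 1])
                else:
                    ins = (
                        seq[a : a + k]
                        if rng.random() < 0.5
                        else "".join(rng.choice(list("ACGT"), size=k))
                    )
                    v = var("chr1", a, seq[a - 1], seq[a - 1] + ins)
                call = normalize_indel(v, g)
                expected = brute_indel_channel(
                    seq, call.pos - 1, call.kind, call.sequence
                )
                assert ID83_LABELS[classify_indel(call, g)] == expected
                checked += 1


class TestIndelSpectrum:
    def test_empty_set_gives_zero_spectrum(self, toy_genome):
        vs = VariantSet([], n_samples=1, n_total_calls=0)
        assert build_indel_spectrum(vs, toy_genome).total == 0

    def test_known_composition_bookkeeping(self):
        g = GenomeSequence({"chr1": "GACTGACTGACTGATTACGCATATTTTTTGG"})
        records = [
            var("chr1", 3, "CT", "C"),
            var("chr1", 7, "CT", "C"),
            var("chr1", 11, "CT", "C"),
            var("chr1", 15, "TTACGC", "T"),  # 5 bp deletion
        ]
        vs = VariantSet(records, n_samples=1, n_total_calls=4)
        spec = build_indel_spectrum(vs, g)
        c16 = spec.collapse_16()
        assert c16["1bp_del_T"] == 3
        assert c16["del_5+"] + c16["mh_del_5+"] == 1
        assert sum(c16.values()) == spec.total == 4

    def test_collapse_totals_match(self, rng):
        counts = rng.integers(0, 9, size=83).astype(float)
        spec = IndelSpectrum(counts)
        assert sum(spec.collapse_16().values()) == pytest.approx(spec.total)

    def test_channel_category_map_is_complete(self):
        assert len(ID83_LABELS) == 83
        assert set(CHANNEL_TO_CATEGORY) == set(range(16))
        assert len(CATEGORY_16) == 16

    def test_tsv_export(self, tmp_path, rng):
        spec = IndelSpectrum(rng.integers(0, 9, 83).astype(float))
        spec.to_tsv(tmp_path / "id83.tsv")
        spec.collapse_16_to_tsv(tmp_path / "c16.tsv")
        assert len((tmp_path / "id83.tsv").read_text().splitlines()) == 84
        assert len((tmp_path / "c16.tsv").read_text().splitlines()) == 17
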