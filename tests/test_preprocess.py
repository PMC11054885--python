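"""Read filtering rules and the unique aligner, cross-checked against a
brute-force all-positions Hamming oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from miredit.preprocess import ReadFilterParams, align_unique, filter_reads, read_sam, write_sam
from miredit.reference import HairpinReference
from miredit.io import MatureAnnotation

from conftest import make_read


class TestFilterReads:
    @pytest.mark.parametrize(
        "length,expect_kept",
        [(14, False), (15, True), (28, True), (29, False)],
    )
    def test_length_bounds(self, length, expect_kept):
        reads = [make_read("r", "A" * length)]
        kept, _ = filter_reads(reads, ReadFilterParams())
        assert bool(kept) is expect_kept

    @pytest.mark.parametrize("n_hq,expect_kept", [(19, True), (18, False)])
    def test_quality_fraction(self, n_hq, expect_kept):
        # 20-nt read: 19/20 bases at Q30 is exactly the 95% cutoff
        quals = [30] * n_hq + [20] * (20 - n_hq)
        reads = [make_read("r", "ACGT" * 5, quals)]
        kept, report = filter_reads(reads, ReadFilterParams())
        assert bool(kept) is expect_kept
        if not expect_kept:
            assert report.removed["low_quality"] == 1

    def test_adapter_trimming_requires_min_overlap(self):
        adapter = "TGGAATTCTCGGGTGCCAAGG"
        insert = "ACGTACGTACGTACGTAC"  # 18 nt
        params = ReadFilterParams(adapter=adapter)
        kept, _ = filter_reads([make_read("full", insert + adapter[:10])], params)
        assert kept and kept[0].seq == insert
        # 7-nt adapter suffix is below the 8-nt overlap rule: kept untrimmed
        kept2, _ = filter_reads([make_read("short", insert + adapter[:7])], params)
        assert kept2 and kept2[0].seq == insert + adapter[:7]

    def test_qc_report_counts_sum(self):
        reads = [
            make_read("ok", "ACGT" * 5),
            make_read("short", "ACGTACG"),
            make_read("long", "A" * 40),
            make_read("lowq", "ACGT" * 5, [20] * 20),
        ]
        kept, report = filter_reads(reads, ReadFilterParams())
        assert report.total == 4 and report.kept == len(kept) == 1
        assert sum(report.removed.values()) == 3


def brute_force_align(seq, ref, max_mm=1):
    """All-positions Hamming scan; returns list of (hp, start0, mm)."""
    hits = []
    for hp, hseq in ref.sequences.items():
        for start in range(len(hseq) - len(seq) + 1):
            mm = sum(1 for a, b in zip(seq, hseq[start : start + len(seq)]) if a != b)
            if mm <= max_mm:
                hits.append((hp, start, mm))
    if not hits:
        return None
    best = min(mm for *_, mm in hits)
    best_hits = [h for h in hits if h[2] == best]
    return best_hits[0] if len(best_hits) == 1 else None


class TestAlignUnique:
    def test_exact_read_with_nta_tail(self, tiny_ref):
        mature = tiny_ref.mature_seq(tiny_ref.annotations[0])
        read = make_read("r", mature + "AA")
        alns = align_unique([read], tiny_ref, trim3=2)
        assert len(alns) == 1
        a = alns[0]
        assert a.hairpin_id == "hpA" and a.start == 3 and a.mismatches == 0
        assert a.length == len(mature)

    def test_read_matching_two_hairpins_discarded(self):
        shared = "ACGTTGCAACGGTCATGCAATC"
        ref = HairpinReference(
            {"h1": "GGG" + shared + "TTTTTTTTTT", "h2": "CCC" + shared + "AAAAAAAAAA"},
            [MatureAnnotation("h1", "m1", 4, 25), MatureAnnotation("h2", "m2", 4, 25)],
        )
        assert align_unique([make_read("r", shared + "AA")], ref, trim3=2) == []

    def test_two_internal_mismatches_discarded(self, tiny_ref):
        mature = tiny_ref.mature_seq(tiny_ref.annotations[0])
        mutated = list(mature)
        for i in (4, 9):
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        read = make_read("r", "".join(mutated) + "AA")
        assert brute_force_align("".join(mutated), tiny_ref) is None
        assert align_unique([read], tiny_ref, trim3=2) == []

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_unique([make_read("r", "ACGTACGTACGTACGT")], HairpinReference({}, []), 2)

    def test_one_mismatch_tolerated_and_counted(self, tiny_ref):
        mature = tiny_ref.mature_seq(tiny_ref.annotations[1])
        mutated = list(mature)
        mutated[7] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[7]]
        alns = align_unique([make_read("r", "".join(mutated) + "TT")], tiny_ref, trim3=2)
        assert len(alns) == 1 and alns[0].mismatches == 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        """Random reads (clean, mutated, or random junk) agree with the
        exhaustive Hamming-scan oracle on a multi-hairpin reference."""
        from miredit.simulate import SimConfig, generate_reference

        rng = np.random.default_rng(seed)
        ref = generate_reference(SimConfig(n_hairpins=10, rng_seed=seed % 17))
        ann = ref.annotations[rng.integers(len(ref.annotations))]
        mature = ref.mature_seq(ann)
        kind = rng.integers(3)
        if kind == 0:
            seq = mature
        elif kind == 1:
            pos = int(rng.integers(len(mature)))
            bases = [b for b in "ACGT" if b != mature[pos]]
            seq = mature[:pos] + str(rng.choice(bases)) + mature[pos + 1 :]
        else:
            seq = "".join(rng.choice(list("ACGT"), size=len(mature)))
        read = make_read("r", seq + "AA")
        alns = align_unique([read], ref, trim3=2)
        oracle = brute_force_align(seq, ref)
        if oracle is None:
            assert alns == []
        else:
            assert len(alns) == 1
            hp, start0, mm = oracle
            assert (alns[0].hairpin_id, alns[0].start - 1, alns[0].mismatches) == (hp, start0, mm)

    def test_filtered_reads_never_align(self, tiny_ref):
        """Filter-then-align contract: rejected reads contribute nothing."""
        params = ReadFilterParams()
        reads = [make_read("short", "ACGTACG"), make_read("lowq", "ACGT" * 5, [10] * 20)]
        kept, _ = filter_reads(reads, params)
        assert kept == []
        assert align_unique(kept, tiny_ref, params.trim3) == []


def test_sam_round_trip(tmp_path, tiny_ref):
    mature = tiny_ref.mature_seq(tiny_ref.annotations[0])
    alns = align_unique([make_read("r1", mature + "AA")], tiny_ref, trim3=2)
    sam = tmp_path / "out.sam"
    write_sam(sam, alns, tiny_ref)
    back = read_sam(sam)
    assert len(back) == 1
    assert (back[0].hairpin_id, back[0].start, back[0].seq) == (
        alns[0].hairpin_id,
        alns[0].start,
        alns[0].seq,
    )


def test_sam_import_discards_multimapped(tmp_path, tiny_ref):
    mature = tiny_ref.mature_seq(tiny_ref.annotations[0])
    a = align_unique([make_read("dup", mature + "AA")], tiny_ref, trim3=2)[0]
    sam = tmp_path / "multi.sam"
    from dataclasses import replace

    write_sam(sam, [a, replace(a, hairpin_id="hpB", start=1)], tiny_ref)
    assert read_sam(sam) == []
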