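"""Seed-edit application and WT/ET target scanning, with string-oracle
and combinatorial-null checks."""

import numpy as np
import pytest
from scipy import stats

from miredit.io import revcomp
from miredit.retarget import (
    ScanParams,
    apply_edit,
    diff_target_sets,
    scan_targets,
    wildtype_variant,
)

MIR497 = "CAGCAGCACACTGTGGTTTGT"  # 21-nt mature used as a worked example


class TestApplyEdit:
    def test_tag_naming_and_single_difference(self):
        et = apply_edit("ssc-miR-497", MIR497, 2, "A", "G")
        assert et.tag == "ssc-miR-497_2"
        diffs = [i for i, (a, b) in enumerate(zip(MIR497, et.sequence)) if a != b]
        assert diffs == [1] and et.sequence[1] == "G"
        # a position-2 edit changes the first base of the seed
        assert et.seed[0] == "G" and wildtype_variant("x", MIR497).seed[0] == "A"

    def test_edit_outside_seed_leaves_seed(self):
        et = apply_edit("m", MIR497, 9, MIR497[8], "T")
        assert et.seed == wildtype_variant("m", MIR497).seed

    def test_ref_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            apply_edit("m", MIR497, 2, "C", "G")
        with pytest.raises(ValueError, match="position"):
            apply_edit("m", MIR497, 99, "A", "G")


class TestSeedScan:
    def _utr_with(self, motif, offset, rng, length=120):
        seq = list(rng.choice(list("ACGT"), size=length))
        seq[offset : offset + len(motif)] = list(motif)
        return "".join(seq)

    def test_designed_8mer_reported_at_offset(self, rng):
        wt = wildtype_variant("m", MIR497)
        motif = revcomp(wt.sequence[1:8]) + "A"
        utr = self._utr_with(motif, 40, rng)
        ts = scan_targets(wt, {"g1": utr})
        assert "g1" in ts.genes
        hit8 = [h for h in ts.hits if h.match_class == "8mer"]
        assert hit8 and hit8[0].position == 41  # 1-based

    def test_seed_edit_destroys_match_unless_restored(self, rng):
        wt = wildtype_variant("m", MIR497)
        et = apply_edit("m", MIR497, 4, MIR497[3], "G")
        motif = revcomp(wt.sequence[1:8]) + "A"
        utr = self._utr_with(motif, 40, rng)
        # guard against accidental ET matches elsewhere in the random part
        et_motif6 = revcomp(et.sequence[1:7])
        assume_clean = et_motif6 not in utr
        ts_et = scan_targets(et, {"g1": utr})
        if assume_clean:
            assert "g1" not in ts_et.genes
        utr_restored = self._utr_with(revcomp(et.sequence[1:8]) + "A", 40, rng)
        assert "g1" in scan_targets(et, {"g1": utr_restored}).genes

    def test_edit_outside_positions_1_to_8_keeps_target_set(self, rng):
        wt = wildtype_variant("m", MIR497)
        et = apply_edit("m", MIR497, 12, MIR497[11], "G")
        utrs = {
            f"g{i}": "".join(rng.choice(list("ACGT"), size=500)) for i in range(30)
        }
        assert scan_targets(wt, utrs).genes == scan_targets(et, utrs).genes

    def test_scan_order_independent(self, rng):
        wt = wildtype_variant("m", MIR497)
        utrs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(20)}
        a = scan_targets(wt, utrs)
        b = scan_targets(wt, dict(reversed(list(utrs.items()))))
        assert a.genes == b.genes

    def test_random_utr_6mer_rate_matches_combinatorial_null(self):
        """Occurrences of the 6-nt seed complement in random UTRs follow
        the 1/4^6 per-position null (Poisson 99% band on the total)."""
        rng = np.random.default_rng(77)
        wt = wildtype_variant("m", MIR497)
        n_utr, L = 200, 1000
        total = 0
        for i in range(n_utr):
            utr = "".join(rng.choice(list("ACGT"), size=L))
            hits = scan_targets(wt, {"g": utr}).hits
            # site6-anchored classes share the 6mer start position
            total += sum(1 for h in hits if h.match_class in ("6mer", "7mer-A1"))
        lam = n_utr * (L - 5) / 4**6
        assert stats.poisson.ppf(0.005, lam) <= total <= stats.poisson.ppf(0.995, lam)


class TestScoreScan:
    def test_perfect_complement_passes_thresholds(self):
        wt = wildtype_variant("m", MIR497)
        utr = "TTTT" + revcomp(wt.sequence) + "TTTT"
        ts = scan_targets(wt, {"g": utr}, ScanParams(mode="score"))
        assert "g" in ts.genes
        hit = ts.hits[0]
        # 21 WC pairs, 7 of them seed-weighted x4: 14*5 + 7*5*4 = 210
        assert hit.score == pytest.approx(210.0)
        assert hit.energy <= -10.0

    def test_non_complementary_utr_scores_below_threshold(self):
        # homopolymer UTR offers no seed pairing at all
        wt = wildtype_variant("m", MIR497)
        ts = scan_targets(wt, {"g": "C" * 200}, ScanParams(mode="score"))
        assert ts.genes == set()

    def test_reported_hits_respect_thresholds(self, rng):
        wt = wildtype_variant("m", MIR497)
        utrs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(10)}
        params = ScanParams(mode="score")
        for h in scan_targets(wt, utrs, params).hits:
            assert h.score >= params.min_score and h.energy <= params.max_energy

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            scan_targets(wildtype_variant("m", MIR497), {"g": "ACGT" * 10}, ScanParams(mode="x"))


class TestSetAlgebra:
    def test_gain_loss_shared(self):
        from miredit.retarget import TargetSet

        uni = frozenset({"g1", "g2", "g3"})
        wt = TargetSet("wt", {"g1", "g2"}, uni)
        et = TargetSet("et", {"g2", "g3"}, uni)
        s = diff_target_sets(wt, et)
        assert s["lost"] == {"g1"} and s["gained"] == {"g3"} and s["shared"] == {"g2"}
        assert s["n_wt"] == s["n_shared"] + s["n_lost"]
        assert s["n_et"] == s["n_shared"] + s["n_gained"]

    def test_identical_sets_no_change(self):
        from miredit.retarget import TargetSet

        uni = frozenset({"g1"})
        s = diff_target_sets(TargetSet("a", {"g1"}, uni), TargetSet("b", {"g1"}, uni))
        assert s["lost"] == set() and s["gained"] == set()

    def test_mismatched_universe_rejected(self):
        from miredit.retarget import TargetSet

        with pytest.raises(ValueError, match="universe"):
            diff_target_sets(
                TargetSet("a", set(), frozenset({"g1"})),
                TargetSet("b", set(), frozenset({"g2"})),
            )

    def test_counts_recount_oracle(self, rng):
        wt = wildtype_variant("m", MIR497)
        et = apply_edit("m", MIR497, 3, MIR497[2], "T")
        utrs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=2000)) for i in range(40)}
        s = diff_target_sets(scan_targets(wt, utrs), scan_targets(et, utrs))
        assert s["n_wt"] == s["n_shared"] + s["n_lost"]
        assert s["n_et"] == s["n_shared"] + s["n_gained"]


def test_empty_utrs_rejected():
    with pytest.raises(ValueError, match="empty"):
        scan_targets(wildtype_variant("m", MIR497), {})
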