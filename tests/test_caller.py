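"""Pileup and binomial caller: exact-tail oracles, filter cascade, and
planted-truth recovery on simulated data."""

import numpy as np
import pytest
from scipy import stats

from miredit.caller import (
    CallerParams,
    EditingSite,
    PileupColumn,
    binomial_site_test,
    build_pileup,
    call_sites,
    map_to_mature,
    pool_pileups,
    quantify_levels,
)
from miredit.preprocess import ReadFilterParams, align_unique, filter_reads
from miredit.reference import seed_flag
from miredit.simulate import SimConfig, generate_reference, make_planted_sites, simulate_reads

from conftest import make_read


class TestBuildPileup:
    def test_error_free_reads_give_pure_ref_columns(self, tiny_ref):
        ann = tiny_ref.annotations[0]
        mature = tiny_ref.mature_seq(ann)
        alns = align_unique([make_read(f"r{i}", mature + "AA") for i in range(10)], tiny_ref, 2)
        pileup = build_pileup(alns, tiny_ref, q_min=30)
        for (hp, pos), col in pileup.items():
            assert col.counts[col.ref] == 10
            assert col.coverage == 10

    def test_low_quality_base_excluded(self, tiny_ref):
        ann = tiny_ref.annotations[0]
        mature = tiny_ref.mature_seq(ann)
        quals = [40] * len(mature)
        quals[5] = 20
        alns = align_unique([make_read("r", mature + "AA", quals + [40, 40])], tiny_ref, 2)
        pileup = build_pileup(alns, tiny_ref, q_min=30)
        assert (ann.hairpin_id, ann.start + 5) not in pileup
        assert pileup[(ann.hairpin_id, ann.start)].coverage == 1

    def test_column_sums_equal_recount_oracle(self, ref, sim_config):
        sites = make_planted_sites(ref, sim_config, n_edit=3, n_decoys=0)
        reads, _t, _c = simulate_reads(ref, sites, sim_config)
        sample = next(iter(reads))
        kept, _ = filter_reads(reads[sample], ReadFilterParams())
        alns = align_unique(kept, ref, 2)
        pileup = build_pileup(alns, ref, q_min=30)
        # independent recount straight from the alignments
        expected: dict[tuple[str, int], int] = {}
        for a in alns:
            for off, q in enumerate(a.qual):
                if q >= 30:
                    key = (a.hairpin_id, a.start + off)
                    expected[key] = expected.get(key, 0) + 1
        assert {k: c.coverage for k, c in pileup.items()} == expected


class TestBinomialTest:
    def test_zero_alt_count_never_candidate(self):
        col = PileupColumn("hp", 5, "A", {"A": 50, "C": 0, "G": 0, "T": 0})
        res = binomial_site_test(col, CallerParams(), n_tests=1000)
        assert all(raw == 1.0 and corr == 1.0 for raw, corr in res.values())

    def test_tail_matches_pmf_summation_oracle(self):
        # P(X >= 3 | n=50, p=0.001) by explicit complement of the pmf sum
        n, k, p = 50, 3, 0.001
        col = PileupColumn("hp", 5, "A", {"A": n - k, "C": 0, "G": k, "T": 0})
        params = CallerParams(p_err=p)
        raw, _ = binomial_site_test(col, params, n_tests=1)["G"]
        oracle = 1.0 - sum(
            stats.binom.pmf(i, n, p) for i in range(k)
        )
        assert raw == pytest.approx(oracle, abs=1e-12)

    def test_bonferroni_monotone_and_capped(self):
        col = PileupColumn("hp", 5, "A", {"A": 45, "C": 0, "G": 5, "T": 0})
        params = CallerParams()
        prev = 0.0
        for T in (1, 10, 1000, 10**9):
            _, corr = binomial_site_test(col, params, n_tests=T)["G"]
            assert corr >= prev and corr <= 1.0
            prev = corr


def _pileups_for_counts(alt_counts_per_sample, ref_base="A", alt="G", cov=30):
    """Single-position pileups across samples with given alt counts."""
    pileups = {}
    for i, k in enumerate(alt_counts_per_sample):
        counts = {b: 0 for b in "ACGT"}
        counts[ref_base] = cov - k
        counts[alt] = k
        pileups[f"s{i}"] = {("hp0001", 5): PileupColumn("hp0001", 5, ref_base, counts)}
    return pileups


@pytest.fixture
def one_pos_ref():
    from miredit.io import MatureAnnotation
    from miredit.reference import HairpinReference

    return HairpinReference(
        {"hp0001": "CCGA" + "ACGTTGCATGCAAGGTCATA" + "GGCC"},
        [MatureAnnotation("hp0001", "m-5p", 4, 24)],
    )


class TestFilterCascade:
    def test_two_individuals_not_enough_three_is(self, one_pos_ref):
        params = CallerParams()
        for n_sig, expect in ((2, 0), (3, 1)):
            alt_counts = [10] * n_sig + [0] * (6 - n_sig)
            sites = call_sites(_pileups_for_counts(alt_counts), one_pos_ref, params)
            assert len(sites) == expect

    def test_multiple_editing_types_removed(self, one_pos_ref):
        pileups = {}
        for i in range(6):
            counts = {"A": 10, "C": 10, "G": 10, "T": 0}
            pileups[f"s{i}"] = {("hp0001", 5): PileupColumn("hp0001", 5, "A", counts)}
        assert call_sites(pileups, one_pos_ref, CallerParams()) == []

    def test_pooled_coverage_threshold(self, one_pos_ref):
        # 3 samples x 3 reads = 9 pooled < 10 -> removed; 10 -> eligible
        for covs, expect in (((3, 3, 3), 0), ((3, 3, 4), 1)):
            pileups = {}
            for i, cov in enumerate(covs):
                counts = {"A": 0, "C": 0, "G": cov, "T": 0}
                pileups[f"s{i}"] = {("hp0001", 5): PileupColumn("hp0001", 5, "A", counts)}
            sites = call_sites(pileups, one_pos_ref, CallerParams())
            assert len(sites) == expect

    def test_snp_positions_excluded(self, one_pos_ref):
        pileups = _pileups_for_counts([10] * 6)
        assert len(call_sites(pileups, one_pos_ref, CallerParams())) == 1
        assert call_sites(pileups, one_pos_ref, CallerParams(), {("hp0001", 5)}) == []

    def test_retained_sites_satisfy_all_predicates(self, ref, sim_config):
        """Every call re-checked independently against the four filters."""
        sites_truth = make_planted_sites(ref, sim_config, n_edit=5, n_decoys=2)
        reads, _t, _c = simulate_reads(ref, sites_truth, sim_config)
        params = CallerParams()
        pileups = {}
        for sample, rds in reads.items():
            kept, _ = filter_reads(rds, ReadFilterParams())
            pileups[sample] = build_pileup(align_unique(kept, ref, 2), ref, params.q_min)
        snps = {(s.hairpin_id, s.position) for s in sites_truth if s.is_snp_decoy}
        called = call_sites(pileups, ref, params, snps)
        pooled = pool_pileups(pileups)
        n_tests = 3 * sum(1 for c in pooled.values() if c.coverage >= params.min_coverage)
        for site in called:
            key = (site.hairpin_id, site.position)
            assert key not in snps
            assert pooled[key].coverage >= params.min_coverage
            n_sig = 0
            for pu in pileups.values():
                col = pu.get(key)
                if col is None:
                    continue
                res = binomial_site_test(col, params, n_tests)
                if site.alt in res and res[site.alt][1] <= params.alpha:
                    n_sig += 1
            assert n_sig >= params.min_individuals


class TestLevels:
    def test_ratio_and_stage_mean(self):
        site = EditingSite(
            "hp", 5, "A", "G",
            {"a_F1": (5, 10), "a_F2": (3, 10), "a_F3": (4, 10), "b_F1": (0, 0)},
        )
        stages = {"a_F1": "a", "a_F2": "a", "a_F3": "a", "b_F1": "b"}
        quantify_levels([site], stages)
        assert site.sample_level("a_F1") == 0.5
        assert site.stage_levels["a"] == pytest.approx((0.5 + 0.3 + 0.4) / 3)
        assert np.isnan(site.stage_levels["b"])  # zero-total sample excluded

    def test_planted_level_recovered_within_3sd(self):
        cfg = SimConfig(
            n_hairpins=4, reads_per_mature=200.0, stages=("S1", "S2"),
            replicates_per_stage=2, rng_seed=21,
        )
        ref = generate_reference(cfg)
        sites_truth = make_planted_sites(
            ref, cfg, n_edit=2, n_decoys=0,
            level_profiles=((0.3, 0.3),),
        )
        reads, _t, _c = simulate_reads(ref, sites_truth, cfg)
        params = CallerParams()
        pileups = {
            s: build_pileup(align_unique(filter_reads(r, ReadFilterParams())[0], ref, 2), ref, 30)
            for s, r in reads.items()
        }
        stages = {s: s.rsplit("_", 1)[0] for s in reads}
        called = quantify_levels(call_sites(pileups, ref, params), stages)
        truth_pos = {(s.hairpin_id, s.position) for s in sites_truth}
        recovered = [s for s in called if (s.hairpin_id, s.position) in truth_pos]
        assert recovered
        for s in recovered:
            for sample, (k, n) in s.sample_counts.items():
                if n == 0:
                    continue
                assert abs(k / n - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / n)


class TestMatureMapping:
    @pytest.mark.parametrize("mature_pos,expect_seed", [(1, False), (2, True), (4, True), (8, True), (9, False)])
    def test_seed_flag_window(self, mature_pos, expect_seed, one_pos_ref):
        assert seed_flag(mature_pos) is expect_seed
        ann = one_pos_ref.annotations[0]
        site = EditingSite("hp0001", ann.start + mature_pos - 1, "A", "G", {})
        map_to_mature(site, one_pos_ref)
        assert site.mature_position == mature_pos and site.seed is expect_seed

    def test_unannotated_hairpin_raises(self, one_pos_ref):
        site = EditingSite("nope", 3, "A", "G", {})
        with pytest.raises(KeyError):
            site.hairpin_id = "nope"
            from miredit.reference import HairpinReference

            map_to_mature(site, HairpinReference({"nope": "ACGTACGTACGT"}, []))
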