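import numpy as np
import pytest

from founderscan.errors import ValidationError
from founderscan.formats_io import MaskRegions
from founderscan.ibd import (
    DetectorParams,
    apply_mask,
    brute_force_identical_runs,
    detect_ibd,
    ibd1_ibd2_profile,
)

from conftest import make_cohort, make_segment


def _random_cohort(rng, n_samples, m):
    return rng.integers(0, 2, (n_samples, 2, m)).astype(np.int8)


def _positions(m, spacing=1000):
    return np.arange(1, m + 1) * spacing


class TestDetect:
    def test_full_chromosome_share_single_segment(self, rng, simple_map):
        m = 640  # 10 windows across 10 Mb / ~6.4 cM... map: 10cM/Mb
        haps = _random_cohort(rng, 2, m)
        haps[1, 1] = haps[0, 0]  # S1 copy 1 == S0 copy 0 everywhere
        pos = np.linspace(1, 10_000_000, m).astype(np.int64)
        cohort = make_cohort(haps, positions=pos)
        segs = detect_ibd(cohort, simple_map, DetectorParams(min_cm=3.0))
        assert len(segs) == 1
        s = segs[0]
        assert (s.pairing, s.pair) == ((0, 1), ("S0", "S1"))
        assert s.start_bp == pos[0] and s.end_bp == pos[-1]
        assert s.length_cm == pytest.approx(simple_map.length_cm("1"))

    def test_planted_stretch_recovered_with_window_slack(self, rng, simple_map):
        # 10 cM (1 Mb here) planted identical stretch inside independent
        # haplotypes; brute-force longest-identical-run scan is the oracle
        m = 2000  # 5000 bp spacing -> 20 SNPs per cM -> 64-SNP window = 3.2cM
        w = 32
        haps = _random_cohort(rng, 2, m)
        lo, hi = 900, 1100  # 200 SNPs = 1 Mb = 10 cM
        haps[1, 0, lo:hi] = haps[0, 1, lo:hi]
        pos = _positions(m, spacing=5000)
        cohort = make_cohort(haps, positions=pos)
        params = DetectorParams(window_snps=w, min_cm=3.0)
        segs = detect_ibd(cohort, simple_map, params)
        assert len(segs) == 1
        oracle = [s for s in brute_force_identical_runs(cohort, simple_map,
                                                        min_cm=3.0)
                  if s.pairing == (1, 0)]
        assert len(oracle) == 1
        # endpoints within one window of the true boundaries
        assert abs(segs[0].start_bp - oracle[0].start_bp) <= w * 5000
        assert abs(segs[0].end_bp - oracle[0].end_bp) <= w * 5000

    def test_short_stretch_filtered(self, rng, simple_map):
        m = 2000
        haps = _random_cohort(rng, 2, m)
        haps[1, 0, 1000:1050] = haps[0, 0, 1000:1050]  # 2.5 cM
        cohort = make_cohort(haps, positions=_positions(m, 5000))
        segs = detect_ibd(cohort, simple_map,
                          DetectorParams(window_snps=16, min_cm=3.0))
        assert segs == []

    def test_too_few_snps_for_window(self, rng, simple_map):
        cohort = make_cohort(_random_cohort(rng, 2, 32))
        with pytest.raises(ValidationError, match="window"):
            detect_ibd(cohort, simple_map, DetectorParams(window_snps=64))

    def test_sample_order_invariance(self, rng, simple_map):
        m = 1280
        haps = _random_cohort(rng, 3, m)
        haps[2, 1, :640] = haps[0, 0, :640]
        pos = _positions(m, 5000)
        cohort = make_cohort(haps, positions=pos)
        permuted = make_cohort(haps[::-1].copy(), positions=pos,
                               sample_ids=["S2", "S1", "S0"])
        a = detect_ibd(cohort, simple_map, DetectorParams(window_snps=32))
        b = detect_ibd(permuted, simple_map, DetectorParams(window_snps=32))
        assert a == b

    def test_min_cm_monotonicity(self, rng, simple_map):
        m = 2000
        haps = _random_cohort(rng, 4, m)
        haps[1, 0, 100:500] = haps[0, 0, 100:500]
        haps[3, 1, 800:1900] = haps[2, 0, 800:1900]
        cohort = make_cohort(haps, positions=_positions(m, 5000))
        sets = []
        for min_cm in (1.0, 3.0, 8.0, 20.0):
            segs = detect_ibd(cohort, simple_map,
                              DetectorParams(window_snps=16, min_cm=min_cm))
            sets.append(set(segs))
        for tighter, looser in zip(sets[1:], sets[:-1]):
            assert tighter <= looser

    def test_mismatch_allowance_bridges_noise(self, rng, simple_map):
        m = 1280
        haps = _random_cohort(rng, 2, m)
        haps[1, 0] = haps[0, 0]
        haps[1, 0, 700] ^= 1  # single discordant allele mid-chromosome
        cohort = make_cohort(haps, positions=_positions(m, 5000))
        exact = detect_ibd(cohort, simple_map,
                           DetectorParams(window_snps=64, min_cm=3.0))
        tolerant = detect_ibd(
            cohort, simple_map,
            DetectorParams(window_snps=64, min_cm=3.0,
                           max_mismatch_per_window=1))
        assert len(exact) == 2
        assert len(tolerant) == 1
        assert tolerant[0].length_cm > max(s.length_cm for s in exact)

    def test_oracle_equivalence_on_random_cohorts(self, simple_map):
        # every reported segment is an identical run; every identical run
        # >= min_cm + 2 windows is reported with <= 1 window slack per side
        rng = np.random.default_rng(77)
        w = 16
        m = 2000
        spacing = 5000
        window_cm = w * spacing * 100.0 / 10_000_000  # map: 100 cM / 10 Mb
        params = DetectorParams(window_snps=w, min_cm=3.0)
        for _ in range(5):
            haps = _random_cohort(rng, 3, m)
            lo = int(rng.integers(0, 1500))
            hi = lo + int(rng.integers(150, 400))
            haps[1, 0, lo:hi] = haps[0, 0, lo:hi]
            cohort = make_cohort(haps, positions=_positions(m, spacing))
            detected = detect_ibd(cohort, simple_map, params)
            runs = brute_force_identical_runs(cohort, simple_map)
            runs_by_key = {}
            for r in runs:
                runs_by_key.setdefault((r.pair, r.pairing), []).append(r)
            for s in detected:
                # soundness: contained in some exact identical run
                assert any(r.start_bp <= s.start_bp and r.end_bp >= s.end_bp
                           for r in runs_by_key[(s.pair, s.pairing)])
            for r in runs:
                if r.length_cm < params.min_cm + 2 * window_cm:
                    continue
                hits = [s for s in detected
                        if (s.pair, s.pairing) == (r.pair, r.pairing)
                        and s.start_bp >= r.start_bp - w * spacing
                        and s.end_bp <= r.end_bp + w * spacing]
                assert hits, f"identical run {r} not reported"


class TestApplyMask:
    def test_boundary_trim(self, simple_map):
        seg = make_segment(start_bp=1_000_000, end_bp=2_000_000,
                           gmap=simple_map)
        mask = MaskRegions([("1", 1_200_000, 2_500_000)])
        out = apply_mask([seg], mask, simple_map, min_cm=1.0)
        assert len(out) == 1
        assert out[0].end_bp == 1_200_000
        assert out[0].start_bp == 1_000_000

    def test_fully_masked_removed(self, simple_map):
        seg = make_segment(start_bp=1_500_000, end_bp=1_800_000,
                           gmap=simple_map)
        mask = MaskRegions([("1", 1_000_000, 2_000_000)])
        assert apply_mask([seg], mask, simple_map, min_cm=1.0) == []

    def test_disjoint_mask_keeps_segment(self, simple_map):
        seg = make_segment(start_bp=1_000_000, end_bp=2_000_000,
                           gmap=simple_map)
        mask = MaskRegions([("1", 5_000_000, 6_000_000)])
        assert apply_mask([seg], mask, simple_map, min_cm=1.0) == [seg]

    def test_split_keeps_both_flanks_and_refilters(self, simple_map):
        seg = make_segment(start_bp=1_000_000, end_bp=3_000_000,
                           gmap=simple_map)  # 20 cM
        mask = MaskRegions([("1", 1_500_000, 1_600_000)])
        out = apply_mask([seg], mask, simple_map, min_cm=3.0)
        assert len(out) == 2
        assert out[0].end_bp == 1_500_000 and out[1].start_bp == 1_600_001
        # flank now below min_cm is dropped
        tight = MaskRegions([("1", 1_100_000, 1_600_000)])
        out2 = apply_mask([seg], tight, simple_map, min_cm=3.0)
        assert len(out2) == 1 and out2[0].start_bp == 1_600_001


class TestProfile:
    def test_half_map_single_segment(self, simple_map):
        seg = make_segment(start_bp=1, end_bp=5_000_000, gmap=simple_map)
        p = ibd1_ibd2_profile([seg], simple_map)
        assert p.ibd1_cm == pytest.approx(50.0)
        assert p.ibd2_cm == 0.0
        assert p.ibd0_cm == pytest.approx(50.0)

    def test_complementary_pairings_make_ibd2(self, simple_map):
        segs = [make_segment(hap_a=0, hap_b=0, start_bp=1,
                             end_bp=10_000_000, gmap=simple_map),
                make_segment(hap_a=1, hap_b=1, start_bp=1,
                             end_bp=10_000_000, gmap=simple_map)]
        p = ibd1_ibd2_profile(segs, simple_map)
        assert p.ibd2_cm == pytest.approx(100.0)
        assert p.ibd1_cm == 0.0

    def test_non_disjoint_pairings_stay_ibd1(self, simple_map):
        segs = [make_segment(hap_a=0, hap_b=0, start_bp=1,
                             end_bp=10_000_000, gmap=simple_map),
                make_segment(hap_a=0, hap_b=1, start_bp=1,
                             end_bp=10_000_000, gmap=simple_map)]
        p = ibd1_ibd2_profile(segs, simple_map)
        assert p.ibd1_cm == pytest.approx(100.0) and p.ibd2_cm == 0.0

    def test_no_segments_all_ibd0(self, simple_map):
        p = ibd1_ibd2_profile([], simple_map)
        assert p.ibd0_cm == pytest.approx(100.0)

    def test_mixed_pairs_rejected(self, simple_map):
        segs = [make_segment(sample_a="A", sample_b="B", gmap=simple_map),
                make_segment(sample_a="A", sample_b="C", gmap=simple_map)]
        with pytest.raises(ValidationError):
            ibd1_ibd2_profile(segs, simple_map)

    def test_length_conservation_on_random_segments(self, simple_map):
        rng = np.random.default_rng(3)
        for _ in range(20):
            segs = []
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(1, 9_000_000))
                e = s + int(rng.integers(1, 1_000_000))
                segs.append(make_segment(
                    hap_a=int(rng.integers(2)), hap_b=int(rng.integers(2)),
                    start_bp=s, end_bp=min(e, 10_000_000), gmap=simple_map))
            p = ibd1_ibd2_profile(segs, simple_map)
            assert (p.ibd0_cm + p.ibd1_cm + p.ibd2_cm
                    == pytest.approx(p.total_cm))
            assert p.ibd0_cm >= -1e-9
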