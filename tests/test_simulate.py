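import numpy as np
import pytest
from scipy import stats

from founderscan.errors import ConfigError
from founderscan.formats_io import GeneticMap
from founderscan.simulate import (
    ClusterSpec,
    SimConfig,
    build_genetic_map,
    five_cluster_config,
    make_founder_pool,
    meiosis,
    simulate_cohort,
    simulate_founder_cluster,
    simulate_relative_pair,
    simulate_segment_lengths,
    _draw_positions,
    _drop_from_founder,
    _ancestral_tract,
)


class TestFounderPool:
    def test_shape(self, rng):
        pool, freqs = make_founder_pool(2, 10, (0.1, 0.5), rng)
        assert pool.shape == (2, 10) and freqs.shape == (10,)

    def test_degenerate_maf_gives_half_frequency(self):
        pool, _ = make_founder_pool(2000, 50, (0.5, 0.5), 7)
        emp = pool.mean(axis=0)
        # binomial tolerance: sd = sqrt(.25/2000) ~ 0.011
        assert np.all(np.abs(emp - 0.5) < 0.06)

    def test_seed_reproducibility(self):
        a, fa = make_founder_pool(5, 100, (0.1, 0.5), 42)
        b, fb = make_founder_pool(5, 100, (0.1, 0.5), 42)
        assert np.array_equal(a, b) and np.array_equal(fa, fb)

    @pytest.mark.parametrize("bounds", [(0.0, 0.5), (0.1, 1.0), (-0.1, 0.5)])
    def test_bad_maf_bounds(self, bounds):
        with pytest.raises(ConfigError):
            make_founder_pool(4, 10, bounds, 0)


class TestMeiosis:
    def test_zero_map_length_copies_one_parent(self, rng):
        # a 0-cM map forces a Poisson(0) crossover count
        pos_cm = np.zeros(50)
        h1 = np.zeros(50, np.int8)
        h2 = np.ones(50, np.int8)
        for _ in range(10):
            g = meiosis(h1, h2, pos_cm, rng)
            assert np.array_equal(g, h1) or np.array_equal(g, h2)

    @pytest.mark.parametrize("length_cm,expected,tol", [
        (100.0, 1.0, 0.05),
        (35.0, 0.35, 0.03),
    ])
    def test_poisson_crossover_rate(self, length_cm, expected, tol):
        rng = np.random.default_rng(99)
        m = 500
        pos_cm = np.linspace(0, length_cm, m)
        h1 = np.zeros(m, np.int8)
        h2 = np.ones(m, np.int8)
        switches = 0
        n = 10_000
        for _ in range(n):
            _, src = meiosis(h1, h2, pos_cm, rng, return_source=True)
            switches += int((src[1:] != src[:-1]).sum())
        assert abs(switches / n - expected) < tol

    def test_allele_conservation(self, rng):
        # every gamete allele equals the corresponding allele of a parent
        for _ in range(20):
            m = int(rng.integers(10, 200))
            h1 = rng.integers(0, 2, m).astype(np.int8)
            h2 = rng.integers(0, 2, m).astype(np.int8)
            pos_cm = np.sort(rng.uniform(0, 150, m))
            g, src = meiosis(h1, h2, pos_cm, rng, return_source=True)
            assert np.array_equal(g, np.where(src == 0, h1, h2))
            assert np.all((g == h1) | (g == h2))

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(Exception):
            meiosis(np.zeros(5, np.int8), np.zeros(6, np.int8),
                    np.arange(5.0), rng)


class TestSegmentLengths:
    def test_two_sided_mean(self):
        lengths = simulate_segment_lengths(10, 10_000, True, 5)
        assert abs(lengths.mean() - 20.0) < 0.5

    def test_one_sided_mean(self):
        lengths = simulate_segment_lengths(10, 10_000, False, 5)
        assert abs(lengths.mean() - 10.0) < 0.4

    def test_seed_reproducibility(self):
        a = simulate_segment_lengths(8, 100, True, 3)
        b = simulate_segment_lengths(8, 100, True, 3)
        assert np.array_equal(a, b)

    def test_invalid_args(self):
        with pytest.raises(ConfigError):
            simulate_segment_lengths(0, 5)


def _long_chromosome_setup(rng, g, length_cm=200.0, n_snps=16_000):
    """Founder drop on a long chromosome (mutation mid-way) so end-censoring
    of tract lengths is negligible."""
    length_bp = 150_000_000
    mut_pos = length_bp // 2
    positions = _draw_positions(rng, n_snps, length_bp, [mut_pos])
    gmap = GeneticMap({"1": (np.array([1, length_bp]),
                             np.array([0.0, length_cm]))})
    pos_cm = gmap.interpolate("1", positions)
    freqs = rng.uniform(0.1, 0.5, positions.size)
    mut_idx = int(np.flatnonzero(positions == mut_pos)[0])
    founder = (rng.random(positions.size) < freqs).astype(np.int8)
    founder[mut_idx] = 1
    return founder, mut_idx, freqs, pos_cm


class TestFounderCluster:
    def test_zero_map_keeps_founder_chromosome_intact(self, rng):
        spec = ClusterSpec("C1", 1, 1, 500, "p.X")
        positions = np.array([100, 500, 900], dtype=np.int64)
        pos_cm = np.zeros(3)
        pool = np.array([[0, 0, 0], [1, 0, 1]], dtype=np.int8)
        freqs = np.array([0.3, 0.0, 0.3])
        ids, haps, truth, tracts, fside = simulate_founder_cluster(
            spec, pool, freqs, positions, pos_cm, "1", rng)
        carrier = haps[0, fside[0]]
        assert np.array_equal(carrier, truth.alleles)
        assert tracts[0] == (0, 2)

    def test_mutation_must_be_a_snp(self, rng):
        spec = ClusterSpec("C1", 1, 1, 777, "p.X")
        positions = np.array([100, 500], dtype=np.int64)
        with pytest.raises(ConfigError):
            simulate_founder_cluster(spec, np.zeros((2, 2), np.int8),
                                     np.array([0.1, 0.1]), positions,
                                     np.array([0.0, 1.0]), "1", rng)

    def test_mean_tract_length_matches_theory(self):
        # g=10: two-sided tract mean = 2/g Morgan = 20 cM
        rng = np.random.default_rng(11)
        founder, mut_idx, freqs, pos_cm = _long_chromosome_setup(rng, 10)
        lengths = []
        for _ in range(200):
            _, anc = _drop_from_founder(founder, mut_idx, 10, freqs,
                                        pos_cm, rng)
            lo, hi = _ancestral_tract(anc, mut_idx)
            lengths.append(pos_cm[hi] - pos_cm[lo])
        assert abs(np.mean(lengths) - 20.0) < 2.0

    def test_one_sided_lengths_are_exponential(self):
        # Kolmogorov-Smirnov against Exp(g) at alpha = 0.01, n >= 1000
        rng = np.random.default_rng(13)
        g = 10
        founder, mut_idx, freqs, pos_cm = _long_chromosome_setup(rng, g)
        sides = []
        for _ in range(1000):
            _, anc = _drop_from_founder(founder, mut_idx, g, freqs,
                                        pos_cm, rng)
            lo, hi = _ancestral_tract(anc, mut_idx)
            sides.append((pos_cm[hi] - pos_cm[mut_idx]) / 100.0)
        res = stats.kstest(sides, "expon", args=(0, 1 / g))
        assert res.pvalue > 0.01

    def test_truth_segments_contain_mutation(self):
        config = five_cluster_config(seed=5)
        _, truth, _ = simulate_cohort(config)
        for seg in truth.segments:
            mut = truth.founder_haplotypes[
                truth.clusters[seg.sample_a]].mutation_position
            assert seg.start_bp <= mut <= seg.end_bp


def _realized_pi(degree, rng, n_chrom=35, reps=300, m=200):
    """Realized IBD sharing pi = IBD1/2 + IBD2 via labeled-ancestry oracle."""
    pos_cm = np.linspace(0, 100, m)
    freqs = np.zeros(m)
    pis = []
    for _ in range(reps):
        acc = 0.0
        for _ in range(n_chrom):
            a, b = simulate_relative_pair(degree, freqs, pos_cm, rng,
                                          labeled=True)
            m00 = a[0] == b[0]
            m11 = a[1] == b[1]
            m01 = a[0] == b[1]
            m10 = a[1] == b[0]
            ibd2 = (m00 & m11) | (m01 & m10)
            ibd1 = (m00 | m11 | m01 | m10) & ~ibd2
            acc += ibd1.mean() / 2 + ibd2.mean()
        pis.append(acc / n_chrom)
    return np.array(pis)


class TestRelativePairs:
    def test_parent_offspring_shares_everywhere(self, rng):
        pos_cm = np.linspace(0, 100, 100)
        parent, child = simulate_relative_pair("PO", np.zeros(100), pos_cm,
                                               rng, labeled=True)
        shared = ((child[0][:, None] == parent.T) |
                  (child[1][:, None] == parent.T)).any(axis=1)
        assert shared.all()

    def test_first_cousins_share_one_eighth(self):
        # pi = 2^-d with d=3; 500 replicates on a 35-chromosome genome
        rng = np.random.default_rng(21)
        pis = _realized_pi(3, rng, reps=500)
        assert abs(pis.mean() - 0.125) < 0.01

    def test_full_sibs_have_ibd2(self):
        rng = np.random.default_rng(22)
        pos_cm = np.linspace(0, 100, 200)
        ibd2 = []
        for _ in range(300):
            for _ in range(5):
                a, b = simulate_relative_pair(1, np.zeros(200), pos_cm, rng,
                                              labeled=True)
                both = ((a[0] == b[0]) & (a[1] == b[1])) | \
                       ((a[0] == b[1]) & (a[1] == b[0]))
                ibd2.append(both.mean())
        assert abs(np.mean(ibd2) - 0.25) < 0.02

    def test_unsupported_degree(self, rng):
        with pytest.raises(ConfigError):
            simulate_relative_pair(12, np.zeros(10), np.arange(10.0), rng)


class TestSimulateCohort:
    def test_five_cluster_bookkeeping(self):
        config = five_cluster_config(seed=3, n_unrelated=4)
        cohort, truth, _ = simulate_cohort(config)
        assert len(truth.clusters) == 22 + 33 + 6 + 3 + 3
        assert cohort.n_samples == 67 + 4
        sizes = sorted(
            sum(1 for c in truth.clusters.values() if c == cid)
            for cid in truth.tmrca)
        assert sizes == [3, 3, 6, 22, 33]

    def test_zero_clusters_no_truth_segments(self):
        config = SimConfig(seed=1, n_snps=200, n_unrelated=10)
        _, truth, _ = simulate_cohort(config)
        assert truth.segments == []

    def test_same_seed_byte_identical_vcf(self, tmp_path):
        config = SimConfig(seed=9, n_snps=300,
                           clusters=[ClusterSpec("C1", 3, 2, 23_000_000,
                                                 "p.X")])
        simulate_cohort(config, out_dir=tmp_path / "a")
        simulate_cohort(config, out_dir=tmp_path / "b")
        assert ((tmp_path / "a" / "cohort.vcf").read_bytes()
                == (tmp_path / "b" / "cohort.vcf").read_bytes())

    def test_duplicate_cluster_ids_rejected(self):
        config = SimConfig(
            seed=1, n_snps=200,
            clusters=[ClusterSpec("C1", 2, 2, 1_000_000, "p.X"),
                      ClusterSpec("C1", 2, 2, 2_000_000, "p.Y")])
        with pytest.raises(ConfigError, match="duplicate"):
            simulate_cohort(config)

    def test_empty_config_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            simulate_cohort(SimConfig(seed=1, n_snps=100))

    def test_genotype_error_flips_alleles(self):
        base = SimConfig(seed=4, n_snps=400, n_unrelated=5)
        noisy = SimConfig(seed=4, n_snps=400, n_unrelated=5,
                          genotype_error_rate=0.2)
        a, _, _ = simulate_cohort(base)
        b, _, _ = simulate_cohort(noisy)
        frac = np.mean(a.haplotypes != b.haplotypes)
        assert 0.1 < frac < 0.3

    def test_uniform_map_construction(self):
        gmap = build_genetic_map(SimConfig(n_chromosomes=2))
        assert gmap.chromosomes == ["1", "2"]
        assert gmap.length_cm("1") == pytest.approx(62.0)
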