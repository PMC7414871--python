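"""Gene-dropping simulator with truth tables.

Emulates the structure of a founder-event cohort: several clusters of
mutation carriers, each descending ``g`` generations from one founder
chromosome (a star genealogy — every carrier takes an independent chain of
``g`` meioses from the founder, conditioned on transmitting the mutation);
relative pairs of specified degree built on minimal connecting pedigrees;
and background unrelated samples drawn from population allele frequencies.

Recombination follows the Haldane model (no interference): the crossover
count per meiosis is Poisson in the chromosome's map length in Morgans, and
crossover points are uniform on the cM scale, honoring map non-uniformity.
Under this model, the retained one-sided ancestral tract around a planted
mutation after g meioses is Exp(g)-distributed per Morgan — the quantity the
Gamma TMRCA estimator is built on.

Background haplotypes are drawn site-independently (no background linkage
disequilibrium), which keeps false-IBD structure minimal and the downstream
oracles exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .formats_io import (
    GeneticMap,
    IBDSegment,
    PhasedCohort,
    write_mutation_labels,
    write_phased_vcf,
    write_segments,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ClusterSpec:
    """One founder event: ``n_carriers`` descendants, each ``generations``
    meioses below a founder chromosome carrying a mutation at
    ``mutation_position`` (which must coincide with a simulated SNP)."""

    cluster_id: str
    n_carriers: int
    generations: int
    mutation_position: int
    mutation_label: str

    def __post_init__(self):
        if self.generations < 1:
            raise ConfigError(f"cluster {self.cluster_id}: generations must be >= 1")
        if self.n_carriers < 1:
            raise ConfigError(f"cluster {self.cluster_id}: n_carriers must be >= 1")


@dataclass
class PairSpec:
    """Relative pairs of one degree. ``degree`` is an integer 1..11 under the
    kinship convention phi = 2^(-d-1), or "PO" for parent-offspring.
    ``same_family`` controls the truth family labels: known relatives share a
    family id; set False to plant 'novel' relatives across nominal families."""

    degree: int | str
    n_pairs: int
    same_family: bool = True

    def __post_init__(self):
        if self.degree != "PO" and not (1 <= int(self.degree) <= 11):
            raise ConfigError(f"unsupported degree {self.degree!r} (1..11 or 'PO')")
        if self.n_pairs < 1:
            raise ConfigError("n_pairs must be >= 1")


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a chr21-like chromosome: 46.7 Mb, 62 cM, with SNP
    density ~128 per cM so that a 64-SNP detection window spans about
    0.5 cM — small against both the 3 cM retention floor and typical
    ancestral tract lengths, keeping window-quantization losses a few
    percent of segment length.
    """

    seed: int = 0
    n_snps: int = 8000
    chrom_length_bp: int = 46_700_000
    chrom_length_cm: float = 62.0
    n_chromosomes: int = 1
    chrom_names: list[str] | None = None
    maf_bounds: tuple[float, float] = (0.1, 0.5)
    clusters: list[ClusterSpec] = field(default_factory=list)
    pairs: list[PairSpec] = field(default_factory=list)
    n_unrelated: int = 0
    genotype_error_rate: float = 0.0

    def __post_init__(self):
        lo, hi = self.maf_bounds
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigError(f"maf_bounds {self.maf_bounds} outside (0, 1)")
        if not (0.0 <= self.genotype_error_rate < 1.0):
            raise ConfigError("genotype_error_rate must be in [0, 1)")
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        for spec in self.clusters:
            if not (1 <= spec.mutation_position <= self.chrom_length_bp):
                raise ConfigError(
                    f"cluster {spec.cluster_id}: mutation position "
                    f"{spec.mutation_position} outside chromosome"
                )

    @property
    def chromosome_names(self) -> list[str]:
        if self.chrom_names is not None:
            if len(self.chrom_names) != self.n_chromosomes:
                raise ConfigError("chrom_names length != n_chromosomes")
            return list(self.chrom_names)
        return [str(i + 1) for i in range(self.n_chromosomes)]


@dataclass
class FounderTruth:
    """The planted founder haplotype of one cluster."""

    cluster_id: str
    chrom: str
    positions: np.ndarray       # all SNP positions on the founder chromosome
    alleles: np.ndarray         # founder allele at each position
    core_start_bp: int          # intersection of all carriers' ancestral tracts
    core_end_bp: int
    mutation_position: int
    mutation_label: str


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated cohort."""

    segments: list[IBDSegment]
    degrees: pd.DataFrame                    # sample_a, sample_b, degree
    clusters: dict[str, str]                 # sample -> cluster_id
    families: dict[str, str | None]          # sample -> family id (None = sporadic)
    founder_haplotypes: dict[str, FounderTruth]
    tmrca: dict[str, int]                    # cluster -> generations
    mutation_labels: dict[str, str]


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------


def make_founder_pool(n_haplotypes: int, n_snps: int,
                      maf_bounds: tuple[float, float],
                      seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw a pool of unrelated haplotypes from per-site allele frequencies.

    Each SNP's alternate-allele frequency is uniform within ``maf_bounds``;
    haplotypes are drawn independently per site.
    """
    if n_haplotypes < 2:
        raise ConfigError("need at least 2 haplotypes in the pool")
    lo, hi = maf_bounds
    if not (0.0 < lo <= hi < 1.0):
        raise ConfigError(f"maf_bounds {maf_bounds} outside (0, 1)")
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    freqs = rng.uniform(lo, hi, size=n_snps)
    pool = (rng.random((n_haplotypes, n_snps)) < freqs).astype(np.int8)
    return pool, freqs


def draw_haplotype(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One fresh background haplotype from per-site frequencies."""
    return (rng.random(freqs.size) < freqs).astype(np.int8)


def meiosis(parent_hap1: np.ndarray, parent_hap2: np.ndarray,
            pos_cm: np.ndarray, rng: np.random.Generator,
            return_source: bool = False):
    """One gamete under the Haldane crossover model.

    The crossover count is Poisson in the map length (Morgans); crossover
    points are uniform on the cM scale and snapped to the nearest inter-SNP
    boundary. The starting parent is chosen by fair coin; the gamete
    alternates parental source at each crossover.

    Parameters
    ----------
    pos_cm
        cM coordinate of each SNP (from :meth:`GeneticMap.interpolate`).
    return_source
        Also return the per-site source indicator (0 = from hap1).
    """
    if parent_hap1.shape != parent_hap2.shape:
        raise ValidationError("parent haplotypes differ in length")
    m = parent_hap1.size
    morgans = (pos_cm[-1] - pos_cm[0]) / 100.0
    k = rng.poisson(morgans)
    start = int(rng.integers(2))
    if k == 0:
        source = np.full(m, start, dtype=np.int8)
    else:
        xs = rng.uniform(pos_cm[0], pos_cm[-1], size=k)
        # crossover between SNP i-1 and i where pos_cm[i-1] <= x < pos_cm[i]
        bidx = np.searchsorted(pos_cm, xs, side="right")
        counts = np.zeros(m + 1, dtype=np.int64)
        np.add.at(counts, bidx, 1)
        source = ((start + np.cumsum(counts)[:m]) % 2).astype(np.int8)
    gamete = np.where(source == 0, parent_hap1, parent_hap2)
    if return_source:
        return gamete, source
    return gamete


def simulate_segment_lengths(g: int, n: int, two_sided: bool = True,
                             rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Ancestral haplotype lengths in cM after ``g`` generations.

    One-sided lengths are Exp(g) per Morgan; two-sided lengths are the sum
    of two independent sides (the mutation sits inside the segment).
    """
    if g < 1 or n < 1:
        raise ConfigError("g and n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    sides = 2 if two_sided else 1
    lengths_morgan = rng.exponential(scale=1.0 / g, size=(n, sides)).sum(axis=1)
    return lengths_morgan * 100.0


# ---------------------------------------------------------------------------
# Founder clusters
# ---------------------------------------------------------------------------


def _drop_from_founder(founder: np.ndarray, mut_idx: int, g: int,
                       freqs: np.ndarray, pos_cm: np.ndarray,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Pass the founder chromosome through g meioses against fresh background
    mates, conditioning each transmission on carrying the mutation.

    Returns the final haplotype and the boolean founder-ancestry mask.
    """
    hap = founder.copy()
    ancestry = np.ones(founder.size, dtype=bool)
    for _ in range(g):
        mate = draw_haplotype(freqs, rng)
        while True:
            gamete, source = meiosis(hap, mate, pos_cm, rng, return_source=True)
            if source[mut_idx] == 0:  # mutation transmitted
                break
        hap = gamete
        ancestry = np.where(source == 0, ancestry, False)
    return hap, ancestry


def _ancestral_tract(ancestry: np.ndarray, mut_idx: int) -> tuple[int, int]:
    """Maximal run of founder ancestry containing the mutation (SNP indices)."""
    lo = mut_idx
    while lo > 0 and ancestry[lo - 1]:
        lo -= 1
    hi = mut_idx
    while hi < ancestry.size - 1 and ancestry[hi + 1]:
        hi += 1
    return lo, hi


def simulate_founder_cluster(spec: ClusterSpec, pool: np.ndarray,
                             freqs: np.ndarray, positions: np.ndarray,
                             pos_cm: np.ndarray, chrom: str,
                             rng: np.random.Generator,
                             sample_ids: list[str] | None = None,
                             founder_index: int | None = None):
    """Gene-drop one founder cluster down a star genealogy.

    Returns ``(sample_ids, haplotype matrix, founder_truth, tract index
    ranges, founder-side hap index per carrier)``. The founder's chromosome
    is drawn from the pool with the mutation planted (alt allele) at
    ``spec.mutation_position``; every carrier receives it through
    ``spec.generations`` independent meioses against fresh background mates,
    so the one-sided retained tract around the mutation is Exp(g) per Morgan.
    The carrier's other chromosome is a fresh background draw, and which of
    the two phased copies holds the founder material is randomized.
    """
    hits = np.flatnonzero(positions == spec.mutation_position)
    if hits.size != 1:
        raise ConfigError(
            f"cluster {spec.cluster_id}: mutation position "
            f"{spec.mutation_position} is not a simulated SNP"
        )
    mut_idx = int(hits[0])
    if founder_index is None:
        founder_index = int(rng.integers(pool.shape[0]))
    founder = pool[founder_index].copy()
    founder[mut_idx] = 1
    n = spec.n_carriers
    m = positions.size
    if sample_ids is None:
        sample_ids = [f"{spec.cluster_id}_{i + 1:02d}" for i in range(n)]
    haps = np.empty((n, 2, m), dtype=np.int8)
    tracts: list[tuple[int, int]] = []
    founder_side: list[int] = []
    for i in range(n):
        carrier_hap, ancestry = _drop_from_founder(
            founder, mut_idx, spec.generations, freqs, pos_cm, rng)
        other = draw_haplotype(freqs, rng)
        other[mut_idx] = 0  # the mutation exists only on the founder lineage
        side = int(rng.integers(2))
        haps[i, side] = carrier_hap
        haps[i, 1 - side] = other
        founder_side.append(side)
        tracts.append(_ancestral_tract(ancestry, mut_idx))
    core_lo = max(t[0] for t in tracts)
    core_hi = min(t[1] for t in tracts)
    truth = FounderTruth(
        cluster_id=spec.cluster_id,
        chrom=chrom,
        positions=positions,
        alleles=founder,
        core_start_bp=int(positions[core_lo]),
        core_end_bp=int(positions[core_hi]),
        mutation_position=spec.mutation_position,
        mutation_label=spec.mutation_label,
    )
    return sample_ids, haps, truth, tracts, founder_side


def _cluster_truth_segments(sample_ids, tracts, founder_side, positions,
                            pos_cm, chrom) -> list[IBDSegment]:
    """Pairwise truth segments: intersections of carriers' ancestral tracts.

    Every intersection contains the mutation position by construction."""
    out = []
    n = len(sample_ids)
    for i in range(n):
        for j in range(i + 1, n):
            lo = max(tracts[i][0], tracts[j][0])
            hi = min(tracts[i][1], tracts[j][1])
            a, b = i, j
            if sample_ids[a] > sample_ids[b]:
                a, b = b, a
            out.append(IBDSegment(
                sample_a=sample_ids[a], hap_a=founder_side[a],
                sample_b=sample_ids[b], hap_b=founder_side[b],
                chrom=chrom,
                start_bp=int(positions[lo]), end_bp=int(positions[hi]),
                start_cm=float(pos_cm[lo]), end_cm=float(pos_cm[hi]),
                length_cm=float(pos_cm[hi] - pos_cm[lo]),
            ))
    return out


# ---------------------------------------------------------------------------
# Relative pairs
# ---------------------------------------------------------------------------


def _pedigree_depths(degree: int) -> tuple[int, int]:
    """Generations below the founding full-sib pair for each side.

    Odd d = 2k+1: k down each side (d=1 the sibs themselves, d=3 first
    cousins, d=5 second cousins, d=7 third cousins). Even d = 2k+2: k down
    one side, k+1 the other (d=2 avuncular, d=4 first cousins once removed).
    Both give kinship phi = 2^(-d-1).
    """
    if degree % 2 == 1:
        k = (degree - 1) // 2
        return k, k
    k = (degree - 2) // 2
    return k, k + 1


def simulate_relative_pair(degree: int | str, freqs: np.ndarray,
                           pos_cm: np.ndarray,
                           rng: np.random.Generator,
                           labeled: bool = False
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Gene-drop one relative pair on its minimal connecting pedigree.

    Returns two (2, n_snps) haplotype arrays. "PO" gives a parent and child;
    integer degrees 1..11 descend from a founding full-sib pair (see
    :func:`_pedigree_depths`).

    With ``labeled=True`` every founder haplotype carries a distinct integer
    label at all sites instead of drawn alleles, so two sites are IBD iff
    their labels agree — the exact-ancestry oracle for realized IBD
    fractions.
    """
    label_counter = iter(range(1, 1_000_000))

    def fresh() -> np.ndarray:
        if labeled:
            return np.full(freqs.size, next(label_counter), dtype=np.int32)
        return draw_haplotype(freqs, rng)

    def person() -> np.ndarray:
        return np.stack([fresh(), fresh()])

    def child_of(parent: np.ndarray) -> np.ndarray:
        gamete = meiosis(parent[0], parent[1], pos_cm, rng)
        return np.stack([gamete, fresh()])

    if degree == "PO":
        parent = person()
        child = child_of(parent)
        return parent, child
    degree = int(degree)
    if not (1 <= degree <= 11):
        raise ConfigError(f"unsupported degree {degree}")
    father, mother = person(), person()
    sib1 = np.stack([meiosis(father[0], father[1], pos_cm, rng),
                     meiosis(mother[0], mother[1], pos_cm, rng)])
    sib2 = np.stack([meiosis(father[0], father[1], pos_cm, rng),
                     meiosis(mother[0], mother[1], pos_cm, rng)])
    depth_a, depth_b = _pedigree_depths(degree)
    a = sib1
    for _ in range(depth_a):
        a = child_of(a)
    b = sib2
    for _ in range(depth_b):
        b = child_of(b)
    return a, b


# ---------------------------------------------------------------------------
# Whole cohorts
# ---------------------------------------------------------------------------


def _draw_positions(rng: np.random.Generator, n_snps: int, length_bp: int,
                    forced: list[int]) -> np.ndarray:
    """Sorted distinct SNP positions including every forced position."""
    chosen: set[int] = set(int(p) for p in forced)
    if len(chosen) > n_snps:
        raise ConfigError("more forced positions than SNPs")
    while len(chosen) < n_snps:
        draw = rng.integers(1, length_bp + 1,
                            size=2 * (n_snps - len(chosen)) + 16)
        for p in draw:
            chosen.add(int(p))
            if len(chosen) == n_snps:
                break
    return np.array(sorted(chosen), dtype=np.int64)


def build_genetic_map(config: SimConfig) -> GeneticMap:
    """Uniform-rate map: 2 anchors per chromosome (1 bp -> 0 cM, end -> L cM)."""
    anchors = {}
    for name in config.chromosome_names:
        anchors[name] = (np.array([1, config.chrom_length_bp]),
                         np.array([0.0, config.chrom_length_cm]))
    return GeneticMap(anchors)


def simulate_cohort(config: SimConfig, out_dir=None
                    ) -> tuple[PhasedCohort, TruthSet, GeneticMap]:
    """Compose clusters, relative pairs and unrelated background into one
    phased cohort with a full truth set. Deterministic under ``config.seed``.

    Clusters are simulated on the first chromosome; relative pairs and
    background samples span all configured chromosomes. If ``out_dir`` is
    given, writes phased VCF, .map and truth TSVs there.
    """
    rng = np.random.default_rng(config.seed)
    gmap = build_genetic_map(config)
    chrom_names = config.chromosome_names

    # --- sample bookkeeping -------------------------------------------------
    sample_ids: list[str] = []
    families: dict[str, str | None] = {}
    clusters_truth: dict[str, str] = {}
    mutation_labels: dict[str, str] = {}
    cluster_samples: dict[str, list[str]] = {}
    for spec in config.clusters:
        ids = [f"{spec.cluster_id}_{i + 1:02d}" for i in range(spec.n_carriers)]
        cluster_samples[spec.cluster_id] = ids
        for sid in ids:
            families[sid] = f"FAM_{sid}"  # carriers present as separate families
            clusters_truth[sid] = spec.cluster_id
            mutation_labels[sid] = spec.mutation_label
        sample_ids.extend(ids)
    pair_samples: list[tuple[PairSpec, str, str]] = []
    for pi, pspec in enumerate(config.pairs):
        for j in range(pspec.n_pairs):
            base = f"D{pspec.degree}_{pi}_{j + 1:03d}"
            sa, sb = f"{base}_a", f"{base}_b"
            fam = f"FAMP_{base}"
            families[sa] = fam
            families[sb] = fam if pspec.same_family else f"{fam}_x"
            pair_samples.append((pspec, sa, sb))
            sample_ids.extend([sa, sb])
    unrelated_ids = [f"UR_{i + 1:03d}" for i in range(config.n_unrelated)]
    for sid in unrelated_ids:
        families[sid] = None
    sample_ids.extend(unrelated_ids)
    if len(set(sample_ids)) != len(sample_ids):
        raise ConfigError("duplicate sample ids across specs")
    if not sample_ids:
        raise ConfigError("empty cohort: no clusters, pairs or unrelated samples")
    index = {sid: i for i, sid in enumerate(sample_ids)}

    # --- per-chromosome simulation -------------------------------------
    all_chrom, all_pos, all_ref, all_alt, all_ids = [], [], [], [], []
    hap_blocks: list[np.ndarray] = []
    truth_segments: list[IBDSegment] = []
    founder_truths: dict[str, FounderTruth] = {}
    tmrca = {spec.cluster_id: spec.generations for spec in config.clusters}

    for ci, chrom in enumerate(chrom_names):
        forced = [s.mutation_position for s in config.clusters] if ci == 0 else []
        positions = _draw_positions(rng, config.n_snps, config.chrom_length_bp,
                                    forced)
        pos_cm = gmap.interpolate(chrom, positions)
        freqs = rng.uniform(*config.maf_bounds, size=positions.size)
        # mutation sites segregate only on founder lineages
        for p in forced:
            freqs[np.searchsorted(positions, p)] = 0.0
        pool, _ = _make_pool_from_freqs(max(2, 2 * len(config.clusters)), freqs, rng)
        H = np.empty((len(sample_ids), 2, positions.size), dtype=np.int8)

        if ci == 0:
            # distinct founder events need distinct founder chromosomes:
            # clusters with the same mutation would otherwise merge
            founder_idx = rng.choice(pool.shape[0], size=len(config.clusters),
                                     replace=False)
            for spec, fidx in zip(config.clusters, founder_idx):
                ids = cluster_samples[spec.cluster_id]
                _, haps, ftruth, tracts, fside = simulate_founder_cluster(
                    spec, pool, freqs, positions, pos_cm, chrom, rng,
                    sample_ids=ids, founder_index=int(fidx))
                for sid, h in zip(ids, haps):
                    H[index[sid]] = h
                truth_segments.extend(_cluster_truth_segments(
                    ids, tracts, fside, positions, pos_cm, chrom))
                founder_truths[spec.cluster_id] = ftruth
        else:
            for spec in config.clusters:
                for sid in cluster_samples[spec.cluster_id]:
                    H[index[sid], 0] = draw_haplotype(freqs, rng)
                    H[index[sid], 1] = draw_haplotype(freqs, rng)

        for pspec, sa, sb in pair_samples:
            ha, hb = simulate_relative_pair(pspec.degree, freqs, pos_cm, rng)
            H[index[sa]] = ha
            H[index[sb]] = hb
        for sid in unrelated_ids:
            H[index[sid], 0] = draw_haplotype(freqs, rng)
            H[index[sid], 1] = draw_haplotype(freqs, rng)

        if config.genotype_error_rate > 0:
            flips = rng.random(H.shape) < config.genotype_error_rate
            H = np.where(flips, 1 - H, H).astype(np.int8)

        hap_blocks.append(H)
        all_chrom.append(np.full(positions.size, chrom, dtype=object))
        all_pos.append(positions)
        all_ref.append(np.full(positions.size, "A", dtype=object))
        all_alt.append(np.full(positions.size, "G", dtype=object))
        all_ids.append(np.array([f"{chrom}:{p}" for p in positions], dtype=object))

    cohort = PhasedCohort(
        sample_ids=sample_ids,
        chrom=np.concatenate(all_chrom),
        pos=np.concatenate(all_pos),
        ref=np.concatenate(all_ref),
        alt=np.concatenate(all_alt),
        variant_ids=np.concatenate(all_ids),
        haplotypes=np.concatenate(hap_blocks, axis=2),
        mutation_labels=mutation_labels,
    )

    degrees = _truth_degrees(config, cluster_samples, pair_samples)
    truth = TruthSet(
        segments=truth_segments,
        degrees=degrees,
        clusters=clusters_truth,
        families=families,
        founder_haplotypes=founder_truths,
        tmrca=tmrca,
        mutation_labels=mutation_labels,
    )
    if out_dir is not None:
        write_cohort(cohort, truth, gmap, out_dir, seed=config.seed)
    return cohort, truth, gmap


def _make_pool_from_freqs(n_haplotypes: int, freqs: np.ndarray,
                          rng: np.random.Generator):
    pool = (rng.random((n_haplotypes, freqs.size)) < freqs).astype(np.int8)
    return pool, freqs


def _truth_degrees(config, cluster_samples, pair_samples) -> pd.DataFrame:
    rows = []
    for spec in config.clusters:
        ids = cluster_samples[spec.cluster_id]
        # two independent chains of g meioses to the shared founder
        d = 2 * spec.generations
        deg = str(d) if d <= 11 else "UR"
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = sorted((ids[i], ids[j]))
                rows.append((a, b, deg))
    for pspec, sa, sb in pair_samples:
        a, b = sorted((sa, sb))
        rows.append((a, b, str(pspec.degree)))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "degree"])


# ---------------------------------------------------------------------------
# Output files
# ---------------------------------------------------------------------------


def write_cohort(cohort: PhasedCohort, truth: TruthSet, gmap: GeneticMap,
                 out_dir, seed: int | None = None) -> None:
    """Write phased VCF, .map and the truth TSVs into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comments = [f"founderscan_seed={seed}"] if seed is not None else []
    write_phased_vcf(cohort, out / "cohort.vcf", header_comments=comments)
    gmap.write(out / "genome.map")
    write_segments(truth.segments, out / "truth_segments.tsv")
    truth.degrees.to_csv(out / "truth_degrees.tsv", sep="\t", index=False)
    with open(out / "truth_clusters.tsv", "w") as fh:
        fh.write("sample_id\tcluster_id\tfamily_id\n")
        for sid, cid in truth.clusters.items():
            fh.write(f"{sid}\t{cid}\t{truth.families.get(sid) or '-'}\n")
    with open(out / "truth_haplotypes.tsv", "w") as fh:
        fh.write("cluster_id\tchrom\tpos\tallele\tcore_start_bp\tcore_end_bp"
                 "\tmutation_position\tmutation_label\tgenerations\n")
        for cid, ft in truth.founder_haplotypes.items():
            g = truth.tmrca[cid]
            for p, a in zip(ft.positions, ft.alleles):
                fh.write(f"{cid}\t{ft.chrom}\t{p}\t{a}\t{ft.core_start_bp}"
                         f"\t{ft.core_end_bp}\t{ft.mutation_position}"
                         f"\t{ft.mutation_label}\t{g}\n")
    write_mutation_labels(truth.mutation_labels, out / "mutations.tsv")


# ---------------------------------------------------------------------------
# Study-shaped presets
# ---------------------------------------------------------------------------

#: hg19 coordinates of the SOD1 gene, the anchor locus for the presets.
SOD1_LOCUS = ("21", 33_031_935, 33_041_243)

#: Mutation positions planted inside the locus (hg19-like coordinates).
MUTATION_POSITIONS = {
    "p.I114T": 33_039_672,
    "p.V149G": 33_040_861,
    "p.E101G": 33_038_385,
}


def five_cluster_config(seed: int = 0, n_unrelated: int = 20,
                        genotype_error_rate: float = 0.0) -> SimConfig:
    """The five-founder-event cohort: cluster sizes 22/33/6/3/3 with
    generational depths 10/8/5/3/4 mirroring the published per-cluster
    TMRCA ranges, all mutations inside the SOD1 locus on a chr21-like
    chromosome. Two clusters share p.I114T and two share p.E101G, so
    discordant-mutation and same-mutation-different-haplotype structure
    are both present."""
    clusters = [
        ClusterSpec("C1", 22, 10, MUTATION_POSITIONS["p.I114T"], "p.I114T"),
        ClusterSpec("C2", 33, 8, MUTATION_POSITIONS["p.V149G"], "p.V149G"),
        ClusterSpec("C3", 6, 5, MUTATION_POSITIONS["p.E101G"], "p.E101G"),
        ClusterSpec("C4", 3, 3, MUTATION_POSITIONS["p.I114T"], "p.I114T"),
        ClusterSpec("C5", 3, 4, MUTATION_POSITIONS["p.E101G"], "p.E101G"),
    ]
    return SimConfig(
        seed=seed,
        n_snps=8000,
        chrom_length_bp=46_700_000,
        chrom_length_cm=62.0,
        chrom_names=["21"],
        clusters=clusters,
        n_unrelated=n_unrelated,
        genotype_error_rate=genotype_error_rate,
    )


def genome_config(seed: int = 0, n_chromosomes: int = 22,
                  pairs: list[PairSpec] | None = None) -> SimConfig:
    """Genome-scale conditions for degree-recovery experiments:
    22 chromosomes of 150 cM (~3300 cM, close to the autosomal map),
    128 SNPs per cM."""
    return SimConfig(
        seed=seed,
        n_snps=19200,
        chrom_length_bp=130_000_000,
        chrom_length_cm=150.0,
        n_chromosomes=n_chromosomes,
        pairs=pairs or [],
    )
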