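"""Founder-haplotype extraction over a target locus.

For each cluster of the locus network: the core interval is the
intersection of the IBD segments inferred between its member pairs (each
pair contributing its longest locus-overlapping segment); the founder
haplotype is the single allele sequence carried by at least one phased copy
of every member across that interval. Haplotypes from different clusters
are then re-reported over the common interval (and hence the same SNPs),
and SNPs carrying the same allele in every founder haplotype are pruned as
uninformative for distinguishing founder events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AmbiguousHaplotypeError,
    EmptyCoreError,
    NoSharedHaplotypeError,
    ValidationError,
)
from .formats_io import IBDSegment, PhasedCohort
from .network import Edge, LocusNetwork, LocusSpec


@dataclass
class ClusterHaplotype:
    """A cluster's founder haplotype: interval, SNPs and allele sequence,
    plus which phased copy of each carrier matches it."""

    cluster_id: str
    chrom: str
    start_bp: int
    end_bp: int
    positions: np.ndarray
    alleles: np.ndarray
    carriers: list[str]
    hap_index: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return int(self.positions.size)


def cluster_core_interval(edges: dict[Edge, list[IBDSegment]],
                          locus: LocusSpec) -> tuple[str, int, int]:
    """Intersection of the member pairs' segments: [max start, min end].

    Each edge contributes its longest locus-overlapping segment. The result
    must still overlap the locus.
    """
    if not edges:
        raise ValidationError("cluster has no edges")
    best: dict[Edge, IBDSegment] = {}
    for pair, segs in edges.items():
        overlapping = [s for s in segs
                       if s.overlaps(locus.chrom, locus.start_bp, locus.end_bp)]
        if not overlapping:
            raise ValidationError(f"pair {pair}: no locus-overlapping segment")
        best[pair] = max(overlapping, key=lambda s: s.length_cm)
    start_pair = max(best, key=lambda p: best[p].start_bp)
    end_pair = min(best, key=lambda p: best[p].end_bp)
    start = best[start_pair].start_bp
    end = best[end_pair].end_bp
    if start > end:
        raise EmptyCoreError(
            f"empty segment intersection: pair {start_pair} starts at {start} "
            f"but pair {end_pair} ends at {end}"
        )
    if not (start <= locus.end_bp and end >= locus.start_bp):
        raise EmptyCoreError("segment intersection does not overlap the locus")
    return locus.chrom, start, end


def extract_shared_haplotype(cohort: PhasedCohort, members: list[str],
                             chrom: str, start_bp: int, end_bp: int,
                             cluster_id: str = "") -> ClusterHaplotype:
    """The singular haplotype appearing in all members over the interval.

    Candidate sequences are the first member's two phased copies; a
    candidate survives if every member carries it on at least one copy.
    Exactly one must survive. A member whose both copies match (an
    autozygous stretch) records copy 0 by convention.
    """
    if not members:
        raise ValidationError("no cluster members")
    idx = cohort.chrom_slice(chrom)
    idx = idx[(cohort.pos[idx] >= start_bp) & (cohort.pos[idx] <= end_bp)]
    if idx.size == 0:
        raise ValidationError(
            f"no SNPs in interval {chrom}:{start_bp}-{end_bp}")
    H = cohort.haplotypes[:, :, idx]
    rows = [cohort.sample_index(m) for m in members]
    first = H[rows[0]]
    candidates = [first[0]]
    if not np.array_equal(first[0], first[1]):
        candidates.append(first[1])
    surviving = []
    for cand in candidates:
        matches: dict[str, int] = {}
        for m, r in zip(members, rows):
            hit = None
            for copy in (0, 1):
                if np.array_equal(H[r, copy], cand):
                    hit = copy
                    break  # both copies matching records copy 0
            if hit is None:
                break
            matches[m] = hit
        else:
            surviving.append((cand, matches))
    if not surviving:
        raise NoSharedHaplotypeError(
            f"cluster {cluster_id or members}: no haplotype shared by all "
            f"members over {chrom}:{start_bp}-{end_bp}"
        )
    if len(surviving) > 1:
        seqs = ["".join(map(str, c)) for c, _ in surviving]
        raise AmbiguousHaplotypeError(
            f"cluster {cluster_id or members}: {len(surviving)} distinct "
            f"shared haplotypes over {chrom}:{start_bp}-{end_bp}: {seqs}"
        )
    alleles, hap_index = surviving[0]
    return ClusterHaplotype(
        cluster_id=cluster_id,
        chrom=chrom, start_bp=start_bp, end_bp=end_bp,
        positions=cohort.pos[idx].copy(),
        alleles=alleles.astype(np.int8).copy(),
        carriers=list(members),
        hap_index=hap_index,
    )


def carries_haplotype(cohort: PhasedCohort, sample_id: str,
                      hap: ClusterHaplotype) -> bool:
    """Does either phased copy of ``sample_id`` equal ``hap`` over its SNPs?"""
    idx = cohort.chrom_slice(hap.chrom)
    idx = idx[np.isin(cohort.pos[idx], hap.positions)]
    r = cohort.sample_index(sample_id)
    return any(np.array_equal(cohort.haplotypes[r, c, idx], hap.alleles)
               for c in (0, 1))


def common_report_interval(haplotypes: list[ClusterHaplotype]
                           ) -> tuple[tuple[str, int, int],
                                      list[ClusterHaplotype]]:
    """Re-report all cluster haplotypes over their common interval and the
    SNP positions present in every haplotype within it."""
    if len(haplotypes) < 2:
        raise ValidationError("need >= 2 cluster haplotypes to compare")
    chroms = {h.chrom for h in haplotypes}
    if len(chroms) > 1:
        raise ValidationError(f"haplotypes on different chromosomes: {chroms}")
    chrom = chroms.pop()
    start = max(h.start_bp for h in haplotypes)
    end = min(h.end_bp for h in haplotypes)
    if start > end:
        raise EmptyCoreError("cluster haplotype intervals share no window")
    shared = None
    for h in haplotypes:
        inside = set(int(p) for p in h.positions
                     if start <= p <= end)
        shared = inside if shared is None else (shared & inside)
    positions = np.array(sorted(shared), dtype=np.int64)
    if positions.size == 0:
        raise EmptyCoreError("no SNPs common to all cluster haplotypes")
    reported = []
    for h in haplotypes:
        keep = np.isin(h.positions, positions)
        reported.append(ClusterHaplotype(
            cluster_id=h.cluster_id, chrom=chrom,
            start_bp=int(start), end_bp=int(end),
            positions=h.positions[keep].copy(),
            alleles=h.alleles[keep].copy(),
            carriers=list(h.carriers),
            hap_index=dict(h.hap_index),
        ))
    return (chrom, int(start), int(end)), reported


def drop_uninformative_snps(haplotypes: list[ClusterHaplotype]
                            ) -> list[ClusterHaplotype]:
    """Remove SNPs carrying an identical allele across all founder
    haplotypes; the remainder is what distinguishes founder events."""
    if not haplotypes:
        return []
    positions = haplotypes[0].positions
    for h in haplotypes[1:]:
        if not np.array_equal(h.positions, positions):
            raise ValidationError(
                "haplotypes must be reported on an identical SNP set first")
    mat = np.stack([h.alleles for h in haplotypes])
    informative = ~np.all(mat == mat[0], axis=0)
    if not informative.any():
        warnings.warn("all SNPs uninformative; pruned haplotypes are empty",
                      stacklevel=2)
    return [ClusterHaplotype(
        cluster_id=h.cluster_id, chrom=h.chrom,
        start_bp=h.start_bp, end_bp=h.end_bp,
        positions=h.positions[informative].copy(),
        alleles=h.alleles[informative].copy(),
        carriers=list(h.carriers),
        hap_index=dict(h.hap_index),
    ) for h in haplotypes]


def extract_founder_haplotypes(network: LocusNetwork, cohort: PhasedCohort,
                               locus: LocusSpec
                               ) -> tuple[list[ClusterHaplotype],
                                          list[ClusterHaplotype],
                                          tuple[str, int, int] | None]:
    """Per-cluster core extraction, common-interval re-reporting and
    uninformative-SNP pruning in one call.

    Returns (full per-cluster haplotypes, pruned comparable haplotypes,
    common interval). With a single cluster there is nothing to compare:
    the pruning steps are skipped and the common interval is None.
    """
    full: list[ClusterHaplotype] = []
    for cid, members in network.clusters.items():
        edges = network.cluster_edges(cid)
        chrom, start, end = cluster_core_interval(edges, locus)
        full.append(extract_shared_haplotype(
            cohort, members, chrom, start, end, cluster_id=cid))
    if len(full) < 2:
        return full, list(full), None
    interval, reported = common_report_interval(full)
    pruned = drop_uninformative_snps(reported)
    return full, pruned, interval


def write_haplotypes(haplotypes: list[ClusterHaplotype], cohort: PhasedCohort,
                     path, header_comments: list[str] | None = None) -> None:
    """TSV: cluster_id, chrom, pos, ref, alt, allele — one row per retained
    SNP per cluster."""
    pos_to_idx = {}
    for chrom in cohort.chromosomes:
        for i in cohort.chrom_slice(chrom):
            pos_to_idx[(chrom, int(cohort.pos[i]))] = i
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        fh.write("cluster_id\tchrom\tpos\tref\talt\tallele\n")
        for h in haplotypes:
            for p, a in zip(h.positions, h.alleles):
                i = pos_to_idx[(h.chrom, int(p))]
                fh.write(f"{h.cluster_id}\t{h.chrom}\t{p}\t{cohort.ref[i]}"
                         f"\t{cohort.alt[i]}\t{a}\n")
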