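"""On-disk formats and the core in-memory containers.

Coordinate conventions (applied consistently across the package):

* variant and segment positions are 1-based inclusive bp, as in VCF;
* mask regions are 0-based half-open, as in BED, and are converted to the
  1-based convention only at the point of use;
* genetic-map positions are centimorgans; queries outside the anchored range
  are clamped to the terminal cM values rather than extrapolated, so segment
  lengths near chromosome ends can never go negative or run away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import MapLookupError, ParseError, ValidationError

logger = logging.getLogger(__name__)

SEGMENT_COLUMNS = [
    "sample_a", "hap_a", "sample_b", "hap_b", "chrom",
    "start_bp", "end_bp", "start_cm", "end_cm", "length_cm",
]


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """Monotone bp -> cM lookup per chromosome.

    Parameters
    ----------
    anchors
        Mapping of chromosome name to ``(positions_bp, positions_cm)`` arrays.
        Positions must be strictly increasing, cM non-decreasing, with at
        least two anchors per chromosome.
    """

    def __init__(self, anchors: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._anchors: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        if not anchors:
            raise ValidationError("genetic map has no anchors")
        for chrom, (bp, cm) in anchors.items():
            bp = np.asarray(bp, dtype=np.int64)
            cm = np.asarray(cm, dtype=np.float64)
            if bp.size < 2:
                raise ValidationError(
                    f"chromosome {chrom}: need >= 2 map anchors, got {bp.size}"
                )
            if bp.size != cm.size:
                raise ValidationError(f"chromosome {chrom}: bp/cM length mismatch")
            if not np.all(np.diff(bp) > 0):
                raise ValidationError(
                    f"chromosome {chrom}: anchor positions not strictly increasing"
                )
            if not np.all(np.diff(cm) >= 0):
                raise ValidationError(
                    f"chromosome {chrom}: cM values decrease along the chromosome"
                )
            self._anchors[chrom] = (bp, cm)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._anchors)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._anchors

    def anchors(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        self._check(chrom)
        return self._anchors[chrom]

    def _check(self, chrom: str) -> None:
        if chrom not in self._anchors:
            raise MapLookupError(
                f"chromosome {chrom!r} not in genetic map "
                f"(has {sorted(self._anchors)})"
            )

    def interpolate(self, chrom: str, position_bp) -> np.ndarray | float:
        """Linearly interpolate cM at ``position_bp`` (scalar or array).

        Positions before the first / after the last anchor are clamped to the
        terminal cM values.
        """
        self._check(chrom)
        bp, cm = self._anchors[chrom]
        out = np.interp(np.asarray(position_bp, dtype=np.float64), bp, cm)
        return float(out) if np.isscalar(position_bp) else out

    def length_cm(self, chrom: str) -> float:
        bp, cm = self.anchors(chrom)
        return float(cm[-1] - cm[0])

    def total_length_cm(self) -> float:
        return sum(self.length_cm(c) for c in self._anchors)

    def write(self, path) -> None:
        """Write a PLINK-style 4-column .map file (chrom, id, cM, bp)."""
        with open(path, "w") as fh:
            for chrom, (bp, cm) in self._anchors.items():
                for b, c in zip(bp, cm):
                    fh.write(f"{chrom}\t{chrom}:{b}\t{c:.8g}\t{b}\n")


def read_genetic_map(path) -> GeneticMap:
    """Read a PLINK-style whitespace-delimited map: chrom, id, cM, bp."""
    anchors: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            chrom = parts[0]
            try:
                cm = float(parts[2])
                bp = int(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            anchors.setdefault(chrom, []).append((bp, cm))
    if not anchors:
        raise ValidationError(f"{path}: genetic map has no anchors")
    arrays = {}
    for chrom, rows in anchors.items():
        bp = np.array([r[0] for r in rows], dtype=np.int64)
        cm = np.array([r[1] for r in rows], dtype=np.float64)
        arrays[chrom] = (bp, cm)
    return GeneticMap(arrays)


def interpolate_cm(gmap: GeneticMap, chrom: str, position_bp):
    """Functional alias for :meth:`GeneticMap.interpolate`."""
    return gmap.interpolate(chrom, position_bp)


# ---------------------------------------------------------------------------
# Phased cohort
# ---------------------------------------------------------------------------

@dataclass
class PhasedCohort:
    """Phased biallelic SNP data: samples x variants x 2 haplotypes.

    ``haplotypes`` has shape ``(n_samples, 2, n_variants)`` with alleles coded
    0 (ref) / 1 (alt). ``mutation_labels`` optionally annotates carriers of a
    named mutation (e.g. ``"p.I114T"``).
    """

    sample_ids: list[str]
    chrom: np.ndarray          # str per variant
    pos: np.ndarray            # int64, 1-based
    ref: np.ndarray            # str per variant
    alt: np.ndarray            # str per variant
    variant_ids: np.ndarray    # str per variant
    haplotypes: np.ndarray     # int8 (n_samples, 2, n_variants)
    mutation_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n, two, m = self.haplotypes.shape
        if two != 2:
            raise ValidationError("haplotype matrix must have 2 copies per sample")
        if n != len(self.sample_ids):
            raise ValidationError("haplotype matrix does not match sample list")
        if not (len(self.chrom) == len(self.pos) == len(self.ref)
                == len(self.alt) == len(self.variant_ids) == m):
            raise ValidationError("variant annotation arrays do not match matrix")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if self.haplotypes.size and (self.haplotypes.min() < 0
                                     or self.haplotypes.max() > 1):
            raise ValidationError("haplotype alleles must be coded 0/1")
        self.chrom = np.asarray(self.chrom, dtype=str)
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if len(np.unique(p)) != len(p):
                raise ValidationError(f"duplicate positions on chromosome {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def chromosomes(self) -> list[str]:
        if self.chrom.size == 0:
            return []
        change = np.flatnonzero(self.chrom[1:] != self.chrom[:-1])
        names = self.chrom[np.concatenate(([0], change + 1))].tolist()
        if len(set(names)) != len(names):
            raise ValidationError("variants not grouped by chromosome")
        return names

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError as exc:
            raise KeyError(f"unknown sample {sample_id!r}") from exc

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Indices of variants on ``chrom`` (file order)."""
        return np.flatnonzero(self.chrom == chrom)


def read_phased_vcf(path, mutation_labels: dict[str, str] | None = None) -> PhasedCohort:
    """Read a phased VCF into a :class:`PhasedCohort`.

    Only biallelic SNP records are used; others are skipped with a logged
    count. Unphased or missing genotypes are hard errors: the pipeline
    requires complete phased data.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    vids: list[str] = []
    haps: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        col = np.empty((len(samples), 2), dtype=np.int8)
        for si, gt in enumerate(rec.genotypes):
            a, b, phased = gt[0], gt[1], gt[2]
            if a < 0 or b < 0:
                raise ValidationError(
                    f"missing genotype at {rec.CHROM}:{rec.POS} for sample "
                    f"{samples[si]}; complete phased data required"
                )
            if not phased:
                raise ValidationError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} for sample "
                    f"{samples[si]}"
                )
            col[si, 0] = a
            col[si, 1] = b
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        vids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        haps.append(col)
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNP records", n_skipped)
    if not haps:
        raise ValidationError(f"{path}: no usable biallelic SNP records")
    matrix = np.stack(haps, axis=2)  # (n_samples, 2, n_variants)
    cohort = PhasedCohort(
        sample_ids=samples,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        variant_ids=np.array(vids, dtype=object),
        haplotypes=matrix,
        mutation_labels=dict(mutation_labels or {}),
    )
    cohort.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return cohort


def write_phased_vcf(cohort: PhasedCohort, path, header_comments: list[str] | None = None) -> None:
    """Write a minimal phased VCF (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for comment in header_comments or []:
            fh.write(f"##{comment}\n")
        for chrom in cohort.chromosomes:
            idx = cohort.chrom_slice(chrom)
            fh.write(f"##contig=<ID={chrom},length={int(cohort.pos[idx].max()) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(cohort.sample_ids) + "\n")
        H = cohort.haplotypes
        for vi in range(cohort.n_variants):
            gts = "\t".join(f"{H[si, 0, vi]}|{H[si, 1, vi]}"
                            for si in range(cohort.n_samples))
            fh.write(f"{cohort.chrom[vi]}\t{cohort.pos[vi]}\t{cohort.variant_ids[vi]}"
                     f"\t{cohort.ref[vi]}\t{cohort.alt[vi]}\t.\tPASS\t.\tGT\t{gts}\n")


def read_mutation_labels(path) -> dict[str, str]:
    """Read a 2-column TSV (sample_id, mutation label)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ParseError(f"{path}: expected 2 columns (sample_id, mutation)")
    return dict(zip(df[cols[0]], df[cols[1]]))


def write_mutation_labels(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmutation\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


# ---------------------------------------------------------------------------
# Mask regions
# ---------------------------------------------------------------------------

class MaskRegions:
    """Genomic intervals excluded from IBD calling; 0-based half-open bp.

    Overlapping or adjacent intervals are merged on construction.
    """

    def __init__(self, intervals: list[tuple[str, int, int]]):
        for chrom, start, end in intervals:
            if start >= end:
                raise ValidationError(
                    f"mask interval {chrom}:{start}-{end}: start must be < end"
                )
        merged: dict[str, list[list[int]]] = {}
        for chrom, start, end in sorted(intervals):
            runs = merged.setdefault(chrom, [])
            if runs and start <= runs[-1][1]:
                runs[-1][1] = max(runs[-1][1], end)
            else:
                runs.append([start, end])
        self._by_chrom = {c: [(s, e) for s, e in runs] for c, runs in merged.items()}

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [(c, s, e) for c, runs in sorted(self._by_chrom.items())
                for s, e in runs]

    def for_chrom(self, chrom: str) -> list[tuple[int, int]]:
        return list(self._by_chrom.get(chrom, []))

    def __len__(self) -> int:
        return sum(len(r) for r in self._by_chrom.values())


def read_mask_bed(path) -> MaskRegions:
    """Read a 3+ column BED file of mask regions."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            intervals.append((parts[0], start, end))
    return MaskRegions(intervals)


# ---------------------------------------------------------------------------
# IBD segments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IBDSegment:
    """One shared stretch between two haplotypes of two samples."""

    sample_a: str
    hap_a: int
    sample_b: str
    hap_b: int
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float
    length_cm: float

    def __post_init__(self):
        if self.hap_a not in (0, 1) or self.hap_b not in (0, 1):
            raise ValidationError("haplotype indices must be 0 or 1")
        if self.sample_a == self.sample_b:
            raise ValidationError("segment endpoints must be distinct samples")
        if self.start_bp > self.end_bp:
            raise ValidationError(
                f"segment {self.chrom}:{self.start_bp}-{self.end_bp}: "
                "start_bp > end_bp"
            )
        if self.end_cm < self.start_cm:
            raise ValidationError("end_cm < start_cm")
        if abs(self.length_cm - (self.end_cm - self.start_cm)) > 1e-6:
            raise ValidationError("length_cm inconsistent with cM endpoints")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.sample_a, self.sample_b)

    @property
    def pairing(self) -> tuple[int, int]:
        return (self.hap_a, self.hap_b)

    def overlaps(self, chrom: str, start_bp: int, end_bp: int) -> bool:
        """1 bp or more overlap with a 1-based inclusive interval."""
        return (self.chrom == chrom and self.start_bp <= end_bp
                and self.end_bp >= start_bp)


def write_segments(segments: list[IBDSegment], path,
                   header_comments: list[str] | None = None) -> None:
    """Write segments as a TSV with the canonical column set."""
    with open(path, "w") as fh:
        for comment in header_comments or []:
            fh.write(f"# {comment}\n")
        fh.write("\t".join(SEGMENT_COLUMNS) + "\n")
        for s in segments:
            fh.write(f"{s.sample_a}\t{s.hap_a}\t{s.sample_b}\t{s.hap_b}\t{s.chrom}"
                     f"\t{s.start_bp}\t{s.end_bp}\t{s.start_cm!r}\t{s.end_cm!r}"
                     f"\t{s.length_cm!r}\n")


def read_segments(path) -> list[IBDSegment]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     float_precision="round_trip",
                     dtype={"sample_a": str, "sample_b": str, "chrom": str})
    if list(df.columns) != SEGMENT_COLUMNS:
        raise ParseError(
            f"{path}: unexpected columns {list(df.columns)}; "
            f"expected {SEGMENT_COLUMNS}"
        )
    return [
        IBDSegment(
            sample_a=row.sample_a, hap_a=int(row.hap_a),
            sample_b=row.sample_b, hap_b=int(row.hap_b),
            chrom=row.chrom,
            start_bp=int(row.start_bp), end_bp=int(row.end_bp),
            start_cm=float(row.start_cm), end_cm=float(row.end_cm),
            length_cm=float(row.length_cm),
        )
        for row in df.itertuples(index=False)
    ]
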