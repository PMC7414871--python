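"""Degree-of-relatedness estimation from genome-wide IBD sharing.

The kinship coefficient is estimated from the IBD1/IBD2 sharing profile as
phi = (0.25 * IBD1 + 0.5 * IBD2) / map length, and mapped to an integer
degree by d = round(-log2(phi)) - 1 (half-up), realizing the convention
phi = 2^(-d-1): d=1 full siblings, d=3 first cousins, d=5 second cousins,
d=7 third cousins. Parent-offspring pairs are recognized first by their
near-complete IBD1 coverage with essentially no IBD2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError
from .formats_io import GeneticMap, IBDSegment
from .ibd import SharingProfile, ibd1_ibd2_profile

PO = "PO"
UR = "UR"


@dataclass
class RelatednessParams:
    po_ibd1_frac: float = 0.95      # min IBD1 genome fraction for PO
    po_ibd2_frac: float = 0.02      # max IBD2 genome fraction for PO
    ur_kinship: float = 2.0 ** -13  # below this, unrelated (beyond 11th degree)
    max_degree: int = 11


@dataclass
class PairRelatedness:
    sample_a: str
    sample_b: str
    kinship_hat: float
    degree_hat: int | str           # 1..11, "PO" or "UR"
    total_ibd1_cm: float
    total_ibd2_cm: float
    reported_degree: int | str | None = None

    def __post_init__(self):
        if not (0.0 <= self.kinship_hat <= 0.5):
            raise ValidationError(f"kinship {self.kinship_hat} outside [0, 0.5]")


def kinship_from_profile(profile: SharingProfile) -> float:
    """phi-hat = (0.25 * IBD1 + 0.5 * IBD2) / total map length."""
    if profile.total_cm <= 0:
        raise ValidationError("zero-length map")
    return (0.25 * profile.ibd1_cm + 0.5 * profile.ibd2_cm) / profile.total_cm


def estimate_degree(kinship_hat: float, ibd1_frac: float = 0.0,
                    ibd2_frac: float = 0.0,
                    params: RelatednessParams | None = None) -> int | str:
    """Map an estimated kinship (plus sharing fractions) to a degree."""
    params = params or RelatednessParams()
    if ibd1_frac >= params.po_ibd1_frac and ibd2_frac <= params.po_ibd2_frac:
        return PO
    if kinship_hat < params.ur_kinship or kinship_hat == 0.0:
        return UR
    d_real = -math.log2(kinship_hat) - 1.0
    d = math.floor(d_real + 0.5)  # half-up; ties round to the larger degree
    return min(max(d, 1), params.max_degree)


def pair_relatedness(segments: list[IBDSegment], gmap: GeneticMap,
                     params: RelatednessParams | None = None,
                     reported_degree=None) -> PairRelatedness:
    """Estimate one pair's kinship and degree from its segments."""
    if not segments:
        raise ValidationError("no segments; absent pairs are UR by definition")
    profile = ibd1_ibd2_profile(segments, gmap)
    kin = kinship_from_profile(profile)
    deg = estimate_degree(kin, profile.ibd1_frac, profile.ibd2_frac, params)
    sa, sb = segments[0].pair
    return PairRelatedness(
        sample_a=sa, sample_b=sb, kinship_hat=kin, degree_hat=deg,
        total_ibd1_cm=profile.ibd1_cm, total_ibd2_cm=profile.ibd2_cm,
        reported_degree=reported_degree,
    )


def relatedness_table(segments: list[IBDSegment], gmap: GeneticMap,
                      params: RelatednessParams | None = None,
                      reported: dict[tuple[str, str], int | str] | None = None
                      ) -> list[PairRelatedness]:
    """Per-pair relatedness for every pair with at least one segment."""
    by_pair: dict[tuple[str, str], list[IBDSegment]] = {}
    for s in segments:
        by_pair.setdefault(s.pair, []).append(s)
    out = []
    for pair, segs in sorted(by_pair.items()):
        rep = (reported or {}).get(pair)
        out.append(pair_relatedness(segs, gmap, params, reported_degree=rep))
    return out


def pairs_dataframe(pairs: list[PairRelatedness]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_a": p.sample_a, "sample_b": p.sample_b,
        "kinship_hat": p.kinship_hat, "degree_hat": p.degree_hat,
        "reported_degree": p.reported_degree,
        "total_ibd1_cm": p.total_ibd1_cm, "total_ibd2_cm": p.total_ibd2_cm,
    } for p in pairs])


def _degree_numeric(degree: int | str | None) -> float:
    """Numeric scale for distance computations: PO sits at 1 (kinship 1/4),
    UR beyond the deepest estimable degree."""
    if degree is None:
        return math.nan
    if degree == PO:
        return 1.0
    if degree == UR:
        return 13.0
    return float(int(degree))


def find_novel_relatives(pairs: list[PairRelatedness],
                         families: dict[str, str | None],
                         max_degree: int = 7,
                         mutation_labels: dict[str, str] | None = None
                         ) -> pd.DataFrame:
    """Pairs from different families (or involving sporadic samples) with an
    estimated degree at or below ``max_degree`` — the newly identified
    relatives a pedigree did not record. Sorted by estimated degree."""
    labels = mutation_labels or {}
    rows = []
    for p in pairs:
        fam_a = families.get(p.sample_a)
        fam_b = families.get(p.sample_b)
        within = fam_a is not None and fam_b is not None and fam_a == fam_b
        if within:
            continue
        if p.degree_hat == UR:
            continue
        if _degree_numeric(p.degree_hat) > max_degree:
            continue
        rows.append({
            "family_a": fam_a or "sporadic", "sample_a": p.sample_a,
            "family_b": fam_b or "sporadic", "sample_b": p.sample_b,
            "degree_hat": p.degree_hat, "kinship_hat": p.kinship_hat,
            "mutation_a": labels.get(p.sample_a, ""),
            "mutation_b": labels.get(p.sample_b, ""),
        })
    df = pd.DataFrame(rows, columns=[
        "family_a", "sample_a", "family_b", "sample_b",
        "degree_hat", "kinship_hat", "mutation_a", "mutation_b"])
    if len(df):
        df = df.sort_values(
            by="degree_hat", key=lambda c: c.map(_degree_numeric),
            kind="stable").reset_index(drop=True)
    return df


def concordance_summary(pairs: list[PairRelatedness]) -> pd.DataFrame:
    """Per reported degree: number of pairs and fraction of estimates within
    one degree of the reported relationship."""
    rows = []
    for p in pairs:
        if p.reported_degree is None:
            continue
        dist = abs(_degree_numeric(p.degree_hat)
                   - _degree_numeric(p.reported_degree))
        rows.append((str(p.reported_degree), dist <= 1.0))
    if not rows:
        return pd.DataFrame(columns=["reported_degree", "n_pairs",
                                     "frac_within_1"])
    df = pd.DataFrame(rows, columns=["reported_degree", "within_1"])
    out = df.groupby("reported_degree", sort=True).agg(
        n_pairs=("within_1", "size"),
        frac_within_1=("within_1", "mean"),
    ).reset_index()
    key = out["reported_degree"].map(_degree_numeric)
    return out.iloc[key.argsort(kind="stable")].reset_index(drop=True)
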