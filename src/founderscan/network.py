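"""Relatedness networks over a target locus.

Each node is a sample; an edge joins two samples inferred IBD over the
locus (any segment overlapping it by at least 1 bp). Samples sharing no
segment over the locus with anyone are omitted, so every node has degree
>= 1. Clusters are the connected components, labelled C1..Ck by decreasing
size (ties by smallest member id) so reports are reproducible.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field

import networkx as nx

from .errors import ValidationError
from .formats_io import IBDSegment

_LOCUS_RE = re.compile(r"^(\w+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class LocusSpec:
    """Target locus, 1-based inclusive bp."""

    chrom: str
    start_bp: int
    end_bp: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValidationError("locus start > end")

    @classmethod
    def parse(cls, text: str) -> "LocusSpec":
        """Parse e.g. ``chr21:33,031,935-33,041,243`` or ``21:100-200``."""
        m = _LOCUS_RE.match(text.strip())
        if not m:
            raise ValidationError(f"cannot parse locus {text!r}")
        return cls(m.group(1), int(m.group(2).replace(",", "")),
                   int(m.group(3).replace(",", "")))


Edge = tuple[str, str]


def segments_at_locus(segments: list[IBDSegment],
                      locus: LocusSpec) -> dict[Edge, list[IBDSegment]]:
    """Edges supported by locus-overlapping segments: an edge exists for a
    pair iff at least one of its segments overlaps the locus by >= 1 bp;
    multiple haplotype-pair segments collapse onto one edge."""
    edges: dict[Edge, list[IBDSegment]] = {}
    for seg in segments:
        if seg.overlaps(locus.chrom, locus.start_bp, locus.end_bp):
            edges.setdefault(seg.pair, []).append(seg)
    return edges


@dataclass
class LocusNetwork:
    graph: nx.Graph
    clusters: dict[str, list[str]] = field(default_factory=dict)

    @property
    def membership(self) -> dict[str, str]:
        return {sid: cid for cid, members in self.clusters.items()
                for sid in members}

    def cluster_edges(self, cluster_id: str) -> dict[Edge, list[IBDSegment]]:
        members = set(self.clusters[cluster_id])
        return {(a, b): data["segments"]
                for a, b, data in self.graph.edges(data=True)
                if a in members}

    def connection_counts(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def to_json(self, path=None, meta: dict | None = None) -> str:
        doc = {
            "nodes": [{"id": n, **{k: v for k, v in d.items()}}
                      for n, d in sorted(self.graph.nodes(data=True))],
            "edges": [{"a": a, "b": b, "n_segments": len(d["segments"])}
                      for a, b, d in sorted(self.graph.edges(data=True))],
            "clusters": {cid: members
                         for cid, members in self.clusters.items()},
        }
        if meta:
            doc["_meta"] = meta
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def build_network(edges: dict[Edge, list[IBDSegment]],
                  mutation_labels: dict[str, str] | None = None
                  ) -> LocusNetwork:
    """Build the locus network and label its connected components."""
    g = nx.Graph()
    for (a, b), segs in edges.items():
        g.add_edge(a, b, segments=list(segs))
    labels = mutation_labels or {}
    for n in g.nodes:
        g.nodes[n]["mutation"] = labels.get(n, "")
    components = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    clusters = {f"C{i + 1}": members for i, members in enumerate(components)}
    return LocusNetwork(graph=g, clusters=clusters)


@dataclass(frozen=True)
class DiscordantEdge:
    sample_a: str
    sample_b: str
    reason: str


def flag_discordant_edges(network: LocusNetwork,
                          mutation_labels: dict[str, str],
                          cohort=None,
                          cluster_haplotypes=None) -> list[DiscordantEdge]:
    """Flag edges inconsistent with a single founder event.

    An edge is flagged when (a) its two samples carry different mutation
    labels, or (b) — when founder haplotypes and the phased cohort are
    supplied — either sample does not carry its cluster's founder haplotype
    over the core interval. Flagged edges are reported, never removed: they
    usually indicate false-positive IBD calls worth inspecting, and dropping
    them is a separate, explicit choice (`drop_flagged` in the pipeline).
    """
    flags: list[DiscordantEdge] = []
    membership = network.membership
    carriers_ok: dict[str, bool] = {}
    if cluster_haplotypes is not None and cohort is not None:
        from .founder import carries_haplotype

        for ch in cluster_haplotypes:
            for sid in network.clusters.get(ch.cluster_id, []):
                carriers_ok[sid] = carries_haplotype(cohort, sid, ch)
    for a, b in sorted(network.graph.edges):
        la = mutation_labels.get(a)
        lb = mutation_labels.get(b)
        if la is None or lb is None:
            missing = a if la is None else b
            warnings.warn(f"no mutation label for {missing}; edge "
                          f"({a}, {b}) skipped", stacklevel=2)
            continue
        if la != lb:
            flags.append(DiscordantEdge(a, b, f"discordant mutations {la}/{lb}"))
            continue
        if carriers_ok:
            for sid in (a, b):
                if sid in carriers_ok and not carriers_ok[sid]:
                    flags.append(DiscordantEdge(
                        a, b,
                        f"{sid} lacks the {membership.get(sid)} founder haplotype"))
                    break
    return flags


def drop_flagged(network: LocusNetwork,
                 flags: list[DiscordantEdge],
                 mutation_labels: dict[str, str] | None = None) -> LocusNetwork:
    """Recompute the network with flagged edges excluded (and any node left
    isolated omitted)."""
    bad = {(f.sample_a, f.sample_b) for f in flags}
    bad |= {(b, a) for a, b in bad}
    edges = {(a, b): d["segments"]
             for a, b, d in network.graph.edges(data=True)
             if (a, b) not in bad}
    return build_network(edges, mutation_labels)
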