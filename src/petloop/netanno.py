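"""Anchor annotation, loop categorization, motif-orientation classes, and
the enhancer-promoter network with degree statistics and a power-law fit."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .core_io import GenomicInterval, Loop

__all__ = [
    "AnnotationSet",
    "RegulatoryNetwork",
    "PowerLawFit",
    "build_annotation",
    "classify_loop",
    "ctcf_orientation",
    "build_network",
    "fit_powerlaw",
]

PROMOTER_TSS_DIST = 2000
MERGE_GAP = 100


def _merge_intervals(
    ivs: Sequence[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is < ``gap`` (0 merges overlapping and
    bookended intervals, matching bedtools merge defaults)."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.chrom, v.start, v.end)):
        if out and out[-1].chrom == iv.chrom and iv.start - out[-1].end <= gap:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


@dataclass
class AnnotationSet:
    promoters: list[GenomicInterval]
    enhancers: list[GenomicInterval]


def build_annotation(
    raw_regions: Sequence[GenomicInterval],
    tss: Sequence[GenomicInterval],
) -> AnnotationSet:
    """Merge raw regions, label each promoter iff it lies within 2 kb of a
    TSS (else enhancer), then re-merge same-label neighbors closer than
    100 bp."""
    merged = _merge_intervals(raw_regions, gap=0)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for t in tss:
        tss_by_chrom.setdefault(t.chrom, [])
    grouped: dict[str, list[int]] = {}
    for t in tss:
        grouped.setdefault(t.chrom, []).append(t.start)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in grouped.items()}

    def near_tss(iv: GenomicInterval) -> bool:
        pos = tss_by_chrom.get(iv.chrom)
        if pos is None or pos.size == 0:
            return False
        k = np.searchsorted(pos, iv.start)
        for idx in (k - 1, k, k + 1):
            if 0 <= idx < pos.size:
                t = pos[idx]
                if iv.start - PROMOTER_TSS_DIST <= t <= iv.end + PROMOTER_TSS_DIST:
                    return True
        return False

    promoters = [iv for iv in merged if near_tss(iv)]
    enhancers = [iv for iv in merged if not near_tss(iv)]
    return AnnotationSet(
        promoters=_merge_intervals(promoters, gap=MERGE_GAP - 1),
        enhancers=_merge_intervals(enhancers, gap=MERGE_GAP - 1),
    )


def _best_element(
    anchor: GenomicInterval, elements: Sequence[GenomicInterval]
) -> GenomicInterval | None:
    """Largest-overlap element hit by the anchor, or None."""
    best, best_ov = None, 0
    for el in elements:
        if not el.overlaps(anchor):
            continue
        ov = min(el.end, anchor.end) - max(el.start, anchor.start)
        if ov > best_ov:
            best, best_ov = el, ov
    return best


def _anchor_label(anchor: GenomicInterval, ann: AnnotationSet) -> str:
    if _best_element(anchor, ann.promoters) is not None:
        return "P"
    if _best_element(anchor, ann.enhancers) is not None:
        return "E"
    return "other"


_PAIR_ORDER = {"P": 0, "E": 1, "other": 2}


def classify_loop(loop: Loop, ann: AnnotationSet) -> str:
    """Unordered anchor-pair category; each anchor labeled with priority
    promoter > enhancer > other."""
    a = _anchor_label(loop.anchor_left, ann)
    b = _anchor_label(loop.anchor_right, ann)
    a, b = sorted((a, b), key=_PAIR_ORDER.get)
    return f"{a}-{b}"


def ctcf_orientation(
    loop: Loop,
    motifs: Sequence[tuple[GenomicInterval, str, float, str]],
) -> str:
    """Loop class from the strands of each anchor's strongest overlapping
    motif: convergent (+/-), divergent (-/+), tandem (same), single, none."""

    def anchor_strand(anchor: GenomicInterval) -> str | None:
        best_strand, best_score = None, -np.inf
        for iv, _name, score, strand in motifs:
            if iv.overlaps(anchor) and score > best_score:
                best_strand, best_score = strand, score
        return best_strand

    s_left = anchor_strand(loop.anchor_left)
    s_right = anchor_strand(loop.anchor_right)
    if s_left is None and s_right is None:
        return "none"
    if s_left is None or s_right is None:
        return "single"
    if s_left == "+" and s_right == "-":
        return "convergent"
    if s_left == "-" and s_right == "+":
        return "divergent"
    return "tandem"


@dataclass
class RegulatoryNetwork:
    graph: nx.Graph

    @property
    def degree_sequence(self) -> list[int]:
        return [d for _, d in self.graph.degree()]

    @property
    def components(self) -> list[set]:
        return sorted(nx.connected_components(self.graph), key=len, reverse=True)

    def largest_component(self) -> nx.Graph:
        comps = self.components
        if not comps:
            return nx.Graph()
        return self.graph.subgraph(comps[0]).copy()


def _element_id(kind: str, iv: GenomicInterval) -> str:
    return f"{kind}:{iv.chrom}:{iv.start}-{iv.end}"


def build_network(
    loops: Sequence[Loop], ann: AnnotationSet
) -> RegulatoryNetwork:
    """Undirected network of annotated elements linked by E/P loops.

    Anchors map to elements with promoter > enhancer priority and
    largest-overlap tie-breaking; loops with an unannotated anchor are
    skipped.  Parallel loops collapse onto one edge with a weight."""
    g = nx.Graph()
    for lp in loops:
        nodes = []
        for anchor in (lp.anchor_left, lp.anchor_right):
            el = _best_element(anchor, ann.promoters)
            kind = "P"
            if el is None:
                el = _best_element(anchor, ann.enhancers)
                kind = "E"
            if el is None:
                nodes = []
                break
            nodes.append((kind, el))
        if len(nodes) != 2:
            continue
        ids = []
        for kind, el in nodes:
            nid = _element_id(kind, el)
            g.add_node(nid, kind=kind, chrom=el.chrom, start=el.start, end=el.end)
            ids.append(nid)
        if ids[0] == ids[1]:
            continue
        if g.has_edge(*ids):
            g[ids[0]][ids[1]]["weight"] += 1
        else:
            g.add_edge(*ids, weight=1)
    return RegulatoryNetwork(g)


@dataclass
class PowerLawFit:
    gamma: float
    r_squared: float
    n_points: int
    poor_fit: bool


def fit_powerlaw(degrees: Sequence[int], r2_floor: float = 0.5) -> PowerLawFit:
    """Binned log-log least-squares fit of the degree distribution.

    Degrees are histogrammed into logarithmically spaced bins and gamma is
    minus the OLS slope of log10(count density) on log10(degree) over
    occupied bins — per-degree counts would let the long tail of singleton
    degrees flatten the fit.  Fewer than 3 distinct degrees is an error and
    a fit with r^2 below ``r2_floor`` is flagged poor."""
    deg = np.asarray([d for d in degrees if d >= 1], dtype=np.int64)
    values, _counts = np.unique(deg, return_counts=True)
    if values.size < 3:
        raise ValueError(
            f"need >= 3 distinct degrees, got {values.size}"
        )
    edges = np.unique(
        np.round(np.logspace(0, np.log10(deg.max() + 1), 12)).astype(int)
    )
    hist, _ = np.histogram(deg, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * np.maximum(edges[1:] - 1, 1))
    ok = hist > 0
    if ok.sum() < 3:
        raise ValueError("need >= 3 occupied degree bins")
    lx = np.log10(centers[ok].astype(float))
    ly = np.log10(hist[ok] / widths[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PowerLawFit(
        gamma=float(-slope),
        r_squared=r2,
        n_points=int(values.size),
        poor_fit=r2 < r2_floor,
    )
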