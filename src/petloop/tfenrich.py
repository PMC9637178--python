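"""Transcription-factor loop-anchor association.

Binary anchor-by-factor binding matrices are built for true loop anchors and
for flanking false-loop backgrounds; per factor, three attributes
(left/right co-binding consistency, anchors co-binding ratio, peak overlap
ratio) are compared against the background, filtered by fixed cutoffs, and
validated with a column-shuffle permutation FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GenomicInterval, Loop

__all__ = [
    "TFEnrichmentRecord",
    "build_background_regions",
    "build_binding_matrix",
    "anchors_consistency",
    "phi_coefficient",
    "score_factors",
    "permutation_fdr",
    "rank_report",
    "tf_enrich_pipeline",
]

BG_STEPS = 3
RATIO_FLOOR = 1e-6
FDR_CUT = 0.001


def build_background_regions(
    loops: Sequence[Loop],
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """False loops: three anchor-width windows stepping upstream of the left
    anchor paired (by step) with three stepping downstream of the right
    anchor.  Pairs with a region overlapping any true anchor, or running past
    the chromosome start, are dropped."""
    anchors = _SortedPeaks(
        [a for lp in loops for a in (lp.anchor_left, lp.anchor_right)]
    )

    def hits_anchor(iv: GenomicInterval) -> bool:
        return anchors.overlaps(iv)

    out = []
    for lp in loops:
        w_l = lp.anchor_left.length
        w_r = lp.anchor_right.length
        for k in range(1, BG_STEPS + 1):
            if lp.anchor_left.start - k * w_l < 0:
                continue
            left_bg = lp.anchor_left.shift(-k * w_l)
            right_bg = lp.anchor_right.shift(k * w_r)
            if hits_anchor(left_bg) or hits_anchor(right_bg):
                continue
            out.append((left_bg, right_bg))
    return out


class _SortedPeaks:
    """Sorted-by-start peaks with a prefix-max of ends for O(log n) overlap."""

    def __init__(self, peaks: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            grouped.setdefault(p.chrom, []).append((p.start, p.end))
        for chrom, rows in grouped.items():
            arr = np.asarray(sorted(rows), dtype=np.int64)
            self.by_chrom[chrom] = (
                arr[:, 0],
                np.maximum.accumulate(arr[:, 1]),
            )

    def overlaps(self, iv: GenomicInterval) -> bool:
        entry = self.by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, maxends = entry
        k = np.searchsorted(starts, iv.end, side="left")
        return bool(k > 0 and maxends[k - 1] > iv.start)


def build_binding_matrix(
    regions: Sequence[GenomicInterval],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
) -> pd.DataFrame:
    """Binary region x factor matrix: 1 iff the region overlaps >= 1 peak."""
    data = {}
    for factor, peaks in peak_sets.items():
        sp = _SortedPeaks(peaks)
        data[factor] = np.array(
            [int(sp.overlaps(r)) for r in regions], dtype=np.int8
        )
    return pd.DataFrame(data, index=range(len(regions)))


def phi_coefficient(a: np.ndarray, b: np.ndarray) -> float | None:
    """Phi (Pearson on 0/1 vectors); None when either vector is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = a.size
    n1a, n1b = a.sum(), b.sum()
    denom = n1a * (n - n1a) * n1b * (n - n1b)
    if denom == 0:
        return None
    n11 = float(a @ b)
    return float((n * n11 - n1a * n1b) / np.sqrt(denom))


def anchors_consistency(
    left_col: np.ndarray, right_col: np.ndarray
) -> float | None:
    """Rank correlation of the paired binary binding vectors.

    On binary data this equals the phi coefficient; a constant vector makes
    it undefined (None), reported downstream as not-passing.
    """
    left_col = np.asarray(left_col)
    right_col = np.asarray(right_col)
    if left_col.size != right_col.size or left_col.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.ptp(left_col) == 0 or np.ptp(right_col) == 0:
        return None
    rho, _ = stats.spearmanr(left_col, right_col)
    return float(rho)


@dataclass
class TFEnrichmentRecord:
    factor: str
    consistency: float | None
    cobind_ratio: float
    peak_overlap_ratio: float
    bg_consistency: float | None
    bg_cobind_ratio: float
    bg_peak_overlap_ratio: float
    consistency_fg_bg: float | None
    cobind_fg_bg: float
    peak_overlap_fg_bg: float
    fdr_perm: float | None = None
    passed: bool = False
    degenerate_background: bool = False


def _peak_overlap_ratio(
    peaks: Sequence[GenomicInterval], regions: Sequence[GenomicInterval]
) -> float:
    if not peaks:
        return 0.0
    sp = _SortedPeaks(regions)
    return sum(sp.overlaps(p) for p in peaks) / len(peaks)


def score_factors(
    true_left: pd.DataFrame,
    true_right: pd.DataFrame,
    bg_left: pd.DataFrame,
    bg_right: pd.DataFrame,
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    true_anchors: Sequence[GenomicInterval],
    bg_regions: Sequence[GenomicInterval],
    floor: float = RATIO_FLOOR,
) -> list[TFEnrichmentRecord]:
    """Per-factor attributes on true loops vs flanking background, plus the
    four-rule filter: consistency ratio > 2, co-binding ratio > 0.1,
    co-binding fg/bg > 2, peak-overlap fg/bg >= 1."""
    records = []
    for factor in true_left.columns:
        tl = true_left[factor].to_numpy()
        tr = true_right[factor].to_numpy()
        bl = bg_left[factor].to_numpy()
        br = bg_right[factor].to_numpy()
        cons = anchors_consistency(tl, tr)
        bg_cons = anchors_consistency(bl, br)
        cobind = float((tl & tr).mean())
        bg_cobind = float((bl & br).mean()) if bl.size else 0.0
        pov = _peak_overlap_ratio(peak_sets[factor], true_anchors)
        bg_pov = _peak_overlap_ratio(peak_sets[factor], bg_regions)
        degenerate = bg_cons is None or bg_cobind <= floor
        cons_ratio = (
            None if cons is None else cons / max(bg_cons or 0.0, floor)
        )
        cobind_ratio_fb = cobind / max(bg_cobind, floor)
        pov_ratio = pov / max(bg_pov, floor)
        passed = (
            cons is not None
            and cons_ratio is not None
            and cons_ratio > 2
            and cobind > 0.1
            and cobind_ratio_fb > 2
            and pov_ratio >= 1
        )
        records.append(
            TFEnrichmentRecord(
                factor=factor,
                consistency=cons,
                cobind_ratio=cobind,
                peak_overlap_ratio=pov,
                bg_consistency=bg_cons,
                bg_cobind_ratio=bg_cobind,
                bg_peak_overlap_ratio=bg_pov,
                consistency_fg_bg=cons_ratio,
                cobind_fg_bg=cobind_ratio_fb,
                peak_overlap_fg_bg=pov_ratio,
                passed=passed,
                degenerate_background=degenerate,
            )
        )
    return records


def permutation_fdr(
    true_left: pd.DataFrame,
    true_right: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Column-shuffle permutation FDR per factor.

    Each shuffle permutes a factor's left and right binding columns across
    rows independently (preserving marginal binding frequencies);
    fdr = fraction of shuffles whose attribute >= the observed one.  Columns:
    ``consistency`` and ``cobind_ratio``.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    n = len(true_left)
    for factor in true_left.columns:
        tl = true_left[factor].to_numpy().astype(np.int64)
        tr = true_right[factor].to_numpy().astype(np.int64)
        obs_cons = phi_coefficient(tl, tr)
        obs_cobind = float((tl & tr).mean())
        n1a, n1b = tl.sum(), tr.sum()
        denom = n1a * (n - n1a) * n1b * (n - n1b)
        ge_cons = 0
        ge_cobind = 0
        for _ in range(n_shuffles):
            pl = rng.permutation(tl)
            pr = rng.permutation(tr)
            n11 = int(pl @ pr)
            if denom > 0:
                phi = (n * n11 - n1a * n1b) / np.sqrt(denom)
                if obs_cons is not None and phi >= obs_cons:
                    ge_cons += 1
            if n11 / n >= obs_cobind:
                ge_cobind += 1
        rows[factor] = {
            "consistency": (
                ge_cons / n_shuffles if obs_cons is not None else np.nan
            ),
            "cobind_ratio": ge_cobind / n_shuffles,
        }
    return pd.DataFrame(rows).T


def rank_report(records: Sequence[TFEnrichmentRecord]) -> pd.DataFrame:
    """Full attribute table: passing factors first, consistency descending,
    ties broken by co-binding ratio descending."""
    rows = []
    for r in records:
        rows.append(
            {
                "factor": r.factor,
                "passed": r.passed,
                "consistency": r.consistency,
                "cobind_ratio": r.cobind_ratio,
                "peak_overlap_ratio": r.peak_overlap_ratio,
                "bg_consistency": r.bg_consistency,
                "bg_cobind_ratio": r.bg_cobind_ratio,
                "bg_peak_overlap_ratio": r.bg_peak_overlap_ratio,
                "consistency_fg_bg": r.consistency_fg_bg,
                "cobind_fg_bg": r.cobind_fg_bg,
                "peak_overlap_fg_bg": r.peak_overlap_fg_bg,
                "fdr_perm": r.fdr_perm,
                "degenerate_background": r.degenerate_background,
            }
        )
    df = pd.DataFrame(rows)
    df["_cons"] = df["consistency"].fillna(-np.inf)
    df = df.sort_values(
        by=["passed", "_cons", "cobind_ratio"],
        ascending=[False, False, False],
        kind="stable",
    ).drop(columns="_cons")
    return df.reset_index(drop=True)


def tf_enrich_pipeline(
    loops: Sequence[Loop],
    peak_sets: Mapping[str, Sequence[GenomicInterval]],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[list[TFEnrichmentRecord], pd.DataFrame]:
    """End-to-end factor enrichment: matrices, attributes, shuffle FDR.

    A factor passes only if it clears the four-rule filter and its
    consistency permutation FDR is < 0.001.
    """
    left_anchors = [lp.anchor_left for lp in loops]
    right_anchors = [lp.anchor_right for lp in loops]
    bg_pairs = build_background_regions(loops)
    bg_lefts = [p[0] for p in bg_pairs]
    bg_rights = [p[1] for p in bg_pairs]
    true_left = build_binding_matrix(left_anchors, peak_sets)
    true_right = build_binding_matrix(right_anchors, peak_sets)
    bg_left = build_binding_matrix(bg_lefts, peak_sets)
    bg_right = build_binding_matrix(bg_rights, peak_sets)
    records = score_factors(
        true_left,
        true_right,
        bg_left,
        bg_right,
        peak_sets,
        left_anchors + right_anchors,
        bg_lefts + bg_rights,
    )
    fdr = permutation_fdr(true_left, true_right, n_shuffles, seed)
    for r in records:
        val = fdr.loc[r.factor, "consistency"]
        r.fdr_perm = None if np.isnan(val) else float(val)
        if r.fdr_perm is None or r.fdr_perm >= FDR_CUT:
            r.passed = False
    return records, rank_report(records)
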