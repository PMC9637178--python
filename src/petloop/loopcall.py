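"""Density-based loop discovery over PET 2D coordinates.

Candidate loops come from DBSCAN clustering of (left-mid, right-mid) points
at several eps values; each candidate is assessed against locally permuted
background windows with a Poisson upper-tail test, candidates from different
eps runs are merged when both anchor pairs overlap, and the surviving loops
are filtered on support, Bonferroni-corrected p-value and enrichment score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core_io import GenomicInterval, Loop, PETIndex

__all__ = [
    "ClusterParams",
    "CandidateLoop",
    "SignificanceResult",
    "dbscan2d",
    "call_candidates",
    "background_windows",
    "test_candidate",
    "call_loops",
    "estimate_max_cut",
    "estimate_resolution",
    "overlap_loops",
]


@dataclass(frozen=True)
class ClusterParams:
    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be > 0")
        if self.min_pts < 2:
            raise ValueError("minPts must be >= 2")


@dataclass
class SignificanceResult:
    n_obs: int
    bg_counts: np.ndarray
    lam: float
    p_value: float
    enrichment_score: float


@dataclass
class CandidateLoop:
    anchor_left: GenomicInterval
    anchor_right: GenomicInterval
    member_count: int
    eps: float
    significance: SignificanceResult | None = None


def dbscan2d(
    x: np.ndarray, y: np.ndarray, eps: float, min_pts: int
) -> np.ndarray:
    """Grid-bucketed DBSCAN with Euclidean distance on integer 2D points.

    Semantics match the textbook algorithm run over points pre-sorted by
    (x, y): a core point has >= min_pts neighbors within eps (self included),
    clusters are expanded one at a time in scan order, and border points get
    the label of the first cluster that reaches them.  Noise is -1.
    Equivalence with a naive O(n^2) implementation is pinned by tests.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n = x.shape[0]
    labels_out = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return labels_out
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]

    cell = max(1, int(math.floor(eps)))
    cx = xs // cell
    cy = ys // cell
    buckets: dict[tuple[int, int], list[int]] = {}
    for i in range(n):
        buckets.setdefault((int(cx[i]), int(cy[i])), []).append(i)
    bucket_arr = {k: np.asarray(v, dtype=np.int64) for k, v in buckets.items()}

    eps2 = float(eps) * float(eps)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    counts = np.zeros(n, dtype=np.int64)
    for (bx, by), members in bucket_arr.items():
        cand_parts = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                nb = bucket_arr.get((bx + dx, by + dy))
                if nb is not None:
                    cand_parts.append(nb)
        cand = np.concatenate(cand_parts)
        ddx = xs[members, None] - xs[cand][None, :]
        ddy = ys[members, None] - ys[cand][None, :]
        hit = (ddx * ddx + ddy * ddy) <= eps2
        counts[members] = hit.sum(axis=1)
        mi, ci = np.nonzero(hit)
        rows.append(members[mi])
        cols.append(cand[ci])
    ii = np.concatenate(rows)
    jj = np.concatenate(cols)
    srt = np.argsort(ii, kind="stable")
    jj = jj[srt]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(np.bincount(ii, minlength=n), out=indptr[1:])

    core = counts >= min_pts
    labels = np.full(n, -1, dtype=np.int64)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            p = stack.pop()
            for q in jj[indptr[p] : indptr[p + 1]]:
                if labels[q] == -1:
                    labels[q] = cid
                    if core[q]:
                        stack.append(int(q))
        cid += 1
    labels_out[order] = labels
    return labels_out


def estimate_max_cut(distances: np.ndarray, slope_cut: float = -0.5) -> int:
    """Distance where the log-log decay of PET distances flattens.

    Builds a log10 histogram of distances, converts it to a per-bp density,
    and returns the smallest distance at which the local log-log slope of the
    density exceeds ``slope_cut``; if the decay never flattens, the maximum
    observed distance is returned.
    """
    d = np.asarray(distances, dtype=np.float64)
    d = d[d > 0]
    if d.size < 100:
        return int(d.max()) if d.size else 0
    lo, hi = np.log10(d.min()), np.log10(d.max())
    # 0.125-decade bins: narrow enough to localize the flattening point,
    # wide enough that adjacent-bin slopes are not noise-dominated
    edges = np.arange(lo, hi + 0.125, 0.125)
    counts, _ = np.histogram(np.log10(d), bins=edges)
    widths_bp = 10 ** edges[1:] - 10 ** edges[:-1]
    centers = (edges[:-1] + edges[1:]) / 2
    ok = counts > 0
    logd = centers[ok]
    logrho = np.log10(counts[ok] / widths_bp[ok])
    for k in range(1, logd.size):
        slope = (logrho[k] - logrho[k - 1]) / (logd[k] - logd[k - 1])
        if slope > slope_cut:
            return int(round(10 ** logd[k]))
    return int(d.max())


def call_candidates(
    index: PETIndex,
    eps_list: Sequence[float],
    min_pts: int,
    cut: int = 0,
    max_cut: int | None = None,
) -> list[CandidateLoop]:
    """Cluster distance-filtered PETs per eps; bounding boxes of clusters
    become candidate loops.  Clusters whose anchors overlap after extension
    by eps (diagonal straddlers) are discarded."""
    if not eps_list:
        raise ValueError("eps_list must be non-empty")
    eps_sorted = sorted(eps_list)
    out: list[CandidateLoop] = []
    for chrom in index.chromosomes():
        x, y = index.points(chrom)
        if x.size == 0:
            continue
        d = y - x
        mask = d >= cut
        if max_cut is not None:
            mask &= d <= max_cut
        xs, ys = x[mask], y[mask]
        if xs.size == 0:
            continue
        for eps in eps_sorted:
            labels = dbscan2d(xs, ys, eps, min_pts)
            for lab in np.unique(labels):
                if lab < 0:
                    continue
                sel = labels == lab
                cx, cy = xs[sel], ys[sel]
                left = GenomicInterval(chrom, int(cx.min()), int(cx.max()) + 1)
                right = GenomicInterval(chrom, int(cy.min()), int(cy.max()) + 1)
                # diagonal guard: a genuine loop is focal, with anchors far
                # apart relative to both eps and their own widths; clusters
                # reaching the diagonal within that scale are self-ligation /
                # distance-decay artifacts
                guard = max(int(eps), left.length, right.length)
                if left.expand(guard).overlaps(right.expand(guard)):
                    continue
                out.append(
                    CandidateLoop(left, right, int(sel.sum()), float(eps))
                )
    return out


def background_windows(
    anchor_left: GenomicInterval,
    anchor_right: GenomicInterval,
    n_shifts: int = 5,
) -> list[tuple[GenomicInterval, GenomicInterval]]:
    """All (i, j)-shifted window pairs, i, j in {-n..n} \\ {(0, 0)}.

    The shift step along each axis is the corresponding anchor's own width.
    Windows running past the chromosome start, overlapping the candidate
    rectangle, or crossing the diagonal (x window not strictly left of the
    y window) are dropped.
    """
    return [
        (wx, wy)
        for _i, _j, wx, wy in _shifted_windows(
            anchor_left, anchor_right, n_shifts
        )
    ]


def _shifted_windows(
    anchor_left: GenomicInterval,
    anchor_right: GenomicInterval,
    n_shifts: int,
) -> list[tuple[int, int, GenomicInterval, GenomicInterval]]:
    w_x, w_y = anchor_left.length, anchor_right.length
    wins = []
    for i in range(-n_shifts, n_shifts + 1):
        for j in range(-n_shifts, n_shifts + 1):
            if i == 0 and j == 0:
                continue
            sx = anchor_left.start + i * w_x
            sy = anchor_right.start + j * w_y
            if sx < 0 or sy < 0:
                continue
            win_x = GenomicInterval(anchor_left.chrom, sx, sx + w_x)
            win_y = GenomicInterval(anchor_right.chrom, sy, sy + w_y)
            if win_x.end > win_y.start:
                continue
            if win_x.overlaps(anchor_left) and win_y.overlaps(anchor_right):
                continue
            wins.append((i, j, win_x, win_y))
    return wins


def test_candidate(
    index: PETIndex,
    cand: CandidateLoop,
    n_shifts: int = 5,
    pseudo: float = 1.0,
) -> SignificanceResult | None:
    """Poisson upper-tail test of a candidate against shifted backgrounds.

    The Poisson rate is the largest of several background estimates, floored
    at ``pseudo``: the all-window mean, the same-column and same-row window
    means (vertical / horizontal shifts only), and a marginal expectation
    (PETs sharing the candidate's x or y range, scaled by the chromosome's
    empirical distance-decay fraction over the candidate's distance range).
    The extra estimates protect against 1D stripe artifacts at highly
    covered anchors, where the plain all-window mean badly underestimates
    the local background.  Returns None when no valid background window
    exists (candidate rejected).
    """
    left, right = cand.anchor_left, cand.anchor_right
    n_obs = index.query_rectangle(left, right)
    wins = _shifted_windows(left, right, n_shifts)
    if not wins:
        return None
    counts = np.array(
        [index.query_rectangle(wx, wy) for _i, _j, wx, wy in wins],
        dtype=np.float64,
    )
    col = np.array([c for (i, _j, _wx, _wy), c in zip(wins, counts) if i == 0])
    row = np.array([c for (_i, j, _wx, _wy), c in zip(wins, counts) if j == 0])
    chrom = left.chrom
    xm, ym = left.midpoint, right.midpoint
    p_dist = index.distance_fraction(
        chrom, max(0, right.start - xm), right.end - xm
    )
    p_dist_y = index.distance_fraction(
        chrom, max(0, ym - left.end + 1), max(1, ym - left.start + 1)
    )
    lam_x = index.count_left(chrom, left.start, left.end) * p_dist
    lam_y = index.count_right(chrom, right.start, right.end) * p_dist_y
    lam = max(
        float(counts.mean()),
        float(col.mean()) if col.size else 0.0,
        float(row.mean()) if row.size else 0.0,
        lam_x,
        lam_y,
        pseudo,
    )
    p = float(stats.poisson.sf(n_obs - 1, lam))
    es = n_obs / lam
    res = SignificanceResult(n_obs, counts, lam, p, es)
    cand.significance = res
    return res


def _merge_groups(cands: list[CandidateLoop]) -> list[list[int]]:
    """Union-find grouping: merge candidates whose both anchor pairs overlap."""
    n = len(cands)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = cands[i], cands[j]
            if ci.anchor_left.overlaps(cj.anchor_left) and ci.anchor_right.overlaps(
                cj.anchor_right
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def call_loops(
    index: PETIndex,
    eps_list: Sequence[float] = (200, 500, 1000, 2000),
    min_pts: int = 10,
    cut: int = 0,
    max_cut: int | str | None = None,
    min_pets: int | None = None,
    p_cut: float = 0.01,
    es_cut: float = 2.0,
    n_shifts: int = 5,
    pseudo: float = 1.0,
) -> list[Loop]:
    """Full loop-calling: cluster per eps, test, merge across eps, filter.

    Merged loops take the union extent and the smallest raw p-value of their
    members; support is re-counted on the union extent.  p-values are
    Bonferroni-corrected over all tested candidates.  ``max_cut="auto"``
    estimates the upper distance cutoff from the distance-decay histogram.
    """
    if min_pets is None:
        min_pets = min_pts
    if max_cut == "auto":
        dists = np.concatenate(
            [index.points(c)[1] - index.points(c)[0] for c in index.chromosomes()]
        ) if index.chromosomes() else np.empty(0)
        max_cut = estimate_max_cut(dists) if dists.size else None
    cands = call_candidates(index, eps_list, min_pts, cut, max_cut)
    tested = [c for c in cands if test_candidate(index, c, n_shifts, pseudo)]
    n_tests = len(tested)
    loops: list[Loop] = []
    by_chrom: dict[str, list[CandidateLoop]] = {}
    for c in tested:
        by_chrom.setdefault(c.anchor_left.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chrom_cands = by_chrom[chrom]
        for group in _merge_groups(chrom_cands):
            members = [chrom_cands[i] for i in group]
            left = GenomicInterval(
                chrom,
                min(m.anchor_left.start for m in members),
                max(m.anchor_left.end for m in members),
            )
            right = GenomicInterval(
                chrom,
                min(m.anchor_right.start for m in members),
                max(m.anchor_right.end for m in members),
            )
            best = min(members, key=lambda m: m.significance.p_value)
            p_raw = best.significance.p_value
            es = best.significance.enrichment_score
            pet_count = index.query_rectangle(left, right)
            p_adj = min(1.0, p_raw * n_tests)
            if pet_count < min_pets or p_adj > p_cut or es < es_cut:
                continue
            loops.append(
                Loop(
                    anchor_left=left,
                    anchor_right=right,
                    pet_count=pet_count,
                    p_value=p_adj,
                    enrichment_score=es,
                )
            )
    loops.sort(key=lambda lp: (lp.chrom, lp.anchor_left.start, lp.anchor_right.start))
    for k, lp in enumerate(loops):
        lp.id = f"loop_{k}"
    return loops


def estimate_resolution(
    index: PETIndex, bin_sizes: Sequence[int]
) -> dict[int, float]:
    """Per bin size, the fraction of PETs landing in non-singleton bin pairs."""
    out = {}
    for size in bin_sizes:
        if size <= 0:
            raise ValueError("bin sizes must be positive")
        non_singleton = 0
        total = 0
        for chrom in index.chromosomes():
            x, y = index.points(chrom)
            if x.size == 0:
                continue
            key = (x // size) * (2**32) + (y // size)
            _, inv, counts = np.unique(key, return_inverse=True, return_counts=True)
            non_singleton += int((counts[inv] >= 2).sum())
            total += x.size
        out[int(size)] = non_singleton / total if total else 0.0
    return out


def overlap_loops(
    set_a: Sequence[Loop],
    set_b: Sequence[Loop],
    extension: int = 5000,
) -> tuple[list[Loop], list[Loop], list[Loop]]:
    """Partition loops by matching under anchor extension.

    Loop a matches loop b iff their extended left anchors overlap AND their
    extended right anchors overlap.  Returns (a loops with a match,
    a loops without, b loops without).
    """

    def match(a: Loop, b: Loop) -> bool:
        return a.anchor_left.expand(extension).overlaps(
            b.anchor_left.expand(extension)
        ) and a.anchor_right.expand(extension).overlaps(
            b.anchor_right.expand(extension)
        )

    b_by_chrom: dict[str, list[Loop]] = {}
    for b in set_b:
        b_by_chrom.setdefault(b.chrom, []).append(b)
    both: list[Loop] = []
    a_only: list[Loop] = []
    b_matched: set[int] = set()
    for a in set_a:
        hits = [
            i
            for i, b in enumerate(b_by_chrom.get(a.chrom, []))
            if match(a, b)
        ]
        if hits:
            both.append(a)
            for i in hits:
                b_matched.add(id(b_by_chrom[a.chrom][i]))
        else:
            a_only.append(a)
    b_only = [b for b in set_b if id(b) not in b_matched]
    return both, a_only, b_only
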