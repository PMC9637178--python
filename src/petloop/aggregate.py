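"""Aggregation (APA-style) analysis of loops.

For each loop an 11x11 contact matrix is built from the loop anchors plus
five same-width windows on each side; the per-loop enrichment score is the
center cell over the mean of the other 120 cells, and the global score is
the mean over loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import Loop, PETIndex

__all__ = ["AggMatrix", "AggResult", "loop_matrix", "enrichment_score", "aggregate_loops"]

N_FLANK = 5
N_WIN = 2 * N_FLANK + 1  # 11


@dataclass
class AggMatrix:
    raw: np.ndarray
    normalized: np.ndarray | None
    es: float | None
    partial: bool


def loop_matrix(index: PETIndex, loop: Loop) -> AggMatrix:
    """Build the 11x11 window-pair count matrix centered on ``loop``.

    Matrices whose windows run past the chromosome bounds are flagged
    partial (and excluded from global scores by aggregate_loops).
    """
    chrom = loop.chrom
    w_x = loop.anchor_left.length
    w_y = loop.anchor_right.length
    x_edges = loop.anchor_left.start + w_x * np.arange(-N_FLANK, N_FLANK + 2)
    y_edges = loop.anchor_right.start + w_y * np.arange(-N_FLANK, N_FLANK + 2)
    partial = bool(x_edges[0] < 0 or y_edges[0] < 0)
    size = index.chrom_sizes.get(chrom)
    if size is not None and (x_edges[-1] > size or y_edges[-1] > size):
        partial = True

    x, y = index.points(chrom)
    raw = np.zeros((N_WIN, N_WIN), dtype=np.float64)
    if x.size:
        i0 = np.searchsorted(x, x_edges[0], side="left")
        i1 = np.searchsorted(x, x_edges[-1], side="left")
        xs, ys = x[i0:i1], y[i0:i1]
        keep = (ys >= y_edges[0]) & (ys < y_edges[-1])
        if keep.any():
            raw, _, _ = np.histogram2d(
                xs[keep], ys[keep], bins=[x_edges, y_edges]
            )
    es = enrichment_score(raw)
    total = raw.sum()
    normalized = None
    if total > 0:
        z = raw / total
        sd = z.std()
        normalized = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
    return AggMatrix(raw=raw, normalized=normalized, es=es, partial=partial)


def enrichment_score(m: np.ndarray) -> float | None:
    """Center cell over the mean of the 120 non-center cells; None if that
    mean is zero."""
    m = np.asarray(m, dtype=np.float64)
    if m.shape != (N_WIN, N_WIN):
        raise ValueError(f"expected {N_WIN}x{N_WIN} matrix, got {m.shape}")
    center = m[N_FLANK, N_FLANK]
    others_mean = (m.sum() - center) / (N_WIN * N_WIN - 1)
    if others_mean == 0:
        return None
    return float(center / others_mean)


@dataclass
class AggResult:
    global_es: float
    mean_matrix: np.ndarray
    es_list: list[float | None]
    n_excluded: int


def aggregate_loops(
    index: PETIndex,
    loops: Sequence[Loop],
    loop_norm: bool = True,
    min_window_pets: int | None = None,
) -> AggResult:
    """Global enrichment score and mean (normalized) matrix over loops.

    Loops with partial matrices, undefined scores, or (when
    ``min_window_pets`` is set) too few PETs in the whole 11x11 neighborhood
    are excluded from the global score; the number excluded is reported.
    """
    es_list: list[float | None] = []
    mats = []
    n_excluded = 0
    for lp in loops:
        m = loop_matrix(index, lp)
        if m.partial or m.es is None or (
            min_window_pets is not None and m.raw.sum() <= min_window_pets
        ):
            es_list.append(None)
            n_excluded += 1
            continue
        es_list.append(m.es)
        if loop_norm:
            if m.normalized is not None:
                mats.append(m.normalized)
        else:
            mats.append(m.raw)
    defined = [e for e in es_list if e is not None]
    if not defined:
        raise ValueError("no loop with a defined enrichment score")
    mean_matrix = (
        np.mean(mats, axis=0) if mats else np.zeros((N_WIN, N_WIN))
    )
    return AggResult(
        global_es=float(np.mean(defined)),
        mean_matrix=mean_matrix,
        es_list=es_list,
        n_excluded=n_excluded,
    )
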