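"""Differential loop calling between two conditions.

The union loop set is quantified in both conditions together with the same
shifted background windows used for loop significance.  A linear fit of the
background (log2 scale) maps treatment counts onto the control scale, MA
cutoffs are chosen so that at most an FDR fraction of background points
exceed them, and each loop is assigned a Poisson p-value

    p = 1 - sum_{i=1}^{fg-1} Poisson(i; max(bg, fgNearby, bgNearby, pseudo))

where fg/bg are the larger/smaller transformed loop counts.  Note the sum
starts at i = 1, so p includes the Poisson mass at zero in addition to the
upper tail; ``tail_exact=True`` computes the standard tail instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .core_io import Loop, PETIndex
from .loopcall import background_windows

__all__ = [
    "DiffLoopRecord",
    "MACutoffs",
    "quantify_pair",
    "fit_background",
    "transform_to_control",
    "prepare_records",
    "find_ma_cutoffs",
    "poisson_diff_p",
    "call_diff_loops",
    "diff_pipeline",
]

PSEUDO = 1.0


@dataclass
class DiffLoopRecord:
    loop: Loop
    count_a: float
    count_b: float
    nearby_a: float
    nearby_b: float
    window_counts_a: np.ndarray
    window_counts_b: np.ndarray
    # filled after transform
    count_b_t: float = 0.0
    nearby_b_t: float = 0.0
    fg: float = 0.0
    bg: float = 0.0
    fg_nearby: float = 0.0
    bg_nearby: float = 0.0
    A: float = 0.0
    M: float = 0.0
    p_raw: float | None = None
    p_adj: float | None = None
    call: str = "unchanged"


@dataclass(frozen=True)
class MACutoffs:
    a_cut: float
    m_cut: float
    fdr_target: float


def quantify_pair(
    index_a: PETIndex,
    index_b: PETIndex,
    loops_union: Sequence[Loop],
    n_shifts: int = 5,
) -> list[DiffLoopRecord]:
    """Rectangle counts per loop and per shifted background window in both
    conditions; nearby_* fields are the means over the window set."""
    records = []
    for lp in loops_union:
        wins = background_windows(lp.anchor_left, lp.anchor_right, n_shifts)
        wa = np.array(
            [index_a.query_rectangle(wx, wy) for wx, wy in wins], dtype=float
        )
        wb = np.array(
            [index_b.query_rectangle(wx, wy) for wx, wy in wins], dtype=float
        )
        records.append(
            DiffLoopRecord(
                loop=lp,
                count_a=float(
                    index_a.query_rectangle(lp.anchor_left, lp.anchor_right)
                ),
                count_b=float(
                    index_b.query_rectangle(lp.anchor_left, lp.anchor_right)
                ),
                nearby_a=float(wa.mean()) if wa.size else 0.0,
                nearby_b=float(wb.mean()) if wb.size else 0.0,
                window_counts_a=wa,
                window_counts_b=wb,
            )
        )
    return records


def fit_background(
    nearby_a: np.ndarray, nearby_b: np.ndarray, method: str = "ols"
) -> tuple[float, float]:
    """Linear fit of log2(nearby_b + 1) on log2(nearby_a + 1).

    ``method="ols"`` is ordinary least squares; ``method="rma"`` is the
    symmetric reduced-major-axis fit (slope = sd ratio, sign from the
    correlation), which is robust to sampling noise on both axes — with
    noisy low-count backgrounds OLS attenuates toward zero and the
    exponential back-transform then distorts loop-scale counts badly.
    """
    a = np.asarray(nearby_a, dtype=float)
    b = np.asarray(nearby_b, dtype=float)
    if a.size != b.size:
        raise ValueError("background vectors must have equal length")
    if a.size < 10:
        raise ValueError(f"need >= 10 background points, got {a.size}")
    if method not in ("ols", "rma", "shift"):
        raise ValueError(f"unknown method {method!r}")
    la = np.log2(a + 1.0)
    lb = np.log2(b + 1.0)
    if np.ptp(la) == 0 or np.ptp(lb) == 0:
        warnings.warn("degenerate (constant) background; identity transform")
        return 1.0, 0.0
    if method == "ols":
        slope, intercept = np.polyfit(la, lb, 1)
    elif method == "rma":
        slope = float(np.std(lb) / np.std(la))
        if np.corrcoef(la, lb)[0, 1] < 0:
            slope = -slope
        intercept = float(lb.mean() - slope * la.mean())
    elif method == "shift":
        # depth-shift model: slope pinned at 1, intercept = mean log ratio
        slope = 1.0
        intercept = float(lb.mean() - la.mean())
    return float(slope), float(intercept)


def transform_to_control(
    x: np.ndarray | float, slope: float, intercept: float
) -> np.ndarray | float:
    """Map treatment-scale counts onto the control scale.

    The background fit gives log2(b+1) ~ slope * log2(a+1) + intercept, so a
    treatment count is transformed with the inverse map
    2^((log2(x+1) - intercept) / slope) - 1.  A non-positive slope falls back
    to the identity with a warning.
    """
    if slope <= 0:
        warnings.warn("non-positive background slope; identity transform")
        return x
    t = np.power(2.0, (np.log2(np.asarray(x, dtype=float) + 1.0) - intercept) / slope) - 1.0
    t = np.maximum(t, 0.0)
    return float(t) if np.isscalar(x) or np.ndim(x) == 0 else t


def prepare_records(
    records: Sequence[DiffLoopRecord], slope: float, intercept: float
) -> None:
    """Transform condition-B counts to the control scale and fill fg/bg,
    A and M (M = transformed treatment minus control, log2) in place."""
    for r in records:
        r.count_b_t = float(transform_to_control(r.count_b, slope, intercept))
        r.nearby_b_t = float(transform_to_control(r.nearby_b, slope, intercept))
        la = math.log2(r.count_a + 1.0)
        lb = math.log2(r.count_b_t + 1.0)
        r.A = (la + lb) / 2.0
        r.M = lb - la
        if r.count_b_t >= r.count_a:
            r.fg, r.bg = r.count_b_t, r.count_a
            r.fg_nearby, r.bg_nearby = r.nearby_b_t, r.nearby_a
        else:
            r.fg, r.bg = r.count_a, r.count_b_t
            r.fg_nearby, r.bg_nearby = r.nearby_a, r.nearby_b_t


def find_ma_cutoffs(
    a_bg: np.ndarray,
    m_bg: np.ndarray,
    fdr: float = 0.05,
    n_grid: int = 501,
) -> MACutoffs:
    """Smallest symmetric-quantile cutoffs (a, m) on the background MA cloud
    such that the fraction of background points with A >= a and |M| >= m is
    at most ``fdr``.  fdr >= 1 returns (0, 0); fdr = 0 returns cutoffs just
    beyond the background extremes."""
    A = np.asarray(a_bg, dtype=float)
    M = np.abs(np.asarray(m_bg, dtype=float))
    if A.size != M.size or A.size == 0:
        raise ValueError("background A/M vectors must be equal-length, non-empty")
    if fdr >= 1.0:
        return MACutoffs(0.0, 0.0, fdr)
    n = A.size
    for q in np.linspace(0.0, 1.0, n_grid):
        a = float(np.quantile(A, q))
        m = float(np.quantile(M, q))
        frac = float(np.count_nonzero((A >= a) & (M >= m))) / n
        if frac <= fdr:
            return MACutoffs(a, m, fdr)
    eps = 1e-9
    return MACutoffs(float(A.max()) + eps, float(M.max()) + eps, fdr)


def poisson_diff_p(
    fg: float,
    bg: float,
    fg_nearby: float,
    bg_nearby: float,
    pseudo: float = PSEUDO,
    tail_exact: bool = False,
) -> float:
    """p = 1 - sum_{i=1}^{fg-1} Poisson(i; lambda) with
    lambda = max(bg, fgNearby, bgNearby, pseudo); inputs are floored to
    integers first.  fg <= 1 gives an empty sum, hence p = 1."""
    for name, v in (("fg", fg), ("bg", bg), ("fgNearby", fg_nearby), ("bgNearby", bg_nearby)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    fgi = int(math.floor(fg))
    lam = max(
        float(math.floor(bg)),
        float(math.floor(fg_nearby)),
        float(math.floor(bg_nearby)),
        float(pseudo),
    )
    if fgi <= 1:
        return 1.0
    tail = float(stats.poisson.sf(fgi - 1, lam))
    if tail_exact:
        return min(1.0, tail)
    return min(1.0, tail + float(stats.poisson.pmf(0, lam)))


def call_diff_loops(
    records: Sequence[DiffLoopRecord],
    cutoffs: MACutoffs,
    p_cut: float = 0.01,
    correct: bool = True,
    tail_exact: bool = False,
) -> list[DiffLoopRecord]:
    """Assign p-values and significance calls to prepared records.

    A loop is significant iff A >= a_cut, |M| >= m_cut, and the (Bonferroni
    adjusted, unless ``correct`` is False) p-value is <= p_cut.  Direction
    follows the sign of M (positive = enriched in condition B)."""
    n = len(records)
    for r in records:
        r.p_raw = poisson_diff_p(
            r.fg, r.bg, r.fg_nearby, r.bg_nearby, tail_exact=tail_exact
        )
        r.p_adj = min(1.0, r.p_raw * n) if correct else r.p_raw
        sig = (
            r.A >= cutoffs.a_cut
            and abs(r.M) >= cutoffs.m_cut
            and r.M != 0.0
            and r.p_adj <= p_cut
        )
        if sig:
            r.call = "enriched_in_B" if r.M > 0 else "enriched_in_A"
        else:
            r.call = "unchanged"
    return list(records)


def diff_pipeline(
    index_a: PETIndex,
    index_b: PETIndex,
    loops_union: Sequence[Loop],
    fdr: float = 0.05,
    p_cut: float = 0.01,
    correct: bool = True,
    n_shifts: int = 5,
    tail_exact: bool = False,
) -> tuple[list[DiffLoopRecord], MACutoffs, tuple[float, float]]:
    """Quantify, fit background, find MA cutoffs, and call differential loops.

    The transform is a depth-shift fit on the pooled per-window background
    pairs: with zero-inflated low-count windows, free-slope estimates (OLS
    or sd-ratio) carry enough sampling error that the exponential
    back-transform distorts loop-scale counts, while the intercept (the
    library depth ratio) is what the data identify.  The MA cutoffs are
    computed on the per-loop background aggregates (window sums), whose
    counts are comparable to loop counts, so their spread sets a meaningful
    fold-change floor at the scale where loops are tested.
    """
    records = quantify_pair(index_a, index_b, loops_union, n_shifts)
    wa = np.concatenate([r.window_counts_a for r in records]) if records else np.empty(0)
    wb = np.concatenate([r.window_counts_b for r in records]) if records else np.empty(0)
    slope, intercept = fit_background(wa, wb, method="shift")
    prepare_records(records, slope, intercept)
    sum_a = np.array([r.window_counts_a.sum() for r in records], dtype=float)
    sum_b = np.array([r.window_counts_b.sum() for r in records], dtype=float)
    sum_b_t = np.asarray(
        transform_to_control(sum_b, slope, intercept), dtype=float
    )
    la, lb = np.log2(sum_a + 1.0), np.log2(sum_b_t + 1.0)
    cutoffs = find_ma_cutoffs((la + lb) / 2.0, lb - la, fdr)
    call_diff_loops(records, cutoffs, p_cut, correct, tail_exact)
    return records, cutoffs, (slope, intercept)
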