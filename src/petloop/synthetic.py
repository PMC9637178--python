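"""Synthetic PET datasets with companion truth tables.

Generates intra-chromosomal PETs with planted anchor-pair loops on
accessible peaks, a truncated power-law distance-decay background biased
toward peaks, PCR duplicates, linker flags, TF peak sets with controllable
anchor co-binding, and an optional second condition with per-loop fold
changes.  Structural randomness (peak/loop placement, loop strengths, TF
binding) derives from ``seed``; PET sampling noise derives from
``noise_seed`` so two draws of the same structure can serve as a null pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import GenomicInterval, Loop, PET, write_bedpe
from .preprocess import LINKER
from .tfenrich import build_background_regions

__all__ = [
    "TFSpec",
    "SimConfig",
    "TruthTable",
    "SimResult",
    "simulate_dataset",
    "write_dataset",
    "background_distance_check",
    "simulate_reads",
    "reference_config",
]


@dataclass(frozen=True)
class TFSpec:
    name: str
    p_cobind_true: float
    p_bind_background: float

    def __post_init__(self) -> None:
        for p in (self.p_cobind_true, self.p_bind_background):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    chrom: str = "chrS"
    chrom_length: int = 10_000_000
    n_peaks: int = 300
    peak_width: int = 1000
    n_loops: int = 50
    pets_per_loop: tuple[int, int] = (25, 80)
    anchor_sigma: float = 150.0
    n_background_pets: int = 200_000
    decay_alpha: float = 1.0
    d_min: int = 1000
    dup_rate: float = 0.0
    linker_rate: float = 1.0
    peak_bias: float = 0.7
    tf_specs: tuple[TFSpec, ...] = ()
    fold_changes: tuple[float, ...] | None = None  # per-loop, condition B
    n_tf_background_peaks: int = 500
    min_loop_distance: int = 20_000
    end_width: int = 50
    seed: int = 42
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.decay_alpha <= 0:
            raise ValueError("decay_alpha must be > 0")
        if self.d_min < 1:
            raise ValueError("d_min must be >= 1")
        for p in (self.dup_rate, self.linker_rate, self.peak_bias):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.fold_changes is not None and len(self.fold_changes) != self.n_loops:
            raise ValueError("fold_changes must have one entry per loop")


def reference_config(**overrides) -> SimConfig:
    """The desk-scale reference fixture used throughout the test suite."""
    base = dict(
        chrom_length=10_000_000,
        n_peaks=300,
        peak_width=1000,
        n_loops=50,
        pets_per_loop=(25, 80),
        anchor_sigma=150.0,
        n_background_pets=200_000,
        decay_alpha=1.0,
        d_min=1000,
        seed=42,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class TruthTable:
    loops: list[Loop]  # pet_count = realized condition-A count
    loop_means: np.ndarray
    counts_a: np.ndarray
    counts_b: np.ndarray | None
    fold_changes: np.ndarray | None
    tf_left: dict[str, np.ndarray]
    tf_right: dict[str, np.ndarray]
    n_unique_a: int
    n_emitted_a: int
    background_distances_a: np.ndarray
    n_close_nolinker_a: int  # cis PETs < 1 kb without any linker end


@dataclass
class SimResult:
    config: SimConfig
    pets_a: list[PET]
    pets_b: list[PET] | None
    peaks: list[GenomicInterval]
    tss: list[GenomicInterval]
    tf_peaks: dict[str, list[GenomicInterval]]
    truth: TruthTable


def _sample_powerlaw(
    rng: np.random.Generator, n: int, alpha: float, d_min: float, d_max: float
) -> np.ndarray:
    """Inverse-CDF sampling from density proportional to d^-alpha on
    [d_min, d_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        return d_min * (d_max / d_min) ** u
    a1 = 1.0 - alpha
    return (d_min**a1 + u * (d_max**a1 - d_min**a1)) ** (1.0 / a1)


def _make_end(chrom: str, pos: float, width: int, length: int) -> GenomicInterval:
    half = width // 2
    p = int(round(pos))
    p = min(max(p, half), length - half - 1)
    return GenomicInterval(chrom, p - half, p - half + width)


def _pet(
    cfg: SimConfig,
    rng: np.random.Generator,
    pos1: float,
    pos2: float,
) -> PET:
    e1 = _make_end(cfg.chrom, pos1, cfg.end_width, cfg.chrom_length)
    e2 = _make_end(cfg.chrom, pos2, cfg.end_width, cfg.chrom_length)
    l1 = bool(rng.random() < cfg.linker_rate)
    l2 = bool(rng.random() < cfg.linker_rate)
    return PET.ordered(e1, e2, 30, 30, l1, l2)


def _draw_condition(
    cfg: SimConfig,
    rng: np.random.Generator,
    loop_pairs: list[tuple[int, int]],
    peak_centers: np.ndarray,
    loop_means: np.ndarray,
    folds: np.ndarray | None,
) -> tuple[list[PET], np.ndarray, np.ndarray, int, int, int]:
    """One condition's PETs: planted loop PETs, decay background, duplicates.

    Returns (emitted pets, per-loop realized counts, background distances,
    n_unique, n_emitted, n_close_nolinker).
    """
    unique: list[PET] = []
    seen: set[tuple] = set()
    counts = np.zeros(len(loop_pairs), dtype=np.int64)
    for k, (i, j) in enumerate(loop_pairs):
        mean = loop_means[k] * (folds[k] if folds is not None else 1.0)
        n_k = int(rng.poisson(mean))
        counts[k] = n_k
        cl, cr = peak_centers[i], peak_centers[j]
        for _ in range(n_k):
            # redraw on exact-coordinate collisions so that truth counts
            # stay exact after de-duplication
            for _attempt in range(100):
                p = _pet(
                    cfg,
                    rng,
                    rng.normal(cl, cfg.anchor_sigma),
                    rng.normal(cr, cfg.anchor_sigma),
                )
                if p.key() not in seen:
                    break
            seen.add(p.key())
            unique.append(p)

    # background: left end biased to peaks, distance from truncated power law
    n_bg = cfg.n_background_pets
    on_peak = rng.random(n_bg) < cfg.peak_bias
    lefts = np.where(
        on_peak,
        peak_centers[rng.integers(0, len(peak_centers), n_bg)]
        + rng.uniform(-cfg.peak_width / 2, cfg.peak_width / 2, n_bg),
        rng.uniform(0, cfg.chrom_length, n_bg),
    )
    dists = np.empty(n_bg)
    rights = np.empty(n_bg)
    todo = np.arange(n_bg)
    margin = cfg.end_width
    for _ in range(200):
        if todo.size == 0:
            break
        d = _sample_powerlaw(
            rng, todo.size, cfg.decay_alpha, cfg.d_min, cfg.chrom_length
        )
        r = lefts[todo] + d
        ok = r < cfg.chrom_length - margin
        sel = todo[ok]
        dists[sel] = d[ok]
        rights[sel] = r[ok]
        todo = todo[~ok]
    if todo.size:  # pathological config: clamp the stragglers
        dists[todo] = cfg.d_min
        rights[todo] = lefts[todo] + cfg.d_min
    bg_keep = np.ones(n_bg, dtype=bool)
    for k, (a, b) in enumerate(zip(lefts, rights)):
        p = _pet(cfg, rng, a, b)
        if p.key() in seen:  # drop coordinate collisions (rare)
            bg_keep[k] = False
            continue
        seen.add(p.key())
        unique.append(p)
    dists = dists[bg_keep]

    n_close_nolinker = sum(
        1
        for p in unique
        if p.distance < 1000 and not p.linker_left and not p.linker_right
    )

    emitted = list(unique)
    dup_mask = rng.random(len(unique)) < cfg.dup_rate
    for p, isdup in zip(unique, dup_mask):
        if isdup:
            emitted.append(
                PET(p.left, p.right, p.mapq_left, p.mapq_right,
                    p.linker_left, p.linker_right)
            )
    rng.shuffle(emitted)
    return emitted, counts, dists, len(unique), len(emitted), n_close_nolinker


def simulate_dataset(config: SimConfig) -> SimResult:
    cfg = config
    rng_struct = np.random.default_rng(cfg.seed)
    noise_seed = cfg.seed + 1 if cfg.noise_seed is None else cfg.noise_seed
    rng_noise = np.random.default_rng(noise_seed)

    # peaks: uniform non-overlapping placement
    w = cfg.peak_width
    slack = cfg.chrom_length - cfg.n_peaks * w
    if slack <= 0:
        raise ValueError("peaks do not fit on the chromosome")
    u = np.sort(rng_struct.uniform(0, slack, cfg.n_peaks))
    starts = (u + np.arange(cfg.n_peaks) * w).astype(np.int64)
    peaks = [GenomicInterval(cfg.chrom, int(s), int(s) + w) for s in starts]
    peak_centers = starts + w // 2
    tss = [
        GenomicInterval(cfg.chrom, int(c), int(c) + 1)
        for c in peak_centers[::2]
    ]

    # loops: pairs of distinct peaks at distance >= min_loop_distance; each
    # peak is used as at most one anchor so that per-loop truth (TF binding,
    # counts) is unambiguous
    if 2 * cfg.n_loops > cfg.n_peaks:
        raise ValueError("need n_peaks >= 2 * n_loops for disjoint anchors")
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    attempts = 0
    while len(pairs) < cfg.n_loops:
        attempts += 1
        if attempts > 200_000:
            raise ValueError("cannot place requested loops; relax config")
        i, j = sorted(rng_struct.integers(0, cfg.n_peaks, 2).tolist())
        if i == j or i in used or j in used:
            continue
        if peak_centers[j] - peak_centers[i] < cfg.min_loop_distance:
            continue
        used.update((i, j))
        pairs.append((i, j))
    lo, hi = cfg.pets_per_loop
    loop_means = rng_struct.integers(lo, hi + 1, cfg.n_loops).astype(float)

    folds = (
        np.asarray(cfg.fold_changes, dtype=float)
        if cfg.fold_changes is not None
        else None
    )

    pets_a, counts_a, bg_d_a, n_uniq, n_emit, n_close = _draw_condition(
        cfg, rng_noise, pairs, peak_centers, loop_means, None
    )
    pets_b = counts_b = None
    if folds is not None:
        rng_b = np.random.default_rng(noise_seed + 104729)
        pets_b, counts_b, _, _, _, _ = _draw_condition(
            cfg, rng_b, pairs, peak_centers, loop_means, folds
        )

    truth_loops = [
        Loop(
            anchor_left=peaks[i],
            anchor_right=peaks[j],
            pet_count=int(counts_a[k]),
            id=f"true_{k}",
        )
        for k, (i, j) in enumerate(pairs)
    ]

    # TF peak sets
    tf_peaks: dict[str, list[GenomicInterval]] = {}
    tf_left: dict[str, np.ndarray] = {}
    tf_right: dict[str, np.ndarray] = {}
    if cfg.tf_specs:
        decoys = build_background_regions(truth_loops)
        for spec in cfg.tf_specs:
            co = rng_struct.random(cfg.n_loops) < spec.p_cobind_true
            left = co | (rng_struct.random(cfg.n_loops) < spec.p_bind_background)
            right = co | (rng_struct.random(cfg.n_loops) < spec.p_bind_background)
            peaks_f: list[GenomicInterval] = []
            for k, lp in enumerate(truth_loops):
                if left[k]:
                    peaks_f.append(lp.anchor_left)
                if right[k]:
                    peaks_f.append(lp.anchor_right)
            for lbg, rbg in decoys:
                if rng_struct.random() < spec.p_bind_background:
                    peaks_f.append(lbg)
                if rng_struct.random() < spec.p_bind_background:
                    peaks_f.append(rbg)
            pos = rng_struct.uniform(
                0, cfg.chrom_length - 400, cfg.n_tf_background_peaks
            )
            peaks_f.extend(
                GenomicInterval(cfg.chrom, int(p), int(p) + 300) for p in pos
            )
            tf_peaks[spec.name] = peaks_f
            tf_left[spec.name] = left
            tf_right[spec.name] = right

    truth = TruthTable(
        loops=truth_loops,
        loop_means=loop_means,
        counts_a=counts_a,
        counts_b=counts_b,
        fold_changes=folds,
        tf_left=tf_left,
        tf_right=tf_right,
        n_unique_a=n_uniq,
        n_emitted_a=n_emit,
        background_distances_a=bg_d_a,
        n_close_nolinker_a=n_close,
    )
    return SimResult(
        config=cfg,
        pets_a=pets_a,
        pets_b=pets_b,
        peaks=peaks,
        tss=tss,
        tf_peaks=tf_peaks,
        truth=truth,
    )


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Emit BEDPE/BED/TSV files for a simulated dataset."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["bedpe_a"] = outdir / "condition_a.bedpe"
    write_bedpe(result.pets_a, paths["bedpe_a"])
    if result.pets_b is not None:
        paths["bedpe_b"] = outdir / "condition_b.bedpe"
        write_bedpe(result.pets_b, paths["bedpe_b"])
    paths["peaks"] = outdir / "peaks.bed"
    with open(paths["peaks"], "w") as fh:
        for iv in result.peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    paths["tss"] = outdir / "tss.bed"
    with open(paths["tss"], "w") as fh:
        for iv in result.tss:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    if result.tf_peaks:
        paths["tf_peaks"] = outdir / "tf_peaks.bed"
        with open(paths["tf_peaks"], "w") as fh:
            for name, ivs in result.tf_peaks.items():
                for iv in ivs:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    paths["truth_loops"] = outdir / "truth_loops.tsv"
    with open(paths["truth_loops"], "w") as fh:
        fh.write("id\tchrom\tstart1\tend1\tstart2\tend2\tcount_a\tcount_b\tfold\n")
        t = result.truth
        for k, lp in enumerate(t.loops):
            cb = "" if t.counts_b is None else str(int(t.counts_b[k]))
            fold = "" if t.fold_changes is None else repr(float(t.fold_changes[k]))
            fh.write(
                f"{lp.id}\t{lp.chrom}\t{lp.anchor_left.start}\t{lp.anchor_left.end}"
                f"\t{lp.anchor_right.start}\t{lp.anchor_right.end}"
                f"\t{lp.pet_count}\t{cb}\t{fold}\n"
            )
    return paths


def background_distance_check(
    distances: np.ndarray,
    config: SimConfig,
    n_bins: int = 20,
) -> float:
    """Recover the decay exponent from background PET distances.

    Log-log OLS on the per-bp density of the distance histogram; the fit is
    restricted to distances below chrom_length / 5, where right-edge
    rejection does not distort the decay.
    """
    d = np.asarray(distances, dtype=float)
    if d.size < 10_000:
        raise ValueError(f"need >= 10000 background PETs, got {d.size}")
    d_max = config.chrom_length / 5
    d = d[(d >= config.d_min) & (d <= d_max)]
    edges = np.logspace(np.log10(config.d_min), np.log10(d_max), n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    ok = counts > 0
    slope, _ = np.polyfit(
        np.log10(centers[ok]), np.log10(counts[ok] / widths[ok]), 1
    )
    return float(-slope)


_BASES = np.array(list("ACGT"))


def simulate_reads(
    n_pairs: int,
    linker: str = LINKER,
    linker_rate: float = 0.8,
    read_len: int = 50,
    seed: int = 0,
) -> list[tuple[str, str, int, int]]:
    """Random read pairs with the linker planted at known positions.

    Returns (read1, read2, linker_pos1, linker_pos2) per pair, where a
    position of -1 means no linker in that mate.  Insert positions are drawn
    uniformly over [0, read_len - len(linker)], so kept/dropped truth under a
    minimum trimmed length is computable exactly.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_pairs):
        reads = []
        positions = []
        for _mate in range(2):
            seq = "".join(rng.choice(_BASES, read_len))
            # avoid accidental linker occurrences in random sequence
            while linker in seq:
                seq = "".join(rng.choice(_BASES, read_len))
            if rng.random() < linker_rate:
                pos = int(rng.integers(0, read_len - len(linker) + 1))
                seq = seq[:pos] + linker + seq[pos + len(linker):]
                # planting may create an earlier spurious hit; record first
                pos = seq.find(linker)
            else:
                pos = -1
            reads.append(seq)
            positions.append(pos)
        out.append((reads[0], reads[1], positions[0], positions[1]))
    return out
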