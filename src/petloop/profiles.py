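"""Virtual 4C extraction, profile correlation, and montage densities."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_io import GenomicInterval, PETIndex, Profile1D

__all__ = [
    "Viewpoint",
    "MontageTable",
    "virtual_4c",
    "profile_correlation",
    "montage_densities",
]


@dataclass(frozen=True)
class Viewpoint:
    chrom: str
    center: int
    flank: int = 1000
    window: int = 250_000

    def __post_init__(self) -> None:
        if self.flank <= 0:
            raise ValueError("flank must be > 0")
        if self.window < self.flank:
            raise ValueError("window must be >= flank")


def virtual_4c(
    index: PETIndex, vp: Viewpoint, bin_size: int = 200
) -> Profile1D:
    """Viewpoint-anchored 1D interaction profile.

    PETs with at least one end midpoint within [center - flank,
    center + flank] are selected; the full intervals of their other ends are
    piled up as per-base coverage over [center - window, center + window) and
    averaged per bin (so the profile total equals clipped covered bases
    divided by bin_size).  PETs with both ends in the viewpoint are piled
    once, via their right end.
    """
    region_start = max(0, vp.center - vp.window)
    region = GenomicInterval(vp.chrom, region_start, vp.center + vp.window)
    n_bins = math.ceil(region.length / bin_size)
    d = index.ends(vp.chrom)
    x, y = d["x"], d["y"]
    if x.size == 0:
        return Profile1D(region, bin_size, np.zeros(n_bins))
    lo, hi = vp.center - vp.flank, vp.center + vp.flank
    in_l = (x >= lo) & (x <= hi)
    in_r = (y >= lo) & (y <= hi)
    # left end in viewpoint (or both) -> pile right end; right only -> left
    pile_right = in_l
    pile_left = in_r & ~in_l
    starts = np.concatenate([d["rs"][pile_right], d["ls"][pile_left]])
    ends = np.concatenate([d["re"][pile_right], d["le"][pile_left]])
    s = np.clip(starts - region.start, 0, region.length)
    e = np.clip(ends - region.start, 0, region.length)
    diff = np.zeros(region.length + 1, dtype=np.float64)
    np.add.at(diff, s, 1.0)
    np.add.at(diff, e, -1.0)
    cov = np.cumsum(diff[:-1])
    padded = np.zeros(n_bins * bin_size)
    padded[: region.length] = cov
    values = padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size
    return Profile1D(region, bin_size, values)


def profile_correlation(p1: Profile1D, p2: Profile1D) -> float | None:
    """Pearson correlation over paired bins; None for a constant profile."""
    if p1.region != p2.region or p1.bin_size != p2.bin_size:
        raise ValueError("profiles must share region and bin size")
    if np.ptp(p1.values) == 0 or np.ptp(p2.values) == 0:
        return None
    return float(np.corrcoef(p1.values, p2.values)[0, 1])


@dataclass
class MontageTable:
    names: list[str]
    densities: np.ndarray  # symmetric, per-million-cis-PET normalized
    viewpoints: list[str] = field(default_factory=list)


def montage_densities(
    index: PETIndex,
    regions: Sequence[tuple[str, GenomicInterval]],
    viewpoints: Sequence[str] | None = None,
) -> MontageTable:
    """Pairwise interaction densities among named regions.

    density(i, j) counts PETs with one end midpoint in region i and the
    other in region j, normalized per million total cis PETs.  Overlapping
    regions are rejected (ambiguous assignment); with viewpoints set, only
    pairs touching a viewpoint are retained.
    """
    if len(regions) < 2:
        raise ValueError("need >= 2 regions")
    names = [nm for nm, _ in regions]
    if len(set(names)) != len(names):
        raise ValueError("region names must be unique")
    ivs = [iv for _, iv in regions]
    chrom = ivs[0].chrom
    if any(iv.chrom != chrom for iv in ivs):
        raise ValueError("all regions must be on one chromosome")
    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            if ivs[i].overlaps(ivs[j]):
                raise ValueError(
                    f"regions {names[i]} and {names[j]} overlap"
                )
    vp_set = set(viewpoints or [])
    unknown = vp_set - set(names)
    if unknown:
        raise ValueError(f"unknown viewpoint names: {sorted(unknown)}")

    x, y = index.points(chrom)
    k = len(ivs)
    dens = np.zeros((k, k), dtype=np.float64)

    def assign(pos: np.ndarray) -> np.ndarray:
        out = np.full(pos.shape, -1, dtype=np.int64)
        for idx, iv in enumerate(ivs):
            out[(pos >= iv.start) & (pos < iv.end)] = idx
        return out

    ai = assign(x)
    aj = assign(y)
    ok = (ai >= 0) & (aj >= 0)
    for i, j in zip(ai[ok], aj[ok]):
        if vp_set and names[i] not in vp_set and names[j] not in vp_set:
            continue
        dens[i, j] += 1
        if i != j:
            dens[j, i] += 1
    scale = 1e6 / index.cis_count if index.cis_count else 0.0
    return MontageTable(names, dens * scale, sorted(vp_set))
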