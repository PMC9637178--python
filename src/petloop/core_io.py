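"""Data model and I/O for paired-end tags (PETs), loops and 1D signal.

Coordinates are 0-based, half-open throughout (BED/BEDPE convention).  A PET
is represented in 2D interaction space by the midpoints of its two ends
(x = left midpoint, y = right midpoint), with the left end defined as the one
with the smaller midpoint, so that x <= y and the PET distance y - x is
non-negative for intra-chromosomal pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "PET",
    "PETCollection",
    "PETIndex",
    "Loop",
    "Profile1D",
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "read_bed6",
    "read_loops",
    "write_loops",
    "query_rectangle",
    "read_profile",
    "write_profile",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset)

    def expand(self, bp: int) -> "GenomicInterval":
        """Symmetrically extend by ``bp`` on each side, clamped at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - bp), self.end + bp)


@dataclass
class PET:
    """One paired tag: two genomic end intervals plus QC flags."""

    left: GenomicInterval
    right: GenomicInterval
    mapq_left: int = 255
    mapq_right: int = 255
    linker_left: bool = False
    linker_right: bool = False

    @classmethod
    def ordered(
        cls,
        end1: GenomicInterval,
        end2: GenomicInterval,
        mapq1: int = 255,
        mapq2: int = 255,
        linker1: bool = False,
        linker2: bool = False,
    ) -> "PET":
        """Build a PET with ends in canonical (left, right) order."""
        if end1.chrom == end2.chrom and (end1.midpoint, end1.start) > (
            end2.midpoint,
            end2.start,
        ):
            end1, end2 = end2, end1
            mapq1, mapq2 = mapq2, mapq1
            linker1, linker2 = linker2, linker1
        return cls(end1, end2, mapq1, mapq2, linker1, linker2)

    @property
    def is_cis(self) -> bool:
        return self.left.chrom == self.right.chrom

    @property
    def distance(self) -> int:
        if not self.is_cis:
            raise ValueError("distance undefined for trans PETs")
        return self.right.midpoint - self.left.midpoint

    def key(self) -> tuple:
        """Exact-location key used for PCR de-duplication."""
        return (
            self.left.chrom,
            self.left.start,
            self.left.end,
            self.right.chrom,
            self.right.start,
            self.right.end,
        )


@dataclass
class PETCollection:
    """Cis PETs (used downstream) plus trans PETs kept for QC only."""

    cis: list[PET] = field(default_factory=list)
    trans: list[PET] = field(default_factory=list)

    def __iter__(self) -> Iterator[PET]:
        return iter(self.cis)

    def __len__(self) -> int:
        return len(self.cis)


class PETIndex:
    """Per-chromosome store of cis PETs as 2D points, sorted by (x, y).

    Backing arrays also retain the full end intervals so 1D pileups can be
    computed from the same object.  Rectangle queries are answered with a
    binary search on x followed by a vectorized mask on y; correctness
    against a brute-force scan is pinned by tests.
    """

    def __init__(self, chrom_sizes: dict[str, int] | None = None):
        self._data: dict[str, dict[str, np.ndarray]] = {}
        self.chrom_sizes = dict(chrom_sizes) if chrom_sizes else {}
        self.total_count = 0
        self.cis_count = 0

    @classmethod
    def from_pets(
        cls,
        pets: Iterable[PET],
        chrom_sizes: dict[str, int] | None = None,
    ) -> "PETIndex":
        idx = cls(chrom_sizes)
        per_chrom: dict[str, list[tuple]] = {}
        total = 0
        for p in pets:
            total += 1
            if not p.is_cis:
                continue
            per_chrom.setdefault(p.left.chrom, []).append(
                (
                    p.left.midpoint,
                    p.right.midpoint,
                    p.left.start,
                    p.left.end,
                    p.right.start,
                    p.right.end,
                )
            )
        idx.total_count = total
        for chrom, rows in per_chrom.items():
            arr = np.asarray(rows, dtype=np.int64)
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            arr = arr[order]
            idx._data[chrom] = {
                "x": np.ascontiguousarray(arr[:, 0]),
                "y": np.ascontiguousarray(arr[:, 1]),
                "ls": np.ascontiguousarray(arr[:, 2]),
                "le": np.ascontiguousarray(arr[:, 3]),
                "rs": np.ascontiguousarray(arr[:, 4]),
                "re": np.ascontiguousarray(arr[:, 5]),
            }
            idx.cis_count += arr.shape[0]
        return idx

    def chromosomes(self) -> list[str]:
        return sorted(self._data)

    def points(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        d = self._data.get(chrom)
        if d is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return d["x"], d["y"]

    def ends(self, chrom: str) -> dict[str, np.ndarray]:
        d = self._data.get(chrom)
        if d is None:
            empty = np.empty(0, dtype=np.int64)
            return {k: empty for k in ("x", "y", "ls", "le", "rs", "re")}
        return d

    def _sorted_y(self, chrom: str) -> np.ndarray:
        d = self._data[chrom]
        if "y_sorted" not in d:
            d["y_sorted"] = np.sort(d["y"])
        return d["y_sorted"]

    def _sorted_dist(self, chrom: str) -> np.ndarray:
        d = self._data[chrom]
        if "d_sorted" not in d:
            d["d_sorted"] = np.sort(d["y"] - d["x"])
        return d["d_sorted"]

    def count_left(self, chrom: str, x0: int, x1: int) -> int:
        """PETs with left midpoint in [x0, x1), any right position."""
        d = self._data.get(chrom)
        if d is None:
            return 0
        x = d["x"]
        return int(
            np.searchsorted(x, x1, "left") - np.searchsorted(x, x0, "left")
        )

    def count_right(self, chrom: str, y0: int, y1: int) -> int:
        """PETs with right midpoint in [y0, y1), any left position."""
        if chrom not in self._data:
            return 0
        y = self._sorted_y(chrom)
        return int(
            np.searchsorted(y, y1, "left") - np.searchsorted(y, y0, "left")
        )

    def distance_fraction(self, chrom: str, lo: int, hi: int) -> float:
        """Fraction of this chromosome's PETs with distance in [lo, hi)."""
        if chrom not in self._data:
            return 0.0
        d = self._sorted_dist(chrom)
        if d.size == 0:
            return 0.0
        return float(
            np.searchsorted(d, hi, "left") - np.searchsorted(d, lo, "left")
        ) / d.size

    def count(self, chrom: str, x0: int, x1: int, y0: int, y1: int) -> int:
        """Count PETs with left midpoint in [x0, x1) and right in [y0, y1)."""
        d = self._data.get(chrom)
        if d is None:
            return 0
        x, y = d["x"], d["y"]
        i0 = np.searchsorted(x, x0, side="left")
        i1 = np.searchsorted(x, x1, side="left")
        if i1 <= i0:
            return 0
        ysub = y[i0:i1]
        return int(np.count_nonzero((ysub >= y0) & (ysub < y1)))

    def query_rectangle(
        self, win_x: GenomicInterval, win_y: GenomicInterval
    ) -> int:
        if win_x.chrom != win_y.chrom:
            raise ValueError(
                f"windows on different chromosomes: {win_x.chrom} vs {win_y.chrom}"
            )
        return self.count(win_x.chrom, win_x.start, win_x.end, win_y.start, win_y.end)


def query_rectangle(
    index: PETIndex, win_x: GenomicInterval, win_y: GenomicInterval
) -> int:
    """Count PETs whose left midpoint falls in ``win_x`` and right in ``win_y``."""
    return index.query_rectangle(win_x, win_y)


@dataclass
class Loop:
    """A chromatin loop: two ordered anchors with support and significance."""

    anchor_left: GenomicInterval
    anchor_right: GenomicInterval
    pet_count: int = 0
    p_value: float = 1.0
    enrichment_score: float = 0.0
    id: str = ""

    def __post_init__(self) -> None:
        if self.anchor_left.chrom != self.anchor_right.chrom:
            raise ValueError("loop anchors must be on the same chromosome")
        if self.anchor_left.start > self.anchor_right.start:
            raise ValueError("anchor_left must precede anchor_right")
        if self.pet_count < 0:
            raise ValueError("pet_count must be >= 0")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")

    @property
    def chrom(self) -> str:
        return self.anchor_left.chrom

    @property
    def distance(self) -> int:
        return self.anchor_right.midpoint - self.anchor_left.midpoint


@dataclass
class Profile1D:
    """Binned non-negative 1D signal over a region."""

    region: GenomicInterval
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.values = np.asarray(self.values, dtype=np.float64)
        n_expected = math.ceil(self.region.length / self.bin_size)
        if self.values.shape != (n_expected,):
            raise ValueError(
                f"expected {n_expected} bins, got {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("profile values must be >= 0")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: bad {what}: {token!r}") from exc


def read_bedpe(path: str | Path, mapq_min: int = 0) -> PETCollection:
    """Read a BEDPE file into cis/trans PETs.

    The score column (8th), when present and numeric, is taken as the MAPQ of
    both ends; records below ``mapq_min`` are dropped.  Optional 11th/12th
    columns carry 0/1 linker flags for the two ends.
    """
    coll = PETCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"line {lineno}: expected >= 6 columns")
            c1, c2 = cols[0], cols[3]
            s1 = _parse_int(cols[1], "start1", lineno)
            e1 = _parse_int(cols[2], "end1", lineno)
            s2 = _parse_int(cols[4], "start2", lineno)
            e2 = _parse_int(cols[5], "end2", lineno)
            try:
                end1 = GenomicInterval(c1, s1, e1)
                end2 = GenomicInterval(c2, s2, e2)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            mapq = 255
            if len(cols) >= 8 and cols[7] not in (".", ""):
                try:
                    mapq = int(float(cols[7]))
                except ValueError:
                    mapq = 255
            l1 = l2 = False
            if len(cols) >= 12:
                l1 = cols[10] not in ("0", "", ".")
                l2 = cols[11] not in ("0", "", ".")
            if mapq < mapq_min:
                continue
            pet = PET.ordered(end1, end2, mapq, mapq, l1, l2)
            (coll.cis if pet.is_cis else coll.trans).append(pet)
    return coll


def write_bedpe(pets: Iterable[PET], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(pets):
            fh.write(
                "\t".join(
                    str(v)
                    for v in (
                        p.left.chrom,
                        p.left.start,
                        p.left.end,
                        p.right.chrom,
                        p.right.start,
                        p.right.end,
                        f"pet{i}",
                        min(p.mapq_left, p.mapq_right),
                        ".",
                        ".",
                        int(p.linker_left),
                        int(p.linker_right),
                    )
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 columns")
            out.append(
                GenomicInterval(
                    cols[0],
                    _parse_int(cols[1], "start", lineno),
                    _parse_int(cols[2], "end", lineno),
                )
            )
    return out


def read_bed6(
    path: str | Path,
) -> list[tuple[GenomicInterval, str, float, str]]:
    """Read BED6 rows as (interval, name, score, strand)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"line {lineno}: expected >= 6 columns")
            iv = GenomicInterval(
                cols[0],
                _parse_int(cols[1], "start", lineno),
                _parse_int(cols[2], "end", lineno),
            )
            score = 0.0 if cols[4] in (".", "") else float(cols[4])
            out.append((iv, cols[3], score, cols[5]))
    return out


_LOOP_HEADER = [
    "chrom1",
    "start1",
    "end1",
    "chrom2",
    "start2",
    "end2",
    "id",
    "pet_count",
    "p_value",
    "enrichment_score",
    "distance",
]


def write_loops(
    loops: Sequence[Loop], path: str | Path, dialect: str = "tsv"
) -> None:
    """Write loops as a TSV table or washU longrange track."""
    if dialect not in ("tsv", "washU"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_LOOP_HEADER) + "\n")
            for lp in loops:
                fh.write(
                    "\t".join(
                        str(v)
                        for v in (
                            lp.anchor_left.chrom,
                            lp.anchor_left.start,
                            lp.anchor_left.end,
                            lp.anchor_right.chrom,
                            lp.anchor_right.start,
                            lp.anchor_right.end,
                            lp.id,
                            lp.pet_count,
                            repr(lp.p_value),
                            repr(lp.enrichment_score),
                            lp.distance,
                        )
                    )
                    + "\n"
                )
        else:
            for lp in loops:
                fh.write(
                    f"{lp.anchor_left.chrom}\t{lp.anchor_left.start}\t"
                    f"{lp.anchor_left.end}\t{lp.anchor_right.chrom}:"
                    f"{lp.anchor_right.start}-{lp.anchor_right.end},"
                    f"{lp.pet_count}\n"
                )


def read_loops(path: str | Path) -> list[Loop]:
    loops = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LOOP_HEADER:
            raise ValueError(f"unexpected loop table header: {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            loops.append(
                Loop(
                    anchor_left=GenomicInterval(
                        cols[0], int(cols[1]), int(cols[2])
                    ),
                    anchor_right=GenomicInterval(
                        cols[3], int(cols[4]), int(cols[5])
                    ),
                    id=cols[6],
                    pet_count=int(cols[7]),
                    p_value=float(cols[8]),
                    enrichment_score=float(cols[9]),
                )
            )
    return loops


def write_profile(profile: Profile1D, path: str | Path) -> None:
    """Write a Profile1D as 4-column bedGraph; zero bins are omitted."""
    region, size = profile.region, profile.bin_size
    with open(path, "w") as fh:
        for i, v in enumerate(profile.values):
            if v == 0:
                continue
            start = region.start + i * size
            end = min(start + size, region.end)
            fh.write(f"{region.chrom}\t{start}\t{end}\t{float(v)!r}\n")


def read_profile(
    path: str | Path, region: GenomicInterval, bin_size: int
) -> Profile1D:
    values = np.zeros(math.ceil(region.length / bin_size))
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, _end, val = line.split("\t")
            if chrom != region.chrom:
                continue
            values[(int(start) - region.start) // bin_size] = float(val)
    return Profile1D(region, bin_size, values)
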