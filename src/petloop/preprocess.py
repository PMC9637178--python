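"""Read/PET cleaning: linker trimming, length filter, near-diagonal
no-linker filter, PCR de-duplication, sub-sampling and QC statistics."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .core_io import PET

__all__ = [
    "LINKER",
    "TrimResult",
    "QCStats",
    "trim_linker",
    "trim_fastq_pair",
    "filter_close_nolinker",
    "dedup_pets",
    "subsample_pets",
    "compute_qc",
]

LINKER = "CTGTCTCTTATACACATCT"


@dataclass(frozen=True)
class TrimResult:
    sequence: str
    found_linker: bool
    kept: bool


def trim_linker(
    read: str, linker: str = LINKER, min_len: int = 10
) -> TrimResult:
    """Truncate ``read`` at the first exact occurrence of ``linker``.

    ``kept`` is True iff the trimmed sequence is at least ``min_len`` bases;
    a read pair should be retained only if both mates are kept.
    """
    if not read:
        return TrimResult("", False, False)
    pos = read.find(linker)
    if pos < 0:
        seq, found = read, False
    else:
        seq, found = read[:pos], True
    return TrimResult(seq, found, len(seq) >= min_len)


def trim_fastq_pair(
    fq1_in: str | Path,
    fq2_in: str | Path,
    fq1_out: str | Path,
    fq2_out: str | Path,
    linker: str = LINKER,
    min_len: int = 10,
) -> dict:
    """Trim a FASTQ pair, keeping only pairs where both mates survive.

    Qualities are truncated alongside sequences.  Returns counters.
    """
    n_pairs = n_kept = n_with_linker = 0
    with open(fq1_in) as f1, open(fq2_in) as f2, open(
        fq1_out, "w"
    ) as o1, open(fq2_out, "w") as o2:
        while True:
            rec1 = [f1.readline() for _ in range(4)]
            rec2 = [f2.readline() for _ in range(4)]
            if not rec1[0] or not rec2[0]:
                break
            n_pairs += 1
            t1 = trim_linker(rec1[1].strip(), linker, min_len)
            t2 = trim_linker(rec2[1].strip(), linker, min_len)
            if t1.found_linker or t2.found_linker:
                n_with_linker += 1
            if not (t1.kept and t2.kept):
                continue
            n_kept += 1
            o1.write(rec1[0])
            o1.write(t1.sequence + "\n+\n")
            o1.write(rec1[3].strip()[: len(t1.sequence)] + "\n")
            o2.write(rec2[0])
            o2.write(t2.sequence + "\n+\n")
            o2.write(rec2[3].strip()[: len(t2.sequence)] + "\n")
    return {
        "total_pairs": n_pairs,
        "pairs_with_linker": n_with_linker,
        "pairs_kept": n_kept,
    }


def filter_close_nolinker(
    pets: Iterable[PET], min_dist: int = 1000
) -> list[PET]:
    """Drop cis PETs closer than ``min_dist`` without a linker in any end."""
    out = []
    for p in pets:
        if (
            p.is_cis
            and p.distance < min_dist
            and not p.linker_left
            and not p.linker_right
        ):
            continue
        out.append(p)
    return out


def dedup_pets(pets: Iterable[PET]) -> list[PET]:
    """Keep one representative per exact (both-end) location; first wins."""
    seen: set[tuple] = set()
    out = []
    for p in pets:
        k = p.key()
        if k in seen:
            continue
        seen.add(k)
        out.append(p)
    return out


def subsample_pets(pets: Sequence[PET], n: int, seed: int) -> list[PET]:
    """Uniform sample of ``n`` PETs without replacement (order-stable)."""
    if n > len(pets):
        raise ValueError(f"cannot sample {n} from {len(pets)} PETs")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pets), size=n, replace=False)
    return [pets[i] for i in np.sort(idx)]


@dataclass(frozen=True)
class QCStats:
    total_pairs: int
    pairs_with_linker: int
    mapped: int
    mapq_pass: int
    cis: int
    trans: int
    unique_cis: int
    redundancy: float

    def __post_init__(self) -> None:
        chain = [
            ("pairs_with_linker", self.pairs_with_linker, self.total_pairs),
            ("mapped", self.mapped, self.total_pairs),
            ("mapq_pass", self.mapq_pass, self.mapped),
            ("cis+trans", self.cis + self.trans, self.mapq_pass),
            ("unique_cis", self.unique_cis, self.cis),
        ]
        for name, lo, hi in chain:
            if lo > hi:
                raise ValueError(f"{name} counter exceeds its upstream stage")
        if not 0.0 <= self.redundancy <= 1.0:
            raise ValueError("redundancy must be in [0, 1]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def compute_qc(
    *,
    total_pairs: int,
    pairs_with_linker: int,
    mapped: int,
    mapq_pass: int,
    cis: int,
    trans: int,
    unique_cis: int,
) -> QCStats:
    """Assemble pipeline counters; redundancy = 1 - unique_cis / mapped."""
    redundancy = 0.0 if mapped == 0 else 1.0 - unique_cis / mapped
    return QCStats(
        total_pairs=total_pairs,
        pairs_with_linker=pairs_with_linker,
        mapped=mapped,
        mapq_pass=mapq_pass,
        cis=cis,
        trans=trans,
        unique_cis=unique_cis,
        redundancy=redundancy,
    )
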