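"""CpG island detection by the Gardiner-Garden criteria.

A CpG island is a non-repetitive stretch of at least ``min_length`` bp with
GC content >= ``min_gc`` and observed/expected CpG ratio >= ``min_oe``
(classically 200 bp / 50% / 0.6).  The observed/expected ratio is

    O/E = (#CpG * L) / (#C * #G)

with L the number of non-N positions.  Detection slides a ``min_length``
window at step 1, merges overlapping passing windows, greedily trims each
merged region until it passes all three criteria again, and discards
regions overlapping the repeat mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import (
    Contig,
    GenomicInterval,
    UndefinedValueError,
    ValidationError,
)


@dataclass(frozen=True)
class CpGIsland:
    """A detected (or externally supplied) CpG island with its attributes."""

    id: str
    interval: GenomicInterval
    length: int
    gc_content: float
    obs_exp_cpg: float

    def __post_init__(self) -> None:
        if self.length != len(self.interval):
            raise ValidationError(
                f"island {self.id}: length {self.length} != interval span "
                f"{len(self.interval)}"
            )


def gc_content(seq: str) -> float:
    """Fraction (#G + #C) / (#non-N bases); N positions are excluded."""
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise UndefinedValueError("all-N sequence: GC content undefined")
    return gc / denom


def obs_exp_cpg(seq: str) -> float:
    """Gardiner-Garden observed/expected CpG ratio (#CpG * L) / (#C * #G).

    L is the number of non-N positions; CpG windows containing N are not
    counted (an N can form neither C nor G).
    """
    if not seq:
        raise ValueError("empty sequence")
    n_c = seq.count("C")
    n_g = seq.count("G")
    if n_c == 0 or n_g == 0:
        raise UndefinedValueError(
            "observed/expected CpG ratio undefined without both C and G"
        )
    n_cpg = _count_cpg(seq)
    length = len(seq) - seq.count("N")
    return n_cpg * length / (n_c * n_g)


def _count_cpg(seq: str) -> int:
    # str.count suffices: "CG" occurrences cannot overlap each other
    return seq.count("CG")


def cpg_positions(seq: str, offset: int = 0) -> list[int]:
    """0-based positions (plus ``offset``) of the C of each CpG in ``seq``."""
    out = []
    i = seq.find("CG")
    while i != -1:
        out.append(i + offset)
        i = seq.find("CG", i + 1)
    return out


def _criteria_ok(
    n_gc: int, n_cpg: int, n_c: int, n_g: int, n_valid: int,
    length: int, min_length: int, min_gc: float, min_oe: float,
) -> bool:
    if length < min_length or n_valid == 0 or n_c == 0 or n_g == 0:
        return False
    if n_gc / n_valid < min_gc:
        return False
    return n_cpg * n_valid / (n_c * n_g) >= min_oe


class _SeqSums:
    """Prefix sums over a contig for O(1) window criteria evaluation."""

    def __init__(self, seq: str) -> None:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        is_n = arr == ord("N")
        is_cpg = np.zeros(len(arr), dtype=bool)
        if len(arr) > 1:
            is_cpg[:-1] = is_c[:-1] & is_g[1:]
        z = np.zeros(1, dtype=np.int64)
        self.c = np.concatenate([z, np.cumsum(is_c)])
        self.g = np.concatenate([z, np.cumsum(is_g)])
        self.n = np.concatenate([z, np.cumsum(is_n)])
        self.cpg = np.concatenate([z, np.cumsum(is_cpg)])

    def window(self, start: int, end: int) -> tuple[int, int, int, int, int]:
        """(n_gc, n_cpg, n_c, n_g, n_valid) for [start, end)."""
        n_c = int(self.c[end] - self.c[start])
        n_g = int(self.g[end] - self.g[start])
        n_n = int(self.n[end] - self.n[start])
        # CpG whose C is at end-1 lies outside the window
        n_cpg = int(self.cpg[end - 1] - self.cpg[start]) if end - 1 > start else 0
        return n_c + n_g, n_cpg, n_c, n_g, (end - start) - n_n


def find_islands(
    contig: Contig,
    repeats: Sequence[GenomicInterval] = (),
    min_length: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Detect CpG islands on ``contig``, excluding repeat-masked regions.

    Returns maximal non-overlapping islands sorted by start, each of which
    re-passes all three criteria, with ids ``chrom:start-end``.
    """
    if min_length <= 0 or min_gc <= 0 or min_oe <= 0:
        raise ValueError("thresholds must be positive")
    seq = contig.sequence
    L = len(seq)
    if L < min_length:
        return []
    sums = _SeqSums(seq)

    # vectorized per-window criteria at step 1
    w = min_length
    starts = np.arange(0, L - w + 1)
    ends = starts + w
    n_c = sums.c[ends] - sums.c[starts]
    n_g = sums.g[ends] - sums.g[starts]
    n_n = sums.n[ends] - sums.n[starts]
    n_cpg = sums.cpg[ends - 1] - sums.cpg[starts]
    n_valid = w - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_ok = np.where(n_valid > 0, (n_c + n_g) / np.maximum(n_valid, 1), 0.0) >= min_gc
        denom = (n_c * n_g).astype(float)
        oe = np.where(denom > 0, n_cpg * n_valid / np.maximum(denom, 1.0), 0.0)
    passing = gc_ok & (oe >= min_oe) & (n_valid > 0)

    # merge overlapping/adjacent passing windows into candidate regions:
    # windows [i, i+w) and [j, j+w) merge when j - i <= w
    regions: list[tuple[int, int]] = []
    idx = np.flatnonzero(passing)
    if idx.size:
        breaks = np.flatnonzero(np.diff(idx) > w)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks, [idx.size - 1]])
        for rs, re in zip(run_starts, run_ends):
            regions.append((int(idx[rs]), int(idx[re]) + w))

    repeat_list = [r for r in repeats if r.chrom == contig.name]
    islands: list[CpGIsland] = []
    for start, end in regions:
        trimmed = _trim_region(sums, start, end, min_length, min_gc, min_oe)
        if trimmed is None:
            continue
        start, end = trimmed
        if any(r.start < end and start < r.end for r in repeat_list):
            continue
        sub = seq[start:end]
        islands.append(
            CpGIsland(
                id=f"{contig.name}:{start}-{end}",
                interval=GenomicInterval(contig.name, start, end),
                length=end - start,
                gc_content=gc_content(sub),
                obs_exp_cpg=obs_exp_cpg(sub),
            )
        )
    return islands


def _trim_region(
    sums: _SeqSums, start: int, end: int,
    min_length: int, min_gc: float, min_oe: float,
) -> tuple[int, int] | None:
    """Greedily trim 1 bp per side until the region passes all criteria."""

    def ok(s: int, e: int) -> bool:
        return _criteria_ok(*sums.window(s, e), e - s, min_length, min_gc, min_oe)

    def score(s: int, e: int) -> tuple[float, float]:
        n_gc, n_cpg, n_c, n_g, n_valid = sums.window(s, e)
        gc = n_gc / n_valid if n_valid else 0.0
        oe = n_cpg * n_valid / (n_c * n_g) if n_c and n_g else 0.0
        return min(gc - min_gc, 0.0), min(oe - min_oe, 0.0)

    while not ok(start, end):
        if end - start <= min_length:
            return None
        # trim the side whose removal leaves the region closer to passing;
        # ties trim the left side
        left = score(start + 1, end)
        right = score(start, end - 1)
        if sum(right) > sum(left):
            end -= 1
        else:
            start += 1
    return start, end


def general_attributes(
    island: CpGIsland | GenomicInterval, genome: dict[str, Contig]
) -> dict[str, float]:
    """The three general-attribute features: length, GC content, O/E CpG ratio.

    Values are recomputed from the sequence and are authoritative over any
    attributes imported with the island.
    """
    interval = island.interval if isinstance(island, CpGIsland) else island
    contig = genome.get(interval.chrom)
    if contig is None:
        raise KeyError(f"contig {interval.chrom!r} not in genome")
    if interval.end > len(contig):
        raise IndexError(
            f"island {interval.chrom}:{interval.start}-{interval.end} "
            f"outside contig of length {len(contig)}"
        )
    seq = contig.sequence[interval.start:interval.end]
    return {
        "length": float(len(interval)),
        "gc_content": gc_content(seq),
        "obs_exp_cpg": obs_exp_cpg(seq),
    }


def islands_from_bed(
    intervals: Sequence[GenomicInterval], genome: dict[str, Contig]
) -> list[CpGIsland]:
    """Wrap externally supplied island intervals (e.g. a browser track).

    Attributes are recomputed from sequence; the Gardiner-Garden thresholds
    are NOT enforced for imported islands.
    """
    out = []
    for iv in intervals:
        attrs = general_attributes(iv, genome)
        out.append(
            CpGIsland(
                id=iv.name or f"{iv.chrom}:{iv.start}-{iv.end}",
                interval=iv,
                length=int(attrs["length"]),
                gc_content=attrs["gc_content"],
                obs_exp_cpg=attrs["obs_exp_cpg"],
            )
        )
    return out


def islands_to_bed(islands: Sequence[CpGIsland], path: str) -> None:
    with open(path, "w") as fh:
        for isl in islands:
            iv = isl.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{isl.id}\n")
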