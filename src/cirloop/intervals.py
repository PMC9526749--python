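"""Genomic interval model and bedtools-style interval algebra.

Coordinates are 0-based half-open throughout the package: an interval
``(chrom, start, end)`` covers the bases ``start .. end-1``.  BED files can
therefore be read and written without any coordinate shift.  Strand is
ignored everywhere: S9.6-based DRIP is not strand-resolved (the DNA strand of
the R-loop is what gets sequenced), so loop-level operations have no use for
it.

The algebra (``merge``, ``intersect``, ``subtract``, ``common_peaks``) is
implemented as linear sweeps over per-chromosome sorted interval lists and is
exact at base resolution; the test suite checks it base-for-base against a
boolean-mask brute force.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ParameterError, ValidationError

CONDITIONS = ("WT", "KO", "other")
TREATMENTS = ("none", "RNaseR")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span with an optional intensity score and label."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self.chrom}:{self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.score < 0:
            raise ValidationError(f"negative score on {self.chrom}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_frac: float = 0.0) -> bool:
        """≥1 bp overlap, optionally requiring a minimum fraction of self."""
        ol = self.overlap_len(other)
        if ol <= 0:
            return False
        if min_frac > 0.0:
            return ol >= min_frac * self.length
        return True

    def with_score(self, score: float) -> "GenomicInterval":
        return replace(self, score=score)


@dataclass
class PeakSet:
    """A set of peaks from one sample (one condition, one treatment).

    ``normalized()`` returns a copy whose intervals are sorted and pairwise
    non-overlapping within each chromosome, the invariant all set operations
    assume.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    sample_id: str = ""
    condition: str = "other"
    treatment: str = "none"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if self.treatment not in TREATMENTS:
            raise ValidationError(f"unknown treatment {self.treatment!r}")

    def normalized(self, gap: int = 0) -> "PeakSet":
        return PeakSet(
            intervals=merge(self.intervals, gap=gap),
            sample_id=self.sample_id,
            condition=self.condition,
            treatment=self.treatment,
        )

    @property
    def total_bases(self) -> int:
        return sum(iv.length for iv in merge(self.intervals, gap=0))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def _as_intervals(x: "PeakSet | Iterable[GenomicInterval]") -> list[GenomicInterval]:
    if isinstance(x, PeakSet):
        return list(x.intervals)
    return list(x)


def _by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Deterministic order: chromosome lexicographic, then start, then end."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Union same-chromosome intervals separated by ≤ ``gap`` bases.

    Book-ended intervals (distance 0) are joined at gap=0, matching bedtools
    merge.  Scores of joined intervals are summed; names are dropped.
    """
    if gap < 0:
        raise ParameterError(f"gap must be nonnegative, got {gap}")
    grouped = _by_chrom(intervals)
    result: list[GenomicInterval] = []
    for chrom in sorted(grouped):
        cur_s: int | None = None
        cur_e = 0
        cur_score = 0.0
        for iv in grouped[chrom]:
            if cur_s is None:
                cur_s, cur_e, cur_score = iv.start, iv.end, iv.score
            elif iv.start - cur_e <= gap:
                cur_e = max(cur_e, iv.end)
                cur_score += iv.score
            else:
                result.append(GenomicInterval(chrom, cur_s, cur_e, cur_score))
                cur_s, cur_e, cur_score = iv.start, iv.end, iv.score
        if cur_s is not None:
            result.append(GenomicInterval(chrom, cur_s, cur_e, cur_score))
    return result


def intersect(
    a: "PeakSet | Iterable[GenomicInterval]",
    b: "PeakSet | Iterable[GenomicInterval]",
) -> list[GenomicInterval]:
    """Base-level intersection of two (normalized) interval sets."""
    ga = _by_chrom(merge(_as_intervals(a), 0))
    gb = _by_chrom(merge(_as_intervals(b), 0))
    out: list[GenomicInterval] = []
    for chrom in sorted(set(ga) & set(gb)):
        ia, ib = ga[chrom], gb[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            s = max(ia[i].start, ib[j].start)
            e = min(ia[i].end, ib[j].end)
            if e > s:
                out.append(GenomicInterval(chrom, s, e))
            if ia[i].end <= ib[j].end:
                i += 1
            else:
                j += 1
    return out


def subtract(
    a: "PeakSet | Iterable[GenomicInterval]",
    b: "PeakSet | Iterable[GenomicInterval]",
    min_len: int = 0,
) -> list[GenomicInterval]:
    """Base-level A \\ B; residual fragments shorter than ``min_len`` dropped."""
    if min_len < 0:
        raise ParameterError(f"min_len must be nonnegative, got {min_len}")
    ga = _by_chrom(merge(_as_intervals(a), 0))
    gb = _by_chrom(merge(_as_intervals(b), 0))
    out: list[GenomicInterval] = []
    for chrom in sorted(ga):
        blockers = gb.get(chrom, [])
        bends = [blk.end for blk in blockers]
        for iv in ga[chrom]:
            cursor = iv.start
            # only blockers overlapping iv matter
            k = bisect.bisect_right(bends, iv.start)
            while k < len(blockers) and blockers[k].start < iv.end:
                blk = blockers[k]
                if blk.start > cursor:
                    frag = GenomicInterval(chrom, cursor, blk.start)
                    if frag.length >= min_len:
                        out.append(frag)
                cursor = max(cursor, blk.end)
                k += 1
            if cursor < iv.end:
                frag = GenomicInterval(chrom, cursor, iv.end)
                if frag.length >= min_len:
                    out.append(frag)
    return out


def _overlaps_any(
    iv: GenomicInterval, grouped: Mapping[str, Sequence[GenomicInterval]]
) -> bool:
    """≥1 bp overlap with a sorted, non-overlapping per-chrom interval list."""
    others = grouped.get(iv.chrom, ())
    if not others:
        return False
    ends = [o.end for o in others]
    k = bisect.bisect_right(ends, iv.start)  # first interval with end > start
    return k < len(others) and others[k].start < iv.end


def common_peaks(rep1: PeakSet, rep2: PeakSet) -> PeakSet:
    """Replicate-reproducible peaks: union-merge of peaks that overlap (≥1 bp)
    at least one peak of the other replicate; replicate-specific peaks drop.
    """
    if rep1.condition != rep2.condition or rep1.treatment != rep2.treatment:
        raise ValidationError(
            "replicates must share condition and treatment: "
            f"({rep1.condition},{rep1.treatment}) vs ({rep2.condition},{rep2.treatment})"
        )
    if not rep1.intervals or not rep2.intervals:
        warnings.warn("empty replicate peak set; common peaks are empty")
        return PeakSet(
            [], sample_id=rep1.sample_id, condition=rep1.condition,
            treatment=rep1.treatment,
        )
    g1 = _by_chrom(merge(rep1.intervals, 0))
    g2 = _by_chrom(merge(rep2.intervals, 0))
    kept: list[GenomicInterval] = []
    for iv in rep1.intervals:
        if _overlaps_any(iv, g2):
            kept.append(iv)
    for iv in rep2.intervals:
        if _overlaps_any(iv, g1):
            kept.append(iv)
    return PeakSet(
        merge(kept, 0),
        sample_id=f"{rep1.sample_id}+{rep2.sample_id}".strip("+"),
        condition=rep1.condition,
        treatment=rep1.treatment,
    )


class Coverage:
    """A per-base coverage track held as sorted non-overlapping segments.

    Built from bedGraph records ``(chrom, start, end, value)``; positions not
    covered by any segment have value 0.
    """

    def __init__(self, chrom_data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = {
            c: (np.asarray(s, dtype=np.int64),
                np.asarray(e, dtype=np.int64),
                np.asarray(v, dtype=np.float64))
            for c, (s, e, v) in chrom_data.items()
        }

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "Coverage":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, v in records:
            if e <= s:
                raise ValidationError(f"bad coverage segment {chrom}:{s}-{e}")
            per.setdefault(chrom, []).append((s, e, v))
        data = {}
        for chrom, segs in per.items():
            segs.sort()
            s, e, v = zip(*segs)
            data[chrom] = (np.array(s), np.array(e), np.array(v))
        return cls(data)

    def records(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in sorted(self._data):
            s, e, v = self._data[chrom]
            out.extend((chrom, int(a), int(b), float(x)) for a, b, x in zip(s, e, v))
        return out

    def sum_over(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end)."""
        if chrom not in self._data:
            return 0.0
        s, e, v = self._data[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        if hi <= lo:
            return 0.0
        ol = np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)
        ol = np.clip(ol, 0, None)
        return float(np.dot(ol, v[lo:hi]))


def assign_intensity(
    peaks: PeakSet, coverage: Coverage, spikein_factor: float = 1.0
) -> PeakSet:
    """Score each peak as (coverage sum over the peak) × spike-in factor."""
    if spikein_factor <= 0:
        raise ParameterError(f"spikein_factor must be positive, got {spikein_factor}")
    scored = [
        iv.with_score(coverage.sum_over(iv.chrom, iv.start, iv.end) * spikein_factor)
        for iv in peaks.intervals
    ]
    return PeakSet(
        scored, sample_id=peaks.sample_id, condition=peaks.condition,
        treatment=peaks.treatment,
    )


def spikein_factors(
    spikein_counts: Mapping[str, float], reference: str | None = None
) -> dict[str, float]:
    """Per-sample scaling: (reference spike-in reads) / (sample spike-in reads).

    The reference defaults to the first sample in insertion order.
    """
    samples = list(spikein_counts)
    if not samples:
        return {}
    ref = reference if reference is not None else samples[0]
    ref_count = spikein_counts[ref]
    if ref_count <= 0:
        raise ParameterError("reference spike-in count must be positive")
    out = {}
    for s, c in spikein_counts.items():
        if c <= 0:
            raise ParameterError(f"nonpositive spike-in count for sample {s!r}")
        out[s] = ref_count / c
    return out
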