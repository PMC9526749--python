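"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cirloop import GenomicInterval, SimulationParams

SMALL_LOOP_COUNTS = {
    "WT": {"cis": 4, "trans": 3, "WAT": 10, "WOT": 5},
    "KO": {"cis": 10, "trans": 18, "WAT": 28, "WOT": 16},
}


def small_params(seed: int, **overrides) -> SimulationParams:
    """Desk-scale-squared parameters: a tiny bundle for fast unit tests."""
    defaults = dict(
        seed=seed,
        n_chrom=2,
        chrom_len=400_000,
        n_genes=60,
        n_circ_loci=50,
        loop_counts={c: dict(v) for c, v in SMALL_LOOP_COUNTS.items()},
        n_circ=60,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


# ---------------------------------------------------------------------------
# per-base boolean-mask oracle for the interval algebra


def mask_of(intervals, chrom: str, length: int) -> np.ndarray:
    m = np.zeros(length, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            m[iv.start : min(iv.end, length)] = True
    return m


def runs_to_intervals(mask: np.ndarray, chrom: str) -> list[GenomicInterval]:
    out = []
    diff = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        out.append(GenomicInterval(chrom, int(s), int(e)))
    return out


def brute_merge(intervals, chrom: str, length: int, gap: int) -> list[GenomicInterval]:
    mask = mask_of(intervals, chrom, length)
    if gap > 0:
        runs = runs_to_intervals(mask, chrom)
        for a, b in zip(runs, runs[1:]):
            if b.start - a.end <= gap:
                mask[a.end : b.start] = True
    return runs_to_intervals(mask, chrom)


def brute_intersect(a, b, chrom: str, length: int) -> list[GenomicInterval]:
    return runs_to_intervals(
        mask_of(a, chrom, length) & mask_of(b, chrom, length), chrom
    )


def brute_subtract(a, b, chrom: str, length: int, min_len: int) -> list[GenomicInterval]:
    mask = mask_of(a, chrom, length) & ~mask_of(b, chrom, length)
    return [iv for iv in runs_to_intervals(mask, chrom) if iv.length >= min_len]


def random_intervals(rng, chroms, max_len: int, n: int) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_len - 1))
        end = int(rng.integers(start + 1, min(start + 1 + rng.integers(1, 400), max_len) + 1))
        out.append(GenomicInterval(chrom, start, min(end, max_len)))
    return out
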