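"""Decomposition of total R-loop peaks into ciR-loops and liR-loops.

The operational definitions: a DRIP peak that survives RNase R predigestion
is a ciR-loop (the RNA moiety is a circRNA, which the exonuclease spares);
the liR-loop profile is the total R-loop profile minus the ciR-loops.
ciR-loops are *cis* when they overlap a circRNA-producing locus and *trans*
otherwise; liR-loops are WAT/WOT according to overlap with an annotated
transcript.  Because the assay sequences the DNA strand, any overlap with a
circRNA-producing locus is counted as cis — a convention that overestimates
cis and underestimates trans calls, which reports emitted here annotate.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DivideByZeroFoldError,
    ParameterError,
    UndefinedCorrelationError,
    ValidationError,
)
from .intervals import (
    GenomicInterval,
    PeakSet,
    _by_chrom,
    assign_intensity,
    common_peaks,
    merge,
    subtract,
)

LOOP_CLASSES = ("R_loop", "ciR_loop", "liR_loop")
SUBCLASSES = {
    "R_loop": ("none",),
    "ciR_loop": ("none", "cis", "trans"),
    "liR_loop": ("none", "WAT", "WOT"),
}


@dataclass(frozen=True)
class LoopCall:
    """A peak annotated with loop class, subclass, intensity and condition."""

    interval: GenomicInterval
    loop_class: str
    subclass: str = "none"
    intensity: float = 0.0
    condition: str = "other"

    def __post_init__(self) -> None:
        if self.loop_class not in LOOP_CLASSES:
            raise ValidationError(f"unknown loop class {self.loop_class!r}")
        if self.subclass not in SUBCLASSES[self.loop_class]:
            raise ValidationError(
                f"subclass {self.subclass!r} invalid for {self.loop_class}"
            )
        if self.intensity < 0:
            raise ValidationError("negative intensity")


@dataclass
class AnnotationSet:
    """CircRNA-producing loci, transcript spans, exon models, expression."""

    circ_loci: list[GenomicInterval] = field(default_factory=list)
    transcripts: list[GenomicInterval] = field(default_factory=list)
    exons: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    gene_expression: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        spans = {t.name: t for t in self.transcripts}
        for gene, exs in self.exons.items():
            span = spans.get(gene)
            if span is None:
                continue
            for ex in exs:
                if ex.chrom != span.chrom or ex.start < span.start or ex.end > span.end:
                    raise ValidationError(f"exon outside transcript span for {gene}")


def decompose(
    total: PeakSet,
    rnr: PeakSet,
    mode: str = "base",
    min_len: int = 50,
) -> tuple[list[LoopCall], list[LoopCall]]:
    """Split a condition's R-loop profile into ciR-loops and liR-loops.

    ``total`` is the replicate-merged untreated peak set, ``rnr`` the
    replicate-merged RNase-R-treated set of the same condition.  In ``base``
    mode the liR profile is the base-level subtraction total \\ ciR with
    residuals < ``min_len`` dropped; in ``whole_peak`` mode it is the total
    peaks that have no overlap with any ciR peak (peak-count semantics).
    """
    if mode not in ("base", "whole_peak"):
        raise ParameterError(f"unknown decomposition mode {mode!r}")
    if total.condition != rnr.condition:
        raise ValidationError(
            f"condition mismatch: total={total.condition} rnr={rnr.condition}"
        )
    cond = total.condition
    rnr_norm = rnr.normalized()
    cir = [
        LoopCall(iv, "ciR_loop", "none", intensity=iv.score, condition=cond)
        for iv in rnr_norm.intervals
    ]
    if mode == "base":
        lir_ivs = subtract(total, rnr_norm, min_len=min_len)
    else:
        grouped = _by_chrom(rnr_norm.intervals)
        lir_ivs = [
            iv for iv in total.normalized().intervals
            if not _any_overlap(iv, grouped)
        ]
    lir = [
        LoopCall(iv, "liR_loop", "none", intensity=iv.score, condition=cond)
        for iv in lir_ivs
    ]
    return cir, lir


def _any_overlap(
    iv: GenomicInterval,
    grouped: Mapping[str, Sequence[GenomicInterval]],
    min_frac: float = 0.0,
) -> bool:
    others = grouped.get(iv.chrom, ())
    if not others:
        return False
    ends = [o.end for o in others]
    k = bisect.bisect_right(ends, iv.start)
    total_ol = 0
    while k < len(others) and others[k].start < iv.end:
        total_ol += min(iv.end, others[k].end) - max(iv.start, others[k].start)
        k += 1
    if total_ol <= 0:
        return False
    if min_frac > 0.0:
        return total_ol >= min_frac * iv.length
    return True


def classify_cir(
    cir: Iterable[LoopCall],
    circ_loci: Iterable[GenomicInterval],
    min_frac: float = 0.0,
) -> list[LoopCall]:
    """Label each ciR-loop cis (overlaps a circRNA-producing locus) or trans."""
    loci = merge(circ_loci, 0)
    if not loci:
        warnings.warn("empty circRNA locus set: all ciR-loops labeled trans")
    grouped = _by_chrom(loci)
    out = []
    for lc in cir:
        if lc.loop_class != "ciR_loop":
            raise ValidationError("classify_cir expects ciR_loop calls")
        sub = "cis" if _any_overlap(lc.interval, grouped, min_frac) else "trans"
        out.append(LoopCall(lc.interval, "ciR_loop", sub, lc.intensity, lc.condition))
    return out


def classify_lir(
    lir: Iterable[LoopCall],
    transcripts: Iterable[GenomicInterval],
    min_frac: float = 0.0,
) -> list[LoopCall]:
    """Label each liR-loop WAT (overlaps an annotated transcript) or WOT."""
    grouped = _by_chrom(merge(transcripts, 0))
    out = []
    for lc in lir:
        if lc.loop_class != "liR_loop":
            raise ValidationError("classify_lir expects liR_loop calls")
        sub = "WAT" if _any_overlap(lc.interval, grouped, min_frac) else "WOT"
        out.append(LoopCall(lc.interval, "liR_loop", sub, lc.intensity, lc.condition))
    return out


def condition_fold(
    a: Sequence[LoopCall],
    b: Sequence[LoopCall],
    mode: str = "count",
) -> float:
    """Ratio (statistic of a)/(statistic of b): loop count, covered bases, or
    total intensity.  Mirrors e.g. the KO/WT R-loop abundance comparison."""
    if mode not in ("count", "area", "intensity"):
        raise ParameterError(f"unknown fold mode {mode!r}")

    def stat(loops: Sequence[LoopCall]) -> float:
        if mode == "count":
            return float(len(loops))
        if mode == "area":
            return float(sum(iv.length for iv in merge([l.interval for l in loops], 0)))
        return float(sum(l.intensity for l in loops))

    denom = stat(b)
    if denom == 0:
        raise DivideByZeroFoldError(
            f"zero denominator in {mode} fold change; add a pseudocount via "
            "configuration or check the comparison inputs"
        )
    return stat(a) / denom


class CorrelationResult(NamedTuple):
    r: float
    r2: float
    p: float
    n: int


def correlate_overlaps(
    cir: Sequence[LoopCall], lir: Sequence[LoopCall], max_gap: int = 0
) -> CorrelationResult:
    """Pearson correlation of log10(intensity+1) over all overlapping
    ciR-loop/liR-loop pairs (the 'at overlapping genomic regions' analysis).

    With ``max_gap`` > 0, pairs within that distance also count; base-level
    subtraction leaves liR fragments abutting their ciR peak (no shared
    base), so pipelines pairing decomposed output use max_gap=1.
    """
    g_lir: dict[str, list[LoopCall]] = {}
    for l in sorted(lir, key=lambda l: (l.interval.chrom, l.interval.start)):
        g_lir.setdefault(l.interval.chrom, []).append(l)
    pairs_x, pairs_y = [], []
    for c in cir:
        for l in g_lir.get(c.interval.chrom, ()):
            if l.interval.start >= c.interval.end + max_gap:
                break
            if l.interval.end > c.interval.start - max_gap:
                pairs_x.append(c.intensity)
                pairs_y.append(l.intensity)
    n = len(pairs_x)
    if n < 3:
        raise UndefinedCorrelationError(f"only {n} overlapping pairs (need ≥3)")
    x = np.log10(np.asarray(pairs_x) + 1.0)
    y = np.log10(np.asarray(pairs_y) + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in an intensity vector")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(r * r), float(p), n)


def fpkm(count: float, length_bp: float, mapped_reads: float) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if length_bp <= 0 or mapped_reads <= 0:
        raise ParameterError("length and mapped reads must be positive")
    return count / (length_bp / 1e3) / (mapped_reads / 1e6)


def expression_association(
    loops: Sequence[LoopCall],
    annotation: AnnotationSet,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Fraction of genes carrying ≥1 loop, per FPKM quantile bin.

    Genes are split into ``n_bins`` quantile bins of expression; per bin the
    fraction of genes whose span overlaps at least one of the given loops is
    reported (used to show e.g. that liR-loops track transcription).
    """
    if n_bins < 2:
        raise ParameterError(f"n_bins must be ≥2, got {n_bins}")
    genes = [t for t in annotation.transcripts if t.name in annotation.gene_expression]
    if not genes:
        raise ValidationError("no genes with expression values")
    expr = np.array([annotation.gene_expression[g.name] for g in genes])
    # quantile bins; ranks break FPKM ties deterministically
    order = np.argsort(expr, kind="stable")
    ranks = np.empty(len(expr), dtype=int)
    ranks[order] = np.arange(len(expr))
    bins = np.minimum((ranks * n_bins) // len(expr), n_bins - 1)
    grouped = _by_chrom(merge([l.interval for l in loops], 0))
    has_loop = np.array([_any_overlap(g, grouped) for g in genes])
    rows = []
    for b in range(n_bins):
        mask = bins == b
        n_genes = int(mask.sum())
        frac = float(has_loop[mask].mean()) if n_genes else float("nan")
        rows.append(
            {"bin": b, "n_genes": n_genes,
             "fpkm_min": float(expr[mask].min()) if n_genes else float("nan"),
             "fpkm_max": float(expr[mask].max()) if n_genes else float("nan"),
             "fraction_with_loop": frac}
        )
    return pd.DataFrame(rows)


@dataclass
class DecompositionReport:
    """Counts per class × subclass × condition, KO/WT folds, correlations."""

    counts: dict[str, dict[str, int]]
    fold_changes: dict[str, float]
    correlations: dict[str, CorrelationResult | None]
    mode: str = "base"
    notes: str = (
        "cis takes precedence on any overlap; DNA-strand sequencing "
        "overestimates cis and WAT calls, underestimates trans and WOT calls"
    )

    def validate(self) -> None:
        for cond, c in self.counts.items():
            if c["cis"] + c["trans"] != c["ciR_loop"]:
                raise ValidationError(f"{cond}: cis+trans != ciR_loop count")
            if c["WAT"] + c["WOT"] != c["liR_loop"]:
                raise ValidationError(f"{cond}: WAT+WOT != liR_loop count")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "counts": self.counts,
            "fold_changes": self.fold_changes,
            "correlations": {
                k: (None if v is None else
                    {"r": v.r, "r2": v.r2, "p": v.p, "n": v.n})
                for k, v in self.correlations.items()
            },
            "notes": self.notes,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cond, c in self.counts.items():
            for key, val in c.items():
                rows.append({"condition": cond, "category": key, "count": val})
        return pd.DataFrame(rows)


def count_classes(
    cir: Sequence[LoopCall], lir: Sequence[LoopCall], total_peaks: int
) -> dict[str, int]:
    c = {
        "R_loop": total_peaks,
        "ciR_loop": len(cir),
        "liR_loop": len(lir),
        "cis": sum(1 for l in cir if l.subclass == "cis"),
        "trans": sum(1 for l in cir if l.subclass == "trans"),
        "WAT": sum(1 for l in lir if l.subclass == "WAT"),
        "WOT": sum(1 for l in lir if l.subclass == "WOT"),
    }
    return c


def decompose_conditions(
    replicates: Mapping[tuple[str, str], Sequence[PeakSet]],
    annotation: AnnotationSet,
    coverages: Mapping[str, "object"] | None = None,
    spikein: Mapping[str, float] | None = None,
    mode: str = "base",
    min_len: int = 50,
    min_frac: float = 0.0,
    fold_mode: str = "count",
) -> tuple[DecompositionReport, dict[str, tuple[list[LoopCall], list[LoopCall]]]]:
    """Full decomposition of a WT/KO experiment.

    ``replicates`` maps (condition, treatment) — treatment "none" for total
    R-loops, "RNaseR" for the circRNA-resistant fraction — to one or two
    replicate PeakSets.  Two replicates are reduced to their reproducible
    common peaks; a single set is taken as pre-merged.  ``coverages`` maps
    condition to a Coverage used to score peaks (scaled by the sample's
    spike-in factor where provided).
    """
    merged: dict[tuple[str, str], PeakSet] = {}
    for key, reps in replicates.items():
        reps = list(reps)
        if len(reps) == 1:
            merged[key] = reps[0].normalized()
        elif len(reps) == 2:
            merged[key] = common_peaks(reps[0], reps[1])
        else:
            raise ValidationError(f"{key}: expected 1 or 2 replicate peak sets")
    conditions = sorted({cond for cond, _ in merged}, reverse=True)  # WT before KO
    loops: dict[str, tuple[list[LoopCall], list[LoopCall]]] = {}
    counts: dict[str, dict[str, int]] = {}
    correlations: dict[str, CorrelationResult | None] = {}
    for cond in conditions:
        total = merged.get((cond, "none"))
        rnr = merged.get((cond, "RNaseR"))
        if total is None or rnr is None:
            raise ValidationError(f"condition {cond}: need both treatments")
        if coverages is not None and cond in coverages:
            factor = (spikein or {}).get(cond, 1.0)
            total = assign_intensity(total, coverages[cond], factor)
            rnr = assign_intensity(rnr, coverages[cond], factor)
        cir, lir = decompose(total, rnr, mode=mode, min_len=min_len)
        cir = classify_cir(cir, annotation.circ_loci, min_frac=min_frac)
        lir = classify_lir(lir, annotation.transcripts, min_frac=min_frac)
        loops[cond] = (cir, lir)
        counts[cond] = count_classes(cir, lir, total_peaks=len(total))
        try:
            correlations[cond] = correlate_overlaps(cir, lir, max_gap=1)
        except UndefinedCorrelationError:
            correlations[cond] = None
    fold_changes: dict[str, float] = {}
    if "KO" in loops and "WT" in loops:
        ko_cir, ko_lir = loops["KO"]
        wt_cir, wt_lir = loops["WT"]
        for label, ko, wt in (
            ("R_loop", ko_cir + ko_lir, wt_cir + wt_lir),
            ("ciR_loop", ko_cir, wt_cir),
            ("liR_loop", ko_lir, wt_lir),
        ):
            try:
                fold_changes[f"{label}_KO_vs_WT"] = condition_fold(ko, wt, fold_mode)
            except DivideByZeroFoldError:
                fold_changes[f"{label}_KO_vs_WT"] = math.nan
        for sub in ("cis", "trans"):
            ko_s = [l for l in ko_cir if l.subclass == sub]
            wt_s = [l for l in wt_cir if l.subclass == sub]
            try:
                fold_changes[f"{sub}_KO_vs_WT"] = condition_fold(ko_s, wt_s, fold_mode)
            except DivideByZeroFoldError:
                fold_changes[f"{sub}_KO_vs_WT"] = math.nan
        for sub in ("WAT", "WOT"):
            ko_s = [l for l in ko_lir if l.subclass == sub]
            wt_s = [l for l in wt_lir if l.subclass == sub]
            try:
                fold_changes[f"{sub}_KO_vs_WT"] = condition_fold(ko_s, wt_s, fold_mode)
            except DivideByZeroFoldError:
                fold_changes[f"{sub}_KO_vs_WT"] = math.nan
    report = DecompositionReport(
        counts=counts, fold_changes=fold_changes, correlations=correlations,
        mode=mode,
    )
    report.validate()
    return report, loops
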