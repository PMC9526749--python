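"""Ground-truthed synthetic data for every pipeline stage.

The generator emulates the statistical structure of a WT-vs-KO
DRIP-seq / nucleocytoplasmic circRNA-seq experiment at desk scale: a small
multi-chromosome genome with gene/exon annotation and circRNA-producing
loci; per-condition R-loop peak sets in which the RNase-R-resistant fraction
is exactly the planted ciR-loops; replicate peak files perturbed by boundary
jitter and dropout; negative-binomial junction-count tables with a planted
exporter-dependent circRNA subset; and junction-spanning reads with decoys
and mate alignments for the EIciRNA call.  Every emitted object carries a
truth record, and identical parameters + seed give byte-identical bundles
(one child random stream per output, so adding a stream never perturbs the
others).
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .decompose import AnnotationSet, LoopCall
from .errors import CapacityError, ParameterError
from .intervals import Coverage, GenomicInterval, PeakSet

# Default per-condition loop counts.  The KO/WT totals (1810 vs 190 = 9.53x),
# the ~29x trans-ciR and ~15x WOT-liR increases mirror, at 1/10-ish scale,
# the class structure of the genome-wide decomposition the package targets.
DEFAULT_LOOP_COUNTS: dict[str, dict[str, int]] = {
    "WT": {"cis": 25, "trans": 10, "WAT": 120, "WOT": 35},
    "KO": {"cis": 160, "trans": 290, "WAT": 835, "WOT": 525},
}


@dataclass
class CovariateLinks:
    """Feature offsets distinguishing the export-dependent circRNA subset:
    longer, more abundant, lower-GC (multiplicative length factor, additive
    GC offset, additive log2 abundance offset)."""

    length_factor: float = 1.25
    gc_offset: float = -0.05
    log2_abundance_offset: float = 0.5


@dataclass
class SimulationParams:
    """All generator knobs, with desk-scale defaults.

    Loop intensities are log-normal on the log10 scale (``intensity_mu`` /
    ``intensity_sigma``); junction counts are negative-binomial with variance
    mu + dispersion*mu^2.  ``baseline_log2nc`` makes circRNAs cytoplasmic at
    baseline; in KO the export-dependent subset is shifted nucleus-ward by
    ``retention_effect`` log2 units.
    """

    seed: int = 0
    # genome / annotation
    n_chrom: int = 4
    chrom_len: int = 3_000_000
    n_genes: int = 400
    exons_per_gene: int = 3
    exon_len_mean: int = 400
    intron_len_mean: int = 800
    n_circ_loci: int = 300
    fpkm_meanlog: float = math.log(5.0)
    fpkm_sdlog: float = 1.0
    # loops
    loop_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_LOOP_COUNTS.items()}
    )
    loop_len_meanlog: float = math.log(400.0)
    loop_len_sdlog: float = 0.4
    loop_min_len: int = 150
    loop_spacing: int = 150
    anchor_overlap: int = 150
    avoid_margin: int = 60
    intensity_mu: float = 2.5   # log10 scale
    intensity_sigma: float = 0.5
    cir_lir_rho: float = 0.8
    replicate_jitter_sd: float = 0.0
    dropout: float = 0.0
    n_replicates: int = 2
    wat_expression_bias: float = 1.0
    # junction counts
    n_circ: int = 1000
    circ_len_meanlog: float = math.log(500.0)
    circ_len_sdlog: float = 0.6
    circ_min_len: int = 150
    gc_mean: float = 0.45
    gc_sd: float = 0.07
    abundance_meanlog: float = math.log(150.0)  # TPM scale
    abundance_sdlog: float = 0.8
    library_size: int = 2_000_000
    library_size_jitter: float = 0.1
    nb_dispersion: float = 0.1
    n_count_replicates: int = 4
    sensitive_fraction: float = 0.3
    retention_effect: float = 1.5
    baseline_log2nc: float = -1.6
    log2nc_sd: float = 0.1
    covariate_links: CovariateLinks = field(default_factory=CovariateLinks)
    # reads
    read_length: int = 60
    junction_flank: int = 40
    min_overhang: int = 8
    reads_per_circ: int = 5
    decoy_reads_per_circ: int = 3
    eicirna_fraction: float = 0.3

    def validate(self) -> None:
        if self.nb_dispersion <= 0:
            raise ParameterError("nb_dispersion must be positive")
        for p, name in (
            (self.dropout, "dropout"),
            (self.sensitive_fraction, "sensitive_fraction"),
            (self.eicirna_fraction, "eicirna_fraction"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if not -1.0 <= self.cir_lir_rho <= 1.0:
            raise ParameterError("cir_lir_rho must lie in [-1, 1]")
        if self.read_length < 2 * self.min_overhang:
            raise ParameterError("read_length must be ≥ 2×min_overhang")
        if self.junction_flank < self.min_overhang or self.read_length > 2 * self.junction_flank:
            raise ParameterError(
                "junction_flank must satisfy min_overhang ≤ flank and "
                "read_length ≤ 2×flank"
            )
        if any(v < 0 for c in self.loop_counts.values() for v in c.values()):
            raise ParameterError("loop counts must be nonnegative")


# fixed stream order; appending new streams never perturbs existing ones
_STREAMS = ("annotation", "genome", "loops", "counts", "reads", "qpcr", "pairs")


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _chrom_name(i: int) -> str:
    return f"chr{i + 1}"


# ---------------------------------------------------------------------------
# annotation + genome


def gen_annotation(params: SimulationParams) -> AnnotationSet:
    """Non-overlapping genes with exon/intron structure; circRNA loci sampled
    from exons of a gene subset; log-normal FPKM per gene."""
    params.validate()
    rng = _streams(params.seed)["annotation"]
    per_chrom = [params.n_genes // params.n_chrom] * params.n_chrom
    for i in range(params.n_genes % params.n_chrom):
        per_chrom[i] += 1
    transcripts: list[GenomicInterval] = []
    exons: dict[str, list[GenomicInterval]] = {}
    gene_idx = 0
    for ci in range(params.n_chrom):
        chrom = _chrom_name(ci)
        n = per_chrom[ci]
        if n == 0:
            continue
        # draw per-gene exon/intron lengths, then scatter genes along the chrom
        gene_parts = []
        for _ in range(n):
            ex = np.maximum(
                100, rng.normal(params.exon_len_mean, params.exon_len_mean * 0.2,
                                size=params.exons_per_gene)
            ).astype(int)
            intr = np.maximum(
                200, rng.normal(params.intron_len_mean, params.intron_len_mean * 0.2,
                                size=max(0, params.exons_per_gene - 1))
            ).astype(int)
            gene_parts.append((ex, intr))
        spans = [int(ex.sum() + intr.sum()) for ex, intr in gene_parts]
        free = params.chrom_len - sum(spans)
        if free < (n + 1) * 50:
            raise CapacityError(
                f"{chrom}: {n} genes do not fit in {params.chrom_len} bp"
            )
        gaps = rng.dirichlet(np.ones(n + 1)) * free
        pos = 0.0
        for g, (ex_lens, intr_lens) in enumerate(gene_parts):
            pos += gaps[g]
            start = int(pos)
            name = f"g{gene_idx:04d}"
            cursor = start
            gexons = []
            for k, el in enumerate(ex_lens):
                gexons.append(GenomicInterval(chrom, cursor, cursor + int(el), name=name))
                cursor += int(el)
                if k < len(intr_lens):
                    cursor += int(intr_lens[k])
            transcripts.append(GenomicInterval(chrom, start, cursor, name=name))
            exons[name] = gexons
            pos = float(cursor)
            gene_idx += 1
    if params.n_genes == 0:
        transcripts, exons = [], {}
    expression = {
        t.name: float(rng.lognormal(params.fpkm_meanlog, params.fpkm_sdlog))
        for t in transcripts
    }
    all_exons = [(gene, ex) for gene, exs in exons.items() for ex in exs]
    n_loci = min(params.n_circ_loci, len(all_exons))
    circ_loci = []
    if n_loci:
        chosen = rng.choice(len(all_exons), size=n_loci, replace=False)
        for j, idx in enumerate(sorted(int(i) for i in chosen)):
            gene, ex = all_exons[idx]
            circ_loci.append(
                GenomicInterval(ex.chrom, ex.start, ex.end, name=f"locus{j:03d}_{gene}")
            )
    ann = AnnotationSet(
        circ_loci=circ_loci, transcripts=transcripts, exons=exons,
        gene_expression=expression,
    )
    ann.validate()
    return ann


def gen_genome(params: SimulationParams) -> dict[str, str]:
    """Random A/C/G/T chromosomes; deterministic under the seed."""
    rng = _streams(params.seed)["genome"]
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = {}
    for ci in range(params.n_chrom):
        draws = rng.integers(0, 4, size=params.chrom_len)
        out[_chrom_name(ci)] = alphabet[draws].tobytes().decode("ascii")
    return out


# ---------------------------------------------------------------------------
# loops


@dataclass
class LoopTruthRecord:
    condition: str
    loop_class: str
    subclass: str
    chrom: str
    start: int
    end: int
    intensity: float
    present: tuple[bool, ...]  # per replicate, shared across treatments

    @property
    def detectable(self) -> bool:
        return all(self.present)


@dataclass
class LoopBundle:
    """Peak files, coverage and truth for one simulated DRIP experiment."""

    peaksets: dict[tuple[str, str, int], PeakSet]  # (condition, treatment, rep)
    coverages: dict[str, Coverage]                 # per condition
    truth: list[LoopTruthRecord]
    spikein_counts: dict[str, float]
    params: SimulationParams

    def truth_counts(self, condition: str, detectable_only: bool = False) -> dict[str, int]:
        recs = [
            t for t in self.truth
            if t.condition == condition and (t.detectable or not detectable_only)
        ]
        return {
            "ciR_loop": sum(1 for t in recs if t.loop_class == "ciR_loop"),
            "liR_loop": sum(1 for t in recs if t.loop_class == "liR_loop"),
            "cis": sum(1 for t in recs if t.subclass == "cis"),
            "trans": sum(1 for t in recs if t.subclass == "trans"),
            "WAT": sum(1 for t in recs if t.subclass == "WAT"),
            "WOT": sum(1 for t in recs if t.subclass == "WOT"),
        }

    def truth_loops(self, condition: str) -> list[LoopCall]:
        return [
            LoopCall(
                GenomicInterval(t.chrom, t.start, t.end, score=t.intensity),
                t.loop_class, t.subclass, t.intensity, t.condition,
            )
            for t in self.truth if t.condition == condition
        ]


class _Occupancy:
    """Sorted, non-overlapping placement bookkeeping with a spacing margin."""

    def __init__(self, spacing: int):
        self.spacing = spacing
        self.starts: dict[str, list[int]] = {}
        self.ends: dict[str, list[int]] = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        starts = self.starts.get(chrom)
        if not starts:
            return True
        ends = self.ends[chrom]
        k = bisect.bisect_left(starts, start)
        if k > 0 and ends[k - 1] + self.spacing > start:
            return False
        if k < len(starts) and starts[k] < end + self.spacing:
            return False
        return True

    def add(self, chrom: str, start: int, end: int) -> None:
        starts = self.starts.setdefault(chrom, [])
        ends = self.ends.setdefault(chrom, [])
        k = bisect.bisect_left(starts, start)
        starts.insert(k, start)
        ends.insert(k, end)


def _merged_arrays(
    intervals: Sequence[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    from .intervals import merge

    per: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[GenomicInterval]] = {}
    for iv in merge(intervals, 0):
        grouped.setdefault(iv.chrom, []).append(iv)
    for chrom, ivs in grouped.items():
        per[chrom] = (
            np.array([i.start for i in ivs]), np.array([i.end for i in ivs])
        )
    return per


def _hits(
    merged: Mapping[str, tuple[np.ndarray, np.ndarray]],
    chrom: str, start: int, end: int, margin: int = 0,
) -> bool:
    if chrom not in merged:
        return False
    s, e = merged[chrom]
    k = int(np.searchsorted(e, start - margin, side="right"))
    return k < s.size and s[k] < end + margin


def gen_loops(params: SimulationParams, annotation: AnnotationSet) -> LoopBundle:
    """Plant ciR/liR loops per condition and emit replicate peak files.

    cis ciR-loops overlap a circRNA locus by ≥ anchor_overlap bases; trans
    ciR-loops keep ≥ avoid_margin bases clear of every circRNA locus; WAT
    liR-loops overlap transcripts (genes drawn with probability ∝
    FPKM^wat_expression_bias); WOT liR-loops keep clear of transcripts.  All
    loops of one condition are mutually separated by ≥ loop_spacing bases so
    the decomposition is exactly invertible at zero jitter.  RNase-R-treated
    replicate files contain exactly the (perturbed) ciR-loops; untreated
    files contain ciR ∪ liR.  The dropout event of a peak in a replicate is
    shared between the treated and untreated libraries of that replicate
    (both derive from the same culture).
    """
    params.validate()
    rng = _streams(params.seed)["loops"]
    circ_merged = _merged_arrays(annotation.circ_loci)
    tx_merged = _merged_arrays(annotation.transcripts)
    chroms = [_chrom_name(i) for i in range(params.n_chrom)]

    genes = list(annotation.transcripts)
    if genes:
        w = np.array(
            [annotation.gene_expression.get(g.name, 1.0) for g in genes], dtype=float
        ) ** params.wat_expression_bias
        gene_p = w / w.sum()
    truth: list[LoopTruthRecord] = []

    def draw_len() -> int:
        return max(
            params.loop_min_len,
            int(rng.lognormal(params.loop_len_meanlog, params.loop_len_sdlog)),
        )

    def place_overlapping(target: GenomicInterval, occ: _Occupancy) -> tuple[str, int, int] | None:
        length = draw_len()
        anchor = min(params.anchor_overlap, target.length, length)
        lo = target.start - (length - anchor)
        hi = target.end - anchor
        for _ in range(40):
            start = int(rng.integers(lo, hi + 1))
            start = max(0, start)
            end = min(start + length, params.chrom_len)
            if end - start < params.loop_min_len:
                continue
            # re-check the anchor after clamping
            ol = min(end, target.end) - max(start, target.start)
            if ol < min(anchor, end - start):
                continue
            if occ.free(target.chrom, start, end):
                return target.chrom, start, end
        return None

    def place_avoiding(forbidden, occ: _Occupancy) -> tuple[str, int, int] | None:
        length = draw_len()
        for _ in range(300):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, params.chrom_len - length))
            end = start + length
            if _hits(forbidden, chrom, start, end, margin=params.avoid_margin):
                continue
            if occ.free(chrom, start, end):
                return chrom, start, end
        return None

    for cond, counts in params.loop_counts.items():
        occ = _Occupancy(params.loop_spacing)
        planted: list[tuple[str, str, str, int, int]] = []
        # cis ciR-loops on circRNA loci
        for _ in range(counts.get("cis", 0)):
            spot = None
            for _ in range(60):
                if not annotation.circ_loci:
                    break
                target = annotation.circ_loci[int(rng.integers(0, len(annotation.circ_loci)))]
                spot = place_overlapping(target, occ)
                if spot:
                    break
            if spot is None:
                raise CapacityError(f"{cond}: cannot place cis ciR-loop")
            occ.add(*spot)
            planted.append(("ciR_loop", "cis") + spot)
        # trans ciR-loops clear of circRNA loci
        for _ in range(counts.get("trans", 0)):
            spot = place_avoiding(circ_merged, occ)
            if spot is None:
                raise CapacityError(f"{cond}: cannot place trans ciR-loop")
            occ.add(*spot)
            planted.append(("ciR_loop", "trans") + spot)
        # WAT liR-loops on transcripts
        for _ in range(counts.get("WAT", 0)):
            spot = None
            for _ in range(60):
                if not genes:
                    break
                target = genes[int(rng.choice(len(genes), p=gene_p))]
                spot = place_overlapping(target, occ)
                if spot:
                    break
            if spot is None:
                raise CapacityError(f"{cond}: cannot place WAT liR-loop")
            occ.add(*spot)
            planted.append(("liR_loop", "WAT") + spot)
        # WOT liR-loops clear of transcripts
        for _ in range(counts.get("WOT", 0)):
            spot = place_avoiding(tx_merged, occ)
            if spot is None:
                raise CapacityError(f"{cond}: cannot place WOT liR-loop")
            occ.add(*spot)
            planted.append(("liR_loop", "WOT") + spot)
        for loop_class, subclass, chrom, start, end in planted:
            intensity = float(10.0 ** rng.normal(params.intensity_mu, params.intensity_sigma))
            present = tuple(
                bool(rng.random() >= params.dropout)
                for _ in range(params.n_replicates)
            )
            truth.append(
                LoopTruthRecord(cond, loop_class, subclass, chrom, start, end,
                                intensity, present)
            )

    # replicate peak files with boundary jitter; dropout shared per replicate
    peaksets: dict[tuple[str, str, int], PeakSet] = {}
    for cond in params.loop_counts:
        recs = [t for t in truth if t.condition == cond]
        for rep in range(params.n_replicates):
            jittered: dict[int, GenomicInterval | None] = {}
            for i, t in enumerate(recs):
                if not t.present[rep]:
                    jittered[i] = None
                    continue
                if params.replicate_jitter_sd > 0:
                    js = int(round(rng.normal(0, params.replicate_jitter_sd)))
                    je = int(round(rng.normal(0, params.replicate_jitter_sd)))
                else:
                    js = je = 0
                s = max(0, t.start + js)
                e = min(params.chrom_len, t.end + je)
                if e - s < 20:
                    mid = (t.start + t.end) // 2
                    s, e = max(0, mid - 10), min(params.chrom_len, mid + 10)
                jittered[i] = GenomicInterval(t.chrom, s, e)
            for treatment in ("none", "RNaseR"):
                ivs = [
                    jittered[i]
                    for i, t in enumerate(recs)
                    if jittered[i] is not None
                    and (treatment == "none" or t.loop_class == "ciR_loop")
                ]
                peaksets[(cond, treatment, rep + 1)] = PeakSet(
                    sorted(ivs, key=lambda iv: (iv.chrom, iv.start)),
                    sample_id=f"{cond}_{treatment}_rep{rep + 1}",
                    condition=cond,
                    treatment=treatment,
                )

    coverages = {
        cond: Coverage.from_records(
            sorted(
                (t.chrom, t.start, t.end, t.intensity / (t.end - t.start))
                for t in truth if t.condition == cond
            )
        )
        for cond in params.loop_counts
    }
    spikein = {
        f"{cond}_{treatment}": 1_000_000.0
        for cond in params.loop_counts for treatment in ("none", "RNaseR")
    }
    return LoopBundle(peaksets, coverages, truth, spikein, params)


def gen_correlated_pairs(
    params: SimulationParams,
    n_pairs: int = 500,
    rho: float | None = None,
    condition: str = "KO",
) -> tuple[list[LoopCall], list[LoopCall]]:
    """Overlapping ciR/liR loop pairs with correlated log10 intensities.

    Emulates the intensity comparison at genomic regions where both loop
    types are seen: pair i occupies a private 1 kb slot on a dedicated
    chromosome, the liR interval overlapping the ciR interval by 200 bp, and
    (log10 ciR, log10 liR) intensities are bivariate normal with correlation
    ``rho`` (default ``params.cir_lir_rho``).
    """
    rng = _streams(params.seed)["pairs"]
    rho = params.cir_lir_rho if rho is None else rho
    if not -1.0 <= rho <= 1.0:
        raise ParameterError("rho must lie in [-1, 1]")
    mu = params.intensity_mu
    sig = params.intensity_sigma
    x = rng.standard_normal(n_pairs)
    y = rng.standard_normal(n_pairs)
    z = np.column_stack(
        [mu + sig * x, mu + sig * (rho * x + math.sqrt(1.0 - rho * rho) * y)]
    )
    cir, lir = [], []
    for i in range(n_pairs):
        base = i * 1000
        ci = GenomicInterval("pairchr", base, base + 400)
        li = GenomicInterval("pairchr", base + 200, base + 700)
        cir.append(LoopCall(ci, "ciR_loop", "none",
                            float(10.0 ** z[i, 0]), condition))
        lir.append(LoopCall(li, "liR_loop", "none",
                            float(10.0 ** z[i, 1]), condition))
    return cir, lir


# ---------------------------------------------------------------------------
# junction counts


@dataclass
class CountsTruth:
    """Per-circRNA generating values for the enrichment analysis."""

    table: pd.DataFrame  # circ_id, sensitive, log2nc_wt, log2nc_ko, length, gc, abundance_tpm
    params: SimulationParams

    @property
    def sensitive_ids(self) -> set[str]:
        return set(self.table.loc[self.table["sensitive"], "circ_id"])


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with variance mean + dispersion*mean^2."""
    mean = np.clip(np.asarray(mean, dtype=float), 1e-9, None)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def gen_counts(
    params: SimulationParams,
) -> tuple["JunctionCountTable", CountsTruth, list["CircRNARecord"]]:
    """Simulate junction-count tables for WT and KO, nuclear/cytoplasmic/total.

    Baseline abundance is log-normal (TPM scale); each circRNA's true
    log2(Nuc/Cyto) is normal around ``baseline_log2nc``; the planted
    export-dependent subset is shifted by ``retention_effect`` in KO only and
    carries the covariate links (longer, more abundant, lower GC).  Replicate
    counts are negative binomial with the configured dispersion.
    """
    from .localization import CircRNARecord, JunctionCountTable

    params.validate()
    rng = _streams(params.seed)["counts"]
    n = params.n_circ
    if n < 1:
        raise ParameterError("n_circ must be ≥1")
    ids = [f"circ{i:04d}" for i in range(n)]
    n_sens = int(round(n * params.sensitive_fraction))
    sensitive = np.zeros(n, dtype=bool)
    sensitive[rng.choice(n, size=n_sens, replace=False)] = True

    links = params.covariate_links
    length = np.maximum(
        params.circ_min_len,
        rng.lognormal(params.circ_len_meanlog, params.circ_len_sdlog, size=n),
    )
    length = np.where(sensitive, length * links.length_factor, length).astype(int)
    gc = np.clip(
        rng.normal(params.gc_mean, params.gc_sd, size=n)
        + np.where(sensitive, links.gc_offset, 0.0),
        0.15, 0.85,
    )
    abundance = rng.lognormal(params.abundance_meanlog, params.abundance_sdlog, size=n)
    abundance = np.where(
        sensitive, abundance * 2.0 ** links.log2_abundance_offset, abundance
    )
    log2nc = rng.normal(params.baseline_log2nc, params.log2nc_sd, size=n)
    log2nc_wt = log2nc
    log2nc_ko = log2nc + np.where(sensitive, params.retention_effect, 0.0)

    rows = []
    library_sizes: dict[str, int] = {}
    for cond, r in (("WT", log2nc_wt), ("KO", log2nc_ko)):
        share = 2.0 ** r / (1.0 + 2.0 ** r)  # nuclear fraction of molecules
        comp_tpm = {
            "nuclear": 2.0 * abundance * share,
            "cytoplasmic": 2.0 * abundance * (1.0 - share),
            "total": abundance,
        }
        for comp in ("nuclear", "cytoplasmic", "total"):
            for rep in range(1, params.n_count_replicates + 1):
                lib = int(round(
                    params.library_size
                    * float(rng.lognormal(0.0, params.library_size_jitter))
                ))
                key = JunctionCountTable.sample_key(cond, comp, rep)
                library_sizes[key] = lib
                mean = comp_tpm[comp] * lib / 1e6
                counts = _nb_draw(rng, mean, params.nb_dispersion)
                rows.extend(
                    {"circ_id": cid, "condition": cond, "compartment": comp,
                     "replicate": rep, "count": int(c)}
                    for cid, c in zip(ids, counts)
                )
    table = JunctionCountTable(pd.DataFrame(rows), library_sizes)
    truth = CountsTruth(
        pd.DataFrame(
            {"circ_id": ids, "sensitive": sensitive,
             "log2nc_wt": log2nc_wt, "log2nc_ko": log2nc_ko,
             "length": length, "gc": gc, "abundance_tpm": abundance}
        ),
        params,
    )
    records = [
        CircRNARecord(cid, length=int(L), gc=float(g))
        for cid, L, g in zip(ids, length, gc)
    ]
    return table, truth, records


# ---------------------------------------------------------------------------
# reads + mates


@dataclass
class ReadBundle:
    """Junction library, reads, mate alignments and truth for counting tests."""

    junction_library: dict[str, str]
    junction_centers: dict[str, int]
    reads: list[tuple[str, str]]                  # (read_id, sequence)
    emitted_counts: dict[str, int]                # junction reads per circRNA
    mate_alignments: dict[str, list[GenomicInterval]]
    host_loci: dict[str, GenomicInterval]
    host_exons: dict[str, list[GenomicInterval]]
    intronic_mate: dict[str, bool]
    mature_sequences: dict[str, str]


def gen_reads(
    params: SimulationParams,
    n_circ: int | None = None,
) -> ReadBundle:
    """Emit junction-spanning reads, colinear decoys, and BSJ mate alignments.

    Each circRNA gets a random mature sequence of its drawn length, a
    junction-spanning library entry (``junction_flank`` bases either side of
    the back-splice point), ``reads_per_circ`` true junction reads with
    random overhangs ≥ min_overhang, and ``decoy_reads_per_circ`` colinear
    reads from the sequence interior that never cross the junction.  Mates
    are placed in an exon or an intron of a two-exon host model according to
    a truth flag drawn with probability ``eicirna_fraction``.
    """
    params.validate()
    rng = _streams(params.seed)["reads"]
    n = n_circ if n_circ is not None else min(params.n_circ, 50)
    L = params.read_length
    flank = params.junction_flank
    bases = np.array(list("ACGT"))
    library: dict[str, str] = {}
    centers: dict[str, int] = {}
    reads: list[tuple[str, str]] = []
    emitted: dict[str, int] = {}
    mates: dict[str, list[GenomicInterval]] = {}
    host_loci: dict[str, GenomicInterval] = {}
    host_exons: dict[str, list[GenomicInterval]] = {}
    intronic: dict[str, bool] = {}
    matures: dict[str, str] = {}
    for i in range(n):
        cid = f"circ{i:04d}"
        seq_len = max(
            params.circ_min_len, L + 2 * flank,
            int(rng.lognormal(params.circ_len_meanlog, params.circ_len_sdlog)),
        )
        seq = "".join(rng.choice(bases, size=seq_len))
        matures[cid] = seq
        junction = seq[-flank:] + seq[:flank]
        library[cid] = junction
        centers[cid] = flank
        # junction reads: left overhang o, read spans [center-o, center-o+L)
        k = params.reads_per_circ
        emitted[cid] = k
        doubled = seq[-L:] + seq[:L]
        # the overhang must stay within the library flank on both sides so
        # every emitted read is recoverable by junction-window matching
        o_lo = max(params.min_overhang, L - flank)
        o_hi = min(L - params.min_overhang, flank)
        for j in range(k):
            o = int(rng.integers(o_lo, o_hi + 1))
            read = doubled[L - o : 2 * L - o]
            reads.append((f"{cid}_junc{j}", read))
        # colinear decoys: interior windows, ≥ L away from both ends impossible
        # for short circles, so keep ≥ flank away from both ends
        interior_lo = flank
        interior_hi = seq_len - flank - L
        for j in range(params.decoy_reads_per_circ):
            if interior_hi <= interior_lo:
                break
            s = int(rng.integers(interior_lo, interior_hi + 1))
            reads.append((f"{cid}_decoy{j}", seq[s : s + L]))
        # two-exon host model on a private chromosome
        chrom = f"host_{cid}"
        e1 = GenomicInterval(chrom, 1000, 1000 + 400, name=cid)
        intron = (e1.end, e1.end + 600)
        e2 = GenomicInterval(chrom, intron[1], intron[1] + 400, name=cid)
        host_loci[cid] = GenomicInterval(chrom, e1.start, e2.end, name=cid)
        host_exons[cid] = [e1, e2]
        is_ei = bool(rng.random() < params.eicirna_fraction)
        intronic[cid] = is_ei
        if is_ei:
            s = int(rng.integers(intron[0], intron[1] - 100))
            mates[cid] = [GenomicInterval(chrom, s, s + 100, name=cid)]
        else:
            s = int(rng.integers(e1.start, e1.end - 100))
            mates[cid] = [GenomicInterval(chrom, s, s + 100, name=cid)]
    order = rng.permutation(len(reads))
    reads = [reads[int(j)] for j in order]
    return ReadBundle(library, centers, reads, emitted, mates, host_loci,
                      host_exons, intronic, matures)


# ---------------------------------------------------------------------------
# qPCR


def gen_qpcr(params: SimulationParams, n_targets: int = 8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ct tables with known fold changes.

    Returns (table, truth): the table has antibody/IgG and nuclear/cytoplasmic
    Ct values per target; the truth holds the generating folds.
    """
    rng = _streams(params.seed)["qpcr"]
    rows, truth_rows = [], []
    for i in range(n_targets):
        target = f"target{i:02d}"
        fold = float(rng.lognormal(1.0, 0.6))
        ct_igg = float(rng.uniform(28, 32))
        ct_ab = ct_igg - math.log2(fold)
        nc_ratio = float(rng.lognormal(0.0, 0.8))
        ct_cyto = float(rng.uniform(22, 26))
        ct_nuc = ct_cyto - math.log2(nc_ratio)
        rows.append({"target": target, "ct_antibody": round(ct_ab, 3),
                     "ct_igg": round(ct_igg, 3), "ct_nuclear": round(ct_nuc, 3),
                     "ct_cytoplasmic": round(ct_cyto, 3)})
        truth_rows.append({"target": target, "rip_fold": fold, "nc_ratio": nc_ratio})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# truth serialization


def truth_to_json(bundle: LoopBundle, counts_truth: CountsTruth | None = None) -> str:
    payload = {
        "params": _params_dict(bundle.params),
        "loops": [
            {"condition": t.condition, "class": t.loop_class,
             "subclass": t.subclass, "chrom": t.chrom, "start": t.start,
             "end": t.end, "intensity": t.intensity,
             "present": list(t.present)}
            for t in bundle.truth
        ],
    }
    if counts_truth is not None:
        payload["circ"] = counts_truth.table.to_dict(orient="records")
    return json.dumps(payload, sort_keys=True, indent=1, default=_json_default)


def _params_dict(params: SimulationParams) -> dict:
    return asdict(params)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
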