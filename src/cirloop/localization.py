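"""CircRNA quantification from back-splice junction reads and
nucleocytoplasmic enrichment analysis.

A circRNA is identified by its back-splice junction (BSJ), the non-colinear
donor–acceptor joint: a read counts toward a circRNA only when it crosses
the junction point with a minimum anchored overhang on both sides, so
colinear host-gene reads never count.  Junction counts are TPM-normalized,
replicate detections are intersected, and per-circRNA nuclear vs cytoplasmic
enrichment is tested with Welch's t on log2(TPM + pseudocount).  A circRNA is
called cytoplasmic when log2(Nuc/Cyto) < -0.3 with p < 0.05 and nuclear when
log2(Nuc/Cyto) > 0.3 with p < 0.05 (strict inequalities); everything else is
unclassified.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .intervals import GenomicInterval, intersect, subtract

LOG2_CUTOFF = 0.3
ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_MIN_OVERHANG = 8

_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")


def gc_content(sequence: str) -> float:
    seq = sequence.upper()
    if not seq:
        raise ValidationError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircRNARecord:
    """A circRNA: coordinates, mature sequence and derived features."""

    circ_id: str
    locus: GenomicInterval | None = None
    mature_sequence: str | None = None
    length: int | None = None
    gc: float | None = None
    fold_proxy: int | None = None
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if self.mature_sequence is not None:
            seq = self.mature_sequence.upper().replace("U", "T")
            if set(seq) - set("ACGTN"):
                raise ValidationError(f"{self.circ_id}: invalid sequence characters")
            self.mature_sequence = seq
            if self.length is None:
                self.length = len(seq)
            elif self.length != len(seq):
                raise ValidationError(f"{self.circ_id}: length != |sequence|")
            if self.gc is None:
                self.gc = gc_content(seq)
        if self.length is not None and self.length <= 0:
            raise ValidationError(f"{self.circ_id}: nonpositive length")


@dataclass
class JunctionCountTable:
    """Junction read counts per (circ_id, condition, compartment, replicate).

    ``counts`` is a long-form DataFrame with those columns plus ``count``;
    ``library_sizes`` maps sample keys "<condition>_<compartment>_rep<k>" to
    total clean reads (the TPM denominator).
    """

    counts: pd.DataFrame
    library_sizes: dict[str, int] = field(default_factory=dict)

    REQUIRED = ("circ_id", "condition", "compartment", "replicate", "count")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.counts.columns)
        if missing:
            raise ValidationError(f"count table missing columns {sorted(missing)}")
        if (self.counts["count"] < 0).any():
            raise ValidationError("negative junction counts")

    @staticmethod
    def sample_key(condition: str, compartment: str, replicate: int) -> str:
        return f"{condition}_{compartment}_rep{replicate}"

    def with_tpm(self) -> pd.DataFrame:
        df = self.counts.copy()
        keys = [
            self.sample_key(c, m, r)
            for c, m, r in zip(df["condition"], df["compartment"], df["replicate"])
        ]
        libs = np.array([self.library_sizes[k] for k in keys], dtype=float)
        if (libs <= 0).any():
            raise ParameterError("library sizes must be positive")
        df["tpm"] = df["count"].to_numpy(dtype=float) / libs * 1e6
        return df


def tpm_normalize(counts, library_size: float):
    """TPM_i = count_i / library_size × 1e6 (junction-read convention)."""
    if library_size <= 0:
        raise ParameterError(f"library size must be positive, got {library_size}")
    arr = np.asarray(counts, dtype=float)
    out = arr / library_size * 1e6
    if np.isscalar(counts) or arr.ndim == 0:
        return float(out)
    return out


def build_junction_index(
    junction_library: Mapping[str, str],
    read_length: int,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    centers: Mapping[str, int] | None = None,
) -> dict[str, list[str]]:
    """Map every junction-spanning window of length ``read_length`` to the
    circRNAs it identifies.

    A window of the junction sequence starting at offset i spans the junction
    point c with ≥ ``min_overhang`` bases on each side iff
    i ≤ c - min_overhang and i + read_length ≥ c + min_overhang.
    """
    if min_overhang < 1:
        raise ParameterError("min_overhang must be ≥1")
    index: dict[str, list[str]] = {}
    for circ_id, seq in junction_library.items():
        seq = seq.upper().replace("U", "T")
        c = (centers or {}).get(circ_id, len(seq) // 2)
        lo = max(0, c + min_overhang - read_length)
        hi = min(len(seq) - read_length, c - min_overhang)
        for i in range(lo, hi + 1):
            window = seq[i : i + read_length]
            index.setdefault(window, []).append(circ_id)
    return index


def count_junctions(
    reads: Iterable[str],
    junction_library: Mapping[str, str],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    centers: Mapping[str, int] | None = None,
    strand_unaware: bool = True,
) -> dict[str, int]:
    """Count reads crossing each circRNA's back-splice junction.

    A read increments a circRNA iff it matches the junction-spanning sequence
    with ≥ ``min_overhang`` matched bases on each side of the junction point;
    reads matching only colinear sequence never count.  With
    ``strand_unaware`` (default) the reverse complement is also tried.
    """
    counts = {circ_id: 0 for circ_id in junction_library}
    indexes: dict[int, dict[str, list[str]]] = {}
    skipped = 0
    for read in reads:
        read = read.upper().replace("U", "T")
        if len(read) < 2 * min_overhang:
            skipped += 1
            continue
        idx = indexes.get(len(read))
        if idx is None:
            idx = build_junction_index(
                junction_library, len(read), min_overhang, centers
            )
            indexes[len(read)] = idx
        hits = idx.get(read)
        if hits is None and strand_unaware:
            hits = idx.get(_revcomp(read))
        for circ_id in hits or ():
            counts[circ_id] += 1
    if skipped:
        warnings.warn(
            f"skipped {skipped} reads shorter than 2×min_overhang={2*min_overhang}"
        )
    return counts


def merge_replicates(
    rep1: Mapping[str, int],
    rep2: Mapping[str, int],
    min_count: int = 1,
) -> dict[str, tuple[int, int]]:
    """Keep circRNAs detected (count ≥ ``min_count``) in both replicates."""
    keep = {
        cid
        for cid in set(rep1) & set(rep2)
        if rep1[cid] >= min_count and rep2[cid] >= min_count
    }
    if not keep:
        warnings.warn("no circRNA detected in both replicates")
    return {cid: (rep1[cid], rep2[cid]) for cid in sorted(keep)}


class NucCytoStat(NamedTuple):
    log2_ratio: float
    p: float


def nuc_cyto_stat(
    nuc_tpm: Sequence[float],
    cyto_tpm: Sequence[float],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> NucCytoStat:
    """log2 Nuc/Cyto ratio and Welch-t p-value on log2(TPM+pseudocount).

    Antisymmetric: swapping compartments negates the ratio, p is unchanged.
    """
    nuc = np.asarray(nuc_tpm, dtype=float)
    cyto = np.asarray(cyto_tpm, dtype=float)
    if nuc.size < 2 or cyto.size < 2:
        raise ParameterError("need ≥2 replicates per compartment")
    if pseudocount <= 0:
        raise ParameterError("pseudocount must be positive")
    ln = np.log2(nuc + pseudocount)
    lc = np.log2(cyto + pseudocount)
    ratio = float(ln.mean() - lc.mean())
    if ln.var() == 0 and lc.var() == 0:
        p = 1.0 if ratio == 0 else 0.0
    else:
        p = float(stats.ttest_ind(ln, lc, equal_var=False).pvalue)
    return NucCytoStat(ratio, p)


def classify_localization(log2_ratio: float, p: float) -> str:
    """Three-way localization call with strict threshold inequalities."""
    if p < ALPHA and log2_ratio < -LOG2_CUTOFF:
        return "cytoplasmic"
    if p < ALPHA and log2_ratio > LOG2_CUTOFF:
        return "nuclear"
    return "unclassified"


@dataclass
class SensitivityAssignment:
    """Condition-wise export-sensitivity sets.

    ``sensitive`` = cytoplasmic in WT; ``insensitive`` = cytoplasmic in KO
    (a circRNA cytoplasmic in both belongs to both sets, the default
    reporting convention).  ``sensitive_only``/``insensitive_only`` are the
    exclusive versions, of which ``sensitive_only`` — cytoplasmically
    enriched only while the exporter is present — is the natural predicted
    export-dependent set.
    """

    sensitive: set[str]
    insensitive: set[str]
    labels: dict[str, tuple[str, ...]]
    export_dependent: set[str] = field(default_factory=set)

    @property
    def sensitive_only(self) -> set[str]:
        return self.sensitive - self.insensitive

    @property
    def insensitive_only(self) -> set[str]:
        return self.insensitive - self.sensitive


def sensitivity_sets(
    class_wt: Mapping[str, str],
    class_ko: Mapping[str, str],
    precedence: str = "both",
    ratio_wt: Mapping[str, float] | None = None,
    ratio_ko: Mapping[str, float] | None = None,
) -> SensitivityAssignment:
    """Assign XPO4 sensitivity labels from per-condition localization calls.

    ``precedence`` controls the flat label of circRNAs cytoplasmic in both
    conditions: "both" (default; reported in both sets), "sensitive", or
    "insensitive".

    When the per-condition log2(Nuc/Cyto) point estimates are supplied, the
    ``export_dependent`` set refines ``sensitive`` with a half-recovery rule:
    a circRNA is export-dependent when it is cytoplasmic in WT and its KO
    ratio has recovered at least half of the WT cytoplasmic enrichment
    (log2 ratio_KO > log2 ratio_WT / 2).  The point-estimate rule is far less
    sensitive to single t-test failures than requiring a localization-class
    flip, because the KO p-value no longer gates the call.  Without ratios,
    ``export_dependent`` falls back to ``sensitive - insensitive``.
    """
    if precedence not in ("both", "sensitive", "insensitive"):
        raise ParameterError(f"unknown precedence {precedence!r}")
    universe = set(class_wt) | set(class_ko)
    sensitive = {c for c in universe if class_wt.get(c) == "cytoplasmic"}
    insensitive = {c for c in universe if class_ko.get(c) == "cytoplasmic"}
    labels: dict[str, tuple[str, ...]] = {}
    for c in sorted(universe):
        in_s, in_i = c in sensitive, c in insensitive
        if in_s and in_i:
            if precedence == "sensitive":
                labels[c] = ("XPO4_sensitive",)
            elif precedence == "insensitive":
                labels[c] = ("XPO4_insensitive",)
            else:
                labels[c] = ("XPO4_sensitive", "XPO4_insensitive")
        elif in_s:
            labels[c] = ("XPO4_sensitive",)
        elif in_i:
            labels[c] = ("XPO4_insensitive",)
        else:
            labels[c] = ("other",)
    if ratio_wt is not None and ratio_ko is not None:
        export_dependent = {
            c for c in sensitive
            if c in ratio_wt and c in ratio_ko
            and ratio_ko[c] > ratio_wt[c] / 2.0
        }
    else:
        export_dependent = sensitive - insensitive
    return SensitivityAssignment(sensitive, insensitive, labels, export_dependent)


@dataclass(frozen=True)
class EnrichmentResult:
    circ_id: str
    log2_ratio: float
    p_value: float
    localization: str
    sensitivity: str = "NA"


def enrichment_analysis(
    table: JunctionCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_count: int = 1,
    precedence: str = "both",
) -> tuple[pd.DataFrame, SensitivityAssignment]:
    """Per-circRNA Nuc/Cyto enrichment for every condition in the table.

    Replicate detections within each compartment are intersected
    (``min_count`` junction reads in each replicate) before testing; a BH-FDR
    column (``p_adj``) is emitted for convenience, but the localization calls
    use the raw p < 0.05 threshold.
    """
    df = table.with_tpm()
    conditions = sorted(df["condition"].unique(), reverse=True)
    rows = []
    per_cond_class: dict[str, dict[str, str]] = {}
    for cond in conditions:
        sub = df[df["condition"] == cond]
        detected: set[str] | None = None
        for comp in ("nuclear", "cytoplasmic"):
            csub = sub[sub["compartment"] == comp]
            piv = csub.pivot_table(
                index="circ_id", columns="replicate", values="count", fill_value=0
            )
            # detection = ≥ min_count junction reads in every replicate
            comp_ids = set(piv.index[(piv >= min_count).all(axis=1)])
            detected = comp_ids if detected is None else (detected & comp_ids)
        piv_n = (
            sub[sub["compartment"] == "nuclear"]
            .pivot_table(index="circ_id", columns="replicate", values="tpm")
        )
        piv_c = (
            sub[sub["compartment"] == "cytoplasmic"]
            .pivot_table(index="circ_id", columns="replicate", values="tpm")
        )
        ids = sorted((detected or set()) & set(piv_n.index) & set(piv_c.index))
        if not ids:
            per_cond_class[cond] = {}
            continue
        nuc = np.log2(piv_n.loc[ids].to_numpy(dtype=float) + pseudocount)
        cyt = np.log2(piv_c.loc[ids].to_numpy(dtype=float) + pseudocount)
        ratio = nuc.mean(axis=1) - cyt.mean(axis=1)
        res = stats.ttest_ind(nuc, cyt, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
        degenerate = np.isnan(pvals)
        pvals[degenerate & (ratio == 0)] = 1.0
        pvals[degenerate & (ratio != 0)] = 0.0
        p_adj = stats.false_discovery_control(np.clip(pvals, 0, 1))
        calls = {
            cid: classify_localization(float(r), float(p))
            for cid, r, p in zip(ids, ratio, pvals)
        }
        per_cond_class[cond] = calls
        for cid, r, p, pa in zip(ids, ratio, pvals, p_adj):
            rows.append(
                {"circ_id": cid, "condition": cond, "log2_ratio": float(r),
                 "p_value": float(p), "p_adj": float(pa),
                 "localization": calls[cid]}
            )
    per_cond_ratio: dict[str, dict[str, float]] = {}
    for row in rows:
        per_cond_ratio.setdefault(row["condition"], {})[row["circ_id"]] = row["log2_ratio"]
    assignment = sensitivity_sets(
        per_cond_class.get("WT", {}), per_cond_class.get("KO", {}),
        precedence=precedence,
        ratio_wt=per_cond_ratio.get("WT"), ratio_ko=per_cond_ratio.get("KO"),
    )
    out = pd.DataFrame(
        rows, columns=["circ_id", "condition", "log2_ratio", "p_value",
                       "p_adj", "localization"],
    )
    if not out.empty:
        out["sensitivity"] = [
            "|".join(assignment.labels.get(cid, ("NA",)))
            for cid in out["circ_id"]
        ]
    return out, assignment


FEATURES = ("length", "tpm", "gc", "fold_proxy")


class FeatureComparison(NamedTuple):
    stats: pd.DataFrame
    curves: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]


def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.sort(values)
    return x, np.arange(1, x.size + 1) / x.size


def feature_compare(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    features: Sequence[str] = FEATURES,
) -> FeatureComparison:
    """Two-sample KS and Welch t per feature, plus cumulative-fraction curves.

    ``group_a``/``group_b`` are DataFrames with one row per circRNA and the
    requested feature columns (length, expression TPM, GC, pairing proxy).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("each group needs ≥2 circRNAs")
    rows = []
    curves: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for feat in features:
        if feat not in group_a.columns or feat not in group_b.columns:
            continue
        a = group_a[feat].dropna().to_numpy(dtype=float)
        b = group_b[feat].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            continue
        ks = stats.ks_2samp(a, b, method="asymp")
        tt = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {"feature": feat, "ks_stat": float(ks.statistic),
             "ks_p": float(min(ks.pvalue, 1.0)),
             "t_p": float(tt.pvalue) if not math.isnan(tt.pvalue) else 1.0,
             "mean_a": float(a.mean()), "mean_b": float(b.mean()),
             "n_a": int(a.size), "n_b": int(b.size)}
        )
        curves[feat] = {"a": _ecdf(a), "b": _ecdf(b)}
    return FeatureComparison(pd.DataFrame(rows), curves)


_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _can_pair(x: str, y: str) -> bool:
    return (x, y) in _PAIRS


def fold_proxy(sequence: str, min_loop: int = 3) -> int:
    """Maximum number of nested Watson–Crick/GU base pairs (Nussinov DP).

    A structural-stability proxy: more attainable pairs ≈ lower folding free
    energy.  Hairpin loops must span ≥ ``min_loop`` unpaired bases, i.e. a
    pair (i, j) requires j - i > min_loop.
    """
    if min_loop < 0:
        raise ParameterError("min_loop must be nonnegative")
    seq = sequence.upper().replace("T", "U")
    if set(seq) - set("ACGU"):
        raise ValidationError("sequence must be over A/C/G/U (or T)")
    n = len(seq)
    if n < min_loop + 2:
        return 0
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]  # i unpaired
            if _can_pair(seq[i], seq[j]):
                inner = dp[i + 1, j - 1] if j - 1 >= i + 1 else 0
                best = max(best, inner + 1)
            for k in range(i + 1, j):  # i pairs with k < j
                if _can_pair(seq[i], seq[k]) and k - i > min_loop:
                    inner = dp[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    rest = dp[k + 1, j] if k + 1 <= j else 0
                    best = max(best, inner + 1 + rest)
            dp[i, j] = best
    return int(dp[0, n - 1])


class EICall(NamedTuple):
    label: str  # "EIciRNA" or "ecircRNA"
    low_evidence: bool


def classify_eicirna(
    circ: CircRNARecord,
    bsj_mate_alignments: Sequence[GenomicInterval],
    exons: Sequence[GenomicInterval],
) -> EICall:
    """Exon-intron circRNA call from mates of back-splice junction reads.

    EIciRNA iff any mate alignment covers ≥1 base inside the circRNA locus
    that lies outside every exon ("any intronic sequence" rule); with no mate
    alignments the call defaults to ecircRNA flagged low-evidence.
    """
    if circ.locus is None:
        raise ValidationError(f"{circ.circ_id}: no locus coordinates")
    if not bsj_mate_alignments:
        return EICall("ecircRNA", low_evidence=True)
    inside = intersect(list(bsj_mate_alignments), [circ.locus])
    intronic = subtract(inside, list(exons), min_len=0)
    if intronic:
        return EICall("EIciRNA", low_evidence=False)
    return EICall("ecircRNA", low_evidence=False)


def qpcr_fold(ct_a: float, ct_ref: float) -> float:
    """ΔCt fold change 2^(Ct_reference − Ct_target)."""
    if not (math.isfinite(ct_a) and math.isfinite(ct_ref)):
        raise ValidationError("Ct values must be finite")
    return 2.0 ** (ct_ref - ct_a)


def qpcr_nuc_cyto_ratio(
    ct_nuclear: float, ct_cytoplasmic: float,
    control_ratio: float | None = None,
) -> float:
    """Nuc:Cyto abundance ratio from Ct values, optionally normalized to a
    control target's ratio."""
    ratio = qpcr_fold(ct_nuclear, ct_cytoplasmic)
    if control_ratio is not None:
        if control_ratio <= 0:
            raise ParameterError("control ratio must be positive")
        ratio /= control_ratio
    return ratio
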