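"""Junction counting, TPM, enrichment testing, features, folding, qPCR."""

import math

import numpy as np
import pandas as pd
import pytest

from cirloop import (
    CircRNARecord,
    GenomicInterval,
    ParameterError,
    ValidationError,
    classify_eicirna,
    classify_localization,
    count_junctions,
    feature_compare,
    fold_proxy,
    gc_content,
    merge_replicates,
    nuc_cyto_stat,
    qpcr_fold,
    qpcr_nuc_cyto_ratio,
    sensitivity_sets,
    tpm_normalize,
)
from cirloop.localization import _PAIRS, _revcomp


class TestCountJunctions:
    # 40 nt junction sequence, back-splice point at position 20
    junction = "ACGTACGTACGTACGTACGT" + "TTGGCCAATTGGCCAATTGG"
    library = {"circA": junction}
    centers = {"circA": 20}

    def read_at(self, offset, length):
        return self.junction[offset : offset + length]

    def test_spanning_read_counts(self):
        read = self.read_at(10, 20)  # 10 nt each side of the junction point
        counts = count_junctions([read], self.library, min_overhang=8,
                                 centers=self.centers)
        assert counts == {"circA": 1}

    def test_insufficient_overhang_rejected(self):
        read = self.read_at(15, 20)  # 5 nt on the left side only
        counts = count_junctions([read], self.library, min_overhang=8,
                                 centers=self.centers)
        assert counts == {"circA": 0}

    def test_colinear_read_never_counts(self):
        colinear = "ACGTACGTACGTACGTACGTACGT"  # upstream exonic continuation
        counts = count_junctions([colinear], self.library, min_overhang=8,
                                 centers=self.centers)
        assert counts == {"circA": 0}

    def test_reverse_complement_matching(self):
        read = _revcomp(self.read_at(10, 20))
        on = count_junctions([read], self.library, min_overhang=8,
                             centers=self.centers, strand_unaware=True)
        off = count_junctions([read], self.library, min_overhang=8,
                              centers=self.centers, strand_unaware=False)
        assert on == {"circA": 1}
        assert off == {"circA": 0}

    def test_short_read_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            counts = count_junctions(["ACGTACGT"], self.library, min_overhang=8,
                                     centers=self.centers)
        assert counts == {"circA": 0}


class TestTpm:
    def test_example(self):
        assert tpm_normalize(4, 2e6) == pytest.approx(2.0)

    def test_zero_count(self):
        assert tpm_normalize(0, 1e6) == 0.0

    def test_conservation(self):
        counts = np.array([10, 20, 70], dtype=float)
        tpm = tpm_normalize(counts, counts.sum())
        assert tpm.sum() == pytest.approx(1e6, rel=1e-9)

    def test_zero_library_rejected(self):
        with pytest.raises(ParameterError):
            tpm_normalize(5, 0)


class TestMergeReplicates:
    def test_intersection(self):
        out = merge_replicates({"A": 3, "B": 1}, {"B": 2, "C": 9})
        assert out == {"B": (1, 2)}

    def test_identical(self):
        reps = {"A": 2, "B": 5}
        assert set(merge_replicates(reps, reps)) == {"A", "B"}

    def test_disjoint_warns(self):
        with pytest.warns(UserWarning):
            out = merge_replicates({"A": 1}, {"B": 1})
        assert out == {}

    def test_min_count_threshold(self):
        out = merge_replicates({"A": 1}, {"A": 5}, min_count=2)
        assert out == {}


class TestNucCytoStat:
    def test_equal_groups(self):
        res = nuc_cyto_stat([10, 10], [10, 10])
        assert res.log2_ratio == 0.0
        assert res.p == 1.0

    def test_exact_doubling_with_small_pseudocount(self):
        res = nuc_cyto_stat([20, 20], [10, 10], pseudocount=1e-9)
        assert res.log2_ratio == pytest.approx(1.0, abs=1e-6)

    def test_antisymmetry(self):
        nuc, cyto = [12.0, 15.0, 9.0], [30.0, 25.0, 40.0]
        a = nuc_cyto_stat(nuc, cyto)
        b = nuc_cyto_stat(cyto, nuc)
        assert a.log2_ratio == pytest.approx(-b.log2_ratio)
        assert a.p == pytest.approx(b.p)

    def test_too_few_replicates(self):
        with pytest.raises(ParameterError):
            nuc_cyto_stat([10], [10, 10])


class TestClassifyLocalization:
    @pytest.mark.parametrize(
        "ratio,p,expected",
        [
            (-0.5, 0.01, "cytoplasmic"),
            (0.5, 0.01, "nuclear"),
            (0.3, 0.001, "unclassified"),   # strict > 0.3
            (-0.3, 0.001, "unclassified"),  # strict < -0.3
            (1.0, 0.2, "unclassified"),     # p < 0.05 required
            (1.0, 0.05, "unclassified"),    # strict p < 0.05
            (0.0, 0.001, "unclassified"),
        ],
    )
    def test_three_way_partition(self, ratio, p, expected):
        assert classify_localization(ratio, p) == expected


class TestSensitivitySets:
    def test_condition_wise_sets(self):
        wt = {"a": "cytoplasmic", "b": "nuclear", "c": "cytoplasmic", "d": "nuclear"}
        ko = {"a": "unclassified", "b": "cytoplasmic", "c": "cytoplasmic", "d": "nuclear"}
        out = sensitivity_sets(wt, ko)
        assert out.sensitive == {"a", "c"}
        assert out.insensitive == {"b", "c"}
        assert out.labels["a"] == ("XPO4_sensitive",)
        assert out.labels["b"] == ("XPO4_insensitive",)
        assert out.labels["c"] == ("XPO4_sensitive", "XPO4_insensitive")
        assert out.labels["d"] == ("other",)
        assert out.sensitive_only == {"a"}

    def test_precedence_options(self):
        wt = {"c": "cytoplasmic"}
        ko = {"c": "cytoplasmic"}
        assert sensitivity_sets(wt, ko, "sensitive").labels["c"] == ("XPO4_sensitive",)
        assert sensitivity_sets(wt, ko, "insensitive").labels["c"] == ("XPO4_insensitive",)
        with pytest.raises(ParameterError):
            sensitivity_sets(wt, ko, "banana")

    def test_export_dependent_half_recovery_rule(self):
        wt = {"a": "cytoplasmic", "b": "cytoplasmic"}
        ko = {"a": "unclassified", "b": "unclassified"}
        # a recovered most of its enrichment in KO; b kept it
        out = sensitivity_sets(wt, ko,
                               ratio_wt={"a": -1.6, "b": -1.6},
                               ratio_ko={"a": -0.2, "b": -1.2})
        assert out.export_dependent == {"a"}


class TestFeatureCompare:
    def frame(self, lengths, gcs=None):
        return pd.DataFrame({
            "length": lengths,
            "gc": gcs if gcs is not None else np.full(len(lengths), 0.5),
        })

    def test_identical_groups(self):
        g = self.frame(np.arange(10, 60, dtype=float))
        res = feature_compare(g, g, features=("length",))
        row = res.stats.iloc[0]
        assert row["ks_stat"] == 0.0
        assert row["ks_p"] == pytest.approx(1.0)

    def test_planted_length_shift_detected(self):
        rng = np.random.default_rng(42)
        a = self.frame(rng.lognormal(math.log(500), 0.6, 700))
        b = self.frame(rng.lognormal(math.log(500 * 1.25), 0.6, 700))
        res = feature_compare(a, b, features=("length",))
        assert res.stats.iloc[0]["ks_p"] < 0.01

    def test_curves_are_cumulative(self):
        g = self.frame(np.arange(0, 50, dtype=float))
        res = feature_compare(g, g, features=("length",))
        x, f = res.curves["length"]["a"]
        assert f[0] > 0 and f[-1] == pytest.approx(1.0)
        assert (np.diff(x) >= 0).all() and (np.diff(f) > 0).all()

    def test_small_group_rejected(self):
        with pytest.raises(ParameterError):
            feature_compare(self.frame([1.0]), self.frame([1.0, 2.0]))

    @pytest.mark.parametrize("seq,expected", [("ATGC", 0.5), ("GGCC", 1.0), ("ATAT", 0.0)])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)


def brute_max_pairs(seq: str, i: int, j: int, min_loop: int) -> int:
    """Exhaustive enumeration of all nested structures (no memoization)."""
    if j - i < min_loop + 1:
        return 0
    best = brute_max_pairs(seq, i + 1, j, min_loop)
    for k in range(i + 1, j + 1):
        if (seq[i], seq[k]) in _PAIRS and k - i > min_loop:
            left = brute_max_pairs(seq, i + 1, k - 1, min_loop)
            right = brute_max_pairs(seq, k + 1, j, min_loop)
            best = max(best, 1 + left + right)
    return best


class TestFoldProxy:
    def test_hairpin(self):
        assert fold_proxy("GGGAAACCC", min_loop=3) == 3

    def test_no_pairs(self):
        assert fold_proxy("AAAA") == 0

    def test_loop_constraint(self):
        assert fold_proxy("GC", min_loop=3) == 0

    def test_gu_wobble_allowed(self):
        assert fold_proxy("GAAAU", min_loop=3) == 1

    def test_invalid_characters(self):
        with pytest.raises(ValidationError):
            fold_proxy("ACGX")

    def test_upper_bound(self):
        assert fold_proxy("GCGCGCGCGC", min_loop=0) <= 5

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 13))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            expected = brute_max_pairs(seq, 0, n - 1, 3)
            assert fold_proxy(seq, min_loop=3) == expected, seq


class TestClassifyEicirna:
    locus = GenomicInterval("chr1", 1000, 2400, name="circX")
    exons = [GenomicInterval("chr1", 1000, 1400), GenomicInterval("chr1", 2000, 2400)]
    circ = CircRNARecord("circX", locus=locus)

    def test_exonic_mate_is_ecircrna(self):
        mate = [GenomicInterval("chr1", 1100, 1200)]
        call = classify_eicirna(self.circ, mate, self.exons)
        assert call.label == "ecircRNA" and not call.low_evidence

    def test_single_intronic_base_is_eicirna(self):
        mate = [GenomicInterval("chr1", 1301, 1401)]  # 1 base into the intron
        call = classify_eicirna(self.circ, mate, self.exons)
        assert call.label == "EIciRNA"

    def test_whole_locus_intronic(self):
        call = classify_eicirna(self.circ, [GenomicInterval("chr1", 1500, 1600)], [])
        assert call.label == "EIciRNA"

    def test_no_mates_low_evidence(self):
        call = classify_eicirna(self.circ, [], self.exons)
        assert call.label == "ecircRNA" and call.low_evidence

    def test_mate_outside_locus_is_ecircrna(self):
        mate = [GenomicInterval("chr1", 3000, 3100)]
        assert classify_eicirna(self.circ, mate, self.exons).label == "ecircRNA"


class TestQpcr:
    def test_identity(self):
        assert qpcr_fold(30.0, 30.0) == pytest.approx(1.0)

    def test_delta_ct(self):
        assert qpcr_fold(30.0, 33.32) == pytest.approx(9.98, abs=0.01)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            qpcr_fold(float("nan"), 30.0)

    def test_control_normalization_identity(self):
        raw = qpcr_nuc_cyto_ratio(28.0, 30.0)
        assert qpcr_nuc_cyto_ratio(28.0, 30.0, control_ratio=raw) == pytest.approx(1.0)

    def test_direction(self):
        # lower nuclear Ct = more nuclear template = ratio > 1
        assert qpcr_nuc_cyto_ratio(25.0, 30.0) > 1.0


class TestCircRNARecord:
    def test_derived_features(self):
        rec = CircRNARecord("c1", mature_sequence="AUGCGC")
        assert rec.length == 6
        assert rec.gc == pytest.approx(4 / 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            CircRNARecord("c1", mature_sequence="ACGT", length=5)

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValidationError):
            CircRNARecord("c1", mature_sequence="ACGZ")
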