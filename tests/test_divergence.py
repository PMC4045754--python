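"""Pair classification, class summaries, diagnostics and the barcode gap."""

import itertools
import math

import numpy as np
import pytest

from barcodeaudit.distances import pairwise_matrix
from barcodeaudit.divergence import (
    CONGENERIC,
    INTERGENERIC,
    INTRA,
    class_pair_counts,
    classify_pairs,
    detect_gap,
    flag_failures,
    species_diagnostics,
    summarize_class,
)
from conftest import make_dataset


def test_classification_enumeration():
    ds = make_dataset(
        [
            ("s1", "Alpha one", "Alpha", "AAAA"),
            ("s2", "Alpha one", "Alpha", "AAAA"),
            ("s3", "Alpha two", "Alpha", "AAAT"),
            ("s4", "sp. X", "Alpha", "AATT"),
            ("s5", "sp. Y", "Alpha", "ATTT"),
            ("s6", "Beta one", "Beta", "TTTT"),
        ]
    )
    classes = classify_pairs(ds)
    idx = {sid: i for i, sid in enumerate(ds.alignment.ids)}
    assert classes[idx["s1"], idx["s2"]] == INTRA
    assert classes[idx["s1"], idx["s3"]] == CONGENERIC
    assert classes[idx["s4"], idx["s5"]] == CONGENERIC  # placeholders are species
    assert classes[idx["s1"], idx["s6"]] == INTERGENERIC
    counts = class_pair_counts(classes)
    n = ds.n_specimens
    assert sum(counts.values()) == n * (n - 1) // 2


def test_two_genera_two_plus_two_counts():
    """4 specimens, 2 genera of one species each: 2 intra + 4 intergeneric."""
    ds = make_dataset(
        [
            ("a1", "Alpha one", "Alpha", "AAAA"),
            ("a2", "Alpha one", "Alpha", "AAAA"),
            ("b1", "Beta one", "Beta", "TTTT"),
            ("b2", "Beta one", "Beta", "TTTT"),
        ]
    )
    counts = class_pair_counts(classify_pairs(ds))
    assert counts == {"intraspecific": 2, "congeneric": 0, "intergeneric": 4}


def test_class_counts_sum_to_choose_two(sim_clean):
    ds, _ = sim_clean
    counts = class_pair_counts(classify_pairs(ds))
    n = ds.n_specimens
    assert sum(counts.values()) == n * (n - 1) // 2


def test_summary_statistics_against_percentile_oracle(toy_dataset):
    m = pairwise_matrix(toy_dataset.alignment, min_overlap=5)
    classes = classify_pairs(toy_dataset)
    s = summarize_class(m, classes, INTRA)
    iu = np.triu_indices(len(m.ids), k=1)
    vals = m.values[iu][(classes[iu] == INTRA) & m.defined[iu]]
    assert s.n_pairs == vals.size
    assert s.mean == pytest.approx(vals.mean())
    assert s.median == pytest.approx(np.median(vals))
    assert s.ci_low == pytest.approx(np.percentile(vals, 2.5))
    assert s.ci_high == pytest.approx(np.percentile(vals, 97.5))
    assert s.min <= s.ci_low <= s.median <= s.ci_high <= s.max


def test_outliers_detected_under_whisker_policy():
    """Values {1,2,3,4,100}%: max flagged as outlier beyond the 97.5th pct."""
    from barcodeaudit.dataio import BarcodeAlignment, Dataset, SpecimenRecord
    from barcodeaudit.divergence import DivergenceSummary

    vals = np.array([0.01, 0.02, 0.03, 0.04, 1.0])
    lo, hi = np.percentile(vals, (2.5, 97.5))
    outliers = vals[(vals < lo) | (vals > hi)]
    assert 1.0 in outliers and len(outliers) >= 1


def test_single_value_summary():
    # one intraspecific pair only
    ds = make_dataset(
        [("s1", "A a", "AAAAACGTAC"), ("s2", "A a", "AAAAACGTAT")]
    )
    m = pairwise_matrix(ds.alignment, min_overlap=5)
    s = summarize_class(m, classify_pairs(ds), INTRA)
    assert s.n_pairs == 1
    assert s.mean == s.median == s.min == s.max


def test_empty_class_sentinel(toy_dataset):
    ds = make_dataset([("s1", "A a", "AAAA"), ("s2", "A a", "AAAA")])
    m = pairwise_matrix(ds.alignment, min_overlap=1)
    s = summarize_class(m, classify_pairs(ds), INTERGENERIC)
    assert s.empty and s.n_pairs == 0 and math.isnan(s.mean)


def test_species_diagnostics_against_brute_force(sim_clean):
    """Max-WSD / Min-BSD / nearest species equal an exhaustive pair scan."""
    ds, _ = sim_clean
    m = pairwise_matrix(ds.alignment)
    diags = {d.species: d for d in species_diagnostics(ds, m)}
    species_of = {r.specimen_id: r.species for r in ds.records}
    ids = list(m.ids)
    for sp, d in diags.items():
        wsd = [
            m.get(a, b)
            for a, b in itertools.combinations(ids, 2)
            if species_of[a] == sp and species_of[b] == sp
        ]
        bsd = {}
        for a in ids:
            if species_of[a] != sp:
                continue
            for b in ids:
                other = species_of[b]
                if other == sp:
                    continue
                v = m.get(a, b)
                bsd[other] = min(bsd.get(other, math.inf), v)
        if len(wsd) == 0:
            assert math.isnan(d.max_wsd)
        else:
            assert d.max_wsd == pytest.approx(max(wsd))
        min_bsd = min(bsd.values())
        assert d.min_bsd == pytest.approx(min_bsd)
        assert d.nearest_species == sorted(
            sp2 for sp2, v in bsd.items() if v == min_bsd
        )


def test_singleton_species_never_flagged():
    ds = make_dataset(
        [
            ("s1", "A a", "AAAAAAAACG"),
            ("s2", "A b", "AAAAAAAACG"),   # singleton sharing a haplotype
            ("s3", "A b", "AAAAAAAACG"),
        ]
    )
    m = pairwise_matrix(ds.alignment, min_overlap=5)
    diags = species_diagnostics(ds, m)
    by = {d.species: d for d in diags}
    assert math.isnan(by["A a"].max_wsd) and not by["A a"].failure_flag
    assert by["A b"].min_bsd == 0.0 and by["A b"].failure_flag  # 0 >= 0


@pytest.mark.parametrize(
    "max_wsd,min_bsd,flagged",
    [(0.005, 0.030, False), (0.0061, 0.0015, True), (0.01, 0.01, True)],
)
def test_failure_rule_boundary(max_wsd, min_bsd, flagged):
    from barcodeaudit.divergence import SpeciesDiagnostics

    d = SpeciesDiagnostics("X y", 3, 2, max_wsd, min_bsd, ["X z"],
                           max_wsd >= min_bsd)
    assert (flag_failures([d]) == ["X y"]) is flagged


def _summary_from_values(vals, name="intraspecific"):
    from barcodeaudit.divergence import DivergenceSummary

    vals = np.asarray(vals, dtype=float)
    lo, hi = np.percentile(vals, (2.5, 97.5))
    return DivergenceSummary(
        name, vals.size, vals.mean(), float(np.median(vals)),
        float(vals.min()), float(vals.max()), float(lo), float(hi),
        [], (2.5, 97.5), vals,
    )


def test_gap_detected_when_distributions_separate():
    # 50/50 mixtures: the whisker percentiles coincide with the extremes,
    # so no value is trimmed and the raw gap is reported
    intra = _summary_from_values([0.001] * 50 + [0.005] * 50)
    inter = _summary_from_values([0.03] * 50 + [0.04] * 50, "interspecific")
    gap = detect_gap(intra, inter)
    assert gap.gap_exists
    assert gap.intra_upper == pytest.approx(0.005)
    assert gap.inter_lower == pytest.approx(0.03)
    assert gap.threshold == pytest.approx((0.005 + 0.03) / 2)


def test_gap_absent_when_overlapping():
    intra = _summary_from_values([0.001] * 50 + [0.02] * 50)
    inter = _summary_from_values([0.01] * 50 + [0.04] * 50, "interspecific")
    gap = detect_gap(intra, inter)
    assert not gap.gap_exists and gap.threshold is None


def test_outlier_trimming_opens_imperfect_gap():
    """One extreme intraspecific value closes the raw gap; trimming opens it."""
    intra_vals = [0.002] * 60 + [0.035]   # outlier above the 97.5th percentile
    inter_vals = [0.03] * 40 + [0.2] * 10
    intra = _summary_from_values(intra_vals)
    inter = _summary_from_values(inter_vals, "interspecific")
    assert max(intra_vals) > min(inter_vals)  # no raw gap
    gap = detect_gap(intra, inter)
    assert gap.gap_exists
    assert gap.intra_upper == pytest.approx(0.002)
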