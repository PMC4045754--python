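"""K2P distance kernel: closed form, pairwise deletion, matrix oracle, K80 recovery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeaudit.dataio import BarcodeAlignment
from barcodeaudit.distances import (
    NO_OVERLAP,
    SATURATED,
    SiteClassCounts,
    count_site_classes,
    k2p,
    pairwise_matrix,
    undefined_reason,
)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ("ACGT", "ACGT", (4, 0, 0)),
        ("ACGT", "GCGT", (4, 1, 0)),      # A->G transition
        ("ACGT", "TCGT", (4, 0, 1)),      # A->T transversion
        ("ACNT", "AC-A", (3, 0, 1)),      # N/'-' column dropped; T-vs-A compared
        ("ACNT", "ACG-", (2, 0, 0)),      # N and '-' columns dropped for the pair
        ("RYSW", "ACGT", (0, 0, 0)),      # ambiguity codes never compared
        ("acgt", "AcGt", (4, 0, 0)),      # case-insensitive
    ],
)
def test_site_class_counting(a, b, expected):
    c = count_site_classes(a, b)
    assert (c.n_compared, c.n_transitions, c.n_transversions) == expected


def test_site_class_counting_matches_column_enumeration():
    """Independent per-column oracle over every 2-character combination."""
    alphabet = "ACGTN-RY"
    bases = set("ACGT")
    purines = set("AG")
    for x in alphabet:
        for y in alphabet:
            c = count_site_classes(x, y)
            if x in bases and y in bases:
                assert c.n_compared == 1
                if x == y:
                    assert (c.n_transitions, c.n_transversions) == (0, 0)
                elif (x in purines) == (y in purines):
                    assert (c.n_transitions, c.n_transversions) == (1, 0)
                else:
                    assert (c.n_transitions, c.n_transversions) == (0, 1)
            else:
                assert c.n_compared == 0


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        count_site_classes("ACGT", "ACG")


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((100, 0, 0), 0.0),
        ((100, 10, 0), -0.5 * math.log(0.8)),                      # 0.11157...
        ((100, 0, 6), -0.5 * math.log(0.94) - 0.25 * math.log(0.88)),  # 0.06290...
    ],
)
def test_k2p_closed_form(counts, expected):
    assert k2p(SiteClassCounts(*counts)) == pytest.approx(expected, abs=1e-12)


def test_k2p_undefined_reasons():
    assert math.isnan(k2p(SiteClassCounts(0, 0, 0)))
    assert undefined_reason(SiteClassCounts(0, 0, 0)) == NO_OVERLAP
    # 1 - 2P - Q <= 0
    assert math.isnan(k2p(SiteClassCounts(100, 50, 0)))
    assert undefined_reason(SiteClassCounts(100, 50, 0)) == SATURATED
    # 1 - 2Q <= 0
    assert math.isnan(k2p(SiteClassCounts(100, 0, 50)))
    assert undefined_reason(SiteClassCounts(100, 0, 50)) == SATURATED


@given(
    n=st.integers(50, 2000),
    ts=st.integers(0, 30),
    tv=st.integers(0, 15),
)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_k2p_dominates_raw_mismatch(n, ts, tv):
    """The log correction only inflates: d >= P + Q whenever defined."""
    c = SiteClassCounts(n, ts, tv)
    d = k2p(c)
    if not math.isnan(d):
        assert d >= c.mismatch - 1e-12


@given(n=st.integers(10, 1000), ts=st.integers(0, 4))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_k2p_q_zero_limit_is_two_state_correction(n, ts):
    c = SiteClassCounts(n, min(ts, n), 0)
    d = k2p(c)
    if not math.isnan(d):
        assert d == pytest.approx(-0.5 * math.log(1 - 2 * c.p), abs=1e-12)


def test_pairwise_matrix_equals_per_pair_oracle():
    """Matrix kernel against the independent scalar loop, ambiguity included."""
    rng = np.random.default_rng(7)
    chars = np.array(list("ACGTN-RY"))
    rows = [
        "".join(rng.choice(chars, size=60, p=[0.22, 0.22, 0.22, 0.22, 0.04, 0.04, 0.02, 0.02]))
        for _ in range(8)
    ]
    aln = BarcodeAlignment([f"s{i}" for i in range(8)], rows)
    m = pairwise_matrix(aln, min_overlap=10)
    for i in range(8):
        for j in range(i + 1, 8):
            d = k2p(count_site_classes(rows[i], rows[j]))
            if math.isnan(d):
                assert not m.defined[i, j]
            else:
                assert m.values[i, j] == pytest.approx(d, abs=1e-14)
                assert m.values[j, i] == m.values[i, j]
    assert np.all(np.diag(m.values) == 0)


def test_pairwise_matrix_flags_no_overlap():
    aln = BarcodeAlignment(["a", "b"], ["ACGTNNNN", "NNNNACGT"])
    m = pairwise_matrix(aln, min_overlap=1)
    assert not m.defined[0, 1]
    assert m.n_no_overlap == 1


def test_identical_sequences_give_zero_matrix():
    aln = BarcodeAlignment(["a", "b", "c"], ["ACGT" * 5] * 3)
    m = pairwise_matrix(aln, min_overlap=1)
    assert np.all(m.values == 0.0)
    assert m.defined.all()


def test_low_confidence_overlap_flagged_but_defined():
    aln = BarcodeAlignment(["a", "b"], ["ACGT" + "N" * 96, "ACGT" + "N" * 96])
    m = pairwise_matrix(aln)  # default min_overlap 100
    assert m.defined[0, 1]
    assert m.low_confidence[0, 1]


def test_k80_monte_carlo_recovers_true_distance():
    """Sequences evolved at distance d recover d within 3 SE (n = 10000)."""
    from barcodeaudit.synthetic_data import evolve

    rng = np.random.default_rng(42)
    n_sites = 10_000
    kappa = 4.0
    for d_true in (0.05, 0.10, 0.20):
        anc = rng.integers(0, 4, size=n_sites).astype(np.uint8)
        der = evolve(anc, d_true, kappa, rng)
        mapping = "ACGT"
        seq_a = "".join(mapping[b] for b in anc)
        seq_b = "".join(mapping[b] for b in der)
        c = count_site_classes(seq_a, seq_b)
        d_hat = k2p(c)
        # delta-method variance of the K2P estimator
        p, q, n = c.p, c.q, c.n_compared
        c1 = 1.0 / (1 - 2 * p - q)
        c2 = 0.5 * (c1 + 1.0 / (1 - 2 * q))
        var = (c1**2 * p + c2**2 * q - (c1 * p + c2 * q) ** 2) / n
        assert abs(d_hat - d_true) < 3 * math.sqrt(var)
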