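"""Exact binomial tails, FDR, cosine similarity, and exposure calls."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aasig.exposure import (
    NullSpec,
    aa_excess_test,
    bh_fdr,
    binom_upper_tail,
    classify_exposure,
    cosine_similarity,
    evaluate_cohort,
    format_pvalue,
    strand_bias_test,
)
from aasig.spectrum import StrandCounts


def exact_tail(k, n, a, b):
    """Arbitrary-precision P(X >= k) for p0 = a/(a+b), as a Fraction."""
    num = sum(comb(n, j) * a**j * b ** (n - j) for j in range(k, n + 1))
    return Fraction(num, (a + b) ** n)


def test_whole_distribution_is_one():
    assert binom_upper_tail(0, 10, 0.5) == (1.0, 0.0)


def test_exact_dyadic_values():
    # P(X >= 38), X ~ Binom(42, 1/2) = 124314 / 2^42
    r = binom_upper_tail(38, 42, 0.5)
    assert r.p == pytest.approx(124314 / 2**42, rel=1e-10)
    # P(X >= 5), X ~ Binom(10, 1/2) = 638/1024
    assert binom_upper_tail(5, 10, 0.5).p == pytest.approx(638 / 1024, rel=1e-12)


def test_log10_preserved_below_underflow():
    # extreme case: p far below 1e-300 still carries its magnitude
    r = binom_upper_tail(2400, 2500, 0.125)
    assert r.p == 0.0
    exact = exact_tail(2400, 2500, 1, 7)

    def log10_int(x):
        shift = max(x.bit_length() - 53, 0)
        return math.log10(x >> shift) + shift * math.log10(2)

    expected_log10 = log10_int(exact.numerator) - log10_int(exact.denominator)
    assert r.log10p == pytest.approx(expected_log10, abs=1e-6)


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        binom_upper_tail(5, 4, 0.5)
    with pytest.raises(ValueError):
        binom_upper_tail(-1, 4, 0.5)
    with pytest.raises(ValueError):
        binom_upper_tail(1, 4, 1.5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(n=st.integers(1, 400), data=st.data(), p0=st.sampled_from([0.125, 0.5]))
def test_tail_decreases_as_k_increases(n, data, p0):
    k = data.draw(st.integers(0, n - 1))
    lo = binom_upper_tail(k, n, p0)
    hi = binom_upper_tail(k + 1, n, p0)
    assert hi.p <= lo.p + 1e-15
    assert hi.log10p <= lo.log10p + 1e-12


def test_excess_test_defaults_to_signature5_null():
    assert aa_excess_test(0, 100).p == 1.0
    r = aa_excess_test(67, 182)
    assert format_pvalue(r.log10p) == "5E-17"
    # undefined on an empty sample
    assert math.isnan(aa_excess_test(0, 0).p)
    with pytest.raises(ValueError):
        aa_excess_test(10, 5)


def test_strand_test_equal_split_null():
    assert strand_bias_test(StrandCounts(5, 5)).p == pytest.approx(638 / 1024, rel=1e-12)
    assert math.isnan(strand_bias_test(StrandCounts(0, 0)).p)


def test_bh_fdr_step_up_by_hand():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    assert bh_fdr([0.5, 0.5]) == pytest.approx([0.5, 0.5])
    # returned in input order
    out = bh_fdr([0.04, 0.001])
    assert out[1] <= out[0]


def test_bh_fdr_dominates_raw_pvalues():
    rng = np.random.default_rng(1)
    p = rng.uniform(size=40)
    q = bh_fdr(p)
    assert (q >= p - 1e-12).all()
    assert (q <= 1.0 + 1e-12).all()


def test_bh_fdr_validation_and_nan_family():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([])
    out = bh_fdr([0.01, float("nan"), 0.02])
    assert math.isnan(out[1])
    # the NaN entry is not part of the family (m = 2)
    assert out[0] == pytest.approx(0.02)


def test_cosine_similarity_closed_forms():
    u = np.zeros(16)
    u[0] = 1.0
    v = np.zeros(16)
    v[:2] = 1.0
    assert cosine_similarity(u, u) == pytest.approx(1.0)
    assert cosine_similarity(u, v) == pytest.approx(1 / math.sqrt(2), abs=1e-6)
    w = np.zeros(16)
    w[5] = 3.0
    assert cosine_similarity(u, w) == 0.0


def test_cosine_scale_invariance_and_errors():
    rng = np.random.default_rng(2)
    u = rng.uniform(size=16)
    v = rng.uniform(size=16)
    assert cosine_similarity(3.7 * u, 0.2 * v) == pytest.approx(cosine_similarity(u, v))
    with pytest.raises(ValueError):
        cosine_similarity(np.zeros(16), u)
    with pytest.raises(ValueError):
        cosine_similarity(-u, v)


def _results_frame(rows):
    return pd.DataFrame(rows, columns=["p_excess", "p_strand", "cosine_aa"])


def test_classification_rules():
    df = _results_frame(
        [
            (1e-229, 1e-28, 0.987),  # both criteria met, similar context
            (4e-4, 1e-2, 0.525),     # significant but context-dissimilar
            (0.5, 0.5, 0.99),        # nothing significant
            (1e-10, 1e-10, float("nan")),  # no A:T>T:A context to compare
        ]
    )
    out = classify_exposure(df)
    assert list(out["call"]) == [
        "AA-exposed",
        "AA-possible-dissimilar",
        "not-detected",
        "not-detected",
    ]
    assert (out["fdr_excess"].dropna() >= out["p_excess"].dropna() - 1e-12).all()


def test_evaluate_cohort_reproduces_reported_rows():
    """Counts typical of heavily and weakly mutagenized tumors."""
    stats = pd.DataFrame(
        {
            "n_total": [688, 1366],
            "n_atta": [450, 980],
            "n_non": [339, 708],
            "n_tr": [111, 272],
            "cosine_aa": [0.987, 0.992],
        },
        index=["hi", "vhi"],
    )
    out = evaluate_cohort(stats)
    assert format_pvalue(out.loc["hi", "log10_p_excess"]) == "1E-229"
    assert format_pvalue(out.loc["hi", "log10_p_strand"]) == "3E-28"
    assert out.loc["vhi", "frac_non"] == pytest.approx(708 / 980)
    assert (out["call"] == "AA-exposed").all()


def test_format_pvalue_rendering():
    assert format_pvalue(math.log10(0.0134)) == "1E-02"
    assert format_pvalue(-320.0) == "0"
    assert format_pvalue(0.0) == "1"
    assert format_pvalue(float("nan")) == "NA"
    # mantissa 9.7 rounds up into the next decade
    assert format_pvalue(math.log10(9.7e-5)) == "1E-04"


def test_nullspec_validation():
    with pytest.raises(ValueError):
        NullSpec(p0_excess=0.0)
    with pytest.raises(ValueError):
        NullSpec(fdr_threshold=1.0)
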