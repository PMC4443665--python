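"""Statistical tests for aristolochic-acid exposure.

Two one-sided exact binomial tests per tumor:

* **A:T>T:A excess** — under the null that all of a tumor's A:T>T:A
  mutations derive from Signature 5 alone, the A:T>T:A count among n total
  SNVs is Binomial(n, 0.125), 12.5% being Signature 5's A:T>T:A
  proportion. The p-value is the exact upper tail P(X ≥ k). The null is
  conservative: other signatures common in bladder tumors carry far less
  A:T>T:A mass.
* **Strand bias** — under the null of equal A>T counts on the transcribed
  and non-transcribed strands, the non-transcribed count among the
  strand-annotated A>T mutations is Binomial(n, 0.5).

P-values are adjusted per test family across all samples of a run with the
Benjamini–Hochberg step-up FDR. A sample is called AA-exposed when both
FDRs fall below the threshold (default 0.05) and the adenine-centric
A:T>T:A context pattern has cosine similarity ≥ 0.90 with the reference AA
signature; both-tests-significant but context-dissimilar samples are
flagged separately (an A>T-rich pattern unlike AA's CAG/TAG preference may
reflect a different mutagen).

P-values are carried with their base-10 logarithm so magnitudes far below
the double-precision underflow threshold survive into machine output;
display formatting renders one significant figure in scientific notation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .spectrum import StrandCounts

__all__ = [
    "NullSpec",
    "BinomTail",
    "binom_upper_tail",
    "aa_excess_test",
    "strand_bias_test",
    "bh_fdr",
    "cosine_similarity",
    "classify_exposure",
    "evaluate_cohort",
    "format_pvalue",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class NullSpec:
    """Null-hypothesis parameters of the exposure tests.

    p0_excess
        A:T>T:A proportion under the Signature-5-only null (0.125).
    p0_strand
        Non-transcribed fraction under the no-bias null (0.5).
    fdr_threshold
        FDR below which a test counts toward an exposure call (0.05).
    """

    p0_excess: float = 0.125
    p0_strand: float = 0.5
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p0_excess", "p0_strand", "fdr_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


class BinomTail(NamedTuple):
    """An exact upper-tail probability with its base-10 logarithm."""

    p: float
    log10p: float


def binom_upper_tail(k: int, n: int, p0: float) -> BinomTail:
    """Exact one-sided upper tail P(X ≥ k), X ~ Binomial(n, p0).

    Computed in log space (log-sum-exp over exact log point masses), so
    the base-10 logarithm is accurate even when the probability itself
    underflows double precision; the linear value is then reported as 0.0
    but ``log10p`` retains the magnitude.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"require 0 <= k <= n and n >= 1, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    if k == 0:
        return BinomTail(1.0, 0.0)
    j = np.arange(k, n + 1)
    logp = float(special.logsumexp(stats.binom.logpmf(j, n, p0)))
    logp = min(logp, 0.0)  # guard roundoff above 1
    return BinomTail(math.exp(logp), logp / LN10)


def aa_excess_test(n_atta: int, n_total: int, null: NullSpec = NullSpec()) -> BinomTail:
    """P-value that Signature 5 alone produced the observed A:T>T:A count.

    Returns NaN (undefined) when the sample has no mutations at all.
    """
    if n_total == 0:
        return BinomTail(float("nan"), float("nan"))
    if n_atta > n_total:
        raise ValueError("n_atta exceeds n_total")
    return binom_upper_tail(n_atta, n_total, null.p0_excess)


def strand_bias_test(counts: StrandCounts, null: NullSpec = NullSpec()) -> BinomTail:
    """P-value of the observed excess of A>T on the non-transcribed strand.

    Returns NaN (undefined) when no A>T mutation has an unambiguous strand.
    """
    n = counts.total
    if n == 0:
        return BinomTail(float("nan"), float("nan"))
    return binom_upper_tail(counts.n_nontranscribed, n, null.p0_strand)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    NaN entries (undefined tests) are excluded from the family and
    returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def cosine_similarity(u: Sequence[float], v: Sequence[float]) -> float:
    """Cosine similarity u·v/(‖u‖‖v‖) of two nonnegative vectors.

    Raises
    ------
    ValueError
        On negative entries, dimension mismatch, or an all-zero vector
        (the angle is undefined).
    """
    a = np.asarray(u, dtype=float)
    b = np.asarray(v, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("cosine_similarity expects nonnegative vectors")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


CALL_EXPOSED = "AA-exposed"
CALL_DISSIMILAR = "AA-possible-dissimilar"
CALL_NOT_DETECTED = "not-detected"


def classify_exposure(
    results: pd.DataFrame,
    null: NullSpec = NullSpec(),
    cosine_cutoff: float = 0.90,
) -> pd.DataFrame:
    """Adjust both p-value families across samples and call exposure.

    ``results`` needs columns ``p_excess``, ``p_strand`` and ``cosine_aa``
    (NaN where undefined). Adds ``fdr_excess``, ``fdr_strand`` and
    ``call``: *AA-exposed* when both FDRs < threshold and cosine ≥ cutoff;
    *AA-possible-dissimilar* when both FDRs pass but the context pattern is
    dissimilar; *not-detected* otherwise (including undefined cosine).
    """
    out = results.copy()
    out["fdr_excess"] = bh_fdr(out["p_excess"])
    out["fdr_strand"] = bh_fdr(out["p_strand"])
    t = null.fdr_threshold
    both = (out["fdr_excess"] < t) & (out["fdr_strand"] < t)
    similar = out["cosine_aa"] >= cosine_cutoff  # False where NaN
    call = np.where(
        both & similar,
        CALL_EXPOSED,
        np.where(both & ~similar & out["cosine_aa"].notna(), CALL_DISSIMILAR, CALL_NOT_DETECTED),
    )
    out["call"] = call
    return out


def evaluate_cohort(
    stats_df: pd.DataFrame,
    null: NullSpec = NullSpec(),
    cosine_cutoff: float = 0.90,
) -> pd.DataFrame:
    """Run both exposure tests and the call over a per-sample summary table.

    ``stats_df`` carries one row per sample with columns ``n_total``,
    ``n_atta``, ``n_non``, ``n_tr`` and ``cosine_aa``. Returns the table
    augmented with p-values (and their log10), strand fraction, FDRs and
    the final call — the layout of a tumor-by-tumor exposure report.
    """
    need = {"n_total", "n_atta", "n_non", "n_tr", "cosine_aa"}
    if not need <= set(stats_df.columns):
        raise ValueError(f"missing columns {sorted(need - set(stats_df.columns))}")
    out = stats_df.copy()
    excess = [
        aa_excess_test(int(k), int(n), null)
        for k, n in zip(out["n_atta"], out["n_total"])
    ]
    strand = [
        strand_bias_test(StrandCounts(int(nn), int(nt)), null)
        for nn, nt in zip(out["n_non"], out["n_tr"])
    ]
    out["prop_atta"] = out["n_atta"] / out["n_total"].replace(0, np.nan)
    out["p_excess"] = [t.p for t in excess]
    out["log10_p_excess"] = [t.log10p for t in excess]
    denom = (out["n_non"] + out["n_tr"]).replace(0, np.nan)
    out["frac_non"] = out["n_non"] / denom
    out["p_strand"] = [t.p for t in strand]
    out["log10_p_strand"] = [t.log10p for t in strand]
    return classify_exposure(out, null=null, cosine_cutoff=cosine_cutoff)


def format_pvalue(log10p: float) -> str:
    """One-significant-figure scientific notation from a log10 p-value.

    Values below 1e-300 are rendered as ``"0"`` (table display
    convention); the log10 value itself is the machine-readable record.
    """
    if math.isnan(log10p):
        return "NA"
    if log10p < -300:
        return "0"
    if log10p >= math.log10(0.95):
        return "1"
    exponent = math.floor(log10p)
    mantissa = 10 ** (log10p - exponent)
    m = round(mantissa)
    if m == 10:
        m, exponent = 1, exponent + 1
    return f"{m}E{exponent:+03d}"
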