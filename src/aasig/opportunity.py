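"""Trinucleotide opportunity vectors.

The *opportunity* of a trinucleotide is the number of positions in the
analyzed territory (an exome, a gene panel, a simulated chromosome) at which
a mutation in that context could have occurred: the count of occurrences of
the trinucleotide, combined with its reverse complement, across the
territory. Opportunities normalise observed spectra ("adjusted for the
frequency of the trinucleotide" in the territory) and weight the Poisson
likelihood in signature factorization.

Opportunities are stored over the 32 pyrimidine-centred trinucleotides and
expanded to 96 channels by replicating each trinucleotide across its three
alternate alleles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .channels import BASES, N_CHANNELS, PYR_TRINUCS, channel_context

__all__ = [
    "compute_opportunities",
    "expand_to_96",
    "read_opportunities",
    "write_opportunities",
    "uniform_opportunities",
]

_BASE_CODE = {b: i for i, b in enumerate(BASES)}


def _trinuc_counts(seq: str) -> np.ndarray:
    """Count all 64 trinucleotide windows of ``seq`` (N-containing skipped)."""
    s = seq.upper()
    codes = np.full(len(s), -1, dtype=np.int64)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    for b, c in _BASE_CODE.items():
        codes[arr == ord(b)] = c
    if len(codes) < 3:
        return np.zeros(64, dtype=np.int64)
    w = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
    valid = (codes[:-2] >= 0) & (codes[1:-1] >= 0) & (codes[2:] >= 0)
    return np.bincount(w[valid], minlength=64)


_TRINUC64 = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
_CODE64 = {t: i for i, t in enumerate(_TRINUC64)}


def _fold64_to_32(counts64: np.ndarray) -> pd.Series:
    from .channels import revcomp

    out = {}
    for t in PYR_TRINUCS:
        out[t] = int(counts64[_CODE64[t]] + counts64[_CODE64[revcomp(t)]])
    return pd.Series(out, name="count")


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent half-open intervals per chromosome."""
    merged = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if s >= e:
                raise ValueError(f"invalid interval {chrom}:{s}-{e} (start >= end)")
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    return pd.DataFrame(merged, columns=["chrom", "start", "end"])


def compute_opportunities(
    reference: str | Path, territory: str | Path | pd.DataFrame | None = None
) -> pd.Series:
    """Count pyrimidine-centred trinucleotide opportunities in a territory.

    Parameters
    ----------
    reference
        FASTA path (indexed on first use).
    territory
        BED3 path or DataFrame with columns ``chrom, start, end`` (0-based,
        half-open). ``None`` counts every sequence in the reference
        end to end. Overlapping intervals are merged before counting so
        shared bases are not double-counted; windows are counted at every
        offset within each merged interval.

    Returns
    -------
    pandas.Series
        Length-32 counts indexed by pyrimidine-centred trinucleotide, each
        the occurrences of that trinucleotide plus its reverse complement.

    Raises
    ------
    ValueError
        If an interval extends beyond its chromosome, or the territory
        contains no valid trinucleotide window.
    """
    fa = Fasta(str(reference), sequence_always_upper=True)
    counts64 = np.zeros(64, dtype=np.int64)
    if territory is None:
        for name in fa.keys():
            counts64 += _trinuc_counts(str(fa[name][:]))
    else:
        if not isinstance(territory, pd.DataFrame):
            territory = pd.read_csv(
                territory,
                sep="\t",
                comment="#",
                header=None,
                usecols=[0, 1, 2],
                names=["chrom", "start", "end"],
            )
        for chrom, start, end in merge_intervals(territory).itertuples(index=False):
            if chrom not in fa:
                raise ValueError(f"territory chromosome {chrom!r} not in reference")
            if end > len(fa[chrom]):
                raise ValueError(
                    f"interval {chrom}:{start}-{end} beyond sequence end "
                    f"({len(fa[chrom])})"
                )
            counts64 += _trinuc_counts(str(fa[chrom][start:end]))
    opp = _fold64_to_32(counts64)
    if opp.sum() == 0:
        raise ValueError("territory contains no valid trinucleotide window")
    opp.index.name = "trinucleotide"
    return opp


def expand_to_96(opportunities: pd.Series | np.ndarray) -> np.ndarray:
    """Replicate 32 trinucleotide opportunities over the 96 channels."""
    if isinstance(opportunities, pd.Series):
        opportunities = opportunities.reindex(PYR_TRINUCS)
        if opportunities.isna().any():
            missing = list(opportunities[opportunities.isna()].index)
            raise ValueError(f"opportunity table missing trinucleotides: {missing}")
        values = opportunities.to_numpy(dtype=float)
    else:
        values = np.asarray(opportunities, dtype=float)
        if values.shape != (32,):
            raise ValueError("expected 32 opportunity values")
    lookup = {t: v for t, v in zip(PYR_TRINUCS, values)}
    return np.array([lookup[channel_context(i)] for i in range(N_CHANNELS)])


def uniform_opportunities() -> pd.Series:
    """A flat opportunity vector (all trinucleotides equally available)."""
    return pd.Series(1.0, index=pd.Index(PYR_TRINUCS, name="trinucleotide"), name="count")


def write_opportunities(opportunities: pd.Series, path: str | Path) -> None:
    opportunities.rename("count").to_csv(path, sep="\t", index_label="trinucleotide")


def read_opportunities(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if not {"trinucleotide", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'trinucleotide' and 'count'")
    s = df.set_index("trinucleotide")["count"]
    s = s.reindex(PYR_TRINUCS)
    if s.isna().any():
        raise ValueError(f"{path}: missing trinucleotides in opportunity table")
    return s
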