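"""96-channel mutation spectra, opportunity adjustment, and strand tallies.

A sample's *spectrum* is the vector of its SNV counts over the 96
trinucleotide mutation channels. The *adjusted* spectrum divides each
channel by the trinucleotide's opportunity in the analyzed territory and
renormalises, so that territories rich in a context do not masquerade as
mutational preference for it.

The A:T>T:A strand tally counts, for each A>T mutation lying in an
unambiguously stranded transcript, whether the mutated adenine sits on the
non-transcribed (coding/sense) strand or the transcribed (template) strand.
Adenine adducts on the transcribed strand are preferentially removed by
transcription-coupled repair, so adduct-driven mutagenesis shows an excess
on the non-transcribed strand. Conventions, for a forward-strand record:
ref A in a plus-strand transcript → the adenine is on the coding strand →
non-transcribed; ref T mirrors this (the adenine is on the reverse strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .channels import (
    ADENINE_LABELS,
    ADENINE_TO_CHANNEL,
    CHANNEL_LABELS,
    N_CHANNELS,
    TA_SLICE,
    channel_index,
)
from .opportunity import expand_to_96

logger = logging.getLogger(__name__)

__all__ = [
    "StrandCounts",
    "build_spectrum",
    "build_spectra_matrix",
    "opportunity_adjust",
    "at_ta_subvector",
    "strand_counts",
    "write_spectrum",
]


@dataclass
class StrandCounts:
    """A>T mutation tallies by strand of the mutated adenine."""

    n_nontranscribed: int
    n_transcribed: int
    sample_id: str = ""
    n_skipped: int = 0  # A:T>T:A mutations with ambiguous or absent strand

    @property
    def total(self) -> int:
        return self.n_nontranscribed + self.n_transcribed

    @property
    def frac_nontranscribed(self) -> float:
        return self.n_nontranscribed / self.total if self.total else float("nan")


def _channel_indices(df: pd.DataFrame) -> np.ndarray:
    return np.array(
        [
            channel_index(r, a, c5, c3)
            for r, a, c5, c3 in zip(
                df["ref"], df["alt"], df["context5"], df["context3"]
            )
        ],
        dtype=np.int64,
    )


def _valid_rows(df: pd.DataFrame) -> pd.DataFrame:
    if "context5" not in df.columns:
        raise ValueError("catalog has no attached context; run attach_context first")
    if "valid" in df.columns:
        return df[df["valid"]]
    return df


def build_spectrum(catalog: MutationCatalog, sample: str) -> pd.Series:
    """96-channel SNV counts for one sample (invalid records excluded)."""
    sub = catalog.for_sample(sample)
    rows = _valid_rows(sub)
    n_excluded = len(sub) - len(rows)
    if n_excluded:
        logger.info("build_spectrum(%s): excluded %d invalid records", sample, n_excluded)
    counts = np.zeros(N_CHANNELS, dtype=np.int64)
    if len(rows):
        np.add.at(counts, _channel_indices(rows), 1)
    else:
        logger.warning("build_spectrum(%s): empty spectrum", sample)
    return pd.Series(counts, index=pd.Index(CHANNEL_LABELS, name="channel"), name=sample)


def build_spectra_matrix(catalog: MutationCatalog) -> pd.DataFrame:
    """96 × samples count matrix over all samples in the catalog."""
    return pd.DataFrame({s: build_spectrum(catalog, s) for s in catalog.sample_ids})


def opportunity_adjust(
    spectrum: pd.Series | np.ndarray, opportunities: pd.Series | np.ndarray
) -> pd.Series:
    """Per-opportunity proportions: (count_c / o_c) / Σ_d (count_d / o_d).

    ``opportunities`` may be a 32-trinucleotide table or an expanded
    96-vector. A channel with mutations but zero opportunity is an error.
    """
    counts = np.asarray(spectrum, dtype=float)
    o = np.asarray(opportunities, dtype=float)
    if o.shape == (32,) or isinstance(opportunities, pd.Series) and len(opportunities) == 32:
        o = expand_to_96(opportunities)
    if o.shape != (N_CHANNELS,) or counts.shape != (N_CHANNELS,):
        raise ValueError("expected 96-channel spectrum and 32- or 96-length opportunities")
    bad = (counts > 0) & (o <= 0)
    if bad.any():
        raise ValueError(
            f"zero opportunity with nonzero counts in channel {CHANNEL_LABELS[int(np.flatnonzero(bad)[0])]}"
        )
    rates = np.where(o > 0, counts / np.where(o > 0, o, 1.0), 0.0)
    total = rates.sum()
    props = rates / total if total > 0 else rates
    name = spectrum.name if isinstance(spectrum, pd.Series) else None
    return pd.Series(props, index=pd.Index(CHANNEL_LABELS, name="channel"), name=name)


def at_ta_subvector(adjusted: pd.Series | np.ndarray, renormalize: bool = True) -> pd.Series:
    """A:T>T:A channels re-expressed in adenine-centric order.

    The 16 pyrimidine-centred T>A channels are re-indexed by the 5'→3'
    context around the mutated adenine (CAG>CTG is read at position C·A·G)
    and renormalised to sum 1. An all-zero subvector is returned as zeros;
    cosine similarity against it is undefined downstream.
    """
    vec = np.asarray(adjusted, dtype=float)
    if vec.shape != (N_CHANNELS,):
        raise ValueError("expected a 96-channel spectrum")
    sub = vec[list(ADENINE_TO_CHANNEL)]
    total = sub.sum()
    if renormalize and total > 0:
        sub = sub / total
    name = adjusted.name if isinstance(adjusted, pd.Series) else None
    return pd.Series(sub, index=pd.Index(ADENINE_LABELS, name="channel"), name=name)


def strand_counts(catalog: MutationCatalog, sample: str) -> StrandCounts:
    """Tally A:T>T:A mutations by strand of the mutated adenine.

    Requires ``tx_strand`` annotation. Mutations with ``ambiguous`` or
    ``none`` transcript strand are skipped and counted in ``n_skipped``.
    """
    sub = catalog.for_sample(sample)
    if "tx_strand" not in sub.columns:
        raise ValueError("catalog has no tx_strand annotation; run annotate_tx_strand")
    rows = _valid_rows(sub) if "context5" in sub.columns else sub
    is_at = ((rows["ref"] == "A") & (rows["alt"] == "T")) | (
        (rows["ref"] == "T") & (rows["alt"] == "A")
    )
    at = rows[is_at]
    stranded = at[at["tx_strand"].isin(["plus", "minus"])]
    n_skipped = len(at) - len(stranded)
    if n_skipped:
        logger.info(
            "strand_counts(%s): skipped %d A>T mutations without unambiguous strand",
            sample,
            n_skipped,
        )
    # adenine on coding strand <=> (ref A, tx plus) or (ref T, tx minus)
    non = ((stranded["ref"] == "A") & (stranded["tx_strand"] == "plus")) | (
        (stranded["ref"] == "T") & (stranded["tx_strand"] == "minus")
    )
    n_non = int(non.sum())
    return StrandCounts(
        n_nontranscribed=n_non,
        n_transcribed=len(stranded) - n_non,
        sample_id=sample,
        n_skipped=n_skipped,
    )


def write_spectrum(
    spectrum: pd.Series, path, adjusted: pd.Series | None = None
) -> None:
    """Write one spectrum as a 96-row TSV (class, context, count[, adjusted])."""
    df = pd.DataFrame(
        {
            "class": [lab[2:5] for lab in CHANNEL_LABELS],
            "context": [lab[0] + lab[2] + lab[6] for lab in CHANNEL_LABELS],
            "count": np.asarray(spectrum),
        }
    )
    if adjusted is not None:
        df["adjusted_proportion"] = np.asarray(adjusted)
    df.to_csv(path, sep="\t", index=False)


def ta_mass(spectrum: pd.Series | np.ndarray) -> float:
    """Total A:T>T:A fraction of a spectrum or signature column."""
    vec = np.asarray(spectrum, dtype=float)
    total = vec.sum()
    return float(vec[TA_SLICE].sum() / total) if total > 0 else float("nan")
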