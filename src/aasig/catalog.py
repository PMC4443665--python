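"""Somatic mutation catalogs: reading, writing, and annotation.

A catalog is a table of somatic single-nucleotide substitutions across one
or more tumor samples. Coordinates are 1-based (MAF/VCF convention);
transcript and territory intervals are 0-based half-open (BED convention) —
the conversion happens inside this module only.

Two input dialects are supported:

``maf-lite``
    A tab-separated file with a header line carrying at least the columns
    ``sample``, ``chrom``, ``pos``, ``ref``, ``alt``; optional
    ``context5``, ``context3`` and ``tx_strand`` columns are preserved.
    This dialect is defined by this project so fixtures need no external
    schema.

``vcf``
    SNV records from a VCF; multi-allelic records are split into one
    substitution per alternate allele.

Trinucleotide context is attached from an indexed FASTA; transcription
strand from a BED6 transcript annotation. A mutation covered by transcripts
on both strands is ``ambiguous`` and is excluded from strand-bias counting
(but not from spectra); uncovered positions are ``none``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .channels import BASES

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCatalog",
    "TranscriptAnnotation",
    "EmptyCatalogWarning",
    "CatalogFormatError",
    "read_catalog",
    "write_catalog",
    "read_transcripts_bed",
    "attach_context",
    "annotate_tx_strand",
]

CATALOG_COLUMNS = ["sample", "chrom", "pos", "ref", "alt"]
OPTIONAL_COLUMNS = ["context5", "context3", "tx_strand", "valid"]

TX_STRANDS = ("plus", "minus", "ambiguous", "none")


class EmptyCatalogWarning(UserWarning):
    """Raised as a warning when a parsed catalog contains no usable SNV."""


class CatalogFormatError(ValueError):
    """Unparseable catalog input; message names the offending line."""


@dataclass
class MutationCatalog:
    """An ordered collection of somatic SNVs, one row per mutation.

    ``df`` columns: sample, chrom, pos (1-based int), ref, alt, and — once
    annotated — context5, context3 (forward-strand flanking bases),
    tx_strand (plus/minus/ambiguous/none) and valid (False for reference
    mismatches, edge positions and non-ACGT contexts).
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CATALOG_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"catalog missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["sample"]))

    @property
    def is_empty(self) -> bool:
        return len(self.df) == 0

    def __len__(self) -> int:
        return len(self.df)

    def for_sample(self, sample: str) -> pd.DataFrame:
        if sample not in set(self.df["sample"]):
            raise KeyError(f"unknown sample {sample!r}")
        return self.df[self.df["sample"] == sample]


@dataclass
class TranscriptAnnotation:
    """Stranded transcript intervals, 0-based half-open."""

    df: pd.DataFrame
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end", "strand"}
        if not need <= set(self.df.columns):
            raise ValueError(f"transcript annotation needs columns {sorted(need)}")
        if len(self.df) == 0:
            raise ValueError("transcript annotation is empty")
        bad = self.df[self.df["start"] >= self.df["end"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValueError(f"invalid interval {r.chrom}:{r.start}-{r.end}")
        if not set(self.df["strand"]) <= {"plus", "minus"}:
            raise ValueError("transcript strand must be 'plus' or 'minus'")
        from .opportunity import merge_intervals

        for strand in ("plus", "minus"):
            sub = self.df[self.df["strand"] == strand]
            for chrom, m in merge_intervals(sub).groupby("chrom", sort=False):
                self._index[(chrom, strand)] = (
                    m["start"].to_numpy(),
                    m["end"].to_numpy(),
                )

    def covers(self, chrom: str, pos0: int, strand: str) -> bool:
        """Whether 0-based position ``pos0`` lies in a ``strand`` transcript."""
        key = (chrom, strand)
        if key not in self._index:
            return False
        starts, ends = self._index[key]
        i = np.searchsorted(starts, pos0, side="right") - 1
        return i >= 0 and pos0 < ends[i]


def read_transcripts_bed(path: str | Path) -> TranscriptAnnotation:
    """Read a BED6 transcript file; the strand column (+/-) is required."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    if df["strand"].isna().any() or not set(df["strand"]) <= {"+", "-"}:
        raise CatalogFormatError(f"{path}: BED6 strand column must be '+' or '-'")
    df["strand"] = df["strand"].map({"+": "plus", "-": "minus"})
    return TranscriptAnnotation(df[["chrom", "start", "end", "strand"]])


def _validate_snvs(df: pd.DataFrame, source: str) -> tuple[pd.DataFrame, int]:
    """Keep single-base ACGT substitutions with ref != alt."""
    ref = df["ref"].astype(str).str.upper()
    alt = df["alt"].astype(str).str.upper()
    keep = ref.isin(list(BASES)) & alt.isin(list(BASES)) & (ref != alt)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d non-SNV or non-ACGT records", source, n_dropped)
    out = df.loc[keep].copy()
    out["ref"] = ref[keep]
    out["alt"] = alt[keep]
    return out, n_dropped


def _read_maf_lite(path: str | Path) -> MutationCatalog:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    except pd.errors.ParserError as exc:
        raise CatalogFormatError(f"{path}: {exc}") from exc
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(f"{path}: missing required columns {missing}")
    try:
        df["pos"] = df["pos"].astype(np.int64)
    except (ValueError, TypeError):
        bad = pd.to_numeric(df["pos"], errors="coerce").isna()
        line = int(np.flatnonzero(bad)[0]) + 2  # +1 header, +1 one-based
        raise CatalogFormatError(f"{path}: non-integer pos at line {line}") from None
    if (df["pos"] < 2).any():
        line = int(np.flatnonzero((df["pos"] < 2).to_numpy())[0]) + 2
        raise CatalogFormatError(
            f"{path}: pos < 2 at line {line} (flanking context must exist)"
        )
    keep_cols = CATALOG_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df, n_dropped = _validate_snvs(df[keep_cols], str(path))
    cat = MutationCatalog(df, n_dropped=n_dropped)
    if cat.is_empty:
        warnings.warn(f"{path}: catalog contains no SNV", EmptyCatalogWarning)
    return cat


def _read_vcf(path: str | Path, sample: str | None) -> MutationCatalog:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is None:
        sample = vcf.samples[0] if vcf.samples else Path(path).stem
    rows = []
    n_dropped = 0
    for v in vcf:
        if v.REF is None or len(v.REF) != 1 or v.REF.upper() not in BASES:
            n_dropped += len(v.ALT) if v.ALT else 1
            continue
        for alt in v.ALT:
            if len(alt) != 1 or alt.upper() not in BASES or alt.upper() == v.REF.upper():
                n_dropped += 1
                continue
            rows.append((sample, v.CHROM, v.POS, v.REF.upper(), alt.upper()))
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    if n_dropped:
        logger.info("%s: dropped %d non-SNV alleles", path, n_dropped)
    cat = MutationCatalog(df, n_dropped=n_dropped)
    if cat.is_empty:
        warnings.warn(f"{path}: catalog contains no SNV", EmptyCatalogWarning)
    return cat


def read_catalog(
    path: str | Path, format: str = "maf-lite", sample: str | None = None
) -> MutationCatalog:
    """Read a mutation catalog.

    Parameters
    ----------
    path
        Input file.
    format
        ``"maf-lite"`` (project TSV dialect) or ``"vcf"``.
    sample
        Sample name override for single-sample VCFs without a sample column.
    """
    if format == "maf-lite":
        return _read_maf_lite(path)
    if format == "vcf":
        return _read_vcf(path, sample)
    raise ValueError(f"unknown catalog format {format!r}")


def write_catalog(catalog: MutationCatalog, path: str | Path) -> None:
    """Write a catalog in the maf-lite dialect (round-trips read_catalog)."""
    cols = CATALOG_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in catalog.df.columns]
    catalog.df[cols].to_csv(path, sep="\t", index=False)


def attach_context(catalog: MutationCatalog, reference: str | Path) -> MutationCatalog:
    """Fill forward-strand flanking bases from the reference sequence.

    Records whose stated reference allele disagrees with the reference
    base, sit at a sequence edge, or have a non-ACGT base in their window
    are marked ``valid = False`` and excluded from spectra downstream.

    Raises
    ------
    ValueError
        If a catalog chromosome is absent from the reference.
    """
    fa = Fasta(str(reference), sequence_always_upper=True)
    df = catalog.df.copy()
    c5 = np.empty(len(df), dtype=object)
    c3 = np.empty(len(df), dtype=object)
    valid = np.ones(len(df), dtype=bool)
    seqs: dict[str, str] = {}
    for i, (chrom, pos, ref) in enumerate(zip(df["chrom"], df["pos"], df["ref"])):
        if chrom not in seqs:
            if chrom not in fa:
                raise ValueError(f"chromosome {chrom!r} not in reference")
            seqs[chrom] = str(fa[chrom][:])
        seq = seqs[chrom]
        if pos < 2 or pos > len(seq) - 1:
            c5[i] = c3[i] = "N"
            valid[i] = False
            continue
        window = seq[pos - 2 : pos + 1]  # pos is 1-based
        c5[i], centre, c3[i] = window[0], window[1], window[2]
        if centre != ref or any(b not in BASES for b in window):
            valid[i] = False
    df["context5"], df["context3"], df["valid"] = c5, c3, valid
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("attach_context: flagged %d invalid records", n_bad)
    return MutationCatalog(df, n_dropped=catalog.n_dropped)


def annotate_tx_strand(
    catalog: MutationCatalog, annotation: TranscriptAnnotation
) -> MutationCatalog:
    """Assign each mutation the strand of its overlapping transcript(s).

    ``plus``/``minus`` when covered by transcripts of a single strand,
    ``ambiguous`` when covered by both, ``none`` when uncovered.
    """
    df = catalog.df.copy()
    out = np.empty(len(df), dtype=object)
    for i, (chrom, pos) in enumerate(zip(df["chrom"], df["pos"])):
        pos0 = pos - 1
        on_plus = annotation.covers(chrom, pos0, "plus")
        on_minus = annotation.covers(chrom, pos0, "minus")
        if on_plus and on_minus:
            out[i] = "ambiguous"
        elif on_plus:
            out[i] = "plus"
        elif on_minus:
            out[i] = "minus"
        else:
            out[i] = "none"
    df["tx_strand"] = out
    return MutationCatalog(df, n_dropped=catalog.n_dropped)
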