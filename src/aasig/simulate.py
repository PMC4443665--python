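"""Synthetic mutation catalogs with known signature structure.

The generator produces everything the analysis consumes — a fixture
reference sequence, stranded "transcripts", an opportunity table, and
per-sample SNV catalogs — from a seeded configuration, so the whole
pipeline is testable without any external data.

Model. Each sample draws its mutation count (burden), then each mutation's
96-channel class from a multinomial whose weights are the sample's
signature mixture multiplied channel-wise by the territory's trinucleotide
opportunities (signatures are per-opportunity profiles, as in the
factorization model). A:T>T:A mutations are placed on the non-transcribed
strand with probability ``strand_bias_q`` — mechanically, by placing them
at genomic sites inside transcripts of the orientation that realizes the
intended strand, so strand annotation is exercised end to end rather than
stamped on. All other mutations land at any site matching their
trinucleotide context.

The fixture reference is an i.i.d. uniform random sequence: every
trinucleotide occurs at usable and nearly equal frequency, so opportunity
weighting is exercised without distorting class proportions. Transcripts
tile 80% of the territory in alternating plus/minus blocks.

Four bundled ground-truth signatures mirror the processes relevant to
aristolochic-acid studies: an AA-like signature (A:T>T:A dominated, CAG and
TAG contexts preferred), CpG>TpG deamination, APOBEC (C>T/C>G at TCW), and
a Signature-5-like background whose A:T>T:A mass is exactly 0.125 — the
null proportion of the exposure test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import MutationCatalog
from .channels import (
    BASES,
    CHANNEL_LABELS,
    N_CHANNELS,
    PYRIMIDINES,
    TA_SLICE,
    channel_context,
    complement,
    revcomp,
)
from .opportunity import expand_to_96
from .spectrum import at_ta_subvector, opportunity_adjust

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SimulatedData",
    "bundled_signatures",
    "make_reference",
    "simulate_catalog",
    "simulate_sample_counts",
    "simulate_cohort_for_power",
]

SIGNATURE_NAMES = ("AA", "CpG", "APOBEC", "Sig5")


def bundled_signatures() -> pd.DataFrame:
    """Four column-stochastic ground-truth signatures (96 × 4).

    * ``AA`` — 0.88 of its mass on A:T>T:A, peaked at the CAG>CTG context
      (0.30) then TAG>TTG (0.22), remainder of the class uniform; the
      residual 0.12 is spread flat over the other 80 channels.
    * ``CpG`` — 0.70 on C>T at the four NCG contexts, rest flat.
    * ``APOBEC`` — 0.90 on C>T and C>G at TCA/TCT, rest flat.
    * ``Sig5`` — A:T>T:A mass exactly 0.125, uniform within the class;
      0.875 flat over the remaining 80 channels.
    """
    from .channels import channel_index

    S = np.zeros((N_CHANNELS, 4))
    ta = np.arange(N_CHANNELS)[TA_SLICE]
    non_ta = np.setdiff1d(np.arange(N_CHANNELS), ta)

    # AA-like: adenine-centric CAG and TAG hotspots
    aa = S[:, 0]
    i_cag = channel_index("A", "T", "C", "G")  # CAG>CTG
    i_tag = channel_index("A", "T", "T", "G")  # TAG>TTG
    aa[list(ta)] = (0.88 - 0.30 - 0.22) / 14.0
    aa[i_cag] = 0.30
    aa[i_tag] = 0.22
    aa[non_ta] = 0.12 / 80.0

    # CpG deamination: C>T at NCG
    cpg = S[:, 1]
    ncg = [channel_index("C", "T", f5, "G") for f5 in BASES]
    cpg[:] = 0.30 / 92.0
    cpg[ncg] = 0.70 / 4.0

    # APOBEC: C>T and C>G at TCW (W = A or T)
    apo = S[:, 2]
    tcw = [channel_index("C", a, "T", w) for a in "TG" for w in "AT"]
    apo[:] = 0.10 / 92.0
    apo[tcw] = 0.90 / 4.0

    # Signature-5-like background
    sig5 = S[:, 3]
    sig5[list(ta)] = 0.125 / 16.0
    sig5[non_ta] = 0.875 / 80.0

    return pd.DataFrame(
        S, index=pd.Index(CHANNEL_LABELS, name="channel"), columns=list(SIGNATURE_NAMES)
    )


@dataclass
class SyntheticConfig:
    """Generator settings; every random decision flows from ``seed``.

    ``burden`` may be an integer (same for every sample), a sequence of
    per-sample integers, or None for the default log-uniform draw on
    [100, 2000] — the span of per-tumor exome mutation totals the analysis
    is designed for.
    """

    samples: int
    exposures: np.ndarray  # (samples, K) mixture weights, rows sum to 1
    signatures: pd.DataFrame = field(default_factory=bundled_signatures)
    burden: int | list[int] | None = None
    strand_bias_q: float = 0.5
    seed: int = 0
    ref_length: int = 100_000
    tx_block: int = 2_000
    tx_fraction: float = 0.8

    def __post_init__(self) -> None:
        self.exposures = np.atleast_2d(np.asarray(self.exposures, dtype=float))
        if self.exposures.shape[0] != self.samples:
            raise ValueError("exposures must have one row per sample")
        if not np.allclose(self.exposures.sum(axis=1), 1.0):
            raise ValueError("exposure rows must sum to 1")
        if (self.exposures < 0).any():
            raise ValueError("exposure weights must be nonnegative")
        if not 0.0 <= self.strand_bias_q <= 1.0:
            raise ValueError("strand_bias_q must be in [0, 1]")


@dataclass
class GroundTruth:
    """Record-level truth emitted alongside a simulated catalog."""

    exposures: pd.DataFrame  # samples x K true mixture weights
    strand_bias_q: float
    records: pd.DataFrame  # sample, channel, strand ('non'/'tr'/'')
    burdens: list[int]


@dataclass
class SimulatedData:
    catalog: MutationCatalog
    truth: GroundTruth
    reference: dict[str, str]  # chromosome name -> sequence
    transcripts: pd.DataFrame  # chrom, start, end, strand (plus/minus)
    opportunities: pd.Series


def make_reference(
    length: int = 100_000,
    seed: int | np.random.Generator = 0,
    block: int = 2_000,
    tx_fraction: float = 0.8,
    name: str = "chrS1",
) -> tuple[dict[str, str], pd.DataFrame]:
    """A random fixture chromosome with alternating stranded transcripts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = "".join(rng.choice(list(BASES), size=length))
    rows = []
    tx_len = int(block * tx_fraction)
    for i, start in enumerate(range(0, length - block + 1, block)):
        strand = "plus" if i % 2 == 0 else "minus"
        rows.append((name, start, start + tx_len, strand))
    transcripts = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return {name: seq}, transcripts


def _site_index(seq: str, transcripts: pd.DataFrame):
    """Positions (0-based window centre) by forward trinucleotide and strand."""
    codes = np.array([BASES.index(b) for b in seq], dtype=np.int64)
    tri = 16 * codes[:-2] + 4 * codes[1:-1] + codes[2:]
    centres = np.arange(1, len(seq) - 1)
    strand_code = np.zeros(len(seq), dtype=np.int8)  # 0 none, 1 plus, 2 minus
    for _, r in transcripts.iterrows():
        strand_code[r.start : r.end] = 1 if r.strand == "plus" else 2
    sc = strand_code[centres]
    index: dict[tuple[str, int], np.ndarray] = {}
    tri_names = [a + b + c for a in BASES for b in BASES for c in BASES]
    for t_i, t in enumerate(tri_names):
        mask = tri == t_i
        for s in (0, 1, 2):
            sel = centres[mask & (sc == s)]
            if len(sel):
                index[(t, s)] = sel
    return index


def _pool(index, trinucs_strands) -> np.ndarray:
    parts = [index[k] for k in trinucs_strands if k in index]
    return np.concatenate(parts) if parts else np.array([], dtype=np.int64)


def _draw_burdens(config: SyntheticConfig, rng: np.random.Generator) -> list[int]:
    if config.burden is None:
        u = rng.uniform(np.log(100), np.log(2000), size=config.samples)
        return [int(round(x)) for x in np.exp(u)]
    if np.isscalar(config.burden):
        return [int(config.burden)] * config.samples
    b = [int(x) for x in config.burden]
    if len(b) != config.samples:
        raise ValueError("per-sample burden list has wrong length")
    return b


def simulate_catalog(
    config: SyntheticConfig, outdir: str | Path | None = None
) -> SimulatedData:
    """Generate a record-level catalog plus its fixture reference and truth.

    When ``outdir`` is given, writes ``reference.fa``, ``transcripts.bed``
    (BED6), ``catalog.tsv`` (maf-lite), ``opportunities.tsv`` and
    ``truth.json`` there. Deterministic for a given config and seed.
    """
    from .opportunity import write_opportunities

    rng = np.random.default_rng(config.seed)
    reference, transcripts = make_reference(
        length=config.ref_length,
        seed=rng,
        block=config.tx_block,
        tx_fraction=config.tx_fraction,
    )
    chrom, seq = next(iter(reference.items()))
    index = _site_index(seq, transcripts)

    # opportunities over the full fixture territory
    counts64 = np.zeros(64, dtype=np.int64)
    from .opportunity import _trinuc_counts, _fold64_to_32

    counts64 += _trinuc_counts(seq)
    opp = _fold64_to_32(counts64)
    opp.index.name = "trinucleotide"
    o96 = expand_to_96(opp)

    Smat = config.signatures.to_numpy(dtype=float)
    burdens = _draw_burdens(config, rng)
    rows = []
    truth_rows = []
    for g in range(config.samples):
        sample = f"S{g + 1:03d}"
        mix = Smat @ config.exposures[g]
        probs = o96 * mix
        total = probs.sum()
        if total <= 0:
            raise ValueError("infeasible configuration: zero total channel weight")
        probs = probs / total
        channel_counts = rng.multinomial(burdens[g], probs)
        for c in np.flatnonzero(channel_counts):
            m = int(channel_counts[c])
            t = channel_context(c)  # pyrimidine-centred, e.g. CTA
            rc = revcomp(t)
            cls_ref, cls_alt = CHANNEL_LABELS[c][2], CHANNEL_LABELS[c][4]
            is_ta = TA_SLICE.start <= c < TA_SLICE.stop
            if is_ta:
                n_non = int(rng.binomial(m, config.strand_bias_q))
                # mutated adenine on the coding strand: forward-T sites in
                # minus transcripts, or forward-A sites in plus transcripts
                pools = [
                    (_pool(index, [(t, 2), (rc, 1)]), n_non, "non"),
                    (_pool(index, [(t, 1), (rc, 2)]), m - n_non, "tr"),
                ]
            else:
                pools = [(_pool(index, [(t, s) for s in (0, 1, 2)] + [(rc, s) for s in (0, 1, 2)]), m, "")]
            for pool, count, label in pools:
                if count == 0:
                    continue
                if len(pool) == 0:
                    raise ValueError(
                        f"infeasible placement: no site for context {t} ({label or 'any'})"
                    )
                sites = rng.choice(pool, size=count, replace=True)
                for p in sites:
                    centre = seq[p]
                    if centre in PYRIMIDINES:  # forward strand carries t
                        ref, alt = cls_ref, cls_alt
                    else:
                        ref, alt = complement(cls_ref), complement(cls_alt)
                    rows.append((sample, chrom, int(p) + 1, ref, alt))
                    truth_rows.append((sample, int(c), label))

    catalog = MutationCatalog(
        pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt"])
    )
    truth = GroundTruth(
        exposures=pd.DataFrame(
            config.exposures,
            index=[f"S{g + 1:03d}" for g in range(config.samples)],
            columns=list(config.signatures.columns),
        ),
        strand_bias_q=config.strand_bias_q,
        records=pd.DataFrame(truth_rows, columns=["sample", "channel", "strand"]),
        burdens=burdens,
    )
    data = SimulatedData(catalog, truth, reference, transcripts, opp)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "reference.fa", "w") as fh:
            for name, s in reference.items():
                fh.write(f">{name}\n")
                for i in range(0, len(s), 70):
                    fh.write(s[i : i + 70] + "\n")
        bed = transcripts.copy()
        bed["name"] = [f"tx{i + 1}" for i in range(len(bed))]
        bed["score"] = 0
        bed["strand6"] = bed["strand"].map({"plus": "+", "minus": "-"})
        bed[["chrom", "start", "end", "name", "score", "strand6"]].to_csv(
            outdir / "transcripts.bed", sep="\t", index=False, header=False
        )
        from .catalog import write_catalog

        write_catalog(catalog, outdir / "catalog.tsv")
        write_opportunities(opp, outdir / "opportunities.tsv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "exposures": truth.exposures.to_dict(orient="index"),
                    "strand_bias_q": config.strand_bias_q,
                    "burdens": burdens,
                    "seed": config.seed,
                },
                fh,
                indent=2,
            )
    return data


def simulate_sample_counts(
    exposure_weights,
    burden: int,
    q: float,
    signatures: pd.DataFrame | None = None,
    opportunities: pd.Series | np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Count-level fast path: one sample's spectrum and strand tallies.

    Draws the channel counts and the binomial strand split directly —
    distributionally identical to ``simulate_catalog`` followed by spectrum
    and strand counting (genomic placement changes neither) — for use in
    replicated power and calibration studies.
    """
    signatures = bundled_signatures() if signatures is None else signatures
    rng = np.random.default_rng() if rng is None else rng
    w = np.asarray(exposure_weights, dtype=float)
    mix = signatures.to_numpy(dtype=float) @ w
    o = (
        np.ones(N_CHANNELS)
        if opportunities is None
        else np.asarray(expand_to_96(opportunities), dtype=float)
    )
    probs = o * mix
    probs = probs / probs.sum()
    counts = rng.multinomial(burden, probs)
    n_atta = int(counts[TA_SLICE].sum())
    n_non = int(rng.binomial(n_atta, q)) if n_atta else 0
    return {
        "counts": counts,
        "n_total": int(burden),
        "n_atta": n_atta,
        "n_non": n_non,
        "n_tr": n_atta - n_non,
    }


def reference_aa_subvector(signatures: pd.DataFrame | None = None) -> pd.Series:
    """Adenine-centric A:T>T:A profile of the AA signature, for cosine tests."""
    signatures = bundled_signatures() if signatures is None else signatures
    return at_ta_subvector(signatures["AA"])


def simulate_cohort_for_power(
    n_exposed: int,
    n_unexposed: int,
    burden: int,
    aa_fraction: float,
    seed: int = 0,
    q_exposed: float = 0.75,
    q_unexposed: float = 0.5,
    signatures: pd.DataFrame | None = None,
    opportunities: pd.Series | None = None,
) -> pd.DataFrame:
    """A labelled cohort for sensitivity/specificity studies of the tests.

    Exposed samples mix the AA signature at ``aa_fraction`` into a
    Signature-5 background with non-transcribed-strand probability
    ``q_exposed``; unexposed samples are pure background with no strand
    bias. Returns the per-sample summary table consumed by
    ``exposure.evaluate_cohort``, plus the truth column ``exposed`` and the
    sample's cosine similarity to the bundled AA signature's A:T>T:A
    context profile.
    """
    signatures = bundled_signatures() if signatures is None else signatures
    if opportunities is None:
        rng0 = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        from .opportunity import _fold64_to_32, _trinuc_counts

        ref, _ = make_reference(seed=rng0)
        opportunities = _fold64_to_32(_trinuc_counts(next(iter(ref.values()))))
    ref16 = reference_aa_subvector(signatures).to_numpy()
    rng = np.random.default_rng(seed)
    K = signatures.shape[1]
    w_exposed = np.zeros(K)
    w_exposed[signatures.columns.get_loc("AA")] = aa_fraction
    w_exposed[signatures.columns.get_loc("Sig5")] = 1.0 - aa_fraction
    w_unexposed = np.zeros(K)
    w_unexposed[signatures.columns.get_loc("Sig5")] = 1.0
    rows = []
    from .exposure import cosine_similarity

    for i in range(n_exposed + n_unexposed):
        exposed = i < n_exposed
        d = simulate_sample_counts(
            w_exposed if exposed else w_unexposed,
            burden,
            q_exposed if exposed else q_unexposed,
            signatures=signatures,
            opportunities=opportunities,
            rng=rng,
        )
        adj = opportunity_adjust(d["counts"], opportunities)
        ta16 = at_ta_subvector(adj).to_numpy()
        cos = (
            cosine_similarity(ta16, ref16) if ta16.sum() > 0 else float("nan")
        )
        rows.append(
            {
                "sample": f"{'E' if exposed else 'U'}{i + 1:03d}",
                "exposed": exposed,
                "n_total": d["n_total"],
                "n_atta": d["n_atta"],
                "n_non": d["n_non"],
                "n_tr": d["n_tr"],
                "cosine_aa": cos,
            }
        )
    return pd.DataFrame(rows).set_index("sample")
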