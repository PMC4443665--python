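"""End-to-end orchestration: catalog → spectra → tests → report.

``run_pipeline`` ties the stages together the way a cohort analysis runs:
read the catalog, attach trinucleotide context from the reference,
annotate transcript strand, build per-sample spectra and strand tallies,
run both exposure tests with cohort-wide FDR adjustment and the cosine
comparison against a reference AA signature, and (optionally) extract
de novo signatures. Outputs are a tumor-by-tumor results TSV, per-sample
spectra, and a JSON manifest recording parameters, seeds and input digests
so a run can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import (
    annotate_tx_strand,
    attach_context,
    read_catalog,
    read_transcripts_bed,
)
from .exposure import NullSpec, cosine_similarity, evaluate_cohort, format_pvalue
from .opportunity import read_opportunities
from .spectrum import (
    at_ta_subvector,
    build_spectra_matrix,
    opportunity_adjust,
    strand_counts,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class RunConfig:
    """Settings of one analysis run; defaults are the standard analysis.

    The null parameters default to the Signature-5 A:T>T:A proportion
    (0.125), the no-strand-bias null (0.5), FDR threshold 0.05 and cosine
    cutoff 0.90; factorization explores 2–8 signatures.
    """

    catalog: str
    reference: str
    transcripts: str
    opportunities: str
    outdir: str
    catalog_format: str = "maf-lite"
    reference_signature: str | None = None  # TSV with a 16-row adenine-centric profile
    p0_excess: float = 0.125
    p0_strand: float = 0.5
    fdr_threshold: float = 0.05
    cosine_cutoff: float = 0.90
    extract: bool = False
    k_min: int = 2
    k_max: int = 8
    restarts: int = 10
    seed: int = 0
    tol: float = 1e-8


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_reference_signature(path: str | None) -> pd.Series:
    if path is None:
        from .simulate import reference_aa_subvector

        return reference_aa_subvector()
    df = pd.read_csv(path, sep="\t")
    if not {"channel", "proportion"} <= set(df.columns):
        raise PipelineError(
            f"reference signature {path}: expected columns 'channel' and 'proportion'"
        )
    s = df.set_index("channel")["proportion"]
    if len(s) != 16:
        raise PipelineError("reference signature must have 16 adenine-centric channels")
    return s


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full exposure analysis; returns the per-sample results table."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, outdir, written)
    except Exception:
        for p in written:  # leave no partial outputs behind
            p.unlink(missing_ok=True)
        raise


def _run(config: RunConfig, outdir: Path, written: list[Path]) -> pd.DataFrame:
    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise PipelineError(f"stage {name!r}: {exc}") from exc

    catalog = stage("read_catalog", read_catalog, config.catalog, config.catalog_format)
    catalog = stage("attach_context", attach_context, catalog, config.reference)
    annotation = stage("read_transcripts", read_transcripts_bed, config.transcripts)
    catalog = stage("annotate_tx_strand", annotate_tx_strand, catalog, annotation)
    opp = stage("read_opportunities", read_opportunities, config.opportunities)
    ref16 = stage("reference_signature", _load_reference_signature, config.reference_signature)

    spectra = stage("build_spectra", build_spectra_matrix, catalog)
    rows = []
    for sample in spectra.columns:
        spec = spectra[sample]
        sc = stage("strand_counts", strand_counts, catalog, sample)
        n_total = int(spec.sum())
        n_atta = int(spec.iloc[48:64].sum())
        if spec.sum() > 0:
            adj = opportunity_adjust(spec, opp)
            ta16 = at_ta_subvector(adj)
            cos = (
                cosine_similarity(ta16.to_numpy(), ref16.to_numpy())
                if ta16.sum() > 0
                else float("nan")
            )
        else:
            cos = float("nan")
        rows.append(
            {
                "sample": sample,
                "n_total": n_total,
                "n_atta": n_atta,
                "n_non": sc.n_nontranscribed,
                "n_tr": sc.n_transcribed,
                "cosine_aa": cos,
            }
        )
    stats_df = pd.DataFrame(rows).set_index("sample")
    null = NullSpec(config.p0_excess, config.p0_strand, config.fdr_threshold)
    results = stage(
        "exposure_tests", evaluate_cohort, stats_df, null, config.cosine_cutoff
    )
    results["p_excess_display"] = results["log10_p_excess"].map(format_pvalue)
    results["p_strand_display"] = results["log10_p_strand"].map(format_pvalue)

    results_path = outdir / "results.tsv"
    written.append(results_path)
    results.to_csv(results_path, sep="\t")
    spectra_path = outdir / "spectra.tsv"
    written.append(spectra_path)
    spectra.to_csv(spectra_path, sep="\t", index_label="channel")

    manifest = {
        "software": {"name": "aasig", "version": __version__},
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("catalog", "reference", "transcripts", "opportunities", "outdir")
        },
        "seed": config.seed,
        "inputs": {
            name: {"path": str(getattr(config, name)), "sha256": _sha256(getattr(config, name))}
            for name in ("catalog", "reference", "transcripts", "opportunities")
        },
        "n_samples": int(len(results)),
        "n_mutations": int(len(catalog)),
        "calls": results["call"].value_counts().to_dict(),
    }

    if config.extract:
        from .signatures import select_k

        fit = stage(
            "signature_extraction",
            select_k,
            spectra,
            opp,
            config.k_min,
            config.k_max,
            config.restarts,
            config.seed,
            config.tol,
        )
        sig_path = outdir / "signatures.tsv"
        written.append(sig_path)
        fit.S.to_csv(sig_path, sep="\t")
        exp_path = outdir / "exposures.tsv"
        written.append(exp_path)
        fit.E.to_csv(exp_path, sep="\t")
        manifest["factorization"] = {
            "K": fit.K,
            "bic_by_k": {str(k): v["bic"] for k, v in fit.k_scores.items()},
            "log_likelihood": fit.log_likelihood,
            "converged": bool(fit.converged),
            "seed": fit.seed,
        }

    manifest_path = outdir / "manifest.json"
    written.append(manifest_path)
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("run complete: %d samples, results in %s", len(results), outdir)
    return results
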