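"""Synthetic-catalog generator: fixtures, determinism, record-level audit."""

import numpy as np
import pandas as pd
import pytest

from aasig.catalog import (
    TranscriptAnnotation,
    annotate_tx_strand,
    attach_context,
    read_catalog,
)
from aasig.channels import channel_index
from aasig.simulate import (
    SyntheticConfig,
    bundled_signatures,
    make_reference,
    simulate_catalog,
    simulate_cohort_for_power,
    simulate_sample_counts,
)
from aasig.spectrum import build_spectrum, strand_counts


def test_bundled_signatures_are_column_stochastic(signatures):
    assert signatures.sum().to_numpy() == pytest.approx(np.ones(4), abs=1e-9)
    assert (signatures.to_numpy() >= 0).all()


def test_aa_signature_shape(signatures):
    aa = signatures["AA"]
    assert aa.iloc[48:64].sum() >= 0.85
    assert aa.idxmax() == "C[T>A]G"  # the CAG>CTG adenine-centric hotspot


def test_apobec_and_cpg_target_their_motifs(signatures):
    cpg = signatures["CpG"]
    ncg = [channel_index("C", "T", f5, "G") for f5 in "ACGT"]
    assert cpg.iloc[ncg].sum() >= 0.5
    apo = signatures["APOBEC"]
    tcw = [channel_index("C", a, "T", w) for a in "TG" for w in "AT"]
    assert apo.iloc[tcw].sum() >= 0.5


def test_generator_is_deterministic():
    w = np.array([[0.5, 0.0, 0.0, 0.5]])
    a = simulate_catalog(SyntheticConfig(samples=1, exposures=w, burden=200, seed=42))
    b = simulate_catalog(SyntheticConfig(samples=1, exposures=w, burden=200, seed=42))
    pd.testing.assert_frame_equal(a.catalog.df, b.catalog.df)
    pd.testing.assert_series_equal(a.opportunities, b.opportunities)


def test_record_level_audit_against_fixture_reference(small_cohort):
    """Every emitted mutation's reference context matches its assigned channel."""
    config, data, outdir = small_cohort
    cat = read_catalog(outdir / "catalog.tsv")
    cat = attach_context(cat, outdir / "reference.fa")
    assert cat.df["valid"].all()
    rebuilt = [
        channel_index(r, a, c5, c3)
        for r, a, c5, c3 in zip(
            cat.df["ref"], cat.df["alt"], cat.df["context5"], cat.df["context3"]
        )
    ]
    assert rebuilt == list(data.truth.records["channel"])


def test_strand_bias_is_mechanical_not_stamped(small_cohort):
    """Re-annotating from the emitted BED reproduces the intended strand labels."""
    config, data, outdir = small_cohort
    cat = read_catalog(outdir / "catalog.tsv")
    cat = attach_context(cat, outdir / "reference.fa")
    ann = TranscriptAnnotation(data.transcripts)
    cat = annotate_tx_strand(cat, ann)
    truth = data.truth.records
    for sample in ["S001", "S002"]:
        sc = strand_counts(cat, sample)
        t = truth[truth["sample"] == sample]
        assert sc.n_nontranscribed == (t["strand"] == "non").sum()
        assert sc.n_transcribed == (t["strand"] == "tr").sum()
        assert sc.n_skipped == 0  # all A:T>T:A were placed inside transcripts


def test_pure_sig5_sample_matches_null_proportion():
    w = np.array([[0.0, 0.0, 0.0, 1.0]])
    data = simulate_catalog(
        SyntheticConfig(samples=1, exposures=w, burden=10_000, seed=13)
    )
    cat = attach_context_in_memory(data)
    spec = build_spectrum(cat, "S001")
    frac = spec.iloc[48:64].sum() / spec.sum()
    assert frac == pytest.approx(0.125, abs=0.01)


def attach_context_in_memory(data, tmp=None):
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as d:
        fa = Path(d) / "ref.fa"
        with open(fa, "w") as fh:
            for name, seq in data.reference.items():
                fh.write(f">{name}\n{seq}\n")
        return attach_context(data.catalog, fa)


def test_pure_aa_sample_realizes_strand_bias():
    w = np.array([[1.0, 0.0, 0.0, 0.0]])
    data = simulate_catalog(
        SyntheticConfig(samples=1, exposures=w, burden=2_000, strand_bias_q=0.75, seed=14)
    )
    cat = attach_context_in_memory(data)
    cat = annotate_tx_strand(cat, TranscriptAnnotation(data.transcripts))
    sc = strand_counts(cat, "S001")
    assert sc.frac_nontranscribed == pytest.approx(0.75, abs=0.03)


def test_zero_burden_gives_empty_catalog_and_valid_files(tmp_path):
    w = np.array([[0.0, 0.0, 0.0, 1.0]])
    data = simulate_catalog(
        SyntheticConfig(samples=1, exposures=w, burden=0, seed=15), outdir=tmp_path
    )
    assert len(data.catalog) == 0
    assert (tmp_path / "reference.fa").exists()
    assert (tmp_path / "transcripts.bed").exists()
    assert (tmp_path / "opportunities.tsv").exists()


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(samples=1, exposures=np.array([[0.5, 0.5, 0.5, 0.5]]))
    with pytest.raises(ValueError):
        SyntheticConfig(
            samples=1, exposures=np.array([[1.0, 0, 0, 0]]), strand_bias_q=1.5
        )


def test_count_level_path_matches_catalog_path_distribution():
    """The fast count-level generator agrees with full placement in expectation."""
    rng = np.random.default_rng(16)
    w = [0.7, 0.0, 0.0, 0.3]
    d = simulate_sample_counts(w, 50_000, q=0.75, rng=rng)
    sigs = bundled_signatures()
    mix = sigs.to_numpy() @ np.asarray(w)
    expected_ta = mix[48:64].sum()
    assert d["n_atta"] / d["n_total"] == pytest.approx(expected_ta, abs=0.01)
    assert d["n_non"] / d["n_atta"] == pytest.approx(0.75, abs=0.01)
    assert d["counts"].sum() == d["n_total"]


def test_cohort_generator_labels_and_columns():
    df = simulate_cohort_for_power(3, 5, burden=400, aa_fraction=0.7, seed=21)
    assert df["exposed"].sum() == 3
    assert len(df) == 8
    assert {"n_total", "n_atta", "n_non", "n_tr", "cosine_aa"} <= set(df.columns)
    # exposed samples show the AA context pattern; background does not
    assert df.loc[df["exposed"], "cosine_aa"].min() > 0.9
    assert df.loc[~df["exposed"], "cosine_aa"].max() < 0.9


def test_reference_transcripts_cover_80_percent():
    ref, tx = make_reference(length=50_000, seed=3)
    covered = (tx["end"] - tx["start"]).sum()
    assert covered == pytest.approx(0.8 * 50_000, rel=0.02)
    # alternating strands, non-overlapping
    assert set(tx["strand"]) == {"plus", "minus"}
    assert (tx["start"].to_numpy()[1:] >= tx["end"].to_numpy()[:-1]).all()
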