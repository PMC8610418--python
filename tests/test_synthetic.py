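"""Determinism, invariants and parameter fidelity of the data generators."""

import json

import numpy as np
import pandas as pd
import pytest

from mutasym import (
    CatalogSimParams,
    FluctuationSimParams,
    SizingError,
    SyntheticGenomeSpec,
    cluster_catalog,
    emit_dataset,
    make_reference,
    read_catalog,
    simulate_catalog,
    simulate_fluctuation,
    simulate_titration,
)
from mutasym.binding import binding_model
from mutasym.io import read_fasta, read_origins_bed, read_transcripts_bed
from mutasym.synthetic import FLANK_SPAN


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

def test_reference_is_deterministic(small_reference):
    spec, (genome, transcripts, origins) = small_reference
    genome2, transcripts2, origins2 = make_reference(spec)
    assert genome == genome2
    assert transcripts == transcripts2
    assert origins == origins2


def test_reference_invariants(small_reference):
    spec, (genome, transcripts, origins) = small_reference
    assert len(genome) == spec.n_chromosomes
    assert all(len(s) == spec.chrom_length for s in genome.values())
    # transcripts non-overlapping including their flank windows
    by_chrom = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    for chrom_txs in by_chrom.values():
        chrom_txs.sort(key=lambda t: t.start)
        for prev, nxt in zip(chrom_txs, chrom_txs[1:]):
            assert prev.end + 2 * FLANK_SPAN <= nxt.start
        for t in chrom_txs:
            assert t.start - FLANK_SPAN >= 0
            assert t.end + FLANK_SPAN <= spec.chrom_length
    # origins strictly increasing, >= 2 per chromosome
    for olist in origins.values():
        assert len(olist) >= 2
        assert all(a < b for a, b in zip(olist, olist[1:]))


def test_gc_fraction_within_binomial_bounds():
    spec = SyntheticGenomeSpec(seed=7, n_chromosomes=1, chrom_length=200_000,
                               gc_fraction=0.5, n_transcripts=5)
    genome, _, _ = make_reference(spec)
    seq = genome["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    sd = np.sqrt(0.5 * 0.5 / len(seq))
    assert abs(gc - 0.5) < 3 * sd


def test_infeasible_annotation_raises_sizing_error():
    spec = SyntheticGenomeSpec(seed=0, n_chromosomes=1, chrom_length=20_000,
                               n_transcripts=10,
                               transcript_length_range=(2000, 2000))
    with pytest.raises(SizingError):
        make_reference(spec)


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

def test_catalog_is_deterministic(small_reference):
    _, (genome, transcripts, origins) = small_reference
    params = CatalogSimParams(seed=9, n_samples=2)
    a = simulate_catalog(genome, transcripts, origins, params)
    b = simulate_catalog(genome, transcripts, origins, params)
    assert [c.records for c in a] == [c.records for c in b]


def test_catalog_refs_match_genome(small_catalogs, small_reference):
    _, (genome, _, _) = small_reference
    for cat in small_catalogs:
        for rec in cat.records:
            seq = genome[rec.chrom]
            assert seq[rec.pos - 1 : rec.pos - 1 + len(rec.ref)] == rec.ref


def test_no_duplicate_positions_within_sample(small_catalogs):
    for cat in small_catalogs:
        keys = [(r.chrom, r.pos) for r in cat.records]
        assert len(keys) == len(set(keys))


def test_substitution_fraction_matches_target(default_reference):
    _, (genome, transcripts, origins) = default_reference
    params = CatalogSimParams(seed=21, n_samples=5,
                              mutations_per_genome_mean=400)
    cats = simulate_catalog(genome, transcripts, origins, params)
    events = [e for c in cats for e in cluster_catalog(c).events]
    subs = sum(e.event_class == "substitution" for e in events)
    frac = subs / len(events)
    sd = np.sqrt(0.95 * 0.05 / len(events))
    assert abs(frac - 0.95) < 4 * sd


def test_complex_events_are_two_records_within_ten_bp(small_reference):
    _, (genome, transcripts, origins) = small_reference
    params = CatalogSimParams(
        seed=13, n_samples=3, mutations_per_genome_mean=60,
        substitution_fraction=0.0, indel_fraction=0.0, complex_fraction=1.0,
    )
    cats = simulate_catalog(genome, transcripts, origins, params)
    for cat in cats:
        clustered = cluster_catalog(cat)
        assert clustered.events, "complex-only catalog should not be empty"
        for ev in clustered.events:
            assert ev.event_class == "complex"
            gaps = np.diff([r.pos for r in ev.records])
            assert (gaps >= 1).all() and (gaps <= 10).all()


def test_depth_and_vaf_straddle_the_call_filter(small_reference):
    """Default read-support metadata produces both passing and failing
    records for the 45-55% window."""
    _, (genome, transcripts, origins) = small_reference
    params = CatalogSimParams(seed=17, n_samples=5,
                              mutations_per_genome_mean=200)
    cats = simulate_catalog(genome, transcripts, origins, params)
    afs = np.array([r.alt_fraction for c in cats for r in c.records])
    inside = ((afs >= 0.45) & (afs <= 0.55)).mean()
    assert 0.80 < inside < 0.98


def test_event_fraction_validation():
    with pytest.raises(ValueError):
        CatalogSimParams(substitution_fraction=0.9, indel_fraction=0.2,
                         complex_fraction=0.0)
    with pytest.raises(ValueError):
        CatalogSimParams(class_weights=(1, 0, 0, 0, 0, 0.1))


def test_impossible_class_request_errors():
    genome = {"chr1": "A" * 9000}
    with pytest.raises(ValueError, match="G:C"):
        simulate_catalog(
            genome, [], {}, CatalogSimParams(
                seed=1, n_samples=1, mutations_per_genome_mean=50,
                substitution_fraction=1.0, indel_fraction=0.0,
                complex_fraction=0.0,
                class_weights=(0, 0, 0, 1, 0, 0)),
        )


# ---------------------------------------------------------------------------
# round trip through the package's own readers
# ---------------------------------------------------------------------------

def test_emitted_dataset_round_trips(tmp_path, small_reference):
    spec, (genome, transcripts, origins) = small_reference
    params = CatalogSimParams(seed=3, n_samples=2,
                              mutations_per_genome_mean=40)
    out = emit_dataset(tmp_path / "ds", spec, params, genotype="wt")
    assert read_fasta(out / "genome.fa") == genome
    assert read_transcripts_bed(out / "transcripts.bed") == transcripts
    assert read_origins_bed(out / "origins.bed") == origins
    truth = json.loads((out / "truth.json").read_text())
    assert truth["catalog_params"]["seed"] == 3
    cats = simulate_catalog(genome, transcripts, origins, params,
                            genotype="wt")
    for cat in cats:
        from_tsv = read_catalog(out / f"{cat.sample_id}.tsv")
        assert from_tsv.records == cat.records
        from_vcf = read_catalog(out / f"{cat.sample_id}.vcf")
        assert [r.key() for r in from_vcf.records] == [
            r.key() for r in sorted(cat.records,
                                    key=lambda r: (r.chrom, r.pos))]


# ---------------------------------------------------------------------------
# fluctuation cultures
# ---------------------------------------------------------------------------

def test_zero_rate_gives_zero_resistant_counts():
    df = simulate_fluctuation(FluctuationSimParams(seed=1, mu=0.0,
                                                   n_final=1e6,
                                                   n_cultures=12))
    assert (df["canr_colonies"] == 0).all()
    assert (df["sc_colonies"] > 0).all()


def test_fluctuation_is_deterministic():
    p = FluctuationSimParams(seed=5)
    pd.testing.assert_frame_equal(simulate_fluctuation(p),
                                  simulate_fluctuation(p))


def _naive_luria_delbruck(rng, mu, n_final):
    """Independent oracle: explicit per-generation populations.  Wild-type
    cells double, each division mutating with probability mu; mutants double
    deterministically."""
    wt, mut = 1, 0
    while wt + mut < n_final:
        new = rng.binomial(wt, mu)
        mut, wt = mut * 2 + new, wt * 2 - new
    return mut


def test_generator_matches_naive_simulation_oracle():
    """Median resistant counts agree with a direct generation-by-generation
    simulation at a dyadic culture size, where both follow the same law."""
    mu, n_final = 1e-5, 2**20
    rng = np.random.default_rng(77)
    naive = [_naive_luria_delbruck(rng, mu, n_final) for _ in range(300)]
    df = simulate_fluctuation(FluctuationSimParams(
        seed=78, mu=mu, n_final=n_final, n_cultures=300))
    assert df["canr_colonies"].median() == pytest.approx(
        np.median(naive), rel=0.30)


# ---------------------------------------------------------------------------
# titrations
# ---------------------------------------------------------------------------

def test_noiseless_titration_reproduces_model_exactly():
    x = np.linspace(0, 1600, 20)
    table = simulate_titration(250.0, 0.2, 5.0, x, noise_sd=0.0)
    assert np.array_equal(table["anisotropy"].to_numpy(),
                          binding_model(x, 0.2, 5.0, 250.0))
    assert table["anisotropy"].iloc[0] == 0.0


def test_titration_deterministic_and_validated():
    x = np.linspace(0, 100, 5)
    a = simulate_titration(250, 0.2, 5, x, noise_sd=0.01, seed=2)
    b = simulate_titration(250, 0.2, 5, x, noise_sd=0.01, seed=2)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(ValueError):
        simulate_titration(250, 0.2, 5, [10, 5, 20])
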