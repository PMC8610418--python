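"""Transcription/replication binning, strand resolution and regression."""

import numpy as np
import pandas as pd
import pytest

from mutasym import (
    CatalogSimParams,
    SampleCatalog,
    Transcript,
    assign_replication_bin,
    assign_transcription_bin,
    fit_asymmetry_regression,
    replication_fraction_profile,
    replication_strand_base,
    simulate_catalog,
    strand_mutated_base,
    transcription_density_profile,
)
from mutasym.asymmetry import transcription_bin_order

from conftest import make_record

TX_PLUS = Transcript(chrom="chr1", start=5000, end=6000, strand="+", id="t+")
TX_MINUS = Transcript(chrom="chr1", start=5000, end=6000, strand="-", id="t-")


# ---------------------------------------------------------------------------
# transcription bins
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pos,expected",
    [
        (5501, "3"),      # fractional position 0.50 -> middle body bin
        (5001, "1"),      # TSS itself
        (6000, "5"),      # last body base
        (4601, "-1"),     # 400 bp upstream of the TSS
        (4501, "-1"),     # 500 bp upstream: still the TSS-adjacent bin
        (4500, "-2"),
        (3501, "-3"),     # 1500 bp upstream: outermost flank bin
        (3500, None),     # 1501 bp upstream: outside
        (6001, "+1"),     # first base after the TTS
        (7500, "+3"),
        (7501, None),
    ],
)
def test_assign_transcription_bin_plus_strand(pos, expected):
    assert assign_transcription_bin(pos, TX_PLUS) == expected


@pytest.mark.parametrize(
    "pos,expected",
    [
        (6000, "1"),      # TSS of a minus-strand transcript is its right end
        (5001, "5"),
        (6400, "-1"),     # upstream now means larger coordinates
        (7500, "-3"),
        (7501, None),
        (5000, "+1"),     # immediately downstream of the TTS
        (3501, "+3"),
        (3500, None),
    ],
)
def test_assign_transcription_bin_minus_strand(pos, expected):
    assert assign_transcription_bin(pos, TX_MINUS) == expected


def test_bins_partition_the_window():
    """Every position in the flank+body window maps to exactly one bin."""
    for tx in (TX_PLUS, TX_MINUS):
        seen = {}
        for pos in range(3501, 7501):
            b = assign_transcription_bin(pos, tx)
            assert b is not None
            seen.setdefault(b, 0)
            seen[b] += 1
        assert set(seen) == set(transcription_bin_order())
        for label in ("-1", "-2", "-3", "+1", "+2", "+3"):
            assert seen[label] == 500
        assert sum(seen[str(b)] for b in range(1, 6)) == len(tx)


# ---------------------------------------------------------------------------
# strand resolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "ref,strand,expected",
    [
        # exhaustive 8-case truth table: the non-transcribed strand is the
        # coding strand, i.e. the top strand of a + transcript
        ("A", "+", ("A", "non_transcribed")),
        ("C", "+", ("C", "non_transcribed")),
        ("T", "+", ("A", "transcribed")),
        ("G", "+", ("C", "transcribed")),
        ("A", "-", ("A", "transcribed")),
        ("C", "-", ("C", "transcribed")),
        ("T", "-", ("A", "non_transcribed")),
        ("G", "-", ("C", "non_transcribed")),
    ],
)
def test_strand_mutated_base_truth_table(ref, strand, expected):
    assert strand_mutated_base(ref, strand) == expected


def test_replication_strand_base():
    assert replication_strand_base("A") == ("A", "top")
    assert replication_strand_base("C") == ("C", "top")
    assert replication_strand_base("T") == ("A", "bottom")
    assert replication_strand_base("G") == ("C", "bottom")
    with pytest.raises(ValueError):
        replication_strand_base("AG")


# ---------------------------------------------------------------------------
# transcription density profile
# ---------------------------------------------------------------------------

def _uniform_genome(length=10_000, base="A"):
    return {"chr1": base * length}


def test_density_counts_and_normalization():
    genome = _uniform_genome()
    tx = Transcript(chrom="chr1", start=5000, end=6000, strand="+", id="t")
    # one A mutation in body bin 3 of an all-A genome
    cat = SampleCatalog("s", [make_record(pos=5501, ref="A", alt="G")])
    prof = transcription_density_profile([cat], [tx], genome)
    row = prof[(prof["base"] == "A") & (prof["strand"] == "non_transcribed")
               & (prof["bin"] == "3")].iloc[0]
    assert row["mutation_count"] == 1
    assert row["opportunity_count"] == 200  # a fifth of the 1-kb body
    assert row["density"] == pytest.approx(1 / 200)
    # all other strand/base combinations have zero opportunity on this genome
    other = prof[(prof["strand"] == "transcribed") & (prof["base"] == "A")]
    assert (other["opportunity_count"] == 0).all()
    assert other["density"].isna().all()


def test_zero_mutations_zero_densities():
    genome = _uniform_genome()
    tx = Transcript(chrom="chr1", start=5000, end=6000, strand="+", id="t")
    prof = transcription_density_profile([], [tx], genome)
    nonzero_opp = prof[prof["opportunity_count"] > 0]
    assert (nonzero_opp["density"] == 0).all()


def test_density_conservation(small_reference, small_catalogs):
    """Every in-window substitution lands in exactly one bin per transcript."""
    _, (genome, transcripts, origins) = small_reference
    prof = transcription_density_profile(small_catalogs, transcripts, genome)
    expected = 0
    for cat in small_catalogs:
        for rec in cat.records:
            if not rec.is_substitution:
                continue
            for t in transcripts:
                if t.chrom == rec.chrom and assign_transcription_bin(
                    rec.pos, t
                ) is not None:
                    expected += 1
    assert prof["mutation_count"].sum() == expected


def test_strand_flip_exchanges_labels_and_mirrors_bins(rng):
    """Flipping every transcript's strand swaps transcribed with
    non-transcribed and reverses the 5'->3' bin order.

    Transcript lengths are multiples of the body-bin count so the mirrored
    bin boundaries coincide exactly.
    """
    genome = {"chr1": "".join(rng.choice(list("ACGT"), size=30_000))}
    transcripts = [
        Transcript("chr1", 5000, 6000, "+", "a"),
        Transcript("chr1", 15_000, 17_500, "-", "b"),
    ]
    flipped = [
        Transcript(t.chrom, t.start, t.end, "-" if t.strand == "+" else "+",
                   t.id)
        for t in transcripts
    ]
    catalogs = [
        SampleCatalog("s", [
            make_record(pos=int(p) + 1, ref=genome["chr1"][int(p)],
                        alt="A" if genome["chr1"][int(p)] != "A" else "C")
            for p in rng.choice(30_000, size=400, replace=False)
        ])
    ]
    a = transcription_density_profile(catalogs, transcripts, genome)
    b = transcription_density_profile(catalogs, flipped, genome)
    order = transcription_bin_order()
    mirror = dict(zip(order, order[::-1]))
    swap = {"transcribed": "non_transcribed", "non_transcribed": "transcribed"}
    b_indexed = b.set_index(["base", "strand", "bin"])
    for row in a.itertuples():
        twin = b_indexed.loc[(row.base, swap[row.strand], mirror[row.bin])]
        assert twin["mutation_count"] == row.mutation_count
        assert twin["opportunity_count"] == row.opportunity_count


# ---------------------------------------------------------------------------
# replication bins and fractions
# ---------------------------------------------------------------------------

def test_assign_replication_bin():
    origins = [10_000, 20_000]
    b, pair = assign_replication_bin(15_001, origins)  # midpoint
    assert b == 5 and pair == (10_000, 20_000)
    assert assign_replication_bin(10_001, origins)[0] == 0  # at left origin
    assert assign_replication_bin(20_000, origins)[0] == 9  # last base inside
    assert assign_replication_bin(5_000, origins) is None   # before first
    assert assign_replication_bin(20_001, origins) is None  # at last origin
    assert assign_replication_bin(25_000, origins) is None


def test_replication_fractions_complementarity():
    origins = {"chr1": [0, 10_000]}
    recs = [make_record(pos=p, ref=r, alt="T" if r == "C" else "C")
            for p, r in [(5001, "C"), (5002, "C"), (5003, "C"), (5010, "G")]]
    prof = replication_fraction_profile([SampleCatalog("s", recs)], origins)
    row = prof[(prof["base"] == "C") & (prof["bin"] == 5)].iloc[0]
    assert row["n_top"] == 3 and row["n_bottom"] == 1
    assert row["fraction_top"] == pytest.approx(0.75)
    assert row["fraction_bottom"] == pytest.approx(0.25)
    filled = prof.dropna(subset=["fraction_top"])
    assert np.allclose(filled["fraction_top"] + filled["fraction_bottom"], 1.0)


def test_empty_bins_flagged_not_imputed():
    origins = {"chr1": [0, 10_000]}
    prof = replication_fraction_profile(
        [SampleCatalog("s", [make_record(pos=501, ref="C", alt="T")])], origins
    )
    assert prof[(prof["base"] == "C") & (prof["bin"] == 3)][
        "fraction_top"].isna().all()


# ---------------------------------------------------------------------------
# asymmetry regression
# ---------------------------------------------------------------------------

def _profile_from_fractions(fracs):
    rows = []
    for b, f in enumerate(fracs):
        rows.append(("C", b, 10, 10, f, 1 - f))
    return pd.DataFrame(rows, columns=["base", "bin", "n_top", "n_bottom",
                                       "fraction_top", "fraction_bottom"])


def test_flat_fractions_fit_zero_slope():
    fits = fit_asymmetry_regression(_profile_from_fractions([0.5] * 10))
    assert fits["top"].slope == pytest.approx(0.0)
    assert fits["top"].intercept == pytest.approx(0.5)


def test_exact_linear_fractions_recovered():
    x = (np.arange(10) + 0.5) / 10
    fits = fit_asymmetry_regression(_profile_from_fractions(0.3 + 0.4 * x))
    assert fits["top"].slope == pytest.approx(0.4)
    assert fits["top"].intercept == pytest.approx(0.3)
    assert fits["top"].r_squared == pytest.approx(1.0)
    assert fits["bottom"].slope == pytest.approx(-0.4)


def test_too_few_bins_rejected():
    with pytest.raises(ValueError):
        fit_asymmetry_regression(_profile_from_fractions([0.5]))


def test_injected_gradient_recovered_within_ci(default_reference):
    """A simulated lagging-strand C gradient is recovered by the regression,
    and complementarity forces equal-magnitude opposite-sign slopes."""
    _, (genome, transcripts, origins) = default_reference
    params = CatalogSimParams(
        seed=101, n_samples=1, mutations_per_genome_mean=20_000,
        substitution_fraction=1.0, indel_fraction=0.0, complex_fraction=0.0,
        class_weights=(0, 0, 0, 1 / 3, 1 / 3, 1 / 3), rep_gradient_C=0.4,
    )
    cats = simulate_catalog(genome, transcripts, origins, params)
    prof = replication_fraction_profile(cats, origins)
    fits = fit_asymmetry_regression(prof, base="C")
    lo, hi = fits["top"].slope_ci()
    assert lo <= 0.4 <= hi
    assert fits["top"].slope == pytest.approx(-fits["bottom"].slope, abs=1e-9)
    assert fits["top"].intercept + fits["bottom"].intercept == pytest.approx(
        1.0, abs=1e-9)
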