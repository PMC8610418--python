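"""Strand-resolved mutation asymmetry across transcripts and replicons.

Two readouts, both restricted to single-base substitutions at A:T or G:C
pairs and reported for the mutated base A or C (each base pair carries
exactly one A or one C, so naming the strand that carries it fully resolves
the strand of the event):

* **Transcriptional asymmetry** — each transcript is split into five
  fractional body bins of 0.2 of its length, flanked by three 500-bp bins
  upstream of the TSS and three downstream of the TTS.  Per bin and per
  strand (transcribed vs non-transcribed), mutation *density* is the number
  of mutated A (or C) bases divided by the number of A (or C) opportunities
  on that strand in that bin.  Excess density on the non-transcribed strand
  is the signature of transcription-coupled repair of the template strand or
  of lesions forming on transiently single-stranded DNA.

* **Replicative asymmetry** — each interval between neighboring replication
  origins is split into ten 0.1 fractional bins; per bin, the fraction of A
  (or C) mutations carried by the top vs bottom strand is computed, and a
  linear regression of fraction against fractional position summarizes the
  gradient expected when a lesion is preferentially formed or bypassed on
  the leading or lagging strand template.

The *non-transcribed* strand is the coding (mRNA-like) strand: for a
plus-strand transcript this is the top/Watson strand.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .catalog import MutationRecord, SampleCatalog
from .spectrum import COMPLEMENT

#: transcription bin labels in 5'->3' order (upstream, body, downstream)
def transcription_bin_order(body_bins: int = 5, flank_bins: int = 3) -> list[str]:
    return (
        [str(-k) for k in range(flank_bins, 0, -1)]
        + [str(b) for b in range(1, body_bins + 1)]
        + [f"+{k}" for k in range(1, flank_bins + 1)]
    )


@dataclass(frozen=True)
class Transcript:
    """A strand-annotated transcript; coordinates 0-based, half-open.

    The TSS is ``start`` for a plus-strand transcript and ``end - 1`` for a
    minus-strand one; the TTS is the opposite end.
    """

    chrom: str
    start: int
    end: int
    strand: str
    id: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"transcript {self.id}: start must be < end")
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.id}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start


def transcription_bin_intervals(
    transcript: Transcript,
    body_bins: int = 5,
    flank_bins: int = 3,
    flank_size: int = 500,
) -> list[tuple[str, int, int]]:
    """Genomic half-open intervals for each bin of one transcript.

    Body bin *b* holds fractional coordinates [(b-1)/B, b/B) measured from
    the TSS in transcript orientation; flank bin -1 abuts the TSS and +1
    abuts the TTS, each flank bin spanning ``flank_size`` bp.  Intervals may
    extend past chromosome ends; callers clip.
    """
    t, L, B, f = transcript, len(transcript), body_bins, flank_size
    out = []
    if t.strand == "+":
        for k in range(1, flank_bins + 1):
            out.append((str(-k), t.start - k * f, t.start - (k - 1) * f))
        for b in range(1, B + 1):
            lo = -(-((b - 1) * L) // B)  # ceil
            hi = -(-(b * L) // B)
            out.append((str(b), t.start + lo, t.start + hi))
        for k in range(1, flank_bins + 1):
            out.append((f"+{k}", t.end + (k - 1) * f, t.end + k * f))
    else:
        for k in range(1, flank_bins + 1):
            out.append((str(-k), t.end + (k - 1) * f, t.end + k * f))
        for b in range(1, B + 1):
            lo = -(-((b - 1) * L) // B)
            hi = -(-(b * L) // B)
            out.append((str(b), t.end - hi, t.end - lo))
        for k in range(1, flank_bins + 1):
            out.append((f"+{k}", t.start - k * f, t.start - (k - 1) * f))
    return out


def assign_transcription_bin(
    pos: int,
    transcript: Transcript,
    body_bins: int = 5,
    flank_bins: int = 3,
    flank_size: int = 500,
) -> str | None:
    """Bin label for 1-based position ``pos``, or None if outside all bins."""
    i = pos - 1
    for label, lo, hi in transcription_bin_intervals(
        transcript, body_bins, flank_bins, flank_size
    ):
        if lo <= i < hi:
            return label
    return None


def strand_mutated_base(ref: str, frame_strand: str) -> tuple[str, str]:
    """Resolve which strand of a transcript frame carries the mutated A or C.

    ``ref`` is the reference base read on the top strand; ``frame_strand`` is
    the transcript's strand.  Returns ``(base, label)`` with base in {A, C}
    and label in {transcribed, non_transcribed}.
    """
    ref = ref.upper()
    if ref not in COMPLEMENT:
        raise ValueError(f"not a single reference base: {ref!r}")
    if frame_strand not in "+-":
        raise ValueError(f"bad strand {frame_strand!r}")
    # top strand is the coding (non-transcribed) strand of a + transcript
    top_label = "non_transcribed" if frame_strand == "+" else "transcribed"
    other = "transcribed" if top_label == "non_transcribed" else "non_transcribed"
    if ref in "AC":
        return ref, top_label
    return COMPLEMENT[ref], other


def replication_strand_base(ref: str) -> tuple[str, str]:
    """Resolve which genomic strand (top/bottom) carries the mutated A or C."""
    ref = ref.upper()
    if ref not in COMPLEMENT:
        raise ValueError(f"not a single reference base: {ref!r}")
    if ref in "AC":
        return ref, "top"
    return COMPLEMENT[ref], "bottom"


# ---------------------------------------------------------------------------
# transcription profile
# ---------------------------------------------------------------------------

_BASE_STRAND = {
    # (top-strand base, transcript strand) -> (mutable base, strand label)
    ("A", "+"): ("A", "non_transcribed"),
    ("T", "+"): ("A", "transcribed"),
    ("C", "+"): ("C", "non_transcribed"),
    ("G", "+"): ("C", "transcribed"),
    ("A", "-"): ("A", "transcribed"),
    ("T", "-"): ("A", "non_transcribed"),
    ("C", "-"): ("C", "transcribed"),
    ("G", "-"): ("C", "non_transcribed"),
}


def _substitutions(catalogs: list[SampleCatalog]) -> list[MutationRecord]:
    return [r for cat in catalogs for r in cat.records if r.is_substitution]


def transcription_density_profile(
    catalogs: list[SampleCatalog],
    transcripts: list[Transcript],
    genome: dict[str, str],
    body_bins: int = 5,
    flank_bins: int = 3,
    flank_size: int = 500,
    exclude_overlapping: bool = False,
) -> pd.DataFrame:
    """Strand-resolved A- and C-mutation densities per transcription bin.

    Density = mutated X bases on a strand in bin b, summed over transcripts,
    divided by the number of X bases on that strand in bin b (the mutational
    opportunity).  A substitution inside two overlapping transcript frames
    counts once per frame unless ``exclude_overlapping``.  Bins with zero
    opportunity get density NaN.
    """
    order = transcription_bin_order(body_bins, flank_bins)
    counts = {
        (base, strand, b): 0
        for base in "AC"
        for strand in ("transcribed", "non_transcribed")
        for b in order
    }
    opps = dict.fromkeys(counts, 0)

    trees: dict[str, IntervalTree] = {}
    flank_span = flank_bins * flank_size
    for t in transcripts:
        if t.chrom not in genome:
            raise ValueError(f"transcript {t.id} on unknown chromosome {t.chrom}")
        if t.end > len(genome[t.chrom]):
            raise ValueError(f"transcript {t.id} outside chromosome bounds")
        trees.setdefault(t.chrom, IntervalTree()).addi(
            max(0, t.start - flank_span), t.end + flank_span, t
        )
        seq = genome[t.chrom]
        for label, lo, hi in transcription_bin_intervals(
            t, body_bins, flank_bins, flank_size
        ):
            window = seq[max(0, lo) : max(0, hi)]
            for top_base in "ACGT":
                base, strand = _BASE_STRAND[(top_base, t.strand)]
                opps[(base, strand, label)] += window.count(top_base)

    for rec in _substitutions(catalogs):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        hits = [iv.data for iv in tree[rec.pos - 1]]
        if exclude_overlapping and len(hits) > 1:
            continue
        for t in hits:
            label = assign_transcription_bin(
                rec.pos, t, body_bins, flank_bins, flank_size
            )
            if label is None:
                continue
            base, strand = _BASE_STRAND[(rec.ref, t.strand)]
            counts[(base, strand, label)] += 1

    rows = []
    for (base, strand, b), n in counts.items():
        opp = opps[(base, strand, b)]
        rows.append((base, strand, b, n, opp, n / opp if opp else np.nan))
    df = pd.DataFrame(
        rows,
        columns=["base", "strand", "bin", "mutation_count", "opportunity_count",
                 "density"],
    )
    df["bin"] = pd.Categorical(df["bin"], categories=order, ordered=True)
    return df.sort_values(["base", "strand", "bin"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# replication profile
# ---------------------------------------------------------------------------

def assign_replication_bin(
    pos: int, origins: list[int], n_bins: int = 10
) -> tuple[int, tuple[int, int]] | None:
    """Fractional bin of 1-based ``pos`` within its inter-origin interval.

    ``origins`` are sorted 0-based origin midpoints on one chromosome.  A
    position at an origin falls in bin 0 of the rightward interval; positions
    before the first or at/after the last origin are outside the analyzed
    domain and return None.
    """
    if len(origins) < 2:
        return None
    p = pos - 1
    idx = bisect_right(origins, p)
    if idx == 0 or idx >= len(origins):
        return None
    o_i, o_j = origins[idx - 1], origins[idx]
    frac = (p - o_i) / (o_j - o_i)
    return min(n_bins - 1, int(frac * n_bins)), (o_i, o_j)


def replication_fraction_profile(
    catalogs: list[SampleCatalog],
    origins: dict[str, list[int]],
    n_bins: int = 10,
) -> pd.DataFrame:
    """Per-bin fraction of A (and C) mutations on the top vs bottom strand.

    For every non-empty bin, fraction_top + fraction_bottom = 1 exactly; bins
    with no mutations get NaN fractions rather than an imputed value.
    """
    counts = {(base, b, s): 0 for base in "AC" for b in range(n_bins)
              for s in ("top", "bottom")}
    for rec in _substitutions(catalogs):
        chrom_origins = origins.get(rec.chrom)
        if not chrom_origins:
            continue
        hit = assign_replication_bin(rec.pos, chrom_origins, n_bins)
        if hit is None:
            continue
        b, _ = hit
        base, strand = replication_strand_base(rec.ref)
        counts[(base, b, strand)] += 1

    rows = []
    for base in "AC":
        for b in range(n_bins):
            top = counts[(base, b, "top")]
            bot = counts[(base, b, "bottom")]
            tot = top + bot
            rows.append(
                (base, b, top, bot,
                 top / tot if tot else np.nan,
                 bot / tot if tot else np.nan)
            )
    return pd.DataFrame(
        rows,
        columns=["base", "bin", "n_top", "n_bottom", "fraction_top",
                 "fraction_bottom"],
    )


@dataclass
class RegressionFit:
    """OLS fit of strand fraction against fractional replicon coordinate."""

    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    n_bins_used: int

    def slope_ci(self, z: float = 1.96) -> tuple[float, float]:
        return (self.slope - z * self.slope_stderr,
                self.slope + z * self.slope_stderr)


def fit_asymmetry_regression(
    profile: pd.DataFrame, base: str = "C", n_bins: int = 10
) -> dict[str, RegressionFit]:
    """Fit fraction-vs-position lines for the top and bottom strands.

    Bin centers (b + 0.5)/n_bins serve as the fractional coordinate.  Because
    the two strand fractions are complementary, the fitted slopes are equal
    in magnitude and opposite in sign.
    """
    sub = profile[(profile["base"] == base) & profile["fraction_top"].notna()]
    if len(sub) < 2:
        raise ValueError(f"need >= 2 non-empty bins for base {base!r}")
    x = (sub["bin"].to_numpy() + 0.5) / n_bins
    fits = {}
    for strand in ("top", "bottom"):
        y = sub[f"fraction_{strand}"].to_numpy(dtype=float)
        if np.allclose(y, y[0]):
            fits[strand] = RegressionFit(0.0, float(y[0]), 0.0, 0.0, len(sub))
            continue
        res = stats.linregress(x, y)
        fits[strand] = RegressionFit(
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue) ** 2,
            slope_stderr=float(res.stderr),
            n_bins_used=len(sub),
        )
    return fits
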