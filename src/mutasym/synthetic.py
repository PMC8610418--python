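"""Synthetic genomes, mutation catalogs, fluctuation counts and titrations.

Every downstream stage of the pipeline is exercisable against data with known
injected structure:

* :func:`make_reference` builds a toy genome with non-overlapping,
  strand-annotated transcripts (kept clear of each other's 1500-bp flank
  windows) and sorted replication-origin maps;
* :func:`simulate_catalog` draws per-sample mutation tables whose event-class
  mix, substitution spectrum, transcriptional strand bias of C mutations and
  replicative top-strand gradient are all set by parameters, with per-record
  depth and allele-fraction metadata so the call filters see both passing and
  failing records;
* :func:`simulate_fluctuation` draws resistant-colony counts from an explicit
  Luria-Delbruck process (mutation events per division, clonal expansion);
* :func:`simulate_titration` evaluates the quadratic one-site binding model
  and adds Gaussian noise.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .asymmetry import Transcript
from .binding import binding_model
from .catalog import MutationRecord, SampleCatalog, write_catalog_tsv, write_catalog_vcf
from .io import write_fasta, write_origins_bed, write_transcripts_bed
from .spectrum import COMPLEMENT, SUBSTITUTION_CLASSES

FLANK_SPAN = 3 * 500  # three 500-bp flank bins on each side of a transcript


class SizingError(ValueError):
    """The requested annotation cannot be placed on the requested genome."""


# ---------------------------------------------------------------------------
# reference genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Sizing of the toy genome and its annotation.

    Defaults give two 200-kb chromosomes at yeast-like 38% GC carrying 40
    transcripts of 2-4 kb (30% transcript occupancy, enough mutational
    opportunity on both strands for density ratios) and four replication
    origins per chromosome.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 200_000
    gc_fraction: float = 0.38
    n_transcripts: int = 40
    transcript_length_range: tuple[int, int] = (2000, 4000)
    intergenic_min: int = 1000
    origins_per_chromosome: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        lo, hi = self.transcript_length_range
        if not 0 < lo <= hi:
            raise ValueError("bad transcript_length_range")
        if self.chrom_length <= hi + 2 * FLANK_SPAN:
            raise SizingError(
                "chrom_length must exceed the longest transcript plus its "
                f"two {FLANK_SPAN}-bp flank windows"
            )
        if self.origins_per_chromosome < 2:
            raise ValueError("need >= 2 origins per chromosome")


def make_reference(
    spec: SyntheticGenomeSpec,
) -> tuple[dict[str, str], list[Transcript], dict[str, list[int]]]:
    """Deterministically generate (genome, transcripts, origins) for ``spec``.

    Transcript blocks (transcript plus both flank windows) are placed without
    overlap and with at least ``intergenic_min`` bp between blocks; a spec
    that cannot be placed raises :class:`SizingError`.  Origins are evenly
    spaced with jitter, strictly increasing within each chromosome.
    """
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_fraction
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    bases = np.array(list("ACGT"))

    genome: dict[str, str] = {}
    transcripts: list[Transcript] = []
    origins: dict[str, list[int]] = {}

    # distribute transcripts across chromosomes as evenly as possible
    per_chrom = [
        spec.n_transcripts // spec.n_chromosomes
        + (1 if c < spec.n_transcripts % spec.n_chromosomes else 0)
        for c in range(spec.n_chromosomes)
    ]

    tx_counter = 0
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        genome[chrom] = "".join(
            rng.choice(bases, size=spec.chrom_length, p=probs)
        )

        k = per_chrom[c]
        lengths = rng.integers(
            spec.transcript_length_range[0],
            spec.transcript_length_range[1] + 1,
            size=k,
        )
        blocks = lengths + 2 * FLANK_SPAN
        slack = spec.chrom_length - int(blocks.sum()) - (k + 1) * spec.intergenic_min
        if slack < 0:
            raise SizingError(
                f"{chrom}: {k} transcripts of total block size {blocks.sum()} "
                f"plus minimum gaps exceed chrom_length {spec.chrom_length}"
            )
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1))) if k else []
        cursor = 0
        for j in range(k):
            cursor += spec.intergenic_min + int(extra[j])
            start = cursor + FLANK_SPAN
            end = start + int(lengths[j])
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                Transcript(chrom=chrom, start=start, end=end, strand=strand,
                           id=f"tx{tx_counter:04d}")
            )
            tx_counter += 1
            cursor += int(blocks[j])

        n_ori = spec.origins_per_chromosome
        anchors = np.linspace(0.05, 0.95, n_ori) * spec.chrom_length
        jitter = rng.uniform(-0.02, 0.02, size=n_ori) * spec.chrom_length
        pos = np.sort(np.clip((anchors + jitter).astype(int), 0,
                              spec.chrom_length - 1))
        while len(set(pos.tolist())) < n_ori:  # nudge rare duplicates apart
            pos = np.sort(pos + np.arange(n_ori))
        origins[chrom] = pos.tolist()

    return genome, transcripts, origins


# ---------------------------------------------------------------------------
# mutation catalogs
# ---------------------------------------------------------------------------

#: spectrum weights loosely emulating chronic-MMS mutagenesis, where A:T-pair
#: substitutions (3meA-type lesions, A>G and A>T) dominate and G:C-pair
#: substitutions spread over G>A / G>C / G>T (3meC-type lesions)
MMS_LIKE_CLASS_WEIGHTS = (0.03, 0.36, 0.31, 0.12, 0.08, 0.10)


@dataclass(frozen=True)
class CatalogSimParams:
    """Knobs of the catalog generator.

    ``class_weights`` follow :data:`~mutasym.spectrum.SUBSTITUTION_CLASSES`
    order.  ``tx_bias_C`` is the non-transcribed:transcribed density ratio for
    C mutations inside transcripts (1 = no bias); ``rep_gradient_C`` is the
    linear change of top-strand C-mutation probability per fractional
    inter-origin unit (0 = no gradient).  Substitutions make up ~95% of
    events, the remainder split between small indels and complex events.
    """

    seed: int = 0
    n_samples: int = 10
    mutations_per_genome_mean: float = 100.0
    substitution_fraction: float = 0.95
    class_weights: tuple[float, ...] = MMS_LIKE_CLASS_WEIGHTS
    indel_fraction: float = 0.03
    complex_fraction: float = 0.02
    tx_bias_C: float = 1.0
    rep_gradient_C: float = 0.0
    depth_mean: float = 40.0
    vaf_mode: float = 0.50
    vaf_sd: float = 0.03

    def __post_init__(self) -> None:
        total = self.substitution_fraction + self.indel_fraction + self.complex_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"event-type fractions sum to {total}, not 1")
        if abs(sum(self.class_weights) - 1.0) > 1e-9 or len(self.class_weights) != 6:
            raise ValueError("class_weights must be 6 values summing to 1")
        if self.tx_bias_C < 0:
            raise ValueError("tx_bias_C must be >= 0")
        if self.n_samples < 1:
            raise ValueError("need >= 1 sample")


class _SiteModel:
    """Flattened per-site arrays used for weighted mutation placement."""

    def __init__(self, genome, transcripts, origins, params: CatalogSimParams):
        chroms = sorted(genome)
        self.chroms = chroms
        base_arrays, chrom_idx, local_pos = [], [], []
        for ci, c in enumerate(chroms):
            arr = np.frombuffer(genome[c].encode(), dtype=np.uint8)
            base_arrays.append(arr)
            chrom_idx.append(np.full(arr.size, ci, dtype=np.int32))
            local_pos.append(np.arange(arr.size, dtype=np.int64))
        self.bases = np.concatenate(base_arrays)
        self.chrom_idx = np.concatenate(chrom_idx)
        self.local_pos = np.concatenate(local_pos)
        self.offsets = np.cumsum([0] + [a.size for a in base_arrays])

        A, C, G, T = (ord(b) for b in "ACGT")
        self.at_sites = np.nonzero((self.bases == A) | (self.bases == T))[0]
        self.gc_sites = np.nonzero((self.bases == C) | (self.bases == G))[0]

        # transcript strand per site: +1 / -1 inside a transcript body, 0 out
        tx_strand = np.zeros(self.bases.size, dtype=np.int8)
        for t in transcripts:
            off = self.offsets[chroms.index(t.chrom)]
            tx_strand[off + t.start : off + t.end] = 1 if t.strand == "+" else -1

        # fractional inter-origin coordinate per site (nan outside domain)
        frac = np.full(self.bases.size, np.nan)
        for ci, c in enumerate(chroms):
            ori = np.asarray(origins.get(c, []), dtype=np.int64)
            if ori.size < 2:
                continue
            off = self.offsets[ci]
            pos = np.arange(self.offsets[ci + 1] - off, dtype=np.int64)
            idx = np.searchsorted(ori, pos, side="right")
            ok = (idx > 0) & (idx < ori.size)
            lo = ori[np.clip(idx - 1, 0, ori.size - 1)]
            hi = ori[np.clip(idx, 0, ori.size - 1)]
            with np.errstate(invalid="ignore"):
                f = (pos - lo) / np.where(hi > lo, hi - lo, 1)
            frac[off:][: pos.size][ok] = f[ok]

        # weight of each G:C site for drawing a C mutation
        gc = self.gc_sites
        top_is_c = self.bases[gc] == C
        strand = tx_strand[gc]
        # C on the non-transcribed strand: top-strand C in a + transcript or
        # top-strand G in a - transcript
        c_on_nt = (top_is_c & (strand == 1)) | (~top_is_c & (strand == -1))
        in_tx = strand != 0
        w_tx = np.where(in_tx & c_on_nt, params.tx_bias_C, 1.0)
        f = frac[gc]
        p_top = np.where(
            np.isnan(f), 0.5,
            np.clip(0.5 + params.rep_gradient_C * (f - 0.5), 0.02, 0.98),
        )
        w_rep = np.where(top_is_c, p_top, 1.0 - p_top)
        self.gc_weights = w_tx * w_rep

    def to_record_pos(self, global_idx: int) -> tuple[str, int]:
        """(chrom, 1-based pos) of a flattened site index."""
        return (self.chroms[self.chrom_idx[global_idx]],
                int(self.local_pos[global_idx]) + 1)


def _thinned_weighted_sites(rng, indices, weights, n_target):
    """Draw sites by Bernoulli thinning with inclusion probability
    proportional to weight.

    Mutations arise independently per site, so each site is included with
    probability ``lam * w_i`` where ``lam`` makes the expected draw count
    equal ``n_target``.  Unlike fixed-count weighted sampling without
    replacement, this keeps the realized per-site rates exactly proportional
    to the weights at any sampling density; the realized count fluctuates
    around ``n_target`` instead.
    """
    if n_target == 0:
        return indices[:0]
    if indices.size == 0:
        raise ValueError("no sites available")
    lam = n_target / weights.sum()
    p = lam * weights
    if p.max() > 1.0:
        raise ValueError(
            "requested mutation load saturates the highest-weight sites; "
            "use a larger genome or fewer mutations"
        )
    return indices[rng.random(indices.size) < p]


_CLASS_ALLELES = {cls: (cls[0], cls[2]) for cls in SUBSTITUTION_CLASSES}


def simulate_catalog(
    genome: dict[str, str],
    transcripts: list[Transcript],
    origins: dict[str, list[int]],
    params: CatalogSimParams,
    genotype: str = "",
    sample_prefix: str = "S",
) -> list[SampleCatalog]:
    """Draw per-sample mutation catalogs with the injected structure.

    Per sample, a Poisson number of events is split multinomially into
    substitutions / indels / complex events; substitution classes follow
    ``class_weights``.  A:T-pair substitutions land uniformly on A/T sites;
    G:C-pair substitutions are drawn with site weights that realize
    ``tx_bias_C`` inside transcripts and ``rep_gradient_C`` along inter-origin
    intervals.  Complex events are two substitutions 1-10 bp apart.  Each
    record carries Poisson(``depth_mean``) depth and a truncated-normal
    allele fraction, so a predictable share of records fails the depth/support
    call filter.
    """
    rng = np.random.default_rng(params.seed)
    model = _SiteModel(genome, transcripts, origins, params)
    n_a_classes = 3  # first three classes mutate the A:T pair

    catalogs = []
    for s in range(params.n_samples):
        sample_id = f"{sample_prefix}{s:03d}"
        n_events = rng.poisson(params.mutations_per_genome_mean)
        n_sub, n_indel, n_complex = rng.multinomial(
            n_events,
            [params.substitution_fraction, params.indel_fraction,
             params.complex_fraction],
        )
        class_counts = rng.multinomial(n_sub, params.class_weights)
        n_a, n_g = int(class_counts[:n_a_classes].sum()), int(
            class_counts[n_a_classes:].sum())
        if n_a and model.at_sites.size == 0:
            raise ValueError("no A:T sites available for requested A-class mutations")
        if n_g and model.gc_sites.size == 0:
            raise ValueError("no G:C sites available for requested C-class mutations")

        a_sites = rng.choice(model.at_sites, size=n_a, replace=False)
        g_sites = (
            _thinned_weighted_sites(rng, model.gc_sites, model.gc_weights, n_g)
            if n_g else model.gc_sites[:0]
        )
        used = set(a_sites.tolist()) | set(g_sites.tolist())

        records: list[MutationRecord] = []

        def support():
            depth = int(rng.poisson(params.depth_mean))
            vaf = float(np.clip(rng.normal(params.vaf_mode, params.vaf_sd), 0, 1))
            return depth, vaf

        def add_substitution(site: int, cls: str) -> None:
            chrom, pos = model.to_record_pos(site)
            ref = chr(model.bases[site])
            pur_ref, pur_alt = _CLASS_ALLELES[cls]
            alt = pur_alt if ref == pur_ref else COMPLEMENT[pur_alt]
            depth, vaf = support()
            records.append(MutationRecord(chrom, pos, ref, alt, sample_id,
                                          depth, vaf))

        a_classes = np.repeat(
            np.array(SUBSTITUTION_CLASSES[:n_a_classes]),
            class_counts[:n_a_classes],
        )
        for site, cls in zip(a_sites, rng.permutation(a_classes)):
            add_substitution(int(site), str(cls))
        w_g = np.asarray(params.class_weights[n_a_classes:], dtype=float)
        if g_sites.size:
            g_classes = rng.choice(
                np.array(SUBSTITUTION_CLASSES[n_a_classes:]),
                size=g_sites.size, p=w_g / w_g.sum(),
            )
            for site, cls in zip(g_sites, g_classes):
                add_substitution(int(site), str(cls))

        def draw_free_site(margin: int = 12) -> int:
            for _ in range(1000):
                site = int(rng.integers(0, model.bases.size - margin))
                ci = model.chrom_idx[site]
                room = model.offsets[ci + 1] - site
                if room <= margin:
                    continue
                if all(site + d not in used for d in range(margin)):
                    return site
            raise RuntimeError("could not place event; genome too saturated")

        for _ in range(n_indel):
            site = draw_free_site(2)
            used.update((site, site + 1))
            chrom, pos = model.to_record_pos(site)
            b0, b1 = chr(model.bases[site]), chr(model.bases[site + 1])
            depth, vaf = support()
            if rng.random() < 0.5:  # 1-bp deletion, VCF anchored
                records.append(MutationRecord(chrom, pos, b0 + b1, b0,
                                              sample_id, depth, vaf))
            else:  # 1-bp insertion
                ins = str(rng.choice(list("ACGT")))
                records.append(MutationRecord(chrom, pos, b0, b0 + ins,
                                              sample_id, depth, vaf))

        for _ in range(n_complex):
            gap = int(rng.integers(1, 11))
            site = draw_free_site(gap + 2)
            used.update((site, site + gap))
            for offset in (0, gap):
                chrom, pos = model.to_record_pos(site + offset)
                ref = chr(model.bases[site + offset])
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                depth, vaf = support()
                records.append(MutationRecord(chrom, pos, ref, alt,
                                              sample_id, depth, vaf))

        records.sort(key=MutationRecord.sort_key)
        catalogs.append(SampleCatalog(sample_id=sample_id, records=records,
                                      genotype=genotype))
    return catalogs


# ---------------------------------------------------------------------------
# fluctuation assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluctuationSimParams:
    """Luria-Delbruck culture parameters.

    Defaults match a typical CAN1 forward-mutation experiment: 24 parallel
    cultures grown to 1e8 cells, permissive plates seeded at a 1e4 dilution.
    """

    seed: int = 0
    mu: float = 1e-7
    n_final: float = 1e8
    n_cultures: int = 24
    plating_dilution: float = 1e4

    def __post_init__(self) -> None:
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")
        if self.n_final < 2:
            raise ValueError("n_final must be >= 2")
        if self.n_cultures < 1:
            raise ValueError("need >= 1 culture")
        if self.plating_dilution <= 0:
            raise ValueError("plating_dilution must be > 0")


def simulate_fluctuation(params: FluctuationSimParams) -> pd.DataFrame:
    """Per-culture resistant and viable colony counts.

    Growth is binary fission from one cell to ``n_final``.  In the j-th
    generation counted back from the end there are ``n_final / 2**j``
    divisions; each division yields a mutant with probability ``mu``, and a
    mutant arising there expands clonally to ``2**(j-1)`` cells, producing
    the characteristic jackpot-skewed resistant counts.  Viable counts are
    Poisson around ``n_final / plating_dilution``.
    """
    rng = np.random.default_rng(params.seed)
    g = max(1, int(np.ceil(np.log2(params.n_final))))
    j = np.arange(1, g + 1, dtype=float)
    divisions = params.n_final / 2.0**j
    clone_size = 2.0 ** (j - 1)
    events = rng.poisson(params.mu * divisions,
                         size=(params.n_cultures, g))
    resistant = np.minimum((events * clone_size).sum(axis=1), params.n_final)
    viable = rng.poisson(params.n_final / params.plating_dilution,
                         size=params.n_cultures)
    return pd.DataFrame(
        {
            "culture": np.arange(params.n_cultures),
            "canr_colonies": resistant.astype(np.int64),
            "sc_colonies": viable,
            "sc_dilution": params.plating_dilution,
        }
    )


# ---------------------------------------------------------------------------
# anisotropy titrations
# ---------------------------------------------------------------------------

def simulate_titration(
    kd: float,
    m_amp: float,
    d_conc: float,
    x_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicate_id: str = "rep1",
    substrate: str = "unmodified",
) -> pd.DataFrame:
    """Noisy anisotropy titration table from the quadratic one-site model."""
    x = np.asarray(x_grid, dtype=float)
    if (x < 0).any() or (np.diff(x) <= 0).any():
        raise ValueError("x_grid must be non-negative and strictly increasing")
    rng = np.random.default_rng(seed)
    y = binding_model(x, m_amp, d_conc, kd)
    if noise_sd:
        y = y + rng.normal(0.0, noise_sd, size=x.size)
    return pd.DataFrame(
        {"replicate": replicate_id, "substrate": substrate, "x_nM": x,
         "anisotropy": y}
    )


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def emit_dataset(
    outdir: str | Path,
    genome_spec: SyntheticGenomeSpec,
    catalog_params: CatalogSimParams,
    genotype: str = "synthetic",
) -> Path:
    """Write a complete synthetic dataset with a ground-truth JSON sidecar.

    Emits genome.fa, transcripts.bed, origins.bed, per-sample VCF and TSV
    catalogs, and truth.json echoing every generator parameter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, transcripts, origins = make_reference(genome_spec)
    catalogs = simulate_catalog(genome, transcripts, origins, catalog_params,
                                genotype=genotype)
    write_fasta(genome, outdir / "genome.fa")
    write_transcripts_bed(transcripts, outdir / "transcripts.bed")
    write_origins_bed(origins, outdir / "origins.bed")
    contigs = {c: len(s) for c, s in genome.items()}
    for cat in catalogs:
        write_catalog_vcf(cat.records, outdir / f"{cat.sample_id}.vcf",
                          sample_id=cat.sample_id, contigs=contigs)
        write_catalog_tsv(cat.records, outdir / f"{cat.sample_id}.tsv")
    truth = {
        "genome_spec": asdict(genome_spec),
        "catalog_params": asdict(catalog_params),
        "genotype": genotype,
        "samples": [cat.sample_id for cat in catalogs],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    return outdir
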