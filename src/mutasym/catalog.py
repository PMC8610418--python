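"""Per-sample mutation catalogs: parsing, call filtering, and event clustering.

A catalog is the list of differences from the reference genome called in one
sequenced clone.  Three quality screens are applied before any spectrum or
asymmetry analysis:

* whole-genome calls must be covered by at least ``min_depth`` reads with an
  alternate-allele fraction inside a window around 50% (mutations arise during
  colony passaging, so true calls are subclonal at roughly half the reads);
* calls shared by two or more independent clones are discarded as inherited
  polymorphisms or recurrent alignment artifacts;
* reporter-gene (CAN1 amplicon) calls use a looser screen: at least two
  supporting reads covering more than 30% of reads for the isolate.

Nearby calls are then chained into events: two or more mutations separated by
10 bp or less form a single *complex* event, the signature of a single
error-prone bypass tract; isolated calls classify as substitution, insertion
or deletion by allele lengths.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_ALLELE_CHARS = set("ACGT-")

#: column order of the TSV catalog dialect
TSV_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "depth", "alt_fraction"]


class CatalogFormatError(ValueError):
    """A catalog file (or row) violates the expected dialect."""


@dataclass(frozen=True)
class MutationRecord:
    """One called variant: position, alleles and read support.

    ``pos`` is 1-based (VCF convention); ``ref``/``alt`` are top-strand allele
    strings over ACGT, anchored VCF-style for indels (a ``-`` allele from the
    TSV dialect denotes an empty allele).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str = ""
    depth: int | None = None
    alt_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CatalogFormatError(f"pos must be >= 1, got {self.pos}")
        for allele in (self.ref, self.alt):
            if not allele or not set(allele) <= _ALLELE_CHARS or (
                "-" in allele and allele != "-"
            ):
                raise CatalogFormatError(f"bad allele {allele!r}")
        if self.ref == self.alt:
            raise CatalogFormatError(
                f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}"
            )
        if self.depth is not None and self.depth < 0:
            raise CatalogFormatError("depth must be >= 0")
        if self.alt_fraction is not None and not 0.0 <= self.alt_fraction <= 1.0:
            raise CatalogFormatError("alt_fraction must be in [0, 1]")

    @property
    def is_substitution(self) -> bool:
        return len(self.ref) == 1 == len(self.alt) and "-" not in (self.ref, self.alt)

    @property
    def is_insertion(self) -> bool:
        return self.ref == "-" or (
            "-" != self.alt and len(self.alt) > len(self.ref)
        )

    @property
    def is_deletion(self) -> bool:
        return self.alt == "-" or (
            "-" != self.ref and len(self.ref) > len(self.alt)
        )

    @property
    def end(self) -> int:
        """Last reference base covered (1-based, inclusive)."""
        return self.pos + (0 if self.ref == "-" else len(self.ref) - 1)

    @property
    def supporting_reads(self) -> int:
        """Reads supporting the alternate allele, from depth x alt_fraction."""
        if self.depth is None or self.alt_fraction is None:
            raise CatalogFormatError(
                f"record {self.chrom}:{self.pos} lacks read-support metadata"
            )
        return round(self.depth * self.alt_fraction)

    def key(self) -> tuple[str, int, str, str]:
        """Identity key used for cross-sample recurrence screening."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def sort_key(self) -> tuple[str, str, int, str, str]:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MutationEvent:
    """A classified mutational event grouping one or more records."""

    event_class: str  # substitution | insertion | deletion | complex
    records: list[MutationRecord]
    chrom: str = field(init=False)
    start: int = field(init=False)
    end: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("event needs >= 1 record")
        chroms = {r.chrom for r in self.records}
        if len(chroms) > 1:
            raise ValueError("event records span chromosomes")
        self.chrom = self.records[0].chrom
        self.start = min(r.pos for r in self.records)
        self.end = max(r.end for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SampleCatalog:
    """All records (and, once clustered, events) for one sequenced clone."""

    sample_id: str
    records: list[MutationRecord]
    genotype: str = ""
    treatment: str = ""
    events: list[MutationEvent] | None = None

    def with_records(self, records: Iterable[MutationRecord]) -> "SampleCatalog":
        return replace(self, records=list(records), events=None)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _records_from_tsv(path: Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogFormatError(f"{path}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            records.append(
                MutationRecord(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref.upper(),
                    alt=row.alt.upper(),
                    sample_id=row.sample,
                    depth=int(row.depth),
                    alt_fraction=float(row.alt_fraction),
                )
            )
        except (CatalogFormatError, ValueError, AttributeError) as exc:
            raise CatalogFormatError(f"{path} line {i}: {exc}") from exc
    return records


def _records_from_vcf(path: Path) -> list[MutationRecord]:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        sample_id = samples[0] if samples else Path(path).stem
        for n, rec in enumerate(vcf.fetch(), start=1):
            if rec.alts is None or len(rec.alts) != 1:
                raise CatalogFormatError(
                    f"{path} record {n}: expected exactly one ALT allele"
                )
            dp = rec.info.get("DP")
            af = rec.info.get("AF")
            if isinstance(af, tuple):
                af = af[0]
            try:
                records.append(
                    MutationRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=rec.alts[0].upper(),
                        sample_id=sample_id,
                        depth=None if dp is None else int(dp),
                        alt_fraction=None if af is None else float(af),
                    )
                )
            except CatalogFormatError as exc:
                raise CatalogFormatError(f"{path} record {n}: {exc}") from exc
    return records


def read_catalog(
    path: str | Path,
    format: str | None = None,
    genotype: str = "",
    treatment: str = "",
) -> SampleCatalog:
    """Read one per-sample mutation table (``vcf`` or ``tsv`` dialect).

    The format is inferred from the file suffix when not given.  Every row
    becomes exactly one :class:`MutationRecord`; malformed rows raise a
    :class:`CatalogFormatError` naming the offending line.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "tsv":
        records = _records_from_tsv(path)
    elif format == "vcf":
        records = _records_from_vcf(path)
    else:
        raise CatalogFormatError(f"unknown catalog format {format!r}")
    sample_id = records[0].sample_id if records else path.stem
    return SampleCatalog(
        sample_id=sample_id, records=records, genotype=genotype, treatment=treatment
    )


def write_catalog_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.sample_id, r.chrom, r.pos, r.ref, r.alt, r.depth, r.alt_fraction)
            for r in records
        ],
        columns=TSV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def write_catalog_vcf(
    records: Sequence[MutationRecord],
    path: str | Path,
    sample_id: str | None = None,
    contigs: dict[str, int] | None = None,
) -> None:
    """Write a minimal single-sample VCF (v4.2; INFO keys DP and AF)."""
    if sample_id is None:
        sample_id = records[0].sample_id if records else "sample"
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele fraction">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if contigs:
        lines += [f"##contig=<ID={c},length={n}>" for c, n in contigs.items()]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for r in sorted(records, key=MutationRecord.sort_key):
        info = []
        if r.depth is not None:
            info.append(f"DP={r.depth}")
        if r.alt_fraction is not None:
            info.append(f"AF={r.alt_fraction:.4f}")
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
            f"{';'.join(info) or '.'}\tGT\t0/1"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-reason rejection tally from a filtering pass."""

    n_input: int
    n_kept: int
    rejected: Counter

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_kept


def _require_support(record: MutationRecord) -> None:
    if record.depth is None or record.alt_fraction is None:
        raise CatalogFormatError(
            f"record {record.chrom}:{record.pos} ({record.sample_id or 'unknown'}) "
            "lacks depth/alt_fraction required for filtering"
        )


def filter_genome_calls(
    records: Iterable[MutationRecord],
    min_depth: int = 10,
    support_lo: float = 0.45,
    support_hi: float = 0.55,
) -> tuple[list[MutationRecord], FilterReport]:
    """Whole-genome call filter: depth >= ``min_depth`` (i.e. more than nine
    reads at the defaults) and alternate fraction within
    ``[support_lo, support_hi]`` inclusive."""
    kept, rejected = [], Counter()
    n = 0
    for r in records:
        n += 1
        _require_support(r)
        if r.depth < min_depth:
            rejected["depth"] += 1
        elif not support_lo <= r.alt_fraction <= support_hi:
            rejected["support"] += 1
        else:
            kept.append(r)
    return kept, FilterReport(n_input=n, n_kept=len(kept), rejected=rejected)


def filter_can1_calls(
    records: Iterable[MutationRecord],
    min_reads: int = 2,
    min_fraction: float = 0.30,
) -> tuple[list[MutationRecord], FilterReport]:
    """Reporter-amplicon filter: >= ``min_reads`` supporting reads that make up
    strictly more than ``min_fraction`` of all reads for the isolate."""
    kept, rejected = [], Counter()
    n = 0
    for r in records:
        n += 1
        _require_support(r)
        if r.supporting_reads < min_reads:
            rejected["reads"] += 1
        elif not r.alt_fraction > min_fraction:
            rejected["fraction"] += 1
        else:
            kept.append(r)
    return kept, FilterReport(n_input=n, n_kept=len(kept), rejected=rejected)


def remove_recurrent(
    catalogs: Sequence[SampleCatalog],
) -> tuple[list[SampleCatalog], dict[tuple, list[str]]]:
    """Drop any (chrom, pos, ref, alt) seen in two or more samples.

    Calls shared between independently passaged clones are inherited
    polymorphisms or systematic artifacts, not new mutations.  Identical
    positions with *different* alternate alleles are independent mutations and
    are retained.  Returns the screened catalogs and a report mapping each
    removed key to the samples that carried it.
    """
    if len(catalogs) < 2:
        raise ValueError("recurrence screening needs >= 2 catalogs")
    carriers: dict[tuple, set[str]] = defaultdict(set)
    for cat in catalogs:
        for r in cat.records:
            carriers[r.key()].add(cat.sample_id)
    recurrent = {k: sorted(v) for k, v in carriers.items() if len(v) >= 2}
    screened = [
        cat.with_records(r for r in cat.records if r.key() not in recurrent)
        for cat in catalogs
    ]
    return screened, recurrent


# ---------------------------------------------------------------------------
# event clustering
# ---------------------------------------------------------------------------

def _classify_single(record: MutationRecord) -> str:
    if record.is_substitution:
        return "substitution"
    if record.is_insertion:
        return "insertion"
    if record.is_deletion:
        return "deletion"
    # equal-length multi-nucleotide block: >= 2 changes within its own span,
    # which meets the clustered-mutation definition on its own
    return "complex"


def cluster_events(
    records: Sequence[MutationRecord], max_gap: int = 10
) -> list[MutationEvent]:
    """Chain records into events by single-linkage on start-position distance.

    Consecutive records (within one sample and chromosome) whose start
    positions differ by ``max_gap`` bp or less join the same event; chaining is
    transitive, so runs of nearby mutations collapse into one event.  Events
    with two or more records are *complex*; singletons classify by allele
    lengths.  Unsorted input is sorted internally (logged).
    """
    records = list(records)
    order = [r.sort_key() for r in records]
    if order != sorted(order):
        logger.info("cluster_events: input not sorted; sorting internally")
        records = sorted(records, key=MutationRecord.sort_key)
    events: list[MutationEvent] = []
    run: list[MutationRecord] = []
    for r in records:
        if run and (
            r.chrom == run[-1].chrom
            and r.sample_id == run[-1].sample_id
            and r.pos - run[-1].pos <= max_gap
        ):
            run.append(r)
        else:
            if run:
                events.append(_finish_run(run))
            run = [r]
    if run:
        events.append(_finish_run(run))
    return events


def _finish_run(run: list[MutationRecord]) -> MutationEvent:
    cls = "complex" if len(run) >= 2 else _classify_single(run[0])
    return MutationEvent(event_class=cls, records=list(run))


def cluster_catalog(catalog: SampleCatalog, max_gap: int = 10) -> SampleCatalog:
    """Return a copy of ``catalog`` with its events populated."""
    events = cluster_events(
        sorted(catalog.records, key=MutationRecord.sort_key), max_gap=max_gap
    )
    return replace(catalog, events=events)
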