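"""Substitution spectra, per-genome burdens and group comparisons.

Single-base substitutions are keyed to the purine reference base: a mutation
reported with a pyrimidine reference (T or C) is complemented to its purine
equivalent, so every substitution falls in one of six classes
(A>C, A>G, A>T, G>A, G>C, G>T).  This makes spectra strand-symmetric — the
classes describe the base *pair* that mutated — which is the convention used
for alkylation-damage spectra, where A:T-pair classes report 3meA-type
lesions and G:C-pair classes report 7meG/3meC-type lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import SampleCatalog

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: purine-keyed substitution classes, in conventional plotting order
SUBSTITUTION_CLASSES = ("A>C", "A>G", "A>T", "G>A", "G>C", "G>T")

#: event classes beyond single-base substitutions
EVENT_CLASSES = ("substitution", "insertion", "deletion", "complex")


def classify_substitution(ref: str, alt: str) -> str:
    """Map a single-base substitution to its purine-keyed class.

    Purine-reference substitutions pass through; pyrimidine-reference ones are
    complemented (T>C becomes A>G, C>A becomes G>T).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        raise ValueError(f"non-ACGT base in substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref == alt is not a substitution")
    if ref in "CT":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def _require_events(catalog: SampleCatalog) -> list:
    if catalog.events is None:
        raise ValueError(
            f"catalog {catalog.sample_id!r} has no events; run cluster_catalog first"
        )
    return catalog.events


def spectrum_table(catalogs: list[SampleCatalog]) -> pd.DataFrame:
    """Tidy per-sample event counts: columns sample, group, class, count.

    Classes are the six purine-keyed substitution classes plus insertion,
    deletion and complex.  Substitution class counts sum to each sample's
    substitution event count (conservation).
    """
    rows = []
    all_classes = list(SUBSTITUTION_CLASSES) + ["insertion", "deletion", "complex"]
    for cat in catalogs:
        counts = dict.fromkeys(all_classes, 0)
        for ev in _require_events(cat):
            if ev.event_class == "substitution":
                r = ev.records[0]
                counts[classify_substitution(r.ref, r.alt)] += 1
            else:
                counts[ev.event_class] += 1
        for cls, n in counts.items():
            rows.append((cat.sample_id, cat.genotype, cls, n))
    return pd.DataFrame(rows, columns=["sample", "group", "class", "count"])


@dataclass
class BurdenResult:
    totals: pd.DataFrame  # sample, group, n_events
    medians: dict[str, float]
    fold_change: float | None


def per_genome_burden(
    catalogs: list[SampleCatalog],
    reference_group: str | None = None,
    test_group: str | None = None,
    count_records: bool = False,
) -> BurdenResult:
    """Per-sample mutation totals, group medians and their fold change.

    Totals count *events*: a complex event contributes once regardless of how
    many member records it carries (``count_records=True`` counts raw records
    instead).  With exactly two groups the fold change is
    ``median(test) / median(reference)``; group order defaults to sorted
    labels with the reference first unless given explicitly.
    """
    rows = []
    for cat in catalogs:
        events = _require_events(cat)
        n = sum(len(ev) for ev in events) if count_records else len(events)
        rows.append((cat.sample_id, cat.genotype, n))
    totals = pd.DataFrame(rows, columns=["sample", "group", "n_events"])
    if totals.empty:
        raise ValueError("no catalogs given")
    medians = totals.groupby("group")["n_events"].median().to_dict()
    fold = None
    groups = sorted(medians)
    if reference_group is None and len(groups) == 2:
        reference_group, test_group = groups
    if reference_group is not None and test_group is not None:
        if medians[reference_group] == 0:
            raise ZeroDivisionError(f"median burden of {reference_group!r} is zero")
        fold = medians[test_group] / medians[reference_group]
    return BurdenResult(totals=totals, medians=medians, fold_change=fold)


def event_class_fractions(catalogs: list[SampleCatalog]) -> pd.DataFrame:
    """Per-group fractions of substitution / insertion / deletion / complex
    events; fractions sum to 1 within each group."""
    rows = []
    for cat in catalogs:
        for ev in _require_events(cat):
            rows.append((cat.genotype, ev.event_class))
    if not rows:
        raise ValueError("no events in any catalog")
    df = pd.DataFrame(rows, columns=["group", "class"])
    counts = (
        df.groupby(["group", "class"]).size().unstack(fill_value=0)
        .reindex(columns=EVENT_CLASSES, fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def spectrum_means(table: pd.DataFrame, group: str) -> pd.DataFrame:
    """Mean and sample SD of per-genome counts for each class in one group."""
    sub = table[table["group"] == group]
    if sub.empty:
        raise ValueError(f"no samples in group {group!r}")
    wide = sub.pivot(index="sample", columns="class", values="count")
    out = pd.DataFrame({"mean": wide.mean(), "sd": wide.std(ddof=1)})
    out.index.name = "class"
    return out


def compare_groups(a, b, test: str = "mann_whitney") -> tuple[float, float]:
    """Two-sided comparison of two groups; returns (statistic, p-value).

    ``mann_whitney`` and ``t_test`` take two value sequences; ``chi_square``
    takes two count vectors over the same categories (e.g. the six-category
    event table: A:T substitutions, G:C substitutions, insertions, deletions,
    complex, clustered) and tests homogeneity of the two distributions.
    """
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "t_test":
        if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
            raise ValueError("degenerate zero-variance identical groups")
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "chi_square":
        table = np.asarray([a, b], dtype=float)
        if table.min() < 0:
            raise ValueError("negative counts")
        # drop categories empty in both groups: they carry no information
        table = table[:, table.sum(axis=0) > 0]
        chi2, p, _, _ = stats.chi2_contingency(table)
        return float(chi2), float(p)
    raise ValueError(f"unknown test {test!r}")


def can1_frequency_spectrum(
    proportions: dict[str, float], total_rate: float
) -> dict[str, float]:
    """Split a total reporter-gene mutation rate across event classes.

    ``proportions`` are the class proportions among sequenced resistant
    isolates (must sum to 1); each class's frequency is its proportion times
    the fluctuation-derived total rate, so the class frequencies sum back to
    the total rate.
    """
    s = sum(proportions.values())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {s}, not 1")
    if total_rate < 0:
        raise ValueError("total_rate must be >= 0")
    return {cls: p * total_rate for cls, p in proportions.items()}
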