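"""Per-genome burdens, event-class mix and substitution spectra.

Computes the median mutation burden per genotype and its fold change, the
event-class fractions, per-class spectrum means +- SD, and the standard group
comparisons (Mann-Whitney on burdens, t-test on per-class counts); writes
tidy tables under results/spectra/.
"""

import json

from common import RESULTS, filtered_clustered_catalogs
from mutasym import (
    SUBSTITUTION_CLASSES,
    compare_groups,
    event_class_fractions,
    per_genome_burden,
    spectrum_means,
    spectrum_table,
)


def main() -> None:
    outdir = RESULTS / "spectra"
    outdir.mkdir(parents=True, exist_ok=True)
    catalogs = filtered_clustered_catalogs()

    burden = per_genome_burden(catalogs, reference_group="wt",
                               test_group="mutant")
    burden.totals.to_csv(outdir / "burden_per_genome.tsv", sep="\t",
                         index=False)
    wt_vals = burden.totals.query("group == 'wt'")["n_events"]
    mut_vals = burden.totals.query("group == 'mutant'")["n_events"]
    _, p_burden = compare_groups(wt_vals, mut_vals, test="mann_whitney")

    fractions = event_class_fractions(catalogs)
    fractions.to_csv(outdir / "event_class_fractions.tsv", sep="\t")

    table = spectrum_table(catalogs)
    table.to_csv(outdir / "spectrum_counts.tsv", sep="\t", index=False)
    for group in ("wt", "mutant"):
        spectrum_means(table, group).to_csv(
            outdir / f"spectrum_means_{group}.tsv", sep="\t")

    wide = table[table["class"].isin(SUBSTITUTION_CLASSES)].pivot_table(
        index=["sample", "group"], columns="class", values="count")
    _, p_ag = compare_groups(
        wide.xs("wt", level="group")["A>G"],
        wide.xs("mutant", level="group")["A>G"], test="t_test")

    summary = {
        "median_burden": burden.medians,
        "fold_change": burden.fold_change,
        "mann_whitney_p_burden": p_burden,
        "t_test_p_AG_per_genome": p_ag,
        "substitution_fraction": fractions["substitution"].to_dict(),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    print(f"median burden wt={burden.medians['wt']:.0f} "
          f"mutant={burden.medians['mutant']:.0f} "
          f"-> {burden.fold_change:.1f}-fold (Mann-Whitney p={p_burden:.2e})")
    print("substitution fraction per group:",
          {g: round(v, 3) for g, v in
           fractions['substitution'].to_dict().items()})
    print(f"tables -> {outdir}")


if __name__ == "__main__":
    main()
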