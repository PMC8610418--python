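"""Filter mutation calls, screen recurrent calls, and cluster events.

Reads the per-clone VCF catalogs, applies the whole-genome call filter
(depth >= 10, 45-55% allele support), removes calls shared between clones,
chains nearby calls into events (complex = >= 2 mutations within 10 bp), and
writes the filtered catalogs plus a rejection report under
results/catalogs/.
"""

import json

import pandas as pd

from common import RESULTS, ensure_datasets
from mutasym import (
    cluster_catalog,
    filter_genome_calls,
    read_catalog,
    remove_recurrent,
    write_catalog_tsv,
)


def main() -> None:
    dirs = ensure_datasets()
    outdir = RESULTS / "catalogs"
    outdir.mkdir(parents=True, exist_ok=True)

    catalogs, rejections = [], []
    for genotype, d in dirs.items():
        for vcf in sorted(d.glob("*.vcf")):
            cat = read_catalog(vcf, genotype=genotype)
            kept, report = filter_genome_calls(cat.records)
            rejections.append(
                {"sample": cat.sample_id, "genotype": genotype,
                 "n_input": report.n_input, "n_kept": report.n_kept,
                 **{f"rejected_{k}": v for k, v in report.rejected.items()}})
            catalogs.append(cat.with_records(kept))

    screened, recurrent = remove_recurrent(catalogs)
    clustered = [cluster_catalog(c) for c in screened]

    all_records = [r for c in clustered for r in c.records]
    write_catalog_tsv(all_records, outdir / "filtered_calls.tsv")
    pd.DataFrame(rejections).to_csv(outdir / "rejection_report.tsv",
                                    sep="\t", index=False)
    (outdir / "recurrent_calls.json").write_text(json.dumps(
        {f"{k[0]}:{k[1]}:{k[2]}>{k[3]}": v for k, v in recurrent.items()},
        indent=2))

    n_in = sum(r["n_input"] for r in rejections)
    n_kept = sum(r["n_kept"] for r in rejections)
    n_events = sum(len(c.events) for c in clustered)
    print(f"{n_in} calls -> {n_kept} after depth/support filter "
          f"({100 * n_kept / n_in:.1f}% kept)")
    print(f"{len(recurrent)} recurrent calls removed across clones")
    print(f"{n_events} events after clustering -> {outdir}")


if __name__ == "__main__":
    main()
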