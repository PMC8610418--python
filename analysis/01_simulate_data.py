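"""Emit the synthetic study datasets (genome, annotation, mutation catalogs).

Writes FASTA/BED/VCF/TSV files plus a ground-truth sidecar for a wild-type
cohort (75 clones, 20 mutations/genome on average) and a hypermutator cohort
(22 clones, 254 mutations/genome, i.e. the 12.7-fold burden ratio), under
scratch/dataset/.
"""

import json

from common import ensure_datasets


def main() -> None:
    dirs = ensure_datasets()
    for genotype, d in dirs.items():
        truth = json.loads((d / "truth.json").read_text())
        n = len(truth["samples"])
        mean = truth["catalog_params"]["mutations_per_genome_mean"]
        print(f"{genotype}: {n} clones at {mean} mutations/genome -> {d}")


if __name__ == "__main__":
    main()
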