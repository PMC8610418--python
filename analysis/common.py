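"""Shared study conditions for the numbered analysis drivers.

The drivers emulate the study design: 75 wild-type and 22 Shu-deficient
(csm2-like) MMS-passaged clones on a toy two-chromosome genome, a 12.7-fold
injected burden ratio, CAN1-style fluctuation assays at 1e-7 mutations per
cell per generation, and anisotropy titrations of the three double-flap
substrates at 5 nM.
"""

from pathlib import Path

from mutasym import (
    CatalogSimParams,
    SyntheticGenomeSpec,
    cluster_catalog,
    emit_dataset,
    filter_genome_calls,
    read_catalog,
    remove_recurrent,
)

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

GENOME_SPEC = SyntheticGenomeSpec(seed=2024)
WT_PARAMS = CatalogSimParams(seed=101, n_samples=75,
                             mutations_per_genome_mean=20.0)
MUT_PARAMS = CatalogSimParams(seed=102, n_samples=22,
                              mutations_per_genome_mean=254.0)

KD_TRUTH_NM = {"unmodified": 180.0, "3meC": 252.0, "1meA": 313.0}


def dataset_dir(genotype: str) -> Path:
    return SCRATCH / "dataset" / genotype


def ensure_datasets() -> dict[str, Path]:
    """Emit (once) the wild-type and mutant synthetic datasets."""
    out = {}
    for genotype, params in [("wt", WT_PARAMS), ("mutant", MUT_PARAMS)]:
        d = dataset_dir(genotype)
        if not (d / "truth.json").exists():
            emit_dataset(d, GENOME_SPEC, params, genotype=genotype)
        out[genotype] = d
    return out


def filtered_clustered_catalogs():
    """The standard catalog pipeline: read, filter, screen, cluster."""
    catalogs = []
    for genotype, d in ensure_datasets().items():
        for vcf in sorted(d.glob("*.vcf")):
            cat = read_catalog(vcf, genotype=genotype)
            kept, _ = filter_genome_calls(cat.records)
            catalogs.append(cat.with_records(kept))
    screened, _ = remove_recurrent(catalogs)
    return [cluster_catalog(c) for c in screened]
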