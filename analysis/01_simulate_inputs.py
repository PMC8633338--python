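#!/usr/bin/env python
"""Generate every input the downstream analyses consume.

Writes, under the output directory:

* ``cohort/`` — a synthetic population cohort (VCF with GT per sample),
  gene regions (BED), consequence annotations (TSV), a ClinVar-style
  classification table (TSV) and the generator's ground-truth ledger.
* ``family/`` — the deterministic index-family fixture: pedigree (PED),
  phased parent-of-origin haplotypes (TSV) and per-individual allelic
  depths at the focal variant (TSV).
"""

import argparse
from pathlib import Path

import pandas as pd

from mhscreen.haplotype_tracing import write_haplotypes_tsv, write_ped
from mhscreen.synthetic_data import SimConfig, index_family, gen_cohort


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--cohort-size", type=int, default=2000)
    parser.add_argument("--n-variants", type=int, default=50)
    parser.add_argument("--out", type=Path, default=Path("results/sim"))
    args = parser.parse_args()

    config = SimConfig(seed=args.seed, cohort_size=args.cohort_size,
                       n_variants=args.n_variants)
    cohort_dir = args.out / "cohort"
    paths = gen_cohort(config).write(cohort_dir)
    print(f"cohort: {args.cohort_size} samples, {args.n_variants} variants")
    for name, path in paths.items():
        print(f"  {name}: {path}")

    family_dir = args.out / "family"
    family_dir.mkdir(parents=True, exist_ok=True)
    fam = index_family()
    write_ped(fam.pedigree, family_dir / "family.ped")
    write_haplotypes_tsv(fam.phased, family_dir / "haplotypes.tsv")
    pd.DataFrame([
        {"individual": d.individual, "ref_reads": d.ref_reads,
         "alt_reads": d.alt_reads, "genotype": fam.genotypes[i].value}
        for i, d in fam.depths.items()
    ]).to_csv(family_dir / "allelic_depths.tsv", sep="\t", index=False)
    print(f"family: {len(fam.pedigree.members)} members "
          f"({len(fam.depths)} typed) -> {family_dir}")


if __name__ == "__main__":
    main()
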