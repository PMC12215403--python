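#!/usr/bin/env python
"""Reduce the plate curves to EAUC-ratio phenotypes and label the classes.

Reads the plate CSV emitted by 01_simulate_study.py exactly as a real
plate-reader export would be read, computes per-replicate relative growth
(stressed EAUC / control EAUC), averages replicates, and applies the
dual-dose 20% tail rule: worst growers at 1 mM -> sensitive (0), best
growers at 2 mM -> resistant (1).
"""

from pathlib import Path

import pandas as pd

from famtrait.features import read_orthogroup_counts
from famtrait.growth import (phenotype_table, read_plate_table,
                             read_well_metadata, write_phenotype_table)
from famtrait.traits import build_instance_table, classify_tails

STUDY = Path("scratch/study")


def main():
    Path("results").mkdir(exist_ok=True)
    curves = read_plate_table(STUDY / "plate.csv",
                              read_well_metadata(STUDY / "metadata.csv"))
    phenotypes = phenotype_table(curves)
    write_phenotype_table(phenotypes, "results/phenotypes.tsv")
    print(f"{len(phenotypes)} phenotype records "
          f"({len({r.species for r in phenotypes})} species x 2 doses)")

    classes = classify_tails(phenotypes, low_dose=1.0, high_dose=2.0, f=0.2)
    classes.to_json("results/classes.json")
    counts = read_orthogroup_counts(STUDY / "gene_counts.tsv")
    instances = build_instance_table(classes, counts)
    instances.to_csv(STUDY / "instances.tsv", sep="\t",
                     index_label="species")
    print(f"{len(classes.sensitive)} sensitive + "
          f"{len(classes.resistant)} resistant = {len(instances)} instances")
    print(f"phenotype cutoffs: sensitive <= {classes.cutoffs[0]:.3f} at 1 mM, "
          f"resistant >= {classes.cutoffs[1]:.3f} at 2 mM")


if __name__ == "__main__":
    main()
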