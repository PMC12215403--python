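"""Binary resistance classes from continuous phenotypes: the dual-dose tail rule.

Species are labelled sensitive (class 0) if they fall in the poorest-growing
fraction *f* at the low stressor dose, and resistant (class 1) if they fall in
the best-growing fraction *f* at the high dose.  Everything in between stays
unlabelled and is excluded from the machine-learning instance table (but kept
for count-vs-growth correlations across all screened species).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import pandas as pd

from .growth import PhenotypeRecord

logger = logging.getLogger(__name__)

__all__ = ["TraitClassTable", "classify_tails", "build_instance_table"]


@dataclass(frozen=True)
class TraitClassTable:
    """Realized class assignments under a (low_dose, high_dose, f) tail rule.

    ``labels`` maps species -> {0, 1}; ``cutoffs`` records the realized
    phenotype thresholds (last value admitted into each tail);
    ``unclassified`` lists the middle species excluded from the instance
    table.
    """

    labels: dict
    rule: tuple  # (low_dose, high_dose, f)
    cutoffs: tuple  # (sensitive_cutoff, resistant_cutoff)
    unclassified: tuple

    @property
    def sensitive(self) -> list:
        return sorted(s for s, c in self.labels.items() if c == 0)

    @property
    def resistant(self) -> list:
        return sorted(s for s, c in self.labels.items() if c == 1)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rule": {"low_dose": self.rule[0], "high_dose": self.rule[1],
                             "fraction": self.rule[2]},
                    "cutoffs": {"sensitive": self.cutoffs[0],
                                "resistant": self.cutoffs[1]},
                    "sensitive": self.sensitive,
                    "resistant": self.resistant,
                    "unclassified": sorted(self.unclassified),
                },
                fh, indent=2,
            )


def classify_tails(phenotypes, low_dose: float, high_dose: float,
                   f: float = 0.2) -> TraitClassTable:
    """Assign the floor(f*N) extreme species at each dose to the two classes.

    Class 0 (sensitive) holds the ``floor(f*N)`` species with the smallest
    relative growth at ``low_dose``; class 1 (resistant) the same number with
    the largest relative growth at ``high_dose``.  Ties at a cutoff are broken
    by a stable ``(value, species)`` sort and logged.  A species selected into
    both tails makes the rule degenerate for the dataset and raises.

    Parameters
    ----------
    phenotypes : iterable of PhenotypeRecord
        Must contain a record at both doses for every species considered.
    f : float
        Tail fraction per class, ``0 < f < 0.5``.
    """
    if not 0 < f < 0.5:
        raise ValueError("tail fraction f must satisfy 0 < f < 0.5")
    by_dose: dict[float, dict[str, float]] = {}
    for rec in phenotypes:
        by_dose.setdefault(rec.dose, {})[rec.species] = rec.relative_growth
    for dose in (low_dose, high_dose):
        if dose not in by_dose:
            raise ValueError(f"no phenotype records at dose {dose} mM")
    low, high = by_dose[low_dose], by_dose[high_dose]
    species = sorted(set(low) & set(high))
    missing = (set(low) ^ set(high))
    if missing:
        raise ValueError(
            f"species lacking a phenotype at one dose: {sorted(missing)}"
        )
    n_tail = math.floor(f * len(species))
    if n_tail == 0:
        raise ValueError("tail fraction selects zero species")

    asc = sorted(species, key=lambda s: (low[s], s))
    sensitive = asc[:n_tail]
    if n_tail < len(asc) and low[asc[n_tail - 1]] == low[asc[n_tail]]:
        logger.info("tie at the sensitive cutoff broken by species identifier")
    desc = sorted(species, key=lambda s: (-high[s], s))
    resistant = desc[:n_tail]
    if n_tail < len(desc) and high[desc[n_tail - 1]] == high[desc[n_tail]]:
        logger.info("tie at the resistant cutoff broken by species identifier")

    overlap = set(sensitive) & set(resistant)
    if overlap:
        raise ValueError(
            "tail rule degenerate: species in both classes: "
            f"{sorted(overlap)}"
        )
    labels = {s: 0 for s in sensitive}
    labels.update({s: 1 for s in resistant})
    unclassified = tuple(sorted(set(species) - set(labels)))
    return TraitClassTable(
        labels=labels,
        rule=(low_dose, high_dose, f),
        cutoffs=(low[sensitive[-1]], high[resistant[-1]]),
        unclassified=unclassified,
    )


def build_instance_table(classes: TraitClassTable,
                         counts: pd.DataFrame) -> pd.DataFrame:
    """Join class labels onto the orthogroup count matrix.

    Returns a DataFrame with one row per classified species (stable species
    order), all family-count columns of ``counts``, and a final integer
    ``class`` column.  A classified species missing from ``counts`` is an
    error listing the species.
    """
    wanted = sorted(classes.labels)
    missing = [s for s in wanted if s not in counts.index]
    if missing:
        raise KeyError(f"classified species missing from count matrix: {missing}")
    if "class" in counts.columns:
        raise ValueError("count matrix already contains a 'class' column")
    table = counts.loc[wanted].copy()
    table["class"] = [classes.labels[s] for s in wanted]
    return table
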