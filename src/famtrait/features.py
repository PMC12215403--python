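"""Orthogroup count matrices, membership tables, and train/test/fold splits.

The count matrix convention throughout the package is a pandas DataFrame with
species as the index, orthogroup identifiers as columns, and non-negative
integer gene counts as values (an optional trailing integer ``class`` column
marks labelled instance tables).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_orthogroup_counts",
    "write_orthogroup_counts",
    "read_membership",
    "membership_counts",
    "SplitPlan",
    "make_split",
]


def _validate_counts(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate species identifiers: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate family identifiers: {dups}")
    arr = df.to_numpy()
    bad = ~np.isfinite(arr.astype(float)) | (arr.astype(float) % 1 != 0) | (arr < 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer or negative count at species {df.index[i]!r}, "
            f"family {df.columns[j]!r}: {arr[i, j]!r}"
        )
    return df.astype(int)


def read_orthogroup_counts(path, orient: str = "orthogroup_rows") -> pd.DataFrame:
    """Read a gene-family count TSV into a species x families matrix.

    ``orient="orthogroup_rows"`` expects the OrthoFinder
    ``Orthogroups.GeneCount.tsv`` dialect (one row per orthogroup, one column
    per species, optional trailing ``Total`` column) and transposes it;
    ``orient="species_rows"`` expects species already in rows.  A ``Total``
    row or column is dropped with a log line.  Non-integer or negative cells
    raise with their coordinates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if "Total" in df.columns:
        df = df.drop(columns="Total")
        logger.info("dropped 'Total' column (OrthoFinder dialect)")
    if "Total" in df.index:
        df = df.drop(index="Total")
        logger.info("dropped 'Total' row (OrthoFinder dialect)")
    if orient == "orthogroup_rows":
        df = df.T
    elif orient != "species_rows":
        raise ValueError(f"unknown orientation {orient!r}")
    return _validate_counts(df)


def write_orthogroup_counts(df: pd.DataFrame, path,
                            orient: str = "orthogroup_rows") -> None:
    """Write a count matrix as TSV in either orientation (no Total column)."""
    out = df.T if orient == "orthogroup_rows" else df
    label = "Orthogroup" if orient == "orthogroup_rows" else "Species"
    out.to_csv(path, sep="\t", index_label=label)


def read_membership(path) -> dict:
    """Read an orthogroup membership TSV (``Orthogroups.tsv`` dialect).

    One row per orthogroup, one column per species, comma-separated gene
    identifiers, empty cell = no members.  Returns
    ``{orthogroup: {species: [gene, ...]}}``.  A gene identifier repeated
    within one cell is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    membership: dict[str, dict[str, list[str]]] = {}
    for og, row in df.iterrows():
        per_species = {}
        for sp, cell in row.items():
            genes = [g.strip() for g in str(cell).split(",") if g.strip()]
            if len(genes) != len(set(genes)):
                dup = sorted({g for g in genes if genes.count(g) > 1})
                raise ValueError(
                    f"duplicate gene identifiers in {og}/{sp}: {dup}"
                )
            per_species[str(sp)] = genes
        membership[str(og)] = per_species
    return membership


def membership_counts(membership: dict) -> pd.DataFrame:
    """Derive a species x families count matrix from a membership mapping."""
    species = sorted({sp for row in membership.values() for sp in row})
    fams = sorted(membership)
    data = {
        og: [len(membership[og].get(sp, [])) for sp in species] for og in fams
    }
    return pd.DataFrame(data, index=species, columns=fams, dtype=int)


@dataclass(frozen=True)
class SplitPlan:
    """A balanced holdout plus stratified cross-validation folds.

    ``test_species`` holds equally many species from each class;
    ``folds`` is a list of disjoint validation sets that partition the
    training species, each approximately class-balanced.
    """

    test_species: tuple
    folds: tuple  # tuple of tuples of species
    seed: int

    @property
    def train_species(self) -> list:
        return sorted(s for fold in self.folds for s in fold)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"seed": self.seed, "test_species": list(self.test_species),
                 "folds": [list(f) for f in self.folds]},
                fh, indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            test_species=tuple(d["test_species"]),
            folds=tuple(tuple(f) for f in d["folds"]),
            seed=int(d["seed"]),
        )


def make_split(table: pd.DataFrame, holdout_frac: float = 0.1,
               k: int = 10, seed: int = 0) -> SplitPlan:
    """Build the balanced holdout and k stratified folds for one replicate.

    Per class, ``round(holdout_frac * N / 2)`` species are held out for
    testing (the closest balanced realization of a fractional holdout); the
    remaining species are shuffled with the seeded generator and dealt
    round-robin into ``k`` folds within each class, so folds are as
    class-balanced as the counts allow.
    """
    if "class" not in table.columns:
        raise ValueError("instance table must carry a 'class' column")
    y = table["class"]
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    n_total = len(table)
    n_test_per_class = int(round(holdout_frac * n_total / 2))
    rng = np.random.default_rng(seed)

    test: list = []
    folds: list[list] = [[] for _ in range(k)]
    cursor = 0  # continue round-robin across classes so fold sizes balance
    for cls in classes:
        members = sorted(table.index[y == cls])
        perm = rng.permutation(len(members))
        shuffled = [members[i] for i in perm]
        test.extend(shuffled[:n_test_per_class])
        train_cls = shuffled[n_test_per_class:]
        if k > len(train_cls):
            raise ValueError(
                f"k={k} folds exceed the {len(train_cls)} training species "
                f"of class {cls}"
            )
        for sp in train_cls:
            folds[cursor % k].append(sp)
            cursor += 1
    return SplitPlan(
        test_species=tuple(sorted(test)),
        folds=tuple(tuple(sorted(f)) for f in folds),
        seed=seed,
    )
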