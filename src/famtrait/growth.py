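"""Plate-reader growth curves and relative-growth (EAUC-ratio) phenotypes.

The screen behind this package grows every species in microtiter plates with
and without an oxidative stressor, reads OD600 hourly, and summarises each
well by its empirical area under the curve (EAUC, a model-free trapezoidal
integral in OD·h).  Resistance is the per-replicate ratio of stressed EAUC to
the matched untreated control, averaged over biological replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthCurve",
    "PhenotypeRecord",
    "InvalidReplicateError",
    "read_plate_table",
    "read_well_metadata",
    "eauc",
    "relative_growth",
    "phenotype_table",
    "write_phenotype_table",
]


class InvalidReplicateError(ValueError):
    """A replicate whose untreated control shows no growth (EAUC == 0)."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well's OD600 time series with its biological metadata.

    Parameters
    ----------
    species : str
        Species identifier.
    condition : str
        Stressor name (e.g. ``"TBOOH"``); free-form label.
    dose : float
        Stressor concentration in mM; 0 marks the untreated control.
    replicate : int
        Biological replicate index (replicates are paired across doses).
    times : ndarray
        Hours, strictly increasing, length >= 2.
    od : ndarray
        OD600 readings, same length as ``times``.
    """

    species: str
    condition: str
    dose: float
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise ValueError("times and od must be 1-D and of equal length")
        if len(times) < 2:
            raise ValueError("a growth curve needs at least 2 timepoints")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(od)) and np.all(np.isfinite(times))):
            raise ValueError("times and od must be finite")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-species relative growth at one stressor dose.

    ``relative_growth`` is the arithmetic mean of ``per_replicate`` EAUC
    ratios over the valid biological replicates.
    """

    species: str
    dose: float
    relative_growth: float
    n_replicates: int
    per_replicate: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_replicates != len(self.per_replicate):
            raise ValueError("n_replicates must equal len(per_replicate)")
        if self.per_replicate and not np.isclose(
            self.relative_growth, float(np.mean(self.per_replicate))
        ):
            raise ValueError("relative_growth must be the mean of per_replicate")
        if self.relative_growth < 0:
            raise ValueError("relative_growth must be >= 0")


def read_well_metadata(path) -> dict:
    """Read a well-metadata CSV (columns well,species,condition,dose_mM,replicate)."""
    df = pd.read_csv(path, dtype={"well": str, "species": str, "condition": str})
    required = {"well", "species", "condition", "dose_mM", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata is missing columns: {sorted(missing)}")
    meta = {}
    for row in df.itertuples(index=False):
        meta[row.well] = (row.species, row.condition, float(row.dose_mM), int(row.replicate))
    return meta


def read_plate_table(path, metadata: dict) -> list[GrowthCurve]:
    """Parse a plate-reader CSV into one :class:`GrowthCurve` per well.

    Two dialects are accepted: *wide* (first column is time, one column per
    well) and *long* (columns ``time``, ``well``, ``od``).  ``metadata`` maps
    each well name to ``(species, condition, dose_mM, replicate)``; a well
    present in the table but absent from the metadata is an error naming the
    well.  Rows are sorted by time; duplicate timestamps within a well are
    rejected.
    """
    df = pd.read_csv(path)
    cols = {c.lower() for c in df.columns}
    if {"time", "well", "od"} <= cols:
        df.columns = [c.lower() for c in df.columns]
        per_well = {
            str(well): (grp["time"].to_numpy(float), grp["od"].to_numpy(float))
            for well, grp in df.groupby("well", sort=True)
        }
    else:
        time = df.iloc[:, 0].to_numpy(float)
        per_well = {
            str(col): (time, df[col].to_numpy(float)) for col in df.columns[1:]
        }

    curves = []
    for well in sorted(per_well):
        if well not in metadata:
            raise KeyError(f"well {well!r} has readings but no metadata entry")
        t, od = per_well[well]
        order = np.argsort(t, kind="stable")
        t, od = t[order], od[order]
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"well {well!r} has duplicate timestamps")
        species, condition, dose, replicate = metadata[well]
        curves.append(
            GrowthCurve(
                species=species, condition=condition, dose=dose,
                replicate=replicate, times=t, od=od,
            )
        )
    return curves


def eauc(curve: GrowthCurve, baseline: str = "none") -> float:
    """Empirical area under the curve (OD·h), trapezoidal on the raw grid.

    ``baseline="subtract_initial"`` first replaces od with
    ``max(od - od[0], 0)``, which removes a constant blank; the default leaves
    the readings untouched.
    """
    od = curve.od
    if baseline == "subtract_initial":
        od = np.maximum(od - od[0], 0.0)
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(od, curve.times))


def relative_growth(treated: GrowthCurve, control: GrowthCurve,
                    baseline: str = "none") -> float:
    """Treated EAUC divided by matched-control EAUC for one replicate."""
    if treated.species != control.species or treated.replicate != control.replicate:
        raise ValueError("treated and control must share species and replicate")
    if control.dose != 0:
        raise ValueError("control curve must have dose 0")
    denom = eauc(control, baseline)
    if denom == 0:
        raise InvalidReplicateError(
            f"control EAUC is 0 for {treated.species} replicate {treated.replicate}"
        )
    return eauc(treated, baseline) / denom


def phenotype_table(curves, baseline: str = "none") -> list[PhenotypeRecord]:
    """Reduce a curve collection to per-(species, dose>0) phenotype records.

    Treated curves pair with the dose-0 control of the same species,
    condition, and replicate.  Replicates whose control has zero EAUC, or
    treated curves with no matching control, are dropped with a warning; a
    species with no valid replicate at a dose is excluded (logged).
    """
    controls = {
        (c.species, c.condition, c.replicate): c for c in curves if c.dose == 0
    }
    ratios: dict[tuple, list[float]] = {}
    for c in curves:
        if c.dose == 0:
            continue
        ctrl = controls.get((c.species, c.condition, c.replicate))
        if ctrl is None:
            logger.warning(
                "no dose-0 control for %s/%s replicate %d; dropped",
                c.species, c.condition, c.replicate,
            )
            continue
        try:
            r = relative_growth(c, ctrl, baseline)
        except InvalidReplicateError as exc:
            logger.warning("invalid replicate excluded: %s", exc)
            continue
        ratios.setdefault((c.species, c.dose), []).append(r)

    records = []
    for (species, dose) in sorted(ratios):
        vals = ratios[(species, dose)]
        if not vals:  # pragma: no cover - empty lists are never inserted
            continue
        records.append(
            PhenotypeRecord(
                species=species, dose=dose,
                relative_growth=float(np.mean(vals)),
                n_replicates=len(vals), per_replicate=tuple(vals),
            )
        )
    return records


def write_phenotype_table(records, path) -> None:
    """Write phenotype records as TSV (species, dose_mM, relative_growth, n_replicates)."""
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "dose_mM": [r.dose for r in records],
            "relative_growth": [r.relative_growth for r in records],
            "n_replicates": [r.n_replicates for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path) -> list[PhenotypeRecord]:
    """Read a TSV written by :func:`write_phenotype_table`.

    Per-replicate values are not stored in the TSV, so the returned records
    carry the mean replicated ``n_replicates`` times (the mean is preserved).
    """
    df = pd.read_csv(path, sep="\t")
    return [
        PhenotypeRecord(
            species=str(row.species), dose=float(row.dose_mM),
            relative_growth=float(row.relative_growth),
            n_replicates=int(row.n_replicates),
            per_replicate=tuple([float(row.relative_growth)] * int(row.n_replicates)),
        )
        for row in df.itertuples(index=False)
    ]
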