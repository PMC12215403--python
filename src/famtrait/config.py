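"""Run configuration: a validated, defaults-filled record loaded from YAML or JSON."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Everything a full pipeline run needs.

    Paths may be None when the corresponding stage is not requested
    (``run_all`` checks and names the missing field).  Doses are the
    (low, high) stressor concentrations of the tail rule in mM.
    """

    outdir: str = "run"
    # inputs
    curves: str | None = None
    metadata: str | None = None
    counts: str | None = None
    membership: str | None = None
    tree: str | None = None
    annotations: str | None = None
    # tail rule
    low_dose: float = 1.0
    high_dose: float = 2.0
    tail_fraction: float = 0.2
    # ML protocol
    n_select: int = 50
    n_replicates: int = 100
    holdout_frac: float = 0.1
    k_folds: int = 10
    base_seed: int = 0
    grid: dict = field(default_factory=lambda: {
        "n_estimators": [100, 500],
        "max_depth": [5, 10],
        "max_features": ["sqrt"],
    })
    # attribution / association
    pgls_families: list = field(default_factory=list)
    # enrichment
    enrich_species: str | None = None
    min_genes: int = 5
    fdr_threshold: float = 1e-3

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"config fields required for this stage are unset: {missing}"
            )


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config; unknown keys and type mismatches raise."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    known = {f.name: f for f in fields(RunConfig)}
    unknown = sorted(set(data) - set(known))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    cfg = RunConfig(**data)
    for name, typ in (("n_select", int), ("n_replicates", int),
                      ("k_folds", int), ("base_seed", int), ("min_genes", int)):
        if not isinstance(getattr(cfg, name), int):
            raise TypeError(f"config key {name!r} must be an integer")
    for name in ("low_dose", "high_dose", "tail_fraction", "holdout_frac",
                 "fdr_threshold"):
        val = getattr(cfg, name)
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            raise TypeError(f"config key {name!r} must be a number")
    if not isinstance(cfg.grid, dict):
        raise TypeError("config key 'grid' must be a mapping of lists")
    return cfg
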