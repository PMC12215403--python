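"""End-to-end orchestration: phenotype -> classify -> train -> explain -> associate -> enrich.

Each stage reads the previous stage's files and writes its own under the run
directory, so any stage can be re-run in isolation; a manifest JSON records
the configuration, seeds, package version, and a checksum of every output.
Reproducibility comes from determinism (single seed, single thread), not
from caching.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .enrich import fisher_enrich, genes_for_features, read_annotations
from .evaluate import evaluate_replicates
from .features import read_membership, read_orthogroup_counts
from .forest import fit_forest
from .growth import phenotype_table, read_plate_table, read_well_metadata, write_phenotype_table
from .phylo import export_itol_annotations, pgls, read_newick
from .shapley import shap_tree
from .traits import build_instance_table, classify_tails

logger = logging.getLogger(__name__)

__all__ = ["run_all"]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute every configured stage; returns the run directory.

    A stage failure aborts with the stage name; outputs of completed stages
    are retained.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    stage = "setup"
    try:
        # ---- phenotypes -------------------------------------------------
        stage = "phenotype"
        config.require("curves", "metadata", "counts")
        curves = read_plate_table(config.curves,
                                  read_well_metadata(config.metadata))
        phenotypes = phenotype_table(curves)
        pheno_path = out / "phenotypes.tsv"
        write_phenotype_table(phenotypes, pheno_path)
        produced.append(pheno_path)
        logger.info("stage=phenotype records=%d", len(phenotypes))

        # ---- classification ---------------------------------------------
        stage = "classify"
        classes = classify_tails(
            phenotypes, config.low_dose, config.high_dose,
            config.tail_fraction,
        )
        classes_path = out / "classes.json"
        classes.to_json(classes_path)
        produced.append(classes_path)
        counts = read_orthogroup_counts(config.counts)
        instances = build_instance_table(classes, counts)
        inst_path = out / "instances.tsv"
        instances.to_csv(inst_path, sep="\t", index_label="species")
        produced.append(inst_path)
        logger.info("stage=classify instances=%d", len(instances))

        # ---- training / evaluation --------------------------------------
        stage = "train"
        report = evaluate_replicates(
            instances, n_replicates=config.n_replicates,
            holdout_frac=config.holdout_frac, k=config.k_folds,
            n_select=config.n_select, grid=config.grid,
            base_seed=config.base_seed,
        )
        report_path = out / "evaluation.json"
        report.to_json(report_path)
        produced.append(report_path)
        metrics_path = out / "metrics.tsv"
        report.metrics.to_csv(metrics_path, sep="\t", index=False)
        produced.append(metrics_path)

        # final model on all instances with the last replicate's winners
        selected = report.selected_features[-1]
        best = report.best_params[-1]
        final = fit_forest(
            instances.loc[:, selected], instances["class"].to_numpy(),
            params=best, seed=config.base_seed,
        )
        model_path = out / "model.json"
        final.to_json(model_path)
        produced.append(model_path)
        logger.info("stage=train best=%s", best.to_dict())

        # ---- SHAP attribution -------------------------------------------
        stage = "explain"
        shap = shap_tree(final, instances.loc[:, selected])
        shap_path = out / "shap.tsv"
        shap.to_tsv(shap_path)
        produced.append(shap_path)
        logger.info("stage=explain local_accuracy_err=%.2e",
                    shap.local_accuracy_error())

        # ---- phylogenetic association ------------------------------------
        if config.pgls_families:
            stage = "pgls"
            config.require("tree")
            tree = read_newick(config.tree)
            pheno = {
                r.species: r.relative_growth
                for r in phenotypes if r.dose == config.high_dose
            }
            rows = []
            for fam in config.pgls_families:
                x = {
                    sp: float(counts.at[sp, fam])
                    for sp in counts.index
                    if sp in pheno and sp in set(tree.tips)
                }
                res = pgls(x, {sp: pheno[sp] for sp in x}, tree)
                rows.append({"family": fam, "slope": res.slope,
                             "intercept": res.intercept, "stderr": res.stderr,
                             "t": res.t, "p": res.p, "r": res.r, "n": res.n})
                bar = export_itol_annotations(x, kind="bar", label=fam)
                bar_path = out / f"itol_{fam}.txt"
                bar_path.write_text(bar)
                produced.append(bar_path)
            pgls_path = out / "pgls.tsv"
            pd.DataFrame(rows).to_csv(pgls_path, sep="\t", index=False)
            produced.append(pgls_path)
            logger.info("stage=pgls families=%d", len(rows))

        # SHAP heatmap annotation for the classified species
        heat = {
            sp: {fam: float(shap.phi.at[sp, fam]) for fam in selected[:10]}
            for sp in shap.phi.index
        }
        heat_path = out / "itol_shap_heatmap.txt"
        heat_path.write_text(export_itol_annotations(heat, kind="heatmap",
                                                     label="shap"))
        produced.append(heat_path)

        # ---- enrichment --------------------------------------------------
        if config.annotations and config.enrich_species:
            stage = "enrich"
            config.require("membership")
            membership = read_membership(config.membership)
            term_genes, term_names = read_annotations(config.annotations)
            study = genes_for_features(selected, membership,
                                       config.enrich_species)
            background = genes_for_features(
                list(counts.columns), membership, config.enrich_species
            )
            enr = fisher_enrich(
                study, background, term_genes, term_names,
                min_genes=config.min_genes,
                fdr_threshold=config.fdr_threshold,
            )
            enr_path = out / "enrichment.tsv"
            enr.to_csv(enr_path, sep="\t", index=False)
            produced.append(enr_path)
            logger.info("stage=enrich terms=%d", len(enr))
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": {k: v for k, v in vars(config).items()},
        "outputs": {p.name: _checksum(p) for p in produced},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out
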