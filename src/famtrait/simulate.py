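"""Synthetic study generator with known ground truth.

Emulates the statistical shape of a gene-family/trait screen end to end: a
Yule phylogeny of a few hundred species; a sparse, zero-inflated integer
orthogroup count matrix evolved by a linear birth-death copy-number process
along the branches; a latent liability that sums weighted causal-family
counts with phylogenetic (Brownian) and independent noise; a true resistance
score r in (0, 1) from the centred liability; and hourly 168-hour logistic
growth curves whose stressed/control EAUC ratio encodes r.  Every stage is
driven by named substreams of one seed, so a dataset is byte-reproducible.

Defaults mirror the screen the pipeline targets: 285 species, doses 0/1/2 mM,
three paired biological replicates, and a 20% dual-dose tail rule that yields
57 + 57 = 114 labelled instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .growth import GrowthCurve, phenotype_table
from .phylo import PhyloTree
from .traits import TraitClassTable, build_instance_table, classify_tails

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "simulate_tree",
    "evolve_family_counts",
    "assign_trait",
    "emit_growth_curves",
    "make_dataset",
    "Dataset",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator, with the study-scale defaults.

    Copy-number process: per-family root count is ``Geometric(root_geom)``
    on {0, 1, ...} (sparse for large ``root_geom``); along a branch of
    length t each copy independently duplicates at rate ``dup_rate`` and is
    lost at rate ``loss_rate`` (rates per copy per unit branch length; the
    tree has unit depth).  Causal families instead follow a
    birth-death-innovation process (per-copy duplication ``causal_dup_rate``
    and loss ``causal_loss_rate`` plus constant gene gain
    ``causal_gain_rate``): excess loss plus innovation makes the process
    mean-reverting around ``gain / (loss - dup)`` copies, so causal counts
    turn over fast and carry little phylogenetic signal — the dynamics of
    the rapidly expanding and contracting families such screens implicate.

    Liability: L_s = sum_c w_c * count_{s,c} + sigma_phylo * BM_s +
    sigma_iid * eps_s; true resistance r_s = logistic(L_s - median(L)).

    Growth: logistic OD curves on an hourly grid over ``duration_h`` hours;
    the carrying capacity under dose d > 0 is ``k0 * logistic(steepness *
    (r_s - dose_midpoint_scale * d))`` so EAUC responds monotonically to r
    at every dose, with per-reading multiplicative lognormal noise and a
    per-(species, replicate) growth-rate jitter shared across doses (paired
    replicates, as when one day's plate carries all doses).
    """

    n_species: int = 285
    n_families: int = 2000
    n_causal: int = 5
    causal_weights: tuple = (1.0, 1.0, 0.9, 0.8, 0.7)
    dup_rate: float = 0.5
    loss_rate: float = 0.5
    root_geom: float = 0.5
    causal_dup_rate: float = 0.5
    causal_loss_rate: float = 3.0
    causal_gain_rate: float = 7.5
    sigma_phylo: float = 0.5
    sigma_iid: float = 0.25
    # growth-curve block
    n0: float = 0.05
    k0: float = 1.0
    growth_rate_range: tuple = (0.05, 0.15)
    steepness: float = 6.0
    dose_midpoint_scale: float = 0.35
    doses: tuple = (0.0, 1.0, 2.0)
    n_replicates: int = 3
    duration_h: float = 168.0
    noise_sd: float = 0.02
    rate_jitter_sd: float = 0.05
    condition: str = "TBOOH"
    # labelling rule
    tail_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_families:
            raise ValueError("n_causal cannot exceed n_families")
        if len(self.causal_weights) != self.n_causal:
            raise ValueError("need one weight per causal family")
        if min(self.dup_rate, self.loss_rate, self.sigma_phylo,
               self.sigma_iid) < 0:
            raise ValueError("rates and noise scales must be >= 0")
        if 0.0 not in self.doses:
            raise ValueError("doses must include the 0 mM control")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    causal_weights: dict  # family -> liability weight per gene copy
    liability: pd.Series
    resistance: pd.Series  # r in (0, 1)
    bm_noise: pd.Series
    iid_noise: pd.Series
    class_labels: dict | None = None  # filled once phenotypes are classified

    @property
    def causal_families(self) -> list:
        return sorted(self.causal_weights)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "causal_weights": self.causal_weights,
                    "liability": self.liability.round(10).to_dict(),
                    "resistance": self.resistance.round(10).to_dict(),
                    "bm_noise": self.bm_noise.round(10).to_dict(),
                    "iid_noise": self.iid_noise.round(10).to_dict(),
                    "class_labels": self.class_labels,
                },
                fh, indent=2, sort_keys=True,
            )


def _stream(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


def simulate_tree(n_species: int, seed: int = 0) -> PhyloTree:
    """A Yule (pure-birth) tree on ``n_species`` tips, scaled to unit depth."""
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = _stream(seed, 0)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # the root splits at time 0 (no stem), so tree depth = elapsed time
    birth_time = {}
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        birth_time[child] = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.edge.length = t - birth_time[parent]
        for _ in range(2):
            child = parent.new_child()
            birth_time[child] = t
        active.extend(parent.child_nodes())
    t_final = t + rng.exponential(1.0 / n_species)
    width = max(4, len(str(n_species)))
    for i, node in enumerate(sorted(active, key=lambda nd: birth_time[nd])):
        node.edge.length = t_final - birth_time[node]
        node.taxon = taxa.new_taxon(label=f"sp{i + 1:0{width}d}")
    # unit total depth: every rate in SimConfig is per unit tree height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_final
    return PhyloTree(tree)


def _branch_transition(n, t, lam, mu, rng):
    """Exact one-branch transition of the linear birth-death copy process.

    Each of the ``n`` starting copies leaves 0 descendants with probability
    alpha, else 1 + Geometric(1 - beta) descendants (the classic Kendall
    solution), so the branch-end count is Binomial(n, 1 - alpha) surviving
    lineages plus NegativeBinomial(survivors, 1 - beta) extra copies.
    Vectorized over families.
    """
    n = np.asarray(n)
    if lam == 0.0 and mu == 0.0:
        return n.copy()
    if np.isclose(lam, mu):
        a = lam * t / (1.0 + lam * t)
        b = a
    else:
        e = np.exp((lam - mu) * t)
        a = mu * (e - 1.0) / (lam * e - mu)
        b = lam * (e - 1.0) / (lam * e - mu)
    surv = rng.binomial(n, 1.0 - a)
    out = surv.copy()
    pos = surv > 0
    if b > 0 and pos.any():
        out[pos] += rng.negative_binomial(surv[pos], 1.0 - b)
    return out


def _bdi_branch(n: int, t: float, lam: float, mu: float, nu: float,
                rng) -> int:
    """Event-by-event simulation of one branch of the birth-death-innovation
    process: per-copy duplication ``lam``, per-copy loss ``mu``, constant
    gain ``nu``.  Exact (Gillespie); used only for the handful of causal
    families, so speed is irrelevant."""
    clock = 0.0
    n = int(n)
    while True:
        total = nu + n * (lam + mu)
        if total <= 0:
            return n
        clock += rng.exponential(1.0 / total)
        if clock > t:
            return n
        u = rng.uniform(0.0, total)
        if u < nu:
            n += 1
        elif u < nu + n * lam:
            n += 1
        else:
            n -= 1


def evolve_family_counts(tree: PhyloTree, config: SimConfig
                         ) -> tuple[pd.DataFrame, list]:
    """Evolve every family's copy number down the tree.

    Returns the species x families integer count matrix and the list of
    causal family identifiers (chosen uniformly).  Neutral families follow
    the pure duplication-loss process; causal families follow the
    mean-reverting birth-death-innovation process and start at its
    stationary mean (Poisson-sampled).
    """
    rng = _stream(config.seed, 1)
    F = config.n_families
    fam_ids = [f"OG{i:07d}" for i in range(F)]
    causal_idx = np.sort(rng.choice(F, size=config.n_causal, replace=False))
    is_causal = np.zeros(F, dtype=bool)
    is_causal[causal_idx] = True

    lam_c, mu_c, nu_c = (config.causal_dup_rate, config.causal_loss_rate,
                         config.causal_gain_rate)
    causal_mean = nu_c / max(mu_c - lam_c, 1e-9)
    root = rng.geometric(config.root_geom, size=F) - 1
    root[is_causal] = rng.poisson(causal_mean, size=config.n_causal)

    counts_at = {tree.tree.seed_node: root}
    tip_rows = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        parent_counts = counts_at[node.parent_node]
        here = np.empty(F, dtype=np.int64)
        plain = ~is_causal
        here[plain] = _branch_transition(
            parent_counts[plain], t, config.dup_rate, config.loss_rate, rng
        )
        here[is_causal] = [
            _bdi_branch(parent_counts[i], t, lam_c, mu_c, nu_c, rng)
            for i in causal_idx
        ]
        if node.is_leaf():
            tip_rows[node.taxon.label] = here
        else:
            counts_at[node] = here

    species = sorted(tip_rows)
    matrix = pd.DataFrame(
        np.vstack([tip_rows[s] for s in species]),
        index=species, columns=fam_ids, dtype=int,
    )
    return matrix, [fam_ids[i] for i in causal_idx]


def _brownian_tips(tree: PhyloTree, rng) -> pd.Series:
    value = {tree.tree.seed_node: 0.0}
    tips = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        v = value[node.parent_node] + rng.normal(0.0, np.sqrt(t))
        if node.is_leaf():
            tips[node.taxon.label] = v
        else:
            value[node] = v
    return pd.Series(tips).sort_index()


def assign_trait(counts: pd.DataFrame, tree: PhyloTree, config: SimConfig,
                 causal_families: list) -> SyntheticTruth:
    """Liability-model trait: weighted causal counts plus BM and iid noise."""
    rng = _stream(config.seed, 2)
    weights = dict(zip(causal_families, config.causal_weights))
    species = list(counts.index)
    bm = config.sigma_phylo * _brownian_tips(tree, rng).loc[species]
    eps = pd.Series(
        config.sigma_iid * rng.standard_normal(len(species)), index=species
    )
    causal_part = counts[causal_families].to_numpy() @ np.asarray(
        config.causal_weights, dtype=float
    )
    liability = pd.Series(causal_part, index=species) + bm + eps
    resistance = 1.0 / (1.0 + np.exp(-(liability - liability.median())))
    return SyntheticTruth(
        causal_weights=weights,
        liability=liability,
        resistance=resistance,
        bm_noise=bm,
        iid_noise=eps,
    )


def _logistic_od(times, n0, k, rho):
    return k / (1.0 + ((k - n0) / n0) * np.exp(-rho * times))


def emit_growth_curves(truth: SyntheticTruth, config: SimConfig
                       ) -> tuple[list, pd.DataFrame, pd.DataFrame]:
    """Logistic plate curves encoding each species' true resistance.

    Returns ``(curves, plate_wide, metadata)`` where ``plate_wide`` is the
    wide plate CSV layout (time column plus one column per well) and
    ``metadata`` the well table (well, species, condition, dose_mM,
    replicate).
    """
    rng = _stream(config.seed, 3)
    times = np.arange(0.0, config.duration_h + 0.5, 1.0)
    lo, hi = config.growth_rate_range
    species = list(truth.resistance.index)
    base_rate = pd.Series(rng.uniform(lo, hi, len(species)), index=species)

    curves, columns, meta_rows = [], {}, []
    well = 0
    for sp in species:
        r_s = truth.resistance[sp]
        for rep in range(1, config.n_replicates + 1):
            rho = base_rate[sp] * np.exp(
                rng.normal(0.0, config.rate_jitter_sd)
            )
            for dose in config.doses:
                if dose == 0:
                    k = config.k0
                else:
                    k = config.k0 / (1.0 + np.exp(
                        -config.steepness
                        * (r_s - config.dose_midpoint_scale * dose)
                    ))
                od = _logistic_od(times, config.n0, k, rho)
                if config.noise_sd > 0:
                    od = od * np.exp(
                        rng.normal(0.0, config.noise_sd, len(times))
                    )
                well += 1
                name = f"W{well:06d}"
                columns[name] = od
                meta_rows.append(
                    {"well": name, "species": sp,
                     "condition": config.condition, "dose_mM": dose,
                     "replicate": rep}
                )
                curves.append(
                    GrowthCurve(species=sp, condition=config.condition,
                                dose=dose, replicate=rep, times=times, od=od)
                )
    plate = pd.DataFrame({"time": times, **columns})
    return curves, plate, pd.DataFrame(meta_rows)


@dataclass
class Dataset:
    """Everything one synthetic study produces, cross-consistent by construction."""

    config: SimConfig
    tree: PhyloTree
    counts: pd.DataFrame
    membership: dict
    truth: SyntheticTruth
    curves: list
    plate: pd.DataFrame
    metadata: pd.DataFrame
    phenotypes: list
    classes: TraitClassTable
    instances: pd.DataFrame
    annotations: dict
    term_names: dict


def _membership_stub(counts: pd.DataFrame) -> dict:
    return {
        og: {
            sp: [f"{sp}|{og}|{i}" for i in range(int(counts.at[sp, og]))]
            for sp in counts.index
        }
        for og in counts.columns
    }


def _annotation_stub(counts, causal_families, reference_species, seed):
    """Flat term->gene annotations for the reference species: causal genes get
    'causal_term'; the rest are dealt into 20 generic terms."""
    rng = _stream(seed, 4)
    term_genes: dict[str, set] = {"causal_term": set()}
    term_names = {"causal_term": "synthetic causal process"}
    for i in range(20):
        term_genes[f"term_{i:02d}"] = set()
        term_names[f"term_{i:02d}"] = f"synthetic process {i:02d}"
    for og in counts.columns:
        n = int(counts.at[reference_species, og])
        if n == 0:
            continue
        genes = [f"{reference_species}|{og}|{i}" for i in range(n)]
        if og in causal_families:
            term_genes["causal_term"].update(genes)
        bucket = f"term_{int(rng.integers(20)):02d}"
        term_genes[bucket].update(genes)
    return {t: g for t, g in term_genes.items() if g}, term_names


def make_dataset(config: SimConfig = SimConfig(),
                 outdir: str | Path | None = None) -> Dataset:
    """Generate a full cross-consistent study; optionally write all files.

    The emitted files (Newick tree, GeneCount TSV, membership TSV, plate and
    metadata CSVs, truth JSON, annotations TSV, instance TSV) are loadable by
    the package's own readers, and the same seed reproduces them byte for
    byte.
    """
    tree = simulate_tree(config.n_species, config.seed)
    counts, causal = evolve_family_counts(tree, config)
    truth = assign_trait(counts, tree, config, causal)
    curves, plate, metadata = emit_growth_curves(truth, config)
    phenotypes = phenotype_table(curves)
    positive_doses = sorted(d for d in config.doses if d > 0)
    classes = classify_tails(
        phenotypes, low_dose=positive_doses[0], high_dose=positive_doses[-1],
        f=config.tail_fraction,
    )
    truth.class_labels = dict(classes.labels)
    instances = build_instance_table(classes, counts)
    membership = _membership_stub(counts)
    reference = counts.index[0]
    annotations, term_names = _annotation_stub(
        counts, set(causal), reference, config.seed
    )

    ds = Dataset(
        config=config, tree=tree, counts=counts, membership=membership,
        truth=truth, curves=curves, plate=plate, metadata=metadata,
        phenotypes=phenotypes, classes=classes, instances=instances,
        annotations=annotations, term_names=term_names,
    )
    if outdir is not None:
        _write_dataset(ds, Path(outdir))
    return ds


def _write_dataset(ds: Dataset, outdir: Path) -> None:
    from .features import write_orthogroup_counts
    from .growth import write_phenotype_table

    outdir.mkdir(parents=True, exist_ok=True)
    ds.tree.write_newick(outdir / "tree.nwk")
    write_orthogroup_counts(ds.counts, outdir / "gene_counts.tsv")

    species = list(ds.counts.index)
    rows = {
        og: {sp: ", ".join(ds.membership[og][sp]) for sp in species}
        for og in ds.counts.columns
    }
    pd.DataFrame(rows).T.reindex(columns=species).to_csv(
        outdir / "membership.tsv", sep="\t", index_label="Orthogroup"
    )

    ds.plate.to_csv(outdir / "plate.csv", index=False)
    ds.metadata.to_csv(outdir / "metadata.csv", index=False)
    write_phenotype_table(ds.phenotypes, outdir / "phenotypes.tsv")
    ds.classes.to_json(outdir / "classes.json")
    ds.instances.to_csv(outdir / "instances.tsv", sep="\t",
                        index_label="species")
    ds.truth.to_json(outdir / "truth.json")

    ann_rows = [
        {"term_id": term, "term_name": ds.term_names[term], "gene": gene}
        for term in sorted(ds.annotations)
        for gene in sorted(ds.annotations[term])
    ]
    pd.DataFrame(ann_rows).to_csv(outdir / "annotations.tsv", sep="\t",
                                  index=False)
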