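"""Phylogenetic tree handling and phylogenetically corrected association.

Trees are Newick files parsed through dendropy and wrapped in a thin
:class:`PhyloTree`.  The association statistic is a generalized least squares
regression whose error covariance is the Brownian-motion covariance implied
by shared branch lengths (PGLS with Pagel's lambda fixed at 1): two species'
trait residuals covary in proportion to the root-to-MRCA path length they
share.  On a star phylogeny with equal branch lengths this reduces exactly to
ordinary least squares.

The module also hosts the pipeline's plain statistical calls (Welch t-test,
Pearson correlation, one-way ANOVA) and the export of tree-annotation files
for external tree viewers.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import stats

__all__ = [
    "PhyloTree",
    "PGLSResult",
    "read_newick",
    "parse_newick",
    "prune",
    "bm_covariance",
    "pgls",
    "export_itol_annotations",
    "welch_ttest",
    "pearson",
    "anova_oneway",
]


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, prunable to a species subset."""

    tree: dendropy.Tree

    @property
    def tips(self) -> list:
        return sorted(l.taxon.label for l in self.tree.leaf_node_iter())

    def write_newick(self, path) -> None:
        self.tree.write(path=str(path), schema="newick",
                        suppress_rooting=True)

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def _validate(self) -> "PhyloTree":
        labels = [l.taxon.label for l in self.tree.leaf_node_iter()]
        dups = sorted({l for l in labels if labels.count(l) > 1})
        if dups:
            raise ValueError(f"duplicate tip labels: {dups}")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and not np.isfinite(edge.length):
                raise ValueError("non-finite branch length")
        return self


def _get_tree(**kwargs) -> PhyloTree:
    try:
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True, **kwargs,
        )
    except dendropy.utility.error.DataParseError as exc:
        kind = "duplicate tip labels" if "uplicate" in str(exc) else "malformed newick"
        raise ValueError(f"{kind}: {exc}") from exc
    return PhyloTree(tree)._validate()


def parse_newick(newick: str) -> PhyloTree:
    return _get_tree(data=newick)


def read_newick(path) -> PhyloTree:
    """Parse a Newick file; quoted labels and internal support values are
    tolerated (support is kept on the nodes but unused)."""
    return _get_tree(path=str(path))


def prune(phylo: PhyloTree, keep) -> PhyloTree:
    """Restrict the tree to ``keep``; collapsed unary nodes sum their branch
    lengths, so tip-to-tip path lengths are preserved."""
    keep = set(keep)
    tips = set(phylo.tips)
    missing = sorted(keep - tips)
    if missing:
        raise KeyError(f"species not in tree: {missing}")
    clone = dendropy.Tree(phylo.tree)
    clone.retain_taxa_with_labels(sorted(keep))
    # dendropy can leave a unary root edge; fold it into its child
    seed = clone.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        if child.edge.length is not None and seed.edge.length:
            child.edge.length += seed.edge.length
        clone.seed_node = child
        child.parent_node = None
        seed = child
    return PhyloTree(clone)._validate()


def bm_covariance(phylo: PhyloTree, order=None) -> tuple[np.ndarray, list]:
    """Brownian-motion covariance: V[i, j] = shared root-to-MRCA path length.

    Accumulated edge by edge — each edge of length l adds l to V[i, j] for
    every tip pair (i, j) below it, which gives the diagonal the full
    root-to-tip lengths.  Returns (V, tip_order).
    """
    tips = phylo.tips if order is None else list(order)
    pos = {label: i for i, label in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))
    for node in phylo.tree.preorder_node_iter():
        if node.edge.length is None or node.parent_node is None:
            continue
        below = [
            pos[l.taxon.label]
            for l in node.leaf_iter()
            if l.taxon.label in pos
        ]
        ix = np.asarray(below, dtype=np.intp)
        V[np.ix_(ix, ix)] += node.edge.length
    return V, tips


@dataclass(frozen=True)
class PGLSResult:
    """GLS slope/intercept with Brownian error covariance.

    ``r`` is the signed square root of the GLS R^2 (the "phylogenetically
    adjusted" correlation): sign(beta1) * sqrt(1 - RSS_V / TSS_V), with both
    sums of squares taken in the V-weighted metric and TSS_V from the
    intercept-only GLS fit.
    """

    slope: float
    intercept: float
    stderr: float
    t: float
    p: float
    r: float
    n: int


def pgls(x, y, phylo: PhyloTree, species=None) -> PGLSResult:
    """PGLS regression of y on x under Brownian covariance from the tree.

    ``x`` and ``y`` may be mappings species -> value or arrays aligned to
    ``species`` (default: sorted tip order).  Requires n >= 3.
    """
    if hasattr(x, "keys"):
        species = sorted(set(x) & set(y) & set(phylo.tips))
        xv = np.array([float(x[s]) for s in species])
        yv = np.array([float(y[s]) for s in species])
    else:
        species = list(species) if species is not None else phylo.tips
        xv = np.asarray(x, dtype=float)
        yv = np.asarray(y, dtype=float)
    n = len(species)
    if n < 3:
        raise ValueError("PGLS needs at least 3 species")
    if len(xv) != n or len(yv) != n:
        raise ValueError("x, y and species must have equal length")

    sub = prune(phylo, species) if set(species) != set(phylo.tips) else phylo
    V, _ = bm_covariance(sub, order=species)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular phylogenetic covariance; zero-length branches may need "
            "a small jitter"
        ) from exc

    X = np.column_stack([np.ones(n), xv])
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, yv)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    dof = n - 2
    sigma2 = rss / dof
    cov_beta = sigma2 * np.linalg.inv(XtX)
    se = float(np.sqrt(cov_beta[1, 1]))
    tstat = float(beta[1] / se) if se > 0 else np.inf * np.sign(beta[1])
    p = float(2 * stats.t.sf(abs(tstat), dof)) if np.isfinite(tstat) else 0.0

    ones_w = Xw[:, 0]
    mu = float((ones_w @ yw) / (ones_w @ ones_w))
    tss = float(np.sum((yw - mu * ones_w) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    r = float(np.sign(beta[1]) * np.sqrt(max(r2, 0.0)))
    return PGLSResult(
        slope=float(beta[1]), intercept=float(beta[0]), stderr=se,
        t=tstat, p=p, r=r, n=n,
    )


def export_itol_annotations(values, kind: str = "bar",
                            label: str = "famtrait",
                            color: str = "#1f77b4") -> str:
    """Render per-species values as an iTOL dataset annotation file.

    ``kind="bar"`` takes a mapping species -> number (DATASET_SIMPLEBAR);
    ``kind="heatmap"`` takes a mapping species -> mapping family -> number
    (DATASET_HEATMAP, one field per family).  Returns the file text.
    """
    if not values:
        raise ValueError("no species values to export")
    sep = "TAB"
    lines = []
    if kind == "bar":
        lines += [
            "DATASET_SIMPLEBAR",
            f"SEPARATOR {sep}",
            f"DATASET_LABEL\t{label}",
            f"COLOR\t{color}",
            "DATA",
        ]
        for sp in sorted(values):
            lines.append(f"{sp}\t{float(values[sp])}")
    elif kind == "heatmap":
        fields = sorted({f for row in values.values() for f in row})
        if not fields:
            raise ValueError("heatmap export needs at least one field")
        lines += [
            "DATASET_HEATMAP",
            f"SEPARATOR {sep}",
            f"DATASET_LABEL\t{label}",
            f"COLOR\t{color}",
            "FIELD_LABELS\t" + "\t".join(fields),
            "DATA",
        ]
        for sp in sorted(values):
            row = values[sp]
            lines.append(
                sp + "\t" + "\t".join(str(float(row.get(f, 0.0))) for f in fields)
            )
    else:
        raise ValueError(f"unknown annotation kind {kind!r}")
    return "\n".join(lines) + "\n"


def welch_ttest(a, b):
    """Two-sided Welch t-test; returns (t, p)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          equal_var=False)
    return float(res.statistic), float(res.pvalue)


def pearson(a, b):
    """Pearson correlation; returns (r, p)."""
    res = stats.pearsonr(np.asarray(a, float), np.asarray(b, float))
    return float(res.statistic), float(res.pvalue)


def anova_oneway(*groups):
    """One-way ANOVA across groups; returns (F, p)."""
    res = stats.f_oneway(*[np.asarray(g, float) for g in groups])
    return float(res.statistic), float(res.pvalue)
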