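"""Over-representation testing of selected-feature genes against a custom background.

The gene universe is the reference species' genes present in the orthogroup
matrix (not the whole genome), so enrichment asks whether a functional term
is over-represented among the genes of the selected families relative to the
genes the dataset could have selected.  Significance is the upper-tail
hypergeometric (one-sided Fisher exact) probability; the false discovery rate
is controlled by Benjamini-Hochberg across all tested terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "genes_for_features",
    "read_annotations",
    "fisher_enrich",
    "bh_fdr",
]


def genes_for_features(features, membership: dict, species: str) -> set:
    """Union of one species' genes across the listed orthogroups."""
    genes: set = set()
    for og in features:
        if og not in membership:
            raise KeyError(f"unknown orthogroup {og!r}")
        genes |= set(membership[og].get(species, []))
    return genes


def read_annotations(path) -> tuple[dict, dict]:
    """Read a flat term->gene TSV (term_id, term_name, gene).

    Returns ``(term_genes, term_names)``.  Term ancestors are not expanded;
    annotations must be pre-propagated if hierarchical closure is wanted.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"term_id", "term_name", "gene"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV needs columns {sorted(required)}")
    term_genes: dict[str, set] = {}
    term_names: dict[str, str] = {}
    for row in df.itertuples(index=False):
        term_genes.setdefault(row.term_id, set()).add(row.gene)
        term_names[row.term_id] = row.term_name
    return term_genes, term_names


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    study: set,
    background: set,
    annotations: dict,
    term_names: dict | None = None,
    min_genes: int = 5,
    fdr_threshold: float = 1e-3,
    two_sided: bool = False,
    apply_filter: bool = True,
) -> pd.DataFrame:
    """Per-term over-representation of ``study`` within ``background``.

    For each term with at least one background gene: ``k`` study genes with
    the term out of ``n`` study genes, ``K`` background genes with the term
    out of ``N``; one-sided p is the upper-tail hypergeometric probability
    P(X >= k) (``two_sided=True`` switches to the two-sided Fisher exact
    test); fold enrichment is (k/n) / (K/N).  BH adjustment runs across all
    tested terms; with ``apply_filter`` the result keeps terms with
    ``k >= min_genes`` and ``fdr < fdr_threshold``, sorted by fold.
    """
    study = set(study)
    background = set(background)
    stray = sorted(study - background)
    if stray:
        raise ValueError(f"study genes missing from background: {stray}")
    n = len(study)
    N = len(background)
    if n == 0 or N == 0:
        raise ValueError("study and background must be non-empty")

    rows = []
    for term in sorted(annotations):
        term_bg = set(annotations[term]) & background
        K = len(term_bg)
        if K == 0:
            logger.info("term %s has no background genes; skipped", term)
            continue
        k = len(term_bg & study)
        if two_sided:
            table = [[k, n - k], [K - k, (N - K) - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        else:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold_enrichment": (k / n) / (K / N),
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = pd.Series(dtype=float)
        return out
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    if apply_filter:
        out = out[(out["k"] >= min_genes) & (out["fdr"] < fdr_threshold)]
    return out.sort_values(
        ["fold_enrichment", "term_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
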