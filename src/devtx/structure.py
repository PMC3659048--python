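"""Global structure summaries of the stage-resolved expression matrix:
stage correlation, PCA with stage loadings, per-gene z-scores, per-term
Fisher enrichment, and TF-family median profiles with 3-way clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

from .threshold import DEFAULT_PSEUDOCOUNT


def correlation_matrix(
    rpkm: pd.DataFrame,
    gene_filter: Optional[Sequence[str]] = None,
    log2: bool = False,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Pairwise Pearson correlation between stage columns.

    Computed over the filtered genes on raw RPKM by default; ``log2=True``
    correlates log2(RPKM + pseudocount) instead, which damps the influence
    of the heavy expression tail.
    """
    mat = rpkm.loc[gene_filter] if gene_filter is not None else rpkm
    if len(mat) < 2:
        raise ValueError("at least two genes are required")
    values = mat.to_numpy(dtype=float)
    if log2:
        values = np.log2(values + pseudocount)
    sd = values.std(axis=0)
    for stage, s in zip(mat.columns, sd):
        if s == 0:
            raise ValueError(f"stage {stage!r} has zero variance across genes")
    corr = np.corrcoef(values, rowvar=False)
    return pd.DataFrame(corr, index=mat.columns, columns=mat.columns)


@dataclass
class PCAResult:
    """Uncentered (by default) PCA of the gene x stage matrix."""

    stage_scores: pd.DataFrame        # stage coordinates: singular value x loading
    loadings: pd.DataFrame            # right singular vectors, one column per PC
    gene_scores: pd.DataFrame         # left singular vectors x singular values
    variance_fraction: np.ndarray     # squared singular values / total
    centered: bool


def pca_stages(
    matrix: pd.DataFrame,
    n_components: int = 3,
    center: bool = False,
) -> PCAResult:
    """SVD-based principal components of a gene x stage expression matrix.

    Uncentered by default so the first component captures the shared
    expression scale across stages; ``center=True`` subtracts the per-stage
    mean first.  Stage loadings are the right singular vectors and the
    variance fractions are the squared singular values over their total.
    """
    x = matrix.to_numpy(dtype=float)
    n_genes, n_stages = x.shape
    if n_genes < n_stages:
        raise ValueError("need at least as many genes as stages")
    if n_components > n_stages:
        raise ValueError(
            f"requested {n_components} components but only {n_stages} stages"
        )
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    loadings = pd.DataFrame(vt[:n_components].T, index=matrix.columns, columns=pcs)
    scores = loadings * s[:n_components]
    gene_scores = pd.DataFrame(
        u[:, :n_components] * s[:n_components], index=matrix.index, columns=pcs
    )
    return PCAResult(
        stage_scores=scores,
        loadings=loadings,
        gene_scores=gene_scores,
        variance_fraction=(s**2 / total)[:n_components],
        centered=center,
    )


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across stages: (x - mean) / sd with sample sd (n-1).

    Rows with zero variance are dropped with a warning.
    """
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} constant row(s) with zero variance",
            stacklevel=2,
        )
    values = values[keep]
    z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(z, index=matrix.index[keep], columns=matrix.columns)


def term_enrichment(
    gene_set: Sequence[str],
    universe: Sequence[str],
    term_map: Mapping[str, Set[str] | Sequence[str]],
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric tail) enrichment per term.

    Classic per-term testing: each term is tested independently against the
    universe, with no decorrelation of the term hierarchy.  Results are
    sorted by p-value with ties broken by term id.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    genes = set(gene_set)
    if not genes <= uni:
        raise ValueError("gene set must be a subset of the universe")
    n_universe = len(uni)
    n_set = len(genes)
    rows = []
    for term in sorted(term_map):
        members = set(term_map[term]) & uni
        overlap = len(members & genes)
        p = float(hypergeom.sf(overlap - 1, n_universe, len(members), n_set))
        rows.append((term, overlap, n_set, len(members), n_universe, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=["term", "overlap", "set_size", "term_size", "universe_size", "p"],
    )
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def read_term_map(path) -> Dict[str, Set[str]]:
    """Read a two-column TSV (term_id, gene_id) into term -> gene-set form."""
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], comment="#")
    return {term: set(sub["gene"]) for term, sub in df.groupby("term")}


@dataclass
class FamilyProfileSet:
    """Per-family median expression profiles and their 3-way clustering."""

    profiles: pd.DataFrame            # family x stage, log2 median RPKM
    clusters: pd.Series               # family -> cluster label
    empty_families: List[str]         # families whose members are all unexpressed


def family_profiles(
    rpkm: pd.DataFrame,
    family_map: Mapping[str, str],
    n_clusters: int = 3,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    method: str = "complete",
    metric: str = "cosine",
) -> FamilyProfileSet:
    """Log2 median expression per family and stage, clustered into groups.

    Each family's profile is the per-stage median RPKM over its member genes
    (log2 with pseudocount); families are merged by complete-linkage
    clustering on cosine distances and the tree is cut at ``n_clusters``.
    Families with no member present in the matrix get the floor profile
    log2(pseudocount) and are flagged.
    """
    families: Dict[str, List[str]] = {}
    for gene, fam in family_map.items():
        families.setdefault(fam, []).append(gene)

    rows, empty = {}, []
    for fam in sorted(families):
        members = families[fam]
        missing = [g for g in members if g not in rpkm.index]
        if missing:
            raise KeyError(
                f"family {fam!r} maps genes absent from the matrix: {missing[:3]}"
            )
        med = rpkm.loc[members].median(axis=0).to_numpy()
        if (med == 0).all():
            empty.append(fam)
        rows[fam] = np.log2(med + pseudocount)
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=rpkm.columns)

    if len(profiles) < n_clusters:
        raise ValueError("fewer families than requested clusters")
    if len(profiles) == 1:
        labels = np.array([1])
    else:
        z = linkage(pdist(profiles.to_numpy(), metric=metric), method=method)
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    clusters = pd.Series(labels, index=profiles.index, name="cluster")
    return FamilyProfileSet(profiles=profiles, clusters=clusters, empty_families=empty)
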