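"""Expression-pattern clustering: histogram equalization, a batch-trained
self-organizing map, and hierarchical merging of map units.

Gene trajectories (log2 RPKM across stages) are first histogram-equalized:
the pooled values are split into near-equal-occupancy quantile bins and
mapped piecewise-linearly onto [0, 1], which removes the heavy tail of the
expression distribution while preserving rank order; the transform stores
its knots so it can be inverted.  A self-organizing map is then batch-
trained on the equalized profiles (Gaussian neighbourhood on a rectangular
grid, linearly decaying radius, deterministic for a given seed), and the
unit codebooks are merged by hierarchical clustering into a small number of
expression-pattern classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist


@dataclass
class EqualizedMatrix:
    """Histogram-equalized values in [0, 1] with the invertible knot map."""

    values: pd.DataFrame
    knots_x: np.ndarray        # original-scale knot positions (strictly increasing)
    knots_y: np.ndarray        # equalized values at the knots (non-decreasing in [0,1])
    n_bins: int

    def transform(self, x: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.knots_x, self.knots_y)

    def inverse(self, y: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(y, dtype=float), self.knots_y, self.knots_x)


def histogram_equalize(matrix: pd.DataFrame | np.ndarray, n_bins: int = 100) -> EqualizedMatrix:
    """Piecewise-linear rank transform of the pooled values onto [0, 1].

    The pooled sample is split into ``n_bins`` quantile bins of near-equal
    occupancy; within each bin values are mapped linearly, and the whole map
    is scaled so the minimum goes to 0 and the maximum to 1.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    df = pd.DataFrame(matrix)
    pooled = df.to_numpy(dtype=float).ravel()
    if not np.isfinite(pooled).all():
        raise ValueError("input contains non-finite values")

    edges = np.quantile(pooled, np.linspace(0, 1, n_bins + 1))
    knots_x = np.unique(edges)
    if len(knots_x) == 1:
        warnings.warn("constant input matrix: all values map to 0.5", stacklevel=2)
        values = df.copy()
        values.loc[:, :] = 0.5
        return EqualizedMatrix(values, knots_x, np.array([0.5]), n_bins)
    # cumulative bin fraction at each distinct edge; ties collapse bins
    frac = np.empty(len(knots_x))
    for i, x in enumerate(knots_x):
        frac[i] = np.searchsorted(edges, x, side="right") - 1
    knots_y = frac / n_bins
    knots_y = (knots_y - knots_y[0]) / (knots_y[-1] - knots_y[0])
    eq = EqualizedMatrix(df.copy(), knots_x, knots_y, n_bins)
    eq.values = pd.DataFrame(
        eq.transform(df.to_numpy()).reshape(df.shape), index=df.index, columns=df.columns
    )
    return eq


# ---------------------------------------------------------------------------
# batch SOM


@dataclass
class SOMModel:
    """A trained self-organizing map over gene trajectories."""

    rows: int
    cols: int
    codebooks: np.ndarray          # (units, stages)
    bmu: np.ndarray                # best-matching unit per gene
    gene_ids: List[str]
    quantization_errors: np.ndarray
    seed: int
    n_epochs: int
    sigma_start: float
    sigma_end: float

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def unit_coords(self) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(self.rows), np.arange(self.cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def gene_units(self) -> pd.Series:
        return pd.Series(self.bmu, index=self.gene_ids, name="unit")


def default_grid(n_genes: int, units_per_gene_sqrt: float = 5.0) -> Tuple[int, int]:
    """Smallest near-square grid with at least ``5 * sqrt(n)`` units."""
    target = max(4, math.ceil(units_per_gene_sqrt * math.sqrt(max(n_genes, 1))))
    rows = max(2, round(math.sqrt(target)))
    cols = math.ceil(target / rows)
    return rows, cols


def fit_som(
    data: EqualizedMatrix | pd.DataFrame | np.ndarray,
    grid: Optional[Tuple[int, int]] = None,
    seed: int = 0,
    n_epochs: int = 30,
    sigma_start: Optional[float] = None,
    sigma_end: float = 1.0,
) -> SOMModel:
    """Batch-train a SOM with a Gaussian neighbourhood on a rectangular grid.

    Each epoch assigns every profile to its best-matching unit (Euclidean
    distance, ties to the lowest unit index) and replaces every codebook by
    the neighbourhood-weighted mean of the assigned profiles; the
    neighbourhood radius decays linearly from ``sigma_start`` (default: half
    the larger grid dimension) to ``sigma_end``.  Deterministic given the
    seed, which only drives the codebook initialization.
    """
    if isinstance(data, EqualizedMatrix):
        frame = data.values
    else:
        frame = pd.DataFrame(data)
    x = frame.to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("empty input matrix")
    n, d = x.shape
    if grid is None:
        grid = default_grid(n)
    rows, cols = grid
    units = rows * cols
    if units < 4:
        raise ValueError("the SOM grid needs at least 4 units")
    if sigma_start is None:
        sigma_start = max(rows, cols) / 2.0

    # start tight around the data mean so the map unfolds as the radius shrinks
    rng = np.random.default_rng(seed)
    spread = x.std(axis=0, ddof=0) * 0.05 + 1e-6
    w = x.mean(axis=0) + rng.normal(0, 1.0, size=(units, d)) * spread

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    x_sq = (x**2).sum(axis=1)
    qe = []
    for epoch in range(n_epochs):
        sigma = sigma_start + (sigma_end - sigma_start) * (
            epoch / max(n_epochs - 1, 1)
        )
        d2 = x_sq[:, None] - 2 * x @ w.T + (w**2).sum(axis=1)[None, :]
        bmu = np.argmin(d2, axis=1)
        qe.append(float(np.sqrt(np.maximum(d2[np.arange(n), bmu], 0)).mean()))
        h = np.exp(-grid_d2 / (2 * sigma**2))
        sums = np.zeros((units, d))
        np.add.at(sums, bmu, x)
        counts = np.bincount(bmu, minlength=units).astype(float)
        denom = h @ counts
        numer = h @ sums
        nonzero = denom > 0
        w[nonzero] = numer[nonzero] / denom[nonzero, None]

    d2 = x_sq[:, None] - 2 * x @ w.T + (w**2).sum(axis=1)[None, :]
    bmu = np.argmin(d2, axis=1)
    qe.append(float(np.sqrt(np.maximum(d2[np.arange(n), bmu], 0)).mean()))

    gene_ids = [str(i) for i in frame.index]
    return SOMModel(
        rows=rows,
        cols=cols,
        codebooks=w,
        bmu=bmu,
        gene_ids=gene_ids,
        quantization_errors=np.array(qe),
        seed=seed,
        n_epochs=n_epochs,
        sigma_start=float(sigma_start),
        sigma_end=float(sigma_end),
    )


# ---------------------------------------------------------------------------
# unit clustering


@dataclass
class ClusterAssignment:
    """Partition of SOM units (and hence genes) into expression-pattern classes."""

    unit_clusters: np.ndarray          # cluster label per unit, 1..k
    gene_clusters: pd.Series           # cluster label per gene
    centroids: pd.DataFrame            # per-cluster mean profile (in input space)
    k: int

    def cluster_sizes(self) -> pd.Series:
        return self.gene_clusters.value_counts().sort_index()


def cluster_units(
    som: SOMModel,
    k: int = 6,
    data: Optional[EqualizedMatrix | pd.DataFrame | np.ndarray] = None,
    method: str = "ward",
    metric: str = "euclidean",
) -> ClusterAssignment:
    """Merge SOM units into ``k`` clusters by hierarchical clustering.

    The unit codebooks are clustered hierarchically and the tree is cut at
    ``k``; each gene inherits the cluster of its best-matching unit.  Ward
    linkage on Euclidean distances is the default — it yields balanced,
    coherent unit groups without the manual post-adjustment that
    complete-linkage trees tend to need; complete linkage and the cosine
    metric (the heatmap convention) remain available.  Deterministic; scipy
    breaks ties by unit index.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if method == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    if k > som.n_units:
        raise ValueError(f"k={k} exceeds the number of units ({som.n_units})")
    if k == som.n_units:
        labels = np.arange(1, som.n_units + 1)
    else:
        z = linkage(pdist(som.codebooks, metric=metric), method=method)
        labels = fcluster(z, t=k, criterion="maxclust")
    gene_clusters = pd.Series(labels[som.bmu], index=som.gene_ids, name="cluster")

    if data is None:
        profiles = pd.DataFrame(som.codebooks[som.bmu], index=som.gene_ids)
    elif isinstance(data, EqualizedMatrix):
        profiles = data.values.set_axis(som.gene_ids, axis=0)
    else:
        profiles = pd.DataFrame(data).set_axis(som.gene_ids, axis=0)
    centroids = profiles.groupby(gene_clusters).mean()
    return ClusterAssignment(
        unit_clusters=labels, gene_clusters=gene_clusters, centroids=centroids, k=int(labels.max())
    )


def representative_genes(
    assignment: ClusterAssignment,
    data: EqualizedMatrix | pd.DataFrame | np.ndarray,
    fraction: float = 0.5,
) -> Dict[int, List[str]]:
    """Per cluster, the genes closest to the cluster centroid.

    Genes are ranked by Euclidean distance to the centroid (mean member
    profile) and the closest ``ceil(fraction * size)`` are returned — the
    "top half" used for the cluster line plots by default.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if isinstance(data, EqualizedMatrix):
        profiles = data.values
    else:
        profiles = pd.DataFrame(data)
    profiles = profiles.set_axis(assignment.gene_clusters.index, axis=0)
    out: Dict[int, List[str]] = {}
    for label, members in assignment.gene_clusters.groupby(assignment.gene_clusters):
        ids = list(members.index)
        sub = profiles.loc[ids].to_numpy(dtype=float)
        centroid = sub.mean(axis=0)
        dist = np.sqrt(((sub - centroid) ** 2).sum(axis=1))
        order = np.lexsort((np.arange(len(ids)), dist))
        n_keep = math.ceil(fraction * len(ids))
        out[int(label)] = [ids[i] for i in order[:n_keep]]
    return out
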