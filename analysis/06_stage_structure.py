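"""Global stage structure: correlation, PCA, enrichment, family profiles.

Pearson correlation between stages over detected genes, uncentered PCA of
the regulated genes' log2 profiles (component 1 is the shared scale), a
per-term Fisher enrichment demonstration on archetype-derived gene sets,
and median expression profiles of synthetic gene families clustered three
ways.
"""

import numpy as np
import pandas as pd

from _common import RESULTS, SCRATCH, ensure_dirs, load_fixture, load_rpkm
from devtx.structure import (
    correlation_matrix,
    family_profiles,
    pca_stages,
    term_enrichment,
    zscore_rows,
)
from devtx.threshold import DEFAULT_PSEUDOCOUNT


def main() -> None:
    ensure_dirs()
    _, _, _, labels = load_fixture()
    rpkm = load_rpkm()

    detected = rpkm.index[(rpkm > 0).any(axis=1)]
    corr = correlation_matrix(rpkm, gene_filter=detected)
    corr.round(4).to_csv(RESULTS / "06_stage_correlation.tsv", sep="\t")

    regulated = labels.index[labels != "background"]
    log2_rpkm = np.log2(rpkm.loc[regulated] + DEFAULT_PSEUDOCOUNT)
    pca = pca_stages(log2_rpkm, n_components=3)
    out = pca.loadings.round(4)
    out["variance_pct"] = np.nan
    pca_summary = pd.DataFrame(
        {"variance_pct": (100 * pca.variance_fraction).round(2)},
        index=pca.loadings.columns,
    )
    pca.loadings.round(4).to_csv(RESULTS / "06_pca_loadings.tsv", sep="\t")
    pca_summary.to_csv(RESULTS / "06_pca_variance.tsv", sep="\t")
    print(f"top-3 PCs explain {100 * pca.variance_fraction.sum():.1f}% of the variation")

    zscore_rows(rpkm.loc[regulated]).round(4).to_csv(SCRATCH / "zscores.tsv", sep="\t")

    # enrichment demo: terms from planted archetypes; the query set is the
    # maternal programme, which should light up the two maternal terms
    universe = list(labels.index)
    term_map = {f"archetype:{a}": set(labels.index[labels == a]) for a in labels.unique()}
    maternal = [g for g in universe if labels[g].startswith("maternal")]
    enrich = term_enrichment(maternal, universe, term_map)
    enrich.to_csv(RESULTS / "06_enrichment.tsv", sep="\t", index=False)

    # synthetic families: groups of genes sharing an archetype
    rng = np.random.default_rng(0)
    fam_map = {}
    for arch in labels.unique():
        members = list(labels.index[labels == arch])
        for i, gene in enumerate(members):
            fam_map[gene] = f"{arch}_fam{i % max(len(members) // 12, 1):02d}"
    fams = family_profiles(rpkm, fam_map, n_clusters=3)
    fams.clusters.rename("cluster").to_csv(RESULTS / "06_family_clusters.tsv", sep="\t")
    print("family cluster sizes:", fams.clusters.value_counts().to_dict())
    print(enrich.head(4)[["term", "overlap", "term_size", "p"]])


if __name__ == "__main__":
    main()
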