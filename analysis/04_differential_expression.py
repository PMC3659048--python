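"""Pairwise Fisher DE across all stage pairs and stage-preferential genes.

Rounded raw counts against library totals, BH FDR per stage pair; DE calls
at FDR < 0.001 with >4-fold RPKM change, stage-preferential calls at
FDR < 0.001 against every other stage with >=2-fold RPKM.
"""

import pandas as pd

from _common import RESULTS, SCRATCH, ensure_dirs, load_counts, load_rpkm, load_totals
from devtx.de import pairwise_de, stage_preferential


def main() -> None:
    ensure_dirs()
    counts, rpkm, totals = load_counts(), load_rpkm(), load_totals()
    result = pairwise_de(counts, totals, rpkm)
    result.table.to_csv(SCRATCH / "pairwise_de.tsv", sep="\t", index=False)

    pair_counts = (
        result.table.groupby(["stage_a", "stage_b"])["is_de"].sum().rename("n_de")
    )
    pair_counts.to_csv(RESULTS / "04_de_pair_counts.tsv", sep="\t")
    de_genes = result.de_gene_ids
    pd.Series(de_genes, name="gene").to_csv(
        SCRATCH / "de_genes.txt", index=False, header=False
    )
    print(f"{len(de_genes)} genes DE in at least one of "
          f"{pair_counts.size} stage pairs")

    preferential = stage_preferential(result, rpkm)
    preferential.to_csv(RESULTS / "04_preferential_genes.tsv", sep="\t", index=False)
    by_stage = preferential["preferred_stage"].value_counts().reindex(rpkm.columns, fill_value=0)
    by_stage.rename("n_preferential").to_csv(RESULTS / "04_preferential_counts.tsv", sep="\t")
    print("preferential genes per stage:")
    print(by_stage)


if __name__ == "__main__":
    main()
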