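"""Assign reads to genes and compute the RPKM matrix.

Fractional multi-mapping assignment (1/n per location, equal split across
overlapping genes), per-library expressed-intron detection via the 80%
density rule, and RPKM over the intron-adjusted effective lengths.
"""

import pandas as pd

from _common import RESULTS, SCRATCH, ensure_dirs, load_fixture
from devtx.counting import (
    GenomeIndex,
    assign_reads,
    build_expression_matrix,
    final_counts_matrix,
    intergenic_rpkm,
    read_alignment_tsv,
)


def main() -> None:
    ensure_dirs()
    manifest, annotation, _, _ = load_fixture()
    index = GenomeIndex(annotation)

    tables, rows = [], []
    for stage, fname in manifest["alignments"].items():
        ct = assign_reads(
            read_alignment_tsv(SCRATCH / fname), annotation, stage=stage, index=index
        )
        tables.append(ct)
        rows.append(
            {
                "stage": stage,
                "retained_weight": round(ct.retained_weight, 3),
                "intergenic_weight": round(ct.intergenic_total, 3),
                "unassigned_weight": round(ct.unassigned, 3),
                "conservation_residual": abs(ct.total_counted - ct.retained_weight),
            }
        )

    matrix = build_expression_matrix(tables, annotation)
    matrix.rpkm.to_csv(SCRATCH / "rpkm.tsv", sep="\t")
    matrix.effective_lengths.to_csv(SCRATCH / "effective_lengths.tsv", sep="\t")
    matrix.library_totals.rename("total").to_csv(SCRATCH / "library_totals.tsv", sep="\t")
    final_counts_matrix(tables, annotation).to_csv(SCRATCH / "final_counts.tsv", sep="\t")

    inter = index.intergenic
    bg = pd.DataFrame(
        {ct.stage: pd.Series(intergenic_rpkm(ct, inter)) for ct in tables}
    )
    bg.to_csv(SCRATCH / "intergenic_rpkm.tsv", sep="\t", index=False)

    summary = pd.DataFrame(rows).set_index("stage")
    summary["expressed_introns"] = [
        sum(len(v) for v in matrix.expressed_introns[s].values()) for s in summary.index
    ]
    summary.to_csv(RESULTS / "02_counting_summary.tsv", sep="\t")
    print(summary)


if __name__ == "__main__":
    main()
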