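"""Estimate the expression threshold and call expressed/activated genes.

Fits the background Gaussian to intergenic RPKM and the two-component
mixture to the pooled late-stage (last five libraries) gene RPKM in log2
space; the equal-density boundary is the expression threshold.  Applies
strict RPKM-above-threshold calls per stage and converts activation /
inactivation events into per-minute rates using stage onset times (hpf).
"""

import json

import numpy as np
import pandas as pd

from _common import RESULTS, SCRATCH, SEED, ensure_dirs, load_rpkm
from devtx.simulate import STAGE_ONSET_HOURS
from devtx.threshold import (
    activation_events,
    activation_rates,
    call_expressed,
    estimate_threshold,
)

N_LATE_STAGES = 5


def main() -> None:
    ensure_dirs()
    rpkm = load_rpkm()
    intergenic = pd.read_csv(SCRATCH / "intergenic_rpkm.tsv", sep="\t")

    late = rpkm.iloc[:, -N_LATE_STAGES:].to_numpy().ravel()
    model = estimate_threshold(late, intergenic.to_numpy().ravel(), seed=SEED)
    print(f"threshold: {model.threshold_rpkm:.4f} RPKM "
          f"(log2 boundary {model.threshold_log2:.3f}, "
          f"background N({model.background_mean:.2f}, {model.background_sd:.2f}))")

    calls = call_expressed(rpkm, model.threshold_rpkm)
    calls.to_csv(SCRATCH / "expressed_calls.tsv", sep="\t")
    events = activation_events(calls)
    rates = activation_rates(events.counts(), STAGE_ONSET_HOURS, stage_order=list(rpkm.columns))
    out = events.counts().join(rates)
    out.insert(0, "expressed_at_current", [int(calls[t.split("->")[1]].sum()) for t in out.index])
    out.to_csv(RESULTS / "03_activation_rates.tsv", sep="\t")

    with open(RESULTS / "03_threshold.json", "w") as handle:
        json.dump(
            {
                "threshold_rpkm": model.threshold_rpkm,
                "threshold_log2": model.threshold_log2,
                "background_mean": model.background_mean,
                "background_sd": model.background_sd,
                "background_weight": model.background_weight,
                "expressed_mean": model.expressed_mean,
                "expressed_sd": model.expressed_sd,
                "expressed_genes_per_stage": {
                    s: int(calls[s].sum()) for s in calls.columns
                },
            },
            handle,
            indent=2,
        )
    print(out)


if __name__ == "__main__":
    main()
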