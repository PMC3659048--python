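"""Shared paths and loaders for the numbered analysis drivers.

The drivers form a pipeline: 01 writes a study-scale synthetic fixture under
``scratch/pipeline`` (large, regenerable), later steps read it and drop
small summary tables under ``results/``.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"
SEED = 1

STAGE_FILES = "alignments_{stage}.tsv"


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)


def load_fixture():
    import json

    from devtx.annotation import load_annotation

    manifest = json.loads((SCRATCH / "manifest.json").read_text())
    annotation = load_annotation(SCRATCH / manifest["annotation"])
    truth_rpkm = pd.read_csv(SCRATCH / "true_rpkm.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(SCRATCH / "true_labels.tsv", sep="\t", index_col=0)["label"]
    return manifest, annotation, truth_rpkm, labels


def load_rpkm():
    return pd.read_csv(SCRATCH / "rpkm.tsv", sep="\t", index_col=0)


def load_counts():
    return pd.read_csv(SCRATCH / "final_counts.tsv", sep="\t", index_col=0)


def load_totals():
    return pd.read_csv(SCRATCH / "library_totals.tsv", sep="\t", index_col=0)["total"]
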