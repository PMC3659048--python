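"""Synthetic stage-structured RNA-seq data with known ground truth.

The generator emulates the statistical structure of a 9-stage developmental
RNA-seq design so that every pipeline stage can be exercised end to end
without external data:

* a genome annotation with multi-exon gene models laid out without overlap
  on a handful of chromosomes, written as GFF3;
* ground-truth expression programs built from six trajectory archetypes —
  maternal-high-then-moderate, maternal-high-then-off, gastrula/segmentation
  peak, early-activated-sustained, late-activated, larval-only — plus a
  never-expressed background class whose near-zero early-stage signal makes
  the early log-RPKM distribution bimodal while late stages are unimodal;
* per-stage alignment location tables: per-gene read counts are Poisson
  with mean inverted from the RPKM definition, read positions are uniform
  over the exon union (plus truly expressed introns), a configurable
  fraction of reads receive 2-9 decoy alignment locations placed in
  intergenic space, and intergenic noise reads provide the background the
  threshold fit estimates.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, intergenic_regions
from .intervals import GenomicInterval

ZEBRAFISH_STAGES: Tuple[str, ...] = (
    "64c", "oblong", "epi50", "som15", "36h", "48h", "60h", "72h", "1wk",
)

#: approximate onset of each stage in hours post-fertilization
STAGE_ONSET_HOURS: Dict[str, float] = {
    "64c": 1.5,
    "oblong": 3.6,
    "epi50": 5.25,
    "som15": 17.0,
    "36h": 36.0,
    "48h": 48.0,
    "60h": 60.0,
    "72h": 72.0,
    "1wk": 168.0,
}

#: trajectory archetypes in RPKM units; entries < 1 are "off" states
ARCHETYPES: Dict[str, Tuple[float, ...]] = {
    "maternal_sustained": (60, 60, 25, 10, 6, 5, 5, 5, 5),
    "maternal_off": (40, 35, 8, 0.6, 0.08, 0.05, 0.05, 0.05, 0.05),
    "gastrula_peak": (0.05, 0.5, 12, 30, 8, 3, 2, 2, 2),
    "early_sustained": (0.05, 0.3, 6, 15, 20, 22, 22, 22, 22),
    "late_activated": (0.05, 0.05, 0.1, 0.5, 4, 12, 18, 22, 25),
    "larval_only": (0.05, 0.05, 0.05, 0.05, 0.1, 0.2, 0.5, 2, 20),
}

EXPRESSED_TEMPLATE_MIN = 1.0   # template RPKM above which a state is truly "on"


@dataclass
class SimulationConfig:
    """Study-emulating defaults for the synthetic 9-stage design."""

    n_genes: int = 2000
    stages: Tuple[str, ...] = ZEBRAFISH_STAGES
    stage_onset_hours: Mapping[str, float] = field(default_factory=lambda: dict(STAGE_ONSET_HOURS))
    n_chromosomes: int = 4
    # gene-structure distributions
    mean_exons_per_gene: float = 4.0
    exon_length_log_mean: float = np.log(250.0)
    exon_length_log_sd: float = 0.6
    exon_length_min: int = 80
    exon_length_max: int = 3000
    intron_length_log_mean: float = np.log(700.0)
    intron_length_log_sd: float = 0.7
    intron_length_min: int = 60
    intron_length_max: int = 10000
    intergenic_gap_min: int = 2000
    intergenic_gap_max: int = 8000
    # expression program
    background_fraction: float = 0.2
    archetype_proportions: Optional[Mapping[str, float]] = None  # default: equal
    scale_log2_sd: float = 0.8
    noise_log2_sd: float = 0.25
    background_leak_rpkm: float = 0.02
    background_leak_log2_sd: float = 2.0
    expressed_intron_prob: float = 0.1
    #: fraction of genes planted as preferential for each stage
    preferential_fraction_per_stage: float = 0.0025
    preferential_base_rpkm: float = 4.0
    preferential_fold: float = 8.0
    # sequencing
    library_size: int = 1_000_000
    read_length: int = 50
    multi_map_fraction: float = 0.15
    multi_map_max_locations: int = 9
    #: fraction of intergenic regions acting as repeat-like decoy zones for
    #: multi-mapper locations; keeps the bulk intergenic background at the
    #: configured noise rate, as real multireads concentrate in repeats
    decoy_region_fraction: float = 0.02
    intergenic_noise_rpkm: float = 0.05
    #: optional gamma-Poisson over-dispersion for gene counts: variance
    #: lambda + dispersion * lambda^2 (None = pure Poisson)
    nb_dispersion: Optional[float] = None
    flank: int = 500

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.library_size <= 0:
            raise ValueError("n_genes and library_size must be positive")
        if not 0 <= self.background_fraction <= 1:
            raise ValueError("background_fraction must be in [0, 1]")
        props = self.archetype_proportions
        if props is not None and sum(props.values()) > 1 + 1e-9:
            raise ValueError("archetype proportions must sum to at most 1")

    @classmethod
    def small(cls, **overrides) -> "SimulationConfig":
        """A light fixture-sized configuration (200 genes, 100k reads/stage)."""
        defaults = dict(n_genes=200, library_size=100_000, n_chromosomes=2)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def n_stages(self) -> int:
        return len(self.stages)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    labels: pd.Series                    # gene -> archetype / 'background' / 'pref_<stage>'
    true_rpkm: pd.DataFrame              # gene x stage
    true_expressed: pd.DataFrame         # gene x stage bool
    expressed_introns: Dict[str, Set[int]]
    preferred_stage: pd.Series           # gene -> stage label or None


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SimulationConfig, seed: int) -> GenomeAnnotation:
    """Draw non-overlapping gene models and return the annotation."""
    rng = np.random.default_rng(seed)
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chromosomes)}
    chroms = list(cursors)
    genes: Dict[str, GeneModel] = {}
    width = len(str(config.n_genes))
    for i in range(config.n_genes):
        gene_id = f"gene{i + 1:0{width}d}"
        chrom = chroms[i % len(chroms)]
        gap = int(rng.integers(config.intergenic_gap_min, config.intergenic_gap_max + 1))
        start = cursors[chrom] + gap
        n_exons = 1 + int(rng.poisson(max(config.mean_exons_per_gene - 1, 0)))
        exon_lens = np.clip(
            rng.lognormal(config.exon_length_log_mean, config.exon_length_log_sd, n_exons),
            config.exon_length_min,
            config.exon_length_max,
        ).astype(int)
        intron_lens = np.clip(
            rng.lognormal(config.intron_length_log_mean, config.intron_length_log_sd, max(n_exons - 1, 0)),
            config.intron_length_min,
            config.intron_length_max,
        ).astype(int)
        strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for j, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(chrom, pos, pos + int(elen), strand))
            pos += int(elen)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        genes[gene_id] = GeneModel(gene_id, chrom, strand, exons)
        cursors[chrom] = pos
    lengths = {
        chrom: cursor + int(rng.integers(config.intergenic_gap_min, config.intergenic_gap_max + 1))
        for chrom, cursor in cursors.items()
    }
    return GenomeAnnotation(genes=genes, chromosome_lengths=lengths)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> Path:
    """Write the annotation as GFF3 (1-based closed, sequence-region pragmas)."""
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for chrom in sorted(annotation.chromosome_lengths):
            handle.write(
                f"##sequence-region {chrom} 1 {annotation.chromosome_lengths[chrom]}\n"
            )
        for gene in annotation.genes.values():
            span = gene.span
            base = (
                f"{gene.chromosome}\tdevtx\t{{kind}}\t{{start}}\t{{end}}\t.\t{gene.strand}\t.\t"
            )
            handle.write(
                base.format(kind="gene", start=span.start + 1, end=span.end)
                + f"ID={gene.gene_id}\n"
            )
            handle.write(
                base.format(kind="mRNA", start=span.start + 1, end=span.end)
                + f"ID={gene.gene_id}.t1;Parent={gene.gene_id}\n"
            )
            for i, exon in enumerate(sorted(gene.exons, key=lambda e: e.start)):
                handle.write(
                    base.format(kind="exon", start=exon.start + 1, end=exon.end)
                    + f"ID={gene.gene_id}.e{i + 1};Parent={gene.gene_id}.t1\n"
                )
    return path


# ---------------------------------------------------------------------------
# expression programs


def simulate_expression(
    config: SimulationConfig, seed: int, annotation: Optional[GenomeAnnotation] = None
) -> GroundTruth:
    """Assign archetypes and draw the true RPKM matrix.

    Each non-background gene gets an archetype template scaled by a
    gene-specific log-normal factor with multiplicative log-normal noise per
    stage; background genes get a low "leak" level at every stage.  Planted
    stage-preferential genes (if configured) are flat with one boosted stage.
    """
    rng = np.random.default_rng(seed)
    stages = list(config.stages)
    width = len(str(config.n_genes))
    gene_ids = [f"gene{i + 1:0{width}d}" for i in range(config.n_genes)]

    n_background = int(round(config.background_fraction * config.n_genes))
    n_pref_per_stage = int(round(config.preferential_fraction_per_stage * config.n_genes))
    n_pref_total = n_pref_per_stage * len(stages)
    n_regular = config.n_genes - n_background - n_pref_total
    if n_regular < 0:
        raise ValueError("background + preferential genes exceed n_genes")

    names = list(ARCHETYPES)
    props = config.archetype_proportions or {name: 1 / len(names) for name in names}
    labels: List[str] = []
    for name in names:
        labels.extend([name] * int(round(props.get(name, 0) * n_regular)))
    while len(labels) < n_regular:
        labels.append(names[len(labels) % len(names)])
    labels = labels[:n_regular]
    for s in stages:
        labels.extend([f"pref_{s}"] * n_pref_per_stage)
    labels.extend(["background"] * (config.n_genes - len(labels)))
    labels = list(rng.permutation(np.array(labels, dtype=object)))

    rpkm = np.empty((config.n_genes, len(stages)))
    expressed = np.zeros((config.n_genes, len(stages)), dtype=bool)
    preferred: List[Optional[str]] = []
    noise = 2.0 ** rng.normal(0.0, config.noise_log2_sd, size=rpkm.shape)
    for i, label in enumerate(labels):
        if label == "background":
            leak = config.background_leak_rpkm * 2.0 ** rng.normal(
                0.0, config.background_leak_log2_sd
            )
            rpkm[i] = leak
            preferred.append(None)
        elif label.startswith("pref_"):
            stage = label[len("pref_"):]
            template = np.full(len(stages), config.preferential_base_rpkm)
            template[stages.index(stage)] *= config.preferential_fold
            rpkm[i] = template
            expressed[i] = True
            preferred.append(stage)
        else:
            template = np.array(ARCHETYPES[label])
            scale = 2.0 ** rng.normal(0.0, config.scale_log2_sd)
            on = template > EXPRESSED_TEMPLATE_MIN
            # silent states show only background-level signal, not a scaled
            # copy of the template floor
            leak = config.background_leak_rpkm * 2.0 ** rng.normal(
                0.0, config.background_leak_log2_sd, size=len(stages)
            )
            rpkm[i] = np.where(on, template * scale, leak)
            expressed[i] = on
            preferred.append(None)
    rpkm *= noise

    expressed_introns: Dict[str, Set[int]] = {}
    if annotation is not None:
        gene_pos = {g: i for i, g in enumerate(gene_ids)}
        for gene_id, gene in annotation.genes.items():
            idx = gene_pos.get(gene_id)
            flagged: Set[int] = set()
            if idx is not None and labels[idx] != "background":
                for j in range(len(gene.introns)):
                    if rng.random() < config.expressed_intron_prob:
                        flagged.add(j)
            expressed_introns[gene_id] = flagged

    return GroundTruth(
        labels=pd.Series(labels, index=gene_ids, name="label"),
        true_rpkm=pd.DataFrame(rpkm, index=gene_ids, columns=stages),
        true_expressed=pd.DataFrame(expressed, index=gene_ids, columns=stages),
        expressed_introns=expressed_introns,
        preferred_stage=pd.Series(preferred, index=gene_ids, name="preferred_stage"),
    )


# ---------------------------------------------------------------------------
# alignments


def _blocks_for_gene(
    gene: GeneModel, expressed_introns: Set[int]
) -> Tuple[np.ndarray, np.ndarray]:
    ivs = list(gene.exon_union) + [gene.introns[j] for j in sorted(expressed_introns)]
    ivs.sort(key=lambda iv: iv.start)
    return (
        np.array([iv.start for iv in ivs], dtype=np.int64),
        np.array([iv.end for iv in ivs], dtype=np.int64),
    )


def _sample_positions(
    rng: np.random.Generator,
    starts: np.ndarray,
    ends: np.ndarray,
    n: int,
    read_length: int,
) -> np.ndarray:
    """Uniform read start positions over blocks, never crossing block edges."""
    avail = np.maximum(ends - starts - read_length + 1, 0)
    if avail.sum() == 0:  # every block shorter than a read: clamp inside blocks
        avail = ends - starts
    cum = np.cumsum(avail)
    u = rng.integers(0, cum[-1], size=n)
    block = np.searchsorted(cum, u, side="right")
    offset = u - np.concatenate(([0], cum[:-1]))[block]
    return starts[block] + offset


def simulate_alignments(
    truth: GroundTruth,
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    seed: int,
) -> Dict[str, pd.DataFrame]:
    """Per-stage alignment location tables (read_id, chrom, start, end, n_locations).

    Gene read counts are Poisson with mean ``RPKM x effective_length/1000 x
    library_size/1e6``; the effective length covers the exon union plus the
    truly expressed introns, where reads are placed uniformly.  A fraction of
    reads is duplicated to 2-9 locations with the decoys placed uniformly in
    intergenic space, and intergenic noise reads are added at the configured
    background RPKM.
    """
    rng = np.random.default_rng(seed)
    stages = list(config.stages)
    read_len = config.read_length
    intergenic = intergenic_regions(annotation, config.flank)
    ig_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intergenic:
        ig_by_chrom.setdefault(iv.chromosome, []).append(iv)

    gene_blocks = {}
    eff_len = {}
    for gene_id, gene in annotation.genes.items():
        starts, ends = _blocks_for_gene(gene, truth.expressed_introns.get(gene_id, set()))
        gene_blocks[gene_id] = (starts, ends)
        eff_len[gene_id] = int((ends - starts).sum())

    chrom_code = {c: i for i, c in enumerate(sorted(annotation.chromosome_lengths))}
    chrom_names = np.array(sorted(annotation.chromosome_lengths))

    # repeat-like decoy zones, fixed for the whole data set
    usable = [
        i for i, iv in enumerate(intergenic) if iv.length > read_len
    ]
    n_zones = max(1, int(round(config.decoy_region_fraction * len(usable))))
    zones = rng.choice(usable, size=min(n_zones, len(usable)), replace=False)
    zone_ivs = [intergenic[i] for i in zones]

    out: Dict[str, pd.DataFrame] = {}
    for stage in stages:
        chunks_chrom, chunks_start, chunks_nloc = [], [], []
        for gene_id, gene in annotation.genes.items():
            lam = (
                truth.true_rpkm.at[gene_id, stage]
                * (eff_len[gene_id] / 1e3)
                * (config.library_size / 1e6)
            )
            if lam > 0 and config.nb_dispersion:
                lam = rng.gamma(1 / config.nb_dispersion, config.nb_dispersion * lam)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            starts, ends = gene_blocks[gene_id]
            pos = _sample_positions(rng, starts, ends, n, read_len)
            chunks_chrom.append(np.full(n, chrom_code[gene.chromosome], dtype=np.int32))
            chunks_start.append(pos)
            chunks_nloc.append(np.ones(n, dtype=np.int64))

        # intergenic noise reads
        for chrom, regions in ig_by_chrom.items():
            for iv in regions:
                if iv.length < read_len:
                    continue
                lam = (
                    config.intergenic_noise_rpkm
                    * (iv.length / 1e3)
                    * (config.library_size / 1e6)
                )
                n = int(rng.poisson(lam)) if lam > 0 else 0
                if n == 0:
                    continue
                pos = iv.start + rng.integers(0, iv.length - read_len + 1, size=n)
                chunks_chrom.append(np.full(n, chrom_code[chrom], dtype=np.int32))
                chunks_start.append(pos.astype(np.int64))
                chunks_nloc.append(np.ones(n, dtype=np.int64))

        chrom = np.concatenate(chunks_chrom) if chunks_chrom else np.zeros(0, dtype=np.int32)
        start = np.concatenate(chunks_start) if chunks_start else np.zeros(0, dtype=np.int64)
        n_loc = np.concatenate(chunks_nloc) if chunks_nloc else np.zeros(0, dtype=np.int64)
        read_id = np.arange(len(start), dtype=np.int64)

        # multi-mapping: duplicate a fraction of reads onto intergenic decoys
        mm = rng.random(len(start)) < config.multi_map_fraction
        if mm.any():
            k = rng.integers(2, config.multi_map_max_locations + 1, size=int(mm.sum()))
            n_loc = n_loc.copy()
            n_loc[mm] = k
            n_decoys = int((k - 1).sum())
            ig_lens = np.array([iv.length - read_len for iv in zone_ivs], dtype=np.int64)
            ig_starts = np.array([iv.start for iv in zone_ivs], dtype=np.int64)
            ig_chroms = np.array(
                [chrom_code[iv.chromosome] for iv in zone_ivs], dtype=np.int32
            )
            cum = np.cumsum(ig_lens)
            u = rng.integers(0, cum[-1], size=n_decoys)
            region = np.searchsorted(cum, u, side="right")
            offset = u - np.concatenate(([0], cum[:-1]))[region]
            decoy_start = ig_starts[region] + offset
            decoy_chrom = ig_chroms[region]
            decoy_id = np.repeat(read_id[mm], k - 1)
            decoy_nloc = np.repeat(k, k - 1)
            chrom = np.concatenate([chrom, decoy_chrom])
            start = np.concatenate([start, decoy_start])
            n_loc = np.concatenate([n_loc, decoy_nloc])
            read_id = np.concatenate([read_id, decoy_id])

        out[stage] = pd.DataFrame(
            {
                "read_id": read_id,
                "chrom": chrom_names[chrom],
                "start": start,
                "end": start + read_len,
                "n_locations": n_loc,
            }
        )
    return out


# ---------------------------------------------------------------------------
# counts-level cohorts (for error-control and recovery studies)


def planted_preferential_counts(
    n_flat: int = 900,
    n_planted: int = 100,
    stages: Sequence[str] = ZEBRAFISH_STAGES,
    base_count: float = 200.0,
    fold: float = 8.0,
    library_size: int = 1_000_000,
    effective_length: int = 1000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series, pd.DataFrame, pd.Series]:
    """A counts-level cohort with stage-preferential genes planted among flat ones.

    Returns (counts, library_totals, rpkm, truth) where ``truth`` maps each
    gene to its planted preferred stage (None for flat genes).  Planted genes
    are boosted ``fold``-fold at one stage (round-robin over stages); all
    genes share one effective length so RPKM is proportional to counts.
    """
    rng = np.random.default_rng(seed)
    stages = list(stages)
    genes = [f"flat{i + 1:04d}" for i in range(n_flat)] + [
        f"pref{i + 1:04d}" for i in range(n_planted)
    ]
    lam = np.full((n_flat + n_planted, len(stages)), base_count)
    preferred: List[Optional[str]] = [None] * n_flat
    for i in range(n_planted):
        stage = stages[i % len(stages)]
        lam[n_flat + i, stages.index(stage)] *= fold
        preferred.append(stage)
    counts = pd.DataFrame(rng.poisson(lam), index=genes, columns=stages, dtype=float)
    totals = pd.Series(float(library_size), index=stages)
    rpkm = counts / ((effective_length / 1e3) * (library_size / 1e6))
    return counts, totals, rpkm, pd.Series(preferred, index=genes, name="preferred_stage")


def null_de_counts(
    n_genes: int = 2000,
    expected_count: float = 100.0,
    library_size: int = 1_000_000,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Two libraries with identical Poisson rates for every gene (pure null)."""
    rng = np.random.default_rng(seed)
    genes = [f"null{i + 1:05d}" for i in range(n_genes)]
    counts = pd.DataFrame(
        rng.poisson(expected_count, size=(n_genes, 2)).astype(float),
        index=genes,
        columns=["A", "B"],
    )
    return counts, pd.Series(float(library_size), index=["A", "B"])


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(config: SimulationConfig, out_dir: str | Path, seed: int) -> dict:
    """Generate and write a complete fixture; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config, seed)
    truth = simulate_expression(config, seed + 1, annotation=annotation)
    alignments = simulate_alignments(truth, annotation, config, seed + 2)

    gff = write_gff3(annotation, out_dir / "annotation.gff3")
    stage_files = {}
    for stage, df in alignments.items():
        p = out_dir / f"alignments_{stage}.tsv"
        df.to_csv(p, sep="\t", header=False, index=False)
        stage_files[stage] = p.name
    truth.true_rpkm.to_csv(out_dir / "true_rpkm.tsv", sep="\t")
    truth.labels.to_frame().join(truth.preferred_stage).to_csv(
        out_dir / "true_labels.tsv", sep="\t"
    )
    truth.true_expressed.to_csv(out_dir / "true_expressed.tsv", sep="\t")

    cfg = asdict(config)
    cfg["stage_onset_hours"] = dict(cfg["stage_onset_hours"])
    manifest = {
        "seed": seed,
        "config": cfg,
        "annotation": gff.name,
        "alignments": stage_files,
        "truth": ["true_rpkm.tsv", "true_labels.tsv", "true_expressed.tsv"],
    }
    with open(out_dir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=str)
    return manifest
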