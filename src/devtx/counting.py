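"""Fractional read-to-gene assignment, expressed-intron detection and RPKM.

Counting rules
--------------
* Reads with more than ``max_locations`` (default 9) reported alignment
  locations are discarded; a retained read carries total weight 1 split
  equally over its locations (1/n each).
* A location overlapping an intron of a gene by more than
  ``intron_overlap_min`` nt (default 10, strict) is intron-originated and
  credits that intron; otherwise a location whose non-exonic overlap is at
  most ``intron_overlap_min`` nt (i.e. exon overlap of at least
  ``read_length − intron_overlap_min``) credits the gene's exon count.
* A location crediting several overlapping genes splits its share equally
  among them; a location fully inside an intergenic region credits the
  intergenic background; anything else (flank buffers, marginal overlaps)
  goes to an explicit unassigned sink so that weight is conserved exactly.

An intron is "potentially expressed" when its per-base read density exceeds
80% of the gene's exonic per-base density; expressed-intron reads are folded
into the gene's final count and the intron lengths into its effective
length, so RPKM is computed per library over exons plus expressed introns.

The classifier pre-computes, per chromosome, the elementary segmentation
induced by all exon-union blocks, introns and intergenic regions.  A read
fully inside one segment (the overwhelming majority for short reads) is
resolved by a table lookup, vectorized over reads; reads spanning segment
boundaries fall back to an explicit per-read overlap computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotation import DEFAULT_FLANK, GenomeAnnotation, intergenic_regions
from .intervals import GenomicInterval, overlap_length

DEFAULT_MAX_LOCATIONS = 9
DEFAULT_INTRON_OVERLAP_MIN = 10
MIN_INTERGENIC_LENGTH = 200


@dataclass
class AlignmentRecord:
    """All reported alignment locations of one read."""

    read_id: str
    locations: List[GenomicInterval]

    @property
    def n_locations(self) -> int:
        return len(self.locations)


@dataclass
class CountTable:
    """Fractional counts for one library (one developmental stage)."""

    stage: str
    gene_ids: List[str]
    exon_counts: np.ndarray                     # (n_genes,)
    intron_counts: Dict[str, np.ndarray]        # gene_id -> (n_introns,)
    intergenic_region_counts: np.ndarray        # one entry per intergenic region
    unassigned: float
    retained_weight: float
    n_skipped: int = 0

    @property
    def intergenic_total(self) -> float:
        return float(self.intergenic_region_counts.sum())

    @property
    def intron_total(self) -> float:
        return float(sum(v.sum() for v in self.intron_counts.values()))

    @property
    def total_counted(self) -> float:
        """Sum over every sink; equals ``retained_weight`` up to float error."""
        return (
            float(self.exon_counts.sum())
            + self.intron_total
            + self.intergenic_total
            + self.unassigned
        )

    def exon_series(self) -> pd.Series:
        return pd.Series(self.exon_counts, index=self.gene_ids, name=self.stage)


@dataclass
class ExpressionMatrix:
    """RPKM values (genes x stages) with the effective lengths behind them."""

    rpkm: pd.DataFrame
    effective_lengths: pd.DataFrame
    library_totals: pd.Series
    expressed_introns: Dict[str, Dict[str, Set[int]]]  # stage -> gene -> intron idx

    @property
    def stages(self) -> List[str]:
        return list(self.rpkm.columns)

    @property
    def gene_ids(self) -> List[str]:
        return list(self.rpkm.index)


# ---------------------------------------------------------------------------
# classifier index


class GenomeIndex:
    """Per-chromosome elementary segmentation used by :func:`assign_reads`."""

    def __init__(self, annotation: GenomeAnnotation, flank: int = DEFAULT_FLANK):
        self.annotation = annotation
        self.flank = flank
        self.gene_ids = annotation.gene_ids
        self.n_genes = len(self.gene_ids)
        gene_index = {g: i for i, g in enumerate(self.gene_ids)}

        # flat sink layout: [0, G) exon counts, [G, G+I) intron counts,
        # then one intergenic and one unassigned slot
        self.intron_offsets = np.zeros(self.n_genes + 1, dtype=np.int64)
        for gid, g in enumerate(annotation.genes.values()):
            self.intron_offsets[gid + 1] = self.intron_offsets[gid] + len(g.introns)
        self.n_introns = int(self.intron_offsets[-1])
        self.intergenic_sink = self.n_genes + self.n_introns
        self.unassigned_sink = self.intergenic_sink + 1
        self.n_sinks = self.unassigned_sink + 1

        self.intergenic = intergenic_regions(annotation, flank)

        # per-gene block arrays for the spanning-read path
        self._gene_blocks: List[Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
        for g in annotation.genes.values():
            ex_s = np.array([iv.start for iv in g.exon_union], dtype=np.int64)
            ex_e = np.array([iv.end for iv in g.exon_union], dtype=np.int64)
            in_s = np.array([iv.start for iv in g.introns], dtype=np.int64)
            in_e = np.array([iv.end for iv in g.introns], dtype=np.int64)
            self._gene_blocks.append((ex_s, ex_e, in_s, in_e))

        # build elementary segments per chromosome
        self._chrom: Dict[str, dict] = {}
        feats: Dict[str, List[Tuple[int, int, Tuple]]] = {
            c: [] for c in annotation.chromosome_lengths
        }
        for gid, g in enumerate(annotation.genes.values()):
            for iv in g.exon_union:
                feats[g.chromosome].append((iv.start, iv.end, ("E", gid)))
            for j, iv in enumerate(g.introns):
                feats[g.chromosome].append((iv.start, iv.end, ("I", gid, j)))
        for r, iv in enumerate(self.intergenic):
            feats[iv.chromosome].append((iv.start, iv.end, ("G", r)))

        for chrom, items in feats.items():
            clen = annotation.chromosome_lengths[chrom]
            cuts = {0, clen}
            for s, e, _ in items:
                cuts.add(s)
                cuts.add(e)
            bounds = np.array(sorted(cuts), dtype=np.int64)
            n_segs = len(bounds) - 1
            active: List[List[Tuple]] = [[] for _ in range(n_segs)]
            left = np.searchsorted(bounds, [s for s, _, _ in items], side="left")
            right = np.searchsorted(bounds, [e for _, e, _ in items], side="left")
            for (s, e, token), i0, i1 in zip(items, left, right):
                for i in range(i0, i1):
                    active[i].append(token)

            seg_sinks: List[np.ndarray] = []
            seg_share: List[float] = []
            seg_genes: List[Tuple[int, ...]] = []
            for tokens in active:
                genes = tuple(sorted({t[1] for t in tokens if t[0] in ("E", "I")}))
                sinks = []
                for t in sorted(tokens):
                    if t[0] == "E":
                        sinks.append(t[1])
                    elif t[0] == "I":
                        sinks.append(self.n_genes + int(self.intron_offsets[t[1]]) + t[2])
                if sinks:
                    seg_sinks.append(np.array(sinks, dtype=np.int64))
                    seg_share.append(1.0 / len(sinks))
                elif any(t[0] == "G" for t in tokens):
                    seg_sinks.append(np.array([self.intergenic_sink], dtype=np.int64))
                    seg_share.append(1.0)
                else:
                    seg_sinks.append(np.array([self.unassigned_sink], dtype=np.int64))
                    seg_share.append(1.0)
                seg_genes.append(genes)

            ig = [
                (r, iv.start, iv.end)
                for r, iv in enumerate(self.intergenic)
                if iv.chromosome == chrom
            ]
            ig_region = {}
            if ig:
                starts = np.searchsorted(bounds, [s for _, s, _ in ig], side="left")
                for (r, _, _), i in zip(ig, starts):
                    ig_region[int(i)] = r
            self._chrom[chrom] = {
                "bounds": bounds,
                "sinks": seg_sinks,
                "share": np.array(seg_share),
                "genes": seg_genes,
                "ig_region": ig_region,
                "ig_starts": np.array([s for _, s, _ in ig], dtype=np.int64),
                "ig_ends": np.array([e for _, _, e in ig], dtype=np.int64),
                "ig_ids": np.array([r for r, _, _ in ig], dtype=np.int64),
            }

    def gene_intron_sink(self, gene_idx: int, intron_idx: int) -> int:
        return self.n_genes + int(self.intron_offsets[gene_idx]) + intron_idx

    def _classify_spanning(
        self, chrom_data: dict, s: int, e: int, intron_overlap_min: int
    ) -> Tuple[List[int], Optional[int]]:
        """Credits for one read via explicit per-gene overlap arithmetic."""
        bounds = chrom_data["bounds"]
        i0 = int(np.searchsorted(bounds, s, side="right")) - 1
        i1 = int(np.searchsorted(bounds, e - 1, side="right")) - 1
        i0 = max(0, min(i0, len(bounds) - 2))
        i1 = max(0, min(i1, len(bounds) - 2))
        candidates: Set[int] = set()
        for i in range(i0, i1 + 1):
            candidates.update(chrom_data["genes"][i])
        read_len = e - s
        credits: List[int] = []
        for gid in sorted(candidates):
            ex_s, ex_e, in_s, in_e = self._gene_blocks[gid]
            intron_ovl = np.maximum(
                0, np.minimum(in_e, e) - np.maximum(in_s, s)
            ) if len(in_s) else np.zeros(0, dtype=np.int64)
            if len(intron_ovl) and intron_ovl.max() > intron_overlap_min:
                credits.append(self.gene_intron_sink(gid, int(intron_ovl.argmax())))
                continue
            exon_ovl = int(np.maximum(0, np.minimum(ex_e, e) - np.maximum(ex_s, s)).sum())
            # non-exonic overlap of at most intron_overlap_min still counts as exonic
            if exon_ovl >= read_len - intron_overlap_min and exon_ovl > 0:
                credits.append(gid)
        if credits:
            return credits, None
        ig_starts = chrom_data["ig_starts"]
        if len(ig_starts):
            k = int(np.searchsorted(ig_starts, s, side="right")) - 1
            if k >= 0 and chrom_data["ig_ends"][k] >= e:
                return [], int(chrom_data["ig_ids"][k])
        return [], None


# ---------------------------------------------------------------------------
# input readers


TSV_COLUMNS = ["read_id", "chrom", "start", "end", "n_locations"]


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    """Read a BED-like location table (one row per alignment location).

    Columns: read_id, chrom, start, end, n_locations[, stage]; tab-separated,
    0-based half-open coordinates, ``#`` comment lines allowed.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] < 5:
        raise ValueError(f"{path}: expected at least 5 columns, got {df.shape[1]}")
    df = df.iloc[:, :5]
    df.columns = TSV_COLUMNS
    return df.astype({"chrom": str, "start": np.int64, "end": np.int64, "n_locations": np.int64})


def read_alignment_sam(path: str | Path) -> pd.DataFrame:
    """Read alignment locations from a SAM/BAM file.

    ``n_locations`` is taken from the NH tag when present; otherwise records
    sharing a query name are collated and counted.
    """
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for rec in handle:
            if rec.is_unmapped:
                continue
            n_loc = rec.get_tag("NH") if rec.has_tag("NH") else None
            rows.append(
                (rec.query_name, rec.reference_name, rec.reference_start, rec.reference_end, n_loc)
            )
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    if df["n_locations"].isna().any():
        counts = df.groupby("read_id")["chrom"].transform("size")
        df["n_locations"] = df["n_locations"].fillna(counts)
    return df.astype({"chrom": str, "start": np.int64, "end": np.int64, "n_locations": np.int64})


def records_to_frame(records: Iterable[AlignmentRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for loc in rec.locations:
            rows.append((rec.read_id, loc.chromosome, loc.start, loc.end, rec.n_locations))
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


# ---------------------------------------------------------------------------
# assignment


def assign_reads(
    alignments: pd.DataFrame | Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    max_locations: int = DEFAULT_MAX_LOCATIONS,
    intron_overlap_min: int = DEFAULT_INTRON_OVERLAP_MIN,
    flank: int = DEFAULT_FLANK,
    stage: str = "library",
    index: Optional[GenomeIndex] = None,
) -> CountTable:
    """Assign aligned reads to genes, introns and the intergenic background.

    ``alignments`` is a location table (see :func:`read_alignment_tsv`) or an
    iterable of :class:`AlignmentRecord`.  Reads with more than
    ``max_locations`` locations are discarded; every retained location row of
    weight ``1/n_locations`` ends in exactly one sink, so the table conserves
    weight to float precision.
    """
    if index is None:
        index = GenomeIndex(annotation, flank=flank)
    if not isinstance(alignments, pd.DataFrame):
        alignments = records_to_frame(alignments)

    df = alignments
    retained = df["n_locations"].to_numpy() <= max_locations
    df = df.loc[retained]

    flat = np.zeros(index.n_sinks)
    intergenic_counts = np.zeros(len(index.intergenic))
    n_skipped = 0
    retained_weight = 0.0

    unknown = ~df["chrom"].isin(index._chrom.keys()).to_numpy()
    if unknown.any():
        n_skipped = int(unknown.sum())
        warnings.warn(
            f"{n_skipped} alignment location(s) on unknown chromosomes were skipped",
            stacklevel=2,
        )
        df = df.loc[~unknown]

    for chrom, sub in df.groupby("chrom", sort=False):
        data = index._chrom[chrom]
        bounds = data["bounds"]
        s = sub["start"].to_numpy(dtype=np.int64)
        e = sub["end"].to_numpy(dtype=np.int64)
        w = 1.0 / sub["n_locations"].to_numpy(dtype=np.float64)
        retained_weight += float(w.sum())

        i0 = np.searchsorted(bounds, s, side="right") - 1
        in_range = (i0 >= 0) & (i0 < len(bounds) - 1) & (e <= bounds[-1])
        contained = np.zeros(len(s), dtype=bool)
        ok = in_range.nonzero()[0]
        contained[ok] = e[ok] <= bounds[i0[ok] + 1]
        fast = contained & (e - s > intron_overlap_min)

        if fast.any():
            seg_w = np.bincount(i0[fast], weights=w[fast], minlength=len(bounds) - 1)
            for seg in np.nonzero(seg_w)[0]:
                sinks = data["sinks"][seg]
                add = seg_w[seg] * data["share"][seg]
                if sinks[0] == index.intergenic_sink:
                    intergenic_counts[data["ig_region"][int(seg)]] += seg_w[seg]
                flat[sinks] += add

        slow = np.nonzero(~fast)[0]
        for i in slow:
            if not in_range[i]:
                # off-chromosome coordinates: clip into the spanning path
                pass
            credits, region = index._classify_spanning(
                data, int(s[i]), int(e[i]), intron_overlap_min
            )
            if credits:
                share = w[i] / len(credits)
                for sink in credits:
                    flat[sink] += share
            elif region is not None:
                flat[index.intergenic_sink] += w[i]
                intergenic_counts[region] += w[i]
            else:
                flat[index.unassigned_sink] += w[i]

    intron_counts = {}
    for gid, gene_id in enumerate(index.gene_ids):
        lo = index.n_genes + int(index.intron_offsets[gid])
        hi = index.n_genes + int(index.intron_offsets[gid + 1])
        intron_counts[gene_id] = flat[lo:hi].copy()

    return CountTable(
        stage=stage,
        gene_ids=index.gene_ids,
        exon_counts=flat[: index.n_genes].copy(),
        intron_counts=intron_counts,
        intergenic_region_counts=intergenic_counts,
        unassigned=float(flat[index.unassigned_sink]),
        retained_weight=retained_weight,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# expressed introns, final counts, RPKM


def detect_expressed_introns(
    counts: CountTable,
    annotation: GenomeAnnotation,
    fraction: float = 0.8,
) -> Dict[str, Set[int]]:
    """Introns whose per-base density exceeds ``fraction`` of the exon density.

    Intron *i* of gene *g* is potentially expressed iff
    ``intron_count_i / intron_length_i > fraction * exon_count_g / exon_union_length_g``
    (strict).  Genes with zero exon count have no expressed introns.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    expressed: Dict[str, Set[int]] = {}
    gene_pos = {g: i for i, g in enumerate(counts.gene_ids)}
    for gene_id, gene in annotation.genes.items():
        exon_count = counts.exon_counts[gene_pos[gene_id]]
        flagged: Set[int] = set()
        if exon_count > 0 and gene.introns:
            exon_density = exon_count / gene.exon_union_length
            ic = counts.intron_counts[gene_id]
            for j, intron in enumerate(gene.introns):
                if ic[j] / intron.length > fraction * exon_density:
                    flagged.add(j)
        expressed[gene_id] = flagged
    return expressed


def final_gene_counts(
    counts: CountTable, expressed_introns: Mapping[str, Set[int]]
) -> pd.Series:
    """Exon count plus the counts of the gene's expressed introns."""
    values = counts.exon_counts.copy()
    for i, gene_id in enumerate(counts.gene_ids):
        for j in expressed_introns.get(gene_id, ()):  # non-expressed introns excluded
            values[i] += counts.intron_counts[gene_id][j]
    return pd.Series(values, index=counts.gene_ids, name=counts.stage)


def effective_lengths(
    annotation: GenomeAnnotation, expressed_introns: Mapping[str, Set[int]]
) -> pd.Series:
    """Exon-union length plus the lengths of expressed introns, per gene."""
    out = {}
    for gene_id, gene in annotation.genes.items():
        length = gene.exon_union_length
        for j in expressed_introns.get(gene_id, ()):
            length += gene.introns[j].length
        out[gene_id] = length
    return pd.Series(out, name="effective_length")


def rpkm(count: float, effective_length: float, library_total: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if effective_length <= 0:
        raise ValueError(f"effective length must be positive, got {effective_length}")
    if library_total <= 0:
        raise ValueError(f"library total must be positive, got {library_total}")
    return count / ((effective_length / 1e3) * (library_total / 1e6))


def intergenic_rpkm(
    counts: CountTable,
    intergenic: Sequence[GenomicInterval],
    min_length: int = MIN_INTERGENIC_LENGTH,
) -> np.ndarray:
    """Per-region RPKM of the intergenic background (short regions skipped)."""
    lengths = np.array([iv.length for iv in intergenic], dtype=float)
    keep = lengths >= min_length
    values = counts.intergenic_region_counts[keep] / (
        (lengths[keep] / 1e3) * (counts.retained_weight / 1e6)
    )
    return values


def build_expression_matrix(
    count_tables: Sequence[CountTable],
    annotation: GenomeAnnotation,
    fraction: float = 0.8,
) -> ExpressionMatrix:
    """Per-library expressed-intron detection, final counts and RPKM columns."""
    rpkm_cols, len_cols, totals, introns = {}, {}, {}, {}
    for ct in count_tables:
        flagged = detect_expressed_introns(ct, annotation, fraction=fraction)
        final = final_gene_counts(ct, flagged)
        eff = effective_lengths(annotation, flagged)
        rpkm_cols[ct.stage] = final / ((eff / 1e3) * (ct.retained_weight / 1e6))
        len_cols[ct.stage] = eff
        totals[ct.stage] = ct.retained_weight
        introns[ct.stage] = flagged
    return ExpressionMatrix(
        rpkm=pd.DataFrame(rpkm_cols),
        effective_lengths=pd.DataFrame(len_cols),
        library_totals=pd.Series(totals, name="library_total"),
        expressed_introns=introns,
    )


def final_counts_matrix(
    count_tables: Sequence[CountTable],
    annotation: GenomeAnnotation,
    fraction: float = 0.8,
) -> pd.DataFrame:
    """Final per-gene fractional counts, one column per stage."""
    cols = {}
    for ct in count_tables:
        flagged = detect_expressed_introns(ct, annotation, fraction=fraction)
        cols[ct.stage] = final_gene_counts(ct, flagged)
    return pd.DataFrame(cols)
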