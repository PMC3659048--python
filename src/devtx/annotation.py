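"""Gene-model geometry: exon unions, introns and intergenic regions.

Gene models are reduced to the geometry the counting pipeline needs: for
each gene the union of all annotated exons across every transcript variant
(the "joined annotated exons"), the introns as the complement of that union
within the gene span, and — genome-wide — the intergenic regions lying
further than a flank (default 500 bp) from any end of any gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import gffutils

from .intervals import GenomicInterval, complement_intervals, interval_gaps, merge_intervals

DEFAULT_FLANK = 500


@dataclass
class GeneModel:
    """One gene reduced to its strand-agnostic exon/intron geometry."""

    gene_id: str
    chromosome: str
    strand: str
    exons: List[GenomicInterval]
    exon_union: List[GenomicInterval] = field(init=False)
    introns: List[GenomicInterval] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        if any(e.chromosome != self.chromosome for e in self.exons):
            raise ValueError(f"gene {self.gene_id} has exons on several chromosomes")
        self.exon_union = merge_intervals(self.exons)
        self.introns = interval_gaps(self.exon_union)

    @property
    def span(self) -> GenomicInterval:
        """Gene span: [min exon start, max exon end)."""
        return GenomicInterval(
            self.chromosome, self.exon_union[0].start, self.exon_union[-1].end, self.strand
        )

    @property
    def exon_union_length(self) -> int:
        return sum(iv.length for iv in self.exon_union)

    @property
    def intron_lengths(self) -> List[int]:
        return [iv.length for iv in self.introns]


@dataclass
class GenomeAnnotation:
    """All gene models plus chromosome lengths, ordered by (chromosome, start)."""

    genes: Dict[str, GeneModel]
    chromosome_lengths: Dict[str, int]

    def __post_init__(self) -> None:
        ordered = sorted(
            self.genes.values(), key=lambda g: (g.chromosome, g.span.start, g.gene_id)
        )
        self.genes = {g.gene_id: g for g in ordered}
        for g in ordered:
            if g.chromosome not in self.chromosome_lengths:
                raise ValueError(
                    f"gene {g.gene_id} on unknown chromosome {g.chromosome}"
                )
            if g.span.end > self.chromosome_lengths[g.chromosome]:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of {g.chromosome}"
                )

    @property
    def gene_ids(self) -> List[str]:
        return list(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def intergenic_regions(
    annotation: GenomeAnnotation, flank: int = DEFAULT_FLANK
) -> List[GenomicInterval]:
    """Regions further than ``flank`` nt from any end of any gene span.

    The complement of the union of all gene spans extended by ``flank`` on
    both sides, clipped to chromosome bounds; zero-length pieces are dropped.
    """
    if flank < 0:
        raise ValueError(f"flank must be non-negative, got {flank}")
    extended = []
    for gene in annotation.genes.values():
        span = gene.span
        extended.append(
            GenomicInterval(
                span.chromosome,
                max(0, span.start - flank),
                min(annotation.chromosome_lengths[span.chromosome], span.end + flank),
            )
        )
    return complement_intervals(extended, annotation.chromosome_lengths)


# ---------------------------------------------------------------------------
# parsing


def _detect_dialect(path: str | Path) -> str:
    name = str(path).lower()
    if name.endswith((".gtf", ".gtf.gz")):
        return "gtf"
    return "gff3"


def load_annotation(
    path: str | Path,
    dialect: Optional[str] = None,
    chromosome_lengths: Optional[Mapping[str, int]] = None,
) -> GenomeAnnotation:
    """Parse a GFF3 or GTF file into a :class:`GenomeAnnotation`.

    Exons are pooled per gene across all transcript variants.  Gene identity
    is taken from the ``gene_id`` attribute when present (GTF) or resolved by
    climbing ``Parent`` links to a ``gene`` feature (GFF3).

    Chromosome lengths come from ``##sequence-region`` pragmas unless an
    explicit mapping is supplied; chromosomes without a stated length fall
    back to the rightmost annotated coordinate.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dialect or _detect_dialect(path)
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown annotation dialect: {dialect!r}")

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils wraps the offending line in its message
        raise ValueError(f"malformed annotation file {path}: {exc}") from exc

    lengths: Dict[str, int] = dict(chromosome_lengths or {})
    if not lengths:
        for directive in db.directives:
            parts = directive.split()
            if parts and parts[0] == "sequence-region" and len(parts) >= 4:
                # pragma is 1-based inclusive: length = end coordinate
                lengths[parts[1]] = int(parts[3])

    exons_by_gene: Dict[str, List[GenomicInterval]] = {}
    meta: Dict[str, tuple] = {}
    n_exons = 0
    for exon in db.features_of_type("exon"):
        n_exons += 1
        gene_id = None
        for key in ("gene_id", "geneID"):
            if key in exon.attributes:
                gene_id = exon.attributes[key][0]
                break
        if gene_id is None:
            parents = list(db.parents(exon, featuretype="gene"))
            if parents:
                gene_id = parents[0].attributes.get("ID", [parents[0].id])[0]
        if gene_id is None:
            raise ValueError(
                f"exon without a resolvable parent gene at "
                f"{exon.seqid}:{exon.start}-{exon.end} in {path}"
            )
        iv = GenomicInterval(exon.seqid, exon.start - 1, exon.end, exon.strand or ".")
        exons_by_gene.setdefault(gene_id, []).append(iv)
        meta.setdefault(gene_id, (exon.seqid, exon.strand or "."))
    if n_exons == 0:
        raise ValueError(f"no exon features found in {path}")

    genes = {
        gid: GeneModel(gid, meta[gid][0], meta[gid][1], ivs)
        for gid, ivs in exons_by_gene.items()
    }
    for gene in genes.values():
        lengths.setdefault(gene.chromosome, 0)
        lengths[gene.chromosome] = max(lengths[gene.chromosome], gene.span.end)
    return GenomeAnnotation(genes=genes, chromosome_lengths=lengths)


def read_chromosome_lengths(path: str | Path) -> Dict[str, int]:
    """Read a two-column TSV (chromosome, length)."""
    lengths: Dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            lengths[parts[0]] = int(parts[1])
    return lengths


# ---------------------------------------------------------------------------
# BED export


def write_bed_tracks(
    annotation: GenomeAnnotation,
    out_dir: str | Path,
    flank: int = DEFAULT_FLANK,
) -> Dict[str, Path]:
    """Write exon-union, intron and intergenic tracks as BED6 files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write(name: str, rows: Sequence[tuple]) -> None:
        p = out_dir / f"{name}.bed"
        with open(p, "w") as handle:
            for chrom, start, end, label, strand in rows:
                handle.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t{strand}\n")
        paths[name] = p

    exon_rows, intron_rows = [], []
    for gene in annotation.genes.values():
        for i, iv in enumerate(gene.exon_union):
            exon_rows.append((iv.chromosome, iv.start, iv.end, f"{gene.gene_id}.exon{i}", gene.strand))
        for i, iv in enumerate(gene.introns):
            intron_rows.append((iv.chromosome, iv.start, iv.end, f"{gene.gene_id}.intron{i}", gene.strand))
    inter_rows = [
        (iv.chromosome, iv.start, iv.end, f"intergenic{i}", ".")
        for i, iv in enumerate(intergenic_regions(annotation, flank))
    ]
    _write("exon_union", exon_rows)
    _write("introns", intron_rows)
    _write("intergenic", inter_rows)
    return paths
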