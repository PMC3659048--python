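import warnings

import numpy as np
import pandas as pd
import pytest

from devtx import counting
from devtx.annotation import GeneModel, GenomeAnnotation, intergenic_regions
from devtx.counting import (
    CountTable,
    GenomeIndex,
    assign_reads,
    build_expression_matrix,
    detect_expressed_introns,
    effective_lengths,
    final_gene_counts,
    intergenic_rpkm,
    read_alignment_tsv,
    rpkm,
)
from devtx.intervals import GenomicInterval, overlap_length
from devtx.simulate import SimulationConfig, simulate_annotation


def frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "chrom", "start", "end", "n_locations"])


def gene_pos(table, gene):
    return table.gene_ids.index(gene)


class TestAssignReads:
    def test_multi_location_equal_split(self, toy_annotation):
        # 4 locations: 2 in geneX exons, 1 in geneY exon, 1 intergenic
        rows = [
            ("r1", "chr1", 1100, 1150, 4),
            ("r1", "chr1", 1950, 2000, 4),
            ("r1", "chr1", 3100, 3150, 4),
            ("r1", "chr1", 5000, 5050, 4),
        ]
        ct = assign_reads(frame(rows), toy_annotation)
        assert ct.exon_counts[gene_pos(ct, "geneX")] == pytest.approx(0.5)
        assert ct.exon_counts[gene_pos(ct, "geneY")] == pytest.approx(0.25)
        assert ct.intergenic_total == pytest.approx(0.25)
        assert ct.retained_weight == pytest.approx(1.0)

    def test_intron_overlap_boundary(self, toy_annotation):
        # geneX intron is [1400,1900); read [1361,1411) overlaps it by 11 nt
        ct = assign_reads(frame([("r1", "chr1", 1361, 1411, 1)]), toy_annotation)
        assert ct.intron_counts["geneX"][0] == pytest.approx(1.0)
        assert ct.exon_counts[gene_pos(ct, "geneX")] == 0.0
        # read [1360,1410) overlaps the intron by exactly 10 nt: exon-assigned
        ct = assign_reads(frame([("r1", "chr1", 1360, 1410, 1)]), toy_annotation)
        assert ct.exon_counts[gene_pos(ct, "geneX")] == pytest.approx(1.0)
        assert ct.intron_counts["geneX"][0] == 0.0

    def test_more_than_max_locations_discarded(self, toy_annotation):
        rows = [("r1", "chr1", 1100 + i, 1150 + i, 10) for i in range(10)]
        ct = assign_reads(frame(rows), toy_annotation)
        assert ct.retained_weight == 0.0
        assert ct.total_counted == 0.0

    def test_overlapping_genes_split_equally(self):
        genes = {
            "gA": GeneModel("gA", "chr1", "+", [GenomicInterval("chr1", 1000, 2000)]),
            "gB": GeneModel("gB", "chr1", "-", [GenomicInterval("chr1", 1500, 2500)]),
        }
        ann = GenomeAnnotation(genes=genes, chromosome_lengths={"chr1": 10_000})
        ct = assign_reads(frame([("r1", "chr1", 1600, 1650, 1)]), ann)
        assert ct.exon_counts[gene_pos(ct, "gA")] == pytest.approx(0.5)
        assert ct.exon_counts[gene_pos(ct, "gB")] == pytest.approx(0.5)

    def test_flank_buffer_read_is_unassigned(self, toy_annotation):
        ct = assign_reads(frame([("r1", "chr1", 600, 650, 1)]), toy_annotation)
        assert ct.unassigned == pytest.approx(1.0)
        assert ct.intergenic_total == 0.0

    def test_unknown_chromosome_skipped_with_warning(self, toy_annotation):
        rows = [("r1", "chrUn", 100, 150, 1), ("r2", "chr1", 5000, 5050, 1)]
        with pytest.warns(UserWarning, match="unknown chromosome"):
            ct = assign_reads(frame(rows), toy_annotation)
        assert ct.n_skipped == 1
        assert ct.retained_weight == pytest.approx(1.0)

    def test_weight_conservation_on_simulated_reads(self, small_counts):
        _, tables = small_counts
        for ct in tables:
            assert abs(ct.total_counted - ct.retained_weight) < 1e-9

    def test_matches_brute_force_reference(self):
        """Vectorized classifier agrees with a literal per-read implementation."""
        cfg = SimulationConfig.small(n_genes=15, n_chromosomes=1)
        ann = simulate_annotation(cfg, seed=21)
        inter = intergenic_regions(ann, flank=500)
        rng = np.random.default_rng(42)
        clen = ann.chromosome_lengths["chr1"]
        # deliberately include boundary-spanning and short reads
        starts = rng.integers(0, clen - 60, size=800)
        lengths = rng.choice([5, 12, 50, 50, 50, 120], size=800)
        nloc = rng.choice([1, 1, 1, 2, 4, 9, 10], size=800)
        rows = [
            (f"r{i}", "chr1", int(s), int(s + L), int(k))
            for i, (s, L, k) in enumerate(zip(starts, lengths, nloc))
        ]
        ct = assign_reads(frame(rows), ann)

        # reference: loop every read over every gene, straight from the rules
        exon = {g: 0.0 for g in ann.genes}
        intron = {g: np.zeros(len(m.introns)) for g, m in ann.genes.items()}
        interg = 0.0
        unassigned = 0.0
        retained = 0.0
        for _, _, s, e, k in rows:
            if k > 9:
                continue
            w = 1.0 / k
            retained += w
            credits = []
            for gid, gene in ann.genes.items():
                best_ovl, best_j = 0, None
                for j, ivn in enumerate(gene.introns):
                    o = overlap_length(s, e, ivn.start, ivn.end)
                    if o > best_ovl:
                        best_ovl, best_j = o, j
                if best_ovl > 10:
                    credits.append(("intron", gid, best_j))
                    continue
                exon_ovl = sum(
                    overlap_length(s, e, b.start, b.end) for b in gene.exon_union
                )
                if exon_ovl > 0 and exon_ovl >= (e - s) - 10:
                    credits.append(("exon", gid, None))
            if credits:
                share = w / len(credits)
                for kind, gid, j in credits:
                    if kind == "exon":
                        exon[gid] += share
                    else:
                        intron[gid][j] += share
            elif any(r.start <= s and e <= r.end for r in inter):
                interg += w
            else:
                unassigned += w

        for gid in ann.genes:
            assert ct.exon_counts[gene_pos(ct, gid)] == pytest.approx(exon[gid], abs=1e-9)
            assert ct.intron_counts[gid] == pytest.approx(intron[gid], abs=1e-9)
        assert ct.intergenic_total == pytest.approx(interg, abs=1e-9)
        assert ct.unassigned == pytest.approx(unassigned, abs=1e-9)
        assert ct.retained_weight == pytest.approx(retained, abs=1e-9)

    def test_tsv_reader_round_trip(self, toy_annotation, tmp_path):
        rows = [("r1", "chr1", 1100, 1150, 1), ("r2", "chr1", 3100, 3150, 2)]
        p = tmp_path / "aln.tsv"
        frame(rows).to_csv(p, sep="\t", header=False, index=False)
        ct = assign_reads(read_alignment_tsv(p), toy_annotation)
        assert ct.exon_counts[gene_pos(ct, "geneX")] == pytest.approx(1.0)
        assert ct.exon_counts[gene_pos(ct, "geneY")] == pytest.approx(0.5)

    def test_sam_reader_matches_tsv(self, toy_annotation, tmp_path):
        sam = tmp_path / "aln.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            "r1\t0\tchr1\t1101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNH:i:1\n"
            "r2\t0\tchr1\t3101\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\tNH:i:2\n"
        )
        df = counting.read_alignment_sam(sam)
        ct = assign_reads(df, toy_annotation)
        assert ct.exon_counts[gene_pos(ct, "geneX")] == pytest.approx(1.0)
        assert ct.exon_counts[gene_pos(ct, "geneY")] == pytest.approx(0.5)


def make_table(gene_ids, exon, introns, stage="s", intergenic=(), unassigned=0.0):
    introns = {g: np.asarray(v, dtype=float) for g, v in introns.items()}
    total = sum(exon) + sum(v.sum() for v in introns.values()) + sum(intergenic) + unassigned
    return CountTable(
        stage=stage,
        gene_ids=list(gene_ids),
        exon_counts=np.array(exon, dtype=float),
        intron_counts={g: np.asarray(v, dtype=float) for g, v in introns.items()},
        intergenic_region_counts=np.array(intergenic, dtype=float),
        unassigned=unassigned,
        retained_weight=total,
    )


class TestExpressedIntrons:
    def make_gene(self):
        # exon union 1000 nt ([0,500)+[1000,1500)), intron [500,1000) of 500 nt
        gene = GeneModel(
            "g", "chr1", "+",
            [GenomicInterval("chr1", 0, 500), GenomicInterval("chr1", 1000, 1500)],
        )
        return GenomeAnnotation(genes={"g": gene}, chromosome_lengths={"chr1": 5000})

    def test_eighty_percent_rule(self):
        ann = self.make_gene()
        # exon density 100/1000 = 0.1; intron density 45/500 = 0.09 > 0.08
        ct = make_table(["g"], [100.0], {"g": [45.0]})
        assert detect_expressed_introns(ct, ann) == {"g": {0}}
        # 30/500 = 0.06 < 0.08: not expressed
        ct = make_table(["g"], [100.0], {"g": [30.0]})
        assert detect_expressed_introns(ct, ann) == {"g": set()}

    def test_zero_exon_count_gives_no_expressed_introns(self):
        ann = self.make_gene()
        ct = make_table(["g"], [0.0], {"g": [500.0]})
        assert detect_expressed_introns(ct, ann) == {"g": set()}

    def test_invalid_fraction_rejected(self):
        ann = self.make_gene()
        ct = make_table(["g"], [1.0], {"g": [0.0]})
        with pytest.raises(ValueError):
            detect_expressed_introns(ct, ann, fraction=0.0)
        with pytest.raises(ValueError):
            detect_expressed_introns(ct, ann, fraction=1.5)

    def test_matches_independent_recomputation(self, small_counts):
        annotation, tables = small_counts
        ct = tables[0]
        flags = detect_expressed_introns(ct, annotation)
        for gid, gene in annotation.genes.items():
            exon_count = ct.exon_counts[gene_pos(ct, gid)]
            expected = set()
            if exon_count > 0:
                for j, ivn in enumerate(gene.introns):
                    lhs = ct.intron_counts[gid][j] / ivn.length
                    rhs = 0.8 * exon_count / gene.exon_union_length
                    if lhs > rhs:
                        expected.add(j)
            assert flags[gid] == expected

    def test_final_counts_fold_in_expressed_introns_only(self):
        ann = self.make_gene()
        ct = make_table(["g"], [100.0], {"g": [45.0]})
        assert final_gene_counts(ct, {"g": {0}})["g"] == pytest.approx(145.0)
        assert final_gene_counts(ct, {"g": set()})["g"] == pytest.approx(100.0)

    def test_final_counts_bounded_by_retained_weight(self, small_counts):
        annotation, tables = small_counts
        for ct in tables:
            flags = detect_expressed_introns(ct, annotation)
            total = final_gene_counts(ct, flags).sum()
            assert total <= ct.retained_weight + 1e-9

    def test_effective_length_includes_expressed_introns(self):
        ann = self.make_gene()
        assert effective_lengths(ann, {"g": set()})["g"] == 1000
        assert effective_lengths(ann, {"g": {0}})["g"] == 1500


class TestRPKM:
    def test_definition(self):
        assert rpkm(100, 2000, 10_000_000) == pytest.approx(5.0)
        assert rpkm(0, 2000, 10_000_000) == 0.0

    def test_scaling_law(self):
        assert rpkm(100, 2000, 2_000_000) == pytest.approx(2 * rpkm(100, 2000, 4_000_000))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 1e6)
        with pytest.raises(ValueError):
            rpkm(1, 1000, 0)

    def test_intergenic_rpkm_per_region(self, toy_annotation):
        inter = intergenic_regions(toy_annotation, flank=500)
        counts = np.zeros(len(inter))
        counts[0] = 1.0
        ct = CountTable(
            stage="s",
            gene_ids=list(toy_annotation.genes),
            exon_counts=np.zeros(2),
            intron_counts={g: np.zeros(len(m.introns)) for g, m in toy_annotation.genes.items()},
            intergenic_region_counts=counts,
            unassigned=0.0,
            retained_weight=1_000_000.0,
        )
        values = intergenic_rpkm(ct, inter, min_length=200)
        lengths = [r.length for r in inter if r.length >= 200]
        assert values[0] == pytest.approx(1.0 / (lengths[0] / 1e3))
        assert (values[1:] == 0).all()

    def test_expression_matrix_columns_match_libraries(self, small_expression):
        _, tables, em = small_expression
        assert list(em.rpkm.columns) == [ct.stage for ct in tables]
        assert np.isfinite(em.rpkm.to_numpy()).all()
        assert (em.effective_lengths.to_numpy() >= 1).all()
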