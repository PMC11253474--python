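"""GFF3 gene index, locate queries and variant-effect classification."""

import numpy as np
import pytest

from bulkmap.annotation import (
    EFFECT_LABELS,
    AnnotationError,
    GenicContext,
    GenomeAnnotation,
    IntergenicContext,
    ReferenceMismatchError,
    annotate_interval,
    classify_indel,
    classify_substitution,
)
from oracles import locate_linear_scan

TOY_GFF = """##gff-version 3
chr1\tsrc\tgene\t1000\t5000\t.\t+\t.\tID=gA
chr1\tsrc\tmRNA\t1000\t5000\t.\t+\t.\tID=gA.1;Parent=gA
chr1\tsrc\texon\t1000\t2000\t.\t+\t.\tParent=gA.1
chr1\tsrc\texon\t3000\t5000\t.\t+\t.\tParent=gA.1
chr1\tsrc\tCDS\t1200\t2000\t.\t+\t0\tParent=gA.1
chr1\tsrc\tCDS\t3000\t4001\t.\t+\t0\tParent=gA.1
chr1\tsrc\tmRNA\t1000\t5000\t.\t+\t.\tID=gA.2;Parent=gA
chr1\tsrc\texon\t1000\t5000\t.\t+\t.\tParent=gA.2
chr1\tsrc\tCDS\t1200\t4001\t.\t+\t0\tParent=gA.2
chr1\tsrc\tgene\t8000\t9000\t.\t-\t.\tID=gB
chr1\tsrc\tmRNA\t8000\t9000\t.\t-\t.\tID=gB.1;Parent=gB
chr1\tsrc\texon\t8000\t9000\t.\t-\t.\tParent=gB.1
chr1\tsrc\tCDS\t8000\t8009\t.\t-\t0\tParent=gB.1
"""


class TestLoadAnnotation:
    def test_multiple_isoforms_preserved(self):
        ann = GenomeAnnotation.from_gff3(TOY_GFF)
        (g,) = [g for g in ann.genes("chr1") if g.id == "gA"]
        assert [t.id for t in g.transcripts] == ["gA.1", "gA.2"]

    def test_non_triplet_cds_flagged_non_canonical(self):
        ann = GenomeAnnotation.from_gff3(TOY_GFF)
        (gb,) = [g for g in ann.genes("chr1") if g.id == "gB"]
        assert gb.transcripts[0].non_canonical  # 10 bp CDS, phase 0

    def test_unannotated_chromosome_is_intergenic_everywhere(self):
        ann = GenomeAnnotation.from_gff3(TOY_GFF)
        ctx = ann.locate("chrZ", 123)
        assert isinstance(ctx, IntergenicContext)
        assert ctx.nearest == []


class TestLocate:
    def test_inside_gene(self):
        ann = GenomeAnnotation.from_gff3(TOY_GFF)
        ctx = ann.locate("chr1", 1500)
        assert isinstance(ctx, GenicContext)
        assert [g.id for g in ctx.genes] == ["gA"]

    def test_between_genes_reports_both_neighbors(self):
        ann = GenomeAnnotation.from_gff3(TOY_GFF)
        ctx = ann.locate("chr1", 5400)
        assert ctx.nearest == [("gA", 400), ("gB", 2600)]

    def test_equals_linear_scan_oracle(self, big_toy):
        ann = GenomeAnnotation.from_gff3(big_toy.gff3)
        genes = [(g.id, g.start, g.end) for g in ann.genes("chrA")]
        length = len(big_toy.sequences["chrA"])
        rng = np.random.default_rng(99)
        mismatches = 0
        for pos in rng.integers(1, length + 1, size=1000):
            pos = int(pos)
            want = locate_linear_scan(genes, pos)
            got = ann.locate("chrA", pos)
            if want[0] == "genic":
                ok = isinstance(got, GenicContext) and tuple(
                    sorted(g.id for g in got.genes)
                ) == want[1]
            else:
                left = (got.left[0].id, got.left[1]) if got.left else None
                right = (got.right[0].id, got.right[1]) if got.right else None
                ok = isinstance(got, IntergenicContext) and (left, right) == want[1:]
            mismatches += not ok
        assert mismatches == 0


class TestPlantedTruthSuite:
    def test_every_planted_variant_gets_its_expected_label(self, toy, toy_ann):
        for v in toy.variants:
            if v["kind"] == "substitution":
                effs = classify_substitution(
                    v["chrom"], v["pos"], v["ref"], v["alt"], toy_ann, toy.sequences
                )
            else:
                effs = classify_indel(
                    v["chrom"], v["pos"], v["ref"], v["alt"], toy_ann, toy.sequences
                )
            labels = {e.effect for e in effs}
            assert v["expected_effect"] in labels, v
            assert labels <= EFFECT_LABELS

    def test_minus_strand_mirror_matches_plus_strand(self, toy, toy_ann):
        """Metamorphic check: every mirrored substitution on the
        reverse-complement chromosome classifies identically."""
        plus = [v for v in toy.variants
                if v["kind"] == "substitution" and v["chrom"] == "chrA"]
        minus = [v for v in toy.variants
                 if v["kind"] == "substitution" and v["chrom"] == "chrB"]
        assert len(plus) == len(minus) >= 6
        for vp, vm in zip(plus, minus):
            ep = classify_substitution(
                vp["chrom"], vp["pos"], vp["ref"], vp["alt"], toy_ann, toy.sequences
            )
            em = classify_substitution(
                vm["chrom"], vm["pos"], vm["ref"], vm["alt"], toy_ann, toy.sequences
            )
            assert sorted(e.effect for e in ep) == sorted(e.effect for e in em)
            # amino-acid changes are strand-invariant
            assert sorted((e.aa_ref, e.aa_alt) for e in ep) == sorted(
                (e.aa_ref, e.aa_alt) for e in em
            )

    def test_reference_cds_translates_without_internal_stop(self, toy, toy_ann):
        from bulkmap.annotation import _cds_sequence
        from Bio.Seq import Seq

        for chrom in ("chrA", "chrB"):
            for g in toy_ann.genes(chrom):
                for tr in g.transcripts:
                    aa = str(Seq(_cds_sequence(tr, toy.sequences[chrom])).translate())
                    assert aa.startswith("M") and aa.endswith("*")
                    assert "*" not in aa[:-1]


class TestClassification:
    def test_multi_isoform_variant_yields_row_per_isoform(self, toy, toy_ann):
        v = next(v for v in toy.variants
                 if v["gene"] == "geneA01" and v["expected_effect"] == "missense")
        effs = classify_substitution(
            v["chrom"], v["pos"], v["ref"], v["alt"], toy_ann, toy.sequences
        )
        assert len(effs) == 2  # geneA01 carries two isoforms
        assert {e.transcript_id for e in effs} == {"geneA01.1", "geneA01.2"}

    def test_reference_mismatch_detected(self, toy, toy_ann):
        v = toy.variants[0]
        wrong = "G" if v["ref"] != "G" else "C"
        with pytest.raises(ReferenceMismatchError):
            classify_substitution(
                v["chrom"], v["pos"], wrong, v["alt"], toy_ann, toy.sequences
            )

    def test_deletion_spanning_two_genes(self, toy, toy_ann):
        genes = toy_ann.genes("chrA")
        g1, g2 = genes[0], genes[1]
        pos = g1.start - 5
        ref = toy.sequences["chrA"][pos - 1 : g2.start + 30]
        effs = classify_indel(
            "chrA", pos, ref, ref[0], toy_ann, toy.sequences
        )
        by_gene = {e.gene_id: e.note for e in effs}
        assert "complete" in by_gene[g1.id]
        assert "partial" in by_gene[g2.id]


class TestAnnotateInterval:
    def test_report_restricted_sorted_and_complete(self, toy, toy_ann):
        subs = [v for v in toy.variants
                if v["chrom"] == "chrA" and v["kind"] == "substitution"]
        variants = [
            {"CHROM": v["chrom"], "POS": v["pos"], "REF": v["ref"], "ALT": v["alt"]}
            for v in subs
        ]
        lo = min(v["pos"] for v in subs)
        hi = max(v["pos"] for v in subs)
        rows = annotate_interval(variants, ("chrA", lo, hi), toy_ann, toy.sequences)
        assert [r.pos for r in rows] == sorted(r.pos for r in rows)
        assert {r.pos for r in rows} == {v["pos"] for v in subs}
        empty = annotate_interval(variants, ("chrA", 1, 5), toy_ann, toy.sequences)
        assert empty == []

    def test_unknown_region_chromosome_rejected(self, toy, toy_ann):
        with pytest.raises(AnnotationError):
            annotate_interval([], ("chrQ", 1, 100), toy_ann, toy.sequences)
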