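from math import comb

import numpy as np
import pytest

from cyclepeaks.annotate import (
    GeneModel,
    GenomicCategory,
    assign_category,
    category_distribution,
    compare_class_fractions,
    gc_content,
    read_bed12,
    read_gff3,
)
from cyclepeaks.classify import classify_sites
from cyclepeaks.intervals import GenomicInterval, ValidationError
from .conftest import make_peaks


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration: sum of probabilities of all
    tables with the same margins whose probability <= the observed one."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(1.0, total)


# + strand gene: span [5000, 15000), TSS at 5000
PLUS_GENE = GeneModel(
    "chr2L", 5000, 15000, "+",
    exons=[(5000, 7000), (9000, 11000), (13000, 15000)],
    cds=[(6000, 7000), (9000, 11000), (13000, 14000)],
    id="gplus",
)
# - strand gene occupying [2000, 8000), TSS at 8000
MINUS_GENE = GeneModel(
    "chrX", 2000, 8000, "-",
    exons=[(2000, 3500), (5000, 8000)],
    cds=[(2500, 3500), (5000, 7000)],
    id="gminus",
)


def site_at(chrom, anchor):
    return GenomicInterval(chrom, max(0, anchor - 1), anchor + 1, summit=min(1, anchor))


class TestAssignCategory:
    def test_tss_region_within_window(self):
        assert assign_category(site_at("chr2L", 4900), [PLUS_GENE]) is GenomicCategory.TSS_region

    def test_promoter_upstream(self):
        assert assign_category(site_at("chr2L", 3500), [PLUS_GENE]) is GenomicCategory.Promoter

    def test_far_site_intergenic(self):
        assert assign_category(site_at("chr2L", 900_000), [PLUS_GENE]) is GenomicCategory.Intergenic

    def test_minus_strand_tss(self):
        assert assign_category(site_at("chrX", 8100), [MINUS_GENE]) is GenomicCategory.TSS_region

    def test_minus_strand_promoter(self):
        assert assign_category(site_at("chrX", 9000), [MINUS_GENE]) is GenomicCategory.Promoter

    def test_downstream_past_tts(self):
        assert assign_category(site_at("chr2L", 16000), [PLUS_GENE]) is GenomicCategory.Downstream

    def test_minus_strand_downstream(self):
        assert assign_category(site_at("chrX", 1000), [MINUS_GENE]) is GenomicCategory.Downstream

    def test_utr5_exonic_before_cds(self):
        assert assign_category(site_at("chr2L", 5500), [PLUS_GENE]) is GenomicCategory.UTR5

    def test_coding_exon(self):
        assert assign_category(site_at("chr2L", 10000), [PLUS_GENE]) is GenomicCategory.CodingExon

    def test_intron(self):
        assert assign_category(site_at("chr2L", 8000), [PLUS_GENE]) is GenomicCategory.Intron

    def test_no_genes_errors(self):
        with pytest.raises(ValidationError):
            assign_category(site_at("chr2L", 100), [])

    def test_tss_outranks_gene_body_of_other_gene(self):
        # anchor inside PLUS_GENE's intron but within 200 bp of another TSS
        other = GeneModel("chr2L", 8100, 12000, "+", exons=[(8100, 12000)], id="g2")
        cat = assign_category(site_at("chr2L", 8000), [PLUS_GENE, other])
        assert cat is GenomicCategory.TSS_region

    def test_brute_force_oracle(self, rng):
        """Precedence result equals an explicit region-membership scan."""
        tssw, flank = 200, 2000
        genes = []
        for k in range(20):
            start = int(rng.integers(0, 180_000))
            end = start + int(rng.integers(1_000, 8_000))
            strand = "+" if rng.random() < 0.5 else "-"
            mid = (start + end) // 2
            exons = [(start, mid - 100), (mid + 100, end)]
            cds = [(start + 300, mid - 100), (mid + 100, end - 300)]
            genes.append(GeneModel("c", start, end, strand, exons, cds, f"g{k}"))

        def oracle(anchor):
            best = GenomicCategory.Intergenic
            order = list(GenomicCategory)
            for g in genes:
                regions = {}
                tss, tts = g.tss, g.tts
                regions[GenomicCategory.TSS_region] = abs(anchor - tss) <= tssw
                if g.strand == "+":
                    regions[GenomicCategory.Promoter] = (
                        tss - tssw - flank <= anchor < tss - tssw
                    )
                    regions[GenomicCategory.Downstream] = (
                        tts < anchor <= tts + flank and not g.start <= anchor < g.end
                    )
                else:
                    regions[GenomicCategory.Promoter] = (
                        tss + tssw < anchor <= tss + tssw + flank
                    )
                    regions[GenomicCategory.Downstream] = (
                        tts - flank <= anchor < tts and not g.start <= anchor < g.end
                    )
                in_gene = g.start <= anchor < g.end
                in_exon = in_gene and any(s <= anchor < e for s, e in g.exons)
                first = g.first_cds_base()
                is_utr5 = in_exon and first is not None and (
                    anchor < first if g.strand == "+" else anchor > first
                )
                regions[GenomicCategory.UTR5] = is_utr5
                regions[GenomicCategory.CodingExon] = in_exon and not is_utr5
                regions[GenomicCategory.Intron] = in_gene and not in_exon
                for cat in order:
                    if regions.get(cat) and order.index(cat) < order.index(best):
                        best = cat
                        break
            return best

        from cyclepeaks.intervals import GenomeTable

        anchors = rng.integers(2, 199_000, size=1000)
        for anchor in anchors:
            site = GenomicInterval("c", int(anchor) - 1, int(anchor) + 1, summit=1)
            assert assign_category(site, genes, tssw, flank) is oracle(int(anchor))


class TestCategoryDistribution:
    def test_all_sites_at_tss(self, genome):
        gene = GeneModel("chr2L", 50_000, 60_000, "+", exons=[(50_000, 60_000)], id="g")
        inter = make_peaks(genome, [("chr2L", 49_950, 50_050, f"i{k}") for k in range(1)])
        inter = make_peaks(
            genome,
            [("chr2L", 49_900 + 10 * k, 50_000 + 10 * k, f"i{k}") for k in range(5)],
        )
        c = classify_sites(inter, make_peaks(genome, []))
        dist = category_distribution(c, [gene])
        io_tss = dist[(dist["class"] == "IO") & (dist["category"] == "TSS_region")]
        assert io_tss["fraction"].iloc[0] == 1.0

    def test_gene_free_genome_all_intergenic(self, genome, rng):
        gene = GeneModel("chrX", 1000, 2000, "+", exons=[(1000, 2000)], id="g")
        spec = [("chr2L", int(s), int(s) + 100, f"i{k}")
                for k, s in enumerate(rng.integers(10_000, 900_000, size=30))]
        c = classify_sites(make_peaks(genome, spec), make_peaks(genome, []))
        dist = category_distribution(c, [gene])
        io = dist[dist["class"] == "IO"].set_index("category")
        assert io.loc["Intergenic", "fraction"] == 1.0

    def test_fractions_sum_to_one(self, genome, rng):
        genes = [GeneModel("chr2L", 50_000, 70_000, "+",
                           exons=[(50_000, 55_000), (60_000, 70_000)],
                           cds=[(52_000, 55_000), (60_000, 68_000)], id="g")]
        spec = [("chr2L", int(s), int(s) + 100, f"i{k}")
                for k, s in enumerate(rng.integers(0, 900_000, size=50))]
        c = classify_sites(make_peaks(genome, spec), make_peaks(genome, []))
        dist = category_distribution(c, genes)
        total = dist[dist["class"] == "IO"]["fraction"].sum()
        assert abs(total - 1.0) < 1e-12

    def test_planted_tss_fraction_recovered(self):
        from cyclepeaks.simulate import (
            SyntheticConfig,
            generate_annotations_and_domains,
            generate_genome,
            generate_peak_data,
        )

        cfg = SyntheticConfig(
            seed=5,
            n_sites={"IM": 300, "IO": 0, "MO": 0},
            tss_fraction={"IM": 0.33, "IO": 0.0, "MO": 0.0},
            chromosomes={"c1": 3_000_000, "c2": 3_000_000},
            n_genes=120,
        )
        genome, _ = generate_genome(cfg, with_sequence=False)
        genes, domains, _ = generate_annotations_and_domains(cfg, genome)
        inter, mito, _, truth = generate_peak_data(cfg, genome, genes=genes)
        c = classify_sites(inter, mito)
        dist = category_distribution(c, genes)
        im_tss = dist[(dist["class"] == "IM") & (dist["category"] == "TSS_region")]
        frac = im_tss["fraction"].iloc[0]
        # 3 binomial SDs at n=300, p=0.33
        assert abs(frac - 0.33) < 3 * np.sqrt(0.33 * 0.67 / 300) + 1e-9


class TestFisher:
    def test_example_table(self):
        p = compare_class_fractions((8, 2), (2, 8))
        assert abs(p - fisher_two_sided_oracle(8, 2, 2, 8)) < 1e-12
        assert abs(p - 0.023) < 0.001

    def test_no_association(self):
        assert compare_class_fractions((5, 5), (5, 5)) == 1.0

    def test_extreme_table_equals_enumeration(self):
        p = compare_class_fractions((10, 0), (0, 10))
        assert abs(p - fisher_two_sided_oracle(10, 0, 0, 10)) < 1e-12

    def test_negative_counts_error(self):
        with pytest.raises(ValidationError):
            compare_class_fractions((-1, 5), (2, 2))

    def test_empty_class_error(self):
        with pytest.raises(ValidationError):
            compare_class_fractions((0, 0), (2, 2))

    def test_matches_oracle_on_small_tables(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b == 0 or c + d == 0:
                continue
            p = compare_class_fractions((a, b), (c, d))
            assert abs(p - fisher_two_sided_oracle(a, b, c, d)) < 1e-12


class TestGcContent:
    def make_site(self, anchor):
        return GenomicInterval("c", anchor - 1, anchor + 1, summit=1)

    def test_all_gc(self):
        seqs = {"c": "GCGC"}
        assert gc_content(self.make_site(2), seqs, window=2) == 1.0

    def test_all_at(self):
        seqs = {"c": "ATAT"}
        assert gc_content(self.make_site(2), seqs, window=2) == 0.0

    def test_half(self):
        seqs = {"c": "GCAT"}
        assert gc_content(self.make_site(2), seqs, window=2) == 0.5

    def test_n_excluded_from_denominator(self):
        seqs = {"c": "GNNA"}
        assert gc_content(self.make_site(2), seqs, window=2) == 0.5

    def test_all_n_absent(self):
        seqs = {"c": "NNNN"}
        assert gc_content(self.make_site(2), seqs, window=2) is None

    def test_case_insensitive(self):
        seqs = {"c": "gcat"}
        assert gc_content(self.make_site(2), seqs, window=2) == 0.5

    def test_complement_balance(self, rng):
        """gc(seq) == 1 - gc(seq with A<->G, T<->C swapped)."""
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, size=200))
        swapped = seq.translate(str.maketrans("AGTC", "GACT"))
        site = GenomicInterval("c", 90, 110, summit=10)
        g1 = gc_content(site, {"c": seq}, window=50)
        g2 = gc_content(site, {"c": swapped}, window=50)
        assert abs(g1 - (1 - g2)) < 1e-12


class TestGeneModelReaders:
    def test_gff3_roundtrip(self, tmp_path):
        from cyclepeaks.simulate import _write_gff3

        genes = [PLUS_GENE, MINUS_GENE]
        p = tmp_path / "genes.gff3"
        _write_gff3(genes, p)
        back = read_gff3(p)
        assert len(back) == 2
        for orig, got in zip(sorted(genes, key=lambda g: (g.chrom, g.start)), back):
            assert (got.chrom, got.start, got.end, got.strand) == (
                orig.chrom, orig.start, orig.end, orig.strand
            )
            assert got.exons == orig.exons
            assert got.cds == orig.cds

    def test_bed12_reader(self, tmp_path):
        # 2 exons of 300 bp at offsets 0 and 700; CDS from 1100 to 1850
        line = "\t".join([
            "chr2L", "1000", "2000", "tx1", "0", "+", "1100", "1850", "0",
            "2", "300,300,", "0,700,",
        ])
        p = tmp_path / "g.bed"
        p.write_text(line + "\n")
        genes = read_bed12(p)
        g = genes[0]
        assert g.exons == [(1000, 1300), (1700, 2000)]
        assert g.cds == [(1100, 1300), (1700, 1850)]
        assert g.tss == 1000 and g.tts == 2000

    def test_gene_model_invariants(self):
        with pytest.raises(ValidationError):
            GeneModel("c", 100, 50, "+", exons=[], id="bad")
        with pytest.raises(ValidationError):
            GeneModel("c", 0, 100, "+", exons=[(0, 60), (50, 100)], id="overlap")
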