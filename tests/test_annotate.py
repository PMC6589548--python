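"""Annotation: feature precedence, coding consequences vs whole-CDS
translation, context profile, hyper-edited genes, liftover, conservation."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from editome import annotate, formats
from editome.annotate import (
    classify_feature,
    codon_consequence,
    conserved_overlap,
    context_profile,
    feature_fractions,
    hyper_edited_genes,
    liftover_sites,
    LiftOver,
)
from editome.calling import ClusterRegion, GeneIndex
from editome.formats import Chain, GeneModel, read_chain


def sites_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
    df.index = df.chrom + ":" + df.pos.astype(str)
    return df


class TestClassifyFeature:
    def test_precedence_over_transcripts(self):
        a = GeneModel("gA", "tA", "chr1", "+", exons=[(1, 100), (500, 600)],
                      cds=[(10, 100), (500, 550)])
        b = GeneModel("gB", "tB", "chr1", "+", exons=[(150, 400)], cds=[(150, 300)])
        idx = GeneIndex([a, b])
        # pos 200: intron of A, CDS of B -> CDS wins
        assert classify_feature("chr1", 200, idx)[0] == "CDS"
        # pos 350: intron of A, 3'UTR of B -> 3'UTR wins
        assert classify_feature("chr1", 350, idx)[0] == "3UTR"
        assert classify_feature("chr1", 450, idx)[0] == "intron"
        assert classify_feature("chr1", 5000, idx)[0] == "intergenic"

    def test_ncrna_exon(self):
        nc = GeneModel("gN", "tN", "chr1", "+", exons=[(10, 50)])
        assert classify_feature("chr1", 20, GeneIndex([nc]))[0] == "ncRNA_exon"

    def test_fractions_sum_to_one(self):
        df = pd.DataFrame({"feature": ["intron"] * 3 + ["3UTR", "intergenic"]})
        assert feature_fractions(df).sum() == pytest.approx(1.0)


class TestCodonConsequence:
    def model(self, genome_seq, strand="+"):
        return {"chr1": genome_seq}, GeneModel(
            "g", "t", "chr1", strand, exons=[(1, len(genome_seq))],
            cds=[(1, len(genome_seq))],
        )

    def test_q_to_r(self):
        genome, m = self.model("CAGGAA")  # Gln, Glu
        assert codon_consequence("chr1", 2, "G", m, genome) == ("missense", "Q>R")

    def test_t_to_a(self):
        genome, m = self.model("ACAGAT")  # Thr, Asp
        assert codon_consequence("chr1", 1, "G", m, genome) == ("missense", "T>A")

    def test_synonymous_third_position(self):
        genome, m = self.model("GAATTT")  # Glu, Phe; GAA->GAG still Glu
        assert codon_consequence("chr1", 3, "G", m, genome) == ("synonymous", None)

    def test_minus_strand_edit_maps_to_sense(self):
        # sense CDS = revcomp(genomic); genomic T>C at the complementary
        # position produces a sense A>G
        sense = "CAGGAA"
        genomic = formats.revcomp(sense)
        genome = {"chr1": genomic}
        m = GeneModel("g", "t", "chr1", "-", exons=[(1, 6)], cds=[(1, 6)])
        # sense position 2 is genomic position 5 (T on forward strand)
        assert genomic[4] == "T"
        assert codon_consequence("chr1", 5, "C", m, genome) == ("missense", "Q>R")

    def test_agrees_with_whole_cds_translation(self, tiny_dataset):
        """Brute-force oracle: translate the full mutated CDS."""
        genome = tiny_dataset.reference.sequences()
        checked = 0
        for m in tiny_dataset.reference.genes:
            cds = m.cds_sequence(genome)
            ref_prot = str(Seq(cds).translate())
            for s, e in m.cds:
                for pos in range(s, min(s + 12, e + 1)):
                    alt = "G" if genome[m.chrom][pos - 1] != "G" else "A"
                    cons, aa = codon_consequence(m.chrom, pos, alt, m, genome)
                    idx = m.cds_index_of(pos)
                    sense_alt = alt if m.strand == "+" else formats.revcomp(alt)
                    mutated = cds[:idx] + sense_alt + cds[idx + 1:]
                    alt_prot = str(Seq(mutated).translate())
                    diffs = [(a, b) for a, b in zip(ref_prot, alt_prot) if a != b]
                    if cons == "synonymous":
                        assert not diffs
                    else:
                        assert len(diffs) == 1
                        assert aa == f"{diffs[0][0]}>{diffs[0][1]}"
                    checked += 1
        assert checked > 50


class TestHyperEditedGenes:
    def gene(self):
        return GeneModel("gH", "tH", "chr1", "+", exons=[(1, 2000)])

    def sites(self, n, gene="gH"):
        return pd.DataFrame(
            {"gene_id": [gene] * n, "chrom": "chr1", "pos": range(100, 100 + n)}
        )

    def test_five_sites_one_cluster_qualifies(self):
        cl = [ClusterRegion("chr1", 100, 150, ["a", "b", "c"])]
        out = hyper_edited_genes(self.sites(5), cl, [self.gene()])
        assert list(out.gene_id) == ["gH"]

    def test_scattered_sites_without_cluster_do_not(self):
        out = hyper_edited_genes(self.sites(10), [], [self.gene()])
        assert out.empty

    def test_four_sites_with_cluster_do_not(self):
        cl = [ClusterRegion("chr1", 100, 150, ["a", "b", "c"])]
        out = hyper_edited_genes(self.sites(4), cl, [self.gene()])
        assert out.empty

    def test_cluster_outside_gene_span_does_not_count(self):
        cl = [ClusterRegion("chr1", 5000, 5100, ["a", "b", "c"])]
        out = hyper_edited_genes(self.sites(6), cl, [self.gene()])
        assert out.empty


class TestContextProfile:
    def test_single_plus_site(self):
        genome = {"c": "TTTAGTT"}
        prof = context_profile(sites_df([("c", 4, "+")]), genome, k=1)
        assert prof.frequencies.loc[-1, "T"] == 1.0
        assert prof.frequencies.loc[0, "A"] == 1.0
        assert prof.frequencies.loc[1, "G"] == 1.0

    def test_minus_strand_profile_identical_after_revcomp(self):
        plus = context_profile(sites_df([("c", 4, "+")]), {"c": "TTTAGTT"}, k=1)
        minus = context_profile(sites_df([("c", 4, "-")]), {"c": "TTCTAAA"}, k=1)
        assert np.allclose(plus.frequencies, minus.frequencies)

    def test_contig_edge_sites_excluded_and_counted(self):
        prof = context_profile(sites_df([("c", 1, "+"), ("c", 4, "+")]),
                               {"c": "ATTAGTT"}, k=2)
        assert prof.n_sites == 1 and prof.n_excluded == 1

    def test_planted_downstream_g_recovered(self, tiny_dataset):
        cfg = tiny_dataset.config
        truth = tiny_dataset.truth.sites
        prof = context_profile(truth, tiny_dataset.reference.sequences(), k=1)
        freq_g = prof.frequencies.loc[1, "G"]
        p = cfg.context_g_downstream
        se = np.sqrt(p * (1 - p) / prof.n_sites)
        # planting may be blocked at reserved neighbours; allow a wide band
        assert abs(freq_g - p) < max(3 * se, 0.05)
        assert prof.frequencies.loc[0, "A"] == 1.0


class TestLiftover:
    def test_identity_chain_maps_to_itself(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 10 chrA 50 + 0 50 chrH 50 + 0 50 1\n50\n\n")
        lo = LiftOver(read_chain(p))
        assert lo.map_position("chrA", 17) == ("chrH", 17, "+")

    def test_gap_positions_unmapped(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 10 chrA 50 + 0 30 chrH 50 + 0 28 1\n10 5 3\n15\n\n")
        lo = LiftOver(read_chain(p))
        for pos in range(11, 16):
            assert lo.map_position("chrA", pos) is None

    def test_minus_chain_against_per_base_oracle(self, tmp_path):
        """Exhaustive map of a 50-bp toy chain with one gap and a minus
        target, checked against manual block arithmetic."""
        p = tmp_path / "c.chain"
        p.write_text("chain 10 chrA 50 + 5 45 chrH 60 - 10 48 1\n20 4 2\n16\n\n")
        (chain,) = read_chain(p)
        expected = {}
        # block 1: t 5..24 (0-based) <-> q 10..29 on the reversed target
        for i in range(20):
            expected[5 + i + 1] = 60 - (10 + i)
        # gap: t 25..28 unmapped; block 2: t 29..44 <-> q 32..47
        for i in range(16):
            expected[29 + i + 1] = 60 - (32 + i)
        for pos in range(1, 51):
            hit = chain.map_position(pos)
            if pos in expected:
                assert hit == (expected[pos], "-")
            else:
                assert hit is None

    def test_injective_within_blocks(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text("chain 10 chrA 100 + 0 60 chrH 100 + 10 65 1\n25 10 5\n25\n\n")
        (chain,) = read_chain(p)
        seen = {}
        for pos in range(1, 101):
            hit = chain.map_position(pos)
            if hit is not None:
                assert hit[0] not in seen
                seen[hit[0]] = pos

    def test_highest_score_chain_wins(self, tmp_path):
        p = tmp_path / "c.chain"
        p.write_text(
            "chain 5 chrA 50 + 0 50 chrH 50 + 0 50 1\n50\n\n"
            "chain 90 chrA 50 + 0 20 chrM 50 + 30 50 2\n20\n\n"
        )
        lo = LiftOver(read_chain(p))
        assert lo.map_position("chrA", 10) == ("chrM", 40, "+")


class TestConservedOverlap:
    def mapped(self, rows):
        df = pd.DataFrame(rows, columns=["mapped", "target_chrom", "target_pos"])
        df.index = [f"s{i}" for i in range(len(df))]
        return df

    def catalog(self, positions):
        return pd.DataFrame(
            [{"chrom": c, "start": p, "end": p, "name": ".", "score": 0,
              "strand": "."} for c, p in positions]
        )

    def test_empty_catalog_zero_conserved(self):
        m = self.mapped([(True, "chrH", 10)])
        assert conserved_overlap(m, self.catalog([])).sum() == 0

    def test_full_catalog_all_conserved(self):
        m = self.mapped([(True, "chrH", 10), (True, "chrH", 22)])
        cat = self.catalog([("chrH", 10), ("chrH", 22)])
        assert conserved_overlap(m, cat).all()

    def test_random_catalog_equals_set_intersection(self, rng):
        mapped_pos = rng.choice(5000, size=100, replace=False)
        cat_pos = rng.choice(5000, size=100, replace=False)
        m = self.mapped([(True, "chrH", int(p)) for p in mapped_pos])
        cat = self.catalog([("chrH", int(p)) for p in cat_pos])
        expected = len(set(mapped_pos) & set(cat_pos))
        assert conserved_overlap(m, cat).sum() == expected
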