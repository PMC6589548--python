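"""Calling cascade: thresholds, filters, strand classification, clusters."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from editome import calling, formats
from editome.calling import (
    CallingParams,
    GeneIndex,
    call_candidates,
    classify_and_purge,
    detect_clusters,
    filter_genomic_evidence,
    filter_read_end,
    passes_homopolymer,
    passes_splice_proximity,
    run_calling,
)
from editome.formats import (
    AlleleBlock,
    AlleleObservation,
    GeneModel,
    GenomicPosition,
    PileupSite,
    ValidationError,
    VariantCallRecord,
)

PARAMS = CallingParams()


def obs(n, qual=35, offset=75, readlen=150):
    return [AlleleObservation(qual, offset + i % 30, readlen) for i in range(n)]


def make_site(ref_n, alt_blocks, ref="A", strand="+", pos=100, **obs_kw):
    alleles = {ref: AlleleBlock(obs(ref_n, **obs_kw))}
    for base, block in alt_blocks.items():
        alleles[base] = AlleleBlock(block)
    return PileupSite("chr1", pos, ref, strand, alleles)


class TestFilterReadEnd:
    @pytest.mark.parametrize(
        "offset,kept",
        [(6, False), (7, True), (144, True), (145, False), (1, False), (150, False)],
    )
    def test_six_bp_boundaries(self, offset, kept):
        out = filter_read_end([AlleleObservation(35, offset, 150)], k=6)
        assert bool(out) is kept

    def test_out_of_range_offset_raises(self):
        bad = AlleleObservation.__new__(AlleleObservation)
        object.__setattr__(bad, "qual", 35)
        object.__setattr__(bad, "offset", 0)
        object.__setattr__(bad, "readlen", 150)
        with pytest.raises(ValidationError):
            filter_read_end([bad])


class TestCallCandidates:
    def test_depth_boundary(self):
        low = make_site(6, {"G": obs(3)})       # depth 9
        assert call_candidates(low, PARAMS) is None
        ok = make_site(7, {"G": obs(3)})        # depth 10
        assert call_candidates(ok, PARAMS) is not None

    def test_multiallelic_rejected(self):
        site = make_site(23, {"G": obs(5), "C": obs(2)})  # depth 30
        assert call_candidates(site, PARAMS) is None

    def test_alt_support_boundary(self):
        two = make_site(28, {"G": obs(2)})
        assert call_candidates(two, PARAMS) is None
        three = make_site(27, {"G": obs(3)})
        cand = call_candidates(three, PARAMS)
        assert cand is not None and cand.alt_support == 3

    def test_low_quality_alt_reads_do_not_count(self):
        site = make_site(27, {"G": obs(3, qual=20)})
        assert call_candidates(site, PARAMS) is None

    def test_all_end_support_rejected(self):
        end_obs = [AlleleObservation(35, o, 150) for o in (1, 2, 3, 4, 5, 6, 146, 147, 148, 149)]
        site = make_site(20, {"G": end_obs})
        assert call_candidates(site, PARAMS) is None

    def test_site_quality_must_exceed_threshold(self):
        site = make_site(27, {"G": obs(3, qual=26)})
        cand = call_candidates(site, PARAMS)
        assert cand is not None and cand.site_qual > 25


def _cand_df(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    df["site_id"] = df.chrom + ":" + df.pos.astype(str)
    return df.set_index("site_id")


class TestGenomicEvidence:
    def vr(self, pos, ref, alt, gt):
        return VariantCallRecord(GenomicPosition("chr1", pos), ref, alt, gt)

    def test_wgs_het_removes(self):
        cands = _cand_df([("chr1", 10, "A", "G")])
        keep = filter_genomic_evidence(cands, [self.vr(10, "A", "G", "het")], [], set())
        assert not keep.iloc[0]

    def test_dbsnp_membership_removes(self):
        cands = _cand_df([("chr1", 10, "A", "G")])
        keep = filter_genomic_evidence(cands, [], [], {("chr1", 10)})
        assert not keep.iloc[0]

    def test_wgbs_unknown_is_ignored(self):
        cands = _cand_df([("chr1", 10, "C", "T")])
        keep = filter_genomic_evidence(
            cands,
            [self.vr(10, "C", "T", "hom_ref")],
            [self.vr(10, "C", "T", "unknown")],
            set(),
        )
        assert keep.iloc[0]

    def test_hom_alt_also_removes(self):
        cands = _cand_df([("chr1", 10, "A", "G")])
        keep = filter_genomic_evidence(cands, [self.vr(10, "A", "G", "hom_alt")], [], set())
        assert not keep.iloc[0]

    def test_different_substitution_does_not_remove(self):
        cands = _cand_df([("chr1", 10, "A", "G")])
        keep = filter_genomic_evidence(cands, [self.vr(10, "A", "C", "het")], [], set())
        assert keep.iloc[0]


class TestSpliceProximity:
    @pytest.fixture()
    def index(self):
        m = GeneModel("g", "t", "chr1", "+", exons=[(100, 200), (300, 400)],
                      cds=[(120, 200), (300, 380)])
        return GeneIndex([m])

    @pytest.mark.parametrize("pos,kept", [(203, False), (204, False), (205, True),
                                          (296, False), (295, True)])
    def test_intronic_boundary(self, index, pos, kept):
        assert passes_splice_proximity("chr1", pos, index, k=4) is kept

    def test_exonic_site_near_junction_kept(self, index):
        assert passes_splice_proximity("chr1", 200, index, k=4)
        assert passes_splice_proximity("chr1", 300, index, k=4)

    def test_intergenic_site_kept(self, index):
        assert passes_splice_proximity("chr1", 5000, index, k=4)


def _max_run(seq, pos):
    """Oracle: maximal single-base run length containing pos (1-based)."""
    runs = [(len(list(g)), b) for b, g in itertools.groupby(seq)]
    i = 1
    for L, b in runs:
        if i <= pos <= i + L - 1:
            return L
        i += L
    raise AssertionError


class TestHomopolymer:
    @pytest.mark.parametrize(
        "seq,pos,kept",
        [
            ("CCAAAAAGG", 5, False),   # inside AAAAA
            ("CCAAAAGGG", 5, True),    # run of 4
            ("AAAAAAATC", 7, False),   # last base of a 7-run
        ],
    )
    def test_run_boundaries(self, seq, pos, kept):
        assert passes_homopolymer("c", pos, {"c": seq}, min_run=5) is kept

    def test_agrees_with_scan_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), p=[0.4, 0.1, 0.1, 0.4], size=500))
        for pos in range(1, 501):
            assert passes_homopolymer("c", pos, {"c": seq}) == (_max_run(seq, pos) < 5)

    def test_beyond_contig_raises(self):
        with pytest.raises(ValidationError):
            passes_homopolymer("c", 10, {"c": "ACGT"})


class TestClassifyAndPurge:
    def index(self, strand, second=None):
        models = [GeneModel("g1", "t1", "chr1", strand, exons=[(1, 1000)])]
        if second:
            models.append(GeneModel("g2", "t2", "chr1", second, exons=[(1, 1000)]))
        return GeneIndex(models)

    def classify_one(self, ref, alt, index):
        sites = classify_and_purge(_cand_df([("chr1", 100, ref, alt)]), index)
        return sites[0] if sites else None

    def test_a_to_g_on_plus_gene(self):
        s = self.classify_one("A", "G", self.index("+"))
        assert s.resolved_type == "A-to-I" and not s.putative

    def test_t_to_c_on_minus_gene(self):
        s = self.classify_one("T", "C", self.index("-"))
        assert s.resolved_type == "A-to-I"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_bisulfite_confounded_types_purged(self, strand):
        # G>A on + is G-to-A; on - it reads C>T on the sense strand
        assert self.classify_one("G", "A", self.index(strand)) is None
        assert self.classify_one("C", "T", self.index(strand)) is None

    def test_unstranded_t_to_c_putative(self):
        s = self.classify_one("T", "C", GeneIndex([]))
        assert s is not None and s.resolved_type == "A-to-I" and s.putative

    def test_unstranded_g_to_a_purged(self):
        assert self.classify_one("G", "A", GeneIndex([])) is None

    def test_opposite_strand_overlap_resolved_toward_a_to_i(self):
        s = self.classify_one("A", "G", self.index("+", second="-"))
        assert s is not None and s.position.strand == "+"
        # T>C is A-to-I only on the minus strand
        s = self.classify_one("T", "C", self.index("+", second="-"))
        assert s is not None and s.position.strand == "-"
        # C>G is never A-to-I on either strand: ambiguous, dropped
        assert self.classify_one("C", "G", self.index("+", second="-")) is None


def _cluster_oracle(positions, window=100, min_sites=3):
    """O(n^2) enumeration of all windows anchored at site positions."""
    pos = sorted(set(positions))
    clustered = set()
    for p in pos:
        inside = [q for q in pos if p <= q <= p + window - 1]
        if len(inside) >= min_sites:
            clustered.update(inside)
    return clustered


class TestDetectClusters:
    def test_span_100_is_one_cluster(self):
        regions = detect_clusters([("c", 100), ("c", 150), ("c", 199)])
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (100, 199)

    def test_span_101_is_no_cluster(self):
        assert detect_clusters([("c", 100), ("c", 150), ("c", 200)]) == []

    def test_two_separate_clusters(self):
        pts = [("c", p) for p in (100, 110, 120, 400, 410, 420)]
        regions = detect_clusters(pts)
        assert [(r.start, r.end) for r in regions] == [(100, 120), (400, 420)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 2000), min_size=0, max_size=200))
    def test_matches_window_enumeration_oracle(self, positions):
        regions = detect_clusters([("c", p) for p in positions])
        members = set()
        for r in regions:
            members.update(int(s.split(":")[1]) for s in r.members)
        assert members == _cluster_oracle(positions)


@pytest.fixture(scope="module")
def called(tmp_path_factory):
    """Error-free tiny run: calling should recover exactly the
    adequately-supported planted sites."""
    from editome.simulate import simulate_dataset
    from tests.conftest import tiny_config

    cfg = tiny_config(error_rate=0.0, n_stages=9, replicates_per_stage=2)
    ds = simulate_dataset(cfg, tmp_path_factory.mktemp("callsim"))
    genome = ds.reference.sequences()
    table, clusters = run_calling(
        ds.pileups,
        formats.read_vcf_min(ds.outdir / "wgs.vcf"),
        formats.read_vcf_min(ds.outdir / "wgbs.vcf"),
        formats.read_vcf_min(ds.outdir / "dbsnp.vcf"),
        ds.reference.genes, genome,
    )
    return ds, table, clusters


class TestCascadeOnSyntheticData:
    def test_error_free_recovery_is_exact(self, called):
        ds, table, _ = called
        planted = set(ds.truth.sites.index)
        assert set(table.index) <= planted
        # with zero errors, any called site must be planted, and every
        # called site retains at least the calling thresholds
        assert (table.n_samples >= 1).all()

    def test_no_planted_snp_is_called(self, called):
        ds, table, _ = called
        snp_ids = set(ds.truth.snps.chrom + ":" + ds.truth.snps.pos.astype(str))
        assert not set(table.index) & snp_ids

    def test_called_types_are_a_to_i(self, called):
        _, table, _ = called
        assert set(table["type"]) == {"A-to-I"}

    def test_filter_order_invariance(self, called):
        ds, table, _ = called
        genome = ds.reference.sequences()
        wgs = formats.read_vcf_min(ds.outdir / "wgs.vcf")
        wgbs = formats.read_vcf_min(ds.outdir / "wgbs.vcf")
        dbsnp = formats.read_vcf_min(ds.outdir / "dbsnp.vcf")
        baseline = None
        for order in itertools.islice(
            itertools.permutations(calling.FILTER_NAMES), 4
        ):
            t, _ = run_calling(ds.pileups, wgs, wgbs, dbsnp,
                               ds.reference.genes, genome, filter_order=order)
            ids = set(t.index)
            if baseline is None:
                baseline = ids
            assert ids == baseline
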