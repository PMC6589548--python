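"""Editing-site identification cascade.

Candidate variants are called per sample from stranded pileups under
stringent depth/quality rules, pooled across samples, and then passed
through a set of independent false-positive filters: DNA-evidence
(WGS/WGBS genotypes and a known-SNP catalog), splice-junction proximity,
homopolymer runs, an optional mappability mask, and strand-aware type
classification that purges bisulfite-confounded C-to-U / G-to-A calls.
Each filter is a pure predicate on its own evidence, so the surviving set
does not depend on the order in which they are applied.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .formats import (
    AlleleObservation,
    GeneModel,
    GenomicPosition,
    PileupSite,
    ValidationError,
    VariantCallRecord,
    read_pileup,
)

SENSE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class CallingParams:
    min_depth: int = 10
    min_site_qual: float = 25.0
    min_alt_reads: int = 3
    max_alt_alleles: int = 1
    splice_exclusion_bp: int = 4
    read_end_exclusion_bp: int = 6
    homopolymer_min_run: int = 5
    cluster_window_bp: int = 100
    cluster_min_sites: int = 3

    def __post_init__(self):
        for name in (
            "min_depth", "min_alt_reads", "max_alt_alleles", "splice_exclusion_bp",
            "read_end_exclusion_bp", "homopolymer_min_run", "cluster_window_bp",
            "cluster_min_sites",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass
class CandidateVariant:
    position: GenomicPosition
    ref_allele: str
    alt_allele: str
    total_depth: int
    alt_support: int          # high-quality alt reads after read-end exclusion
    site_qual: float
    n_kept: int = 0
    n_dropped: int = 0

    def __post_init__(self):
        if self.alt_support > self.total_depth:
            raise ValidationError("alt_support cannot exceed total depth")


@dataclass
class EditingSite:
    position: GenomicPosition
    genomic_change: str       # e.g. "A>G" on the forward genomic strand
    resolved_type: str        # e.g. "A-to-I" after strand resolution
    putative: bool = False    # unstranded antisense assumption
    filter_trace: list[tuple[str, bool]] = field(default_factory=list)
    cluster_id: str | None = None
    gene_id: str = ""


@dataclass
class ClusterRegion:
    chrom: str
    start: int
    end: int
    members: list[str]        # site ids (chrom:pos)


# ---------------------------------------------------------------------------
# Per-sample candidate calling
# ---------------------------------------------------------------------------

def filter_read_end(observations: Iterable[AlleleObservation],
                    k: int = 6) -> list[AlleleObservation]:
    """Drop observations within k bp of either read end.

    An observation at 1-based offset o in a read of length L is kept iff
    o > k and L - o + 1 > k.
    """
    kept = []
    for o in observations:
        if not 1 <= o.offset <= o.readlen:
            raise ValidationError(
                f"offset {o.offset} outside read of length {o.readlen}"
            )
        if o.offset > k and o.readlen - o.offset + 1 > k:
            kept.append(o)
    return kept


def call_candidates(site: PileupSite,
                    params: CallingParams) -> CandidateVariant | None:
    """Apply the stringent per-site calling rules to one pileup record.

    A site is emitted iff raw depth >= min_depth, exactly one alternative
    allele is observed (an allele counts as observed when it retains at
    least one high-quality read away from the read ends), the site quality
    exceeds min_site_qual, and at least min_alt_reads high-quality,
    end-excluded reads support the variant.
    """
    depth = site.depth
    if depth < params.min_depth:
        return None
    alt_blocks = {
        b: blk for b, blk in site.alleles.items()
        if b != site.ref_base and blk.count > 0
    }
    if not alt_blocks:
        return None
    # cheap bound: no alt allele can possibly reach min_alt_reads
    if max(blk.count for blk in alt_blocks.values()) < params.min_alt_reads:
        return None

    k = params.read_end_exclusion_bp
    observed: dict[str, list[AlleleObservation]] = {}
    dropped = 0
    for base, blk in alt_blocks.items():
        kept = [
            o for o in filter_read_end(blk.observations, k)
            if o.qual > params.min_site_qual
        ]
        dropped += blk.count - len(kept)
        if kept:
            observed[base] = kept
    if len(observed) != params.max_alt_alleles:
        return None
    alt, kept = next(iter(observed.items()))
    if len(kept) < params.min_alt_reads:
        return None
    site_qual = float(np.mean([o.qual for o in kept]))
    if not site_qual > params.min_site_qual:
        return None
    return CandidateVariant(
        position=GenomicPosition(site.chrom, site.pos, site.strand_hint),
        ref_allele=site.ref_base,
        alt_allele=alt,
        total_depth=depth,
        alt_support=len(kept),
        site_qual=site_qual,
        n_kept=len(kept),
        n_dropped=dropped,
    )


def call_sample(pileup: Iterable[PileupSite],
                params: CallingParams) -> list[CandidateVariant]:
    out = []
    for site in pileup:
        cand = call_candidates(site, params)
        if cand is not None:
            out.append(cand)
    return out


def aggregate_candidates(per_sample: dict[str, list[CandidateVariant]]) -> pd.DataFrame:
    """Pool per-sample candidates into one row per (chrom, pos, ref, alt).

    If different samples support different alt alleles at the same position
    (rare, error-driven), the allele with the most supporting samples wins.
    """
    counter: dict[tuple, dict] = {}
    for sample, cands in per_sample.items():
        for c in cands:
            key = (c.position.chrom, c.position.pos, c.ref_allele, c.alt_allele)
            rec = counter.setdefault(
                key,
                {"strand_hint": c.position.strand, "n_samples": 0, "quals": []},
            )
            rec["n_samples"] += 1
            rec["quals"].append(c.site_qual)
    best: dict[tuple, tuple] = {}
    for (chrom, pos, ref, alt), rec in counter.items():
        cur = best.get((chrom, pos))
        if cur is None or rec["n_samples"] > cur[1]["n_samples"]:
            best[(chrom, pos)] = ((ref, alt), rec)
    rows = []
    for (chrom, pos), ((ref, alt), rec) in sorted(best.items()):
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "strand_hint": rec["strand_hint"],
                "n_samples": rec["n_samples"],
                "mean_site_qual": float(np.mean(rec["quals"])),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "strand_hint", "n_samples",
                 "mean_site_qual"],
    )
    df["site_id"] = df["chrom"] + ":" + df["pos"].astype(str)
    return df.set_index("site_id")


# ---------------------------------------------------------------------------
# Independent false-positive filters (pure predicates)
# ---------------------------------------------------------------------------

def _index_variants(records: Sequence[VariantCallRecord]):
    idx = defaultdict(list)
    for r in records:
        idx[(r.position.chrom, r.position.pos)].append(r)
    return idx


def passes_genomic_evidence(chrom, pos, ref, alt, wgs_idx, wgbs_idx,
                            dbsnp_pos: set) -> bool:
    """False iff DNA evidence says the substitution is germline.

    A candidate fails when (a) WGS or WGBS genotypes the same substitution
    as het or hom_alt — bisulfite-blind (unknown) WGBS genotypes are
    ignored — or (b) its position is in the known-SNP catalog.
    """
    if (chrom, pos) in dbsnp_pos:
        return False
    for idx in (wgs_idx, wgbs_idx):
        for rec in idx.get((chrom, pos), ()):
            if (
                rec.ref_allele == ref
                and rec.alt_allele == alt
                and rec.genotype in ("het", "hom_alt")
            ):
                return False
    return True


def filter_genomic_evidence(candidates: pd.DataFrame,
                            wgs: Sequence[VariantCallRecord],
                            wgbs: Sequence[VariantCallRecord],
                            dbsnp: Sequence[VariantCallRecord] | set) -> pd.Series:
    """Boolean keep-mask over the candidate table."""
    wgs_idx, wgbs_idx = _index_variants(wgs), _index_variants(wgbs)
    if isinstance(dbsnp, set):
        dbsnp_pos = dbsnp
    else:
        dbsnp_pos = {(r.position.chrom, r.position.pos) for r in dbsnp}
    return pd.Series(
        [
            passes_genomic_evidence(r.chrom, r.pos, r.ref, r.alt,
                                    wgs_idx, wgbs_idx, dbsnp_pos)
            for r in candidates.itertuples()
        ],
        index=candidates.index,
    )


class GeneIndex:
    """Per-chromosome interval lookup over transcript models."""

    def __init__(self, models: Sequence[GeneModel]):
        from intervaltree import IntervalTree

        self._trees: dict[str, object] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            tree[m.start : m.end + 1] = m

    def overlapping(self, chrom, pos) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[pos]),
                      key=lambda m: m.transcript_id)


def passes_splice_proximity(chrom, pos, gene_index: GeneIndex, k: int = 4) -> bool:
    """False iff the site is intronic and within k bp of a splice junction.

    A site exonic in any overlapping transcript is treated as exonic.
    """
    models = gene_index.overlapping(chrom, pos)
    if not models:
        return True
    dists = []
    for m in models:
        f = m.feature_at(pos)
        if f != "intron":
            return True
        dists.append(m.splice_distance(pos))
    return min(d for d in dists if d is not None) > k


def passes_homopolymer(chrom, pos, genome: dict[str, str], min_run: int = 5) -> bool:
    """False iff the reference base at pos sits in a run of >= min_run."""
    seq = genome[chrom]
    if not 1 <= pos <= len(seq):
        raise ValidationError(f"{chrom}:{pos} beyond contig end ({len(seq)})")
    b = seq[pos - 1]
    lo = pos - 1
    while lo > 0 and seq[lo - 1] == b:
        lo -= 1
    hi = pos - 1
    while hi < len(seq) - 1 and seq[hi + 1] == b:
        hi += 1
    return (hi - lo + 1) < min_run


def passes_mappability(chrom, pos, mask_df) -> bool:
    """False iff pos lies inside a masked (low-mappability/paralog) region."""
    if mask_df is None or len(mask_df) == 0:
        return True
    sub = mask_df[mask_df.chrom == chrom]
    return not ((sub.start <= pos) & (pos <= sub.end)).any()


# ---------------------------------------------------------------------------
# Strand-aware type classification
# ---------------------------------------------------------------------------

def resolve_type(ref: str, alt: str, strand: str) -> str:
    """Map a genomic substitution to the transcribed-strand editing type."""
    if strand == "-":
        ref, alt = SENSE_COMPLEMENT[ref], SENSE_COMPLEMENT[alt]
    names = {("A", "G"): "A-to-I", ("C", "T"): "C-to-U", ("G", "A"): "G-to-A"}
    return names.get((ref, alt), f"{ref}-to-{alt}")


def classify_and_purge(candidates: pd.DataFrame,
                       gene_index: GeneIndex) -> list[EditingSite]:
    """Resolve strand from overlapping gene models and assign editing types.

    C-to-U and G-to-A calls are purged (bisulfite conversion makes the
    matching DNA genotypes unobservable, so they cannot be separated from
    germline variation); this applies to unstranded C>T/G>A as well.
    Unstranded T>C calls are retained as putative A-to-I under the
    antisense-transcription assumption, as are unstranded A>G calls.
    Opposite-strand gene overlap is resolved in favour of the strand whose
    type is A-to-I if exactly one qualifies, else the site is dropped.
    """
    out = []
    for r in candidates.itertuples():
        strands = {m.strand for m in gene_index.overlapping(r.chrom, r.pos)}
        putative = False
        if not strands:
            strand = "."
        elif len(strands) == 1:
            strand = next(iter(strands))
        else:
            a_to_i = [s for s in ("+", "-") if resolve_type(r.ref, r.alt, s) == "A-to-I"]
            if len(a_to_i) == 1:
                strand = a_to_i[0]
            else:
                continue  # strand_ambiguous
        if strand == ".":
            putative = True
            if (r.ref, r.alt) in (("C", "T"), ("G", "A")):
                continue  # bisulfite-confounded regardless of strand
            if (r.ref, r.alt) == ("T", "C"):
                rtype = "A-to-I"  # antisense assumption
            else:
                rtype = resolve_type(r.ref, r.alt, "+")
        else:
            rtype = resolve_type(r.ref, r.alt, strand)
            if rtype in ("C-to-U", "G-to-A"):
                continue
        out.append(
            EditingSite(
                position=GenomicPosition(r.chrom, r.pos, strand),
                genomic_change=f"{r.ref}>{r.alt}",
                resolved_type=rtype,
                putative=putative,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def detect_clusters(sites: Sequence[tuple[str, int]], window: int = 100,
                    min_sites: int = 3) -> list[ClusterRegion]:
    """Maximal merged regions of qualifying fixed-width windows.

    A window of width ``window`` starting at position p spans p..p+window-1;
    it qualifies when it contains >= min_sites sites. Overlapping qualifying
    windows (sharing at least one site) are merged into one region.
    """
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, pos in sites:
        by_chrom[chrom].append(pos)
    regions = []
    for chrom in sorted(by_chrom):
        pos = sorted(set(by_chrom[chrom]))
        n = len(pos)
        spans = []  # qualifying windows as index ranges [i, j]
        j = 0
        for i in range(n):
            if j < i:
                j = i
            while j + 1 < n and pos[j + 1] - pos[i] <= window - 1:
                j += 1
            if j - i + 1 >= min_sites:
                spans.append((i, j))
        merged = []
        for i, j in spans:
            if merged and i <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], j))
            else:
                merged.append((i, j))
        for i, j in merged:
            members = [f"{chrom}:{p}" for p in pos[i : j + 1]]
            regions.append(ClusterRegion(chrom, pos[i], pos[j], members))
    return regions


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

FILTER_NAMES = ("genomic_evidence", "splice_proximity", "homopolymer",
                "paralog_mask")


def run_calling(pileup_paths: dict[str, object],
                wgs: Sequence[VariantCallRecord],
                wgbs: Sequence[VariantCallRecord],
                dbsnp: Sequence[VariantCallRecord] | set,
                gene_models: Sequence[GeneModel],
                genome: dict[str, str],
                params: CallingParams | None = None,
                mappability_mask=None,
                filter_order: Sequence[str] = FILTER_NAMES) -> tuple[pd.DataFrame,
                                                                     list[ClusterRegion]]:
    """Run the full cascade and return (sites table, cluster regions).

    ``filter_order`` exists to demonstrate order-invariance; each filter is
    a pure predicate, so any permutation yields the same site set.
    """
    params = params or CallingParams()
    per_sample = {
        sample: call_sample(read_pileup(path), params)
        for sample, path in pileup_paths.items()
    }
    candidates = aggregate_candidates(per_sample)
    gene_index = GeneIndex(gene_models)

    predicates = {
        "genomic_evidence": lambda df: filter_genomic_evidence(df, wgs, wgbs, dbsnp),
        "splice_proximity": lambda df: pd.Series(
            [passes_splice_proximity(r.chrom, r.pos, gene_index,
                                     params.splice_exclusion_bp)
             for r in df.itertuples()], index=df.index),
        "homopolymer": lambda df: pd.Series(
            [passes_homopolymer(r.chrom, r.pos, genome, params.homopolymer_min_run)
             for r in df.itertuples()], index=df.index),
        "paralog_mask": lambda df: pd.Series(
            [passes_mappability(r.chrom, r.pos, mappability_mask)
             for r in df.itertuples()], index=df.index),
    }
    traces = {}
    keep = pd.Series(True, index=candidates.index)
    for name in filter_order:
        mask = predicates[name](candidates)
        traces[name] = mask
        keep &= mask

    survivors = candidates[keep]
    sites = classify_and_purge(survivors, gene_index)
    traces["type_purge"] = pd.Series(False, index=candidates.index)

    rows = []
    site_positions = []
    for s in sites:
        sid = f"{s.position.chrom}:{s.position.pos}"
        traces["type_purge"].loc[sid] = True
        site_positions.append((s.position.chrom, s.position.pos))
        rows.append(
            {
                "site_id": sid,
                "chrom": s.position.chrom,
                "pos": s.position.pos,
                "strand": s.position.strand,
                "change": s.genomic_change,
                "type": s.resolved_type,
                "putative": s.putative,
                "n_samples": int(candidates.loc[sid, "n_samples"]),
            }
        )
    table = pd.DataFrame(
        rows, columns=["site_id", "chrom", "pos", "strand", "change", "type",
                       "putative", "n_samples"]
    ).set_index("site_id")

    clusters = detect_clusters(site_positions, params.cluster_window_bp,
                               params.cluster_min_sites)
    table["cluster_id"] = ""
    for i, region in enumerate(clusters, 1):
        cid = f"CL{i:05d}"
        for sid in region.members:
            table.loc[sid, "cluster_id"] = cid
    trace_str = []
    for sid in table.index:
        parts = [f"{name}:{'pass' if traces[name].loc[sid] else 'fail'}"
                 for name in (*filter_order, "type_purge")]
        trace_str.append(";".join(parts))
    table["filter_trace"] = trace_str
    return table.sort_values(["chrom", "pos"]), clusters
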