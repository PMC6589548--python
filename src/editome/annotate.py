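"""Genic-feature annotation, coding consequences, repeats, sequence context,
hyper-edited genes, and cross-assembly liftover / conservation overlap."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .calling import ClusterRegion, GeneIndex
from .formats import Chain, GeneModel, revcomp

FEATURES = ("CDS", "3UTR", "5UTR", "ncRNA_exon", "intron", "intergenic")
# precedence when a site overlaps multiple transcripts
_FEATURE_RANK = {f: i for i, f in enumerate(FEATURES)}


@dataclass
class SiteAnnotation:
    feature: str
    consequence: str = "none"          # synonymous / missense / none
    aa_change: str | None = None       # e.g. "Q>R" for missense only
    gene_id: str = ""
    transcript_id: str = ""
    strand: str = "."
    repeat_family: str | None = None
    conserved_in: frozenset = frozenset()

    def __post_init__(self):
        if (self.consequence == "missense") != (self.aa_change is not None):
            raise ValueError("aa_change must be set iff consequence is missense")


def classify_feature(chrom: str, pos: int,
                     gene_index: GeneIndex) -> tuple[str, GeneModel | None]:
    """Highest-precedence feature among all overlapping transcripts.

    Precedence: CDS > 3'UTR > 5'UTR > ncRNA exon > intron > intergenic.
    Returns the feature and the transcript that assigned it.
    """
    best = ("intergenic", None)
    for m in gene_index.overlapping(chrom, pos):
        f = m.feature_at(pos)
        if f is not None and _FEATURE_RANK[f] < _FEATURE_RANK[best[0]]:
            best = (f, m)
    return best


def codon_consequence(chrom: str, pos: int, alt: str, model: GeneModel,
                      genome: dict[str, str]) -> tuple[str, str | None]:
    """Consequence of substituting ``alt`` (forward-genomic) at a CDS position.

    The substitution is mapped to the sense strand of the transcript (an
    A>G genomic change in a minus-strand gene edits T>C at the
    complementary sense position), the affected codon is mutated, and both
    codons are translated with the standard genetic code.
    """
    idx = model.cds_index_of(pos)
    if idx is None:
        return "none", None
    cds = model.cds_sequence(genome)
    if len(cds) % 3 != 0:
        import warnings

        warnings.warn(f"{model.transcript_id}: CDS length not divisible by 3")
        return "none", None
    sense_alt = alt if model.strand == "+" else revcomp(alt)
    codon_start = (idx // 3) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    within = idx - codon_start
    alt_codon = ref_codon[:within] + sense_alt + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous", None
    return "missense", f"{ref_aa}>{alt_aa}"


def repeat_overlap(chrom: str, pos: int, repeat_trees) -> str | None:
    """Repeat family at a position; longest-overlap (then first) tie-break."""
    tree = repeat_trees.get(chrom)
    if tree is None:
        return None
    hits = sorted(
        tree[pos],
        key=lambda iv: (-(iv.end - iv.begin), iv.begin),
    )
    return hits[0].data if hits else None


def build_repeat_trees(repeats: pd.DataFrame):
    from intervaltree import IntervalTree

    label_col = "family" if "family" in repeats.columns else "name"
    trees: dict[str, object] = {}
    for _, r in repeats.iterrows():
        trees.setdefault(r["chrom"], IntervalTree())[
            r["start"] : r["end"] + 1
        ] = r[label_col]
    return trees


def hyper_edited_genes(sites: pd.DataFrame, clusters: list[ClusterRegion],
                       gene_models: list[GeneModel],
                       min_sites: int = 5) -> pd.DataFrame:
    """Genes with >= min_sites assigned sites and >= 1 cluster within the span."""
    spans = {}
    for m in gene_models:
        s, e = spans.get(m.gene_id, (m.start, m.end))
        spans[m.gene_id] = (min(s, m.start), max(e, m.end))
    chrom_of = {m.gene_id: m.chrom for m in gene_models}
    site_counts = Counter(g for g in sites["gene_id"] if g)
    rows = []
    for gid, n_sites in sorted(site_counts.items()):
        if n_sites < min_sites:
            continue
        lo, hi = spans[gid]
        n_clusters = sum(
            1 for c in clusters
            if c.chrom == chrom_of[gid] and lo <= c.start and c.end <= hi
        )
        if n_clusters >= 1:
            rows.append({"gene_id": gid, "n_sites": n_sites,
                         "n_clusters": n_clusters})
    return pd.DataFrame(rows, columns=["gene_id", "n_sites", "n_clusters"])


@dataclass
class ContextProfile:
    """Per-position nucleotide frequencies around edited adenosines."""

    frequencies: pd.DataFrame   # index: offset -k..k, columns: A/C/G/T
    n_sites: int
    n_excluded: int = 0


def context_profile(sites: pd.DataFrame, genome: dict[str, str],
                    k: int = 3) -> ContextProfile:
    """Nucleotide context of edited sites, oriented so the edit is always A.

    Minus-strand sites are reverse-complemented before counting; sites whose
    flank would run off the contig are excluded (and counted).
    """
    counts = np.zeros((2 * k + 1, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    used = excluded = 0
    for r in sites.itertuples():
        seq = genome[r.chrom]
        if r.pos - k < 1 or r.pos + k > len(seq):
            excluded += 1
            continue
        flank = seq[r.pos - 1 - k : r.pos + k]
        if r.strand == "-":
            flank = revcomp(flank)
        used += 1
        for i, b in enumerate(flank):
            if b in base_idx:
                counts[i, base_idx[b]] += 1
    if used:
        counts /= used
    freq = pd.DataFrame(counts, index=range(-k, k + 1), columns=list("ACGT"))
    return ContextProfile(frequencies=freq, n_sites=used, n_excluded=excluded)


# ---------------------------------------------------------------------------
# Liftover and conservation
# ---------------------------------------------------------------------------

class LiftOver:
    """Coordinate mapping through chained alignments.

    When several chains cover the same source position, the highest-score
    chain wins.
    """

    def __init__(self, chains: list[Chain]):
        self.chains = sorted(chains, key=lambda c: -c.score)

    def map_position(self, chrom: str, pos: int) -> tuple[str, int, str] | None:
        for chain in self.chains:
            if chain.t_name != chrom:
                continue
            hit = chain.map_position(pos)
            if hit is not None:
                return chain.q_name, hit[0], hit[1]
        return None


def liftover_sites(sites: pd.DataFrame, chains: list[Chain]) -> pd.DataFrame:
    lo = LiftOver(chains)
    rows = []
    for r in sites.itertuples():
        hit = lo.map_position(r.chrom, r.pos)
        rows.append(
            {"site_id": r.Index, "mapped": hit is not None,
             "target_chrom": hit[0] if hit else "",
             "target_pos": hit[1] if hit else 0,
             "target_strand": hit[2] if hit else "."}
        )
    return pd.DataFrame(rows).set_index("site_id")


def conserved_overlap(mapped: pd.DataFrame, catalog: pd.DataFrame) -> pd.Series:
    """Exact-position membership of mapped sites in a known-editing catalog.

    The catalog is a BED-derived frame (1-based inclusive); single-base
    records are matched exactly, wider records by containment.
    """
    if len(catalog) == 0:
        return pd.Series(False, index=mapped.index)
    keys = set()
    for r in catalog.itertuples():
        for p in range(r.start, r.end + 1):
            keys.add((r.chrom, p))
    return pd.Series(
        [
            bool(r.mapped) and (r.target_chrom, r.target_pos) in keys
            for r in mapped.itertuples()
        ],
        index=mapped.index,
    )


# ---------------------------------------------------------------------------
# Whole-table annotation
# ---------------------------------------------------------------------------

def annotate_sites(sites: pd.DataFrame, gene_models: list[GeneModel],
                   genome: dict[str, str],
                   repeats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Add feature / consequence / repeat columns to a called-sites table."""
    gene_index = GeneIndex(gene_models)
    repeat_trees = build_repeat_trees(repeats) if repeats is not None else {}
    rows = []
    for r in sites.itertuples():
        feature, model = classify_feature(r.chrom, r.pos, gene_index)
        consequence, aa = "none", ""
        gene_id = model.gene_id if model else ""
        tid = model.transcript_id if model else ""
        if feature == "CDS":
            alt = r.change.split(">")[1] if hasattr(r, "change") else r.alt
            consequence, aa_change = codon_consequence(
                r.chrom, r.pos, alt, model, genome
            )
            aa = aa_change or ""
        fam = repeat_overlap(r.chrom, r.pos, repeat_trees) if repeat_trees else None
        rows.append(
            {"feature": feature, "consequence": consequence, "aa_change": aa,
             "gene_id": gene_id, "transcript_id": tid,
             "repeat_family": fam or ""}
        )
    extra = pd.DataFrame(rows, index=sites.index)
    return pd.concat([sites, extra], axis=1)


def feature_fractions(annotated: pd.DataFrame) -> pd.Series:
    counts = annotated["feature"].value_counts()
    return counts / counts.sum()
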