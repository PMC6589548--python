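"""Readers and writers for the text formats the pipeline exchanges.

Coordinate convention: everything held in memory is 1-based inclusive.
BED is converted at the I/O boundary (0-based half-open on disk) and UCSC
chain arithmetic is kept 0-based internally to the parser but exposes
1-based positions. All text readers transparently accept gzip (``.gz``).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

STRANDS = ("+", "-", ".")
COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FormatError(ValueError):
    """A file does not follow its declared dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


def xopen(path, mode: str = "rt"):
    """Open a possibly gzip-compressed text file."""
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Core positional types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicPosition:
    """A single 1-based genomic coordinate with optional strand."""

    chrom: str
    pos: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")


# ---------------------------------------------------------------------------
# Pileup TSV
# ---------------------------------------------------------------------------
#
# One line per covered site:
#   chrom  pos  ref_base  strand_hint  BASE:count:q,o,L|q,o,L|...  [more blocks]
# Each observation is "qual,offset,readlen" with offset 1-based from the
# read start. A block with count 0 has an empty observation list.

@dataclass(frozen=True)
class AlleleObservation:
    """One read's evidence for an allele at a site."""

    qual: int
    offset: int
    readlen: int

    def __post_init__(self):
        if self.readlen < 1:
            raise ValidationError(f"readlen must be >= 1, got {self.readlen}")
        if not 1 <= self.offset <= self.readlen:
            raise ValidationError(
                f"offset {self.offset} outside read of length {self.readlen}"
            )
        if self.qual < 0:
            raise ValidationError("negative base quality")


class AlleleBlock:
    """Per-allele observation list; raw text is parsed lazily.

    Deferring the per-observation parse matters: most pileup lines are
    rejected by cheap count-level checks during calling and never need
    their observations materialised.
    """

    __slots__ = ("count", "_raw", "_obs")

    def __init__(self, observations=None, raw=None, count=None):
        if observations is not None:
            self._obs = list(observations)
            self.count = len(self._obs)
            self._raw = None
        else:
            self._obs = None
            self._raw = raw or ""
            self.count = int(count)

    @property
    def observations(self) -> list[AlleleObservation]:
        if self._obs is None:
            obs = []
            if self._raw:
                for token in self._raw.split("|"):
                    parts = token.split(",")
                    if len(parts) != 3:
                        raise FormatError(f"bad observation token {token!r}")
                    obs.append(
                        AlleleObservation(int(parts[0]), int(parts[1]), int(parts[2]))
                    )
            if len(obs) != self.count:
                raise FormatError(
                    f"allele block count {self.count} != {len(obs)} observations"
                )
            self._obs = obs
        return self._obs

    def __eq__(self, other):
        return (
            isinstance(other, AlleleBlock)
            and self.count == other.count
            and self.observations == other.observations
        )

    def __repr__(self):
        return f"AlleleBlock(count={self.count})"


@dataclass
class PileupSite:
    """Stranded per-site read evidence, the substrate of all filters."""

    chrom: str
    pos: int
    ref_base: str
    strand_hint: str
    alleles: dict[str, AlleleBlock]

    @property
    def depth(self) -> int:
        return sum(b.count for b in self.alleles.values())

    def observations(self, base: str) -> list[AlleleObservation]:
        block = self.alleles.get(base)
        return block.observations if block is not None else []


def read_pileup(path) -> Iterator[PileupSite]:
    """Stream PileupSite records from a pileup TSV."""
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}: line {lineno}: expected >= 4 fields")
            chrom, pos_s, ref, strand = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad position {pos_s!r}") from exc
            if strand not in STRANDS:
                raise FormatError(f"{path}: line {lineno}: bad strand {strand!r}")
            alleles: dict[str, AlleleBlock] = {}
            for block in fields[4:]:
                parts = block.split(":", 2)
                if len(parts) != 3 or len(parts[0]) != 1:
                    raise FormatError(f"{path}: line {lineno}: bad allele block {block!r}")
                base, count_s, raw = parts
                try:
                    count = int(count_s)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: bad count in {block!r}"
                    ) from exc
                alleles[base] = AlleleBlock(raw=raw, count=count)
            yield PileupSite(chrom, pos, ref, strand, alleles)


def write_pileup(sites: Iterable[PileupSite], path) -> None:
    with xopen(path, "wt") as fh:
        for site in sites:
            blocks = []
            for base in sorted(site.alleles):
                blk = site.alleles[base]
                obs = "|".join(
                    f"{o.qual},{o.offset},{o.readlen}" for o in blk.observations
                )
                blocks.append(f"{base}:{blk.count}:{obs}")
            fh.write(
                "\t".join(
                    [site.chrom, str(site.pos), site.ref_base, site.strand_hint]
                    + blocks
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Gene models / GTF
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One transcript: exons and CDS as sorted 1-based inclusive intervals.

    Exons are stored in ascending genomic order regardless of strand;
    transcription order is derived from ``strand`` where needed.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "protein_coding"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene strand must be +/-, got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        for c in self.cds:
            if not any(s <= c[0] and c[1] <= e for s, e in self.exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS {c} not contained in an exon"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def feature_at(self, pos: int) -> str | None:
        """Feature of ``pos`` within this transcript, or None if outside."""
        if not self.contains(pos):
            return None
        in_exon = any(s <= pos <= e for s, e in self.exons)
        if not in_exon:
            return "intron"
        if not self.cds:
            return "ncRNA_exon"
        if any(s <= pos <= e for s, e in self.cds):
            return "CDS"
        cds_lo, cds_hi = self.cds[0][0], self.cds[-1][1]
        if pos < cds_lo:
            return "5UTR" if self.strand == "+" else "3UTR"
        if pos > cds_hi:
            return "3UTR" if self.strand == "+" else "5UTR"
        return "ncRNA_exon"  # exonic gap between CDS segments; not produced by our models

    def splice_distance(self, pos: int) -> int | None:
        """Distance from an intronic position to the nearest exon boundary.

        Returns None for positions that are not intronic in this transcript.
        """
        if self.feature_at(pos) != "intron":
            return None
        dist = None
        for s, e in self.exons:
            if e < pos:
                d = pos - e
            elif s > pos:
                d = s - pos
            else:
                continue
            dist = d if dist is None else min(dist, d)
        return dist

    def cds_sequence(self, genome: dict[str, str]) -> str:
        """Spliced CDS in translation order (reverse-complemented for minus)."""
        seq = "".join(genome[self.chrom][s - 1 : e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_index_of(self, pos: int) -> int | None:
        """0-based index of a genomic position within the spliced CDS."""
        if not any(s <= pos <= e for s, e in self.cds):
            return None
        offset = 0
        for s, e in self.cds:
            if s <= pos <= e:
                idx = offset + (pos - s)
                break
            offset += e - s + 1
        else:  # pragma: no cover
            return None
        if self.strand == "-":
            total = sum(e - s + 1 for s, e in self.cds)
            idx = total - 1 - idx
        return idx


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf(path) -> list[GeneModel]:
    """Assemble per-transcript models from exon/CDS features of a GTF."""
    exons: dict[str, dict] = {}
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 fields")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature not in ("exon", "CDS"):
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            tid = attr.get("transcript_id")
            if tid is None:
                raise FormatError(f"{path}: line {lineno}: missing transcript_id")
            rec = exons.setdefault(
                tid,
                {
                    "gene_id": attr.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attr.get("gene_biotype", "protein_coding"),
                    "exons": [],
                    "cds": [],
                },
            )
            interval = (int(start), int(end))
            rec["exons" if feature == "exon" else "cds"].append(interval)
    models = []
    for tid, rec in exons.items():
        models.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                cds=rec["cds"],
                biotype=rec["biotype"],
            )
        )
    return models


def write_gtf(models: Sequence[GeneModel], path) -> None:
    with xopen(path, "wt") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'gene_biotype "{m.biotype}";'
            )
            rows = [("exon", s, e, ".") for s, e in m.exons]
            # frame: bases to the next codon start, accumulated in translation order
            cds_t = m.cds if m.strand == "+" else m.cds[::-1]
            cum = 0
            frames = []
            for s, e in cds_t:
                frames.append((s, e, (3 - cum % 3) % 3))
                cum += e - s + 1
            rows += [("CDS", s, e, str(f)) for s, e, f in frames]
            rows.sort(key=lambda r: (r[1], r[0]))
            for feature, s, e, frame in rows:
                fh.write(
                    f"{m.chrom}\teditome\t{feature}\t{s}\t{e}\t.\t{m.strand}\t{frame}\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# Minimal VCF
# ---------------------------------------------------------------------------

GENOTYPES = ("hom_ref", "het", "hom_alt", "unknown")


@dataclass(frozen=True)
class VariantCallRecord:
    """One biallelic DNA variant call consumed from an upstream caller."""

    position: GenomicPosition
    ref_allele: str
    alt_allele: str
    genotype: str
    depth: int = 0
    qual: float = 0.0

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref and alt alleles must differ")
        if self.genotype not in GENOTYPES:
            raise ValidationError(f"genotype must be one of {GENOTYPES}")
        if self.depth < 0:
            raise ValidationError("negative depth")


def _genotype_for_alt(gt: tuple, alt_index: int) -> str:
    if gt is None or any(a is None for a in gt):
        return "unknown"
    hits = sum(1 for a in gt if a == alt_index)
    if hits == 0:
        return "hom_ref"
    if hits == len(gt):
        return "hom_alt"
    return "het"


def read_vcf_min(path) -> list[VariantCallRecord]:
    """Read CHROM/POS/REF/ALT/QUAL/GT/DP; multi-allelic records are split."""
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vf:
        has_samples = len(vf.header.samples) > 0
        for rec in vf:
            gt = None
            depth = 0
            try:
                info_dp = rec.info.get("DP", 0) or 0
            except ValueError:  # DP absent from the header definitions
                info_dp = 0
            if has_samples:
                sample = rec.samples[0]
                gt = sample.get("GT")
                depth = sample.get("DP") or info_dp
            else:
                depth = info_dp
            for i, alt in enumerate(rec.alts or (), start=1):
                if alt is None or len(alt) != 1 or len(rec.ref) != 1:
                    continue  # SNVs only
                records.append(
                    VariantCallRecord(
                        position=GenomicPosition(rec.chrom, rec.pos),
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        genotype=_genotype_for_alt(gt, i) if has_samples else "unknown",
                        depth=int(depth),
                        qual=float(rec.qual) if rec.qual is not None else 0.0,
                    )
                )
    return records


_GT_CODE = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "unknown": "./."}


def write_vcf_min(records: Sequence[VariantCallRecord], path, contigs=None) -> None:
    with xopen(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        if contigs:
            for name, length in contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for r in sorted(records, key=lambda r: (r.position.chrom, r.position.pos)):
            fh.write(
                f"{r.position.chrom}\t{r.position.pos}\t.\t{r.ref_allele}\t"
                f"{r.alt_allele}\t{r.qual:g}\t.\t.\tGT:DP\t"
                f"{_GT_CODE[r.genotype]}:{r.depth}\n"
            )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read BED(3-6); coordinates converted to 1-based inclusive."""
    rows = []
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 BED fields")
            rows.append(
                {
                    "chrom": f[0],
                    "start": int(f[1]) + 1,
                    "end": int(f[2]),
                    "name": f[3] if len(f) > 3 else ".",
                    "score": float(f[4]) if len(f) > 4 and f[4] != "." else 0.0,
                    "strand": f[5] if len(f) > 5 else ".",
                }
            )
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path) -> None:
    with xopen(path, "wt") as fh:
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.name}\t"
                f"{row.score:g}\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# UCSC chain
# ---------------------------------------------------------------------------

@dataclass
class Chain:
    """One chained alignment between a source ('t') and target ('q') sequence.

    Coordinates follow the UCSC convention: 0-based half-open, and for a
    minus-strand side relative to the reverse-complemented sequence.
    ``blocks`` holds (size, dt, dq) triples; the last triple has dt=dq=0.
    """

    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list[tuple[int, int, int]]

    def validate(self):
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if any(b[0] <= 0 for b in self.blocks):
            raise FormatError(f"chain {self.chain_id}: non-positive block size")
        if sizes + dts != self.t_end - self.t_start:
            raise FormatError(f"chain {self.chain_id}: source span inconsistent")
        if sizes + dqs != self.q_end - self.q_start:
            raise FormatError(f"chain {self.chain_id}: target span inconsistent")

    def map_position(self, pos: int) -> tuple[int, str] | None:
        """Map a 1-based source position to (1-based target position, strand).

        Positions falling in a gap (or outside the chain span) are unmapped.
        """
        p0 = pos - 1
        if not self.t_start <= p0 < self.t_end:
            return None
        t, q = self.t_start, self.q_start
        for size, dt, dq in self.blocks:
            if t <= p0 < t + size:
                q0 = q + (p0 - t)
                if self.q_strand == "+":
                    return q0 + 1, "+"
                return self.q_size - q0, "-"
            t += size + dt
            q += size + dq
        return None


def read_chain(path) -> list[Chain]:
    chains: list[Chain] = []
    current: Chain | None = None
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                f = line.split()
                if len(f) != 13:
                    raise FormatError(f"{path}: line {lineno}: bad chain header")
                current = Chain(
                    score=float(f[1]),
                    t_name=f[2], t_size=int(f[3]), t_strand=f[4],
                    t_start=int(f[5]), t_end=int(f[6]),
                    q_name=f[7], q_size=int(f[8]), q_strand=f[9],
                    q_start=int(f[10]), q_end=int(f[11]),
                    chain_id=f[12], blocks=[],
                )
                chains.append(current)
            else:
                if current is None:
                    raise FormatError(f"{path}: line {lineno}: data before chain header")
                f = line.split()
                if len(f) == 3:
                    current.blocks.append((int(f[0]), int(f[1]), int(f[2])))
                elif len(f) == 1:
                    current.blocks.append((int(f[0]), 0, 0))
                    current = None
                else:
                    raise FormatError(f"{path}: line {lineno}: bad alignment line")
    for c in chains:
        c.validate()
    return chains


def write_chain(chains: Sequence[Chain], path) -> None:
    with xopen(path, "wt") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} "
                f"{c.t_start} {c.t_end} {c.q_name} {c.q_size} {c.q_strand} "
                f"{c.q_start} {c.q_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


# ---------------------------------------------------------------------------
# FASTA / matrices
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    with xopen(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with xopen(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_mirna_fasta(path) -> dict[str, str]:
    """Mature miRNA sequences; RNA or DNA alphabet accepted, U normalised to T."""
    seqs = read_fasta(path)
    return {name: s.replace("U", "T") for name, s in seqs.items()}


def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV with a header row of sample IDs."""
    df = pd.read_csv(xopen(path), sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    return df


def write_matrix(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(xopen(path, "wt"), sep="\t", float_format=float_format)


def read_level_matrix(path) -> pd.DataFrame:
    """Sites x samples editing-level TSV (empty cells = missing)."""
    return pd.read_csv(xopen(path), sep="\t", index_col=0)
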