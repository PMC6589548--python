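"""Synthetic multi-omic data with known truth.

Emulates the study design the pipeline targets: 27 developmental stages of
pig skeletal muscle with 3 biological replicates each (81 RNA libraries),
one WGS and one WGBS DNA call set, a genome with multi-exon genes, SINE-like
repeats, homopolymer tracts, clustered editing sites inside repeats,
germline het/hom SNPs (WGBS bisulfite-blind for C>T/G>A), and sequencing
errors enriched near read ends.

Editing levels follow a Beta baseline (mean 4.6%, the average editing rate
reported for mammalian skeletal muscle) and developmental sites follow a
monotone logistic trend in days post-conception. Every alternative read in
the emitted pileups is attributable to exactly one of editing / SNP / error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import formats
from .formats import GeneModel, GenomicPosition, VariantCallRecord

BASES = np.frombuffer(b"ACGT", dtype="S1")
BASE_STR = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASE_STR)}
COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G

PRENATAL_DAYS = [33, 40, 45, 50, 55, 60, 65, 70, 75, 80, 85, 90, 95, 100, 105]
POSTNATAL_DAYS = [0, 9, 20, 30, 40, 60, 80, 100, 120, 140, 160, 180]
GESTATION_DAYS = 114
STOP_FIX = {"TAA": "TAC", "TAG": "TAC", "TGA": "TGC"}


class CapacityError(RuntimeError):
    """Requested features exceed what the configured genome can host."""


class PlacementError(RuntimeError):
    """A feature could not be placed after the retry budget."""


def stage_table(n_stages: int = 27) -> pd.DataFrame:
    """Stage labels, 1-based index, and age in days post-conception.

    Embryonic day E<d> maps to d; postnatal day D<d> maps to gestation
    (114 d) + d, so development is a single continuous axis.
    """
    labels = [f"E{d}" for d in PRENATAL_DAYS] + [f"D{d}" for d in POSTNATAL_DAYS]
    days = PRENATAL_DAYS + [GESTATION_DAYS + d for d in POSTNATAL_DAYS]
    if not 1 <= n_stages <= len(labels):
        raise ValueError(f"n_stages must be in [1, {len(labels)}]")
    return pd.DataFrame(
        {
            "stage_index": np.arange(1, n_stages + 1),
            "stage_label": labels[:n_stages],
            "stage_days": days[:n_stages],
        }
    )


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the desk-scale study conditions."""

    seed: int = 42
    # genome & annotation
    n_chroms: int = 2
    chrom_length: int = 500_000
    n_genes: int = 40
    n_repeats: int = 260
    repeat_length_range: tuple[int, int] = (120, 300)
    n_homopolymers_per_chrom: int = 20
    # editing sites
    n_editing_sites: int = 2000
    frac_developmental: float = 0.10
    frac_in_repeats: float = 0.95
    frac_clustered: float = 0.70
    cluster_size_range: tuple[int, int] = (3, 6)
    frac_cds_sites: float = 0.005
    level_beta_mean: float = 0.046
    level_beta_conc: float = 4.0
    dev_level_beta_mean: float = 0.25
    dev_level_beta_conc: float = 8.0
    trend_logit_amplitude: float = 1.5
    frac_decreasing: float = 0.7
    context_g_downstream: float = 0.5
    context_g_upstream: float = 0.044
    # samples
    n_stages: int = 27
    replicates_per_stage: int = 3
    sex_assignment: tuple[str, ...] | None = None  # per stage; default alternates M/F
    # sequencing model
    read_length: int = 150
    mean_depth: float = 50.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.002
    end_error_multiplier: float = 10.0
    end_region_bp: int = 6
    base_qual_mean: float = 37.0
    base_qual_sd: float = 3.0
    error_qual_mean: float = 28.0
    error_qual_sd: float = 6.0
    # germline variation
    n_het_snps: int = 150
    n_hom_snps: int = 100
    frac_snps_in_dbsnp: float = 0.7
    dna_depth: float = 47.0
    # background (reference-only) pileup positions
    n_background_sites: int = 1000
    # miRNA panel
    n_mirnas: int = 20

    def __post_init__(self):
        for name in (
            "n_chroms", "chrom_length", "n_genes", "n_repeats", "n_editing_sites",
            "n_het_snps", "n_hom_snps", "n_background_sites", "n_mirnas",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "frac_developmental", "frac_in_repeats", "frac_clustered",
            "frac_snps_in_dbsnp", "frac_decreasing", "frac_cds_sites",
            "context_g_downstream", "context_g_upstream",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length <= self.read_length:
            raise ValueError("chrom_length must exceed read_length")

    @property
    def n_samples(self) -> int:
        return self.n_stages * self.replicates_per_stage

    def samples(self) -> pd.DataFrame:
        stages = stage_table(self.n_stages)
        if self.sex_assignment is not None:
            if len(self.sex_assignment) != self.n_stages:
                raise ValueError("sex_assignment must have one entry per stage")
            sexes = list(self.sex_assignment)
        else:
            sexes = ["M" if i % 2 == 0 else "F" for i in range(self.n_stages)]
        rows = []
        for _, st in stages.iterrows():
            for rep in range(1, self.replicates_per_stage + 1):
                rows.append(
                    {
                        "sample": f"{st.stage_label}_r{rep}",
                        "stage_index": int(st.stage_index),
                        "stage_label": st.stage_label,
                        "stage_days": int(st.stage_days),
                        "sex": sexes[int(st.stage_index) - 1],
                        "replicate": rep,
                    }
                )
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class Reference:
    genome: dict[str, np.ndarray]  # uint8 base codes, mutable until written
    genes: list[GeneModel]
    repeats: pd.DataFrame  # chrom, start, end, family, repeat_id
    homopolymers: list[tuple[str, int, int]]

    def sequences(self) -> dict[str, str]:
        return {
            c: arr.astype(np.uint8).tobytes().translate(
                bytes.maketrans(b"\x00\x01\x02\x03", b"ACGT")
            ).decode()
            for c, arr in self.genome.items()
        }


@dataclass
class TruthTable:
    """Ground truth for every planted feature."""

    sites: pd.DataFrame      # site_id, chrom, pos, strand, ref, alt, feature, ...
    levels: pd.DataFrame     # site_id x sample true editing level
    snps: pd.DataFrame       # chrom, pos, ref, alt, genotype, in_dbsnp
    background: pd.DataFrame # chrom, pos (reference-only pileup positions)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def _random_genome(rng, n_chroms, length) -> dict[str, np.ndarray]:
    return {
        f"chr{i + 1}": rng.integers(0, 4, size=length).astype(np.uint8)
        for i in range(n_chroms)
    }


def _build_gene(rng, chrom, cursor, strand) -> GeneModel | None:
    n_exons = int(rng.integers(2, 7))
    exon_lens = rng.integers(150, 400, size=n_exons)
    intron_lens = rng.integers(200, 1500, size=n_exons - 1)
    exons = []
    p = cursor
    for i, L in enumerate(exon_lens):
        exons.append((p, p + int(L) - 1))
        p = exons[-1][1] + 1 + (int(intron_lens[i]) if i < n_exons - 1 else 0)
    # UTR lengths in transcription order; 3'UTRs are roomy so they can host
    # repeats, clusters, and miRNA flanks
    utr5 = int(rng.integers(50, 140))
    utr3 = int(rng.integers(200, 391))
    order = exons if strand == "+" else exons[::-1]
    flat = []
    for s, e in order:
        if strand == "+":
            flat.extend(range(s, e + 1))
        else:
            flat.extend(range(e, s - 1, -1))
    cds_positions = flat[utr5 : len(flat) - utr3]
    n_keep = len(cds_positions) - len(cds_positions) % 3
    if n_keep < 30:
        return None
    cds_positions = cds_positions[:n_keep]
    cds_sorted = sorted(cds_positions)
    cds_intervals = []
    run_start = prev = cds_sorted[0]
    for x in cds_sorted[1:]:
        if x == prev + 1:
            prev = x
        else:
            cds_intervals.append((run_start, prev))
            run_start = prev = x
    cds_intervals.append((run_start, prev))
    return GeneModel(
        gene_id="", transcript_id="", chrom=chrom, strand=strand,
        exons=exons, cds=cds_intervals,
    )


def _patch_cds(genome, model, rng):
    """Force a start codon and remove in-frame stops so translation is clean."""
    positions = []  # genomic positions in translation order
    cds_t = model.cds if model.strand == "+" else model.cds[::-1]
    for s, e in cds_t:
        rng_pos = range(s, e + 1) if model.strand == "+" else range(e, s - 1, -1)
        positions.extend(rng_pos)
    arr = genome[model.chrom]

    def get(i):
        b = BASE_STR[arr[positions[i] - 1]]
        return b if model.strand == "+" else BASE_STR[COMP_IDX[BASE_INDEX[b]]]

    def put(i, base):
        code = BASE_INDEX[base]
        if model.strand == "-":
            code = COMP_IDX[code]
        arr[positions[i] - 1] = code

    for i, b in enumerate("ATG"):
        put(i, b)
    for c in range(1, len(positions) // 3):
        codon = get(3 * c) + get(3 * c + 1) + get(3 * c + 2)
        if codon in STOP_FIX:
            for k, b in enumerate(STOP_FIX[codon]):
                put(3 * c + k, b)


def _place_intervals(rng, hosts, n, length_range, max_tries=None,
                     host_weights=None):
    """Place n disjoint intervals inside host intervals, weighted by length
    (optionally scaled per host)."""
    if n == 0:
        return []
    if not hosts:
        raise CapacityError("no host intervals available for placement")
    weights = np.array([e - s + 1 for _, s, e in hosts], dtype=float)
    if host_weights is not None:
        weights *= np.asarray(host_weights, dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    tries = 0
    budget = max_tries or 200 * n
    while len(placed) < n:
        if tries > budget:
            raise CapacityError(
                f"placed only {len(placed)}/{n} intervals within the retry budget"
            )
        tries += 1
        chrom, hs, he = hosts[int(rng.choice(len(hosts), p=weights))]
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        if he - hs + 1 < L:
            continue
        s = int(rng.integers(hs, he - L + 2))
        e = s + L - 1
        if any(c == chrom and not (e < ps or s > pe) for c, ps, pe in placed):
            continue
        placed.append((chrom, s, e))
    return placed


def build_reference(config: SimulationConfig, rng=None) -> Reference:
    """Genome, gene models, repeat annotation, and homopolymer tracts."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    genome = _random_genome(rng, config.n_chroms, config.chrom_length)
    chroms = list(genome)

    genes: list[GeneModel] = []
    per_chrom = np.array_split(np.arange(config.n_genes), config.n_chroms)
    for ci, idxs in enumerate(per_chrom):
        cursor = 2000
        for _ in idxs:
            cursor += int(rng.integers(2000, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            model = _build_gene(rng, chroms[ci], cursor, strand)
            if model is None or model.end > config.chrom_length - 2000:
                raise CapacityError(
                    f"cannot fit {len(idxs)} genes on {chroms[ci]} "
                    f"of length {config.chrom_length}"
                )
            gid = f"GENE{len(genes) + 1:04d}"
            model.gene_id = gid
            model.transcript_id = gid + ".1"
            genes.append(model)
            cursor = model.end
    for m in genes:
        _patch_cds(genome, m, rng)

    # repeat hosts: introns, 3'UTR exon chunks, intergenic gaps (CDS excluded
    # by construction)
    hosts = []
    host_w = []  # genic hosts up-weighted so the editome is mostly intronic
    for m in genes:
        for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
            if s2 - e1 > 60:
                hosts.append((m.chrom, e1 + 10, s2 - 10))
                host_w.append(12.0)
        cds_lo, cds_hi = m.cds[0][0], m.cds[-1][1]
        for s, e in m.exons:
            if m.strand == "+" and e > cds_hi:
                hosts.append((m.chrom, max(s, cds_hi + 3), e))
                host_w.append(30.0)
            if m.strand == "-" and s < cds_lo:
                hosts.append((m.chrom, s, min(e, cds_lo - 3)))
                host_w.append(30.0)
    for c in chroms:
        spans = sorted((m.start, m.end) for m in genes if m.chrom == c)
        prev = 1000
        for s, e in spans:
            if s - prev > 2000:
                hosts.append((c, prev + 500, s - 500))
                host_w.append(1.0)
            prev = e
        if config.chrom_length - prev > 2000:
            hosts.append((c, prev + 500, config.chrom_length - 1000))
            host_w.append(1.0)
    host_w = [w for h, w in zip(hosts, host_w) if h[2] - h[1] > 50]
    hosts = [h for h in hosts if h[2] - h[1] > 50]

    repeat_iv = _place_intervals(rng, hosts, config.n_repeats,
                                 config.repeat_length_range, host_weights=host_w)
    fam_draw = rng.random(len(repeat_iv))
    families = np.where(
        fam_draw < 0.65, "SINE/Pre0_SS", np.where(fam_draw < 0.95, "SINE/tRNA", "LINE/L1")
    )
    repeats = pd.DataFrame(
        {
            "chrom": [c for c, _, _ in repeat_iv],
            "start": [s for _, s, _ in repeat_iv],
            "end": [e for _, _, e in repeat_iv],
            "family": families,
        }
    ).sort_values(["chrom", "start"], ignore_index=True)
    repeats["repeat_id"] = [f"REP{i + 1:04d}" for i in range(len(repeats))]

    # homopolymer tracts: outside CDS and repeats so they never collide with
    # the sites planted later (sites must themselves avoid homopolymers)
    homopolymers = []
    occupied = {c: np.zeros(config.chrom_length + 1, dtype=bool) for c in chroms}
    for m in genes:
        for s, e in m.cds:
            occupied[m.chrom][s : e + 1] = True
    for r in repeats.itertuples():
        occupied[r.chrom][r.start : r.end + 1] = True
    for c in chroms:
        placed = 0
        tries = 0
        while placed < config.n_homopolymers_per_chrom and tries < 5000:
            tries += 1
            L = int(rng.integers(5, 13))
            s = int(rng.integers(100, config.chrom_length - L - 100))
            if occupied[c][s - 1 : s + L + 1].any():
                continue
            base = int(rng.integers(0, 4))
            genome[c][s - 1 : s + L - 1] = base
            # break the run at both flanks
            for flank in (s - 2, s + L - 1):
                if genome[c][flank] == base:
                    genome[c][flank] = (base + 1) % 4
            occupied[c][s - 1 : s + L + 1] = True
            homopolymers.append((c, s, s + L - 1))
            placed += 1
        if placed == 0 and config.n_homopolymers_per_chrom > 0:
            raise CapacityError(f"could not place homopolymers on {c}")

    return Reference(genome=genome, genes=genes, repeats=repeats,
                     homopolymers=homopolymers)


# ---------------------------------------------------------------------------
# Feature planting
# ---------------------------------------------------------------------------

def _beta_params(mean, conc):
    return mean * conc, (1.0 - mean) * conc


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _run_length(arr, idx0):
    """Length of the maximal single-base run containing 0-based index idx0."""
    b = arr[idx0]
    lo = idx0
    while lo > 0 and arr[lo - 1] == b:
        lo -= 1
    hi = idx0
    while hi < len(arr) - 1 and arr[hi + 1] == b:
        hi += 1
    return hi - lo + 1


class _Planter:
    """Places editing sites and SNPs under the validity constraints."""

    MIN_SPACING = 3

    def __init__(self, config, reference, rng):
        self.cfg = config
        self.ref = reference
        self.rng = rng
        self.used: set[tuple[str, int]] = set()
        self.gene_lookup = sorted(
            reference.genes, key=lambda m: (m.chrom, m.start)
        )

    def gene_at(self, chrom, pos) -> GeneModel | None:
        for m in self.gene_lookup:
            if m.chrom == chrom and m.start <= pos <= m.end:
                return m
        return None

    def _free(self, chrom, pos):
        return all(
            (chrom, p) not in self.used
            for p in range(pos - self.MIN_SPACING, pos + self.MIN_SPACING + 1)
        )

    def _valid_editing_pos(self, chrom, pos, want_feature=None):
        cfg = self.cfg
        if not 60 <= pos <= cfg.chrom_length - 60:
            return None
        if not self._free(chrom, pos):
            return None
        gene = self.gene_at(chrom, pos)
        if gene is None:
            feature, strand = "intergenic", "."
        else:
            feature = gene.feature_at(pos)
            strand = gene.strand
            if feature == "intron":
                d = gene.splice_distance(pos)
                if d is not None and d <= 4:
                    return None
        if want_feature is not None and feature != want_feature:
            return None
        return feature, strand, gene

    def _apply_site(self, chrom, pos, strand):
        """Write the edited-strand A (or minus-strand T) and local context."""
        arr = self.ref.genome[chrom]
        sense_a, sense_g = ("A", "G") if strand != "-" else ("T", "C")
        arr[pos - 1] = BASE_INDEX[sense_a]
        up, dn = (pos - 2, pos) if strand != "-" else (pos, pos - 2)
        # downstream-G preference / upstream-G aversion, in sense orientation
        if (chrom, pos + (1 if strand != "-" else -1)) not in self.used:
            if self.rng.random() < self.cfg.context_g_downstream:
                arr[dn] = BASE_INDEX["G" if strand != "-" else "C"]
            elif BASE_STR[arr[dn]] in ("G" if strand != "-" else "C"):
                arr[dn] = BASE_INDEX["A" if strand != "-" else "T"]
        if (chrom, pos - (1 if strand != "-" else -1)) not in self.used:
            is_g = BASE_STR[arr[up]] == ("G" if strand != "-" else "C")
            if is_g and self.rng.random() > self.cfg.context_g_upstream:
                arr[up] = BASE_INDEX["C" if strand != "-" else "G"]
        if _run_length(arr, pos - 1) >= 5:
            return None  # would sit in a homopolymer after substitution
        ref_base = BASE_STR[arr[pos - 1]]
        alt_base = "G" if ref_base == "A" else "C"
        return ref_base, alt_base

    def reserve(self, chrom, pos):
        self.used.add((chrom, pos))

    def place_editing_site(self, in_repeat, want_feature=None, repeat_row=None,
                           window=None, max_tries=400):
        for _ in range(max_tries):
            if window is not None:
                chrom = window[0]
                pos = int(self.rng.integers(window[1], window[2] + 1))
            elif in_repeat and repeat_row is None:
                r = self.ref.repeats.iloc[int(self.rng.integers(len(self.ref.repeats)))]
                chrom, pos = r.chrom, int(self.rng.integers(r.start, r.end + 1))
            elif repeat_row is not None:
                chrom = repeat_row.chrom
                pos = int(self.rng.integers(repeat_row.start, repeat_row.end + 1))
            else:
                chrom = f"chr{int(self.rng.integers(1, self.cfg.n_chroms + 1))}"
                pos = int(self.rng.integers(100, self.cfg.chrom_length - 100))
            ok = self._valid_editing_pos(chrom, pos, want_feature)
            if ok is None:
                continue
            feature, strand, gene = ok
            applied = self._apply_site(chrom, pos, strand)
            if applied is None:
                continue
            ref_base, alt_base = applied
            self.reserve(chrom, pos)
            return {
                "chrom": chrom, "pos": pos, "strand": strand,
                "ref": ref_base, "alt": alt_base, "feature": feature,
                "gene_id": gene.gene_id if gene else "",
            }
        raise PlacementError("could not place an editing site within the retry budget")


def plant_editing_and_snps(config: SimulationConfig, reference: Reference,
                           rng=None) -> TruthTable:
    """Plant editing sites (with per-stage true levels) and germline SNPs."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    planter = _Planter(config, reference, rng)
    samples = config.samples()
    n = config.n_editing_sites

    rows = []
    # clustered sites inside repeats: >= 3 sites within a 100-bp window
    n_clustered_target = int(round(config.frac_clustered * n))
    cluster_id = 0
    long_repeats = reference.repeats[
        reference.repeats.end - reference.repeats.start + 1 >= 110
    ]
    if len(long_repeats) == 0:
        n_clustered_target = 0
    while sum(1 for r in rows if r["cluster_id"]) < n_clustered_target and len(rows) < n:
        cluster_id += 1
        size = int(rng.integers(config.cluster_size_range[0],
                                config.cluster_size_range[1] + 1))
        size = min(size, n - len(rows))
        if size < config.cluster_size_range[0]:
            break
        rep = long_repeats.iloc[int(rng.integers(len(long_repeats)))]
        span = min(99, rep.end - rep.start)
        w_start = int(rng.integers(rep.start, rep.end - span + 1))
        window = (rep.chrom, w_start, w_start + span)
        placed = []
        try:
            for _ in range(size):
                rec = planter.place_editing_site(
                    in_repeat=True, window=window, max_tries=200
                )
                rec["cluster_id"] = f"TRUTHCL{cluster_id:04d}"
                rec["repeat_id"] = rep.repeat_id
                rec["repeat_family"] = rep.family
                placed.append(rec)
        except PlacementError:
            pass
        if len(placed) >= config.cluster_size_range[0]:
            rows.extend(placed)
        # else: window too crowded; positions stay reserved, cluster skipped

    # singles: mostly inside repeats, a small CDS quota, the rest anywhere
    n_cds = int(round(config.frac_cds_sites * n))
    while len(rows) < n:
        try:
            if n_cds > 0 and reference.genes:
                rec = planter.place_editing_site(in_repeat=False, want_feature="CDS")
                n_cds -= 1
            elif len(reference.repeats) and rng.random() < config.frac_in_repeats:
                rec = planter.place_editing_site(in_repeat=True)
                r = reference.repeats
                hit = r[(r.chrom == rec["chrom"]) & (r.start <= rec["pos"])
                        & (r.end >= rec["pos"])]
                rec["repeat_id"] = hit.iloc[0].repeat_id if len(hit) else ""
                rec["repeat_family"] = hit.iloc[0].family if len(hit) else ""
            else:
                rec = planter.place_editing_site(in_repeat=False)
        except PlacementError:
            if n_cds > 0:
                n_cds = 0  # genome has no more room in CDS; fall back
                continue
            raise
        rec.setdefault("cluster_id", "")
        rec.setdefault("repeat_id", "")
        rec.setdefault("repeat_family", "")
        rows.append(rec)

    sites = pd.DataFrame(rows)
    sites["site_id"] = sites["chrom"] + ":" + sites["pos"].astype(str)
    sites = sites.set_index("site_id")

    # developmental trend assignment and level model
    n_dev = int(round(config.frac_developmental * n))
    dev_idx = rng.permutation(n)[:n_dev]
    is_dev = np.zeros(n, dtype=bool)
    is_dev[dev_idx] = True
    sites["developmental"] = is_dev
    sign = np.zeros(n)
    sign[is_dev] = np.where(rng.random(n_dev) < config.frac_decreasing, -1.0, 1.0)
    sites["trend_sign"] = sign.astype(int)

    a0, b0 = _beta_params(config.level_beta_mean, config.level_beta_conc)
    a1, b1 = _beta_params(config.dev_level_beta_mean, config.dev_level_beta_conc)
    base = rng.beta(a0, b0, size=n)
    base[is_dev] = rng.beta(a1, b1, size=n_dev)
    base = np.clip(base, 1e-4, 1.0 - 1e-4)
    sites["baseline_level"] = base

    days = samples["stage_days"].to_numpy(float)
    d0, d1 = days.min(), days.max()
    x = 2.0 * (days - d0) / max(d1 - d0, 1.0) - 1.0  # [-1, 1] across development
    logit0 = np.log(base / (1.0 - base))
    amp = config.trend_logit_amplitude
    levels = _logistic(
        logit0[:, None] + sign[:, None] * amp * x[None, :]
    )
    levels[~is_dev, :] = base[~is_dev, None]
    levels_df = pd.DataFrame(levels, index=sites.index, columns=samples.index)

    # germline SNPs, never co-located with editing sites
    snp_rows = []
    genos = ["het"] * config.n_het_snps + ["hom_alt"] * config.n_hom_snps
    tries = 0
    while len(snp_rows) < len(genos):
        if tries > 200 * max(len(genos), 1):
            raise PlacementError("could not place SNPs within the retry budget")
        tries += 1
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        pos = int(rng.integers(100, config.chrom_length - 100))
        if not planter._free(chrom, pos):
            continue
        arr = reference.genome[chrom]
        ref_base = BASE_STR[arr[pos - 1]]
        alt_base = BASE_STR[(BASE_INDEX[ref_base] + int(rng.integers(1, 4))) % 4]
        planter.reserve(chrom, pos)
        snp_rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref_base, "alt": alt_base,
                "genotype": genos[len(snp_rows)],
                "in_dbsnp": bool(rng.random() < config.frac_snps_in_dbsnp),
            }
        )
    snps = pd.DataFrame(
        snp_rows, columns=["chrom", "pos", "ref", "alt", "genotype", "in_dbsnp"]
    )

    # background positions: covered but reference-only (error substrate)
    bg_rows = []
    tries = 0
    while len(bg_rows) < config.n_background_sites and tries < 100 * max(
        config.n_background_sites, 1
    ):
        tries += 1
        chrom = f"chr{int(rng.integers(1, config.n_chroms + 1))}"
        pos = int(rng.integers(100, config.chrom_length - 100))
        if not planter._free(chrom, pos):
            continue
        planter.reserve(chrom, pos)
        bg_rows.append({"chrom": chrom, "pos": pos})
    background = pd.DataFrame(bg_rows, columns=["chrom", "pos"])

    return TruthTable(
        sites=sites.sort_values(["chrom", "pos"]),
        levels=levels_df.loc[sites.sort_values(["chrom", "pos"]).index],
        snps=snps.sort_values(["chrom", "pos"], ignore_index=True),
        background=background.sort_values(["chrom", "pos"], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Pileup / VCF emission
# ---------------------------------------------------------------------------

def _emit_sample_pileup(config, sequences, frame, levels, sample, rng, path):
    """Write one sample's pileup TSV.

    ``frame`` holds one row per emitted position (chrom, pos, ref, strand,
    alt, kind); ``levels`` is the per-position true alternative-allele
    fraction for this sample (0 for background).
    """
    L = config.read_length
    k = config.depth_dispersion
    depth = rng.negative_binomial(k, k / (k + config.mean_depth), size=len(frame))
    n_reads = int(depth.sum())
    site_of_read = np.repeat(np.arange(len(frame)), depth)

    ref_codes = frame["ref_code"].to_numpy()
    alt_codes = frame["alt_code"].to_numpy()
    is_alt_true = rng.random(n_reads) < levels[site_of_read]
    true_code = np.where(is_alt_true, alt_codes[site_of_read], ref_codes[site_of_read])

    offsets = rng.integers(1, L + 1, size=n_reads)
    near_end = (offsets <= config.end_region_bp) | (offsets > L - config.end_region_bp)
    p_err = np.where(near_end, config.error_rate * config.end_error_multiplier,
                     config.error_rate)
    is_err = rng.random(n_reads) < p_err
    err_shift = rng.integers(1, 4, size=n_reads)
    obs_code = np.where(is_err, (true_code + err_shift) % 4, true_code)

    quals = np.where(
        is_err,
        rng.normal(config.error_qual_mean, config.error_qual_sd, size=n_reads),
        rng.normal(config.base_qual_mean, config.base_qual_sd, size=n_reads),
    )
    quals = np.clip(np.rint(quals), 2, 41).astype(int)

    bounds = np.concatenate([[0], np.cumsum(depth)])
    chroms = frame["chrom"].to_numpy()
    positions = frame["pos"].to_numpy()
    refs = frame["ref"].to_numpy()
    strands = frame["strand"].to_numpy()
    with open(path, "w") as fh:
        for i in range(len(frame)):
            lo, hi = bounds[i], bounds[i + 1]
            if hi == lo:
                continue  # zero coverage: site absent from this sample
            codes = obs_code[lo:hi]
            blocks = []
            for code in sorted(set(codes.tolist())):
                mask = codes == code
                obs = "|".join(
                    f"{q},{o},{L}"
                    for q, o in zip(quals[lo:hi][mask], offsets[lo:hi][mask])
                )
                blocks.append(f"{BASE_STR[code]}:{int(mask.sum())}:{obs}")
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t{refs[i]}\t{strands[i]}\t"
                + "\t".join(blocks) + "\n"
            )


def emit_pileups(config: SimulationConfig, reference: Reference, truth: TruthTable,
                 outdir, rng=None) -> dict[str, Path]:
    """Write per-sample RNA pileups plus WGS/WGBS/dbSNP VCFs; return paths."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    outdir = Path(outdir)
    (outdir / "rna").mkdir(parents=True, exist_ok=True)
    sequences = reference.sequences()
    samples = config.samples()

    sites = truth.sites.reset_index()
    frame = pd.concat(
        [
            pd.DataFrame(
                {
                    "chrom": sites.chrom, "pos": sites.pos, "ref": sites.ref,
                    "strand": sites.strand, "alt": sites.alt, "kind": "edit",
                    "site_id": sites.site_id,
                }
            ),
            pd.DataFrame(
                {
                    "chrom": truth.snps.chrom, "pos": truth.snps.pos,
                    "ref": truth.snps.ref, "strand": ".", "alt": truth.snps.alt,
                    "kind": "snp", "site_id": "",
                }
            ),
            pd.DataFrame(
                {
                    "chrom": truth.background.chrom, "pos": truth.background.pos,
                    "ref": [
                        sequences[c][p - 1]
                        for c, p in zip(truth.background.chrom, truth.background.pos)
                    ],
                    "strand": ".", "alt": "", "kind": "background", "site_id": "",
                }
            ),
        ],
        ignore_index=True,
    ).sort_values(["chrom", "pos"], ignore_index=True)
    frame["ref_code"] = frame["ref"].map(BASE_INDEX)
    frame["alt_code"] = frame["alt"].map(lambda b: BASE_INDEX.get(b, 0))

    snp_frac = truth.snps.genotype.map({"het": 0.5, "hom_alt": 1.0})
    snp_frac.index = truth.snps.chrom + ":" + truth.snps.pos.astype(str)

    paths = {}
    child_rngs = rng.spawn(len(samples))
    for (sample, _), srng in zip(samples.iterrows(), child_rngs):
        lv = np.zeros(len(frame))
        edit_mask = frame["kind"] == "edit"
        lv[edit_mask.to_numpy()] = truth.levels.loc[
            frame.loc[edit_mask, "site_id"], sample
        ].to_numpy()
        snp_mask = (frame["kind"] == "snp").to_numpy()
        keys = (frame.loc[snp_mask, "chrom"] + ":" + frame.loc[snp_mask, "pos"].astype(str))
        lv[snp_mask] = snp_frac.loc[keys].to_numpy()
        path = outdir / "rna" / f"{sample}.pileup.tsv"
        _emit_sample_pileup(config, sequences, frame, lv, sample, srng, path)
        paths[sample] = path

    # DNA evidence
    contigs = {c: config.chrom_length for c in sequences}
    wgs, wgbs, dbsnp = [], [], []
    for r in truth.snps.itertuples():
        depth = max(int(rng.poisson(config.dna_depth)), 1)
        rec = VariantCallRecord(
            position=GenomicPosition(r.chrom, r.pos), ref_allele=r.ref,
            alt_allele=r.alt, genotype=r.genotype, depth=depth, qual=225.0,
        )
        wgs.append(rec)
        blind = (r.ref, r.alt) in (("C", "T"), ("G", "A"))
        wgbs.append(
            dataclasses.replace(rec, genotype="unknown" if blind else r.genotype)
        )
        if r.in_dbsnp:
            dbsnp.append(rec)
    formats.write_vcf_min(wgs, outdir / "wgs.vcf", contigs)
    formats.write_vcf_min(wgbs, outdir / "wgbs.vcf", contigs)
    formats.write_vcf_min(dbsnp, outdir / "dbsnp.vcf", contigs)
    paths.update(
        wgs=outdir / "wgs.vcf", wgbs=outdir / "wgbs.vcf", dbsnp=outdir / "dbsnp.vcf"
    )
    return paths


# ---------------------------------------------------------------------------
# Expression and miRNA panels
# ---------------------------------------------------------------------------

def emit_expression(config, reference, truth, outdir, rng) -> Path:
    """FPKM-like gene expression; genes hosting developmental sites co-vary
    (positively or negatively) with their site's editing trend so host-mRNA
    correlation analyses have signal."""
    samples = config.samples()
    genes = [m.gene_id for m in reference.genes]
    base = rng.lognormal(mean=2.0, sigma=1.0, size=len(genes))
    expr = np.outer(base, np.ones(len(samples)))
    dev_sites = truth.sites[truth.sites.developmental & (truth.sites.gene_id != "")]
    coupled = {}
    for sid, row in dev_sites.iterrows():
        if row.gene_id in coupled:
            continue
        coupled[row.gene_id] = sid
    for gid, sid in coupled.items():
        gi = genes.index(gid)
        lv = truth.levels.loc[sid].to_numpy()
        z = (lv - lv.mean()) / (lv.std() + 1e-12)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        expr[gi] *= np.exp(0.8 * sign * z)
    expr *= np.exp(rng.normal(0.0, 0.15, size=expr.shape))
    df = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"),
                      columns=samples.index)
    path = Path(outdir) / "fpkm.tsv"
    formats.write_matrix(df, path)
    return path


def emit_mirnas(config, reference, truth, outdir, rng) -> Path:
    """miRNA panel: mostly random 22-mers plus a few engineered to gain or
    lose a seed match when a 3'UTR site is edited (A->G on the sense strand)."""
    sequences = reference.sequences()
    genes = {m.gene_id: m for m in reference.genes}
    mirnas: dict[str, str] = {}
    utr3 = truth.sites[(truth.sites.feature == "3UTR") & (truth.sites.gene_id != "")]
    engineered = 0
    for sid, row in utr3.iterrows():
        if engineered >= 4:
            break
        gene = genes[row.gene_id]
        seq = sequences[row.chrom][row.pos - 9 : row.pos + 8]
        if gene.strand == "-":
            seq = formats.revcomp(seq)
        center = 8  # index of the editable A in the 17-nt sense window
        if seq[center] != "A":
            continue
        # target heptamer covering the edited base; complement gives the seed
        start = center - 3
        target_ref = seq[start : start + 7]
        target_edit = target_ref[:3] + "G" + target_ref[4:]
        target = target_edit if engineered % 2 == 0 else target_ref  # gain : loss
        seed = formats.revcomp(target)  # miRNA positions 2-8
        tail = "".join(BASE_STR[i] for i in rng.integers(0, 4, size=14))
        mirnas[f"ssc-miR-sim{engineered + 1}"] = ("T" + seed + tail)[:22]
        engineered += 1
    while len(mirnas) < config.n_mirnas:
        name = f"ssc-miR-rnd{len(mirnas) + 1}"
        mirnas[name] = "".join(BASE_STR[i] for i in rng.integers(0, 4, size=22))
    path = Path(outdir) / "mirna.fa"
    formats.write_fasta({k: v.replace("T", "U") for k, v in mirnas.items()}, path)
    return path


# ---------------------------------------------------------------------------
# Null matrices for calibration experiments
# ---------------------------------------------------------------------------

def null_level_matrix(n_sites: int, samples: pd.DataFrame, seed: int,
                      mean: float = 0.1, sd: float = 0.03) -> pd.DataFrame:
    """Editing-level-like matrix with no association to any covariate."""
    rng = np.random.default_rng(seed)
    x = rng.normal(mean, sd, size=(n_sites, len(samples)))
    return pd.DataFrame(
        x, index=[f"null{i}" for i in range(n_sites)], columns=samples.index
    )


def coediting_block_matrix(n_per_block: int, samples: pd.DataFrame, seed: int,
                           within_cor: float = 0.9,
                           stage_block: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Two planted co-editing blocks with a known partition.

    Block ``stage_block`` follows the (standardised) developmental-stage
    trajectory, the other an independent latent factor; within-block
    correlation is ``within_cor``, between-block ~0. Returns the sites x
    samples matrix and the truth labels.
    """
    rng = np.random.default_rng(seed)
    n_samples = len(samples)
    days = samples["stage_days"].to_numpy(float)
    f_stage = (days - days.mean()) / days.std()
    factors = [f_stage, rng.standard_normal(n_samples)]
    if stage_block == 1:
        factors = factors[::-1]
    rows, labels = [], []
    for b, f in enumerate(factors):
        load = np.sqrt(within_cor)
        noise_sd = np.sqrt(1.0 - within_cor)
        for i in range(n_per_block):
            rows.append(load * f + noise_sd * rng.standard_normal(n_samples))
            labels.append(b)
    idx = [f"site_b{l}_{i}" for i, l in enumerate(labels)]
    return (
        pd.DataFrame(rows, index=idx, columns=samples.index),
        pd.Series(labels, index=idx, name="block"),
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    outdir: Path
    reference: Reference
    truth: TruthTable
    samples: pd.DataFrame
    pileups: dict[str, Path]

    @property
    def genome_path(self):
        return self.outdir / "genome.fa"


def simulate_dataset(config: SimulationConfig, outdir) -> SimulatedDataset:
    """Run the full generator and write every artefact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    ref_rng, plant_rng, emit_rng, expr_rng, mirna_rng = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )
    reference = build_reference(config, ref_rng)
    truth = plant_editing_and_snps(config, reference, plant_rng)

    formats.write_fasta(reference.sequences(), outdir / "genome.fa")
    formats.write_gtf(reference.genes, outdir / "genes.gtf")
    bed = reference.repeats.rename(columns={"family": "name"})[
        ["chrom", "start", "end", "name"]
    ].assign(score=0.0, strand=".")
    formats.write_bed(bed, outdir / "repeats.bed")

    samples = config.samples()
    samples.to_csv(outdir / "samples.tsv", sep="\t")

    pileups = emit_pileups(config, reference, truth, outdir, emit_rng)
    emit_expression(config, reference, truth, outdir, expr_rng)
    emit_mirnas(config, reference, truth, outdir, mirna_rng)

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    truth.sites.to_csv(truth_dir / "sites.tsv", sep="\t")
    formats.write_matrix(truth.levels, truth_dir / "levels.tsv")
    truth.snps.to_csv(truth_dir / "snps.tsv", sep="\t", index=False)
    truth.background.to_csv(truth_dir / "background.tsv", sep="\t", index=False)

    return SimulatedDataset(
        config=config, outdir=outdir, reference=reference, truth=truth,
        samples=samples,
        pileups={k: v for k, v in pileups.items() if isinstance(k, str) and k not in
                 ("wgs", "wgbs", "dbsnp")},
    )
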