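"""miRNA target gain/loss after A-to-I editing in 3'-UTRs.

For each edited site a +/-50 nt sense-strand flank is built in a reference
and an edited (A->G) version, both are scanned with a canonical seed-match
predictor (8mer / 7mer-m8 / 7mer-A1 / 6mer, Watson-Crick complementarity
to miRNA positions 2-8), and the two prediction sets are compared to
classify each miRNA-site pair as gained, lost, score-changed, or
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .formats import GeneModel, revcomp

CLASS_WEIGHT = {"8mer": 4, "7mer-m8": 3, "7mer-A1": 2, "6mer": 1}


@dataclass
class FlankPair:
    """Reference and edited flank sequences around one editing site."""

    site_id: str
    ref_seq: str
    edited_seq: str
    edit_index: int          # 0-based index of the edited base in both seqs
    truncated: bool = False

    def __post_init__(self):
        diff = [i for i, (a, b) in enumerate(zip(self.ref_seq, self.edited_seq))
                if a != b]
        if diff != [self.edit_index]:
            raise ValueError("flank pair must differ at exactly the edited base")
        if self.ref_seq[self.edit_index] != "A" or \
                self.edited_seq[self.edit_index] != "G":
            raise ValueError("edited base must change A -> G on the sense strand")


@dataclass(frozen=True)
class TargetPair:
    mirna_id: str
    site_id: str
    match_class: str
    score: float
    span: tuple[int, int]    # 1-based inclusive on the flank

    def __post_init__(self):
        if self.match_class not in CLASS_WEIGHT:
            raise ValueError(f"unknown match class {self.match_class!r}")


@dataclass
class RewiringCall:
    mirna_id: str
    site_id: str
    category: str            # gained / lost / score_changed / unchanged
    ref_pair: TargetPair | None = None
    edit_pair: TargetPair | None = None


def make_flank_pair(site_id: str, chrom: str, pos: int, strand: str,
                    genome: dict[str, str], k: int = 50) -> FlankPair:
    """Sense-strand +/-k nt flank with the edit applied as A->G.

    Minus-strand genes are reverse-complemented so the edited base reads A
    in the reference flank; flanks crossing a contig end are truncated and
    flagged.
    """
    seq = genome[chrom]
    lo = max(1, pos - k)
    hi = min(len(seq), pos + k)
    truncated = (lo != pos - k) or (hi != pos + k)
    flank = seq[lo - 1 : hi]
    idx = pos - lo
    if strand == "-":
        flank = revcomp(flank)
        idx = len(flank) - 1 - idx
    if flank[idx] != "A":
        raise ValueError(
            f"{site_id}: sense-strand base at the edit position is "
            f"{flank[idx]!r}, expected 'A'"
        )
    edited = flank[:idx] + "G" + flank[idx + 1 :]
    return FlankPair(site_id=site_id, ref_seq=flank, edited_seq=edited,
                     edit_index=idx, truncated=truncated)


def _au_fraction(seq: str, span: tuple[int, int], context: int = 5) -> float:
    """A/U fraction of the up-to-10-nt context flanking the binding span."""
    lo = max(0, span[0] - 1 - context)
    hi = min(len(seq), span[1] + context)
    ctx = seq[lo : span[0] - 1] + seq[span[1] : hi]
    if not ctx:
        return 0.0
    return sum(1 for b in ctx if b in "AT") / len(ctx)


def predict_targets(flank: str, mirnas: dict[str, str],
                    site_id: str = "") -> list[TargetPair]:
    """Scan a flank (mRNA sense, 5'->3', DNA alphabet) for canonical seed sites.

    Matches are Watson-Crick complements of miRNA positions 2-7 (6mer core)
    optionally extended by an m8 match and/or an adenosine opposite
    position 1. Score = class weight + AU-context bonus. At one core
    position only the best class is reported.
    """
    out = []
    for mid, mseq in sorted(mirnas.items()):
        m = mseq.upper().replace("U", "T")
        if not 18 <= len(m) <= 26:
            raise ValueError(f"{mid}: miRNA length {len(m)} outside 18-26 nt")
        seed7 = revcomp(m[1:8])   # complements of positions 2-8, mRNA 5'->3'
        core6 = seed7[1:]         # complements of positions 2-7
        # i indexes the would-be m8 match position (0-based)
        for i in range(-1, len(flank) - 6):
            if flank[i + 1 : i + 7] != core6:
                continue
            has_m8 = i >= 0 and flank[i] == seed7[0]
            a1_pos = i + 7
            has_a1 = a1_pos < len(flank) and flank[a1_pos] == "A"
            if has_m8 and has_a1:
                cls, span = "8mer", (i + 1, i + 8)
            elif has_m8:
                cls, span = "7mer-m8", (i + 1, i + 7)
            elif has_a1:
                cls, span = "7mer-A1", (i + 2, i + 8)
            else:
                cls, span = "6mer", (i + 2, i + 7)
            score = CLASS_WEIGHT[cls] + _au_fraction(flank, span)
            out.append(TargetPair(mid, site_id, cls, round(score, 6), span))
    out.sort(key=lambda t: (-t.score, t.span[0], t.mirna_id))
    return out


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def classify_rewiring(pairs_ref: Sequence[TargetPair],
                      pairs_edit: Sequence[TargetPair]) -> list[RewiringCall]:
    """Compare reference vs edited predictions keyed by (miRNA, site, span).

    A reference pair matched by an overlapping edited pair of the same
    miRNA is unchanged when class and span are identical, score_changed
    otherwise; unmatched reference pairs are lost, unmatched edited pairs
    gained.
    """
    calls = []
    by_key_edit: dict[tuple, list[TargetPair]] = {}
    for p in pairs_edit:
        by_key_edit.setdefault((p.mirna_id, p.site_id), []).append(p)
    consumed = set()
    for p in sorted(pairs_ref, key=lambda t: (t.mirna_id, t.span)):
        candidates = [
            q for q in by_key_edit.get((p.mirna_id, p.site_id), [])
            if id(q) not in consumed and _spans_overlap(p.span, q.span)
        ]
        if not candidates:
            calls.append(RewiringCall(p.mirna_id, p.site_id, "lost", ref_pair=p))
            continue
        q = sorted(candidates, key=lambda t: (t.span != p.span, t.span))[0]
        consumed.add(id(q))
        if q.match_class == p.match_class and q.span == p.span:
            calls.append(RewiringCall(p.mirna_id, p.site_id, "unchanged",
                                      ref_pair=p, edit_pair=q))
        else:
            calls.append(RewiringCall(p.mirna_id, p.site_id, "score_changed",
                                      ref_pair=p, edit_pair=q))
    for p in pairs_edit:
        if id(p) not in consumed:
            calls.append(RewiringCall(p.mirna_id, p.site_id, "gained",
                                      edit_pair=p))
    return calls


def rewiring_summary(calls: Sequence[RewiringCall]) -> dict:
    """Pair-level category counts and per-site gain/loss rollups."""
    counts = {"gained": 0, "lost": 0, "score_changed": 0, "unchanged": 0}
    gained_sites, lost_sites = set(), set()
    for c in calls:
        counts[c.category] += 1
        if c.category == "gained":
            gained_sites.add(c.site_id)
        elif c.category == "lost":
            lost_sites.add(c.site_id)
    counts["sites_with_gain"] = len(gained_sites)
    counts["sites_with_loss"] = len(lost_sites)
    return counts


def rewire_sites(annotated: pd.DataFrame, genome: dict[str, str],
                 mirnas: dict[str, str], k: int = 50,
                 features: tuple[str, ...] = ("3UTR",)) -> tuple[pd.DataFrame, dict]:
    """Run the flank/predict/compare pipeline over annotated 3'-UTR sites."""
    rows = []
    all_calls = []
    for sid, r in annotated[annotated["feature"].isin(features)].iterrows():
        if r["strand"] not in ("+", "-"):
            continue
        try:
            fp = make_flank_pair(sid, r["chrom"], int(r["pos"]), r["strand"],
                                 genome, k)
        except ValueError:
            continue
        ref_pairs = predict_targets(fp.ref_seq, mirnas, sid)
        edit_pairs = predict_targets(fp.edited_seq, mirnas, sid)
        calls = classify_rewiring(ref_pairs, edit_pairs)
        all_calls.extend(calls)
        for c in calls:
            pair = c.edit_pair or c.ref_pair
            rows.append(
                {"site_id": sid, "mirna_id": c.mirna_id, "category": c.category,
                 "match_class": pair.match_class, "span_start": pair.span[0],
                 "span_end": pair.span[1], "score": pair.score}
            )
    table = pd.DataFrame(
        rows, columns=["site_id", "mirna_id", "category", "match_class",
                       "span_start", "span_end", "score"]
    )
    return table, rewiring_summary(all_calls)
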