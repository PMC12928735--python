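"""Classification of discordant/soft-clipped read pairs (Patterns I–VIII)
and estimation of the minor-isoform frequency.

A genome mixture of a normal-type plastome and its sIR-mediated inverted
isoform leaves two signatures on the normal-type reference: fully aligned
read pairs with discordant orientation separated by approximately the span
of the recombination (HR) region, and reads soft-clipped at an arm boundary
whose clipped fragment remaps next to the opposite arm.  Candidates are
additionally required to align properly — forward/reverse orientation with
a mate span below a strict bound — on the inverted-type reference.

The operational Pattern taxonomy:

==========  ===========================================================
Pattern     geometry on the normal reference
==========  ===========================================================
I           fully aligned, one read overlaps sIR-1, mate outside the HR
II          fully aligned, one read overlaps sIR-2, mate outside the HR
III         fully aligned, one read overlaps sIR-1, mate inside the HR
IV          fully aligned, one read overlaps sIR-2, mate inside the HR
V           fully aligned, no arm overlap: one read inside the HR, mate
            outside within the vicinity of an arm
VI          soft-clipped at the sIR-1 boundary, mate not inside the HR
VII         soft-clipped at the sIR-2 boundary, mate not inside the HR
VIII        soft-clipped at an arm boundary, mate inside the HR
==========  ===========================================================

The estimated minor-isoform frequency is the number of supporting read
pairs divided by the mean depth over the HR region, in percent.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import edlib
import numpy as np

from .genome_core import InputError, Interval, reverse_complement
from .repeat_discovery import InvertedRepeatPair
from .isoform_builder import IsoformPair
from .alignment_layer import (
    AlignedPair,
    FUNMAP,
    MapParams,
    ReadAlignment,
    ReferenceIndex,
    map_encoded_pairs,
    mean_depth,
    pair_alignments,
    read_sam,
)

__all__ = [
    "DetectionParams",
    "PairEvidence",
    "EvidenceSummary",
    "is_discordant_candidate",
    "sir_overlap_rule",
    "remap_softclip",
    "verify_on_inverted",
    "assign_pattern",
    "detect",
    "detect_pairs",
    "estimate_frequency",
    "evidence_to_table",
]

PATTERNS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")


@dataclass
class DetectionParams:
    """Tunable criteria for candidate selection and classification.

    span_tolerance_bp
        Allowed deviation of the observed mate span on the normal reference
        from the HR-region span (the "approximately 22 kb insert" rule).
    vicinity_bp
        Window beyond an arm within which a mate counts as "in the vicinity".
    inverted_max_span_bp
        Strict upper bound (exclusive) on the mate span when remapped to the
        inverted reference.
    min_clip_bp
        Minimum soft-clip length worth remapping.
    clip_min_identity
        Minimum identity of the remapped clip over its full length.
    variant_tolerance
        Maximum mismatches+indels for the "minor variation" class; pairs
        with more are excluded.
    clip_junction_slack_bp
        Allowed distance between a clip junction and the arm interval for
        the clip to count as "at the arm boundary".
    """

    span_tolerance_bp: int = 1000
    vicinity_bp: int = 1000
    inverted_max_span_bp: int = 500
    min_clip_bp: int = 20
    clip_min_identity: float = 0.9
    variant_tolerance: int = 3
    clip_junction_slack_bp: int = 50

    def __post_init__(self) -> None:
        if self.inverted_max_span_bp <= 0:
            raise InputError("inverted_max_span_bp must be positive")
        if self.min_clip_bp < 10:
            raise InputError("min_clip_bp must be >= 10")


@dataclass
class PairEvidence:
    read_id: str
    pattern: str
    variation: str  # "exact" | "minor_variant"
    normal_pos1: int  # 0-based leftmost positions of the two mates
    normal_pos2: int
    inverted_span_bp: int
    clip_len: int = 0
    clip_arm: str = ""  # arm at whose boundary the clip sits ("sIR-1"/"sIR-2")
    clip_identity: float = 0.0


@dataclass
class EvidenceSummary:
    per_pattern_counts: dict[str, int]
    total_pairs: int
    mean_depth_hr: float
    frequency_pct: float

    def to_dict(self) -> dict:
        return {
            "per_pattern_counts": dict(self.per_pattern_counts),
            "total_pairs": self.total_pairs,
            "mean_depth_hr": round(self.mean_depth_hr, 2),
            "frequency_pct": round(self.frequency_pct, 2),
        }


# --- elementary rules ------------------------------------------------------


def _m_interval(a: ReadAlignment) -> tuple[int, int]:
    return a.pos, a.pos + a.ref_span


def is_discordant_candidate(
    pair: AlignedPair, hr: Interval, params: DetectionParams
) -> bool:
    """Orientation is not proper FR and the mate span is within
    ``span_tolerance_bp`` of the HR-region span.  (The soft-clip path is
    handled separately and does not require the span criterion.)
    """
    if not pair.both_mapped:
        return False
    if pair.orientation == "FR":
        return False
    return abs(pair.observed_span - hr.span()) <= params.span_tolerance_bp


def sir_overlap_rule(
    pair: AlignedPair,
    arms: InvertedRepeatPair,
    hr: Interval,
    params: DetectionParams,
) -> str:
    """'arm_overlap' | 'interior_exterior' | 'fail' per the candidate criteria."""
    a1, a2 = arms.arm1.interval, arms.arm2.interval
    reads = [r for r in (pair.read1, pair.read2) if r is not None]
    for r in reads:
        lo, hi = _m_interval(r)
        if (lo < a1.end and a1.start < hi) or (lo < a2.end and a2.start < hi):
            return "arm_overlap"
    for rin, rout in ((pair.read1, pair.read2), (pair.read2, pair.read1)):
        if rin is None or rout is None:
            continue
        ilo, ihi = _m_interval(rin)
        olo, ohi = _m_interval(rout)
        if not (hr.start <= ilo and ihi <= hr.end):
            continue
        if not (ohi <= hr.start or olo >= hr.end):
            continue
        dist = min(
            _interval_distance(olo, ohi, a1.start, a1.end),
            _interval_distance(olo, ohi, a2.start, a2.end),
        )
        if dist <= params.vicinity_bp:
            return "interior_exterior"
    return "fail"


def _interval_distance(lo1: int, hi1: int, lo2: int, hi2: int) -> int:
    if lo1 < hi2 and lo2 < hi1:
        return 0
    return lo2 - hi1 if hi1 <= lo2 else lo1 - hi2


def remap_softclip(
    clip_seq: str, target_window: str, params: DetectionParams
) -> tuple[float, int, str] | None:
    """Best placement of a soft-clipped fragment inside a reference window.

    The whole clip is aligned semi-globally (query global, target local) in
    both orientations; returns ``(identity, offset, orientation)`` when the
    identity over the full clip reaches ``clip_min_identity``, else ``None``.
    Clips shorter than ``min_clip_bp`` are not attempted.
    """
    if len(clip_seq) < params.min_clip_bp:
        return None
    best: tuple[float, int, str] | None = None
    for orient, target in (("+", target_window), ("-", reverse_complement(target_window))):
        res = edlib.align(clip_seq, target, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        ident = 1.0 - res["editDistance"] / len(clip_seq)
        if best is None or ident > best[0]:
            loc = res["locations"][0] if res["locations"] else (0, 0)
            best = (ident, int(loc[0] or 0), orient)
    if best is not None and best[0] >= params.clip_min_identity:
        return best
    return None


def verify_on_inverted(pair: AlignedPair, params: DetectionParams) -> bool:
    """On the inverted reference the mates must be proper FR with a span
    strictly below ``inverted_max_span_bp``."""
    if not pair.both_mapped:
        return False
    return pair.orientation == "FR" and pair.observed_span < params.inverted_max_span_bp


# --- detection -------------------------------------------------------------


@dataclass
class _Candidate:
    pair: AlignedPair
    path: str  # "clip" | "full"
    clip_read: ReadAlignment | None = None
    clip_len: int = 0
    clip_arm: str = ""
    clip_identity: float = 0.0
    overlap: str = ""  # full path: arm_overlap | interior_exterior


def _find_qualifying_clip(
    pair: AlignedPair,
    iso: IsoformPair,
    params: DetectionParams,
) -> tuple[ReadAlignment, int, str, float] | None:
    """A soft clip of >= min_clip_bp at an arm boundary that remaps with
    sufficient identity to the window flanking the opposite arm."""
    arms = {"sIR-1": iso.pair.arm1.interval, "sIR-2": iso.pair.arm2.interval}
    slack = params.clip_junction_slack_bp
    for r in (pair.read1, pair.read2):
        if r is None or r.is_unmapped or r.seq is None:
            continue
        for side in ("left", "right"):
            clip = r.left_clip if side == "left" else r.right_clip
            if clip < params.min_clip_bp:
                continue
            junction = r.pos if side == "left" else r.pos + r.ref_span
            arm_label = None
            for label, iv in arms.items():
                if iv.start - slack <= junction <= iv.end + slack:
                    arm_label = label
            if arm_label is None:
                continue
            opposite = arms["sIR-2" if arm_label == "sIR-1" else "sIR-1"]
            win_lo = max(0, opposite.start - params.vicinity_bp)
            win_hi = min(iso.normal.length, opposite.end + params.vicinity_bp)
            window = iso.normal.seq[win_lo:win_hi]
            seq = r.seq_str()
            assert seq is not None
            clip_seq = seq[:clip] if side == "left" else seq[-clip:]
            hit = remap_softclip(clip_seq, window, params)
            if hit is not None:
                return r, clip, arm_label, hit[0]
    return None


def detect_pairs(
    normal_pairs: list[AlignedPair],
    iso: IsoformPair,
    params: DetectionParams | None = None,
    inverted_pairs: dict[str, AlignedPair] | None = None,
    map_params: MapParams | None = None,
    log=None,
) -> tuple[list[PairEvidence], list[tuple[str, str]]]:
    """Run the full candidate → verification → classification cascade.

    ``inverted_pairs`` maps read ids to alignments on the inverted
    reference; when absent, candidate reads are mapped to the inverted
    reference with the internal mapper.  Returns the evidence list and the
    list of excluded candidates with machine-parsable reasons.
    """
    params = params or DetectionParams()
    hr = iso.pair.hr_region
    hr_span = hr.span()
    excluded: list[tuple[str, str]] = []

    # Phase 1: cheap geometric shortlist.
    shortlist: list[_Candidate] = []
    min_clip = params.min_clip_bp
    tol = params.span_tolerance_bp
    for ap in normal_pairs:
        a, b = ap.read1, ap.read2
        if a is None or b is None or a.flag & FUNMAP or b.flag & FUNMAP:
            continue
        has_clip = a.max_clip >= min_clip or b.max_clip >= min_clip
        spanning = (
            ap.orientation != "FR"
            and abs(ap.observed_span - hr_span) <= tol
        )
        if not has_clip and not spanning:
            continue
        if has_clip:
            hit = _find_qualifying_clip(ap, iso, params)
            if hit is not None:
                r, clip, arm_label, ident = hit
                shortlist.append(
                    _Candidate(ap, "clip", r, clip, arm_label, ident)
                )
                continue
        if spanning:
            overlap = sir_overlap_rule(ap, iso.pair, hr, params)
            if overlap == "fail":
                excluded.append((a.read_id, "overlap_rule_fail"))
                continue
            shortlist.append(_Candidate(ap, "full", overlap=overlap))

    # Phase 2: verification on the inverted reference.
    if inverted_pairs is None:
        inverted_pairs = _map_candidates_on_inverted(shortlist, iso, map_params)
    evidence: list[PairEvidence] = []
    for cand in shortlist:
        ap = cand.pair
        rid = ap.read1.read_id if ap.read1 else ap.read2.read_id  # type: ignore[union-attr]
        inv = inverted_pairs.get(rid)
        if inv is None or not verify_on_inverted(inv, params):
            excluded.append((rid, "inverted_reference_check_fail"))
            continue

        nm = sum(int(r.nm or 0) for r in (ap.read1, ap.read2) if r is not None)
        if nm > params.variant_tolerance:
            excluded.append((rid, "excess_variation"))
            continue
        variation = "minor_variant" if nm >= 1 else "exact"

        pattern = assign_pattern(cand, iso, params)
        if pattern is None:
            excluded.append((rid, "unclassifiable_geometry"))
            continue
        evidence.append(
            PairEvidence(
                read_id=rid,
                pattern=pattern,
                variation=variation,
                normal_pos1=ap.read1.pos,  # type: ignore[union-attr]
                normal_pos2=ap.read2.pos,  # type: ignore[union-attr]
                inverted_span_bp=inv.observed_span,
                clip_len=cand.clip_len,
                clip_arm=cand.clip_arm,
                clip_identity=round(cand.clip_identity, 4),
            )
        )
    if log is not None:
        for rid, reason in excluded:
            print(f"excluded\t{rid}\t{reason}", file=log)
    return evidence, excluded


def assign_pattern(cand: _Candidate, iso: IsoformPair, params: DetectionParams) -> str | None:
    """Assign the Pattern I–VIII label to a verified candidate."""
    hr = iso.pair.hr_region
    a1, a2 = iso.pair.arm1.interval, iso.pair.arm2.interval
    ap = cand.pair

    def wholly_inside(r: ReadAlignment) -> bool:
        lo, hi = _m_interval(r)
        return hr.start <= lo and hi <= hr.end

    if cand.path == "clip":
        assert cand.clip_read is not None
        mate = ap.read2 if cand.clip_read is ap.read1 else ap.read1
        if mate is not None and wholly_inside(mate):
            return "VIII"
        return "VI" if cand.clip_arm == "sIR-1" else "VII"

    # fully aligned path
    if cand.overlap == "interior_exterior":
        return "V"
    for r, mate in ((ap.read1, ap.read2), (ap.read2, ap.read1)):
        if r is None or mate is None:
            continue
        lo, hi = _m_interval(r)
        if lo < a1.end and a1.start < hi:
            return "III" if wholly_inside(mate) else "I"
        if lo < a2.end and a2.start < hi:
            return "IV" if wholly_inside(mate) else "II"
    return None


def _map_candidates_on_inverted(
    shortlist: list[_Candidate],
    iso: IsoformPair,
    map_params: MapParams | None,
) -> dict[str, AlignedPair]:
    """Remap the shortlisted reads to the inverted reference internally."""
    from .genome_core import encode_seq

    if not shortlist:
        return {}
    ids, s1, s2 = [], [], []
    for cand in shortlist:
        r1, r2 = cand.pair.read1, cand.pair.read2
        if r1 is None or r2 is None or r1.seq is None or r2.seq is None:
            continue
        ids.append(r1.read_id)
        # restore original read orientation before remapping
        q1, q2 = r1.seq_str(), r2.seq_str()
        assert q1 is not None and q2 is not None
        s1.append(q1 if r1.strand == "+" else reverse_complement(q1))
        s2.append(q2 if r2.strand == "+" else reverse_complement(q2))
    if not ids:
        return {}
    rl = max(max(len(s) for s in s1), max(len(s) for s in s2))
    if any(len(s) != rl for s in s1 + s2):
        raise InputError("internal remapping requires uniform read length")
    r1m = np.vstack([encode_seq(s) for s in s1])
    r2m = np.vstack([encode_seq(s) for s in s2])
    index = ReferenceIndex(iso.inverted, k=(map_params or MapParams()).seed_k)
    alns = map_encoded_pairs(ids, r1m, r2m, index, map_params)
    return {p.read1.read_id: p for p in pair_alignments(alns) if p.read1 is not None}


def detect(
    normal_sam,
    inverted_sam,
    iso: IsoformPair,
    params: DetectionParams | None = None,
    log=None,
) -> tuple[list[PairEvidence], list[tuple[str, str]], float]:
    """SAM-file entry point: classify pairs and measure HR-region depth.

    Both SAM files must derive from the same read set; the reference names
    must match the isoform pair.  Returns (evidence, excluded, mean depth
    over the HR region on the normal reference).
    """
    normal_alns = list(read_sam(normal_sam, expected_ref=iso.normal.id))
    inverted_alns = list(read_sam(inverted_sam, expected_ref=iso.inverted.id))
    normal_pairs = pair_alignments(normal_alns)
    inv_pairs = {
        p.read1.read_id: p
        for p in pair_alignments(inverted_alns)
        if p.read1 is not None
    }
    depth = mean_depth(normal_alns, iso.pair.hr_region, ref_length=iso.normal.length)
    evidence, excluded = detect_pairs(
        normal_pairs, iso, params, inverted_pairs=inv_pairs, log=log
    )
    return evidence, excluded, depth


# --- summary ---------------------------------------------------------------


def estimate_frequency(
    evidence: list[PairEvidence], mean_depth_hr: float
) -> EvidenceSummary:
    """Supporting pairs divided by mean HR-region depth, in percent.

    Each read pair counts once.  With no evidence the frequency is 0 even at
    zero depth (degenerate but reachable on tiny inputs); nonzero evidence
    at zero depth is a computation error.
    """
    counts = {p: 0 for p in PATTERNS}
    for ev in evidence:
        counts[ev.pattern] += 1
    total = len(evidence)
    if total == 0:
        if mean_depth_hr == 0:
            print("warning: zero depth and zero evidence; frequency reported as 0", file=sys.stderr)
        freq = 0.0
    else:
        if mean_depth_hr <= 0:
            raise InputError("nonzero evidence with zero mean depth")
        freq = 100.0 * total / mean_depth_hr
    return EvidenceSummary(
        per_pattern_counts=counts,
        total_pairs=total,
        mean_depth_hr=float(mean_depth_hr),
        frequency_pct=freq,
    )


def evidence_to_table(evidence: list[PairEvidence]):
    """TSV-ready evidence table (1-based positions)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "read_id": e.read_id,
                "pattern": e.pattern,
                "variation": e.variation,
                "normal_pos1": e.normal_pos1 + 1,
                "normal_pos2": e.normal_pos2 + 1,
                "inverted_span": e.inverted_span_bp,
                "clip_len": e.clip_len,
                "clip_arm": e.clip_arm,
                "clip_identity": e.clip_identity,
            }
            for e in evidence
        ],
        columns=[
            "read_id",
            "pattern",
            "variation",
            "normal_pos1",
            "normal_pos2",
            "inverted_span",
            "clip_len",
            "clip_arm",
            "clip_identity",
        ],
    )
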