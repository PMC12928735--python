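"""Synthetic data emulating a structurally heteroplasmic plastome study.

The generator produces a circular ~160 kb genome of ~38% GC with a planted
53 bp inverted-repeat pair whose arms span a 22 kb region, the corresponding
inverted isoform, and 150 bp paired-end reads drawn from a two-isoform
mixture at a chosen minor-isoform fraction — the regime of shallow
whole-genome plastome sequencing (depths of a few hundred fold, insert
~400 bp).  Each fragment is recorded in a truth table, and
:func:`truth_supporting_set` derives — by pure coordinate arithmetic, never
from alignments — the exact set of fragments whose read geometry satisfies
the detection criteria, serving as the independent oracle for the detector.

All randomness flows from a single seeded generator consumed in a fixed
order (genome, then arm placement, then fragment starts, inserts,
isoform-origin uniforms, then errors), so datasets are bit-reproducible and
datasets differing only in the isoform fraction share fragment coordinates
(the supporting set grows monotonically with the fraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .genome_core import (
    CircularSequence,
    InputError,
    Interval,
    decode_seq,
    _COMP_CODES,
)
from .repeat_discovery import InvertedRepeatPair, find_inverted_repeat_pairs, make_pair
from .isoform_builder import IsoformPair, build_inverted_isoform
from .alignment_layer import MapParams

__all__ = [
    "SimConfig",
    "FragmentTruth",
    "TruthTable",
    "ReadSet",
    "SimResult",
    "simulate_plastome",
    "simulate_reads",
    "simulate_dataset",
    "truth_supporting_set",
]


@dataclass
class SimConfig:
    genome_bp: int = 160_000
    gc: float = 0.38
    arm_bp: int = 53
    hr_span_bp: int = 22_000
    isoform_fraction: float = 0.0
    depth_x: float = 500.0
    read_bp: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    error_rate: float = 0.0
    seed: int = 0
    arm_subs: int = 0  # substitutions planted in the downstream arm copy
    arm_indels: int = 0  # single-base indels planted in the downstream arm copy

    def __post_init__(self) -> None:
        if self.arm_bp < 12:
            raise InputError("arm_bp must be >= 12")
        if not 0 <= self.isoform_fraction <= 1:
            raise InputError("isoform_fraction must be in [0, 1]")
        if self.hr_span_bp + 2 * self.insert_mean >= self.genome_bp:
            raise InputError("genome too small for the requested HR span")
        if self.hr_span_bp <= 2 * self.arm_bp:
            raise InputError("hr_span_bp must exceed twice the arm length")
        if not 0 <= self.gc <= 1:
            raise InputError("gc must be a fraction")


@dataclass(frozen=True)
class FragmentTruth:
    fragment_id: str
    origin_isoform: str  # "normal" | "inverted"
    start: int
    insert_bp: int
    crosses_breakpoint: bool
    error_positions: tuple[tuple[int, int], ...]  # (mate 1/2, read offset)


class TruthTable:
    """Columnar per-fragment ground truth."""

    def __init__(
        self,
        start: np.ndarray,
        insert: np.ndarray,
        origin_inverted: np.ndarray,
        crosses: np.ndarray,
        errors: dict[int, list[tuple[int, int]]],
    ):
        self.start = start
        self.insert = insert
        self.origin_inverted = origin_inverted
        self.crosses = crosses
        self.errors = errors

    def __len__(self) -> int:
        return self.start.size

    @staticmethod
    def fragment_id(i: int) -> str:
        return f"frag{i:07d}"

    def row(self, i: int) -> FragmentTruth:
        return FragmentTruth(
            fragment_id=self.fragment_id(i),
            origin_isoform="inverted" if self.origin_inverted[i] else "normal",
            start=int(self.start[i]),
            insert_bp=int(self.insert[i]),
            crosses_breakpoint=bool(self.crosses[i]),
            error_positions=tuple(self.errors.get(i, ())),
        )

    def __iter__(self) -> Iterator[FragmentTruth]:
        return (self.row(i) for i in range(len(self)))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fragment_id": [self.fragment_id(i) for i in range(len(self))],
                "origin_isoform": np.where(self.origin_inverted, "inverted", "normal"),
                "start": self.start,
                "insert_bp": self.insert,
                "crosses_breakpoint": self.crosses,
                "n_errors": [len(self.errors.get(i, ())) for i in range(len(self))],
            }
        )


@dataclass
class ReadSet:
    ids: list[str]
    r1: np.ndarray  # (N, read_bp) codes
    r2: np.ndarray

    def write_fastq(self, r1_path, r2_path) -> None:
        qual = "I" * self.r1.shape[1]
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for i, rid in enumerate(self.ids):
                f1.write(f"@{rid}/1\n{decode_seq(self.r1[i])}\n+\n{qual}\n")
                f2.write(f"@{rid}/2\n{decode_seq(self.r2[i])}\n+\n{qual}\n")

    def iter_pairs(self) -> Iterator[tuple[str, str, str]]:
        for i, rid in enumerate(self.ids):
            yield rid, decode_seq(self.r1[i]), decode_seq(self.r2[i])


@dataclass
class SimResult:
    config: SimConfig
    normal: CircularSequence
    inverted: CircularSequence
    pair: InvertedRepeatPair
    iso: IsoformPair
    reads: ReadSet
    truth: TruthTable


# --- genome ----------------------------------------------------------------


def _draw_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2
    p = [at, gc / 2, gc / 2, at]  # A C G T
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def simulate_plastome(
    cfg: SimConfig, rng: np.random.Generator | None = None, max_tries: int = 30
) -> tuple[CircularSequence, InvertedRepeatPair, CircularSequence]:
    """Background genome with one planted sIR pair, plus its inverted isoform.

    The pair is planted symmetrically around the genome midpoint so the
    spanned region never touches the origin.  Draws are rejected until the
    planted pair is the only inverted repeat with arms of >= 20 bp and its
    maximal extension is exactly the planted arms.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    L, a, hr = cfg.genome_bp, cfg.arm_bp, cfg.hr_span_bp
    h0 = (L - hr) // 2
    h1 = h0 + hr
    for _ in range(max_tries):
        codes = _draw_codes(rng, L, cfg.gc)
        arm = _draw_codes(rng, a, cfg.gc)
        codes[h0 : h0 + a] = arm
        codes[h1 - a : h1] = _COMP_CODES[arm][::-1]
        genome = CircularSequence("sim_plastome", decode_seq(codes), circular=True)
        found = find_inverted_repeat_pairs(
            genome,
            min_arm_bp=20,
            max_arm_bp=L,
            min_span_bp=2 * a + 1,
            max_span_bp=L,
            min_identity=1.0,
        )
        planted_ok = (
            len(found) == 1
            and found[0].arm1.interval == Interval(h0, h0 + a)
            and found[0].arm2.interval == Interval(h1 - a, h1)
        )
        if not planted_ok:
            continue
        if cfg.arm_subs or cfg.arm_indels:
            genome = _mutate_arm2(genome, h1 - a, a, cfg, rng)
            pair = make_pair(
                genome,
                Interval(h0, h0 + a),
                Interval(h1 - a, h1 - a + a - cfg.arm_indels if cfg.arm_indels else h1),
            )
        else:
            pair = found[0]
        iso = build_inverted_isoform(genome, pair)
        return genome, pair, iso.inverted
    raise InputError("rejection budget exhausted while planting the sIR pair; retry with a new seed")


def _mutate_arm2(
    genome: CircularSequence, arm2_start: int, a: int, cfg: SimConfig, rng: np.random.Generator
) -> CircularSequence:
    """Introduce substitutions/deletions into the downstream arm copy.

    Deletions shorten the genome by ``arm_indels`` bases; coordinates
    downstream shift accordingly (the planted pair becomes incomplete).
    """
    codes = genome.codes.copy()
    armseg = codes[arm2_start : arm2_start + a].copy()
    if cfg.arm_subs:
        pos = rng.choice(a, size=min(cfg.arm_subs, a), replace=False)
        armseg[pos] = (armseg[pos] + rng.integers(1, 4, pos.size)) % 4
    if cfg.arm_indels:
        keep = np.ones(armseg.size, dtype=bool)
        drop = rng.choice(armseg.size, size=min(cfg.arm_indels, armseg.size - 1), replace=False)
        keep[drop] = False
        armseg = armseg[keep]
    new = np.concatenate([codes[:arm2_start], armseg, codes[arm2_start + a :]])
    return CircularSequence(genome.id, decode_seq(new), circular=True)


# --- reads -----------------------------------------------------------------


def simulate_reads(
    normal: CircularSequence,
    inverted: CircularSequence,
    cfg: SimConfig,
    rng: np.random.Generator,
    pair: InvertedRepeatPair | None = None,
) -> tuple[ReadSet, TruthTable]:
    """Paired-end FR reads from a two-isoform mixture.

    Fragment count ``N = round(depth_x * genome_bp / (2 * read_bp))``; starts
    uniform on the circle; inserts normal(insert_mean, insert_sd) truncated
    at ``2 * read_bp``; origin isoform Bernoulli(isoform_fraction) via a
    shared per-fragment uniform; substitution errors i.i.d. per base.
    """
    L = normal.length
    rl = cfg.read_bp
    n = int(round(cfg.depth_x * cfg.genome_bp / (2 * rl)))
    starts = rng.integers(0, L, size=n)
    inserts = np.maximum(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)).astype(np.int64),
        2 * rl,
    )
    u = rng.random(n)
    origin_inverted = u < cfg.isoform_fraction

    norm2 = np.concatenate([normal.codes, normal.codes])
    inv2 = np.concatenate([inverted.codes, inverted.codes])
    idx1 = (starts[:, None] + np.arange(rl)) % (2 * L)
    idx2 = ((starts + inserts - rl)[:, None] + np.arange(rl)) % (2 * L)
    src = np.where(origin_inverted[:, None], 0, 1)
    r1 = np.where(src == 0, inv2[idx1], norm2[idx1]).astype(np.uint8)
    r2raw = np.where(src == 0, inv2[idx2], norm2[idx2]).astype(np.uint8)
    r2 = _COMP_CODES[r2raw][:, ::-1]

    errors: dict[int, list[tuple[int, int]]] = {}
    if cfg.error_rate > 0:
        for mate, mat in ((1, r1), (2, r2)):
            kerr = rng.binomial(rl, cfg.error_rate, size=n)
            tot = int(kerr.sum())
            if tot:
                rows = np.repeat(np.arange(n), kerr)
                poss = rng.integers(0, rl, size=tot)
                shift = rng.integers(1, 4, size=tot).astype(np.uint8)
                mat[rows, poss] = (mat[rows, poss] + shift) % 4
                for rr, pp in zip(rows.tolist(), poss.tolist()):
                    errors.setdefault(rr, []).append((mate, pp))

    crosses = np.zeros(n, dtype=bool)
    if pair is not None:
        bounds = {
            pair.arm1.interval.start,
            pair.arm1.interval.end,
            pair.arm2.interval.start,
            pair.arm2.interval.end,
        }
        for b in bounds:
            crosses |= ((b - starts) % L) < inserts

    ids = [TruthTable.fragment_id(i) for i in range(n)]
    reads = ReadSet(ids=ids, r1=r1, r2=r2)
    truth = TruthTable(
        start=starts.astype(np.int64),
        insert=inserts,
        origin_inverted=origin_inverted,
        crosses=crosses,
        errors=errors,
    )
    return reads, truth


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Genome, isoform, reads and truth from one seeded stream."""
    rng = np.random.default_rng(cfg.seed)
    normal, pair, inverted = simulate_plastome(cfg, rng)
    iso = build_inverted_isoform(normal, pair)
    reads, truth = simulate_reads(normal, inverted, cfg, rng, pair=pair)
    return SimResult(
        config=cfg,
        normal=normal,
        inverted=inverted,
        pair=pair,
        iso=iso,
        reads=reads,
        truth=truth,
    )


# --- truth oracle ----------------------------------------------------------


def _max_segment(match: np.ndarray, penalty: int) -> tuple[int, int, int]:
    # independent maximal-scoring-subarray used only by the oracle
    best_score, best_a, best_b = 0, 0, 0
    cur, cur_a = 0, 0
    for i, m in enumerate(match.tolist()):
        v = 1 if m else -penalty
        if cur <= 0:
            cur, cur_a = v, i
        else:
            cur += v
        if cur > best_score:
            best_score, best_a, best_b = cur, cur_a, i + 1
    return best_a, best_b, best_score


@dataclass
class _PredictedAln:
    pos: int  # reference start of the M segment
    m_len: int
    strand: str
    left_clip: int  # in reference orientation
    right_clip: int
    nm: int

    @property
    def end(self) -> int:
        return self.pos + self.m_len


def _predict_read(
    v_lo: int,
    v_hi: int,
    is_r2: bool,
    ncodes: np.ndarray,
    vcodes: np.ndarray,
    h0: int,
    h1: int,
    mp: MapParams,
) -> _PredictedAln | None:
    """Predicted primary alignment on the normal reference of a read copied
    from the inverted isoform over ``[v_lo, v_hi)`` (linear coordinates near
    the HR region).

    Mirrors the internal mapper's conventions: full-length placement when the
    mismatch count allows, otherwise the maximal-scoring ungapped segment of
    the better of the identity and reflected placements; ties by (mismatches,
    reference offset, orientation).
    """
    rl = v_hi - v_lo
    rc = h0 + h1  # reflection: position p maps to rc - 1 - p
    vseg = vcodes[v_lo:v_hi]
    # identity placement: read at its own coordinates, strand preserved
    id_match = vseg == ncodes[v_lo:v_hi]
    # reflected placement: read maps at the mirrored interval, strand flipped
    refl_lo, refl_hi = rc - v_hi, rc - v_lo
    refl_ref = _COMP_CODES[ncodes[refl_lo:refl_hi]][::-1]
    refl_match_readorder = vseg == refl_ref
    # in reference orientation the reflected match vector runs backwards
    refl_match = refl_match_readorder[::-1]

    id_strand = "-" if is_r2 else "+"
    refl_strand = "+" if is_r2 else "-"
    # orientation index as the mapper sees it (0 = '+', 1 = '-')
    id_orient = 1 if is_r2 else 0
    refl_orient = 1 - id_orient

    mm_id = int((~id_match).sum())
    mm_refl = int((~refl_match).sum())
    max_mm = int(np.floor(mp.max_mismatch_rate * rl))

    cands = sorted(
        [(mm_id, v_lo, id_orient, "id"), (mm_refl, refl_lo, refl_orient, "refl")]
    )
    if cands[0][0] <= max_mm:
        mm, pos, orient, which = cands[0]
        strand = id_strand if which == "id" else refl_strand
        return _PredictedAln(pos=pos, m_len=rl, strand=strand, left_clip=0, right_clip=0, nm=mm)

    # soft-clip fallback: best segment of each placement, mapper tie-breaks
    best = None
    for match, base, orient, strand in (
        (id_match, v_lo, id_orient, id_strand),
        (refl_match, refl_lo, refl_orient, refl_strand),
    ):
        a, b, score = _max_segment(match, mp.mismatch_penalty)
        if b - a < mp.min_seg_bp:
            continue
        nm_seg = int((~match[a:b]).sum())
        cand = (-score, base + a, orient, a, b, nm_seg, strand, base)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    _, seg_pos, orient, a, b, nm_seg, strand, base = best
    return _PredictedAln(
        pos=seg_pos,
        m_len=b - a,
        strand=strand,
        left_clip=a,
        right_clip=rl - b,
        nm=nm_seg,
    )


def truth_supporting_set(
    truth: TruthTable,
    iso: IsoformPair,
    cfg: SimConfig,
    params,
    map_params: MapParams | None = None,
) -> set[str]:
    """Fragment ids whose geometry satisfies the detection criteria.

    Computed purely from truth coordinates and the two genome sequences.
    Exact for complete-match arms and error-free reads (the regime in which
    it serves as the oracle for the detector); raises otherwise.
    """
    if cfg.error_rate > 0 or truth.errors:
        raise InputError("the truth oracle is defined for error-free reads")
    if iso.pair.match_class != "complete":
        raise InputError("the truth oracle requires a complete-match sIR pair")
    mp = map_params or MapParams()
    L = iso.normal.length
    rl = cfg.read_bp
    h0, h1 = iso.hr_start, iso.hr_end
    a = iso.pair.arm1.interval.span()
    b0, b1 = h0 + a, h1 - a  # inner arm edges: the genomes diverge only between them
    ncodes = iso.normal.codes
    vcodes = iso.inverted.codes
    arm1 = iso.pair.arm1.interval
    arm2 = iso.pair.arm2.interval

    # shortlist: inverted-origin fragments whose interval contains b0 or b1
    idx = np.flatnonzero(truth.origin_inverted)
    if idx.size == 0:
        return set()
    starts = truth.start[idx]
    inserts = truth.insert[idx]
    hit = np.zeros(idx.size, dtype=bool)
    for b in (b0, b1):
        hit |= ((b - starts) % L) < inserts
    shortlist = idx[hit]

    def wholly_inside(p: _PredictedAln) -> bool:
        return h0 <= p.pos and p.end <= h1

    def wholly_outside(p: _PredictedAln) -> bool:
        return p.end <= h0 or p.pos >= h1

    def overlaps(p: _PredictedAln, iv: Interval) -> bool:
        return p.pos < iv.end and iv.start < p.end

    def arm_distance(p: _PredictedAln, iv: Interval) -> int:
        if overlaps(p, iv):
            return 0
        return iv.start - p.end if p.end <= iv.start else p.pos - iv.end

    supporting: set[str] = set()
    for i in shortlist.tolist():
        s = int(truth.start[i])
        ins = int(truth.insert[i])
        # linearize around the crossed boundary (the HR region is origin-free)
        b = b0 if ((b0 - s) % L) < ins else b1
        s_lin = b - int((b - s) % L)
        e_lin = s_lin + ins
        if ins >= params.inverted_max_span_bp:
            continue  # mate span on the inverted reference fails the bound
        p1 = _predict_read(s_lin, s_lin + rl, False, ncodes, vcodes, h0, h1, mp)
        p2 = _predict_read(e_lin - rl, e_lin, True, ncodes, vcodes, h0, h1, mp)
        if p1 is None or p2 is None:
            continue

        # soft-clip path: a clip of >= min_clip_bp whose junction sits at an arm
        clip_read = None
        for p in (p1, p2):
            for clip, junction in ((p.left_clip, p.pos), (p.right_clip, p.end)):
                if clip >= params.min_clip_bp:
                    near1 = arm1.start - params.clip_junction_slack_bp <= junction <= arm1.end + params.clip_junction_slack_bp
                    near2 = arm2.start - params.clip_junction_slack_bp <= junction <= arm2.end + params.clip_junction_slack_bp
                    if near1 or near2:
                        clip_read = p
        if clip_read is not None:
            supporting.add(truth.fragment_id(i))
            continue

        # fully-aligned path: discordant orientation, ~HR-span separation
        left, right = (p1, p2) if p1.pos <= p2.pos else (p2, p1)
        orientation = ("F" if left.strand == "+" else "R") + (
            "F" if right.strand == "+" else "R"
        )
        span = max(left.end, right.end) - left.pos
        if orientation == "FR":
            continue
        if abs(span - (h1 - h0)) > params.span_tolerance_bp:
            continue
        arm_hit = any(overlaps(p, iv) for p in (p1, p2) for iv in (arm1, arm2))
        if not arm_hit:
            ok = False
            for pin, pout in ((p1, p2), (p2, p1)):
                if wholly_inside(pin) and wholly_outside(pout):
                    if min(arm_distance(pout, arm1), arm_distance(pout, arm2)) <= params.vicinity_bp:
                        ok = True
            if not ok:
                continue
        supporting.add(truth.fragment_id(i))
    return supporting
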