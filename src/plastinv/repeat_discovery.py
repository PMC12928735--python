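"""Discovery of short inverted-repeat (sIR) pairs and hairpin prediction.

A plastome carrying a short inverted-repeat pair — two ~50 bp arms in
opposite orientation separated by tens of kilobases — can undergo
intramolecular homologous recombination between the arms, inverting the
enclosed segment.  This module finds such arm pairs in a circular genome by
comparing the genome against its own reverse complement (k-mer seeding plus
maximal extension), classifies each pair as a complete or incomplete match,
and predicts the stem-loop (hairpin) structure each arm can fold into.

The hairpin model is purely combinatorial: the maximal antiparallel
Watson–Crick stem with a loop of at least ``min_loop_nt`` unpaired bases.
G·T wobble pairs are not allowed (DNA context).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from Bio import Align

from .genome_core import (
    CircularSequence,
    InputError,
    Interval,
    encode_seq,
    reverse_complement,
    revcomp_codes,
    _COMP_CODES,
)

__all__ = [
    "RepeatArm",
    "InvertedRepeatPair",
    "Hairpin",
    "find_inverted_repeat_pairs",
    "classify_match",
    "predict_hairpin",
    "arm_identity",
    "pairs_to_table",
]


@dataclass(frozen=True)
class RepeatArm:
    interval: Interval
    sequence: str
    label: str  # "sIR-1" (upstream) or "sIR-2" (downstream)


@dataclass(frozen=True)
class Hairpin:
    stem_bp: int
    loop_nt: int
    stem5_interval: Interval  # within the arm, 0-based half-open
    stem3_interval: Interval


@dataclass(frozen=True)
class InvertedRepeatPair:
    arm1: RepeatArm
    arm2: RepeatArm
    identity: float
    match_class: str  # "complete" | "incomplete"
    hr_region: Interval  # arm1.start .. arm2.end on the chosen linearization
    spacer_bp: int

    @property
    def hr_span(self) -> int:
        return self.hr_region.span()


def arm_identity(arm1_seq: str, arm2_seq: str) -> float:
    """Identity between arm1 and reverse_complement(arm2).

    Defined as identities / alignment columns of a global alignment with free
    end gaps (match +1, mismatch -1, gap -2).  1.0 iff the arms are perfect
    reverse complements of equal length.
    """
    a = arm1_seq
    b = reverse_complement(arm2_seq)
    if a == b:
        return 1.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    try:  # free end gaps; attribute names changed across Biopython releases
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # pragma: no cover
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def make_pair(genome: CircularSequence, a1: Interval, a2: Interval) -> InvertedRepeatPair:
    """Assemble an :class:`InvertedRepeatPair` from two arm intervals.

    ``a1`` must precede ``a2`` on the linearization and the arms must not
    overlap (the spanned region must not wrap the origin).
    """
    if a1.wraps or a2.wraps:
        raise InputError("arm intervals must not wrap the origin; rotate the genome first")
    if a1.end > a2.start:
        raise InputError("arm1 must precede arm2 with a non-negative spacer")
    s1 = genome.seq[a1.start : a1.end]
    s2 = genome.seq[a2.start : a2.end]
    ident = arm_identity(s1, s2)
    complete = ident == 1.0 and a1.span() == a2.span()
    return InvertedRepeatPair(
        arm1=RepeatArm(a1, s1, "sIR-1"),
        arm2=RepeatArm(a2, s2, "sIR-2"),
        identity=ident,
        match_class="complete" if complete else "incomplete",
        hr_region=Interval(a1.start, a2.end),
        spacer_bp=a2.start - a1.end,
    )


def classify_match(pair: InvertedRepeatPair) -> str:
    """complete iff identity == 1.0 and the arms have equal length."""
    if pair.identity == 1.0 and pair.arm1.interval.span() == pair.arm2.interval.span():
        return "complete"
    return "incomplete"


# --- discovery -------------------------------------------------------------


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact base-4 hashes of all k-mers; windows containing N are invalid."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    pow4 = (4 ** np.arange(k, dtype=np.uint64))[::-1]
    clean = np.where(codes == 4, 0, codes).astype(np.uint64)
    hashes = np.lib.stride_tricks.sliding_window_view(clean, k) @ pow4
    valid = ~np.any(win == 4, axis=1)
    return hashes, valid


def _maximal_run(comp: np.ndarray, codes: np.ndarray, D: int, x: int) -> tuple[int, int]:
    """Maximal run around x on anti-diagonal D of the self-vs-complement relation.

    Positions x with ``codes[x] == complement(codes[D - x])`` extend the run.
    Returns the inclusive run bounds (x0, x1).
    """
    L = codes.size
    x0 = x
    while x0 - 1 >= 0 and D - (x0 - 1) < L and codes[x0 - 1] == comp[D - x0 + 1]:
        x0 -= 1
    x1 = x
    while x1 + 1 < L and D - (x1 + 1) >= 0 and codes[x1 + 1] == comp[D - x1 - 1]:
        x1 += 1
    return x0, x1


def _exact_runs(
    genome: CircularSequence, k: int, max_seed_occ: int = 100
) -> list[tuple[int, int, int]]:
    """All distinct maximal exact inverted-repeat runs seeded by shared k-mers.

    Returns triples ``(D, x0, x1)``: on anti-diagonal ``D`` every position
    ``x`` in ``[x0, x1]`` satisfies ``g[x] == complement(g[D - x])``.  Each
    physical arm pair appears as two mirrored runs on the same diagonal; the
    caller canonicalizes.
    """
    codes = genome.codes
    L = codes.size
    comp = _COMP_CODES[codes]
    rc = revcomp_codes(codes)
    hg, vg = _kmer_hashes(codes, k)
    hr, vr = _kmer_hashes(rc, k)

    order = np.argsort(hr, kind="stable")
    sorted_hr = hr[order]
    lo = np.searchsorted(sorted_hr, hg, side="left")
    hi = np.searchsorted(sorted_hr, hg, side="right")
    counts = hi - lo
    counts[~vg] = 0
    # Frequency cap: skip hyper-abundant seeds (low-complexity sequence).
    counts[counts > max_seed_occ] = 0
    gi = np.repeat(np.arange(hg.size), counts)
    if gi.size == 0:
        return []
    offsets = np.concatenate([np.arange(lo[i], hi[i]) for i in np.flatnonzero(counts)])
    rj = order[offsets]
    valid = vr[rj]
    gi, rj = gi[valid], rj[valid]

    # rc index j corresponds to genome positions [L - j - k, L - j)
    q = L - rj - k
    D = gi + q + k - 1

    runs: dict[tuple[int, int], int] = {}
    seen_seed: set[tuple[int, int]] = set()
    out: list[tuple[int, int, int]] = []
    for i, d in zip(gi.tolist(), D.tolist()):
        key = (d, i)
        if key in seen_seed:
            continue
        x0, x1 = _maximal_run(comp, codes, d, int(i))
        for xx in range(x0, x1 - k + 2):
            seen_seed.add((d, xx))
        if (d, x0) not in runs:
            runs[(d, x0)] = x1
            out.append((d, x0, x1))
    return out


def find_inverted_repeat_pairs(
    genome: CircularSequence,
    min_arm_bp: int = 30,
    max_arm_bp: int = 1000,
    min_span_bp: int = 5000,
    max_span_bp: int = 60000,
    min_identity: float = 0.8,
    seed_k: int = 12,
    cluster_gap_bp: int = 60,
    cluster_band_bp: int = 10,
) -> list[InvertedRepeatPair]:
    """Find sIR pairs by self-comparison of the genome with its reverse complement.

    Exact maximal inverted matches are seeded with shared ``seed_k``-mers and
    extended to their full extent.  When ``min_identity < 1``, nearby exact
    runs (separated by substitutions, or by small indels shifting the
    anti-diagonal by at most ``cluster_band_bp``) are chained into a single
    imperfect candidate whose identity is then scored by global end-free
    alignment of arm1 against the reverse complement of arm2.

    Returned pairs satisfy the arm-length, spanned-region and identity
    bounds, have arm1 before arm2 with a non-negative spacer, and are sorted
    by descending identity, then descending arm length, then position.
    Reports nested inside a larger report of the same pair are dropped.
    """
    if min_arm_bp < 12:
        raise InputError("min_arm_bp must be >= 12")
    max_span_bp = min(max_span_bp, genome.length)
    if not 0 < min_span_bp < max_span_bp:
        raise InputError("require 0 < min_span_bp < max_span_bp")
    k = min(seed_k, min_arm_bp)

    runs = _exact_runs(genome, k)
    # Candidate (arm1, arm2) from single runs, canonicalized arm1 < arm2.
    singles: set[tuple[int, int, int, int]] = set()
    for d, x0, x1 in runs:
        a = (x0, x1 + 1)
        b = (d - x1, d - x0 + 1)
        (s1, e1), (s2, e2) = sorted([a, b])
        if e1 <= s2:  # disjoint arms with non-negative spacer
            singles.add((s1, e1, s2, e2))

    candidates = set(singles)
    if min_identity < 1.0:
        ordered = sorted(singles)
        used = [False] * len(ordered)
        for i0 in range(len(ordered)):
            if used[i0]:
                continue
            chain = [ordered[i0]]
            cur = ordered[i0]
            for j0 in range(i0 + 1, len(ordered)):
                nxt = ordered[j0]
                d_cur = cur[0] + cur[3] - 1
                d_nxt = nxt[0] + nxt[3] - 1
                gap1 = nxt[0] - cur[1]
                gap2 = cur[2] - nxt[3]
                if (
                    -5 <= gap1 <= cluster_gap_bp
                    and -5 <= gap2 <= cluster_gap_bp
                    and abs(d_nxt - d_cur) <= cluster_band_bp
                ):
                    chain.append(nxt)
                    used[j0] = True
                    cur = (
                        min(cur[0], nxt[0]),
                        max(cur[1], nxt[1]),
                        min(cur[2], nxt[2]),
                        max(cur[3], nxt[3]),
                    )
            if len(chain) > 1 and cur[1] <= cur[2]:
                candidates.add(cur)

    results: list[InvertedRepeatPair] = []
    for s1, e1, s2, e2 in candidates:
        len1, len2 = e1 - s1, e2 - s2
        if not (min_arm_bp <= len1 <= max_arm_bp and min_arm_bp <= len2 <= max_arm_bp):
            continue
        span = e2 - s1
        if not (min_span_bp <= span <= max_span_bp):
            continue
        pair = make_pair(genome, Interval(s1, e1), Interval(s2, e2))
        if pair.identity >= min_identity:
            results.append(pair)

    # Drop reports nested inside a larger report of the same pair.
    def _nested(p: InvertedRepeatPair, q: InvertedRepeatPair) -> bool:
        return (
            q.arm1.interval.start <= p.arm1.interval.start
            and p.arm1.interval.end <= q.arm1.interval.end
            and q.arm2.interval.start <= p.arm2.interval.start
            and p.arm2.interval.end <= q.arm2.interval.end
            and (p.arm1.interval, p.arm2.interval) != (q.arm1.interval, q.arm2.interval)
        )

    results = [p for p in results if not any(_nested(p, q) for q in results)]
    results.sort(
        key=lambda p: (
            -p.identity,
            -(p.arm1.interval.span() + p.arm2.interval.span()),
            p.arm1.interval.start,
        )
    )
    return results


# --- hairpin ---------------------------------------------------------------


def predict_hairpin(arm_seq: str, min_loop_nt: int = 3) -> Hairpin | None:
    """Maximal-stem hairpin of a single-stranded DNA sequence.

    Among all antiparallel strict Watson–Crick stems (positions ``i..i+L-1``
    pairing with ``j..j+L-1``, loop ``j - (i + L) >= min_loop_nt``), returns
    the structure maximizing the stem length; ties are broken by smaller
    loop, then smaller ``i``.  Returns ``None`` when no stem of at least
    2 bp exists.
    """
    codes = encode_seq(arm_seq)
    n = codes.size
    if n < min_loop_nt + 2:
        raise InputError("sequence shorter than min_loop_nt + 2")
    comp = _COMP_CODES[codes]
    best: tuple[int, int, int] | None = None  # (-stem, loop, i): min() is the winner
    for D in range(min_loop_nt + 2, 2 * n - 2):
        # base pairs (x, D - x) with x < D - x; x_hi enforces the loop minimum
        x_lo = max(0, D - n + 1)
        x_hi = (D - 1 - min_loop_nt) // 2
        run_start = -1
        for x in range(x_lo, x_hi + 2):
            ok = (
                x <= x_hi
                and codes[x] != 4
                and codes[D - x] != 4
                and codes[x] == comp[D - x]
            )
            if ok and run_start < 0:
                run_start = x
            elif not ok and run_start >= 0:
                inner = x - 1
                stem = inner - run_start + 1
                loop = D - 2 * inner - 1
                cand = (-stem, loop, run_start)
                if stem >= 2 and (best is None or cand < best):
                    best = cand
                run_start = -1
    if best is None:
        return None
    stem, loop, i = -best[0], best[1], best[2]
    inner = i + stem - 1
    D = 2 * inner + 1 + loop
    return Hairpin(
        stem_bp=stem,
        loop_nt=loop,
        stem5_interval=Interval(i, i + stem),
        stem3_interval=Interval(D - inner, D - i + 1),
    )


# --- reporting -------------------------------------------------------------


def pairs_to_table(genome: CircularSequence, pairs: Iterable[InvertedRepeatPair]):
    """TSV-ready report of discovered pairs (1-based inclusive coordinates)."""
    import pandas as pd

    rows = []
    for p in pairs:
        hp = predict_hairpin(p.arm2.sequence) if p.arm2.interval.span() >= 5 else None
        rows.append(
            {
                "genome_id": genome.id,
                "arm1_start": p.arm1.interval.start + 1,
                "arm1_end": p.arm1.interval.end,
                "arm2_start": p.arm2.interval.start + 1,
                "arm2_end": p.arm2.interval.end,
                "arm1_seq": p.arm1.sequence,
                "arm2_seq": p.arm2.sequence,
                "identity": round(p.identity, 4),
                "match_class": p.match_class,
                "hr_span_bp": p.hr_span,
                "hairpin_stem_bp": hp.stem_bp if hp else 0,
                "hairpin_loop_nt": hp.loop_nt if hp else 0,
            }
        )
    return pd.DataFrame(rows)
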