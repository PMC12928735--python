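"""SAM parsing, per-base depth, and a lightweight internal read mapper.

The production path of the pipeline consumes SAM produced by any external
aligner.  The internal mapper exists so the whole pipeline can run with no
external tooling: it is a seed-and-verify ungapped mapper (exact k-mer
seeds, full-length verification, soft-clipping by maximal-scoring segment)
adequate for short reads against a single small circular reference.  It
reports one primary alignment per read; bases outside the best-scoring
ungapped segment are soft-clipped.

Circular references are indexed on a doubled sequence; positions are
reported in ``[0, L)`` and an alignment may overhang the origin (depth
computation folds the overhang back).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

from .genome_core import (
    CircularSequence,
    InputError,
    Interval,
    decode_seq,
    encode_seq,
    _COMP_CODES,
)

__all__ = [
    "ReadAlignment",
    "AlignedPair",
    "MapParams",
    "ReferenceIndex",
    "read_sam",
    "write_sam",
    "pair_alignments",
    "mean_depth",
    "lightweight_map",
    "map_encoded_pairs",
]

# SAM flag bits
FPAIRED, FPROPER, FUNMAP, FMUNMAP = 0x1, 0x2, 0x4, 0x8
FREVERSE, FMREVERSE, FREAD1, FREAD2 = 0x10, 0x20, 0x40, 0x80
FSECONDARY, FQCFAIL, FDUP, FSUPPLEMENTARY = 0x100, 0x200, 0x400, 0x800

_CIGAR_OPS = "MIDNSHP=X"


@dataclass(slots=True)
class ReadAlignment:
    read_id: str
    mate_rank: int  # 1 or 2
    ref_id: str
    pos: int  # 0-based leftmost mapped position (-1 if unmapped)
    strand: str  # '+' or '-'
    cigar: tuple[tuple[str, int], ...]
    mapq: int
    flag: int
    # sequence as stored in SAM (reverse-complemented for '-'); kept either
    # as a string or as a uint8 code array decoded on demand via seq_str()
    seq: "str | np.ndarray | None" = None
    nm: int | None = None

    def seq_str(self) -> str | None:
        if self.seq is None or isinstance(self.seq, str):
            return self.seq
        self.seq = decode_seq(self.seq)
        return self.seq

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FUNMAP)

    @property
    def is_primary(self) -> bool:
        return not self.flag & (FSECONDARY | FSUPPLEMENTARY)

    @property
    def counted_for_depth(self) -> bool:
        return not self.flag & (FUNMAP | FSECONDARY | FSUPPLEMENTARY | FDUP | FQCFAIL)

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def end(self) -> int:
        return self.pos + self.ref_span

    @property
    def read_len(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    @property
    def left_clip(self) -> int:
        return self.cigar[0][1] if self.cigar and self.cigar[0][0] == "S" else 0

    @property
    def right_clip(self) -> int:
        return self.cigar[-1][1] if self.cigar and self.cigar[-1][0] == "S" else 0

    @property
    def max_clip(self) -> int:
        return max(self.left_clip, self.right_clip)

    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.cigar)


@dataclass(slots=True)
class AlignedPair:
    read1: ReadAlignment | None
    read2: ReadAlignment | None

    @property
    def both_mapped(self) -> bool:
        return (
            self.read1 is not None
            and self.read2 is not None
            and not self.read1.is_unmapped
            and not self.read2.is_unmapped
        )

    @property
    def ordered(self) -> tuple[ReadAlignment, ReadAlignment]:
        """Mates ordered by leftmost mapped position."""
        a, b = self.read1, self.read2
        assert a is not None and b is not None
        return (a, b) if a.pos <= b.pos else (b, a)

    @property
    def orientation(self) -> str:
        """FR / RF / FF / RR by leftmost-then-rightmost strand; '?' if unpaired."""
        if not self.both_mapped:
            return "?"
        left, right = self.ordered
        code = {"+": "F", "-": "R"}
        return code[left.strand] + code[right.strand]

    @property
    def observed_span(self) -> int:
        left, right = self.ordered
        return max(left.end, right.end) - left.pos


# --- SAM I/O ---------------------------------------------------------------


def _from_pysam(rec: pysam.AlignedSegment, line_no: int) -> ReadAlignment:
    cig: list[tuple[str, int]] = []
    if rec.cigartuples:
        for op, n in rec.cigartuples:
            ch = _CIGAR_OPS[op]
            if ch in "=X":
                ch = "M"
            if ch == "H":
                continue  # hard clips carry no sequence
            if ch not in "MIDS":
                raise InputError(
                    f"unsupported CIGAR op {ch!r} in SAM record at line ~{line_no}"
                )
            if cig and cig[-1][0] == ch:
                cig[-1] = (ch, cig[-1][1] + n)
            else:
                cig.append((ch, n))
    seq = rec.query_sequence
    if seq and cig:
        implied = sum(n for op, n in cig if op in "MIS")
        if implied != len(seq):
            raise InputError(
                f"CIGAR/sequence length mismatch ({implied} vs {len(seq)}) "
                f"for read {rec.query_name!r} at line ~{line_no}"
            )
    nm = None
    try:
        nm = int(rec.get_tag("NM"))
    except KeyError:
        pass
    return ReadAlignment(
        read_id=rec.query_name or "",
        mate_rank=2 if rec.flag & FREAD2 else 1,
        ref_id=rec.reference_name or "*",
        pos=rec.reference_start if not rec.is_unmapped else -1,
        strand="-" if rec.flag & FREVERSE else "+",
        cigar=tuple(cig),
        mapq=rec.mapping_quality,
        flag=rec.flag,
        seq=seq,
        nm=nm,
    )


def read_sam(path, expected_ref: str | None = None) -> Iterator[ReadAlignment]:
    """Iterate over all records of a SAM text file (secondary included, flagged)."""
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        if expected_ref is not None:
            names = list(fh.references or [])
            if names and expected_ref not in names:
                raise InputError(
                    f"SAM references {names} do not include expected {expected_ref!r}"
                )
        for i, rec in enumerate(fh):
            yield _from_pysam(rec, i + 1)


def write_sam(alignments: Iterable[ReadAlignment], ref: CircularSequence, path) -> None:
    """Write a minimal SAM (@HD/@SQ header, 11 mandatory columns, NM tag)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.id, "LN": ref.length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.read_id
            rec.flag = a.flag
            if a.is_unmapped:
                rec.reference_id = -1
                rec.reference_start = -1
                rec.mapping_quality = 0
            else:
                rec.reference_id = 0
                rec.reference_start = a.pos
                rec.mapping_quality = a.mapq
                rec.cigarstring = a.cigar_string()
            seq = a.seq_str()
            if seq:
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if a.nm is not None:
                rec.set_tag("NM", a.nm)
            out.write(rec)


def pair_alignments(alignments: Iterable[ReadAlignment]) -> list[AlignedPair]:
    """Pair primary alignments by read id; missing mates yield one-sided pairs."""
    by_id: dict[str, list[ReadAlignment | None]] = {}
    order: list[str] = []
    for a in alignments:
        if not a.is_primary:
            continue
        slot = by_id.get(a.read_id)
        if slot is None:
            slot = [None, None]
            by_id[a.read_id] = slot
            order.append(a.read_id)
        slot[a.mate_rank - 1] = a
    return [AlignedPair(*by_id[rid]) for rid in order]


def mean_depth(
    alignments: Iterable[ReadAlignment],
    region: Interval,
    ref_length: int | None = None,
) -> float:
    """Mean per-base count of covering alignments over ``region``.

    Counts M/D reference spans of mapped primary, non-duplicate, non-QC-fail
    records (soft clips contribute nothing); no MAPQ or base-quality
    threshold, mirroring the common default of ``samtools depth``.
    """
    if region.wraps:
        raise InputError("depth over a wrapping region is not supported; rotate first")
    if region.span() <= 0:
        raise InputError("empty region")
    starts: list[int] = []
    ends: list[int] = []
    for a in alignments:
        if not a.counted_for_depth:
            continue
        starts.append(a.pos)
        ends.append(a.pos + a.ref_span)
    if not starts:
        return 0.0
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if ref_length is not None:
        # fold origin-overhanging alignments back onto the circle
        wrap = e > ref_length
        if np.any(wrap):
            extra_s = np.zeros(int(wrap.sum()), dtype=np.int64)
            extra_e = e[wrap] - ref_length
            e = np.where(wrap, ref_length, e)
            s = np.concatenate([s, extra_s])
            e = np.concatenate([e, extra_e])
    lo, hi = region.start, region.end
    s = np.clip(s, lo, hi)
    e = np.clip(e, lo, hi)
    keep = e > s
    diff = np.zeros(hi - lo + 1, dtype=np.int64)
    np.add.at(diff, s[keep] - lo, 1)
    np.add.at(diff, e[keep] - lo, -1)
    cover = np.cumsum(diff[:-1])
    return float(cover.mean())


# --- internal mapper -------------------------------------------------------


@dataclass
class MapParams:
    seed_k: int = 21
    max_mismatch_rate: float = 0.02  # full-length acceptance threshold
    min_seg_bp: int = 30  # minimum soft-clipped alignment segment
    mismatch_penalty: int = 4  # segment scoring: match +1, mismatch -penalty


class ReferenceIndex:
    """Exact k-mer index of a (doubled, if circular) reference sequence."""

    def __init__(self, ref: CircularSequence, k: int = 21):
        self.ref = ref
        self.k = k
        self.L = ref.length
        codes = ref.codes
        self.codes2 = np.concatenate([codes, codes]) if ref.circular else codes
        from .repeat_discovery import _kmer_hashes

        hashes, valid = _kmer_hashes(self.codes2, k)
        hashes = hashes.copy()
        hashes[~valid] = np.uint64(0xFFFFFFFFFFFFFFFF)
        self.order = np.argsort(hashes, kind="stable")
        self.sorted_hashes = hashes[self.order]

    def lookup_ranges(self, qhashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_hashes, qhashes, side="left")
        hi = np.searchsorted(self.sorted_hashes, qhashes, side="right")
        return lo, hi


def _row_hashes(mat: np.ndarray, off: int, k: int) -> np.ndarray:
    pow4 = (4 ** np.arange(k, dtype=np.uint64))[::-1]
    block = mat[:, off : off + k].astype(np.uint64)
    return block @ pow4


def _best_segment(matchvec: np.ndarray, penalty: int) -> tuple[int, int, int]:
    """Maximal-scoring contiguous segment (match +1, mismatch -penalty).

    Returns (start, end, score); ties resolved to the leftmost segment.
    """
    score = np.where(matchvec, 1, -penalty).astype(np.int64)
    best = 0
    best_se = (0, 0)
    run = 0
    run_start = 0
    for i, v in enumerate(score.tolist()):
        if run <= 0:
            run = v
            run_start = i
        else:
            run += v
        if run > best:
            best = run
            best_se = (run_start, i + 1)
    return best_se[0], best_se[1], best


def map_encoded_pairs(
    ids: Sequence[str],
    r1: np.ndarray,
    r2: np.ndarray,
    index: ReferenceIndex,
    params: MapParams | None = None,
) -> list[ReadAlignment]:
    """Map paired reads given as code matrices (N, read_len) against the index.

    Returns 2N alignments in input order (R1 then R2 per pair).  Deterministic:
    among equal-scoring placements the lowest reference offset wins, with '+'
    orientation preferred on exact ties.
    """
    params = params or MapParams()
    n_pairs, rl = r1.shape
    reads = np.concatenate([r1, r2], axis=0)
    n = reads.shape[0]
    k = index.k
    L = index.L
    max_mm = math.floor(params.max_mismatch_rate * rl)

    rc = _COMP_CODES[reads][:, ::-1]
    oriented = (reads, rc)

    # candidate collection: (read, orient, start mod L)
    cand_read: list[np.ndarray] = []
    cand_start: list[np.ndarray] = []
    cand_orient: list[np.ndarray] = []

    def _collect(offsets: Sequence[int], subset: np.ndarray | None) -> None:
        for orient in (0, 1):
            mat = oriented[orient] if subset is None else oriented[orient][subset]
            ridx0 = np.arange(n) if subset is None else subset
            for off in offsets:
                qh = _row_hashes(mat, off, k)
                lo, hi = index.lookup_ranges(qh)
                counts = hi - lo
                counts = np.minimum(counts, 50)  # ambiguity cap per seed
                nz = np.flatnonzero(counts)
                if nz.size == 0:
                    continue
                reps = counts[nz]
                rows = np.repeat(nz, reps)
                total = int(reps.sum())
                within = np.arange(total) - np.repeat(np.cumsum(reps) - reps, reps)
                offs = np.repeat(lo[nz], reps) + within
                hitpos = index.order[offs]
                start = hitpos - off
                ok = (start >= 0) & (start + rl <= index.codes2.size)
                cand_read.append(ridx0[rows[ok]])
                cand_start.append(start[ok] % L)
                cand_orient.append(np.full(int(ok.sum()), orient, dtype=np.int8))

    _collect([0, (rl - k) // 2, rl - k], None)

    def _dedup() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if not cand_read:
            return (np.empty(0, np.int64),) * 3
        r = np.concatenate(cand_read)
        s = np.concatenate(cand_start)
        o = np.concatenate([c.astype(np.int64) for c in cand_orient])
        key = (r.astype(np.int64) * 2 + o) * L + s
        _, uniq = np.unique(key, return_index=True)
        return r[uniq].astype(np.int64), s[uniq].astype(np.int64), o[uniq]

    def _verify(rs: np.ndarray, ss: np.ndarray, os_: np.ndarray) -> np.ndarray:
        mm = np.empty(rs.size, dtype=np.int32)
        for c0 in range(0, rs.size, 200_000):
            c1 = min(c0 + 200_000, rs.size)
            seg = index.codes2[ss[c0:c1, None] + np.arange(rl)]
            sel = np.where(
                (os_[c0:c1] == 0)[:, None], reads[rs[c0:c1]], rc[rs[c0:c1]]
            )
            mm[c0:c1] = (seg != sel).sum(axis=1, dtype=np.int32)
        return mm

    def _select_best(rs, ss, os_, mm):
        # best candidate per read: lexicographic (mismatches, start, orient)
        pos = np.full(n, -1, dtype=np.int64)
        strand = np.zeros(n, dtype=np.int8)
        best_mm = np.full(n, rl + 1, dtype=np.int32)
        mapq = np.zeros(n, dtype=np.int16)
        if rs.size:
            order = np.lexsort((os_, ss, mm, rs))
            ro, so, oo, mo = rs[order], ss[order], os_[order], mm[order]
            first = np.ones(ro.size, dtype=bool)
            first[1:] = ro[1:] != ro[:-1]
            fi = np.flatnonzero(first)
            pos[ro[fi]] = so[fi]
            strand[ro[fi]] = oo[fi]
            best_mm[ro[fi]] = mo[fi]
            # unique placement => mapq 60; a second equal-mismatch one => 0
            nxt = fi + 1
            has_next = nxt < ro.size
            tie = np.zeros(fi.size, dtype=bool)
            tie[has_next] = (ro[nxt[has_next]] == ro[fi[has_next]]) & (
                mo[nxt[has_next]] == mo[fi[has_next]]
            )
            mapq[ro[fi]] = np.where(tie, 0, 60)
        return pos, strand, best_mm, mapq

    r_idx, s_pos, o_idx = _dedup()
    mm = _verify(r_idx, s_pos, o_idx)
    results_pos, results_strand, results_mm, results_mapq = _select_best(
        r_idx, s_pos, o_idx, mm
    )

    # Reads without an acceptable full-length placement retry with dense
    # seed offsets: errors or a breakpoint may dirty every sparse window
    # while a repeat elsewhere still seeds a (misleading) candidate.
    needs_more = np.flatnonzero(results_mm > max_mm)
    if needs_more.size:
        cand_read.clear()
        cand_start.clear()
        cand_orient.clear()
        dense = sorted(set(range(0, rl - k + 1, max(1, k // 2))) | {rl - k})
        _collect(dense, needs_more)
        r2_idx, s2_pos, o2_idx = _dedup()
        if r2_idx.size:
            keep = np.isin(r_idx, needs_more)
            pool_r = np.concatenate([r_idx[keep], r2_idx])
            pool_s = np.concatenate([s_pos[keep], s2_pos])
            pool_o = np.concatenate([o_idx[keep], o2_idx])
            key = (pool_r * 2 + pool_o) * L + pool_s
            _, uniq = np.unique(key, return_index=True)
            pool_r, pool_s, pool_o = pool_r[uniq], pool_s[uniq], pool_o[uniq]
            pool_mm = _verify(pool_r, pool_s, pool_o)
            p_pos, p_strand, p_mm, p_mapq = _select_best(
                pool_r, pool_s, pool_o, pool_mm
            )
            results_pos[needs_more] = p_pos[needs_more]
            results_strand[needs_more] = p_strand[needs_more]
            results_mm[needs_more] = p_mm[needs_more]
            results_mapq[needs_more] = p_mapq[needs_more]
            # merged pool feeds the soft-clip fallback below
            r_idx = np.concatenate([r_idx[~keep], pool_r])
            s_pos = np.concatenate([s_pos[~keep], pool_s])
            o_idx = np.concatenate([o_idx[~keep], pool_o])

    full_ok = results_mm <= max_mm
    fallback = np.flatnonzero((results_pos >= 0) & ~full_ok)

    # per-read soft-clip fallback over its candidate list
    fb_res: dict[int, tuple[int, int, int, int, int, int]] = {}
    if fallback.size:
        by_read: dict[int, list[int]] = {}
        for ci in range(r_idx.size):
            rr = int(r_idx[ci])
            if (~full_ok)[rr] and results_pos[rr] >= 0:
                by_read.setdefault(rr, []).append(ci)
        for rr in fallback.tolist():
            best = None  # (-score, ref_start, orient, a, b, nm_seg)
            for ci in by_read.get(rr, []):
                start = int(s_pos[ci])
                orient = int(o_idx[ci])
                sel = reads[rr] if orient == 0 else rc[rr]
                seg = index.codes2[start : start + rl]
                matchvec = seg == sel
                a, b, score = _best_segment(matchvec, params.mismatch_penalty)
                if b - a < params.min_seg_bp:
                    continue
                nm_seg = int((~matchvec[a:b]).sum())
                cand = (-score, start + a, orient, a, b, nm_seg)
                if best is None or cand < best:
                    best = cand
            if best is not None:
                fb_res[rr] = best

    alignments: list[ReadAlignment | None] = [None] * n
    ref_id = index.ref.id
    for i in range(n):
        pair_i = i % n_pairs
        rank = 1 if i < n_pairs else 2
        rid = ids[pair_i]
        mapped = False
        if results_pos[i] >= 0 and full_ok[i]:
            pos = int(results_pos[i])
            orient = int(results_strand[i])
            cig: tuple[tuple[str, int], ...] = (("M", rl),)
            nm_val = int(results_mm[i])
            mapq = int(results_mapq[i])
            mapped = True
        elif i in fb_res:
            negscore, refstart, orient, a, b, nm_val = fb_res[i]
            pos = refstart
            cig = tuple(
                [("S", a)] * (a > 0) + [("M", b - a)] + [("S", rl - b)] * (rl - b > 0)
            )
            mapq = 30
            mapped = True
        if mapped:
            stored = reads[i] if orient == 0 else rc[i]
            flag = FPAIRED | (FREAD1 if rank == 1 else FREAD2)
            if orient == 1:
                flag |= FREVERSE
            alignments[i] = ReadAlignment(
                rid, rank, ref_id, pos,
                "-" if orient else "+", cig, mapq, flag, stored, nm_val,
            )
        else:
            flag = FPAIRED | FUNMAP | (FREAD1 if rank == 1 else FREAD2)
            alignments[i] = ReadAlignment(
                rid, rank, "*", -1, "+", (), 0, flag, reads[i], None,
            )

    # mate flags (mate-reverse / mate-unmapped / proper-pair)
    out: list[ReadAlignment] = []
    for i in range(n_pairs):
        a1 = alignments[i]
        a2 = alignments[i + n_pairs]
        assert a1 is not None and a2 is not None
        for a, b in ((a1, a2), (a2, a1)):
            if b.is_unmapped:
                a.flag |= FMUNMAP
            elif b.strand == "-":
                a.flag |= FMREVERSE
        if not a1.is_unmapped and not a2.is_unmapped:
            pr = AlignedPair(a1, a2)
            if pr.orientation == "FR" and pr.observed_span <= 2000:
                a1.flag |= FPROPER
                a2.flag |= FPROPER
        out.append(a1)
        out.append(a2)
    return out


def lightweight_map(
    reads: Iterable[tuple[str, str, str]] | tuple,
    ref: CircularSequence,
    params: MapParams | None = None,
) -> list[ReadAlignment]:
    """Map paired-end reads against a reference with the internal mapper.

    ``reads`` is either a pair of FASTQ paths ``(r1_path, r2_path)`` or a
    pair of sequences-of-(id, seq) iterables.  All reads in one call must
    share a common length.
    """
    params = params or MapParams()
    r1_src, r2_src = reads

    def _load(src) -> tuple[list[str], list[str]]:
        if isinstance(src, (str, bytes)) or hasattr(src, "__fspath__"):
            from .genome_core import read_fastq

            pairs = [(rid, s) for rid, s, _q in read_fastq(src)]
        else:
            pairs = [(rid, s) for rid, s in src]
        return [p[0] for p in pairs], [p[1] for p in pairs]

    ids1, seqs1 = _load(r1_src)
    ids2, seqs2 = _load(r2_src)
    if len(ids1) != len(ids2):
        raise InputError("R1/R2 read counts differ")
    ids = [i1.rsplit("/", 1)[0] for i1 in ids1]
    lens = {len(s) for s in seqs1} | {len(s) for s in seqs2}
    if len(lens) != 1:
        raise InputError("internal mapper requires uniform read length")
    rl = lens.pop()
    r1 = np.vstack([encode_seq(s) for s in seqs1]) if seqs1 else np.empty((0, rl), np.uint8)
    r2 = np.vstack([encode_seq(s) for s in seqs2]) if seqs2 else np.empty((0, rl), np.uint8)
    index = ReferenceIndex(ref, k=params.seed_k)
    return map_encoded_pairs(ids, r1, r2, index, params)
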