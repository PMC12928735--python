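import subprocess

import numpy as np
import pytest

from plastinv.genome_core import CircularSequence, Interval, reverse_complement, write_fasta
from plastinv.alignment_layer import (
    AlignedPair,
    MapParams,
    ReadAlignment,
    ReferenceIndex,
    lightweight_map,
    map_encoded_pairs,
    mean_depth,
    pair_alignments,
    read_sam,
    write_sam,
)
from plastinv.isoform_builder import build_inverted_isoform
from plastinv.read_simulator import SimConfig, simulate_dataset

from conftest import random_seq


def _aln(pos, strand, cigar, rank=1, rid="r", flag=None):
    fl = 0x1 | (0x40 if rank == 1 else 0x80)
    if strand == "-":
        fl |= 0x10
    if flag is not None:
        fl = flag
    return ReadAlignment(rid, rank, "ref", pos, strand, cigar, 60, fl)


def test_cigar_arithmetic():
    a = _aln(100, "+", (("M", 100), ("S", 50)))
    assert a.ref_span == 100
    assert a.read_len == 150
    assert a.right_clip == 50 and a.left_clip == 0
    assert a.end == 200


def test_pair_orientation_and_span():
    p = AlignedPair(_aln(100, "+", (("M", 150),)), _aln(350, "-", (("M", 150),), rank=2))
    assert p.orientation == "FR"
    assert p.observed_span == 400
    q = AlignedPair(_aln(350, "+", (("M", 150),)), _aln(100, "+", (("M", 150),), rank=2))
    assert q.orientation == "FF"


def test_sam_round_trip(tmp_path, rng):
    ref = CircularSequence("ref", random_seq(rng, 500))
    alns = [
        ReadAlignment("a", 1, "ref", 10, "+", (("M", 20),), 60, 0x1 | 0x40, "ACGT" * 5, 0),
        ReadAlignment("a", 2, "ref", 100, "-", (("S", 5), ("M", 15)), 60, 0x1 | 0x80 | 0x10, "ACGT" * 5, 1),
        ReadAlignment("b", 1, "*", -1, "+", (), 0, 0x1 | 0x40 | 0x4, "ACGT" * 5, None),
    ]
    path = tmp_path / "x.sam"
    write_sam(alns, ref, path)
    back = list(read_sam(path, expected_ref="ref"))
    assert len(back) == 3
    for orig, rt in zip(alns, back):
        assert (rt.read_id, rt.mate_rank, rt.pos, rt.strand, rt.cigar, rt.flag) == (
            orig.read_id,
            orig.mate_rank,
            orig.pos,
            orig.strand,
            orig.cigar,
            orig.flag,
        )
        assert rt.nm == orig.nm


def test_mean_depth_examples():
    region = Interval(0, 300)
    assert mean_depth([], region) == 0.0
    one = [_aln(50, "+", (("M", 150),))]
    assert mean_depth(one, region) == pytest.approx(0.5)
    # secondary/duplicate/qcfail and soft-clipped portions do not count
    sec = _aln(50, "+", (("M", 150),), flag=0x100)
    dup = _aln(50, "+", (("M", 150),), flag=0x400)
    clipped = _aln(50, "+", (("S", 100), ("M", 50)))
    assert mean_depth([sec, dup], region) == 0.0
    assert mean_depth([clipped], region) == pytest.approx(50 / 300)


def test_depth_conservation(small_sim):
    index = ReferenceIndex(small_sim.normal, k=21)
    alns = map_encoded_pairs(
        small_sim.reads.ids, small_sim.reads.r1, small_sim.reads.r2, index
    )
    L = small_sim.normal.length
    total_m = sum(a.ref_span for a in alns if a.counted_for_depth)
    whole = mean_depth(alns, Interval(0, L), ref_length=L)
    assert whole * L == pytest.approx(total_m)


def test_mapper_exact_and_reverse_reads(rng):
    ref = CircularSequence("ref", random_seq(rng, 8000))
    fwd = ref.seq[1000:1150]
    rev = reverse_complement(ref.seq[4000:4150])
    alns = lightweight_map(
        ([("p", fwd)], [("p", rev)]),
        ref,
    )
    a, b = alns
    assert (a.pos, a.strand, a.cigar) == (1000, "+", (("M", 150),))
    assert (b.pos, b.strand, b.cigar) == (4000, "-", (("M", 150),))
    assert AlignedPair(a, b).orientation == "FR"


def test_breakpoint_read_soft_clips_on_normal_and_maps_fully_on_inverted(rng):
    from plastinv.repeat_discovery import find_inverted_repeat_pairs

    arm = random_seq(rng, 53)
    g = CircularSequence(
        "g",
        random_seq(rng, 1999) + "A" + arm + "A" + random_seq(rng, 5892) + "A"
        + reverse_complement(arm) + "A" + random_seq(rng, 1999),
    )
    pair = find_inverted_repeat_pairs(g, min_span_bp=1000, max_span_bp=g.length)[0]
    iso = build_inverted_isoform(g, pair)
    # read from the inverted isoform across the inner edge of arm1, with the
    # identity-side segment (120 bp incl. the arm) longer than the reflected
    # alternative (30 bp of spacer + 53 bp arm)
    b0 = pair.arm1.interval.end
    read = iso.inverted.seq[b0 - 120 : b0 + 30]
    mate = reverse_complement(iso.inverted.seq[b0 + 200 : b0 + 350])
    alns = lightweight_map(([("x", read)], [("x", mate)]), g)
    a = alns[0]
    assert a.pos == b0 - 120
    assert a.cigar[0][0] == "M" and a.cigar[0][1] >= 120  # chance extension may add bases
    assert a.left_clip == 0 and 20 <= a.right_clip <= 30
    # the clip junction sits at the arm's inner edge (up to chance extension)
    assert 0 <= a.end - b0 <= 10
    # the same read maps end-to-end on the inverted reference
    alns_inv = lightweight_map(([("x", read)], [("x", mate)]), iso.inverted)
    assert alns_inv[0].cigar == (("M", 150),)
    assert alns_inv[0].nm == 0


def test_mapper_soundness_on_simulated_reads(small_sim):
    index = ReferenceIndex(small_sim.normal, k=21)
    sim = small_sim
    normal_idx = np.flatnonzero(~sim.truth.origin_inverted)
    alns = map_encoded_pairs(sim.reads.ids, sim.reads.r1, sim.reads.r2, index)
    n = len(sim.truth)
    ok = 0
    total = 0
    L = sim.normal.length
    for i in normal_idx.tolist():
        a1 = alns[2 * i]
        a2 = alns[2 * i + 1]
        start = int(sim.truth.start[i])
        end = (start + int(sim.truth.insert[i]) - 150) % L
        total += 2
        ok += int(a1.cigar == (("M", 150),) and a1.pos == start and a1.strand == "+")
        ok += int(a2.cigar == (("M", 150),) and a2.pos == end and a2.strand == "-")
    assert ok / total >= 0.999


def test_internal_mapper_depth_agrees_with_bwa(tmp_path, small_sim):
    """Independent cross-check: mean HR-region depth from the internal
    mapper agrees within 2% with depth from BWA-MEM alignments of the
    same simulated reads."""
    sim = small_sim
    ref_path = tmp_path / "ref.fasta"
    write_fasta([sim.normal], ref_path)
    r1, r2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
    sim.reads.write_fastq(r1, r2)
    subprocess.run(["bwa", "index", str(ref_path)], check=True, capture_output=True)
    sam_path = tmp_path / "bwa.sam"
    with open(sam_path, "w") as out:
        subprocess.run(
            ["bwa", "mem", "-M", str(ref_path), str(r1), str(r2)],
            check=True,
            stdout=out,
            stderr=subprocess.DEVNULL,
        )
    bwa_alns = list(read_sam(sam_path, expected_ref=sim.normal.id))
    internal = map_encoded_pairs(
        sim.reads.ids, sim.reads.r1, sim.reads.r2, ReferenceIndex(sim.normal, k=21)
    )
    region = sim.pair.hr_region
    d_bwa = mean_depth(bwa_alns, region, ref_length=sim.normal.length)
    d_int = mean_depth(internal, region, ref_length=sim.normal.length)
    assert d_int == pytest.approx(d_bwa, rel=0.02)


def test_pairing_handles_missing_mates():
    alns = [
        _aln(10, "+", (("M", 150),), rank=1, rid="solo"),
        _aln(10, "+", (("M", 150),), rank=1, rid="both"),
        _aln(400, "-", (("M", 150),), rank=2, rid="both"),
    ]
    pairs = pair_alignments(alns)
    assert len(pairs) == 2
    assert pairs[0].read2 is None
    assert pairs[1].both_mapped
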