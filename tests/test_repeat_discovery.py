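import numpy as np
import pytest

from plastinv.genome_core import CircularSequence, Interval, reverse_complement, rotate
from plastinv.repeat_discovery import (
    InvertedRepeatPair,
    arm_identity,
    classify_match,
    find_inverted_repeat_pairs,
    make_pair,
    predict_hairpin,
)

from conftest import random_seq


# --- brute-force oracles ---------------------------------------------------


def brute_force_inverted_pairs(
    genome: CircularSequence,
    min_arm: int,
    max_arm: int,
    min_span: int,
    max_span: int,
) -> set[tuple[int, int, int, int]]:
    """All maximal exact inverted-repeat pairs by a full anti-diagonal scan
    of the self-versus-complement match matrix (nested reports dropped),
    independent of the seeded finder."""
    g = genome.codes.astype(np.int16)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.int16)[g]
    n = g.size
    M = g[:, None] == comp[None, :]
    found: set[tuple[int, int, int, int]] = set()
    for D in range(2 * n - 1):
        x_lo, x_hi = max(0, D - n + 1), min(n - 1, D)
        xs = np.arange(x_lo, x_hi + 1)
        ok = M[xs, D - xs]
        if not ok.any():
            continue
        padded = np.concatenate([[False], ok, [False]])
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        for s, e in zip(starts, ends):
            x0, x1 = x_lo + s, x_lo + e - 1
            a = (x0, x1 + 1)
            b = (D - x1, D - x0 + 1)
            (s1, e1), (s2, e2) = sorted([a, b])
            if e1 > s2:
                continue
            if not (min_arm <= e1 - s1 <= max_arm and min_arm <= e2 - s2 <= max_arm):
                continue
            if not (min_span <= e2 - s1 <= max_span):
                continue
            found.add((s1, e1, s2, e2))
    # drop reports nested inside a larger report of the same pair
    return {
        p
        for p in found
        if not any(
            q != p
            and q[0] <= p[0]
            and p[1] <= q[1]
            and q[2] <= p[2]
            and p[3] <= q[3]
            for q in found
        )
    }


def brute_force_hairpin(seq: str, min_loop: int = 3):
    """Exhaustive enumeration of every (i, j, L) stem candidate."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    n = len(seq)
    best = None  # (-stem, loop, i)
    # positions i..i+L-1 pair with j..j+L-1 antiparallel:
    # seq[i+t] complements seq[j+L-1-t]
    for i in range(n):
        for j in range(i + 1, n):
            for L in range(1, n - j + 1):
                if j - (i + L) < min_loop:
                    break
                if all(
                    comp.get(seq[i + t]) == seq[j + L - 1 - t] for t in range(L)
                ):
                    loop = j - (i + L)
                    cand = (-L, loop, i)
                    if L >= 2 and (best is None or cand < best):
                        best = cand
    if best is None:
        return None
    return (-best[0], best[1])


# --- discovery -------------------------------------------------------------


def _plant(rng, n_pairs: int, length: int):
    seq = list(random_seq(rng, length))
    for _ in range(n_pairs):
        arm = rng.integers(18, 40)
        span = rng.integers(max(600, 2 * arm + 50), length)
        p = rng.integers(0, length - span)
        armseq = random_seq(rng, arm)
        seq[p : p + arm] = armseq
        q = p + span - arm
        seq[q : q + arm] = reverse_complement(armseq)
    return CircularSequence("t", "".join(seq))


@pytest.mark.parametrize("n_pairs", [0, 1, 2])
def test_discovery_matches_brute_force_oracle(rng, n_pairs):
    for _ in range(8):
        length = int(rng.integers(1500, 5000))
        g = _plant(rng, n_pairs, length)
        kwargs = dict(min_arm_bp=15, max_arm_bp=500, min_span_bp=500, max_span_bp=length)
        got = {
            (
                p.arm1.interval.start,
                p.arm1.interval.end,
                p.arm2.interval.start,
                p.arm2.interval.end,
            )
            for p in find_inverted_repeat_pairs(g, min_identity=1.0, **kwargs)
        }
        expect = brute_force_inverted_pairs(g, 15, 500, 500, length)
        assert got == expect


def test_no_repeat_in_random_sequence(rng):
    g = CircularSequence("r", random_seq(rng, 10_000))
    assert (
        find_inverted_repeat_pairs(
            g, min_arm_bp=30, min_span_bp=1000, max_span_bp=10_000, min_identity=1.0
        )
        == []
    )


def test_planted_pair_found_with_exact_geometry(rng):
    arm = random_seq(rng, 53)
    # 'A' guards on both sides of each arm block maximal extension beyond
    # the planted coordinates (A never complements A)
    g = CircularSequence(
        "p",
        random_seq(rng, 1999) + "A" + arm + "A" + random_seq(rng, 21892) + "A"
        + reverse_complement(arm) + "A" + random_seq(rng, 2999),
    )
    pairs = find_inverted_repeat_pairs(g)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.arm1.interval == Interval(2000, 2053)
    assert p.arm2.interval == Interval(23947, 24000)
    assert p.identity == 1.0
    assert p.match_class == "complete"
    assert p.hr_span == 22_000
    assert p.spacer_bp == 22_000 - 106


def test_strand_symmetry(rng):
    arm = random_seq(rng, 40)
    g = CircularSequence(
        "p", random_seq(rng, 1000) + arm + random_seq(rng, 6000) + reverse_complement(arm) + random_seq(rng, 900)
    )
    kwargs = dict(min_arm_bp=20, min_span_bp=1000, max_span_bp=g.length, min_identity=1.0)
    fwd = find_inverted_repeat_pairs(g, **kwargs)
    rev = find_inverted_repeat_pairs(
        CircularSequence("rc", reverse_complement(g.seq)), **kwargs
    )
    assert len(fwd) == len(rev) == 1
    L = g.length
    assert rev[0].arm1.interval == Interval(L - fwd[0].arm2.interval.end, L - fwd[0].arm2.interval.start)
    assert rev[0].arm2.interval == Interval(L - fwd[0].arm1.interval.end, L - fwd[0].arm1.interval.start)
    assert rev[0].arm1.sequence == reverse_complement(fwd[0].arm2.sequence)


def test_rotation_covariance(rng):
    arm = random_seq(rng, 40)
    g = CircularSequence(
        "p", random_seq(rng, 1000) + arm + random_seq(rng, 6000) + reverse_complement(arm) + random_seq(rng, 900)
    )
    kwargs = dict(min_arm_bp=20, min_span_bp=1000, max_span_bp=g.length, min_identity=1.0)
    base = find_inverted_repeat_pairs(g, **kwargs)[0]
    k = 500
    rot = find_inverted_repeat_pairs(rotate(g, k), **kwargs)[0]
    assert rot.arm1.interval.start == base.arm1.interval.start - k
    assert rot.arm2.interval.end == base.arm2.interval.end - k


# --- match classification --------------------------------------------------


def test_classify_match_complete_and_substitution(rng):
    arm = random_seq(rng, 53)
    g = CircularSequence(
        "p", "AC" + arm + random_seq(rng, 800) + reverse_complement(arm) + "GT"
    )
    pair = make_pair(g, Interval(2, 55), Interval(855, 908))
    assert pair.identity == 1.0
    assert classify_match(pair) == "complete"

    # one substitution in arm2
    arm2 = list(reverse_complement(arm))
    arm2[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm2[10]]
    g2 = CircularSequence("p2", "AC" + arm + random_seq(rng, 800) + "".join(arm2) + "GT")
    pair2 = make_pair(g2, Interval(2, 55), Interval(855, 908))
    assert pair2.identity == pytest.approx(52 / 53)
    assert classify_match(pair2) == "incomplete"


def test_classify_match_insertion_is_incomplete(rng):
    arm = random_seq(rng, 53)
    arm2 = reverse_complement(arm)
    arm2 = arm2[:20] + "A" + arm2[20:]  # 1 bp insertion
    g = CircularSequence("p", "AC" + arm + random_seq(rng, 800) + arm2 + "GT")
    pair = make_pair(g, Interval(2, 55), Interval(855, 909))
    assert pair.match_class == "incomplete"
    assert pair.identity < 1.0


def test_arm_identity_is_symmetric_in_alignment_sense(rng):
    a = random_seq(rng, 53)
    assert arm_identity(a, reverse_complement(a)) == 1.0


# --- hairpin ---------------------------------------------------------------


def test_hairpin_on_the_conserved_motif():
    hp = predict_hairpin("TTTGATTCCTGATTCAATCAAA")
    assert hp is not None
    assert (hp.stem_bp, hp.loop_nt) == (7, 8)
    # 1-based: stem positions 1-7 pair with 16-22
    assert (hp.stem5_interval.start, hp.stem5_interval.end) == (0, 7)
    assert (hp.stem3_interval.start, hp.stem3_interval.end) == (15, 22)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("AAAAAAAAAA", None),
        ("GCGCAAAAGCGC", (4, 4)),
    ],
)
def test_hairpin_examples(seq, expected):
    hp = predict_hairpin(seq)
    if expected is None:
        assert hp is None
    else:
        assert (hp.stem_bp, hp.loop_nt) == expected


def test_hairpin_matches_exhaustive_enumeration(rng):
    for _ in range(60):
        n = int(rng.integers(6, 30))
        seq = random_seq(rng, n)
        hp = predict_hairpin(seq)
        expect = brute_force_hairpin(seq)
        if expect is None:
            assert hp is None
        else:
            assert hp is not None
            assert (hp.stem_bp, hp.loop_nt) == expect


def test_hairpin_invariants_on_random_sequences(rng):
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for _ in range(40):
        seq = random_seq(rng, int(rng.integers(10, 60)))
        hp = predict_hairpin(seq)
        if hp is None:
            continue
        assert hp.loop_nt >= 3 and hp.stem_bp >= 1
        assert 2 * hp.stem_bp + hp.loop_nt <= len(seq)
        i, L = hp.stem5_interval.start, hp.stem_bp
        j = hp.stem3_interval.start
        for t in range(L):
            assert comp[seq[i + t]] == seq[j + L - 1 - t]
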