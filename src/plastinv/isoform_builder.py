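"""Construction of the inverted-type reference from the normal-type genome.

Recombination between the two arms of an sIR pair inverts the enclosed
segment.  The builder replaces the spanned region — inclusive of both arms —
with its reverse complement.  For a complete-match pair this leaves the arm
sequences at the boundaries unchanged (the arms are each other's reverse
complement), so applying the builder twice restores the original genome
exactly.  For an incomplete pair the convention exchanges the arm variants
between the two ends, mimicking a crossover at the arm midpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .genome_core import CircularSequence, InputError, Interval, reverse_complement
from .repeat_discovery import InvertedRepeatPair

__all__ = ["IsoformPair", "build_inverted_isoform", "map_position", "write_isoform_sidecar", "read_isoform_sidecar"]


@dataclass
class IsoformPair:
    """Normal and inverted references plus the coordinate map between them.

    The map is the identity outside the spanned (HR) region and reverses
    order inside it: normal position ``p`` in ``[hr_start, hr_end)`` maps to
    ``hr_start + (hr_end - 1 - p)`` on the inverted reference, and the map is
    its own inverse.
    """

    normal: CircularSequence
    inverted: CircularSequence
    pair: InvertedRepeatPair

    @property
    def hr_start(self) -> int:
        return self.pair.hr_region.start

    @property
    def hr_end(self) -> int:
        return self.pair.hr_region.end


def build_inverted_isoform(genome: CircularSequence, pair: InvertedRepeatPair) -> IsoformPair:
    """Build the inverted-type genome by reverse-complementing the HR region.

    The HR region (``pair.hr_region``) must not wrap the origin; rotate the
    genome first if it does.
    """
    hr = pair.hr_region
    if hr.wraps:
        raise InputError(
            "HR region wraps the origin; rotate the genome so the region is contiguous"
        )
    if hr.end > genome.length:
        raise InputError("sIR pair coordinates fall outside the genome")
    seq = genome.seq
    inv_seq = seq[: hr.start] + reverse_complement(seq[hr.start : hr.end]) + seq[hr.end :]
    inverted = CircularSequence(genome.id + "_inverted", inv_seq, circular=genome.circular)
    return IsoformPair(normal=genome, inverted=inverted, pair=pair)


def map_position(iso: IsoformPair, pos: int) -> int:
    """Map a 0-based normal-reference position to the inverted reference."""
    if not 0 <= pos < iso.normal.length:
        raise InputError(f"position {pos} outside [0, {iso.normal.length})")
    if iso.hr_start <= pos < iso.hr_end:
        return iso.hr_start + (iso.hr_end - 1 - pos)
    return pos


def map_positions(iso: IsoformPair, pos: np.ndarray) -> np.ndarray:
    """Vectorized :func:`map_position`."""
    pos = np.asarray(pos)
    inside = (pos >= iso.hr_start) & (pos < iso.hr_end)
    return np.where(inside, iso.hr_start + (iso.hr_end - 1 - pos), pos)


def write_isoform_sidecar(iso: IsoformPair, path: str) -> None:
    """JSON sidecar recording arm coordinates on both references (1-based)."""
    p = iso.pair
    arm1, arm2 = p.arm1.interval, p.arm2.interval
    payload = {
        "normal_id": iso.normal.id,
        "inverted_id": iso.inverted.id,
        "genome_length": iso.normal.length,
        "identity": p.identity,
        "match_class": p.match_class,
        "hr_region": {"start": iso.hr_start + 1, "end": iso.hr_end},
        "normal": {
            "arm1": {"start": arm1.start + 1, "end": arm1.end},
            "arm2": {"start": arm2.start + 1, "end": arm2.end},
        },
        # The inversion maps each arm interval onto the opposite one.
        "inverted": {
            "arm1": {"start": arm1.start + 1, "end": arm1.end},
            "arm2": {"start": arm2.start + 1, "end": arm2.end},
        },
        "arm1_seq": p.arm1.sequence,
        "arm2_seq": p.arm2.sequence,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_isoform_sidecar(path: str, normal: CircularSequence, inverted: CircularSequence) -> IsoformPair:
    from .repeat_discovery import make_pair

    with open(path) as fh:
        d = json.load(fh)
    a1 = Interval(d["normal"]["arm1"]["start"] - 1, d["normal"]["arm1"]["end"])
    a2 = Interval(d["normal"]["arm2"]["start"] - 1, d["normal"]["arm2"]["end"])
    pair = make_pair(normal, a1, a2)
    return IsoformPair(normal=normal, inverted=inverted, pair=pair)
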