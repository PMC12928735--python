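import numpy as np
import pytest

from plastinv import (
    DetectionParams,
    SimConfig,
    detect_pairs,
    estimate_frequency,
    mean_depth,
    pair_alignments,
    simulate_dataset,
)
from plastinv.alignment_layer import ReferenceIndex, map_encoded_pairs


def run_pipeline(cfg: SimConfig, params: DetectionParams | None = None):
    """Simulate, map with the internal mapper, and detect; returns
    (sim, evidence, excluded, mean HR depth)."""
    sim = simulate_dataset(cfg)
    index = ReferenceIndex(sim.normal, k=21)
    alns = map_encoded_pairs(sim.reads.ids, sim.reads.r1, sim.reads.r2, index)
    pairs = pair_alignments(alns)
    depth = mean_depth(alns, sim.pair.hr_region, ref_length=sim.normal.length)
    evidence, excluded = detect_pairs(pairs, sim.iso, params)
    return sim, evidence, excluded, depth


@pytest.fixture(scope="session")
def small_cfg():
    """Desk-scale study conditions: smaller genome, same arm/read geometry."""
    return SimConfig(
        genome_bp=40_000,
        hr_span_bp=8_000,
        depth_x=60,
        isoform_fraction=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_seq(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
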