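"""Shared fixtures: seeded random genomes and simulated scenarios.

The heavyweight fixture (``default_scenario``) runs the simulator at its
default scale once per session and feeds the parameter-recovery and
unstranded-degradation suites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from l1locus import pipeline
from l1locus.simulate import (
    SimConfig,
    simulate_alignments,
    simulate_genome,
    simulate_transcripts,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_genome(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced scenario with one locus of every class; runs in seconds."""
    return SimConfig(
        genome_length=400_000, copies_per_subfamily=2, n_truncated=2,
        n_genes=10, n_promoter_driven=3, n_asp_coupled=1,
        n_unmappable_upstream=1, n_asp_only=1, n_co_transcribed=2,
        n_intronic_opposite=1, n_readthrough=1, n_unannotated_upstream=1,
        fragments_per_sample=5000, seed=7,
    )


@dataclass
class Scenario:
    config: SimConfig
    sim: object
    transcripts: list
    samples: list
    result: pipeline.PipelineResult


def _build_scenario(config: SimConfig, out_dir, samples=None) -> Scenario:
    sim = simulate_genome(config)
    transcripts = simulate_transcripts(sim)
    kwargs = {"samples": samples} if samples else {}
    sams = simulate_alignments(sim, transcripts, out_dir, **kwargs)
    result = pipeline.run_pipeline(
        sim.genome, sim.repeats, sim.promoter_query, sim.genes,
        {s.sample_id: s.path for s in sams},
    )
    return Scenario(config, sim, transcripts, sams, result)


@pytest.fixture(scope="session")
def small_scenario(small_config, tmp_path_factory) -> Scenario:
    return _build_scenario(
        small_config, tmp_path_factory.mktemp("small_sim"),
        samples=(("cytoplasmic_1", "cytoplasmic"),),
    )


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory) -> Scenario:
    """The default study conditions at a fixed seed, fully analysed."""
    return _build_scenario(SimConfig(seed=1), tmp_path_factory.mktemp("default_sim"))
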