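"""Shared fixtures: one small simulated scenario reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import ventmge as v


@pytest.fixture(scope="session")
def small_params() -> v.SimParams:
    """A reduced scenario: 3 families x 3 members, 2 hosts, 30 decoys."""
    return v.SimParams(
        seed=3,
        n_hosts=2,
        n_mge_families=3,
        mges_per_family=3,
        host_genome_length=20_000,
        n_decoys=30,
    )


@pytest.fixture(scope="session")
def small_sim(small_params) -> v.SimResult:
    return v.simulate(small_params)


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """Full pipeline result on the small scenario."""
    tmp = tmp_path_factory.mktemp("smallrun")
    sim_dir = tmp / "sim"
    small_sim.write(sim_dir)
    cfg = v.RunConfig(
        contigs=str(sim_dir / "contigs.fasta"),
        reference_repeats=str(sim_dir / "reference_repeats.fasta"),
        host_genomes=str(sim_dir / "hosts.fasta"),
        seed=small_sim.params.seed,
    )
    return v.run_pipeline(cfg, tmp / "out"), tmp / "out"


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
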