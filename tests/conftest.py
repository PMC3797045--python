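"""Shared fixtures: synthetic genomes and simulated read samples.

The expensive simulations are session-scoped and reused across test modules;
every fixture is fully seeded so the suite is deterministic.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from mitomap.genome import GenomeSequence
from mitomap.simulate import (SimConfig, build_genome, transcribe_and_process,
                              simulate_reads)
from mitomap.reads import load_alignments


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def sim_truth(sim_config):
    return build_genome(sim_config)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("sim")


def _sample(truth, condition, outdir, name, seed, noise=None):
    cfg = truth.config if noise is None else replace(truth.config, noise=noise)
    mols = transcribe_and_process(truth, condition)
    rng = np.random.default_rng(seed)
    return simulate_reads(mols, truth.genome, cfg, outdir, sample_name=name, rng=rng)


@pytest.fixture(scope="session")
def samples_a(sim_truth, sim_dir):
    """Four condition-a replicates at default noise (also the null set)."""
    return [_sample(sim_truth, "a", sim_dir, f"a{i}", seed=100 + i)
            for i in range(4)]


@pytest.fixture(scope="session")
def samples_b(sim_truth, sim_dir):
    return [_sample(sim_truth, "b", sim_dir, f"b{i}", seed=200 + i)
            for i in range(2)]


@pytest.fixture(scope="session")
def sample_clean(sim_truth, sim_dir):
    """One condition-a sample at zero read noise (closure testing)."""
    return _sample(sim_truth, "a", sim_dir, "clean", seed=300, noise=0.0)


@pytest.fixture(scope="session")
def views_clean(sample_clean):
    return load_alignments(sample_clean["sam"])


@pytest.fixture(scope="session")
def views_a(samples_a):
    return [load_alignments(s["sam"]) for s in samples_a]


@pytest.fixture
def toy_genome():
    return GenomeSequence("toy", "ATCG", circular=False)


def random_genome(rng, n, circular=True, at=0.7):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    seq = "".join(rng.choice(list("ACGT"), size=n, p=p))
    return GenomeSequence("rand", seq, circular=circular)
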