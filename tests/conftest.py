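"""Shared fixtures: one small simulated study reused across test modules.

The small simulation (12 planted SVs, two 2-offspring families, 30×
reads for two samples) is expensive enough that it is built once per
session; tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from graphsv.simulate import SimConfig, simulate_all


SMALL_CONFIG = SimConfig(
    seed=7,
    contig_length=120_000,
    n_sv_per_type={"DEL": 3, "INS": 3, "DUP": 3, "INV": 3},
    families=(2, 2),
)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """Small simulated study: truth + reads for two samples."""
    out = tmp_path_factory.mktemp("small_sim")
    run = simulate_all(SMALL_CONFIG, str(out),
                       read_samples=["fam1_father", "fam1_mother"])
    return run


@pytest.fixture(scope="session")
def small_truth(small_sim):
    return small_sim["truth"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def pedigree_truth():
    """Full-scale pedigree truth (80 SVs, 4 families / 48 trios), no reads."""
    from graphsv.simulate import plant_svs, simulate_reference
    cfg = SimConfig(seed=1)
    ref = simulate_reference(cfg.contig_length, cfg.rng(1))
    return plant_svs(ref, cfg)


@pytest.fixture(scope="session")
def pedigree_vcf(pedigree_truth, tmp_path_factory):
    from graphsv.simulate import write_truth_vcf
    out = tmp_path_factory.mktemp("pedigree") / "truth.vcf"
    write_truth_vcf(pedigree_truth, str(out))
    return str(out)
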