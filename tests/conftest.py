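"""Shared fixtures: small deterministic simulations reused across tests."""

from __future__ import annotations

import pytest
from hypothesis import settings

import radmut as rm

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def tiny_lines(n_lines: int = 3, snv: int = 6, indel: int = 3, sv: int = 2):
    """A small mutant population plus two controls."""
    specs = [
        rm.LineSpec(
            line_id=f"L{i + 1}",
            treatment="gamma" if i % 2 == 0 else "xray",
            dose_gy=150 if i % 2 == 0 else 75,
            induced_snv_count=snv,
            induced_indel_count=indel,
            induced_sv_count=sv,
            replicate_ids=(f"L{i + 1}_r1", f"L{i + 1}_r2"),
        )
        for i in range(n_lines)
    ]
    specs.append(rm.LineSpec("ctrl_a", "none", 0, replicate_ids=("CA",)))
    specs.append(rm.LineSpec("ctrl_b", "none", 0, replicate_ids=("CB",)))
    return tuple(specs)


@pytest.fixture(scope="session")
def tiny_config():
    return rm.SimulationConfig(
        seed=101,
        n_chroms=2,
        chrom_length=60_000,
        n_genes=8,
        natural_variant_density=5e-4,
        lines=tiny_lines(),
        noiseless=True,
    )


@pytest.fixture(scope="session")
def tiny_result(tiny_config):
    return rm.simulate_all(tiny_config)


@pytest.fixture(scope="session")
def noiseless_pipeline():
    """Full default population, noiseless: the exact-recovery regime."""
    cfg = rm.SimulationConfig(seed=1, noiseless=True)
    return rm.run_pipeline(cfg)


@pytest.fixture(scope="session")
def reference_300k():
    """A gene-dense reference for effect-annotation tests."""
    cfg = rm.SimulationConfig(seed=77, n_chroms=2, chrom_length=300_000, n_genes=40)
    return rm.generate_reference(cfg)
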