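import numpy as np
import pytest

from ampdel.reference import AmpliconReference
from ampdel.simdata import (
    DEFAULT_PRIMER3,
    DEFAULT_PRIMER5,
    SimConfig,
    StandardDesign,
    build_standard,
    random_sequence,
    simulate_umi_library,
)
from ampdel.umi import UmiSpec, extract_umi_pair


@pytest.fixture(scope="session")
def umi_spec():
    return UmiSpec(DEFAULT_PRIMER5, DEFAULT_PRIMER3)


@pytest.fixture(scope="session")
def small_ref():
    rng = np.random.default_rng(11)
    return AmpliconReference("amp", random_sequence(3000, rng), cut_site=1500)


@pytest.fixture(scope="session")
def standard():
    design = StandardDesign()
    templates, ref, truth = build_standard(design, seed=0)
    return design, templates, ref, truth


@pytest.fixture(scope="session")
def small_library(standard):
    """A modest noisy library off the 9-template standard (shared; read-only)."""
    design, templates, ref, _ = standard
    cfg = SimConfig(seed=3, n_molecules=200, chimera_rate=0.02, error_rate=0.002)
    records, truth = simulate_umi_library(templates, design.fractions, cfg)
    return cfg, records, truth


def tag_records(records, spec):
    tagged, invalid = [], []
    for rec in records:
        t = extract_umi_pair(rec.sequence, spec, rec.read_id)
        (tagged if hasattr(t, "insert") else invalid).append(t)
    return tagged, invalid
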