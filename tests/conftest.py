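import logging

import pytest

from hbstrand.dna_model import detect_base_pairs
from hbstrand.synthetic_data import (
    FixtureSpec,
    ProbeSpec,
    build_fixture,
    build_helix,
    build_sheet,
    fixture_unit,
    generate_bdna,
)

logging.getLogger("hbstrand").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def gaattc_duplex():
    s1, s2 = generate_bdna("GAATTC")
    return detect_base_pairs(s1, s2)


@pytest.fixture(scope="session")
def simple_fixture():
    """3 bond probes on strand 1, 2 on strand 2, incl. one fully engaged
    pair (step 0: G1(B).C6(C)); plus one near-miss."""
    spec = FixtureSpec(
        dna_sequence="GAATTC",
        probes=[
            ProbeSpec(strand=1, base_index=0, groove="major"),  # G O6
            ProbeSpec(strand=2, base_index=5, groove="major"),  # paired C N4
            ProbeSpec(strand=1, base_index=2, groove="major"),  # A N6 donor
            ProbeSpec(strand=1, base_index=4, groove="minor"),  # T O2
            ProbeSpec(strand=2, base_index=1, groove="major"),  # T? depends
            ProbeSpec(strand=2, base_index=3, groove="minor", outcome="near_miss_distance"),
        ],
        seed=42,
    )
    structure, gt = build_fixture(spec)
    return spec, structure, gt, fixture_unit(structure)


@pytest.fixture(scope="session")
def helix_chain():
    return build_helix(12)


@pytest.fixture(scope="session")
def sheet_chain():
    return build_sheet(6)
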