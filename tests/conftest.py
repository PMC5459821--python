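from __future__ import annotations

import pytest

from fl16s.io import PrimerScheme
from fl16s.synthetic import CommunitySpec, generate_reference_set, simulate_reads


@pytest.fixture(scope="session")
def scheme() -> PrimerScheme:
    return PrimerScheme()


@pytest.fixture(scope="session")
def small_refs():
    """8 species, one V3V4-confusable pair (Species_001/002)."""
    return generate_reference_set(8, n_confusable_pairs=1, region_for_confusion="V3V4", seed=11)


@pytest.fixture(scope="session")
def clean_community(small_refs):
    """Two samples, zero noise, no chimeras; returns (spec, reads, truth)."""
    names = small_refs.species_names
    spec = CommunitySpec(
        samples=[("S1", "MN", "gulf"), ("S2", "MT", "andaman")],
        composition={
            "S1": {names[0]: 0.4, names[1]: 0.3, names[2]: 0.3},
            "S2": {names[3]: 0.5, names[4]: 0.5},
        },
        n_reads=60,
        error_rate=0.0,
        chimera_rate=0.0,
        seed=7,
    )
    reads, truth = simulate_reads(small_refs, spec)
    return spec, reads, truth
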