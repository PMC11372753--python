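import numpy as np
import pytest

from monomix.protonation import MixtureComposition, default_species


@pytest.fixture(scope="session")
def species():
    return default_species()


@pytest.fixture(scope="session")
def pure_la(species):
    return MixtureComposition.from_pairs([(species["LA"], 1.0)])


@pytest.fixture(scope="session")
def binary_la_pa(species):
    return MixtureComposition.from_pairs([(species["LA"], 1.0), (species["PA"], 1.0)])


@pytest.fixture(scope="session")
def proxy_mix(species):
    return MixtureComposition.from_pairs(
        [(species["LA"], 1.0), (species["MA"], 2.0), (species["PA"], 4.0), (species["SA"], 3.0)]
    )


@pytest.fixture(scope="session")
def control_mix(species):
    return MixtureComposition.from_pairs(
        [(species["MA"], 2.0), (species["PA"], 4.0), (species["SA"], 3.0)]
    )


def brute_force_pairs(frame, species_name, cutoff):
    """O(n²) minimum-image oracle for same-type neighbor pairs (test reference)."""
    idx = np.flatnonzero(frame.select(species=species_name))
    pairs = set()
    L = frame.box[:2]
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            d = frame.positions[idx[a], :2] - frame.positions[idx[b], :2]
            d -= L * np.round(d / L)
            if np.hypot(d[0], d[1]) <= cutoff:
                pairs.add((int(frame.ids[idx[a]]), int(frame.ids[idx[b]])))
    return pairs
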