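import numpy as np
import pytest

from grappi.fixtures import FixtureSpec, make_decoys, make_reference_complex
from grappi.graph import GraphBuildConfig, build_graph
from grappi.features import featurize


@pytest.fixture(scope="session")
def ref_complex():
    """Deterministic synthetic two-chain reference complex."""
    return make_reference_complex(FixtureSpec(seed=11), structure_id="ref11")


@pytest.fixture(scope="session")
def ref_graph(ref_complex):
    g = build_graph(ref_complex)
    featurize(g, ref_complex)
    return g


@pytest.fixture(scope="session")
def decoy_set(ref_complex):
    return make_decoys(ref_complex, FixtureSpec(seed=11, decoys_per_level=6))


def random_rigid_transform(rng: np.random.Generator):
    """A uniformly random proper rotation and a bounded translation."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    trans = rng.uniform(-30, 30, size=3)
    return rot, trans


def brute_force_contacts(structure, cutoff):
    """O(n^2) oracle: all cross-chain residue-key pairs within cutoff."""
    cid_a, cid_b = structure.chain_ids
    pairs = set()
    for ra in structure.chains[cid_a]:
        for rb in structure.chains[cid_b]:
            d = np.linalg.norm(ra.coords()[:, None] - rb.coords()[None], axis=-1).min()
            if d <= cutoff:
                pairs.add((ra.key, rb.key))
    return pairs
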