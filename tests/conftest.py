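import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from loopscape import AtomRecord, RegionSpec, Residue, Structure, SyntheticSpec

settings.register_profile(
    "loopscape",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("loopscape")

# a small fast spec reused across module tests
SMALL_LOOPS = (
    RegionSpec("L1", 10, 17),
    RegionSpec("L2", 22, 27),
    RegionSpec("L3", 32, 44),
    RegionSpec("L4", 50, 58),
)


@pytest.fixture
def small_spec():
    return SyntheticSpec(n_residues=70, loop_spans=SMALL_LOOPS,
                         flexible_loop="L3", seed=11)


def make_ca_residue(chain_id: str, seq_num: int, res_name: str,
                    xyz, b: float = 20.0) -> Residue:
    r = Residue(chain_id, seq_num, "", res_name)
    r.atoms.append(AtomRecord("CA", "C", np.asarray(xyz, float), b_factor=b))
    return r


def make_ca_chain(start: int, end: int, chain_id: str = "A",
                  res_name: str = "ALA", b: float = 20.0,
                  rng: np.random.Generator | None = None) -> Structure:
    """A chain of consecutive residues with one Cα each.

    Coordinates are random (non-collinear) unless no rng is given, in
    which case they sit on a gentle arc.
    """
    s = Structure(id="toy")
    residues = []
    for i, num in enumerate(range(start, end + 1)):
        if rng is not None:
            xyz = rng.normal(0, 10, 3)
        else:
            t = 0.2 * i
            xyz = [10 * np.cos(t), 10 * np.sin(t), 1.5 * i]
        residues.append(make_ca_residue(chain_id, num, res_name, xyz, b))
    s.chains[chain_id] = residues
    return s


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=rng).as_matrix()
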