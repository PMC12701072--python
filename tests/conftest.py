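import numpy as np
import pytest

from wrapkit.builder import DuplexSpec, build_bdna
from wrapkit.structio import Structure
from wrapkit.synthetic import ToySpec, gen_toy_complex


@pytest.fixture(scope="session")
def wrap_toy():
    """Wrapping-mode toy ensemble: all four sites engaged."""
    return gen_toy_complex(ToySpec(n_frames=40, jitter=0.3, seed=11))


@pytest.fixture(scope="session")
def bridge_toy():
    """Bridging-mode toy ensemble: only the B-sites engaged."""
    return gen_toy_complex(ToySpec.bridging(n_frames=40, jitter=0.3, seed=11))


@pytest.fixture(scope="session")
def duplex20():
    """A 20-bp straight fibre-B duplex."""
    return build_bdna(DuplexSpec("ATGCATGCATGCATGCATGC"))


def make_structure(records, **kw):
    """Build a Structure from (chain, resnum, resname, atom, element, xyz)."""
    chain, resnum, resname, name, element, xyz = zip(*records)
    return Structure(list(chain), list(resnum), list(resname), list(name),
                     list(element), np.array(xyz, dtype=float), **kw)


def ideal_helix(axis, n=18, offset=(0.0, 0.0, 0.0), rise=1.5, radius=2.3,
                omega_deg=100.0):
    """Cα trace of an ideal helix along ``axis``; n·ω a whole number of turns
    makes the principal-component axis exact."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    tmp = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else np.array([0, 1.0, 0])
    e1 = np.cross(axis, tmp)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    t = np.arange(n)
    ang = np.radians(omega_deg) * t
    pts = (t[:, None] * rise * axis + radius * np.cos(ang)[:, None] * e1 +
           radius * np.sin(ang)[:, None] * e2)
    return pts + np.asarray(offset, dtype=float)


def random_rotation(rng):
    """Uniform random proper rotation matrix."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
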