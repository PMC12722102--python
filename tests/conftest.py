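import math

import numpy as np
import pytest

import riemls as R


@pytest.fixture
def sphere():
    return R.Sphere(1.0)


@pytest.fixture
def poincare():
    return R.PoincareHalfPlane()


@pytest.fixture
def torus():
    return R.Torus(1.0, 0.3)


@pytest.fixture
def plane():
    return R.Plane()


def sphere_clairaut(space, path):
    """r·sinβ along a path on a surface of revolution."""
    vals = []
    for u, v in zip(path.u, path.v):
        uw = space.wrap(u)
        r = space.revolution_radius(uw)
        V = space.pushforward(uw, v)
        _, sq = space.partials(uw)
        e_phi = sq / np.linalg.norm(sq)
        vals.append(r * float(V @ e_phi) / np.linalg.norm(V))
    return np.array(vals)


def uv_from_xyz(v):
    """Unit-sphere chart coordinates of a unit 3-vector."""
    return np.array(
        [math.acos(np.clip(v[2], -1, 1)), math.atan2(v[1], v[0]) % (2 * math.pi)]
    )


class EuclideanTurtle:
    """Independent flat-space reference turtle (complex arithmetic)."""

    def __init__(self, pos=0j, heading=1 + 0j):
        self.pos = pos
        self.heading = heading
        self.stack = []
        #: (start, end) complex pairs, one per drawn segment
        self.segments = []

    def execute(self, modules):
        """modules: iterable of (name, params) pairs."""
        for name, params in modules:
            if name == "F":
                l = params[0] if params else 1.0
                new = self.pos + l * self.heading
                self.segments.append((self.pos, new))
                self.pos = new
            elif name == "f":
                l = params[0] if params else 1.0
                self.pos = self.pos + l * self.heading
            elif name == "+":
                a = math.radians(params[0] if params else 90.0)
                self.heading *= complex(math.cos(a), math.sin(a))
            elif name == "-":
                a = math.radians(params[0] if params else 90.0)
                self.heading *= complex(math.cos(a), -math.sin(a))
            elif name == "[":
                self.stack.append((self.pos, self.heading))
            elif name == "]":
                self.pos, self.heading = self.stack.pop()
        return self


@pytest.fixture
def euclid_turtle_cls():
    return EuclideanTurtle
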