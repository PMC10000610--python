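import numpy as np
import pytest

from powdercone import make_perfect_cone
from powdercone.slicing import ContourSlice

R0, H = 50.0, 100.0


@pytest.fixture(scope="session")
def perfect_cone():
    return make_perfect_cone(R0, H)


@pytest.fixture(scope="session")
def unit_cube_mesh():
    """Closed axis-aligned unit cube, 12 triangles."""
    from powdercone import TriangleMesh

    v = np.array(
        [[x, y, z] for z in (0.0, 1.0) for y in (0.0, 1.0) for x in (0.0, 1.0)]
    )
    # index layout: bit0=x, bit1=y, bit2=z
    quads = [
        (0, 1, 3, 2),  # bottom z=0
        (4, 6, 7, 5),  # top z=1
        (0, 4, 5, 1),  # y=0
        (2, 3, 7, 6),  # y=1
        (0, 2, 6, 4),  # x=0
        (1, 5, 7, 3),  # x=1
    ]
    faces = []
    for a, b, c, d in quads:
        faces.append((a, b, c))
        faces.append((a, c, d))
    return TriangleMesh(v, np.array(faces)).validate()


def cosine_contour(R=10.0, amp=0.5, harmonic=4, n=720):
    """Analytic contour r(theta) = R + amp*cos(harmonic*theta)."""
    theta = 2.0 * np.pi * np.arange(n) / n
    r = R + amp * np.cos(harmonic * theta)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return ContourSlice(layer_index=0, z=1.0, points=pts)
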