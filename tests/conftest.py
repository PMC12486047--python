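import numpy as np
import pytest

from vascbci import synth
from vascbci.types import Hemisphere, SurfaceModel


def bare_hemisphere(pial, white=None, labels=None, tag="R"):
    """Minimal hemisphere for geometric unit tests (no triangles needed by
    the vertex-based operators)."""
    pial = np.asarray(pial, dtype=float)
    if white is None:
        white = pial.copy()
    if labels is None:
        labels = np.full(len(pial), "OTHER")
    return Hemisphere(
        pial=pial,
        white=white,
        triangles=np.empty((0, 3), dtype=np.int64),
        labels=np.asarray(labels),
        tag=tag,
    )


def sheet(x, stations, z=0.0):
    """Vertices of a parasagittal sheet at fixed lateral offset ``x``."""
    stations = np.asarray(stations, dtype=float)
    return np.stack(
        [np.full_like(stations, x), stations, np.full_like(stations, z)], axis=1
    )


@pytest.fixture(scope="session")
def small_surface():
    """A coarse folded surface reused by read-only geometry tests."""
    return synth.generate_surface(spacing=2.0, seed=42)


@pytest.fixture(scope="session")
def flat_surface():
    return synth.generate_flat_surface(thickness=2.5, spacing=2.0, seed=7)
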