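import numpy as np
import pytest

from basinselect import DEFAULT_SCHEMA, Ensemble


def make_ensemble(points, energies, target_id="toy", rng=None,
                  rmsd_native=None, features=None):
    """Ensemble from low-dimensional points (interpreted as one pseudo-atom
    each); features are filled with arbitrary values unless given."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n, d = points.shape
    coords = np.zeros((n, 1, 3))
    coords[:, 0, :d] = points
    if features is None:
        if rng is None:
            rng = np.random.default_rng(0)
        features = rng.normal(size=(n, DEFAULT_SCHEMA.total))
    return Ensemble(
        target_id=target_id,
        decoy_ids=[f"d{i}" for i in range(n)],
        energies=np.asarray(energies, dtype=float),
        features=np.asarray(features, dtype=float),
        rmsd_native=None if rmsd_native is None else np.asarray(rmsd_native, float),
        coords=coords,
        distance_spec="euclidean",
    )


def random_ensemble(rng, n=None, rmsd=False):
    n = n or int(rng.integers(5, 40))
    pts = rng.normal(scale=3.0, size=(n, 3))
    energies = rng.normal(size=n)
    rmsd_native = np.linalg.norm(pts, axis=1) if rmsd else None
    return make_ensemble(pts, energies, rng=rng, rmsd_native=rmsd_native)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
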