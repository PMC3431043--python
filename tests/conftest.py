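"""Shared fixtures: small synthetic morphologies, stacks and the seeded
phantom benchmark (session-scoped — it backs several slow tests)."""

import warnings

import numpy as np
import pytest

import mothatlas as ma

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def benchmark_results():
    """Auto + semiauto traces and scores for the 12-phantom suite."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ma.run_benchmark(n_per_condition=3, base_seed=BENCHMARK_SEED)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def straight_morphology(length=50.0, radius=2.0, center=(32.0, 32.0, 16.0),
                        axis=(1.0, 0.0, 0.0), n_nodes=2):
    """A straight cable of given length/radius centred in a phantom volume."""
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    center = np.asarray(center, dtype=float)
    t = np.linspace(-0.5, 0.5, n_nodes)
    pts = center + np.outer(t * length, axis)
    return ma.Morphology.from_arrays(
        ids=range(1, n_nodes + 1),
        type_codes=[1] + [3] * (n_nodes - 1),
        xyz=pts,
        radii=[radius] * n_nodes,
        parent_ids=[-1] + list(range(1, n_nodes)),
    )


def y_morphology(trunk=20.0, arm=18.0, radius=2.0, base=(32.0, 16.0, 16.0)):
    """Trunk splitting into two arms (one bifurcation, two tips)."""
    base = np.asarray(base, dtype=float)
    split = base + (0.0, trunk, 0.0)
    c = arm / np.sqrt(2.0)
    tip1 = split + (-c, c, 0.0)
    tip2 = split + (c, c, 0.0)
    return ma.Morphology.from_arrays(
        ids=[1, 2, 3, 4],
        type_codes=[1, 3, 3, 3],
        xyz=[base, split, tip1, tip2],
        radii=[radius, radius, radius * 0.8, radius * 0.8],
        parent_ids=[-1, 1, 2, 2],
    )


def random_tree(seed, n_nodes=40, box=200.0):
    """A random valid morphology (not rendered; for format/metric tests)."""
    r = np.random.default_rng(seed)
    ids = np.arange(1, n_nodes + 1)
    parents = np.full(n_nodes, -1, dtype=int)
    for k in range(1, n_nodes):
        parents[k] = ids[r.integers(0, k)]
    xyz = r.uniform(0, box, size=(n_nodes, 3))
    radii = r.uniform(0.3, 4.0, size=n_nodes)
    return ma.Morphology.from_arrays(ids, np.zeros(n_nodes, dtype=int),
                                     xyz, radii, parents)


def ball_stack(shape=(32, 48, 48), spacing=(1.0, 1.0, 1.0), center=None,
               r=10.0, fg=200, bg=10):
    """A bright ball on dark background (simple binarization target)."""
    if center is None:
        center = tuple(s * sp / 2 for s, sp in zip(shape, spacing))
    grids = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                        indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    vol = np.where(d2 <= r * r, fg, bg).astype(np.uint8)
    return ma.ImageStack(vol, spacing)
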