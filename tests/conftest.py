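import numpy as np
import pytest

from absasfit.structures import AtomisticModel, RegionScheme


def point_model(coords, elements=None, chains=None, resnums=None,
                resnames=None, atom_names=None, model_id="test") -> AtomisticModel:
    """Minimal model factory for geometric tests."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = np.asarray(elements if elements is not None else ["C"] * n,
                          dtype=object)
    return AtomisticModel(
        coords=coords,
        element=elements,
        is_heavy=np.array([e.upper() not in ("H", "D") for e in elements]),
        chain=np.asarray(chains if chains is not None else ["A"] * n,
                         dtype=object),
        resnum=np.asarray(resnums if resnums is not None
                          else np.arange(1, n + 1), dtype=int),
        icode=np.full(n, "", dtype=object),
        resname=np.asarray(resnames if resnames is not None else ["ALA"] * n,
                           dtype=object),
        atom_name=np.asarray(atom_names if atom_names is not None
                             else ["CA"] * n, dtype=object),
        model_id=model_id,
    )


@pytest.fixture
def make_model():
    return point_model


@pytest.fixture
def triangle_345():
    """Three one-atom lobes at the vertices of a 3-4-5 triangle (nm)."""
    # Fab1 at origin, Fab2 3 nm away, Fc placed for d2=4, d3=5
    x = (3.0 ** 2 + 4.0 ** 2 - 5.0 ** 2) / (2 * 3.0)
    y = np.sqrt(4.0 ** 2 - x ** 2)
    model = point_model(
        [[0, 0, 0], [3, 0, 0], [x, y, 0]],
        chains=["A", "B", "C"], resnums=[1, 1, 1])
    scheme = RegionScheme(intervals=[("A", 1, 1, "Fab1"), ("B", 1, 1, "Fab2"),
                                     ("C", 1, 1, "Fc")])
    return model, scheme


@pytest.fixture
def mini_antibody():
    from absasfit.synthetic import make_mini_antibody
    return make_mini_antibody(8, seed=0)
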