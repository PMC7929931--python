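import numpy as np
import pytest

from rootdome.outline_geometry import RawOutline, unify_coordinates
from rootdome.synthetic_data import OutlineGeneratorSpec, generate_outline


@pytest.fixture
def v_outline() -> RawOutline:
    """Symmetric 5-point V already in the unified frame."""
    return RawOutline("v", np.array(
        [[-2.0, 4.0], [-1.0, 1.0], [0.0, 0.0], [1.0, 1.0], [2.0, 4.0]]))


@pytest.fixture
def catenary_std():
    """Noiseless catenary (a = 30 µm, height 50 µm) in the unified frame."""
    spec = OutlineGeneratorSpec(family="catenary", params=(30.0,),
                                height=50.0, noise_sd=0.0, seed=11)
    return unify_coordinates(generate_outline(spec))


def exact_outline(family: str, params: tuple, height: float = 40.0,
                  spacing: float = 10.0, seed: int = 5):
    spec = OutlineGeneratorSpec(family=family, params=params, height=height,
                                spacing=spacing, noise_sd=0.0, seed=seed)
    return unify_coordinates(generate_outline(spec))


def mirror_mismatch(verts: np.ndarray) -> float:
    """Worst-case distance from each vertex to its nearest mirror image."""
    flip = verts * np.array([-1.0, 1.0])
    return max(float(np.abs(verts - flip[None, i]).sum(axis=1).min())
               for i in range(len(verts)))
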