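import numpy as np
import pytest

from hybridir import (
    BinaryMask,
    DeformationSpec,
    DegradationSpec,
    ContourNoiseSpec,
    Grid,
    PhantomSpec,
    make_case,
)


def sphere_mask(n: int, spacing: float, center, radius: float) -> BinaryMask:
    """Analytic sphere mask on a centered n^3 grid (shared test helper)."""
    grid = Grid((n,) * 3, (spacing,) * 3, (-(n - 1) * spacing / 2.0,) * 3)
    axes = [grid.origin[a] + np.arange(n) * spacing for a in range(3)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    c = np.asarray(center, dtype=float)
    return BinaryMask(
        (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= radius**2, grid
    )


@pytest.fixture(scope="session")
def recovery_case():
    """Default-geometry 64-cube phantom with an 8 mm peak deformation."""
    return make_case(PhantomSpec(seed=42, deformation=DeformationSpec(peak_magnitude=8.0)))


@pytest.fixture(scope="session")
def clean_small_case():
    """Small, undegraded, undeformed case for fixed-point style checks."""
    return make_case(
        PhantomSpec(
            grid_size=(32, 32, 32),
            spacing=(4.0, 4.0, 4.0),
            seed=3,
            deformation=DeformationSpec(peak_magnitude=0.0),
            degradation=DegradationSpec(0.0, 0.0, 0.0, 90.0, 0.0),
            contour_noise=ContourNoiseSpec(target_dice=1.0),
        )
    )
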