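"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by literal enumeration
(pair-by-pair variogram sums, face-by-face surface counts) so they share no
code path with the vectorized implementations they check.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lesionvario import GridSpec, LesionMask, fit_all, make_cohort, morphometry

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def variogram_oracle_literal(values: np.ndarray, spacing, axis: int, cutoff_mm: float):
    """Empirical variogram by literal enumeration of all in-bounds pairs.

    Returns a list of (lag_mm, gamma, n_pairs) triples for integer lags
    k = 1 .. floor(cutoff / spacing).
    """
    shape = values.shape
    s = spacing[axis]
    k_max = min(int(np.floor(cutoff_mm / s + 1e-9)), shape[axis] - 1)
    out = []
    for k in range(1, k_max + 1):
        total = 0
        n = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for l in range(shape[2]):
                    idx = [i, j, l]
                    idx[axis] += k
                    if idx[axis] < shape[axis]:
                        d = int(values[i, j, l]) - int(values[tuple(idx)])
                        total += d * d
                        n += 1
        out.append((k * s, total / (2.0 * n), n))
    return out


def surface_oracle_literal(values: np.ndarray, spacing) -> float:
    """Surface area by looping over every voxel and its six face neighbors."""
    shape = values.shape
    face_area = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    total = 0.0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for l in range(shape[2]):
                if not values[i, j, l]:
                    continue
                for axis, area in enumerate(face_area):
                    for step in (-1, 1):
                        idx = [i, j, l]
                        idx[axis] += step
                        if not (0 <= idx[axis] < shape[axis]) or not values[tuple(idx)]:
                            total += area
    return total


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec((12, 10, 11), (1.5, 1.5, 1.5))


def random_mask(shape, p: float, seed: int, spacing=(1.5, 1.5, 1.5)) -> LesionMask:
    rng = np.random.default_rng(seed)
    values = (rng.random(shape) < p).astype(np.uint8)
    return LesionMask(values, GridSpec(shape, spacing), id=f"rand{seed}")


@pytest.fixture(scope="session")
def cohort_results():
    """A 50-pattern synthetic cohort run through the full pipeline once.

    Volumes are log-normal in [200, 50000] mm³ on the reference grid with a
    50/50 isotropic/Z-stretched mix; per-lesion size is fixed so the sill
    tracks total volume.
    """
    masks = make_cohort(50, (200.0, 50000.0), anisotropy_mix=0.5, seed=20509)
    rows = []
    for mask in masks:
        fits = fit_all(mask)
        report = morphometry(mask)
        rows.append(
            {
                "id": mask.id,
                "volume": mask.volume_mm3,
                "surface": report.total_surface_mm2,
                "n_lesions": report.n_lesions,
                "mean_sill": float(np.mean([f.c for f in fits])),
                "mean_range": float(np.mean([f.a for f in fits])),
                "fits": fits,
                "p": mask.lesion_fraction,
            }
        )
    return rows
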