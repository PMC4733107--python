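"""Synthetic binary lesion phantoms with controlled count, size and anisotropy.

Patterns are unions of ellipsoids placed by seeded rejection sampling and
voxelized by center inclusion (a voxel is foreground iff its center lies
inside an ellipsoid).  The generator emulates the geometry of normalized
MS-lesion masks — 1 to a few hundred compact lesions, total volumes from
tens to tens of thousands of mm³ on an MNI-like 1.5 mm grid, isotropic
(spherical) or axis-stretched (ellipsoidal) lesions — without any claim of
anatomical realism (no periventricular predilection, no confluent shapes).

Voxel centers sit at index * spacing, matching the lag geometry of the
variogram module.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .errors import PlacementError
from .masks import MNI_GRID, GridSpec, LesionMask

_SPHERE = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic lesion pattern.

    ``radius_mm`` may be a single value or a (lo, hi) range sampled per
    lesion; ``stretch`` multiplies the radius per axis to give the ellipsoid
    semi-axes.  If ``target_volume_mm3`` is set, radii are rescaled until
    the realized foreground volume is within 10% of the target.

    With ``snap_centers`` the sampled centers are rounded to the voxel
    lattice, so every lesion of a given size is voxelized identically and
    axis-symmetrically.  That removes sub-voxel aliasing anisotropy — the
    right setting when a pattern must be isotropic by construction — at the
    cost of slightly quantized placement.
    """

    grid: GridSpec = MNI_GRID
    n_lesions: int = 10
    radius_mm: float | tuple[float, float] = 3.0
    stretch: tuple[float, float, float] = _SPHERE
    min_separation_mm: float = 1.5
    seed: int = 0
    target_volume_mm3: float | None = None
    snap_centers: bool = False
    #: Keep lesion surfaces at least this far from the array boundary.  The
    #: brain sits well inside the MNI array, so real lesions never approach
    #: the edge; the margin also keeps edge-truncated voxel pairs (which drop
    #: out of n(h)) from biasing directional variograms.
    edge_margin_mm: float = 15.0
    id: str = ""
    exam_date: _dt.date | None = None


def _sample_radii(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    if isinstance(spec.radius_mm, tuple):
        lo, hi = spec.radius_mm
        return rng.uniform(lo, hi, size=spec.n_lesions)
    return np.full(spec.n_lesions, float(spec.radius_mm))


def _place_centers(
    grid: GridSpec,
    reach_mm: np.ndarray,
    min_separation_mm: float,
    rng: np.random.Generator,
    edge_margin_mm: float = 15.0,
    max_attempts_per_lesion: int = 2000,
) -> np.ndarray:
    """Rejection-sample lesion centers (mm) with non-overlap guarantees.

    ``reach_mm[i]`` is the largest semi-axis of lesion i; accepted centers
    satisfy |ci - cj| >= reach_i + reach_j + min_separation, every lesion
    fits fully inside the grid with a safety margin (1.3 x reach) that
    absorbs later radius rescaling, and lesion surfaces stay
    ``edge_margin_mm`` away from the array boundary.
    """
    extent = np.array([(n - 1) * s for n, s in zip(grid.shape, grid.spacing)])
    n = len(reach_mm)
    centers = np.empty((n, 3))
    for i in range(n):
        margin = 1.3 * reach_mm[i] + max(grid.spacing) + edge_margin_mm
        lo, hi = margin, extent - margin
        if np.any(hi <= lo):
            raise PlacementError(
                f"lesion of reach {reach_mm[i]:.1f} mm cannot fit inside grid extent {extent}"
            )
        for _ in range(max_attempts_per_lesion):
            cand = rng.uniform(lo, hi)
            if i == 0:
                centers[0] = cand
                break
            dist = np.linalg.norm(centers[:i] - cand, axis=1)
            if np.all(dist >= reach_mm[:i] + reach_mm[i] + min_separation_mm):
                centers[i] = cand
                break
        else:
            raise PlacementError(
                f"could not place lesion {i + 1}/{n} after {max_attempts_per_lesion} attempts: "
                f"min_separation={min_separation_mm} mm too demanding for grid {grid.shape}"
            )
    return centers


def _voxelize(
    grid: GridSpec, centers: np.ndarray, semi_axes: np.ndarray
) -> np.ndarray:
    """Center-inclusion voxelization of a union of ellipsoids."""
    values = np.zeros(grid.shape, dtype=np.uint8)
    spacing = np.asarray(grid.spacing)
    for center, semi in zip(centers, semi_axes):
        ilo = np.maximum(np.ceil((center - semi) / spacing), 0).astype(int)
        ihi = np.minimum(np.floor((center + semi) / spacing), np.array(grid.shape) - 1).astype(int)
        if np.any(ihi < ilo):
            continue
        coords = [
            np.arange(ilo[ax], ihi[ax] + 1) * spacing[ax] - center[ax] for ax in range(3)
        ]
        xs, ys, zs = np.meshgrid(*coords, indexing="ij", sparse=True)
        inside = (xs / semi[0]) ** 2 + (ys / semi[1]) ** 2 + (zs / semi[2]) ** 2 <= 1.0
        values[ilo[0] : ihi[0] + 1, ilo[1] : ihi[1] + 1, ilo[2] : ihi[2] + 1] |= inside.astype(
            np.uint8
        )
    return values


def make_pattern(spec: SyntheticSpec) -> LesionMask:
    """Generate one synthetic lesion mask; bit-reproducible per seed."""
    if spec.n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    rng = np.random.default_rng(spec.seed)
    radii = _sample_radii(spec, rng)
    stretch = np.asarray(spec.stretch, dtype=float)
    if np.any(stretch <= 0):
        raise ValueError(f"stretch must be positive, got {spec.stretch}")

    if spec.target_volume_mm3 is not None:
        if spec.target_volume_mm3 <= 0:
            raise ValueError("target_volume_mm3 must be positive")
        # Analytic pre-scaling: union volume of disjoint ellipsoids.
        analytic = np.sum(4.0 / 3.0 * np.pi * radii**3 * np.prod(stretch))
        radii = radii * (spec.target_volume_mm3 / analytic) ** (1.0 / 3.0)

    semi = radii[:, None] * stretch[None, :]
    reach = semi.max(axis=1)
    centers = _place_centers(
        spec.grid, reach, spec.min_separation_mm, rng, spec.edge_margin_mm
    )
    if spec.snap_centers:
        spacing = np.asarray(spec.grid.spacing)
        centers = np.round(centers / spacing) * spacing
    values = _voxelize(spec.grid, centers, semi)

    if spec.target_volume_mm3 is not None:
        target = spec.target_volume_mm3
        for _ in range(12):
            realized = np.count_nonzero(values) * spec.grid.voxel_volume_mm3
            if realized > 0 and abs(realized - target) / target <= 0.10:
                break
            scale = (target / realized) ** (1.0 / 3.0) if realized > 0 else 1.5
            semi = semi * np.clip(scale, 0.5, 1.3)
            values = _voxelize(spec.grid, centers, semi)
        else:
            realized = np.count_nonzero(values) * spec.grid.voxel_volume_mm3
            raise PlacementError(
                f"could not realize target volume {target} mm³ within 10% "
                f"(got {realized:.0f} mm³); lesions too small for the voxel size?"
            )
    return LesionMask(values, spec.grid, id=spec.id or f"syn_seed{spec.seed}", exam_date=spec.exam_date)


def _normalized_stretch(stretch: tuple[float, float, float]) -> tuple[float, float, float]:
    """Scale a stretch triple to unit volume multiplier (geometric mean 1)."""
    s = np.asarray(stretch, dtype=float)
    return tuple(s / np.prod(s) ** (1.0 / 3.0))


def make_cohort(
    n_patterns: int,
    volume_range_mm3: tuple[float, float] = (200.0, 50000.0),
    anisotropy_mix: float = 0.5,
    seed: int = 0,
    grid: GridSpec = MNI_GRID,
    radius_mm: float = 3.0,
    stretch: tuple[float, float, float] = (1.0, 1.0, 3.0),
) -> list[LesionMask]:
    """Generate a cohort with log-normally distributed total volumes.

    Per-lesion size is fixed (``radius_mm``), so total volume is controlled
    by lesion count — the cohort has fixed shape statistics, which is what
    makes the sill-volume relation linear.  A fraction ``anisotropy_mix`` of
    patterns uses the (volume-normalized) ``stretch`` to elongate lesions.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    lo, hi = volume_range_mm3
    if not (0 < lo < hi):
        raise ValueError(f"invalid volume range {volume_range_mm3}")
    rng = np.random.default_rng(seed)
    ln_lo, ln_hi = np.log(lo), np.log(hi)
    # Log-normal within range: normal in ln-volume, clipped with a margin so
    # the 10% realization tolerance cannot push volumes out of range.
    ln_v = rng.normal((ln_lo + ln_hi) / 2.0, (ln_hi - ln_lo) / 6.0, size=n_patterns)
    targets = np.exp(np.clip(ln_v, ln_lo + np.log(1.12), ln_hi - np.log(1.12)))
    lesion_vol = 4.0 / 3.0 * np.pi * radius_mm**3
    stretched = rng.random(n_patterns) < anisotropy_mix
    norm_stretch = _normalized_stretch(stretch)

    masks = []
    for i in range(n_patterns):
        n_lesions = max(1, int(round(targets[i] / lesion_vol)))
        spec = SyntheticSpec(
            grid=grid,
            n_lesions=n_lesions,
            radius_mm=radius_mm,
            stretch=norm_stretch if stretched[i] else _SPHERE,
            seed=int(rng.integers(0, 2**31 - 1)),
            target_volume_mm3=float(targets[i]),
            id=f"syn_{i:03d}" + ("_aniso" if stretched[i] else "_iso"),
        )
        masks.append(make_pattern(spec))
    return masks


def make_followup_series(
    kind: str,
    n_exams: int = 4,
    seed: int = 0,
    grid: GridSpec = MNI_GRID,
    base_volume_mm3: float = 4000.0,
    start_date: _dt.date = _dt.date(2009, 1, 1),
    interval_days: int = 180,
) -> list[LesionMask]:
    """Synthetic longitudinal series: 'growth', 'shrink' or 'fragmentation'.

    Growth/shrink scale lesion radii monotonically at fixed centers;
    fragmentation replaces one large sphere by progressively many small
    spheres of the same total volume (volume constant, surface complexity
    rising).  Exam dates ascend from ``start_date``.
    """
    if n_exams < 2:
        raise ValueError("a follow-up series needs >= 2 exams")
    rng = np.random.default_rng(seed)
    dates = [start_date + _dt.timedelta(days=interval_days * t) for t in range(n_exams)]
    masks: list[LesionMask] = []

    if kind in ("growth", "shrink"):
        n_lesions = 6
        base_r = (base_volume_mm3 / (n_lesions * 4.0 / 3.0 * np.pi)) ** (1.0 / 3.0)
        factors = np.linspace(1.0, 1.6, n_exams)
        if kind == "shrink":
            factors = factors[::-1]
        reach = np.full(n_lesions, base_r * factors.max())
        centers = _place_centers(grid, reach, 3.0, rng)
        for t, (f, date) in enumerate(zip(factors, dates)):
            semi = np.full((n_lesions, 3), base_r * f)
            values = _voxelize(grid, centers, semi)
            masks.append(
                LesionMask(values, grid, id=f"{kind}_{t + 1}", exam_date=date)
            )
    elif kind == "fragmentation":
        counts = [2**t for t in range(n_exams)]
        for t, (n, date) in enumerate(zip(counts, dates)):
            spec = SyntheticSpec(
                grid=grid,
                n_lesions=n,
                radius_mm=(base_volume_mm3 / (n * 4.0 / 3.0 * np.pi)) ** (1.0 / 3.0),
                seed=int(rng.integers(0, 2**31 - 1)),
                target_volume_mm3=base_volume_mm3,
                id=f"fragmentation_{t + 1}",
                exam_date=date,
            )
            masks.append(make_pattern(spec))
    else:
        raise ValueError(f"unknown follow-up kind {kind!r}")
    return masks


def aliasing_probe(seed: int = 0, grid: GridSpec = MNI_GRID) -> list[LesionMask]:
    """Tiny patterns (1-3 lesions of 1-4 voxels, <= 12 foreground voxels).

    Lesions represented by a handful of voxels alias badly: their variogram
    parameters, and hence the standard distance, are unstable.  These probes
    exercise the small-pattern warning path.
    """
    rng = np.random.default_rng(seed)
    center = np.array(grid.shape) // 2

    def offset() -> np.ndarray:
        return center + rng.integers(-15, 16, size=3)

    masks = []
    # One single-voxel lesion.
    v = np.zeros(grid.shape, dtype=np.uint8)
    v[tuple(offset())] = 1
    masks.append(LesionMask(v, grid, id="probe_1vox"))
    # One 2-voxel lesion collinear along Z.
    v = np.zeros(grid.shape, dtype=np.uint8)
    i, j, k = offset()
    v[i, j, k : k + 2] = 1
    masks.append(LesionMask(v, grid, id="probe_2vox_z"))
    # Three lesions of 4 voxels each (2x2x1 plates), 12 voxels total.
    v = np.zeros(grid.shape, dtype=np.uint8)
    for _ in range(3):
        i, j, k = offset()
        v[i : i + 2, j : j + 2, k] = 1
    masks.append(LesionMask(v, grid, id="probe_3x4vox"))
    # 8-voxel cube: the most compact tiny pattern, for contrast.
    v = np.zeros(grid.shape, dtype=np.uint8)
    i, j, k = offset()
    v[i : i + 2, j : j + 2, k : k + 2] = 1
    masks.append(LesionMask(v, grid, id="probe_cube8"))
    return masks
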