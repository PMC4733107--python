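"""Directional empirical indicator variograms on a regular voxel grid.

For a binary field z(x) the empirical variogram at lag vector h is

    gamma(h) = 1 / (2 n(h)) * sum over pairs [z(x) - z(x + h)]^2,

which for 0/1 data is half the fraction of voxel pairs at separation h whose
values disagree.  Lags are taken along one grid axis at a time, at exact
integer multiples of the voxel spacing, up to a cutoff (default 15 mm):
short lags carry the spatial-correlation signal of lesion-scale structure,
and a model can be fitted over this window without interference from
long-range layout effects.

The pair sum runs over the full rectangular array, background zeros
included, and never wraps around edges.  Keeping the domain fixed across
patterns makes the variogram sill directly comparable between masks
normalized to one grid (it is what ties the sill to total lesion volume).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masks import AXES, LesionMask

DEFAULT_CUTOFF_MM = 15.0


@dataclass(frozen=True)
class DirectionalVariogram:
    """Empirical variogram along one grid axis.

    ``lags_mm`` are ascending positive lag magnitudes |h|, ``gamma`` the
    semivariance per lag, ``n_pairs`` the number of voxel pairs per lag.
    """

    axis: str
    lags_mm: np.ndarray
    gamma: np.ndarray
    n_pairs: np.ndarray
    cutoff_mm: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": self.axis,
                "lag_mm": self.lags_mm,
                "gamma": self.gamma,
                "n_pairs": self.n_pairs,
            }
        )


def _axis_index(axis: int | str) -> int:
    if isinstance(axis, str):
        ax = axis.upper()
        if ax not in AXES:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
        return AXES.index(ax)
    if axis not in (0, 1, 2):
        raise ValueError(f"unknown axis index {axis}; expected 0, 1 or 2")
    return int(axis)


def empirical_variogram(
    mask: LesionMask, axis: int | str, cutoff_mm: float = DEFAULT_CUTOFF_MM
) -> DirectionalVariogram:
    """Estimate the empirical indicator variogram along one grid axis.

    Lags are k * spacing for k = 1 .. floor(cutoff_mm / spacing); lag 0 is
    identically zero and not emitted.  Pairs at lag k along an axis of
    length L number (L - k) * A with A the full cross-section, since edge
    pairs drop out rather than wrap.
    """
    ax = _axis_index(axis)
    spacing = mask.grid.spacing[ax]
    if cutoff_mm < spacing:
        raise ValueError(
            f"cutoff_mm={cutoff_mm} is below one voxel spacing ({spacing} mm) on axis {AXES[ax]}"
        )
    length = mask.grid.shape[ax]
    k_max = min(int(np.floor(cutoff_mm / spacing + 1e-9)), length - 1)
    cross_section = mask.grid.n_voxels // length

    z = mask.values
    lags = np.empty(k_max, dtype=float)
    gamma = np.empty(k_max, dtype=float)
    n_pairs = np.empty(k_max, dtype=np.int64)
    head = [slice(None)] * 3
    tail = [slice(None)] * 3
    for k in range(1, k_max + 1):
        head[ax] = slice(0, length - k)
        tail[ax] = slice(k, length)
        mismatches = np.count_nonzero(z[tuple(head)] != z[tuple(tail)])
        n = (length - k) * cross_section
        lags[k - 1] = k * spacing
        gamma[k - 1] = mismatches / (2.0 * n)
        n_pairs[k - 1] = n
    return DirectionalVariogram(AXES[ax], lags, gamma, n_pairs, float(cutoff_mm))


def variogram_set(
    mask: LesionMask, cutoff_mm: float = DEFAULT_CUTOFF_MM
) -> tuple[DirectionalVariogram, DirectionalVariogram, DirectionalVariogram]:
    """Directional variograms along X, Y and Z with a common cutoff."""
    return tuple(empirical_variogram(mask, ax, cutoff_mm) for ax in AXES)


def variograms_to_frame(vgs: tuple[DirectionalVariogram, ...]) -> pd.DataFrame:
    """Stack directional variograms into one long-format table."""
    return pd.concat([vg.to_frame() for vg in vgs], ignore_index=True)
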