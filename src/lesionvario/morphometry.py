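"""Classical lesion morphometry: count, volume, surface area, ratios.

These quantities cross-check the geostatistical parameters: total lesion
volume tracks the variogram sill, and volume/surface (an inverse measure of
surface complexity) tracks the range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .masks import LesionMask

#: Map connectivity naming (number of neighbors sharing a face/edge/corner)
#: to scipy's structuring-element rank.
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class MorphometryReport:
    """Per-pattern geometric summary.

    Ratios are NaN when their denominator is zero (empty mask).
    """

    id: str
    n_lesions: int
    total_volume_mm3: float
    total_surface_mm2: float
    vol_per_lesion: float
    surf_per_lesion: float
    vol_over_surf: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [self.id],
                "nLesions": [self.n_lesions],
                "Volume": [self.total_volume_mm3],
                "Surface": [self.total_surface_mm2],
                "Vol/Lesion": [self.vol_per_lesion],
                "Surf/Lesion": [self.surf_per_lesion],
                "Vol/Surf": [self.vol_over_surf],
            }
        )


def count_lesions(mask: LesionMask, connectivity: int = 26) -> int:
    """Number of connected foreground components.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (faces+edges+
    corners); 26 is the common convention for bright foreground in
    neuroimaging and the default here.
    """
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}, got {connectivity}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    _, n = ndimage.label(mask.values, structure=structure)
    return int(n)


def surface_area(mask: LesionMask) -> float:
    """Total exposed voxel-face area in mm².

    Counts every face where a 1-voxel abuts a 0-voxel or the array boundary;
    a face perpendicular to axis i contributes the product of the other two
    spacings (2.25 mm² on the 1.5 mm reference grid).
    """
    z = mask.values
    sx, sy, sz = mask.grid.spacing
    face_area = (sy * sz, sx * sz, sx * sy)
    padded = np.pad(z, 1, mode="constant")
    total = 0.0
    for ax, area in enumerate(face_area):
        diff = np.diff(padded.astype(np.int8), axis=ax)
        total += np.count_nonzero(diff) * area
    return float(total)


def ratios(n_lesions: int, volume: float, surface: float) -> tuple[float, float, float]:
    """(Vol/Lesion, Surf/Lesion, Vol/Surf); NaN where the denominator is 0."""
    vol_per = volume / n_lesions if n_lesions else math.nan
    surf_per = surface / n_lesions if n_lesions else math.nan
    vol_surf = volume / surface if surface else math.nan
    return vol_per, surf_per, vol_surf


def morphometry(mask: LesionMask, connectivity: int = 26) -> MorphometryReport:
    """Assemble the full morphometric report for one mask."""
    n = count_lesions(mask, connectivity)
    volume = mask.volume_mm3
    surface = surface_area(mask)
    vol_per, surf_per, vol_surf = ratios(n, volume, surface)
    return MorphometryReport(mask.id, n, volume, surface, vol_per, surf_per, vol_surf)
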