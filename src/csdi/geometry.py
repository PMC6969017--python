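"""ETDRS macular grid geometry: subfield definitions and rasterization.

The Early Treatment Diabetic Retinopathy Study (ETDRS) grid partitions the
macula into nine subfields centred on the fovea: a central disc (1 mm
diameter by convention) and two annuli — inner (1–3 mm) and outer (3–6 mm) —
each cut into superior, inferior, temporal and nasal quadrants by the
45-degree diagonals.

Masks are rasterized by the pixel-centre rule: a pixel belongs to the
subfield that contains its centre point in fovea-centred physical
coordinates.  Radial bins are half-open ``[0, c/2)``, ``[c/2, i/2)``,
``[i/2, o/2)`` and angular bins are half-open starting at 45°, so pixels on
a boundary are assigned deterministically.

Coordinates are anatomical: +x temporal, +y superior.  For a right eye (OD)
the temporal direction coincides with increasing column index; for a left
eye (OS) the horizontal axis is mirrored so that the temporal/nasal labels
follow the anatomy rather than the image side.  Everything downstream of
mask construction is therefore laterality-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Canonical subfield labels: central; superior/inferior/temporal/nasal
#: crossed with inner/outer.
SUBFIELD_LABELS = ("C", "SI", "SO", "II", "IO", "TI", "TO", "NI", "NO")

LATERALITIES = ("OD", "OS")

_QUADRANTS = ("S", "N", "I", "T")


class TruncationError(ValueError):
    """The outer ETDRS circle does not fit on the raster.

    Attributes
    ----------
    clipped : tuple of str
        Labels of the subfields whose analytic footprint extends beyond the
        raster extent.
    """

    def __init__(self, clipped):
        self.clipped = tuple(clipped)
        super().__init__(
            "outer ETDRS circle extends beyond the raster extent; "
            "clipped subfields: " + ", ".join(self.clipped)
        )


@dataclass(frozen=True)
class GridSpec:
    """ETDRS circle diameters (mm) and the eye's laterality.

    Defaults are the standard ETDRS 1/3/6-mm circles.
    """

    center_diameter_mm: float = 1.0
    inner_diameter_mm: float = 3.0
    outer_diameter_mm: float = 6.0
    laterality: str = "OD"

    def __post_init__(self):
        if not (
            0.0
            < self.center_diameter_mm
            < self.inner_diameter_mm
            < self.outer_diameter_mm
        ):
            raise ValueError(
                "diameters must satisfy 0 < center < inner < outer; got "
                f"{self.center_diameter_mm}, {self.inner_diameter_mm}, "
                f"{self.outer_diameter_mm}"
            )
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )


@dataclass(frozen=True)
class RasterSpec:
    """Geometry of a thickness-map raster.

    Rows run superior→inferior (image top to bottom), columns along the
    B-scan.  The fovea position is a real-valued (sub-pixel) index;
    distances are measured from pixel centres to it.  Spacing may be
    anisotropic — the standard volumetric scan used here has 31 B-scans
    spaced 0.240 mm vertically and 768 A-scans over 9.0 mm horizontally.
    """

    n_rows: int
    n_cols: int
    row_spacing_mm: float
    col_spacing_mm: float
    fovea_row: float
    fovea_col: float

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("raster must have at least one row and column")
        if self.row_spacing_mm <= 0 or self.col_spacing_mm <= 0:
            raise ValueError(
                "pixel spacings must be positive; got "
                f"row {self.row_spacing_mm} mm, col {self.col_spacing_mm} mm"
            )
        if not (0 <= self.fovea_row <= self.n_rows - 1):
            raise ValueError(f"fovea_row {self.fovea_row} outside [0, {self.n_rows - 1}]")
        if not (0 <= self.fovea_col <= self.n_cols - 1):
            raise ValueError(f"fovea_col {self.fovea_col} outside [0, {self.n_cols - 1}]")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_mm2(self) -> float:
        return self.row_spacing_mm * self.col_spacing_mm

    def pixel_centers_mm(self, laterality: str = "OD"):
        """Anatomical coordinates (x temporal, y superior) of pixel centres.

        Returns two ``(n_rows, n_cols)`` arrays ``(x, y)`` in mm relative to
        the fovea.  For OS the horizontal axis is mirrored.
        """
        if laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")
        rows = np.arange(self.n_rows, dtype=float)
        cols = np.arange(self.n_cols, dtype=float)
        y = ((self.fovea_row - rows) * self.row_spacing_mm)[:, None]
        x = ((cols - self.fovea_col) * self.col_spacing_mm)[None, :]
        if laterality == "OS":
            x = -x
        return np.broadcast_arrays(x + 0.0 * y, y + 0.0 * x)

    def margins_mm(self) -> dict[str, float]:
        """Physical distance from the fovea to each raster edge.

        Measured to the outer edge of the boundary pixel cells (each pixel
        cell covers ±half a spacing around its centre).  Keys are image
        sides: top/bottom/left/right.
        """
        return {
            "top": (self.fovea_row + 0.5) * self.row_spacing_mm,
            "bottom": (self.n_rows - 0.5 - self.fovea_row) * self.row_spacing_mm,
            "left": (self.fovea_col + 0.5) * self.col_spacing_mm,
            "right": (self.n_cols - 0.5 - self.fovea_col) * self.col_spacing_mm,
        }


@dataclass(frozen=True)
class SubfieldMasks:
    """Boolean masks for the nine ETDRS subfields on one raster."""

    grid: GridSpec
    raster: RasterSpec
    masks: dict[str, np.ndarray] = field(repr=False)

    @property
    def pixel_counts(self) -> dict[str, int]:
        return {s: int(m.sum()) for s, m in self.masks.items()}

    @property
    def area_mm2(self) -> dict[str, float]:
        px = self.raster.pixel_area_mm2
        return {s: n * px for s, n in self.pixel_counts.items()}

    @property
    def disc(self) -> np.ndarray:
        """Union of all nine masks: the rasterized 6-mm disc."""
        out = np.zeros(self.raster.shape, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out

    def label_raster(self) -> np.ndarray:
        """Integer raster: 0 outside the grid, 1..9 per SUBFIELD_LABELS order."""
        out = np.zeros(self.raster.shape, dtype=np.int8)
        for code, label in enumerate(SUBFIELD_LABELS, start=1):
            out[self.masks[label]] = code
        return out


def _clipped_subfields(grid: GridSpec, raster: RasterSpec) -> list[str]:
    """Subfields whose analytic footprint exceeds the raster extent."""
    margins = raster.margins_mm()
    # Map image sides to anatomical directions.
    side_to_dir = {"top": "S", "bottom": "I"}
    if grid.laterality == "OD":
        side_to_dir.update({"right": "T", "left": "N"})
    else:
        side_to_dir.update({"right": "N", "left": "T"})
    c = grid.center_diameter_mm / 2.0
    i = grid.inner_diameter_mm / 2.0
    o = grid.outer_diameter_mm / 2.0
    clipped: list[str] = []
    for side, margin in margins.items():
        d = side_to_dir[side]
        overshoot = o - margin
        if overshoot <= 0:
            continue
        clipped.append(d + "O")
        if overshoot > o - i:
            clipped.append(d + "I")
        if overshoot > o - c:
            clipped.append("C")
    return sorted(set(clipped), key=lambda s: SUBFIELD_LABELS.index(s))


def build_masks(grid: GridSpec, raster: RasterSpec) -> SubfieldMasks:
    """Rasterize the nine ETDRS subfields onto a raster.

    Parameters
    ----------
    grid
        Circle diameters and laterality.
    raster
        Raster geometry, including the (sub-pixel) fovea position.

    Returns
    -------
    SubfieldMasks
        Pairwise-disjoint boolean masks whose union is exactly the set of
        pixels whose centres lie within ``outer_diameter_mm / 2`` of the
        fovea.

    Raises
    ------
    TruncationError
        If the outer circle does not fit on the raster; the error names the
        clipped subfields.
    """
    clipped = _clipped_subfields(grid, raster)
    if clipped:
        raise TruncationError(clipped)

    x, y = raster.pixel_centers_mm(grid.laterality)
    r = np.hypot(x, y)
    theta = np.degrees(np.arctan2(y, x)) % 360.0

    c = grid.center_diameter_mm / 2.0
    i = grid.inner_diameter_mm / 2.0
    o = grid.outer_diameter_mm / 2.0

    in_center = r < c
    in_inner = (r >= c) & (r < i)
    in_outer = (r >= i) & (r < o)

    quad = {
        "S": (theta >= 45.0) & (theta < 135.0),
        "N": (theta >= 135.0) & (theta < 225.0),
        "I": (theta >= 225.0) & (theta < 315.0),
        "T": (theta >= 315.0) | (theta < 45.0),
    }

    masks: dict[str, np.ndarray] = {"C": in_center}
    for q in _QUADRANTS:
        masks[q + "I"] = in_inner & quad[q]
        masks[q + "O"] = in_outer & quad[q]

    empty = [s for s in SUBFIELD_LABELS if not masks[s].any()]
    if empty:
        warnings.warn(
            "raster too coarse: empty subfield masks " + ", ".join(empty),
            RuntimeWarning,
            stacklevel=2,
        )
    return SubfieldMasks(grid=grid, raster=raster, masks=masks)


def annular_sector_area_mm2(
    inner_diameter_mm: float, outer_diameter_mm: float, n_sectors: int = 4
) -> float:
    """Analytic area of one quadrant of an annulus (closed form)."""
    ri = inner_diameter_mm / 2.0
    ro = outer_diameter_mm / 2.0
    return np.pi * (ro**2 - ri**2) / n_sectors
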