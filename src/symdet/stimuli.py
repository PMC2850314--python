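"""Random-dot stimulus generation: mirror-symmetric targets, count-matched
random controls, superimposed noise maskers, the 8-aperture viewing mask,
and the reverse-mapping symmetry count.

Grids live at dot resolution: one cell is one dot (4 arcmin by default).
Coordinates are centered on the grid, y up; axis orientation is measured
counter-clockwise from vertical (0 = vertical, 90 = horizontal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AxisOrientation",
    "DotPattern",
    "ApertureMask",
    "SymmetryCount",
    "generate_symmetric_pattern",
    "generate_control_pattern",
    "superimpose_noise",
    "make_aperture_mask",
    "apply_mask",
    "axis_blank_arc",
    "count_mirror_pairs",
    "to_pgm",
    "to_png",
    "render_display",
]


class AxisOrientation(enum.IntEnum):
    """Candidate symmetry-axis orientations, degrees CCW from vertical."""

    VERTICAL = 0
    DIAGONAL_45 = 45
    HORIZONTAL = 90
    DIAGONAL_135 = 135


@dataclass
class DotPattern:
    """Binary dot grid with geometry metadata.

    ``grid`` is a 2-D boolean array (rows x cols, True = dot);
    ``cell_arcmin`` is the angular size of one cell (one dot).
    """

    grid: np.ndarray
    cell_arcmin: float = 4.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2-D")
        if self.grid.dtype != bool:
            uniq = np.unique(self.grid)
            if not np.isin(uniq, (0, 1)).all():
                raise ValueError("grid must be binary")
            self.grid = self.grid.astype(bool)

    @property
    def height_px(self) -> int:
        return self.grid.shape[0]

    @property
    def width_px(self) -> int:
        return self.grid.shape[1]

    @property
    def n_dots(self) -> int:
        return int(self.grid.sum())

    @property
    def density(self) -> float:
        return self.n_dots / self.grid.size

    @property
    def extent_deg(self) -> tuple[float, float]:
        """Angular extent (width, height) in degrees."""
        return (self.width_px * self.cell_arcmin / 60.0,
                self.height_px * self.cell_arcmin / 60.0)


@dataclass(frozen=True)
class ApertureMask:
    """Eight circular apertures evenly spaced on a viewing circle.

    ``center_angles_deg`` are polar angles (CCW from the horizontal) of
    the aperture centers on the circle of ``circle_diameter_deg``.  High
    salience puts centers at 0..315 in 45-degree steps so every candidate
    axis passes through a diametrically opposite aperture pair; low
    salience shifts centers clockwise by 22.5 degrees so no axis line
    touches any aperture.
    """

    salience: str
    circle_diameter_deg: float = 6.0
    aperture_diameter_deg: float = 1.2
    n_apertures: int = 8
    center_angles_deg: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.salience not in ("high", "low"):
            raise ValueError(f"salience must be 'high' or 'low', got {self.salience!r}")
        if not self.center_angles_deg:
            shift = 0.0 if self.salience == "high" else -22.5
            angles = tuple((45.0 * k + shift) % 360.0 for k in range(self.n_apertures))
            object.__setattr__(self, "center_angles_deg", angles)
        # non-overlap: adjacent center chord must exceed the aperture diameter
        r = self.circle_diameter_deg / 2.0
        chord = 2.0 * r * np.sin(np.pi / self.n_apertures)
        if chord <= self.aperture_diameter_deg:
            raise ValueError("apertures overlap for this geometry")

    def centers_deg(self) -> np.ndarray:
        """Cartesian aperture centers (x, y) in degrees, origin at fixation."""
        r = self.circle_diameter_deg / 2.0
        a = np.deg2rad(np.asarray(self.center_angles_deg))
        return np.column_stack([r * np.cos(a), r * np.sin(a)])


@dataclass(frozen=True)
class SymmetryCount:
    """Reverse-mapping count: dots with an occupied mirror position."""

    ns: int
    n_total: int
    axis: AxisOrientation

    def __post_init__(self) -> None:
        if not (0 <= self.ns <= self.n_total):
            raise ValueError("need 0 <= ns <= n_total")


def _centered_coords(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int]):
    h, w = shape
    x = cols - (w - 1) / 2.0
    y = (h - 1) / 2.0 - rows
    return x, y


def _mirror_cells(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int],
                  axis: AxisOrientation):
    """Mirror cell indices about the axis through the grid center.

    Rotate into the axis frame (x' = x cos t + y sin t,
    y' = y cos t - x sin t), negate x', rotate back, round to the nearest
    cell.  Returns (mirror_rows, mirror_cols, in_bounds mask).
    """
    h, w = shape
    t = np.deg2rad(float(axis))
    c, s = np.cos(t), np.sin(t)
    x, y = _centered_coords(np.asarray(rows, float), np.asarray(cols, float), shape)
    xr = x * c + y * s
    yr = y * c - x * s
    xm = -xr * c - yr * s
    ym = yr * c - xr * s
    mc = np.rint(xm + (w - 1) / 2.0).astype(int)
    mr = np.rint((h - 1) / 2.0 - ym).astype(int)
    ok = (mr >= 0) & (mr < h) & (mc >= 0) & (mc < w)
    return mr, mc, ok


def _exact_count(density: float, n_cells: int) -> int:
    if not (0.0 <= density <= 1.0):
        raise ValueError(f"density must lie in [0, 1], got {density}")
    return int(round(density * n_cells))


def generate_symmetric_pattern(width_px: int, height_px: int, density: float,
                               axis: AxisOrientation, seed=None,
                               cell_arcmin: float = 4.0) -> DotPattern:
    """Dot pattern mirror-symmetric about the given axis through the center.

    Cells are seeded in mirror pairs (on-axis cells are their own
    partner), giving a realized count within one dot of
    round(density * cells).  Candidate cells whose rounded mirror is out
    of bounds or not a clean involution (possible for diagonal axes on
    non-square grids) are skipped.
    """
    if width_px <= 0 or height_px <= 0:
        raise ValueError("grid dimensions must be positive")
    axis = AxisOrientation(axis)
    rng = np.random.default_rng(seed)
    n_cells = width_px * height_px
    k = _exact_count(density, n_cells)

    grid = np.zeros((height_px, width_px), dtype=bool)
    if k == 0:
        return DotPattern(grid, cell_arcmin)

    order = rng.permutation(n_cells)
    rows, cols = np.unravel_index(order, grid.shape)
    mr, mc, ok = _mirror_cells(rows, cols, grid.shape, axis)
    # clean involution check: mirror of mirror must return the original
    mr2, mc2, ok2 = _mirror_cells(mr, mc, grid.shape, axis)
    ok &= ok2 & (mr2 == rows) & (mc2 == cols)

    count = 0
    axis_cells: list[tuple[int, int]] = []
    for r, c, r2, c2, valid in zip(rows, cols, mr, mc, ok):
        if count >= k or (count + 2 > k and axis_cells):
            break
        if not valid or grid[r, c]:
            continue
        if r == r2 and c == c2:
            axis_cells.append((int(r), int(c)))
            continue
        if grid[r2, c2]:
            continue
        if count + 2 <= k:
            grid[r, c] = grid[r2, c2] = True
            count += 2
    if count < k and axis_cells:
        r, c = axis_cells[0]
        grid[r, c] = True
        count += 1
    if abs(count - k) > 1:
        raise ValueError(
            f"could not realize density {density} on a {width_px}x{height_px} "
            f"grid with axis {axis.name} (placed {count} of {k} dots)"
        )
    return DotPattern(grid, cell_arcmin)


def generate_control_pattern(width_px: int, height_px: int, density: float,
                             seed=None, cell_arcmin: float = 4.0) -> DotPattern:
    """Uniform random pattern with exactly round(density * cells) dots."""
    if width_px <= 0 or height_px <= 0:
        raise ValueError("grid dimensions must be positive")
    rng = np.random.default_rng(seed)
    n_cells = width_px * height_px
    k = _exact_count(density, n_cells)
    grid = np.zeros(n_cells, dtype=bool)
    if k:
        grid[rng.choice(n_cells, size=k, replace=False)] = True
    return DotPattern(grid.reshape(height_px, width_px), cell_arcmin)


def superimpose_noise(pattern: DotPattern, noise, seed=None) -> DotPattern:
    """Union of a pattern with a random noise masker.

    ``noise`` is either a density in [0, 1] (an independent exact-count
    random pattern is drawn) or a DotPattern of the same shape.  Overlap
    is absorbed: the output on-count is at most the sum of the two.
    """
    if isinstance(noise, DotPattern):
        if noise.grid.shape != pattern.grid.shape:
            raise ValueError(
                f"size mismatch: {pattern.grid.shape} vs {noise.grid.shape}"
            )
        noise_grid = noise.grid
    else:
        noise_pat = generate_control_pattern(
            pattern.width_px, pattern.height_px, float(noise), seed,
            pattern.cell_arcmin,
        )
        noise_grid = noise_pat.grid
    return DotPattern(pattern.grid | noise_grid, pattern.cell_arcmin)


def make_aperture_mask(salience: str) -> ApertureMask:
    """The 8-aperture mask for the given axial-salience condition."""
    return ApertureMask(salience=salience)


def apply_mask(pattern: DotPattern, mask: ApertureMask) -> DotPattern:
    """Remove all dots outside the aperture discs.

    The pattern must be large enough to cover the full mask extent
    (viewing circle radius plus aperture radius).
    """
    need = mask.circle_diameter_deg + mask.aperture_diameter_deg
    w_deg, h_deg = pattern.extent_deg
    if w_deg < need or h_deg < need:
        raise ValueError(
            f"pattern extent {w_deg:.2f}x{h_deg:.2f} deg is smaller than the "
            f"mask extent {need:.2f} deg"
        )
    rows, cols = np.nonzero(pattern.grid)
    out = np.zeros_like(pattern.grid)
    if rows.size:
        x, y = _centered_coords(rows.astype(float), cols.astype(float),
                                pattern.grid.shape)
        scale = pattern.cell_arcmin / 60.0
        x_deg, y_deg = x * scale, y * scale
        centers = mask.centers_deg()
        r_ap = mask.aperture_diameter_deg / 2.0
        d2 = (x_deg[:, None] - centers[None, :, 0]) ** 2 + (
            y_deg[:, None] - centers[None, :, 1]
        ) ** 2
        keep = (d2 <= r_ap**2).any(axis=1)
        out[rows[keep], cols[keep]] = True
    return DotPattern(out, pattern.cell_arcmin)


def axis_blank_arc(mask: ApertureMask, axis: AxisOrientation | None = None) -> float:
    """Aperture-free arc (degrees of visual angle along the viewing
    circle) centered on the symmetry-axis crossing.

    High salience: each axis crossing sits inside an aperture, so the
    blank arc is 0.  Low salience: the axis crossing is midway between
    adjacent apertures; the arc convention is (arc between adjacent
    aperture centers) minus (one aperture diameter).
    """
    if axis is not None:
        AxisOrientation(axis)
    if mask.salience == "high":
        return 0.0
    r = mask.circle_diameter_deg / 2.0
    center_arc = r * (2.0 * np.pi / mask.n_apertures)
    return float(center_arc - mask.aperture_diameter_deg)


def count_mirror_pairs(pattern: DotPattern, axis: AxisOrientation) -> SymmetryCount:
    """Reverse-mapping count: number of dots whose mirror cell about the
    axis is also occupied (on-axis dots are their own partner)."""
    axis = AxisOrientation(axis)
    rows, cols = np.nonzero(pattern.grid)
    n_total = rows.size
    if n_total == 0:
        return SymmetryCount(0, 0, axis)
    mr, mc, ok = _mirror_cells(rows, cols, pattern.grid.shape, axis)
    ns = int(np.count_nonzero(pattern.grid[mr[ok], mc[ok]]))
    return SymmetryCount(ns, int(n_total), axis)


# ---------------------------------------------------------------------------
# rendering / export

def render_display(pattern: DotPattern, mask: ApertureMask | None = None,
                   dot_level: int = 255, background_level: int = 0,
                   field_level: int = 128) -> np.ndarray:
    """Render to a uint8 image at dot resolution.

    With a mask, cells outside every aperture disc are painted the gray
    field level; dots inside apertures stay white on black.
    """
    img = np.full(pattern.grid.shape, background_level, dtype=np.uint8)
    img[pattern.grid] = dot_level
    if mask is not None:
        rows, cols = np.indices(pattern.grid.shape)
        x, y = _centered_coords(rows.astype(float), cols.astype(float),
                                pattern.grid.shape)
        scale = pattern.cell_arcmin / 60.0
        centers = mask.centers_deg()
        r_ap = mask.aperture_diameter_deg / 2.0
        d2 = (x[..., None] * scale - centers[None, None, :, 0]) ** 2 + (
            y[..., None] * scale - centers[None, None, :, 1]
        ) ** 2
        outside = ~(d2 <= r_ap**2).any(axis=-1)
        img[outside] = field_level
    return img


def to_pgm(image: np.ndarray, path) -> None:
    """Write a uint8 image as plain-text PGM (P2)."""
    image = np.asarray(image, dtype=np.uint8)
    lines = [f"P2", f"{image.shape[1]} {image.shape[0]}", "255"]
    lines += [" ".join(str(v) for v in row) for row in image]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def to_png(image: np.ndarray, path) -> None:
    """Write a uint8 image as PNG."""
    from PIL import Image

    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)
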