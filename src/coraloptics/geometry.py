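"""Voxelized coral geometry and per-medium optical properties.

The model coral is a simplified two-layer faviid structure: a calcium
carbonate skeleton with ~3 mm wide coenosteum walls and ~10 mm wide,
~8 mm deep corallite cups, draped by a ~2 mm living tissue layer, all
under water.  The cross-section is drawn in the x-z plane and extruded
unchanged along y, so every x-z slice of the label volume is identical.

Coordinates: z increases downward from the top of the water column,
x = 0 is the center of the illuminated coenosteum wall, y = 0 the
center of the extrusion axis.  Voxel (i, j, k) spans
[i*dx, (i+1)*dx) x [j*dy, (j+1)*dy) x [k*dz, (k+1)*dz) in local
(offset) coordinates; helper methods convert to the centered physical
frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "OpticalProperties",
    "CoralModelParams",
    "VoxelGrid",
    "WATER",
    "TISSUE",
    "SKELETON",
    "make_medium",
    "build_coral_model",
    "build_bare_skeleton",
    "replace_skeleton_with_tissue",
    "build_homogeneous_slab",
    "internal_reflectance",
]

# Medium labels shared by all builders.
WATER = 0
TISSUE = 1
SKELETON = 2


@dataclass(frozen=True)
class OpticalProperties:
    """Inherent optical properties of one homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient [cm^-1], >= 0.
    mu_s : float
        Scattering coefficient [cm^-1], >= 0.
    g : float
        Scattering anisotropy (mean cosine of the Henyey-Greenstein
        deflection angle), -1 < g < 1.
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s: float
    g: float = 0.9
    n: float = 1.38

    def __post_init__(self) -> None:
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError("mu_a and mu_s must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must satisfy -1 < g < 1")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s' = mu_s (1 - g) [cm^-1]."""
        return self.mu_s * (1.0 - self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s [cm^-1]."""
        return self.mu_a + self.mu_s


def make_medium(mu_a: float, mu_s_prime: float, g: float = 0.9,
                n: float = 1.38) -> OpticalProperties:
    """Build a medium from (mu_a, mu_s') with mu_s = mu_s' / (1 - g).

    Reduced scattering is the quantity reported by diffuse-optics
    experiments; the transport loop needs mu_s, so the stored scattering
    coefficient is scaled up by 1/(1-g) for forward-peaked media.
    """
    if mu_s_prime < 0:
        raise ValueError("mu_s_prime must be non-negative")
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must satisfy -1 < g < 1")
    return OpticalProperties(mu_a=mu_a, mu_s=mu_s_prime / (1.0 - g), g=g, n=n)


#: Water as a (weakly) participating medium at 636 nm, so that fluence is
#: scored in the water column above the tissue as well.
def water_medium() -> OpticalProperties:
    return make_medium(mu_a=0.003, mu_s_prime=0.05, g=0.9, n=1.33)


@dataclass(frozen=True)
class CoralModelParams:
    """Dimensions [mm] of the simplified two-layer coral model."""

    wall_thickness: float = 3.0
    corallite_width: float = 10.0
    corallite_depth: float = 8.0
    tissue_thickness: float = 2.0
    water_depth: float = 2.0
    x_extent: float = 30.0
    y_extent: float = 44.0
    z_extent: float = 16.0
    dx: float = 0.25
    dy: float = 0.25
    dz: float = 0.25

    def __post_init__(self) -> None:
        for name in ("wall_thickness", "corallite_width", "corallite_depth",
                     "tissue_thickness", "water_depth", "x_extent",
                     "y_extent", "z_extent", "dx", "dy", "dz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tissue_thickness >= self.corallite_depth:
            raise ValueError("tissue layer cannot fill the corallite cup")
        period = self.wall_thickness + self.corallite_width
        if self.x_extent < period + self.wall_thickness:
            raise ValueError(
                "domain must contain one corallite plus flanking walls")
        needed_z = (self.water_depth + self.tissue_thickness
                    + self.corallite_depth)
        if self.z_extent <= needed_z:
            raise ValueError("z_extent too shallow for water+tissue+corallite")

    @property
    def crest_depth(self) -> float:
        """Depth z [mm] of the skeleton crest (top of the coenosteum)."""
        return self.water_depth + self.tissue_thickness


def fitting_params() -> CoralModelParams:
    """Grid preset for inverse-fitting forward runs: 0.5 mm voxels.

    The radial observable varies over ~3 mm decay lengths, so 0.5 mm
    voxels (the coarsest that still resolve the 2 mm tissue layer)
    lose no usable shape information while the larger tally volumes
    cut the Monte Carlo variance of each forward evaluation severalfold.
    """
    return CoralModelParams(dx=0.5, dy=0.5, dz=0.5)


@dataclass
class VoxelGrid:
    """Labeled voxel volume plus the label -> medium table.

    ``labels`` is indexed [ix, iy, iz] with z increasing downward.
    """

    labels: np.ndarray
    media: dict[int, OpticalProperties]
    dx: float
    dy: float
    dz: float
    params: CoralModelParams | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.media)
        if missing:
            raise ValueError(f"labels without media entries: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        nx, ny, nz = self.labels.shape
        return nx * self.dx, ny * self.dy, nz * self.dz

    @property
    def voxel_volume_cm3(self) -> float:
        return (self.dx * self.dy * self.dz) * 1e-3  # mm^3 -> cm^3

    def index_of(self, x_mm: float, y_mm: float, z_mm: float) -> tuple[int, int, int]:
        """Voxel index for a point in the centered frame (x=y=0 center, z down)."""
        lx, ly, _ = self.extent_mm
        ix = int((x_mm + lx / 2) / self.dx)
        iy = int((y_mm + ly / 2) / self.dy)
        iz = int(z_mm / self.dz)
        nx, ny, nz = self.labels.shape
        if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
            raise ValueError(f"point ({x_mm}, {y_mm}, {z_mm}) mm outside domain")
        return ix, iy, iz

    def label_at(self, x_mm: float, y_mm: float, z_mm: float) -> int:
        return int(self.labels[self.index_of(x_mm, y_mm, z_mm)])

    def property_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(mu_a, mu_s, g) lookup arrays indexed by label, for the kernel."""
        n = max(self.media) + 1
        mu_a = np.zeros(n)
        mu_s = np.zeros(n)
        g = np.zeros(n)
        for lab, props in self.media.items():
            mu_a[lab] = props.mu_a
            mu_s[lab] = props.mu_s
            g[lab] = props.g
        return mu_a, mu_s, g


def _cross_section(params: CoralModelParams) -> np.ndarray:
    """Labels for one x-z slice (shape nx, nz) of the coral model."""
    nx = int(round(params.x_extent / params.dx))
    nz = int(round(params.z_extent / params.dz))
    x = (np.arange(nx) + 0.5) * params.dx - params.x_extent / 2.0
    z = (np.arange(nz) + 0.5) * params.dz

    period = params.wall_thickness + params.corallite_width
    # Signed distance of each column from the nearest wall center; the
    # illuminated wall is centered at x = 0 and the pattern repeats.
    x_wall = np.abs((x + period / 2.0) % period - period / 2.0)
    in_wall = x_wall <= params.wall_thickness / 2.0

    crest = params.crest_depth
    floor = crest + params.corallite_depth

    skel = np.zeros((nx, nz), dtype=bool)
    zz = z[None, :]
    # walls rise to the crest; between walls the skeleton starts below the cup
    skel |= in_wall[:, None] & (zz >= crest)
    skel |= ~in_wall[:, None] & (zz >= floor)

    # conformal tissue drape: voxels within tissue_thickness of the skeleton
    dist = ndimage.distance_transform_edt(
        ~skel, sampling=(params.dx, params.dz))
    tissue = (~skel) & (dist <= params.tissue_thickness)

    labels = np.full((nx, nz), WATER, dtype=np.uint8)
    labels[tissue] = TISSUE
    labels[skel] = SKELETON
    return labels


def _check_resolution(params: CoralModelParams) -> None:
    coarse = max(params.dx, params.dz)
    if coarse > params.tissue_thickness / 4.0:
        raise ValueError(
            "voxel size coarser than tissue_thickness/4; the tissue layer "
            "would be unresolved")


def build_coral_model(params: CoralModelParams,
                      tissue: OpticalProperties,
                      skeleton: OpticalProperties,
                      water: OpticalProperties | None = None) -> VoxelGrid:
    """Two-layer coral: water over a conformal tissue drape over skeleton.

    The tissue layer lines the wall crest, the corallite side walls and
    the cup floor with uniform thickness; the cross-section is extruded
    along y.
    """
    _check_resolution(params)
    if water is None:
        water = water_medium()
    ny = int(round(params.y_extent / params.dy))
    slice_xz = _cross_section(params)
    labels = np.repeat(slice_xz[:, None, :], ny, axis=1)
    return VoxelGrid(labels=labels,
                     media={WATER: water, TISSUE: tissue, SKELETON: skeleton},
                     dx=params.dx, dy=params.dy, dz=params.dz, params=params)


def build_bare_skeleton(params: CoralModelParams,
                        skeleton: OpticalProperties,
                        water: OpticalProperties | None = None) -> VoxelGrid:
    """Coral model with the tissue removed: tissue voxels become water.

    Emulates the cleaned-skeleton measurement, performed underwater on
    the same colony after the living tissue is blown off.
    """
    if water is None:
        water = water_medium()
    grid = build_coral_model(params, tissue=make_medium(0.0, 0.0, g=0.0),
                             skeleton=skeleton, water=water)
    labels = grid.labels.copy()
    labels[labels == TISSUE] = WATER
    return VoxelGrid(labels=labels,
                     media={WATER: water, SKELETON: skeleton},
                     dx=params.dx, dy=params.dy, dz=params.dz, params=params)


def replace_skeleton_with_tissue(grid: VoxelGrid,
                                 tissue: OpticalProperties) -> VoxelGrid:
    """Hypothetical coral where the skeleton is a solid mass of tissue.

    Only the media table changes; the label volume is shared unchanged,
    so the geometry (and any label-based masks) is identical.
    """
    if SKELETON not in grid.media:
        raise ValueError("grid has no skeleton medium to replace")
    media = dict(grid.media)
    media[SKELETON] = tissue
    return VoxelGrid(labels=grid.labels, media=media,
                     dx=grid.dx, dy=grid.dy, dz=grid.dz, params=grid.params)


def build_homogeneous_slab(props: OpticalProperties, thickness_mm: float,
                           x_extent: float = 20.0, y_extent: float = 20.0,
                           dx: float = 0.2, dy: float = 0.2,
                           dz: float = 0.05) -> VoxelGrid:
    """Single-medium slab starting at z = 0, for closed-form validation."""
    if thickness_mm <= 0:
        raise ValueError("thickness must be positive")
    nx = int(round(x_extent / dx))
    ny = int(round(y_extent / dy))
    nz = int(round(thickness_mm / dz))
    labels = np.full((nx, ny, nz), TISSUE, dtype=np.uint8)
    return VoxelGrid(labels=labels, media={TISSUE: props},
                     dx=dx, dy=dy, dz=dz)


def internal_reflectance(n_rel: float) -> float:
    """Effective internal reflectance for diffuse light at a boundary.

    Empirical polynomial in the relative refractive index n_rel
    (tissue over surround) from the tissue-optics literature:

        r_i = 0.668 + 0.0636 n + 0.710 / n - 1.440 / n^2

    For coral tissue (n ~ 1.38) under seawater (n ~ 1.33) this gives
    ~0.08; for tissue exposed to air, ~0.51.  Provided as a standalone
    utility; the transport loop itself assumes matched indices.
    """
    if n_rel <= 0:
        raise ValueError("relative refractive index must be positive")
    r = 0.668 + 0.0636 * n_rel + 0.710 / n_rel - 1.440 / n_rel ** 2
    return float(min(max(r, 0.0), 1.0 - 1e-12))
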