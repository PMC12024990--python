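"""Voxelized porous-tissue geometry: ECM fiber networks, tumor-cell packings,
degradation editing, and regular validation fixtures.

All structures live on a cubic node-centered lattice: node ``(i, j, k)`` sits at
physical position ``(i + 0.5) * spacing`` etc.  Occupancy labels distinguish the
solid phases (collagen/hyaluronic-acid fiber, tumor cell, stromal cell, test
sphere) from interstitial fluid.  Geometry generation is stochastic but fully
reproducible from the GeometrySpec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage


class Label(IntEnum):
    """Node occupancy labels."""

    FLUID = 0
    FIBER = 1
    TUMOR_CELL = 2
    STROMAL_CELL = 3
    SPHERE = 4


SOLID_LABELS = (Label.FIBER, Label.TUMOR_CELL, Label.STROMAL_CELL, Label.SPHERE)


class GeometryError(RuntimeError):
    """Raised when a requested structure cannot be realized."""


@dataclass
class PorousLattice:
    """3-D occupancy grid with physical node spacing.

    Parameters
    ----------
    occupancy
        ``uint8`` array of :class:`Label` values, shape ``(nx, ny, nz)``.
    spacing
        Edge length of one node cell in meters.
    """

    occupancy: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.occupancy = np.ascontiguousarray(self.occupancy, dtype=np.uint8)
        if self.occupancy.ndim != 3 or min(self.occupancy.shape) < 2:
            raise ValueError("occupancy must be 3-D with at least 2 nodes per axis")
        if not self.spacing > 0:
            raise ValueError("spacing must be positive")
        valid = np.isin(self.occupancy, [int(l) for l in Label])
        if not valid.all():
            raise ValueError("occupancy contains labels outside the enumerated set")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape

    @property
    def solid(self) -> np.ndarray:
        """Boolean mask of solid nodes."""
        return self.occupancy != Label.FLUID

    @property
    def porosity(self) -> float:
        """Exact fluid fraction: (# fluid nodes) / (total nodes)."""
        return float(np.count_nonzero(self.occupancy == Label.FLUID) / self.occupancy.size)

    @property
    def extent(self) -> np.ndarray:
        """Physical domain edge lengths (m)."""
        return np.asarray(self.shape) * self.spacing

    def copy(self) -> "PorousLattice":
        return PorousLattice(self.occupancy.copy(), self.spacing)

    def wall_gap(self, particle_radius: float = 0.0) -> np.ndarray:
        """Distance (m) from each node center to the nearest solid voxel face,
        minus ``particle_radius``: the surface-to-surface gap seen by a particle
        of that radius sitting at the node.  Negative values mean the particle
        would overlap the wall; solid nodes get ``-inf``."""
        fluid = ~self.solid
        if fluid.all():
            return np.full(self.shape, np.inf)
        dist = ndimage.distance_transform_edt(fluid, sampling=self.spacing)
        gap = dist - 0.5 * self.spacing - particle_radius
        gap[~fluid] = -np.inf
        return gap


@dataclass
class GeometrySpec:
    """Parameters for stochastic geometry generation.

    Lengths in meters; fractions dimensionless.  ``domain_kind`` selects the
    structure family: random fiber network (``ecm``), cell packing (``tumor``)
    or a regular sphere array (``sphere_array``).
    """

    domain_kind: str = "ecm"
    shape: tuple[int, int, int] = (100, 100, 100)
    spacing: float = 50e-9
    target_porosity: float | None = 0.95
    cell_volume_fraction: float | None = None
    fiber_diameter: float = 100e-9
    fiber_length: float = 70e-6
    stromal_diameter: float = 10e-6
    tumor_semi_axes: tuple[float, float, float] = (7.5e-6, 5e-6, 5e-6)
    tumor_to_stromal_ratio: float = 4.0
    n_degradation_points: int = 0
    degradation_segment_length: float = 200e-9
    porosity_tolerance: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_kind not in ("ecm", "tumor", "sphere_array"):
            raise ValueError(f"unknown domain_kind {self.domain_kind!r}")
        for name in ("spacing", "fiber_diameter", "fiber_length", "stromal_diameter"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.target_porosity is not None and not 0 < self.target_porosity <= 1:
            raise ValueError("target_porosity must lie in (0, 1]")
        if self.cell_volume_fraction is not None and not 0 <= self.cell_volume_fraction < 1:
            raise ValueError("cell_volume_fraction must lie in [0, 1)")
        if not self.tumor_to_stromal_ratio > 0:
            raise ValueError("tumor_to_stromal_ratio must be positive")


# ---------------------------------------------------------------------------
# voxelization helpers


def _node_coords(shape: tuple[int, int, int], spacing: float) -> tuple[np.ndarray, ...]:
    return tuple((np.arange(n) + 0.5) * spacing for n in shape)


def _paint_rod(
    occ: np.ndarray,
    spacing: float,
    start: np.ndarray,
    direction: np.ndarray,
    length: float,
    radius: float,
    label: int,
) -> int:
    """Paint a straight cylinder (periodic wrap) onto ``occ``; returns the
    number of newly solid nodes.  The rod axis is sampled densely and nodes
    within ``radius`` of any sample point are claimed, which matches the exact
    cylinder to well under one voxel."""
    shape = np.asarray(occ.shape)
    ext = shape * spacing
    step = 0.25 * spacing
    n_s = max(2, int(np.ceil(length / step)) + 1)
    t = np.linspace(0.0, length, n_s)
    pts = start[None, :] + t[:, None] * direction[None, :]

    r_vox = int(np.ceil(radius / spacing + 0.5))
    offs = np.arange(-r_vox, r_vox + 1)
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)

    base = np.floor(pts / spacing - 0.5).astype(np.int64)
    # candidate nodes = sample's nearest node + neighborhood cube
    cand = base[:, None, :] + offsets[None, :, :]
    centers = (cand + 0.5) * spacing
    d2 = ((centers - pts[:, None, :]) ** 2).sum(axis=2)
    sel = d2 <= radius * radius
    idx = cand[sel] % shape
    before = int(np.count_nonzero(occ))
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = label
    return int(np.count_nonzero(occ)) - before


def _ellipsoid_mask_indices(
    shape: np.ndarray,
    spacing: float,
    center: np.ndarray,
    semi_axes: np.ndarray,
    rot: np.ndarray | None,
) -> np.ndarray:
    """Indices (periodic) of nodes inside an ellipsoid; ``rot`` maps body to
    lab frame (columns = body axes)."""
    r_max = float(np.max(semi_axes))
    lo = np.floor((center - r_max) / spacing - 0.5).astype(np.int64)
    hi = np.ceil((center + r_max) / spacing - 0.5).astype(np.int64)
    axes = [np.arange(lo[a], hi[a] + 1) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    cand = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    rel = (cand + 0.5) * spacing - center
    if rot is not None:
        rel = rel @ rot  # lab -> body frame
    inside = ((rel / semi_axes) ** 2).sum(axis=1) <= 1.0
    return cand[inside] % shape


# ---------------------------------------------------------------------------
# generators


def generate_ecm(spec: GeometrySpec) -> PorousLattice:
    """Generate a random straight-fiber network at a target porosity.

    Fibers are rigid rods of ``fiber_diameter`` and ``fiber_length`` with
    uniformly random positions and orientations, wrapped periodically.  Rods
    may interpenetrate (fiber networks physically do).  Rods are added until
    the realized porosity is within ``porosity_tolerance`` of the target; the
    final rod is shortened as needed so the tolerance is attainable even when
    one full fiber changes the porosity by more than the tolerance.
    """
    if spec.domain_kind != "ecm":
        raise ValueError("spec.domain_kind must be 'ecm'")
    if spec.target_porosity is None:
        raise ValueError("target_porosity is required for ECM generation")
    if spec.fiber_diameter < spec.spacing:
        raise GeometryError(
            f"fiber diameter {spec.fiber_diameter:g} m is below the lattice "
            f"spacing {spec.spacing:g} m and cannot be resolved"
        )
    rng = np.random.default_rng(spec.seed)
    occ = np.zeros(spec.shape, dtype=np.uint8)
    ntot = occ.size
    target = spec.target_porosity
    tol = spec.porosity_tolerance
    radius = 0.5 * spec.fiber_diameter
    ext = np.asarray(spec.shape) * spec.spacing

    def porosity() -> float:
        return 1.0 - np.count_nonzero(occ) / ntot

    # solid nodes claimed per meter of rod: analytic upper bound (overlaps with
    # existing fibers only reduce the real gain), so trimming never overshoots
    voxels_per_len = np.pi * (radius / spec.spacing + 0.5) ** 2 / spec.spacing
    max_fibers = 100_000
    for _ in range(max_fibers):
        p = porosity()
        if p - target <= tol:
            break
        deficit_nodes = (p - target) * ntot
        length = spec.fiber_length
        # shorten the rod if a full fiber would overshoot past the band
        est_full = voxels_per_len * length
        if est_full > deficit_nodes + tol * ntot:
            length = max(spec.fiber_diameter, deficit_nodes / voxels_per_len)
        start = rng.uniform(0.0, 1.0, 3) * ext
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        _paint_rod(occ, spec.spacing, start, direction, length, radius, Label.FIBER)
    achieved = porosity()
    if abs(achieved - target) > tol:
        raise GeometryError(
            f"could not reach porosity {target:.4f} +/- {tol:.4f}; achieved {achieved:.4f}"
        )
    return PorousLattice(occ, spec.spacing)


def _fcc_sites(ext: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Centers of an FCC arrangement with (possibly anisotropic) cubic unit
    cell ``cell``, tiled to fill the periodic box ``ext``."""
    n = np.maximum(1, np.round(ext / cell).astype(int))
    a = ext / n  # commensurate adjusted cell
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
    )
    ii, jj, kk = np.meshgrid(*(np.arange(m) for m in n), indexing="ij")
    corners = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    sites = (corners[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    return sites + 0.25 * a  # keep away from exact box edges


def generate_tumor(spec: GeometrySpec) -> PorousLattice:
    """Pack ellipsoidal tumor cells and spherical stromal cells to a target
    cell volume fraction without overlap.

    Tumor:stromal counts follow the nearest-integer split of the configured
    ratio (default 4:1).  Up to a fraction of ~0.35 the cells are placed by
    random sequential addition with random ellipsoid orientations; above that
    (random addition jams near 0.38) cells are placed on a jittered
    face-centered arrangement, affinely stretched along x so the aligned
    ellipsoids remain overlap-free at any attainable density.
    """
    if spec.domain_kind != "tumor":
        raise ValueError("spec.domain_kind must be 'tumor'")
    if spec.cell_volume_fraction is None:
        raise ValueError("cell_volume_fraction is required for tumor generation")
    rng = np.random.default_rng(spec.seed)
    occ = np.zeros(spec.shape, dtype=np.uint8)
    shape = np.asarray(spec.shape)
    ntot = occ.size
    target = spec.cell_volume_fraction
    if target == 0:
        return PorousLattice(occ, spec.spacing)
    ext = shape * spec.spacing
    semi = np.asarray(spec.tumor_semi_axes)
    r_s = 0.5 * spec.stromal_diameter
    ratio = spec.tumor_to_stromal_ratio

    def solid_fraction() -> float:
        return np.count_nonzero(occ) / ntot

    def cell_plan(n: int) -> np.ndarray:
        """Label sequence (True = tumor) realizing the nearest-integer split."""
        n_t = int(round(n * ratio / (ratio + 1.0)))
        kinds = np.zeros(n, dtype=bool)
        kinds[:n_t] = True
        rng.shuffle(kinds)
        return kinds

    placed_masks: list[np.ndarray] = []

    def try_place(center: np.ndarray, is_tumor: bool, rot: np.ndarray | None) -> bool:
        if is_tumor:
            idx = _ellipsoid_mask_indices(shape, spec.spacing, center, semi, rot)
            label = Label.TUMOR_CELL
        else:
            idx = _ellipsoid_mask_indices(
                shape, spec.spacing, center, np.array([r_s, r_s, r_s]), None
            )
            label = Label.STROMAL_CELL
        if idx.size == 0:
            return False
        if occ[idx[:, 0], idx[:, 1], idx[:, 2]].any():
            return False
        occ[idx[:, 0], idx[:, 1], idx[:, 2]] = label
        return True

    if target <= 0.35:
        # random sequential addition, random orientations
        mean_vol = (
            ratio * (4 / 3) * np.pi * semi.prod() + (4 / 3) * np.pi * r_s**3
        ) / (ratio + 1.0)
        n_est = int(np.ceil(target * ext.prod() / mean_vol * 1.5)) + 8
        kinds = cell_plan(n_est)
        attempts_per_cell = 200
        i = 0
        while solid_fraction() < target and i < n_est:
            ok = False
            for _ in range(attempts_per_cell):
                center = rng.uniform(0.0, 1.0, 3) * ext
                rot = _random_rotation(rng) if kinds[i] else None
                if try_place(center, kinds[i], rot):
                    ok = True
                    break
            if not ok:
                raise GeometryError(
                    f"cell packing stalled at fraction {solid_fraction():.4f} "
                    f"(target {target:.4f})"
                )
            i += 1
    else:
        # dense mode: x-stretched FCC of virtual spheres of diameter d_s(=10 um);
        # the affine image of a non-overlapping sphere packing keeps aligned
        # ellipsoids (and the inscribed stromal spheres) non-overlapping.
        stretch = np.array([semi[0] / r_s, semi[1] / r_s, semi[2] / r_s])
        mean_vol = (
            ratio * (4 / 3) * np.pi * semi.prod() + (4 / 3) * np.pi * r_s**3
        ) / (ratio + 1.0)
        site_vol_needed = mean_vol / target
        # virtual (unstretched) unit cell: 4 sites per cell
        cell_virtual = (4 * site_vol_needed / stretch.prod()) ** (1 / 3)
        nn_virtual = cell_virtual / np.sqrt(2.0)
        if nn_virtual < 2 * r_s:
            raise GeometryError(
                f"cell volume fraction {target:.3f} exceeds the attainable "
                f"packing for these cell shapes"
            )
        jitter = 0.45 * (nn_virtual - 2 * r_s)
        sites_v = _fcc_sites(ext / stretch, np.full(3, cell_virtual))
        sites_v = sites_v + rng.uniform(-jitter, jitter, sites_v.shape)
        sites = sites_v * stretch
        order = rng.permutation(len(sites))
        kinds = cell_plan(len(sites))
        for n_placed, s in enumerate(order):
            if solid_fraction() >= target:
                break
            if not try_place(sites[s] % ext, kinds[n_placed], None):
                # voxel-rounding collision: retry without jitter on this site
                base = (_fcc_sites(ext / stretch, np.full(3, cell_virtual))[s] * stretch) % ext
                try_place(base, kinds[n_placed], None)
        if solid_fraction() < target - 0.01:
            raise GeometryError(
                f"cell packing stalled at fraction {solid_fraction():.4f} "
                f"(target {target:.4f})"
            )
    return PorousLattice(occ, spec.spacing)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-random rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def apply_degradation(
    lattice: PorousLattice,
    n_points: int,
    segment_length: float = 200e-9,
    seed: int = 0,
) -> PorousLattice:
    """Convert ``n_points`` randomly chosen fiber segments to fluid.

    Each degradation point removes all fiber nodes inside a ball of diameter
    ``segment_length`` centered on a randomly chosen fiber node, i.e. a fiber
    stretch of that extent along the local axis.  Porosity is non-decreasing;
    ``n_points = 0`` returns an identical copy.
    """
    if n_points < 0:
        raise ValueError("n_points must be non-negative")
    out = lattice.copy()
    if n_points == 0:
        return out
    occ = out.occupancy
    fiber_idx = np.argwhere(occ == Label.FIBER)
    if len(fiber_idx) == 0:
        raise GeometryError("lattice contains no fiber nodes to degrade")
    if n_points > len(fiber_idx):
        raise GeometryError(
            f"requested {n_points} degradation points but only "
            f"{len(fiber_idx)} distinct fiber loci exist"
        )
    rng = np.random.default_rng(seed)
    loci = fiber_idx[rng.choice(len(fiber_idx), size=n_points, replace=False)]
    shape = np.asarray(occ.shape)
    r = 0.5 * segment_length
    r_vox = int(np.ceil(r / lattice.spacing + 0.5))
    offs = np.arange(-r_vox, r_vox + 1)
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    ball = offsets[(offsets**2).sum(axis=1) * lattice.spacing**2 <= r * r]
    for locus in loci:
        idx = (locus[None, :] + ball) % shape
        sel = occ[idx[:, 0], idx[:, 1], idx[:, 2]] == Label.FIBER
        hit = idx[sel]
        occ[hit[:, 0], hit[:, 1], hit[:, 2]] = Label.FLUID
    return out


def generate_sphere_array(
    sphere_diameter: float,
    pitch: float,
    shape: tuple[int, int, int] = (40, 40, 40),
) -> PorousLattice:
    """Simple-cubic array of identical spheres (validation fixture).

    The lattice resolves one cubic unit cell of edge ``pitch`` per
    ``shape[0]`` nodes along each axis (``spacing = pitch / shape[0]``), with
    the sphere at the cell center; under periodic boundaries this tiles to the
    infinite simple-cubic array.  Voxelized porosity converges to
    ``1 - (pi/6)(d/pitch)^3`` as the resolution grows.
    """
    if sphere_diameter < 0 or pitch <= 0:
        raise ValueError("diameter must be >= 0 and pitch positive")
    if sphere_diameter >= pitch:
        raise ValueError("sphere diameter must be smaller than the pitch")
    shape_arr = np.asarray(shape)
    spacing = pitch / shape_arr[0]
    occ = np.zeros(shape, dtype=np.uint8)
    if sphere_diameter == 0:
        return PorousLattice(occ, spacing)
    coords = _node_coords(shape, spacing)
    r = 0.5 * sphere_diameter
    # periodic distance of each node to the nearest sphere center
    # (centers at (n + 1/2) * pitch on every axis)
    rel = [np.abs(((c - 0.5 * pitch) % pitch + 0.5 * pitch) % pitch - 0.5 * pitch) for c in coords]
    dx2 = (rel[0] ** 2)[:, None, None]
    dy2 = (rel[1] ** 2)[None, :, None]
    dz2 = (rel[2] ** 2)[None, None, :]
    inside = dx2 + dy2 + dz2 <= r * r
    occ[inside] = Label.SPHERE
    return PorousLattice(occ, spacing)


def measure_connectivity(lattice: PorousLattice) -> float:
    """Fraction of fluid nodes belonging to the largest face-connected fluid
    component (deterministic flood fill)."""
    fluid = ~lattice.solid
    n_fluid = int(np.count_nonzero(fluid))
    if n_fluid == 0:
        raise GeometryError("lattice has no fluid nodes")
    structure = ndimage.generate_binary_structure(3, 1)
    labels, n = ndimage.label(fluid, structure=structure)
    if n == 0:
        raise GeometryError("lattice has no fluid nodes")
    counts = np.bincount(labels.ravel())[1:]
    return float(counts.max() / n_fluid)
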