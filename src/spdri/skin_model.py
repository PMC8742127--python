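"""Voxelized seven-layer skin model with capillary loops and a vascular plexus.

The simulation volume is a labelled voxel grid: seven horizontal skin layers
stacked along +z (z = 0 is the illuminated surface) with blood-filled vessels
burned in on top.  Each capillary loop is a hairpin: two vertical limb
cylinders descending from a turning depth down to the superficial vascular
plexus, joined by a horizontal connector at the turning depth.  The plexus legs
are horizontal cylinders running across the full y extent.

Coordinates follow the voxel convention of voxelized Monte-Carlo engines:
voxel ``i`` covers the interval ``[i, i+1)`` so its centre sits at ``i + 0.5``.
Vessel axis coordinates are therefore voxel-boundary positions; an even vessel
diameter of ``D`` voxels labels exactly ``D`` voxel centres across.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .optics import OpticalProperties

LAYER_NAMES: tuple[str, ...] = (
    "stratum_corneum",
    "epidermis",
    "papillary_dermis",
    "upper_blood_net_dermis",
    "reticular_dermis",
    "deep_blood_net_dermis",
    "subcutaneous_tissue",
)

#: label used for every blood-filled voxel (vessels override the layer label)
BLOOD_LABEL = len(LAYER_NAMES)

MEDIA_NAMES: tuple[str, ...] = LAYER_NAMES + ("blood",)


class GeometryError(ValueError):
    """Raised when a vessel lies outside the volume or two loops collide."""


@dataclass(frozen=True)
class SkinLayer:
    """One horizontal skin layer: a name, a thickness and optical properties."""

    name: str
    thickness_um: float
    props: OpticalProperties

    def __post_init__(self) -> None:
        if self.thickness_um <= 0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness_um}")


@dataclass(frozen=True)
class VesselElement:
    """A blood vessel, either a capillary loop or one plexus leg.

    ``x_range``/``y_range`` hold the two lateral anchor coordinates (voxel
    units).  For a loop these are the positions of its two vertical limbs and
    ``z_range`` is (turning depth, plexus depth); a loop with coincident
    anchors degenerates to a single vertical cylinder.  For a plexus leg the
    anchors are the two ends of its horizontal axis and ``z_range`` collapses
    to the axis depth.
    """

    kind: str  # "capillary_loop" | "plexus_leg"
    x_range: tuple[float, float]
    y_range: tuple[float, float]
    z_range: tuple[float, float]
    diameter_um: float

    def __post_init__(self) -> None:
        if self.kind not in ("capillary_loop", "plexus_leg"):
            raise ValueError(f"unknown vessel kind {self.kind!r}")
        if self.diameter_um < 0:
            raise ValueError("vessel diameter must be >= 0")

    def axis_segments(self, voxel_size_um: float) -> list[tuple[np.ndarray, np.ndarray]]:
        """Axis segments (p0, p1) in voxel units describing this vessel."""
        (x1, x2), (y1, y2), (z1, z2) = self.x_range, self.y_range, self.z_range
        if self.kind == "plexus_leg":
            zc = 0.5 * (z1 + z2)
            return [(np.array([x1, y1, zc]), np.array([x2, y2, zc]))]
        segs = [
            (np.array([x1, y1, z1]), np.array([x1, y1, z2])),  # limb A
        ]
        if (x1, y1) != (x2, y2):
            segs.append((np.array([x2, y2, z1]), np.array([x2, y2, z2])))  # limb B
            segs.append((np.array([x1, y1, z1]), np.array([x2, y2, z1])))  # top connector
        return segs

    def radius_vox(self, voxel_size_um: float) -> float:
        return self.diameter_um / (2.0 * voxel_size_um)


@dataclass(frozen=True)
class GeometryConfig:
    """Static geometry of one simulation volume (all coordinates in voxels)."""

    dims: tuple[int, int, int]
    voxel_size_um: float
    vessels: tuple[VesselElement, ...]
    source_positions: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("volume dims must be positive")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")


@dataclass
class TissueVolume:
    """Labelled voxel grid plus the media table mapping label -> properties."""

    labels: np.ndarray  # uint8, shape (nx, ny, nz)
    voxel_size_um: float
    media: tuple[OpticalProperties, ...]  # indexed by label, len == 8
    media_names: tuple[str, ...] = MEDIA_NAMES
    geometry: GeometryConfig | None = None
    layer_boundaries_vox: np.ndarray | None = None  # z boundaries incl. 0 and nz

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        if present.max(initial=0) >= len(self.media):
            raise ValueError("label present without a media entry")

    @property
    def dims(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    def blood_mask(self) -> np.ndarray:
        return self.labels == BLOOD_LABEL

    def blood_volume_fraction(self) -> float:
        return float(np.count_nonzero(self.labels == BLOOD_LABEL)) / self.labels.size

    def media_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-label arrays (mu_a, mu_s, g, n) for the transport kernel."""
        mua = np.array([m.mu_a for m in self.media])
        mus = np.array([m.mu_s for m in self.media])
        g = np.array([m.g for m in self.media])
        n = np.array([m.n for m in self.media])
        return mua, mus, g, n

    def to_tiff(self, path) -> None:
        """Write the label stack as a multi-page TIFF (one page per z plane)."""
        import tifffile

        tifffile.imwrite(path, np.ascontiguousarray(np.moveaxis(self.labels, 2, 0)))


def _paint_capsule(labels: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                   radius: float, value: int,
                   collision_labels: Sequence[int] = ()) -> int:
    """Label voxels whose centre lies inside the finite cylinder p0 -> p1.

    The cylinder has flat ends (projection parameter clamped to [0, 1] is
    rejected, not clamped), so a straight vessel of length L voxels and radius
    r labels approximately pi*r^2*L voxel centres.  Returns the number of
    voxels painted.  Raises ``GeometryError`` when a voxel carrying one of
    ``collision_labels`` would be overwritten (loop/loop overlap detection).
    """
    if radius <= 0:
        return 0
    nx, ny, nz = labels.shape
    lo = np.floor(np.minimum(p0, p1) - radius - 1).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + radius + 1).astype(int)
    if np.any(hi < 0) or lo[0] >= nx or lo[1] >= ny or lo[2] >= nz:
        raise GeometryError(f"vessel segment {p0}->{p1} lies outside the volume")
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, [nx, ny, nz])
    xs = np.arange(lo[0], hi[0]) + 0.5
    ys = np.arange(lo[1], hi[1]) + 0.5
    zs = np.arange(lo[2], hi[2]) + 0.5
    cx, cy, cz = np.meshgrid(xs, ys, zs, indexing="ij", sparse=True)
    v = p1 - p0
    L2 = float(v @ v)
    if L2 == 0.0:  # degenerate: a sphere of voxel centres
        d2 = (cx - p0[0]) ** 2 + (cy - p0[1]) ** 2 + (cz - p0[2]) ** 2
        inside = d2 < radius**2
    else:
        t = ((cx - p0[0]) * v[0] + (cy - p0[1]) * v[1] + (cz - p0[2]) * v[2]) / L2
        px = p0[0] + t * v[0]
        py = p0[1] + t * v[1]
        pz = p0[2] + t * v[2]
        d2 = (cx - px) ** 2 + (cy - py) ** 2 + (cz - pz) ** 2
        inside = (t >= 0.0) & (t <= 1.0) & (d2 < radius**2)
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if collision_labels:
        for cl in collision_labels:
            if np.any(inside & (sub == cl)):
                raise GeometryError("overlapping capillary loops")
    sub[inside] = value
    return int(np.count_nonzero(inside))


def _check_vessel_bounds(vessel: VesselElement, dims: tuple[int, int, int],
                         voxel_size_um: float) -> None:
    r = vessel.radius_vox(voxel_size_um)
    for p0, p1 in vessel.axis_segments(voxel_size_um):
        v = p1 - p0
        norm = np.linalg.norm(v)
        # the radius extends only perpendicular to the axis
        expand = r * (np.sqrt(np.clip(1.0 - (v / norm) ** 2, 0.0, 1.0))
                      if norm > 0 else np.ones(3))
        lo = np.minimum(p0, p1) - expand
        hi = np.maximum(p0, p1) + expand
        if np.any(lo < -1e-9) or np.any(hi > np.array(dims) + 1e-9):
            raise GeometryError(
                f"{vessel.kind} at x={vessel.x_range}, y={vessel.y_range} "
                f"extends outside the volume {dims}"
            )


def _check_loop_overlap(vessels: Sequence[VesselElement], voxel_size_um: float) -> None:
    """Pairwise lateral-distance check between limbs of distinct loops."""
    loops = [v for v in vessels if v.kind == "capillary_loop"]
    for i in range(len(loops)):
        for j in range(i + 1, len(loops)):
            a, b = loops[i], loops[j]
            ra = a.radius_vox(voxel_size_um)
            rb = b.radius_vox(voxel_size_um)
            pts_a = {(a.x_range[0], a.y_range[0]), (a.x_range[1], a.y_range[1])}
            pts_b = {(b.x_range[0], b.y_range[0]), (b.x_range[1], b.y_range[1])}
            for pa in pts_a:
                for pb in pts_b:
                    d = np.hypot(pa[0] - pb[0], pa[1] - pb[1])
                    if d < ra + rb:
                        raise GeometryError(
                            f"capillary loops {i} and {j} overlap (limb distance "
                            f"{d:.2f} voxels < {ra + rb:.2f})"
                        )


def build_tissue_volume(geometry: GeometryConfig,
                        layers: Sequence[SkinLayer],
                        blood_props: OpticalProperties) -> TissueVolume:
    """Build the labelled voxel volume: layer slabs first, vessels burned in.

    Layer boundaries are planes of constant z; the last layer is trimmed to
    the volume depth.  Every voxel whose centre lies within a vessel cylinder
    is relabelled as blood.  Raises :class:`GeometryError` for vessels outside
    the bounds or for overlapping capillary loops.
    """
    if len(layers) != len(LAYER_NAMES):
        raise ValueError(f"expected {len(LAYER_NAMES)} layers, got {len(layers)}")
    nx, ny, nz = geometry.dims
    vs = geometry.voxel_size_um
    thick_vox = np.array([l.thickness_um for l in layers]) / vs
    if thick_vox.sum() < nz:
        raise ValueError(
            f"layer thicknesses sum to {thick_vox.sum():.0f} voxels "
            f"but the volume is {nz} voxels deep"
        )
    bounds = np.concatenate([[0.0], np.cumsum(thick_vox)])
    bounds = np.clip(bounds, 0, nz)
    bounds[-1] = nz  # trim the deepest layer

    for v in geometry.vessels:
        _check_vessel_bounds(v, geometry.dims, vs)
    _check_loop_overlap(geometry.vessels, vs)

    labels = np.empty((nx, ny, nz), dtype=np.uint8)
    z_centers = np.arange(nz) + 0.5
    layer_of_z = np.searchsorted(bounds, z_centers, side="right") - 1
    layer_of_z = np.clip(layer_of_z, 0, len(layers) - 1).astype(np.uint8)
    labels[:, :, :] = layer_of_z[np.newaxis, np.newaxis, :]

    loop_tmp_labels: list[int] = []
    # Loops are painted with temporary distinct labels so voxel-level overlap
    # between *different* loops is caught; afterwards all collapse to blood.
    tmp = labels.copy() if any(v.kind == "capillary_loop" for v in geometry.vessels) else labels
    next_tmp = BLOOD_LABEL + 1
    for v in geometry.vessels:
        if v.kind != "capillary_loop":
            continue
        r = v.radius_vox(vs)
        for p0, p1 in v.axis_segments(vs):
            _paint_capsule(tmp, p0, p1, r, next_tmp,
                           collision_labels=[l for l in loop_tmp_labels])
        loop_tmp_labels.append(next_tmp)
        next_tmp += 1
    if tmp is not labels:
        labels[tmp > BLOOD_LABEL] = BLOOD_LABEL
    for v in geometry.vessels:
        if v.kind != "plexus_leg":
            continue
        r = v.radius_vox(vs)
        for p0, p1 in v.axis_segments(vs):
            _paint_capsule(labels, p0, p1, r, BLOOD_LABEL)

    media = tuple(l.props for l in layers) + (blood_props,)
    return TissueVolume(labels=labels, voxel_size_um=vs, media=media,
                        geometry=geometry, layer_boundaries_vox=bounds)


def build_shelled_volume(geometries: Sequence[tuple[float, GeometryConfig]],
                         layers: Sequence[SkinLayer],
                         blood_props: OpticalProperties,
                         shell_props: OpticalProperties) -> TissueVolume:
    """Volume whose capillary loops are labelled as nested diameter shells.

    ``geometries`` maps each capillary diameter to its geometry (identical
    apart from the loop diameter).  Loops are painted from the largest
    diameter inward, so each loop voxel's label records the *smallest*
    diameter whose cylinder contains it: label ``BLOOD_LABEL + 1 + i`` for
    the i-th diameter in ascending order.  The plexus keeps the plain blood
    label.

    The shells share one set of transport properties (``shell_props``,
    typically the surrounding dermis: at 424 nm the optical contrast of a
    capillary is overwhelmingly absorptive), so a single detected photon set
    can be re-rendered for every diameter by assigning blood absorption to
    the shells inside the diameter and dermis absorption to the rest --
    an absorption-perturbation evaluation with fully correlated photon
    noise across diameters.  Use :func:`shell_mu_a_map` to build the
    per-diameter absorption maps.
    """
    diams = sorted(d for d, _ in geometries)
    if len(set(diams)) != len(diams):
        raise ValueError("duplicate diameters")
    by_d = dict(geometries)
    base_geo = by_d[diams[-1]]
    plexus_only = GeometryConfig(
        dims=base_geo.dims, voxel_size_um=base_geo.voxel_size_um,
        vessels=tuple(v for v in base_geo.vessels if v.kind == "plexus_leg"),
        source_positions=base_geo.source_positions,
    )
    volume = build_tissue_volume(plexus_only, layers, blood_props)
    vs = base_geo.voxel_size_um
    for i, d in list(enumerate(diams))[::-1]:
        geo = by_d[d]
        label = BLOOD_LABEL + 1 + i
        for v in geo.vessels:
            if v.kind != "capillary_loop":
                continue
            r = v.radius_vox(vs)
            for p0, p1 in v.axis_segments(vs):
                _paint_capsule(volume.labels, p0, p1, r, label)
    volume.media = tuple(l.props for l in layers) + (blood_props,) + \
        tuple(shell_props for _ in diams)
    volume.media_names = MEDIA_NAMES + tuple(
        f"capillary_shell_{d:g}um" for d in diams)
    volume.geometry = base_geo
    return volume


def shell_mu_a_map(volume: TissueVolume, diameter_um: float,
                   blood_mu_a: float, shell_background_mu_a: float,
                   base_mu_a: np.ndarray | None = None) -> np.ndarray:
    """Absorption map rendering one capillary diameter of a shelled volume.

    Shells whose nominal diameter is <= ``diameter_um`` absorb like blood;
    larger shells absorb like the surrounding dermis.
    """
    if base_mu_a is None:
        base_mu_a = np.array([m.mu_a for m in volume.media])
    mua = np.asarray(base_mu_a, dtype=float).copy()
    for i, name in enumerate(volume.media_names):
        if not name.startswith("capillary_shell_"):
            continue
        d = float(name[len("capillary_shell_"):-2])
        mua[i] = blood_mu_a if d <= diameter_um + 1e-9 else shell_background_mu_a
    return mua


def measure_plexus_cross_section(volume: TissueVolume) -> float:
    """Maximal cross-sectional extent (um) of plexus-labelled voxels.

    Takes an (x, z) slice through each plexus leg at a y position well away
    from every capillary loop, isolates the blood voxels belonging to that
    leg, and returns the larger of the x- and z-extents times the voxel size.
    """
    geo = volume.geometry
    if geo is None:
        raise ValueError("volume carries no geometry metadata")
    legs = [v for v in geo.vessels if v.kind == "plexus_leg"]
    if not legs:
        raise ValueError("geometry contains no plexus legs")
    loops = [v for v in geo.vessels if v.kind == "capillary_loop"]
    vs = volume.voxel_size_um

    def clear_of_loops(y: float) -> bool:
        for lp in loops:
            r = lp.radius_vox(vs) + 2
            if min(lp.y_range) - r <= y <= max(lp.y_range) + r:
                return False
        return True

    best = 0.0
    for leg in legs:
        y_lo, y_hi = sorted(leg.y_range)
        iy = next(
            int(y) for y in np.arange(np.ceil(y_lo) + 1, y_hi - 1)
            if clear_of_loops(y + 0.5)
        )
        r = leg.radius_vox(vs) + 2
        x0 = max(int(min(leg.x_range) - r), 0)
        x1 = min(int(max(leg.x_range) + r) + 1, volume.dims[0])
        sl = volume.labels[x0:x1, iy, :] == BLOOD_LABEL
        xs, zs = np.nonzero(sl)
        if xs.size == 0:
            continue
        extent = max(xs.max() - xs.min() + 1, zs.max() - zs.min() + 1)
        best = max(best, extent * vs)
    return best
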