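"""Voxel Monte-Carlo photon transport with pathlength-resolved detection.

The engine propagates photon packets through a labelled voxel volume:

* free paths are sampled from the scattering coefficient of the current
  medium (dimensionless scattering depth consumed voxel by voxel, so media
  changes along a step are handled exactly);
* scattering angles come from the Henyey-Greenstein phase function with the
  medium's anisotropy ``g``;
* refractive-index mismatches at voxel faces are handled by unpolarized
  Fresnel reflection/transmission with Snell refraction (total internal
  reflection respected);
* absorption is applied continuously in flight, ``exp(-mu_a * l)`` per
  segment, and the per-medium partial pathlengths are recorded so that the
  detected set can be re-weighted with *any* absorption map afterwards
  (Beer-law rendering) without re-running the transport;
* packets below 1% of the launch weight enter Russian roulette (survive with
  probability 1/m, weight times m);
* packets crossing the illuminated ``-z`` face are refracted into the
  external medium and detected when their exit direction falls inside the
  detector's acceptance cone.

The source is a fiber: positions uniform over the core disc, directions
uniform in solid angle inside the cone given by the numerical aperture.
Photons are launched from the external side, so the specular reflection at
the surface is part of the transport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .skin_model import MEDIA_NAMES, TissueVolume

_BIG = 1e30


class EngineError(RuntimeError):
    """Raised when the transport kernel reports non-finite photon states."""


@dataclass(frozen=True)
class SourceSpec:
    """Illumination fiber on the -z face pointing in +z.

    ``center`` is in voxel units of the target volume; the core diameter and
    numerical aperture default to the study values (20 um, 0.35).
    """

    center: tuple[float, float]
    core_diameter_um: float = 20.0
    numerical_aperture: float = 0.35

    def __post_init__(self) -> None:
        if self.core_diameter_um < 0:
            raise ValueError("core diameter must be >= 0")
        if not 0 <= self.numerical_aperture:
            raise ValueError("numerical aperture must be >= 0")


@dataclass(frozen=True)
class DetectorSpec:
    """Fiber-bundle detector covering the whole -z face (NA per fiber 0.25)."""

    numerical_aperture: float = 0.25


@dataclass(frozen=True)
class MCConfig:
    """Run-level transport settings."""

    n_photons: int = 10**6
    roulette_threshold: float = 0.01   # fraction of the launch weight
    roulette_m: float = 10.0           # survival factor
    seed: int = 1
    n_external: float = 1.0            # refractive index outside the volume
    #: side/deep-face handling: "absorb" terminates escaping packets,
    #: "mirror" reflects them, emulating laterally extended tissue in a
    #: reduced-size compute box (the -z detector face is never mirrored)
    boundary: str = "absorb"

    def __post_init__(self) -> None:
        if self.boundary not in ("absorb", "mirror"):
            raise ValueError("boundary must be 'absorb' or 'mirror'")
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0 < self.roulette_threshold < 1:
            raise ValueError("roulette threshold must lie in (0, 1)")
        if self.roulette_m < 2:
            raise ValueError("roulette survival factor must be >= 2")
        if self.n_external < 1:
            raise ValueError("external refractive index must be >= 1")


@dataclass
class DetectedPhotons:
    """Struct-of-arrays record of every detected packet."""

    exit_x: np.ndarray            # int32 pixel index
    exit_y: np.ndarray
    direction: np.ndarray         # (n, 3) exit direction in the external medium
    pathlengths_um: np.ndarray    # (n, n_media) per-medium partial pathlengths
    boost: np.ndarray             # accumulated roulette survival factor
    #: Beer-law weight at the moment of exit under the propagation mu_a
    weight_at_exit: np.ndarray
    photons_launched: int
    grid_shape: tuple[int, int]
    voxel_size_um: float
    media_names: tuple[str, ...]
    tallies: dict[str, float]

    def __len__(self) -> int:
        return int(self.exit_x.shape[0])

    def inflight_weight(self, mu_a_mm: np.ndarray) -> np.ndarray:
        """Beer-law weight of each packet under the given absorption map."""
        mu_a_mm = np.asarray(mu_a_mm, dtype=float)
        if np.any(mu_a_mm < 0):
            raise ValueError("mu_a must be >= 0")
        expo = self.pathlengths_um @ (mu_a_mm / 1000.0)
        return self.boost * np.exp(-expo)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("exit_x", data=self.exit_x)
            f.create_dataset("exit_y", data=self.exit_y)
            f.create_dataset("direction", data=self.direction)
            f.create_dataset("pathlengths_um", data=self.pathlengths_um)
            f.create_dataset("boost", data=self.boost)
            f.create_dataset("weight_at_exit", data=self.weight_at_exit)
            f.attrs["photons_launched"] = self.photons_launched
            f.attrs["grid_shape"] = self.grid_shape
            f.attrs["voxel_size_um"] = self.voxel_size_um
            f.attrs["media_names"] = ",".join(self.media_names)
            for k, v in self.tallies.items():
                f.attrs[f"tally_{k}"] = v

    @classmethod
    def from_hdf5(cls, path) -> "DetectedPhotons":
        import h5py

        with h5py.File(path, "r") as f:
            tallies = {
                k[len("tally_"):]: float(v)
                for k, v in f.attrs.items() if k.startswith("tally_")
            }
            return cls(
                exit_x=f["exit_x"][:],
                exit_y=f["exit_y"][:],
                direction=f["direction"][:],
                pathlengths_um=f["pathlengths_um"][:],
                boost=f["boost"][:],
                weight_at_exit=f["weight_at_exit"][:],
                photons_launched=int(f.attrs["photons_launched"]),
                grid_shape=tuple(f.attrs["grid_shape"]),
                voxel_size_um=float(f.attrs["voxel_size_um"]),
                media_names=tuple(str(f.attrs["media_names"]).split(",")),
                tallies=tallies,
            )


@dataclass
class ReflectanceImage:
    """Accumulated detected weight per (x, y) pixel of the -z face."""

    grid: np.ndarray              # (nx, ny) float64
    photons_launched: int
    mu_a_used: np.ndarray         # per-medium absorption applied at rendering

    def __post_init__(self) -> None:
        if np.any(self.grid < 0):
            raise ValueError("reflectance pixels must be >= 0")


def sample_source_rays(source: SourceSpec, n_external: float, n: int,
                       rng: np.random.Generator | int | None = None,
                       voxel_size_um: float = 1.0,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Sample launch positions (voxel units) and unit directions.

    Positions are uniform on the fiber core disc; directions uniform in solid
    angle within the cone of half-angle ``asin(NA / n_external)`` about +z.
    This mirrors the kernel's launch sampling and exists for diagnostics and
    tests.
    """
    if source.numerical_aperture >= n_external:
        raise ValueError("source NA must be smaller than the external index")
    gen = np.random.default_rng(rng)
    r = (source.core_diameter_um / 2.0 / voxel_size_um) * np.sqrt(gen.random(n))
    phi = 2 * np.pi * gen.random(n)
    pos = np.column_stack([
        source.center[0] + r * np.cos(phi),
        source.center[1] + r * np.sin(phi),
        np.zeros(n),
    ])
    sin_max = source.numerical_aperture / n_external
    cos_max = np.sqrt(1.0 - sin_max**2)
    ct = 1.0 - gen.random(n) * (1.0 - cos_max)
    st = np.sqrt(1.0 - ct**2)
    psi = 2 * np.pi * gen.random(n)
    dirs = np.column_stack([st * np.cos(psi), st * np.sin(psi), ct])
    return pos, dirs


# --------------------------------------------------------------------------
# numba kernel
# --------------------------------------------------------------------------

@njit(cache=True)
def _fresnel_unpolarized(n1, n2, cosi):
    sini2 = 1.0 - cosi * cosi
    if sini2 < 0.0:
        sini2 = 0.0
    ratio = n1 / n2
    sint2 = ratio * ratio * sini2
    if sint2 >= 1.0:
        return 1.0
    cost = np.sqrt(1.0 - sint2)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _scatter_hg(dx, dy, dz, g):
    u = np.random.random()
    if abs(g) < 1e-6:
        ct = 1.0 - 2.0 * u
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    st = np.sqrt(1.0 - ct * ct)
    phi = 2.0 * np.pi * np.random.random()
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(dz) > 0.99999:
        ndx = st * cp
        ndy = st * sp
        ndz = ct if dz > 0.0 else -ct
    else:
        den = np.sqrt(1.0 - dz * dz)
        ndx = st * (dx * dz * cp - dy * sp) / den + dx * ct
        ndy = st * (dy * dz * cp + dx * sp) / den + dy * ct
        ndz = -st * cp * den + dz * ct
    norm = np.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    return ndx / norm, ndy / norm, ndz / norm


@njit(cache=True)
def _run_kernel(labels, mua_vox, mus_vox, g_arr, n_arr, n_ext,
                src_x, src_y, src_radius, sin_src_max, sin_det_max,
                n_photons, thr, m_roulette, seed, mirror,
                out_x, out_y, out_dir, out_path, out_boost, out_weight,
                tallies):
    """Transport n_photons packets; returns the number of detected packets.

    tallies: [0] reflected weight (-z escapes, detected or not),
             [1] transmitted weight (+z), [2] side-escaped weight,
             [3] roulette-killed weight, [4] detected weight,
             [5] non-finite-state error count.
    """
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    nm = mua_vox.shape[0]
    ndet = 0
    cos_max = np.sqrt(1.0 - sin_src_max * sin_src_max)
    L = np.zeros(nm)
    max_events = 50_000_000

    for _ in range(n_photons):
        # --- launch ---------------------------------------------------
        r = src_radius * np.sqrt(np.random.random())
        phi = 2.0 * np.pi * np.random.random()
        x = src_x + r * np.cos(phi)
        y = src_y + r * np.sin(phi)
        z = 0.0
        ct = 1.0 - np.random.random() * (1.0 - cos_max)
        st = np.sqrt(1.0 - ct * ct)
        psi = 2.0 * np.pi * np.random.random()
        dx = st * np.cos(psi)
        dy = st * np.sin(psi)
        dz = ct

        ix = int(np.floor(x))
        iy = int(np.floor(y))
        if ix < 0:
            ix = 0
        elif ix >= nx:
            ix = nx - 1
        if iy < 0:
            iy = 0
        elif iy >= ny:
            iy = ny - 1
        iz = 0

        # --- external -> tissue interface -----------------------------
        med = labels[ix, iy, iz]
        n1 = n_arr[med]
        if np.random.random() < _fresnel_unpolarized(n_ext, n1, dz):
            # specular reflection straight back into the external medium
            tallies[0] += 1.0
            sin_exit = np.sqrt(dx * dx + dy * dy)
            if sin_exit <= sin_det_max:
                out_x[ndet] = ix
                out_y[ndet] = iy
                out_dir[ndet, 0] = dx
                out_dir[ndet, 1] = dy
                out_dir[ndet, 2] = -dz
                for k in range(nm):
                    out_path[ndet, k] = 0.0
                out_boost[ndet] = 1.0
                out_weight[ndet] = 1.0
                tallies[4] += 1.0
                ndet += 1
            continue
        k_refr = n_ext / n1
        dx *= k_refr
        dy *= k_refr
        s2 = dx * dx + dy * dy
        if s2 > 1.0:
            s2 = 1.0
        dz = np.sqrt(1.0 - s2)

        # --- propagate -------------------------------------------------
        for k in range(nm):
            L[k] = 0.0
        A = 0.0            # accumulated absorption exponent
        boost = 1.0        # roulette survival factor
        tau = -np.log(np.random.random())
        alive = True
        events = 0

        while alive:
            events += 1
            if events > max_events:
                tallies[5] += 1.0
                break
            if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
                tallies[5] += 1.0
                break
            med = labels[ix, iy, iz]
            musv = mus_vox[med]

            # distance to the voxel faces
            if dx > 1e-12:
                tx = (ix + 1.0 - x) / dx
            elif dx < -1e-12:
                tx = (ix - x) / dx
            else:
                tx = _BIG
            if dy > 1e-12:
                ty = (iy + 1.0 - y) / dy
            elif dy < -1e-12:
                ty = (iy - y) / dy
            else:
                ty = _BIG
            if dz > 1e-12:
                tz = (iz + 1.0 - z) / dz
            elif dz < -1e-12:
                tz = (iz - z) / dz
            else:
                tz = _BIG
            t = tx
            axis = 0
            if ty < t:
                t = ty
                axis = 1
            if tz < t:
                t = tz
                axis = 2
            if t < 0.0:
                t = 0.0

            if musv > 0.0 and tau < musv * t:
                # scatter inside this voxel
                step = tau / musv
                x += dx * step
                y += dy * step
                z += dz * step
                L[med] += step
                A += mua_vox[med] * step
                dx, dy, dz = _scatter_hg(dx, dy, dz, g_arr[med])
                tau = -np.log(np.random.random())
                w = np.exp(-A) * boost
                if w < thr:
                    if np.random.random() * m_roulette < 1.0:
                        boost *= m_roulette
                    else:
                        tallies[3] += w
                        alive = False
                continue

            # advance to the face
            x += dx * t
            y += dy * t
            z += dz * t
            L[med] += t
            A += mua_vox[med] * t
            tau -= musv * t

            if axis == 0:
                step_dir = 1 if dx > 0.0 else -1
                jx, jy, jz = ix + step_dir, iy, iz
                x = float(ix + 1) if step_dir > 0 else float(ix)
                d_axis = dx
            elif axis == 1:
                step_dir = 1 if dy > 0.0 else -1
                jx, jy, jz = ix, iy + step_dir, iz
                y = float(iy + 1) if step_dir > 0 else float(iy)
                d_axis = dy
            else:
                step_dir = 1 if dz > 0.0 else -1
                jx, jy, jz = ix, iy, iz + step_dir
                z = float(iz + 1) if step_dir > 0 else float(iz)
                d_axis = dz

            if jz < 0:
                # the illuminated face: Fresnel against the external medium
                n1 = n_arr[med]
                cosi = -dz
                if np.random.random() < _fresnel_unpolarized(n1, n_ext, cosi):
                    dz = -dz
                    continue
                w = np.exp(-A) * boost
                tallies[0] += w
                k_refr = n1 / n_ext
                ex = dx * k_refr
                ey = dy * k_refr
                sin_exit = np.sqrt(ex * ex + ey * ey)
                if sin_exit <= sin_det_max:
                    s2 = sin_exit * sin_exit
                    if s2 > 1.0:
                        s2 = 1.0
                    out_x[ndet] = min(max(int(np.floor(x)), 0), nx - 1)
                    out_y[ndet] = min(max(int(np.floor(y)), 0), ny - 1)
                    out_dir[ndet, 0] = ex
                    out_dir[ndet, 1] = ey
                    out_dir[ndet, 2] = -np.sqrt(1.0 - s2)
                    for k in range(nm):
                        out_path[ndet, k] = L[k]
                    out_boost[ndet] = boost
                    out_weight[ndet] = w
                    tallies[4] += w
                    ndet += 1
                alive = False
                continue
            if jz >= nz:
                if mirror:
                    dz = -dz
                    continue
                tallies[1] += np.exp(-A) * boost
                alive = False
                continue
            if jx < 0 or jx >= nx:
                if mirror:
                    dx = -dx
                    continue
                tallies[2] += np.exp(-A) * boost
                alive = False
                continue
            if jy < 0 or jy >= ny:
                if mirror:
                    dy = -dy
                    continue
                tallies[2] += np.exp(-A) * boost
                alive = False
                continue

            med2 = labels[jx, jy, jz]
            n1 = n_arr[med]
            n2 = n_arr[med2]
            if n1 != n2:
                cosi = abs(d_axis)
                if np.random.random() < _fresnel_unpolarized(n1, n2, cosi):
                    # reflect off the face, stay in the current voxel
                    if axis == 0:
                        dx = -dx
                    elif axis == 1:
                        dy = -dy
                    else:
                        dz = -dz
                    continue
                # refract: scale the tangential components
                k_refr = n1 / n2
                if axis == 0:
                    dy *= k_refr
                    dz *= k_refr
                    s2 = dy * dy + dz * dz
                    if s2 > 1.0:
                        s2 = 1.0
                    dx = np.sqrt(1.0 - s2) * (1.0 if d_axis > 0.0 else -1.0)
                elif axis == 1:
                    dx *= k_refr
                    dz *= k_refr
                    s2 = dx * dx + dz * dz
                    if s2 > 1.0:
                        s2 = 1.0
                    dy = np.sqrt(1.0 - s2) * (1.0 if d_axis > 0.0 else -1.0)
                else:
                    dx *= k_refr
                    dy *= k_refr
                    s2 = dx * dx + dy * dy
                    if s2 > 1.0:
                        s2 = 1.0
                    dz = np.sqrt(1.0 - s2) * (1.0 if d_axis > 0.0 else -1.0)
            ix, iy, iz = jx, jy, jz

    return ndet


def simulate(volume: TissueVolume, source: SourceSpec, config: MCConfig,
             detector: DetectorSpec | None = None) -> DetectedPhotons:
    """Run the transport and return the detected-photon record.

    Same seed and configuration give a bit-identical photon stream.
    """
    detector = detector or DetectorSpec()
    if source.numerical_aperture >= config.n_external:
        raise ValueError("source NA must be smaller than the external index")
    mua, mus, g, n = volume.media_arrays()
    vs_mm = volume.voxel_size_um / 1000.0
    mua_vox = np.ascontiguousarray(mua * vs_mm)
    mus_vox = np.ascontiguousarray(mus * vs_mm)
    g = np.ascontiguousarray(g)
    n = np.ascontiguousarray(n)
    nm = len(volume.media)
    nph = int(config.n_photons)

    out_x = np.empty(nph, dtype=np.int32)
    out_y = np.empty(nph, dtype=np.int32)
    out_dir = np.empty((nph, 3))
    out_path = np.empty((nph, nm))
    out_boost = np.empty(nph)
    out_weight = np.empty(nph)
    tallies = np.zeros(6)

    src_radius = source.core_diameter_um / 2.0 / volume.voxel_size_um
    sin_src = source.numerical_aperture / config.n_external
    sin_det = detector.numerical_aperture / config.n_external

    ndet = _run_kernel(
        volume.labels, mua_vox, mus_vox, g, n, config.n_external,
        float(source.center[0]), float(source.center[1]), src_radius,
        sin_src, sin_det, nph, config.roulette_threshold,
        float(config.roulette_m), int(config.seed),
        config.boundary == "mirror",
        out_x, out_y, out_dir, out_path, out_boost, out_weight, tallies,
    )
    if tallies[5] > 0:
        raise EngineError(
            f"{int(tallies[5])} photons reached a non-finite or runaway state"
        )
    nx, ny, _ = volume.dims
    return DetectedPhotons(
        exit_x=out_x[:ndet].copy(),
        exit_y=out_y[:ndet].copy(),
        direction=out_dir[:ndet].copy(),
        pathlengths_um=out_path[:ndet] * volume.voxel_size_um,
        boost=out_boost[:ndet].copy(),
        weight_at_exit=out_weight[:ndet].copy(),
        photons_launched=nph,
        grid_shape=(nx, ny),
        voxel_size_um=volume.voxel_size_um,
        media_names=volume.media_names,
        tallies={
            "reflected": float(tallies[0]),
            "transmitted": float(tallies[1]),
            "side_escaped": float(tallies[2]),
            "roulette_killed": float(tallies[3]),
            "detected": float(tallies[4]),
        },
    )


def render_reflectance(detected: DetectedPhotons,
                       mu_a_mm: np.ndarray | dict[str, float],
                       ) -> ReflectanceImage:
    """Beer-law rendering: accumulate re-weighted packets on the pixel grid.

    ``mu_a_mm`` may be a per-medium array (in the detected set's media order)
    or a name -> mu_a mapping.  Arbitrary absorption maps can be applied to
    the same detected set.
    """
    if isinstance(mu_a_mm, dict):
        missing = [m for m in detected.media_names if m not in mu_a_mm]
        if missing:
            raise ValueError(f"mu_a map missing media: {missing}")
        mu_a_mm = np.array([mu_a_mm[m] for m in detected.media_names])
    w = detected.inflight_weight(mu_a_mm)
    grid = np.zeros(detected.grid_shape)
    np.add.at(grid, (detected.exit_x, detected.exit_y), w)
    return ReflectanceImage(grid=grid,
                            photons_launched=detected.photons_launched,
                            mu_a_used=np.asarray(mu_a_mm, dtype=float))
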