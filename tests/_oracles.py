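"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's transport kernel: the slab Monte
Carlo below is a vectorized free-flight random walk (no voxel traversal),
with its own RNG stream, usable only for homogeneous boxes with matched
refractive indices.
"""

import numpy as np


def slab_diffuse_reflectance(mu_a_mm: float, mu_s_mm: float, g: float,
                             box_um: tuple[float, float, float],
                             source_xy_um: tuple[float, float],
                             n_photons: int, seed: int) -> float:
    """Total -z escape weight fraction of a homogeneous absorbing box.

    Collimated pencil beam entering at ``source_xy_um`` along +z; scattering
    free paths ~ Exp(mu_s), Henyey-Greenstein deflections, continuous Beer
    absorption along every segment, absorbing faces everywhere.
    """
    rng = np.random.default_rng(seed)
    mu_s = mu_s_mm / 1000.0  # per um
    mu_a = mu_a_mm / 1000.0
    lx, ly, lz = box_um
    n = n_photons
    pos = np.zeros((n, 3))
    pos[:, 0] = source_xy_um[0]
    pos[:, 1] = source_xy_um[1]
    d = np.zeros((n, 3))
    d[:, 2] = 1.0
    weight = np.ones(n)
    alive = np.ones(n, dtype=bool)
    reflect = 0.0

    for _ in range(100_000):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        step = -np.log(rng.random(idx.size)) / mu_s
        new = pos[idx] + d[idx] * step[:, None]
        # distance to the box boundary along the current direction
        with np.errstate(divide="ignore"):
            t_lo = (np.array([0.0, 0.0, 0.0]) - pos[idx]) / d[idx]
            t_hi = (np.array([lx, ly, lz]) - pos[idx]) / d[idx]
        t_exit = np.where(d[idx] > 0, t_hi, np.where(d[idx] < 0, t_lo, np.inf))
        t_exit = t_exit.min(axis=1)
        exit_axis = np.argmin(
            np.where(d[idx] > 0, t_hi, np.where(d[idx] < 0, t_lo, np.inf)),
            axis=1,
        )
        escaped = step >= t_exit
        # photons escaping through z = 0 moving downward count as reflected
        esc_idx = idx[escaped]
        w_esc = weight[esc_idx] * np.exp(-mu_a * t_exit[escaped])
        down = (exit_axis[escaped] == 2) & (d[esc_idx, 2] < 0)
        reflect += w_esc[down].sum()
        alive[esc_idx] = False

        stay = idx[~escaped]
        if stay.size:
            weight[stay] *= np.exp(-mu_a * step[~escaped])
            pos[stay] = new[~escaped]
            # kill negligible weight (no roulette needed for an oracle)
            dead = weight[stay] < 1e-6
            alive[stay[dead]] = False
            live = stay[~dead]
            if live.size:
                d[live] = _hg_scatter(d[live], g, rng)
    return reflect / n_photons


def _hg_scatter(dirs: np.ndarray, g: float, rng: np.random.Generator
                ) -> np.ndarray:
    n = dirs.shape[0]
    u = rng.random(n)
    if abs(g) < 1e-6:
        ct = 1.0 - 2.0 * u
    else:
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    ct = np.clip(ct, -1.0, 1.0)
    st = np.sqrt(1.0 - ct * ct)
    phi = 2.0 * np.pi * rng.random(n)
    cp, sp = np.cos(phi), np.sin(phi)
    dx, dy, dz = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    out = np.empty_like(dirs)
    near_pole = np.abs(dz) > 0.99999
    den = np.sqrt(np.clip(1.0 - dz * dz, 1e-12, None))
    out[:, 0] = st * (dx * dz * cp - dy * sp) / den + dx * ct
    out[:, 1] = st * (dy * dz * cp + dx * sp) / den + dy * ct
    out[:, 2] = -st * cp * den + dz * ct
    out[near_pole, 0] = st[near_pole] * cp[near_pole]
    out[near_pole, 1] = st[near_pole] * sp[near_pole]
    out[near_pole, 2] = np.sign(dz[near_pole]) * ct[near_pole]
    norm = np.linalg.norm(out, axis=1, keepdims=True)
    return out / norm


def ols_normal_equations(x: np.ndarray, y: np.ndarray
                         ) -> tuple[float, float]:
    """Closed-form simple-regression slope/intercept via normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return ybar - slope * xbar, slope
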