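"""Shared test utilities: ground-truth labelling, map-level noise, oracles."""

from __future__ import annotations

import numpy as np

from gelfront.phantom import REGIONS, PhantomSpec, RegionParams
from gelfront.relaxometry import ParametricMaps


def uniform_disc_spec(a_s=2.0, a_l=4.0, radius=4.0, grid=(96, 96), centered=True) -> PhantomSpec:
    """A single-material disc (gel everywhere): all regions share one parameter set."""
    params = RegionParams(a_s=a_s, t2s=20.0, a_l=a_l, t2l=150.0, t1=800.0)
    grid_center = ((grid[0] - 1) / 2.0, (grid[1] - 1) / 2.0)
    return PhantomSpec(
        hydration_time=1.0,
        center=grid_center if centered else (grid[0] // 2 + 2.0, grid[1] // 2 - 3.0),
        region_boundaries={
            "core": 0.25 * radius,
            "interface1": 0.5 * radius,
            "interface2": 0.75 * radius,
            "gel": radius,
        },
        region_params={r: params for r in REGIONS},
        interface_profile="constant",
        pixel_size=15.0 / grid[0],
        grid_shape=grid,
    )


def add_map_noise(maps: ParametricMaps, sigma: float, seed: int) -> ParametricMaps:
    """Gaussian perturbation of the amplitude maps (map-level noise model)."""
    rng = np.random.default_rng(seed)
    a_s = np.clip(maps.a_s + rng.normal(0, sigma, maps.a_s.shape), 0, None)
    a_l = np.clip(maps.a_l + rng.normal(0, sigma, maps.a_l.shape), 0, None)
    a_s[~maps.mask] = 0.0
    a_l[~maps.mask] = 0.0
    return ParametricMaps(
        a_s=a_s, t2s=maps.t2s, a_l=a_l, t2l=maps.t2l, t1=maps.t1, a_t=a_s + a_l,
        mask=maps.mask, pixel_size=maps.pixel_size, center=maps.center,
    )


def truth_labels(spec: PhantomSpec, radii: np.ndarray) -> list[str]:
    """Ground-truth region label of each radial bin center."""
    b = spec.region_boundaries
    core_label = "unhydrated" if not spec.region_params["core"].detectable else "minimally_hydrated"
    out = []
    for r in radii:
        if r < b["core"]:
            out.append(core_label)
        elif r < b["interface1"]:
            out.append("interface1")
        elif r < b["interface2"]:
            out.append("interface2")
        else:
            out.append("gel")
    return out


# --- independent exhaustive-search oracles (linear amplitudes solved exactly) ---

def oracle_monoexp(y: np.ndarray, t: np.ndarray, t2_grid: np.ndarray) -> tuple[float, float]:
    """Exhaustive search over T2L with the closed-form optimal amplitude."""
    best = (np.inf, None, None)
    for chunk in np.array_split(t2_grid, max(1, t2_grid.size // 20000)):
        e = np.exp(-t[None, :] / chunk[:, None])
        s_ee = np.sum(e * e, axis=1)
        s_ey = e @ y
        s0 = s_ey / s_ee
        sse = np.sum(y * y) - s0 * s_ey
        i = int(np.argmin(sse))
        if sse[i] < best[0]:
            best = (float(sse[i]), float(s0[i]), float(chunk[i]))
    return best[1], best[2]


def oracle_blip(y: np.ndarray, t: np.ndarray, t2_grid: np.ndarray) -> tuple[float, float, float]:
    """Exhaustive search over T2S with closed-form (A_S, A_L) at each step."""
    e = np.exp(-t[None, :] / t2_grid[:, None])
    n = t.size
    s_e, s_ee = e.sum(axis=1), (e * e).sum(axis=1)
    s_y, s_ey = y.sum(), e @ y
    det = s_ee * n - s_e**2
    a_s = (s_ey * n - s_e * s_y) / det
    a_l = (s_ee * s_y - s_e * s_ey) / det
    sse = np.sum(y * y) - a_s * s_ey - a_l * s_y
    i = int(np.argmin(sse))
    return float(a_s[i]), float(t2_grid[i]), float(a_l[i])
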