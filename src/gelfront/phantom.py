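"""Concentric-layer tablet phantoms and simulated multi-echo acquisitions.

A hydrating HPMC matrix tablet, imaged in a coronal slice, is modelled as a
disc of concentric layers ordered from the center outward:

``core`` (unhydrated at 0.5 h, minimally hydrated / solid-like from 1 h on)
-> ``interface1`` (only the short component; its amplitude rises steeply
toward the water phase) -> ``interface2`` (the "amplitude crossing" layer:
the short amplitude falls while the long component appears and grows)
-> ``gel`` (both components present with spatially constant parameters).

Each layer carries ground-truth relaxometric parameters (A_S, T2S, A_L, T2L,
T1); interface layers interpolate linearly in radius between the adjacent
layers so the total proton density A_T stays flat across the crossing, as
observed in real amplitude profiles.  The dry tablet (9 mm diameter, radius
4.5 mm) swells outward while the inner fronts move inward ~ sqrt(time);
the higher-viscosity grade (HPMC 10000 cP) forms a thicker firm gel layer
than HPMC 400 cP at every hydration time.

Simulated magnitude images add complex Gaussian noise channel-wise and take
the magnitude (Rician statistics), with the default noise scaled so the
background level is ~0.6 a.u. against a fully hydrated signal of ~6 a.u.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .relaxometry import (
    FOV_MM,
    MATRIX_SIZE,
    PIXEL_SIZE_MM,
    AcquisitionSchedule,
    ImageStack,
    ParametricMaps,
)

__all__ = [
    "RegionParams",
    "PhantomSpec",
    "NoiseModel",
    "REGIONS",
    "PRESETS",
    "DEFAULT_NOISE_SIGMA",
    "DRY_TABLET_DIAMETER_MM",
    "build_phantom_spec",
    "render_parameter_maps",
    "simulate_acquisition",
]

REGIONS = ("core", "interface1", "interface2", "gel")

#: Tablet geometry before hydration: 9 mm diameter discs.
DRY_TABLET_DIAMETER_MM = 9.0

#: Background magnitude mean of ~0.6 a.u. => complex channel sigma 0.6/sqrt(pi/2).
DEFAULT_NOISE_SIGMA = 0.6 / float(np.sqrt(np.pi / 2.0))


@dataclass
class RegionParams:
    """Ground-truth relaxometric parameters of one layer.

    Amplitudes in a.u., times in ms.  ``detectable=False`` means the layer
    produces no MR signal at all (the unhydrated core), regardless of the
    stored amplitudes.
    """

    a_s: float
    t2s: float
    a_l: float
    t2l: float
    t1: float
    detectable: bool = True

    def __post_init__(self) -> None:
        if self.a_s < 0 or self.a_l < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.a_s > 0 and self.t2s <= 0:
            raise ValueError("t2s must be positive when a_s > 0")
        if self.a_l > 0 and self.t2l <= 0:
            raise ValueError("t2l must be positive when a_l > 0")
        if (self.a_s > 0 or self.a_l > 0) and self.t1 <= 0:
            raise ValueError("t1 must be positive for detectable signal")
        if self.a_s > 0 and self.a_l > 0 and self.t2s > self.t2l:
            raise ValueError("short T2 must not exceed long T2")

    @property
    def a_t(self) -> float:
        return self.a_s + self.a_l


@dataclass
class NoiseModel:
    """Measurement noise: magnitude of (signal + complex Gaussian).

    ``sigma`` is the standard deviation of each complex channel (a.u.).
    ``kind="gaussian"`` adds real Gaussian noise instead (clipped at zero),
    which is convenient for unit tests.  The same seed reproduces a stack
    bit-identically.
    """

    sigma: float = DEFAULT_NOISE_SIGMA
    kind: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.kind not in ("rician", "gaussian"):
            raise ValueError("noise kind must be 'rician' or 'gaussian'")


@dataclass
class PhantomSpec:
    """Full ground truth of one phantom at one hydration time.

    ``region_boundaries`` maps each region name to its outer radius (mm),
    strictly increasing in the order core < interface1 < interface2 < gel;
    the four radii are the ground-truth positions of the penetration, full
    hydration, total gelification and apparent erosion fronts.
    """

    hydration_time: float
    center: tuple[float, float]
    region_boundaries: dict[str, float]
    region_params: dict[str, RegionParams]
    interface_profile: str = "linear-crossing"
    pixel_size: float = PIXEL_SIZE_MM
    grid_shape: tuple[int, int] = (MATRIX_SIZE, MATRIX_SIZE)
    dry_radius: float = DRY_TABLET_DIAMETER_MM / 2.0

    def __post_init__(self) -> None:
        if self.hydration_time <= 0:
            raise ValueError("hydration_time must be positive (hours)")
        if set(self.region_boundaries) != set(REGIONS) or set(self.region_params) != set(REGIONS):
            raise ValueError(f"need boundaries and parameters for all regions {REGIONS}")
        radii = [self.region_boundaries[r] for r in REGIONS]
        if radii[0] <= 0 or not np.all(np.diff(radii) > 0):
            raise ValueError("region boundaries must be positive and strictly increasing")
        if self.interface_profile not in ("linear-crossing", "constant"):
            raise ValueError("interface_profile must be 'linear-crossing' or 'constant'")

    @property
    def boundary_radii(self) -> np.ndarray:
        return np.array([self.region_boundaries[r] for r in REGIONS])

    @property
    def gel_thickness(self) -> float:
        return self.region_boundaries["gel"] - self.region_boundaries["interface2"]

    def to_json(self) -> str:
        d = asdict(self)
        d["center"] = list(self.center)
        d["grid_shape"] = list(self.grid_shape)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["center"] = tuple(d["center"])
        d["grid_shape"] = tuple(d["grid_shape"])
        d["region_params"] = {k: RegionParams(**v) for k, v in d["region_params"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

# Literature-anchored defaults: minimally hydrated core A_S 1.8 / 1.3 a.u. with
# T2S 3.6 / 3.8 ms (HPMC 400 / 10000 cP); fully hydrated A_T ~ 6.0 a.u.
# Boundary trajectories are smooth sqrt(t) interpolations of the observed front
# motion: inner fronts move inward at the same rate for both grades, the second
# interface is wider for the low-viscosity grade (its gel is thinner "at the
# expense of the second interface layer"), swelling is stronger for 10000 cP.
PRESETS: dict[str, dict[str, float]] = {
    "HPMC400": {
        "core_a_s": 1.8,
        "core_t2s": 3.6,
        "penetration_rate": 1.0,   # mm / sqrt(h), inward
        "interface1_width": 0.4,   # mm
        "interface2_width": 0.55,  # mm
        "swell_rate": 0.8,         # mm / sqrt(h), outward
    },
    "HPMC10000": {
        "core_a_s": 1.3,
        "core_t2s": 3.8,
        "penetration_rate": 1.0,
        "interface1_width": 0.4,
        "interface2_width": 0.35,
        "swell_rate": 1.0,
    },
}

# Shared layer endpoint parameters (a.u. / ms).
_GEL = dict(a_s=1.5, t2s=20.0, a_l=4.5, t2l=150.0, t1=800.0)
_INTERFACE1_OUTER = dict(a_s=6.0, t2s=8.0, a_l=0.0, t2l=50.0, t1=500.0)
_CORE_T1 = 900.0


def build_phantom_spec(
    hydration_time: float,
    polymer_preset: str = "HPMC400",
    overrides: dict | None = None,
    grid_shape: tuple[int, int] = (MATRIX_SIZE, MATRIX_SIZE),
    pixel_size: float | None = None,
    center: tuple[float, float] | None = None,
) -> PhantomSpec:
    """Build the ground-truth phantom for a polymer grade at a hydration time.

    The core is undetectable (no MR signal) for ``hydration_time <= 0.5`` h;
    from 1 h on it is minimally hydrated with the preset's short-T2 core
    parameters.  ``overrides`` may replace region parameters (nested, e.g.
    ``{"core": {"a_s": 2.0}}``) or boundary radii (``{"boundaries":
    {"gel": 5.6}}``); invalid values are rejected.

    By default the tablet center sits a couple of pixels off the grid center
    (sub-pixel offset) so that recentering is exercised downstream.
    """
    if hydration_time <= 0:
        raise ValueError("hydration_time must be positive (hours)")
    if polymer_preset not in PRESETS:
        raise ValueError(f"unknown preset {polymer_preset!r}; expected one of {sorted(PRESETS)}")
    p = PRESETS[polymer_preset]
    if pixel_size is None:
        pixel_size = FOV_MM / grid_shape[0]

    dry = DRY_TABLET_DIAMETER_MM / 2.0
    rt = float(np.sqrt(hydration_time))
    r_core = dry - p["penetration_rate"] * rt
    if r_core <= 0.2:
        raise ValueError(f"hydration_time {hydration_time} h leaves no core (penetration front at {r_core:.2f} mm)")
    boundaries = {
        "core": r_core,
        "interface1": r_core + p["interface1_width"],
        "interface2": r_core + p["interface1_width"] + p["interface2_width"],
        "gel": dry + p["swell_rate"] * rt,
    }

    detectable = hydration_time > 0.5
    params = {
        "core": RegionParams(
            a_s=p["core_a_s"] if detectable else 0.0,
            t2s=p["core_t2s"],
            a_l=0.0,
            t2l=_GEL["t2l"],
            t1=_CORE_T1,
            detectable=detectable,
        ),
        "interface1": RegionParams(**_INTERFACE1_OUTER),
        "interface2": RegionParams(**_GEL),
        "gel": RegionParams(**_GEL),
    }

    if overrides:
        overrides = copy.deepcopy(dict(overrides))
        bnd = overrides.pop("boundaries", {})
        for region, value in bnd.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} in boundary overrides")
            boundaries[region] = float(value)
        for region, upd in overrides.items():
            if region not in REGIONS:
                raise ValueError(f"unknown region {region!r} in overrides")
            current = asdict(params[region])
            current.update(upd)
            params[region] = RegionParams(**current)  # re-validates invariants

    if center is None:
        center = (grid_shape[0] // 2 + 2.3, grid_shape[1] // 2 - 1.6)

    return PhantomSpec(
        hydration_time=hydration_time,
        center=center,
        region_boundaries=boundaries,
        region_params=params,
        pixel_size=pixel_size,
        grid_shape=grid_shape,
        dry_radius=dry,
    )


# ---------------------------------------------------------------------------
# rendering & simulation
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("a_s", "t2s", "a_l", "t2l", "t1")


def _region_vector(params: RegionParams) -> np.ndarray:
    v = np.array([params.a_s, params.t2s, params.a_l, params.t2l, params.t1])
    if not params.detectable:
        v[0] = 0.0
        v[2] = 0.0
    return v


def pixel_radii(spec: PhantomSpec) -> np.ndarray:
    """Radius (mm) of every pixel center from the (sub-pixel) tablet center."""
    rr, cc = np.indices(spec.grid_shape)
    return np.hypot(rr - spec.center[0], cc - spec.center[1]) * spec.pixel_size


def render_parameter_maps(spec: PhantomSpec) -> ParametricMaps:
    """Rasterise the ground-truth layer parameters onto the pixel grid.

    Pixels outside the outermost (gel) boundary get zero amplitudes and are
    excluded from the mask; interface-layer pixels interpolate linearly in
    radius between the neighbouring layers (``linear-crossing`` profile) or
    hold their own layer values (``constant``).  ``a_t = a_s + a_l``
    pointwise; time constants are NaN where the matching amplitude is zero.
    """
    radius = pixel_radii(spec)
    rows, cols = spec.grid_shape
    edge_distance = min(
        spec.center[0], rows - 1 - spec.center[0], spec.center[1], cols - 1 - spec.center[1]
    ) * spec.pixel_size
    if spec.region_boundaries["gel"] >= edge_distance:
        raise ValueError("outermost boundary exceeds the field of view")

    vals = {name: np.zeros(spec.grid_shape) for name in _PARAM_NAMES}
    inner_edge = 0.0
    prev_vec = _region_vector(spec.region_params["core"])
    for region in REGIONS:
        outer_edge = spec.region_boundaries[region]
        vec = _region_vector(spec.region_params[region])
        sel = (radius >= inner_edge) & (radius < outer_edge)
        if region in ("interface1", "interface2") and spec.interface_profile == "linear-crossing":
            frac = (radius[sel] - inner_edge) / (outer_edge - inner_edge)
            for i, name in enumerate(_PARAM_NAMES):
                vals[name][sel] = prev_vec[i] + frac * (vec[i] - prev_vec[i])
        else:
            for i, name in enumerate(_PARAM_NAMES):
                vals[name][sel] = vec[i]
        inner_edge = outer_edge
        prev_vec = vec

    mask = radius < spec.region_boundaries["gel"]
    a_s, t2s, a_l, t2l, t1 = (vals[n] for n in _PARAM_NAMES)
    a_t = a_s + a_l
    t2s = np.where(a_s > 0, t2s, np.nan)
    t2l = np.where(a_l > 0, t2l, np.nan)
    t1 = np.where(a_t > 0, t1, np.nan)
    for arr in (a_s, a_l, a_t):
        arr[~mask] = 0.0

    return ParametricMaps(
        a_s=a_s, t2s=t2s, a_l=a_l, t2l=t2l, t1=t1, a_t=a_t,
        mask=mask, pixel_size=spec.pixel_size, center=spec.center,
    )


def _forward_signal(maps: ParametricMaps, schedule: AcquisitionSchedule) -> np.ndarray:
    """Noiseless forward model evaluated at every schedule time."""
    t = schedule.times_ms[:, None, None]
    a_s = np.nan_to_num(maps.a_s)
    a_l = np.nan_to_num(maps.a_l)
    if schedule.kind in ("MSME", "BLIP"):
        with np.errstate(divide="ignore", invalid="ignore"):
            short = np.where(a_s > 0, a_s * np.exp(-t / np.nan_to_num(maps.t2s, nan=1.0)), 0.0)
            long = np.where(a_l > 0, a_l * np.exp(-t / np.nan_to_num(maps.t2l, nan=1.0)), 0.0)
        return short + long
    if schedule.kind == "FISP":
        a_t = np.nan_to_num(maps.a_t)
        with np.errstate(divide="ignore", invalid="ignore"):
            rec = np.abs(1.0 - 2.0 * np.exp(-t / np.nan_to_num(maps.t1, nan=1.0)))
        return np.where(a_t > 0, a_t * rec, 0.0)
    raise ValueError(f"unsupported sequence kind {schedule.kind!r}")


def simulate_acquisition(
    maps: ParametricMaps,
    schedule: AcquisitionSchedule,
    noise: NoiseModel | None = None,
) -> ImageStack:
    """Simulate a noisy magnitude image stack from ground-truth maps.

    MSME/BLIP images evaluate the bi-exponential decay at each echo time;
    FISP images evaluate the magnitude inversion-recovery model at each
    inversion time.  Rician noise is realised as the magnitude of
    signal-plus-complex-Gaussian; ``sigma=0`` returns the exact noiseless
    forward model.  Identical (maps, schedule, seed) give bit-identical
    stacks.
    """
    if noise is None:
        noise = NoiseModel()
    signal = _forward_signal(maps, schedule)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        if noise.kind == "rician":
            re = signal + rng.normal(0.0, noise.sigma, signal.shape)
            im = rng.normal(0.0, noise.sigma, signal.shape)
            signal = np.hypot(re, im)
        else:
            signal = np.clip(signal + rng.normal(0.0, noise.sigma, signal.shape), 0.0, None)
    return ImageStack(signal, schedule, maps.pixel_size)
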