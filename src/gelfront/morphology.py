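"""Layer classification and moving-front detection on radial profiles.

Walking outward from the tablet center, five regions are distinguished by
the behaviour of the component amplitudes:

``unhydrated``
    no detectable MR signal (dry glassy polymer; observed only at the
    earliest hydration time),
``minimally_hydrated``
    solid-like matrix: a weak short-component signal above the noise floor,
    no long component, flat profile,
``interface1``
    only the short component, its amplitude rising steeply toward the water
    phase (high solvent gradient; the infiltration layer),
``interface2``
    both components present and changing over a wide range — the "amplitude
    crossing" layer where A_S falls below the rising A_L,
``gel``
    both components present with spatially stable parameters.

The region boundaries are the four moving fronts: *penetration* (inner edge
of interface1, where the steep total-amplitude gradient begins), *full
hydration* (radius where A_S peaks), *total gelification* (interface2/gel
boundary) and *apparent erosion* (outermost detectable radius of the
consistent gel that remains after solvent removal).

The qualitative selection criteria ("increases steeply", "do not change
substantially") are made quantitative through configurable thresholds whose
defaults were calibrated on the phantom presets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .phantom import DRY_TABLET_DIAMETER_MM
from .profiles import RadialProfile

__all__ = [
    "LAYER_NAMES",
    "SegmentationThresholds",
    "LayerSegmentation",
    "FrontPositions",
    "classify_layers",
    "detect_fronts",
    "track_front_evolution",
]

LAYER_NAMES = ("unhydrated", "minimally_hydrated", "interface1", "interface2", "gel")
FRONT_NAMES = ("penetration", "full_hydration", "total_gelification", "apparent_erosion")


@dataclass
class SegmentationThresholds:
    """Quantitative decision rules for the qualitative layer criteria.

    Attributes
    ----------
    noise_floor
        Background magnitude level in a.u. (the study's background mean).
    detect_mult
        A bin is detectable when its ``a_t`` exceeds ``detect_mult *
        noise_floor``.
    echo1_mult
        When the profile carries a blurred first-echo intensity channel
        (``echo1_blur``), detectability uses it instead: a bin is detectable
        when the blurred short-TE image intensity exceeds ``echo1_mult *
        noise_floor``.  This is the histogram rationale — the blurred
        first-echo image separates the tablet-center signal from noise far
        more reliably than the per-pixel fit amplitudes.
    a_l_frac
        The long component is "present" when ``a_l`` exceeds this fraction
        of the gel-level total amplitude.
    slope_min
        Minimum relative radial slope (fraction of gel level per mm) for an
        amplitude to count as "increasing steeply" (interface1 rule).
    flat_tol
        Relative-slope tolerance below which parameters "do not change
        substantially" (gel rule).
    core_ceiling_frac
        Minimally hydrated bins must stay below this fraction of the
        gel-level total amplitude.
    smooth_bins
        Moving-average window (bins) applied before slope estimation; raw
        profiles are retained for the front positions.
    min_run
        Region runs shorter than this many bins are merged into the
        neighbouring outer region.
    """

    noise_floor: float = 0.6
    detect_mult: float = 1.6
    echo1_mult: float = 1.3
    a_l_frac: float = 0.15
    slope_min: float = 1.0
    flat_tol: float = 0.35
    core_ceiling_frac: float = 0.5
    smooth_bins: int = 5
    min_run: int = 2


@dataclass
class LayerSegmentation:
    """Per-bin region labels (contiguous runs, ordered center -> rim)."""

    radii: np.ndarray
    labels: list[str]
    boundaries: dict[str, float]      # region name -> outer radius (mm) where present
    hydration_time: float | None = None
    degenerate: bool = False

    def regions_present(self) -> list[str]:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class FrontPositions:
    """The four front radii (mm) at one hydration time; absent fronts are None."""

    penetration: float | None
    full_hydration: float | None
    total_gelification: float | None
    apparent_erosion: float | None
    hydration_time: float | None = None

    def __post_init__(self) -> None:
        present = [getattr(self, n) for n in FRONT_NAMES if getattr(self, n) is not None]
        if any(b < a - 1e-9 for a, b in zip(present, present[1:])):
            raise ValueError(f"front ordering violated: {present}")

    def as_dict(self) -> dict[str, float | None]:
        return {n: getattr(self, n) for n in FRONT_NAMES}


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    out = np.full_like(x, np.nan, dtype=float)
    half = window // 2
    for i in range(x.size):
        seg = x[max(0, i - half): i + half + 1]
        seg = seg[np.isfinite(seg)]
        if seg.size:
            out[i] = seg.mean()
    return out


def _merge_short_runs(stages: np.ndarray, min_run: int) -> np.ndarray:
    """Merge region runs shorter than min_run into the neighbouring outer region."""
    stages = stages.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, stages.size + 1):
            if i == stages.size or stages[i] != stages[start]:
                runs.append((start, i))
                start = i
        for start, end in runs:
            if end - start < min_run and len(runs) > 1:
                if end < stages.size:
                    stages[start:end] = stages[end]
                else:
                    stages[start:end] = stages[start - 1]
                changed = True
                break
    return stages


def classify_layers(
    profile: RadialProfile,
    thresholds: SegmentationThresholds | None = None,
) -> LayerSegmentation:
    """Label each radial bin with one of the five hydration regions.

    Bins are first classified independently by the amplitude rules, then the
    label sequence is regularised: a 3-bin median filter, a merge of runs
    shorter than ``min_run`` into their outer neighbour, and a cumulative
    maximum over the region order so labels form contiguous runs ordered
    center -> rim.  ``unhydrated`` and ``minimally_hydrated`` are mutually
    exclusive at one time point: when an unhydrated core exists, stray
    minimally-hydrated bins are promoted to interface1.

    A profile without any detectable bin yields an all-unhydrated
    segmentation flagged ``degenerate``.
    """
    th = thresholds or SegmentationThresholds()
    radii = profile.radii
    echo1 = profile.values.get("echo1_blur")
    has_pixels = profile.counts > 0
    if echo1 is not None:
        has_pixels = has_pixels | np.isfinite(echo1)
    nz = np.nonzero(has_pixels)[0]
    if nz.size == 0:
        return LayerSegmentation(radii, ["unhydrated"] * radii.size, {}, profile.hydration_time, True)
    last = int(nz.max())  # trim trailing empty bins
    radii = radii[: last + 1]
    a_s = profile.values["a_s"][: last + 1]
    a_l = profile.values["a_l"][: last + 1]
    a_t = profile.values["a_t"][: last + 1]
    counts = profile.counts[: last + 1]
    echo1 = echo1[: last + 1] if echo1 is not None else None

    a_s_s = _moving_average(a_s, th.smooth_bins)
    a_l_s = _moving_average(a_l, th.smooth_bins)
    a_t_s = _moving_average(a_t, th.smooth_bins)

    # Detectability: the blurred short-TE first-echo intensity when available
    # (robust against the heavy-tailed per-pixel fits in the low-SNR core),
    # otherwise the binned total amplitude.
    detect_level = th.detect_mult * th.noise_floor
    if echo1 is not None:
        e1s = _moving_average(echo1, th.smooth_bins)
        detectable = np.isfinite(e1s) & (e1s > th.echo1_mult * th.noise_floor)
    else:
        detectable = (counts > 0) & np.isfinite(a_t_s) & (a_t_s > detect_level)
    if not detectable.any():
        return LayerSegmentation(
            radii, ["unhydrated"] * radii.size, {}, profile.hydration_time, True
        )

    valid = np.isfinite(a_t_s) & (counts > 0)
    tail = np.nonzero(valid)[0]
    tail = tail[-max(3, tail.size // 4):]
    gel_level = float(np.nanmedian(a_t_s[tail])) if tail.size else detect_level
    gel_level = max(gel_level, detect_level)
    a_l_min = th.a_l_frac * gel_level

    def fill_nearest(x: np.ndarray) -> np.ndarray:
        # propagate nearest finite values into NaN gaps so gradients do not
        # see spurious steps at bins without valid fits
        x = x.copy()
        finite = np.isfinite(x)
        if not finite.any():
            return np.zeros_like(x)
        idx = np.arange(x.size)
        x[~finite] = np.interp(idx[~finite], idx[finite], x[finite])
        return x

    def rel_slope(x: np.ndarray) -> np.ndarray:
        g = np.gradient(fill_nearest(x), radii)
        return g / gel_level

    ds = rel_slope(a_s_s)
    dl = rel_slope(a_l_s)
    dt = rel_slope(a_t_s)

    stages = np.zeros(radii.size, dtype=int)
    informative = np.zeros(radii.size, dtype=bool)
    for i in range(radii.size):
        if not detectable[i]:
            stages[i] = 0
            informative[i] = bool(has_pixels[i])
            continue
        informative[i] = True
        if np.nan_to_num(a_l_s[i]) < a_l_min:
            if ds[i] > th.slope_min or dt[i] > th.slope_min:
                stages[i] = 2  # one component, rising steeply
            elif np.nan_to_num(a_t_s[i]) < th.core_ceiling_frac * gel_level:
                stages[i] = 1  # weak, flat, short component only
            else:
                stages[i] = 2
        else:
            if abs(ds[i]) > th.flat_tol or abs(dl[i]) > th.flat_tol:
                stages[i] = 3
            else:
                stages[i] = 4

    # leading bins without any pixel inherit the first informative stage
    first_info = int(np.argmax(informative))
    stages[:first_info] = stages[first_info]

    # regularise: median filter, short-run merge, enforce outward ordering
    med = stages.copy()
    for i in range(1, stages.size - 1):
        med[i] = int(np.median(stages[i - 1: i + 2]))
    stages = _merge_short_runs(med, th.min_run)
    stages = np.maximum.accumulate(stages)
    if (stages == 0).any() and (stages == 1).any():
        stages[stages == 1] = 2  # unhydrated and minimally hydrated are exclusive

    labels = [LAYER_NAMES[s] for s in stages]
    boundaries: dict[str, float] = {}
    for i, lab in enumerate(labels):
        boundaries[lab] = float(radii[i] + profile.bin_width / 2.0)
    return LayerSegmentation(radii, labels, boundaries, profile.hydration_time, False)


def detect_fronts(
    profile: RadialProfile,
    segmentation: LayerSegmentation,
    thresholds: SegmentationThresholds | None = None,
) -> FrontPositions:
    """Locate the four moving fronts from a profile and its segmentation.

    * penetration: inner edge of the interface1 run,
    * full hydration: radius of the maximum binned ``a_s`` (innermost bin of
      a plateau),
    * total gelification: interface2/gel boundary,
    * apparent erosion: outer edge of the outermost bin with pixels and
      detectable total amplitude.

    Fronts of missing layers are reported as ``None``; the ordering
    invariant is enforced on the present ones.
    """
    th = thresholds or SegmentationThresholds()
    labels = segmentation.labels
    radii = segmentation.radii
    bw = profile.bin_width

    def inner_edge(name: str) -> float | None:
        idx = [i for i, lab in enumerate(labels) if lab == name]
        return float(radii[idx[0]] - bw / 2.0) if idx else None

    penetration = inner_edge("interface1")

    # full hydration: peak of the binned short amplitude, searched over the
    # interface layers (the peak is their boundary by definition); first
    # index of a tie -> innermost bin of a plateau
    full_hydration = None
    iface = np.array([lab in ("interface1", "interface2") for lab in labels])
    if iface.any():
        a_s = profile.values["a_s"][: radii.size].copy()
        a_s[~iface] = np.nan
        if np.any(np.isfinite(a_s)):
            i_max = int(np.nanargmax(a_s))
            full_hydration = float(radii[i_max])

    total_gelification = inner_edge("gel")

    apparent_erosion = None
    a_t = profile.values["a_t"][: radii.size]
    counts = profile.counts[: radii.size]
    det = (counts > 0) & np.isfinite(a_t) & (a_t > th.detect_mult * th.noise_floor)
    if det.any():
        apparent_erosion = float(radii[int(np.max(np.nonzero(det)[0]))] + bw / 2.0)

    # enforce ordering on present fronts (cumulative maximum outward)
    vals = [penetration, full_hydration, total_gelification, apparent_erosion]
    running = -np.inf
    for i, v in enumerate(vals):
        if v is not None:
            running = max(running, v)
            vals[i] = running
    return FrontPositions(*vals, hydration_time=profile.hydration_time)


def track_front_evolution(
    fronts: Sequence[FrontPositions],
    dry_radius: float = DRY_TABLET_DIAMETER_MM / 2.0,
) -> pd.DataFrame:
    """Tabulate front motion over hydration time.

    Returns a tidy table (time_h, front, radius_mm, displacement_mm) where
    displacement is measured from the dry-tablet radius (4.5 mm by
    convention, so 0 marks the original tablet border), plus the per-front
    displacement sign over the observed interval.
    """
    if len(fronts) < 2:
        raise ValueError("need at least two time points to track fronts")
    times = [f.hydration_time for f in fronts]
    if any(t is None for t in times) or not np.all(np.diff(times) > 0):
        raise ValueError("front sets must carry strictly increasing hydration times")

    rows = []
    for f in fronts:
        for name, radius in f.as_dict().items():
            if radius is None:
                continue
            rows.append(
                {
                    "time_h": f.hydration_time,
                    "front": name,
                    "radius_mm": radius,
                    "displacement_mm": radius - dry_radius,
                }
            )
    table = pd.DataFrame(rows, columns=["time_h", "front", "radius_mm", "displacement_mm"])
    signs = (
        table.sort_values("time_h")
        .groupby("front")["radius_mm"]
        .agg(lambda s: float(np.sign(s.iloc[-1] - s.iloc[0])))
        .rename("motion_sign")
    )
    table = table.merge(signs, on="front", how="left")
    return table.sort_values(["time_h", "front"], ignore_index=True)
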