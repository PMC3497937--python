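"""Pixel-wise relaxometric fitting of multi-echo tablet image stacks.

The transverse decay of a hydrating polymer matrix voxel is modelled with two
proton pools: a *short* component (water tightly coupled to the polymer,
T2 of a few ms) and a *long* component (free water clusters, T2 of tens to
hundreds of ms).  Two acquisitions sample complementary windows of the decay
envelope:

* **MSME** (CPMG multi-echo, TE spacing 6.5 ms, 32 echoes up to 208 ms) sees
  essentially only the long pool and is fitted with the two-parameter model

  .. math:: S(t) = S_0 \\exp(-t / T_{2L})

* **BLIP** (short-TE single-echo series, 3..12 ms in 1 ms steps) resolves the
  fast decay on top of a quasi-constant long-pool baseline and is fitted with
  the three-parameter model

  .. math:: S(t) = A_S \\exp(-t / T_{2S}) + A_L

  The baseline :math:`A_L` absorbs the long component, so the component
  amplitudes :math:`A_S, A_L` come exclusively from the BLIP fits while the
  long time constant :math:`T_{2L}` comes from the MSME fits.  The total
  proton density is :math:`A_T = A_S + A_L`.

* **FISP** inversion-recovery series map the longitudinal time via the
  magnitude model :math:`|A (1 - 2 e^{-TI/T_1})|` (single component).

Fits use Levenberg-Marquardt nonlinear least squares per pixel.  Components
are named by model ("short" = the exponential of the BLIP model, "long" = the
MSME decay / BLIP baseline), never by sorting fitted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "AcquisitionSchedule",
    "ImageStack",
    "PixelFitMono",
    "PixelFitBlip",
    "PixelFitT1",
    "ParametricMaps",
    "make_signal_mask",
    "recenter_stack",
    "rician_bias_correct",
    "fit_monoexp_pixel",
    "fit_blip_pixel",
    "fit_inversion_recovery_pixel",
    "fit_parameter_maps",
]

SEQUENCE_KINDS = ("MSME", "BLIP", "FISP")

# Acquisition protocol constants (ms / mm unless noted).
MSME_TE_MS = 6.5
MSME_N_ECHOES = 32
MSME_TR_MS = 4000.0
BLIP_FIRST_TE_MS = 3.0
BLIP_TE_STEP_MS = 1.0
BLIP_N_ECHOES = 10
BLIP_TR_MS = 500.0
FISP_TI0_MS = 400.0
FISP_DTI_MS = 160.0
FISP_N_IMAGES = 40
FISP_TR_MS = 4.0
FOV_MM = 15.0
MATRIX_SIZE = 256

#: In-plane pixel size of the reference acquisition geometry (mm/pixel).
PIXEL_SIZE_MM = FOV_MM / MATRIX_SIZE

# Plausibility bounds for fitted parameters; estimates outside these ranges
# are reported but flagged converged=False.  The short-T2 lower bound is set
# by the sampling resolution: with a first echo at 3 ms, decays faster than
# ~1 ms are not resolvable and fits demanding them are noise artifacts.
T2S_BOUNDS_MS = (1.0, 50.0)
T2L_BOUNDS_MS = (5.0, 2000.0)
T1_BOUNDS_MS = (10.0, 10_000.0)
AMP_BOUND_FACTOR = 3.0  # amplitude upper bound = factor * max observed intensity


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Echo (or inversion) time grid of one acquisition.

    Parameters
    ----------
    kind
        One of ``"MSME"``, ``"BLIP"``, ``"FISP"``.
    times
        Strictly increasing, positive echo/inversion times in ms.
    tr
        Repetition time in ms (metadata only).
    """

    kind: str
    times: tuple[float, ...]
    tr: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SEQUENCE_KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}; expected one of {SEQUENCE_KINDS}")
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("schedule needs a non-empty 1D time grid")
        if not np.all(t > 0) or not np.all(np.diff(t) > 0):
            raise ValueError("schedule times must be positive and strictly increasing")
        object.__setattr__(self, "times", tuple(float(x) for x in t))

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_ms(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @classmethod
    def msme(cls, n_echoes: int = MSME_N_ECHOES, te: float = MSME_TE_MS, tr: float = MSME_TR_MS) -> "AcquisitionSchedule":
        """CPMG echo train: TE, 2 TE, ... n TE (default 6.5 ms x 32 -> 208 ms)."""
        return cls("MSME", tuple(te * k for k in range(1, n_echoes + 1)), tr)

    @classmethod
    def blip(
        cls,
        n_echoes: int = BLIP_N_ECHOES,
        first_te: float = BLIP_FIRST_TE_MS,
        step: float = BLIP_TE_STEP_MS,
        tr: float = BLIP_TR_MS,
    ) -> "AcquisitionSchedule":
        """Short-TE series: first echo at 3 ms, then 1 ms apart (3..12 ms)."""
        return cls("BLIP", tuple(first_te + step * k for k in range(n_echoes)), tr)

    @classmethod
    def fisp(
        cls,
        n_images: int = FISP_N_IMAGES,
        ti0: float = FISP_TI0_MS,
        dti: float = FISP_DTI_MS,
        tr: float = FISP_TR_MS,
    ) -> "AcquisitionSchedule":
        """Inversion-recovery series: TI = 400 ms, then 160 ms apart (40 images)."""
        return cls("FISP", tuple(ti0 + dti * k for k in range(n_images)), tr)


@dataclass
class ImageStack:
    """A magnitude image time series (time x rows x cols) with its schedule."""

    data: np.ndarray
    schedule: AcquisitionSchedule
    pixel_size: float = PIXEL_SIZE_MM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("stack data must be 3D (time, rows, cols)")
        if self.data.shape[0] != len(self.schedule):
            raise ValueError(
                f"time axis length {self.data.shape[0]} does not match schedule length {len(self.schedule)}"
            )
        if np.nanmin(self.data) < 0:
            raise ValueError("magnitude images must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (mm)")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class PixelFitMono:
    """Two-parameter monoexponential fit result (MSME model)."""

    s0: float
    t2l: float
    residual_rms: float
    converged: bool


@dataclass(frozen=True)
class PixelFitBlip:
    """Three-parameter short-decay-plus-baseline fit result (BLIP model)."""

    a_s: float
    t2s: float
    a_l: float
    residual_rms: float
    converged: bool


@dataclass(frozen=True)
class PixelFitT1:
    """Magnitude inversion-recovery fit result."""

    s0: float
    t1: float
    residual_rms: float
    converged: bool


@dataclass
class ParametricMaps:
    """Per-pixel relaxometric parameter maps with a validity mask.

    ``a_t = a_s + a_l`` holds exactly wherever ``mask`` is True.  Parameters
    are NaN outside the mask or where the corresponding fit failed (``t2l``
    additionally requires the MSME fit, ``t1`` the FISP fit, to converge).
    """

    a_s: np.ndarray
    t2s: np.ndarray
    a_l: np.ndarray
    t2l: np.ndarray
    t1: np.ndarray
    a_t: np.ndarray
    mask: np.ndarray
    pixel_size: float
    center: tuple[float, float]
    s0_msme: np.ndarray | None = None  # diagnostic only; amplitudes come from BLIP

    PARAMETERS = ("a_s", "t2s", "a_l", "t2l", "t1", "a_t")

    def parameters(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.PARAMETERS}

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.mask.shape


# ---------------------------------------------------------------------------
# masking & recentering
# ---------------------------------------------------------------------------

def _border_pixels(image: np.ndarray, width: int) -> np.ndarray:
    w = max(1, width)
    return np.concatenate(
        [image[:w].ravel(), image[-w:].ravel(), image[w:-w, :w].ravel(), image[w:-w, -w:].ravel()]
    )


def estimate_background(image: np.ndarray, border: int | None = None) -> tuple[float, float]:
    """Robust background level and spread from image-border pixels.

    Returns (median, 1.4826 * MAD) of a border band; the band width defaults
    to rows/32 (>= 3 px).
    """
    if border is None:
        border = max(3, image.shape[0] // 32)
    ring = _border_pixels(image, border)
    med = float(np.median(ring))
    mad = float(np.median(np.abs(ring - med))) * 1.4826
    return med, mad


def make_signal_mask(
    stack: ImageStack,
    k_sigma: float = 3.0,
    border: int | None = None,
    keep_largest: bool = True,
    fill_holes: bool = True,
    min_size: int = 9,
) -> np.ndarray:
    """Separate signal-containing pixels from background noise.

    Thresholds the first-echo image at ``background median + k_sigma *
    background spread`` (both estimated from border pixels), then keeps the
    largest connected component (if at least ``min_size`` pixels — isolated
    noise spikes do not constitute a tablet) and fills its holes, so that a
    low-signal tablet core ends up inside the analysis mask.  Disable
    ``keep_largest`` / ``fill_holes`` for raw per-pixel detectability maps
    (binary sequence comparisons).
    """
    first = stack.data[0]
    med, spread = estimate_background(first, border)
    mask = first > med + k_sigma * spread
    if keep_largest and mask.any():
        labels, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        if sizes.max() < min_size:
            mask = np.zeros_like(mask)
        else:
            mask = labels == (1 + int(np.argmax(sizes)))
    if fill_holes and mask.any():
        mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        warnings.warn("degenerate mask: no pixels above background threshold", stacklevel=2)
    elif mask.all():
        warnings.warn("degenerate mask: every pixel above background threshold", stacklevel=2)
    return mask


def _integer_shift(plane: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    out = np.zeros_like(plane)
    dr, dc = shift
    rows, cols = plane.shape
    src_r = slice(max(0, -dr), min(rows, rows - dr))
    src_c = slice(max(0, -dc), min(cols, cols - dc))
    dst_r = slice(max(0, dr), min(rows, rows + dr))
    dst_c = slice(max(0, dc), min(cols, cols + dc))
    out[dst_r, dst_c] = plane[src_r, src_c]
    return out


def recenter_stack(stack: ImageStack, mask: np.ndarray) -> tuple[ImageStack, np.ndarray, tuple[int, int]]:
    """Shift the tablet to the image-matrix center by an integer translation.

    The mask centroid is moved onto the grid center ``(rows//2, cols//2)``;
    no interpolation is performed so decay curves are unaltered.  Returns the
    shifted stack, the shifted mask, and the applied (row, col) shift.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot recenter with an empty mask")
    com = ndimage.center_of_mass(mask)
    rows, cols = mask.shape
    shift = (int(round(rows // 2 - com[0])), int(round(cols // 2 - com[1])))
    if shift == (0, 0):
        return stack, mask, shift
    data = np.stack([_integer_shift(plane, shift) for plane in stack.data])
    new_mask = _integer_shift(mask.astype(np.uint8), shift).astype(bool)
    return ImageStack(data, stack.schedule, stack.pixel_size), new_mask, shift


def rician_bias_correct(stack: ImageStack, sigma: float) -> ImageStack:
    """Optional magnitude-bias correction (off by default in the pipeline).

    Subtracts the squared mean background magnitude ``(pi/2) * sigma**2`` in
    quadrature from each intensity.
    """
    corrected = np.sqrt(np.clip(stack.data**2 - (np.pi / 2.0) * sigma**2, 0.0, None))
    return ImageStack(corrected, stack.schedule, stack.pixel_size)


# ---------------------------------------------------------------------------
# per-pixel fits
# ---------------------------------------------------------------------------

def _lm_fit(residual, x0, jac=None, max_nfev=100):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.least_squares(
                residual, x0, jac=jac if jac is not None else "2-point",
                method="lm", max_nfev=max_nfev,
            )
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return res.x, rms, bool(res.success)


def fit_monoexp_pixel(decay: np.ndarray, times: np.ndarray) -> PixelFitMono:
    """Fit ``S0 * exp(-t/T2L)`` to one pixel's echo series (MSME model).

    Initialisation comes from a log-linear regression of the positive
    samples.  ``converged`` is False when the solver fails or the estimates
    fall outside the plausibility bounds (degenerate decays such as an
    all-zero or constant series end up flagged).
    """
    y = np.asarray(decay, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.size < 3:
        raise ValueError("need >= 3 samples with matching time grid")
    ymax = float(np.max(y))
    if not np.isfinite(ymax) or ymax <= 0:
        return PixelFitMono(np.nan, np.nan, np.nan, False)

    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        if slope < 0:
            x0 = [float(np.exp(intercept)), float(-1.0 / slope)]
        else:
            x0 = [ymax, float(t[-1] - t[0])]
    else:
        x0 = [ymax, float(t[-1] - t[0])]

    def residual(p):
        return p[0] * np.exp(-t / p[1]) - y

    def jac(p):
        e = np.exp(-t / p[1])
        return np.column_stack([e, p[0] * e * t / p[1] ** 2])

    out = _lm_fit(residual, x0, jac)
    if out is None:
        return PixelFitMono(np.nan, np.nan, np.nan, False)
    (s0, t2l), rms, success = out
    ok = (
        success
        and 0.0 <= s0 <= AMP_BOUND_FACTOR * ymax
        and T2L_BOUNDS_MS[0] <= t2l <= T2L_BOUNDS_MS[1]
    )
    return PixelFitMono(float(s0), float(t2l), rms, ok)


def fit_blip_pixel(decay: np.ndarray, times: np.ndarray) -> PixelFitBlip:
    """Fit ``A_S * exp(-t/T2S) + A_L`` to one pixel's short-TE series.

    Heuristic initialisation: ``A_L`` from the last sample, ``A_S`` from
    first minus last, ``T2S`` one third of the sampled time span.
    """
    y = np.asarray(decay, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape or y.size < 4:
        raise ValueError("need >= 4 samples with matching time grid")
    ymax = float(np.max(y))
    if not np.isfinite(ymax) or ymax <= 0:
        return PixelFitBlip(np.nan, np.nan, np.nan, np.nan, False)

    a_l0 = float(y[-1])
    a_s0 = max(float(y[0] - y[-1]), 1e-3 * max(ymax, 1.0))
    t2s0 = max((t[-1] - t[0]) / 3.0, 0.5)

    def residual(p):
        return p[0] * np.exp(-t / p[1]) + p[2] - y

    def jac(p):
        e = np.exp(-t / p[1])
        return np.column_stack([e, p[0] * e * t / p[1] ** 2, np.ones_like(t)])

    out = _lm_fit(residual, [a_s0, t2s0, a_l0], jac)
    if out is None:
        return PixelFitBlip(np.nan, np.nan, np.nan, np.nan, False)
    (a_s, t2s, a_l), rms, success = out
    ok = (
        success
        and 0.0 <= a_s <= AMP_BOUND_FACTOR * ymax
        and -0.05 * ymax <= a_l <= AMP_BOUND_FACTOR * ymax
        and T2S_BOUNDS_MS[0] <= t2s <= T2S_BOUNDS_MS[1]
    )
    return PixelFitBlip(float(a_s), float(t2s), float(max(a_l, 0.0)), rms, ok)


def fit_inversion_recovery_pixel(signals: np.ndarray, tis: np.ndarray) -> PixelFitT1:
    """Fit the magnitude inversion-recovery model ``|A (1 - 2 exp(-TI/T1))|``.

    Single-component by construction; ``T1`` is seeded from the null point
    (TI at the signal minimum, T1 = TI_null / ln 2).
    """
    y = np.asarray(signals, dtype=float)
    t = np.asarray(tis, dtype=float)
    if y.shape != t.shape or y.size < 3:
        raise ValueError("need >= 3 samples with matching inversion-time grid")
    ymax = float(np.max(y))
    if not np.isfinite(ymax) or ymax <= 0:
        return PixelFitT1(np.nan, np.nan, np.nan, False)

    ti_null = float(t[int(np.argmin(y))])
    t1_0 = min(max(ti_null / np.log(2.0), T1_BOUNDS_MS[0]), T1_BOUNDS_MS[1])

    def residual(p):
        return np.abs(p[0] * (1.0 - 2.0 * np.exp(-t / p[1]))) - y

    def jac(p):
        e = np.exp(-t / p[1])
        f = p[0] * (1.0 - 2.0 * e)
        s = np.sign(f)
        return np.column_stack([s * (1.0 - 2.0 * e), s * p[0] * (-2.0) * e * t / p[1] ** 2])

    out = _lm_fit(residual, [ymax, t1_0], jac, max_nfev=200)
    if out is None:
        return PixelFitT1(np.nan, np.nan, np.nan, False)
    (s0, t1), rms, success = out
    ok = (
        success
        and 0.0 <= s0 <= AMP_BOUND_FACTOR * ymax
        and T1_BOUNDS_MS[0] <= t1 <= T1_BOUNDS_MS[1]
    )
    return PixelFitT1(float(s0), float(t1), rms, ok)


# ---------------------------------------------------------------------------
# map-level fitting
# ---------------------------------------------------------------------------

def fit_parameter_maps(
    msme: ImageStack,
    blip: ImageStack,
    fisp: ImageStack | None = None,
    mask: np.ndarray | None = None,
    k_sigma: float = 3.0,
) -> ParametricMaps:
    """Fit every masked pixel of the co-registered stacks into parameter maps.

    Component amplitudes ``a_s``, ``a_l`` (and ``t2s``) come exclusively from
    the BLIP fits; ``t2l`` from the MSME fits; ``t1`` from the FISP fits when
    a FISP stack is given.  The MSME amplitude is kept as the ``s0_msme``
    diagnostic only.  The validity mask excludes pixels whose BLIP fit
    failed; ``t2l``/``t1`` are additionally NaN where their own fit failed.
    """
    if msme.grid_shape != blip.grid_shape:
        raise ValueError(f"grid mismatch: MSME {msme.grid_shape} vs BLIP {blip.grid_shape}")
    if fisp is not None and fisp.grid_shape != blip.grid_shape:
        raise ValueError(f"grid mismatch: FISP {fisp.grid_shape} vs BLIP {blip.grid_shape}")
    if mask is None:
        mask = make_signal_mask(blip, k_sigma=k_sigma)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != blip.grid_shape:
        raise ValueError("mask shape does not match stack grid")

    shape = blip.grid_shape
    nan = np.full(shape, np.nan)
    a_s, t2s, a_l, t2l, t1, s0m = (nan.copy() for _ in range(6))
    blip_ok = np.zeros(shape, dtype=bool)

    t_blip = blip.schedule.times_ms
    t_msme = msme.schedule.times_ms
    t_fisp = fisp.schedule.times_ms if fisp is not None else None

    for r, c in np.argwhere(mask):
        fb = fit_blip_pixel(blip.data[:, r, c], t_blip)
        if not fb.converged:
            continue  # pixel leaves the validity mask; skip the slower fits
        blip_ok[r, c] = True
        a_s[r, c], t2s[r, c], a_l[r, c] = fb.a_s, fb.t2s, fb.a_l
        fm = fit_monoexp_pixel(msme.data[:, r, c], t_msme)
        if fm.converged:
            t2l[r, c] = fm.t2l
            s0m[r, c] = fm.s0
        if fisp is not None:
            ft = fit_inversion_recovery_pixel(fisp.data[:, r, c], t_fisp)
            if ft.converged:
                t1[r, c] = ft.t1

    valid = mask & blip_ok
    for arr in (a_s, t2s, a_l, t2l, t1, s0m):
        arr[~valid] = np.nan
    a_t = a_s + a_l  # exact by construction on the validity mask

    center = (shape[0] // 2, shape[1] // 2)
    return ParametricMaps(
        a_s=a_s, t2s=t2s, a_l=a_l, t2l=t2l, t1=t1, a_t=a_t,
        mask=valid, pixel_size=blip.pixel_size, center=center, s0_msme=s0m,
    )
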