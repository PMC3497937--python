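"""File formats, pipeline configuration, and the end-to-end pipeline.

Image stacks travel as multi-page TIFF or NIfTI files with a JSON sidecar
recording the echo/inversion schedule (ms), pixel size (mm), sequence kind
and, for simulated data, the noise seed.  Parameter maps are written as a
multi-channel TIFF plus a tidy per-pixel CSV; profiles, segmentations and
front tables as CSV/JSON.  Units are fixed project-wide: ms for times, mm
for distances, a.u. for intensities; image coordinates are 0-based
(row, col) and radii are measured from the recentered grid center.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .morphology import SegmentationThresholds, track_front_evolution
from .phantom import DRY_TABLET_DIAMETER_MM
from .relaxometry import (
    AcquisitionSchedule,
    ImageStack,
    ParametricMaps,
    make_signal_mask,
    recenter_stack,
)

__all__ = [
    "load_image_stack",
    "save_image_stack",
    "save_parameter_maps",
    "profile_to_frame",
    "PipelineConfig",
    "TimePointInputs",
    "run_pipeline",
]

log = logging.getLogger("gelfront")

_FLOAT_FMT = "%.9g"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_image_stack(stack: ImageStack, path: str | Path, seed: int | None = None) -> Path:
    """Write a stack as TIFF (.tif/.tiff) or NIfTI (.nii/.nii.gz) + JSON sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, stack.data)  # float64: round trips bit-exactly
    elif suffix in (".nii", ".gz"):
        import nibabel as nib

        affine = np.diag([stack.pixel_size, stack.pixel_size, 1.0, 1.0])
        img = nib.Nifti1Image(np.moveaxis(stack.data, 0, -1), affine)
        nib.save(img, path)
    else:
        raise ValueError(f"unsupported stack format {suffix!r} (use .tif/.tiff/.nii/.nii.gz)")
    sidecar = {
        "kind": stack.schedule.kind,
        "times_ms": list(stack.schedule.times),
        "tr_ms": stack.schedule.tr,
        "pixel_size_mm": stack.pixel_size,
    }
    if seed is not None:
        sidecar["seed"] = seed
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def load_image_stack(path: str | Path, sidecar: str | Path | None = None) -> ImageStack:
    """Read a TIFF/NIfTI stack with its JSON schedule sidecar.

    The sidecar defaults to ``<path>.json``.  A schedule whose length does
    not match the stack's time axis is rejected with both lengths named.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing schedule sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    schedule = AcquisitionSchedule(meta["kind"], tuple(meta["times_ms"]), meta.get("tr_ms"))

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        data = np.asarray(tifffile.imread(path), dtype=float)
        if data.ndim == 2:
            data = data[None]
    elif suffix in (".nii", ".gz"):
        import nibabel as nib

        data = np.moveaxis(np.asarray(nib.load(path).dataobj, dtype=float), -1, 0)
    else:
        raise ValueError(f"unsupported stack format {suffix!r}")
    if data.shape[0] != len(schedule):
        raise ValueError(
            f"stack has {data.shape[0]} images but the sidecar lists {len(schedule)} times"
        )
    return ImageStack(data, schedule, float(meta.get("pixel_size_mm", 1.0)))


def save_parameter_maps(maps: ParametricMaps, out_dir: str | Path) -> dict[str, Path]:
    """Write maps as a multi-channel TIFF plus a tidy per-pixel CSV."""
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channels = list(ParametricMaps.PARAMETERS)
    stack = np.stack([getattr(maps, name) for name in channels]).astype(np.float32)
    tif = out_dir / "maps.tif"
    tifffile.imwrite(tif, stack, metadata={"channels": channels})

    rows, cols = np.nonzero(maps.mask)
    frame = pd.DataFrame({"row": rows, "col": cols})
    for name in channels:
        frame[name] = getattr(maps, name)[rows, cols]
    frame["converged"] = True
    csv = out_dir / "maps.csv"
    frame.to_csv(csv, index=False, float_format=_FLOAT_FMT)

    meta = out_dir / "maps.json"
    meta.write_text(
        json.dumps(
            {
                "channels": channels,
                "pixel_size_mm": maps.pixel_size,
                "center": list(maps.center),
            },
            indent=2,
            sort_keys=True,
        )
    )
    return {"tif": tif, "csv": csv, "json": meta}


def profile_to_frame(profile) -> pd.DataFrame:
    """Tidy (radius_mm, parameter, mean, count, sector_deg, hydration_time_h) table."""
    rows = []
    for name, vals in profile.values.items():
        for r, v, c in zip(profile.radii, vals, profile.counts):
            rows.append(
                {
                    "radius_mm": r,
                    "parameter": name,
                    "mean": v,
                    "count": int(c),
                    "sector_deg": profile.sector[0],
                    "sector_width_deg": profile.sector[1],
                    "hydration_time_h": profile.hydration_time,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class TimePointInputs:
    """Paths of the acquisitions of one hydration time (FISP optional)."""

    time_h: float
    msme: str
    blip: str
    fisp: str | None = None


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, JSON round-trippable."""

    timepoints: list[TimePointInputs]
    output_dir: str
    seed: int = 0
    mask_k_sigma: float = 3.0
    sector_orientation: float | str = "auto"  # degrees or "auto"
    sector_width: float = 60.0
    bin_width_mm: float | None = None
    dry_radius_mm: float = DRY_TABLET_DIAMETER_MM / 2.0
    thresholds: SegmentationThresholds = field(default_factory=SegmentationThresholds)
    histogram_bins: int = 64
    blur_sigma_px: float = 2.0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["timepoints"] = [TimePointInputs(**tp) for tp in d["timepoints"]]
        d["thresholds"] = SegmentationThresholds(**d.get("thresholds", {}))
        return cls(**d)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run fit -> profile -> segment -> fronts -> histogram for each time point.

    Per-time-point failures are recorded and do not stop independent time
    points.  Outputs (maps, profiles, segmentations, front evolution table,
    histogram modes) land under ``config.output_dir`` together with a run
    manifest listing every file with a checksum; identical config+inputs
    reproduce the outputs byte-identically.
    """
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    report: dict = {"timepoints": {}, "errors": {}}
    all_fronts = []

    for tp in sorted(config.timepoints, key=lambda t: t.time_h):
        tag = f"t{tp.time_h:g}h"
        tp_dir = out_root / tag
        try:
            msme = load_image_stack(tp.msme)
        except Exception as exc:
            log.warning("time point %s failed: %s", tag, exc)
            report["errors"][tag] = str(exc)
            continue
        try:
            blip = load_image_stack(tp.blip)
            fisp = load_image_stack(tp.fisp) if tp.fisp else None
        except Exception as exc:
            # amplitudes need the short-TE data; emit long-T2 diagnostics only
            log.warning("time point %s: %s; writing MSME-only diagnostics", tag, exc)
            report["errors"][tag] = str(exc)
            tp_dir.mkdir(parents=True, exist_ok=True)
            _msme_only_diagnostics(msme, config, tp_dir)
            continue
        try:
            from .study import analyze_stacks

            result = analyze_stacks(
                msme,
                blip,
                fisp,
                hydration_time=tp.time_h,
                mask_k_sigma=config.mask_k_sigma,
                sector_orientation=config.sector_orientation,
                sector_width=config.sector_width,
                bin_width=config.bin_width_mm,
                thresholds=config.thresholds,
                blur_sigma_px=config.blur_sigma_px,
            )
            tp_dir.mkdir(parents=True, exist_ok=True)
            save_parameter_maps(result.maps, tp_dir)
            profile_to_frame(result.profile).to_csv(
                tp_dir / "profile.csv", index=False, float_format=_FLOAT_FMT
            )
            (tp_dir / "morphology.json").write_text(
                json.dumps(
                    {
                        "hydration_time_h": tp.time_h,
                        "labels": result.segmentation.labels,
                        "bin_radii_mm": [float(r) for r in result.segmentation.radii],
                        "fronts_mm": result.fronts.as_dict(),
                        "degenerate": result.segmentation.degenerate,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            modes = result.histogram_modes
            (tp_dir / "histogram_modes.json").write_text(
                json.dumps(
                    {
                        "nm": modes.nm,
                        "tcm": modes.tcm,
                        "fhm": modes.fhm,
                        "window_max": modes.window_max,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
            all_fronts.append(result.fronts)
            report["timepoints"][tag] = {
                "n_mask_pixels": int(result.analysis_mask.sum()),
                "n_valid_pixels": int(result.maps.mask.sum()),
                "shift": list(result.shift),
                "sector_orientation_deg": result.sector_orientation,
                "regions": result.segmentation.regions_present(),
                "fronts_mm": result.fronts.as_dict(),
                "histogram_modes": {"nm": modes.nm, "tcm": modes.tcm},
            }
            log.info(
                "%s: %d valid pixels, regions %s",
                tag, result.maps.mask.sum(), result.segmentation.regions_present(),
            )
        except Exception as exc:  # keep independent time points running
            log.warning("time point %s failed: %s", tag, exc)
            report["errors"][tag] = str(exc)

    if len(all_fronts) >= 2:
        evolution = track_front_evolution(all_fronts, dry_radius=config.dry_radius_mm)
        evolution.to_csv(out_root / "fronts.csv", index=False, float_format=_FLOAT_FMT)
        report["fronts_table"] = str(out_root / "fronts.csv")

    manifest = {
        "gelfront_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "outputs": {
            str(p.relative_to(out_root)): _sha256(p)
            for p in sorted(out_root.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out_root / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = str(out_root / "manifest.json")
    return report


def _msme_only_diagnostics(msme: ImageStack, config: PipelineConfig, tp_dir: Path) -> None:
    """Long-T2 diagnostic fits (s0_msme, t2l) when short-TE data are missing."""
    from .relaxometry import fit_monoexp_pixel

    mask = make_signal_mask(msme, k_sigma=config.mask_k_sigma)
    msme, mask, _ = recenter_stack(msme, mask)
    t = msme.schedule.times_ms
    rows = []
    for r, c in np.argwhere(mask):
        f = fit_monoexp_pixel(msme.data[:, r, c], t)
        if f.converged:
            rows.append({"row": r, "col": c, "s0_msme": f.s0, "t2l": f.t2l})
    pd.DataFrame(rows, columns=["row", "col", "s0_msme", "t2l"]).to_csv(
        tp_dir / "msme_diagnostics.csv", index=False, float_format=_FLOAT_FMT
    )
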