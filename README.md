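# gelfront

Spatially resolved T₂/T₁ MR relaxometry of hydrating polymer matrix tablets:
phantom simulation, pixel-wise two-component decay fitting, pie-sector radial
profiling, five-region layer classification and moving-front tracking.

## The problem

Hydrophilic matrix tablets (e.g. hydroxypropylmethyl cellulose, HPMC) control
drug release through the gel barrier that forms as water penetrates the
compact. Where exactly the matrix is glassy, swollen or gelled — and how fast
those boundaries move — decides the release profile. Optical methods see two
or three zones at best; MR microscopy resolves the water itself, and the
relaxation behaviour of that water encodes its mobility.

`gelfront` implements the multiparametric analysis that resolves **five**
concentric regions in a hydrating tablet cross-section and the **four moving
fronts** separating them. Each pixel's transverse decay envelope is modelled
with two proton pools:

- a CPMG multi-echo series (MSME, TE = 6.5 ms, 32 echoes up to 208 ms) is
  fitted with the two-parameter model
  `S(t) = S₀·exp(−t/T₂L)`,
- a short-TE series (BLIP_MODES, echoes at 3…12 ms) is fitted with the
  three-parameter model
  `S(t) = A_S·exp(−t/T₂S) + A_L`,
  whose baseline A_L absorbs the long-T₂ pool, so the component amplitudes
  come exclusively from the short-TE data,
- an inversion-recovery FISP series maps T₁ via `|A(1 − 2·exp(−TI/T₁))|`.

The total proton density is `A_T = A_S + A_L`. Radial profiles of these
parameters, averaged over a 60° pie sector, are classified walking outward:
**unhydrated** core (no signal) or **minimally hydrated** solid-like core
(weak short-T₂ signal), **first interface** (only the short component, rising
steeply), **second interface** (the "amplitude-crossing" layer where A_S
falls below the rising A_L), and **gel** (both components, spatially stable).
The region boundaries are the penetration, full-hydration, total-gelification
and apparent-erosion fronts, tracked over hydration time against the dry
tablet radius (4.5 mm).

Because no scanner data are deposited for such studies, the package includes
a first-class phantom module: concentric-layer tablet specs for two polymer
grades (HPMC 400 / 10 000 cP) at any hydration time, rendered to parameter
maps and observed through the three acquisitions with Rician noise
(background mean ≈ 0.6 a.u. against a fully hydrated signal of ≈ 6 a.u.).
Every stage of the analysis is testable against this ground truth.

## Worked example

```python
import gelfront as gf

result = gf.simulate_hydration_study(1.0, "HPMC400", seed=7, grid_shape=(128, 128))
print("regions :", result.segmentation.regions_present())
for name, radius in result.fronts.as_dict().items():
    print(f"{name:>18s} : {radius:.2f} mm")
m = result.histogram_modes
print(f"histogram modes    : NM={m.nm:.2f}  TCM={m.tcm:.2f}")
print("ground truth       :", {k: round(v, 2) for k, v in result.spec.region_boundaries.items()})
```

prints

```
regions : ['minimally_hydrated', 'interface1', 'interface2', 'gel']
       penetration : 3.63 mm
    full_hydration : 3.93 mm
total_gelification : 4.57 mm
  apparent_erosion : 5.39 mm
histogram modes    : NM=0.61  TCM=0.95
ground truth       : {'core': 3.5, 'interface1': 3.9, 'interface2': 4.45, 'gel': 5.3}
```

One call simulated a 1 h HPMC 400 cP tablet phantom at the default noise
level, fitted every masked pixel of the MSME and BLIP stacks, profiled a 60°
sector and classified it. The four detected fronts sit within about one
radial bin (0.12 mm) of the ground-truth layer boundaries; the low-intensity
histogram of the blurred 3 ms echo image shows the noise mode (NM ≈ 0.6 a.u.)
and the separate tablet-center mode (TCM) that betrays the minimally hydrated
solid-like core — a mode that is absent both at 0.5 h (unhydrated core) and
in the 6.5 ms MSME image (the core signal has already decayed).

## Command line

Each stage is also a subcommand: `gelfront simulate | fit | profile |
segment | fronts | histogram | run` — e.g.

```sh
gelfront simulate --preset HPMC400 --time 1.0 --sequence blip --seed 7 --out blip.tif
gelfront fit --msme msme.tif --blip blip.tif --out maps/
gelfront profile --maps maps/ --orientation auto --out profile.csv
```

`gelfront run --config config.json` executes the whole pipeline over several
time points and writes maps, profiles, segmentations, a front-evolution
table and a checksummed run manifest.

## Layout

- `gelfront.phantom` — tablet phantom specs, parameter-map rendering, noisy
  forward simulation of the three acquisitions
- `gelfront.relaxometry` — schedules, masking, recentering, the per-pixel
  Levenberg–Marquardt fits, parametric maps
- `gelfront.profiles` — pie-sector selection and radial binning
- `gelfront.morphology` — layer classification, front detection, front
  evolution tables
- `gelfront.histogram` — blurred low-intensity histogram modes (NM/TCM/FHM)
- `gelfront.io` / `gelfront.cli` — TIFF/NIfTI + JSON sidecar I/O, pipeline
  configuration, CLI
- `docs/methods.md` — model assumptions, parameter defaults and their
  rationale, numerical choices, limitations
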