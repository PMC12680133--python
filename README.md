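# dopm

Toolkit for characterizing a dual-view oblique plane microscope (dOPM): a
folded light-sheet system in which one high-NA primary objective both
illuminates and collects, a polarizing beam splitter plus quarter-wave plate
fold the remote arm so a single air objective serves as secondary and
tertiary, and a translating prism mirror switches between two views tilted
by twice the oblique angle.

The package implements the computational models used to characterize such a
system, all runnable on synthetic data:

- **`dopm.geometry`** — geometric collection aperture: cone half-angles,
  triple-cone solid-angle intersection on the unit sphere (deterministic
  Fibonacci lattice), effective latitudinal/longitudinal NAs, minimum
  oblique angle, and the geometric relative collection efficiency
  (solid-angle ratio × optics transmission × ideal PBS fluorescence factor).
- **`dopm.trace`** — full vectorial Jones-matrix ray tracing of the
  collection path (dipole far fields → meridional lens transforms → PBS
  transmit → QWP → coated tilted mirror via Householder reflection and
  per-ray s/p reflectivities → QWP → PBS reflect), giving pupil intensity
  maps and collection efficiency relative to the primary objective.
- **`dopm.coatings`** — thin-film complex reflectivity of the fold mirror
  (transfer-matrix method; perfect, bare silver, SiO₂-protected silver and
  SiO-protected aluminum stacks built in, all configurable).
- **`dopm.dose`** — equal-signal light-dose comparison between a widefield
  z-stack and dual-view Gaussian-sheet scanning of a point object.
- **`dopm.volume`** — deskew of sheared per-view oblique stacks into the lab
  frame, translation registration by phase correlation, and fusion; plus the
  exact forward (skewing) model used by the synthetic generator.
- **`dopm.metrology`** — bead detection, per-axis Gaussian FWHM fits,
  optical sectioning from beads and from a thin fluorescent sheet,
  median/IQR/95 %-CI summaries, Airy-ROI relative-collection photometry, and
  photobleaching statistics.
- **`dopm.synthetic`** — seed-deterministic generators for bead phantoms,
  thin sheets, dual-view oblique acquisitions and bleaching time series.

## CLI

Every model is exposed through the `dopm` command:

```bash
# aperture report (solid angles, effective NAs, geometric RCE)
dopm geometry --angle 35 --regime static --out report.json

# vectorial ray trace with a protected-silver mirror
dopm trace --angle 35 --mirror silver_sio2 --regime static \
    --rays 15000 --dipoles 7500 --out eff.json --pupil pupil.tif

# widefield vs dual-view light-sheet dose ratio
dopm dose --planes 151 --spacing 1.0 --sheet-fwhm 3.0 --rc 0.23 --out dose.json

# synthetic dual-view pipeline
dopm simulate acquisition --out acq/ --angle 35 --n 20 --seed 1
dopm deskew --in acq/view1.tif --angle 35 --view 1 \
    --scan-step 0.1 --pixel-row 0.174 --pixel-col 0.1 --out lab1.ome.tif
dopm deskew --in acq/view2.tif --angle 35 --view 2 \
    --scan-step 0.1 --pixel-row 0.174 --pixel-col 0.1 --out lab2.ome.tif
dopm fuse --v1 lab1.ome.tif --v2 lab2.ome.tif --out fused.ome.tif

# metrology
dopm beads --in fused.ome.tif --out beads.csv --summary summary.json
dopm simulate sheet --out sheet.ome.tif --fwhm 3.0
dopm sheet --in sheet.ome.tif --out sectioning.json
```

(`simulate acquisition` writes the sampling intervals it used to
`acq/params.json`; pass the same values to `deskew`.)

A system can also be described in YAML and passed with `--config`:

```yaml
objectives:
  primary: {na: 1.2, index: 1.333}
  secondary_tertiary: {na: 0.95, index: 1.0, transmission: 0.9}
opm_angle_deg: 35.0
t_pbs: 0.8
coating: silver_sio2
```

## Conventions

- Lab frame: z is distance from the coverslip; the optical axis of the
  primary objective is +z; the fold mirror tilts in the x–z plane; the two
  views shear in opposite senses along the scan axis y.
- Raw oblique stacks index (scan frame, camera row, camera column); voxel
  (i, r, c) sits at x = c·px, y = y₀ + i·Δy ± r·pr·cosθ, z = r·pr·sinθ.
- Angles are degrees at API boundaries; NAs are never rounded internally.
- All random generators take explicit seeds; simulations are reproducible
  bit-for-bit.
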