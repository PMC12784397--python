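# solls

A desk-scale simulation and analysis toolkit for **single-objective
lattice light-sheet (soLLS) microscopy** and the single-molecule
localization pipeline built around it.

Light-sheet illumination confines excitation to the detection focal
plane, which raises the signal-to-background ratio (SBR) of
single-molecule localization microscopy and limits photodamage.  A
*lattice* light sheet — a coherent array of Bessel-like beamlets
generated by a multi-slit photomask in the objective's back focal plane
(BFP) — holds its thin profile over a longer propagation range than a
Gaussian sheet of the same focal thickness, and in a single-objective
geometry the sheet is launched and the fluorescence detected through
one high-NA objective, with a micromirror inside a microfluidic chip
folding the sheet into the sample plane.

The package models that optical chain and the downstream analysis:

- **`solls.fields`** — scalar Fourier optics: angular-spectrum
  propagation, ideal-lens 2f Fourier mapping, beam-volume synthesis,
  TIFF+YAML volume I/O.
- **`solls.beams`** — slit-mask lattice sheets and cylindrical-lens
  Gaussian sheets, sine-dwell dithering, calibrated galvo/tunable-lens
  steering, micromirror reflection.
- **`solls.metrics`** — 1/e² thickness fits, thickness-vs-propagation
  curves, the √2 effective range, maximum-intensity projections.
- **`solls.scatter`** — split-step propagation through random
  phase-screen media with absorbing beads; self-healing comparisons.
- **`solls.smlm`** — synthetic single-molecule movies: emitter
  phantoms, Gaussian and double-helix (DH) PSFs, EMCCD noise with
  calibrated gains (EM gain 182, 4.41 e⁻/count, dark level 500).
- **`solls.localize`** — wavelet spot detection, weighted
  least-squares Gaussian and double-Gaussian DH fitting, EMCCD
  localization precision, fiducial drift correction, rule-based
  filtering, 0.75× axial rescaling, region statistics, SBR, Fourier
  ring correlation (FRC) resolution.
- **`solls.config` / `solls.cli`** — YAML run configurations, the
  end-to-end pipeline, and the `solls` command-line tool.

## The core quantities

A light sheet of 1/e² focal thickness `w0` is useful while its
thickness stays close to `w0`.  Following the confocal parameter of a
Gaussian beam, the **effective range** is the longest contiguous
propagation interval containing the waist over which the fitted 1/e²
thickness satisfies

```
w(x) ≤ √2 · w0
```

For an ideal Gaussian sheet this equals `2·z_R = 2π·n·w0²/λ`
(48.3 µm for `w0 = 1.8 µm`, `n = 1.33`, `λ = 560 nm`).  The lattice
sheet, built from the default 3-slit mask (slit width 0.08 mm, outer
separation 2.4 mm, auto-scaled to the same 1.8 µm focal thickness and
dithered along its width), propagates substantially further.

Localization precision uses a least-squares expression for EMCCD
detection with the shot-noise term doubled by the electron-multiplying
excess noise factor:

```
σ² = 2 · σₐ²/N · (16/9 + 8π·σₐ²·b / (N·a²)),   σₐ² = σ_PSF² + a²/12
```

with `N` signal photons, `b` background photons/pixel and `a` the
camera pixel size.

## Worked example

```python
from solls import (MaskSpec, OpticalTrain, SheetSpec,
                   make_lattice_sheet, make_gaussian_sheet)
from solls.metrics import thickness_curve, effective_range

train = OpticalTrain()                      # NA 1.45, f = 1.8 mm, 560 nm, water
lattice = make_lattice_sheet(MaskSpec(), train, SheetSpec(family="lattice"))
gaussian = make_gaussian_sheet(SheetSpec(family="gaussian"), train)

for name, vol in [("lattice", lattice), ("gaussian", gaussian)]:
    prof = thickness_curve(vol)
    print(f"{name:8s} waist {prof.waist_w0:.3f} um, "
          f"range {effective_range(prof):.1f} um")
```

prints

```
lattice  waist 1.789 um, range 89.3 um
gaussian waist 1.802 um, range 47.9 um
```

Both sheets are constructed with a 1.8 µm 1/e² focal thickness; the
Gaussian sheet's 47.9 µm range matches its confocal parameter
(48.3 µm) and the lattice sheet holds the same thickness 1.86× longer.
The same objects feed the rest of the pipeline, e.g. a full
simulate → localize → filter → statistics run:

```sh
solls pipeline --seed 1 --outdir demo_run
solls simulate-beam --family lattice --waist-um 1.8 --mirror-deg 39 --out beam.tif
solls metrics --in beam.tif --mode symmetric --report metrics.yaml
```

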