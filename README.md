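# semmorph

Morphometry of neuronal ultrastructure in scanning-electron-microscopy
(SEM) images — built for quantifying axons, cell bodies and compact-myelin
lamellae in vitrified central-nervous-system tissue, where structures span
four orders of magnitude (tens of nm of myelin period to tens of µm of
soma diameter) and every measurement must be physical, not in pixels.

The pipeline mirrors how such micrographs are analysed:

1. **Wavelet denoising** — 2-D DWT (default Daubechies-4, 3 levels) with
   soft shrinkage at the universal threshold σ√(2 ln N), σ from the MAD of
   the finest diagonal band, preserving membrane-scale detail that plain
   smoothing destroys.
2. **ROI extraction** — region-based (two-phase Chan–Vese) active contour
   from an Otsu initialization filters the background.
3. **Fuzzy segmentation** — fuzzy c-means minimizing
   Σᵢₖ uᵢₖᵐ‖xᵢ−cₖ‖² with deterministic quantile initialization, plus a
   progressive refinement pass that resolves low-confidence pixels from
   their spatial context.
4. **Morphometry** — per-object area (pixel count × pixel area), mean
   Feret diameter (180 directions), tube diameter (2 × distance transform
   along the medial axis), FWHM wall thickness; size classes by the exact
   1-D least-squares k-partition (dynamic programming, no random init);
   mean / SD (n−1) / SEM summaries.
5. **Lamellae periodicity** — radial intensity profiles around an annular
   ROI, band-limited periodogram (5–20 nm default), peak counting and
   major-dense / intraperiod amplitude classification.

A synthetic scene generator renders tubes, somata, multilamellar rings and
filament textures with exact ground truth (masks + true parameters) under
a blur → Poisson → Gaussian → gradient noise chain, so every stage is
validated against analytic oracles without real micrographs. A small
atom% ↔ mass% converter supports EDS composition bookkeeping.

## Worked example

```python
import semmorph as sm
from semmorph.morphometry import (load_reference_axon_diameters,
                                  load_reference_cell_bodies)

# bundled reference tables (comma-decimal CSVs, parsed to floats)
ax = load_reference_axon_diameters()
brain = ax.loc[ax.compartment == "brain", "diameter_nm"]
mean, sd, sem = sm.summarize_group(brain)
print(f"brain axons: {mean:.1f} +/- {sem:.1f} nm (SEM), SD {sd:.1f} nm")

cb = load_reference_cell_bodies()
labels = sm.classify_size_groups(cb["diameter_um"].to_numpy(), 3)
for g in ("1A", "1B", "1C"):
    m, s, e = sm.summarize_group(cb.loc[labels == g, "diameter_um"])
    print(f"group {g}: n={int((labels==g).sum()):2d}  diameter {m:.2f} +/- {e:.3f} um")

# synthetic compact myelin: 6 lamellae, 11 nm period, noisy
ring = sm.LamellarRing(center=(200, 200), inner_radius_nm=80, n_layers=6,
                       period_nm=11, amplitude_ratio=0.6, contrast=0.5)
image, truth = sm.generate_scene([ring], sm.NoiseModel(gaussian_sigma=0.03),
                                 (400, 400), pixel_size=1.0, seed=7)
res = sm.count_myelin_layers(image, sm.ROI(truth.records[0].mask))
print(f"lamellae: {res.n_layers} layers, period {res.period_nm:.2f} nm")
```

prints

```
brain axons: 717.7 +/- 24.0 nm (SEM), SD 93.1 nm
group 1A: n= 2  diameter 14.17 +/- 1.655 um
group 1B: n= 4  diameter 8.06 +/- 0.324 um
group 1C: n=13  diameter 2.72 +/- 0.279 um
lamellae: 6 layers, period 10.96 nm
```

The 15 brain-axon diameters summarize to 717.7 ± 24.0 nm; the exact size
partition splits the 19 cell bodies into classes of 2, 4 and 13 with mean
diameters 14.17, 8.06 and 2.72 µm; and the lamellae detector recovers all
six layers of the simulated sheath with the period within half a
nanometre of the generating 11 nm, alternating major-dense and
intraperiod lines.

## Command line

```sh
semmorph simulate scene.yaml --out sim/     # render a synthetic scene + truth
semmorph measure config.yaml                # denoise→segment→measure→group
semmorph lamellae img.tif --pixel-size 1.0  # myelin layer count & period
semmorph report groups.csv                  # plain-text summary table
```

Calibration (nm/pixel) is always explicit — there is no default pixel
size. See `docs/methods.md` for the models, defaults and limitations.

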