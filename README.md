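# filotwist

Quantitative modelling and image analysis of filopodial actin bundles.

Growth-cone filopodia are supported by hexagonally packed bundles of
actin filaments.  Near the filopodium base, cofilin can saturate these
filaments, converting them to **cofilactin**: the filament over-twists
from −166.6° to −162.1° per subunit, which shortens the apparent
helical crossover from ~37 nm to ~28 nm, and the bundle repacks — the
filaments sit closer together (11.5 nm vs 12.3 nm in fascin-linked
bundles) with every other column rotated 90° about its axis, so the
width modulations of neighbouring filaments run out of phase.
`filotwist` implements the measurements behind those observations as a
tested pipeline, together with a ground-truthed synthetic-data
generator, so every stage can be validated by parameter recovery.

## The model

A filament is a helix of subunits with axial rise `h` (nm) and signed
per-subunit twist `φ` (degrees; negative = left-handed).  Because `|φ|`
is close to 180°, projections show two apparent long-pitch strands that
cross over every

```
L = h · 180 / (180 − |φ|)      [nm]
```

so cofilactin (h = 2.76 nm, φ = −162.1°) gives L ≈ 27.75 nm and bare
F-actin (φ = −166.6°) L ≈ 37.07 nm.  Rolling a filament about its own
axis by `ρ` degrees advances its apparent width modulation by
`L·ρ/180`: the 90° column alternation of cofilactin bundles puts
neighbours half a crossover out of phase.

The package covers, module by module:

- **`helix`** — helical parameters, subunit placement along arbitrary
  centerlines (parallel-transported frames), hexagonal bundle
  construction with roll alternation, pseudo-atomic/atomic decoration
  and contact analysis (closest approach, named-residue distances).
- **`synth`** — synthetic tomograms (Gaussian-blob rendering, seeded
  noise at a chosen SNR, Fourier missing wedge) and two-channel
  filopodium movies (cofilin-bright base fraction, seeded base/tip
  wobble), all with serialized ground truth.
- **`tomo`** — centerline tracing (threshold → 3D skeleton → path
  decomposition with an 8 nm minimum interfilament distance),
  nearest-neighbour spacing with a single-pass ±3 SD outlier filter,
  width-modulation signals, crossover/pitch estimation, neighbour phase
  offsets, filament/bundle classification, and a simplified helical
  subtomogram average.
- **`fluor`** — line-scan profiles and their correlation, Costes
  thresholds, Pearson colocalization, transition-region detection,
  cofilin base fraction, windowed maximum-intensity projections, three
  width measurements and the two-fold resting/searching rule.
- **`cli` / `io`** — `filotwist` command-line entry points and
  MRC/TIFF/CSV/JSON/PDB round-tripping.

## Worked example

Simulate a 19-filament cofilactin bundle at SNR 4, then analyze the
volume with no knowledge of the ground truth:

```
$ filotwist simulate-bundle --preset cofilactin --n-rings 2 \
      --length 150 --snr 4 --seed 1 --out-dir demo/sim
INFO filotwist: wrote demo/sim/bundle.mrc ((60, 66, 166) voxels)

$ filotwist analyze-tomo demo/sim/bundle.mrc --out-dir demo/tomo
INFO filotwist: NN spacing 11.43 nm over 1992 points; bundle pure_cofilactin
```

The analysis traced 19 centerlines, measured a post-filter mean
nearest-neighbour spacing of 11.43 nm (ground truth 11.5 nm), estimated
a determinate crossover for all 19 filaments (mean 26.98 nm, truth
27.75 nm) and classified the bundle `pure_cofilactin`.  Per-point
distances, histograms, pitch estimates and the resolved configuration
are written as CSV/JSON next to the volume.

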