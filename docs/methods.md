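# Methods

## Helical geometry

A filament is parameterized by the per-subunit axial rise `h` (nm) and
signed azimuthal twist `φ` (deg); negative twist is a left-handed
genetic helix.  Presets: bare/fascin-linked F-actin `(2.76 nm, −166.6°)`
and cofilactin `(2.76 nm, −162.1°)`.  Ångström values are accepted at
the boundary and converted; internally everything tomographic is nm and
degrees, fluorescence quantities are µm (matching how the two kinds of
data are usually reported).

The apparent crossover length is `L = h·180/(180 − |φ|)`, the axial
distance over which the two apparent long-pitch strands cross once.  It
is undefined at `φ = 0` and `|φ| = 180°`; both are rejected.  `φ = 0`
(an untwisted "ribbon") is still a legal geometry for every other
operation and serves as a flat-signal control.

Subunits are placed every `h` nm along the centerline, with azimuth
`roll + phase + i·φ`.  Along curved centerlines the normal frame is
parallel-transported (double-reflection rotation-minimizing frames), so
the azimuth acquires no spurious drift from centerline bending; bundle
models in practice use straight filaments, and the transported frames
reduce exactly to the fixed frame there.

`subunit_radius` (default 1.6 nm, a typical offset of the actin subunit
centre of mass from the filament axis) controls only the amplitude of
the rendered width modulation, not its period, and is exposed in the
configuration.

## Hexagonal bundles

A bundle of `r` rings has `1 + 3r(r+1)` straight parallel filaments at
lattice constant `a` (presets: 12.3 nm fascin-linked, 11.5 nm
cofilactin).  Lattice coordinates are (column, layer); with the
`column_roll_90` alternation every other column *within a layer* is
rolled 90° about its own axis, which by `shift = L·roll/180` puts
adjacent columns half a crossover out of phase — the packing signature
of cofilactin bundles.  Axial phase offsets between columns default to
0 and are configurable; filaments run along x, with z the tomographic
viewing axis.

## Decoration and contacts

Each subunit frame can carry either a single pseudo-atom at a
configurable radial offset (default 4.5 nm, a coarse stand-in for the
outer cofilin centroid with no measured anchor) or a rigidly
transformed copy of an atomic repeating unit read from PDB/mmCIF
(gemmi).  Chains are classified actin/cofilin by length (≥250 residues
= actin) unless explicit chain lists are given; the unit is
canonicalized assuming the deposited helix axis runs along z.  Contact
analysis reports per-pair minimum distances (KD-trees, verified against
brute force in the tests), whether the arg-min pair is same-layer or
cross-layer, and representative-atom distances between named residues
(default Cα) for the closest decoration pair on each interface; ties
break toward the lowest filament-id pair, then lowest subunit index.
Both all-atom and Cα minima can be obtained by decorating with and
without atom selection.  No rigid-body fitting into experimental maps
and no steric/energetic scoring is attempted — only distances are
reported.

## Synthetic tomograms

Volumes are sums of isotropic Gaussian blobs (σ = 2 nm) at the subunit
positions — a deliberately coarse forward model that still produces the
two signals the analyses consume: the width modulation at the crossover
period and the hexagonal packing at the lattice constant.  The default
voxel is 1.0 nm (experimental pixel-size presets of 0.4306/0.3326 nm
are available but slower); rendering rejects voxels ≥ blob σ as
undersampled.  Corruption adds Gaussian noise scaled so
var(signal)/var(noise) equals the requested SNR, then optionally zeroes
the Fourier wedge within a half-angle of the beam axis (±60° tilt ↔ 30°
half-angle).  All generators are seed-deterministic and their ground
truth serializes to JSON.

What the generator does *not* emulate: atomic scattering contrast, CTF,
reconstruction artefacts beyond the ideal missing wedge, filament
elasticity, or crowding by other cellular material.  Passing recovery
tests therefore demonstrate correctness of the measurement pipeline
under the stated geometry and noise model, not robustness to every
property of real tomograms.

## Tomographic measurements

**Tracing.**  Otsu threshold on a lightly smoothed volume → 3D
skeletonization → per-component longest path (exact on tree-like
skeletons) → duplicate suppression: a path lying within the 8 nm
minimum interfilament distance of a longer path over >50% of its length
is merged into it.  Each polyline is boxcar-smoothed (20 nm), then
re-centred on the local in-plane density centre of mass and smoothed
again.  The refinement matters quantitatively: raw skeletons ride the
helical density ridge and are voxel-quantized, and because every point
takes the *minimum* distance over ~6 neighbours, zero-mean wander
rectifies into a systematic ~0.2 nm underestimate of the lattice
constant; with refinement the recovered spacing is within ~0.1 nm of
truth at SNR 4.

**Nearest neighbours.**  Centerlines are resampled at 1.0 nm (the
spacing is configurable; the mean spacing of straight bundles is
insensitive to it) and, for every point, the distance to the nearest
point on any other filament is accumulated.  The outlier filter is a
single pass: bounds `mean ± k·SD` (default k = 3) computed on the
pre-filter data, with pre-filter statistics preserved for provenance.
An `interior_only` mode drops 5% of points at each polyline end; edge
effects are negligible for straight bundles, so the default keeps all
points.

**Width signal and pitch.**  At each axial sample the density in the
plane normal to the local tangent is projected along the viewing axis
(z, the tomographic slice convention) and the apparent half-width is
the second-moment spread of that profile — robust to noise and
period-preserving, unlike edge detection.  The probe half-window is
5 nm: full filament half-width, but hexagonal neighbours (≥ ~11 nm)
stay outside.  Crossovers are estimated from the spacings of successive
wide points: peaks are located with a prominence gate (0.5 signal SD)
at a minimum separation of 0.6 of the dominant spectral period (FFT
zero-padded 8× so short signals do not quantize the period), peaks
within a quarter-period of the signal ends are discarded as truncated,
and the surviving positions are refined by parabolic interpolation.
The estimate reports per-crossover lengths, mean, SEM and the spectral
period as a cross-check; fewer than two usable peaks flags it
indeterminate.  Phase offsets between two filaments are taken from the
phase of each signal's Fourier component at the crossover period
(equivalent to circular cross-correlation restricted to that period),
folded into [0, 0.5]; signals whose dominant periods differ by more
than 10% are not comparable and are rejected.

**Classification.**  Crossover < 31 nm → cofilactin, > 33 nm → actin,
between → indeterminate.  The dead zone sits at the midpoint of the two
populations (~27.9 and ~37.1 nm), separating them by more than twice
the per-filament spread observed in recovery runs.  A bundle is pure
only if all determinate members agree; otherwise mixed, with label
fractions.

**Helical averaging.**  Subvolumes are resampled on the subunit frames
(extraction in the frame is simultaneously the counter-rotation by
`i·φ` and counter-translation by `i·h`), then averaged; frames whose
box would cut the filament ends are skipped.  On noisy input the
average's correlation to a clean reference exceeds any single
particle's; a mismatched twist smears the azimuth and flattens the
width modulation of the average, which is the diagnostic reported
(`modulation_amplitude_nm`).  Orientations come from the supplied
centerline — no alignment search, CTF handling or multi-reference
classification.

## Fluorescence measurements

Line profiles average across a perpendicular width (default 3 px) and
normalize each channel to its own maximum over the profile (the
normalization rule is recorded).  The profile correlation is plain
Pearson; the inverse cofilin/actin gradient of a cofilactin-based
filopodium makes it negative.  Costes thresholds: orthogonal (total
least squares) regression of channel 2 on channel 1, candidate
thresholds stepped down from the maximum in 1% decrements of the
intensity range until the below-both-thresholds pixels have Pearson
≤ 0; non-convergence returns the channel minima with a flag.
Colocalization is Pearson over above-threshold pixels, reported with
the pixel count.

The transition region is the maximal contiguous interval where both
normalized channels are ≥ 50% of their maxima — a documented stand-in,
exposed in the configuration, for a definition that is not fully
specified in the public record.  The cofilin base fraction is the
distal end of the first cofilin-above-50% run, measured from the
proximal end, over the total length; batch mode reports mean ± SEM and
groups bundle lengths by the presence of a base.

Motility: maximum-intensity projections over tiling 40-frame windows
(2 min at 3 s/frame); per channel the MIP is Otsu-thresholded (a
parameter-free, reproducible substitute for manual inspection) and the
width at each axial station is the above-threshold extent along the
perpendicular.  The cofilin width is the maximum over cofilin-dominant
stations (normalized cofilin > normalized actin), the actin width the
maximum over actin-dominant stations distal to the cofilin region, and
the inflection width is measured where the two normalized signals meet.
Searching ⇔ actin width ≥ 2× cofilin width; a zero cofilin width counts
as searching whenever any actin width was measured.

## Movie generator

A filopodium is an anchored two-segment line source: base segment from
anchor to the hinge at `cofilin_fraction` of the length (default 0.353,
the mean proximal cofilin coverage of growth-cone filopodia), distal
segment from hinge to tip.  Lateral displacements of hinge and tip
follow stationary AR(1) walks (frame-to-frame correlation 0.9) with the
`base_wobble` / `tip_wobble` amplitudes; the phenotype intent is
searching when tip ≥ 2× base amplitude.  The actin channel covers the
full length and rises linearly toward the tip (default 40% base
brightness), the cofilin channel covers only the base fraction.  Images
are line sources convolved with a Gaussian PSF (σ = 100 nm at 50 nm
pixels — an Airyscan-like scale; the movies' true pixel size is not on
record) with Poisson photon noise and Gaussian read noise; photon noise
can be disabled for noise-free controls.  The wobble statistics of real
filopodia are uncharacterized; the AR(1) model is a stand-in with all
parameters exposed.

## Problem sizes and defaults

Recovery runs use 2-ring (19-filament) bundles 100 nm long at SNR 4
over three seeds for the lattice constants, an 11.5-crossover single
filament for pitch estimation, 160 nm 7-filament bundles for the
classification panel, and 40-frame movies for the motility panel —
sizes at which every estimate is stable to well within its acceptance
tolerance while the whole suite stays fast on a single CPU.

## Known limitations

- Tracing assumes bright, roughly tubular filaments on a darker
  background; it is not a general curvilinear-structure segmenter and
  deliberately replaces the neural-network/commercial tracing stack
  with threshold + skeleton + the same 8 nm rule.
- The atomic canonicalization assumes the deposited fibril axis is the
  z axis through the origin; models with other conventions need an
  explicit axis.
- Phase comparison requires both filaments to share a crossover period
  within 10%; actin–cofilactin phase relations are undefined by
  construction.
- The classification dead zone (31–33 nm) means heavily but not fully
  decorated filaments with intermediate twist are reported
  indeterminate rather than forced into a class.
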