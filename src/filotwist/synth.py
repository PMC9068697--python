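"""Ground-truthed synthetic data: tomogram-like density volumes of
filament bundles and two-channel filopodium movies.

Volumes are rendered as sums of isotropic Gaussian blobs centred on
helical subunit positions -- a deliberately coarse forward model that
nevertheless reproduces the two observables the tomographic analyses
consume: the apparent width modulation at the crossover period, and the
hexagonal packing at the lattice constant.  Volumes can then be
corrupted with Gaussian noise at a chosen SNR and an optional Fourier
missing wedge mimicking a limited (+/-60 deg) tilt range.

Movies emulate growth-cone filopodia imaged in two channels (cofilin
and an F-actin reporter) every few seconds: a line source convolved
with a Gaussian PSF plus Poisson/read noise, with the cofilin channel
bright over the proximal base fraction and seeded smooth random walks
wobbling the base and tip laterally about a hinge at the
cofilin-to-actin transition point.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .helix import BundleSpec, FilamentSpec, place_subunits

__all__ = [
    "DensityVolume",
    "MovieScene",
    "GroundTruth",
    "render_volume",
    "corrupt_volume",
    "make_centerline",
    "simulate_movie",
]


# ---------------------------------------------------------------------------
# Density volumes
# ---------------------------------------------------------------------------

@dataclass
class DensityVolume:
    """3D scalar field on an isotropic grid.

    ``data`` is indexed ``[z, y, x]``; ``origin`` is the nm position of
    the grid corner, with voxel centres at ``origin + (i + 0.5) * voxel``.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("volume must be a non-empty 3D grid")

    @property
    def shape(self):
        return self.data.shape

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (z, y, x) voxel-index coordinates of nm points."""
        xyz = np.atleast_2d(xyz)
        idx = (xyz - self.origin) / self.voxel_size - 0.5
        return idx[:, ::-1]

    def index_to_world(self, zyx: np.ndarray) -> np.ndarray:
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        return self.origin + (zyx[:, ::-1] + 0.5) * self.voxel_size


def render_volume(
    bundle: BundleSpec,
    voxel_size: float = 1.0,
    padding: float = 8.0,
    blob_sigma: float = 2.0,
    n_subunits: int | None = None,
) -> DensityVolume:
    """Render a bundle as a sum of Gaussian blobs (sigma ~ 2 nm), one per
    subunit, noise-free.

    The helical placement of the blobs makes the projected filament
    width oscillate with the crossover period, and total density scales
    linearly with subunit count.
    """
    if voxel_size >= blob_sigma:
        raise ValueError(
            f"voxel_size {voxel_size} nm undersamples blobs of sigma "
            f"{blob_sigma} nm"
        )
    centres = []
    for fil in bundle.filaments:
        for f in place_subunits(fil, n=n_subunits):
            centres.append(f.position)
    if centres:
        centres = np.asarray(centres)
        lo = centres.min(axis=0) - padding
        hi = centres.max(axis=0) + padding
    else:
        centres = np.zeros((0, 3))
        lo, hi = np.zeros(3), np.ones(3)

    shape = np.maximum(np.ceil((hi - lo) / voxel_size).astype(int), 1)
    vol = np.zeros(shape[::-1], dtype=np.float32)  # (z, y, x)
    reach = int(math.ceil(4 * blob_sigma / voxel_size))
    axes = [
        (np.arange(shape[k]) + 0.5) * voxel_size + lo[k] for k in range(3)
    ]
    for c in centres:
        ic = ((c - lo) / voxel_size - 0.5).round().astype(int)
        sl = []
        local = []
        for k in range(3):
            a = max(ic[k] - reach, 0)
            b = min(ic[k] + reach + 1, shape[k])
            sl.append(slice(a, b))
            local.append(axes[k][a:b] - c[k])
        gx = np.exp(-0.5 * (local[0] / blob_sigma) ** 2)
        gy = np.exp(-0.5 * (local[1] / blob_sigma) ** 2)
        gz = np.exp(-0.5 * (local[2] / blob_sigma) ** 2)
        vol[sl[2], sl[1], sl[0]] += (
            gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        )
    return DensityVolume(data=vol, voxel_size=voxel_size, origin=lo)


def corrupt_volume(
    vol: DensityVolume,
    snr: float | None = None,
    wedge_halfangle: float | None = None,
    seed: int = 0,
) -> DensityVolume:
    """Additive Gaussian noise at the requested variance SNR plus an
    optional Fourier missing wedge.

    ``snr`` is var(signal)/var(noise) over the volume; ``None`` means
    noise-free.  The wedge zeroes Fourier components within
    ``wedge_halfangle`` degrees of the beam axis (z) in the x-z plane,
    as a +/-(90 - halfangle) deg tilt series about the y axis would.
    Same seed, same output.
    """
    data = vol.data.astype(np.float32).copy()
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        noise_sd = float(data.std()) / math.sqrt(snr)
        data = data + rng.normal(0.0, noise_sd, size=data.shape).astype(np.float32)
    if wedge_halfangle is not None and wedge_halfangle > 0:
        F = np.fft.rfftn(data)
        kz = np.fft.fftfreq(data.shape[0])[:, None, None]
        kx = np.fft.rfftfreq(data.shape[2])[None, None, :]
        with np.errstate(invalid="ignore"):
            ang = np.degrees(np.arctan2(np.abs(kx), np.abs(kz)))
        wedge = ang < wedge_halfangle
        wedge[0, :, 0] = False  # keep DC
        F = F * ~wedge
        data = np.fft.irfftn(F, s=data.shape, axes=(0, 1, 2)).astype(np.float32)
    return DensityVolume(data=data, voxel_size=vol.voxel_size, origin=vol.origin.copy())


# ---------------------------------------------------------------------------
# Centerline shapes
# ---------------------------------------------------------------------------

def make_centerline(kind: str, spacing: float = 0.5, **params) -> np.ndarray:
    """Polyline generators for filament/filopodium geometry.

    kinds: ``straight(length)``, ``arc(radius, sweep_deg)``,
    ``sine(length, amplitude, wavelength)``,
    ``kink(angle_deg, arm_length)``.  Points lie in the x-y plane with
    the main axis along +x; ~``spacing`` nm apart.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if kind == "straight":
        L = params["length"]
        if L <= 0:
            raise ValueError("length must be positive")
        n = max(2, int(round(L / spacing)) + 1)
        t = np.linspace(0, L, n)
        return np.column_stack([t, np.zeros(n), np.zeros(n)])
    if kind == "arc":
        r, sweep = params["radius"], params["sweep_deg"]
        if r <= 0 or sweep <= 0:
            raise ValueError("radius and sweep must be positive")
        L = r * math.radians(sweep)
        n = max(2, int(round(L / spacing)) + 1)
        th = np.linspace(0, math.radians(sweep), n)
        return np.column_stack([r * np.sin(th), r * (1 - np.cos(th)), np.zeros(n)])
    if kind == "sine":
        L, amp, wl = params["length"], params["amplitude"], params["wavelength"]
        if L <= 0 or wl <= 0:
            raise ValueError("length and wavelength must be positive")
        n = max(2, int(round(L / spacing)) + 1)
        t = np.linspace(0, L, n)
        return np.column_stack(
            [t, amp * np.sin(2 * math.pi * t / wl), np.zeros(n)]
        )
    if kind == "kink":
        ang, arm = params["angle_deg"], params["arm_length"]
        if arm <= 0:
            raise ValueError("arm_length must be positive")
        n = max(2, int(round(arm / spacing)) + 1)
        t = np.linspace(0, arm, n)
        first = np.column_stack([t, np.zeros(n), np.zeros(n)])
        # deflection from straight-on by (180 - angle): interior angle = angle_deg
        d = math.radians(180.0 - ang)
        dirv = np.array([math.cos(d), math.sin(d), 0.0])
        second = first[-1] + np.outer(t[1:], dirv)
        return np.vstack([first, second])
    raise ValueError(f"unknown centerline kind {kind!r}")


# ---------------------------------------------------------------------------
# Filopodium movies
# ---------------------------------------------------------------------------

@dataclass
class MovieScene:
    """Parameters of a synthetic two-channel filopodium movie.

    Defaults mirror live growth-cone imaging: 3 s frame interval, a
    cofilin-rich base covering 35.3% of the filopodium from its proximal
    end, 50 nm pixels and a ~100 nm PSF sigma.  ``base_wobble`` and
    ``tip_wobble`` are stationary lateral amplitudes (nm) of smooth
    seeded random walks; a resting filopodium has base >> tip wobble, a
    searching one the reverse.
    """

    frames: int = 200
    interval_s: float = 3.0
    length_um: float = 5.0
    cofilin_fraction: float = 0.353
    base_wobble: float = 100.0
    tip_wobble: float = 100.0
    pixel_size_nm: float = 50.0
    psf_sigma_nm: float = 100.0
    photons: float | None = 200.0  # None disables photon noise
    read_noise: float = 2.0
    #: proximal-to-distal rise of the actin reporter: intensity at the
    #: base is (1 - actin_gradient) of the tip value, reproducing the
    #: inverse cofilin/actin gradient of real filopodia
    actin_gradient: float = 0.6
    wobble_corr: float = 0.9  # frame-to-frame correlation of the walks
    shape: tuple[int, int] = (64, 128)  # (H, W) pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.cofilin_fraction <= 1:
            raise ValueError("cofilin_fraction must lie in [0, 1]")
        if self.frames < 1:
            raise ValueError("need at least one frame")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)  # JSON-canonical
        return d


@dataclass
class GroundTruth:
    """Exact generator inputs plus derived true values; seed included so
    regeneration is bit-identical."""

    kind: str
    spec: dict
    derived: dict
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _smooth_walk(rng, n: int, amplitude: float, corr: float) -> np.ndarray:
    """Stationary AR(1) walk with sd = amplitude."""
    if amplitude == 0:
        return np.zeros(n)
    x = np.empty(n)
    x[0] = rng.normal(0, amplitude)
    innov_sd = amplitude * math.sqrt(1 - corr**2)
    for i in range(1, n):
        x[i] = corr * x[i - 1] + rng.normal(0, innov_sd)
    return x


def simulate_movie(scene: MovieScene):
    """Render the movie; returns ``(stack, truth)`` with stack shape
    ``(frames, 2, H, W)``, channel 0 = actin (full length), channel 1 =
    cofilin (proximal base fraction only).

    Per frame the filopodium is an anchored two-segment polyline: the
    base segment tilts so the hinge (at ``cofilin_fraction`` of the
    length) is displaced laterally by the base walk, and the tip segment
    adds the tip walk on top.  Line sources are convolved with the PSF
    and corrupted with Poisson photon noise plus Gaussian read noise.
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(scene.seed)
    H, W = scene.shape
    px = scene.pixel_size_nm
    L = scene.length_um * 1000.0
    frac = scene.cofilin_fraction
    anchor = np.array([0.1 * W * px, 0.5 * H * px])  # (x, y) nm

    base_walk = _smooth_walk(rng, scene.frames, scene.base_wobble, scene.wobble_corr)
    tip_walk = _smooth_walk(rng, scene.frames, scene.tip_wobble, scene.wobble_corr)

    stack = np.empty((scene.frames, 2, H, W), dtype=np.float32)
    hinge_s = frac * L
    n_samp = max(int(L / (px / 2.0)), 2)
    s = np.linspace(0, L, n_samp)
    for t in range(scene.frames):
        # piecewise-linear lateral displacement: 0 at anchor, base_walk at
        # hinge, base+tip at the tip
        if frac > 0:
            lat = np.where(
                s <= hinge_s,
                base_walk[t] * (s / max(hinge_s, 1e-9)),
                base_walk[t] + tip_walk[t] * (s - hinge_s) / max(L - hinge_s, 1e-9),
            )
        else:
            lat = tip_walk[t] * s / L
        x = anchor[0] + s
        y = anchor[1] + lat
        ix = np.clip((x / px).astype(int), 0, W - 1)
        iy = np.clip((y / px).astype(int), 0, H - 1)
        for ch in range(2):
            img = np.zeros((H, W), dtype=np.float32)
            keep = s <= (L if ch == 0 else hinge_s)
            if keep.any():
                if ch == 0:  # actin rises toward the tip
                    wgt = (1.0 - scene.actin_gradient) + scene.actin_gradient * (
                        s[keep] / L
                    )
                else:
                    wgt = np.ones(keep.sum())
                np.add.at(img, (iy[keep], ix[keep]), wgt.astype(np.float32))
            img = gaussian_filter(img, scene.psf_sigma_nm / px)
            if img.max() > 0:
                img /= img.max()
            if scene.photons is None:  # noise-free rendering
                counts = img.astype(np.float32)
            else:
                counts = rng.poisson(img * scene.photons).astype(np.float32)
            if scene.read_noise > 0:
                counts += rng.normal(0, scene.read_noise, size=img.shape).astype(
                    np.float32
                )
            stack[t, ch] = counts
    truth = GroundTruth(
        kind="movie",
        spec=scene.to_dict(),
        derived={
            "base_walk_nm": base_walk.tolist(),
            "tip_walk_nm": tip_walk.tolist(),
            "hinge_s_nm": hinge_s,
            "length_nm": L,
            "intended_phenotype": (
                "searching"
                if scene.tip_wobble >= 2 * scene.base_wobble
                else "resting"
            ),
        },
        seed=scene.seed,
    )
    return stack, truth


def bundle_ground_truth(bundle: BundleSpec, seed: int = 0) -> GroundTruth:
    """GroundTruth record for a rendered bundle (true crossover lengths,
    lattice constant, per-filament labels)."""
    from .helix import crossover_length

    return GroundTruth(
        kind="bundle",
        spec=bundle.to_dict(),
        derived={
            "lattice_constant_nm": bundle.lattice_constant,
            "crossover_nm": {
                f.id: crossover_length(f.params) for f in bundle.filaments
            },
            "labels": {f.id: f.params.label for f in bundle.filaments},
        },
        seed=seed,
    )
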