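"""End-to-end workflows tying the generator and the analyses together.

These are the entry points the CLI and the reproduction script use: each
one goes synthetic bundle -> rendered/corrupted volume -> measurement,
so every reported number is recomputed from scratch.
"""

from __future__ import annotations

import numpy as np

from .config import BUNDLE_PRESETS
from .helix import COFILACTIN, HelicalParams, build_hexagonal_bundle
from .synth import DensityVolume, bundle_ground_truth, corrupt_volume, render_volume
from .tomo import (
    NNResult,
    classify_bundle,
    classify_filament,
    estimate_crossover,
    filter_outliers,
    nn_distances,
    resample_polyline,
    trace_centerlines,
    width_signal,
)

__all__ = [
    "simulate_bundle_volume",
    "measure_bundle_spacing",
    "recover_lattice_spacing",
    "measure_filament_crossover",
    "classify_bundle_volume",
]


def simulate_bundle_volume(
    preset: str = "cofilactin",
    n_rings: int = 1,
    length: float = 150.0,
    voxel_size: float = 1.0,
    snr: float | None = None,
    wedge_halfangle: float | None = None,
    seed: int = 0,
    params: HelicalParams | None = None,
    lattice_constant: float | None = None,
    alternation: str | None = None,
):
    """Build a hexagonal bundle from a preset (or explicit overrides),
    render it and optionally corrupt it.  Returns (volume, bundle,
    ground_truth)."""
    p = BUNDLE_PRESETS[preset]
    params = params or p["params"]
    lattice_constant = lattice_constant or p["lattice_constant"]
    alternation = alternation if alternation is not None else p["alternation"]
    bundle = build_hexagonal_bundle(
        n_rings=n_rings,
        lattice_constant=lattice_constant,
        params=params,
        alternation=alternation,
        length=length,
    )
    vol = render_volume(bundle, voxel_size=voxel_size)
    if snr is not None or wedge_halfangle is not None:
        vol = corrupt_volume(vol, snr=snr, wedge_halfangle=wedge_halfangle,
                             seed=seed)
    return vol, bundle, bundle_ground_truth(bundle, seed=seed)


def measure_bundle_spacing(
    vol: DensityVolume,
    centerlines: list[np.ndarray] | None = None,
    min_separation: float = 8.0,
    spacing: float = 1.0,
    outlier_k: float = 3.0,
) -> NNResult:
    """Nearest-neighbour interfilament spacing of a bundle volume:
    trace centerlines (unless supplied), resample at ``spacing`` nm,
    accumulate nearest-neighbour distances and apply the single-pass
    k-SD outlier filter."""
    if centerlines is None:
        centerlines = trace_centerlines(vol, min_separation=min_separation)
    if len(centerlines) < 2:
        raise ValueError(f"traced only {len(centerlines)} centerline(s)")
    pts = [resample_polyline(c, spacing) for c in centerlines]
    return filter_outliers(nn_distances(pts), k=outlier_k)


def recover_lattice_spacing(
    preset: str,
    seeds=(0, 1, 2),
    snr: float = 4.0,
    n_rings: int = 2,
    length: float = 100.0,
    voxel_size: float = 1.0,
) -> dict:
    """Full parameter-recovery protocol for one bundle preset: simulate
    at each seed, trace, measure, filter; report the across-seed mean.
    """
    means = []
    results = []
    for seed in seeds:
        vol, bundle, _ = simulate_bundle_volume(
            preset=preset, n_rings=n_rings, length=length,
            voxel_size=voxel_size, snr=snr, seed=seed,
        )
        res = measure_bundle_spacing(vol)
        means.append(res.post_mean)
        results.append(res)
    return {
        "preset": preset,
        "true_lattice_nm": BUNDLE_PRESETS[preset]["lattice_constant"],
        "per_seed_mean_nm": means,
        "mean_nm": float(np.mean(means)),
        "n_points": int(sum(r.post_n for r in results)),
        "results": results,
    }


def measure_filament_crossover(
    params: HelicalParams = COFILACTIN,
    n_crossovers: int = 10,
    voxel_size: float = 1.0,
    snr: float | None = None,
    seed: int = 0,
    use_traced_centerline: bool = False,
):
    """Render a single straight filament spanning ``n_crossovers`` and
    estimate its crossover length from the width-modulation signal."""
    from .helix import crossover_length

    length = (n_crossovers + 1.5) * crossover_length(params)
    bundle = build_hexagonal_bundle(
        n_rings=0, lattice_constant=12.0, params=params, length=length
    )
    vol = render_volume(bundle, voxel_size=voxel_size)
    if snr is not None:
        vol = corrupt_volume(vol, snr=snr, seed=seed)
    if use_traced_centerline:
        traces = trace_centerlines(vol)
        centerline = max(traces, key=len)
    else:
        centerline = bundle.filaments[0].centerline
    sig = width_signal(vol, centerline)
    return estimate_crossover(sig, filament_id=bundle.filaments[0].id)


def classify_bundle_volume(
    vol: DensityVolume,
    bundle=None,
    centerlines: list[np.ndarray] | None = None,
    low_max: float = 31.0,
    high_min: float = 33.0,
):
    """Per-filament pitch estimation and bundle-level classification.

    Centerlines default to the bundle's ground-truth ones when a bundle
    is given, otherwise they are traced from the volume.
    """
    ids = None
    if centerlines is None:
        if bundle is not None:
            centerlines = [f.centerline for f in bundle.filaments]
            ids = [f.id for f in bundle.filaments]
        else:
            centerlines = trace_centerlines(vol)
    if ids is None:
        ids = [f"trace{i}" for i in range(len(centerlines))]
    members = []
    estimates = []
    for fid, cl in zip(ids, centerlines):
        est = estimate_crossover(width_signal(vol, cl), filament_id=fid)
        estimates.append(est)
        if not est.indeterminate:
            members.append(classify_filament(est, low_max, high_min))
    if not members:
        raise ValueError("no filament yielded a determinate pitch estimate")
    return classify_bundle(members), estimates
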