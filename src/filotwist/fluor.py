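"""Fluorescence quantification of filopodia.

Covers the light-microscopy side of the analysis: line-scan intensity
profiles along single filopodia (cofilin vs actin/fascin channels, the
inverse-gradient signature of a cofilactin base), Costes-thresholded
Pearson colocalization, the cofilin base fraction, and live-imaging
motility quantification (windowed maximum-intensity projections, three
width measurements, and the two-fold resting/searching rule).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "FilopodiumProfile",
    "MotilityRecord",
    "max_intensity_projection",
    "line_profile",
    "profile_correlation",
    "costes_threshold",
    "pearson_colocalization",
    "detect_transition_region",
    "measure_widths",
    "classify_filopodium",
    "base_fraction",
    "base_fraction_batch",
]

#: Both-channels level (fraction of each channel's profile maximum)
#: defining the transition region and the cofilin base region.
TRANSITION_LEVEL = 0.5


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class FilopodiumProfile:
    """Two-channel intensity trace along a filopodium axis.

    Positions are µm from the proximal end; each channel is normalized
    to its own maximum over the profile.
    """

    positions_um: np.ndarray
    cofilin: np.ndarray
    actin: np.ndarray
    normalization: dict = field(default_factory=dict)
    transition_um: tuple[float, float] | None = None
    base_fraction: float | None = None

    def __post_init__(self) -> None:
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.cofilin = np.asarray(self.cofilin, dtype=float)
        self.actin = np.asarray(self.actin, dtype=float)
        if not np.all(np.diff(self.positions_um) > 0):
            raise ValueError("profile positions must be strictly increasing")
        if not len(self.positions_um) == len(self.cofilin) == len(self.actin):
            raise ValueError("profile arrays must have equal length")

    @property
    def length_um(self) -> float:
        return float(self.positions_um[-1] - self.positions_um[0])


@dataclass
class MotilityRecord:
    """Three MIP width measurements and the motility label."""

    filopodium_id: str
    cofilin_width_um: float
    actin_width_um: float
    inflection_width_um: float
    label: str | None = None  # resting | searching
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# MIPs
# ---------------------------------------------------------------------------

def max_intensity_projection(stack: np.ndarray, window: int = 40) -> np.ndarray:
    """Per-pixel maximum over consecutive ``window``-frame blocks.

    ``stack`` is (T, H, W); returns (n_windows, H, W).  Windows tile the
    movie; a trailing partial window is dropped unless the movie is
    shorter than one window, in which case a single truncated MIP is
    returned with a warning.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, H, W)")
    T = stack.shape[0]
    if T < window:
        warnings.warn(
            f"movie has {T} frames < window {window}; single truncated MIP"
        )
        return stack.max(axis=0, keepdims=True)
    n = T // window
    return stack[: n * window].reshape(n, window, *stack.shape[1:]).max(axis=1)


# ---------------------------------------------------------------------------
# Line profiles and colocalization
# ---------------------------------------------------------------------------

def line_profile(
    cofilin_img: np.ndarray,
    actin_img: np.ndarray,
    path: np.ndarray,
    width: int = 3,
    pixel_size_um: float = 0.05,
    spacing_px: float = 1.0,
) -> FilopodiumProfile:
    """Intensity profile along a polyline, averaged across ``width``
    pixels perpendicular to it, each channel normalized to its own
    maximum over the profile.

    ``path`` is (N, 2) in (row, col) pixels, from the base of the
    cofilin-rich portion to the distal tip.
    """
    from scipy.ndimage import map_coordinates

    if width < 1:
        raise ValueError("profile width must be >= 1 pixel")
    path = np.asarray(path, dtype=float)
    if path.ndim != 2 or path.shape[1] != 2 or len(path) < 2:
        raise ValueError("path must be an (N, 2) polyline")
    H, W = cofilin_img.shape
    if np.any(path < 0) or np.any(path[:, 0] > H - 1) or np.any(path[:, 1] > W - 1):
        raise ValueError("path exits the image bounds")

    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(round(s[-1] / spacing_px)) + 1)
    si = np.linspace(0, s[-1], n)
    pts = np.column_stack([np.interp(si, s, path[:, k]) for k in range(2)])
    tan = np.gradient(pts, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    perp = np.column_stack([-tan[:, 1], tan[:, 0]])
    offs = np.arange(width) - (width - 1) / 2.0

    def sample(img):
        vals = np.empty((n, width))
        for k, o in enumerate(offs):
            q = pts + o * perp
            vals[:, k] = map_coordinates(
                img.astype(float), [q[:, 0], q[:, 1]], order=1, mode="nearest"
            )
        return vals.mean(axis=1)

    cof = sample(cofilin_img)
    act = sample(actin_img)
    norm = {"cofilin_max": float(cof.max()), "actin_max": float(act.max())}
    cof = cof / norm["cofilin_max"] if norm["cofilin_max"] > 0 else cof
    act = act / norm["actin_max"] if norm["actin_max"] > 0 else act
    return FilopodiumProfile(
        positions_um=si * pixel_size_um, cofilin=cof, actin=act,
        normalization=norm,
    )


def profile_correlation(profile: FilopodiumProfile) -> float:
    """Pearson correlation of the two channel traces.  Inverse gradients
    (cofilin falling while actin rises) give negative values.  Returns
    NaN (with a warning) for a zero-variance channel."""
    if len(profile.cofilin) < 3:
        raise ValueError("need at least 3 profile samples")
    if profile.cofilin.std() == 0 or profile.actin.std() == 0:
        warnings.warn("zero-variance channel; correlation undefined")
        return math.nan
    return float(np.corrcoef(profile.cofilin, profile.actin)[0, 1])


class CostesThresholds(NamedTuple):
    t1: float
    t2: float
    converged: bool


def costes_threshold(
    ch1: np.ndarray,
    ch2: np.ndarray,
    roi: np.ndarray | None = None,
    step_fraction: float = 0.01,
) -> CostesThresholds:
    """Costes automatic threshold pair.

    An orthogonal (total least squares) regression ch2 = a*ch1 + b is
    fitted over the ROI; the candidate threshold T is stepped down from
    the ch1 maximum in 1% decrements of the intensity range, pairing it
    with a*T + b, until the Pearson correlation of the pixels *below*
    both thresholds drops to <= 0.  If no threshold achieves this the
    channel minima are returned flagged as unconverged.
    """
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if roi is None:
        roi = np.ones(ch1.shape, dtype=bool)
    x = ch1[roi]
    y = ch2[roi]
    if x.size == 0:
        raise ValueError("empty ROI")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant channel; Costes regression undefined")
    # orthogonal regression via principal axis of the covariance
    cov = np.cov(x, y)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    if major[0] == 0:
        raise ValueError("degenerate regression (vertical axis)")
    a = major[1] / major[0]
    b = y.mean() - a * x.mean()

    step = step_fraction * (x.max() - x.min() or 1.0)
    T = x.max()
    while T >= x.min():
        t2 = a * T + b
        below = (x < T) & (y < t2)
        if below.sum() >= 3:
            xb, yb = x[below], y[below]
            if xb.std() > 0 and yb.std() > 0:
                r = float(np.corrcoef(xb, yb)[0, 1])
            else:
                r = 0.0
            if r <= 0:
                return CostesThresholds(float(T), float(t2), True)
        T -= step
    return CostesThresholds(float(x.min()), float(a * x.min() + b), False)


class ColocalizationResult(NamedTuple):
    r: float
    n_pixels: int


def pearson_colocalization(
    ch1: np.ndarray,
    ch2: np.ndarray,
    roi: np.ndarray | None = None,
    thresholds: tuple[float, float] = (0.0, 0.0),
) -> ColocalizationResult:
    """Pearson correlation over ROI pixels above both thresholds."""
    ch1 = np.asarray(ch1, dtype=float)
    ch2 = np.asarray(ch2, dtype=float)
    if roi is None:
        roi = np.ones(ch1.shape, dtype=bool)
    t1, t2 = thresholds[:2]
    mask = roi & (ch1 > t1) & (ch2 > t2)
    n = int(mask.sum())
    if n < 3:
        warnings.warn("fewer than 3 qualifying pixels; correlation undefined")
        return ColocalizationResult(math.nan, n)
    x, y = ch1[mask], ch2[mask]
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero-variance above-threshold pixels")
        return ColocalizationResult(math.nan, n)
    return ColocalizationResult(float(np.corrcoef(x, y)[0, 1]), n)


# ---------------------------------------------------------------------------
# Transition region and base fraction
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index runs of True."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def detect_transition_region(
    profile: FilopodiumProfile, level: float = TRANSITION_LEVEL
) -> tuple[float, float] | None:
    """Maximal contiguous interval (µm) where both normalized channels
    are at or above ``level`` of their maxima; ``None`` when the
    channels never overlap at that level."""
    both = (profile.cofilin >= level) & (profile.actin >= level)
    runs = _runs(both)
    if not runs:
        profile.transition_um = None
        return None
    i, j = max(runs, key=lambda ij: ij[1] - ij[0])
    interval = (
        float(profile.positions_um[i]),
        float(profile.positions_um[j - 1]),
    )
    profile.transition_um = interval
    return interval


def base_fraction(
    profile: FilopodiumProfile, level: float = TRANSITION_LEVEL
) -> float:
    """Fraction of the filopodium length covered by the proximal
    cofilin-rich region.

    The cofilin region is the first contiguous run where the normalized
    cofilin signal is at or above ``level``; the fraction is its distal
    end measured from the proximal end of the profile, over the total
    length.  No such region gives 0.
    """
    runs = _runs(profile.cofilin >= level)
    L = profile.length_um
    if not runs or L == 0:
        profile.base_fraction = 0.0
        return 0.0
    i, j = runs[0]
    frac = (profile.positions_um[j - 1] - profile.positions_um[0]) / L
    frac = float(np.clip(frac, 0.0, 1.0))
    profile.base_fraction = frac
    return frac


def base_fraction_batch(profiles: list[FilopodiumProfile]) -> dict:
    """Aggregate base fractions and bundle lengths over many filopodia:
    mean +/- SEM of the fraction, and length statistics grouped by
    whether a cofilin base is present."""
    fracs = np.array([base_fraction(p) for p in profiles])
    lengths = np.array([p.length_um for p in profiles])
    has_base = fracs > 0
    out = {
        "n": len(profiles),
        "fraction_mean": float(fracs.mean()),
        "fraction_sem": float(fracs.std(ddof=1) / math.sqrt(len(fracs)))
        if len(fracs) > 1
        else 0.0,
        "length_with_base_um": lengths[has_base].tolist(),
        "length_without_base_um": lengths[~has_base].tolist(),
    }
    for key, grp in (("with_base", lengths[has_base]),
                     ("without_base", lengths[~has_base])):
        out[f"length_{key}_mean_um"] = float(grp.mean()) if len(grp) else math.nan
        out[f"length_{key}_sd_um"] = (
            float(grp.std(ddof=1)) if len(grp) > 1 else 0.0
        )
    return out


# ---------------------------------------------------------------------------
# Motility widths
# ---------------------------------------------------------------------------

def measure_widths(
    mip_cofilin: np.ndarray,
    mip_actin: np.ndarray,
    axis: np.ndarray,
    pixel_size_um: float = 0.05,
    max_halfwidth_px: int = 25,
    filopodium_id: str = "",
) -> MotilityRecord:
    """Three width measurements on a pair of MIPs.

    At each station along the axis polyline the width of each channel is
    the extent of its Otsu-thresholded MIP mask along the perpendicular.
    The cofilin width is the maximum over cofilin-dominant stations
    (normalized cofilin > normalized actin), the actin width the maximum
    over actin-dominant stations distal to the cofilin region, and the
    inflection width is taken where the two normalized signals meet.
    A channel entirely below threshold yields zero width and a flag.
    """
    from scipy.ndimage import map_coordinates
    from skimage.filters import threshold_otsu

    axis = np.asarray(axis, dtype=float)
    seg = np.linalg.norm(np.diff(axis, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n = max(2, int(round(s[-1])) + 1)
    si = np.linspace(0, s[-1], n)
    pts = np.column_stack([np.interp(si, s, axis[:, k]) for k in range(2)])
    tan = np.gradient(pts, axis=0)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    perp = np.column_stack([-tan[:, 1], tan[:, 0]])
    offs = np.arange(-max_halfwidth_px, max_halfwidth_px + 1, 0.5)

    flags: list[str] = []

    def station_widths(img):
        img = np.asarray(img, dtype=float)
        if img.max() <= img.min():
            flags.append("flat channel")
            return np.zeros(n), np.zeros(n)
        thr = threshold_otsu(img)
        widths = np.zeros(n)
        inten = np.zeros(n)
        for i in range(n):
            q = pts[i][None, :] + offs[:, None] * perp[i][None, :]
            vals = map_coordinates(
                img, [q[:, 0], q[:, 1]], order=1, mode="constant", cval=0.0
            )
            above = vals > thr
            if above.any():
                idx = np.flatnonzero(above)
                widths[i] = (offs[idx[-1]] - offs[idx[0]]) * pixel_size_um
            inten[i] = vals.max()
        return widths, inten

    w_cof, i_cof = station_widths(mip_cofilin)
    w_act, i_act = station_widths(mip_actin)
    nc = i_cof / i_cof.max() if i_cof.max() > 0 else i_cof
    na = i_act / i_act.max() if i_act.max() > 0 else i_act

    cof_dom = nc > na
    if cof_dom.any():
        cof_width = float(w_cof[cof_dom].max())
        last_cof = int(np.flatnonzero(cof_dom)[-1])
    else:
        cof_width = 0.0
        last_cof = 0
        flags.append("no cofilin-dominant station")
    act_dom = ~cof_dom
    act_dom[: last_cof] = False
    if act_dom.any():
        act_width = float(w_act[act_dom].max())
    else:
        act_width = float(w_act.max())
        flags.append("no actin-dominant station distal to cofilin region")
    # inflection: station where the normalized signals meet (closest approach)
    meet = int(np.argmin(np.abs(nc - na)))
    infl_width = float(max(w_cof[meet], w_act[meet]))

    return MotilityRecord(
        filopodium_id=filopodium_id,
        cofilin_width_um=cof_width,
        actin_width_um=act_width,
        inflection_width_um=infl_width,
        flags=flags,
    )


def classify_filopodium(record: MotilityRecord) -> str:
    """Searching iff the actin width is at least two-fold the cofilin
    width; a zero cofilin width counts as searching whenever any actin
    width was measured."""
    if record.cofilin_width_um < 0 or record.actin_width_um < 0:
        raise ValueError("widths must be non-negative")
    if record.cofilin_width_um == 0:
        label = "searching" if record.actin_width_um > 0 else "resting"
    else:
        label = (
            "searching"
            if record.actin_width_um >= 2.0 * record.cofilin_width_um
            else "resting"
        )
    record.label = label
    return label
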