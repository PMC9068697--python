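"""Parametric helical filaments and hexagonally packed bundles.

An actin filament is a left-handed single-start ("genetic") helix of
globular subunits: each subunit sits ``rise`` nm further along the axis
and ``twist`` degrees further around it than its predecessor.  Because
``|twist|`` is close to 180 deg, projections show the familiar two
apparent long-pitch strands that cross over every

    L = rise * 180 / (180 - |twist|)   [nm]

Cofilin binding over-twists the filament (twist approx -162.1 deg per
subunit instead of -166.6 deg), shortening the crossover from ~37 nm to
~28 nm -- the signature used throughout this package to tell cofilactin
from bare/fascin-linked F-actin.

Filopodial bundles are modelled as hexagonal lattices of parallel
filaments.  Cofilactin bundles additionally alternate a 90 deg rotation
("roll") of every other filament within a layer, which shifts the
apparent width modulation of neighbours by half a crossover (the
out-of-phase packing seen in tomograms).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

NM_PER_ANGSTROM = 0.1

__all__ = [
    "HelicalParams",
    "ACTIN",
    "COFILACTIN",
    "SubunitFrame",
    "FilamentSpec",
    "BundleSpec",
    "DecorationCloud",
    "crossover_length",
    "apparent_phase_shift",
    "place_subunits",
    "build_hexagonal_bundle",
    "decorate",
    "closest_approach",
    "residue_pair_distance",
]


# ---------------------------------------------------------------------------
# Helical parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelicalParams:
    """Axial rise (nm) and signed azimuthal twist (deg) per subunit.

    Negative twist is a left-handed genetic helix.  ``subunit_radius`` is
    the radial offset of the subunit centre of mass from the filament
    axis; it controls the amplitude of the apparent width modulation in
    rendered densities but not the crossover length.
    """

    rise: float
    twist: float
    subunit_radius: float = 1.6
    label: str = "custom"

    def __post_init__(self) -> None:
        if not self.rise > 0:
            raise ValueError(f"rise must be positive, got {self.rise}")
        t = abs(self.twist)
        if t >= 360:
            raise ValueError(f"|twist| must be below 360 deg, got {self.twist}")
        # twist 0 (an untwisted ribbon) is a legal geometry; only the
        # crossover is undefined for it (and for exactly 180 deg)


#: Bare/fascin-linked F-actin: 27.6 A rise, -166.6 deg twist per subunit.
ACTIN = HelicalParams(rise=2.76, twist=-166.6, label="actin")
#: Cofilin-saturated actin: same rise, over-twisted to -162.1 deg per subunit.
COFILACTIN = HelicalParams(rise=2.76, twist=-162.1, label="cofilactin")

PRESETS = {"actin": ACTIN, "cofilactin": COFILACTIN}


def crossover_length(params: HelicalParams) -> float:
    """Axial distance (nm) between successive apparent strand crossings.

    The two apparent long-pitch strands of the actin double helix cross
    once every half-turn of the slow apparent rotation ``180 - |twist|``
    deg per subunit, giving ``rise * 180 / |180 - |twist||``.
    """
    t = abs(params.twist)
    if t == 0 or t == 180 or t >= 360:
        raise ValueError("crossover undefined for this twist")
    return params.rise * 180.0 / abs(180.0 - t)


def apparent_phase_shift(roll: float, params: HelicalParams) -> float:
    """Axial shift (nm) of the apparent width modulation caused by rolling
    a filament about its own axis.

    The width modulation follows the two-start helix, so a roll of
    ``r`` degrees advances it by ``crossover * r / 180``: 90 deg puts a
    filament fully out of phase with an unrolled neighbour, 180 deg is in
    phase again.
    """
    return crossover_length(params) * roll / 180.0


# ---------------------------------------------------------------------------
# Filament and bundle specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubunitFrame:
    """Rigid frame of one subunit along a filament.

    ``position`` is the subunit centre (axis point displaced by
    ``subunit_radius`` along the azimuth direction); ``axis_point`` the
    corresponding centerline point.  ``azimuth_dir`` and ``binormal``
    complete a right-handed orthonormal frame with ``axis_tangent``.
    """

    index: int
    axial_s: float
    azimuth: float
    position: np.ndarray
    axis_point: np.ndarray
    axis_tangent: np.ndarray
    azimuth_dir: np.ndarray
    binormal: np.ndarray

    def rotation(self) -> np.ndarray:
        """3x3 matrix mapping reference coords (subunit along +x, axis +z)
        into world coords."""
        return np.column_stack([self.azimuth_dir, self.binormal, self.axis_tangent])


@dataclass
class FilamentSpec:
    """A centerline polyline (nm) plus helical parameters and phases."""

    id: str
    centerline: np.ndarray
    params: HelicalParams
    roll: float = 0.0
    phase_axial: float = 0.0
    lattice_coords: tuple[int, int] | None = None  # (column, layer)

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3:
            raise ValueError("centerline must be an (N, 3) array of nm points")
        if len(self.centerline) < 2:
            raise ValueError("centerline needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        if np.any(seg > self.params.rise + 1e-9):
            raise ValueError(
                "centerline point spacing exceeds the subunit rise; "
                "resample it more finely before placing subunits"
            )

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum()
        )

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "centerline_nm": self.centerline.tolist(),
            "params": asdict(self.params),
            "roll_deg": self.roll,
            "phase_axial_nm": self.phase_axial,
            "lattice_coords": list(self.lattice_coords)
            if self.lattice_coords is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilamentSpec":
        return cls(
            id=d["id"],
            centerline=np.asarray(d["centerline_nm"], dtype=float),
            params=HelicalParams(**d["params"]),
            roll=d.get("roll_deg", 0.0),
            phase_axial=d.get("phase_axial_nm", 0.0),
            lattice_coords=tuple(d["lattice_coords"])
            if d.get("lattice_coords") is not None
            else None,
        )


@dataclass
class BundleSpec:
    """A lattice of filaments with an optional roll-alternation rule."""

    filaments: list[FilamentSpec]
    lattice_constant: float
    alternation: str = "none"  # none | column_roll_90
    n_rings: int = 0

    def to_dict(self) -> dict:
        return {
            "lattice_constant_nm": self.lattice_constant,
            "alternation": self.alternation,
            "n_rings": self.n_rings,
            "filaments": [f.to_dict() for f in self.filaments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BundleSpec":
        return cls(
            filaments=[FilamentSpec.from_dict(f) for f in d["filaments"]],
            lattice_constant=d["lattice_constant_nm"],
            alternation=d.get("alternation", "none"),
            n_rings=d.get("n_rings", 0),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BundleSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Subunit placement (parallel transport along the centerline)
# ---------------------------------------------------------------------------

def _polyline_arclength(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation-minimizing (parallel-transported) frames at each vertex.

    Returns (tangents, normals, binormals).  The normal at the first
    vertex is an arbitrary unit vector perpendicular to the tangent; it
    is then transported with the double-reflection method so the frame
    does not spin about the tangent as the centerline bends.
    """
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)

    t0 = tangents[0]
    seed = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(seed, t0)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    n0 = seed - np.dot(seed, t0) * t0
    n0 /= np.linalg.norm(n0)

    normals = np.empty_like(points)
    normals[0] = n0
    for i in range(len(points) - 1):
        # double reflection (Wang et al. rotation minimizing frames)
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        if c1 < 1e-20:
            normals[i + 1] = normals[i]
            continue
        rL = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tL = tangents[i] - (2.0 / c1) * np.dot(v1, tangents[i]) * v1
        v2 = tangents[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-20:
            n_next = rL
        else:
            n_next = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        n_next -= np.dot(n_next, tangents[i + 1]) * tangents[i + 1]
        n_next /= np.linalg.norm(n_next)
        normals[i + 1] = n_next
    binormals = np.cross(tangents, normals)
    return tangents, normals, binormals


def place_subunits(
    filament: FilamentSpec,
    n: int | None = None,
    phase_azimuth: float = 0.0,
) -> list[SubunitFrame]:
    """Place subunits every ``rise`` nm along the centerline, each rotated
    by ``twist`` degrees relative to its predecessor.

    Azimuths follow ``roll + phase_azimuth + index * twist`` (mod 360)
    and are measured in a parallel-transported normal frame, so curved
    centerlines acquire no spurious azimuthal drift.  With ``n`` omitted,
    as many subunits as fit are placed.
    """
    p = filament.params
    s = _polyline_arclength(filament.centerline)
    total = s[-1]
    n_fit = int(math.floor((total - filament.phase_axial) / p.rise)) + 1
    if n is None:
        n = n_fit
    if n < 1:
        raise ValueError("need at least one subunit")
    needed = filament.phase_axial + (n - 1) * p.rise
    if needed > total + 1e-9:
        raise ValueError(
            f"centerline of filament {filament.id!r} is {total:.2f} nm long "
            f"but {needed:.2f} nm are required for {n} subunits "
            f"(rise {p.rise} nm, axial phase {filament.phase_axial} nm)"
        )

    tangents, normals, binormals = _transport_frames(filament.centerline)
    s_sub = filament.phase_axial + np.arange(n) * p.rise

    def interp_rows(arr: np.ndarray, si: np.ndarray) -> np.ndarray:
        out = np.empty((len(si), 3))
        for k in range(3):
            out[:, k] = np.interp(si, s, arr[:, k])
        return out

    pts = interp_rows(filament.centerline, s_sub)
    tan = interp_rows(tangents, s_sub)
    tan /= np.linalg.norm(tan, axis=1, keepdims=True)
    nor = interp_rows(normals, s_sub)
    nor -= np.sum(nor * tan, axis=1, keepdims=True) * tan
    nor /= np.linalg.norm(nor, axis=1, keepdims=True)
    bin_ = np.cross(tan, nor)

    frames = []
    for i in range(n):
        az = (filament.roll + phase_azimuth + i * p.twist) % 360.0
        a = math.radians(az)
        azdir = math.cos(a) * nor[i] + math.sin(a) * bin_[i]
        frames.append(
            SubunitFrame(
                index=i,
                axial_s=float(s_sub[i]),
                azimuth=az,
                position=pts[i] + p.subunit_radius * azdir,
                axis_point=pts[i],
                axis_tangent=tan[i],
                azimuth_dir=azdir,
                binormal=np.cross(tan[i], azdir),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Hexagonal bundles
# ---------------------------------------------------------------------------

def hexagonal_lattice_sites(n_rings: int) -> list[tuple[int, int]]:
    """Axial (column, layer) coordinates of a hexagonal patch of rings."""
    sites = []
    for i in range(-n_rings, n_rings + 1):
        for j in range(-n_rings, n_rings + 1):
            if max(abs(i), abs(j), abs(i + j)) <= n_rings:
                sites.append((i, j))
    sites.sort(key=lambda ij: (max(abs(ij[0]), abs(ij[1]), abs(ij[0] + ij[1])), ij))
    return sites


def build_hexagonal_bundle(
    n_rings: int,
    lattice_constant: float,
    params: HelicalParams,
    alternation: str = "none",
    length: float = 100.0,
    axis: str = "x",
    centerline_spacing: float | None = None,
) -> BundleSpec:
    """Straight, parallel filaments on a hexagonal lattice.

    ``n_rings=0`` gives a single filament, ``n_rings=r`` gives
    ``1 + 3 r (r+1)`` filaments.  With ``alternation='column_roll_90'``
    every other column within a layer is rolled 90 deg about its own
    axis (the cofilactin-bundle packing); otherwise all rolls are 0.
    """
    if n_rings < 0:
        raise ValueError("n_rings must be >= 0")
    if lattice_constant <= 2 * params.subunit_radius:
        raise ValueError("lattice constant must exceed the filament diameter")
    if alternation not in ("none", "column_roll_90"):
        raise ValueError(f"unknown alternation rule {alternation!r}")
    if length <= 0:
        raise ValueError("length must be positive")

    spacing = centerline_spacing or min(1.0, params.rise)
    npts = max(2, int(round(length / spacing)) + 1)
    t = np.linspace(0.0, length, npts)

    ax = {"x": 0, "y": 1, "z": 2}[axis]
    in_plane = [k for k in range(3) if k != ax]

    a1 = np.array([lattice_constant, 0.0])  # column step (within a layer)
    a2 = np.array([lattice_constant / 2.0, lattice_constant * math.sqrt(3) / 2.0])

    filaments = []
    for col, layer in hexagonal_lattice_sites(n_rings):
        xy = col * a1 + layer * a2
        cl = np.zeros((npts, 3))
        cl[:, ax] = t
        cl[:, in_plane[0]] = xy[0]
        cl[:, in_plane[1]] = xy[1]
        roll = 90.0 * (col % 2) if alternation == "column_roll_90" else 0.0
        filaments.append(
            FilamentSpec(
                id=f"f{col:+d}{layer:+d}",
                centerline=cl,
                params=params,
                roll=roll,
                lattice_coords=(col, layer),
            )
        )
    return BundleSpec(
        filaments=filaments,
        lattice_constant=lattice_constant,
        alternation=alternation,
        n_rings=n_rings,
    )


# ---------------------------------------------------------------------------
# Decoration (pseudo-atoms or atomic models)
# ---------------------------------------------------------------------------

@dataclass
class DecorationCloud:
    """Labelled 3D points decorating each filament of a bundle.

    ``points[fid]`` is an (N, 3) nm array; ``labels[fid]`` a DataFrame
    aligned with it carrying subunit index plus (atomic mode) chain kind,
    residue and atom names.  ``lattice_coords`` mirrors the source bundle
    so contact analyses can report same-layer vs cross-layer geometry.
    """

    points: dict[str, np.ndarray]
    labels: dict[str, pd.DataFrame]
    source: str  # pseudo_atom | atomic
    lattice_coords: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def filament_ids(self) -> list[str]:
        return list(self.points)


@dataclass
class ReferenceSubunit:
    """One repeating unit of an atomic model, expressed in the canonical
    filament frame: helix axis along +z, subunit azimuth 0 (centre of
    mass in the +x half-plane), axial position 0."""

    coords: np.ndarray  # (N, 3) nm
    labels: pd.DataFrame  # chain_kind, chain, resname, resnum, atom, element


def reference_from_structure(
    structure,
    actin_chains: Sequence[str] | None = None,
    cofilin_chains: Sequence[str] | None = None,
    axis_point=(0.0, 0.0, 0.0),
    axis_dir=(0.0, 0.0, 1.0),
) -> ReferenceSubunit:
    """Extract one actin(+cofilin) repeating unit from a gemmi Structure.

    The helical axis of fibril models is assumed to run along
    ``axis_dir`` through ``axis_point`` (model coordinates, Angstrom)
    unless stated otherwise.  Chains are classified as actin (>=250
    residues) or cofilin (<250) when no explicit chain lists are given.
    The unit is recentred so its centre of mass sits at azimuth 0 and
    axial position 0.
    """
    rows = []
    xyz = []
    for model in structure:
        for chain in model:
            nres = len(chain)
            if actin_chains is not None or cofilin_chains is not None:
                if actin_chains and chain.name in actin_chains:
                    kind = "actin"
                elif cofilin_chains and chain.name in cofilin_chains:
                    kind = "cofilin"
                else:
                    continue
            else:
                kind = "actin" if nres >= 250 else "cofilin"
            for res in chain:
                for atom in res:
                    rows.append(
                        (kind, chain.name, res.name, res.seqid.num, atom.name,
                         atom.element.name)
                    )
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not rows:
        raise ValueError("structure contains no usable chains")
    labels = pd.DataFrame(
        rows, columns=["chain_kind", "chain", "resname", "resnum", "atom", "element"]
    )
    coords = np.asarray(xyz) * NM_PER_ANGSTROM

    ap = np.asarray(axis_point, dtype=float) * NM_PER_ANGSTROM
    ad = np.asarray(axis_dir, dtype=float)
    ad /= np.linalg.norm(ad)
    # rotate model axis onto +z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(ad, z)
    c = np.dot(ad, z)
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx / (1.0 + c)
    coords = (coords - ap) @ R.T
    # centre of actin mass defines azimuth 0 and axial 0
    act = coords[(labels["chain_kind"] == "actin").to_numpy()]
    com = act.mean(axis=0) if len(act) else coords.mean(axis=0)
    phi = math.atan2(com[1], com[0])
    cz, sz = math.cos(-phi), math.sin(-phi)
    Rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    coords = coords @ Rz.T
    coords[:, 2] -= com[2]
    return ReferenceSubunit(coords=coords, labels=labels)


def decorate(
    bundle: BundleSpec,
    source: str = "pseudo_atom",
    radius: float = 4.5,
    reference: ReferenceSubunit | None = None,
    selection: str | None = None,
    n_subunits: int | None = None,
) -> DecorationCloud:
    """Decorate every subunit of every filament.

    ``pseudo_atom`` places one labelled point per subunit at ``radius``
    nm from the axis along the subunit azimuth (a coarse stand-in for
    the outer cofilin centroid).  ``atomic`` rigidly transforms a
    :class:`ReferenceSubunit` into each subunit frame; ``selection``
    restricts to a chain kind (e.g. ``'cofilin'``).
    """
    if source not in ("pseudo_atom", "atomic"):
        raise ValueError(f"unknown decoration source {source!r}")
    if source == "atomic":
        if reference is None:
            raise ValueError("atomic decoration requires a reference subunit")
        ref_labels = reference.labels
        if selection is not None:
            mask = (ref_labels["chain_kind"] == selection).to_numpy()
            if not mask.any():
                raise ValueError(
                    f"selection {selection!r} matches no chains in the "
                    f"reference (kinds: {sorted(ref_labels['chain_kind'].unique())})"
                )
            ref_coords = reference.coords[mask]
            ref_labels = ref_labels.loc[mask].reset_index(drop=True)
        else:
            ref_coords = reference.coords

    points: dict[str, np.ndarray] = {}
    labels: dict[str, pd.DataFrame] = {}
    lattice: dict[str, tuple[int, int] | None] = {}
    for fil in bundle.filaments:
        frames = place_subunits(fil, n=n_subunits)
        if source == "pseudo_atom":
            pts = np.array(
                [f.axis_point + radius * f.azimuth_dir for f in frames]
            )
            lab = pd.DataFrame({"subunit": [f.index for f in frames]})
        else:
            chunks = []
            lab_chunks = []
            for f in frames:
                R = f.rotation()
                chunks.append(ref_coords @ R.T + f.axis_point)
                lc = ref_labels.copy()
                lc.insert(0, "subunit", f.index)
                lab_chunks.append(lc)
            pts = np.vstack(chunks)
            lab = pd.concat(lab_chunks, ignore_index=True)
        points[fil.id] = pts
        labels[fil.id] = lab
        lattice[fil.id] = fil.lattice_coords
    return DecorationCloud(
        points=points, labels=labels, source=source, lattice_coords=lattice
    )


# ---------------------------------------------------------------------------
# Contact analysis
# ---------------------------------------------------------------------------

def _pair_relation(lc_a, lc_b) -> str:
    if lc_a is None or lc_b is None:
        return "unknown"
    return "same_layer" if lc_a[1] == lc_b[1] else "cross_layer"


def closest_approach(
    cloud: DecorationCloud,
    pairs: Iterable[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-filament-pair minimum point distances, sorted ascending.

    Each row reports the pair (id order normalised), the minimum
    distance in nm, the arg-min labels on both sides and whether the
    pair sits in the same layer of the lattice or across layers.  Ties
    are broken toward the lowest filament-id pair, then lowest subunit
    index.
    """
    from scipy.spatial import cKDTree

    ids = cloud.filament_ids()
    if len(ids) < 2:
        raise ValueError("closest_approach needs at least two decorated filaments")
    if any(len(cloud.points[i]) == 0 for i in ids):
        raise ValueError("empty decoration cloud")
    if pairs is None:
        pairs = itertools.combinations(sorted(ids), 2)

    rows = []
    trees = {i: cKDTree(cloud.points[i]) for i in ids}
    for a, b in pairs:
        a, b = sorted((a, b))
        d, j = trees[b].query(cloud.points[a])
        i = int(np.argmin(d))
        rows.append(
            {
                "filament_a": a,
                "filament_b": b,
                "min_distance_nm": float(d[i]),
                "label_a": cloud.labels[a].iloc[i].to_dict(),
                "label_b": cloud.labels[b].iloc[int(j[i])].to_dict(),
                "relation": _pair_relation(
                    cloud.lattice_coords.get(a), cloud.lattice_coords.get(b)
                ),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["min_distance_nm", "filament_a", "filament_b"], kind="stable"
    ).reset_index(drop=True)


def residue_pair_distance(
    cloud: DecorationCloud,
    residues: Sequence[int],
    chain_kind: str = "cofilin",
    atom: str = "CA",
    neighbor_within: float | None = None,
) -> pd.DataFrame:
    """Distances between named residues of the *closest* decoration pair
    on each neighbouring-filament interface.

    For every filament pair, the two subunit copies (one per filament)
    with the smallest point-cloud separation are located first; the
    table then lists, for each ordered residue combination, the distance
    between their representative atoms (default C-alpha) across the two
    filaments.  Inter-filament only by construction.
    """
    if cloud.source != "atomic":
        raise ValueError("residue distances need an atomic decoration")
    ids = sorted(cloud.filament_ids())
    if len(ids) < 2:
        raise ValueError("need at least two filaments")

    from scipy.spatial import cKDTree

    rows = []
    for a, b in itertools.combinations(ids, 2):
        pa, pb = cloud.points[a], cloud.points[b]
        la, lb = cloud.labels[a], cloud.labels[b]
        ka = (la["chain_kind"] == chain_kind).to_numpy()
        kb = (lb["chain_kind"] == chain_kind).to_numpy()
        if not (ka.any() and kb.any()):
            raise ValueError(f"no {chain_kind!r} atoms on pair ({a}, {b})")
        d, j = cKDTree(pb[kb]).query(pa[ka])
        i = int(np.argmin(d))
        if neighbor_within is not None and d[i] > neighbor_within:
            continue
        sub_a = int(la.loc[ka, "subunit"].iloc[i])
        sub_b = int(lb.loc[kb, "subunit"].iloc[int(j[i])])

        def rep_atom(labels, pts, sub, resnum):
            m = (
                (labels["chain_kind"] == chain_kind)
                & (labels["subunit"] == sub)
                & (labels["resnum"] == resnum)
            ).to_numpy()
            if not m.any():
                raise ValueError(
                    f"residue {resnum} absent from {chain_kind} chains"
                )
            sel = labels.loc[m]
            prefer = sel["atom"] == atom
            idx = sel.index[prefer.to_numpy()] if prefer.any() else sel.index[:1]
            return pts[idx[0]]

        for ra in residues:
            for rb in residues:
                xa = rep_atom(la, pa, sub_a, ra)
                xb = rep_atom(lb, pb, sub_b, rb)
                rows.append(
                    {
                        "filament_a": a,
                        "filament_b": b,
                        "subunit_a": sub_a,
                        "subunit_b": sub_b,
                        "residue_a": ra,
                        "residue_b": rb,
                        "distance_nm": float(np.linalg.norm(xa - xb)),
                        "relation": _pair_relation(
                            cloud.lattice_coords.get(a), cloud.lattice_coords.get(b)
                        ),
                    }
                )
    return pd.DataFrame(rows)
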