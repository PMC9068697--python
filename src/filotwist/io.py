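"""File formats: MRC volumes, multi-page TIFF movies, centerline CSV,
JSON summaries, and PDB/mmCIF atomic models.

Conventions: tomographic quantities in nm, fluorescence in µm.  MRC
volumes are written mode 2 (float32) through gemmi's CCP4/MRC support
with the voxel size encoded in the unit cell and the nm origin stored
in the standard ORIGIN header words (in Angstrom); voxel centres sit at
``origin + (i + 0.5) * voxel_size``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import DensityVolume

NM_PER_ANGSTROM = 0.1

__all__ = [
    "write_mrc",
    "read_mrc",
    "write_movie_tiff",
    "read_movie_tiff",
    "write_centerlines_csv",
    "read_centerlines_csv",
    "write_nn_result",
    "write_json",
    "read_structure",
    "write_decoration_pdb",
]


# ---------------------------------------------------------------------------
# MRC volumes (gemmi CCP4/MRC maps)
# ---------------------------------------------------------------------------

def write_mrc(vol: DensityVolume, path) -> None:
    import gemmi

    nz, ny, nx = vol.data.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    np.array(grid, copy=False)[:] = np.ascontiguousarray(
        vol.data.transpose(2, 1, 0)
    )
    a = 10.0 * vol.voxel_size  # Angstrom per voxel
    grid.set_unit_cell(gemmi.UnitCell(nx * a, ny * a, nz * a, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    for k, word in enumerate((50, 51, 52)):
        m.set_header_float(word, float(vol.origin[k]) / NM_PER_ANGSTROM)
    m.write_ccp4_map(str(path))


def read_mrc(path) -> DensityVolume:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    data = np.array(m.grid, copy=True).transpose(2, 1, 0)
    voxel = m.grid.unit_cell.a / m.grid.nu * NM_PER_ANGSTROM
    origin = np.array(
        [m.header_float(w) for w in (50, 51, 52)], dtype=float
    ) * NM_PER_ANGSTROM
    return DensityVolume(data=data, voxel_size=voxel, origin=origin)


# ---------------------------------------------------------------------------
# Movies (multi-page TIFF, axes TCYX)
# ---------------------------------------------------------------------------

def write_movie_tiff(stack: np.ndarray, path, interval_s: float | None = None,
                     pixel_size_nm: float | None = None) -> None:
    import tifffile

    meta = {"axes": "TCYX"}
    if interval_s is not None:
        meta["frame_interval_s"] = interval_s
    if pixel_size_nm is not None:
        meta["pixel_size_nm"] = pixel_size_nm
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32),
                     metadata=meta)


def read_movie_tiff(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))


# ---------------------------------------------------------------------------
# Centerlines and NN results
# ---------------------------------------------------------------------------

def write_centerlines_csv(polylines, path) -> None:
    """filament_id, point_index, x_nm, y_nm, z_nm."""
    rows = []
    for i, poly in enumerate(polylines):
        fid = poly[0] if isinstance(poly, tuple) else f"f{i}"
        pts = poly[1] if isinstance(poly, tuple) else poly
        for j, p in enumerate(np.asarray(pts)):
            rows.append((fid, j, p[0], p[1], p[2]))
    pd.DataFrame(
        rows, columns=["filament_id", "point_index", "x_nm", "y_nm", "z_nm"]
    ).to_csv(path, index=False)


def read_centerlines_csv(path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    return [
        g.sort_values("point_index")[["x_nm", "y_nm", "z_nm"]].to_numpy()
        for _, g in df.groupby("filament_id", sort=True)
    ]


def write_nn_result(result, out_dir, stem: str = "nn") -> None:
    """Per-point CSV, histogram CSV and summary JSON."""
    out = Path(out_dir)
    result.records.rename(
        columns={"distance_nm": "nearest_neighbor_distance_nm"}
    ).to_csv(out / f"{stem}_points.csv", index=False)
    pd.DataFrame(
        {
            "bin_left_nm": result.hist_edges[:-1],
            "bin_right_nm": result.hist_edges[1:],
            "count": result.hist_counts,
        }
    ).to_csv(out / f"{stem}_histogram.csv", index=False)
    write_json(result.summary(), out / f"{stem}_summary.json")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------

def read_structure(path):
    """Read a PDB or mmCIF file into a gemmi Structure."""
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def write_decoration_pdb(cloud, path, max_atoms_per_model: int = 99999) -> None:
    """Write a DecorationCloud as a multi-model PDB, one model per
    filament.  Pseudo-atom decorations become single-atom (carbon)
    residues named DEC."""
    import gemmi

    st = gemmi.Structure()
    st.name = "filotwist bundle decoration"
    for mi, fid in enumerate(cloud.filament_ids(), start=1):
        model = gemmi.Model(mi)
        chain = gemmi.Chain("A")
        pts = cloud.points[fid]
        lab = cloud.labels[fid]
        for i in range(min(len(pts), max_atoms_per_model)):
            res = gemmi.Residue()
            if cloud.source == "pseudo_atom":
                res.name = "DEC"
                res.seqid = gemmi.SeqId(i + 1, " ")
                atom = gemmi.Atom()
                atom.name = "C"
                atom.element = gemmi.Element("C")
            else:
                row = lab.iloc[i]
                res.name = str(row["resname"])
                res.seqid = gemmi.SeqId(int(row["resnum"]), " ")
                atom = gemmi.Atom()
                atom.name = str(row["atom"])
                atom.element = gemmi.Element(str(row["element"]))
            x, y, z = (pts[i] / NM_PER_ANGSTROM).tolist()
            atom.pos = gemmi.Position(x, y, z)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.write_pdb(str(path))
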