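"""Shared fixtures: small synthetic bundles/volumes and a synthetic
atomic repeating unit (actin + cofilin blobs) for decoration tests."""

from __future__ import annotations

import numpy as np
import pytest

from filotwist.helix import (
    ACTIN,
    COFILACTIN,
    build_hexagonal_bundle,
)
from filotwist.synth import render_volume


def make_synthetic_unit_structure():
    """SYNTHETIC stand-in for a cofilactin repeating-unit structure.

    Not a real deposited model: an 'actin' chain of pseudo-atoms around
    radius ~1.8 nm from the axis and a 'cofilin' chain further out
    (~4.2 nm), with CYS 39 and CYS 147 placed deterministically, enough
    to exercise atomic decoration, selection and residue lookups.
    Coordinates in Angstrom; helix axis = z through the origin.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic cofilactin repeating unit"
    model = gemmi.Model(1)
    rng = np.random.default_rng(7)

    def add_chain(name, center, radius, n, first_resnum=1):
        chain = gemmi.Chain(name)
        pts = rng.normal(size=(n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = np.asarray(center) + radius * pts
        for i, p in enumerate(pts):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(first_resnum + i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*p.tolist())
            res.add_atom(atom)
            chain.add_residue(res)
        return chain

    model.add_chain(add_chain("A", (18.0, 0.0, 0.0), 8.0, 40))
    cof = add_chain("C", (42.0, 0.0, 0.0), 6.0, 30, first_resnum=1)
    # named cysteines at deterministic outer positions
    for resnum, pos in ((39, (47.0, 2.0, 5.0)), (147, (46.0, -3.0, -6.0))):
        res = gemmi.Residue()
        res.name = "CYS"
        res.seqid = gemmi.SeqId(resnum, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*pos)
        res.add_atom(atom)
        cof.add_residue(res)
    model.add_chain(cof)
    st.add_model(model)
    return st


@pytest.fixture(scope="session")
def synthetic_structure():
    return make_synthetic_unit_structure()


@pytest.fixture(scope="session")
def synthetic_reference(synthetic_structure):
    from filotwist.helix import reference_from_structure

    return reference_from_structure(
        synthetic_structure, actin_chains=["A"], cofilin_chains=["C"]
    )


@pytest.fixture(scope="session")
def cofilactin_hexagon():
    """Seven-filament cofilactin bundle with 90-deg column alternation."""
    return build_hexagonal_bundle(
        n_rings=1, lattice_constant=11.5, params=COFILACTIN,
        alternation="column_roll_90", length=60.0,
    )


@pytest.fixture(scope="session")
def rendered_hexagon_volume():
    """Noise-free rendered 7-filament cofilactin bundle, 150 nm long."""
    bundle = build_hexagonal_bundle(
        n_rings=1, lattice_constant=11.5, params=COFILACTIN,
        alternation="column_roll_90", length=150.0,
    )
    return render_volume(bundle), bundle


@pytest.fixture(scope="session")
def single_cofilactin_volume():
    """Noise-free single cofilactin filament spanning >10 crossovers."""
    from filotwist.helix import crossover_length

    length = 11.5 * crossover_length(COFILACTIN)
    bundle = build_hexagonal_bundle(
        n_rings=0, lattice_constant=12.0, params=COFILACTIN, length=length
    )
    return render_volume(bundle), bundle
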