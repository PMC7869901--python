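"""Shared fixtures: synthetic crystals and chain sets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tncs_scout.coord_tncs import ChainModel
from tncs_scout.reflection_io import SpaceGroupInfo, UnitCell
from tncs_scout.synthetic import (
    CrystalSpec,
    direct_sf,
    generate_crystal,
    rotation_matrix,
)


@pytest.fixture(scope="session")
def p1_cell() -> UnitCell:
    return UnitCell(70.0, 75.0, 80.0)


@pytest.fixture(scope="session")
def p1_sg() -> SpaceGroupInfo:
    return SpaceGroupInfo.from_symbol("P 1")


@pytest.fixture(scope="session")
def tncs2_refs():
    """Exact order-2 TNCS at t = (1/2, 0, 0); 5-10 A band."""
    cry = generate_crystal(CrystalSpec(order=2, t=(0.5, 0.0, 0.0)), seed=7)
    return direct_sf(cry, dmin=5.0, dmax=10.0)


@pytest.fixture(scope="session")
def null_refs():
    """Single molecule, no TNCS; 5-10 A band."""
    cry = generate_crystal(CrystalSpec(order=1), seed=7)
    return direct_sf(cry, dmin=5.0, dmax=10.0)


@pytest.fixture(scope="session")
def tncs2_map(tncs2_refs):
    from tncs_scout.patterson import compute_patterson

    return compute_patterson(tncs2_refs)


SEQ30 = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"


@pytest.fixture(scope="session")
def chain_factory(p1_cell):
    """Factory for synthetic chains: a fixed 30-residue backbone placed with a
    given rotation (about its centroid, z axis) and fractional translation."""
    rng = np.random.default_rng(11)
    base = rng.normal(scale=6.0, size=(30, 3)) + np.array([10.0, 10.0, 10.0])
    axis = np.array([0.0, 0.0, 1.0])

    def make(name: str, angle_deg: float, t_frac, seq: str = SEQ30,
             axis_=None) -> ChainModel:
        c = base.mean(axis=0)
        R = rotation_matrix(axis_ if axis_ is not None else axis, angle_deg)
        shift = p1_cell.orthogonalize(np.asarray(t_frac, dtype=float))
        return ChainModel(name, seq, (base - c) @ R.T + c + shift)

    return make


def frac_vectors_match(a, b, rots, tol: float = 0.02) -> bool:
    """Fractional vectors equal within tol under Laue images, inversion and
    lattice wrap — the equivalence class a Patterson peak defines."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for R in rots:
        for sgn in (1.0, -1.0):
            delta = np.mod(a - sgn * (b @ R) + 0.5, 1.0) - 0.5
            if np.all(np.abs(delta) <= tol):
                return True
    return False
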