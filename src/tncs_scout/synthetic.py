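"""Synthetic point-atom crystals with planted TNCS.

The generator builds a molecule of point scatterers (constant form factor,
zero B factor; band limiting is done purely by resolution cuts) and plants
``n`` copies related by multiples of a basic fractional translation, an
optional rotational perturbation about each copy's centroid and independent
Gaussian coordinate jitter per copy.  Structure factors are computed by
direct summation over every atom, copy and symmetry mate — no FFT is
involved — so the output serves as an exact, independent oracle for the
Patterson, epsilon-factor and detection modules.

Randomness is split into named streams (coordinates, jitter, noise), all
derived from the user seed, so that e.g. regenerating with a different jitter
level keeps the same base molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .reflection_io import (
    Provenance,
    ReflectionSet,
    SpaceGroupInfo,
    UnitCell,
    enumerate_unique_hkl,
)


@dataclass(frozen=True)
class CrystalSpec:
    """Recipe for a synthetic crystal.

    ``jitter`` is the r.m.s. displacement per atom (Angstrom); each copy is
    jittered independently, so the pairwise r.m.s. deviation between two
    copies is sqrt(2) * jitter.  ``rot_deg`` is applied to copy ``m`` as a
    rotation of ``m * rot_deg`` about a random axis fixed per crystal,
    so adjacent copies differ by ``rot_deg``.
    """

    cell: UnitCell = UnitCell(70.0, 75.0, 80.0)
    spacegroup: str = "P 1"
    n_atoms: int = 100
    mol_radius: float = 12.0
    order: int = 1
    t: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rot_deg: float = 0.0
    jitter: float = 0.0
    center: tuple[float, float, float] = (0.2, 0.2, 0.2)
    weight: float = 6.0

    def __post_init__(self):
        if not 1 <= self.order:
            raise ValueError("order must be >= 1")
        if not 10 <= self.n_atoms <= 500:
            raise ValueError("n_atoms must be in [10, 500]")
        if self.order >= 2 and not any(abs(x) > 1e-9 for x in self.t):
            raise ValueError("order >= 2 requires a nonzero translation")


@dataclass
class SyntheticCrystal:
    spec: CrystalSpec
    seed: int
    coords: np.ndarray          # (order, n_atoms, 3) orthogonal Angstrom
    weights: np.ndarray         # (n_atoms,)
    rot_axis: np.ndarray        # unit axis of the per-copy perturbation

    @property
    def cell(self) -> UnitCell:
        return self.spec.cell

    @property
    def sg(self) -> SpaceGroupInfo:
        return SpaceGroupInfo.from_symbol(self.spec.spacegroup)

    def all_atoms_frac(self) -> tuple[np.ndarray, np.ndarray]:
        """Fractional coordinates and weights of every atom of every copy."""
        frac = self.cell.fractionalize(self.coords.reshape(-1, 3))
        w = np.tile(self.weights, self.spec.order)
        return frac, w


def rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    names = ("coordinates", "jitter", "noise")
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_crystal(spec: CrystalSpec, seed: int) -> SyntheticCrystal:
    """Deterministically build the crystal for (spec, seed).

    Copy ``m`` sits at ``base + m*t`` (fractional), rotated by ``m*rot_deg``
    about the copy centroid around a random axis, with independent per-atom
    jitter.
    """
    rng = _streams(seed)
    coord_rng = rng["coordinates"]
    # uniform points in a sphere of mol_radius
    v = coord_rng.normal(size=(spec.n_atoms, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = spec.mol_radius * coord_rng.random(spec.n_atoms) ** (1.0 / 3.0)
    base = v * r[:, None]              # orthogonal Angstrom
    base -= base.mean(axis=0)          # rotations act about the copy centroid
    center_orth = spec.cell.orthogonalize(np.asarray(spec.center))
    axis = coord_rng.normal(size=3)
    axis /= np.linalg.norm(axis)

    t_orth = spec.cell.orthogonalize(np.asarray(spec.t))
    jit_rng = rng["jitter"]
    sd = spec.jitter / math.sqrt(3.0)
    copies = []
    for m in range(spec.order):
        R = rotation_matrix(axis, m * spec.rot_deg)
        xyz = base @ R.T + center_orth + m * t_orth
        if sd > 0:
            xyz = xyz + jit_rng.normal(scale=sd, size=xyz.shape)
        copies.append(xyz)
    coords = np.array(copies)
    weights = np.full(spec.n_atoms, spec.weight)
    return SyntheticCrystal(spec=spec, seed=seed, coords=coords,
                            weights=weights, rot_axis=axis)


def direct_sf(cry: SyntheticCrystal, dmin: float, dmax: float = np.inf) -> ReflectionSet:
    """Structure factors by direct summation; I = |F|^2.

    F(h) = sum over symmetry operations s and atoms j of
    w_j * exp(2 pi i h . (R_s x_j + t_s)).  Output reflections are reduced to
    the canonical asymmetric unit of reciprocal space.
    """
    cell, sg = cry.cell, cry.sg
    hkl = enumerate_unique_hkl(cell, sg, dmin, dmax)
    frac, w = cry.all_atoms_frac()
    F = np.zeros(len(hkl), dtype=complex)
    for R, t in zip(sg.rotation_arrays(), sg.translation_arrays()):
        pos = frac @ R.T + t
        phase = 2.0 * np.pi * (hkl @ pos.T)     # (N_hkl, N_atoms)
        F += (w * np.exp(1j * phase)).sum(axis=1)
    I = np.abs(F) ** 2
    return ReflectionSet(cell=cell, sg=sg, hkl=hkl, I=I,
                         sigI=np.zeros_like(I),
                         provenance=Provenance.MEAN_INTENSITY,
                         patterson_mask=np.ones(len(I), dtype=bool))


def degrade(rs: ReflectionSet, wedge_fraction: float = 0.0,
            noise_level: float = 0.0, seed: int = 0) -> ReflectionSet:
    """Degrade a reflection set: remove a reciprocal-space wedge and add
    multiplicative Gaussian noise.

    The wedge is contiguous in azimuth about a random axis and is applied
    modulo pi so that Friedel-mate directions are removed together, as a
    missing rotation range does in practice; it covers the given fraction of
    the unique directions, so expected completeness after removal is
    ``1 - wedge_fraction``.  Noise: I -> I * (1 + noise_level * N(0,1)),
    clipped at zero, with sigI set to noise_level * |I|.
    """
    if not 0 <= wedge_fraction < 1:
        raise ValueError("wedge_fraction must be in [0, 1)")
    rng = _streams(seed)["noise"]
    out = rs.select(np.ones(len(rs), dtype=bool))
    if wedge_fraction > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        # azimuth of each reciprocal vector about the axis
        s = rs.hkl @ rs.cell.frac_matrix()
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ axis) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ axis) * axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        phi = np.arctan2(s @ e2, s @ e1)  # (-pi, pi]
        phi0 = rng.uniform(-np.pi, np.pi)
        width = np.pi * wedge_fraction
        rel = np.mod(phi - phi0, np.pi)   # line direction, Friedel-symmetric
        out = out.select(rel >= width)
    if noise_level > 0:
        factors = 1.0 + noise_level * rng.normal(size=len(out))
        I = np.maximum(out.I * factors, 0.0)
        out.I = I
        out.sigI = noise_level * np.abs(out.I)
    return out


# ---------------------------------------------------------------------------
# file output, so the reader modules are exercised by synthetic fixtures

def write_mtz(rs: ReflectionSet, path: str | Path, mode: str = "mean") -> None:
    """Write reflections to MTZ.

    ``mode``: 'mean' writes IMEAN/SIGIMEAN; 'anom' writes I(+)/I(-) pairs
    (both mates equal to I); 'amplitude' writes F/SIGF with F = sqrt(max(I,0)).
    """
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup(rs.sg.hm)
    mtz.set_cell_for_all(rs.cell.gemmi)
    sigI = rs.sigI if rs.sigI is not None else np.zeros(len(rs))
    if mode == "mean":
        mtz.add_column("IMEAN", "J")
        mtz.add_column("SIGIMEAN", "Q")
        data = np.column_stack([rs.hkl, rs.I, sigI])
    elif mode == "anom":
        mtz.add_column("I(+)", "K")
        mtz.add_column("SIGI(+)", "M")
        mtz.add_column("I(-)", "K")
        mtz.add_column("SIGI(-)", "M")
        ip = rs.I_plus if rs.I_plus is not None else rs.I
        im = rs.I_minus if rs.I_minus is not None else rs.I
        data = np.column_stack([rs.hkl, ip, sigI, im, sigI])
    elif mode == "amplitude":
        mtz.add_column("F", "F")
        mtz.add_column("SIGF", "Q")
        F = np.sqrt(np.maximum(rs.I, 0.0))
        sigF = np.where(F > 0, sigI / np.maximum(2.0 * F, 1e-9), 0.0)
        data = np.column_stack([rs.hkl, F, sigF])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    mtz.set_data(data)
    mtz.write_to_file(str(path))


def to_structure(cry: SyntheticCrystal, element: str = "C") -> gemmi.Structure:
    """Represent the point-atom crystal as a gemmi Structure (one chain per
    copy, one 'residue' per atom) for the coordinate-analysis code paths."""
    st = gemmi.Structure()
    st.cell = cry.cell.gemmi
    st.spacegroup_hm = cry.sg.hm
    model = gemmi.Model("1")
    for m in range(cry.spec.order):
        chain = gemmi.Chain(chr(ord("A") + m))
        for i, xyz in enumerate(cry.coords[m]):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(cry: SyntheticCrystal, path: str | Path) -> None:
    to_structure(cry).write_pdb(str(path))
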