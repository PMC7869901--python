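"""Coordinate-space TNCS analysis: the closed-group classifier.

Given an asymmetric unit, chains with high sequence identity are superposed
pairwise under every crystal symmetry operation (identity included).  Pairs
that superpose with a small residual rotation and a genuine translation are
edges of a graph; connected components form closed TNCS groups.  Closure
means that a component of order n counts as TNCS of order n even when some
member pairs exceed the rotational tolerance individually: with tolerance
3 deg, rotations A-B 2 deg, B-C 2 deg and A-C 4 deg still give one group of
order 3.

The boolean result at tolerance ``r`` degrees is the ground-truth classifier
used to calibrate the intensity-based detection thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .reflection_io import SpaceGroupInfo, UnitCell


@dataclass
class ChainModel:
    """One chain: sequence plus superposition coordinates.

    ``ca`` holds the main-chain representative atoms (C-alpha) used for
    superposition; ``weight`` is the chain's total scattering (sum of atomic
    numbers over all atoms) for the scattering-fraction report.
    """

    chain_id: str
    sequence: str
    ca: np.ndarray            # (n_res, 3) orthogonal Angstrom
    weight: float = 0.0

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.ca)):
            raise ValueError(f"chain {self.chain_id}: non-finite coordinates")
        if self.weight == 0.0:
            self.weight = 6.0 * len(self.ca)


@dataclass
class SuperpositionResult:
    op_index: int
    angle_deg: float
    t_frac: np.ndarray        # reduced to (-0.5, 0.5] per axis
    rmsd: float
    degenerate: bool = False


@dataclass
class TncsGroup:
    """A closed group of translation-related chains."""

    members: tuple[str, ...]
    order: int
    t_frac: np.ndarray
    t_orth: np.ndarray
    max_rotation_deg: float
    scattering_fraction: float

    def to_dict(self) -> dict:
        return {
            "members": list(self.members),
            "order": self.order,
            "t_frac": [round(float(x), 4) for x in self.t_frac],
            "t_orth": [round(float(x), 3) for x in self.t_orth],
            "t_orth_length": round(float(np.linalg.norm(self.t_orth)), 3),
            "max_rotation_deg": round(self.max_rotation_deg, 2),
            "scattering_fraction": round(self.scattering_fraction, 4),
        }


@dataclass
class PdbTncsResult:
    has_tncs: bool
    groups: list[TncsGroup]
    tolerance_deg: float


# ---------------------------------------------------------------------------
# model input

def chains_from_structure(st: gemmi.Structure, expand_ncs: bool = True
                          ) -> tuple[list[ChainModel], UnitCell, SpaceGroupInfo]:
    """Extract chain models from a gemmi Structure (PDB or mmCIF).

    When the deposition carries MTRIX operators that are not already applied
    (``given`` false), the full asymmetric unit is reconstructed first.
    """
    st = st.clone()
    st.setup_entities()
    if expand_ncs and any(not op.given for op in st.ncs):
        st.expand_ncs(gemmi.HowToNameCopiedChain.AddNumber)
    cell = UnitCell.from_gemmi(st.cell)
    hm = st.spacegroup_hm or "P 1"
    sg = SpaceGroupInfo.from_symbol(hm)
    chains = []
    for chain in st[0]:
        seq, ca = [], []
        weight = 0.0
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            one = info.one_letter_code.upper() if info else "X"
            rep = None
            for atom in res:
                weight += atom.element.atomic_number
                if atom.name == "CA":
                    rep = atom.pos
            if rep is None and len(res) > 0:
                rep = res[0].pos
            if rep is not None:
                seq.append(one if one.isalpha() else "X")
                ca.append([rep.x, rep.y, rep.z])
        if len(ca) >= 3:
            chains.append(ChainModel(chain_id=chain.name, sequence="".join(seq),
                                     ca=np.array(ca), weight=weight))
    return chains, cell, sg


def load_chains(path) -> tuple[list[ChainModel], UnitCell, SpaceGroupInfo]:
    return chains_from_structure(gemmi.read_structure(str(path)))


# ---------------------------------------------------------------------------
# sequence matching

def _align_pair(seq_a: str, seq_b: str):
    """Global alignment; returns (identity over aligned columns, index pairs)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                matches += 1
    if not pairs:
        return 0.0, []
    return matches / len(pairs), pairs


def match_chains(chains: list[ChainModel], identity_threshold: float = 0.95,
                 min_aligned: int = 20) -> list[tuple[int, int, list[tuple[int, int]]]]:
    """Chain pairs with sequence identity above threshold.

    Identity is computed over aligned (non-gap) columns of a global
    alignment; pairs with fewer than ``min_aligned`` aligned residues are
    rejected unless both chains are shorter than that (small synthetic
    fixtures).
    """
    out = []
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            ident, pairs = _align_pair(chains[i].sequence, chains[j].sequence)
            min_len = min(len(chains[i].sequence), len(chains[j].sequence))
            need = min(min_aligned, min_len)
            if ident >= identity_threshold and len(pairs) >= need:
                out.append((i, j, pairs))
    return out


# ---------------------------------------------------------------------------
# superposition

def kabsch(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares proper rotation R minimizing |target - R moving| over
    centred coordinate sets; returns (R, rmsd after superposition)."""
    mc = moving - moving.mean(axis=0)
    tc = target - target.mean(axis=0)
    H = mc.T @ tc
    U, S, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    resid = tc - mc @ R.T
    return R, float(np.sqrt((resid**2).sum() / len(moving)))


def rotation_angle_deg(R: np.ndarray) -> float:
    """Angle of a rotation matrix: arccos((trace - 1) / 2)."""
    c = (np.trace(R) - 1.0) / 2.0
    return math.degrees(math.acos(float(np.clip(c, -1.0, 1.0))))


def _reduce_frac(t: np.ndarray) -> np.ndarray:
    """Reduce a fractional vector to (-0.5, 0.5] per axis."""
    return t - np.round(t)


def superpose_pair(chain_a: ChainModel, chain_b: ChainModel,
                   sg: SpaceGroupInfo, cell: UnitCell,
                   pairs: list[tuple[int, int]] | None = None
                   ) -> list[SuperpositionResult]:
    """Superpose A onto every symmetry image of B; one result per operation.

    The candidate TNCS relation for the pair is the operation with the
    smallest residual rotation.  Collinear atom sets cannot define a rotation
    and are flagged degenerate.
    """
    if pairs is None:
        n = min(len(chain_a.ca), len(chain_b.ca))
        pairs = list(zip(range(n), range(n)))
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched residues")
    ia = [p[0] for p in pairs]
    ib = [p[1] for p in pairs]
    A = chain_a.ca[ia]
    B = chain_b.ca[ib]

    centred = A - A.mean(axis=0)
    degenerate = np.linalg.matrix_rank(centred, tol=1e-6) < 2

    results = []
    frac_b = cell.fractionalize(B)
    for k, (R_s, t_s) in enumerate(zip(sg.rotation_arrays(), sg.translation_arrays())):
        B_img = cell.orthogonalize(frac_b @ R_s.T + t_s)
        R, rmsd = kabsch(A, B_img)
        angle = rotation_angle_deg(R)
        v = B_img.mean(axis=0) - A.mean(axis=0) @ R.T
        t_frac = _reduce_frac(cell.fractionalize(v))
        results.append(SuperpositionResult(op_index=k, angle_deg=angle,
                                           t_frac=t_frac, rmsd=rmsd,
                                           degenerate=degenerate))
    return results


# ---------------------------------------------------------------------------
# closed groups

@dataclass
class PairRelation:
    """Best superposition relation for a matched chain pair."""

    i: int
    j: int
    angle_deg: float
    t_frac: np.ndarray
    op_index: int = 0


def _wrap_close(u: np.ndarray, v: np.ndarray, tol: float) -> bool:
    d = np.abs(_reduce_frac(np.asarray(u) - np.asarray(v)))
    return bool(np.all(d <= tol))


def _multiples_assignment(rel: dict[int, np.ndarray], t: np.ndarray,
                          n: int, tol: float) -> dict[int, int] | None:
    """Assign distinct multipliers 0..n-1 so that rel[i] ~ m_i * t (mod 1)."""
    assign: dict[int, int] = {}
    used: set[int] = set()
    for node, u in rel.items():
        found = None
        for m in range(n):
            if m in used:
                continue
            if _wrap_close(u, m * t, tol):
                found = m
                break
        if found is None:
            return None
        assign[node] = found
        used.add(found)
    return assign


def build_closed_groups(relations: list[PairRelation], chains: list[ChainModel],
                        cell: UnitCell, r_deg: float,
                        trans_tol: float = 0.05,
                        min_translation: float = 2.0) -> list[TncsGroup]:
    """Transitive closure of the within-tolerance pair graph into TNCS groups.

    Edges are pair relations with rotation <= ``r_deg`` and translation of at
    least ``min_translation`` Angstrom.  Within each connected component the
    member translations relative to a reference chain must be successive
    multiples of a basic vector (per-axis tolerance ``trans_tol``); if the
    full component fails this test, the largest consistent subset is
    reported instead.
    """
    edges = [r for r in relations
             if r.angle_deg <= r_deg
             and np.linalg.norm(cell.orthogonalize(r.t_frac)) >= min_translation]
    if not edges:
        return []

    parent = list(range(len(chains)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    adj: dict[int, list[tuple[int, np.ndarray]]] = {}
    for e in edges:
        union(e.i, e.j)
        adj.setdefault(e.i, []).append((e.j, e.t_frac))
        adj.setdefault(e.j, []).append((e.i, -e.t_frac))

    comps: dict[int, list[int]] = {}
    for e in edges:
        comps.setdefault(find(e.i), None)
    for root in list(comps):
        comps[root] = [i for i in range(len(chains)) if find(i) == root]

    # full pairwise angles for the max-rotation report
    angle_of: dict[tuple[int, int], float] = {}
    for r in relations:
        key = (min(r.i, r.j), max(r.i, r.j))
        angle_of[key] = min(angle_of.get(key, np.inf), r.angle_deg)

    total_weight = sum(c.weight for c in chains)
    groups = []
    for members in comps.values():
        # accumulate translations relative to the reference along BFS paths
        ref = min(members)
        rel: dict[int, np.ndarray] = {ref: np.zeros(3)}
        queue = [ref]
        while queue:
            node = queue.pop(0)
            for nbr, t in adj.get(node, []):
                if nbr not in rel:
                    rel[nbr] = rel[node] + t
                    queue.append(nbr)
        n = len(members)
        # candidate basic vectors: each member's relative translation and
        # pairwise differences, shortest first
        cands = [u for u in rel.values() if
                 np.linalg.norm(cell.orthogonalize(_reduce_frac(u))) >= min_translation]
        cands.sort(key=lambda u: np.linalg.norm(cell.orthogonalize(_reduce_frac(u))))
        chosen = None
        for t in cands:
            assign = _multiples_assignment(rel, t, n, trans_tol)
            if assign is not None:
                chosen = (t, assign, members)
                break
        if chosen is None:
            # largest subset consistent with some candidate basic vector
            best_subset = None
            for t in cands:
                sub = [node for node in members
                       if any(_wrap_close(rel[node], m * t, trans_tol)
                              for m in range(n))]
                if len(sub) >= 2 and (best_subset is None or len(sub) > len(best_subset[1])):
                    best_subset = (t, sub)
            if best_subset is None:
                continue
            t, sub = best_subset
            chosen = (t, {node: 0 for node in sub}, sub)
        t, _, grp_members = chosen
        t = _reduce_frac(t)
        # canonical sign: the basic vector is defined only up to inversion
        # (reversing member order); make the first significant component positive
        for comp in t:
            if abs(comp) > 1e-6:
                if comp < 0:
                    t = _reduce_frac(-t)
                break
        pair_angles = [angle_of.get((min(a, b), max(a, b)), 0.0)
                       for ai, a in enumerate(grp_members)
                       for b in grp_members[ai + 1:]
                       if (min(a, b), max(a, b)) in angle_of]
        weight = sum(chains[m].weight for m in grp_members)
        groups.append(TncsGroup(
            members=tuple(chains[m].chain_id for m in sorted(grp_members)),
            order=len(grp_members),
            t_frac=t,
            t_orth=cell.orthogonalize(t),
            max_rotation_deg=max(pair_angles) if pair_angles else 0.0,
            scattering_fraction=weight / total_weight if total_weight else 0.0,
        ))
    groups.sort(key=lambda g: (-g.order, g.members))
    return groups


def pdb_tncs(chains: list[ChainModel], cell: UnitCell, sg: SpaceGroupInfo,
             r_deg: float = 10.0, identity_threshold: float = 0.95,
             trans_tol: float = 0.05, min_translation: float = 2.0
             ) -> PdbTncsResult:
    """The pdb-TNCS(r deg) classifier: True iff any closed group of order
    >= 2 exists at rotational tolerance ``r_deg``."""
    if len(chains) < 2:
        return PdbTncsResult(has_tncs=False, groups=[], tolerance_deg=r_deg)
    matched = match_chains(chains, identity_threshold=identity_threshold)
    relations = []
    for i, j, pairs in matched:
        try:
            results = superpose_pair(chains[i], chains[j], sg, cell, pairs)
        except ValueError:
            continue
        results = [r for r in results if not r.degenerate]
        if not results:
            continue
        best = min(results, key=lambda r: r.angle_deg)
        relations.append(PairRelation(i=i, j=j, angle_deg=best.angle_deg,
                                      t_frac=best.t_frac, op_index=best.op_index))
    groups = build_closed_groups(relations, chains, cell, r_deg,
                                 trans_tol=trans_tol,
                                 min_translation=min_translation)
    return PdbTncsResult(has_tncs=any(g.order >= 2 for g in groups),
                         groups=groups, tolerance_deg=r_deg)
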