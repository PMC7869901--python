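"""Merged reflection data: domain types, file input and intensity recovery.

Reflections are stored with a unit cell, space-group information and one
intensity column.  Depending on what the input file provides, intensities are
recovered by different rules before Patterson analysis:

* mean intensities are used directly (only net-positive ones enter the
  Patterson synthesis);
* anomalous intensities are averaged over Friedel mates (simple unweighted
  mean, singletons used alone);
* amplitudes produced by the French & Wilson procedure are converted back to
  intensities by numerically inverting the posterior-mean mapping;
* raw amplitudes are squared, with the information loss that originally
  negative intensities become zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
import gemmi
import numpy as np
from numpy.polynomial.legendre import leggauss


class Provenance(str, Enum):
    """How the stored intensity column was obtained."""

    MEAN_INTENSITY = "mean-intensity"
    ANOMALOUS_INTENSITY = "anomalous-intensity"
    AMPLITUDE_FRENCH_WILSON = "amplitude-french-wilson"
    AMPLITUDE_RAW = "amplitude-raw"


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise ValueError("cell angles must lie in (0, 180)")

    @property
    def gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def lengths(self) -> tuple[float, float, float]:
        return (self.a, self.b, self.c)

    @property
    def volume(self) -> float:
        return self.gemmi.volume

    def orth_matrix(self) -> np.ndarray:
        """3x3 fractional -> orthogonal (Angstrom) matrix."""
        return np.array(self.gemmi.orth.mat.tolist(), dtype=float)

    def frac_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.orth_matrix())

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.orth_matrix().T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        return np.asarray(orth, dtype=float) @ self.frac_matrix().T

    def d_spacings(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Angstrom) per Miller index row."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        # reciprocal vectors: s = A^-T h, |s| = 1/d
        s = hkl @ self.frac_matrix()
        norm = np.linalg.norm(s, axis=1)
        with np.errstate(divide="ignore"):
            return np.where(norm > 0, 1.0 / norm, np.inf)

    @classmethod
    def from_gemmi(cls, cell: gemmi.UnitCell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)


@dataclass(frozen=True)
class SpaceGroupInfo:
    """Space-group symmetry: Hermann-Mauguin symbol plus explicit operations.

    ``rotations``/``translations`` are the rotational and translational parts
    of every symmetry operation (identity included).  ``laue_rotations`` are
    the distinct rotational parts of the Laue group, i.e. the point group of
    the intensity-weighted reciprocal lattice including the inversion.
    """

    hm: str
    rotations: tuple = ()        # tuple of 3x3 int tuples
    translations: tuple = ()     # tuple of length-3 float tuples

    def __post_init__(self):
        if not self.rotations:
            sg = gemmi.SpaceGroup(self.hm)
            rots, trans = [], []
            for op in sg.operations():
                rots.append(tuple(tuple(r // gemmi.Op.DEN for r in row) for row in op.rot))
                trans.append(tuple(t / gemmi.Op.DEN for t in op.tran))
            object.__setattr__(self, "rotations", tuple(rots))
            object.__setattr__(self, "translations", tuple(trans))
        ident = tuple(tuple(int(i == j) for j in range(3)) for i in range(3))
        if ident not in self.rotations:
            raise ValueError("symmetry operations must include the identity")

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    def rotation_arrays(self) -> np.ndarray:
        return np.array(self.rotations, dtype=int)

    def translation_arrays(self) -> np.ndarray:
        return np.array(self.translations, dtype=float)

    def laue_rotations(self) -> np.ndarray:
        """Distinct rotation parts of the Laue group (includes -R for every R)."""
        seen: dict[bytes, np.ndarray] = {}
        for rot in self.rotation_arrays():
            for mat in (rot, -rot):
                seen.setdefault(mat.tobytes(), mat)
        return np.array(list(seen.values()), dtype=int)

    @classmethod
    def from_symbol(cls, hm: str) -> "SpaceGroupInfo":
        sg = gemmi.find_spacegroup_by_name(hm)
        if sg is None:
            raise ValueError(f"unknown space group {hm!r}")
        return cls(hm=sg.hm)


@dataclass
class ReflectionSet:
    """Merged reflections with a single intensity column.

    ``hkl`` rows are unique under the Laue group after reduction to a
    canonical asymmetric unit of reciprocal space (the lexicographically
    largest index triple of the orbit ``{±R h}``).
    """

    cell: UnitCell
    sg: SpaceGroupInfo
    hkl: np.ndarray                 # (N, 3) int
    I: np.ndarray                   # (N,) float
    sigI: np.ndarray | None = None  # (N,) float
    provenance: Provenance = Provenance.MEAN_INTENSITY
    d: np.ndarray = field(default=None)  # (N,) float, derived if absent
    # Friedel-separated intensities kept when provenance is anomalous
    I_plus: np.ndarray | None = None
    I_minus: np.ndarray | None = None
    # mask of reflections admitted to Patterson synthesis (net-positive rule)
    patterson_mask: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        self.I = np.asarray(self.I, dtype=float).ravel()
        if self.sigI is not None:
            self.sigI = np.asarray(self.sigI, dtype=float).ravel()
            if np.any(self.sigI < 0):
                raise ValueError("sigI must be non-negative")
        if self.d is None:
            self.d = self.cell.d_spacings(self.hkl)
        else:
            self.d = np.asarray(self.d, dtype=float).ravel()
        if len(self.I) != len(self.hkl):
            raise ValueError("hkl and I length mismatch")

    def __len__(self) -> int:
        return len(self.hkl)

    def select(self, mask: np.ndarray) -> "ReflectionSet":
        def pick(arr):
            return None if arr is None else arr[mask]
        return ReflectionSet(
            cell=self.cell, sg=self.sg,
            hkl=self.hkl[mask], I=self.I[mask], sigI=pick(self.sigI),
            provenance=self.provenance, d=self.d[mask],
            I_plus=pick(self.I_plus), I_minus=pick(self.I_minus),
            patterson_mask=pick(self.patterson_mask),
        )


# ---------------------------------------------------------------------------
# asymmetric-unit reduction

def asu_map(hkl: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    """Canonical representative per reflection: lexicographically largest
    member of the Laue orbit {R h, -R h}."""
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    rots = sg.laue_rotations()
    # images[k] has shape (N, 3): h . R  (row-vector convention, h' = h R)
    images = np.einsum("nj,kji->kni", hkl, rots)
    # lexicographic max over orbit
    best = images[0].copy()
    for img in images[1:]:
        better = _lex_greater(img, best)
        best[better] = img[better]
    return best


def _lex_greater(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    gt0 = a[:, 0] > b[:, 0]
    eq0 = a[:, 0] == b[:, 0]
    gt1 = a[:, 1] > b[:, 1]
    eq1 = a[:, 1] == b[:, 1]
    gt2 = a[:, 2] > b[:, 2]
    return gt0 | (eq0 & (gt1 | (eq1 & gt2)))


# ---------------------------------------------------------------------------
# file input

_MEAN_I_LABELS = ("IMEAN", "I", "IOBS", "I-obs")
_ANOM_PLUS = ("I(+)", "IOBS(+)", "I-obs(+)")
_ANOM_MINUS = ("I(-)", "IOBS(-)", "I-obs(-)")
_F_LABELS = ("F", "FP", "FOBS", "F-obs", "FMEANS")


def load_reflections(
    path: str | Path,
    fmt: str | None = None,
    french_wilson: bool = True,
    icol: str | None = None,
    fcol: str | None = None,
) -> ReflectionSet:
    """Read an MTZ or structure-factor mmCIF file.

    Provenance is inferred from available columns with precedence
    mean intensity > anomalous intensity > amplitude.  ``french_wilson``
    chooses between the two amplitude provenances (it cannot be inferred from
    the file itself).  Cell or space group missing is a hard error, as is the
    absence of any intensity or amplitude column.
    """
    path = Path(path)
    if fmt is None:
        fmt = "mtz" if path.suffix.lower() == ".mtz" else "sf-mmcif"
    if fmt == "mtz":
        return _load_mtz(path, french_wilson, icol, fcol)
    if fmt == "sf-mmcif":
        return _load_sf_mmcif(path, french_wilson)
    raise ValueError(f"unknown format {fmt!r}")


def _finish_load(cell, sg, hkl, data, provenance) -> ReflectionSet:
    hkl = np.asarray(hkl, dtype=int)
    if provenance is Provenance.ANOMALOUS_INTENSITY:
        ip, im = data["I_plus"], data["I_minus"]
        # placeholder I; recover_intensities computes the Friedel mean
        both = ~np.isnan(ip) | ~np.isnan(im)
        rs = ReflectionSet(
            cell=cell, sg=sg, hkl=hkl[both],
            I=np.where(np.isnan(ip[both]), im[both], ip[both]),
            sigI=None, provenance=provenance,
            I_plus=ip[both], I_minus=im[both],
        )
        return rs
    I = data["I"]
    sigI = data.get("sigI")
    good = ~np.isnan(I)
    if sigI is not None:
        sigI = np.where(np.isnan(sigI), 0.0, sigI)[good]
    return ReflectionSet(cell=cell, sg=sg, hkl=hkl[good], I=I[good],
                         sigI=sigI, provenance=provenance)


def _load_mtz(path: Path, french_wilson: bool, icol, fcol) -> ReflectionSet:
    mtz = gemmi.read_mtz_file(str(path))
    if mtz.spacegroup is None:
        raise ValueError(f"{path}: no space group in file")
    cell = UnitCell.from_gemmi(mtz.cell)
    if cell.volume <= 0:
        raise ValueError(f"{path}: invalid unit cell")
    sg = SpaceGroupInfo(hm=mtz.spacegroup.hm)
    labels = mtz.column_labels()
    hkl = np.array(mtz.make_miller_array(), dtype=int)

    def col(label):
        return np.array(mtz.column_with_label(label), dtype=float)

    chosen_i = icol if icol in labels else next((l for l in _MEAN_I_LABELS if l in labels), None)
    if chosen_i:
        sig = next((s for s in (f"SIG{chosen_i}", "SIGI", "SIGIMEAN") if s in labels), None)
        return _finish_load(cell, sg, hkl,
                            {"I": col(chosen_i), "sigI": col(sig) if sig else None},
                            Provenance.MEAN_INTENSITY)
    plus = next((l for l in _ANOM_PLUS if l in labels), None)
    minus = next((l for l in _ANOM_MINUS if l in labels), None)
    if plus and minus:
        return _finish_load(cell, sg, hkl,
                            {"I_plus": col(plus), "I_minus": col(minus)},
                            Provenance.ANOMALOUS_INTENSITY)
    chosen_f = fcol if fcol in labels else next((l for l in _F_LABELS if l in labels), None)
    if chosen_f:
        sig = f"SIG{chosen_f}" if f"SIG{chosen_f}" in labels else ("SIGF" if "SIGF" in labels else None)
        prov = Provenance.AMPLITUDE_FRENCH_WILSON if french_wilson else Provenance.AMPLITUDE_RAW
        F = col(chosen_f)
        sigF = col(sig) if sig else np.zeros_like(F)
        # store amplitudes in I slot until recover_intensities squares/inverts
        return _finish_load(cell, sg, hkl, {"I": F, "sigI": sigF}, prov)
    raise ValueError(f"{path}: no intensity or amplitude columns found")


def _load_sf_mmcif(path: Path, french_wilson: bool) -> ReflectionSet:
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    def num(tag):
        val = block.find_value(tag)
        return None if val in (None, "?", ".") else float(val)

    cell_vals = [num(f"_cell.length_{x}") for x in "abc"] + \
                [num(f"_cell.angle_{x}") for x in ("alpha", "beta", "gamma")]
    if any(v is None for v in cell_vals):
        raise ValueError(f"{path}: missing unit cell")
    hm = block.find_value("_symmetry.space_group_name_H-M")
    if hm is None:
        hm = block.find_value("_space_group.name_H-M_alt")
    if hm is None:
        raise ValueError(f"{path}: missing space group")
    cell = UnitCell(*cell_vals)
    sg = SpaceGroupInfo.from_symbol(gemmi.cif.as_string(hm))

    pre = "_refln."
    def loop(tag):
        col = block.find_loop(pre + tag)
        if len(col) == 0:
            return None
        return np.array([float(v) if v not in ("?", ".") else np.nan for v in col])

    h = loop("index_h"); k = loop("index_k"); l = loop("index_l")
    if h is None:
        raise ValueError(f"{path}: no _refln loop")
    hkl = np.column_stack([h, k, l]).astype(int)

    imean = loop("intensity_meas")
    if imean is not None:
        return _finish_load(cell, sg, hkl, {"I": imean, "sigI": loop("intensity_sigma")},
                            Provenance.MEAN_INTENSITY)
    ip, im = loop("pdbx_I_plus"), loop("pdbx_I_minus")
    if ip is not None and im is not None:
        return _finish_load(cell, sg, hkl, {"I_plus": ip, "I_minus": im},
                            Provenance.ANOMALOUS_INTENSITY)
    f = loop("F_meas_au")
    if f is None:
        f = loop("F_meas")
    if f is not None:
        prov = Provenance.AMPLITUDE_FRENCH_WILSON if french_wilson else Provenance.AMPLITUDE_RAW
        sf = loop("F_meas_sigma_au")
        if sf is None:
            sf = loop("F_meas_sigma")
        return _finish_load(cell, sg, hkl, {"I": f, "sigI": sf}, prov)
    raise ValueError(f"{path}: no intensity or amplitude columns found")


# ---------------------------------------------------------------------------
# French & Wilson posterior-mean mapping and its inversion

_GAUSS_N = 96
_GL_X, _GL_W = leggauss(_GAUSS_N)


def _fw_moments(iobs: np.ndarray, sigi: np.ndarray, sigma_n: np.ndarray):
    """Posterior mean of sqrt(J) and of J for the acentric French & Wilson
    posterior: p(J) ∝ N(J; iobs, sigi^2) * exp(-J/Sigma) on J >= 0.

    Completing the square gives a Gaussian in J centred at
    mu = iobs - sigi^2/Sigma truncated at zero.  The substitution J = u^2
    removes the sqrt cusp at the truncation point, so Gauss-Legendre
    quadrature converges spectrally; moments are accurate to well below 1e-8
    relative.
    """
    iobs = np.asarray(iobs, dtype=float)
    sigi = np.asarray(sigi, dtype=float)
    mu = iobs - sigi**2 / sigma_n
    lo_u = np.sqrt(np.maximum(0.0, mu - 12.0 * sigi))
    hi_u = np.sqrt(np.maximum(mu + 12.0 * sigi, lo_u**2 + 1e-3 * sigma_n))
    half = 0.5 * (hi_u - lo_u)
    u = 0.5 * (hi_u + lo_u)[..., None] + half[..., None] * _GL_X   # (N, q)
    w = half[..., None] * _GL_W
    j = u * u
    logpdf = -0.5 * ((j - mu[..., None]) / sigi[..., None]) ** 2
    logpdf -= logpdf.max(axis=-1, keepdims=True)
    # dJ = 2 u du
    pdf = np.exp(logpdf) * w * 2.0 * u
    z = pdf.sum(axis=-1)
    ef = (u * pdf).sum(axis=-1) / z
    ej = (j * pdf).sum(axis=-1) / z
    ej2 = (j * j * pdf).sum(axis=-1) / z
    return ef, ej, ej2


def french_wilson_forward(iobs, sigi, sigma_n):
    """Acentric French & Wilson transform: (I, sigI) -> (F, sigF).

    ``sigma_n`` is the expected intensity (Wilson parameter) for each
    reflection's resolution bin.
    """
    ef, ej, ej2 = _fw_moments(iobs, sigi, np.broadcast_to(np.asarray(sigma_n, float), np.shape(iobs)))
    var_f = np.maximum(ej - ef**2, 0.0)
    return ef, np.sqrt(var_f)


def french_wilson_reverse(F, sigF, sigma_n, sigi=None, tol=1e-8, max_iter=200):
    """Invert the posterior-mean amplitude mapping back to intensities.

    The forward map I -> E[sqrt(J)] is strictly increasing in the observed
    intensity, so per-reflection bisection recovers the unique pre-image.
    ``sigi`` defaults to the first-order propagation 2*F*sigF when the
    original intensity uncertainty is not available.
    """
    F = np.asarray(F, dtype=float)
    sigF = np.asarray(sigF, dtype=float)
    sigma_n = np.broadcast_to(np.asarray(sigma_n, dtype=float), F.shape).copy()
    if sigi is None:
        sigi = np.maximum(2.0 * F * sigF, 1e-6 * np.maximum(sigma_n, 1e-12))
    sigi = np.broadcast_to(np.asarray(sigi, dtype=float), F.shape).copy()
    sigi = np.maximum(sigi, 1e-12)

    lo = F**2 - 10.0 * sigi - sigma_n
    hi = F**2 + 10.0 * sigi + sigma_n
    flo, _, _ = _fw_moments(lo, sigi, sigma_n)
    fhi, _, _ = _fw_moments(hi, sigi, sigma_n)
    bad = (flo > F) | (fhi < F)
    if np.any(bad):
        lo = np.where(bad, F**2 - 100.0 * sigi - 10 * sigma_n, lo)
        hi = np.where(bad, F**2 + 100.0 * sigi + 10 * sigma_n, hi)
        flo, _, _ = _fw_moments(lo, sigi, sigma_n)
        fhi, _, _ = _fw_moments(hi, sigi, sigma_n)
        still = (flo > F) | (fhi < F)
        if np.any(still):
            warnings.warn("French-Wilson reversal failed to bracket for "
                          f"{int(still.sum())} reflections; falling back to F^2")
    scale = np.maximum(np.abs(F**2), sigma_n)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fmid, _, _ = _fw_moments(mid, sigi, sigma_n)
        go_up = fmid < F
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
        if np.max((hi - lo) / scale) < tol:
            break
    out = 0.5 * (lo + hi)
    if np.any(bad):
        out = np.where(bad, F**2, out)
    return out


def _bin_means(values: np.ndarray, d: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Per-reflection mean of ``values`` in equal-volume resolution bins."""
    s3 = 1.0 / np.maximum(d, 1e-9) ** 3
    edges = np.linspace(s3.min(), s3.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(s3, edges) - 1, 0, n_bins - 1)
    out = np.empty_like(values, dtype=float)
    overall = float(np.mean(values))
    for b in range(n_bins):
        m = idx == b
        out[m] = values[m].mean() if m.sum() >= 3 else overall
    return out


# ---------------------------------------------------------------------------
# operations

def recover_intensities(rs: ReflectionSet) -> ReflectionSet:
    """Apply the provenance-specific intensity-recovery rule.

    Returns a new ReflectionSet whose ``I`` column contains intensities on a
    common footing, with ``patterson_mask`` marking the reflections admitted
    to Patterson synthesis (the net-positive rule for mean intensities; all
    reflections are retained for likelihood work).
    """
    if rs.provenance is None:
        raise ValueError("provenance not set")
    prov = rs.provenance
    if prov is Provenance.MEAN_INTENSITY:
        out = rs.select(np.ones(len(rs), dtype=bool))
        out.patterson_mask = rs.I > 0
        return out
    if prov is Provenance.ANOMALOUS_INTENSITY:
        if rs.I_plus is None or rs.I_minus is None:
            raise ValueError("anomalous provenance requires I_plus/I_minus")
        ip, im = rs.I_plus, rs.I_minus
        both = ~np.isnan(ip) & ~np.isnan(im)
        I = np.where(both, 0.5 * (ip + im), np.where(np.isnan(ip), im, ip))
        out = rs.select(np.ones(len(rs), dtype=bool))
        out.I = I
        out.provenance = Provenance.MEAN_INTENSITY
        out.patterson_mask = I > 0
        return out
    if prov is Provenance.AMPLITUDE_RAW:
        out = rs.select(np.ones(len(rs), dtype=bool))
        out.I = rs.I**2  # negative original intensities are already stored as F=0
        if rs.sigI is not None:
            out.sigI = 2.0 * np.abs(rs.I) * rs.sigI
        out.provenance = Provenance.MEAN_INTENSITY
        out.patterson_mask = np.ones(len(out), dtype=bool)
        return out
    if prov is Provenance.AMPLITUDE_FRENCH_WILSON:
        F = rs.I
        sigF = rs.sigI if rs.sigI is not None else np.zeros_like(F)
        # Wilson parameter per bin from F^2, refined once after inversion
        sigma_n = _bin_means(F**2, rs.d)
        I = french_wilson_reverse(F, sigF, sigma_n)
        sigma_n = _bin_means(np.maximum(I, 0.0), rs.d)
        I = french_wilson_reverse(F, sigF, sigma_n)
        out = rs.select(np.ones(len(rs), dtype=bool))
        out.I = I
        out.sigI = 2.0 * np.abs(F) * sigF
        out.provenance = Provenance.MEAN_INTENSITY
        out.patterson_mask = I > 0
        return out
    raise ValueError(f"unknown provenance {prov}")


def truncate_resolution(rs: ReflectionSet, dmin: float = 3.0) -> ReflectionSet:
    """Remove reflections with d < dmin (high-resolution truncation)."""
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    mask = rs.d >= dmin
    if not mask.any():
        raise ValueError(f"no reflections at resolution {dmin} A or lower")
    return rs.select(mask)


def enumerate_unique_hkl(cell: UnitCell, sg: SpaceGroupInfo,
                         dmin: float, dmax: float = np.inf) -> np.ndarray:
    """All symmetry-unique Miller indices with dmin <= d <= dmax.

    Enumerates the full index box, reduces under the Laue group to canonical
    representatives and drops systematic absences of the translational
    symmetry.
    """
    lims = [int(math.floor(length / dmin)) + 1 for length in cell.lengths]
    h = np.arange(-lims[0], lims[0] + 1)
    k = np.arange(-lims[1], lims[1] + 1)
    l = np.arange(-lims[2], lims[2] + 1)
    hkl = np.stack(np.meshgrid(h, k, l, indexing="ij"), axis=-1).reshape(-1, 3)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    d = cell.d_spacings(hkl)
    hkl = hkl[(d >= dmin) & (d <= dmax)]
    reps = asu_map(hkl, sg)
    uniq = np.unique(reps, axis=0)
    return uniq[~_systematically_absent(uniq, sg)]


def _systematically_absent(hkl: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    rots = sg.rotation_arrays()
    trans = sg.translation_arrays()
    absent = np.zeros(len(hkl), dtype=bool)
    for R, t in zip(rots, trans):
        img = hkl @ R
        same = np.all(img == hkl, axis=1)
        phase = hkl @ t
        frac = phase - np.round(phase)
        absent |= same & (np.abs(frac) > 1e-6)
    return absent


def completeness(rs: ReflectionSet, dmin: float, dmax: float) -> float:
    """Observed / theoretical unique reflections in the shell [dmin, dmax]."""
    if dmax <= dmin:
        raise ValueError("dmax must exceed dmin")
    theoretical = enumerate_unique_hkl(rs.cell, rs.sg, dmin, dmax)
    if len(theoretical) == 0:
        return 1.0
    in_shell = (rs.d >= dmin) & (rs.d <= dmax)
    observed = np.unique(asu_map(rs.hkl[in_shell], rs.sg), axis=0)
    theo_set = set(map(tuple, theoretical))
    n_obs = sum(1 for h in map(tuple, observed) if h in theo_set)
    return n_obs / len(theoretical)
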