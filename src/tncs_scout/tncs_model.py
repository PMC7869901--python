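"""TNCS expected-intensity (epsilon) factors and their refinement.

For TNCS of order n with basic translation t, the contributions of the n
copies to a structure factor share (nearly) the same amplitude but differ in
phase by multiples of 2*pi*h.t, so they interfere constructively for some
reflections and destructively for others.  Averaging over random molecular
structure, the expected intensity acquires a per-reflection factor

    g(h) = n + 2 * sum_{m=1}^{n-1} (n - m) * rho(h)^m * cos(2 pi m h . t_s)

averaged over the distinct symmetry images t_s of t.  The correlation
rho(h) in [0, 1] between copies m apart (modelled geometrically as rho^m)
combines two dampings:

* coordinate differences: the Luzzati-style falloff
  D = exp(-(8 pi^2 / 3) * sigma_d^2 * (sin theta / lambda)^2), with
  sin theta / lambda = 1 / (2 d);
* rotational differences: the spherical interference (G-function) falloff
  G(x) = 3 (sin x - x cos x) / x^3 with x = 2 pi R_mol |q|, where q is the
  reciprocal-space offset produced by the perturbation rotation acting on
  the scattering vector.  When the rotation axis is unknown the offset
  magnitude is isotropically averaged: |q| ~ 2 sin(theta_rot/2) |s| sqrt(2/3).

Normalized factors eps = g / <g> have mean 1; their variance about 1
(sigma_1^2, "eps-TNCS") measures the degree of modulation and is the
statistic refined against the data through a Wilson (exponential acentric)
likelihood with bin-wise mean intensities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .reflection_io import ReflectionSet, SpaceGroupInfo, UnitCell
from .synthetic import rotation_matrix


@dataclass
class TncsHypothesis:
    """A TNCS model: order, translation and the perturbation parameters.

    ``order`` = 1 means "no TNCS" (epsilon identically 1).  ``rot_deg`` is
    the rotation between adjacent copies; ``rot_axis`` may be None, in which
    case the rotational damping is isotropically averaged over axis
    orientations.  ``rmsd`` (sigma_d, Angstrom) is the random coordinate
    difference between adjacent copies; ``r_mol`` the effective molecular
    radius for the interference falloff.
    """

    order: int
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rot_deg: float = 0.0
    rot_axis: np.ndarray | None = None
    rmsd: float = 0.0
    r_mol: float = 12.0

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("TNCS order must be >= 1")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if self.r_mol <= 0:
            raise ValueError("r_mol must be positive")
        self.t = np.asarray(self.t, dtype=float)
        if self.rot_axis is not None:
            ax = np.asarray(self.rot_axis, dtype=float)
            self.rot_axis = ax / np.linalg.norm(ax)

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "t": [round(float(x), 4) for x in self.t],
            "rot_deg": round(float(self.rot_deg), 3),
            "rmsd": round(float(self.rmsd), 3),
            "r_mol": round(float(self.r_mol), 2),
        }


@dataclass
class EpsilonFactors:
    """Per-reflection TNCS expected-intensity factors, mean-normalized."""

    eps: np.ndarray
    d: np.ndarray
    band: tuple[float, float] | None = None

    def __post_init__(self):
        self.eps = np.asarray(self.eps, dtype=float)
        if len(self.eps) and abs(self.eps.mean() - 1.0) > 1e-6:
            raise ValueError("epsilon factors must be normalized to mean 1")

    def to_frame(self, hkl: np.ndarray | None = None):
        """Per-reflection factors as a DataFrame (for CSV export)."""
        import pandas as pd

        data = {"d": self.d, "epsilon": self.eps}
        if hkl is not None:
            hkl = np.asarray(hkl, dtype=int)
            data = {"h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], **data}
        return pd.DataFrame(data)


def g_function(x: np.ndarray) -> np.ndarray:
    """Spherical interference function G(x) = 3 (sin x - x cos x) / x^3.

    G(0) = 1; evaluated with a series near zero for numerical stability.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    small = np.abs(x) < 1e-3
    xs = x[~small]
    out[~small] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    x2 = x[small] ** 2
    out[small] = 1.0 - x2 / 10.0 + x2 * x2 / 280.0
    return out


def _pair_correlation(hkl: np.ndarray, cell: UnitCell, hyp: TncsHypothesis) -> np.ndarray:
    """rho(h): correlation of adjacent-copy contributions, in [0, 1]."""
    d = cell.d_spacings(hkl)
    # Luzzati damping with sin(theta)/lambda = 1/(2d)
    stol2 = 1.0 / (4.0 * d**2)
    damp = np.exp(-(8.0 * math.pi**2 / 3.0) * hyp.rmsd**2 * stol2)
    if hyp.rot_deg != 0.0:
        s = hkl @ cell.frac_matrix()          # reciprocal vectors, 1/Angstrom
        if hyp.rot_axis is not None:
            R = rotation_matrix(hyp.rot_axis, hyp.rot_deg)
            q = s @ R - s
            qn = np.linalg.norm(q, axis=1)
        else:
            qn = 2.0 * math.sin(math.radians(hyp.rot_deg) / 2.0) \
                 * np.linalg.norm(s, axis=1) * math.sqrt(2.0 / 3.0)
        damp = damp * g_function(2.0 * math.pi * hyp.r_mol * qn)
    return np.clip(damp, 0.0, 1.0)


def _symmetry_images(t: np.ndarray, sg: SpaceGroupInfo) -> np.ndarray:
    """Distinct images of the TNCS translation under the rotational parts of
    the space group.  Symmetry copies of the TNCS pair are related by R t,
    and very different images tend to cancel each other's modulation."""
    images = []
    seen = set()
    for R in sg.rotation_arrays():
        img = R @ t
        key = tuple(np.round(np.mod(img, 1.0), 6))
        if key not in seen:
            seen.add(key)
            images.append(img)
    return np.array(images)


def epsilon_factors(hkl: np.ndarray, hyp: TncsHypothesis, cell: UnitCell,
                    sg: SpaceGroupInfo, band: tuple[float, float] | None = None
                    ) -> EpsilonFactors:
    """TNCS epsilon factors for the given reflections and hypothesis."""
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    if len(hkl) == 0:
        raise ValueError("empty reflection set")
    d = cell.d_spacings(hkl)
    n = hyp.order
    if n == 1:
        return EpsilonFactors(eps=np.ones(len(hkl)), d=d, band=band)
    rho = _pair_correlation(hkl, cell, hyp)
    images = _symmetry_images(hyp.t, sg)
    g = np.zeros(len(hkl))
    for t_s in images:
        phase = 2.0 * math.pi * (hkl @ t_s)
        gi = np.full(len(hkl), float(n))
        for m in range(1, n):
            gi += 2.0 * (n - m) * rho**m * np.cos(m * phase)
        g += gi
    g /= len(images)
    g = np.maximum(g, 0.0)
    mean = g.mean()
    if mean <= 0:
        raise ValueError("degenerate hypothesis: zero mean expected intensity")
    return EpsilonFactors(eps=g / mean, d=d, band=band)


def eps_tncs(eps: EpsilonFactors) -> float:
    """The eps-TNCS statistic sigma_1^2: variance of epsilon about 1.

    Zero for unmodulated data; n - 1 for ideal commensurate TNCS of order n
    with balanced reflection classes; bounded by (n/2)^2 + (n/2 - 1)^2.
    """
    if len(eps.eps) == 0:
        raise ValueError("empty epsilon factors")
    return float(np.mean((eps.eps - 1.0) ** 2))


@dataclass
class RefinementResult:
    hypothesis: TncsHypothesis
    epsilon: EpsilonFactors
    sigma1_sq: float
    log_likelihood: float
    converged: bool
    n_reflections: int

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis.to_dict(),
            "sigma1_sq": round(self.sigma1_sq, 4),
            "log_likelihood": round(self.log_likelihood, 2),
            "converged": self.converged,
            "n_reflections": self.n_reflections,
        }


def _bin_indices(d: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal reciprocal-volume resolution bins (uniform in 1/d^3)."""
    s3 = 1.0 / np.maximum(d, 1e-9) ** 3
    edges = np.linspace(s3.min(), s3.max() * (1 + 1e-12), n_bins + 1)
    return np.clip(np.digitize(s3, edges) - 1, 0, n_bins - 1)


def wilson_log_likelihood(I: np.ndarray, eps: np.ndarray, bins: np.ndarray,
                          n_bins: int) -> float:
    """Acentric Wilson log-likelihood with profiled bin means.

    p(I) = 1/(eps Sigma_bin) exp(-I / (eps Sigma_bin)); the per-bin mean
    intensity Sigma_bin is profiled out at its maximum-likelihood value
    mean(I / eps) over the bin.  Centric reflections are treated with the
    same acentric form (documented approximation).
    """
    eps = np.maximum(eps, 1e-3)
    I = np.maximum(I, 0.0)
    logl = 0.0
    for b in range(n_bins):
        m = bins == b
        if m.sum() < 3:
            continue
        sigma = np.mean(I[m] / eps[m])
        sigma = max(sigma, 1e-12)
        logl += float(np.sum(-np.log(eps[m] * sigma) - I[m] / (eps[m] * sigma)))
    return logl


def refine_tncs(rs: ReflectionSet, hyp0: TncsHypothesis,
                band: tuple[float, float] = (5.0, 10.0),
                n_bins: int = 20,
                rot_starts: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0),
                rmsd_starts: tuple[float, ...] = (0.3, 1.0)) -> RefinementResult:
    """Refine the TNCS rotational perturbation and r.m.s.d. against the data.

    The rotation is parametrized as a 3-component rotation vector (degrees);
    multiple starts over perturbation magnitudes about the coordinate axes
    guard against local optima.  The translation vector and order are fixed
    by the hypothesis.  Returns the best local optimum; when no start
    improves on the initial model the input hypothesis is returned with
    ``converged=False``.
    """
    sel = (rs.d >= band[0]) & (rs.d <= band[1])
    if sel.sum() < 200:
        raise ValueError(f"need >= 200 reflections in the {band} A band, "
                         f"have {int(sel.sum())}")
    hkl = rs.hkl[sel]
    I = rs.I[sel]
    d = rs.d[sel]
    bins = _bin_indices(d, n_bins)

    def hyp_from(params: np.ndarray) -> TncsHypothesis:
        vec = params[:3]
        ang = float(np.linalg.norm(vec))
        axis = vec / ang if ang > 1e-9 else None
        return replace(hyp0, rot_deg=ang, rot_axis=axis,
                       rmsd=float(abs(params[3])))

    def neg_logl(params: np.ndarray) -> float:
        eps = epsilon_factors(hkl, hyp_from(params), rs.cell, rs.sg, band=band)
        return -wilson_log_likelihood(I, eps.eps, bins, n_bins)

    v0 = (hyp0.rot_axis if hyp0.rot_axis is not None else np.array([1.0, 0, 0]))
    p_init = np.array([*(hyp0.rot_deg * v0), hyp0.rmsd])
    logl0 = -neg_logl(p_init)

    starts = [p_init]
    axes = [np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0])]
    for ang in rot_starts:
        for rm in rmsd_starts:
            if ang == 0.0:
                starts.append(np.array([0.0, 0.0, 0.0, rm]))
            else:
                for ax in axes:
                    starts.append(np.array([*(ang * ax), rm]))

    bounds = [(-25.0, 25.0)] * 3 + [(0.0, 4.0)]
    best_p, best_val = p_init, -logl0
    for p0 in starts:
        try:
            res = minimize(neg_logl, p0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 200, "ftol": 1e-10})
        except Exception:
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val, best_p = float(res.fun), res.x

    converged = best_val < -logl0 - 1e-9 or np.allclose(best_p, p_init)
    if not converged:
        warnings.warn("TNCS refinement did not improve on the initial model")
        best_p = p_init
        best_val = -logl0
    hyp = hyp_from(best_p)
    eps = epsilon_factors(hkl, hyp, rs.cell, rs.sg, band=band)
    return RefinementResult(hypothesis=hyp, epsilon=eps,
                            sigma1_sq=eps_tncs(eps),
                            log_likelihood=-best_val,
                            converged=converged,
                            n_reflections=int(sel.sum()))
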