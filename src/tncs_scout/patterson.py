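"""Band-limited Patterson synthesis and origin-relative peak analysis.

The Patterson function is the Fourier transform of the intensities; exact or
approximate TNCS places a large off-origin peak at the translation vector (and
its multiples for higher orders).  Peaks are characterized relative to the
origin peak: percentage height, Z-score over the map away from the origin
region, and minimum-image distance from the origin.  The default analysis
band is 5-10 A, which emphasizes the low-resolution molecular transform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.fft import fftn, next_fast_len

from .reflection_io import ReflectionSet, SpaceGroupInfo, UnitCell


class PattersonBandError(ValueError):
    """Raised when the requested resolution band contains too few data."""


class PathologicalCellError(ValueError):
    """Raised when a cell edge is shorter than the origin-exclusion distance.

    Such cells (most likely peptides) cannot host a TNCS vector beyond the
    exclusion radius and are excluded from analysis.
    """


@dataclass
class PattersonPeak:
    """A symmetry-unique off-origin Patterson peak."""

    frac: np.ndarray          # fractional coordinates in [0, 1)^3
    height: float             # map value (arbitrary scale)
    height_pct: float         # 100 * height / origin height
    zscore: float             # (height - map mean) / map s.d., origin masked
    orth_dist: float          # min-image distance from the origin, Angstrom

    def to_dict(self) -> dict:
        return {
            "frac": [round(float(x), 6) for x in self.frac],
            "height_pct": round(self.height_pct, 3),
            "zscore": round(self.zscore, 3),
            "orth_dist": round(self.orth_dist, 3),
        }


@dataclass
class PattersonMap:
    """Patterson function sampled on a fractional grid.

    The map is centrosymmetric, v(x) = v(-x), and the origin is its global
    maximum for any physically valid (non-negative) intensity set.  Mean and
    standard deviation for Z-scores are computed over grid points outside a
    sphere of ``stat_mask_radius`` around the origin (minimum-image), since
    the origin peak would otherwise dominate the moments.
    """

    values: np.ndarray
    cell: UnitCell
    sg: SpaceGroupInfo
    band: tuple[float, float]
    stat_mask_radius: float = 15.0
    _stats: tuple[float, float] | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def origin_height(self) -> float:
        return float(self.values[0, 0, 0])

    def grid_fracs(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(np.arange(n) / n for n in self.shape)

    def min_image_distances(self) -> np.ndarray:
        """Min-image orthogonal distance from the origin for each grid point."""
        fx, fy, fz = self.grid_fracs()
        fx = np.minimum(fx, 1 - fx)[:, None, None]
        fy = np.minimum(fy, 1 - fy)[None, :, None]
        fz = np.minimum(fz, 1 - fz)[None, None, :]
        # For the general (oblique) cell the min-image must scan neighbours;
        # done via min_image_dist on demand for peaks.  For the grid mask the
        # wrapped-component approximation is adequate for near-orthogonal
        # cells and errs on the inclusive side.
        O = self.cell.orth_matrix()
        xs = fx * O[0, 0]
        ys = fy * O[1, 1]
        zs = fz * O[2, 2]
        if abs(O[0, 1]) + abs(O[0, 2]) + abs(O[1, 2]) > 1e-6:
            g = np.stack(np.meshgrid(*[np.arange(n) / n for n in self.shape],
                                     indexing="ij"), axis=-1)
            return min_image_dist(g.reshape(-1, 3), self.cell).reshape(self.shape)
        return np.sqrt(xs**2 + ys**2 + zs**2)

    def stats(self) -> tuple[float, float]:
        """(mean, sd) of the map outside the origin-exclusion sphere."""
        if self._stats is None:
            mask = self.min_image_distances() >= self.stat_mask_radius
            if not mask.any():
                mask = np.ones(self.shape, dtype=bool)
            vals = self.values[mask]
            self._stats = (float(vals.mean()), float(vals.std()))
        return self._stats

    def value_at(self, frac: np.ndarray) -> float:
        """Trilinearly interpolated map value at a fractional position."""
        idx = np.mod(np.asarray(frac, float), 1.0) * np.array(self.shape)
        return float(ndimage.map_coordinates(self.values, idx.reshape(3, 1),
                                             order=1, mode="grid-wrap")[0])


def write_ccp4(pmap: PattersonMap, path) -> None:
    """Export the Patterson map in CCP4 format for graphical inspection."""
    import gemmi

    grid = gemmi.FloatGrid(*pmap.shape)
    grid.set_unit_cell(pmap.cell.gemmi)
    grid.spacegroup = gemmi.find_spacegroup_by_name("P 1")
    arr = np.array(grid, copy=False)
    arr[...] = pmap.values.astype(np.float32)
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


def min_image_dist(frac: np.ndarray, cell: UnitCell) -> np.ndarray:
    """Minimum distance (A) from the origin over the 27 neighbouring lattice
    translations, for fractional positions."""
    frac = np.atleast_2d(np.mod(np.asarray(frac, dtype=float), 1.0))
    shifts = np.array([(i, j, k) for i in (-1, 0, 1)
                       for j in (-1, 0, 1) for k in (-1, 0, 1)])
    best = np.full(len(frac), np.inf)
    for sh in shifts:
        d = np.linalg.norm(cell.orthogonalize(frac + sh), axis=1)
        best = np.minimum(best, d)
    return best


def compute_patterson(rs: ReflectionSet, dmin: float = 5.0, dmax: float = 10.0,
                      grid_factor: float = 4.0,
                      stat_mask_radius: float = 15.0) -> PattersonMap:
    """Inverse Fourier synthesis of band intensities on a fractional grid.

    Reflections in the band are expanded to the full sphere under the Laue
    group and Friedel symmetry; F(000) is omitted (the synthesized map has
    zero mean before the origin term, so only relative heights matter).  Grid
    spacing is at most ``dmin / grid_factor`` per axis, rounded to
    FFT-friendly sizes.  The net-positive mask from intensity recovery is
    honoured when present.
    """
    band = (rs.d >= dmin) & (rs.d <= dmax)
    if rs.patterson_mask is not None:
        band &= rs.patterson_mask
    n_in_band = int(band.sum())
    if n_in_band < 30:
        raise PattersonBandError(
            f"only {n_in_band} reflections in the {dmin}-{dmax} A band")
    hkl = rs.hkl[band]
    I = rs.I[band]

    dims = tuple(next_fast_len(max(int(math.ceil(grid_factor * length / dmin)), 8))
                 for length in rs.cell.lengths)

    # expand to the full sphere: h' = h R for every Laue rotation (includes -I).
    # Orbit images carry identical intensity, so plain assignment both fills
    # and deduplicates; grid dims exceed 2*hmax so no aliasing collisions.
    grid = np.zeros(dims, dtype=float)
    for R in rs.sg.laue_rotations():
        img = hkl @ R
        grid[img[:, 0] % dims[0], img[:, 1] % dims[1], img[:, 2] % dims[2]] = I
    # P(u) = sum_h I(h) exp(-2 pi i h.u): forward FFT of the filled grid
    values = fftn(grid).real
    return PattersonMap(values=values, cell=rs.cell, sg=rs.sg,
                        band=(dmin, dmax), stat_mask_radius=stat_mask_radius)


def _quadratic_refine(values: np.ndarray, idx: tuple[int, int, int]) -> tuple[np.ndarray, float]:
    """Sub-grid peak position/height by separable quadratic interpolation
    over the 3x3x3 neighbourhood (per-axis parabola through the maximum)."""
    dims = values.shape
    offset = np.zeros(3)
    height = float(values[idx])
    for ax in range(3):
        lo = list(idx); hi = list(idx)
        lo[ax] = (idx[ax] - 1) % dims[ax]
        hi[ax] = (idx[ax] + 1) % dims[ax]
        fm, f0, fp = float(values[tuple(lo)]), height, float(values[tuple(hi)])
        denom = fm - 2.0 * f0 + fp
        if denom < -1e-12:
            off = 0.5 * (fm - fp) / denom
            off = float(np.clip(off, -0.5, 0.5))
            offset[ax] = off
            height = max(height, f0 - 0.25 * (fm - fp) * off)
    frac = (np.array(idx) + offset) / np.array(dims)
    return np.mod(frac, 1.0), height


def _canonical_frac(frac: np.ndarray, rots: np.ndarray, dims: tuple) -> tuple:
    """Canonical representative of a peak position under the Patterson
    symmetry (Laue rotations, which include the inversion): the
    lexicographically smallest grid-rounded image."""
    best = None
    for R in rots:
        img = np.mod(frac @ R, 1.0)
        key = tuple(int(round(x * n)) % n for x, n in zip(img, dims))
        if best is None or key < best:
            best = key
    return best


def pick_peaks(pmap: PattersonMap, min_dist: float = 15.0,
               min_height_pct: float = 16.8,
               merge_grid_pts: int = 2) -> list[PattersonPeak]:
    """Symmetry-unique local maxima above the height and distance thresholds.

    Raises :class:`PathologicalCellError` when any cell edge is shorter than
    ``min_dist`` — no genuine TNCS vector can then clear the origin-exclusion
    sphere.  Peaks closer together than ``merge_grid_pts`` grid points are
    merged (the taller one kept).  The list is sorted by descending height,
    ties broken lexicographically on fractional coordinates.
    """
    if min(pmap.cell.lengths) < min_dist:
        raise PathologicalCellError(
            f"cell edge shorter than origin-distance threshold {min_dist} A")
    values = pmap.values
    origin = pmap.origin_height
    if origin <= 0:
        return []
    local_max = values >= ndimage.maximum_filter(values, size=3, mode="wrap")
    high = values >= (min_height_pct / 100.0) * origin
    cand = np.argwhere(local_max & high)
    if len(cand) == 0:
        return []

    mean, sd = pmap.stats()
    dims = pmap.shape
    rots = pmap.sg.laue_rotations()
    by_canon: dict[tuple, tuple] = {}
    for idx in map(tuple, cand):
        frac, height = _quadratic_refine(values, idx)
        dist = float(min_image_dist(frac, pmap.cell)[0])
        if dist < min_dist:
            continue
        canon = _canonical_frac(frac, rots, dims)
        prev = by_canon.get(canon)
        if prev is None or height > prev[1]:
            by_canon[canon] = (frac, height, dist)

    # merge near-duplicates (within merge_grid_pts grid points, min-image)
    entries = sorted(by_canon.values(), key=lambda e: (-e[1], tuple(e[0])))
    step = np.min(np.array(pmap.cell.lengths) / np.array(dims))
    merge_dist = merge_grid_pts * step
    kept: list[tuple] = []
    for e in entries:
        dup = False
        for k in kept:
            delta = np.mod(e[0] - k[0] + 0.5, 1.0) - 0.5
            if np.linalg.norm(pmap.cell.orthogonalize(delta)) < merge_dist:
                dup = True
                break
        if not dup:
            kept.append(e)

    peaks = []
    for frac, height, dist in kept:
        z = (height - mean) / sd if sd > 0 else float("nan")
        peaks.append(PattersonPeak(frac=frac, height=height,
                                   height_pct=100.0 * height / origin,
                                   zscore=z, orth_dist=dist))
    peaks.sort(key=lambda p: (-p.height_pct, tuple(np.round(p.frac, 6))))
    return peaks


def zscore_threshold(pmap: PattersonMap, peak: PattersonPeak,
                     t: float = 11.36) -> bool:
    """True iff the peak's Z-score is at least ``t``.

    The default 11.36 is the threshold appropriate to a 5-15 A band at 10
    degrees rotational tolerance.  A constant map has undefined Z-scores and
    yields False with a warning.
    """
    _, sd = pmap.stats()
    if sd == 0 or not np.isfinite(peak.zscore):
        warnings.warn("map has zero variance; Z-score undefined")
        return False
    return peak.zscore >= t


def coiled_coil_filter(peaks: list[PattersonPeak],
                       spacing_window: tuple[float, float] = (4.5, 6.0),
                       min_cluster: int = 3) -> list[PattersonPeak]:
    """Remove peak clusters with the short, regular origin-distance spacing
    characteristic of coiled-coil helical repeats.

    Peaks are ordered by origin distance; any run of ``min_cluster`` or more
    whose successive distance increments all fall inside ``spacing_window``
    is excluded from TNCS analysis.  The defaults (4.5-6.0 A) bracket the
    alpha-helical rise repeat; they are heuristics, exposed as configuration.
    """
    if len(peaks) < min_cluster:
        return list(peaks)
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].orth_dist)
    drop: set[int] = set()
    run = [order[0]]
    for prev, cur in zip(order, order[1:]):
        gap = peaks[cur].orth_dist - peaks[prev].orth_dist
        if spacing_window[0] <= gap <= spacing_window[1]:
            run.append(cur)
        else:
            if len(run) >= min_cluster:
                drop.update(run)
            run = [cur]
    if len(run) >= min_cluster:
        drop.update(run)
    return [p for i, p in enumerate(peaks) if i not in drop]
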