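"""TNCS detection: peak interpretation, commensurate-order analysis and a
ranked hypothesis list.

The pipeline computes a 5-10 A Patterson function, picks off-origin peaks
above the calibrated defaults (15 A origin distance, 16.8% of the origin
height), and interprets them.  A noise-reduced Patterson (values below 8% of
the origin set to zero) is transformed back to reciprocal space, where
commensurate modulation of order n shows up as strong Fourier terms on the
sublattice {h : h . t integer}.  Each surviving commensurate order yields a
hypothesis predicting peaks at every multiple of the basic vector;
commensurate hypotheses that explain the top peak are ranked first, then the
remaining commensurate ones, then one independent order-2 hypothesis per
surviving peak (strength ranked by peak height), and the "no TNCS"
hypothesis is always appended last — strong Patterson peaks can arise from
lattice-translocation disorder without any true TNCS.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from itertools import product

import numpy as np
from scipy.fft import ifftn

from .patterson import (
    PathologicalCellError,
    PattersonMap,
    PattersonPeak,
    coiled_coil_filter,
    compute_patterson,
    pick_peaks,
    zscore_threshold,
)
from .reflection_io import ReflectionSet, completeness, recover_intensities
from .tncs_model import TncsHypothesis


@dataclass
class DetectionConfig:
    """All thresholds of the detection algorithm, with calibrated defaults."""

    pmin: float = 5.0            # Patterson band, Angstrom
    pmax: float = 10.0
    origin_dist: float = 15.0    # origin-exclusion radius, Angstrom
    peak_frac: float = 16.8      # % of origin height
    use_zscore: bool = False     # alternative Z-score threshold (5-15 A band)
    zscore_t: float = 11.36
    noise_floor: float = 8.0     # % of origin for the noise-reduced Patterson
    max_order: int = 8
    strong_factor: float = 3.0   # Fourier-term significance vs median
    max_fourier_index: int = 8
    match_tol: float = 0.02      # fractional, predicted-peak matching
    dmin_truncate: float = 3.0
    completeness_warn: float = 0.8
    coiled_coil_window: tuple[float, float] = (4.5, 6.0)
    grid_factor: float = 4.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CommensurateCandidate:
    order: int
    t: np.ndarray
    predicted_peaks: list[np.ndarray]
    score: float                # mean |Fourier term| on the sublattice / median
    support: int                # predicted peaks above the noise floor


@dataclass
class RankedHypothesis:
    hypothesis: TncsHypothesis
    evidence: dict

    def to_dict(self) -> dict:
        return {"hypothesis": self.hypothesis.to_dict(), "evidence": self.evidence}


@dataclass
class TncsReport:
    status: str                           # hypotheses | tncs-not-indicated | pathological
    hypotheses: list[RankedHypothesis]
    peaks: list[PattersonPeak]
    warnings: list[str] = field(default_factory=list)
    config: DetectionConfig = field(default_factory=DetectionConfig)

    @property
    def top(self) -> RankedHypothesis | None:
        return self.hypotheses[0] if self.hypotheses else None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "hypotheses": [h.to_dict() for h in self.hypotheses],
            "peaks": [p.to_dict() for p in self.peaks],
            "warnings": self.warnings,
            "config": self.config.to_dict(),
        }


# ---------------------------------------------------------------------------
# commensurate analysis

def _canonical_divisor(c: tuple[int, int, int], n: int) -> tuple[int, int, int]:
    """Canonical generator of the cyclic translation group {m c / n}: the
    lexicographically smallest multiple m c mod n over m coprime with n."""
    best = None
    for m in range(1, n):
        if math.gcd(m, n) != 1:
            continue
        cand = tuple((m * ci) % n for ci in c)
        if best is None or cand < best:
            best = cand
    return best


def commensurate_orders(pmap: PattersonMap, noise_floor_pct: float = 8.0,
                        max_order: int = 8, strong_factor: float = 3.0,
                        max_index: int = 8) -> list[CommensurateCandidate]:
    """Detect commensurate pseudo-cell modulation in the noise-reduced map.

    Values below ``noise_floor_pct`` % of the origin are zeroed and the map
    is Fourier-transformed; order-n TNCS with basic vector t = c/n leaves
    strong terms exactly on the sublattice {h : h.c = 0 mod n}.  A candidate
    (n, t) is kept when its sublattice terms are strong (mean magnitude at
    least ``strong_factor`` times the median over the low-order terms OFF the
    sublattice — the sublattice can be a large fraction of the index box, so
    the on-sublattice terms must not contaminate their own baseline) and at
    least ceil((n-1)/2) of its predicted peaks survive the noise floor —
    imperfect translations leave some predicted peaks below threshold.
    """
    values = pmap.values
    origin = pmap.origin_height
    if origin <= 0:
        return []
    floored = np.where(values >= (noise_floor_pct / 100.0) * origin, values, 0.0)
    coeffs = ifftn(floored)
    dims = pmap.shape

    box = [h for h in product(range(-max_index, max_index + 1), repeat=3)
           if h != (0, 0, 0)]
    mags = {h: abs(coeffs[h[0] % dims[0], h[1] % dims[1], h[2] % dims[2]])
            for h in box}
    mean_all = float(np.mean(list(mags.values())))

    out = []
    seen: set[tuple[int, tuple[int, int, int]]] = set()
    for n in range(2, max_order + 1):
        for c in product(range(n), repeat=3):
            if c == (0, 0, 0):
                continue
            if math.gcd(math.gcd(c[0], c[1]), math.gcd(c[2], n)) != 1:
                continue
            canon = _canonical_divisor(c, n)
            if (n, canon) in seen:
                continue
            seen.add((n, canon))
            c = canon
            t = np.array(c, dtype=float) / n
            on_sub = [(h[0] * c[0] + h[1] * c[1] + h[2] * c[2]) % n == 0
                      for h in box]
            sub_mags = [m for m, s in zip(mags.values(), on_sub) if s]
            off_mags = [m for m, s in zip(mags.values(), on_sub) if not s]
            if not sub_mags or not off_mags:
                continue
            baseline = max(float(np.median(off_mags)), 1e-9 * mean_all, 1e-300)
            score = float(np.mean(sub_mags)) / baseline
            if score < strong_factor:
                continue
            predicted = [np.mod(m * t, 1.0) for m in range(1, n)]
            support = sum(1 for p in predicted if pmap.value_at(p) >
                          (noise_floor_pct / 100.0) * origin)
            if support < math.ceil((n - 1) / 2):
                continue
            out.append(CommensurateCandidate(order=n, t=t,
                                             predicted_peaks=predicted,
                                             score=score, support=support))
    out.sort(key=lambda cd: (-cd.order, -cd.score, tuple(cd.t)))
    return out


# ---------------------------------------------------------------------------
# ranking

def _frac_match(a: np.ndarray, b: np.ndarray, rots: np.ndarray, tol: float) -> bool:
    """True if fractional vectors a and b agree within tol under any Laue
    image and minimum-image wrap (a Patterson peak is only defined up to its
    symmetry orbit and centrosymmetric mate)."""
    for R in rots:
        delta = np.mod(a - b @ R + 0.5, 1.0) - 0.5
        if np.all(np.abs(delta) <= tol):
            return True
    return False


def rank_hypotheses(peaks: list[PattersonPeak],
                    candidates: list[CommensurateCandidate],
                    pmap: PattersonMap,
                    config: DetectionConfig | None = None) -> TncsReport:
    """Assemble the ranked hypothesis list from surviving peaks and
    commensurate candidates; the "no TNCS" entry is always last."""
    config = config or DetectionConfig()
    no_tncs = RankedHypothesis(hypothesis=TncsHypothesis(order=1),
                               evidence={"note": "no TNCS"})
    if not peaks:
        return TncsReport(status="tncs-not-indicated", hypotheses=[no_tncs],
                          peaks=[], config=config)
    rots = pmap.sg.laue_rotations()
    tol = config.match_tol
    top_peak = peaks[0]

    ranked_comm: list[tuple[tuple, RankedHypothesis]] = []
    explained_t: list[tuple[int, np.ndarray]] = []
    for cand in candidates:
        matched = []
        for p_idx, peak in enumerate(peaks):
            if any(_frac_match(peak.frac, pred, rots, tol)
                   for pred in cand.predicted_peaks):
                matched.append(p_idx)
        coverage = sum(1 for pred in cand.predicted_peaks
                       if any(_frac_match(pk.frac, pred, rots, tol) for pk in peaks)
                       ) / max(len(cand.predicted_peaks), 1)
        predicts_top = 0 in matched
        hyp = TncsHypothesis(order=cand.order, t=cand.t)
        ev = {
            "kind": "commensurate",
            "predicts_top_peak": predicts_top,
            "coverage": round(coverage, 3),
            "supporting_peaks": matched,
            "top_peak_height_pct": round(top_peak.height_pct, 2),
            "fourier_score": round(cand.score, 2),
        }
        key = (0 if predicts_top else 1, -coverage, -cand.score, -cand.order,
               tuple(np.round(cand.t, 6)))
        ranked_comm.append((key, RankedHypothesis(hyp, ev)))
        explained_t.append((cand.order, cand.t))
    ranked_comm.sort(key=lambda kv: kv[0])

    ranked_pair: list[RankedHypothesis] = []
    for peak in peaks:
        dup = any(o == 2 and _frac_match(peak.frac, t, rots, tol)
                  for o, t in explained_t)
        if dup:
            continue
        hyp = TncsHypothesis(order=2, t=np.mod(peak.frac, 1.0))
        ev = {
            "kind": "independent-pair",
            "height_pct": round(peak.height_pct, 2),
            "zscore": round(peak.zscore, 2),
            "orth_dist": round(peak.orth_dist, 2),
        }
        ranked_pair.append(RankedHypothesis(hyp, ev))

    hypotheses = [rh for _, rh in ranked_comm] + ranked_pair + [no_tncs]
    return TncsReport(status="hypotheses", hypotheses=hypotheses,
                      peaks=peaks, config=config)


# ---------------------------------------------------------------------------
# end-to-end detection

def detect_tncs(rs: ReflectionSet, config: DetectionConfig | None = None
                ) -> TncsReport:
    """Full detection pipeline on a merged reflection set.

    recover intensities -> band-limited Patterson -> peak picking with the
    coiled-coil cluster exclusion -> commensurate-order analysis -> ranked
    hypotheses.  Cells with an edge shorter than the origin-distance
    threshold are reported as pathological; data below the completeness
    threshold produce a warning (detection reliability degrades with missing
    wedges), not a failure.
    """
    config = config or DetectionConfig()
    warns: list[str] = []
    rs = recover_intensities(rs)
    try:
        frac_complete = completeness(rs, config.pmin, config.pmax)
        if frac_complete < config.completeness_warn:
            warns.append(f"data only {100 * frac_complete:.1f}% complete in the "
                         f"{config.pmin}-{config.pmax} A band; detection is "
                         "less reliable on incomplete data")
    except ValueError:
        pass
    pmap = compute_patterson(rs, dmin=config.pmin, dmax=config.pmax,
                             grid_factor=config.grid_factor,
                             stat_mask_radius=config.origin_dist)
    try:
        peaks = pick_peaks(pmap, min_dist=config.origin_dist,
                           min_height_pct=config.peak_frac)
    except PathologicalCellError as exc:
        return TncsReport(status="pathological", hypotheses=[],
                          peaks=[], warnings=[str(exc)], config=config)
    peaks = coiled_coil_filter(peaks, spacing_window=config.coiled_coil_window)
    if config.use_zscore:
        peaks = [p for p in peaks if zscore_threshold(pmap, p, config.zscore_t)]
    if not peaks:
        report = TncsReport(
            status="tncs-not-indicated",
            hypotheses=[RankedHypothesis(TncsHypothesis(order=1),
                                         {"note": "no TNCS"})],
            peaks=[], warnings=warns, config=config)
        return report
    candidates = commensurate_orders(pmap,
                                     noise_floor_pct=config.noise_floor,
                                     max_order=config.max_order,
                                     strong_factor=config.strong_factor,
                                     max_index=config.max_fourier_index)
    report = rank_hypotheses(peaks, candidates, pmap, config)
    report.warnings = warns + report.warnings
    return report
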