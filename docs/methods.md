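# Methods

This note records the models, conventions and numerical choices behind
tncs-scout, and what the synthetic validation does and does not establish.

## Reflection handling

Input is merged data in MTZ or structure-factor mmCIF. Provenance is
inferred from the available columns with precedence *mean intensity* >
*anomalous intensity* > *amplitude*; whether amplitudes came from a
French & Wilson treatment cannot be read from the file, so a user flag
selects between reversal and plain squaring (default: reversal, the common
case for deposited amplitudes). Recovery rules:

* **Mean intensities** are used as stored. Only net-positive reflections
  enter the Patterson synthesis; all reflections are retained for
  likelihood work (the two uses have different robustness requirements).
* **Anomalous intensities**: unweighted mean of the Friedel mates;
  a singleton mate is used alone.
* **French–Wilson amplitudes**: the acentric posterior-mean mapping
  I ↦ E[√J | I, σI, Σ] (truncated-Gaussian posterior under an exponential
  Wilson prior with bin-wise mean Σ) is inverted per reflection by bisection
  to 1e-8 relative. Moments are computed by Gauss–Legendre quadrature after
  the substitution J = u², which removes the √J cusp at the truncation
  point. σI is recovered from σF by first-order propagation (σI ≈ 2F·σF)
  when not supplied; Σ is estimated from bin means of F² and re-estimated
  once from the inverted intensities. The forward map is strictly
  increasing in I, so the inverse is unique.
* **Raw amplitudes**: I = F²; reflections deposited as F = 0 (negative
  experimental intensities) stay at I = 0.

The reciprocal-space asymmetric unit is the lexicographically largest
member of the Laue orbit {±R**h**} — an arbitrary but fixed canonical
choice. Completeness is observed unique reflections over a brute-force
enumeration of the theoretical unique set in the shell, with systematic
absences of translational symmetry elements removed.

## Patterson synthesis and peak statistics

The Patterson function is synthesized by FFT from band intensities
(default 5–10 Å) expanded to the full sphere under the Laue group plus
Friedel symmetry; F(000) is omitted. Grid spacing is at most dmin/4 per
axis (1.25 Å at the default band), rounded up to FFT-friendly sizes —
fine enough that peak positions are resolved far below the 15 Å exclusion
radius. Peak positions and heights are refined by separable quadratic
interpolation over the 3×3×3 neighbourhood; peaks are reduced to
symmetry-unique representatives under the Patterson symmetry and merged
within two grid points (minimum image). Ties in height break
lexicographically on fractional coordinates, making reports deterministic.

Origin distance uses the minimum over the 27 neighbouring lattice images.
Z-score statistics (mean, s.d.) are computed over all grid points outside
the origin-exclusion sphere (same radius as the distance threshold,
configurable) — with the origin region included, the origin peak would
dominate the moments.

Defaults: origin distance 15 Å, peak height 16.8 % of the origin, Z-score
option 11.36 (appropriate to a 5–15 Å band). Cells with an edge shorter
than the origin-exclusion distance cannot host an admissible TNCS vector
and are reported as *pathological*. Peak ladders whose successive origin
distances repeat a spacing in a configurable window (default 4.5–6.0 Å,
bracketing the α-helical rise) are excluded as coiled-coil pseudo-symmetry;
the window is a heuristic, not a calibrated value.

## Commensurate-order analysis

Noise reduction zeroes all map values below 8 % of the origin; the floored
map is Fourier-transformed. For a commensurate hypothesis **t** = **c**/n
(components of **c** reduced so gcd(**c**, n) = 1, generator canonicalized
to the lexicographically smallest coprime multiple), the signature is
strong terms on the sublattice {**h** : **h**·**c** ≡ 0 (mod n)}. A
candidate is accepted when the mean magnitude over its sublattice (indices
with max |index| ≤ 8) is at least 3× the median over the *off-sublattice*
indices — the sublattice can be as much as half the index box, so its own
terms must not contaminate the baseline — and at least ⌈(n−1)/2⌉ of its
predicted peaks at m·**t** survive the noise floor (imperfect translations
push some predicted peaks below threshold). Orders up to 8 are considered.

Ranking: commensurate hypotheses that predict the top peak first (by
predicted-peak coverage, then Fourier score), remaining commensurate ones
next, then an independent order-2 hypothesis per surviving peak ordered by
height (skipping duplicates of commensurate order-2 vectors within the
0.02-fractional matching tolerance), and always "no TNCS" last.

## Epsilon-factor model

For order n with basic translation **t**, the TNCS expected-intensity
factor before normalization is

    g(h) = n + 2 Σ_{m=1}^{n−1} (n − m) ρ(h)^m cos(2π m h·t_s),

averaged over the distinct images t_s = R **t** under the rotational parts
of the space group (very different symmetry images cancel each other's
modulation). ε = g/⟨g⟩ has mean 1 by construction (enforced to 1e-6).
The adjacent-copy correlation ρ ∈ [0, 1] combines:

* **Coordinate differences**: the Luzzati factor
  D = exp(−(8π²/3) σΔ² (sin θ/λ)²) with sin θ/λ = 1/(2d), where σΔ is the
  r.m.s. deviation between adjacent copies. This normalization is exact for
  isotropic Gaussian displacements: copies jittered independently with
  per-atom r.m.s. σ differ by σΔ = √2·σ, and the model then reproduces the
  Monte-Carlo mean intensity of the point-atom simulator per reflection
  class (validated to 3 standard errors).
* **Rotational differences**: the spherical interference (G-function)
  falloff G(x) = 3(sin x − x cos x)/x³ with x = 2π R_mol |q|, where
  q = R_rotᵀ s − s is the reciprocal-space offset the perturbation rotation
  produces on the scattering vector s (exact, direction-dependent, when the
  rotation axis is known) or its isotropic r.m.s.
  |q| ≈ 2 sin(θ/2)|s|·√(2/3) when it is not. R_mol is the effective
  molecular radius; the uniform-sphere form is exact for the synthetic
  molecules and an approximation for real ones.

For n > 2, relative orientations between non-adjacent copies are not
modelled separately; the geometric decay ρ^m absorbs them approximately.

**eps-TNCS** is σ₁² = ⟨(ε − 1)²⟩: zero for unmodulated data, n − 1 for
ideal commensurate order n with balanced reflection classes, and bounded by
(n/2)² + (n/2 − 1)² (checked, not derived, for all tested hypotheses to
n = 8).

## Likelihood refinement

The rotational perturbation (3-component rotation vector, degrees) and σΔ
are refined by maximizing the acentric Wilson log-likelihood
Σ_h [−log(ε_h Σ_bin) − I_h/(ε_h Σ_bin)] with the bin means Σ_bin profiled
out at their ML values (mean of I/ε per bin; 20 equal reciprocal-volume
bins). Centric reflections are treated with the same acentric form — a
documented approximation that is exact for the P1 validation crystals.
L-BFGS-B runs from a multi-start grid (magnitudes {0, 2, 5, 10}° on the
three coordinate axes × σΔ starts {0.3, 1.0} Å, plus the input hypothesis);
ε is floored at 1e-3 inside the likelihood so exact extinctions cannot
produce −∞. If no start improves on the input model the input is returned
flagged unconverged. The default refinement band is 5–10 Å; parameter
*recovery* of small rotations benefits from the fuller 3–10 Å range, where
the interference falloff is informative (at 5 Å and R_mol = 12 Å a 2°
rotation dampens by under 3 %), and the band is an explicit argument.

## Coordinate-space classifier

Chains with ≥ 95 % sequence identity over the aligned length (global
alignment, Biopython pairwise aligner) are superposed (Kabsch on Cα atoms)
under every space-group operation; the minimal-rotation operation is the
candidate relation. Pairs with rotation ≤ r and translation ≥ 2 Å form a
graph; connected components are closed TNCS groups. Member translations
relative to a reference chain must be multiples of a basic vector within
0.05 fractional per axis; if the full component fails, the largest
consistent subset is reported. The basic vector's sign is canonicalized
(first significant component positive) since it is defined only up to
inversion. The group's scattering fraction is the group's share of total
asymmetric-unit scattering (summed atomic numbers); deposited MTRIX
operators not already applied are expanded before analysis.

## Synthetic crystals and the oracle

The generator places `n_atoms` point scatterers (constant form factor,
B = 0 — band limiting is purely by resolution cuts) uniformly in a sphere
of radius `mol_radius`, then plants copies at m·**t** with rotation
m·rot_deg about the copy centroid (random axis fixed per crystal) and
independent per-atom Gaussian jitter of r.m.s. `jitter` Å. Structure
factors are computed by direct summation over every atom, copy and
symmetry mate — no FFT — so the reflection set is an exact oracle.
Named random streams (coordinates / jitter / noise) derive from one seed.

Degradation removes a contiguous azimuthal wedge about a random axis,
taken modulo π so Friedel-mate directions disappear together (as a missing
rotation range does experimentally); completeness after removal is
1 − wedge_fraction. Multiplicative Gaussian noise is optional.

Default study conditions (chosen once): P1, 70×75×80 Å cell, 100 atoms,
12 Å molecular radius — a small-protein-sized scatterer in a cell that
comfortably separates TNCS peaks from the 15 Å origin exclusion. The
detection cohort plants orders 2 and 3 with jitter uniform in 0.3–1.0 Å
per atom and rotations up to 3°, spanning near-exact to visibly perturbed
TNCS while staying within the regime where TNCS correction is clearly
warranted.

What the synthetic data do **not** emulate: atomic form factors and B
factors, solvent, measurement-error profiles, anomalous signal, twinning
and lattice-translocation disorder, and the correlation between low
completeness and processing artifacts seen in real archives. Passing tests
therefore establish internal consistency of the models and algorithms on
idealized crystals, not archive-scale accuracy figures. One consequence is
measurable: on these clean crystals the Patterson peak-to-origin ratio is
essentially unbiased under a 50 % wedge removal — the wedge adds variance,
not a systematic deficit — so binary detection barely degrades with
incompleteness, whereas real incomplete data degrade markedly; the
completeness comparison in the acceptance suite documents this gap.

## Numerical conventions

* Rotation angles from matrices: arccos((trace − 1)/2), clipped.
* Fractional translations reduced to (−½, ½] per axis; vector equality is
  tested under lattice wrap, inversion and Laue images.
* G(x) evaluated by series below |x| = 1e-3.
* Patterson grid dimensions via `next_fast_len`, ≥ 4 samples per dmin.
* All stochastic tests are seeded; reports are deterministic for fixed
  input and configuration (tie-breaks are lexicographic).
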