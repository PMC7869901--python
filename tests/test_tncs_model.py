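"""Epsilon factors, the eps-TNCS statistic and Wilson-likelihood refinement."""

from __future__ import annotations

import numpy as np
import pytest

from tncs_scout.reflection_io import enumerate_unique_hkl
from tncs_scout.synthetic import CrystalSpec, direct_sf, generate_crystal
from tncs_scout.tncs_model import (
    EpsilonFactors,
    TncsHypothesis,
    eps_tncs,
    epsilon_factors,
    g_function,
    refine_tncs,
)


@pytest.fixture(scope="module")
def band_hkl(p1_cell, p1_sg):
    return enumerate_unique_hkl(p1_cell, p1_sg, 5.0, 10.0)


class TestEpsilonFactors:
    def test_no_tncs_is_unity(self, band_hkl, p1_cell, p1_sg):
        eps = epsilon_factors(band_hkl, TncsHypothesis(order=1), p1_cell, p1_sg)
        np.testing.assert_array_equal(eps.eps, 1.0)

    def test_ideal_order2_parity_split(self, p1_cell, p1_sg):
        """Exact order-2 TNCS at t=(0,1/2,0): epsilon 2 for even k, 0 for odd."""
        k = np.arange(1, 41)
        hkl = np.column_stack([np.zeros_like(k), k, np.zeros_like(k)])
        hyp = TncsHypothesis(order=2, t=np.array([0.0, 0.5, 0.0]))
        eps = epsilon_factors(hkl, hyp, p1_cell, p1_sg).eps
        np.testing.assert_allclose(eps[k % 2 == 0], 2.0, atol=1e-9)
        np.testing.assert_allclose(eps[k % 2 == 1], 0.0, atol=1e-9)

    def test_damped_order2_partial_modulation(self, p1_sg):
        """With pair correlation rho the classes sit at 1 +- rho.  In a cell
        with a = b, (k,0,0) and (0,k,0) share the same resolution exactly but
        opposite modulation for t = (0, 1/2, 0), so a damping tuned to 0.5
        gives epsilon exactly {1.5, 0.5}."""
        from tncs_scout.reflection_io import UnitCell

        cell = UnitCell(70.0, 70.0, 80.0)
        for kk in (3, 7):
            d = cell.d_spacings(np.array([[0, kk, 0]]))[0]
            # Luzzati damping exp(-(8 pi^2/3) rmsd^2 / (4 d^2)) = 0.5
            rmsd = np.sqrt(np.log(2.0) * 3.0 * 4.0 * d**2 / (8.0 * np.pi**2))
            hyp = TncsHypothesis(order=2, t=np.array([0.0, 0.5, 0.0]), rmsd=rmsd)
            sub = np.array([[kk, 0, 0], [0, kk, 0]])
            eps = epsilon_factors(sub, hyp, cell, p1_sg).eps
            strong, weak = max(eps), min(eps)
            # odd kk: (kk,0,0) has h.t = 0 (strong, 1+rho); (0,kk,0) weak
            assert strong == pytest.approx(1.5, abs=1e-9)
            assert weak == pytest.approx(0.5, abs=1e-9)

    def test_mean_normalization_property(self, band_hkl, p1_cell, p1_sg):
        rng = np.random.default_rng(0)
        for _ in range(12):
            hyp = TncsHypothesis(
                order=int(rng.integers(2, 7)),
                t=rng.integers(0, 4, 3) / 4.0 + rng.normal(0, 0.01, 3),
                rot_deg=float(rng.uniform(0, 8)),
                rmsd=float(rng.uniform(0, 2)),
            )
            if np.allclose(hyp.t, 0):
                continue
            eps = epsilon_factors(band_hkl, hyp, p1_cell, p1_sg)
            assert abs(eps.eps.mean() - 1.0) <= 1e-6
            assert np.all(eps.eps >= 0.0)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            TncsHypothesis(order=0)

    def test_g_function_limits(self):
        assert g_function(np.array([0.0]))[0] == pytest.approx(1.0)
        x = np.array([0.5, 2.0, 5.0])
        direct = 3.0 * (np.sin(x) - x * np.cos(x)) / x**3
        np.testing.assert_allclose(g_function(x), direct, rtol=1e-10)


class TestEpsTncs:
    def test_unmodulated_is_zero(self):
        eps = EpsilonFactors(eps=np.ones(100), d=np.full(100, 7.0))
        assert eps_tncs(eps) == 0.0

    def test_ideal_order2_is_one(self):
        eps = EpsilonFactors(eps=np.array([2.0, 0.0] * 50), d=np.full(100, 7.0))
        assert eps_tncs(eps) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_ideal_order_n_equals_n_minus_1(self, n, p1_cell, p1_sg):
        """Balanced classes: one in n reflections sees epsilon = n, the rest 0,
        giving sigma_1^2 = (n-1)^2/n + (n-1)/n = n - 1."""
        k = np.arange(1, 12 * n + 1)   # balanced residues mod n
        hkl = np.column_stack([np.zeros_like(k), k, np.zeros_like(k)])
        hyp = TncsHypothesis(order=n, t=np.array([0.0, 1.0 / n, 0.0]))
        eps = epsilon_factors(hkl, hyp, p1_cell, p1_sg)
        assert eps_tncs(eps) == pytest.approx(n - 1, abs=1e-9)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6, 7, 8])
    def test_printed_range_bound(self, n, band_hkl, p1_cell, p1_sg):
        """sigma_1^2 never exceeds (n/2)^2 + (n/2 - 1)^2 for any tested
        hypothesis up to order 8."""
        bound = (n / 2.0) ** 2 + (n / 2.0 - 1.0) ** 2
        rng = np.random.default_rng(n)
        for _ in range(6):
            hyp = TncsHypothesis(order=n,
                                 t=np.array([rng.integers(0, n), 0, 0]) / n
                                 if rng.random() < 0.5 else rng.random(3),
                                 rmsd=float(rng.uniform(0, 1.5)))
            if np.allclose(hyp.t, 0):
                continue
            val = eps_tncs(epsilon_factors(band_hkl, hyp, p1_cell, p1_sg))
            assert 0.0 <= val <= bound + 1e-9

    def test_strictly_decreasing_in_rmsd(self, band_hkl, p1_cell, p1_sg):
        vals = []
        for rmsd in (0.0, 0.4, 0.8, 1.2, 1.6):
            hyp = TncsHypothesis(order=2, t=np.array([0.0, 0.5, 0.0]), rmsd=rmsd)
            vals.append(eps_tncs(epsilon_factors(band_hkl, hyp, p1_cell, p1_sg)))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            eps_tncs(EpsilonFactors(eps=np.array([]), d=np.array([])))

    def test_csv_export_frame(self, band_hkl, p1_cell, p1_sg):
        hyp = TncsHypothesis(order=2, t=np.array([0.5, 0.0, 0.0]))
        eps = epsilon_factors(band_hkl, hyp, p1_cell, p1_sg)
        df = eps.to_frame(band_hkl)
        assert list(df.columns) == ["h", "k", "l", "d", "epsilon"]
        assert len(df) == len(band_hkl)
        assert df.epsilon.mean() == pytest.approx(1.0, abs=1e-6)


class TestRefinement:
    def test_refined_likelihood_never_below_start(self):
        spec = CrystalSpec(order=2, t=(0.5, 0.0, 0.0), jitter=0.5, n_atoms=60)
        rs = direct_sf(generate_crystal(spec, seed=5), dmin=5.0, dmax=10.0)
        hyp0 = TncsHypothesis(order=2, t=np.array([0.5, 0.0, 0.0]),
                              rmsd=1.5, r_mol=12.0)
        from tncs_scout.tncs_model import (_bin_indices, wilson_log_likelihood)

        res = refine_tncs(rs, hyp0, rot_starts=(0.0, 2.0), rmsd_starts=(0.5,))
        sel = (rs.d >= 5.0) & (rs.d <= 10.0)
        eps0 = epsilon_factors(rs.hkl[sel], hyp0, rs.cell, rs.sg)
        logl0 = wilson_log_likelihood(rs.I[sel], eps0.eps,
                                      _bin_indices(rs.d[sel], 20), 20)
        assert res.log_likelihood >= logl0 - 1e-6

    def test_no_tncs_data_damps_forced_hypothesis(self):
        """Forcing an order-2 model onto unmodulated data refines the damping
        until the predicted modulation nearly vanishes."""
        rs = direct_sf(generate_crystal(CrystalSpec(order=1), seed=6),
                       dmin=5.0, dmax=10.0)
        hyp0 = TncsHypothesis(order=2, t=np.array([0.0, 0.5, 0.0]), r_mol=12.0)
        res = refine_tncs(rs, hyp0, rot_starts=(0.0, 5.0), rmsd_starts=(0.5, 2.0))
        assert res.sigma1_sq < 0.05

    def test_too_few_reflections_error(self):
        rs = direct_sf(generate_crystal(CrystalSpec(order=1, n_atoms=10), seed=0),
                       dmin=9.5, dmax=10.0)
        assert len(rs) < 200
        hyp0 = TncsHypothesis(order=2, t=np.array([0.5, 0.0, 0.0]))
        with pytest.raises(ValueError, match="200"):
            refine_tncs(rs, hyp0)
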