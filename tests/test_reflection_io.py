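"""Reflection I/O: provenance rules, intensity recovery, truncation,
completeness."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

from tncs_scout.reflection_io import (
    Provenance,
    ReflectionSet,
    SpaceGroupInfo,
    UnitCell,
    completeness,
    enumerate_unique_hkl,
    french_wilson_forward,
    french_wilson_reverse,
    load_reflections,
    recover_intensities,
    truncate_resolution,
)
from tncs_scout.synthetic import CrystalSpec, direct_sf, generate_crystal, write_mtz


class TestLoading:
    def test_mtz_mean_round_trip(self, tncs2_refs, tmp_path):
        path = tmp_path / "mean.mtz"
        write_mtz(tncs2_refs, path, mode="mean")
        back = load_reflections(path)
        assert back.provenance is Provenance.MEAN_INTENSITY
        order = np.lexsort(back.hkl.T)
        order0 = np.lexsort(tncs2_refs.hkl.T)
        assert np.array_equal(back.hkl[order], tncs2_refs.hkl[order0])
        np.testing.assert_allclose(back.I[order], tncs2_refs.I[order0], rtol=1e-5)
        assert back.cell.lengths == pytest.approx(tncs2_refs.cell.lengths)

    def test_anomalous_provenance_detected(self, tncs2_refs, tmp_path):
        path = tmp_path / "anom.mtz"
        write_mtz(tncs2_refs, path, mode="anom")
        back = load_reflections(path)
        assert back.provenance is Provenance.ANOMALOUS_INTENSITY

    @pytest.mark.parametrize("flag,expected", [
        (True, Provenance.AMPLITUDE_FRENCH_WILSON),
        (False, Provenance.AMPLITUDE_RAW),
    ])
    def test_amplitude_provenance_from_flag(self, tncs2_refs, tmp_path, flag, expected):
        path = tmp_path / "amp.mtz"
        write_mtz(tncs2_refs, path, mode="amplitude")
        assert load_reflections(path, french_wilson=flag).provenance is expected

    def test_no_data_columns_is_hard_error(self, tmp_path):
        import gemmi

        mtz = gemmi.Mtz(with_base=True)
        mtz.spacegroup = gemmi.SpaceGroup("P 1")
        mtz.set_cell_for_all(gemmi.UnitCell(40, 40, 40, 90, 90, 90))
        mtz.set_data(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
        path = tmp_path / "empty.mtz"
        mtz.write_to_file(str(path))
        with pytest.raises(ValueError, match="no intensity or amplitude"):
            load_reflections(path)


class TestRecovery:
    def test_friedel_simple_average(self, p1_cell, p1_sg):
        rs = ReflectionSet(
            cell=p1_cell, sg=p1_sg,
            hkl=np.array([[1, 2, 3], [2, 0, 1]]),
            I=np.array([0.0, 0.0]),
            provenance=Provenance.ANOMALOUS_INTENSITY,
            I_plus=np.array([4.0, np.nan]),
            I_minus=np.array([2.0, 5.0]),
        )
        out = recover_intensities(rs)
        # mean of mates; singleton used alone
        np.testing.assert_allclose(out.I, [3.0, 5.0])

    def test_amplitude_raw_squares(self, p1_cell, p1_sg):
        rs = ReflectionSet(cell=p1_cell, sg=p1_sg,
                           hkl=np.array([[1, 0, 0], [0, 2, 0]]),
                           I=np.array([0.0, 3.0]),   # F column
                           provenance=Provenance.AMPLITUDE_RAW)
        out = recover_intensities(rs)
        np.testing.assert_allclose(out.I, [0.0, 9.0])

    def test_mean_intensity_idempotent_and_net_positive_mask(self, p1_cell, p1_sg):
        rs = ReflectionSet(cell=p1_cell, sg=p1_sg,
                           hkl=np.array([[1, 0, 0], [0, 2, 0], [0, 0, 3]]),
                           I=np.array([5.0, -1.0, 2.0]),
                           provenance=Provenance.MEAN_INTENSITY)
        once = recover_intensities(rs)
        twice = recover_intensities(once)
        np.testing.assert_array_equal(once.I, twice.I)
        # all reflections retained; only net-positive admitted to the Patterson
        assert len(once) == 3
        np.testing.assert_array_equal(once.patterson_mask, [True, False, True])


class TestFrenchWilson:
    """The reversal inverts the acentric posterior-mean mapping."""

    def test_forward_matches_quadrature_oracle(self):
        # oracle: direct numerical integration of E[sqrt(J)] under the
        # truncated-Gaussian-times-exponential-prior posterior
        sigma_n = 80.0
        for iobs, sigi in [(120.0, 30.0), (5.0, 25.0), (-40.0, 30.0)]:
            mu = iobs - sigi**2 / sigma_n

            def pdf(j):
                return np.exp(-0.5 * ((j - mu) / sigi) ** 2)

            z = quad(pdf, 0, mu + 12 * sigi)[0]
            ef_oracle = quad(lambda j: np.sqrt(j) * pdf(j), 0, mu + 12 * sigi)[0] / z
            f, _ = french_wilson_forward(np.array([iobs]), np.array([sigi]), sigma_n)
            assert f[0] == pytest.approx(ef_oracle, rel=1e-6)

    def test_round_trip_on_simulated_exponential_data(self):
        rng = np.random.default_rng(5)
        n = 1000
        sigma_n = 100.0
        i_true = rng.exponential(sigma_n, n)
        sig_i = 0.3 * np.sqrt(i_true * sigma_n + sigma_n**2 / 4)
        i_obs = i_true + rng.normal(0.0, sig_i)
        F, sigF = french_wilson_forward(i_obs, sig_i, sigma_n)
        # reversal recovers the observed intensities
        i_back = french_wilson_reverse(F, sigF, sigma_n, sigi=sig_i)
        np.testing.assert_allclose(i_back, i_obs, atol=1e-5 * sigma_n)
        # and the forward transform of the reversal reproduces the amplitudes
        F2, _ = french_wilson_forward(i_back, sig_i, sigma_n)
        assert np.max(np.abs(F2 - F) / np.maximum(F, 1e-9)) < 1e-4

    def test_forward_map_strictly_increasing(self):
        """The posterior-mean amplitude is strictly increasing in the observed
        intensity — the property that makes bisection inversion valid."""
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            iobs=st.floats(-200.0, 500.0),
            delta=st.floats(1e-3, 200.0),
            sigi=st.floats(1.0, 80.0),
            sigma_n=st.floats(10.0, 300.0),
        )
        def check(iobs, delta, sigi, sigma_n):
            f_lo, _ = french_wilson_forward(np.array([iobs]), np.array([sigi]),
                                            sigma_n)
            f_hi, _ = french_wilson_forward(np.array([iobs + delta]),
                                            np.array([sigi]), sigma_n)
            assert f_hi[0] > f_lo[0]
            assert f_lo[0] > 0.0

        check()

    def test_recover_through_reflection_set(self, p1_cell, p1_sg):
        rng = np.random.default_rng(9)
        hkl = enumerate_unique_hkl(p1_cell, p1_sg, 5.0, 10.0)[:400]
        I = rng.exponential(50.0, len(hkl))
        sigI = 10.0 * np.ones(len(hkl))
        F, sigF = french_wilson_forward(I, sigI, 50.0)
        rs = ReflectionSet(cell=p1_cell, sg=p1_sg, hkl=hkl, I=F, sigI=sigF,
                           provenance=Provenance.AMPLITUDE_FRENCH_WILSON)
        out = recover_intensities(rs)
        # internal Sigma estimate differs from the true 50, so tolerance is loose
        assert np.corrcoef(out.I, I)[0, 1] > 0.999


class TestResolutionHandling:
    def test_truncate_keeps_low_resolution(self, p1_cell, p1_sg):
        cry = generate_crystal(CrystalSpec(n_atoms=20), seed=0)
        rs = direct_sf(cry, dmin=1.5, dmax=20.0)
        out = truncate_resolution(rs, dmin=3.0)
        assert out.d.min() >= 3.0
        # surviving count matches a direct count over the enumerated sphere
        assert len(out) == int(np.sum(rs.d >= 3.0))
        assert len(out) == len(enumerate_unique_hkl(rs.cell, rs.sg, 3.0, 20.0))

    def test_truncate_everything_is_error(self, tncs2_refs):
        with pytest.raises(ValueError):
            truncate_resolution(tncs2_refs, dmin=50.0)

    def test_completeness_full_and_half(self, tncs2_refs):
        assert completeness(tncs2_refs, 5.0, 10.0) == pytest.approx(1.0)
        half = tncs2_refs.select(np.arange(len(tncs2_refs)) % 2 == 0)
        n = len(tncs2_refs)
        assert completeness(half, 5.0, 10.0) == pytest.approx(0.5, abs=1.5 / n)

    def test_completeness_monotone_under_deletion(self, tncs2_refs):
        rng = np.random.default_rng(3)
        keep = np.ones(len(tncs2_refs), dtype=bool)
        prev = completeness(tncs2_refs, 5.0, 10.0)
        for _ in range(4):
            keep &= rng.random(len(tncs2_refs)) > 0.25
            cur = completeness(tncs2_refs.select(keep), 5.0, 10.0)
            assert cur <= prev + 1e-12
            prev = cur


class TestUnitCellAndSymmetry:
    def test_cell_validation(self):
        with pytest.raises(ValueError):
            UnitCell(-1.0, 10.0, 10.0)
        with pytest.raises(ValueError):
            UnitCell(10.0, 10.0, 10.0, alpha=180.0)

    def test_laue_group_contains_inversion(self):
        sg = SpaceGroupInfo.from_symbol("P 21")
        rots = sg.laue_rotations()
        assert len(rots) == 4  # 2/m
        assert any(np.array_equal(R, -np.eye(3, dtype=int)) for R in rots)

    def test_d_spacings_orthorhombic(self, p1_cell):
        d = p1_cell.d_spacings(np.array([[2, 0, 0], [0, 0, 4]]))
        np.testing.assert_allclose(d, [70.0 / 2, 80.0 / 4])
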