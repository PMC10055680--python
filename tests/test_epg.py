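"""Unit and property tests of the EPG operators against closed forms and a
single-isochromat rotation oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrf3d import (
    EPGState,
    TissueParams,
    epg_grad_shift,
    epg_norm,
    epg_relax,
    epg_rf,
    inversion,
    t1rho_prep,
)

PARAMS = TissueParams(t1=1000.0, t2=80.0, t1rho=100.0)


def random_state(rng, k=6):
    s = EPGState.equilibrium(k)
    fp = rng.standard_normal(k + 1) + 1j * rng.standard_normal(k + 1)
    s.f_plus[:] = fp
    s.f_minus[:] = 0
    s.f_minus[0] = np.conj(fp[0])
    s.z[:] = rng.standard_normal(k + 1)
    return s


class TestRF:
    def test_zero_flip_is_identity(self):
        s = random_state(np.random.default_rng(0))
        out = epg_rf(s, 0.0, 123.0)
        np.testing.assert_allclose(out.f_plus, s.f_plus)
        np.testing.assert_allclose(out.z, s.z)

    def test_perfect_inversion_pulse(self):
        out = epg_rf(EPGState.equilibrium(4), 180.0, 0.0)
        assert out.z[0] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.abs(out.f_plus), 0.0, atol=1e-12)

    @pytest.mark.parametrize("phase", [0.0, 45.0, 90.0, 210.0])
    def test_90_excitation_matches_isochromat_rotation(self, phase):
        """Tipping equilibrium magnetization must reproduce the 3-D rotation
        of M = (0,0,1) about the in-plane axis at `phase` from +x."""
        from bloch_oracle import rotation_about_xy_axis

        out = epg_rf(EPGState.equilibrium(2), 90.0, phase)
        m = rotation_about_xy_axis(90.0, phase) @ np.array([0.0, 0.0, 1.0])
        assert complex(out.f_plus[0]) == pytest.approx(m[0] + 1j * m[1])
        assert complex(out.f_minus[0]) == pytest.approx(m[0] - 1j * m[1])
        assert complex(out.z[0]) == pytest.approx(m[2], abs=1e-12)

    @settings(deadline=None, max_examples=40)
    @given(
        flip=st.floats(0.0, 360.0),
        phase=st.floats(-360.0, 360.0),
        seed=st.integers(0, 100),
    )
    def test_norm_preserved_and_conjugate_invariant(self, flip, phase, seed):
        s = random_state(np.random.default_rng(seed))
        out = epg_rf(s, flip, phase)
        assert epg_norm(out) == pytest.approx(epg_norm(s), rel=1e-10)
        assert complex(out.f_minus[0]) == pytest.approx(
            np.conj(complex(out.f_plus[0]))
        )

    def test_rejects_nonfinite_angles(self):
        with pytest.raises(ValueError):
            epg_rf(EPGState.equilibrium(2), np.nan, 0.0)


class TestGradShift:
    def test_pure_longitudinal_unchanged(self):
        s = EPGState.equilibrium(4)
        out = epg_grad_shift(s)
        np.testing.assert_allclose(out.z, s.z)
        assert np.all(out.f_plus == 0)

    def test_shift_and_composition(self):
        s = EPGState.equilibrium(4)
        s.f_plus[0] = 1.0
        once = epg_grad_shift(s)
        assert once.f_plus[1] == 1.0 and once.f_plus[0] == 0.0
        twice = epg_grad_shift(once)
        assert twice.f_plus[2] == 1.0

    def test_truncation_beyond_max_order(self):
        s = EPGState.equilibrium(2)
        s.f_plus[2] = 1.0
        out = epg_grad_shift(s)
        assert np.all(out.f_plus[1:] == 0)

    def test_crossover_conjugation(self):
        """An F- state at order 1 refocuses into the observable F+_0 as its
        conjugate."""
        s = EPGState.equilibrium(3)
        s.f_minus[1] = 0.3 - 0.4j
        out = epg_grad_shift(s)
        assert complex(out.f_plus[0]) == pytest.approx(0.3 + 0.4j)


class TestRelax:
    def test_zero_dt_identity(self):
        s = random_state(np.random.default_rng(1))
        out = epg_relax(s, 0.0, PARAMS)
        np.testing.assert_allclose(out.f_plus, s.f_plus)
        np.testing.assert_allclose(out.z, s.z)

    def test_long_dt_reaches_equilibrium(self):
        s = random_state(np.random.default_rng(2))
        out = epg_relax(s, 1e7, PARAMS)
        assert complex(out.z[0]) == pytest.approx(1.0)
        assert np.max(np.abs(out.f_plus)) < 1e-12

    def test_saturation_recovery_closed_form(self):
        s = EPGState.equilibrium(2)
        s.z[0] = 0.0
        out = epg_relax(s, PARAMS.t1, PARAMS)
        assert complex(out.z[0]) == pytest.approx(1.0 - np.exp(-1.0))

    def test_inversion_recovery_closed_form(self):
        """z(dt) = 1 - (1 - z0) exp(-dt/T1) for any start z0 and delay."""
        for z0, dt in [(-1.0, 123.0), (0.25, 700.0), (0.9, 10.0)]:
            s = EPGState.equilibrium(2)
            s.z[0] = z0
            out = epg_relax(s, dt, PARAMS)
            expect = 1.0 - (1.0 - z0) * np.exp(-dt / PARAMS.t1)
            assert complex(out.z[0]) == pytest.approx(expect)

    def test_contraction_toward_equilibrium(self):
        s = random_state(np.random.default_rng(3))
        eq = EPGState.equilibrium(s.max_order)
        d0 = epg_norm(
            EPGState(s.f_plus - eq.f_plus, s.f_minus - eq.f_minus, s.z - eq.z, s.max_order)
        )
        out = epg_relax(s, 50.0, PARAMS)
        d1 = epg_norm(
            EPGState(out.f_plus, out.f_minus, out.z - eq.z, out.max_order)
        )
        assert d1 < d0

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            epg_relax(EPGState.equilibrium(2), -1.0, PARAMS)


class TestT1rhoPrep:
    def test_closed_form_attenuation(self):
        s = EPGState.equilibrium(2)
        out = t1rho_prep(s, PARAMS.t1rho, PARAMS)
        assert complex(out.z[0]) == pytest.approx(np.exp(-1.0))
        out2 = t1rho_prep(s, 45.0, TissueParams(t1=1000, t2=80, t1rho=90))
        assert complex(out2.z[0]) == pytest.approx(np.exp(-0.5))

    def test_zero_tsl_crushes_transverse_only(self):
        s = random_state(np.random.default_rng(4))
        out = t1rho_prep(s, 0.0, PARAMS)
        np.testing.assert_allclose(out.z, s.z)
        assert np.all(out.f_plus == 0) and np.all(out.f_minus == 0)

    @settings(deadline=None, max_examples=30)
    @given(
        tsl=st.floats(0.1, 100.0),
        dtsl=st.floats(0.1, 50.0),
        t1rho=st.floats(10.0, 300.0),
        dt1rho=st.floats(1.0, 100.0),
    )
    def test_attenuation_monotone_in_tsl_and_t1rho(self, tsl, dtsl, t1rho, dt1rho):
        s = EPGState.equilibrium(1)

        def att(ts, tr):
            p = TissueParams(t1=3000.0, t2=100.0, t1rho=tr)
            return abs(complex(t1rho_prep(s, ts, p).z[0]))

        assert att(tsl + dtsl, t1rho) < att(tsl, t1rho)
        assert att(tsl, t1rho + dt1rho) > att(tsl, t1rho)

    def test_negative_tsl_rejected(self):
        with pytest.raises(ValueError):
            t1rho_prep(EPGState.equilibrium(1), -0.1, PARAMS)


class TestInversion:
    @pytest.mark.parametrize(
        "eff,z0,expected", [(1.0, 1.0, -1.0), (0.0, 1.0, 0.0), (0.95, 0.5, -0.475)]
    )
    def test_efficiency_scaling(self, eff, z0, expected):
        s = EPGState.equilibrium(2)
        s.z[0] = z0
        out = inversion(s, eff)
        assert complex(out.z[0]) == pytest.approx(expected)

    def test_efficiency_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            inversion(EPGState.equilibrium(1), 1.5)


class TestTissueParams:
    def test_t2_gt_t1_rejected_but_overridable(self):
        with pytest.raises(ValueError):
            TissueParams(t1=100.0, t2=200.0, t1rho=50.0)
        p = TissueParams(t1=100.0, t2=200.0, t1rho=50.0, validate=False)
        assert p.t2 == 200.0

    def test_nonpositive_times_rejected(self):
        for kw in ({"t1": -1.0}, {"t2": 0.0}, {"t1rho": -5.0}):
            base = {"t1": 1000.0, "t2": 80.0, "t1rho": 90.0}
            base.update(kw)
            with pytest.raises(ValueError):
                TissueParams(**base)
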