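"""DLVO adhesion, DEP repulsion and the force balance between them."""

import logging
import math
from dataclasses import replace

import numpy as np
import pytest

from depclog.errors import DomainError, ThresholdOutOfRangeError, UsageError
from depclog.forces import (
    AdhesionParams,
    FieldModel,
    adhesive_force,
    dep_force,
    edl_force,
    field_gradient,
    force_balance,
    gamma_factor,
    protected_diameter_threshold,
    van_der_waals_force,
)

log = logging.getLogger(__name__)

RE_FCM_NDEP = -0.5  # blood cells below 10 kHz


class TestGammaFactor:
    def test_zero_zeta_gives_zero(self):
        assert gamma_factor(0.0) == 0.0

    @pytest.mark.parametrize(
        "zeta,expected", [(-10.8e-3, -0.10544), (-13.825e-3, -0.13466)]
    )
    def test_reference_zeta_values(self, zeta, expected):
        assert gamma_factor(zeta, 1, 296.15) == pytest.approx(expected, rel=1e-3)

    def test_odd_and_bounded(self):
        for z in (1e-3, 25e-3, 0.5):
            assert gamma_factor(z) == -gamma_factor(-z)
            assert abs(gamma_factor(z)) < 1.0


class TestVanDerWaals:
    def test_reference_value(self):
        # RBC (7 um) at 0.5 nm with A = 5 zJ
        assert van_der_waals_force(7e-6, 0.5e-9, 5e-21) == pytest.approx(
            1.1667e-8, rel=1e-3
        )

    def test_linear_in_diameter(self):
        assert van_der_waals_force(14e-6, 1e-9) == pytest.approx(
            2 * van_der_waals_force(7e-6, 1e-9)
        )

    def test_vanishes_far_from_wall(self):
        assert van_der_waals_force(7e-6, 1.0) < 1e-15

    def test_contact_singularity_rejected(self):
        with pytest.raises(DomainError):
            van_der_waals_force(7e-6, 0.0)


class TestEDLForce:
    def test_zero_zeta_kills_force(self, adhesion):
        p = replace(adhesion, zeta_particle=0.0)
        assert edl_force(7e-6, 0.5e-9, p) == 0.0

    def test_reference_value(self, adhesion):
        assert edl_force(7e-6, 0.5e-9, adhesion) == pytest.approx(6.595e-10, rel=1e-3)

    def test_exponential_decay_constant(self, adhesion):
        h = 2e-9
        ratio = edl_force(7e-6, h, adhesion) / edl_force(
            7e-6, h + 1.0 / adhesion.debye_kappa, adhesion
        )
        assert ratio == pytest.approx(math.e, rel=1e-9)


class TestAdhesiveForce:
    def test_zero_zetas_reduce_to_van_der_waals(self, adhesion):
        p = replace(adhesion, zeta_particle=0.0, zeta_wall=0.0)
        for conv in ("literal-sum", "signed"):
            assert adhesive_force(7e-6, 1e-9, p, conv) == van_der_waals_force(
                7e-6, 1e-9, p.hamaker_A
            )

    def test_short_range_dominance(self, adhesion):
        # the 1/h^2 term makes the force rise sharply below ~0.5 nm
        assert adhesive_force(7e-6, 0.3e-9, adhesion) > 10 * adhesive_force(
            7e-6, 3e-9, adhesion
        )

    def test_convention_difference_is_twice_edl(self, adhesion):
        d, h = 7e-6, 1e-9
        diff = adhesive_force(d, h, adhesion, "literal-sum") - adhesive_force(
            d, h, adhesion, "signed"
        )
        assert diff == pytest.approx(2 * edl_force(d, h, adhesion), rel=1e-12)

    def test_unknown_convention_rejected(self, adhesion):
        with pytest.raises(UsageError):
            adhesive_force(7e-6, 1e-9, adhesion, "both")


class TestFieldGradient:
    def test_zero_voltage_gives_zero_everywhere(self):
        f = FieldModel(voltage_amplitude=0.0)
        assert field_gradient(f, 0.0) == 0.0
        assert field_gradient(f, 1e-6) == 0.0

    def test_value_at_wall_matches_definition(self, field_20v):
        v_rms = 20.0 / math.sqrt(2)
        expected = (v_rms / field_20v.electrode_gap_g) ** 2 * (
            4 * math.pi / field_20v.electrode_pitch_p
        )
        assert field_gradient(field_20v, 0.0) == pytest.approx(expected, rel=1e-12)

    def test_quadratic_in_voltage_and_decaying_in_height(self, field_20v):
        f40 = replace(field_20v, voltage_amplitude=40.0)
        assert field_gradient(f40, 1e-6) == pytest.approx(
            4 * field_gradient(field_20v, 1e-6), rel=1e-12
        )
        hs = np.linspace(0, 20e-6, 30)
        vals = [field_gradient(field_20v, h) for h in hs]
        assert np.all(np.diff(vals) < 0)


class TestDEPForce:
    def test_zero_cm_factor_gives_zero(self):
        assert dep_force(3.5e-6, 0.0, 1e18) == 0.0

    def test_cubic_in_radius(self):
        assert dep_force(2e-6, -0.5, 1e18) == pytest.approx(
            8 * dep_force(1e-6, -0.5, 1e18), rel=1e-12
        )

    def test_ndep_sign_is_repulsive(self):
        assert dep_force(3.5e-6, RE_FCM_NDEP, 1e18) < 0


class TestForceBalance:
    def test_zero_voltage_never_protected(self, adhesion, h_grid):
        res = force_balance(
            7e-6, FieldModel(voltage_amplitude=0.0), adhesion, RE_FCM_NDEP, h_grid
        )
        assert not res.protected and res.crossover_h is None
        assert np.all(res.f_dep_curve == 0.0)

    def test_crossover_decreases_with_voltage(self, adhesion, h_grid):
        crossings = []
        for v in (10.0, 15.0, 20.0, 30.0):
            res = force_balance(
                7e-6, FieldModel(voltage_amplitude=v), adhesion, RE_FCM_NDEP, h_grid
            )
            assert res.crossover_h is not None
            crossings.append(res.crossover_h)
        assert np.all(np.diff(crossings) < 0)

    def test_bisection_agrees_with_dense_grid_oracle(self, adhesion, field_20v):
        # dense-grid cell size is commensurate with the 1 pm bisection
        # tolerance at the ~0.1 nm crossover
        grid = np.logspace(-12, -7, 40)
        res = force_balance(7e-6, field_20v, adhesion, RE_FCM_NDEP, grid)
        dense = np.logspace(-12, -7, 10_000)
        dres = force_balance(7e-6, field_20v, adhesion, RE_FCM_NDEP, dense)
        i = int(np.argmin(np.abs(dres.f_adh_curve - dres.f_dep_curve)))
        # within a couple of dense-grid cells of the brute-force minimiser
        assert abs(math.log(res.crossover_h / dense[i])) < math.log(dense[1] / dense[0]) * 2

    def test_rbc_protected_but_small_debris_not_at_20v(self, adhesion, field_20v, h_grid):
        assert force_balance(7e-6, field_20v, adhesion, RE_FCM_NDEP, h_grid).protected
        assert not force_balance(
            0.5e-6, field_20v, adhesion, RE_FCM_NDEP, h_grid
        ).protected

    def test_empty_grid_rejected(self, adhesion, field_20v):
        with pytest.raises(UsageError):
            force_balance(7e-6, field_20v, adhesion, RE_FCM_NDEP, [])


class TestProtectedDiameterThreshold:
    def test_monotone_non_increasing_in_voltage(self, adhesion):
        thr = [
            protected_diameter_threshold(
                FieldModel(voltage_amplitude=v), adhesion, RE_FCM_NDEP, 0.5e-9
            )
            for v in (10.0, 15.0, 20.0, 25.0, 30.0)
        ]
        assert np.all(np.diff(thr) <= 0)

    def test_zero_cm_factor_is_out_of_range(self, adhesion, field_20v):
        with pytest.raises(ThresholdOutOfRangeError):
            protected_diameter_threshold(field_20v, adhesion, 0.0, 0.5e-9)

    def test_calibration_values_logged(self, adhesion, field_20v, h_grid):
        """Calibration check, logged rather than asserted: at 20 V the
        protection threshold should sit near 1 um and adhesion dominance
        should be confined below ~0.5 nm."""
        thr = protected_diameter_threshold(field_20v, adhesion, RE_FCM_NDEP, 0.5e-9)
        res = force_balance(7e-6, field_20v, adhesion, RE_FCM_NDEP, h_grid)
        log.info("20 V protection threshold: %.3f um (target ~1 um)", thr * 1e6)
        log.info(
            "20 V RBC adhesion-dominance boundary: %.3f nm (target < ~0.5 nm)",
            res.crossover_h * 1e9,
        )
        assert thr > 0 and res.crossover_h > 0
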