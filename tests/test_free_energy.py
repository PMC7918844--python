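"""Free-energy ratio F/F0, point-charge limit, fs(s) sweep, unit conversion."""
import math

import numpy as np
import pytest
from scipy import constants

from dhdl import (
    CellGeometry,
    ElectrolyteInterface,
    SeriesControl,
    debye_length,
    free_energy_ratio,
    free_energy_ratio_quadrature,
    loglog_slope,
    point_charge_free_energy,
    scaled_sweep,
    to_physical_units,
)
from dhdl.free_energy import FreeEnergyResult


class TestFreeEnergyRatio:
    def test_total_potential_at_full_disk_recovers_continuum(self, water_like):
        # replacing the difference potential by the full cell potential at
        # r0 = R counts the self-energy and must give F/F0 = 1 exactly
        val = free_energy_ratio_quadrature(
            CellGeometry(R=1.0, r0=1.0),
            water_like,
            SeriesControl(n_max=10, adaptive=False),
            potential="total",
        )
        assert val == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize(
        "rho0, eta, n_max",
        [(0.3, 1.0, 2000), (0.1, 0.0, 4000), (0.02, 1.0, 4000)],
    )
    def test_closed_form_agrees_with_radial_quadrature(self, rho0, eta, n_max):
        geom = CellGeometry(R=1.0, r0=rho0)
        med = ElectrolyteInterface(lD=1.0, eps_ratio=eta)
        ctrl = SeriesControl(n_max=n_max, adaptive=False)
        closed = free_energy_ratio(geom, med, ctrl).ratio
        direct = free_energy_ratio_quadrature(geom, med, ctrl)
        assert closed == pytest.approx(direct, rel=5e-3)

    def test_paired_truncation_stability(self, water_like):
        # once n_max >= 5 R/r0 a doubling of the cutoff moves F/F0 by < 1e-3
        geom = CellGeometry(R=1.0, r0=0.1)
        a = free_energy_ratio(geom, water_like, SeriesControl(n_max=50, adaptive=False))
        b = free_energy_ratio(geom, water_like, SeriesControl(n_max=100, adaptive=False))
        assert abs(a.ratio - b.ratio) < 1e-3

    def test_bounded_between_zero_and_one_for_weak_lower_dielectric(self):
        for lam in (0.2, 1.0, 5.0):
            for eta in (0.0, 0.5, 1.0):
                res = point_charge_free_energy(
                    1.0, ElectrolyteInterface(lD=lam, eps_ratio=eta), 1e-3
                )
                assert 0.0 <= res.ratio <= 1.0

    def test_truncation_convergence_is_nonuniform_in_disk_size(self, water_like):
        # fixed cutoffs converge pointwise for every r0 > 0, but the cutoff
        # needed grows as the disk shrinks
        cutoffs = (10, 33, 100, 333, 1000)
        curves = {
            rho0: [
                free_energy_ratio(
                    CellGeometry(R=1.0, r0=rho0),
                    water_like,
                    SeriesControl(n_max=n, adaptive=False),
                ).ratio
                for n in cutoffs
            ]
            for rho0 in (0.3, 0.05, 0.01)
        }
        for rho0, vals in curves.items():
            errs = np.abs(np.asarray(vals[:-1]) - vals[-1])
            assert errs[0] > errs[-1]  # refinement helps at every r0
        # at the same modest cutoff the small disk is much further from its
        # converged value than the large one
        err_large = abs(curves[0.3][1] - curves[0.3][-1])
        err_small = abs(curves[0.01][1] - curves[0.01][-1])
        assert err_small > 10 * err_large


class TestPointChargeLimit:
    def test_flatness_near_vanishing_disk_size(self, water_like):
        ctrl = SeriesControl(n_max=1000, adaptive=False)
        r1 = free_energy_ratio(CellGeometry(R=1.0, r0=0.01), water_like, ctrl).ratio
        r2 = free_energy_ratio(CellGeometry(R=1.0, r0=0.02), water_like, ctrl).ratio
        assert abs(r2 - r1) / 0.01 < 0.05

    def test_weak_screening_limit_reaches_continuum(self):
        ratios = [
            point_charge_free_energy(
                1.0, ElectrolyteInterface(lD=lam, eps_ratio=1.0), 1e-3
            ).ratio
            for lam in (30.0, 100.0, 300.0)
        ]
        x = 1.0 / np.array([30.0, 100.0, 300.0])
        extrap = np.polyfit(x, ratios, 1)[1]
        assert extrap == pytest.approx(1.0, abs=0.02)

    def test_strong_screening_limit_vanishes(self):
        res = point_charge_free_energy(
            1.0, ElectrolyteInterface(lD=0.05, eps_ratio=0.0), 1e-3
        )
        assert abs(res.ratio) < 1e-3

    def test_monotone_in_dielectric_ratio(self):
        ratios = [
            point_charge_free_energy(
                1.0, ElectrolyteInterface(lD=1.0, eps_ratio=eta), 1e-3
            ).ratio
            for eta in (0.0, 0.5, 1.0, 2.0)
        ]
        assert np.all(np.diff(ratios) > 0)

    def test_diagnostics_are_reported(self, water_like):
        res = point_charge_free_energy(1.0, water_like, 1e-3)
        assert isinstance(res, FreeEnergyResult)
        assert res.r0_used < 0.05 * 1.0 + 1e-15
        assert res.convergence_estimate < 1e-3
        with pytest.raises(ValueError):
            point_charge_free_energy(1.0, water_like, -1.0)


class TestScaledSweep:
    def test_continuum_reference_and_identity(self):
        pts = scaled_sweep([1e-2, 1e-3], 1.0, 1e-3)
        for p in pts:
            assert p.fs_continuum == p.s**2
            assert p.fs == pytest.approx(p.result.ratio * p.s**2, rel=1e-14)

    def test_exponential_suppression_without_lower_dielectric(self):
        p = scaled_sweep([1e-3], 0.0, 1e-3)[0]
        assert p.fs / p.s**2 < 1e-2

    def test_rejects_nonpositive_density(self):
        with pytest.raises(ValueError):
            scaled_sweep([-1e-3], 1.0)


class TestLogLogSlope:
    @pytest.mark.parametrize(
        "power, expected", [(2.5, 2.5), (2.0, 2.0), (0.0, 0.0)]
    )
    def test_exact_power_laws_recovered(self, power, expected):
        s = np.array([1e-1, 1e-2, 1e-3])
        assert loglog_slope((s, s**power)) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            loglog_slope((np.array([1.0, 2.0]), np.array([1.0, -1.0])))
        with pytest.raises(ValueError):
            loglog_slope((np.array([1.0, 1.0]), np.array([1.0, 2.0])))


class TestPhysicalUnits:
    @staticmethod
    def _medium_1nm():
        # eps_w = 80, T = 298 K; pick n0 so that lD = 1 nm exactly
        eps_w, temp = 80.0, 298.0
        n0 = eps_w * constants.epsilon_0 * constants.k * temp / (
            2.0 * constants.e**2 * (1e-9) ** 2
        )
        return ElectrolyteInterface(
            lD=debye_length(eps_w, temp, n0), eps_ratio=0.025,
            eps_w=eps_w, temperature=temp, n0=n0,
        )

    def test_debye_length_consistency_enforced(self):
        med = self._medium_1nm()
        assert med.lD == pytest.approx(1e-9, rel=1e-12)
        with pytest.raises(ValueError):
            ElectrolyteInterface(
                lD=2e-9, eps_ratio=0.025, eps_w=80.0, temperature=298.0, n0=med.n0
            )

    def test_continuum_value_reproduced(self):
        med = self._medium_1nm()
        R = 1e-9
        res = FreeEnergyResult(
            ratio=1.0, n_max_used=1, r0_used=R, R_used=R, convergence_estimate=0.0
        )
        out = to_physical_units(res, med)
        sigma0 = constants.e / (math.pi * R**2)
        expected = sigma0**2 * med.lD / (2.0 * med.eps_w * constants.epsilon_0)
        assert out["F_per_area_J_per_m2"] == pytest.approx(expected, rel=1e-12)

    def test_quadratic_charge_density_scaling(self):
        # doubling sigma0 means shrinking R by sqrt(2); at fixed F/F0 the
        # area density of free energy grows fourfold
        med = self._medium_1nm()
        mk = lambda R: to_physical_units(
            FreeEnergyResult(1.0, 1, R, R, 0.0), med
        )["F_per_area_J_per_m2"]
        assert mk(1e-9 / math.sqrt(2)) == pytest.approx(4.0 * mk(1e-9), rel=1e-12)

    def test_requires_physical_block(self, water_like):
        res = FreeEnergyResult(1.0, 1, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            to_physical_units(res, water_like)
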