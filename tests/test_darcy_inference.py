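"""Radial Darcy chain: perfusion radius, stretch, permeabilities, pressures."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from osmoflux import (CalibrationRecord, DisplacementSeries, PhysicalConstants,
                      ProbeGeometry, TissueFluxRecord, calibrate,
                      effective_total_permeability, infer_sample,
                      osmolality_from_pressure, perfusion_radius,
                      pressure_from_osmolality, radial_stretch,
                      swelling_pressure_from_flux, tissue_permeability)
from osmoflux.errors import (CalibrationLookupError, GeometryError,
                             InvalidInputError, ModelError)
from osmoflux.instrument_model import membrane_flux


class TestPerfusionRadius:
    def test_no_perfusion_stays_at_membrane_surface(self, geometry):
        assert perfusion_radius(0.0, 300, geometry) == geometry.r2

    def test_algebraic_identity_doubles_radius(self, geometry):
        # q t = 3 pi L r2^2  ->  r3 = 2 r2
        qt = 3 * math.pi * geometry.membrane_length * geometry.r2 ** 2
        assert perfusion_radius(qt / 300, 300, geometry) == pytest.approx(
            2 * geometry.r2, rel=1e-12)

    def test_hand_value(self, geometry):
        r3 = perfusion_radius(1.890e-12, 300, geometry)
        assert r3 == pytest.approx(2.247e-4, rel=1e-3)

    def test_strictly_increasing_in_flux(self, geometry):
        qs = np.linspace(0, 5e-12, 20)
        radii = [perfusion_radius(q, 300, geometry) for q in qs]
        assert all(b > a for a, b in zip(radii, radii[1:]))

    def test_negative_flux_rejected(self, geometry):
        with pytest.raises(InvalidInputError):
            perfusion_radius(-1e-12, 300, geometry)


class TestRadialStretch:
    @pytest.mark.parametrize("m0,mf,expected", [
        (1.0, 1.0, 1.0),
        (1.0, 0.5, 0.7937),
        (1.0, 8.0, 2.0),
    ])
    def test_cube_root_of_mass_ratio(self, m0, mf, expected):
        assert radial_stretch(m0, mf) == pytest.approx(expected, rel=1e-4)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InvalidInputError):
            radial_stretch(0.0, 1.0)


class TestTissuePermeability:
    def test_reference_value_at_unit_stretch(self):
        assert tissue_permeability(1.0) == 1.59e-15

    def test_vanishes_as_pores_close(self):
        assert tissue_permeability(0.2 + 1e-9) < 1e-20

    def test_direct_evaluation_at_0_6(self):
        assert tissue_permeability(0.6) == pytest.approx(7.206e-16, rel=1e-3)

    def test_undefined_below_closure(self):
        with pytest.raises(ModelError):
            tissue_permeability(0.2)

    def test_strictly_increasing_up_to_unit_stretch(self):
        lams = np.linspace(0.21, 1.0, 50)
        ks = [tissue_permeability(l) for l in lams]
        assert all(b > a for a, b in zip(ks, ks[1:]))


class TestEffectiveTotalPermeability:
    def test_no_tissue_annulus_gives_membrane(self, geometry):
        k = effective_total_permeability(1e-18, 1.59e-15, geometry.r1,
                                         geometry.r2, geometry.r2)
        assert k == 1e-18

    def test_homogeneous_medium(self, geometry):
        k = effective_total_permeability(3e-16, 3e-16, geometry.r1,
                                         geometry.r2, 2.5e-4)
        assert k == pytest.approx(3e-16, rel=1e-12)

    def test_series_resistance_hand_value(self):
        # ln(1.98849)/[ln(1.06195)/1e-15 + ln(1.87250)/1.59e-15]
        k = effective_total_permeability(1e-15, 1.59e-15, 1.13e-4, 1.2e-4,
                                         2.247e-4)
        assert k == pytest.approx(1.5120e-15, rel=1e-3)

    @given(st.floats(1e-18, 1e-14), st.floats(1e-18, 1e-14),
           st.floats(1.21e-4, 1e-3))
    @settings(max_examples=50, deadline=None)
    def test_bounded_by_component_permeabilities(self, km, kt, r3):
        k = effective_total_permeability(km, kt, 1.13e-4, 1.2e-4, r3)
        assert min(km, kt) * (1 - 1e-12) <= k <= max(km, kt) * (1 + 1e-12)

    def test_limit_to_membrane_as_annulus_shrinks(self, geometry):
        k = effective_total_permeability(1e-18, 1.59e-15, geometry.r1,
                                         geometry.r2, geometry.r2 + 1e-12)
        assert k == pytest.approx(1e-18, rel=1e-4)

    def test_inverted_radii_rejected(self, geometry):
        with pytest.raises(GeometryError):
            effective_total_permeability(1e-18, 1e-15, geometry.r1,
                                         geometry.r2, 1.1e-4)


class TestSwellingPressure:
    def test_equilibrium_with_probe(self, geometry):
        assert swelling_pressure_from_flux(0.0, geometry, 1e-18,
                                           geometry.r2) == 0.0

    def test_linear_in_flux_at_fixed_geometry(self, geometry):
        p1 = swelling_pressure_from_flux(1e-13, geometry, 1e-18, 2e-4)
        p2 = swelling_pressure_from_flux(2e-13, geometry, 1e-18, 2e-4)
        assert p2 == pytest.approx(2 * p1, rel=1e-12)

    def test_zero_permeability_is_model_error(self, geometry):
        with pytest.raises(ModelError):
            swelling_pressure_from_flux(1e-13, geometry, 0.0, 2e-4)

    def test_hydrostatic_offset_subtracts(self, geometry):
        base = swelling_pressure_from_flux(1e-13, geometry, 1e-18, 2e-4)
        off = swelling_pressure_from_flux(1e-13, geometry, 1e-18, 2e-4,
                                          hydrostatic_offset=500.0)
        assert base - off == pytest.approx(500.0)


class TestOsmolality:
    def test_bath_equilibrium_is_279(self, constants):
        # 2 * 0.93 * 150 mol/m^3 at zero swelling pressure
        assert osmolality_from_pressure(0.0, constants) == pytest.approx(279.0)

    def test_half_mpa_scale_value(self, constants):
        osm = osmolality_from_pressure(552.9e3, constants)
        assert osm == pytest.approx(502.0, abs=0.5)

    def test_inverse_round_trip(self, constants):
        assert pressure_from_osmolality(279.0, constants) == pytest.approx(
            0.0, abs=1e-9)
        for dp in (1e4, 2e5, 5e5):
            osm = osmolality_from_pressure(dp, constants)
            assert pressure_from_osmolality(osm, constants) == pytest.approx(
                dp, rel=1e-12)

    def test_negative_osmolality_is_model_violation(self, constants):
        with pytest.raises(ModelError):
            osmolality_from_pressure(-constants.bath_osmotic_pressure - 1.0,
                                     constants)


def test_closed_form_matches_numeric_radial_integration():
    """The inferred pressure drop must equal the numerically integrated
    dP/dr = q / (2 pi r L K(r)) over the piecewise-constant permeability
    profile (membrane annulus, then tissue annulus)."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        r1 = rng.uniform(0.5e-4, 2e-4)
        r2 = r1 * rng.uniform(1.02, 1.5)
        r3 = r2 * rng.uniform(1.0001, 5.0)
        km = 10 ** rng.uniform(-18, -15)
        kt = 10 ** rng.uniform(-16, -14)
        length = rng.uniform(1e-3, 1e-2)
        q = 10 ** rng.uniform(-14, -12)
        geometry = ProbeGeometry(inner_membrane_radius=r1,
                                 outer_membrane_radius=r2,
                                 membrane_length=length)
        k_tot = effective_total_permeability(km, kt, r1, r2, r3)
        closed = swelling_pressure_from_flux(q, geometry, k_tot, r3)

        def grad(r, k):
            return q / (2 * math.pi * r * length * k)

        numeric = (quad(grad, r1, r2, args=(km,), epsrel=1e-12)[0]
                   + quad(grad, r2, r3, args=(kt,), epsrel=1e-12)[0])
        assert closed == pytest.approx(numeric, rel=1e-9)


def _flux_record(fluxes, pressure=0.1e6, probe="P1"):
    return TissueFluxRecord(
        sample_id="s1", probe_id=probe, applied_pressure=pressure,
        excision_wet_mass=2e-4, post_equilibration_wet_mass=1.8e-4,
        post_flux_wet_mass=1.8e-4, dry_mass=3e-5,
        triplicate_fluxes=tuple(fluxes))


def _calibration(pressure=0.1e6, k_mem=1e-18, probe="P1"):
    geometry = ProbeGeometry()
    q = membrane_flux(k_mem, geometry, pressure)
    times = [0.0, 60, 120, 180, 240, 300]
    pos = [q / geometry.tubing_cross_section * t for t in times]
    return calibrate([CalibrationRecord(
        probe_id=probe, series=DisplacementSeries(times, pos),
        applied_osmotic_pressure=pressure)], geometry)


class TestInferSample:
    def test_zero_flux_means_bath_equilibrium(self, constants):
        res = infer_sample(_flux_record([0.0, 0.0, 0.0]), _calibration(),
                           constants)
        assert res.delta_pi == 0.0
        assert res.osmolality == pytest.approx(279.0)

    def test_missing_calibration_is_lookup_error(self, constants):
        with pytest.raises(CalibrationLookupError):
            infer_sample(_flux_record([1e-13], probe="absent"),
                         _calibration(), constants)

    def test_triplicates_are_averaged_before_inference(self, constants):
        mean_only = infer_sample(_flux_record([2e-13, 2e-13, 2e-13]),
                                 _calibration(), constants)
        spread = infer_sample(_flux_record([1e-13, 2e-13, 3e-13]),
                              _calibration(), constants)
        assert spread.mean_flux == pytest.approx(mean_only.mean_flux)
        assert spread.delta_pi == pytest.approx(mean_only.delta_pi)

    def test_collapsed_tissue_is_domain_error(self, constants):
        rec = TissueFluxRecord(
            sample_id="s1", probe_id="P1", applied_pressure=0.1e6,
            excision_wet_mass=2e-4, post_equilibration_wet_mass=1e-6,
            post_flux_wet_mass=1e-6, dry_mass=5e-7,
            triplicate_fluxes=(1e-13,))
        assert radial_stretch(rec.excision_wet_mass,
                              rec.post_equilibration_wet_mass) < 0.2
        with pytest.raises(ModelError):
            infer_sample(rec, _calibration(), constants)


def test_record_mass_invariants():
    with pytest.raises(InvalidInputError):
        TissueFluxRecord(sample_id="s", probe_id="p", applied_pressure=1e5,
                         excision_wet_mass=2e-4,
                         post_equilibration_wet_mass=1.8e-4,
                         post_flux_wet_mass=2e-5, dry_mass=3e-5,
                         triplicate_fluxes=(1e-13,))
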