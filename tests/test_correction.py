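"""Extra-material correction: recovering contrast agent and fixative fractions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from demix import (
    AttenuationVector,
    BasisMaterial,
    BasisSet,
    HistologyFractions,
    SpecimenMeasurement,
    corrected_point,
    fit_extra_fractions,
    fraction_to_concentration,
    histology_point,
    matching_error,
    relative_error_pct,
    renormalize_composition,
)
from demix import materials
from demix.errors import (
    CompositionError,
    ConfigurationError,
    DegenerateGeometryWarning,
    DomainError,
)


@pytest.fixture
def histo():
    return HistologyFractions({"fibrin_platelets": 0.5, "RBC": 0.3, "WBC": 0.2})


@pytest.fixture
def extras(formalin, iomeprol):
    return [formalin, iomeprol]


def measure(point: AttenuationVector, sid="s") -> SpecimenMeasurement:
    return SpecimenMeasurement(sid, point)


class TestHistologyPoint:
    def test_pure_fibrin_returns_calibrated_attenuation(self, clot_basis):
        h = HistologyFractions({"fibrin_platelets": 1.0, "RBC": 0.0, "WBC": 0.0})
        point = histology_point(h, clot_basis)
        assert point.mu_low == pytest.approx(0.2693)
        assert point.mu_high == pytest.approx(0.1636)

    def test_equal_thirds_is_the_triangle_centroid(self, clot_basis):
        h = HistologyFractions({n: 1 / 3 for n in clot_basis.names})
        np.testing.assert_allclose(
            histology_point(h, clot_basis).as_array(),
            clot_basis.mu_matrix().mean(axis=1),
            atol=1e-14,
        )

    def test_point_lies_inside_basis_triangle(self, clot_basis, histo):
        point = histology_point(histo, clot_basis).as_array()
        mus = clot_basis.mu_matrix()
        for e in (0, 1):
            assert mus[e].min() <= point[e] <= mus[e].max()

    def test_missing_material_raises(self, aqueous_triplet, histo):
        with pytest.raises(ConfigurationError):
            histology_point(histo, aqueous_triplet)


class TestCorrectedPoint:
    def test_zero_extras_is_identity(self, histo, clot_basis, extras):
        p = histology_point(histo, clot_basis)
        shifted = corrected_point(p, [0.0, 0.0], extras)
        np.testing.assert_array_equal(shifted.as_array(), p.as_array())

    def test_half_fraction_reaches_the_midpoint(self, formalin):
        p = AttenuationVector(0.2693, 0.1636)
        shifted = corrected_point(p, [0.5], [formalin])
        np.testing.assert_allclose(
            shifted.as_array(),
            0.5 * (p.as_array() + formalin.attenuation.as_array()),
            atol=1e-14,
        )

    def test_hand_computed_affine_shift(self):
        test_formalin = BasisMaterial("formalin", AttenuationVector(0.20, 0.14))
        shifted = corrected_point(
            AttenuationVector(0.2693, 0.1636), [0.1], [test_formalin]
        )
        assert shifted.mu_low == pytest.approx(0.26237, abs=1e-12)
        assert shifted.mu_high == pytest.approx(0.16124, abs=1e-12)

    def test_constraint_violations(self, formalin, iomeprol):
        p = AttenuationVector(0.2693, 0.1636)
        with pytest.raises(DomainError):
            corrected_point(p, [-0.1], [formalin])
        with pytest.raises(DomainError):
            corrected_point(p, [0.6, 0.5], [formalin, iomeprol])


def grid_oracle_single_extra(measurement, histo, basis, extra, step=1e-5):
    """Dense grid search over one extra fraction — independent of the solver."""
    mu_h = histology_point(histo, basis).as_array()
    b = mu_h - measurement.mu_ct.as_array()
    a = mu_h - extra.attenuation.as_array()
    grid = np.arange(0.0, 1.0, step)
    costs = np.sum((b[None, :] - grid[:, None] * a[None, :]) ** 2, axis=1)
    return grid[np.argmin(costs)]


class TestFitExtraFractions:
    def test_measurement_at_histology_point_needs_no_correction(
        self, histo, clot_basis, extras
    ):
        p = histology_point(histo, clot_basis)
        r = fit_extra_fractions(measure(p), histo, clot_basis, extras)
        assert all(v == 0 for v in r.extra_fractions.values())
        assert r.cost_value == pytest.approx(0.0, abs=1e-30)
        assert r.matching_error_pct == (0.0, 0.0)

    def test_single_formalin_fraction_recovered(self, histo, clot_basis, formalin):
        p = histology_point(histo, clot_basis)
        target = corrected_point(p, [0.1], [formalin])
        r = fit_extra_fractions(measure(target), histo, clot_basis, [formalin])
        assert r.extra_fractions["formalin"] == pytest.approx(0.1, abs=1e-8)
        assert max(r.matching_error_pct) < 1e-8
        oracle = grid_oracle_single_extra(
            measure(target), histo, clot_basis, formalin
        )
        assert r.extra_fractions["formalin"] == pytest.approx(oracle, abs=2e-5)

    def test_two_independent_extras_recovered_exactly(self, histo, clot_basis, extras):
        p = histology_point(histo, clot_basis)
        target = corrected_point(p, [0.3, 0.05], extras)
        r = fit_extra_fractions(measure(target), histo, clot_basis, extras)
        assert r.extra_fractions["formalin"] == pytest.approx(0.3, abs=1e-8)
        assert r.extra_fractions["iomeprol"] == pytest.approx(0.05, abs=1e-8)
        assert r.cost_value <= 1e-16
        # 2 unknowns / 2 equations: direct linear solve as oracle
        A = np.column_stack(
            [p.as_array() - m.attenuation.as_array() for m in extras]
        )
        oracle = np.linalg.solve(A, p.as_array() - target.as_array())
        np.testing.assert_allclose(
            [r.extra_fractions["formalin"], r.extra_fractions["iomeprol"]],
            oracle,
            atol=1e-10,
        )

    def test_negative_unconstrained_solution_refits_on_formalin_only(
        self, histo, clot_basis, extras
    ):
        """Specimens reachable only along the formalin path get iomeprol = 0."""
        p = histology_point(histo, clot_basis)
        formalin, iomeprol = extras
        # move along formalin, then push slightly *away* from iomeprol
        away = p.as_array() - 0.02 * (iomeprol.attenuation.as_array() - p.as_array())
        target = corrected_point(AttenuationVector(*away), [0.2], [formalin])
        r = fit_extra_fractions(measure(target), histo, clot_basis, extras)
        assert r.extra_fractions["iomeprol"] == 0.0
        assert r.extra_fractions["formalin"] > 0
        oracle = grid_oracle_single_extra(measure(target), histo, clot_basis, formalin)
        assert r.extra_fractions["formalin"] == pytest.approx(oracle, abs=2e-5)

    def test_collinear_paths_warn_and_reduce(self, histo, clot_basis, formalin):
        p = histology_point(histo, clot_basis).as_array()
        f_mu = formalin.attenuation.as_array()
        collinear = BasisMaterial(
            "formalin2", AttenuationVector(*(p + 2.0 * (f_mu - p)))
        )
        target = corrected_point(AttenuationVector(*p), [0.2], [formalin])
        with pytest.warns(DegenerateGeometryWarning):
            r = fit_extra_fractions(
                measure(target), histo, clot_basis, [formalin, collinear]
            )
        assert min(r.extra_fractions.values()) == 0.0
        assert max(r.matching_error_pct) < 1e-8

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_exact_recovery_property(self, seed):
        """corrected_point -> fit inverts exactly for interior extras (<=1e-6)."""
        rng = np.random.default_rng(seed)
        basis = materials.clot_basis()
        h = HistologyFractions(dict(zip(basis.names, rng.dirichlet(np.ones(3)))))
        extras = [materials.formalin(), materials.iomeprol()]
        f_true = rng.uniform([0.0, 0.0], [0.6, 0.3])
        p = histology_point(h, basis)
        target = corrected_point(p, f_true, extras)
        r = fit_extra_fractions(measure(target), h, basis, extras)
        recovered = np.array(
            [r.extra_fractions["formalin"], r.extra_fractions["iomeprol"]]
        )
        np.testing.assert_allclose(recovered, f_true, atol=1e-6)
        assert r.c_a * r.c_s == pytest.approx(1.0, abs=1e-12)
        assert sum(v for _, v in r.full_composition.items()) == pytest.approx(
            1.0, abs=1e-12
        )


class TestRenormalize:
    def test_zero_extras_keeps_histology(self, histo):
        full = renormalize_composition(histo, {"formalin": 0.0})
        for name, value in histo.fractions.items():
            assert full[name] == value

    def test_hand_arithmetic(self):
        h = HistologyFractions({"a": 0.5, "b": 0.3, "c": 0.2})
        full = renormalize_composition(h, {"formalin": 0.2})
        np.testing.assert_allclose(
            full.as_array(("a", "b", "c", "formalin")), [0.4, 0.24, 0.16, 0.2]
        )
        assert sum(v for _, v in full.items()) == pytest.approx(1.0, abs=1e-15)

    def test_extras_near_one_squeeze_histology_to_zero(self, histo):
        full = renormalize_composition(histo, {"formalin": 1 - 1e-9})
        assert all(
            full[name] < 1e-8 for name in histo.names
        )

    def test_extras_summing_to_one_rejected(self, histo):
        with pytest.raises(DomainError):
            renormalize_composition(histo, {"formalin": 0.7, "iomeprol": 0.3})


class TestScalarHelpers:
    def test_matching_error_reference_cases(self):
        a = AttenuationVector(0.30, 0.15)
        assert matching_error(a, a) == (0.0, 0.0)
        off = AttenuationVector(0.30 * 1.01, 0.15)
        assert matching_error(off, a)[0] == pytest.approx(1.0, abs=1e-12)
        with pytest.raises(DomainError):
            matching_error(a, AttenuationVector(0.0, 0.15))

    def test_single_path_cohort_has_positive_mean_matching_error(
        self, histo, clot_basis, extras
    ):
        """Truth uses two paths but the fit is allowed only one -> error > 0."""
        formalin, iomeprol = extras
        p = histology_point(histo, clot_basis)
        errors = []
        for f_form, f_iom in [(0.1, 0.03), (0.2, 0.05), (0.3, 0.02)]:
            target = corrected_point(p, [f_form, f_iom], extras)
            r = fit_extra_fractions(measure(target), histo, clot_basis, [formalin])
            errors.append(np.mean(r.matching_error_pct))
        assert np.mean(errors) > 0

    @pytest.mark.parametrize(
        "fraction, stock, expected",
        [(0.250, 20.0, 5.0), (0.033, 20.0, 0.66), (0.0, 20.0, 0.0)],
    )
    def test_fraction_to_concentration(self, fraction, stock, expected):
        material = materials.iomeprol(stock)
        assert fraction_to_concentration(fraction, material) == pytest.approx(expected)

    def test_missing_stock_concentration(self, formalin):
        with pytest.raises(ConfigurationError):
            fraction_to_concentration(0.1, formalin)

    @pytest.mark.parametrize(
        "true, est, expected, decimals",
        [(1.66, 1.72, 3.61, 2), (0.66, 0.16, 75.8, 1), (0.42, 0.42, 0.0, 10)],
    )
    def test_relative_error_pct(self, true, est, expected, decimals):
        assert round(relative_error_pct(true, est), decimals) == expected

    def test_relative_error_undefined_at_zero(self):
        with pytest.raises(DomainError):
            relative_error_pct(0.0, 1.0)


class TestHistologyFractionsType:
    def test_percentish_sum_renormalized(self):
        h = HistologyFractions({"a": 0.501, "b": 0.30, "c": 0.20})
        assert sum(h.fractions.values()) == pytest.approx(1.0, abs=1e-15)

    def test_bad_sum_rejected(self):
        with pytest.raises(CompositionError):
            HistologyFractions({"a": 0.5, "b": 0.3, "c": 0.3})
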