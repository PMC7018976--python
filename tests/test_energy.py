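import dataclasses
import math

import numpy as np
import pytest

from nanobead import (
    ModelParameters,
    bending_energy_density,
    induced_length_scales,
    protein_energy_density,
    single_domain_profiles,
    spontaneous_curvature,
    total_energy,
)
from nanobead.energy import entropic_energy_density


class TestSpontaneousCurvature:
    @pytest.mark.parametrize(
        "sigma, expected",
        [(0.0, 0.0), (1.25e-4, -0.025), (2.5e-5, -5e-3)],
    )
    def test_linear_coupling(self, params, sigma, expected):
        assert spontaneous_curvature(sigma, params) == pytest.approx(expected)

    def test_negative_density_rejected(self, params):
        with pytest.raises(ValueError):
            spontaneous_curvature(-1e-5, params)

    def test_negative_for_cone_proteins(self, params):
        sig = np.linspace(1e-6, 3.75e-4, 20)
        assert np.all(spontaneous_curvature(sig, params) < 0)


class TestProteinEnergyDensity:
    def test_zero_density(self, params):
        assert protein_energy_density(0.0, 0.0, params) == 0.0

    def test_aggregation_term(self, params):
        # -alpha sigma^2 at sigma = 2.5e-5
        assert protein_energy_density(2.5e-5, 0.0, params) == pytest.approx(-8e-3)

    def test_beta_zero_kills_gradient_term(self, params):
        assert protein_energy_density(2.5e-5, 1e-8, params) == pytest.approx(-8e-3)

    def test_gradient_term_with_nonzero_beta(self, params):
        p = params.replace(beta=1e10)
        expected = -8e-3 + 1e10 * (1e-8) ** 2
        assert protein_energy_density(2.5e-5, 1e-8, p) == pytest.approx(expected)

    def test_entropic_limit_at_zero_density(self, params):
        p = params.replace(include_entropy=True)
        # sigma log sigma -> 0, not an error
        assert protein_energy_density(0.0, 0.0, p) == 0.0
        assert entropic_energy_density(0.0, p) == 0.0


class TestBendingEnergyDensity:
    def test_bare_tube_value(self, params):
        w = bending_energy_density(1.0 / 70.0, 0.0, 0.0, 320.0, -288.0, params)
        assert w == pytest.approx(320.0 / (4 * 35.0**2))

    def test_vanishes_when_curvature_matches_spontaneous(self, params):
        C = spontaneous_curvature(1e-4, params)
        assert bending_energy_density(C, 0.0, 1e-4, 320.0, -288.0, params) == pytest.approx(0.0)

    def test_independent_of_kappaG_at_zero_gaussian_curvature(self, params):
        a = bending_energy_density(0.01, 0.0, 0.0, 320.0, -288.0, params)
        b = bending_energy_density(0.01, 0.0, 0.0, 320.0, +500.0, params)
        assert a == b

    def test_nonpositive_kappa_rejected(self, params):
        with pytest.raises(ValueError):
            bending_energy_density(0.01, 0.0, 0.0, -320.0, 0.0, params)


class TestTotalEnergy:
    def test_uniform_cylinder_closed_form(self, params, homogeneous_shape):
        fields = single_domain_profiles(params, sigma0=0.0)
        e = total_energy(homogeneous_shape, fields, params)
        # dominated by W0 * area; the clamped edge deviates from the
        # unloaded radius by ~1%, so the integral sits within ~2%
        area = 2 * np.pi * 35.355 * params.Lc
        assert e.bending == pytest.approx(params.W0 * area, rel=0.02)
        assert e.gaussian == pytest.approx(0.0, abs=1e-6 * abs(e.bending))
        assert e.aggregation == 0.0
        assert e.total == pytest.approx(
            e.bending + e.gaussian + e.aggregation + e.gradient + e.entropic
        )

    def test_quadrature_converges_under_refinement(self, protein_bead, params):
        fields = protein_bead.fields
        coarse = total_energy(protein_bead.resample(1001), fields, params)
        fine = total_energy(protein_bead.resample(2001), fields, params)
        assert fine.total == pytest.approx(coarse.total, rel=1e-3)

    def test_heterogeneity_raises_energy_above_bare_tube(self, protein_bead, params):
        # the reference state is the undeformed cylinder at the same
        # edge tension: heterogeneity can only cost energy
        fields = protein_bead.fields
        e = total_energy(protein_bead, fields, params)
        baseline = params.W0 * 2 * np.pi * params.Rc * params.Lc
        assert e.total >= baseline

    def test_translation_invariance(self, protein_bead, params):
        fields = protein_bead.fields
        shifted = dataclasses.replace(protein_bead, z=protein_bead.z + 500.0)
        a = total_energy(protein_bead, fields, params)
        b = total_energy(shifted, fields, params)
        assert a.total == pytest.approx(b.total)

    def test_entropic_component_is_percent_level(self, protein_bead):
        # justifies neglecting the entropic term at dilute densities
        p = protein_bead.params.replace(include_entropy=True)
        e = total_energy(protein_bead, protein_bead.fields, p)
        assert abs(e.entropic) < 0.02 * e.bending

    def test_non_overlapping_grid_rejected(self, protein_bead, params):
        q = params.replace(Lc=500.0)
        fields = single_domain_profiles(q, sigma0=0.0, L_domain=100.0, transition_width=25.0)
        with pytest.raises(ValueError, match="overlap"):
            total_energy(protein_bead, fields, params)


class TestInducedLengthScales:
    def test_rigid_domain_scale_equals_tube_radius(self, params):
        l_sig, l_kap, ratio = induced_length_scales(1.25e-4, 0.064, 320.0, params)
        assert l_kap == pytest.approx(35.3553, rel=1e-4)

    def test_protein_scale(self, params):
        l_sig, _, _ = induced_length_scales(1.25e-4, 0.064, 320.0, params)
        assert l_sig == pytest.approx(40.0)

    def test_zero_density_flagged_infinite(self, params):
        l_sig, l_kap, ratio = induced_length_scales(0.0, 0.064, 320.0, params)
        assert math.isinf(l_sig) and math.isinf(ratio)
        assert l_kap > 0

    @pytest.mark.parametrize("bad", [(1e-4, 0.0, 320.0), (1e-4, 0.064, 0.0), (-1e-4, 0.064, 320.0)])
    def test_invalid_inputs(self, params, bad):
        with pytest.raises(ValueError):
            induced_length_scales(*bad, params)
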