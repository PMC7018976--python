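import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanobead import DomainSpec, ProfileSet, single_domain_profiles, tanh_profile, two_domain_profiles
from nanobead.profiles import TanhField


def make_grid(L=20000.0, n=4001):
    return np.linspace(0.0, L, n)


class TestTanhProfile:
    def test_no_domains_is_baseline(self):
        s = make_grid()
        assert np.all(tanh_profile(s, [], 0.5) == 0.5)

    def test_plateau_and_baseline_recovery(self):
        s = make_grid()
        d = DomainSpec(center=10000.0, length=8000.0, amplitude=1.25e-4, transition_width=350.0)
        f = tanh_profile(s, [d], 0.0)
        assert f[2000] == pytest.approx(1.25e-4, rel=1e-3)  # domain center
        assert abs(f[0]) < 1e-3 * 1.25e-4                   # far outside
        # baseline recovered beyond 5 transition widths from the edge
        far = s > d.end + 5 * d.transition_width
        assert np.all(np.abs(f[far]) < 1e-3 * 1.25e-4)

    def test_amplitude_equal_baseline_is_flat(self):
        s = make_grid()
        d = DomainSpec(center=10000.0, length=8000.0, amplitude=2.0, transition_width=350.0)
        assert np.allclose(tanh_profile(s, [d], 2.0), 2.0)

    def test_overlapping_different_amplitudes_rejected(self):
        s = make_grid()
        d1 = DomainSpec(center=9000.0, length=6000.0, amplitude=1.0, transition_width=300.0)
        d2 = DomainSpec(center=11000.0, length=6000.0, amplitude=2.0, transition_width=300.0)
        with pytest.raises(ValueError, match="ambiguous"):
            tanh_profile(s, [d1, d2], 0.0)

    def test_domain_outside_grid_rejected(self):
        s = make_grid(L=5000.0)
        d = DomainSpec(center=4000.0, length=3000.0, amplitude=1.0, transition_width=300.0)
        with pytest.raises(ValueError, match="margin"):
            tanh_profile(s, [d], 0.0)

    @given(
        amplitude=st.floats(1e-6, 4e-4),
        length=st.floats(2000.0, 10000.0),
        width=st.floats(50.0, 400.0),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_centered_domain_is_mirror_symmetric(self, amplitude, length, width):
        if width > length / 4:
            width = length / 4
        s = make_grid()
        d = DomainSpec(center=10000.0, length=length, amplitude=amplitude, transition_width=width)
        f = tanh_profile(s, [d], 0.0)
        assert np.allclose(f, f[::-1], rtol=0, atol=1e-12 * amplitude + 1e-300)

    def test_smoothness_scales_with_transition_width(self):
        s = make_grid(n=20001)
        ds = s[1] - s[0]
        curv = {}
        for w in (100.0, 200.0):
            d = DomainSpec(center=10000.0, length=8000.0, amplitude=1.0, transition_width=w)
            f = tanh_profile(s, [d], 0.0)
            curv[w] = np.max(np.abs(np.diff(f, 2))) / ds**2
        # max |f''| ~ 1/w^2
        assert curv[100.0] / curv[200.0] == pytest.approx(4.0, rel=0.15)

    def test_analytic_derivatives_match_finite_differences(self):
        field = TanhField(0.0, [DomainSpec(10000.0, 8000.0, 1.0, 350.0)])
        s = np.linspace(4000.0, 16000.0, 2001)
        h = 1e-2
        fd1 = (field(s + h) - field(s - h)) / (2 * h)
        fd2 = (field(s + h) - 2 * field(s) + field(s - h)) / h**2
        assert np.allclose(field(s, 1), fd1, atol=1e-8)
        assert np.allclose(field(s, 2), fd2, atol=1e-6)


class TestSingleDomain:
    def test_homogeneous_when_all_amplitudes_trivial(self, params):
        ps = single_domain_profiles(params, sigma0=0.0, kappa_ratio=1.0, delta_kappaG=0.0)
        assert ps.is_homogeneous()

    def test_protein_domain_geometry(self, params):
        ps = single_domain_profiles(params, sigma0=1.25e-4)
        i_mid = np.argmin(np.abs(ps.s_grid - 1e4))
        assert ps.sigma[i_mid] == pytest.approx(1.25e-4, rel=1e-3)
        assert ps.sigma[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(ps.kappa_field == params.kappa)

    def test_rigidity_domain_shares_geometry(self, params):
        ps = single_domain_profiles(params, sigma0=1.25e-4, kappa_ratio=30.0, uniform_sigma=True)
        i_mid = np.argmin(np.abs(ps.s_grid - 1e4))
        assert ps.kappa_field[i_mid] == pytest.approx(30.0 * params.kappa, rel=1e-3)
        assert ps.kappa_field[0] == pytest.approx(params.kappa, rel=1e-3)
        assert np.all(ps.sigma == 1.25e-4)  # composition uniform

    def test_domain_longer_than_tube_rejected(self, params):
        with pytest.raises(ValueError):
            single_domain_profiles(params, sigma0=1e-5, L_domain=2.5e4)

    def test_symmetry_detection(self, params):
        assert single_domain_profiles(params, sigma0=1e-4).is_symmetric()

    def test_csv_roundtrip(self, params, tmp_path):
        ps = single_domain_profiles(params, sigma0=1e-4, kappa_ratio=5.0)
        f = tmp_path / "profiles.csv"
        ps.to_csv(f)
        back = ProfileSet.from_csv(f)
        assert np.allclose(back.sigma, ps.sigma)
        assert np.allclose(back.kappa_field, ps.kappa_field)


class TestTwoDomain:
    def test_far_domains_positions(self, params):
        ps = two_domain_profiles(params, sigma0=1.25e-4, L_separation=4000.0)
        # plateaus at [0, 8] and [12, 20] um up to transition smoothing
        centers = [m[0] for m in ps.domain_meta]
        assert centers == pytest.approx([4000.0, 16000.0])
        i = np.argmin(np.abs(ps.s_grid - 4000.0))
        assert ps.sigma[i] == pytest.approx(1.25e-4, rel=1e-3)
        i_mid = np.argmin(np.abs(ps.s_grid - 1e4))
        assert ps.sigma[i_mid] < 1e-3 * 1.25e-4

    def test_touching_domains_match_single_double_length(self, params):
        ps2 = two_domain_profiles(params, sigma0=1e-4, L_separation=0.0)
        ps1 = single_domain_profiles(params, sigma0=1e-4, L_domain=16000.0)
        away = np.abs(ps2.s_grid - 1e4) > 3 * 350.0  # away from the seam
        assert np.allclose(ps2.sigma[away], ps1.sigma[away], rtol=0.01, atol=1e-9)

    def test_zero_amplitude_homogeneous(self, params):
        assert two_domain_profiles(params, sigma0=0.0).is_homogeneous()

    def test_geometric_overflow_rejected(self, params):
        with pytest.raises(ValueError, match="exceeds"):
            two_domain_profiles(params, sigma0=1e-4, L_domain=9000.0, L_separation=3000.0)

    def test_pair_is_mirror_symmetric(self, params):
        ps = two_domain_profiles(params, sigma0=1e-4, kappa_ratio=4.0, L_separation=2000.0)
        assert ps.is_symmetric()
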