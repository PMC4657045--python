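"""Rod-on-springs simulator: discretisation, relaxation, mode selection."""

import math

import numpy as np
import pytest

from mtbuckle import units
from mtbuckle.mechanics import FilamentMechanics
from mtbuckle.simulator import (RodModel, _energy_grad, dominant_wavelength,
                                finite_length_critical_force, relax,
                                simulate_ramp, total_energy)

# dense-kinesin-like flexural rigidity used for all scenarios
EI = 2.347e-24  # N·m² (7.15 MPa × 32.82e-32 m⁴)
MECH = FilamentMechanics(EI / 32.82e-32, 32.82e-32)


def scenario(lam_um=4.0, nodes_per_lam=16, n_lam=5, k_scale=1.0,
             boundary="clamped", anchor_per_node=True):
    """Rod whose continuum wavelength is ``lam_um`` (before ``k_scale``)."""
    ds = lam_um / nodes_per_lam * units.UM
    n_nodes = nodes_per_lam * n_lam + 1
    ec = EI * (2 * math.pi / (lam_um * units.UM)) ** 4
    anchor = ds if anchor_per_node else ds / 3
    k = ec * anchor * k_scale
    return RodModel(n_nodes=n_nodes, node_spacing=ds, mech=MECH,
                    k_spring=k, anchor_spacing=anchor, boundary=boundary)


class TestEnergy:
    def test_straight_rest_shape_has_zero_energy(self):
        m = scenario()
        assert total_energy(m, m.rest_shape()) == pytest.approx(0.0,
                                                                abs=1e-30)

    def test_circular_arc_matches_continuum_bending_energy(self):
        """A 200-node arc reproduces EI·L/(2R²) within 1%."""
        ds, R = 0.2 * units.UM, 20.0 * units.UM
        n = 201
        m = RodModel(n_nodes=n, node_spacing=ds, mech=MECH,
                     k_spring=1e-30, anchor_spacing=ds)
        phi = 2 * math.asin(ds / (2 * R))
        ang = phi * np.arange(n)
        shape = np.column_stack([R * np.sin(ang), R * (1 - np.cos(ang))])
        L = (n - 1) * ds
        expect = EI * L / (2 * R * R)
        assert total_energy(m, shape) == pytest.approx(expect, rel=0.01)

    def test_rigid_transverse_offset_loads_only_the_springs(self):
        m = scenario()
        delta = 0.05 * units.UM
        shape = m.rest_shape()
        shape[:, 1] += delta
        expect = 0.5 * m.node_foundation_stiffness().sum() * delta ** 2
        assert total_energy(m, shape) == pytest.approx(expect, rel=1e-9)
        # per-anchor share is k_spring δ²/2
        assert expect == pytest.approx(
            m.n_anchors * 0.5 * m.k_spring * delta ** 2, rel=1e-9)

    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(5)
        p = np.column_stack([np.arange(30.0), np.zeros(30)])
        p += rng.normal(0, 0.05, p.shape)
        kf = rng.uniform(0, 1e-3, 30)
        e0, g = _energy_grad(p, 1000.0, kf)
        eps = 1e-7
        for idx in [(0, 0), (3, 1), (15, 0), (15, 1), (29, 1)]:
            q = p.copy()
            q[idx] += eps
            ep, _ = _energy_grad(q, 1000.0, kf)
            q[idx] -= 2 * eps
            em, _ = _energy_grad(q, 1000.0, kf)
            assert g[idx] == pytest.approx((ep - em) / (2 * eps),
                                           rel=1e-4, abs=1e-8)

    def test_shape_size_mismatch_rejected(self):
        m = scenario()
        with pytest.raises(ValueError):
            total_energy(m, np.zeros((3, 2)))


class TestRelax:
    def test_zero_strain_stays_straight(self):
        m = scenario()
        shape = relax(m, m.rest_shape(), 0.0, seed=1)
        assert np.abs(shape[:, 1]).max() < m.node_spacing / 50
        assert total_energy(m, shape) == pytest.approx(
            0.0, abs=1e-3 * EI / m.node_spacing)

    def test_buckled_state_beats_straight_compression(self):
        m = scenario()
        strain = 0.01
        buckled = relax(m, m.rest_shape(), strain, seed=1)
        straight = m.rest_shape()
        straight[:, 0] *= (1 - strain)
        assert np.abs(buckled[:, 1]).max() > m.node_spacing / 10
        assert total_energy(m, buckled) < total_energy(m, straight)

    def test_wavelength_independent_of_seed(self):
        m = scenario()
        lams = []
        for seed in (1, 2):
            shape = relax(m, m.rest_shape(), 0.01, seed=seed)
            lams.append(dominant_wavelength(shape))
        assert lams[0] == pytest.approx(lams[1], rel=0.05)

    def test_strain_out_of_range_rejected(self):
        m = scenario()
        with pytest.raises(Exception):
            relax(m, m.rest_shape(), 0.9, seed=0)


@pytest.fixture(scope="module")
def ramp_result():
    m = scenario()
    return m, simulate_ramp(m, max_strain=0.01, n_steps=8, seed=3)


class TestSimulateRamp:
    def test_wavelength_matches_continuum_theory(self, ramp_result):
        m, res = ramp_result
        lam = res.post_onset_wavelength()
        assert lam is not None
        assert lam == pytest.approx(m.analytic_wavelength(), rel=0.10)

    def test_onset_recorded_and_amplitude_grows(self, ramp_result):
        _, res = ramp_result
        assert res.onset_strain is not None
        assert res.max_amplitude_m[-1] > res.max_amplitude_m[0] * 0.99
        post = res.max_amplitude_m[res.strain_history >= res.onset_strain]
        assert np.all(np.diff(post) > -1e-12)

    def test_axial_force_near_critical_load(self, ramp_result):
        """Post-onset the rod carries ≈ its finite-length critical force."""
        m, res = ramp_result
        fc, _ = finite_length_critical_force(
            MECH, m.k_spring / m.anchor_spacing, m.length, m.boundary)
        assert res.axial_force[-1] == pytest.approx(fc, rel=0.15)

    def test_step_count_insensitivity(self):
        """A strain-rate surrogate: 4x more ramp steps changes the
        selected wavelength by < 5%."""
        m = scenario(nodes_per_lam=14, n_lam=4)
        lam = {}
        for steps in (6, 24):
            res = simulate_ramp(m, max_strain=0.01, n_steps=steps, seed=2)
            lam[steps] = res.post_onset_wavelength()
        assert lam[6] == pytest.approx(lam[24], rel=0.05)

    def test_vanishing_foundation_gives_single_euler_crest(self):
        from mtbuckle.traces import detect_crests
        m = scenario(lam_um=4.0, nodes_per_lam=12, n_lam=5, k_scale=1e-6)
        res = simulate_ramp(m, max_strain=0.02, n_steps=6, seed=4)
        tr = res.to_trace()
        crests = detect_crests(tr, noise_sigma=0.0)
        assert len(crests) == 1

    def test_crest_count_non_decreasing_with_foundation_density(self):
        """Euler -> multiwave: shrinking the anchor spacing (denser
        kinesin) never reduces the number of buckling crests."""
        from mtbuckle.traces import CrestParams, detect_crests
        # noise-free traces allow a low amplitude floor; the stiffest
        # foundation selects the shortest wavelength and hence the
        # smallest amplitude at fixed strain
        params = CrestParams(amplitude_floor_um=0.05)
        counts = []
        for k_scale in (1e-6, 1.0, 8.0):
            m = scenario(lam_um=4.0, nodes_per_lam=12, n_lam=5,
                         k_scale=k_scale)
            res = simulate_ramp(m, max_strain=0.02, n_steps=6, seed=5)
            counts.append(len(detect_crests(res.to_trace(),
                                            noise_sigma=0.0, params=params)))
        assert counts == sorted(counts)
        assert counts[0] == 1 and counts[-1] >= 3

    def test_onset_strain_non_decreasing_in_foundation_stiffness(self):
        onsets = []
        for k_scale in (1.0, 4.0, 16.0):
            m = scenario(lam_um=3.0, nodes_per_lam=16, n_lam=3,
                         k_scale=k_scale)
            res = simulate_ramp(m, max_strain=0.004, n_steps=20, seed=6)
            assert res.onset_strain is not None
            onsets.append(res.onset_strain)
        assert onsets == sorted(onsets)
        assert onsets[-1] > onsets[0]

    def test_discretisation_energy_convergence(self):
        """Doubling the node count changes the converged energy < 1%."""
        energies = {}
        for npl in (12, 24):
            m = scenario(lam_um=4.0, nodes_per_lam=npl, n_lam=4)
            shape = relax(m, m.rest_shape(), 0.01, seed=7)
            energies[npl] = total_energy(m, shape)
        assert energies[24] == pytest.approx(energies[12], rel=0.01)


class TestFiniteLengthCriticalForce:
    def test_euler_limit_without_foundation(self):
        L = 20 * units.UM
        f, m = finite_length_critical_force(MECH, 0.0, L, "clamped")
        assert m == 1
        assert f == pytest.approx(EI * (2 * math.pi / L) ** 2, rel=1e-12)
        f_pin, _ = finite_length_critical_force(MECH, 0.0, L, "pinned")
        assert f_pin == pytest.approx(f / 4, rel=1e-12)

    def test_long_rod_limit_is_continuum_value(self):
        ec = 0.5  # N/m²
        lam_c = 2 * math.pi * (EI / ec) ** 0.25
        f, _ = finite_length_critical_force(MECH, ec, 50 * lam_c)
        assert f == pytest.approx(2 * math.sqrt(ec * EI), rel=0.02)

    def test_short_rods_pay_a_premium(self):
        """F(L) ≥ continuum everywhere, growing as L falls below λ_c."""
        ec = 0.5
        cont = 2 * math.sqrt(ec * EI)
        lam_c = 2 * math.pi * (EI / ec) ** 0.25
        forces = [finite_length_critical_force(MECH, ec, f * lam_c)[0]
                  for f in (0.3, 0.45, 0.7, 10.5)]
        assert all(f >= cont * (1 - 1e-12) for f in forces)
        # the premium grows as the rod shrinks below λ_c ...
        assert forces[0] > forces[1] > forces[2] > cont
        # ... and is negligible for long rods (away from resonant lengths)
        assert forces[3] == pytest.approx(cont, rel=0.05)

    def test_mode_number_grows_with_length(self):
        ec = 0.5
        lam_c = 2 * math.pi * (EI / ec) ** 0.25
        modes = [finite_length_critical_force(MECH, ec, f * lam_c)[1]
                 for f in (1.0, 5.0, 20.0)]
        assert modes == sorted(modes)
        assert modes[-1] > modes[0]
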