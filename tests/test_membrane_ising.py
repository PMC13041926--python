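"""Lipid-lattice Metropolis dynamics and channel gating tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from riftsim.membrane_ising import (
    LipidLattice,
    channel_update,
    epsp_spatial_field,
    init_lattice,
    metropolis_step,
    refractory_steps_for,
    run_membrane_sim,
    substrate_metrics,
)


class TestInitLattice:
    def test_default_channel_count(self):
        lat = init_lattice(100, 0.04, np.random.default_rng(0))
        assert lat.n_channels == 400

    def test_balanced_initial_spins(self):
        lat = init_lattice(100, 0.04, np.random.default_rng(1))
        frac = (lat.spins == 1).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(20))
    def test_no_duplicate_channel_sites(self, seed):
        lat = init_lattice(50, 0.05, np.random.default_rng(seed))
        sites = set(map(tuple, lat.channel_rc))
        assert len(sites) == lat.n_channels

    def test_parameter_guards(self):
        with pytest.raises(ValueError):
            init_lattice(10)
        with pytest.raises(ValueError):
            init_lattice(100, 0.5)


class TestEPSPField:
    def test_level_radii_and_center_peak(self):
        size = 101
        f = epsp_spatial_field({1: 1.0}, size)
        c = (size - 1) // 2
        assert f[c, c] == pytest.approx(1.0, rel=1e-6)
        # independent Gaussian oracle at an off-center cell
        radius = size / 4.0
        d2 = 10.0 ** 2
        assert f[c + 10, c] == pytest.approx(np.exp(-d2 / (2 * radius ** 2)),
                                             rel=1e-6)

    def test_kernel_value_at_one_radius(self):
        size = 100
        radius = size / 4.0
        f = epsp_spatial_field({1: 1.0}, size)
        yy, xx = np.indices((size, size), dtype=float)
        c = (size - 1) / 2.0
        d = np.hypot(yy - c, xx - c)
        sel = np.abs(d - radius) < 0.5
        assert np.allclose(f[sel], np.exp(-d[sel] ** 2 / (2 * radius ** 2)),
                           rtol=1e-6)
        assert np.exp(-0.5) == pytest.approx(0.6065, abs=1e-4)

    def test_zero_amplitudes(self):
        assert epsp_spatial_field({1: 0.0, 2: 0.0}, 60).sum() == 0.0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            epsp_spatial_field({4: 1.0}, 40)  # 40/4 - 15 < 0


def _lattice_from(spins):
    s = np.asarray(spins, dtype=np.int8)
    return LipidLattice(s, np.zeros((1, 2), dtype=int),
                        np.zeros(1, dtype=bool))


class TestMetropolis:
    def test_zero_delta_e_always_flips_with_temperature_field(self):
        # alternating columns: every site has two opposite-sign horizontal
        # neighbours and two same-sign vertical ones -> dE = 0 everywhere
        n = 12
        spins = np.fromfunction(lambda i, j: np.where(j % 2 == 0, 1, -1),
                                (n, n)).astype(np.int8)
        # one attempt per fresh lattice (later flips would change dE)
        for seed in range(30):
            lat = _lattice_from(spins.copy())
            flips = np.zeros((n, n))
            metropolis_step(lat, temperature_field=np.full((n, n), 1.0),
                            site_fraction=1.0 / (n * n),
                            rng=np.random.default_rng(seed),
                            flip_accum=flips)
            assert flips.sum() == 1  # the single attempt always accepted

    def test_negative_delta_e_always_accepted(self):
        # all aligned except one opposed site: attempts there have dE < 0
        n = 10
        spins = -np.ones((n, n), dtype=np.int8)
        spins[4, 4] = 1
        lat = _lattice_from(spins)
        for seed in range(5):
            la = _lattice_from(spins.copy())
            metropolis_step(la, site_fraction=2.0,
                            rng=np.random.default_rng(seed))
            assert la.spins[4, 4] == -1  # flipped at first visit

    def test_base_acceptance_rate_exp_minus_four(self):
        # uniform +1 lattice: every flip has dE = 8, acceptance exp(-4)
        n = 30
        accepted = 0
        attempts = 0
        for seed in range(40):
            lat = _lattice_from(np.ones((n, n), dtype=np.int8))
            flips = np.zeros((n, n))
            metropolis_step(lat, site_fraction=0.2,
                            rng=np.random.default_rng(seed),
                            flip_accum=flips)
            first = int(flips.sum())  # most flips are first flips at dE=8
            accepted += first
            attempts += int(0.2 * n * n)
        rate = accepted / attempts
        assert rate == pytest.approx(np.exp(-4.0), abs=0.012)

    def test_positive_temperature_required(self):
        lat = _lattice_from(np.ones((8, 8), dtype=np.int8))
        with pytest.raises(ValueError):
            metropolis_step(lat, temperature_field=np.zeros((8, 8)))

    def test_relaxation_orders_domains(self):
        lat = init_lattice(20, 0.05, np.random.default_rng(3))
        s0 = lat.spins.copy()

        def alignment(s):
            return float(np.mean(s * np.roll(s, 1, 0))
                         + np.mean(s * np.roll(s, 1, 1)))

        rng = np.random.default_rng(4)
        for _ in range(100):
            metropolis_step(lat, site_fraction=0.25, rng=rng)
        assert alignment(lat.spins) > alignment(s0) + 0.3

    def test_detailed_balance_against_exact_enumeration(self):
        """3x3 periodic Ising sampled by our kernel vs exact Boltzmann."""
        n, T = 3, 2.0

        def nn_corr(s):
            return float(np.mean(s * np.roll(s, 1, 0))
                         + np.mean(s * np.roll(s, 1, 1))) / 2.0

        # exact enumeration over all 2^9 states
        z = 0.0
        acc = 0.0
        for bits in itertools.product([-1, 1], repeat=n * n):
            s = np.array(bits).reshape(n, n)
            e = -(np.sum(s * np.roll(s, 1, 0)) + np.sum(s * np.roll(s, 1, 1)))
            w = np.exp(-e / T)
            z += w
            acc += w * nn_corr(s)
        exact = acc / z

        lat = _lattice_from(np.ones((n, n), dtype=np.int8))
        tf = np.full((n, n), T)
        rng = np.random.default_rng(8)
        samples = []
        for sweep in range(6000):
            metropolis_step(lat, temperature_field=tf, site_fraction=1.0,
                            rng=rng)
            if sweep >= 500 and sweep % 5 == 0:
                samples.append(nn_corr(lat.spins))
        assert np.mean(samples) == pytest.approx(exact, abs=0.03)


class TestChannelUpdate:
    def test_neutral_baseline_half_open_probability(self):
        n = 30
        spins = np.fromfunction(lambda i, j: np.where((i + j) % 2 == 0, 1, -1),
                                (n, n)).astype(np.int8)
        lat = LipidLattice(spins, np.array([[15, 15]]),
                           np.zeros(1, dtype=bool))
        p = channel_update(lat, np.zeros((n, n)), np.random.default_rng(0))
        assert p[0] == pytest.approx(0.5, abs=0.01)

    def test_lipid_bias_symmetry_and_gamma_scaling(self):
        n = 30

        def p_open(sign, gamma):
            spins = sign * np.ones((n, n), dtype=np.int8)
            lat = LipidLattice(spins, np.array([[15, 15]]),
                               np.zeros(1, dtype=bool), gamma=gamma)
            return channel_update(lat, np.zeros((n, n)),
                                  np.random.default_rng(0))[0]

        p_plus, p_minus = p_open(+1, 1.0), p_open(-1, 1.0)
        assert p_plus > 0.5 > p_minus
        assert p_plus + p_minus == pytest.approx(1.0, abs=1e-9)
        logit = lambda p: np.log(p / (1 - p))
        assert logit(p_open(+1, 2.0)) == pytest.approx(2 * logit(p_plus),
                                                       rel=1e-9)

    def test_channel_count_conserved_and_distinct(self):
        lat = init_lattice(40, 0.05, np.random.default_rng(2))
        for _ in range(20):
            channel_update(lat, np.zeros((40, 40)), np.random.default_rng(3))
        assert lat.n_channels == 80
        assert len(set(map(tuple, lat.channel_rc))) == 80


@pytest.fixture(scope="module")
def blocked():
    return run_membrane_sim(mode="blocked", rng=np.random.default_rng(21))


class TestRunMembraneSim:
    def test_refractory_formula(self):
        assert refractory_steps_for(0.5) == 12
        assert refractory_steps_for(1.0) == 25

    def test_spins_stay_binary(self, blocked):
        assert set(np.unique(blocked.lattice.spins)) <= {-1, 1}

    def test_channel_count_conserved_across_aps(self, blocked):
        assert len(blocked.ap_steps) >= 2
        assert blocked.lattice.n_channels == 400

    def test_lipid_field_continuous_across_aps(self, blocked):
        # channel positions reset at APs but the lipid field is untouched:
        # successive snapshots bridging an AP differ only by Metropolis
        # flips (<= 5% of sites per step)
        snaps = dict(blocked.spin_snapshots)
        steps = sorted(snaps)
        for ap in blocked.ap_steps:
            before = max(s for s in steps if s <= ap)
            after = min(s for s in steps if s > ap)
            changed = np.mean(snaps[before] != snaps[after])
            assert changed <= 0.05 * (after - before) + 0.01

    def test_trajectory_reproducible(self):
        a = run_membrane_sim(n_steps=30, rng=np.random.default_rng(9))
        b = run_membrane_sim(n_steps=30, rng=np.random.default_rng(9))
        pd.testing.assert_frame_equal(a.summary, b.summary)
        assert np.array_equal(a.lattice.spins, b.lattice.spins)

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            run_membrane_sim(mode="hybrid")
        with pytest.raises(ValueError):
            run_membrane_sim(threshold=5.0)

    def test_substrate_metrics_shape(self, blocked):
        sm = substrate_metrics(blocked)
        assert sm.phi_star_lipid >= 0
        assert sm.phi_star_channel >= 0
        assert not sm.lipid_fd_series.empty
        fracs = sm.contribution_fractions
        assert set(fracs) == {"epsp", "channel", "lipid"}
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)
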