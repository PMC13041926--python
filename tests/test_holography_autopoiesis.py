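"""IFS encoding, chaos game, endospace projection and feedback tests."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from riftsim.gfm_multifractal import epsp_train
from riftsim.holography_autopoiesis import (
    IFSTransformSet,
    _geometric_phases,
    autopoietic_feedback,
    chaos_game,
    coherent_sources,
    default_regions,
    derive_ifs_from_epsp,
    differential_transforms,
    extract_ifs_from_lattice,
    ifs_temperature_field,
    project_endospace,
)

SIERPINSKI = IFSTransformSet(
    np.array([[.5, 0, 0, .5, 0, 0], [.5, 0, 0, .5, .5, 0],
              [.5, 0, 0, .5, .25, .5]]),
    np.full(3, 1 / 3),
)


def _trains():
    return [epsp_train(l, event_times=(0.0, 2.0, 4.0, 6.0))
            for l in range(1, 5)]


class TestDeriveIFS:
    def test_count_contraction_and_probabilities(self):
        tset = derive_ifs_from_epsp(_trains())
        assert 4 <= len(tset) <= 6
        assert tset.is_contractive()
        assert np.all(np.abs(tset.determinants) < 1.0)
        assert tset.probs.sum() == pytest.approx(1.0)

    def test_deterministic(self):
        a = derive_ifs_from_epsp(_trains())
        b = derive_ifs_from_epsp(_trains())
        assert np.array_equal(a.params, b.params)

    def test_dominant_peak_mapping(self):
        tset = derive_ifs_from_epsp(_trains())
        # the largest-amplitude peak has normalized amplitude 1 -> scale 0.8
        assert tset.scales.max() == pytest.approx(0.8, rel=1e-9)
        i = np.argmax(np.abs(tset.determinants))
        assert abs(tset.determinants[i]) == pytest.approx(0.64, rel=1e-9)
        assert tset.probs[i] == pytest.approx(tset.probs.max())

    def test_too_few_peaks(self):
        with pytest.raises(ValueError):
            derive_ifs_from_epsp([epsp_train(1, event_times=(0.0,))])


class TestChaosGame:
    def test_sierpinski_box_dimension(self):
        pts = chaos_game(SIERPINSKI, 100_000, rng=np.random.default_rng(0))
        counts = []
        ks = [4, 8, 16, 32, 64]
        for m in ks:
            h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=m)
            counts.append((h > 0).sum())
        slope = np.polyfit(np.log(ks), np.log(counts), 1)[0]
        assert slope == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_single_map_converges_to_fixed_point(self):
        one = IFSTransformSet(np.array([[.5, 0, 0, .5, .3, .3]]),
                              np.array([1.0]))
        pts = chaos_game(one, 100, rng=np.random.default_rng(1))
        assert np.allclose(pts, [0.6, 0.6], atol=1e-6)

    def test_seeded_reproducibility(self):
        a = chaos_game(SIERPINSKI, 1000, rng=np.random.default_rng(5))
        b = chaos_game(SIERPINSKI, 1000, rng=np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_divergence_guard(self):
        bad = IFSTransformSet(np.array([[1.5, 0, 0, 1.5, 0, 0]]),
                              np.array([1.0]))
        with pytest.raises(ValueError):
            chaos_game(bad, 10)


class TestTemperatureField:
    def test_empty_set_uniform_baseline(self):
        f = ifs_temperature_field(None, 50)
        assert f.std() == 0.0 and f.max() == pytest.approx(0.5)

    def test_hotspot_band_and_positivity(self):
        tset = derive_ifs_from_epsp(_trains())
        f = ifs_temperature_field(tset, 100, rng=np.random.default_rng(0))
        assert 0.52 <= f.max() <= 0.56
        assert f.min() > 0.0
        assert 0.3 <= f.mean() <= 0.7  # within base +/- strength


class TestExtractIFS:
    @staticmethod
    def _collage_lattice(n=96):
        """Four filled corner boxes = images of the frame under a 4-map IFS."""
        spins = -np.ones((n, n), dtype=np.int8)
        h = int(0.45 * n)
        spins[:h, :h] = 1
        spins[:h, -h:] = 1
        spins[-h:, :h] = 1
        spins[-h:, -h:] = 1
        return spins

    def test_round_trip_collage_error(self):
        spins = self._collage_lattice()
        tset = extract_ifs_from_lattice(spins, 4)
        assert len(tset) == 4 and tset.is_contractive()
        # reference 4-corner IFS in the same [-1, 1] frame
        s = 0.45
        ref = IFSTransformSet(np.array([
            [s, 0, 0, s, -(1 - s), -(1 - s)],
            [s, 0, 0, s, (1 - s), -(1 - s)],
            [s, 0, 0, s, -(1 - s), (1 - s)],
            [s, 0, 0, s, (1 - s), (1 - s)],
        ]), np.full(4, 0.25))
        a = chaos_game(ref, 20_000, rng=np.random.default_rng(2))
        b = chaos_game(tset, 20_000, rng=np.random.default_rng(3))
        d_ab = cKDTree(b).query(a)[0].mean()
        d_ba = cKDTree(a).query(b)[0].mean()
        assert max(d_ab, d_ba) < 0.1

    def test_uniform_lattice_degenerate(self):
        tset = extract_ifs_from_lattice(np.ones((30, 30), dtype=np.int8))
        assert tset.degenerate

    def test_deterministic(self):
        spins = self._collage_lattice()
        a = extract_ifs_from_lattice(spins)
        b = extract_ifs_from_lattice(spins)
        assert np.array_equal(a.params, b.params)


class TestDifferentialTransforms:
    def test_identical_sets_give_zero_parameters(self):
        tset = derive_ifs_from_epsp(_trains())
        h = differential_transforms(tset, tset)
        assert np.allclose(h.params, 0.0)

    def test_hand_subtraction(self):
        a = IFSTransformSet(np.array([[.5, 0, 0, .5, .2, .2],
                                      [.3, 0, 0, .3, -.1, .4]]),
                            np.array([.7, .3]))
        b = IFSTransformSet(np.array([[.4, 0, 0, .4, .1, .1],
                                      [.2, 0, 0, .2, -.2, .3]]),
                            np.array([.8, .2]))
        h = differential_transforms(a, b)
        assert np.allclose(sorted(h.params[:, 0]), [0.1, 0.1])
        assert np.allclose(h.params[:, 4:6],
                           [[.1, .1], [.1, .1]])

    def test_unequal_sizes_drop_extras(self):
        rng = np.random.default_rng(0)
        mk = lambda k: IFSTransformSet(
            np.column_stack([rng.uniform(.1, .4, k), np.zeros(k),
                             np.zeros(k), rng.uniform(.1, .4, k),
                             rng.uniform(-1, 1, k), rng.uniform(-1, 1, k)]),
            np.full(k, 1.0 / k))
        h = differential_transforms(mk(5), mk(4))
        assert len(h) == 4

    def test_degenerate_inputs_rejected(self):
        good = derive_ifs_from_epsp(_trains())
        bad = IFSTransformSet(np.empty((0, 6)), np.empty(0), degenerate=True)
        with pytest.raises(ValueError):
            differential_transforms(good, bad)


class TestCoherentSources:
    @pytest.fixture(scope="class")
    def h_rift(self):
        a = derive_ifs_from_epsp(_trains())
        b = IFSTransformSet(a.params * 0.7, a.probs)
        return differential_transforms(a, b)

    def test_phase_formula_hand_oracle(self):
        tset = IFSTransformSet(np.array([[.5, 0, 0, .5, 0, 0]]),
                               np.array([1.0]))
        # center = fixed point = origin; w = |det| * s = 0.125
        d = 0.7
        phases = _geometric_phases(np.array([[-d, 0.0]]), tset)
        expected = (0.125 * (0.0 + 2 * np.pi * d / 0.5)) % (2 * np.pi)
        assert phases[0] == pytest.approx(expected, rel=1e-9)

    def test_phase_translation_invariance(self):
        m = np.array([[.4, .1, -.1, .4]])
        t = np.array([[.2, -.3]])
        shift = np.array([0.8, -0.5])
        mk = lambda tr: IFSTransformSet(
            np.column_stack([m, tr]), np.array([1.0]))
        base = mk(t)
        # translate the fixed point by `shift`: t' = t + (I - M) shift
        mat = base.matrices[0]
        t2 = t + ((np.eye(2) - mat) @ shift)[None, :]
        xy = np.array([[0.3, 0.4]])
        p1 = _geometric_phases(xy, base)
        p2 = _geometric_phases(xy + shift, mk(t2))
        assert p1[0] == pytest.approx(p2[0], rel=1e-9)

    def test_source_properties(self, h_rift):
        src = coherent_sources(h_rift, 2000, rng=np.random.default_rng(0))
        assert np.all((src.phase >= 0) & (src.phase < 2 * np.pi))
        assert np.all(src.amplitude >= 0)
        assert src.amplitude.max() == pytest.approx(1.0)
        # f = 50 / (1 + s) per generating transform
        s_all = h_rift.scales
        assert np.all(np.isin(np.round(src.frequency, 9),
                              np.round(50.0 / (1.0 + s_all), 9)))
        assert np.allclose(src.wavenumber,
                           2 * np.pi * src.frequency / 100.0)

    def test_zero_signature_rejected(self):
        zero = IFSTransformSet(np.zeros((2, 6)), np.full(2, 0.5))
        with pytest.raises(ValueError):
            coherent_sources(zero, 10)


class TestProjectEndospace:
    @staticmethod
    def _sources(xy, amp, phase, freq=40.0):
        from riftsim.holography_autopoiesis import InterferenceSources
        n = len(xy)
        return InterferenceSources(np.asarray(xy, float),
                                   np.asarray(amp, float),
                                   np.asarray(phase, float),
                                   np.full(n, freq))

    def test_single_source_at_voxel(self):
        src = self._sources([[0.0, 0.0]], [0.7], [0.0])
        f = project_endospace(src, grid=(25, 25, 13), normalize=False)
        assert f.raw_magnitude[12, 12, 6] == pytest.approx(0.7, rel=1e-5)

    def test_destructive_interference(self):
        src = self._sources([[0.0, 0.0], [0.0, 0.0]], [1.0, 1.0],
                            [0.0, np.pi])
        f = project_endospace(src, grid=(9, 9, 5), normalize=False)
        assert np.all(f.raw_magnitude < 1e-5)

    def test_normalization_range(self):
        rng = np.random.default_rng(1)
        src = self._sources(rng.uniform(-1, 1, (50, 2)), rng.random(50),
                            rng.uniform(0, 2 * np.pi, 50))
        f = project_endospace(src)
        assert f.magnitude.min() == pytest.approx(0.0)
        assert f.magnitude.max() == pytest.approx(1.0)

    def test_superposition_linearity(self):
        rng = np.random.default_rng(2)
        xy = rng.uniform(-1, 1, (40, 2))
        amp = rng.random(40)
        ph = rng.uniform(0, 2 * np.pi, 40)
        fa = project_endospace(self._sources(xy[:20], amp[:20], ph[:20]),
                               grid=(12, 12, 6), normalize=False)
        fb = project_endospace(self._sources(xy[20:], amp[20:], ph[20:]),
                               grid=(12, 12, 6), normalize=False)
        fab = project_endospace(self._sources(xy, amp, ph),
                                grid=(12, 12, 6), normalize=False)
        assert np.allclose(fab.psi, fa.psi + fb.psi, rtol=1e-4, atol=1e-7)


class TestAutopoieticFeedback:
    def _field(self, value=0.5):
        from riftsim.holography_autopoiesis import EndospaceField
        mag = np.full((8, 8, 4), value)
        return EndospaceField(np.zeros((8, 8, 4), complex), mag, mag)

    def test_alpha_zero_identity(self):
        g, _ = autopoietic_feedback(self._field(0.9), gamma_0=1.3, alpha=0.0)
        assert g == pytest.approx(1.3)

    def test_linear_response(self):
        g, pb = autopoietic_feedback(self._field(0.5), gamma_0=1.0, alpha=1.0)
        assert pb == pytest.approx(0.5)
        assert g == pytest.approx(1.5)

    def test_monotone_in_psi_bar(self):
        gs = [autopoietic_feedback(self._field(v), alpha=2.0)[0]
              for v in (0.1, 0.4, 0.8)]
        assert gs[0] < gs[1] < gs[2]

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            autopoietic_feedback(self._field(),
                                 region=np.zeros((8, 8, 4), bool))


class TestRegions:
    def test_eight_regions_cover_expected_areas(self):
        regs = default_regions(100)
        assert len(regs) == 8
        assert regs["full"].sum() == 10_000
        assert regs["center_half"].sum() == 2500
        assert regs["periphery"].sum() == 7500
        assert regs["quadrant_nw"].sum() == 2500
        assert regs["center_core"].sum() == 576  # 24x24 central box
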