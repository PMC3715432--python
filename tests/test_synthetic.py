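"""Generative model: chain displacement law, radial placement laws, in-nucleus
probe placement, rendering, and cohort bookkeeping."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import fishloc.synthetic as syn
from fishloc.synthetic import (ChainModel, CohortConfig, ImagingModel,
                               NucleusGeometry, NucleusModel, RadialModel,
                               RegionSpec, ellipse_edge_distance,
                               generate_cohort, place_probe_pair, render_stack,
                               sample_chain_displacement,
                               sample_radial_fraction, sample_cohort_truth)


class TestChainModel:
    def test_zero_separation_forces_coincidence(self):
        v = sample_chain_displacement(ChainModel(0.001, 0.0), 5, seed=0)
        np.testing.assert_array_equal(v, np.zeros((5, 3)))

    def test_mean_squared_distance_is_c_times_g(self):
        v = sample_chain_displacement(ChainModel(0.001, 100.0), 100_000, seed=1)
        mean_d2 = (v ** 2).sum(axis=1).mean()
        assert abs(mean_d2 - 0.1) / 0.1 < 0.02

    def test_linearity_in_g(self):
        m = {}
        for g in (65.0, 130.0):
            v = sample_chain_displacement(ChainModel(0.002, g), 100_000, seed=2)
            m[g] = (v ** 2).sum(axis=1).mean()
        assert abs(m[130.0] / m[65.0] - 2.0) < 0.1

    def test_mean_within_three_mc_standard_errors_on_grid(self):
        n = 100_000
        for i, (c, g) in enumerate([(0.001, 60), (0.001, 120),
                                    (0.003, 60), (0.003, 120)]):
            d2 = (sample_chain_displacement(ChainModel(c, g), n, seed=10 + i)
                  ** 2).sum(axis=1)
            se = d2.std() / math.sqrt(n)
            assert abs(d2.mean() - c * g) < 3 * se

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ChainModel(0.0, 10.0)
        with pytest.raises(ValueError):
            ChainModel(0.001, -1.0)
        with pytest.raises(ValueError):
            sample_chain_displacement(ChainModel(0.001, 10.0), 0, seed=0)


class TestRadialModel:
    def test_uniform_volume_law(self):
        f = sample_radial_fraction(RadialModel("uniform_volume"), 50_000, seed=3)
        assert ((f >= 0) & (f <= 1)).all()
        ks = sps.kstest(f, lambda x: 1 - (1 - x) ** 3).statistic
        assert ks < 0.02

    @pytest.mark.parametrize("a,b,mean", [(1.0, 1.0, 0.5), (2.0, 5.0, 2.0 / 7.0)])
    def test_beta_family_mean(self, a, b, mean):
        f = sample_radial_fraction(RadialModel("beta", a, b), 50_000, seed=4)
        assert abs(f.mean() - mean) < 0.01

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            RadialModel("gamma")
        with pytest.raises(ValueError):
            RadialModel("beta", a=0.0, b=1.0)


class TestEllipseDistance:
    def test_matches_dense_boundary_oracle(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 2 * np.pi, 200_000)
        for _ in range(20):
            a, b = rng.uniform(0.5, 3.0, size=2)
            # random interior point
            u, phi = rng.uniform(0, 1), rng.uniform(0, 2 * np.pi)
            y, x = 0.95 * u * a * np.sin(phi), 0.95 * u * b * np.cos(phi)
            boundary = np.column_stack([a * np.sin(t), b * np.cos(t)])
            oracle = np.sqrt(((boundary - [y, x]) ** 2).sum(axis=1)).min()
            assert abs(ellipse_edge_distance(a, b, y, x) - oracle) < 1e-4

    def test_centre_returns_minor_semi_axis(self):
        assert ellipse_edge_distance(0.8, 0.4, 0.0, 0.0) == pytest.approx(0.4)


class TestPlaceProbePair:
    SPHERE = NucleusGeometry(centre=(5.0, 5.0, 5.0), semi_axes=(4.0, 4.0, 4.0))

    def test_zero_genomic_separation_coincident_centroids(self):
        pair = place_probe_pair(self.SPHERE, ChainModel(0.001, 0.0),
                                RadialModel("beta", 2, 2), seed=0)
        assert pair.centroid_a == pair.centroid_b
        assert pair.d_um == 0.0

    def test_f_one_is_nucleus_centre(self, monkeypatch):
        monkeypatch.setattr(syn, "sample_radial_fraction",
                            lambda model, n, seed: np.array([1.0]))
        pair = place_probe_pair(self.SPHERE, ChainModel(0.001, 0.0),
                                RadialModel("beta", 2, 2), seed=0)
        np.testing.assert_allclose(pair.centroid_a, self.SPHERE.centre, atol=1e-9)

    def test_midpoint_attains_sampled_fraction(self):
        geom = NucleusGeometry(centre=(4.0, 5.0, 5.0), semi_axes=(1.4, 2.4, 1.7),
                               orientation=0.7)
        for seed in range(20):
            pair = place_probe_pair(geom, ChainModel(0.001, 0.0),
                                    RadialModel("beta", 2, 2), seed=seed)
            mid = geom.to_local(np.array([pair.centroid_a]))[0]
            scale = math.sqrt(1 - (mid[0] / geom.semi_axes[0]) ** 2)
            ey, ex = geom.semi_axes[1] * scale, geom.semi_axes[2] * scale
            f = ellipse_edge_distance(ey, ex, mid[1], mid[2]) / max(ey, ex)
            assert f == pytest.approx(pair.f_mid, abs=1e-6)

    def test_mean_d2_preserved_under_truncation(self):
        # separation small relative to the nucleus: truncation bias < 5%
        d2 = []
        chain = ChainModel(c=0.0004, g=100.0)  # c*g = 0.04 µm²
        radial = RadialModel("uniform_volume")
        rng = np.random.default_rng(8)
        for _ in range(10_000):
            pair = place_probe_pair(self.SPHERE, chain, radial, rng)
            d2.append(pair.d2_um2)
        assert abs(np.mean(d2) - 0.04) / 0.04 < 0.05

    def test_oversized_separation_rejected(self):
        small = NucleusGeometry(centre=(5.0, 5.0, 5.0),
                                semi_axes=(0.05, 0.05, 0.05))
        with pytest.raises(RuntimeError, match="resamples"):
            place_probe_pair(small, ChainModel(0.01, 10_000.0),
                             RadialModel("beta", 2, 2), seed=0)


class TestRenderStack:
    def test_noiseless_argmax_is_true_centroid_voxel(self, placed_nucleus):
        imaging = ImagingModel(noise_sd=0.0)
        stack = render_stack([placed_nucleus], imaging, seed=0)
        vox = np.asarray(imaging.voxel_size)
        true_vox = np.round(np.asarray(placed_nucleus.pair.centroid_a) / vox)
        peak = np.unravel_index(np.argmax(stack.data[1]), stack.shape)
        np.testing.assert_array_equal(peak, true_vox)

    def test_channel_shift_displaces_argmax(self, placed_nucleus):
        ref = render_stack([placed_nucleus], ImagingModel(noise_sd=0.0), seed=0)
        shifted = render_stack([placed_nucleus],
                               ImagingModel(noise_sd=0.0,
                                            channel_shift={"probeB": (0, 3)}),
                               seed=0)
        p0 = np.array(np.unravel_index(np.argmax(ref.data[2]), ref.shape))
        p1 = np.array(np.unravel_index(np.argmax(shifted.data[2]), shifted.shape))
        np.testing.assert_array_equal(p1 - p0, (0, 0, 3))

    def test_same_seed_bit_identical(self, placed_nucleus):
        a = render_stack([placed_nucleus], ImagingModel(), seed=9)
        b = render_stack([placed_nucleus], ImagingModel(), seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_undetectable_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ImagingModel(spot_amplitude=50.0, background=100.0)


def _two_region_config(n_embryos=3, n_nuclei=5, seed=0, c2=0.003):
    regions = (
        RegionSpec("stem_zone", "control", ChainModel(0.0015, 65.0),
                   RadialModel("beta", 1.6, 2.6)),
        RegionSpec("neural_tube", "control", ChainModel(c2, 65.0),
                   RadialModel("beta", 2.8, 1.8)),
    )
    return CohortConfig(regions=regions, n_embryos=n_embryos,
                        n_nuclei=n_nuclei, seed=seed)


class TestCohort:
    def test_roi_table_and_stack_counts(self):
        ds = generate_cohort(_two_region_config(), render=False)
        assert len(ds.bundles) == 6          # 2 regions x 3 embryos
        assert len(ds.rois) == 30            # 2 x 3 x 5
        assert list(ds.rois.columns[:4]) == ["nucleus_id", "embryo_id",
                                             "region", "condition"]

    def test_same_seed_identical_tables(self):
        a = generate_cohort(_two_region_config(seed=5), render=False)
        b = generate_cohort(_two_region_config(seed=5), render=False)
        assert a.rois.equals(b.rois)
        assert a.truth.equals(b.truth)

    def test_duplicate_region_labels_rejected(self):
        r = RegionSpec("sz", "ctrl", ChainModel(0.001, 65.0),
                       RadialModel("beta", 2, 2))
        with pytest.raises(ValueError, match="duplicate"):
            CohortConfig(regions=(r, r))

    def test_doubled_compaction_doubles_ground_truth_d2(self):
        cfg = _two_region_config(n_embryos=2, n_nuclei=150, seed=2)
        truth = sample_cohort_truth(cfg)
        means = truth.groupby("region")["true_d2_um2"].mean()
        ratio = means["neural_tube"] / means["stem_zone"]
        # each arm's mean has ~5% relative MC error at n=300
        assert abs(ratio - 2.0) < 0.3

    def test_truth_fractional_radius_in_unit_interval(self):
        truth = sample_cohort_truth(_two_region_config(n_nuclei=20, seed=3))
        assert ((truth.true_frac_radius >= 0) & (truth.true_frac_radius <= 1)).all()
        assert (truth.true_d2_um2 >= 0).all()
        np.testing.assert_allclose(truth.true_d_um ** 2, truth.true_d2_um2,
                                   rtol=1e-12)
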