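"""Segmentation and the size / throughput / encapsulation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dexdrop import (
    DropletSet,
    GridSpec,
    LabeledDroplet,
    encapsulation_efficiency,
    filter_satellites,
    gaussian_fit,
    segment_droplets,
    size_statistics,
    throughput_estimate,
    width_diameter_regression,
)
from dexdrop.synthetic import SyntheticImageSpec, generate_droplet_image, generate_field_fixture


class TestSegmentation:
    @pytest.mark.parametrize("scale", [1.0, 0.2])
    @pytest.mark.parametrize("diameter", [4.0, 10.0, 18.0, 20.0])
    def test_noise_free_disks_recovered_within_one_pixel(self, scale, diameter):
        spec = SyntheticImageSpec(
            channel_length=5 * (diameter + 8) + 20,
            channel_width=20.0,
            px_scale=scale,
            n_droplets=5,
            diameter_mean=diameter,
            diameter_sd=0.0,
            psf_sigma=0.0,
            noise_sd=0.0,
            seed=1,
        )
        img, truth = generate_droplet_image(spec)
        ds = segment_droplets(img, 0.5, min_area=2 * scale**2, grid_scale=scale)
        assert len(ds) == 5
        for d in ds.droplets:
            assert d.equiv_diameter == pytest.approx(diameter, abs=scale)

    def test_all_zero_field_gives_empty_set(self):
        ds = segment_droplets(np.zeros((128, 20)), 0.5)
        assert len(ds) == 0
        with pytest.raises(ValueError):
            size_statistics(ds)

    def test_min_area_discards_specks(self):
        arr = np.zeros((64, 20))
        arr[10, 10] = 1.0  # single pixel
        arr[30:36, 8:14] = 1.0  # 36 px blob
        ds = segment_droplets(arr, 0.5, min_area=2.0)
        assert len(ds) == 1
        assert ds.droplets[0].area == pytest.approx(36.0)

    def test_boundary_touching_flagged(self):
        arr = np.zeros((64, 20))
        arr[5:15, 0:6] = 1.0  # touches z wall
        arr[30:40, 8:14] = 1.0  # interior
        ds = segment_droplets(arr, 0.5)
        flags = sorted(d.touches_boundary for d in ds.droplets)
        assert flags == [False, True]
        stats = size_statistics(ds, exclude_boundary=True)
        assert stats.n == 1

    def test_periodic_seam_component_merged(self):
        grid = GridSpec(nx=128, nz=20)
        state = generate_field_fixture(grid, [(0.0, 14.0), (64.0, 14.0)])
        # the disk centred at x = 0 wraps across the seam
        ds_wrap = segment_droplets(state.eta, 0.5, grid_scale=1.0, periodic_x=True)
        ds_cut = segment_droplets(state.eta, 0.5, grid_scale=1.0, periodic_x=False)
        assert len(ds_wrap) == 2
        assert len(ds_cut) == 3
        wrapped = min(ds_wrap.droplets, key=lambda d: min(d.centroid[0], 128 - d.centroid[0]))
        assert min(wrapped.centroid[0], 128.0 - wrapped.centroid[0]) < 1.0
        d1, d2 = (d.equiv_diameter for d in ds_wrap.droplets)
        assert d1 == pytest.approx(d2, abs=0.5)

    def test_matches_regionprops_on_nonperiodic_input(self, rng):
        """Areas and centroids agree with the skimage reference measurer."""
        from skimage.measure import label as sk_label
        from skimage.measure import regionprops

        arr = (rng.uniform(size=(96, 32)) > 0.7).astype(float)
        ds = segment_droplets(arr, 0.5, min_area=0.0, grid_scale=1.0)
        props = regionprops(sk_label(arr > 0.5, connectivity=2))
        assert len(ds) == len(props)
        ours = sorted((d.area, d.centroid[0], d.centroid[1]) for d in ds.droplets)
        ref = sorted(
            (p.area, p.centroid[0] + 0.5, p.centroid[1] + 0.5) for p in props
        )
        for (a1, x1, z1), (a2, x2, z2) in zip(ours, ref):
            assert a1 == pytest.approx(a2)
            assert x1 == pytest.approx(x2, abs=1e-9)
            assert z1 == pytest.approx(z2, abs=1e-9)


class TestSizeStatistics:
    def test_hand_computed_values(self):
        ds = _set_from_diameters([10.0, 10.0, 10.0])
        s = size_statistics(ds)
        assert (s.mean, s.sd, s.cv) == (10.0, 0.0, 0.0)

        s2 = size_statistics(_set_from_diameters([18.0, 20.0, 22.0]))
        assert s2.mean == pytest.approx(20.0)
        assert s2.sd == pytest.approx(2.0)  # sample SD, n-1 denominator
        assert s2.cv == pytest.approx(10.0)

    def test_linear_density(self):
        ds = _set_from_diameters([10.0] * 4, channel_length=250.0)
        s = size_statistics(ds)
        assert s.linear_density == pytest.approx(4 / 250.0)

    @given(scale=st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_cv_is_scale_invariant(self, scale):
        base = [14.0, 17.0, 21.0, 19.0]
        cv1 = size_statistics(_set_from_diameters(base)).cv
        cv2 = size_statistics(_set_from_diameters([scale * d for d in base])).cv
        assert cv2 == pytest.approx(cv1, rel=1e-9)


class TestSatelliteFilter:
    def test_identity_at_zero(self):
        ds = _set_from_diameters([19.0, 20.0, 5.0])
        assert len(filter_satellites(ds, 0.0)) == 3

    def test_cutoff(self):
        ds = _set_from_diameters([19.0, 20.0, 5.0])
        kept = filter_satellites(ds, 14.0)
        assert sorted(d.equiv_diameter for d in kept.droplets) == [19.0, 20.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_bimodal_mixture_statistics_improve(self, seed):
        """Removing the satellite mode raises the mean and lowers the CV."""
        rng = np.random.default_rng(seed)
        main = rng.normal(19.0, 1.4, 120)
        sats = rng.uniform(3.0, 12.0, 18)
        ds = _set_from_diameters(np.concatenate([main, sats]))
        full = size_statistics(ds)
        kept = size_statistics(filter_satellites(ds, 14.0))
        assert kept.n <= full.n
        assert kept.mean >= full.mean
        assert kept.cv <= full.cv


class TestGaussianFit:
    def test_degenerate_sample(self):
        fit = gaussian_fit([7.0, 7.0, 7.0])
        assert (fit.mu, fit.sigma, fit.degenerate) == (7.0, 0.0, True)

    def test_parameter_recovery(self, rng):
        samples = rng.normal(18.3, 1.3, 10_000)
        fit = gaussian_fit(samples)
        assert fit.mu == pytest.approx(18.3, rel=0.01)
        assert fit.sigma == pytest.approx(1.3, rel=0.03)

    def test_order_invariance(self, rng):
        samples = list(rng.normal(10, 2, 50))
        a = gaussian_fit(samples)
        b = gaussian_fit(sorted(samples))
        assert a.mu == pytest.approx(b.mu, rel=1e-12)
        assert a.sigma == pytest.approx(b.sigma, rel=1e-12)


class TestWidthDiameterRegression:
    def test_measured_means_are_nearly_linear_in_width(self):
        # hand OLS on the four (width, mean diameter) pairs: slope 0.918,
        # intercept 0.10
        pairs = [(5, 4.6), (10, 9.3), (15, 14.1), (20, 18.3)]
        res = width_diameter_regression(pairs)
        assert res.slope == pytest.approx(0.918, abs=1e-3)
        assert res.intercept == pytest.approx(0.10, abs=1e-2)
        assert res.r_squared > 0.999

    def test_perfect_line(self):
        res = width_diameter_regression([(5, 5.0), (10, 10.0), (20, 20.0)])
        assert res.r_squared == pytest.approx(1.0)

    def test_singular_design(self):
        with pytest.raises(ValueError):
            width_diameter_regression([(10, 9.0), (10, 9.5)])


class TestThroughput:
    def test_discussion_arithmetic(self):
        out = throughput_estimate(10 / 250.0, 100)
        assert out["droplets_per_cm_channel"] == pytest.approx(400.0)
        assert out["droplets_per_cm_width"] == pytest.approx(40_000.0)

    def test_zero_density(self):
        out = throughput_estimate(0.0, 100)
        assert out["droplets_per_cm_channel"] == 0.0

    @given(d=st.floats(0, 1), k=st.floats(0, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_exact_linearity(self, d, k):
        out = throughput_estimate(d, k)
        assert out["droplets_per_cm_channel"] == pytest.approx(d * 1e4)
        assert out["droplets_per_cm_width"] == pytest.approx(d * 1e4 * k)


class TestEncapsulation:
    def test_no_particles(self):
        ds = _set_from_diameters([10.0, 12.0])
        res = encapsulation_efficiency(ds, [])
        assert res.efficiency == 0.0

    def test_one_particle_per_droplet(self):
        ds = _set_from_diameters([10.0, 12.0, 14.0])
        pts = [d.centroid for d in ds.droplets]
        res = encapsulation_efficiency(ds, pts)
        assert res.efficiency == 1.0
        assert list(res.counts) == [1, 1, 1]

    def test_label_route_equals_brute_force_mask_counting(self, rng):
        grid = GridSpec(nx=256, nz=20)
        state = generate_field_fixture(
            grid, [(40.0, 16.0), (100.0, 12.0), (170.0, 18.0), (230.0, 8.0)]
        )
        ds = segment_droplets(state.eta, 0.5, grid_scale=1.0)
        pts = np.column_stack(
            [rng.uniform(0, 256, 300), rng.uniform(0, 20, 300)]
        )
        res = encapsulation_efficiency(ds, pts)
        # brute force: count points whose pixel lies in each labeled component
        occupied = set()
        inside = 0
        for x, z in pts:
            lab = ds.labels[min(int(x), 255), min(int(z), 19)]
            if lab > 0:
                occupied.add(int(lab))
                inside += 1
        assert res.n_particles_inside == inside
        assert res.efficiency == pytest.approx(len(occupied) / len(ds))


def _set_from_diameters(diameters, channel_length=1000.0):
    droplets = [
        LabeledDroplet(
            id=i + 1,
            centroid=(20.0 * (i + 1), 10.0),
            area=math.pi * (d / 2) ** 2,
            equiv_diameter=float(d),
            touches_boundary=False,
        )
        for i, d in enumerate(diameters)
    ]
    return DropletSet(
        droplets=droplets,
        channel_length=channel_length,
        channel_width=20.0,
        threshold=0.5,
    )
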