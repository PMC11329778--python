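"""Tests for fiber detection, orientation entropy and coverage analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from detensio import (
    FiberAnalysisConfig,
    FiberFieldSpec,
    FiberMask,
    ImageStack,
    OrientationDistribution,
    analyze_fiber_image,
    coverage_fraction,
    isodata_threshold,
    max_intensity_projection,
    orientation_entropy,
    orientation_histogram,
    render_fiber_image,
    segment_fibers,
    tubeness_filter,
)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def tubeness_oracle(image, scale_um, pixel_size_um):
    """Per-pixel loop: finite differences of the smoothed image, then the
    symmetric 2x2 eigenproblem via numpy's solver."""
    sigma = scale_um / pixel_size_um
    s = ndimage.gaussian_filter(np.asarray(image, float), sigma, mode="nearest")

    def d1(arr):
        h, w = arr.shape
        out = np.empty_like(arr)
        for j in range(w):
            for i in range(h):
                if i == 0:
                    out[i, j] = arr[1, j] - arr[0, j]
                elif i == h - 1:
                    out[i, j] = arr[-1, j] - arr[-2, j]
                else:
                    out[i, j] = (arr[i + 1, j] - arr[i - 1, j]) / 2.0
        return out

    gy = d1(s)
    gx = d1(s.T).T
    gyy = d1(gy)
    gyx = d1(gy.T).T
    gxy_ = d1(gx)
    gxx = d1(gx.T).T
    gxy = 0.5 * (gyx + gxy_)
    h, w = s.shape
    resp = np.zeros_like(s)
    for i in range(h):
        for j in range(w):
            lam = np.linalg.eigvalsh(
                np.array([[gyy[i, j], gxy[i, j]], [gxy[i, j], gxx[i, j]]])
            )
            resp[i, j] = max(0.0, -lam[0])
    return resp


def isodata_oracle(values):
    """All isodata fixed points by scanning candidate split thresholds."""
    v = np.sort(np.unique(np.asarray(values, float).ravel()))
    x = np.asarray(values, float).ravel()
    fixed = []
    for k in range(1, v.size):
        cut = v[k]  # foreground = x >= cut
        low, high = x[x < cut], x[x >= cut]
        t = 0.5 * (low.mean() + high.mean())
        # fixed point: t induces the same partition as cut
        if low.max() < t <= high.min():
            fixed.append(t)
    return fixed


def flood_fill_areas(binary):
    """8-connected component areas via BFS, independent of scipy.label."""
    visited = np.zeros_like(binary, dtype=bool)
    areas = []
    h, w = binary.shape
    for si in range(h):
        for sj in range(w):
            if binary[si, sj] and not visited[si, sj]:
                area = 0
                stack = [(si, sj)]
                visited[si, sj] = True
                while stack:
                    i, j = stack.pop()
                    area += 1
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            ni, nj = i + di, j + dj
                            if (
                                0 <= ni < h
                                and 0 <= nj < w
                                and binary[ni, nj]
                                and not visited[ni, nj]
                            ):
                                visited[ni, nj] = True
                                stack.append((ni, nj))
                areas.append(area)
    return areas


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


class TestProjection:
    def test_identical_slices_project_to_slice(self, rng):
        sl = rng.uniform(0, 10, size=(16, 16))
        stack = ImageStack(
            voxels=np.dstack([sl] * 5), pixel_size_um=0.5, z_step_um=1.0
        )
        assert np.array_equal(max_intensity_projection(stack, 5.0), sl)

    def test_elementwise_maximum(self):
        a = np.zeros((16, 16))
        b = np.zeros((16, 16))
        a[0, 0], b[0, 0] = 0.0, 3.0
        a[5, 5], b[5, 5] = 5.0, 1.0
        stack = ImageStack(
            voxels=np.dstack([a, b]), pixel_size_um=1.0, z_step_um=1.0
        )
        proj = max_intensity_projection(stack, 2.0)
        assert proj[0, 0] == 3.0 and proj[5, 5] == 5.0

    def test_matches_bruteforce_loop_over_depth(self, rng):
        vox = rng.uniform(0, 100, size=(16, 16, 8))
        stack = ImageStack(voxels=vox, pixel_size_um=0.5, z_step_um=2.0)
        proj = max_intensity_projection(stack, 8.0)  # 4 slices
        expected = np.zeros((16, 16))
        for i in range(16):
            for j in range(16):
                expected[i, j] = max(vox[i, j, k] for k in range(4))
        assert np.array_equal(proj, expected)

    def test_2d_input_rejected(self):
        stack = ImageStack(voxels=np.ones((16, 16)), pixel_size_um=1.0)
        with pytest.raises(ValueError, match="projection requires a stack"):
            max_intensity_projection(stack, 5.0)

    def test_nonpositive_depth_rejected(self):
        stack = ImageStack(
            voxels=np.ones((16, 16, 3)), pixel_size_um=1.0, z_step_um=1.0
        )
        with pytest.raises(ValueError, match="positive"):
            max_intensity_projection(stack, 0.0)


# ---------------------------------------------------------------------------
# Tubeness
# ---------------------------------------------------------------------------


class TestTubeness:
    def test_constant_image_gives_zero_response(self):
        resp = tubeness_filter(np.full((32, 32), 7.0), 1.0, 1.0)
        assert np.all(resp.values == 0)

    def test_bright_line_response_peaks_on_line(self):
        img = np.zeros((33, 33))
        img[16, :] = 10.0
        resp = tubeness_filter(img, 1.0, 1.0).values
        assert resp[16, 16] > 0
        assert resp[16, 16] > 50 * resp[4, 16]

    def test_matches_closed_form_eigenvalue_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 1, size=(32, 32))
            impl = tubeness_filter(img, 1.5, 1.0).values
            oracle = tubeness_oracle(img, 1.5, 1.0)
            scale = impl.max()
            assert np.allclose(impl, oracle, rtol=1e-10, atol=1e-10 * scale)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            tubeness_filter(np.ones((16, 16)), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


class TestSegmentation:
    def test_separable_bimodal_classes(self, rng):
        vals = np.zeros((20, 20))
        idx = rng.choice(400, size=40, replace=False)
        vals.ravel()[idx] = 100.0
        from detensio import RidgeResponse

        mask = segment_fibers(RidgeResponse(values=vals, scale_um=1.0))
        thr = mask.provenance["threshold"]
        assert 0 < thr < 100
        assert mask.pixels.sum() == 40

    def test_fixed_threshold_above_max_gives_empty_mask(self):
        from detensio import RidgeResponse

        resp = RidgeResponse(values=np.random.rand(16, 16), scale_um=1.0)
        mask = segment_fibers(resp, "fixed", fixed_threshold=2.0)
        assert not mask.pixels.any()

    def test_all_zero_response_warns_and_returns_empty(self):
        from detensio import RidgeResponse

        resp = RidgeResponse(values=np.zeros((16, 16)), scale_um=1.0)
        with pytest.warns(UserWarning, match="no fibers"):
            mask = segment_fibers(resp)
        assert not mask.pixels.any()

    def test_isodata_is_fixed_point_of_bruteforce_scan(self, rng):
        stack, _ = render_fiber_image(
            FiberFieldSpec(image_size_px=(64, 64), n_fibers=12, seed=3)
        )
        vals = stack.voxels
        t = isodata_threshold(vals)
        fixed = isodata_oracle(vals)
        assert any(abs(t - f) < 1e-9 for f in fixed)

    def test_isodata_partition_self_consistent(self, rng):
        v = rng.normal(0, 1, size=(30, 30)) ** 2
        t = isodata_threshold(v)
        low, high = v[v < t], v[v >= t]
        assert abs(t - 0.5 * (low.mean() + high.mean())) < 1e-9


# ---------------------------------------------------------------------------
# Orientation histogram + entropy
# ---------------------------------------------------------------------------


def line_image(angle_deg, size=64, n_lines=6):
    """Parallel anti-aliased lines at the given axial angle."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rad = np.radians(angle_deg)
    # signed distance to a family of parallel lines with normal (sin, cos)
    d = (xx - size / 2) * np.sin(rad) + (size / 2 - yy) * -np.cos(rad)
    spacing = size / n_lines
    frac = np.abs((d % spacing) - spacing / 2)
    return np.exp(-((frac - spacing / 4) ** 2))  # smooth stripes


class TestOrientationHistogram:
    def test_horizontal_lines_give_zero_degree_mode(self):
        img = line_image(0.0)
        mask = FiberMask(pixels=np.ones_like(img, dtype=bool), provenance={})
        d = orientation_histogram(img, mask, n_bins=36, smoothing_scale_um=1.0)
        zero_bin = np.argmin(np.abs(d.bin_centers_deg - 0.0))
        assert d.p[zero_bin - 1 : zero_bin + 2].sum() >= 0.9

    def test_rotated_lines_shift_mode(self):
        img = line_image(45.0)
        mask = FiberMask(pixels=np.ones_like(img, dtype=bool), provenance={})
        d = orientation_histogram(img, mask, n_bins=36, smoothing_scale_um=1.0)
        mode_center = d.bin_centers_deg[np.argmax(d.p)]
        assert abs(mode_center - 45.0) <= 7.5

    def test_empty_mask_rejected(self):
        img = line_image(0.0)
        mask = FiberMask(pixels=np.zeros_like(img, dtype=bool), provenance={})
        with pytest.raises(ValueError, match="no oriented structure"):
            orientation_histogram(img, mask)

    def test_constant_image_rejected(self):
        img = np.ones((32, 32))
        mask = FiberMask(pixels=np.ones_like(img, dtype=bool), provenance={})
        with pytest.raises(ValueError, match="no oriented structure"):
            orientation_histogram(img, mask)

    def test_uniform_segments_give_flat_histogram(self):
        """Many short segments with uniform orientations: estimated
        histogram flat within 3 sigma of the multinomial per-bin level."""
        n_bins = 12
        spec = FiberFieldSpec(
            image_size_px=(1024, 1024),
            kappa=0.0,
            n_fibers=2000,
            fiber_length_um=30.0,
            seed=11,
        )
        stack, truth = render_fiber_image(spec, truth_n_bins=n_bins)
        cfg = FiberAnalysisConfig(
            pixel_size_um=0.5, n_bins=n_bins, circular_fov=True
        )
        res = analyze_fiber_image(stack, cfg)
        p0 = 1.0 / n_bins
        sigma = np.sqrt(p0 * (1 - p0) / spec.n_fibers)
        assert np.all(np.abs(res.distribution.p - p0) < 3 * sigma + 0.01)


class TestEntropy:
    def test_uniform_distribution_maximal(self):
        edges = np.linspace(-90, 90, 181)
        d = OrientationDistribution(edges, np.full(180, 1 / 180), 1.0)
        h = orientation_entropy(d)
        assert h.H_nats == pytest.approx(np.log(180), abs=1e-12)

    def test_degenerate_distribution_zero(self):
        p = np.zeros(180)
        p[17] = 1.0
        d = OrientationDistribution(np.linspace(-90, 90, 181), p, 1.0)
        assert orientation_entropy(d).H_nats == 0.0

    def test_dyadic_closed_form(self):
        p = np.zeros(16)
        p[:3] = [0.5, 0.25, 0.25]
        d = OrientationDistribution(np.linspace(-90, 90, 17), p, 1.0)
        assert orientation_entropy(d).H_nats == pytest.approx(
            1.5 * np.log(2), abs=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 64), st.integers(0, 2**31 - 1))
    def test_bounds_and_permutation_invariance(self, n_bins, seed):
        r = np.random.default_rng(seed)
        w = r.random(n_bins) + 1e-12
        p = w / w.sum()
        edges = np.linspace(-90, 90, n_bins + 1)
        h = orientation_entropy(OrientationDistribution(edges, p, 1.0)).H_nats
        assert 0.0 <= h <= np.log(n_bins) + 1e-12
        perm = r.permutation(n_bins)
        h2 = orientation_entropy(
            OrientationDistribution(edges, p[perm], 1.0)
        ).H_nats
        assert h2 == pytest.approx(h, abs=1e-12)


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


class TestCoverage:
    def test_all_foreground_is_single_full_particle(self):
        img = np.ones((20, 20))
        cov = coverage_fraction(img, 0.5, min_particle_area_um2=0.0)
        assert cov.fraction == 1.0
        assert cov.n_particles == 1

    def test_small_particle_filtered_out(self):
        img = np.zeros((20, 20))
        img[2:4, 2:7] = 1.0  # 10 px blob
        img[10, 10] = 1.0
        img[10, 11] = 1.0  # 2 px blob
        cov = coverage_fraction(
            img, 0.5, min_particle_area_um2=5.0, pixel_size_um=1.0
        )
        assert cov.n_particles == 1
        assert cov.fraction == pytest.approx(10 / 400)

    def test_matches_flood_fill_oracle(self, rng):
        binary = rng.random((40, 40)) < 0.35
        img = binary.astype(float)
        min_area = 3.0
        cov = coverage_fraction(img, 0.5, min_particle_area_um2=min_area)
        areas = flood_fill_areas(binary)
        kept = [a for a in areas if a >= min_area]
        assert cov.n_particles == len(kept)
        assert cov.fraction == pytest.approx(sum(kept) / 1600)

    def test_monotone_in_min_particle_area(self, rng):
        binary = rng.random((40, 40)) < 0.3
        img = binary.astype(float)
        fracs = [
            coverage_fraction(img, 0.5, min_particle_area_um2=a).fraction
            for a in (0.0, 2.0, 5.0, 10.0, 50.0)
        ]
        assert all(f1 >= f2 for f1, f2 in zip(fracs, fracs[1:]))

    def test_roi_restricts_analysis(self):
        img = np.zeros((20, 20))
        img[0:10, 0:20] = 1.0
        roi = [(0.0, 0.0), (19.0, 0.0), (19.0, 9.0), (0.0, 9.0)]
        cov = coverage_fraction(img, 0.5, min_particle_area_um2=0.0, roi=roi)
        assert cov.fraction == pytest.approx(1.0)

    def test_zero_area_roi_rejected(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError, match="zero area"):
            coverage_fraction(img, 0.5, roi=[(0, 0), (0, 0), (0, 0)])


# ---------------------------------------------------------------------------
# Composed pipeline
# ---------------------------------------------------------------------------


class TestPipeline:
    def test_disordered_field_has_higher_entropy(self):
        cfg = FiberAnalysisConfig(pixel_size_um=0.5, n_bins=16, circular_fov=True)
        h = {}
        for kappa in (2.0, 50.0):
            vals = []
            for seed in range(3):
                stack, _ = render_fiber_image(
                    FiberFieldSpec(
                        image_size_px=(256, 256),
                        n_fibers=60,
                        kappa=kappa,
                        seed=seed,
                    )
                )
                vals.append(analyze_fiber_image(stack, cfg).entropy.H_nats)
            h[kappa] = np.mean(vals)
        assert h[2.0] > h[50.0]

    def test_bitwise_deterministic(self, small_fiber_spec):
        stack, _ = render_fiber_image(small_fiber_spec)
        cfg = FiberAnalysisConfig(pixel_size_um=0.5, n_bins=18)
        r1 = analyze_fiber_image(stack, cfg)
        r2 = analyze_fiber_image(stack, cfg)
        assert np.array_equal(r1.distribution.p, r2.distribution.p)
        assert r1.entropy.H_nats == r2.entropy.H_nats
        assert r1.coverage.fraction == r2.coverage.fraction

    def test_90_degree_rotation_preserves_entropy(self, small_fiber_spec):
        stack, _ = render_fiber_image(small_fiber_spec)
        cfg = FiberAnalysisConfig(pixel_size_um=0.5, n_bins=18)
        h1 = analyze_fiber_image(stack, cfg).entropy.H_nats
        rot = ImageStack(
            voxels=np.rot90(stack.voxels).copy(), pixel_size_um=0.5
        )
        h2 = analyze_fiber_image(rot, cfg).entropy.H_nats
        assert h2 == pytest.approx(h1, rel=0.02)

    def test_intermediates_returned_for_audit(self, small_fiber_spec):
        stack, _ = render_fiber_image(small_fiber_spec)
        res = analyze_fiber_image(
            stack, FiberAnalysisConfig(pixel_size_um=0.5, n_bins=18)
        )
        assert res.projected.shape == stack.voxels.shape
        assert res.ridge.values.shape == stack.voxels.shape
        assert res.mask.pixels.shape == stack.voxels.shape
        assert res.distribution.n_bins == 18
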