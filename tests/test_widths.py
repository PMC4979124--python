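"""Width estimation: profile sampling, peak-pair width, tube recovery."""

import numpy as np
import pytest

from hyphamorph import (
    DegenerateGeometryError,
    ImageStack,
    WidthParams,
    estimate_cell_width,
    sample_profile,
    tube_phantom,
    width_from_profile,
)
from hyphamorph.core import PAPER_DX_UM, VoxelGrid
from hyphamorph.widths import Profile

FWHM_FACTOR = 2 * np.sqrt(2 * np.log(2))


class TestSampleProfile:
    def test_constant_stack_constant_profile(self, flat_stack, small_grid):
        center = small_grid.extent_um / 2
        profile = sample_profile(flat_stack, center, np.array([1.0, 0, 0]), 2.0, 0.1)
        assert np.allclose(profile.intensities, 7.0)

    def test_lattice_points_return_voxel_values(self, small_grid):
        # integer ramp along x; sampling at voxel centres is interpolation-free
        arr = np.broadcast_to(
            np.arange(small_grid.nx, dtype=float), small_grid.shape
        ).copy()
        stack = ImageStack(intensities=arr, grid=small_grid)
        center = np.array([8 * small_grid.dx, 4 * small_grid.dy, 2 * small_grid.dz])
        profile = sample_profile(
            stack, center, np.array([1.0, 0, 0]), 2 * small_grid.dx, small_grid.dx
        )
        assert np.allclose(profile.intensities, [6, 7, 8, 9, 10])

    def test_linear_ramp_slope_matches_analytic(self, small_grid):
        arr = np.broadcast_to(
            np.arange(small_grid.nx, dtype=float), small_grid.shape
        ).copy()
        stack = ImageStack(intensities=arr, grid=small_grid)
        center = small_grid.extent_um / 2
        profile = sample_profile(stack, center, np.array([1.0, 0, 0]), 1.5, 0.05)
        slope = np.polyfit(profile.offsets, profile.intensities, 1)[0]
        assert slope == pytest.approx(1.0 / small_grid.dx, rel=1e-6)

    def test_out_of_volume_samples_dropped(self, flat_stack, small_grid):
        center = np.array([0.2, small_grid.extent_um[1] / 2, small_grid.extent_um[2] / 2])
        profile = sample_profile(flat_stack, center, np.array([1.0, 0, 0]), 3.0, 0.1)
        assert profile.offsets[0] >= -0.2 - 1e-9
        assert len(profile.offsets) < 61

    def test_zero_direction_rejected(self, flat_stack, small_grid):
        with pytest.raises(ValueError):
            sample_profile(
                flat_stack, small_grid.extent_um / 2, np.zeros(3), 1.0, 0.1
            )


def _gaussian_bump(x, mu, sigma):
    return np.exp(-((x - mu) ** 2) / (2 * sigma**2))


class TestWidthFromProfile:
    def test_symmetric_peak_pair_distance(self):
        x = np.arange(-5, 5.001, 0.05)
        y = 10 + 100 * (_gaussian_bump(x, -1.75, 0.2) + _gaussian_bump(x, 1.75, 0.2))
        width = width_from_profile(Profile(x, y), WidthParams())
        assert width == pytest.approx(3.5, abs=0.05)

    def test_fwhm_fallback_on_single_bump(self):
        sigma = 2.0 / FWHM_FACTOR  # FWHM exactly 2 µm
        x = np.arange(-5, 5.001, 0.05)
        y = 5 + 80 * _gaussian_bump(x, 0.0, sigma)
        width = width_from_profile(Profile(x, y), WidthParams())
        assert width == pytest.approx(2.0, abs=0.05)

    def test_flat_profile_fails(self):
        x = np.arange(-5, 5.001, 0.05)
        assert width_from_profile(Profile(x, np.full_like(x, 3.0)), WidthParams()) is None

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            width_from_profile(
                Profile(np.array([0.0, 1, 2]), np.array([0.0, 1, 0])), WidthParams()
            )

    def test_innermost_opposing_pair_chosen(self):
        # four walls (a neighbouring hypha): the innermost pair defines the cell
        x = np.arange(-5, 5.001, 0.05)
        y = (
            5
            + 90 * (_gaussian_bump(x, -1.5, 0.2) + _gaussian_bump(x, 1.5, 0.2))
            + 90 * (_gaussian_bump(x, -4.0, 0.2) + _gaussian_bump(x, 4.0, 0.2))
        )
        width = width_from_profile(Profile(x, y), WidthParams())
        assert width == pytest.approx(3.0, abs=0.05)


class TestEstimateCellWidth:
    def test_noiseless_tube_recovers_diameter(self, crop_grid):
        stack, skel, truth = tube_phantom(crop_grid, diameter_um=3.5)
        width = estimate_cell_width(stack, skel.cells[0], skel)
        assert width == pytest.approx(3.5, abs=0.25)

    def test_invariant_under_intensity_scaling(self, crop_grid):
        stack, skel, _ = tube_phantom(crop_grid, diameter_um=3.0)
        scaled = ImageStack(intensities=stack.intensities * 37.0, grid=crop_grid)
        w1 = estimate_cell_width(stack, skel.cells[0], skel)
        w2 = estimate_cell_width(scaled, skel.cells[0], skel)
        # invariance up to float32 rounding of the scaled intensities
        assert w1 == pytest.approx(w2, abs=1e-6)

    def test_monotone_in_true_diameter(self, crop_grid):
        estimates = []
        for diameter in (2.0, 3.0, 4.0, 5.0):
            stack, skel, _ = tube_phantom(crop_grid, diameter_um=diameter)
            estimates.append(estimate_cell_width(stack, skel.cells[0], skel))
        assert all(a < b for a, b in zip(estimates, estimates[1:]))

    def test_recovery_across_random_orientations(self, crop_grid):
        # oblique tubes within the lateral-dominant cone
        rng = np.random.default_rng(11)
        for diameter in (2.5, 3.5, 4.5):
            estimates = []
            for _ in range(5):
                phi = rng.uniform(0, 2 * np.pi)
                eta = rng.uniform(-0.2, 0.2)
                direction = (np.cos(phi), np.sin(phi), eta)
                stack, skel, _ = tube_phantom(
                    crop_grid, diameter_um=diameter, direction=direction
                )
                estimates.append(estimate_cell_width(stack, skel.cells[0], skel))
            err = abs(float(np.median(estimates)) - diameter)
            assert err <= max(0.25, 0.07 * diameter)

    def test_noisy_tube_within_wider_tolerance(self, crop_grid):
        # SNR ~5: noise sd = one fifth of the blurred wall amplitude
        estimates = []
        for seed in range(20):
            stack, skel, _ = tube_phantom(
                crop_grid,
                diameter_um=3.5,
                noise_model="gaussian",
                noise_param=30.0,
                seed=seed,
            )
            w = estimate_cell_width(stack, skel.cells[0], skel)
            if w is not None:
                estimates.append(w)
        assert len(estimates) >= 15
        assert float(np.mean(estimates)) == pytest.approx(3.5, abs=0.4)

    def test_empty_stack_fails_cleanly(self, crop_grid):
        stack, skel, _ = tube_phantom(crop_grid, diameter_um=3.0)
        background = ImageStack(
            intensities=np.full(crop_grid.shape, 10.0, dtype=np.float32), grid=crop_grid
        )
        assert estimate_cell_width(background, skel.cells[0], skel) is None

    def test_zero_length_cell_rejected(self, small_grid):
        from hyphamorph import CellSegment, HyphalSkeleton, SeptumNode

        skel = HyphalSkeleton(
            grid=small_grid,
            nodes=[
                SeptumNode(id="a", x=3, y=3, z=3),
                SeptumNode(id="b", x=3, y=3, z=3),
            ],
            cells=[CellSegment(id="c", node_a="a", node_b="b")],
        )
        stack = ImageStack(intensities=np.ones(small_grid.shape), grid=small_grid)
        with pytest.raises(DegenerateGeometryError):
            estimate_cell_width(stack, skel.cells[0], skel)


class TestWidthParams:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(end_margin_fraction=0.6),
            dict(background_quantile=1.5),
            dict(profile_step_um=0.0),
            dict(n_axial_samples=0),
        ],
    )
    def test_invalid_params_rejected(self, bad):
        from hyphamorph import ConfigurationError

        with pytest.raises(ConfigurationError):
            WidthParams(**bad)

    def test_dict_round_trip(self):
        params = WidthParams(n_axial_samples=7)
        assert WidthParams.from_dict(params.to_dict()) == params
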