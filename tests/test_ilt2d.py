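"""Kernel construction and the compressed non-negative Tikhonov inversion."""

import numpy as np
import pytest

from cartrelax.ilt2d import (
    InversionError,
    InversionGrid,
    InversionOptions,
    _solve_nnls_tikhonov,
    build_kernels,
    default_grid,
    invert,
    invert_1d,
)
from cartrelax.models import ParameterError
from cartrelax.synthetic import (
    AcquisitionScheme,
    DecayDataset,
    RelaxationComponent,
    default_scheme,
    simulate_ir_fidcpmg,
)


class TestKernels:
    grid = InversionGrid(
        T1_values=np.geomspace(1.0, 1e4, 8),
        T2_values=np.array([0.02, 0.1, 1.0, 80.0, 500.0]),
        gaussian_boundary=1.0,
    )

    def test_saturation_recovery_saturates_to_one(self):
        scheme = AcquisitionScheme(
            recovery_times=(1.0, 1e7), recovery_mode="saturation",
            fid_times=(20.0,), n_echoes=2,
        )
        K1, _ = build_kernels(scheme, self.grid)
        assert np.allclose(K1[-1], 1.0, atol=1e-6)
        assert np.all((K1 >= -1.0) & (K1 <= 1.0))

    def test_gaussian_cell_at_t_equal_T2(self):
        scheme = AcquisitionScheme(
            recovery_times=(1.0, 100.0), fid_times=(20.0,), n_echoes=0,
        )
        _, K2 = build_kernels(scheme, self.grid)
        # T2 = 0.02 ms < boundary: Gaussian kernel, t = 20 us = T2
        assert K2[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_exponential_cell_at_t_equal_T2(self):
        scheme = AcquisitionScheme(
            recovery_times=(1.0, 100.0), fid_times=(20.0,),
            echo_time=80_000.0, n_echoes=1,
        )
        _, K2 = build_kernels(scheme, self.grid)
        # T2 = 80 ms > boundary: exponential kernel at t = 80 ms
        assert K2[1, 3] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_acquisition_inside_dead_time_rejected(self):
        scheme = AcquisitionScheme(
            recovery_times=(1.0, 100.0), fid_times=(20.0,), n_echoes=1,
        )
        with pytest.raises(ParameterError):
            build_kernels(scheme, self.grid, acquisition_times=np.array([5.0, 20.0]))


def _two_pool_dataset(scheme):
    return simulate_ir_fidcpmg(
        [
            RelaxationComponent(T1=200.0, T2=30.0, amplitude=5.0),
            RelaxationComponent(T1=500.0, T2=0.03, amplitude=1.0, decay_shape="gaussian"),
        ],
        scheme,
    )


class TestInvert:
    def test_noiseless_single_component_concentrates(self, small_scheme, single_component):
        ds = simulate_ir_fidcpmg(single_component, small_scheme)
        rmap = invert(ds, default_grid(48, 48), InversionOptions())
        g = rmap.grid
        i, j = np.unravel_index(np.argmax(rmap.amplitude), rmap.amplitude.shape)
        # peak cell within one grid cell of the true (T1, T2)
        assert abs(np.log(g.T1_values[i] / 100.0)) <= np.log(g.T1_values[1] / g.T1_values[0]) * 1.5
        assert abs(np.log(g.T2_values[j] / 10.0)) <= np.log(g.T2_values[1] / g.T2_values[0]) * 1.5
        neighborhood = rmap.amplitude[i - 1 : i + 2, j - 1 : j + 2].sum()
        assert neighborhood >= 0.9 * rmap.total_intensity

    def test_compressed_solver_matches_uncompressed_oracle(self):
        """SVD-compressed solve vs brute-force full-kernel NNLS, 16x16 grid."""
        grid = InversionGrid(
            T1_values=np.geomspace(1.0, 1e4, 16),
            T2_values=np.geomspace(5e-3, 1e3, 16),
        )
        scheme = default_scheme(n_recovery=12, n_echoes=60, fid_spacing=10.0)
        ds = _two_pool_dataset(scheme)
        alpha = 1e-3
        K1, K2 = build_kernels(scheme, grid, ds.acquisition_times)
        A = np.kron(K2, K1)
        f_oracle = _solve_nnls_tikhonov(A, ds.signal.ravel(order="F"), alpha)
        rmap = invert(
            ds, grid, InversionOptions(alpha_method="fixed", alpha=alpha, svd_rank=64)
        )
        f = rmap.amplitude.ravel(order="F")
        assert np.linalg.norm(f - f_oracle) <= 1e-6 * np.linalg.norm(f_oracle)

    def test_alpha_sweep_tikhonov_tradeoff(self):
        grid = InversionGrid(
            T1_values=np.geomspace(1.0, 1e4, 16),
            T2_values=np.geomspace(5e-3, 1e3, 16),
        )
        scheme = default_scheme(n_recovery=12, n_echoes=60, fid_spacing=10.0)
        ds = _two_pool_dataset(scheme)
        residuals, solutions = [], []
        for alpha in [1e-4, 1e-2, 1e0, 1e2]:
            rmap = invert(ds, grid, InversionOptions(alpha_method="fixed", alpha=alpha))
            residuals.append(rmap.residual_norm)
            solutions.append(rmap.solution_norm)
        assert np.all(np.diff(residuals) >= -1e-9)
        assert np.all(np.diff(solutions) <= 1e-9)

    def test_brd_alpha_selection_runs(self):
        grid = InversionGrid(
            T1_values=np.geomspace(1.0, 1e4, 16),
            T2_values=np.geomspace(5e-3, 1e3, 16),
        )
        scheme = default_scheme(
            n_recovery=12, n_echoes=60, fid_spacing=10.0, noise_sigma=0.01, seed=1
        )
        ds = _two_pool_dataset(scheme)
        rmap = invert(ds, grid, InversionOptions(alpha_method="brd"))
        assert rmap.alpha > 0
        assert np.all(rmap.amplitude >= 0)

    def test_conservation_of_total_intensity(self, d1_map):
        # total map mass vs extrapolated fully-recovered t=0 signal (1062)
        assert d1_map.total_intensity == pytest.approx(1062.0, rel=0.05)

    def test_all_zero_data_rejected(self, small_scheme):
        ds = simulate_ir_fidcpmg(
            [RelaxationComponent(T1=100.0, T2=10.0, amplitude=1.0)], small_scheme
        )
        zero = DecayDataset(
            scheme=small_scheme,
            signal=np.zeros_like(ds.signal),
            acquisition_times=ds.acquisition_times,
        )
        with pytest.raises(InversionError):
            invert(zero)

    def test_rank_larger_than_data_rejected(self, small_scheme, single_component):
        ds = simulate_ir_fidcpmg(single_component, small_scheme)
        with pytest.raises(InversionError):
            invert(ds, default_grid(16, 16), InversionOptions(svd_rank=10_000))


class TestInvert1d:
    axis = np.geomspace(1.0, 1e4, 48)

    def test_single_exponential_recovers_peak(self):
        t = np.geomspace(1.0, 5000.0, 40)
        y = 1.0 - np.exp(-t / 200.0)
        f, meta = invert_1d(t, y, "T1", self.axis)
        peak = self.axis[np.argmax(f)]
        step = self.axis[1] / self.axis[0]
        assert abs(np.log(peak / 200.0)) <= 1.5 * np.log(step)
        assert meta["residual_norm"] < 1e-3

    def test_two_separated_decades_resolved(self):
        t = np.geomspace(0.01, 500.0, 200)  # ms-domain T2 decay (us input)
        y = np.exp(-t / 5.0) + np.exp(-t / 50.0)
        f, _ = invert_1d(t * 1000.0, y, "T2", np.geomspace(0.1, 500.0, 64))
        # count local maxima of the distribution
        peaks = np.flatnonzero((f[1:-1] > f[:-2]) & (f[1:-1] >= f[2:]) & (f[1:-1] > 1e-3 * f.max()))
        assert len(peaks) == 2

    def test_merged_components_never_exceed_component_count(self):
        t = np.geomspace(0.01, 500.0, 200)
        y = np.exp(-t / 20.0) + np.exp(-t / 30.0)  # closer than factor 2
        rng = np.random.default_rng(0)
        y = y + rng.normal(0, y.max() / 100, y.size)  # SNR 100
        f, _ = invert_1d(t * 1000.0, y, "T2", np.geomspace(0.1, 500.0, 64))
        peaks = np.flatnonzero(
            (f[1:-1] > f[:-2]) & (f[1:-1] >= f[2:]) & (f[1:-1] > 0.05 * f.max())
        )
        assert 1 <= len(peaks) <= 2

    def test_zero_data_rejected(self):
        with pytest.raises(InversionError):
            invert_1d(np.geomspace(1, 100, 10), np.zeros(10), "T1", self.axis)
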