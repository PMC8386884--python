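"""Regularized 1D/2D inverse Laplace transform for T1-T2 correlation maps.

A recovery-by-decay experiment measures
``M[m, n] = sum_ij K1[m, i] F[i, j] K2[n, j] + noise`` where K1 encodes
longitudinal recovery over a log grid of T1 and K2 the acquisition decay
over a log grid of T2.  The acquisition kernel is mixed: T2 values below a
boundary (solid-like pool, tens of microseconds) decay as a Gaussian
``exp(-(t/T2)^2)``, longer values (liquid-like pool) exponentially.  The
inversion solves the Tikhonov-regularized non-negative least-squares
problem

    min_{F >= 0}  || K1 F K2^T - M ||^2 + alpha ||F||^2

after SVD compression of both kernels, the standard approach for 2D
relaxation-map inversion.  The regularization weight alpha is chosen by
generalized cross-validation (default), the Butler-Reed-Dawson iteration,
or fixed by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import nnls

from .models import ParameterError
from .synthetic import AcquisitionScheme, DecayDataset

__all__ = [
    "InversionGrid",
    "InversionOptions",
    "RelaxationMap",
    "default_grid",
    "build_kernels",
    "invert",
    "invert_1d",
]


class InversionError(RuntimeError):
    """Raised when the inversion cannot be carried out."""


@dataclass(frozen=True)
class InversionGrid:
    """Log-spaced T1/T2 grids with the Gaussian/exponential T2 boundary."""

    T1_values: np.ndarray  # ms
    T2_values: np.ndarray  # ms
    gaussian_boundary: float = 1.0  # ms; T2 below this uses the Gaussian kernel

    def __post_init__(self) -> None:
        t1 = np.asarray(self.T1_values, dtype=float)
        t2 = np.asarray(self.T2_values, dtype=float)
        for name, axis in (("T1", t1), ("T2", t2)):
            if axis.size < 2 or np.any(axis <= 0) or np.any(np.diff(axis) <= 0):
                raise ParameterError(f"{name} grid must be positive, strictly increasing")
        if not t2[0] <= self.gaussian_boundary <= t2[-1]:
            raise ParameterError("gaussian_boundary must lie within the T2 range")
        object.__setattr__(self, "T1_values", t1)
        object.__setattr__(self, "T2_values", t2)


def default_grid(n_T1: int = 64, n_T2: int = 64) -> InversionGrid:
    """T1 in [1 ms, 10 s], T2 in [5 us, 1 s], Gaussian boundary at 1 ms."""
    return InversionGrid(
        T1_values=np.geomspace(1.0, 1e4, n_T1),
        T2_values=np.geomspace(5e-3, 1e3, n_T2),
        gaussian_boundary=1.0,
    )


@dataclass(frozen=True)
class InversionOptions:
    """Solver options: alpha selection, compression rank, tolerances."""

    alpha_method: Literal["gcv", "brd", "fixed"] = "gcv"
    alpha: float | None = None
    svd_rank: int = 16
    alpha_floor_rel: float = 1e-10  # relative to largest squared singular value
    max_brd_iter: int = 20

    def __post_init__(self) -> None:
        if self.alpha_method not in ("gcv", "brd", "fixed"):
            raise ParameterError(f"unknown alpha method {self.alpha_method!r}")
        if self.alpha_method == "fixed" and (self.alpha is None or self.alpha < 0):
            raise ParameterError("fixed alpha_method requires alpha >= 0")
        if self.svd_rank < 1:
            raise ParameterError("svd_rank must be >= 1")


@dataclass(frozen=True)
class RelaxationMap:
    """Non-negative amplitude map over the (T1, T2) log grid."""

    grid: InversionGrid
    amplitude: np.ndarray  # (|T1|, |T2|), >= 0
    alpha: float
    residual_norm: float
    solution_norm: float

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude, dtype=float)
        if amp.shape != (self.grid.T1_values.size, self.grid.T2_values.size):
            raise ParameterError("amplitude shape inconsistent with grid")
        if np.any(amp < -1e-12) or not np.all(np.isfinite(amp)):
            raise ParameterError("amplitude must be non-negative and finite")
        object.__setattr__(self, "amplitude", np.clip(amp, 0.0, None))

    @property
    def total_intensity(self) -> float:
        return float(self.amplitude.sum())


def build_kernels(
    scheme: AcquisitionScheme,
    grid: InversionGrid,
    acquisition_times: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Recovery kernel K1 (times x T1) and acquisition kernel K2 (times x T2).

    K1 follows the scheme's recovery mode and inversion efficiency; K2 uses
    the Gaussian decay for grid T2 below the boundary and the exponential
    decay above it.  Raises if any acquisition time falls inside the dead
    time, where no sample can exist.
    """
    t_rec = np.asarray(scheme.recovery_times, dtype=float)  # ms
    t_acq = (
        scheme.acquisition_times if acquisition_times is None
        else np.asarray(acquisition_times, dtype=float)
    )  # us
    if np.any(t_acq < scheme.dead_time):
        raise ParameterError("acquisition times inside the dead time are not observable")

    T1 = grid.T1_values
    if scheme.recovery_mode == "inversion":
        K1 = 1.0 - 2.0 * scheme.inversion_efficiency * np.exp(-t_rec[:, None] / T1[None, :])
    else:
        K1 = 1.0 - np.exp(-t_rec[:, None] / T1[None, :])

    T2 = grid.T2_values
    t_ms = t_acq[:, None] / 1000.0
    gaussian = T2[None, :] < grid.gaussian_boundary
    K2 = np.where(
        gaussian,
        np.exp(-((t_ms / T2[None, :]) ** 2)),
        np.exp(-t_ms / T2[None, :]),
    )
    return K1, K2


def _truncated_svd(K: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (U_r, S_r V_r^T): projection basis and compressed kernel."""
    U, s, Vt = np.linalg.svd(K, full_matrices=False)
    r = min(rank, np.count_nonzero(s > s[0] * 1e-14))
    return U[:, :r], s[:r, None] * Vt[:r]


def _gcv_alpha(s: np.ndarray, b: np.ndarray, floor: float) -> float:
    """Generalized cross-validation on the SVD-diagonalized Tikhonov problem.

    ``s`` are singular values of the (separable) forward operator and ``b``
    the data coefficients in the corresponding left singular basis.  GCV is
    evaluated on the compressed data only: the projection residual left
    behind by kernel compression is alpha-independent model error, and
    folding it into the numerator would bias alpha upward.
    """
    s2 = s**2
    b2 = b**2
    n = b.size

    def gcv(log_alpha: float) -> float:
        a = 10.0**log_alpha
        filt = a / (s2 + a)
        resid = np.sum((filt * np.abs(b)) ** 2)
        denom = (n - np.sum(s2 / (s2 + a))) ** 2
        return resid / denom

    grid = np.linspace(np.log10(floor), np.log10(s2.max() * 1e2), 120)
    values = [gcv(g) for g in grid]
    return float(10.0 ** grid[int(np.argmin(values))])


def _solve_nnls_tikhonov(A: np.ndarray, b: np.ndarray, alpha: float) -> np.ndarray:
    """min_{f>=0} ||A f - b||^2 + alpha ||f||^2 via augmented NNLS."""
    n = A.shape[1]
    if alpha > 0:
        A_aug = np.vstack([A, np.sqrt(alpha) * np.eye(n)])
        b_aug = np.concatenate([b, np.zeros(n)])
    else:
        A_aug, b_aug = A, b
    f, _ = nnls(A_aug, b_aug)
    return f


def invert(
    dataset: DecayDataset,
    grid: InversionGrid | None = None,
    options: InversionOptions | None = None,
) -> RelaxationMap:
    """Invert an FID-CPMG recovery dataset into a T1-T2 relaxation map.

    Both kernels are SVD-compressed to ``options.svd_rank``; the data are
    projected into the compressed basis and the non-negative Tikhonov
    problem is solved there.  For noiseless single-component data the
    recovered mass concentrates within one grid cell of the true (T1, T2).
    """
    grid = grid or default_grid()
    options = options or InversionOptions()
    M = dataset.signal
    if not np.any(M):
        raise InversionError("all-zero data cannot be inverted")
    if options.svd_rank > max(M.shape):
        raise InversionError(
            f"svd_rank {options.svd_rank} exceeds data dimensions {M.shape}"
        )
    K1, K2 = build_kernels(dataset.scheme, grid, dataset.acquisition_times)

    U1, K1c = _truncated_svd(K1, options.svd_rank)
    U2, K2c = _truncated_svd(K2, options.svd_rank)
    Mc = U1.T @ M @ U2  # compressed data

    # column-major vec: vec(K1c F K2c^T) = kron(K2c, K1c) vec(F)
    A = np.kron(K2c, K1c)
    b = Mc.ravel(order="F")

    s = np.linalg.svd(A, compute_uv=False)
    floor = options.alpha_floor_rel * s[0] ** 2

    if options.alpha_method == "fixed":
        alpha = float(options.alpha)
    elif options.alpha_method == "gcv":
        # data coefficients in the left singular basis of A
        U, s_full, _ = np.linalg.svd(A, full_matrices=False)
        alpha = _gcv_alpha(s_full, U.T @ b, floor)
    else:  # Butler-Reed-Dawson iteration on the compressed residual
        alpha = float(s[0] ** 2 * 1e-3)
        for _ in range(options.max_brd_iter):
            f = _solve_nnls_tikhonov(A, b, alpha)
            c = (b - A @ f) / alpha
            c_norm = np.linalg.norm(c)
            if c_norm == 0:
                alpha = floor
                break
            new_alpha = max(np.sqrt(b.size) / c_norm, floor)
            if abs(new_alpha - alpha) <= 0.05 * alpha:
                alpha = new_alpha
                break
            alpha = new_alpha
        else:
            raise InversionError(
                f"Butler-Reed-Dawson iteration did not converge (last alpha {alpha:.3g})"
            )
    alpha = max(alpha, floor)

    f = _solve_nnls_tikhonov(A, b, alpha)
    F = f.reshape(grid.T1_values.size, grid.T2_values.size, order="F")
    residual = float(np.linalg.norm(K1 @ F @ K2.T - M))
    return RelaxationMap(
        grid=grid,
        amplitude=F,
        alpha=alpha,
        residual_norm=residual,
        solution_norm=float(np.linalg.norm(F)),
    )


def invert_1d(
    times: np.ndarray,
    values: np.ndarray,
    kind: Literal["T1", "T2"],
    grid_axis: np.ndarray,
    scheme: AcquisitionScheme | None = None,
    gaussian_boundary: float = 1.0,
    options: InversionOptions | None = None,
) -> tuple[np.ndarray, dict]:
    """1D inversion of a single recovery (T1) or decay (T2) curve.

    ``times`` are in ms for kind="T1" (recovery) and us for kind="T2"
    (acquisition); ``grid_axis`` is the log-spaced relaxation-time grid in
    ms.  Returns the non-negative amplitude distribution over the grid and
    a metadata dict (alpha, residual_norm, solution_norm).
    """
    options = options or InversionOptions()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    grid_axis = np.asarray(grid_axis, dtype=float)
    if times.size != values.size:
        raise ParameterError("times and values must have equal length")
    if not np.any(values):
        raise InversionError("all-zero data cannot be inverted")

    if kind == "T1":
        mode = scheme.recovery_mode if scheme is not None else "saturation"
        f_inv = scheme.inversion_efficiency if scheme is not None else 1.0
        if mode == "inversion":
            K = 1.0 - 2.0 * f_inv * np.exp(-times[:, None] / grid_axis[None, :])
        else:
            K = 1.0 - np.exp(-times[:, None] / grid_axis[None, :])
    elif kind == "T2":
        t_ms = times[:, None] / 1000.0
        gaussian = grid_axis[None, :] < gaussian_boundary
        K = np.where(
            gaussian,
            np.exp(-((t_ms / grid_axis[None, :]) ** 2)),
            np.exp(-t_ms / grid_axis[None, :]),
        )
    else:
        raise ParameterError(f"unknown inversion kind {kind!r}")

    U, Kc = _truncated_svd(K, options.svd_rank)
    b = U.T @ values
    s = np.linalg.svd(Kc, compute_uv=False)
    floor = options.alpha_floor_rel * s[0] ** 2
    if options.alpha_method == "fixed":
        alpha = float(options.alpha)
    else:
        Uc, s_full, _ = np.linalg.svd(Kc, full_matrices=False)
        alpha = _gcv_alpha(s_full, Uc.T @ b, floor)
    alpha = max(alpha, floor)
    f = _solve_nnls_tikhonov(Kc, b, alpha)
    meta = {
        "alpha": alpha,
        "residual_norm": float(np.linalg.norm(K @ f - values)),
        "solution_norm": float(np.linalg.norm(f)),
    }
    return f, meta
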