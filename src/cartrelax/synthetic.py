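"""Synthetic relaxation datasets with known ground truth.

Every analysis stage of the package can be exercised without instrument
data: this module generates FID-CPMG inversion-recovery signal matrices
from a list of relaxation components, field-cycling T1 dispersion
profiles with quadrupolar dips, single recovery curves, and depth-resolved
recovery stacks mimicking a single-sided scan of a drying sample.

The default acquisition scheme mirrors a benchtop T1-T2 correlation
experiment: 32 logarithmically spaced recovery times from 1 to 5000 ms,
an FID sampled every microsecond from the 15 us receiver dead time up to
the first echo, then a CPMG train with 250 us echo spacing and 2000
echoes (one point per echo top).  Noise is additive Gaussian on a single
real channel, reproducible from the scheme seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .models import CouplingConstant, ParameterError, RmtdModel, SpectralDensity, r1_dipolar
from .dispersion import DispersionProfile

__all__ = [
    "RelaxationComponent",
    "AcquisitionScheme",
    "DecayDataset",
    "DipModel",
    "default_scheme",
    "d1_components",
    "simulate_ir_fidcpmg",
    "simulate_dispersion",
    "simulate_recovery_curve",
    "simulate_depth_profile",
    "DepthProfileStack",
]


@dataclass(frozen=True)
class RelaxationComponent:
    """One relaxation pool: (T1, T2, amplitude) plus its decay shape.

    ``decay_shape`` is "exponential" for liquid-like pools and "gaussian"
    (``exp(-(t/T2)^2)``) for the solid-like pool of strongly coupled
    protons with T2 of a few tens of microseconds.
    """

    T1: float  # ms
    T2: float  # ms
    amplitude: float
    decay_shape: Literal["exponential", "gaussian"] = "exponential"

    def __post_init__(self) -> None:
        if self.T1 <= 0 or self.T2 <= 0 or self.amplitude <= 0:
            raise ParameterError("T1, T2 and amplitude must all be > 0")
        if self.decay_shape not in ("exponential", "gaussian"):
            raise ParameterError(f"unknown decay shape {self.decay_shape!r}")

    def recovery_factor(self, t_rec_ms: np.ndarray, mode: str, f_inv: float) -> np.ndarray:
        t = np.asarray(t_rec_ms, dtype=float)
        if mode == "inversion":
            return 1.0 - 2.0 * f_inv * np.exp(-t / self.T1)
        return 1.0 - np.exp(-t / self.T1)

    def decay_factor(self, t_acq_us: np.ndarray) -> np.ndarray:
        t_ms = np.asarray(t_acq_us, dtype=float) / 1000.0
        if self.decay_shape == "gaussian":
            return np.exp(-((t_ms / self.T2) ** 2))
        return np.exp(-t_ms / self.T2)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Timing and noise parameters of an FID-CPMG inversion-recovery run."""

    recovery_times: tuple  # ms, strictly increasing
    recovery_mode: Literal["inversion", "saturation"] = "inversion"
    inversion_efficiency: float = 1.0
    fid_times: tuple = ()  # us, samples before the first echo
    echo_time: float = 250.0  # us
    n_echoes: int = 2000
    dead_time: float = 15.0  # us
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        rec = np.asarray(self.recovery_times, dtype=float)
        if rec.size == 0 or np.any(np.diff(rec) <= 0):
            raise ParameterError("recovery_times must be strictly increasing")
        if self.recovery_mode not in ("inversion", "saturation"):
            raise ParameterError(f"unknown recovery mode {self.recovery_mode!r}")
        if not 0.0 < self.inversion_efficiency <= 1.0:
            raise ParameterError("inversion efficiency must lie in (0, 1]")
        if self.echo_time <= 0:
            raise ParameterError("echo_time must be > 0")
        if self.n_echoes < 0:
            raise ParameterError("n_echoes must be >= 0")
        fid = np.asarray(self.fid_times, dtype=float)
        if fid.size and (np.any(np.diff(fid) <= 0) or fid[0] <= self.dead_time):
            raise ParameterError(
                "fid_times must be strictly increasing and start after dead_time"
            )
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")

    @property
    def acquisition_times(self) -> np.ndarray:
        """Concatenated FID sample times and CPMG echo-top times, in us."""
        echoes = self.echo_time * np.arange(1, self.n_echoes + 1)
        return np.concatenate([np.asarray(self.fid_times, dtype=float), echoes])

    @property
    def channel_labels(self) -> np.ndarray:
        return np.array(
            ["fid"] * len(self.fid_times) + ["echo"] * self.n_echoes, dtype=object
        )


def default_scheme(
    n_recovery: int = 32,
    recovery_min: float = 1.0,
    recovery_max: float = 5000.0,
    echo_time: float = 250.0,
    n_echoes: int = 2000,
    dead_time: float = 15.0,
    fid_spacing: float = 1.0,
    noise_sigma: float = 0.0,
    recovery_mode: str = "inversion",
    seed: int = 0,
) -> AcquisitionScheme:
    """Scheme of the benchtop T1-T2 experiment (32 recovery steps, 1-5000 ms)."""
    recovery = np.geomspace(recovery_min, recovery_max, n_recovery)
    fid = np.arange(dead_time + fid_spacing, echo_time, fid_spacing)
    return AcquisitionScheme(
        recovery_times=tuple(recovery),
        recovery_mode=recovery_mode,
        fid_times=tuple(fid),
        echo_time=echo_time,
        n_echoes=n_echoes,
        dead_time=dead_time,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def d1_components() -> list[RelaxationComponent]:
    """Two-pool composition of a fully hydrated cartilage sample.

    Main liquid-like peak T1 = 635 ms, T2 = 80.8 ms, amplitude 928;
    solid-like secondary peak T1 = 666 ms, T2 = 30 us (Gaussian decay),
    amplitude 134; total extrapolated signal 1062.
    """
    return [
        RelaxationComponent(T1=635.0, T2=80.8, amplitude=928.0, decay_shape="exponential"),
        RelaxationComponent(T1=666.0, T2=0.03, amplitude=134.0, decay_shape="gaussian"),
    ]


@dataclass(frozen=True)
class DecayDataset:
    """Signal matrix over (recovery time, acquisition time) plus its scheme."""

    scheme: AcquisitionScheme
    signal: np.ndarray  # (n_recovery, n_acquisition)
    acquisition_times: np.ndarray  # us
    channel_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        acq = np.asarray(self.acquisition_times, dtype=float)
        if sig.shape != (len(self.scheme.recovery_times), acq.size):
            raise ParameterError(
                f"signal shape {sig.shape} inconsistent with scheme "
                f"({len(self.scheme.recovery_times)} x {acq.size})"
            )
        if np.any(np.diff(acq) <= 0):
            raise ParameterError("acquisition_times must be strictly increasing")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "acquisition_times", acq)


@dataclass(frozen=True)
class DipModel:
    """Quadrupolar relaxation dips as Lorentzians added to R1(f).

    Each dip contributes ``amplitude * width^2 / ((f - center)^2 + width^2)``
    (peak height ``amplitude`` in 1/s, half width at half maximum ``width``
    in MHz).  Defaults place the three 1H-14N level-crossing dips at 0.6,
    2.3 and 2.9 MHz.
    """

    centers: tuple = (0.6, 2.3, 2.9)  # MHz
    widths: tuple = (0.08, 0.1, 0.1)  # MHz, HWHM
    amplitudes: tuple = (1.0, 1.0, 1.0)  # 1/s peak heights

    def __post_init__(self) -> None:
        c, w, a = map(np.asarray, (self.centers, self.widths, self.amplitudes))
        if not (c.size == w.size == a.size):
            raise ParameterError("centers, widths, amplitudes must have equal length")
        if np.any(c <= 0) or np.any(w <= 0) or np.any(a < 0):
            raise ParameterError("dip parameters must be positive")

    def evaluate(self, freqs_MHz: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs_MHz, dtype=float)
        total = np.zeros_like(f)
        for c, w, a in zip(self.centers, self.widths, self.amplitudes):
            total += a * w**2 / ((f - c) ** 2 + w**2)
        return total


def simulate_ir_fidcpmg(
    components: Sequence[RelaxationComponent], scheme: AcquisitionScheme
) -> DecayDataset:
    """Simulate an FID-CPMG inversion/saturation-recovery signal matrix.

    ``signal(t_rec, t_acq) = sum_j A_j rec_j(t_rec) dec_j(t_acq) + noise``
    with the recovery factor ``1 - 2 f_inv exp(-t_rec/T1)`` (inversion) or
    ``1 - exp(-t_rec/T1)`` (saturation) and the exponential or Gaussian
    acquisition decay of each component.  Samples inside the dead time are
    never generated (the scheme's FID grid starts after it).
    """
    if not components:
        raise ParameterError("need at least one relaxation component")
    t_rec = np.asarray(scheme.recovery_times, dtype=float)
    t_acq = scheme.acquisition_times
    signal = np.zeros((t_rec.size, t_acq.size))
    for comp in components:
        rec = comp.recovery_factor(t_rec, scheme.recovery_mode, scheme.inversion_efficiency)
        dec = comp.decay_factor(t_acq)
        signal += comp.amplitude * np.outer(rec, dec)
    if scheme.noise_sigma > 0:
        rng = np.random.default_rng(scheme.seed)
        signal = signal + rng.normal(0.0, scheme.noise_sigma, signal.shape)
    return DecayDataset(
        scheme=scheme,
        signal=signal,
        acquisition_times=t_acq,
        channel_labels=scheme.channel_labels,
    )


def simulate_dispersion(
    rmtd: RmtdModel | None,
    coupling: CouplingConstant,
    dips: DipModel | None,
    bulk_rate: float,
    freqs: np.ndarray,
    noise_rel: float = 0.0,
    seed: int = 0,
    nucleus: str = "1H",
) -> DispersionProfile:
    """Simulate a field-cycling R1 dispersion profile.

    ``R1(f) = r1_dipolar(I_rmtd, const, 2 pi f) + bulk_rate + dips(f)``,
    with optional multiplicative Gaussian noise of relative width
    ``noise_rel``.  ``rmtd=None`` drops the dispersive term, ``dips=None``
    drops the quadrupolar dips.
    """
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ParameterError("frequencies must be positive (MHz)")
    if noise_rel < 0:
        raise ParameterError("noise_rel must be >= 0")
    if bulk_rate < 0:
        raise ParameterError("bulk_rate must be >= 0")
    r1 = np.full(freqs.shape, float(bulk_rate))
    if rmtd is not None:
        omega = 2.0 * np.pi * freqs * 1e6
        r1 = r1 + r1_dipolar(SpectralDensity.rmtd(rmtd), coupling, omega)
    if dips is not None:
        r1 = r1 + dips.evaluate(freqs)
    err = np.abs(r1) * noise_rel
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        r1 = r1 * (1.0 + rng.normal(0.0, noise_rel, freqs.shape))
    return DispersionProfile(frequencies=freqs, R1=r1, R1_err=err, nucleus=nucleus)


def simulate_recovery_curve(
    T1: float,
    scheme: AcquisitionScheme | None = None,
    seed: int | None = None,
    amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single magnetization recovery curve M(t_rec) for a monoexponential T1.

    Returns ``(t_rec in ms, M)``.  Uses the scheme's recovery grid, mode
    and noise level; ``seed`` overrides the scheme seed when given.
    """
    if T1 <= 0:
        raise ParameterError("T1 must be > 0")
    if scheme is None:
        scheme = default_scheme(recovery_mode="saturation")
    t = np.asarray(scheme.recovery_times, dtype=float)
    comp = RelaxationComponent(T1=T1, T2=1.0, amplitude=amplitude)
    m = amplitude * comp.recovery_factor(t, scheme.recovery_mode, scheme.inversion_efficiency)
    if scheme.noise_sigma > 0:
        rng = np.random.default_rng(scheme.seed if seed is None else seed)
        m = m + rng.normal(0.0, scheme.noise_sigma, m.shape)
    return t, m


@dataclass(frozen=True)
class DepthProfileStack:
    """Recovery curves per depth slice and drying time step.

    ``signal[i, j, k]`` is the magnetization at drying step i, depth j and
    recovery time k.  Slices above the (shrinking) sample height contain
    noise only.
    """

    depths: np.ndarray  # mm, monotone increasing
    heights: np.ndarray  # mm, sample height per time step
    recovery_times: np.ndarray  # ms
    signal: np.ndarray  # (n_steps, n_depths, n_recovery)
    T1_true: np.ndarray  # (n_steps, n_depths); nan outside the sample


def simulate_depth_profile(
    T1_map: np.ndarray,
    heights: Sequence[float],
    depths: Sequence[float],
    scheme: AcquisitionScheme | None = None,
    amplitude: float = 1.0,
    seed: int = 0,
) -> DepthProfileStack:
    """Emulate a single-sided depth scan of a drying sample.

    ``T1_map[i, j]`` gives the local T1 (ms) at drying step i and depth
    ``depths[j]``; slices deeper than ``heights[i]`` are outside the
    shrunken sample and return pure noise.  Saturation recovery is used,
    matching single-sided profiling practice.
    """
    depths = np.asarray(depths, dtype=float)
    heights = np.asarray(heights, dtype=float)
    T1_map = np.asarray(T1_map, dtype=float)
    if depths.size == 0 or heights.size == 0:
        raise ParameterError("depth grid and heights must be non-empty")
    if np.any(np.diff(depths) <= 0):
        raise ParameterError("depth grid must be strictly increasing")
    if T1_map.shape != (heights.size, depths.size):
        raise ParameterError("T1_map must have shape (n_steps, n_depths)")
    if scheme is None:
        scheme = default_scheme(
            n_recovery=20, recovery_max=2000.0, recovery_mode="saturation"
        )
    t = np.asarray(scheme.recovery_times, dtype=float)
    rng = np.random.default_rng(seed)
    signal = np.zeros((heights.size, depths.size, t.size))
    truth = np.full((heights.size, depths.size), np.nan)
    for i, h in enumerate(heights):
        for j, d in enumerate(depths):
            if d <= h:
                T1 = T1_map[i, j]
                if T1 <= 0:
                    raise ParameterError("T1 values inside the sample must be > 0")
                signal[i, j] = amplitude * (1.0 - np.exp(-t / T1))
                truth[i, j] = T1
            # outside the sample: noise only
            if scheme.noise_sigma > 0:
                signal[i, j] += rng.normal(0.0, scheme.noise_sigma, t.size)
    return DepthProfileStack(
        depths=depths, heights=heights, recovery_times=t, signal=signal, T1_true=truth
    )
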