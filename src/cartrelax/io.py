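"""CSV/JSON serialization of datasets, profiles, maps and run configs.

Conventions: frequencies in MHz, relaxation times in ms, acquisition
times in us, rates in 1/s.  Decay datasets are stored as long-format CSV
(``recovery_ms, acq_us, signal, channel``) with a JSON sidecar holding
the acquisition scheme; relaxation maps as a CSV trio (T1 axis, T2 axis,
amplitude matrix) plus JSON metadata.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersion import DispersionProfile
from .ilt2d import InversionGrid, InversionOptions, RelaxationMap
from .models import ParameterError
from .synthetic import AcquisitionScheme, DecayDataset

__all__ = [
    "RunConfig",
    "write_decay_csv",
    "read_decay_csv",
    "write_dispersion_csv",
    "read_dispersion_csv",
    "write_map",
    "read_map",
]


class ParseError(ValueError):
    """Raised when an input file is malformed."""


def _scheme_to_dict(scheme: AcquisitionScheme) -> dict:
    d = dataclasses.asdict(scheme)
    d["recovery_times"] = list(scheme.recovery_times)
    d["fid_times"] = list(scheme.fid_times)
    return d


def _scheme_from_dict(d: dict) -> AcquisitionScheme:
    return AcquisitionScheme(
        recovery_times=tuple(d["recovery_times"]),
        recovery_mode=d["recovery_mode"],
        inversion_efficiency=d["inversion_efficiency"],
        fid_times=tuple(d["fid_times"]),
        echo_time=d["echo_time"],
        n_echoes=d["n_echoes"],
        dead_time=d["dead_time"],
        noise_sigma=d["noise_sigma"],
        seed=d["seed"],
    )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_decay_csv(dataset: DecayDataset, path) -> None:
    """Write a decay dataset as long-format CSV plus a JSON scheme sidecar."""
    path = Path(path)
    rec = np.asarray(dataset.scheme.recovery_times, dtype=float)
    n_rec, n_acq = dataset.signal.shape
    labels = (
        dataset.channel_labels
        if dataset.channel_labels is not None
        else np.array([""] * n_acq, dtype=object)
    )
    frame = pd.DataFrame(
        {
            "recovery_ms": np.repeat(rec, n_acq),
            "acq_us": np.tile(dataset.acquisition_times, n_rec),
            "signal": dataset.signal.ravel(),
            "channel": np.tile(labels, n_rec),
        }
    )
    # %.17g guarantees exact binary round trip of the signal values
    frame.to_csv(path, index=False, float_format="%.17g")
    _sidecar(path).write_text(json.dumps(_scheme_to_dict(dataset.scheme), indent=1))


def read_decay_csv(path) -> DecayDataset:
    """Read a decay dataset written by :func:`write_decay_csv` (lossless)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ParseError(f"missing JSON scheme sidecar: {sidecar}")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("recovery_ms", "acq_us", "signal"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    scheme = _scheme_from_dict(json.loads(sidecar.read_text()))
    rec = np.asarray(scheme.recovery_times, dtype=float)
    acq = np.unique(frame["acq_us"].to_numpy())
    n_rec, n_acq = rec.size, acq.size
    if len(frame) != n_rec * n_acq:
        raise ParseError(
            f"{path}: {len(frame)} rows inconsistent with scheme "
            f"({n_rec} recovery x {n_acq} acquisition times)"
        )
    signal = frame["signal"].to_numpy().reshape(n_rec, n_acq)
    labels = None
    if "channel" in frame.columns:
        labels = frame["channel"].to_numpy()[:n_acq].astype(object)
    return DecayDataset(
        scheme=scheme, signal=signal, acquisition_times=acq, channel_labels=labels
    )


def write_dispersion_csv(profile: DispersionProfile, path) -> None:
    """Write a dispersion profile as CSV (freq_MHz, R1_per_s, err, nucleus)."""
    path = Path(path)
    err = (
        profile.R1_err
        if profile.R1_err is not None
        else np.zeros_like(profile.R1)
    )
    pd.DataFrame(
        {
            "freq_MHz": profile.frequencies,
            "R1_per_s": profile.R1,
            "err": err,
            "nucleus": profile.nucleus,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_dispersion_csv(path) -> DispersionProfile:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("freq_MHz", "R1_per_s"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    err = frame["err"].to_numpy() if "err" in frame.columns else None
    nucleus = str(frame["nucleus"].iloc[0]) if "nucleus" in frame.columns else "1H"
    return DispersionProfile(
        frequencies=frame["freq_MHz"].to_numpy(),
        R1=frame["R1_per_s"].to_numpy(),
        R1_err=err,
        nucleus=nucleus,
    )


def write_map(rmap: RelaxationMap, prefix) -> None:
    """Write a relaxation map as T1/T2 axis CSVs, amplitude CSV and JSON meta."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}_T1_ms.csv", rmap.grid.T1_values, delimiter=",")
    np.savetxt(f"{prefix}_T2_ms.csv", rmap.grid.T2_values, delimiter=",")
    np.savetxt(f"{prefix}_amplitude.csv", rmap.amplitude, delimiter=",")
    meta = {
        "gaussian_boundary_ms": rmap.grid.gaussian_boundary,
        "alpha": rmap.alpha,
        "residual_norm": rmap.residual_norm,
        "solution_norm": rmap.solution_norm,
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=1))


def read_map(prefix) -> RelaxationMap:
    prefix = Path(prefix)
    try:
        T1 = np.loadtxt(f"{prefix}_T1_ms.csv", delimiter=",")
        T2 = np.loadtxt(f"{prefix}_T2_ms.csv", delimiter=",")
        amp = np.loadtxt(f"{prefix}_amplitude.csv", delimiter=",")
        meta = json.loads(Path(f"{prefix}_meta.json").read_text())
    except OSError as exc:
        raise ParseError(f"cannot read map files with prefix {prefix}: {exc}") from exc
    grid = InversionGrid(
        T1_values=T1, T2_values=T2, gaussian_boundary=meta["gaussian_boundary_ms"]
    )
    return RelaxationMap(
        grid=grid,
        amplitude=amp,
        alpha=meta["alpha"],
        residual_norm=meta["residual_norm"],
        solution_norm=meta["solution_norm"],
    )


@dataclass(frozen=True)
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    n_T1: int = 64
    n_T2: int = 64
    gaussian_boundary_ms: float = 1.0
    alpha_method: str = "gcv"
    alpha: float | None = None
    svd_rank: int = 16
    noise_sigma: float = 0.0
    output_dir: str = "."

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def inversion_options(self) -> InversionOptions:
        return InversionOptions(
            alpha_method=self.alpha_method, alpha=self.alpha, svd_rank=self.svd_rank
        )
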