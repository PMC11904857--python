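"""On-disk interchange formats: CSV traces and multi-page TIFF images, each
with a JSON sidecar carrying modality, units, protocol, and ground truth.

CSV layout: column 1 is time (ms for electrophysiology, s for calcium);
subsequent columns are sweeps (one per step voltage) or the single signal.
The sidecar shares the file stem with extension ``.json``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .presets import InactProtocol, VClampProtocol
from .records import (FluorescenceTrace, MultiChannelImage, SweepFamily,
                      VoltageTrace)

__all__ = [
    "sidecar_path",
    "write_sweep_family",
    "write_voltage_trace",
    "write_fluorescence_trace",
    "write_image",
    "read_trace_csv",
    "read_image",
]


def sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return super().default(obj)


def _write_sidecar(path: str | Path, payload: dict) -> None:
    with open(sidecar_path(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, cls=_NumpyEncoder)
        fh.write("\n")


def _read_sidecar(path: str | Path) -> dict:
    sp = sidecar_path(path)
    if not sp.exists():
        raise ConfigError(f"missing sidecar {sp}")
    with open(sp) as fh:
        return json.load(fh)


def write_sweep_family(family: SweepFamily, path: str | Path) -> Path:
    """Write a current family as CSV (time_ms + one column per step)."""
    path = Path(path)
    cols = {"time_ms": family.time_ms}
    for v, sweep in zip(family.step_voltages, family.sweeps.T):
        cols[f"sweep_{v:+.1f}mV"] = sweep
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")
    proto = family.protocol
    _write_sidecar(path, {
        "modality": family.meta.get("modality",
                                    "inact" if isinstance(proto, InactProtocol)
                                    else "na"),
        "units": {"time": "ms", "signal": "pA"},
        "protocol_type": type(proto).__name__,
        "protocol": proto.to_dict(),
        "step_voltages_mv": family.step_voltages,
        "capacitance_pf": family.capacitance,
        "step_onset_ms": family.step_onset,
        "meta": family.meta,
    })
    return path


def write_voltage_trace(trace: VoltageTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_ms": trace.time_ms,
                  "voltage_mV": trace.voltage_mv}).to_csv(
        path, index=False, float_format="%.6g")
    _write_sidecar(path, {
        "modality": "ap",
        "units": {"time": "ms", "signal": "mV"},
        "stimulus_times_ms": trace.stimulus_times,
        "sampling_rate_khz": trace.sampling_rate,
        "meta": trace.meta,
    })
    return path


def write_fluorescence_trace(trace: FluorescenceTrace,
                             path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s,
                  "ratio": trace.ratio}).to_csv(
        path, index=False, float_format="%.8g")
    _write_sidecar(path, {
        "modality": "ca",
        "units": {"time": "s", "signal": "ratio"},
        "stimulus_times_s": trace.stimulus_times,
        "pacing_hz": trace.pacing_hz,
        "meta": trace.meta,
    })
    return path


def write_image(image: MultiChannelImage, path: str | Path) -> Path:
    """Write a multi-page TIFF (one page per channel) plus sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.channels.astype(np.float32))
    _write_sidecar(path, {
        "modality": "image",
        "pixel_size_um": image.pixel_size,
        "channel_labels": image.channel_labels,
        "meta": image.meta,
    })
    return path


def _check_uniform(time: np.ndarray, path) -> None:
    dt = np.diff(time)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ConfigError(f"non-uniform time grid in {path}")


def _protocol_from(sidecar: dict):
    cls = {"VClampProtocol": VClampProtocol,
           "InactProtocol": InactProtocol}.get(sidecar.get("protocol_type"))
    if cls is None:
        raise ConfigError("sidecar lacks a recognizable protocol_type")
    return cls(**sidecar["protocol"])


def read_trace_csv(path: str | Path):
    """Read a trace CSV + sidecar into its typed record.

    Dispatches on the sidecar ``modality``: ``na``/``inact`` ->
    :class:`SweepFamily`, ``ap`` -> :class:`VoltageTrace`, ``ca`` ->
    :class:`FluorescenceTrace`.
    """
    path = Path(path)
    sidecar = _read_sidecar(path)
    modality = sidecar.get("modality")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ConfigError(f"{path}: need a time column plus >= 1 signal "
                          "column")
    time = df.iloc[:, 0].to_numpy(float)
    _check_uniform(time, path)

    if modality in ("na", "inact"):
        if sidecar.get("units", {}).get("time") != "ms":
            raise ConfigError(f"{path}: electrophysiology time must be ms")
        sweeps = df.iloc[:, 1:].to_numpy(float)
        voltages = np.asarray(sidecar["step_voltages_mv"], dtype=float)
        if sweeps.shape[1] != voltages.size:
            raise ConfigError(
                f"{path}: {sweeps.shape[1]} sweep column(s) but "
                f"{voltages.size} step voltage(s) declared")
        if sweeps.shape[1] < 2:
            raise ConfigError(f"{path}: a sweep family needs >= 2 sweeps")
        return SweepFamily(time_ms=time, sweeps=sweeps, step_voltages=voltages,
                           capacitance=float(sidecar["capacitance_pf"]),
                           protocol=_protocol_from(sidecar),
                           step_onset=float(sidecar["step_onset_ms"]),
                           meta=sidecar.get("meta", {}))
    if modality == "ap":
        if sidecar.get("units", {}).get("time") != "ms":
            raise ConfigError(f"{path}: AP time must be ms")
        return VoltageTrace(
            time_ms=time, voltage_mv=df.iloc[:, 1].to_numpy(float),
            stimulus_times=np.asarray(sidecar["stimulus_times_ms"], float),
            sampling_rate=float(sidecar["sampling_rate_khz"]),
            meta=sidecar.get("meta", {}))
    if modality == "ca":
        if sidecar.get("units", {}).get("time") != "s":
            raise ConfigError(f"{path}: calcium time must be s")
        return FluorescenceTrace(
            time_s=time, ratio=df.iloc[:, 1].to_numpy(float),
            stimulus_times=np.asarray(sidecar["stimulus_times_s"], float),
            pacing_hz=float(sidecar["pacing_hz"]),
            meta=sidecar.get("meta", {}))
    raise ConfigError(f"{path}: unknown modality {modality!r}")


def read_image(path: str | Path) -> MultiChannelImage:
    import tifffile

    path = Path(path)
    sidecar = _read_sidecar(path)
    if sidecar.get("modality") != "image":
        raise ConfigError(f"{path}: sidecar modality is not 'image'")
    channels = np.asarray(tifffile.imread(path), dtype=float)
    if channels.ndim == 2:
        channels = channels[None]
    return MultiChannelImage(channels=channels,
                             pixel_size=float(sidecar["pixel_size_um"]),
                             channel_labels=list(sidecar["channel_labels"]),
                             meta=sidecar.get("meta", {}))
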