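"""File formats: HDF5 capture container, CSV series, JSON reports.

The capture container is a single HDF5 file holding the ``samples``
dataset (ramp x channel x fast-time) plus every radar-configuration field,
a format-version string and, when known, the creation seed as attributes.
Round-tripping reproduces the capture bit-exactly including metadata.
1-D series (rates, ground truth, apnea events) travel as CSV for easy
inspection; agreement reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    AgreementReport,
    ApneaEvent,
    RadarConfig,
    RateSeries,
    RateSource,
    RawCapture,
)

__all__ = [
    "FORMAT_VERSION",
    "write_capture",
    "read_capture",
    "write_rate_series",
    "read_rate_series",
    "write_apnea_events",
    "read_apnea_events",
    "write_report",
]

FORMAT_VERSION = "1"

_CONFIG_ATTRS = (
    "carrier_frequency",
    "bandwidth",
    "samples_per_ramp",
    "sampling_frequency",
    "ramp_rate",
    "n_channels",
    "acquisition_mode",
    "standoff",
)


def write_capture(
    capture: RawCapture,
    path,
    seed: int | None = None,
    config_echo: dict | None = None,
) -> None:
    """Write *capture* to a single-file HDF5 container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("samples", data=capture.samples)
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["start_time"] = capture.start_time
        fh.attrs["n_ramps"] = capture.n_ramps
        cfg = capture.config
        for name in _CONFIG_ATTRS:
            value = getattr(cfg, name)
            fh.attrs[name] = value.value if name == "acquisition_mode" else value
        if cfg.wavelength_override is not None:
            fh.attrs["wavelength_override"] = cfg.wavelength_override
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        if config_echo is not None:
            fh.attrs["config_json"] = json.dumps(config_echo)


def read_capture(path) -> RawCapture:
    """Read a capture container written by :func:`write_capture`."""
    with h5py.File(path, "r") as fh:
        version = fh.attrs.get("format_version")
        if version is None:
            raise ValueError(f"{path}: missing attribute 'format_version'")
        if str(version) != FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported format version {version!r} (supported: {FORMAT_VERSION})"
            )
        if "samples" not in fh:
            raise ValueError(f"{path}: missing dataset 'samples'")
        for name in _CONFIG_ATTRS:
            if name not in fh.attrs:
                raise ValueError(f"{path}: missing attribute {name!r}")
        cfg = RadarConfig(
            carrier_frequency=float(fh.attrs["carrier_frequency"]),
            bandwidth=float(fh.attrs["bandwidth"]),
            samples_per_ramp=int(fh.attrs["samples_per_ramp"]),
            sampling_frequency=float(fh.attrs["sampling_frequency"]),
            ramp_rate=float(fh.attrs["ramp_rate"]),
            n_channels=int(fh.attrs["n_channels"]),
            acquisition_mode=str(fh.attrs["acquisition_mode"]),
            standoff=float(fh.attrs["standoff"]),
            wavelength_override=(
                float(fh.attrs["wavelength_override"])
                if "wavelength_override" in fh.attrs
                else None
            ),
        )
        samples = fh["samples"][...]
        return RawCapture(
            samples=samples,
            config=cfg,
            start_time=float(fh.attrs.get("start_time", 0.0)),
            n_ramps=int(fh.attrs["n_ramps"]),
        )


def write_rate_series(series: RateSeries, path, config_echo: dict | None = None) -> None:
    """Write a rate series as CSV (``time_s, rate_bpm, source``)."""
    path = Path(path)
    with open(path, "w") as fh:
        if config_echo is not None:
            fh.write(f"# config: {json.dumps(config_echo)}\n")
        pd.DataFrame(
            {
                "time_s": series.timestamps,
                "rate_bpm": series.rate,
                "source": series.source.value,
            }
        ).to_csv(fh, index=False)


def read_rate_series(path, band: tuple[float, float] | None = None) -> RateSeries:
    df = pd.read_csv(path, comment="#")
    for col in ("time_s", "rate_bpm", "source"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    sources = df["source"].unique()
    if len(sources) != 1:
        raise ValueError(f"{path}: expected a single source, got {list(sources)}")
    kwargs = {"band": band} if band is not None else {}
    return RateSeries(
        timestamps=df["time_s"].to_numpy(float),
        rate=df["rate_bpm"].to_numpy(float),
        source=RateSource(sources[0]),
        **kwargs,
    )


def write_apnea_events(events: list[ApneaEvent], path) -> None:
    pd.DataFrame(
        {
            "start_s": [e.start for e in events],
            "end_s": [e.end for e in events],
            "duration_s": [e.duration for e in events],
        }
    ).to_csv(path, index=False)


def read_apnea_events(path) -> list[ApneaEvent]:
    df = pd.read_csv(path)
    return [ApneaEvent(start=row.start_s, end=row.end_s) for row in df.itertuples()]


def write_report(report: AgreementReport, path, config_echo: dict | None = None) -> None:
    payload = report.to_dict()
    if config_echo is not None:
        payload["config"] = config_echo
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
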