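"""Recording readers and writers: SNIRF, plain HDF5, and CSV + JSON sidecar.

Three on-disk layouts are supported for an optical-density session:

``snirf``
    A minimal SNIRF v1.0 file (SNIRF is an HDF5 convention): one data block
    whose ``dataTimeSeries`` is samples x measurements with a
    ``measurementList`` entry per (channel, wavelength), probe wavelengths,
    and one stim group per trial class.
``hdf5``
    A compact native layout: dataset ``/od`` shaped channels x wavelengths
    x samples with ``sample_rate``/``wavelengths``/``channel_ids`` attributes
    and an ``/events`` group (``onsets``, ``labels``).
``csv``
    A wide table (``time`` plus one ``<channel>_wl<nm>`` column per
    measurement) next to a ``.json`` sidecar holding sample rate,
    wavelengths, channel ids and events.

Readers normalize the wavelength axis to (780, 805, 830) nm regardless of
the on-disk column order.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    WAVELENGTHS,
    EventList,
    FormatError,
    OpticalDensitySeries,
)

__all__ = ["write_recording", "read_recording"]

_FORMATS = ("snirf", "hdf5", "csv")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise FormatError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    mapping = {".snirf": "snirf", ".h5": "hdf5", ".hdf5": "hdf5", ".csv": "csv"}
    if suffix not in mapping:
        raise FormatError(f"cannot infer format from suffix {suffix!r}")
    return mapping[suffix]


def _normalize_wavelength_order(
    data: np.ndarray, wavelengths: list[float]
) -> np.ndarray:
    """Reorder the wavelength axis to the canonical (780, 805, 830) triple."""
    if sorted(wavelengths) != sorted(WAVELENGTHS):
        raise FormatError(
            f"expected wavelengths {WAVELENGTHS} in some order, got {wavelengths}"
        )
    order = [wavelengths.index(w) for w in WAVELENGTHS]
    return data[:, order, :]


# ---------------------------------------------------------------------------
# SNIRF


def _write_snirf(path: Path, od: OpticalDensitySeries, events: EventList) -> None:
    n_ch, n_wl, n_samp = od.data.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data="synthetic")
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(od.wavelengths))
        pos = np.column_stack([np.arange(n_ch), np.zeros(n_ch), np.zeros(n_ch)])
        probe.create_dataset("sourcePos3D", data=pos.astype(float))
        probe.create_dataset("detectorPos3D", data=pos.astype(float))

        data1 = nirs.create_group("data1")
        # samples x measurements; measurement m = channel * n_wl + wavelength
        flat = od.data.reshape(n_ch * n_wl, n_samp).T
        data1.create_dataset("dataTimeSeries", data=flat)
        data1.create_dataset("time", data=np.arange(n_samp) / od.sample_rate)
        m = 1
        for ch in range(n_ch):
            for wl in range(n_wl):
                ml = data1.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=ch + 1)
                ml.create_dataset("detectorIndex", data=ch + 1)
                ml.create_dataset("wavelengthIndex", data=wl + 1)
                ml.create_dataset("dataType", data=99999)  # processed
                ml.create_dataset("dataTypeLabel", data="dOD")
                ml.create_dataset("dataTypeIndex", data=1)
                m += 1

        for si, cls in enumerate(sorted(set(events.labels)), start=1):
            stim = nirs.create_group(f"stim{si}")
            stim.create_dataset("name", data=str(cls))
            sel = events.labels == cls
            block = np.column_stack(
                [
                    events.onsets[sel],
                    np.full(int(sel.sum()), 10.0),
                    np.ones(int(sel.sum())),
                ]
            )
            stim.create_dataset("data", data=block)


def _read_str(ds) -> str:
    val = ds[()]
    return val.decode() if isinstance(val, bytes) else str(val)


def _read_snirf(path: Path) -> tuple[OpticalDensitySeries, EventList]:
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise FormatError("not a SNIRF file: missing /nirs group")
        nirs = f["nirs"]
        data1 = nirs["data1"]
        flat = np.asarray(data1["dataTimeSeries"])  # samples x measurements
        time = np.asarray(data1["time"])
        if time.size < 2:
            raise FormatError("SNIRF time vector too short to infer sample rate")
        sample_rate = 1.0 / float(np.mean(np.diff(time)))
        wavelengths = [float(w) for w in np.asarray(nirs["probe"]["wavelengths"])]

        ml_names = sorted(
            (k for k in data1 if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList") :]),
        )
        if len(ml_names) != flat.shape[1]:
            raise FormatError("measurementList count does not match data columns")
        src = [int(data1[k]["sourceIndex"][()]) for k in ml_names]
        wli = [int(data1[k]["wavelengthIndex"][()]) for k in ml_names]
        channels = sorted(set(src))
        n_ch, n_wl = len(channels), len(wavelengths)
        data = np.empty((n_ch, n_wl, flat.shape[0]))
        for col, (s, w) in enumerate(zip(src, wli)):
            data[channels.index(s), w - 1, :] = flat[:, col]
        data = _normalize_wavelength_order(data, wavelengths)

        onsets: list[float] = []
        labels: list[str] = []
        for key in sorted(k for k in nirs if k.startswith("stim")):
            stim = nirs[key]
            name = _read_str(stim["name"])
            for row in np.atleast_2d(np.asarray(stim["data"])):
                onsets.append(float(row[0]))
                labels.append(name)
        order = np.argsort(onsets)
        events = EventList(
            onsets=np.asarray(onsets)[order],
            labels=np.asarray(labels, dtype=object)[order],
        )
        od = OpticalDensitySeries(
            data=data,
            sample_rate=sample_rate,
            wavelengths=WAVELENGTHS,
            channel_ids=[f"CH{c:02d}" for c in channels],
        )
        return od, events


# ---------------------------------------------------------------------------
# native HDF5


def _write_hdf5(path: Path, od: OpticalDensitySeries, events: EventList) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("od", data=od.data)
        ds.attrs["sample_rate"] = od.sample_rate
        ds.attrs["wavelengths"] = np.asarray(od.wavelengths)
        ds.attrs["channel_ids"] = [str(c) for c in od.channel_ids]
        ev = f.create_group("events")
        ev.create_dataset("onsets", data=events.onsets)
        ev.create_dataset("labels", data=[str(l) for l in events.labels])


def _read_hdf5(path: Path) -> tuple[OpticalDensitySeries, EventList]:
    with h5py.File(path, "r") as f:
        if "od" not in f or "events" not in f:
            raise FormatError("missing 'od' dataset or 'events' group")
        ds = f["od"]
        for attr in ("sample_rate", "wavelengths", "channel_ids"):
            if attr not in ds.attrs:
                raise FormatError(f"missing required attribute {attr!r} on /od")
        wavelengths = [float(w) for w in ds.attrs["wavelengths"]]
        data = _normalize_wavelength_order(np.asarray(ds), wavelengths)
        od = OpticalDensitySeries(
            data=data,
            sample_rate=float(ds.attrs["sample_rate"]),
            wavelengths=WAVELENGTHS,
            channel_ids=[
                c.decode() if isinstance(c, bytes) else str(c)
                for c in ds.attrs["channel_ids"]
            ],
        )
        labels = [
            l.decode() if isinstance(l, bytes) else str(l)
            for l in f["events"]["labels"]
        ]
        events = EventList(
            onsets=np.asarray(f["events"]["onsets"]),
            labels=np.asarray(labels, dtype=object),
        )
        return od, events


# ---------------------------------------------------------------------------
# CSV + JSON sidecar


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_csv(path: Path, od: OpticalDensitySeries, events: EventList) -> None:
    cols = {"time": od.times}
    for ki, ch in enumerate(od.channel_ids):
        for wi, wl in enumerate(od.wavelengths):
            cols[f"{ch}_wl{int(wl)}"] = od.data[ki, wi, :]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {
        "sample_rate": od.sample_rate,
        "wavelengths": list(od.wavelengths),
        "channel_ids": [str(c) for c in od.channel_ids],
        "events": {
            "onsets": events.onsets.tolist(),
            "labels": [str(l) for l in events.labels],
        },
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def _read_csv(path: Path) -> tuple[OpticalDensitySeries, EventList]:
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar.name}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"unreadable sidecar {sidecar.name}: {exc}") from exc
    for key in ("sample_rate", "wavelengths", "channel_ids", "events"):
        if key not in meta:
            raise FormatError(f"sidecar missing field {key!r}")
    table = pd.read_csv(path)
    channel_ids = [str(c) for c in meta["channel_ids"]]
    wavelengths = [float(w) for w in meta["wavelengths"]]
    n_samp = len(table)
    data = np.empty((len(channel_ids), len(wavelengths), n_samp))
    for ki, ch in enumerate(channel_ids):
        for wi, wl in enumerate(wavelengths):
            col = f"{ch}_wl{int(wl)}"
            if col not in table.columns:
                raise FormatError(f"CSV missing column {col!r}")
            data[ki, wi, :] = table[col].to_numpy()
    data = _normalize_wavelength_order(data, wavelengths)
    od = OpticalDensitySeries(
        data=data,
        sample_rate=float(meta["sample_rate"]),
        wavelengths=WAVELENGTHS,
        channel_ids=channel_ids,
    )
    events = EventList(
        onsets=np.asarray(meta["events"]["onsets"], dtype=float),
        labels=np.asarray(meta["events"]["labels"], dtype=object),
    )
    return od, events


# ---------------------------------------------------------------------------
# public API

_WRITERS = {"snirf": _write_snirf, "hdf5": _write_hdf5, "csv": _write_csv}
_READERS = {"snirf": _read_snirf, "hdf5": _read_hdf5, "csv": _read_csv}


def write_recording(
    path: str | Path,
    od: OpticalDensitySeries,
    events: EventList,
    format: str | None = None,
) -> Path:
    """Write a session to disk; the format is inferred from the suffix if omitted."""
    path = Path(path)
    _WRITERS[_infer_format(path, format)](path, od, events)
    return path


def read_recording(
    path: str | Path, format: str | None = None
) -> tuple[OpticalDensitySeries, EventList]:
    """Read a session; wavelength order is normalized to (780, 805, 830) nm.

    Raises
    ------
    FormatError
        On missing metadata, truncated files or layout mismatches.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        return _READERS[fmt](path)
    except (OSError, KeyError, ValueError, IndexError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"cannot read {path.name} as {fmt}: {exc}") from exc
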