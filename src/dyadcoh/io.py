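"""Reading and writing recordings.

Two on-disk formats are supported: SNIRF (the HDF5-based fNIRS standard;
a minimal but standard-conformant subset is written: ``/nirs/data1`` with a
measurementList, ``/nirs/probe`` with optode positions whose distances encode
the source-detector separations, and one stim group per trigger label) and a
plain-text CSV dialect (a directory holding ``intensity.csv`` in long format
``time,channel,wavelength,intensity``, plus ``channels.csv``,
``triggers.csv`` and ``meta.json``) for inspectable fixtures.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .channels import ChannelInfo
from .errors import CorruptDataError, FormatError
from .recording import OpticalRecording

_CSV_FILES = ("intensity.csv", "channels.csv", "triggers.csv", "meta.json")


def write_recording(rec: OpticalRecording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording as SNIRF (``.snirf``) or the CSV dialect (directory)."""
    path = Path(path)
    fmt = format or ("snirf" if path.suffix == ".snirf" else "csv")
    if fmt == "snirf":
        _write_snirf(rec, path)
    elif fmt == "csv":
        _write_csv(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")
    return path


def read_recording(path: str | Path, format: str | None = None) -> OpticalRecording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    fmt = format or ("snirf" if path.suffix == ".snirf" else "csv")
    if fmt == "snirf":
        return _read_snirf(path)
    if fmt == "csv":
        return _read_csv(path)
    raise FormatError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

def _str_ds(group: h5py.Group, name: str, value: str) -> None:
    group.create_dataset(name, data=np.bytes_(value))


def _write_snirf(rec: OpticalRecording, path: Path) -> None:
    n_ch = len(rec.channels)
    with h5py.File(path, "w") as f:
        _str_ds(f, "formatVersion", "1.1")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        _str_ds(meta, "SubjectID", rec.role)
        _str_ds(meta, "MeasurementDate", "unknown")
        _str_ds(meta, "MeasurementTime", "unknown")
        _str_ds(meta, "LengthUnit", "mm")
        _str_ds(meta, "TimeUnit", "s")
        _str_ds(meta, "FrequencyUnit", "Hz")

        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths, float))
        # Dedicated optodes per channel, spaced widely; distance == separation.
        n_src = max(c.source for c in rec.channels)
        n_det = max(c.detector for c in rec.channels)
        spos = np.zeros((n_src, 2))
        dpos = np.zeros((n_det, 2))
        for i, c in enumerate(rec.channels):
            spos[c.source - 1] = (i * 200.0, 0.0)
            dpos[c.detector - 1] = (i * 200.0 + c.separation, 0.0)
        probe.create_dataset("sourcePos2D", data=spos)
        probe.create_dataset("detectorPos2D", data=dpos)
        probe.create_dataset(
            "sourceLabels", data=[np.bytes_(f"S{i+1}") for i in range(n_src)]
        )
        probe.create_dataset(
            "detectorLabels", data=[np.bytes_(f"D{i+1}") for i in range(n_det)]
        )

        data = nirs.create_group("data1")
        flat = rec.intensity.reshape(rec.n_times, n_ch * 2, order="F")
        # column k*n_ch + i  <->  channel i, wavelength k (Fortran order)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times)
        m = 0
        for k in range(2):
            for i, c in enumerate(rec.channels):
                m += 1
                ml = data.create_group(f"measurementList{m}")
                ml.create_dataset("sourceIndex", data=c.source)
                ml.create_dataset("detectorIndex", data=c.detector)
                ml.create_dataset("wavelengthIndex", data=k + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)

        # Channel metadata not covered by the SNIRF core schema.
        aux = nirs.create_group("metaDataTags/channelInfo")
        for key, conv in (("id", str), ("roi", str), ("kind", str)):
            aux.create_dataset(key, data=[np.bytes_(conv(getattr(c, key))) for c in rec.channels])
        aux.create_dataset("valid", data=[int(c.valid) for c in rec.channels])

        labels = sorted({lab for _, lab in rec.triggers})
        for j, lab in enumerate(labels, start=1):
            stim = nirs.create_group(f"stim{j}")
            _str_ds(stim, "name", lab)
            onsets = [t for t, L in rec.triggers if L == lab]
            stim.create_dataset(
                "data", data=np.array([[t, 0.0, 1.0] for t in onsets], float)
            )


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def _read_snirf(path: Path) -> OpticalRecording:
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise FormatError("missing /nirs group")
        nirs = f["nirs"]
        if "probe" not in nirs or "data1" not in nirs:
            raise FormatError("missing probe or data block")
        probe = nirs["probe"]
        wavelengths = tuple(float(w) for w in probe["wavelengths"][()])
        spos = probe["sourcePos2D"][()]
        dpos = probe["detectorPos2D"][()]
        data = nirs["data1"]
        ts = data["dataTimeSeries"][()]
        time = data["time"][()]
        if time.size < 2:
            raise FormatError("need at least two time samples")
        fs = 1.0 / float(np.median(np.diff(time)))

        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        n_ch = len(ml_names) // len(wavelengths)
        aux = nirs.get("metaDataTags/channelInfo")
        channels: list[ChannelInfo] = []
        for i in range(n_ch):
            ml = data[ml_names[i]]
            src = int(ml["sourceIndex"][()])
            det = int(ml["detectorIndex"][()])
            sep = float(np.linalg.norm(spos[src - 1] - dpos[det - 1]))
            if aux is not None:
                cid = aux["id"][i].decode()
                roi = aux["roi"][i].decode()
                valid = bool(aux["valid"][i])
            else:
                cid, roi, valid = f"CH{i+1}", "none", True
            kind = "short" if sep <= 15.0 else "long"
            channels.append(ChannelInfo(cid, src, det, sep, kind, roi, valid))

        intensity = ts.reshape(ts.shape[0], n_ch, len(wavelengths), order="F")
        if np.any(intensity <= 0):
            raise CorruptDataError("non-positive intensity in SNIRF data block")

        triggers: list[tuple[float, str]] = []
        for k in nirs.keys():
            if k.startswith("stim"):
                stim = nirs[k]
                lab = _read_str(stim["name"])
                for row in np.atleast_2d(stim["data"][()]):
                    triggers.append((float(row[0]), lab))
        triggers.sort(key=lambda p: p[0])

        role = "child"
        tags = nirs.get("metaDataTags")
        if tags is not None and "SubjectID" in tags:
            role = _read_str(tags["SubjectID"])
    return OpticalRecording(
        role=role, fs=fs, wavelengths=wavelengths, intensity=intensity,
        channels=channels, triggers=triggers,
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _write_csv(rec: OpticalRecording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    t = rec.times
    frames = []
    for k, wl in enumerate(rec.wavelengths):
        for i, c in enumerate(rec.channels):
            frames.append(
                pd.DataFrame(
                    {
                        "time": t,
                        "channel": c.id,
                        "wavelength": wl,
                        "intensity": rec.intensity[:, i, k],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path / "intensity.csv", index=False)
    pd.DataFrame(
        [
            {
                "id": c.id, "source": c.source, "detector": c.detector,
                "separation": c.separation, "kind": c.kind, "roi": c.roi,
                "valid": c.valid,
            }
            for c in rec.channels
        ]
    ).to_csv(path / "channels.csv", index=False)
    pd.DataFrame(rec.triggers, columns=["time", "label"]).to_csv(
        path / "triggers.csv", index=False
    )
    (path / "meta.json").write_text(
        json.dumps({"role": rec.role, "fs": rec.fs, "wavelengths": list(rec.wavelengths)})
    )


def _read_csv(path: Path) -> OpticalRecording:
    path = Path(path)
    for fname in _CSV_FILES:
        if not (path / fname).exists():
            raise FormatError(f"CSV recording is missing {fname}")
    meta = json.loads((path / "meta.json").read_text())
    ch_df = pd.read_csv(path / "channels.csv")
    if ch_df.empty:
        raise FormatError("channels.csv holds no geometry")
    channels = [
        ChannelInfo(
            id=str(r.id), source=int(r.source), detector=int(r.detector),
            separation=float(r.separation), kind=str(r.kind), roi=str(r.roi),
            valid=bool(r.valid),
        )
        for r in ch_df.itertuples()
    ]
    inten = pd.read_csv(path / "intensity.csv")
    if (inten["intensity"] <= 0).any():
        raise CorruptDataError("non-positive intensity sample in intensity.csv")
    wavelengths = tuple(float(w) for w in meta["wavelengths"])
    times = np.sort(inten["time"].unique())
    n, n_ch = times.size, len(channels)
    cube = np.empty((n, n_ch, len(wavelengths)))
    piv = inten.pivot_table(
        index="time", columns=["channel", "wavelength"], values="intensity"
    )
    for i, c in enumerate(channels):
        for k, wl in enumerate(wavelengths):
            cube[:, i, k] = piv[(c.id, wl)].to_numpy()
    trig_df = pd.read_csv(path / "triggers.csv")
    triggers = [(float(r.time), str(r.label)) for r in trig_df.itertuples()]
    return OpticalRecording(
        role=str(meta["role"]), fs=float(meta["fs"]), wavelengths=wavelengths,
        intensity=cube, channels=channels, triggers=triggers,
    )
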