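"""In-memory containers for raw optical and haemoglobin time series."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .channels import ChannelInfo
from .errors import CorruptDataError

#: Order of provenance flags through the preprocessing chain.
PROVENANCE_STEPS = (
    "od_converted",
    "motion_corrected",
    "filtered",
    "conc_converted",
    "ssr_applied",
)


@dataclass
class OpticalRecording:
    """One participant's raw continuous-wave recording.

    ``intensity`` has shape (n_times, n_channels, n_wavelengths), strictly
    positive detector counts.  ``triggers`` are (time-in-seconds, label)
    events marking epoch onsets.
    """

    role: str  # {"child", "mother"}
    fs: float
    wavelengths: tuple[float, float]
    intensity: np.ndarray
    channels: list[ChannelInfo]
    triggers: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise CorruptDataError("intensity must be (time, channel, wavelength)")
        if self.intensity.shape[1] != len(self.channels):
            raise CorruptDataError("channel list does not match intensity shape")
        if self.intensity.shape[2] != len(self.wavelengths):
            raise CorruptDataError("wavelength axis does not match wavelengths")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity <= 0):
            raise CorruptDataError("intensities must be finite and strictly positive")
        dur = self.duration
        for t, _ in self.triggers:
            if not 0.0 <= t <= dur + 0.5 / self.fs:
                raise CorruptDataError(f"trigger at {t} s outside recording [0, {dur}] s")

    @property
    def n_times(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    def channel_index(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.id == channel_id:
                return i
        raise KeyError(channel_id)

    def cropped(self, t0: float, t1: float) -> "OpticalRecording":
        """Return the sub-recording on [t0, t1), with triggers re-referenced."""
        i0 = int(np.ceil(t0 * self.fs - 1e-9))
        i1 = int(np.floor(t1 * self.fs + 1e-9))
        trig = [
            (t - i0 / self.fs, lab)
            for t, lab in self.triggers
            if i0 / self.fs - 1e-9 <= t <= i1 / self.fs + 1e-9
        ]
        return OpticalRecording(
            role=self.role,
            fs=self.fs,
            wavelengths=self.wavelengths,
            intensity=self.intensity[i0:i1],
            channels=list(self.channels),
            triggers=trig,
        )


@dataclass
class HemoTimeSeries:
    """Per-channel haemoglobin concentration changes (molar, mean-referenced).

    ``hbo`` and ``hbr`` have shape (n_times, n_channels).  ``provenance``
    records which pipeline stages produced this object; flags only ever
    accumulate.
    """

    fs: float
    hbo: np.ndarray
    hbr: np.ndarray
    channels: list[ChannelInfo]
    provenance: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise CorruptDataError("HbO2 and HbR arrays must share a shape")
        if self.hbo.ndim != 2 or self.hbo.shape[1] != len(self.channels):
            raise CorruptDataError("concentration arrays must be (time, channel)")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise CorruptDataError("concentrations must be finite")
        for step in PROVENANCE_STEPS:
            self.provenance.setdefault(step, False)

    @property
    def n_times(self) -> int:
        return self.hbo.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_times) / self.fs

    def chromophore(self, which: str) -> np.ndarray:
        if which == "HbO2":
            return self.hbo
        if which == "HbR":
            return self.hbr
        raise KeyError(which)

    def channel_index(self, channel_id: str) -> int:
        for i, c in enumerate(self.channels):
            if c.id == channel_id:
                return i
        raise KeyError(channel_id)

    def with_flags(self, **flags: bool) -> "HemoTimeSeries":
        """Return a shallow copy with provenance flags switched on."""
        prov = dict(self.provenance)
        for k, v in flags.items():
            if k not in PROVENANCE_STEPS:
                raise KeyError(k)
            if prov.get(k) and not v:
                raise ValueError(f"provenance flag {k!r} cannot be cleared")
            prov[k] = prov.get(k, False) or v
        return replace(self, provenance=prov)
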