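"""Wavelet transform coherence (WTC) between dyad members.

The continuous wavelet transform with an analytic Morlet mother wavelet
(centre frequency omega0 = 6) decomposes each signal into the time-scale
plane.  Squared coherence is the modulus-squared of the smoothed cross-
spectrum normalised by the smoothed auto-spectra,

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) ),

with S a Gaussian smoother in time (width proportional to scale) followed by
a boxcar across scale (0.6 octave).  R^2 lies in [0, 1] and is invariant to
constant phase shifts and amplitude rescaling of either signal.  Values are
then averaged over the scales whose equivalent Fourier frequency lies in the
band of interest (0.02-0.10 Hz) and over the samples of each task epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.ndimage import uniform_filter1d

from .channels import ROIS, ChannelInfo, long_channels
from .errors import AlignmentError, InvalidConfigError
from .protocol import ProtocolTimeline
from .recording import HemoTimeSeries

OMEGA0 = 6.0
#: Fourier factor: period = FOURIER_FACTOR * scale for the Morlet wavelet.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))

DEFAULT_BAND = (0.02, 0.10)  # Hz
DEFAULT_DJ = 1.0 / 12.0  # 12 voices per octave
#: Decorrelation length of the boxcar scale smoother, in octaves.
SCALE_SMOOTH_OCTAVES = 0.6


def morlet_scales(
    fs: float,
    n: int,
    dj: float = DEFAULT_DJ,
    min_period: float | None = None,
    max_period: float | None = None,
) -> np.ndarray:
    """Logarithmic scale grid.

    Defaults: smallest scale 2*dt, `dj` voices per octave, extended so the
    largest equivalent period reaches at least 64 s (covering 0.02 Hz) but no
    further than the record length.
    """
    dt = 1.0 / fs
    s0 = 2.0 * dt if min_period is None else min_period / FOURIER_FACTOR
    longest = max_period if max_period is not None else max(64.0, 0.0)
    longest = min(longest, n * dt)
    s_max = longest / FOURIER_FACTOR
    if s_max <= s0:
        raise InvalidConfigError("scale grid is empty; record too short for the band")
    J = int(np.ceil(np.log2(s_max / s0) / dj))
    return s0 * 2.0 ** (dj * np.arange(J + 1))


@dataclass
class CoherenceMap:
    """Time-scale squared coherence with its cone of influence.

    ``values`` has shape (n_scales, n_times) with entries in [0, 1];
    ``freqs`` are the equivalent Fourier frequencies (strictly decreasing in
    scale); ``coi`` holds, per time sample, the lowest trustworthy frequency
    (edge effects contaminate anything below it).
    """

    values: np.ndarray
    scales: np.ndarray
    freqs: np.ndarray
    coi: np.ndarray
    fs: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[1]) / self.fs


def cwt_morlet(
    x: np.ndarray,
    fs: float,
    scales: np.ndarray,
) -> np.ndarray:
    """Continuous Morlet wavelet transform, shape (n_scales, n_times).

    FFT implementation with zero padding; the transform is L2-normalised so
    that a unit-variance broadband signal's scale-integrated power
    approximates its variance.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidConfigError("input track must be finite")
    n = x.size
    dt = 1.0 / fs
    npad = sfft.next_fast_len(2 * n)
    xh = sfft.fft(x - x.mean(), npad)
    omega = 2.0 * np.pi * sfft.fftfreq(npad, d=dt)
    W = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi**-0.25
    pos = omega > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(npad)
        psi_hat[pos] = (
            norm_const * np.sqrt(2.0 * np.pi * s / dt)
            * np.exp(-0.5 * (s * omega[pos] - OMEGA0) ** 2)
        )
        W[i] = sfft.ifft(xh * psi_hat)[:n]
    return W


def coi_min_frequency(n: int, fs: float) -> np.ndarray:
    """Lowest trustworthy frequency per time sample.

    The Morlet e-folding time is sqrt(2)*scale, so at distance ``t`` from the
    nearer record edge scales above ``t/sqrt(2)`` (frequencies below
    ``sqrt(2)/(FOURIER_FACTOR*t)``) are edge-contaminated.
    """
    t = np.arange(n) / fs
    edge = np.minimum(t, (n - 1) / fs - t)
    with np.errstate(divide="ignore"):
        return np.where(edge > 0, np.sqrt(2.0) / (FOURIER_FACTOR * edge), np.inf)


def _smooth(
    field: np.ndarray, scales: np.ndarray, fs: float, dj: float
) -> np.ndarray:
    """Smoothing operator S: Gaussian in time (sigma = scale), boxcar in scale."""
    n_s, n = field.shape
    sigma_samples = scales * fs
    npad = sfft.next_fast_len(n + int(6 * sigma_samples.max()) + 1)
    omega = 2.0 * np.pi * sfft.fftfreq(npad)
    fh = sfft.fft(field, npad, axis=1)
    fh *= np.exp(-0.5 * (sigma_samples[:, None] * omega[None, :]) ** 2)
    out = sfft.ifft(fh, axis=1)[:, :n]
    win = max(1, int(round(SCALE_SMOOTH_OCTAVES / dj)))
    if win > 1 and n_s > 1:
        out = uniform_filter1d(out.real, win, axis=0, mode="nearest") + 1j * (
            uniform_filter1d(out.imag, win, axis=0, mode="nearest")
        )
    return out


def smoothed_power(W: np.ndarray, scales: np.ndarray, fs: float, dj: float = DEFAULT_DJ) -> np.ndarray:
    """S(|W|^2 / s); cached by surrogate ensembles for the unscrambled partner.

    Computed through the identical code path as the cross term so that
    self-coherence is exactly one.
    """
    return np.abs(_smooth(W * np.conj(W) / scales[:, None], scales, fs, dj))


def wtc_from_transforms(
    Wx: np.ndarray,
    Wy: np.ndarray,
    scales: np.ndarray,
    fs: float,
    dj: float = DEFAULT_DJ,
    Sx: np.ndarray | None = None,
    Sy: np.ndarray | None = None,
) -> np.ndarray:
    """Squared coherence from precomputed transforms on a common scale grid."""
    inv_s = 1.0 / scales[:, None]
    if Sx is None:
        Sx = smoothed_power(Wx, scales, fs, dj)
    if Sy is None:
        Sy = smoothed_power(Wy, scales, fs, dj)
    Sxy = np.abs(_smooth(Wx * np.conj(Wy) * inv_s, scales, fs, dj))
    denom = Sx * Sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, (Sxy * Sxy) / denom, 0.0)
    return np.clip(r2, 0.0, 1.0)


def wtc(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    dj: float = DEFAULT_DJ,
    min_period: float | None = None,
    max_period: float | None = None,
) -> CoherenceMap:
    """Wavelet transform coherence between two equal-length tracks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise AlignmentError("wtc requires two equal-length 1-D tracks")
    scales = morlet_scales(fs, x.size, dj, min_period, max_period)
    Wx = cwt_morlet(x, fs, scales)
    Wy = cwt_morlet(y, fs, scales)
    values = wtc_from_transforms(Wx, Wy, scales, fs, dj)
    return CoherenceMap(
        values=values,
        scales=scales,
        freqs=1.0 / (FOURIER_FACTOR * scales),
        coi=coi_min_frequency(x.size, fs),
        fs=fs,
    )


def band_scale_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    eps = 1e-12
    mask = (freqs >= lo - eps) & (freqs <= hi + eps)
    if not mask.any():
        raise InvalidConfigError(f"no scales with frequency inside {band}")
    return mask


def band_condition_average(
    cmap: CoherenceMap,
    band: tuple[float, float],
    timeline: ProtocolTimeline,
    coi_policy: str = "include",
) -> pd.DataFrame:
    """Average coherence over band scales and task-epoch samples.

    Returns one row per (condition, trial) with ``mean_wtc`` and
    ``n_samples_used``.  Rest epochs never contribute.  With
    ``coi_policy="exclude"`` cells whose frequency falls below the cone of
    influence are dropped; an epoch left empty yields NaN (recorded, not
    fatal).
    """
    if coi_policy not in {"include", "exclude"}:
        raise InvalidConfigError(f"unknown coi_policy {coi_policy!r}")
    smask = band_scale_mask(cmap.freqs, band)
    vals = cmap.values[smask]
    freqs = cmap.freqs[smask]
    n = vals.shape[1]
    rows = []
    for e in timeline.task_epochs:
        i0 = int(np.ceil(e.onset * cmap.fs - 1e-9))
        i1 = min(n, int(np.floor(e.end * cmap.fs + 1e-9)))
        seg = vals[:, i0:i1]
        if coi_policy == "exclude":
            ok = freqs[:, None] >= cmap.coi[None, i0:i1]
            used = int(ok.any(axis=0).sum())
            mean = float(seg[ok].mean()) if ok.any() else float("nan")
        else:
            used = seg.shape[1]
            mean = float(seg.mean()) if seg.size else float("nan")
        rows.append(
            {"condition": e.condition, "trial": e.trial, "mean_wtc": mean, "n_samples_used": used}
        )
    return pd.DataFrame(rows)


def roi_validity(channels: list[ChannelInfo], min_channels: int = 2) -> dict[str, bool]:
    """A region of interest is valid iff it holds >= 2 valid long channels."""
    counts = {r: 0 for r in ROIS}
    for c in long_channels(channels, valid_only=True):
        if c.roi in counts:
            counts[c.roi] += 1
    return {r: counts[r] >= min_channels for r in ROIS}


def roi_average_signals(hemo: HemoTimeSeries, min_channels: int = 2) -> HemoTimeSeries:
    """Average valid long channels within each valid ROI, per chromophore.

    The result re-uses the channel container with one pseudo-channel per
    valid ROI; ROIs with fewer than ``min_channels`` valid long channels are
    excluded entirely.
    """
    validity = roi_validity(hemo.channels, min_channels)
    roi_channels: list[ChannelInfo] = []
    hbo_cols, hbr_cols = [], []
    for roi in ROIS:
        if not validity[roi]:
            continue
        members = [c for c in long_channels(hemo.channels, valid_only=True) if c.roi == roi]
        idx = [hemo.channel_index(c.id) for c in members]
        hbo_cols.append(hemo.hbo[:, idx].mean(axis=1))
        hbr_cols.append(hemo.hbr[:, idx].mean(axis=1))
        roi_channels.append(
            ChannelInfo(
                id=roi, source=0, detector=0,
                separation=members[0].separation, kind="long", roi=roi,
            )
        )
    hbo = np.column_stack(hbo_cols) if hbo_cols else np.empty((hemo.n_times, 0))
    hbr = np.column_stack(hbr_cols) if hbr_cols else np.empty((hemo.n_times, 0))
    return HemoTimeSeries(
        fs=hemo.fs, hbo=hbo, hbr=hbr, channels=roi_channels,
        provenance=dict(hemo.provenance),
    )


def enumerate_pairs(
    child: HemoTimeSeries, mother: HemoTimeSeries, level: str = "channel"
) -> list[tuple[str, str]]:
    """All child-unit x mother-unit combinations at the requested level.

    Channel level: Cartesian product of the valid long channels (short
    channels never enter).  ROI level: product of the valid ROIs on each
    side.  An empty list signals that one side has no valid unit.
    """
    if level == "channel":
        cu = [c.id for c in long_channels(child.channels, valid_only=True)]
        mu = [c.id for c in long_channels(mother.channels, valid_only=True)]
    elif level == "roi":
        cu = [r for r, ok in roi_validity(child.channels).items() if ok]
        mu = [r for r, ok in roi_validity(mother.channels).items() if ok]
    else:
        raise InvalidConfigError(f"unknown pairing level {level!r}")
    return list(product(cu, mu))
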