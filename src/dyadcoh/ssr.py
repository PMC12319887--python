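"""Superficial signal regression (SSR).

Short-separation channels sample only scalp haemodynamics.  Averaging the
valid short channels gives one global superficial regressor per chromophore,
which is regressed (ordinary least squares with intercept) out of every
long-separation channel.  Recordings without any valid short channel pass
through unchanged with ``applied=False`` — mirroring cohorts where only part
of the sample contributes short-channel data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError
from .recording import HemoTimeSeries
from .channels import long_channels, short_channels

CHROMOPHORES = ("HbO2", "HbR")


@dataclass
class SsrResult:
    cleaned: HemoTimeSeries
    betas: dict[str, dict[str, float]]  # chromophore -> channel id -> beta
    regressor_channels: list[str]
    applied: bool


def global_short_regressor(hemo: HemoTimeSeries, chromophore: str) -> np.ndarray | None:
    """Mean of the valid short-channel tracks, or None if no valid SSC exists."""
    ssc = short_channels(hemo.channels, valid_only=True)
    if not ssc:
        return None
    idx = [hemo.channel_index(c.id) for c in ssc]
    return hemo.chromophore(chromophore)[:, idx].mean(axis=1)


def _regress_out(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """OLS of y on [1, x]; returns (residual + fitted-intercept removal, beta)."""
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom <= 0:
        return y - y.mean(), 0.0
    beta = float(xc @ (y - y.mean())) / denom
    cleaned = y - y.mean() - beta * xc
    return cleaned, beta


def apply_ssr(hemo: HemoTimeSeries) -> SsrResult:
    """Regress the global superficial signal out of every long channel.

    Per chromophore, each long channel ``y`` is replaced by the OLS residual
    of ``y ~ 1 + regressor``; short-channel tracks are left untouched.  The
    residual is orthogonal to the regressor, never has more energy than the
    mean-centred input, and the operation is idempotent.
    """
    ssc = short_channels(hemo.channels, valid_only=True)
    if not ssc:
        return SsrResult(
            cleaned=hemo, betas={c: {} for c in CHROMOPHORES},
            regressor_channels=[], applied=False,
        )

    hbo = hemo.hbo.copy()
    hbr = hemo.hbr.copy()
    arrays = {"HbO2": hbo, "HbR": hbr}
    betas: dict[str, dict[str, float]] = {}
    lsc = long_channels(hemo.channels)
    for chrom, arr in arrays.items():
        reg = global_short_regressor(hemo, chrom)
        betas[chrom] = {}
        if reg is None or reg.std() == 0:
            # Zero-variance regressor: record beta 0, leave channels as-is.
            for ch in lsc:
                betas[chrom][ch.id] = 0.0
            continue
        for ch in lsc:
            j = hemo.channel_index(ch.id)
            arr[:, j], betas[chrom][ch.id] = _regress_out(arr[:, j], reg)

    cleaned = HemoTimeSeries(
        fs=hemo.fs, hbo=hbo, hbr=hbr, channels=list(hemo.channels),
        provenance=dict(hemo.provenance),
    ).with_flags(ssr_applied=True)
    return SsrResult(
        cleaned=cleaned,
        betas=betas,
        regressor_channels=[c.id for c in ssc],
        applied=True,
    )


def maybe_apply_ssr(hemo: HemoTimeSeries, mode: str = "auto") -> SsrResult:
    """Dispatch on the SSR policy: 'auto' applies when a valid SSC exists,
    'on' requires one, 'off' passes through."""
    if mode not in {"auto", "on", "off"}:
        raise InvalidConfigError(f"unknown SSR mode {mode!r}")
    if mode == "off":
        return SsrResult(hemo, {c: {} for c in CHROMOPHORES}, [], False)
    result = apply_ssr(hemo)
    if mode == "on" and not result.applied:
        raise InvalidConfigError("SSR mode 'on' but no valid short channel available")
    return result
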