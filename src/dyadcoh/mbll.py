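"""Modified Beer–Lambert law (MBLL) forward and inverse maps.

The MBLL relates optical-density changes at two wavelengths to concentration
changes of oxy- and deoxyhaemoglobin:

    dOD_l(t) = (eps_HbO2,l * dHbO2(t) + eps_HbR,l * dHbR(t)) * d * DPF_l

with ``d`` the source-detector separation, ``DPF_l`` the wavelength- and
age-dependent differential pathlength factor, and ``eps`` molar extinction
coefficients.  Continuous-wave fNIRS only resolves *changes*; all tracks are
mean-referenced and the absolute baseline is unidentified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelInfo
from .errors import NumericalConfigError
from .recording import HemoTimeSeries, OpticalRecording

#: Molar extinction coefficients [cm^-1 / (mol/L)] at (760, 850) nm,
#: rows = wavelength, columns = (HbO2, HbR).  Standard tabulated values;
#: overridable everywhere they are used — the pipeline only requires the
#: forward and inverse maps to share one table.
DEFAULT_EXTINCTION = np.array(
    [
        [586.0, 1548.52],  # 760 nm
        [1058.0, 691.32],  # 850 nm
    ]
)

#: Differential pathlength factors at (760, 850) nm by participant role.
#: DPF decreases with wavelength, so the larger value is assigned to 760 nm.
DEFAULT_DPF = {"child": (5.4, 4.7), "mother": (6.0, 6.0)}


@dataclass(frozen=True)
class DpfTable:
    """Role → (DPF at first wavelength, DPF at second wavelength)."""

    values: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DPF)
    )

    def __post_init__(self) -> None:
        for role, pair in self.values.items():
            if any(v <= 0 for v in pair):
                raise NumericalConfigError(f"DPFs for {role!r} must be positive")

    def for_role(self, role: str) -> tuple[float, float]:
        return self.values[role]


def _pathlength_matrix(
    separation_mm: float, dpf: tuple[float, float], extinction: np.ndarray
) -> np.ndarray:
    """2x2 system matrix A with dOD = A @ (dHbO2, dHbR) for one channel."""
    ext = np.asarray(extinction, dtype=float)
    if ext.shape != (2, 2):
        raise NumericalConfigError("extinction table must be 2x2")
    d_cm = separation_mm / 10.0
    L = d_cm * np.asarray(dpf, dtype=float)  # effective pathlength per wavelength
    A = ext * L[:, None]
    if abs(np.linalg.det(A)) < 1e-12 * np.abs(A).max() ** 2:
        raise NumericalConfigError("extinction/pathlength system is singular")
    return A


def conc_to_od(
    hemo: HemoTimeSeries,
    role: str,
    dpf: DpfTable | None = None,
    extinction: np.ndarray | None = None,
) -> np.ndarray:
    """Forward MBLL: concentrations → optical-density changes.

    Returns an array of shape (n_times, n_channels, 2).
    """
    dpf = dpf or DpfTable()
    ext = DEFAULT_EXTINCTION if extinction is None else np.asarray(extinction, float)
    od = np.empty((hemo.n_times, len(hemo.channels), 2))
    conc = np.stack([hemo.hbo, hemo.hbr], axis=-1)  # (t, ch, 2)
    for i, ch in enumerate(hemo.channels):
        A = _pathlength_matrix(ch.separation, dpf.for_role(role), ext)
        od[:, i, :] = conc[:, i, :] @ A.T
    return od


def forward_mbll(
    hemo: HemoTimeSeries,
    role: str,
    dpf: DpfTable | None = None,
    extinction: np.ndarray | None = None,
    baseline_intensity: float = 1e6,
    wavelengths: tuple[float, float] = (760.0, 850.0),
    triggers: list[tuple[float, str]] | None = None,
) -> OpticalRecording:
    """Map concentration changes to strictly positive raw intensities.

    I_l(t) = baseline * exp(-dOD_l(t)); the exact inverse (up to the
    mean-referencing constant) of ``intensity_to_od`` followed by
    ``od_to_conc`` with the same table.
    """
    if baseline_intensity <= 0:
        raise NumericalConfigError("baseline intensity must be positive")
    od = conc_to_od(hemo, role, dpf, extinction)
    intensity = baseline_intensity * np.exp(-od)
    return OpticalRecording(
        role=role,
        fs=hemo.fs,
        wavelengths=wavelengths,
        intensity=intensity,
        channels=list(hemo.channels),
        triggers=list(triggers or []),
    )


def od_to_conc_tracks(
    od: np.ndarray,
    channels: list[ChannelInfo],
    role: str,
    dpf: DpfTable | None = None,
    extinction: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse MBLL on (n_times, n_channels, 2) OD tracks → (hbo, hbr)."""
    dpf = dpf or DpfTable()
    ext = DEFAULT_EXTINCTION if extinction is None else np.asarray(extinction, float)
    od = np.asarray(od, dtype=float)
    hbo = np.empty(od.shape[:2])
    hbr = np.empty(od.shape[:2])
    for i, ch in enumerate(channels):
        A = _pathlength_matrix(ch.separation, dpf.for_role(role), ext)
        conc = np.linalg.solve(A, od[:, i, :].T)  # (2, t)
        hbo[:, i] = conc[0]
        hbr[:, i] = conc[1]
    return hbo, hbr
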