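"""Synthetic dyad generator with known ground-truth coupling.

Each dyad shares a band-limited (0.02–0.10 Hz by default) latent cerebral
oscillation.  A participant's cerebral haemoglobin track mixes that shared
oscillation with an independent band-limited track; the mixing weight is the
configured per-condition coupling strength, so cross-partner coherence in the
band rises monotonically with the configured strength and vanishes when it is
zero.  On top of the cerebral signal each participant carries extracerebral
physiology — cardiac, respiratory and Mayer-wave oscillations plus slow
drift — an adjustable fraction of which is shared within the dyad (partners'
physiology synchronises during interaction), scaled to dominate the cortical
signal by ``extracerebral_gain``.  Short-separation channels record only the
extracerebral component; long channels record cerebral + extracerebral plus
white measurement noise.  Motion artifacts (spikes and baseline steps) are
injected at Poisson times.  Concentrations are pushed through the forward
modified Beer–Lambert law to yield strictly positive raw intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .channels import default_montage
from .errors import InvalidConfigError
from .mbll import DpfTable, forward_mbll
from .protocol import ProtocolTimeline, timeline_to_triggers
from .recording import HemoTimeSeries, OpticalRecording

_CARDIAC_MAX_HZ = 2.5


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults reproduce the acquisition described for the study cohort:
    25 Hz sampling, 760/850 nm, 16 long channels (25 mm child, 30 mm mother),
    two 10 mm short channels, coupling restricted to 0.02–0.10 Hz, and an
    extracerebral component ten times the cortical amplitude.
    """

    n_dyads: int = 20
    fs: float = 25.0
    wavelengths: tuple[float, float] = (760.0, 850.0)
    n_lsc: int = 16
    n_ssc: int = 2
    coupling_band: tuple[float, float] = (0.02, 0.10)
    coupling_strength_by_condition: dict[str, float] = field(
        default_factory=lambda: {
            "individual": 0.0,
            "collaboration_screen": 0.5,
            "collaboration": 0.6,
        }
    )
    systemic_share: float = 0.5
    artifact_rate: float = 0.5  # events / minute / participant
    extracerebral_gain: float = 10.0
    amp_cerebral: float = 1e-7  # molar; ~0.1 uM cortical fluctuation scale
    hbr_ratio: float = -0.4  # typical inverse HbR/HbO2 cortical coupling
    channel_noise: float = 0.1  # white noise SD relative to amp_cerebral
    baseline_intensity: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * _CARDIAC_MAX_HZ:
            raise InvalidConfigError("fs must exceed twice the cardiac frequency")
        for cond, c in self.coupling_strength_by_condition.items():
            if not 0.0 <= c <= 1.0:
                raise InvalidConfigError(f"coupling strength for {cond!r} not in [0,1]")
        if not 0.0 <= self.systemic_share <= 1.0:
            raise InvalidConfigError("systemic_share must lie in [0,1]")
        if self.extracerebral_gain < 0:
            raise InvalidConfigError("extracerebral_gain must be >= 0")
        if not 0 < self.coupling_band[0] < self.coupling_band[1] < self.fs / 2:
            raise InvalidConfigError("coupling band must satisfy 0 < lo < hi < fs/2")
        if self.artifact_rate < 0:
            raise InvalidConfigError("artifact_rate must be >= 0")


@dataclass
class Artifact:
    onset: float  # s
    kind: str  # {"spike", "step"}
    amplitude: float  # molar, signed
    width: float  # s (spike only; 0 for steps)


@dataclass
class GroundTruth:
    """Latent state of one simulated dyad, for parameter-recovery tests."""

    latent: np.ndarray  # shared cerebral oscillation, unit variance
    coupling_track: np.ndarray  # per-sample configured coupling strength
    coupling_strengths: dict[str, float]
    cerebral_hbo: dict[str, np.ndarray]  # role -> track (molar)
    extracerebral_hbo: dict[str, np.ndarray]  # role -> track incl. artifacts
    extracerebral_hbr: dict[str, np.ndarray]
    systemic_components: dict[str, dict[str, np.ndarray]]  # role -> name -> track
    artifacts: dict[str, list[Artifact]]


def narrowband_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (zero-phase filtered)."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / y.std()


def _lowpass_drift(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    x = rng.standard_normal(n)
    sos = signal.butter(2, 0.008, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    s = y.std()
    return y / s if s > 0 else y


def _oscillation(rng: np.random.Generator, t: np.ndarray, f_range: tuple[float, float]) -> np.ndarray:
    f = rng.uniform(*f_range)
    phi = rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.sin(2 * np.pi * f * t + phi)  # unit variance


def _coupling_track(timeline: ProtocolTimeline, strengths: dict[str, float], n: int, fs: float) -> np.ndarray:
    c = np.zeros(n)
    for e in timeline.task_epochs:
        i0 = int(round(e.onset * fs))
        i1 = min(n, int(round(e.end * fs)))
        c[i0:i1] = strengths.get(e.condition, 0.0)
    return c


def _draw_artifacts(
    rng: np.random.Generator, duration: float, rate_per_min: float, conc_sd: float
) -> list[Artifact]:
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    out: list[Artifact] = []
    for _ in range(n_events):
        onset = float(rng.uniform(0, duration))
        if rng.random() < 0.5:
            amp = float(rng.choice([-1, 1]) * rng.uniform(5, 15) * conc_sd)
            out.append(Artifact(onset, "spike", amp, float(rng.uniform(0.3, 1.0))))
        else:
            amp = float(rng.choice([-1, 1]) * rng.uniform(2, 5) * conc_sd)
            out.append(Artifact(onset, "step", amp, 0.0))
    return out


def _artifact_track(artifacts: list[Artifact], t: np.ndarray) -> np.ndarray:
    track = np.zeros_like(t)
    for a in artifacts:
        if a.kind == "spike":
            track += a.amplitude * np.exp(-0.5 * ((t - a.onset) / a.width) ** 2)
        else:
            track += a.amplitude * (t >= a.onset)
    return track


# Relative amplitudes of the extracerebral components (unit-variance tracks).
_SYSTEMIC_WEIGHTS = {
    "cardiac": 1.0,
    "respiration": 0.6,
    "mayer": 0.8,
    "lfo": 1.0,
    "drift": 1.5,
}


def simulate_dyad(
    config: SimulationConfig,
    timeline: ProtocolTimeline,
    seed: int,
) -> tuple[OpticalRecording, OpticalRecording, GroundTruth]:
    """Generate one dyad's raw recordings plus its ground truth.

    Identical (config, timeline, seed) give bit-identical outputs.
    """
    if timeline.duration <= 0 or not timeline.epochs:
        raise InvalidConfigError("timeline must contain at least one epoch")
    fs = config.fs
    n = int(round(timeline.duration * fs))
    if n < 16:
        raise InvalidConfigError("timeline too short to simulate")
    t = np.arange(n) / fs

    rng = np.random.default_rng(np.random.SeedSequence([0x5D, seed]))
    roles = ("child", "mother")

    # Shared and independent cerebral oscillations.
    z = narrowband_noise(rng, n, fs, config.coupling_band)
    indep = {r: narrowband_noise(rng, n, fs, config.coupling_band) for r in roles}
    hbr_extra = {r: narrowband_noise(rng, n, fs, config.coupling_band) for r in roles}
    c_track = _coupling_track(timeline, config.coupling_strength_by_condition, n, fs)
    w_shared = np.sqrt(c_track)
    w_own = np.sqrt(1.0 - c_track)

    amp = config.amp_cerebral
    cerebral_hbo = {r: amp * (w_shared * z + w_own * indep[r]) for r in roles}
    cerebral_hbr = {
        r: config.hbr_ratio * cerebral_hbo[r] + 0.2 * amp * hbr_extra[r] for r in roles
    }

    # Extracerebral physiology: dyad-common and participant-specific parts.
    share, own_w = np.sqrt(config.systemic_share), np.sqrt(1.0 - config.systemic_share)
    # Cardiac and respiration are quasi-sinusoidal; Mayer waves and the slower
    # low-frequency oscillations (LFO) are narrowband noise processes whose
    # support overlaps the 0.02-0.10 Hz analysis band — they, not the fast
    # rhythms, carry the within-dyad systemic coherence that superficial
    # regression is meant to remove.
    common = {
        "cardiac": _oscillation(rng, t, (1.4, 1.9)),
        "respiration": _oscillation(rng, t, (0.25, 0.35)),
        "mayer": narrowband_noise(rng, n, fs, (0.06, 0.12)),
        "lfo": narrowband_noise(rng, n, fs, (0.015, 0.08)),
    }
    cardiac_range = {"child": (1.7, 2.3), "mother": (1.1, 1.5)}
    systemic_components: dict[str, dict[str, np.ndarray]] = {}
    systemic_hbo: dict[str, np.ndarray] = {}
    for r in roles:
        comps = {
            "cardiac": share * common["cardiac"]
            + own_w * _oscillation(rng, t, cardiac_range[r]),
            "respiration": share * common["respiration"]
            + own_w * _oscillation(rng, t, (0.25, 0.35)),
            "mayer": share * common["mayer"]
            + own_w * narrowband_noise(rng, n, fs, (0.06, 0.12)),
            "lfo": share * common["lfo"]
            + own_w * narrowband_noise(rng, n, fs, (0.015, 0.08)),
            "drift": _lowpass_drift(rng, n, fs),
        }
        systemic_components[r] = comps
        mix = sum(_SYSTEMIC_WEIGHTS[k] * v for k, v in comps.items())
        norm = np.sqrt(sum(w**2 for w in _SYSTEMIC_WEIGHTS.values()))
        systemic_hbo[r] = config.extracerebral_gain * amp * mix / norm

    # Motion artifacts: one participant-global additive track.
    artifacts: dict[str, list[Artifact]] = {}
    artifact_hbo: dict[str, np.ndarray] = {}
    for r in roles:
        conc_sd = float(np.std(cerebral_hbo[r] + systemic_hbo[r]))
        artifacts[r] = _draw_artifacts(rng, timeline.duration, config.artifact_rate, conc_sd)
        artifact_hbo[r] = _artifact_track(artifacts[r], t)

    extracerebral_hbo = {r: systemic_hbo[r] + artifact_hbo[r] for r in roles}
    extracerebral_hbr = {r: 0.3 * extracerebral_hbo[r] for r in roles}

    recordings: dict[str, OpticalRecording] = {}
    for r in roles:
        montage = default_montage(r, config.n_lsc, config.n_ssc)
        n_ch = len(montage)
        hbo = np.empty((n, n_ch))
        hbr = np.empty((n, n_ch))
        noise_sd = config.channel_noise * amp
        for i, ch in enumerate(montage):
            if ch.kind == "long":
                hbo[:, i] = (
                    cerebral_hbo[r]
                    + extracerebral_hbo[r]
                    + noise_sd * rng.standard_normal(n)
                )
                hbr[:, i] = (
                    cerebral_hbr[r]
                    + extracerebral_hbr[r]
                    + noise_sd * rng.standard_normal(n)
                )
            else:  # short channel: extracerebral component exactly
                hbo[:, i] = extracerebral_hbo[r]
                hbr[:, i] = extracerebral_hbr[r]
        hemo = HemoTimeSeries(fs=fs, hbo=hbo, hbr=hbr, channels=montage)
        recordings[r] = forward_mbll(
            hemo,
            role=r,
            dpf=DpfTable(),
            baseline_intensity=config.baseline_intensity,
            wavelengths=config.wavelengths,
            triggers=timeline_to_triggers(timeline),
        )

    truth = GroundTruth(
        latent=z,
        coupling_track=c_track,
        coupling_strengths=dict(config.coupling_strength_by_condition),
        cerebral_hbo=cerebral_hbo,
        extracerebral_hbo=extracerebral_hbo,
        extracerebral_hbr=extracerebral_hbr,
        systemic_components=systemic_components,
        artifacts=artifacts,
    )
    return recordings["child"], recordings["mother"], truth


def dyad_seeds(master_seed: int, n_dyads: int) -> list[int]:
    """Derive one independent per-dyad seed stream from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_dyads)]
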