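"""Phase-scrambled pseudodyad null distributions.

A surrogate keeps one partner's signal intact (the child's) and replaces the
other's (the mother's) by a phase-randomised copy: forward FFT, phases of the
positive-frequency bins redrawn uniformly, Hermitian symmetry restored so the
inverse transform is real.  The surrogate has *exactly* the original
amplitude spectrum (hence mean and autocorrelation) but no meaningful
temporal alignment with the partner.  Coherence computed against many such
surrogates gives a per-pair, per-condition null for "same task and
environment, no coordinated interaction".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coherence import (
    DEFAULT_BAND,
    DEFAULT_DJ,
    FOURIER_FACTOR,
    CoherenceMap,
    band_condition_average,
    coi_min_frequency,
    cwt_morlet,
    morlet_scales,
    smoothed_power,
    wtc_from_transforms,
)
from .errors import InvalidConfigError
from .protocol import ProtocolTimeline
from .recording import HemoTimeSeries


def phase_scramble(x: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Randomise the Fourier phases of ``x`` while preserving its amplitude
    spectrum exactly.

    The DC bin (and, for even length, the Nyquist bin) stay real, so the mean
    is preserved to rounding error.
    """
    x = np.asarray(x, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = x.size
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    phases = np.zeros_like(amp)
    hi = amp.size - 1 if n % 2 == 0 else amp.size  # keep even-length Nyquist real
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, hi - 1)
    # DC keeps the sign of the original (amplitude |spec[0]| with phase 0 or pi)
    new = amp * np.exp(1j * phases)
    new[0] = spec[0]
    if n % 2 == 0:
        new[-1] = amp[-1] * np.sign(spec[-1].real) if spec[-1].real != 0 else amp[-1]
    return np.fft.irfft(new, n)


@dataclass
class SurrogateEnsemble:
    """Null coherence values for one (pair, condition)."""

    dyad_id: str
    pair: tuple[str, str]
    condition: str
    n_iter: int
    values: np.ndarray  # per-iteration band/condition mean WTC
    master_seed: int
    iteration_seeds: list[int] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def iteration_seeds(master_seed: int, n_iter: int) -> list[int]:
    """Counter-based derivation of per-iteration seeds (recorded for replay)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_iter)]


def pseudodyad_ensemble(
    child: HemoTimeSeries,
    mother: HemoTimeSeries,
    pairs: list[tuple[str, str]],
    timeline: ProtocolTimeline,
    n_iter: int = 100,
    master_seed: int = 0,
    chromophore: str = "HbO2",
    band: tuple[float, float] = DEFAULT_BAND,
    coi_policy: str = "include",
    dj: float = DEFAULT_DJ,
    min_period: float | None = None,
    max_period: float | None = None,
    shared_phases: bool = False,
) -> list[SurrogateEnsemble]:
    """Build the phase-scrambled null for every pair and condition.

    Only the mother's tracks are scrambled; the child's signal is untouched.
    Per iteration each mother unit is scrambled once (independent phase draws
    per unit unless ``shared_phases``), coherence with the child's true
    signal is computed, and band/condition averages are taken exactly as for
    true dyads.  The child's wavelet transforms are computed once and reused
    across iterations.
    """
    if n_iter < 1:
        raise InvalidConfigError("n_iter must be >= 1")
    if not pairs:
        return []
    fs = child.fs
    n = child.n_times
    scales = morlet_scales(fs, n, dj, min_period, max_period)
    freqs = 1.0 / (FOURIER_FACTOR * scales)
    coi = coi_min_frequency(n, fs)

    child_units = sorted({p[0] for p in pairs})
    mother_units = sorted({p[1] for p in pairs})
    xs = {u: child.chromophore(chromophore)[:, child.channel_index(u)] for u in child_units}
    Wx = {u: cwt_morlet(xs[u], fs, scales) for u in child_units}
    Sx = {u: smoothed_power(Wx[u], scales, fs, dj) for u in child_units}

    seeds = iteration_seeds(master_seed, n_iter)
    conditions = timeline.conditions()
    acc: dict[tuple[tuple[str, str], str], list[float]] = {
        (p, c): [] for p in pairs for c in conditions
    }

    for it_seed in seeds:
        rng = np.random.default_rng(it_seed)
        Wy: dict[str, np.ndarray] = {}
        Sy: dict[str, np.ndarray] = {}
        for u in mother_units:
            y = mother.chromophore(chromophore)[:, mother.channel_index(u)]
            # shared_phases: every unit re-seeds the generator, so all units
            # receive one common random phase vector per iteration.
            y_s = phase_scramble(y, np.random.default_rng(it_seed) if shared_phases else rng)
            Wy[u] = cwt_morlet(y_s, fs, scales)
            Sy[u] = smoothed_power(Wy[u], scales, fs, dj)
        for p in pairs:
            cu, mu = p
            r2 = wtc_from_transforms(Wx[cu], Wy[mu], scales, fs, dj, Sx=Sx[cu], Sy=Sy[mu])
            cmap = CoherenceMap(values=r2, scales=scales, freqs=freqs, coi=coi, fs=fs)
            table = band_condition_average(cmap, band, timeline, coi_policy)
            per_cond = table.groupby("condition")["mean_wtc"].mean()
            for c in conditions:
                acc[(p, c)].append(float(per_cond.get(c, np.nan)))

    return [
        SurrogateEnsemble(
            dyad_id="", pair=p, condition=c, n_iter=n_iter,
            values=np.asarray(vals), master_seed=master_seed,
            iteration_seeds=list(seeds),
        )
        for (p, c), vals in acc.items()
    ]


def ensemble_table(ensembles: list[SurrogateEnsemble]) -> pd.DataFrame:
    """Tidy per-(pair, condition) summary of a surrogate ensemble list."""
    return pd.DataFrame(
        {
            "child_unit": [e.pair[0] for e in ensembles],
            "mother_unit": [e.pair[1] for e in ensembles],
            "condition": [e.condition for e in ensembles],
            "n_iter": [e.n_iter for e in ensembles],
            "pseudo_mean_wtc": [e.mean for e in ensembles],
        }
    )
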