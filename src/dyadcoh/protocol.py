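"""Experimental protocol timelines.

The task protocol alternates rest phases with task phases drawn from three
conditions (individual problem solving, collaboration behind a screen, and
full face-to-face collaboration).  A session begins and ends with rest, every
pair of task epochs is separated by exactly one rest epoch, and the order of
the task epochs is randomised per dyad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

#: Canonical condition labels, in "coupling strength" narrative order.
CONDITIONS = ("individual", "collaboration_screen", "collaboration")

REST = "rest"


@dataclass(frozen=True)
class Epoch:
    """One contiguous phase of the session.

    ``condition`` is ``"rest"`` for rest phases; ``trial`` counts occurrences
    of a condition (1-based) and is 0 for rest.  Times are seconds from the
    start of the recording; an epoch spans the half-open interval
    ``[onset, onset + duration)``.
    """

    condition: str
    trial: int
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration

    @property
    def is_task(self) -> bool:
        return self.condition != REST


@dataclass(frozen=True)
class ProtocolTimeline:
    """Ordered sequence of rest/task epochs covering the whole session."""

    epochs: tuple[Epoch, ...] = field(default_factory=tuple)

    @property
    def duration(self) -> float:
        return 0.0 if not self.epochs else self.epochs[-1].end

    @property
    def task_epochs(self) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if e.is_task)

    @property
    def rest_epochs(self) -> tuple[Epoch, ...]:
        return tuple(e for e in self.epochs if not e.is_task)

    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.task_epochs:
            if e.condition not in seen:
                seen.append(e.condition)
        return tuple(seen)

    def trials_per_condition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.task_epochs:
            out[e.condition] = max(out.get(e.condition, 0), e.trial)
        return out


def make_protocol(
    n_trials_per_condition: int = 3,
    task_dur: float = 120.0,
    rest_dur: float = 80.0,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> ProtocolTimeline:
    """Build a randomised rest/task timeline.

    With the defaults this reproduces the study protocol: three trials of each
    of three 120 s conditions separated by 80 s rests, beginning and ending
    with rest — 9 task epochs, 10 rest epochs, 1880 s in total.

    Parameters
    ----------
    n_trials_per_condition : number of task epochs per condition (>= 1).
    task_dur, rest_dur : epoch durations in seconds (> 0).
    seed : seeds the random ordering of task epochs.
    """
    if task_dur <= 0 or rest_dur <= 0:
        raise InvalidConfigError("task and rest durations must be positive")
    if n_trials_per_condition < 1:
        raise InvalidConfigError("need at least one trial per condition")
    if not conditions:
        raise InvalidConfigError("need at least one condition")

    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(conditions)), n_trials_per_condition)
    rng.shuffle(order)

    epochs: list[Epoch] = []
    t = 0.0
    trial_count = {c: 0 for c in conditions}
    epochs.append(Epoch(REST, 0, t, rest_dur))
    t += rest_dur
    for idx in order:
        cond = conditions[int(idx)]
        trial_count[cond] += 1
        epochs.append(Epoch(cond, trial_count[cond], t, task_dur))
        t += task_dur
        epochs.append(Epoch(REST, 0, t, rest_dur))
        t += rest_dur
    return ProtocolTimeline(tuple(epochs))


def timeline_to_triggers(timeline: ProtocolTimeline) -> list[tuple[float, str]]:
    """Flatten a timeline into (onset, label) trigger events plus a final "end"."""
    trig = [(e.onset, e.condition) for e in timeline.epochs]
    trig.append((timeline.duration, "end"))
    return trig


def timeline_from_triggers(triggers: list[tuple[float, str]]) -> ProtocolTimeline:
    """Rebuild a timeline from trigger events written by :func:`timeline_to_triggers`.

    Trial indices are re-derived from the order of occurrence of each
    condition label.
    """
    if len(triggers) < 2:
        raise InvalidConfigError("need at least one epoch trigger and an end marker")
    trig = sorted(triggers, key=lambda p: p[0])
    epochs: list[Epoch] = []
    trial_count: dict[str, int] = {}
    for (t0, label), (t1, _) in zip(trig[:-1], trig[1:]):
        if label == "end":
            raise InvalidConfigError("'end' marker must be the last trigger")
        if label == REST:
            epochs.append(Epoch(REST, 0, t0, t1 - t0))
        else:
            trial_count[label] = trial_count.get(label, 0) + 1
            epochs.append(Epoch(label, trial_count[label], t0, t1 - t0))
    return ProtocolTimeline(tuple(epochs))
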