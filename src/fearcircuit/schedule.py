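"""Trial protocols for fear conditioning and extinction experiments.

A protocol is an ordered sequence of discrete trials.  Each trial presents a
conditioned stimulus (CS, binary) and an unconditioned stimulus (US, a
nonnegative intensity; 0 means no shock).  Trials are grouped into contiguous
phases -- conditioning, extinction, resting, retrieval, reconditioning -- and
the schedule is the sole stimulus input to both circuit models.

There is no intra-trial time: plasticity in the models is updated once per
trial, so a schedule is purely the event sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PHASE_LABELS = ("conditioning", "extinction", "resting", "retrieval", "reconditioning")

#: phases in which the CS is presented alone (no US allowed)
_CS_ALONE_PHASES = frozenset({"extinction", "retrieval"})


class ScheduleError(ValueError):
    """Raised when a protocol specification is invalid."""


@dataclass(frozen=True)
class Trial:
    """A single discrete trial: CS indicator, US intensity and phase label.

    Invariants enforced on construction:

    * ``us > 0`` implies ``cs == 1`` (a US is only ever delivered paired with
      the CS; unsignaled-shock trials are out of scope),
    * resting trials have ``cs == 0`` and ``us == 0``,
    * extinction and retrieval trials have ``cs == 1`` and ``us == 0``.
    """

    cs: int
    us: float
    phase: str

    def __post_init__(self) -> None:
        if self.cs not in (0, 1):
            raise ScheduleError(f"cs must be 0 or 1, got {self.cs!r}")
        if not np.isfinite(self.us) or self.us < 0:
            raise ScheduleError(f"us intensity must be finite and >= 0, got {self.us!r}")
        if self.phase not in PHASE_LABELS:
            raise ScheduleError(
                f"unknown phase {self.phase!r}; expected one of {PHASE_LABELS}"
            )
        if self.us > 0 and self.cs == 0:
            raise ScheduleError("US-alone trials are out of scope (us > 0 requires cs = 1)")
        if self.phase == "resting" and (self.cs != 0 or self.us != 0):
            raise ScheduleError("resting trials must have cs = 0 and us = 0")
        if self.phase in _CS_ALONE_PHASES and (self.cs != 1 or self.us != 0):
            raise ScheduleError(f"{self.phase} trials must have cs = 1 and us = 0")


@dataclass(frozen=True)
class TrialSchedule:
    """An ordered sequence of trials partitioned into contiguous phase segments.

    ``segments`` is a tuple of ``(label, start, stop)`` half-open index ranges
    partitioning ``trials``.  ``metadata`` records how the schedule was built
    (reinforcement probability, RNG seed, mode) so runs are reproducible.
    """

    trials: tuple[Trial, ...]
    segments: tuple[tuple[str, int, int], ...]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        pos = 0
        for label, start, stop in self.segments:
            if label not in PHASE_LABELS:
                raise ScheduleError(f"unknown phase label {label!r}")
            if start != pos or stop <= start:
                raise ScheduleError("segments must partition the trial sequence in order")
            for t in self.trials[start:stop]:
                if t.phase != label:
                    raise ScheduleError(
                        f"trial in segment {label!r} has phase {t.phase!r}"
                    )
            pos = stop
        if pos != len(self.trials):
            raise ScheduleError("segments do not cover all trials")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def cs(self) -> np.ndarray:
        return np.array([t.cs for t in self.trials], dtype=float)

    @property
    def us(self) -> np.ndarray:
        return np.array([t.us for t in self.trials], dtype=float)

    @property
    def phases(self) -> tuple[str, ...]:
        """Phase label of every trial, in order."""
        return tuple(t.phase for t in self.trials)

    def segments_with_label(self, label: str) -> list[tuple[int, int]]:
        """Index ranges (half-open) of every segment carrying ``label``."""
        return [(a, b) for (lab, a, b) in self.segments if lab == label]

    def phase_slice(self, label: str, which: int = -1) -> slice:
        """Trial-index slice of one segment with ``label`` (default: the last)."""
        segs = self.segments_with_label(label)
        if not segs:
            raise ScheduleError(f"schedule has no {label!r} phase")
        a, b = segs[which]
        return slice(a, b)

    # ------------------------------------------------------------------ I/O

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(len(self.trials)),
                "phase": [t.phase for t in self.trials],
                "cs": [t.cs for t in self.trials],
                "us": [t.us for t in self.trials],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write ``trial,phase,cs,us`` CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "metadata": _jsonable(self.metadata),
            "segments": [list(s) for s in self.segments],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialSchedule":
        path = Path(path)
        df = pd.read_csv(path)
        trials = tuple(
            Trial(cs=int(r.cs), us=float(r.us), phase=str(r.phase))
            for r in df.itertuples()
        )
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            segments = tuple(tuple(s) for s in sidecar.get("segments", []))
            metadata = sidecar.get("metadata", {})
        else:
            segments = _segments_from_labels([t.phase for t in trials])
            metadata = {}
        return cls(trials=trials, segments=segments, metadata=metadata)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _segments_from_labels(labels: Sequence[str]) -> tuple[tuple[str, int, int], ...]:
    segments: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append((labels[start], start, i))
            start = i
    return tuple(segments)


def _single_phase(label: str, trials: Iterable[Trial], metadata: dict) -> TrialSchedule:
    trials = tuple(trials)
    return TrialSchedule(
        trials=trials, segments=((label, 0, len(trials)),), metadata=metadata
    )


def _check_counts(n_trials: int) -> None:
    if not isinstance(n_trials, (int, np.integer)) or n_trials < 1:
        raise ScheduleError(f"n_trials must be a positive integer, got {n_trials!r}")


# ---------------------------------------------------------------- builders


def full_reinforcement(n_trials: int, us_intensity: float = 1.0) -> TrialSchedule:
    """Conditioning with the CS and US paired on every trial."""
    _check_counts(n_trials)
    if us_intensity < 0:
        raise ScheduleError(f"us_intensity must be >= 0, got {us_intensity!r}")
    trials = (Trial(1, float(us_intensity), "conditioning"),) * n_trials
    return _single_phase(
        "conditioning", trials, {"p_us": 1.0, "us_intensity": float(us_intensity)}
    )


def partial_reinforcement(
    n_trials: int,
    p_us: float,
    us_intensity: float = 1.0,
    seed: int | None = None,
    mode: str = "bernoulli",
) -> TrialSchedule:
    """Conditioning with the US delivered on a fraction ``p_us`` of CS trials.

    ``mode="bernoulli"`` draws each trial's US independently with probability
    ``p_us`` from a seeded generator.  ``mode="deterministic_interleave"``
    places ``floor(p_us * n + 0.5)`` US trials as evenly as possible (trial
    ``i`` is reinforced iff ``floor((i+1) p) > floor(i p)``), which gives
    reproducible worked examples without a seed.
    """
    _check_counts(n_trials)
    if not (0 < p_us <= 1):
        raise ScheduleError(f"p_us must be in (0, 1], got {p_us!r}")
    if us_intensity < 0:
        raise ScheduleError(f"us_intensity must be >= 0, got {us_intensity!r}")
    if mode == "bernoulli":
        rng = np.random.default_rng(seed)
        reinforced = rng.random(n_trials) < p_us
    elif mode == "deterministic_interleave":
        i = np.arange(n_trials)
        reinforced = np.floor((i + 1) * p_us) > np.floor(i * p_us)
    else:
        raise ScheduleError(f"unknown mode {mode!r}")
    trials = tuple(
        Trial(1, float(us_intensity) if r else 0.0, "conditioning") for r in reinforced
    )
    return _single_phase(
        "conditioning",
        trials,
        {
            "p_us": float(p_us),
            "us_intensity": float(us_intensity),
            "seed": seed,
            "mode": mode,
        },
    )


def extinction(n_trials: int) -> TrialSchedule:
    """CS-alone trials (US = 0)."""
    _check_counts(n_trials)
    return _single_phase("extinction", (Trial(1, 0.0, "extinction"),) * n_trials, {})


def resting(n_trials: int) -> TrialSchedule:
    """Stimulus-free trials: neither CS nor US is presented."""
    _check_counts(n_trials)
    return _single_phase("resting", (Trial(0, 0.0, "resting"),) * n_trials, {})


def retrieval(n_trials: int) -> TrialSchedule:
    """CS-alone trials probing the memory after a resting period."""
    _check_counts(n_trials)
    return _single_phase("retrieval", (Trial(1, 0.0, "retrieval"),) * n_trials, {})


def concat(*schedules: TrialSchedule) -> TrialSchedule:
    """Concatenate schedules in order, preserving their phase segments."""
    if not schedules:
        raise ScheduleError("concat requires at least one schedule")
    trials: list[Trial] = []
    segments: list[tuple[str, int, int]] = []
    metadata: dict = {}
    offset = 0
    for sched in schedules:
        trials.extend(sched.trials)
        segments.extend((lab, a + offset, b + offset) for (lab, a, b) in sched.segments)
        for k, v in sched.metadata.items():
            metadata.setdefault(k, v)
        offset += len(sched)
    return TrialSchedule(tuple(trials), tuple(segments), metadata)


def shock_procedure(
    base: TrialSchedule,
    us_multiplier: float,
    n_pairings: int,
    n_reextinction: int,
) -> TrialSchedule:
    """Append re-conditioning with a scaled US, then re-extinction, to ``base``.

    The re-conditioning US intensity is ``us_multiplier`` times the base
    conditioning intensity (the strongest US delivered during conditioning).
    ``base`` must end with an extinction phase; with zero pairings and zero
    re-extinction trials the base is returned unchanged.
    """
    if us_multiplier <= 0:
        raise ScheduleError(f"us_multiplier must be > 0, got {us_multiplier!r}")
    if n_pairings < 0 or n_reextinction < 0:
        raise ScheduleError("n_pairings and n_reextinction must be >= 0")
    if base.segments[-1][0] != "extinction":
        raise ScheduleError("shock procedure requires the base to end with extinction")
    if n_pairings == 0 and n_reextinction == 0:
        return base
    cond_us = [t.us for t in base.trials if t.phase == "conditioning" and t.us > 0]
    if not cond_us:
        raise ScheduleError("base has no reinforced conditioning trial to scale")
    base_intensity = max(cond_us)
    parts: list[TrialSchedule] = [base]
    if n_pairings:
        parts.append(
            _single_phase(
                "reconditioning",
                (Trial(1, us_multiplier * base_intensity, "reconditioning"),)
                * n_pairings,
                {},
            )
        )
    if n_reextinction:
        parts.append(extinction(n_reextinction))
    out = concat(*parts)
    out.metadata["us_multiplier"] = float(us_multiplier)
    return out


# Default per-phase trial counts used by the bundled scenarios.  The source
# figures do not state counts; these are long enough for the weight dynamics
# to converge at the default learning rates.
DEFAULT_COUNTS = {
    "conditioning": 60,
    "extinction": 50,
    "resting": 20,
    "retrieval": 5,
    "reextinction": 50,
}
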