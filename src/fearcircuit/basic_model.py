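"""Basic three-unit circuit: fear (F), persistent (P) and extinction (E) units.

Rate-based units driven by the CS through modifiable weights.  The extinction
unit inhibits the fear unit, whose activity is the behavioral freezing
readout.  Per trial,

    F = [w_F CS - w_FE E]_+      (prediction of net severity)
    P = w_P CS                   (prediction of US intensity)
    E = w_E CS                   (prediction of safety / no-US)

and after each trial the CS-input weights change under rectified
prediction-error rules,

    dw_F = a_F CS [US - F]_+
    dw_P = a_P CS [US - P]_+
    dw_E = a_E CS [F (P - US - E)]_+

where [x]_+ = max(x, 0) is the learning signal gating plasticity.  w_F and
w_P follow Rescorla-Wagner learning; w_E grows only when an expressed fear
response (F > 0) coincides with a safety prediction error (P - US - E > 0),
which is what makes extinction of a partially reinforced memory slow and
incomplete (the partial reinforcement extinction effect).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import TrialSchedule


@dataclass(frozen=True)
class BasicParams:
    """Learning rates, the E->F inhibition weight, and the activity floor.

    Defaults are calibrated to the regime where the circuit expresses the
    partial reinforcement extinction effect in graded form: fear acquisition
    converges within the default conditioning phase at every reinforcement
    probability, while safety learning (``alpha_E``) is slow enough that the
    extinction unit is not saturated when extinction begins, so both the
    extinction time constant and the residual fear vary monotonically with
    the reinforcement probability.  ``rectify_activities`` clamps F at 0 (firing rates
    are nonnegative); the unclamped variant is exposed for sensitivity
    analysis.  The clamped F is also the F entering the w_E learning signal.
    """

    alpha_F: float = 0.5
    alpha_P: float = 0.5
    alpha_E: float = 0.05
    w_FE: float = 2.0
    rectify_activities: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_F", "alpha_P", "alpha_E"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        if self.w_FE < 0:
            raise ValueError(f"w_FE must be >= 0, got {self.w_FE!r}")


@dataclass(frozen=True)
class BasicState:
    """Modifiable synaptic weights of the CS input to F, P and E."""

    w_F: float = 0.0
    w_P: float = 0.0
    w_E: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.w_F, self.w_P, self.w_E])


@dataclass(frozen=True)
class TrialRecord:
    """Per-trial snapshot: stimuli, activities, learning signals, weights."""

    trial: int
    phase: str
    cs: int
    us: float
    F: float
    P: float
    E: float
    s_F: float
    s_P: float
    s_E: float
    state_before: BasicState = field(repr=False)
    state_after: BasicState = field(repr=False)


def compute_activities(
    state: BasicState, cs: int, params: BasicParams
) -> tuple[float, float, float]:
    """CS-evoked activities (F, P, E) for the current weights."""
    E = state.w_E * cs
    P = state.w_P * cs
    F = state.w_F * cs - params.w_FE * E
    if params.rectify_activities:
        F = max(F, 0.0)
    return F, P, E


def learning_signals(
    F: float, P: float, E: float, us: float
) -> tuple[float, float, float]:
    """Rectified prediction errors gating plasticity of w_F, w_P, w_E."""
    s_F = max(us - F, 0.0)
    s_P = max(us - P, 0.0)
    s_E = max(F * (P - us - E), 0.0)
    return s_F, s_P, s_E


def update_weights(
    state: BasicState, cs: int, us: float, params: BasicParams
) -> BasicState:
    """One synchronous trial update (signals from the pre-update state)."""
    if cs == 0:
        return state
    F, P, E = compute_activities(state, cs, params)
    s_F, s_P, s_E = learning_signals(F, P, E, us)
    return BasicState(
        w_F=state.w_F + params.alpha_F * cs * s_F,
        w_P=state.w_P + params.alpha_P * cs * s_P,
        w_E=state.w_E + params.alpha_E * cs * s_E,
    )


def run(
    schedule: TrialSchedule,
    params: BasicParams | None = None,
    initial_state: BasicState | None = None,
) -> list[TrialRecord]:
    """Simulate a schedule trial by trial; deterministic given its inputs."""
    params = params or BasicParams()
    state = initial_state or BasicState()
    records: list[TrialRecord] = []
    for i, trial in enumerate(schedule.trials):
        F, P, E = compute_activities(state, trial.cs, params)
        s_F, s_P, s_E = learning_signals(F, P, E, trial.us)
        new_state = update_weights(state, trial.cs, trial.us, params)
        records.append(
            TrialRecord(
                trial=i,
                phase=trial.phase,
                cs=trial.cs,
                us=trial.us,
                F=F,
                P=P,
                E=E,
                s_F=s_F,
                s_P=s_P,
                s_E=s_E,
                state_before=state,
                state_after=new_state,
            )
        )
        state = new_state
    return records


def run_to_convergence(
    us_intensity: float = 1.0,
    params: BasicParams | None = None,
    initial_state: BasicState | None = None,
    tol: float = 1e-9,
    max_trials: int = 10_000,
) -> list[TrialRecord]:
    """Full-reinforcement conditioning until the weight change per trial < tol."""
    from . import schedule as sched_mod

    params = params or BasicParams()
    state = initial_state or BasicState()
    records: list[TrialRecord] = []
    for i in range(max_trials):
        one = sched_mod.full_reinforcement(1, us_intensity)
        rec = run(one, params, state)[0]
        rec = replace(rec, trial=i)
        records.append(rec)
        delta = np.max(np.abs(rec.state_after.as_array() - state.as_array()))
        state = rec.state_after
        if delta < tol:
            break
    return records


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Tabulate a trajectory as ``trial,phase,cs,us,F,P,E,sF,sP,sE,wF,wP,wE``."""
    return pd.DataFrame(
        {
            "trial": [r.trial for r in records],
            "phase": [r.phase for r in records],
            "cs": [r.cs for r in records],
            "us": [r.us for r in records],
            "F": [r.F for r in records],
            "P": [r.P for r in records],
            "E": [r.E for r in records],
            "sF": [r.s_F for r in records],
            "sP": [r.s_P for r in records],
            "sE": [r.s_E for r in records],
            "wF": [r.state_after.w_F for r in records],
            "wP": [r.state_after.w_P for r in records],
            "wE": [r.state_after.w_E for r in records],
        }
    )
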