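"""Extended amygdala-mPFC circuit: LA (P), CEA (F), vmPFC (E1) and ITC (E2).

The persistent and fear roles of the basic model map onto the lateral and
central amygdala; extinction is carried by two units, the vmPFC (E1) and the
GABAergic intercalated cells (E2), with the vmPFC exciting the ITC and the
ITC inhibiting the CEA:

    F  = [w_F CS - w_F,E2 E2]_+
    P  = w_P CS
    E1 = w_E1 CS                       (overridable by perturbation)
    E2 = w_E2 CS + w_E2,E1 E1

Plasticity of w_F, w_P and w_E1 follows the basic model's rectified
prediction-error rules.  The ITC weight w_E2 additionally carries
two-timescale dynamics modelling early- and late-phase LTP (AMPA-receptor
trafficking vs postsynaptic-density growth):

    dw_E2    = a_E2 CS [F (P - US - E2)]_+  -  b_E2    (w_E2 - w_E2inf)
    dw_E2inf = a_E2inf CS E1                -  b_E2inf (w_E2inf - w_E2)

The relaxation (beta) terms carry no CS factor, so they run on every trial
including stimulus-free resting trials: that is the consolidation mechanism,
and it is why spontaneous recovery and the vmPFC's role in consolidation
(but not retrieval) emerge.  The capacity w_E2inf grows only in proportion
to vmPFC activity E1, so silencing the vmPFC during extinction leaves
within-session extinction intact (driven by the fast term) while blocking
consolidation.

Optogenetic-style perturbations clamp the vmPFC's output firing: silencing
sets E1 = 0 and activation sets E1 to a drive level (default: the current LA
activity P, a saturating activation).  The clamped E1 is what reaches the
ITC and the capacity dynamics.  A silenced unit undergoes no postsynaptic
plasticity, so w_E1 is frozen while E1 is clamped to 0; under activation the
clamped E1 enters the w_E1 learning signal, which therefore vanishes when
the drive exceeds the safety prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedule import TrialSchedule


@dataclass(frozen=True)
class ExtendedParams:
    """Learning/relaxation rates and fixed weights of the extended circuit.

    Rates shared with the basic model keep the same defaults, so that with
    consolidation and the vmPFC->ITC coupling switched off the E2 pathway
    reduces exactly to the basic model's E.  The slow (consolidation) rates
    sit well below ``alpha_E2``, giving the fast/slow separation that early-
    vs late-phase plasticity requires; the vmPFC->ITC drive ``w_E2_E1`` is
    deliberately weak, so the vmPFC shapes fear mainly through the slow
    capacity pathway rather than through online inhibition -- which is what
    makes retrieval of the extinction memory vmPFC-independent.
    """

    alpha_F: float = 0.5
    alpha_P: float = 0.5
    alpha_E1: float = 0.05
    alpha_E2: float = 0.05
    beta_E2: float = 0.005
    alpha_E2_inf: float = 0.02
    beta_E2_inf: float = 0.005
    w_F_E2: float = 2.0
    w_E2_E1: float = 0.02
    rectify_activities: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_F", "alpha_P", "alpha_E1", "alpha_E2"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v!r}")
        for name in ("beta_E2", "alpha_E2_inf", "beta_E2_inf"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("w_F_E2", "w_E2_E1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class ExtendedState:
    """Modifiable CS-input weights plus the late-phase capacity of the ITC."""

    w_F: float = 0.0
    w_P: float = 0.0
    w_E1: float = 0.0
    w_E2: float = 0.0
    w_E2_inf: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.w_F, self.w_P, self.w_E1, self.w_E2, self.w_E2_inf])


@dataclass(frozen=True)
class Perturbation:
    """Clamp of the vmPFC unit's output over a window of the schedule.

    ``window`` is either a phase label (applies to every segment with that
    label) or an explicit half-open trial-index range ``(start, stop)``.
    ``mode`` is ``"silence"`` (E1 = 0) or ``"activate"`` (E1 = ``drive``; a
    ``drive`` of None means "clamp to the current LA activity P").
    """

    mode: str
    window: str | tuple[int, int]
    drive: float | None = None
    target: str = "E1"

    def __post_init__(self) -> None:
        if self.target != "E1":
            raise ValueError("only perturbations of the vmPFC unit (E1) are supported")
        if self.mode not in ("silence", "activate"):
            raise ValueError(f"mode must be 'silence' or 'activate', got {self.mode!r}")
        if self.drive is not None and self.drive < 0:
            raise ValueError("activation drive must be >= 0")

    def trial_indices(self, schedule: TrialSchedule) -> set[int]:
        if isinstance(self.window, str):
            segs = schedule.segments_with_label(self.window)
            if not segs:
                raise ValueError(f"schedule has no {self.window!r} phase")
            return {i for a, b in segs for i in range(a, b)}
        a, b = self.window
        if not (0 <= a < b <= len(schedule)):
            raise ValueError(f"perturbation window {self.window!r} outside the schedule")
        return set(range(a, b))


@dataclass(frozen=True)
class ExtendedTrialRecord:
    trial: int
    phase: str
    cs: int
    us: float
    F: float
    P: float
    E1: float
    E2: float
    s_F: float
    s_P: float
    s_E1: float
    s_E2: float
    state_before: ExtendedState = field(repr=False)
    state_after: ExtendedState = field(repr=False)
    perturbed: bool = False


def compute_activities_ext(
    state: ExtendedState,
    cs: int,
    params: ExtendedParams,
    perturbation: Perturbation | None = None,
) -> tuple[float, float, float, float]:
    """Activities (F, P, E1, E2); E1 is clamped first if a perturbation applies."""
    P = state.w_P * cs
    E1 = state.w_E1 * cs
    if perturbation is not None:
        if perturbation.mode == "silence":
            E1 = 0.0
        else:
            E1 = perturbation.drive if perturbation.drive is not None else P
    E2 = state.w_E2 * cs + params.w_E2_E1 * E1
    F = state.w_F * cs - params.w_F_E2 * E2
    if params.rectify_activities:
        F = max(F, 0.0)
        E2 = max(E2, 0.0)
    return F, P, E1, E2


def learning_signals_ext(
    F: float, P: float, E1: float, E2: float, us: float
) -> tuple[float, float, float, float]:
    s_F = max(us - F, 0.0)
    s_P = max(us - P, 0.0)
    s_E1 = max(F * (P - us - E1), 0.0)
    s_E2 = max(F * (P - us - E2), 0.0)
    return s_F, s_P, s_E1, s_E2


def update_weights_ext(
    state: ExtendedState,
    cs: int,
    us: float,
    params: ExtendedParams,
    perturbation: Perturbation | None = None,
) -> ExtendedState:
    """One synchronous trial update.

    The fast (alpha) terms are CS-gated; the relaxation (beta) terms act on
    every trial, including resting trials with cs = 0.  Weights are floored
    at 0 after the update (synaptic efficacies cannot be negative).
    """
    F, P, E1, E2 = compute_activities_ext(state, cs, params, perturbation)
    s_F, s_P, s_E1, s_E2 = learning_signals_ext(F, P, E1, E2, us)
    silenced = perturbation is not None and perturbation.mode == "silence"
    d_E1 = 0.0 if silenced else params.alpha_E1 * cs * s_E1
    w_F = state.w_F + params.alpha_F * cs * s_F
    w_P = state.w_P + params.alpha_P * cs * s_P
    w_E1 = state.w_E1 + d_E1
    w_E2 = (
        state.w_E2
        + params.alpha_E2 * cs * s_E2
        - params.beta_E2 * (state.w_E2 - state.w_E2_inf)
    )
    w_E2_inf = (
        state.w_E2_inf
        + params.alpha_E2_inf * cs * E1
        - params.beta_E2_inf * (state.w_E2_inf - state.w_E2)
    )
    return ExtendedState(
        w_F=max(w_F, 0.0),
        w_P=max(w_P, 0.0),
        w_E1=max(w_E1, 0.0),
        w_E2=max(w_E2, 0.0),
        w_E2_inf=max(w_E2_inf, 0.0),
    )


def _perturbation_map(
    schedule: TrialSchedule, perturbations: list[Perturbation]
) -> dict[int, Perturbation]:
    """Trial index -> perturbation; contradictory overlaps are rejected."""
    mapping: dict[int, Perturbation] = {}
    for pert in perturbations:
        for i in pert.trial_indices(schedule):
            if i in mapping and mapping[i] != pert:
                raise ValueError(
                    f"contradictory perturbations overlap at trial {i}: "
                    f"{mapping[i]} vs {pert}"
                )
            mapping[i] = pert
    return mapping


def run_ext(
    schedule: TrialSchedule,
    params: ExtendedParams | None = None,
    initial_state: ExtendedState | None = None,
    perturbations: list[Perturbation] | None = None,
) -> list[ExtendedTrialRecord]:
    """Simulate a schedule under optional vmPFC perturbations."""
    params = params or ExtendedParams()
    state = initial_state or ExtendedState()
    pert_map = _perturbation_map(schedule, perturbations or [])
    records: list[ExtendedTrialRecord] = []
    for i, trial in enumerate(schedule.trials):
        pert = pert_map.get(i)
        F, P, E1, E2 = compute_activities_ext(state, trial.cs, params, pert)
        s_F, s_P, s_E1, s_E2 = learning_signals_ext(F, P, E1, E2, trial.us)
        if pert is not None and pert.mode == "silence":
            s_E1 = 0.0  # no postsynaptic activity, no plasticity at the CS->vmPFC synapse
        new_state = update_weights_ext(state, trial.cs, trial.us, params, pert)
        records.append(
            ExtendedTrialRecord(
                trial=i,
                phase=trial.phase,
                cs=trial.cs,
                us=trial.us,
                F=F,
                P=P,
                E1=E1,
                E2=E2,
                s_F=s_F,
                s_P=s_P,
                s_E1=s_E1,
                s_E2=s_E2,
                state_before=state,
                state_after=new_state,
                perturbed=pert is not None,
            )
        )
        state = new_state
    return records


def run_shock_experiment(
    base_protocol: TrialSchedule,
    us_multiplier_grid: list[float],
    params: ExtendedParams | None = None,
    n_pairings: int = 1,
    n_reextinction: int = 50,
) -> pd.DataFrame:
    """Final CEA activity after re-extinction, for each US multiplier.

    For every multiplier the base protocol (which must end with extinction)
    is extended with ``n_pairings`` re-conditioning trials at the scaled US
    intensity followed by ``n_reextinction`` extinction trials, and the fear
    unit's activity on the last trial is reported.
    """
    from .schedule import shock_procedure

    if not us_multiplier_grid:
        raise ValueError("us_multiplier_grid must be non-empty")
    rows = []
    for mult in us_multiplier_grid:
        sched = shock_procedure(base_protocol, mult, n_pairings, n_reextinction)
        records = run_ext(sched, params)
        rows.append({"us_multiplier": float(mult), "final_F": records[-1].F})
    return pd.DataFrame(rows)


def records_to_frame_ext(records: list[ExtendedTrialRecord]) -> pd.DataFrame:
    """Tabulate with columns ``...,F,P,E1,E2,sF,...,wF,...,wE2inf``."""
    return pd.DataFrame(
        {
            "trial": [r.trial for r in records],
            "phase": [r.phase for r in records],
            "cs": [r.cs for r in records],
            "us": [r.us for r in records],
            "F": [r.F for r in records],
            "P": [r.P for r in records],
            "E1": [r.E1 for r in records],
            "E2": [r.E2 for r in records],
            "sF": [r.s_F for r in records],
            "sP": [r.s_P for r in records],
            "sE1": [r.s_E1 for r in records],
            "sE2": [r.s_E2 for r in records],
            "wF": [r.state_after.w_F for r in records],
            "wP": [r.state_after.w_P for r in records],
            "wE1": [r.state_after.w_E1 for r in records],
            "wE2": [r.state_after.w_E2 for r in records],
            "wE2inf": [r.state_after.w_E2_inf for r in records],
        }
    )
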