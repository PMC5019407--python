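"""Named scenario presets: the standard simulated experiments.

Each preset bundles a schedule, a model choice, parameters and (for the
extended model) perturbations, so every figure-style experiment is runnable
end to end with defaults:

* ``fig2_full`` / ``fig2_partial`` -- basic model, full vs seeded partial
  (p = 0.5) reinforcement conditioning followed by extinction (the PREE
  comparison).
* ``fig3_control`` and the four ``fig3_*`` perturbation variants -- extended
  model, conditioning + extinction + resting + retrieval, with the vmPFC
  activated or silenced during extinction or retrieval.
* ``fig4_shock_x3`` / ``fig4_shock_x1`` -- extended model, the shock
  procedure: partial conditioning, extinction, one re-conditioning pairing
  with a 3x (or 1x) US, then re-extinction.
* ``s2_alternating`` -- basic model, repeated full-reinforcement
  conditioning/extinction cycles (the accumulating-residual protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

from . import basic_model, extended_model, schedule as S
from .extended_model import Perturbation

DEFAULT_SEED = 7


@dataclass
class Scenario:
    name: str
    model: str
    schedule: S.TrialSchedule
    params: Any
    perturbations: list = field(default_factory=list)
    seed: int | None = None


@dataclass(frozen=True)
class Preset:
    name: str
    description: str
    _builder: Callable[..., Scenario]

    def build(self, seed: int | None = None, params: dict | None = None, **kwargs) -> Scenario:
        return self._builder(seed=seed, param_overrides=params or {}, **kwargs)


def _counts(**overrides) -> dict:
    c = dict(S.DEFAULT_COUNTS)
    c.update(overrides)
    return c


def _basic_params(overrides: dict) -> basic_model.BasicParams:
    return basic_model.BasicParams(**overrides)


def _ext_params(overrides: dict) -> extended_model.ExtendedParams:
    return extended_model.ExtendedParams(**overrides)


def _fig2(seed, param_overrides, p_us=1.0):
    c = _counts()
    seed = DEFAULT_SEED if seed is None else seed
    if p_us >= 1.0:
        cond = S.full_reinforcement(c["conditioning"], 1.0)
    else:
        cond = S.partial_reinforcement(c["conditioning"], p_us, 1.0, seed=seed)
    sched = S.concat(cond, S.extinction(c["extinction"]))
    name = "fig2_full" if p_us >= 1.0 else "fig2_partial"
    return Scenario(name, "basic", sched, _basic_params(param_overrides), seed=seed)


def _fig3_schedule() -> S.TrialSchedule:
    c = _counts()
    return S.concat(
        S.full_reinforcement(c["conditioning"], 1.0),
        S.extinction(c["extinction"]),
        S.resting(c["resting"]),
        S.retrieval(c["retrieval"]),
    )


def _fig3(seed, param_overrides, mode=None, window=None):
    perts = [] if mode is None else [Perturbation(mode, window)]
    name = "fig3_control" if mode is None else f"fig3_{mode[:3]}_{window[:3]}"
    return Scenario(name, "extended", _fig3_schedule(), _ext_params(param_overrides),
                    perturbations=perts, seed=seed)


def _fig4(seed, param_overrides, multiplier=3.0):
    c = _counts()
    seed = DEFAULT_SEED if seed is None else seed
    base = S.concat(
        S.partial_reinforcement(c["conditioning"], 0.5, 1.0, seed=seed),
        S.extinction(c["extinction"]),
    )
    sched = S.shock_procedure(base, multiplier, 1, c["reextinction"])
    name = f"fig4_shock_x{int(multiplier)}"
    return Scenario(name, "extended", sched, _ext_params(param_overrides), seed=seed)


def _s2(seed, param_overrides, n_sessions=5):
    c = _counts()
    parts = []
    for _ in range(n_sessions):
        parts += [S.full_reinforcement(c["conditioning"], 1.0), S.extinction(c["extinction"])]
    return Scenario("s2_alternating", "basic", S.concat(*parts),
                    _basic_params(param_overrides), seed=seed)


PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        Preset("fig2_full", "basic model, full reinforcement then extinction",
               lambda seed, param_overrides: _fig2(seed, param_overrides, 1.0)),
        Preset("fig2_partial", "basic model, partial (p=0.5) reinforcement then extinction",
               lambda seed, param_overrides: _fig2(seed, param_overrides, 0.5)),
        Preset("fig3_control", "extended model, conditioning/extinction/resting/retrieval",
               lambda seed, param_overrides: _fig3(seed, param_overrides)),
        Preset("fig3_act_ext", "vmPFC activation during extinction",
               lambda seed, param_overrides: _fig3(seed, param_overrides, "activate", "extinction")),
        Preset("fig3_act_ret", "vmPFC activation during retrieval",
               lambda seed, param_overrides: _fig3(seed, param_overrides, "activate", "retrieval")),
        Preset("fig3_sil_ext", "vmPFC silencing during extinction",
               lambda seed, param_overrides: _fig3(seed, param_overrides, "silence", "extinction")),
        Preset("fig3_sil_ret", "vmPFC silencing during retrieval",
               lambda seed, param_overrides: _fig3(seed, param_overrides, "silence", "retrieval")),
        Preset("fig4_shock_x3", "shock procedure with a 3x-stronger US",
               lambda seed, param_overrides: _fig4(seed, param_overrides, 3.0)),
        Preset("fig4_shock_x1", "shock-procedure control with a same-intensity US",
               lambda seed, param_overrides: _fig4(seed, param_overrides, 1.0)),
        Preset("s2_alternating", "repeated conditioning/extinction cycles (basic model)",
               lambda seed, param_overrides: _s2(seed, param_overrides)),
    ]
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        available = ", ".join(sorted(PRESETS))
        raise KeyError(f"unknown scenario {name!r}; available presets: {available}") from None
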