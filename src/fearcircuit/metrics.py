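"""Uncertainty, extinction-speed and residual-fear metrics.

Quantifies the partial-reinforcement analysis: the Shannon entropy of the
waiting time until the next US, the time constant of fear decay during
extinction (exponential fit), and the residual fear activity at the end of
extinction, swept over the reinforcement probability.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import basic_model, schedule as sched_mod


def waiting_time_entropy(p_us: float, base: float = 2.0) -> float:
    """Entropy of the geometric waiting time until the next US observation.

    Under reinforcement probability ``p``, the number of CS trials until the
    next US is geometric, P(n) = p (1-p)^(n-1) for n = 1, 2, ....  Its
    Shannon entropy has the closed form H = h(p) / p, with h the binary
    entropy; in bits by default (``base=np.e`` gives nats).  Uncertainty is
    maximal as p -> 0 and vanishes at p = 1.
    """
    if not (0 < p_us <= 1):
        raise ValueError(f"p_us must be in (0, 1], got {p_us!r}")
    if p_us == 1.0:
        return 0.0
    q = 1.0 - p_us
    h_binary = -(p_us * np.log(p_us) + q * np.log(q))
    return float(h_binary / p_us / np.log(base))


@dataclass(frozen=True)
class ExtinctionFit:
    """Exponential decay fit F(t) = F1 exp(-t / tau) + F0 over extinction."""

    F0: float
    F1: float
    tau: float
    rss: float
    converged: bool


def fit_extinction_time_constant(
    f_series: Sequence[float],
    amplitude_tol: float = 1e-8,
) -> ExtinctionFit:
    """Least-squares fit of ``F1 exp(-t/tau) + F0`` to a fear-activity series.

    ``t`` counts extinction trials from 0 at the first sample.  F0 and F1
    are constrained nonnegative and tau positive.  ``converged`` is False
    when the optimizer fails or the fitted amplitude is below
    ``amplitude_tol`` (a flat series carries no time constant).
    """
    y = np.asarray(f_series, dtype=float)
    if y.ndim != 1 or len(y) < 4:
        raise ValueError("f_series must be a 1-D sequence of length >= 4")
    if np.any(~np.isfinite(y)) or np.any(y < 0):
        raise ValueError("f_series must be finite and nonnegative")
    t = np.arange(len(y), dtype=float)

    def model(t, F1, tau, F0):
        return F1 * np.exp(-t / tau) + F0

    f0_init = max(y[-1], 0.0)
    f1_init = max(y[0] - y[-1], amplitude_tol)
    tau_init = max(len(y) / 3.0, 1e-3)
    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[f1_init, tau_init, f0_init],
            bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError:
        return ExtinctionFit(F0=np.nan, F1=np.nan, tau=np.nan, rss=np.nan, converged=False)
    F1_hat, tau_hat, F0_hat = popt
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    converged = bool(F1_hat >= amplitude_tol and np.isfinite(tau_hat))
    return ExtinctionFit(
        F0=float(F0_hat), F1=float(F1_hat), tau=float(tau_hat), rss=rss,
        converged=converged,
    )


def residual_fear(records: list, phase: str, which: int = -1) -> float:
    """Fear-unit activity on the final trial of the named phase.

    ``records`` is a basic- or extended-model trajectory; with repeated
    phases (alternating protocols), ``which`` selects the segment in order
    of occurrence (default: the last).
    """
    segments: list[list] = []
    current_label = None
    for r in records:
        if r.phase != current_label:
            segments.append([])
            current_label = r.phase
        if r.phase == phase:
            segments[-1].append(r)
    segments = [s for s in segments if s]
    if not segments:
        raise ValueError(f"trajectory contains no {phase!r} phase")
    return segments[which][-1].F


def extinction_fear_series(records: list, which: int = -1) -> np.ndarray:
    """Fear activity over one extinction segment of a trajectory."""
    segs: list[list[float]] = []
    prev = None
    for r in records:
        if r.phase == "extinction":
            if prev != "extinction":
                segs.append([])
            segs[-1].append(r.F)
        prev = r.phase
    if not segs:
        raise ValueError("trajectory contains no extinction phase")
    return np.asarray(segs[which], dtype=float)


def pree_curves(
    p_grid: Sequence[float],
    params: basic_model.BasicParams | None = None,
    n_conditioning: int = sched_mod.DEFAULT_COUNTS["conditioning"],
    n_extinction: int = sched_mod.DEFAULT_COUNTS["extinction"],
    us_intensity: float = 1.0,
) -> pd.DataFrame:
    """Sweep the reinforcement probability and tabulate the PREE quantities.

    For each p, the basic model is conditioned on an evenly interleaved
    partial-reinforcement schedule and extinguished, and four quantities are
    reported: the waiting-time entropy (bits), the fitted extinction time
    constant (trials; NaN when no decay is fittable), the residual fear at
    the end of extinction, and the extinction unit's learning signal on the
    first extinction trial.
    """
    params = params or basic_model.BasicParams()
    rows = []
    for p in p_grid:
        sched = sched_mod.concat(
            sched_mod.partial_reinforcement(
                n_conditioning, p, us_intensity, mode="deterministic_interleave"
            ),
            sched_mod.extinction(n_extinction),
        )
        records = basic_model.run(sched, params)
        ext_slice = sched.phase_slice("extinction")
        ext_records = records[ext_slice]
        fit = fit_extinction_time_constant([r.F for r in ext_records])
        rows.append(
            {
                "p": float(p),
                "entropy_bits": waiting_time_entropy(p),
                "tau": fit.tau if fit.converged else np.nan,
                "residual_F": ext_records[-1].F,
                "sE_onset": ext_records[0].s_E,
            }
        )
    return pd.DataFrame(rows)
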