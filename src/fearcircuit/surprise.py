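"""Sequential Bayesian estimation of the US probability, and trialwise surprise.

A statistical observer for the same trial stream the circuit models see: a
Bayesian logistic regression over features (intercept, CS) with a Gaussian
weight summary, updated one trial at a time.  On each CS trial the
posterior-predictive probability of the US, p_t, defines two information
quantities,

    surprise_US    = -log p_t        (realized when the US occurs)
    surprise_no-US = -log (1 - p_t)  (realized when it does not)

which the circuit model's learning signals are compared against.

Because the feature vector is the same on every CS trial, the Bernoulli
likelihood constrains the weights only through the single linear score
a = w0 + w1, and the exact posterior is the Gaussian prior tilted along that
one direction by sigma(a)^n1 * sigma(-a)^n0, where (n1, n0) count the US and
no-US outcomes seen so far.  The sequential update therefore tracks the
exact posterior: it increments the counts and recomputes the exact first
two moments of the score by mode-centred Gauss-Hermite quadrature, from
which the exact weight-space mean and covariance follow in closed form.
The predictive uses the standard probit approximation to the
logistic-Gaussian integral.  ``GridBayesOracle`` performs the same
computation by brute force on a dense 2-D weight grid, as an independent
validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit, log_expit, roots_hermite
from scipy.stats import pearsonr

from .schedule import TrialSchedule

_GH_NODES, _GH_WEIGHTS = roots_hermite(81)
_GH_LOG_WEIGHTS = np.log(_GH_WEIGHTS)
_LAMBDA = np.pi / 8.0  # probit-logit matching constant


def _score_log_posterior(a, a0, s2, n1, n0):
    return -0.5 * (a - a0) ** 2 / s2 + n1 * log_expit(a) + n0 * log_expit(-a)


def _score_moments(a0: float, s2: float, n1: int, n0: int) -> tuple[float, float]:
    """Exact mean and variance of the tilted score distribution
    N(a; a0, s2) * sigma(a)^n1 * sigma(-a)^n0, by quadrature centred on the
    posterior mode (robust even when the likelihood dominates the prior)."""
    if n1 == 0 and n0 == 0:
        return a0, s2
    # Newton iterations for the unimodal, log-concave 1-D posterior
    a = a0
    for _ in range(50):
        sig = expit(a)
        grad = -(a - a0) / s2 + n1 * (1.0 - sig) - n0 * sig
        hess = -1.0 / s2 - (n1 + n0) * sig * (1.0 - sig)
        step = grad / hess
        a -= step
        if abs(step) < 1e-13:
            break
    mode, scale = a, np.sqrt(-1.0 / hess)
    nodes = mode + np.sqrt(2.0) * scale * _GH_NODES
    logw = _GH_LOG_WEIGHTS + _GH_NODES**2 + _score_log_posterior(nodes, a0, s2, n1, n0)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    m = float(np.sum(w * nodes))
    v = float(np.sum(w * (nodes - m) ** 2))
    return m, v


@dataclass(frozen=True)
class SurprisePosterior:
    """Posterior over the logistic-regression weights (intercept, CS).

    ``mean`` and ``cov`` are the exact first two moments of the weight
    posterior given the Gaussian prior and the outcome counts accumulated so
    far.  A posterior constructed directly from a mean and covariance is
    treated as a fresh Gaussian prior with no observations.
    """

    mean: np.ndarray = field(default_factory=lambda: np.zeros(2))
    cov: np.ndarray = field(default_factory=lambda: np.eye(2))
    prior_mean: np.ndarray | None = field(default=None, repr=False)
    prior_cov: np.ndarray | None = field(default=None, repr=False)
    n_us: int = 0
    n_no_us: int = 0

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if mean.shape != (2,) or cov.shape != (2, 2):
            raise ValueError("posterior is over 2 weights: (intercept, CS)")
        if not np.allclose(cov, cov.T) or np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("covariance must be symmetric positive definite")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if self.prior_mean is None:
            object.__setattr__(self, "prior_mean", mean)
            object.__setattr__(self, "prior_cov", cov)
            object.__setattr__(self, "n_us", 0)
            object.__setattr__(self, "n_no_us", 0)


def _features(cs: int) -> np.ndarray:
    return np.array([1.0, float(cs)])


def predictive_us_probability(posterior: SurprisePosterior, cs: int = 1) -> float:
    """Posterior-predictive P(US | CS) via the probit approximation.

    Defined on CS trials only; strictly inside (0, 1).
    """
    if cs != 1:
        raise ValueError("the US prediction is defined on CS trials (cs = 1)")
    x = _features(cs)
    m = float(x @ posterior.mean)
    s2 = float(x @ posterior.cov @ x)
    p = float(expit(m / np.sqrt(1.0 + _LAMBDA * s2)))
    eps = np.finfo(float).tiny
    return min(max(p, eps), 1.0 - eps)


def update_posterior(
    posterior: SurprisePosterior, cs: int, us_observed: int
) -> SurprisePosterior:
    """One-trial Bayesian update with the observed US outcome (0 or 1).

    The returned posterior's mean and covariance are the exact moments of
    the prior tilted by all outcomes seen so far: the likelihood acts along
    the single score direction x = (1, 1), so with score moments (m, v) the
    weight posterior has mean ``mu + Sigma x (m - a0) / s2`` and covariance
    ``Sigma + (Sigma x)(Sigma x)^T (v - s2) / s2^2`` exactly.  Deterministic.
    """
    if cs != 1:
        raise ValueError("updates are defined on CS trials (cs = 1)")
    if us_observed not in (0, 1):
        raise ValueError("us_observed must be the binary US outcome")
    n1 = posterior.n_us + int(us_observed)
    n0 = posterior.n_no_us + int(1 - us_observed)
    x = _features(cs)
    mu0 = np.asarray(posterior.prior_mean)
    cov0 = np.asarray(posterior.prior_cov)
    sigma_x = cov0 @ x
    a0 = float(x @ mu0)
    s2 = float(x @ sigma_x)
    m, v = _score_moments(a0, s2, n1, n0)
    mean = mu0 + sigma_x * ((m - a0) / s2)
    cov = cov0 + np.outer(sigma_x, sigma_x) * ((v - s2) / s2**2)
    cov = (cov + cov.T) / 2.0
    return SurprisePosterior(
        mean=mean, cov=cov, prior_mean=mu0, prior_cov=cov0, n_us=n1, n_no_us=n0
    )


@dataclass(frozen=True)
class SurpriseRecord:
    """Per-CS-trial predictive probability and both surprise branches."""

    trial: int
    cs: int
    us_observed: int
    p_us: float
    surprise_us: float
    surprise_no_us: float

    @property
    def realized_surprise(self) -> float:
        return self.surprise_us if self.us_observed else self.surprise_no_us


def surprise_series(
    schedule: TrialSchedule,
    prior: SurprisePosterior | None = None,
    base: float = np.e,
    max_surprise: float = 30.0,
) -> list[SurpriseRecord]:
    """Predict-then-update over every CS trial of a schedule.

    Stimulus-free (resting) trials carry no prediction and are skipped.
    Surprise is the information content of the outcome, in nats by default
    (``base=2`` for bits), capped at ``max_surprise`` for numerical safety.
    """
    posterior = prior or SurprisePosterior()
    log_base = np.log(base)
    records: list[SurpriseRecord] = []
    for i, trial in enumerate(schedule.trials):
        if trial.cs == 0:
            continue
        y = int(trial.us > 0)
        p = predictive_us_probability(posterior, trial.cs)
        s_us = min(-np.log(p) / log_base, max_surprise)
        s_no = min(-np.log(1.0 - p) / log_base, max_surprise)
        records.append(
            SurpriseRecord(
                trial=i, cs=trial.cs, us_observed=y, p_us=p,
                surprise_us=float(s_us), surprise_no_us=float(s_no),
            )
        )
        posterior = update_posterior(posterior, trial.cs, y)
    if not records:
        raise ValueError("schedule contains no CS trials")
    return records


@dataclass(frozen=True)
class SignalSurpriseCorrelation:
    """Pearson correlations between circuit learning signals and surprise."""

    r_us: float
    r_no_us: float
    n_us: int
    n_no_us: int
    valid_us: bool
    valid_no_us: bool


def correlate_signal_surprise(
    circuit_records: Sequence,
    surprise_records: Sequence[SurpriseRecord],
) -> SignalSurpriseCorrelation:
    """Correlate learning signals with the realized surprise, trial by trial.

    US-side: the fear and persistent units' learning signals (s_F, s_P) are
    pooled against the US surprise on reinforced trials.  No-US side: the
    extinction unit's signal s_E against the no-US surprise on unreinforced
    CS trials.  Trials where a branch is not realized are excluded (during
    extinction the US surprise and s_F are identically 0 and carry no
    information).  A zero-variance side is flagged invalid (r = NaN).
    """
    by_trial = {s.trial: s for s in surprise_records}
    us_pairs: list[tuple[float, float]] = []
    no_us_pairs: list[tuple[float, float]] = []
    for rec in circuit_records:
        s = by_trial.get(rec.trial)
        if s is None or rec.cs != 1:
            continue
        if s.us_observed:
            us_pairs.append((rec.s_F, s.surprise_us))
            us_pairs.append((rec.s_P, s.surprise_us))
        else:
            s_ext = rec.s_E if hasattr(rec, "s_E") else rec.s_E2
            no_us_pairs.append((s_ext, s.surprise_no_us))
    if len(us_pairs) < 3 or len(no_us_pairs) < 3:
        raise ValueError("need at least 3 trial pairs on each side to correlate")

    def _corr(pairs: list[tuple[float, float]]) -> tuple[float, bool]:
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            return float("nan"), False
        return float(pearsonr(a, b).statistic), True

    r_us, valid_us = _corr(us_pairs)
    r_no, valid_no = _corr(no_us_pairs)
    return SignalSurpriseCorrelation(
        r_us=r_us, r_no_us=r_no,
        n_us=len(us_pairs), n_no_us=len(no_us_pairs),
        valid_us=valid_us, valid_no_us=valid_no,
    )


class GridBayesOracle:
    """Exact sequential Bayes on a dense 2-D weight grid (validation oracle).

    Maintains the unnormalized log posterior over (intercept, CS-weight) on
    a regular grid and exposes its mean, covariance and exact predictive by
    numerical integration.  Slow by design; used to validate the sequential
    quadrature update.
    """

    def __init__(
        self,
        prior: SurprisePosterior | None = None,
        half_width: float = 8.0,
        n_points: int = 321,
    ) -> None:
        prior = prior or SurprisePosterior()
        sd = np.sqrt(np.diag(prior.cov))
        self.w0 = np.linspace(
            prior.mean[0] - half_width * sd[0], prior.mean[0] + half_width * sd[0], n_points
        )
        self.w1 = np.linspace(
            prior.mean[1] - half_width * sd[1], prior.mean[1] + half_width * sd[1], n_points
        )
        g0, g1 = np.meshgrid(self.w0, self.w1, indexing="ij")
        self._w = np.stack([g0, g1], axis=-1)
        diff = self._w - prior.mean
        prec = np.linalg.inv(prior.cov)
        self._log_post = -0.5 * np.einsum("...i,ij,...j->...", diff, prec, diff)

    def update(self, cs: int, us_observed: int) -> None:
        a = self._w @ _features(cs)
        self._log_post = self._log_post + (log_expit(a) if us_observed else log_expit(-a))
        self._log_post -= self._log_post.max()

    @property
    def _density(self) -> np.ndarray:
        d = np.exp(self._log_post)
        return d / d.sum()

    def mean(self) -> np.ndarray:
        d = self._density
        return np.einsum("ij,ijk->k", d, self._w)

    def cov(self) -> np.ndarray:
        d = self._density
        mu = self.mean()
        diff = self._w - mu
        return np.einsum("ij,ijk,ijl->kl", d, diff, diff)

    def predictive_us_probability(self, cs: int = 1) -> float:
        a = self._w @ _features(cs)
        return float(np.sum(self._density * expit(a)))
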