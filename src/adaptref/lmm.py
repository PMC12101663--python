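"""Population-informed adaptive reference ranges via a random-intercept LMM.

Model: ``Y_ij = mu_i + eps_ij`` with ``mu_i ~ N(mu, tau2)`` and
``eps_ij ~ N(0, sigma2_i)`` -- a random intercept per subject and a
*subject-specific* residual variance.  Parameters are estimated by EM
treating the intercepts as latent:

E-step (per subject, from sufficient statistics ``n_i``, ``ybar_i``,
``ss_i``)::

    v_i = 1 / (1/tau2 + n_i/sigma2_i)
    m_i = v_i * (mu/tau2 + n_i*ybar_i/sigma2_i)

M-step::

    mu      = mean_i(m_i)
    tau2    = mean_i((m_i - mu)^2 + v_i)
    sigma2_i = (ss_i + n_i*(ybar_i - m_i)^2 + n_i*v_i) / n_i

The marginal log-likelihood is available in closed form and is guaranteed
non-decreasing across iterations; the fit records its trace.

Given a fitted population, the reference range for a subject's occasion
``j`` (with ``j - 1`` prior values of mean ``ybar``) shrinks the subject
mean toward the population mean::

    centre = (mu/tau2 + (j-1)*ybar/sigma2_i) / (1/tau2 + (j-1)/sigma2_i)
    half   = z * sqrt( 1/(1/tau2 + (j-1)/sigma2_i) + sigma2_i )

with ``z`` the Normal quantile at the requested level.  At ``j = 1`` this
is the population prediction interval; as ``j`` grows it approaches the
subject's own interval.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import (
    LongitudinalSeries,
    NotFittedError,
    ReferenceRange,
    SubjectSummary,
    _check_alpha,
    _check_sidedness,
)

__all__ = [
    "PopulationModel",
    "LmmRangeState",
    "fit_population_em",
    "update_subject_variance",
    "lmm_range",
    "marginal_loglik",
]

METHOD = "lmm"

#: Variance floor applied to tau2 and every sigma2_i, keeping ranges finite.
VAR_FLOOR = 1e-8

#: Pseudo-observation count for the pooled-shrinkage working variance.
DEFAULT_PSEUDO_OBS = 3.0


@dataclass
class PopulationModel:
    """Fitted population parameters and per-subject posteriors."""

    mu: float
    tau2: float
    sigma2_by_subject: dict[str, float]
    sigma2_pooled: float
    posterior_by_subject: dict[str, tuple[float, float]]
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "tau2": self.tau2,
            "sigma2_by_subject": self.sigma2_by_subject,
            "sigma2_pooled": self.sigma2_pooled,
            "posterior_by_subject": {
                k: list(v) for k, v in self.posterior_by_subject.items()
            },
            "loglik_trace": self.loglik_trace,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "degenerate": self.degenerate,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            mu=float(d["mu"]),
            tau2=float(d["tau2"]),
            sigma2_by_subject={k: float(v) for k, v in d["sigma2_by_subject"].items()},
            sigma2_pooled=float(d["sigma2_pooled"]),
            posterior_by_subject={
                k: (float(v[0]), float(v[1]))
                for k, v in d["posterior_by_subject"].items()
            },
            loglik_trace=[float(x) for x in d.get("loglik_trace", [])],
            converged=bool(d.get("converged", False)),
            n_iter=int(d.get("n_iter", 0)),
            degenerate=bool(d.get("degenerate", False)),
        )

    @classmethod
    def from_json(cls, path) -> "PopulationModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class LmmRangeState:
    """Per-occasion quantities for one assessed subject.

    ``n_history`` is ``j - 1`` (prior observation count), ``history_mean``
    their mean (ignored when ``n_history == 0``) and ``sigma2`` the working
    within-subject variance plugged into the range formula.
    """

    n_history: int
    history_mean: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.n_history < 0:
            raise ValueError("n_history must be >= 0")
        if not (self.sigma2 > 0):
            raise ValueError("sigma2 must be positive")

    @classmethod
    def for_new_subject(cls, model: "PopulationModel") -> "LmmRangeState":
        """State at occasion 1: no history, pooled within-subject variance."""
        return cls(n_history=0, history_mean=0.0, sigma2=model.sigma2_pooled)

    @classmethod
    def from_history(
        cls,
        model: "PopulationModel",
        history: SubjectSummary,
        pseudo_obs: float = DEFAULT_PSEUDO_OBS,
    ) -> "LmmRangeState":
        return cls(
            n_history=history.n,
            history_mean=history.mean if history.n else 0.0,
            sigma2=update_subject_variance(model, history, pseudo_obs=pseudo_obs),
        )


def marginal_loglik(
    n: np.ndarray, ybar: np.ndarray, ss: np.ndarray,
    mu: float, tau2: float, sigma2: np.ndarray,
) -> float:
    """Exact marginal log-likelihood from per-subject sufficient statistics.

    Integrating out the random intercept, ``Y_i`` is multivariate Normal with
    compound-symmetric covariance; its density depends on the data only
    through ``(n_i, ybar_i, ss_i)``.
    """
    total_var = sigma2 + n * tau2
    ll = -0.5 * (
        n * math.log(2.0 * math.pi)
        + (n - 1) * np.log(sigma2)
        + np.log(total_var)
        + ss / sigma2
        + n * (ybar - mu) ** 2 / total_var
    )
    return float(np.sum(ll))


def _suff_stats(control: Sequence[LongitudinalSeries]):
    n = np.array([len(s) for s in control], dtype=float)
    ybar = np.array([float(np.mean(s.values)) for s in control])
    ss = np.array(
        [float(np.sum((s.values - np.mean(s.values)) ** 2)) for s in control]
    )
    return n, ybar, ss


def fit_population_em(
    control: Sequence[LongitudinalSeries],
    *,
    rtol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = VAR_FLOOR,
) -> PopulationModel:
    """Fit the heteroscedastic random-intercept model by EM.

    Parameters
    ----------
    control
        At least two subjects, each with at least one observation and at
        least one subject with two or more.
    rtol
        Relative change of the marginal log-likelihood below which the
        iteration stops.
    max_iter
        Iteration cap; ``converged`` is reported honestly.
    var_floor
        Lower bound applied to ``tau2`` and every ``sigma2_i``.

    Returns
    -------
    PopulationModel
        With a ``degenerate`` warning flag when all variances collapsed to
        the floor (e.g. constant data).
    """
    if len(control) < 2:
        raise ValueError("need at least two subjects to fit the population model")
    if all(len(s) < 2 for s in control):
        raise ValueError("need at least one subject with two or more observations")

    n, ybar, ss = _suff_stats(control)
    ids = [s.subject_id for s in control]

    # Initialisation: grand mean; between-variance from subject means;
    # within-variance from each subject's own sample variance.
    mu = float(np.sum(n * ybar) / np.sum(n))
    tau2 = max(float(np.var(ybar, ddof=1)), var_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(n >= 2, ss / np.maximum(n - 1.0, 1.0), np.nan)
    fallback = np.nanmean(s2) if np.isfinite(np.nanmean(s2)) else var_floor
    sigma2 = np.where(np.isfinite(s2) & (s2 > 0), s2, max(fallback, var_floor))
    sigma2 = np.maximum(sigma2, var_floor)

    trace = [marginal_loglik(n, ybar, ss, mu, tau2, sigma2)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        v = 1.0 / (1.0 / tau2 + n / sigma2)
        m = v * (mu / tau2 + n * ybar / sigma2)
        # M-step
        mu = float(np.mean(m))
        tau2 = max(float(np.mean((m - mu) ** 2 + v)), var_floor)
        sigma2 = np.maximum((ss + n * (ybar - m) ** 2 + n * v) / n, var_floor)

        ll = marginal_loglik(n, ybar, ss, mu, tau2, sigma2)
        trace.append(ll)
        if abs(ll - trace[-2]) <= rtol * (abs(trace[-2]) + 1e-12):
            converged = True
            break

    # Final posteriors at the fitted parameters.
    v = 1.0 / (1.0 / tau2 + n / sigma2)
    m = v * (mu / tau2 + n * ybar / sigma2)

    degenerate = bool(tau2 <= var_floor and np.all(sigma2 <= var_floor))
    if degenerate:
        warnings.warn(
            "degenerate fit: all variance components at the floor "
            "(constant data?)",
            RuntimeWarning,
            stacklevel=2,
        )

    return PopulationModel(
        mu=mu,
        tau2=tau2,
        sigma2_by_subject=dict(zip(ids, sigma2.tolist())),
        sigma2_pooled=float(np.mean(sigma2)),
        posterior_by_subject={i: (float(a), float(b)) for i, a, b in zip(ids, m, v)},
        loglik_trace=trace,
        converged=converged,
        n_iter=it,
        degenerate=degenerate,
    )


def update_subject_variance(
    model: PopulationModel,
    history: SubjectSummary,
    pseudo_obs: float = DEFAULT_PSEUDO_OBS,
    *,
    var_floor: float = VAR_FLOOR,
) -> float:
    """Working within-subject variance for a subject with accruing history.

    Pooled-shrinkage rule with ``a = pseudo_obs`` pseudo-observations::

        sigma2(j) = (a * sigma2_pooled + ss) / (a + max(j - 2, 0))

    where ``ss`` is the history's sum of squared deviations and ``j - 1``
    the history length.  Equals the pooled variance while the history holds
    fewer than two points, and converges to the subject's own sample
    variance as the history grows.
    """
    if model is None:
        raise NotFittedError("a fitted PopulationModel is required")
    denom = pseudo_obs + max(history.n - 1, 0)
    if denom <= 0:
        return max(model.sigma2_pooled, var_floor)
    return max((pseudo_obs * model.sigma2_pooled + history.ss) / denom, var_floor)


def lmm_range(
    model: PopulationModel,
    state: LmmRangeState,
    alpha: float,
    sidedness: str = "two_sided",
) -> ReferenceRange:
    """Reference range for occasion ``state.n_history + 1`` of a subject.

    Normal (z) quantiles are used; the centre is a precision-weighted
    average of the population mean and the subject's history mean, and the
    predictive variance adds the intercept-posterior variance to the working
    within-subject variance.
    """
    if model is None:
        raise NotFittedError("a fitted PopulationModel is required")
    _check_alpha(alpha)
    _check_sidedness(sidedness)
    tau2 = max(model.tau2, VAR_FLOOR)
    nh = state.n_history
    precision = 1.0 / tau2 + nh / state.sigma2
    centre = (model.mu / tau2 + nh * state.history_mean / state.sigma2) / precision
    pred_sd = math.sqrt(1.0 / precision + state.sigma2)
    occasion = nh + 1
    if sidedness == "two_sided":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return ReferenceRange(
            lower=centre - z * pred_sd,
            upper=centre + z * pred_sd,
            alpha=alpha,
            sidedness=sidedness,
            occasion=occasion,
            method=METHOD,
        )
    z = stats.norm.ppf(1.0 - alpha)
    return ReferenceRange(
        lower=0.0,
        upper=centre + z * pred_sd,
        alpha=alpha,
        sidedness=sidedness,
        occasion=occasion,
        method=METHOD,
    )
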