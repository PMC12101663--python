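"""Adaptive reference ranges from a subject's own history (Z-score method).

The statistic for a new observation against ``n`` prior measurements is

    T = (y_new - mean) / (sd * sqrt(1 + 1/n)),

which for iid Normal data follows a Student t distribution with ``n - 1``
degrees of freedom *exactly*, at every finite ``n``.  The corresponding
reference range inverts this statistic at the requested level.  At least two
prior observations are required, so the first flaggable occasion is the
third.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .data_model import (
    DegenerateHistoryError,
    InsufficientHistoryError,
    ReferenceRange,
    SubjectSummary,
    _check_alpha,
    _check_sidedness,
)

__all__ = ["ZScoreResult", "zscore_statistic", "zscore_range"]

METHOD = "zscore"


@dataclass(frozen=True)
class ZScoreResult:
    """The t-distributed statistic for one new observation.

    ``t_value`` follows a Student t distribution with ``df = n - 1`` degrees
    of freedom under the null of an unchanged subject.
    """

    t_value: float
    df: int
    n: int


def _require_usable_history(history: SubjectSummary) -> float:
    if history.n < 2:
        raise InsufficientHistoryError(
            "the Z-score method needs at least two prior observations and can "
            "only be calculated starting from the third observation "
            f"(history has {history.n})"
        )
    sd = history.sd
    assert sd is not None
    if sd == 0.0:
        raise DegenerateHistoryError(
            "history has zero spread; the within-subject scale is undefined"
        )
    return sd


def zscore_statistic(history: SubjectSummary, y_new: float) -> ZScoreResult:
    """Standardise ``y_new`` against the subject's own history.

    Raises
    ------
    InsufficientHistoryError
        If fewer than two observations have been consumed.
    DegenerateHistoryError
        If the history standard deviation is zero.
    """
    sd = _require_usable_history(history)
    scale = sd * math.sqrt(1.0 + 1.0 / history.n)
    t_value = (float(y_new) - history.mean) / scale
    return ZScoreResult(t_value=t_value, df=history.n - 1, n=history.n)


def zscore_range(
    history: SubjectSummary,
    alpha: float,
    sidedness: str = "two_sided",
) -> ReferenceRange:
    """Reference range for the next observation, from history alone.

    Two-sided:  ``mean +/- t_{1-alpha/2, n-1} * sd * sqrt(1 + 1/n)``.
    Upper-only: upper bound uses the ``1 - alpha`` quantile and the lower
    bound is clamped to 0.

    Consistency contract: classifying a value against the two-sided range is
    equivalent to comparing ``|zscore_statistic|`` with the t quantile.
    """
    _check_alpha(alpha)
    _check_sidedness(sidedness)
    sd = _require_usable_history(history)
    n = history.n
    scale = sd * math.sqrt(1.0 + 1.0 / n)
    occasion = n + 1
    if sidedness == "two_sided":
        q = stats.t.ppf(1.0 - alpha / 2.0, df=n - 1)
        half = q * scale
        return ReferenceRange(
            lower=history.mean - half,
            upper=history.mean + half,
            alpha=alpha,
            sidedness=sidedness,
            occasion=occasion,
            method=METHOD,
        )
    q = stats.t.ppf(1.0 - alpha, df=n - 1)
    return ReferenceRange(
        lower=0.0,
        upper=history.mean + q * scale,
        alpha=alpha,
        sidedness=sidedness,
        occasion=occasion,
        method=METHOD,
    )
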