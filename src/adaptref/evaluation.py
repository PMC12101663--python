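"""Sensitivity/specificity evaluation of adaptive ranges on labelled series.

Flags each occasion of a labelled series sequentially (the range for
occasion ``j`` is built from the admissible history before ``j``), sweeps
significance levels, stratifies by context tag, and implements the
leave-one-subject-out protocol in which the population model is re-fitted
excluding the subject under assessment.

Rates with an empty denominator are reported as NaN (undefined), never
coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DegenerateHistoryError,
    Flag,
    LongitudinalSeries,
    NotFittedError,
    SubjectSummary,
    classify,
)
from .lmm import (
    DEFAULT_PSEUDO_OBS,
    LmmRangeState,
    PopulationModel,
    fit_population_em,
    lmm_range,
)
from .zscore import zscore_range

__all__ = ["EvalReport", "evaluate_series", "alpha_sweep", "loo_protocol"]

METHODS = ("zscore", "lmm")


@dataclass
class EvalReport:
    """Rates plus the flag-level audit table they were computed from.

    ``rates`` columns: method, alpha, context, metric (sensitivity | fpr),
    scope (pooled | mean_per_subject), value (NaN when undefined).
    ``flags`` columns: subject, method, alpha, occasion, observed, lower,
    upper, verdict, label, context.
    """

    rates: pd.DataFrame
    flags: pd.DataFrame
    models: dict[str, PopulationModel] = field(default_factory=dict)

    def rate(
        self,
        method: str,
        alpha: float,
        metric: str,
        *,
        context: str = "all",
        scope: str = "pooled",
    ) -> float:
        df = self.rates
        sel = df[
            (df["method"] == method)
            & (np.isclose(df["alpha"], alpha))
            & (df["context"] == context)
            & (df["metric"] == metric)
            & (df["scope"] == scope)
        ]
        if len(sel) != 1:
            raise KeyError(
                f"no unique rate for ({method}, {alpha}, {metric}, {context}, {scope})"
            )
        return float(sel["value"].iloc[0])


def evaluate_series(
    series: LongitudinalSeries,
    method: str,
    model: PopulationModel | None = None,
    alpha: float = 0.05,
    sidedness: str = "two_sided",
    exclude_flagged_from_history: bool = False,
    *,
    pseudo_obs: float = DEFAULT_PSEUDO_OBS,
) -> list[Flag]:
    """Sequentially flag each occasion of one series.

    The range at occasion ``j`` uses only prior occasions; with
    ``exclude_flagged_from_history`` on, occasions whose truth label is
    abnormal are omitted from the history (mirroring the omission of
    readings taken while a subject was known to be unwell), so a spike does
    not inflate later ranges.

    Z-score ranges exist only once the admissible history holds two or more
    values (and has positive spread); earlier occasions yield no record.
    LMM ranges exist from the first occasion.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if method == "lmm" and model is None:
        raise NotFittedError("the LMM method requires a fitted PopulationModel")

    flags: list[Flag] = []
    hist = SubjectSummary.empty()
    for j, y in enumerate(series.values, start=1):
        rr = None
        if method == "zscore":
            if hist.n >= 2 and hist.sd:
                try:
                    rr = zscore_range(hist, alpha, sidedness)
                except DegenerateHistoryError:
                    rr = None
        else:
            state = LmmRangeState.from_history(model, hist, pseudo_obs=pseudo_obs)
            rr = lmm_range(model, state, alpha, sidedness)
        if rr is not None:
            flags.append(classify(y, replace(rr, occasion=j)))
        if not (
            exclude_flagged_from_history and series.label_at(j) == "abnormal"
        ):
            hist = hist.update(y)
    return flags


def _flag_rows(
    series: LongitudinalSeries, method: str, alpha: float, flags: Sequence[Flag]
) -> list[dict]:
    rows = []
    for f in flags:
        rows.append(
            {
                "subject": series.subject_id,
                "method": method,
                "alpha": alpha,
                "occasion": f.occasion,
                "observed": f.observed,
                "lower": f.range.lower,
                "upper": f.range.upper,
                "verdict": f.verdict,
                "label": series.label_at(f.occasion),
                "context": (
                    series.context[f.occasion - 1] if series.context else ""
                ),
            }
        )
    return rows


def _rates_from_flags(flags: pd.DataFrame) -> pd.DataFrame:
    """Recompute all rates from the audit table (the single source of truth)."""
    rows = []
    if flags.empty:
        return pd.DataFrame(
            columns=["method", "alpha", "context", "metric", "scope", "value"]
        )
    contexts = ["all"] + sorted(c for c in flags["context"].unique() if c)
    for (method, alpha), grp in flags.groupby(["method", "alpha"]):
        for context in contexts:
            sub = grp if context == "all" else grp[grp["context"] == context]
            for metric, label in (("sensitivity", "abnormal"), ("fpr", "normal")):
                denom_mask = sub["label"] == label
                hit = denom_mask & (sub["verdict"] == "abnormal")
                pooled = (
                    float(hit.sum() / denom_mask.sum())
                    if denom_mask.sum()
                    else np.nan
                )
                per_subject = []
                for _, ssub in sub.groupby("subject"):
                    d = ssub["label"] == label
                    if d.sum():
                        per_subject.append(
                            float((d & (ssub["verdict"] == "abnormal")).sum() / d.sum())
                        )
                mean_ps = float(np.mean(per_subject)) if per_subject else np.nan
                rows.append(
                    dict(method=method, alpha=alpha, context=context,
                         metric=metric, scope="pooled", value=pooled)
                )
                rows.append(
                    dict(method=method, alpha=alpha, context=context,
                         metric=metric, scope="mean_per_subject", value=mean_ps)
                )
    return pd.DataFrame(rows)


def alpha_sweep(
    collection: Sequence[LongitudinalSeries],
    methods: Sequence[str] = METHODS,
    alphas: Sequence[float] = (0.05,),
    sidedness: str = "two_sided",
    loo: bool = False,
    *,
    exclude_flagged_from_history: bool = True,
    pseudo_obs: float = DEFAULT_PSEUDO_OBS,
    em_kwargs: dict | None = None,
) -> EvalReport:
    """Sensitivity and false-positive rate over a grid of alphas.

    With ``loo`` the population model for each subject is fitted on the
    other subjects (the subject is assessed as wholly new); otherwise a
    single model fitted on the whole collection is shared.  Both pooled
    (occasion-weighted) and unweighted per-subject-mean rates are reported,
    stratified by context tag.
    """
    em_kwargs = em_kwargs or {}
    models: dict[str, PopulationModel] = {}
    if "lmm" in methods:
        if loo:
            if len(collection) < 3:
                raise ValueError("leave-one-subject-out needs at least 3 subjects")
            for s in collection:
                others = [t for t in collection if t.subject_id != s.subject_id]
                models[s.subject_id] = fit_population_em(others, **em_kwargs)
        else:
            shared = fit_population_em(list(collection), **em_kwargs)
            models = {s.subject_id: shared for s in collection}

    rows: list[dict] = []
    for method in methods:
        for alpha in alphas:
            for s in collection:
                flags = evaluate_series(
                    s,
                    method,
                    model=models.get(s.subject_id),
                    alpha=alpha,
                    sidedness=sidedness,
                    exclude_flagged_from_history=exclude_flagged_from_history,
                    pseudo_obs=pseudo_obs,
                )
                rows.extend(_flag_rows(s, method, alpha, flags))

    flags_df = pd.DataFrame(
        rows,
        columns=["subject", "method", "alpha", "occasion", "observed",
                 "lower", "upper", "verdict", "label", "context"],
    )
    return EvalReport(
        rates=_rates_from_flags(flags_df),
        flags=flags_df,
        models=models if loo else {},
    )


def loo_protocol(
    collection: Sequence[LongitudinalSeries],
    alpha: float = 0.05,
    sidedness: str = "upper_only",
    methods: Sequence[str] = METHODS,
    **kwargs,
) -> EvalReport:
    """Leave-one-subject-out evaluation at a single significance level.

    For each subject the population parameters are re-estimated on all other
    subjects and the subject is evaluated as entirely new; the per-subject
    models are retained on the report for audit.
    """
    return alpha_sweep(
        collection,
        methods=methods,
        alphas=[alpha],
        sidedness=sidedness,
        loo=True,
        **kwargs,
    )
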