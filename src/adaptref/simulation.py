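"""Simulation study: data generation, scenario grid, false-positive rates.

Data are generated from the random-intercept model ``Y_ij = mu_i + eps_ij``
with ``mu_i ~ N(mu, tau2)`` and ``eps_ij ~ N(0, sigma2_i)``.  The scenario
grid crosses 12 within-to-between SD ratios with 3 between-subject SDs
(36 scenarios).  For each scenario a population is generated, an assessment
sample and a control sample are drawn, the population model is fitted on
the control, and both methods produce sequential reference ranges for every
assessed subject from the third occasion onward; the per-subject and
per-occasion false-positive rates are collected.

Also provides a generator of hsCRP-like labelled fixtures (nonnegative,
log-normal baseline, multiplicative post-event spikes) for evaluating
sensitivity/specificity on labelled series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import LongitudinalSeries
from .lmm import DEFAULT_PSEUDO_OBS, PopulationModel, fit_population_em

__all__ = [
    "RATIOS",
    "BETWEEN_SDS",
    "ScenarioSpec",
    "SimulationResult",
    "SpikeSpec",
    "table1_grid",
    "simulate_population",
    "run_simulation_study",
    "make_hscrp_fixture",
]

#: Within-to-between SD ratios of the scenario grid (rows).
RATIOS = (
    0.001, 0.005, 0.010, 0.025, 0.050, 0.075,
    0.100, 0.250, 0.500, 1.000, 2.000, 5.000,
)

#: Between-subject SDs of the scenario grid (columns).
BETWEEN_SDS = (0.5, 1.0, 2.0)

#: First occasion at which flags are counted (the first two observations
#: are needed to estimate within-subject variability).
FIRST_FLAGGED_OCCASION = 3


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario grid.

    ``within_sd`` is derived as ``ratio * between_sd`` when not given.
    """

    between_sd: float
    ratio: float
    within_sd: float | None = None
    mu: float = 5.0
    n_subjects_pop: int = 1000
    n_per_subject: int = 100
    n_sampled: int = 100
    n_control: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.within_sd is None:
            object.__setattr__(self, "within_sd", self.ratio * self.between_sd)
        if not np.isclose(self.within_sd, self.ratio * self.between_sd, rtol=1e-12):
            raise ValueError("within_sd must equal ratio * between_sd")
        for name in ("n_subjects_pop", "n_per_subject", "n_sampled", "n_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def label(self) -> str:
        return f"tau{self.between_sd:g}_r{self.ratio:g}"


def table1_grid(
    *,
    mu: float = 5.0,
    n_subjects_pop: int = 1000,
    n_per_subject: int = 100,
    n_sampled: int = 100,
    n_control: int = 120,
    master_seed: int = 20250523,
    ratios: Sequence[float] = RATIOS,
    between_sds: Sequence[float] = BETWEEN_SDS,
) -> list[ScenarioSpec]:
    """The full scenario grid (ratios x between-SDs), seeded per scenario.

    A single master seed spawns one independent stream per scenario so each
    scenario is reproducible in isolation.
    """
    children = np.random.SeedSequence(master_seed).generate_state(
        len(ratios) * len(between_sds)
    )
    specs = []
    k = 0
    for ratio in ratios:
        for between_sd in between_sds:
            specs.append(
                ScenarioSpec(
                    between_sd=float(between_sd),
                    ratio=float(ratio),
                    mu=mu,
                    n_subjects_pop=n_subjects_pop,
                    n_per_subject=n_per_subject,
                    n_sampled=n_sampled,
                    n_control=n_control,
                    seed=int(children[k]),
                )
            )
            k += 1
    return specs


def simulate_population(spec: ScenarioSpec) -> list[LongitudinalSeries]:
    """Generate the scenario's population, reproducibly from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    mu_i = spec.mu + spec.between_sd * rng.standard_normal(spec.n_subjects_pop)
    noise = spec.within_sd * rng.standard_normal(
        (spec.n_subjects_pop, spec.n_per_subject)
    )
    values = mu_i[:, None] + noise
    return [
        LongitudinalSeries(subject_id=f"{spec.label}_s{i + 1}", values=values[i])
        for i in range(spec.n_subjects_pop)
    ]


# ---------------------------------------------------------------------------
# Vectorised sequential flagging (fast path used by the study; each mirrors
# the per-occasion object API and is tested against it)
# ---------------------------------------------------------------------------

def _running_history_stats(values: np.ndarray, start: int):
    """History mean and sum of squared deviations before each occasion.

    Returns ``(n_hist, hist_mean, hist_ss, y)`` aligned on occasions
    ``start .. len(values)``; entry ``k`` describes the first
    ``occasion - 1`` values.  Values are centred internally so the running
    sums stay accurate when the spread is tiny relative to the level.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    shift = values.mean()
    v0 = values - shift
    cs = np.concatenate(([0.0], np.cumsum(v0)))
    cs2 = np.concatenate(([0.0], np.cumsum(v0 * v0)))
    occ = np.arange(start, n + 1)
    nh = occ - 1
    hist_mean = shift + cs[nh] / nh
    hist_ss = np.maximum(cs2[nh] - cs[nh] ** 2 / nh, 0.0)
    return nh, hist_mean, hist_ss, values[occ - 1]


def zscore_flag_path(
    values: np.ndarray,
    alpha: float,
    sidedness: str = "two_sided",
    start: int = FIRST_FLAGGED_OCCASION,
) -> np.ndarray:
    """Flags for occasions ``start..n`` under the Z-score method.

    Returns a float array: 1.0 flagged, 0.0 not flagged, NaN skipped
    (zero-variance history).
    """
    nh, hist_mean, hist_ss, y = _running_history_stats(values, start)
    sd = np.sqrt(hist_ss / (nh - 1))
    scale = sd * np.sqrt(1.0 + 1.0 / nh)
    if sidedness == "two_sided":
        q = stats.t.ppf(1.0 - alpha / 2.0, df=nh - 1)
        flagged = np.abs(y - hist_mean) > q * scale
    else:
        q = stats.t.ppf(1.0 - alpha, df=nh - 1)
        flagged = (y > hist_mean + q * scale) | (y < 0.0)
    out = flagged.astype(float)
    out[sd == 0.0] = np.nan
    return out


def lmm_flag_path(
    values: np.ndarray,
    model: PopulationModel,
    alpha: float,
    sidedness: str = "two_sided",
    start: int = FIRST_FLAGGED_OCCASION,
    pseudo_obs: float = DEFAULT_PSEUDO_OBS,
) -> np.ndarray:
    """Flags for occasions ``start..n`` under the LMM method (new subject).

    The working within-subject variance follows the pooled-shrinkage rule;
    the centre and width follow the shrinkage range formula with Normal
    quantiles.
    """
    nh, hist_mean, hist_ss, y = _running_history_stats(values, start)
    tau2 = max(model.tau2, 1e-12)
    sigma2 = (pseudo_obs * model.sigma2_pooled + hist_ss) / (
        pseudo_obs + np.maximum(nh - 1, 0)
    )
    precision = 1.0 / tau2 + nh / sigma2
    centre = (model.mu / tau2 + nh * hist_mean / sigma2) / precision
    pred_sd = np.sqrt(1.0 / precision + sigma2)
    if sidedness == "two_sided":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        flagged = np.abs(y - centre) > z * pred_sd
    else:
        z = stats.norm.ppf(1.0 - alpha)
        flagged = (y > centre + z * pred_sd) | (y < 0.0)
    return flagged.astype(float)


# ---------------------------------------------------------------------------
# The study
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Per-subject and per-occasion false-positive rates from a study run.

    ``per_subject`` columns: scenario, ratio, between_sd, subject, method,
    fpr, n_flagged, n_occasions.  ``per_occasion`` columns: scenario, ratio,
    between_sd, method, occasion, fpr.
    """

    per_subject: pd.DataFrame
    per_occasion: pd.DataFrame
    alpha: float
    n_skipped: int = 0

    def medians(self) -> dict[str, float]:
        """Median per-subject FPR by method."""
        return self.per_subject.groupby("method")["fpr"].median().to_dict()

    def pairwise_differences(self) -> pd.Series:
        """Per-subject FPR difference, LMM minus Z-score."""
        wide = self.per_subject.pivot_table(
            index=["scenario", "subject"], columns="method", values="fpr"
        )
        return wide["lmm"] - wide["zscore"]

    def per_occasion_mean(
        self, method: str, first: int, last: int
    ) -> float:
        """Mean per-occasion FPR over ``[first, last]``, averaged over
        scenarios."""
        df = self.per_occasion
        sel = df[
            (df["method"] == method)
            & (df["occasion"] >= first)
            & (df["occasion"] <= last)
        ]
        return float(sel["fpr"].mean())

    def summary(self) -> dict:
        med = self.medians()
        diff = self.pairwise_differences()
        return {
            "alpha": self.alpha,
            "median_fpr": med,
            "mean_fpr": self.per_subject.groupby("method")["fpr"].mean().to_dict(),
            "median_pairwise_diff_lmm_minus_zscore": float(diff.median()),
            "n_subjects": int(
                self.per_subject.groupby("method")["subject"].count().iloc[0]
            ),
            "n_skipped_occasions": self.n_skipped,
        }


def run_simulation_study(
    grid: Iterable[ScenarioSpec],
    alpha: float = 0.05,
    *,
    sidedness: str = "two_sided",
    pseudo_obs: float = DEFAULT_PSEUDO_OBS,
    em_rtol: float = 1e-8,
    em_max_iter: int = 500,
) -> SimulationResult:
    """Run the false-positive-rate comparison over a scenario grid.

    Per scenario: generate the population, draw the assessment and control
    samples, fit the population model on the control, then flag each assessed
    subject's occasions 3..n_i sequentially with both methods.  All data are
    generated from a single regime per scenario, so every flag is a false
    positive.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be nonempty")

    subject_rows = []
    occasion_rows = []
    n_skipped = 0

    for s_idx, spec in enumerate(grid):
        population = simulate_population(spec)
        rng = np.random.default_rng([spec.seed, 1])
        assessed_idx = rng.choice(
            spec.n_subjects_pop, size=spec.n_sampled, replace=False
        )
        control_idx = rng.choice(
            spec.n_subjects_pop, size=spec.n_control, replace=False
        )
        model = fit_population_em(
            [population[i] for i in control_idx],
            rtol=em_rtol,
            max_iter=em_max_iter,
        )

        flags = {"zscore": [], "lmm": []}
        for i in assessed_idx:
            series = population[i]
            fz = zscore_flag_path(series.values, alpha, sidedness)
            fl = lmm_flag_path(
                series.values, model, alpha, sidedness, pseudo_obs=pseudo_obs
            )
            flags["zscore"].append(fz)
            flags["lmm"].append(fl)
            n_skipped += int(np.isnan(fz).sum())
            for method, f in (("zscore", fz), ("lmm", fl)):
                n_occ = int(np.sum(~np.isnan(f)))
                n_flagged = int(np.nansum(f))
                subject_rows.append(
                    {
                        "scenario": spec.label,
                        "ratio": spec.ratio,
                        "between_sd": spec.between_sd,
                        "subject": series.subject_id,
                        "method": method,
                        "fpr": n_flagged / n_occ if n_occ else np.nan,
                        "n_flagged": n_flagged,
                        "n_occasions": n_occ,
                    }
                )

        occasions = np.arange(FIRST_FLAGGED_OCCASION, spec.n_per_subject + 1)
        for method in ("zscore", "lmm"):
            mat = np.vstack(flags[method])
            with np.errstate(invalid="ignore"):
                rate = np.nanmean(mat, axis=0)
            for occ, r in zip(occasions, rate):
                occasion_rows.append(
                    {
                        "scenario": spec.label,
                        "ratio": spec.ratio,
                        "between_sd": spec.between_sd,
                        "method": method,
                        "occasion": int(occ),
                        "fpr": float(r),
                    }
                )

    return SimulationResult(
        per_subject=pd.DataFrame(subject_rows),
        per_occasion=pd.DataFrame(occasion_rows),
        alpha=alpha,
        n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# hsCRP-like labelled fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeSpec:
    """Parameters of the labelled fixture generator.

    Baseline values are log-normal: per-subject log-mean drawn from
    ``N(baseline_meanlog, between_sdlog^2)``, per-occasion log-noise with SD
    ``within_sdlog``.  Each occasion independently receives a multiplicative
    spike (labelled abnormal) with probability ``probability``.
    """

    probability: float = 0.2
    multiplier: float = 10.0
    baseline_meanlog: float = 0.0
    within_sdlog: float = 0.3
    between_sdlog: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must be in [0, 1]")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


def make_hscrp_fixture(
    n_subjects: int = 4,
    n_occasions: int = 15,
    spike_spec: SpikeSpec = SpikeSpec(),
    seed: int = 0,
) -> list[LongitudinalSeries]:
    """Generate nonnegative inflammation-marker-like labelled series.

    Context tags alternate ``"pre"``/``"post"`` over occasions.  Spiked
    occasions are labelled abnormal, all others normal.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        meanlog = spike_spec.baseline_meanlog + spike_spec.between_sdlog * rng.standard_normal()
        logvals = meanlog + spike_spec.within_sdlog * rng.standard_normal(n_occasions)
        values = np.exp(logvals)
        spiked = rng.random(n_occasions) < spike_spec.probability
        values = np.where(spiked, values * spike_spec.multiplier, values)
        labels = tuple("abnormal" if s else "normal" for s in spiked)
        context = tuple("pre" if j % 2 == 0 else "post" for j in range(n_occasions))
        out.append(
            LongitudinalSeries(
                subject_id=f"athlete{i + 1}",
                values=values,
                labels=labels,
                context=context,
            )
        )
    return out
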