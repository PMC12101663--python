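"""Shared domain types for longitudinal biomarker series.

This module defines the core value objects used throughout the package:

* :class:`LongitudinalSeries` -- one subject's ordered measurements, with
  optional truth labels and free-form context tags,
* :class:`SubjectSummary` -- a streaming (one-pass) summary of a subject's
  history: count, mean and sum of squared deviations,
* :class:`ReferenceRange` -- an interval against which the next observation
  is judged,
* :class:`Flag` -- the verdict for a single observation,

plus long-format delimited-text I/O (:func:`read_long_table`,
:func:`write_long_table`) and :func:`classify`.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "SIDEDNESS",
    "LongitudinalSeries",
    "SubjectSummary",
    "ReferenceRange",
    "Flag",
    "FormatError",
    "ParseError",
    "InsufficientHistoryError",
    "DegenerateHistoryError",
    "NotFittedError",
    "read_long_table",
    "write_long_table",
    "classify",
]

LABELS = ("normal", "abnormal", "unlabelled")
SIDEDNESS = ("two_sided", "upper_only")

#: Default long-format column names; remap via the ``column_map`` argument
#: of :func:`read_long_table`.
DEFAULT_COLUMNS = {
    "subject": "subject",
    "occasion": "occasion",
    "value": "value",
    "label": "label",
    "context": "context",
}


class FormatError(ValueError):
    """Structural problem with an input table (missing column, duplicates)."""


class ParseError(ValueError):
    """A cell could not be parsed; the message names the offending row."""


class InsufficientHistoryError(ValueError):
    """Too few prior observations for the requested computation."""


class DegenerateHistoryError(ValueError):
    """History has zero spread, so the within-subject scale is undefined."""


class NotFittedError(RuntimeError):
    """A population model was required but none was supplied/fitted."""


def _check_sidedness(sidedness: str) -> None:
    if sidedness not in SIDEDNESS:
        raise ValueError(f"sidedness must be one of {SIDEDNESS}, got {sidedness!r}")


def _check_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha!r}")


@dataclass(frozen=True)
class LongitudinalSeries:
    """One subject's ordered biomarker measurements.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    values
        Measurements in occasion order (1-based occasions, re-packed: the
        j-th element is occasion ``j`` regardless of gaps in the source).
    labels
        Optional per-value truth marks, each in ``{"normal", "abnormal",
        "unlabelled"}``; must align 1:1 with ``values``.
    context
        Optional per-value free-form tags (e.g. ``"pre"``/``"post"``).
    """

    subject_id: str
    values: np.ndarray
    labels: tuple[str, ...] | None = None
    context: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"subject {self.subject_id!r}: values must be finite")
        object.__setattr__(self, "values", vals)
        for name in ("labels", "context"):
            seq = getattr(self, name)
            if seq is not None:
                seq = tuple(seq)
                if len(seq) != len(vals):
                    raise ValueError(
                        f"subject {self.subject_id!r}: {name} must align with values"
                    )
                object.__setattr__(self, name, seq)
        if self.labels is not None:
            bad = set(self.labels) - set(LABELS)
            if bad:
                raise ValueError(f"unknown labels {sorted(bad)}; allowed: {LABELS}")

    def __len__(self) -> int:
        return len(self.values)

    def label_at(self, occasion: int) -> str:
        """Truth label at a 1-based occasion (``"unlabelled"`` if absent)."""
        if self.labels is None:
            return "unlabelled"
        return self.labels[occasion - 1]

    def summary(self) -> "SubjectSummary":
        """Summary over the full series."""
        return SubjectSummary.from_values(self.values)


@dataclass(frozen=True)
class SubjectSummary:
    """Streaming summary of a history: count, mean, sum of squared deviations.

    ``sd`` (the unbiased standard deviation ``sqrt(ss / (n - 1))``) is
    *undefined* -- reported as ``None`` -- for ``n < 2``, never coerced to
    zero.  Updating one value at a time agrees with the batch computation to
    1e-10 relative tolerance (Welford's algorithm).
    """

    n: int = 0
    mean: float = 0.0
    ss: float = 0.0

    @classmethod
    def empty(cls) -> "SubjectSummary":
        return cls()

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "SubjectSummary":
        s = cls()
        for y in values:
            s = s.update(y)
        return s

    def update(self, y: float) -> "SubjectSummary":
        """Return a new summary with ``y`` consumed (one-pass, stable)."""
        y = float(y)
        if not math.isfinite(y):
            raise ValueError(f"value must be finite, got {y!r}")
        n1 = self.n + 1
        delta = y - self.mean
        mean1 = self.mean + delta / n1
        ss1 = self.ss + delta * (y - mean1)
        return SubjectSummary(n=n1, mean=mean1, ss=max(ss1, 0.0))

    @property
    def sd(self) -> float | None:
        if self.n < 2:
            return None
        return math.sqrt(self.ss / (self.n - 1))

    @property
    def variance(self) -> float | None:
        if self.n < 2:
            return None
        return self.ss / (self.n - 1)


@dataclass(frozen=True)
class ReferenceRange:
    """An interval for judging one observation.

    ``lower <= upper`` always; for ``upper_only`` ranges the lower bound is
    clamped to 0 (low values carry no signal for the intended biomarkers).
    ``occasion`` is the 1-based index of the observation the range applies to.
    """

    lower: float
    upper: float
    alpha: float
    sidedness: str
    occasion: int
    method: str

    def __post_init__(self) -> None:
        _check_sidedness(self.sidedness)
        _check_alpha(self.alpha)
        if self.lower > self.upper:
            raise ValueError(
                f"lower ({self.lower}) must not exceed upper ({self.upper})"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def exp(self) -> "ReferenceRange":
        """Back-transform a range computed on the log scale.

        A clamped lower bound of 0 stays at 0; otherwise bounds map through
        ``exp`` (so -inf maps to 0).
        """
        lower = 0.0 if (self.sidedness == "upper_only" and self.lower == 0.0) else math.exp(self.lower)
        return replace(self, lower=lower, upper=math.exp(self.upper))


@dataclass(frozen=True)
class Flag:
    """Verdict for one observation against one reference range."""

    occasion: int
    observed: float
    range: ReferenceRange
    verdict: str = field(init=False)

    def __post_init__(self) -> None:
        verdict = (
            "abnormal"
            if (self.observed < self.range.lower or self.observed > self.range.upper)
            else "normal"
        )
        object.__setattr__(self, "verdict", verdict)

    @property
    def is_abnormal(self) -> bool:
        return self.verdict == "abnormal"


def classify(y: float, range_: ReferenceRange) -> Flag:
    """Classify ``y`` against ``range_``.

    Boundary convention: values exactly on a limit are *normal* (strict
    exterior abnormality -- conservative flagging).
    """
    return Flag(occasion=range_.occasion, observed=float(y), range=range_)


# ---------------------------------------------------------------------------
# Long-format I/O
# ---------------------------------------------------------------------------

def _resolve_columns(
    df: pd.DataFrame, column_map: Mapping[str, str] | None
) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown column-map keys: {sorted(unknown)}")
        cols.update(column_map)
    for role in ("subject", "occasion", "value"):
        if cols[role] not in df.columns:
            raise FormatError(f"missing required column {cols[role]!r}")
    return cols


def read_long_table(
    source,
    column_map: Mapping[str, str] | None = None,
    *,
    sep: str = ",",
    transform: str | None = None,
) -> list[LongitudinalSeries]:
    """Read a long-format delimited table into one series per subject.

    Parameters
    ----------
    source
        Path or open text handle; a header row is required.
    column_map
        Optional remapping of the roles ``subject``, ``occasion``, ``value``,
        ``label``, ``context`` to actual column names.
    sep
        Field delimiter (``","`` for CSV, ``"\\t"`` for TSV).
    transform
        ``"log"`` applies a natural-log transform to the values at read time
        (for right-skewed biomarkers); values must then be positive.  Ranges
        computed on the log scale can be reported back on the original scale
        via :meth:`ReferenceRange.exp`.

    Raises
    ------
    FormatError
        Missing required column or duplicate (subject, occasion) pair.
    ParseError
        Non-numeric or empty value cell (the message gives the data row
        number, 1-based, excluding the header).
    """
    df = pd.read_csv(source, sep=sep, dtype=str, keep_default_na=False)
    cols = _resolve_columns(df, column_map)

    raw_values = df[cols["value"]].str.strip()
    numeric = pd.to_numeric(raw_values.replace("", np.nan), errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.fillna(np.nan))
    if bad.any():
        row = int(bad.idxmax()) + 1  # 1-based data row
        raise ParseError(
            f"row {row}: value {raw_values.iloc[row - 1]!r} is not a finite number"
        )

    occ_raw = df[cols["occasion"]].str.strip()
    occ = pd.to_numeric(occ_raw, errors="coerce")
    if occ.isna().any():
        try:
            occ = pd.to_datetime(occ_raw, format="ISO8601")
        except (ValueError, TypeError) as exc:
            row = int(pd.to_numeric(occ_raw, errors="coerce").isna().idxmax()) + 1
            raise ParseError(
                f"row {row}: occasion {occ_raw.iloc[row - 1]!r} is neither an "
                f"integer nor an ISO timestamp"
            ) from exc

    subjects = df[cols["subject"]].str.strip()
    dup = pd.DataFrame({"s": subjects, "o": occ}).duplicated()
    if dup.any():
        row = int(dup.idxmax()) + 1
        raise FormatError(
            f"row {row}: duplicate (subject, occasion) pair "
            f"({subjects.iloc[row - 1]!r}, {occ_raw.iloc[row - 1]!r})"
        )

    values = numeric.astype(float)
    if transform == "log":
        if (values <= 0).any():
            row = int((values <= 0).idxmax()) + 1
            raise ParseError(f"row {row}: log transform requires positive values")
        values = np.log(values)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")

    has_label = cols["label"] in df.columns
    has_context = cols["context"] in df.columns

    work = pd.DataFrame({"subject": subjects, "occasion": occ, "value": values})
    if has_label:
        lab = df[cols["label"]].str.strip().replace("", "unlabelled")
        work["label"] = lab
    if has_context:
        work["context"] = df[cols["context"]].str.strip()

    out: list[LongitudinalSeries] = []
    for subject_id, grp in work.groupby("subject", sort=False):
        grp = grp.sort_values("occasion", kind="stable")
        out.append(
            LongitudinalSeries(
                subject_id=str(subject_id),
                values=grp["value"].to_numpy(),
                labels=tuple(grp["label"]) if has_label else None,
                context=tuple(grp["context"]) if has_context else None,
            )
        )
    return out


def write_long_table(
    collection: Sequence[LongitudinalSeries],
    dest,
    *,
    sep: str = ",",
) -> None:
    """Write series to a long-format delimited table (inverse of reading)."""
    any_labels = any(s.labels is not None for s in collection)
    any_context = any(s.context is not None for s in collection)
    rows = []
    for s in collection:
        for j, y in enumerate(s.values, start=1):
            row: dict[str, object] = {"subject": s.subject_id, "occasion": j, "value": y}
            if any_labels:
                row["label"] = s.labels[j - 1] if s.labels is not None else "unlabelled"
            if any_context:
                row["context"] = s.context[j - 1] if s.context is not None else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(dest, sep=sep, index=False)


def to_csv_string(collection: Sequence[LongitudinalSeries], *, sep: str = ",") -> str:
    """Serialise a collection as CSV text (handy for byte-identity checks)."""
    buf = io.StringIO()
    write_long_table(collection, buf, sep=sep)
    return buf.getvalue()
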