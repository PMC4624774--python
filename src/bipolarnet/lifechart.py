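"""Life-chart representation and longitudinal course-type classification.

The retrospective Life Chart Method (LCM-r) rates, for every month, the
functional impairment arising from depression and from mania on an ordinal
0-4 scale (0 none, 1 mild, 2 moderately low, 3 moderately high, 4 severe).
Over a fixed 24-month observation window each patient is assigned to one of
three longitudinal course types:

* ``mildly_impaired`` -- stable (euthymic) mood for more than 90% of the
  time, or only mild impairment for at most a third of the time, or
  mild-to-moderate impairment for at most a quarter of the time;
* ``depressed``      -- depressive impairment for more than a third of the
  time at mild to mild-moderate severity, or for at least a quarter of the
  time with at least one severe month, while manic impairment stays rare
  and mild;
* ``cycling``        -- more than a quarter of the time impaired on *both*
  poles (with at least one moderate month on each), or at least an eighth
  of the time on both poles with at least one severe month, or a
  predominantly manic/mixed pattern (manic impairment at least a third of
  the time with depression under a quarter).

Mixed months (both poles impaired simultaneously) count toward both poles'
time fractions. The three printed rules are not mathematically total, so a
documented nearest-rule fallback assigns the remaining charts and records
that the fallback fired.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_MONTHS = 24

__all__ = [
    "N_MONTHS",
    "CourseLabel",
    "LifeChart",
    "TimeProportions",
    "ClassificationResult",
    "time_proportions",
    "classify_course",
    "CourseClassifier",
    "read_lifechart_table",
    "lifecharts_to_table",
    "classification_report",
]


class CourseLabel(str, enum.Enum):
    """The three two-year longitudinal course types."""

    MILDLY_IMPAIRED = "mildly_impaired"
    DEPRESSED = "depressed"
    CYCLING = "cycling"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class LifeChartError(ValueError):
    """Raised for malformed life charts; names the offending month."""


@dataclass(frozen=True)
class LifeChart:
    """One patient's 24 monthly (depression, mania) severity pairs.

    Parameters
    ----------
    patient_id:
        Opaque identifier.
    months:
        Sequence of exactly 24 ``(dep_severity, man_severity)`` pairs,
        each severity an integer in [0, 4].
    """

    patient_id: str
    months: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.months) != N_MONTHS:
            raise LifeChartError(
                f"patient {self.patient_id!r}: expected {N_MONTHS} monthly "
                f"entries, got {len(self.months)}"
            )
        for i, (dep, man) in enumerate(self.months, start=1):
            for pole, value in (("dep", dep), ("man", man)):
                if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
                    raise LifeChartError(
                        f"patient {self.patient_id!r}, month {i}: {pole}_severity "
                        f"{value!r} is not an integer"
                    )
                if not 0 <= int(value) <= 4:
                    raise LifeChartError(
                        f"patient {self.patient_id!r}, month {i}: {pole}_severity "
                        f"{value} outside [0, 4]"
                    )

    @property
    def dep(self) -> np.ndarray:
        return np.asarray([m[0] for m in self.months], dtype=int)

    @property
    def man(self) -> np.ndarray:
        return np.asarray([m[1] for m in self.months], dtype=int)


@dataclass(frozen=True)
class TimeProportions:
    """Per-pole fractions of impaired months and per-pole maxima.

    Fractions are multiples of 1/24; a mixed month counts toward both
    poles, so ``dep_frac + man_frac`` may exceed 1.
    """

    dep_frac: float
    man_frac: float
    max_dep_severity: int
    max_man_severity: int


@dataclass(frozen=True)
class ClassificationResult:
    patient_id: str
    label: CourseLabel
    proportions: TimeProportions
    rule_fired: str


def time_proportions(chart: LifeChart) -> TimeProportions:
    """Fraction of the 24 months impaired on each pole, plus severity maxima.

    A month counts as impaired on a pole when its severity is >= 1; months
    impaired on both poles (mixed states) contribute to both fractions.
    """
    dep, man = chart.dep, chart.man
    return TimeProportions(
        dep_frac=float(np.count_nonzero(dep >= 1)) / N_MONTHS,
        man_frac=float(np.count_nonzero(man >= 1)) / N_MONTHS,
        max_dep_severity=int(dep.max()),
        max_man_severity=int(man.max()),
    )


def _classify(chart: LifeChart) -> ClassificationResult:
    dep, man = chart.dep, chart.man
    tp = time_proportions(chart)
    dep_frac, man_frac = tp.dep_frac, tp.man_frac
    max_dep, max_man = tp.max_dep_severity, tp.max_man_severity
    # counts of months at / above given severities
    dep_ge2 = int(np.count_nonzero(dep >= 2))
    man_ge2 = int(np.count_nonzero(man >= 2))
    stable_frac = float(np.count_nonzero((dep == 0) & (man == 0))) / N_MONTHS

    def result(label: CourseLabel, rule: str) -> ClassificationResult:
        return ClassificationResult(chart.patient_id, label, tp, rule)

    # --- cycling (highest precedence) -----------------------------------
    # >1/4 of time on both poles with >=1 moderate month on each pole
    if dep_frac > 0.25 and man_frac > 0.25 and dep_ge2 >= 1 and man_ge2 >= 1:
        return result(CourseLabel.CYCLING, "cycling:bilateral_quarter")
    # >=1/8 of time on both poles with >=1 month exceeding high moderate
    if dep_frac >= 1 / 8 and man_frac >= 1 / 8 and max(max_dep, max_man) >= 4:
        return result(CourseLabel.CYCLING, "cycling:bilateral_eighth_severe")
    # predominantly manic / mixed
    if man_frac >= 1 / 3 and dep_frac < 0.25:
        return result(CourseLabel.CYCLING, "cycling:predominantly_manic")

    # --- predominantly depressed ----------------------------------------
    # manic impairment must stay <=1/4 of time and not exceed mild severity
    man_ok = man_frac <= 0.25 and max_man <= 1
    if man_ok and dep_frac > 1 / 3 and max_dep <= 2:
        return result(CourseLabel.DEPRESSED, "depressed:third_mild_moderate")
    if man_ok and dep_frac >= 0.25 and max_dep >= 4:
        return result(CourseLabel.DEPRESSED, "depressed:quarter_severe")

    # --- mildly impaired -------------------------------------------------
    if stable_frac > 0.90:
        return result(CourseLabel.MILDLY_IMPAIRED, "mild:stable_90pct")
    if max_dep <= 1 and max_man <= 1 and dep_frac <= 1 / 3 and man_frac <= 1 / 3:
        return result(CourseLabel.MILDLY_IMPAIRED, "mild:mild_third")
    if max_dep <= 3 and max_man <= 3 and dep_frac <= 0.25 and man_frac <= 0.25:
        return result(CourseLabel.MILDLY_IMPAIRED, "mild:moderate_quarter")

    # --- fallback: nearest rule, keeps the taxonomy exhaustive -----------
    if dep_frac >= 0.25 and dep_frac > man_frac:
        return result(CourseLabel.DEPRESSED, "fallback:depressed")
    if man_frac >= 0.25 or (man_frac > 1 / 8 and dep_frac > 1 / 8):
        return result(CourseLabel.CYCLING, "fallback:cycling")
    return result(CourseLabel.MILDLY_IMPAIRED, "fallback:mildly_impaired")


def classify_course(chart: LifeChart) -> CourseLabel:
    """Assign the chart to exactly one course type.

    Rules are evaluated in fixed precedence order cycling -> depressed ->
    mildly impaired, then the documented nearest-rule fallback; the result
    is a pure function of the chart content.
    """
    return _classify(chart).label


class CourseClassifier:
    """Rule-based course-type classifier with a scikit-learn interface.

    The classifier is stateless (the rules carry no free parameters), so
    :meth:`fit` only validates the input and returns ``self``; it exists so
    the estimator composes with sklearn pipelines and model selection.

    Examples
    --------
    >>> chart = LifeChart("p1", tuple((0, 0) for _ in range(24)))
    >>> CourseClassifier().predict([chart])
    [<CourseLabel.MILDLY_IMPAIRED: 'mildly_impaired'>]
    """

    def fit(self, X: Iterable[LifeChart], y=None) -> "CourseClassifier":
        for chart in X:
            if not isinstance(chart, LifeChart):
                raise TypeError("CourseClassifier expects LifeChart instances")
        self.classes_ = [label for label in CourseLabel]
        return self

    def predict(self, X: Iterable[LifeChart]) -> list[CourseLabel]:
        return [classify_course(chart) for chart in X]

    def predict_detail(self, X: Iterable[LifeChart]) -> list[ClassificationResult]:
        """Like :meth:`predict` but also reports which rule fired."""
        return [_classify(chart) for chart in X]

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "CourseClassifier":
        if params:
            raise ValueError(f"CourseClassifier has no parameters; got {params}")
        return self


# ---------------------------------------------------------------------------
# tidy-table I/O
# ---------------------------------------------------------------------------

_LIFECHART_COLUMNS = ["patient_id", "month_index", "dep_severity", "man_severity"]


def read_lifechart_table(source, sep: str = ",") -> list[LifeChart]:
    """Read life charts from a tidy table (one row per patient-month).

    Expected columns: ``patient_id``, ``month_index`` (1-24),
    ``dep_severity``, ``man_severity``. Accepts a path or a DataFrame.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=sep)
    missing = [c for c in _LIFECHART_COLUMNS if c not in df.columns]
    if missing:
        raise LifeChartError(f"life-chart table missing columns {missing}")
    charts = []
    for pid, sub in df.groupby("patient_id", sort=True):
        sub = sub.sort_values("month_index")
        idx = sub["month_index"].to_numpy()
        if len(idx) != N_MONTHS or not np.array_equal(idx, np.arange(1, N_MONTHS + 1)):
            raise LifeChartError(
                f"patient {pid!r}: month_index must be exactly 1..{N_MONTHS}"
            )
        months = tuple(
            (int(d), int(m))
            for d, m in zip(sub["dep_severity"], sub["man_severity"])
        )
        charts.append(LifeChart(str(pid), months))
    return charts


def lifecharts_to_table(charts: Sequence[LifeChart]) -> pd.DataFrame:
    """Inverse of :func:`read_lifechart_table` (tidy patient-month rows)."""
    rows = [
        (c.patient_id, i + 1, dep, man)
        for c in charts
        for i, (dep, man) in enumerate(c.months)
    ]
    return pd.DataFrame(rows, columns=_LIFECHART_COLUMNS)


def classification_report(charts: Sequence[LifeChart]) -> pd.DataFrame:
    """Tidy report: patient_id, label, dep_frac, man_frac, rule_fired."""
    results = CourseClassifier().fit(charts).predict_detail(charts)
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in results],
            "label": [r.label.value for r in results],
            "dep_frac": [r.proportions.dep_frac for r in results],
            "man_frac": [r.proportions.man_frac for r in results],
            "rule_fired": [r.rule_fired for r in results],
        }
    )
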