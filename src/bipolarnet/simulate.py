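"""Synthetic cohorts: life-chart dynamics and copula-driven symptom panels.

Two generators make every pipeline stage testable without patient data:

* *Life charts* follow a first-order Markov process over the joint
  monthly (depression, mania) severity state, parametrised per course
  type by episode entry, persistence and pole-switch rates plus
  within-episode severity distributions. The three default models are
  archetypes of the three course types (rare mild episodes; persistent
  depression; alternating bilateral episodes).

* *Symptom items* come from a Gaussian copula: a latent multivariate
  normal draw with a type-specific correlation matrix is cut at per-item
  thresholds into ordinal categories, reproducing the zero-inflated,
  heavily tied distributions of QIDS/YMRS items while controlling the
  latent correlation structure. Before discretisation the population
  Spearman correlation of a latent pair with Pearson correlation r is
  (6/pi)*asin(r/2); discretisation attenuates it, so the default latent
  correlations were calibrated against a large-sample run of this same
  generator so that the population Spearman *densities* of the three
  groups are 0.25 (cycling), 0.19 (mildly impaired) and 0.14 (depressed).

Symptom severity is coupled to the course type (via latent mean offsets
by pole and by timepoint), not to individual chart months; the analysis
pipeline never joins months to timepoints, so this looser coupling is
sufficient for testing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lifechart import N_MONTHS, CourseLabel, LifeChart
from .panel import (
    ALL_ITEMS,
    ITEM_RANGES,
    MERGED_ITEM_ORDER,
    N_TIMEPOINTS,
    SymptomPanel,
    default_item_map,
)

__all__ = [
    "ChartModel",
    "CohortSpec",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_CHART_MODELS",
    "DEFAULT_COPULA_BLOCKS",
    "block_copula",
    "latent_spearman",
    "simulate_lifechart",
    "simulate_symptom_scores",
    "simulate_cohort",
]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# life-chart Markov models
# ---------------------------------------------------------------------------

_EUTHYMIC, _DEP, _MAN, _MIXED = range(4)


@dataclass(frozen=True)
class ChartModel:
    """Constrained parametric monthly Markov model over mood states.

    The latent macro state is euthymic / depressed / manic / mixed;
    month-to-month transitions are governed by entry rates from euthymia,
    an episode persistence probability and a pole-switch probability on
    episode exit. Within an episode the month's severity (1-4) is drawn
    from the pole's severity distribution; mixed months draw both poles
    independently. The induced chain over the 25 joint (dep, man)
    severity states is first order and is exposed by
    :meth:`joint_transition_matrix`.
    """

    p_enter_dep: float
    p_enter_man: float
    p_enter_mixed: float
    p_stay: float
    p_switch: float
    dep_severity_probs: tuple[float, float, float, float]
    man_severity_probs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name in ("p_enter_dep", "p_enter_man", "p_enter_mixed",
                     "p_stay", "p_switch"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        if self.p_enter_dep + self.p_enter_man + self.p_enter_mixed > 1:
            raise SimulationError("episode entry probabilities exceed 1")
        for name in ("dep_severity_probs", "man_severity_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (4,) or (p < 0).any() or abs(p.sum() - 1) > 1e-9:
                raise SimulationError(
                    f"{name} must be 4 non-negative probabilities summing to 1"
                )

    def macro_transition_matrix(self) -> np.ndarray:
        """4x4 transition matrix over euthymic/dep/man/mixed."""
        P = np.zeros((4, 4))
        P[_EUTHYMIC] = [1 - self.p_enter_dep - self.p_enter_man - self.p_enter_mixed,
                        self.p_enter_dep, self.p_enter_man, self.p_enter_mixed]
        leave = 1 - self.p_stay
        P[_DEP] = [leave * (1 - self.p_switch), self.p_stay,
                   leave * self.p_switch, 0.0]
        P[_MAN] = [leave * (1 - self.p_switch), leave * self.p_switch,
                   self.p_stay, 0.0]
        P[_MIXED] = [leave * (1 - self.p_switch),
                     leave * self.p_switch / 2, leave * self.p_switch / 2,
                     self.p_stay]
        return P

    def joint_transition_matrix(self) -> np.ndarray:
        """25x25 transition matrix over joint (dep, man) severity states,
        ordered as dep * 5 + man. Rows sum to one."""
        macro = self.macro_transition_matrix()
        dep_p = np.asarray(self.dep_severity_probs)
        man_p = np.asarray(self.man_severity_probs)
        # emission distribution of each macro state over joint states
        emit = np.zeros((4, 25))
        emit[_EUTHYMIC, 0] = 1.0
        emit[_DEP, [d * 5 for d in range(1, 5)]] = dep_p
        emit[_MAN, [m for m in range(1, 5)]] = man_p
        for d in range(1, 5):
            for m in range(1, 5):
                emit[_MIXED, d * 5 + m] = dep_p[d - 1] * man_p[m - 1]
        joint = np.zeros((25, 25))
        for d in range(5):
            for m in range(5):
                if d and m:
                    g = _MIXED
                elif d:
                    g = _DEP
                elif m:
                    g = _MAN
                else:
                    g = _EUTHYMIC
                joint[d * 5 + m] = macro[g] @ emit
        return joint


def _validate_transition_matrix(P: np.ndarray) -> None:
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise SimulationError("transition matrix must be square")
    if (P < -1e-12).any() or not np.allclose(P.sum(axis=1), 1.0):
        bad = np.nonzero(~np.isclose(P.sum(axis=1), 1.0))[0]
        raise SimulationError(f"transition-matrix rows {list(bad)} do not sum to 1")


#: archetypal monthly dynamics for the three course types
DEFAULT_CHART_MODELS: dict[CourseLabel, ChartModel] = {
    # rare, short, mild episodes; mostly euthymic
    CourseLabel.MILDLY_IMPAIRED: ChartModel(
        p_enter_dep=0.05, p_enter_man=0.03, p_enter_mixed=0.0,
        p_stay=0.35, p_switch=0.0,
        dep_severity_probs=(0.85, 0.15, 0.0, 0.0),
        man_severity_probs=(0.85, 0.15, 0.0, 0.0),
    ),
    # frequent, persistent depressive episodes; mania rare and mild
    CourseLabel.DEPRESSED: ChartModel(
        p_enter_dep=0.32, p_enter_man=0.01, p_enter_mixed=0.01,
        p_stay=0.82, p_switch=0.02,
        dep_severity_probs=(0.30, 0.50, 0.20, 0.0),
        man_severity_probs=(0.90, 0.10, 0.0, 0.0),
    ),
    # alternating bilateral episodes with frequent pole switches
    CourseLabel.CYCLING: ChartModel(
        p_enter_dep=0.18, p_enter_man=0.24, p_enter_mixed=0.05,
        p_stay=0.65, p_switch=0.45,
        dep_severity_probs=(0.25, 0.50, 0.20, 0.05),
        man_severity_probs=(0.25, 0.50, 0.20, 0.05),
    ),
}

DEFAULT_GROUP_SIZES: dict[CourseLabel, int] = {
    CourseLabel.MILDLY_IMPAIRED: 47,
    CourseLabel.DEPRESSED: 42,
    CourseLabel.CYCLING: 36,
}

#: latent (within-pole, cross-pole) correlations per group, calibrated by
#: large-n simulation of this generator so the population Spearman density
#: of the discretised items is 0.25 / 0.19 / 0.14 (cycling / mild /
#: depressed); the cycling group gets relatively stronger cross-pole
#: edges, its hallmark (manic and depressive symptoms interconnected)
DEFAULT_COPULA_BLOCKS: dict[CourseLabel, tuple[float, float]] = {
    CourseLabel.MILDLY_IMPAIRED: (0.450, 0.060),
    CourseLabel.DEPRESSED: (0.313, 0.042),
    CourseLabel.CYCLING: (0.385, 0.220),
}

#: merged items expressing the manic pole (others express depression)
_MANIC_ITEMS = frozenset({
    "irritability", "increased speech", "elevated mood", "restlessness",
    "sleep duration",
})

#: latent mean offset per course type and pole: depressed group loads on
#: depressive items, cycling on both, mildly impaired on neither
_TYPE_POLE_OFFSET: dict[CourseLabel, tuple[float, float]] = {
    CourseLabel.MILDLY_IMPAIRED: (-0.45, -0.30),  # (dep items, man items)
    CourseLabel.DEPRESSED: (0.25, -0.55),
    CourseLabel.CYCLING: (0.15, 0.15),
}

#: base category probabilities of a merged (4-category) item at the peak
#: condition, before pole/type mean offsets; manic-pole items are more
#: zero-inflated, as they are in outpatient samples
_DEP_BASE_PROBS = (0.40, 0.28, 0.20, 0.12)
_MAN_BASE_PROBS = (0.62, 0.20, 0.11, 0.07)


def _item_base_probs(merged_name: str) -> tuple[float, ...]:
    return _MAN_BASE_PROBS if merged_name in _MANIC_ITEMS else _DEP_BASE_PROBS


def block_copula(within_pole: float, cross_pole: float) -> np.ndarray:
    """Two-pole latent correlation matrix over the 14 merged items.

    Items within the same pole (depressive or manic) share
    ``within_pole``; cross-pole pairs share ``cross_pole``.
    """
    man = np.array([item in _MANIC_ITEMS for item in MERGED_ITEM_ORDER])
    R = np.where(np.equal.outer(man, man), within_pole, cross_pole).astype(float)
    np.fill_diagonal(R, 1.0)
    if np.linalg.eigvalsh(R).min() <= 0:
        raise SimulationError(
            f"block copula ({within_pole}, {cross_pole}) not positive definite")
    return R


def _cutpoints(probs) -> np.ndarray:
    """Strictly increasing z-cutpoints from category probabilities."""
    p = np.asarray(probs, dtype=float)
    if (p <= 0).any() or abs(p.sum() - 1) > 1e-9:
        raise SimulationError("category probabilities must be positive and sum to 1")
    cuts = stats.norm.ppf(np.cumsum(p)[:-1])
    if not (np.diff(cuts) > 0).all():
        raise SimulationError("thresholds must be strictly increasing")
    return cuts


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 125 patients split 47/42/36
    over mildly impaired / depressed / cycling, 24-month charts, five
    symptom timepoints, and group copulas whose population Spearman
    densities are ordered cycling > mildly impaired > depressed.
    """

    group_sizes: dict[CourseLabel, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    chart_models: dict[CourseLabel, ChartModel] = field(
        default_factory=lambda: dict(DEFAULT_CHART_MODELS))
    copulas: dict[CourseLabel, np.ndarray] | None = None
    n_timepoints: int = N_TIMEPOINTS
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n in self.group_sizes.items():
            if n < 3:
                raise SimulationError(f"group size for {label} must be >= 3")
        if self.copulas is None:
            cop = {label: block_copula(rw, rx)
                   for label, (rw, rx) in DEFAULT_COPULA_BLOCKS.items()}
            object.__setattr__(self, "copulas", cop)
        for label, R in self.copulas.items():
            R = np.asarray(R, dtype=float)
            if not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
                raise SimulationError(
                    f"copula for {label} must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(R).min() <= 0:
                raise SimulationError(f"copula for {label} is not positive definite")

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes.values())


def latent_spearman(r: float) -> float:
    """Population Spearman of a bivariate-normal pair with Pearson r,
    before discretisation: (6/pi) * asin(r/2)."""
    return float(6.0 / np.pi * np.arcsin(r / 2.0))


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_lifechart(label: CourseLabel, spec: CohortSpec | None = None,
                       seed=None, patient_id: str = "sim") -> LifeChart:
    """Draw one 24-month life chart from the course type's Markov model."""
    spec = spec if spec is not None else CohortSpec()
    model = spec.chart_models[label]
    P = model.joint_transition_matrix()
    _validate_transition_matrix(P)
    rng = _as_rng(seed)
    state = 0  # start euthymic
    months = []
    for _ in range(N_MONTHS):
        state = int(rng.choice(25, p=P[state]))
        months.append((state // 5, state % 5))
    return LifeChart(patient_id, tuple(months))


def _merged_latent_offsets(label: CourseLabel) -> np.ndarray:
    dep_off, man_off = _TYPE_POLE_OFFSET[label]
    return np.asarray([
        man_off if item in _MANIC_ITEMS else dep_off
        for item in MERGED_ITEM_ORDER
    ])


def _discretise(latent: np.ndarray, cuts: np.ndarray) -> np.ndarray:
    return np.searchsorted(cuts, latent, side="left")


def simulate_symptom_scores(label: CourseLabel, spec: CohortSpec | None = None,
                            n: int = 40, seed=None,
                            mean_shift: float = 0.0) -> pd.DataFrame:
    """Draw n merged 14-item ordinal vectors at the peak condition.

    A latent MVN draw with the type's copula (plus pole-specific mean
    offsets and an optional extra ``mean_shift``) is cut into four
    ordinal categories per item.
    """
    spec = spec if spec is not None else CohortSpec()
    rng = _as_rng(seed)
    R = np.asarray(spec.copulas[label], dtype=float)
    k = R.shape[0]
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n, k)) @ L.T
    z += _merged_latent_offsets(label) + mean_shift
    values = np.empty_like(z)
    for i, item in enumerate(MERGED_ITEM_ORDER):
        values[:, i] = _discretise(z[:, i], _cutpoints(_item_base_probs(item)))
    return pd.DataFrame(values, columns=list(MERGED_ITEM_ORDER))


# ---------------------------------------------------------------------------
# full cohort with raw source items
# ---------------------------------------------------------------------------

#: per-source-item raw category values (subset of the item's legal range);
#: double-weighted YMRS items use even scores, as their anchors do
def _source_categories(code: str) -> np.ndarray:
    lo, hi = ITEM_RANGES[code]
    if hi == 8:
        return np.array([0, 2, 4, 6])
    return np.arange(0, 4)


#: the three screened-out YMRS items are generated almost always zero so
#: the low-variance screen reproduces their exclusion
_SPARSE_ITEMS = {"y03": 0.96, "y10": 0.97, "y11": 0.96}

#: loading of a source item on its merged item's latent factor
_SOURCE_LOADING = 0.90

#: latent mean offsets relative to the peak condition. The gaps are wide:
#: the peak visit represents a genuine episode state while other visits
#: are largely remitted (mostly-zero items, the baseline most of all), so
#: the empirical most-symptomatic timepoint is almost always the designed
#: one and max-selection adds little selection distortion
_BASELINE_SHIFT = -2.2
_NONPEAK_SHIFT = -1.6


def simulate_cohort(spec: CohortSpec | None = None):
    """Simulate a full cohort: life charts, raw symptom panel, true labels.

    Returns ``(charts, panel, labels)`` where ``charts`` is a list of
    :class:`LifeChart`, ``panel`` a :class:`SymptomPanel` of raw QIDS/YMRS
    item scores at 5 timepoints, and ``labels`` a Series of true course
    types indexed by patient_id. Each patient has one randomly placed
    post-baseline peak timepoint at full severity; other timepoints are
    shifted toward zero (the baseline most strongly, matching the mostly
    euthymic study entry). Raw source items load on their merged item's
    latent factor, so the merge step recovers the copula structure.
    Deterministic for a fixed ``spec.seed``.
    """
    spec = spec if spec is not None else CohortSpec()
    rng = np.random.default_rng(spec.seed)
    item_map = default_item_map()
    merged_of = {s: m for m in item_map.merged for s in m.sources}

    charts: list[LifeChart] = []
    labels: dict[str, str] = {}
    rows = []
    pid_counter = 0
    cuts_of = {m: _cutpoints(_item_base_probs(m)) for m in MERGED_ITEM_ORDER}
    for label in (CourseLabel.MILDLY_IMPAIRED, CourseLabel.DEPRESSED,
                  CourseLabel.CYCLING):
        n = spec.group_sizes[label]
        R = np.asarray(spec.copulas[label], dtype=float)
        L = np.linalg.cholesky(R)
        offsets = _merged_latent_offsets(label)
        for _ in range(n):
            pid = f"p{pid_counter:04d}"
            pid_counter += 1
            labels[pid] = label.value
            charts.append(simulate_lifechart(label, spec, seed=rng, patient_id=pid))
            peak_tp = int(rng.integers(1, spec.n_timepoints))
            for tp in range(spec.n_timepoints):
                if tp == 0:
                    shift = _BASELINE_SHIFT
                elif tp == peak_tp:
                    shift = 0.0
                else:
                    shift = _NONPEAK_SHIFT
                z = L @ rng.standard_normal(len(MERGED_ITEM_ORDER))
                z += offsets + shift
                row: dict = {"patient_id": pid, "timepoint": tp}
                zm = dict(zip(MERGED_ITEM_ORDER, z))
                for code in ALL_ITEMS:
                    if code in _SPARSE_ITEMS:
                        p0 = _SPARSE_ITEMS[code]
                        row[code] = int(rng.random() > p0)
                        continue
                    mname = merged_of[code].name
                    eps = rng.standard_normal()
                    zi = _SOURCE_LOADING * zm[mname] + \
                        np.sqrt(1 - _SOURCE_LOADING ** 2) * eps
                    cats = _source_categories(code)
                    row[code] = int(cats[min(int(_discretise(zi, cuts_of[mname])),
                                             len(cats) - 1)])
                rows.append(row)

    panel = SymptomPanel.from_tidy(pd.DataFrame(rows))
    label_series = pd.Series(labels, name="true_label")
    label_series.index.name = "patient_id"
    return charts, panel, label_series
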