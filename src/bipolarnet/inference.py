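"""Bootstrap confidence intervals and group comparison for network metrics.

Groups are compared descriptively: each metric (density, per-item
strength, per-item random-walk betweenness) gets a percentile bootstrap
confidence interval from resampling *patients* with replacement (10,000
iterations, 95% level by default), and two groups count as distinct on a
metric when their intervals overlap by less than half of the mean
interval width. A sensitivity variant rebuilds each group's network as
the entrywise mean of the five per-timepoint Spearman matrices instead of
using only the most symptomatic timepoint.

Point estimates are the plug-in statistics on the observed sample; a
percentile interval is not guaranteed to contain them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import (
    NetworkError,
    SymptomNetwork,
    build_network,
    current_flow_betweenness,
    network_density,
    node_strength,
    spearman_edge,
)
from .panel import ItemMap, ItemMerger, SymptomPanel

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapSummary",
    "OverlapVerdict",
    "NetworkBootstrap",
    "bootstrap_metric_ci",
    "ci_overlap_fraction",
    "timepoint_averaged_network",
    "TopKResult",
    "top_k_items",
]


@dataclass(frozen=True)
class BootstrapSummary:
    """Point estimate plus percentile CI for one metric in one group."""

    metric: str
    group: str
    point_estimate: float
    lower: float
    upper: float
    n_iterations: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("lower bound exceeds upper bound")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    @property
    def width(self) -> float:
        return self.upper - self.lower


class NetworkBootstrap:
    """Patient-resampling bootstrap of network metrics for one group.

    Parameters
    ----------
    n_iter:
        Bootstrap iterations (default 10,000).
    level:
        Confidence level for the percentile interval (default 0.95).
    seed:
        Seed for the resampling RNG; identical seed + data reproduce the
        summaries bit for bit.
    statistics:
        Subset of {"density", "strength", "rw_betweenness"} to track;
        restricting to "density" makes large simulation studies cheap.
    absolute:
        Absolute-value variant for density and strength.

    Replicates in which any item is constant (so some Spearman edge is
    undefined) are redrawn and counted in ``n_redrawn_``; if fewer than
    half of the attempted replicates are valid, the run aborts.
    """

    def __init__(self, n_iter: int = 10_000, level: float = 0.95,
                 seed: int | None = None,
                 statistics: tuple[str, ...] = ("density", "strength",
                                                "rw_betweenness"),
                 absolute: bool = False):
        self.n_iter = n_iter
        self.level = level
        self.seed = seed
        self.statistics = statistics
        self.absolute = absolute

    def fit(self, X, y=None, group: str = "") -> "NetworkBootstrap":
        if isinstance(X, pd.DataFrame):
            items = tuple(X.columns)
            data = X.to_numpy(dtype=float)
        else:
            data = np.asarray(X, dtype=float)
            items = tuple(f"item_{i}" for i in range(data.shape[1]))
        n, k = data.shape
        if n < 3:
            raise NetworkError(f"group size {n} < 3")
        unknown = set(self.statistics) - {"density", "strength", "rw_betweenness"}
        if unknown:
            raise ValueError(f"unknown statistics {sorted(unknown)}")

        net = build_network(pd.DataFrame(data, columns=items))
        self.network_ = net
        point = {
            "density": network_density(net, absolute=self.absolute),
            "strength": node_strength(net, absolute=self.absolute).to_numpy(),
            "rw_betweenness": current_flow_betweenness(net.weights),
        }

        rng = np.random.default_rng(self.seed)
        want_rwb = "rw_betweenness" in self.statistics
        dens = np.empty(self.n_iter)
        stre = np.empty((self.n_iter, k)) if "strength" in self.statistics else None
        rwb = np.empty((self.n_iter, k)) if want_rwb else None
        iu = np.triu_indices(k, 1)
        done = 0
        attempts = 0
        redrawn = 0
        max_attempts = 2 * self.n_iter
        while done < self.n_iter:
            if attempts >= max_attempts:
                raise NetworkError(
                    f"metric undefined on more than half of the bootstrap "
                    f"replicates ({redrawn}/{attempts} redrawn): group too "
                    f"small or items too sparse"
                )
            attempts += 1
            idx = rng.integers(0, n, n)
            Xi = data[idx]
            if (Xi == Xi[0]).all(axis=0).any():  # constant column -> undefined
                redrawn += 1
                continue
            ranks = stats.rankdata(Xi, axis=0)
            C = np.corrcoef(ranks, rowvar=False)
            np.fill_diagonal(C, 0.0)
            C = np.clip(C, -1.0, 1.0)
            W = np.abs(C) if self.absolute else C
            dens[done] = W[iu].mean()
            if stre is not None:
                stre[done] = W.sum(axis=1)
            if want_rwb:
                rwb[done] = current_flow_betweenness(C)
            done += 1

        self.n_redrawn_ = redrawn
        if redrawn:
            logger.warning("bootstrap (group=%s): %d replicates redrawn "
                           "because of undefined edges", group, redrawn)
        alpha = (1.0 - self.level) / 2.0
        qs = [100 * alpha, 100 * (1 - alpha)]

        def summarise(name: str, est: float, draws: np.ndarray) -> BootstrapSummary:
            lo, hi = np.percentile(draws, qs)
            return BootstrapSummary(name, group, float(est), float(lo),
                                    float(hi), self.n_iter, self.seed)

        self.replicates_ = {"density": dens}
        self.summaries_ = {}
        if "density" in self.statistics:
            self.summaries_["density"] = summarise("density", point["density"], dens)
        if stre is not None:
            self.replicates_["strength"] = stre
            for i, item in enumerate(items):
                self.summaries_[f"strength:{item}"] = summarise(
                    f"strength:{item}", point["strength"][i], stre[:, i])
        if want_rwb:
            self.replicates_["rw_betweenness"] = rwb
            for i, item in enumerate(items):
                self.summaries_[f"rw_betweenness:{item}"] = summarise(
                    f"rw_betweenness:{item}", point["rw_betweenness"][i], rwb[:, i])
        self.items_ = items
        return self

    def get_params(self, deep: bool = True) -> dict:
        return {"n_iter": self.n_iter, "level": self.level, "seed": self.seed,
                "statistics": self.statistics, "absolute": self.absolute}

    def set_params(self, **params) -> "NetworkBootstrap":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self


def bootstrap_metric_ci(group, metric: str, n_iter: int = 10_000,
                        level: float = 0.95, seed: int | None = None,
                        group_label: str = "") -> BootstrapSummary:
    """Percentile bootstrap CI for one metric of one group.

    ``metric`` is ``"density"``, ``"strength:<item>"`` or
    ``"rw_betweenness:<item>"``; ``group`` is a patients x items frame.
    """
    base = metric.split(":", 1)[0]
    nb = NetworkBootstrap(n_iter=n_iter, level=level, seed=seed,
                          statistics=(base,)).fit(group, group=group_label)
    if metric not in nb.summaries_:
        raise NetworkError(f"unknown metric {metric!r}")
    return nb.summaries_[metric]


@dataclass(frozen=True)
class OverlapVerdict:
    """CI-overlap comparison of one metric between two groups."""

    groups: tuple[str, str]
    metric: str
    overlap_fraction: float
    distinct: bool


def ci_overlap_fraction(a: BootstrapSummary, b: BootstrapSummary,
                        rule: str = "width") -> OverlapVerdict:
    """Overlap of two CIs relative to their mean width.

    ``overlap = |[a.lower, a.upper] ∩ [b.lower, b.upper]| / mean(widths)``,
    clipped to [0, 1]; the groups are called distinct when the fraction is
    strictly below 0.5 (non-overlap always implies distinct). With
    ``rule="arm"`` the denominator is the mean half-width instead.
    If both intervals are degenerate points, overlap is 1 when they
    coincide and 0 otherwise.
    """
    if a.metric != b.metric:
        raise ValueError(f"metrics differ: {a.metric!r} vs {b.metric!r}")
    if rule not in ("width", "arm"):
        raise ValueError(f"unknown overlap rule {rule!r}")
    inter = min(a.upper, b.upper) - max(a.lower, b.lower)
    mean_width = 0.5 * (a.width + b.width)
    if mean_width == 0:
        frac = 1.0 if (a.lower == b.lower and a.upper == b.upper) else 0.0
    else:
        denom = mean_width if rule == "width" else 0.5 * mean_width
        frac = float(np.clip(max(inter, 0.0) / denom, 0.0, 1.0))
    return OverlapVerdict(groups=(a.group, b.group), metric=a.metric,
                          overlap_fraction=frac, distinct=frac < 0.5)


# ---------------------------------------------------------------------------
# sensitivity analysis: timepoint-averaged networks
# ---------------------------------------------------------------------------


def _lenient_spearman(X: np.ndarray, min_pairs: int = 3) -> np.ndarray:
    """Pairwise Spearman matrix with NaN where an edge is undefined."""
    k = X.shape[1]
    C = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                C[i, j] = C[j, i] = spearman_edge(X[:, i], X[:, j], min_pairs)
            except NetworkError:
                C[i, j] = C[j, i] = np.nan
    return C


def timepoint_averaged_network(panel: SymptomPanel, item_map: ItemMap,
                               patient_ids=None,
                               merger: ItemMerger | None = None) -> SymptomNetwork:
    """Sensitivity network: per-timepoint Spearman matrices averaged entrywise.

    For each of the five timepoints a full Spearman matrix is computed over
    the group's merged item vectors at that timepoint; the output edge
    weights are the entrywise means. Timepoints where an edge is undefined
    are dropped from that edge's mean (counted and logged); an edge
    undefined at every timepoint raises.

    ``merger`` may carry pre-fitted standardisation moments (e.g. pooled
    over the whole cohort); by default the merger is fitted on the pooled
    records of the supplied panel.
    """
    records = panel.data
    if patient_ids is not None:
        patient_ids = [str(p) for p in patient_ids]
        records = records[records.index.get_level_values("patient_id").isin(patient_ids)]
    if merger is None:
        merger = ItemMerger(item_map).fit(panel.data)
    merged = merger.transform(records)
    items = tuple(merger.columns_)
    k = len(items)
    timepoints = sorted(set(records.index.get_level_values("timepoint")))
    mats = []
    for t in timepoints:
        sub = merged.xs(t, level="timepoint")
        if len(sub) < 3:
            raise NetworkError(f"fewer than 3 patients with data at timepoint {t}")
        mats.append(_lenient_spearman(sub.to_numpy(dtype=float)))
    stack = np.stack(mats)
    n_dropped = int(np.isnan(stack).sum() // 2)
    if n_dropped:
        logger.warning("timepoint-averaged network: %d edge-timepoints dropped "
                       "(undefined edges)", n_dropped)
    all_nan = np.isnan(stack).all(axis=0)
    np.fill_diagonal(all_nan, False)
    if all_nan.any():
        i, j = np.argwhere(all_nan)[0]
        raise NetworkError(
            f"edge ({items[i]!r}, {items[j]!r}) undefined at every timepoint")
    with np.errstate(invalid="ignore"):
        W = np.nanmean(stack, axis=0)
    np.fill_diagonal(W, 0.0)
    n_patients = len(set(records.index.get_level_values("patient_id")))
    return SymptomNetwork(items=items, weights=W, n_patients=n_patients)


# ---------------------------------------------------------------------------
# top-k tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopKResult:
    items: tuple[str, ...]
    tied: bool  # a tie straddles the k-th position (order partly arbitrary)

    def __iter__(self):
        return iter(self.items)


def top_k_items(metrics: pd.Series | dict, k: int = 5) -> TopKResult:
    """The k items with the highest metric, descending; alphabetical on ties.

    ``tied`` flags a tie crossing the cut (items inside and outside the
    top-k share a value), in which case membership is alphabetical among
    the tied block and partly arbitrary scientifically.
    """
    s = pd.Series(metrics, dtype=float)
    if k > len(s):
        raise ValueError(f"k={k} exceeds number of items {len(s)}")
    ordered = s.sort_index().sort_values(ascending=False, kind="stable")
    top = ordered.iloc[:k]
    tied = bool(k < len(ordered) and ordered.iloc[k - 1] == ordered.iloc[k])
    return TopKResult(items=tuple(top.index), tied=tied)
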