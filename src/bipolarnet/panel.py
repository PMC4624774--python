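"""Raw QIDS-SR / YMRS item panels and their preparation for network analysis.

The panel holds, per patient and per assessment timepoint (0 = baseline,
then every 6 months, 5 timepoints in total), the raw ordinal item scores of
two mood scales:

* QIDS-SR16 -- 16 self-report depression items, each 0-3; the published
  total (0-27) scores nine domains: the highest of the four sleep items,
  the highest of the four appetite/weight items, the highest of the two
  psychomotor items, plus the six single-item domains.
* YMRS -- 11 observer-rated mania items; seven are rated 0-4 and four
  (irritability, speech, content, disruptive-aggressive behaviour) are
  double-weighted 0-8, total 0-60 by plain summation.

Preparation for the networks follows three steps:

1. *Peak-timepoint selection*: both scale totals are z-scored over the
   pooled set of all patient-timepoint records and summed; each patient's
   most symptomatic timepoint is the argmax (ties go to the earliest).
2. *Item merging*: overlapping QIDS/YMRS items are combined into 14
   symptom variables. Each source item is z-scored over the analysis
   sample, the highest z wins, and the winning z is mapped back onto the
   reference item's raw scale (a strictly monotone transform, so Spearman
   edges downstream are unaffected by the back-transformation).
3. *Low-variance screening*: items answered zero by at least 94% of the
   sample are unusable for rank correlations and are dropped.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QIDS_ITEMS",
    "YMRS_ITEMS",
    "ITEM_RANGES",
    "N_TIMEPOINTS",
    "MERGED_ITEM_ORDER",
    "SymptomPanel",
    "ItemMap",
    "MergedItem",
    "default_item_map",
    "scale_totals",
    "qids_total",
    "ymrs_total",
    "select_peak_timepoint",
    "PeakTimepointSelector",
    "ItemMerger",
    "merge_items",
    "screen_low_variance",
]

N_TIMEPOINTS = 5

#: QIDS-SR16 item codes -> short descriptions (all rated 0-3)
QIDS_ITEMS: dict[str, str] = {
    "q01": "sleep onset insomnia",
    "q02": "mid-nocturnal insomnia",
    "q03": "early morning waking",
    "q04": "hypersomnia",
    "q05": "sad mood",
    "q06": "appetite decrease",
    "q07": "appetite increase",
    "q08": "weight decrease",
    "q09": "weight increase",
    "q10": "concentration / decision making",
    "q11": "self view",
    "q12": "suicidal ideation",
    "q13": "general interest",
    "q14": "energy level",
    "q15": "psychomotor slowing",
    "q16": "psychomotor agitation",
}

#: YMRS item codes -> (description, max score). Double-weighted items max 8.
YMRS_ITEMS: dict[str, tuple[str, int]] = {
    "y01": ("elevated mood", 4),
    "y02": ("increased motor activity-energy", 4),
    "y03": ("sexual interest", 4),
    "y04": ("sleep", 4),
    "y05": ("irritability", 8),
    "y06": ("speech rate and amount", 8),
    "y07": ("language-thought disorder", 4),
    "y08": ("content", 8),
    "y09": ("disruptive-aggressive behaviour", 8),
    "y10": ("appearance", 4),
    "y11": ("insight", 4),
}

#: item code -> inclusive (min, max) score range
ITEM_RANGES: dict[str, tuple[int, int]] = {
    **{code: (0, 3) for code in QIDS_ITEMS},
    **{code: (0, mx) for code, (_, mx) in YMRS_ITEMS.items()},
}

ALL_ITEMS: tuple[str, ...] = tuple(ITEM_RANGES)

#: fixed order of the 14 merged symptom variables
MERGED_ITEM_ORDER: tuple[str, ...] = (
    "irritability",
    "increased speech",
    "elevated mood",
    "appetite/weight",
    "restlessness",
    "suicidality",
    "concentration",
    "self-esteem",
    "interest",
    "depressed mood",
    "sleep duration",
    "slowness",
    "energy decrease",
    "sleep quality",
)


class PanelError(ValueError):
    """Raised for malformed symptom panels."""


@dataclass
class SymptomPanel:
    """Patient x timepoint grid of raw QIDS/YMRS item scores.

    ``data`` is indexed by ``(patient_id, timepoint)`` with one column per
    item code (q01..q16, y01..y11); missing entries are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if list(df.index.names) != ["patient_id", "timepoint"]:
            raise PanelError(
                "panel index must be a (patient_id, timepoint) MultiIndex"
            )
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise PanelError(f"duplicate record for patient-timepoint {dup}")
        missing_cols = [c for c in ALL_ITEMS if c not in df.columns]
        if missing_cols:
            raise PanelError(f"panel missing item columns {missing_cols}")
        tps = df.index.get_level_values("timepoint")
        bad_tp = set(tps) - set(range(N_TIMEPOINTS))
        if bad_tp:
            raise PanelError(f"timepoints outside 0..{N_TIMEPOINTS - 1}: {sorted(bad_tp)}")
        for code in ALL_ITEMS:
            lo, hi = ITEM_RANGES[code]
            col = df[code]
            bad = col.notna() & ((col < lo) | (col > hi) | (col % 1 != 0))
            if bad.any():
                where = df.index[bad][0]
                raise PanelError(
                    f"item {code} out of range [{lo}, {hi}] (or non-integer) "
                    f"at patient-timepoint {where}"
                )
        self.data = df[list(ALL_ITEMS)].astype(float)

    @property
    def patients(self) -> list[str]:
        return sorted(set(self.data.index.get_level_values("patient_id")))

    @classmethod
    def from_tidy(cls, source, sep: str = ",") -> "SymptomPanel":
        """Build a panel from a tidy table: one row per patient-timepoint,
        columns ``patient_id``, ``timepoint``, then one column per item."""
        df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep=sep)
        for col in ("patient_id", "timepoint"):
            if col not in df.columns:
                raise PanelError(f"tidy symptom table missing column {col!r}")
        df = df.copy()
        df["patient_id"] = df["patient_id"].astype(str)
        df = df.set_index(["patient_id", "timepoint"])
        return cls(df)

    def to_tidy(self) -> pd.DataFrame:
        return self.data.reset_index()

    def records(self) -> pd.DataFrame:
        """Alias for the underlying (patient, timepoint)-indexed frame."""
        return self.data


# ---------------------------------------------------------------------------
# item map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MergedItem:
    name: str
    sources: tuple[str, ...]
    reference: str

    def __post_init__(self) -> None:
        if len(self.sources) < 1:
            raise PanelError(f"merged item {self.name!r} has no sources")
        if self.reference not in self.sources:
            raise PanelError(
                f"merged item {self.name!r}: reference {self.reference!r} "
                f"not among sources {self.sources}"
            )


@dataclass(frozen=True)
class ItemMap:
    """Partition of the source items into 14 merged variables + exclusions.

    Every source item appears in exactly one merged item or in ``excluded``;
    each merged item designates one reference item whose raw scale the
    merged score is expressed on.
    """

    merged: tuple[MergedItem, ...]
    excluded: tuple[str, ...]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for m in self.merged:
            for s in m.sources:
                if s not in ITEM_RANGES:
                    raise PanelError(f"unknown source item {s!r} in {m.name!r}")
                if s in seen:
                    raise PanelError(
                        f"source item {s!r} appears in both {seen[s]!r} and {m.name!r}"
                    )
                seen[s] = m.name
        for s in self.excluded:
            if s not in ITEM_RANGES:
                raise PanelError(f"unknown excluded item {s!r}")
            if s in seen:
                raise PanelError(f"item {s!r} both merged (in {seen[s]!r}) and excluded")
            seen[s] = "<excluded>"
        unassigned = [s for s in ALL_ITEMS if s not in seen]
        if unassigned:
            raise PanelError(f"source items not assigned anywhere: {unassigned}")

    @property
    def merged_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.merged)

    def to_yaml(self, path) -> None:
        payload = {
            "merged": [
                {"name": m.name, "sources": list(m.sources), "reference": m.reference}
                for m in self.merged
            ],
            "excluded": list(self.excluded),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ItemMap":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        merged = tuple(
            MergedItem(d["name"], tuple(d["sources"]), d["reference"])
            for d in payload["merged"]
        )
        return cls(merged=merged, excluded=tuple(payload.get("excluded", ())))

    def drop_sources(self, items: Iterable[str]) -> "ItemMap":
        """Return a map with the given source items moved to ``excluded``.

        A merged item that loses all its sources is dropped entirely."""
        items = set(items)
        merged = []
        for m in self.merged:
            keep = tuple(s for s in m.sources if s not in items)
            if not keep:
                continue
            ref = m.reference if m.reference in keep else keep[0]
            merged.append(MergedItem(m.name, keep, ref))
        return ItemMap(tuple(merged), tuple(sorted(set(self.excluded) | items)))


def default_item_map() -> ItemMap:
    """The documented default 14-item map (user-overridable via YAML).

    Quantity-type sleep items form *sleep duration*, disturbance-type
    items form *sleep quality*; YMRS content (grandiosity) joins
    self-esteem, disruptive-aggressive behaviour joins irritability, and
    language-thought disorder joins increased speech. YMRS sexual
    interest, appearance and insight are excluded up front (the sample's
    zero-fractions put them past the 94% screen).
    """
    merged = (
        MergedItem("irritability", ("y05", "y09"), "y05"),
        MergedItem("increased speech", ("y06", "y07"), "y06"),
        MergedItem("elevated mood", ("y01",), "y01"),
        MergedItem("appetite/weight", ("q06", "q07", "q08", "q09"), "q07"),
        MergedItem("restlessness", ("q16", "y02"), "q16"),
        MergedItem("suicidality", ("q12",), "q12"),
        MergedItem("concentration", ("q10",), "q10"),
        MergedItem("self-esteem", ("q11", "y08"), "q11"),
        MergedItem("interest", ("q13",), "q13"),
        MergedItem("depressed mood", ("q05",), "q05"),
        MergedItem("sleep duration", ("q04", "y04"), "q04"),
        MergedItem("slowness", ("q15",), "q15"),
        MergedItem("energy decrease", ("q14",), "q14"),
        MergedItem("sleep quality", ("q01", "q02", "q03"), "q02"),
    )
    assert tuple(m.name for m in merged) == MERGED_ITEM_ORDER
    return ItemMap(merged=merged, excluded=("y03", "y10", "y11"))


# ---------------------------------------------------------------------------
# scale totals & peak timepoint
# ---------------------------------------------------------------------------

_QIDS_SLEEP = ["q01", "q02", "q03", "q04"]
_QIDS_APPETITE = ["q06", "q07", "q08", "q09"]
_QIDS_PSYCHOMOTOR = ["q15", "q16"]
_QIDS_SINGLE = ["q05", "q10", "q11", "q12", "q13", "q14"]


def qids_total(row: Mapping[str, float]) -> float:
    """Published QIDS-SR16 total (0-27); NaN if any item is missing."""
    vals = {c: row[c] for c in QIDS_ITEMS}
    if any(pd.isna(v) for v in vals.values()):
        return float("nan")
    return float(
        max(vals[c] for c in _QIDS_SLEEP)
        + max(vals[c] for c in _QIDS_APPETITE)
        + max(vals[c] for c in _QIDS_PSYCHOMOTOR)
        + sum(vals[c] for c in _QIDS_SINGLE)
    )


def ymrs_total(row: Mapping[str, float]) -> float:
    """YMRS total (0-60, plain item sum); NaN if any item is missing."""
    vals = [row[c] for c in YMRS_ITEMS]
    if any(pd.isna(v) for v in vals):
        return float("nan")
    return float(sum(vals))


def scale_totals(panel: SymptomPanel) -> pd.DataFrame:
    """Per patient-timepoint QIDS and YMRS totals (missing-propagating)."""
    df = panel.data
    sleep = df[_QIDS_SLEEP].max(axis=1, skipna=False)
    appetite = df[_QIDS_APPETITE].max(axis=1, skipna=False)
    psychomotor = df[_QIDS_PSYCHOMOTOR].max(axis=1, skipna=False)
    single = df[_QIDS_SINGLE].sum(axis=1, skipna=False)
    out = pd.DataFrame(index=df.index)
    out["qids_total"] = sleep + appetite + psychomotor + single
    out["ymrs_total"] = df[list(YMRS_ITEMS)].sum(axis=1, skipna=False)
    return out


class PeakTimepointSelector:
    """Select each patient's most symptomatic timepoint.

    fit() z-scores both scale totals over the pooled set of all
    patient-timepoint records (its standardisation population); predict()
    returns, per patient, the argmax of z(QIDS total) + z(YMRS total) over
    that patient's scoreable timepoints, earliest timepoint on ties.
    Invariant to affine rescaling of either total.
    """

    def fit(self, panel: SymptomPanel, y=None) -> "PeakTimepointSelector":
        totals = scale_totals(panel).dropna()
        if totals.empty:
            raise PanelError("no patient-timepoint with both totals scoreable")
        self.totals_ = totals
        self.mean_ = totals.mean()
        # ddof=0: population SD over the pooled records
        self.std_ = totals.std(ddof=0)
        if (self.std_ == 0).any():
            flat = list(self.std_.index[self.std_ == 0])
            raise PanelError(f"zero pooled variance for totals {flat}")
        return self

    def predict(self, patient_ids: Sequence[str] | None = None) -> pd.Series:
        z = (self.totals_ - self.mean_) / self.std_
        score = z["qids_total"] + z["ymrs_total"]
        if patient_ids is None:
            patient_ids = sorted(set(score.index.get_level_values("patient_id")))
        out = {}
        for pid in patient_ids:
            try:
                s = score.xs(pid, level="patient_id")
            except KeyError:
                raise PanelError(f"patient {pid!r} has no scoreable timepoint")
            s = s.sort_index()  # earliest timepoint wins ties
            out[pid] = int(s.index[np.argmax(s.to_numpy())])
        return pd.Series(out, name="peak_timepoint")

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "PeakTimepointSelector":
        if params:
            raise ValueError(f"no parameters; got {params}")
        return self


def select_peak_timepoint(panel: SymptomPanel, patient_id: str) -> int:
    """Functional wrapper over :class:`PeakTimepointSelector`."""
    sel = PeakTimepointSelector().fit(panel)
    return int(sel.predict([patient_id]).loc[patient_id])


# ---------------------------------------------------------------------------
# item merging
# ---------------------------------------------------------------------------


class ItemMerger:
    """Combine overlapping scale items into the merged symptom variables.

    fit() learns per-source-item means and SDs over the analysis sample
    (the standardisation population, by default all supplied records);
    transform() z-scores every source of a merged item, keeps the highest
    z, and maps it back to the reference item's raw scale:
    ``merged = z_max * sd_ref + mean_ref`` (continuous, not re-rounded).
    Single-source items pass through unchanged. The back-transform is
    strictly monotone in z, so rank-based statistics downstream are
    unchanged by it.
    """

    def __init__(self, item_map: ItemMap | None = None):
        self.item_map = item_map if item_map is not None else default_item_map()

    def fit(self, records: pd.DataFrame, y=None) -> "ItemMerger":
        used = sorted({s for m in self.item_map.merged for s in m.sources})
        missing = [c for c in used if c not in records.columns]
        if missing:
            raise PanelError(f"records missing source columns {missing}")
        self.mean_ = records[used].mean()
        self.std_ = records[used].std(ddof=0)
        self.columns_ = list(self.item_map.merged_names)
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        out = pd.DataFrame(index=records.index, columns=self.columns_, dtype=float)
        for m in self.item_map.merged:
            if len(m.sources) == 1:
                out[m.name] = records[m.sources[0]].astype(float)
                continue
            varying = [s for s in m.sources if self.std_[s] > 0]
            if not varying:
                # every source constant over the sample: nothing to rank,
                # pass the reference item through
                out[m.name] = records[m.reference].astype(float)
                continue
            zs = pd.DataFrame(index=records.index, columns=varying, dtype=float)
            for s in varying:
                zs[s] = (records[s] - self.mean_[s]) / self.std_[s]
            zmax = zs.max(axis=1, skipna=True)  # all-NaN rows stay NaN
            ref_sd = self.std_[m.reference]
            if ref_sd == 0:
                raise PanelError(
                    f"reference item {m.reference!r} of {m.name!r} is constant "
                    "over the analysis sample"
                )
            out[m.name] = zmax * ref_sd + self.mean_[m.reference]
        return out

    def fit_transform(self, records: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(records).transform(records)

    def get_params(self, deep: bool = True) -> dict:
        return {"item_map": self.item_map}

    def set_params(self, **params) -> "ItemMerger":
        for k, v in params.items():
            if k != "item_map":
                raise ValueError(f"unknown parameter {k!r}")
            self.item_map = v
        return self


def merge_items(
    panel: SymptomPanel,
    item_map: ItemMap,
    patient_id: str,
    timepoint: int,
    standardisation_records: pd.DataFrame | None = None,
) -> pd.Series:
    """Merged 14-item vector for one patient-timepoint.

    Standardisation moments come from ``standardisation_records`` (default:
    the pooled set of all patient-timepoint records in the panel).
    """
    records = panel.data
    pop = standardisation_records if standardisation_records is not None else records
    merger = ItemMerger(item_map).fit(pop)
    row = merger.transform(records.loc[[(patient_id, timepoint)]])
    return row.iloc[0]


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


def screen_low_variance(
    values: Sequence[float] | pd.Series, threshold: float = 0.94
) -> tuple[bool, float]:
    """Keep/drop decision for one item across patients.

    Returns ``(keep, zero_fraction)``; the item is dropped when the
    fraction of (non-missing) zero responses is >= ``threshold``.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise PanelError("cannot screen an all-missing item")
    zero_frac = float(np.mean(arr == 0))
    return zero_frac < threshold, zero_frac
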