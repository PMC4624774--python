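"""End-to-end orchestration: classification -> item prep -> networks ->
bootstrap -> sensitivity -> report.

One call (or ``bipolarnet run-all``) reproduces the whole analysis from
two tidy input tables:

* a life-chart table (patient_id, month_index 1-24, dep_severity,
  man_severity), and
* a symptom table (patient_id, timepoint 0-4, one column per raw
  QIDS/YMRS item q01..q16 / y01..y11).

All tunables live in :class:`RunConfig`; every effective value is echoed
into the run log, which is written without timestamps so identical
config + seed yields bit-identical output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .inference import (
    BootstrapSummary,
    NetworkBootstrap,
    OverlapVerdict,
    ci_overlap_fraction,
    timepoint_averaged_network,
    top_k_items,
)
from .lifechart import LifeChart, classification_report, read_lifechart_table
from .network import (
    SpearmanNetwork,
    SymptomNetwork,
    export_network,
    network_density,
    prune_edges,
)
from .panel import (
    ItemMap,
    ItemMerger,
    PeakTimepointSelector,
    SymptomPanel,
    default_item_map,
    scale_totals,
    screen_low_variance,
)

__all__ = ["RunConfig", "ResultBundle", "read_cohort_tables",
           "read_spss_panel", "run_full_pipeline"]

GROUP_ORDER = ("mildly_impaired", "depressed", "cycling")


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline run (YAML-serialisable)."""

    lifechart_path: str = ""
    symptom_path: str = ""
    output_dir: str = "results"
    item_map_path: str | None = None  # None -> documented default map
    low_variance_threshold: float = 0.94
    prune_threshold: float = 0.2
    ci_level: float = 0.95
    n_iter: int = 10_000
    overlap_rule: str = "width"
    seed: int = 0
    absolute_metrics: bool = False
    bootstrap_statistics: tuple[str, ...] = ("density", "strength",
                                             "rw_betweenness")
    sensitivity_bootstrap: bool = False
    top_k: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.low_variance_threshold <= 1:
            raise ValueError("low_variance_threshold outside [0, 1]")
        if not 0 <= self.prune_threshold <= 1:
            raise ValueError("prune_threshold outside [0, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level outside (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        self.bootstrap_statistics = tuple(self.bootstrap_statistics)

    def item_map(self) -> ItemMap:
        if self.item_map_path:
            return ItemMap.from_yaml(self.item_map_path)
        return default_item_map()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bootstrap_statistics"] = list(self.bootstrap_statistics)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_cohort_tables(config: RunConfig) -> tuple[list[LifeChart], SymptomPanel]:
    """Read and validate the life-chart and symptom tables."""
    charts = read_lifechart_table(config.lifechart_path)
    panel = SymptomPanel.from_tidy(config.symptom_path)
    return charts, panel


def read_spss_panel(path, column_binding: dict[str, str]) -> SymptomPanel:
    """Read a symptom panel from an SPSS .sav file.

    ``column_binding`` maps the .sav variable names onto the package's
    schema (patient_id, timepoint, q01..q16, y01..y11) — variable naming
    inside deposited files varies, so the binding is always explicit.
    Requires the optional ``pyreadstat`` backend.
    """
    try:
        df = pd.read_spss(path)
    except ImportError as exc:  # pragma: no cover - backend-dependent
        raise ImportError(
            "reading SPSS files requires the optional dependency pyreadstat "
            "(pip install bipolarnet[spss]); alternatively export the data "
            "to a delimited table"
        ) from exc
    df = df.rename(columns={v: k for k, v in column_binding.items()})
    return SymptomPanel.from_tidy(df)


@dataclass
class ResultBundle:
    """Everything one pipeline run computes, in memory."""

    config: RunConfig
    classification: pd.DataFrame
    peak_timepoints: pd.Series
    screen_log: pd.DataFrame
    item_map: ItemMap
    merged_peak: pd.DataFrame  # patients x items, peak timepoint, + label col
    networks: dict[str, SymptomNetwork]
    node_metrics: dict[str, pd.DataFrame]
    densities: dict[str, float]
    bootstrap_summaries: list[BootstrapSummary]
    overlap_verdicts: list[OverlapVerdict]
    sensitivity_networks: dict[str, SymptomNetwork]
    sensitivity_densities: dict[str, float]
    sensitivity_summaries: list[BootstrapSummary]
    top_strength: dict[str, tuple[tuple[str, ...], bool]]
    top_rwb: dict[str, tuple[tuple[str, ...], bool]]
    mean_qids_at_peak: float
    mean_ymrs_at_peak: float
    log_lines: list[str]


def _group_seed(seed: int, group_index: int) -> int:
    ss = np.random.SeedSequence([seed, group_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _peak_records(panel: SymptomPanel, peaks: pd.Series) -> pd.DataFrame:
    idx = [(pid, int(tp)) for pid, tp in peaks.items()]
    records = panel.data.loc[idx]
    return records.droplevel("timepoint")


def run_full_pipeline(config: RunConfig,
                      charts: list[LifeChart] | None = None,
                      panel: SymptomPanel | None = None) -> ResultBundle:
    """Run every stage in order and write all artifacts to the output dir.

    ``charts``/``panel`` may be passed directly (e.g. fresh from the
    simulator) to skip file reading; otherwise they come from the paths in
    ``config``.
    """
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)

    say(f"bipolarnet {__version__}  numpy {np.__version__}  pandas {pd.__version__}")
    say(f"config hash {config.config_hash()}  seed {config.seed}")
    for key, value in sorted(config.to_dict().items()):
        say(f"config {key} = {value!r}")

    if charts is None or panel is None:
        charts, panel = read_cohort_tables(config)
    say(f"cohort: {len(charts)} charts, "
        f"{panel.data.shape[0]} symptom records x {panel.data.shape[1]} items")

    # --- 1. course classification ---------------------------------------
    classification = classification_report(charts)
    n_fallback = int(classification["rule_fired"].str.startswith("fallback").sum())
    counts = classification["label"].value_counts()
    say("classification: " + ", ".join(
        f"{g}={int(counts.get(g, 0))}" for g in GROUP_ORDER))
    if n_fallback:
        for _, row in classification[
                classification["rule_fired"].str.startswith("fallback")].iterrows():
            say(f"warning: fallback classification for patient "
                f"{row['patient_id']} -> {row['label']}")
    label_of = classification.set_index("patient_id")["label"]

    # --- 2. totals and peak timepoints ----------------------------------
    selector = PeakTimepointSelector().fit(panel)
    peaks = selector.predict()
    totals = scale_totals(panel)
    peak_idx = [(pid, int(tp)) for pid, tp in peaks.items()]
    mean_qids = float(totals.loc[peak_idx, "qids_total"].mean())
    mean_ymrs = float(totals.loc[peak_idx, "ymrs_total"].mean())
    say(f"peak timepoints selected; mean QIDS at peak {mean_qids:.1f}, "
        f"mean YMRS at peak {mean_ymrs:.1f}")

    # --- 3. low-variance screening at the peak sample -------------------
    item_map = config.item_map()
    peak_records = _peak_records(panel, peaks)
    screen_rows = []
    to_drop = []
    in_map = sorted({s for m in item_map.merged for s in m.sources})
    for code in in_map:
        keep, zero_frac = screen_low_variance(
            peak_records[code], config.low_variance_threshold)
        screen_rows.append((code, zero_frac, "keep" if keep else "drop"))
        if not keep:
            to_drop.append(code)
    screen_log = pd.DataFrame(screen_rows,
                              columns=["item", "zero_fraction", "decision"])
    if to_drop:
        say(f"screen: dropping low-variance items {to_drop}")
        item_map = item_map.drop_sources(to_drop)
    for code in item_map.excluded:
        say(f"screen: item {code} excluded from the analysis")
    say(f"item map resolved: {len(item_map.merged)} merged items")

    # --- 4. item merging (pooled standardisation population) ------------
    merger = ItemMerger(item_map).fit(panel.data)
    merged_peak = merger.transform(peak_records)
    merged_peak = merged_peak.join(label_of)

    # --- 5. groupwise networks and metrics ------------------------------
    networks: dict[str, SymptomNetwork] = {}
    node_metrics: dict[str, pd.DataFrame] = {}
    densities: dict[str, float] = {}
    top_strength: dict = {}
    top_rwb: dict = {}
    estimators: dict[str, SpearmanNetwork] = {}
    for group in GROUP_ORDER:
        X = merged_peak[merged_peak["label"] == group].drop(columns="label")
        est = SpearmanNetwork(absolute=config.absolute_metrics).fit(X)
        estimators[group] = est
        networks[group] = est.network_
        densities[group] = est.density_
        node_metrics[group] = pd.DataFrame(
            {"strength": est.strengths_, "rw_betweenness": est.rw_betweenness_})
        ks = top_k_items(est.strengths_, config.top_k)
        kb = top_k_items(est.rw_betweenness_, config.top_k)
        top_strength[group] = (ks.items, ks.tied)
        top_rwb[group] = (kb.items, kb.tied)
        if ks.tied or kb.tied:
            say(f"warning: tie at the top-{config.top_k} cut for group {group}")
        say(f"network {group}: n={est.network_.n_patients}, "
            f"density {est.density_:.3f}")

    # --- 6. bootstrap and group comparison ------------------------------
    summaries: list[BootstrapSummary] = []
    by_group: dict[str, dict[str, BootstrapSummary]] = {}
    for gidx, group in enumerate(GROUP_ORDER):
        X = merged_peak[merged_peak["label"] == group].drop(columns="label")
        nb = NetworkBootstrap(
            n_iter=config.n_iter, level=config.ci_level,
            seed=_group_seed(config.seed, gidx),
            statistics=config.bootstrap_statistics,
            absolute=config.absolute_metrics,
        ).fit(X, group=group)
        if nb.n_redrawn_:
            say(f"warning: bootstrap {group}: {nb.n_redrawn_} replicates "
                f"redrawn (undefined edges)")
        by_group[group] = nb.summaries_
        summaries.extend(nb.summaries_.values())
    verdicts: list[OverlapVerdict] = []
    for ga, gb in itertools.combinations(GROUP_ORDER, 2):
        for metric in by_group[ga]:
            verdicts.append(ci_overlap_fraction(
                by_group[ga][metric], by_group[gb][metric],
                rule=config.overlap_rule))

    # --- 7. sensitivity: timepoint-averaged networks --------------------
    sens_networks: dict[str, SymptomNetwork] = {}
    sens_densities: dict[str, float] = {}
    sens_summaries: list[BootstrapSummary] = []
    for gidx, group in enumerate(GROUP_ORDER):
        pids = label_of.index[label_of == group]
        net = timepoint_averaged_network(panel, item_map, patient_ids=pids,
                                         merger=merger)
        sens_networks[group] = net
        sens_densities[group] = network_density(
            net, absolute=config.absolute_metrics)
        say(f"sensitivity network {group}: density {sens_densities[group]:.3f}")
        if config.sensitivity_bootstrap:
            sens_summaries.append(_bootstrap_averaged_density(
                panel, merger, pids, group, config,
                seed=_group_seed(config.seed, 100 + gidx)))

    bundle = ResultBundle(
        config=config, classification=classification, peak_timepoints=peaks,
        screen_log=screen_log, item_map=item_map, merged_peak=merged_peak,
        networks=networks, node_metrics=node_metrics, densities=densities,
        bootstrap_summaries=summaries, overlap_verdicts=verdicts,
        sensitivity_networks=sens_networks,
        sensitivity_densities=sens_densities,
        sensitivity_summaries=sens_summaries,
        top_strength=top_strength, top_rwb=top_rwb,
        mean_qids_at_peak=mean_qids, mean_ymrs_at_peak=mean_ymrs,
        log_lines=log,
    )
    _write_bundle(bundle)
    return bundle


def _bootstrap_averaged_density(panel: SymptomPanel, merger: ItemMerger,
                                pids, group: str, config: RunConfig,
                                seed: int) -> BootstrapSummary:
    """Percentile CI for the timepoint-averaged density (patients resampled,
    all five per-timepoint matrices rebuilt per replicate)."""
    from scipy import stats as sstats

    records = panel.data
    records = records[records.index.get_level_values("patient_id").isin(pids)]
    merged = merger.transform(records)
    tps = sorted(set(records.index.get_level_values("timepoint")))
    mats = [merged.xs(t, level="timepoint").to_numpy(float) for t in tps]
    pid_list = sorted(set(records.index.get_level_values("patient_id")))
    n = len(pid_list)
    k = mats[0].shape[1]
    iu = np.triu_indices(k, 1)
    point = np.nanmean(np.stack([_safe_spearman(m) for m in mats]), axis=0)[iu].mean()
    rng = np.random.default_rng(seed)
    draws = np.empty(config.n_iter)
    done, attempts = 0, 0
    while done < config.n_iter:
        if attempts >= 2 * config.n_iter:
            raise RuntimeError("averaged-density bootstrap: too many "
                               "degenerate replicates")
        attempts += 1
        idx = rng.integers(0, n, n)
        per_tp = []
        ok = True
        for m in mats:
            Xi = m[idx]
            if (Xi == Xi[0]).all(axis=0).any():
                ok = False
                break
            ranks = sstats.rankdata(Xi, axis=0)
            C = np.corrcoef(ranks, rowvar=False)
            per_tp.append(C)
        if not ok:
            continue
        W = np.mean(per_tp, axis=0)
        draws[done] = W[iu].mean()
        done += 1
    alpha = (1 - config.ci_level) / 2
    lo, hi = np.percentile(draws, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapSummary("density_timepoint_averaged", group,
                            float(point), float(lo), float(hi),
                            config.n_iter, seed)


def _safe_spearman(X: np.ndarray) -> np.ndarray:
    from .inference import _lenient_spearman

    return _lenient_spearman(X)


# ---------------------------------------------------------------------------
# artifact writing
# ---------------------------------------------------------------------------


def _summaries_frame(summaries) -> pd.DataFrame:
    return pd.DataFrame([
        {"metric": s.metric, "group": s.group, "estimate": s.point_estimate,
         "lower": s.lower, "upper": s.upper, "n_iter": s.n_iterations,
         "seed": s.seed}
        for s in summaries
    ])


def _write_bundle(bundle: ResultBundle) -> None:
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = "%.17g"
    bundle.classification.to_csv(out / "classification.csv", index=False,
                                 float_format=ff)
    bundle.peak_timepoints.rename("peak_timepoint").to_csv(
        out / "peak_timepoints.csv", index_label="patient_id")
    bundle.screen_log.to_csv(out / "screen_log.csv", index=False,
                             float_format=ff)
    bundle.item_map.to_yaml(out / "item_map_resolved.yaml")
    bundle.merged_peak.to_csv(out / "merged_peak.csv",
                              index_label="patient_id", float_format=ff)
    for group in bundle.networks:
        for fmt, suffix in (("matrix", "matrix.csv"),
                            ("edgelist", "edges.csv"),
                            ("graphml", "net.graphml")):
            export_network(bundle.networks[group], fmt,
                           out / f"network_{group}_{suffix}")
        pruned = prune_edges(bundle.networks[group],
                             bundle.config.prune_threshold)
        export_network(pruned, "edgelist", out / f"network_{group}_pruned.csv")
        bundle.node_metrics[group].to_csv(out / f"node_metrics_{group}.csv",
                                          index_label="item", float_format=ff)
        export_network(bundle.sensitivity_networks[group], "matrix",
                       out / f"sensitivity_{group}_matrix.csv")
    _summaries_frame(bundle.bootstrap_summaries).to_csv(
        out / "bootstrap_summaries.csv", index=False, float_format=ff)
    if bundle.sensitivity_summaries:
        _summaries_frame(bundle.sensitivity_summaries).to_csv(
            out / "sensitivity_bootstrap.csv", index=False, float_format=ff)
    pd.DataFrame([
        {"group_a": v.groups[0], "group_b": v.groups[1], "metric": v.metric,
         "overlap_fraction": v.overlap_fraction, "distinct": v.distinct}
        for v in bundle.overlap_verdicts
    ]).to_csv(out / "overlap_verdicts.csv", index=False, float_format=ff)
    for name, table in (("top_strength", bundle.top_strength),
                        ("top_rw_betweenness", bundle.top_rwb)):
        pd.DataFrame([
            {"group": g, "rank": i + 1, "item": item, "tie_at_cut": tied}
            for g, (items, tied) in table.items()
            for i, item in enumerate(items)
        ]).to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "config": bundle.config.to_dict(),
        "config_hash": bundle.config.config_hash(),
        "n_patients": int(len(bundle.classification)),
        "group_sizes": {g: int((bundle.classification["label"] == g).sum())
                        for g in GROUP_ORDER},
        "densities": bundle.densities,
        "sensitivity_densities": bundle.sensitivity_densities,
        "mean_qids_at_peak": bundle.mean_qids_at_peak,
        "mean_ymrs_at_peak": bundle.mean_ymrs_at_peak,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(bundle.log_lines) + "\n")
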