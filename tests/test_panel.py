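"""Scale totals, peak-timepoint selection, item merging and screening."""

import numpy as np
import pandas as pd
import pytest

from bipolarnet.network import spearman_matrix
from bipolarnet.panel import (
    ALL_ITEMS,
    ITEM_RANGES,
    MERGED_ITEM_ORDER,
    ItemMap,
    ItemMerger,
    MergedItem,
    PanelError,
    PeakTimepointSelector,
    SymptomPanel,
    default_item_map,
    scale_totals,
    screen_low_variance,
    select_peak_timepoint,
)
from conftest import panel_from_rows


class TestScaleTotals:
    def test_all_zero(self):
        panel = panel_from_rows([{"patient_id": "a", "timepoint": 0}])
        totals = scale_totals(panel)
        assert totals.loc[("a", 0), "qids_total"] == 0
        assert totals.loc[("a", 0), "ymrs_total"] == 0

    def test_ceiling(self):
        row = {"patient_id": "a", "timepoint": 0}
        row.update({c: ITEM_RANGES[c][1] for c in ALL_ITEMS})
        totals = scale_totals(panel_from_rows([row]))
        # domain-maximum scoring caps QIDS at 27; YMRS plain sum at 60
        assert totals.loc[("a", 0), "qids_total"] == 27
        assert totals.loc[("a", 0), "ymrs_total"] == 60

    def test_sleep_domain_uses_maximum(self):
        row = {"patient_id": "a", "timepoint": 0,
               "q01": 2, "q02": 1, "q03": 3, "q04": 0}
        totals = scale_totals(panel_from_rows([row]))
        assert totals.loc[("a", 0), "qids_total"] == 3

    def test_missing_item_flags_total_missing(self):
        row = {"patient_id": "a", "timepoint": 0, "q05": np.nan, "y01": np.nan}
        totals = scale_totals(panel_from_rows([row]))
        assert np.isnan(totals.loc[("a", 0), "qids_total"])
        assert np.isnan(totals.loc[("a", 0), "ymrs_total"])


class TestPanelValidation:
    def test_out_of_range_item_rejected(self):
        with pytest.raises(PanelError, match="q03"):
            panel_from_rows([{"patient_id": "a", "timepoint": 0, "q03": 9}])

    def test_duplicate_record_rejected(self):
        rows = [{"patient_id": "a", "timepoint": 1},
                {"patient_id": "a", "timepoint": 1}]
        with pytest.raises(PanelError, match="duplicate"):
            panel_from_rows(rows)

    def test_bad_timepoint_rejected(self):
        with pytest.raises(PanelError, match="timepoint"):
            panel_from_rows([{"patient_id": "a", "timepoint": 7}])


class TestPeakTimepoint:
    def test_unique_maximum(self):
        rows = []
        for pid in ("a", "b"):
            for tp in range(5):
                sev = 3 if (pid == "a" and tp == 3) else 0
                rows.append({"patient_id": pid, "timepoint": tp,
                             "q05": sev, "y01": sev,
                             "q10": tp % 2})  # cohort-level variation
        assert select_peak_timepoint(panel_from_rows(rows), "a") == 3

    def test_tie_breaks_to_earliest(self):
        rows = [{"patient_id": "a", "timepoint": tp, "q05": 1}
                for tp in range(5)]
        rows += [{"patient_id": "b", "timepoint": tp, "q05": tp % 2, "y01": 1}
                 for tp in range(5)]
        assert select_peak_timepoint(panel_from_rows(rows), "a") == 0

    def test_pooled_z_scores_match_hand_computation(self):
        # 3 patients x 2 timepoints, z-scores recomputed independently
        rows = [
            {"patient_id": "a", "timepoint": 0, "q05": 3, "y01": 0},
            {"patient_id": "a", "timepoint": 1, "q05": 1, "y01": 2},
            {"patient_id": "b", "timepoint": 0, "q05": 2, "y01": 1},
            {"patient_id": "b", "timepoint": 1, "q05": 0, "y01": 4},
            {"patient_id": "c", "timepoint": 0, "q05": 1, "y01": 3},
            {"patient_id": "c", "timepoint": 1, "q05": 3, "y01": 3},
        ]
        panel = panel_from_rows(rows)
        totals = scale_totals(panel)
        q = totals["qids_total"].to_numpy()
        y = totals["ymrs_total"].to_numpy()
        zsum = (q - q.mean()) / q.std() + (y - y.mean()) / y.std()
        expected = {}
        for i, (pid, tp) in enumerate(totals.index):
            if zsum[i] > expected.get(pid, (None, -np.inf))[1]:
                expected[pid] = (tp, zsum[i])
        sel = PeakTimepointSelector().fit(panel)
        got = sel.predict()
        for pid in ("a", "b", "c"):
            assert got[pid] == expected[pid][0]

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        rows = [{"patient_id": f"p{i}", "timepoint": tp,
                 "q05": int(rng.integers(0, 4)), "y05": int(rng.integers(0, 4)),
                 "q10": int(rng.integers(0, 4))}
                for i in range(6) for tp in range(5)]
        panel = panel_from_rows(rows)
        base = PeakTimepointSelector().fit(panel).predict()
        # y05 is the only nonzero YMRS item, so doubling it (within its 0-8
        # range) rescales ymrs_total affinely
        doubled = panel.data.copy()
        doubled["y05"] = doubled["y05"] * 2
        rescaled = SymptomPanel(doubled)
        assert PeakTimepointSelector().fit(rescaled).predict().equals(base)

    def test_unscoreable_patient_raises(self):
        rows = [{"patient_id": "a", "timepoint": 0, "q05": np.nan},
                {"patient_id": "b", "timepoint": 0, "q05": 1},
                {"patient_id": "b", "timepoint": 1, "q05": 2, "y01": 1}]
        sel = PeakTimepointSelector().fit(panel_from_rows(rows))
        with pytest.raises(PanelError, match="'a'"):
            sel.predict(["a"])


class TestItemMap:
    def test_default_map_partitions_all_items(self):
        imap = default_item_map()
        assigned = [s for m in imap.merged for s in m.sources]
        assert sorted(assigned + list(imap.excluded)) == sorted(ALL_ITEMS)
        assert imap.merged_names == MERGED_ITEM_ORDER
        assert len(imap.merged) == 14

    def test_duplicate_source_rejected(self):
        with pytest.raises(PanelError, match="appears in both"):
            ItemMap(
                merged=(MergedItem("a", ("q05",), "q05"),
                        MergedItem("b", ("q05",), "q05")),
                excluded=tuple(c for c in ALL_ITEMS if c != "q05"),
            )

    def test_unassigned_source_rejected(self):
        with pytest.raises(PanelError, match="not assigned"):
            ItemMap(merged=(MergedItem("a", ("q05",), "q05"),), excluded=())

    def test_reference_must_be_a_source(self):
        with pytest.raises(PanelError, match="reference"):
            MergedItem("a", ("q05",), "q06")

    def test_yaml_round_trip(self, tmp_path):
        imap = default_item_map()
        path = tmp_path / "map.yaml"
        imap.to_yaml(path)
        assert ItemMap.from_yaml(path) == imap

    def test_drop_sources_moves_to_excluded(self):
        imap = default_item_map().drop_sources(["q05"])
        assert "q05" in imap.excluded
        assert "depressed mood" not in imap.merged_names


class TestItemMerger:
    def test_single_source_passes_through(self):
        rows = [{"patient_id": f"p{i}", "timepoint": 0, "q05": i % 4}
                for i in range(8)]
        panel = panel_from_rows(rows)
        merged = ItemMerger().fit_transform(panel.data)
        assert merged["depressed mood"].tolist() == [i % 4 for i in range(8)]

    def test_two_source_max_z_back_transformed(self):
        # restlessness <- q16 (reference) + y02; hand-computed moments
        rows = [
            {"patient_id": "a", "timepoint": 0, "q16": 0, "y02": 2},
            {"patient_id": "b", "timepoint": 0, "q16": 1, "y02": 0},
            {"patient_id": "c", "timepoint": 0, "q16": 2, "y02": 1},
            {"patient_id": "d", "timepoint": 0, "q16": 3, "y02": 1},
        ]
        panel = panel_from_rows(rows)
        merged = ItemMerger().fit_transform(panel.data)
        q16 = np.array([0, 1, 2, 3], float)
        y02 = np.array([2, 0, 1, 1], float)
        zq = (q16 - q16.mean()) / q16.std()
        zy = (y02 - y02.mean()) / y02.std()
        expected = np.maximum(zq, zy) * q16.std() + q16.mean()
        np.testing.assert_allclose(merged["restlessness"].to_numpy(), expected)

    def test_excluded_sources_never_appear(self):
        rows = [{"patient_id": f"p{i}", "timepoint": 0, "y11": 3}
                for i in range(4)]
        merged = ItemMerger().fit_transform(panel_from_rows(rows).data)
        assert set(merged.columns) == set(MERGED_ITEM_ORDER)

    def test_all_sources_missing_gives_missing(self):
        rows = [{"patient_id": f"p{i}", "timepoint": 0,
                 "q16": np.nan if i == 0 else i % 4,
                 "y02": np.nan if i == 0 else (i + 1) % 4}
                for i in range(6)]
        merged = ItemMerger().fit_transform(panel_from_rows(rows).data)
        assert np.isnan(merged.loc[("p0", 0), "restlessness"])

    def test_back_transform_preserves_spearman_edges(self):
        # strictly monotone back-transformation leaves rank edges unchanged
        rng = np.random.default_rng(1)
        rows = [{"patient_id": f"p{i}", "timepoint": 0,
                 **{c: int(rng.integers(0, 4)) for c in ("q16", "y02", "q05",
                                                         "q12", "q04", "y04")}}
                for i in range(30)]
        panel = panel_from_rows(rows)
        merger = ItemMerger().fit(panel.data)
        merged = merger.transform(panel.data)
        cols = ["restlessness", "depressed mood", "sleep duration",
                "suicidality"]
        with_bt = spearman_matrix(merged[cols].to_numpy(float))
        # raw max-z (no back-transformation): same ranks by construction
        raw = merged.copy()
        for m in merger.item_map.merged:
            if len(m.sources) > 1:
                zs = [(panel.data[s] - merger.mean_[s]) / merger.std_[s]
                      for s in m.sources]
                raw[m.name] = pd.concat(zs, axis=1).max(axis=1)
        without_bt = spearman_matrix(raw[cols].to_numpy(float))
        np.testing.assert_array_equal(with_bt, without_bt)


class TestScreening:
    @pytest.mark.parametrize("zeros, keep", [(95, False), (90, True)])
    def test_threshold(self, zeros, keep):
        values = [0] * zeros + [1] * (100 - zeros)
        decision, frac = screen_low_variance(values)
        assert decision is keep
        assert frac == pytest.approx(zeros / 100)

    def test_all_missing_raises(self):
        with pytest.raises(PanelError):
            screen_low_variance([np.nan, np.nan])
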