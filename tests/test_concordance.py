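"""FISH-panel event calling, aggregation, co-occurrence, discordance."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from rarepc import cnv
from rarepc.concordance import (
    CytogeneticLocus,
    aggregate_events,
    call_event,
    call_events,
    cooccurrence_sets,
    default_locus_panel,
    discordance_report,
)
from rarepc.genome import HG19_CHROM_LENGTHS
from rarepc.io import FishPanelResult


def _profile(cid, cn, baseline=2):
    return cnv.CopyNumberProfile(
        cell_id=cid, ratios=cn / cn.mean(), segments=pd.DataFrame(),
        cn=np.asarray(cn), ploidy_scale=2.0, baseline_ploidy=baseline,
    )


def _cn(bins, **chrom_cn):
    cn = np.full(len(bins), 2)
    for chrom, value in chrom_cn.items():
        cn[(bins["chrom"] == chrom).to_numpy()] = value
    return cn


class TestDefaultPanel:
    def test_twelve_events(self):
        panel = default_locus_panel()
        assert len(panel) == 12
        assert len({locus.event_name for locus in panel}) == 12

    def test_translocation_entries(self):
        panel = {locus.event_name: locus for locus in default_locus_panel()}
        for name in ("t(4;14)", "t(11;14)", "t(14;16)"):
            assert panel[name].direction == "translocation"

    def test_every_cn_event_overlaps_the_default_grid(self, bins5000):
        starts = bins5000["start"].to_numpy()
        ends = bins5000["end"].to_numpy()
        chroms = bins5000["chrom"].to_numpy()
        for locus in default_locus_panel():
            if locus.direction == "translocation":
                continue
            overlap = (chroms == locus.chrom) & (np.minimum(ends, locus.end) > np.maximum(starts, locus.start))
            assert overlap.any(), locus.event_name


class TestCallEvent:
    def test_flat_diploid_all_events_absent(self, bins5000):
        profile = _profile("c", _cn(bins5000))
        calls = call_events([profile], default_locus_panel(), bins5000)
        cn_calls = calls[~calls["event_name"].str.startswith("t(")]
        assert (cn_calls["status"] == "absent").all()

    def test_chr11_trisomy_gives_ccnd1_gain_with_cn3(self, bins5000):
        profile = _profile("c", _cn(bins5000, chr11=3))
        panel = {l.event_name: l for l in default_locus_panel()}
        call = call_event(profile, panel["CCND1_11q13_gain"], bins5000)
        assert call.status == "present"
        assert call.observed_cn == 3.0

    def test_13q_hemizygous_loss_present(self, bins5000):
        profile = _profile("c", _cn(bins5000, chr13=1))
        panel = {l.event_name: l for l in default_locus_panel()}
        call = call_event(profile, panel["RB1_13q14_loss"], bins5000)
        assert call.status == "present"
        assert call.observed_cn == 1.0

    def test_translocation_not_evaluable(self, bins5000):
        profile = _profile("c", _cn(bins5000, chr14=3))
        panel = {l.event_name: l for l in default_locus_panel()}
        call = call_event(profile, panel["t(11;14)"], bins5000)
        assert call.status == "not_evaluable"
        assert call.observed_cn is None

    def test_zero_overlap_errors_naming_locus(self):
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [249250621], "gc": [0.4]})
        profile = _profile("c", np.array([2]))
        locus = CytogeneticLocus("RB1_13q14_loss", "chr13", 45_200_000, 55_300_000, "loss")
        with pytest.raises(ValueError, match="RB1_13q14_loss"):
            call_event(profile, locus, bins)

    def test_relative_to_ploidy_mode(self, bins5000):
        # flat triploid: every gain locus shows CN 3 vs absolute reference 2,
        # but no deviation from the cell's own ploidy
        profile = _profile("c", _cn(bins5000) + 1, baseline=3)
        panel = {l.event_name: l for l in default_locus_panel()}
        absolute = call_event(profile, panel["CCND1_11q13_gain"], bins5000)
        relative = call_event(profile, panel["CCND1_11q13_gain"], bins5000, relative_to_ploidy=True)
        assert absolute.status == "present"
        assert relative.status == "absent"

    def test_recalling_is_idempotent(self, bins5000):
        profile = _profile("c", _cn(bins5000, chr13=1, chr11=3))
        panel = default_locus_panel()
        a = call_events([profile], panel, bins5000)
        b = call_events([profile], panel, bins5000)
        pd.testing.assert_frame_equal(a, b)


def _calls_from_counts(event_patients):
    """Build an event-call table + meta with n present cells per (event, patient)."""
    rows, meta = [], []
    i = 0
    for event, patients in event_patients.items():
        for patient, n in patients.items():
            for _ in range(n):
                cid = f"cell{i}"
                i += 1
                rows.append({"cell_id": cid, "event_name": event, "status": "present",
                             "observed_cn": 3.0})
                meta.append({"cell_id": cid, "patient_id": patient, "compartment": "PB"})
    return pd.DataFrame(rows), pd.DataFrame(meta)


class TestAggregation:
    def test_cohort_totals_sum_per_patient_counts(self):
        calls, meta = _calls_from_counts({"RB1_13q14_loss": {"MM01": 22, "MM02": 53}})
        agg = aggregate_events(calls, meta)
        assert agg["cohort"].loc["RB1_13q14_loss", "n_present"] == 75
        assert agg["by_patient"].loc["RB1_13q14_loss"].sum() == 75

    def test_five_patient_counts(self):
        calls, meta = _calls_from_counts(
            {"CCND1_11q13_gain": {"MGUS": 12, "MM02": 30, "MM01": 1, "MM03": 5, "MM04": 19}}
        )
        agg = aggregate_events(calls, meta)
        assert agg["cohort"].loc["CCND1_11q13_gain", "n_present"] == 67

    def test_no_present_calls_gives_zero_table(self):
        calls = pd.DataFrame(
            [{"cell_id": "c", "event_name": "RB1_13q14_loss", "status": "absent",
              "observed_cn": 2.0}]
        )
        meta = pd.DataFrame([{"cell_id": "c", "patient_id": "P", "compartment": "PB"}])
        agg = aggregate_events(calls, meta)
        assert agg["cohort"]["n_present"].sum() == 0

    def test_compartment_counts_conserve_totals(self):
        calls, meta = _calls_from_counts({"TP53_17p13_loss": {"MM01": 12, "MM02": 5}})
        meta.loc[meta.index[:6], "compartment"] = "BMA"
        agg = aggregate_events(calls, meta)
        assert agg["by_compartment"].loc["TP53_17p13_loss"].sum() == 17
        assert agg["cohort"].loc["TP53_17p13_loss", "n_present"] == 17


class TestCooccurrence:
    def test_small_example(self):
        rows = []
        for cid, events in (("a", ["13q"]), ("b", ["13q"]), ("c", ["13q", "11q"])):
            for e in events:
                rows.append({"cell_id": cid, "event_name": e, "status": "present",
                             "observed_cn": 3.0})
        table = cooccurrence_sets(pd.DataFrame(rows))
        sizes = dict(zip(table["combination"], table["n_cells"]))
        assert sizes == {"13q": 2, "11q + 13q": 1}

    def test_no_events_empty_table(self):
        calls = pd.DataFrame(columns=["cell_id", "event_name", "status", "observed_cn"])
        assert cooccurrence_sets(calls).empty

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        events = ["e1", "e2", "e3", "e4"]
        rows = []
        truth = {}
        for i in range(30):
            present = [e for e in events if rng.random() < 0.4]
            truth[f"c{i}"] = frozenset(present)
            for e in events:
                rows.append({
                    "cell_id": f"c{i}", "event_name": e,
                    "status": "present" if e in present else "absent",
                    "observed_cn": 3.0,
                })
        table = cooccurrence_sets(pd.DataFrame(rows))
        # brute force: count cells per exact subset
        for r in range(1, len(events) + 1):
            for combo in combinations(events, r):
                expected = sum(1 for s in truth.values() if s == frozenset(combo))
                got = table.loc[table["combination"] == " + ".join(sorted(combo)), "n_cells"]
                assert (got.iloc[0] if len(got) else 0) == expected
        n_positive_cells = sum(1 for s in truth.values() if s)
        assert table["n_cells"].sum() == n_positive_cells


class TestDiscordance:
    panel_events = [l.event_name for l in default_locus_panel()]

    def _fish(self, positives):
        calls = {e: ("positive" if e in positives else "negative") for e in self.panel_events}
        return FishPanelResult("MM01", calls)

    def _calls(self, cell_events):
        rows = []
        for cid, present in cell_events.items():
            for e in self.panel_events:
                status = "not_evaluable" if e.startswith("t(") else (
                    "present" if e in present else "absent"
                )
                rows.append({"cell_id": cid, "event_name": e, "status": status,
                             "observed_cn": None})
        return pd.DataFrame(rows)

    def test_cell_only_event_reported(self):
        fish = self._fish({"CCND1_11q13_gain", "RB1_13q14_loss"})
        calls = self._calls({
            "a": {"CCND1_11q13_gain", "RB1_13q14_loss", "TP53_17p13_loss"},
        })
        report = discordance_report(calls, fish)
        cell_only = report[report["category"] == "cell_only"]["event_name"].tolist()
        clinical_only = report[report["category"] == "clinical_only"]["event_name"].tolist()
        assert cell_only == ["TP53_17p13_loss"]
        assert clinical_only == []

    def test_clinically_positive_event_with_no_cells(self):
        fish = self._fish({"IGH_14q32_gain"})
        calls = self._calls({"a": set()})
        report = discordance_report(calls, fish)
        clinical_only = report[report["category"] == "clinical_only"]["event_name"].tolist()
        assert clinical_only == ["IGH_14q32_gain"]

    def test_concordant_inputs_give_empty_report(self):
        fish = self._fish({"RB1_13q14_loss"})
        calls = self._calls({"a": {"RB1_13q14_loss"}})
        assert discordance_report(calls, fish).empty

    def test_translocations_never_listed(self):
        fish = FishPanelResult(
            "MM01",
            {**{e: "negative" for e in self.panel_events}, "t(11;14)": "positive"},
        )
        calls = self._calls({"a": set()})
        report = discordance_report(calls, fish)
        assert "t(11;14)" not in set(report["event_name"])

    def test_unknown_event_errors(self):
        fish = FishPanelResult("MM01", {"RB1_13q14_loss": "negative"})
        calls = self._calls({"a": set()})
        with pytest.raises(ValueError, match="missing"):
            discordance_report(calls, fish)
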