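"""Mapping single-cell copy-number profiles onto a clinical FISH panel.

Clinical myeloma cytogenetics reports 12 common events: copy-number changes
at probe loci (CCND1/11q13, RB1/13q14, 13q34, TP53/17p13, CKS1B/1q21,
CDKN2C/1p32, FGFR3/4p16, IGH/14q32, CEP17) and the three canonical IGH
translocations t(4;14), t(11;14), t(14;16). For every sequenced cell, each
copy-number event is judged present or absent from the integer profile:
the observed copy number at a locus is the bin-length-weighted median over
overlapping bins, and — matching interphase-FISH copy counting — a gain is
present iff that number exceeds 2 absolute copies and a loss iff it falls
below 2, regardless of the cell's baseline ploidy (a relative-to-ploidy
mode exists but is off by default). Translocations cannot be detected from
low-pass copy number and are always "not_evaluable".

Aggregations count event-positive cells per patient / compartment / cohort,
enumerate co-occurring event combinations (UpSet-style intersections), and
report discordances against the clinical panel in both directions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rarepc._util import weighted_median
from rarepc.genome import HG19_CHROM_LENGTHS, validate_interval
from rarepc.io import FishPanelResult

STATUS_PRESENT = "present"
STATUS_ABSENT = "absent"
STATUS_NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class CytogeneticLocus:
    """A FISH-probe-analog interval with a tested direction.

    Coordinates are hg19-approximate arm/band-scale intervals (0-based
    half-open); clinical probes are named, not published as coordinates, so
    the panel file is the override mechanism. Translocation entries keep a
    nominal interval (the IGH partner locus) but it is never used.
    """

    event_name: str
    chrom: str
    start: int
    end: int
    direction: str  # gain | loss | translocation

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss", "translocation"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.chrom in HG19_CHROM_LENGTHS:
            validate_interval(self.chrom, self.start, self.end)
        elif self.direction != "translocation":
            raise ValueError(f"unknown chromosome {self.chrom!r} for CN event")


def default_locus_panel() -> list[CytogeneticLocus]:
    """The 12-event clinical panel with hg19-approximate intervals."""
    return [
        CytogeneticLocus("CKS1B_1q21_gain", "chr1", 143_000_000, 155_100_000, "gain"),
        CytogeneticLocus("CDKN2C_1p32_loss", "chr1", 46_000_000, 56_100_000, "loss"),
        CytogeneticLocus("FGFR3_4p16_gain", "chr4", 0, 11_300_000, "gain"),
        CytogeneticLocus("CCND1_11q13_gain", "chr11", 63_400_000, 77_100_000, "gain"),
        CytogeneticLocus("RB1_13q14_loss", "chr13", 45_200_000, 55_300_000, "loss"),
        CytogeneticLocus("13q34_loss", "chr13", 110_300_000, 115_169_878, "loss"),
        CytogeneticLocus("IGH_14q32_gain", "chr14", 95_800_000, 107_349_540, "gain"),
        CytogeneticLocus("TP53_17p13_loss", "chr17", 0, 10_800_000, "loss"),
        CytogeneticLocus("CEP17_gain", "chr17", 22_200_000, 25_800_000, "gain"),
        CytogeneticLocus("t(4;14)", "chr14", 95_800_000, 107_349_540, "translocation"),
        CytogeneticLocus("t(11;14)", "chr14", 95_800_000, 107_349_540, "translocation"),
        CytogeneticLocus("t(14;16)", "chr14", 95_800_000, 107_349_540, "translocation"),
    ]


@dataclass(frozen=True)
class EventCall:
    """Per-cell presence call for one panel event."""

    cell_id: str
    event_name: str
    status: str
    observed_cn: float | None = None

    def __post_init__(self) -> None:
        if self.status not in (STATUS_PRESENT, STATUS_ABSENT, STATUS_NOT_EVALUABLE):
            raise ValueError(f"invalid status {self.status!r}")


def call_event(
    profile,
    locus: CytogeneticLocus,
    bins: pd.DataFrame,
    relative_to_ploidy: bool = False,
) -> EventCall:
    """Judge one event on one cell's integer CN profile.

    Observed CN at the locus = bin-length-weighted median integer CN over
    the overlapping bins (median, not mean, to resist boundary bins). The
    reference is 2 absolute copies, or the cell's baseline ploidy when
    `relative_to_ploidy` is set.
    """
    if locus.direction == "translocation":
        return EventCall(profile.cell_id, locus.event_name, STATUS_NOT_EVALUABLE, None)
    chrom = bins["chrom"].to_numpy()
    start = bins["start"].to_numpy()
    end = bins["end"].to_numpy()
    overlap = np.minimum(end, locus.end) - np.maximum(start, locus.start)
    mask = (chrom == locus.chrom) & (overlap > 0)
    if not mask.any():
        raise ValueError(
            f"locus {locus.event_name} ({locus.chrom}:{locus.start}-{locus.end}) "
            "overlaps zero bins of the bin table"
        )
    cn = np.asarray(profile.cn)[mask]
    observed = weighted_median(cn, overlap[mask])
    reference = profile.baseline_ploidy if relative_to_ploidy else 2
    present = observed > reference if locus.direction == "gain" else observed < reference
    return EventCall(
        profile.cell_id,
        locus.event_name,
        STATUS_PRESENT if present else STATUS_ABSENT,
        float(observed),
    )


def call_events(
    profiles,
    panel,
    bins: pd.DataFrame,
    relative_to_ploidy: bool = False,
) -> pd.DataFrame:
    """Call every panel event for every cell; long table of EventCalls.

    Calls are a pure function of the integer profiles, so re-calling the
    same profiles reproduces the table exactly.
    """
    rows = []
    for profile in profiles:
        for locus in panel:
            call = call_event(profile, locus, bins, relative_to_ploidy=relative_to_ploidy)
            rows.append(
                {
                    "cell_id": call.cell_id,
                    "event_name": call.event_name,
                    "status": call.status,
                    "observed_cn": call.observed_cn,
                }
            )
    return pd.DataFrame(rows)


def aggregate_events(calls: pd.DataFrame, meta: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Count event-positive cells per patient, per compartment, and cohort-wide.

    `meta` maps cell_id to patient_id and compartment. Cohort totals equal
    the sum of per-patient counts by construction.
    """
    joined = calls.merge(meta[["cell_id", "patient_id", "compartment"]], on="cell_id", how="left")
    present = joined[joined["status"] == STATUS_PRESENT]
    events = sorted(calls["event_name"].unique())

    def _pivot(col):
        if present.empty:
            return pd.DataFrame(0, index=events, columns=[]).rename_axis(index="event_name")
        return (
            present.groupby(["event_name", col])
            .size()
            .unstack(fill_value=0)
            .reindex(events, fill_value=0)
            .rename_axis(index="event_name", columns=None)
        )

    by_patient = _pivot("patient_id")
    by_compartment = _pivot("compartment")
    cohort = pd.DataFrame(
        {"n_present": by_patient.sum(axis=1).reindex(events, fill_value=0)}
    ).rename_axis(index="event_name")
    return {"by_patient": by_patient, "by_compartment": by_compartment, "cohort": cohort}


def cooccurrence_sets(calls: pd.DataFrame) -> pd.DataFrame:
    """UpSet-style intersection sizes over per-cell present-event sets.

    For every observed combination of present events, the number of cells
    carrying exactly that combination; the sizes sum to the number of cells
    with at least one present event.
    """
    present = calls[calls["status"] == STATUS_PRESENT]
    combos = Counter(
        tuple(sorted(group)) for _, group in present.groupby("cell_id")["event_name"]
    )
    rows = [
        {"combination": " + ".join(combo), "n_events": len(combo), "n_cells": n}
        for combo, n in sorted(combos.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["combination", "n_events", "n_cells"])


def discordance_report(
    calls: pd.DataFrame,
    fish: FishPanelResult | dict[str, FishPanelResult],
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Two discordance lists per patient.

    * ``cell_only`` — events present in >= 1 cell but clinically negative.
    * ``clinical_only`` — events clinically positive with 0 present cells.

    Events that are not evaluable from single-cell copy number
    (translocations) are excluded from both lists, as are clinically
    untested events. Output is deterministic and sorted. Event names in the
    clinical panel must cover the single-cell vocabulary.
    """
    if isinstance(fish, FishPanelResult):
        fish = {fish.patient_id: fish}
    cell_events = set(calls["event_name"].unique())
    rows = []
    for patient_id in sorted(fish):
        panel = fish[patient_id]
        unknown = sorted(cell_events - set(panel.calls))
        if unknown:
            raise ValueError(
                f"patient {patient_id}: events missing from clinical panel: {unknown}"
            )
        if meta is not None:
            cells = set(meta.loc[meta["patient_id"] == patient_id, "cell_id"].astype(str))
            patient_calls = calls[calls["cell_id"].astype(str).isin(cells)]
        else:
            patient_calls = calls
        evaluable = set(
            patient_calls.loc[patient_calls["status"] != STATUS_NOT_EVALUABLE, "event_name"]
        )
        present = set(
            patient_calls.loc[patient_calls["status"] == STATUS_PRESENT, "event_name"]
        )
        clinical_pos = panel.positive_events()
        cell_only = sorted(
            e for e in present if panel.calls.get(e) == "negative" and e in evaluable
        )
        clinical_only = sorted(e for e in clinical_pos & evaluable if e not in present)
        rows.extend(
            {"patient_id": patient_id, "category": "cell_only", "event_name": e}
            for e in cell_only
        )
        rows.extend(
            {"patient_id": patient_id, "category": "clinical_only", "event_name": e}
            for e in clinical_only
        )
    return pd.DataFrame(rows, columns=["patient_id", "category", "event_name"])
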