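"""Readers, writers and configuration for the pipeline's tabular artifacts.

All formats are plain UTF-8 TSV with ``#``-prefixed comment lines at the top
and ``NA`` for missing values, so outputs are bit-exact diffable and every
writer/reader pair round-trips. Genomic coordinates are 0-based half-open
(BED convention) everywhere. Files are parsed with explicit schemas: a
missing required column raises :class:`SchemaError`; a value violating its
domain (negative count, unknown compartment code, ...) raises
:class:`ValidationError` naming the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

COMPARTMENTS = ("PB", "BMA", "NBD")
DIAGNOSES = ("NDMM", "MGUS", "NBD")
FISH_STATUSES = ("positive", "negative", "not_tested")

NA = "NA"


class SchemaError(ValueError):
    """A file's header does not match the expected schema."""


class ValidationError(ValueError):
    """A file row violates a domain constraint."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample (slide), mirroring a clinical characteristics table."""

    sample_id: str
    patient_id: str
    compartment: str  # PB | BMA | NBD
    diagnosis: str  # NDMM | MGUS | NBD
    ml_equivalent: float  # blood-volume equivalent of the slide, mL
    percent_bmpc: float | None = None
    flow_cd138: str | None = None
    flow_cd56: str | None = None
    flow_cd45: str | None = None
    m_spike_g_dl: float | None = None
    sflc_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}"
            )
        if self.diagnosis not in DIAGNOSES:
            raise ValidationError(
                f"unknown diagnosis {self.diagnosis!r}; expected one of {DIAGNOSES}"
            )
        if not self.ml_equivalent > 0:
            raise ValidationError("ml_equivalent must be > 0")


@dataclass(frozen=True)
class FishPanelResult:
    """Clinical FISH panel outcome for one patient: event name -> status."""

    patient_id: str
    calls: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for event, status in self.calls.items():
            if status not in FISH_STATUSES:
                raise ValidationError(
                    f"FISH status for {event!r} must be one of {FISH_STATUSES}, got {status!r}"
                )

    def positive_events(self) -> set[str]:
        return {e for e, s in self.calls.items() if s == "positive"}


# ---------------------------------------------------------------------------
# low-level TSV helpers


def _read_raw(path) -> tuple[pd.DataFrame, int]:
    """Read a commented TSV as strings; return (frame, 1-based header line number)."""
    path = Path(path)
    header_line = 1
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                header_line += 1
            else:
                break
        else:
            raise SchemaError(f"{path}: no header line found")
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False, skip_blank_lines=True
    )
    return df, header_line


def _require(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _to_float(df, col, path, header_line, minimum=None, maximum=None, allow_na=False):
    raw = df[col]
    out = np.full(len(raw), np.nan)
    for i, v in enumerate(raw):
        if v == NA:
            if allow_na:
                continue
            raise ValidationError(f"{path} line {header_line + 1 + i}: {col} is NA")
        try:
            out[i] = float(v)
        except ValueError:
            raise ValidationError(
                f"{path} line {header_line + 1 + i}: {col}={v!r} is not a number"
            ) from None
        if minimum is not None and out[i] < minimum:
            raise ValidationError(
                f"{path} line {header_line + 1 + i}: {col}={v} below minimum {minimum}"
            )
        if maximum is not None and out[i] > maximum:
            raise ValidationError(
                f"{path} line {header_line + 1 + i}: {col}={v} above maximum {maximum}"
            )
    return out


def _to_int(df, col, path, header_line, minimum=None):
    vals = _to_float(df, col, path, header_line, minimum=minimum)
    if not np.allclose(vals, np.round(vals)):
        bad = int(np.flatnonzero(vals != np.round(vals))[0])
        raise ValidationError(f"{path} line {header_line + 1 + bad}: {col} is not an integer")
    return vals.astype(np.int64)


def _to_bool(df, col, path, header_line):
    mapping = {"True": True, "False": False, "true": True, "false": False}
    out = np.empty(len(df), dtype=bool)
    for i, v in enumerate(df[col]):
        if v not in mapping:
            raise ValidationError(f"{path} line {header_line + 1 + i}: {col}={v!r} is not boolean")
        out[i] = mapping[v]
    return out


def _write_tsv(df: pd.DataFrame, path, comment: str, index=False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=NA)


# ---------------------------------------------------------------------------
# cell feature tables

FEATURE_REQUIRED = (
    "cell_id",
    "sample_id",
    "frame_id",
    "dapi",
    "cd138",
    "cd56",
    "cd45",
    "area",
    "eccentricity",
    "nucleus_count",
    "apoptosis_score",
)


def write_cell_features(path, features: pd.DataFrame) -> None:
    _write_tsv(features, path, "rarepc cell feature table v1")


def read_cell_features(path) -> pd.DataFrame:
    """Read a per-cell immunofluorescence feature table, validating domains."""
    df, hline = _read_raw(path)
    _require(df, FEATURE_REQUIRED, path)
    out = pd.DataFrame({"cell_id": df["cell_id"], "sample_id": df["sample_id"]})
    if "compartment" in df.columns:
        bad = ~df["compartment"].isin(COMPARTMENTS)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path} line {hline + 1 + i}: unknown compartment {df['compartment'].iloc[i]!r}"
            )
        out["compartment"] = df["compartment"]
    out["frame_id"] = _to_int(df, "frame_id", path, hline, minimum=0)
    for ch in ("dapi", "cd138", "cd56", "cd45"):
        out[ch] = _to_float(df, ch, path, hline, minimum=0.0)
    out["area"] = _to_float(df, "area", path, hline, minimum=0.0)
    out["eccentricity"] = _to_float(df, "eccentricity", path, hline, minimum=0.0, maximum=1.0)
    out["nucleus_count"] = _to_int(df, "nucleus_count", path, hline, minimum=1)
    out["cluster_id"] = df["cluster_id"] if "cluster_id" in df.columns else NA
    out["apoptosis_score"] = _to_float(df, "apoptosis_score", path, hline, minimum=0.0, maximum=1.0)
    return out


# ---------------------------------------------------------------------------
# classification tables


def write_classifications(path, classes: pd.DataFrame) -> None:
    _write_tsv(classes, path, "rarepc cell classification table v1")


def read_classifications(path) -> pd.DataFrame:
    df, hline = _read_raw(path)
    _require(df, ("cell_id", "sample_id", "subtype"), path)
    out = pd.DataFrame(
        {"cell_id": df["cell_id"], "sample_id": df["sample_id"], "subtype": df["subtype"]}
    )
    for col in ("cd138_pos", "cd56_pos", "cd45_pos", "flag_cluster", "flag_binucleated", "flag_apoptotic"):
        if col in df.columns:
            out[col] = _to_bool(df, col, path, hline)
    if "outlier_score" in df.columns:
        out["outlier_score"] = _to_float(df, "outlier_score", path, hline, allow_na=True)
    return out


# ---------------------------------------------------------------------------
# bin tables and bin-count matrices


def write_bin_table(path, bins: pd.DataFrame) -> None:
    _write_tsv(bins, path, "rarepc genome bin table v1 (chrom, start, end, gc; 0-based half-open)")


def read_bin_table(path) -> pd.DataFrame:
    df, hline = _read_raw(path)
    _require(df, ("chrom", "start", "end", "gc"), path)
    out = pd.DataFrame({"chrom": df["chrom"]})
    out["start"] = _to_int(df, "start", path, hline, minimum=0)
    out["end"] = _to_int(df, "end", path, hline, minimum=0)
    out["gc"] = _to_float(df, "gc", path, hline, minimum=0.0, maximum=1.0)
    bad = out["end"] <= out["start"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"{path} line {hline + 1 + i}: empty or inverted bin interval")
    return out


def write_bin_counts(path, counts: pd.DataFrame) -> None:
    """Write a cells x bins count matrix; columns are bin indices, first column cell_id."""
    df = counts.copy()
    df.columns = [str(c) for c in df.columns]
    _write_tsv(df, path, "rarepc bin count matrix v1 (rows cells, columns bin indices)", index=True)


def read_bin_counts(path, bins: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a bin-count matrix (index cell_id, integer bin columns 0..n-1).

    If a bin table is supplied, its length must match the matrix width.
    """
    df, hline = _read_raw(path)
    if "cell_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column(s) ['cell_id']")
    bin_cols = [c for c in df.columns if c != "cell_id"]
    try:
        order = sorted(bin_cols, key=int)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer bin column name: {exc}") from None
    if [int(c) for c in order] != list(range(len(order))):
        raise SchemaError(f"{path}: bin columns must be a contiguous 0-based range")
    if bins is not None and len(bins) != len(order):
        raise SchemaError(
            f"{path}: count matrix has {len(order)} bins but bin table declares {len(bins)}"
        )
    mat = np.empty((len(df), len(order)), dtype=np.int64)
    for j, c in enumerate(order):
        mat[:, j] = _to_int(df, c, path, hline, minimum=0)
    return pd.DataFrame(mat, index=pd.Index(df["cell_id"], name="cell_id"))


# ---------------------------------------------------------------------------
# copy-number profiles (written as a set of files under one prefix)


def write_cn_profiles(prefix, profiles, bins: pd.DataFrame | None = None) -> None:
    """Write per-cell CN profiles under ``{prefix}.{cells,segments,copynumber,ratios}.tsv``."""
    prefix = str(prefix)
    cells = pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in profiles],
            "ploidy_scale": [p.ploidy_scale for p in profiles],
            "baseline_ploidy": [p.baseline_ploidy for p in profiles],
            "altered": [p.altered for p in profiles],
            "quality": [p.quality for p in profiles],
            "degenerate": [p.degenerate for p in profiles],
        }
    )
    _write_tsv(cells, f"{prefix}.cells.tsv", "rarepc cn profile summary v1")
    seg_frames = []
    for p in profiles:
        seg = p.segments.copy()
        seg.insert(0, "cell_id", p.cell_id)
        seg_frames.append(seg)
    _write_tsv(
        pd.concat(seg_frames, ignore_index=True),
        f"{prefix}.segments.tsv",
        "rarepc cn segments v1 (bin indices, half-open)",
    )
    cn = pd.DataFrame(
        np.vstack([p.cn for p in profiles]),
        index=pd.Index([p.cell_id for p in profiles], name="cell_id"),
    )
    _write_tsv(cn, f"{prefix}.copynumber.tsv", "rarepc integer copy number matrix v1", index=True)
    ratios = pd.DataFrame(
        np.vstack([p.ratios for p in profiles]),
        index=pd.Index([p.cell_id for p in profiles], name="cell_id"),
    )
    _write_tsv(ratios, f"{prefix}.ratios.tsv", "rarepc normalized ratio matrix v1", index=True)
    if bins is not None:
        write_bin_table(f"{prefix}.bins.tsv", bins)


def read_cn_profiles(prefix):
    """Read profiles written by :func:`write_cn_profiles`."""
    from rarepc.cnv import CopyNumberProfile  # local import to avoid a cycle

    prefix = str(prefix)
    cells, hline = _read_raw(f"{prefix}.cells.tsv")
    _require(cells, ("cell_id", "ploidy_scale", "baseline_ploidy", "altered", "quality"), prefix)
    scale = _to_float(cells, "ploidy_scale", prefix, hline)
    baseline = _to_int(cells, "baseline_ploidy", prefix, hline, minimum=0)
    altered = _to_bool(cells, "altered", prefix, hline)
    quality = _to_float(cells, "quality", prefix, hline)
    degenerate = _to_bool(cells, "degenerate", prefix, hline)

    seg_df, seg_hline = _read_raw(f"{prefix}.segments.tsv")
    _require(seg_df, ("cell_id", "chrom", "start_bin", "end_bin", "n_bins", "mean_ratio", "cn"), prefix)
    seg_all = pd.DataFrame(
        {
            "cell_id": seg_df["cell_id"],
            "chrom": seg_df["chrom"],
            "start_bin": _to_int(seg_df, "start_bin", prefix, seg_hline, minimum=0),
            "end_bin": _to_int(seg_df, "end_bin", prefix, seg_hline, minimum=0),
            "n_bins": _to_int(seg_df, "n_bins", prefix, seg_hline, minimum=1),
            "mean_ratio": _to_float(seg_df, "mean_ratio", prefix, seg_hline),
            "cn": _to_int(seg_df, "cn", prefix, seg_hline, minimum=0),
        }
    )
    cn_df, cn_hline = _read_raw(f"{prefix}.copynumber.tsv")
    ratio_df, _ = _read_raw(f"{prefix}.ratios.tsv")

    profiles = []
    for i, cell_id in enumerate(cells["cell_id"]):
        seg = seg_all[seg_all["cell_id"] == cell_id].drop(columns="cell_id").reset_index(drop=True)
        cn_row = cn_df[cn_df["cell_id"] == cell_id].drop(columns="cell_id")
        cn = np.array([int(v) for v in cn_row.iloc[0]], dtype=np.int64)
        r_row = ratio_df[ratio_df["cell_id"] == cell_id].drop(columns="cell_id")
        ratios = np.array([float(v) for v in r_row.iloc[0]], dtype=float)
        profiles.append(
            CopyNumberProfile(
                cell_id=cell_id,
                ratios=ratios,
                segments=seg,
                cn=cn,
                ploidy_scale=float(scale[i]),
                baseline_ploidy=int(baseline[i]),
                altered=bool(altered[i]),
                quality=float(quality[i]),
                degenerate=bool(degenerate[i]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# FISH panels and locus panels


def write_fish_panel(path, results) -> None:
    """Write one or more FishPanelResults as a long TSV."""
    if isinstance(results, FishPanelResult):
        results = [results]
    rows = [
        {"patient_id": r.patient_id, "event_name": e, "status": s}
        for r in results
        for e, s in r.calls.items()
    ]
    _write_tsv(pd.DataFrame(rows), path, "rarepc clinical FISH panel v1")


def read_fish_panel(path, locus_panel=None) -> dict[str, FishPanelResult]:
    """Read FISH panel results; returns {patient_id: FishPanelResult}.

    If a locus panel is supplied, event names must come from it.
    """
    df, hline = _read_raw(path)
    _require(df, ("patient_id", "event_name", "status"), path)
    if locus_panel is not None:
        known = {locus.event_name for locus in locus_panel}
        bad = ~df["event_name"].isin(known)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path} line {hline + 1 + i}: unknown event {df['event_name'].iloc[i]!r}"
            )
    results: dict[str, FishPanelResult] = {}
    for patient_id, group in df.groupby("patient_id", sort=False):
        calls = {}
        for i, row in group.iterrows():
            if row["status"] not in FISH_STATUSES:
                raise ValidationError(
                    f"{path} line {hline + 1 + i}: invalid status {row['status']!r}"
                )
            calls[row["event_name"]] = row["status"]
        results[str(patient_id)] = FishPanelResult(patient_id=str(patient_id), calls=calls)
    return results


def write_locus_panel(path, panel) -> None:
    rows = [
        {
            "chrom": locus.chrom,
            "start": locus.start,
            "end": locus.end,
            "event_name": locus.event_name,
            "direction": locus.direction,
        }
        for locus in panel
    ]
    _write_tsv(pd.DataFrame(rows), path, "rarepc cytogenetic locus panel v1 (BED-like)")


def read_locus_panel(path):
    """Read a BED-like locus panel (chrom, start, end, event_name, direction)."""
    from rarepc.concordance import CytogeneticLocus  # local import to avoid a cycle

    df, hline = _read_raw(path)
    _require(df, ("chrom", "start", "end", "event_name", "direction"), path)
    start = _to_int(df, "start", path, hline, minimum=0)
    end = _to_int(df, "end", path, hline, minimum=0)
    panel = []
    for i in range(len(df)):
        direction = df["direction"].iloc[i]
        if direction not in ("gain", "loss", "translocation"):
            raise ValidationError(
                f"{path} line {hline + 1 + i}: unknown direction {direction!r}"
            )
        panel.append(
            CytogeneticLocus(
                event_name=df["event_name"].iloc[i],
                chrom=df["chrom"].iloc[i],
                start=int(start[i]),
                end=int(end[i]),
                direction=direction,
            )
        )
    return panel


# ---------------------------------------------------------------------------
# sample metadata and configuration

META_REQUIRED = ("sample_id", "patient_id", "compartment", "diagnosis", "ml_equivalent")


def write_sample_meta(path, metas) -> None:
    rows = [vars(m) for m in metas]
    _write_tsv(pd.DataFrame(rows), path, "rarepc sample metadata v1")


def read_sample_meta(path) -> list[SampleMeta]:
    df, hline = _read_raw(path)
    _require(df, META_REQUIRED, path)
    ml = _to_float(df, "ml_equivalent", path, hline)
    optional_float = {}
    for col in ("percent_bmpc", "m_spike_g_dl", "sflc_ratio"):
        if col in df.columns:
            optional_float[col] = _to_float(df, col, path, hline, allow_na=True)
    metas = []
    for i in range(len(df)):
        kwargs = {}
        for col, vals in optional_float.items():
            kwargs[col] = None if np.isnan(vals[i]) else float(vals[i])
        for col in ("flow_cd138", "flow_cd56", "flow_cd45"):
            if col in df.columns and df[col].iloc[i] != NA:
                kwargs[col] = df[col].iloc[i]
        metas.append(
            SampleMeta(
                sample_id=df["sample_id"].iloc[i],
                patient_id=df["patient_id"].iloc[i],
                compartment=df["compartment"].iloc[i],
                diagnosis=df["diagnosis"].iloc[i],
                ml_equivalent=float(ml[i]),
                **kwargs,
            )
        )
    return metas


def load_config(path) -> dict:
    """Load and minimally validate a YAML configuration file."""
    with open(path, encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise SchemaError(f"{path}: configuration must be a YAML mapping")
    if "seed" in config and not isinstance(config["seed"], int):
        raise ValidationError(f"{path}: seed must be an integer")
    return config
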