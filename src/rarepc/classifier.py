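"""Rare plasma-cell classification and enumeration.

Cells arrive as one feature row each (DAPI/CD138/CD56/CD45 mean intensities
plus morphometrics) from an enrichment-free slide scan. Channel positivity
cutoffs are calibrated per sample as median + k * MAD of log1p intensities:
rare positives are a negligible minority, so the bulk of cells defines the
negative distribution and the cutoff is robust to the spike. Every DAPI+
cell is then assigned exactly one of eleven mutually exclusive classes —
the eight myeloma CTC / bone-marrow plasma-cell candidate subtypes
(CD138+ marker combinations, CD138- candidate PC, apoptotic PC, PC cluster,
binucleated PC) plus CD56+ non-PC, common WBC and an "other rare" bucket —
and counts are normalised to cells per mL of blood equivalent.

Because the morphology-defined subtypes overlap the marker combinations
(a binucleated CD138+CD56+ cell is both), enumeration uses a fixed
precedence: apoptotic PC > PC cluster > binucleated PC > marker subtype.
Marker positivity is recorded separately so no information is lost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

CHANNELS = ("cd138", "cd56", "cd45")

# The eight MM CTC / BMPC candidate subtypes.
SUBTYPE_CD138 = "CD138+"
SUBTYPE_CD138_CD56 = "CD138+CD56+"
SUBTYPE_CD138_CD45 = "CD138+CD45+"
SUBTYPE_CD138_CD56_CD45 = "CD138+CD56+CD45+"
SUBTYPE_CD138_NEG_PC = "CD138- candidate PC"
SUBTYPE_APOPTOTIC = "apoptotic PC"
SUBTYPE_CLUSTER = "PC cluster"
SUBTYPE_BINUCLEATED = "binucleated PC"
# Non-candidate classes.
SUBTYPE_CD56_NON_PC = "CD56+ non-PC"
SUBTYPE_WBC = "common WBC"
SUBTYPE_OTHER = "other rare"

PC_CANDIDATE_SUBTYPES: tuple[str, ...] = (
    SUBTYPE_CD138,
    SUBTYPE_CD138_CD56,
    SUBTYPE_CD138_CD45,
    SUBTYPE_CD138_CD56_CD45,
    SUBTYPE_CD138_NEG_PC,
    SUBTYPE_APOPTOTIC,
    SUBTYPE_CLUSTER,
    SUBTYPE_BINUCLEATED,
)

SUBTYPES: tuple[str, ...] = PC_CANDIDATE_SUBTYPES + (
    SUBTYPE_CD56_NON_PC,
    SUBTYPE_WBC,
    SUBTYPE_OTHER,
)

#: Subtypes whose definition requires CD138 positivity; their union is the
#: "total CD138+" enumeration used for patient stratification.
CD138_POS_SUBTYPES: frozenset[str] = frozenset(
    {
        SUBTYPE_CD138,
        SUBTYPE_CD138_CD56,
        SUBTYPE_CD138_CD45,
        SUBTYPE_CD138_CD56_CD45,
        SUBTYPE_APOPTOTIC,
        SUBTYPE_CLUSTER,
        SUBTYPE_BINUCLEATED,
    }
)

DEFAULT_FEATURE_COLUMNS = (
    "dapi",
    "cd138",
    "cd56",
    "cd45",
    "area",
    "eccentricity",
    "nucleus_count",
    "apoptosis_score",
)


@dataclass(frozen=True)
class ChannelThresholds:
    """Per-channel positivity cutoffs on the original intensity scale."""

    cutoffs: dict[str, float]
    method: str = "median_kmad_log1p"
    location: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for channel, cut in self.cutoffs.items():
            if cut < 0:
                raise ValueError(f"negative cutoff for channel {channel!r}")


@dataclass(frozen=True)
class ClassifierParams:
    """Tunable rules for the morphology-dependent classes.

    size_quantile: a CD138- cell counts as "larger than surrounding WBCs"
        when its area exceeds this quantile of the CD45+CD138- cells of the
        same sample.
    eccentricity_cutoff: minimum nuclear eccentricity for the eccentric-
        nucleus criterion of CD138- candidate PCs.
    apoptosis_cutoff: minimum apoptosis score (DAPI condensation / blebbing
        proxy, in [0, 1]) for the apoptotic-PC flag.
    """

    size_quantile: float = 0.95
    eccentricity_cutoff: float = 0.6
    apoptosis_cutoff: float = 0.7


#: Which population dominates each channel on an enrichment-free slide.
#: CD138 and CD56 positives are rare events, so the bulk of cells defines
#: the negative distribution and the cutoff is its upper robust fence.
#: CD45 is the common-leukocyte marker: nearly every plated cell is
#: positive, so its bulk defines the POSITIVE distribution and the
#: negativity cutoff is the lower robust fence instead.
DEFAULT_BULK = {"cd138": "negative", "cd56": "negative", "cd45": "positive", "dapi": "positive"}


def calibrate_thresholds(
    features: pd.DataFrame,
    k_mad: float = 5.0,
    channels: tuple[str, ...] = CHANNELS,
    bulk: dict[str, str] | None = None,
) -> ChannelThresholds:
    """Calibrate per-channel positivity cutoffs from a sample's cells.

    cutoff = median +/- k_mad * MAD of log1p(intensity) over all cells,
    mapped back to the original intensity scale; the sign follows which
    population the bulk of cells represents on that channel (see
    DEFAULT_BULK). A channel whose MAD is 0 (degenerate, e.g. constant
    staining) falls back to a small epsilon above the median so that, under
    the strict '>' positivity comparison, no cell of the constant bulk is
    called positive; a warning is emitted.
    """
    if len(features) < 100:
        raise ValueError(f"need >= 100 cells to calibrate thresholds, got {len(features)}")
    if k_mad <= 0:
        raise ValueError("k_mad must be > 0")
    if bulk is None:
        bulk = DEFAULT_BULK
    cutoffs: dict[str, float] = {}
    location: dict[str, float] = {}
    scale: dict[str, float] = {}
    for channel in channels:
        x = np.log1p(np.asarray(features[channel], dtype=float))
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        sign = -1.0 if bulk.get(channel, "negative") == "positive" else 1.0
        if mad == 0.0:
            warnings.warn(
                f"MAD of log1p({channel}) is 0; falling back to epsilon above the median",
                RuntimeWarning,
                stacklevel=2,
            )
            cut_log = med + 1e-6
        else:
            cut_log = med + sign * k_mad * mad
        cutoffs[channel] = float(np.expm1(cut_log))
        location[channel] = med
        scale[channel] = mad
    return ChannelThresholds(cutoffs=cutoffs, location=location, scale=scale)


def score_outliers(
    features: pd.DataFrame,
    k_neighbors: int = 10,
    feature_columns: tuple[str, ...] = DEFAULT_FEATURE_COLUMNS,
) -> np.ndarray:
    """Mean distance to the k nearest neighbours in robust-z feature space.

    The score ranks cells by morphological atypicality for review; it never
    overrules the marker rules. Features are standardised per column with a
    robust z (median / 1.4826 * MAD); zero-MAD columns get unit scale so a
    constant column contributes nothing.
    """
    n = len(features)
    if n <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} cells, got {n}")
    cols = [c for c in feature_columns if c in features.columns]
    x = features[cols].to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    scale = np.where(mad > 0, 1.4826 * mad, 1.0)
    z = (x - med) / scale
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(z)
    dist, _ = nn.kneighbors(z)
    return dist[:, 1:].mean(axis=1)  # drop self-distance


def _positivity(features: pd.DataFrame, thresholds: ChannelThresholds) -> pd.DataFrame:
    pos = pd.DataFrame(index=features.index)
    for channel in CHANNELS:
        pos[f"{channel}_pos"] = features[channel].to_numpy(dtype=float) > thresholds.cutoffs[channel]
    return pos


def classify_cells(
    features: pd.DataFrame,
    thresholds: ChannelThresholds,
    params: ClassifierParams | None = None,
    outlier_scores: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign every DAPI+ cell exactly one subtype.

    Returns a table with cell_id, sample_id, the positivity triple, the
    morphology flags (cluster / binucleated / apoptotic), the subtype and
    the outlier score (NaN when not supplied). The subtype set partitions
    the cells: counts over subtypes always sum to the number of rows.
    """
    if params is None:
        params = ClassifierParams()
    if thresholds is None:
        raise ValueError("thresholds must be calibrated before classification")
    missing = {c for c in CHANNELS} - set(thresholds.cutoffs)
    if missing:
        raise ValueError(f"thresholds missing channels: {sorted(missing)}")

    pos = _positivity(features, thresholds)
    cd138 = pos["cd138_pos"].to_numpy()
    cd56 = pos["cd56_pos"].to_numpy()
    cd45 = pos["cd45_pos"].to_numpy()

    area = features["area"].to_numpy(dtype=float)
    ecc = features["eccentricity"].to_numpy(dtype=float)
    nuclei = features["nucleus_count"].to_numpy(dtype=float)
    apo = features["apoptosis_score"].to_numpy(dtype=float)

    # "Larger than surrounding WBCs": above the size_quantile of the
    # CD45+CD138- cells of the same sample.
    sample_ids = features["sample_id"].astype(str).to_numpy()
    size_cut = np.empty(len(features), dtype=float)
    for sid in np.unique(sample_ids):
        in_sample = sample_ids == sid
        wbc_like = in_sample & cd45 & ~cd138
        ref = area[wbc_like] if wbc_like.any() else area[in_sample]
        size_cut[in_sample] = np.quantile(ref, params.size_quantile)
    large = area > size_cut
    eccentric = ecc > params.eccentricity_cutoff

    # Cluster flag: >= 2 CD138+ cells sharing a cluster_id within a sample.
    cluster_ids = features["cluster_id"] if "cluster_id" in features.columns else pd.Series(
        [None] * len(features), index=features.index
    )
    has_cluster = cluster_ids.notna().to_numpy() & (cluster_ids.astype(str) != "NA").to_numpy()
    key = pd.Series(
        np.where(has_cluster & cd138, sample_ids + "::" + cluster_ids.astype(str), ""),
        index=features.index,
    )
    sizes = key[key != ""].map(key[key != ""].value_counts())
    cluster_size = np.zeros(len(features), dtype=int)
    cluster_size[(key != "").to_numpy()] = sizes.to_numpy(dtype=int)
    flag_cluster = cd138 & (cluster_size >= 2)

    flag_binucleated = cd138 & (nuclei >= 2)
    flag_apoptotic = cd138 & (apo > params.apoptosis_cutoff)

    subtype = np.full(len(features), SUBTYPE_OTHER, dtype=object)
    marker = np.select(
        [cd56 & cd45, cd56 & ~cd45, ~cd56 & cd45],
        [SUBTYPE_CD138_CD56_CD45, SUBTYPE_CD138_CD56, SUBTYPE_CD138_CD45],
        default=SUBTYPE_CD138,
    )
    # Precedence among overlapping CD138+ categories (see module docstring).
    subtype[cd138] = marker[cd138]
    subtype[flag_binucleated] = SUBTYPE_BINUCLEATED
    subtype[flag_cluster] = SUBTYPE_CLUSTER
    subtype[flag_apoptotic] = SUBTYPE_APOPTOTIC
    neg = ~cd138
    subtype[neg & large & eccentric] = SUBTYPE_CD138_NEG_PC
    subtype[neg & ~(large & eccentric) & cd56] = SUBTYPE_CD56_NON_PC
    subtype[neg & ~(large & eccentric) & ~cd56 & cd45] = SUBTYPE_WBC
    # remaining CD138-CD56-CD45- cells without PC morphology stay "other rare"

    out = pd.DataFrame(
        {
            "cell_id": features["cell_id"].to_numpy(),
            "sample_id": features["sample_id"].to_numpy(),
            "cd138_pos": cd138,
            "cd56_pos": cd56,
            "cd45_pos": cd45,
            "flag_cluster": flag_cluster,
            "flag_binucleated": flag_binucleated,
            "flag_apoptotic": flag_apoptotic,
            "subtype": subtype,
            "outlier_score": np.nan if outlier_scores is None else np.asarray(outlier_scores, float),
        }
    )
    return out


def classify_cell(
    record: pd.Series | dict,
    thresholds: ChannelThresholds,
    params: ClassifierParams | None = None,
    cluster_size: int = 1,
    wbc_size_cutoff: float | None = None,
) -> pd.Series:
    """Classify a single cell record.

    Cluster membership and the sample-level WBC size reference cannot be
    derived from one record, so they are passed in (`cluster_size` = number
    of CD138+ cells sharing this cell's cluster, `wbc_size_cutoff` = the
    sample's size threshold; defaults to the cell's own area so an isolated
    record is never called large).
    """
    rec = pd.Series(record).copy()
    if params is None:
        params = ClassifierParams()
    df = pd.DataFrame([rec])
    if "sample_id" not in df.columns:
        df["sample_id"] = "sample"
    if "cluster_id" not in df.columns or cluster_size < 2:
        df["cluster_id"] = pd.NA
    out = classify_cells(df, thresholds, params).iloc[0].copy()
    cd138 = bool(out["cd138_pos"])
    # Re-apply rules that need sample context.
    if cd138 and cluster_size >= 2 and not out["flag_apoptotic"]:
        out["flag_cluster"] = True
        out["subtype"] = SUBTYPE_CLUSTER
    if not cd138 and wbc_size_cutoff is not None:
        large = float(rec["area"]) > wbc_size_cutoff
        eccentric = float(rec["eccentricity"]) > params.eccentricity_cutoff
        if large and eccentric:
            out["subtype"] = SUBTYPE_CD138_NEG_PC
        elif out["subtype"] == SUBTYPE_CD138_NEG_PC:
            out["subtype"] = (
                SUBTYPE_CD56_NON_PC
                if out["cd56_pos"]
                else (SUBTYPE_WBC if out["cd45_pos"] else SUBTYPE_OTHER)
            )
    return out


def enumerate_subtypes(classes: pd.DataFrame, meta) -> pd.DataFrame:
    """Per-subtype counts and cells/mL for one sample.

    `meta` is a SampleMeta (or anything with an ml_equivalent attribute).
    Emits one row per subtype (zeros included) plus a "total CD138+" row,
    the union of the CD138-positive subtypes used for stratification.
    """
    ml = float(getattr(meta, "ml_equivalent", meta if np.isscalar(meta) else np.nan))
    if not ml > 0:
        raise ValueError("ml_equivalent must be > 0")
    counts = classes["subtype"].value_counts()
    rows = []
    for subtype in SUBTYPES:
        n = int(counts.get(subtype, 0))
        rows.append({"subtype": subtype, "count": n, "cells_per_ml": n / ml})
    n_cd138 = int(classes["subtype"].isin(CD138_POS_SUBTYPES).sum())
    rows.append({"subtype": "total CD138+", "count": n_cd138, "cells_per_ml": n_cd138 / ml})
    return pd.DataFrame(rows)


def stratify_by_ctc_threshold(cells_per_ml: float, threshold: float = 3.0) -> str:
    """Label a sample myeloma-like iff CD138+ cells/mL strictly exceeds the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return "myeloma-like" if cells_per_ml > threshold else "normal-like"
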