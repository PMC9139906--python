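"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators emulate the study's three inputs, each returning ground
truth for recovery tests:

* ``simulate_if_cohort`` — per-cell immunofluorescence feature tables from a
  slide of mostly common WBCs with rare plasma-cell subtypes spiked at
  configurable frequencies (default well below 1e-2 in total). Channel
  intensities are log-normal (negative vs ~10x brighter positive
  populations); plasma cells are larger and more eccentric than WBCs.
* ``simulate_cnv_cells`` — per-cell genomic bin counts from a mixture of
  clones with integer copy-number architectures (hyperdiploid trisomies,
  arm/chromosome losses) on an hg19-proportioned genome. Expected bin
  counts are proportional to copy number x bin width x a quadratic GC-bias
  factor; counts are negative-binomial with a single genome-wide dispersion
  (Poisson in the dispersion -> 0 limit), totalling ~500,000 reads per cell.
* ``simulate_fish_panel`` — the clinical FISH panel a cytogenetics lab would
  report for the same clone mixture: a copy-number event is panel-positive
  iff the clone-fraction-weighted share of cells carrying it reaches the
  clinical cutoff (default 20%). Translocations are not modelled and are
  reported negative.

Sex chromosomes are simulated at copy number 2 regardless of clone ploidy
(female-like) so they cannot confound ploidy fitting, which excludes them
anyway. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rarepc import classifier as _cls
from rarepc._util import weighted_median
from rarepc.genome import (
    AUTOSOMES,
    CHROMOSOMES,
    HG19_CHROM_LENGTHS,
    SEX_CHROMS,
    validate_interval,
)
from rarepc.io import FishPanelResult

MIN_BINS = len(CHROMOSOMES)  # at least one bin per chromosome


# ---------------------------------------------------------------------------
# genome bin table


def make_bin_table(n_bins: int, seed: int = 0) -> pd.DataFrame:
    """Partition an hg19-proportioned genome into n_bins bins with GC content.

    Bins are allocated to chromosomes proportional to length (>= 1 each,
    largest-remainder rounding) and are equal-width within a chromosome up
    to integer rounding; coordinates are 0-based half-open and exactly
    partition each chromosome. GC fractions are drawn in (0.2, 0.8) from a
    logistic-transformed AR(1) process, so neighbouring bins have correlated
    GC as on a real genome.
    """
    if n_bins < MIN_BINS:
        raise ValueError(f"n_bins must be >= {MIN_BINS} (one bin per chromosome), got {n_bins}")
    rng = np.random.default_rng(seed)
    lengths = np.array([HG19_CHROM_LENGTHS[c] for c in CHROMOSOMES], dtype=float)
    extra = n_bins - MIN_BINS
    quota = extra * lengths / lengths.sum()
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    short = extra - alloc.sum()
    if short > 0:
        for i in np.argsort(-remainder, kind="stable")[:short]:
            alloc[i] += 1
    alloc += 1

    rho = 0.7
    rows: list[tuple[str, int, int, float]] = []
    for chrom, k in zip(CHROMOSOMES, alloc):
        length = HG19_CHROM_LENGTHS[chrom]
        edges = np.rint(np.linspace(0, length, k + 1)).astype(np.int64)
        x = np.empty(k)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(k)
        for i in range(1, k):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho**2) * eps[i]
        gc = 0.2 + 0.6 / (1.0 + np.exp(-(0.8 * x - 0.2)))
        for i in range(k):
            rows.append((chrom, int(edges[i]), int(edges[i + 1]), float(gc[i])))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"])


# ---------------------------------------------------------------------------
# immunofluorescence cohort


@dataclass(frozen=True)
class ChannelModel:
    """Log-normal intensity model for one channel (natural-log location/scale)."""

    neg_loc: float
    neg_scale: float
    pos_loc: float
    pos_scale: float

    def __post_init__(self) -> None:
        if self.pos_loc <= self.neg_loc:
            raise ValueError("positive location must exceed negative location")
        if min(self.neg_scale, self.pos_scale) <= 0:
            raise ValueError("scales must be > 0")


def _default_channel_models() -> dict[str, ChannelModel]:
    # ~10x separation between negative and positive populations; the
    # log-scale spread (0.3, ~30% CV) reflects a validated high-separation
    # assay where single-channel misclassification is a <1e-3 tail event.
    sep = float(np.log(10.0))
    base = {"dapi": 5.5, "cd138": 4.0, "cd56": 4.0, "cd45": 4.2}
    return {ch: ChannelModel(loc, 0.3, loc + sep, 0.3) for ch, loc in base.items()}


@dataclass(frozen=True)
class MorphoModels:
    """Size / shape distributions for WBCs vs plasma cells.

    Areas are log-normal (um^2); plasma cells run ~2.5x larger than WBCs.
    Nuclear eccentricity is Beta-distributed: WBC nuclei are round, plasma
    cell nuclei eccentric. Apoptosis scores are Beta as well, concentrated
    near 0 for healthy cells and near 1 for the apoptotic subtype.
    """

    wbc_area_logmu: float = 4.25  # ~70 um^2
    wbc_area_logsd: float = 0.25
    pc_area_logmu: float = 5.19  # ~180 um^2
    pc_area_logsd: float = 0.25
    wbc_ecc_ab: tuple[float, float] = (2.0, 5.0)
    pc_ecc_ab: tuple[float, float] = (12.0, 3.0)
    apoptosis_ab: tuple[float, float] = (1.0, 20.0)
    apoptotic_ab: tuple[float, float] = (15.0, 2.0)


def default_subtype_frequencies() -> dict[str, float]:
    """Rare-subtype frequencies of a myeloma-like slide (sum << 1e-2)."""
    return {
        _cls.SUBTYPE_CD138: 1e-4,
        _cls.SUBTYPE_CD138_CD56: 1e-4,
        _cls.SUBTYPE_CD138_CD45: 5e-5,
        _cls.SUBTYPE_CD138_CD56_CD45: 5e-5,
        _cls.SUBTYPE_CD138_NEG_PC: 5e-5,
        _cls.SUBTYPE_APOPTOTIC: 3e-5,
        _cls.SUBTYPE_CLUSTER: 4e-5,
        _cls.SUBTYPE_BINUCLEATED: 3e-5,
        _cls.SUBTYPE_CD56_NON_PC: 1e-3,
        _cls.SUBTYPE_OTHER: 1e-4,
    }


@dataclass(frozen=True)
class IFCohortSpec:
    """Study conditions for a synthetic immunofluorescence cohort.

    cells_per_sample defaults to a 50,000-cell scaled-down slide (real
    slides carry ~3 million cells); ml_equivalent_per_sample is the blood
    volume the slide represents, used for cells/mL normalisation.
    """

    n_samples: int = 1
    cells_per_sample: int = 50_000
    ml_equivalent_per_sample: float = 1.0
    subtype_frequencies: dict[str, float] = field(default_factory=default_subtype_frequencies)
    channel_models: dict[str, ChannelModel] = field(default_factory=_default_channel_models)
    morpho_models: MorphoModels = field(default_factory=MorphoModels)
    compartment: str = "PB"
    seed: int = 0

    def validate(self) -> None:
        if self.cells_per_sample < 1:
            raise ValueError("cells_per_sample must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.ml_equivalent_per_sample <= 0:
            raise ValueError("ml_equivalent_per_sample must be > 0")
        freqs = self.subtype_frequencies
        unknown = set(freqs) - set(_cls.SUBTYPES)
        if unknown:
            raise ValueError(f"unknown subtypes in frequencies: {sorted(unknown)}")
        if any(f < 0 for f in freqs.values()):
            raise ValueError("frequencies must be >= 0")
        if sum(freqs.values()) >= 1.0:
            raise ValueError("subtype frequencies must sum to < 1")
        rare = sum(f for s, f in freqs.items() if s in _cls.PC_CANDIDATE_SUBTYPES)
        if rare >= 0.01:
            raise ValueError("rare-subtype frequencies must sum to < 0.01")
        for ch in ("dapi", "cd138", "cd56", "cd45"):
            if ch not in self.channel_models:
                raise ValueError(f"missing channel model for {ch!r}")


# which channels are positive for each generated subtype
_SUBTYPE_MARKERS: dict[str, tuple[bool, bool, bool]] = {
    # (cd138, cd56, cd45)
    _cls.SUBTYPE_CD138: (True, False, False),
    _cls.SUBTYPE_CD138_CD56: (True, True, False),
    _cls.SUBTYPE_CD138_CD45: (True, False, True),
    _cls.SUBTYPE_CD138_CD56_CD45: (True, True, True),
    _cls.SUBTYPE_CD138_NEG_PC: (False, False, False),
    _cls.SUBTYPE_APOPTOTIC: (True, False, False),
    _cls.SUBTYPE_CLUSTER: (True, True, False),
    _cls.SUBTYPE_BINUCLEATED: (True, False, False),
    _cls.SUBTYPE_CD56_NON_PC: (False, True, True),
    _cls.SUBTYPE_WBC: (False, False, True),
    _cls.SUBTYPE_OTHER: (False, False, False),
}

_PC_LIKE = set(_cls.PC_CANDIDATE_SUBTYPES)


def simulate_if_cohort(spec: IFCohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (cell feature table, truth table) for an IF cohort.

    Every cell is DAPI+ (the classification gate). The truth table links
    each cell_id to its generating subtype; rare subtypes appear at their
    specified frequencies up to binomial sampling error. PC-cluster cells
    are emitted in groups of >= 2 sharing a cluster_id whenever at least two
    were drawn.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.morpho_models

    labels = list(spec.subtype_frequencies)
    probs = np.array([spec.subtype_frequencies[s] for s in labels], dtype=float)
    labels.append(_cls.SUBTYPE_WBC)
    probs = np.append(probs, 1.0 - probs.sum())

    feat_frames: list[pd.DataFrame] = []
    truth_frames: list[pd.DataFrame] = []
    for s in range(spec.n_samples):
        sid = f"S{s + 1:02d}"
        n = spec.cells_per_sample
        subtype = rng.choice(len(labels), size=n, p=probs)
        subtype_labels = np.array(labels, dtype=object)[subtype]

        markers = np.array([_SUBTYPE_MARKERS[s_] for s_ in subtype_labels], dtype=bool)
        intensities: dict[str, np.ndarray] = {}
        cm_dapi = spec.channel_models["dapi"]
        intensities["dapi"] = rng.lognormal(cm_dapi.pos_loc, cm_dapi.pos_scale, size=n)
        for j, ch in enumerate(("cd138", "cd56", "cd45")):
            cm = spec.channel_models[ch]
            loc = np.where(markers[:, j], cm.pos_loc, cm.neg_loc)
            sc = np.where(markers[:, j], cm.pos_scale, cm.neg_scale)
            intensities[ch] = rng.lognormal(loc, sc)

        pc_like = np.isin(subtype_labels, list(_PC_LIKE))
        area = np.where(
            pc_like,
            rng.lognormal(m.pc_area_logmu, m.pc_area_logsd, size=n),
            rng.lognormal(m.wbc_area_logmu, m.wbc_area_logsd, size=n),
        )
        ecc = np.where(
            pc_like,
            rng.beta(*m.pc_ecc_ab, size=n),
            rng.beta(*m.wbc_ecc_ab, size=n),
        )
        apoptotic = subtype_labels == _cls.SUBTYPE_APOPTOTIC
        apo = np.where(
            apoptotic,
            rng.beta(*m.apoptotic_ab, size=n),
            rng.beta(*m.apoptosis_ab, size=n),
        )
        nuclei = np.where(subtype_labels == _cls.SUBTYPE_BINUCLEATED, 2, 1)

        cluster_id = np.full(n, "NA", dtype=object)
        members = np.flatnonzero(subtype_labels == _cls.SUBTYPE_CLUSTER)
        if members.size >= 2:
            n_groups = members.size // 2
            for g in range(n_groups):
                lo = 2 * g
                hi = members.size if g == n_groups - 1 else 2 * g + 2
                cluster_id[members[lo:hi]] = f"{sid}_cl{g + 1}"

        frame_id = rng.integers(1, 2305, size=n)
        cell_id = np.array([f"{sid}_c{i:06d}" for i in range(n)], dtype=object)
        feat_frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "sample_id": sid,
                    "compartment": spec.compartment,
                    "frame_id": frame_id,
                    "dapi": intensities["dapi"],
                    "cd138": intensities["cd138"],
                    "cd56": intensities["cd56"],
                    "cd45": intensities["cd45"],
                    "area": area,
                    "eccentricity": ecc,
                    "nucleus_count": nuclei,
                    "cluster_id": cluster_id,
                    "apoptosis_score": apo,
                }
            )
        )
        truth_frames.append(
            pd.DataFrame({"cell_id": cell_id, "sample_id": sid, "true_subtype": subtype_labels})
        )
    return (
        pd.concat(feat_frames, ignore_index=True),
        pd.concat(truth_frames, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# single-cell CNV simulation


@dataclass(frozen=True)
class CloneSpec:
    """One clone: baseline integer ploidy plus (chrom, start, end, cn) events.

    Events override the baseline on the bins they cover. fraction is the
    proportion of cells drawn from this clone.
    """

    clone_id: str
    ploidy: int = 2
    events: tuple[tuple[str, int, int, int], ...] = ()
    fraction: float = 1.0

    def validate(self) -> None:
        if not (2 <= self.ploidy <= 5):
            raise ValueError(f"clone ploidy must be in [2, 5], got {self.ploidy}")
        if not (0 <= self.fraction <= 1):
            raise ValueError("clone fraction must be in [0, 1]")
        for chrom, start, end, cn in self.events:
            validate_interval(chrom, start, end)
            if cn < 0:
                raise ValueError(f"negative copy number in event {chrom}:{start}-{end}")

    def cn_per_bin(self, bins: pd.DataFrame) -> np.ndarray:
        """True integer CN per bin: ploidy on autosomes, 2 on sex chromosomes,
        events applied (in order) to bins whose midpoint they cover."""
        chrom = bins["chrom"].to_numpy()
        mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
        cn = np.where(np.isin(chrom, list(SEX_CHROMS)), 2, self.ploidy).astype(np.int64)
        for ev_chrom, start, end, ev_cn in self.events:
            mask = (chrom == ev_chrom) & (mid >= start) & (mid < end)
            cn[mask] = ev_cn
        return cn

    def cn_at_locus(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted median CN over [start, end) from the piecewise profile."""
        validate_interval(chrom, start, end)
        base = 2 if chrom in SEX_CHROMS else self.ploidy
        points = {start, end}
        for ev_chrom, s, e, _ in self.events:
            if ev_chrom == chrom:
                points.update(p for p in (s, e) if start < p < end)
        edges = sorted(points)
        mids = [(a + b) / 2 for a, b in zip(edges[:-1], edges[1:])]
        widths = [b - a for a, b in zip(edges[:-1], edges[1:])]
        cns = []
        for mp in mids:
            cn = base
            for ev_chrom, s, e, ev_cn in self.events:
                if ev_chrom == chrom and s <= mp < e:
                    cn = ev_cn
            cns.append(cn)
        return weighted_median(cns, widths)


@dataclass(frozen=True)
class CNVSimSpec:
    """Study conditions for single-cell bin-count simulation.

    Defaults match the sequencing design the pipeline targets: ~500,000
    mapped reads per cell over 5,000 genome bins (~100 reads/bin), with
    negative-binomial overdispersion `dispersion` (variance = mu + d*mu^2;
    0 means Poisson) and a multiplicative quadratic GC-bias curve
    gc_bias_coefficients = (a0, a1, a2) normalised to mean factor 1.
    """

    clone_specs: tuple[CloneSpec, ...] = (CloneSpec("diploid"),)
    n_cells: int = 100
    reads_per_cell: int = 500_000
    n_bins: int = 5_000
    dispersion: float = 0.1
    gc_bias_coefficients: tuple[float, float, float] = (1.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if not self.clone_specs:
            raise ValueError("need at least one clone")
        for clone in self.clone_specs:
            clone.validate()
        total = sum(c.fraction for c in self.clone_specs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"clone fractions must sum to 1, got {total}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.reads_per_cell < self.n_bins:
            raise ValueError("reads_per_cell must be >= n_bins")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass(frozen=True)
class CNVTruth:
    """Ground truth for simulated cells: per-cell labels and true CN matrix."""

    cells: pd.DataFrame  # cell_id, clone_id, true_ploidy
    copy_number: pd.DataFrame  # cells x bins, integer CN


def simulate_cnv_cells(
    spec: CNVSimSpec, bins: pd.DataFrame
) -> tuple[pd.DataFrame, CNVTruth]:
    """Generate (bin-count matrix, truth) for a clone mixture.

    Expected count per bin is proportional to true CN x bin width x GC-bias
    factor, scaled so each cell totals ~reads_per_cell in expectation.
    Counts are negative-binomial (Poisson when dispersion == 0).
    """
    spec.validate()
    if len(bins) != spec.n_bins:
        raise ValueError(f"bin table has {len(bins)} bins but spec.n_bins = {spec.n_bins}")
    rng = np.random.default_rng(spec.seed)

    width = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    gc = bins["gc"].to_numpy(dtype=float)
    a0, a1, a2 = spec.gc_bias_coefficients
    gc_factor = a0 + a1 * gc + a2 * gc**2
    gc_factor = np.clip(gc_factor, 1e-6, None)
    gc_factor = gc_factor / gc_factor.mean()

    clone_cn = {c.clone_id: c.cn_per_bin(bins) for c in spec.clone_specs}
    fractions = np.array([c.fraction for c in spec.clone_specs])
    pick = rng.choice(len(spec.clone_specs), size=spec.n_cells, p=fractions)

    cell_ids = [f"cell_{i:04d}" for i in range(spec.n_cells)]
    counts = np.empty((spec.n_cells, spec.n_bins), dtype=np.int64)
    truth_rows = []
    cn_rows = np.empty((spec.n_cells, spec.n_bins), dtype=np.int64)
    for i, k in enumerate(pick):
        clone = spec.clone_specs[k]
        cn = clone_cn[clone.clone_id]
        w = cn * width * gc_factor
        total = w.sum()
        if total <= 0:
            raise ValueError(f"clone {clone.clone_id!r} has zero expected coverage")
        mu = spec.reads_per_cell * w / total
        if spec.dispersion == 0:
            counts[i] = rng.poisson(mu)
        else:
            size = 1.0 / spec.dispersion
            with np.errstate(divide="ignore"):
                p = size / (size + mu)
            counts[i] = np.where(mu > 0, rng.negative_binomial(size, np.clip(p, 1e-12, 1.0)), 0)
        cn_rows[i] = cn
        truth_rows.append(
            {"cell_id": cell_ids[i], "clone_id": clone.clone_id, "true_ploidy": clone.ploidy}
        )

    counts_df = pd.DataFrame(counts, index=pd.Index(cell_ids, name="cell_id"))
    truth = CNVTruth(
        cells=pd.DataFrame(truth_rows),
        copy_number=pd.DataFrame(cn_rows, index=pd.Index(cell_ids, name="cell_id")),
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# clinical FISH panel from clone truth


def simulate_fish_panel(
    clone_specs,
    locus_panel,
    positivity_cutoff: float = 0.20,
    patient_id: str = "P01",
) -> FishPanelResult:
    """Derive the clinical FISH panel result implied by a clone mixture.

    A copy-number event is panel-positive iff the clone-fraction-weighted
    share of cells whose CN at the locus deviates in the event's direction
    reaches `positivity_cutoff` (clinical cut-off, default 20%).
    Translocation events are not modelled and always report negative.
    """
    clone_specs = tuple(clone_specs)
    if not clone_specs:
        raise ValueError("need at least one clone")
    if not (0 < positivity_cutoff < 1):
        raise ValueError("positivity_cutoff must be in (0, 1)")
    for clone in clone_specs:
        clone.validate()

    calls: dict[str, str] = {}
    for locus in locus_panel:
        if locus.direction == "translocation":
            calls[locus.event_name] = "negative"
            continue
        carrier_fraction = 0.0
        for clone in clone_specs:
            cn = clone.cn_at_locus(locus.chrom, locus.start, locus.end)
            hit = cn > 2 if locus.direction == "gain" else cn < 2
            if hit:
                carrier_fraction += clone.fraction
        calls[locus.event_name] = (
            "positive" if carrier_fraction >= positivity_cutoff else "negative"
        )
    return FishPanelResult(patient_id=patient_id, calls=calls)
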