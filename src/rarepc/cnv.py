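"""Single-cell low-pass copy-number calling from genomic bin counts.

The caller takes one cell's read counts over fixed genome bins (~500,000
reads over ~5,000 bins) and produces an integer copy-number profile in four
steps:

1. **Normalisation** — counts are converted to per-bp rates, a lowess fit of
   rate against GC fraction is divided out (whole-genome-amplified single
   cells carry a strong smooth GC bias), and the result is scaled to genome
   mean 1.
2. **Segmentation** — per-chromosome binary segmentation minimising
   within-segment squared error, accepting a breakpoint only when it reduces
   the error by more than a BIC-like penalty (log of the number of bins
   times a robust noise-variance estimate). Segments never cross chromosome
   boundaries.
3. **Integer ploidy fit** — a scale factor s on a grid [1.5, 6.0] (step
   0.05) is chosen to minimise the bin-weighted squared distance of
   s x (segment mean ratio) to the nearest integer; copy number per bin is
   the rounded product and the baseline ploidy is the bin-weighted modal
   copy number. Ties (e.g. a featureless flat profile fits every integer
   multiple) break toward the smallest scale, i.e. the lowest ploidy
   consistent with the data, and such degenerate fits are flagged.
4. **Altered call** — a cell is altered when its baseline ploidy deviates
   from 2 or any run of bins with copy number != 2 reaches a minimum size
   (default 10 bins, roughly arm scale at 5,000 bins).

Sex chromosomes are excluded from the ploidy fit and the altered call by
default: patient sex is not modelled, and an unmatched X/Y dose would
masquerade as an aberration.

Altered cells are grouped into clones by average-linkage hierarchical
clustering of integer profiles, with distance = fraction of bins whose
copy number differs, cut at 1 - similarity_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.nonparametric.smoothers_lowess import lowess

from rarepc.genome import SEX_CHROMS

NORMAL_CLONE_LABEL = "normal"


@dataclass
class CopyNumberProfile:
    """One cell's copy-number call: ratios, segments, integer CN and ploidy."""

    cell_id: str
    ratios: np.ndarray
    segments: pd.DataFrame  # chrom, start_bin, end_bin, n_bins, mean_ratio, cn
    cn: np.ndarray
    ploidy_scale: float
    baseline_ploidy: int
    altered: bool | None = None
    quality: float = np.nan
    degenerate: bool = False


@dataclass(frozen=True)
class CloneAssignment:
    """Clone grouping of altered cells plus consensus profiles and counts."""

    assignments: dict[str, str]  # cell_id -> clone label ("normal" reserved)
    consensus: dict[str, np.ndarray]  # clone label -> per-bin modal integer CN
    counts: pd.DataFrame  # clone x compartment cell counts


# ---------------------------------------------------------------------------
# normalisation


def normalize_bins(
    counts,
    bins: pd.DataFrame,
    gc_correct: bool = True,
    lowess_frac: float = 0.3,
) -> np.ndarray:
    """Normalise one cell's bin counts to ratios with genome mean 1.

    Counts are divided by bin width, the lowess regression of rate on GC
    fraction is divided out (skipped when GC has no variation), and the
    result is rescaled to mean 1. Linear in the counts, so a global scaling
    of the input leaves the ratios unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("cannot normalize an all-zero bin-count profile")
    if len(counts) != len(bins):
        raise ValueError(f"profile has {len(counts)} bins, bin table {len(bins)}")
    width = (bins["end"] - bins["start"]).to_numpy(dtype=float)
    rate = counts / width
    gc = bins["gc"].to_numpy(dtype=float)
    if gc_correct and np.ptp(gc) > 1e-9:
        # Estimate the GC curve on copy-number-detrended rates (each
        # chromosome divided by its median) so that a chromosome-scale
        # aberration is not partially absorbed into — and distorted by —
        # the GC fit; the correction itself is then applied to the raw
        # rates. Detrending is scale-free, so the whole step stays linear
        # in the counts. it=0 keeps lowess linear; delta thins the
        # evaluation grid for speed without visible loss at ~5,000 bins.
        chroms = bins["chrom"].to_numpy()
        detrended = rate.copy()
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            med = np.median(rate[mask])
            if med > 0:
                detrended[mask] = rate[mask] / med
        fitted = lowess(
            detrended,
            gc,
            frac=lowess_frac,
            it=0,
            delta=0.01 * np.ptp(gc),
            return_sorted=False,
        )
        floor = 1e-3 * float(np.mean(np.abs(fitted)))
        fitted = np.where(fitted > floor, fitted, max(floor, 1e-12))
        rate = rate / fitted
    return rate / rate.mean()


# ---------------------------------------------------------------------------
# segmentation


def _best_split(prefix, prefix_sq, lo: int, hi: int, min_seg: int):
    """Best single breakpoint of [lo, hi) by SSE reduction; (gain, split)."""
    n = hi - lo
    if n < 2 * min_seg:
        return 0.0, -1
    total = prefix[hi] - prefix[lo]
    total_sq = prefix_sq[hi] - prefix_sq[lo]
    sse_all = total_sq - total * total / n
    ks = np.arange(lo + min_seg, hi - min_seg + 1)
    left_n = ks - lo
    right_n = hi - ks
    left_sum = prefix[ks] - prefix[lo]
    right_sum = total - left_sum
    left_sq = prefix_sq[ks] - prefix_sq[lo]
    right_sq = total_sq - left_sq
    sse = (left_sq - left_sum**2 / left_n) + (right_sq - right_sum**2 / right_n)
    best = int(np.argmin(sse))
    return float(sse_all - sse[best]), int(ks[best])


def segment_profile(
    ratios,
    bins: pd.DataFrame,
    min_seg_bins: int = 5,
    penalty: float | None = None,
) -> pd.DataFrame:
    """Segment a ratio profile per chromosome by penalised binary segmentation.

    A candidate breakpoint is accepted only when it reduces the
    within-segment squared error by more than `penalty` (default BIC-like:
    log(total bins) x a robust noise-variance estimate from successive
    differences). Returns segments (chrom, start_bin, end_bin half-open
    global bin indices, n_bins, mean_ratio) that partition each chromosome.
    """
    if min_seg_bins < 2:
        raise ValueError("min_seg_bins must be >= 2")
    ratios = np.asarray(ratios, dtype=float)
    n = len(ratios)
    if n != len(bins):
        raise ValueError("ratios and bin table length mismatch")
    prefix = np.concatenate([[0.0], np.cumsum(ratios)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(ratios**2)])

    chroms = bins["chrom"].to_numpy()
    boundaries = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [n]])

    rows = []
    for c_start, c_end in zip(starts, ends):
        if penalty is None:
            # Read-depth noise scales with the local copy number, so the
            # noise variance is estimated per chromosome (robustly, from
            # successive differences); a global estimate under-penalises
            # splits inside gained chromosomes. 2 parameters per accepted
            # changepoint (location + new level).
            diffs = np.abs(np.diff(ratios[c_start:c_end]))
            sigma = np.median(diffs) / (0.6745 * np.sqrt(2.0)) if diffs.size else 0.0
            chrom_penalty = 2.0 * np.log(n) * sigma**2
        else:
            chrom_penalty = penalty
        stack = [(int(c_start), int(c_end))]
        breaks: list[int] = []
        while stack:
            lo, hi = stack.pop()
            gain, split = _best_split(prefix, prefix_sq, lo, hi, min_seg_bins)
            if split >= 0 and gain > chrom_penalty:
                breaks.append(split)
                stack.append((lo, split))
                stack.append((split, hi))
        edges = [int(c_start)] + sorted(breaks) + [int(c_end)]
        for lo, hi in zip(edges[:-1], edges[1:]):
            seg_sum = prefix[hi] - prefix[lo]
            rows.append(
                {
                    "chrom": chroms[lo],
                    "start_bin": lo,
                    "end_bin": hi,
                    "n_bins": hi - lo,
                    "mean_ratio": seg_sum / (hi - lo),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# integer ploidy fit


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass(frozen=True)
class PloidyFit:
    ploidy_scale: float
    cn: np.ndarray
    baseline_ploidy: int
    quality: float
    degenerate: bool
    segment_cn: np.ndarray = field(repr=False, default=None)


def fit_ploidy(
    segments: pd.DataFrame,
    bins: pd.DataFrame,
    ratios=None,
    grid: tuple[float, float, float] = (1.5, 6.0, 0.05),
    exclude_sex: bool = True,
    tie_tol: float = 1e-6,
    min_fit_bins: int = 10,
) -> PloidyFit:
    """Fit the scale mapping mean-1 ratios to integer copy numbers.

    The objective is the segment-length-weighted mean squared distance of
    s x (segment mean ratio) to the nearest integer, normalised by s^2 and
    evaluated on autosomal segments of at least `min_fit_bins` bins (sex
    chromosomes excluded by default; shorter segments carry too noisy a
    mean and are often segmentation artifacts). Among scales within a small
    tolerance of the optimum the smallest wins, preferring the lowest
    consistent ploidy; a fit where all usable segment means coincide is
    flagged degenerate. `ratios` is accepted for interface compatibility;
    the fit uses only the segment summaries.
    """
    lo, hi, step = grid
    scales = np.round(np.arange(lo, hi + step / 2, step), 10)
    means = segments["mean_ratio"].to_numpy(dtype=float)
    weights = segments["n_bins"].to_numpy(dtype=float)
    usable = np.ones(len(segments), dtype=bool)
    if exclude_sex:
        usable = ~segments["chrom"].isin(SEX_CHROMS).to_numpy()
    # short segments are dominated by their mean's noise (and are often
    # segmentation artifacts); they destabilise the scale fit
    long_enough = usable & (weights >= min_fit_bins)
    if long_enough.any():
        usable = long_enough
    elif not usable.any():
        usable = np.ones(len(segments), dtype=bool)
    m, w = means[usable], weights[usable]

    prod = scales[:, None] * m[None, :]
    dist = prod - _round_half_up(prod)
    # Normalising the integer-distance objective by s^2 expresses it as the
    # implied squared error of the segment means themselves, which makes
    # fits at different scales comparable: noise in a segment mean inflates
    # the raw distances in proportion to s, and multiples of a well-fitting
    # scale tie instead of competing. The best value over the grid is then
    # a per-cell noise estimate, and the chosen scale is the SMALLEST one
    # whose normalised misfit stays within `noise_factor` of it — the lowest
    # ploidy consistent with the data. On noise-free input the estimate is
    # 0 and only exact fits tie (resolved by tie_tol). The worst-fitting 2%
    # of bin weight is trimmed per scale so a single aberrant segment (often
    # a segmentation artifact) cannot veto an otherwise consistent scale; a
    # genuinely wrong scale misfits far more weight than the trim absorbs.
    sq = dist**2
    contrib = sq * w[None, :]
    order = np.argsort(-sq, axis=1, kind="stable")
    w_sorted = np.take_along_axis(np.broadcast_to(w, sq.shape), order, axis=1)
    c_sorted = np.take_along_axis(contrib, order, axis=1)
    drop = np.cumsum(w_sorted, axis=1) <= 0.02 * w.sum()
    trimmed = (c_sorted * ~drop).sum(axis=1)
    kept_weight = w.sum() - (w_sorted * drop).sum(axis=1)
    objective = trimmed / kept_weight / scales**2
    best = objective.min()
    s_best = float(scales[int(np.argmin(objective))])
    # Acceptance band for preferring a smaller scale over the minimiser.
    # An integer divisor of the best scale describes the same integer
    # profile with every copy number divided by k — if it were wrong it
    # would put half-integer states on most of the genome and its objective
    # would explode (>10x), so divisors get a wide band; non-divisor
    # alternatives (e.g. 4/5 of the true scale on a pentaploid cell)
    # genuinely compete with the fit and get a tight one.
    noise_factor = 2.2
    divisor_factor = 8.0
    q = s_best / scales
    is_divisor = (np.abs(q - np.round(q)) <= 0.06) & (np.round(q) >= 2)
    band = np.where(is_divisor, divisor_factor, noise_factor)
    idx = int(np.flatnonzero(objective <= best * band + tie_tol)[0])
    scale = float(scales[idx])
    quality = float(objective[idx])
    degenerate = bool(np.ptp(m) < 1e-9)

    segment_cn = np.maximum(_round_half_up(scale * means), 0).astype(np.int64)
    cn = np.repeat(segment_cn, segments["n_bins"].to_numpy())

    # baseline = bin-count-weighted modal CN over autosomal segments;
    # ties break toward the smaller copy number.
    auto_cn = segment_cn[usable]
    auto_w = weights[usable]
    tally: dict[int, float] = {}
    for c, wt in zip(auto_cn, auto_w):
        tally[int(c)] = tally.get(int(c), 0.0) + wt
    baseline = min(tally, key=lambda c: (-tally[c], c))
    return PloidyFit(scale, cn, int(baseline), quality, degenerate, segment_cn)


# ---------------------------------------------------------------------------
# altered call


def call_altered(
    profile: CopyNumberProfile,
    bins: pd.DataFrame,
    min_event_bins: int = 10,
    exclude_sex: bool = True,
) -> bool:
    """Altered iff baseline ploidy != 2 or a CN != 2 run spans >= min_event_bins.

    Runs are evaluated on the bin-level integer profile within chromosomes,
    so an event split across adjacent segments still counts once.
    """
    if min_event_bins < 1:
        raise ValueError("min_event_bins must be >= 1")
    if profile.baseline_ploidy != 2:
        return True
    chroms = bins["chrom"].to_numpy()
    cn = np.asarray(profile.cn)
    keep = ~np.isin(chroms, list(SEX_CHROMS)) if exclude_sex else np.ones(len(cn), bool)
    for chrom in pd.unique(chroms[keep]):
        mask = chroms == chrom
        deviates = cn[mask] != 2
        if not deviates.any():
            continue
        # longest run of deviating bins
        padded = np.concatenate([[0], deviates.astype(int), [0]])
        edges = np.flatnonzero(np.diff(padded))
        run_lengths = edges[1::2] - edges[0::2]
        if run_lengths.max() >= min_event_bins:
            return True
    return False


# ---------------------------------------------------------------------------
# full per-cell pipeline


def call_profile(
    cell_id: str,
    counts,
    bins: pd.DataFrame,
    gc_correct: bool = True,
    min_seg_bins: int = 5,
    penalty: float | None = None,
    grid: tuple[float, float, float] = (1.5, 6.0, 0.05),
    min_event_bins: int = 10,
    exclude_sex: bool = True,
) -> CopyNumberProfile:
    """Normalise, segment, integer-fit and altered-call one cell."""
    ratios = normalize_bins(counts, bins, gc_correct=gc_correct)
    segments = segment_profile(ratios, bins, min_seg_bins=min_seg_bins, penalty=penalty)
    fit = fit_ploidy(segments, bins, ratios=ratios, grid=grid, exclude_sex=exclude_sex)
    segments = segments.assign(cn=fit.segment_cn)
    profile = CopyNumberProfile(
        cell_id=cell_id,
        ratios=ratios,
        segments=segments,
        cn=fit.cn,
        ploidy_scale=fit.ploidy_scale,
        baseline_ploidy=fit.baseline_ploidy,
        quality=fit.quality,
        degenerate=fit.degenerate,
    )
    profile.altered = call_altered(
        profile, bins, min_event_bins=min_event_bins, exclude_sex=exclude_sex
    )
    return profile


def call_cells(counts: pd.DataFrame, bins: pd.DataFrame, **kwargs) -> list[CopyNumberProfile]:
    """Run :func:`call_profile` for every row (cell) of a count matrix."""
    return [
        call_profile(str(cell_id), counts.loc[cell_id].to_numpy(), bins, **kwargs)
        for cell_id in counts.index
    ]


# ---------------------------------------------------------------------------
# clone grouping


def group_clones(
    profiles,
    bins: pd.DataFrame,
    similarity_threshold: float = 0.95,
    meta: pd.DataFrame | None = None,
    exclude_sex: bool = True,
) -> CloneAssignment:
    """Group altered cells into clones by integer-profile similarity.

    Similarity between two cells is the fraction of (autosomal) bins with
    identical integer CN; cells merge into one clone while their
    average-linkage distance stays within 1 - similarity_threshold. Normal
    cells receive the reserved label "normal". Clones are numbered by
    descending size. `meta` (cell_id, compartment) makes the per-clone
    compartment counts meaningful; cells without metadata count under "all".
    """
    if not (0 < similarity_threshold <= 1):
        raise ValueError("similarity_threshold must be in (0, 1]")
    profiles = list(profiles)
    altered = [p for p in profiles if p.altered]
    assignments: dict[str, str] = {
        p.cell_id: NORMAL_CLONE_LABEL for p in profiles if not p.altered
    }
    consensus: dict[str, np.ndarray] = {}
    if altered:
        chroms = bins["chrom"].to_numpy()
        keep = ~np.isin(chroms, list(SEX_CHROMS)) if exclude_sex else np.ones(len(chroms), bool)
        x = np.vstack([p.cn[keep] for p in altered])
        if len(altered) == 1:
            labels = np.array([1])
        else:
            d = pdist(x, metric="hamming")
            z = linkage(d, method="average")
            labels = fcluster(z, t=1.0 - similarity_threshold, criterion="distance")
        order = pd.Series(labels).value_counts(sort=True).index  # by size desc
        rename = {int(old): f"clone_{i + 1}" for i, old in enumerate(order)}
        for p, lab in zip(altered, labels):
            assignments[p.cell_id] = rename[int(lab)]
        full = np.vstack([p.cn for p in altered])
        for old, name in rename.items():
            members = full[labels == old]
            # per-bin modal CN; ties toward the smaller copy number
            consensus[name] = np.apply_along_axis(
                lambda col: np.bincount(col).argmax(), 0, members
            ).astype(np.int64)

    comp = {}
    if meta is not None:
        comp = dict(zip(meta["cell_id"].astype(str), meta["compartment"].astype(str)))
    rows = [
        {"cell_id": cid, "clone": clone, "compartment": comp.get(cid, "all")}
        for cid, clone in assignments.items()
    ]
    counts = (
        pd.DataFrame(rows)
        .groupby(["clone", "compartment"])
        .size()
        .unstack(fill_value=0)
        .rename_axis(columns=None)
        if rows
        else pd.DataFrame()
    )
    return CloneAssignment(assignments=assignments, consensus=consensus, counts=counts)
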