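"""Cohort-level statistics and summary tables.

Small rare-cell cohorts (a handful of patients, a few hundred sequenced
cells) call for exact rather than asymptotic inference: group comparisons
use the exact Wilcoxon rank-sum (Mann-Whitney) test with midranks for ties,
enumerating all C(n_a + n_b, n_a) group assignments when the total sample
is small and falling back to seeded Monte-Carlo permutation otherwise. At
4-vs-4 with complete separation the two-sided p is exactly 2/70 ~= 0.029,
the resolution limit of such a comparison.

The table builders summarise the joined morphology x genomics data:
altered/normal counts per morphotype and compartment, ploidy-class
fractions among altered cells, and sequencing-outcome tallies. Percentages
are rounded half-away-from-zero to one decimal uniformly.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from rarepc._util import round_half_away

__all__ = [
    "exact_rank_sum_test",
    "permutation_rank_sum_test",
    "percent_altered_by_morphotype",
    "ploidy_distribution",
    "sequencing_outcome_summary",
    "round_half_away",
]

_TIE_EPS = 1e-9


def _rank_setup(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))  # midranks for ties
    n_a, n = a.size, a.size + b.size
    w_obs = ranks[:n_a].sum()
    expected = n_a * (n + 1) / 2.0
    return ranks, n_a, n, abs(w_obs - expected), expected


def exact_rank_sum_test(a, b, max_exact_n: int = 12, seed: int = 0, n_perm: int = 100_000) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value.

    p = Pr(|W - E[W]| >= |w_obs - E[W]|) over all group assignments of the
    midranks. Totals up to `max_exact_n` are fully enumerated; larger
    inputs use seeded permutation sampling. Symmetric in (a, b); p in
    (0, 1].
    """
    ranks, n_a, n, t_obs, expected = _rank_setup(a, b)
    if n > max_exact_n:
        return permutation_rank_sum_test(a, b, n_perm=n_perm, seed=seed)
    hits = 0
    total = comb(n, n_a)
    for combo in combinations(range(n), n_a):
        w = ranks[list(combo)].sum()
        if abs(w - expected) >= t_obs - _TIE_EPS:
            hits += 1
    return hits / total


def permutation_rank_sum_test(a, b, n_perm: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo version of the same two-sided rank-sum tail probability.

    Includes the observed assignment in the tally, so p > 0 always.
    """
    ranks, n_a, n, t_obs, expected = _rank_setup(a, b)
    rng = np.random.default_rng(seed)
    hits = 1  # observed assignment
    for _ in range(n_perm):
        w = ranks[rng.permutation(n)[:n_a]].sum()
        if abs(w - expected) >= t_obs - _TIE_EPS:
            hits += 1
    return hits / (n_perm + 1)


UNJOINED = "unjoined"


def percent_altered_by_morphotype(
    classifications: pd.DataFrame,
    profiles: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Altered / sequenced counts per morphotype x compartment, with percents.

    `profiles` needs cell_id + altered (bool); `classifications` needs
    cell_id + subtype; `meta` (cell_id, compartment) is optional —
    without it all cells fall in one "all" compartment. Sequenced cells
    lacking a classification are reported under an "unjoined" morphotype
    rather than dropped. normal + altered counts partition the sequenced
    cells in every row.
    """
    df = profiles[["cell_id", "altered"]].copy()
    df = df.merge(classifications[["cell_id", "subtype"]], on="cell_id", how="left")
    df["subtype"] = df["subtype"].fillna(UNJOINED)
    if meta is not None:
        df = df.merge(meta[["cell_id", "compartment"]], on="cell_id", how="left")
        df["compartment"] = df["compartment"].fillna("all")
    else:
        df["compartment"] = "all"
    grouped = df.groupby(["subtype", "compartment"], sort=True)
    out = grouped["altered"].agg(n_sequenced="size", n_altered="sum").reset_index()
    out["n_normal"] = out["n_sequenced"] - out["n_altered"]
    out["percent_altered"] = round_half_away(
        100.0 * out["n_altered"].to_numpy() / out["n_sequenced"].to_numpy(), 1
    )
    return out.rename(columns={"subtype": "morphotype"})


def ploidy_distribution(profiles: pd.DataFrame, group_cols=None) -> pd.DataFrame:
    """Ploidy-class fractions among altered cells, per group.

    `profiles` needs cell_id, altered, baseline_ploidy plus any grouping
    columns. Percentages are rounded half-away-from-zero to one decimal and
    sum to 100 within each group up to rounding.
    """
    altered = profiles[profiles["altered"].astype(bool)].copy()
    if group_cols is None:
        group_cols = []
    group_cols = list(group_cols)
    if altered.empty:
        return pd.DataFrame(columns=group_cols + ["baseline_ploidy", "n_cells", "percent"])
    keys = group_cols + ["baseline_ploidy"]
    counts = altered.groupby(keys, sort=True).size().rename("n_cells").reset_index()
    if group_cols:
        totals = counts.groupby(group_cols)["n_cells"].transform("sum")
    else:
        totals = counts["n_cells"].sum()
    counts["percent"] = round_half_away(100.0 * counts["n_cells"] / totals, 1)
    return counts


def sequencing_outcome_summary(
    meta: pd.DataFrame, profiles: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Sequenced and altered cell tallies per sample and per diagnosis group.

    `meta` maps cell_id to patient_id, compartment and (optionally)
    diagnosis. Diagnosis-group and cohort totals equal the sums of the
    per-sample counts.
    """
    df = profiles[["cell_id", "altered"]].merge(meta, on="cell_id", how="left")
    by_sample = (
        df.groupby(["patient_id", "compartment"], sort=True, dropna=False)["altered"]
        .agg(n_sequenced="size", n_altered="sum")
        .reset_index()
    )
    if "diagnosis" in meta.columns:
        by_diagnosis = (
            df.groupby("diagnosis", sort=True, dropna=False)["altered"]
            .agg(n_sequenced="size", n_altered="sum")
            .reset_index()
        )
    else:
        by_diagnosis = pd.DataFrame(columns=["diagnosis", "n_sequenced", "n_altered"])
    total = pd.DataFrame(
        {"n_sequenced": [len(df)], "n_altered": [int(df["altered"].sum())]}
    )
    return {"by_sample": by_sample, "by_diagnosis": by_diagnosis, "total": total}
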