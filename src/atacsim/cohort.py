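"""Cohort-level statistics: every sample pair, with and without co-zeros.

For a cohort of samples on a common bin grid, the suite (default panel:
Spearman, Pearson, R^2 and NMI) is computed between every unordered pair
under both co-zero policies. Pairs sharing an experiment identifier are
*replicates*; all other pairs are *non-replicates*. Two questions are then
asked: does removing co-zeros shift the paired values (Wilcoxon signed-rank
against a Bonferroni-adjusted alpha), and does removal widen the gap
between the mean replicate and mean non-replicate values?
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .binning import WfpkmTrack
from .errors import LayoutMismatchError, ValidationError
from .metrics import compute_statistic, make_bivariate

#: the default cohort panel used on real-data comparisons
DEFAULT_COHORT_STATISTICS = ("spearman_rho", "pearson_r", "r_squared", "nmi")

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PairedEffectResult:
    statistic: str
    group: str
    p_value: float
    mean_change: float
    mean_gap_change: float | None
    alpha_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha_adjusted


def bonferroni_alpha(
    n_statistic_tests: int, n_assays: int, alpha: float = DEFAULT_ALPHA
) -> float:
    """Adjusted alpha = alpha / (number of statistic tests x number of assays)."""
    if n_statistic_tests < 1 or n_assays < 1:
        raise ValidationError("comparison counts must be >= 1")
    return alpha / (n_statistic_tests * n_assays)


def pairwise_statistic_table(
    tracks: Mapping[str, WfpkmTrack],
    sheet: pd.DataFrame,
    statistics: Sequence[str] = DEFAULT_COHORT_STATISTICS,
) -> pd.DataFrame:
    """Statistic values for all unordered sample pairs x statistics x policies.

    ``sheet`` must carry columns ``sample`` and ``experiment_id``; two
    samples with the same experiment id are labelled ``replicate``,
    otherwise ``non_replicate``. Returns a tidy frame with columns
    (sample_a, sample_b, relationship, statistic, policy, value).
    """
    if len(tracks) < 2:
        raise ValidationError("cohort needs at least 2 samples")
    for col in ("sample", "experiment_id"):
        if col not in sheet.columns:
            raise ValidationError(f"sample sheet missing column {col!r}")
    exp_of = dict(zip(sheet["sample"], sheet["experiment_id"]))
    missing = [s for s in tracks if s not in exp_of]
    if missing:
        raise ValidationError(f"samples missing from sheet: {missing}")
    grids = {t.grid for t in tracks.values()}
    if len(grids) > 1:
        raise LayoutMismatchError("cohort tracks are on different bin grids")

    rows = []
    for a, b in combinations(sorted(tracks), 2):
        relationship = "replicate" if exp_of[a] == exp_of[b] else "non_replicate"
        for drop in (False, True):
            pair = make_bivariate(tracks[a], tracks[b], drop_cozeros=drop)
            for name in statistics:
                res = compute_statistic(name, pair)
                rows.append((a, b, relationship, name, res.cozero_policy, res.value))
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "relationship", "statistic", "policy", "value"]
    )


def _paired_values(table: pd.DataFrame, statistic: str, group: str) -> tuple[np.ndarray, np.ndarray]:
    sub = table[table["statistic"] == statistic]
    if group == "replicates":
        sub = sub[sub["relationship"] == "replicate"]
    elif group == "non_replicates":
        sub = sub[sub["relationship"] == "non_replicate"]
    elif group != "all":
        raise ValueError(f"unknown group {group!r}")
    wide = sub.pivot_table(
        index=["sample_a", "sample_b"], columns="policy", values="value"
    )
    if wide.empty or "retained" not in wide or "removed" not in wide:
        raise ValidationError(f"no paired observations for {statistic}/{group}")
    return wide["retained"].to_numpy(), wide["removed"].to_numpy()


def cozero_effect_test(
    table: pd.DataFrame,
    group: str = "all",
    *,
    statistic: str | None = None,
    n_statistic_tests: int = 12,
    n_assays: int = 3,
    alpha: float = DEFAULT_ALPHA,
) -> list[PairedEffectResult]:
    """Two-sided Wilcoxon signed-rank of retained-vs-removed paired values.

    One result per statistic (or the single named statistic). All paired
    differences exactly zero is a degenerate test and is reported with
    p = 1 by convention. Significance is judged against
    ``alpha / (n_statistic_tests * n_assays)``.
    """
    alpha_adj = bonferroni_alpha(n_statistic_tests, n_assays, alpha)
    stats = [statistic] if statistic else sorted(table["statistic"].unique())
    results = []
    for name in stats:
        retained, removed = _paired_values(table, name, group)
        diffs = removed - retained
        if np.all(diffs == 0):
            p = 1.0
        else:
            p = float(sps.wilcoxon(retained, removed).pvalue)
        gap_change = None
        if group == "all" and {"replicate", "non_replicate"} <= set(table["relationship"]):
            gaps = replicate_vs_nonreplicate_gap(table)
            sub = gaps[gaps["statistic"] == name]
            gap_change = float(
                sub.loc[sub["policy"] == "removed", "gap"].iloc[0]
                - sub.loc[sub["policy"] == "retained", "gap"].iloc[0]
            )
        results.append(
            PairedEffectResult(name, group, p, float(diffs.mean()), gap_change, alpha_adj)
        )
    return results


def replicate_vs_nonreplicate_gap(table: pd.DataFrame) -> pd.DataFrame:
    """Mean replicate value minus mean non-replicate value, per statistic/policy."""
    for rel in ("replicate", "non_replicate"):
        if rel not in set(table["relationship"]):
            raise ValidationError(f"no {rel} pairs in cohort table")
    means = (
        table.groupby(["statistic", "policy", "relationship"])["value"]
        .mean()
        .unstack("relationship")
    )
    gaps = (means["replicate"] - means["non_replicate"]).rename("gap").reset_index()
    return gaps
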