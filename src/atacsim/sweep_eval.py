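"""Curves, normalized AUCs and resampling tests over sweep outputs.

Each simulation yields, per statistic and co-zero policy, a curve of the
statistic value against the designed shared-peak fraction. Its summary is
the trapezoidal area under that curve divided by the span of the fraction
grid (*normalized AUC*), so a constant curve at c scores exactly c and the
identity curve scores the grid midpoint. Mean AUCs across simulations get
percentile bootstrap confidence intervals; differences of mean AUC are
tested with label-permutation tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class StatisticCurve:
    statistic: str
    cozero_policy: str
    x: np.ndarray
    y: np.ndarray
    auc: float


@dataclass(frozen=True)
class AucSummary:
    statistic: str
    policy: str
    mean_auc: float
    ci_low: float
    ci_high: float
    n_simulations: int


@dataclass(frozen=True)
class PermutationResult:
    observed_diff: float
    p_value: float
    n_permutations: int


def statistic_curve_auc(
    x: Sequence[float],
    y: Sequence[float],
    *,
    statistic: str = "",
    cozero_policy: str = "",
) -> StatisticCurve:
    """Normalized AUC: trapezoidal integral of y over x divided by the x span.

    Points are sorted ascending in x before integration regardless of the
    sweep's execution order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValidationError("x and y differ in length")
    if len(x) < 2:
        raise ValidationError("need at least 2 points to integrate")
    order = np.argsort(x)
    x, y = x[order], y[order]
    span = x[-1] - x[0]
    if span <= 0:
        raise ValidationError("degenerate x span")
    auc = float(np.trapezoid(y, x) / span)
    return StatisticCurve(statistic, cozero_policy, x, y, auc)


def mean_auc_bootstrap_ci(
    aucs: Sequence[float], n_boot: int = 1000, seed: int | None = None,
    *, statistic: str = "", policy: str = "",
) -> AucSummary:
    """Mean AUC with a 95% percentile bootstrap CI (resamples of the same size)."""
    aucs = np.asarray(aucs, dtype=float)
    if len(aucs) == 0:
        raise ValidationError("no AUC values")
    rng = np.random.default_rng(seed)
    means = rng.choice(aucs, size=(n_boot, len(aucs)), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return AucSummary(statistic, policy, float(aucs.mean()), float(lo), float(hi), len(aucs))


def mean_auc_permutation_test(
    aucs_a: Sequence[float],
    aucs_b: Sequence[float],
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    plus_one: bool = False,
) -> PermutationResult:
    """Two-sided permutation test of the difference in mean AUC.

    Group labels are pooled and reshuffled ``n_perm`` times; the p-value is
    the proportion of permuted |mean difference| >= the observed |mean
    difference|, reported as an exact proportion (0 is possible). The
    ``plus_one`` flag applies the (k+1)/(n+1) correction instead.
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    observed = a.mean() - b.mean()
    # canonical pooled order and split size make the p-value exactly
    # invariant under swapping the two groups
    pooled = np.sort(np.concatenate([a, b]))
    n_small = min(len(a), len(b))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        diff = perm[:n_small].mean() - perm[n_small:].mean()
        if abs(diff) >= abs(observed):
            count += 1
    if plus_one:
        p = (count + 1) / (n_perm + 1)
    else:
        p = count / n_perm
    return PermutationResult(float(observed), float(p), n_perm)


def per_simulation_aucs(sweep: pd.DataFrame) -> pd.DataFrame:
    """Collapse a tidy sweep table to one normalized AUC per
    (parent, repeat, statistic, policy)."""
    required = {"parent", "repeat", "fraction", "statistic", "policy", "value"}
    missing = required - set(sweep.columns)
    if missing:
        raise ValidationError(f"sweep table missing columns {sorted(missing)}")
    rows = []
    for (parent, repeat, stat, policy), grp in sweep.groupby(
        ["parent", "repeat", "statistic", "policy"], sort=False
    ):
        curve = statistic_curve_auc(
            grp["fraction"].to_numpy(), grp["value"].to_numpy(),
            statistic=stat, cozero_policy=policy,
        )
        rows.append((parent, repeat, stat, policy, curve.auc))
    return pd.DataFrame(rows, columns=["parent", "repeat", "statistic", "policy", "auc"])


def summarize_simulation_set(
    sweep: pd.DataFrame,
    *,
    n_boot: int = 1000,
    n_perm: int = 1000,
    seed: int | None = None,
    between_statistics: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(statistic, policy) mean-AUC summaries plus permutation tests.

    Returns ``(summaries, tests)``:

    * ``summaries`` has one row per statistic and policy with the mean AUC
      and 95% bootstrap CI;
    * ``tests`` holds within-statistic retained-vs-removed permutation
      tests (``kind == 'policy'``) and, optionally, all pairwise
      between-statistic tests within each policy (``kind == 'between'``).
    """
    aucs = per_simulation_aucs(sweep)
    rng = np.random.default_rng(seed)
    summaries = []
    for (stat, policy), grp in aucs.groupby(["statistic", "policy"], sort=False):
        s = mean_auc_bootstrap_ci(
            grp["auc"].to_numpy(), n_boot, int(rng.integers(2**31)),
            statistic=stat, policy=policy,
        )
        summaries.append(
            (stat, policy, s.mean_auc, s.ci_low, s.ci_high, s.n_simulations)
        )
    summary_df = pd.DataFrame(
        summaries,
        columns=["statistic", "policy", "mean_auc", "ci_low", "ci_high", "n_simulations"],
    )

    tests = []
    statistics = summary_df["statistic"].unique()
    for stat in statistics:
        grp = aucs[aucs["statistic"] == stat]
        retained = grp.loc[grp["policy"] == "retained", "auc"].to_numpy()
        removed = grp.loc[grp["policy"] == "removed", "auc"].to_numpy()
        if len(retained) and len(removed):
            res = mean_auc_permutation_test(
                retained, removed, n_perm, int(rng.integers(2**31))
            )
            tests.append(
                ("policy", stat, "retained_vs_removed", res.observed_diff, res.p_value)
            )
    if between_statistics:
        for policy in summary_df["policy"].unique():
            grp = aucs[aucs["policy"] == policy]
            for i, s1 in enumerate(statistics):
                for s2 in statistics[i + 1 :]:
                    a = grp.loc[grp["statistic"] == s1, "auc"].to_numpy()
                    b = grp.loc[grp["statistic"] == s2, "auc"].to_numpy()
                    if len(a) and len(b):
                        res = mean_auc_permutation_test(
                            a, b, n_perm, int(rng.integers(2**31))
                        )
                        tests.append(
                            ("between", f"{s1}_vs_{s2}", policy, res.observed_diff, res.p_value)
                        )
    tests_df = pd.DataFrame(
        tests, columns=["kind", "comparison", "context", "observed_diff", "p_value"]
    )
    return summary_df, tests_df
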