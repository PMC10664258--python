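"""Synthetic-replicate generation by peak-targeted fragment depletion.

A parent sample is duplicated into two synthetic "sister" replicates. A
designed fraction of the reproducible peaks is left untouched in both
copies (the *shared-peak fraction*); each remaining "varied" peak is
assigned to one replicate by fair coin and depleted there by removing a
fixed portion of the fragments overlapping the peak. Sweeping the shared
fraction from 0.99 down to 0.05 produces replicate pairs with a known,
designed amount of disagreement.

Randomness is structured so the sweep axis stays autocorrelated instead of
being resampled at every fraction:

* one fixed random permutation of the peaks is drawn per simulation and
  the varied set at fraction p is its first round((1-p) N) entries, so
  varied sets are *nested* across the grid;
* each fragment carries one removal key per simulation, and a varied peak
  drops the smallest-keyed round(rate * n) of its n overlapping fragments,
  so a peak varied at two fractions loses exactly the same fragments at
  both.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import DEFAULT_BIN_SIZE, make_bins, wfpkm_track
from .errors import ValidationError
from .genomic_io import FragmentSet, Peak, PeakSet
from .metrics import STATISTIC_NAMES, compute_statistic_suite

#: shared-peak fractions: 0.99 then 0.95 down to 0.05 in steps of 0.05
DEFAULT_FRACTION_GRID = (0.99,) + tuple(round(f, 2) for f in np.arange(0.95, 0.04, -0.05))

DEFAULT_DEPLETION_RATE = 0.85
DEPLETION_RATES = (0.50, 0.85, 0.95)


def _round_half_even(x: float) -> int:
    return int(round(x))


@dataclass(frozen=True)
class SweepDesign:
    """Parameters of one shared-peak-fraction sweep."""

    shared_fraction_grid: tuple[float, ...] = DEFAULT_FRACTION_GRID
    depletion_rate: float = DEFAULT_DEPLETION_RATE
    n_repeats: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        grid = self.shared_fraction_grid
        if any(not 0 < f <= 1 for f in grid):
            raise ValidationError("shared fractions must lie in (0, 1]")
        if any(a <= b for a, b in zip(grid, grid[1:])):
            raise ValidationError("shared fraction grid must be strictly decreasing")
        if not 0 < self.depletion_rate < 1:
            raise ValidationError("depletion rate must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")


@dataclass
class VariedPeakPlan:
    """Fixed per-simulation randomness: which peaks vary, and where.

    The varied set at fraction p is the first ``varied_count_by_fraction[p]``
    entries of ``permutation``, so varied sets are nested across the grid.
    """

    permutation: np.ndarray
    per_peak_target: np.ndarray  # replicate label 1 or 2 per peak index
    varied_count_by_fraction: dict[float, int]
    seed_key: tuple[int, int]  # (design seed, repeat index)

    def varied_indices(self, fraction: float) -> np.ndarray:
        k = self.varied_count_by_fraction[fraction]
        return self.permutation[:k]


@dataclass
class ReplicatePair:
    rep1: FragmentSet
    rep2: FragmentSet
    designed_shared_fraction: float
    varied_peaks: list[tuple[int, int, int]]  # (peak index, target replicate, removed)


def plan_varied_peaks(peaks: PeakSet, design: SweepDesign, repeat_index: int) -> VariedPeakPlan:
    """Draw one simulation's peak permutation, targets and varied counts.

    The varied count at fraction p is round-half-even of (1-p) N, with a
    floor of one varied peak whenever (1-p) N > 0 would otherwise round to
    zero (so the 0.99 point always perturbs something on small peak sets).
    """
    n = len(peaks)
    if n == 0:
        raise ValidationError("cannot plan varied peaks on an empty peak set")
    rng = np.random.default_rng((design.seed, repeat_index))
    permutation = rng.permutation(n)
    per_peak_target = rng.integers(1, 3, size=n)
    counts: dict[float, int] = {}
    for p in design.shared_fraction_grid:
        raw = (1.0 - p) * n
        k = _round_half_even(raw)
        if k == 0 and raw > 0:
            k = 1
        counts[p] = min(k, n)
    return VariedPeakPlan(permutation, per_peak_target, counts, (design.seed, repeat_index))


def assign_fragments_to_peaks(frags: FragmentSet, peaks: PeakSet) -> np.ndarray:
    """Peak index per fragment (-1 where no peak overlaps).

    Peaks are disjoint and sorted; a fragment overlapping a peak is
    assigned to the right-most peak whose start precedes the fragment end,
    which for disjoint peaks and short fragments is the (essentially
    always unique) overlapping peak. A fragment can therefore be removed
    at most once even when the varied set is large.
    """
    assigned = np.full(len(frags), -1, dtype=np.int64)
    for ci in range(frags.layout.n_chromosomes):
        on_p = np.nonzero(peaks.chrom_idx == ci)[0]
        if len(on_p) == 0:
            continue
        ps, pe = peaks.start[on_p], peaks.end[on_p]
        on_f = np.nonzero(frags.chrom_idx == ci)[0]
        fs, fe = frags.start[on_f], frags.end[on_f]
        idx = np.searchsorted(ps, fe, side="left") - 1
        valid = idx >= 0
        hit = np.zeros(len(on_f), dtype=bool)
        hit[valid] = pe[idx[valid]] > fs[valid]
        assigned[on_f[hit]] = on_p[idx[hit]]
    return assigned


class _DepletionCache:
    """Per-(parent, repeat) precomputation for the fraction sweep.

    Ranks every fragment within its peak by a per-simulation random key;
    a varied peak removes its ``k_per_peak`` lowest-keyed fragments from
    the peak's target replicate, identically at every fraction.
    """

    def __init__(
        self,
        parent: FragmentSet,
        peaks: PeakSet,
        plan: VariedPeakPlan,
        rate: float,
        assigned: np.ndarray | None = None,
    ) -> None:
        if assigned is None:
            assigned = assign_fragments_to_peaks(parent, peaks)
        self.assigned = assigned
        self.n_peaks = len(peaks)
        rng = np.random.default_rng((*plan.seed_key, 2**20))
        keys = rng.random(len(parent))
        in_peak = assigned >= 0
        self.n_per_peak = np.bincount(assigned[in_peak], minlength=self.n_peaks)
        self.k_per_peak = np.round(rate * self.n_per_peak).astype(np.int64)
        # rank of each in-peak fragment within its peak, ordered by key
        order = np.lexsort((keys, assigned))
        order = order[assigned[order] >= 0]
        group_first = np.concatenate([[0], np.cumsum(self.n_per_peak)[:-1]])
        rank = np.empty(len(parent), dtype=np.int64)
        rank.fill(np.iinfo(np.int64).max)
        rank[order] = np.arange(len(order)) - group_first[assigned[order]]
        # fragment would be removed if its peak were varied
        self.candidate = np.zeros(len(parent), dtype=bool)
        self.candidate[in_peak] = rank[in_peak] < self.k_per_peak[assigned[in_peak]]
        self.target_of_fragment = np.where(
            in_peak, plan.per_peak_target[np.maximum(assigned, 0)], 0
        )
        self.plan = plan

    def removal_masks(self, fraction: float) -> tuple[np.ndarray, np.ndarray]:
        varied = np.zeros(self.n_peaks, dtype=bool)
        varied[self.plan.varied_indices(fraction)] = True
        doomed = self.candidate & varied[np.maximum(self.assigned, 0)] & (self.assigned >= 0)
        return doomed & (self.target_of_fragment == 1), doomed & (self.target_of_fragment == 2)


def deplete_fragments_in_peak(
    frags: FragmentSet, peak: Peak, rate: float, rng: np.random.Generator
) -> FragmentSet:
    """Remove round(rate * n) of the n fragments overlapping a peak.

    Sampling is uniform without replacement; fragments outside the peak
    are untouched. Zero overlapping fragments is a no-op.
    """
    if not 0 < rate < 1:
        raise ValidationError("rate must lie in (0, 1)")
    ci = frags.layout.index(peak.chrom)
    hit = (frags.chrom_idx == ci) & (frags.start < peak.end) & (frags.end > peak.start)
    idx = np.nonzero(hit)[0]
    n = len(idx)
    if n == 0:
        return frags
    n_remove = _round_half_even(rate * n)
    if n_remove == 0:
        return frags
    removed = rng.choice(idx, size=n_remove, replace=False)
    keep = np.ones(len(frags), dtype=bool)
    keep[removed] = False
    return frags.subset(keep)


def generate_replicate_pair(
    parent: FragmentSet,
    peaks: PeakSet,
    plan: VariedPeakPlan,
    fraction: float,
    rate: float,
    *,
    cache: _DepletionCache | None = None,
) -> ReplicatePair:
    """Build the two sister replicates for one shared-peak fraction.

    Both replicates start as exact copies of the parent; each varied peak
    is depleted only in its target replicate by round(rate * n) of its n
    overlapping fragments. Removal draws are fixed per simulation, so the
    same peak loses the same fragments at every fraction where it is
    varied, and fragments outside the varied peaks are identical across
    parent and both replicates.
    """
    if cache is None:
        cache = _DepletionCache(parent, peaks, plan, rate)
    drop1, drop2 = cache.removal_masks(fraction)
    manifest = []
    for peak_idx in np.sort(plan.varied_indices(fraction)):
        target = int(plan.per_peak_target[peak_idx])
        manifest.append((int(peak_idx), target, int(cache.k_per_peak[peak_idx])))
    return ReplicatePair(
        parent.subset(~drop1),
        parent.subset(~drop2),
        fraction,
        manifest,
    )


def run_shared_fraction_sweep(
    parent: FragmentSet,
    peaks: PeakSet,
    design: SweepDesign,
    *,
    bin_size: int = DEFAULT_BIN_SIZE,
    statistics: Sequence[str] = STATISTIC_NAMES,
    parent_label: str = "parent",
) -> pd.DataFrame:
    """Run the full sweep: per repeat and fraction, build the replicate
    pair, bin both at ``bin_size``, and compute the statistic suite under
    both co-zero policies.

    Returns a tidy DataFrame with columns
    (parent, repeat, fraction, statistic, policy, value, n_points),
    bit-reproducible from ``design.seed``.
    """
    grid = make_bins(parent.layout, bin_size)
    assigned = assign_fragments_to_peaks(parent, peaks)
    rows: list[tuple] = []
    for repeat in range(design.n_repeats):
        plan = plan_varied_peaks(peaks, design, repeat)
        cache = _DepletionCache(parent, peaks, plan, design.depletion_rate, assigned)
        for fraction in design.shared_fraction_grid:
            drop1, drop2 = cache.removal_masks(fraction)
            t1 = wfpkm_track(parent.subset(~drop1), grid)
            t2 = wfpkm_track(parent.subset(~drop2), grid)
            for res in compute_statistic_suite(t1, t2, statistics):
                rows.append(
                    (
                        parent_label,
                        repeat,
                        fraction,
                        res.name,
                        res.cozero_policy,
                        res.value,
                        res.n_points,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["parent", "repeat", "fraction", "statistic", "policy", "value", "n_points"],
    )
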