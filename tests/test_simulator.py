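import numpy as np
import pytest

from atacsim import (
    SweepDesign,
    ValidationError,
    deplete_fragments_in_peak,
    generate_replicate_pair,
    plan_varied_peaks,
    run_shared_fraction_sweep,
)
from atacsim.genomic_io import GenomeLayout, Peak
from atacsim.simulator import DEFAULT_FRACTION_GRID, assign_fragments_to_peaks

from conftest import make_fragments, make_peaks


@pytest.fixture
def design():
    return SweepDesign(seed=3, n_repeats=2)


class TestSweepDesign:
    def test_default_grid_has_twenty_points(self):
        assert len(DEFAULT_FRACTION_GRID) == 20
        assert DEFAULT_FRACTION_GRID[0] == 0.99
        assert DEFAULT_FRACTION_GRID[-1] == 0.05

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"shared_fraction_grid": (0.5, 0.9)},   # not decreasing
            {"depletion_rate": 1.0},
            {"n_repeats": 0},
        ],
    )
    def test_invalid_designs_raise(self, kwargs):
        with pytest.raises(ValidationError):
            SweepDesign(**kwargs)


class TestPlan:
    def test_varied_counts_round_half_even(self, small_layout, design):
        peaks = make_peaks(small_layout, [("chr1", i * 100, i * 100 + 50) for i in range(200)])
        plan = plan_varied_peaks(peaks, design, 0)
        assert plan.varied_count_by_fraction[0.95] == 10  # round(0.05*200)
        assert plan.varied_count_by_fraction[0.05] == 190

    def test_floor_of_one_varied_peak(self, small_layout, design):
        # (1-0.99)*50 = 0.5 rounds to 0 under banker's rounding; floored to 1
        peaks = make_peaks(small_layout, [("chr1", i * 100, i * 100 + 50) for i in range(50)])
        plan = plan_varied_peaks(peaks, design, 0)
        assert plan.varied_count_by_fraction[0.99] == 1

    def test_nested_across_grid(self, small_layout, design):
        peaks = make_peaks(small_layout, [("chr1", i * 100, i * 100 + 50) for i in range(200)])
        plan = plan_varied_peaks(peaks, design, 0)
        previous = set()
        for frac in design.shared_fraction_grid:
            varied = set(plan.varied_indices(frac).tolist())
            assert previous <= varied
            previous = varied

    def test_targets_are_both_replicates(self, small_layout, design):
        peaks = make_peaks(small_layout, [("chr1", i * 100, i * 100 + 50) for i in range(200)])
        plan = plan_varied_peaks(peaks, design, 0)
        assert set(np.unique(plan.per_peak_target)) == {1, 2}

    def test_empty_peaks_raise(self, small_layout, design):
        with pytest.raises(ValidationError):
            plan_varied_peaks(make_peaks(small_layout, []), design, 0)


class TestDepletion:
    def test_removal_count_round_half_even(self, small_layout):
        frags = make_fragments(small_layout, [("chr1", 1000 + i, 1100 + i) for i in range(7)])
        peak = Peak("chr1", 900, 1300)
        out = deplete_fragments_in_peak(frags, peak, 0.5, np.random.default_rng(0))
        assert out.library_size == 3  # round(0.5*7) = 4 removed

    def test_85_percent_removal(self, small_layout):
        frags = make_fragments(small_layout, [("chr1", 1000, 1100)] * 100)
        out = deplete_fragments_in_peak(frags, Peak("chr1", 900, 1300), 0.85,
                                        np.random.default_rng(0))
        assert out.library_size == 15

    def test_no_overlap_is_noop(self, small_layout):
        frags = make_fragments(small_layout, [("chr1", 10, 60)])
        out = deplete_fragments_in_peak(frags, Peak("chr1", 900, 1300), 0.85,
                                        np.random.default_rng(0))
        assert out.library_size == 1


class TestReplicatePair:
    @pytest.fixture
    def setting(self, small_layout):
        rng = np.random.default_rng(9)
        starts = rng.integers(0, 99_000, 2_000)
        frags = make_fragments(small_layout, [("chr1", int(s), int(s) + 100) for s in starts])
        peaks = make_peaks(
            small_layout, [("chr1", p, p + 400) for p in range(0, 100_000, 2_000)]
        )
        return frags, peaks

    def test_fraction_one_yields_identical_copies(self, setting, small_layout):
        frags, peaks = setting
        design = SweepDesign(shared_fraction_grid=(1.0,), seed=1)
        plan = plan_varied_peaks(peaks, design, 0)
        pair = generate_replicate_pair(frags, peaks, plan, 1.0, 0.85)
        assert pair.rep1.library_size == pair.rep2.library_size == frags.library_size

    def test_conservation_outside_varied_peaks(self, setting):
        frags, peaks = setting
        design = SweepDesign(seed=1)
        plan = plan_varied_peaks(peaks, design, 0)
        pair = generate_replicate_pair(frags, peaks, plan, 0.50, 0.85)
        varied = plan.varied_indices(0.50)
        assigned = assign_fragments_to_peaks(frags, peaks)
        outside = ~np.isin(assigned, varied)
        for rep in (pair.rep1, pair.rep2):
            rep_keys = set(zip(rep.chrom_idx, rep.start, rep.end))
            parent_outside = list(
                zip(frags.chrom_idx[outside], frags.start[outside], frags.end[outside])
            )
            assert all(k in rep_keys for k in parent_outside)

    def test_each_varied_peak_depleted_in_exactly_one_replicate(self, setting):
        frags, peaks = setting
        design = SweepDesign(seed=1)
        plan = plan_varied_peaks(peaks, design, 0)
        pair = generate_replicate_pair(frags, peaks, plan, 0.50, 0.85)
        assigned = assign_fragments_to_peaks(frags, peaks)
        n_parent = np.bincount(assigned[assigned >= 0], minlength=len(peaks))

        def peak_counts(rep):
            a = assign_fragments_to_peaks(rep, peaks)
            return np.bincount(a[a >= 0], minlength=len(peaks))

        n1, n2 = peak_counts(pair.rep1), peak_counts(pair.rep2)
        for peak_idx, target, removed in pair.varied_peaks:
            assert removed == round(0.85 * n_parent[peak_idx])
            depleted, untouched = (n1, n2) if target == 1 else (n2, n1)
            assert depleted[peak_idx] == n_parent[peak_idx] - removed
            assert untouched[peak_idx] == n_parent[peak_idx]

    def test_total_removed_matches_disjoint_peak_sum(self, setting):
        frags, peaks = setting
        design = SweepDesign(seed=1)
        plan = plan_varied_peaks(peaks, design, 0)
        pair = generate_replicate_pair(frags, peaks, plan, 0.25, 0.85)
        removed_total = sum(r for _, _, r in pair.varied_peaks)
        assert (
            2 * frags.library_size - pair.rep1.library_size - pair.rep2.library_size
            == removed_total
        )

    def test_library_size_monotone_in_perturbation(self, setting):
        frags, peaks = setting
        design = SweepDesign(seed=1)
        plan = plan_varied_peaks(peaks, design, 0)
        sizes = []
        for frac in design.shared_fraction_grid:
            pair = generate_replicate_pair(frags, peaks, plan, frac, 0.85)
            sizes.append(pair.rep1.library_size + pair.rep2.library_size)
        assert sizes == sorted(sizes, reverse=True)

    def test_same_peak_loses_same_fragments_across_fractions(self, setting):
        frags, peaks = setting
        design = SweepDesign(seed=1)
        plan = plan_varied_peaks(peaks, design, 0)
        p95 = generate_replicate_pair(frags, peaks, plan, 0.95, 0.85)
        p50 = generate_replicate_pair(frags, peaks, plan, 0.50, 0.85)
        k95 = set(zip(p95.rep1.chrom_idx, p95.rep1.start, p95.rep1.end))
        k50 = set(zip(p50.rep1.chrom_idx, p50.rep1.start, p50.rep1.end))
        # everything removed at 0.95 is also removed at 0.50 (nested damage)
        assert k50 <= k95


class TestSweep:
    def test_deterministic_and_complete(self, toy_parent):
        frags, peaks, layout = toy_parent
        design = SweepDesign(
            shared_fraction_grid=(0.99, 0.5, 0.05), n_repeats=2, seed=5
        )
        df1 = run_shared_fraction_sweep(frags, peaks, design, statistics=("pearson_r", "nmi"))
        df2 = run_shared_fraction_sweep(frags, peaks, design, statistics=("pearson_r", "nmi"))
        assert df1.equals(df2)
        # repeats x fractions x statistics x policies
        assert len(df1) == 2 * 3 * 2 * 2

    def test_statistics_decline_with_shared_fraction(self, toy_parent):
        frags, peaks, layout = toy_parent
        design = SweepDesign(
            shared_fraction_grid=(0.99, 0.05), n_repeats=2, seed=5
        )
        df = run_shared_fraction_sweep(frags, peaks, design, statistics=("pearson_r",))
        means = df.groupby("fraction")["value"].mean()
        assert means[0.99] > means[0.05]
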