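import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from atacsim import (
    UndefinedStatisticError,
    ValidationError,
    compute_statistic_suite,
    kendall_tau,
    kendall_w,
    make_bivariate,
    normalized_mutual_information,
    pearson_r,
    r_squared,
    savage_scores,
    spearman_rho,
    topdown_correlation,
)
from atacsim.metrics import kendall_w_pair


def pair_of(x, y, drop=False):
    return make_bivariate(np.asarray(x), np.asarray(y), drop_cozeros=drop)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_tau_b(x, y):
    """Exhaustive O(n^2) concordant/discordant pair count with tie terms."""
    n = len(x)
    conc = disc = 0
    for i, j in itertools.combinations(range(n), 2):
        s = (x[i] - x[j]) * (y[i] - y[j])
        if s > 0:
            conc += 1
        elif s < 0:
            disc += 1
    n0 = n * (n - 1) / 2
    n1 = sum(t * (t - 1) / 2 for t in np.unique(x, return_counts=True)[1])
    n2 = sum(t * (t - 1) / 2 for t in np.unique(y, return_counts=True)[1])
    denom = math.sqrt((n0 - n1) * (n0 - n2))
    if denom == 0:
        return None
    return (conc - disc) / denom


def brute_force_nmi(x, y):
    """Contingency-table NMI, arithmetic normalization, natural log."""
    n = len(x)
    pxy = {}
    for a, b in zip(x, y):
        pxy[(a, b)] = pxy.get((a, b), 0) + 1 / n
    px, py = {}, {}
    for (a, b), p in pxy.items():
        px[a] = px.get(a, 0) + p
        py[b] = py.get(b, 0) + p
    mi = sum(p * math.log(p / (px[a] * py[b])) for (a, b), p in pxy.items())
    hx = -sum(p * math.log(p) for p in px.values())
    hy = -sum(p * math.log(p) for p in py.values())
    if hx == 0 and hy == 0:
        return 1.0
    if hx == 0 or hy == 0:
        return 0.0
    return min(1.0, max(0.0, mi / ((hx + hy) / 2)))


def oracle_savage(values):
    """Savage scores from first principles: tie-averaged harmonic tails,
    rank 1 = largest value."""
    n = len(values)
    base = [sum(1.0 / j for j in range(i, n + 1)) for i in range(1, n + 1)]
    order = np.argsort(-np.asarray(values), kind="stable")
    out = np.empty(n)
    i = 0
    ranked = np.asarray(values)[order]
    while i < n:
        j = i
        while j < n and ranked[j] == ranked[i]:
            j += 1
        avg = float(np.mean(base[i:j]))
        for k in range(i, j):
            out[order[k]] = avg
        i = j
    return out


# ---------------------------------------------------------------------------
# co-zero masking
# ---------------------------------------------------------------------------


class TestMakeBivariate:
    def test_mask_and_removal(self):
        pair = pair_of([0, 3, 0, 2], [0, 0, 5, 1], drop=True)
        assert pair.n_points == 3
        assert list(pair.x) == [3, 0, 2]
        assert list(pair.y) == [0, 5, 1]
        assert pair.cozero_fraction == 0.25

    def test_no_cozeros_is_noop(self):
        pair = pair_of([0, 3], [1, 0], drop=True)
        assert pair.n_points == 2

    def test_all_cozero_raises(self):
        with pytest.raises(ValidationError):
            pair_of([0, 0], [0, 0], drop=True)


# ---------------------------------------------------------------------------
# worked examples, frozen from the oracles above
# ---------------------------------------------------------------------------


class TestWorkedExamples:
    def test_pearson_hand_computed(self):
        # x=[1,2,3,4], y=[2,1,4,3]: sum dx*dy = 3, sum dx^2 = sum dy^2 = 5
        assert pearson_r(pair_of([1, 2, 3, 4], [2, 1, 4, 3])).value == pytest.approx(0.6)

    def test_pearson_perfect_lines(self):
        x = np.array([1, 4, 2, 7])
        assert pearson_r(pair_of(x, x)).value == pytest.approx(1.0)
        assert pearson_r(pair_of(x, -x + 10)).value == pytest.approx(-1.0)

    def test_r_squared_is_square(self):
        v = r_squared(pair_of([1, 2, 3, 4], [2, 1, 4, 3])).value
        assert v == pytest.approx(0.36)

    def test_spearman_equals_pearson_on_midranks(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        expected = sps.pearsonr(
            sps.rankdata(x, method="average"), sps.rankdata(y, method="average")
        ).statistic
        assert spearman_rho(pair_of(x, y)).value == pytest.approx(expected)
        assert expected == pytest.approx(0.9486832980505138)

    def test_kendall_tau_hand_computed(self):
        # 4 concordant, 2 discordant of 6 pairs, no ties
        assert kendall_tau(pair_of([1, 2, 3, 4], [2, 1, 4, 3])).value == pytest.approx(1 / 3)
        assert kendall_tau(pair_of([1, 2, 3], [3, 2, 1])).value == pytest.approx(-1.0)

    def test_savage_scores_n3(self):
        np.testing.assert_allclose(
            savage_scores(np.array([1.0, 2.0, 3.0])), [11 / 6, 5 / 6, 1 / 3]
        )

    def test_savage_tie_averaging_and_conservation(self):
        scores = savage_scores(np.array([1.5, 1.5, 3.0]))
        np.testing.assert_allclose(scores, [4 / 3, 4 / 3, 1 / 3])
        assert scores.sum() == pytest.approx(3.0)

    def test_topdown_reversal(self):
        assert topdown_correlation(pair_of([1, 2, 3], [3, 2, 1])).value == pytest.approx(-13 / 14)

    def test_topdown_identity_untied(self):
        x = [5, 1, 9, 3, 7]
        assert topdown_correlation(pair_of(x, x)).value == pytest.approx(1.0)

    def test_kendall_w_extremes(self):
        assert kendall_w([np.array([1, 2, 3, 4]), np.array([1, 2, 3, 4])]) == pytest.approx(1.0)
        assert kendall_w([np.array([1, 2, 3, 4]), np.array([4, 3, 2, 1])]) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [1, 2, 3, 4], 1.0),      # identical partitions
            ([0, 0, 1, 1], [1, 1, 0, 0], 1.0),       # identical up to relabeling
            ([0, 1, 0, 1], [0, 0, 1, 1], 0.0),       # uniform joint, no information
        ],
    )
    def test_nmi_examples(self, x, y, expected):
        assert normalized_mutual_information(pair_of(x, y)).value == pytest.approx(expected)

    def test_nmi_degenerate_constant_vectors(self):
        assert normalized_mutual_information(pair_of([2, 2], [2, 2])).value == 1.0
        assert normalized_mutual_information(pair_of([2, 2], [1, 3])).value == 0.0


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    def test_tau_matches_brute_force_exhaustive_small(self):
        """Exhaustive over all ordered label-vector pairs of length 4."""
        for x in itertools.product(range(3), repeat=4):
            xa = np.array(x)
            if len(set(x)) == 1:
                continue
            for y in itertools.product(range(3), repeat=4):
                if len(set(y)) == 1:
                    continue
                expected = brute_force_tau_b(x, y)
                got = kendall_tau(pair_of(xa, np.array(y))).value
                assert got == pytest.approx(expected, abs=1e-12)

    def test_tau_matches_brute_force_random_longer(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = rng.integers(5, 9)
            x = rng.integers(0, 3, n)
            y = rng.integers(0, 3, n)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            assert kendall_tau(pair_of(x, y)).value == pytest.approx(
                brute_force_tau_b(x, y), abs=1e-12
            )

    def test_savage_matches_first_principles(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            v = rng.integers(0, 5, rng.integers(2, 12))
            ranks = sps.rankdata(-v, method="average")
            np.testing.assert_allclose(savage_scores(ranks), oracle_savage(v))

    def test_topdown_matches_pearson_on_savage_untied(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            x = rng.permutation(n) + rng.random(n) * 0  # untied integers
            y = rng.permutation(n)
            expected = sps.pearsonr(oracle_savage(x), oracle_savage(y)).statistic
            assert topdown_correlation(pair_of(x, y)).value == pytest.approx(
                expected, abs=1e-10
            )

    def test_nmi_matches_contingency_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(2, 20))
            x = rng.integers(0, 4, n)
            y = rng.integers(0, 4, n)
            got = normalized_mutual_information(pair_of(x, y)).value
            assert got == pytest.approx(brute_force_nmi(x, y), abs=1e-9)

    def test_kendall_w_spearman_identity_untied(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = rng.permutation(n)
            y = rng.permutation(n)
            rho = spearman_rho(pair_of(x, y)).value
            assert kendall_w([x, y]) == pytest.approx((rho + 1) / 2, abs=1e-12)

    def test_r_squared_equals_pearson_squared(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            x = rng.integers(0, 10, 30)
            y = rng.integers(0, 10, 30)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            pair = pair_of(x, y)
            assert r_squared(pair).value == pytest.approx(
                pearson_r(pair).value ** 2, abs=1e-12
            )


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


vectors = st.lists(st.integers(0, 5), min_size=4, max_size=30)


@st.composite
def nonconstant_pairs(draw):
    n = draw(st.integers(4, 25))
    x = draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
    y = draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
    if len(set(x)) == 1 or len(set(y)) == 1:
        x = list(x)
        x[0] = x[0] + 1
        y = list(y)
        y[-1] = y[-1] + 1
    return np.array(x), np.array(y)


class TestInvariants:
    @settings(max_examples=60, deadline=None)
    @given(nonconstant_pairs())
    def test_symmetry(self, xy):
        x, y = xy
        for fn in (pearson_r, spearman_rho, kendall_tau, topdown_correlation,
                   r_squared, kendall_w_pair, normalized_mutual_information):
            assert fn(pair_of(x, y)).value == pytest.approx(
                fn(pair_of(y, x)).value, abs=1e-10
            )

    @settings(max_examples=60, deadline=None)
    @given(nonconstant_pairs())
    def test_rank_statistics_invariant_under_monotone_transform(self, xy):
        x, y = xy
        tx = 3 ** x.astype(float)  # strictly increasing transform
        for fn in (spearman_rho, kendall_tau, topdown_correlation):
            assert fn(pair_of(x, y)).value == pytest.approx(
                fn(pair_of(tx, y)).value, abs=1e-9
            )
        # NMI under an injective relabeling
        relabel = np.array([7, 3, 9, 0, 5, 1])
        assert normalized_mutual_information(pair_of(x, y)).value == pytest.approx(
            normalized_mutual_information(pair_of(relabel[x], y)).value, abs=1e-9
        )

    @settings(max_examples=60, deadline=None)
    @given(nonconstant_pairs())
    def test_bounds_and_mi_inequality(self, xy):
        x, y = xy
        for fn, lo in ((pearson_r, -1), (spearman_rho, -1), (kendall_tau, -1),
                       (r_squared, 0), (kendall_w_pair, 0),
                       (normalized_mutual_information, 0)):
            v = fn(pair_of(x, y)).value
            assert lo - 1e-12 <= v <= 1 + 1e-12
        # I(X;Y) <= min(H(X), H(Y))
        n = len(x)
        hx = sps.entropy(np.unique(x, return_counts=True)[1] / n)
        hy = sps.entropy(np.unique(y, return_counts=True)[1] / n)
        nmi = normalized_mutual_information(pair_of(x, y)).value
        assert nmi * (hx + hy) / 2 <= min(hx, hy) + 1e-9

    def test_savage_scores_sum_to_n(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            v = rng.integers(0, 4, int(rng.integers(2, 40)))
            ranks = sps.rankdata(-v, method="average")
            assert savage_scores(ranks).sum() == pytest.approx(len(v))


class TestSuite:
    def test_identical_tracks_all_ones(self):
        x = np.array([0, 1, 0, 5, 2, 1])
        results = compute_statistic_suite(x, x.copy())
        assert len(results) == 14
        for res in results:
            if res.name == "topdown":
                continue  # tie-heavy self-correlation < 1 under the raw form
            assert res.value == pytest.approx(1.0), res.name

    def test_no_cozero_input_same_under_both_policies(self):
        x = np.array([1, 2, 3, 1, 4])
        y = np.array([2, 1, 3, 4, 1])
        results = compute_statistic_suite(x, y)
        by_name = {}
        for res in results:
            by_name.setdefault(res.name, []).append(res.value)
        for name, (a, b) in by_name.items():
            assert a == pytest.approx(b), name

    def test_zero_variance_raises_typed_error(self):
        const = np.array([3, 3, 3])
        varying = np.array([1, 2, 3])
        for fn in (pearson_r, spearman_rho, kendall_tau, topdown_correlation):
            with pytest.raises(UndefinedStatisticError):
                fn(pair_of(const, varying))
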