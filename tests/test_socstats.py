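import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emosim.config import default_doms
from emosim.socstats import (
    fisher_z_mean,
    mean_group_evenness,
    partner_specificity_sd,
    rank_distance_categorize,
    rowwise_pearson,
    shannon_evenness,
    taukr,
)


# --- independent oracles ------------------------------------------------


def taub_oracle(a, b):
    """Tie-corrected Kendall tau-b by explicit pair counting."""
    n = len(a)
    conc = disc = ties_a = ties_b = 0
    for i in range(n):
        for j in range(i + 1, n):
            da, db = a[i] - a[j], b[i] - b[j]
            if da == 0 and db == 0:
                continue
            if da == 0:
                ties_a += 1
            elif db == 0:
                ties_b += 1
            elif da * db > 0:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + ties_a) * (conc + disc + ties_b))
    if denom == 0:
        return float("nan")
    return (conc - disc) / denom


def taukr_oracle(x):
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    taus = []
    for i in range(n):
        mask = np.arange(n) != i
        a, b = x[i, mask], x[mask, i]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        t = taub_oracle(list(a), list(b))
        if not math.isnan(t):
            taus.append(t)
    return float(np.mean(taus)) if taus else float("nan")


def pearson_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am**2).sum() * (bm**2).sum()))


# --- evenness -------------------------------------------------------------


class TestShannonEvenness:
    def test_uniform_is_one(self):
        assert shannon_evenness(np.full(19, 1 / 19)) == pytest.approx(1.0)

    def test_single_partner(self):
        row = np.zeros(19)
        row[4] = 3.0
        assert shannon_evenness(row) == pytest.approx(1 / 19)

    def test_two_even_partners(self):
        row = np.zeros(19)
        row[0] = row[1] = 0.5
        assert shannon_evenness(row) == pytest.approx(2 / 19)

    def test_zero_row_nan(self):
        assert math.isnan(shannon_evenness(np.zeros(19)))

    def test_scale_invariant(self, rng):
        row = rng.uniform(0, 5, size=19)
        assert shannon_evenness(row) == pytest.approx(shannon_evenness(row * 7.3))

    @settings(max_examples=100, deadline=None)
    @given(st.permutations(list(range(12))))
    def test_permutation_invariant(self, perm):
        row = np.arange(12, dtype=float)
        assert shannon_evenness(row[perm]) == pytest.approx(shannon_evenness(row))

    def test_uniform_is_unique_maximum(self, rng):
        uniform = shannon_evenness(np.full(10, 0.1))
        for _ in range(50):
            row = rng.uniform(0, 1, size=10)
            row = row / row.sum()
            if np.ptp(row) > 1e-9:
                assert shannon_evenness(row) < uniform

    def test_group_mean_skips_zero_rows(self):
        m = np.zeros((4, 4))
        m[0, 1:] = 1.0  # only agent 0 acts, evenly over its 3 partners
        assert mean_group_evenness(m) == pytest.approx(1.0)


# --- Tau-Kr ----------------------------------------------------------------


class TestTauKr:
    def test_symmetric_matrix_gives_one(self, rng):
        a = rng.uniform(0, 1, size=(6, 6))
        x = a + a.T
        assert taukr(x) == pytest.approx(1.0)

    def test_reverse_ordered_rows_give_minus_one(self):
        # X[i, j] = (j - i) mod n makes every received vector the exact
        # reversal of the given vector: perfect discordance row by row
        n = 5
        x = np.fromfunction(lambda i, j: (j - i) % n, (n, n))
        assert taukr(x) == pytest.approx(-1.0)

    def test_fixed_4x4_matches_oracle(self):
        x = np.array(
            [
                [0, 3, 1, 2],
                [2, 0, 3, 1],
                [1, 2, 0, 3],
                [3, 1, 2, 0],
            ],
            dtype=float,
        )
        assert taukr(x) == pytest.approx(taukr_oracle(x), abs=1e-12)

    def test_oracle_equivalence_100_random(self, rng):
        for _ in range(100):
            x = rng.integers(0, 5, size=(5, 5)).astype(float)
            got, want = taukr(x), taukr_oracle(x)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)

    def test_transpose_invariant(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 1, size=(7, 7))
            assert taukr(x) == pytest.approx(taukr(x.T))

    def test_sparse_guard(self):
        x = np.zeros((5, 5))
        x[0, 1] = 1.0
        assert math.isnan(taukr(x))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            taukr(np.zeros((2, 2)))


# --- rank-distance categorization ------------------------------------------


class TestRankDistance:
    def test_printed_dyad_counts(self):
        out = rank_distance_categorize(default_doms(20), 0.35)
        assert out["n_similar_unordered"] == 99
        assert out["n_distant_unordered"] == 91
        assert out["n_similar_directed"] == 198
        assert out["n_distant_directed"] == 182

    def test_two_agents(self):
        out = rank_distance_categorize([0.25, 0.75], 0.35)
        assert out["n_similar_unordered"] == 0
        assert out["n_distant_unordered"] == 1

    def test_strict_threshold(self):
        out = rank_distance_categorize([0.3, 0.65], 0.35)  # diff exactly 0.35
        assert out["n_distant_unordered"] == 1

    def test_partition_complete(self):
        out = rank_distance_categorize(default_doms(20))
        assert out["n_similar_unordered"] + out["n_distant_unordered"] == 190


# --- partner-specificity SD --------------------------------------------------


class TestPartnerSpecificitySD:
    def test_fixed_like_matrix_is_zero(self, default_doms20):
        from emosim.affect import fixed_like

        n = 20
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    m[i, j] = fixed_like(default_doms20[i], default_doms20[j])
        assert partner_specificity_sd(m, default_doms20, kind="directed") == 0.0

    def test_constant_matrix_zero(self, default_doms20):
        m = np.full((20, 20), 0.3)
        assert partner_specificity_sd(m, default_doms20, kind="directed") == 0.0

    def test_toy_matrix_matches_hand_grouping(self):
        doms = np.array([0.25, 0.5, 0.75, 1.0])
        m = np.zeros((4, 4))
        m[0, 1] = 1.0  # the only deviating dyad at signed distance +0.25
        # signed-distance groups with >= 2 members:
        # +0.25: entries (0,1)=1, (1,2)=0, (2,3)=0  -> sd([1,0,0])
        # -0.25: (1,0), (2,1), (3,2) all 0          -> 0
        # +0.50: (0,2), (1,3) = 0                   -> 0
        # -0.50: 0; +-0.75 single dyads excluded
        expected = np.mean([np.std([1.0, 0, 0], ddof=1), 0.0, 0.0, 0.0])
        got = partner_specificity_sd(m, doms, kind="directed")
        assert got == pytest.approx(expected)

    def test_extreme_rank_distance_excluded(self, default_doms20):
        m = np.zeros((20, 20))
        m[0, 19] = 100.0  # the unique +0.95 dyad: must not contribute
        assert partner_specificity_sd(m, default_doms20, kind="directed") == 0.0

    def test_shift_invariant_scale_linear(self, rng, default_doms20):
        m = rng.uniform(0, 1, size=(20, 20))
        base = partner_specificity_sd(m, default_doms20)
        assert partner_specificity_sd(m + 5.0, default_doms20) == pytest.approx(base)
        assert partner_specificity_sd(m * 3.0, default_doms20) == pytest.approx(3 * base)

    def test_symmetric_kind_groups_unordered(self):
        doms = np.array([0.25, 0.5, 0.75, 1.0])
        m = np.zeros((4, 4))
        m[0, 1] = m[1, 0] = 1.0
        # abs-distance 0.25 group: {01}=1, {12}=0, {23}=0 ; 0.5: {02},{13}=0
        expected = np.mean([np.std([1.0, 0, 0], ddof=1), 0.0])
        assert partner_specificity_sd(m, doms, kind="symmetric") == pytest.approx(expected)


# --- rowwise Pearson / Fisher z ----------------------------------------------


class TestRowwisePearson:
    def test_self_correlation_one(self, rng):
        x = rng.uniform(0, 1, size=(6, 6))
        assert rowwise_pearson(x, x) == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.uniform(0, 1, size=(6, 6))
        assert rowwise_pearson(x, 2.0 + 3.0 * x) == pytest.approx(1.0)

    def test_fixed_4x4_matches_oracle(self, rng):
        x = rng.uniform(0, 1, size=(4, 4))
        p = rng.uniform(0, 1, size=(4, 4))
        rs = []
        for i in range(4):
            mask = np.arange(4) != i
            rs.append(pearson_oracle(x[i, mask], p[i, mask]))
        want = abs(math.tanh(np.mean([math.atanh(r) for r in rs])))
        assert rowwise_pearson(x, p) == pytest.approx(want, abs=1e-12)

    def test_no_variance_rows_skipped(self):
        x = np.zeros((4, 4))
        p = np.ones((4, 4))
        assert math.isnan(rowwise_pearson(x, p))


class TestFisherZMean:
    def test_fixed_point(self):
        assert fisher_z_mean([0.3, 0.3, 0.3]) == pytest.approx(0.3)

    def test_antisymmetric_pair(self):
        assert fisher_z_mean([-0.6, 0.6]) == pytest.approx(0.0)

    def test_closed_form(self):
        want = math.tanh((math.atanh(0.5) + math.atanh(0.8)) / 2)
        assert fisher_z_mean([0.5, 0.8]) == pytest.approx(want, abs=1e-12)

    def test_clipping_with_warning(self):
        with pytest.warns(UserWarning):
            out = fisher_z_mean([1.0, 0.0])
        assert 0.9 < out < 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z_mean([1.5])
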