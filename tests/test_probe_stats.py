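from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylprofile import (
    compute_probe_stats,
    compute_qvalues,
    filter_significant,
    mannwhitney_probe,
    methyl_score,
)
from methylprofile.probes import classify_sign, estimate_pi0


def exact_mw_pvalue(x, y):
    """Exhaustive-enumeration two-sided Mann-Whitney oracle (tie-free data).

    Enumerates every way the pooled ranks can be split between the two
    groups, builds the exact null distribution of U1, and doubles the
    smaller tail probability of the observed U1.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    m, n = len(x), len(y)
    ranks = {v: r for r, v in enumerate(np.sort(np.concatenate([x, y])), start=1)}
    u1_obs = sum(ranks[v] for v in x) - m * (m + 1) / 2
    dist = []
    for combo in combinations(range(1, m + n + 1), m):
        dist.append(sum(combo) - m * (m + 1) / 2)
    dist = np.asarray(dist)
    p_low = np.mean(dist <= u1_obs)
    p_high = np.mean(dist >= u1_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


class TestMannWhitney:
    def test_separated_small_groups(self):
        # all three x below all three y: 2/20 rank splits this extreme
        assert mannwhitney_probe([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_degenerate(self):
        assert mannwhitney_probe([0.3, 0.3, 0.3], [0.3, 0.3, 0.3]) == 1.0

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(6), rng.random(5)
        assert mannwhitney_probe(x, y) == pytest.approx(mannwhitney_probe(y, x))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = rng.integers(2, 8)
            n = rng.integers(2, 8)
            pooled = rng.permutation(rng.random(m + n))  # tie-free a.s.
            x, y = pooled[:m], pooled[m:]
            assert mannwhitney_probe(x, y) == pytest.approx(exact_mw_pvalue(x, y))

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError):
            mannwhitney_probe([0.5], [0.1, 0.2])

    def test_missing_values_dropped(self):
        p = mannwhitney_probe([1, 2, 3, np.nan], [4, 5, 6])
        assert p == pytest.approx(0.1)


class TestMethylScore:
    def test_mean_difference(self):
        assert methyl_score([0.3, 0.3], [0.5, 0.5]) == pytest.approx(-0.2)

    def test_identical_groups_zero(self):
        assert methyl_score([0.4, 0.6], [0.4, 0.6]) == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(5), rng.random(4)
        assert methyl_score(x, y) == pytest.approx(-methyl_score(y, x))


def bh_stepup_oracle(p):
    """Textbook Benjamini-Hochberg step-up, written directly from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        rank = i + 1
        running = min(running, m * p[order[i]] / rank)
        q[order[i]] = running
    return q


class TestQValues:
    def test_bh_hand_example(self):
        q = compute_qvalues([0.01, 0.02, 0.03, 0.04], method="bh")
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=200))
    def test_bh_matches_stepup_oracle(self, p):
        assert compute_qvalues(p, method="bh") == pytest.approx(bh_stepup_oracle(p))

    @pytest.mark.parametrize("method", ["bh", "storey"])
    def test_monotone_in_p(self, method):
        rng = np.random.default_rng(3)
        p = rng.random(500)
        q = compute_qvalues(p, method=method)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_storey_pi0_uniform_null(self):
        for seed in range(10):
            p = np.random.default_rng(seed).random(10_000)
            assert 0.9 <= estimate_pi0(p) <= 1.1

    def test_storey_below_bh_with_signal(self):
        rng = np.random.default_rng(5)
        p = np.concatenate([rng.beta(0.1, 10, 500), rng.random(500)])
        qs = compute_qvalues(p, method="storey")
        qbh = compute_qvalues(p, method="bh")
        assert (qs <= qbh + 1e-12).all()

    def test_empty_and_nan_errors(self):
        with pytest.raises(ValueError):
            compute_qvalues([])
        with pytest.raises(ValueError):
            compute_qvalues([0.1, np.nan])


class TestFilterAndSigns:
    def _stats(self):
        return pd.DataFrame({
            "probe_id": ["a", "b", "c", "d"],
            "gene_id": ["G"] * 4,
            "group": ["immune"] * 4,
            "tss_offset": [-2001, -2000, 2000, 2001],
            "p_value": [0.001] * 4,
            "q_value": [0.05, 0.05, 0.051, 0.04],
            "methyl_score": [-0.1, 0.2, 0.0, -0.3],
            "sign": ["negative", "positive", "zero", "negative"],
        })

    def test_q_boundary_kept_position_boundary_dropped(self):
        out = filter_significant(self._stats())
        # q == 0.05 is kept; offsets beyond +/-2000 and q > 0.05 are not
        assert list(out["probe_id"]) == ["b"]

    def test_empty_survivors_graceful(self):
        out = filter_significant(self._stats(), q_max=0.0)
        assert out.empty

    def test_sign_partition_and_consistency(self, small_sig):
        signs = classify_sign(small_sig["methyl_score"])
        assert (signs == small_sig["sign"]).all()
        n = (small_sig["sign"] == "negative").sum() + \
            (small_sig["sign"] == "positive").sum() + (small_sig["sign"] == "zero").sum()
        assert n == len(small_sig)


class TestComputeProbeStats:
    def test_small_sample_fixture_uses_exact_path(self):
        # 3 probes x (2+2) samples: p from exact enumeration, score from means
        values = pd.DataFrame(
            {"d1": [0.1, 0.8, 0.5], "d2": [0.2, 0.9, 0.5],
             "h1": [0.7, 0.1, 0.5], "h2": [0.8, 0.2, 0.5]},
            index=pd.Index(["cg1", "cg2", "cg3"], name="probe_id"),
        )
        from methylprofile import BetaMatrix

        bm = BetaMatrix(values=values, condition=pd.Series(
            ["disease", "disease", "healthy", "healthy"], index=values.columns))
        annot = pd.DataFrame({
            "probe_id": ["cg1", "cg2", "cg3"], "gene_id": ["G"] * 3,
            "group": ["immune"] * 3, "tss_offset": [-100, 0, 100],
            "gene_end_offset": [1000] * 3,
        })
        stats = compute_probe_stats(bm, annot, fdr_method="bh")
        by = stats.set_index("probe_id")
        assert by.loc["cg1", "methyl_score"] == pytest.approx(-0.6)
        assert by.loc["cg1", "p_value"] == pytest.approx(mannwhitney_probe([0.1, 0.2], [0.7, 0.8]))
        assert by.loc["cg3", "p_value"] == 1.0  # constant probe is degenerate
        assert by.loc["cg3", "sign"] == "zero"

    def test_vectorized_matches_per_probe(self, small_study):
        beta = small_study.beta
        annot = small_study.annotation.head(50)
        stats = compute_probe_stats(beta, annot, fdr_method="bh")
        for _, row in stats.head(20).iterrows():
            d = beta.disease.loc[row.probe_id].to_numpy()
            h = beta.healthy.loc[row.probe_id].to_numpy()
            assert row.p_value == pytest.approx(mannwhitney_probe(d, h), rel=1e-9)
            assert row.methyl_score == pytest.approx(methyl_score(d, h))
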