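import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from methylprofile import difference_track, make_windows, profile_group, significant_runs


def _stats(offsets, signs, scores=None):
    n = len(offsets)
    if scores is None:
        scores = [-0.1 if s == "negative" else (0.1 if s == "positive" else 0.0)
                  for s in signs]
    return pd.DataFrame({
        "probe_id": [f"p{i}" for i in range(n)], "gene_id": ["G"] * n,
        "group": ["immune"] * n, "tss_offset": offsets,
        "p_value": [0.001] * n, "q_value": [0.01] * n,
        "methyl_score": scores, "sign": signs,
    })


class TestMakeWindows:
    def test_default_first_and_last(self):
        win = make_windows()
        assert len(win) == 3861
        assert (win.iloc[0].lo, win.iloc[0].hi) == (1860, 2000)
        assert (win.iloc[-1].lo, win.iloc[-1].hi) == (-2000, -1860)

    def test_tiling(self):
        win = make_windows(start=420, end=0, width=140, step=140)
        assert list(win.w) == [420, 280, 140]
        assert list(win.lo) == [280, 140, 0]

    @given(start=st.integers(-500, 500), span=st.integers(150, 1000),
           width=st.integers(1, 140), step=st.integers(1, 50))
    def test_count_formula(self, start, span, width, step):
        end = start - span
        win = make_windows(start=start, end=end, width=width, step=step)
        assert len(win) == (start - end - width) // step + 1
        assert (win.lo >= end).all() and (win.hi <= start).all()

    def test_degenerate_ranges_error(self):
        with pytest.raises(ValueError):
            make_windows(start=0, end=100)
        with pytest.raises(ValueError):
            make_windows(width=0)


class TestProfileGroup:
    def test_single_negative_probe_covers_windows(self):
        win = make_windows(start=200, end=-400, width=140, step=1)
        prof = profile_group(_stats([-100], ["negative"]), win)
        covering = (win.lo <= -100) & (win.hi >= -100)
        assert (prof.loc[covering.to_numpy(), "freq_neg"] == 1.0).all()
        assert prof.loc[~covering.to_numpy(), "freq_neg"].isna().all()

    def test_mixed_probes_same_offset(self):
        win = make_windows(start=100, end=-200, width=140, step=10)
        prof = profile_group(_stats([-50, -50], ["negative", "positive"]), win)
        row = prof[(prof.lo <= -50) & (prof.hi >= -50)]
        assert (row["freq_neg"] == 0.5).all()

    def test_recount_oracle(self):
        rng = np.random.default_rng(9)
        win = make_windows(start=500, end=-500, width=140, step=17)
        for _ in range(100):
            n = rng.integers(1, 60)
            offsets = rng.integers(-600, 600, size=n)
            signs = rng.choice(["negative", "positive", "zero"], size=n)
            stats = _stats(list(offsets), list(signs))
            prof = profile_group(stats, win)
            for _, w in win.sample(5, random_state=1).iterrows():
                inside = (offsets >= w.lo) & (offsets <= w.hi)
                row = prof[prof.w == w.w].iloc[0]
                assert row.n_probes == inside.sum()
                assert row.n_negative == (inside & (signs == "negative")).sum()
                assert row.n_positive == (inside & (signs == "positive")).sum()

    def test_translation_equivariance(self):
        rng = np.random.default_rng(10)
        offsets = rng.integers(-300, 300, size=40)
        signs = rng.choice(["negative", "positive"], size=40)
        win = make_windows(start=400, end=-400, width=140, step=1)
        prof = profile_group(_stats(list(offsets), list(signs)), win)
        k = 37
        prof_shift = profile_group(_stats(list(offsets + k), list(signs)), win)
        merged = prof.merge(prof_shift, left_on="w", right_on=prof_shift["w"] - k,
                            suffixes=("", "_s"))
        interior = (merged.w >= -400 + 140 + k) & (merged.w <= 400 - k)
        sub = merged[interior]
        assert (sub["n_probes"].to_numpy() == sub["n_probes_s"].to_numpy()).all()

    def test_weighted_merge_of_disjoint_sets(self):
        rng = np.random.default_rng(12)
        win = make_windows(start=300, end=-300, width=140, step=25)
        a = _stats(list(rng.integers(-350, 350, 30)),
                   list(rng.choice(["negative", "positive"], 30)))
        b = _stats(list(rng.integers(-350, 350, 20)),
                   list(rng.choice(["negative", "positive"], 20)))
        b["probe_id"] = [f"q{i}" for i in range(len(b))]
        pa, pb = profile_group(a, win), profile_group(b, win)
        pu = profile_group(pd.concat([a, b]), win)
        assert (pu.n_negative == pa.n_negative + pb.n_negative).all()
        total = pa.n_probes + pb.n_probes
        expect = (pa.mean_score.fillna(0) * pa.n_probes
                  + pb.mean_score.fillna(0) * pb.n_probes) / total.replace(0, np.nan)
        assert np.allclose(pu.mean_score.to_numpy(), expect.to_numpy(), equal_nan=True)


class TestDifferenceTrack:
    def test_identical_groups_flat(self):
        rng = np.random.default_rng(13)
        stats = _stats(list(rng.integers(-200, 200, 30)),
                       list(rng.choice(["negative", "positive"], 30)))
        win = make_windows(start=250, end=-250, width=140, step=10)
        track = difference_track(stats, stats, win, mode="freq_neg")
        ok = ~track.masked
        assert (track.loc[ok, "delta"] == 0).all()
        assert (track.loc[ok, "p_value"] == 1.0).all()

    def test_opposed_groups(self):
        from methylprofile import mannwhitney_probe

        a = _stats([0] * 10, ["negative"] * 10)
        b = _stats([0] * 10, ["positive"] * 10)
        win = make_windows(start=140, end=-140, width=140, step=140)
        track = difference_track(a, b, win, mode="freq_neg")
        row = track[track.w == 0].iloc[0]
        assert row.delta == 1.0
        expected = mannwhitney_probe(-np.ones(10), np.ones(10))
        assert row.p_value == pytest.approx(expected)

    def test_masking_threshold(self):
        a = _stats([0, 0, 0], ["negative"] * 3)
        b = _stats([0, 0], ["positive"] * 2)
        win = make_windows(start=140, end=-140, width=140, step=140)
        track = difference_track(a, b, win, mode="freq_neg", min_probes=3)
        assert track[track.w == 0].iloc[0]["masked"]

    def test_mismatched_modes_rejected(self):
        a = _stats([0], ["negative"])
        with pytest.raises(ValueError):
            difference_track(a, a, mode="median")
        with pytest.raises(ValueError):
            difference_track(a, a, mode="mean_score", test="proportion")

    def test_proportion_test_variant(self):
        rng = np.random.default_rng(14)
        a = _stats(list(rng.integers(-100, 100, 40)),
                   list(rng.choice(["negative", "positive"], 40, p=[0.8, 0.2])))
        b = _stats(list(rng.integers(-100, 100, 40)),
                   list(rng.choice(["negative", "positive"], 40, p=[0.2, 0.8])))
        win = make_windows(start=150, end=-150, width=140, step=50)
        track = difference_track(a, b, win, mode="freq_neg", test="proportion")
        ok = ~track.masked
        assert (track.loc[ok, "p_value"] <= 1).all()
        assert (track.loc[ok, "delta"] > 0).any()


class TestSignificantRuns:
    def test_runs_and_spans(self):
        track = pd.DataFrame({
            "w": [100, 90, 80, 70, 60], "lo": [0, -10, -20, -30, -40],
            "hi": [100, 90, 80, 70, 60],
            "delta": [0.5, 0.4, -0.2, 0.6, 0.7],
            "p_value": [0.01, 0.02, 0.01, 0.2, 0.03],
            "masked": [False] * 5,
        })
        runs = significant_runs(track, direction="positive")
        assert len(runs) == 2
        first = runs.iloc[0]
        assert first.w_first == 100 and first.w_last == 90 and first.n_windows == 2
        assert first.span_lo == -10 and first.span_hi == 100
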