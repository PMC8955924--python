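import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from berrydeg.deg_ratio import (
    RatioStatus,
    call_degs,
    ratio_histogram,
    signed_ratio,
    top_k,
)
from berrydeg.errors import InputError

positive = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False)


def oracle_signed(t, c):
    """Direct evaluation of the ratio-then-invert definition."""
    r = t / c
    return r if r >= 1 else -1.0 / r


def _merged(t_vals, c_vals, ids=None, stage="V"):
    ids = ids or [f"t{i}" for i in range(len(t_vals))]
    return pd.DataFrame(
        {f"R{stage}": t_vals, f"S{stage}": c_vals},
        index=pd.Index(ids, name="transcript_id"),
    )


class TestSignedRatio:
    @pytest.mark.parametrize(
        "t,c,expected",
        [(3, 1, 3.0), (1, 2, -2.0), (5, 5, 1.0), (6.61, 1.0, 6.61)],
    )
    def test_examples(self, t, c, expected):
        assert signed_ratio(t, c) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "t,c,sentinel",
        [(2.0, 0.0, RatioStatus.EXCLUSIVE_TREATMENT),
         (0.0, 2.0, RatioStatus.EXCLUSIVE_CONTROL),
         (0.0, 0.0, RatioStatus.UNDEFINED)],
    )
    def test_sentinels(self, t, c, sentinel):
        assert signed_ratio(t, c) is sentinel

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            signed_ratio(-1.0, 2.0)

    @given(t=positive, c=positive)
    @settings(max_examples=200, deadline=None)
    def test_image_avoids_open_unit_interval_and_matches_oracle(self, t, c):
        v = signed_ratio(t, c)
        assert abs(v) >= 1.0
        assert v == oracle_signed(t, c)
        if t == c:
            assert v == 1.0

    @given(t=positive, c=positive)
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_under_swap(self, t, c):
        if t != c:
            assert signed_ratio(t, c) == pytest.approx(-signed_ratio(c, t), rel=1e-12)

    def test_monotone_in_treatment(self):
        grid = np.linspace(0.1, 10.0, 50)
        values = [signed_ratio(t, 2.0) for t in grid]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestCallDegs:
    def test_basic_calls(self):
        merged = _merged([4.5, 1.4], [1.0, 1.0])
        out = call_degs(merged, "V")
        assert out.loc[0, "significant"] and out.loc[0, "direction"] == "up"
        assert not out.loc[1, "significant"] and out.loc[1, "direction"] == "none"
        assert out.loc[0, "ratio_signed"] == pytest.approx(4.5)

    def test_cutoff_is_strict(self):
        merged = _merged([1.5, 1.5 + 1e-9], [1.0, 1.0])
        out = call_degs(merged, "V")
        assert not out.loc[0, "significant"]
        assert out.loc[1, "significant"]

    def test_sentinels_never_significant(self):
        merged = _merged([5.0, 0.0, 0.0], [0.0, 5.0, 0.0])
        out = call_degs(merged, "V")
        assert not out["significant"].any()
        assert out["status"].tolist() == [
            RatioStatus.EXCLUSIVE_TREATMENT.value,
            RatioStatus.EXCLUSIVE_CONTROL.value,
            RatioStatus.UNDEFINED.value,
        ]

    def test_missing_condition_column_rejected(self):
        merged = _merged([1.0], [1.0], stage="V")
        with pytest.raises(InputError, match="SM|RM"):
            call_degs(merged, "M")

    def test_planted_construction_recovered_exactly(self, rng):
        n_up, n_down, n_null, fold = 20, 20, 160, 4.0
        base = rng.lognormal(2, 1, n_up + n_down + n_null) + 1.0
        control = base.copy()
        treatment = base.copy()
        treatment[:n_up] *= fold
        treatment[n_up:n_up + n_down] /= fold
        out = call_degs(_merged(treatment, control), "V")
        assert int(out["significant"].sum()) == n_up + n_down
        directions = out["direction"].to_numpy()
        assert (directions[:n_up] == "up").all()
        assert (directions[n_up:n_up + n_down] == "down").all()
        assert (directions[n_up + n_down:] == "none").all()

    def test_raising_cutoff_never_adds_calls(self, rng):
        t = rng.lognormal(1, 1.5, 300)
        c = rng.lognormal(1, 1.5, 300)
        loose = call_degs(_merged(t, c), "V", cutoff=1.5)["significant"]
        tight = call_degs(_merged(t, c), "V", cutoff=2.5)["significant"]
        assert not (tight & ~loose).any()


class TestRatioHistogram:
    def _table(self, values, statuses=None):
        n = len(values)
        statuses = statuses or [RatioStatus.FINITE.value] * n
        return pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(n)], "stage": "V",
             "ratio_signed": values, "status": statuses}
        )

    def test_example_bins(self):
        hist = ratio_histogram(self._table([-6.0, -2.2, 1.2, 7.0]))
        by_label = hist.bins.set_index("label")["count"]
        assert by_label["<= -5"] == 1
        assert by_label["(-3, -2]"] == 1
        assert by_label["[-1.5, 1.5]"] == 1
        assert by_label[">= 5"] == 1
        assert hist.total_finite == 4

    def test_empty_table_all_zero(self):
        hist = ratio_histogram(self._table([]))
        assert hist.bins["count"].sum() == 0

    def test_conservation_with_sentinels(self, rng):
        raw = rng.uniform(0.05, 20.0, 500)
        signed = np.where(raw >= 1, raw, -1 / raw)
        statuses = [RatioStatus.FINITE.value] * 500
        for i in range(0, 30):
            statuses[i] = RatioStatus.EXCLUSIVE_TREATMENT.value
        table = self._table(list(signed), statuses)
        table.loc[:29, "ratio_signed"] = np.nan
        hist = ratio_histogram(table)
        assert hist.total_finite + sum(hist.sentinel_counts.values()) == 500

    def test_matches_brute_force_binning(self, rng):
        raw = rng.uniform(0.05, 20.0, 500)
        signed = np.where(raw >= 1, raw, -1 / raw)
        hist = ratio_histogram(self._table(list(signed)))
        pos_edges = [1.5, 2, 3, 4, 5]
        for _, row in hist.bins.iterrows():
            lo, hi = row["lo"], row["hi"]
            if row["label"].startswith("[-"):
                expected = (np.abs(signed) <= pos_edges[0]).sum()
            elif np.isinf(lo):
                expected = ((signed < 0) & (np.abs(signed) > 5)).sum()
            elif np.isinf(hi):
                expected = ((signed > 0) & (np.abs(signed) > 5)).sum()
            elif hi <= 0:
                expected = ((signed < 0) & (np.abs(signed) > abs(hi)) &
                            (np.abs(signed) <= abs(lo))).sum()
            else:
                expected = ((signed > 0) & (signed > lo) & (signed <= hi)).sum()
            assert row["count"] == expected, row["label"]

    def test_unsorted_edges_rejected(self):
        with pytest.raises(InputError, match="increasing"):
            ratio_histogram(self._table([2.0]), edges=(1.5, -1.5, 3.0, -3.0))


class TestTopK:
    def test_degenerate_fewer_than_k(self):
        table = call_degs(_merged([3.0, 2.0, 1.0], [1.0, 1.0, 1.0]), "V")
        with pytest.warns(UserWarning, match="top-10"):
            up, down = top_k(table, 10)
        assert len(up) == 3 and len(down) == 3

    def test_tie_broken_lexicographically(self):
        merged = _merged([5.0, 4.0, 4.0], [1.0, 1.0, 1.0], ids=["c", "b", "a"])
        up, _ = top_k(call_degs(merged, "V"), 2)
        assert up["transcript_id"].tolist() == ["c", "a"]

    def test_agrees_with_full_sort_oracle(self, rng):
        t = rng.lognormal(1, 1.5, 300)
        c = rng.lognormal(1, 1.5, 300)
        table = call_degs(_merged(t, c), "V")
        up, down = top_k(table, 10)
        signed = np.where(t / c >= 1, t / c, -c / t)
        assert up["ratio_signed"].tolist() == sorted(signed, reverse=True)[:10]
        assert down["ratio_signed"].tolist() == sorted(signed)[:10]
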