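import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from berrydeg.errors import InputError
from berrydeg.quantify import activity_mask, compute_rpkm, universe_summary

from conftest import make_annotation


def brute_force_rpkm(counts, lengths, lib_sizes):
    """Independent cell-by-cell evaluation of the RPKM definition."""
    out = np.empty(counts.shape)
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            out[i, j] = (counts[i, j] / (lib_sizes[j] / 1e6)) / (lengths[i] / 1e3)
    return out


def _matrix(values, ids, samples):
    return pd.DataFrame(values, index=pd.Index(ids, name="transcript_id"), columns=samples)


class TestComputeRpkm:
    def test_unit_factors_cancel(self):
        counts = _matrix([[10]], ["tx1"], ["SV1"])
        ann = make_annotation(["tx1"], lengths=[1000])
        rpkm = compute_rpkm(counts, ann, lib_sizes=pd.Series({"SV1": 1_000_000}))
        assert rpkm.loc["tx1", "SV1"] == pytest.approx(10.0)

    def test_zero_counts_give_zero(self):
        counts = _matrix([[0]], ["tx1"], ["SV1"])
        ann = make_annotation(["tx1"], lengths=[350])
        rpkm = compute_rpkm(counts, ann, lib_sizes=pd.Series({"SV1": 2_500_000}))
        assert rpkm.loc["tx1", "SV1"] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        # frozen hand evaluation of one cell: 7 reads, 2.5M library, 350 bp
        counts7 = _matrix([[7]], ["tx1"], ["SV1"])
        ann7 = make_annotation(["tx1"], lengths=[350])
        val = compute_rpkm(counts7, ann7, lib_sizes=pd.Series({"SV1": 2_500_000}))
        assert val.loc["tx1", "SV1"] == pytest.approx(8.0, rel=1e-12)

        ids = [f"t{i}" for i in range(5)]
        samples = [f"s{j}" for j in range(4)]
        vals = rng.integers(0, 1000, size=(5, 4))
        lengths = rng.integers(150, 5000, size=5)
        libs = rng.integers(1_000_000, 5_000_000, size=4).astype(float)
        counts = _matrix(vals, ids, samples)
        ann = make_annotation(ids, lengths=lengths)
        got = compute_rpkm(counts, ann, lib_sizes=pd.Series(libs, index=samples))
        expected = brute_force_rpkm(vals, lengths, libs)
        np.testing.assert_allclose(got.to_numpy(), expected, rtol=1e-12)

    def test_missing_annotation_and_zero_library_rejected(self):
        counts = _matrix([[1]], ["tx1"], ["SV1"])
        with pytest.raises(InputError, match="annotation"):
            compute_rpkm(counts, make_annotation(["other"]))
        with pytest.raises(InputError, match="positive"):
            compute_rpkm(counts, make_annotation(["tx1"]),
                         lib_sizes=pd.Series({"SV1": 0.0}))

    @given(factor=st.integers(min_value=2, max_value=100))
    @settings(max_examples=20, deadline=None)
    def test_linearity_and_depth_invariance(self, factor):
        ids, samples = ["a", "b"], ["s1"]
        counts = _matrix([[10], [20]], ids, samples)
        ann = make_annotation(ids, lengths=[500, 2000])
        libs = pd.Series({"s1": 1_000_000.0})
        base = compute_rpkm(counts, ann, lib_sizes=libs)
        # doubling one cell doubles its RPKM
        scaled = compute_rpkm(counts * factor, ann, lib_sizes=libs)
        np.testing.assert_allclose(scaled.to_numpy(), base.to_numpy() * factor)
        # scaling counts and library together leaves RPKM unchanged
        invariant = compute_rpkm(counts * factor, ann, lib_sizes=libs * factor)
        np.testing.assert_allclose(invariant.to_numpy(), base.to_numpy(), rtol=1e-12)


class TestActivityMask:
    def test_boundary_values_inclusive(self):
        expr = _matrix([[1.0], [0.999]], ["ok", "low"], ["s1"])
        ann = make_annotation(["ok", "low"], lengths=[150, 150])
        mask = activity_mask(expr, ann)
        assert bool(mask.loc["ok", "s1"]) is True
        assert bool(mask.loc["low", "s1"]) is False

    def test_length_filter_dominates(self):
        expr = _matrix([[50.0, 80.0]], ["shorty"], ["s1", "s2"])
        ann = make_annotation(["shorty"], lengths=[149])
        assert not activity_mask(expr, ann).any().any()

    def test_matches_double_loop_oracle(self, rng):
        ids = [f"t{i}" for i in range(50)]
        samples = [f"s{j}" for j in range(4)]
        expr = _matrix(rng.uniform(0, 3, size=(50, 4)), ids, samples)
        lengths = rng.integers(100, 300, size=50)
        ann = make_annotation(ids, lengths=lengths)
        mask = activity_mask(expr, ann)
        for i, tx in enumerate(ids):
            for s in samples:
                expected = lengths[i] >= 150 and expr.loc[tx, s] >= 1.0
                assert bool(mask.loc[tx, s]) == expected

    def test_monotone_in_rpkm_min(self, rng):
        ids = [f"t{i}" for i in range(30)]
        expr = _matrix(rng.uniform(0, 5, size=(30, 2)), ids, ["s1", "s2"])
        ann = make_annotation(ids, lengths=[200] * 30)
        low = activity_mask(expr, ann, rpkm_min=0.5)
        high = activity_mask(expr, ann, rpkm_min=2.0)
        assert (high & ~low).sum().sum() == 0


class TestUniverseSummary:
    def test_three_patterns(self):
        mask = _matrix([[True, True], [False, False], [True, False]],
                       ["all", "none", "mix"], ["s1", "s2"])
        s = universe_summary(mask)
        assert (s.active_in_all, s.active_in_none, s.active_in_some) == (1, 1, 1)

    def test_all_true_degenerate(self):
        mask = _matrix(np.ones((4, 3), dtype=bool), list("abcd"), ["x", "y", "z"])
        s = universe_summary(mask)
        assert (s.active_in_all, s.active_in_none, s.active_in_some) == (4, 0, 0)

    def test_counts_sum_to_transcripts(self, rng):
        mask = _matrix(rng.random((40, 4)) > 0.5, [f"t{i}" for i in range(40)],
                       list("wxyz"))
        s = universe_summary(mask)
        assert s.active_in_all + s.active_in_none + s.active_in_some == 40
        # set-algebra oracle
        per_row = mask.sum(axis=1)
        assert s.active_in_all == (per_row == 4).sum()
        assert s.active_in_none == (per_row == 0).sum()
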