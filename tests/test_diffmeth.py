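"""Per-CpG logistic-regression LRT and gene-level aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import xlogy

from methage import (GeneFeature, MethylationMatrix, SampleRecord, call_dmps,
                     classify_consistent, dmp_test, gene_level_dm,
                     weighted_methylation)
from methage.diffmeth import DmpCalls, _status
from methage.errors import DataError, ValidationError


def grouped_lrt_oracle(ma, ca, mb, cb):
    """Closed-form grouped-binomial likelihood ratio: pooled vs split MLEs."""
    def ll(m, c, p):
        return xlogy(m, p) + xlogy(c - m, 1 - p)
    sa, sb = sum(ma), sum(mb)
    na, nb = sum(ca), sum(cb)
    p_a, p_b, p_0 = sa / na, sb / nb, (sa + sb) / (na + nb)
    alt = ll(sa, na, p_a) + ll(sb, nb, p_b)
    null = ll(sa, na, p_0) + ll(sb, nb, p_0)
    return 2 * (alt - null)


class TestDmpTest:
    def test_worked_example(self):
        delta, dev, p = dmp_test([2, 3], [10, 10], [8, 7], [10, 10])
        assert delta == pytest.approx(0.5)
        assert dev == pytest.approx(10.47, abs=0.01)
        assert p == pytest.approx(1.2e-3, rel=0.05)

    def test_identical_groups_null(self):
        delta, dev, p = dmp_test([5, 5], [10, 10], [5, 5], [10, 10])
        assert delta == 0.0 and dev == 0.0 and p == 1.0

    def test_maximal_separation(self):
        delta, dev, p = dmp_test([0, 0], [30, 30], [30, 30], [30, 30])
        assert delta == 1.0
        assert p < 1e-10

    def test_zero_coverage_group_rejected(self):
        with pytest.raises(DataError):
            dmp_test([0, 0], [0, 0], [1, 1], [5, 5])

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_matches_brute_force_lrt(self, seed):
        """Deviance equals the closed-form grouped-binomial LRT on random
        small instances (<= 4 samples per group, coverage <= 20)."""
        rng = np.random.default_rng(seed)
        na, nb = rng.integers(2, 5), rng.integers(2, 5)
        ca = rng.integers(1, 21, na)
        cb = rng.integers(1, 21, nb)
        ma = rng.binomial(ca, rng.uniform(0, 1))
        mb = rng.binomial(cb, rng.uniform(0, 1))
        delta, dev, _ = dmp_test(ma, ca, mb, cb)
        assert dev == pytest.approx(grouped_lrt_oracle(ma, ca, mb, cb), abs=1e-10)
        # antisymmetry: swapping groups negates delta, keeps the deviance
        delta2, dev2, _ = dmp_test(mb, cb, ma, ca)
        assert delta2 == pytest.approx(-delta, abs=1e-12)
        assert dev2 == pytest.approx(dev, abs=1e-10)


class TestCallThresholds:
    """hyper iff q < 0.05 and delta > 0.15 — both strict."""

    @pytest.mark.parametrize("q,delta,expected", [
        (0.04, 0.16, "hyper"),
        (0.04, 0.15, "ns"),       # the 15% floor is strict
        (0.06, 0.50, "ns"),
        (0.04, -0.16, "hypo"),
        (0.05, 0.16, "ns"),       # q must be below, not equal
    ])
    def test_status_rule(self, q, delta, expected):
        out = _status(np.array([delta]), np.array([q]), 0.05, 0.15)
        assert out[0] == expected

    def test_unknown_comparison_rejected(self):
        samples = [SampleRecord(f"s{i}", "F", a, r)
                   for i, (a, r) in enumerate([(0, 1), (0, 2), (8, 1), (8, 2)])]
        m = MethylationMatrix([("c", 1)], samples,
                              np.array([[1, 2, 3, 4]]), np.array([[9, 9, 9, 9]]))
        with pytest.raises(ValidationError):
            call_dmps(m, comparisons=[("M", 0, 8)])


def calls_from_frame(rows):
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "comparison", "sex",
                                        "age_a", "age_b", "delta", "deviance",
                                        "p", "q", "status"])
    sig = frame[frame["status"] != "ns"]
    union = sorted({(c, int(p)) for c, p in zip(sig["chrom"], sig["pos"])})
    return DmpCalls(frame=frame, union_sites=union, q_max=0.05, min_delta=0.15)


class TestClassifyConsistent:
    def row(self, pos, comparison, status):
        sex, pair = comparison.split(":")
        a, b = pair.split("v")
        return ("c", pos, comparison, sex, int(a), int(b),
                0.2 if status == "hyper" else -0.2, 9.0, 0.001, 0.01, status)

    def test_partition(self):
        calls = calls_from_frame([
            self.row(1, "M:0v8", "hyper"), self.row(1, "M:8v16", "hyper"),
            self.row(2, "M:0v8", "hyper"), self.row(2, "M:8v16", "hypo"),
            self.row(3, "M:0v8", "hypo"), self.row(3, "M:8v16", "hypo"),
            self.row(4, "M:0v8", "ns"), self.row(4, "M:8v16", "ns"),
        ])
        parts = classify_consistent(calls, "M")
        assert parts["consistent_hyper"] == {("c", 1)}
        assert parts["consistent_hypo"] == {("c", 3)}
        assert parts["other"] == {("c", 2)}
        assert not parts["consistent_hyper"] & parts["consistent_hypo"]

    def test_missing_comparison_rejected(self):
        calls = calls_from_frame([self.row(1, "M:0v8", "hyper")])
        with pytest.raises(DataError, match="8v16"):
            classify_consistent(calls, "M")


class TestWeightedMethylation:
    def test_pooled_ratio(self):
        assert weighted_methylation([3, 7], [10, 10]) == 0.5

    def test_single_unmethylated(self):
        assert weighted_methylation([0], [10]) == 0.0

    def test_zero_coverage_is_missing(self):
        assert np.isnan(weighted_methylation([0, 0], [0, 0]))


class TestGeneLevel:
    def build(self, statuses, fractions_a, fractions_b):
        """Three CpGs in one gene; per-comparison statuses forced."""
        samples = [SampleRecord(s, "F", a, r) for s, a, r in
                   [("a1", 0, 1), ("a2", 0, 2), ("b1", 16, 1), ("b2", 16, 2)]]
        cov = np.full((3, 4), 100)
        meth = np.column_stack([
            np.array(fractions_a) * 100, np.array(fractions_a) * 100,
            np.array(fractions_b) * 100, np.array(fractions_b) * 100,
        ]).astype(int)
        matrix = MethylationMatrix([("c", 10), ("c", 20), ("c", 30)],
                                   samples, meth, cov)
        rows = [("c", 10 * (i + 1), "F:0v16", "F", 0, 16, 0.2, 9.0, 1e-4,
                 1e-3, s) for i, s in enumerate(statuses)]
        return calls_from_frame(rows), matrix

    def test_two_dmps_and_large_delta_is_dm(self):
        calls, matrix = self.build(["hyper", "hyper", "ns"],
                                   [0.1, 0.1, 0.1], [0.3, 0.3, 0.3])
        out = gene_level_dm(calls, [GeneFeature("g1", "c", 1, 100)], matrix)
        row = out.iloc[0]
        assert row["n_dm_cpgs"] == 2
        assert row["weighted_delta"] == pytest.approx(0.2)
        assert row["status"] == "dm"

    def test_one_dmp_is_ns_even_with_large_delta(self):
        calls, matrix = self.build(["hyper", "ns", "ns"],
                                   [0.1, 0.1, 0.1], [0.5, 0.5, 0.5])
        out = gene_level_dm(calls, [GeneFeature("g1", "c", 1, 100)], matrix)
        assert out.iloc[0]["status"] == "ns"

    def test_three_dmps_with_small_weighted_delta_is_ns(self):
        calls, matrix = self.build(["hyper", "hyper", "hyper"],
                                   [0.1, 0.1, 0.1], [0.2, 0.2, 0.2])
        out = gene_level_dm(calls, [GeneFeature("g1", "c", 1, 100)], matrix)
        assert out.iloc[0]["n_dm_cpgs"] == 3
        assert out.iloc[0]["status"] == "ns"


class TestOnSyntheticRun:
    def test_age_null_sites_rarely_called(self, pipeline_run, classes):
        """Empirical false-positive control on the stable class."""
        frame = pipeline_run.dmp_calls.frame
        for label in ("F:0v16", "M:0v16"):
            sub = frame[frame["comparison"] == label]
            status = dict(zip(zip(sub["chrom"], sub["pos"]), sub["status"]))
            null = [status[k] != "ns" for k in classes["stable"] if k in status]
            rate = np.mean(null)
            bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / len(null))
            assert rate <= bound, f"{label}: {rate:.3f} > {bound:.3f}"

    def test_trending_sites_recovered(self, pipeline_run, classes):
        frame = pipeline_run.dmp_calls.frame
        for label in ("F:0v16", "M:0v16"):
            sub = frame[frame["comparison"] == label]
            status = dict(zip(zip(sub["chrom"], sub["pos"]), sub["status"]))
            for cls in ("dmp_hyper", "dmp_hypo"):
                hits = [status[k] != "ns" for k in classes[cls] if k in status]
                assert np.mean(hits) >= 0.60
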