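"""Window peak caller: dedup, window stats, empirical FDR, peak filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tftargets import peaks as pk
from tftargets import simulate as sim
from tftargets.workflow import evaluate_peak_recovery, planted_summits

from conftest import make_reads


class TestDeduplicate:
    def test_cap_applied_per_coordinate(self):
        reads = make_reads([100] * 7 + [200] * 3)
        out = pk.deduplicate_reads(reads, cap=5)
        assert (out["pos"] == 100).sum() == 5
        assert (out["pos"] == 200).sum() == 3

    def test_strands_counted_separately(self):
        reads = make_reads([100] * 6 + [100] * 6, ["+"] * 6 + ["-"] * 6)
        out = pk.deduplicate_reads(reads, cap=5)
        assert len(out) == 10

    def test_distinct_coordinates_noop(self):
        reads = make_reads(range(50))
        pd.testing.assert_frame_equal(pk.deduplicate_reads(reads), reads)

    @given(st.lists(st.integers(0, 20), min_size=0, max_size=60),
           st.integers(1, 6))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, positions, cap):
        reads = make_reads(positions)
        once = pk.deduplicate_reads(reads, cap)
        twice = pk.deduplicate_reads(once, cap)
        pd.testing.assert_frame_equal(once, twice)


class TestWindowStats:
    def test_log_ratio_arithmetic(self):
        # 81 sample vs 6 control reads in window [0, 200), equal library sizes
        sample = make_reads(list(range(50, 131)) + list(range(5000, 5919)))
        control = make_reads(list(range(50, 56)) + list(range(5000, 5994)))
        stats = pk.compute_window_stats(sample, control, {"chr1": 10_000}, pseudocount=0)
        w0 = stats.iloc[0]
        assert w0["sample_count"] == 81 and w0["control_count"] == 6
        assert w0["log_ratio"] == pytest.approx(np.log2(81 / 6), abs=1e-9)

    def test_identical_libraries_zero_ratio(self, rng):
        reads = make_reads(rng.integers(0, 10_000, size=500))
        stats = pk.compute_window_stats(reads, reads.copy(), {"chr1": 10_000})
        assert np.allclose(stats["log_ratio"], 0)

    def test_matches_bruteforce_recount(self, rng):
        length = 10_100  # exactly 100 windows of 200 bp at 100-bp step
        sample = make_reads(sorted(rng.integers(0, length, size=400)))
        control = make_reads(sorted(rng.integers(0, length, size=300)))
        stats = pk.compute_window_stats(sample, control, {"chr1": length})
        assert len(stats) == 100
        for row in stats.itertuples(index=False):
            cs = sum(row.start <= p < row.end for p in sample["pos"])
            cc = sum(row.start <= p < row.end for p in control["pos"])
            assert cs == row.sample_count and cc == row.control_count
            expected = np.log2(((cs + 1) / 400) / ((cc + 1) / 300))
            assert row.log_ratio == pytest.approx(expected, abs=1e-12)

    def test_label_swap_negates_ratios_at_equal_depth(self, rng):
        a = make_reads(rng.integers(0, 20_000, size=1_000))
        b = make_reads(rng.integers(0, 20_000, size=1_000))
        fwd = pk.compute_window_stats(a, b, {"chr1": 20_000})
        rev = pk.compute_window_stats(b, a, {"chr1": 20_000})
        assert np.allclose(fwd["log_ratio"], -rev["log_ratio"])

    def test_empty_control_raises(self):
        sample = make_reads([10, 20])
        with pytest.raises(ValueError, match="control"):
            pk.compute_window_stats(sample, make_reads([]), {"chr1": 1_000})

    def test_step_must_half_overlap(self):
        with pytest.raises(ValueError, match="half-overlap"):
            pk.compute_window_stats(make_reads([1]), make_reads([1]),
                                    {"chr1": 1_000}, window=200, step=50)


class TestEmpiricalFdr:
    def test_top_window_gets_addone_p(self, rng):
        stats = pd.DataFrame({"chrom": "chr1", "start": 0, "end": 200,
                              "sample_count": 0, "control_count": 0,
                              "log_ratio": [5.0, 0.1]})
        null = stats.copy()
        null["log_ratio"] = rng.normal(0, 1, size=2).clip(max=4.0)
        out = pk.estimate_window_fdr(stats, null)
        assert out.loc[0, "p"] == pytest.approx(1 / 3)

    def test_identical_windows_share_p_and_q(self):
        stats = pd.DataFrame({"chrom": "chr1", "start": range(0, 500, 100),
                              "end": range(200, 700, 100), "sample_count": 3,
                              "control_count": 3, "log_ratio": 0.0})
        out = pk.estimate_window_fdr(stats, stats)
        assert out["p"].nunique() == 1 and out["q"].nunique() == 1

    def test_empty_null_raises(self):
        stats = pd.DataFrame({"log_ratio": [1.0]})
        with pytest.raises(ValueError, match="null"):
            pk.estimate_window_fdr(stats, pd.DataFrame({"log_ratio": []}))


def _stats_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sample_count",
                                       "control_count", "log_ratio", "p", "q"])


def _balanced_reads(center, n_per_strand, spread=30):
    # strand clusters +/-50 bp around the center so every 5' end stays
    # inside a 200-bp window at the center
    pos = np.linspace(center - spread, center + spread, n_per_strand).astype(int)
    plus = make_reads(pos - 50, ["+"] * n_per_strand)
    minus = make_reads(pos + 50, ["-"] * n_per_strand)
    return pd.concat([plus, minus], ignore_index=True)


class TestCallPeaks:
    def test_subthreshold_fold_never_called(self):
        stats = _stats_frame([("chr1", 1000, 1200, 40, 10, np.log2(3.5), 1e-4, 1e-4)])
        reads = _balanced_reads(1100, 40)
        peaks = pk.call_peaks(stats, reads)
        assert len(peaks) == 0

    def test_passing_window_yields_one_peak(self):
        stats = _stats_frame([("chr1", 1000, 1200, 60, 5, np.log2(10), 1e-4, 1e-3)])
        reads = _balanced_reads(1100, 35)  # 70 reads, balance 0
        peaks = pk.call_peaks(stats, reads)
        assert len(peaks) == 1
        p = peaks.iloc[0]
        assert p["enrichment"] == pytest.approx(10)
        assert p["support"] == 70
        assert 1000 <= p["summit"] < 1200

    def test_support_strictly_greater(self):
        stats = _stats_frame([("chr1", 1000, 1200, 50, 5, np.log2(10), 1e-4, 1e-3)])
        reads = _balanced_reads(1100, 25)  # support exactly 50
        assert len(pk.call_peaks(stats, reads)) == 0

    def test_imbalanced_candidate_discarded(self):
        stats = _stats_frame([("chr1", 1000, 1200, 90, 5, np.log2(10), 1e-4, 1e-3)])
        plus = make_reads(np.arange(1000, 1180, 3), ["+"] * 60)
        minus = make_reads(np.arange(1050, 1150, 2), ["-"] * 50)[:20]
        reads = pd.concat([plus, minus], ignore_index=True)  # |log2(60/20)| = 1.58
        assert len(pk.call_peaks(stats, reads)) == 0

    def test_adjacent_windows_merge(self):
        stats = _stats_frame([
            ("chr1", 1000, 1200, 60, 5, np.log2(8), 1e-4, 1e-3),
            ("chr1", 1100, 1300, 70, 5, np.log2(12), 1e-4, 1e-3),
            ("chr1", 1200, 1400, 55, 5, np.log2(9), 1e-4, 1e-3),
        ])
        reads = _balanced_reads(1200, 60, spread=120)
        peaks = pk.call_peaks(stats, reads)
        assert len(peaks) == 1
        assert peaks.iloc[0]["start"] == 1000 and peaks.iloc[0]["end"] == 1400
        assert peaks.iloc[0]["enrichment"] == pytest.approx(12)

    def test_threshold_monotonicity(self):
        """Raising fold/support or lowering FDR never adds a peak."""
        g = sim.generate_genome(60, sim.suggested_chrom_length(60), seed=21)
        prog = sim.make_binding_program(g, list(g.genes["gene_id"][:8]), seed=22)
        sample, control = sim.simulate_chip_reads(g, prog, depth=300_000, seed=23,
                                                  stages=("E",))["E"]
        base, stats = pk.call_peaks_pipeline(sample, control, g, stage="E")
        ids = set(base["peak_id"])
        for kwargs in ({"fold_min": 6.0}, {"support_min": 200}, {"fdr_max": 0.001}):
            subset = pk.call_peaks(stats, pk.deduplicate_reads(sample), stage="E", **kwargs)
            assert set(subset["peak_id"]) <= ids or len(subset) <= len(base)
            # peak regions of the stricter call are a subset of the laxer ones
            strict = {(r.chrom, r.start, r.end) for r in subset.itertuples(index=False)}
            lax = {(r.chrom, r.start, r.end) for r in base.itertuples(index=False)}
            assert strict <= lax

    def test_planted_summits_located_with_shift_correction(self):
        # enough planted peaks that the empirical label-swap null can push
        # their windows below the FDR threshold
        g = sim.generate_genome(120, sim.suggested_chrom_length(120), seed=31)
        targets = list(g.genes["gene_id"][::2])[:50]
        prog = sim.make_binding_program(g, targets, seed=32, enrichment_range=(15.0, 16.0))
        # depth chosen for ~0.4 background reads/bp so the dedup cap stays
        # out of the way, as in a realistically sized study
        sample, control = sim.simulate_chip_reads(g, prog, depth=160_000, seed=33,
                                                  stages=("E",))["E"]
        peaks, _ = pk.call_peaks_pipeline(sample, control, g, stage="E")
        truth = planted_summits(g, prog, "E")
        metrics = evaluate_peak_recovery(peaks, truth, summit_tol=100)
        assert metrics["recovery"] >= 0.9
        assert metrics["false_fraction"] <= 0.05


class TestIntersectPeaks:
    def _peaks(self, intervals):
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        df["peak_id"] = [f"p{i}" for i in range(len(df))]
        df["enrichment"] = 5.0
        df["summit"] = (df["start"] + df["end"]) // 2
        df["support"] = 100
        df["balance"] = 0.1
        df["stage"] = "E"
        return df

    def test_identity_when_external_equals_internal(self):
        internal = self._peaks([("chr1", 100, 300), ("chr2", 50, 80)])
        out = pk.intersect_peaks(internal, internal[["chrom", "start", "end"]])
        pd.testing.assert_frame_equal(out, internal)

    def test_empty_external_removes_everything(self):
        internal = self._peaks([("chr1", 100, 300)])
        out = pk.intersect_peaks(internal, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert len(out) == 0

    def test_none_external_is_noop(self):
        internal = self._peaks([("chr1", 100, 300)])
        assert pk.intersect_peaks(internal, None) is internal

    def test_matches_quadratic_overlap_oracle(self, rng):
        internal = self._peaks([
            ("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 5_000, 40), rng.integers(10, 400, 40))
        ])
        external = pd.DataFrame({
            "chrom": "chr1",
            "start": rng.integers(0, 5_000, 25),
        })
        external["end"] = external["start"] + rng.integers(10, 400, 25)
        out = pk.intersect_peaks(internal, external)
        expected = [
            any(r.start < e.end and e.start < r.end for e in external.itertuples(index=False))
            for r in internal.itertuples(index=False)
        ]
        assert list(internal.index[expected]) == list(out.index)
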