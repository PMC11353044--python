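"""GC correction, per-bin scores, run-based segmentation, recurrence labels."""

import numpy as np
import pandas as pd
import pytest

from stemdrift.cnv import (BinScores, CnvSegment, annotate_recurrence,
                           compute_scores, default_catalog, gc_correct,
                           karyotype_status, segment)
from stemdrift.core import GenomicInterval

from conftest import make_coverage, n_bins, toy_genome  # noqa: F401


def scores_from_z(z, chrom="chr1", bin_size=50_000, log2r=None):
    """Construct BinScores directly from a z array (for segmentation tests)."""
    z = np.asarray(z, dtype=float)
    table = pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(len(z)) * bin_size,
        "end": (np.arange(len(z)) + 1) * bin_size,
        "gc": 0.4,
        "corrected": 1.0,
        "fold_change": 1.0,
        "log2ratio": np.where(z > 0, 0.585, np.where(z < 0, -1.0, 0.0))
        if log2r is None else log2r,
        "z": z,
    })
    return BinScores("synthetic", table, median_raw_count=100.0)


def brute_force_runs(z, z_thresh=3.0, merge_gap=4, min_bins=10):
    """Oracle: enumerate maximal same-direction runs allowing short gaps."""
    z = np.asarray(z, dtype=float)
    out = []
    for direction in (1, -1):
        qualify = np.where(direction * z > z_thresh)[0]
        if len(qualify) == 0:
            continue
        groups = [[qualify[0]]]
        for idx in qualify[1:]:
            if idx - groups[-1][-1] - 1 <= merge_gap:
                groups[-1].append(idx)
            else:
                groups.append([idx])
        for g in groups:
            span = g[-1] - g[0] + 1
            if span >= min_bins:
                out.append((g[0], g[-1], direction))
    return sorted(out)


class TestGcCorrect:
    def test_recovers_generating_curve_exactly_on_discrete_gc(
            self, toy_genome):
        """Counts exactly proportional to a bias curve evaluated on 10
        discrete GC values: per-stratum medians hit the curve's nodes, so
        correction is exact and every bin comes out at 1."""
        nb = n_bins(toy_genome)
        rng = np.random.default_rng(1)
        gc_levels = np.linspace(0.3, 0.6, 10)
        gc = rng.choice(gc_levels, size=nb)
        bias = 1.0 - 2.0 * (gc - 0.45) ** 2
        counts = 200.0 * bias
        cov = make_coverage(toy_genome, counts, gc)
        scores = gc_correct(cov)
        assert np.allclose(scores.table["corrected"], 1.0, atol=1e-6)

    def test_constant_gc_is_identity_up_to_scalar(self, toy_genome):
        nb = n_bins(toy_genome)
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=nb).astype(float)
        cov = make_coverage(toy_genome, counts, np.full(nb, 0.41))
        scores = gc_correct(cov)
        ratio = counts / scores.table["corrected"].to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_median_fold_change_normalized_to_one(self, toy_genome):
        nb = n_bins(toy_genome)
        rng = np.random.default_rng(3)
        gc = np.clip(rng.normal(0.41, 0.05, nb), 0.3, 0.6)
        counts = rng.poisson(100 * (1 - 1.5 * (gc - 0.45) ** 2))
        scores = compute_scores(gc_correct(make_coverage(toy_genome, counts, gc)))
        assert np.median(scores.table["fold_change"]) == pytest.approx(
            1.0, abs=1e-6)

    def test_all_zero_coverage_rejected(self, toy_genome):
        nb = n_bins(toy_genome)
        cov = make_coverage(toy_genome, np.zeros(nb), np.full(nb, 0.4))
        with pytest.raises(ValueError, match="all-zero"):
            gc_correct(cov)

    def test_too_few_bins_rejected(self):
        tiny = {"chr1": 5_000_000}
        cov = make_coverage(tiny, np.full(100, 50), np.full(100, 0.4))
        with pytest.raises(ValueError, match="populated bins"):
            gc_correct(cov)


class TestComputeScores:
    def test_log2ratio_closed_forms(self):
        sc = scores_from_z([0.0] * 4)
        sc.table["corrected"] = [1.5, 0.5, 1.0, 2.0]
        del sc.table["fold_change"], sc.table["log2ratio"], sc.table["z"]
        out = compute_scores(sc)
        assert out.table["log2ratio"].tolist() == pytest.approx(
            [np.log2(1.5), -1.0, 0.0, 1.0])
        assert out.table["log2ratio"][0] == pytest.approx(0.585, abs=5e-4)

    def test_noiseless_diploid_gives_all_zero_scores(self, toy_genome):
        nb = n_bins(toy_genome)
        cov = make_coverage(toy_genome, np.full(nb, 150.0), np.full(nb, 0.4))
        out = compute_scores(gc_correct(cov))
        assert np.allclose(out.table["fold_change"], 1.0)
        assert np.allclose(out.table["log2ratio"], 0.0)
        assert np.allclose(out.table["z"], 0.0)

    def test_diploid_noise_z_tail_below_one_percent(self, toy_genome):
        nb = n_bins(toy_genome)
        rng = np.random.default_rng(4)
        counts = rng.poisson(120, size=nb)
        out = compute_scores(gc_correct(
            make_coverage(toy_genome, counts, np.full(nb, 0.4))))
        assert np.mean(np.abs(out.table["z"]) > 3) < 0.01


class TestSegment:
    def test_no_signal_gives_no_segments(self):
        assert segment(scores_from_z(np.zeros(200))) == []

    def test_noiseless_injected_gain_recovered_exactly(self):
        z = np.zeros(200)
        z[60:100] = 10.0  # 40 contiguous bins, 2 Mb
        segs = segment(scores_from_z(z))
        assert len(segs) == 1
        s = segs[0]
        assert (s.interval.start, s.interval.end) == (60 * 50_000, 100 * 50_000)
        assert s.direction == "gain" and s.n_bins == 40
        assert s.mean_log2ratio == pytest.approx(0.585, abs=5e-4)

    def test_matches_brute_force_enumeration_on_random_inputs(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            z = rng.normal(0, 1.5, size=int(rng.integers(40, 200)))
            # sprinkle strong runs
            for _k in range(rng.integers(0, 3)):
                i = int(rng.integers(0, len(z) - 15))
                width = int(rng.integers(5, 30))
                z[i:i + width] += rng.choice([-8, 8])
            segs = segment(scores_from_z(z))
            got = sorted((s.interval.start // 50_000,
                          s.interval.end // 50_000 - 1,
                          1 if s.direction == "gain" else -1) for s in segs)
            assert got == brute_force_runs(z)

    def test_lowering_threshold_never_removes_called_span(self):
        rng = np.random.default_rng(10)
        z = rng.normal(0, 1.5, 300)
        z[50:80] += 8
        z[200:240] -= 8
        strict = segment(scores_from_z(z), z_thresh=3.5)
        loose = segment(scores_from_z(z), z_thresh=2.5)

        def covered(seg, segs):
            return any(s.direction == seg.direction
                       and s.interval.start <= seg.interval.start
                       and s.interval.end >= seg.interval.end for s in segs)

        for seg in strict:
            assert covered(seg, loose)

    def test_short_runs_below_min_bins_dropped(self):
        z = np.zeros(100)
        z[10:19] = 10.0  # 9 bins < 10
        assert segment(scores_from_z(z)) == []
        z[10:20] = 10.0
        assert len(segment(scores_from_z(z))) == 1

    def test_invariant_to_appended_blacklisted_bins(self, toy_genome):
        nb = n_bins(toy_genome)
        rng = np.random.default_rng(12)
        counts = rng.poisson(120, size=nb).astype(float)
        counts[100:130] *= 1.5
        gc = np.full(nb, 0.4)
        cov = make_coverage(toy_genome, counts, gc)
        base = segment(compute_scores(gc_correct(cov)))
        # same data plus a blacklisted tail on a new chromosome
        genome2 = dict(toy_genome, chr9=2_000_000)
        nb2 = n_bins(genome2)
        counts2 = np.concatenate([counts, np.zeros(nb2 - nb)])
        black = np.zeros(nb2, dtype=bool)
        black[nb:] = True
        cov2 = make_coverage(genome2, counts2, np.full(nb2, 0.4),
                             blacklisted=black)
        with_black = segment(compute_scores(gc_correct(cov2)))
        assert [(s.interval, s.direction) for s in base] == \
            [(s.interval, s.direction) for s in with_black]

    def test_sex_chromosomes_not_called_by_default(self):
        z = np.zeros(60)
        z[10:40] = 10.0
        sc = scores_from_z(z, chrom="chrX")
        assert segment(sc) == []
        assert len(segment(sc, call_sex_chroms=True)) == 1


class TestAnnotateRecurrence:
    def seg(self, chrom, start, end, direction="gain"):
        return CnvSegment(GenomicInterval(chrom, start, end), direction,
                          0.58 if direction == "gain" else -1.0, 30)

    def test_gain_spanning_bcl2l1_labelled_20q(self):
        out = annotate_recurrence([self.seg("chr20", 29_370_000, 35_000_000)])
        assert out[0].recurrent_label == "20q11.21/BCL2L1"

    def test_terminal_1q_gain_spanning_mdm4_labelled(self):
        out = annotate_recurrence([self.seg("chr1", 203_000_000, 249_250_621)])
        assert out[0].recurrent_label == "1q/MDM4"

    def test_18q_loss_labelled_and_gain_not(self):
        loss = self.seg("chr18", 70_000_000, 78_077_248, "loss")
        gain = self.seg("chr18", 70_000_000, 78_077_248, "gain")
        out = annotate_recurrence([loss, gain])
        assert out[0].recurrent_label == "18q/SALL3"
        assert out[1].recurrent_label is None

    def test_9p_like_gain_is_rare(self):
        out = annotate_recurrence([self.seg("chr9", 0, 33_000_000)])
        assert out[0].recurrent_label is None

    def test_20q_gain_missing_driver_not_labelled(self):
        # overlaps the 20q11.21 region but stops short of the BCL2L1 locus
        out = annotate_recurrence([self.seg("chr20", 29_370_000, 30_000_000)])
        assert out[0].recurrent_label is None

    def test_catalog_valid_on_hg19(self, hg19):
        default_catalog().validate(hg19)


class TestKaryotypeStatus:
    def test_no_segments_is_normal(self):
        assert karyotype_status([]) == "normal"

    def test_any_segment_is_abnormal(self):
        seg = CnvSegment(GenomicInterval("chr20", 29_370_000, 30_445_000),
                         "gain", 0.58, 21)
        assert karyotype_status([seg]) == "abnormal"
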