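"""Clonal-evolution simulator: dynamics, determinism, rendered observables."""

import numpy as np
import pytest

from stemdrift.cnv import compute_scores, gc_correct
from stemdrift.core import GenomicInterval
from stemdrift.integrate import expected_af, AfModelInput
from stemdrift.sim import (CoverageParams, GermlineVariant, MutationEvent,
                           SimParams, gc_bias_quadratic, make_gc_track,
                           make_panel, render_coverage, render_variants,
                           simulate_cohort, simulate_line)
from stemdrift.stats import logistic_acquisition_regression, \
    poisson_load_regression

from conftest import single_clone_history


def null_params(seed=0, **kw):
    return SimParams(p_cnv_recurrent=0.0, p_cnv_rare=0.0, p_snv=0.0,
                     seed=seed, **kw)


class TestDynamics:
    def test_no_mutation_keeps_single_wild_type_clone(self):
        hist = simulate_line(null_params(), "L0")
        for frac in hist.fractions:
            assert frac == {0: 1.0}
        assert hist.event_log == []

    def test_fractions_sum_to_one_every_passage(self):
        for seed in range(5):
            hist = simulate_line(SimParams(seed=seed), f"L{seed}")
            for frac in hist.fractions:
                assert sum(frac.values()) == pytest.approx(1.0, abs=1e-9)

    def test_child_genotype_is_superset_of_parent(self):
        hist = simulate_line(SimParams(seed=3, n_passages=40), "L3")
        for cid, clone in hist.clones.items():
            if clone.parent_id is None:
                continue
            parent_events = {e.event_id for e in hist.events_of(clone.parent_id)}
            child_events = {e.event_id for e in hist.events_of(cid)}
            assert parent_events < child_events

    def test_determinism_bit_identical(self):
        p = SimParams(seed=17)
        h1 = simulate_line(p, "L")
        h2 = simulate_line(p, "L")
        assert h1.fractions == h2.fractions
        assert [(pa, c, e.event_id, e.kind) for pa, c, e in h1.event_log] == \
            [(pa, c, e.event_id, e.kind) for pa, c, e in h2.event_log]
        gt = make_gc_track({"chr1": 20_000_000}, seed=1)
        c1 = render_coverage(h1, 10, gt, seed=5)
        c2 = render_coverage(h2, 10, gt, seed=5)
        assert (c1.bins["count"] == c2.bins["count"]).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(p_snv=1.5)
        with pytest.raises(ValueError):
            SimParams(bottleneck_size=5)
        with pytest.raises(ValueError):
            SimParams(snv_rate_multiplier_given_driver=0.5)

    def test_driver_mean_trajectory_nondecreasing(self):
        """Once a driver clone appears, selection makes its expected
        fraction non-decreasing: the appearance-aligned mean trajectory
        over replicates must rise monotonically (within noise)."""
        trajs = []
        for seed in range(200):
            p = SimParams(seed=seed, n_passages=30, p_cnv_recurrent=0.05,
                          p_cnv_rare=0.0, p_snv=0.0, s_recurrent=0.5)
            hist = simulate_line(p, "T")
            fracs = [hist.driver_fraction(t) for t in range(31)]
            first = next((t for t, f in enumerate(fracs) if f > 0), None)
            if first is not None:
                aligned = fracs[first:]
                trajs.append(aligned + [np.nan] * (31 - len(aligned)))
        mat = np.array(trajs, dtype=float)
        assert len(trajs) > 100
        # only positions with enough replicates carry a stable mean
        n_contrib = np.sum(~np.isnan(mat), axis=0)
        well_sampled = n_contrib >= 30
        mean_traj = np.nanmean(mat[:, well_sampled], axis=0)
        diffs = np.diff(mean_traj)
        assert np.all(diffs > -0.02)
        assert mean_traj[-1] > mean_traj[0]

    def test_driver_takeover_with_strong_selection(self):
        """s = 0.5 over 40 passages: the driver sweeps to near-fixation."""
        finals = []
        for seed in range(30):
            p = SimParams(seed=seed, n_passages=40, p_cnv_recurrent=0.05,
                          p_cnv_rare=0.0, p_snv=0.0, s_recurrent=0.5)
            finals.append(simulate_line(p, "T").driver_fraction(40))
        assert np.median(finals) > 0.9

    def test_de_novo_snv_count_increases_with_rank(self):
        """Cumulative acquisition: SNVs segregating above 1% at sampled
        passages increase with sample rank (positive regression slope)."""
        pts = []
        for seed in range(200):
            p = SimParams(seed=seed)
            hist = simulate_line(p, f"L{seed}")
            sched = [10, 30, 50]
            for rank, passage in enumerate(sched, 1):
                n = sum(1 for _, _, e in hist.event_log
                        if e.kind == "snv"
                        and hist.variant_af(passage, e) > 0.01)
                pts.append((rank, n))
        r = poisson_load_regression(pts, predictor="rank")
        assert r.slope > 0
        assert r.p < 0.01

    def test_constant_rate_no_passage_trend_in_acquisition(self):
        """With a constant per-passage SNV probability, whether a new SNV
        arose in a sampling interval shows no trend in absolute passage."""
        pts = []
        for seed in range(300):
            p = SimParams(seed=seed, p_cnv_recurrent=0.0, p_cnv_rare=0.0,
                          p_snv=0.05)
            hist = simulate_line(p, f"L{seed}")
            sched = [10, 30, 50]
            prev_events: set[int] = set()
            for passage in sched:
                seen = {e.event_id for _, _, e in hist.event_log
                        if e.kind == "snv"
                        and hist.variant_af(passage, e) > 0.01}
                if passage != sched[0]:
                    pts.append((passage, int(bool(seen - prev_events))))
                prev_events |= seen
        r = logistic_acquisition_regression(pts, predictor="passage")
        lo, hi = r.ci95
        assert lo <= 0 <= hi


class TestRenderCoverage:
    def test_deterministic_limit_equals_base_count(self):
        genome = {"chr1": 20_000_000}
        hist = simulate_line(null_params(), "L", genome=genome,
                             panel=make_panel(genome, n_genes=5))
        gt = make_gc_track(genome, seed=2)
        cov = render_coverage(hist, 5, gt, CoverageParams(dispersion=0.0))
        assert (cov.bins["count"] == 113).all()

    @pytest.mark.parametrize("fraction, expected_ratio", [
        (1.0, 1.5),    # clonal single-copy gain
        (0.5, 1.25),   # 50% mosaic gain
    ])
    def test_gain_mean_count_ratio(self, fraction, expected_ratio):
        genome = {"chr1": 60_000_000}  # 1200 bins
        gain = MutationEvent(1, "cnv_gain",
                             region=GenomicInterval("chr1", 5_000_000,
                                                    10_000_000),
                             copies_delta=1)
        hist = single_clone_history(gain, genome, fraction=fraction)
        gt = make_gc_track(genome, seed=3)
        ratios = []
        for seed in range(5):
            cov = render_coverage(hist, 1, gt, seed=seed)
            counts = cov.bins["count"].to_numpy(dtype=float)
            in_gain = (cov.bins["start"] >= 5_000_000) & \
                (cov.bins["end"] <= 10_000_000)
            ratios.append(counts[in_gain].mean() / counts[~in_gain].mean())
        assert np.mean(ratios) == pytest.approx(expected_ratio, rel=0.02)

    def test_gc_bias_shapes_expected_counts(self):
        genome = {"chr1": 60_000_000}
        hist = single_clone_history(None, genome)
        gt = make_gc_track(genome, seed=4)
        bias = gc_bias_quadratic(amplitude=0.2)
        cov = render_coverage(hist, 1, gt,
                              CoverageParams(dispersion=0.0, gc_bias=bias))
        expected = np.round(113.0 * bias(gt["gc"].to_numpy())).astype(int)
        assert (cov.bins["count"].to_numpy() == expected).all()

    def test_bin_grid_mismatch_rejected(self):
        hist = single_clone_history(None, {"chr1": 20_000_000})
        gt = make_gc_track({"chr7": 10_000_000}, seed=5)
        with pytest.raises(ValueError, match="chr7"):
            render_coverage(hist, 1, gt)

    def test_gc_corrected_recovery_of_mosaic_gain(self):
        """End to end: 20% GC bias plus a clonal gain; after correction the
        diploid bins centre on fold change 1.00 and gain bins on 1.50.

        Uses the full genome so the gained region is a realistically small
        fraction of bins and does not perturb the normalization median."""
        from stemdrift.core import GENOME_HG19 as genome
        gain = MutationEvent(1, "cnv_gain",
                             region=GenomicInterval("chr2", 20_000_000,
                                                    30_000_000),
                             copies_delta=1)
        hist = single_clone_history(gain, genome)
        gt = make_gc_track(genome, seed=6)
        diploid_means, gain_means = [], []
        for seed in range(10):
            cov = render_coverage(
                hist, 1, gt,
                CoverageParams(gc_bias=gc_bias_quadratic()), seed=seed)
            sc = compute_scores(gc_correct(cov))
            fold = sc.table["fold_change"].to_numpy()
            in_gain = ((sc.table["chrom"] == "chr2")
                       & (sc.table["start"] >= 20_000_000)
                       & (sc.table["end"] <= 30_000_000)).to_numpy()
            autosomal = sc.autosomal_mask()
            diploid_means.append(fold[autosomal & ~in_gain].mean())
            gain_means.append(fold[in_gain].mean())
        assert np.mean(diploid_means) == pytest.approx(1.00, abs=0.02)
        assert np.mean(gain_means) == pytest.approx(1.50, abs=0.03)


class TestRenderVariants:
    def _germline_hist(self, genome, zygosity="heterozygous", event=None):
        gv = GermlineVariant(gene="PG0001", chrom="chr1", pos=1_000_000,
                             ref="A", alt="T", zygosity=zygosity, hap=0)
        return single_clone_history(event, genome, germline=[gv])

    def test_het_diploid_af_centers_on_half(self):
        genome = {"chr1": 20_000_000}
        hist = self._germline_hist(genome)
        panel = [p for p in make_panel(genome, n_genes=1)]
        panel[0] = panel[0].__class__("PG0001",
                                      GenomicInterval("chr1", 900_000,
                                                      1_100_000))
        afs = [render_variants(hist, 1, panel, seed=s)[0].af
               for s in range(500)]
        assert 0.49 <= np.mean(afs) <= 0.51

    def test_variant_outside_panel_not_observed(self):
        genome = {"chr1": 20_000_000}
        hist = self._germline_hist(genome)
        far_panel = [make_panel(genome, n_genes=1)[0].__class__(
            "OTHER", GenomicInterval("chr1", 5_000_000, 5_100_000))]
        assert render_variants(hist, 1, far_panel, seed=1) == []

    def test_extinct_clone_variant_absent(self):
        genome = {"chr1": 20_000_000}
        snv = MutationEvent(1, "snv", gene="PG0001", chrom="chr1",
                            pos=1_000_000, ref="A", alt="T",
                            effect="missense", deleterious=False,
                            cosmic="none")
        hist = single_clone_history(snv, genome, fraction=1.0)
        hist.fractions[1] = {0: 1.0}  # clone swept away before sampling
        panel = [make_panel(genome, n_genes=1)[0].__class__(
            "PG0001", GenomicInterval("chr1", 900_000, 1_100_000))]
        assert render_variants(hist, 1, panel, seed=1) == []

    def test_duplicated_haplotype_germline_af_centers_on_two_thirds(self):
        """Germline het whose haplotype is duplicated in a full-takeover
        clone: analytic AF 2/3 (the published case observed ~0.7)."""
        genome = {"chr1": 20_000_000}
        gain = MutationEvent(1, "cnv_gain",
                             region=GenomicInterval("chr1", 0, 5_000_000),
                             copies_delta=1, hap=0)
        hist = self._germline_hist(genome, event=gain)
        gv = hist.germline[0]
        true_af = hist.variant_af(1, gv)
        assert true_af == pytest.approx(2 / 3, abs=1e-12)
        assert true_af == pytest.approx(
            expected_af(AfModelInput(3, 2, 1, 1.0)), abs=1e-12)
        panel = [make_panel(genome, n_genes=1)[0].__class__(
            "PG0001", GenomicInterval("chr1", 900_000, 1_100_000))]
        afs = [render_variants(hist, 1, panel, seed=s)[0].af
               for s in range(300)]
        assert np.mean(afs) == pytest.approx(2 / 3, abs=0.01)

    def test_de_novo_snv_on_duplicated_hap_is_single_copy(self):
        """An SNV acquired after the gain sits on one of three copies."""
        genome = {"chr1": 20_000_000}
        gain = MutationEvent(1, "cnv_gain",
                             region=GenomicInterval("chr1", 0, 5_000_000),
                             copies_delta=1, hap=0)
        snv = MutationEvent(2, "snv", gene="PG0001", chrom="chr1",
                            pos=1_000_000, ref="A", alt="T", hap=0,
                            effect="missense", deleterious=False,
                            cosmic="none")
        hist = single_clone_history(gain, genome)
        # graft a grandchild clone carrying the SNV after the gain
        from stemdrift.sim import Clone
        hist.clones[2] = Clone(2, 1, snv)
        hist.fractions[1] = {2: 1.0}
        hist.event_log.append((1, 2, snv))
        m, c = hist.locus_config(2, snv)
        assert (m, c) == (1.0, 3)
        assert hist.variant_af(1, snv) == pytest.approx(1 / 3)


class TestCohort:
    def test_cohort_reproducible_and_sampled_ranks_increasing(self):
        p = SimParams(seed=5, n_passages=30)
        c1 = simulate_cohort(3, p)
        c2 = simulate_cohort(3, p)
        for (h1, s1), (h2, s2) in zip(c1, c2):
            assert s1 == s2 and h1.fractions == h2.fractions
            assert s1 == sorted(s1) and len(set(s1)) == 3
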