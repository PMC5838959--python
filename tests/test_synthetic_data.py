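"""Generators: determinism, configured moments, planted ground truth."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import promoterome.synthetic_data as sd
from promoterome import motif_scanning as ms
from promoterome.io_formats import GenomicRegion
from promoterome.qpcr_quant import fold_change


def small_config(**kw):
    kw.setdefault("seed", 42)
    return sd.SimulationConfig(**kw)


class TestExpressionMatrix:
    def test_noise_free_limit_reproduces_means(self):
        cfg = small_config(lognormal_sigma=1e-12)
        expr, plan = sd.gen_expression_matrix(cfg)
        broad = plan[plan.kind == "broad"].iloc[0]["tss_id"]
        tissue = expr.category_values("tissue")
        np.testing.assert_allclose(tissue.loc[broad], 20.0, rtol=1e-9)

    def test_zero_group_mean_yields_exact_zeros(self):
        cfg = small_config()
        plan = sd.default_tss_plan(cfg).head(2).copy()
        plan["mean_in_organ"] = [10.0, 0.0]
        plan["mean_elsewhere"] = [10.0, 0.0]
        plan["mean_pc"] = [5.0, 0.0]
        plan["mean_cl"] = [5.0, 0.0]
        plan["merge_partner_of"] = ""
        expr, _ = sd.gen_expression_matrix(cfg, plan)
        assert (expr.values.iloc[1] == 0.0).all()
        assert (expr.values.iloc[0] > 0.0).all()

    def test_determinism_under_fixed_seed(self):
        a, _ = sd.gen_expression_matrix(small_config())
        b, _ = sd.gen_expression_matrix(small_config())
        assert a.values.equals(b.values)

    def test_column_means_match_configured_moments(self):
        """Monte-Carlo: observed means within 3 s.e. of the log-normal
        expectation mean * exp(sigma^2 / 2)."""
        cfg = small_config()
        expr, plan = sd.gen_expression_matrix(cfg)
        sigma = cfg.lognormal_sigma
        factor = np.exp(sigma**2 / 2)
        sd_factor = np.sqrt(np.exp(2 * sigma**2) - np.exp(sigma**2))
        broad_ids = plan[(plan.kind == "broad")
                         & (plan.merge_partner_of == "")]["tss_id"]
        tissue = expr.category_values("tissue")
        values = tissue.loc[broad_ids].to_numpy().ravel()
        expected = 20.0 * factor
        se = 20.0 * sd_factor / np.sqrt(values.size)
        assert abs(values.mean() - expected) <= 3 * se


class TestPromoterWindows:
    def test_no_planting_and_gc_within_binomial_bounds(self):
        cfg = small_config(gc_content=0.5)
        pfm = sd.default_xbox_pfm()[2]
        seqs, _, truth = sd.gen_promoter_windows(cfg, pfm, 1, 0.0, None)
        (seq,) = seqs.values()
        assert len(seq) == 7001 and truth.empty
        gc = sum(c in "GC" for c in seq)
        # binomial 99% bound around n/2
        bound = 2.58 * np.sqrt(7001 * 0.25)
        assert abs(gc - 7001 / 2) <= bound

    def test_folded_normal_offset_moment(self):
        """Planted offsets under normal(0,150): mean |offset| over 500
        windows matches 150 * sqrt(2/pi) within 10%."""
        cfg = small_config(window_up=1000, window_down=1000)
        pfm = sd.default_xbox_pfm()[2]
        _, _, truth = sd.gen_promoter_windows(
            cfg, pfm, 500, 1.0, ("normal", 0.0, 150.0))
        mean_abs = truth["offset"].abs().mean()
        expected = 150.0 * np.sqrt(2 / np.pi)
        assert abs(mean_abs - expected) <= 0.1 * expected

    def test_consensus_pfm_planted_instance_recovered_by_scan(self):
        """A consensus-only PFM planted at -100 yields a rel-score-1 hit
        at -100."""
        consensus = "GTACGTACGTAC"
        counts = np.zeros((4, len(consensus)))
        for j, b in enumerate(consensus):
            counts["ACGT".index(b), j] = 1.0
        cfg = small_config(window_up=500, window_down=200)
        law = ("uniform", -100, -100)
        seqs, _, truth = sd.gen_promoter_windows(cfg, counts, 1, 1.0, law)
        if truth.empty:  # Poisson(1) drew zero instances: force via rate
            seqs, _, truth = sd.gen_promoter_windows(
                small_config(seed=43, window_up=500, window_down=200),
                counts, 1, 5.0, law)
        pwm = ms.build_pwm(counts, pseudocount=0.01)
        (seq,) = seqs.values()
        hits = ms.scan(pwm, seq, 0.999, origin=500)
        assert any(h.offset == -100 and h.rel_score == pytest.approx(1.0)
                   for h in hits)

    def test_instance_overrunning_window_raises(self):
        cfg = small_config(window_up=100, window_down=100)
        pfm = sd.default_xbox_pfm()[2]
        with pytest.raises(ValueError, match="100 tries"):
            sd.gen_promoter_windows(cfg, pfm, 5, 5.0,
                                    ("uniform", 500, 600))


class TestAnnotation:
    def test_offsets_and_tolerance_flags(self):
        cfg = small_config(annotation_offsets=(0, 30, -60, 200))
        tss = [GenomicRegion("chr1", 1000 * (i + 1), 1000 * (i + 1) + 20,
                             "+", f"t{i}") for i in range(4)]
        regions, truth = sd.gen_annotation(cfg, tss)
        assert [r.tss_point - t.tss_point
                for r, t in zip(regions, tss)] == [0, 30, -60, 200]
        assert list(truth["within_tolerance"]) == [True, True, False, False]

    def test_minus_strand_offset_is_transcription_oriented(self):
        cfg = small_config(annotation_offsets=(51,))
        tss = [GenomicRegion("chr1", 1000, 1020, "-", "t")]
        (region,), truth = sd.gen_annotation(cfg, tss)
        # downstream on '-' means lower coordinate
        assert region.tss_point == tss[0].tss_point - 51
        assert not truth["within_tolerance"].iloc[0]


class TestEnhancers:
    def _run(self, rho, seed=42):
        cfg = small_config(seed=seed, enhancer_rho=rho)
        expr, plan = sd.gen_expression_matrix(cfg)
        tss = [GenomicRegion(r.chrom, int(r.start), int(r.end), r.strand,
                             r.tss_id) for r in plan.itertuples()]
        return cfg, expr, sd.gen_enhancers(cfg, expr, tss)

    def test_rho_one_is_monotone_transform(self):
        _, expr, (regions, values, truth) = self._run(1.0)
        row = truth[truth.target_rho == 1.0].iloc[0]
        x = expr.values.loc[row.paired_tss].to_numpy()
        y = values.loc[row.enhancer_id].to_numpy()
        assert spearmanr(x, y).statistic == pytest.approx(1.0)

    def test_rho_zero_uncorrelated(self):
        rhos = []
        for seed in range(40, 50):
            _, expr, (regions, values, truth) = self._run(0.8, seed=seed)
            for row in truth[truth.target_rho == 0.0].itertuples():
                x = expr.values.loc[row.paired_tss].to_numpy()
                y = values.loc[row.enhancer_id].to_numpy()
                rhos.append(abs(spearmanr(x, y).statistic))
        assert np.mean(rhos) < 0.1

    def test_rho_recovered_within_tolerance(self):
        achieved = []
        for seed in range(40, 45):
            _, expr, (regions, values, truth) = self._run(0.8, seed=seed)
            for row in truth[truth.target_rho == 0.8].itertuples():
                x = expr.values.loc[row.paired_tss].to_numpy()
                y = values.loc[row.enhancer_id].to_numpy()
                achieved.append(spearmanr(x, y).statistic)
        assert 0.7 <= np.mean(achieved) <= 0.9


class TestQpcrTable:
    def test_noise_free_delta_ct_closed_form(self):
        cfg = small_config(ct_noise=0.0,
                           qpcr_truth=[("T", 2.0, 2.0)],
                           qpcr_references=[("R1", 2.0), ("R2", 2.0)])
        ct, eff, _ = sd.gen_qpcr_table(cfg)
        t = ct[ct.gene == "T"].groupby(["condition", "bio_replicate"])["ct"]
        means = t.mean().unstack(level=0)
        np.testing.assert_allclose(means["scr"] - means["test"], 1.0)

    def test_fc_one_gives_zero_delta_ct(self):
        cfg = small_config(ct_noise=0.0, qpcr_truth=[("T", 1.0, 2.0)],
                           qpcr_references=[("R1", 2.0), ("R2", 2.0)])
        ct, _, _ = sd.gen_qpcr_table(cfg)
        t = ct[ct.gene == "T"].groupby(["condition", "bio_replicate"])["ct"]
        means = t.mean().unstack(level=0)
        np.testing.assert_allclose(means["scr"] - means["test"], 0.0)

    def test_non_dyadic_efficiency_closed_form(self):
        cfg = small_config(ct_noise=0.0, qpcr_truth=[("T", 2.5527, 1.9)],
                           qpcr_references=[("R1", 2.0), ("R2", 2.0)])
        ct, eff, _ = sd.gen_qpcr_table(cfg)
        t = ct[ct.gene == "T"].groupby(["condition", "bio_replicate"])["ct"]
        means = t.mean().unstack(level=0)
        expected = np.log(2.5527) / np.log(1.9)
        np.testing.assert_allclose(means["scr"] - means["test"], expected,
                                   rtol=1e-9)
        assert expected == pytest.approx(1.46007, abs=1e-4)

    def test_quantification_recovers_truth_noise_free(self):
        cfg = small_config(ct_noise=0.0)
        ct, eff, truth = sd.gen_qpcr_table(cfg)
        effd = dict(zip(eff["gene"], eff["efficiency"]))
        for row in truth[~truth.gene.isin(["HPRT1", "HSPCB"])].itertuples():
            fcs = fold_change(ct, effd, row.gene)
            np.testing.assert_allclose(fcs, row.true_fc, rtol=1e-9)


def test_profile_panel_contains_xbox_and_is_deterministic():
    panel_a = sd.gen_profile_panel(small_config(), n_profiles=10)
    panel_b = sd.gen_profile_panel(small_config(), n_profiles=10)
    assert panel_a[0][0] == "SYN0001"
    assert len(panel_a) == 10
    for (ida, _, ca), (idb, _, cb) in zip(panel_a, panel_b):
        assert ida == idb
        np.testing.assert_array_equal(ca, cb)
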