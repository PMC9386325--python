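"""Telomere-anchored windows, moderated t and preranked enrichment."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from telohallmark import subtelo, synthdata
from telohallmark.subtelo import (
    assign_genes,
    build_windows,
    compare_compartments,
    fit_variance_prior,
    moderated_t,
    preranked_enrichment,
    running_sum_es,
)


def chrom_table(rows):
    return pd.DataFrame(rows, columns=["name", "length", "cen_start", "cen_end", "acrocentric"])


class TestWindows:
    def test_hand_tiling_23mb_chromosome(self):
        chrom = chrom_table([("chr1", 23_000_000, 12_000_000, 13_000_000, False)])
        win = build_windows(chrom)
        p = win[win.arm == "p"].sort_values("index")
        q = win[win.arm == "q"].sort_values("index")
        assert list(zip(p.start, p.end)) == [
            (0, 5_000_000), (5_000_000, 10_000_000), (10_000_000, 12_000_000)
        ]
        assert list(zip(q.start, q.end)) == [
            (18_000_000, 23_000_000), (13_000_000, 18_000_000)
        ]
        assert win[win.subtelomeric]["index"].eq(0).all()

    def test_short_arm_single_partial_window(self):
        chrom = chrom_table([("chr1", 20_000_000, 3_000_000, 16_000_000, False)])
        win = build_windows(chrom)
        p = win[win.arm == "p"]
        assert len(p) == 1 and (p.iloc[0].start, p.iloc[0].end) == (0, 3_000_000)

    def test_acrocentric_p_arm_skipped(self):
        chrom = chrom_table([("chr13", 23_000_000, 12_000_000, 13_000_000, True)])
        win = build_windows(chrom)
        assert (win.arm == "q").all()

    def test_windows_never_cross_chromosomes(self):
        chrom = chrom_table(
            [
                ("chr1", 23_000_000, 12_000_000, 13_000_000, False),
                ("chr2", 30_000_000, 14_000_000, 15_000_000, False),
            ]
        )
        win = build_windows(chrom)
        for _, w in win.iterrows():
            length = chrom.set_index("name").loc[w.chrom, "length"]
            assert 0 <= w.start < w.end <= length

    def test_invalid_window_size(self):
        with pytest.raises(ValueError):
            build_windows(chrom_table([("c", 10, 4, 5, False)]), window_size=0)


class TestGeneAssignment:
    CHROM = chrom_table([("chr1", 23_000_000, 12_000_000, 13_000_000, False)])

    def _genes(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "strand"])

    def test_midpoint_boundary_goes_to_upper_window(self):
        genes = self._genes([("chr1", 4_900_000, 5_100_000, "gA", "+")])
        win = build_windows(self.CHROM)
        _, member = assign_genes(genes, win, self.CHROM, min_genes=1)
        assert member["gA"] == "chr1p_w1"  # midpoint exactly 5 Mb

    def test_min_gene_filter_sets_retained(self):
        genes = self._genes(
            [("chr1", 1000 * i, 1000 * i + 500, f"g{i}", "+") for i in range(14)]
        )
        win = build_windows(self.CHROM)
        win2, _ = assign_genes(genes, win, self.CHROM, min_genes=15)
        assert not win2.loc["chr1p_w0", "retained"]
        assert win2.loc["chr1p_w0", "n_genes"] == 14

    def test_gene_beyond_chromosome_rejected(self):
        genes = self._genes([("chr1", 22_999_000, 24_000_000, "g", "+")])
        with pytest.raises(ValueError, match="beyond"):
            assign_genes(genes, build_windows(self.CHROM), self.CHROM)

    def test_assignment_partitions_arm_genes(self, rng):
        starts = rng.integers(0, 22_900_000, 300)
        genes = self._genes(
            [("chr1", int(s), int(s) + 1000, f"g{i}", "+") for i, s in enumerate(starts)]
        )
        win = build_windows(self.CHROM)
        _, member = assign_genes(genes, win, self.CHROM, min_genes=1)
        mids = (genes.start + genes.end) / 2
        outside_cen = ((mids < 12_000_000) | (mids >= 13_000_000)).sum()
        assert member.notna().sum() == outside_cen


class TestModeratedT:
    def test_shrinkage_off_equals_ordinary_t(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(40, 9)), columns=[f"s{i}" for i in range(9)]
        )
        groups = ["short"] * 5 + ["normal"] * 4
        m = moderated_t(expr, groups, d0_override=0)
        np.testing.assert_allclose(
            m.table.t_moderated, m.table.t_ordinary, atol=1e-12
        )

    def test_equal_variances_give_infinite_prior_df(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, 10))
        expr = pd.DataFrame(
            np.repeat(base, 30, axis=0), columns=[f"s{i}" for i in range(10)]
        )
        groups = ["short"] * 5 + ["normal"] * 5
        m = moderated_t(expr, groups)
        assert np.isinf(m.d0)
        assert np.allclose(m.table.s2_post, m.s0_sq)

    def test_hyperparameter_recovery_within_15_percent(self):
        rng = np.random.default_rng(21)
        d0, s0_sq, dg = 4.0, 0.05, 13
        sigma2 = d0 * s0_sq / rng.chisquare(d0, 5000)
        s2 = sigma2 * rng.chisquare(dg, 5000) / dg
        d0_hat, s0_hat = fit_variance_prior(s2, dg)
        assert d0_hat == pytest.approx(d0, rel=0.15)
        assert s0_hat == pytest.approx(s0_sq, rel=0.15)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(size=(3000, 12)), columns=[f"s{i}" for i in range(12)]
        )
        groups = ["short"] * 6 + ["normal"] * 6
        m = moderated_t(expr, groups)
        from scipy import stats

        assert stats.kstest(m.table.p, "uniform").pvalue > 0.01

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: R limma's squeezeVar/eBayes on the same
        matrix must give the same prior estimates and moderated t."""
        rng = np.random.default_rng(5)
        sigma2 = 4 * 0.05 / rng.chisquare(4, 150)
        x1 = rng.normal(0, np.sqrt(sigma2)[:, None], (150, 6))
        x2 = rng.normal(0.2, np.sqrt(sigma2)[:, None], (150, 4))
        mat = np.hstack([x1, x2])
        expr = pd.DataFrame(mat, columns=[f"s{i}" for i in range(10)])
        m = moderated_t(expr, ["short"] * 6 + ["normal"] * 4)
        csv = tmp_path / "m.csv"
        expr.to_csv(csv, index=False)
        out = tmp_path / "r.csv"
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.csv("{csv}"))
            design <- cbind(1, c(rep(1, 6), rep(0, 4)))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(d0 = fit$df.prior, s0 = fit$s2.prior,
                                 t = fit$t[, 2]), "{out}", row.names = FALSE)
            """
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out)
        assert m.d0 == pytest.approx(ref["d0"][0], rel=1e-4)
        assert m.s0_sq == pytest.approx(ref["s0"][0], rel=1e-4)
        np.testing.assert_allclose(m.table.t_moderated, ref["t"], rtol=1e-6)


def brute_force_es(stats_ranked: np.ndarray, hit: np.ndarray) -> float:
    """Plain-loop running-sum oracle."""
    n_r = np.abs(stats_ranked[hit]).sum()
    n_miss = (~hit).sum()
    run, best = 0.0, 0.0
    for s, h in zip(stats_ranked, hit):
        run += abs(s) / n_r if h else -1.0 / n_miss
        if abs(run) > abs(best):
            best = run
    return best


class TestEnrichment:
    def test_single_top_gene_es_one(self):
        stats_r = np.array([3.0, 2.0, 1.0])
        assert running_sum_es(stats_r, [True, False, False]) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            stats_r = np.sort(rng.normal(size=n))[::-1]
            size = int(rng.integers(1, n))
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size, replace=False)] = True
            assert running_sum_es(stats_r, hit) == pytest.approx(
                brute_force_es(stats_r, hit), rel=1e-9, abs=1e-12
            )

    def test_whole_universe_window_is_degenerate(self):
        gene_stats = pd.Series([2.0, 1.0, -1.0], index=["a", "b", "c"])
        windows = pd.DataFrame(
            {"retained": [True], "subtelomeric": [True]}, index=["w0"]
        )
        member = pd.Series(["w0", "w0", "w0"], index=["a", "b", "c"])
        res = preranked_enrichment(gene_stats, windows, member, n_perm=10, seed=0)
        assert np.isnan(res.table.loc["w0", "es"])

    def test_planted_subtelomeric_signal_detected(self):
        cfg = synthdata.SynthConfig(seed=4)  # study-scale toy genome
        chrom, genes, expr, groups, truth = synthdata.gen_toy_genome(cfg)
        windows = build_windows(chrom)
        win, member = assign_genes(genes, windows, chrom, expressed=expr.index)
        model = moderated_t(expr, groups)
        enr = preranked_enrichment(
            model.table.t_moderated, win, member, n_perm=500, seed=4
        )
        comp = compare_compartments(model, win, member, enr)
        assert comp.median_subtelomeric > comp.median_interior
        assert comp.fisher_windows.p_value < 0.05
        sub_q = enr.table.loc[enr.table.index.isin(win.index[win.subtelomeric]), "q"]
        assert (sub_q < 0.1).mean() > 0.5

    def test_null_delta_compartments_equal(self, small_cfg):
        import dataclasses

        cfg = dataclasses.replace(
            small_cfg,
            genome=dataclasses.replace(small_cfg.genome, delta_log2=0.0),
        )
        chrom, genes, expr, groups, _ = synthdata.gen_toy_genome(cfg)
        windows = build_windows(chrom)
        win, member = assign_genes(genes, windows, chrom, expressed=expr.index)
        model = moderated_t(expr, groups)
        comp = compare_compartments(model, win, member)
        assert abs(comp.median_subtelomeric - comp.median_interior) < 0.5
        assert comp.mann_whitney_unpaired.p_value > 0.01
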