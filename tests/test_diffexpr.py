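import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mycnfunnel import diffexpr, io_formats as io, synthetic_data
from mycnfunnel.diffexpr import (
    ScreenThresholds,
    StratificationConfig,
    benjamini_hochberg,
    differential_screen,
    fit_voom_weights,
    log_cpm,
    moderated_t_test,
    screen_survivors,
    stratify,
)


def _matrix(values, unit=io.RAW_COUNTS, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return io.ExpressionMatrix(genes, samples, values, unit)


class TestLogCpm:
    def test_closed_form_zero_count(self):
        # second gene fills the library to 1e6 - 1, so the zero-count gene
        # lands at log2(0.5 / 1e6 * 1e6) = -1
        m = _matrix([[0.0], [999_999.0]])
        lc = log_cpm(m)
        assert lc.values[0, 0] == pytest.approx(-1.0)
        assert lc.unit == io.NORMALIZED_INTENSITY

    def test_scale_invariance_of_cpm(self, rng):
        counts = rng.integers(1000, 100_000, size=(50, 1)).astype(float)
        m = _matrix(np.hstack([counts, 2 * counts]))
        lc = log_cpm(m)
        np.testing.assert_allclose(lc.values[:, 0], lc.values[:, 1], atol=5e-3)

    def test_doubling_a_count_approaches_one_log2_unit(self):
        # doubling one gene's count at (almost) fixed library size raises its
        # log-CPM by log2((2c+.5)/(c+.5)): < 1 always, -> 1 as c grows
        filler = 10**12  # dominates the library so it is effectively fixed
        deltas = []
        for c in (1.0, 10.0, 1000.0, 100_000.0):
            a = log_cpm(_matrix([[c], [filler]])).values[0, 0]
            b = log_cpm(_matrix([[2 * c], [filler]])).values[0, 0]
            deltas.append(b - a)
        assert all(d < 1.0 for d in deltas)
        assert deltas == sorted(deltas)
        assert deltas[-1] == pytest.approx(1.0, abs=1e-3)

    def test_zero_library_size_names_sample(self):
        m = _matrix([[1.0, 0.0], [2.0, 0.0]], samples=["ok", "empty"])
        with pytest.raises(io.DataError, match="empty"):
            log_cpm(m)

    def test_rejects_non_count_units(self):
        m = _matrix([[1.0, 2.0]], unit=io.FPKM)
        with pytest.raises(io.DataError):
            log_cpm(m)


class TestVoomWeights:
    def test_homoscedastic_weights_flat(self, rng):
        # constant-sd Gaussian log intensities: trend flat, weights near-constant
        y = rng.normal(loc=rng.uniform(2, 12, size=(2000, 1)), scale=0.5,
                       size=(2000, 30))
        m = _matrix(y, unit=io.NORMALIZED_INTENSITY)
        groups = np.array([1] * 15 + [0] * 15)
        w = fit_voom_weights(m, groups)
        cv = w.std() / w.mean()
        assert cv < 0.2

    def test_planted_decreasing_sd_gives_increasing_weights(self, rng):
        means = np.linspace(2, 12, 1000)
        sd = 1.2 - 0.08 * means  # sd falls from ~1.0 to ~0.24 as mean grows
        y = rng.normal(means[:, None], sd[:, None], size=(1000, 20))
        m = _matrix(y, unit=io.NORMALIZED_INTENSITY)
        groups = np.array([1] * 10 + [0] * 10)
        w = fit_voom_weights(m, groups).mean(axis=1)
        rho = stats.spearmanr(means, w).statistic
        assert rho > 0.9

    def test_degenerate_identical_columns_floored(self):
        y = np.tile(np.arange(1.0, 6.0)[:, None], (1, 6))
        m = _matrix(y, unit=io.NORMALIZED_INTENSITY)
        groups = np.array([1, 1, 1, 0, 0, 0])
        w = fit_voom_weights(m, groups)
        assert np.all(np.isfinite(w)) and np.all(w > 0)

    def test_requires_two_per_group(self):
        m = _matrix(np.ones((3, 3)), unit=io.NORMALIZED_INTENSITY)
        with pytest.raises(io.ConfigError):
            fit_voom_weights(m, np.array([1, 0, 0]))


class TestModeratedT:
    def test_null_identity_gene(self, rng):
        y = rng.normal(size=(50, 8))
        y[0] = np.tile([1.0, 2.0, 3.0, 4.0], 2)  # identical group profiles
        m = _matrix(y, unit=io.NORMALIZED_INTENSITY)
        groups = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        res = moderated_t_test(m, None, groups)
        assert res[0].log_fc == pytest.approx(0.0)
        assert res[0].moderated_t == pytest.approx(0.0)
        assert res[0].raw_p == pytest.approx(1.0)

    def test_prior_df_limits_match_direct_formulas(self, rng):
        """d0=0 is the ordinary weighted t; d0=inf the pooled-variance z."""
        y = rng.normal(size=(5, 10))
        m = _matrix(y, unit=io.NORMALIZED_INTENSITY)
        groups = np.array([1] * 5 + [0] * 5)
        w = rng.uniform(0.5, 2.0, size=y.shape)

        # brute-force weighted two-group statistics
        wh, wl = w[:, :5], w[:, 5:]
        mh = (wh * y[:, :5]).sum(1) / wh.sum(1)
        ml = (wl * y[:, 5:]).sum(1) / wl.sum(1)
        lfc = mh - ml
        resid = y - np.where(np.arange(10) < 5, mh[:, None], ml[:, None])
        s2 = (w * resid**2).sum(1) / 8
        se = np.sqrt(1 / wh.sum(1) + 1 / wl.sum(1))

        res0 = moderated_t_test(m, w, groups, prior_df_override=0.0)
        t_ord = lfc / (np.sqrt(s2) * se)
        np.testing.assert_allclose([r.moderated_t for r in res0], t_ord, rtol=1e-10)
        np.testing.assert_allclose(
            [r.raw_p for r in res0], 2 * stats.t.sf(np.abs(t_ord), 8), rtol=1e-10
        )

        resinf = moderated_t_test(m, w, groups, prior_df_override=math.inf)
        t_z = lfc / (np.sqrt(s2.mean()) * se)
        np.testing.assert_allclose([r.moderated_t for r in resinf], t_z, rtol=1e-10)
        np.testing.assert_allclose(
            [r.raw_p for r in resinf], 2 * stats.norm.sf(np.abs(t_z)), rtol=1e-10
        )

    def test_antisymmetric_under_group_swap(self, rng):
        y = rng.normal(size=(100, 12))
        m = _matrix(y, unit=io.NORMALIZED_INTENSITY)
        groups = np.array([1] * 6 + [0] * 6)
        a = moderated_t_test(m, None, groups)
        b = moderated_t_test(m, None, 1 - groups)
        np.testing.assert_allclose(
            [r.log_fc for r in a], [-r.log_fc for r in b], atol=1e-12
        )
        np.testing.assert_allclose(
            [r.moderated_t for r in a], [-r.moderated_t for r in b], atol=1e-10
        )

    def test_agrees_with_limma_voom(self, small_cohort, tmp_path):
        """Independent oracle: the R limma/voom pipeline on the same counts."""
        _, matrix, annotations, _ = small_cohort
        groups = np.array(
            [1 if a.mycn_status == io.MYCN_AMPLIFIED else 0 for a in annotations]
        )
        lc = log_cpm(matrix)
        w = fit_voom_weights(lc, groups)
        res = moderated_t_test(lc, w, groups)

        counts_path = tmp_path / "counts.tsv"
        io.write_expression_tsv(matrix, counts_path)
        (tmp_path / "groups.txt").write_text("\n".join(map(str, groups)) + "\n")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"counts <- as.matrix(read.delim('{counts_path}', row.names=1, check.names=FALSE))\n"
            f"grp <- scan('{tmp_path / 'groups.txt'}', quiet=TRUE)\n"
            "design <- model.matrix(~grp)\n"
            "fit <- eBayes(lmFit(voom(counts, design), design))\n"
            "tt <- topTable(fit, coef=2, number=Inf, sort.by='none')\n"
            f"write.table(data.frame(lfc=tt$logFC, t=tt$t), '{tmp_path / 'r.tsv'}',\n"
            "            sep='\\t', row.names=FALSE, quote=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r = np.loadtxt(tmp_path / "r.tsv", skiprows=1)
        np.testing.assert_allclose([x.log_fc for x in res], r[:, 0], atol=1e-3)
        np.testing.assert_allclose([x.moderated_t for x in res], r[:, 1], rtol=5e-3)


class TestBenjaminiHochberg:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_all_ones(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_identity(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_rejects_out_of_range(self):
        with pytest.raises(io.DataError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_permutation_invariant_and_rank_monotone(self, ps):
        adj = benjamini_hochberg(ps)
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_perm = benjamini_hochberg([ps[i] for i in perm])
        np.testing.assert_allclose(adj_perm, adj[perm])
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj >= np.asarray(ps) - 1e-15)


class TestStratify:
    def _annots(self, matrix, status=io.MYCN_UNKNOWN):
        return [io.SampleAnnotation(s, status) for s in matrix.sample_ids]

    def test_quantile_counts_20_samples(self, rng):
        y = rng.uniform(1, 100, size=(3, 20))
        m = _matrix(y, genes=["MYCN", "a", "b"])
        cfg = StratificationConfig(mode="by_quantile", driver_gene_id="MYCN")
        out = stratify(m, self._annots(m), cfg)
        labels = [a.group_label for a in out]
        assert labels.count(io.GROUP_HIGH) == 3
        assert labels.count(io.GROUP_LOW) == 3
        assert labels.count(io.GROUP_EXCLUDED) == 14

    def test_all_amplified_is_config_error(self):
        m = _matrix(np.ones((2, 4)))
        ann = [io.SampleAnnotation(s, io.MYCN_AMPLIFIED) for s in m.sample_ids]
        with pytest.raises(io.ConfigError):
            stratify(m, ann, StratificationConfig(mode="by_status"))

    def test_status_mapping(self):
        m = _matrix(np.ones((2, 4)))
        statuses = [io.MYCN_AMPLIFIED, io.MYCN_NON_AMPLIFIED,
                    io.MYCN_UNKNOWN, io.MYCN_AMPLIFIED]
        ann = [io.SampleAnnotation(s, st_) for s, st_ in zip(m.sample_ids, statuses)]
        out = stratify(m, ann, StratificationConfig(mode="by_status"))
        assert [a.group_label for a in out] == [
            io.GROUP_HIGH, io.GROUP_LOW, io.GROUP_EXCLUDED, io.GROUP_HIGH,
        ]

    def test_boundary_ties_broken_by_sample_id(self, rng):
        # driver expression with heavy ties: assignment must not depend on
        # column order
        driver = np.array([5.0, 5.0, 5.0, 5.0, 1.0, 1.0, 9.0, 9.0, 5.0, 5.0,
                           5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0])
        m = _matrix(driver[None, :], genes=["MYCN"])
        cfg = StratificationConfig(mode="by_quantile", driver_gene_id="MYCN")
        base = {a.sample_id: a.group_label
                for a in stratify(m, self._annots(m), cfg)}
        perm = rng.permutation(20)
        m2 = io.ExpressionMatrix(
            ["MYCN"], [m.sample_ids[i] for i in perm],
            m.values[:, perm], io.RAW_COUNTS,
        )
        permuted = {a.sample_id: a.group_label
                    for a in stratify(m2, self._annots(m2), cfg)}
        assert base == permuted

    def test_overlapping_quantile_groups_rejected(self):
        m = _matrix(np.ones((1, 3)), genes=["MYCN"])
        cfg = StratificationConfig(mode="by_quantile", driver_gene_id="MYCN")
        with pytest.raises(io.ConfigError):
            stratify(m, self._annots(m), cfg)


class TestScreen:
    def test_published_nominee_passes_and_boundary_fails(self):
        results = [
            diffexpr.DEResult("CAMKV", log_fc=1.73, raw_p=1e-7, adj_p=2.02e-6),
            diffexpr.DEResult("boundary", log_fc=1.0, raw_p=1e-9, adj_p=1e-8),
        ]
        assert screen_survivors(results) == {"CAMKV"}

    def test_adj_p_boundary_strict(self):
        results = [diffexpr.DEResult("g", log_fc=2.0, raw_p=0.04, adj_p=0.05)]
        assert screen_survivors(results) == set()

    def test_planted_target_recovery(self):
        """Sensitivity >= 0.9 and FDP <= 0.1 on planted-effect cohorts."""
        tp = fp = fn = 0
        for seed in range(10):
            cfg = synthetic_data.CohortSimConfig(
                n_genes=2000, n_samples=60, amplified_fraction=0.5,
                n_target_genes=50, target_log2fc=1.5, seed=seed,
            )
            matrix, annotations, truth = synthetic_data.simulate_cohort(cfg)
            survivors, _, _ = diffexpr.run_screen(matrix, annotations)
            survivors = survivors - {cfg.driver_gene_id}
            tp += len(survivors & truth)
            fp += len(survivors - truth)
            fn += len(truth - survivors)
        assert tp / (tp + fn) >= 0.9
        assert fp / (tp + fp) <= 0.1

    def test_dual_platform_intersection_keeps_high_effect_truth(self, rng):
        """Quantile screen on re-exported intensities agrees on strong targets."""
        cfg = synthetic_data.CohortSimConfig(
            n_genes=1000, n_samples=60, amplified_fraction=0.5,
            n_target_genes=25, target_log2fc=2.5, seed=5,
        )
        matrix, annotations, truth = synthetic_data.simulate_cohort(cfg)
        rna_survivors, _, _ = diffexpr.run_screen(matrix, annotations)
        lc = log_cpm(matrix)
        intensities = io.ExpressionMatrix(
            list(lc.gene_ids), list(lc.sample_ids), lc.values,
            io.NORMALIZED_INTENSITY,
        )
        arr_survivors, _, _ = diffexpr.run_screen(
            intensities,
            annotations,
            StratificationConfig(mode="by_quantile", driver_gene_id="MYCN"),
        )
        assert truth <= (rna_survivors & arr_survivors)
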