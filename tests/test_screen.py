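import numpy as np
import pandas as pd
import pytest

from mirstrat.io import (
    AlignedDataset,
    BindingPredictionTable,
    ClinicalTable,
    ExpressionMatrix,
    align_dataset,
)
from mirstrat.partition import Partition
from mirstrat.screen import (
    MirGeneScreen,
    PairResult,
    PipelineConfig,
    abundance_filter,
    annotate_binding,
    apply_family_correction,
    covariate_balance,
    permutation_fdr,
    scan_pairs,
    sensitivity_analysis,
)
from mirstrat.stats import CorrelationResult, LogrankResult, logrank_test
from mirstrat.partition import ValidityFlags, pair_validity


def _fake_pair(mir, gene, valid, logrank_p=None, n=40, n1=20):
    """A minimal PairResult with prescribed validity and log-rank p."""
    g1 = tuple(range(n1))
    g2 = tuple(range(n1, n))
    part = Partition(
        group1=g1,
        group2=g2,
        corr1=CorrelationResult(-0.9 if valid else -0.1, 1e-12 if valid else 0.8, n1),
        corr2=CorrelationResult(0.0, 0.9, n - n1),
        init_triple=g1[:3],
    )
    res = PairResult(mir_id=mir, gene_id=gene, partition=part)
    res.validity = ValidityFlags(valid, valid, True, True) if valid else ValidityFlags(
        False, False, True, True
    )
    if valid and logrank_p is not None:
        res.logrank = LogrankResult(chi2=1.0, p=logrank_p, n1=n1, n2=n - n1)
    return res


class TestScan:
    def test_planted_pair_found_and_survival_tested(self, small_cohort):
        cfg = PipelineConfig(seed=2, min_group_size=8)
        results = scan_pairs(small_cohort.data, cfg)
        assert len(results) == 16
        t = small_cohort.truth[0]
        planted = next(
            r for r in results if r.mir_id == t.mir_id and r.gene_id == t.gene_id
        )
        assert planted.valid
        assert planted.logrank is not None and planted.logrank.p < 0.05

    def test_constant_expression_is_skip_flagged(self):
        ids = [f"s{i:02d}" for i in range(20)]
        gene = ExpressionMatrix(
            pd.DataFrame(np.ones((2, 20)), index=["g1", "g2"], columns=ids)
        )
        rng = np.random.default_rng(0)
        mir = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(1, 20)), index=["m1"], columns=ids)
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {"time": rng.exponential(100, 20), "event": True},
                index=pd.Index(ids, name="sample_id"),
            )
        )
        data = align_dataset(gene, mir, clin, min_group_size=2)
        results = scan_pairs(data, PipelineConfig(seed=0, min_group_size=2))
        assert all(r.skipped for r in results)
        assert all(not r.valid for r in results)

    def test_pair_universe_restriction(self, small_cohort):
        cfg = PipelineConfig(seed=0, pair_universe=(("MIR0002", "GENE0003"),))
        results = scan_pairs(small_cohort.data, cfg)
        assert len(results) == 1
        assert (results[0].mir_id, results[0].gene_id) == ("MIR0002", "GENE0003")

    def test_empty_universe_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty pair universe"):
            scan_pairs(small_cohort.data, PipelineConfig(pair_universe=()))


class TestFamilyCorrection:
    def test_threshold_uses_valid_pair_count(self):
        results = [_fake_pair(f"m{i}", "g", True, logrank_p=1e-3) for i in range(100)]
        apply_family_correction(results, 0.05)
        assert not any(r.bonferroni_pass for r in results)  # 1e-3 > 0.05/100
        results = [_fake_pair(f"m{i}", "g", True, logrank_p=3.3e-9) for i in range(100)]
        apply_family_correction(results, 0.05)
        assert all(r.bonferroni_pass for r in results)

    def test_paper_scale_family(self):
        results = [_fake_pair(f"m{i}", "g", True, logrank_p=0.5) for i in range(7509)]
        results[0].logrank = LogrankResult(chi2=35.0, p=3.3044e-9, n1=20, n2=20)
        apply_family_correction(results, 0.05)
        assert results[0].bonferroni_pass  # 3.3e-9 < 0.05 / 7509 = 6.66e-6
        assert sum(r.bonferroni_pass for r in results) == 1

    def test_no_valid_pairs_warns_and_passes_none(self, caplog):
        results = [_fake_pair("m", "g", False)]
        with caplog.at_level("WARNING"):
            apply_family_correction(results, 0.05)
        assert not results[0].bonferroni_pass
        assert any("no valid pairs" in rec.message for rec in caplog.records)


class TestAbundanceFilter:
    @staticmethod
    def _data(gene_row, mir_row):
        n = len(gene_row)
        ids = [f"s{i:02d}" for i in range(n)]
        gene = ExpressionMatrix(
            pd.DataFrame([gene_row], index=["g"], columns=ids)
        )
        mir = ExpressionMatrix(pd.DataFrame([mir_row], index=["m"], columns=ids))
        clin = ClinicalTable(
            pd.DataFrame(
                {"time": 100.0, "event": True}, index=pd.Index(ids, name="sample_id")
            )
        )
        return align_dataset(gene, mir, clin, min_group_size=2)

    def test_identical_distributions_pass(self, rng):
        base = rng.normal(size=20)
        gene_row = np.concatenate([base, base])
        mir_row = np.concatenate([base, base])
        data = self._data(gene_row, mir_row)
        res = _fake_pair("m", "g", True, logrank_p=0.5, n=40, n1=20)
        abundance_filter([res], data, 0.05)
        assert res.abundance_pass
        assert res.abundance_p_gene > 0.9

    def test_absent_mir_in_group1_fails(self, rng):
        # miR expressed only in Group 2: stratification is level-driven
        mir_row = np.concatenate([np.zeros(20), rng.normal(10, 1, 20)])
        gene_row = rng.normal(size=40)
        data = self._data(gene_row, mir_row)
        res = _fake_pair("m", "g", True, logrank_p=0.5, n=40, n1=20)
        abundance_filter([res], data, 0.05)
        assert not res.abundance_pass
        assert res.abundance_p_mir < 1e-6


class TestAnnotateBinding:
    def test_supported_and_unsupported_pairs(self):
        preds = BindingPredictionTable(
            frozenset(
                {("m1", "g1", t) for t in ("PITA", "RNA22", "RNAhybrid", "miRanda")}
            )
        )
        supported = _fake_pair("m1", "g1", True, logrank_p=1e-9)
        unsupported = _fake_pair("m2", "g2", True, logrank_p=1e-9)
        apply_family_correction([supported, unsupported], 0.05)
        for r in (supported, unsupported):
            r.abundance_pass = True
        annotate_binding([supported, unsupported], preds)
        assert len(supported.binding_tools) == 4
        assert supported.final_pass
        assert unsupported.binding_tools == []
        assert not unsupported.final_pass

    def test_without_table_binding_is_vacuous(self):
        res = _fake_pair("m1", "g1", True, logrank_p=1e-9)
        apply_family_correction([res], 0.05)
        res.abundance_pass = True
        annotate_binding([res], None)
        assert res.binding_tools is None
        assert res.final_pass


class TestPermutationFdr:
    def test_matches_brute_force_rerun(self, small_cohort):
        cfg = PipelineConfig(seed=3, min_group_size=8)
        results = scan_pairs(small_cohort.data, cfg)
        apply_family_correction(results, cfg.alpha_family)
        valid = [r for r in results if r.valid][:5]
        others = [r for r in results if not r.valid]
        subset = valid + others
        n_iter = 20
        fdr = permutation_fdr(subset, small_cohort.data, cfg, n_iterations=n_iter)

        # oracle: same generator, permute (time, event) jointly, recompute
        # the log-rank test per pair from scratch
        m = len(valid)
        thr = cfg.alpha_family / m
        times = small_cohort.data.clinical.times()
        events = small_cohort.data.clinical.events()
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, 0xFD0])
        )
        for it in range(n_iter):
            perm = rng.permutation(len(times))
            count = sum(
                logrank_test(times[perm], events[perm], r.partition.labels()).p < thr
                for r in valid
            )
            assert count == fdr.counts[it]

    def test_zero_events_gives_zero_counts(self):
        ids = [f"s{i:02d}" for i in range(30)]
        rng = np.random.default_rng(1)
        gene = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(1, 30)), index=["g"], columns=ids)
        )
        mir = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(1, 30)), index=["m"], columns=ids)
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {"time": 100.0, "event": False}, index=pd.Index(ids, name="sample_id")
            )
        )
        data = align_dataset(gene, mir, clin, min_group_size=2)
        res = _fake_pair("m", "g", True, logrank_p=1.0, n=30, n1=15)
        fdr = permutation_fdr([res], data, PipelineConfig(seed=0), n_iterations=10)
        assert fdr.counts.sum() == 0

    def test_add_one_bound_with_zero_observed(self):
        res = _fake_pair("m", "g", False)
        ids = [f"s{i:02d}" for i in range(30)]
        rng = np.random.default_rng(1)
        gene = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(1, 30)), index=["g"], columns=ids)
        )
        mir = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(1, 30)), index=["m"], columns=ids)
        )
        clin = ClinicalTable(
            pd.DataFrame(
                {"time": rng.exponential(100, 30), "event": True},
                index=pd.Index(ids, name="sample_id"),
            )
        )
        data = align_dataset(gene, mir, clin, min_group_size=2)
        fdr = permutation_fdr([res], data, PipelineConfig(seed=0), n_iterations=25)
        assert fdr.observed_count == 0
        assert fdr.empirical_fdr_bound == 1.0


class TestSensitivity:
    def test_perfect_data_has_zero_spread(self):
        x = np.arange(20.0)
        y = -x
        res = sensitivity_analysis(x, y, n_triples=30, seed=0)
        assert res.std == 0.0
        np.testing.assert_allclose(res.abs_r, 1.0)

    def test_exhaustive_mode_counts_triples(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=5), rng.normal(size=5)
        res = sensitivity_analysis(x, y, mode="exhaustive")
        assert res.n_triples_evaluated == 10  # C(5,3)

    def test_exhaustive_cap_enforced(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=100), rng.normal(size=100)
        with pytest.raises(ValueError, match="cap"):
            sensitivity_analysis(x, y, mode="exhaustive", exhaustive_cap=1000)


class TestCovariateBalance:
    @staticmethod
    def _clinical(n, **cov):
        return ClinicalTable(
            pd.DataFrame(
                {"time": 100.0, "event": True, **cov},
                index=pd.Index([f"s{i:03d}" for i in range(n)], name="sample_id"),
            )
        )

    @staticmethod
    def _partition(n, n1):
        return Partition(
            group1=tuple(range(n1)),
            group2=tuple(range(n1, n)),
            corr1=CorrelationResult(-0.9, 1e-9, n1),
            corr2=CorrelationResult(0.0, 0.9, n - n1),
            init_triple=(0, 1, 2),
        )

    def test_identical_covariate_distribution(self):
        vals = np.tile(np.arange(20.0), 2)
        clin = self._clinical(40, age=vals)
        table = covariate_balance(self._partition(40, 20), clin)
        row = table[table.covariate == "age"].iloc[0]
        assert row.p == pytest.approx(1.0, abs=0.05)

    def test_confounded_binary_covariate_detected(self):
        gender = ["male"] * 20 + ["female"] * 20
        clin = self._clinical(40, gender=gender)
        table = covariate_balance(self._partition(40, 20), clin)
        row = table[table.covariate == "gender"].iloc[0]
        assert row.test == "chi-square"
        assert row.p < 1e-3

    def test_constant_covariate_skipped(self):
        clin = self._clinical(40, centre=["A"] * 40)
        table = covariate_balance(self._partition(40, 20), clin)
        row = table[table.covariate == "centre"].iloc[0]
        assert row.test == "skipped"

    def test_balanced_covariates_rarely_flagged(self):
        rng = np.random.default_rng(0)
        flags = 0
        n_tests = 200
        for _ in range(n_tests):
            clin = self._clinical(40, age=rng.normal(60, 10, size=40))
            table = covariate_balance(self._partition(40, 20), clin)
            flags += table[table.covariate == "age"].iloc[0].p < 0.05
        assert flags / n_tests == pytest.approx(0.05, abs=0.04)

    def test_no_covariates_rejected(self):
        with pytest.raises(ValueError, match="no covariates"):
            covariate_balance(self._partition(10, 5), self._clinical(10))


class TestModelResults:
    def test_cascade_is_monotone_and_deterministic(self, small_cohort):
        cfg = PipelineConfig(seed=6, min_group_size=8)
        res1 = MirGeneScreen(small_cohort.data, cfg).fit()
        res2 = MirGeneScreen(small_cohort.data, cfg).fit()
        pd.testing.assert_frame_equal(res1.to_frame(), res2.to_frame())
        c = res1.cascade_counts()
        assert c["final"] <= c["abundance"] <= c["bonferroni"] <= c["valid"] <= c["scanned"]
        for r in res1.pairs:
            if r.final_pass:
                assert r.valid and r.bonferroni_pass and r.abundance_pass
            if r.logrank is not None:
                assert r.valid

    def test_summary_and_write(self, small_cohort, tmp_path):
        cfg = PipelineConfig(seed=6, min_group_size=8)
        res = MirGeneScreen(small_cohort.data, cfg).fit()
        text = res.summary()
        assert "pairs scanned: 16" in text
        paths = res.write(tmp_path)
        assert paths["results"].exists()
        import json

        manifest = json.loads(paths["manifest"].read_text())
        cascade = manifest["cascade"]
        assert cascade["valid"] >= cascade["bonferroni"] >= cascade["final"]
        df = pd.read_csv(paths["results"], sep="\t")
        assert len(df) == 16

    def test_dataset_too_small_for_config(self, small_cohort):
        with pytest.raises(ValueError, match="too small"):
            MirGeneScreen(small_cohort.data, PipelineConfig(min_group_size=50))

    def test_plot_km_returns_axes(self, small_cohort):
        cfg = PipelineConfig(seed=6, min_group_size=8)
        res = MirGeneScreen(small_cohort.data, cfg).fit()
        t = small_cohort.truth[0]
        ax = res.plot_km(t.mir_id, t.gene_id)
        assert ax.get_ylabel() == "survival probability"
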