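"""Bias/precision metrics and replicate-study orchestration."""

import numpy as np
import pytest

import toxkinsim as tk
from toxkinsim.errors import ConfigurationError, InputError

class TestMetrics:
    def test_relative_error_basics(self):
        assert tk.relative_error(10.0, 10.0) == 0.0
        assert tk.relative_error(11.0, 10.0) == pytest.approx(10.0)
        assert tk.relative_error(5.0, 10.0) == pytest.approx(-50.0)
        with pytest.raises(InputError):
            tk.relative_error(1.0, 0.0)

    def test_smre_formula(self):
        assert tk.smre([100.0, 100.0], 100.0) == 0.0
        assert tk.smre([120.0], 100.0) == pytest.approx(20.0)
        assert tk.smre([80.0, 120.0], 100.0) == pytest.approx(0.0)
        # per-estimate truths are averaged the same way
        assert tk.smre([110.0, 90.0], [100.0, 100.0]) == pytest.approx(0.0)

    def test_cv_printed_formula(self):
        # 1/N * sqrt(sum(((x-mean)/mean)^2)) * 100
        assert tk.cv([90.0, 110.0]) == pytest.approx(
            0.5 * np.sqrt(0.01 + 0.01) * 100)
        assert tk.cv([5.0, 5.0, 5.0]) == 0.0

    def test_cv_printed_formula_shrinks_with_duplication(self):
        # duplicating the sample halves the printed-formula CV by
        # sqrt(2)/2 (documented non-standard N-scaling)
        x = [90.0, 110.0, 95.0]
        assert tk.cv(x * 2) == pytest.approx(tk.cv(x) / np.sqrt(2.0))

    def test_cv_sample_convention(self):
        x = [90.0, 110.0]
        assert tk.cv(x, convention="sample") == pytest.approx(
            np.std(x, ddof=1) / np.mean(x) * 100)
        with pytest.raises(ConfigurationError):
            tk.cv(x, convention="bogus")


class TestScenarioConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = tk.ScenarioConfig(model_id="ONE_CMT", duration="1_WEEK",
                                n_replicates=3, master_seed=7)
        p = tmp_path / "scenario.yaml"
        cfg.to_yaml(p)
        cfg2 = tk.ScenarioConfig.from_yaml(p)
        assert cfg2 == cfg

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            tk.ScenarioConfig(n_replicates=0)
        with pytest.raises(ConfigurationError):
            tk.ScenarioConfig(methods=())
        with pytest.raises(ConfigurationError):
            tk.ScenarioConfig(methods=("NCA_MAGIC",))
        with pytest.raises(ConfigurationError):
            tk.ScenarioConfig(truth_convention="group-median")


def small_nca_config(**kw):
    """1-week NCA-only scenario: fast enough for orchestration tests."""
    defaults = dict(model_id="ONE_CMT", duration="1_WEEK", dose_group=30.0,
                    n_replicates=4, master_seed=99,
                    methods=("NCA_COMPOSITE_MEAN", "NCA_SERIAL_MEAN",
                             "NCA_SERIAL_GEOMEAN"),
                    measures=("auc24", "cmax24", "tat24"))
    defaults.update(kw)
    return tk.ScenarioConfig(**defaults)


class TestRunStudy:
    def test_reproducible_from_master_seed(self):
        t1 = tk.run_study(small_nca_config())
        t2 = tk.run_study(small_nca_config())
        assert t1.summary.equals(t2.summary)
        assert t1.records.equals(t2.records)

    def test_smre_equals_mean_of_replicate_relative_errors(self):
        table = tk.run_study(small_nca_config())
        for method in ("NCA_COMPOSITE_MEAN", "NCA_SERIAL_MEAN"):
            row = table.row(method, "auc24")
            rel = table.rel_errors(method, "auc24")
            assert row["smre"] == pytest.approx(np.mean(rel), rel=1e-12)

    def test_quantile_rows_are_ordered(self):
        table = tk.run_study(small_nca_config())
        q = table.summary[["re_q05", "re_q25", "re_q50", "re_q75", "re_q95"]]
        assert (q.diff(axis=1).iloc[:, 1:] >= -1e-12).all().all()

    def test_noise_free_bsv_free_nca_has_zero_error(self):
        # sigma = 0 and no BSV: serial NCA differs from truth only by
        # the sparse-grid interpolation error of the trapezoid
        cfg = small_nca_config(sigma_prop=0.0, n_replicates=2,
                               methods=("NCA_SERIAL_MEAN",))
        cfg.population_overrides = {"bsv_cv": {"KA": 0.0, "V": 0.0, "CL": 0.0},
                                    "sigma_prop": 0.0}
        table = tk.run_study(cfg)
        assert abs(table.row("NCA_SERIAL_MEAN", "cmax24")["cv"]) < 1e-9
        # every replicate sees identical data -> zero spread
        assert table.row("NCA_SERIAL_MEAN", "auc24")["cv"] == pytest.approx(0.0,
                                                                            abs=1e-9)

    def test_summary_csv_round_trip(self, tmp_path):
        import pandas as pd
        table = tk.run_study(small_nca_config(n_replicates=2))
        paths = tk.summarize_to_tables(table, tmp_path)
        re_read = pd.read_csv(paths["summary"])
        assert len(re_read) == len(table.summary)
        re_records = pd.read_csv(paths["records"])
        assert len(re_records) == len(table.records)

    def test_empty_table_rejected(self, tmp_path):
        import pandas as pd
        table = tk.ComparisonTable(summary=pd.DataFrame(),
                                   records=pd.DataFrame(),
                                   config=small_nca_config())
        with pytest.raises(InputError):
            tk.summarize_to_tables(table, tmp_path)


class TestTruthConventions:
    def test_typical_truth_equals_population_exposure(self):
        from toxkinsim.evaluation import _truth_exposures
        cfg = small_nca_config(truth_convention="typical", n_replicates=1)
        design = cfg.design()
        ds = tk.simulate_trial(design, cfg.spec(), cfg.population(), 1)
        truth = _truth_exposures(cfg, ds, evaluation_day=1,
                                 n_days=design.n_days,
                                 measures=("auc24", "cmax24"))
        reg = tk.DoseRegimen(dose=30.0, n_doses=design.n_days)
        ref = tk.exposure_from_params(cfg.spec(), cfg.population(), reg, 1,
                                      measures=("auc24", "cmax24"))
        assert truth["auc24"] == ref.auc24
        assert truth["cmax24"] == ref.cmax24

    def test_individual_mean_truth_averages_group_animals(self):
        from toxkinsim.evaluation import _truth_exposures
        cfg = small_nca_config(n_replicates=1)
        design = cfg.design()
        ds = tk.simulate_trial(design, cfg.spec(), cfg.population(), 1)
        truth = _truth_exposures(cfg, ds, evaluation_day=1,
                                 n_days=design.n_days, measures=("auc24",))
        reg = tk.DoseRegimen(dose=30.0, n_doses=design.n_days)
        import numpy as np
        per_animal = [
            tk.exposure_from_params(cfg.spec(), ds.individual_params[a], reg,
                                    1, measures=("auc24",)).auc24
            for a in ds.animals(dose=30.0)]
        assert truth["auc24"] == np.mean(per_animal)


class TestParallelExecution:
    def test_worker_count_does_not_change_results(self):
        cfg = small_nca_config(n_replicates=3)
        serial = tk.run_study(cfg, n_jobs=1)
        parallel = tk.run_study(cfg, n_jobs=2)
        assert serial.records.equals(parallel.records)
        assert serial.summary.equals(parallel.summary)
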