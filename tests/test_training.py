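"""Splitting, cross-validation, the experiment driver and transfer."""

import numpy as np
import pytest

from coxfuse.synthetic import SyntheticConfig, simulate_cohort
from coxfuse.training import (CohortData, TrainerConfig, benchmark_strategies,
                              cv_folds, load_fitted, run_experiment,
                              save_fitted, stratified_split, train_model,
                              transfer_evaluate)

from conftest import make_records


def covariate_records(n, seed=0):
    rng = np.random.default_rng(seed)
    covs = [{"age": float(rng.normal(55, 10)),
             "gender": str(rng.choice(["F", "M"])),
             "grade": int(rng.integers(0, 2))} for _ in range(n)]
    return make_records(rng.exponential(10, n) + 0.1,
                        rng.integers(0, 2, n), covariates=covs)


class TestStratifiedSplit:
    def test_split_sizes(self):
        recs = covariate_records(100)
        train, test = stratified_split(recs, 0.8, seed=1)
        assert abs(len(train) - 80) <= 1
        assert len(train) + len(test) == 100
        assert set(train).isdisjoint(test)

    def test_two_equal_strata_preserve_proportions(self):
        recs = make_records(
            np.concatenate([np.full(50, 5.0), np.full(50, 50.0)]),
            np.ones(100, int),
            covariates=[{"grade": 0}] * 50 + [{"grade": 1}] * 50)
        train, test = stratified_split(recs, 0.8, strata_spec=("grade",),
                                       seed=2)
        by_id = {r.patient_id: r.covariates["grade"] for r in recs}
        for grade in (0, 1):
            n_tr = sum(1 for i in train if by_id[i] == grade)
            n_te = sum(1 for i in test if by_id[i] == grade)
            assert abs(n_tr - 40) <= 1
            assert abs(n_te - 10) <= 1

    def test_deterministic_under_seed(self):
        recs = covariate_records(60, seed=3)
        assert stratified_split(recs, 0.8, seed=7) == \
            stratified_split(recs, 0.8, seed=7)
        assert stratified_split(recs, 0.8, seed=7) != \
            stratified_split(recs, 0.8, seed=8)

    def test_no_systematic_stratum_imbalance_over_seeds(self):
        """Across many seeded splits, each stratum's test share should
        fluctuate around the nominal 20% without bias."""
        recs = make_records(
            np.tile([3.0, 30.0], 50), np.ones(100, int),
            covariates=[{"grade": g} for g in np.tile([0, 1], 50)])
        shares = []
        for seed in range(200):
            _, test = stratified_split(recs, 0.8, strata_spec=("grade",),
                                       seed=seed)
            by_id = {r.patient_id: r.covariates["grade"] for r in recs}
            shares.append(sum(1 for i in test if by_id[i] == 1) / len(test))
        assert abs(np.mean(shares) - 0.5) < 0.02

    def test_tiny_cohort_rejected(self):
        with pytest.raises(ValueError, match="small"):
            stratified_split(covariate_records(5), 0.8)


class TestCVFolds:
    def test_folds_partition_the_pool(self):
        recs = covariate_records(60, seed=4)
        plan = cv_folds(recs, k=3, seed=0)
        all_ids = {r.patient_id for r in recs}
        for train_ids, val_ids in plan.folds:
            assert set(train_ids).isdisjoint(val_ids)
            assert set(train_ids) | set(val_ids) == all_ids
        val_union = set()
        for _, val_ids in plan.folds:
            assert val_union.isdisjoint(val_ids)
            val_union |= set(val_ids)
        assert val_union == all_ids

    def test_fold_sizes_balanced_within_strata(self):
        recs = make_records(np.arange(1, 61, dtype=float), np.ones(60, int),
                            covariates=[{"grade": i % 2} for i in range(60)])
        plan = cv_folds(recs, k=3, strata_spec=("grade",), seed=1)
        by_id = {r.patient_id: r.covariates["grade"] for r in recs}
        for _, val_ids in plan.folds:
            counts = [sum(1 for i in val_ids if by_id[i] == g)
                      for g in (0, 1)]
            assert abs(counts[0] - counts[1]) <= 1

    def test_k_too_large_suggests_maximum(self):
        recs = covariate_records(20, seed=5)
        with pytest.raises(ValueError, match="maximum feasible"):
            cv_folds(recs, k=15)


class TestTrainModel:
    def test_zero_epochs_returns_initialized_model(self, fast_trainer_config,
                                                   tiny_multimodal_cohort):
        from dataclasses import replace

        data = CohortData.from_cohort(tiny_multimodal_cohort.public_view())
        tr_ids, va_ids = stratified_split(data.records, 0.8, seed=0)
        cfg = replace(fast_trainer_config, epochs_expr=0)
        fitted = train_model("expression", data.subset(tr_ids),
                             data.subset(va_ids), cfg, seed=0)
        assert fitted.history == []

    def test_identical_seeds_give_identical_history(self, fast_trainer_config,
                                                    tiny_multimodal_cohort):
        data = CohortData.from_cohort(tiny_multimodal_cohort.public_view())
        tr_ids, va_ids = stratified_split(data.records, 0.8, seed=0)
        tr, va = data.subset(tr_ids), data.subset(va_ids)
        a = train_model("expression", tr, va, fast_trainer_config, seed=5)
        b = train_model("expression", tr, va, fast_trainer_config, seed=5)
        assert a.history == b.history

    def test_training_reduces_loss_on_strong_signal(self, tiny_multimodal_cohort):
        data = CohortData.from_cohort(tiny_multimodal_cohort.public_view())
        tr_ids, va_ids = stratified_split(data.records, 0.8, seed=0)
        cfg = TrainerConfig(epochs_expr=15)
        fitted = train_model("expression", data.subset(tr_ids),
                             data.subset(va_ids), cfg, seed=1)
        assert fitted.history[-1]["train_loss"] < fitted.history[0]["train_loss"]

    def test_unknown_strategy_rejected(self, fast_trainer_config,
                                       tiny_multimodal_cohort):
        data = CohortData.from_cohort(tiny_multimodal_cohort.public_view())
        tr_ids, va_ids = stratified_split(data.records, 0.8, seed=0)
        with pytest.raises(ValueError, match="strategy"):
            train_model("ensemble", data.subset(tr_ids), data.subset(va_ids),
                        fast_trainer_config, seed=0)

    def test_missing_images_rejected_for_image_strategy(
            self, fast_trainer_config):
        cohort = simulate_cohort(SyntheticConfig(
            n_patients=30, patches_per_patient=0, n_genes=10, module_size=3,
            seed=8))
        data = CohortData.from_cohort(cohort.public_view())
        tr_ids, va_ids = stratified_split(data.records, 0.8, seed=0)
        with pytest.raises(ValueError, match="image"):
            train_model("image", data.subset(tr_ids), data.subset(va_ids),
                        fast_trainer_config, seed=0)


class TestExperimentDriver:
    @pytest.fixture(scope="class")
    def result(self, tiny_multimodal_cohort):
        cfg = TrainerConfig(epochs_image=2, epochs_expr=8, epochs_early=10,
                            epochs_joint=2, k_folds=2)
        return run_experiment(tiny_multimodal_cohort, cfg, seed=0)

    def test_summary_covers_five_strategies_and_three_columns(self, result):
        table = result.summary()
        assert len(table) == 5
        assert list(table.columns) == ["strategy", "train_cs", "val_cs",
                                       "test_cs"]

    def test_summary_stats_match_per_fold_reports(self, result):
        for strategy, folds in result.per_fold.items():
            vals = [f["val_report"].cs for f in folds]
            row = result.summary().set_index("strategy").loc[strategy]
            mean, sd = row["val_cs"].split(" ± ")
            assert float(mean) == pytest.approx(np.mean(vals), abs=5e-4)
            assert float(sd) == pytest.approx(np.std(vals), abs=5e-4)

    def test_selected_fold_minimizes_validation_loss(self, result):
        for strategy, folds in result.per_fold.items():
            losses = [f["val_loss"] for f in folds]
            assert result.selected_fold[strategy] == int(np.argmin(losses))

    def test_test_cs_satisfies_composite_formula(self, result):
        for report in result.test_reports.values():
            assert report.cs == pytest.approx(
                (report.ci + (1 - report.ibs)) / 2, abs=1e-12)


class TestTransfer:
    @pytest.fixture(scope="class")
    def fitted_expression(self, tiny_multimodal_cohort):
        data = CohortData.from_cohort(tiny_multimodal_cohort.public_view())
        tr_ids, va_ids = stratified_split(data.records, 0.8, seed=0)
        cfg = TrainerConfig(epochs_expr=10)
        return train_model("expression", data.subset(tr_ids),
                           data.subset(va_ids), cfg, seed=0), data

    def test_identity_transfer_reproduces_in_cohort_metrics(
            self, fitted_expression):
        from coxfuse.metrics import evaluate_risk_scores

        fitted, data = fitted_expression
        direct = evaluate_risk_scores(fitted.train_records,
                                      fitted.train_scores, data.records,
                                      fitted.predict(data))
        via_transfer = transfer_evaluate(fitted, data)
        assert via_transfer.ci == direct.ci
        assert via_transfer.ibs == direct.ibs

    def test_gene_alignment_zero_fills_missing(self, fitted_expression):
        fitted, data = fitted_expression
        # target cohort measured a superset ordering: drop nothing, permute
        perm = list(reversed(range(len(data.gene_ids))))
        shuffled = CohortData(records=data.records,
                              X_expr=data.X_expr[:, perm],
                              gene_ids=[data.gene_ids[i] for i in perm],
                              images=data.images)
        report = transfer_evaluate(fitted, shuffled)
        baseline = transfer_evaluate(fitted, data)
        assert report.ci == pytest.approx(baseline.ci)

    def test_low_gene_overlap_is_a_hard_error(self, fitted_expression):
        fitted, data = fitted_expression
        few = len(data.gene_ids) // 3
        small = CohortData(records=data.records,
                           X_expr=data.X_expr[:, :few],
                           gene_ids=data.gene_ids[:few],
                           images=data.images)
        with pytest.raises(ValueError, match="50%"):
            transfer_evaluate(fitted, small)

    def test_save_load_round_trip_preserves_predictions(
            self, fitted_expression, tmp_path):
        fitted, data = fitted_expression
        save_fitted(fitted, tmp_path / "model")
        back = load_fitted(tmp_path / "model")
        np.testing.assert_allclose(back.predict(data), fitted.predict(data))


class TestNoLeakage:
    def test_benchmark_raises_if_test_ids_reach_training(self, monkeypatch,
                                                         tiny_multimodal_cohort):
        import coxfuse.training as T

        real_split = T.stratified_split
        calls = {"n": 0}

        def leaky_split(records, ratio, strata_spec=None, seed=0):
            train, test = real_split(records, ratio, strata_spec or (),
                                     seed=seed)
            calls["n"] += 1
            if calls["n"] == 2:       # inner carve-out: inject a test id
                train = train + [leaky_split.test_id]
            else:
                leaky_split.test_id = test[0]
            return train, test

        monkeypatch.setattr(T, "stratified_split", leaky_split)
        cfg = TrainerConfig(epochs_expr=1)
        with pytest.raises(AssertionError, match="leaked"):
            T.benchmark_strategies(tiny_multimodal_cohort, cfg, seed=0,
                                   strategies=("expression",))
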