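"""Protocol tests: split determinism and CI arithmetic, coverage, vote
semantics, ensemble/shared-split contracts, ranking, and permutation
importance against a naive double-loop oracle."""

import numpy as np
import pandas as pd
import pytest

import fusebench as fb
from fusebench import (
    DataError,
    EnsembleSpec,
    EvalResult,
    PipelineSpec,
    ReducerSpec,
    SplitPlan,
)
from fusebench.cohort import code_labels
from fusebench.evaluation import _split_seed


def _result(mean, half, name="r", task="binary"):
    return EvalResult(name=name, task=task,
                      per_split_accuracies=np.array([mean] * 3),
                      mean_accuracy=mean, ci_low=mean - half, ci_high=mean + half)


class TestConfidenceInterval:
    def test_zero_variance(self):
        lo, hi = fb.confidence_interval([0.8, 0.8, 0.8])
        assert lo == hi == pytest.approx(0.8)

    def test_worked_example(self):
        """{0.7, 0.8, 0.9}: mean 0.8, half-width 1.96*0.1/sqrt(3)."""
        lo, hi = fb.confidence_interval([0.7, 0.8, 0.9])
        assert lo == pytest.approx(0.6868, abs=2e-4)
        assert hi == pytest.approx(0.9132, abs=2e-4)

    def test_too_few_values_errors(self):
        with pytest.raises(DataError):
            fb.confidence_interval([0.5])

    def test_coverage_of_simulated_accuracy_streams(self):
        """95% CI covers the true mean in ~95% of 1000 meta-replicates."""
        rng = np.random.default_rng(0)
        true_p = 0.8
        n_test, n_repeats = 100, 50
        covered = 0
        for _ in range(1000):
            accs = rng.binomial(n_test, true_p, size=n_repeats) / n_test
            lo, hi = fb.confidence_interval(accs)
            covered += lo <= true_p <= hi
        assert 0.93 <= covered / 1000 <= 0.97

    def test_width_shrinks_as_inverse_sqrt_repeats(self):
        """Quadrupling the repeat count halves the expected half-width."""
        rng = np.random.default_rng(1)
        widths = {}
        for r in (25, 100):
            ws = []
            for _ in range(400):
                accs = rng.normal(0.8, 0.04, size=r)
                lo, hi = fb.confidence_interval(accs)
                ws.append(hi - lo)
            widths[r] = np.mean(ws)
        assert widths[25] / widths[100] == pytest.approx(2.0, rel=0.05)

    def test_bootstrap_alternative_brackets_mean(self):
        accs = [0.7, 0.75, 0.8, 0.85, 0.9]
        lo, hi = fb.confidence_interval(accs, method="bootstrap", seed=3)
        assert lo <= np.mean(accs) <= hi


class TestSignificance:
    def test_disjoint_intervals(self):
        assert fb.significantly_different(_result(0.81, 0.01), _result(0.84, 0.01))

    def test_overlapping_intervals(self):
        assert not fb.significantly_different(_result(0.82, 0.02),
                                              _result(0.84, 0.01))

    def test_identical_results_overlap(self):
        r = _result(0.8, 0.01)
        assert not fb.significantly_different(r, r)


class TestMajorityVote:
    def test_clear_majority(self):
        votes = np.array([[2], [2], [0]])  # AD, AD, HC
        assert fb.majority_vote(votes, "multiclass")[0] == 2

    def test_unanimous(self):
        votes = np.array([[1], [1], [1]])
        assert fb.majority_vote(votes, "multiclass")[0] == 1

    def test_three_way_tie_prevalence_rule(self):
        """[HC, MCI, AD] with training prevalence HC > MCI > AD -> HC."""
        votes = np.array([[0], [1], [2]])
        counts = np.array([100, 60, 40])
        assert fb.majority_vote(votes, "multiclass", counts)[0] == 0

    def test_tie_falls_back_to_label_order(self):
        votes = np.array([[1], [2], [0], [99 % 3]])[:3]
        counts = np.array([50, 50, 50])
        assert fb.majority_vote(votes, "multiclass", counts)[0] == 0

    def test_matches_bruteforce_vote_recount(self):
        rng = np.random.default_rng(4)
        votes = rng.integers(0, 3, size=(5, 200))
        counts = np.array([30, 20, 10])
        got = fb.majority_vote(votes, "multiclass", counts)
        for j in range(200):
            tallies = [(np.sum(votes[:, j] == c), counts[c], -c) for c in range(3)]
            best = max(range(3), key=lambda c: tallies[c])
            assert got[j] == best

    def test_single_member_errors(self):
        with pytest.raises(DataError):
            fb.majority_vote(np.array([[1, 2]]), "multiclass")


class TestRepeatedSplits:
    def test_protocol_defaults(self):
        plan = SplitPlan()
        assert plan.train_fraction == 0.75
        assert plan.n_repeats == 50

    def test_splits_deterministic_and_sized(self, small_cohort):
        plan = SplitPlan(n_repeats=5, base_seed=3)
        s1 = fb.make_splits(plan, small_cohort.labels)
        s2 = fb.make_splits(plan, small_cohort.labels)
        for (a1, b1), (a2, b2) in zip(s1, s2):
            assert np.array_equal(a1, a2) and np.array_equal(b1, b2)
            assert len(a1) == round(0.75 * small_cohort.n_subjects)
            assert len(np.intersect1d(a1, b1)) == 0

    def test_stratified_splits_keep_all_classes(self, small_cohort):
        plan = SplitPlan(n_repeats=10, base_seed=1)
        labels = np.asarray(small_cohort.labels)
        for tr, _ in fb.make_splits(plan, small_cohort.labels):
            assert len(np.unique(labels[tr])) == 3

    def test_evaluation_reproducible(self, small_cohort):
        plan = SplitPlan(n_repeats=4, base_seed=5)
        spec = PipelineSpec(topology="single",
                            modality_names=(small_cohort.modality_names()[0],),
                            classifier="logistic", task="binary",
                            reducers=ReducerSpec.pca(3))
        r1 = fb.repeated_split_evaluate(spec, small_cohort, plan)
        r2 = fb.repeated_split_evaluate(spec, small_cohort, plan)
        assert np.array_equal(r1.per_split_accuracies, r2.per_split_accuracies)
        assert r1.ci_low <= r1.mean_accuracy <= r1.ci_high

    def test_majority_baseline_accuracy(self):
        """A constant-prediction model scores the majority-class rate."""
        cfg = fb.CohortConfig(n_subjects=600, block_dims=(4,), signal_weights=(0.0,),
                              n_informative=(0,), nuisance_factors=(1,),
                              modality_names=("m",), seed=8)
        cohort = fb.generate_cohort(cfg).cohort
        plan = SplitPlan(n_repeats=8, base_seed=2)
        spec = PipelineSpec(topology="single", modality_names=("m",),
                            classifier="random_forest", task="multiclass",
                            reducers=None,
                            classifier_params={"n_estimators": 50})
        res = fb.repeated_split_evaluate(spec, cohort, plan)
        majority = (cohort.labels == "HC").mean()
        # uninformative features: accuracy near the majority rate
        assert res.mean_accuracy == pytest.approx(majority, abs=0.08)


class TestEnsembles:
    def _member(self, cohort, method, seed=0):
        return PipelineSpec(topology="single",
                            modality_names=(cohort.modality_names()[0],),
                            classifier="logistic", task="binary",
                            reducers=ReducerSpec.pca(3, seed=seed),
                            label=f"m-{method}-{seed}")

    def test_identical_members_equal_single_member(self, small_cohort):
        plan = SplitPlan(n_repeats=3, base_seed=7)
        a = self._member(small_cohort, "pca", 0)
        b = self._member(small_cohort, "pca", 0)
        b.label = "m-pca-copy"
        single = fb.repeated_split_evaluate(a, small_cohort, plan)
        ens = fb.evaluate_ensemble(EnsembleSpec([a, b], "ens"), small_cohort, plan)
        assert np.array_equal(ens.per_split_accuracies,
                              single.per_split_accuracies)

    def test_vote_matches_manual_recount(self, small_cohort):
        plan = SplitPlan(n_repeats=3, base_seed=9)
        members = [self._member(small_cohort, "pca", s) for s in (0, 1, 2)]
        splits = fb.make_splits(plan, small_cohort.labels)
        ens = fb.evaluate_ensemble(EnsembleSpec(members, "ens"), small_cohort,
                                   plan, splits=splits)
        y = code_labels(small_cohort.labels, "binary")
        for r, (tr, te) in enumerate(splits):
            preds = []
            counts = None
            for m in members:
                fp = fb.fit_pipeline(m, small_cohort, tr,
                                     seed=_split_seed(m.seed, r))
                preds.append(fp.predict(small_cohort, te))
                counts = fp.train_class_counts
            vote = fb.majority_vote(np.asarray(preds), "binary", counts)
            assert ens.per_split_accuracies[r] == pytest.approx(
                np.mean(vote == y[te]))

    def test_members_share_splits(self, small_cohort):
        plan = SplitPlan(n_repeats=3, base_seed=11)
        members = [self._member(small_cohort, "pca", s) for s in (0, 1)]
        ens = fb.evaluate_ensemble(EnsembleSpec(members, "ens"), small_cohort, plan)
        # the audit fingerprints are those of the shared split sequence
        splits = fb.make_splits(plan, small_cohort.labels)
        expected = [int(np.sum(tr) % (2**31)) for tr, _ in splits]
        assert ens.extras["split_fingerprints"] == expected

    def test_mismatched_tasks_rejected(self, small_cohort):
        a = self._member(small_cohort, "pca", 0)
        b = PipelineSpec(topology="single",
                         modality_names=(small_cohort.modality_names()[0],),
                         classifier="random_forest", task="multiclass",
                         reducers=ReducerSpec.pca(3))
        with pytest.raises(fb.ConfigError):
            EnsembleSpec([a, b], "bad")


class TestRanking:
    def test_descending_order(self):
        rs = [_result(0.85, 0.01, "b"), _result(0.90, 0.01, "a")]
        assert [r.name for r in fb.rank_models(rs)] == ["a", "b"]

    def test_tie_broken_by_narrower_ci(self):
        rs = [_result(0.9, 0.03, "wide"), _result(0.9, 0.01, "narrow")]
        assert [r.name for r in fb.rank_models(rs)] == ["narrow", "wide"]

    def test_matches_bruteforce_sort(self):
        rng = np.random.default_rng(5)
        rs = [_result(round(float(rng.choice([0.7, 0.8, 0.9])), 3),
                      round(float(rng.uniform(0.005, 0.03)), 4), f"m{i}")
              for i in range(12)]
        got = [r.name for r in fb.rank_models(rs)]
        brute = [r.name for r in
                 sorted(rs, key=lambda r: (-r.mean_accuracy,
                                           r.ci_high - r.ci_low, r.name))]
        assert got == brute


@pytest.fixture(scope="module")
def fitted():
    cfg = fb.CohortConfig(n_subjects=400, block_dims=(6,), signal_weights=(1.5,),
                          n_informative=(1,), nuisance_factors=(0,),
                          noise_sd=0.5, label_noise_sd=0.1,
                          modality_names=("m",), seed=13)
    cohort = fb.generate_cohort(cfg).cohort
    spec = PipelineSpec(topology="single", modality_names=("m",),
                        classifier="logistic", task="binary",
                        reducers=ReducerSpec.lasso(lambda_grid=[0.1]))
    tr, te = np.arange(300), np.arange(300, 400)
    fp = fb.fit_pipeline(spec, cohort, tr, seed=1)
    return cohort, fp, te


class TestPermutationImportance:
    def test_unselected_feature_scores_exactly_zero(self, fitted):
        cohort, fp, te = fitted
        rep = fb.permutation_importance(fp, cohort, te, n_perm=5, seed=0)
        selected = set(fp.reducers["m"].params["selected"].tolist())
        for j in range(6):
            if j not in selected:
                row = rep.table[rep.table.feature == f"m_{j:03d}"]
                assert row["mean_importance"].iloc[0] == 0.0

    def test_planted_feature_ranks_first(self, fitted):
        cohort, fp, te = fitted
        rep = fb.permutation_importance(fp, cohort, te, n_perm=10, seed=0)
        assert rep.table.iloc[0]["feature"] == "m_000"
        assert rep.table.iloc[0]["mean_importance"] > 0.1

    def test_matches_naive_double_loop_oracle(self, fitted):
        cohort, fp, te = fitted
        rep = fb.permutation_importance(fp, cohort, te, n_perm=400, seed=0)
        # independent naive implementation with its own randomness
        rng = np.random.default_rng(999)
        y = code_labels(cohort.labels, "binary")[te]
        X = cohort.X("m")[te].copy()
        base = np.mean(fp.predict_arrays({"m": X}) == y)
        for j in range(6):
            drops = []
            for _ in range(400):
                Xp = X.copy()
                Xp[:, j] = Xp[rng.permutation(len(te)), j]
                drops.append(base - np.mean(fp.predict_arrays({"m": Xp}) == y))
            row = rep.table[rep.table.feature == f"m_{j:03d}"]
            # two independent 400-draw Monte-Carlo estimates of the same mean
            assert row["mean_importance"].iloc[0] == pytest.approx(
                np.mean(drops), abs=0.02)

    def test_importance_frame_columns(self, fitted):
        cohort, fp, te = fitted
        rep = fb.permutation_importance(fp, cohort, te, n_perm=3, seed=0)
        df = fb.evaluation.importance_frame(rep)
        assert list(df.columns) == ["feature", "modality", "mean_importance",
                                    "sd", "rank"]
        assert len(df) == 6


class TestRunBenchmark:
    def test_results_frame_and_ensembles(self, small_cohort):
        specs, ensembles = fb.standard_grid(
            tuple(small_cohort.modality_names()), seed=1,
            classifier_params={"random_forest": {"n_estimators": 30},
                               "neural_net": {"max_iter": 60}},
            reducer_overrides={"pca": {"n_components": 3},
                               "se": {"n_components": 3, "epochs": 60},
                               "ae": {"n_components": 2, "epochs": 60}},
        )
        # a small sub-grid keeps this a unit test rather than a benchmark
        sub = [s for s in specs if s.name.startswith(("clinical", "simple"))]
        subens = [(n, m) for n, m in ensembles
                  if n.startswith(("clinical", "simple"))]
        plan = SplitPlan(n_repeats=2, base_seed=4)
        out = fb.run_benchmark(small_cohort, sub, subens, plan)
        df = out["results_frame"]
        assert len(df) == len(sub) + len(subens)
        assert (df.loc[df.topology == "ensemble", "reducer"] == "vote").all()
        comp = out["comparisons_frame"]
        assert set(comp.task) <= {"binary", "multiclass"}
        # ensemble accuracy derives from the cached member predictions:
        # rerunning standalone gives the identical numbers
        ens_name, members = subens[0]
        standalone = fb.evaluate_ensemble(
            EnsembleSpec(list(members), ens_name), small_cohort, plan)
        cached = next(r for r in out["results"] if r.name == ens_name)
        assert np.array_equal(standalone.per_split_accuracies,
                              cached.per_split_accuracies)
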