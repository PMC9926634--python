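import numpy as np
import pytest

from omicstack.architectures import HYPERPARAMETER_GRID, HyperparameterSet
from omicstack.comparison import (
    _search,
    draw_hyperparameters,
    inner_cv_with_pruning,
    run_comparison,
    stratified_kfold,
)
from omicstack.synthetic import SyntheticSpec, generate, make_external_shifted

QUICK_GRID = dict(HYPERPARAMETER_GRID, layer_dim=(32, 64), epochs=(3, 4, 5, 6))


class TestStratifiedKfold:
    def test_minority_smaller_than_k_rejected(self):
        y = np.array([1, 1] + [0] * 8)
        with pytest.raises(ValueError, match="minority"):
            stratified_kfold(y, 5, 0)

    def test_exact_divisibility_gives_equal_folds(self):
        y = np.array([1] * 5 + [0] * 15)
        folds = stratified_kfold(y, 5, 0)
        for f in folds:
            assert (y[f] == 1).sum() == 1 and (y[f] == 0).sum() == 3

    def test_partition_property_on_random_label_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(20, 120))
            k = int(rng.integers(2, 6))
            y = np.zeros(n, dtype=int)
            n_pos = int(rng.integers(k, n - k + 1))
            y[rng.permutation(n)[:n_pos]] = 1
            folds = stratified_kfold(y, k, int(rng.integers(1 << 16)))
            allidx = np.concatenate(folds)
            assert len(allidx) == n and len(np.unique(allidx)) == n
            # class proportions within 1 sample of exact proportionality
            for f in folds:
                expected = n_pos * len(f) / n
                assert abs((y[f] == 1).sum() - expected) < 1.0


class TestDrawHyperparameters:
    def test_two_hundred_draws_all_in_grid(self):
        hps = draw_hyperparameters(HYPERPARAMETER_GRID, 200, 0)
        assert len(hps) == 200
        for hp in hps:
            hp.validate_grid()

    def test_reproducible_by_seed(self):
        a = draw_hyperparameters(HYPERPARAMETER_GRID, 50, 7)
        b = draw_hyperparameters(HYPERPARAMETER_GRID, 50, 7)
        assert a == b
        c = draw_hyperparameters(HYPERPARAMETER_GRID, 50, 8)
        assert a != c

    def test_draws_uniform_over_batch_size(self):
        hps = draw_hyperparameters(HYPERPARAMETER_GRID, 10_000, 1)
        counts = {b: 0 for b in HYPERPARAMETER_GRID["batch_size"]}
        for hp in hps:
            counts[hp.batch_size] += 1
        p = 1 / 3
        sigma = np.sqrt(10_000 * p * (1 - p))
        for c in counts.values():
            assert abs(c - 10_000 * p) < 3 * sigma

    def test_empty_grid_dimension_rejected(self):
        bad = dict(HYPERPARAMETER_GRID, margin=())
        with pytest.raises(ValueError, match="margin"):
            draw_hyperparameters(bad, 5, 0)


class TestPruning:
    def test_upper_bound_rule_direct_substitution(self):
        # best mean 0.9; candidate B: after fold 1, bound = (0.5 + 4)/5 = 0.9
        # <= 0.9 -> pruned immediately (equality cannot improve); candidate C:
        # (0.85 + 4)/5 = 0.97 survives fold 1, then (1.25 + 3)/5 = 0.85 <= 0.9
        # -> pruned after two folds
        table = {0: [1.0, 0.9, 0.8, 0.9, 0.9],   # mean 0.9
                 1: [0.5, 1.0, 1.0, 1.0, 1.0],
                 2: [0.85, 0.4, 1.0, 1.0, 1.0]}
        cands = draw_hyperparameters(HYPERPARAMETER_GRID, 3, 0)
        idx = {id(hp): i for i, hp in enumerate(cands)}
        trace, best = _search(lambda hp, j: table[idx[id(hp)]][j], cands, 5)
        assert trace.candidates[0].status == "completed"
        assert trace.candidates[1].status == "pruned"
        assert trace.candidates[1].fold_scores == [0.5]
        assert trace.candidates[2].status == "pruned"
        assert trace.candidates[2].fold_scores == [0.85, 0.4]
        assert best is cands[0]

    def test_first_candidate_never_pruned(self):
        cands = draw_hyperparameters(HYPERPARAMETER_GRID, 1, 0)
        trace, best = _search(lambda hp, j: 0.0, cands, 5)
        assert trace.candidates[0].status == "completed"

    def test_selection_matches_exhaustive_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n_cand, k = int(rng.integers(3, 20)), int(rng.integers(2, 6))
            table = np.round(rng.random((n_cand, k)), 3)
            cands = draw_hyperparameters(HYPERPARAMETER_GRID, n_cand, int(rng.integers(1 << 16)))
            idx = {id(hp): i for i, hp in enumerate(cands)}
            trace, best = _search(lambda hp, j: table[idx[id(hp)], j], cands, k)
            exhaustive_best = table.mean(axis=1).max()
            assert table[idx[id(best)]].mean() == pytest.approx(exhaustive_best)
            # soundness: no pruned candidate could have beaten the winner
            for c in trace.candidates:
                if c.status == "pruned":
                    full = table[idx[id(c.hyperparameters)]].mean()
                    assert full <= exhaustive_best + 1e-12
            assert np.all(np.diff(trace.best_so_far) >= 0)

    def test_all_candidates_failing_reports_diagnostics(self):
        cands = draw_hyperparameters(HYPERPARAMETER_GRID, 3, 0)

        def boom(hp, j):
            raise RuntimeError("exploded")

        with pytest.raises(RuntimeError, match="exploded"):
            _search(boom, cands, 3)


@pytest.fixture(scope="module")
def cv_data():
    spec = SyntheticSpec(n_samples=180, view_dims=(40, 50, 50),
                         n_informative=(12, 12, 12), responder_fraction=0.2, seed=21)
    data = generate(spec)
    external = make_external_shifted(data, 0.3, seed=77, spec=spec, n_samples=80)
    return data, external


class TestRunComparison:
    def test_result_shape_and_leakage_audit(self, cv_data):
        data, external = cv_data
        res = run_comparison(["early_integration"], data, external, seed=0,
                             n_candidates=4, k_outer=3, k_inner=3, grid=QUICK_GRID)
        assert len(res) == 3 * 2  # 3 outer folds x {test, external}
        assert set(res["split"]) == {"test", "external"}
        assert res["auroc"].between(0, 1).all()
        assert res["auprc"].between(0, 1).all()
        # test and external rows of one fold share the same selected model
        for f in range(3):
            fold = res[res["outer_fold"] == f]
            assert fold["selected_hyperparameters"].nunique() == 1

    def test_stacking_variant_labels(self, cv_data):
        data, external = cv_data
        res = run_comparison([("omics_stacking", "without_integration")],
                             data, external, seed=0, n_candidates=2,
                             k_outer=3, k_inner=3, grid=QUICK_GRID)
        assert set(res["architecture"]) == {"omics_stacking:without_integration"}

    def test_view_mismatch_rejected(self, cv_data):
        data, _ = cv_data
        bad_external = generate(SyntheticSpec(n_samples=40, view_dims=(10, 10, 10),
                                              n_informative=(2, 2, 2), seed=1))
        with pytest.raises(ValueError, match="external"):
            run_comparison(["early_integration"], data, bad_external, seed=0,
                           n_candidates=2, k_outer=3, k_inner=3, grid=QUICK_GRID)

    def test_moli_recovers_signal_with_reduced_search(self, oracle_data, oracle_spec):
        external = make_external_shifted(oracle_data, 0.2, seed=55,
                                         spec=oracle_spec, n_samples=150)
        res = run_comparison(["moli"], oracle_data, external, seed=0,
                             n_candidates=5, k_outer=3, k_inner=3, grid=QUICK_GRID)
        mean_test_auroc = res[res["split"] == "test"]["auroc"].mean()
        assert mean_test_auroc >= 0.75


class TestInnerCV:
    def test_search_trains_real_models(self, cv_data):
        data, _ = cv_data
        folds = stratified_kfold(data.labels, 3, 0)
        cands = draw_hyperparameters(QUICK_GRID, 3, 2)
        trace, best = inner_cv_with_pruning("early_integration", cands, data, folds)
        completed = [c for c in trace.candidates if c.status == "completed"]
        assert completed and best in [c.hyperparameters for c in completed]
        assert all(len(c.fold_scores) < 3 for c in trace.candidates
                   if c.status == "pruned")
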