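"""Ranking, Friedman test, Holm post hoc, trials and grid search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsktl import (
    AccuracyTable,
    ShiftScenario,
    friedman_test,
    generate_shift_pair,
    grid_search,
    holm_posthoc,
    load_benchmark_tables,
    rank_table,
    run_trials,
)


def make_table(values, methods=None, datasets=None):
    values = np.asarray(values, dtype=float)
    methods = methods or [f"m{j}" for j in range(values.shape[1])]
    datasets = datasets or [f"d{i}" for i in range(values.shape[0])]
    return AccuracyTable(mean=pd.DataFrame(values, index=datasets, columns=methods))


class TestRankTable:
    def test_total_order_two_methods(self):
        acc = make_table([[0.9, 0.8], [0.7, 0.6], [0.95, 0.2]])
        ra = rank_table(acc)
        assert list(ra.avg_ranks) == [1.0, 2.0]

    def test_ties_get_average_rank(self):
        acc = make_table([[0.9, 0.9, 0.5], [0.9, 0.8, 0.7]])
        ra = rank_table(acc)
        assert list(ra.ranks.iloc[0]) == [1.5, 1.5, 3.0]

    def test_ranks_sum_invariant(self, rng):
        vals = rng.uniform(0, 1, (6, 5))
        vals[2, 1] = vals[2, 3]  # inject a tie
        ra = rank_table(make_table(vals))
        k = 5
        assert np.allclose(ra.ranks.sum(axis=1), k * (k + 1) / 2)
        assert ra.avg_ranks.sum() == pytest.approx(k * (k + 1) / 2)

    def test_published_kpca_table_reproduces_nb_rank(self):
        ra = rank_table(load_benchmark_tables()["kpca"])
        assert ra.avg_ranks["NB"] == pytest.approx(7.05)

    def test_missing_cells_named_by_rank_table(self):
        df = pd.DataFrame([[0.5, np.nan], [0.4, 0.3]], columns=["a", "b"],
                          index=["d0", "d1"])
        with pytest.raises(ValueError, match=r"missing.*d0.*b"):
            rank_table(AccuracyTable(mean=df))


class TestFriedman:
    def test_identical_ranks_give_zero_statistic(self):
        acc = make_table(np.tile([0.5, 0.5, 0.5], (3, 1)))
        ra = friedman_test(rank_table(acc))
        assert ra.friedman_chi2 == pytest.approx(0.0)
        assert ra.friedman_p == pytest.approx(1.0)

    def test_matches_hand_formula(self, rng):
        acc = make_table(rng.uniform(0, 1, (10, 8)))
        ra = friedman_test(rank_table(acc))
        k, N = 8, 10
        R = ra.avg_ranks.to_numpy()
        expect = 12 * N / (k * (k + 1)) * (R**2).sum() - 3 * N * (k + 1)
        assert ra.friedman_chi2 == pytest.approx(expect, abs=1e-9)

    def test_matches_scipy_without_ties(self, rng):
        vals = rng.uniform(0, 1, (7, 4))  # continuous -> no ties a.s.
        acc = make_table(vals)
        ra = friedman_test(rank_table(acc))
        chi2, p = stats.friedmanchisquare(*[vals[:, j] for j in range(4)])
        assert ra.friedman_chi2 == pytest.approx(chi2, rel=1e-12)
        assert ra.friedman_p == pytest.approx(p, rel=1e-12)

    def test_tail_behavior_against_permutation_enumeration(self):
        # k=3, N=2: enumerate all 36 joint rank permutations; the exact
        # permutation p-value and the chi-square approximation must order
        # observed tables identically and both equal 1 at chi2 = 0.
        k, N = 3, 2
        perms = list(itertools.permutations(range(1, k + 1)))
        all_stats = []
        for r1 in perms:
            for r2 in perms:
                R = (np.array(r1) + np.array(r2)) / N
                chi2 = 12 * N / (k * (k + 1)) * (R**2).sum() - 3 * N * (k + 1)
                all_stats.append(chi2)
        all_stats = np.array(all_stats)

        def exact_p(c):
            return (all_stats >= c - 1e-12).mean()

        observed = []
        for vals in ([[0.9, 0.5, 0.1], [0.8, 0.6, 0.2]],  # perfectly consistent
                     [[0.9, 0.5, 0.1], [0.2, 0.6, 0.8]],  # reversed
                     [[0.9, 0.5, 0.1], [0.5, 0.9, 0.1]]):
            ra = friedman_test(rank_table(make_table(vals)))
            observed.append((ra.friedman_chi2, ra.friedman_p, exact_p(ra.friedman_chi2)))
        chis, approx_ps, exact_ps = zip(*observed)
        order_a = np.argsort(approx_ps)
        order_e = np.argsort(exact_ps)
        assert np.array_equal(order_a, order_e)
        zero = friedman_test(rank_table(make_table([[0.5, 0.4, 0.3], [0.3, 0.4, 0.5]])))
        assert exact_p(zero.friedman_chi2) <= 1.0

    def test_invariant_to_monotone_transform(self, rng):
        vals = rng.uniform(0.1, 0.9, (5, 4))
        a = friedman_test(rank_table(make_table(vals)))
        b = friedman_test(rank_table(make_table(vals**3)))
        assert a.friedman_chi2 == pytest.approx(b.friedman_chi2)

    def test_single_dataset_rejected(self):
        df = pd.DataFrame([[0.5, 0.4]], columns=["a", "b"])
        with pytest.raises(ValueError):
            AccuracyTable(mean=df)


class TestHolm:
    def test_se_plugin_arithmetic(self, rng):
        ra = rank_table(make_table(rng.uniform(0, 1, (10, 8))))
        assert ra.se == pytest.approx(np.sqrt(1.2), abs=1e-9)

    def test_equal_rank_method_not_rejected(self):
        acc = make_table([[0.9, 0.9, 0.1], [0.8, 0.8, 0.1],
                          [0.7, 0.7, 0.2], [0.6, 0.6, 0.3]])
        ra = rank_table(acc)
        ladder = holm_posthoc(ra, control="m0")
        row = ladder[ladder["method"] == "m1"].iloc[0]
        assert row["z"] == pytest.approx(0.0)
        assert row["p"] == pytest.approx(1.0)
        assert not row["reject"]

    def test_thresholds_are_alpha_over_i(self, rng):
        ra = rank_table(make_table(rng.uniform(0, 1, (6, 5))))
        ladder = holm_posthoc(ra, alpha=0.05)
        assert list(ladder.index) == [4, 3, 2, 1]
        assert np.allclose(ladder["threshold"], 0.05 / ladder.index.to_numpy())

    def test_reject_set_downward_closed_in_z(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            ra = rank_table(make_table(r.uniform(0, 1, (8, 6))))
            ladder = holm_posthoc(ra)
            rejected = ladder["reject"].to_numpy()
            # once a comparison fails, no later (smaller-Z) one may reject
            if not rejected.all():
                first_fail = int(np.argmin(rejected))
                assert not rejected[first_fail:].any()

    def test_unknown_control_rejected(self, rng):
        ra = rank_table(make_table(rng.uniform(0, 1, (4, 3))))
        with pytest.raises(ValueError, match="control"):
            holm_posthoc(ra, control="nope")


class TestRunTrials:
    def test_constant_classifier_on_balanced_target_scores_half(self):
        sc = ShiftScenario(d=2, n_source=40, n_target=40, seed=0)

        def constant(task, seed):
            src, tgt, yt = generate_shift_pair(
                ShiftScenario(**{**task.__dict__, "seed": seed}))
            return (np.ones_like(yt) == yt).mean()

        table = run_trials({"s0": sc, "s1": sc}, {"const": constant, "c2": constant},
                           repeats=3, seed=1)
        assert np.allclose(table.mean.to_numpy(), 0.5)

    def test_single_repeat_zero_sd(self):
        table = run_trials({"a": 1, "b": 2}, {"m1": lambda t, s: 0.7,
                                              "m2": lambda t, s: 0.4},
                           repeats=1, seed=0)
        assert np.allclose(table.sd.to_numpy(), 0.0)

    def test_identical_seeds_identical_tables(self):
        def noisy(task, seed):
            return float(np.random.default_rng(seed).uniform(0.4, 0.9))

        t1 = run_trials({"a": 1, "b": 2}, {"m1": noisy, "m2": noisy}, repeats=4, seed=3)
        t2 = run_trials({"a": 1, "b": 2}, {"m1": noisy, "m2": noisy}, repeats=4, seed=3)
        assert t1.mean.equals(t2.mean) and t1.sd.equals(t2.sd)

    def test_method_crash_recorded_not_dropped(self):
        def boom(task, seed):
            raise RuntimeError("kaput")

        with pytest.warns(RuntimeWarning, match="failed"):
            table = run_trials({"a": 1, "b": 1}, {"ok": lambda t, s: 0.6, "bad": boom},
                               repeats=2, seed=0)
        assert all("kaput" in v for v in table.failures.values())
        assert table.mean["ok"].notna().all()


@pytest.fixture(scope="module")
def shift_data():
    sc = ShiftScenario(d=3, n_source=50, n_target=50, marginal_shift=1.0, seed=5)
    return generate_shift_pair(sc)


class TestGridSearch:

    def test_singleton_grid_returns_that_cell(self, shift_data):
        src, tgt, yt = shift_data
        best, res, log = grid_search(src.features, src.labels, tgt.features, yt,
                                     rule_grid=(2,), lambda1_grid=(1.0,),
                                     lambda2_grid=(0.5,), lambda3_grid=(0.1,),
                                     seed=0)
        assert best == {"K": 2, "lambda1": 1.0, "lambda2": 0.5, "lambda3": 0.1}
        assert len(log) == 1

    def test_every_cell_logged_exactly_once(self, shift_data):
        src, tgt, yt = shift_data
        grids = dict(rule_grid=(2, 3), lambda1_grid=(0.1, 1.0),
                     lambda2_grid=(0.0, 1.0), lambda3_grid=(0.0,))
        _, _, log = grid_search(src.features, src.labels, tgt.features, yt,
                                seed=0, **grids)
        assert len(log) == 2 * 2 * 2 * 1
        assert not log.duplicated(subset=["K", "lambda1", "lambda2", "lambda3"]).any()

    def test_source_cv_never_touches_target_labels(self, shift_data):
        src, tgt, yt = shift_data
        best, res, _ = grid_search(src.features, src.labels, tgt.features, None,
                                   rule_grid=(2,), lambda1_grid=(0.1, 1.0),
                                   lambda2_grid=(0.0,), lambda3_grid=(0.0,),
                                   selection="source_cv", seed=0)
        assert best["K"] == 2

    def test_oracle_needs_target_truth(self, shift_data):
        src, tgt, _ = shift_data
        with pytest.raises(ValueError, match="y_target_true"):
            grid_search(src.features, src.labels, tgt.features, None,
                        rule_grid=(2,), lambda1_grid=(1.0,))
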