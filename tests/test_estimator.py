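import math
import warnings

import numpy as np
import pytest
from scipy import optimize, stats

import sparsecmm as sc
from sparsecmm.estimator import AugmentationPlan, ProblemStatus, SolverOptions
from sparsecmm.models import IdentityLink

FULL3 = np.array(sc.full_support((2, 2, 2)))
MH_SOLUTION = np.array([20.000, 14.397, 8.060, 11.695, 0.000, 19.755, 26.092, 30.000])


def slsqp_oracle(model, patterns, n, N, restarts=6, seed=0):
    """Independent constrained maximizer of sum(n log m) over the simplex."""
    patterns = np.asarray(patterns)
    ev = model.evaluator(patterns)
    S = len(patterns)
    rng = np.random.default_rng(seed)

    def negll(m):
        m = np.maximum(m, 1e-12)
        pos = n > 0
        return -np.sum(n[pos] * np.log(m[pos]))

    cons = [
        {
            "type": "eq",
            "fun": lambda m: np.append(ev.g(np.maximum(m, 1e-12), N), m.sum() - N),
        }
    ]
    best = None
    starts = [n + 0.5, np.full(S, N / S)] + [
        N * rng.dirichlet(np.ones(S)) for _ in range(restarts - 2)
    ]
    for x0 in starts:
        res = optimize.minimize(
            negll,
            x0,
            method="SLSQP",
            bounds=[(0.0, N)] * S,
            constraints=cons,
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if not res.success:
            continue
        m = np.maximum(res.x, 1e-12)
        if np.abs(ev.g(m, N)).max() > 1e-6 * N:
            continue
        G2 = 2 * np.sum(n[n > 0] * np.log(n[n > 0] / m[n > 0]))
        if best is None or G2 < best:
            best = G2
    return best


class TestMLFits:
    def test_marginal_homogeneity_reference_fit(self, three_item_table):
        result = sc.fit(sc.mean_model(3), three_item_table, method="ml")
        assert result.converged
        assert result.m_hat == pytest.approx(MH_SOLUTION, abs=1e-3)
        assert result.G2 == pytest.approx(2.6107, abs=5e-4)
        assert result.df == 2
        assert result.p_value == pytest.approx(0.2711, abs=5e-4)

    def test_saturated_feasible_point_is_identity(self):
        # a table already satisfying marginal homogeneity: m_hat = n, G2 = 0
        table = sc.build_table(
            [((0, 0), 20), ((0, 1), 7), ((1, 0), 7), ((1, 1), 16)]
        )
        result = sc.fit(sc.mean_model(2), table, method="ml")
        assert result.G2 == pytest.approx(0.0, abs=1e-8)
        assert result.m_hat == pytest.approx(table.dense_counts(), abs=1e-5)

    def test_scalability_constraint_fit(self, three_item_table):
        result = sc.fit(sc.hj_model(3, 0.3), three_item_table, method="ml")
        assert result.converged and result.df == 3
        # the fitted deviance agrees with an independent constrained
        # maximizer, and with the printed significance level p = 0.0023
        oracle = slsqp_oracle(
            sc.hj_model(3, 0.3), FULL3, three_item_table.dense_counts(), 130.0
        )
        assert result.G2 == pytest.approx(oracle, abs=1e-3)
        assert round(result.p_value, 4) == pytest.approx(0.0023, abs=2e-4)

    def test_extreme_sparsity_boundary_fit(self, sparse_two_pattern_table):
        result = sc.fit(sc.mean_model(3), sparse_two_pattern_table, method="ml")
        assert result.converged
        assert result.G2 == pytest.approx(180.22, abs=0.01)
        assert result.m_hat == pytest.approx(
            [0, 32.5, 0, 32.5, 32.5, 0, 32.5, 0], abs=1e-3
        )

    def test_dense_cap_blocks_huge_ml(self):
        table = sc.build_table([(0,) * 30, (1,) * 30])
        with pytest.raises(sc.TableSizeError):
            sc.fit(sc.mean_model(30), table, method="ml")


class TestMELFits:
    def test_observed_support_reproduces_reference_fit(self, three_item_table):
        result = sc.fit(sc.mean_model(3), three_item_table, method="mel")
        assert len(result.support) == 7
        assert result.G2 == pytest.approx(2.611, abs=5e-4)
        # identical fitted values on the observed cells
        keep = [i for i, p in enumerate(FULL3) if tuple(p) != (1, 0, 0)]
        assert result.m_hat == pytest.approx(MH_SOLUTION[keep], abs=1e-3)

    def test_ml_equals_mel_on_dense_tables(self, rng):
        from conftest import random_dense_table

        for _ in range(5):
            table = random_dense_table(rng, J=3, max_cat=2)
            ml = sc.fit(sc.mean_model(3), table, method="ml")
            mel = sc.fit(sc.mean_model(3), table, method="mel")
            assert ml.m_hat == pytest.approx(mel.m_hat, abs=1e-8)
            assert ml.G2 == pytest.approx(mel.G2, abs=1e-10)

    def test_mel_equals_mael_with_empty_plan(self, rng):
        from conftest import random_dense_table

        table = random_dense_table(rng, J=3, max_cat=2)
        mel = sc.fit(sc.mean_model(3), table, method="mel")
        mael = sc.fit(sc.mean_model(3), table, method="mael", seed=3)
        assert mael.plan.added_cells == []
        assert mel.m_hat == pytest.approx(mael.m_hat, abs=0)
        assert mel.G2 == mael.G2

    def test_infeasible_support_raises_first_order(self):
        table = sc.fixtures.single_cell_2x2()
        with pytest.raises(sc.FirstOrderProblem):
            sc.fit(sc.mean_model(2), table, method="mel")

    def test_degenerate_support_raises_second_order(self):
        table = sc.fixtures.diagonal_2x2()
        with pytest.raises(sc.SecondOrderProblem):
            sc.fit(sc.mean_model(2), table, method="mel")

    def test_unreachable_scalability_raises_first_order(self):
        table = sc.fixtures.guttman_pair()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sc.hj_model(2, 0.3)
        with pytest.raises(sc.FirstOrderProblem):
            sc.fit(model, table, method="mel", seed=5)


class TestMAELFits:
    def test_five_cell_augmented_fit(self, sparse_two_pattern_table):
        plan = AugmentationPlan(
            added_cells=[(0, 0, 0), (0, 1, 1), (1, 0, 1)], seed=None, level="second"
        )
        result = sc.fit(
            sc.mean_model(3), sparse_two_pattern_table, method="mael", plan=plan
        )
        assert result.converged
        assert [tuple(p) for p in result.support] == [
            (0, 0, 0), (0, 1, 1), (1, 0, 0), (1, 0, 1), (1, 1, 0),
        ]
        assert result.m_hat == pytest.approx(
            [0, 54.1667, 32.5, 21.6667, 21.6667], abs=1e-3
        )
        # closed form: G2 = 2·65·(log 2 + log 3)
        assert result.G2 == pytest.approx(130 * math.log(6), abs=1e-3)
        assert result.G2 == pytest.approx(232.93, abs=0.01)

    def test_too_small_augmentation_is_a_boundary_infinite_deviance_case(
        self, sparse_two_pattern_table
    ):
        # adding only cell 011 leaves the constraints forcing m_110 to zero
        # against 65 observations: the exact optimum has infinite deviance,
        # and any finite value is an artifact of where the solver stops
        plan = AugmentationPlan(added_cells=[(0, 1, 1)], seed=None, level="first")
        result = sc.fit(
            sc.mean_model(3), sparse_two_pattern_table, method="mael", plan=plan
        )
        assert result.G2 == math.inf
        assert result.G2_truncated is not None and result.G2_truncated > 180.22
        idx110 = [tuple(p) for p in result.support].index((1, 1, 0))
        assert idx110 in result.boundary_cells
        assert result.p_value == 0.0

    def test_augmentation_shrinks_deviance_towards_ml(self, sparse_two_pattern_table):
        # nested supports: a larger support can only lower the constrained
        # optimum, and ML (full support) is the floor
        table = sparse_two_pattern_table
        model = sc.mean_model(3)
        five = sc.fit(model, table, method="mael",
                      plan=AugmentationPlan([(0, 0, 0), (0, 1, 1), (1, 0, 1)], None, "second"))
        seven = sc.fit(model, table, method="mael",
                       plan=AugmentationPlan(
                           [(0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1), (1, 0, 1)],
                           None, "second"))
        ml = sc.fit(model, table, method="ml")
        assert ml.G2 <= seven.G2 + 1e-6 <= five.G2 + 1e-6

    def test_automatic_augmentation_restores_estimability(self):
        table = sc.fixtures.diagonal_2x2()
        result = sc.fit(sc.mean_model(2), table, method="mael", seed=11)
        assert result.converged
        assert len(result.plan.added_cells) >= 1
        status = sc.detect_second_order_problem(sc.mean_model(2), result.support)
        assert status is ProblemStatus.ABSENT


class TestAugmentSupport:
    def test_covered_table_yields_empty_plan(self, rng):
        from conftest import random_dense_table

        table = random_dense_table(rng, J=3, max_cat=2)
        plan = sc.augment_support(table, sc.mean_model(3), seed=1, level="first")
        assert plan.added_cells == []

    def test_deterministic_given_seed(self, sparse_two_pattern_table):
        model = sc.mean_model(3)
        p1 = sc.augment_support(sparse_two_pattern_table, model, seed=9, level="second")
        p2 = sc.augment_support(sparse_two_pattern_table, model, seed=9, level="second")
        assert p1.added_cells == p2.added_cells
        p3 = sc.augment_support(sparse_two_pattern_table, model, seed=10, level="second")
        assert p1.added_cells != p3.added_cells or p1.seed != p3.seed

    def test_first_level_covers_every_margin(self, sparse_two_pattern_table):
        model = sc.mean_model(3)
        plan = sc.augment_support(
            sparse_two_pattern_table, model, seed=2, level="first"
        )
        support = sparse_two_pattern_table.patterns + plan.added_cells
        for spec in model.margins:
            assert any(spec.matches(p) for p in support)
        # added cells are genuine zero cells, no duplicates
        assert len(set(plan.added_cells)) == len(plan.added_cells)
        assert not set(plan.added_cells) & set(sparse_two_pattern_table.patterns)

    def test_second_level_passes_rank_test(self, sparse_two_pattern_table):
        model = sc.mean_model(3)
        plan = sc.augment_support(
            sparse_two_pattern_table, model, seed=3, level="second"
        )
        support = sparse_two_pattern_table.patterns + plan.added_cells
        assert (
            sc.detect_second_order_problem(model, support)
            is ProblemStatus.ABSENT
        )

    def test_extra_cells_appended(self, sparse_two_pattern_table):
        model = sc.mean_model(3)
        base = sc.augment_support(sparse_two_pattern_table, model, seed=4)
        extra = sc.augment_support(sparse_two_pattern_table, model, seed=4, extra=2)
        assert len(extra.added_cells) == len(base.added_cells) + 2


class TestProblemDetectors:
    def test_single_cell_support_is_infeasible(self):
        model = sc.mean_model(2)
        assert (
            sc.detect_first_order_problem(model, [(0, 1)], 1.0)
            is ProblemStatus.PRESENT
        )

    def test_diagonal_support_is_feasible_but_degenerate(self):
        model = sc.mean_model(2)
        support = [(0, 0), (1, 1)]
        assert (
            sc.detect_first_order_problem(model, support, 2.0)
            is ProblemStatus.ABSENT
        )
        assert (
            sc.detect_second_order_problem(model, support) is ProblemStatus.PRESENT
        )

    def test_full_support_has_neither_problem(self):
        model = sc.mean_model(2)
        support = sc.full_support((2, 2))
        assert (
            sc.detect_first_order_problem(model, support, 4.0)
            is ProblemStatus.ABSENT
        )
        assert sc.detect_second_order_problem(model, support) is ProblemStatus.ABSENT

    def test_two_pattern_support_is_degenerate(self):
        model = sc.mean_model(3)
        support = [(1, 0, 0), (1, 1, 0)]
        assert sc.detect_second_order_problem(model, support) is ProblemStatus.PRESENT

    def test_nonlinear_infeasibility_detected_heuristically(self):
        table = sc.fixtures.guttman_pair()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sc.hj_model(2, 0.3)
        assert (
            sc.detect_first_order_problem(model, table.patterns, table.N, seed=1)
            is ProblemStatus.PRESENT
        )


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        n = np.array([5.0, 10.0, 5.0])
        gof = sc.goodness_of_fit(n, n, df=2)
        assert gof.G2 == 0.0 and gof.X2 == 0.0 and gof.p_value == 1.0

    def test_closed_form_augmented_example(self):
        n = np.array([0.0, 0, 65, 0, 65])
        m = np.array([0.0, 54.1667, 32.5, 21.6667, 21.6667])
        gof = sc.goodness_of_fit(n, m, df=2)
        assert gof.G2 == pytest.approx(130 * math.log(6), abs=1e-3)

    def test_positive_count_on_zero_expectation_is_infinite(self):
        n = np.array([65.0, 65.0])
        m = np.array([130.0, 0.0])
        gof = sc.goodness_of_fit(n, m, df=1)
        assert gof.G2 == math.inf and gof.p_value == 0.0
        assert gof.G2_truncated is not None

    def test_mismatched_totals_rejected(self):
        with pytest.raises(ValueError):
            sc.goodness_of_fit(np.array([3.0]), np.array([5.0]), df=1)


class TestSolverProperties:
    def test_lagrangian_stationarity_at_fixed_point(self, three_item_table):
        model = sc.mean_model(3)
        result = sc.fit(model, three_item_table, method="ml")
        ev = model.evaluator(np.asarray(result.support))
        _, G = ev.g_and_G(np.maximum(result.m_hat, 1e-10), 130.0)
        Gt = np.vstack([G, np.ones(len(result.support))])
        n = result.n
        interior = result.m_hat > 1e-6 * 130
        # fixed point: m = n − D_m G̃ᵀλ, so n_i/m_i − (G̃ᵀλ)_i = 1 on
        # interior cells (the sum-constraint multiplier absorbs μ − 1)
        resid = n[interior] / result.m_hat[interior] - (Gt.T @ result.lam)[interior]
        assert np.max(np.abs(resid - 1.0)) < 1e-6

    def test_oracle_equivalence_on_random_tables(self, rng):
        from conftest import random_dense_table

        # each model family against an independent general-purpose
        # constrained maximizer on small full-support tables
        for trial in range(3):
            table = random_dense_table(rng, J=3, max_cat=2, min_count=2)
            n = table.dense_counts()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models = [
                    sc.mean_model(3),
                    sc.alpha_model(
                        3, criterion=float(np.clip(sc.coefficient_alpha(table) - 0.05, 0.05, 0.9))
                    ),
                    sc.hj_model(
                        3,
                        criterion=float(
                            np.clip(np.mean(sc.item_scalability(table)) - 0.05, 0.05, 0.9)
                        ),
                    ),
                ]
            for model in models:
                ours = sc.fit(model, table, method="ml")
                assert ours.converged
                oracle = slsqp_oracle(model, FULL3, n, table.N, seed=trial)
                assert oracle is not None
                assert ours.G2 == pytest.approx(oracle, abs=1e-3)

    def test_constraints_hold_at_every_converged_fit(self, rng):
        from conftest import random_dense_table

        for _ in range(5):
            table = random_dense_table(rng, J=3, max_cat=2)
            result = sc.fit(sc.mean_model(3), table, method="ml")
            assert result.converged
            assert abs(result.m_hat.sum() - table.N) < 1e-6 * table.N
            g, _ = sc.evaluate_constraints(
                sc.mean_model(3), np.asarray(result.support), result.m_hat, table.N
            )
            assert np.max(np.abs(g)) < 1e-6 * table.N

    def test_warm_start_reconverges_immediately(self, three_item_table):
        model = sc.mean_model(3)
        first = sc.fit(model, three_item_table, method="ml")
        again = sc.fit(
            model,
            three_item_table,
            method="ml",
            options=SolverOptions(start=first.m_hat),
        )
        assert again.converged and again.iterations <= 2
        assert again.G2 == pytest.approx(first.G2, abs=1e-5)


class TestStandardErrors:
    def test_saturated_margin_se_is_multinomial_closed_form(self):
        # D = 0 model reporting one univariate margin: SE = sqrt(m(N−m)/N)
        table = sc.build_table([((0, 0), 30), ((0, 1), 20), ((1, 0), 25), ((1, 1), 25)])
        model = sc.CMModel(
            name="margin-report",
            cats=(2, 2),
            margins=[sc.MarginSpec((0,), (1,))],
            link=IdentityLink(),
            B_t=np.zeros((0, 1)),
            criterion=np.zeros(0),
            Z=np.array([[1.0]]),
        )
        result = sc.fit(model, table, method="ml")
        assert result.converged
        m = 50.0
        N = 100.0
        se = sc.beta_se(model, result, N)
        assert se[0] == pytest.approx(math.sqrt(m * (N - m) / N), rel=1e-6)

    def test_reference_fit_reports_finite_se(self, three_item_table):
        result = sc.fit(sc.mean_model(3), three_item_table, method="ml")
        assert result.beta_se is not None and result.beta_se[0] > 0
        assert result.overall_mean == pytest.approx(0.5834, abs=1e-3)
        assert result.overall_mean_se == pytest.approx(
            result.beta_se[0] / (math.sqrt(3) * 130.0)
        )


class TestFitReportRoundTrip:
    def test_report_serializes_and_warm_restarts(self, three_item_table, tmp_path):
        model = sc.mean_model(3)
        result = sc.fit(model, three_item_table, method="mel")
        path = tmp_path / "report.json"
        sc.write_fit_report(result, three_item_table.cats, path)
        doc = sc.read_fit_report(path)
        assert doc["G2"] == pytest.approx(result.G2)
        assert doc["df"] == 2 and doc["converged"]
        start = np.array(
            [doc["m_hat_patterns"][p] for p in three_item_table.patterns]
        )
        again = sc.fit(
            model, three_item_table, method="mel", options=SolverOptions(start=start)
        )
        assert again.converged and again.iterations <= 2
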