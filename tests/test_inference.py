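"""Resampling tests and conformal prediction: formulas, edge cases, validity."""

import numpy as np
import pytest

from cocreg.estimation import FitConfig, lambda_max
from cocreg.inference import (ConformalCalibration, bootstrap_test,
                              conformal_projection_grid,
                              full_conformal_contains, full_conformal_pvalue,
                              permutation_test, rowwise_kld,
                              split_conformal_calibrate,
                              split_conformal_contains)
from cocreg.simplex import CoefficientMatrix
from cocreg.simulation import Scenario, gen_responses, simulate_dataset

FAST = dict(max_iter=400, cv_max_iter=150, n_grid=6)


class TestResamplingTests:
    def test_single_bootstrap_pvalue_is_half_or_one(self, tiny_tables):
        x, y = tiny_tables
        tr = bootstrap_test(x, y, FitConfig(lam=0.01, **FAST), n_boot=1, seed=4)
        assert tr.p_value in (0.5, 1.0)

    def test_pvalue_formula_never_zero(self, tiny_tables):
        x, y = tiny_tables
        tr = bootstrap_test(x, y, FitConfig(lam=0.02, **FAST), n_boot=19, seed=0)
        assert 1 / 20 <= tr.p_value <= 1.0
        assert tr.p_value == pytest.approx(
            (1 + np.sum(tr.statistics_null >= tr.statistic_observed)) / 20)

    def test_permutation_identical_rows_gives_p_one(self, rng):
        x = rng.dirichlet(np.ones(4), size=16)
        y = np.tile(rng.dirichlet(np.ones(3)), (16, 1))
        tr = permutation_test(x, y, FitConfig(lam=0.0, **FAST), n_perm=9, seed=1)
        assert tr.p_value == 1.0

    def test_statistic_invariant_to_common_row_reordering(self, rng):
        sc = Scenario(p=5, q=4, n=30, signal="dense", concentration=50.0, seed=9)
        x, _, y = simulate_dataset(sc)
        perm = rng.permutation(30)
        cfg = FitConfig(lam=0.05, **FAST)
        a = bootstrap_test(x.values, y.values, cfg, n_boot=5, seed=3)
        b = bootstrap_test(x.values[perm], y.values[perm], cfg, n_boot=5, seed=3)
        assert a.statistic_observed == pytest.approx(b.statistic_observed, abs=1e-9)

    def test_bootstrap_null_pvalues_stochastically_valid(self):
        """Under H0, the test as actually run (penalty weight selected by CV
        on the observed data) produces p-values that are stochastically at
        least uniform: rejection at level alpha stays within binomial noise
        of alpha.  (At a fixed, deliberately under-shrunk penalty the
        residual bootstrap is anti-conservative because overfit residuals
        understate the null variation; CV selection is part of the
        procedure, not an optional refinement.)"""
        alpha, n_sims, n_boot = 0.2, 40, 39
        rej, pvals = 0, []
        for s in range(n_sims):
            rng = np.random.default_rng([77, s])
            x = rng.dirichlet(np.ones(5), size=30)
            y = rng.dirichlet(np.ones(5) * 2, size=30)  # independent of x
            tr = bootstrap_test(x, y, FitConfig(lam="auto", **FAST),
                                n_boot=n_boot, seed=1000 + s)
            pvals.append(tr.p_value)
            rej += tr.p_value <= alpha
        rate = rej / n_sims
        assert rate <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_sims)
        assert np.mean(pvals) >= 0.4

    def test_invalid_resample_counts(self, tiny_tables):
        x, y = tiny_tables
        with pytest.raises(ValueError):
            bootstrap_test(x, y, n_boot=0)
        with pytest.raises(ValueError):
            permutation_test(x, y, n_perm=0)


class TestFullConformal:
    def test_two_ranks_only_with_single_sample(self, rng):
        x = rng.dirichlet(np.ones(3), size=1)
        y = rng.dirichlet(np.ones(3), size=1)
        pi = full_conformal_pvalue(x, y, rng.dirichlet(np.ones(3)),
                                   rng.dirichlet(np.ones(3)),
                                   FitConfig(lam=0.1, **FAST))
        assert pi in (0.5, 1.0)

    def test_outlandish_candidate_ranks_higher(self, rng):
        # central data: a near-vertex candidate must conform less than a
        # central one
        x = rng.dirichlet(np.ones(4) * 5, size=25)
        y = rng.dirichlet(np.ones(3) * 5, size=25)
        x_new = np.full(4, 0.25)
        cfg = FitConfig(lam=0.05, **FAST)
        pi_far = full_conformal_pvalue(x, y, x_new, np.array([0.98, 0.01, 0.01]), cfg)
        pi_central = full_conformal_pvalue(x, y, x_new, np.full(3, 1 / 3), cfg)
        assert pi_far > pi_central

    def test_large_response_dimension_guarded(self, rng):
        x = rng.dirichlet(np.ones(3), size=8)
        y = rng.dirichlet(np.ones(11), size=8)
        with pytest.raises(ValueError, match="split"):
            full_conformal_pvalue(x, y, x[0], y[0])

    def test_membership_rule(self):
        assert full_conformal_contains(0.5, n=9, alpha=0.05)
        assert not full_conformal_contains(1.0, n=99, alpha=0.05)


class TestSplitConformal:
    @pytest.fixture
    def cal(self, small_dataset):
        x, _, y = small_dataset
        return split_conformal_calibrate(x, y, 0.1, FitConfig(lam=0.02, **FAST), seed=2)

    def test_cutoff_is_calibration_order_statistic(self, cal):
        n2 = cal.scores.size
        rank = int(np.ceil((n2 + 1) * (1 - cal.alpha)))
        assert cal.cutoff_c == pytest.approx(np.sort(cal.scores)[rank - 1])

    def test_tiny_alpha_gives_whole_simplex(self, small_dataset):
        x, _, y = small_dataset
        cal = split_conformal_calibrate(x, y, 1e-4, FitConfig(lam=0.02, **FAST), seed=2)
        assert cal.whole_simplex
        assert split_conformal_contains(cal, np.full(6, 1 / 6), np.array([0.97, 0.01, 0.01, 0.01]))

    def test_equal_scores_give_that_cutoff(self, rng):
        x = np.tile(rng.dirichlet(np.ones(4)), (12, 1))
        y = np.tile(rng.dirichlet(np.ones(3)), (12, 1))
        cal = split_conformal_calibrate(x, y, 0.2, FitConfig(lam=0.0, **FAST), seed=0)
        assert cal.cutoff_c == pytest.approx(cal.scores[0], abs=1e-10)
        assert np.allclose(cal.scores, cal.scores[0])

    def test_cutoff_nondecreasing_in_coverage(self, small_dataset):
        x, _, y = small_dataset
        cuts = [split_conformal_calibrate(x, y, a, FitConfig(lam=0.02, **FAST),
                                          seed=5).cutoff_c
                for a in (0.5, 0.2, 0.05)]
        assert cuts[0] <= cuts[1] <= cuts[2]

    def test_exact_prediction_always_inside(self, cal):
        x_new = np.full(6, 1 / 6)
        y_hat = cal.B_hat.entries @ x_new
        assert split_conformal_contains(cal, x_new, y_hat)

    def test_candidate_outside_support_excluded(self):
        B = CoefficientMatrix(np.array([[1.0, 1.0], [0.0, 0.0]]))
        cal = ConformalCalibration(B_hat=B, scores=np.zeros(5), cutoff_c=10.0,
                                   alpha=0.1, split_seed=0, lambda_used=0.0)
        assert not split_conformal_contains(cal, np.array([0.5, 0.5]),
                                            np.array([0.5, 0.5]))

    def test_odd_sample_size_split(self, rng):
        x = rng.dirichlet(np.ones(4), size=13)
        y = rng.dirichlet(np.ones(3), size=13)
        cal = split_conformal_calibrate(x, y, 0.2, FitConfig(lam=0.1, **FAST), seed=1)
        assert cal.train_index.size == 7 and cal.calibration_index.size == 6

    def test_fresh_pair_coverage_at_least_nominal(self):
        """Marginal validity: fresh i.i.d. pairs fall in the region at least
        1 - alpha of the time, up to binomial noise."""
        alpha, hits, trials = 0.2, 0, 60
        sc = Scenario(p=5, q=3, n=40, signal="dense", concentration=20.0, seed=31)
        for s in range(trials):
            rng = np.random.default_rng([31, s])
            x, B, y = simulate_dataset(sc, rng)
            x_new = rng.dirichlet(np.ones(5))
            y_new = gen_responses(x_new[None, :], B, 20.0, rng).values[0]
            cal = split_conformal_calibrate(x, y, alpha,
                                            FitConfig(lam="auto", **FAST),
                                            seed=int(rng.integers(2**31)))
            hits += split_conformal_contains(cal, x_new, y_new)
        assert hits / trials >= (1 - alpha) - 2 * np.sqrt(alpha * (1 - alpha) / trials)


class TestProjectionGrid:
    @pytest.fixture
    def cal3(self, rng):
        sc = Scenario(p=4, q=3, n=40, signal="dense", concentration=30.0, seed=12)
        x, _, y = simulate_dataset(sc)
        return split_conformal_calibrate(x.values, y.values, 0.2,
                                         FitConfig(lam=0.02, **FAST), seed=3)

    def test_matches_pointwise_membership(self, cal3):
        x_new = np.full(4, 0.25)
        grid = conformal_projection_grid(cal3, x_new, resolution=6)
        q = 3
        for row in grid.itertuples():
            cand = np.zeros(q)
            cand[row.k], cand[row.k_prime] = row.u, row.v
            rest = 1.0 - row.u - row.v
            others = np.ones(q, bool)
            others[[row.k, row.k_prime]] = False
            cand[others] = rest / (q - 2)
            assert row.inside == split_conformal_contains(cal3, x_new, cand)

    def test_covers_all_pairs_on_a_valid_lattice(self, cal3):
        grid = conformal_projection_grid(cal3, np.full(4, 0.25), resolution=5)
        pairs = set(map(tuple, grid[["k", "k_prime"]].drop_duplicates().values))
        assert pairs == {(0, 1), (0, 2), (1, 2)}
        assert (grid.u + grid.v <= 1 + 1e-12).all()
        # the lattice is symmetric in (u, v), so swapping the two projection
        # axes is a relabelling of the same candidate set
        sub = grid[(grid.k == 0) & (grid.k_prime == 1)]
        pts = {(round(r.u, 9), round(r.v, 9)) for r in sub.itertuples()}
        assert pts == {(v, u) for (u, v) in pts}

    def test_infinite_cutoff_flags_everything_inside(self, cal3):
        cal = ConformalCalibration(B_hat=cal3.B_hat, scores=cal3.scores,
                                   cutoff_c=np.inf, alpha=0.001, split_seed=0,
                                   lambda_used=cal3.lambda_used)
        grid = conformal_projection_grid(cal, np.full(4, 0.25), resolution=4)
        assert grid.inside.all()

    def test_resolution_validated(self, cal3):
        with pytest.raises(ValueError):
            conformal_projection_grid(cal3, np.full(4, 0.25), resolution=1)


class TestRowwiseKLD:
    def test_matches_direct_formula_and_inf_on_support_violation(self):
        y = np.array([[0.5, 0.5], [1.0, 0.0]])
        yhat = np.array([[0.25, 0.75], [0.0, 1.0]])
        out = rowwise_kld(y, yhat)
        assert out[0] == pytest.approx(0.5 * np.log(2) + 0.5 * np.log(2 / 3))
        assert out[1] == np.inf
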