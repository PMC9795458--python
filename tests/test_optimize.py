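"""Sequential-search tests: expected improvement, candidate selection,
the BO loop, and the GA baseline."""

import numpy as np
import pytest
from scipy.stats import norm

from bntopo import (
    BNPModel,
    KernelHyperparams,
    SurrogateState,
    TopologySpace,
    UnknownEntrySet,
    encode_observations,
    expected_improvement,
    ga_baseline,
    log_likelihood,
    run_inference,
    select_next,
    simulate,
)
from bntopo.optimize import _ei_over


class TestExpectedImprovement:
    def test_zero_variance_cases(self):
        assert expected_improvement(0.0, 0.0, 0.0) == 0.0
        assert expected_improvement(-1.0, 0.0, 0.0) == 0.0
        assert expected_improvement(2.0, 0.0, 0.0) == 2.0

    def test_zero_gap_unit_sd(self):
        assert expected_improvement(5.0, 1.0, 5.0) == pytest.approx(1 / np.sqrt(2 * np.pi), rel=1e-9)
        assert expected_improvement(5.0, 1.0, 5.0) == pytest.approx(0.398942, abs=1e-6)

    def test_positive_gap_closed_form(self):
        value = expected_improvement(2.0, 1.0, 0.0)
        assert value == pytest.approx(2 * norm.cdf(2) + norm.pdf(2), rel=1e-12)
        assert value == pytest.approx(2.008491, abs=1e-6)

    def test_vectorized_and_nonnegative(self):
        rng = np.random.default_rng(0)
        mean, var = rng.normal(size=100), rng.uniform(0, 2, size=100)
        ei = expected_improvement(mean, var, 0.5)
        assert ei.shape == (100,)
        assert (ei >= 0).all()


def _tiny_space(L=2, d=3, p=0.2, seed=0):
    rng = np.random.default_rng(seed)
    base = BNPModel(rng.integers(-1, 2, (d, d)), rng.choice([-0.5, 0.5], d), p)
    return TopologySpace(base, UnknownEntrySet(tuple((1, j + 1) for j in range(L))))


class TestSelectNext:
    def _surrogate(self, space, n, seed=0):
        rng = np.random.default_rng(seed)
        thetas = space.random_thetas(n, rng)
        return SurrogateState(thetas, rng.normal(size=n), KernelHyperparams(1.0, 1.0, 0.0))

    def test_matches_brute_force_scoring(self):
        space = _tiny_space(L=2)
        s = self._surrogate(space, 3, seed=1)
        chosen = select_next(s, space)
        evaluated = {t.tobytes() for t in s.thetas}
        best_ei = -1.0
        for cand in space.enumerate():
            if cand.tobytes() in evaluated:
                continue
            ei = float(_ei_over(s, cand[None, :])[0])
            best_ei = max(best_ei, ei)
        assert float(_ei_over(s, chosen[None, :])[0]) == pytest.approx(best_ei, rel=1e-12)

    def test_never_returns_evaluated(self):
        space = _tiny_space(L=2)
        s = self._surrogate(space, 8, seed=2)
        evaluated = {t.tobytes() for t in s.thetas}
        chosen = select_next(s, space)
        assert chosen.tobytes() not in evaluated

    def test_forced_choice_when_one_left(self):
        space = _tiny_space(L=1)
        all_t = space.all_thetas()
        s = SurrogateState(all_t[:2], np.array([0.0, 1.0]))
        assert (select_next(s, space) == all_t[2]).all()

    def test_exhausted_space_raises(self):
        space = _tiny_space(L=1)
        s = SurrogateState(space.all_thetas(), np.zeros(3))
        with pytest.raises(RuntimeError, match="exhausted"):
            select_next(s, space)

    def test_ei_of_evaluated_is_negligible(self, monkeypatch):
        """In the near-zero-jitter limit the GP interpolates exactly, so
        already-evaluated candidates carry (essentially) no expected
        improvement and exploration cannot stall on them."""
        import bntopo.gp as gp_mod

        monkeypatch.setattr(gp_mod, "JITTER_REL", 1e-14)
        space = _tiny_space(L=2)
        s = self._surrogate(space, 5, seed=3)
        ei = _ei_over(s, s.thetas)
        assert (ei <= 1e-6 * np.sqrt(s.hp.sigma_f2)).all()

    def test_ga_mode_returns_unevaluated(self):
        space = _tiny_space(L=3)
        s = self._surrogate(space, 6, seed=4)
        evaluated = {t.tobytes() for t in s.thetas}
        chosen = select_next(s, space, optimizer="ga", rng=np.random.default_rng(5), ga_generations=10)
        assert chosen.tobytes() not in evaluated


@pytest.fixture(scope="module")
def tiny_problem():
    space = _tiny_space(L=2, seed=7)
    truth = np.array([1, -1], dtype=np.int8)
    traj = simulate(space.embed(truth), 80, seed=8)
    I = encode_observations(traj)
    exhaustive = {tuple(t): log_likelihood(space, t, I) for t in space.enumerate()}
    best = max(exhaustive, key=exhaustive.get)
    return space, I, np.array(best, dtype=np.int8), exhaustive


class TestRunInference:
    def test_full_budget_equals_exhaustive_search(self, tiny_problem):
        space, I, ml_theta, exhaustive = tiny_problem
        result = run_inference(space, I, budget=space.size, init_n=3, seed=0)
        assert (result.best_theta == ml_theta).all()
        assert result.best_loglik == pytest.approx(max(exhaustive.values()), rel=1e-12)
        assert result.n_evaluations == space.size

    def test_best_so_far_monotone(self, tiny_problem):
        space, I, _, _ = tiny_problem
        result = run_inference(space, I, budget=9, init_n=3, seed=1)
        assert (np.diff(result.best_so_far()) >= 0).all()

    def test_same_seed_same_trace(self, tiny_problem):
        space, I, _, _ = tiny_problem
        a = run_inference(space, I, budget=7, init_n=3, seed=5)
        b = run_inference(space, I, budget=7, init_n=3, seed=5)
        assert a.trace["theta"].tolist() == b.trace["theta"].tolist()
        np.testing.assert_allclose(a.trace["loglik"], b.trace["loglik"])

    def test_trace_has_no_duplicate_candidates(self, tiny_problem):
        space, I, _, _ = tiny_problem
        result = run_inference(space, I, budget=space.size, init_n=2, seed=2)
        assert result.trace["theta"].nunique() == space.size

    def test_connectivity_error_tracks_incumbent(self, tiny_problem):
        space, I, ml_theta, _ = tiny_problem
        result = run_inference(space, I, budget=space.size, init_n=2, seed=3, truth=ml_theta)
        err = result.trace["connectivity_error"].to_numpy()
        assert err[-1] == 0.0
        best = result.trace["best_loglik"].to_numpy()
        # error changes only when the incumbent improves
        changes = np.flatnonzero(np.diff(err) != 0)
        assert (np.diff(best)[changes] > 0).all()

    def test_budget_validation(self, tiny_problem):
        space, I, _, _ = tiny_problem
        with pytest.raises(ValueError, match="budget"):
            run_inference(space, I, budget=2, init_n=5, seed=0)

    def test_plateau_stop(self, tiny_problem):
        space, I, _, _ = tiny_problem
        result = run_inference(space, I, budget=9, init_n=2, seed=4, plateau=(1e9, 2))
        assert result.n_evaluations <= 4  # stops two evaluations after the design

    def test_recovers_truth_on_cell_cycle_subproblem(self, cell_cycle):
        """BO with budget 15 of 27 finds the data-generating assignment of
        3 masked cell-cycle entries in >= 8/10 seeded replicates
        (T=100, p=0.1, fully observed)."""
        from bntopo.networks import cell_cycle_model

        model = cell_cycle_model(0.1)
        unknowns = UnknownEntrySet(((2, 1), (5, 4), (9, 8)))
        space = TopologySpace(model, unknowns)
        truth = np.array([-1, 1, -1], dtype=np.int8)
        assert (space.embed(truth).C == model.C).all()
        wins = 0
        for rep in range(10):
            traj = simulate(model, 100, seed=300 + rep)
            I = encode_observations(traj)
            result = run_inference(space, I, budget=15, init_n=5, seed=rep)
            wins += (result.best_theta == truth).all()
        assert wins >= 8


class TestGABaseline:
    def test_full_budget_finds_global_maximum(self, tiny_problem):
        space, I, ml_theta, exhaustive = tiny_problem
        result = ga_baseline(space, I, budget=space.size, seed=0)
        assert result.best_loglik == pytest.approx(max(exhaustive.values()), rel=1e-12)
        assert (result.best_theta == ml_theta).all()

    def test_budget_counts_unique_evaluations(self, tiny_problem):
        space, I, _, _ = tiny_problem
        result = ga_baseline(space, I, budget=6, seed=1)
        assert result.n_evaluations == 6
        assert result.trace["theta"].nunique() == 6

    def test_same_seed_same_trace(self, tiny_problem):
        space, I, _, _ = tiny_problem
        a = ga_baseline(space, I, budget=6, seed=2)
        b = ga_baseline(space, I, budget=6, seed=2)
        assert a.trace["theta"].tolist() == b.trace["theta"].tolist()

    def test_best_so_far_monotone(self, tiny_problem):
        space, I, _, _ = tiny_problem
        result = ga_baseline(space, I, budget=8, seed=3)
        assert (np.diff(result.best_so_far()) >= 0).all()
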