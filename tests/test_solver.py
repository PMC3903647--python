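import numpy as np
import pytest

from rangemon.features import Feature, FeatureIncidence, TargetTable, build_targets
from rangemon.solver import (
    SolverConfig,
    anneal_once,
    exact_oracle,
    objective,
    run_ensemble,
)

from conftest import random_instance
from test_features import STUDY_STATUSES

FAST = dict(n_iterations=1_000, n_temp_decreases=50)


def small_instance():
    """u0={f0}, u1={f1}, u2={f0,f1}: optimum is {u2} for unit targets."""
    feats = [Feature("s0", "G", "A2a"), Feature("s1", "G", "A2a")]
    inc = FeatureIncidence(
        units=np.arange(3),
        features=feats,
        incidence=np.array([[1, 0], [0, 1], [1, 1]], bool),
    )
    tt = TargetTable({f.name: 1 for f in feats})
    return inc, tt


class TestObjective:
    def test_empty_set_penalty_from_level1_targets(self):
        """With no stations, the penalty is FPF times the summed targets:
        one scenario, 7 species, level 1 → 100 × 116."""
        tt = build_targets(STUDY_STATUSES, "MN1", scenarios=("A2a",))
        feats = [
            Feature(sp, kind, "A2a") for sp in STUDY_STATUSES for kind in ("G", "M", "L")
        ] + [Feature(sp, "Full", "none") for sp in STUDY_STATUSES]
        # one unit incident to everything keeps all targets "present" in the
        # instance; capping is disabled so printed targets apply in full
        inc = FeatureIncidence(np.arange(1), feats, np.ones((1, len(feats)), bool))
        cfg = SolverConfig(cap_targets_to_attainable=False)
        sol = objective([], inc, tt, cfg)
        assert sol.penalty_term == 100 * 116
        assert sol.cost_term == 0

    def test_meeting_all_targets_costs_only_units(self):
        inc, tt = small_instance()
        sol = objective([2], inc, tt, SolverConfig())
        assert sol.objective == 1 and sol.feasible and not sol.shortfalls

    def test_matches_from_scratch_recount_on_random_sets(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            inc, tt = random_instance(rng, max_units=12)
            cfg = SolverConfig()
            sel = [int(u) for u in np.flatnonzero(rng.random(inc.n_units) < 0.4)]
            sol = objective(sel, inc, tt, cfg)
            tvec = np.minimum(tt.target_vector(inc.features), inc.incident_counts())
            rep = inc.representation(sel)
            expect = cfg.unit_cost * len(sel) + cfg.feature_penalty_factor * np.maximum(
                0, tvec - rep
            ).sum()
            assert sol.objective == pytest.approx(expect)


class TestAnneal:
    def test_single_covering_unit_found(self):
        inc, tt = small_instance()
        sol = anneal_once(inc, tt, SolverConfig(**FAST), run_seed=0)
        assert sol.selected == {2} and sol.objective == 1

    def test_lock_in_always_selected(self):
        rng = np.random.default_rng(23)
        for trial in range(10):
            inc, tt = random_instance(rng)
            cfg = SolverConfig(locked_in=frozenset({0}), **FAST)
            sol = anneal_once(inc, tt, cfg, run_seed=trial)
            assert 0 in sol.selected

    def test_incremental_bookkeeping_audited_every_move(self):
        # audit_every=1 recomputes the objective from scratch after every
        # accepted move and raises on any drift
        rng = np.random.default_rng(3)
        inc, tt = random_instance(rng)
        cfg = SolverConfig(audit_every=1, **FAST)
        anneal_once(inc, tt, cfg, run_seed=5)

    def test_feasible_when_attainable_and_uncapped(self, demo_problem):
        inc = demo_problem.incidence
        tt = build_targets(demo_problem.statuses, "MN1", features=inc.features)
        cfg = SolverConfig(n_iterations=20_000, n_temp_decreases=500, seed=0)
        sol = anneal_once(inc, tt, cfg, run_seed=1)
        assert sol.penalty_term == 0.0 and sol.feasible

    def test_infeasible_lock_in_rejected(self):
        inc, tt = small_instance()
        cfg = SolverConfig(cost_threshold=1.0, locked_in=frozenset({0, 1}), **FAST)
        with pytest.raises(ValueError, match="locked"):
            anneal_once(inc, tt, cfg, run_seed=0)

    def test_cost_threshold_respected(self):
        rng = np.random.default_rng(31)
        for trial in range(10):
            inc, tt = random_instance(rng)
            cfg = SolverConfig(cost_threshold=2.0, **FAST)
            sol = anneal_once(inc, tt, cfg, run_seed=trial)
            assert sol.cost_term <= 2.0 + 1e-9


class TestEnsemble:
    def test_single_run_is_best(self):
        inc, tt = small_instance()
        ens = run_ensemble(inc, tt, SolverConfig(n_runs=1, seed=4, **FAST))
        assert ens.best is ens.per_run[0]

    def test_locked_unit_frequency_equals_runs(self):
        rng = np.random.default_rng(41)
        inc, tt = random_instance(rng)
        cfg = SolverConfig(n_runs=6, locked_in=frozenset({1}), seed=2, **FAST)
        ens = run_ensemble(inc, tt, cfg)
        assert ens.selection_frequency[1] == 6

    def test_deterministic_under_master_seed(self):
        rng = np.random.default_rng(55)
        inc, tt = random_instance(rng)
        cfg = SolverConfig(n_runs=4, seed=9, **FAST)
        a = run_ensemble(inc, tt, cfg)
        b = run_ensemble(inc, tt, cfg)
        assert [s.selected for s in a.per_run] == [s.selected for s in b.per_run]
        assert a.best.selected == b.best.selected
        assert np.array_equal(a.selection_frequency, b.selection_frequency)


class TestExactOracle:
    def test_hand_instances(self):
        inc, tt = small_instance()
        sol = exact_oracle(inc, tt)
        assert sol.selected == {2} and sol.objective == 1
        # target 2 on f0 forces both incident units
        tt2 = TargetTable({"s0:G:A2a": 2, "s1:G:A2a": 1})
        sol2 = exact_oracle(inc, tt2)
        assert sol2.selected == {0, 2} and sol2.objective == 2

    def test_matches_exhaustive_enumeration(self):
        from itertools import product

        rng = np.random.default_rng(6)
        for trial in range(25):
            inc, tt = random_instance(rng, max_units=10)
            cfg = SolverConfig()
            best = min(
                objective([i for i, b in enumerate(bits) if b], inc, tt, cfg).objective
                for bits in product([0, 1], repeat=inc.n_units)
            )
            assert exact_oracle(inc, tt, cfg).objective == pytest.approx(best)

    def test_lower_bounds_random_subsets(self):
        rng = np.random.default_rng(77)
        inc, tt = random_instance(rng, max_units=12)
        cfg = SolverConfig()
        opt = exact_oracle(inc, tt, cfg).objective
        for _ in range(1000):
            sel = list(np.flatnonzero(rng.random(inc.n_units) < 0.5))
            assert opt <= objective(sel, inc, tt, cfg).objective + 1e-9

    def test_too_large_instance_rejected(self):
        feats = [Feature("s", "G", "A2a")]
        inc = FeatureIncidence(np.arange(30), feats, np.ones((30, 1), bool))
        with pytest.raises(ValueError):
            exact_oracle(inc, TargetTable({"s:G:A2a": 1}))
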