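import numpy as np
import pytest

from rangemon.evaluate import (
    build_comparison_network,
    build_current_incidence,
    distribution_only_targets,
    evaluate_against_stratified_targets,
)
from rangemon.features import build_targets
from rangemon.solver import EnsembleResult, Solution, SolverConfig

COMPARISON_SOLVER = dict(n_runs=20, n_iterations=50_000, n_temp_decreases=1_000)


@pytest.fixture(scope="module")
def current_incidence(demo_problem):
    return build_current_incidence(demo_problem.climatic_bins, demo_problem.full_bins)


@pytest.fixture(scope="module")
def mn1_comparison(demo_problem, demo_networks, current_incidence):
    net = demo_networks[0]
    dist_tt = distribution_only_targets(
        net, demo_problem.incidence, demo_problem.climatic_bins, demo_problem.full_bins
    )
    cfg = SolverConfig(seed=99, **COMPARISON_SOLVER)
    ens = build_comparison_network(dist_tt, current_incidence, net.n_stations, cfg)
    return dist_tt, ens


class TestDistributionOnlyTargets:
    def test_counts_match_brute_force(self, demo_problem, demo_networks):
        net = demo_networks[0]
        tt = distribution_only_targets(
            net, demo_problem.incidence, demo_problem.climatic_bins, demo_problem.full_bins
        )
        cells = net.station_cells(demo_problem.incidence)
        for sp in demo_problem.statuses:
            clim = demo_problem.climatic_bins[sp].presence.ravel()
            full = demo_problem.full_bins[sp].presence.ravel()
            assert tt.targets[f"{sp}:CurClim"] == int(sum(clim[c] for c in cells))
            assert tt.targets[f"{sp}:CurFull"] == int(sum(full[c] for c in cells))

    def test_zero_station_species_gets_zero_target(self, demo_problem, demo_networks):
        # erase one species' suitable area: its target must drop to 0
        import copy

        clim = copy.deepcopy(demo_problem.climatic_bins)
        clim["Mdau"].presence[:] = False
        tt = distribution_only_targets(
            demo_networks[0], demo_problem.incidence, clim, demo_problem.full_bins
        )
        assert tt.targets["Mdau:CurClim"] == 0


class TestComparisonNetwork:
    def test_every_run_within_size_cap(self, demo_networks, mn1_comparison):
        _, ens = mn1_comparison
        cap = demo_networks[0].n_stations
        assert all(s.n_selected <= cap for s in ens.per_run)

    def test_uncapped_problem_meets_distribution_targets(
        self, demo_problem, demo_networks, current_incidence
    ):
        net = demo_networks[0]
        dist_tt = distribution_only_targets(
            net, demo_problem.incidence, demo_problem.climatic_bins, demo_problem.full_bins
        )
        cfg = SolverConfig(n_runs=1, n_iterations=20_000, n_temp_decreases=500, seed=5)
        ens = build_comparison_network(
            dist_tt, current_incidence, size_cap=current_incidence.n_units, cfg=cfg
        )
        assert ens.best.penalty_term == 0.0


class TestEvaluation:
    def test_optimized_network_meets_own_targets(self, demo_problem, demo_networks):
        """Unmet fraction of the optimized ensemble against its own targets is
        zero for attainable features in every run."""
        inc = demo_problem.incidence
        counts = inc.incident_counts()
        for net in demo_networks:
            tt = build_targets(demo_problem.statuses, net.level, features=inc.features)
            tvec = tt.target_vector(inc.features)
            rep = evaluate_against_stratified_targets(net.ensemble, inc, tt)
            attainable = counts >= tvec
            per_feature_met = rep.tidy.groupby("feature")["met"].all()
            for j, f in enumerate(inc.features):
                if attainable[j]:
                    assert per_feature_met[f.name]

    def test_empty_selection_leaves_everything_unmet(self, demo_problem):
        inc = demo_problem.incidence
        tt = build_targets(demo_problem.statuses, "MN1", features=inc.features)
        empty = Solution(
            selected=frozenset(), objective=0, cost_term=0, penalty_term=0,
            threshold_term=0, shortfalls={}, feasible=False,
        )
        ens = EnsembleResult(best=empty, per_run=[empty], selection_frequency=np.zeros(inc.n_units, int))
        rep = evaluate_against_stratified_targets(ens, inc, tt)
        assert rep.per_run_unmet_fraction == [1.0]

    def test_comparison_runs_mirror_study_direction(
        self, demo_problem, demo_networks, mn1_comparison
    ):
        """Occurrence-only networks: every run misses targets, and the gain
        stratum is the hardest to satisfy."""
        _, ens = mn1_comparison
        inc = demo_problem.incidence
        tt = build_targets(demo_problem.statuses, "MN1", features=inc.features)
        inc_cur = build_current_incidence(
            demo_problem.climatic_bins, demo_problem.full_bins
        )
        rep = evaluate_against_stratified_targets(ens, inc, tt, ens_incidence=inc_cur)
        arr = np.asarray(rep.per_run_unmet_fraction)
        assert (arr > 0).all()
        med = {k: v["median"] for k, v in rep.by_class.items()}
        assert med["G"] >= med["M"] >= med["L"]
        assert med["G"] == max(med.values())

    def test_report_summary_bounds(self, demo_problem, demo_networks, mn1_comparison):
        _, ens = mn1_comparison
        inc = demo_problem.incidence
        tt = build_targets(demo_problem.statuses, "MN1", features=inc.features)
        inc_cur = build_current_incidence(
            demo_problem.climatic_bins, demo_problem.full_bins
        )
        rep = evaluate_against_stratified_targets(ens, inc, tt, ens_incidence=inc_cur)
        s = rep.summary()
        for block in [s["overall"], *s["by_class"].values()]:
            assert 0.0 <= block["min"] <= block["median"] <= block["max"] <= 1.0

    def test_invariant_to_feature_order(self, demo_problem, demo_networks):
        """Permuting features leaves per-run unmet fractions unchanged."""
        import numpy as np

        inc = demo_problem.incidence
        net = demo_networks[0]
        tt = build_targets(demo_problem.statuses, "MN1", features=inc.features)
        rep = evaluate_against_stratified_targets(net.ensemble, inc, tt)

        from rangemon.features import FeatureIncidence

        rng = np.random.default_rng(0)
        perm = rng.permutation(inc.n_features)
        inc2 = FeatureIncidence(
            units=inc.units,
            features=[inc.features[j] for j in perm],
            incidence=inc.incidence[:, perm],
        )
        rep2 = evaluate_against_stratified_targets(net.ensemble, inc2, tt)
        assert rep.per_run_unmet_fraction == rep2.per_run_unmet_fraction
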