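"""Minimum-set station selection by simulated annealing.

The optimization problem mirrors the classic reserve-selection formulation:
choose a set S of planning units minimizing

    objective(S) = cost(S) + FPF * sum_f shortfall_f(S) + threshold_penalty

where cost is the number of selected units times the unit cost, a feature's
shortfall is the gap between its representation (selected units incident to
it) and its target, FPF is the feature penalty factor, and the optional
threshold penalty punishes solutions whose cost exceeds a hard size cap.
Units can be locked in, which is how a smaller network is forced into a
larger one when networks are designed as nested expansions.

The annealer proposes uniform single-unit toggles, accepts improving moves
always and worsening moves with probability exp(-dO/T) under a geometric
temperature schedule calibrated adaptively from probe moves, then finishes
with a deterministic greedy repair (add best shortfall-reducer per cost)
and a randomized trim of redundant units. An exact branch-and-bound oracle
for small instances backs the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import FeatureIncidence, TargetTable

__all__ = [
    "SolverConfig",
    "Solution",
    "EnsembleResult",
    "objective",
    "anneal_once",
    "run_ensemble",
    "exact_oracle",
]


@dataclass(frozen=True)
class SolverConfig:
    """Annealing and problem parameters.

    Production defaults follow the standard reserve-selection setup this
    pipeline reproduces: 100 restarts, penalty factor 100, one million
    iterations with ten thousand temperature decreases, adaptive initial
    temperature, no spatial compactness term.
    """

    n_runs: int = 100
    n_iterations: int = 1_000_000
    n_temp_decreases: int = 10_000
    feature_penalty_factor: float = 100.0
    unit_cost: float = 1.0
    cost_threshold: float | None = None
    locked_in: frozenset[int] = frozenset()  # unit POSITIONS (row index into incidence)
    seed: int = 0
    cap_targets_to_attainable: bool = True
    n_probe_moves: int = 1_000
    final_temp_fraction: float = 0.02
    audit_every: int = 10_000  # accepted moves between from-scratch objective audits

    def __post_init__(self) -> None:
        if self.n_temp_decreases > self.n_iterations:
            raise ValueError("n_temp_decreases must not exceed n_iterations")
        if self.feature_penalty_factor <= 0 or self.unit_cost <= 0:
            raise ValueError("penalty factor and unit cost must be positive")


@dataclass
class Solution:
    """One solver outcome with its objective decomposition."""

    selected: frozenset[int]  # unit positions
    objective: float
    cost_term: float
    penalty_term: float
    threshold_term: float
    shortfalls: dict[str, int]
    feasible: bool
    run_index: int = 0

    @property
    def n_selected(self) -> int:
        return len(self.selected)


@dataclass
class EnsembleResult:
    """All restarts of one problem plus the best solution and frequencies."""

    best: Solution
    per_run: list[Solution]
    selection_frequency: np.ndarray  # per unit position, counts in [0, n_runs]

    @property
    def n_runs(self) -> int:
        return len(self.per_run)


def _problem_arrays(inc: FeatureIncidence, tt: TargetTable, cfg: SolverConfig):
    """Targets (optionally capped to attainable), per-unit feature lists."""
    tvec = tt.target_vector(inc.features)
    counts = inc.incident_counts()
    tcap = np.minimum(tvec, counts) if cfg.cap_targets_to_attainable else tvec
    unit_feats = [np.flatnonzero(inc.incidence[i]) for i in range(inc.n_units)]
    beta = 10.0 * cfg.feature_penalty_factor * float(tvec.sum()) if cfg.cost_threshold is not None else 0.0
    return tvec, tcap, unit_feats, beta


def _decompose(
    sel: np.ndarray,
    inc: FeatureIncidence,
    tcap: np.ndarray,
    cfg: SolverConfig,
    beta: float,
) -> tuple[float, float, float, np.ndarray]:
    """From-scratch objective terms for a selection vector (bool per unit)."""
    r = inc.incidence[sel].sum(axis=0).astype(int) if sel.any() else np.zeros(inc.n_features, int)
    short = np.maximum(0, tcap - r)
    cost = cfg.unit_cost * float(sel.sum())
    pen = cfg.feature_penalty_factor * float(short.sum())
    thr = 0.0
    if cfg.cost_threshold is not None:
        thr = beta * max(0.0, cost - cfg.cost_threshold)
    return cost, pen, thr, short


def objective(
    selected, inc: FeatureIncidence, tt: TargetTable, cfg: SolverConfig
) -> Solution:
    """Score an arbitrary unit set (by position) from scratch."""
    sel = np.zeros(inc.n_units, dtype=bool)
    sel[list(selected)] = True
    _, tcap, _, beta = _problem_arrays(inc, tt, cfg)
    cost, pen, thr, short = _decompose(sel, inc, tcap, cfg, beta)
    feasible = bool(short.sum() == 0) and (
        cfg.cost_threshold is None or cost <= cfg.cost_threshold + 1e-9
    )
    return Solution(
        selected=frozenset(int(i) for i in np.flatnonzero(sel)),
        objective=cost + pen + thr,
        cost_term=cost,
        penalty_term=pen,
        threshold_term=thr,
        shortfalls={
            inc.features[j].name: int(s) for j, s in enumerate(short) if s > 0
        },
        feasible=feasible,
    )


def _repair_and_trim(
    sel: np.ndarray,
    inc: FeatureIncidence,
    tcap: np.ndarray,
    cfg: SolverConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Greedy add until no attainable shortfall remains, then trim redundancy.

    Adding respects the cost threshold: no unit is added once the cap is
    reached, so capped problems may legitimately retain shortfalls.
    """
    r = inc.incidence[sel].sum(axis=0).astype(int) if sel.any() else np.zeros(inc.n_features, int)
    short = np.maximum(0, tcap - r)
    locked = cfg.locked_in
    cap_units = (
        int(np.floor(cfg.cost_threshold / cfg.unit_cost + 1e-9))
        if cfg.cost_threshold is not None
        else inc.n_units
    )
    while short.sum() > 0 and sel.sum() < cap_units:
        needy = short > 0
        # gain of each unselected unit: newly covered shortfall occurrences
        gains = inc.incidence[:, needy].sum(axis=1)
        gains[sel] = 0
        best = int(np.argmax(gains))
        if gains[best] == 0:
            break  # remaining shortfall is unattainable from unselected units
        sel[best] = True
        f = np.flatnonzero(inc.incidence[best])
        r[f] += 1
        short = np.maximum(0, tcap - r)
    # trim: drop unlocked units whose removal leaves every covered feature at
    # or above its capped target
    order = np.flatnonzero(sel)
    rng.shuffle(order)
    for u in order:
        if int(u) in locked:
            continue
        f = np.flatnonzero(inc.incidence[u])
        if np.all(r[f] - 1 >= tcap[f]):
            sel[u] = False
            r[f] -= 1
    # hard size cap: if still over the cost threshold, shed the unlocked
    # units whose removal hurts coverage least until the cap is respected
    while sel.sum() > cap_units:
        cands = [u for u in np.flatnonzero(sel) if int(u) not in locked]
        if not cands:
            break
        damages = []
        for u in cands:
            f = np.flatnonzero(inc.incidence[u])
            damages.append(int(np.count_nonzero(r[f] <= tcap[f])))
        u = cands[int(np.argmin(damages))]
        f = np.flatnonzero(inc.incidence[u])
        sel[u] = False
        r[f] -= 1
    return sel


def anneal_once(
    inc: FeatureIncidence,
    tt: TargetTable,
    cfg: SolverConfig,
    run_seed: int,
    run_index: int = 0,
) -> Solution:
    """One annealing restart followed by repair-and-trim."""
    rng = np.random.default_rng(run_seed)
    tvec, tcap, unit_feats, beta = _problem_arrays(inc, tt, cfg)
    n = inc.n_units
    fpf = cfg.feature_penalty_factor
    uc = cfg.unit_cost
    thr_cap = cfg.cost_threshold

    locked = np.zeros(n, dtype=bool)
    if cfg.locked_in:
        locked[list(cfg.locked_in)] = True
    if thr_cap is not None and uc * locked.sum() > thr_cap + 1e-9:
        raise ValueError("locked-in cost alone exceeds the cost threshold")

    # initial state: locked units plus a sparse random subset
    sel = locked.copy()
    extra = rng.random(n) < 0.05
    sel |= extra

    r = inc.incidence[sel].sum(axis=0).astype(int) if sel.any() else np.zeros(inc.n_features, int)
    cost = uc * float(sel.sum())
    pen = fpf * float(np.maximum(0, tcap - r).sum())

    def thr_term(c: float) -> float:
        return beta * max(0.0, c - thr_cap) if thr_cap is not None else 0.0

    def delta_for(u: int) -> float:
        """Objective change of toggling unit u from the current state."""
        f = unit_feats[u]
        if sel[u]:
            d_cost = -uc
            d_pen = fpf * float(np.count_nonzero(r[f] <= tcap[f]))
        else:
            d_cost = uc
            d_pen = -fpf * float(np.count_nonzero(r[f] < tcap[f]))
        return d_cost + d_pen + thr_term(cost + d_cost) - thr_term(cost)

    # adaptive temperature: largest |dO| over probe toggles from the start
    n_probe = min(cfg.n_probe_moves, max(1, 4 * n))
    probe_units = rng.integers(0, n, size=n_probe)
    t0 = max((abs(delta_for(int(u))) for u in probe_units), default=1.0)
    t0 = max(t0, 1e-9)
    t_final = cfg.final_temp_fraction * t0
    n_dec = max(cfg.n_temp_decreases, 1)
    decay = (t_final / t0) ** (1.0 / max(n_dec - 1, 1))
    iters_per_step = max(cfg.n_iterations // n_dec, 1)

    accepted = 0
    temp = t0
    chunk = 4096
    it = 0
    total_iters = cfg.n_iterations
    while it < total_iters:
        m = min(chunk, total_iters - it)
        units = rng.integers(0, n, size=m)
        coins = rng.random(m)
        for k in range(m):
            step = (it + k) // iters_per_step
            if step < n_dec:
                temp = t0 * decay**step
            u = int(units[k])
            if locked[u] and sel[u]:
                continue  # locked units are never removable
            f = unit_feats[u]
            if sel[u]:
                d_cost = -uc
                d_pen = fpf * float(np.count_nonzero(r[f] <= tcap[f]))
            else:
                d_cost = uc
                d_pen = -fpf * float(np.count_nonzero(r[f] < tcap[f]))
            d = d_cost + d_pen + thr_term(cost + d_cost) - thr_term(cost)
            if d <= 0.0 or coins[k] < np.exp(-d / temp):
                if sel[u]:
                    sel[u] = False
                    r[f] -= 1
                else:
                    sel[u] = True
                    r[f] += 1
                cost += d_cost
                pen += d_pen
                accepted += 1
                if cfg.audit_every and accepted % cfg.audit_every == 0:
                    c2, p2, _, _ = _decompose(sel, inc, tcap, cfg, beta)
                    if abs(c2 - cost) > 1e-9 or abs(p2 - pen) > 1e-9:
                        raise AssertionError(
                            "incremental objective drifted from the from-scratch value"
                        )
        it += m

    sel = _repair_and_trim(sel, inc, tcap, cfg, rng)
    sol = objective(np.flatnonzero(sel), inc, tt, cfg)
    return replace(sol, run_index=run_index)


def run_ensemble(
    inc: FeatureIncidence, tt: TargetTable, cfg: SolverConfig
) -> EnsembleResult:
    """Run ``cfg.n_runs`` restarts with seeds derived from the master seed.

    The best solution has the minimal objective; ties break toward fewer
    units, then the earliest run.
    """
    if cfg.n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    seeds = np.random.SeedSequence(cfg.seed).generate_state(cfg.n_runs) % (2**31 - 1)
    per_run = [
        anneal_once(inc, tt, cfg, run_seed=int(seeds[i]), run_index=i)
        for i in range(cfg.n_runs)
    ]
    freq = np.zeros(inc.n_units, dtype=int)
    for sol in per_run:
        freq[list(sol.selected)] += 1
    best = min(per_run, key=lambda s: (s.objective, s.n_selected, s.run_index))
    return EnsembleResult(best=best, per_run=per_run, selection_frequency=freq)


# ---------------------------------------------------------------------------
# Exact oracle (branch and bound) for small instances
# ---------------------------------------------------------------------------

MAX_ORACLE_UNITS = 25


def exact_oracle(
    inc: FeatureIncidence,
    tt: TargetTable,
    cfg: SolverConfig | None = None,
    max_units: int = MAX_ORACLE_UNITS,
) -> Solution:
    """Provably optimal solution by depth-first branch and bound.

    Units are considered in decreasing coverage order; at each node the
    admissible bound combines the unavoidable penalty for shortfall no
    remaining unit can cover with a lower bound on the units (or penalties)
    still needed for coverable shortfall.
    """
    cfg = cfg or SolverConfig()
    n = inc.n_units
    if n > max_units:
        raise ValueError(f"instance too large for the exact oracle ({n} > {max_units})")
    tvec, tcap, unit_feats, beta = _problem_arrays(inc, tt, cfg)
    fpf, uc = cfg.feature_penalty_factor, cfg.unit_cost
    thr_cap = cfg.cost_threshold
    locked = set(cfg.locked_in)

    order = sorted(range(n), key=lambda u: -len(unit_feats[u]))
    # suffix coverage: for feature f, how many units from position i on are incident
    suffix_cov = np.zeros((n + 1, inc.n_features), dtype=int)
    for i in range(n - 1, -1, -1):
        suffix_cov[i] = suffix_cov[i + 1]
        suffix_cov[i, unit_feats[order[i]]] += 1
    max_feats_per_unit = max((len(unit_feats[u]) for u in range(n)), default=1) or 1

    best_obj = np.inf
    best_sel: list[int] = []

    def thr_term(c: float) -> float:
        return beta * max(0.0, c - thr_cap) if thr_cap is not None else 0.0

    def leaf_obj(cost: float, short_sum: int) -> float:
        return cost + fpf * short_sum + thr_term(cost)

    r = np.zeros(inc.n_features, dtype=int)
    chosen: list[int] = []

    def bound(i: int, cost: float) -> float:
        short = np.maximum(0, tcap - r)
        cov = suffix_cov[i]
        dead = np.maximum(0, short - cov)  # shortfall no remaining unit can fix
        live = np.minimum(short, cov)
        unit_or_pen = min(uc, fpf)
        lb_units = max(
            int(live.max()) if live.size else 0,
            int(np.ceil(live.sum() / max_feats_per_unit)),
        )
        return cost + thr_term(cost) + fpf * float(dead.sum()) + unit_or_pen * lb_units

    def dfs(i: int, cost: float) -> None:
        nonlocal best_obj, best_sel
        if bound(i, cost) >= best_obj - 1e-12:
            return
        if i == n:
            short_sum = int(np.maximum(0, tcap - r).sum())
            obj = leaf_obj(cost, short_sum)
            if obj < best_obj - 1e-12 or (
                abs(obj - best_obj) <= 1e-12 and len(chosen) < len(best_sel)
            ):
                best_obj = obj
                best_sel = list(chosen)
            return
        u = order[i]
        f = unit_feats[u]
        # branch: include u (mandatory if locked)
        chosen.append(u)
        r[f] += 1
        dfs(i + 1, cost + uc)
        r[f] -= 1
        chosen.pop()
        if u not in locked:
            dfs(i + 1, cost)

    dfs(0, 0.0)
    return objective(best_sel, inc, tt, cfg)
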