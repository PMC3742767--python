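"""Minimum-set conservation prioritization by simulated annealing.

The planning problem selects 1-km2 grid cells (planning units) so that
every conservation feature (a species' standardized habitat amount)
meets its target proportion of the feature's total, at minimum cost:

    objective(S) = sum_{u in S} cost_u
                 + sum_f SPF_f * max(0, target_f - held_f(S))

where held_f is the feature amount summed over selected units and SPF is
the species penalty factor weighting target shortfalls.  Scenario 1
costs each cell 1 (minimize area); scenario 2 costs 1 + the cell's
general human-use score, steering solutions away from heavily used
waters.  Solutions come from simulated annealing over single-cell
add/remove moves with Boltzmann acceptance and geometric cooling,
followed by greedy shortfall repair and redundancy pruning; ensembles of
independent runs yield per-cell selection frequencies and a best
solution.  An exhaustive-search oracle is provided for small problems.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PlanningProblem", "PrioritizationSolution", "RunEnsemble", "AnnealSchedule",
    "build_problem", "objective", "anneal", "run_ensemble", "brute_force",
    "marxan_tables",
]

TARGET_LEVELS = (0.10, 0.30, 0.50)


@dataclass
class PlanningProblem:
    """Planning units, feature amounts, targets and penalties."""

    unit_ids: np.ndarray
    costs: np.ndarray  # (n_units,)
    amounts: np.ndarray  # (n_features, n_units)
    target_prop: float
    spfs: np.ndarray  # (n_features,)
    feature_names: list[str] = field(default_factory=list)
    scenario: int = 1

    def __post_init__(self):
        self.costs = np.asarray(self.costs, dtype=float)
        self.amounts = np.atleast_2d(np.asarray(self.amounts, dtype=float))
        self.spfs = np.asarray(self.spfs, dtype=float)
        if np.any(self.costs <= 0):
            raise ValueError("unit costs must be > 0")
        if np.any(self.amounts < 0):
            raise ValueError("feature amounts must be >= 0")
        if not 0.0 < self.target_prop <= 1.0:
            raise ValueError("target proportion must lie in (0, 1]")
        if np.any(self.spfs <= 0):
            raise ValueError("species penalty factors must be > 0")

    @property
    def n_units(self) -> int:
        return len(self.costs)

    @property
    def n_features(self) -> int:
        return self.amounts.shape[0]

    @property
    def targets(self) -> np.ndarray:
        """Absolute target amounts: proportion x feature total."""
        return self.target_prop * self.amounts.sum(axis=1)


@dataclass
class PrioritizationSolution:
    selected: np.ndarray  # boolean per unit
    objective: float
    held: np.ndarray
    shortfall: np.ndarray
    cost: float
    run_index: int = 0
    seed: int = 0

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def targets_met(self) -> bool:
        return bool(np.all(self.shortfall <= 1e-9))


@dataclass
class RunEnsemble:
    solutions: list[PrioritizationSolution]
    selection_frequency: np.ndarray
    best: PrioritizationSolution

    def upper_half(self) -> np.ndarray:
        """Cells in the upper 50% of the selection-frequency scale."""
        return self.selection_frequency >= 0.5


def build_problem(
    cells: pd.DataFrame,
    scenario: int,
    target: float,
    spf_scale: float = 100.0,
    species: list[str] | None = None,
) -> PlanningProblem:
    """Assemble a planning problem from the habitat-map cells table.

    ``cells`` carries ``amount_<SP>`` columns of standardized habitat
    per species and, for scenario 2, ``human_use_score``.  Scenario 1
    costs each cell 1 (area); scenario 2 adds the human-use score.
    Default SPFs scale inversely with each feature's total amount so
    scarce features are penalized harder for shortfalls.
    """
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    if not 0.0 < target <= 1.0:
        raise ValueError("target must lie in (0, 1]")
    amount_cols = ([f"amount_{s}" for s in species] if species is not None
                   else sorted(c for c in cells.columns if c.startswith("amount_")))
    if not amount_cols:
        raise ValueError("cells table has no amount_<species> columns")
    amounts = cells[amount_cols].to_numpy(dtype=float).T
    if scenario == 2:
        if "human_use_score" not in cells:
            raise ValueError("scenario 2 requires a human_use_score column")
        costs = 1.0 + cells["human_use_score"].to_numpy(dtype=float)
    else:
        costs = np.ones(len(cells))
    totals = amounts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every feature needs positive total amount")
    spfs = spf_scale * totals.max() / totals
    return PlanningProblem(
        unit_ids=cells["cell_id"].to_numpy(), costs=costs, amounts=amounts,
        target_prop=float(target), spfs=spfs,
        feature_names=[c.removeprefix("amount_") for c in amount_cols],
        scenario=scenario,
    )


def objective(problem: PlanningProblem, selected: np.ndarray) -> float:
    """Total cost plus SPF-weighted target shortfalls for a selection."""
    selected = np.asarray(selected, dtype=bool)
    held = problem.amounts[:, selected].sum(axis=1)
    short = np.maximum(0.0, problem.targets - held)
    return float(problem.costs[selected].sum() + problem.spfs @ short)


def _solution_from(problem, selected, run_index=0, seed=0) -> PrioritizationSolution:
    selected = np.asarray(selected, dtype=bool)
    held = problem.amounts[:, selected].sum(axis=1)
    short = np.maximum(0.0, problem.targets - held)
    cost = float(problem.costs[selected].sum())
    return PrioritizationSolution(
        selected=selected.copy(), objective=cost + float(problem.spfs @ short),
        held=held, shortfall=short, cost=cost, run_index=run_index, seed=seed)


def _greedy_repair(problem, selected, held):
    """Add the unit with the best SPF-weighted shortfall reduction per
    unit cost until every attainable target is met."""
    targets, spfs, amounts, costs = problem.targets, problem.spfs, problem.amounts, problem.costs
    while True:
        short = np.maximum(0.0, targets - held)
        if not np.any(short > 1e-12):
            break
        gain = spfs @ np.minimum(amounts, short[:, None])  # per-unit penalty averted
        gain[selected] = 0.0
        ratio = gain / costs
        u = int(np.argmax(ratio))
        if gain[u] <= 1e-15:
            break  # irreducible shortfall (infeasible target)
        selected[u] = True
        held += amounts[:, u]
    return selected, held


def _one_opt(problem, selected, held):
    """Steepest-descent over single toggles until no move improves."""
    targets, spfs, amounts, costs = problem.targets, problem.spfs, problem.amounts, problem.costs
    pen = float(spfs @ np.maximum(0.0, targets - held))
    improved = True
    while improved:
        improved = False
        signs = np.where(selected, -1.0, 1.0)
        new_held = held[:, None] + signs[None, :] * amounts
        new_pen = spfs @ np.maximum(0.0, targets[:, None] - new_held)
        deltas = signs * costs + (new_pen - pen)
        u = int(np.argmin(deltas))
        if deltas[u] < -1e-12:
            selected[u] = not selected[u]
            held = held + signs[u] * amounts[:, u]
            pen = float(spfs @ np.maximum(0.0, targets - held))
            improved = True
    return selected, held


def _swap_opt(problem, selected, held, max_units: int = 500):
    """Steepest-descent over remove-one/add-one exchanges (skipped on
    large problems, where annealing carries the search)."""
    n = problem.n_units
    if n > max_units:
        return selected, held
    targets, spfs, amounts, costs = problem.targets, problem.spfs, problem.amounts, problem.costs

    def pen(h):
        return spfs @ np.maximum(0.0, targets - (h if h.ndim == 1 else h))

    improved = True
    while improved:
        improved = False
        cur = float(costs[selected].sum() + pen(held))
        best = (0.0, None, None)
        for u in np.flatnonzero(selected):
            h_minus = held - amounts[:, u]
            outs = np.flatnonzero(~selected)
            if len(outs) == 0:
                continue
            new_held = h_minus[:, None] + amounts[:, outs]
            new_pen = spfs @ np.maximum(0.0, targets[:, None] - new_held)
            delta = -costs[u] + costs[outs] + (new_pen - pen(held))
            v = int(np.argmin(delta))
            if delta[v] < best[0] - 1e-12:
                best = (float(delta[v]), u, outs[v])
        if best[1] is not None:
            u, v = best[1], best[2]
            selected[u], selected[v] = False, True
            held = held - amounts[:, u] + amounts[:, v]
            improved = True
    return selected, held


def _prune(problem, selected, held):
    """Drop redundant units (most expensive first) whenever removal
    lowers the objective."""
    targets, spfs, amounts, costs = problem.targets, problem.spfs, problem.amounts, problem.costs
    order = np.argsort(-costs)
    changed = True
    while changed:
        changed = False
        for u in order:
            if not selected[u]:
                continue
            new_held = held - amounts[:, u]
            dpen = spfs @ (np.maximum(0.0, targets - new_held)
                           - np.maximum(0.0, targets - held))
            if dpen < costs[u] - 1e-12:
                selected[u] = False
                held = new_held
                changed = True
    return selected, held


@dataclass
class AnnealSchedule:
    """Annealing controls (all overridable).

    The initial temperature is calibrated so roughly ``accept_target``
    of uphill moves are accepted at the start; temperature then decays
    geometrically by ``cooling`` at each of ``n_coolings`` evenly spaced
    points, over ``moves_per_unit * n_units`` total moves.
    """

    moves_per_unit: int = 100
    min_moves: int = 2000
    cooling: float = 0.995
    n_coolings: int = 2000
    accept_target: float = 0.8
    calibration_moves: int = 100
    t_init: float | None = None


def anneal(problem: PlanningProblem, seed: int = 0,
           schedule: AnnealSchedule | None = None,
           run_index: int = 0) -> PrioritizationSolution:
    """One annealing run followed by greedy repair and pruning.

    Deterministic given ``seed``.  The returned solution never scores
    worse than the pure greedy-construction solution (which is computed
    as a floor and used if the annealed chain ends above it).
    """
    sched = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    n = problem.n_units
    targets, spfs, amounts, costs = (problem.targets, problem.spfs,
                                     problem.amounts, problem.costs)
    selected = rng.random(n) < 0.5
    held = amounts[:, selected].sum(axis=1)

    n_moves = max(sched.min_moves, sched.moves_per_unit * n)
    # temperature calibration: sample uphill deltas from random toggles
    deltas = []
    for u in rng.integers(0, n, size=sched.calibration_moves):
        sign = -1.0 if selected[u] else 1.0
        nh = held + sign * amounts[:, u]
        d = sign * costs[u] + spfs @ (np.maximum(0.0, targets - nh)
                                      - np.maximum(0.0, targets - held))
        if d > 0:
            deltas.append(d)
    if sched.t_init is not None:
        T = float(sched.t_init)
    elif deltas:
        T = float(np.mean(deltas) / -np.log(sched.accept_target))
    else:
        T = 1.0
    cool_every = max(1, n_moves // sched.n_coolings)

    units = rng.integers(0, n, size=n_moves)
    unif = rng.random(n_moves)
    short = np.maximum(0.0, targets - held)
    pen = spfs @ short
    for i in range(n_moves):
        u = units[i]
        sign = -1.0 if selected[u] else 1.0
        nh = held + sign * amounts[:, u]
        npen = spfs @ np.maximum(0.0, targets - nh)
        d = sign * costs[u] + npen - pen
        if d <= 0.0 or unif[i] < np.exp(-d / T):
            selected[u] = not selected[u]
            held = nh
            pen = npen
        if i % cool_every == 0:
            T *= sched.cooling
    selected, held = _greedy_repair(problem, selected, held)
    selected, held = _prune(problem, selected, held)
    selected, held = _one_opt(problem, selected, held)
    selected, held = _swap_opt(problem, selected, held)
    annealed = _solution_from(problem, selected, run_index, seed)

    greedy_sel = np.zeros(n, dtype=bool)
    gsel, gheld = _greedy_repair(problem, greedy_sel, np.zeros(problem.n_features))
    gsel, gheld = _prune(problem, gsel, gheld)
    gsel, gheld = _one_opt(problem, gsel, gheld)
    gsel, gheld = _swap_opt(problem, gsel, gheld)
    greedy = _solution_from(problem, gsel, run_index, seed)
    return annealed if annealed.objective <= greedy.objective else greedy


def run_ensemble(problem: PlanningProblem, R: int = 100, seed: int = 0,
                 schedule: AnnealSchedule | None = None) -> RunEnsemble:
    """R independent annealing runs -> selection frequencies and best.

    The best solution is the minimum-objective run (earliest run wins
    ties), reproducible from the run seeds ``seed + run_index``.
    """
    if R < 1:
        raise ValueError("need at least one run")
    solutions = []
    for r in range(R):
        solutions.append(anneal(problem, seed=seed + r, schedule=schedule, run_index=r))
    freq = np.mean([s.selected for s in solutions], axis=0)
    best = min(solutions, key=lambda s: (s.objective, s.run_index))
    return RunEnsemble(solutions=solutions, selection_frequency=freq, best=best)


def brute_force(problem: PlanningProblem) -> PrioritizationSolution:
    """Exact optimum by exhaustive enumeration (n_units <= 20).

    Ties are broken by smaller selection size, then lexicographically
    on the selected unit indices.
    """
    n = problem.n_units
    if n > 20:
        raise ValueError("brute force is limited to 20 planning units")
    if n == 0:
        return _solution_from(problem, np.zeros(0, dtype=bool))
    masks = np.arange(2**n, dtype=np.uint32)
    members = ((masks[:, None] >> np.arange(n)) & 1).astype(bool)  # (2^n, n)
    cost = members @ problem.costs
    held = members @ problem.amounts.T  # (2^n, F)
    short = np.maximum(0.0, problem.targets[None, :] - held)
    obj = cost + short @ problem.spfs
    card = members.sum(axis=1)
    best_obj = obj.min()
    tied = np.flatnonzero(obj <= best_obj + 1e-12)
    tied = tied[np.lexsort((tied, card[tied]))]  # cardinality, then mask order
    return _solution_from(problem, members[tied[0]])


def marxan_tables(problem: PlanningProblem) -> dict[str, pd.DataFrame]:
    """Problem as minimum-set input tables (pu / spec / puvspr dialect)."""
    pu = pd.DataFrame({"id": problem.unit_ids, "cost": problem.costs})
    names = (problem.feature_names if len(problem.feature_names) == problem.n_features
             else [f"f{i + 1}" for i in range(problem.n_features)])
    spec = pd.DataFrame({
        "id": np.arange(1, problem.n_features + 1),
        "name": names,
        "target": problem.targets,
        "spf": problem.spfs,
    })
    f_idx, u_idx = np.nonzero(problem.amounts > 0)
    puvspr = pd.DataFrame({
        "species": f_idx + 1,
        "pu": problem.unit_ids[u_idx],
        "amount": problem.amounts[f_idx, u_idx],
    })
    return {"pu": pu, "spec": spec, "puvspr": puvspr}
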