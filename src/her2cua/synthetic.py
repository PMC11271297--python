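"""Synthetic model generation and a patient-level microsimulation oracle.

``random_model`` draws valid parameter sets of the same shape as the
packaged model (canonical value names, piecewise schedules, sampling
distributions) so every pipeline stage can be property-tested without
external data. Reduced state counts are expressed by switching pathways
off: a 4-state model has no remission, a 3-state model no locoregional
pathway, and a 2-state model no disease events at all (background mortality
only).

``microsim_oracle`` simulates individual monthly trajectories with exactly
the cohort engine's transition rows, clocks and valuation conventions, so
any disagreement beyond Monte Carlo error isolates an implementation bug
rather than a convention mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import DistributionSpec
from .engine import ef_event_probability
from .parameters import (
    ParameterSet,
    StrategySpec,
    base_values,
    build_parameter_set,
)
from .states import HealthState, Perspective

__all__ = ["random_model", "microsim_oracle", "MicrosimResult"]


def _spec_for(name: str, value: float, rng: np.random.Generator) -> DistributionSpec:
    """A plausible sampling distribution for a generated value."""
    if value <= 0.0:
        return DistributionSpec("fixed", value)
    if name.startswith("hr."):
        lo = value * rng.uniform(0.6, 0.95)
        hi = value * rng.uniform(1.05, 1.5)
        return DistributionSpec("lognormal", value, ci_low=lo, ci_high=hi)
    if name.startswith("cost."):
        return DistributionSpec("gamma", value, se=0.1 * value)
    if value >= 1.0:
        return DistributionSpec("fixed", value)
    return DistributionSpec("beta", value, se=max(0.1 * value, 1e-6))


def random_model(
    seed: int, n_states: int = 5, horizon_age_years: float | None = None
) -> ParameterSet:
    """A random, valid parameter set; deterministic in ``seed``."""
    if not 2 <= n_states <= 5:
        raise ValueError("n_states must be between 2 and 5")
    rng = np.random.default_rng(seed)
    v = dict(base_values())

    # event-free -> event schedules
    for name in (
        "tp.ef_event.adjuvant_t",
        "tp.ef_event.s5",
        "tp.ef_event.after_60m",
    ):
        v[name] = rng.uniform(0.002, 0.02)
    for name in (
        "tp.ef_event.s4.year1",
        "tp.ef_event.s4.year2",
        "tp.ef_event.s4.year3",
        "tp.ef_event.s4.year4",
    ):
        v[name] = rng.uniform(0.0005, 0.01)

    v["tp.event_split_lrr"] = rng.uniform(0.05, 0.6)
    exits = rng.dirichlet([2.0, 2.0, 6.0, 1.0])[:3]  # met, death, remission, stay
    v["tp.lrr_to_met"], v["tp.lrr_to_death"], v["tp.lrr_to_rem"] = exits
    v["tp.rem_to_met"] = rng.uniform(0.001, 0.02)
    v["tp.met_to_death"] = rng.uniform(0.01, 0.1)

    # monotone life table
    p = rng.uniform(1e-4, 5e-4)
    for name in (
        "mort.age_50_54",
        "mort.age_55_59",
        "mort.age_60_64",
        "mort.age_65_69",
        "mort.age_70_74",
        "mort.age_75_79",
        "mort.age_80_84",
        "mort.age_85_plus",
    ):
        v[name] = min(p, 0.05)
        p *= rng.uniform(1.0, 1.8)

    for name in ("hr.s2", "hr.s3", "hr.s4", "hr.s5"):
        v[name] = rng.uniform(0.4, 1.05)

    v["util.ef_after_year1"] = rng.uniform(0.7, 0.95)
    v["util.ef_year1"] = rng.uniform(0.6, v["util.ef_after_year1"])
    v["util.lrr"] = rng.uniform(0.4, 0.85)
    v["util.remission"] = rng.uniform(0.5, 0.95)
    v["util.metastasis"] = rng.uniform(0.3, 0.8)

    for name in list(v):
        if name.startswith("cost."):
            v[name] = v[name] * rng.uniform(0.5, 2.0)

    # reduced topologies: switch pathways off
    if n_states <= 4:  # no remission (locoregional exits to met/death only)
        v["tp.lrr_to_rem"] = 0.0
        v["tp.rem_to_met"] = 0.0
    if n_states <= 3:  # no locoregional pathway either
        v["tp.event_split_lrr"] = 0.0
    if n_states == 2:  # alive/dead only
        for name in list(v):
            if name.startswith("tp.ef_event"):
                v[name] = 0.0

    if horizon_age_years is None:
        horizon_age_years = float(rng.integers(70, 101))
    specs = {name: _spec_for(name, value, rng) for name, value in v.items()}
    return build_parameter_set(
        v,
        distribution_specs=specs,
        horizon_age_years=horizon_age_years,
        discount_rate_costs=rng.uniform(0.0, 0.05),
        discount_rate_outcomes=rng.uniform(0.0, 0.05),
    )


@dataclass(frozen=True)
class MicrosimResult:
    """Monte Carlo estimates (mean and SE) of the discounted outcomes."""

    strategy_id: str
    perspective: Perspective
    n_patients: int
    ly_mean: float
    ly_se: float
    qaly_mean: float
    qaly_se: float
    cost_mean: float
    cost_se: float


def microsim_oracle(
    strategy: StrategySpec | str,
    params: ParameterSet,
    n_patients: int,
    seed: int,
    perspective: Perspective = Perspective.PUBLIC,
) -> MicrosimResult:
    """Individual-level simulation of the cohort model.

    Simulates ``n_patients`` monthly trajectories with the engine's
    transition rows and accrual conventions (cycle-start valuation, model
    clock for event-free costs and utilities, time-in-state clocks for the
    recurrence and remission schedules, one-time neoadjuvant outlay at
    cycle 0) and returns means with Monte Carlo standard errors.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    perspective = Perspective(perspective)
    societal = perspective is Perspective.SOCIETAL
    if isinstance(strategy, str):
        strategy = params.strategy(strategy)
    rng = np.random.default_rng(seed)
    sh = params.shared
    T = params.horizon_months
    B = params.tenure_cap_months + 1
    cap = B - 1

    q = np.array([ef_event_probability(strategy, t, params.efficacy_mode) for t in range(T)])
    ages = params.start_age_years + np.arange(T) / 12.0
    m = np.array([params.life_table.monthly_death_probability(a) for a in ages])

    u = params.utilities
    util_by_state = np.zeros((T, len(HealthState)))
    util_by_state[:, HealthState.EVENT_FREE] = np.where(
        np.arange(T) < 12, u.ef_year1, u.ef_after_year1
    )
    util_by_state[:, HealthState.LOCOREGIONAL] = u.lrr
    util_by_state[:, HealthState.METASTASIS] = u.metastasis
    util_by_state[:, HealthState.REMISSION] = u.remission

    sched = params.cost_schedules[strategy.id]
    ef_cost = np.array(
        [sched[HealthState.EVENT_FREE].monthly_cost(t, societal) for t in range(T)]
    )
    lrr_cost = np.array(
        [sched[HealthState.LOCOREGIONAL].monthly_cost(b, societal) for b in range(B)]
    )
    rem_cost = np.array(
        [sched[HealthState.REMISSION].monthly_cost(b, societal) for b in range(B)]
    )
    met_cost = sched[HealthState.METASTASIS].monthly_cost(0, societal)

    d_cost = (1.0 + params.discount_rate_costs) ** (-np.arange(T) / 12.0)
    d_out = (1.0 + params.discount_rate_outcomes) ** (-np.arange(T) / 12.0)

    state = np.full(n_patients, int(HealthState.EVENT_FREE), dtype=np.int8)
    tenure = np.zeros(n_patients, dtype=np.int32)
    ly = np.zeros(n_patients)
    qaly = np.zeros(n_patients)
    cost = np.full(
        n_patients,
        strategy.neoadjuvant_dmc + (strategy.neoadjuvant_dnmc if societal else 0.0),
    )

    EF, LRR, MET, REM, DEAD = (
        int(HealthState.EVENT_FREE),
        int(HealthState.LOCOREGIONAL),
        int(HealthState.METASTASIS),
        int(HealthState.REMISSION),
        int(HealthState.DEAD),
    )
    for t in range(T):
        alive = state != DEAD
        if not alive.any():
            break
        ly += alive * (d_out[t] / 12.0)
        qaly += util_by_state[t, state] * (d_out[t] / 12.0)
        c = np.zeros(n_patients)
        c[state == EF] = ef_cost[t]
        c[state == LRR] = lrr_cost[tenure[state == LRR]]
        c[state == REM] = rem_cost[tenure[state == REM]]
        c[state == MET] = met_cost
        cost += c * d_cost[t]

        uni = rng.random(n_patients)
        new_state = state.copy()
        ef_mask = state == EF
        new_state[ef_mask] = np.select(
            [
                uni[ef_mask] < q[t] * sh.p_event_split_lrr,
                uni[ef_mask] < q[t],
                uni[ef_mask] < q[t] + m[t],
            ],
            [LRR, MET, DEAD],
            default=EF,
        )
        lrr_mask = state == LRR
        c1 = sh.p_lrr_to_met
        c2 = c1 + sh.p_lrr_to_death
        c3 = c2 + sh.p_lrr_to_rem
        new_state[lrr_mask] = np.select(
            [uni[lrr_mask] < c1, uni[lrr_mask] < c2, uni[lrr_mask] < c3],
            [MET, DEAD, REM],
            default=LRR,
        )
        rem_mask = state == REM
        new_state[rem_mask] = np.select(
            [uni[rem_mask] < sh.p_rem_to_met, uni[rem_mask] < sh.p_rem_to_met + m[t]],
            [MET, DEAD],
            default=REM,
        )
        met_mask = state == MET
        new_state[met_mask] = np.where(
            uni[met_mask] < sh.p_met_to_death, DEAD, MET
        )
        tenure = np.where(new_state == state, np.minimum(tenure + 1, cap), 0)
        state = new_state

    sqrt_n = np.sqrt(n_patients)
    return MicrosimResult(
        strategy_id=strategy.id,
        perspective=perspective,
        n_patients=n_patients,
        ly_mean=float(ly.mean()),
        ly_se=float(ly.std(ddof=1) / sqrt_n) if n_patients > 1 else 0.0,
        qaly_mean=float(qaly.mean()),
        qaly_se=float(qaly.std(ddof=1) / sqrt_n) if n_patients > 1 else 0.0,
        cost_mean=float(cost.mean()),
        cost_se=float(cost.std(ddof=1) / sqrt_n) if n_patients > 1 else 0.0,
    )


def simulate_path(
    strategy: StrategySpec | str,
    params: ParameterSet,
    seed: int,
) -> list[tuple[int, HealthState, int]]:
    """One seeded patient trajectory as (cycle, state, months_in_state)."""
    if isinstance(strategy, str):
        strategy = params.strategy(strategy)
    rng = np.random.default_rng(seed)
    from .engine import transition_distribution

    state = HealthState.EVENT_FREE
    tenure = 0
    path = [(0, state, 0)]
    for t in range(params.horizon_months):
        row = transition_distribution(state, tenure, t, strategy, params)
        states = list(row)
        probs = np.array([row[s] for s in states])
        nxt = states[rng.choice(len(states), p=probs / probs.sum())]
        tenure = min(tenure + 1, params.tenure_cap_months) if nxt is state else 0
        state = nxt
        path.append((t + 1, state, tenure))
        if state is HealthState.DEAD and len(path) > 2:
            break
    return path
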