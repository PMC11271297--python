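"""Deterministic Markov cohort engine.

Propagates the cohort through the five health states in monthly cycles from
the start age to the horizon, tracking months-in-state tenure for the states
whose costs follow a time-in-state clock, and accumulates (discounted and
undiscounted) life-years, QALYs and costs.

Conventions: occupancy, utilities and costs are valued at cycle start (no
half-cycle correction); discounting uses the factor (1 + r)^(-t/12) so the
cycle-0 amounts — including the one-time neoadjuvant outlay — are
undiscounted; background mortality competes additively with disease
transitions in the event-free and remission rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import LifeTable, ParameterSet, StrategySpec
from .states import CostClock, EfficacyMode, HealthState, Perspective

__all__ = [
    "hazard_scale",
    "ef_event_probability",
    "background_mortality",
    "transition_distribution",
    "run_cohort",
    "accumulate",
    "run_strategy",
    "CohortTrace",
    "EconResult",
]


def hazard_scale(p: float, hr: float) -> float:
    """Rescale a per-cycle probability by a hazard ratio.

    Converts to a rate, multiplies, converts back: ``1 - (1 - p)**hr``.
    Identity at hr = 1; undefined for p = 1 (infinite rate).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    if hr <= 0.0:
        raise ValueError(f"hazard ratio must be positive, got {hr}")
    if p == 1.0:
        if hr == 1.0:
            return 1.0
        raise ValueError("cannot rescale p = 1 (hazard is unbounded)")
    return 1.0 - (1.0 - p) ** hr


def ef_event_probability(
    strategy: StrategySpec,
    cycle: int,
    mode: EfficacyMode = EfficacyMode.HR_ON_BASELINE,
) -> float:
    """Per-cycle probability of leaving EVENT_FREE for an event (before the
    locoregional/metastatic split) at model month ``cycle``.

    The composition of the baseline schedule with the strategy's hazard
    ratio, and the 12-year cap on the treatment effect, follow ``mode``
    (see :class:`~her2cua.states.EfficacyMode`).
    """
    if cycle < 0:
        raise ValueError("cycle must be non-negative")
    base = strategy.ef_event_baseline.at(cycle)
    eff = strategy.efficacy
    if eff is None or mode is EfficacyMode.BASELINE_ONLY:
        return base
    if cycle >= eff.effect_duration_months:
        return base
    if mode is EfficacyMode.HR_ON_BASELINE:
        return hazard_scale(base, eff.hr_point)
    if mode is EfficacyMode.TRIAL_THEN_HR:
        if cycle < strategy.trial_baseline_months:
            return base
        return hazard_scale(base, eff.hr_point)
    raise ValueError(f"unknown efficacy mode {mode!r}")


def background_mortality(age_years: float, life_table: LifeTable) -> float:
    """General-population monthly death probability at the given age."""
    return life_table.monthly_death_probability(age_years)


def transition_distribution(
    state: HealthState,
    months_in_state: int,
    cycle: int,
    strategy: StrategySpec,
    params: ParameterSet,
) -> dict[HealthState, float]:
    """One row of the (time-inhomogeneous) transition matrix.

    Transitions do not depend on ``months_in_state`` in this model (tenure
    matters only for costing); the argument is kept for interface symmetry
    with the microsimulation oracle.
    """
    sh = params.shared
    age = params.start_age_years + cycle / 12.0
    if state is HealthState.DEAD:
        return {HealthState.DEAD: 1.0}
    if state is HealthState.EVENT_FREE:
        q = ef_event_probability(strategy, cycle, params.efficacy_mode)
        m = background_mortality(age, params.life_table)
        stay = 1.0 - q - m
        if stay < 0:
            raise ValueError(
                f"EVENT_FREE exits exceed 1 at cycle {cycle}: q={q}, mortality={m}"
            )
        return {
            HealthState.LOCOREGIONAL: q * sh.p_event_split_lrr,
            HealthState.METASTASIS: q * sh.p_event_split_met,
            HealthState.DEAD: m,
            HealthState.EVENT_FREE: stay,
        }
    if state is HealthState.LOCOREGIONAL:
        stay = 1.0 - sh.p_lrr_to_met - sh.p_lrr_to_death - sh.p_lrr_to_rem
        if stay < -1e-12:
            raise ValueError("LOCOREGIONAL exit probabilities exceed 1")
        return {
            HealthState.METASTASIS: sh.p_lrr_to_met,
            HealthState.DEAD: sh.p_lrr_to_death,
            HealthState.REMISSION: sh.p_lrr_to_rem,
            HealthState.LOCOREGIONAL: max(stay, 0.0),
        }
    if state is HealthState.REMISSION:
        m = background_mortality(age, params.life_table)
        stay = 1.0 - sh.p_rem_to_met - m
        if stay < 0:
            raise ValueError(f"REMISSION exits exceed 1 at cycle {cycle}")
        return {
            HealthState.METASTASIS: sh.p_rem_to_met,
            HealthState.DEAD: m,
            HealthState.REMISSION: stay,
        }
    # METASTASIS
    return {
        HealthState.DEAD: sh.p_met_to_death,
        HealthState.METASTASIS: 1.0 - sh.p_met_to_death,
    }


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle with months-in-state resolution.

    ``occupancy`` has shape ``(T + 1, 5, B)``: cycle, health state, tenure
    bucket (capped at ``B - 1`` months). Cycle 0 is entirely
    (EVENT_FREE, tenure 0).
    """

    strategy_id: str
    occupancy: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state_totals(self) -> np.ndarray:
        """Occupancy summed over tenure: shape (T + 1, 5)."""
        return self.occupancy.sum(axis=2)

    def tenure_mass(self, state: HealthState, lo: int, hi: int | None) -> np.ndarray:
        """Per-cycle fraction in ``state`` with tenure in [lo, hi)."""
        sl = slice(lo, hi)
        return self.occupancy[:, int(state), sl].sum(axis=1)

    def to_frame(self, start_age_years: float = 50.0) -> pd.DataFrame:
        """Long-format export (nonzero cells only): cycle, age_years, state,
        months_in_state, fraction."""
        t_idx, s_idx, b_idx = np.nonzero(self.occupancy)
        return pd.DataFrame(
            {
                "cycle": t_idx,
                "age_years": start_age_years + t_idx / 12.0,
                "state": [HealthState(s).name for s in s_idx],
                "months_in_state": b_idx,
                "fraction": self.occupancy[t_idx, s_idx, b_idx],
            }
        )


@dataclass(frozen=True)
class EconResult:
    """Discounted and undiscounted outcomes for one strategy/perspective."""

    strategy_id: str
    perspective: Perspective
    ly_discounted: float
    qaly_discounted: float
    cost_discounted: float
    ly_undiscounted: float
    qaly_undiscounted: float
    cost_undiscounted: float
    #: undiscounted LKR per cycle under this perspective (reused by the BIA)
    per_cycle_cost_stream: np.ndarray

    def to_dict(self) -> dict:
        return {
            "strategy_id": self.strategy_id,
            "perspective": self.perspective.value,
            "ly_discounted": self.ly_discounted,
            "qaly_discounted": self.qaly_discounted,
            "cost_discounted": self.cost_discounted,
            "ly_undiscounted": self.ly_undiscounted,
            "qaly_undiscounted": self.qaly_undiscounted,
            "cost_undiscounted": self.cost_undiscounted,
        }


def _precompute_cycle_inputs(strategy: StrategySpec, params: ParameterSet):
    """Per-cycle event probability and background mortality arrays."""
    T = params.horizon_months
    q = np.array(
        [ef_event_probability(strategy, t, params.efficacy_mode) for t in range(T)]
    )
    ages = params.start_age_years + np.arange(T) / 12.0
    m = np.array([params.life_table.monthly_death_probability(a) for a in ages])
    return q, m


def run_cohort(strategy: StrategySpec | str, params: ParameterSet) -> CohortTrace:
    """Propagate a unit cohort from (EVENT_FREE, tenure 0) over the horizon."""
    if isinstance(strategy, str):
        strategy = params.strategy(strategy)
    T = params.horizon_months
    B = params.tenure_cap_months + 1
    q, m = _precompute_cycle_inputs(strategy, params)
    sh = params.shared

    if np.any(q + m > 1.0):
        t_bad = int(np.argmax(q + m > 1.0))
        raise ValueError(f"EVENT_FREE exit probabilities exceed 1 at cycle {t_bad}")
    lrr_stay = 1.0 - sh.p_lrr_to_met - sh.p_lrr_to_death - sh.p_lrr_to_rem
    if lrr_stay < -1e-12:
        raise ValueError("LOCOREGIONAL exit probabilities exceed 1")
    lrr_stay = max(lrr_stay, 0.0)
    if np.any(sh.p_rem_to_met + m > 1.0):
        raise ValueError("REMISSION exit probabilities exceed 1")

    occ = np.zeros((T + 1, len(HealthState), B))
    occ[0, HealthState.EVENT_FREE, 0] = 1.0

    EF, LRR, MET, REM, DEAD = (
        int(HealthState.EVENT_FREE),
        int(HealthState.LOCOREGIONAL),
        int(HealthState.METASTASIS),
        int(HealthState.REMISSION),
        int(HealthState.DEAD),
    )
    cap = B - 1
    for t in range(T):
        cur = occ[t]
        nxt = occ[t + 1]
        ef = cur[EF].sum()
        lrr = cur[LRR]
        met = cur[MET].sum()
        rem = cur[REM]
        dead = cur[DEAD].sum()
        lrr_tot = lrr.sum()
        rem_tot = rem.sum()

        events = ef * q[t]
        to_lrr = events * sh.p_event_split_lrr
        to_met = events * sh.p_event_split_met + lrr_tot * sh.p_lrr_to_met + rem_tot * sh.p_rem_to_met
        to_rem = lrr_tot * sh.p_lrr_to_rem
        deaths = (
            ef * m[t]
            + lrr_tot * sh.p_lrr_to_death
            + rem_tot * m[t]
            + met * sh.p_met_to_death
        )

        # event-free: tenure equals model time (no re-entry)
        nxt[EF, min(t + 1, cap)] = ef * (1.0 - q[t] - m[t])
        # tunnel states: stayers age one bucket, entrants start at 0
        nxt[LRR, 1:] = lrr[:-1] * lrr_stay
        nxt[LRR, cap] += lrr[cap] * lrr_stay
        nxt[LRR, 0] = to_lrr
        rem_stay = 1.0 - sh.p_rem_to_met - m[t]
        nxt[REM, 1:] = rem[:-1] * rem_stay
        nxt[REM, cap] += rem[cap] * rem_stay
        nxt[REM, 0] = to_rem
        # metastasis and death keep no tenure resolution
        nxt[MET, 0] = met * (1.0 - sh.p_met_to_death) + to_met
        nxt[DEAD, 0] = dead + deaths

    return CohortTrace(strategy_id=strategy.id, occupancy=occ)


def _bucket_cost_vector(schedule, B: int, societal: bool) -> np.ndarray:
    """Monthly cost per tenure (or model-time) month, evaluated 0..B-1."""
    return np.array([schedule.monthly_cost(b, societal) for b in range(B)])


def accumulate(
    trace: CohortTrace,
    strategy: StrategySpec | str,
    params: ParameterSet,
    perspective: Perspective,
) -> EconResult:
    """Aggregate a cohort trace into discounted LY, QALYs and costs.

    Utilities for EVENT_FREE follow the model clock (first model year versus
    later); costs follow each state schedule's declared clock. The one-time
    neoadjuvant outlay is charged, undiscounted, at cycle 0.
    """
    perspective = Perspective(perspective)
    if isinstance(strategy, str):
        strategy = params.strategy(strategy)
    if trace.strategy_id != strategy.id:
        raise ValueError(
            f"trace was produced for {trace.strategy_id}, not {strategy.id}"
        )
    societal = perspective is Perspective.SOCIETAL
    T = params.horizon_months
    B = params.tenure_cap_months + 1
    t_arr = np.arange(T)
    d_cost = (1.0 + params.discount_rate_costs) ** (-t_arr / 12.0)
    d_out = (1.0 + params.discount_rate_outcomes) ** (-t_arr / 12.0)

    totals = trace.state_totals()[:T]  # occupancy valued at cycle start
    ef = totals[:, HealthState.EVENT_FREE]
    lrr = totals[:, HealthState.LOCOREGIONAL]
    met = totals[:, HealthState.METASTASIS]
    rem = totals[:, HealthState.REMISSION]
    alive = ef + lrr + met + rem

    u = params.utilities
    u_ef = np.where(t_arr < 12, u.ef_year1, u.ef_after_year1)
    ly_stream = alive / 12.0
    qaly_stream = (ef * u_ef + lrr * u.lrr + rem * u.remission + met * u.metastasis) / 12.0

    schedules = params.cost_schedules[strategy.id]
    cost_stream = np.zeros(T)
    for state in (
        HealthState.EVENT_FREE,
        HealthState.LOCOREGIONAL,
        HealthState.METASTASIS,
        HealthState.REMISSION,
    ):
        sched = schedules[state]
        if sched.clock is CostClock.MODEL_TIME:
            monthly = np.array([sched.monthly_cost(t, societal) for t in range(T)])
            cost_stream += totals[:, state] * monthly
        else:
            by_bucket = _bucket_cost_vector(sched, B, societal)
            cost_stream += trace.occupancy[:T, state, :] @ by_bucket
    cost_stream[0] += strategy.neoadjuvant_dmc + (
        strategy.neoadjuvant_dnmc if societal else 0.0
    )

    return EconResult(
        strategy_id=strategy.id,
        perspective=perspective,
        ly_discounted=float(ly_stream @ d_out),
        qaly_discounted=float(qaly_stream @ d_out),
        cost_discounted=float(cost_stream @ d_cost),
        ly_undiscounted=float(ly_stream.sum()),
        qaly_undiscounted=float(qaly_stream.sum()),
        cost_undiscounted=float(cost_stream.sum()),
        per_cycle_cost_stream=cost_stream,
    )


def run_strategy(
    strategy_id: str, params: ParameterSet, perspective: Perspective
) -> EconResult:
    """Convenience: run the cohort and accumulate in one call."""
    strategy = params.strategy(strategy_id)
    return accumulate(run_cohort(strategy, params), strategy, params, perspective)


def run_all_strategies(
    params: ParameterSet, perspective: Perspective
) -> dict[str, EconResult]:
    """Base-case run of every strategy under one perspective."""
    results = {}
    for strategy in params.strategies:
        trace = run_cohort(strategy, params)
        results[strategy.id] = accumulate(trace, strategy, params, perspective)
    return results
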