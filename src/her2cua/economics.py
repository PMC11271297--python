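"""Cost-effectiveness analysis: ICERs, incremental (frontier) analysis,
net monetary benefit, currency conversion, threshold price-reduction search.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .engine import EconResult, run_strategy
from .parameters import ParameterSet
from .states import Dominance, Perspective

__all__ = [
    "icer",
    "incremental_analysis",
    "nmb",
    "to_usd",
    "threshold_reduction",
    "CostComponent",
    "NOT_ACHIEVABLE",
    "DominatedError",
    "UndefinedICERError",
]


class UndefinedICERError(ValueError):
    """Raised when the QALY difference between the two results is zero."""


class DominatedError(ValueError):
    """Raised when the new strategy is cheaper and more effective (or the
    reverse), so the comparison is a dominance call, not an ICER."""


def icer(result_new: EconResult, result_ref: EconResult) -> tuple[float, float]:
    """(cost per QALY gained, cost per LY gained) of ``result_new`` versus
    ``result_ref``.

    Raises :class:`UndefinedICERError` when the QALY difference is zero and
    :class:`DominatedError` when the sign pattern is a dominance call (one
    strategy cheaper *and* more effective) rather than a trade-off.
    """
    if result_new.perspective is not result_ref.perspective:
        raise ValueError("ICER requires results from the same perspective")
    d_cost = result_new.cost_discounted - result_ref.cost_discounted
    d_qaly = result_new.qaly_discounted - result_ref.qaly_discounted
    d_ly = result_new.ly_discounted - result_ref.ly_discounted
    if d_qaly == 0.0:
        raise UndefinedICERError("QALY difference is zero; ICER undefined")
    if (d_cost <= 0.0 and d_qaly > 0.0) or (d_cost >= 0.0 and d_qaly < 0.0):
        raise DominatedError(
            "one strategy dominates (cheaper and more effective); no ICER"
        )
    per_ly = d_cost / d_ly if d_ly != 0.0 else math.inf
    return d_cost / d_qaly, per_ly


def nmb(result: EconResult, wtp: float) -> float:
    """Net monetary benefit: QALYs x willingness-to-pay - cost (LKR)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return result.qaly_discounted * wtp - result.cost_discounted


def to_usd(lkr: float, lkr_per_usd: float = 194.78) -> float:
    """Convert 2021 LKR to USD at the study exchange rate."""
    return lkr / lkr_per_usd


def _ratio_or_none(d_cost: float, d_eff: float) -> float | None:
    if d_eff == 0.0:
        return None
    return d_cost / d_eff


def incremental_analysis(
    results: Mapping[str, EconResult] | Sequence[EconResult],
    wtp: float | None = None,
    comparator: str = "S1",
) -> pd.DataFrame:
    """Full incremental analysis over a set of strategies.

    Strategies are ordered by ascending discounted total cost. For each row
    the table reports totals, pairwise differences and ICERs versus the
    comparator, the sequential ICER versus the next least-costly strategy
    (reported for *every* adjacent pair, dominated or not), the dominance
    flag over the efficiency frontier, and — when ``wtp`` is given — the net
    monetary benefit.
    """
    if not isinstance(results, Mapping):
        results = {r.strategy_id: r for r in results}
    if len(results) != len({r.strategy_id for r in results.values()}):
        raise ValueError("duplicate strategy ids in results")
    if comparator not in results:
        raise ValueError(f"comparator {comparator!r} missing from results")
    persp = {r.perspective for r in results.values()}
    if len(persp) != 1:
        raise ValueError("all results must share one perspective")

    order = sorted(results.values(), key=lambda r: r.cost_discounted)
    ref = results[comparator]
    rows = []
    for i, res in enumerate(order):
        prev = order[i - 1] if i > 0 else None
        d_cost = res.cost_discounted - (prev.cost_discounted if prev else 0.0)
        d_qaly = res.qaly_discounted - (prev.qaly_discounted if prev else 0.0)
        d_ly = res.ly_discounted - (prev.ly_discounted if prev else 0.0)
        rows.append(
            {
                "strategy_id": res.strategy_id,
                "total_cost": res.cost_discounted,
                "total_qaly": res.qaly_discounted,
                "total_ly": res.ly_discounted,
                "delta_cost": d_cost if prev else None,
                "delta_qaly": d_qaly if prev else None,
                "delta_ly": d_ly if prev else None,
                "sequential_icer": _ratio_or_none(d_cost, d_qaly) if prev else None,
                "pairwise_icer_vs_comparator": (
                    _ratio_or_none(
                        res.cost_discounted - ref.cost_discounted,
                        res.qaly_discounted - ref.qaly_discounted,
                    )
                    if res.strategy_id != comparator
                    else None
                ),
                "nmb": nmb(res, wtp) if wtp is not None else None,
            }
        )
    table = pd.DataFrame(rows)

    # dominance over the frontier: strict dominance first, then extended
    flags = {r.strategy_id: Dominance.NONE for r in order}
    for a in order:
        for b in order:
            if a is b:
                continue
            if (
                b.cost_discounted <= a.cost_discounted
                and b.qaly_discounted >= a.qaly_discounted
                and (
                    b.cost_discounted < a.cost_discounted
                    or b.qaly_discounted > a.qaly_discounted
                )
            ):
                flags[a.strategy_id] = Dominance.DOMINATED
                break
    frontier = [r for r in order if flags[r.strategy_id] is Dominance.NONE]
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = _ratio_or_none(
                mid.cost_discounted - lo.cost_discounted,
                mid.qaly_discounted - lo.qaly_discounted,
            )
            icer_hi = _ratio_or_none(
                hi.cost_discounted - mid.cost_discounted,
                hi.qaly_discounted - mid.qaly_discounted,
            )
            if icer_lo is not None and icer_hi is not None and icer_lo > icer_hi:
                flags[mid.strategy_id] = Dominance.EXTENDEDLY_DOMINATED
                frontier.pop(i)
                changed = True
                break
    table["dominance"] = [flags[sid].value for sid in table["strategy_id"]]
    return table


class CostComponent(str, enum.Enum):
    """Cost components that a threshold price-reduction may scale."""

    NEOADJUVANT = "neoadjuvant"
    ADJUVANT_EF_YEAR1 = "adjuvant_ef_year1"


class _NotAchievable:
    """Sentinel: no reduction up to 100% makes the strategy cost-effective."""

    def __repr__(self) -> str:  # pragma: no cover - repr only
        return "NOT_ACHIEVABLE"

    def __bool__(self) -> bool:
        return False


NOT_ACHIEVABLE = _NotAchievable()


def _reduced_params(
    params: ParameterSet,
    strategy_id: str,
    components: Iterable[CostComponent],
    reduction: float,
    perspective: Perspective,
) -> ParameterSet:
    """Parameter set with the named cost components of one strategy scaled by
    (1 - reduction).

    The NEOADJUVANT component is the strategy's own one-time neoadjuvant-phase
    outlay under the active perspective (direct medical cost alone for the
    public payer, plus the phase's non-medical lump under the societal view).
    The ADJUVANT_EF_YEAR1 component is the strategy's adjuvant-year monthly
    DMC excess over the single-HER2 adjuvant backbone (strategy 2's). The
    returned set is an ephemeral evaluation copy: its structured fields are
    rescaled in place and its flat ``values`` are not kept in sync.
    """
    from dataclasses import replace

    from .parameters import StateCostSchedule
    from .states import HealthState

    societal = Perspective(perspective) is Perspective.SOCIETAL
    scale = 1.0 - reduction
    target = params.strategy(strategy_id)
    for comp in components:
        comp = CostComponent(comp)
        if comp is CostComponent.NEOADJUVANT:
            target = replace(
                target,
                neoadjuvant_dmc=target.neoadjuvant_dmc * scale,
                neoadjuvant_dnmc=(
                    target.neoadjuvant_dnmc * scale if societal else target.neoadjuvant_dnmc
                ),
            )
        else:
            backbone = params.strategy("S2").ef_year1_monthly_dmc
            excess = max(target.ef_year1_monthly_dmc - backbone, 0.0)
            target = replace(target, ef_year1_monthly_dmc=backbone + excess * scale)

    schedules = dict(params.cost_schedules[strategy_id])
    ef_sched = schedules[HealthState.EVENT_FREE]
    first, *rest = ef_sched.pieces
    schedules[HealthState.EVENT_FREE] = StateCostSchedule(
        ef_sched.state,
        ef_sched.clock,
        ((first[0], first[1], target.ef_year1_monthly_dmc, first[3]), *rest),
    )
    cost_schedules = {**params.cost_schedules, strategy_id: schedules}
    strategies = tuple(
        target if s.id == strategy_id else s for s in params.strategies
    )
    return replace(params, strategies=strategies, cost_schedules=cost_schedules)


def threshold_reduction(
    params: ParameterSet,
    strategy_id: str,
    reference_id: str,
    perspective: Perspective,
    wtp: float | None = None,
    components: Iterable[CostComponent] = (CostComponent.NEOADJUVANT,),
    step: float = 0.05,
    method: str = "grid",
    tol: float = 0.001,
):
    """Minimal fractional cost reduction making ``strategy_id`` cost-effective
    versus ``reference_id`` at the willingness-to-pay threshold.

    ``method="grid"`` searches multiples of ``step`` in [0, 1];
    ``method="bisect"`` refines continuously to ``tol``. Returns the fraction,
    or :data:`NOT_ACHIEVABLE` when even a 100% reduction of the named
    components does not suffice.
    """
    if strategy_id == reference_id:
        raise ValueError("reference must differ from the strategy under test")
    if wtp is None:
        wtp = params.wtp_lkr
    components = tuple(CostComponent(c) for c in components)
    ref = run_strategy(reference_id, params, perspective)

    def cost_effective(reduction: float) -> bool:
        reduced = _reduced_params(params, strategy_id, components, reduction, perspective)
        res = run_strategy(strategy_id, reduced, perspective)
        d_qaly = res.qaly_discounted - ref.qaly_discounted
        d_cost = res.cost_discounted - ref.cost_discounted
        if d_qaly > 0.0:
            return d_cost / d_qaly <= wtp
        return d_cost <= 0.0  # not more effective: only acceptable if cheaper

    if method == "grid":
        n_steps = round(1.0 / step)
        if abs(n_steps * step - 1.0) > 1e-9:
            raise ValueError("step must divide 100%")
        for k in range(n_steps + 1):
            r = k * step
            if cost_effective(r):
                return r
        return NOT_ACHIEVABLE
    if method != "bisect":
        raise ValueError(f"unknown method {method!r}")
    if cost_effective(0.0):
        return 0.0
    if not cost_effective(1.0):
        return NOT_ACHIEVABLE
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cost_effective(mid):
            hi = mid
        else:
            lo = mid
    return hi
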