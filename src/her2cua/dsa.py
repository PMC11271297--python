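"""One-way deterministic sensitivity analysis (tornado data).

Each uncertain parameter is set in turn to its lower and upper bound — by
default the 2.5th/97.5th percentiles of its sampling distribution, with
hazard ratios using their published 95% CI directly — while everything else
stays at base case, and the ICER of the chosen strategy versus the reference
is recomputed. Discount rates, which carry no sampling distribution, are
varied between 0% and 6%. Dominance reversals are flagged, never dropped.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from .engine import run_strategy
from .parameters import LRR_EXIT_NAMES, ParameterSet, repair_lrr_simplex
from .states import Perspective

__all__ = ["one_way_dsa", "DISCOUNT_BOUNDS"]

#: low/high bounds used for the per-annum discount rates (common HTA practice).
DISCOUNT_BOUNDS = (0.0, 0.06)

_DISCOUNT_PARAMS = ("discount_rate_costs", "discount_rate_outcomes")


def _perturbed(params: ParameterSet, name: str, value: float) -> ParameterSet:
    if name in _DISCOUNT_PARAMS:
        return replace(params, **{name: value})
    updates = {name: value}
    if name in LRR_EXIT_NAMES:
        # raising one exit above the base-case simplex renormalizes the row,
        # as in the probabilistic analysis
        values = dict(params.values)
        values[name] = value
        repair_lrr_simplex(values)
        updates = {k: values[k] for k in LRR_EXIT_NAMES}
    return params.with_values(updates, validate="structural")


def _signed_icer(params, strategy_id, reference_id, perspective):
    new = run_strategy(strategy_id, params, perspective)
    ref = run_strategy(reference_id, params, perspective)
    d_cost = new.cost_discounted - ref.cost_discounted
    d_qaly = new.qaly_discounted - ref.qaly_discounted
    if d_qaly == 0.0:
        return float("nan"), "undefined"
    value = d_cost / d_qaly
    if d_cost >= 0.0 and d_qaly < 0.0:
        return value, "dominated"
    if d_cost <= 0.0 and d_qaly > 0.0:
        return value, "dominant"
    return value, "trade-off"


def one_way_dsa(
    params: ParameterSet,
    strategy_id: str,
    reference_id: str = "S1",
    perspective: Perspective = Perspective.SOCIETAL,
    top_k: int | None = 10,
    bounds: str = "percentile",
) -> pd.DataFrame:
    """Tornado table for one strategy-versus-reference comparison.

    ``bounds="percentile"`` uses each distribution's 2.5th/97.5th
    percentiles; ``bounds="pm20"`` uses mean +/- 20%. Rows are sorted by
    descending ICER range; ``top_k=None`` keeps every parameter. The signed
    ICER is reported together with a flag (``trade-off``, ``dominant``,
    ``dominated``) because a bound can flip the comparison's sign.
    """
    if strategy_id == reference_id:
        raise ValueError("strategy and reference must differ")
    if bounds not in ("percentile", "pm20"):
        raise ValueError(f"unknown bounds convention {bounds!r}")
    perspective = Perspective(perspective)
    base_icer, base_flag = _signed_icer(params, strategy_id, reference_id, perspective)

    names = list(sorted(params.distribution_specs)) + list(_DISCOUNT_PARAMS)
    rows = []
    for name in names:
        if name in _DISCOUNT_PARAMS:
            lo, hi = DISCOUNT_BOUNDS
        else:
            spec = params.distribution_specs[name]
            if bounds == "percentile":
                lo, hi = spec.percentile(0.025), spec.percentile(0.975)
            else:
                lo, hi = spec.mean * 0.8, spec.mean * 1.2
        icer_lo, flag_lo = (
            (base_icer, base_flag)
            if lo == _base_value(params, name)
            else _signed_icer(
                _perturbed(params, name, lo), strategy_id, reference_id, perspective
            )
        )
        icer_hi, flag_hi = (
            (base_icer, base_flag)
            if hi == _base_value(params, name)
            else _signed_icer(
                _perturbed(params, name, hi), strategy_id, reference_id, perspective
            )
        )
        rows.append(
            {
                "parameter": name,
                "low_bound": lo,
                "high_bound": hi,
                "icer_at_low": icer_lo,
                "icer_at_high": icer_hi,
                "flag_at_low": flag_lo,
                "flag_at_high": flag_hi,
                "icer_range": abs(icer_hi - icer_lo),
            }
        )
    table = pd.DataFrame(rows)
    table["base_icer"] = base_icer
    table = table.sort_values("icer_range", ascending=False, kind="stable")
    if top_k is not None:
        table = table.head(top_k)
    return table.reset_index(drop=True)


def _base_value(params: ParameterSet, name: str) -> float:
    if name in _DISCOUNT_PARAMS:
        return getattr(params, name)
    return params.values[name]
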