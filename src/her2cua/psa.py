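"""Probabilistic sensitivity analysis.

All uncertain parameters are drawn jointly (and independently) from their
assigned distributions — Beta for probabilities and utilities, Gamma for
costs, LogNormal for hazard ratios — and the cohort model is re-evaluated
per draw for all five strategies. Results feed the cost-effectiveness plane
and the cost-effectiveness acceptability curves.

Randomness: one root seed; iteration ``i`` uses the independent substream
``SeedSequence([seed, i])``, and within an iteration parameters are drawn in
sorted-name order. Identical (parameters, n, seed) therefore reproduce the
result exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import accumulate, run_cohort
from .parameters import (
    ParameterSet,
    ParameterValidationError,
    STRATEGY_IDS,
    repair_lrr_simplex,
)
from .states import Perspective

__all__ = ["PSAResult", "sample_parameter_set", "run_psa", "ceac", "ce_plane", "quadrant_counts"]

_MAX_RETRIES = 100


def _draw_values(params: ParameterSet, rng: np.random.Generator) -> tuple[dict, bool]:
    """One joint draw of the flat values; returns (values, simplex_renormalized)."""
    values = dict(params.values)
    for name in sorted(params.distribution_specs):
        if name in values:
            values[name] = params.distribution_specs[name].sample(rng)
    # locoregional exits must stay on the probability simplex; renormalize
    # only when the independent draws overshoot it
    renorm = repair_lrr_simplex(values)
    return values, renorm


def sample_parameter_set(
    params: ParameterSet, rng: np.random.Generator
) -> ParameterSet:
    """One joint parameter draw, returned as a validated parameter set.

    The discount rates, cycle structure and horizon are never sampled. The
    metastatic share of events is the complement of the sampled locoregional
    share, and the locoregional exit row is renormalized onto the simplex if
    the independent draws overshoot it. Invalid draws are retried a bounded
    number of times.
    """
    for _ in range(_MAX_RETRIES):
        values, _ = _draw_values(params, rng)
        try:
            return _rebuild(params, values)
        except ParameterValidationError:
            continue
    raise ParameterValidationError(
        f"no valid parameter draw after {_MAX_RETRIES} attempts"
    )


def _rebuild(params: ParameterSet, values: dict) -> ParameterSet:
    from .parameters import build_parameter_set

    return build_parameter_set(
        values,
        validate="structural",
        distribution_specs=params.distribution_specs,
        start_age_years=params.start_age_years,
        horizon_age_years=params.horizon_age_years,
        discount_rate_costs=params.discount_rate_costs,
        discount_rate_outcomes=params.discount_rate_outcomes,
        wtp_lkr=params.wtp_lkr,
        lkr_per_usd=params.lkr_per_usd,
        efficacy_mode=params.efficacy_mode,
    )


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo evaluation of all strategies under one perspective.

    ``costs``/``qalys``/``lys`` have shape (n_iterations, n_strategies) with
    strategy columns in ``strategy_ids`` order; ``draws`` retains every
    sampled parameter vector for audit.
    """

    n_iterations: int
    seed: int
    perspective: Perspective
    strategy_ids: tuple[str, ...]
    costs: np.ndarray
    qalys: np.ndarray
    lys: np.ndarray
    draws: pd.DataFrame
    n_simplex_renormalized: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long format: iteration, strategy, cost_lkr, qaly."""
        n, k = self.costs.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n), k),
                "strategy": np.tile(self.strategy_ids, n),
                "cost_lkr": self.costs.ravel(),
                "qaly": self.qalys.ravel(),
            }
        )


def run_psa(
    params: ParameterSet,
    n: int = 1000,
    seed: int = 0,
    perspective: Perspective = Perspective.SOCIETAL,
) -> PSAResult:
    """Monte Carlo PSA: ``n`` joint draws, each run through the cohort model
    for every strategy."""
    if n < 1:
        raise ValueError("n must be >= 1")
    perspective = Perspective(perspective)
    ids = tuple(s.id for s in params.strategies)
    costs = np.empty((n, len(ids)))
    qalys = np.empty((n, len(ids)))
    lys = np.empty((n, len(ids)))
    draw_rows = []
    n_renorm = 0
    for i in range(n):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed, i])))
        values = None
        for _ in range(_MAX_RETRIES):
            candidate, renorm = _draw_values(params, rng)
            try:
                sampled = _rebuild(params, candidate)
            except ParameterValidationError:
                continue
            values = candidate
            n_renorm += int(renorm)
            break
        if values is None:
            raise ParameterValidationError(
                f"iteration {i}: no valid parameter draw after {_MAX_RETRIES} attempts"
            )
        for j, strategy in enumerate(sampled.strategies):
            res = accumulate(
                run_cohort(strategy, sampled), strategy, sampled, perspective
            )
            costs[i, j] = res.cost_discounted
            qalys[i, j] = res.qaly_discounted
            lys[i, j] = res.ly_discounted
        draw_rows.append(values)
    draws = pd.DataFrame(draw_rows)
    draws.insert(0, "iteration", np.arange(n))
    return PSAResult(
        n_iterations=n,
        seed=seed,
        perspective=perspective,
        strategy_ids=ids,
        costs=costs,
        qalys=qalys,
        lys=lys,
        draws=draws,
        n_simplex_renormalized=n_renorm,
    )


def ceac(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, the probability that each strategy has
    the highest net monetary benefit across the Monte Carlo draws (exact ties
    split equally). Probabilities sum to 1 at every threshold.
    """
    wtp_grid = np.atleast_1d(np.asarray(wtp_grid, dtype=float))
    if wtp_grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    rows = []
    n = psa.n_iterations
    for wtp in wtp_grid:
        net = psa.qalys * wtp - psa.costs
        best = net.max(axis=1, keepdims=True)
        winners = net == best
        shares = winners / winners.sum(axis=1, keepdims=True)
        probs = shares.sum(axis=0) / n
        for sid, p in zip(psa.strategy_ids, probs):
            rows.append({"wtp_lkr": wtp, "strategy": sid, "probability": p})
    return pd.DataFrame(rows)


def ce_plane(psa: PSAResult, reference: str = "S1") -> pd.DataFrame:
    """Per-iteration incremental (cost, QALY) pairs versus the reference.

    Quadrants follow the usual compass naming on the incremental plane
    (northeast: more costly and more effective).
    """
    if reference not in psa.strategy_ids:
        raise ValueError(f"reference {reference!r} not among strategies")
    ref_idx = psa.strategy_ids.index(reference)
    frames = []
    for j, sid in enumerate(psa.strategy_ids):
        if sid == reference:
            continue
        d_cost = psa.costs[:, j] - psa.costs[:, ref_idx]
        d_qaly = psa.qalys[:, j] - psa.qalys[:, ref_idx]
        quadrant = np.where(
            d_qaly >= 0,
            np.where(d_cost >= 0, "NE", "SE"),
            np.where(d_cost >= 0, "NW", "SW"),
        )
        frames.append(
            pd.DataFrame(
                {
                    "iteration": np.arange(psa.n_iterations),
                    "strategy": sid,
                    "delta_cost": d_cost,
                    "delta_qaly": d_qaly,
                    "quadrant": quadrant,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def quadrant_counts(plane: pd.DataFrame) -> pd.DataFrame:
    """Draws per quadrant for each strategy on the CE plane."""
    counts = (
        plane.groupby(["strategy", "quadrant"]).size().unstack(fill_value=0)
    )
    return counts.reindex(columns=["NE", "NW", "SE", "SW"], fill_value=0)
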