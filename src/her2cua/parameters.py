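"""Model parameterisation: typed parameter set, validation, base case.

The model is parameterised by a flat registry of named scalar values (the
canonical schema used by configuration files, probabilistic sampling and
one-way sensitivity analysis) from which the structured objects the engine
consumes — strategy specs, the life table, cost schedules — are built.

The packaged base case encodes the published Sri Lankan evaluation of five
neoadjuvant/adjuvant HER2-targeted strategies: monthly cycles from age 50 to
age 100, 3% annual discounting of costs and outcomes, costs in 2021 LKR, and
a willingness-to-pay threshold of one GDP per capita (LKR 758,680).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .distributions import DistributionSpec
from .states import CostClock, EfficacyMode, HealthState

__all__ = [
    "ParameterValidationError",
    "PiecewiseMonthlyProbability",
    "LifeTable",
    "EfficacySpec",
    "StateCostSchedule",
    "UtilitySet",
    "StrategySpec",
    "SharedTransitions",
    "ParameterSet",
    "STRATEGY_IDS",
    "base_values",
    "base_distribution_specs",
    "build_parameter_set",
    "builtin_base_case",
    "validate_parameter_set",
]

STRATEGY_IDS = ("S1", "S2", "S3", "S4", "S5")

STRATEGY_LABELS = {
    "S1": "Neoadjuvant TC + adjuvant T (comparator)",
    "S2": "Neoadjuvant PTC + adjuvant T",
    "S3": "Neoadjuvant LTC + adjuvant T",
    "S4": "Neoadjuvant PTC + adjuvant PT",
    "S5": "Neoadjuvant LTC + adjuvant LT",
}

#: Tunnel bookkeeping cap: months-in-state beyond this share the last bucket.
TENURE_CAP_MONTHS = 121


class ParameterValidationError(ValueError):
    """A parameter set failed validation; the message names the offending key."""


# ---------------------------------------------------------------------------
# structured value types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiecewiseMonthlyProbability:
    """Piecewise-constant per-cycle probability over model months.

    ``pieces`` is an ordered tuple of ``(start_month, end_month, probability)``
    with ``end_month`` ``None`` on the final, open-ended piece.
    """

    pieces: tuple[tuple[int, int | None, float], ...]

    def at(self, month: int) -> float:
        for start, end, p in self.pieces:
            if start <= month and (end is None or month < end):
                return p
        raise ValueError(f"month {month} outside schedule domain")

    def validate(self, name: str, horizon_months: int) -> None:
        expected_start = 0
        for start, end, p in self.pieces:
            if start != expected_start:
                raise ParameterValidationError(
                    f"{name}: pieces must be contiguous from month 0 "
                    f"(gap/overlap at month {start})"
                )
            if not 0.0 <= p <= 1.0:
                raise ParameterValidationError(
                    f"{name}: probability {p} outside [0, 1] in piece starting {start}"
                )
            if end is None:
                return
            if end <= start:
                raise ParameterValidationError(f"{name}: empty piece [{start}, {end})")
            expected_start = end
        if expected_start < horizon_months:
            raise ParameterValidationError(
                f"{name}: schedule ends at month {expected_start}, "
                f"before the horizon {horizon_months}"
            )


@dataclass(frozen=True)
class LifeTable:
    """Age-banded monthly all-cause death probabilities (general population).

    ``bands`` are ``(age_low, age_high, monthly_death_probability)`` with the
    final band open-ended (``age_high`` ``None``).
    """

    bands: tuple[tuple[float, float | None, float], ...]

    def monthly_death_probability(self, age_years: float) -> float:
        for lo, hi, p in self.bands:
            if lo <= age_years and (hi is None or age_years < hi):
                return p
        raise ValueError(f"age {age_years} below the life table's first band")

    def validate(self, start_age: float, monotone: bool = True) -> None:
        """Structural checks; ``monotone=False`` skips the age-monotonicity
        plausibility check (sampled or perturbed tables may overshoot it)."""
        if not self.bands:
            raise ParameterValidationError("life_table required")
        if self.bands[0][0] > start_age:
            raise ParameterValidationError(
                f"life_table: first band starts at {self.bands[0][0]}, "
                f"above the cohort start age {start_age}"
            )
        prev_hi, prev_p = None, 0.0
        for lo, hi, p in self.bands:
            if prev_hi is not None and lo != prev_hi:
                raise ParameterValidationError(
                    f"life_table: bands not contiguous at age {lo}"
                )
            if not 0.0 <= p <= 1.0:
                raise ParameterValidationError(
                    f"life_table: probability {p} outside [0, 1] in band {lo}-{hi}"
                )
            if monotone and p < prev_p:
                raise ParameterValidationError(
                    f"life_table: probability decreases with age at band {lo}-{hi}"
                )
            prev_hi, prev_p = hi, p
        if prev_hi is not None:
            raise ParameterValidationError("life_table: last band must be open-ended")


@dataclass(frozen=True)
class EfficacySpec:
    """Hazard ratio of an intervention versus the comparator, with its 95% CI
    and the maximum duration of the treatment effect (12 years by default)."""

    hr_point: float
    ci_low: float
    ci_high: float
    effect_duration_months: int = 144

    def validate(self, name: str) -> None:
        if not 0.0 < self.ci_low <= self.hr_point <= self.ci_high:
            raise ParameterValidationError(
                f"{name}: require 0 < ci_low <= hr <= ci_high, got "
                f"{self.ci_low}, {self.hr_point}, {self.ci_high}"
            )
        if self.effect_duration_months <= 0:
            raise ParameterValidationError(f"{name}: effect duration must be positive")


@dataclass(frozen=True)
class StateCostSchedule:
    """Per-cycle direct medical / non-medical costs for one health state.

    ``pieces`` are ``(start_month, end_month, monthly_dmc, monthly_dnmc)`` in
    LKR per cycle, indexed on the schedule's ``clock``.
    """

    state: HealthState
    clock: CostClock
    pieces: tuple[tuple[int, int | None, float, float], ...]

    def monthly_cost(self, month: int, societal: bool) -> float:
        for start, end, dmc, dnmc in self.pieces:
            if start <= month and (end is None or month < end):
                return dmc + dnmc if societal else dmc
        raise ValueError(f"month {month} outside cost schedule domain")

    def validate(self, name: str) -> None:
        expected = 0
        for start, end, dmc, dnmc in self.pieces:
            if start != expected:
                raise ParameterValidationError(
                    f"{name}: cost pieces not contiguous at month {start}"
                )
            if dmc < 0 or dnmc < 0:
                raise ParameterValidationError(
                    f"{name}: negative cost in piece starting {start}"
                )
            if end is None:
                if self.state is HealthState.DEAD and (dmc or dnmc):
                    raise ParameterValidationError(f"{name}: DEAD must have zero cost")
                return
            expected = end
        raise ParameterValidationError(f"{name}: last cost piece must be open-ended")


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights; event-free is split at one model-year."""

    ef_year1: float
    ef_after_year1: float
    lrr: float
    remission: float
    metastasis: float
    dead: float = 0.0

    def validate(self) -> None:
        for key in ("ef_year1", "ef_after_year1", "lrr", "remission", "metastasis"):
            u = getattr(self, key)
            if not 0.0 <= u <= 1.0:
                raise ParameterValidationError(f"util.{key}: {u} outside [0, 1]")
        if self.dead != 0.0:
            raise ParameterValidationError("util.dead must be 0")


@dataclass(frozen=True)
class StrategySpec:
    """One neoadjuvant/adjuvant treatment strategy.

    ``trial_baseline_months`` marks how long the baseline event schedule is
    trial-derived for this strategy (used by the TRIAL_THEN_HR efficacy
    composition); the comparator has no efficacy modifier.
    """

    id: str
    label: str
    neoadjuvant_dmc: float
    neoadjuvant_dnmc: float
    ef_event_baseline: PiecewiseMonthlyProbability
    efficacy: EfficacySpec | None
    ef_year1_monthly_dmc: float
    trial_baseline_months: int = 0

    def validate(self, horizon_months: int) -> None:
        if self.neoadjuvant_dmc < 0 or self.neoadjuvant_dnmc < 0:
            raise ParameterValidationError(f"{self.id}: negative neoadjuvant cost")
        if self.ef_year1_monthly_dmc < 0:
            raise ParameterValidationError(f"{self.id}: negative EF year-1 cost")
        self.ef_event_baseline.validate(f"{self.id}.ef_event_baseline", horizon_months)
        if self.efficacy is not None:
            self.efficacy.validate(f"{self.id}.efficacy")


@dataclass(frozen=True)
class SharedTransitions:
    """Transition probabilities shared by all strategies."""

    p_event_split_lrr: float
    p_event_split_met: float
    p_lrr_to_met: float
    p_lrr_to_death: float
    p_lrr_to_rem: float
    p_rem_to_met: float
    p_met_to_death: float

    def validate(self) -> None:
        for key in (
            "p_event_split_lrr",
            "p_event_split_met",
            "p_lrr_to_met",
            "p_lrr_to_death",
            "p_lrr_to_rem",
            "p_rem_to_met",
            "p_met_to_death",
        ):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ParameterValidationError(f"shared.{key}: {v} outside [0, 1]")
        if abs(self.p_event_split_lrr + self.p_event_split_met - 1.0) > 1e-9:
            raise ParameterValidationError(
                "shared.p_event_split_lrr + p_event_split_met must sum to 1"
            )
        exits = self.p_lrr_to_met + self.p_lrr_to_death + self.p_lrr_to_rem
        if exits > 1.0 + 1e-9:
            raise ParameterValidationError(
                f"shared: locoregional exit probabilities sum to {exits} > 1"
            )


@dataclass(frozen=True)
class ParameterSet:
    """The complete model configuration.

    The structured fields (``strategies``, ``life_table``, ``utilities``,
    ``cost_schedules``, ``shared``) are derived from the canonical flat
    ``values`` mapping by :func:`build_parameter_set`; ``distribution_specs``
    assigns a sampling distribution to every uncertain value by name.
    """

    values: Mapping[str, float]
    distribution_specs: Mapping[str, DistributionSpec]
    strategies: tuple[StrategySpec, ...]
    shared: SharedTransitions
    life_table: LifeTable
    utilities: UtilitySet
    cost_schedules: Mapping[str, Mapping[HealthState, StateCostSchedule]]
    start_age_years: float = 50.0
    horizon_age_years: float = 100.0
    cycle_months: int = 1
    discount_rate_costs: float = 0.03
    discount_rate_outcomes: float = 0.03
    wtp_lkr: float = 758_680.0
    lkr_per_usd: float = 194.78
    efficacy_mode: EfficacyMode = EfficacyMode.HR_ON_BASELINE
    tenure_cap_months: int = TENURE_CAP_MONTHS

    @property
    def horizon_months(self) -> int:
        return int(round((self.horizon_age_years - self.start_age_years) * 12))

    def strategy(self, strategy_id: str) -> StrategySpec:
        for s in self.strategies:
            if s.id == strategy_id:
                return s
        raise KeyError(f"unknown strategy {strategy_id!r}")

    def with_values(
        self, updates: Mapping[str, float], validate: bool | str = True
    ) -> "ParameterSet":
        """A new parameter set with some canonical values replaced.

        ``validate="structural"`` skips plausibility checks that a one-way
        perturbation may deliberately break (life-table monotonicity).
        """
        new_values = dict(self.values)
        for key, v in updates.items():
            if key not in new_values:
                raise KeyError(f"unknown parameter name {key!r}")
            new_values[key] = float(v)
        return build_parameter_set(
            new_values,
            validate=validate,
            distribution_specs=self.distribution_specs,
            start_age_years=self.start_age_years,
            horizon_age_years=self.horizon_age_years,
            discount_rate_costs=self.discount_rate_costs,
            discount_rate_outcomes=self.discount_rate_outcomes,
            wtp_lkr=self.wtp_lkr,
            lkr_per_usd=self.lkr_per_usd,
            efficacy_mode=self.efficacy_mode,
        )


# ---------------------------------------------------------------------------
# canonical base-case registry
# ---------------------------------------------------------------------------

# (value, family, se) or (value, "lognormal", (ci_low, ci_high)); "fixed" -> se None
_BASE_TABLE: dict[str, tuple] = {
    # event-free -> event, per cycle
    "tp.ef_event.adjuvant_t": (0.01015, "beta", 0.00102),
    "tp.ef_event.s4.year1": (0.00118, "beta", 0.00012),
    "tp.ef_event.s4.year2": (0.00229, "beta", 0.00023),
    "tp.ef_event.s4.year3": (0.00220, "beta", 0.00022),
    "tp.ef_event.s4.year4": (0.00220, "beta", 0.00022),
    "tp.ef_event.s5": (0.00798, "beta", 0.00080),
    "tp.ef_event.after_60m": (0.01015, "beta", 0.00102),
    # event split and downstream transitions
    "tp.event_split_lrr": (0.25, "beta", 0.025),
    "tp.lrr_to_met": (0.02317, "beta", 0.00232),
    "tp.lrr_to_death": (0.01064, "beta", 0.00106),
    "tp.lrr_to_rem": (0.96619, "beta", 0.09662),
    "tp.rem_to_met": (0.0076, "beta", 0.00076),
    "tp.met_to_death": (0.04672, "beta", 0.00467),
    # general-population monthly mortality by age band
    "mort.age_50_54": (0.00027, "beta", 0.00003),
    "mort.age_55_59": (0.00041, "beta", 0.00004),
    "mort.age_60_64": (0.00067, "beta", 0.00007),
    "mort.age_65_69": (0.00120, "beta", 0.00012),
    "mort.age_70_74": (0.00226, "beta", 0.00023),
    "mort.age_75_79": (0.00379, "beta", 0.00038),
    "mort.age_80_84": (0.00708, "beta", 0.00071),
    "mort.age_85_plus": (0.00708, "beta", 0.00071),
    # hazard ratios vs the comparator (point, 95% CI)
    "hr.s2": (0.54, "lognormal", (0.32, 0.91)),
    "hr.s3": (0.85, "lognormal", (0.60, 1.22)),
    "hr.s4": (0.54, "lognormal", (0.32, 0.91)),
    "hr.s5": (0.85, "lognormal", (0.60, 1.22)),
    # utilities
    "util.ef_year1": (0.81, "beta", 0.0183),
    "util.ef_after_year1": (0.85, "beta", 0.0102),
    "util.lrr": (0.72, "beta", 0.0198),
    "util.remission": (0.82, "beta", 0.0174),
    "util.metastasis": (0.70, "beta", 0.0266),
    # direct medical costs (LKR)
    "cost.neoadj_dmc.s1": (403_337.46, "gamma", 40_333.75),
    "cost.neoadj_dmc.s2": (2_591_980.99, "gamma", 259_198.10),
    "cost.neoadj_dmc.s3": (712_164.10, "gamma", 71_216.41),
    "cost.neoadj_dmc.s4": (2_591_980.99, "gamma", 259_198.10),
    "cost.neoadj_dmc.s5": (712_164.10, "gamma", 71_216.41),
    "cost.ef_dmc_y1.s1": (66_740.23, "gamma", 6_674.02),
    "cost.ef_dmc_y1.s2": (66_819.49, "gamma", 6_681.95),
    "cost.ef_dmc_y1.s3": (66_740.23, "gamma", 6_674.02),
    "cost.ef_dmc_y1.s4": (576_956.06, "gamma", 57_695.61),
    "cost.ef_dmc_y1.s5": (157_203.06, "gamma", 15_720.31),
    "cost.ef_dmc_y2_5": (1_097.03, "gamma", 109.70),
    "cost.ef_dmc_y6_10": (876.94, "gamma", 87.69),
    "cost.ef_dmc_gt10": (404.15, "gamma", 40.42),
    "cost.lrr_dmc_y1": (307_205.83, "gamma", 30_720.58),
    "cost.lrr_dmc_later": (263_124.47, "gamma", 26_312.44),
    "cost.rem_dmc_y1": (67_429.98, "gamma", 6_743.00),
    "cost.rem_dmc_y2_5": (742.72, "gamma", 74.27),
    "cost.rem_dmc_y6_10": (1_137.50, "gamma", 113.75),
    "cost.rem_dmc_gt10": (664.71, "gamma", 66.47),
    "cost.met_dmc": (111_356.35, "gamma", 11_135.63),
    # direct non-medical costs (LKR)
    "cost.neoadj_dnmc": (61_575.58, "gamma", 6_157.56),
    "cost.ef_dnmc_y1": (9_045.57, "gamma", 904.56),
    "cost.ef_dnmc_later": (1_768.42, "gamma", 176.84),
    "cost.lrr_dnmc": (103_098.78, "gamma", 10_309.88),
    "cost.rem_dnmc_y1": (6_189.48, "gamma", 618.95),
    "cost.rem_dnmc_later": (1_768.42, "gamma", 176.84),
    "cost.met_dnmc": (9_172.73, "gamma", 917.27),
}

_MORT_BANDS: tuple[tuple[str, float, float | None], ...] = (
    ("mort.age_50_54", 50, 55),
    ("mort.age_55_59", 55, 60),
    ("mort.age_60_64", 60, 65),
    ("mort.age_65_69", 65, 70),
    ("mort.age_70_74", 70, 75),
    ("mort.age_75_79", 75, 80),
    ("mort.age_80_84", 80, 85),
    ("mort.age_85_plus", 85, None),
)


LRR_EXIT_NAMES = ("tp.lrr_to_met", "tp.lrr_to_death", "tp.lrr_to_rem")


def repair_lrr_simplex(values: dict) -> bool:
    """Scale the locoregional exit probabilities onto the simplex in place.

    Returns True when a repair was needed (the row's base-case values sum to
    exactly 1, so independent sampling or one-way perturbation of a single
    exit overshoots it about half the time).
    """
    total = sum(values[name] for name in LRR_EXIT_NAMES)
    if total <= 1.0:
        return False
    for name in LRR_EXIT_NAMES:
        values[name] /= total
    return True


def base_values() -> dict[str, float]:
    """The flat canonical parameter values of the packaged base case."""
    return {name: row[0] for name, row in _BASE_TABLE.items()}


def base_distribution_specs() -> dict[str, DistributionSpec]:
    """Sampling distributions assigned to every uncertain base-case value."""
    specs = {}
    for name, (mean, family, extra) in _BASE_TABLE.items():
        if family == "lognormal":
            lo, hi = extra
            specs[name] = DistributionSpec("lognormal", mean, ci_low=lo, ci_high=hi)
        else:
            specs[name] = DistributionSpec(family, mean, se=extra)
    return specs


_REQUIRED_GROUPS = {
    "life_table required": tuple(name for name, _, _ in _MORT_BANDS),
    "utilities required": (
        "util.ef_year1",
        "util.ef_after_year1",
        "util.lrr",
        "util.remission",
        "util.metastasis",
    ),
}


def _get(values: Mapping[str, float], key: str) -> float:
    try:
        return float(values[key])
    except KeyError:
        for msg, names in _REQUIRED_GROUPS.items():
            if key in names:
                raise ParameterValidationError(msg) from None
        raise ParameterValidationError(f"missing parameter {key!r}") from None


def _baseline(values: Mapping[str, float], strategy_id: str) -> PiecewiseMonthlyProbability:
    after = _get(values, "tp.ef_event.after_60m")
    if strategy_id in ("S1", "S2", "S3"):
        first = _get(values, "tp.ef_event.adjuvant_t")
        return PiecewiseMonthlyProbability(((0, 60, first), (60, None, after)))
    if strategy_id == "S4":
        return PiecewiseMonthlyProbability(
            (
                (0, 12, _get(values, "tp.ef_event.s4.year1")),
                (12, 24, _get(values, "tp.ef_event.s4.year2")),
                (24, 36, _get(values, "tp.ef_event.s4.year3")),
                (36, 60, _get(values, "tp.ef_event.s4.year4")),
                (60, None, after),
            )
        )
    return PiecewiseMonthlyProbability(
        ((0, 60, _get(values, "tp.ef_event.s5")), (60, None, after))
    )


def _cost_schedules(
    values: Mapping[str, float], strategy_id: str
) -> dict[HealthState, StateCostSchedule]:
    v = lambda k: _get(values, k)  # noqa: E731
    sl = strategy_id.lower()
    ef = StateCostSchedule(
        HealthState.EVENT_FREE,
        CostClock.MODEL_TIME,
        (
            (0, 12, v(f"cost.ef_dmc_y1.{sl}"), v("cost.ef_dnmc_y1")),
            (12, 60, v("cost.ef_dmc_y2_5"), v("cost.ef_dnmc_later")),
            (60, 120, v("cost.ef_dmc_y6_10"), v("cost.ef_dnmc_later")),
            (120, None, v("cost.ef_dmc_gt10"), v("cost.ef_dnmc_later")),
        ),
    )
    lrr = StateCostSchedule(
        HealthState.LOCOREGIONAL,
        CostClock.TIME_IN_STATE,
        (
            (0, 12, v("cost.lrr_dmc_y1"), v("cost.lrr_dnmc")),
            (12, None, v("cost.lrr_dmc_later"), v("cost.lrr_dnmc")),
        ),
    )
    rem = StateCostSchedule(
        HealthState.REMISSION,
        CostClock.TIME_IN_STATE,
        (
            (0, 12, v("cost.rem_dmc_y1"), v("cost.rem_dnmc_y1")),
            (12, 60, v("cost.rem_dmc_y2_5"), v("cost.rem_dnmc_later")),
            (60, 120, v("cost.rem_dmc_y6_10"), v("cost.rem_dnmc_later")),
            (120, None, v("cost.rem_dmc_gt10"), v("cost.rem_dnmc_later")),
        ),
    )
    met = StateCostSchedule(
        HealthState.METASTASIS,
        CostClock.MODEL_TIME,
        ((0, None, v("cost.met_dmc"), v("cost.met_dnmc")),),
    )
    dead = StateCostSchedule(
        HealthState.DEAD, CostClock.MODEL_TIME, ((0, None, 0.0, 0.0),)
    )
    return {s.state: s for s in (ef, lrr, rem, met, dead)}


def build_parameter_set(
    values: Mapping[str, float],
    *,
    distribution_specs: Mapping[str, DistributionSpec] | None = None,
    start_age_years: float = 50.0,
    horizon_age_years: float = 100.0,
    discount_rate_costs: float = 0.03,
    discount_rate_outcomes: float = 0.03,
    wtp_lkr: float = 758_680.0,
    lkr_per_usd: float = 194.78,
    efficacy_mode: EfficacyMode = EfficacyMode.HR_ON_BASELINE,
    validate: bool | str = True,
) -> ParameterSet:
    """Assemble a structured :class:`ParameterSet` from canonical flat values.

    ``validate`` may be ``True`` (all invariants), ``"structural"`` (skip
    plausibility-only checks, used for sampled/perturbed sets) or ``False``.
    """
    values = {k: float(v) for k, v in values.items()}
    specs = dict(distribution_specs) if distribution_specs is not None else {
        name: DistributionSpec("fixed", values[name]) for name in values
    }

    hr_ci = {
        name: (
            (specs[name].ci_low, specs[name].ci_high)
            if name in specs and specs[name].family == "lognormal"
            else (values[name], values[name])
        )
        for name in ("hr.s2", "hr.s3", "hr.s4", "hr.s5")
        if name in values
    }

    strategies = []
    for sid in STRATEGY_IDS:
        sl = sid.lower()
        if sid == "S1":
            eff = None
        else:
            hr = _get(values, f"hr.{sl}")
            lo, hi = hr_ci.get(f"hr.{sl}", (hr, hr))
            eff = EfficacySpec(hr, min(lo, hr), max(hi, hr))
        strategies.append(
            StrategySpec(
                id=sid,
                label=STRATEGY_LABELS[sid],
                neoadjuvant_dmc=_get(values, f"cost.neoadj_dmc.{sl}"),
                neoadjuvant_dnmc=_get(values, "cost.neoadj_dnmc"),
                ef_event_baseline=_baseline(values, sid),
                efficacy=eff,
                ef_year1_monthly_dmc=_get(values, f"cost.ef_dmc_y1.{sl}"),
                trial_baseline_months=60 if sid in ("S4", "S5") else 0,
            )
        )

    split_lrr = _get(values, "tp.event_split_lrr")
    shared = SharedTransitions(
        p_event_split_lrr=split_lrr,
        p_event_split_met=1.0 - split_lrr,
        p_lrr_to_met=_get(values, "tp.lrr_to_met"),
        p_lrr_to_death=_get(values, "tp.lrr_to_death"),
        p_lrr_to_rem=_get(values, "tp.lrr_to_rem"),
        p_rem_to_met=_get(values, "tp.rem_to_met"),
        p_met_to_death=_get(values, "tp.met_to_death"),
    )
    life_table = LifeTable(
        tuple((lo, hi, _get(values, name)) for name, lo, hi in _MORT_BANDS)
    )
    utilities = UtilitySet(
        ef_year1=_get(values, "util.ef_year1"),
        ef_after_year1=_get(values, "util.ef_after_year1"),
        lrr=_get(values, "util.lrr"),
        remission=_get(values, "util.remission"),
        metastasis=_get(values, "util.metastasis"),
    )
    cost_schedules = {sid: _cost_schedules(values, sid) for sid in STRATEGY_IDS}

    ps = ParameterSet(
        values=values,
        distribution_specs=specs,
        strategies=tuple(strategies),
        shared=shared,
        life_table=life_table,
        utilities=utilities,
        cost_schedules=cost_schedules,
        start_age_years=start_age_years,
        horizon_age_years=horizon_age_years,
        discount_rate_costs=discount_rate_costs,
        discount_rate_outcomes=discount_rate_outcomes,
        wtp_lkr=wtp_lkr,
        lkr_per_usd=lkr_per_usd,
        efficacy_mode=EfficacyMode(efficacy_mode),
    )
    if validate:
        validate_parameter_set(ps, strict=validate is True)
    return ps


def builtin_base_case(
    *, efficacy_mode: EfficacyMode = EfficacyMode.HR_ON_BASELINE
) -> ParameterSet:
    """The packaged base-case parameter set (every published input value)."""
    return build_parameter_set(
        base_values(),
        distribution_specs=base_distribution_specs(),
        efficacy_mode=efficacy_mode,
    )


def validate_parameter_set(ps: ParameterSet, strict: bool = True) -> None:
    """Check every structural invariant; raise ParameterValidationError naming
    the offending key otherwise. ``strict=False`` skips plausibility-only
    checks (life-table age monotonicity) for sampled or perturbed sets."""
    if ps.horizon_age_years <= ps.start_age_years:
        raise ParameterValidationError("horizon_age_years must exceed start_age_years")
    if ps.cycle_months != 1:
        raise ParameterValidationError("cycle_months must be 1 (monthly cycles)")
    for rate_name in ("discount_rate_costs", "discount_rate_outcomes"):
        if getattr(ps, rate_name) < 0:
            raise ParameterValidationError(f"{rate_name} must be >= 0")
    if len(ps.strategies) != len(STRATEGY_IDS):
        raise ParameterValidationError(f"expected {len(STRATEGY_IDS)} strategies")
    if ps.strategies[0].efficacy is not None:
        raise ParameterValidationError("S1 (comparator) must have no efficacy modifier")
    horizon = ps.horizon_months
    for strat in ps.strategies:
        strat.validate(horizon)
    ps.shared.validate()
    ps.life_table.validate(ps.start_age_years, monotone=strict)
    ps.utilities.validate()
    for sid, schedules in ps.cost_schedules.items():
        for state in HealthState:
            if state not in schedules:
                raise ParameterValidationError(f"{sid}: missing cost schedule for {state.name}")
            schedules[state].validate(f"{sid}.cost.{state.name}")
    for name in ps.values:
        if name not in ps.distribution_specs:
            raise ParameterValidationError(
                f"parameter {name!r} has no distribution spec"
            )
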