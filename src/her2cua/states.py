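"""Enumerations shared across the model: health states, perspectives, modes."""

from __future__ import annotations

import enum


class HealthState(enum.IntEnum):
    """The five health states of the cohort model.

    ``DEAD`` is absorbing; the cohort starts entirely in ``EVENT_FREE``.
    """

    EVENT_FREE = 0
    LOCOREGIONAL = 1
    METASTASIS = 2
    REMISSION = 3
    DEAD = 4


#: States in which the cohort accrues life-years.
ALIVE_STATES = (
    HealthState.EVENT_FREE,
    HealthState.LOCOREGIONAL,
    HealthState.METASTASIS,
    HealthState.REMISSION,
)


class Perspective(str, enum.Enum):
    """Costing perspective: public healthcare system (direct medical costs
    only) or societal (direct medical plus direct non-medical costs)."""

    PUBLIC = "public"
    SOCIETAL = "societal"


class CostClock(str, enum.Enum):
    """Which clock a state-cost schedule follows.

    ``MODEL_TIME`` pieces are indexed by months since model entry;
    ``TIME_IN_STATE`` pieces by months since the current state was entered
    (tunnel bookkeeping).
    """

    MODEL_TIME = "model_time"
    TIME_IN_STATE = "time_in_state"


class EfficacyMode(str, enum.Enum):
    """How a strategy's hazard ratio is composed with its baseline
    event-free -> event schedule during the treatment-effect window.

    HR_ON_BASELINE
        The hazard ratio rescales the strategy's own baseline probability for
        every cycle inside the effect window (the default; see
        docs/methods.md for the calibration rationale).
    TRIAL_THEN_HR
        Strategies whose baseline schedule is trial-derived use it unscaled
        for its duration, then the hazard ratio applies to the shared
        post-trial baseline until the window closes.
    BASELINE_ONLY
        Hazard ratios are ignored; each strategy runs on its raw baseline.
    """

    HR_ON_BASELINE = "hr_on_baseline"
    TRIAL_THEN_HR = "trial_then_hr"
    BASELINE_ONLY = "baseline_only"


class Dominance(str, enum.Enum):
    """Dominance status of a strategy in the incremental analysis."""

    NONE = "none"
    DOMINATED = "dominated"
    EXTENDEDLY_DOMINATED = "extendedly_dominated"
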