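"""Parameter containers for the diagnostic-strategy model.

Two strategies for diagnosing hemodynamically significant coronary artery
disease (CAD) are compared:

* strategy 1 — perfusion cardiovascular magnetic resonance (CMR) first, with
  invasive coronary angiography (CXA) in ischemia-positive patients;
* strategy 2 — CXA in every patient, with fractional flow reserve (FFR)
  measurement in patients showing a >=50% diameter stenosis.

The containers here hold the test-performance probabilities, the payer-side
fee schedule, and the cohort description that the closed-form model and the
microsimulation both consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

from .errors import DomainError

__all__ = [
    "TestPerformance",
    "CostSchedule",
    "CohortScenario",
    "StrategyOutcome",
    "validate_probability",
]

_PROBABILITY_FIELDS = frozenset(
    {"sn_cmr", "sp_cmr", "ndx", "sn_cxa", "sp_cxa", "sn_ffr", "sp_ffr", "r_cxa", "r_f"}
)


def validate_probability(value: float, name: str = "probability") -> float:
    """Return ``value`` if it is a finite number in [0, 1], else raise DomainError."""
    try:
        x = float(value)
    except (TypeError, ValueError) as exc:
        raise DomainError(f"{name} must be a number, got {value!r}") from exc
    if not math.isfinite(x) or not 0.0 <= x <= 1.0:
        raise DomainError(f"{name} must lie in [0, 1], got {value!r}")
    return x


@dataclass(frozen=True)
class TestPerformance:
    """Diagnostic-test performance parameters.

    Defaults are the literature values used throughout: per-patient CMR
    sensitivity/specificity against an FFR <= 0.75 ischemia reference
    (0.88 / 0.90), a 5% non-diagnostic CMR rate, perfect accuracy for the
    invasive reference tests (CXA, FFR), a 0.05% major-complication rate per
    invasive CXA procedure, and a 15% complication rate per 10-year follow-up
    in false-negative (missed) CAD patients.
    """

    sn_cmr: float = 0.88
    sp_cmr: float = 0.90
    ndx: float = 0.05
    sn_cxa: float = 1.0
    sp_cxa: float = 1.0
    sn_ffr: float = 1.0
    sp_ffr: float = 1.0
    r_cxa: float = 0.0005
    r_f: float = 0.15

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name in _PROBABILITY_FIELDS:
                validate_probability(getattr(self, f.name), f.name)

    def replace(self, **changes: float) -> "TestPerformance":
        return replace(self, **changes)


@dataclass(frozen=True)
class CostSchedule:
    """Third-party-payer fee schedule for one health-care system.

    ``f_ffr`` is the incremental fee of an FFR measurement on top of the CXA
    it is performed during.  ``c_complication`` is the cost of one major
    complication (a myocardial infarction: PCI, one week in hospital, four
    weeks of rehabilitation); it prices both procedure-related events and
    late events in false-negative patients.  Future false-negative
    complication costs are discounted annually (default 3%) over the
    follow-up horizon (default 10 years).
    """

    f_cmr: float
    f_cxa_outpatient: float
    f_cxa_inpatient: float
    f_ffr: float
    c_complication: float
    discount_rate: float = 0.03
    horizon_years: int = 10
    currency: str = "XXX"
    cxa_setting: str = "outpatient"

    def __post_init__(self) -> None:
        for name in ("f_cmr", "f_cxa_outpatient", "f_cxa_inpatient", "f_ffr", "c_complication"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise DomainError(f"{name} must be a non-negative finite amount, got {v!r}")
        if not 0.0 <= self.discount_rate < 1.0:
            raise DomainError(f"discount_rate must lie in [0, 1), got {self.discount_rate!r}")
        if not (isinstance(self.horizon_years, int) and self.horizon_years >= 1):
            raise DomainError(f"horizon_years must be an integer >= 1, got {self.horizon_years!r}")
        if self.cxa_setting not in ("outpatient", "inpatient"):
            raise DomainError(
                f"cxa_setting must be 'outpatient' or 'inpatient', got {self.cxa_setting!r}"
            )

    @property
    def f_cxa(self) -> float:
        """Active CXA fee selected by ``cxa_setting``."""
        return self.f_cxa_outpatient if self.cxa_setting == "outpatient" else self.f_cxa_inpatient

    def replace(self, **changes) -> "CostSchedule":
        return replace(self, **changes)


@dataclass(frozen=True)
class CohortScenario:
    """A hypothetical cohort: pre-test likelihood of significant CAD and its size.

    ``n_patients`` only matters to the microsimulation; the closed forms are
    per patient tested.
    """

    p_isch: float
    n_patients: int = 1

    def __post_init__(self) -> None:
        validate_probability(self.p_isch, "p_isch")
        if not (isinstance(self.n_patients, int) and self.n_patients >= 1):
            raise DomainError(f"n_patients must be an integer >= 1, got {self.n_patients!r}")


@dataclass(frozen=True)
class StrategyOutcome:
    """Effectiveness, expected cost and cost-effectiveness ratio of one strategy.

    Effectiveness is the expected fraction of patients tested who are
    correctly identified as having significant CAD (with full anatomical
    information).  The cost-effectiveness ratio is cost per patient correctly
    diagnosed; it is undefined when effectiveness is zero, in which case
    ``ce_ratio`` is NaN and ``ce_defined`` is False.
    """

    effectiveness: float
    expected_cost: float
    ce_ratio: float = field(default=math.nan)
    ce_defined: bool = field(default=True)

    @classmethod
    def from_cost_and_effect(cls, effectiveness: float, expected_cost: float) -> "StrategyOutcome":
        if effectiveness > 0.0:
            return cls(effectiveness, expected_cost, expected_cost / effectiveness, True)
        return cls(effectiveness, expected_cost, math.nan, False)
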