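"""Closed-form per-patient effectiveness and cost equations for both strategies.

The model is an expectation over the diagnostic decision tree, driven by
Bayes' theorem: a cohort with pre-test likelihood ``p_isch`` of significant
CAD is pushed through each strategy and the expected fraction of correct
positive diagnoses (effectiveness) and the expected third-party-payer cost
per patient tested are accumulated over the tree's leaves.

Strategy 1 (CMR + CXA)
    Every patient has a perfusion-CMR (fee ``f_cmr``).  A fraction ``ndx`` of
    examinations is non-diagnostic; those patients cross over to strategy 2
    (CXA in all, FFR if stenosed) and are diagnosed with reference accuracy.
    Among diagnostic examinations, ischemic patients test positive with
    probability ``sn_cmr`` and non-ischemic patients with ``1 - sp_cmr``;
    every CMR-positive patient undergoes a CXA (fee, plus a major
    procedure complication with probability ``r_cxa`` costing
    ``c_complication``).  False negatives are managed as disease-free and
    face a complication risk ``r_f`` over the follow-up horizon; that future
    cost is discounted to present value.
Strategy 2 (CXA + FFR)
    Every patient has a CXA; patients with a >=50% stenosis (a fraction
    ``apply_link(link, p_isch)`` of the cohort) additionally have an FFR.
    The invasive tests are the reference, so effectiveness is ``p_isch``
    exactly and there are no false-negative costs.

The cost-effectiveness ratio of a strategy is its expected cost per patient
tested divided by its effectiveness: cost per patient correctly diagnosed.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .errors import ConfigurationError
from .link import StenosisLink
from .params import CostSchedule, StrategyOutcome, TestPerformance, validate_probability

__all__ = [
    "strategy1_effectiveness",
    "strategy2_effectiveness",
    "discounted_fn_complication_cost",
    "strategy1_expected_cost",
    "strategy2_expected_cost",
    "strategy1_cost_components",
    "evaluate_strategies",
]


def strategy1_effectiveness(p_isch: float, perf: TestPerformance) -> float:
    """Expected fraction correctly diagnosed as significant CAD under CMR + CXA.

    Diseased patients are found either through a diagnostic, true-positive
    CMR (probability ``(1 - ndx) * sn_cmr``) or through the non-diagnostic
    cross-over to the invasive reference (probability ``ndx``, accuracy 1):

        p_isch * (sn_cmr * (1 - ndx) + ndx)
    """
    p = validate_probability(p_isch, "p_isch")
    return p * (perf.sn_cmr * (1.0 - perf.ndx) + perf.ndx)


def strategy2_effectiveness(p_isch: float) -> float:
    """Expected fraction correctly diagnosed under CXA + FFR: ``p_isch`` exactly.

    CXA and FFR are the reference tests with assumed 100% accuracy, so every
    diseased patient is detected with full anatomy.
    """
    return validate_probability(p_isch, "p_isch")


def _annuity_average(discount_rate: float, horizon_years: int) -> float:
    """Mean present-value factor of one payment uniform over years 1..horizon."""
    return sum((1.0 + discount_rate) ** -t for t in range(1, horizon_years + 1)) / horizon_years


def discounted_fn_complication_cost(costs: CostSchedule, perf: TestPerformance) -> float:
    """Expected present-value complication cost per false-negative patient.

    A missed (false-negative) CAD patient suffers a major complication with
    probability ``r_f`` over the follow-up horizon.  The event year is taken
    uniform over years 1..horizon and each year's cost is discounted
    annually, so the expectation is

        c_complication * r_f * (1/H) * sum_{t=1..H} (1 + d)^-t .

    With ``discount_rate = 0`` this reduces exactly to ``c_complication * r_f``.
    """
    return costs.c_complication * perf.r_f * _annuity_average(costs.discount_rate, costs.horizon_years)


def strategy2_expected_cost(
    p_isch: float, perf: TestPerformance, costs: CostSchedule, link: StenosisLink
) -> float:
    """Expected cost per patient tested under CXA + FFR.

    Every patient pays the active CXA fee and carries the per-procedure
    complication risk; the stenosed fraction ``apply_link(link, p_isch)``
    additionally pays the incremental FFR fee.  The reference tests make no
    diagnostic errors, so there is no false-negative term.
    """
    p = validate_probability(p_isch, "p_isch")
    if not isinstance(link, StenosisLink) or not link.is_fitted:
        raise ConfigurationError("strategy 2 requires a calibrated StenosisLink")
    return costs.f_cxa + link.transform(p) * costs.f_ffr + perf.r_cxa * costs.c_complication


def strategy1_cost_components(
    p_isch: float, perf: TestPerformance, costs: CostSchedule, link: StenosisLink
) -> Dict[str, float]:
    """Per-patient expected cost of CMR + CXA, decomposed by decision-tree branch.

    Returns a dict with keys

    ``cmr_fee``
        first-line CMR fee, paid by every patient;
    ``cxa_after_positive_cmr``
        CXA fee plus expected procedure-complication cost for the
        CMR-positive fraction (true positives and false positives alike —
        false positives incur exactly one unnecessary CXA);
    ``false_negative_complications``
        discounted expected complication cost of missed disease;
    ``crossover_to_invasive``
        full strategy-2 cost for the non-diagnostic fraction;
    ``total``
        their sum.
    """
    p = validate_probability(p_isch, "p_isch")
    diagnostic = 1.0 - perf.ndx
    p_cmr_positive = perf.sn_cmr * p + (1.0 - perf.sp_cmr) * (1.0 - p)
    p_false_negative = (1.0 - perf.sn_cmr) * p

    components = {
        "cmr_fee": costs.f_cmr,
        "cxa_after_positive_cmr": diagnostic
        * p_cmr_positive
        * (costs.f_cxa + perf.r_cxa * costs.c_complication),
        "false_negative_complications": diagnostic
        * p_false_negative
        * discounted_fn_complication_cost(costs, perf),
        "crossover_to_invasive": perf.ndx
        * strategy2_expected_cost(p, perf, costs, link),
    }
    components["total"] = sum(components.values())
    return components


def strategy1_expected_cost(
    p_isch: float, perf: TestPerformance, costs: CostSchedule, link: StenosisLink
) -> float:
    """Expected cost per patient tested under CMR + CXA (see strategy1_cost_components)."""
    return strategy1_cost_components(p_isch, perf, costs, link)["total"]


def evaluate_strategies(
    p_isch: float, perf: TestPerformance, costs: CostSchedule, link: StenosisLink
) -> Tuple[StrategyOutcome, StrategyOutcome]:
    """Effectiveness, expected cost and CE ratio for both strategies at one prevalence.

    At ``p_isch = 0`` both effectiveness values are zero and the CE ratios
    are flagged undefined (NaN) rather than raising.
    """
    p = validate_probability(p_isch, "p_isch")
    s1 = StrategyOutcome.from_cost_and_effect(
        strategy1_effectiveness(p, perf), strategy1_expected_cost(p, perf, costs, link)
    )
    s2 = StrategyOutcome.from_cost_and_effect(
        strategy2_effectiveness(p), strategy2_expected_cost(p, perf, costs, link)
    )
    return s1, s2
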