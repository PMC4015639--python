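"""Patient-level microsimulation of the two diagnostic pathways.

The closed-form model is a per-patient expectation; this module samples
individual patients with exactly the probabilities the closed forms
integrate over, so the Monte-Carlo means converge to the closed-form values.
It serves two purposes: an independent oracle for verifying the equations,
and a synthetic-data generator producing patient-level tables.

Sampling rules (single numpy Generator stream, seeded — no silent
nondeterminism):

* disease: ``ischemic ~ Bernoulli(p_isch)``; ``stenosed`` is true for every
  ischemic patient (ischemia implies a >=50% stenosis) and otherwise
  Bernoulli with the conditional probability that makes the marginal
  stenosis rate equal ``apply_link(link, p_isch)``;
* CMR (strategy 1): non-diagnostic with probability ``ndx`` independent of
  disease; otherwise positive with probability ``sn_cmr`` in ischemic and
  ``1 - sp_cmr`` in non-ischemic patients;
* each CXA carries a Bernoulli(``r_cxa``) major complication costed at test
  time; a false negative suffers a Bernoulli(``r_f``) complication whose
  year is uniform on 1..horizon and whose cost is discounted to present
  value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .link import StenosisLink
from .params import CohortScenario, CostSchedule, StrategyOutcome, TestPerformance

__all__ = ["SimulationEstimate", "simulate_cohort", "estimate_ce"]

PATIENT_COLUMNS = [
    "id",
    "ischemic",
    "stenosed",
    "cmr_result",
    "cxa_done",
    "ffr_done",
    "procedure_complication",
    "fn_complication",
    "fn_event_year",
    "cost_accrued",
    "classification",
]

_CORRECT_POSITIVE = ("TP", "crossover_TP")


@dataclass(frozen=True)
class SimulationEstimate:
    """Monte-Carlo aggregate of one simulated cohort with standard errors."""

    effectiveness_hat: float
    cost_hat: float
    se_effectiveness: float
    se_cost: float
    n: int
    seed: int


def simulate_cohort(
    scenario: CohortScenario,
    perf: TestPerformance,
    costs: CostSchedule,
    link: StenosisLink,
    strategy: int,
    seed: int,
):
    """Simulate ``scenario.n_patients`` patients through one strategy.

    Returns ``(patient_table, SimulationEstimate)`` where the table has one
    row per patient with the columns in :data:`PATIENT_COLUMNS`.  Identical
    inputs and seed give identical tables.
    """
    if strategy not in (1, 2):
        raise DomainError(f"strategy must be 1 or 2, got {strategy!r}")
    p = scenario.p_isch
    n = scenario.n_patients
    p_sten = link.transform(p)
    if p_sten < p - 1e-12:
        raise ConfigurationError(
            f"link gives stenosis prevalence {p_sten:.4g} < ischemia prevalence {p:.4g}; "
            "ischemia must imply stenosis"
        )
    rng = np.random.default_rng(seed)

    ischemic = rng.random(n) < p
    # conditional stenosis prob among non-ischemic so the marginal rate is p_sten
    q = 0.0 if p >= 1.0 else max(p_sten - p, 0.0) / (1.0 - p)
    stenosed = ischemic | (rng.random(n) < q)

    cost = np.zeros(n)
    cxa_done = np.zeros(n, dtype=bool)
    ffr_done = np.zeros(n, dtype=bool)
    proc_comp = np.zeros(n, dtype=bool)
    fn_comp = np.zeros(n, dtype=bool)
    fn_year = np.zeros(n, dtype=int)  # 0 = no event
    classification = np.empty(n, dtype=object)
    cmr_result = np.full(n, "not_done", dtype=object)

    def invasive_workup(mask: np.ndarray) -> None:
        """CXA for everyone in ``mask``, FFR if stenosed, complication per CXA."""
        cxa_done[mask] = True
        ffr_done[mask] = stenosed[mask]
        cost[mask] += costs.f_cxa + stenosed[mask] * costs.f_ffr
        comp = mask & (rng.random(n) < perf.r_cxa)
        proc_comp[comp] = True
        cost[comp] += costs.c_complication

    if strategy == 2:
        invasive_workup(np.ones(n, dtype=bool))
        classification[ischemic] = "TP"
        classification[~ischemic] = "TN"
    else:
        cost += costs.f_cmr
        nondx = rng.random(n) < perf.ndx
        u = rng.random(n)
        positive = ~nondx & np.where(ischemic, u < perf.sn_cmr, u < 1.0 - perf.sp_cmr)
        negative = ~nondx & ~positive
        cmr_result[nondx] = "nondiagnostic"
        cmr_result[positive] = "positive"
        cmr_result[negative] = "negative"

        # non-diagnostic patients cross over to the invasive reference pathway
        invasive_workup(nondx)
        classification[nondx & ischemic] = "crossover_TP"
        classification[nondx & ~ischemic] = "crossover_TN"

        # CMR-positive patients get a CXA (anatomy only; no FFR after positive CMR)
        cxa_done[positive] = True
        cost[positive] += costs.f_cxa
        comp = positive & (rng.random(n) < perf.r_cxa)
        proc_comp[comp] = True
        cost[comp] += costs.c_complication
        classification[positive & ischemic] = "TP"
        classification[positive & ~ischemic] = "FP"

        # CMR-negative: true negatives free; false negatives risk a late MI
        classification[negative & ~ischemic] = "TN"
        fn = negative & ischemic
        classification[fn] = "FN"
        event = fn & (rng.random(n) < perf.r_f)
        years = rng.integers(1, costs.horizon_years + 1, size=n)
        fn_comp[event] = True
        fn_year[event] = years[event]
        cost[event] += costs.c_complication * (1.0 + costs.discount_rate) ** -years[event]

    table = pd.DataFrame(
        {
            "id": np.arange(n),
            "ischemic": ischemic,
            "stenosed": stenosed,
            "cmr_result": cmr_result,
            "cxa_done": cxa_done,
            "ffr_done": ffr_done,
            "procedure_complication": proc_comp,
            "fn_complication": fn_comp,
            "fn_event_year": fn_year,
            "cost_accrued": cost,
            "classification": classification,
        },
        columns=PATIENT_COLUMNS,
    )

    eff_hat = float(np.isin(classification, _CORRECT_POSITIVE).mean())
    cost_hat = float(cost.mean())
    se_eff = float(np.sqrt(eff_hat * (1.0 - eff_hat) / n))
    se_cost = float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    estimate = SimulationEstimate(eff_hat, cost_hat, se_eff, se_cost, n, seed)
    return table, estimate


def estimate_ce(table: pd.DataFrame) -> StrategyOutcome:
    """Aggregate a patient table into a :class:`StrategyOutcome`.

    Effectiveness is the fraction of correct positive diagnoses (including
    cross-over true positives); cost is the mean accrued cost; the CE ratio
    is flagged undefined when there are no true positives.
    """
    if len(table) == 0:
        raise DomainError("patient table is empty")
    effectiveness = float(table["classification"].isin(_CORRECT_POSITIVE).mean())
    cost = float(table["cost_accrued"].mean())
    return StrategyOutcome.from_cost_and_effect(effectiveness, cost)
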