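"""Prevalence sweeps, crossing-point location, and one-way sensitivity analysis.

The crossing point is the pre-test likelihood at which the two strategies'
cost-effectiveness ratios (or per-patient costs) are equal; below it the
CMR-first strategy buys a correct diagnosis more cheaply, above it the
invasive-first strategy does.  Crossings are located by scanning a fine grid
for a sign change of the difference curve and refining the bracket with
Brent's method; absence of a crossing is a reported status, never an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, DomainError
from .link import StenosisLink
from .model import (
    evaluate_strategies,
    strategy1_expected_cost,
    strategy2_expected_cost,
)
from .params import CostSchedule, TestPerformance

__all__ = [
    "CrossingResult",
    "SensitivityScenario",
    "ce_curve",
    "find_ce_crossing",
    "find_cost_crossing",
    "one_way_sensitivity",
    "default_grid",
]

#: scan step before root refinement; crossings are reported to ~1e-9 but the
#: scan only needs to be finer than any plausible pair of roots
SCAN_STEP = 1e-3
#: relative tolerance on the difference curve for the degenerate-equal call
DELTA_RTOL = 1e-6
#: root localisation tolerance
ROOT_XTOL = 1e-9


def default_grid(start: float = 0.10, stop: float = 1.00, step: float = 0.01) -> np.ndarray:
    """The standard reporting grid of pre-test likelihoods (10%..100% by 1%)."""
    n = int(round((stop - start) / step)) + 1
    return np.round(np.linspace(start, stop, n), 12)


def ce_curve(
    perf: TestPerformance,
    costs: CostSchedule,
    link: StenosisLink,
    grid: Optional[Iterable[float]] = None,
) -> pd.DataFrame:
    """Evaluate both strategies on a prevalence grid.

    Returns a DataFrame with columns ``p_isch, eff1, eff2, cost1, cost2,
    cer1, cer2``; rows where effectiveness is zero carry NaN CE ratios (the
    undefined flag).
    """
    pts = default_grid() if grid is None else np.asarray(list(grid), dtype=float)
    if pts.size == 0:
        raise ConfigurationError("prevalence grid is empty")
    rows = []
    for p in pts:
        s1, s2 = evaluate_strategies(float(p), perf, costs, link)
        rows.append(
            {
                "p_isch": float(p),
                "eff1": s1.effectiveness,
                "eff2": s2.effectiveness,
                "cost1": s1.expected_cost,
                "cost2": s2.expected_cost,
                "cer1": s1.ce_ratio,
                "cer2": s2.ce_ratio,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CrossingResult:
    """Location of the prevalence at which the two strategies' curves meet.

    ``status`` is ``found`` (with ``p_star`` and the common value of the
    compared quantity at the crossing), ``none_in_domain`` (the difference
    curve never changes sign), or ``degenerate_equal`` (the curves coincide
    within tolerance over the whole domain).
    """

    status: str
    p_star: Optional[float] = None
    ce_at_crossing: Optional[float] = None
    bracket: Optional[Tuple[float, float]] = None


def _find_crossing(
    delta: Callable[[float], float],
    value_at: Callable[[float], float],
    domain: Tuple[float, float],
    scan_step: float = SCAN_STEP,
) -> CrossingResult:
    lo, hi = float(domain[0]), float(domain[1])
    if not (0.0 <= lo < hi <= 1.0):
        raise DomainError(f"crossing domain must satisfy 0 <= lo < hi <= 1, got {domain!r}")
    n = max(int(math.ceil((hi - lo) / scan_step)) + 1, 2)
    grid = np.linspace(lo, hi, n)
    values = np.array([delta(p) for p in grid])

    scale = np.nanmax(np.abs(values)) if values.size else 0.0
    finite = values[np.isfinite(values)]
    if finite.size and np.all(np.abs(finite) <= DELTA_RTOL * max(scale, 1.0)):
        return CrossingResult(status="degenerate_equal")

    sign = np.sign(values)
    sign_change = np.where(
        np.isfinite(values[:-1]) & np.isfinite(values[1:]) & (sign[:-1] * sign[1:] < 0)
    )[0]
    exact_zero = np.where(np.isfinite(values) & (values == 0.0))[0]

    roots = []
    for i in sign_change:
        a, b = float(grid[i]), float(grid[i + 1])
        root = brentq(delta, a, b, xtol=ROOT_XTOL)
        roots.append((root, (a, b)))
    for i in exact_zero:
        roots.append((float(grid[i]), (float(grid[i]), float(grid[i]))))
    if not roots:
        return CrossingResult(status="none_in_domain")
    roots.sort(key=lambda r: r[0])
    if len(roots) > 1:
        warnings.warn(
            f"{len(roots)} crossings found in {domain}; reporting the smallest",
            stacklevel=3,
        )
    p_star, bracket = roots[0]
    return CrossingResult(
        status="found", p_star=p_star, ce_at_crossing=value_at(p_star), bracket=bracket
    )


def find_ce_crossing(
    perf: TestPerformance,
    costs: CostSchedule,
    link: StenosisLink,
    domain: Tuple[float, float] = (0.01, 1.0),
) -> CrossingResult:
    """Prevalence at which the two cost-effectiveness ratios are equal.

    The domain excludes 0, where both CE ratios are undefined.
    """

    def delta(p: float) -> float:
        s1, s2 = evaluate_strategies(p, perf, costs, link)
        if not (s1.ce_defined and s2.ce_defined):
            return math.nan
        return s1.ce_ratio - s2.ce_ratio

    def value_at(p: float) -> float:
        _, s2 = evaluate_strategies(p, perf, costs, link)
        return s2.ce_ratio

    return _find_crossing(delta, value_at, domain)


def find_cost_crossing(
    perf: TestPerformance,
    costs: CostSchedule,
    link: StenosisLink,
    domain: Tuple[float, float] = (0.0, 1.0),
) -> CrossingResult:
    """Prevalence at which the two per-patient-tested expected costs are equal."""

    def delta(p: float) -> float:
        return strategy1_expected_cost(p, perf, costs, link) - strategy2_expected_cost(
            p, perf, costs, link
        )

    def value_at(p: float) -> float:
        return strategy2_expected_cost(p, perf, costs, link)

    return _find_crossing(delta, value_at, domain)


@dataclass(frozen=True)
class SensitivityScenario:
    """One-way perturbation of a single model parameter.

    ``parameter_path`` addresses a field as ``perf.<name>`` or
    ``costs.<name>`` (use ``link`` for ``swap_link``).  ``perturbation`` is
    one of ``relative_scale`` (multiply by ``magnitude``), ``absolute_set``
    (set to ``magnitude``), ``swap_link`` (use ``replacement_link``) or
    ``swap_setting`` (toggle/set the CXA outpatient/inpatient setting, with
    ``setting`` naming the target).  Probabilities pushed outside [0, 1] by a
    relative scale are clipped with a warning.
    """

    label: str
    parameter_path: str = ""
    perturbation: str = "relative_scale"
    magnitude: Optional[float] = None
    replacement_link: Optional[StenosisLink] = None
    setting: Optional[str] = None

    def apply(
        self, perf: TestPerformance, costs: CostSchedule, link: StenosisLink
    ) -> Tuple[TestPerformance, CostSchedule, StenosisLink]:
        if self.perturbation == "swap_link":
            if self.replacement_link is None or not self.replacement_link.is_fitted:
                raise ConfigurationError(f"scenario {self.label!r}: no calibrated replacement link")
            return perf, costs, self.replacement_link
        if self.perturbation == "swap_setting":
            target = self.setting or (
                "inpatient" if costs.cxa_setting == "outpatient" else "outpatient"
            )
            return perf, costs.replace(cxa_setting=target), link
        if self.perturbation not in ("relative_scale", "absolute_set"):
            raise ConfigurationError(
                f"scenario {self.label!r}: unknown perturbation {self.perturbation!r}"
            )
        if self.magnitude is None:
            raise ConfigurationError(f"scenario {self.label!r}: magnitude is required")
        try:
            obj_name, field_name = self.parameter_path.split(".", 1)
        except ValueError as exc:
            raise ConfigurationError(
                f"scenario {self.label!r}: parameter_path must look like 'perf.sn_cmr' "
                f"or 'costs.f_cmr', got {self.parameter_path!r}"
            ) from exc
        if obj_name == "perf":
            base = getattr(perf, field_name)
            value = base * self.magnitude if self.perturbation == "relative_scale" else self.magnitude
            if not 0.0 <= value <= 1.0:
                clipped = min(max(value, 0.0), 1.0)
                warnings.warn(
                    f"scenario {self.label!r}: {field_name} perturbed to {value:.4g}, "
                    f"clipped to {clipped:.4g}",
                    stacklevel=2,
                )
                value = clipped
            return perf.replace(**{field_name: value}), costs, link
        if obj_name == "costs":
            base = getattr(costs, field_name)
            value = base * self.magnitude if self.perturbation == "relative_scale" else self.magnitude
            return perf, costs.replace(**{field_name: value}), link
        raise ConfigurationError(
            f"scenario {self.label!r}: parameter_path root must be 'perf' or 'costs'"
        )


def one_way_sensitivity(
    perf: TestPerformance,
    costs: CostSchedule,
    link: StenosisLink,
    scenarios: Sequence[SensitivityScenario],
    crossing: str = "ce",
    domain: Tuple[float, float] = (0.01, 1.0),
) -> pd.DataFrame:
    """Recompute the crossing point under each one-at-a-time perturbation.

    Every scenario starts from the same base parameters (statelessness: the
    output is independent of scenario order).  The shift is reported in
    percentage points of pre-test likelihood; each crossing is recomputed
    from scratch, never updated incrementally.  A scenario whose perturbed
    parameters are invalid is reported with status ``invalid`` and the run
    continues.

    Returns a DataFrame with columns ``label, p_star_base, p_star_perturbed,
    shift_percentage_points, status``.
    """
    finder = find_ce_crossing if crossing == "ce" else find_cost_crossing
    if crossing not in ("ce", "cost"):
        raise ConfigurationError(f"crossing must be 'ce' or 'cost', got {crossing!r}")
    base = finder(perf, costs, link, domain=domain)
    rows = []
    for sc in scenarios:
        try:
            p2, c2, l2 = sc.apply(perf, costs, link)
            result = finder(p2, c2, l2, domain=domain)
            status = result.status
            p_star_perturbed = result.p_star
        except (ConfigurationError, DomainError) as exc:
            warnings.warn(f"scenario {sc.label!r} invalid: {exc}", stacklevel=2)
            status, p_star_perturbed = "invalid", None
        shift = (
            100.0 * (p_star_perturbed - base.p_star)
            if (base.p_star is not None and p_star_perturbed is not None)
            else math.nan
        )
        rows.append(
            {
                "label": sc.label,
                "p_star_base": base.p_star if base.p_star is not None else math.nan,
                "p_star_perturbed": p_star_perturbed if p_star_perturbed is not None else math.nan,
                "shift_percentage_points": shift,
                "status": status,
            }
        )
    columns = ["label", "p_star_base", "p_star_perturbed", "shift_percentage_points", "status"]
    return pd.DataFrame(rows, columns=columns)
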