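"""Country configuration files: fee schedules, test performance, link calibration.

A configuration is a YAML mapping with the cost schedule of one health-care
system, optional overrides of the default test-performance parameters, and
an optional stenosis-link section (either a functional form fitted to a
calibration-point table, or the identity default).  A non-empty
``provenance_note`` is mandatory so synthetic illustrative schedules are
never mistaken for a country's transcribed fees.

Example::

    country_label: Synthetic example
    provenance_note: synthetic illustrative fees, not any country's schedule
    costs:
      f_cmr: 1000
      f_cxa_outpatient: 2000
      f_cxa_inpatient: 3500
      f_ffr: 600
      c_complication: 10000
      discount_rate: 0.03
      horizon_years: 10
      currency: XXX
      cxa_setting: outpatient
    performance: {}          # omitted fields take the literature defaults
    link:
      form: identity
      points_path: null      # CSV: p_isch,p_sten,weight,threshold_label
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .errors import CadCeaError, ConfigurationError
from .link import LinkPoint, StenosisLink, fit_link, identity_link
from .params import CostSchedule, TestPerformance

__all__ = ["CountryConfig", "load_config", "save_config", "read_link_points"]

_REQUIRED_COST_FIELDS = ("f_cmr", "f_cxa_outpatient", "f_cxa_inpatient", "f_ffr", "c_complication")


@dataclass(frozen=True)
class CountryConfig:
    country_label: str
    provenance_note: str
    cost_schedule: CostSchedule
    performance: TestPerformance
    link: StenosisLink
    link_points_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not str(self.provenance_note).strip():
            raise ConfigurationError(
                "provenance_note is mandatory: state whether the fees are transcribed "
                "from a source or synthetic"
            )


def read_link_points(path) -> list[LinkPoint]:
    """Read calibration points from a delimited table.

    Expected columns ``p_isch, p_sten`` with optional ``weight`` (default 1)
    and ``threshold_label`` (default "0.75").
    """
    df = pd.read_csv(path, comment="#")
    missing = {"p_isch", "p_sten"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"link-point table {path} lacks columns: {sorted(missing)}")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if "threshold_label" not in df.columns:
        df["threshold_label"] = "0.75"

    def norm_label(v) -> str:
        # YAML/CSV readers turn "0.80" into the float 0.8; restore 2 decimals
        try:
            return f"{float(v):.2f}"
        except (TypeError, ValueError):
            return str(v)

    return [
        LinkPoint(float(r.p_isch), float(r.p_sten), float(r.weight), norm_label(r.threshold_label))
        for r in df.itertuples()
    ]


def _build_link(section: Optional[dict], base_dir: Path) -> tuple[StenosisLink, Optional[str]]:
    if not section:
        return identity_link(), None
    form = section.get("form", "identity")
    raw_threshold = section.get("ffr_threshold_label", "0.75")
    try:
        threshold = f"{float(raw_threshold):.2f}"
    except (TypeError, ValueError):
        threshold = str(raw_threshold)
    points_path = section.get("points_path")
    if form == "identity" or points_path is None:
        if form != "identity" and points_path is None:
            raise ConfigurationError(f"link form {form!r} requires points_path")
        return StenosisLink(form="identity", ffr_threshold_label=threshold), points_path
    resolved = Path(points_path)
    if not resolved.is_absolute():
        resolved = base_dir / resolved
    points = [p for p in read_link_points(resolved) if p.threshold_label == threshold]
    if not points:
        raise ConfigurationError(
            f"no calibration points with threshold_label={threshold!r} in {resolved}"
        )
    return fit_link(points, form=form, ffr_threshold_label=threshold), str(points_path)


def load_config(path) -> CountryConfig:
    """Load and validate a country configuration file.

    Missing mandatory cost fields and out-of-range values raise
    :class:`ConfigurationError` naming the offending field; omitted
    performance fields take the :class:`TestPerformance` defaults.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path} must contain a YAML mapping")

    costs_raw = raw.get("costs")
    if not isinstance(costs_raw, dict):
        raise ConfigurationError(f"{path}: missing 'costs' section")
    missing = [f for f in _REQUIRED_COST_FIELDS if f not in costs_raw]
    if missing:
        raise ConfigurationError(f"{path}: missing mandatory cost field(s): {missing}")
    known_cost = {f.name for f in dataclasses.fields(CostSchedule)}
    unknown = sorted(set(costs_raw) - known_cost)
    if unknown:
        raise ConfigurationError(f"{path}: unknown cost field(s): {unknown}")

    perf_raw = raw.get("performance") or {}
    known_perf = {f.name for f in dataclasses.fields(TestPerformance)}
    unknown = sorted(set(perf_raw) - known_perf)
    if unknown:
        raise ConfigurationError(f"{path}: unknown performance field(s): {unknown}")

    try:
        costs = CostSchedule(**costs_raw)
        perf = TestPerformance(**perf_raw)
        link, points_path = _build_link(raw.get("link"), path.parent)
        return CountryConfig(
            country_label=str(raw.get("country_label", path.stem)),
            provenance_note=str(raw.get("provenance_note", "")),
            cost_schedule=costs,
            performance=perf,
            link=link,
            link_points_path=points_path,
        )
    except CadCeaError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


def save_config(config: CountryConfig, path) -> None:
    """Write a configuration back to YAML (round-trips with load_config)."""
    payload = {
        "country_label": config.country_label,
        "provenance_note": config.provenance_note,
        "costs": dataclasses.asdict(config.cost_schedule),
        "performance": dataclasses.asdict(config.performance),
        "link": {
            "form": config.link.form,
            "ffr_threshold_label": config.link.ffr_threshold_label,
            "points_path": config.link_points_path,
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
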