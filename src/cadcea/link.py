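"""Calibration of the ischemia-to-stenosis prevalence link.

Strategy 2 performs an FFR measurement only in patients whose angiogram shows
a >=50% diameter stenosis, so the expected FFR cost depends on the stenosis
prevalence ``P_sten`` in a cohort whose ischemia prevalence is ``P_isch``.
Because every FFR-positive (ischemic) lesion is a >=50% stenosis, the link
must be monotone non-decreasing with ``P_sten >= P_isch``.

The link is an estimator in the scikit-learn style: construct with a
functional form, call :meth:`StenosisLink.fit` on study-level calibration
points ``(p_isch, p_sten, weight)``, then :meth:`StenosisLink.transform` (or
simply call the object) to map prevalences.  Three forms are supported:

``identity``
    ``P_sten = P_isch`` — the shipped default when no calibration data are
    supplied.
``linear_clipped``
    Weighted least-squares straight line, outputs clipped to [0, 1].
``logit_linear``
    Weighted least-squares straight line in logit-logit space (boundary
    points excluded from the fit), which is monotone and needs no clipping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import expit, logit

from .errors import CalibrationError, DomainError
from .params import validate_probability

__all__ = ["LinkPoint", "StenosisLink", "fit_link", "apply_link", "identity_link"]

LINK_FORMS = ("identity", "linear_clipped", "logit_linear")


@dataclass(frozen=True)
class LinkPoint:
    """One study-level calibration point: FFR-positive fraction vs stenosis fraction."""

    p_isch: float
    p_sten: float
    weight: float = 1.0
    threshold_label: str = "0.75"

    def __post_init__(self) -> None:
        validate_probability(self.p_isch, "p_isch")
        validate_probability(self.p_sten, "p_sten")
        if not self.weight > 0:
            raise DomainError(f"weight must be positive, got {self.weight!r}")


class StenosisLink:
    """Monotone map from ischemia prevalence to >=50%-stenosis prevalence.

    Parameters
    ----------
    form : {"identity", "linear_clipped", "logit_linear"}
        Functional form of the map.
    ffr_threshold_label : {"0.75", "0.80"}
        Label of the FFR ischemia cut-off the calibration points refer to.
        Two alternative calibration sets (one per threshold) realise the
        FFR-threshold sensitivity analysis; the label is carried for
        reporting only.

    Attributes
    ----------
    slope_, intercept_ : float
        Fitted coefficients (in logit space for ``logit_linear``).  The
        identity form is born fitted with slope 1, intercept 0.
    """

    def __init__(self, form: str = "identity", ffr_threshold_label: str = "0.75") -> None:
        if form not in LINK_FORMS:
            raise CalibrationError(f"unknown link form {form!r}; expected one of {LINK_FORMS}")
        if str(ffr_threshold_label) not in ("0.75", "0.80"):
            raise CalibrationError(
                f"ffr_threshold_label must be '0.75' or '0.80', got {ffr_threshold_label!r}"
            )
        self.form = form
        self.ffr_threshold_label = str(ffr_threshold_label)
        if form == "identity":
            self.slope_ = 1.0
            self.intercept_ = 0.0

    # -- estimator API -------------------------------------------------

    def get_params(self, deep: bool = True) -> dict:
        return {"form": self.form, "ffr_threshold_label": self.ffr_threshold_label}

    def set_params(self, **params) -> "StenosisLink":
        self.__init__(**{**self.get_params(), **params})
        return self

    @property
    def is_fitted(self) -> bool:
        return hasattr(self, "slope_")

    def fit(self, p_isch, p_sten, sample_weight=None) -> "StenosisLink":
        """Weighted least-squares calibration on study-level points.

        Non-identity forms need at least two points with distinct ``p_isch``.
        A fitted slope < 0 violates monotonicity and raises
        :class:`CalibrationError`.
        """
        x = np.asarray(p_isch, dtype=float).ravel()
        y = np.asarray(p_sten, dtype=float).ravel()
        if x.shape != y.shape:
            raise CalibrationError("p_isch and p_sten must have the same length")
        w = (
            np.ones_like(x)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=float).ravel()
        )
        if w.shape != x.shape or np.any(w <= 0):
            raise CalibrationError("sample_weight must be positive and match the points")
        if np.any((x < 0) | (x > 1) | (y < 0) | (y > 1)):
            raise DomainError("calibration points must be probabilities in [0, 1]")

        if self.form == "identity":
            self.slope_, self.intercept_ = 1.0, 0.0
            return self

        if self.form == "logit_linear":
            interior = (x > 0) & (x < 1) & (y > 0) & (y < 1)
            x, y, w = x[interior], y[interior], w[interior]
            x, y = logit(x), logit(y)

        if np.unique(x).size < 2:
            raise CalibrationError(
                "need at least 2 calibration points with distinct p_isch "
                f"for form {self.form!r}"
            )
        # WLS via sqrt-weighted lstsq; minimises sum w_i (y_i - a - b x_i)^2.
        sw = np.sqrt(w)
        design = np.column_stack([x, np.ones_like(x)]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
        if slope < 0:
            raise CalibrationError(
                f"fitted slope {slope:.4g} is negative: the prevalence link must be "
                "non-decreasing"
            )
        self.slope_, self.intercept_ = slope, intercept
        return self

    def fit_points(self, points: Iterable[LinkPoint]) -> "StenosisLink":
        """Fit from :class:`LinkPoint` records."""
        pts = list(points)
        if not pts and self.form != "identity":
            raise CalibrationError("no calibration points supplied")
        if pts:
            return self.fit(
                [p.p_isch for p in pts],
                [p.p_sten for p in pts],
                [p.weight for p in pts],
            )
        self.slope_, self.intercept_ = 1.0, 0.0
        return self

    def transform(self, p_isch):
        """Map ischemia prevalence(s) to stenosis prevalence(s), clipped to [0, 1]."""
        if not self.is_fitted:
            raise CalibrationError("link is not calibrated; call fit() first")
        p = np.asarray(p_isch, dtype=float)
        if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
            raise DomainError("p_isch must lie in [0, 1]")
        if self.form == "logit_linear":
            with np.errstate(divide="ignore"):
                out = expit(self.intercept_ + self.slope_ * logit(p))
            # limits at the boundary (slope > 0): logit(0) -> -inf, logit(1) -> +inf
            out = np.where(p == 0.0, 0.0 if self.slope_ > 0 else out, out)
            out = np.where(p == 1.0, 1.0 if self.slope_ > 0 else out, out)
        else:
            out = self.intercept_ + self.slope_ * p
        out = np.clip(out, 0.0, 1.0)
        return float(out) if np.isscalar(p_isch) or np.ndim(p_isch) == 0 else out

    __call__ = transform

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        coef = (
            f", slope_={self.slope_:.4g}, intercept_={self.intercept_:.4g}"
            if self.is_fitted
            else " (unfitted)"
        )
        return f"StenosisLink(form={self.form!r}, ffr_threshold_label={self.ffr_threshold_label!r}{coef})"


def identity_link() -> StenosisLink:
    """The default P_sten = P_isch link (no calibration data required)."""
    return StenosisLink(form="identity")


def fit_link(points: Sequence[LinkPoint], form: str = "linear_clipped", **kwargs) -> StenosisLink:
    """Calibrate a :class:`StenosisLink` of the given form on LinkPoint records."""
    link = StenosisLink(form=form, **kwargs)
    link.fit_points(points)
    if any(p.p_sten < p.p_isch for p in points):
        warnings.warn(
            "some calibration points have p_sten < p_isch; every FFR-positive lesion "
            "should be a >=50% stenosis — check the data orientation",
            stacklevel=2,
        )
    return link


def apply_link(link: StenosisLink, p_isch):
    """Functional alias for ``link.transform(p_isch)``."""
    return link.transform(p_isch)
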