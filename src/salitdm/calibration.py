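"""Weighted through-origin quadratic calibration.

The instrument response is modelled as ``y(c) = a*c + b*c**2`` with zero
intercept; ``a`` is the sensitivity (response per ng/ml) and ``b`` captures
mild detector saturation (b < 0) or enhancement (b > 0).  Fitting minimises
the weighted squared residuals with weights ``1/x`` by default, which keeps
relative accuracy at the low end of a range that spans 256-fold.  The fit is
closed-form: two coefficients from the 2x2 weighted normal equations.

A curve is accepted only if monotone increasing on [0, ULOQ]
(``a > 0`` and ``a + 2*b*ULOQ > 0``), which makes inverse prediction
(quantification of unknowns) single-valued on the working range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    OutOfModelError,
    RejectedCurveError,
    UnderDeterminedError,
    UndefinedRSquaredError,
)

WEIGHTING_SCHEMES = ("1/x", "1/x2", "none")

#: qualifier labels attached to inverse predictions
BELOW_LOD = "below_lod"
BELOW_LLOQ = "below_lloq"
ABOVE_ULOQ = "above_uloq"
QUANTIFIED = "quantified"


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration observation: nominal concentration and response.

    ``response`` is the analyte/IS area ratio when an internal standard is
    assigned (``response_mode="is_ratio"``), otherwise the raw analyte area.
    ``weight`` overrides the scheme-derived weight when given.
    """

    nominal: float
    response: float
    weight: float | None = None

    def __post_init__(self) -> None:
        if not (self.nominal > 0):
            raise ValueError(f"nominal must be positive, got {self.nominal}")
        if self.response < 0:
            raise ValueError(f"response must be non-negative, got {self.response}")
        if self.weight is not None and not (self.weight > 0):
            raise ValueError(f"weight must be positive, got {self.weight}")


def scheme_weights(nominals: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "1/x":
        return 1.0 / nominals
    if weighting == "1/x2":
        return 1.0 / nominals**2
    if weighting == "none":
        return np.ones_like(nominals)
    raise ValueError(f"unknown weighting scheme {weighting!r}; expected one of {WEIGHTING_SCHEMES}")


@dataclass
class CalibrationCurve:
    """A fitted through-origin quadratic ``y = a*c + b*c**2`` with its range."""

    analyte: str
    a: float
    b: float
    r2: float
    lloq: float
    uloq: float
    weighting: str = "1/x"
    response_mode: str = "is_ratio"
    lod: float | None = None
    r2_warning: bool = False  # set when r2 < 0 (pathological fit, reported as-is)

    def predict(self, conc):
        """Forward model: expected response at concentration `conc`."""
        c = np.asarray(conc, dtype=float)
        out = self.a * c + self.b * c**2
        return float(out) if np.isscalar(conc) else out

    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "a": self.a,
            "b": self.b,
            "r2": self.r2,
            "lloq": self.lloq,
            "uloq": self.uloq,
            "weighting": self.weighting,
            "response_mode": self.response_mode,
            "lod": self.lod,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "CalibrationCurve":
        return cls(**{k: obj[k] for k in
                      ("analyte", "a", "b", "r2", "lloq", "uloq",
                       "weighting", "response_mode", "lod") if k in obj})


def _as_arrays(points: Iterable[CalibrationPoint], weighting: str):
    pts = list(points)
    c = np.array([p.nominal for p in pts], dtype=float)
    y = np.array([p.response for p in pts], dtype=float)
    w = scheme_weights(c, weighting)
    override = np.array([p.weight if p.weight is not None else np.nan for p in pts])
    w = np.where(np.isnan(override), w, override)
    return c, y, w


def fit_calibration(
    points: Iterable[CalibrationPoint],
    weighting: str = "1/x",
    *,
    analyte: str = "",
    lloq: float | None = None,
    uloq: float | None = None,
    lod: float | None = None,
    response_mode: str = "is_ratio",
) -> CalibrationCurve:
    """Fit the weighted through-origin quadratic to calibration points.

    ``(a, b)`` minimise ``sum(w_i * (y_i - a*c_i - b*c_i**2)**2)``; the
    solution is the exact 2x2 weighted normal-equation solve, so the fit is
    deterministic.  Raises :class:`UnderDeterminedError` with fewer than three
    distinct nominal levels and :class:`RejectedCurveError` when the fitted
    curve is not monotone increasing on [0, ULOQ].
    """
    c, y, w = _as_arrays(points, weighting)
    if np.unique(c).size < 3:
        raise UnderDeterminedError(
            f"need >= 3 distinct nominal levels, got {np.unique(c).size}"
        )
    lo = float(np.min(c)) if lloq is None else float(lloq)
    hi = float(np.max(c)) if uloq is None else float(uloq)

    s2 = np.sum(w * c**2)
    s3 = np.sum(w * c**3)
    s4 = np.sum(w * c**4)
    t1 = np.sum(w * c * y)
    t2 = np.sum(w * c**2 * y)
    a, b = np.linalg.solve(np.array([[s2, s3], [s3, s4]]), np.array([t1, t2]))
    a, b = float(a), float(b)

    if a <= 0 or a + 2.0 * b * hi <= 0:
        raise RejectedCurveError(
            f"{analyte or 'curve'}: fitted model non-monotone on [0, {hi:g}] "
            f"(a={a:.6g}, b={b:.6g})"
        )

    curve = CalibrationCurve(
        analyte=analyte, a=a, b=b, r2=np.nan, lloq=lo, uloq=hi,
        weighting=weighting, response_mode=response_mode, lod=lod,
    )
    curve.r2 = r_squared(curve, points=list(zip(c, y, w)))
    if curve.r2 < 0:
        curve.r2_warning = True
        warnings.warn(
            f"{analyte or 'curve'}: negative weighted r2 ({curve.r2:.4g}) — pathological fit",
            stacklevel=2,
        )
    return curve


def r_squared(curve: CalibrationCurve, points) -> float:
    """Weighted coefficient of determination about the weighted mean response.

    ``1 - SSres_w / SStot_w`` with ``SStot_w`` taken about the weighted mean
    of the responses (standard WLS definition).  Not clipped: a negative value
    signals a fit worse than the weighted-mean model.
    """
    triples = [
        (p.nominal, p.response, p.weight if p.weight is not None else None)
        if isinstance(p, CalibrationPoint) else tuple(p)
        for p in points
    ]
    c = np.array([t[0] for t in triples], dtype=float)
    y = np.array([t[1] for t in triples], dtype=float)
    w = np.array(
        [t[2] if t[2] is not None else np.nan for t in triples], dtype=float
    )
    if np.isnan(w).any():
        w = np.where(np.isnan(w), scheme_weights(c, curve.weighting), w)

    yhat = curve.a * c + curve.b * c**2
    ybar = np.sum(w * y) / np.sum(w)
    ss_tot = np.sum(w * (y - ybar) ** 2)
    if ss_tot == 0:
        raise UndefinedRSquaredError("zero weighted variance of responses")
    ss_res = np.sum(w * (y - yhat) ** 2)
    return float(1.0 - ss_res / ss_tot)


@dataclass(frozen=True)
class InversePrediction:
    conc: float
    qualifier: str


def inverse_predict(curve: CalibrationCurve, response: float) -> InversePrediction:
    """Solve ``b*c**2 + a*c - y = 0`` for the concentration of an unknown.

    For a near-linear curve (|b| < 1e-12 * a) the linear inverse ``y/a`` is
    used.  Otherwise the root lying in [0, 2*ULOQ] is returned; monotonicity
    on the range makes it unique.  The qualifier flags where the value falls
    relative to LOD / LLOQ / ULOQ.
    """
    y = float(response)
    if y < 0:
        raise ValueError(f"response must be non-negative, got {y}")
    a, b = curve.a, curve.b
    if abs(b) < 1e-12 * abs(a):
        c = y / a
    else:
        disc = a * a + 4.0 * b * y
        if disc < 0:
            raise OutOfModelError(
                f"response {y:g} beyond the model maximum (discriminant < 0)"
            )
        sq = math.sqrt(disc)
        # stable quadratic roots of b c^2 + a c - y = 0
        q = -0.5 * (a + math.copysign(sq, a))
        roots = [r for r in (q / b, -y / q if q != 0 else np.inf)]
        inrange = [r for r in roots if np.isfinite(r) and -1e-12 <= r <= 2.0 * curve.uloq]
        if not inrange:
            raise OutOfModelError(
                f"no inverse root in [0, {2 * curve.uloq:g}] for response {y:g}"
            )
        c = max(0.0, min(inrange))
    return InversePrediction(conc=c, qualifier=_qualify(c, curve))


def _qualify(c: float, curve: CalibrationCurve) -> str:
    lod = curve.lod
    if c > curve.uloq:
        return ABOVE_ULOQ
    if lod is not None and c < lod:
        return BELOW_LOD
    if lod is None and c == 0.0:
        return BELOW_LOD
    if c < curve.lloq:
        return BELOW_LLOQ
    return QUANTIFIED


def back_calculate(
    curve: CalibrationCurve, points: Iterable[CalibrationPoint]
) -> pd.DataFrame:
    """Back-calculate each point and report the % deviation from nominal.

    Deviation is ``100 * (c_back - c_nominal) / c_nominal`` — the accuracy
    measure judged against 15% (20% at the LLOQ level).
    """
    rows = []
    for p in points:
        pred = inverse_predict(curve, p.response)
        rows.append(
            {
                "nominal": p.nominal,
                "response": p.response,
                "back_calculated": pred.conc,
                "deviation_pct": 100.0 * (pred.conc - p.nominal) / p.nominal,
                "qualifier": pred.qualifier,
            }
        )
    return pd.DataFrame(rows)
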