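"""Weighted through-origin quadratic fitting, r², and inverse prediction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from salitdm import (
    CalibrationPoint,
    back_calculate,
    fit_calibration,
    inverse_predict,
    r_squared,
)
from salitdm.calibration import (
    ABOVE_ULOQ,
    BELOW_LLOQ,
    BELOW_LOD,
    QUANTIFIED,
    CalibrationCurve,
)
from salitdm.errors import (
    RejectedCurveError,
    UnderDeterminedError,
    UndefinedRSquaredError,
)


def dyadic_points(a, b, std9=100.0, n=9, noise=None, rng=None):
    c = std9 / 2.0 ** np.arange(n - 1, -1, -1)
    y = a * c + b * c**2
    if noise:
        y = y * np.exp(rng.normal(0.0, noise, size=c.size))
    return [CalibrationPoint(ci, yi) for ci, yi in zip(c, y)]


@pytest.mark.parametrize("a,b", [(1000.0, -0.5), (2.0, 0.0), (50.0, 0.01)])
@pytest.mark.parametrize("weighting", ["1/x", "1/x2", "none"])
def test_noiseless_fit_recovers_generating_coefficients(a, b, weighting):
    """Exact interpolation: coefficients recovered to 1e-9 relative, r² = 1."""
    curve = fit_calibration(dyadic_points(a, b), weighting)
    assert curve.a == pytest.approx(a, rel=1e-9)
    assert curve.b == pytest.approx(b, rel=1e-9, abs=1e-9 * a)
    assert curve.r2 == pytest.approx(1.0, abs=1e-12)


def test_three_point_fit_matches_normal_equation_oracle():
    """(a, b) equal the direct solve of the weighted moment system
    [[Σwc², Σwc³], [Σwc³, Σwc⁴]] · (a, b) = (Σwcy, Σwc²y)."""
    c = np.array([1.0, 2.0, 4.0])
    y = np.array([2.0, 5.0, 14.0])
    w = 1.0 / c
    # independent oracle: scaled least squares instead of the moment solve
    X = np.column_stack([c, c**2]) * np.sqrt(w)[:, None]
    expected, *_ = np.linalg.lstsq(X, y * np.sqrt(w), rcond=None)

    curve = fit_calibration(
        [CalibrationPoint(ci, yi) for ci, yi in zip(c, y)], "1/x"
    )
    assert (curve.a, curve.b) == pytest.approx(tuple(expected), rel=1e-10)


def test_fit_invariant_to_uniform_weight_rescaling():
    rng = np.random.default_rng(3)
    pts = dyadic_points(1000.0, -0.5, noise=0.05, rng=rng)
    base = fit_calibration(pts, "1/x")
    scaled = fit_calibration(
        [CalibrationPoint(p.nominal, p.response, 7.5 / p.nominal) for p in pts],
        "1/x",
    )
    assert scaled.a == pytest.approx(base.a, rel=1e-12)
    assert scaled.b == pytest.approx(base.b, rel=1e-12)
    assert scaled.r2 == pytest.approx(base.r2, rel=1e-12)


def test_under_determined_and_rejected_curves():
    with pytest.raises(UnderDeterminedError):
        fit_calibration(
            [CalibrationPoint(1, 1), CalibrationPoint(2, 2), CalibrationPoint(2, 2.1)]
        )
    # strong saturation: response turns over inside the range
    c = np.array([10.0, 20.0, 40.0, 80.0, 100.0])
    y = 100.0 * c - 0.8 * c**2
    with pytest.raises(RejectedCurveError):
        fit_calibration([CalibrationPoint(ci, max(yi, 0.0)) for ci, yi in zip(c, y)])


def test_r_squared_matches_direct_formula():
    """Value agrees with an independent evaluation of 1 - SSres_w/SStot_w."""
    rng = np.random.default_rng(11)
    pts = dyadic_points(1000.0, -0.5, noise=0.05, rng=rng)
    curve = fit_calibration(pts, "1/x")
    c = np.array([p.nominal for p in pts])
    y = np.array([p.response for p in pts])
    w = 1.0 / c
    yhat = curve.a * c + curve.b * c**2
    ybar = (w * y).sum() / w.sum()
    expected = 1.0 - (w * (y - yhat) ** 2).sum() / (w * (y - ybar) ** 2).sum()
    assert curve.r2 == pytest.approx(expected, abs=1e-12)


def test_r_squared_undefined_for_flat_responses():
    curve = CalibrationCurve("X", a=1.0, b=0.0, r2=np.nan, lloq=1, uloq=4)
    pts = [CalibrationPoint(c, 5.0) for c in (1.0, 2.0, 4.0)]
    with pytest.raises(UndefinedRSquaredError):
        r_squared(curve, pts)


def test_linear_inversion_and_zero_response():
    curve = CalibrationCurve("X", a=2.0, b=0.0, r2=1.0, lloq=1.0, uloq=100.0)
    assert inverse_predict(curve, 10.0).conc == pytest.approx(5.0)
    pred = inverse_predict(curve, 0.0)
    assert pred.conc == 0.0
    assert pred.qualifier == BELOW_LOD


def test_quadratic_inversion_recovers_forward_value():
    curve = CalibrationCurve("X", a=1000.0, b=-0.5, r2=1.0, lloq=1.0, uloq=100.0)
    y = curve.predict(100.0)
    assert y == pytest.approx(95000.0)
    assert inverse_predict(curve, y).conc == pytest.approx(100.0, rel=1e-9)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    c=st.floats(min_value=0.4, max_value=100.0),
    b=st.floats(min_value=-0.4, max_value=0.4),
)
def test_inverse_predict_roundtrip_identity(c, b):
    """inverse_predict(y(c)) == c to 1e-9 relative across the working range."""
    curve = CalibrationCurve("X", a=100.0, b=b, r2=1.0, lloq=0.39, uloq=100.0)
    assert curve.a + 2 * curve.b * curve.uloq > 0  # monotone by construction
    assert inverse_predict(curve, curve.predict(c)).conc == pytest.approx(c, rel=1e-9)


def test_inverse_qualifiers_against_limits():
    curve = CalibrationCurve(
        "X", a=10.0, b=0.0, r2=1.0, lloq=1.0, uloq=100.0, lod=0.5
    )
    assert inverse_predict(curve, 10.0 * 0.2).qualifier == BELOW_LOD
    assert inverse_predict(curve, 10.0 * 0.7).qualifier == BELOW_LLOQ
    assert inverse_predict(curve, 10.0 * 1.0).qualifier == QUANTIFIED  # at LLOQ
    assert inverse_predict(curve, 10.0 * 50).qualifier == QUANTIFIED
    assert inverse_predict(curve, 10.0 * 101).qualifier == ABOVE_ULOQ


def test_back_calculation_deviation_tracks_response_inflation():
    """A 10% inflated response on a linear curve shows as +10% deviation."""
    curve = CalibrationCurve("X", a=5.0, b=0.0, r2=1.0, lloq=1.0, uloq=100.0)
    pts = [CalibrationPoint(10.0, 50.0), CalibrationPoint(20.0, 5.0 * 20 * 1.1)]
    out = back_calculate(curve, pts)
    assert out["deviation_pct"].iloc[0] == pytest.approx(0.0, abs=1e-12)
    assert out["deviation_pct"].iloc[1] == pytest.approx(10.0, rel=1e-9)


def test_lloq_deviation_judged_at_20_not_15():
    """An 18% bias passes compliance at the LLOQ level (<20% bound) but fails
    at a QC level (<15% bound)."""
    import pandas as pd

    from salitdm import ValidationReport, evaluate_compliance

    tab = pd.DataFrame(
        {
            "qc_level": ["LLOQ", "L"],
            "accuracy_pct": [118.0, 118.0],
            "intra_day_rsd": [5.0, 5.0],
            "inter_day_rsd": [5.0, 5.0],
        }
    )
    report = evaluate_compliance(ValidationReport(table=tab))
    assert report.table["accuracy_pass"].tolist() == [True, False]
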