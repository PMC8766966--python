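"""Validation metrics: accuracy, RSD, REC/EE/ME/IS-nME, limits, selectivity,
compliance flags and device-retention classification."""

import numpy as np
import pandas as pd
import pytest

from salitdm import (
    ValidationReport,
    accuracy,
    determine_limits,
    evaluate_compliance,
    extraction_efficiency,
    imprecision,
    is_normalized_me,
    matrix_effect,
    recovery,
    rsd,
    salivette_retention,
    selectivity_check,
    triplet_metrics,
)
from salitdm.errors import (
    InsufficientReplicatesError,
    InvalidNominalError,
    InvalidPairError,
    MethodInsensitiveError,
    UndefinedRSDError,
    UnmatchedDesignError,
)


# --- accuracy & RSD --------------------------------------------------------

def test_accuracy_examples():
    assert accuracy([10, 10, 10], 10) == pytest.approx(100.0)
    assert accuracy([9, 10, 11], 10) == pytest.approx(100.0)
    assert accuracy([7.66], 8) == pytest.approx(95.75)
    with pytest.raises(InvalidNominalError):
        accuracy([1.0], 0.0)


def test_rsd_examples():
    assert rsd([5.0, 5.0, 5.0]) == 0.0
    assert rsd([8.0, 10.0, 12.0]) == pytest.approx(20.0)  # sd 2, mean 10
    with pytest.raises(InsufficientReplicatesError):
        rsd([1.0])
    with pytest.raises(UndefinedRSDError):
        rsd([-1.0, 1.0])


def test_imprecision_scopes():
    df = pd.DataFrame(
        {"session": [1, 1, 1, 2, 3], "value": [4.0, 4.0, 4.0, 9.0, 11.0]}
    )
    assert imprecision(df, "intra_day") == 0.0
    pooled = pd.DataFrame({"session": [1, 2, 3], "value": [9.0, 10.0, 11.0]})
    assert imprecision(pooled, "inter_day") == pytest.approx(10.0)
    with pytest.raises(InsufficientReplicatesError):
        imprecision(pd.DataFrame({"session": [1, 1], "value": [1.0, 2.0]}), "inter_day")


def test_inter_day_session_means_variant():
    df = pd.DataFrame(
        {"session": [1, 1, 2, 2], "value": [8.0, 12.0, 9.0, 11.0]}
    )
    pooled = imprecision(df, "inter_day", inter_mode="pooled")
    by_means = imprecision(df, "inter_day", inter_mode="session_means")
    assert pooled == pytest.approx(rsd([8, 12, 9, 11]))
    assert by_means == pytest.approx(rsd([10.0, 10.0]))


# --- REC / EE / ME / IS-nME ------------------------------------------------

def _areas(values, key="session"):
    return pd.DataFrame({key: np.arange(1, len(values) + 1), "area": values})


def test_recovery_and_ee_session_ratios():
    assert recovery(_areas([100.0]), _areas([100.0])).mean == pytest.approx(100.0)
    assert recovery(_areas([90.0]), _areas([100.0])).mean == pytest.approx(90.0)
    assert extraction_efficiency(_areas([80.0]), _areas([100.0])).mean == pytest.approx(80.0)
    with pytest.raises(UnmatchedDesignError):
        recovery(_areas([1.0]), pd.DataFrame({"session": [9], "area": [1.0]}))


def test_matrix_effect_sign_convention():
    post = pd.DataFrame({"matrix_lot": [1, 2], "area": [120.0, 120.0]})
    neat = pd.DataFrame({"area": [100.0, 100.0]})
    assert matrix_effect(post, neat).mean == pytest.approx(+20.0)
    post["area"] = 80.0
    assert matrix_effect(post, neat).mean == pytest.approx(-20.0)
    neat_eq = pd.DataFrame({"area": [120.0]})
    post["area"] = 120.0
    assert matrix_effect(post, neat_eq).mean == pytest.approx(0.0)


def test_is_normalized_me_ratio_algebra():
    # co-suppression of analyte and IS cancels exactly, every realisation
    post = pd.DataFrame(
        {"matrix_lot": [1, 2, 3], "area_analyte": [60.0, 45.0, 90.0],
         "area_is": [120.0, 90.0, 180.0]}
    )
    neat = pd.DataFrame({"area_analyte": [100.0], "area_is": [200.0]})
    assert is_normalized_me(post, neat).mean == pytest.approx(0.0, abs=1e-12)

    # analyte enhanced +20%, IS untouched -> +20
    post2 = pd.DataFrame(
        {"matrix_lot": [1], "area_analyte": [120.0], "area_is": [200.0]}
    )
    assert is_normalized_me(post2, neat).mean == pytest.approx(+20.0)

    # analyte untouched, IS enhanced +25% -> 1/1.25 - 1 = -20
    post3 = pd.DataFrame(
        {"matrix_lot": [1], "area_analyte": [100.0], "area_is": [250.0]}
    )
    assert is_normalized_me(post3, neat).mean == pytest.approx(-20.0)


def test_triplet_identity_rec_equals_ee_times_me():
    """REC = EE * (1 + ME/100) holds exactly for any signal triplet; the
    magnitudes here give REC 90.0, EE 94.24, ME -4.5."""
    rec, ee, me = triplet_metrics(90.0, 95.5, 100.0)
    assert rec == pytest.approx(90.0)
    assert ee == pytest.approx(94.24, abs=0.005)
    assert me == pytest.approx(-4.5)
    assert rec == pytest.approx(ee * (1 + me / 100.0), rel=1e-12)


# --- limit determination ---------------------------------------------------

def _series(nominals, sn, dev=0.0, prec=5.0):
    return pd.DataFrame(
        {
            "nominal": nominals,
            "deviation_pct": [dev] * len(nominals),
            "rsd_pct": [prec] * len(nominals),
            "sn": sn,
        }
    )


def test_limits_from_sn_decay():
    """S/N halving per dilution from 8: LLOQ at the S/N-8 level, LOD one
    dilution below (S/N 4 >= 3)."""
    c = 1.0
    tab = _series([c / 4, c / 2, c], sn=[2.0, 4.0, 8.0])
    limits = determine_limits(tab)
    assert limits.lloq == pytest.approx(c)
    assert limits.lod == pytest.approx(c / 2)
    assert limits.lod <= limits.lloq


def test_limits_rule_conjunction_skips_imprecise_level():
    """A level with S/N 6 but RSD 25% cannot be the LLOQ."""
    tab = pd.DataFrame(
        {
            "nominal": [0.5, 1.0],
            "deviation_pct": [5.0, 5.0],
            "rsd_pct": [25.0, 5.0],
            "sn": [6.0, 12.0],
        }
    )
    limits = determine_limits(tab)
    assert limits.lloq == pytest.approx(1.0)
    assert limits.lod == pytest.approx(0.5)  # S/N rule alone governs the LOD


def test_all_sub_detection_series_raises():
    with pytest.raises(MethodInsensitiveError):
        determine_limits(_series([0.1, 0.2, 0.4], sn=[1.0, 1.5, 2.0]))


def test_limits_monotone_under_uniform_signal_scaling():
    """Scaling all signals up never raises LLOQ or LOD (100 random series)."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = 6
        noms = np.sort(rng.uniform(0.05, 2.0, size=n))
        sn = np.sort(rng.uniform(0.5, 40.0, size=n))
        dev = rng.uniform(-25, 25, size=n)
        prec = rng.uniform(0, 30, size=n)
        tab = pd.DataFrame(
            {"nominal": noms, "deviation_pct": dev, "rsd_pct": prec, "sn": sn}
        )
        scale = rng.uniform(1.0, 10.0)
        scaled = tab.assign(sn=tab["sn"] * scale)
        try:
            base = determine_limits(tab)
        except MethodInsensitiveError:
            continue
        up = determine_limits(scaled)
        assert up.lloq <= base.lloq
        assert up.lod <= base.lod


# --- selectivity -----------------------------------------------------------

def test_selectivity_thresholds_are_strict():
    lloq_ref = pd.DataFrame({"area_analyte": [100.0] * 3, "area_is": [1000.0] * 3})
    blanks = pd.DataFrame(
        {
            "matrix_lot": [1, 2, 3, 4],
            "area_analyte": [0.0, 30.0, 20.0, 19.9],   # 0%, 30%, exactly 20%, 19.9%
            "area_is": [0.0, 0.0, 0.0, 0.0],
        }
    )
    out = selectivity_check(blanks, lloq_ref).set_index("matrix_lot")["passes"]
    assert out[1] and out[4]
    assert not out[2]          # interference at 30% of the LLOQ response
    assert not out[3]          # boundary: exactly 20% fails (strict <)


def test_selectivity_is_interference_fails_lot():
    lloq_ref = pd.DataFrame({"area_analyte": [100.0], "area_is": [1000.0]})
    blanks = pd.DataFrame(
        {"matrix_lot": [1], "area_analyte": [0.0], "area_is": [60.0]}  # 6% of IS
    )
    assert not selectivity_check(blanks, lloq_ref)["passes"].iloc[0]


# --- compliance flags ------------------------------------------------------

@pytest.mark.parametrize(
    "acc,intra,inter,expected",
    [
        (95.9, 0.8, 0.7, True),
        (51.7, 4.2, 10.0, False),
        (85.1, 14.9, 14.9, True),    # strictly inside both bounds
        (85.0, 14.9, 14.9, False),   # |bias| exactly 15 fails (strict)
        (115.0, 1.0, 1.0, False),    # |bias| exactly 15 fails (strict)
        (100.0, 15.0, 1.0, False),
    ],
)
def test_compliance_flags_qc_levels(acc, intra, inter, expected):
    tab = pd.DataFrame(
        {
            "qc_level": ["H"],
            "accuracy_pct": [acc],
            "intra_day_rsd": [intra],
            "inter_day_rsd": [inter],
        }
    )
    report = evaluate_compliance(ValidationReport(table=tab))
    assert bool(report.table["passes"].iloc[0]) is expected


# --- device retention ------------------------------------------------------

@pytest.mark.parametrize(
    "pre,post,loss,tier",
    [
        ([100.0], [6.0], -94.0, "severe"),
        ([100.0], [100.0], 0.0, "negligible"),
        ([100.0], [124.0], +24.0, "increase"),
        ([100.0], [65.0], -35.0, "moderate"),
        ([100.0], [50.0], -50.0, "severe"),     # boundary: -50 is severe
        ([100.0], [80.0], -20.0, "moderate"),   # boundary: -20 is moderate
    ],
)
def test_salivette_retention_classification(pre, post, loss, tier):
    res = salivette_retention(pre, post, medium="solvent")
    assert res.loss_pct == pytest.approx(loss)
    assert res.tier == tier


def test_retention_requires_positive_pre():
    with pytest.raises(InvalidPairError):
        salivette_retention([0.0], [1.0])
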