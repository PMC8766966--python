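"""Adherence classification and multi-matrix concordance statistics.

A patient is called adherence-positive for a prescribed drug in a matrix when
the measured concentration reaches the limit of detection.  Concentrations
between LOD and LLOQ are kept as evidence of intake but flagged as carrying a
quantification error risk above 20%.  Saliva calls are judged against plasma
(and urine) as the established reference matrices, yielding sensitivity,
specificity and accuracy from the 2x2 match table, a three-matrix agreement
summary, and per-drug saliva/plasma concentration-ratio statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IncompleteMatchError, InvalidLimitsError, NoMatchesError

NOT_DETECTED = "not_detected"
DETECTED_SUB_LLOQ = "detected_sub_lloq"
QUANTIFIED = "quantified"

MATRICES = ("saliva", "plasma", "urine")


def classify_detection(conc: float, lod: float, lloq: float) -> str:
    """Three-way detection class for a measured concentration.

    ``conc < lod`` is not detected; ``lod <= conc < lloq`` is detected but
    below reliable quantification (error risk > 20%); ``conc >= lloq`` is
    quantified.  Adherence-positive means at least detected.
    """
    if not (lod < lloq):
        raise InvalidLimitsError(f"need LOD < LLOQ, got lod={lod}, lloq={lloq}")
    if conc < lod:
        return NOT_DETECTED
    if conc < lloq:
        return DETECTED_SUB_LLOQ
    return QUANTIFIED


def is_positive(conc: float, lod: float, lloq: float) -> bool:
    return classify_detection(conc, lod, lloq) != NOT_DETECTED


def call_samples(
    samples: pd.DataFrame,
    limits: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Attach detection class and positivity to a patient-results table.

    `samples` needs columns (patient, drug, matrix, conc_ng_ml); `limits`
    maps drug code to (LOD, LLOQ).  Per-matrix limit sets are supported by
    calling once per matrix with the appropriate mapping.
    """
    out = samples.copy()
    cls = [
        classify_detection(c, *limits[d])
        for c, d in zip(out["conc_ng_ml"], out["drug"])
    ]
    out["detection"] = cls
    out["positive"] = [c != NOT_DETECTED for c in cls]
    return out


@dataclass(frozen=True)
class ConcordanceResult:
    """2x2 agreement between a test matrix and a reference matrix.

    A "match" is one prescribed drug in one patient assayed in both matrices.
    Sensitivity/specificity are ``None`` (not applicable) when the positive /
    negative reference margin is empty, rather than inflated to 100%.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n_matches(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return 100.0 * self.tn / d if d else None

    @property
    def accuracy(self) -> float | None:
        n = self.n_matches
        return 100.0 * (self.tp + self.tn) / n if n else None

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "n_matches": self.n_matches,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
            "accuracy_pct": self.accuracy,
        }


def concordance(calls_test: pd.DataFrame, calls_ref: pd.DataFrame) -> ConcordanceResult:
    """Cross-tabulate positivity of matched (patient, drug) pairs.

    Both frames need columns (patient, drug, positive); only pairs present in
    both are counted.
    """
    merged = calls_test.merge(
        calls_ref, on=["patient", "drug"], suffixes=("_test", "_ref")
    )
    if merged.empty:
        raise NoMatchesError("no (patient, drug) pair present in both matrices")
    t = merged["positive_test"].astype(bool)
    r = merged["positive_ref"].astype(bool)
    return ConcordanceResult(
        tp=int((t & r).sum()),
        fp=int((t & ~r).sum()),
        fn=int((~t & r).sum()),
        tn=int((~t & ~r).sum()),
    )


@dataclass(frozen=True)
class ThreeMatrixSummary:
    n_matches: int
    full_agreement: int      # all three matrices agree
    partial_agreement: int   # at least two of three agree (majority)


def three_matrix_summary(calls: pd.DataFrame) -> ThreeMatrixSummary:
    """Agreement of each (patient, drug) call across saliva, plasma and urine.

    `calls` needs columns (patient, drug, matrix, positive) with all three
    matrices present for every match; the majority call defines agreement.
    """
    wide = calls.pivot_table(
        index=["patient", "drug"], columns="matrix", values="positive",
        aggfunc="first",
    )
    missing = [m for m in MATRICES if m not in wide.columns]
    if missing or wide[list(MATRICES)].isna().any().any():
        raise IncompleteMatchError(
            f"every match needs calls in all of {MATRICES}; missing: "
            f"{missing or 'some per-match entries'}"
        )
    votes = wide[list(MATRICES)].astype(bool).sum(axis=1)  # positives out of 3
    agree_with_majority = np.maximum(votes, 3 - votes)
    return ThreeMatrixSummary(
        n_matches=len(wide),
        full_agreement=int((agree_with_majority == 3).sum()),
        partial_agreement=int((agree_with_majority >= 2).sum()),
    )


@dataclass(frozen=True)
class SPRatioStats:
    """Saliva/plasma concentration-ratio summary for one drug."""

    drug: str
    n: int
    median_ratio: float
    iqr: tuple[float, float]
    correlation_r: float | None
    correlation_p: float | None


def sp_ratio_stats(
    pairs: pd.DataFrame,
    drug: str = "",
    method: str = "pearson",
) -> SPRatioStats:
    """Median and IQR of per-patient saliva/plasma ratios plus correlation.

    `pairs` needs columns (saliva, plasma); pairs with plasma == 0 are
    excluded with a warning.  Correlation (Pearson by default, Spearman via
    `method`) is computed on the raw paired concentrations when at least
    three pairs remain, otherwise reported as not applicable (``None``).
    Quartiles use the inclusive (linear interpolation) convention.
    """
    df = pairs[["saliva", "plasma"]].astype(float)
    bad = df["plasma"] == 0
    if bad.any():
        warnings.warn(
            f"{drug or 'drug'}: excluded {int(bad.sum())} pair(s) with zero plasma "
            "concentration", stacklevel=2,
        )
        df = df[~bad]
    if df.empty:
        raise NoMatchesError("no quantifiable saliva/plasma pair")
    ratios = (df["saliva"] / df["plasma"]).to_numpy()
    q1, med, q3 = np.percentile(ratios, [25, 50, 75])
    r = p = None
    if len(df) >= 3:
        if method == "pearson":
            r, p = stats.pearsonr(df["saliva"], df["plasma"])
        elif method == "spearman":
            r, p = stats.spearmanr(df["saliva"], df["plasma"])
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        r, p = float(r), float(p)
    return SPRatioStats(
        drug=drug, n=len(df), median_ratio=float(med), iqr=(float(q1), float(q3)),
        correlation_r=r, correlation_p=p,
    )


def sp_summary_table(
    samples: pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Per-drug saliva/plasma summary from a long patient-results table."""
    wide = samples.pivot_table(
        index=["patient", "drug"], columns="matrix", values="conc_ng_ml",
        aggfunc="first",
    ).reset_index()
    rows = []
    for drug, grp in wide.groupby("drug"):
        grp = grp.dropna(subset=["saliva", "plasma"])
        grp = grp[grp["plasma"] > 0]
        if grp.empty:
            continue
        st = sp_ratio_stats(grp, drug=drug, method=method)
        rows.append(
            {
                "drug": drug,
                "n": st.n,
                "saliva_median": float(grp["saliva"].median()),
                "plasma_median": float(grp["plasma"].median()),
                "sp_ratio_median": st.median_ratio,
                "sp_ratio_q1": st.iqr[0],
                "sp_ratio_q3": st.iqr[1],
                "correlation_r": st.correlation_r,
                "correlation_p": st.correlation_p,
            }
        )
    return pd.DataFrame(rows)
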