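"""Synthetic instrument and cohort generator.

Stands in for the UHPLC-MS/MS instrument and the patient cohort so that every
pipeline stage is testable end-to-end.  The signal model for one injection is

    area_analyte = (a*c + b*c**2) * attenuation(role, lot)
                   * exp(eps_session) * exp(eps_injection) * exp(eps_detection)
    area_is      = A_IS * attenuation_IS(role, lot)
                   * exp(eps_session) * exp(eps_injection)

with multiplicative lognormal noise throughout (proportional RSDs across a
256-fold concentration range imply heteroscedastic, not additive, noise).
The session and injection factors are shared between the analyte and its
internal standard — they model batch drift and injected volume — so the
analyte/IS area ratio cancels them and retains only the analyte-channel
detection noise.  Role attenuation encodes the sample-preparation physics:

* ``neat``            — direct injection of the chemical mix: no attenuation;
* ``qc_post_spiked``  — blank matrix extracted, spiked after: matrix effect
                        of the lot, ``(1 + ME_lot)``;
* ``qc_pre_spiked`` / ``standard`` / ``dilution`` — spiked before extraction
  in pooled blank matrix: extraction efficiency times matrix effect,
  ``EE * (1 + ME)``;
* ``blank``           — folded-normal baseline noise only.

Peak heights are proportional to areas (factor 0.25).  Patient samples draw a
plasma level around a drug-typical median, then derive saliva through the
salivary partition ratio and the collection-device retention factor, and
urine through a urinary accumulation scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .assay_design import AssayDesign, QC_LEVELS, default_design

HEIGHT_FACTOR = 0.25

#: fraction of drug surviving passage through the collection swab, per medium,
#: for the bundled panel (1 + mean observed loss/100)
RETENTION_SALIVA = {
    "AML": 0.03, "TEL": 0.38, "DOX": 0.00, "NBV": 0.02, "HCTZ": 0.46,
    "ATE": 0.79, "SCB": 0.86, "RAM": 1.02, "OLM": 1.02, "CHL": 0.70,
    "CLN": 1.24, "IDP": 1.33, "VAL": 0.90, "NFD": 0.62, "RAM-M": 1.13,
    "SCB-M": 0.98,
}
RETENTION_SOLVENT = {
    "AML": 0.06, "TEL": 0.00, "DOX": 0.01, "NBV": 0.03, "HCTZ": 0.665,
    "ATE": 0.535, "SCB": 0.70, "RAM": 0.69, "OLM": 0.985, "CHL": 0.86,
    "CLN": 0.715, "IDP": 1.195, "VAL": 0.87, "NFD": 0.87, "RAM-M": 0.88,
    "SCB-M": 0.775,
}

#: typical steady-state plasma concentrations (ng/ml) of treated patients;
#: drugs without a population value default to the geometric mid-range of the
#: calibration interval (STD9/16)
PLASMA_MEDIAN = {
    "ATE": 100.72, "NBV": 0.57, "AML": 6.29, "NFD": 36.22, "DOX": 7.12,
    "OLM": 244.94, "TEL": 45.82, "VAL": 749.78, "RAM": 0.73, "RAM-M": 11.12,
    "HCTZ": 10.82, "CHL": 50.50,
}

#: median saliva/plasma partition ratios (before device retention)
SP_RATIO = {
    "ATE": 0.38, "NBV": 9.50, "AML": 0.67, "NFD": 0.05, "DOX": 0.32,
    "OLM": 0.005, "TEL": 0.02, "VAL": 0.005, "RAM": 0.10, "RAM-M": 0.01,
    "HCTZ": 10.48, "CHL": 0.17,
}
DEFAULT_SP_RATIO = 0.5  # drugs without a reported ratio

ROLE_ORDER = ("standard", "qc_pre_spiked", "qc_post_spiked", "neat", "blank",
              "dilution")


@dataclass(frozen=True)
class AnalyteTruth:
    """Ground-truth generator parameters for one analyte."""

    name: str
    slope: float                     # response per ng/ml
    curvature: float                 # response per (ng/ml)^2, <0 = saturation
    extraction_efficiency: float = 0.90
    matrix_effect: float = -0.10     # mean lot ME as a fraction (suppression < 0)
    matrix_effect_lot_sd: float = 0.03
    salivette_retention: float = 1.0
    s_p_ratio: float = DEFAULT_SP_RATIO
    s_p_sigma: float = 0.5           # lognormal sd of the per-patient S/P ratio
    urine_scale: float = 10.0
    urine_sigma: float = 0.5
    plasma_median: float = 100.0
    pk_sigma: float = 0.5            # lognormal sd of plasma levels
    is_area: float = 5.0e5           # nominal IS area per injection
    blank_noise_sd: float = 1.0      # sd of blank analyte area

    @property
    def expected_sp_median(self) -> float:
        """Median observed saliva/plasma ratio: partition times retention."""
        return self.s_p_ratio * self.salivette_retention

    def base_response(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return self.slope * c + self.curvature * c**2


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic instrument and cohort.

    Defaults mirror the validation layout of the assay: six inter-day
    sessions, five intra-day replicates, six blank-matrix lots, 5% intra- and
    inter-day coefficients of variation.
    """

    analytes: dict[str, AnalyteTruth]
    intra_day_cv: float = 0.05
    inter_day_cv: float = 0.05
    n_sessions: int = 6
    n_intra_replicates: int = 5
    n_lots: int = 6
    n_dilution_levels: int = 5
    n_dilution_replicates: int = 3
    is_shares_matrix_effect: bool = True
    ensure_detectable: bool = True   # floor typical plasma levels so an adherent
                                     # intake is detectable at the median signal
    seed: int = 0

    def __post_init__(self) -> None:
        for cv in (self.intra_day_cv, self.inter_day_cv):
            if cv < 0:
                raise ValueError(f"CV must be non-negative, got {cv}")

    @classmethod
    def default(cls, design: AssayDesign | None = None, seed: int = 0,
                **overrides) -> "GeneratorConfig":
        design = design or default_design()
        truths = {}
        for spec in design:
            slope = 1.0e6 / spec.uloq          # ~1e6 counts at the top standard
            truths[spec.name] = AnalyteTruth(
                name=spec.name,
                slope=slope,
                curvature=-0.05 * slope / spec.uloq,   # 5% sag at ULOQ, monotone
                salivette_retention=RETENTION_SALIVA.get(spec.name, 1.0),
                s_p_ratio=SP_RATIO.get(spec.name, DEFAULT_SP_RATIO),
                plasma_median=PLASMA_MEDIAN.get(spec.name, spec.std9 / 16.0),
                blank_noise_sd=slope * spec.lloq / 10.0,
            )
        return cls(analytes=truths, seed=seed, **overrides)

    def noiseless(self, retention_one: bool = False) -> "GeneratorConfig":
        """Copy with all random variability switched off (correctness harness)."""
        truths = {
            k: replace(
                t,
                matrix_effect_lot_sd=0.0,
                s_p_sigma=0.0, pk_sigma=0.0, urine_sigma=0.0,
                blank_noise_sd=0.0,
                salivette_retention=1.0 if retention_one else t.salivette_retention,
            )
            for k, t in self.analytes.items()
        }
        return replace(self, analytes=truths, intra_day_cv=0.0, inter_day_cv=0.0)


# ---------------------------------------------------------------------------
# single-injection model
# ---------------------------------------------------------------------------

def simulate_response(
    conc: float,
    role: str,
    truth: AnalyteTruth,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    *,
    session: int = 1,
    replicate: int = 1,
    matrix_lot: int = 0,
    qc_level: str = "",
    session_factor: float = 1.0,
    lot_me: float | None = None,
) -> dict:
    """One injection record under the multiplicative signal model.

    `session_factor` and `lot_me` are the realised per-session and per-lot
    effects (drawn once per batch so records of a session/lot are coherent);
    when `lot_me` is None the configured mean matrix effect is used (pooled
    blank matrix).
    """
    me = truth.matrix_effect if lot_me is None else lot_me
    if role == "neat":
        atten, atten_is = 1.0, 1.0
    elif role == "qc_post_spiked":
        atten = 1.0 + me
        atten_is = atten if cfg.is_shares_matrix_effect else 1.0
    elif role in ("qc_pre_spiked", "standard", "dilution"):
        atten = truth.extraction_efficiency * (1.0 + me)
        atten_is = (1.0 + me) if cfg.is_shares_matrix_effect else 1.0
        atten_is *= truth.extraction_efficiency
    elif role == "blank":
        area = abs(rng.normal(0.0, truth.blank_noise_sd)) if truth.blank_noise_sd else 0.0
        return {
            "analyte": truth.name, "role": role, "qc_level": "",
            "session": session, "replicate": replicate, "matrix_lot": matrix_lot,
            "area_analyte": area, "area_is": truth.is_area,
            "height_analyte": HEIGHT_FACTOR * area, "nominal": np.nan,
        }
    else:
        raise ValueError(f"unknown role {role!r}")

    inj = np.exp(rng.normal(0.0, cfg.intra_day_cv)) if cfg.intra_day_cv else 1.0
    det = np.exp(rng.normal(0.0, cfg.intra_day_cv)) if cfg.intra_day_cv else 1.0
    area = truth.base_response(conc) * atten * session_factor * inj * det
    area_is = truth.is_area * atten_is * session_factor * inj
    return {
        "analyte": truth.name, "role": role, "qc_level": qc_level,
        "session": session, "replicate": replicate, "matrix_lot": matrix_lot,
        "area_analyte": float(area), "area_is": float(area_is),
        "height_analyte": HEIGHT_FACTOR * float(area), "nominal": float(conc),
    }


# ---------------------------------------------------------------------------
# validation batch
# ---------------------------------------------------------------------------

def expected_batch_size(cfg: GeneratorConfig, design: AssayDesign) -> int:
    """Closed-form record count of :func:`simulate_validation_batch`."""
    total = 0
    for spec in design:
        n_std = spec.n_std_levels * cfg.n_sessions
        n_qc = 3 * (
            cfg.n_sessions * cfg.n_intra_replicates       # pre-spiked
            + cfg.n_sessions * cfg.n_lots                 # post-spiked
            + cfg.n_sessions * cfg.n_intra_replicates     # neat
        )
        n_blank = cfg.n_lots
        n_dil = cfg.n_dilution_levels * cfg.n_dilution_replicates
        total += n_std + n_qc + n_blank + n_dil
    return total


def simulate_validation_batch(
    design: AssayDesign, cfg: GeneratorConfig
) -> tuple[pd.DataFrame, dict]:
    """Emit the full validation layout and its ground truth.

    Per analyte: standards at every level in every session; QC H/M/L in roles
    pre-spiked and neat (sessions x intra replicates) and post-spiked
    (sessions x lots); blanks per lot; and a descending dilution series
    around and below the design LLOQ for limit determination.

    Returns ``(records, truth)`` where `truth` holds, per analyte, the
    configured parameters and the realised per-lot matrix effects.
    """
    rng = np.random.default_rng(cfg.seed)
    records: list[dict] = []
    truth: dict = {"seed": cfg.seed, "analytes": {}}

    for spec in design:
        t = cfg.analytes[spec.name]
        sess_factors = (
            np.exp(rng.normal(0.0, cfg.inter_day_cv, size=cfg.n_sessions))
            if cfg.inter_day_cv else np.ones(cfg.n_sessions)
        )
        lot_me = t.matrix_effect + (
            rng.normal(0.0, t.matrix_effect_lot_sd, size=cfg.n_lots)
            if t.matrix_effect_lot_sd else np.zeros(cfg.n_lots)
        )
        truth["analytes"][spec.name] = {
            "slope": t.slope,
            "curvature": t.curvature,
            "extraction_efficiency": t.extraction_efficiency,
            "matrix_effect": t.matrix_effect,
            "matrix_effect_lot_realized": [float(x) for x in lot_me],
            "matrix_effect_lot_mean": float(np.mean(lot_me)),
            "blank_noise_sd": t.blank_noise_sd,
            "salivette_retention": t.salivette_retention,
            "s_p_ratio": t.s_p_ratio,
            "expected_sp_median": t.expected_sp_median,
        }

        levels = spec.calibration_levels()
        qc = dict(zip(QC_LEVELS, spec.qc_levels()))

        for s in range(1, cfg.n_sessions + 1):
            sf = float(sess_factors[s - 1])
            for c in levels:
                records.append(simulate_response(
                    c, "standard", t, cfg, rng, session=s, session_factor=sf))
            for level, c in qc.items():
                for r in range(1, cfg.n_intra_replicates + 1):
                    # pre-spiked QCs rotate through the blank-matrix lots so
                    # the EE estimator sees the same lot population as the
                    # post-spiked samples
                    lot = ((s - 1) * cfg.n_intra_replicates + r - 1) % cfg.n_lots + 1
                    records.append(simulate_response(
                        c, "qc_pre_spiked", t, cfg, rng, session=s, replicate=r,
                        matrix_lot=lot, qc_level=level, session_factor=sf,
                        lot_me=float(lot_me[lot - 1])))
                for lot in range(1, cfg.n_lots + 1):
                    records.append(simulate_response(
                        c, "qc_post_spiked", t, cfg, rng, session=s,
                        matrix_lot=lot, qc_level=level, session_factor=sf,
                        lot_me=float(lot_me[lot - 1])))
                for r in range(1, cfg.n_intra_replicates + 1):
                    records.append(simulate_response(
                        c, "neat", t, cfg, rng, session=s, replicate=r,
                        qc_level=level, session_factor=sf))

        for lot in range(1, cfg.n_lots + 1):
            records.append(simulate_response(
                0.0, "blank", t, cfg, rng, matrix_lot=lot))

        # dilution series: LLOQ*2 down to LLOQ/2**(n-2), one session
        dil_levels = spec.lloq * 2.0 ** np.arange(1, 1 - cfg.n_dilution_levels, -1)
        for c in dil_levels:
            for r in range(1, cfg.n_dilution_replicates + 1):
                records.append(simulate_response(
                    c, "dilution", t, cfg, rng, session=1, replicate=r,
                    session_factor=float(sess_factors[0])))

    return pd.DataFrame.from_records(records), truth


# ---------------------------------------------------------------------------
# device-retention experiment
# ---------------------------------------------------------------------------

def simulate_retention_experiment(
    cfg: GeneratorConfig,
    design: AssayDesign | None = None,
    n_replicates: int = 2,
    noise_cv: float = 0.03,
) -> pd.DataFrame:
    """Paired pre/post-device concentrations in solvent and saliva media."""
    design = design or default_design()
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for spec in design:
        t = cfg.analytes[spec.name]
        c0 = spec.qc_concentration("M")
        for medium, factor in (
            ("solvent", RETENTION_SOLVENT.get(spec.name, 1.0)),
            ("saliva", t.salivette_retention),
        ):
            for r in range(1, n_replicates + 1):
                noise = np.exp(rng.normal(0.0, noise_cv)) if noise_cv else 1.0
                rows.append(
                    {
                        "analyte": spec.name, "medium": medium, "replicate": r,
                        "pre_conc": c0, "post_conc": c0 * factor * noise,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# patient cohort
# ---------------------------------------------------------------------------

ADHERENT, PARTIAL, NON_ADHERENT = "adherent", "partial", "non_adherent"


def simulate_cohort(
    n_patients: int,
    adherence_mix: Sequence[float] = (0.7, 0.15, 0.15),
    cfg: GeneratorConfig | None = None,
    design: AssayDesign | None = None,
    max_drugs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a tri-matrix cohort with known adherence states.

    Each patient carries 1..`max_drugs` prescribed parent drugs and an
    adherence state drawn from `adherence_mix` = (adherent, partial,
    non-adherent).  Taken drugs produce a plasma level lognormal around the
    drug-typical median, a saliva level through the salivary partition ratio
    and device retention, and a urine level through the urinary scale; drugs
    not taken yield zero in every matrix.  Partial patients skip a random
    non-empty proper subset of their drugs (all of them when only one is
    prescribed).

    Returns ``(samples, truth)``: long-format samples
    (patient, drug, matrix, conc_ng_ml, prescribed) and per-(patient, drug)
    intake truth.
    """
    mix = np.asarray(adherence_mix, dtype=float)
    if mix.size != 3 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("adherence_mix must be three fractions summing to 1")
    design = design or default_design()
    cfg = cfg or GeneratorConfig.default(design)
    rng = np.random.default_rng(cfg.seed + 2)

    parent_drugs = [s.name for s in design if not s.name.endswith("-M")]
    lod = {s.name: s.lod for s in design}

    sample_rows, truth_rows = [], []
    for pid in range(1, n_patients + 1):
        state = rng.choice([ADHERENT, PARTIAL, NON_ADHERENT], p=mix)
        n_drugs = int(rng.integers(1, max_drugs + 1))
        drugs = list(rng.choice(parent_drugs, size=n_drugs, replace=False))
        if state == ADHERENT:
            skipped = set()
        elif state == NON_ADHERENT:
            skipped = set(drugs)
        else:
            k = int(rng.integers(1, n_drugs)) if n_drugs > 1 else n_drugs
            skipped = set(rng.choice(drugs, size=k, replace=False))

        for drug in drugs:
            t = cfg.analytes[drug]
            taken = drug not in skipped
            if taken:
                level = t.plasma_median
                if cfg.ensure_detectable and t.expected_sp_median > 0:
                    level = max(level, 2.0 * lod[drug] / t.expected_sp_median)
                plasma = level * (
                    np.exp(rng.normal(0.0, t.pk_sigma)) if t.pk_sigma else 1.0)
                saliva = (
                    plasma * t.s_p_ratio * t.salivette_retention
                    * (np.exp(rng.normal(0.0, t.s_p_sigma)) if t.s_p_sigma else 1.0)
                )
                urine = plasma * t.urine_scale * (
                    np.exp(rng.normal(0.0, t.urine_sigma)) if t.urine_sigma else 1.0)
            else:
                plasma = saliva = urine = 0.0
            for matrix, conc in (("saliva", saliva), ("plasma", plasma),
                                 ("urine", urine)):
                sample_rows.append(
                    {"patient": pid, "drug": drug, "matrix": matrix,
                     "conc_ng_ml": float(conc), "prescribed": True}
                )
            truth_rows.append(
                {"patient": pid, "drug": drug, "taken": taken, "state": state}
            )
    return pd.DataFrame(sample_rows), pd.DataFrame(truth_rows)
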