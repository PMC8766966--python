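"""Calibration and quality-control concentration scheme for the salivary panel.

The assay quantifies each analyte against a 9-point calibration curve built by
serial 1:1 dilution of the top standard (STD9 = ULOQ), giving a dyadic ladder
STD1..STD9 with STD1 = STD9 / 2**8 as the LLOQ.  Three quality-control levels
(H, M, L) are fixed fractions of STD9 (0.8, 0.1 and 0.01 by default).  The
limit of detection is an empirical per-analyte datum determined from a
signal-to-noise dilution series, not derived from the LLOQ.

Reported concentrations are rounded half-away-from-zero to a configurable
number of decimal places (2 by default); all arithmetic keeps full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidDesignError

DEFAULT_QC_FRACTIONS: tuple[float, float, float] = (0.8, 0.1, 0.01)
DEFAULT_N_STD_LEVELS = 9
DEFAULT_ROUNDING_DP = 2

QC_LEVELS = ("H", "M", "L")


def round_reported(value: float, dp: int = DEFAULT_ROUNDING_DP) -> float:
    """Round half-away-from-zero to `dp` decimals (reporting convention).

    Python's builtin round() is banker's rounding; reported concentrations
    follow the half-away convention instead (0.0390625 -> 0.04 at 2 dp).
    """
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def build_calibration_levels(std9: float, n_levels: int = DEFAULT_N_STD_LEVELS) -> np.ndarray:
    """Return the calibration ladder STD1..STDn (strictly increasing, ng/ml).

    Level k (1-based from the lowest) equals ``std9 / 2**(n_levels - k)``, the
    result of ``n_levels - k`` successive 1:1 dilutions of the top standard.
    Values are returned at full precision; apply :func:`round_reported` when
    printing.
    """
    if not np.isfinite(std9) or std9 <= 0:
        raise InvalidDesignError(f"STD9 must be a positive concentration, got {std9!r}")
    if n_levels < 1:
        raise InvalidDesignError(f"need at least one calibration level, got {n_levels}")
    k = np.arange(1, n_levels + 1)
    return std9 / 2.0 ** (n_levels - k)


def build_qc_levels(
    std9: float,
    qc_fractions: Sequence[float] = DEFAULT_QC_FRACTIONS,
) -> tuple[float, float, float]:
    """Return the (H, M, L) quality-control concentrations for a top standard."""
    if not np.isfinite(std9) or std9 <= 0:
        raise InvalidDesignError(f"STD9 must be a positive concentration, got {std9!r}")
    fr = tuple(float(f) for f in qc_fractions)
    if len(fr) != 3:
        raise InvalidDesignError(f"expected three QC fractions (H, M, L), got {len(fr)}")
    if any(not (0 < f <= 1) for f in fr):
        raise InvalidDesignError(f"QC fractions must lie in (0, 1], got {fr}")
    if not (fr[0] > fr[1] > fr[2]):
        raise InvalidDesignError(f"QC fractions must be strictly decreasing, got {fr}")
    return (std9 * fr[0], std9 * fr[1], std9 * fr[2])


@dataclass(frozen=True)
class AnalyteSpec:
    """Assay design for one analyte.

    Parameters
    ----------
    name
        Short analyte code, e.g. ``"VAL"``.
    std9
        Top-standard concentration (ULOQ), ng/ml.
    lod
        Empirical limit of detection, ng/ml.  Must be below the LLOQ.
    is_name
        Code of the internal standard assigned to this analyte.
    n_std_levels
        Number of calibration standards (dyadic ladder), default 9.
    qc_fractions
        (H, M, L) fractions of STD9, default (0.8, 0.1, 0.01).
    polarity
        Ionisation mode, ``"positive"`` or ``"negative"``; metadata only.
    """

    name: str
    std9: float
    lod: float
    is_name: str
    n_std_levels: int = DEFAULT_N_STD_LEVELS
    qc_fractions: tuple[float, float, float] = DEFAULT_QC_FRACTIONS
    polarity: str = "positive"

    def __post_init__(self) -> None:
        if self.std9 <= 0:
            raise InvalidDesignError(f"{self.name}: STD9 must be positive, got {self.std9}")
        if self.n_std_levels < 2:
            raise InvalidDesignError(f"{self.name}: need >= 2 standard levels")
        build_qc_levels(self.std9, self.qc_fractions)  # validates fractions
        if self.polarity not in ("positive", "negative"):
            raise InvalidDesignError(f"{self.name}: unknown polarity {self.polarity!r}")
        if not (0 < self.lod < self.lloq):
            raise InvalidDesignError(
                f"{self.name}: LOD ({self.lod}) must lie in (0, LLOQ={self.lloq:g})"
            )

    @property
    def lloq(self) -> float:
        """Lowest standard (STD1) at full precision, ng/ml."""
        return self.std9 / 2.0 ** (self.n_std_levels - 1)

    @property
    def uloq(self) -> float:
        """Upper limit of quantification (STD9), ng/ml."""
        return self.std9

    def calibration_levels(self) -> np.ndarray:
        return build_calibration_levels(self.std9, self.n_std_levels)

    def qc_levels(self) -> tuple[float, float, float]:
        return build_qc_levels(self.std9, self.qc_fractions)

    def qc_concentration(self, level: str) -> float:
        return dict(zip(QC_LEVELS, self.qc_levels()))[level]


@dataclass
class AssayDesign:
    """The full panel: per-analyte specs plus internal-standard metadata."""

    analytes: dict[str, AnalyteSpec]
    internal_standards: Mapping[str, float] = field(default_factory=dict)
    rounding_dp: int = DEFAULT_ROUNDING_DP

    def __post_init__(self) -> None:
        for name, spec in self.analytes.items():
            if name != spec.name:
                raise InvalidDesignError(f"analyte key {name!r} != spec name {spec.name!r}")
            if self.internal_standards and spec.is_name not in self.internal_standards:
                raise InvalidDesignError(
                    f"{name}: internal standard {spec.is_name!r} not declared"
                )

    @classmethod
    def from_specs(cls, specs: Iterable[AnalyteSpec], **kw) -> "AssayDesign":
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise InvalidDesignError("analyte codes must be unique")
        return cls(analytes={s.name: s for s in specs}, **kw)

    def __iter__(self):
        return iter(self.analytes.values())

    def __len__(self) -> int:
        return len(self.analytes)

    def __getitem__(self, name: str) -> AnalyteSpec:
        return self.analytes[name]

    def round(self, value: float) -> float:
        return round_reported(value, self.rounding_dp)

    def limits(self) -> dict[str, tuple[float, float]]:
        """Per-analyte (LOD, LLOQ) pairs, ng/ml."""
        return {s.name: (s.lod, s.lloq) for s in self}

    # --- JSON round-trip ---------------------------------------------------

    @classmethod
    def from_dict(cls, obj: Mapping) -> "AssayDesign":
        specs = []
        for rec in obj["analytes"]:
            specs.append(
                AnalyteSpec(
                    name=rec["name"],
                    std9=float(rec["std9_ng_ml"]),
                    lod=float(rec["lod_ng_ml"]),
                    is_name=rec["is_name"],
                    n_std_levels=int(rec.get("n_std_levels", DEFAULT_N_STD_LEVELS)),
                    qc_fractions=tuple(rec.get("qc_fractions", DEFAULT_QC_FRACTIONS)),
                    polarity=rec.get("polarity", "positive"),
                )
            )
        return cls.from_specs(
            specs,
            internal_standards=dict(obj.get("internal_standards", {})),
            rounding_dp=int(obj.get("rounding_dp", DEFAULT_ROUNDING_DP)),
        )

    def to_dict(self) -> dict:
        return {
            "rounding_dp": self.rounding_dp,
            "internal_standards": dict(self.internal_standards),
            "analytes": [
                {
                    "name": s.name,
                    "std9_ng_ml": s.std9,
                    "lod_ng_ml": s.lod,
                    "is_name": s.is_name,
                    "n_std_levels": s.n_std_levels,
                    "qc_fractions": list(s.qc_fractions),
                    "polarity": s.polarity,
                }
                for s in self
            ],
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "AssayDesign":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")


def default_design() -> AssayDesign:
    """The bundled 16-analyte antihypertensive panel (14 drugs + 2 metabolites)."""
    with resources.files("salitdm.data").joinpath("default_assay.json").open(
        encoding="utf-8"
    ) as fh:
        return AssayDesign.from_dict(json.load(fh))
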