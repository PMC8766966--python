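"""File formats and report rendering.

All tables are comma-separated UTF-8 with a mandatory header and period
decimal separator.  The measurement table is long format, one row per
injection, with the columns of
:data:`salitdm.validation.MEASUREMENT_COLUMNS`; the ``dilution`` role marks
the sub-LLOQ series used for limit determination.  Rendered reports carry
percentages at 1 decimal place and concentrations at 2; the JSON twin keeps
full precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adherence import ConcordanceResult
from .assay_design import AssayDesign, round_reported
from .errors import ParseError
from .validation import MEASUREMENT_COLUMNS, ROLES, ValidationReport

_NOMINAL_ROLES = {"standard", "qc_pre_spiked", "qc_post_spiked", "neat", "dilution"}
_NUMERIC = ("area_analyte", "area_is", "height_analyte")


def read_measurements(
    path: str | Path,
    design: AssayDesign | None = None,
    response_mode: str | None = None,
) -> pd.DataFrame:
    """Read and validate a long-format measurement table.

    Error messages name the offending file line (header = line 1).  When a
    design is given, analyte codes are checked against it; with
    ``response_mode="is_ratio"`` the ``area_is`` column is required.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns and c != "area_is"]
    if missing:
        raise ParseError(f"{path.name}: missing column(s) {missing}")
    if response_mode == "is_ratio" and "area_is" not in df.columns:
        raise ParseError(
            f"{path.name}: response_mode=is_ratio requires an area_is column"
        )
    if "area_is" not in df.columns:
        df["area_is"] = np.nan

    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        if row["role"] not in ROLES:
            raise ParseError(f"{path.name}:{line}: unknown role {row['role']!r}")
        for col in _NUMERIC:
            v = row[col]
            if pd.notna(v) and not isinstance(v, (int, float, np.number)):
                raise ParseError(f"{path.name}:{line}: non-numeric {col} {v!r}")
            if pd.notna(v) and v < 0:
                raise ParseError(f"{path.name}:{line}: negative {col} {v!r}")
        has_nominal = pd.notna(row["nominal"])
        if row["role"] in _NOMINAL_ROLES and not has_nominal:
            raise ParseError(
                f"{path.name}:{line}: role {row['role']!r} requires a nominal"
            )
        if row["role"] in ("blank", "patient") and has_nominal:
            raise ParseError(
                f"{path.name}:{line}: role {row['role']!r} must not carry a nominal"
            )
        if design is not None and row["analyte"] not in design.analytes:
            raise ParseError(
                f"{path.name}:{line}: unknown analyte {row['analyte']!r}"
            )
    return df


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in MEASUREMENT_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

#: column order of the rendered validation table
VALIDATION_RENDER_COLUMNS = (
    "analyte", "qc_level", "nominal", "n", "accuracy_pct",
    "intra_day_rsd", "inter_day_rsd",
    "recovery_mean", "recovery_rsd", "ee_mean", "ee_rsd",
    "me_mean", "me_sd", "isnme_mean", "isnme_sd",
    "accuracy_pass", "precision_pass", "passes",
)

_PCT_COLS = (
    "accuracy_pct", "intra_day_rsd", "inter_day_rsd", "recovery_mean",
    "recovery_rsd", "ee_mean", "ee_rsd", "me_mean", "me_sd", "isnme_mean",
    "isnme_sd",
)


def _round_pct(x):
    return np.nan if pd.isna(x) else round_reported(x, 1)


def render_validation_report(
    report: ValidationReport, out_dir: str | Path, stem: str = "validation_report"
) -> tuple[Path, Path]:
    """Write the delimited table (rounded) and its full-precision JSON twin."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tab = report.table.copy()
    csv_path = out_dir / f"{stem}.csv"
    json_path = out_dir / f"{stem}.json"

    rendered = tab.reindex(columns=[c for c in VALIDATION_RENDER_COLUMNS
                                    if c in tab.columns])
    for col in _PCT_COLS:
        if col in rendered.columns:
            rendered[col] = rendered[col].map(_round_pct)
    if "nominal" in rendered.columns:
        rendered["nominal"] = rendered["nominal"].map(
            lambda x: round_reported(x, 2) if pd.notna(x) else np.nan)
    rendered.to_csv(csv_path, index=False)

    payload = {
        "table": tab.replace({np.nan: None}).to_dict(orient="records"),
        "curves": {
            a: {str(s): c.to_dict() for s, c in by_session.items()}
            for a, by_session in report.curves.items()
        },
        "limits": {
            a: {"lloq": l.lloq, "lod": l.lod} for a, l in report.limits.items()
        },
        "selectivity": {
            a: df.replace({np.nan: None}).to_dict(orient="records")
            for a, df in report.selectivity.items()
        },
    }
    json_path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return csv_path, json_path


def render_concordance(
    result: ConcordanceResult,
    out_dir: str | Path,
    sp_table: pd.DataFrame | None = None,
    stem: str = "concordance",
) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(result.to_dict(), indent=2), encoding="utf-8")
    if sp_table is not None:
        rendered = sp_table.copy()
        for col in rendered.columns:
            if rendered[col].dtype.kind == "f":
                rendered[col] = rendered[col].map(
                    lambda x: round_reported(x, 2) if pd.notna(x) else np.nan)
        rendered.to_csv(out_dir / "sp_summary.csv", index=False)
    return json_path


# ---------------------------------------------------------------------------
# run provenance
# ---------------------------------------------------------------------------

def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_run_manifest(
    out_dir: str | Path,
    subcommand: str,
    params: dict,
    seed: int | None = None,
    inputs: list[str | Path] = (),
) -> Path:
    """Record config hash, seed, input checksums and package version."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params_json = json.dumps(params, sort_keys=True, default=str)
    manifest = {
        "subcommand": subcommand,
        "package_version": __version__,
        "seed": seed,
        "config_hash": hashlib.sha256(params_json.encode()).hexdigest(),
        "params": json.loads(params_json),
        "inputs": {str(p): file_checksum(p) for p in inputs},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return path
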