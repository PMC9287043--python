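"""Reading and writing the toolkit's tabular formats.

The native transition-table format is a comma-separated UTF-8 file with a
header row and one record per analyte x acquisition mode x quantitation
level x channel x replicate x concentration.  A reader-side adapter maps
Skyline "Transition Results" style exports onto the same records, so
chromatogram areas integrated elsewhere can flow straight into the
pipeline.  All writers use deterministic column order and enough digits
for values to round-trip.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("satcal")

__all__ = [
    "NATIVE_COLUMNS",
    "TableValidationError",
    "read_transition_table",
    "write_transition_table",
    "write_results",
]

NATIVE_COLUMNS = [
    "analyte",
    "mode",
    "quant_level",
    "channel",
    "replicate",
    "concentration",
    "area",
    "mz_observed",
    "mz_theoretical",
    "rt",
]
MANDATORY = NATIVE_COLUMNS[:7]
KEY = ["analyte", "mode", "quant_level", "channel", "replicate", "concentration"]

FLOAT_FORMAT = "%.17g"


class TableValidationError(ValueError):
    """Structurally invalid transition table (missing columns, duplicate keys)."""


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop invalid rows, reporting 1-based file line numbers (header = line 1)."""
    issues = []
    keep = np.ones(len(df), dtype=bool)
    line = df.index.to_numpy() + 2  # header occupies line 1
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    bad = ~np.isfinite(conc) | (conc <= 0)
    for ln in line[bad & keep]:
        issues.append(f"line {ln}: concentration must be a positive number")
    keep &= ~bad
    area = pd.to_numeric(df["area"], errors="coerce")
    # empty area cells are missing measurements, not zeros: keep as NaN
    bad = area.notna().to_numpy() & ~(area.to_numpy(float) >= 0)
    bad |= np.isinf(area.to_numpy(float))
    for ln in line[bad & keep]:
        issues.append(f"line {ln}: area must be finite and non-negative")
    keep &= ~bad
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad = (~np.isfinite(rep) | (rep < 1) | (rep != rep.round())).to_numpy()
    for ln in line[bad & keep]:
        issues.append(f"line {ln}: replicate must be an integer >= 1")
    keep &= ~bad
    out = df[keep].copy()
    out["concentration"] = conc[keep].astype(float)
    out["area"] = area[keep].astype(float)
    out["replicate"] = rep[keep].astype(int)
    return out, issues


def _finalize(df: pd.DataFrame) -> pd.DataFrame:
    for col in NATIVE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[NATIVE_COLUMNS].reset_index(drop=True)
    dup = df.duplicated(subset=KEY)
    if dup.any():
        first = df[dup].iloc[0]
        raise TableValidationError(
            "duplicate record key "
            f"({first['analyte']}, {first['mode']}, {first['quant_level']}, "
            f"{first['channel']}, {first['replicate']}, {first['concentration']})"
        )
    return df


def read_transition_table(
    path,
    dialect: str = "native",
    concentration_column: str = "Analyte Concentration",
    mode_column: str | None = None,
    default_mode: str = "unknown",
) -> pd.DataFrame:
    """Read a transition table into validated native records.

    ``dialect="native"`` expects the package's own column layout;
    ``dialect="skyline-transition-results"`` adapts a Skyline Transition
    Results report, taking the analyte from Peptide/Molecule, the channel
    from Fragment Ion ("precursor", "precursor [M+1]", ... become MS1
    isotope indices; anything else is an MS2 fragment), the concentration
    from ``concentration_column``, and the replicate index from the order
    of Replicate Name values within each group.

    Rows failing value-level validation are dropped and reported with
    their line numbers in ``df.attrs["issues"]`` (and the log); missing
    mandatory columns or duplicate keys raise ``TableValidationError``.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if dialect == "native":
        missing = [c for c in MANDATORY if c not in raw.columns]
        if missing:
            raise TableValidationError(f"missing mandatory column(s): {', '.join(missing)}")
        df = raw.copy()
    elif dialect == "skyline-transition-results":
        df = _from_skyline(raw, concentration_column, mode_column, default_mode)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df["channel"] = df["channel"].astype(str)
    df, issues = _validate_rows(df)
    for col in ("mz_observed", "mz_theoretical", "rt"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df = _finalize(df)
    for msg in issues:
        log.warning("%s: %s", path.name, msg)
    df.attrs["issues"] = issues
    return df


_SKYLINE_ANALYTE = ("Peptide", "Molecule", "Peptide Sequence", "Molecule Name")


def _from_skyline(raw, concentration_column, mode_column, default_mode):
    analyte_col = next((c for c in _SKYLINE_ANALYTE if c in raw.columns), None)
    if analyte_col is None:
        raise TableValidationError(
            "missing mandatory column(s): one of " + "/".join(_SKYLINE_ANALYTE)
        )
    for col in ("Fragment Ion", "Area", concentration_column, "Replicate Name"):
        if col not in raw.columns:
            raise TableValidationError(f"missing mandatory column(s): {col}")

    frag = raw["Fragment Ion"].fillna("")
    is_precursor = frag.str.lower().str.startswith("precursor")
    iso_index = frag.str.extract(r"\[M\+(\d+)\]", expand=False).fillna("0")
    channel = np.where(is_precursor, iso_index, frag)
    quant = np.where(is_precursor, "MS1", "MS2")
    mz_theo_col = np.where(is_precursor, "Precursor Mz", "Product Mz")
    mz_theo = [
        raw[c].iloc[i] if c in raw.columns else np.nan
        for i, c in enumerate(mz_theo_col)
    ]
    df = pd.DataFrame(
        {
            "analyte": raw[analyte_col],
            "mode": raw[mode_column] if mode_column else default_mode,
            "quant_level": quant,
            "channel": channel,
            "concentration": raw[concentration_column],
            "area": raw["Area"],
            "mz_theoretical": mz_theo,
            "rt": raw["Retention Time"] if "Retention Time" in raw.columns else np.nan,
        }
    )
    # replicate index = 1-based rank of the injection within its group
    df["replicate"] = (
        raw.groupby(
            [df["analyte"], df["quant_level"], df["channel"], df["concentration"]]
        )["Replicate Name"]
        .rank(method="dense")
        .astype(int)
    )
    df.index = raw.index
    return df


def write_transition_table(df: pd.DataFrame, path) -> None:
    df = df[NATIVE_COLUMNS]
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_results(
    fits=None,
    summaries=None,
    corrections=None,
    outdir=".",
) -> dict:
    """Write fit, summary and correction reports as CSV plus JSON mirrors.

    ``fits`` is a list of CalibrationFit, ``summaries`` a list of
    ModeSummary, ``corrections`` a DataFrame from ``corrections_table``.
    Empty inputs still produce headers-only files so downstream tooling
    sees a stable layout.  Returns the mapping of report name to path.
    """
    from .summary import summary_table  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}

    fit_cols = [
        "analyte",
        "mode",
        "quant_level",
        "C",
        "R",
        "b",
        "s",
        "slope",
        "lloq",
        "uloq",
        "ldr",
        "r2",
        "residual_norm",
        "converged",
        "linear_fallback",
        "uloq_censored",
        "lloq_defined",
        "delta",
    ]
    fit_rows = []
    for f in fits or []:
        d = dataclasses.asdict(f)
        fit_rows.append({c: d.get(c) for c in fit_cols})
    fits_df = pd.DataFrame(fit_rows, columns=fit_cols)
    fits_df.to_csv(outdir / "fits.csv", index=False, float_format=FLOAT_FORMAT)
    with open(outdir / "fits.json", "w") as fh:
        json.dump(fit_rows, fh, indent=2, sort_keys=True, default=_jsonable)
    written["fits"] = outdir / "fits.csv"

    sum_df = summary_table(list(summaries)) if summaries else summary_table([])
    sum_df.to_csv(outdir / "summaries.csv", index=False, float_format=FLOAT_FORMAT)
    with open(outdir / "summaries.json", "w") as fh:
        json.dump(
            sum_df.to_dict(orient="records"), fh, indent=2, sort_keys=True, default=_jsonable
        )
    written["summaries"] = outdir / "summaries.csv"

    corr_cols = [
        "analyte",
        "mode",
        "concentration",
        "replicate",
        "method",
        "flagged",
        "isotope_index",
        "original",
        "corrected",
        "scale",
    ]
    if corrections is None or (hasattr(corrections, "empty") and corrections.empty):
        corrections = pd.DataFrame(columns=corr_cols)
    corrections = corrections.reindex(columns=corr_cols)
    corrections.to_csv(outdir / "corrections.csv", index=False, float_format=FLOAT_FORMAT)
    written["corrections"] = outdir / "corrections.csv"
    return written
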