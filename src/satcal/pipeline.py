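"""End-to-end analysis driver: records -> corrections -> fits -> summaries."""

from __future__ import annotations

import pandas as pd

from .calibration import CalibrationError, CalibrationSeries, characterize
from .corrections import apply_corrections, corrections_table
from .isotopes import IsotopeDistribution
from .summary import DEFAULT_Z_THRESHOLD, SummaryError, summarize_mode

__all__ = ["analyze"]


def analyze(
    records: pd.DataFrame,
    distributions: dict[str, IsotopeDistribution] | None = None,
    quant_level: str = "MS1",
    delta: float = 0.2,
    tol: float = 0.2,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> dict:
    """Run the full semi-quantitation pipeline over a transition table.

    For every analyte x mode: compute the applicable saturation-correction
    variants, fit each variant's calibration curve, and derive the figures
    of merit.  Per mode and variant, aggregate analytes into an
    outlier-excluded summary (skipped when fewer than three analytes have
    defined metrics).

    ``distributions`` maps analyte id to its theoretical isotopologue
    distribution; analytes without one only get the MS2-based correction.

    Returns ``{"fits": [CalibrationFit], "summaries": [ModeSummary],
    "corrections": DataFrame, "errors": [(analyte, mode, message)]}``.
    """
    distributions = distributions or {}
    fits = []
    corr_records = []
    errors = []
    by_variant_mode: dict[tuple[str, str], list] = {}
    for (analyte, mode), _ in records.groupby(["analyte", "mode"]):
        try:
            series = CalibrationSeries.from_records(
                records, analyte, mode, quant_level=quant_level
            )
            variants = apply_corrections(
                series, distributions.get(analyte), tol=tol
            )
        except (CalibrationError, ValueError) as exc:
            errors.append((analyte, mode, str(exc)))
            continue
        for tag, (variant_series, crecs) in variants.items():
            corr_records.extend(crecs)
            try:
                fit = characterize(variant_series, delta=delta)
            except CalibrationError as exc:
                errors.append((analyte, mode, f"{tag}: {exc}"))
                continue
            fit.notes.append(f"correction={tag}")
            fits.append((tag, fit))
            by_variant_mode.setdefault((mode, tag), []).append(fit)
    summaries = []
    for (mode, tag), mode_fits in sorted(by_variant_mode.items()):
        try:
            summaries.append(
                summarize_mode(mode_fits, threshold=z_threshold, correction=tag)
            )
        except SummaryError as exc:
            errors.append(("*", mode, f"{tag}: {exc}"))
    return {
        "fits": [f for _, f in fits],
        "fit_tags": [t for t, _ in fits],
        "summaries": summaries,
        "corrections": corrections_table(corr_records),
        "errors": errors,
    }
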