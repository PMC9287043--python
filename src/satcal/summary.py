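"""Per-acquisition-mode aggregation of figures of merit.

Individual analytes occasionally produce wild LLOQ or LDR estimates —
integration problems, acquisition dropouts, fits pulled off by a bad
level.  Before averaging across a panel, such analytes are excluded with
the Iglewicz–Hoaglin modified z-score, a median/MAD-based statistic that
tolerates the very outliers it is hunting.  The retained analytes are
then summarized as mean ± SD per mode and correction variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationFit

__all__ = [
    "ModeSummary",
    "SummaryError",
    "modified_zscore",
    "summarize_mode",
    "correction_gain",
    "summary_table",
]

#: Iglewicz & Hoaglin's recommended outlier cutoff for |modified z|.
DEFAULT_Z_THRESHOLD = 3.5

_MAD_SCALE = 0.6745  # makes MAD-based scores ~N(0,1) under normality
_MEANAD_SCALE = 1.253314  # fallback scale when MAD collapses to zero


class SummaryError(ValueError):
    """Too few defined metrics to summarize."""


def modified_zscore(values) -> np.ndarray:
    """Iglewicz–Hoaglin modified z-scores, M = 0.6745 (x - median) / MAD.

    When the MAD is zero (more than half the values tie) the mean absolute
    deviation scaled by 1.253314 is used instead; if that is also zero the
    data are constant and every score is 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise SummaryError("need >= 3 values for outlier scores")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        return _MAD_SCALE * (x - med) / mad
    mean_ad = np.mean(np.abs(x - med))
    if mean_ad > 0:
        return (x - med) / (_MEANAD_SCALE * mean_ad)
    return np.zeros_like(x)


@dataclass
class ModeSummary:
    """Outlier-excluded mean ± SD of LLOQ and LDR for one acquisition mode."""

    mode: str
    quant_level: str
    correction: str
    n_input: int
    n_retained: int
    lloq_mean: float
    lloq_sd: float
    ldr_mean: float
    ldr_sd: float
    retained: list = field(default_factory=list)
    excluded: list = field(default_factory=list)  # (analyte, reason)


def summarize_mode(
    fits: list[CalibrationFit],
    threshold: float = DEFAULT_Z_THRESHOLD,
    correction: str = "uncorrected",
) -> ModeSummary:
    """Aggregate per-analyte fits of one mode into mean ± SD with exclusions.

    Analytes are excluded when their fit failed, a metric is undefined, or
    the |modified z-score| of their LLOQ or LDR exceeds ``threshold``
    (union over the two metrics).  At least three analytes with defined
    metrics are required.
    """
    if not fits:
        raise SummaryError("no fits to summarize")
    modes = {f.mode for f in fits}
    quant = {f.quant_level for f in fits}
    if len(modes) > 1 or len(quant) > 1:
        raise SummaryError("fits mix acquisition modes or quant levels")
    excluded = []
    defined = []
    for f in fits:
        if not f.converged:
            excluded.append((f.analyte, "fit_failed"))
        elif f.lloq is None or not f.lloq_defined or f.ldr is None:
            excluded.append((f.analyte, "undefined_metric"))
        else:
            defined.append(f)
    if len(defined) < 3:
        raise SummaryError(
            f"only {len(defined)} analytes with defined metrics (< 3)"
        )
    lloq = np.array([f.lloq for f in defined])
    ldr = np.array([f.ldr for f in defined])
    z_lloq = np.abs(modified_zscore(lloq))
    z_ldr = np.abs(modified_zscore(ldr))
    keep = (z_lloq <= threshold) & (z_ldr <= threshold)
    for f, k, zl, zd in zip(defined, keep, z_lloq, z_ldr):
        if not k:
            metric = "lloq" if zl > threshold else "ldr"
            excluded.append((f.analyte, f"{metric}_outlier_z={max(zl, zd):.2f}"))
    retained = [f for f, k in zip(defined, keep) if k]
    lloq_r, ldr_r = lloq[keep], ldr[keep]
    return ModeSummary(
        mode=modes.pop(),
        quant_level=quant.pop(),
        correction=correction,
        n_input=len(fits),
        n_retained=len(retained),
        lloq_mean=float(lloq_r.mean()),
        lloq_sd=float(lloq_r.std(ddof=1)) if lloq_r.size > 1 else 0.0,
        ldr_mean=float(ldr_r.mean()),
        ldr_sd=float(ldr_r.std(ddof=1)) if ldr_r.size > 1 else 0.0,
        retained=[f.analyte for f in retained],
        excluded=excluded,
    )


def correction_gain(before: ModeSummary, after: ModeSummary) -> float:
    """Relative gain in mean LDR from a correction, in percent."""
    if before.mode != after.mode or before.quant_level != after.quant_level:
        raise ValueError("summaries refer to different modes or quant levels")
    if set(before.retained) | {a for a, _ in before.excluded} != set(
        after.retained
    ) | {a for a, _ in after.excluded}:
        raise ValueError("summaries cover different analyte sets")
    return float(100.0 * (after.ldr_mean - before.ldr_mean) / before.ldr_mean)


def summary_table(summaries: list[ModeSummary]) -> pd.DataFrame:
    """Tabulate summaries in the mode x correction layout of a report table."""
    return pd.DataFrame(
        {
            "mode": [s.mode for s in summaries],
            "quant_level": [s.quant_level for s in summaries],
            "correction": [s.correction for s in summaries],
            "n_retained": [s.n_retained for s in summaries],
            "n_excluded": [s.n_input - s.n_retained for s in summaries],
            "lloq_mean": [s.lloq_mean for s in summaries],
            "lloq_sd": [s.lloq_sd for s in summaries],
            "ldr_mean": [s.ldr_mean for s in summaries],
            "ldr_sd": [s.ldr_sd for s in summaries],
            "excluded": ["; ".join(f"{a}:{r}" for a, r in s.excluded) for s in summaries],
        }
    )
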