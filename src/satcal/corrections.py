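"""Detection and post-acquisition correction of detector saturation.

An ion-counting ToF detector under-reports intense peaks, bending the top
of a calibration curve.  Two observable signatures expose this:

* **MS1 isotope signature** — the observed ratio of the first isotope to
  the monoisotopic peak (I1/I0) rises above the theoretical natural
  ratio, because the more intense monoisotopic peak saturates first.
* **MS2 signature** — the ratio of MS1 precursor intensity to the summed
  MS2 fragment intensities drops at high concentration, because the CID
  fragments divide the ion current over several smaller (unsaturated)
  peaks.

Each signature drives a correction:

* **Isotope correction** — the saturated monoisotopic intensity is
  replaced by the intensity of the lowest unsaturated isotope peak k*
  scaled by the theoretical ratio I0_th / Ik*_th.
* **MS2 correction** — the saturated MS1 intensity is replaced by
  k_hat * sum(MS2), where k_hat is the robust MS1/sum(MS2) ratio
  established from unsaturated low-concentration levels.

Both corrections are computed per flagged concentration level; unflagged
levels pass through unchanged.  When both are possible, compute both and
compare — the better method varies between analytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CalibrationError, CalibrationSeries, estimate_noise
from .isotopes import IsotopeDistribution

__all__ = [
    "SaturationFlags",
    "CorrectedIntensity",
    "SaturationError",
    "detect_saturation_isotope",
    "isotope_correct",
    "detect_saturation_ms2",
    "ms2_correct",
    "apply_corrections",
    "corrections_table",
]

DEFAULT_TOL = 0.2


class SaturationError(ValueError):
    """Series cannot support the requested detection/correction."""


@dataclass
class SaturationFlags:
    """Per-level, per-channel saturation calls plus diagnostics.

    ``channel_flags[channel][i]`` says whether ``channel`` is saturated at
    ``levels[i]``.  Flags are monotone-closed in concentration: physical
    saturation cannot recede as more analyte is loaded, so a flag at one
    level implies flags at all higher levels.  ``kstar[i]`` is the lowest
    unsaturated MS1 isotope index at level i (None when every channel is
    saturated, i.e. the level is uncorrectable by the isotope method).
    """

    method: str
    levels: np.ndarray
    channel_flags: dict = field(default_factory=dict)
    kstar: list = field(default_factory=list)
    reference_ratio: float | None = None
    diagnostics: pd.DataFrame | None = None

    def flagged_levels(self, channel="0") -> np.ndarray:
        return self.levels[self.channel_flags[str(channel)]]

    def any_flagged(self) -> bool:
        return any(f.any() for f in self.channel_flags.values())


@dataclass
class CorrectedIntensity:
    """One corrected (or passed-through) monoisotopic intensity."""

    analyte: str
    mode: str
    concentration: float
    replicate: int
    original: float
    corrected: float
    method: str  # none | isotope | ms2 | uncorrectable
    isotope_index: int | None = None
    scale: float = 1.0


def _monotone_close(flags: np.ndarray) -> np.ndarray:
    """Propagate a saturation flag to every higher concentration level."""
    return np.maximum.accumulate(flags).astype(bool)


def _ms1_level_means(series: CalibrationSeries) -> pd.DataFrame:
    ms1 = series.data[series.data["quant_level"] == "MS1"].dropna(subset=["area"])
    if ms1.empty:
        raise SaturationError("series has no MS1 channels")
    pivot = ms1.pivot_table(
        index="concentration",
        columns=ms1["channel"].astype(int),
        values="area",
        aggfunc="mean",
    ).sort_index()
    return pivot


def _noise_guard(series: CalibrationSeries, tol: float) -> float:
    """Intensity below which ratio tests are unreliable.

    An additive background of mean b biases an intensity ratio by up to
    ~b/I for a channel of intensity I, so requiring I > (2/tol) * b keeps
    the floor-induced bias under half the detection tolerance; 3 noise SDs
    are added against fluctuation.
    """
    try:
        b, s = estimate_noise(series)
        return (2.0 / tol) * b + 3.0 * s
    except CalibrationError:
        return 0.0


def detect_saturation_isotope(
    series: CalibrationSeries,
    dist: IsotopeDistribution,
    tol: float = DEFAULT_TOL,
) -> SaturationFlags:
    """Flag MS1 isotope channels whose observed ratios betray saturation.

    Channel k at a level is flagged when the observed I(k+1)/I(k) ratio
    (replicate-mean) exceeds the theoretical ratio by more than ``tol``
    (relative).  Levels whose channel intensities sit below the noise
    guard (background + 3 SD) are exempt — ratio tests on floor-dominated
    signal are meaningless.  Flags are monotone-closed in concentration.
    The highest isotope channel has no heavier neighbor to test against
    and is assumed unsaturated.
    """
    if not 0 < tol < 1:
        raise ValueError("tol must lie in (0, 1)")
    pivot = _ms1_level_means(series)
    channels = sorted(pivot.columns)
    if len(channels) < 2:
        raise SaturationError(
            "need >= 2 MS1 isotope channels for the isotope test; "
            "use the MS2 correction instead"
        )
    levels = pivot.index.to_numpy(float)
    guard = _noise_guard(series, tol)
    rows = []
    flags = {str(k): np.zeros(levels.size, dtype=bool) for k in channels}
    for k in channels[:-1]:
        if k + 1 not in pivot.columns:
            continue
        theo = dist.ratio(k + 1, k)
        lo = pivot[k].to_numpy(float)
        hi = pivot[k + 1].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            obs = hi / lo
        testable = (lo > guard) & (hi > guard) & np.isfinite(obs)
        dev = obs / theo - 1.0
        raw = testable & (dev > tol)
        flags[str(k)] = _monotone_close(raw)
        for i, lev in enumerate(levels):
            rows.append(
                {
                    "concentration": lev,
                    "channel": str(k),
                    "observed_ratio": obs[i] if np.isfinite(obs[i]) else np.nan,
                    "theoretical_ratio": theo,
                    "relative_deviation": dev[i] if np.isfinite(dev[i]) else np.nan,
                    "testable": bool(testable[i]),
                    "flagged": bool(flags[str(k)][i]),
                }
            )
    kstar = []
    for i in range(levels.size):
        unsat = [k for k in channels if not flags[str(k)][i]]
        kstar.append(min(unsat) if unsat else None)
    return SaturationFlags(
        method="isotope",
        levels=levels,
        channel_flags=flags,
        kstar=kstar,
        diagnostics=pd.DataFrame(rows),
    )


def isotope_correct(
    series: CalibrationSeries,
    dist: IsotopeDistribution,
    flags: SaturationFlags,
) -> tuple[CalibrationSeries, list[CorrectedIntensity]]:
    """Replace saturated monoisotopic intensities using higher isotopes.

    At each flagged level, Icorr = I(k*)_exp * (I0_th / Ik*_th) with k* the
    lowest unsaturated isotope channel, applied per replicate.  Levels with
    every channel saturated are marked uncorrectable and their monoisotopic
    rows dropped from the corrected series — no value is invented.
    """
    if flags.method != "isotope":
        raise ValueError("flags were not produced by detect_saturation_isotope")
    ms1 = series.data[series.data["quant_level"] == "MS1"]
    mono_mask = (series.data["quant_level"] == "MS1") & (
        series.data["channel"].astype(str) == "0"
    )
    level_index = {lev: i for i, lev in enumerate(flags.levels)}
    out = series.data.copy()
    records: list[CorrectedIntensity] = []
    drop_rows = []
    for idx in series.data.index[mono_mask]:
        row = series.data.loc[idx]
        i = level_index.get(row["concentration"])
        if i is None or not flags.channel_flags["0"][i]:
            records.append(
                CorrectedIntensity(
                    series.analyte,
                    series.mode,
                    float(row["concentration"]),
                    int(row["replicate"]),
                    float(row["area"]),
                    float(row["area"]),
                    "none",
                )
            )
            continue
        kstar = flags.kstar[i]
        if kstar is None:
            records.append(
                CorrectedIntensity(
                    series.analyte,
                    series.mode,
                    float(row["concentration"]),
                    int(row["replicate"]),
                    float(row["area"]),
                    float("nan"),
                    "uncorrectable",
                )
            )
            drop_rows.append(idx)
            continue
        donor = ms1[
            (ms1["channel"].astype(int) == kstar)
            & (ms1["concentration"] == row["concentration"])
            & (ms1["replicate"] == row["replicate"])
        ]
        if donor.empty or not np.isfinite(donor["area"].iloc[0]):
            records.append(
                CorrectedIntensity(
                    series.analyte,
                    series.mode,
                    float(row["concentration"]),
                    int(row["replicate"]),
                    float(row["area"]),
                    float("nan"),
                    "uncorrectable",
                )
            )
            drop_rows.append(idx)
            continue
        scale = dist.ratio(0, kstar)
        corrected = float(donor["area"].iloc[0]) * scale
        out.loc[idx, "area"] = corrected
        records.append(
            CorrectedIntensity(
                series.analyte,
                series.mode,
                float(row["concentration"]),
                int(row["replicate"]),
                float(row["area"]),
                corrected,
                "isotope",
                isotope_index=kstar,
                scale=scale,
            )
        )
    if drop_rows:
        out = out.drop(index=drop_rows)
    corrected_series = CalibrationSeries(
        series.analyte, series.mode, out.reset_index(drop=True), series.quant_level
    )
    return corrected_series, records


def _ms1_ms2_ratios(
    series: CalibrationSeries, exclude_fragments=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level replicate-mean MS1 mono intensity, sum(MS2), and their ratio."""
    ms1 = series.data[
        (series.data["quant_level"] == "MS1")
        & (series.data["channel"].astype(str) == "0")
    ].dropna(subset=["area"])
    ms2 = series.data[series.data["quant_level"] == "MS2"].dropna(subset=["area"])
    if exclude_fragments:
        ms2 = ms2[~ms2["channel"].astype(str).isin(set(exclude_fragments))]
    if ms1.empty or ms2.empty:
        raise SaturationError("MS2 detection needs MS1 mono and >= 1 MS2 channel")
    levels = np.sort(series.data["concentration"].unique()).astype(float)
    ms1_mean = ms1.groupby("concentration")["area"].mean().reindex(levels).to_numpy()
    ms2_sum = (
        ms2.groupby(["concentration", "replicate"])["area"]
        .sum()
        .groupby("concentration")
        .mean()
        .reindex(levels)
        .to_numpy()
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ms1_mean / ms2_sum
    return levels, ratio, ms2_sum


def detect_saturation_ms2(
    series: CalibrationSeries,
    tol: float = DEFAULT_TOL,
    exclude_fragments=None,
) -> SaturationFlags:
    """Flag levels where the MS1/sum(MS2) ratio drops below its reference.

    The reference ratio k_hat is the median over the lowest half of the
    usable levels (minimum 2), refined once after a first-pass screen so a
    saturated level cannot contaminate it.  A level is flagged when its
    ratio falls below (1 - tol) * k_hat; flags are monotone-closed.
    """
    if not 0 < tol < 1:
        raise ValueError("tol must lie in (0, 1)")
    levels, ratio, ms2_sum = _ms1_ms2_ratios(series, exclude_fragments)
    guard = _noise_guard(series, tol)
    valid = np.isfinite(ratio) & (ratio > 0) & (ms2_sum > guard)
    if valid.sum() < 2:
        valid = np.isfinite(ratio) & (ratio > 0)  # floor estimate too coarse
    if valid.sum() < 2:
        raise SaturationError("need >= 2 levels with nonzero MS2 intensity")

    def reference(mask):
        idx = np.flatnonzero(mask)
        n_ref = max(2, idx.size // 2)
        return float(np.median(ratio[idx[:n_ref]]))

    k0 = reference(valid)
    first_pass = valid & (ratio < (1.0 - tol) * k0)
    usable = valid & ~first_pass
    if usable.sum() < 2:
        raise SaturationError("fewer than 2 unsaturated levels to set the reference")
    k_hat = reference(usable)
    raw = np.where(valid, ratio < (1.0 - tol) * k_hat, False)
    flags = _monotone_close(raw)
    diag = pd.DataFrame(
        {
            "concentration": levels,
            "ms1_ms2_ratio": ratio,
            "reference_ratio": k_hat,
            "flagged": flags,
        }
    )
    return SaturationFlags(
        method="ms2",
        levels=levels,
        channel_flags={"0": flags},
        kstar=[None] * levels.size,
        reference_ratio=k_hat,
        diagnostics=diag,
    )


def ms2_correct(
    series: CalibrationSeries,
    flags: SaturationFlags,
    exclude_fragments=None,
) -> tuple[CalibrationSeries, list[CorrectedIntensity]]:
    """Replace saturated MS1 intensities with k_hat * sum(MS2).

    Applied per replicate at each flagged level.  Fragments known to be
    saturated themselves (e.g. flagged by their own isotope test) can be
    excluded; k_hat must then have been computed over the same retained
    fragment set by passing the same ``exclude_fragments`` to the detector.
    """
    if flags.method != "ms2":
        raise ValueError("flags were not produced by detect_saturation_ms2")
    k_hat = flags.reference_ratio
    ms2 = series.data[series.data["quant_level"] == "MS2"].dropna(subset=["area"])
    if exclude_fragments:
        ms2 = ms2[~ms2["channel"].astype(str).isin(set(exclude_fragments))]
    sums = ms2.groupby(["concentration", "replicate"])["area"].sum()
    mono_mask = (series.data["quant_level"] == "MS1") & (
        series.data["channel"].astype(str) == "0"
    )
    level_index = {lev: i for i, lev in enumerate(flags.levels)}
    out = series.data.copy()
    records: list[CorrectedIntensity] = []
    for idx in series.data.index[mono_mask]:
        row = series.data.loc[idx]
        i = level_index.get(row["concentration"])
        if i is None or not flags.channel_flags["0"][i]:
            records.append(
                CorrectedIntensity(
                    series.analyte,
                    series.mode,
                    float(row["concentration"]),
                    int(row["replicate"]),
                    float(row["area"]),
                    float(row["area"]),
                    "none",
                )
            )
            continue
        key = (row["concentration"], row["replicate"])
        total = float(sums.get(key, np.nan))
        if not np.isfinite(total):
            records.append(
                CorrectedIntensity(
                    series.analyte,
                    series.mode,
                    float(row["concentration"]),
                    int(row["replicate"]),
                    float(row["area"]),
                    float("nan"),
                    "uncorrectable",
                )
            )
            continue
        corrected = k_hat * total
        out.loc[idx, "area"] = corrected
        records.append(
            CorrectedIntensity(
                series.analyte,
                series.mode,
                float(row["concentration"]),
                int(row["replicate"]),
                float(row["area"]),
                corrected,
                "ms2",
                scale=k_hat,
            )
        )
    corrected_series = CalibrationSeries(
        series.analyte, series.mode, out.reset_index(drop=True), series.quant_level
    )
    return corrected_series, records


def apply_corrections(
    series: CalibrationSeries,
    dist: IsotopeDistribution | None = None,
    tol: float = DEFAULT_TOL,
) -> dict:
    """Compute every applicable correction variant for one series.

    Returns a mapping from tag ("uncorrected", "isotope", "ms2") to
    (series, corrected-intensity records).  The optimum correction varies
    between analytes, so both are reported rather than auto-selecting one.
    Variants whose preconditions the series cannot meet are simply absent.
    """
    variants = {"uncorrected": (series, [])}
    if dist is not None:
        try:
            iso_flags = detect_saturation_isotope(series, dist, tol=tol)
            variants["isotope"] = isotope_correct(series, dist, iso_flags)
        except SaturationError:
            pass
    try:
        ms2_flags = detect_saturation_ms2(series, tol=tol)
        variants["ms2"] = ms2_correct(series, ms2_flags)
    except SaturationError:
        pass
    return variants


def corrections_table(records: list[CorrectedIntensity]) -> pd.DataFrame:
    """Flatten correction records into the report table layout."""
    return pd.DataFrame(
        {
            "analyte": [r.analyte for r in records],
            "mode": [r.mode for r in records],
            "concentration": [r.concentration for r in records],
            "replicate": [r.replicate for r in records],
            "method": [r.method for r in records],
            "flagged": [r.method not in ("none",) for r in records],
            "isotope_index": [r.isotope_index for r in records],
            "original": [r.original for r in records],
            "corrected": [r.corrected for r in records],
            "scale": [r.scale for r in records],
        }
    )
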