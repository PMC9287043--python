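"""Calibration-curve modeling and figures of merit for dilution series.

The response of an analyte over a serial dilution is modeled as

    y(x) = b + C * (1 - exp(-x / R))

where ``x`` is the on-column concentration, ``C`` the asymptotic response
the saturating detector approaches, ``R`` the concentration scale at which
saturation sets in (the low-concentration slope is ``C/R``), and ``b`` a
background/noise floor.  The model is linear for x << R and flat for
x >> R, which captures both limits seen on a log-log calibration plot:
noise domination at the bottom and detector saturation at the top.

Figures of merit derived from the fit:

* LLOQ — the concentration at which the modeled signal rises one noise
  standard deviation ``s`` above the background (y = b + s).
* ULOQ — the concentration at which the model first falls a relative
  fraction ``delta`` short of its own low-concentration linear
  extrapolation; the shortfall 1 - (1 - exp(-u))/u with u = x/R depends
  only on u, so ULOQ = u*(delta) * R.
* LDR — log10(ULOQ / LLOQ), the linear dynamic range in orders of
  magnitude.

Fitting is done on log10-transformed responses so that levels spanning
several orders of magnitude contribute comparably, with a deterministic
initialization so repeated fits are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CalibrationSeries",
    "CalibrationFit",
    "CalibrationError",
    "fit_response_model",
    "estimate_noise",
    "estimate_lloq",
    "estimate_uloq",
    "compute_ldr",
    "linear_range_r2",
    "mass_error_rmse",
    "duplicate_error",
    "linearity_departure_point",
    "characterize",
]

#: Curvature below which a fitted curve is indistinguishable from a line
#: over the measured range (max(x)/R under this triggers the linear fallback).
LINEAR_CURVATURE_LIMIT = 0.05


class CalibrationError(ValueError):
    """Invalid calibration series or undefined figure of merit."""


@dataclass
class CalibrationSeries:
    """All transition records for one analyte in one acquisition mode.

    ``data`` is a tidy table with columns ``analyte, mode, quant_level,
    channel, replicate, concentration, area`` (plus optional m/z and RT
    columns).  ``quant_level`` selects how a scalar response per injection
    is formed: the monoisotopic MS1 area, the summed MS2 fragment areas,
    or their sum ("combined").
    """

    analyte: str
    mode: str
    data: pd.DataFrame
    quant_level: str = "MS1"

    def __post_init__(self):
        if self.quant_level not in ("MS1", "MS2", "combined"):
            raise CalibrationError(f"unknown quant_level {self.quant_level!r}")
        conc = np.sort(self.data["concentration"].unique())
        if conc.size < 3:
            raise CalibrationError("need >= 3 distinct concentration levels")
        if not np.all(conc > 0):
            raise CalibrationError("concentrations must be strictly positive")
        self.concentrations = conc.astype(float)

    @classmethod
    def from_records(
        cls,
        records: pd.DataFrame,
        analyte: str | None = None,
        mode: str | None = None,
        quant_level: str = "MS1",
    ) -> "CalibrationSeries":
        df = records
        if analyte is not None:
            df = df[df["analyte"] == analyte]
        if mode is not None:
            df = df[df["mode"] == mode]
        if df.empty:
            raise CalibrationError(f"no records for analyte={analyte!r} mode={mode!r}")
        analytes = df["analyte"].unique()
        modes = df["mode"].unique()
        if len(analytes) != 1 or len(modes) != 1:
            raise CalibrationError("series must cover exactly one analyte and one mode")
        return cls(analytes[0], modes[0], df.reset_index(drop=True), quant_level)

    # -- response extraction ------------------------------------------------

    def _ms1_mono(self) -> pd.DataFrame:
        ms1 = self.data[self.data["quant_level"] == "MS1"]
        mono = ms1[ms1["channel"].astype(str) == "0"]
        if mono.empty:
            raise CalibrationError("no monoisotopic MS1 channel in series")
        return mono

    def _ms2_sums(self) -> pd.DataFrame:
        ms2 = self.data[self.data["quant_level"] == "MS2"]
        if ms2.empty:
            raise CalibrationError("no MS2 channels in series")
        return (
            ms2.dropna(subset=["area"])
            .groupby(["concentration", "replicate"], as_index=False)["area"]
            .sum()
        )

    def response_table(self) -> pd.DataFrame:
        """Scalar response per (concentration, replicate) at the quant level."""
        if self.quant_level == "MS1":
            tab = self._ms1_mono()[["concentration", "replicate", "area"]]
            tab = tab.dropna(subset=["area"])
        elif self.quant_level == "MS2":
            tab = self._ms2_sums()
        else:  # combined
            mono = self._ms1_mono()[["concentration", "replicate", "area"]].dropna(
                subset=["area"]
            )
            ms2 = self._ms2_sums()
            tab = (
                pd.concat([mono, ms2])
                .groupby(["concentration", "replicate"], as_index=False)["area"]
                .sum()
            )
        return tab.sort_values(["concentration", "replicate"]).reset_index(drop=True)

    def response_points(self) -> tuple[np.ndarray, np.ndarray]:
        tab = self.response_table()
        return tab["concentration"].to_numpy(float), tab["area"].to_numpy(float)

    def level_replicates(self, concentration: float) -> np.ndarray:
        tab = self.response_table()
        return tab.loc[
            np.isclose(tab["concentration"], concentration), "area"
        ].to_numpy(float)


@dataclass
class CalibrationFit:
    """Fitted saturating-response model plus figures of merit."""

    C: float
    R: float
    b: float
    slope: float  # low-concentration slope C/R (or the linear-fallback slope)
    s: float | None = None  # noise standard deviation
    lloq: float | None = None
    uloq: float | None = None
    ldr: float | None = None
    r2: float | None = None
    residual_norm: float = float("nan")
    converged: bool = True
    linear_fallback: bool = False
    uloq_censored: bool = False
    lloq_defined: bool = True
    delta: float | None = None
    analyte: str | None = None
    mode: str | None = None
    quant_level: str | None = None
    x_max: float | None = None
    n_levels: int | None = None
    notes: list = field(default_factory=list)

    def model(self, x):
        x = np.asarray(x, dtype=float)
        if self.linear_fallback:
            return self.b + self.slope * x
        return self.b + self.C * (-np.expm1(-x / self.R))


def _model(x, C, R, b):
    return b + C * (-np.expm1(-x / R))


def estimate_noise(
    series: CalibrationSeries | None = None,
    values=None,
) -> tuple[float, float]:
    """Background level b and noise SD s from designated background responses.

    By default the replicate responses at the lowest concentration level
    stand in for blank injections.  Requires at least two values; ``s`` is
    the unbiased (n-1) standard deviation.
    """
    if values is None:
        if series is None:
            raise CalibrationError("provide a series or explicit values")
        values = series.level_replicates(series.concentrations[0])
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise CalibrationError("need >= 2 background responses to estimate noise")
    return float(values.mean()), float(values.std(ddof=1))


def _log_residuals(y_hat, y, shift):
    return np.log10(np.maximum(y_hat, 0.0) + shift) - np.log10(y + shift)


def _fit_linear(x, y, shift):
    pos = y > 0
    m0 = np.median(y[pos] / x[pos]) if pos.any() else 1.0

    def resid(p):
        return _log_residuals(p[1] + np.exp(p[0]) * x, y, shift)

    res = optimize.least_squares(
        resid,
        [np.log(max(m0, 1e-300)), max(y.min(), 0.0)],
        bounds=([-np.inf, 0.0], [np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=2000,
    )
    return float(np.exp(res.x[0])), float(res.x[1]), res


def fit_response_model(
    series: CalibrationSeries | None = None,
    x=None,
    y=None,
    noise: tuple[float, float] | None = None,
) -> CalibrationFit:
    """Least-squares fit of y = b + C(1 - exp(-x/R)) in log-response space.

    Residuals are computed on log10(y + b_hat), with b_hat the background
    estimate, so that concentration levels spanning orders of magnitude are
    weighted comparably.  Initialization is deterministic: C0 = max(y),
    R0 = geometric mean of x, b0 = min(y).

    When the fitted curvature over the measured range is negligible
    (max(x)/R below ``LINEAR_CURVATURE_LIMIT``) or the nonlinear fit does
    not improve on a straight line, the fit falls back to the pure-linear
    R -> infinity limit and only the slope C/R is meaningful.
    """
    if series is not None:
        x, y = series.response_points()
        if noise is None:
            try:
                noise = estimate_noise(series)
            except CalibrationError:
                noise = None
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise CalibrationError("need >= 3 finite response points")
    if np.any(y < 0):
        raise CalibrationError("responses must be non-negative")
    if np.all(y == 0):
        raise CalibrationError("all responses are zero")

    b_hat, s_hat = noise if noise is not None else (0.0, None)
    C0 = float(y.max())
    R0 = float(np.exp(np.mean(np.log(x))))
    b0 = float(y.min())
    shift = max(b_hat, 1e-9 * C0)

    def resid(p):
        return _log_residuals(_model(x, np.exp(p[0]), np.exp(p[1]), p[2]), y, shift)

    res = optimize.least_squares(
        resid,
        [np.log(C0), np.log(R0), b0],
        bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        xtol=1e-15,
        ftol=1e-15,
        gtol=1e-15,
        max_nfev=5000,
    )
    C, R, b = float(np.exp(res.x[0])), float(np.exp(res.x[1])), float(res.x[2])

    m_lin, b_lin, res_lin = _fit_linear(x, y, shift)
    x_max = float(x.max())
    linear = (x_max / R) < LINEAR_CURVATURE_LIMIT or res_lin.cost <= res.cost * (
        1.0 + 1e-12
    )

    if linear:
        fit = CalibrationFit(
            C=float("inf"),
            R=float("inf"),
            b=b_lin,
            slope=m_lin,
            residual_norm=float(np.sqrt(2.0 * res_lin.cost)),
            converged=bool(res_lin.success),
            linear_fallback=True,
        )
    else:
        fit = CalibrationFit(
            C=C,
            R=R,
            b=b,
            slope=C / R,
            residual_norm=float(np.sqrt(2.0 * res.cost)),
            converged=bool(res.success),
        )
    fit.s = s_hat
    fit.x_max = x_max
    fit.n_levels = int(np.unique(x).size)
    if series is not None:
        fit.analyte, fit.mode, fit.quant_level = (
            series.analyte,
            series.mode,
            series.quant_level,
        )
    return fit


def estimate_lloq(fit: CalibrationFit) -> float | None:
    """Concentration where the modeled signal equals background plus one SD.

    Solves C(1 - exp(-x/R)) = s by bisection-style bracketing root finding
    (Brent) to 1e-10 relative; approximately R*s/C when s << C.  With s = 0
    the LLOQ degenerates to 0 and is flagged undefined-by-noise; with
    s >= C the noise exceeds the response asymptote and no LLOQ exists.
    """
    if fit.s is None or fit.s <= 0:
        fit.lloq = 0.0
        fit.lloq_defined = False
        fit.notes.append("lloq undefined: no noise estimate (s <= 0)")
        return fit.lloq
    s = fit.s
    if fit.linear_fallback:
        if fit.slope <= 0:
            fit.lloq = None
            fit.lloq_defined = False
            return None
        fit.lloq = s / fit.slope
        return fit.lloq
    if s >= fit.C:
        fit.lloq = None
        fit.lloq_defined = False
        fit.notes.append("lloq undefined: noise exceeds response asymptote")
        return None

    def g(xv):
        return fit.C * (-np.expm1(-xv / fit.R)) - s

    hi = fit.R
    while g(hi) < 0:
        hi *= 2.0
    lo = fit.R * 1e-300
    fit.lloq = float(optimize.brentq(g, lo, hi, rtol=1e-12, xtol=1e-300))
    return fit.lloq


def linearity_departure_point(delta: float) -> float:
    """u* such that the model falls a fraction delta short of linearity.

    The relative shortfall from the low-concentration linear extrapolation
    is f(u) = 1 - (1 - exp(-u))/u with u = x/R; f is strictly increasing,
    so u*(delta) is the unique root of f(u) = delta.
    """
    if not 0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 0.5)")

    def f(u):
        return 1.0 + np.expm1(-u) / u - delta

    return float(optimize.brentq(f, 1e-12, 60.0, rtol=1e-12))


def estimate_uloq(fit: CalibrationFit, delta: float = 0.2) -> float | None:
    """Smallest concentration with relative shortfall from linearity > delta.

    ULOQ = u*(delta) * R.  Linear-fallback fits saw no saturation and are
    censored at the top measured concentration; converged fits whose
    u*(delta)*R exceeds the measured range are likewise censored rather
    than extrapolated.
    """
    fit.delta = delta
    if fit.linear_fallback:
        if fit.x_max is None:
            raise CalibrationError("linear fit without data range: ULOQ undefined")
        fit.uloq = fit.x_max
        fit.uloq_censored = True
        return fit.uloq
    uloq = linearity_departure_point(delta) * fit.R
    if fit.x_max is not None and uloq > fit.x_max:
        uloq = fit.x_max
        fit.uloq_censored = True
    fit.uloq = float(uloq)
    return fit.uloq


def compute_ldr(fit: CalibrationFit) -> float | None:
    """Linear dynamic range in log10 orders: log10(ULOQ / LLOQ)."""
    if (
        fit.lloq is None
        or fit.uloq is None
        or not fit.lloq_defined
        or fit.lloq <= 0
    ):
        fit.ldr = None
        return None
    fit.ldr = float(np.log10(fit.uloq / fit.lloq))
    return fit.ldr


def linear_range_r2(series: CalibrationSeries, fit: CalibrationFit) -> float | None:
    """R-squared of an ordinary least-squares line through in-range points.

    Points with LLOQ <= x <= ULOQ enter; at least three distinct levels are
    required.  A constant response has zero explained variance and returns
    0.0 by convention.
    """
    if fit.lloq is None or fit.uloq is None:
        fit.r2 = None
        return None
    x, y = series.response_points()
    keep = (x >= fit.lloq) & (x <= fit.uloq)
    if np.unique(x[keep]).size < 3:
        fit.r2 = None
        return None
    xs, ys = x[keep], y[keep]
    if np.allclose(ys, ys[0]):
        fit.r2 = 0.0
        return 0.0
    reg = stats.linregress(xs, ys)
    fit.r2 = float(reg.rvalue**2)
    return fit.r2


def mass_error_rmse(records: pd.DataFrame) -> float | None:
    """RMSE of per-record relative mass errors in ppm.

    Uses rows carrying both observed and theoretical m/z; returns None for
    an empty set.
    """
    if not {"mz_observed", "mz_theoretical"} <= set(records.columns):
        return None
    sub = records.dropna(subset=["mz_observed", "mz_theoretical"])
    if sub.empty:
        return None
    err = (
        1e6
        * (sub["mz_observed"] - sub["mz_theoretical"])
        / sub["mz_theoretical"]
    ).to_numpy(float)
    return float(np.sqrt(np.mean(err**2)))


def duplicate_error(series: CalibrationSeries) -> float | None:
    """Median over levels of the replicate-agreement error, in percent.

    For duplicate injections the per-level error is |y1 - y2| / mean * 100;
    with more than two replicates the coefficient of variation (percent) is
    used.  Levels with a single replicate are skipped; returns None when no
    level has replicates.
    """
    errors = []
    for conc in series.concentrations:
        reps = series.level_replicates(conc)
        if reps.size < 2:
            continue
        mean = reps.mean()
        if mean == 0:
            continue
        if reps.size == 2:
            errors.append(abs(reps[0] - reps[1]) / mean * 100.0)
        else:
            errors.append(reps.std(ddof=1) / mean * 100.0)
    if not errors:
        return None
    return float(np.median(errors))


def characterize(
    series: CalibrationSeries,
    delta: float = 0.2,
    noise: tuple[float, float] | None = None,
) -> CalibrationFit:
    """Fit a series and fill in LLOQ, ULOQ, LDR and linear-range R²."""
    fit = fit_response_model(series, noise=noise)
    estimate_lloq(fit)
    estimate_uloq(fit, delta=delta)
    compute_ldr(fit)
    linear_range_r2(series, fit)
    return fit
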