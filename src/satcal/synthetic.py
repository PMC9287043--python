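"""Synthetic serial-dilution experiments with known ground truth.

The generator emulates the statistical structure of a label-free LC-MS
dilution study: a handful of analytes measured over 5-7 ten-fold
concentration levels in duplicate injections, with

* a linear central response (area = slope * concentration per channel,
  partitioned over isotope peaks and CID fragments),
* per-channel detector saturation at high concentration, modeled by the
  smooth bounded transfer function I_obs = Imax (1 - exp(-I_true/Imax)),
* a lognormal noise floor that dominates the lowest levels,
* lognormal multiplicative replicate noise (constant CV across orders of
  magnitude, as positive peak areas warrant), and
* Gaussian ppm-scale m/z jitter around the theoretical values.

The transfer function is the inverse-consistent counterpart of the
calibration model y = C(1 - exp(-x/R)): a linear true response pushed
through it lands exactly on that model with C = Imax and
R = Imax / slope, so every figure of merit the pipeline estimates has a
closed form the ground-truth sidecar reports.

An optional ion-mobility multiplier (< 1) on the ceilings emulates the
earlier saturation onset of gated ion packets relative to a continuous
beam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import linearity_departure_point
from .isotopes import (
    NEUTRON_SPACING,
    IsotopeDistribution,
    averagine_distribution,
    isotope_distribution,
    parse_formula,
)

__all__ = [
    "FragmentSpec",
    "AnalyteSpec",
    "SimulationConfig",
    "saturate",
    "simulate_experiment",
    "example_metabolite_panel",
]


@dataclass
class FragmentSpec:
    """One CID fragment channel: name, ion-current yield, and m/z."""

    name: str
    ion_yield: float  # fraction of the precursor ion current
    mz: float = 400.0


@dataclass
class AnalyteSpec:
    """One simulated analyte and its true response parameters."""

    analyte_id: str
    response_slope: float  # total area per concentration unit
    formula: str | None = None
    mass: float | None = None  # used with the averagine model when no formula
    charge: int = 1
    fragments: list = field(default_factory=list)
    #: explicit isotopologue abundances, overriding formula/mass
    isotope_abundances: list | None = None

    def distribution(self) -> IsotopeDistribution:
        if self.isotope_abundances is not None:
            a = np.asarray(self.isotope_abundances, dtype=float)
            mz = (self.mass or 500.0) / self.charge + 1.00728
            return IsotopeDistribution(a / a.sum(), charge=self.charge, monoisotopic_mz=mz)
        if self.formula is not None:
            return isotope_distribution(parse_formula(self.formula), charge=self.charge)
        if self.mass is not None:
            return averagine_distribution(self.mass, self.charge)
        raise ValueError(
            f"analyte {self.analyte_id!r} needs a formula, mass, or explicit abundances"
        )

    def validate(self):
        if self.response_slope <= 0:
            raise ValueError("response_slope must be positive")
        total_yield = sum(f.ion_yield for f in self.fragments)
        if any(f.ion_yield < 0 for f in self.fragments) or total_yield > 1.0 + 1e-12:
            raise ValueError("fragment yields must be non-negative and sum to <= 1")


@dataclass
class SimulationConfig:
    """Study design and noise/saturation settings for one simulated run.

    Defaults mirror a peptide-style design: 7 ten-fold levels starting at
    1 concentration unit, duplicate injections, ~5 % replicate CV, and a
    few ppm of mass jitter.  ``imax_ms1``/``imax_ms2`` of None disable
    saturation for that channel class; ``im_multiplier`` (< 1) lowers the
    ceilings as ion-mobility gating does; ``mono_only_saturation``
    restricts the MS1 ceiling to the monoisotopic channel, the cleanest
    setting for studying the isotope correction.
    """

    analytes: list
    mode: str = "SIM"
    n_levels: int = 7
    lowest_concentration: float = 1.0
    fold_step: float = 10.0
    replicates: int = 2
    replicate_cv: float = 0.05
    noise_floor_median: float = 50.0
    noise_floor_log_sd: float = 0.5
    imax_ms1: float | None = None
    imax_ms2: float | None = None
    im_multiplier: float | None = None
    mono_only_saturation: bool = False
    n_isotope_channels: int = 3
    mz_ppm_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_levels < 3:
            raise ValueError("need >= 3 concentration levels")
        if self.fold_step <= 1:
            raise ValueError("fold_step must exceed 1")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")
        if self.im_multiplier is not None and not 0 < self.im_multiplier < 1:
            raise ValueError("im_multiplier must lie in (0, 1)")
        for a in self.analytes:
            a.validate()

    def concentration_levels(self) -> np.ndarray:
        return self.lowest_concentration * self.fold_step ** np.arange(self.n_levels)

    def effective_imax(self, channel_class: str) -> float | None:
        imax = self.imax_ms1 if channel_class == "MS1" else self.imax_ms2
        if imax is not None and self.im_multiplier is not None:
            imax = imax * self.im_multiplier
        return imax


def saturate(i_true, imax: float | None):
    """Bounded detector transfer: I_obs = Imax (1 - exp(-I_true/Imax)).

    Strictly increasing, unit slope at zero, asymptote Imax.  ``imax`` of
    None means no ceiling (identity).
    """
    i_true = np.asarray(i_true, dtype=float)
    if np.any(i_true < 0):
        raise ValueError("true intensity must be non-negative")
    if imax is None:
        return i_true if i_true.ndim else float(i_true)
    if imax <= 0:
        raise ValueError("Imax must be positive")
    out = imax * (-np.expm1(-i_true / imax))
    return out if out.ndim else float(out)


def _lognormal_factor(rng, cv, size):
    """Mean-1 multiplicative noise with the requested coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2.0, sigma, size)


def simulate_experiment(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Generate a transition table and its ground-truth sidecar.

    Returns a tidy native-format table (one row per analyte x level x
    replicate x channel) plus a sidecar recording, per analyte, the true
    channel intensities, the true linear slope of the monoisotopic
    response, and the analytic LLOQ/ULOQ/LDR the configuration implies.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    levels = config.concentration_levels()
    rows = []
    truth: dict = {"config_seed": config.seed, "analytes": {}}
    floor_sigma = config.noise_floor_log_sd
    floor_mu = np.log(config.noise_floor_median) if config.noise_floor_median > 0 else None
    # moments of the additive lognormal floor, for analytic noise figures
    if floor_mu is not None:
        floor_mean = float(np.exp(floor_mu + floor_sigma**2 / 2.0))
        floor_sd = float(floor_mean * np.sqrt(np.expm1(floor_sigma**2)))
    else:
        floor_mean = floor_sd = 0.0

    imax_ms1 = config.effective_imax("MS1")
    imax_ms2 = config.effective_imax("MS2")
    u_star = linearity_departure_point(0.2)

    for spec in config.analytes:
        dist = spec.distribution()
        n_iso = min(config.n_isotope_channels, len(dist))
        abund = dist.abundances[:n_iso]
        slope_mono = spec.response_slope * abund[0]
        true_rows = []
        for level_i, x in enumerate(levels):
            for rep in range(1, config.replicates + 1):
                # MS1 isotope channels
                for k in range(n_iso):
                    i_true = spec.response_slope * x * abund[k]
                    ceiling = imax_ms1 if (k == 0 or not config.mono_only_saturation) else None
                    i_obs = saturate(i_true, ceiling)
                    i_obs *= _lognormal_factor(rng, config.replicate_cv, 1)[0]
                    if floor_mu is not None:
                        i_obs += rng.lognormal(floor_mu, floor_sigma)
                    mz_theo = dist.channel_mz(k)
                    mz_obs = mz_theo * (1.0 + rng.normal(0.0, config.mz_ppm_sd) * 1e-6)
                    rows.append(
                        (
                            spec.analyte_id,
                            config.mode,
                            "MS1",
                            str(k),
                            rep,
                            x,
                            i_obs,
                            mz_obs,
                            mz_theo,
                            np.nan,
                        )
                    )
                    true_rows.append((x, rep, "MS1", str(k), i_true))
                # MS2 fragment channels
                for frag in spec.fragments:
                    i_true = spec.response_slope * x * frag.ion_yield
                    i_obs = saturate(i_true, imax_ms2)
                    i_obs *= _lognormal_factor(rng, config.replicate_cv, 1)[0]
                    if floor_mu is not None:
                        i_obs += rng.lognormal(floor_mu, floor_sigma)
                    mz_obs = frag.mz * (1.0 + rng.normal(0.0, config.mz_ppm_sd) * 1e-6)
                    rows.append(
                        (
                            spec.analyte_id,
                            config.mode,
                            "MS2",
                            frag.name,
                            rep,
                            x,
                            i_obs,
                            mz_obs,
                            frag.mz,
                            np.nan,
                        )
                    )
                    true_rows.append((x, rep, "MS2", frag.name, i_true))
        analytic_uloq = (
            u_star * imax_ms1 / slope_mono if imax_ms1 is not None else float(levels[-1])
        )
        analytic_lloq = floor_sd / slope_mono if floor_sd > 0 else None
        truth["analytes"][spec.analyte_id] = {
            "slope_mono": float(slope_mono),
            "response_slope": float(spec.response_slope),
            "isotope_abundances": [float(a) for a in abund],
            "analytic_uloq_delta02": float(analytic_uloq),
            "uloq_censored": imax_ms1 is None,
            "analytic_lloq": (float(analytic_lloq) if analytic_lloq else None),
            "analytic_ldr": (
                float(np.log10(analytic_uloq / analytic_lloq)) if analytic_lloq else None
            ),
            "true_intensities": [
                {
                    "concentration": float(x),
                    "replicate": int(r),
                    "quant_level": q,
                    "channel": c,
                    "intensity": float(v),
                }
                for x, r, q, c, v in true_rows
            ],
        }
    truth["noise_floor"] = {"mean": floor_mean, "sd": floor_sd}
    table = pd.DataFrame(
        rows,
        columns=[
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
        ],
    )
    return table, truth


def example_metabolite_panel(
    seed: int = 0,
    im_multiplier: float | None = None,
    n_analytes: int = 8,
) -> SimulationConfig:
    """Metabolite-style study design: 5 ten-fold levels, duplicate injections.

    Eight small-molecule analytes with known formulas, response slopes
    spread over an order of magnitude, two CID fragments each, a shared
    detector ceiling, ~5 % replicate CV and a lognormal noise floor.  The
    panel composition is fixed; ``seed`` moves only the noise realization.
    ``im_multiplier`` lowers the ceilings the way ion-mobility gating does.
    """
    comp_rng = np.random.default_rng(123)  # frozen panel composition
    formulas = [
        "C8H10N4O2",
        "C9H13NO3",
        "C6H13NO2",
        "C10H12N2O",
        "C7H8N4O2",
        "C11H12N2O2",
        "C9H11NO2",
        "C5H9NO4",
    ]
    analytes = [
        AnalyteSpec(
            f"met{i + 1}",
            response_slope=float(10 ** comp_rng.uniform(2.5, 3.5)),
            formula=formulas[i % len(formulas)],
            charge=1,
            fragments=[
                FragmentSpec("f1", 0.25, 120.0 + 10 * i),
                FragmentSpec("f2", 0.15, 180.0 + 10 * i),
            ],
        )
        for i in range(n_analytes)
    ]
    return SimulationConfig(
        analytes,
        mode="HDMS" if im_multiplier else "MS",
        n_levels=5,
        lowest_concentration=1.0,
        fold_step=10.0,
        replicates=2,
        replicate_cv=0.05,
        noise_floor_median=100.0,
        noise_floor_log_sd=0.5,
        imax_ms1=2e5,
        imax_ms2=2e5,
        im_multiplier=im_multiplier,
        n_isotope_channels=3,
        mz_ppm_sd=4.0,
        seed=seed,
    )
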