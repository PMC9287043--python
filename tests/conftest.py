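import numpy as np
import pandas as pd
import pytest

from satcal import (
    AnalyteSpec,
    CalibrationSeries,
    FragmentSpec,
    SimulationConfig,
    simulate_experiment,
)


def make_series(
    levels,
    ms1_areas,
    ms2_areas=None,
    replicates=1,
    analyte="a1",
    mode="M",
    quant_level="MS1",
):
    """Build a CalibrationSeries from per-level channel intensity dicts.

    ``ms1_areas`` maps isotope index (int) to a sequence of per-level
    intensities; ``ms2_areas`` maps fragment name to the same.  The same
    values are repeated for every replicate.
    """
    rows = []
    for rep in range(1, replicates + 1):
        for k, areas in ms1_areas.items():
            for x, area in zip(levels, areas):
                rows.append((analyte, mode, "MS1", str(k), rep, x, area))
        for name, areas in (ms2_areas or {}).items():
            for x, area in zip(levels, areas):
                rows.append((analyte, mode, "MS2", name, rep, x, area))
    df = pd.DataFrame(
        rows,
        columns=[
            "analyte",
            "mode",
            "quant_level",
            "channel",
            "replicate",
            "concentration",
            "area",
        ],
    )
    df["mz_observed"] = np.nan
    df["mz_theoretical"] = np.nan
    df["rt"] = np.nan
    return CalibrationSeries(analyte, mode, df, quant_level)


@pytest.fixture
def two_peak_analyte():
    """Doubly charged peptide-like analyte with I0:I1 = 2:1 and two fragments."""
    return AnalyteSpec(
        "pep",
        response_slope=1.0,
        isotope_abundances=[2.0 / 3.0, 1.0 / 3.0],
        charge=2,
        mass=1000.0,
        fragments=[FragmentSpec("y4", 0.3, 450.0), FragmentSpec("y5", 0.2, 550.0)],
    )


@pytest.fixture
def mono_sat_experiment(two_peak_analyte):
    """Half-decade dilution with an MS1 ceiling; detectable mono saturation."""
    cfg = SimulationConfig(
        [two_peak_analyte],
        n_levels=13,
        lowest_concentration=1.0,
        fold_step=10.0**0.5,
        replicates=2,
        replicate_cv=0.0,
        noise_floor_median=5.0,
        noise_floor_log_sd=0.5,
        imax_ms1=1e4,
        imax_ms2=None,
        n_isotope_channels=2,
        seed=7,
    )
    table, truth = simulate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture
def noiseless_sat_experiment(two_peak_analyte):
    """Zero-noise version: observations land exactly on the transfer curve."""
    cfg = SimulationConfig(
        [two_peak_analyte],
        n_levels=13,
        lowest_concentration=1.0,
        fold_step=10.0**0.5,
        replicates=2,
        replicate_cv=0.0,
        noise_floor_median=0.0,
        noise_floor_log_sd=0.5,
        imax_ms1=1e4,
        imax_ms2=None,
        n_isotope_channels=2,
        seed=11,
    )
    table, truth = simulate_experiment(cfg)
    return cfg, table, truth


@pytest.fixture
def noiseless_mono_only_experiment(two_peak_analyte):
    """Zero noise with the ceiling restricted to the monoisotopic channel."""
    cfg = SimulationConfig(
        [two_peak_analyte],
        n_levels=13,
        lowest_concentration=1.0,
        fold_step=10.0**0.5,
        replicates=2,
        replicate_cv=0.0,
        noise_floor_median=0.0,
        noise_floor_log_sd=0.5,
        imax_ms1=1e4,
        imax_ms2=None,
        mono_only_saturation=True,
        n_isotope_channels=2,
        seed=13,
    )
    table, truth = simulate_experiment(cfg)
    return cfg, table, truth


def metabolite_panel_config(seed=0, im_multiplier=None, n_analytes=8):
    """Shared metabolite-style study design (see synthetic.example_metabolite_panel)."""
    from satcal.synthetic import example_metabolite_panel

    return example_metabolite_panel(seed=seed, im_multiplier=im_multiplier,
                                    n_analytes=n_analytes)
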