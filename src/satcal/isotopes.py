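"""Theoretical isotopologue distributions for analyte ions.

Saturation of an ion-counting ToF detector distorts the *relative* heights
of the isotope peaks of a precursor: the intense monoisotopic peak
under-reports first, so the observed I1/I0 ratio drifts above its natural
value.  Recognizing and correcting that drift requires the theoretical
isotopologue distribution of the analyte ion, which this module computes

* exactly, by iterated convolution of per-element isotopologue vectors
  aggregated to nominal (unit) mass offsets, when the elemental formula is
  known; or
* approximately, via the averagine average-residue model, when only a
  monoisotopic mass and charge are known (typical for peptides identified
  by mass alone).

Distributions are unit-mass binned: fine structure within one nominal
offset is summed, which is what unit-spaced isotope peak ratios need.
Elemental abundances ship with the package as a plain-text table so that
results are reproducible without network access.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "ElementCounts",
    "IsotopeDistribution",
    "FormulaError",
    "parse_formula",
    "formula_string",
    "isotope_distribution",
    "averagine_distribution",
    "monoisotopic_mass",
    "element_table",
]

PROTON_MASS = 1.00727646688  # Da
#: Mean spacing of unit-resolved isotope peaks (13C-12C mass difference), Da.
NEUTRON_SPACING = 1.00335483507

# Senko et al. averagine: average amino-acid residue composition per 111.1254 Da.
AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
AVERAGINE_UNIT_MASS = 111.1254

ElementCounts = dict  # element symbol -> positive integer count


class FormulaError(ValueError):
    """Malformed elemental formula or unknown element symbol."""


@dataclass(frozen=True)
class IsotopeDistribution:
    """Normalized unit-mass isotopologue abundances of an analyte ion.

    Parameters
    ----------
    abundances : ndarray
        ``abundances[k]`` is the relative abundance of the isotopologue at
        nominal mass offset ``k`` (0 = monoisotopic).  Normalized to sum 1.
    charge : int
        Positive charge state of the observed ion.
    monoisotopic_mz : float
        m/z (Th) of the monoisotopic peak, assuming protonation.
    """

    abundances: np.ndarray
    charge: int = 1
    monoisotopic_mz: float = field(default=float("nan"))

    def __post_init__(self):
        object.__setattr__(self, "abundances", np.asarray(self.abundances, dtype=float))
        if self.abundances.size == 0 or self.abundances[0] <= 0:
            raise ValueError("monoisotopic abundance must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")

    def __len__(self) -> int:
        return self.abundances.size

    def ratio(self, k: int, j: int = 0) -> float:
        """Abundance ratio a[k] / a[j] (default: relative to monoisotopic)."""
        return float(self.abundances[k] / self.abundances[j])

    def channel_mz(self, k: int) -> float:
        """Expected m/z of the isotope peak at nominal offset ``k``."""
        return self.monoisotopic_mz + k * NEUTRON_SPACING / self.charge


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

_table_cache: dict | None = None


def element_table() -> dict:
    """Bundled elemental isotope table: symbol -> list of (mass Da, abundance)."""
    global _table_cache
    if _table_cache is None:
        table: dict[str, list[tuple[float, float]]] = {}
        text = resources.files("satcal.data").joinpath("element_isotopes.tsv").read_text()
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sym, mass, ab = line.split("\t")
            table.setdefault(sym, []).append((float(mass), float(ab)))
        for sym in table:
            table[sym].sort()
        _table_cache = table
    return _table_cache


def parse_formula(formula: str) -> ElementCounts:
    """Parse a Hill-style elemental formula such as ``"C6H12O6"``.

    Counts default to 1 when omitted (``"H2O"``).  Zero or negative counts
    and unknown element symbols are rejected with the offending token named.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    table = element_table()
    counts: ElementCounts = {}
    pos = 0
    while pos < len(formula):
        m = _TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed token at {formula[pos:]!r} in {formula!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in table:
            raise FormulaError(f"unknown element symbol {sym!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for element {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return counts


def formula_string(counts: ElementCounts) -> str:
    """Canonical Hill-order string (C first, H second, rest alphabetical)."""
    order = [s for s in ("C", "H") if s in counts]
    order += sorted(s for s in counts if s not in ("C", "H"))
    return "".join(f"{s}{counts[s]}" if counts[s] != 1 else s for s in order)


def monoisotopic_mass(counts: ElementCounts) -> float:
    """Monoisotopic (lightest-isotope) mass of the neutral formula, Da."""
    table = element_table()
    return float(sum(n * table[s][0][0] for s, n in counts.items()))


def _element_vector(symbol: str) -> np.ndarray:
    """Per-atom abundance vector indexed by nominal mass offset."""
    isotopes = element_table()[symbol]
    base_mass = isotopes[0][0]
    offsets = [int(round(m - base_mass)) for m, _ in isotopes]
    vec = np.zeros(max(offsets) + 1)
    for (m, ab), off in zip(isotopes, offsets):
        vec[off] += ab
    return vec


def _vector_power(vec: np.ndarray, n: int) -> np.ndarray:
    """vec convolved with itself n times (exponentiation by squaring)."""
    result = np.array([1.0])
    base = vec
    while n:
        if n & 1:
            result = np.convolve(result, base)
        n >>= 1
        if n:
            base = np.convolve(base, base)
    return result


def isotope_distribution(
    counts: ElementCounts,
    truncation: float = 1e-9,
    charge: int = 1,
) -> IsotopeDistribution:
    """Exact unit-mass isotopologue distribution of a formula.

    Parameters
    ----------
    counts : ElementCounts
        Element -> integral atom count; every element must appear in the
        bundled isotope table.
    truncation : float
        Trailing abundance fraction allowed to be dropped, in (0, 1e-3].
        The retained peaks are renormalized to sum 1.
    charge : int
        Charge state used to compute the monoisotopic m/z (protonation).
    """
    if not counts:
        raise FormulaError("empty composition")
    if not 0 < truncation <= 1e-3:
        raise ValueError("truncation must lie in (0, 1e-3]")
    table = element_table()
    dist = np.array([1.0])
    for sym, n in counts.items():
        if sym not in table:
            raise FormulaError(f"no isotope table for element {sym!r}")
        if n != int(n) or n <= 0:
            raise FormulaError(f"count for {sym!r} must be a positive integer, got {n}")
        dist = np.convolve(dist, _vector_power(_element_vector(sym), int(n)))
    total = dist.sum()
    keep = np.searchsorted(np.cumsum(dist), total * (1.0 - truncation)) + 1
    dist = dist[:keep]
    dist = dist / dist.sum()
    mz = (monoisotopic_mass(counts) + charge * PROTON_MASS) / charge
    return IsotopeDistribution(dist, charge=charge, monoisotopic_mz=mz)


def averagine_composition(mass: float) -> ElementCounts:
    """Integer averagine composition approximating a neutral monoisotopic mass.

    Non-hydrogen counts are rounded to the nearest integer; the hydrogen
    count is then chosen to bring the monoisotopic mass within half a
    hydrogen mass of the target.
    """
    if mass < AVERAGINE_UNIT_MASS:
        raise ValueError(
            f"mass {mass:g} Da is below one averagine unit ({AVERAGINE_UNIT_MASS} Da)"
        )
    scale = mass / AVERAGINE_UNIT_MASS
    table = element_table()
    counts: ElementCounts = {}
    heavy_mass = 0.0
    for sym in ("C", "N", "O", "S"):
        n = int(round(AVERAGINE_UNIT[sym] * scale))
        if n > 0:
            counts[sym] = n
            heavy_mass += n * table[sym][0][0]
    h_mass = table["H"][0][0]
    n_h = int(round((mass - heavy_mass) / h_mass))
    if n_h < 1:
        n_h = 1
    counts["H"] = n_h
    return counts


def averagine_distribution(
    monoisotopic_mass_da: float,
    charge: int,
    truncation: float = 1e-9,
) -> IsotopeDistribution:
    """Isotopologue distribution from mass alone, via the averagine model."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    counts = averagine_composition(monoisotopic_mass_da)
    return isotope_distribution(counts, truncation=truncation, charge=charge)
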