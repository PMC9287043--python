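"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: isotope distributions
come from exhaustive enumeration over all isotopologue combinations, and
root-finding checks use dense grid search.
"""

from math import factorial

import numpy as np

from satcal.isotopes import element_table


def _compositions(n, k):
    """All ways to split n atoms over k isotopes."""
    if k == 1:
        yield (n,)
        return
    for i in range(n + 1):
        for rest in _compositions(n - i, k - 1):
            yield (i,) + rest


def _element_enumeration(symbol, n):
    """Exact offset->probability map for n atoms of one element."""
    isotopes = element_table()[symbol]
    base = isotopes[0][0]
    offsets = [int(round(m - base)) for m, _ in isotopes]
    out = {}
    for combo in _compositions(n, len(isotopes)):
        coeff = factorial(n)
        prob = 1.0
        for c, (_, ab) in zip(combo, isotopes):
            coeff //= factorial(c)
            prob *= ab**c
        off = sum(c * o for c, o in zip(combo, offsets))
        out[off] = out.get(off, 0.0) + coeff * prob
    return out


def _convolve_maps(a, b):
    out = {}
    for ka, va in a.items():
        for kb, vb in b.items():
            out[ka + kb] = out.get(ka + kb, 0.0) + va * vb
    return out


def enumerated_distribution(counts) -> np.ndarray:
    """Exhaustive isotopologue enumeration, aggregated to nominal offsets."""
    dist = {0: 1.0}
    for sym, n in counts.items():
        dist = _convolve_maps(dist, _element_enumeration(sym, n))
    k_max = max(dist)
    out = np.zeros(k_max + 1)
    for k, v in dist.items():
        out[k] = v
    return out


def grid_root(f, lo, hi, n=2_000_001):
    """Smallest grid point where f changes sign (dense grid-search oracle)."""
    xs = np.linspace(lo, hi, n)
    vals = f(xs)
    idx = np.flatnonzero(np.diff(np.sign(vals)) != 0)
    if idx.size == 0:
        raise ValueError("no sign change on grid")
    return xs[idx[0]], xs[idx[0] + 1]
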