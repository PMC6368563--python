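"""Independent brute-force oracles used to pin expected values in tests.

These deliberately avoid the library's own dynamic-programming and
library-statistics code paths: score distributions come from enumerating
every possible window, and binomial tail probabilities from exact rational
arithmetic.
"""

from fractions import Fraction
from itertools import product
from math import comb

import numpy as np


def brute_force_distribution(lom):
    """Null distribution of the integer score by enumerating all 4^w windows
    weighted by the zero-order background. Returns (min_score, pmf, survival)
    on the same contiguous integer grid as ``exact_pvalue_table``."""
    w = lom.width
    ints = lom.int_entries
    bg = lom.background
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    pmf = np.zeros(hi - lo + 1)
    for combo in product(range(4), repeat=w):
        score = sum(int(ints[i, a]) for i, a in enumerate(combo))
        weight = 1.0
        for a in combo:
            weight *= bg[a]
        pmf[score - lo] += weight
    survival = np.cumsum(pmf[::-1])[::-1]
    return lo, pmf, survival


def brute_force_uniform_counts(lom):
    """Same enumeration specialised to a uniform background: integer counts
    per grid point times 4^-w, exact in binary floating point."""
    w = lom.width
    ints = lom.int_entries
    lo = int(ints.min(axis=1).sum())
    hi = int(ints.max(axis=1).sum())
    counts = np.zeros(hi - lo + 1, dtype=np.int64)
    # vectorized enumeration: mixed-radix codes for all 4^w windows
    codes = np.stack(
        np.meshgrid(*[np.arange(4)] * w, indexing="ij"), axis=-1
    ).reshape(-1, w)
    scores = np.zeros(len(codes), dtype=np.int64)
    for i in range(w):
        scores += ints[i, codes[:, i]]
    np.add.at(counts, scores - lo, 1)
    pmf = counts * (0.25**w)
    survival = np.cumsum(pmf[::-1])[::-1]
    return lo, pmf, survival


def exact_binomial_two_sided(k: int, n: int, ratio=Fraction(1, 2)) -> Fraction:
    """Minimum-likelihood two-sided binomial p-value in exact rationals:
    sum of P(j) over every j whose probability does not exceed P(k)."""
    ratio = Fraction(ratio)
    probs = [
        comb(n, j) * ratio**j * (1 - ratio) ** (n - j) for j in range(n + 1)
    ]
    observed = probs[k]
    return sum(p for p in probs if p <= observed)
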