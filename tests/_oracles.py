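"""Independent brute-force oracles used by the tests.

Deliberately written with plain-Python loops and itertools (no shared code
paths with the package's vectorized implementations).
"""

from itertools import accumulate, combinations
from math import comb


def brute_candidate_spans(values, min_len=8, max_len=40, flank=3, f_threshold=2.0):
    """Exhaustively enumerate footprint candidates on a circular track.

    Returns a dict (start, width) -> (central, left, right, f) for every span
    whose central mean is strictly below both 3-nt flank means and whose
    F score is below the threshold.
    """
    vals = list(values)
    L = len(vals)
    doubled = vals + vals
    cum = [0.0] + list(accumulate(doubled))

    def mean(i, n):  # mean of doubled[i:i+n]
        return (cum[i + n] - cum[i]) / n

    out = {}
    for start in range(L):
        for width in range(min_len, max_len + 1):
            central = mean(start, width)
            left = mean((start - flank) % L, flank)
            right = mean(start + width, flank)
            if central < left and central < right:
                f = 10.0 ** (central - left) + 10.0 ** (central - right)
                if f < f_threshold:
                    out[(start, width)] = (central, left, right, f)
    return out


def brute_hypergeom_upper(N, K, n, k):
    """P(X >= k) by exact combinatorial count (feasible for N <= 12)."""
    total = comb(N, n)
    hits = 0
    population = list(range(N))
    successes = set(range(K))
    for draw in combinations(population, n):
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total
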