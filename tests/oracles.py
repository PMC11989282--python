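"""Independent brute-force oracles used by the test suite.

These deliberately avoid the vectorized code paths of the package: pure-python
loops and math.comb only, so they can disagree with the implementation if the
implementation is wrong.
"""

import math

from msikit import outcomes


def barnard_oracle(a, b, c, d, grid_size=outcomes.BARNARD_GRID_SIZE):
    """Enumeration oracle for the two-sided unconditional exact test.

    Enumerates every outcome with the observed group sizes, scores it with the
    pooled score statistic, and maximizes the extreme-set probability over the
    same nuisance grid of equally spaced interior points.
    """
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        return 1.0

    def z(x1, x2):
        pooled = (x1 + x2) / (n1 + n2)
        var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
        if var <= 0:
            return 0.0
        return (x1 / n1 - x2 / n2) / math.sqrt(var)

    z_obs = abs(z(a, c))
    extreme = [
        (x1, x2)
        for x1 in range(n1 + 1)
        for x2 in range(n2 + 1)
        if abs(z(x1, x2)) >= z_obs - 1e-12
    ]
    best = 0.0
    for i in range(1, grid_size + 1):
        pi = i / (grid_size + 1)
        total = 0.0
        for x1, x2 in extreme:
            total += (
                math.comb(n1, x1) * pi**x1 * (1 - pi) ** (n1 - x1)
                * math.comb(n2, x2) * pi**x2 * (1 - pi) ** (n2 - x2)
            )
        best = max(best, total)
    return min(1.0, best)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def table_prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    p_obs = table_prob(a)
    return sum(table_prob(x) for x in range(lo, hi + 1) if table_prob(x) <= p_obs + 1e-12)


def km_oracle(times, events):
    """Hand product-limit estimator: S(t) stepped at each distinct event time."""
    order = sorted(range(len(times)), key=lambda i: times[i])
    at_risk = len(times)
    surv = 1.0
    curve = {}
    i = 0
    while i < len(order):
        t = times[order[i]]
        d = sum(1 for j in order[i:] if times[j] == t and events[j])
        n_t = sum(1 for j in order[i:] if times[j] == t)
        if d > 0:
            surv *= 1.0 - d / at_risk
            curve[t] = surv
        at_risk -= n_t
        i += n_t
    return curve
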