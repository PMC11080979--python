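"""Independent brute-force oracles used by the tests.

Everything here is written with naive scalar loops from first principles
(band lookup by linear scan, hazard as an explicit sum over merged band
edges, the LR as a literal product over carriers divided by the mean
weight to the K-th power) and deliberately shares no code with the
package's vectorized implementation.
"""

import math


def band_value(breaks, values, x, outside):
    """Piecewise-constant lookup by linear scan.

    ``outside='zero'`` returns 0 outside the bands; ``outside='edge'``
    extends the first/last band.
    """
    if x < breaks[0]:
        return values[0] if outside == "edge" else 0.0
    for i in range(len(values)):
        if breaks[i] <= x < breaks[i + 1]:
            return values[i]
    if x == breaks[-1]:
        return values[-1]
    return values[-1] if outside == "edge" else 0.0


def naive_hazard(inc_breaks, inc_rates, rr_breaks, rr_logs, t, k):
    """Exact integral of rate * exp(beta * k) over [0, t] via merged edges."""
    edges = sorted(set(list(inc_breaks) + list(rr_breaks) + [0.0, t]))
    edges = [e for e in edges if 0.0 <= e <= t]
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + b)
        rate = band_value(inc_breaks, inc_rates, mid, outside="zero")
        beta = band_value(rr_breaks, rr_logs, mid, outside="edge")
        total += rate * math.exp(beta * k) * (b - a)
    return total


def naive_weight(inc_breaks, inc_rates, rr_breaks, rr_logs, t, d):
    """w(t, d) = S1(t) exp(beta(t) d) / S0(t), from the naive hazards."""
    h0 = naive_hazard(inc_breaks, inc_rates, rr_breaks, rr_logs, t, 0)
    h1 = naive_hazard(inc_breaks, inc_rates, rr_breaks, rr_logs, t, 1)
    beta = band_value(rr_breaks, rr_logs, t, outside="edge")
    return math.exp(-h1) * math.exp(beta * d) / math.exp(-h0)


def naive_lr(individuals, inc_breaks, inc_rates, rr_breaks, rr_logs):
    """Literal ccLR: product of carrier weights / (mean weight)^K.

    ``individuals`` is a list of (carrier, status, age) triples.
    """
    weights = [
        naive_weight(inc_breaks, inc_rates, rr_breaks, rr_logs, age, status)
        for _, status, age in individuals
    ]
    carriers = [w for (v, _, _), w in zip(individuals, weights) if v == 1]
    k = len(carriers)
    if k == 0:
        return 1.0
    numerator = 1.0
    for w in carriers:
        numerator *= w
    mean_w = sum(weights) / len(weights)
    return numerator / mean_w**k
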