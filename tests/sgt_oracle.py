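"""Brute-force scalar Simple Good-Turing oracle for cross-checking.

Written independently of the package: pure-Python floats, explicit
loops, hand-rolled least squares.  Follows the classic Gale-Sampson
recipe step by step — neighbor-averaged Z values, log-log regression,
Turing vs smoothed adjusted counts with the 1.96-sd switch rule, P0 =
N1/N, proportional renormalization to 1 - P0.
"""

import math


def oracle_z_values(r_values, n_values):
    """Z_r = 2 N_r / (t - q) with q, t the represented neighbors."""
    out = []
    k = len(r_values)
    for i in range(k):
        q = r_values[i - 1] if i > 0 else 0
        t = r_values[i + 1] if i + 1 < k else 2 * r_values[i] - q
        out.append(2.0 * n_values[i] / (t - q))
    return out


def oracle_loglog_fit(xs, ys):
    """Least squares of ln(y) on ln(x) by the textbook sums."""
    lx = [math.log(x) for x in xs]
    ly = [math.log(y) for y in ys]
    n = len(lx)
    mx = sum(lx) / n
    my = sum(ly) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(lx, ly))
    sxx = sum((x - mx) ** 2 for x in lx)
    b = sxy / sxx
    a = my - b * mx
    return a, b


def oracle_sgt(counts):
    """Full Simple Good-Turing fit of a list of per-gene counts.

    Returns (per_count_prob, p0, a, b, switch_count, fallback).
    """
    positive = sorted(c for c in counts if c > 0)
    if not positive:
        raise ValueError("all counts zero")
    n_total = sum(positive)
    fof = {}
    for c in positive:
        fof[c] = fof.get(c, 0) + 1
    r_values = sorted(fof)
    n_values = [fof[r] for r in r_values]

    if len(r_values) < 2:
        return ({r: r / n_total for r in r_values}, 0.0, None, None, None, True)

    a, b = oracle_loglog_fit(r_values, oracle_z_values(r_values, n_values))

    p0 = fof.get(1, 0) / n_total
    r_star = {}
    switched = False
    switch_count = None
    for r in r_values:
        smoothed = (r + 1) * math.exp(
            (a + b * math.log(r + 1)) - (a + b * math.log(r))
        )
        if not switched:
            if (r + 1) not in fof:
                switched = True
            else:
                turing = (r + 1) * fof[r + 1] / fof[r]
                sd = math.sqrt(
                    (r + 1) ** 2 * (fof[r + 1] / fof[r] ** 2) * (1 + fof[r + 1] / fof[r])
                )
                if abs(turing - smoothed) <= 1.96 * sd:
                    switched = True
                else:
                    r_star[r] = turing
                    continue
            if switch_count is None:
                switch_count = r
        r_star[r] = smoothed

    denom = sum(fof[r] * r_star[r] for r in r_values)
    probs = {r: (1.0 - p0) * r_star[r] / denom for r in r_values}
    return (probs, p0, a, b, switch_count, False)
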