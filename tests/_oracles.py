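"""Independent brute-force oracles used to validate the package's engines.

These deliberately avoid the code paths under test: plain-Python loops and
first-principles formulas only.
"""

from __future__ import annotations

import math
from collections import Counter


def rank_with_ties(values):
    """Average ranks (1-based), mean rank for ties."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    return sxy / math.sqrt(sxx * syy)


def spearman(x, y):
    return pearson(rank_with_ties(list(x)), rank_with_ties(list(y)))


def ssp_posteriors(outcomes, prob_rows, priors):
    """Hand-summed log posterior -> softmax.

    outcomes: list of 0/1 per evaluated rule; prob_rows: per rule, list of
    P(rule true | subtype k); priors: list per subtype.
    """
    n_subtypes = len(priors)
    log_post = [math.log(priors[k]) for k in range(n_subtypes)]
    for outcome, row in zip(outcomes, prob_rows):
        for k in range(n_subtypes):
            p = row[k]
            log_post[k] += math.log(p) if outcome else math.log(1.0 - p)
    top = max(log_post)
    raw = [math.exp(v - top) for v in log_post]
    total = sum(raw)
    return [v / total for v in raw]


def kappa_from_contingency(a, b):
    """Unweighted Cohen's kappa via an explicit contingency table."""
    pairs = [(x, y) for x, y in zip(a, b) if x is not None and y is not None]
    n = len(pairs)
    table = Counter(pairs)
    labels = sorted({x for x, _ in pairs} | {y for _, y in pairs})
    p_o = sum(table[(lab, lab)] for lab in labels) / n
    row = Counter(x for x, _ in pairs)
    col = Counter(y for _, y in pairs)
    p_e = sum(row[lab] * col[lab] for lab in labels) / (n * n)
    if abs(1.0 - p_e) < 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def percentile_linear(values, q):
    """Linear-interpolation percentile (numpy's default), q in [0, 100]."""
    ordered = sorted(values)
    if len(ordered) == 1:
        return ordered[0]
    pos = (len(ordered) - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    frac = pos - lo
    return ordered[lo] * (1 - frac) + ordered[hi] * frac


def uq_log2cpm(count_columns, offset=1.0):
    """Step-by-step upper-quartile log2 CPM for a dict sample -> list of counts."""
    samples = list(count_columns)
    lib = {s: sum(count_columns[s]) for s in samples}
    uq = {
        s: percentile_linear([c for c in count_columns[s] if c > 0], 75.0)
        for s in samples
    }
    ratios = {s: uq[s] / lib[s] for s in samples}
    log_mean = sum(math.log(ratios[s]) for s in samples) / len(samples)
    geo = math.exp(log_mean)
    out = {}
    for s in samples:
        f = ratios[s] / geo
        eff = lib[s] * f
        out[s] = [math.log2(c * 1e6 / eff + offset) for c in count_columns[s]]
    return out


def shannon_entropy_bits(labels):
    usable = [v for v in labels if v is not None]
    if not usable:
        return float("nan")
    counts = Counter(usable)
    n = len(usable)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())
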