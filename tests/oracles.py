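"""Independent brute-force implementations of the agreement coefficients.

Pure-python, loop-based transcriptions of the defining formulas, written
without reference to the package internals.  They exist so the vectorized
implementations can be checked against the definitions on enumerable and
random inputs.
"""

from math import comb


def weight_table(categories, kind):
    """Agreement weights as a dict keyed by label pairs."""
    q = len(categories)
    pos = {c: i for i, c in enumerate(categories)}
    w = {}
    for a in categories:
        for b in categories:
            d = abs(pos[a] - pos[b])
            if kind == "identity":
                w[(a, b)] = 1.0 if d == 0 else 0.0
            elif kind == "linear":
                w[(a, b)] = 1.0 - d / (q - 1)
            elif kind == "quadratic":
                w[(a, b)] = 1.0 - d * d / (q - 1) ** 2
            elif kind == "ordinal":
                w[(a, b)] = 1.0 - comb(d + 1, 2) / comb(q, 2)
            else:
                raise ValueError(kind)
    return w


def _mean(xs):
    xs = list(xs)
    return sum(xs) / len(xs)


def bf_percent_agreement(rows, w):
    """Mean over informative units of the weighted ordered-pair agreement."""
    vals = []
    for row in rows:
        u = [v for v in row if v is not None]
        if len(u) < 2:
            continue
        pairs = [(a, b) for i, a in enumerate(u) for j, b in enumerate(u) if i != j]
        vals.append(_mean(w[p] for p in pairs))
    return _mean(vals)


def bf_prevalences(rows, categories):
    """Unit-averaged category proportions over units with >= 1 rating."""
    per_unit = []
    for row in rows:
        u = [v for v in row if v is not None]
        if not u:
            continue
        per_unit.append([sum(1 for v in u if v == c) / len(u) for c in categories])
    return [_mean(col) for col in zip(*per_unit)]


def bf_gwet(rows, categories, kind):
    """Gwet's AC from the defining formulas (AC1 for identity weights)."""
    w = weight_table(categories, kind)
    q = len(categories)
    pa = bf_percent_agreement(rows, w)
    pi = bf_prevalences(rows, categories)
    tw = sum(w.values())
    pe = tw / (q * (q - 1)) * sum(p * (1 - p) for p in pi)
    return (pa - pe) / (1 - pe)


def bf_fleiss(rows, categories):
    """Multi-rater kappa: identity-pair agreement vs sum of squared prevalences."""
    w = weight_table(categories, "identity")
    pa = bf_percent_agreement(rows, w)
    pi = bf_prevalences(rows, categories)
    pe = sum(p * p for p in pi)
    return (pa - pe) / (1 - pe)


def bf_cohen_weighted(pairs, categories, kind):
    """Weighted Cohen's kappa from the joint distribution of one rater pair."""
    w = weight_table(categories, kind)
    complete = [(a, b) for a, b in pairs if a is not None and b is not None]
    n = len(complete)
    po = _mean(w[p] for p in complete)
    pe = 0.0
    for a in categories:
        for b in categories:
            pa_ = sum(1 for x, _ in complete if x == a) / n
            pb = sum(1 for _, y in complete if y == b) / n
            pe += w[(a, b)] * pa_ * pb
    return (po - pe) / (1 - pe)


def bf_jackknife_se(rows, categories, kind):
    """Delete-one-unit jackknife SE of Gwet's AC."""
    n = len(rows)
    full = bf_gwet(rows, categories, kind)
    loo = [bf_gwet(rows[:i] + rows[i + 1:], categories, kind) for i in range(n)]
    mean_loo = _mean(loo)
    var = (n - 1) / n * sum((v - mean_loo) ** 2 for v in loo)
    return var**0.5, full
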