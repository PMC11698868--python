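"""Independent naive re-implementations used only as test oracles.

Deliberately written as direct formula transcriptions — plain loops and
``math`` — sharing no code with the package. Keep them slow and
obvious.
"""

import math


def _pos(counts):
    return [float(x) for x in counts if x > 0]


def observed(counts):
    return len(_pos(counts))


def singletons(counts):
    return sum(1 for x in counts if x == 1)


def doubletons(counts):
    return sum(1 for x in counts if x == 2)


def chao1(counts):
    s = observed(counts)
    a = singletons(counts)
    b = doubletons(counts)
    if b > 0:
        return s + a * a / (2 * b)
    return s + a * (a - 1) / (2 * (b + 1))


def ace(counts, k=10):
    pos = _pos(counts)
    abund = [x for x in pos if x > k]
    rare = [x for x in pos if x <= k]
    if not rare:
        return float(len(abund))
    n_rare = sum(rare)
    f1 = sum(1 for x in rare if x == 1)
    c_rare = 1 - f1 / n_rare
    if c_rare == 0:
        raise ValueError("undefined")
    total = 0.0
    for i in range(1, k + 1):
        fi = sum(1 for x in rare if x == i)
        total += i * (i - 1) * fi
    if n_rare > 1:
        gamma2 = len(rare) / c_rare * total / (n_rare * (n_rare - 1)) - 1
        gamma2 = max(gamma2, 0.0)
    else:
        gamma2 = 0.0
    return len(abund) + len(rare) / c_rare + f1 / c_rare * gamma2


def fisher_alpha(counts):
    # plain bisection on S = a ln(1 + N/a)
    pos = _pos(counts)
    s = len(pos)
    n = sum(pos)
    if s < 2 or s >= n:
        raise ValueError("no finite root")
    lo, hi = 1e-10, 1e9
    for _ in range(500):
        mid = (lo + hi) / 2
        if mid * math.log(1 + n / mid) < s:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def margalef(counts):
    pos = _pos(counts)
    if len(pos) == 1:
        return 0.0
    return (len(pos) - 1) / math.log(sum(pos))


def menhinick(counts):
    pos = _pos(counts)
    return len(pos) / math.sqrt(sum(pos))


def robbins_reads(counts):
    return singletons(counts) / (sum(_pos(counts)) + 1)


def robbins_features(counts):
    return singletons(counts) / (observed(counts) + 1)


def berger_parker(counts):
    pos = _pos(counts)
    return max(pos) / sum(pos)


def simpson(counts):
    pos = _pos(counts)
    n = sum(pos)
    return 1 - sum((x / n) ** 2 for x in pos)


def dominance(counts):
    pos = _pos(counts)
    n = sum(pos)
    return sum((x / n) ** 2 for x in pos)


def enspie(counts):
    return 1 / dominance(counts)


def gini(counts):
    # mean absolute difference over 2 * mean
    pos = _pos(counts)
    s = len(pos)
    m = sum(pos) / s
    total = 0.0
    for xi in pos:
        for xj in pos:
            total += abs(xi - xj)
    return total / (2 * s * s * m)


def mcintosh(counts):
    pos = _pos(counts)
    n = sum(pos)
    u = math.sqrt(sum(x * x for x in pos))
    return (n - u) / (n - math.sqrt(n))


def strong(counts):
    pos = sorted(_pos(counts), reverse=True)
    s = len(pos)
    n = sum(pos)
    best = -math.inf
    cum = 0.0
    for i, x in enumerate(pos, start=1):
        cum += x
        best = max(best, cum / n - i / s)
    return best


def shannon(counts, base=2):
    pos = _pos(counts)
    n = sum(pos)
    return -sum((x / n) * math.log(x / n, base) for x in pos)


def brillouin(counts):
    pos = _pos(counts)
    n = sum(pos)
    return (math.lgamma(n + 1) - sum(math.lgamma(x + 1) for x in pos)) / n


def heip(counts):
    pos = _pos(counts)
    if len(pos) == 1:
        return math.nan
    h = shannon(pos, base=math.e)
    return (math.exp(h) - 1) / (len(pos) - 1)


def pielou(counts):
    pos = _pos(counts)
    if len(pos) == 1:
        return math.nan
    return shannon(pos, base=math.e) / math.log(len(pos))


def faith_edge_marking(observed_labels, tree):
    """Brute force: an edge counts iff any observed tip sits below it."""
    observed_labels = set(observed_labels)
    total = 0.0
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            below = {node.name}
        else:
            below = {t.name for t in node.tips()}
        if below & observed_labels:
            total += node.length or 0.0
    return total


ABUNDANCE_ORACLES = {
    "observed_features": observed,
    "chao1": chao1,
    "ace": ace,
    "fisher_alpha": fisher_alpha,
    "margalef": margalef,
    "menhinick": menhinick,
    "robbins": robbins_reads,
    "berger_parker": berger_parker,
    "simpson": simpson,
    "dominance": dominance,
    "enspie": enspie,
    "gini": gini,
    "mcintosh": mcintosh,
    "strong": strong,
    "shannon": shannon,
    "brillouin": brillouin,
    "heip": heip,
    "pielou": pielou,
}
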