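"""Independent brute-force oracles for the diversity formulas.

Deliberately naive transcriptions of the textbook definitions — pure-Python
loops, no shared code with the package — so agreement between these and the
package implementations is a meaningful check, not a tautology.
"""

import math

from scipy.optimize import brentq


def proportions(v):
    total = sum(v)
    return None if total <= 0 else [x / total for x in v]


# ---- alpha ----------------------------------------------------------------

def o_richness(v):
    return sum(1 for x in v if x > 0)


def o_shannon(v, base=2.0):
    p = proportions(v)
    if p is None:
        return math.nan
    return -sum(x * math.log(x, base) for x in p if x > 0)


def o_gini_simpson(v):
    p = proportions(v)
    if p is None:
        return math.nan
    return 1.0 - sum(x * x for x in p)


def o_inverse_simpson(v):
    p = proportions(v)
    if p is None:
        return math.nan
    return 1.0 / sum(x * x for x in p)


def o_simpsons_evenness(v):
    s = o_richness(v)
    return math.nan if s == 0 else o_inverse_simpson(v) / s


def o_pielou(v, base=2.0):
    s = o_richness(v)
    if s <= 1 or sum(v) <= 0:
        return math.nan
    return o_shannon(v, base) / math.log(s, base)


def o_berger_parker(v):
    p = proportions(v)
    return math.nan if p is None else max(p)


def o_heip(v):
    s = o_richness(v)
    if s <= 1 or sum(v) <= 0:
        return math.nan
    return (math.exp(o_shannon(v, math.e)) - 1.0) / (s - 1.0)


def o_margalef(v):
    s, n = o_richness(v), sum(v)
    if s == 0 or n <= 0 or n == 1:
        return math.nan
    return (s - 1.0) / math.log(n)


def o_mcintosh_d(v):
    n = sum(v)
    if n <= 0 or n == 1:
        return math.nan
    u = math.sqrt(sum(x * x for x in v))
    return (n - u) / (n - math.sqrt(n))


def o_mcintosh_e(v):
    s, n = o_richness(v), sum(v)
    if s == 0 or n <= 0:
        return math.nan
    u = math.sqrt(sum(x * x for x in v))
    return u / math.sqrt((n - s + 1.0) ** 2 + s - 1.0)


def o_menhinick(v):
    s, n = o_richness(v), sum(v)
    return math.nan if s == 0 or n <= 0 else s / math.sqrt(n)


def o_fishers_alpha(v):
    """Root of S = a*ln(1+N/a) by bracketed bisection (scipy brentq)."""
    s, n = o_richness(v), sum(v)
    if s == 0 or n <= 0 or s >= n:
        return math.nan

    def f(a):
        return a * math.log(1.0 + n / a) - s

    lo, hi = 1e-12, float(s)
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return math.nan
    return brentq(f, lo, hi, xtol=1e-12)


# ---- beta -----------------------------------------------------------------

def o_bray_curtis(x, y):
    denom = sum(a + b for a, b in zip(x, y))
    if denom == 0:
        return math.nan
    return sum(abs(a - b) for a, b in zip(x, y)) / denom


def o_jaccard(x, y):
    a = {i for i, v in enumerate(x) if v > 0}
    b = {i for i, v in enumerate(y) if v > 0}
    if not a | b:
        return math.nan
    return 1.0 - len(a & b) / len(a | b)


def o_jensen_shannon(x, y):
    """Direct KL summation with natural logs."""
    if sum(x) == 0 or sum(y) == 0:
        return math.nan
    p = [v / sum(x) for v in x]
    q = [v / sum(y) for v in y]
    m = [(a + b) / 2.0 for a, b in zip(p, q)]

    def kl(r, s):
        return sum(a * math.log(a / b) for a, b in zip(r, s) if a > 0)

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


def o_euclidean(x, y):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))


def o_manhattan(x, y):
    return sum(abs(a - b) for a, b in zip(x, y))


def o_canberra(x, y):
    return sum(
        abs(a - b) / (abs(a) + abs(b)) for a, b in zip(x, y) if abs(a) + abs(b) > 0
    )


def o_chebyshev(x, y):
    return max(abs(a - b) for a, b in zip(x, y))


def o_hellinger(x, y):
    if sum(x) == 0 or sum(y) == 0:
        return math.nan
    p = [math.sqrt(v / sum(x)) for v in x]
    q = [math.sqrt(v / sum(y)) for v in y]
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def o_whittaker(x, y):
    if sum(x) == 0 or sum(y) == 0:
        return math.nan
    p = [v / sum(x) for v in x]
    q = [v / sum(y) for v in y]
    return 0.5 * sum(abs(a - b) for a, b in zip(p, q))


# ---- tree oracles ---------------------------------------------------------

def enumerate_branches(tree):
    """All (length, frozenset-of-descendant-tip-names) pairs, one per
    non-root node, by direct recursion."""
    out = []

    def visit(node):
        if node.is_tip():
            tips = frozenset([node.name])
        else:
            tips = frozenset()
            for child in node.children:
                tips |= visit(child)
        if node.parent is not None:
            out.append((float(node.length), tips))
        return tips

    visit(tree)
    return out


def o_faith_pd(present_names, tree):
    """Union of root paths of present tips (path walking, not masks)."""
    present = set(present_names)
    if not present:
        return 0.0
    edges = {}
    for tip in tree.tips():
        if tip.name in present:
            node = tip
            while node.parent is not None:
                edges[id(node)] = float(node.length)
                node = node.parent
    return sum(edges.values())


def o_unweighted_unifrac(x_names, y_names, tree):
    a, b = set(x_names), set(y_names)
    unshared = total = 0.0
    for length, tips in enumerate_branches(tree):
        in_a = bool(tips & a)
        in_b = bool(tips & b)
        if in_a or in_b:
            total += length
            if in_a != in_b:
                unshared += length
    return math.nan if total == 0 else unshared / total


def o_weighted_unifrac(x, y, tree, normalized=True):
    """x, y: dicts tip name -> abundance."""
    tx, ty = sum(x.values()), sum(y.values())
    if tx == 0 or ty == 0:
        return math.nan
    raw = denom = 0.0
    for length, tips in enumerate_branches(tree):
        p = sum(x.get(t, 0.0) for t in tips) / tx
        q = sum(y.get(t, 0.0) for t in tips) / ty
        raw += length * abs(p - q)
        denom += length * (p + q)
    if not normalized:
        return raw
    return math.nan if denom == 0 else raw / denom


ALPHA_ORACLES = {
    "richness": o_richness,
    "shannon_index": o_shannon,
    "gini_simpson": o_gini_simpson,
    "inverse_simpson": o_inverse_simpson,
    "simpsons_evenness": o_simpsons_evenness,
    "pielou_evenness": o_pielou,
    "berger_parker_dominance": o_berger_parker,
    "ens_pie": o_inverse_simpson,
    "fishers_alpha": o_fishers_alpha,
    "heips_evenness": o_heip,
    "margalefs_richness": o_margalef,
    "mcintoshs_dominance": o_mcintosh_d,
    "mcintoshs_evenness": o_mcintosh_e,
    "menhinicks_richness": o_menhinick,
}

BETA_ORACLES = {
    "bray_curtis": o_bray_curtis,
    "jaccard_binary": o_jaccard,
    "jensen_shannon": o_jensen_shannon,
    "euclidean": o_euclidean,
    "manhattan": o_manhattan,
    "canberra": o_canberra,
    "chebyshev": o_chebyshev,
    "hellinger": o_hellinger,
    "whittaker": o_whittaker,
}
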