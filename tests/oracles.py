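"""Independent reference implementations used only to check the package.

These deliberately use exact rational arithmetic or naive enumeration so
that they share no code path with the implementations they verify.
"""

from fractions import Fraction
from math import comb, log


def fisher_two_tailed_exact(a, b, c, d):
    """Two-tailed Fisher p by exhaustive hypergeometric enumeration.

    Exact Fraction arithmetic; tables with point probability <= that of
    the observed table (exact ties included) contribute to p.
    """
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    if n == 0 or n1 == 0 or n2 == 0 or k == 0 or k == n:
        return 1.0
    denom = comb(n, k)
    probs = [
        Fraction(comb(n1, x) * comb(n2, k - x), denom)
        for x in range(max(0, k - n2), min(k, n1) + 1)
    ]
    p_obs = Fraction(comb(n1, a) * comb(n2, c), denom)
    return float(sum(p for p in probs if p <= p_obs))


def g_closed_form(table):
    """G = 2 sum n ln(n/e) computed term by term with scalar math."""
    (a, b), (c, d) = table
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if n == 0 or 0 in rows or 0 in cols:
        return 0.0
    g = 0.0
    for val, r, col in ((a, 0, 0), (b, 0, 1), (c, 1, 0), (d, 1, 1)):
        if val > 0:
            e = rows[r] * cols[col] / n
            g += val * log(val / e)
    return 2.0 * g


def locate_linear_scan(genes, pos):
    """Nearest/overlapping genes by full linear scan over (id, start, end)."""
    hits = sorted(g[0] for g in genes if g[1] <= pos <= g[2])
    if hits:
        return ("genic", tuple(hits))
    left = min(
        ((g[0], pos - g[2]) for g in genes if g[2] < pos),
        key=lambda t: t[1],
        default=None,
    )
    right = min(
        ((g[0], g[1] - pos) for g in genes if g[1] > pos),
        key=lambda t: t[1],
        default=None,
    )
    return ("intergenic", left, right)
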