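"""Per-marker and windowed statistics for bulked-segregant scans.

All functions are pure.  Marker-level quantities operate on the oriented
biallelic counts of one site; window-level quantities (moving averages,
ED100^4, Bonferroni thresholds, averaged confidence bands) are deferred to
the binning and plotting stages because they need the whole marker set.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm

_TIE_REL = 1e-12  # two-sided Fisher: tables within this relative slack tie


def snp_index(count_a: int, count_b: int, oriented: bool = True) -> float:
    """Allele frequency at one site in one bulk.

    Oriented: frequency of the allele inherited from the recessive parent
    (count_a).  Unoriented: frequency of the most abundant allele, which is
    by construction >= 0.5.
    """
    total = count_a + count_b
    if total <= 0:
        raise ValueError("snp_index requires positive depth")
    if oriented:
        return count_a / total
    return max(count_a, count_b) / total


def delta_snp_index(index_top: float, index_bottom: float, oriented: bool = True) -> float:
    """Difference of SNP-indices: D-minus-R (MBS) or H-minus-L (QTL-seq).

    Signed when alleles are oriented by parental origin; otherwise the
    absolute difference is reported.
    """
    d = index_top - index_bottom
    return d if oriented else abs(d)


def _logcomb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_exact_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher exact test on a 2x2 bulk-by-allele count table.

    p is the total hypergeometric probability of all tables with the same
    margins whose point probability does not exceed that of the observed
    table (ties included).  A zero margin returns 1 by convention.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n1, n2 = a + b, c + d
    k = a + c
    n = n1 + n2
    if n == 0 or n1 == 0 or n2 == 0 or k == 0 or k == n:
        return 1.0
    lo, hi = max(0, k - n2), min(k, n1)
    support = np.arange(lo, hi + 1)
    logp = _logcomb(n1, support) + _logcomb(n2, k - support) - _logcomb(n, k)
    p = np.exp(logp - logp.max())
    p /= p.sum()  # exact normalization of the hypergeometric support
    p_obs = p[a - lo]
    return float(min(1.0, p[p <= p_obs * (1.0 + _TIE_REL)].sum()))


def g_statistic(table: Sequence[Sequence[int]]) -> float:
    """Likelihood-ratio G statistic, 2*sum(n*ln(n/e)) with 0*ln(0)=0.

    e is the margin-product expected count.  G >= 0, equals 0 exactly for
    tables whose proportions match across bulks, and is invariant under row
    and column swaps.  A zero margin yields G = 0.
    """
    t = np.asarray(table, dtype=float)
    n = t.sum()
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return 0.0
    e = np.outer(rows, cols) / n
    mask = t > 0
    g = 2.0 * float(np.sum(t[mask] * np.log(t[mask] / e[mask])))
    return max(g, 0.0)


def euclidean_distance_marker(
    af_a: Sequence[float], af_b: Sequence[float]
) -> float:
    """Per-marker Euclidean distance between two allele-frequency vectors.

    For a biallelic site this equals sqrt(2)*|delta AF| and lies in
    [0, sqrt(2)].
    """
    a = np.asarray(af_a, dtype=float)
    b = np.asarray(af_b, dtype=float)
    return float(np.sqrt(np.sum((a - b) ** 2)))


def ed_window_power(ed_values: Sequence[float], window: int = 100) -> float:
    """Fourth power of the sum of `window` consecutive per-marker distances."""
    v = np.asarray(ed_values, dtype=float)
    if v.size != window:
        raise ValueError(f"expected exactly {window} values, got {v.size}")
    return float(v.sum() ** 4)


def ed_power_series(
    ed_values: Sequence[float], window: int = 100, stride: int = 1
) -> np.ndarray:
    """Sliding (sum of ED over `window` markers)^4 along one chromosome.

    Windows advance by `stride` markers (default 1, i.e. overlapping).
    Chromosomes with fewer than `window` markers yield an empty array: the
    statistic is simply omitted for them.
    """
    v = np.asarray(ed_values, dtype=float)
    if v.size < window:
        return np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(v)])
    sums = c[window:] - c[:-window]
    return sums[::stride] ** 4


def weighted_moving_average(
    values: Sequence[float],
    weights: Sequence[float] | None,
    n: int,
) -> np.ndarray:
    """Depth-weighted moving average over n adjacent markers.

    Centered window, truncated at the ends of the series (windows never
    span chromosomes; apply per chromosome).  ``weights=None`` means
    uniform weights, reducing to the arithmetic moving average; ``n=1`` is
    the identity.
    """
    v = np.asarray(values, dtype=float)
    if n < 1:
        raise ValueError("window size must be >= 1")
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != v.shape:
        raise ValueError("values and weights must align")
    left = (n - 1) // 2
    right = n // 2
    idx = np.arange(v.size)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, v.size)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cvw = np.concatenate([[0.0], np.cumsum(v * w)])
    den = cw[hi] - cw[lo]
    num = cvw[hi] - cvw[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def physical_window_average(
    positions: Sequence[int],
    values: Sequence[float],
    weights: Sequence[float] | None,
    size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """One weighted mean per non-overlapping genomic interval of `size` bp.

    Returns (interval midpoints, averages); empty intervals emit nothing.
    """
    pos = np.asarray(positions, dtype=np.int64)
    v = np.asarray(values, dtype=float)
    w = np.ones_like(v) if weights is None else np.asarray(weights, dtype=float)
    if size < 1:
        raise ValueError("window size must be >= 1")
    bins = (pos - 1) // size
    mids, avgs = [], []
    for b in np.unique(bins):
        m = bins == b
        den = w[m].sum()
        if den <= 0:
            continue
        mids.append(b * size + (size + 1) / 2.0)
        avgs.append(float((v[m] * w[m]).sum() / den))
    return np.asarray(mids), np.asarray(avgs)


def boost(af, cap: float = 100.0):
    """SHOREmap-style amplification of allele frequencies near fixation.

    Reciprocal distance to fixation, 1/(1-af), clipped to ``cap`` so that
    af=1 stays finite.  Monotonically increasing on [0, 1); boost(0)=1.
    """
    a = np.clip(np.asarray(af, dtype=float), 0.0, 1.0)
    with np.errstate(divide="ignore"):
        b = np.where(a < 1.0, 1.0 / (1.0 - a), np.inf)
    out = np.minimum(b, cap)
    return float(out) if np.isscalar(af) or out.ndim == 0 else out


def delta_ci_bounds(
    counts_top: tuple[int, int],
    counts_bottom: tuple[int, int],
    alpha: float = 0.05,
    n_tests: int = 1,
) -> tuple[float, float]:
    """Per-marker confidence bounds for the difference of two proportions.

    delta +/- z_{1-alpha/(2*n_tests)} * sqrt(p1 q1/d1 + p2 q2/d2), i.e. the
    normal-approximation interval with Bonferroni-adjusted level.  The
    plotted band is the moving average of these per-marker limits.
    """
    if not (0.0 < alpha < 1.0) or n_tests < 1:
        raise ValueError("alpha in (0,1) and n_tests >= 1 required")
    a1, b1 = counts_top
    a2, b2 = counts_bottom
    d1, d2 = a1 + b1, a2 + b2
    if d1 == 0 or d2 == 0:
        raise ValueError("both bulks need positive depth")
    p1, p2 = a1 / d1, a2 / d2
    z = norm.ppf(1.0 - alpha / (2.0 * n_tests))
    se = math.sqrt(p1 * (1 - p1) / d1 + p2 * (1 - p2) / d2)
    delta = p1 - p2
    return delta - z * se, delta + z * se


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Plotting threshold -log10(alpha/n_tests) for n_tests markers."""
    if not (0.0 < alpha < 1.0) or n_tests < 1:
        raise ValueError("alpha in (0,1) and n_tests >= 1 required")
    return -math.log10(alpha / n_tests)


# ---------------------------------------------------------------------------
# per-site assembly used by the mbs/qtl/merge pipelines


def site_statistics(
    counts: Mapping[str, tuple[int, int]], oriented: bool, mode: str
) -> dict[str, float]:
    """All marker statistics computable from one site's bulk counts.

    ``counts[bulk] = (allele-A reads, allele-B reads)`` with allele A the
    recessive-parent (or P-parent) allele when oriented.  Two-bulk
    statistics (delta, Fisher p, G, ED) appear only when both bulks of the
    design are present.
    """
    top, bottom = ("D", "R") if mode == "mbs" else ("H", "L")
    out: dict[str, float] = {}
    for bulk, (a, b) in counts.items():
        out[f"SNPIDX_{bulk}"] = snp_index(a, b, oriented)
    if top in counts and bottom in counts:
        at, bt = counts[top]
        ab, bb = counts[bottom]
        dt, db = at + bt, ab + bb
        if oriented:
            out["DELTA"] = delta_snp_index(at / dt, ab / db, True)
        else:
            out["DELTA"] = abs(at / dt - ab / db)
        out["PVALUE"] = fisher_exact_two_tailed(((at, bt), (ab, bb)))
        out["GSTAT"] = g_statistic(((at, bt), (ab, bb)))
        out["ED"] = euclidean_distance_marker(
            (at / dt, bt / dt), (ab / db, bb / db)
        )
    return out
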