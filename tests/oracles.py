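"""Independent brute-force reference implementations used only in tests.

Each oracle is deliberately written with a different algorithmic route
than the library (explicit loops, generic least-squares, grid search) so
agreement is informative.
"""

import numpy as np
from scipy import stats


def ivw_by_sums(beta_exp, se_exp, beta_out, se_out):
    """IVW point estimate and fixed-effects SE via explicit scalar sums."""
    num = den = 0.0
    for bx, so, bo in zip(beta_exp, se_out, beta_out):
        num += bx * bo / so ** 2
        den += bx ** 2 / so ** 2
    return num / den, (1.0 / den) ** 0.5


def wls_by_statsmodels(beta_exp, beta_out, se_out):
    """Generic weighted least squares (intercept + slope) via statsmodels."""
    import statsmodels.api as sm

    bx = np.asarray(beta_exp, dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    x = sm.add_constant(bx * sign)
    fit = sm.WLS(np.asarray(beta_out) * sign, x,
                 weights=1.0 / np.asarray(se_out) ** 2).fit()
    return fit.params[0], fit.params[1]


def weighted_median_by_scan(theta, weights):
    """Weighted median via explicit cumulative scan and interpolation."""
    order = sorted(range(len(theta)), key=lambda i: theta[i])
    th = [theta[i] for i in order]
    w = [weights[i] for i in order]
    total = sum(w)
    w = [x / total for x in w]
    cum = 0.0
    mids = []
    for wi in w:
        mids.append(cum + wi / 2)
        cum += wi
    if 0.5 <= mids[0]:
        return th[0]
    if 0.5 >= mids[-1]:
        return th[-1]
    for k in range(1, len(mids)):
        if mids[k - 1] <= 0.5 <= mids[k]:
            frac = (0.5 - mids[k - 1]) / (mids[k] - mids[k - 1])
            return th[k - 1] + frac * (th[k] - th[k - 1])
    raise AssertionError("unreachable")


def kde_mode_by_grid(theta, weights, bandwidth_factor=1.0, n_grid=512):
    """Mode via scipy normal pdf evaluated point by point on the grid."""
    theta = np.asarray(theta, dtype=float)
    j = len(theta)
    sd = np.std(theta, ddof=1)
    iqr = np.percentile(theta, 75) - np.percentile(theta, 25)
    h = bandwidth_factor * 0.9 * min(sd, iqr / 1.349) * j ** (-0.2)
    if h <= 0:
        return float(np.median(theta))
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, n_grid)
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    best_x, best_d = grid[0], -1.0
    for x in grid:
        d = sum(wi * stats.norm.pdf((x - t) / h) for wi, t in zip(w, theta))
        if d > best_d:
            best_d, best_x = d, x
    return float(best_x)


def clump_is_valid(selected, discarded, ld, window_kb, r2_max):
    """Exhaustive pairwise verification of a clumping result: every
    retained pair must be compatible (different chromosome, outside the
    window, or r^2 below threshold) and every discarded variant must
    conflict with some retained variant of better (or equal, earlier
    tie-order) p-value."""
    window_bp = window_kb * 1000.0

    def r2(a, b):
        if ld is None or a.snp_id not in ld or b.snp_id not in ld:
            return 0.0
        return ld.lookup(a.snp_id, b.snp_id)

    def conflicts(a, b):
        return (a.chrom == b.chrom and abs(a.pos - b.pos) <= window_bp
                and r2(a, b) >= r2_max)

    for i, a in enumerate(selected):
        for b in selected[i + 1:]:
            if conflicts(a, b):
                return False
    for d in discarded:
        if not any(conflicts(k, d) and k.pval <= d.pval for k in selected):
            return False
    return True


def clump_by_rebuild(snps, ld, window_kb, r2_max):
    """Independent greedy reimplementation using index bookkeeping."""
    def chrom_key(c):
        try:
            return (0, int(c), "")
        except ValueError:
            return (1, 0, c)

    remaining = sorted(snps, key=lambda s: (s.pval, chrom_key(s.chrom), s.pos))
    window_bp = window_kb * 1000.0
    picked = []
    while remaining:
        idx = remaining[0]
        picked.append(idx)
        keep = []
        for s in remaining[1:]:
            if s.chrom != idx.chrom or abs(s.pos - idx.pos) > window_bp:
                keep.append(s)
                continue
            r2 = 0.0
            if ld is not None and s.snp_id in ld and idx.snp_id in ld:
                r2 = ld.lookup(s.snp_id, idx.snp_id)
            if r2 < r2_max:
                keep.append(s)
        remaining = keep
    return picked
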