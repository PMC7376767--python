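"""Independent brute-force / extended-precision oracles used by the tests.

These deliberately avoid the code paths they check: morphology by pure
Python voxel loops, regression by exact rational normal equations, p-values
by mpmath's regularized incomplete beta, and Dixon fitting by exhaustive
grid search over the nonlinear parameters.
"""

from __future__ import annotations

from fractions import Fraction

import mpmath
import numpy as np

mpmath.mp.dps = 50


# ---------------------------------------------------------------------------
# Morphology (pure Python voxel loops)

def brute_threshold(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    out = np.zeros(values.shape, dtype=bool)
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            for k in range(values.shape[2]):
                out[i, j, k] = lo <= values[i, j, k] <= hi
    return out


def brute_intersect(masks) -> np.ndarray:
    out = np.ones(masks[0].shape, dtype=bool)
    for m in masks:
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                for k in range(out.shape[2]):
                    out[i, j, k] = out[i, j, k] and m[i, j, k]
    return out


def brute_erode_once(mask: np.ndarray) -> np.ndarray:
    """One erosion with the 6-connected cross; outside counts as background."""
    nx, ny, nz = mask.shape
    out = np.zeros_like(mask)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k]:
                    continue
                keep = True
                for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if not (0 <= ii < nx and 0 <= jj < ny and 0 <= kk < nz):
                        keep = False
                        break
                    if not mask[ii, jj, kk]:
                        keep = False
                        break
                out[i, j, k] = keep
    return out


def brute_erode(mask: np.ndarray, n: int) -> np.ndarray:
    out = mask.copy()
    for _ in range(n):
        out = brute_erode_once(out)
    return out


def brute_label_sizes(mask: np.ndarray) -> list[int]:
    """Sizes of 6-connected components via flood fill."""
    seen = np.zeros(mask.shape, dtype=bool)
    sizes = []
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if not mask[i, j, k] or seen[i, j, k]:
                    continue
                stack = [(i, j, k)]
                seen[i, j, k] = True
                size = 0
                while stack:
                    a, b, c = stack.pop()
                    size += 1
                    for da, db, dc in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                       (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                        aa, bb, cc = a + da, b + db, c + dc
                        if (0 <= aa < nx and 0 <= bb < ny and 0 <= cc < nz
                                and mask[aa, bb, cc] and not seen[aa, bb, cc]):
                            seen[aa, bb, cc] = True
                            stack.append((aa, bb, cc))
                sizes.append(size)
    return sizes


# ---------------------------------------------------------------------------
# Statistics (exact rationals + mpmath)

def t_sf_two_sided(t: float, df: int) -> float:
    """Two-sided Student-t p-value via the regularized incomplete beta."""
    t = mpmath.mpf(abs(float(t)))
    x = df / (df + t ** 2)
    return float(mpmath.betainc(mpmath.mpf(df) / 2, mpmath.mpf(1) / 2,
                                0, x, regularized=True))


def exact_ols(X_rows, y):
    """OLS by exact rational normal equations.

    X_rows: list of predictor rows WITHOUT intercept; an intercept column is
    prepended. Returns dict with beta, se, t, p, r2, adj_r2 (floats).
    """
    n = len(y)
    X = [[Fraction(1)] + [Fraction(v).limit_denominator(10 ** 12)
                          for v in row] for row in X_rows]
    yv = [Fraction(v).limit_denominator(10 ** 12) for v in y]
    p = len(X[0])
    # normal equations A beta = b with exact rationals
    A = [[sum(X[i][r] * X[i][c] for i in range(n)) for c in range(p)]
         for r in range(p)]
    b = [sum(X[i][r] * yv[i] for i in range(n)) for r in range(p)]
    Ainv = _mat_inv(A)
    beta = [sum(Ainv[r][c] * b[c] for c in range(p)) for r in range(p)]
    resid = [yv[i] - sum(X[i][c] * beta[c] for c in range(p)) for i in range(n)]
    rss = sum(r * r for r in resid)
    ybar = sum(yv) / n
    sstot = sum((v - ybar) ** 2 for v in yv)
    df_resid = n - p
    sigma2 = rss / df_resid
    se = [mpmath.sqrt(mpmath.mpf(float(sigma2 * Ainv[j][j]))) for j in range(p)]
    tvals = [float(mpmath.mpf(float(beta[j])) / se[j]) if se[j] != 0 else 0.0
             for j in range(p)]
    pvals = [t_sf_two_sided(tj, df_resid) for tj in tvals]
    r2 = 1 - rss / sstot if sstot else Fraction(0)
    adj = 1 - (1 - r2) * Fraction(n - 1, df_resid)
    return {
        "beta": [float(v) for v in beta],
        "se": [float(v) for v in se],
        "t": tvals,
        "p": pvals,
        "r2": float(r2),
        "adj_r2": float(adj),
    }


def _mat_inv(A):
    """Exact Gauss-Jordan inverse of a rational matrix."""
    n = len(A)
    M = [row[:] + [Fraction(int(i == j)) for j in range(n)]
         for i, row in enumerate(A)]
    for col in range(n):
        piv = next(r for r in range(col, n) if M[r][col] != 0)
        M[col], M[piv] = M[piv], M[col]
        inv = Fraction(1) / M[col][col]
        M[col] = [v * inv for v in M[col]]
        for r in range(n):
            if r != col and M[r][col] != 0:
                f = M[r][col]
                M[r] = [vr - f * vc for vr, vc in zip(M[r], M[col])]
    return [row[n:] for row in M]


def exact_paired_t(x, y):
    """Paired t statistic and two-sided p in extended precision."""
    d = [mpmath.mpf(a) - mpmath.mpf(b) for a, b in zip(x, y)]
    n = len(d)
    mean = mpmath.fsum(d) / n
    var = mpmath.fsum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / mpmath.sqrt(var / n)
    return float(t), n - 1, t_sf_two_sided(float(t), n - 1)


# ---------------------------------------------------------------------------
# Dixon grid-search oracle

def dixon_grid_oracle(signals: np.ndarray, te_ms, fat_phasor: np.ndarray,
                      ff_step: float = 2.0, psi_range: float = 100.0,
                      psi_step: float = 1.0, r2_max: float = 120.0,
                      r2_step: float = 10.0, zoom_stages: int = 5):
    """Exhaustive search over (FF, psi, R2*) minimizing the fit residual.

    At every (psi, R2*) lattice point the full FF axis is scanned and the
    complex scalar amplitude is the closed-form projection of the signal
    onto the model direction. The residual has a long, nearly flat valley
    coupling FF with (psi, R2*), so after the global coarse pass the
    (psi, R2*) lattice is iteratively zoomed (8x finer per stage, spanning
    +/-2 previous steps) with the FF axis re-scanned densely each time.
    Returns (ff_per_mille, psi_hz, r2star) arrays of shape (n_voxels,).
    """
    te_s = np.asarray(te_ms, dtype=float) / 1000.0
    s = np.asarray(signals)  # (E, N)
    nvox = s.shape[1]

    ff_grid = np.arange(0.0, 1000.0 + 1e-9, ff_step)
    frac = ff_grid / 1000.0
    base = (1 - frac)[:, None] + frac[:, None] * fat_phasor[None, :]  # (F, E)
    base_conj = np.conj(base)
    base_pow = np.abs(base) ** 2
    s_pow = (np.abs(s) ** 2).sum(axis=0)  # (N,)

    def best_over_ff(psi_v, r2_v):
        """Min-over-FF residual at per-voxel (psi, r2); returns (rss, ff)."""
        g = np.exp((-2j * np.pi * psi_v - r2_v)[None, :] * te_s[:, None])
        num = np.abs(base_conj @ (s * g)) ** 2          # (F, N)
        mm = base_pow @ np.exp(-2.0 * r2_v[None, :] * te_s[:, None])  # (F, N)
        proj = num / mm
        k = np.argmax(proj, axis=0)
        return s_pow - proj[k, np.arange(nvox)], ff_grid[k]

    # global coarse pass over the full (psi, r2) lattice
    best = np.full(nvox, np.inf)
    ff = np.zeros(nvox)
    psi = np.zeros(nvox)
    r2 = np.zeros(nvox)
    for p in np.arange(-psi_range, psi_range + 1e-9, psi_step):
        for r in np.arange(0.0, r2_max + 1e-9, r2_step):
            rss, ffb = best_over_ff(np.full(nvox, p), np.full(nvox, r))
            better = rss < best
            best[better] = rss[better]
            ff[better] = ffb[better]
            psi[better] = p
            r2[better] = r

    # iterative zoom on (psi, r2) with dense FF re-scan
    dp, dr = psi_step, r2_step
    for _ in range(zoom_stages):
        dp, dr = dp / 8, dr / 8
        best = np.full(nvox, np.inf)
        bf, bp, br = ff.copy(), psi.copy(), r2.copy()
        for j in range(-8, 9):
            for k in range(-8, 9):
                cp = psi + j * dp
                cr = np.clip(r2 + k * dr, 0.0, None)
                rss, ffb = best_over_ff(cp, cr)
                better = rss < best
                best[better] = rss[better]
                bf[better] = ffb[better]
                bp[better] = cp[better]
                br[better] = cr[better]
        ff, psi, r2 = bf, bp, br

    # final dense FF polish at the converged (psi, r2)
    for fine in (ff_step / 10, ff_step / 100):
        best = np.full(nvox, np.inf)
        bf = ff.copy()
        for i in range(-12, 13):
            cf = np.clip(ff + i * fine, 0, 1000)
            rss = _rss_at(s, te_s, fat_phasor, cf, psi, r2)
            better = rss < best
            best[better] = rss[better]
            bf[better] = cf[better]
        ff = bf
    return _polish_pattern_search(s, te_s, fat_phasor, ff, psi, r2)


def _polish_pattern_search(s, te_s, fat_phasor, ff, psi, r2, iters=40):
    """Joint (FF, psi, R2*) pattern search in extended precision.

    The residual valley is so flat that double-precision evaluation noise
    limits the FF resolution near the optimum; long-double arithmetic
    resolves the minimum to well below the per-mille scale.
    """
    sl = np.asarray(s).astype(np.clongdouble)
    te_l = np.asarray(te_s).astype(np.longdouble)
    cl = np.asarray(fat_phasor).astype(np.clongdouble)
    nvox = sl.shape[1]

    def rss_at(cf, cp, cr):
        frac = (cf / 1000.0).astype(np.longdouble)
        m = ((1 - frac)[None, :] + frac[None, :] * cl[:, None]) * np.exp(
            (2j * np.pi * cp.astype(np.longdouble)
             - cr.astype(np.longdouble))[None, :] * te_l[:, None])
        mm = (np.abs(m) ** 2).sum(axis=0)
        amp = (np.conj(m) * sl).sum(axis=0) / mm
        return (np.abs(sl - m * amp[None, :]) ** 2).sum(axis=0)

    scale = np.ones(nvox, dtype=np.longdouble)
    cur = rss_at(ff, psi, r2)
    steps = (0.2, 0.02, 0.2)
    for _ in range(iters):
        nb = cur.copy()
        bf, bp, br = ff.copy(), psi.copy(), r2.copy()
        for i in (-1, 0, 1):
            for j in (-1, 0, 1):
                for k in (-1, 0, 1):
                    if i == j == k == 0:
                        continue
                    cf = np.clip(ff + i * steps[0] * scale, 0, 1000)
                    cp = psi + j * steps[1] * scale
                    cr = np.clip(r2 + k * steps[2] * scale, 0, None)
                    rss = rss_at(cf, cp, cr)
                    better = rss < nb
                    nb[better] = rss[better]
                    bf[better] = cf[better]
                    bp[better] = cp[better]
                    br[better] = cr[better]
        improved = nb < cur
        scale[~improved] *= 0.5
        ff, psi, r2, cur = bf, bp, br, nb
    return (np.asarray(ff, dtype=float), np.asarray(psi, dtype=float),
            np.asarray(r2, dtype=float))


def _rss_at(s, te_s, fat_phasor, ff, psi, r2):
    frac = np.atleast_1d(ff) / 1000.0
    m = (((1 - frac)[None, :] + frac[None, :] * fat_phasor[:, None])
         * np.exp((2j * np.pi * np.atleast_1d(psi) - np.atleast_1d(r2))[None, :]
                  * te_s[:, None]))
    mm = (np.abs(m) ** 2).sum(axis=0)
    amp = (np.conj(m) * s).sum(axis=0) / np.where(mm == 0, 1, mm)
    return (np.abs(s - m * amp[None, :]) ** 2).sum(axis=0)
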