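"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they are checking: the sinusoid
oracle scans a dense (c, d) grid with an exact 2-parameter linear solve
per node (plus one local refinement pass), rather than quasi-Newton
iterations or the concentrated-over-c solver the package uses.
"""

import numpy as np

from valuewave.sine_fit import c_bounds, d_bounds


def _best_ssr_on_grid(y, x, c_grid, d_grid):
    """Exact min-SSR over (a, b) for every (c, d) node; return the best.

    For fixed (c, d) the model a + b*sin(c*x + d) is linear in (a, b),
    so the optimum is a 2x2 least-squares solve.  Valid as a bound on
    the box-constrained problem whenever the unconstrained (a, b) stays
    inside [-1, 1], which holds for profiles well inside the unit box.
    """
    k = y.size
    cc, dd = np.meshgrid(c_grid, d_grid, indexing="ij")
    phase = cc[..., None] * x + dd[..., None]  # (nc, nd, K)
    s = np.sin(phase)
    t1 = s.sum(axis=-1)
    t2 = (s * s).sum(axis=-1)
    sy = (s * y).sum(axis=-1)
    ysum = y.sum()
    det = k * t2 - t1 * t1
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (ysum * t2 - sy * t1) / det
        b = (k * sy - ysum * t1) / det
    ssr = (
        (y * y).sum()
        + k * a * a
        + b * b * t2
        + 2 * a * b * t1
        - 2 * a * ysum
        - 2 * b * sy
    )
    ssr = np.where(np.isfinite(ssr), ssr, np.inf)
    i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
    assert abs(a[i, j]) <= 1 and abs(b[i, j]) <= 1, "oracle left the box"
    return float(ssr[i, j]), float(c_grid[i]), float(d_grid[j])


def grid_search_ssr(y, convention="circle", n_c=60, n_d=240):
    """Dense (c, d) grid search with one refinement pass around the min."""
    y = np.asarray(y, dtype=float)
    k = y.size
    x = np.arange(1, k + 1, dtype=float)
    clo, chi = c_bounds(k, convention)
    dlo, dhi = d_bounds(k, convention)
    c_grid = np.linspace(clo, chi, n_c)
    d_grid = np.linspace(dlo, dhi, n_d)
    ssr0, c0, d0 = _best_ssr_on_grid(y, x, c_grid, d_grid)
    hc = c_grid[1] - c_grid[0]
    hd = d_grid[1] - d_grid[0]
    c_ref = np.linspace(max(clo, c0 - hc), min(chi, c0 + hc), n_c)
    d_ref = np.linspace(max(dlo, d0 - hd), min(dhi, d0 + hd), n_d)
    ssr1, _, _ = _best_ssr_on_grid(y, x, c_ref, d_ref)
    return min(ssr0, ssr1)


def pearson_r(u, v):
    """Textbook Pearson correlation from raw sums (no numpy shortcut)."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    n = u.size
    su, sv = u.sum(), v.sum()
    num = n * (u * v).sum() - su * sv
    den = np.sqrt(n * (u * u).sum() - su * su) * np.sqrt(
        n * (v * v).sum() - sv * sv
    )
    return num / den
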