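"""Constrained sinusoid fits to ordered correlation profiles.

A circumplex model predicts that the correlations of an external variable
with the K value types, ordered by their position on the value circle,
trace one period of a sine wave:

    y = a + b * sin(c * x + d),   x = 1 .. K

with the vertical offset ``a`` and amplitude ``b`` box-constrained to
[-1, 1] (the range of correlation coefficients), the angular frequency
``c`` restricted to 85–95% of a full wave across the K positions (the
circle's spacing is not assumed exactly equal), and the phase ``d``
effectively unrestricted.  Fit quality is summarised by the Sinusoidal
Fit Index

    SFI = SSR / TSS

(residual sum of squares of the fitted sinusoid over the total sum of
squares of the profile): 0 is a perfect sinusoid, 1 is no improvement
over the profile mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

#: Circular order of the 10 Schwartz value types used on the x-axis.
DEFAULT_VALUE_ORDER: tuple[str, ...] = (
    "conformity",
    "tradition",
    "benevolence",
    "universalism",
    "self-direction",
    "stimulation",
    "hedonism",
    "achievement",
    "power",
    "security",
)


def c_bounds(k: int, convention: str = "circle") -> tuple[float, float]:
    """Bounds on the angular frequency ``c`` for a K-point profile.

    ``"circle"`` (default): the K ordered points span 0.85–0.95 of one
    full period, i.e. c in [0.85, 0.95] * 2*pi/K.

    ``"period-units"``: the alternative reading in which the *period*
    measures 0.85–0.95 * K position units, i.e.
    c in [2*pi/(0.95*K), 2*pi/(0.85*K)].
    """
    if k < 2:
        raise ValueError("profile length k must be >= 2")
    if convention == "circle":
        return 0.85 * 2 * math.pi / k, 0.95 * 2 * math.pi / k
    if convention == "period-units":
        return 2 * math.pi / (0.95 * k), 2 * math.pi / (0.85 * k)
    raise ValueError(f"unknown c-bound convention: {convention!r}")


def d_bounds(k: int, convention: str = "circle") -> tuple[float, float]:
    """Phase bounds wide enough that every phase at x = 1 is reachable.

    The phase of the wave at the first position is c + d; for it to cover
    the full circle [-pi, pi] at any admissible c the box on d must be
    [-pi - c_hi, pi - c_lo] (slightly wider than one period).
    """
    lo, hi = c_bounds(k, convention)
    return -math.pi - hi, math.pi - lo


@dataclass(frozen=True)
class SineParams:
    """Parameters of ``y = a + b * sin(c * x + d)``."""

    a: float  # vertical offset, in correlation units
    b: float  # amplitude, in correlation units
    c: float  # angular frequency, radians per position
    d: float  # phase offset, radians

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=float)


def sine_model(x, params: SineParams) -> np.ndarray | float:
    """Evaluate the sinusoid at position(s) ``x``."""
    x = np.asarray(x, dtype=float)
    out = params.a + params.b * np.sin(params.c * x + params.d)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class CorrelationProfile:
    """Ordered correlations of K value types with an external variable.

    ``labels`` follow the circular order; positions are the integers
    1..K.  Values must be valid correlation coefficients.
    """

    labels: tuple[str, ...]
    y: np.ndarray

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) != y.size:
            raise ValueError("labels and y must have equal length")
        if y.size < 4:
            raise ValueError("profile needs at least 4 points (K >= 4)")
        if not np.all(np.isfinite(y)):
            raise ValueError("profile contains non-finite correlations")
        if np.any(np.abs(y) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def k(self) -> int:
        return self.y.size

    @property
    def x(self) -> np.ndarray:
        return np.arange(1, self.k + 1, dtype=float)

    def drop(self, label: str) -> "CorrelationProfile":
        """Remove one value type; remaining points re-index to 1..K-1."""
        if label not in self.labels:
            raise KeyError(f"unknown value type: {label!r}")
        keep = [i for i, lab in enumerate(self.labels) if lab != label]
        return CorrelationProfile(
            labels=tuple(self.labels[i] for i in keep), y=self.y[keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": self.labels, "position": self.x.astype(int), "r": self.y}
        )


def compute_sfi(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Sinusoidal Fit Index: residual SS over total SS of the profile.

    Defined as the residual variance of the fit divided by the variance
    of the observed correlations; the shared 1/(K-1) factors cancel, so
    it is computed as SSR / TSS.  Undefined (error) when the profile has
    zero variance.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size != y_hat.size:
        raise ValueError("y and y_hat must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 points")
    tss = float(np.sum((y - y.mean()) ** 2))
    # correlations are O(1), so anything below this is numerically constant
    if tss <= 1e-20:
        raise ValueError("SFI undefined: profile has zero variance")
    ssr = float(np.sum((y - y_hat) ** 2))
    return ssr / tss


@dataclass(frozen=True)
class SineFitResult:
    """Result of a constrained sinusoid fit."""

    params: SineParams
    fitted: np.ndarray
    ssr: float
    sfi: float
    n_starts: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "a": self.params.a,
            "b": self.params.b,
            "c": self.params.c,
            "d": self.params.d,
            "ssr": self.ssr,
            "sfi": self.sfi,
            "n_starts": self.n_starts,
            "converged": self.converged,
        }


def _canonical(a: float, b: float, c: float, d: float, k: int,
               convention: str) -> SineParams:
    """Fold the sine symmetry b -> -b, d -> d + pi into b >= 0 and wrap d."""
    if b < 0:
        b, d = -b, d + math.pi
    lo, hi = d_bounds(k, convention)
    width = hi - lo
    # wrap by full periods into the admissible phase box
    while d > hi:
        d -= 2 * math.pi
    while d < lo:
        d += 2 * math.pi
    if d > hi:  # box is wider than 2*pi, so this cannot trigger; guard anyway
        d = lo + (d - lo) % width
    return SineParams(a=float(a), b=float(b), c=float(c), d=float(d))


def fit_sine(
    profile: CorrelationProfile,
    n_starts: int = 16,
    seed: int | None = None,
    c_convention: str = "circle",
    random_starts: int = 0,
) -> SineFitResult:
    """Fit the constrained sinusoid by multi-start bounded quasi-Newton.

    Minimises the residual sum of squares with L-BFGS-B inside the box
    (a, b in [-1, 1]; c in the 85–95%-of-a-wave band; d spanning one full
    period of phase).  Starts form a deterministic grid over the phase d
    (covering one period) crossed with amplitude signs b = ±0.5, with c
    at its bound midpoint and a at the profile mean.  ``seed`` is used
    only when ``random_starts`` additional random initial points are
    requested; the default fit is fully deterministic.

    The constant model (b = 0, a = profile mean) is always admissible
    for correlation data, so the returned SSR never exceeds the total
    sum of squares and SFI lies in [0, 1].
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    y = profile.y
    x = profile.x
    k = profile.k
    if k <= 4:
        import warnings

        warnings.warn(
            "K <= 4: the 4-parameter sinusoid is (nearly) saturated",
            stacklevel=2,
        )
    clo, chi = c_bounds(k, c_convention)
    dlo, dhi = d_bounds(k, c_convention)
    bounds = [(-1.0, 1.0), (-1.0, 1.0), (clo, chi), (dlo, dhi)]

    def objective(theta):
        a, b, c, d = theta
        s = np.sin(c * x + d)
        r = a + b * s - y
        g = np.empty(4)
        cosv = np.cos(c * x + d)
        g[0] = 2.0 * r.sum()
        g[1] = 2.0 * (r * s).sum()
        g[2] = 2.0 * b * (r * cosv * x).sum()
        g[3] = 2.0 * b * (r * cosv).sum()
        return float(r @ r), g

    a0 = float(np.clip(y.mean(), -1.0, 1.0))
    cmid = 0.5 * (clo + chi)
    n_phase = max(1, (n_starts + 1) // 2)
    d_grid = np.linspace(dlo, dhi, n_phase, endpoint=False)
    starts = []
    for d0 in d_grid:
        for b0 in (0.5, -0.5):
            starts.append((a0, b0, cmid, d0))
    starts = starts[:n_starts]
    if random_starts > 0:
        rng = np.random.default_rng(seed)
        for _ in range(random_starts):
            starts.append(
                (
                    rng.uniform(-1, 1),
                    rng.uniform(-1, 1),
                    rng.uniform(clo, chi),
                    rng.uniform(dlo, dhi),
                )
            )

    best = None
    any_converged = False
    for theta0 in starts:
        res = minimize(
            objective,
            np.asarray(theta0, dtype=float),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-12, "maxiter": 500},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not any_converged:
        raise RuntimeError(
            "sine fit failed to converge from every start "
            f"(n_starts={len(starts)}); last status: {best and best.message}"
        )

    a, b, c, d = best.x
    ssr = float(best.fun)
    tss = float(np.sum((y - y.mean()) ** 2))
    # the feasible constant model caps SSR at TSS
    if ssr > tss:
        a, b, c, d = a0, 0.0, cmid, 0.0
        ssr = tss
    params = _canonical(a, b, c, d, k, c_convention)
    fitted = sine_model(x, params)
    return SineFitResult(
        params=params,
        fitted=np.asarray(fitted),
        ssr=ssr,
        sfi=compute_sfi(y, fitted),
        n_starts=len(starts),
        converged=any_converged,
    )


def _linear_refit(c_vec: np.ndarray, Y: np.ndarray, x: np.ndarray):
    """Per-profile exact least squares at frequency c (linear in a, b1, b2).

    Returns (ssr, coef) with coef columns (a, b*cos d, b*sin d).
    """
    S = np.sin(c_vec[:, None] * x[None, :])
    C = np.cos(c_vec[:, None] * x[None, :])
    X = np.stack([np.ones_like(S), S, C], axis=2)  # (m, K, 3)
    A = np.einsum("mki,mkj->mij", X, X)
    rhs = np.einsum("mki,mk->mi", X, Y)
    coef = np.linalg.solve(A, rhs[..., None])[..., 0]
    fit = np.einsum("mki,mi->mk", X, coef)
    ssr = np.sum((Y - fit) ** 2, axis=1)
    return ssr, coef


def fit_profiles(
    Y: np.ndarray,
    c_convention: str = "circle",
    n_grid: int = 65,
    full: bool = False,
):
    """Globally fit the constrained sinusoid to many profiles at once.

    For fixed frequency c the model is linear in (a, b*cos d, b*sin d),
    so the SSR is concentrated: it is minimised exactly in closed form
    on a grid over the narrow admissible c band, the grid minimum is
    refined by parabolic interpolation, and the linear solve is repeated
    at the refined c.  Profiles whose unconstrained optimum violates the
    a/b box (|a| > 1 or amplitude > 1 — impossible for profiles well
    inside [-1, 1]) are re-fitted with the bounded multi-start
    :func:`fit_sine`.

    Parameters
    ----------
    Y : (n, K) array of profiles (rows are profiles).
    full : return ``(sfi, ssr, params)`` with ``params`` an (n, 4) array
        of (a, b, c, d) instead of the SFI vector alone.

    Notes
    -----
    Rows with zero variance have undefined SFI and are returned as NaN.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, k = Y.shape
    if k < 4:
        raise ValueError("profiles need K >= 4")
    x = np.arange(1, k + 1, dtype=float)
    clo, chi = c_bounds(k, c_convention)
    cs = np.linspace(clo, chi, n_grid)
    h = cs[1] - cs[0]

    yy = np.einsum("ij,ij->i", Y, Y)
    ssr_grid = np.empty((n_grid, n))
    for i, c in enumerate(cs):
        X = np.column_stack([np.ones(k), np.sin(c * x), np.cos(c * x)])
        P = X @ np.linalg.solve(X.T @ X, X.T)
        ssr_grid[i] = yy - np.einsum("ij,ij->i", Y @ P, Y)
    idx = np.argmin(ssr_grid, axis=0)
    rows = np.arange(n)
    c_best = cs[idx]
    ssr_best = ssr_grid[idx, rows]

    # parabolic refinement of the concentrated SSR(c) at interior minima
    interior = (idx > 0) & (idx < n_grid - 1)
    if np.any(interior):
        ii = idx[interior]
        jj = rows[interior]
        s_m, s_0, s_p = (
            ssr_grid[ii - 1, jj],
            ssr_grid[ii, jj],
            ssr_grid[ii + 1, jj],
        )
        denom = s_m - 2.0 * s_0 + s_p
        shift = np.where(
            denom > 0, 0.5 * h * (s_m - s_p) / np.where(denom > 0, denom, 1.0), 0.0
        )
        c_ref = np.clip(cs[ii] + shift, clo, chi)
        ssr_ref, _ = _linear_refit(c_ref, Y[interior], x)
        improved = ssr_ref < ssr_best[interior]
        tmp_c = c_best[interior]
        tmp_c[improved] = c_ref[improved]
        c_best[interior] = tmp_c
        tmp_s = ssr_best[interior]
        tmp_s[improved] = ssr_ref[improved]
        ssr_best[interior] = tmp_s

    ssr_final, coef = _linear_refit(c_best, Y, x)
    # keep the better of grid and refined solves (they agree to rounding)
    ssr_final = np.minimum(ssr_final, ssr_best)
    a = coef[:, 0]
    b = np.hypot(coef[:, 1], coef[:, 2])
    d = np.arctan2(coef[:, 2], coef[:, 1])

    ssr_final = np.maximum(ssr_final, 0.0)
    tss = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    ok = tss > 1e-20  # numerically constant rows have undefined SFI
    with np.errstate(invalid="ignore", divide="ignore"):
        sfi = np.where(ok, ssr_final / np.where(ok, tss, 1.0), np.nan)

    # bounded fallback for the (rare) profiles outside the a/b box
    out_of_box = (np.abs(a) > 1.0) | (b > 1.0)
    if np.any(out_of_box):
        labels = tuple(f"v{j + 1}" for j in range(k))
        for i in np.flatnonzero(out_of_box):
            fit = fit_sine(
                CorrelationProfile(labels=labels, y=Y[i]),
                c_convention=c_convention,
            )
            sfi[i] = fit.sfi
            ssr_final[i] = fit.ssr
            a[i], b[i] = fit.params.a, fit.params.b
            c_best[i], d[i] = fit.params.c, fit.params.d

    sfi = np.where(ok, np.minimum(sfi, 1.0), np.nan)
    if not full:
        return sfi
    return sfi, ssr_final, np.column_stack([a, b, c_best, d])


def correlate_profile(
    value_scores: pd.DataFrame,
    external: pd.Series | np.ndarray,
    order: Sequence[str] = DEFAULT_VALUE_ORDER,
) -> CorrelationProfile:
    """Pearson correlations of each value type with an external variable.

    ``value_scores`` is a participants x value-types frame; ``external``
    is aligned on its index (or positionally for a bare array).  Each
    correlation uses the participants with both measurements present;
    fewer than 3 complete pairs or a constant column is an error.
    """
    if not isinstance(external, pd.Series):
        external = pd.Series(np.asarray(external, dtype=float),
                             index=value_scores.index)
    common = value_scores.index.intersection(external.index)
    if len(common) < 3:
        raise ValueError("need at least 3 participants with both measures")
    vs = value_scores.loc[common]
    ext = external.loc[common].astype(float)

    missing = [lab for lab in order if lab not in vs.columns]
    if missing:
        raise KeyError(f"value types absent from scores: {missing}")

    rs = []
    for lab in order:
        col = vs[lab].astype(float)
        ok = col.notna() & ext.notna()
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 complete pairs for {lab!r}")
        v = col[ok].to_numpy()
        e = ext[ok].to_numpy()
        if np.ptp(v) == 0:
            raise ValueError(f"value type {lab!r} is constant; r undefined")
        if np.ptp(e) == 0:
            raise ValueError("external variable is constant; r undefined")
        rs.append(float(np.corrcoef(v, e)[0, 1]))
    return CorrelationProfile(labels=tuple(order), y=np.array(rs))


def read_profile(path) -> CorrelationProfile:
    """Read a profile from TSV columns (label, position, r)."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values("position")
    return CorrelationProfile(labels=tuple(df["label"]), y=df["r"].to_numpy())


def write_fit_report(result: SineFitResult, profile: CorrelationProfile, path):
    """Write a JSON fit report (parameters, SSR, SFI, convergence)."""
    import json

    payload = result.to_dict()
    payload["labels"] = list(profile.labels)
    payload["y"] = [float(v) for v in profile.y]
    payload["fitted"] = [float(v) for v in result.fitted]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
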