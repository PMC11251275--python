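"""Initial-rate extraction from single absorbance traces.

A well's catalysis is read as a declining A340 (NADH oxidation).  The job
of this module is to locate the initial linear region of a trace, fit an
ordinary least-squares slope there, and convert the slope into a
carboxylation flux (nM of carboxylation events per second) via the
Beer-Lambert relation and the NADH:carboxylation stoichiometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .assay import AssayConstants

#: QC flag names
FLAG_SHORT = "short"
FLAG_FLAT = "flat"
FLAG_DEPLETED = "depleted"
FLAG_NONLINEAR = "nonlinear"
FLAG_CLAMPED = "clamped"


@dataclass
class AbsorbanceTrace:
    """One well's A340 time series.

    ``times`` must be strictly increasing; ``a340`` the same length.
    ``dilution`` is the lysate dilution factor applied before assay
    (metadata carried through to reporting; >= 1).
    """

    sample_id: str
    cabp_nM: float
    dilution: float
    times: np.ndarray
    a340: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.times.ndim != 1 or self.a340.ndim != 1:
            raise ValueError("times and a340 must be 1-D")
        if len(self.times) != len(self.a340):
            raise ValueError("times and a340 must have the same length")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(~np.isfinite(self.times)) or np.any(~np.isfinite(self.a340)):
            raise ValueError("times and a340 must be finite (no NaN/inf)")
        if self.cabp_nM < 0:
            raise ValueError("cabp_nM must be >= 0")
        if self.dilution < 1:
            raise ValueError("dilution factor must be >= 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class WindowPolicy:
    """How the initial-rate window is chosen.

    The default scans candidate start points (on a ``start_grid_s`` grid,
    restricted to the first half of the usable trace), extends each window
    as far as local linearity (R^2 >= ``r2_threshold``) allows, and keeps
    the earliest start that yields a passing window.  Depletion plateaus
    and lag dead-time at the trace ends are trimmed away beforehand.
    """

    min_window_s: float = 60.0
    r2_threshold: float = 0.98
    start_grid_s: float = 30.0
    max_start_frac: float = 0.5
    flat_z: float = 3.0
    #: a window also passes if its residual sd is consistent with the
    #: trace's own read noise (shallow traces can be perfectly linear at
    #: R^2 < threshold simply because noise dominates their range)
    noise_consistency_factor: float = 1.2


DEFAULT_WINDOW_POLICY = WindowPolicy()


@dataclass
class RateEstimate:
    """Fitted initial rate for one trace."""

    sample_id: str
    cabp_nM: float
    dilution: float
    slope: float  # A/s
    intercept: float
    r_squared: float
    residual_sd: float
    slope_se: float
    fit_window: tuple  # (start_s, end_s)
    n_points: int
    qc_flags: set = field(default_factory=set)
    flux_nM_s: float | None = None  # filled by slope_to_flux callers

    @property
    def usable(self) -> bool:
        return FLAG_SHORT not in self.qc_flags


def _ols(t: np.ndarray, y: np.ndarray):
    """Plain OLS of y on t: slope, intercept, r2, residual sd, slope se."""
    n = len(t)
    tm, ym = t.mean(), y.mean()
    dt, dy = t - tm, y - ym
    sxx = float(dt @ dt)
    sxy = float(dt @ dy)
    syy = float(dy @ dy)
    slope = sxy / sxx
    intercept = ym - slope * tm
    ssr = max(0.0, syy - slope * sxy)
    r2 = 1.0 - ssr / syy if syy > 0 else 1.0
    resid_sd = math.sqrt(ssr / (n - 2)) if n > 2 else 0.0
    slope_se = resid_sd / math.sqrt(sxx) if sxx > 0 else 0.0
    return slope, intercept, r2, resid_sd, slope_se


def _robust_noise_sd(y: np.ndarray) -> float:
    """Noise scale from second differences (trend-insensitive)."""
    if len(y) < 4:
        return 0.0
    d2 = np.diff(y, n=2)
    mad = np.median(np.abs(d2 - np.median(d2)))
    # var(d2) = 6 sigma^2 for white noise
    return 1.4826 * mad / math.sqrt(6.0)


def _trim_bounds(y: np.ndarray, sigma: float):
    """Indices (lo, hi) of the declining part: lag dead-time stripped from
    the front, depletion plateau stripped from the back.  Returns
    ``(lo, hi, declining, depleted)``; hi is inclusive."""
    n = len(y)
    k = max(5, n // 20)  # enough points for a stable level estimate
    top = float(np.median(y[: min(k, n)]))
    floor = float(np.median(y[-min(k, n):]))
    span = top - floor
    tiny = 1e-9 * max(1.0, abs(top))
    eps = max(4.0 * sigma, tiny)
    if span <= max(5.0 * sigma, tiny):
        return 0, n - 1, False, False
    below = np.nonzero(top - y > eps)[0]
    lo = max(0, int(below[0]) - 1) if len(below) else 0
    above = np.nonzero(y - floor > eps)[0]
    hi = min(n - 1, int(above[-1])) if len(above) else n - 1
    if hi <= lo:
        return 0, n - 1, False, False
    # depleted only when a real flat tail was cut off, not when the level
    # estimate shaved a few points from a still-declining trace
    tail = y[hi + 1:]
    depleted = (hi < n - 1 - max(3, int(0.02 * n))
                and tail.size > 1
                and float(np.ptp(tail)) <= max(8.0 * sigma, 2.0 * tiny))
    return lo, hi, True, depleted


def fit_initial_slope(
    trace: AbsorbanceTrace,
    policy: WindowPolicy = DEFAULT_WINDOW_POLICY,
) -> RateEstimate:
    """Fit the initial-rate slope of one trace.

    Returns a :class:`RateEstimate` whose ``qc_flags`` may contain

    - ``short``      not enough points for any candidate window (no fit);
    - ``flat``       slope indistinguishable from zero;
    - ``depleted``   the trace plateaus before its end (NADH or substrate
      exhausted); the fitted window stops at the plateau;
    - ``nonlinear``  no candidate window met the R^2 threshold; the slope
      is the full-trace OLS slope.
    """
    t, y = trace.times, trace.a340
    n = len(t)
    dt = float(np.median(np.diff(t)))
    min_pts = max(3, int(round(policy.min_window_s / dt)) + 1)
    flags: set = set()

    if n < min_pts:
        flags.add(FLAG_SHORT)
        return RateEstimate(
            trace.sample_id, trace.cabp_nM, trace.dilution,
            slope=float("nan"), intercept=float("nan"), r_squared=float("nan"),
            residual_sd=float("nan"), slope_se=float("nan"),
            fit_window=(float(t[0]), float(t[-1])), n_points=n, qc_flags=flags,
        )

    sigma = _robust_noise_sd(y)
    lo, hi, declining, depleted = _trim_bounds(y, sigma)

    if not declining:
        slope, icpt, r2, rsd, sse = _ols(t, y)
        if abs(slope) <= max(policy.flat_z * sse, 1e-12):
            flags.add(FLAG_FLAT)
        return RateEstimate(
            trace.sample_id, trace.cabp_nM, trace.dilution,
            slope, icpt, r2, rsd, sse,
            (float(t[0]), float(t[-1])), n, flags,
        )

    if depleted:
        flags.add(FLAG_DEPLETED)

    # candidate starts on a grid within the first half of the usable region
    usable = hi - lo + 1
    if usable < min_pts:
        # declining but too short after trimming: fit what there is
        slope, icpt, r2, rsd, sse = _ols(t[lo:hi + 1], y[lo:hi + 1])
        flags.add(FLAG_NONLINEAR)
        return RateEstimate(
            trace.sample_id, trace.cabp_nM, trace.dilution,
            slope, icpt, r2, rsd, sse,
            (float(t[lo]), float(t[hi])), hi - lo + 1, flags,
        )

    step = max(1, int(round(policy.start_grid_s / dt)))
    last_start = lo + int(policy.max_start_frac * usable)
    starts = list(range(lo, max(lo + 1, last_start), step))

    chosen = None
    ts, ys = t[: hi + 1], y[: hi + 1]
    c1 = np.concatenate([[0.0], np.cumsum(ts)])
    cy = np.concatenate([[0.0], np.cumsum(ys)])
    ct2 = np.concatenate([[0.0], np.cumsum(ts * ts)])
    cy2 = np.concatenate([[0.0], np.cumsum(ys * ys)])
    cty = np.concatenate([[0.0], np.cumsum(ts * ys)])
    for s in starts:
        ends = np.arange(s + min_pts - 1, hi + 1)
        if len(ends) == 0:
            continue
        m = (ends - s + 1).astype(float)
        st = c1[ends + 1] - c1[s]
        sy = cy[ends + 1] - cy[s]
        st2 = ct2[ends + 1] - ct2[s]
        sy2 = cy2[ends + 1] - cy2[s]
        sty = cty[ends + 1] - cty[s]
        sxx = st2 - st * st / m
        syy = sy2 - sy * sy / m
        sxy = sty - st * sy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(syy > 0, (sxy * sxy) / (sxx * syy), 1.0)
            ssr = np.maximum(0.0, syy - sxy * sxy / sxx)
            resid_var = np.where(m > 2, ssr / np.maximum(m - 2, 1), 0.0)
        noise_ok = resid_var <= (policy.noise_consistency_factor * sigma) ** 2
        ok = np.nonzero((r2 >= policy.r2_threshold) | noise_ok)[0]
        if len(ok):
            chosen = (s, int(ends[ok[-1]]))
            break

    if chosen is None:
        slope, icpt, r2v, rsd, sse = _ols(t[lo:hi + 1], y[lo:hi + 1])
        flags.add(FLAG_NONLINEAR)
        if abs(slope) <= max(policy.flat_z * sse, 1e-12):
            flags.add(FLAG_FLAT)
        return RateEstimate(
            trace.sample_id, trace.cabp_nM, trace.dilution,
            slope, icpt, r2v, rsd, sse,
            (float(t[lo]), float(t[hi])), hi - lo + 1, flags,
        )

    s, e = chosen
    slope, icpt, r2v, rsd, sse = _ols(t[s:e + 1], y[s:e + 1])
    if abs(slope) <= max(policy.flat_z * sse, 1e-12):
        flags.add(FLAG_FLAT)
    return RateEstimate(
        trace.sample_id, trace.cabp_nM, trace.dilution,
        slope, icpt, r2v, rsd, sse,
        (float(t[s]), float(t[e])), e - s + 1, flags,
    )


def slope_to_flux(slope: float, constants: AssayConstants) -> tuple[float, bool]:
    """Convert an A340 slope (A/s) into a carboxylation flux (nM/s).

    NADH is consumed, so catalysis shows as a negative slope.  Positive
    slopes are clamped to zero flux; the second return value reports
    whether clamping occurred.

    flux = max(0, -slope) / (epsilon * l) / nadh_per_carboxylation * 1e9
    """
    clamped = slope > 0
    nadh_rate_M_s = max(0.0, -slope) / constants.epsilon_l
    flux_M_s = nadh_rate_M_s / constants.nadh_per_carboxylation
    return flux_M_s * 1e9, bool(clamped)


def estimate_flux(
    trace: AbsorbanceTrace,
    constants: AssayConstants,
    policy: WindowPolicy = DEFAULT_WINDOW_POLICY,
) -> RateEstimate:
    """Fit the initial slope and attach the converted flux (nM/s)."""
    est = fit_initial_slope(trace, policy)
    if est.usable:
        flux, clamped = slope_to_flux(est.slope, constants)
        est.flux_nM_s = flux
        if clamped:
            est.qc_flags.add(FLAG_CLAMPED)
    return est
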