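"""Active-site titration: from a CABP ladder to site concentration and kcat.

CABP binds rubisco active sites essentially irreversibly, so measured
activity falls linearly with inhibitor concentration until all sites are
blocked.  Fitting ``v = a + b * [CABP]`` and extrapolating to the x-axis
yields the in-assay active-site concentration; dividing the uninhibited
activity by that concentration gives the per-site turnover rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assay import ACTIVITY_THRESHOLD_KCAT, AssayConstants
from .traces import (
    DEFAULT_WINDOW_POLICY,
    AbsorbanceTrace,
    RateEstimate,
    WindowPolicy,
    estimate_flux,
)

FLAG_SATURATED = "saturated_needs_dilution"
FLAG_POOR_FIT = "poor_fit"
FLAG_INACTIVE = "inactive"


@dataclass
class TitrationSeries:
    """A full CABP ladder for one sample (typically six wells)."""

    sample_id: str
    traces: list
    constants: AssayConstants
    dilution: float = 1.0
    batch_id: str | None = None
    is_reference: bool = False

    def __post_init__(self) -> None:
        if len(self.traces) < 2:
            raise ValueError("a titration series needs at least 2 traces")
        concs = {tr.cabp_nM for tr in self.traces}
        if len(concs) < 2:
            raise ValueError("ladder must span >= 2 distinct CABP concentrations")
        if not any(tr.cabp_nM == 0 for tr in self.traces):
            raise ValueError("ladder must include a zero-CABP trace")


@dataclass
class TitrationPoint:
    cabp_nM: float
    flux_nM_s: float
    estimate: RateEstimate


@dataclass
class SiteFit:
    """Linear-regression fit of flux vs [CABP] and its x-intercept."""

    site_conc_nM: float | None
    slope: float | None
    intercept: float | None
    r_squared: float | None
    excluded_points: list
    n_points_used: int
    qc_flags: set = field(default_factory=set)


@dataclass
class KineticResult:
    sample_id: str
    v0_nM_s: float
    site_conc_nM: float | None
    kcat_s: float | None
    active: bool
    qc_flags: set
    dilution: float = 1.0
    batch_id: str | None = None
    site_fit: SiteFit | None = None
    points: list | None = None

    @property
    def stock_site_conc_nM(self) -> float | None:
        """Active-site concentration in the undiluted lysate."""
        if self.site_conc_nM is None:
            return None
        return self.site_conc_nM * self.dilution


def titration_points(
    series: TitrationSeries,
    policy: WindowPolicy = DEFAULT_WINDOW_POLICY,
) -> tuple[list, list]:
    """Convert every trace in the ladder to a (cabp, flux) point.

    Order is preserved and both zero-CABP replicates are retained.  Traces
    failing hard QC (``short``) are dropped; the second return value lists
    the dropped estimates.
    """
    points, dropped = [], []
    for tr in series.traces:
        est = estimate_flux(tr, series.constants, policy)
        if not est.usable:
            dropped.append(est)
            continue
        points.append(TitrationPoint(tr.cabp_nM, est.flux_nM_s, est))
    return points, dropped


def _ols_line(x: np.ndarray, y: np.ndarray):
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0:
        return None
    b = float(dx @ (y - ym)) / sxx
    a = ym - b * xm
    pred = a + b * x
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2


def fit_active_sites(
    points: Sequence[TitrationPoint],
    saturation_frac: float = 0.8,
) -> SiteFit:
    """Fit flux vs [CABP] and return the x-intercept site concentration.

    Points beyond the equivalence point violate the linear titration model
    (flux is already zero there), so the largest-CABP point is excluded
    iteratively whenever the current fit predicts non-positive flux at it,
    stopping when 3 points remain.  A non-negative fitted slope means no
    detectable inhibition (too much enzyme): flagged
    ``saturated_needs_dilution`` with no site estimate.
    """
    flags: set = set()
    pts = [(i, p.cabp_nM, p.flux_nM_s) for i, p in enumerate(points)]
    if len(pts) < 3 or len({c for _, c, _ in pts}) < 2:
        return SiteFit(None, None, None, None, [], len(pts), {FLAG_POOR_FIT})

    v0_guess = float(np.mean([v for _, c, v in pts if c == 0])) if any(
        c == 0 for _, c, _ in pts) else max(v for _, _, v in pts)
    cmax = max(c for _, c, _ in pts)
    vmax_c = float(np.mean([v for _, c, v in pts if c == cmax]))
    if v0_guess > 0 and vmax_c > saturation_frac * v0_guess:
        flags.add(FLAG_SATURATED)

    excluded: list = []
    while True:
        x = np.array([c for _, c, _ in pts], dtype=float)
        y = np.array([v for _, _, v in pts], dtype=float)
        line = _ols_line(x, y)
        if line is None:
            return SiteFit(None, None, None, None, excluded, len(pts),
                           flags | {FLAG_POOR_FIT})
        a, b, r2 = line
        if b >= 0:
            flags.add(FLAG_SATURATED)
            return SiteFit(None, a, b, r2, excluded, len(pts), flags)
        if len(pts) > 3:
            i_max = int(np.argmax(x))
            if a + b * x[i_max] <= 0:
                excluded.append(pts[i_max][0])
                del pts[i_max]
                continue
        break

    site = -a / b
    if site <= 0:
        flags.add(FLAG_POOR_FIT)
        return SiteFit(None, a, b, r2, excluded, len(pts), flags)
    return SiteFit(float(site), float(b), float(a), float(r2),
                   excluded, len(pts), flags)


def compute_kcat(
    series: TitrationSeries,
    policy: WindowPolicy = DEFAULT_WINDOW_POLICY,
    activity_threshold: float = ACTIVITY_THRESHOLD_KCAT,
    saturation_frac: float = 0.8,
) -> KineticResult:
    """Full per-sample inference: traces -> fluxes -> site fit -> kcat.

    ``v0`` is the mean flux of the zero-CABP wells (not the regression
    intercept, which is available on the attached :class:`SiteFit`).
    ``kcat = v0 / site_conc`` is dilution-invariant because numerator and
    denominator scale together.
    """
    points, dropped = titration_points(series, policy)
    flags: set = set()
    for est in dropped:
        flags |= est.qc_flags

    zeros = [p.flux_nM_s for p in points if p.cabp_nM == 0]
    v0 = float(np.mean(zeros)) if zeros else 0.0

    fit = fit_active_sites(points, saturation_frac=saturation_frac)
    flags |= fit.qc_flags

    if fit.site_conc_nM is None or fit.site_conc_nM <= 0:
        # no usable site estimate; a dead sample (v0 = 0) still gets kcat 0
        kcat = 0.0 if v0 == 0 else None
        active = False
        flags.add(FLAG_INACTIVE if v0 == 0 else FLAG_POOR_FIT)
    else:
        kcat = v0 / fit.site_conc_nM
        active = kcat > activity_threshold
        if not active:
            flags.add(FLAG_INACTIVE)
    return KineticResult(
        sample_id=series.sample_id, v0_nM_s=v0,
        site_conc_nM=fit.site_conc_nM, kcat_s=kcat, active=active,
        qc_flags=flags, dilution=series.dilution, batch_id=series.batch_id,
        site_fit=fit, points=points,
    )


@dataclass
class BatchReferenceReport:
    reference_id: str
    grand_median_kcat: float | None
    per_batch: dict  # batch -> {"kcat": float | None, "deviation": float | None, "flagged": bool}
    flagged_batches: list


def batch_reference_check(
    results_by_batch: Mapping[str, Iterable[KineticResult]],
    reference_id: str,
    max_deviation: float = 0.2,
) -> BatchReferenceReport:
    """QC the internal-standard sample across measurement batches.

    Each batch should contain the reference sample; its kcat is compared
    with the grand median over batches and batches deviating by more than
    ``max_deviation`` (fractional) are flagged.  Measurements are NOT
    rescaled -- this is a report only.
    """
    ref_kcats: dict[str, float | None] = {}
    for batch, results in results_by_batch.items():
        k = None
        for r in results:
            if r.sample_id == reference_id and r.kcat_s is not None:
                k = r.kcat_s
                break
        ref_kcats[batch] = k
    observed = [k for k in ref_kcats.values() if k is not None]
    grand = float(np.median(observed)) if observed else None

    per_batch, flagged = {}, []
    for batch, k in ref_kcats.items():
        if k is None or grand is None or grand == 0:
            dev = None
            bad = True
        else:
            dev = abs(k - grand) / grand
            bad = dev > max_deviation
        per_batch[batch] = {"kcat": k, "deviation": dev, "flagged": bad}
        if bad:
            flagged.append(batch)
    return BatchReferenceReport(reference_id, grand, per_batch, sorted(flagged))
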