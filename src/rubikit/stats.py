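"""Nonparametric group comparisons, summaries, and temperature correction.

Rank tests are implemented directly (midranks, tie corrections, exact
Mann-Whitney null by counting) so they can be validated against
brute-force enumeration oracles; quartiles use linear interpolation of
order statistics because printed IQRs depend on the convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .assay import ACTIVITY_THRESHOLD_KCAT

EXACT_PRODUCT_CUTOFF = 400


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) by linear interpolation of order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _u_count(u: int, n: int, m: int) -> int:
    """Number of arrangements of n-vs-m ranks with U statistic exactly u."""
    if u < 0 or u > n * m:
        return 0
    if n == 0 or m == 0:
        return 1 if u == 0 else 0
    return _u_count(u - m, n - 1, m) + _u_count(u, n, m - 1)


def _exact_mw_p(u_obs: float, n: int, m: int) -> float:
    """Two-sided exact p: 2 * min(P(U <= u), P(U >= u)), capped at 1."""
    total = math.comb(n + m, n)
    u_int = int(round(u_obs))
    cdf = sum(_u_count(u, n, m) for u in range(0, u_int + 1)) / total
    sf = sum(_u_count(u, n, m) for u in range(u_int, n * m + 1)) / total
    return min(1.0, 2.0 * min(cdf, sf))


def _tie_term(pooled: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups in the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


@dataclass
class MannWhitneyResult:
    u: float  # U statistic of the first sample
    p_value: float
    method: str  # "exact" | "asymptotic"
    n_x: int
    n_y: int


def mann_whitney_u(x, y, mode: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with midranks for ties.

    ``mode="auto"`` uses the exact null (by counting) when there are no
    ties and ``n_x * n_y <= 400``, otherwise a normal approximation with
    tie and continuity corrections.  ``"exact"``/``"asymptotic"`` force a
    method; forcing exact with ties falls back to full enumeration of
    group assignments when feasible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r_x = float(ranks[:n].sum())
    u_x = r_x - n * (n + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n + m

    if mode not in {"auto", "exact", "asymptotic"}:
        raise ValueError(f"unknown mode: {mode!r}")
    use_exact = (mode == "exact") or (
        mode == "auto" and not has_ties and n * m <= EXACT_PRODUCT_CUTOFF)

    if use_exact and not has_ties:
        return MannWhitneyResult(u_x, _exact_mw_p(u_x, n, m), "exact", n, m)
    if use_exact and has_ties:
        nc = math.comb(n + m, n)
        if nc > 200_000:
            raise ValueError(
                "exact test with ties requires full enumeration; sample too "
                "large -- use mode='asymptotic'")
        lo = hi = 0
        for idx in combinations(range(n + m), n):
            u_perm = float(ranks[list(idx)].sum()) - n * (n + 1) / 2.0
            if u_perm <= u_x + 1e-9:
                lo += 1
            if u_perm >= u_x - 1e-9:
                hi += 1
        return MannWhitneyResult(
            u_x, min(1.0, 2.0 * min(lo, hi) / nc), "exact", n, m)

    mu = n * m / 2.0
    nm = n + m
    var = n * m / 12.0 * ((nm + 1) - _tie_term(pooled) / (nm * (nm - 1)))
    if var <= 0:
        warnings.warn("all pooled values identical; p = 1")
        return MannWhitneyResult(u_x, 1.0, "asymptotic", n, m)
    z = (abs(u_x - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(max(0.0, z)))
    return MannWhitneyResult(u_x, p, "asymptotic", n, m)


# ---------------------------------------------------------------------------
# Kruskal-Wallis and Dunn


@dataclass
class KruskalResult:
    h: float
    p_value: float
    df: int


def kruskal_wallis(groups) -> KruskalResult:
    """Kruskal-Wallis H with tie correction; chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    tie = _tie_term(pooled)
    correction = 1.0 - tie / (N ** 3 - N)
    if correction <= 0:
        warnings.warn("all pooled values identical; H = 0, p = 1")
        return KruskalResult(0.0, 1.0, len(groups) - 1)
    h /= correction
    df = len(groups) - 1
    return KruskalResult(float(h), float(chi2.sf(h, df)), df)


def _adjust_p(pvals: list, method: str) -> list:
    """Holm / Bonferroni / no adjustment."""
    p = np.asarray(pvals, dtype=float)
    k = p.size
    if method == "none":
        return list(p)
    if method == "bonferroni":
        return list(np.minimum(1.0, p * k))
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(k)
        running = 0.0
        for rank_i, idx in enumerate(order):
            val = min(1.0, (k - rank_i) * p[idx])
            running = max(running, val)
            adj[idx] = running
        return list(adj)
    raise ValueError(f"unknown adjustment method: {method!r}")


@dataclass
class DunnResult:
    pairs: list  # (name_i, name_j)
    z: list
    p_raw: list
    p_adjusted: list
    adjust: str

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group_a": [a for a, _ in self.pairs],
            "group_b": [b for _, b in self.pairs],
            "z": self.z,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
        })


def dunn_test(groups, names=None, adjust: str = "holm") -> DunnResult:
    """Dunn's pairwise post-hoc z tests on pooled midranks.

    Tie-corrected; two-sided; adjusted with Holm by default (Bonferroni
    and "none" available).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    k = len(groups)
    if names is None:
        names = [f"group{i}" for i in range(k)]
    pooled = np.concatenate(groups)
    N = pooled.size
    ranks = rankdata(pooled)
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        mean_ranks.append(float(ranks[start:start + g.size].mean()))
        sizes.append(g.size)
        start += g.size
    tie = _tie_term(pooled)
    base_var = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))

    pairs, zs, praw = [], [], []
    for i, j in combinations(range(k), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            z = 0.0
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / se
        pairs.append((names[i], names[j]))
        zs.append(float(z))
        praw.append(float(min(1.0, 2.0 * norm.sf(abs(z)))))
    return DunnResult(pairs, zs, praw, _adjust_p(praw, adjust), adjust)


# ---------------------------------------------------------------------------
# temperature correction


def q10_correct(rate: float, t_measured: float, t_target: float,
                q10: float = 2.2) -> float:
    """Rescale a rate between temperatures: rate * q10**((target-measured)/10)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if q10 <= 0:
        raise ValueError("q10 must be > 0")
    return rate * q10 ** ((t_target - t_measured) / 10.0)


# ---------------------------------------------------------------------------
# panel-level comparisons


@dataclass
class GroupComparison:
    comparison: str
    test: str
    group_names: list
    group_sizes: list
    medians: list
    q1s: list
    q3s: list
    statistic: float
    p_value: float
    fold_median: float | None  # largest median / smallest median
    pairwise: pd.DataFrame | None = None
    boxplot: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "comparison": self.comparison,
            "test": self.test,
            "groups": [
                {
                    "name": n, "n": int(s), "median": m, "q1": q1, "q3": q3,
                }
                for n, s, m, q1, q3 in zip(
                    self.group_names, self.group_sizes, self.medians,
                    self.q1s, self.q3s)
            ],
            "statistic": self.statistic,
            "p_value": self.p_value,
            "fold_median": self.fold_median,
            "boxplot": self.boxplot,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def _box_stats(values: np.ndarray) -> dict:
    """Box/whisker summary with whiskers at the most extreme data points
    within 1.5 * IQR of the quartiles."""
    med, q1, q3 = median_iqr(values)
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    lo = float(inside.min()) if inside.size else float(values.min())
    hi = float(inside.max()) if inside.size else float(values.max())
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return {
        "median": med, "q1": q1, "q3": q3,
        "whisker_low": lo, "whisker_high": hi,
        "outliers": [float(v) for v in outliers],
        "n": int(values.size),
    }


#: comparison name -> (grouping column, ordered expected labels)
FIG2_COMPARISONS = {
    "trophic": ("trophic_mode", ["photo", "chemo"]),
    "carboxysome": ("carboxysome", ["yes", "no"]),
    "clade": ("clade", ["alpha_cyano", "beta_cyano", "ccm_proteo"]),
}


def _one_comparison(panel: pd.DataFrame, name: str,
                    adjust: str) -> GroupComparison | None:
    column, labels = FIG2_COMPARISONS[name]
    groups, names = [], []
    for lab in labels:
        vals = panel.loc[panel[column] == lab, "kcat"].to_numpy(dtype=float)
        if vals.size:
            groups.append(vals)
            names.append(lab)
    if len(groups) < 2:
        warnings.warn(f"comparison {name!r}: fewer than 2 non-empty groups, skipped")
        return None
    meds = [median_iqr(g) for g in groups]
    medians = [m for m, _, _ in meds]
    fold = max(medians) / min(medians) if min(medians) > 0 else None
    box = {n: _box_stats(g) for n, g in zip(names, groups)}
    if len(groups) == 2:
        res = mann_whitney_u(groups[0], groups[1])
        return GroupComparison(
            name, "mann_whitney_u", names, [g.size for g in groups],
            medians, [q1 for _, q1, _ in meds], [q3 for _, _, q3 in meds],
            res.u, res.p_value, fold, None, box)
    kw = kruskal_wallis(groups)
    dunn = dunn_test(groups, names, adjust=adjust)
    return GroupComparison(
        name, "kruskal_wallis+dunn", names, [g.size for g in groups],
        medians, [q1 for _, q1, _ in meds], [q3 for _, _, q3 in meds],
        kw.h, kw.p_value, fold, dunn.as_frame(), box)


def compare_groups(
    panel: pd.DataFrame,
    comparisons=("trophic", "carboxysome", "clade"),
    activity_threshold: float = ACTIVITY_THRESHOLD_KCAT,
    adjust: str = "holm",
) -> dict:
    """Run the group-wise rate comparisons on a panel table.

    Only active variants (kcat > threshold) enter each comparison.  If a
    boolean ``subset_<comparison>`` column is present, it additionally
    restricts that comparison to its class-representative subset.
    Returns ``{comparison name: GroupComparison}`` (skipped comparisons
    are absent).
    """
    if "kcat" not in panel.columns:
        raise ValueError("panel must have a 'kcat' column")
    active = panel[panel["kcat"] > activity_threshold]
    out = {}
    for name in comparisons:
        if name not in FIG2_COMPARISONS:
            raise ValueError(f"unknown comparison: {name!r}")
        column, _ = FIG2_COMPARISONS[name]
        if column not in panel.columns:
            warnings.warn(f"comparison {name!r}: column {column!r} missing, skipped")
            continue
        sub = active
        flag_col = f"subset_{name}"
        if flag_col in panel.columns:
            sub = sub[sub[flag_col].astype(bool)]
        comp = _one_comparison(sub, name, adjust)
        if comp is not None:
            out[name] = comp
    return out
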