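"""Synthetic data with known ground truth.

Three generators stand in for the wet lab: plate-reader titration traces
(linear NADH depletion with dead-time lag, Gaussian read noise and
depletion plateaus), variant panels whose group-wise rate distributions
follow configurable median/IQR targets, and protein-sequence families
with controlled within/between-cluster identity.  Everything is
deterministic under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assay import AssayConstants, DEFAULT_CONSTANTS
from .selection import SequenceRecord
from .titration import TitrationSeries
from .traces import AbsorbanceTrace

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one simulated titration series.

    ``site_conc_true_nM`` is the in-assay active-site concentration at
    dilution 1; simulating the same truth at dilution ``d`` scales the
    in-assay sites (and hence all fluxes) by ``1/d``.
    """

    variant_id: str
    kcat_true: float  # s^-1
    site_conc_true_nM: float
    lag_time_s: float = 0.0
    noise_sd: float = 0.0  # absorbance units
    baseline_a340: float = 0.05

    def __post_init__(self) -> None:
        if self.kcat_true < 0:
            raise ValueError("kcat_true must be >= 0")
        if self.site_conc_true_nM < 0:
            raise ValueError("site_conc_true_nM must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lag_time_s < 0:
            raise ValueError("lag_time_s must be >= 0")


def trace_noise_sd(
    truth_kcat: float,
    truth_site_nM: float,
    constants: AssayConstants = DEFAULT_CONSTANTS,
    fraction: float = 0.02,
) -> float:
    """Absorbance noise SD equal to ``fraction`` of the zero-CABP trace's
    ideal signal amplitude (the A340 drop it would show, capped by full
    NADH depletion).  This is the meaning of "2% trace noise" throughout."""
    consumed_nM = min(
        constants.nadh0_nM,
        constants.nadh_per_carboxylation * truth_kcat * truth_site_nM
        * constants.duration_s,
    )
    return fraction * constants.epsilon_l * consumed_nM * 1e-9


def simulate_titration_series(
    truth: TruthRecord,
    constants: AssayConstants = DEFAULT_CONSTANTS,
    seed: int = 0,
    dilution: float = 1.0,
    batch_id: str | None = None,
    is_reference: bool = False,
) -> TitrationSeries:
    """Forward-simulate the six-well CABP ladder for one sample.

    Per well with inhibitor concentration ``c``: free sites are
    ``E_eff = max(0, sites - c)`` (tight stoichiometric binding), the
    carboxylation flux is ``kcat * E_eff`` and NADH declines linearly at
    twice that flux after the lag dead-time, floored at zero and at the
    substrate-limited plateau.  A340 is baseline + Beer-Lambert NADH
    signal + Gaussian noise.
    """
    if constants.duration_s <= 0 or len(constants.cabp_ladder_nM) == 0:
        raise ValueError("invalid assay configuration")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, constants.duration_s + 1e-9, constants.read_interval_s)
    site_nM = truth.site_conc_true_nM / dilution

    # NADH cannot drop below what full RuBP turnover allows, nor below 0
    nadh_floor_nM = max(
        0.0,
        constants.nadh0_nM
        - constants.nadh_per_carboxylation * constants.rubp_conc_nM,
    )

    traces = []
    for c in constants.cabp_ladder_nM:
        e_eff = max(0.0, site_nM - c)
        v = truth.kcat_true * e_eff  # nM/s
        consumed = (constants.nadh_per_carboxylation * v
                    * np.maximum(0.0, times - truth.lag_time_s))
        nadh_nM = np.maximum(nadh_floor_nM, constants.nadh0_nM - consumed)
        a340 = truth.baseline_a340 + constants.epsilon_l * nadh_nM * 1e-9
        if truth.noise_sd > 0:
            a340 = a340 + rng.normal(0.0, truth.noise_sd, size=len(times))
        traces.append(AbsorbanceTrace(
            sample_id=truth.variant_id, cabp_nM=float(c),
            dilution=dilution, times=times.copy(), a340=a340,
        ))
    return TitrationSeries(
        sample_id=truth.variant_id, traces=traces, constants=constants,
        dilution=dilution, batch_id=batch_id, is_reference=is_reference,
    )


# ---------------------------------------------------------------------------
# variant panels


def lognormal_from_median_iqr(median: float, q1: float, q3: float):
    """(mu, sigma) of a log-normal with the given median whose IQR equals
    ``q3 - q1``.  The quartile asymmetry of a log-normal is fixed by
    (median, IQR), so q1/q3 are matched in width, not individually."""
    if median <= 0:
        raise ValueError("median must be > 0")
    if not (q1 <= median <= q3):
        raise ValueError("need q1 <= median <= q3")
    iqr = q3 - q1
    z75 = norm.ppf(0.75)
    sigma = math.asinh(iqr / (2.0 * median)) / z75
    return math.log(median), sigma


@dataclass(frozen=True)
class GroupSpec:
    """Rate distribution and biological labels for one panel group."""

    name: str
    n: int
    median: float
    q1: float
    q3: float
    trophic_mode: str  # "photo" | "chemo"
    carboxysome: str  # "yes" | "no"
    clade: str  # "alpha_cyano" | "beta_cyano" | "ccm_proteo" | "other"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.median <= 0:
            raise ValueError("median must be > 0")
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("need q1 <= median <= q3")
        if self.trophic_mode not in {"photo", "chemo"}:
            raise ValueError(f"unknown trophic mode: {self.trophic_mode}")
        if self.carboxysome not in {"yes", "no"}:
            raise ValueError(f"unknown carboxysome label: {self.carboxysome}")
        if self.clade not in {"alpha_cyano", "beta_cyano", "ccm_proteo", "other"}:
            raise ValueError(f"unknown clade: {self.clade}")


# Median [q1-q3] targets (s^-1) and class-representative subset sizes for
# the three group comparisons.
FIG2_TROPHIC = {
    "photo": (6.5, 4.4, 7.9, 9),
    "chemo": (2.1, 1.4, 4.0, 19),
}
FIG2_CARBOXYSOME = {
    "yes": (7.4, 5.2, 8.3, 9),
    "no": (1.3, 1.1, 2.1, 9),
}
FIG2_CLADE = {
    "alpha_cyano": (9.8, 8.6, 10.5, 15),
    "beta_cyano": (6.3, 5.6, 7.5, 19),
    "ccm_proteo": (6.6, 4.7, 7.5, 20),
}


def default_panel_groups() -> list:
    """A coherent five-group panel combining the clade, carboxysome and
    trophic-mode rate targets; used by the demo pipeline and the
    attribution power checks."""
    return [
        GroupSpec("alpha_cyano", 15, 9.8, 8.6, 10.5, "photo", "yes", "alpha_cyano"),
        GroupSpec("beta_cyano", 19, 6.3, 5.6, 7.5, "photo", "yes", "beta_cyano"),
        GroupSpec("ccm_proteo", 20, 6.6, 4.7, 7.5, "chemo", "yes", "ccm_proteo"),
        GroupSpec("other_chemo", 19, 2.1, 1.4, 4.0, "chemo", "no", "other"),
        GroupSpec("other_photo", 9, 1.3, 1.1, 2.1, "photo", "no", "other"),
    ]


def simulate_panel(
    groups: list,
    seed: int = 0,
    inactive_fraction: float = 0.0,
    activity_threshold: float = 0.5,
) -> tuple[pd.DataFrame, list]:
    """Draw a variant panel from per-group log-normal rate distributions.

    Returns the panel table and the matching list of
    :class:`TruthRecord` (one per variant; inactive variants get
    ``kcat_true = 0``).  ``inactive_fraction`` marks a random fraction of
    each group as insoluble/inactive.
    """
    if not groups:
        raise ValueError("need at least one group")
    if not 0 <= inactive_fraction < 1:
        raise ValueError("inactive_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows, truths = [], []
    for g in groups:
        mu, sigma = lognormal_from_median_iqr(g.median, g.q1, g.q3)
        kcats = np.exp(rng.normal(mu, sigma, size=g.n)) if sigma > 0 \
            else np.full(g.n, g.median)
        n_inactive = int(round(inactive_fraction * g.n))
        inactive_idx = set(rng.choice(g.n, size=n_inactive, replace=False)) \
            if n_inactive else set()
        for i, k in enumerate(kcats):
            kcat = 0.0 if i in inactive_idx else float(k)
            vid = f"{g.name}_{i:03d}"
            rows.append({
                "variant_id": vid,
                "group": g.name,
                "clade": g.clade,
                "trophic_mode": g.trophic_mode,
                "carboxysome": g.carboxysome,
                "kcat_true": kcat,
                "kcat": kcat,
                "active": kcat > activity_threshold,
            })
            truths.append(TruthRecord(variant_id=vid, kcat_true=kcat,
                                      site_conc_true_nM=50.0))
    return pd.DataFrame(rows), truths


def sample_group_rates(
    median: float, q1: float, q3: float, n: int, seed: int = 0,
) -> np.ndarray:
    """Draw ``n`` rates from the log-normal matched to (median, IQR)."""
    mu, sigma = lognormal_from_median_iqr(median, q1, q3)
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, median)
    return np.exp(rng.normal(mu, sigma, size=n))


# ---------------------------------------------------------------------------
# sequence families


def _mutate(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, always to a different residue."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hit:
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_sequence_family(
    n_clusters: int,
    members_per_cluster: int,
    within_identity: float,
    between_identity: float,
    length: int,
    seed: int = 0,
) -> list:
    """Generate clustered protein sequences with controlled identities.

    Cluster ancestors are mutated copies of a common root chosen so that
    the expected identity between two ancestors is about
    ``between_identity``; members are mutated copies of their ancestor
    with expected member-to-ancestor identity ``within_identity``.

    Records are tagged with ``all`` and their family name, so families
    can serve as scheme subsets for iterative selection.
    """
    if not (0 < between_identity < within_identity <= 1):
        raise ValueError("need 0 < between_identity < within_identity <= 1")
    if length < 50:
        raise ValueError("length must be >= 50 (identity targets are "
                         "unreliable on trivially short sequences)")
    if n_clusters < 1 or members_per_cluster < 1:
        raise ValueError("need >= 1 cluster and >= 1 member per cluster")
    rng = np.random.default_rng(seed)
    root = rng.choice(AMINO_ACIDS, size=length)
    # two ancestors each diverged from the root at rate p match with
    # probability ~ (1-p)^2, so p = 1 - sqrt(between)
    p_between = 1.0 - math.sqrt(between_identity)
    p_within = 1.0 - within_identity
    records = []
    for ci in range(n_clusters):
        ancestor = _mutate(root, p_between, rng)
        tags = frozenset({"all", f"fam{ci}"})
        records.append(SequenceRecord(f"fam{ci}_anc", "".join(ancestor), tags))
        for mi in range(members_per_cluster - 1):
            member = _mutate(ancestor, p_within, rng)
            records.append(
                SequenceRecord(f"fam{ci}_m{mi:02d}", "".join(member), tags))
    return records
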