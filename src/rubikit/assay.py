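"""Shared assay configuration for the NADH-coupled carboxylation assay.

All concentrations are handled in nM and all times in seconds unless a
field name says otherwise.  Absorbance follows Beer-Lambert:
``A340 = epsilon340 * path_length * c`` with ``c`` in molar units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence


@dataclass(frozen=True)
class AssayConstants:
    """Physical constants and plate-reader settings for one assay setup.

    Parameters
    ----------
    epsilon340 : float
        NADH molar extinction coefficient at 340 nm (M^-1 cm^-1).
    path_length : float
        Optical path length of the well (cm).
    nadh_per_carboxylation : float
        Stoichiometric ratio of NADH oxidised per carboxylation event.
    rubp_conc_mM : float
        Substrate (RuBP) concentration in the well (mM).
    nadh0_uM : float
        Initial NADH concentration (µM).
    temperature_C : float
        Assay temperature (°C).
    co2_percent, o2_percent : float
        Head-space gas composition.
    cabp_ladder_nM : sequence of float
        Ordered inhibitor concentrations, one well per entry.  Repeated
        entries are replicate wells.
    read_interval_s, duration_s : float
        Plate-reader sampling interval and total read time.
    """

    epsilon340: float = 6220.0
    path_length: float = 0.26
    nadh_per_carboxylation: float = 2.0
    rubp_conc_mM: float = 1.0
    nadh0_uM: float = 200.0
    temperature_C: float = 30.0
    co2_percent: float = 4.0
    o2_percent: float = 0.4
    cabp_ladder_nM: Sequence[float] = (0.0, 0.0, 10.0, 20.0, 30.0, 90.0)
    read_interval_s: float = 2.0
    duration_s: float = 900.0

    def __post_init__(self) -> None:
        if self.epsilon340 <= 0:
            raise ValueError("epsilon340 must be > 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")
        if self.nadh_per_carboxylation <= 0:
            raise ValueError("nadh_per_carboxylation must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.read_interval_s <= 0:
            raise ValueError("read_interval_s must be > 0")
        if len(self.cabp_ladder_nM) == 0:
            raise ValueError("cabp_ladder_nM must not be empty")
        if any(c < 0 for c in self.cabp_ladder_nM):
            raise ValueError("CABP concentrations must be >= 0")
        if self.nadh0_uM <= 0:
            raise ValueError("nadh0_uM must be > 0")

    @property
    def epsilon_l(self) -> float:
        """Absorbance per molar NADH (A * M^-1)."""
        return self.epsilon340 * self.path_length

    @property
    def nadh0_nM(self) -> float:
        return self.nadh0_uM * 1e3

    @property
    def rubp_conc_nM(self) -> float:
        return self.rubp_conc_mM * 1e6

    def with_(self, **kwargs) -> "AssayConstants":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = AssayConstants()

#: catalytic-activity threshold separating "active" variants (s^-1)
ACTIVITY_THRESHOLD_KCAT = 0.5
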