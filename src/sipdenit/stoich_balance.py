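"""Carbon, nitrogen, and electron recoveries from a phase balance.

The bookkeeping is standard redox accounting for acetate-fueled nitrate
respiration: acetate carbon (oxidation state 0) releases 4 e⁻ per C-mol when
oxidized to CO₂, and nitrate N accepts 4, 5, or 8 e⁻ on the way to N₂O, N₂,
or NH₄⁺ respectively. Hydrogenotrophic methanogenesis consumes 8 e⁻ per CH₄
formed from CO₂. The electron-release denominator is deliberately tied to
the CO₂ actually produced (4 e⁻ × ΔCO₂-C), not to acetate consumed: carbon
routed to biomass is assimilated, not oxidized, and donates no electrons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .chem_timeseries import PhaseBalance

__all__ = [
    "StoichiometryTable",
    "RecoveryReport",
    "carbon_recovery",
    "nitrogen_recovery",
    "electron_balance",
    "n2o_index",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (report convention)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class StoichiometryTable:
    """Per-transformation carbon content and electron-transfer coefficients.

    ``ch4_mode`` selects how CH₄ enters the electron balance:
    ``"hydrogenotrophic"`` counts 8 e⁻ consumed per CH₄ produced from CO₂
    (the default), ``"neutral"`` counts 0 (acetoclastic methane splits
    acetate without net external electron flow).
    """

    carbon_per_mol: dict[str, int] = field(
        default_factory=lambda: {"acetate": 2, "CO2": 1, "CH4": 1}
    )
    electrons_released_per_co2_c: int = 4
    electrons_per_n: dict[str, int] = field(
        default_factory=lambda: {"N2O_N": 4, "N2_N": 5, "NH4_N": 8, "NO2_N": 2}
    )
    electrons_per_ch4: int = 8
    ch4_mode: str = "hydrogenotrophic"

    def __post_init__(self) -> None:
        coeffs = [
            *self.carbon_per_mol.values(),
            self.electrons_released_per_co2_c,
            *self.electrons_per_n.values(),
            self.electrons_per_ch4,
        ]
        if any(int(c) != c or c <= 0 for c in coeffs):
            raise ValueError("stoichiometric coefficients must be positive integers")
        if self.ch4_mode not in ("hydrogenotrophic", "neutral"):
            raise ValueError("ch4_mode must be 'hydrogenotrophic' or 'neutral'")


@dataclass(frozen=True)
class RecoveryReport:
    """Per-product recovery percentages with their numerators/denominator.

    ``per_product_percent`` holds raw (unrounded) values; ``rounded`` mirrors
    it rounded half-away-from-zero for table display. ``denominator`` is in
    C-mol µM, N-mol µM, or e⁻ µM-equivalents depending on the balance.
    """

    per_product_percent: dict[str, float]
    numerators: dict[str, float]
    denominator: float
    unit: str

    @property
    def total_percent(self) -> float:
        return sum(self.per_product_percent.values())

    @property
    def rounded(self) -> dict[str, int]:
        return {k: round_half_away(v) for k, v in self.per_product_percent.items()}

    @property
    def total_rounded(self) -> int:
        return round_half_away(self.total_percent)


def carbon_recovery(
    balance: PhaseBalance, stoich: StoichiometryTable | None = None
) -> RecoveryReport:
    """% of consumed acetate carbon recovered in CO₂-C and CH₄-C."""
    stoich = stoich or StoichiometryTable()
    if balance.delta_acetate <= 0:
        raise ValueError("no acetate consumed")
    denom = stoich.carbon_per_mol["acetate"] * balance.delta_acetate
    numerators = {"CO2_C": balance.delta_co2_c, "CH4_C": balance.delta_ch4_c}
    return RecoveryReport(
        per_product_percent={k: 100.0 * v / denom for k, v in numerators.items()},
        numerators=numerators,
        denominator=denom,
        unit="C-mol µM",
    )


def nitrogen_recovery(balance: PhaseBalance) -> RecoveryReport:
    """% of consumed nitrate N recovered in N₂O-N, N₂-N, and NH₄⁺-N.

    A phase with net N₂O consumption yields a negative N₂O entry; the raw
    signed value is reported rather than clamped.
    """
    if balance.delta_no3_n <= 0:
        raise ValueError("no nitrate consumed")
    denom = balance.delta_no3_n
    numerators = {
        "N2O_N": balance.delta_n2o_n,
        "N2_N": balance.delta_n2_n,
        "NH4_N": balance.delta_nh4_n,
    }
    return RecoveryReport(
        per_product_percent={k: 100.0 * v / denom for k, v in numerators.items()},
        numerators=numerators,
        denominator=denom,
        unit="N-mol µM",
    )


def electron_balance(
    balance: PhaseBalance, stoich: StoichiometryTable | None = None
) -> RecoveryReport:
    """% of electrons released by acetate oxidation recovered in each sink.

    Electrons released = 4 e⁻ × ΔCO₂-C. Sinks are the nitrogenous products
    (4/5/8 e⁻ per N to N₂O/N₂/NH₄⁺) and, under the default
    hydrogenotrophic accounting, CH₄ at 8 e⁻ each.
    """
    stoich = stoich or StoichiometryTable()
    if balance.delta_co2_c <= 0:
        raise ValueError("no oxidation observed")
    released = stoich.electrons_released_per_co2_c * balance.delta_co2_c
    e_n = stoich.electrons_per_n
    numerators = {
        "N2O_N": e_n["N2O_N"] * balance.delta_n2o_n,
        "N2_N": e_n["N2_N"] * balance.delta_n2_n,
        "NH4_N": e_n["NH4_N"] * balance.delta_nh4_n,
    }
    if stoich.ch4_mode == "hydrogenotrophic":
        numerators["CH4"] = stoich.electrons_per_ch4 * balance.delta_ch4_c
    else:
        numerators["CH4"] = 0.0
    return RecoveryReport(
        per_product_percent={k: 100.0 * v / released for k, v in numerators.items()},
        numerators=numerators,
        denominator=released,
        unit="e⁻ µM-equivalents",
    )


def n2o_index(n2o_n: float, n2_n: float) -> float | None:
    """N₂O-N / (N₂O-N + N₂-N) as %, the share of denitrified N escaping
    as N₂O. Returns None (with a warning) when both inputs are zero."""
    if n2o_n < 0 or n2_n < 0:
        raise ValueError("N-mol inputs must be non-negative")
    if n2o_n == 0 and n2_n == 0:
        warnings.warn("N2O index undefined: no N2O or N2 produced", stacklevel=2)
        return None
    return 100.0 * n2o_n / (n2o_n + n2_n)
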