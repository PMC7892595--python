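"""¹³C isotopologue accounting and two-pool source partitioning.

Acetate has two carbons, so its mass spectrum shows three isotopologues at
m/z 59 (¹²C₂, unlabeled), 60 (¹³C₁, half labeled) and 61 (¹³C₂, fully
labeled). The atom fraction of ¹³C in the pool is the abundance-weighted
mean of 0/1/2 labeled carbons out of 2 (unlabeled carbon still carries the
natural ¹³C abundance). Observed ¹³CO₂ atom fractions are interpreted with
a two-pool mixing model between substrate-derived carbon (at the measured
source atom fraction) and endogenous carbon (at natural abundance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotopologueProfile",
    "IsotopeConfig",
    "isotopologue_fractions",
    "atom_fraction_13c",
    "source_partition",
    "assimilation_partition",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class IsotopologueProfile:
    """Relative abundances of the three acetate isotopologues (sum to 1)."""

    f59: float  # unlabeled 12C2
    f60: float  # half-labeled 13C1
    f61: float  # fully labeled 13C2

    def __post_init__(self) -> None:
        fs = (self.f59, self.f60, self.f61)
        if any(f < 0 or f > 1 for f in fs):
            raise ValueError("isotopologue fractions must lie in [0, 1]")
        if abs(sum(fs) - 1.0) > _NORM_TOL:
            raise ValueError("isotopologue fractions must sum to 1")


@dataclass(frozen=True)
class IsotopeConfig:
    """Natural-abundance and labeled-source ¹³C atom fractions."""

    a_nat: float = 0.011
    a_src: float = 0.99

    def __post_init__(self) -> None:
        if not (0 <= self.a_nat < self.a_src <= 1):
            raise ValueError("require 0 <= a_nat < a_src <= 1")


def isotopologue_fractions(
    intensities: tuple[float, float, float] | np.ndarray,
) -> IsotopologueProfile:
    """Normalize raw m/z 59/60/61 signal intensities to fractions."""
    arr = np.asarray(intensities, dtype=float)
    if arr.shape != (3,):
        raise ValueError("expected three intensities (m/z 59, 60, 61)")
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero intensities")
    f = arr / total
    return IsotopologueProfile(f59=float(f[0]), f60=float(f[1]), f61=float(f[2]))


def atom_fraction_13c(
    profile: IsotopologueProfile, config: IsotopeConfig | None = None
) -> float:
    """¹³C atom fraction of the acetate pool.

    Fully labeled molecules contribute both carbons, half-labeled one of
    two; unlabeled molecules still sit at natural abundance ``a_nat``.
    """
    config = config or IsotopeConfig()
    return profile.f61 * 1.0 + profile.f60 * 0.5 + profile.f59 * config.a_nat


def source_partition(a_obs: float, config: IsotopeConfig) -> float:
    """Fraction of a carbon pool derived from the labeled substrate.

    Inverts the two-pool mixing model
    ``a_obs = f * a_src + (1 - f) * a_nat``. Observations outside
    [a_nat, a_src] by more than 1e-6 are clipped with a warning.
    """
    if config.a_src == config.a_nat:
        raise ValueError("unidentifiable mixture: a_src equals a_nat")
    tol = 1e-6
    if a_obs < config.a_nat - tol or a_obs > config.a_src + tol:
        warnings.warn(
            f"observed atom fraction {a_obs} outside "
            f"[{config.a_nat}, {config.a_src}]; clipping",
            stacklevel=2,
        )
    a = min(max(a_obs, config.a_nat), config.a_src)
    return (a - config.a_nat) / (config.a_src - config.a_nat)


def assimilation_partition(carbon_recovery_total_percent: float) -> float:
    """% of consumed acetate carbon assimilated, given % oxidized.

    Values above 100% (more CO₂-C than acetate-C consumed) indicate that
    endogenous carbon mineralization dominates; they are flagged with a
    warning and yield a negative assimilation estimate.
    """
    if carbon_recovery_total_percent < 0:
        raise ValueError("oxidized percentage cannot be negative")
    if carbon_recovery_total_percent > 100:
        warnings.warn(
            "oxidized fraction exceeds 100%: endogenous carbon mineralization "
            "dominates; assimilation estimate is negative",
            stacklevel=2,
        )
    return 100.0 - carbon_recovery_total_percent
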