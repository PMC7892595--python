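"""Microcosm chemistry time series: parsing, validation, and phase balances.

Concentration series are bulk-slurry values in µM (pH is unitless) sampled
at strictly increasing days. Substrate refeeds are recorded in an explicit
supplementation-event log rather than inferred from concentration jumps, so
gross consumption across a refeed is the sum of the declines on either side
of the event with the added amount credited to the running expected
concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "ChemSeries",
    "SupplementationEvent",
    "Phase",
    "PhaseBalance",
    "NetChange",
    "Rate",
    "read_chem_table",
    "net_change",
    "phase_balance",
    "rate",
    "default_phases",
]

#: Recognized analyte labels. ``pH`` is the only unitless one.
ANALYTES = frozenset(
    {
        "acetate",
        "nitrate",
        "nitrite",
        "ammonium",
        "CO2",
        "CH4",
        "N2O",
        "N2",
        "sulfate",
        "ironII",
        "pH",
    }
)

#: Analytes that must be present before a phase balance can be assembled.
MANDATORY_ANALYTES = ("acetate", "nitrate", "CO2")


@dataclass(frozen=True)
class ChemSeries:
    """One analyte's concentration trajectory for a (treatment, replicate)."""

    treatment: str
    replicate: str
    analyte: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if days.ndim != 1 or days.shape != values.shape or days.size == 0:
            raise ValueError("days and values must be equal-length 1-d arrays")
        if np.any(days < 0):
            raise ValueError("days must be non-negative")
        if np.any(np.diff(days) <= 0):
            dup = days[1:][np.diff(days) <= 0][0]
            raise ValueError(
                f"days must be strictly increasing within a series "
                f"(offending day {dup} in {self.key()})"
            )
        if self.analyte == "pH":
            if np.any((values < 0) | (values > 14)):
                raise ValueError("pH values must lie in [0, 14]")
        elif np.any(values < 0):
            raise ValueError(f"negative concentration in series {self.key()}")

    def key(self) -> tuple[str, str, str]:
        return (self.treatment, self.replicate, self.analyte)

    @property
    def unitless(self) -> bool:
        """True for pH, which carries no concentration unit."""
        return self.analyte == "pH"

    def interp(self, day: float | np.ndarray) -> float | np.ndarray:
        """Linearly interpolated value at ``day`` (must lie in range)."""
        return np.interp(day, self.days, self.values)


@dataclass(frozen=True)
class SupplementationEvent:
    """A refeed: ``amount_uM`` of ``analyte`` added at ``day``."""

    treatment: str
    analyte: str
    day: float
    amount_uM: float

    def __post_init__(self) -> None:
        if self.amount_uM <= 0:
            raise ValueError("supplementation amount must be positive")


@dataclass(frozen=True)
class Phase:
    """A named, half-open-by-convention incubation window in days."""

    name: str
    start_day: float
    end_day: float

    def __post_init__(self) -> None:
        if not self.start_day < self.end_day:
            raise ValueError("phase start must precede its end")

    @property
    def length(self) -> float:
        return self.end_day - self.start_day


def default_phases(boundaries: Sequence[float] = (0.0, 6.0, 15.0)) -> list[Phase]:
    """Phases I, II, ... from a boundary list (default days 0/6/15)."""
    if len(boundaries) < 2:
        raise ValueError("need at least two boundaries")
    names = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    return [
        Phase(names[i] if i < len(names) else str(i + 1), a, b)
        for i, (a, b) in enumerate(zip(boundaries[:-1], boundaries[1:]))
    ]


@dataclass(frozen=True)
class NetChange:
    """Signed net change plus the gross flows it decomposes into (µM)."""

    net: float
    consumption: float
    production: float


@dataclass(frozen=True)
class Rate:
    """Per-day flows over a window (µM day⁻¹)."""

    net: float
    consumption: float
    production: float


@dataclass(frozen=True)
class PhaseBalance:
    """Net consumption/production of the balance-relevant analytes (µM).

    Nitrogen deltas are in N-mol µM: each N₂O contributes 2 N, each N₂
    contributes 2 N. ``delta_n2o_n`` is signed (negative = net consumption,
    as observed when accumulated N₂O is reduced on to N₂).
    """

    phase: Phase
    delta_acetate: float
    delta_no3_n: float
    delta_co2_c: float
    delta_ch4_c: float = 0.0
    delta_n2o_n: float = 0.0
    delta_n2_n: float = 0.0
    delta_nh4_n: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_acetate < 0 or self.delta_no3_n < 0:
            raise ValueError("consumption deltas must be non-negative")


def read_chem_table(
    path: str | Path,
    event_path: str | Path | None = None,
) -> tuple[list[ChemSeries], list[SupplementationEvent]]:
    """Read a long-format chemistry CSV and an optional event log.

    The chemistry file has columns ``treatment,replicate,day,analyte,value``;
    the event file has ``treatment,analyte,day,amount_uM``. Duplicate
    (treatment, replicate, analyte, day) rows and negative concentrations are
    hard errors reported with 1-based data row numbers.
    """
    df = pd.read_csv(path)
    required = {"treatment", "replicate", "day", "analyte", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"chemistry table missing columns: {sorted(missing)}")

    keycols = ["treatment", "replicate", "analyte", "day"]
    dup = df.duplicated(subset=keycols, keep=False)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise ValueError(
            f"duplicate (treatment, replicate, analyte, day) at data rows {rows}"
        )
    bad_val = df["value"] < 0
    if bad_val.any():
        rows = (df.index[bad_val] + 1).tolist()
        raise ValueError(f"negative concentration at data rows {rows}")

    series: list[ChemSeries] = []
    for (treatment, replicate, analyte), grp in df.groupby(
        ["treatment", "replicate", "analyte"], sort=True
    ):
        grp = grp.sort_values("day")
        series.append(
            ChemSeries(
                treatment=str(treatment),
                replicate=str(replicate),
                analyte=str(analyte),
                days=grp["day"].to_numpy(float),
                values=grp["value"].to_numpy(float),
            )
        )

    events: list[SupplementationEvent] = []
    if event_path is not None:
        ev = pd.read_csv(event_path)
        ev_required = {"treatment", "analyte", "day", "amount_uM"}
        ev_missing = ev_required - set(ev.columns)
        if ev_missing:
            raise ValueError(f"event log missing columns: {sorted(ev_missing)}")
        for row in ev.itertuples(index=False):
            events.append(
                SupplementationEvent(
                    treatment=str(row.treatment),
                    analyte=str(row.analyte),
                    day=float(row.day),
                    amount_uM=float(row.amount_uM),
                )
            )
    return series, events


def _events_for(
    series: ChemSeries, events: Iterable[SupplementationEvent]
) -> list[SupplementationEvent]:
    return [
        e
        for e in events
        if e.treatment == series.treatment and e.analyte == series.analyte
    ]


def net_change(
    series: ChemSeries,
    events: Iterable[SupplementationEvent],
    phase: Phase,
) -> NetChange:
    """Refeed-corrected net change of ``series`` over ``phase``.

    The phase is split into inter-event segments (delimited by the phase
    boundaries and any supplementation days inside the phase). Gross
    consumption is the sum over segments of the positive part of the
    decline, where each segment's start value is the interpolated
    concentration plus any amount supplemented at that day; gross
    production is symmetric. Using only segment-boundary values (rather
    than every intermediate measurement) keeps the estimate from
    accumulating measurement noise as spurious consumption+production.
    Events at exactly the phase end have no segment left to act on and do
    not contribute.
    """
    lo, hi = series.days[0], series.days[-1]
    if phase.start_day < lo or phase.end_day > hi:
        raise ValueError(
            f"phase [{phase.start_day}, {phase.end_day}] outside data range "
            f"[{lo}, {hi}] for {series.key()}"
        )
    evs = _events_for(series, events)
    for e in evs:
        if not (lo <= e.day <= hi):
            raise ValueError(
                f"event at day {e.day} has no bracketing measurements "
                f"(data span [{lo}, {hi}])"
            )

    ev_days = [
        e.day for e in evs if phase.start_day <= e.day < phase.end_day
    ]
    breakpoints = np.unique(
        np.concatenate(
            [[phase.start_day, phase.end_day], np.asarray(ev_days, float)]
        )
    )
    values = series.interp(breakpoints)
    added = np.zeros_like(values)
    for e in evs:
        if phase.start_day <= e.day < phase.end_day:
            idx = int(np.searchsorted(breakpoints, e.day))
            added[idx] += e.amount_uM

    consumption = 0.0
    production = 0.0
    for i in range(len(breakpoints) - 1):
        start = values[i] + added[i]
        end = values[i + 1]
        if end < start:
            consumption += start - end
        else:
            production += end - start
    return NetChange(
        net=production - consumption,
        consumption=consumption,
        production=production,
    )


def phase_balance(
    series_set: Iterable[ChemSeries] | Mapping[str, ChemSeries],
    events: Iterable[SupplementationEvent],
    phase: Phase,
) -> PhaseBalance:
    """Assemble a :class:`PhaseBalance` from one replicate's series.

    ``series_set`` holds at most one series per analyte (acetate, nitrate and
    CO₂ mandatory; CH₄, N₂O, N₂ and ammonium optional, treated as zero with a
    warning when absent). N₂O and N₂ changes are converted to N-mol (×2).
    """
    if isinstance(series_set, Mapping):
        by_analyte = dict(series_set)
    else:
        by_analyte = {}
        for s in series_set:
            if s.analyte in by_analyte:
                raise ValueError(
                    f"multiple series for analyte {s.analyte!r}; "
                    "phase_balance expects one replicate"
                )
            by_analyte[s.analyte] = s

    missing = [a for a in MANDATORY_ANALYTES if a not in by_analyte]
    if missing:
        raise ValueError(f"missing mandatory analytes: {missing}")

    events = list(events)

    def change(analyte: str) -> NetChange | None:
        s = by_analyte.get(analyte)
        if s is None:
            warnings.warn(
                f"no {analyte} series; its delta is taken as 0", stacklevel=2
            )
            return None
        return net_change(s, events, phase)

    nc_ch4 = change("CH4")
    nc_n2o = change("N2O")
    nc_n2 = change("N2")
    nc_nh4 = change("ammonium")
    return PhaseBalance(
        phase=phase,
        delta_acetate=net_change(by_analyte["acetate"], events, phase).consumption,
        delta_no3_n=net_change(by_analyte["nitrate"], events, phase).consumption,
        delta_co2_c=net_change(by_analyte["CO2"], events, phase).net,
        delta_ch4_c=nc_ch4.net if nc_ch4 else 0.0,
        delta_n2o_n=2.0 * nc_n2o.net if nc_n2o else 0.0,
        delta_n2_n=2.0 * nc_n2.net if nc_n2 else 0.0,
        delta_nh4_n=nc_nh4.net if nc_nh4 else 0.0,
    )


def rate(
    series: ChemSeries,
    events: Iterable[SupplementationEvent],
    window: Phase | tuple[float, float],
) -> Rate:
    """Refeed-corrected per-day consumption/production over ``window``."""
    if isinstance(window, tuple):
        window = Phase("window", *window)
    if window.length <= 0:
        raise ValueError("zero-length window")
    n_inside = int(
        np.sum((series.days >= window.start_day) & (series.days <= window.end_day))
    )
    if n_inside < 2:
        raise ValueError("window must contain at least two measurements")
    nc = net_change(series, events, window)
    return Rate(
        net=nc.net / window.length,
        consumption=nc.consumption / window.length,
        production=nc.production / window.length,
    )
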