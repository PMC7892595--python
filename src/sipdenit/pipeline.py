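"""High-level workflows tying the modules together.

These are the entry points the command line uses: chemistry series →
per-replicate phase balances → mean ± SD recovery report, and fractioned
OTU counts → three heavy-vs-light contrasts → labeled-taxon call.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .chem_timeseries import (
    ChemSeries,
    Phase,
    PhaseBalance,
    SupplementationEvent,
    phase_balance,
)
from .community_enrichment import LabeledCall, call_labeled, enrichment_test
from .sip_fractions import FractionedCounts
from .stoich_balance import (
    StoichiometryTable,
    carbon_recovery,
    electron_balance,
    n2o_index,
    nitrogen_recovery,
)

__all__ = ["replicate_balances", "recovery_summary", "sip_call"]


def replicate_balances(
    series: Iterable[ChemSeries],
    events: Iterable[SupplementationEvent],
    phases: Iterable[Phase],
    treatment: str | None = None,
) -> dict[tuple[str, str, str], PhaseBalance]:
    """Per-(treatment, replicate, phase) balances from a mixed series list."""
    series = list(series)
    events = list(events)
    groups: dict[tuple[str, str], dict[str, ChemSeries]] = {}
    for s in series:
        if treatment is not None and s.treatment != treatment:
            continue
        groups.setdefault((s.treatment, s.replicate), {})[s.analyte] = s
    out = {}
    for (trt, rep), by_analyte in sorted(groups.items()):
        for phase in phases:
            out[(trt, rep, phase.name)] = phase_balance(by_analyte, events, phase)
    return out


def recovery_summary(
    balances: dict[tuple[str, str, str], PhaseBalance],
    stoich: StoichiometryTable | None = None,
) -> pd.DataFrame:
    """Mean ± SD recoveries per (treatment, phase), over replicates.

    Recoveries are computed per replicate first and then averaged, so the
    summary reflects replicate-to-replicate variability of the derived
    quantities rather than of pooled raw points.
    """
    stoich = stoich or StoichiometryTable()
    rows = []
    for (trt, rep, phase_name), bal in balances.items():
        c = carbon_recovery(bal, stoich)
        n = nitrogen_recovery(bal)
        e = electron_balance(bal, stoich)
        idx = n2o_index(max(bal.delta_n2o_n, 0.0), max(bal.delta_n2_n, 0.0))
        rows.append(
            {
                "treatment": trt,
                "replicate": rep,
                "phase": phase_name,
                "delta_acetate": bal.delta_acetate,
                "delta_no3_n": bal.delta_no3_n,
                "delta_co2_c": bal.delta_co2_c,
                "c_recovery_co2": c.per_product_percent["CO2_C"],
                "c_recovery_total": c.total_percent,
                "n_recovery_n2o": n.per_product_percent["N2O_N"],
                "n_recovery_n2": n.per_product_percent["N2_N"],
                "n_recovery_nh4": n.per_product_percent["NH4_N"],
                "e_recovery_n2o": e.per_product_percent["N2O_N"],
                "e_recovery_n2": e.per_product_percent["N2_N"],
                "e_recovery_nh4": e.per_product_percent["NH4_N"],
                "n2o_index": np.nan if idx is None else idx,
            }
        )
    per_rep = pd.DataFrame(rows)
    value_cols = [
        c for c in per_rep.columns if c not in ("treatment", "replicate", "phase")
    ]
    return (
        per_rep.groupby(["treatment", "phase"])[value_cols]
        .agg(["mean", "std"])
        .reset_index()
    )


def sip_call(
    fc: FractionedCounts,
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int | None = None,
    treatments: tuple[str, str, str] = ("13C", "12C", "t0"),
    use_adjusted: bool = True,
) -> LabeledCall:
    """Heavy-vs-light enrichment in each treatment, then the labeled call.

    For each treatment the heavy- and light-window fraction samples are
    contrasted; unassigned fractions are excluded. The labeled set contains
    OTUs heavy-enriched in the first (labeled) treatment only.
    """
    results = {}
    for i, trt in enumerate(treatments):
        heavy = fc.samples_with_label(trt, "heavy")
        light = fc.samples_with_label(trt, "light")
        if len(heavy) < 2 or len(light) < 2:
            raise ValueError(
                f"treatment {trt!r} needs >=2 heavy and >=2 light samples, "
                f"found {len(heavy)}/{len(light)}"
            )
        results[trt] = enrichment_test(
            fc.subset(heavy),
            fc.subset(light),
            n_perm=n_perm,
            seed=None if seed is None else seed + i,
        )
    labeled_trt, unlabeled_trt, t0_trt = treatments
    return call_labeled(
        results[labeled_trt],
        results[unlabeled_trt],
        results[t0_trt],
        alpha=alpha,
        use_adjusted=use_adjusted,
    )
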