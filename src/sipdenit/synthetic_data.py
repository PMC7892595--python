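"""Synthetic microcosm chemistry and SIP count data with known truth.

Two generators emulate the study design end to end so that every pipeline
stage can be tested against a machine-readable ground truth:

* :func:`simulate_incubation` builds phase-structured acetate/nitrate
  consumption with refeeds, and produces CO₂/CH₄/N₂O/N₂/NH₄⁺ in exact
  stoichiometric proportion to configured per-phase recovery targets before
  Gaussian noise is added. The noise-free recoveries are stored in the
  truth record.
* :func:`simulate_gradient_counts` draws Dirichlet-multinomial OTU counts
  across 10 buoyant-density fractions per gradient, with planted
  acetate-assimilator OTUs whose rRNA mass is redistributed into the heavy
  window in the ¹³C treatment only.

Both generators are deterministic under a fixed seed; changing only the
seed changes noise, not the noise-free structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_timeseries import ChemSeries, Phase, SupplementationEvent, default_phases
from .isotope_tracing import IsotopeConfig, IsotopologueProfile, atom_fraction_13c
from .sip_fractions import FractionedCounts, GradientWindows

__all__ = [
    "IncubationScenario",
    "SipScenario",
    "simulate_incubation",
    "simulate_gradient_counts",
    "simulate_isotopologues",
    "simulate_correlated_counts",
]


@dataclass(frozen=True)
class IncubationScenario:
    """Configuration of a synthetic anoxic microcosm incubation.

    Doses are bulk-slurry µM. ``target_c_recovery`` is the per-phase % of
    consumed acetate-C appearing as CO₂-C; ``target_n_split`` holds the
    per-phase fractions of consumed nitrate-N routed to (N₂O-N, N₂-N,
    NH₄⁺-N) — the N₂O entry may be negative in a later phase to model net
    reduction of previously accumulated N₂O. ``target_ch4_c`` is µM CH₄-C
    produced per phase (traces by default).
    """

    endogenous_no3: float = 300.0
    acetate_dose: float = 400.0
    acetate_refeed_dose: float | None = None  # defaults to acetate_dose
    n_refeeds: int = 3
    acetate_refeed_days: tuple[float, ...] = (11.0, 13.0, 14.0)
    nitrate_refeed: float = 600.0
    nitrate_refeed_days: tuple[float, ...] = (6.0, 11.0)
    phase_boundaries: tuple[float, ...] = (0.0, 6.0, 15.0)
    target_c_recovery: tuple[float, ...] = (56.0, 83.0)
    target_n_split: tuple[tuple[float, float, float], ...] = (
        (0.12, 0.33, 0.04),
        (-0.006, 0.434, 0.0),
    )
    target_ch4_c: tuple[float, ...] = (2.0, 0.0)
    noise_sd: float = 10.0
    treatments: tuple[str, ...] = ("13C", "12C")
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.endogenous_no3 <= 0 or self.acetate_dose <= 0:
            raise ValueError("doses must be positive")
        if len(self.acetate_refeed_days) != self.n_refeeds:
            raise ValueError("need one refeed day per refeed")
        n_phases = len(self.phase_boundaries) - 1
        for name in ("target_c_recovery", "target_n_split", "target_ch4_c"):
            if len(getattr(self, name)) != n_phases:
                raise ValueError(f"{name} must have one entry per phase")
        for split in self.target_n_split:
            if sum(split) > 1.0 + 1e-12:
                raise ValueError("N-split fractions must sum to <= 1")

    @property
    def refeed_dose(self) -> float:
        return (
            self.acetate_dose
            if self.acetate_refeed_dose is None
            else self.acetate_refeed_dose
        )

    @property
    def phases(self) -> list[Phase]:
        return default_phases(self.phase_boundaries)


def study_scenario(noise_sd: float = 0.0, seed: int = 0) -> IncubationScenario:
    """Scenario whose targets encode the incubation study's phase balances.

    Phase I (days 0–6) consumes 111 µM acetate and 215 µM nitrate-N,
    yielding 124 µM CO₂-C, 2 µM CH₄-C, 25/71/8 µM N as N₂O/N₂/NH₄⁺; phase
    II (days 6–15) consumes 405 µM acetate (three 135 µM refeeds) and 1200
    µM nitrate-N, yielding 669 µM CO₂-C and 498 µM N₂-N. Running the full
    chemistry pipeline on the noise-free output reproduces the study's
    integer recoveries (56% C and 72% of electrons to N₂ in phase I, 83%
    and 93% in phase II).
    """
    return IncubationScenario(
        endogenous_no3=215.0,
        acetate_dose=111.0,
        acetate_refeed_dose=135.0,
        n_refeeds=3,
        acetate_refeed_days=(6.0, 11.0, 13.0),
        nitrate_refeed=600.0,
        nitrate_refeed_days=(6.0, 11.0),
        phase_boundaries=(0.0, 6.0, 15.0),
        target_c_recovery=(100.0 * 124.0 / 222.0, 100.0 * 669.0 / 810.0),
        target_n_split=(
            (25.0 / 215.0, 71.0 / 215.0, 8.0 / 215.0),
            (0.0, 498.0 / 1200.0, 0.0),
        ),
        target_ch4_c=(2.0, 0.0),
        noise_sd=noise_sd,
        seed=seed,
    )


def _piecewise_consumption(
    grid: np.ndarray,
    initial: float,
    refeeds: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Concentration and cumulative-consumption trajectories on ``grid``.

    The pool starts at ``initial`` and is consumed linearly to zero at the
    next refeed day (or the end of the grid). At a refeed day the recorded
    concentration is the *pre-refeed* value (zero), matching the sampling
    convention the event-aware balance assumes: the added amount is logged
    in the event record, not in the measurement.
    """
    t_end = grid[-1]
    knots = [0.0] + [d for d, _ in refeeds if d < t_end] + [t_end]
    amounts = [initial] + [a for d, a in refeeds if d < t_end]
    conc = np.zeros_like(grid)
    consumed = np.zeros_like(grid)
    cum = 0.0
    for k in range(len(knots) - 1):
        a, b = knots[k], knots[k + 1]
        amt = amounts[k]
        sel = (grid >= a) & (grid <= b) if k == 0 else (grid > a) & (grid <= b)
        frac = (grid[sel] - a) / (b - a)
        conc[sel] = amt * (1.0 - frac)
        consumed[sel] = cum + amt * frac
        cum += amt
    return conc, consumed


def _phase_index(scn: IncubationScenario, t: float) -> int:
    b = scn.phase_boundaries
    for k in range(len(b) - 1):
        if t <= b[k + 1]:
            return k
    return len(b) - 2


def _check_feasibility(scn: IncubationScenario, grid: np.ndarray) -> None:
    """Refuse scenarios whose N/CH₄ targets demand more electrons than full
    acetate oxidation could supply (8 e⁻ per acetate)."""
    _, ac_cum = _piecewise_consumption(
        grid,
        scn.acetate_dose,
        [(d, scn.refeed_dose) for d in scn.acetate_refeed_days],
    )
    _, no3_cum = _piecewise_consumption(
        grid,
        scn.endogenous_no3,
        [(d, scn.nitrate_refeed) for d in scn.nitrate_refeed_days],
    )
    for k, phase in enumerate(scn.phases):
        a = np.interp(phase.end_day, grid, ac_cum) - np.interp(
            phase.start_day, grid, ac_cum
        )
        n = np.interp(phase.end_day, grid, no3_cum) - np.interp(
            phase.start_day, grid, no3_cum
        )
        f_n2o, f_n2, f_nh4 = scn.target_n_split[k]
        demand = (
            4.0 * max(f_n2o, 0.0) * n
            + 5.0 * f_n2 * n
            + 8.0 * f_nh4 * n
            + 8.0 * scn.target_ch4_c[k]
        )
        supply = 8.0 * a
        if demand > supply + 1e-9:
            raise ValueError(
                f"infeasible targets in phase {phase.name}: electron demand "
                f"{demand:.0f} µM e⁻ exceeds supply {supply:.0f} µM e⁻"
            )


def simulate_incubation(
    scenario: IncubationScenario,
) -> tuple[list[ChemSeries], list[SupplementationEvent], dict]:
    """Generate chemistry series, the refeed log, and a truth record.

    The truth record holds, per phase, the noise-free deltas and the
    recoveries implied by the configured targets (what the analysis
    pipeline should reproduce).
    """
    scn = scenario
    grid = np.arange(0.0, scn.phase_boundaries[-1] + 0.5, 1.0)
    extra = [d for d in (*scn.acetate_refeed_days, *scn.nitrate_refeed_days)]
    grid = np.unique(np.concatenate([grid, extra, list(scn.phase_boundaries)]))
    _check_feasibility(scn, grid)

    ac_conc, ac_cum = _piecewise_consumption(
        grid,
        scn.acetate_dose,
        [(d, scn.refeed_dose) for d in scn.acetate_refeed_days],
    )
    no3_conc, no3_cum = _piecewise_consumption(
        grid,
        scn.endogenous_no3,
        [(d, scn.nitrate_refeed) for d in scn.nitrate_refeed_days],
    )

    # cumulative products, driven phase-wise by cumulative consumption
    co2 = np.zeros_like(grid)
    ch4 = np.zeros_like(grid)
    n2o_n = np.zeros_like(grid)
    n2_n = np.zeros_like(grid)
    nh4_n = np.zeros_like(grid)
    for i, t in enumerate(grid[1:], start=1):
        k = _phase_index(scn, t)
        d_ac = ac_cum[i] - ac_cum[i - 1]
        d_no3 = no3_cum[i] - no3_cum[i - 1]
        phase = scn.phases[k]
        frac_of_phase = (grid[i] - grid[i - 1]) / phase.length
        f_n2o, f_n2, f_nh4 = scn.target_n_split[k]
        co2[i] = co2[i - 1] + scn.target_c_recovery[k] / 100.0 * 2.0 * d_ac
        ch4[i] = ch4[i - 1] + scn.target_ch4_c[k] * frac_of_phase
        n2o_n[i] = n2o_n[i - 1] + f_n2o * d_no3
        n2_n[i] = n2_n[i - 1] + f_n2 * d_no3
        nh4_n[i] = nh4_n[i - 1] + f_nh4 * d_no3
    if np.any(n2o_n < -1e-9):
        raise ValueError("N2O consumption target exceeds accumulated N2O")
    n2o_n = np.maximum(n2o_n, 0.0)

    ph = np.where(grid <= 11.0, 4.4, 4.4 + (5.5 - 4.4) * (grid - 11.0) / 4.0)
    ph = np.minimum(ph, 5.5)

    trajectories = {
        "acetate": ac_conc,
        "nitrate": no3_conc,
        "CO2": co2,
        "CH4": ch4,
        "N2O": n2o_n / 2.0,  # µM molecules
        "N2": n2_n / 2.0,
        "ammonium": nh4_n,
        "pH": ph,
    }

    rng = np.random.default_rng(scn.seed)
    series: list[ChemSeries] = []
    events: list[SupplementationEvent] = []
    for treatment in scn.treatments:
        for rep in range(1, scn.n_replicates + 1):
            for analyte, traj in trajectories.items():
                # day 0 is the prepared initial state (known doses, no
                # products yet), not a measurement: noise applies to t > 0
                noise_mask = (grid > 0).astype(float)
                if analyte == "pH":
                    sd = 0.02 if scn.noise_sd else 0.0
                    vals = traj + noise_mask * rng.normal(0.0, sd, traj.shape)
                    vals = np.clip(vals, 0.0, 14.0)
                else:
                    vals = traj + noise_mask * rng.normal(
                        0.0, scn.noise_sd, traj.shape
                    )
                    vals = np.maximum(vals, 0.0)
                series.append(
                    ChemSeries(
                        treatment=treatment,
                        replicate=str(rep),
                        analyte=analyte,
                        days=grid.copy(),
                        values=vals,
                    )
                )
        for d in scn.acetate_refeed_days:
            events.append(
                SupplementationEvent(treatment, "acetate", d, scn.refeed_dose)
            )
        for d in scn.nitrate_refeed_days:
            events.append(
                SupplementationEvent(treatment, "nitrate", d, scn.nitrate_refeed)
            )

    truth: dict = {"phases": []}
    for k, phase in enumerate(scn.phases):
        def seg(cum: np.ndarray) -> float:
            return float(
                np.interp(phase.end_day, grid, cum)
                - np.interp(phase.start_day, grid, cum)
            )

        d_ac, d_no3 = seg(ac_cum), seg(no3_cum)
        d_co2, d_ch4 = seg(co2), seg(ch4)
        d_n2o, d_n2, d_nh4 = seg(n2o_n), seg(n2_n), seg(nh4_n)
        released = 4.0 * d_co2
        truth["phases"].append(
            {
                "name": phase.name,
                "delta_acetate": d_ac,
                "delta_no3_n": d_no3,
                "delta_co2_c": d_co2,
                "delta_ch4_c": d_ch4,
                "delta_n2o_n": d_n2o,
                "delta_n2_n": d_n2,
                "delta_nh4_n": d_nh4,
                "c_recovery_co2": 100.0 * d_co2 / (2.0 * d_ac),
                "n_recovery": {
                    "N2O_N": 100.0 * d_n2o / d_no3,
                    "N2_N": 100.0 * d_n2 / d_no3,
                    "NH4_N": 100.0 * d_nh4 / d_no3,
                },
                "e_recovery": {
                    "N2O_N": 100.0 * 4.0 * d_n2o / released,
                    "N2_N": 100.0 * 5.0 * d_n2 / released,
                    "NH4_N": 100.0 * 8.0 * d_nh4 / released,
                    "CH4": 100.0 * 8.0 * d_ch4 / released,
                },
            }
        )
    return series, events, truth


@dataclass(frozen=True)
class SipScenario:
    """Configuration of a synthetic rRNA-SIP gradient experiment.

    ``labeled_otus`` maps a planted assimilator's OTU id to its heavy-shift
    fraction: the proportion of that OTU's rRNA mass moved from its
    unlabeled buoyant-density profile into the heavy-window profile in ¹³C
    samples. The default plants exactly one assimilator among 200 OTUs,
    mirroring the single-taxon outcome the design is meant to resolve.
    """

    n_otus: int = 200
    dirichlet_alpha: float | np.ndarray = 0.5
    replicate_concentration: float = 500.0
    labeled_otus: dict[str, float] = field(
        default_factory=lambda: {"OTU_001": 0.9}
    )
    labeled_baseline: float = 0.05  # baseline community share per labeled OTU
    depth: int = 10_000
    n_replicates: int = 3
    treatments: tuple[str, ...] = ("t0", "12C", "13C")
    fraction_densities: tuple[float, ...] = tuple(
        np.round(np.linspace(1.76, 1.83, 10), 5)
    )
    light_center: float = 1.777
    light_sd: float = 0.008
    heavy_center: float = 1.8215
    heavy_sd: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        dens = np.asarray(self.fraction_densities)
        if np.any(np.diff(dens) <= 0):
            raise ValueError("fraction densities must be strictly increasing")
        for otu, s in self.labeled_otus.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"shift fraction for {otu} must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")

    def otu_ids(self) -> list[str]:
        return [f"OTU_{i + 1:03d}" for i in range(self.n_otus)]


def _density_profile(densities: np.ndarray, center: float, sd: float) -> np.ndarray:
    w = np.exp(-0.5 * ((densities - center) / sd) ** 2)
    return w / w.sum()


def simulate_gradient_counts(
    scenario: SipScenario,
) -> tuple[FractionedCounts, dict]:
    """Generate fraction-resolved OTU counts plus the planted truth.

    Per (treatment, replicate), a replicate composition is drawn around a
    scenario-level baseline; each OTU's mass is spread over the 10
    fractions by its buoyant-density profile (unlabeled for everything
    except the labeled OTUs in the ¹³C treatment, whose profile is shifted
    toward the heavy window by their shift fraction); each fraction sample
    is a multinomial draw at the configured depth.
    """
    scn = scenario
    rng = np.random.default_rng(scn.seed)
    densities = np.asarray(scn.fraction_densities)
    n_frac = densities.size
    otus = scn.otu_ids()

    alpha = scn.dirichlet_alpha
    alpha_vec = (
        np.full(scn.n_otus, float(alpha)) if np.isscalar(alpha) else np.asarray(alpha)
    )
    baseline = rng.dirichlet(alpha_vec)
    # labeled OTUs get a fixed baseline share: the assimilator the design
    # resolves is an established community member, not a rare-taxon lottery
    labeled_idx = [otus.index(o) for o in scn.labeled_otus]
    if labeled_idx:
        others = np.setdiff1d(np.arange(scn.n_otus), labeled_idx)
        baseline[labeled_idx] = 0.0
        total_labeled = scn.labeled_baseline * len(labeled_idx)
        if total_labeled >= 1.0:
            raise ValueError("labeled baseline shares must sum to < 1")
        baseline[others] *= (1.0 - total_labeled) / baseline[others].sum()
        baseline[labeled_idx] = scn.labeled_baseline

    w_light = _density_profile(densities, scn.light_center, scn.light_sd)
    w_heavy = _density_profile(densities, scn.heavy_center, scn.heavy_sd)

    profiles = {}  # (treatment-kind, otu index) -> fraction weights
    shifts = np.zeros(scn.n_otus)
    for otu, s in scn.labeled_otus.items():
        shifts[otus.index(otu)] = s

    counts: dict[str, np.ndarray] = {}
    meta_rows = []
    for treatment in scn.treatments:
        labeled_here = treatment == "13C"
        for rep in range(1, scn.n_replicates + 1):
            p_rep = rng.dirichlet(scn.replicate_concentration * baseline + 1e-9)
            # OTU × fraction mass matrix
            w = np.tile(w_light, (scn.n_otus, 1))
            if labeled_here:
                w = (1.0 - shifts)[:, None] * w_light + shifts[:, None] * w_heavy
            mass = p_rep[:, None] * w
            for f in range(n_frac):
                comp = mass[:, f] / mass[:, f].sum()
                sid = f"{treatment}_{rep}_F{f + 1}"
                counts[sid] = rng.multinomial(scn.depth, comp)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "treatment": treatment,
                        "replicate": str(rep),
                        "fraction_index": f + 1,
                        "buoyant_density": float(densities[f]),
                    }
                )

    counts_df = pd.DataFrame(counts, index=otus)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    taxonomy = pd.Series(
        {
            otu: (
                "Bacteria;Proteobacteria;Gammaproteobacteria;Burkholderiales;"
                "Burkholderiaceae;Burkholderia-Caballeronia-Paraburkholderia"
                if otu in scn.labeled_otus
                else f"Bacteria;Unclassified;Genus_{i + 1}"
            )
            for i, otu in enumerate(otus)
        }
    )
    fc = FractionedCounts(counts=counts_df, sample_meta=meta, taxonomy=taxonomy)
    truth = {
        "labeled_otus": dict(scn.labeled_otus),
        "baseline_composition": baseline,
        "light_profile": w_light,
        "heavy_profile": w_heavy,
        "densities": densities,
    }
    return fc, truth


def simulate_isotopologues(
    a_src_profile: IsotopologueProfile,
    mix_fraction: float | np.ndarray,
    config: IsotopeConfig | None = None,
) -> float | np.ndarray:
    """Forward two-pool mixing: observed ¹³C atom fraction(s) of CO₂.

    The labeled-source atom fraction is computed from the supplied acetate
    isotopologue profile (honoring its isotopic dilution); endogenous
    carbon sits at natural abundance.
    """
    config = config or IsotopeConfig()
    f = np.asarray(mix_fraction, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("mix_fraction must lie in [0, 1]")
    a_src = atom_fraction_13c(a_src_profile, config)
    a_obs = f * a_src + (1.0 - f) * config.a_nat
    return float(a_obs) if np.isscalar(mix_fraction) else a_obs


def simulate_correlated_counts(
    n_otus: int = 50,
    n_samples: int = 200,
    depth: int = 50_000,
    corr_pairs: dict[tuple[int, int], float] | None = None,
    log_mean_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Counts from a log-normal basis with known pairwise correlations.

    Basis abundances are exp of a multivariate normal whose correlation
    matrix is the identity except for the entries in ``corr_pairs``
    (default: pair (0, 1) at 0.8). Samples are multinomial draws from the
    closed composition. Returns the OTU × sample table and the true basis
    (log-scale) correlation matrix — the quantity a compositionality-aware
    estimator should recover.
    """
    corr_pairs = corr_pairs if corr_pairs is not None else {(0, 1): 0.8}
    rng = np.random.default_rng(seed)
    sigma = np.eye(n_otus)
    for (i, j), r in corr_pairs.items():
        sigma[i, j] = sigma[j, i] = r
    mu = rng.normal(0.0, log_mean_sd, n_otus)
    # correlated (truth-bearing) OTUs sit at typical abundance: log-ratio
    # variances of rare taxa are dominated by count noise, not covariation
    for pair in corr_pairs:
        for i in pair:
            mu[i] = 0.0
    chol = np.linalg.cholesky(sigma)
    z = mu + rng.standard_normal((n_samples, n_otus)) @ chol.T
    basis = np.exp(z)
    comp = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, comp[s]) for s in range(n_samples)])
    table = pd.DataFrame(
        counts.T,
        index=[f"OTU_{i + 1:03d}" for i in range(n_otus)],
        columns=[f"S{s + 1}" for s in range(n_samples)],
    )
    return table, sigma
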