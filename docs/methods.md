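# Methods

This note documents the models, estimators and numerical choices behind
`sipdenit`, and what the synthetic generators do and do not emulate.

## Chemistry balances

Concentration series are bulk-slurry µM at strictly increasing days; gas ↔
liquid partitioning is assumed already folded into the reported values.
Supplementation (refeeds) comes from an explicit event log — amounts and
days — never from jump detection, which is ambiguous under noise.

**Net change and gross flows.** A phase is split into *inter-event
segments*: breakpoints are the phase boundaries plus any event days inside
the phase, with concentrations linearly interpolated at breakpoints that
fall between measurements. Gross consumption is the sum over segments of
the positive part of (start value + amount supplemented at the start
day − end value); gross production is the symmetric negative part; net
change = production − consumption. Summing declines between *every*
measurement would accumulate measurement noise as spurious flow (each
wiggle counts once as consumption and once as production), so only
segment-boundary values enter. The cost is that within-segment
non-monotonicity (e.g., a production hump entirely inside one segment) is
seen only as its net effect; phase boundaries in this design sit at the
turning points (nitrate depletion, refeeds), where that matters least.
Events at exactly a phase's end day belong to the following phase.

**Phase balances.** Acetate and nitrate enter as gross consumption, the
products as net change. N₂O and N₂ are converted to N-mol (×2 per
molecule); the N₂O delta is signed, because accumulated N₂O can be
consumed in a later phase when N₂O reductase activity develops. Default
phases are I = days 0–6 and II = days 6–15, overridable. Replicate
summaries (mean ± SD) are computed on per-replicate balances, not on
pooled raw points, so they reflect the spread of the derived quantities.

## Stoichiometry

Coefficients are standard redox bookkeeping for acetate-driven nitrate
respiration: 2 C per acetate; 4 e⁻ released per acetate C-mol oxidized to
CO₂ (C oxidation state 0 → +4); 4/5/8 e⁻ accepted per N to N₂O/N₂/NH₄⁺;
8 e⁻ per CH₄ formed from CO₂. The electron-release denominator is
4 e⁻ × ΔCO₂-C rather than 8 e⁻ × Δacetate: carbon routed to biomass is
assimilated, not oxidized, and contributes no electrons. CH₄ is counted as
a hydrogenotrophic sink by default; an acetoclastic/neutral mode (0 e⁻) is
available because trace methane's pathway is not identifiable from the
balances alone. NO₂⁻ (2 e⁻ per N) is present in the coefficient table but
not a default sink, as no nitrite accumulation is modeled. Report rounding
is nearest integer, halves away from zero; raw values are always kept.

## Isotope arithmetic

Acetate isotopologues at m/z 59/60/61 carry 0/1/2 ¹³C of 2 carbons. Atom
fraction of the pool: `a = f61 + 0.5·f60 + a_nat·f59` with natural
abundance `a_nat = 0.011`. The source atom fraction `a_src` is computed
from the measured day-1 profile rather than assumed 0.99, honoring the
isotopic dilution of the supplement. CO₂ observations are treated as atom
fractions and inverted through the two-pool mixing model
`f = (a_obs − a_nat)/(a_src − a_nat)`; observations outside the
identifiable interval by more than 1e-6 are clipped with a warning.
Whether instrument-reported "¹³C proportions" are atom-% or molar
¹³CO₂/(¹²CO₂+¹³CO₂) is numerically immaterial for a 1-carbon molecule and
documented as an assumption. The assimilation partition is simply
100 − (% oxidized); values above 100 % flag dominant endogenous-carbon
mineralization rather than an error.

## Gradient fractions

Heavy/light windows (1.818–1.824 and 1.770–1.784 g ml⁻¹) have inclusive
bounds; densities between windows remain "unassigned" and are excluded
from contrasts rather than force-assigned. Pairwise pooling (fractions
1–2, 3–4, …, 9–10) sums counts, averages the pair's densities, and
re-classifies the pool; both pooled and unpooled analysis paths are
supported.

## Differential enrichment and the labeled call

The heavy-vs-light test is a label-permutation test on
median-of-ratios-normalized counts. The statistic is
`|log2((mean_H + 0.5)/(mean_L + 0.5))|` on normalized per-sample
abundances. When the number of distinct heavy/light labelings is ≤ 5000
the null is enumerated exactly (p ≥ 1/N by construction); otherwise
10,000 random labelings are drawn by default and the add-one estimator
`(1 + k)/(B + 1)` keeps p in (0, 1]. P-values are Benjamini–Hochberg
adjusted over tested OTUs; all-zero OTUs are excluded and counted.

*Size-factor robustness.* Median-of-ratios needs a reference set of OTUs
observed in every sample. When fewer than 5 such OTUs exist — the typical
situation when heavy fractions are near-monocultures of the labeled
taxon — a median over that tiny set is not a location estimate (in the
extreme it would normalize the one shifted taxon into flatness), so the
normalization falls back to relative library size.

An OTU is called ¹³C-labeled iff it is significantly heavy-enriched
(positive log2fc, adjusted p < α = 0.05) in the labeled treatment and not
significantly heavy-enriched in either the unlabeled treatment or the
pre-incubation samples. Adjusted p is the default (the conservative
reading of an unqualified "p < 0.05" threshold); raw-p mode is exposed.
Samples are treated as unpaired; a within-replicate pairing mode is out of
scope. Note a statistical floor: with h heavy and l light samples, an
exact permutation p cannot fall below 1/C(h+l, h), so designs with very
few fraction samples per side cannot reach BH-adjusted significance for a
*lone* enriched taxon no matter how strong its enrichment; in practice a
strongly labeled gradient also strongly depletes every other taxon in the
heavy window, and those co-discoveries restore the adjusted call (this is
exactly what the default synthetic scenario produces).

## Diversity and ordination

Inverse Simpson (1/Σp²) and Good's coverage (100·(1 − singletons/reads))
follow their textbook definitions. The CI on inverse Simpson is a
bootstrap percentile interval (2.5/97.5) from multinomial read resampling
at the observed depth — chosen because no closed-form interval is
standard. Bray–Curtis runs on total-sum-scaled abundances by default.
PCoA is classical scaling (double-centering + eigendecomposition);
negative eigenvalues of non-Euclidean dissimilarities are reported as-is,
with no Lingoes/Cailliez correction, and percent variance is taken over
the positive eigenvalues only.

## Co-occurrence network

Basis correlations are inferred from the log-ratio variation matrix
t_ij = Var(log(x_i/x_j)) under the sparse-correlation approximation
Σⱼ t_ij ≈ (m−2)ω_i² + Σⱼ ω_j², solved as a linear system; pairs with
|ρ| above 0.1 are iteratively excluded (up to 10 rounds) and the system
re-solved, stopping early if exclusion makes it singular. Counts become
compositions via Dirichlet posterior draws with a uniform prior; the
estimate is the element-wise median over 20 inner iterations (all defaults
exposed). OTUs present in < 30 % of samples are filtered first: their
log-ratio variances are dominated by count noise. Significance is a
permutation bootstrap (each OTU's counts permuted independently across
samples) with add-one p-values; edges require |ρ| ≥ 0.3 and p < 0.05 by
default — thresholds are conventions, exposed as flags.

## Synthetic data

**Incubation generator.** Acetate and nitrate pools decline linearly to
zero between supplementation events; products accrue in exact
stoichiometric proportion to per-phase targets (% of acetate-C to CO₂,
fractions of NO₃⁻-N to N₂O/N₂/NH₄⁺ — the N₂O fraction may be negative in
a later phase to model net N₂O reduction). Defaults mirror the study
design: ~300 µM endogenous nitrate, 400 µM acetate refed three times,
600 µM nitrate refeeds, phases 0/6/15 d. A scenario is rejected up front
if its targets demand more electrons than full oxidation of the consumed
acetate could supply (8 e⁻ per acetate). Noise is additive Gaussian on
concentrations (floored at 0) applied to t > 0 samples only — day 0 is
the prepared initial state (known doses, no products), not a measurement.
`study_scenario()` encodes the reference phase balances (111/405 µM
acetate, 215/1200 µM NO₃⁻-N, 124/669 µM CO₂-C, 25/71/8 and 498 µM N
products) so the noise-free round-trip reproduces the integer recoveries
56/83 % (C), 72/93 % (e⁻ → N₂) and 12/33/4 % (N). At these signal sizes
(tens of µM against 10 µM noise), single-replicate recoveries scatter by
5–20 percentage points; round-trip accuracy is therefore assessed on
means over replicates and seeds, where residual bias (from flooring noisy
near-zero concentrations) stays within ~2 points.

**Gradient generator.** Each OTU's rRNA mass is spread over 10 fractions
(densities 1.76–1.83 g ml⁻¹) by a Gaussian density profile centered in
the light region; labeled OTUs have a configured share of their mass
moved to a heavy-window profile in the ¹³C treatment only. Replicate
compositions are Dirichlet-resampled around a scenario baseline, and each
fraction sample is a multinomial draw at fixed depth (10⁴). The planted
assimilator holds a fixed 5 % baseline share: the question the design
answers is *which established community member takes up the label*, not
whether a rare-taxon lottery was won. The default plants exactly one
assimilator among 200 OTUs. Not emulated: GC-content-dependent banding
(which in real gradients makes heavy fractions of *unlabeled* samples
compositionally distinct), gradient smearing, chimeras/contaminants, and
biomass differences between fractions (library depth is fixed). Passing
tests therefore show the statistical machinery recovers planted truth
under clean compositional shifts, not that real gradients are free of
these confounders.

**Correlated counts.** A log-normal basis with a specified correlation
matrix (default: one pair at 0.8), closed to compositions and sampled
multinomially; the truth is the log-scale basis correlation. The
truth-bearing OTUs sit at typical (not rare) abundance and the default
depth is 5×10⁴, so the benchmark measures estimator error rather than
count-noise attenuation, which at low depth provably biases any
log-ratio-variance estimate toward zero.

**Isotopologue generator.** Forward two-pool mixing; inverse round-trips
to 1e-12 by construction.

All generators are deterministic under a fixed seed and emit truth
records; every downstream stage has a test asserting recovery of that
truth.

## Problem sizes in the standard runs

The test suite and the acceptance script use: 1000-OTU, 5+5-sample null
communities at depth 10⁵ for type-I error; 100-OTU tables with 3
replicates × 3 fractions per side at depth 10⁴ for effect-size recovery;
20 generator seeds for the labeled call; 50 OTUs × 200 samples for the
network benchmark; and 50 seeds (×2 treatments × 3 replicates) for the
noisy chemistry round-trip. These sizes make the whole suite run in a few
seconds while keeping Monte-Carlo standard errors well inside the asserted
tolerances.

## Known limitations

* Gas/liquid partitioning, instrument calibration and headspace
  corrections are upstream of this package.
* Treatment-effect hypothesis testing on chemistry (ANOVA between
  treatments) is out of scope; balances are descriptive.
* The enrichment test does not model overdispersion parametrically; its
  validity rests on label exchangeability within a contrast.
* The comparative labeled call is only as good as its contrasts: taxa that
  band heavy for compositional reasons in *all* treatments are excluded by
  design, but taxa near the significance boundary can flicker between
  contrasts on real data.
* SparCC-style estimates are unreliable for very few OTUs (< ~10) or very
  sparse tables; the prevalence filter and the exclusion-iteration guard
  mitigate but do not remove this.
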