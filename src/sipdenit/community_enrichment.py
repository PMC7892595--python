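"""Diversity, ordination, and heavy-vs-light differential enrichment.

The differential test is a permutation test on median-of-ratios-normalized
counts: the statistic is the absolute log2 fold change between the mean
normalized abundance in heavy and in light fraction samples (with a
pseudo-count), and the null distribution comes from permuting the
heavy/light sample labels — enumerated exactly when few enough labelings
exist, Monte-Carlo sampled otherwise. P-values are Benjamini–Hochberg
adjusted across tested OTUs. A taxon is called ¹³C-labeled when it is
significantly heavy-enriched in the labeled treatment but in neither the
unlabeled treatment nor the pre-incubation samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DiversitySummary",
    "LabeledCall",
    "goods_coverage",
    "inverse_simpson",
    "diversity_table",
    "bray_curtis_matrix",
    "pcoa",
    "PCoAResult",
    "size_factors",
    "enrichment_test",
    "call_labeled",
]

EXACT_ENUMERATION_LIMIT = 5000


@dataclass(frozen=True)
class DiversitySummary:
    """Alpha-diversity numbers for one sample."""

    inverse_simpson: float
    inv_simpson_ci: tuple[float, float] | None
    goods_coverage: float
    n_reads: int
    n_otus: int


@dataclass(frozen=True)
class LabeledCall:
    """Set of OTUs called isotope-labeled, with per-contrast evidence."""

    labeled_otus: frozenset[str]
    evidence: dict[str, pd.DataFrame]


def goods_coverage(counts: np.ndarray | list[int]) -> float:
    """Good's coverage, 100 × (1 − singletons / reads)."""
    c = np.asarray(counts)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("empty count vector")
    total = c.sum()
    singletons = int(np.sum(c == 1))
    return 100.0 * (1.0 - singletons / total)


def inverse_simpson(
    counts: np.ndarray | list[int],
    n_boot: int = 0,
    seed: int | None = None,
) -> DiversitySummary:
    """Inverse Simpson index 1/Σpᵢ² with optional bootstrap percentile CI.

    The CI resamples reads (multinomial at the observed depth and
    composition) ``n_boot`` times and takes the 2.5/97.5 percentiles; the
    method is a pragmatic choice since no closed-form interval is standard.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    total = c.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = c / total
    d = 1.0 / np.sum(p**2)

    ci = None
    if n_boot:
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1 when a CI is requested")
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        depth = int(round(total))
        for b in range(n_boot):
            res = rng.multinomial(depth, p)
            q = res[res > 0] / depth
            boots[b] = 1.0 / np.sum(q**2)
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return DiversitySummary(
        inverse_simpson=float(d),
        inv_simpson_ci=ci,
        goods_coverage=goods_coverage(c.astype(int)),
        n_reads=int(total),
        n_otus=int(c.size),
    )


def diversity_table(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-(treatment, label) mean ± SD diversity table.

    Summarizes sample-wise inverse Simpson values (with bootstrap CIs) into
    the usual treatment × fraction layout with columns
    ``inv_simpson, inv_simpson_sd, lci, hci, goods_coverage``.
    """
    rows = []
    for sid in counts.columns:
        meta = sample_meta.loc[sid]
        summ = inverse_simpson(counts[sid].to_numpy(), n_boot=n_boot, seed=seed)
        rows.append(
            {
                "sample_id": sid,
                "treatment": meta["treatment"],
                "label": meta.get("label", "unassigned"),
                "inv_simpson": summ.inverse_simpson,
                "lci": summ.inv_simpson_ci[0] if summ.inv_simpson_ci else np.nan,
                "hci": summ.inv_simpson_ci[1] if summ.inv_simpson_ci else np.nan,
                "goods_coverage": summ.goods_coverage,
            }
        )
    per_sample = pd.DataFrame(rows).set_index("sample_id")
    return (
        per_sample.groupby(["treatment", "label"])
        .agg(
            inv_simpson=("inv_simpson", "mean"),
            inv_simpson_sd=("inv_simpson", "std"),
            lci=("lci", "mean"),
            hci=("hci", "mean"),
            goods_coverage=("goods_coverage", "mean"),
        )
        .reset_index()
    )


def bray_curtis_matrix(
    table: pd.DataFrame, normalization: str = "tss"
) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarities between samples.

    ``table`` is OTUs × samples. Total-sum scaling (relative abundance) is
    applied by default; pass ``normalization="none"`` to use raw counts.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two samples")
    totals = table.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    if normalization == "tss":
        mat = (table / totals).to_numpy().T
    elif normalization == "none":
        mat = table.to_numpy().T.astype(float)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    d = squareform(pdist(mat, metric="braycurtis"))
    return pd.DataFrame(d, index=table.columns, columns=table.columns)


@dataclass(frozen=True)
class PCoAResult:
    """Classical-scaling ordination of a dissimilarity matrix.

    ``coordinates`` has one column per axis with a positive eigenvalue;
    ``percent_variance`` is each positive eigenvalue over the positive sum.
    Negative eigenvalues (possible for non-Euclidean dissimilarities) are
    reported in ``eigenvalues`` rather than corrected or dropped.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    percent_variance: np.ndarray


def pcoa(dissimilarity: pd.DataFrame | np.ndarray) -> PCoAResult:
    """Principal coordinates analysis by double-centering + eigendecomposition."""
    if isinstance(dissimilarity, pd.DataFrame):
        labels = list(dissimilarity.index)
        d = dissimilarity.to_numpy(dtype=float)
    else:
        d = np.asarray(dissimilarity, dtype=float)
        labels = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("dissimilarity must have a zero diagonal")

    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals).max(initial=1.0))
    if not pos.any():  # degenerate: all points coincide
        return PCoAResult(
            coordinates=pd.DataFrame(
                np.zeros((n, 1)), index=labels, columns=["PCo1"]
            ),
            eigenvalues=eigvals,
            percent_variance=np.zeros(1),
        )
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pct = 100.0 * eigvals[pos] / eigvals[pos].sum()
    axis_names = [f"PCo{i + 1}" for i in range(int(pos.sum()))]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axis_names),
        eigenvalues=eigvals,
        percent_variance=pct,
    )


MIN_REFERENCE_OTUS = 5


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (OTUs × samples array).

    The reference is the per-OTU geometric mean over samples, computed on
    OTUs observed in every sample; each sample's factor is the median ratio
    to that reference, rescaled to geometric mean 1. A median over fewer
    than :data:`MIN_REFERENCE_OTUS` ubiquitous OTUs is not a robust
    location estimate (in the extreme, a single reference OTU would be
    normalized into flatness), so sparse tables fall back to relative
    library size.
    """
    counts = np.asarray(counts, dtype=float)
    all_pos = np.all(counts > 0, axis=1)
    if all_pos.sum() >= MIN_REFERENCE_OTUS:
        logref = np.mean(np.log(counts[all_pos]), axis=1)
        ratios = np.log(counts[all_pos]) - logref[:, None]
        logsf = np.median(ratios, axis=0)
    else:
        libsize = counts.sum(axis=0)
        logsf = np.log(libsize)
    logsf = logsf - logsf.mean()
    return np.exp(logsf)


def _log2fc(
    norm: np.ndarray, heavy_mask: np.ndarray, pc: float
) -> np.ndarray:
    """log2((mean heavy + pc) / (mean light + pc)) per OTU; vectorized over
    the trailing axis of a (n_perm, n_samples) mask."""
    heavy_mask = np.atleast_2d(heavy_mask)
    n_h = heavy_mask.sum(axis=1)[0]
    n_l = heavy_mask.shape[1] - n_h
    mean_h = norm @ heavy_mask.T / n_h
    mean_l = norm @ (~heavy_mask).T / n_l
    return np.log2((mean_h + pc) / (mean_l + pc))


def enrichment_test(
    counts_heavy: pd.DataFrame,
    counts_light: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-OTU heavy-vs-light differential enrichment.

    Returns a DataFrame indexed like the inputs with columns ``log2fc, p,
    padj, base_mean``; OTUs with zero counts everywhere are not tested
    (NaN statistics, count in ``result.attrs["n_excluded"]``). When at most
    5,000 distinct heavy/light labelings exist the permutation null is
    enumerated exactly, otherwise ``n_perm`` random relabelings are drawn
    and the add-one estimator is used. ``result.attrs`` records the seed
    and the enumeration mode.
    """
    if not counts_heavy.index.equals(counts_light.index):
        raise ValueError("heavy and light tables must share an OTU index")
    n_h, n_l = counts_heavy.shape[1], counts_light.shape[1]
    if n_h < 2 or n_l < 2:
        raise ValueError("need at least 2 replicates per side")

    combined = pd.concat([counts_heavy, counts_light], axis=1)
    tested = combined.sum(axis=1) > 0
    n_excluded = int((~tested).sum())
    mat = combined.loc[tested].to_numpy(dtype=float)

    sf = size_factors(mat)
    norm = mat / sf

    n = n_h + n_l
    obs_mask = np.zeros(n, dtype=bool)
    obs_mask[:n_h] = True
    obs = _log2fc(norm, obs_mask, pseudocount)[:, 0]

    n_labelings = comb(n, n_h)
    if n_labelings <= EXACT_ENUMERATION_LIMIT:
        masks = np.zeros((n_labelings, n), dtype=bool)
        for i, c in enumerate(combinations(range(n), n_h)):
            masks[i, list(c)] = True
        stats = np.abs(_log2fc(norm, masks, pseudocount))
        # exact p: the observed labeling is one of the enumerated ones
        p = np.sum(stats >= np.abs(obs)[:, None] - 1e-12, axis=1) / n_labelings
        mode = "exact"
    else:
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            masks[i, rng.choice(n, size=n_h, replace=False)] = True
        stats = np.abs(_log2fc(norm, masks, pseudocount))
        exceed = np.sum(stats >= np.abs(obs)[:, None] - 1e-12, axis=1)
        p = (1.0 + exceed) / (n_perm + 1.0)
        mode = "monte-carlo"

    padj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        index=combined.index,
        columns=["log2fc", "p", "padj", "base_mean"],
        dtype=float,
    )
    out.loc[tested, "log2fc"] = obs
    out.loc[tested, "p"] = p
    out.loc[tested, "padj"] = padj
    out.loc[tested, "base_mean"] = norm.mean(axis=1)
    out.attrs.update(
        {"n_excluded": n_excluded, "mode": mode, "seed": seed, "n_perm": n_perm}
    )
    return out


def _significant_positive(
    result: pd.DataFrame, alpha: float, use_adjusted: bool
) -> pd.Series:
    pcol = result["padj"] if use_adjusted else result["p"]
    return (pcol < alpha) & (result["log2fc"] > 0)


def call_labeled(
    results_13c: pd.DataFrame,
    results_12c: pd.DataFrame,
    results_t0: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = True,
) -> LabeledCall:
    """Call isotope-labeled OTUs from three heavy-vs-light contrasts.

    An OTU is labeled iff it is significantly heavy-enriched (positive
    log2fc at ``alpha``) in the ¹³C treatment and not significantly
    heavy-enriched in either the ¹²C treatment or the pre-incubation (t₀)
    samples. Untested OTUs (NaN) are never significant.
    """
    if not (
        results_13c.index.equals(results_12c.index)
        and results_13c.index.equals(results_t0.index)
    ):
        raise ValueError("the three result sets must cover the same OTU universe")
    sig13 = _significant_positive(results_13c, alpha, use_adjusted)
    sig12 = _significant_positive(results_12c, alpha, use_adjusted)
    sig0 = _significant_positive(results_t0, alpha, use_adjusted)
    labeled = sig13 & ~sig12 & ~sig0
    return LabeledCall(
        labeled_otus=frozenset(results_13c.index[labeled]),
        evidence={"13C": results_13c, "12C": results_12c, "t0": results_t0},
    )
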